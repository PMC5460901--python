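# Methods

## Assay model

The package analyzes a heterologous odorant-receptor (OR) functional assay:
HEK293T-style cells co-transfected with an OR, a CRE-driven firefly
luciferase reporter of cAMP signaling, a constitutive *Renilla* luciferase
control, and one of four chaperone conditions — empty vector ("none"),
RTP1S, RTP2, or both. Receptor activation by an odorant raises cAMP and
therefore firefly counts; *Renilla* counts absorb well-to-well variation in
cell number and transfection efficiency.

### Normalization

Per well, `ratio = firefly / renilla`; wells with non-positive *Renilla*
signal carry no usable information and are dropped (logged, never silently).
Ratios are min-max scaled within a *normalization scope*: either one plate
(`per_plate`) or the whole batch analyzed together (`per_batch`, the
default, because condition series are routinely pooled across plates).
Exactly one well per scope anchors 0 and one anchors 1; ties at the extrema
are broken by first encounter and do not change any value. The scaling is
invariant under a common gain applied to both channels and idempotent on an
already-normalized scope. A scope whose ratios are all identical is
degenerate and rejected.

Replicate wells are summarized as mean ± SEM with the sample (n − 1)
standard deviation, matching the convention of mainstream graphing
software; identical replicates get SEM exactly 0, and singleton groups are
flagged rather than rejected.

## Dose–response and detection thresholds

Curves are assembled per (OR, condition, odorant) with the condition's
0 µM vehicle wells as baseline. Zero concentration has no position on a
log axis, so the baseline is a reference level only and never a fit point.

The Hill model `psi(c) = bottom + (top − bottom)·cⁿ/(EC50ⁿ + cⁿ)` is fitted
by least squares (`scipy.optimize.curve_fit`) on the positive-concentration
points, using replicate-level values when the curve carries them (honest
weighting: a concentration measured in triplicate contributes three
residuals). EC50 is optimized as log10(EC50); the bottom is bounded within
0.1 normalized units of the measured baseline; the Hill coefficient is
bounded to (0, 10]. Non-convergence and flat inputs return a flagged fit,
never an exception. Requires ≥ 4 distinct positive concentrations.

The *detection threshold* is the lowest tested concentration passing a dual
rule: mean > baseline mean + k·√(SEM_baseline² + SEM_c²) (default k = 3)
AND a one-sided Welch t test against the baseline replicates with p < α
(default 0.05). The activation criterion behind published threshold calls
is typically visual; this rule is the package's own declared default, both
knobs exposed in the config, chosen to be robust for N = 3 replicate
structures. Activation is tested one-sided because the reporter design only
lets responses rise above baseline. Threshold shifts between two conditions
are reported as fold changes (threshold_b / threshold_a); a condition that
never reaches threshold yields no ratio and is flagged "not restored".

**Zero-variance degeneracy.** When both samples of a t test have zero
variance (exact-replicate data, e.g. noise-free simulations), the statistic
is undefined; the call is then decided by the sign of the mean difference
(p → 0 for a positive difference, else 1). On noise-free data the dual rule
therefore reduces to "any response strictly above baseline", which is also
how generator ground-truth thresholds are defined, keeping round-trip
comparisons exact.

## Interaction analysis

With ψ the response level of one receptor–ligand pair at one concentration
under a named condition:

    τ_RTP1S = ψ_RTP1S / (ψ_RTP1S + ψ_RTP2)        τ_RTP1S + τ_RTP2 = 1
    σ       = ψ_mix   / (ψ_RTP1S + ψ_RTP2)

σ classifies the joint effect: hyper-addition (σ > 1), complete addition
(σ = 1), hypo-addition (σ < 1). Since σ = 1 is measure-zero in noisy data,
a tolerance band (default ± 0.05) around 1 defines "complete"; the band is
a config knob. On the σ = f(τ) diagram, σ > τ iff ψ_mix > ψ_RTP1S and
σ > 1 − τ iff ψ_mix > ψ_RTP2, so the diagonals partition the hypo-addition
region into mixture-above-both / between / below-both; points exactly on a
diagonal are assigned "between" by convention.

Two declared choices, both configurable:

- **ψ definition.** Whether published σ–τ analyses baseline-subtract ψ is
  generally unstated. Default here: ψ = activity at concentration c minus
  the same condition's 0 µM activity, floored at 0 — this stops
  vector-driven constitutive signal from inflating σ. `psi_mode="raw"`
  uses the normalized activity unmodified.
- **Denominator floor.** τ and σ are undefined when ψ_RTP1S + ψ_RTP2 ≤ ε
  (default 1e-3 normalized units), guarding ratio blow-up at sub-threshold
  responses.

A pair–concentration point is *valid* when at least one single-chaperone
condition passes the activation rule and the denominator clears ε; invalid
points are kept with `valid = False` so filtering is auditable.

**Receptor categories.** Category 1 (RTP1S-dominated): median τ over valid
points > τ_cat (default 0.65). Category 2: median τ ≤ τ_cat *and* RTP2
demonstrably activates the receptor for at least one ligand. Fewer than
`min_points` (default 2) valid points → uncategorized. Published category
assignments of this kind are visual; these cuts are declared defaults, not
attributions.

**Dependence analysis.** To ask whether the interaction mode tracks
receptor type or odorant type, valid points are grouped either way and the
mean within-group pairwise Euclidean distance in (τ, σ) space, averaged
over groups with ≥ 2 points, measures dispersion. Significance comes from
permuting group labels (default 999 permutations, seeded; p with the +1
correction, one-sided toward tight clustering). The comparison report
states which grouping clusters more tightly.

## Expression statistics

Surface expression: fold over the empty-vector control (OR/pCI). The
positivity threshold is explicitly arbitrary in this assay class; the
default 1.5× vector is carried on every call so reports are
self-describing. Colocalization counting sessions (nominally 100 cells per
session; the recorded denominator is always used for fractions) are
summarized as mean ± SEM of positive counts and compared with the classical
paired two-tailed t test, sessions paired by index, starred ** for
p < 0.01 and * for p < 0.05 (strict inequalities, so p = 0.05 is "ns").
All-identical nonzero differences make the statistic infinite; the
comparison is flagged and p reported as 0. No multiplicity correction is
applied across a comparison grid by default (a Holm option exists) —
matching common practice for small hand-counted grids.

## Synthetic-data generator

The generator emulates the screen structure the analysis assumes: each
receptor archetype has Hill parameters per single condition, and the
co-transfection response is the convex combination
ψ_mix(c) = φ·ψ_RTP1S(c) + (1 − φ)·ψ_RTP2(c), the minimal model of two
chaperones competing for a shared binding site at equal plasmid dose, with
φ the relative RTP1S occupancy. Because min(ψ1, ψ2) ≤ ψ_mix ≤ max(ψ1, ψ2),
σ < 1 whenever both singles respond — universal hypo-addition emerges from
the mechanism rather than being imposed. A `mix_boost` knob can inflate the
Category-2 mixture response mildly (their suppression is empirically less
obvious); it is off by default precisely to preserve the provable σ < 1
bound.

Defaults (the desk-scale study conditions): 6 receptors — 4 Category-1
(RTP1S top 0.75–0.99, RTP2 top ≈ OR-only level 0.05–0.08, φ ≈ 0.82–0.88)
and 2 Category-2 (RTP2 top ≈ 0.6, φ ≈ 0.55) — × 4 odorants × concentrations
0, 1, 3, 10, 30, 100, 300 µM × 3 replicate wells × 4 conditions, plus
vehicle baselines and empty-vector control wells ≈ 1800 wells. EC50s spread
over 3–30 µM. Firefly counts are `gain · (constitutive + ψ) · noise` and
*Renilla* counts lognormal about their mean: multiplicative lognormal noise
(unit mean; default CV 0.1 firefly, 0.05 *Renilla*) because luminescence is
positive and heteroscedastic. All draws come from one
`numpy.random.default_rng(seed)`; a seed is mandatory and identical seeds
give bit-identical tables.

What the generator does **not** emulate: plate-edge and position effects,
cross-plate drift, odorant carryover, receptor-specific efficacy ceilings
beyond the Hill top, and any departure from convex mixing (e.g. allosteric
synergy). Passing recovery tests therefore shows the pipeline is correct
under its own stated model, not that real screens satisfy that model.

## Numerical choices and problem sizes

- Normalization requires ≥ 2 distinct ratios per scope; everything else
  propagates NaN-free tables or raises a named error.
- Hill fit initialization: bottom at baseline, top at the max response,
  EC50 at the first concentration reaching half-max, n = 1.
- Permutation p-values use the add-one estimator, so the smallest
  attainable p is 1/(n_perm + 1).
- Recovery and calibration studies in the test suite use the desk-scale
  screen: 100 seeded noisy screens for category recovery, 200 seeded
  curves for EC50 recovery, 1000 permutation-null datasets (199
  permutations each) and 2000 paired-t null triplets for calibration —
  sizes chosen to keep Monte-Carlo error well inside the asserted bands.

## Known limitations

- τ and σ are ratios of means; no uncertainty is propagated onto the
  scatter points (the source analyses plot them the same way).
- EC50s are reported per condition but not statistically compared across
  conditions; threshold shifts carry the qualitative burden.
- The category rule reduces a 2-D point cloud to a median and an existence
  check; receptors straddling τ_cat with few ligands are sensitive to the
  cut and honestly end up uncategorized.
- The permutation dispersion test conditions on the observed set of valid
  points; validity filtering itself is not re-randomized.
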