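import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rtpscreen import dose_response as dr


def make_curve(conc_uM, means, sems=None, n=3, values=None, cond="RTP1S"):
    sems = sems if sems is not None else [0.0] * len(means)
    points = pd.DataFrame(
        {
            "concentration": np.asarray(conc_uM) * 1e-6,
            "mean": means,
            "sem": sems,
            "n_replicates": n,
        }
    )
    if values is not None:
        points["values"] = values
    return dr.DoseResponseCurve("OR1", cond, "odorA", points)


def summaries_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["or_name", "rtp_condition", "odorant", "concentration", "mean", "sem", "n_replicates"],
    )


class TestBuildCurves:
    def base_rows(self):
        return [
            ("OR1", "RTP1S", "vehicle", 0.0, 0.05, 0.01, 3),
            ("OR1", "RTP1S", "odorA", 100e-6, 0.9, 0.02, 3),
            ("OR1", "RTP1S", "odorA", 1e-6, 0.1, 0.02, 3),
            ("OR1", "RTP1S", "odorA", 10e-6, 0.5, 0.02, 3),
        ]

    def test_points_sorted_with_baseline_first(self):
        curves = dr.build_curves(summaries_frame(self.base_rows()))
        assert len(curves) == 1
        conc = curves[0].points["concentration"].tolist()
        assert conc == sorted(conc)
        assert conc[0] == 0.0
        assert len(conc) == 4

    def test_group_without_baseline_excluded(self, caplog):
        rows = [r for r in self.base_rows() if r[3] != 0.0]
        with caplog.at_level("WARNING"):
            curves = dr.build_curves(summaries_frame(rows))
        assert curves == []
        assert "baseline" in caplog.text

    def test_duplicate_concentration_rejected(self):
        rows = self.base_rows() + [("OR1", "RTP1S", "odorA", 10e-6, 0.55, 0.02, 3)]
        with pytest.raises(ValueError, match="OR1"):
            dr.build_curves(summaries_frame(rows))


class TestFitHill:
    CONC_UM = [1, 3, 10, 30, 100, 300]

    def test_exact_model_data_recovered(self):
        true = dict(bottom=0.0, top=1.0, ec50=10e-6, hill_n=1.0)
        conc = np.asarray(self.CONC_UM) * 1e-6
        means = dr.hill(conc, **true)
        curve = make_curve([0] + self.CONC_UM, [0.0] + list(means))
        fit = dr.fit_hill(curve)
        assert fit.converged
        assert fit.top == pytest.approx(1.0, rel=1e-6)
        assert fit.ec50 == pytest.approx(10e-6, rel=1e-6)
        assert fit.hill_n == pytest.approx(1.0, rel=1e-6)
        assert fit.rss < 1e-12

    def test_noisy_ec50_within_twofold_95pct(self):
        """Simulation oracle: EC50 recovered within 2x for >= 95% of seeds."""
        conc = np.asarray(self.CONC_UM) * 1e-6
        truth = dr.hill(conc, 0.0, 1.0, 10e-6, 1.0)
        ok = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            values = [np.array([0.0, 0.0, 0.0])] + [
                m + rng.normal(0, 0.05, size=3) for m in truth
            ]
            means = [v.mean() for v in values]
            sems = [v.std(ddof=1) / math.sqrt(3) for v in values]
            curve = make_curve([0] + self.CONC_UM, means, sems, values=values)
            fit = dr.fit_hill(curve)
            if fit.converged and 5e-6 <= fit.ec50 <= 20e-6:
                ok += 1
        assert ok / n_seeds >= 0.95

    def test_flat_curve_not_converged(self):
        curve = make_curve([0] + self.CONC_UM, [0.2] * 7)
        fit = dr.fit_hill(curve)
        assert not fit.converged
        assert fit.top == pytest.approx(fit.bottom)

    def test_too_few_concentrations_rejected(self):
        curve = make_curve([0, 1, 10], [0.0, 0.1, 0.5])
        with pytest.raises(ValueError):
            dr.fit_hill(curve)


class TestDetectThreshold:
    def rising_curve(self, scale=1.0):
        return make_curve(
            [0, 1, 3, 10, 30],
            [0.05, 0.05, 0.06, 0.05 + 0.45 * scale, 0.05 + 0.75 * scale],
            [0.01, 0.01, 0.01, 0.02, 0.02],
        )

    def test_change_point_found(self):
        call = dr.detect_threshold(self.rising_curve())
        assert call.threshold == pytest.approx(10e-6)
        assert call.rule_params == {"alpha": 0.05, "k_sem": 3.0}

    def test_flat_curve_has_no_threshold(self):
        curve = make_curve([0, 1, 10, 100], [0.05] * 4, [0.01] * 4)
        assert dr.detect_threshold(curve).threshold is None

    def test_amplitude_invariance(self):
        """Halving the response amplitude leaves the threshold unchanged
        when the rise still clears the baseline rule (baseline-relative)."""
        full = dr.detect_threshold(self.rising_curve(1.0))
        half = dr.detect_threshold(self.rising_curve(0.5))
        assert half.threshold == full.threshold

    def test_uniform_offset_monotone(self):
        """Raising all positive-concentration means never raises the threshold."""
        curve = self.rising_curve()
        call = dr.detect_threshold(curve)
        shifted = curve.points.copy()
        shifted.loc[shifted["concentration"] > 0, "mean"] += 0.2
        up = dr.detect_threshold(
            dr.DoseResponseCurve("OR1", "RTP1S", "odorA", shifted)
        )
        assert up.threshold is not None
        assert up.threshold <= call.threshold

    def test_zero_variance_decided_by_sign(self):
        curve = make_curve([0, 1, 10], [0.05, 0.05, 0.5], [0.0, 0.0, 0.0])
        assert dr.detect_threshold(curve).threshold == pytest.approx(10e-6)


class TestThresholdShift:
    def call(self, threshold, cond="RTP1S"):
        return dr.ThresholdCall("OR1", cond, "odorA", threshold)

    def test_fold_change(self):
        assert dr.threshold_shift(self.call(10e-6), self.call(100e-6, "RTP2")) == pytest.approx(10.0)

    def test_identity(self):
        a = self.call(10e-6)
        assert dr.threshold_shift(a, a) == 1.0

    def test_not_restored_returns_none(self):
        assert dr.threshold_shift(self.call(10e-6), self.call(None, "RTP2")) is None

    def test_mismatched_pair_rejected(self):
        b = dr.ThresholdCall("OR2", "RTP2", "odorA", 1e-5)
        with pytest.raises(ValueError):
            dr.threshold_shift(self.call(1e-5), b)


class TestResponsiveLigandMatrix:
    def summaries(self):
        rows = [
            ("OR1", "RTP1S", "vehicle", 0.0, 0.05, 0.01, 3),
            ("OR1", "RTP1S", "odorA", 100e-6, 0.8, 0.02, 3),
            ("OR1", "RTP1S", "odorB", 100e-6, 0.05, 0.02, 3),
            ("OR1", "RTP2", "vehicle", 0.0, 0.05, 0.01, 3),
            ("OR1", "RTP2", "odorA", 100e-6, 0.06, 0.02, 3),
        ]
        return summaries_frame(rows)

    def test_matrix_calls_per_condition(self):
        out = dr.responsive_ligand_matrix(self.summaries())
        assert len(out) == 3
        calls = {
            (r.rtp_condition, r.odorant): r.responsive
            for r in out.itertuples()
        }
        assert calls[("RTP1S", "odorA")]
        assert not calls[("RTP1S", "odorB")]
        assert not calls[("RTP2", "odorA")]

    def test_fixed_concentration_filter(self):
        rows = self.summaries()
        out = dr.responsive_ligand_matrix(rows, concentration=10e-6)
        assert len(out) == 0  # nothing tested at 10 µM


class TestResponsiveLigandCall:
    def test_clear_response_significant(self, summary_row_factory):
        base = summary_row_factory(0.05, 0.01, 6)
        resp = summary_row_factory(0.6, 0.02, 6)
        assert dr.responsive_ligand_call(resp, base)
        # cross-check against the scipy Welch t from the same summary stats
        t = (0.6 - 0.05) / math.sqrt(0.01**2 + 0.02**2)
        df = (0.01**2 + 0.02**2) ** 2 / (0.01**4 / 5 + 0.02**4 / 5)
        assert stats.t.sf(t, df) < 0.05

    def test_equal_means_not_responsive(self, summary_row_factory):
        base = summary_row_factory(0.3, 0.02, 3)
        assert not dr.responsive_ligand_call(base, base)

    def test_overlapping_sems_small_n_not_significant(self, summary_row_factory):
        base = summary_row_factory(0.10, 0.05, 2)
        resp = summary_row_factory(0.16, 0.05, 2)
        assert not dr.responsive_ligand_call(resp, base)

    def test_one_sided_p_matches_scipy_on_replicates(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            a = rng.normal(0.1, 0.05, size=4)
            b = rng.normal(0.5, 0.05, size=4)
            p_pkg = dr.one_sided_p(
                a.mean(), a.std(ddof=1) / 2, 4, b.mean(), b.std(ddof=1) / 2, 4
            )
            p_ref = stats.ttest_ind(b, a, equal_var=False, alternative="greater").pvalue
            assert p_pkg == pytest.approx(p_ref, rel=1e-9)
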