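import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import rtpscreen as rts
from rtpscreen import interaction as ia

positive_psi = st.floats(0.01, 2.0, allow_nan=False)


class TestComputeTau:
    def test_equal_responses_split_evenly(self):
        assert ia.compute_tau(0.4, 0.4) == pytest.approx((0.5, 0.5))

    def test_single_sided_response(self):
        assert ia.compute_tau(0.8, 0.0) == (1.0, 0.0)

    def test_hand_arithmetic(self):
        assert ia.compute_tau(0.6, 0.2) == pytest.approx((0.75, 0.25))

    def test_denominator_floor(self):
        with pytest.raises(ia.UndefinedPointError):
            ia.compute_tau(0.0004, 0.0004, eps=1e-3)

    @given(psi1=positive_psi, psi2=positive_psi)
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_tau_components_sum_to_one(self, psi1, psi2):
        t1, t2 = ia.compute_tau(psi1, psi2)
        assert t1 + t2 == pytest.approx(1.0, abs=1e-12)

    @given(psi1=positive_psi, psi2=positive_psi, k=st.floats(0.1, 50.0))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_scale_invariance(self, psi1, psi2, k):
        base = ia.compute_tau(psi1, psi2)
        scaled = ia.compute_tau(k * psi1, k * psi2)
        assert scaled == pytest.approx(base, rel=1e-9)


class TestComputeSigma:
    def test_exact_additivity_gives_one(self):
        assert ia.compute_sigma(0.4 + 0.2, 0.4, 0.2) == pytest.approx(1.0)

    def test_zero_mixture(self):
        assert ia.compute_sigma(0.0, 0.3, 0.3) == 0.0

    def test_hand_arithmetic(self):
        assert ia.compute_sigma(0.3, 0.4, 0.2) == pytest.approx(0.5)

    @given(psi1=positive_psi, psi2=positive_psi, mix=st.floats(0.0, 4.0), k=st.floats(0.1, 50.0))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_scale_invariance(self, psi1, psi2, mix, k):
        assert ia.compute_sigma(k * mix, k * psi1, k * psi2) == pytest.approx(
            ia.compute_sigma(mix, psi1, psi2), rel=1e-9
        )

    @given(psi1=positive_psi, psi2=positive_psi, frac=st.floats(0.001, 1.0))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_mixture_below_larger_single_is_hypo(self, psi1, psi2, frac):
        """0 < psi_mix <= max(psi1, psi2) with both singles positive forces
        sigma < 1."""
        mix = frac * max(psi1, psi2)
        assert ia.compute_sigma(mix, psi1, psi2) < 1.0


class TestClassifyAddition:
    @pytest.mark.parametrize(
        "sigma,expected",
        [(1.0, "complete"), (0.5, "hypo"), (1.04, "complete"), (1.2, "hyper"), (0.951, "complete")],
    )
    def test_band_classification(self, sigma, expected):
        assert ia.classify_addition(sigma, tolerance=0.05) == expected


class TestAssignSubregion:
    @pytest.mark.parametrize(
        "tau,sigma,expected",
        [
            (0.5, 0.9, "mix_above_both"),
            (0.5, 0.3, "mix_below_both"),
            (0.7, 0.7, "mix_between"),  # exactly on a diagonal
            (0.8, 0.5, "mix_between"),
        ],
    )
    def test_direct_evaluation(self, tau, sigma, expected):
        assert ia.assign_subregion(tau, sigma) == expected

    def test_oracle_equivalence_on_random_points(self):
        """The diagonal geometry agrees with direct psi comparisons."""
        rng = np.random.default_rng(17)
        for _ in range(2000):
            psi1, psi2 = rng.uniform(0.05, 1.5, size=2)
            mix = rng.uniform(0.0, 2.0)
            tau, _ = ia.compute_tau(psi1, psi2)
            sigma = ia.compute_sigma(mix, psi1, psi2)
            got = ia.assign_subregion(tau, sigma)
            above1, above2 = mix > psi1, mix > psi2
            if above1 and above2:
                expected = "mix_above_both"
            elif not above1 and not above2 and mix != psi1 and mix != psi2:
                expected = "mix_below_both"
            else:
                expected = "mix_between"
            assert got == expected


def make_pairs(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "or_name",
            "odorant",
            "concentration",
            "psi_rtp1s",
            "psi_rtp2",
            "psi_mix",
            "psi_or_only",
            "active_rtp1s",
            "active_rtp2",
        ],
    )


class TestSelectValidPoints:
    def test_validity_rules(self):
        pairs = make_pairs(
            [
                ("OR1", "odA", 1e-6, 0.4, 0.2, 0.3, 0.0, True, False),  # valid
                ("OR1", "odA", 1e-7, 0.4, 0.2, 0.3, 0.0, False, False),  # inactive
                ("OR1", "odA", 1e-8, 0.0, 0.0, 0.0, 0.0, True, True),  # denominator
            ]
        )
        out = ia.select_valid_points(pairs)
        assert out["valid"].tolist() == [True, False, False]
        assert out.loc[0, "tau_rtp1s"] == pytest.approx(2 / 3)
        assert out.loc[0, "sigma"] == pytest.approx(0.5)
        assert out.loc[0, "addition_class"] == "hypo"
        assert np.isnan(out.loc[2, "sigma"])

    def test_one_active_single_suffices(self):
        pairs = make_pairs([("OR1", "odA", 1e-6, 0.5, 0.01, 0.3, 0.0, False, True)])
        assert ia.select_valid_points(pairs)["valid"].all()

    def test_invalid_points_retained(self):
        pairs = make_pairs([("OR1", "odA", 1e-6, 0.5, 0.1, 0.3, 0.0, False, False)])
        out = ia.select_valid_points(pairs)
        assert len(out) == 1 and not out["valid"].any()


class TestCategorizeReceptor:
    def points_for(self, or_name, taus, active_rtp2=True):
        rows = [
            (or_name, f"od{i}", 1e-6, t, 1 - t, 0.4, 0.0, True, active_rtp2)
            for i, t in enumerate(taus)
        ]
        return ia.select_valid_points(make_pairs(rows))

    def test_rtp1s_dominated_receptor_is_category1(self):
        cat = ia.categorize_receptor(self.points_for("OR1", [0.9, 0.95, 0.85]))
        assert cat.category == "category1"
        assert cat.median_tau == pytest.approx(0.9)

    def test_dual_enhanced_receptor_is_category2(self):
        cat = ia.categorize_receptor(self.points_for("OR1", [0.5, 0.55, 0.6]))
        assert cat.category == "category2"

    def test_low_tau_without_rtp2_activation_uncategorized(self):
        cat = ia.categorize_receptor(
            self.points_for("OR1", [0.5, 0.55], active_rtp2=False)
        )
        assert cat.category == "uncategorized"

    def test_single_valid_point_uncategorized(self):
        cat = ia.categorize_receptor(self.points_for("OR1", [0.9]))
        assert cat.category == "uncategorized"

    def test_generator_archetypes_recovered(self, zero_noise_screen, zero_noise_result):
        _, _, truth = zero_noise_screen
        merged = zero_noise_result.categories.merge(
            truth.categories, on="or_name", suffixes=("", "_true")
        )
        assert (merged["category"] == merged["category_true"]).all()


class TestDependenceAnalysis:
    def clustered_points(self):
        rows = []
        centers = {"OR1": (0.9, 0.8), "OR2": (0.5, 0.4), "OR3": (0.2, 0.6)}
        for or_name, (tau, sigma) in centers.items():
            for i in range(4):
                psi1 = tau
                psi2 = 1 - tau
                rows.append(
                    (or_name, f"od{i}", 1e-6, psi1, psi2, sigma, 0.0, True, True)
                )
        return ia.select_valid_points(make_pairs(rows))

    def test_perfect_clustering_gives_minimal_p(self):
        points = self.clustered_points()
        res = ia.dependence_analysis(points, "by_or", n_perm=199, seed=0)
        assert res["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] <= 1 / 200 + 1e-12

    def test_or_dependence_in_generated_screen(self, zero_noise_result):
        """Interaction parameters are programmed per receptor, so grouping by
        receptor clusters far more tightly than grouping by odorant."""
        res = ia.compare_dependence(zero_noise_result.points, n_perm=99, seed=1)
        assert res["by_or"]["statistic"] < res["by_odorant"]["statistic"]
        assert res["tighter_grouping"] == "by_or"

    def test_degenerate_grouping_rejected(self):
        points = self.clustered_points()
        with pytest.raises(ValueError):
            ia.dependence_analysis(points[points["or_name"] == "OR1"], "by_or")

    def test_unknown_grouping_rejected(self):
        with pytest.raises(ValueError):
            ia.dependence_analysis(self.clustered_points(), "by_plate")
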