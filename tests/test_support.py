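"""Candidate filtering, PROP/MSC metrics, permutation background, support."""

import numpy as np
import pandas as pd
import pytest

from hmoflux.scoring import ScoringConfig
from hmoflux.support import (
    PermConfig,
    _fisher_pool,
    compute_msc,
    compute_prop,
    filter_candidates,
    metric_table,
    permutation_background,
    support_analysis,
    support_table,
)


def mk_gls(rows, columns):
    df = pd.DataFrame(rows, columns=pd.MultiIndex.from_tuples(columns))
    df.columns.names = ["linkage", "gene"]
    return df


class TestFilterCandidates:
    @staticmethod
    def _inputs(detected_frac, tpm, ref):
        n = 8
        det = pd.DataFrame(
            {
                g: [i < int(round(f * n)) for i in range(n)]
                for g, f in detected_frac.items()
            }
        )
        return (
            {"cohort1": det},
            pd.Series(tpm),
            pd.Series(ref),
        )

    def test_undetected_low_tpm_gene_excluded(self):
        # FUT9-like: microarray-silent, RNA-Seq Q3 TPM 0.37 below both cutoffs
        det, tpm, ref = self._inputs(
            {"FUT9": 0.0, "FUT3": 1.0}, {"FUT9": 0.37, "FUT3": 40.0},
            {"FUT9": 10.0, "FUT3": 5.0},
        )
        res = filter_candidates(det, tpm, ref, {"L3": ["FUT3", "FUT9"]})
        assert res.excluded == ["FUT9"] and res.retained == ["FUT3"]

    def test_detected_gene_retained_regardless_of_tpm(self):
        det, tpm, ref = self._inputs({"G1": 1.0}, {"G1": 0.0}, {"G1": 99.0})
        res = filter_candidates(det, tpm, ref, {"L1": ["G1"]})
        assert res.retained == ["G1"]

    def test_rnaseq_rescue_is_an_or(self):
        # undetected on array but TPM above the reference median -> rescued
        det, tpm, ref = self._inputs({"G1": 0.1}, {"G1": 1.5}, {"G1": 1.0})
        res = filter_candidates(det, tpm, ref, {"L1": ["G1"]})
        assert res.retained == ["G1"]

    def test_single_survivor_is_default_selected(self):
        det, tpm, ref = self._inputs(
            {"FUT1": 0.0, "FUT2": 1.0}, {"FUT1": 0.1, "FUT2": 50.0},
            {"FUT1": 20.0, "FUT2": 1.0},
        )
        res = filter_candidates(det, tpm, ref, {"L2": ["FUT1", "FUT2"]})
        assert res.default_selected == {"L2": "FUT2"}


class TestMetrics:
    def test_prop_single_candidate(self):
        gls = mk_gls([[0.5], [0.7]], [("L1", "a")])
        assert compute_prop(gls)[("L1", "a")] == 1.0

    def test_prop_fraction_and_tie_split(self):
        gls = mk_gls(
            [[0.9, 0.1], [0.2, 0.8], [0.5, 0.5], [0.6, 0.2]],
            [("L1", "a"), ("L1", "b")],
        )
        prop = compute_prop(gls)
        assert prop[("L1", "a")] == pytest.approx((1 + 0.5 + 1) / 4)
        assert prop[("L1", "b")] == pytest.approx((1 + 0.5) / 4)
        assert prop.sum() == pytest.approx(1.0)

    def test_prop_sums_below_one_when_linkage_absent(self):
        gls = mk_gls(
            [[0.9, 0.1], [np.nan, np.nan]], [("L1", "a"), ("L1", "b")]
        )
        assert compute_prop(gls).sum() == pytest.approx(0.5)

    def test_msc_perfect_and_inverse(self):
        scores = pd.Series([0.1, 0.2, 0.3])
        gls = mk_gls([[0.1, 0.3], [0.2, 0.2], [0.3, 0.1]], [("L1", "a"), ("L1", "b")])
        msc = compute_msc(scores, gls)
        assert msc[("L1", "a")] == pytest.approx(1.0)
        assert msc[("L1", "b")] == pytest.approx(-1.0)

    def test_msc_independent_noise_is_small(self):
        rng = np.random.default_rng(0)
        scores = pd.Series(rng.standard_normal(1000))
        gls = mk_gls(rng.standard_normal((1000, 1)), [("L1", "a")])
        assert abs(compute_msc(scores, gls)[("L1", "a")]) < 0.1

    def test_msc_needs_three_models(self):
        scores = pd.Series([0.1, 0.2])
        gls = mk_gls([[0.1], [0.2]], [("L1", "a")])
        assert np.isnan(compute_msc(scores, gls)[("L1", "a")])

    def test_msc_constant_gls_has_no_influence(self):
        # a single-route linkage gives every model the same GLS: defined as 0
        scores = pd.Series([0.1, 0.2, 0.3])
        gls = mk_gls([[0.4], [0.4], [0.4]], [("L1", "a")])
        assert compute_msc(scores, gls)[("L1", "a")] == 0.0


class TestPermutationBackground:
    @staticmethod
    def _random_gls(rng, n_models=30, genes=("a", "b", "c")):
        cols = [("L1", g) for g in genes] + [("L2", "x"), ("L2", "y")]
        return mk_gls(rng.uniform(-1, 1, size=(n_models, len(cols))), cols)

    def test_same_seed_reproduces(self):
        gls = self._random_gls(np.random.default_rng(1))
        a = permutation_background(gls, perm=PermConfig(n_perm=5, seed=9))
        b = permutation_background(gls, perm=PermConfig(n_perm=5, seed=9))
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_background_prop_mean_near_reciprocal_k(self):
        # exchangeable shuffling makes each of k candidates equally likely best
        gls = self._random_gls(np.random.default_rng(2), n_models=40)
        mean, _ = permutation_background(gls, perm=PermConfig(n_perm=60, seed=0))
        three = mean.loc[("L1",), "prop"]
        assert three.mean() == pytest.approx(1 / 3, abs=0.02)
        assert np.allclose(three, 1 / 3, atol=0.08)
        two = mean.loc[("L2",), "prop"]
        assert two.mean() == pytest.approx(1 / 2, abs=0.02)

    def test_shuffle_preserves_value_multiset(self):
        gls = self._random_gls(np.random.default_rng(3))
        rng = np.random.default_rng(4)
        flat = np.sort(gls.to_numpy().ravel())
        shuffled = rng.permutation(gls.to_numpy().ravel())
        assert np.allclose(np.sort(shuffled), flat)


class TestSupportTable:
    def test_fisher_pooling_closed_form(self):
        # chi2 sf with 4 df has the closed form exp(-x/2) * (1 + x/2)
        x = -2 * (np.log(0.05) + np.log(0.05))
        expected = np.exp(-x / 2) * (1 + x / 2)
        assert expected == pytest.approx(0.0175, abs=2e-4)
        assert _fisher_pool([0.05, 0.05]) == pytest.approx(expected, abs=1e-9)

    def test_bh_stepup_example(self):
        from statsmodels.stats.multitest import multipletests

        q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-9)

    def test_missing_metric_drops_cohort_from_pooling(self):
        idx = pd.MultiIndex.from_tuples([("L1", "a")], names=["linkage", "gene"])
        m1 = pd.DataFrame({"prop": [0.9], "gls_mean": [0.8], "msc": [0.7]}, index=idx)
        m2 = pd.DataFrame({"prop": [0.9], "gls_mean": [np.nan], "msc": [0.7]}, index=idx)
        bg_mean = pd.DataFrame({"prop": [0.5], "gls_mean": [0.0], "msc": [0.0]}, index=idx)
        bg_sd = pd.DataFrame({"prop": [0.1], "gls_mean": [0.1], "msc": [0.1]}, index=idx)
        out = support_table(
            {"c1": m1, "c2": m2}, {"c1": (bg_mean, bg_sd), "c2": (bg_mean, bg_sd)}
        )
        assert np.isnan(out.loc[("L1", "a"), "p_c2"])
        assert np.isfinite(out.loc[("L1", "a"), "p_pooled"])
        # pooled p equals the single available cohort p (df = 2)
        assert out.loc[("L1", "a"), "p_pooled"] == pytest.approx(
            out.loc[("L1", "a"), "p_c1"], abs=1e-12
        )

    def test_invariant_to_gene_and_model_ordering(self):
        rng = np.random.default_rng(8)
        cols = [("L1", "a"), ("L1", "b"), ("L2", "x"), ("L2", "y")]
        gls = mk_gls(rng.uniform(-1, 1, size=(25, 4)), cols)
        perm = PermConfig(n_perm=7, seed=3)
        base = support_analysis({"c1": gls}, perm=perm)
        shuffled = gls.iloc[::-1, ::-1]  # reversed model and column order
        again = support_analysis({"c1": shuffled}, perm=perm)
        pd.testing.assert_frame_equal(base.sort_index(), again.sort_index())


def test_cohort_label_symmetry():
    """Swapping cohort labels swaps the per-cohort outputs exactly."""
    rng = np.random.default_rng(12)
    cols = [("L1", "a"), ("L1", "b")]
    g1 = mk_gls(rng.uniform(-1, 1, size=(20, 2)), cols)
    g2 = mk_gls(rng.uniform(-1, 1, size=(20, 2)), cols)
    perm = PermConfig(n_perm=6, seed=2)
    fwd = support_analysis({"c1": g1, "c2": g2}, perm=perm)
    rev = support_analysis({"c1": g2, "c2": g1}, perm=perm)
    for metric in ("z_sum", "p"):
        pd.testing.assert_series_equal(
            fwd[f"{metric}_c1"], rev[f"{metric}_c2"], check_names=False
        )
        pd.testing.assert_series_equal(
            fwd[f"{metric}_c2"], rev[f"{metric}_c1"], check_names=False
        )
    pd.testing.assert_series_equal(fwd["p_pooled"], rev["p_pooled"])
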