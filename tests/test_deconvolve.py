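"""Deconvolution statistics: PCA, interaction model, noise, FF test, maps."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp

from smurfdeconv import deconvolve as dc
from smurfdeconv import synth
from smurfdeconv.enrichment import EnrichmentResult


def _counts_from_log2(y: np.ndarray, samples, gene_prefix="g", n_filler=50):
    """Counts whose log2(normalized+1) equals ``y`` exactly (unit size factors).

    A block of constant filler genes pins the median-of-ratios factors at 1.
    """
    mat = np.power(2.0, np.atleast_2d(y)) - 1.0
    filler = np.tile(np.linspace(50, 500, n_filler)[:, None], (1, len(samples)))
    data = np.vstack([mat, filler])
    idx = [f"{gene_prefix}{i}" for i in range(len(mat))] + [
        f"filler{i}" for i in range(n_filler)
    ]
    return pd.DataFrame(data, index=idx, columns=samples)


def _design_meta():
    return synth.default_design()


class TestPCA:
    def test_dominant_binary_shift_loads_pc1(self, rng):
        meta = _design_meta()
        s = meta["smurf"].to_numpy()
        y = 5.0 + 2.0 * s[None, :] + rng.normal(0, 0.05, size=(200, 32))
        counts = _counts_from_log2(y, meta["sample"])
        res = dc.pca_factor_association(counts, meta, n_top=100)
        assert res.associations.loc[1, "smurf_r2"] > 0.9
        assert res.associations.loc[1, "smurf_p"] < 1e-6

    def test_age_only_drift_correlates_pc1_with_age(self, rng):
        meta = _design_meta()
        d = (meta["age_days"].to_numpy() - 20) / 10
        y = 5.0 + 1.5 * d[None, :] + rng.normal(0, 0.05, size=(200, 32))
        counts = _counts_from_log2(y, meta["sample"])
        res = dc.pca_factor_association(counts, meta, n_top=100)
        assert abs(res.associations.loc[1, "age_r"]) > 0.9
        assert res.associations.loc[1, "smurf_p"] > 0.05

    def test_default_bundle_separates_state_then_age(self, bundle):
        _, expt, _, _ = bundle
        res = dc.pca_factor_association(expt.counts, expt.meta)
        assoc = res.associations
        assert assoc.loc[1, "smurf_p"] < 0.01
        assert assoc.loc[2, "age_p"] < 0.01
        assert assoc.loc[1, "smurf_r2"] > assoc.loc[2, "smurf_r2"]

    def test_n_top_capped_with_warning(self, bundle):
        _, expt, _, _ = bundle
        sub = expt.counts.iloc[:500]
        with pytest.warns(UserWarning, match="n_top"):
            res = dc.pca_factor_association(sub, expt.meta, n_top=1000)
        assert res.n_top == 500


class TestInteractionScan:
    def test_exact_state_shift_recovered(self):
        meta = _design_meta()
        s = meta["smurf"].to_numpy(dtype=float)
        counts = _counts_from_log2(3.0 + 0.5 * s, meta["sample"])
        lm = dc.interaction_scan(counts, meta)
        row = lm.table.loc["g0"]
        assert row["beta_smurf"] == pytest.approx(0.5, abs=1e-9)
        assert row["beta_age"] == pytest.approx(0.0, abs=1e-9)
        assert row["beta_inter"] == pytest.approx(0.0, abs=1e-9)
        assert row["r2"] == pytest.approx(1.0, abs=1e-9)

    def test_pure_interaction_signal_detected(self, rng):
        meta = _design_meta()
        s = meta["smurf"].to_numpy(dtype=float)
        d = (meta["age_days"].to_numpy(dtype=float) - 20) / 10
        y = 6.0 + 0.4 * s * d + rng.normal(0, 0.02, size=(100, 32))
        # enough filler genes that the signal block cannot move the size factors
        counts = _counts_from_log2(y, meta["sample"], n_filler=400)
        lm = dc.interaction_scan(counts, meta)
        genes = [f"g{i}" for i in range(100)]
        tab = lm.table.loc[genes]
        assert (tab["q_inter"] < 0.05).mean() > 0.95
        assert (tab["p_smurf"] < 0.05).mean() < 0.2  # mains stay quiet

    def test_null_type_one_error_calibrated(self):
        # constant dispersion across ages: the homoskedastic regime the
        # per-coefficient t-tests assume (the age-growing-dispersion default
        # makes them mildly conservative/liberal by coefficient)
        truth = synth.generate_gene_truth(3000, class_fractions={}, seed=61)
        truth.gamma = 0.0
        expt = synth.simulate_counts(truth, seed=62)
        lm = dc.interaction_scan(expt.counts, expt.meta)
        for coef in ("smurf", "age", "inter"):
            rate = (lm.table[f"p_{coef}"] < 0.05).mean()
            assert 0.02 < rate < 0.09, (coef, rate)

    def test_collinear_design_rejected(self, null_bundle):
        _, expt = null_bundle
        meta = expt.meta.copy()
        meta["age_days"] = 20  # single age: interaction column collinear
        with pytest.raises(ValueError):
            dc.interaction_scan(expt.counts, meta)


class TestAgeRegression:
    def test_exact_linear_gene_passes(self):
        meta = _design_meta()
        age = meta["age_days"].to_numpy(dtype=float)
        counts = _counts_from_log2(age / 10.0, meta["sample"])
        res = dc.age_regression_nonsmurf(counts, meta)
        row = res.table.loc["g0"]
        assert row["slope"] == pytest.approx(0.1, abs=1e-9)
        assert row["r2"] == pytest.approx(1.0, abs=1e-9)
        assert bool(row["passed"])

    def test_noise_gene_fails_r2_filter(self, rng):
        meta = _design_meta()
        y = 6.0 + rng.normal(0, 0.3, size=(300, 32))
        counts = _counts_from_log2(y, meta["sample"])
        res = dc.age_regression_nonsmurf(counts, meta)
        genes = [f"g{i}" for i in range(300)]
        assert res.table.loc[genes, "passed"].mean() < 0.01

    def test_recall_of_generator_age_class(self, bundle):
        truth, expt, _, _ = bundle
        tb = truth.table.set_index("gene")
        res = dc.age_regression_nonsmurf(expt.counts, expt.meta,
                                         smurf_degs=tb.index[tb.beta_smurf != 0])
        targets = tb.index[(tb["gene_class"] == "age_linear") & (tb["beta_age"].abs() >= 0.5)]
        assert res.table.loc[targets, "passed"].mean() >= 0.8
        assert res.n_up + res.n_down == int(res.table["passed"].sum())
        assert res.smurf_overlap["n_passed"] >= len(targets) * 0.8

    def test_requires_three_ages(self, bundle):
        _, expt, _, _ = bundle
        meta = expt.meta[expt.meta["age_days"] != 30]
        with pytest.raises(ValueError, match="3 distinct ages"):
            dc.age_regression_nonsmurf(expt.counts[meta["sample"]], meta)


class TestRSD:
    def test_hand_rsd_value(self):
        meta = pd.DataFrame(
            {"sample": ["a", "b", "c"], "age_days": [20, 20, 20], "smurf": [0, 0, 0]}
        )
        counts = _counts_from_log2(np.log2(np.array([[2.0, 4.0, 6.0]]) + 1), meta["sample"])
        noise = dc.rsd_analysis(counts, meta, min_samples=3)
        assert noise.rsd[(0, 20)]["g0"] == pytest.approx(0.5)  # sd 2, mean 4

    def test_printed_peak_ratios(self):
        assert dc.peak_ratio(0.089, 0.046) == pytest.approx(1.93, abs=0.005)
        assert dc.peak_ratio(0.094, 0.051) == pytest.approx(1.84, abs=0.005)

    def test_identical_group_matrices_have_zero_ks(self, rng):
        meta = pd.DataFrame(
            {
                "sample": [f"s{i}" for i in range(8)],
                "age_days": [20] * 4 + [40] * 4,
                "smurf": [0] * 8,
            }
        )
        block = rng.poisson(100, size=(300, 4)).astype(float)
        counts = pd.DataFrame(np.hstack([block, block]),
                              index=[f"g{i}" for i in range(300)],
                              columns=meta["sample"])
        noise = dc.rsd_analysis(counts, meta)
        assert noise.ks["D"].iloc[0] == pytest.approx(0.0)
        assert noise.peak_ratios[0] == pytest.approx(1.0)

    def test_small_groups_skipped_with_warning(self, bundle):
        _, expt, _, _ = bundle
        meta = expt.meta.copy()
        keep = meta.groupby(["smurf", "age_days"]).head(4)
        drop_two = keep[~((keep.smurf == 1) & (keep.age_days == 40))]
        extra = meta[(meta.smurf == 1) & (meta.age_days == 40)].head(2)
        meta2 = pd.concat([drop_two, extra])
        with pytest.warns(UserWarning, match="skipped"):
            noise = dc.rsd_analysis(expt.counts[meta2["sample"]], meta2)
        assert (1, 40) not in noise.rsd


def brute_ff(A, B):
    """Quadrant-count oracle with both boundary closures (independent loops)."""

    def quad_fracs(S, xi, yi, closed):
        if closed:
            lx, ly = S[:, 0] <= xi, S[:, 1] <= yi
        else:
            lx, ly = S[:, 0] < xi, S[:, 1] < yi
        return [np.mean(lx & ly), np.mean(lx & ~ly), np.mean(~lx & ly),
                np.mean(~lx & ~ly)]

    def dmax(origins):
        best = 0.0
        for (xi, yi) in origins:
            for closed in (True, False):
                fa = quad_fracs(A, xi, yi, closed)
                fb = quad_fracs(B, xi, yi, closed)
                best = max(best, max(abs(a - b) for a, b in zip(fa, fb)))
        return best

    return 0.5 * (dmax(A) + dmax(B))


class TestFasanoFranceschini:
    def test_identical_samples_give_zero(self, rng):
        a = rng.normal(size=(15, 2))
        d, p = dc.fasano_franceschini(a, a.copy(), n_perm=100, seed=1)
        assert d == pytest.approx(0.0)
        assert p == pytest.approx(1.0, abs=0.02)

    def test_complete_separation_gives_one(self, rng):
        a = rng.random((10, 2)) * 0.4
        b = rng.random((10, 2)) * 0.4 + 0.6
        d, p = dc.fasano_franceschini(a, b, n_perm=400, seed=2)
        assert d == pytest.approx(1.0)
        assert p < 0.01

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            n_a, n_b = rng.integers(3, 50, size=2)
            a = rng.normal(size=(n_a, 2)).round(1)  # rounding forces ties
            b = rng.normal(loc=rng.normal(), size=(n_b, 2)).round(1)
            from smurfdeconv._ff2d import ff_statistic

            assert ff_statistic(a, b) == pytest.approx(brute_ff(a, b), abs=1e-12)

    def test_reduces_to_1d_ks_when_one_coordinate_constant(self, rng):
        for _ in range(5):
            x1 = rng.normal(size=25)
            x2 = rng.normal(0.7, size=30)
            a = np.column_stack([x1, np.zeros_like(x1)])
            b = np.column_stack([x2, np.zeros_like(x2)])
            from smurfdeconv._ff2d import ff_statistic

            assert ff_statistic(a, b) == pytest.approx(
                ks_2samp(x1, x2).statistic, abs=1e-12
            )

    def test_degenerate_identical_points(self):
        pts = np.ones((5, 2))
        with pytest.warns(UserWarning, match="identical"):
            d, p = dc.fasano_franceschini(pts, np.ones((4, 2)), n_perm=50, seed=0)
        assert d == 0.0 and p == 1.0

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            dc.fasano_franceschini(np.ones((2, 2)), np.zeros((5, 2)))


class TestCorrelationMap:
    def test_noiseless_indicator_gene(self):
        meta = _design_meta()
        s = meta["smurf"].to_numpy(dtype=float)
        counts = _counts_from_log2(5.0 + s, meta["sample"])
        cmap = dc.correlation_map(counts, meta, {}, n_perm=10)
        assert cmap.gene_table.loc["g0", "r_smurf"] == pytest.approx(1.0)
        assert abs(cmap.gene_table.loc["g0", "r_age"]) < 0.2

    def test_signal_set_significant_and_small_sets_dropped(self, bundle):
        truth, expt, sets, _ = bundle
        tb = truth.table.set_index("gene")
        up = list(tb.index[tb["gene_class"] == "smurf_up"][:40])
        test_sets = {"up_set": up, "tiny": up[:3]}
        cmap = dc.correlation_map(expt.counts, expt.meta, test_sets,
                                  n_perm=300, seed=4)
        assert cmap.dropped == ["tiny"]
        row = cmap.set_table.set_index("set").loc["up_set"]
        assert row["mean_r_smurf"] > 0.3
        assert row["q"] < 0.05

    def test_decoy_sets_calibrated_on_null_universe(self, null_bundle):
        """Null-gene decoys against a null background: q stays above 0.05."""
        truth, expt = null_bundle
        rng = np.random.default_rng(8)
        genes = truth.table["gene"].to_numpy()
        decoys = {f"d{i}": list(rng.choice(genes, size=30, replace=False))
                  for i in range(10)}
        cmap = dc.correlation_map(expt.counts, expt.meta, decoys,
                                  n_perm=400, seed=9)
        assert (cmap.set_table["q"] >= 0.05).mean() >= 0.9

    def test_invariant_to_sample_and_gene_order(self, bundle, rng):
        _, expt, _, _ = bundle
        counts = expt.counts.iloc[:400]
        meta = expt.meta
        cmap1 = dc.correlation_map(counts, meta, {}, n_perm=10)
        perm_cols = rng.permutation(counts.columns.to_numpy())
        perm_rows = rng.permutation(counts.index.to_numpy())
        cmap2 = dc.correlation_map(counts.loc[perm_rows, perm_cols], meta, {}, n_perm=10)
        pd.testing.assert_frame_equal(
            cmap1.gene_table.sort_index(), cmap2.gene_table.sort_index()
        )


def _enrichment_stub(sig_sets, all_sets):
    rows = [{"set": s, "size": 20, "es": 0.5, "nes": 1.5,
             "p": 0.001 if s in sig_sets else 0.8,
             "q": 0.01 if s in sig_sets else 0.9,
             "direction": "up", "leading_edge": ""} for s in all_sets]
    return EnrichmentResult(pd.DataFrame(rows), pd.DataFrame(columns=["set", "reason"]),
                            100, 10, 600, 1.0)


class TestHallmarkAttribution:
    def test_precedence_rules(self):
        hallmark_map = {f"ATH{i}_set": f"ATH{i}" for i in range(1, 7)}
        all_sets = list(hallmark_map)
        enr = {
            "smurf": _enrichment_stub({"ATH1_set", "ATH5_set"}, all_sets),
            "old_smurf": _enrichment_stub({"ATH5_set", "ATH6_set"}, all_sets),
            "old_nonsmurf": _enrichment_stub({"ATH2_set"}, all_sets),
        }
        att = dc.hallmark_attribution(enr, None, hallmark_map)
        got = att.table.set_index("hallmark")["attribution"]
        assert got["ATH1"] == "smurf_specific"
        assert got["ATH5"] == "old_smurf"   # old-Smurf movement dominates
        assert got["ATH6"] == "old_smurf"
        assert got["ATH2"] == "chronological"
        assert got["ATH3"] == "none"

    def test_unmapped_hallmark_warns_none(self):
        hallmark_map = {"ATH1_set": "ATH1"}
        enr = {k: _enrichment_stub(set(), ["ATH1_set"])
               for k in ("smurf", "old_smurf", "old_nonsmurf")}
        with pytest.warns(UserWarning, match="no mapped gene sets"):
            att = dc.hallmark_attribution(enr, None, hallmark_map)
        assert (att.table["attribution"] == "none").all()

    def test_noise_facet_rule(self):
        hallmark_map = {"ATH1_set": "ATH1"}
        enr = {k: _enrichment_stub(set(), ["ATH1_set"])
               for k in ("smurf", "old_smurf", "old_nonsmurf")}
        noise_hi = dc.NoiseSummary(rsd={}, peaks={}, ks=pd.DataFrame(),
                                   peak_ratios={0: 1.8, 1: 1.9})
        noise_lo = dc.NoiseSummary(rsd={}, peaks={}, ks=pd.DataFrame(),
                                   peak_ratios={0: 1.8, 1: 1.2})
        assert dc.hallmark_attribution(enr, noise_hi, hallmark_map).noise_facet == "chronological"
        assert dc.hallmark_attribution(enr, noise_lo, hallmark_map).noise_facet == "none"


class TestMixtureProjection:
    def test_endpoint_and_midpoint(self):
        assert dc.mixture_projection(10.0, 20.0, 0.0) == pytest.approx(10.0)
        assert dc.mixture_projection(10.0, 20.0, 0.5) == pytest.approx(15.0)
        with pytest.raises(ValueError):
            dc.mixture_projection(10.0, 20.0, 1.5)

    def test_array_prevalence_broadcasts(self):
        out = dc.mixture_projection(np.array([10.0, 0.0]), np.array([20.0, 8.0]),
                                    np.array([0.0, 0.5, 1.0]))
        assert out.shape == (2, 3)
        assert out[0].tolist() == [10.0, 15.0, 20.0]
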