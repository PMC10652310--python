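"""Differential-expression engine: normalization, NB tests, concordance."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special

from smurfdeconv import de, synth


def _meta(samples, smurf=None, age=None):
    return pd.DataFrame(
        {
            "sample": samples,
            "smurf": smurf if smurf is not None else [0] * len(samples),
            "age_days": age if age is not None else [20] * len(samples),
        }
    )


class TestSizeFactors:
    def test_doubled_sample_splits_ratio_symmetrically(self):
        counts = pd.DataFrame({"s1": [10, 100, 50], "s2": [20, 200, 100]})
        s = de.size_factors(counts)
        assert s["s1"] == pytest.approx(1 / np.sqrt(2))
        assert s["s2"] == pytest.approx(np.sqrt(2))
        assert s["s2"] / s["s1"] == pytest.approx(2.0)

    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"a": [5, 9, 14], "b": [5, 9, 14], "c": [5, 9, 14]})
        assert de.size_factors(counts).to_numpy() == pytest.approx(1.0)

    def test_recovers_generator_truth(self, bundle):
        _, expt, _, _ = bundle
        s = de.size_factors(expt.counts)
        r = np.corrcoef(s.to_numpy(), expt.meta["size_factor"].to_numpy())[0, 1]
        assert r >= 0.99

    def test_fallback_when_no_all_positive_gene(self):
        counts = pd.DataFrame({"a": [0, 8], "b": [4, 0]})
        with pytest.warns(UserWarning, match="falling back"):
            s = de.size_factors(counts)
        assert (s > 0).all()


def _nb_mle_log2fc(y1, y2):
    """Exact NB maximum likelihood on a two-group instance (independent oracle).

    Profiles the log-likelihood over (log mu1, log mu2, log alpha) directly.
    """
    y1, y2 = np.asarray(y1, float), np.asarray(y2, float)

    def nll(theta):
        lm1, lm2, la = theta
        a = np.exp(la)
        r = 1.0 / a
        out = 0.0
        for y, lm in ((y1, lm1), (y2, lm2)):
            mu = np.exp(lm)
            out -= np.sum(
                special.gammaln(y + r) - special.gammaln(r) - special.gammaln(y + 1)
                + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))
            )
        return out

    res = optimize.minimize(nll, x0=[np.log(y1.mean()), np.log(y2.mean()), np.log(0.05)],
                            method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
    return (res.x[1] - res.x[0]) / np.log(2.0)


class TestNBWald:
    def test_two_group_toy_matches_exact_mle(self):
        counts = pd.DataFrame(
            [[10, 12, 11, 40, 44, 42]], columns=[f"s{i}" for i in range(6)],
            index=["g0"],
        )
        # pad with stable null genes so normalization and the trend are sane
        rng = np.random.default_rng(0)
        filler = pd.DataFrame(rng.poisson(100, size=(60, 6)),
                              columns=counts.columns,
                              index=[f"f{i}" for i in range(60)])
        counts = pd.concat([counts, filler])
        meta = _meta(counts.columns, smurf=[0, 0, 0, 1, 1, 1])
        res = de.nb_wald_test(counts, meta, contrast="smurf",
                              sf=pd.Series(1.0, index=counts.columns))
        oracle = _nb_mle_log2fc([10, 12, 11], [40, 44, 42])
        assert res.table.loc["g0", "log2FC"] == pytest.approx(oracle, abs=0.01)
        assert res.table.loc["g0", "log2FC"] == pytest.approx(2.0, abs=0.1)

    def test_null_gene_with_identical_group_means(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(200, size=(200, 32))
        counts = pd.DataFrame(base, columns=[f"s{i}" for i in range(32)])
        meta = _meta(counts.columns, smurf=[0] * 16 + [1] * 16)
        # gene 0: exactly equal group means
        counts.iloc[0, :16] = [200, 201, 199, 200, 200, 201, 199, 200] * 2
        counts.iloc[0, 16:] = [200, 201, 199, 200, 200, 201, 199, 200] * 2
        res = de.nb_wald_test(counts, meta, contrast="smurf")
        assert abs(res.table.iloc[0]["log2FC"]) < 0.05
        assert res.table.iloc[0]["p"] > 0.1

    def test_recall_and_sign_on_synthetic_truth(self, bundle, smurf_de):
        truth, _, _, _ = bundle
        tb = truth.table.set_index("gene")
        strong = tb.index[tb["beta_smurf"].abs() >= 1]
        sig = set(smurf_de.significant(0.05))
        recall = np.mean([g in sig for g in strong])
        assert recall >= 0.9
        tested = smurf_de.table.loc[strong]
        tested = tested[tested["tested"]]
        sign_ok = np.sign(tested["log2FC"]) == np.sign(tb.loc[tested.index, "beta_smurf"])
        assert sign_ok.mean() >= 0.99

    def test_low_expression_genes_flagged_not_tested(self, bundle):
        _, expt, _, _ = bundle
        counts = expt.counts.copy()
        counts.iloc[0] = 0  # all-zero gene
        res = de.nb_wald_test(counts, expt.meta, contrast="smurf")
        row = res.table.iloc[0]
        assert not row["tested"] and np.isnan(row["q"])

    def test_q_at_least_p_and_order_preserving(self, smurf_de):
        tab = smurf_de.table[smurf_de.table["tested"]]
        assert (tab["q"] >= tab["p"] - 1e-12).all()
        assert (tab["q"] <= 1.0).all()
        order = tab.sort_values("p")
        assert (np.diff(order["q"].to_numpy()) >= -1e-12).all()

    def test_design_validation(self, bundle):
        _, expt, _, _ = bundle
        meta = expt.meta.copy()
        meta["smurf"] = 0
        with pytest.raises(ValueError, match="2 levels"):
            de.nb_wald_test(expt.counts, meta, contrast="smurf")


class TestQuasiVariant:
    def test_null_gene_not_significant(self, null_bundle):
        _, expt = null_bundle
        res = de.nb_quasi_test(expt.counts, expt.meta, contrast="smurf")
        tab = res.table[res.table["tested"]]
        # approximately uniform p under the null for both variants
        assert 0.02 < (tab["p"] < 0.05).mean() < 0.08
        res_a = de.nb_wald_test(expt.counts, expt.meta, contrast="smurf")
        tab_a = res_a.table[res_a.table["tested"]]
        assert 0.01 < (tab_a["p"] < 0.05).mean() < 0.08

    def test_variant_concordance(self, bundle, smurf_de):
        _, expt, _, _ = bundle
        res_b = de.nb_quasi_test(expt.counts, expt.meta, contrast="smurf")
        sig_a, sig_b = set(smurf_de.significant()), set(res_b.significant())
        assert len(sig_b) > 0
        assert len(sig_a & sig_b) / len(sig_b) >= 0.85
        both = smurf_de.table["tested"] & res_b.table["tested"]
        r = np.corrcoef(smurf_de.table.loc[both, "log2FC"],
                        res_b.table.loc[both, "log2FC"])[0, 1]
        assert r >= 0.98


class TestDEGCountByAge:
    def test_counts_decrease_when_interaction_opposes_state_effect(self):
        truth = synth.generate_gene_truth(
            3000, class_fractions={"smurf": 0.2}, seed=41
        )
        tab = truth.table
        # old Smurfs drift back toward non-Smurf levels: bI cancels bS by 40 d
        tab["beta_inter"] = -tab["beta_smurf"] / 2.0
        expt = synth.simulate_counts(synth.GeneTruth(table=tab), seed=42)
        summary, _ = de.deg_count_by_age(expt.counts, expt.meta)
        counts = summary.set_index("age_days")["n_deg"]
        assert counts[20] > counts[30] > counts[40]

    def test_null_generator_gives_no_degs(self, null_bundle):
        _, expt = null_bundle
        summary, _ = de.deg_count_by_age(expt.counts, expt.meta)
        assert (summary["n_deg"] <= 2).all()

    def test_deterministic_and_skips_missing_stratum(self, null_bundle):
        _, expt = null_bundle
        a, _ = de.deg_count_by_age(expt.counts, expt.meta)
        b, _ = de.deg_count_by_age(expt.counts, expt.meta)
        pd.testing.assert_frame_equal(a, b)
        meta = expt.meta[~((expt.meta.age_days == 30) & (expt.meta.smurf == 1))]
        counts = expt.counts[meta["sample"]]
        with pytest.warns(UserWarning, match="stratum"):
            summary, _ = de.deg_count_by_age(counts, meta)
        assert set(summary["age_days"]) == {20, 40}
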