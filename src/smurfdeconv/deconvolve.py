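"""Separating Smurfness-associated from chronological-age-associated signal.

This module holds the statistics that deconvolve the two axes of the
experiment: PCA factor association, the per-gene Smurfness x time
interaction model, the non-Smurf age-only regression with F-test and R^2
filters, transcriptional-noise (RSD) summaries, the per-gene
(r_smurf, r_age) correlation map with Fasano-Franceschini set tests, and
the hallmark attribution rule combining them.  Expression is always
log2(median-of-ratios-normalized + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from ._ff2d import _Pooled, ff_statistic
from .de import log_normalized, normalized_counts
from .enrichment import EnrichmentResult

__all__ = [
    "pca_factor_association",
    "interaction_scan",
    "age_regression_nonsmurf",
    "rsd_analysis",
    "peak_ratio",
    "fasano_franceschini",
    "correlation_map",
    "hallmark_attribution",
    "mixture_projection",
    "GeneLM",
    "NoiseSummary",
    "CorrelationMap",
    "HallmarkAttribution",
]

HALLMARKS = ("ATH1", "ATH2", "ATH3", "ATH4", "ATH5", "ATH6")


# ---------------------------------------------------------------------------
# PCA factor association


@dataclass
class PCAAssociation:
    """Variance decomposition and PC1/PC2 factor associations."""

    variance_ratio: np.ndarray
    scores: pd.DataFrame           # samples x components, with metadata columns
    associations: pd.DataFrame     # per PC: smurf_r2, smurf_p, age_r, age_p
    n_top: int


def _anova_r2(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """One-way ANOVA R^2 (eta squared) and p-value."""
    levels = [values[groups == g] for g in np.unique(groups)]
    grand = values.mean()
    ss_total = ((values - grand) ** 2).sum()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in levels)
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    p = stats.f_oneway(*levels).pvalue if len(levels) > 1 else 1.0
    return float(r2), float(p)


def pca_factor_association(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    n_top: int = 1000,
    n_components: int = 5,
) -> PCAAssociation:
    """PCA on the top-variance genes with PC-factor association statistics.

    Components are computed from the centred log-normalized matrix
    restricted to the ``n_top`` highest-variance genes; each PC's sample
    scores are then associated with Smurfness (one-way ANOVA R^2 and p)
    and age (Pearson r and p).
    """
    if len(meta) < 3:
        raise ValueError("PCA factor association needs at least 3 samples")
    meta = meta.set_index("sample").loc[counts.columns].rename_axis("sample").reset_index()
    expr = log_normalized(counts)
    if n_top > len(expr):
        warnings.warn(f"n_top={n_top} exceeds gene count {len(expr)}; using all genes",
                      stacklevel=2)
        n_top = len(expr)
    variances = expr.var(axis=1)
    top = variances.sort_values(ascending=False).index[:n_top]
    mat = expr.loc[top].to_numpy().T  # samples x genes
    mat = mat - mat.mean(axis=0)
    n_components = min(n_components, mat.shape[0] - 1, mat.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    comps = pca.fit_transform(mat)

    smurf = meta["smurf"].to_numpy()
    age = meta["age_days"].to_numpy(dtype=float)
    assoc_rows = []
    for i in range(n_components):
        r2, p_anova = _anova_r2(comps[:, i], smurf)
        r_age, p_age = stats.pearsonr(comps[:, i], age)
        assoc_rows.append(
            {"pc": i + 1, "smurf_r2": r2, "smurf_p": p_anova,
             "age_r": float(r_age), "age_p": float(p_age)}
        )
    scores = pd.DataFrame(comps, columns=[f"PC{i + 1}" for i in range(n_components)])
    scores.insert(0, "sample", meta["sample"].to_numpy())
    scores["smurf"] = smurf
    scores["age_days"] = age
    return PCAAssociation(
        variance_ratio=pca.explained_variance_ratio_,
        scores=scores,
        associations=pd.DataFrame(assoc_rows).set_index("pc"),
        n_top=n_top,
    )


# ---------------------------------------------------------------------------
# per-gene interaction model


@dataclass
class GeneLM:
    """Per-gene linear model y ~ smurf + age + smurf:age on log expression.

    ``table`` columns: intercept, beta_smurf, beta_age (per decade),
    beta_inter, per-coefficient p and BH q (one family per coefficient),
    r2 and the overall F-test p.
    """

    table: pd.DataFrame
    coefficients: tuple[str, ...] = ("smurf", "age", "inter")

    def significant(self, coefficient: str, q_threshold: float = 0.05) -> pd.Index:
        tab = self.table
        return tab.index[tab[f"q_{coefficient}"] < q_threshold]


def _ols_batch(Y: np.ndarray, X: np.ndarray):
    """OLS of every row of Y on shared design X; returns beta, se, r2, f_p."""
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is collinear; cannot fit the interaction model")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = Y @ (xtx_inv @ X.T).T
    resid = Y - beta @ X.T
    rss = (resid**2).sum(axis=1)
    tss = ((Y - Y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df_resid = n - p
    sigma2 = rss / df_resid
    se = np.sqrt(np.outer(sigma2, np.diag(xtx_inv)))
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(tss > 0, 1.0 - rss / tss, 0.0)
        f_stat = np.where(rss > 0, ((tss - rss) / (p - 1)) / sigma2, np.inf)
    f_p = stats.f.sf(f_stat, p - 1, df_resid)
    f_p = np.where(tss > 0, f_p, 1.0)
    return beta, se, np.clip(r2, 0.0, 1.0), f_p, df_resid


def interaction_scan(counts: pd.DataFrame, meta: pd.DataFrame) -> GeneLM:
    """Fit, per gene, expression ~ Smurfness + age + Smurfness:age.

    Age enters in decades past day 20 so coefficients read as log2 change
    per 10 days.  Requires both states and >= 2 distinct ages.
    """
    meta = meta.set_index("sample").loc[counts.columns].rename_axis("sample").reset_index()
    if meta["smurf"].nunique() < 2 or meta["age_days"].nunique() < 2:
        raise ValueError("interaction model needs both states and >= 2 ages")
    expr = log_normalized(counts).to_numpy()
    s = meta["smurf"].to_numpy(dtype=float)
    d = (meta["age_days"].to_numpy(dtype=float) - 20.0) / 10.0
    X = np.column_stack([np.ones(len(meta)), s, d, s * d])
    beta, se, r2, f_p, df_resid = _ols_batch(expr, X)
    with np.errstate(invalid="ignore", divide="ignore"):
        tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)

    table = pd.DataFrame(index=counts.index)
    table.index.name = "gene"
    names = ("intercept", "smurf", "age", "inter")
    for j, name in enumerate(names):
        table[f"beta_{name}"] = beta[:, j]
        if name != "intercept":
            table[f"p_{name}"] = pvals[:, j]
            table[f"q_{name}"] = multipletests(pvals[:, j], method="fdr_bh")[1]
    table["r2"] = r2
    table["f_p"] = f_p
    return GeneLM(table=table)


# ---------------------------------------------------------------------------
# age-only regression in non-Smurfs


@dataclass
class AgeRegression:
    """Non-Smurf age regression with significance and fit-quality filters."""

    table: pd.DataFrame        # slope (per day), r2, p, passed
    p_max: float
    r2_min: float
    smurf_overlap: dict | None = None

    @property
    def passed(self) -> pd.Index:
        return self.table.index[self.table["passed"]]

    @property
    def n_up(self) -> int:
        return int(((self.table["passed"]) & (self.table["slope"] > 0)).sum())

    @property
    def n_down(self) -> int:
        return int(((self.table["passed"]) & (self.table["slope"] < 0)).sum())


def age_regression_nonsmurf(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    p_max: float = 0.05,
    r2_min: float = 0.5,
    smurf_degs=None,
) -> AgeRegression:
    """Per-gene regression of non-Smurf expression on age (days).

    A gene passes iff its F-test p < ``p_max`` AND R^2 > ``r2_min``; the
    passing list is partitioned by slope sign, and its overlap with a
    supplied Smurf DEG list is reported.
    """
    meta = meta.set_index("sample").loc[counts.columns].rename_axis("sample").reset_index()
    ns = meta[meta["smurf"] == 0]
    if ns["age_days"].nunique() < 3:
        raise ValueError("age regression needs >= 3 distinct ages in non-Smurfs")
    expr = log_normalized(counts[ns["sample"]]).to_numpy()
    age = ns["age_days"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(ns)), age])
    beta, se, r2, f_p, _ = _ols_batch(expr, X)
    table = pd.DataFrame(
        {"slope": beta[:, 1], "r2": r2, "p": f_p},
        index=counts.index,
    )
    table.index.name = "gene"
    table["passed"] = (table["p"] < p_max) & (table["r2"] > r2_min)
    overlap = None
    if smurf_degs is not None:
        smurf_degs = pd.Index(smurf_degs)
        passed = table.index[table["passed"]]
        shared = passed.intersection(smurf_degs)
        overlap = {
            "n_passed": int(len(passed)),
            "n_shared_with_smurf": int(len(shared)),
            "fraction_shared": float(len(shared) / len(passed)) if len(passed) else np.nan,
        }
    return AgeRegression(table=table, p_max=p_max, r2_min=r2_min, smurf_overlap=overlap)


# ---------------------------------------------------------------------------
# transcriptional noise (RSD)


@dataclass
class NoiseSummary:
    """Per-group RSD values, density peaks, KS comparisons and peak ratios."""

    rsd: dict                     # (state, age) -> pd.Series of per-gene RSD
    peaks: dict                   # (state, age) -> density mode
    ks: pd.DataFrame              # state, age_a, age_b, D, p
    peak_ratios: dict             # state -> peak(40)/peak(20)-style oldest/youngest ratio
    rsd_cap: float = 0.6          # display cap; statistics use uncapped values


def _density_mode(values: np.ndarray, grid_size: int = 512) -> float:
    """Mode of a Gaussian KDE (Silverman bandwidth) on a [0, max] grid."""
    values = values[np.isfinite(values)]
    if values.size < 3 or np.ptp(values) == 0:
        return float(values[0]) if values.size else np.nan
    kde = stats.gaussian_kde(values, bw_method="silverman")
    grid = np.linspace(0.0, values.max(), grid_size)
    return float(grid[np.argmax(kde(grid))])


def peak_ratio(peak_old: float, peak_young: float) -> float:
    """Fold increase of a density peak between two age groups."""
    return peak_old / peak_young


def rsd_analysis(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    rsd_cap: float = 0.6,
    min_samples: int = 3,
) -> NoiseSummary:
    """Relative standard deviation (sd/mean) of normalized expression per group.

    Groups are (state, age); genes with zero mean within a group are
    excluded from that group's distribution.  Density modes are estimated
    on uncapped values (the cap only trims plots), age groups are compared
    pairwise within state by two-sample KS, and the oldest/youngest peak
    ratio is reported per state.
    """
    meta = meta.set_index("sample").loc[counts.columns].rename_axis("sample").reset_index()
    norm = normalized_counts(counts)
    rsd: dict = {}
    peaks: dict = {}
    for (state, age), grp in meta.groupby(["smurf", "age_days"]):
        if len(grp) < min_samples:
            warnings.warn(f"group (smurf={state}, age={age}) has <{min_samples} samples; skipped",
                          stacklevel=2)
            continue
        sub = norm[grp["sample"]].to_numpy()
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        ok = mean > 0
        series = pd.Series(sd[ok] / mean[ok], index=counts.index[ok])
        key = (int(state), int(age))
        rsd[key] = series
        peaks[key] = _density_mode(series.to_numpy())

    ks_rows = []
    ratios: dict = {}
    for state in sorted({k[0] for k in rsd}):
        ages = sorted(k[1] for k in rsd if k[0] == state)
        for i, age_a in enumerate(ages):
            for age_b in ages[i + 1:]:
                res = stats.ks_2samp(rsd[(state, age_a)], rsd[(state, age_b)])
                ks_rows.append(
                    {"smurf": state, "age_a": age_a, "age_b": age_b,
                     "D": float(res.statistic), "p": float(res.pvalue)}
                )
        if len(ages) >= 2:
            ratios[state] = peak_ratio(peaks[(state, ages[-1])], peaks[(state, ages[0])])
    ks = pd.DataFrame(ks_rows, columns=["smurf", "age_a", "age_b", "D", "p"])
    return NoiseSummary(rsd=rsd, peaks=peaks, ks=ks, peak_ratios=ratios, rsd_cap=rsd_cap)


# ---------------------------------------------------------------------------
# Fasano-Franceschini 2-D two-sample test


def fasano_franceschini(
    sample_a: np.ndarray,
    sample_b: np.ndarray,
    n_perm: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Two-sample 2-D KS test (Fasano-Franceschini) with permutation p-value.

    D is the maximum over data points and the four quadrant orientations
    of the two samples' quadrant-fraction difference, averaged over the
    two conditioning samples; the p-value permutes the pooled labels.
    """
    sample_a = np.atleast_2d(np.asarray(sample_a, dtype=float))
    sample_b = np.atleast_2d(np.asarray(sample_b, dtype=float))
    if len(sample_a) < 3 or len(sample_b) < 3:
        raise ValueError("each sample needs at least 3 points")
    x = np.concatenate([sample_a[:, 0], sample_b[:, 0]])
    y = np.concatenate([sample_a[:, 1], sample_b[:, 1]])
    pooled = _Pooled(x, y)
    labels = np.zeros(len(x), dtype=bool)
    labels[: len(sample_a)] = True
    d_obs = pooled.stat(labels)
    if np.all(x == x[0]) and np.all(y == y[0]):
        warnings.warn("all points identical; p set to 1", stacklevel=2)
        return d_obs, 1.0
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if pooled.stat(perm) >= d_obs - 1e-12:
            count += 1
    return d_obs, (1.0 + count) / (1.0 + n_perm)


# ---------------------------------------------------------------------------
# (r_smurf, r_age) correlation map


@dataclass
class CorrelationMap:
    """Per-gene correlations with Smurfness/age and per-set FF tests."""

    gene_table: pd.DataFrame  # r_smurf, r_age
    set_table: pd.DataFrame   # set, n_genes, mean_r_smurf, mean_r_age, D, p, q
    dropped: list[str] = field(default_factory=list)


def _pearson_with(mat: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of ``mat`` with a vector."""
    mc = mat - mat.mean(axis=1, keepdims=True)
    tc = target - target.mean()
    denom = np.sqrt((mc**2).sum(axis=1) * (tc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, mc @ tc / denom, np.nan)


def correlation_map(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    min_genes: int = 10,
    n_perm: int = 2000,
    seed: int = 0,
) -> CorrelationMap:
    """Map genes into the (r_smurf, r_age) plane and test gene-set shifts.

    r_smurf is the point-biserial correlation (Pearson on the 0/1 Smurf
    coding) of log-normalized expression with state; r_age the Pearson
    correlation with age in days.  Each gene set's member cloud is
    compared with the non-member cloud by the Fasano-Franceschini test,
    with BH adjustment across sets.
    """
    meta = meta.set_index("sample").loc[counts.columns].rename_axis("sample").reset_index()
    expr = log_normalized(counts)
    mat = expr.to_numpy()
    r_smurf = _pearson_with(mat, meta["smurf"].to_numpy(dtype=float))
    r_age = _pearson_with(mat, meta["age_days"].to_numpy(dtype=float))
    gene_table = pd.DataFrame({"r_smurf": r_smurf, "r_age": r_age}, index=counts.index)
    gene_table.index.name = "gene"
    usable = gene_table.dropna()
    points = usable.to_numpy()
    pooled = _Pooled(points[:, 0], points[:, 1])
    universe = pd.Index(usable.index)
    rng = np.random.default_rng(seed)

    rows, dropped = [], []
    for name in sorted(gene_sets):
        member = universe.isin(set(gene_sets[name]))
        k = int(member.sum())
        if k < min_genes:
            dropped.append(name)
            continue
        d_obs = pooled.stat(member)
        count = 0
        for _ in range(n_perm):
            if pooled.stat(rng.permutation(member)) >= d_obs - 1e-12:
                count += 1
        rows.append(
            {
                "set": name,
                "n_genes": k,
                "mean_r_smurf": float(points[member, 0].mean()),
                "mean_r_age": float(points[member, 1].mean()),
                "D": d_obs,
                "p": (1.0 + count) / (1.0 + n_perm),
            }
        )
    set_table = pd.DataFrame(rows, columns=["set", "n_genes", "mean_r_smurf",
                                            "mean_r_age", "D", "p"])
    if len(set_table):
        set_table["q"] = multipletests(set_table["p"], method="fdr_bh")[1]
    else:
        set_table["q"] = pd.Series(dtype=float)
    return CorrelationMap(gene_table=gene_table, set_table=set_table, dropped=dropped)


# ---------------------------------------------------------------------------
# hallmark attribution


@dataclass
class HallmarkAttribution:
    """Attribution of each transcriptional ageing hallmark to a contrast."""

    table: pd.DataFrame  # hallmark, sig_smurf, sig_old_smurf, sig_old_nonsmurf, attribution
    noise_facet: str = "none"


def hallmark_attribution(
    enrichments: dict[str, EnrichmentResult],
    noise: NoiseSummary | None,
    hallmark_map: dict[str, str],
    q_threshold: float = 0.05,
    noise_ratio_threshold: float = 1.5,
) -> HallmarkAttribution:
    """Assign each hallmark to {smurf_specific, old_smurf, chronological, none}.

    A hallmark's sets are looked up in the Smurf-vs-non-Smurf, old-vs-young
    Smurf and old-vs-young non-Smurf enrichment runs; it is attributed to
    old_smurf when its sets move between young and old Smurfs (an
    age-modulated signature), to smurf_specific when they move only with
    state, and to chronological when only the non-Smurf age contrast shows
    them.  The noise facet of the heterogeneity hallmark is attributed to
    chronological age when the oldest/youngest RSD peak ratio exceeds
    ``noise_ratio_threshold`` in both states.
    """
    required = {"smurf", "old_smurf", "old_nonsmurf"}
    missing = required - set(enrichments)
    if missing:
        raise ValueError(f"missing enrichment contrasts: {sorted(missing)}")
    sig = {
        name: set(res.significant(q_threshold)["set"]) for name, res in enrichments.items()
    }
    sets_by_hallmark: dict[str, list[str]] = {h: [] for h in HALLMARKS}
    for set_name, tag in hallmark_map.items():
        if tag in sets_by_hallmark:
            sets_by_hallmark[tag].append(set_name)

    rows = []
    for tag in HALLMARKS:
        mapped = sets_by_hallmark[tag]
        if not mapped:
            warnings.warn(f"hallmark {tag} has no mapped gene sets; attributed 'none'",
                          stacklevel=2)
            rows.append({"hallmark": tag, "sig_smurf": False, "sig_old_smurf": False,
                         "sig_old_nonsmurf": False, "attribution": "none"})
            continue
        in_smurf = any(s in sig["smurf"] for s in mapped)
        in_old_smurf = any(s in sig["old_smurf"] for s in mapped)
        in_old_ns = any(s in sig["old_nonsmurf"] for s in mapped)
        if in_old_smurf:
            label = "old_smurf"
        elif in_smurf:
            label = "smurf_specific"
        elif in_old_ns:
            label = "chronological"
        else:
            label = "none"
        rows.append({"hallmark": tag, "sig_smurf": in_smurf, "sig_old_smurf": in_old_smurf,
                     "sig_old_nonsmurf": in_old_ns, "attribution": label})
    noise_facet = "none"
    if noise is not None and len(noise.peak_ratios) >= 2:
        if all(r > noise_ratio_threshold for r in noise.peak_ratios.values()):
            noise_facet = "chronological"
    return HallmarkAttribution(table=pd.DataFrame(rows), noise_facet=noise_facet)


# ---------------------------------------------------------------------------
# mixture projection


def mixture_projection(mu_nonsmurf, mu_smurf, prevalence):
    """Expected unlabeled-population mean expression (1-p)*mu_NS + p*mu_S.

    ``prevalence`` may be a scalar or an array over observation times; in
    the latter case the result is genes x times.  This is the quantity an
    age-only analysis of unlabeled samples actually regresses on: a gene
    whose expression differs only by state acquires a spurious age slope
    proportional to its state effect times dp/dt.
    """
    mu_ns = np.asarray(mu_nonsmurf, dtype=float)
    mu_s = np.asarray(mu_smurf, dtype=float)
    p = np.asarray(prevalence, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("prevalence must lie in [0, 1]")
    if p.ndim == 0:
        return (1.0 - p) * mu_ns + p * mu_s
    return np.outer(mu_ns, 1.0 - p) + np.outer(mu_s, p)
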