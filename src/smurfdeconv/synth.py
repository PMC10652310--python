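"""Synthetic bulk RNA-seq experiments with a biphasic (Smurf) structure.

The generator emulates the study design the downstream statistics assume:
16 Smurf and 16 age-matched non-Smurf whole-body samples collected at 20,
30 and 40 days (5/6/5 per age within each state), ~15,364 genes, raw
negative-binomial counts.  Per-gene ground truth is explicit so every
estimator can be scored against it:

    E[count_gj] = s_j * mu_g * 2^(bS*S_j + bA*d_j + bI*S_j*d_j)

with ``d_j = (age_j - 20)/10`` (age in decades past day 20), ``S_j`` the
0/1 Smurf status, and a negative-binomial dispersion that increases with
age, ``alpha_g(age) = alpha0_g * (1 + gamma*(age-20)/20)``.  The default
``gamma = 3`` quadruples the dispersion between day 20 and day 40, which
doubles the high-expression RSD (sd/mean) and reproduces the roughly
2-fold rise of the transcriptional-noise peak between young and old
samples.

Gene classes: ``smurf_up`` / ``smurf_down`` (state effect only, ~19.6% of
genes), ``age_linear`` (~2%, both states), ``old_smurf_interaction``
(Smurf-only age-amplified effect), and ``null``.  Hallmark tags ATH1-ATH6
mark coherent gene subsets used to build gene-set (GMT) fixtures: ATH1-2
among Smurf-upregulated genes, ATH3-4 among Smurf-downregulated genes,
ATH5-6 among downward old-Smurf interaction genes.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import twophase
from .io import write_gmt

__all__ = [
    "GeneTruth",
    "CountsExperiment",
    "default_design",
    "generate_gene_truth",
    "simulate_counts",
    "build_genesets",
    "write_fixture_bundle",
]

HALLMARKS = ("ATH1", "ATH2", "ATH3", "ATH4", "ATH5", "ATH6")

#: default gene-class fractions (remainder is null)
DEFAULT_CLASS_FRACTIONS = {
    "smurf": 0.196,          # ~3000 of 15,364 genes state-shifted
    "age_linear": 0.0196,    # ~300 genes drifting with age in both states
    "old_smurf_interaction": 0.10,
}
#: fraction of state-shifted genes that are upregulated (1618/3009)
SMURF_UP_FRACTION = 0.5377
#: fraction of age-linear genes with a positive slope (207/301)
AGE_UP_FRACTION = 0.688

DEFAULT_EFFECT_SCALES = {
    "smurf_mean": 0.8,    # mean |bS| in log2 units
    "smurf_tail": 0.05,   # heavy tail fraction with |bS| >= 2 (AMP-like genes)
    "age_mean": 0.6,      # mean |bA| in log2 units per decade
    "inter_mean": 0.8,    # mean |bI| in log2 units per decade (Smurf-only)
}

#: dispersion-age link slope: alpha(age) = alpha0 * (1 + GAMMA*(age-20)/20)
DISPERSION_AGE_GAMMA = 3.0


@dataclass
class GeneTruth:
    """Per-gene generator ground truth."""

    table: pd.DataFrame  # gene, mu, beta_smurf, beta_age, beta_inter, alpha0, gene_class, hallmark
    gamma: float = DISPERSION_AGE_GAMMA

    def alpha(self, age_days: np.ndarray | float) -> np.ndarray:
        """Negative-binomial dispersion at a given age (non-decreasing)."""
        factor = 1.0 + self.gamma * (np.asarray(age_days, dtype=float) - 20.0) / 20.0
        if np.any(factor <= 0):
            raise ValueError("age outside the dispersion domain (age-dispersion factor <= 0)")
        return np.multiply.outer(self.table["alpha0"].to_numpy(), factor)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class CountsExperiment:
    """Gene x sample raw count matrix with per-sample metadata."""

    counts: pd.DataFrame          # genes x samples, non-negative integers
    meta: pd.DataFrame            # sample, age_days, smurf, hours_since_transition, size_factor
    truth: GeneTruth | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.meta["sample"]):
            raise ValueError("metadata rows do not match count-matrix columns")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")


def default_design() -> pd.DataFrame:
    """The 16 Smurf + 16 non-Smurf design: 5/6/5 samples per age and state.

    ``hours_since_transition`` records the collection delay after the Smurf
    transition (5h, 1d or mixed); it carries no expression effect and is
    kept as metadata only, mirroring the pooling of collection times.
    """
    rows = []
    hours_cycle = ["mixed", "5h", "1d", "1d", "5h", "1d"]
    for smurf in (1, 0):
        state = "S" if smurf else "NS"
        for age, n_rep in ((20, 5), (30, 6), (40, 5)):
            for i in range(n_rep):
                rows.append(
                    {
                        "sample": f"{state}{age}_{i + 1}",
                        "age_days": age,
                        "smurf": smurf,
                        "hours_since_transition": hours_cycle[i],
                    }
                )
    return pd.DataFrame(rows)


def _smurf_effect_sizes(n: int, scales: dict, rng: np.random.Generator) -> np.ndarray:
    """|bS| draws: Gamma body plus a heavy tail of strong (>=2 log2) effects."""
    tail_frac = scales["smurf_tail"]
    body_mean = (scales["smurf_mean"] - tail_frac * 2.33) / (1.0 - tail_frac)
    body_mean = max(body_mean, 0.1)
    mag = rng.gamma(shape=2.0, scale=body_mean / 2.0, size=n)
    tail = rng.random(n) < tail_frac
    mag[tail] = 2.0 + rng.exponential(0.33, size=int(tail.sum()))
    return mag


def generate_gene_truth(
    n_genes: int,
    class_fractions: dict | None = None,
    effect_scales: dict | None = None,
    seed: int = 0,
    n_hallmark_genes: int = 60,
) -> GeneTruth:
    """Draw per-gene baselines, effect sizes, dispersions and class labels.

    ``class_fractions`` maps class name to the fraction of genes in it
    (must sum to <= 1; the remainder is null).  Reproducible under ``seed``.
    """
    fractions = dict(DEFAULT_CLASS_FRACTIONS if class_fractions is None else class_fractions)
    scales = {**DEFAULT_EFFECT_SCALES, **(effect_scales or {})}
    for name, f in fractions.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"class fraction {name}={f} outside [0, 1]")
    if sum(fractions.values()) > 1.0 + 1e-12:
        raise ValueError("class fractions sum to more than 1")

    rng = np.random.default_rng(seed)
    genes = np.array([f"gene{i:05d}" for i in range(n_genes)])
    # baseline means and dispersions calibrated so the within-group RSD
    # (sd/mean) density peaks near 0.05 at day 20 and near 0.09 at day 40,
    # the regime whole-body pooled fly samples sit in
    mu = rng.lognormal(mean=np.log(2500.0), sigma=1.2, size=n_genes)
    alpha0 = rng.lognormal(mean=np.log(0.002), sigma=0.6, size=n_genes)

    beta_s = np.zeros(n_genes)
    beta_a = np.zeros(n_genes)
    beta_i = np.zeros(n_genes)
    gene_class = np.full(n_genes, "null", dtype=object)

    u = rng.random(n_genes)  # class assignment by a single uniform draw
    edges = np.cumsum([fractions.get("smurf", 0.0), fractions.get("age_linear", 0.0),
                       fractions.get("old_smurf_interaction", 0.0)])
    is_smurf = u < edges[0]
    is_age = (u >= edges[0]) & (u < edges[1])
    is_inter = (u >= edges[1]) & (u < edges[2])

    n_s = int(is_smurf.sum())
    if n_s:
        mag = _smurf_effect_sizes(n_s, scales, rng)
        sign = np.where(rng.random(n_s) < SMURF_UP_FRACTION, 1.0, -1.0)
        beta_s[is_smurf] = sign * mag
        gene_class[is_smurf] = np.where(sign > 0, "smurf_up", "smurf_down")

    n_a = int(is_age.sum())
    if n_a:
        mag = rng.gamma(shape=2.0, scale=scales["age_mean"] / 2.0, size=n_a)
        sign = np.where(rng.random(n_a) < AGE_UP_FRACTION, 1.0, -1.0)
        beta_a[is_age] = sign * mag
        gene_class[is_age] = "age_linear"

    n_i = int(is_inter.sum())
    if n_i:
        mag = rng.gamma(shape=2.0, scale=scales["inter_mean"] / 2.0, size=n_i)
        sign = np.where(rng.random(n_i) < 0.25, 1.0, -1.0)  # old-Smurf changes mostly downward
        beta_i[is_inter] = sign * mag
        gene_class[is_inter] = "old_smurf_interaction"

    hallmark = np.full(n_genes, "none", dtype=object)
    pools = {
        "ATH1": np.flatnonzero((gene_class == "smurf_up")),
        "ATH2": np.flatnonzero((gene_class == "smurf_up")),
        "ATH3": np.flatnonzero((gene_class == "smurf_down")),
        "ATH4": np.flatnonzero((gene_class == "smurf_down")),
        "ATH5": np.flatnonzero((gene_class == "old_smurf_interaction") & (beta_i < 0)),
        "ATH6": np.flatnonzero((gene_class == "old_smurf_interaction") & (beta_i < 0)),
    }
    for tag in HALLMARKS:
        pool = pools[tag][hallmark[pools[tag]] == "none"]
        take = min(n_hallmark_genes, len(pool))
        if take:
            chosen = rng.choice(pool, size=take, replace=False)
            hallmark[chosen] = tag

    table = pd.DataFrame(
        {
            "gene": genes,
            "mu": mu,
            "beta_smurf": beta_s,
            "beta_age": beta_a,
            "beta_inter": beta_i,
            "alpha0": alpha0,
            "gene_class": gene_class,
            "hallmark": hallmark,
        }
    )
    return GeneTruth(table=table)


def simulate_counts(
    truth: GeneTruth,
    design: pd.DataFrame | None = None,
    seed: int = 0,
    size_factors: np.ndarray | None = None,
    size_factor_sigma: float = 0.1,
) -> CountsExperiment:
    """Draw negative-binomial counts for ``truth`` under a sample design.

    Size factors default to log-normal(0, ``size_factor_sigma``) draws so
    the normalization step downstream always has real work to do.
    """
    if design is None:
        design = default_design()
    design = design.reset_index(drop=True)
    rng = np.random.default_rng(seed)

    n_samples = len(design)
    if size_factors is None:
        size_factors = rng.lognormal(mean=0.0, sigma=size_factor_sigma, size=n_samples)
    size_factors = np.asarray(size_factors, dtype=float)
    if np.any(size_factors <= 0):
        raise ValueError("size factors must be positive")

    age_dec = (design["age_days"].to_numpy(dtype=float) - 20.0) / 10.0
    smurf = design["smurf"].to_numpy(dtype=float)
    tb = truth.table
    log2fc = (
        np.outer(tb["beta_smurf"], smurf)
        + np.outer(tb["beta_age"], age_dec)
        + np.outer(tb["beta_inter"], smurf * age_dec)
    )
    mean = size_factors[None, :] * tb["mu"].to_numpy()[:, None] * np.exp2(log2fc)
    alpha = truth.alpha(design["age_days"].to_numpy(dtype=float))

    # numpy's NB: mean = n(1-p)/p with n = 1/alpha, p = 1/(1 + alpha*mean)
    n_param = 1.0 / alpha
    p_param = 1.0 / (1.0 + alpha * mean)
    counts = rng.negative_binomial(n_param, p_param)

    meta = design.copy()
    meta["size_factor"] = size_factors
    counts_df = pd.DataFrame(counts, index=tb["gene"].to_numpy(), columns=meta["sample"].to_numpy())
    counts_df.index.name = "gene_id"
    return CountsExperiment(counts=counts_df, meta=meta, truth=truth)


def expected_mean(truth: GeneTruth, smurf: int, age_days: float, size_factor: float = 1.0) -> np.ndarray:
    """Expected (pre-sampling) count for every gene in one sample condition."""
    d = (age_days - 20.0) / 10.0
    tb = truth.table
    log2fc = tb["beta_smurf"] * smurf + tb["beta_age"] * d + tb["beta_inter"] * smurf * d
    return (size_factor * tb["mu"] * np.exp2(log2fc)).to_numpy()


def build_genesets(
    truth: GeneTruth,
    seed: int = 0,
    n_decoys: int = 20,
    decoy_size_range: tuple[int, int] = (15, 200),
) -> tuple[dict[str, list[str]], dict[str, str]]:
    """Hallmark gene sets plus random decoy sets of null genes.

    Returns ``(sets, hallmark_map)`` where ``hallmark_map`` assigns each
    hallmark set to its ATH label.  Decoy sets contain only null-class
    genes, so on the synthetic bundle their enrichment p-values calibrate
    the permutation null.
    """
    rng = np.random.default_rng(seed)
    tb = truth.table
    sets: dict[str, list[str]] = {}
    hallmark_map: dict[str, str] = {}
    for tag in HALLMARKS:
        members = tb.loc[tb["hallmark"] == tag, "gene"].tolist()
        if members:
            name = f"{tag}_set"
            sets[name] = members
            hallmark_map[name] = tag
    null_genes = tb.loc[tb["gene_class"] == "null", "gene"].to_numpy()
    lo, hi = decoy_size_range
    for i in range(n_decoys):
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(null_genes))
        sets[f"decoy_{i:02d}"] = sorted(rng.choice(null_genes, size=size, replace=False).tolist())
    return sets, hallmark_map


def simulate_longevity_tables(
    params_control: twophase.TwoPhaseParams,
    params_treated: twophase.TwoPhaseParams,
    n_per_condition: int = 150,
    horizon: float = 90.0,
    seed: int = 0,
    scoring_step: float = 2.0,
    prevalence_step: float = 7.0,
    labels: tuple[str, str] = ("RU0", "RU50"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Death-event and Smurf-prevalence tables from two simulated cohorts.

    Deaths are binned onto a ``scoring_step``-day grid (flies are scored a
    few times a week, not continuously); prevalence is observed every
    ``prevalence_step`` days.
    """
    events_rows, prev_rows = [], []
    for label, params, sub in zip(labels, (params_control, params_treated), (0, 1)):
        cohort = twophase.simulate_cohort(params, n_per_condition, horizon, seed=seed * 2 + sub + 1)
        death = cohort.individuals["death_age"].to_numpy()
        death = death[np.isfinite(death)]
        bins = np.ceil(death / scoring_step) * scoring_step
        at_risk = n_per_condition
        for day in np.unique(bins):
            d = int((bins == day).sum())
            events_rows.append({"condition": label, "day": float(day), "deaths": d, "n_at_risk": at_risk})
            at_risk -= d
        byday = cohort.by_day
        obs_days = np.arange(prevalence_step, horizon + 0.5, prevalence_step)
        sel = byday[byday["day"].isin(obs_days) & (byday["n_alive"] > 0)]
        for _, row in sel.iterrows():
            prev_rows.append(
                {
                    "condition": label,
                    "day": float(row["day"]),
                    "n_alive": int(row["n_alive"]),
                    "n_smurf": int(row["n_smurf"]),
                }
            )
    return pd.DataFrame(events_rows), pd.DataFrame(prev_rows)


def write_fixture_bundle(
    outdir,
    seed: int = 0,
    n_genes: int = 15364,
    class_fractions: dict | None = None,
) -> dict[str, str]:
    """Write the full synthetic bundle (counts, metadata, GMT, longevity tables).

    Byte-identical for identical seeds.  Returns a path map.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = generate_gene_truth(n_genes, class_fractions=class_fractions, seed=seed)
    expt = simulate_counts(truth, seed=seed + 1)
    sets, hallmark_map = build_genesets(truth, seed=seed + 2)
    control = twophase.TwoPhaseParams()
    treated = twophase.TwoPhaseParams(c=control.c / 2.0)
    events, prev = simulate_longevity_tables(control, treated, seed=seed + 3)

    paths = {
        "counts": outdir / "counts.tsv",
        "metadata": outdir / "metadata.csv",
        "genesets": outdir / "genesets.gmt",
        "hallmarks": outdir / "hallmarks.tsv",
        "longevity": outdir / "longevity.csv",
        "prevalence": outdir / "prevalence.csv",
        "gene_truth": outdir / "gene_truth.tsv",
    }
    try:
        expt.counts.to_csv(paths["counts"], sep="\t")
        expt.meta.to_csv(paths["metadata"], index=False)
        write_gmt(sets, paths["genesets"])
        pd.DataFrame(
            {"set": list(hallmark_map), "hallmark": [hallmark_map[k] for k in hallmark_map]}
        ).to_csv(paths["hallmarks"], sep="\t", index=False)
        events.to_csv(paths["longevity"], index=False)
        prev.to_csv(paths["prevalence"], index=False)
        truth.table.to_csv(paths["gene_truth"], sep="\t", index=False, float_format="%.8g")
    except OSError as exc:  # pragma: no cover - I/O failure path
        raise OSError(f"failed writing fixture bundle under {outdir}: {exc}") from exc
    return {k: str(v) for k, v in paths.items()}


def file_sha256(path) -> str:
    """SHA-256 hex digest of a file (used to check bundle determinism)."""
    hasher = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            hasher.update(chunk)
    return hasher.hexdigest()
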