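"""End-to-end orchestration: simulate -> DE -> GSEA -> deconvolve -> longevity.

A single declarative :class:`RunConfig` (YAML round-trippable) carries all
paths, analysis parameters and the master seed; stage seeds are derived
deterministically from the master seed through ``numpy.random.SeedSequence``
spawning in a fixed stage order, so a full run is reproducible end to end.
Every output file starts with a comment header recording the config hash
and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import de, deconvolve, enrichment, io, longevity, synth

__all__ = ["RunConfig", "run_pipeline", "validate_inputs"]

logger = logging.getLogger("smurfdeconv")

STAGES = ("simulate", "de", "gsea", "deconvolve", "longevity", "report")


@dataclass
class RunConfig:
    """Declarative pipeline configuration with the analysis defaults."""

    outdir: str = "smurfdeconv_run"
    counts: str | None = None       # None -> simulate a synthetic bundle
    metadata: str | None = None
    genesets: str | None = None
    hallmarks: str | None = None
    longevity_events: str | None = None
    prevalence: str | None = None
    control_condition: str | None = None

    seed: int = 0
    n_genes: int = 15364
    fdr_threshold: float = 0.05
    gsea_nperm: int = 15000
    gsea_min_size: int = 10
    gsea_max_size: int = 600
    pca_n_top: int = 1000
    age_p_max: float = 0.05
    age_r2_min: float = 0.5
    corr_min_genes: int = 10
    corr_nperm: int = 2000
    rsd_cap: float = 0.6
    stages: dict = field(
        default_factory=lambda: {s: True for s in STAGES}
    )

    _PATH_FIELDS = ("outdir", "counts", "metadata", "genesets", "hallmarks",
                    "longevity_events", "prevalence")

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded: identical analyses
        written to different directories share a hash)."""
        payload = {k: v for k, v in asdict(self).items() if k not in self._PATH_FIELDS}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def stage_seeds(self) -> dict[str, int]:
        """Per-stage integer seeds spawned from the master seed (fixed order)."""
        children = np.random.SeedSequence(self.seed).spawn(len(STAGES))
        return {
            stage: int(child.generate_state(1)[0] % (2**31))
            for stage, child in zip(STAGES, children)
        }


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig, stage_seed: int,
               index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# smurfdeconv config={config.config_hash()} seed={config.seed} "
                 f"stage_seed={stage_seed}\n")
        df.to_csv(fh, sep="\t", index=index)


def validate_inputs(paths: dict[str, str]) -> list[dict]:
    """Machine-readable diagnostics for a bundle of input files.

    Checks matrix/metadata concordance, GMT well-formedness and monotone
    day columns.  Returns a list of diagnostics (empty when clean) rather
    than raising.
    """
    diagnostics: list[dict] = []

    def add(kind: str, message: str) -> None:
        diagnostics.append({"kind": kind, "message": message})

    counts = meta = None
    if paths.get("counts"):
        if not Path(paths["counts"]).exists():
            add("missing file", f"counts file not found: {paths['counts']}")
        else:
            counts = io.read_counts(paths["counts"])
            if (counts.to_numpy() < 0).any():
                add("invalid count", "count matrix contains negative values")
            if counts.to_numpy().dtype.kind not in "iu" and not np.allclose(
                counts.to_numpy(), np.round(counts.to_numpy())
            ):
                add("invalid count", "count matrix contains non-integer values")
    if paths.get("metadata"):
        if not Path(paths["metadata"]).exists():
            add("missing file", f"metadata file not found: {paths['metadata']}")
        else:
            try:
                meta = io.read_metadata(paths["metadata"])
            except ValueError as exc:
                add("invalid metadata", str(exc))
    if counts is not None and meta is not None:
        matrix_samples = set(counts.columns)
        meta_samples = set(meta["sample"])
        for s in sorted(matrix_samples - meta_samples):
            add("unmatched sample", f"count column {s!r} missing from metadata")
        for s in sorted(meta_samples - matrix_samples):
            add("unmatched sample", f"metadata sample {s!r} missing from count matrix")
    if paths.get("genesets"):
        if not Path(paths["genesets"]).exists():
            add("missing file", f"gene-set file not found: {paths['genesets']}")
        else:
            sets = io.read_gmt(paths["genesets"])
            if not sets:
                add("invalid gmt", "gene-set file defines no sets")
            for name, members in sets.items():
                if not members:
                    add("invalid gmt", f"gene set {name!r} has no members")
    for key in ("longevity_events", "prevalence"):
        if paths.get(key):
            if not Path(paths[key]).exists():
                add("missing file", f"{key} file not found: {paths[key]}")
                continue
            df = pd.read_csv(paths[key])
            if "day" not in df.columns:
                add("invalid table", f"{key} table lacks a 'day' column")
            elif "condition" in df.columns:
                for cond, grp in df.groupby("condition"):
                    if (np.diff(grp["day"].to_numpy(dtype=float)) < 0).any():
                        add("non-monotone days", f"{key}: days not sorted for {cond!r}")
    return diagnostics


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> dict:
    """Run all enabled stages in dependency order; returns an artifact map.

    Stage failures abort with :class:`StageError` naming the stage.  With
    all stages toggled off this is a validation-only run producing an
    empty report.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    artifacts: dict = {"outdir": str(outdir)}
    report_rows: list[dict] = []
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    current_stage = {"name": "validate"}

    def timed(stage):
        current_stage["name"] = stage

        class _Timer:
            def __enter__(self):
                self.t0 = time.time()
                logger.info("stage %s started (seed %d)", stage, seeds[stage])
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is None:
                    logger.info("stage %s finished in %.1fs", stage, time.time() - self.t0)
                return False

        return _Timer()

    try:
        expt = truth = None
        sets: dict[str, list[str]] | None = None
        hallmark_map: dict[str, str] | None = None

        if config.stages.get("simulate", False) and config.counts is None:
            with timed("simulate"):
                bundle_dir = outdir / "bundle"
                paths = synth.write_fixture_bundle(bundle_dir, seed=seeds["simulate"],
                                                   n_genes=config.n_genes)
                config.counts = paths["counts"]
                config.metadata = paths["metadata"]
                config.genesets = paths["genesets"]
                config.hallmarks = paths["hallmarks"]
                config.longevity_events = paths["longevity"]
                config.prevalence = paths["prevalence"]
                artifacts["bundle"] = paths
                report_rows.append({"section": "simulate", "key": "n_genes",
                                    "value": config.n_genes})

        if config.counts is not None:
            diagnostics = validate_inputs(
                {
                    "counts": config.counts,
                    "metadata": config.metadata,
                    "genesets": config.genesets,
                    "longevity_events": config.longevity_events,
                    "prevalence": config.prevalence,
                }
            )
            artifacts["diagnostics"] = diagnostics
            if diagnostics:
                raise ValueError(f"input validation failed: {diagnostics}")
            counts = io.read_counts(config.counts)
            meta = io.read_metadata(config.metadata)
            if config.genesets:
                sets = io.read_gmt(config.genesets)
            if config.hallmarks:
                hallmark_map = io.read_hallmark_map(config.hallmarks)

        de_results: dict[str, de.DEResult] = {}
        if config.stages.get("de", False) and config.counts is not None:
            with timed("de"):
                de_results["smurf"] = de.nb_wald_test(counts, meta, contrast="smurf")
                for label, state in (("old_smurf", 1), ("old_nonsmurf", 0)):
                    sel = meta[(meta["smurf"] == state) & meta["age_days"].isin([20, 40])]
                    de_results[label] = de.nb_wald_test(
                        counts[sel["sample"]], sel, contrast="age_days"
                    )
                for label, res in de_results.items():
                    _write_tsv(res.table, outdir / f"de_{label}.tsv", config, seeds["de"])
                n_deg = len(de_results["smurf"].significant(config.fdr_threshold))
                report_rows.append({"section": "de", "key": "smurf_degs", "value": n_deg})
                artifacts["de"] = {k: str(outdir / f"de_{k}.tsv") for k in de_results}

        gsea_results: dict[str, enrichment.EnrichmentResult] = {}
        if config.stages.get("gsea", False) and de_results and sets:
            with timed("gsea"):
                for label, res in de_results.items():
                    gsea_results[label] = enrichment.gsea(
                        res,
                        sets,
                        n_perm=config.gsea_nperm,
                        min_size=config.gsea_min_size,
                        max_size=config.gsea_max_size,
                        seed=seeds["gsea"],
                    )
                    out = outdir / f"gsea_{label}.tsv"
                    with open(out, "w") as fh:
                        fh.write(f"# smurfdeconv config={config.config_hash()} "
                                 f"seed={config.seed} stage_seed={seeds['gsea']} "
                                 f"nPerm={config.gsea_nperm}\n")
                        gsea_results[label].table.to_csv(fh, sep="\t", index=False)
                artifacts["gsea"] = {k: str(outdir / f"gsea_{k}.tsv") for k in gsea_results}
                n_sig = len(gsea_results["smurf"].significant(config.fdr_threshold))
                report_rows.append({"section": "gsea", "key": "significant_sets_smurf",
                                    "value": n_sig})

        if config.stages.get("deconvolve", False) and config.counts is not None:
            with timed("deconvolve"):
                pca = deconvolve.pca_factor_association(counts, meta, n_top=config.pca_n_top)
                _write_tsv(pca.associations, outdir / "pca_associations.tsv", config,
                           seeds["deconvolve"])
                lm = deconvolve.interaction_scan(counts, meta)
                _write_tsv(lm.table, outdir / "gene_lm.tsv", config, seeds["deconvolve"])
                smurf_degs = (
                    de_results["smurf"].significant(config.fdr_threshold)
                    if "smurf" in de_results else None
                )
                agereg = deconvolve.age_regression_nonsmurf(
                    counts, meta, p_max=config.age_p_max, r2_min=config.age_r2_min,
                    smurf_degs=smurf_degs,
                )
                _write_tsv(agereg.table, outdir / "age_regression.tsv", config,
                           seeds["deconvolve"])
                noise = deconvolve.rsd_analysis(counts, meta, rsd_cap=config.rsd_cap)
                noise_table = pd.DataFrame(
                    [{"smurf": k[0], "age_days": k[1], "peak": v}
                     for k, v in sorted(noise.peaks.items())]
                )
                _write_tsv(noise_table, outdir / "noise.tsv", config, seeds["deconvolve"],
                           index=False)
                if sets:
                    cmap = deconvolve.correlation_map(
                        counts, meta, sets, min_genes=config.corr_min_genes,
                        n_perm=config.corr_nperm, seed=seeds["deconvolve"],
                    )
                    _write_tsv(cmap.set_table, outdir / "corr_map.tsv", config,
                               seeds["deconvolve"], index=False)
                attribution = None
                if gsea_results and hallmark_map:
                    attribution = deconvolve.hallmark_attribution(
                        gsea_results, noise, hallmark_map, q_threshold=config.fdr_threshold
                    )
                    _write_tsv(attribution.table, outdir / "hallmarks_attribution.tsv",
                               config, seeds["deconvolve"], index=False)
                    for _, row in attribution.table.iterrows():
                        report_rows.append({"section": "hallmarks", "key": row["hallmark"],
                                            "value": row["attribution"]})
                    report_rows.append({"section": "hallmarks", "key": "ATH6_noise_facet",
                                        "value": attribution.noise_facet})
                for state, ratio in sorted(noise.peak_ratios.items()):
                    report_rows.append({"section": "noise",
                                        "key": f"peak_ratio_smurf{state}",
                                        "value": round(float(ratio), 3)})
                artifacts["deconvolve"] = str(outdir)

        if config.stages.get("longevity", False) and config.longevity_events:
            with timed("longevity"):
                events = pd.read_csv(config.longevity_events)
                summary = longevity.mean_lifespan(events, control=config.control_condition)
                _write_tsv(summary.table, outdir / "lifespan.tsv", config,
                           seeds["longevity"], index=False)
                if config.prevalence:
                    prev = pd.read_csv(config.prevalence)
                    fit = longevity.fit_prevalence(prev, reference=config.control_condition)
                    _write_tsv(fit.per_condition, outdir / "prevalence_fit.tsv", config,
                               seeds["longevity"], index=False)
                    if fit.interaction is not None:
                        _write_tsv(fit.interaction, outdir / "prevalence_interaction.tsv",
                                   config, seeds["longevity"], index=False)
                for _, row in summary.table.iterrows():
                    report_rows.append({"section": "longevity",
                                        "key": f"mean_lifespan_{row['condition']}",
                                        "value": round(float(row["mean_lifespan"]), 2)})
                artifacts["longevity"] = str(outdir / "lifespan.tsv")

        if config.stages.get("report", True):
            with timed("report"):
                report = pd.DataFrame(report_rows, columns=["section", "key", "value"])
                _write_tsv(report, outdir / "report.tsv", config, seeds["report"],
                           index=False)
                html_rows = "\n".join(
                    f"<tr><td>{r['section']}</td><td>{r['key']}</td><td>{r['value']}</td></tr>"
                    for r in report_rows
                )
                (outdir / "report.html").write_text(
                    "<html><body><h1>smurfdeconv run report</h1>"
                    f"<p>config {config.config_hash()}, seed {config.seed}</p>"
                    f"<table border='1'><tr><th>section</th><th>key</th><th>value</th></tr>"
                    f"{html_rows}</table></body></html>\n"
                )
                artifacts["report"] = str(outdir / "report.tsv")
    except StageError:
        raise
    except Exception as exc:  # attribute failure to the running stage
        logger.error("pipeline aborted in stage %s: %s", current_stage["name"], exc)
        raise StageError(current_stage["name"], exc) from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    return artifacts
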