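"""Readers and writers for the plain-text formats the pipeline uses.

Counts are tab-separated gene x sample tables with a ``gene_id`` index
column; sample metadata is CSV; gene sets use the standard GMT layout
(set name, description, then tab-separated members).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["read_counts", "read_metadata", "read_gmt", "write_gmt", "read_hallmark_map"]


def read_counts(path) -> pd.DataFrame:
    """Read a gene x sample raw count TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index.name = "gene_id"
    return df


def read_metadata(path) -> pd.DataFrame:
    """Read per-sample metadata CSV (sample, age_days, smurf, ...)."""
    meta = pd.read_csv(path, comment="#")
    required = {"sample", "age_days", "smurf"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata is missing required columns: {sorted(missing)}")
    return meta


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file; tolerates a missing description field."""
    sets: dict[str, list[str]] = {}
    for raw in Path(path).read_text().splitlines():
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.rstrip("\n").split("\t")
        name = fields[0]
        # second field is the (optional) description; treat a line with only
        # two fields as name + single member to tolerate malformed writers
        members = fields[2:] if len(fields) > 2 else fields[1:]
        sets[name] = [m for m in members if m]
    return sets


def write_gmt(sets: dict[str, list[str]], path, descriptions: dict[str, str] | None = None) -> None:
    """Write gene sets in GMT format."""
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_hallmark_map(path) -> dict[str, str]:
    """Read a two-column TSV mapping gene-set name to hallmark (ATH) label."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
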