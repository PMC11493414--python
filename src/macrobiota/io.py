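"""Readers, writers and run configuration.

The interchange format is a plain TSV count table: species as rows, samples
as columns, first column the species identifier, header row the sample
identifiers, integer counts throughout.  Cohort labels travel in an optional
two-column sidecar TSV (sample_id <tab> cohort).  Pattern curves and score
tables serialise as tidy TSV; fit reports as JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .patterns import CUTOFFS, PatternCurve
from .table import AbundanceTable

__all__ = [
    "read_table",
    "write_table",
    "read_cohorts",
    "write_cohorts",
    "write_curves",
    "read_curves",
    "write_fit_report",
    "RunConfig",
]


def read_table(path, format: str = "tsv", cohort_path=None) -> AbundanceTable:
    """Read a species x sample count table.

    Only the TSV dialect described in the module docstring is supported.
    Validation errors name the offending row/column.
    """
    if format.lower() != "tsv":
        raise ValueError(f"unsupported format {format!r}; supported: tsv")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such count table: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.empty or df.shape[1] == 0:
        raise ValueError(f"empty count table: {path}")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate species ID {dup!r} in {path}")
    try:
        counts = df.to_numpy(dtype=np.float64)
    except ValueError as exc:
        raise ValueError(f"non-numeric count in {path}: {exc}") from exc
    if not np.isfinite(counts).all() or (counts != np.round(counts)).any():
        i, j = np.argwhere((~np.isfinite(counts)) | (counts != np.round(counts)))[0]
        raise ValueError(
            f"non-integer count at species {df.index[i]!r}, sample {df.columns[j]!r} in {path}"
        )
    if (counts < 0).any():
        i, j = np.argwhere(counts < 0)[0]
        raise ValueError(
            f"negative count at species {df.index[i]!r}, sample {df.columns[j]!r} in {path}"
        )
    cohort = None
    if cohort_path is not None:
        mapping = read_cohorts(cohort_path)
        cohort = np.array([mapping.get(c, "") for c in df.columns], dtype=object)
    return AbundanceTable(
        counts=counts.astype(np.int64),
        species_ids=list(df.index),
        sample_ids=list(df.columns),
        cohort=cohort,
    )


def write_table(table: AbundanceTable, path) -> None:
    """Write the TSV count-table dialect (round-trips byte-identically)."""
    df = table.to_dataframe()
    df.index.name = "species_id"
    df.to_csv(path, sep="\t")


def read_cohorts(path) -> dict:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"cohort file {path} needs columns: sample_id, cohort")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_cohorts(table: AbundanceTable, path) -> None:
    pd.DataFrame({"sample_id": table.sample_ids, "cohort": table.cohort}).to_csv(
        path, sep="\t", index=False
    )


def write_curves(curves, path, header_meta: dict | None = None) -> None:
    """Serialise pattern curves as tidy TSV (kind, kappa, cohort, x, y)."""
    rows = []
    for c in curves:
        for x, y in zip(c.x, c.y):
            rows.append({"kind": c.kind, "kappa": c.kappa, "cohort": c.cohort, "x": x, "y": y})
    df = pd.DataFrame(rows, columns=["kind", "kappa", "cohort", "x", "y"])
    with open(path, "w") as fh:
        if header_meta:
            fh.write("# " + json.dumps(header_meta, sort_keys=True) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_curves(path) -> list[PatternCurve]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for (kind, kappa, cohort), grp in df.groupby(["kind", "kappa", "cohort"], dropna=False, sort=False):
        out.append(
            PatternCurve(
                kind=kind,
                x=grp["x"].to_numpy(),
                y=grp["y"].to_numpy(),
                kappa=float(kappa),
                cohort="" if pd.isna(cohort) else str(cohort),
            )
        )
    return out


def write_fit_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run; embedded in every output."""

    input: str | None = None
    cohort_file: str | None = None
    cutoffs: tuple = tuple(CUTOFFS.values())
    models: tuple = ("mssd", "pslg", "md")
    n_realizations: int = 500
    seed: int = 0
    outdir: str = "."
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cutoffs = tuple(float(k) for k in self.cutoffs)
        if any(k < 0 for k in self.cutoffs):
            raise ValueError("cutoffs must be non-negative")
        if list(self.cutoffs) != sorted(self.cutoffs):
            raise ValueError("cutoffs must be sorted ascending")
        self.models = tuple(str(m).lower() for m in self.models)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
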