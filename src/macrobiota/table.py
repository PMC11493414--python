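"""Species-by-sample count tables.

The :class:`AbundanceTable` is the exchange object of the whole package: an
integer matrix of classified-read counts with species as rows and samples as
columns, plus per-sample read depths and an optional cohort label per sample
(e.g. ``"H"``/``"U"``).  Relative abundances are always a *derived* view —
counts divided by the per-sample total of classified reads — and are never
stored, so the compositional and count representations cannot drift apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["AbundanceTable"]


@dataclass
class AbundanceTable:
    """Species x sample integer count matrix with depths and cohort labels.

    Parameters
    ----------
    counts
        Non-negative integer matrix of shape (S, R).
    species_ids, sample_ids
        Row and column labels.  Defaults are ``sp0001``-style identifiers.
    cohort
        Per-sample cohort label; defaults to ``""`` for every sample.
    depths
        Per-sample totals of classified reads, N_r.  Default: the column
        sums of ``counts``.  After a relative-abundance cutoff has zeroed
        entries, the stored depths stay at their original values so that
        relative abundances remain referenced to the classified-read total.
    """

    counts: np.ndarray
    species_ids: list[str] = field(default=None)  # type: ignore[assignment]
    sample_ids: list[str] = field(default=None)  # type: ignore[assignment]
    cohort: np.ndarray = field(default=None)  # type: ignore[assignment]
    depths: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D species x sample matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise ValueError("counts must be integers")
            self.counts = as_int
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValueError(f"negative count at species row {i}, sample column {j}")
        s, r = self.counts.shape
        if s == 0 or r == 0:
            raise ValueError("empty abundance table")
        if self.species_ids is None:
            self.species_ids = [f"sp{i + 1:04d}" for i in range(s)]
        else:
            self.species_ids = [str(x) for x in self.species_ids]
        if len(set(self.species_ids)) != len(self.species_ids):
            raise ValueError("duplicate species IDs")
        if self.sample_ids is None:
            self.sample_ids = [f"sample{j + 1:04d}" for j in range(r)]
        else:
            self.sample_ids = [str(x) for x in self.sample_ids]
        if len(self.species_ids) != s or len(self.sample_ids) != r:
            raise ValueError("label lengths do not match count matrix shape")
        if self.cohort is None:
            self.cohort = np.array([""] * r, dtype=object)
        else:
            self.cohort = np.asarray(self.cohort, dtype=object)
            if self.cohort.shape != (r,):
                raise ValueError("cohort must have one label per sample")
        col = self.counts.sum(axis=0)
        if self.depths is None:
            self.depths = col.astype(np.int64)
        else:
            self.depths = np.asarray(self.depths, dtype=np.int64)
            if self.depths.shape != (r,):
                raise ValueError("depths must have one entry per sample")
            if (self.depths < col).any():
                raise ValueError("depths smaller than column sums")

    # ------------------------------------------------------------------
    @property
    def n_species(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def relative_abundances(self) -> np.ndarray:
        """v_ij = counts_ij / N_j, referenced to the classified-read depths."""
        depths = np.where(self.depths > 0, self.depths, 1)
        return self.counts / depths

    def present(self) -> np.ndarray:
        """Boolean presence/absence matrix (counts > 0)."""
        return self.counts > 0

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        cohort: np.ndarray | dict | None = None,
        depths: np.ndarray | None = None,
    ) -> "AbundanceTable":
        """Build a table from a species-indexed DataFrame (samples as columns)."""
        if isinstance(cohort, dict):
            cohort = np.array([cohort.get(c, "") for c in df.columns], dtype=object)
        return cls(
            counts=df.to_numpy(),
            species_ids=list(df.index.astype(str)),
            sample_ids=list(df.columns.astype(str)),
            cohort=cohort,
            depths=depths,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.species_ids, columns=self.sample_ids)

    def select_samples(self, mask: np.ndarray) -> "AbundanceTable":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return replace(
            self,
            counts=self.counts[:, idx],
            sample_ids=[self.sample_ids[j] for j in idx],
            cohort=self.cohort[idx],
            depths=self.depths[idx],
        )

    def select_species(self, mask: np.ndarray) -> "AbundanceTable":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return replace(
            self,
            counts=self.counts[idx, :],
            species_ids=[self.species_ids[i] for i in idx],
        )

    def subset_cohort(self, label: str) -> "AbundanceTable":
        return self.select_samples(self.cohort == label)

    def copy(self) -> "AbundanceTable":
        return replace(
            self,
            counts=self.counts.copy(),
            species_ids=list(self.species_ids),
            sample_ids=list(self.sample_ids),
            cohort=self.cohort.copy(),
            depths=self.depths.copy(),
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        lab = sorted(set(map(str, self.cohort)) - {""})
        extra = f", cohorts={lab}" if lab else ""
        return f"AbundanceTable(S={self.n_species}, R={self.n_samples}{extra})"
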