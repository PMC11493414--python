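"""Macroecological patterns of species-by-sample count tables.

Every pattern operates on an :class:`~macrobiota.table.AbundanceTable` and
returns either plain arrays (means, occupancies, diversities) or a
:class:`PatternCurve` carrying the abscissa/ordinate pair plus the metadata
needed to reproduce it (cutoff, bin edges, cohort label).

Relative-abundance cutoffs mimic the removal of false-positive species from
taxonomic profiles: entries with v_ij < kappa are set to zero *after* count
generation, and the remaining counts are not renormalised (presence/absence
and diversity then follow the thresholded table directly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .table import AbundanceTable

__all__ = [
    "PatternCurve",
    "PATTERN_KINDS",
    "CUTOFFS",
    "apply_cutoff",
    "mean_abundance",
    "taylor_points",
    "diversity",
    "occupancy",
    "ao_curve",
    "sad",
    "sar_curve",
]

PATTERN_KINDS = ("MAD", "TL", "SAD", "AO", "OCCUPANCY", "SAR", "DIVERSITY")

#: the three relative-abundance cutoffs used throughout: low, medium, high
CUTOFFS = {"low": 4.5e-7, "medium": 9e-6, "high": 1.8e-4}


@dataclass
class PatternCurve:
    """A named empirical or model-generated macroecological pattern."""

    kind: str
    x: np.ndarray
    y: np.ndarray
    kappa: float = 0.0
    cohort: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in PATTERN_KINDS:
            raise ValueError(f"unknown pattern kind {self.kind!r}")
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have matching shapes")
        if not np.isfinite(self.y).all():
            raise ValueError("pattern ordinates must be finite")


# ----------------------------------------------------------------------
def apply_cutoff(table: AbundanceTable, kappa: float, renormalize: bool = False) -> AbundanceTable:
    """Zero every entry whose relative abundance is below ``kappa``.

    Relative abundances are referenced to the stored per-sample depths; the
    surviving counts are left unchanged unless ``renormalize`` is set, in
    which case depths are reset to the post-cutoff column sums.
    """
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    out = table.copy()
    if kappa == 0:
        return out
    v = table.relative_abundances()
    out.counts[v < kappa] = 0
    if renormalize:
        out.depths = out.counts.sum(axis=0).astype(np.int64)
    return out


def mean_abundance(table: AbundanceTable) -> np.ndarray:
    """Across-sample mean relative abundance per species (zeros included)."""
    if table.n_samples < 1:
        raise ValueError("table has no samples")
    return table.relative_abundances().mean(axis=1)


def taylor_points(
    table: AbundanceTable, min_occupancy: float = 0.5, sampling_correction: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Across-sample (mean, unbiased variance) of relative abundance per species.

    Species with occupancy below ``min_occupancy`` are excluded: species
    present in only a few samples blur the mean-variance scaling, since
    their observed variance is dominated by detection noise.

    With ``sampling_correction`` the expected within-sample read-sampling
    variance, estimated per sample as ``v(1-v)/(N-1)`` and averaged, is
    subtracted from the across-sample variance.  At finite depth the raw
    variance of a species with mean v is inflated by about ``v/N``, which
    flattens the mean-variance scaling near the detection threshold; the
    corrected points estimate the variance of the underlying composition.
    """
    if not 0 <= min_occupancy <= 1:
        raise ValueError("min_occupancy must lie in [0, 1]")
    if table.n_samples < 2:
        raise ValueError("variance across samples needs at least 2 samples")
    v = table.relative_abundances()
    keep = occupancy(table) >= min_occupancy
    mean = v[keep].mean(axis=1)
    var = v[keep].var(axis=1, ddof=1)
    if sampling_correction:
        n = np.maximum(np.asarray(table.depths, dtype=float), 2.0)
        var = var - (v[keep] * (1.0 - v[keep]) / (n - 1.0)).mean(axis=1)
    return mean, var


def diversity(table: AbundanceTable) -> tuple[np.ndarray, int]:
    """(alpha per sample, gamma): per-sample and pooled species richness."""
    present = table.present()
    alpha = present.sum(axis=0)
    gamma = int(present.any(axis=1).sum())
    return alpha, gamma


def occupancy(table: AbundanceTable) -> np.ndarray:
    """Fraction of samples in which each species has a nonzero count."""
    return table.present().mean(axis=1)


def _log_bin_edges(values: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if lo == hi:  # degenerate range: a single enclosing bin
        return np.array([lo * 0.5, hi * 2.0]) if lo > 0 else np.array([0.0, 1.0])
    return np.geomspace(lo, hi * (1 + 1e-12), n_bins + 1)


def ao_curve(
    table: AbundanceTable,
    n_bins: int = 20,
    kappa: float = 0.0,
    cohort: str = "",
    bin_edges: np.ndarray | None = None,
) -> PatternCurve:
    """Abundance-occupancy curve: mean occupancy in log-spaced bins of vbar.

    The per-species scatter (log vbar_i, o_i) is kept in ``meta``; the curve
    averages occupancy within log-spaced abundance bins, dropping empty bins.
    """
    vbar = mean_abundance(table)
    occ = occupancy(table)
    pos = vbar > 0
    if not pos.any():
        raise ValueError("no species with positive mean abundance")
    vb, oc = vbar[pos], occ[pos]
    edges = np.asarray(bin_edges) if bin_edges is not None else _log_bin_edges(vb, n_bins)
    idx = np.clip(np.digitize(vb, edges) - 1, 0, len(edges) - 2)
    xs, ys = [], []
    for b in range(len(edges) - 1):
        m = idx == b
        if m.any():
            xs.append(np.log(np.sqrt(edges[b] * edges[b + 1])))
            ys.append(oc[m].mean())
    return PatternCurve(
        kind="AO",
        x=np.array(xs),
        y=np.array(ys),
        kappa=kappa,
        cohort=cohort,
        meta={"bin_edges": edges, "scatter_log_vbar": np.log(vb), "scatter_occupancy": oc},
    )


def sad(
    table: AbundanceTable,
    scope: str = "metacommunity",
    n_bins: int = 20,
    kappa: float = 0.0,
    cohort: str = "",
    bin_edges: np.ndarray | None = None,
) -> PatternCurve:
    """Species abundance distribution, log-binned, with bin masses summing to 1.

    ``metacommunity`` scope pools all positive per-sample relative abundances
    across samples; ``sample`` scope averages the per-sample histograms on the
    shared bin grid (each sample weighted equally).
    """
    if scope not in ("sample", "metacommunity"):
        raise ValueError("scope must be 'sample' or 'metacommunity'")
    v = table.relative_abundances()
    pooled = v[v > 0]
    if pooled.size == 0:
        raise ValueError("table has no positive abundances")
    edges = np.asarray(bin_edges) if bin_edges is not None else _log_bin_edges(pooled, n_bins)
    centers = np.log(np.sqrt(edges[:-1] * edges[1:]))
    if scope == "metacommunity":
        hist, _ = np.histogram(pooled, bins=edges)
        mass = hist / hist.sum() if hist.sum() else hist.astype(float)
    else:
        per_sample = []
        for r in range(table.n_samples):
            col = v[:, r][v[:, r] > 0]
            if col.size == 0:
                continue
            h, _ = np.histogram(col, bins=edges)
            tot = h.sum()
            per_sample.append(h / tot if tot else h.astype(float))
        mass = np.mean(per_sample, axis=0)
        mass = mass / mass.sum()
    return PatternCurve(
        kind="SAD", x=centers, y=mass, kappa=kappa, cohort=cohort, meta={"bin_edges": edges, "scope": scope}
    )


def sar_curve(
    table: AbundanceTable,
    n_permutations: int = 50,
    seed=None,
    kappa: float = 0.0,
    cohort: str = "",
) -> PatternCurve:
    """Metagenomic species-area relation.

    Samples are aggregated in random order; after each addition the number of
    unique species in the aggregate, normalised by the gamma diversity, is
    recorded against the cumulative number of classified reads.  The curve is
    averaged over ``n_permutations`` sample orderings; its final ordinate is
    exactly 1.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    present = table.present()
    reads = table.counts.sum(axis=0).astype(float)
    gamma = present.any(axis=1).sum()
    if gamma == 0:
        raise ValueError("table has no present species")
    R = table.n_samples
    cum_reads = np.zeros(R)
    cum_rich = np.zeros(R)
    for _ in range(n_permutations):
        order = rng.permutation(R)
        cum_reads += np.cumsum(reads[order])
        cum_rich += np.cumsum(present[:, order], axis=1).astype(bool).sum(axis=0)
    x = cum_reads / n_permutations
    y = cum_rich / n_permutations / gamma
    y[-1] = 1.0  # exact by construction; guard against float accumulation
    return PatternCurve(kind="SAR", x=x, y=y, kappa=kappa, cohort=cohort, meta={"n_permutations": n_permutations})
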