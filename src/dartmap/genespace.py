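"""Marker distribution relative to annotated gene models.

Pseudochromosomes are tiled into fixed-width bins (5 Mbp by default,
half-open, the final bin truncated at the chromosome end); probe
positions, genetically mapped markers and gene models are counted per
bin by their start coordinate, so every feature is counted exactly once.
Bin-level agreement between feature counts is measured with a Spearman
rank correlation (mid-rank ties, t-approximation p value).  Gene-space
proximity is the bp distance from each probe interval to the closest
gene model on the same chromosome (0 on any overlap), summarized into
distance-class proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

DEFAULT_BIN_WIDTH = 5_000_000
#: distance class edges in bp; classes: 0, (0,1k], (1k,5k], (5k,10k], >10k
DEFAULT_EDGES = (1_000, 5_000, 10_000)


def make_bins(
    chromosome_lengths: dict[str, int], width: int = DEFAULT_BIN_WIDTH
) -> pd.DataFrame:
    """Half-open bins tiling each chromosome; last bin truncated.

    Returns columns chromosome, bin_index, start, end.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    rows = []
    for chrom, length in chromosome_lengths.items():
        if length <= 0:
            raise ValueError(f"non-positive length for {chrom}")
        n_bins = -(-length // width)  # ceil
        for b in range(n_bins):
            rows.append((chrom, b, b * width, min((b + 1) * width, length)))
    return pd.DataFrame(rows, columns=["chromosome", "bin_index", "start", "end"])


def count_features(
    bins: pd.DataFrame, positions: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Count features per bin by start coordinate.

    ``positions`` maps a feature name (e.g. ``probes``, ``markers``,
    ``genes``) to a frame with columns chromosome and bp; a count column
    ``n_<name>`` is added per feature type.  Positions beyond the
    chromosome end raise a validation error; totals are conserved.
    """
    out = bins.copy()
    chrom_groups = {c: g for c, g in bins.groupby("chromosome")}
    for name, frame in positions.items():
        col = np.zeros(len(bins), dtype=int)
        for chrom, sub in frame.groupby("chromosome"):
            if chrom not in chrom_groups:
                raise ValueError(f"{name}: unknown chromosome {chrom}")
            cb = chrom_groups[chrom]
            end = int(cb["end"].max())
            bp = sub["bp"].to_numpy()
            if np.any((bp < 0) | (bp >= end)):
                raise ValueError(f"{name}: position beyond {chrom} end ({end})")
            width = int(cb["end"].iloc[0] - cb["start"].iloc[0]) if len(cb) else 1
            width = int((cb["end"] - cb["start"]).max())
            idx = bp // width
            counts = np.bincount(idx, minlength=len(cb))
            col[cb.index] += counts[: len(cb)]
        out[f"n_{name}"] = col
    return out


@dataclass
class BinCorrelation:
    rho: float | None
    p_value: float | None
    n_bins: int


def bin_correlation(counts_a, counts_b) -> BinCorrelation:
    """Spearman rank correlation between two per-bin count vectors.

    Mid-rank ties; p value by the t approximation.  Undefined (None) for
    constant input vectors.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.size != b.size:
        raise ValueError("count vectors must have equal length")
    if a.size < 4:
        raise ValueError("need at least 4 bins")
    if np.all(a == a[0]) or np.all(b == b[0]):
        return BinCorrelation(rho=None, p_value=None, n_bins=a.size)
    res = stats.spearmanr(a, b)
    return BinCorrelation(
        rho=float(res.statistic), p_value=float(res.pvalue), n_bins=a.size
    )


@dataclass
class GeneDistanceReport:
    """Per-probe distances to the closest gene model, with class shares."""

    distances: np.ndarray
    class_edges: tuple[int, ...]
    n_excluded: int = 0  # probes on chromosomes without gene models

    @property
    def class_labels(self) -> list[str]:
        edges = self.class_edges
        labels = ["0"]
        prev = 0
        for e in edges:
            labels.append(f"({prev},{e}]")
            prev = e
        labels.append(f">{edges[-1]}")
        return labels

    @property
    def class_proportions(self) -> dict[str, float]:
        d = self.distances
        if d.size == 0:
            return {lab: 0.0 for lab in self.class_labels}
        edges = self.class_edges
        counts = [int((d == 0).sum())]
        prev = 0
        for e in edges:
            counts.append(int(((d > prev) & (d <= e)).sum()))
            prev = e
        counts.append(int((d > edges[-1]).sum()))
        return {
            lab: c / d.size for lab, c in zip(self.class_labels, counts)
        }


def nearest_gene_distances(
    probe_intervals: pd.DataFrame,
    genes: pd.DataFrame,
    class_edges: tuple[int, ...] = DEFAULT_EDGES,
) -> GeneDistanceReport:
    """Distance from each probe interval to the closest gene model.

    ``probe_intervals`` needs columns chromosome, start, end (0-based
    half-open); ``genes`` needs scaffold (or chromosome), start, end.
    Distance is 0 on any overlap, otherwise the gap between closest
    interval ends on the same chromosome; strand is ignored.  Probes on
    chromosomes without annotated genes are excluded and counted.
    """
    gene_chrom_col = "scaffold" if "scaffold" in genes.columns else "chromosome"
    trees: dict[str, IntervalTree] = {}
    starts_sorted: dict[str, np.ndarray] = {}
    ends_sorted: dict[str, np.ndarray] = {}
    for chrom, sub in genes.groupby(gene_chrom_col):
        trees[chrom] = IntervalTree.from_tuples(
            zip(sub["start"].astype(int), sub["end"].astype(int))
        )
        starts_sorted[chrom] = np.sort(sub["start"].to_numpy(int))
        ends_sorted[chrom] = np.sort(sub["end"].to_numpy(int))

    distances = []
    n_excluded = 0
    for row in probe_intervals.itertuples(index=False):
        chrom, s, e = row.chromosome, int(row.start), int(row.end)
        if chrom not in trees:
            n_excluded += 1
            continue
        if trees[chrom].overlap(s, e):
            distances.append(0)
            continue
        gap = np.inf
        ends = ends_sorted[chrom]
        i = int(np.searchsorted(ends, s, side="right")) - 1
        if i >= 0:
            gap = min(gap, s - int(ends[i]))
        starts = starts_sorted[chrom]
        j = int(np.searchsorted(starts, e, side="left"))
        if j < starts.size:
            gap = min(gap, int(starts[j]) - e)
        distances.append(int(gap) if np.isfinite(gap) else 0)
    return GeneDistanceReport(
        distances=np.asarray(distances, dtype=int),
        class_edges=tuple(class_edges),
        n_excluded=n_excluded,
    )
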