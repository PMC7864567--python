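"""Kernel-smoothed genomic expression topography and region permutation tests.

For a cell type, mean depth-normalized expression of each gene is placed at
the gene's transcription start site and smoothed with a Gaussian kernel
(default bandwidth 200 kb): ``track(x) = sum_g w_g * phi_sigma(x - tss_g)``,
roughly a running mean of normalized expression along the genome.  Regions
of interest (recurrent copy-number gains/losses, breakpoint windows) are then
tested by comparing the mean track difference between two cell types inside
the region against the same statistic in randomly placed regions of the same
size; the permutation p-value is the plain fraction of random regions with a
difference at least as large as the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "GenomicTrack",
    "RegionTest",
    "mean_normalized_expression",
    "smooth_expression_track",
    "define_recurrent_regions",
    "define_breakpoint_region",
    "region_difference_test",
]


@dataclass
class GenomicTrack:
    """Smoothed expression density per chromosome on a regular grid."""

    positions: dict[str, np.ndarray]
    values: dict[str, np.ndarray]
    bandwidth: float
    grid_step: float
    cell_type: str = ""

    def total_weight(self) -> float:
        """Grid-quadrature integral of the track (should match input weight)."""
        return float(
            sum(np.trapezoid(self.values[c], self.positions[c]) for c in self.values)
        )

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in self.positions:
                pos = self.positions[chrom]
                val = self.values[chrom]
                for p, v in zip(pos, val):
                    fh.write(f"{chrom}\t{int(p)}\t{int(p + self.grid_step)}\t{v:.6g}\n")


@dataclass
class RegionTest:
    region: tuple[str, int, int]
    observed_diff: float
    null_diffs: np.ndarray
    n_permutations: int = field(init=False)
    p: float = field(init=False)

    def __post_init__(self) -> None:
        self.null_diffs = np.asarray(self.null_diffs, dtype=float)
        self.n_permutations = len(self.null_diffs)
        self.p = float((self.null_diffs >= self.observed_diff).mean())


def mean_normalized_expression(adata, cells=None) -> pd.Series:
    """Per-gene mean of depth-normalized counts over the given cells.

    Each cell's counts are divided by its total, so every cell contributes
    unit weight; the mean (not the sum) keeps tracks comparable between cell
    types of different sizes.
    """
    import scipy.sparse as sp

    X = adata.layers["counts"] if "counts" in adata.layers else adata.X
    X = sp.csr_matrix(X, dtype=float)
    if cells is not None:
        X = X[adata.obs_names.get_indexer(pd.Index(cells))]
    totals = np.asarray(X.sum(axis=1)).ravel()
    totals[totals == 0] = 1.0
    normalized = sp.diags(1.0 / totals) @ X
    return pd.Series(np.asarray(normalized.mean(axis=0)).ravel(), index=adata.var_names)


def smooth_expression_track(
    annotation: pd.DataFrame,
    weights: pd.Series,
    bandwidth: float = 200_000.0,
    grid_step: float | None = None,
    chrom_lengths: dict[str, int] | None = None,
    cell_type: str = "",
) -> GenomicTrack:
    """Gaussian-kernel smoothed expression density along the genome.

    Parameters
    ----------
    annotation
        Table with columns ``gene, chrom, tss`` (0-based bp).
    weights
        Non-negative per-gene weights (library-size-normalized mean
        expression of one cell type); genes must appear in the annotation.
    bandwidth
        Standard deviation of the Gaussian kernel in bp (default 200,000).
    grid_step
        Evaluation grid spacing; defaults to bandwidth / 10.
    chrom_lengths
        Chromosome lengths for the grid extent; default: max TSS + 3
        bandwidths per chromosome.
    """
    weights = pd.Series(weights, dtype=float)
    if (weights < 0).any():
        bad = weights.index[weights < 0][:3].tolist()
        raise ValueError(f"negative weights not allowed (e.g. {bad})")
    missing = weights.index.difference(pd.Index(annotation["gene"]))
    if len(missing):
        raise ValueError(f"genes missing from the annotation: {list(missing[:5])}")
    if grid_step is None:
        grid_step = bandwidth / 10.0

    ann = annotation.set_index("gene").loc[weights.index]
    positions, values = {}, {}
    for chrom, sub in ann.groupby("chrom", sort=True, observed=True):
        if chrom_lengths is not None and chrom in chrom_lengths:
            length = chrom_lengths[chrom]
        else:
            length = float(sub["tss"].max()) + 3 * bandwidth
        grid = np.arange(0.0, length + grid_step / 2, grid_step)
        tss = sub["tss"].to_numpy(dtype=float)
        w = weights.loc[sub.index].to_numpy()
        # (grid, genes) kernel matrix; chromosomes are modest at desk scale
        dens = norm.pdf((grid[:, None] - tss[None, :]) / bandwidth) / bandwidth
        positions[chrom] = grid
        values[chrom] = dens @ w
    return GenomicTrack(positions, values, bandwidth, grid_step, cell_type)


def define_recurrent_regions(
    bins: pd.DataFrame,
    calls: pd.DataFrame | np.ndarray,
    min_samples: int = 200,
) -> pd.DataFrame:
    """Maximal runs of bins altered in at least ``min_samples`` tumors.

    ``bins`` holds the shared genome partition (columns ``chrom, start,
    end``, sorted, non-overlapping); ``calls`` is samples × bins with values
    in {-1 (loss), 0, +1 (gain)}.  Gains and losses are assessed separately;
    a bin qualifies when its altered-sample count is >= ``min_samples``
    ("200 or more" is inclusive).
    """
    calls = np.asarray(calls)
    if calls.shape[1] != len(bins):
        raise ValueError("calls and bins disagree on the number of bins")
    for chrom, sub in bins.groupby("chrom", sort=False):
        s = sub.sort_index()
        if not (s["start"].to_numpy() == sorted(s["start"])).all() or (
            s["end"].to_numpy()[:-1] > s["start"].to_numpy()[1:]
        ).any():
            raise ValueError(f"bin grid on {chrom} is unsorted or overlapping")

    regions = []
    for kind, val in (("gain", 1), ("loss", -1)):
        qualifies = (calls == val).sum(axis=0) >= min_samples
        for chrom, sub in bins.groupby("chrom", sort=False):
            idx = sub.index.to_numpy()
            q = qualifies[idx]
            start_i = None
            for j, flag in enumerate(list(q) + [False]):
                if flag and start_i is None:
                    start_i = j
                elif not flag and start_i is not None:
                    regions.append(
                        {
                            "chrom": chrom,
                            "start": int(sub.iloc[start_i]["start"]),
                            "end": int(sub.iloc[j - 1]["end"]),
                            "kind": kind,
                            "n_bins": j - start_i,
                        }
                    )
                    start_i = None
    return pd.DataFrame(regions, columns=["chrom", "start", "end", "kind", "n_bins"])


def define_breakpoint_region(
    chrom: str,
    position: int,
    chrom_lengths: dict[str, int],
    half_width: float = 1e6,
) -> tuple[str, int, int]:
    """Window of ±half_width around a copy-number transition point, clipped
    to the chromosome."""
    if chrom not in chrom_lengths:
        raise ValueError(f"unknown chromosome '{chrom}'")
    length = chrom_lengths[chrom]
    if not (0 <= position <= length):
        raise ValueError(f"position {position} is off chromosome {chrom} (length {length})")
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    start = max(0, int(position - half_width))
    end = min(length, int(position + half_width))
    if start >= end:
        raise ValueError("degenerate empty breakpoint region")
    return (chrom, start, end)


def _region_mean(track_diff: dict, positions: dict, chrom: str, start: float, end: float) -> float:
    pos = positions[chrom]
    lo, hi = np.searchsorted(pos, [start, end])
    if hi <= lo:
        raise ValueError("region contains no grid points")
    return float(track_diff[chrom][lo:hi].mean())


def region_difference_test(
    track_a: GenomicTrack,
    track_b: GenomicTrack,
    region: tuple[str, int, int],
    n_permutations: int = 1000,
    seed: int = 0,
) -> RegionTest:
    """Permutation test of the mean track difference within a region.

    The observed statistic is the mean of (track_a - track_b) over the
    region's grid points.  The null distribution places ``n_permutations``
    regions of the same length uniformly over all valid start positions on
    chromosomes long enough to hold the region; the p-value is the fraction
    of null differences >= the observed one (the plain empirical fraction,
    which can be 0).
    """
    if track_a.grid_step != track_b.grid_step or track_a.bandwidth != track_b.bandwidth:
        raise ValueError("tracks must share grid and bandwidth")
    for chrom in track_a.positions:
        if chrom not in track_b.positions or len(track_a.positions[chrom]) != len(
            track_b.positions[chrom]
        ):
            raise ValueError("tracks must share the evaluation grid")
    chrom, start, end = region
    length = end - start
    diff = {c: track_a.values[c] - track_b.values[c] for c in track_a.values}
    observed = _region_mean(diff, track_a.positions, chrom, start, end)

    eligible = [
        c
        for c in track_a.positions
        if track_a.positions[c][-1] - track_a.positions[c][0] >= length
    ]
    if not eligible:
        raise ValueError("region is longer than every chromosome")
    max_start = {
        c: track_a.positions[c][-1] - length for c in eligible
    }
    # uniform over valid start positions genome-wide
    weights = np.array([max_start[c] - track_a.positions[c][0] + 1.0 for c in eligible])
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        c = eligible[rng.choice(len(eligible), p=weights)]
        s = rng.uniform(track_a.positions[c][0], max_start[c])
        null[i] = _region_mean(diff, track_a.positions, c, s, s + length)
    return RegionTest((chrom, start, end), observed, null)
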