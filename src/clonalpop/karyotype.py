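"""Aneuploidy and loss-of-heterozygosity detection from windowed tracks.

Depth is summarised as the per-window median divided by the genome-wide
median, so a euploid window sits at ratio 1 and a trisomic window of a
diploid at 1.5.  Heterozygosity is the per-window count of heterozygous SNPs
divided by the genome-wide median window count.  Runs of windows in a
non-baseline copy band become aneuploid segments; runs of near-zero
heterozygosity become LOH segments, classified as copy-neutral (depth ratio
near 1) or deletion-driven (near 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import DepthRaw, GenotypeMatrix


@dataclass
class AnalysisConfig:
    """Window sizes and calling knobs.

    ``depth_window`` (30 kbp) and ``loh_window`` (25 kbp) follow the
    windowing of the underlying survey; ``band_tolerance`` (how close a
    depth ratio must be to a copy-state band) and ``min_run`` (minimum
    consecutive windows per call, default 5 windows = 150 kbp of depth) are
    this package's own explicit knobs for what the survey judged visually.
    """

    depth_window: int = 30_000
    loh_window: int = 25_000
    band_tolerance: float = 0.15
    min_run: int = 5
    loh_het_threshold: float = 0.1
    use_mean: bool = False  # window statistic: median (default) or mean

    def __post_init__(self) -> None:
        if self.depth_window <= 0 or self.loh_window <= 0:
            raise ValidationError("window sizes must be positive")
        if not (0 < self.band_tolerance < 0.5):
            raise ValidationError("band_tolerance must lie in (0, 0.5)")
        if self.min_run < 1:
            raise ValidationError("min_run must be >= 1")


@dataclass
class WindowTrack:
    """Per-window ratios on a fixed grid (0-based half-open windows)."""

    contig: np.ndarray
    start: np.ndarray
    end: np.ndarray
    ratio: np.ndarray
    complete: np.ndarray  # full-width windows; partial ones are not called


@dataclass
class AneuploidSegment:
    strain_id: str
    contig: str
    start: int
    end: int
    copy_state: int
    mean_ratio: float
    n_windows: int


@dataclass
class LOHSegment:
    strain_id: str
    contig: str
    start: int
    end: int
    classification: str  # "copy_neutral" | "deletion" | "ambiguous"
    mean_het_ratio: float
    mean_depth_ratio: float


# ---------------------------------------------------------------------------
# depth windows


def window_depth(raw: DepthRaw, config: AnalysisConfig = AnalysisConfig()) -> WindowTrack:
    """Median (or mean) depth per window as a fraction of the genome median.

    The genome-wide median is a length-weighted median of the input values,
    i.e. the median of the per-base depth.  Trailing partial windows are
    returned but flagged incomplete so segment calling can skip them.
    """
    lengths = (raw.end - raw.start).astype(float)
    genome_median = _weighted_median(raw.depth, lengths)
    if genome_median <= 0:
        raise ValidationError("genome-wide median depth is zero")
    contigs, starts, ends, ratios, complete = [], [], [], [], []
    w = config.depth_window
    for contig in pd.unique(raw.contig):
        sel = raw.contig == contig
        s, e, d = raw.start[sel], raw.end[sel], raw.depth[sel]
        span = int(e.max())
        for wstart in range(0, span, w):
            wend = min(wstart + w, span)
            inside = (s >= wstart) & (e <= wend)
            if not inside.any():
                continue
            vals, wts = d[inside], (e - s)[inside].astype(float)
            if config.use_mean:
                stat = float((vals * wts).sum() / wts.sum())
            else:
                stat = _weighted_median(vals, wts)
            contigs.append(contig)
            starts.append(wstart)
            ends.append(wend)
            ratios.append(stat / genome_median)
            complete.append(wend - wstart == w)
    if not contigs:
        raise ValidationError("depth track does not cover one full window")
    return WindowTrack(
        np.array(contigs, dtype=object),
        np.array(starts),
        np.array(ends),
        np.array(ratios),
        np.array(complete, dtype=bool),
    )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median (midpoint rule, like np.median)."""
    order = np.argsort(values)
    v, w = values[order].astype(float), weights[order].astype(float)
    cum = np.cumsum(w) - 0.5 * w  # probability mass centred on each value
    return float(np.interp(0.5 * w.sum(), cum, v))


def call_aneuploid_segments(
    track: WindowTrack,
    baseline_ploidy: int,
    config: AnalysisConfig = AnalysisConfig(),
    strain_id: str = "",
) -> list[AneuploidSegment]:
    """Runs of >= min_run windows assigned to one non-baseline copy band.

    Each complete window is assigned to the nearest band k / baseline_ploidy
    (k = 1 .. 2 x baseline) when within ``band_tolerance`` of it, else left
    unassigned; maximal runs in a single non-baseline band become segments
    spanning the union of their windows.
    """
    if baseline_ploidy not in (1, 2, 4):
        raise ValidationError(f"unsupported baseline ploidy {baseline_ploidy}")
    ks = np.arange(1, 2 * baseline_ploidy + 1)
    bands = ks / baseline_ploidy
    segments: list[AneuploidSegment] = []
    for contig in pd.unique(track.contig):
        sel = np.flatnonzero((track.contig == contig) & track.complete)
        if len(sel) == 0:
            continue
        ratios = track.ratio[sel]
        dist = np.abs(ratios[:, None] - bands[None, :])
        nearest = np.argmin(dist, axis=1)
        assigned = np.where(
            dist[np.arange(len(ratios)), nearest] <= config.band_tolerance,
            ks[nearest],
            0,
        )
        for run_start, run_end in _runs(assigned):
            k = assigned[run_start]
            if k == 0 or k == baseline_ploidy:
                continue
            if run_end - run_start < config.min_run:
                continue
            idx = sel[run_start:run_end]
            segments.append(
                AneuploidSegment(
                    strain_id=strain_id,
                    contig=str(contig),
                    start=int(track.start[idx[0]]),
                    end=int(track.end[idx[-1]]),
                    copy_state=int(k),
                    mean_ratio=float(track.ratio[idx].mean()),
                    n_windows=len(idx),
                )
            )
    return segments


def _runs(values: np.ndarray):
    """Yield (start, end) index pairs of maximal constant runs."""
    if len(values) == 0:
        return
    change = np.flatnonzero(np.diff(values) != 0) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(values)]])
    yield from zip(starts, ends)


# ---------------------------------------------------------------------------
# heterozygosity windows


def window_heterozygosity(
    gm: GenotypeMatrix,
    strain_id: str,
    contig_lengths: dict[str, int],
    config: AnalysisConfig = AnalysisConfig(),
) -> WindowTrack:
    """Heterozygous-SNP count per window over the genome-wide median count.

    Requires a strain of ploidy >= 2 and a genome with enough heterozygosity
    for the median window count to be positive.
    """
    if strain_id not in gm.samples:
        raise ValidationError(f"unknown strain {strain_id}")
    j = gm.samples.index(strain_id)
    if gm.ploidy[strain_id] < 2:
        raise ValidationError(f"strain {strain_id} is haploid; LOH is undefined")
    het = gm.het_mask()[:, j]
    w = config.loh_window
    contigs, starts, ends, counts, complete = [], [], [], [], []
    for contig, length in contig_lengths.items():
        on = (gm.contigs == contig) & het
        pos = gm.positions[on]
        for wstart in range(0, length, w):
            wend = min(wstart + w, length)
            contigs.append(contig)
            starts.append(wstart)
            ends.append(wend)
            counts.append(int(((pos >= wstart) & (pos < wend)).sum()))
            complete.append(wend - wstart == w)
    counts_a = np.array(counts, dtype=float)
    complete_a = np.array(complete, dtype=bool)
    median = float(np.median(counts_a[complete_a])) if complete_a.any() else 0.0
    if median <= 0:
        raise ValidationError(
            f"median heterozygous-SNP window count is zero for {strain_id}; "
            "insufficient heterozygosity"
        )
    return WindowTrack(
        np.array(contigs, dtype=object),
        np.array(starts),
        np.array(ends),
        counts_a / median,
        complete_a,
    )


def resample_depth_to(
    depth: WindowTrack, grid: WindowTrack
) -> np.ndarray:
    """Interval-weighted mean depth ratio on another window grid."""
    out = np.full(len(grid.start), np.nan)
    for contig in pd.unique(grid.contig):
        gsel = np.flatnonzero(grid.contig == contig)
        dsel = np.flatnonzero(depth.contig == contig)
        if len(dsel) == 0:
            continue
        ds, de, dr = depth.start[dsel], depth.end[dsel], depth.ratio[dsel]
        for gi in gsel:
            lo, hi = grid.start[gi], grid.end[gi]
            overlap = np.minimum(de, hi) - np.maximum(ds, lo)
            overlap = np.clip(overlap, 0, None).astype(float)
            if overlap.sum() > 0:
                out[gi] = float((overlap * dr).sum() / overlap.sum())
    return out


def call_loh_segments(
    het: WindowTrack,
    depth: WindowTrack,
    config: AnalysisConfig = AnalysisConfig(),
    strain_id: str = "",
) -> list[LOHSegment]:
    """LOH runs classified as copy-neutral or deletion by their depth ratio.

    A run of >= min_run complete windows with heterozygosity ratio below
    ``loh_het_threshold`` becomes a segment; its mean depth ratio (resampled
    onto the heterozygosity grid) within band_tolerance of 1.0 marks
    copy-neutral LOH, within band_tolerance of 0.5 deletion-driven LOH, and
    anything else is reported as ambiguous.
    """
    depth_on_grid = resample_depth_to(depth, het)
    segments: list[LOHSegment] = []
    for contig in pd.unique(het.contig):
        sel = np.flatnonzero((het.contig == contig) & het.complete)
        if len(sel) == 0:
            continue
        low = (het.ratio[sel] < config.loh_het_threshold).astype(int)
        for run_start, run_end in _runs(low):
            if low[run_start] != 1 or run_end - run_start < config.min_run:
                continue
            idx = sel[run_start:run_end]
            mean_depth = float(np.nanmean(depth_on_grid[idx]))
            if abs(mean_depth - 0.5) <= config.band_tolerance:
                label = "deletion"
            elif abs(mean_depth - 1.0) <= config.band_tolerance:
                label = "copy_neutral"
            else:
                label = "ambiguous"
            segments.append(
                LOHSegment(
                    strain_id=strain_id,
                    contig=str(contig),
                    start=int(het.start[idx[0]]),
                    end=int(het.end[idx[-1]]),
                    classification=label,
                    mean_het_ratio=float(het.ratio[idx].mean()),
                    mean_depth_ratio=mean_depth,
                )
            )
    return segments
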