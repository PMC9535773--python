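"""Linkage-disequilibrium decay: pairwise r-squared and the half-max readout.

In a recombining population the squared allele-dosage correlation r² between
two loci decays with their distance; in a strictly clonal one all loci share
a single genealogy and r² stays flat.  The readout used here is the smallest
distance at which a smoothed r²-vs-distance curve drops below half of its
maximum ("half-decay distance"); a clonal signal never reaches it within the
scanned range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import MISSING, GenotypeMatrix


@dataclass
class LDPairs:
    """Same-contig locus pairs with their distance (bp) and r²."""

    distance: np.ndarray
    r2: np.ndarray


@dataclass
class LDCurve:
    bin_mid: np.ndarray
    n_pairs: np.ndarray
    mean_r2: np.ndarray
    smoothed_r2: np.ndarray
    max_observed: float
    half_max: float
    half_decay_distance: float | None  # bp, or None for "not reached"


def filter_ld_loci(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Keep biallelic loci whose minor allele is carried by >= 2 strains.

    "Carried" is per strain: a strain carries the alternate allele when its
    dosage is > 0 and the reference allele when dosage < ploidy.  Singleton
    loci contribute no linkage information and are excluded.
    """
    pl = gm.ploidy_vector[None, :]
    typed = gm.dosage != MISSING
    alt_carriers = ((gm.dosage > 0) & typed).sum(axis=1)
    ref_carriers = ((gm.dosage < pl) & typed).sum(axis=1)
    keep = gm.biallelic & (np.minimum(alt_carriers, ref_carriers) >= 2)
    return gm.take_loci(keep)


def pairwise_r2(gm: GenotypeMatrix, max_dist: int = 10_000) -> LDPairs:
    """r² = squared Pearson correlation of ploidy-scaled dosages.

    Computed for every same-contig pair of loci with 0 < distance <=
    ``max_dist``; loci with zero variance are skipped.  Missing dosages are
    handled by dropping strains untyped at either locus of a pair.
    """
    dists: list[np.ndarray] = []
    r2s: list[np.ndarray] = []
    x = gm.scaled_dosage()
    has_missing = np.isnan(x).any()
    for contig in pd.unique(gm.contigs):
        sel = np.flatnonzero(gm.contigs == contig)
        pos = gm.positions[sel]
        xc = x[sel]
        if has_missing:
            d, r = _pairs_masked(xc, pos, max_dist)
        else:
            d, r = _pairs_dense(xc, pos, max_dist)
        dists.append(d)
        r2s.append(r)
    if dists:
        return LDPairs(np.concatenate(dists), np.concatenate(r2s))
    return LDPairs(np.empty(0, dtype=np.int64), np.empty(0))


def _pairs_dense(x: np.ndarray, pos: np.ndarray, max_dist: int):
    sd = x.std(axis=1)
    ok = sd > 0
    x, pos = x[ok], pos[ok]
    if len(pos) < 2:
        return np.empty(0, dtype=np.int64), np.empty(0)
    z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    n = x.shape[1]
    corr = (z @ z.T) / n
    i, j = np.triu_indices(len(pos), k=1)
    d = pos[j] - pos[i]
    near = (d > 0) & (d <= max_dist)
    return d[near], np.clip(corr[i[near], j[near]] ** 2, 0.0, 1.0)


def _pairs_masked(x: np.ndarray, pos: np.ndarray, max_dist: int):
    dists, r2s = [], []
    for i in range(len(pos)):
        for j in range(i + 1, len(pos)):
            d = pos[j] - pos[i]
            if d <= 0 or d > max_dist:
                continue
            both = ~np.isnan(x[i]) & ~np.isnan(x[j])
            if both.sum() < 2:
                continue
            a, b = x[i, both], x[j, both]
            if a.std() == 0 or b.std() == 0:
                continue
            r = np.corrcoef(a, b)[0, 1]
            dists.append(d)
            r2s.append(min(r * r, 1.0))
    return np.array(dists, dtype=np.int64), np.array(r2s)


def haplotype_r2(p_ab: float, p_a: float, p_b: float) -> float:
    """Closed-form r² from phased haplotype frequencies: D²/(pA qA pB qB)."""
    d = p_ab - p_a * p_b
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    if denom == 0:
        raise ValidationError("monomorphic locus in haplotype_r2")
    return d * d / denom


def _tricube_smooth(x: np.ndarray, y: np.ndarray, span: float) -> np.ndarray:
    """Local tricube-weighted mean of y over x; span is a fraction of range."""
    width = span * (x.max() - x.min()) if len(x) > 1 else 1.0
    if width <= 0:
        return y.copy()
    out = np.empty_like(y, dtype=float)
    for k in range(len(x)):
        u = np.abs(x - x[k]) / width
        w = np.where(u < 1, (1 - u**3) ** 3, 0.0)
        out[k] = (w * y).sum() / w.sum()
    return out


def ld_curve(
    pairs: LDPairs, bin_width: int = 100, smoother_span: float = 0.3
) -> LDCurve:
    """Distance-binned mean r² with a tricube local-mean smoother.

    The smoother stands in for a generalized-additive-model fit; the half-max
    readout only needs a monotone-robust smooth, not the exact GAM.  The
    half-decay distance is the smallest bin midpoint at which the smoothed
    curve falls below half of its maximum, or None when never reached.
    """
    if len(pairs.r2) == 0:
        raise ValidationError("insufficient LD pairs")
    max_d = int(pairs.distance.max())
    edges = np.arange(0, max_d + bin_width, bin_width)
    n_bins = len(edges) - 1
    idx = np.clip(np.digitize(pairs.distance, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=pairs.r2, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    filled = counts > 0
    mid = (edges[:-1] + edges[1:]) / 2.0
    mid, sums, counts = mid[filled], sums[filled], counts[filled]
    mean_r2 = sums / counts
    smoothed = _tricube_smooth(mid, mean_r2, smoother_span)
    max_obs = float(smoothed.max())
    half = max_obs / 2.0
    below = np.flatnonzero(smoothed < half)
    half_decay = float(mid[below[0]]) if len(below) else None
    return LDCurve(mid, counts, mean_r2, smoothed, max_obs, half, half_decay)
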