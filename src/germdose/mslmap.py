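"""Gene-to-MSL-peak distance annotation and proximity categories.

Distances follow ``bedtools closest -d`` semantics on 0-based half-open
intervals: overlapping or bookended gene/peak pairs get distance 0, otherwise
the gap between the nearest interval edges. Strand is ignored.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

#: category5 upper bounds (inclusive) after the overlap class.
CATEGORY5_BOUNDS = (1_000, 5_000, 20_000)
CATEGORY5_LABELS = ("overlap", "le1kb", "le5kb", "le20kb", "gt20kb")
PROXIMAL_CUTOFF = 2_000  # category2: proximal iff distance < 2 kb (strict)


def nearest_peak_distance(genes: pd.DataFrame, peaks: pd.DataFrame) -> pd.DataFrame:
    """Distance from each gene to its nearest peak on the same chromosome.

    Parameters
    ----------
    genes
        Indexed by gene id with columns ``chromosome, start, end``
        (0-based half-open).
    peaks
        Columns ``chromosome, start, end``; intervals may overlap.

    Returns a frame indexed by gene id with ``distance_bp`` (float; 0 for
    overlap/bookended, NaN where the chromosome has no peak) and
    ``no_peak_on_chrom``.
    """
    dist = pd.Series(np.nan, index=genes.index, dtype=float)
    no_peak = pd.Series(True, index=genes.index, dtype=bool)

    for chrom, sub in genes.groupby("chromosome", observed=True):
        p = peaks[peaks.chromosome == chrom]
        if len(p) == 0:
            continue
        order = np.argsort(p.start.to_numpy(), kind="stable")
        ps = p.start.to_numpy()[order]
        pe = p.end.to_numpy()[order]
        pe_cummax = np.maximum.accumulate(pe)

        gs = sub.start.to_numpy()
        ge = sub.end.to_numpy()
        # peaks with start < gene end are on/left of the gene
        i = np.searchsorted(ps, ge, side="left")
        left_gap = np.full(len(sub), np.inf)
        has_left = i > 0
        left_gap[has_left] = gs[has_left] - pe_cummax[i[has_left] - 1]
        right_gap = np.full(len(sub), np.inf)
        has_right = i < len(ps)
        right_gap[has_right] = ps[i[has_right]] - ge[has_right]
        d = np.minimum(np.maximum(left_gap, 0.0), np.maximum(right_gap, 0.0))
        dist.loc[sub.index] = d
        no_peak.loc[sub.index] = False

    return pd.DataFrame({"distance_bp": dist, "no_peak_on_chrom": no_peak})


def categorize_msl(
    distance_bp,
    bounds: tuple = CATEGORY5_BOUNDS,
    proximal_cutoff: int = PROXIMAL_CUTOFF,
):
    """Map distances to the five-level and binary proximity categories.

    category5: ``overlap`` at d = 0, then inclusive upper bounds 1 kb / 5 kb /
    20 kb, ``gt20kb`` beyond. category2: ``proximal`` iff d < 2 kb (strict).
    Accepts a scalar or an array-like; NaN propagates.
    """
    d = np.asarray(distance_bp, dtype=float)
    scalar = d.ndim == 0
    d = np.atleast_1d(d)
    if np.any(d[~np.isnan(d)] < 0):
        raise ValueError("distance must be >= 0")

    cat5 = np.full(d.shape, None, dtype=object)
    cat5[d == 0] = CATEGORY5_LABELS[0]
    lower = 0.0
    for bound, label in zip(bounds, CATEGORY5_LABELS[1:-1]):
        cat5[(d > lower) & (d <= bound)] = label
        lower = bound
    cat5[d > bounds[-1]] = CATEGORY5_LABELS[-1]

    cat2 = np.where(np.isnan(d), None,
                    np.where(d < proximal_cutoff, "proximal", "distal"))
    if scalar:
        return cat5[0], cat2[0]
    return cat5, cat2


def annotate_msl(genes: pd.DataFrame, peaks: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Full MSL annotation: distance plus both category schemes per gene."""
    out = nearest_peak_distance(genes, peaks)
    cat5, cat2 = categorize_msl(out.distance_bp.to_numpy(), **kwargs)
    out["category5"] = cat5
    out["category2"] = cat2
    return out
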