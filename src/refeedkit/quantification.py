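"""Signal-track conventions: scaling, windowed quantification, profiles.

Tracks are scaled so the genome-wide total equals 1e7 (comparable across
libraries).  Site quantification sums scaled per-base signal in a
half-open window ``[center - 200, center + 200)`` around the floor
midpoint of each site; aggregate profiles average per-bp signal in 10 bp
bins over +/- 4 kb.  Promoter-proximal means the site centre lies within
-1 kb .. +0.1 kb of a TSS in transcription orientation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .containers import SignalTrack, ValidationError

__all__ = [
    "TRACK_TOTAL",
    "scale_track",
    "site_centers",
    "window_signal",
    "aggregate_profile",
    "annotate_promoter_proximal",
]

TRACK_TOTAL = 1e7


def scale_track(track: SignalTrack, target_total: float = TRACK_TOTAL) -> SignalTrack:
    """Rescale so the summed signal equals ``target_total`` (idempotent)."""
    total = track.total
    if total <= 0:
        raise ValidationError("cannot scale an empty track")
    factor = target_total / total
    scaled = track.copy()
    for chrom in scaled.values:
        scaled.values[chrom] = scaled.values[chrom] * factor
    scaled.scale_factor = track.scale_factor * factor
    return scaled


def site_centers(sites: pd.DataFrame) -> np.ndarray:
    """Floor midpoints of half-open intervals."""
    return ((sites["start"].to_numpy() + sites["end"].to_numpy()) // 2).astype(np.int64)


def window_signal(
    track: SignalTrack, sites: pd.DataFrame, half_width: int = 200
) -> pd.DataFrame:
    """Summed signal in ``[center - half_width, center + half_width)``.

    Windows crossing a contig edge are clipped (missing bases contribute
    zero) and flagged.  Returns a DataFrame aligned to ``sites`` with
    columns ``signal`` and ``clipped``; the mean over sites and the
    10th/90th percentile summary live in ``.attrs``.
    """
    if len(sites) == 0:
        raise ValidationError("no sites given")
    centers = site_centers(sites)
    out = np.empty(len(sites), dtype=float)
    clipped = np.zeros(len(sites), dtype=bool)
    for i, (chrom, c) in enumerate(zip(sites["chrom"], centers)):
        arr = track.values[chrom]
        lo, hi = c - half_width, c + half_width
        if lo < 0 or hi > len(arr):
            clipped[i] = True
        out[i] = arr[max(lo, 0) : min(hi, len(arr))].sum()
    df = pd.DataFrame({"signal": out, "clipped": clipped})
    if "name" in sites.columns:
        df.index = pd.Index(sites["name"], name="site")
    df.attrs["mean"] = float(out.mean())
    df.attrs["p10"], df.attrs["p90"] = (
        float(np.percentile(out, 10)),
        float(np.percentile(out, 90)),
    )
    return df


def aggregate_profile(
    track: SignalTrack,
    sites: pd.DataFrame,
    half_width: int = 4000,
    bin_size: int = 10,
) -> pd.DataFrame:
    """Mean per-site signal in fixed bins over ``+/- half_width``.

    Bin value = mean over sites of the summed signal in the bin (divide
    by ``bin_size`` for a per-bp rate); clipped windows are zero-padded
    so the site denominator stays fixed.  Returns a DataFrame with
    ``bin_offset`` (left edge relative to the site centre) and
    ``mean_value``.
    """
    if 2 * half_width % bin_size:
        raise ValidationError("bin size must divide the window")
    if len(sites) == 0:
        raise ValidationError("no sites given")
    n_bins = 2 * half_width // bin_size
    acc = np.zeros(n_bins, dtype=float)
    centers = site_centers(sites)
    for chrom, c in zip(sites["chrom"], centers):
        arr = track.values[chrom]
        lo, hi = c - half_width, c + half_width
        window = np.zeros(2 * half_width, dtype=float)
        src_lo, src_hi = max(lo, 0), min(hi, len(arr))
        window[src_lo - lo : src_hi - lo] = arr[src_lo:src_hi]
        acc += window.reshape(n_bins, bin_size).sum(axis=1)
    mean_per_bin = acc / len(sites)
    offsets = np.arange(-half_width, half_width, bin_size)
    return pd.DataFrame({"bin_offset": offsets, "mean_value": mean_per_bin})


def annotate_promoter_proximal(
    sites: pd.DataFrame,
    annotation: pd.DataFrame,
    upstream: int = 1000,
    downstream: int = 100,
) -> pd.DataFrame:
    """Classify each site as promoter-proximal or distal.

    A site is promoter-proximal when its centre lies within
    ``[TSS - upstream, TSS + downstream]`` in the transcription direction
    of at least one gene; for minus-strand genes the genomic window is
    ``[TSS - downstream, TSS + upstream]``.  Unknown strands are treated
    as '+' (recorded in ``.attrs['unknown_strand']``).
    """
    trees: dict[str, IntervalTree] = {}
    unknown = []
    for gid, row in annotation.iterrows():
        strand = row["strand"]
        if strand not in ("+", "-"):
            unknown.append(gid)
            strand = "+"
        tss = int(row["tss"])
        if strand == "+":
            lo, hi = tss - upstream, tss + downstream
        else:
            lo, hi = tss - downstream, tss + upstream
        trees.setdefault(row["chrom"], IntervalTree()).addi(lo, hi + 1, gid)

    centers = site_centers(sites)
    classes = []
    for chrom, c in zip(sites["chrom"], centers):
        tree = trees.get(chrom)
        hit = bool(tree is not None and tree.overlaps_point(int(c)))
        classes.append("promoter-proximal" if hit else "distal")
    out = pd.DataFrame({"class": classes})
    if "name" in sites.columns:
        out.index = pd.Index(sites["name"], name="site")
    out.attrs["fraction_distal"] = float(np.mean(np.array(classes) == "distal"))
    out.attrs["unknown_strand"] = unknown
    return out
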