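"""Bivariate genomic footprinting: FPD/FA statistics and bagplot deltas.

For every motif, transposase cut counts are aggregated strand-orientedly
over all occurrences inside accessible sites, on a fixed offset grid of
-200..+199 bp around the occurrence centre.  Two log2 summaries follow:

* FA (flanking accessibility): log2 mean per-bp cut density over the
  flank band (35 < |offset| <= 200);
* FPD (footprint depth): FA minus log2 mean density over the motif
  interior (|offset| <= ceil(width / 2)) — positive when the motif is
  protected relative to its flanks.

Condition deltas (dFA, dFPD) for all motifs form a bivariate cloud which
is summarised by a bag plot: the "bag" is the convex hull of the 50%
deepest points by Tukey (halfspace) depth, the "fence" inflates the bag
threefold about the depth median, and motifs outside the fence are
flagged as outliers.  Motifs in the jointly-increased quadrant
(dFA > 0 and dFPD > 0) indicate factors both more bound and more locally
open in the second condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from scipy.spatial import ConvexHull, QhullError
from statsmodels.stats.multitest import multipletests

from .containers import SignalTrack, ValidationError

__all__ = [
    "MotifProfile",
    "FootprintStat",
    "BagplotResult",
    "motif_cut_profile",
    "footprint_stats",
    "footprint_stat_table",
    "tukey_depth",
    "bagfoot_delta",
    "motif_enrichment",
]

PROFILE_HALF_WIDTH = 200
_FLANK_INNER = 35  # flank band is 35 < |offset| <= 200
_MAX_MOTIF_WIDTH = 70


@dataclass
class MotifProfile:
    """Aggregate cut-count profile of one motif in one condition."""

    motif_id: str
    width: int
    counts: np.ndarray  # length 400, offsets -200..+199 relative to centre
    n_occurrences: int
    condition: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (2 * PROFILE_HALF_WIDTH,):
            raise ValidationError("profile must span exactly 400 offsets")
        if self.n_occurrences < 1:
            raise ValidationError("profile needs >= 1 occurrence")


@dataclass
class FootprintStat:
    motif_id: str
    fa: float
    fpd: float
    condition: str = ""


def _interval_trees(sites: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in sites.groupby("chrom", sort=False):
        tree = IntervalTree()
        for s, e in zip(sub["start"], sub["end"]):
            tree.addi(int(s), int(e))
        trees[chrom] = tree
    return trees


def motif_cut_profile(
    track: SignalTrack,
    occurrences: pd.DataFrame,
    motif_id: str | None = None,
    accessible_sites: pd.DataFrame | None = None,
    condition: str = "",
) -> MotifProfile:
    """Pool per-offset cut counts over a motif's occurrences.

    Occurrences outside ``accessible_sites`` (when given) are dropped.
    Minus-strand occurrences are reversed so offsets are in motif
    orientation.  Raises when no occurrence survives filtering.
    """
    occ = occurrences
    if motif_id is not None and "name" in occ.columns:
        occ = occ[occ["name"] == motif_id]
    else:
        motif_id = motif_id or (
            str(occ["name"].iloc[0]) if "name" in occ.columns and len(occ) else "motif"
        )
    if accessible_sites is not None:
        trees = _interval_trees(accessible_sites)
        keep = [
            bool(trees.get(c) and trees[c].overlap(int(s), int(e)))
            for c, s, e in zip(occ["chrom"], occ["start"], occ["end"])
        ]
        occ = occ[np.asarray(keep, dtype=bool)] if len(occ) else occ
    if len(occ) == 0:
        raise ValidationError(
            f"motif {motif_id!r}: no occurrences inside accessible sites"
        )

    h = PROFILE_HALF_WIDTH
    counts = np.zeros(2 * h, dtype=float)
    widths = []
    for _, row in occ.iterrows():
        arr = track.values[row["chrom"]]
        c = (int(row["start"]) + int(row["end"])) // 2
        widths.append(int(row["end"]) - int(row["start"]))
        if row.get("strand", "+") == "-":
            # genomic slice [c-199, c+201) reversed maps offset o -> -o
            lo, hi = c - h + 1, c + h + 1
            window = np.zeros(2 * h)
            src_lo, src_hi = max(lo, 0), min(hi, len(arr))
            window[src_lo - lo : src_hi - lo] = arr[src_lo:src_hi]
            counts += window[::-1]
        else:
            lo, hi = c - h, c + h
            window = np.zeros(2 * h)
            src_lo, src_hi = max(lo, 0), min(hi, len(arr))
            window[src_lo - lo : src_hi - lo] = arr[src_lo:src_hi]
            counts += window
    width = int(np.median(widths))
    return MotifProfile(motif_id, width, counts, len(occ), condition)


def footprint_stats(profile: MotifProfile, pseudocount: float = 0.5) -> FootprintStat:
    """FA and FPD from an aggregate profile.

    Per-bp density is ``(counts + pseudocount) / n_occurrences``; the
    pseudocount bounds the logs for sparse motifs.  Motifs at least 70 bp
    wide would collide with the flank band and are refused.
    """
    if profile.width >= _MAX_MOTIF_WIDTH:
        raise ValidationError(
            f"motif {profile.motif_id!r} too wide ({profile.width} bp >= "
            f"{_MAX_MOTIF_WIDTH} bp) for footprint statistics"
        )
    h = PROFILE_HALF_WIDTH
    offsets = np.arange(-h, h)
    half_w = int(np.ceil(profile.width / 2))
    interior = np.abs(offsets) <= half_w
    flank = (np.abs(offsets) > _FLANK_INNER) & (np.abs(offsets) <= h)
    density = (profile.counts + pseudocount) / profile.n_occurrences
    fa = float(np.log2(density[flank].mean()))
    fpd = float(fa - np.log2(density[interior].mean()))
    return FootprintStat(profile.motif_id, fa, fpd, profile.condition)


def footprint_stat_table(
    track: SignalTrack,
    occurrences: pd.DataFrame,
    accessible_sites: pd.DataFrame | None = None,
    condition: str = "",
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """FA/FPD for every motif named in an occurrence table."""
    rows = []
    for motif_id in pd.unique(occurrences["name"]):
        prof = motif_cut_profile(
            track, occurrences, motif_id, accessible_sites, condition
        )
        st = footprint_stats(prof, pseudocount)
        rows.append((motif_id, st.fa, st.fpd, prof.n_occurrences))
    return pd.DataFrame(
        rows, columns=["motif_id", "FA", "FPD", "n_occurrences"]
    ).set_index("motif_id")


# ---------------------------------------------------------------------------
# bagplot


def tukey_depth(points: np.ndarray) -> np.ndarray:
    """Exact halfspace depth of every point of a 2-D cloud.

    For each point the minimum, over all closed halfplanes containing it,
    of the number of cloud points in the halfplane — computed by an
    angular sweep over the directions to the other points (O(n log n) per
    point).  Coincident points always share every halfplane.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    depths = np.empty(n, dtype=int)
    for i in range(n):
        d = pts - pts[i]
        coincident = (d[:, 0] == 0) & (d[:, 1] == 0)
        nc = int(coincident.sum())  # includes the point itself
        rest = d[~coincident]
        m = len(rest)
        if m == 0:
            depths[i] = nc
            continue
        ang = np.sort(np.arctan2(rest[:, 1], rest[:, 0]))
        full = np.concatenate([ang, ang + 2 * np.pi])
        left = np.searchsorted(full, ang, side="right")
        right = np.searchsorted(full, ang + np.pi, side="right")
        c = right - left  # points with angle in (a_j, a_j + pi]
        depths[i] = nc + int(np.min(np.minimum(c, m - c)))
    return depths


def _convex_hull_vertices(pts: np.ndarray) -> np.ndarray | None:
    try:
        hull = ConvexHull(pts)
        return pts[hull.vertices]  # counter-clockwise
    except (QhullError, ValueError):
        return None


def _inside_convex(poly: np.ndarray, pts: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Boundary-inclusive membership test for a CCW convex polygon."""
    inside = np.ones(len(pts), dtype=bool)
    k = len(poly)
    scale = max(1.0, np.abs(poly).max())
    for a in range(k):
        v1, v2 = poly[a], poly[(a + 1) % k]
        edge = v2 - v1
        cross = edge[0] * (pts[:, 1] - v1[1]) - edge[1] * (pts[:, 0] - v1[0])
        inside &= cross >= -tol * scale**2
    return inside


@dataclass
class BagplotResult:
    deltas: pd.DataFrame  # index motif, columns dFA, dFPD, depth, in_bag, outlier
    bag_vertices: np.ndarray
    fence_vertices: np.ndarray
    depth_median: np.ndarray
    outliers: list[str] = field(default_factory=list)
    jointly_increased: list[str] = field(default_factory=list)


def bagfoot_delta(
    stats_a: pd.DataFrame,
    stats_b: pd.DataFrame,
    fence_factor: float = 3.0,
    min_motifs: int = 10,
) -> BagplotResult:
    """Per-motif (dFA, dFPD) = condition B minus A, with bagplot outliers.

    Both tables must be indexed by motif id with columns FA and FPD over
    the same motif universe.  Fewer than ``min_motifs`` motifs make the
    depth computation unstable and are refused.
    """
    if set(stats_a.index) != set(stats_b.index):
        raise ValidationError("conditions cover different motif universes")
    if len(stats_a) < min_motifs:
        raise ValidationError(
            f"need >= {min_motifs} motifs for a stable bag, got {len(stats_a)}"
        )
    b = stats_b.loc[stats_a.index]
    d = pd.DataFrame(
        {
            "dFA": b["FA"] - stats_a["FA"],
            "dFPD": b["FPD"] - stats_a["FPD"],
        },
        index=stats_a.index,
    )
    pts = d[["dFA", "dFPD"]].to_numpy()
    depths = tukey_depth(pts)
    d["depth"] = depths

    median_pt = pts[depths == depths.max()].mean(axis=0)
    order = np.sort(depths)[::-1]
    threshold = order[int(np.ceil(len(pts) / 2)) - 1]
    in_bag = depths >= threshold
    d["in_bag"] = in_bag

    bag_pts = pts[in_bag]
    bag = _convex_hull_vertices(bag_pts)
    if bag is None:  # degenerate bag (collinear/identical): radial fence
        radii = np.linalg.norm(bag_pts - median_pt, axis=1)
        rmax = fence_factor * radii.max()
        dist = np.linalg.norm(pts - median_pt, axis=1)
        outlier = dist > max(rmax, 1e-12)
        bag_v = bag_pts
        fence_v = bag_pts
    else:
        bag_v = bag
        fence_v = median_pt + fence_factor * (bag - median_pt)
        outlier = ~_inside_convex(fence_v, pts)
    d["outlier"] = outlier
    top_right = d.index[(d["dFA"] > 0) & (d["dFPD"] > 0)]
    return BagplotResult(
        deltas=d,
        bag_vertices=bag_v,
        fence_vertices=fence_v,
        depth_median=median_pt,
        outliers=list(d.index[outlier]),
        jointly_increased=list(top_right),
    )


# ---------------------------------------------------------------------------
# motif enrichment


def motif_enrichment(
    foreground: pd.DataFrame,
    background: pd.DataFrame,
    occurrences: pd.DataFrame,
) -> pd.DataFrame:
    """Known-motif enrichment of a site subset against the full landscape.

    Foreground sites must be a subset (by name) of the background.  For
    each motif the count of sites containing >= 1 occurrence yields a
    one-sided hypergeometric p-value, BH-adjusted across motifs, with
    fold enrichment = foreground fraction / background fraction.
    """
    fg_names = set(foreground["name"])
    bg_names = set(background["name"])
    if not fg_names <= bg_names:
        raise ValidationError("foreground sites are not a subset of the background")

    rows = []
    n_bg, n_fg = len(bg_names), len(fg_names)
    for motif_id, occ in occurrences.groupby("name", sort=False):
        trees = _interval_trees(occ)
        def hit(sites):
            got = set()
            for nm, c, s, e in zip(
                sites["name"], sites["chrom"], sites["start"], sites["end"]
            ):
                t = trees.get(c)
                if t is not None and t.overlap(int(s), int(e)):
                    got.add(nm)
            return got
        bg_hit = hit(background)
        k_bg = len(bg_hit)
        k_fg = len(bg_hit & fg_names)
        p = float(stats.hypergeom.sf(k_fg - 1, n_bg, k_bg, n_fg))
        fold = (
            (k_fg / n_fg) / (k_bg / n_bg) if k_bg > 0 and k_fg > 0 else
            (np.nan if k_bg == 0 else 0.0)
        )
        rows.append((motif_id, k_fg, n_fg, k_bg, n_bg, fold, p))
    out = pd.DataFrame(
        rows,
        columns=[
            "motif_id", "fg_with_motif", "fg_total",
            "bg_with_motif", "bg_total", "fold_enrichment", "pvalue",
        ],
    ).set_index("motif_id")
    out["padj"] = multipletests(out["pvalue"].to_numpy(), method="fdr_bh")[1]
    return out.sort_values("pvalue")
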