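"""Footprint profiles, FPD/FA statistics, Tukey depth, bagplot, enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from refeedkit.containers import SignalTrack, ValidationError, interval_frame
from refeedkit.footprinting import (
    MotifProfile,
    bagfoot_delta,
    footprint_stats,
    motif_cut_profile,
    motif_enrichment,
    tukey_depth,
)


def _occ(centers, width=12, strand="+", chrom="chrS", name="M00"):
    starts = [c - width // 2 for c in centers]
    return interval_frame(
        chrom, starts, [s + width for s in starts],
        names=[name] * len(centers),
        strands=[strand] * len(centers),
    )


class TestMotifCutProfile:
    def test_spike_at_center_maps_to_offset_zero(self):
        arr = np.zeros(10_000)
        arr[5000] = 3.0
        prof = motif_cut_profile(SignalTrack({"chrS": arr}), _occ([5000]))
        nz = np.flatnonzero(prof.counts)
        assert list(nz) == [200]  # offset 0
        assert prof.counts[200] == 3.0

    def test_two_occurrences_double_the_profile(self):
        arr = np.zeros(10_000)
        arr[2000] = arr[7000] = 3.0
        single = motif_cut_profile(SignalTrack({"chrS": arr}), _occ([2000]))
        double = motif_cut_profile(SignalTrack({"chrS": arr}), _occ([2000, 7000]))
        assert np.array_equal(double.counts, 2 * single.counts)

    def test_minus_strand_reverses_offsets(self):
        # spike 5 bp right of the centre appears at motif-frame offset -5
        arr = np.zeros(10_000)
        arr[5005] = 2.0
        prof = motif_cut_profile(
            SignalTrack({"chrS": arr}), _occ([5000], strand="-")
        )
        nz = np.flatnonzero(prof.counts)
        assert list(nz) == [195]  # offset -5
        assert prof.counts[195] == 2.0

    def test_occurrences_filtered_to_accessible_sites(self):
        arr = np.ones(10_000)
        occ = _occ([2000, 7000])
        sites = interval_frame("chrS", [1800], [2200], names=["s1"])
        prof = motif_cut_profile(
            SignalTrack({"chrS": arr}), occ, accessible_sites=sites
        )
        assert prof.n_occurrences == 1

    def test_no_accessible_occurrence_rejected(self):
        arr = np.ones(10_000)
        sites = interval_frame("chrS", [9000], [9100], names=["s1"])
        with pytest.raises(ValidationError, match="M00"):
            motif_cut_profile(
                SignalTrack({"chrS": arr}), _occ([2000]), accessible_sites=sites
            )


def _profile(interior, flank, width=12, n_occ=1):
    counts = np.full(400, float(flank))
    offsets = np.arange(-200, 200)
    half_w = int(np.ceil(width / 2))
    counts[np.abs(offsets) <= half_w] = float(interior)
    return MotifProfile("M00", width, counts * n_occ, n_occ)


class TestFootprintStats:
    def test_flat_profile_has_zero_depth(self):
        st = footprint_stats(_profile(5.0, 5.0))
        assert st.fpd == 0.0

    def test_quarter_interior_gives_depth_two(self):
        st = footprint_stats(_profile(200.0, 800.0))
        assert st.fpd == pytest.approx(2.0, abs=0.05)

    def test_doubling_track_shifts_fa_not_fpd(self):
        a = footprint_stats(_profile(200.0, 800.0))
        b = footprint_stats(_profile(400.0, 1600.0))
        assert b.fa - a.fa == pytest.approx(1.0, abs=0.01)
        assert b.fpd - a.fpd == pytest.approx(0.0, abs=0.01)

    @pytest.mark.parametrize("c", [0.5, 2.0, 8.0])
    def test_scaling_invariance(self, c):
        base = _profile(300.0, 900.0)
        scaled = MotifProfile("M00", 12, base.counts * c, 1)
        a, b = footprint_stats(base), footprint_stats(scaled)
        assert b.fa - a.fa == pytest.approx(np.log2(c), abs=0.01)
        assert b.fpd == pytest.approx(a.fpd, abs=0.01)

    def test_wide_motif_rejected(self):
        with pytest.raises(ValidationError, match="wide"):
            footprint_stats(_profile(1.0, 1.0, width=80))


def brute_force_depth(points, eps=1e-7):
    """Enumeration over direction angles defined by point pairs.

    For each point, candidate halfplane normals are the perpendiculars
    of the directions to every other point, plus tiny rotations either
    way (realizing halfplanes whose boundary just excludes the paired
    point); the depth is the minimum closed-halfplane count.
    """
    pts = np.asarray(points, float)
    n = len(pts)
    out = np.empty(n, dtype=int)
    for i in range(n):
        d = pts - pts[i]
        best = n
        for j in range(n):
            if d[j, 0] == 0 and d[j, 1] == 0:
                continue
            phi = np.arctan2(d[j, 1], d[j, 0])
            for theta in (phi + np.pi / 2, phi - np.pi / 2):
                for t in (theta, theta + eps, theta - eps):
                    u = np.array([np.cos(t), np.sin(t)])
                    best = min(best, int(np.sum(d @ u >= -1e-12)))
        out[i] = best
    return out


class TestTukeyDepth:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_pairwise_enumeration(self, seed):
        pts = np.random.default_rng(seed).normal(size=(25, 2))
        assert np.array_equal(tukey_depth(pts), brute_force_depth(pts))

    def test_collinear_points(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        assert list(tukey_depth(pts)) == [1, 2, 1]

    def test_center_of_cross(self):
        pts = np.array([[0, 0], [1, 0], [-1, 0], [0, 1], [0, -1]], float)
        assert tukey_depth(pts)[0] == 3


def _stat_frames(points):
    ids = [f"M{i:03d}" for i in range(len(points))]
    a = pd.DataFrame({"FA": 0.0, "FPD": 0.0}, index=pd.Index(ids))
    b = pd.DataFrame(
        {"FA": points[:, 0], "FPD": points[:, 1]}, index=pd.Index(ids)
    )
    return a, b


def _truncated_normal_cloud(n, rng, rmax=3.5):
    """Bivariate normal truncated at radius ``rmax`` sd, so the cloud
    itself contains no point a x3 fence could legitimately flag."""
    pts = []
    while len(pts) < n:
        p = rng.normal(size=2)
        if np.linalg.norm(p) < rmax:
            pts.append(p)
    return np.asarray(pts)


class TestBagplot:
    def test_identical_conditions_give_no_outliers(self):
        a, b = _stat_frames(np.zeros((20, 2)))
        res = bagfoot_delta(a, a.copy())
        assert res.outliers == []
        assert np.allclose(res.deltas[["dFA", "dFPD"]], 0.0)

    def test_planted_far_outlier_is_unique(self):
        rng = np.random.default_rng(17)
        cloud = _truncated_normal_cloud(200, rng)
        pts = np.vstack([cloud, [10.0, 10.0]])
        a, b = _stat_frames(pts)
        res = bagfoot_delta(a, b)
        assert res.outliers == ["M200"]
        assert "M200" in res.jointly_increased

    def test_bag_inside_fence_and_median_in_bag(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(60, 2))
        a, b = _stat_frames(pts)
        res = bagfoot_delta(a, b)
        from refeedkit.footprinting import _inside_convex

        assert _inside_convex(res.fence_vertices, res.bag_vertices).all()
        assert _inside_convex(res.bag_vertices, res.depth_median[None, :]).all()

    def test_point_at_depth_median_does_not_change_outliers(self):
        rng = np.random.default_rng(4)
        cloud = _truncated_normal_cloud(100, rng)
        pts = np.vstack([cloud, [8.0, -8.0]])
        a, b = _stat_frames(pts)
        res = bagfoot_delta(a, b)
        pts2 = np.vstack([pts, res.depth_median])
        a2, b2 = _stat_frames(pts2)
        res2 = bagfoot_delta(a2, b2)
        assert set(res2.outliers) == set(res.outliers)

    def test_too_few_motifs_rejected(self):
        a, b = _stat_frames(np.random.default_rng(0).normal(size=(5, 2)))
        with pytest.raises(ValidationError, match="10"):
            bagfoot_delta(a, b)

    def test_mismatched_universes_rejected(self):
        a, b = _stat_frames(np.zeros((12, 2)))
        with pytest.raises(ValidationError):
            bagfoot_delta(a, b.iloc[:-1])


def _site_table(n, prefix="s", spacing=1000):
    starts = np.arange(n) * spacing
    return interval_frame(
        "chrS", starts, starts + 400, names=[f"{prefix}{i}" for i in range(n)]
    )


class TestMotifEnrichment:
    def test_motif_in_every_site_is_unenriched(self):
        bg = _site_table(50)
        fg = bg.iloc[:10]
        occ = _occ(list((bg["start"] + 200)), name="M00")
        out = motif_enrichment(fg, bg, occ)
        assert out.loc["M00", "fold_enrichment"] == pytest.approx(1.0)
        assert out.loc["M00", "pvalue"] == pytest.approx(1.0)

    def test_p_equals_direct_hypergeometric_tail(self):
        # foreground = exactly the sites containing the motif
        bg = _site_table(50)
        with_motif = bg.iloc[:12]
        occ = _occ(list(with_motif["start"] + 200), name="M00")
        out = motif_enrichment(with_motif, bg, occ)
        # direct summation of the hypergeometric tail
        p_direct = sum(
            stats.hypergeom.pmf(k, 50, 12, 12) for k in range(12, 13)
        )
        assert out.loc["M00", "pvalue"] == pytest.approx(p_direct)

    def test_foreground_must_be_subset(self):
        bg = _site_table(10)
        fg = _site_table(3, prefix="other")
        occ = _occ([200], name="M00")
        with pytest.raises(ValidationError, match="subset"):
            motif_enrichment(fg, bg, occ)

    def test_planted_motif_ranks_first(self):
        # motif planted in 80% of foreground vs 10% of background sites
        # should top the enrichment ranking in nearly every simulation
        rng = np.random.default_rng(17)
        n_first = 0
        n_sims = 100
        for _ in range(n_sims):
            bg = _site_table(200)
            fg = bg.iloc[:40]
            fg_hit = fg[rng.random(len(fg)) < 0.8]
            bg_rest = bg.iloc[40:]
            bg_hit = bg_rest[rng.random(len(bg_rest)) < 0.1]
            planted = _occ(
                list(pd.concat([fg_hit, bg_hit])["start"] + 200), name="Mplanted"
            )
            decoys = []
            for d in range(3):
                hits = bg[rng.random(len(bg)) < 0.3]
                decoys.append(_occ(list(hits["start"] + 150), name=f"Mdecoy{d}"))
            occ = pd.concat([planted] + decoys, ignore_index=True)
            out = motif_enrichment(fg, bg, occ)
            n_first += out.index[0] == "Mplanted"
        assert n_first / n_sims >= 0.95
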