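"""Enhancer classes, nearest-gene linkage, and class statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import status_frame
from refeedkit import diffexpr
from refeedkit.containers import SignalTrack, interval_frame
from refeedkit.diffexpr import contrast_name
from refeedkit.enhancers import (
    classify_enhancers,
    classify_genotype_response,
    compare_proximal_fractions,
    group_regulation_breakdown,
    nearest_gene,
    occupancy_at_classes,
    proximal_enhancer_fraction,
)
from refeedkit.simulate import (
    make_gene_annotation,
    simulate_counts,
    simulate_enhancer_peaks,
)


def _peak_calls(ids, fast, late, fast_vs_late):
    return {
        contrast_name("Adlib", "Fasted"): status_frame(ids, fast),
        contrast_name("Adlib", "Refed_24h"): status_frame(ids, late),
        contrast_name("Refed_24h", "Fasted"): status_frame(ids, fast_vs_late),
    }


class TestClassifyEnhancers:
    def test_rule_cases(self):
        ids = ["p_over", "p_rec", "p_none", "p_act"]
        calls = _peak_calls(
            ids,
            fast=["repressed", "repressed", "unchanged", "unchanged"],
            late=["induced", "unchanged", "unchanged", "induced"],
            fast_vs_late=["repressed", "repressed", "unchanged", "unchanged"],
        )
        out = classify_enhancers(calls)
        assert out.loc["p_over", "pattern"] == "overshoot"
        assert out.loc["p_over", "refeeding_activated"]
        assert out.loc["p_rec", "pattern"] == "recovered"
        assert out.loc["p_none", "pattern"] == "none"
        assert out.loc["p_act", "refeeding_activated"]
        assert not out.loc["p_act", "overshoot"]

    def test_overshoot_subset_of_activated_and_exclusive(self, small_sim):
        peak_calls = {
            k: small_sim["calls"][k]
            for k in (
                contrast_name("Adlib", "Fasted"),
                contrast_name("Adlib", "Refed_24h"),
                contrast_name("Refed_24h", "Fasted"),
            )
        }
        out = classify_enhancers(peak_calls)
        assert (out["overshoot"] & ~out["refeeding_activated"]).sum() == 0
        assert (out["overshoot"] & out["recovered"]).sum() == 0

    def test_planted_overshoot_recall(self, design):
        cm, truth = simulate_counts(
            design, n_per_template={"E": 200, "D": 200, "flat": 400}, seed=31
        )
        calls = diffexpr.run_contrasts(
            cm,
            [("Adlib", "Fasted"), ("Adlib", "Refed_24h"), ("Refed_24h", "Fasted")],
        )
        out = classify_enhancers(calls)
        e_feats = truth.index[truth == "E"]
        assert out.loc[e_feats, "overshoot"].mean() >= 0.9

    def test_genotype_classes(self):
        calls = {
            contrast_name("DKO", "WT"): status_frame(
                ["a", "b", "c"], ["induced", "repressed", "unchanged"]
            )
        }
        out = classify_genotype_response(calls)
        assert list(out["status"]) == ["increased", "decreased", "unchanged"]


def _brute_nearest(peaks, annotation):
    rows = []
    centers = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
    for pid, chrom, c in zip(peaks["name"], peaks["chrom"], centers):
        best = None
        for gid, row in annotation.iterrows():
            if row["chrom"] != chrom:
                continue
            key = (abs(int(row["tss"]) - int(c)), str(gid))
            if best is None or key < best:
                best = key
                best_gid = gid
        rows.append((pid, best_gid if best else None))
    return rows


@pytest.fixture(scope="module")
def annotation():
    return make_gene_annotation(200, seed=41)


class TestNearestGene:
    def test_peak_on_tss(self, annotation):
        tss = int(annotation.iloc[5]["tss"])
        peaks = interval_frame("chrS", [tss - 100], [tss + 100], names=["pk"])
        out = nearest_gene(peaks, annotation)
        assert out.iloc[0]["gene_id"] == annotation.index[5]
        assert out.iloc[0]["distance"] == 0

    def test_equidistant_tie_breaks_lexicographically(self):
        ann = pd.DataFrame(
            {"chrom": "chrS", "tss": [1000, 3000], "strand": "+",
             "length_bp": 500},
            index=pd.Index(["geneB", "geneA"], name="gene_id"),
        )
        peaks = interval_frame("chrS", [1950], [2050], names=["pk"])  # center 2000
        out = nearest_gene(peaks, ann)
        assert out.iloc[0]["gene_id"] == "geneA"

    def test_matches_brute_force_on_random_peaks(self, annotation):
        rng = np.random.default_rng(6)
        centers = rng.integers(0, 10_000_000 - 100, 2000)
        peaks = interval_frame(
            "chrS", centers, centers + 100,
            names=[f"pk{i}" for i in range(2000)],
        )
        out = nearest_gene(peaks, annotation)
        brute = _brute_nearest(peaks, annotation)
        assert list(zip(out["peak_id"], out["gene_id"])) == brute

    def test_translation_invariance(self, annotation):
        rng = np.random.default_rng(7)
        centers = rng.integers(10_000, 1_000_000, 200)
        peaks = interval_frame("chrS", centers, centers + 100,
                               names=[f"pk{i}" for i in range(200)])
        shift = 5_000
        ann2 = annotation.copy()
        ann2["tss"] = ann2["tss"] + shift
        peaks2 = peaks.copy()
        peaks2["start"] += shift
        peaks2["end"] += shift
        out1 = nearest_gene(peaks, annotation)
        out2 = nearest_gene(peaks2, ann2)
        assert out1["gene_id"].equals(out2["gene_id"])

    def test_chrom_without_genes_flagged(self, annotation):
        peaks = interval_frame("chrX", [100], [200], names=["pk"])
        out = nearest_gene(peaks, annotation)
        assert not out.iloc[0]["assigned"]


class TestProximalFractions:
    def test_full_and_empty_classes(self):
        links = pd.DataFrame(
            {"peak_id": ["p1", "p2"], "gene_id": ["g1", "g2"],
             "distance": [0, 0], "assigned": True}
        )
        full = proximal_enhancer_fraction(["g1", "g2"], ["p1", "p2"], links)
        assert full["fraction"] == 1.0
        empty = proximal_enhancer_fraction(["g1", "g2"], [], links)
        assert empty["fraction"] == 0.0

    def test_planted_linkage_fraction_recovered(self, design):
        cm, truth = simulate_counts(
            design, n_per_template={"E": 200, "D": 100, "flat": 300}, seed=51
        )
        ann = make_gene_annotation(len(truth), seed=52)
        peaks, peak_cm, _ = simulate_enhancer_peaks(
            design, ann, truth, linkage_fraction=0.4, n_background=300, seed=53
        )
        peak_calls = diffexpr.run_contrasts(
            peak_cm,
            [("Adlib", "Fasted"), ("Adlib", "Refed_24h"), ("Refed_24h", "Fasted")],
        )
        enh = classify_enhancers(peak_calls)
        links = nearest_gene(peaks, ann)
        activated = enh.index[enh["refeeding_activated"]]
        e_genes = truth.index[truth == "E"]
        out = proximal_enhancer_fraction(e_genes, activated, links)
        assert abs(out["fraction"] - 0.4) <= 0.07

    def test_monotone_in_class_size(self):
        links = pd.DataFrame(
            {"peak_id": [f"p{i}" for i in range(10)],
             "gene_id": [f"g{i % 5}" for i in range(10)],
             "distance": 0, "assigned": True}
        )
        genes = [f"g{i}" for i in range(5)]
        small = proximal_enhancer_fraction(genes, ["p0"], links)["fraction"]
        large = proximal_enhancer_fraction(genes, [f"p{i}" for i in range(10)],
                                           links)["fraction"]
        assert large >= small

    def test_fisher_matches_hypergeometric_enumeration(self):
        # small-margin table: two-sided Fisher p = sum of hypergeometric
        # probabilities not exceeding the observed table's
        links = pd.DataFrame(
            {"peak_id": [f"p{i}" for i in range(8)],
             "gene_id": [f"a{i}" for i in range(6)] + ["b0", "b1"],
             "distance": 0, "assigned": True}
        )
        set_a = [f"a{i}" for i in range(10)]
        set_b = [f"b{i}" for i in range(12)]
        out = compare_proximal_fractions(set_a, set_b, links["peak_id"], links)
        k, n1 = out["set_a"]["n_with_enhancer"], out["set_a"]["n_genes"]
        k2, n2 = out["set_b"]["n_with_enhancer"], out["set_b"]["n_genes"]
        total_hits = k + k2
        probs = [
            stats.hypergeom.pmf(x, n1 + n2, total_hits, n1)
            for x in range(total_hits + 1)
        ]
        p_obs = stats.hypergeom.pmf(k, n1 + n2, total_hits, n1)
        p_enum = sum(p for p in probs if p <= p_obs * (1 + 1e-9))
        assert out["pvalue"] == pytest.approx(p_enum)


class TestBreakdownAndOccupancy:
    def test_breakdown_fractions(self):
        calls = pd.DataFrame(
            {"status": ["increased"] * 7 + ["decreased"] * 2 + ["unchanged"]},
            index=pd.Index([f"g{i}" for i in range(10)]),
        )
        out = group_regulation_breakdown([f"g{i}" for i in range(10)], calls)
        assert out.set_index("status").loc["increased", "fraction"] == 0.7
        assert out["fraction"].sum() == pytest.approx(1.0)

    def test_breakdown_with_no_tested_genes(self):
        calls = pd.DataFrame({"status": []}, index=pd.Index([]))
        out = group_regulation_breakdown(["gX"], calls)
        assert (out["count"] == 0).all()
        assert out.attrs["warning"]

    def test_identical_signal_not_significant(self):
        arr = np.random.default_rng(2).poisson(5, 50_000).astype(float)
        t = SignalTrack({"chrS": arr})
        sites = interval_frame("chrS", np.arange(500, 20_500, 500),
                               np.arange(600, 20_600, 500))
        summary, tests = occupancy_at_classes(t, {"x": sites, "y": sites})
        assert (tests["pvalue"] >= 0.99).all()

    def test_planted_enrichment_ratio(self):
        rng = np.random.default_rng(9)
        arr = rng.poisson(2.0, 2_000_000).astype(float)
        centers_bg = np.arange(1000, 501_000, 1000)
        centers_fg = np.arange(1_100_000, 1_600_000, 1000)
        for c in centers_fg:  # 3x signal at enriched class
            arr[c - 200 : c + 200] *= 3
        t = SignalTrack({"chrS": arr})
        fg = interval_frame("chrS", centers_fg - 50, centers_fg + 50)
        bg = interval_frame("chrS", centers_bg - 50, centers_bg + 50)
        summary, _ = occupancy_at_classes(t, {"fg": fg}, baseline=bg)
        s = summary.set_index("class")["mean"]
        assert 2.5 <= s["fg"] / s["all_sites"] <= 3.5

    def test_empty_track_gives_zero_occupancy(self):
        t = SignalTrack({"chrS": np.zeros(10_000)})
        sites = interval_frame("chrS", [1000, 2000], [1100, 2100])
        summary, _ = occupancy_at_classes(t, {"x": sites})
        assert (summary["mean"] == 0).all()
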