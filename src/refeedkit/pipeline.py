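"""End-to-end orchestration of the fasting/refeeding analysis.

``run_demo`` generates a synthetic five-condition dataset with planted
kinetic patterns, runs every analysis stage, and writes a full output
tree (contrasts, pattern calls, cluster assignments, group reports,
enhancer classes and links, footprint statistics, a truth-vs-called
confusion matrix, and a machine-readable run manifest).  Deterministic
given the seed: rerunning with the same seed reproduces every output
byte for byte.

``run_pipeline`` runs a configurable subset of stages on inputs on disk
(the synthetic_data TSV/BED dialect), so the same analysis applies to
real count tables and peak sets.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr, enhancers, footprinting, lipid_groups, patterns, quantification
from .containers import ValidationError
from .io import (
    read_annotation_tsv,
    read_bed,
    read_bedgraph,
    read_counts_tsv,
    write_annotation_tsv,
    write_bed,
    write_bedgraph,
    write_counts_tsv,
)
from .simulate import (
    StudyDesign,
    default_templates,
    make_gene_annotation,
    simulate_counts,
    simulate_cut_profiles,
    simulate_enhancer_peaks,
)

__all__ = ["PipelineConfig", "run_demo", "run_pipeline", "STAGES"]

STAGES = ("diffexpr", "patterns", "groups", "enhancers", "footprint")

#: Contrasts (cond_a, cond_b) needed by the gene-level stages.
GENE_CONTRASTS = [
    ("Adlib", "Fasted"),
    ("Adlib", "Refed_3h"),
    ("Adlib", "Refed_10h"),
    ("Adlib", "Refed_24h"),
    ("Refed_24h", "Fasted"),
    ("Refed_3h", "Fasted"),
    ("Refed_10h", "Fasted"),
]
PEAK_CONTRASTS = [
    ("Adlib", "Fasted"),
    ("Adlib", "Refed_24h"),
    ("Refed_24h", "Fasted"),
]

#: Schematic condition-shape templates used to name the A-C clusters.
ABC_SCHEMATICS = {
    "A": (1.0, 4.0, 3.5, 1.1, 1.0),
    "B": (1.0, 4.0, 1.0, 1.0, 1.0),
    "C": (1.0, 1.0, 0.25, 1.0, 1.0),
}


@dataclass
class PipelineConfig:
    """Paths, thresholds and stage selection for a pipeline run."""

    outdir: Path
    counts: Path | None = None
    annotation: Path | None = None
    peaks: Path | None = None
    peak_counts: Path | None = None
    group_lists: Path | None = None
    cut_track_a: Path | None = None
    cut_track_b: Path | None = None
    motifs: Path | None = None
    accessible_sites: Path | None = None
    stages: tuple[str, ...] = STAGES
    fc_min: float = diffexpr.FC_MIN
    alpha: float = diffexpr.ALPHA
    rpkm_min: float = 1.0
    seed: int = 17

    def __post_init__(self) -> None:
        if self.fc_min <= 0 or self.alpha <= 0 or self.rpkm_min <= 0:
            raise ValidationError("thresholds must be positive")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValidationError(f"unknown stages: {sorted(unknown)}")
        self.outdir = Path(self.outdir)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def _confusion(truth: pd.Series, called: pd.Series, labels) -> pd.DataFrame:
    """Rows = truth label, columns = called label, plus recall/precision."""
    tab = pd.crosstab(truth, called).reindex(
        index=labels, columns=list(labels) + ["none"], fill_value=0
    )
    recall = {
        lab: tab.loc[lab, lab] / tab.loc[lab].sum() if tab.loc[lab].sum() else np.nan
        for lab in labels
    }
    precision = {
        lab: tab.loc[lab, lab] / tab[lab].sum() if tab[lab].sum() else np.nan
        for lab in labels
    }
    tab["recall"] = pd.Series(recall)
    tab.loc["precision"] = [precision.get(c, np.nan) for c in tab.columns]
    return tab


def run_demo(
    seed: int = 17,
    outdir: str | Path = "demo_out",
    n_per_pattern: int = 200,
    n_abc: int = 300,
    n_flat: int = 3300,
    n_background_peaks: int = 2920,
    linkage_fraction: float = 0.4,
    n_motifs: int = 50,
    occurrences_per_motif: int = 50,
    hard_mode: bool = False,
) -> dict:
    """Generate a synthetic dataset, run all stages, write the output tree.

    Default sizes: 5,000 genes (300 each of patterns A-C, 200 each of
    D-G, the rest flat), 3,000 peaks, 50 motifs.  Returns the run
    manifest (also written as ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = StudyDesign(seed=seed)
    templates = default_templates(hard_mode=hard_mode)
    rng = np.random.default_rng(seed)

    # ---- stage: simulate -------------------------------------------------
    n_per = {"A": n_abc, "B": n_abc, "C": n_abc,
             "D": n_per_pattern, "E": n_per_pattern,
             "F": n_per_pattern, "G": n_per_pattern, "flat": n_flat}
    gene_cm, gene_truth = simulate_counts(
        design, templates, n_per, seed=seed,
    )
    annotation = make_gene_annotation(len(gene_truth), seed=seed + 1)
    gene_cm.lengths = annotation["length_bp"]

    peaks, peak_cm, truth_linkage = simulate_enhancer_peaks(
        design, annotation, gene_truth,
        linkage_fraction=linkage_fraction,
        n_background=n_background_peaks,
        templates=templates,
        seed=seed + 2,
    )
    peak_truth = peak_cm.meta["truth"]

    # footprinting inputs live on their own contig so motif windows
    # cannot collide with each other
    chrF_len = max(2_000_000, (n_motifs * occurrences_per_motif + 2) * 500)
    motif_tables = {}
    pos = 500
    motif_width = 12
    occ_rows = []
    for m in range(n_motifs):
        mid = f"M{m:02d}"
        for _ in range(occurrences_per_motif):
            strand = "+" if rng.random() < 0.5 else "-"
            occ_rows.append(("chrF", pos, pos + motif_width, mid, 0, strand))
            pos += 500
    occurrences = pd.DataFrame(
        occ_rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
    for mid, sub in occurrences.groupby("name", sort=False):
        motif_tables[mid] = sub.reset_index(drop=True)
    accessible_f = occurrences.assign(
        start=occurrences["start"] - 180,
        end=occurrences["end"] + 180,
        name=[f"fs{i:05d}" for i in range(len(occurrences))],
    )
    planted_motif = "M00"
    cut_tracks, truth_fp = simulate_cut_profiles(
        design,
        motif_tables,
        flank_rate=8.0,
        interior_fraction=0.5,
        footprint_depth_by_condition={planted_motif: {"Refed_24h": 0.15}},
        flank_scale_by_condition={planted_motif: {"Refed_24h": 1.5}},
        noise=True,
        chrom_lengths={"chrF": chrF_len},
        conditions=("Adlib", "Refed_24h"),
        seed=seed + 3,
    )

    # motif-hit table for enrichment: planted motif present in 80% of
    # overshoot (pattern-E) peaks and 10% of the rest
    e_peaks = peaks[peak_truth.loc[peaks["name"]].to_numpy() == "E"]
    other_peaks = peaks[peak_truth.loc[peaks["name"]].to_numpy() != "E"]
    hit_rows = []
    for i, (_, row) in enumerate(e_peaks.iterrows()):
        if rng.random() < 0.8:
            c = (row["start"] + row["end"]) // 2
            hit_rows.append((row["chrom"], c, c + motif_width, planted_motif, 0, "+"))
    for i, (_, row) in enumerate(other_peaks.iterrows()):
        if rng.random() < 0.1:
            c = (row["start"] + row["end"]) // 2
            hit_rows.append((row["chrom"], c, c + motif_width, planted_motif, 0, "+"))
    # a neutral motif present in 30% of all peaks
    for _, row in peaks.iterrows():
        if rng.random() < 0.3:
            c = (row["start"] + row["end"]) // 2 - 50
            hit_rows.append((row["chrom"], c, c + motif_width, "M01", 0, "+"))
    peak_motif_hits = pd.DataFrame(
        hit_rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )

    inputs = outdir / "inputs"
    inputs.mkdir(exist_ok=True)
    write_counts_tsv(gene_cm, inputs / "gene_counts.tsv")
    write_annotation_tsv(annotation, inputs / "gene_annotation.tsv")
    write_counts_tsv(peak_cm, inputs / "peak_counts.tsv")
    write_bed(peaks, inputs / "peaks.bed")
    write_bed(occurrences, inputs / "footprint_motifs.bed")
    write_bed(peak_motif_hits, inputs / "peak_motif_hits.bed")
    for cond, track in cut_tracks.items():
        write_bedgraph(track, inputs / f"cuts_{cond}.bedGraph")
    _write_tsv(gene_truth.to_frame(), inputs / "truth_gene_patterns.tsv")
    _write_tsv(peak_truth.to_frame(), inputs / "truth_peak_patterns.tsv")
    _write_tsv(truth_linkage, inputs / "truth_linkage.tsv", index=False)

    # ---- stage: diffexpr -------------------------------------------------
    gene_cm_nz, dropped = gene_cm.drop_all_zero()
    size_factors = diffexpr.normalize_libraries(gene_cm_nz)
    gene_calls = diffexpr.run_contrasts(gene_cm_nz, GENE_CONTRASTS, size_factors)
    for key, table in gene_calls.items():
        _write_tsv(table, outdir / "contrasts" / f"genes_{key}.tsv")
    peak_calls = diffexpr.run_contrasts(peak_cm, PEAK_CONTRASTS)

    # ---- stage: patterns -------------------------------------------------
    induced_uni, repressed_uni = patterns.fasting_regulated_universe(gene_calls)
    cond_means = gene_cm_nz.condition_means(size_factors)
    cluster = patterns.cluster_patterns(cond_means.loc[induced_uni], k=3, seed=seed)
    cluster_names = patterns.match_clusters_to_templates(cluster, ABC_SCHEMATICS)
    cluster_out = cluster.assignments.map(cluster_names).rename("cluster_pattern")
    calls_defg = patterns.call_refeeding_patterns(gene_calls)
    _write_tsv(calls_defg, outdir / "patterns" / "pattern_calls.tsv")
    _write_tsv(cluster_out.to_frame(), outdir / "patterns" / "cluster_assignments.tsv")

    confusion = _confusion(
        gene_truth.reindex(calls_defg.index),
        calls_defg["pattern"],
        ["D", "E", "F", "G"],
    )
    _write_tsv(confusion, outdir / "patterns" / "confusion_defg.tsv")

    # ---- stage: groups ---------------------------------------------------
    e_genes = list(gene_truth.index[gene_truth == "E"])
    d_genes = list(gene_truth.index[gene_truth == "D"])
    n_lipo = min(20, max(3, len(e_genes) // 2))
    n_aid = min(15, max(3, len(e_genes) - n_lipo))
    groups = [
        lipid_groups.GeneGroup("LIPO", tuple(e_genes[:n_lipo]),
                               "synthetic overshoot-like"),
        lipid_groups.GeneGroup("CHOL", tuple(d_genes[: min(20, len(d_genes))]),
                               "synthetic recovered-like"),
        lipid_groups.GeneGroup("AID", tuple(e_genes[n_lipo : n_lipo + n_aid]),
                               "synthetic overshoot-like"),
    ]
    rpkm = diffexpr.compute_rpkm(gene_cm_nz)
    filtered, reports = [], []
    for g in groups:
        fg, rep = lipid_groups.filter_group(
            g, rpkm, gene_calls,
            condition_of_sample=gene_cm_nz.samples["condition"],
        )
        filtered.append(fg)
        reports.append(
            (rep.group, rep.n_input, len(rep.missing_ids),
             rep.n_failed_expression, rep.n_failed_repression, rep.n_survivors)
        )
    report_df = pd.DataFrame(
        reports,
        columns=["group", "n_input", "n_missing", "n_failed_expression",
                 "n_failed_repression", "n_survivors"],
    )
    _write_tsv(report_df, outdir / "groups" / "filter_report.tsv", index=False)
    fc_table, fc_tests = lipid_groups.group_fc_comparison(filtered, gene_calls)
    _write_tsv(fc_table, outdir / "groups" / "group_fc.tsv", index=False)
    _write_tsv(fc_tests, outdir / "groups" / "group_fc_tests.tsv", index=False)

    # ---- stage: enhancers ------------------------------------------------
    enh_calls = enhancers.classify_enhancers(peak_calls)
    links = enhancers.nearest_gene(peaks, annotation)
    _write_tsv(enh_calls, outdir / "enhancers" / "enhancer_classes.tsv")
    _write_tsv(links, outdir / "enhancers" / "gene_links.tsv", index=False)

    overshoot_genes = calls_defg.index[calls_defg["pattern"] == "E"]
    recovered_genes = calls_defg.index[calls_defg["pattern"] == "D"]
    activated_peaks = enh_calls.index[enh_calls["refeeding_activated"]]
    prox = enhancers.compare_proximal_fractions(
        overshoot_genes, recovered_genes, activated_peaks, links
    )
    prox_df = pd.DataFrame(
        [
            ("overshoot", prox["set_a"]["n_genes"], prox["set_a"]["n_with_enhancer"],
             prox["set_a"]["fraction"]),
            ("recovered", prox["set_b"]["n_genes"], prox["set_b"]["n_with_enhancer"],
             prox["set_b"]["fraction"]),
        ],
        columns=["gene_set", "n_genes", "n_with_activated_enhancer", "fraction"],
    )
    prox_df.attrs["fisher_p"] = prox["pvalue"]
    _write_tsv(prox_df, outdir / "enhancers" / "proximal_fractions.tsv", index=False)

    enh_confusion = _confusion(
        peak_truth.map({"E": "overshoot", "D": "recovered", "flat": "none"}),
        enh_calls["pattern"],
        ["overshoot", "recovered"],
    )
    _write_tsv(enh_confusion, outdir / "enhancers" / "confusion_enhancers.tsv")

    # ---- stage: footprint ------------------------------------------------
    stats_by_cond = {}
    for cond in ("Adlib", "Refed_24h"):
        track = quantification.scale_track(cut_tracks[cond])
        stats_by_cond[cond] = footprinting.footprint_stat_table(
            track, occurrences, accessible_f, condition=cond
        )
    bag = footprinting.bagfoot_delta(stats_by_cond["Adlib"], stats_by_cond["Refed_24h"])
    fp_out = pd.concat(
        [
            stats_by_cond["Adlib"].rename(columns={"FA": "FA_Adlib", "FPD": "FPD_Adlib"}),
            stats_by_cond["Refed_24h"][["FA", "FPD"]].rename(
                columns={"FA": "FA_Refed_24h", "FPD": "FPD_Refed_24h"}
            ),
            bag.deltas[["dFA", "dFPD", "depth", "outlier"]],
        ],
        axis=1,
    )
    _write_tsv(fp_out, outdir / "footprint" / "footprint_stats.tsv")

    overshoot_peaks = peaks[enh_calls.loc[peaks["name"], "overshoot"].to_numpy()]
    enrich = footprinting.motif_enrichment(overshoot_peaks, peaks, peak_motif_hits)
    _write_tsv(enrich, outdir / "footprint" / "motif_enrichment.tsv")

    # ---- manifest --------------------------------------------------------
    manifest = {
        "seed": seed,
        "design": {
            "conditions": list(design.conditions),
            "replicates_per_condition": design.replicates_per_condition,
        },
        "thresholds": {"fc_min": diffexpr.FC_MIN, "alpha": diffexpr.ALPHA,
                       "rpkm_min": 1.0},
        "sizes": {
            "n_genes": int(len(gene_truth)),
            "n_peaks": int(len(peaks)),
            "n_motifs": int(n_motifs),
            "n_dropped_all_zero": int(len(dropped)),
        },
        "planted": {
            "linkage_fraction": linkage_fraction,
            "footprint_motif": planted_motif,
        },
        "results": {
            "n_fasting_induced": int(len(induced_uni)),
            "n_fasting_repressed": int(len(repressed_uni)),
            "pattern_counts": calls_defg["pattern"].value_counts().to_dict(),
            "proximal_fraction_overshoot": prox["set_a"]["fraction"],
            "proximal_fraction_recovered": prox["set_b"]["fraction"],
            "proximal_fisher_p": prox["pvalue"],
            "bagplot_outliers": bag.outliers,
            "top_enriched_motif": str(enrich.index[0]),
        },
        "outputs": {},
    }
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][str(path.relative_to(outdir))] = _sha256(path)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the selected stages on inputs from disk.

    Inputs follow the synthetic_data dialect (counts TSV with
    ``<condition>_rep<N>`` columns, annotation TSV, BED6 peaks).  Each
    stage validates its inputs and fails with an error naming the stage;
    a manifest with parameters and output hashes is written at the end.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    want = [s for s in STAGES if s in config.stages]
    artefacts: dict = {}

    def need(path, what, stage):
        if path is None or not Path(path).exists():
            raise ValidationError(f"stage {stage!r} requires {what} input")
        return Path(path)

    if {"diffexpr", "patterns", "groups"} & set(want):
        cm = read_counts_tsv(need(config.counts, "counts", "diffexpr"))
        cm, _ = cm.drop_all_zero()
        sf = diffexpr.normalize_libraries(cm)
        calls = diffexpr.run_contrasts(
            cm, GENE_CONTRASTS, sf, fc_min=config.fc_min, alpha=config.alpha
        )
        artefacts["gene_calls"] = calls
        if "diffexpr" in want:
            for key, table in calls.items():
                _write_tsv(table, out / "contrasts" / f"genes_{key}.tsv")

    if "patterns" in want:
        calls = artefacts["gene_calls"]
        calls_defg = patterns.call_refeeding_patterns(calls)
        _write_tsv(calls_defg, out / "patterns" / "pattern_calls.tsv")
        artefacts["pattern_calls"] = calls_defg

    if "groups" in want:
        path = need(config.group_lists, "group lists", "groups")
        ann = need(config.annotation, "annotation", "groups")
        annotation = read_annotation_tsv(ann)
        cm = read_counts_tsv(Path(config.counts), lengths=annotation["length_bp"])
        cm, _ = cm.drop_all_zero()
        rpkm = diffexpr.compute_rpkm(cm)
        groups = lipid_groups.load_gene_groups(path)
        filtered = []
        for g in groups:
            fg, _ = lipid_groups.filter_group(
                g, rpkm, artefacts["gene_calls"],
                condition_of_sample=cm.samples["condition"],
                rpkm_min=config.rpkm_min,
            )
            filtered.append(fg)
        fc_table, fc_tests = lipid_groups.group_fc_comparison(
            filtered, artefacts["gene_calls"]
        )
        _write_tsv(fc_table, out / "groups" / "group_fc.tsv", index=False)
        _write_tsv(fc_tests, out / "groups" / "group_fc_tests.tsv", index=False)

    if "enhancers" in want:
        peaks = read_bed(need(config.peaks, "peaks", "enhancers"))
        pcm = read_counts_tsv(need(config.peak_counts, "peak counts", "enhancers"))
        annotation = read_annotation_tsv(
            need(config.annotation, "annotation", "enhancers")
        )
        peak_calls = diffexpr.run_contrasts(
            pcm, PEAK_CONTRASTS, fc_min=config.fc_min, alpha=config.alpha
        )
        enh = enhancers.classify_enhancers(peak_calls)
        links = enhancers.nearest_gene(peaks, annotation)
        _write_tsv(enh, out / "enhancers" / "enhancer_classes.tsv")
        _write_tsv(links, out / "enhancers" / "gene_links.tsv", index=False)

    if "footprint" in want:
        track_a = read_bedgraph(need(config.cut_track_a, "cut track A", "footprint"))
        track_b = read_bedgraph(need(config.cut_track_b, "cut track B", "footprint"))
        motifs = read_bed(need(config.motifs, "motif BED", "footprint"))
        sites = (
            read_bed(Path(config.accessible_sites))
            if config.accessible_sites is not None
            else None
        )
        stats_a = footprinting.footprint_stat_table(
            quantification.scale_track(track_a), motifs, sites, condition="A"
        )
        stats_b = footprinting.footprint_stat_table(
            quantification.scale_track(track_b), motifs, sites, condition="B"
        )
        bag = footprinting.bagfoot_delta(stats_a, stats_b)
        fp_out = pd.concat(
            [
                stats_a.rename(columns={"FA": "FA_A", "FPD": "FPD_A"}),
                stats_b[["FA", "FPD"]].rename(columns={"FA": "FA_B", "FPD": "FPD_B"}),
                bag.deltas[["dFA", "dFPD", "depth", "outlier"]],
            ],
            axis=1,
        )
        _write_tsv(fp_out, out / "footprint" / "footprint_stats.tsv")

    manifest = {
        "stages": want,
        "thresholds": {"fc_min": config.fc_min, "alpha": config.alpha,
                       "rpkm_min": config.rpkm_min},
        "seed": config.seed,
        "outputs": {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
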