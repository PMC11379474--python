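"""Synthetic fasting/refeeding datasets with planted ground truth.

The generator emulates a five-state feeding time course — ad libitum
(``Adlib``), a 24 h fast (``Fasted``), and three refeeding time points
(``Refed_3h``, ``Refed_10h``, ``Refed_24h``) — with three biological
replicates per state.  Gene counts are drawn from a negative binomial
with variance ``mu + alpha * mu**2``; each gene follows one of the kinetic
pattern templates A-G (or stays flat), so every downstream call can be
scored against planted truth.

Enhancer peaks, motif occurrences, and per-base transposase cut-count
tracks are generated on a single synthetic contig (``chrS``, 10 Mb,
0-based half-open coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix, SignalTrack, ValidationError, interval_frame
from .io import sample_name

__all__ = [
    "DEFAULT_CONDITIONS",
    "CONTIG",
    "CONTIG_LENGTH",
    "StudyDesign",
    "PatternTemplate",
    "SimulatedDataset",
    "default_templates",
    "simulate_counts",
    "make_gene_annotation",
    "simulate_enhancer_peaks",
    "simulate_cut_profiles",
]

DEFAULT_CONDITIONS = ("Adlib", "Fasted", "Refed_3h", "Refed_10h", "Refed_24h")

#: The single synthetic contig on which all coordinates live.
CONTIG = "chrS"
CONTIG_LENGTH = 10_000_000

DEFAULT_SEED = 17


@dataclass(frozen=True)
class StudyDesign:
    """Ordered condition labels and replication of the simulated study."""

    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    replicates_per_condition: int = 3
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if len(set(self.conditions)) != len(self.conditions):
            raise ValidationError("condition labels must be unique")
        if self.replicates_per_condition < 2:
            raise ValidationError("need >= 2 replicates per condition")

    @property
    def sample_ids(self) -> list[str]:
        return [
            sample_name(c, r + 1)
            for c in self.conditions
            for r in range(self.replicates_per_condition)
        ]

    def sample_table(self) -> pd.DataFrame:
        rows = [
            (c, r + 1)
            for c in self.conditions
            for r in range(self.replicates_per_condition)
        ]
        return pd.DataFrame(rows, index=self.sample_ids, columns=["condition", "replicate"])


@dataclass(frozen=True)
class PatternTemplate:
    """Per-condition mean multipliers for one kinetic pattern.

    Multipliers are relative to the gene's base mean in the Adlib state;
    the ``flat`` template is the null (all ones).
    """

    label: str
    multipliers: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.multipliers):
            raise ValidationError(f"template {self.label}: multipliers must be > 0")

    def scaled(self, exponent: float) -> "PatternTemplate":
        """Shrink (or amplify) effect sizes on the log scale."""
        return PatternTemplate(
            self.label, tuple(float(m) ** exponent for m in self.multipliers)
        )


def default_templates(hard_mode: bool = False) -> dict[str, PatternTemplate]:
    """Pattern templates over (Adlib, Fasted, Refed_3h, Refed_10h, Refed_24h).

    A: fasting-induced, wanes slowly after refeeding.
    B: fasting-induced, reverts within 3 h of refeeding.
    C: unchanged by fasting, transiently repressed early in refeeding.
    D: fasting-repressed, recovered to baseline by Refed_24h.
    E: fasting-repressed, overshoots above baseline late in refeeding.
    F: unchanged by fasting, induced late in refeeding.
    G: induced early (Refed_3h) only.

    ``hard_mode`` halves every effect size on the log scale for power
    studies.
    """
    raw = {
        "A": (1.0, 4.0, 3.5, 1.1, 1.0),
        "B": (1.0, 4.0, 1.0, 1.0, 1.0),
        "C": (1.0, 1.0, 0.25, 1.0, 1.0),
        "D": (1.0, 0.25, 0.4, 0.8, 1.0),
        "E": (1.0, 0.25, 0.5, 2.5, 3.0),
        "F": (1.0, 1.0, 1.0, 2.5, 3.0),
        "G": (1.0, 1.0, 3.0, 1.1, 1.0),
        "flat": (1.0, 1.0, 1.0, 1.0, 1.0),
    }
    templates = {k: PatternTemplate(k, v) for k, v in raw.items()}
    if hard_mode:
        templates = {k: t.scaled(0.5) for k, t in templates.items()}
    return templates


def _check_design_templates(design: StudyDesign, templates) -> None:
    for t in templates.values():
        if len(t.multipliers) != len(design.conditions):
            raise ValidationError(
                f"template {t.label}: {len(t.multipliers)} multipliers for "
                f"{len(design.conditions)} conditions"
            )


def simulate_counts(
    design: StudyDesign,
    templates: dict[str, PatternTemplate] | None = None,
    n_per_template: dict[str, int] | None = None,
    base_mean_range: tuple[float, float] = (20.0, 2000.0),
    dispersion: float = 0.05,
    library_size_factors: np.ndarray | None = None,
    seed: int | None = None,
    prefix: str = "g",
) -> tuple[CountMatrix, pd.Series]:
    """Draw a count matrix with planted pattern templates.

    Counts for feature *i* in sample *j* are NB with mean
    ``base_mean_i * multiplier[condition_j] * library_factor_j`` and
    variance ``mu + dispersion * mu**2``.  Base means are log-uniform over
    ``base_mean_range``.  Library size factors default to log-normal(0, 0.1)
    so normalization is exercised.

    Returns the matrix and a Series of truth labels (template per feature).
    """
    if templates is None:
        templates = default_templates()
    if n_per_template is None:
        n_per_template = {"A": 200, "B": 200, "C": 200, "D": 200, "E": 200,
                          "F": 200, "G": 200, "flat": 1000}
    _check_design_templates(design, templates)
    if dispersion <= 0:
        raise ValidationError("dispersion must be > 0")
    lo, hi = base_mean_range
    if lo <= 0 or hi < lo:
        raise ValidationError("base_mean_range must be positive and ordered")
    for label, n in n_per_template.items():
        if label not in templates:
            raise ValidationError(f"no template for label {label!r}")
        if n < 0:
            raise ValidationError("n_per_template values must be >= 0")

    rng = np.random.default_rng(design.seed if seed is None else seed)
    n_samples = len(design.sample_ids)
    if library_size_factors is None:
        library_size_factors = np.exp(rng.normal(0.0, 0.1, size=n_samples))
    library_size_factors = np.asarray(library_size_factors, dtype=float)
    if library_size_factors.shape != (n_samples,):
        raise ValidationError("need one library size factor per sample")
    if np.any(library_size_factors <= 0):
        raise ValidationError("library size factors must be > 0")

    labels: list[str] = []
    mult_rows: list[np.ndarray] = []
    for label in n_per_template:  # insertion order keeps determinism
        mult = np.asarray(templates[label].multipliers, dtype=float)
        for _ in range(n_per_template[label]):
            labels.append(label)
            mult_rows.append(mult)
    n_features = len(labels)
    if n_features == 0:
        raise ValidationError("no features requested")
    mult_matrix = np.vstack(mult_rows)  # features x conditions

    base_means = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_features))
    reps = design.replicates_per_condition
    cond_expanded = np.repeat(mult_matrix, reps, axis=1)  # features x samples
    mu = base_means[:, None] * cond_expanded * library_size_factors[None, :]

    # gamma-Poisson mixture => NB with variance mu + dispersion * mu^2
    lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * mu)
    counts = rng.poisson(lam).astype(np.int64)

    ids = pd.Index([f"{prefix}{i:05d}" for i in range(n_features)], name="feature_id")
    cm = CountMatrix(
        pd.DataFrame(counts, index=ids, columns=design.sample_ids),
        design.sample_table(),
    )
    truth = pd.Series(labels, index=ids, name="pattern")
    return cm, truth


def make_gene_annotation(
    n_genes: int,
    contig: str = CONTIG,
    contig_length: int = CONTIG_LENGTH,
    seed: int = DEFAULT_SEED,
    prefix: str = "g",
) -> pd.DataFrame:
    """Evenly spaced TSSs with random strand and gene length.

    Returns a DataFrame indexed by gene_id with columns
    chrom, tss, strand, length_bp.
    """
    spacing = contig_length // (n_genes + 1)
    if spacing < 100:
        raise ValidationError("contig too small for requested gene count")
    rng = np.random.default_rng(seed)
    tss = (np.arange(1, n_genes + 1) * spacing).astype(np.int64)
    strands = rng.choice(["+", "-"], size=n_genes)
    lengths = rng.integers(500, 5000, size=n_genes)
    ids = pd.Index([f"{prefix}{i:05d}" for i in range(n_genes)], name="gene_id")
    return pd.DataFrame(
        {"chrom": contig, "tss": tss, "strand": strands, "length_bp": lengths},
        index=ids,
    )


def simulate_enhancer_peaks(
    design: StudyDesign,
    annotation: pd.DataFrame,
    gene_truth: pd.Series,
    linkage_fraction: float = 0.4,
    linked_pattern: str = "E",
    n_background: int = 1000,
    background_labels: tuple[str, ...] = ("D", "flat"),
    templates: dict[str, PatternTemplate] | None = None,
    base_mean_range: tuple[float, float] = (20.0, 500.0),
    dispersion: float = 0.05,
    peak_width: int = 500,
    peak_offset: tuple[int, int] = (600, 900),
    seed: int | None = None,
) -> tuple[pd.DataFrame, CountMatrix, pd.DataFrame]:
    """Plant proximal enhancer peaks for a fraction of pattern genes.

    For ``floor(linkage_fraction * n)`` of the genes carrying
    ``linked_pattern``, a peak is placed near the gene's TSS (closer to it
    than to any neighbouring TSS) and given the gene's count template, so
    that nearest-TSS mapping recovers the planted gene.  ``n_background``
    additional peaks with patterns drawn from ``background_labels`` are
    scattered midway between genes.

    Returns (peak intervals BED6, peak CountMatrix + truth via attrs,
    truth linkage table with columns gene_id, peak_id).
    """
    if not 0.0 <= linkage_fraction <= 1.0:
        raise ValidationError("linkage_fraction must lie in [0, 1]")
    if templates is None:
        templates = default_templates()
    rng = np.random.default_rng(design.seed + 1 if seed is None else seed)

    target_genes = gene_truth.index[gene_truth == linked_pattern]
    n_linked = int(np.floor(linkage_fraction * len(target_genes)))
    linked = list(target_genes[:n_linked])  # deterministic choice

    ann = annotation.sort_values("tss")
    tss = ann["tss"].to_numpy()
    order = {g: i for i, g in enumerate(ann.index)}
    if len(tss) > 1:
        min_gap = int(np.min(np.diff(tss)))
    else:
        min_gap = CONTIG_LENGTH
    # the peak centre must be nearer its target TSS than any neighbour's
    lo_off, hi_off = peak_offset
    hi_off = min(hi_off, min_gap // 2 - 1)
    if n_linked and hi_off <= lo_off:
        raise ValidationError(
            "contig too small to place linked peaks closer to their "
            "target TSS than to neighbouring genes"
        )

    chroms, starts, ends, names, labels = [], [], [], [], []
    link_rows = []
    k = 0
    for g in linked:
        g_tss = int(annotation.loc[g, "tss"])
        off = int(rng.integers(lo_off, hi_off))
        sign = -1 if rng.random() < 0.5 else 1
        center = g_tss + sign * off
        start = center - peak_width // 2
        if start < 0 or start + peak_width > CONTIG_LENGTH:
            raise ValidationError("contig too small for linked peak placement")
        pid = f"pk{k:05d}"
        k += 1
        chroms.append(str(annotation.loc[g, "chrom"]))
        starts.append(start)
        ends.append(start + peak_width)
        names.append(pid)
        labels.append(linked_pattern)
        link_rows.append((g, pid))

    # background peaks: midway between consecutive TSSs, jittered
    for i in range(n_background):
        j = int(rng.integers(0, max(1, len(tss) - 1)))
        mid = (tss[j] + tss[min(j + 1, len(tss) - 1)]) // 2
        center = int(mid + rng.integers(-min_gap // 8, min_gap // 8 + 1))
        start = max(0, center - peak_width // 2)
        pid = f"pk{k:05d}"
        k += 1
        chroms.append(CONTIG)
        starts.append(start)
        ends.append(start + peak_width)
        names.append(pid)
        labels.append(background_labels[i % len(background_labels)])

    peaks = interval_frame(chroms, starts, ends, names=names)
    truth_linkage = pd.DataFrame(link_rows, columns=["gene_id", "peak_id"])

    # verify planted linkage against nearest-TSS mapping
    from .enhancers import nearest_gene  # local import avoids a cycle

    links = nearest_gene(peaks, annotation).set_index("peak_id")
    for g, pid in link_rows:
        if links.loc[pid, "gene_id"] != g:
            raise ValidationError(
                f"planted peak {pid} is nearest to "
                f"{links.loc[pid, 'gene_id']}, not its target {g}"
            )

    # counts follow each peak's template
    n_per = {}
    tmpl_order = []
    for lab in labels:
        n_per[lab] = n_per.get(lab, 0) + 1
    # simulate per-label blocks, then reorder to peak order
    cm_all, truth_all = simulate_counts(
        design,
        templates=templates,
        n_per_template=n_per,
        base_mean_range=base_mean_range,
        dispersion=dispersion,
        seed=int(rng.integers(0, 2**31 - 1)),
        prefix="tmp",
    )
    # map template blocks back onto the peak ordering
    by_label: dict[str, list[str]] = {}
    for fid, lab in truth_all.items():
        by_label.setdefault(lab, []).append(fid)
    cursor = {lab: 0 for lab in by_label}
    rows = []
    for lab in labels:
        rows.append(by_label[lab][cursor[lab]])
        cursor[lab] += 1
    counts = cm_all.counts.loc[rows].copy()
    counts.index = pd.Index(names, name="feature_id")
    peak_cm = CountMatrix(counts, design.sample_table())
    peak_truth = pd.Series(labels, index=counts.index, name="pattern")
    peak_cm.meta = {"truth": peak_truth}  # type: ignore[attr-defined]
    return peaks, peak_cm, truth_linkage


def simulate_cut_profiles(
    design: StudyDesign,
    motif_sets: dict[str, pd.DataFrame],
    flank_rate: float = 8.0,
    interior_fraction: float = 0.25,
    footprint_depth_by_condition: dict[str, dict[str, float]] | None = None,
    flank_scale_by_condition: dict[str, dict[str, float]] | None = None,
    noise: bool = True,
    half_width: int = 200,
    chrom_lengths: dict[str, int] | None = None,
    conditions: tuple[str, ...] | None = None,
    seed: int | None = None,
) -> tuple[dict[str, SignalTrack], pd.DataFrame]:
    """Per-condition cut-count tracks with motif-centred footprints.

    Expected per-base cuts are ``flank_rate`` within ``half_width`` bp of a
    motif occurrence centre and ``flank_rate * f`` inside the motif, where
    ``f`` is the interior fraction for that motif and condition
    (``footprint_depth_by_condition[motif][condition]``, falling back to the
    global ``interior_fraction``).  ``flank_scale_by_condition`` multiplies
    a motif's flank rate in a given condition (models increased local
    accessibility).  With ``noise`` the track is Poisson around this
    expectation; without, it equals it exactly.

    Returns the tracks and a motif x condition table of the planted
    interior fractions (truth).
    """
    if not 0.0 <= interior_fraction <= 1.0:
        raise ValidationError("interior_fraction must lie in [0, 1]")
    if flank_rate <= 0:
        raise ValidationError("flank_rate must be > 0")
    if chrom_lengths is None:
        chrom_lengths = {CONTIG: CONTIG_LENGTH}
    conds = tuple(conditions) if conditions is not None else design.conditions
    depth_map = footprint_depth_by_condition or {}
    flank_map = flank_scale_by_condition or {}

    # validate occurrences: inside contig, not wider than the window, and
    # with non-overlapping +/- half_width neighbourhoods
    windows: list[tuple[str, int, int]] = []
    for motif_id, occ in motif_sets.items():
        for _, row in occ.iterrows():
            w = int(row["end"]) - int(row["start"])
            if w >= 2 * half_width:
                raise ValidationError(
                    f"motif {motif_id}: occurrence wider ({w} bp) than its "
                    f"flanking window ({2 * half_width} bp)"
                )
            c = (int(row["start"]) + int(row["end"])) // 2
            if c - half_width < 0 or c + half_width > chrom_lengths[row["chrom"]]:
                raise ValidationError(f"motif {motif_id}: window exceeds contig")
            windows.append((row["chrom"], c - half_width, c + half_width))
    windows.sort()
    for (c1, s1, e1), (c2, s2, e2) in zip(windows, windows[1:]):
        if c1 == c2 and s2 < e1:
            raise ValidationError("motif windows overlap; place occurrences apart")

    rng = np.random.default_rng(design.seed + 2 if seed is None else seed)
    tracks: dict[str, SignalTrack] = {}
    truth_rows = {}
    for cond in conds:
        values = {c: np.zeros(n, dtype=float) for c, n in chrom_lengths.items()}
        for motif_id, occ in motif_sets.items():
            f = depth_map.get(motif_id, {}).get(cond, interior_fraction)
            rate = flank_rate * flank_map.get(motif_id, {}).get(cond, 1.0)
            truth_rows.setdefault(motif_id, {})[cond] = f
            for _, row in occ.iterrows():
                chrom = row["chrom"]
                s, e = int(row["start"]), int(row["end"])
                c = (s + e) // 2
                arr = values[chrom]
                arr[c - half_width : c + half_width] = rate
                arr[s:e] = rate * f
        if noise:
            for chrom, arr in values.items():
                nz = np.flatnonzero(arr)
                arr[nz] = rng.poisson(arr[nz])
        tracks[cond] = SignalTrack(values)
    truth = pd.DataFrame(truth_rows).T  # motifs x conditions
    truth.index.name = "motif_id"
    return tracks, truth[list(conds)]


@dataclass
class SimulatedDataset:
    """Bundle of all generated artefacts plus their planted truth."""

    design: StudyDesign
    gene_counts: CountMatrix
    gene_truth: pd.Series
    annotation: pd.DataFrame
    peaks: pd.DataFrame
    peak_counts: CountMatrix
    peak_truth: pd.Series
    truth_linkage: pd.DataFrame
    motif_occurrences: pd.DataFrame
    cut_tracks: dict[str, SignalTrack] = field(default_factory=dict)
    truth_footprints: pd.DataFrame | None = None
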