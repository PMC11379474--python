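"""Enhancer kinetic classes, nearest-gene linkage, and class statistics.

Accessibility peaks are classified with the same fold-change and adjusted
p-value cutoffs used for genes: *overshoot* and *recovered* reuse the
pattern E/D rules, *refeeding-activated* means induced at Refed_24h over
Adlib, and genotype classes (*increased*/*decreased*) come from a
wild-type vs knockout contrast.  Each peak is linked to the gene whose
TSS is closest to the peak centre; "a gene has a proximal enhancer of a
class" means it is the nearest gene of at least one such peak (no
distance cap by default).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ValidationError
from .diffexpr import contrast_name
from .quantification import site_centers, window_signal

__all__ = [
    "classify_enhancers",
    "nearest_gene",
    "proximal_enhancer_fraction",
    "compare_proximal_fractions",
    "group_regulation_breakdown",
    "occupancy_at_classes",
]


def _status(calls, key: str) -> pd.Series:
    try:
        obj = calls[key]
    except KeyError:
        raise ValidationError(f"missing contrast {key!r}") from None
    return obj["status"] if isinstance(obj, pd.DataFrame) else obj


def classify_enhancers(
    calls: dict[str, pd.DataFrame | pd.Series],
    adlib: str = "Adlib",
    fasted: str = "Fasted",
    refed_late: str = "Refed_24h",
) -> pd.DataFrame:
    """Kinetic classes from peak regulation calls.

    Returns a DataFrame with boolean columns ``overshoot``, ``recovered``
    and ``refeeding_activated`` plus a ``pattern`` column ("overshoot",
    "recovered" or "none"; mutually exclusive).  Overshoot implies
    refeeding-activated by construction.
    """
    s_fast = _status(calls, contrast_name(adlib, fasted))
    s_late = _status(calls, contrast_name(adlib, refed_late))
    s_fast_vs_late = _status(calls, contrast_name(refed_late, fasted))

    overshoot = (s_fast == "repressed") & (s_late == "induced")
    recovered = (
        (s_fast == "repressed")
        & (s_fast_vs_late == "repressed")
        & (s_late != "induced")
    )
    activated = s_late == "induced"
    pattern = np.where(overshoot, "overshoot", np.where(recovered, "recovered", "none"))
    return pd.DataFrame(
        {
            "overshoot": overshoot,
            "recovered": recovered,
            "refeeding_activated": activated,
            "pattern": pattern,
        },
        index=s_fast.index,
    )


def classify_genotype_response(
    calls: dict[str, pd.DataFrame | pd.Series], wt: str = "WT", ko: str = "DKO"
) -> pd.DataFrame:
    """Increased/decreased/unchanged in the presence of a factor.

    Uses the ``{wt}_vs_{ko}`` contrast: induced means higher with the
    factor present (increased), repressed means decreased.
    """
    s = _status(calls, contrast_name(ko, wt))
    status = s.map(
        {"induced": "increased", "repressed": "decreased", "unchanged": "unchanged"}
    )
    return pd.DataFrame({"status": status}, index=s.index)


def nearest_gene(peaks: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Link every peak to the gene with the closest TSS.

    Distance is ``|peak center - TSS|``; the reported signed distance is
    relative to transcription orientation (negative = upstream of the
    TSS).  Ties break to the lexicographically smaller gene id.  Peaks on
    contigs without genes get gene_id NA and ``assigned=False``.
    """
    results = []
    centers = site_centers(peaks)
    names = (
        peaks["name"].tolist()
        if "name" in peaks.columns
        else [f"pk{i}" for i in range(len(peaks))]
    )
    # sort each contig's genes by (tss, gene_id): within an equal-TSS run
    # the first entry is already the lexicographic tie-winner
    by_chrom: dict[str, pd.DataFrame] = {
        chrom: sub.sort_index().sort_values("tss", kind="stable")
        for chrom, sub in annotation.groupby("chrom", sort=False)
    }
    for pid, chrom, c in zip(names, peaks["chrom"], centers):
        genes = by_chrom.get(chrom)
        if genes is None or len(genes) == 0:
            results.append((pid, pd.NA, np.nan, False))
            continue
        tss = genes["tss"].to_numpy()
        i = int(np.searchsorted(tss, c))
        best = None
        for j in (i - 1, i):
            if not 0 <= j < len(tss):
                continue
            # first index of the equal-TSS run gives the smallest gene id
            j = int(np.searchsorted(tss, tss[j], side="left"))
            key = (abs(int(tss[j]) - int(c)), str(genes.index[j]))
            if best is None or key < best[0]:
                best = (key, j)
        j = best[1]
        gid = genes.index[j]
        signed = int(c) - int(tss[j])
        if genes.loc[gid, "strand"] == "-":
            signed = -signed
        results.append((pid, gid, signed, True))
    return pd.DataFrame(
        results, columns=["peak_id", "gene_id", "distance", "assigned"]
    )


def proximal_enhancer_fraction(
    gene_set, class_peaks, links: pd.DataFrame
) -> dict:
    """Fraction of genes that are the nearest gene of >= 1 class peak."""
    genes = list(gene_set)
    if not genes:
        raise ValidationError("gene set is empty")
    class_peaks = set(class_peaks)
    hit_genes = set(
        links.loc[links["peak_id"].isin(class_peaks), "gene_id"].dropna()
    )
    n_with = sum(g in hit_genes for g in genes)
    return {
        "n_genes": len(genes),
        "n_with_enhancer": n_with,
        "fraction": n_with / len(genes),
    }


def compare_proximal_fractions(
    gene_set_a, gene_set_b, class_peaks, links: pd.DataFrame
) -> dict:
    """Two-set comparison with a two-sided Fisher exact test on the
    (has / has-not enhancer) x (set A / set B) table."""
    fa = proximal_enhancer_fraction(gene_set_a, class_peaks, links)
    fb = proximal_enhancer_fraction(gene_set_b, class_peaks, links)
    table = [
        [fa["n_with_enhancer"], fa["n_genes"] - fa["n_with_enhancer"]],
        [fb["n_with_enhancer"], fb["n_genes"] - fb["n_with_enhancer"]],
    ]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return {"set_a": fa, "set_b": fb, "odds_ratio": float(odds), "pvalue": float(p)}


def group_regulation_breakdown(
    group_members, genotype_calls: pd.DataFrame
) -> pd.DataFrame:
    """Counts and fractions of increased/decreased/unchanged in a group.

    Genes absent from the call table are reported under ``untested``;
    fractions are over tested genes and sum to 1 (all zero, with a
    warning flag in ``.attrs``, when nothing was tested).
    """
    members = list(group_members)
    if not members:
        raise ValidationError("group is empty")
    tested = [g for g in members if g in genotype_calls.index]
    statuses = genotype_calls.loc[tested, "status"] if tested else pd.Series(dtype=object)
    rows = []
    for status in ("increased", "decreased", "unchanged"):
        n = int((statuses == status).sum())
        frac = n / len(tested) if tested else 0.0
        rows.append((status, n, frac))
    out = pd.DataFrame(rows, columns=["status", "count", "fraction"])
    out.attrs["n_untested"] = len(members) - len(tested)
    out.attrs["warning"] = "no tested genes in group" if not tested else ""
    return out


def occupancy_at_classes(
    track,
    classes: dict[str, pd.DataFrame],
    baseline: pd.DataFrame | None = None,
    half_width: int = 200,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Windowed occupancy per enhancer class plus pairwise U tests.

    ``classes`` maps class name to a site table; ``baseline`` (e.g. all
    accessible sites) is added as class ``all_sites`` when given.
    Returns (per-class summary, pairwise Mann-Whitney table).
    """
    all_classes = dict(classes)
    if baseline is not None:
        all_classes["all_sites"] = baseline
    per_site: dict[str, np.ndarray] = {}
    summaries = []
    for name, sites in all_classes.items():
        if len(sites) == 0:
            raise ValidationError(f"class {name!r} is empty")
        sig = window_signal(track, sites, half_width=half_width)
        vals = sig["signal"].to_numpy()
        per_site[name] = vals
        summaries.append(
            (name, len(vals), float(vals.mean()),
             float(np.percentile(vals, 10)), float(np.percentile(vals, 90)))
        )
    summary = pd.DataFrame(
        summaries, columns=["class", "n_sites", "mean", "p10", "p90"]
    )
    tests = []
    names = list(all_classes)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            if np.array_equal(per_site[a], per_site[b]):
                u, p = float("nan"), 1.0
            else:
                res = stats.mannwhitneyu(
                    per_site[a], per_site[b], alternative="two-sided"
                )
                u, p = float(res.statistic), float(res.pvalue)
            tests.append((a, b, u, p))
    return summary, pd.DataFrame(tests, columns=["class_a", "class_b", "U", "pvalue"])
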