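"""Curation filters and group comparisons for lipid-pathway gene lists.

Users supply curated gene groups — LIPO (lipogenesis), CHOL (cholesterol
biosynthesis), AID (shared supporting pathways: acetyl-CoA supply, NADPH
regeneration) or custom lists.  Two filters mirror the curation pipeline:

1. expressed in liver: maximum condition-mean RPKM >= 1 (inclusive);
2. repressed by fasting vs at least one fed state.

Group fold-change comparisons (fasting repression Adlib/Fasted and
refeeding induction Refed_24h/Adlib) are tested between groups with a
two-sided Mann-Whitney U, exact for small groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .containers import ValidationError
from .diffexpr import contrast_name

__all__ = [
    "GeneGroup",
    "FilterReport",
    "load_gene_groups",
    "filter_group",
    "group_fc_comparison",
]


@dataclass(frozen=True)
class GeneGroup:
    name: str
    members: tuple[str, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValidationError(f"group {self.name}: duplicate member ids")


@dataclass
class FilterReport:
    group: str
    n_input: int
    missing_ids: list[str]
    n_failed_expression: int
    n_failed_repression: int
    survivors: list[str] = field(default_factory=list)

    @property
    def n_survivors(self) -> int:
        return len(self.survivors)


def load_gene_groups(path) -> list[GeneGroup]:
    """Read a two-column TSV (gene_id, group); groups may not overlap."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "group"} <= set(df.columns):
        raise ValidationError("group list needs columns gene_id, group")
    seen: dict[str, str] = {}
    for gid, grp in zip(df["gene_id"], df["group"]):
        if gid in seen and seen[gid] != grp:
            raise ValidationError(f"gene {gid} appears in groups {seen[gid]} and {grp}")
        seen[gid] = grp
    return [
        GeneGroup(grp, tuple(sub["gene_id"]), provenance=str(path))
        for grp, sub in df.groupby("group", sort=False)
    ]


def filter_group(
    group: GeneGroup,
    rpkm: pd.DataFrame,
    calls: dict[str, pd.DataFrame | pd.Series],
    condition_of_sample: pd.Series | None = None,
    rpkm_min: float = 1.0,
    fasted: str = "Fasted",
    fed_states: tuple[str, ...] = ("Adlib", "Refed_3h", "Refed_10h", "Refed_24h"),
) -> tuple[GeneGroup, FilterReport]:
    """Apply the expression and fasting-repression filters to one group.

    ``rpkm`` is features x samples; when ``condition_of_sample`` is given,
    per-condition means are taken before the max, otherwise columns are
    treated as conditions directly.  The two predicates are independent,
    so filter order cannot change the result; the report nevertheless
    attributes each exclusion to the first failing step for bookkeeping.
    """
    if not group.members:
        raise ValidationError(f"group {group.name} is empty")
    if condition_of_sample is not None:
        cond_rpkm = rpkm.T.groupby(condition_of_sample, sort=False).mean().T
    else:
        cond_rpkm = rpkm
    present = [g for g in group.members if g in cond_rpkm.index]
    missing = [g for g in group.members if g not in cond_rpkm.index]

    from .patterns import fasting_regulated_universe

    _, repressed_universe = fasting_regulated_universe(
        calls, fasted=fasted, fed_states=fed_states
    )
    repressed = set(repressed_universe)

    expressed = set(
        cond_rpkm.loc[present].max(axis=1).pipe(lambda s: s[s >= rpkm_min]).index
    )
    survivors, fail_expr, fail_rep = [], 0, 0
    for g in present:
        if g not in expressed:
            fail_expr += 1
        elif g not in repressed:
            fail_rep += 1
        else:
            survivors.append(g)
    report = FilterReport(
        group=group.name,
        n_input=len(group.members),
        missing_ids=missing,
        n_failed_expression=fail_expr,
        n_failed_repression=fail_rep,
        survivors=survivors,
    )
    filtered = GeneGroup(group.name, tuple(survivors), group.provenance)
    return filtered, report


def group_fc_comparison(
    groups: list[GeneGroup],
    calls: dict[str, pd.DataFrame],
    adlib: str = "Adlib",
    fasted: str = "Fasted",
    refed_late: str = "Refed_24h",
    min_size: int = 3,
    exact_max_n: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene fasting-repression and refeeding-induction fold changes,
    plus pairwise Mann-Whitney U tests between groups on each axis.

    Fasting repression is reported as Adlib over Fasted (>1 means the gene
    was lower in fasting) and refeeding induction as Refed_24h over Adlib.
    The U test is exact when both groups have at most ``exact_max_n``
    genes; groups smaller than ``min_size`` after filtering are skipped.

    Returns (per-gene FC table, pairwise test table).
    """
    fast_key = contrast_name(adlib, fasted)
    late_key = contrast_name(adlib, refed_late)
    for key in (fast_key, late_key):
        if key not in calls:
            raise ValidationError(f"missing contrast {key!r}")
    usable = [g for g in groups if len(g.members) >= min_size]
    skipped = [g.name for g in groups if len(g.members) < min_size]
    if len(usable) < 2:
        raise ValidationError("need >= 2 groups with enough genes to compare")

    rows = []
    for g in usable:
        for gid in g.members:
            # contrast log2FC is Fasted over Adlib; repression FC flips it
            rep_fc = 2.0 ** (-calls[fast_key].loc[gid, "log2FC"])
            ind_fc = 2.0 ** (calls[late_key].loc[gid, "log2FC"])
            rows.append((g.name, gid, rep_fc, ind_fc))
    fc = pd.DataFrame(
        rows, columns=["group", "gene_id", "fasting_repression_fc", "refeeding_induction_fc"]
    )

    tests = []
    for i in range(len(usable)):
        for j in range(i + 1, len(usable)):
            a, b = usable[i], usable[j]
            for axis in ("fasting_repression_fc", "refeeding_induction_fc"):
                xa = fc.loc[fc["group"] == a.name, axis].to_numpy()
                xb = fc.loc[fc["group"] == b.name, axis].to_numpy()
                method = (
                    "exact"
                    if max(len(xa), len(xb)) <= exact_max_n
                    else "asymptotic"
                )
                res = stats.mannwhitneyu(
                    xa, xb, alternative="two-sided", method=method
                )
                tests.append(
                    (a.name, b.name, axis, method, float(res.statistic), float(res.pvalue))
                )
    test_df = pd.DataFrame(
        tests, columns=["group_a", "group_b", "axis", "method", "U", "pvalue"]
    )
    test_df.attrs["skipped_groups"] = skipped
    return fc, test_df
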