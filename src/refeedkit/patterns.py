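"""Kinetic pattern discovery and rule-based pattern calling.

Two complementary views of the time course:

* unsupervised: k-means over z-scored condition means with a
  one-minus-Pearson-correlation distance (patterns A-C arise as clusters
  of the fasting-induced universe);
* rule-based: explicit fold-change/significance rules over pairwise
  regulation calls define the refeeding patterns

  - D ("recovered"): repressed in fasting vs both ad libitum and late
    refeeding, with no late induction above ad libitum;
  - E ("overshoot"): repressed in fasting and induced above ad libitum
    after 24 h of refeeding;
  - F ("late-induced"): induced at 10 h or 24 h of refeeding but not in
    fasting or at 3 h;
  - G ("early-induced"): induced only at 3 h of refeeding.

Overlaps are resolved by the fixed precedence E > D > G > F, which makes
the taxonomy a partition (E and G, E and D, G and F are already mutually
exclusive by their rules).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ValidationError
from .diffexpr import contrast_name

__all__ = [
    "PATTERN_PRECEDENCE",
    "required_pattern_contrasts",
    "pattern_from_statuses",
    "fasting_regulated_universe",
    "call_refeeding_patterns",
    "cluster_patterns",
    "match_clusters_to_templates",
    "set_overlap",
    "ClusteringResult",
]

PATTERN_PRECEDENCE = ("E", "D", "G", "F")

_STATUSES = ("induced", "repressed", "unchanged")


def _status_series(calls, key: str) -> pd.Series:
    try:
        obj = calls[key]
    except KeyError:
        raise ValidationError(f"missing contrast {key!r}") from None
    if isinstance(obj, pd.DataFrame):
        return obj["status"]
    return obj


def required_pattern_contrasts(
    adlib: str = "Adlib",
    fasted: str = "Fasted",
    refed_early: str = "Refed_3h",
    refed_mid: str = "Refed_10h",
    refed_late: str = "Refed_24h",
) -> list[str]:
    """Contrast keys the rule-based pattern caller consumes, in rule order:
    fasting, early, mid and late refeeding each vs ad libitum, plus
    fasting vs late refeeding."""
    return [
        contrast_name(adlib, fasted),
        contrast_name(adlib, refed_early),
        contrast_name(adlib, refed_mid),
        contrast_name(adlib, refed_late),
        contrast_name(refed_late, fasted),
    ]


def pattern_from_statuses(
    s_fast: str, s_early: str, s_mid: str, s_late: str, s_fast_vs_late: str
) -> str:
    """Apply the D/E/F/G rule table to one gene's five contrast statuses.

    Arguments are the statuses of: fasting vs ad libitum, 3 h / 10 h /
    24 h refeeding vs ad libitum, and fasting vs 24 h refeeding (in that
    contrast "repressed" means fasting below late refeeding).
    """
    is_e = s_fast == "repressed" and s_late == "induced"
    is_d = (
        s_fast == "repressed"
        and s_fast_vs_late == "repressed"
        and s_late != "induced"
    )
    is_g = (
        s_early == "induced"
        and s_fast != "induced"
        and s_mid != "induced"
        and s_late != "induced"
    )
    is_f = (
        (s_mid == "induced" or s_late == "induced")
        and s_fast != "induced"
        and s_early != "induced"
    )
    for label, fired in zip(PATTERN_PRECEDENCE, (is_e, is_d, is_g, is_f)):
        if fired:
            return label
    return "none"


def fasting_regulated_universe(
    calls: dict[str, pd.DataFrame | pd.Series],
    fasted: str = "Fasted",
    fed_states: tuple[str, ...] = ("Adlib", "Refed_3h", "Refed_10h", "Refed_24h"),
) -> tuple[pd.Index, pd.Index]:
    """Fasting-induced and fasting-repressed gene universes.

    A gene is fasting-induced when significantly higher in the fasted
    state than in at least one fed state, fasting-repressed when lower in
    at least one; contrasts are keyed ``{fasted}_vs_{fed}`` so "induced"
    there means fasting above that fed state.  Genes with contradictory
    calls land in both sets (rare; surfaced to the caller).
    """
    statuses = pd.DataFrame(
        {fed: _status_series(calls, contrast_name(fed, fasted)) for fed in fed_states}
    )
    induced = statuses.index[(statuses == "induced").any(axis=1)]
    repressed = statuses.index[(statuses == "repressed").any(axis=1)]
    return induced, repressed


def call_refeeding_patterns(
    calls: dict[str, pd.DataFrame | pd.Series],
    adlib: str = "Adlib",
    fasted: str = "Fasted",
    refed_early: str = "Refed_3h",
    refed_mid: str = "Refed_10h",
    refed_late: str = "Refed_24h",
) -> pd.DataFrame:
    """Rule-based D/E/F/G calls for every feature in the contrast tables.

    Returns a DataFrame with columns ``pattern`` and ``rule_trace`` (the
    five contrast statuses that produced the call, as
    ``contrast=status`` pairs joined by ``;``).
    """
    keys = required_pattern_contrasts(adlib, fasted, refed_early, refed_mid, refed_late)
    status_cols = [_status_series(calls, k) for k in keys]
    statuses = pd.DataFrame(dict(zip(keys, status_cols)))
    if statuses.isna().any().any():
        raise ValidationError("contrast tables cover different feature sets")

    arr = statuses.to_numpy()
    patterns = [pattern_from_statuses(*row) for row in arr]
    trace = [
        ";".join(f"{k}={s}" for k, s in zip(keys, row)) for row in arr
    ]
    return pd.DataFrame(
        {"pattern": patterns, "rule_trace": trace}, index=statuses.index
    )


# ---------------------------------------------------------------------------
# clustering


@dataclass
class ClusteringResult:
    assignments: pd.Series
    centroids: np.ndarray  # k x n_conditions, z-scored space
    k: int
    inertia: float
    excluded: pd.Index
    metric: str = "one minus Pearson correlation"


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    return (x - mu) / sd


def _corr_to_centroids(z: np.ndarray, cent: np.ndarray) -> np.ndarray:
    """Pearson r of each z-scored row against each centroid (rows x k)."""
    zc = _zscore_rows(cent)
    n = z.shape[1]
    return z @ zc.T / n


def cluster_patterns(
    condition_means: pd.DataFrame,
    k: int = 3,
    seed: int = 0,
    restarts: int = 10,
    max_iter: int = 1000,
) -> ClusteringResult:
    """k-means over z-scored condition means, distance 1 - Pearson r.

    Rows with zero variance across conditions carry no shape information
    for a correlation metric and are excluded (reported in ``excluded``).
    The best of ``restarts`` seeded initializations by total within-cluster
    distance is kept; ties go to the lowest restart index.
    """
    x = condition_means.to_numpy(dtype=float)
    var = x.std(axis=1)
    ok = var > 0
    excluded = condition_means.index[~ok]
    z = _zscore_rows(x[ok])
    n = z.shape[0]
    if n < k:
        raise ValidationError(f"need at least k={k} variable features, got {n}")

    best = None
    for r in range(restarts):
        rng = np.random.default_rng(seed + r)
        cent = z[rng.choice(n, size=k, replace=False)]
        labels = np.zeros(n, dtype=int)
        for _ in range(max_iter):
            corr = _corr_to_centroids(z, cent)
            new_labels = np.argmax(corr, axis=1)
            if np.array_equal(new_labels, labels) and _ > 0:
                break
            labels = new_labels
            for j in range(k):
                members = z[labels == j]
                if len(members) == 0:  # re-seed an empty cluster
                    cent[j] = z[rng.integers(0, n)]
                else:
                    cent[j] = members.mean(axis=0)
            cent = _zscore_rows(cent)
        corr = _corr_to_centroids(z, cent)
        inertia = float(np.sum(1.0 - corr[np.arange(n), labels]))
        if best is None or inertia < best[0] - 1e-12:
            best = (inertia, labels.copy(), cent.copy())
    inertia, labels, cent = best
    assignments = pd.Series(labels, index=condition_means.index[ok], name="cluster")
    return ClusteringResult(assignments, cent, k, inertia, excluded)


def match_clusters_to_templates(
    result: ClusteringResult, templates: dict[str, tuple[float, ...]]
) -> dict[int, str]:
    """Label each cluster by the schematic template its centroid best
    correlates with (used to name the A/B/C clusters)."""
    t_ids = list(templates)
    t = _zscore_rows(np.asarray([templates[i] for i in t_ids], dtype=float))
    corr = _corr_to_centroids(result.centroids, t)
    return {j: t_ids[int(np.argmax(corr[j]))] for j in range(result.k)}


def set_overlap(set_x, set_y) -> dict:
    """Venn counts and the fraction of X found in Y."""
    sx, sy = set(set_x), set(set_y)
    inter = sx & sy
    return {
        "n_x": len(sx),
        "n_y": len(sy),
        "n_intersection": len(inter),
        "n_x_only": len(sx - sy),
        "n_y_only": len(sy - sx),
        "fraction_x_in_y": len(inter) / len(sx) if sx else float("nan"),
    }
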