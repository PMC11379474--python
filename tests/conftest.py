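"""Shared fixtures: a small simulated five-condition study."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from refeedkit import diffexpr
from refeedkit.simulate import StudyDesign, simulate_counts

#: contrasts covering the fasting universe and the D-G pattern rules
ALL_PAIRS = [
    ("Adlib", "Fasted"),
    ("Adlib", "Refed_3h"),
    ("Adlib", "Refed_10h"),
    ("Adlib", "Refed_24h"),
    ("Refed_24h", "Fasted"),
    ("Refed_3h", "Fasted"),
    ("Refed_10h", "Fasted"),
]


@pytest.fixture(scope="session")
def design():
    return StudyDesign(seed=17)


@pytest.fixture(scope="session")
def small_sim(design):
    """50 genes per planted pattern plus 200 flat genes, with all the
    regulation-call tables the pattern rules consume."""
    n_per = {lab: 50 for lab in "ABCDEFG"}
    n_per["flat"] = 200
    cm, truth = simulate_counts(design, n_per_template=n_per, seed=17)
    sf = diffexpr.normalize_libraries(cm)
    disp = diffexpr.estimate_dispersion(cm, sf)
    calls = diffexpr.run_contrasts(cm, ALL_PAIRS, sf, disp)
    return {
        "cm": cm,
        "truth": truth,
        "size_factors": sf,
        "dispersions": disp,
        "calls": calls,
    }


def status_frame(feature_ids, statuses) -> pd.DataFrame:
    """Build a minimal regulation-call table from bare statuses."""
    return pd.DataFrame({"status": list(statuses)}, index=pd.Index(feature_ids))


def make_count_matrix(counts: np.ndarray, conditions, lengths=None):
    """CountMatrix from a raw array with <condition>_rep<N> sample names."""
    from refeedkit.containers import CountMatrix

    names, meta = [], []
    for cond, n in conditions:
        for r in range(n):
            names.append(f"{cond}_rep{r + 1}")
            meta.append((cond, r + 1))
    samples = pd.DataFrame(meta, index=names, columns=["condition", "replicate"])
    ids = pd.Index([f"f{i:05d}" for i in range(counts.shape[0])], name="feature_id")
    df = pd.DataFrame(np.asarray(counts, dtype=np.int64), index=ids, columns=names)
    lg = pd.Series(lengths, index=ids) if lengths is not None else None
    return CountMatrix(df, samples, lg)
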