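"""Core in-memory containers shared across the pipeline.

The toolkit works on three kinds of objects: integer count matrices
(genes x samples or peaks x samples), BED-like interval tables held as
:class:`pandas.DataFrame`, and per-base signal tracks (transposase cut
counts or ChIP tag density) held densely per contig.

Coordinates are 0-based half-open throughout (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "SignalTrack",
    "ValidationError",
    "BED_COLUMNS",
    "interval_frame",
]

#: Canonical column order for interval tables (BED6).
BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


def interval_frame(
    chroms, starts, ends, names=None, scores=None, strands=None
) -> pd.DataFrame:
    """Assemble a BED6-like DataFrame with validated half-open intervals."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if np.any(starts >= ends):
        bad = int(np.argmax(starts >= ends))
        raise ValidationError(
            f"interval {bad}: start ({starts[bad]}) must be < end ({ends[bad]})"
        )
    n = len(starts)
    df = pd.DataFrame(
        {
            "chrom": np.broadcast_to(np.asarray(chroms, dtype=object), (n,)).copy()
            if np.ndim(chroms)
            else [chroms] * n,
            "start": starts,
            "end": ends,
            "name": list(names) if names is not None else [f"iv{i}" for i in range(n)],
            "score": list(scores) if scores is not None else [0] * n,
            "strand": list(strands) if strands is not None else ["+"] * n,
        }
    )
    return df[BED_COLUMNS]


@dataclass
class CountMatrix:
    """Integer counts for features (genes or peaks) across labelled samples.

    Parameters
    ----------
    counts
        Features x samples integer DataFrame; the index holds feature ids.
    samples
        Per-sample metadata indexed by sample id with columns
        ``condition`` and ``replicate``.
    lengths
        Optional per-feature lengths in bp (required for RPKM).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValidationError(f"duplicate feature ids: {list(dups[:5])}")
        if not self.counts.columns.equals(self.samples.index):
            if set(self.counts.columns) != set(self.samples.index):
                raise ValidationError("sample ids in counts and metadata disagree")
            self.samples = self.samples.loc[self.counts.columns]
        for col in ("condition", "replicate"):
            if col not in self.samples.columns:
                raise ValidationError(f"sample table lacks '{col}' column")
        vals = self.counts.to_numpy()
        if np.any(vals < 0):
            raise ValidationError("counts must be non-negative")
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.counts.index)

    # -- basic accessors ---------------------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.samples["condition"]:
            seen.setdefault(c, None)
        return list(seen)

    def samples_of(self, condition: str) -> list[str]:
        mask = self.samples["condition"] == condition
        if not mask.any():
            raise KeyError(f"unknown condition label: {condition!r}")
        return list(self.samples.index[mask])

    def normalized(self, size_factors: pd.Series) -> pd.DataFrame:
        """Counts divided column-wise by per-sample size factors."""
        sf = size_factors.reindex(self.counts.columns)
        if sf.isna().any():
            raise ValidationError("size factors missing for some samples")
        return self.counts / sf

    def condition_means(self, size_factors: pd.Series) -> pd.DataFrame:
        """Per-condition mean of normalized counts (features x conditions)."""
        norm = self.normalized(size_factors)
        groups = self.samples["condition"]
        out = norm.T.groupby(groups, sort=False).mean().T
        return out[self.conditions]

    def drop_all_zero(self) -> tuple["CountMatrix", pd.Index]:
        """Remove features with zero counts in every sample.

        Returns the reduced matrix and the index of dropped features.
        """
        keep = self.counts.sum(axis=1) > 0
        dropped = self.counts.index[~keep]
        lengths = self.lengths[keep] if self.lengths is not None else None
        return (
            CountMatrix(self.counts.loc[keep], self.samples.copy(), lengths),
            dropped,
        )

    def subset(self, feature_ids) -> "CountMatrix":
        lengths = (
            self.lengths.loc[feature_ids] if self.lengths is not None else None
        )
        return CountMatrix(self.counts.loc[feature_ids], self.samples.copy(), lengths)


@dataclass
class SignalTrack:
    """Dense per-base signal over one or more contigs.

    ``values`` maps contig name to a float array whose length is the contig
    size.  ``scale_factor`` records the multiplier applied by
    :func:`refeedkit.quantification.scale_track` (1.0 when raw).
    """

    values: dict[str, np.ndarray]
    scale_factor: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, arr in self.values.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 1:
                raise ValidationError(f"track for {chrom} must be 1-D")
            if np.any(arr < 0):
                raise ValidationError(f"track for {chrom} has negative values")
            self.values[chrom] = arr

    @property
    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.values.values()))

    def chrom_length(self, chrom: str) -> int:
        try:
            return len(self.values[chrom])
        except KeyError:
            raise KeyError(f"contig {chrom!r} not in track") from None

    def copy(self) -> "SignalTrack":
        return replace(
            self,
            values={c: v.copy() for c, v in self.values.items()},
            meta=dict(self.meta),
        )
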