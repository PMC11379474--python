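"""Plain-text readers and writers: counts TSV, BED6, bedGraph, annotation TSV.

Sample columns in count TSVs follow the ``<condition>_rep<N>`` dialect, e.g.
``Fasted_rep2``; condition labels themselves may contain underscores
(``Refed_3h_rep1``), so the replicate suffix is parsed from the right.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .containers import BED_COLUMNS, CountMatrix, SignalTrack, ValidationError

__all__ = [
    "sample_name",
    "parse_sample_name",
    "write_counts_tsv",
    "read_counts_tsv",
    "write_annotation_tsv",
    "read_annotation_tsv",
    "write_bed",
    "read_bed",
    "write_bedgraph",
    "read_bedgraph",
]

_REP_RE = re.compile(r"^(?P<cond>.+)_rep(?P<rep>\d+)$")


def sample_name(condition: str, replicate: int) -> str:
    return f"{condition}_rep{replicate}"


def parse_sample_name(name: str) -> tuple[str, int]:
    m = _REP_RE.match(name)
    if m is None:
        raise ValidationError(
            f"sample column {name!r} does not match '<condition>_rep<N>'"
        )
    return m.group("cond"), int(m.group("rep"))


def write_counts_tsv(cm: CountMatrix, path) -> None:
    out = cm.counts.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_counts_tsv(path, lengths: pd.Series | None = None) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="feature_id")
    meta = pd.DataFrame(
        [parse_sample_name(c) for c in df.columns],
        index=df.columns,
        columns=["condition", "replicate"],
    )
    return CountMatrix(df.astype(np.int64), meta, lengths)


def write_annotation_tsv(annotation: pd.DataFrame, path) -> None:
    out = annotation.reset_index() if annotation.index.name == "gene_id" else annotation
    out.to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "tss", "strand", "length_bp"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"annotation lacks columns: {sorted(missing)}")
    return df.set_index("gene_id")


def write_bed(intervals: pd.DataFrame, path) -> None:
    intervals[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(BED_COLUMNS)]
    df.columns = BED_COLUMNS[: df.shape[1]]
    for col, default in (("name", None), ("score", 0), ("strand", "+")):
        if col not in df.columns:
            df[col] = (
                [f"iv{i}" for i in range(len(df))] if default is None else default
            )
    if np.any(df["start"].to_numpy() >= df["end"].to_numpy()):
        raise ValidationError(f"{path}: interval with start >= end")
    return df[BED_COLUMNS]


def write_bedgraph(track: SignalTrack, path) -> None:
    """Write runs of equal value; zero runs are omitted (sparse convention)."""
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            arr = track.values[chrom]
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def _parse_bedgraph(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValidationError(f"{path}:{lineno}: expected 4 columns")
            yield lineno, fields[0], int(fields[1]), int(fields[2]), float(fields[3])


def read_bedgraph(path, chrom_lengths: dict[str, int] | None = None) -> SignalTrack:
    """Read a bedGraph into a dense track.

    Without ``chrom_lengths`` the contig sizes are inferred from the
    largest interval end seen per contig.
    """
    if chrom_lengths is None:
        chrom_lengths = {}
        for _, chrom, _, e, _ in _parse_bedgraph(path):
            chrom_lengths[chrom] = max(chrom_lengths.get(chrom, 0), e)
    values = {c: np.zeros(n, dtype=float) for c, n in chrom_lengths.items()}
    for lineno, chrom, s, e, v in _parse_bedgraph(path):
        if chrom not in values:
            raise ValidationError(f"{path}:{lineno}: unknown contig {chrom!r}")
        values[chrom][s:e] = v
    return SignalTrack(values)
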