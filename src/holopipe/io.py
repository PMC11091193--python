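"""Readers and writers for the pipeline's external formats.

All coordinates are 0-based, half-open. FASTA ids are truncated at the
first whitespace; the remainder is kept as a description. Counts must be
non-negative integers (the negative-binomial model downstream assumes
counts), so non-integer cells are a hard error, never silently rounded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "TranscriptSet",
    "SampleSheet",
    "CountMatrix",
    "read_fasta",
    "write_fasta",
    "read_depth_table",
    "write_depth_table",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_counts",
    "write_counts",
    "write_species_fastas",
    "load_config",
    "save_config",
]

_VALID_BASES = set("ACGTN")

TIMEPOINTS = ["0hpa", "3hpa", "6hpa", "1dpa", "2dpa"]
CONDITIONS = ["control", "runt_rnai", "light_stress", "none"]


@dataclass
class TranscriptSet:
    """An ordered collection of transcript sequences with unique ids."""

    records: list[tuple[str, str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for tid, seq in self.records:
            if tid in seen:
                raise ValueError(f"duplicate transcript id: {tid!r}")
            seen.add(tid)
            if not seq:
                raise ValueError(f"empty sequence for transcript {tid!r}")
            bad = set(seq.upper()) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"transcript {tid!r} contains invalid characters {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def ids(self) -> list[str]:
        return [tid for tid, _ in self.records]

    def lengths(self) -> dict[str, int]:
        return {tid: len(seq) for tid, seq in self.records}

    def sequence(self, tid: str) -> str:
        for t, s in self.records:
            if t == tid:
                return s
        raise KeyError(tid)


@dataclass
class SampleSheet:
    """Per-sample metadata: timepoint, condition and replicate index."""

    table: pd.DataFrame  # columns: sample_id, timepoint, condition, replicate

    def __post_init__(self) -> None:
        required = {"sample_id", "timepoint", "condition", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            dups = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample ids: {sorted(set(dups))}")
        if (self.table["replicate"].astype(int) < 1).any():
            raise ValueError("replicate indices must be >= 1")
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples_where(self, timepoint: str | None = None, condition: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.table.index)
        if timepoint is not None:
            mask &= self.table["timepoint"] == timepoint
        if condition is not None:
            mask &= self.table["condition"] == condition
        return list(self.table.loc[mask, "sample_id"])


@dataclass
class CountMatrix:
    """Transcript x sample integer count matrix tied to a sample sheet."""

    transcript_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # shape (n_transcripts, n_samples), integer
    sheet: SampleSheet

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.transcript_ids), len(self.sample_ids)):
            raise ValueError("count matrix shape does not match ids")
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be integers")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        sheet_ids = set(self.sheet.sample_ids)
        for sid in self.sample_ids:
            if sid not in sheet_ids:
                raise ValueError(f"sample {sid!r} missing from sample sheet")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.transcript_ids, columns=self.sample_ids)

    def subset_transcripts(self, ids: list[str]) -> "CountMatrix":
        index = {t: i for i, t in enumerate(self.transcript_ids)}
        rows = [index[t] for t in ids]
        return CountMatrix(list(ids), self.sample_ids, self.counts[rows, :], self.sheet)

    def subset_samples(self, ids: list[str]) -> "CountMatrix":
        index = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [index[s] for s in ids]
        sub_sheet = SampleSheet(
            self.sheet.table[self.sheet.table["sample_id"].isin(ids)].copy()
        )
        return CountMatrix(self.transcript_ids, list(ids), self.counts[:, cols], sub_sheet)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> TranscriptSet:
    """Read a transcript FASTA; ids are the header up to the first whitespace.

    Sequences are upper-cased. Duplicate ids and empty files are hard errors.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    descriptions: dict[str, str] = {}
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        tid = rec.id
        if tid in seen:
            raise ValueError(f"duplicate transcript id in {path}: {tid!r}")
        seen.add(tid)
        desc = rec.description[len(rec.id):].strip()
        if desc:
            descriptions[tid] = desc
        records.append((tid, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return TranscriptSet(records, descriptions)


def write_fasta(ts: TranscriptSet, path: str | Path, width: int = 70) -> None:
    recs = []
    for tid, seq in ts.records:
        desc = ts.descriptions.get(tid, "")
        recs.append(SeqRecord(Seq(seq), id=tid, description=desc))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def write_species_fastas(
    ts: TranscriptSet,
    calls: pd.DataFrame,
    out_dir: str | Path,
    prefix: str = "transcripts",
) -> dict[str, Path]:
    """Split a transcript set into host / symbiont / ambiguous FASTA files.

    ``calls`` must have columns transcript_id, label and cover every
    transcript exactly once; output record counts always sum to ``len(ts)``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    label_of = dict(zip(calls["transcript_id"], calls["label"]))
    buckets: dict[str, list[tuple[str, str]]] = {"host": [], "symbiont": [], "ambiguous": []}
    for tid, seq in ts.records:
        if tid not in label_of:
            raise ValueError(f"no species call for transcript {tid!r}")
        label = label_of[tid]
        if label not in buckets:
            raise ValueError(f"unknown label {label!r} for transcript {tid!r}")
        buckets[label].append((tid, seq))
    paths: dict[str, Path] = {}
    for label, recs in buckets.items():
        p = out_dir / f"{prefix}.{label}.fasta"
        if recs:
            write_fasta(TranscriptSet(recs), p)
        else:
            p.write_text("")
        paths[label] = p
    return paths


# ---------------------------------------------------------------------------
# Depth tables (per-base pileup-style TSV)

def read_depth_table(path: str | Path, lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Read a per-base depth TSV (transcript_id, pos, depth; pos 0-based).

    Returns a dense non-negative integer array over [0, length) for every
    transcript in ``lengths``; positions absent from the table are 0.
    """
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    required = {"transcript_id", "pos", "depth"}
    if not required.issubset(df.columns):
        raise ValueError(f"depth table must have columns {sorted(required)}")
    if (df["depth"] < 0).any():
        bad = df.loc[df["depth"] < 0].iloc[0]
        raise ValueError(
            f"negative depth {bad['depth']} at {bad['transcript_id']}:{bad['pos']}"
        )
    profiles = {tid: np.zeros(length, dtype=np.int64) for tid, length in lengths.items()}
    for tid, group in df.groupby("transcript_id"):
        if tid not in profiles:
            raise ValueError(f"transcript {tid!r} in depth table but not declared")
        pos = group["pos"].to_numpy(dtype=np.int64)
        if (pos >= len(profiles[tid])).any() or (pos < 0).any():
            raise ValueError(f"position out of range for transcript {tid!r}")
        profiles[tid][pos] = group["depth"].to_numpy(dtype=np.int64)
    return profiles


def write_depth_table(profiles: dict[str, np.ndarray], path: str | Path) -> None:
    """Write dense profiles as a sparse (nonzero positions only) depth TSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for tid in sorted(profiles):
        depth = np.asarray(profiles[tid])
        nz = np.nonzero(depth)[0]
        for p in nz:
            rows.append((tid, int(p), int(depth[p])))
    df = pd.DataFrame(rows, columns=["transcript_id", "pos", "depth"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sample sheets and count matrices

def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "timepoint": str, "condition": str})
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sheet.table.to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path, sheet: SampleSheet) -> CountMatrix:
    """Read a transcript x sample count TSV; columns follow sheet order."""
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    if df.columns[0] != "transcript_id":
        raise ValueError("first column of a counts table must be 'transcript_id'")
    data_cols = list(df.columns[1:])
    sheet_ids = sheet.sample_ids
    extra = set(data_cols) - set(sheet_ids)
    if extra:
        raise ValueError(f"count columns missing from sample sheet: {sorted(extra)}")
    missing = set(sheet_ids) - set(data_cols)
    if missing:
        raise ValueError(f"sample sheet samples missing from counts: {sorted(missing)}")
    values = df[sheet_ids].to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        float_view = np.asarray(values, dtype=float)
        if not np.array_equal(float_view, np.round(float_view)):
            raise ValueError("counts table contains non-integer cells")
        values = float_view.astype(np.int64)
    return CountMatrix(list(df["transcript_id"]), sheet_ids, values.astype(np.int64), sheet)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = cm.to_frame().reset_index().rename(columns={"index": "transcript_id"})
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Run configuration

def _default_config() -> dict:
    from .config import default_run_config

    return default_run_config()


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration; unknown keys are rejected."""
    from .config import validate_config

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return validate_config(cfg)


def save_config(cfg: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True, default_flow_style=False)
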