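"""Species-of-origin assignment of transcripts from dual-enrichment gDNA.

Two genomic DNA libraries — one enriched for the animal host (symbionts
chemically cleared) and one for the algal symbiont (flow-sorted cells) —
are mapped against the mixed transcriptome. Transcripts encoded by one
genome are deep in that partner's enriched sample and shallow in the
other, so gates drawn in the (host depth, symbiont depth) plane separate
the two species; everything near the diagonal stays ambiguous. High-copy
sequences (organellar genomes in particular) are deep in both samples and
land in the ambiguous bucket, where chloroplast annotations can flag them.

Depth is reads mapped to the transcript divided by transcript length;
breadth is the fraction of bases covered by at least one read. GC content
supports the split diagnostically (the two genomes have contrasting GC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import TranscriptSet

__all__ = [
    "GateSpec",
    "compute_enrichment_profiles",
    "fit_auto_gates",
    "classify",
    "flag_chloroplast",
    "gc_separation_report",
]

CHLOROPLAST_GO = {"GO:0009507", "GO:0009535"}


@dataclass
class GateSpec:
    """Gating rule in log10-depth space.

    ``auto`` mode: a transcript is called host when its pseudocounted
    log10(host depth / symbiont depth) is at least ``min_log10_ratio`` AND
    its host-enriched depth is at least ``min_enriched_depth`` (symmetric
    for symbiont). ``manual`` mode reproduces a drawn gate as two
    rectangles in (log10 host depth, log10 symbiont depth).
    """

    mode: str = "auto"  # auto | manual
    pseudocount: float = 0.5  # reads added before length normalization
    min_log10_ratio: float = 1.0
    min_enriched_depth_host: float = 0.0
    min_enriched_depth_symb: float = 0.0
    # manual rectangles: (x_min, x_max, y_min, y_max) in log10 depth space,
    # x = host-enriched, y = symbiont-enriched
    host_box: tuple[float, float, float, float] | None = None
    symbiont_box: tuple[float, float, float, float] | None = None

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "pseudocount": self.pseudocount,
            "min_log10_ratio": self.min_log10_ratio,
            "min_enriched_depth_host": self.min_enriched_depth_host,
            "min_enriched_depth_symb": self.min_enriched_depth_symb,
            "host_box": list(self.host_box) if self.host_box else None,
            "symbiont_box": list(self.symbiont_box) if self.symbiont_box else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GateSpec":
        d = dict(d)
        for key in ("host_box", "symbiont_box"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def compute_enrichment_profiles(
    ts: TranscriptSet,
    reads_host_enr: dict[str, int],
    reads_symb_enr: dict[str, int],
    breadth_host_enr: dict[str, float] | None = None,
    breadth_symb_enr: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Build the per-transcript enrichment table: reads, depth (reads per
    bp), optional breadth, and GC content (computed over non-N bases)."""
    rows = []
    for tid, seq in ts.records:
        if tid not in reads_host_enr or tid not in reads_symb_enr:
            raise ValueError(f"read counts missing for transcript {tid!r}")
        length = len(seq)
        seq_u = seq.upper()
        non_n = sum(seq_u.count(b) for b in "ACGT")
        gc = (seq_u.count("G") + seq_u.count("C")) / non_n if non_n else float("nan")
        rh, rs = int(reads_host_enr[tid]), int(reads_symb_enr[tid])
        rows.append(
            {
                "transcript_id": tid,
                "length": length,
                "reads_host_enr": rh,
                "reads_symb_enr": rs,
                "depth_host_enr": rh / length,
                "depth_symb_enr": rs / length,
                "breadth_host_enr": breadth_host_enr.get(tid, np.nan) if breadth_host_enr else np.nan,
                "breadth_symb_enr": breadth_symb_enr.get(tid, np.nan) if breadth_symb_enr else np.nan,
                "gc": gc,
            }
        )
    extra = (set(reads_host_enr) | set(reads_symb_enr)) - {tid for tid, _ in ts.records}
    if extra:
        raise ValueError(f"read counts for transcripts absent from FASTA: {sorted(extra)[:5]}")
    return pd.DataFrame(rows)


def fit_auto_gates(
    profiles: pd.DataFrame,
    min_enriched_depth: float | None = None,
    min_log10_ratio: float = 1.0,
    pseudocount: float = 0.5,
) -> GateSpec:
    """Derive conservative data-driven gates.

    The depth floor defaults to 0.1x the median depth of the respective
    enriched sample, so the gates rescale with sequencing effort.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 transcripts to fit gates")
    if (profiles["depth_host_enr"] == 0).all() and (profiles["depth_symb_enr"] == 0).all():
        raise ValueError("all depths are zero; cannot fit gates")
    if min_enriched_depth is not None:
        floor_host = floor_symb = float(min_enriched_depth)
    else:
        floor_host = 0.1 * float(profiles["depth_host_enr"].median())
        floor_symb = 0.1 * float(profiles["depth_symb_enr"].median())
    return GateSpec(
        mode="auto",
        pseudocount=pseudocount,
        min_log10_ratio=min_log10_ratio,
        min_enriched_depth_host=floor_host,
        min_enriched_depth_symb=floor_symb,
    )


def _log10_depths(profiles: pd.DataFrame, pseudocount: float) -> tuple[np.ndarray, np.ndarray]:
    lengths = profiles["length"].to_numpy(dtype=float)
    dh = (profiles["reads_host_enr"].to_numpy(dtype=float) + pseudocount) / lengths
    ds = (profiles["reads_symb_enr"].to_numpy(dtype=float) + pseudocount) / lengths
    return np.log10(dh), np.log10(ds)


def classify(profiles: pd.DataFrame, gates: GateSpec) -> pd.DataFrame:
    """Label every transcript host / symbiont / ambiguous.

    Boundary points (ratio exactly at the gate) satisfy the >= rule of one
    region only; anything satisfying neither region — including equal
    depths in both samples — is ambiguous. The output always partitions
    the input: one label per transcript.
    """
    lh, ls = _log10_depths(profiles, gates.pseudocount)
    ratio = lh - ls
    if gates.mode == "auto":
        host = (ratio >= gates.min_log10_ratio) & (
            profiles["depth_host_enr"].to_numpy() >= gates.min_enriched_depth_host
        )
        symb = (-ratio >= gates.min_log10_ratio) & (
            profiles["depth_symb_enr"].to_numpy() >= gates.min_enriched_depth_symb
        )
    elif gates.mode == "manual":
        if gates.host_box is None or gates.symbiont_box is None:
            raise ValueError("manual gates require host_box and symbiont_box")
        hx0, hx1, hy0, hy1 = gates.host_box
        sx0, sx1, sy0, sy1 = gates.symbiont_box
        host = (lh >= hx0) & (lh <= hx1) & (ls >= hy0) & (ls <= hy1)
        symb = (lh >= sx0) & (lh <= sx1) & (ls >= sy0) & (ls <= sy1)
    else:
        raise ValueError(f"unknown gate mode {gates.mode!r}")
    overlap = host & symb
    if overlap.any():  # disjointness invariant: overlapping claims are ambiguous
        host = host & ~overlap
        symb = symb & ~overlap
    label = np.where(host, "host", np.where(symb, "symbiont", "ambiguous"))
    return pd.DataFrame(
        {
            "transcript_id": profiles["transcript_id"].to_numpy(),
            "label": label,
            "chloroplast_flag": False,
            "log10_depth_host_enr": lh,
            "log10_depth_symb_enr": ls,
        }
    )


def flag_chloroplast(
    calls: pd.DataFrame,
    profiles: pd.DataFrame,
    annotation: dict[str, set[str]],
    depth_quantile: float = 0.90,
) -> pd.DataFrame:
    """Flag putative chloroplast transcripts among the ambiguous ones.

    A transcript is flagged iff it is ambiguous, its symbiont-enriched
    depth is at or above the given quantile of all symbiont-enriched
    depths, and its annotation contains a chloroplast cellular-component
    GO term (GO:0009507 or GO:0009535). Host/symbiont-labelled transcripts
    are never flagged.
    """
    calls = calls.copy()
    depth = profiles.set_index("transcript_id")["depth_symb_enr"]
    cutoff = float(depth.quantile(depth_quantile))
    flags = []
    for _, row in calls.iterrows():
        tid = row["transcript_id"]
        go = annotation.get(tid, set())
        flags.append(
            row["label"] == "ambiguous"
            and float(depth.get(tid, 0.0)) >= cutoff
            and bool(CHLOROPLAST_GO & set(go))
        )
    calls["chloroplast_flag"] = flags
    return calls


def gc_separation_report(profiles: pd.DataFrame, calls: pd.DataFrame) -> dict:
    """Per-label GC summaries and a rank-based host-vs-symbiont separation
    statistic (Mann-Whitney U with its common-language effect size)."""
    merged = profiles.merge(calls[["transcript_id", "label"]], on="transcript_id")
    report: dict = {"groups": {}}
    for label, grp in merged.groupby("label"):
        if len(grp) == 0:
            continue
        report["groups"][label] = {
            "n": int(len(grp)),
            "gc_mean": float(grp["gc"].mean()),
            "gc_sd": float(grp["gc"].std(ddof=1)) if len(grp) > 1 else 0.0,
        }
    host_gc = merged.loc[merged["label"] == "host", "gc"]
    symb_gc = merged.loc[merged["label"] == "symbiont", "gc"]
    if len(host_gc) > 0 and len(symb_gc) > 0:
        u, p = stats.mannwhitneyu(host_gc, symb_gc, alternative="two-sided")
        auc = u / (len(host_gc) * len(symb_gc))  # P(host GC > symbiont GC)
        report["separation"] = {"mannwhitney_u": float(u), "p": float(p), "auc": float(auc)}
    return report
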