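"""Coverage-scan trimming of assembled transcripts.

Chimeric joints and poorly supported ends of de novo assembled transcripts
show up as low-coverage flanks in the read pileup. The scan slides a
rolling window (default 10 bp, 1-bp stride) along the per-base depth,
thresholds the window means at a fraction (default 0.33) of the maximum
window mean, and trims both ends outside the first/last passing window.
Interior dips are never removed — only the ends are trimmed. Transcripts
shorter than ``min_len`` (default 300 bp) after trimming are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TrimParams", "TrimResult", "rolling_window_means", "scan_trim", "trim_set"]


@dataclass(frozen=True)
class TrimParams:
    window: int = 10
    frac: float = 0.33
    min_len: int = 300

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if not (0 < self.frac <= 1):
            raise ValueError("frac must be in (0, 1]")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")


@dataclass(frozen=True)
class TrimResult:
    transcript_id: str
    kept: bool
    start: int | None  # 0-based, inclusive
    end: int | None  # 0-based, exclusive
    reason: str  # ok | below_min_len | no_window_passes

    @property
    def retained_length(self) -> int:
        if not self.kept:
            return 0
        return self.end - self.start


def rolling_window_means(depth: np.ndarray, window: int) -> np.ndarray:
    """Means of every length-``window`` interval, 1-bp stride.

    Output entry i is mean(depth[i:i+window]); there are L - window + 1
    entries. Raises if the profile is shorter than the window.
    """
    depth = np.asarray(depth, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > depth.size:
        raise ValueError(f"window {window} exceeds profile length {depth.size}")
    csum = np.concatenate(([0.0], np.cumsum(depth)))
    return (csum[window:] - csum[:-window]) / window


def scan_trim(transcript_id: str, depth: np.ndarray, params: TrimParams = TrimParams()) -> TrimResult:
    """Trim both ends of one coverage profile.

    The threshold is ``frac`` times the maximum window mean; windows whose
    mean is >= the threshold pass (a window at exactly the threshold is
    retained). The retained interval runs from the first passing window's
    start to the last passing window's end.
    """
    depth = np.asarray(depth)
    if depth.size == 0:
        raise ValueError("empty coverage profile")
    if (depth < 0).any():
        raise ValueError("coverage depths must be non-negative")
    if depth.size < params.window:
        return TrimResult(transcript_id, False, None, None, "no_window_passes")
    means = rolling_window_means(depth, params.window)
    threshold = params.frac * means.max()
    passing = np.nonzero(means >= threshold)[0]
    if passing.size == 0:  # unreachable for frac <= 1 but kept as a guard
        return TrimResult(transcript_id, False, None, None, "no_window_passes")
    start = int(passing[0])
    end = int(passing[-1]) + params.window
    if end - start < params.min_len:
        return TrimResult(transcript_id, False, None, None, "below_min_len")
    return TrimResult(transcript_id, True, start, end, "ok")


def trim_set(
    profiles: dict[str, np.ndarray], params: TrimParams = TrimParams()
) -> tuple[list[TrimResult], dict[str, int]]:
    """Trim every profile; returns per-transcript results plus a summary
    (n_kept, n_dropped, bases_trimmed over kept transcripts)."""
    if not profiles:
        raise ValueError("no coverage profiles supplied")
    results = [scan_trim(tid, depth, params) for tid, depth in profiles.items()]
    n_kept = sum(r.kept for r in results)
    bases_trimmed = sum(
        len(profiles[r.transcript_id]) - r.retained_length for r in results if r.kept
    )
    summary = {
        "n_input": len(results),
        "n_kept": n_kept,
        "n_dropped": len(results) - n_kept,
        "bases_trimmed": int(bases_trimmed),
    }
    return results, summary
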