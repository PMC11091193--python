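"""PAM chlorophyll-fluorescence analysis: F_o, F_m, F, F_m' and PSII yields.

A pulse-amplitude-modulation (PAM) fluorometer records chlorophyll
fluorescence under weak detection pulses. After dark adaptation all
functional PSII centers are open and fluorescence sits at its basal level
F_o; a saturating flash transiently closes every center, raising
fluorescence to its maximum F_m. The maximum quantum yield of PSII is

    F_v/F_m = (F_m - F_o) / F_m.

Under actinic (background) light, steady-state fluorescence F and the
flash maximum F_m' give the operating quantum yield

    Y(II) = (F_m' - F) / F_m'.

An alternative arithmetic, (F_m' - F_o)/F_m, circulates in some protocol
write-ups; it is exposed behind ``yii_formula="printed"`` for auditability
but is not the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TraceEvent",
    "FluorescenceTrace",
    "YieldResult",
    "extract_dark_params",
    "compute_fvfm",
    "compute_yii",
    "compute_light_yields",
    "light_curve",
]


@dataclass(frozen=True)
class TraceEvent:
    kind: str  # dark_start | saturating_pulse | actinic_step
    t_start: float
    t_end: float
    par: float | None = None  # photon flux, umol m^-2 s^-1 (actinic steps)


@dataclass
class FluorescenceTrace:
    """Timestamped fluorescence with instrument event annotations."""

    time: np.ndarray  # seconds, strictly increasing
    fluor: np.ndarray  # arbitrary units, >= 0
    events: list[TraceEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.fluor = np.asarray(self.fluor, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.fluor.shape:
            raise ValueError("time and fluor must be 1-D arrays of equal length")
        if self.time.size and (np.diff(self.time) <= 0).any():
            raise ValueError("time must be strictly increasing")
        pulses = sorted(
            (e for e in self.events if e.kind == "saturating_pulse"),
            key=lambda e: e.t_start,
        )
        for a, b in zip(pulses, pulses[1:]):
            if b.t_start < a.t_end:
                raise ValueError("saturating pulses overlap")
        for e in self.events:
            if e.kind == "actinic_step" and e.par is None:
                raise ValueError("actinic_step events must carry a PAR level")

    def window_mean(self, t0: float, t1: float) -> float:
        mask = (self.time >= t0) & (self.time < t1)
        if not mask.any():
            raise ValueError(f"no samples in window [{t0}, {t1})")
        return float(self.fluor[mask].mean())

    def pulses(self) -> list[TraceEvent]:
        return sorted(
            (e for e in self.events if e.kind == "saturating_pulse"),
            key=lambda e: e.t_start,
        )

    def actinic_steps(self) -> list[TraceEvent]:
        return sorted(
            (e for e in self.events if e.kind == "actinic_step"),
            key=lambda e: e.t_start,
        )

    def dark_period(self) -> TraceEvent:
        darks = [e for e in self.events if e.kind == "dark_start"]
        if not darks:
            raise ValueError("trace has no dark period")
        return darks[0]

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        trace = pd.DataFrame({"time_s": self.time, "fluor": self.fluor})
        ev = pd.DataFrame(
            [
                {"kind": e.kind, "t_start": e.t_start, "t_end": e.t_end, "par": e.par}
                for e in self.events
            ]
        )
        return trace, ev

    @classmethod
    def from_frames(cls, trace: pd.DataFrame, events: pd.DataFrame) -> "FluorescenceTrace":
        evs = [
            TraceEvent(
                kind=str(r["kind"]),
                t_start=float(r["t_start"]),
                t_end=float(r["t_end"]),
                par=None if pd.isna(r.get("par")) else float(r["par"]),
            )
            for _, r in events.iterrows()
        ]
        return cls(trace["time_s"].to_numpy(), trace["fluor"].to_numpy(), evs)


@dataclass
class YieldResult:
    Fo: float
    Fm: float
    FvFm: float
    valid: bool
    steps: pd.DataFrame  # columns: par, F_steady, Fm_prime, YII, valid


def _pulse_plateau(trace: FluorescenceTrace, pulse: TraceEvent, central_frac: float) -> float:
    """Mean fluorescence over the central fraction of a pulse, skipping the
    rise and fall edges."""
    width = pulse.t_end - pulse.t_start
    pad = (1.0 - central_frac) / 2.0 * width
    return trace.window_mean(pulse.t_start + pad, pulse.t_end - pad)


def extract_dark_params(
    trace: FluorescenceTrace,
    fo_window_s: float = 10.0,
    plateau_central_frac: float = 0.5,
) -> tuple[float, float, bool]:
    """F_o from the pre-pulse dark window and F_m from the first dark pulse.

    Returns (Fo, Fm, valid); valid is False when Fm <= Fo, which signals a
    failed measurement rather than raising.
    """
    dark = trace.dark_period()
    pulses = [p for p in trace.pulses() if p.t_start >= dark.t_start]
    in_dark = [p for p in pulses if p.t_start <= dark.t_end]
    if not in_dark:
        raise ValueError("no saturating pulse found within/at the dark period")
    first = in_dark[0]
    fo = trace.window_mean(max(dark.t_start, first.t_start - fo_window_s), first.t_start)
    fm = _pulse_plateau(trace, first, plateau_central_frac)
    return fo, fm, fm > fo


def compute_fvfm(fo: float, fm: float) -> tuple[float, bool]:
    """(F_m - F_o)/F_m; flagged invalid (not clipped) outside [0, 1]."""
    if fm <= 0:
        raise ValueError("Fm must be positive")
    value = (fm - fo) / fm
    return value, 0.0 <= value <= 1.0


def compute_yii(f_steady: float, fm_prime: float, fo: float | None = None,
                fm: float | None = None, formula: str = "standard") -> tuple[float, bool]:
    """Operating yield of PSII for one actinic step.

    ``standard``: (Fm' - F)/Fm'. ``printed``: (Fm' - Fo)/Fm, the variant
    that appears verbatim in some protocol texts (requires fo and fm).
    """
    if formula == "standard":
        if fm_prime <= 0:
            raise ValueError("Fm' must be positive")
        value = (fm_prime - f_steady) / fm_prime
    elif formula == "printed":
        if fo is None or fm is None:
            raise ValueError("printed formula requires dark-adapted Fo and Fm")
        if fm <= 0:
            raise ValueError("Fm must be positive")
        value = (fm_prime - fo) / fm
    else:
        raise ValueError(f"unknown YII formula {formula!r}")
    return value, 0.0 <= value <= 1.0


def compute_light_yields(
    trace: FluorescenceTrace,
    steady_window_s: float = 10.0,
    plateau_central_frac: float = 0.5,
    acclimation_s: float = 120.0,
    yii_formula: str = "standard",
    fo: float | None = None,
    fm: float | None = None,
) -> pd.DataFrame:
    """Per actinic step: steady-state F, pulse plateau Fm', and Y(II).

    Only pulses after the step's acclimation window count; earlier pulses
    are excluded (the tissue has not reached steady state yet). With the
    printed-variant formula the dark-adapted Fo/Fm must be supplied.
    """
    rows = []
    for step in trace.actinic_steps():
        pulses = [
            p
            for p in trace.pulses()
            if p.t_start >= step.t_start + acclimation_s and p.t_end <= step.t_end
        ]
        if not pulses:
            continue
        pulse = pulses[0]
        f_steady = trace.window_mean(
            max(step.t_start, pulse.t_start - steady_window_s), pulse.t_start
        )
        fm_prime = _pulse_plateau(trace, pulse, plateau_central_frac)
        yii, valid = compute_yii(f_steady, fm_prime, fo=fo, fm=fm, formula=yii_formula)
        rows.append(
            {
                "par": step.par,
                "F_steady": f_steady,
                "Fm_prime": fm_prime,
                "YII": yii,
                "valid": valid and fm_prime >= f_steady,
            }
        )
    if not rows:
        raise ValueError("no actinic step contained a post-acclimation pulse")
    return pd.DataFrame(rows)


def analyze_trace(
    trace: FluorescenceTrace,
    fo_window_s: float = 10.0,
    plateau_central_frac: float = 0.5,
    steady_window_s: float = 10.0,
    acclimation_s: float = 120.0,
    yii_formula: str = "standard",
) -> YieldResult:
    """Full single-trace analysis: dark parameters, F_v/F_m, then the
    per-step light yields (if any actinic steps are annotated)."""
    fo, fm, dark_valid = extract_dark_params(trace, fo_window_s, plateau_central_frac)
    fvfm, fvfm_valid = compute_fvfm(fo, fm)
    try:
        steps = compute_light_yields(
            trace,
            steady_window_s=steady_window_s,
            plateau_central_frac=plateau_central_frac,
            acclimation_s=acclimation_s,
            yii_formula=yii_formula,
            fo=fo,
            fm=fm,
        )
    except ValueError:
        steps = pd.DataFrame(columns=["par", "F_steady", "Fm_prime", "YII", "valid"])
    return YieldResult(fo, fm, fvfm, dark_valid and fvfm_valid, steps)


def light_curve(yields: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Sort per-step yields by PAR and report Y(II) monotonicity.

    Duplicate PAR levels are averaged (noted in the report). The report
    lists the first offending (PAR, PAR) pair when the curve is not
    non-increasing.
    """
    if len(yields) < 2:
        raise ValueError("light curve needs at least 2 actinic steps")
    notes = []
    if yields["par"].duplicated().any():
        notes.append("duplicate PAR levels averaged")
    curve = (
        yields.groupby("par", as_index=False)["YII"].mean().sort_values("par").reset_index(drop=True)
    )
    yii = curve["YII"].to_numpy()
    par = curve["par"].to_numpy()
    non_increasing = True
    offending = None
    for i in range(len(yii) - 1):
        if yii[i + 1] > yii[i]:
            non_increasing = False
            offending = (float(par[i]), float(par[i + 1]))
            break
    report = {"non_increasing": non_increasing, "offending_pair": offending, "notes": notes}
    return curve, report
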