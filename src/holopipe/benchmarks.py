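"""Standard planted-truth evaluation scenarios.

Each function builds a synthetic dataset with known ground truth, runs
the corresponding pipeline stage, and returns the headline quality
metrics. The same scenarios back the test suite and the reproduction
script, so the numbers reported there are always recomputed from scratch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import CountMatrix, SampleSheet
from .simulate import (
    ExpressionSimConfig,
    HolobiontSimConfig,
    TraceSimConfig,
    gen_counts,
    gen_enrichment_profiles,
    gen_injury_scenario,
    gen_random_block_profiles,
    gen_trace,
    gen_transcriptomes,
)
from .species import classify, fit_auto_gates
from .trim import TrimParams, scan_trim
from . import de as de_mod
from .dependence import DependenceParams, select_dependent, spearman_profile
from .pam import analyze_trace

__all__ = [
    "brute_force_scan_trim",
    "trim_oracle_benchmark",
    "assignment_benchmark",
    "de_type1_benchmark",
    "de_lfc_recovery_benchmark",
    "two_wave_benchmark",
    "dependence_benchmark",
    "pam_recovery_benchmark",
    "pam_injury_benchmark",
]


# ---------------------------------------------------------------------------
# Trimming oracle


def brute_force_scan_trim(depth: np.ndarray, params: TrimParams) -> tuple[bool, int | None, int | None]:
    """Independent O(L*W) re-derivation of the coverage-scan trim: window
    means by explicit re-summation, threshold against the max, first/last
    passing window by linear scan."""
    depth = np.asarray(depth, dtype=float)
    length = depth.size
    if length < params.window:
        return False, None, None
    means = []
    for i in range(length - params.window + 1):
        total = 0.0
        for j in range(i, i + params.window):
            total += depth[j]
        means.append(total / params.window)
    threshold = params.frac * max(means)
    passing = [i for i, m in enumerate(means) if m >= threshold]
    if not passing:
        return False, None, None
    start, end = passing[0], passing[-1] + params.window
    if end - start < params.min_len:
        return False, None, None
    return True, start, end


def trim_oracle_benchmark(seed: int, n_profiles: int = 1000) -> dict:
    """Fraction of random block profiles where scan_trim agrees exactly
    with the brute-force oracle (kept flag and retained interval)."""
    profiles = gen_random_block_profiles(n_profiles, seed=seed, length_range=(50, 5000))
    params = TrimParams()
    agree = 0
    for tid, depth in profiles.items():
        res = scan_trim(tid, depth, params)
        kept, start, end = brute_force_scan_trim(depth, params)
        if res.kept == kept and res.start == start and res.end == end:
            agree += 1
    return {"agreement": agree / n_profiles, "n": n_profiles}


# ---------------------------------------------------------------------------
# Species assignment


def assignment_benchmark(seed: int, enrichment_factor: float = 50.0, n_total: int = 2000) -> dict:
    """Auto-gate classification against planted truth.

    Reports accuracy on non-shared transcripts (label equals the planted
    species) and the fraction of planted shared/organelle-like
    transcripts that land in ambiguous.
    """
    n_shared = max(1, round(0.02 * n_total))
    n_host = round((n_total - n_shared) * 0.625)
    n_symb = n_total - n_shared - n_host
    cfg = HolobiontSimConfig(
        n_host=n_host,
        n_symbiont=n_symb,
        n_shared=n_shared,
        enrichment_factor=enrichment_factor,
        seed=seed,
    )
    ts, truth = gen_transcriptomes(cfg)
    profiles = gen_enrichment_profiles(ts, truth, cfg)
    gates = fit_auto_gates(profiles)
    calls = classify(profiles, gates)
    merged = truth.merge(calls, on="transcript_id")
    non_shared = merged[merged["species"] != "shared"]
    accuracy = float((non_shared["label"] == non_shared["species"]).mean())
    shared = merged[merged["species"] == "shared"]
    shared_ambiguous = float((shared["label"] == "ambiguous").mean()) if len(shared) else 1.0
    ambiguous_frac = float((merged["label"] == "ambiguous").mean())
    return {
        "accuracy_non_shared": accuracy,
        "shared_ambiguous_frac": shared_ambiguous,
        "ambiguous_frac": ambiguous_frac,
        "n": n_total,
    }


# ---------------------------------------------------------------------------
# DE engine calibration


def _two_group_matrix(counts: np.ndarray) -> CountMatrix:
    n = counts.shape[1] // 2
    rows = [
        {
            "sample_id": f"s{j}",
            "timepoint": "0hpa",
            "condition": "control" if j < n else "runt_rnai",
            "replicate": j % n + 1,
        }
        for j in range(counts.shape[1])
    ]
    return CountMatrix(
        [f"g{i:05d}" for i in range(counts.shape[0])],
        [f"s{j}" for j in range(counts.shape[1])],
        counts,
        SampleSheet(pd.DataFrame(rows)),
    )


def de_type1_benchmark(seed: int, n_genes: int = 5000, mean: float = 100.0,
                       dispersion: float = 0.1, n_rep: int = 3) -> dict:
    """Empirical type-I error of the NB Wald test on planted-null genes."""
    rng = np.random.default_rng(seed)
    size = 1.0 / dispersion
    counts = rng.negative_binomial(
        size, size / (size + mean), size=(n_genes, 2 * n_rep)
    ).astype(np.int64)
    cm = _two_group_matrix(counts)
    res = de_mod.run_de(cm, [f"s{j}" for j in range(n_rep)], [f"s{j}" for j in range(n_rep, 2 * n_rep)])
    return {"type1_error": float((res["p"] < 0.05).mean()), "n": n_genes}


def de_lfc_recovery_benchmark(seed: int, n_genes: int = 5000, n_planted: int = 500,
                              mean: float = 100.0, dispersion: float = 0.1) -> dict:
    """Median estimated log2FC for planted 2-fold genes (half up, half
    down, so normalization stays anchored by the null majority)."""
    rng = np.random.default_rng(seed)
    size = 1.0 / dispersion
    half = n_planted // 2
    mu = np.full((n_genes, 6), mean)
    mu[:half, :3] = 2.0 * mean  # 2-fold up in group A
    mu[half:n_planted, :3] = 0.5 * mean  # 2-fold down
    counts = rng.negative_binomial(size, size / (size + mu)).astype(np.int64)
    cm = _two_group_matrix(counts)
    res = de_mod.run_de(cm, [f"s{j}" for j in range(3)], [f"s{j}" for j in range(3, 6)])
    return {
        "median_lfc_up": float(res["log2fc"][:half].median()),
        "median_lfc_down": float(res["log2fc"][half:n_planted].median()),
        "n": n_planted,
    }


# ---------------------------------------------------------------------------
# Two-wave + knockdown reproduction


def _contrast_degs(cm: CountMatrix, tp_a: str, tp_b: str, condition: str,
                   filt: de_mod.DEGFilter) -> tuple[set, set]:
    sheet = cm.sheet
    a = sheet.samples_where(timepoint=tp_a, condition=condition)
    b = sheet.samples_where(timepoint=tp_b, condition=condition)
    res = de_mod.run_de(cm, a, b)
    return de_mod.call_degs(res, filt)


def _f1(called: set, planted: set) -> float:
    tp = len(called & planted)
    if tp == 0:
        return 0.0
    precision = tp / len(called)
    recall = tp / len(planted)
    return 2 * precision * recall / (precision + recall)


def two_wave_benchmark(seed: int, n_genes: int = 2000) -> dict:
    """Recovery of the planted early and late DE waves and the knockdown
    attenuation of both, in the full two-condition time-course design."""
    cfg = ExpressionSimConfig(n_genes=n_genes, n_dependent=0, seed=seed)
    cm, truth = gen_counts(cfg)
    filt = de_mod.DEGFilter()

    early_planted = set(truth.loc[truth["role"].isin(["early", "overlap"]), "gene_id"])
    late_planted = set(truth.loc[truth["role"].isin(["late", "overlap"]), "gene_id"])
    overlap_planted = set(truth.loc[truth["role"] == "overlap", "gene_id"])

    up_e, down_e = _contrast_degs(cm, "3hpa", "0hpa", "control", filt)
    early_called = up_e | down_e
    up_l, down_l = _contrast_degs(cm, "2dpa", "0hpa", "control", filt)
    late_called = up_l | down_l

    # driver and dependent genes legitimately respond at 3 hpa; score the
    # waves on the wave universe only
    wave_universe = set(truth.loc[truth["role"].isin(["early", "late", "overlap", "null"]), "gene_id"])
    early_called_w = early_called & wave_universe
    late_called_w = late_called & wave_universe

    _, _, shared = de_mod.compare_waves(early_called_w, late_called_w)

    up_e_kd, down_e_kd = _contrast_degs(cm, "3hpa", "0hpa", "runt_rnai", filt)
    up_l_kd, down_l_kd = _contrast_degs(cm, "2dpa", "0hpa", "runt_rnai", filt)
    n_control = len(early_called) + len(late_called)
    n_kd = len(up_e_kd | down_e_kd) + len(up_l_kd | down_l_kd)
    reduction = 1.0 - n_kd / n_control if n_control else 0.0

    return {
        "early_f1": _f1(early_called_w, early_planted),
        "late_f1": _f1(late_called_w, late_planted),
        "overlap_jaccard": (
            len(shared & overlap_planted) / len(shared | overlap_planted)
            if (shared | overlap_planted)
            else 1.0
        ),
        "knockdown_deg_reduction": reduction,
        "n_degs_control": n_control,
        "n_degs_knockdown": n_kd,
        "n": n_genes,
    }


# ---------------------------------------------------------------------------
# Dependence selection


def dependence_benchmark(seed: int, n_genes: int = 2000, n_dependent: int = 30) -> dict:
    """Recall/precision of the driver-dependence selector on a planted
    coupling simulation (no wave genes, so the dependent set is the only
    driver-coupled truth)."""
    cfg = ExpressionSimConfig(
        n_genes=n_genes,
        n_early=0,
        n_late=0,
        n_overlap=0,
        n_dependent=n_dependent,
        timepoints=("0hpa", "3hpa"),
        seed=seed,
    )
    cm, truth = gen_counts(cfg)
    params = DependenceParams(driver_id=cfg.driver_id)

    rho = spearman_profile(cm, cfg.driver_id)
    # knockdown-vs-control DE at 3 hpa, control in the numerator
    a = cm.sheet.samples_where(timepoint="3hpa", condition="control")
    b = cm.sheet.samples_where(timepoint="3hpa", condition="runt_rnai")
    de_res = de_mod.run_de(cm, a, b)
    table = select_dependent(rho, de_res, params)

    planted = set(truth.loc[truth["role"] == "dependent", "gene_id"])
    selected = set(table.loc[table["selected"], "transcript_id"]) - {cfg.driver_id}
    tp = len(selected & planted)
    recall = tp / len(planted) if planted else 1.0
    precision = tp / len(selected) if selected else 0.0
    return {"recall": recall, "precision": precision,
            "n_selected": len(selected), "n": n_genes}


# ---------------------------------------------------------------------------
# PAM recovery


def pam_recovery_benchmark(seed_fvfm: int = 3, seed_yii: int = 5) -> dict:
    """Absolute recovery errors of planted F_v/F_m and per-step Y(II) at
    1% multiplicative noise."""
    cfg1 = TraceSimConfig(true_fvfm=0.65, noise_sd=0.01, seed=seed_fvfm)
    res1 = analyze_trace(gen_trace(cfg1))
    fvfm_err = abs(res1.FvFm - cfg1.true_fvfm)

    cfg2 = TraceSimConfig(true_yii=(0.6, 0.45, 0.3, 0.15), noise_sd=0.01, seed=seed_yii)
    res2 = analyze_trace(gen_trace(cfg2))
    yii_err = float(np.max(np.abs(res2.steps["YII"].to_numpy() - np.array(cfg2.true_yii))))
    return {"fvfm_abs_error": float(fvfm_err), "yii_max_abs_error": yii_err,
            "n": int(cfg1.sampling_hz * cfg1.pulse_width_s)}


def pam_injury_benchmark(seed: int) -> dict:
    """Group-level qualitative reproduction of the injury scenario:
    F_v/F_m drops by 3 hpa then plateaus; Y(II) keeps dropping at 24 hpa."""
    traces, _ = gen_injury_scenario(seed=seed)
    fvfm = {}
    yii = {}
    for tp, reps in traces.items():
        results = [analyze_trace(t) for t in reps]
        fvfm[tp] = float(np.mean([r.FvFm for r in results]))
        yii[tp] = float(np.mean([r.steps["YII"].mean() for r in results]))
    pattern_ok = (
        fvfm["3hpa"] < fvfm["0hpa"]
        and abs(fvfm["24hpa"] - fvfm["3hpa"]) < 0.05
        and yii["3hpa"] < yii["0hpa"]
        and yii["24hpa"] < yii["3hpa"]
    )
    return {"fvfm_by_tp": fvfm, "yii_by_tp": yii, "pattern_ok": bool(pattern_ok)}
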