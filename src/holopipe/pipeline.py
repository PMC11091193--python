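"""End-to-end orchestration: simulate -> trim -> assign -> de -> depend
-> pam, from one configuration, with a machine-readable run manifest.

Each stage derives its RNG seed from the global seed and the stage name
(CRC32 of the name, so adding a stage never perturbs the others), writes
plain-text outputs into ``out_dir``, and records SHA-256 digests in the
manifest. Deterministic stages are byte-identical across runs with the
same seed.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import de as de_mod
from .config import validate_config
from .dependence import DependenceParams, select_dependent, spearman_profile
from .io import (
    SampleSheet,
    TranscriptSet,
    read_counts,
    read_depth_table,
    read_fasta,
    read_sample_sheet,
    write_counts,
    write_depth_table,
    write_fasta,
    write_sample_sheet,
    write_species_fastas,
)
from .pam import FluorescenceTrace, analyze_trace, light_curve
from .simulate import (
    ExpressionSimConfig,
    HolobiontSimConfig,
    TraceSimConfig,
    gen_counts,
    gen_coverage_profiles,
    gen_enrichment_profiles,
    gen_trace,
    gen_transcriptomes,
)
from .species import classify, fit_auto_gates, flag_chloroplast, gc_separation_report
from .trim import TrimParams, trim_set

__all__ = ["run_pipeline", "report", "stage_seed"]

STAGES = ["simulate", "trim", "assign", "de", "depend", "pam"]


def stage_seed(seed: int, stage: str) -> int:
    """Fan one global seed out to per-stage substreams by stage-name hash."""
    return (int(seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict | None = None, out_dir: str | Path | None = None) -> dict:
    """Execute all stages in dependency order; returns the manifest.

    Stage failures abort with an error naming the stage; outputs written
    so far stay on disk next to a ``failed`` marker file.
    """
    cfg = validate_config(config or {})
    out = Path(out_dir if out_dir is not None else cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    manifest: dict = {"version": __version__, "seed": seed, "config": cfg, "stages": []}
    artifacts: dict = {}
    for stage in STAGES:
        try:
            files = _STAGE_FUNCS[stage](cfg, out, stage_seed(seed, stage), artifacts)
        except Exception as exc:  # pragma: no cover - error path
            (out / "failed").write_text(f"stage {stage} failed: {exc}\n")
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        manifest["stages"].append(
            {
                "name": stage,
                "outputs": {str(f.relative_to(out)): _sha256(f) for f in sorted(files)},
            }
        )
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# Stages


def _stage_simulate(cfg: dict, out: Path, seed: int, art: dict) -> list[Path]:
    hcfg_d = cfg["simulate"]["holobiont"]
    hcfg = HolobiontSimConfig(
        n_host=hcfg_d["n_host"],
        n_symbiont=hcfg_d["n_symbiont"],
        n_shared=hcfg_d["n_shared"],
        gc_host_mean=hcfg_d["gc_host_mean"],
        gc_symbiont_mean=hcfg_d["gc_symbiont_mean"],
        length_range=(hcfg_d["length_min"], hcfg_d["length_max"]),
        enrichment_factor=hcfg_d["enrichment_factor"],
        base_depth=hcfg_d["base_depth"],
        nb_size=hcfg_d["nb_size"],
        shared_depth_multiplier=hcfg_d["shared_depth_multiplier"],
        seed=seed,
    )
    ts, truth = gen_transcriptomes(hcfg)
    profiles = gen_enrichment_profiles(ts, truth, hcfg)
    coverage = gen_coverage_profiles(ts, seed=seed + 1)

    ccfg_d = cfg["simulate"]["counts"]
    ccfg = ExpressionSimConfig(
        n_genes=ccfg_d["n_genes"],
        n_replicates=ccfg_d["n_replicates"],
        timepoints=tuple(ccfg_d["timepoints"]),
        conditions=tuple(ccfg_d["conditions"]),
        n_early=ccfg_d["n_early"],
        n_late=ccfg_d["n_late"],
        n_overlap=ccfg_d["n_overlap"],
        effect_log2=ccfg_d["effect_log2"],
        driver_effect_log2=ccfg_d["driver_effect_log2"],
        knockdown_factor=ccfg_d["knockdown_factor"],
        n_dependent=ccfg_d["n_dependent"],
        dependent_slope=ccfg_d["dependent_slope"],
        nb_dispersion=ccfg_d["nb_dispersion"],
        mean_expression_log_mu=ccfg_d["mean_expression_log_mu"],
        mean_expression_log_sd=ccfg_d["mean_expression_log_sd"],
        waves_runt_dependent=ccfg_d["waves_runt_dependent"],
        seed=seed + 2,
    )
    cm, counts_truth = gen_counts(ccfg)

    tcfg_d = cfg["simulate"]["trace"]
    tcfg = TraceSimConfig(
        true_fvfm=tcfg_d["true_fvfm"],
        true_yii=tuple(tcfg_d["true_yii"]),
        par_levels=tuple(tcfg_d["par_levels"]),
        f_o=tcfg_d["f_o"],
        dark_duration_s=tcfg_d["dark_duration_s"],
        step_duration_s=tcfg_d["step_duration_s"],
        pulse_width_s=tcfg_d["pulse_width_s"],
        sampling_hz=tcfg_d["sampling_hz"],
        noise_sd=tcfg_d["noise_sd"],
        seed=seed + 3,
    )
    trace = gen_trace(tcfg)

    # chloroplast-like GO annotation for half the shared transcripts
    shared_ids = sorted(truth.loc[truth["species"] == "shared", "transcript_id"])
    annotation = pd.DataFrame(
        {
            "transcript_id": shared_ids,
            "go_ids": ["GO:0009507" if i % 2 == 0 else "" for i in range(len(shared_ids))],
        }
    )

    files = []
    write_fasta(ts, out / "transcripts.fasta")
    truth.to_csv(out / "truth_labels.tsv", sep="\t", index=False)
    profiles.to_csv(out / "enrichment_profiles.tsv", sep="\t", index=False)
    write_depth_table(coverage, out / "depth_table.tsv")
    write_counts(cm, out / "counts.tsv")
    write_sample_sheet(cm.sheet, out / "sample_sheet.tsv")
    counts_truth.to_csv(out / "counts_truth.tsv", sep="\t", index=False)
    trace_df, events_df = trace.to_frames()
    trace_df.to_csv(out / "trace.csv", index=False, float_format="%.6f")
    events_df.to_csv(out / "trace_events.csv", index=False)
    annotation.to_csv(out / "annotation.tsv", sep="\t", index=False)
    files = [
        out / n
        for n in (
            "transcripts.fasta",
            "truth_labels.tsv",
            "enrichment_profiles.tsv",
            "depth_table.tsv",
            "counts.tsv",
            "sample_sheet.tsv",
            "counts_truth.tsv",
            "trace.csv",
            "trace_events.csv",
            "annotation.tsv",
        )
    ]
    art["ts"] = ts
    art["profiles"] = profiles
    art["trace_cfg"] = tcfg
    return files


def _stage_trim(cfg: dict, out: Path, seed: int, art: dict) -> list[Path]:
    ts: TranscriptSet = art.get("ts") or read_fasta(out / "transcripts.fasta")
    coverage = read_depth_table(out / "depth_table.tsv", ts.lengths())
    params = TrimParams(**cfg["trim"])
    results, summary = trim_set(coverage, params)
    rows = [
        {
            "transcript_id": r.transcript_id,
            "kept": r.kept,
            "start": r.start if r.kept else "",
            "end": r.end if r.kept else "",
            "reason": r.reason,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(out / "trim_results.tsv", sep="\t", index=False)
    kept_records = []
    for r in results:
        if r.kept:
            seq = ts.sequence(r.transcript_id)[r.start : r.end]
            kept_records.append((r.transcript_id, seq))
    write_fasta(TranscriptSet(kept_records), out / "transcripts.trimmed.fasta")
    (out / "trim_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return [out / "trim_results.tsv", out / "transcripts.trimmed.fasta", out / "trim_summary.json"]


def _stage_assign(cfg: dict, out: Path, seed: int, art: dict) -> list[Path]:
    ts: TranscriptSet = art.get("ts") or read_fasta(out / "transcripts.fasta")
    profiles = art.get("profiles")
    if profiles is None:
        profiles = pd.read_csv(out / "enrichment_profiles.tsv", sep="\t")
    acfg = cfg["assign"]
    gates = fit_auto_gates(
        profiles,
        min_enriched_depth=acfg["min_enriched_depth"],
        min_log10_ratio=acfg["min_log10_ratio"],
        pseudocount=acfg["pseudocount"],
    )
    calls = classify(profiles, gates)
    annotation_df = pd.read_csv(out / "annotation.tsv", sep="\t").fillna("")
    annotation = {
        r["transcript_id"]: set(filter(None, str(r["go_ids"]).split(",")))
        for _, r in annotation_df.iterrows()
    }
    calls = flag_chloroplast(calls, profiles, annotation, acfg["chloroplast_depth_quantile"])
    calls.to_csv(out / "species_calls.tsv", sep="\t", index=False)
    write_species_fastas(ts, calls, out, prefix="transcripts")
    gc_report = gc_separation_report(profiles, calls)
    (out / "gc_report.json").write_text(json.dumps(gc_report, indent=2, sort_keys=True) + "\n")
    art["calls"] = calls
    return [
        out / "species_calls.tsv",
        out / "transcripts.host.fasta",
        out / "transcripts.symbiont.fasta",
        out / "transcripts.ambiguous.fasta",
        out / "gc_report.json",
    ]


def _default_contrasts(sheet: SampleSheet) -> list[tuple[str, str, str]]:
    """(timepoint_a, timepoint_b, condition) contrasts, later vs baseline."""
    tps = [t for t in sheet.table["timepoint"].unique() if t != "0hpa"]
    conds = list(sheet.table["condition"].unique())
    return [(tp, "0hpa", c) for c in conds for tp in tps]


def _stage_de(cfg: dict, out: Path, seed: int, art: dict) -> list[Path]:
    sheet = read_sample_sheet(out / "sample_sheet.tsv")
    cm = read_counts(out / "counts.tsv", sheet)
    filt = de_mod.DEGFilter(cfg["de"]["lfc_threshold"], cfg["de"]["alpha"])
    w = cfg["de"]["dispersion_shrink_weight"]
    files = []
    deg_summary = {}
    for tp_a, tp_b, cond in _default_contrasts(sheet):
        a = sheet.samples_where(timepoint=tp_a, condition=cond)
        b = sheet.samples_where(timepoint=tp_b, condition=cond)
        if not a or not b:
            continue
        res = de_mod.run_de(cm, a, b, shrink_weight=w)
        name = f"de_{tp_a}_vs_{tp_b}_{cond}"
        path = out / f"{name}.tsv"
        res.to_csv(path, sep="\t", index=False, float_format="%.6g")
        up, down = de_mod.call_degs(res, filt)
        deg_summary[name] = {"n_up": len(up), "n_down": len(down)}
        files.append(path)
        art[name] = res

    # early vs late wave overlap in the control arm
    def degs(name: str) -> set:
        if name not in art:
            return set()
        up, down = de_mod.call_degs(art[name], filt)
        return up | down

    early = degs("de_3hpa_vs_0hpa_control")
    late = degs("de_2dpa_vs_0hpa_control")
    only_e, only_l, shared = de_mod.compare_waves(early, late)
    waves = pd.DataFrame(
        [
            {"set": "early_only", "n": len(only_e), "ids": ",".join(sorted(only_e))},
            {"set": "late_only", "n": len(only_l), "ids": ",".join(sorted(only_l))},
            {"set": "shared", "n": len(shared), "ids": ",".join(sorted(shared))},
        ]
    )
    waves.to_csv(out / "wave_comparison.tsv", sep="\t", index=False)
    (out / "deg_summary.json").write_text(json.dumps(deg_summary, indent=2, sort_keys=True) + "\n")
    files += [out / "wave_comparison.tsv", out / "deg_summary.json"]
    return files


def _stage_depend(cfg: dict, out: Path, seed: int, art: dict) -> list[Path]:
    sheet = read_sample_sheet(out / "sample_sheet.tsv")
    cm = read_counts(out / "counts.tsv", sheet)
    dcfg = cfg["depend"]
    params = DependenceParams(
        driver_id="driver",
        rho_min=dcfg["rho_min"],
        alpha=dcfg["alpha"],
        lfc=dcfg["lfc"],
        absolute_lfc=dcfg["absolute_lfc"],
    )
    rho = spearman_profile(cm, params.driver_id)
    a = sheet.samples_where(timepoint="3hpa", condition="control")
    b = sheet.samples_where(timepoint="3hpa", condition="runt_rnai")
    de_res = de_mod.run_de(cm, a, b, shrink_weight=cfg["de"]["dispersion_shrink_weight"])
    table = select_dependent(rho, de_res, params)
    table.to_csv(out / "dependence.tsv", sep="\t", index=False, float_format="%.6g")
    return [out / "dependence.tsv"]


def _stage_pam(cfg: dict, out: Path, seed: int, art: dict) -> list[Path]:
    trace_df = pd.read_csv(out / "trace.csv")
    events_df = pd.read_csv(out / "trace_events.csv")
    trace = FluorescenceTrace.from_frames(trace_df, events_df)
    pcfg = cfg["pam"]
    result = analyze_trace(
        trace,
        fo_window_s=pcfg["fo_window_s"],
        plateau_central_frac=pcfg["plateau_central_frac"],
        steady_window_s=pcfg["steady_window_s"],
        acclimation_s=pcfg["acclimation_s"],
        yii_formula=pcfg["yii_formula"],
    )
    yields = {
        "Fo": result.Fo,
        "Fm": result.Fm,
        "FvFm": result.FvFm,
        "valid": bool(result.valid),
    }
    (out / "yields.json").write_text(json.dumps(yields, indent=2, sort_keys=True) + "\n")
    result.steps.to_csv(out / "light_steps.tsv", sep="\t", index=False, float_format="%.6g")
    curve, mono = light_curve(result.steps)
    curve.to_csv(out / "light_curve.tsv", sep="\t", index=False, float_format="%.6g")
    (out / "light_curve_report.json").write_text(json.dumps(mono, indent=2, sort_keys=True) + "\n")
    return [
        out / "yields.json",
        out / "light_steps.tsv",
        out / "light_curve.tsv",
        out / "light_curve_report.json",
    ]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "trim": _stage_trim,
    "assign": _stage_assign,
    "de": _stage_de,
    "depend": _stage_depend,
    "pam": _stage_pam,
}


# ---------------------------------------------------------------------------
# Reporting


def report(out_dir: str | Path) -> str:
    """Human-readable run summary; every number is recomputed from the
    stage outputs, and file digests are re-verified against the manifest."""
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    lines = [f"holopipe run summary (seed {manifest['seed']})", ""]

    for stage in manifest["stages"]:
        for rel, digest in stage["outputs"].items():
            path = out / rel
            if not path.exists():
                raise ValueError(f"missing stage output: {rel}")
            if _sha256(path) != digest:
                raise ValueError(f"digest mismatch for {rel}: output was modified after the run")

    trim = pd.read_csv(out / "trim_results.tsv", sep="\t")
    lines.append(
        f"trim: {int(trim['kept'].sum())} kept / {int((~trim['kept']).sum())} dropped"
    )

    calls = pd.read_csv(out / "species_calls.tsv", sep="\t")
    n = len(calls)
    pct = (calls["label"].value_counts() / n * 100).round(1)
    parts = ", ".join(f"{lab} {pct.get(lab, 0.0)}%" for lab in ("host", "symbiont", "ambiguous"))
    lines.append(f"species split (n={n}): {parts} (sum {float(pct.sum()):.1f}%)")
    lines.append(f"chloroplast-flagged: {int(calls['chloroplast_flag'].sum())}")

    degs = json.loads((out / "deg_summary.json").read_text())
    for name, counts in sorted(degs.items()):
        lines.append(f"{name}: {counts['n_up']} up, {counts['n_down']} down")

    dep = pd.read_csv(out / "dependence.tsv", sep="\t")
    lines.append(f"dependence: {int(dep['selected'].sum())} genes selected")

    if (out / "yields.json").exists():
        y = json.loads((out / "yields.json").read_text())
        curve = pd.read_csv(out / "light_curve.tsv", sep="\t")
        lines.append(f"PAM: Fv/Fm = {y['FvFm']:.3f}; Y(II) by PAR: "
                     + ", ".join(f"{r.par:g}:{r.YII:.3f}" for r in curve.itertuples()))
    text = "\n".join(lines) + "\n"
    (out / "summary.txt").write_text(text)
    return text
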