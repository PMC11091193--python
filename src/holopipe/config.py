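"""Run configuration: defaults for every stage and strict validation.

Defaults mirror the study protocol: a 10-bp rolling coverage window with a
0.33-of-maximum threshold and a 300-bp minimum length for trimming; DEG
thresholds |log2FC| >= 0.8 at BH-adjusted p <= 0.05; dependence selection at
rho >= 0.8 or adjusted p <= 0.1 with |log2FC| >= 0.8.
"""

from __future__ import annotations

import copy

__all__ = ["default_run_config", "validate_config"]


def default_run_config() -> dict:
    return {
        "seed": 0,
        "out_dir": "holopipe_run",
        "simulate": {
            "holobiont": {
                "n_host": 1000,
                "n_symbiont": 600,
                "n_shared": 40,
                "gc_host_mean": 0.40,
                "gc_symbiont_mean": 0.58,
                "length_min": 300,
                "length_max": 4000,
                "enrichment_factor": 50.0,
                "base_depth": 300.0,
                "nb_size": 20.0,
                "shared_depth_multiplier": 10.0,
            },
            "counts": {
                "n_genes": 2000,
                "n_replicates": 3,
                "timepoints": ["0hpa", "3hpa", "6hpa", "1dpa", "2dpa"],
                "conditions": ["control", "runt_rnai"],
                "n_early": 60,
                "n_late": 60,
                "n_overlap": 10,
                "effect_log2": 2.0,
                "driver_effect_log2": 2.0,
                "knockdown_factor": 0.2,
                "n_dependent": 30,
                "dependent_slope": 1.0,
                "nb_dispersion": 0.1,
                "mean_expression_log_mu": 5.5,
                "mean_expression_log_sd": 1.0,
                "waves_runt_dependent": True,
            },
            "trace": {
                "true_fvfm": 0.65,
                "true_yii": [0.6, 0.45, 0.3, 0.15],
                "par_levels": [25, 50, 100, 200],
                "dark_duration_s": 1200.0,
                "step_duration_s": 150.0,
                "pulse_width_s": 0.6,
                "sampling_hz": 100.0,
                "noise_sd": 0.01,
                "f_o": 200.0,
            },
        },
        "trim": {"window": 10, "frac": 0.33, "min_len": 300},
        "assign": {
            "mode": "auto",
            "pseudocount": 0.5,
            "min_log10_ratio": 1.0,
            "min_enriched_depth": None,  # None -> 0.1 x median enriched depth
            "chloroplast_depth_quantile": 0.90,
        },
        "de": {
            "lfc_threshold": 0.8,
            "alpha": 0.05,
            "drop_chloroplast": True,
            "dispersion_shrink_weight": 0.1,
        },
        "depend": {
            "rho_min": 0.8,
            "alpha": 0.1,
            "lfc": 0.8,
            "absolute_lfc": False,
        },
        "pam": {
            "yii_formula": "standard",
            "fo_window_s": 10.0,
            "plateau_central_frac": 0.5,
            "steady_window_s": 10.0,
            "acclimation_s": 120.0,
        },
    }


def _check_keys(cfg: dict, defaults: dict, path: str = "") -> None:
    for key, value in cfg.items():
        if key not in defaults:
            raise ValueError(f"unknown config key: {path}{key}")
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            _check_keys(value, defaults[key], path=f"{path}{key}.")


def _merge(defaults: dict, override: dict) -> dict:
    out = copy.deepcopy(defaults)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def validate_config(cfg: dict) -> dict:
    """Merge a partial config onto defaults, rejecting unknown keys and
    out-of-range stage parameters before any stage runs."""
    defaults = default_run_config()
    _check_keys(cfg, defaults)
    merged = _merge(defaults, cfg)

    trim = merged["trim"]
    if trim["window"] < 1:
        raise ValueError("trim.window must be >= 1")
    if not (0 < trim["frac"] <= 1):
        raise ValueError("trim.frac must be in (0, 1]")
    if trim["min_len"] < 1:
        raise ValueError("trim.min_len must be >= 1")
    de = merged["de"]
    if de["lfc_threshold"] < 0:
        raise ValueError("de.lfc_threshold must be >= 0")
    if not (0 < de["alpha"] < 1):
        raise ValueError("de.alpha must be in (0, 1)")
    dep = merged["depend"]
    if not (0 < dep["rho_min"] <= 1):
        raise ValueError("depend.rho_min must be in (0, 1]")
    if not (0 < dep["alpha"] < 1):
        raise ValueError("depend.alpha must be in (0, 1)")
    sim = merged["simulate"]["holobiont"]
    if sim["enrichment_factor"] < 1:
        raise ValueError("simulate.holobiont.enrichment_factor must be >= 1")
    if not (0 < sim["gc_host_mean"] < 1 and 0 < sim["gc_symbiont_mean"] < 1):
        raise ValueError("GC means must be in (0, 1)")
    return merged
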