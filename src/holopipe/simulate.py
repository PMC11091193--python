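"""Synthetic holobiont data with planted ground truth.

Every input the pipeline consumes can be generated here: a mixed-species
transcript FASTA with contrasting GC content, per-transcript read counts
for the two enrichment gDNA samples, per-base coverage profiles with
poorly supported ends, negative-binomial RNA-seq count matrices with two
temporally distinct waves of differential expression plus an
injury-induced driver gene and driver-coupled dependent genes, and PAM
fluorescence traces with planted quantum yields. All generators are
deterministic under their seed and emit machine-readable truth tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix, SampleSheet, TranscriptSet
from .pam import FluorescenceTrace, TraceEvent

__all__ = [
    "HolobiontSimConfig",
    "ExpressionSimConfig",
    "TraceSimConfig",
    "gen_transcriptomes",
    "gen_enrichment_reads",
    "gen_enrichment_profiles",
    "gen_coverage_profiles",
    "gen_random_block_profiles",
    "gen_counts",
    "gen_trace",
    "gen_injury_scenario",
]


# ---------------------------------------------------------------------------
# Transcriptomes and enrichment sequencing


@dataclass
class HolobiontSimConfig:
    """Two transcript populations with contrasting GC plus a minority of
    shared, organelle-like (high copy in both genomes) transcripts."""

    n_host: int = 1000
    n_symbiont: int = 600
    n_shared: int = 40
    gc_host_mean: float = 0.40
    gc_symbiont_mean: float = 0.58
    length_range: tuple[int, int] = (300, 4000)
    enrichment_factor: float = 50.0
    base_depth: float = 300.0  # mean reads per kb in the enriched sample
    nb_size: float = 20.0  # NB size parameter of the gDNA count law
    shared_depth_multiplier: float = 10.0  # high-copy factor, both samples
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_host, self.n_symbiont, self.n_shared) < 0:
            raise ValueError("transcript counts must be >= 0")
        if not (0 < self.gc_host_mean < 1 and 0 < self.gc_symbiont_mean < 1):
            raise ValueError("GC means must be in (0, 1)")
        if self.length_range[0] < 100:
            raise ValueError("minimum transcript length must be >= 100")
        if self.length_range[0] > self.length_range[1]:
            raise ValueError("length_range must be (min, max) with min <= max")
        if self.enrichment_factor < 1:
            raise ValueError("enrichment_factor must be >= 1")


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    is_gc = rng.random(length) < gc
    pick = rng.random(length) < 0.5
    bases = np.where(is_gc, np.where(pick, "G", "C"), np.where(pick, "A", "T"))
    return "".join(bases)


def gen_transcriptomes(cfg: HolobiontSimConfig) -> tuple[TranscriptSet, pd.DataFrame]:
    """Sample host/symbiont/shared transcripts; returns the sequences and a
    truth table (transcript_id, species in {host, symbiont, shared},
    length, gc_target)."""
    rng = np.random.default_rng(cfg.seed)
    records: list[tuple[str, str]] = []
    rows = []
    lo, hi = cfg.length_range
    gc_shared = 0.5 * (cfg.gc_host_mean + cfg.gc_symbiont_mean)
    for species, n, gc in (
        ("host", cfg.n_host, cfg.gc_host_mean),
        ("symbiont", cfg.n_symbiont, cfg.gc_symbiont_mean),
        ("shared", cfg.n_shared, gc_shared),
    ):
        for i in range(n):
            tid = f"{species}_{i:05d}"
            length = int(rng.integers(lo, hi + 1))
            records.append((tid, _random_sequence(rng, length, gc)))
            rows.append(
                {"transcript_id": tid, "species": species, "length": length, "gc_target": gc}
            )
    return TranscriptSet(records), pd.DataFrame(rows)


def gen_enrichment_reads(
    truth: pd.DataFrame, cfg: HolobiontSimConfig
) -> tuple[dict[str, int], dict[str, int]]:
    """Simulate properly-paired read counts per transcript for the
    host-enriched and symbiont-enriched gDNA samples.

    Expected reads scale with length at ``base_depth`` reads/kb in the
    partner's enriched sample and base_depth/enrichment_factor in the
    depleted one; shared transcripts are high copy in both. Counts follow
    a negative binomial with size ``nb_size``.
    """
    if cfg.enrichment_factor < 1:
        raise ValueError("enrichment_factor must be >= 1")
    rng = np.random.default_rng(cfg.seed + 1)
    reads_host: dict[str, int] = {}
    reads_symb: dict[str, int] = {}

    def draw(mean: float) -> int:
        if mean <= 0:
            return 0
        p = cfg.nb_size / (cfg.nb_size + mean)
        return int(rng.negative_binomial(cfg.nb_size, p))

    for _, row in truth.iterrows():
        per_kb = row["length"] / 1000.0
        base = cfg.base_depth * per_kb
        if row["species"] == "host":
            mh, ms = base, base / cfg.enrichment_factor
        elif row["species"] == "symbiont":
            mh, ms = base / cfg.enrichment_factor, base
        else:  # shared / organelle-like: high copy on both sides
            mh = ms = base * cfg.shared_depth_multiplier
        reads_host[row["transcript_id"]] = draw(mh)
        reads_symb[row["transcript_id"]] = draw(ms)
    return reads_host, reads_symb


def gen_enrichment_profiles(
    ts: TranscriptSet, truth: pd.DataFrame, cfg: HolobiontSimConfig
) -> pd.DataFrame:
    """Full synthetic enrichment table (reads, depth, breadth, GC).

    Breadth follows the Lander-Waterman expectation 1 - exp(-depth x read
    length) for 150-bp reads, clipped to [0, 1].
    """
    from .species import compute_enrichment_profiles

    reads_host, reads_symb = gen_enrichment_reads(truth, cfg)
    lengths = ts.lengths()
    breadth_h = {
        t: float(1.0 - np.exp(-150.0 * reads_host[t] / lengths[t])) for t in lengths
    }
    breadth_s = {
        t: float(1.0 - np.exp(-150.0 * reads_symb[t] / lengths[t])) for t in lengths
    }
    return compute_enrichment_profiles(ts, reads_host, reads_symb, breadth_h, breadth_s)


def gen_coverage_profiles(
    ts: TranscriptSet,
    seed: int = 0,
    core_depth: float = 60.0,
    flank_frac_max: float = 0.2,
    flank_depth_ratio: float = 0.1,
    drop_frac: float = 0.05,
) -> dict[str, np.ndarray]:
    """Per-base alignment depth with poorly supported ends.

    Each transcript gets a well-covered core with Poisson noise and two
    low-coverage flanks (chimeric joints and assembly overhangs appear as
    such flanks in real pileups). A ``drop_frac`` minority gets a core
    shorter than is survivable, to exercise the minimum-length filter.
    """
    rng = np.random.default_rng(seed)
    profiles: dict[str, np.ndarray] = {}
    for tid, seq in ts.records:
        length = len(seq)
        if rng.random() < drop_frac:
            core = min(length, int(rng.integers(20, 280)))
        else:
            core = max(1, int(length * (1 - rng.uniform(0, 2 * flank_frac_max))))
        left = int(rng.integers(0, length - core + 1))
        depth = rng.poisson(core_depth * flank_depth_ratio, size=length).astype(np.int64)
        depth[left : left + core] = rng.poisson(core_depth, size=core)
        profiles[tid] = depth
    return profiles


def gen_random_block_profiles(
    n: int, seed: int = 0, length_range: tuple[int, int] = (50, 5000), max_blocks: int = 6
) -> dict[str, np.ndarray]:
    """Random piecewise-constant coverage profiles (for oracle testing):
    1..max_blocks blocks of random length, each at a random depth 0..200."""
    rng = np.random.default_rng(seed)
    profiles: dict[str, np.ndarray] = {}
    for i in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        n_blocks = int(rng.integers(1, max_blocks + 1))
        cuts = np.sort(rng.integers(0, length + 1, size=n_blocks - 1))
        bounds = np.concatenate(([0], cuts, [length]))
        depth = np.zeros(length, dtype=np.int64)
        for b in range(len(bounds) - 1):
            depth[bounds[b] : bounds[b + 1]] = int(rng.integers(0, 201))
        profiles[f"rand_{i:05d}"] = depth
    return profiles


# ---------------------------------------------------------------------------
# Expression counts


@dataclass
class ExpressionSimConfig:
    """Negative-binomial counts with two DE waves, an injury-induced
    driver, and driver-coupled dependent genes.

    The early wave is active at 3 and 6 hpa, the late wave at 2 dpa, and
    ``n_overlap`` genes respond in both. The driver is induced at 3 hpa;
    under the knockdown condition its expression is multiplied by
    ``knockdown_factor`` (the knockdown reduces but never eliminates it).
    When ``waves_runt_dependent`` is set, planted wave effects are
    attenuated by the same factor in knockdown samples. Dependent genes
    follow log-mean = alpha + slope x log(driver mean of that sample).
    """

    n_genes: int = 2000
    n_replicates: int = 3
    timepoints: tuple[str, ...] = ("0hpa", "3hpa", "6hpa", "1dpa", "2dpa")
    conditions: tuple[str, ...] = ("control", "runt_rnai")
    n_early: int = 60
    n_late: int = 60
    n_overlap: int = 10
    effect_log2: float = 2.0
    driver_effect_log2: float = 2.0
    knockdown_factor: float = 0.2
    n_dependent: int = 30
    dependent_slope: float = 1.0
    nb_dispersion: float = 0.1
    mean_expression_log_mu: float = 5.5  # natural-log scale of baseline means
    mean_expression_log_sd: float = 1.0
    min_planted_mean: float = 200.0
    library_size_log_sd: float = 0.1
    waves_runt_dependent: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        n_special = self.n_early + self.n_late + self.n_overlap + self.n_dependent + 1
        if n_special > self.n_genes:
            raise ValueError("planted sets exceed n_genes")
        if not (0 < self.knockdown_factor < 1):
            raise ValueError("knockdown_factor must be in (0, 1)")
        for eff in (self.effect_log2, self.driver_effect_log2):
            if abs(eff) > 10:
                raise ValueError("planted |log2 effect| > 10 is unrealistic")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")

    @property
    def driver_id(self) -> str:
        return "driver"


def _design_sheet(cfg: ExpressionSimConfig) -> SampleSheet:
    rows = []
    for cond in cfg.conditions:
        for tp in cfg.timepoints:
            for rep in range(1, cfg.n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{tp}_{cond}_r{rep}",
                        "timepoint": tp,
                        "condition": cond,
                        "replicate": rep,
                    }
                )
    return SampleSheet(pd.DataFrame(rows))


def gen_counts(cfg: ExpressionSimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate the count matrix; returns it with a per-gene truth table
    (gene_id, role, sign, effect_log2)."""
    rng = np.random.default_rng(cfg.seed)
    sheet = _design_sheet(cfg)
    samples = sheet.table

    roles = ["driver"]
    roles += ["early"] * cfg.n_early + ["late"] * cfg.n_late + ["overlap"] * cfg.n_overlap
    roles += ["dependent"] * cfg.n_dependent
    roles += ["null"] * (cfg.n_genes - len(roles))
    gene_ids = ["driver"] + [f"gene_{i:05d}" for i in range(1, cfg.n_genes)]

    baselines = np.exp(
        rng.normal(cfg.mean_expression_log_mu, cfg.mean_expression_log_sd, cfg.n_genes)
    )
    # planted genes need headroom above the noise floor to be recoverable
    planted = np.array([r != "null" for r in roles])
    baselines[planted] = np.maximum(baselines[planted], cfg.min_planted_mean)

    signs = np.ones(cfg.n_genes)
    wave_idx = [i for i, r in enumerate(roles) if r in ("early", "late", "overlap")]
    for k, i in enumerate(wave_idx):
        signs[i] = 1.0 if k % 2 == 0 else -1.0

    tp = samples["timepoint"].to_numpy()
    cond = samples["condition"].to_numpy()
    n_samples = len(samples)
    is_rnai = cond == "runt_rnai"

    # driver log2 offset per sample: induced at 3 hpa, scaled by the
    # knockdown factor in RNAi animals at every timepoint
    driver_offset = np.where(tp == "3hpa", cfg.driver_effect_log2, 0.0)
    driver_offset = driver_offset + np.where(is_rnai, np.log2(cfg.knockdown_factor), 0.0)

    wave_scale = np.where(is_rnai & cfg.waves_runt_dependent, cfg.knockdown_factor, 1.0)
    early_on = np.isin(tp, ("3hpa", "6hpa")).astype(float)
    late_on = (tp == "2dpa").astype(float)

    log2_mu = np.zeros((cfg.n_genes, n_samples))
    for i, role in enumerate(roles):
        base = np.log2(baselines[i])
        if role == "driver":
            log2_mu[i] = base + driver_offset
        elif role == "early":
            log2_mu[i] = base + signs[i] * cfg.effect_log2 * early_on * wave_scale
        elif role == "late":
            log2_mu[i] = base + signs[i] * cfg.effect_log2 * late_on * wave_scale
        elif role == "overlap":
            log2_mu[i] = base + signs[i] * cfg.effect_log2 * (early_on + late_on) * wave_scale
        elif role == "dependent":
            log2_mu[i] = base + cfg.dependent_slope * driver_offset
        else:
            log2_mu[i] = base

    size_factors = np.exp(rng.normal(0.0, cfg.library_size_log_sd, n_samples))
    mu = (2.0 ** log2_mu) * size_factors[None, :]
    nb_size = 1.0 / cfg.nb_dispersion
    counts = rng.negative_binomial(nb_size, nb_size / (nb_size + mu)).astype(np.int64)

    cm = CountMatrix(gene_ids, list(samples["sample_id"]), counts, sheet)
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "role": roles,
            "sign": signs,
            "effect_log2": [
                cfg.driver_effect_log2
                if r == "driver"
                else (cfg.effect_log2 * s if r in ("early", "late", "overlap") else 0.0)
                for r, s in zip(roles, signs)
            ],
            "baseline_mean": baselines,
        }
    )
    return cm, truth


# ---------------------------------------------------------------------------
# PAM traces


@dataclass
class TraceSimConfig:
    """A dark-adaptation block with one saturating flash, followed by
    stepped actinic light with one flash per step after acclimation.

    Planted yields set the plateaus through F_m = F_o/(1 - FvFm) and
    F_m' = F/(1 - YII); pulses are modelled as instantaneous plateaus
    (only plateau values enter the yield arithmetic). Noise is
    multiplicative Gaussian at ``noise_sd``.
    """

    true_fvfm: float = 0.65
    true_yii: tuple[float, ...] = (0.6, 0.45, 0.3, 0.15)
    par_levels: tuple[float, ...] = (25.0, 50.0, 100.0, 200.0)
    f_o: float = 200.0
    f_steady_rel: float = 1.1  # steady-state F under light, relative to F_o
    dark_duration_s: float = 1200.0  # 20-min dark adaptation
    step_duration_s: float = 150.0
    pulse_width_s: float = 0.6
    inter_block_gap_s: float = 5.0
    sampling_hz: float = 100.0
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        yields = (self.true_fvfm, *self.true_yii)
        if any(not (0.0 <= y < 1.0) for y in yields):
            raise ValueError("planted yields must be in [0, 1); 1 is unphysical")
        if len(self.true_yii) != len(self.par_levels):
            raise ValueError("one PAR level per planted Y(II) value")
        if self.pulse_width_s <= 0 or self.sampling_hz <= 0:
            raise ValueError("pulse width and sampling rate must be positive")


def gen_trace(cfg: TraceSimConfig) -> FluorescenceTrace:
    rng = np.random.default_rng(cfg.seed)
    dt = 1.0 / cfg.sampling_hz
    fm = cfg.f_o / (1.0 - cfg.true_fvfm)
    f_steady = cfg.f_o * cfg.f_steady_rel

    events: list[TraceEvent] = [TraceEvent("dark_start", 0.0, cfg.dark_duration_s)]
    segments: list[tuple[float, float, float]] = [(0.0, cfg.dark_duration_s, cfg.f_o)]
    t = cfg.dark_duration_s
    events.append(TraceEvent("saturating_pulse", t, t + cfg.pulse_width_s))
    segments.append((t, t + cfg.pulse_width_s, fm))
    t += cfg.pulse_width_s + cfg.inter_block_gap_s

    for par, yii in zip(cfg.par_levels, cfg.true_yii):
        step_start = t
        step_end = t + cfg.step_duration_s
        events.append(TraceEvent("actinic_step", step_start, step_end, par=par))
        pulse_start = step_end - cfg.pulse_width_s
        fm_prime = f_steady / (1.0 - yii)
        segments.append((step_start, pulse_start, f_steady))
        segments.append((pulse_start, step_end, fm_prime))
        events.append(TraceEvent("saturating_pulse", pulse_start, step_end))
        t = step_end + cfg.inter_block_gap_s
        segments.append((step_end, t, f_steady))

    total = segments[-1][1]
    time = np.arange(0.0, total, dt)
    fluor = np.full_like(time, cfg.f_o)
    for t0, t1, level in segments:
        fluor[(time >= t0) & (time < t1)] = level
    fluor = fluor * (1.0 + rng.normal(0.0, cfg.noise_sd, size=fluor.size))
    fluor = np.clip(fluor, 0.0, None)
    return FluorescenceTrace(time, fluor, events)


def gen_injury_scenario(
    seed: int = 0, n_replicates: int = 4, noise_sd: float = 0.01
) -> tuple[dict[str, list[FluorescenceTrace]], pd.DataFrame]:
    """Planted post-amputation scenario: F_v/F_m drops by 3 hpa and then
    plateaus, while Y(II) keeps dropping through 24 hpa.

    Returns replicate traces per timepoint plus the planted-truth table.
    """
    planted = {
        "0hpa": {"fvfm": 0.65, "yii": (0.60, 0.45, 0.30, 0.15)},
        "3hpa": {"fvfm": 0.55, "yii": (0.50, 0.37, 0.25, 0.12)},
        "24hpa": {"fvfm": 0.55, "yii": (0.40, 0.28, 0.18, 0.08)},
    }
    traces: dict[str, list[FluorescenceTrace]] = {}
    rows = []
    for k, (tp, vals) in enumerate(planted.items()):
        traces[tp] = []
        for rep in range(n_replicates):
            cfg = TraceSimConfig(
                true_fvfm=vals["fvfm"],
                true_yii=vals["yii"],
                noise_sd=noise_sd,
                seed=seed + 1000 * k + rep,
            )
            traces[tp].append(gen_trace(cfg))
        rows.append(
            {"timepoint": tp, "true_fvfm": vals["fvfm"], "true_yii": list(vals["yii"])}
        )
    return traces, pd.DataFrame(rows)
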