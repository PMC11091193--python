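"""Driver-dependence selection: which genes track the injury-induced
transcription factor.

Because RNAi reduces but does not eliminate the driver's expression, the
residual variation in driver levels across samples carries information:
genes whose expression rises and falls with the driver are candidate
members of its downstream program. The selector combines two routes —
significant differential expression in the knockdown-vs-control contrast
at the early timepoint, or strong positive Spearman correlation with the
driver's normalized expression — and keeps a gene if either fires
(thresholds inclusive: adjusted p <= 0.1 with |log2FC| >= 0.8, or
rho >= 0.8).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix
from .de import median_of_ratios_size_factors

__all__ = ["DependenceParams", "spearman_profile", "select_dependent"]


@dataclass(frozen=True)
class DependenceParams:
    """Selection thresholds.

    The default DE route is directional: the selector targets genes
    *activated* by the driver's program, so a gene qualifies when it is
    downregulated in the knockdown (log2FC >= +lfc with control in the
    numerator), matching the positive-correlation route's orientation.
    ``absolute_lfc=True`` switches to a sign-agnostic |log2FC| reading.
    """

    driver_id: str
    rho_min: float = 0.8
    alpha: float = 0.1
    lfc: float = 0.8
    absolute_lfc: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.rho_min <= 1):
            raise ValueError("rho_min must be in (0, 1]")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


def spearman_profile(
    cm: CountMatrix, driver_id: str, scope: list[str] | None = None
) -> pd.Series:
    """Spearman rho of every gene against the driver, on size-factor
    normalized counts over the ``scope`` samples (default: all samples of
    the matrix, i.e. the pooled knockdown experiment).

    Ties get average ranks. Genes with zero rank variance (constant
    expression) are reported as NaN and never selected by the rho route.
    """
    if driver_id not in cm.transcript_ids:
        raise ValueError(f"driver {driver_id!r} not in count matrix")
    if scope is None:
        scope = list(cm.sample_ids)
    if len(scope) < 3:
        raise ValueError("need at least 3 samples for a correlation")
    sub = cm.subset_samples(scope)
    factors = median_of_ratios_size_factors(sub.counts)
    y = sub.counts / factors[None, :]
    i_driver = sub.transcript_ids.index(driver_id)
    driver = y[i_driver]
    if np.unique(driver).size < 2:
        raise ValueError("driver expression is constant across the scope")

    driver_ranks = stats.rankdata(driver)
    ranks = stats.rankdata(y, axis=1)
    dr = driver_ranks - driver_ranks.mean()
    gr = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.sqrt((gr**2).sum(axis=1) * (dr**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(denom > 0, (gr * dr).sum(axis=1) / denom, np.nan)
    return pd.Series(rho, index=sub.transcript_ids, name="rho")


def select_dependent(
    rho: pd.Series, de_results: pd.DataFrame, params: DependenceParams
) -> pd.DataFrame:
    """Apply the OR rule and record each gene's selection route.

    ``de_results`` must come from the knockdown-vs-control contrast at the
    early timepoint (numerator = control under the default orientation so
    that "downregulated in knockdown" has positive log2FC; with the
    default |log2FC| reading the orientation does not matter).
    """
    de = de_results.set_index("transcript_id")
    rows = []
    de_route_available = True
    if params.driver_id not in de.index:
        import warnings

        warnings.warn(
            f"driver {params.driver_id!r} absent from DE results; DE route disabled",
            stacklevel=2,
        )
        de_route_available = False
    for gene in rho.index:
        r = rho[gene]
        by_rho = bool(np.isfinite(r) and r >= params.rho_min)
        by_de = False
        if de_route_available and gene in de.index:
            row = de.loc[gene]
            sig = pd.notna(row["p_adj"]) and row["p_adj"] <= params.alpha
            if params.absolute_lfc:
                strong = abs(row["log2fc"]) >= params.lfc
            else:
                # downregulated in knockdown: log2FC >= +lfc, control numerator
                strong = row["log2fc"] >= params.lfc
            by_de = bool(sig and strong)
        route = {
            (True, True): "both",
            (True, False): "by_de",
            (False, True): "by_rho",
            (False, False): "none",
        }[(by_de, by_rho)]
        rows.append(
            {
                "transcript_id": gene,
                "rho": r,
                "de_flag": by_de,
                "selected": by_de or by_rho,
                "selection_route": route,
            }
        )
    return pd.DataFrame(rows)
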