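"""Titer estimation and plaque-assay arithmetic.

Plaque counts from a dilution series are modelled as Poisson draws with
mean C * V * 10^-d (sample concentration C in PFU/mL, plated volume V in
mL, decimal dilution exponent d).  Pooling counts over plates gives the
maximum-likelihood titer (sum of counts over summed effective volumes) and
an exact Poisson (Garwood) confidence interval on the pooled count, scaled
by the effective volume.  The module also implements the small pieces of
assay arithmetic used around enumeration: multiplicity of infection,
dilution to a final concentration, percent unadsorbed phage, and the
site-by-class abundance table.

All volumes are mL and all concentrations PFU/mL (or CFU/mL for cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountObservation",
    "TiterEstimate",
    "garwood_interval",
    "titer_from_counts",
    "moi",
    "final_concentration",
    "percent_unadsorbed",
    "abundance_table",
]


@dataclass(frozen=True)
class CountObservation:
    """One plate's plaque count with its plating parameters."""

    count: int
    plated_volume_ml: float
    dilution_exponent: int
    phage_class: str = ""
    sample: str = ""
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if self.plated_volume_ml <= 0:
            raise ValueError("plated volume must be positive")

    @property
    def effective_volume_ml(self) -> float:
        """Volume of the undiluted sample represented by this plate."""
        return self.plated_volume_ml * 10.0 ** (-self.dilution_exponent)


@dataclass
class TiterEstimate:
    """Pooled titer with its exact Poisson confidence interval (PFU/mL)."""

    titer: float
    ci_lower: float
    ci_upper: float
    alpha: float
    effective_volume_ml: float
    total_count: int
    countable_filter_applied: bool = True

    def __post_init__(self) -> None:
        if not (self.ci_lower <= self.titer <= self.ci_upper):
            raise ValueError("confidence interval must bracket the point estimate")

    def covers(self, truth: float) -> bool:
        return self.ci_lower <= truth <= self.ci_upper


def garwood_interval(count: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Garwood) 1-alpha confidence interval for a Poisson mean given
    one observed count, via chi-square quantiles.

    lower = chi2(alpha/2, 2c)/2 (0 when c=0); upper = chi2(1-alpha/2, 2c+2)/2.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    lower = 0.0 if count == 0 else stats.chi2.ppf(alpha / 2, 2 * count) / 2.0
    upper = stats.chi2.ppf(1 - alpha / 2, 2 * count + 2) / 2.0
    return float(lower), float(upper)


def titer_from_counts(
    observations: Sequence[CountObservation],
    alpha: float = 0.05,
    countable_range: tuple[int, int] | None = (3, 300),
) -> TiterEstimate:
    """Pooled maximum-likelihood titer with an exact Poisson CI.

    T = (sum of counts) / (sum of effective volumes); the Garwood interval
    on the pooled count is divided by the same effective volume.  With a
    ``countable_range``, plates outside the countable window (default
    3-300 plaques) are excluded; if no plate qualifies, all are used and
    the estimate is flagged (``countable_filter_applied=False``).
    """
    observations = list(observations)
    if not observations:
        raise ValueError("need at least one observation")
    used = observations
    filtered = True
    if countable_range is not None:
        lo, hi = countable_range
        qualifying = [o for o in observations if lo <= o.count <= hi]
        if qualifying:
            used = qualifying
        else:
            filtered = False
    total = int(sum(o.count for o in used))
    volume = float(sum(o.effective_volume_ml for o in used))
    lower, upper = garwood_interval(total, alpha)
    return TiterEstimate(
        titer=total / volume,
        ci_lower=lower / volume,
        ci_upper=upper / volume,
        alpha=alpha,
        effective_volume_ml=volume,
        total_count=total,
        countable_filter_applied=filtered,
    )


def moi(
    phage_volume_ml: float,
    phage_concentration: float,
    cell_volume_ml: float,
    cell_concentration: float,
) -> float:
    """Multiplicity of infection: infectious phage per bacterial cell at
    mixing, (V_phage * C_phage) / (V_cell * C_cell)."""
    for name, v in (
        ("phage volume", phage_volume_ml),
        ("phage concentration", phage_concentration),
        ("cell volume", cell_volume_ml),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    if cell_concentration <= 0:
        raise ValueError("cell concentration must be positive (no cells, no MOI)")
    return (phage_volume_ml * phage_concentration) / (cell_volume_ml * cell_concentration)


def final_concentration(
    stock_pfu_per_ml: float, stock_volume_ml: float, total_volume_ml: float
) -> float:
    """Concentration after diluting ``stock_volume_ml`` of stock into
    ``total_volume_ml`` total."""
    if stock_volume_ml <= 0:
        raise ValueError("stock volume must be positive")
    if stock_volume_ml > total_volume_ml:
        raise ValueError("stock volume cannot exceed the total volume")
    return stock_pfu_per_ml * stock_volume_ml / total_volume_ml


def percent_unadsorbed(
    filtrate_titers: Iterable[float], control_titers: Iterable[float]
) -> float:
    """Free phage after adsorption, as a percent of the cell-free control:
    100 * mean(filtrate titers) / mean(control titers)."""
    filtrate = np.asarray(list(filtrate_titers), dtype=float)
    control = np.asarray(list(control_titers), dtype=float)
    if control.size == 0:
        raise ValueError("need at least one cell-free control titer")
    if filtrate.size == 0:
        raise ValueError("need at least one filtrate titer")
    control_mean = control.mean()
    if control_mean <= 0:
        raise ValueError("control mean titer must be positive")
    return float(100.0 * filtrate.mean() / control_mean)


def abundance_table(
    records: Sequence[tuple[str, str, int, TiterEstimate]]
) -> pd.DataFrame:
    """Summarize per-replicate titer estimates into one row per (site, class).

    ``records`` are (site, phage_class, replicate, estimate) tuples.  Each
    output row carries the pooled point estimate (total counts over total
    effective volume across replicates), the pooled Garwood CI, and the
    standard deviation of the per-replicate point estimates.  Row order
    follows first appearance in the input.  Duplicate
    (site, class, replicate) keys are an error.
    """
    if not records:
        raise ValueError("no estimates supplied")
    seen: set[tuple[str, str, int]] = set()
    groups: dict[tuple[str, str], list[TiterEstimate]] = {}
    order: list[tuple[str, str]] = []
    alpha = records[0][3].alpha
    for site, cls, replicate, est in records:
        key = (site, cls, replicate)
        if key in seen:
            raise ValueError(f"duplicate (site, class, replicate) key: {key}")
        seen.add(key)
        gkey = (site, cls)
        if gkey not in groups:
            groups[gkey] = []
            order.append(gkey)
        groups[gkey].append(est)
    rows = []
    for site, cls in order:
        ests = groups[(site, cls)]
        total = sum(e.total_count for e in ests)
        volume = sum(e.effective_volume_ml for e in ests)
        lower, upper = garwood_interval(total, alpha)
        points = [e.titer for e in ests]
        rows.append(
            {
                "site": site,
                "class": cls,
                "n_replicates": len(ests),
                "titer_pfu_per_ml": total / volume,
                "ci_lower": lower / volume,
                "ci_upper": upper / volume,
                "replicate_sd": float(np.std(points, ddof=1)) if len(points) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)
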