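"""Per-metabolite tracer and level quantities.

Covers the headline read-outs of a ¹³C tracing study: total carbon
contribution of a tracer to a metabolite pool, metabolite levels normalized
to an internal standard and biomass (protein in vitro, tissue weight in
vivo), ratio metrics such as NADPH/NADP⁺, folds relative to a control
group, media-based uptake/secretion rates, and the blood-enrichment QC used
to confirm comparable tracer delivery across infused animals.

Total contribution of carbon for a metabolite with n tracer-accessible
carbons and corrected MID m0..mn is

    TC = Σᵢ i·mᵢ / (n · Σᵢ mᵢ)

i.e. the weighted-average fraction of labeled carbons; it equals the
labeled-molecule fraction f exactly for both binomial-mixture and two-pool
labeling states.

Sign convention for exchange rates: uptake (net consumption from media) is
positive, secretion negative, package-wide.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .isotope_correction import CorrectedMID

__all__ = [
    "EnrichmentQC",
    "ExchangeRate",
    "NormalizedLevel",
    "TotalContribution",
    "enrichment_qc",
    "exchange_rate",
    "normalized_level",
    "ratio_metric",
    "relative_to_control",
    "total_contribution",
]


@dataclasses.dataclass(frozen=True)
class TotalContribution:
    """Fraction of a metabolite's carbons derived from the labeled tracer."""

    metabolite: str
    value: float

    def __post_init__(self) -> None:
        if not -1e-12 <= self.value <= 1 + 1e-12:
            raise ValueError(f"{self.metabolite}: total contribution {self.value} outside [0, 1]")
        object.__setattr__(self, "value", float(min(max(self.value, 0.0), 1.0)))


@dataclasses.dataclass(frozen=True)
class NormalizedLevel:
    """Metabolite level = area / internal-standard area / biomass (mg)."""

    metabolite: str
    value: float
    denominator: str = "protein"  # "protein" (mg protein) or "tissue" (mg wet tissue)

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"{self.metabolite}: negative level")
        if self.denominator not in ("protein", "tissue"):
            raise ValueError(f"{self.metabolite}: unknown denominator {self.denominator!r}")


@dataclasses.dataclass(frozen=True)
class ExchangeRate:
    """Net media exchange in nmol per mg biomass per h; uptake positive."""

    metabolite: str
    value: float


@dataclasses.dataclass(frozen=True)
class EnrichmentQC:
    """Dispersion summary of reference-compartment enrichment across subjects."""

    cv: float
    passed: bool
    threshold: float


def total_contribution(mid: CorrectedMID | np.ndarray, n: int, metabolite: str = "") -> TotalContribution:
    """Weighted-average labeled-carbon fraction of a corrected MID.

    ``value = Σᵢ i·mᵢ / (n · Σᵢ mᵢ)`` with mᵢ the abundance of mass
    isotopomer M+i and n the number of tracer-accessible carbons.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if isinstance(mid, CorrectedMID):
        metabolite = metabolite or mid.metabolite
        fractions = mid.fractions
    else:
        fractions = np.asarray(mid, dtype=float)
    if len(fractions) != n + 1:
        raise ValueError(f"MID length {len(fractions)} != n+1 = {n + 1}")
    total = float(fractions.sum())
    if total <= 0:
        raise ValueError("MID sums to zero")
    value = float(np.arange(n + 1) @ fractions) / (n * total)
    return TotalContribution(metabolite, value)


def normalized_level(
    area: float,
    istd_area: float,
    biomass_mg: float,
    metabolite: str = "",
    denominator: str = "protein",
) -> NormalizedLevel:
    """Area normalized to an internal standard and protein content or tissue weight."""
    if istd_area <= 0:
        raise ValueError(f"{metabolite}: internal-standard area must be > 0, got {istd_area}")
    if biomass_mg <= 0:
        raise ValueError(f"{metabolite}: biomass must be > 0, got {biomass_mg}")
    if area < 0:
        raise ValueError(f"{metabolite}: negative area {area}")
    return NormalizedLevel(metabolite, area / istd_area / biomass_mg, denominator)


def ratio_metric(level_a: NormalizedLevel, level_b: NormalizedLevel) -> float:
    """Ratio of two normalized levels sharing denominators (e.g. NADPH/NADP⁺)."""
    if level_a.denominator != level_b.denominator:
        raise ValueError(
            f"cannot ratio levels with different denominators "
            f"({level_a.denominator} vs {level_b.denominator})"
        )
    if level_b.value <= 0:
        raise ValueError(f"{level_b.metabolite}: zero denominator level")
    return level_a.value / level_b.value


def relative_to_control(
    levels: pd.Series, groups: pd.Series, control_group: str
) -> pd.Series:
    """Fold of each sample's level over the control-group mean.

    The mean of the transformed control group is 1 by construction.
    """
    control = levels[groups == control_group]
    if len(control) == 0:
        raise ValueError(f"control group {control_group!r} is empty")
    mean = float(control.mean())
    if mean == 0:
        raise ValueError(f"control group {control_group!r} has zero mean level")
    return levels / mean


def exchange_rate(
    conc_fresh_uM: float,
    conc_spent_uM: float,
    volume_ml: float,
    span_h: float,
    biomass_mg: float,
    metabolite: str = "",
) -> ExchangeRate:
    """Net uptake(+)/secretion(−) rate from fresh vs spent media concentrations.

    ``value = (conc_fresh − conc_spent) · volume / (biomass · span)`` in
    nmol·mg⁻¹·h⁻¹ (1 µM × 1 ml = 1 nmol).
    """
    for name, val in (("conc_fresh_uM", conc_fresh_uM), ("conc_spent_uM", conc_spent_uM)):
        if val < 0:
            raise ValueError(f"{metabolite}: {name} must be >= 0, got {val}")
    if volume_ml <= 0 or span_h <= 0 or biomass_mg <= 0:
        raise ValueError(f"{metabolite}: volume, span and biomass must be > 0")
    value = (conc_fresh_uM - conc_spent_uM) * volume_ml / (biomass_mg * span_h)
    return ExchangeRate(metabolite, value)


def enrichment_qc(contributions, threshold: float = 0.10) -> EnrichmentQC:
    """Check that reference-compartment (e.g. blood) enrichment is uniform.

    Computes the coefficient of variation of total contribution across
    subjects; fails above ``threshold``.  Requires >= 2 subjects.
    """
    values = np.asarray(
        [c.value if isinstance(c, TotalContribution) else float(c) for c in contributions]
    )
    if len(values) < 2:
        raise ValueError("enrichment QC needs >= 2 subjects")
    mean = values.mean()
    if mean == 0:
        raise ValueError("zero mean enrichment")
    cv = float(values.std(ddof=1) / mean)
    return EnrichmentQC(cv=cv, passed=cv <= threshold, threshold=threshold)
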