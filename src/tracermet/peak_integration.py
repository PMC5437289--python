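"""Ion-chromatogram integration: consistent bounds, baseline correction, MIDs.

Raw ion chromatograms (one trace per nominal mass M+0..M+n of a fragment)
are turned into a raw, uncorrected mass distribution vector by applying the
same integration bounds and a two-point linear baseline to every ion of a
metabolite, then integrating by the trapezoidal rule.  The baseline is the
line through the trace values at the two bound endpoints — the minimal
auditable model.  Negative integrals (noise below baseline) clip to zero
with a logged warning.

Pipelines that start from vendor-exported area tables skip this module
entirely (pre-integrated mode).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BoundsError",
    "IntegrationBounds",
    "IonTrace",
    "RawMID",
    "baseline_correct",
    "extract_mid",
    "integrate_ion",
    "read_bounds_table",
    "read_chromatogram_table",
]


class BoundsError(ValueError):
    """Integration bounds invalid or outside the trace's time span."""


@dataclasses.dataclass(frozen=True)
class IonTrace:
    """One extracted-ion chromatogram: (time s, intensity counts) samples."""

    metabolite: str
    mass_shift: int
    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        intensities = np.asarray(self.intensities, dtype=float)
        if times.shape != intensities.shape or times.ndim != 1:
            raise ValueError("times and intensities must be matching 1-D arrays")
        if len(times) and np.any(np.diff(times) <= 0):
            raise ValueError(f"{self.metabolite} M+{self.mass_shift}: times must increase strictly")
        if not np.all(np.isfinite(intensities)):
            raise ValueError(f"{self.metabolite} M+{self.mass_shift}: non-finite intensities")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "intensities", intensities)


@dataclasses.dataclass(frozen=True)
class IntegrationBounds:
    """One integration window per metabolite, shared across all samples and ions."""

    metabolite: str
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise BoundsError(
                f"{self.metabolite}: t_start={self.t_start} must precede t_end={self.t_end}"
            )


@dataclasses.dataclass(frozen=True)
class RawMID:
    """Baseline-corrected integrated areas a0..an, before isotope correction."""

    metabolite: str
    areas: np.ndarray

    def __post_init__(self) -> None:
        areas = np.asarray(self.areas, dtype=float)
        if areas.ndim != 1 or np.any(areas < 0) or not np.all(np.isfinite(areas)):
            raise ValueError(f"{self.metabolite}: areas must be finite and >= 0")
        object.__setattr__(self, "areas", areas)


def _check_span(trace: IonTrace, bounds: IntegrationBounds) -> None:
    if len(trace.times) == 0 or bounds.t_start < trace.times[0] or bounds.t_end > trace.times[-1]:
        raise BoundsError(
            f"{bounds.metabolite}: bounds [{bounds.t_start}, {bounds.t_end}] outside "
            f"trace span [{trace.times[0] if len(trace.times) else None}, "
            f"{trace.times[-1] if len(trace.times) else None}]"
        )


def baseline_correct(trace: IonTrace, bounds: IntegrationBounds) -> IonTrace:
    """Subtract the linear baseline through the trace values at the bounds.

    Only samples inside ``[t_start, t_end]`` are modified; the rest of the
    trace is untouched.  Deterministic.
    """
    _check_span(trace, bounds)
    y_start = float(np.interp(bounds.t_start, trace.times, trace.intensities))
    y_end = float(np.interp(bounds.t_end, trace.times, trace.intensities))
    slope = (y_end - y_start) / (bounds.t_end - bounds.t_start)
    corrected = trace.intensities.copy()
    inside = (trace.times >= bounds.t_start) & (trace.times <= bounds.t_end)
    corrected[inside] -= y_start + slope * (trace.times[inside] - bounds.t_start)
    return IonTrace(trace.metabolite, trace.mass_shift, trace.times, corrected)


def integrate_ion(trace: IonTrace, bounds: IntegrationBounds) -> float:
    """Trapezoidal integral of a (baseline-corrected) trace over the bounds.

    Interpolated values at the exact bound endpoints are included so the
    integral does not depend on whether a sample lands on the boundary.
    Negative integrals clip to 0 with a logged warning.
    """
    _check_span(trace, bounds)
    within = (trace.times >= bounds.t_start) & (trace.times <= bounds.t_end)
    if int(within.sum()) < 2:
        raise BoundsError(
            f"{bounds.metabolite} M+{trace.mass_shift}: fewer than 2 samples inside bounds"
        )
    inside = (trace.times > bounds.t_start) & (trace.times < bounds.t_end)
    times = np.concatenate(([bounds.t_start], trace.times[inside], [bounds.t_end]))
    values = np.concatenate((
        [np.interp(bounds.t_start, trace.times, trace.intensities)],
        trace.intensities[inside],
        [np.interp(bounds.t_end, trace.times, trace.intensities)],
    ))
    area = float(np.trapezoid(values, times))
    if area < 0:
        logger.warning(
            "%s M+%d: negative area %.4g clipped to 0", trace.metabolite, trace.mass_shift, area
        )
        return 0.0
    return area


def extract_mid(traces: list[IonTrace], bounds: IntegrationBounds) -> RawMID:
    """Assemble baseline-corrected per-ion areas into a raw MID.

    ``traces`` must contain exactly one trace per mass shift 0..n of a
    single metabolite; a missing shift is a structural error listing the
    missing masses.
    """
    if not traces:
        raise ValueError("no traces supplied")
    metabolites = {t.metabolite for t in traces}
    if metabolites != {bounds.metabolite}:
        raise ValueError(f"traces {metabolites} do not match bounds metabolite {bounds.metabolite!r}")
    by_shift = {t.mass_shift: t for t in traces}
    if len(by_shift) != len(traces):
        raise ValueError(f"{bounds.metabolite}: duplicate mass shifts in traces")
    n = max(by_shift)
    missing = sorted(set(range(n + 1)) - set(by_shift))
    if missing:
        raise ValueError(f"{bounds.metabolite}: missing mass shifts {missing}")
    areas = np.array([
        integrate_ion(baseline_correct(by_shift[shift], bounds), bounds)
        for shift in range(n + 1)
    ])
    return RawMID(bounds.metabolite, areas)


def read_chromatogram_table(path) -> dict[tuple[str, str], list[IonTrace]]:
    """Read a long-format TSV (sample, metabolite, mass_shift, time_s, intensity).

    Returns traces grouped by ``(sample, metabolite)``, sorted by mass shift.
    """
    df = pd.read_csv(path, sep="\t")
    out: dict[tuple[str, str], list[IonTrace]] = {}
    for (sample, metabolite, shift), group in df.groupby(
        ["sample", "metabolite", "mass_shift"], sort=True
    ):
        group = group.sort_values("time_s")
        out.setdefault((str(sample), str(metabolite)), []).append(
            IonTrace(str(metabolite), int(shift),
                     group["time_s"].to_numpy(), group["intensity"].to_numpy())
        )
    return out


def read_bounds_table(path) -> dict[str, IntegrationBounds]:
    """Read an integration-bounds TSV (metabolite, t_start_s, t_end_s)."""
    df = pd.read_csv(path, sep="\t")
    return {
        str(r.metabolite): IntegrationBounds(str(r.metabolite), float(r.t_start_s), float(r.t_end_s))
        for r in df.itertuples(index=False)
    }
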