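"""Measurement-campaign data model and summary statistics.

A campaign measures four excised hearts (A1-A4) at 17 anatomical locations,
15 repeated probe placements per location, for 1020 measurements in total.
Locations are grouped into six tissue parts (epicardium, endocardium,
myocardium, the two atrial-appendage surfaces, and the luminal surface of the
great vessels).  Two vector network analyzers share the work: VNA1 sweeps
500 MHz-20 GHz and VNA2 500 MHz-8.5 GHz, both on logarithmic grids obtained by
filtering a 101-point sweep that starts at 200 MHz (the coaxial probe is only
trusted from 500 MHz up).

This module provides the plan and record types plus the analyses run on a
campaign: per-(heart, part) mean +/- SD summaries at a single frequency,
pointwise mean spectra, one-way ANOVA across hearts, and an ordinary
least-squares drift diagnostic of permittivity against time from excision.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .models import (
    FrequencyGrid,
    GridAlignmentError,
    PermittivitySpectrum,
    value_at_frequency,
)

__all__ = [
    "TissuePart",
    "MeasurementLocation",
    "MeasurementRecord",
    "CampaignPlan",
    "GroupSummary",
    "AnovaResult",
    "DegenerateInputError",
    "DEFAULT_LOCATIONS",
    "DEFAULT_HEARTS",
    "DEFAULT_INSTRUMENTS",
    "build_log_grid",
    "filter_min_frequency",
    "vna1_grid",
    "vna2_grid",
    "instrument_grid",
    "build_default_plan",
    "group_summary",
    "mean_spectrum",
    "one_way_anova",
    "anova_battery",
    "drift_diagnostic",
]


class DegenerateInputError(ValueError):
    """Statistic undefined for the given input (e.g. zero variance)."""


class TissuePart(str, enum.Enum):
    """The six anatomical groups of measurement locations."""

    EPICARDIUM = "epicardium"
    ENDOCARDIUM = "endocardium"
    MYOCARDIUM = "myocardium"
    APPENDAGE_INTERIOR = "appendage_interior"
    APPENDAGE_EXTERIOR = "appendage_exterior"
    GREAT_VESSELS = "great_vessels_luminal"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class MeasurementLocation:
    """One probe placement site, assigned to exactly one tissue part."""

    label: str
    part: TissuePart


# Endocardium (4: ventricle and atrium interiors), myocardium (1: septum) and
# great vessels (4) are fixed by the study design.  The remaining 8 of 17
# locations split among epicardium and the two appendage surfaces is a
# catalogue choice: 6 epicardial sites plus the left atrial appendage inside
# and outside.  Override the catalogue to change it; totals stay 17.
DEFAULT_LOCATIONS: tuple[MeasurementLocation, ...] = (
    MeasurementLocation("epicardium_lv_anterior", TissuePart.EPICARDIUM),
    MeasurementLocation("epicardium_lv_posterior", TissuePart.EPICARDIUM),
    MeasurementLocation("epicardium_rv_anterior", TissuePart.EPICARDIUM),
    MeasurementLocation("epicardium_rv_posterior", TissuePart.EPICARDIUM),
    MeasurementLocation("epicardium_apex", TissuePart.EPICARDIUM),
    MeasurementLocation("epicardium_atria", TissuePart.EPICARDIUM),
    MeasurementLocation("endocardium_lv", TissuePart.ENDOCARDIUM),
    MeasurementLocation("endocardium_rv", TissuePart.ENDOCARDIUM),
    MeasurementLocation("endocardium_la", TissuePart.ENDOCARDIUM),
    MeasurementLocation("endocardium_ra", TissuePart.ENDOCARDIUM),
    MeasurementLocation("myocardium_septum", TissuePart.MYOCARDIUM),
    MeasurementLocation("appendage_la_interior", TissuePart.APPENDAGE_INTERIOR),
    MeasurementLocation("appendage_la_exterior", TissuePart.APPENDAGE_EXTERIOR),
    MeasurementLocation("vessel_aorta", TissuePart.GREAT_VESSELS),
    MeasurementLocation("vessel_pulmonary_artery", TissuePart.GREAT_VESSELS),
    MeasurementLocation("vessel_pulmonary_vein", TissuePart.GREAT_VESSELS),
    MeasurementLocation("vessel_vena_cava", TissuePart.GREAT_VESSELS),
)

DEFAULT_HEARTS: tuple[str, ...] = ("A1", "A2", "A3", "A4")

#: Which VNA measured which heart (two hearts per instrument, run in parallel).
DEFAULT_INSTRUMENTS: dict[str, str] = {
    "A1": "VNA1",
    "A2": "VNA2",
    "A3": "VNA1",
    "A4": "VNA2",
}

TEMPERATURE_PLAUSIBLE_C = (15.0, 40.0)


def build_log_grid(f_min: float, f_max: float, n_points: int) -> FrequencyGrid:
    """``n_points`` frequencies uniform in log10(f), endpoints included exactly."""
    if not (0.0 < f_min < f_max):
        raise ValueError(f"need 0 < f_min < f_max, got ({f_min}, {f_max})")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    f = np.logspace(np.log10(f_min), np.log10(f_max), n_points)
    f[0], f[-1] = f_min, f_max
    return FrequencyGrid(f)


def filter_min_frequency(grid: FrequencyGrid, f_cut: float) -> FrequencyGrid:
    """Drop grid points below ``f_cut`` Hz, preserving order."""
    keep = grid.frequencies >= float(f_cut)
    return FrequencyGrid(grid.frequencies[keep])


def vna1_grid() -> FrequencyGrid:
    """VNA1 grid: 101 log points on 200 MHz-20 GHz filtered at 500 MHz (81 points)."""
    return filter_min_frequency(build_log_grid(200e6, 20e9, 101), 500e6)


def vna2_grid() -> FrequencyGrid:
    """VNA2 grid: 101 log points on 200 MHz-8.5 GHz filtered at 500 MHz."""
    return filter_min_frequency(build_log_grid(200e6, 8.5e9, 101), 500e6)


def instrument_grid(instrument: str) -> FrequencyGrid:
    grids = {"VNA1": vna1_grid, "VNA2": vna2_grid}
    try:
        return grids[instrument]()
    except KeyError:
        raise ValueError(f"unknown instrument {instrument!r}") from None


@dataclass(frozen=True)
class MeasurementRecord:
    """One probe measurement with its metadata and spectrum."""

    heart_id: str
    location: MeasurementLocation
    repeat_index: int
    time_from_excision_min: float
    temperature_c: float
    instrument: str
    spectrum: PermittivitySpectrum
    temperature_flagged: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        lo, hi = TEMPERATURE_PLAUSIBLE_C
        if not (lo <= self.temperature_c <= hi):
            object.__setattr__(self, "temperature_flagged", True)
            warnings.warn(
                f"temperature {self.temperature_c:.1f} C outside the plausibility "
                f"band [{lo}, {hi}] C; record flagged",
                stacklevel=2,
            )

    @property
    def part(self) -> TissuePart:
        return self.location.part


@dataclass(frozen=True)
class CampaignPlan:
    """Structured design: hearts x location catalogue x repeats."""

    hearts: tuple[str, ...] = DEFAULT_HEARTS
    locations: tuple[MeasurementLocation, ...] = DEFAULT_LOCATIONS
    repeats_per_location: int = 15
    instruments: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_INSTRUMENTS))

    def __post_init__(self) -> None:
        if self.repeats_per_location < 1:
            raise ValueError("repeats_per_location must be >= 1")
        missing = [h for h in self.hearts if h not in self.instruments]
        if missing:
            raise ValueError(f"no instrument assigned for hearts {missing}")

    @property
    def n_records(self) -> int:
        return len(self.hearts) * len(self.locations) * self.repeats_per_location

    def locations_for_part(self, part: TissuePart) -> tuple[MeasurementLocation, ...]:
        return tuple(loc for loc in self.locations if loc.part == part)


def build_default_plan() -> CampaignPlan:
    """The default study design: 4 hearts x 17 locations x 15 repeats = 1020."""
    return CampaignPlan()


@dataclass(frozen=True)
class GroupSummary:
    """Mean +/- sample SD of one (heart, part) group at a stated frequency."""

    heart_id: str
    part: TissuePart
    n: int
    frequency_hz: float
    mean_eps_r: float
    sd_eps_r: float
    mean_sigma: float
    sd_sigma: float

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("group must contain at least one record")
        if self.sd_eps_r < 0 or self.sd_sigma < 0:
            raise ValueError("standard deviations must be non-negative")


def _sample_sd(values: np.ndarray) -> float:
    """Sample SD with the n-1 denominator; exactly 0 for constant data."""
    if values.size < 2 or np.ptp(values) == 0.0:
        return 0.0
    return float(np.std(values, ddof=1))


def group_summary(
    records: list[MeasurementRecord], f: float
) -> list[GroupSummary]:
    """Per-(heart, part) mean and sample SD of eps_r and sigma at frequency ``f``.

    Single-frequency values are extracted with :func:`value_at_frequency`
    (log-frequency interpolation when ``f`` is off-grid).  Groups are returned
    sorted by (heart, part value).
    """
    if not records:
        raise ValueError("no records to summarize")
    groups: dict[tuple[str, TissuePart], list[tuple[float, float]]] = {}
    for rec in records:
        groups.setdefault((rec.heart_id, rec.part), []).append(
            value_at_frequency(rec.spectrum, f)
        )
    out = []
    for (heart, part), vals in sorted(groups.items(), key=lambda kv: (kv[0][0], kv[0][1].value)):
        eps = np.array([v[0] for v in vals])
        sig = np.array([v[1] for v in vals])
        out.append(
            GroupSummary(
                heart_id=heart,
                part=part,
                n=len(vals),
                frequency_hz=float(f),
                mean_eps_r=float(eps.mean()),
                sd_eps_r=_sample_sd(eps),
                mean_sigma=float(sig.mean()),
                sd_sigma=_sample_sd(sig),
            )
        )
    return out


def mean_spectrum(
    records: list[MeasurementRecord],
) -> tuple[PermittivitySpectrum, PermittivitySpectrum]:
    """Pointwise mean and sample SD spectra of records sharing one grid."""
    if not records:
        raise ValueError("no records to average")
    grid = records[0].spectrum.grid
    for rec in records[1:]:
        if rec.spectrum.grid != grid:
            raise GridAlignmentError("records are on different frequency grids")
    eps = np.stack([rec.spectrum.eps_r for rec in records])
    sig = np.stack([rec.spectrum.sigma for rec in records])
    mean = PermittivitySpectrum(grid, eps.mean(axis=0), sig.mean(axis=0))
    n = eps.shape[0]
    if n > 1:
        # exact zeros for pointwise-constant data (no rounding dust)
        sd_eps = np.where(np.ptp(eps, axis=0) == 0.0, 0.0, eps.std(axis=0, ddof=1))
        sd_sig = np.where(np.ptp(sig, axis=0) == 0.0, 0.0, sig.std(axis=0, ddof=1))
    else:
        sd_eps = np.zeros(len(grid))
        sd_sig = np.zeros(len(grid))
    sd = PermittivitySpectrum(grid, sd_eps, sd_sig, check_physical=False)
    return mean, sd


@dataclass(frozen=True)
class AnovaResult:
    """Classical one-way ANOVA outcome."""

    F: float
    p: float
    df_between: int
    df_within: int


def one_way_anova(groups: list[np.ndarray]) -> AnovaResult:
    """One-way ANOVA: F = MS_between / MS_within with (k-1, N-k) df.

    Requires at least two groups of at least two values each and non-zero
    pooled within-group variance.
    """
    if len(groups) < 2:
        raise ValueError("one-way ANOVA needs at least two groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrs):
        raise ValueError("every group needs at least two values")
    ssw = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrs)
    if ssw == 0.0:
        raise DegenerateInputError("zero within-group variance; F undefined")
    F, p = stats.f_oneway(*arrs)
    k = len(arrs)
    n_total = sum(a.size for a in arrs)
    return AnovaResult(F=float(F), p=float(p), df_between=k - 1, df_within=n_total - k)


def anova_battery(
    records: list[MeasurementRecord],
    f: float,
    mode: str = "parts_within_heart",
) -> dict[tuple[str, str], AnovaResult]:
    """A battery of one-way ANOVAs on single-frequency values at ``f``.

    Two factorizations are supported, because reported protocols are
    ambiguous about which comparison a "per heart sample" ANOVA means:

    ``"parts_within_heart"`` (default)
        For each heart and each quantity, compare the tissue-part group
        means within that heart (2 quantities x 4 hearts = 8 tests for the
        default design).  Keys are ``(heart_id, quantity)``.
    ``"hearts_within_part"``
        For each tissue part and each quantity, compare the four hearts.
        Keys are ``(part value, quantity)``.
    """
    if mode not in ("parts_within_heart", "hearts_within_part"):
        raise ValueError(f"unknown ANOVA battery mode {mode!r}")
    by_cell: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for rec in records:
        by_cell.setdefault((rec.heart_id, rec.part.value), []).append(
            value_at_frequency(rec.spectrum, f)
        )
    if mode == "parts_within_heart":
        outer = sorted({heart for heart, _ in by_cell})
        cells_for = lambda o: [v for (h, _), v in sorted(by_cell.items()) if h == o]
    else:
        outer = sorted({part for _, part in by_cell})
        cells_for = lambda o: [v for (_, p), v in sorted(by_cell.items()) if p == o]
    results: dict[tuple[str, str], AnovaResult] = {}
    for o in outer:
        cells = cells_for(o)
        if len(cells) < 2:
            continue
        for qi, quantity in enumerate(("eps_r", "sigma")):
            groups = [np.array([v[qi] for v in cell]) for cell in cells]
            results[(o, quantity)] = one_way_anova(groups)
    return results


def drift_diagnostic(
    records: list[MeasurementRecord], f: float
) -> tuple[float, float]:
    """OLS slope (per minute) and Pearson r of eps_r at ``f`` vs time from excision.

    A flat slope supports the assumption that tissue dehydration over the
    measurement window did not systematically shift the dielectric properties.
    """
    if len(records) < 2:
        raise ValueError("drift diagnostic needs at least two records")
    t = np.array([rec.time_from_excision_min for rec in records], dtype=float)
    if np.ptp(t) == 0.0:
        raise DegenerateInputError("all records share one timestamp; slope undefined")
    y = np.array([value_at_frequency(rec.spectrum, f)[0] for rec in records])
    if np.ptp(y) == 0.0:
        # regression of a constant: slope 0, correlation undefined -> report 0
        return 0.0, 0.0
    res = stats.linregress(t, y)
    return float(res.slope), float(res.rvalue)
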