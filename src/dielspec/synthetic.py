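"""Seeded generator of synthetic measurement campaigns.

The generator emulates the statistical structure of a multi-location,
multi-repeat probe campaign on excised hearts so every downstream analysis
(mean spectra, Debye fitting, single-frequency summaries, ANOVA, drift
diagnostics) can be exercised without any measured data:

* each (heart, tissue part) has a ground-truth three-pole Debye model
  (default: the packaged fitted heart models);
* biological variability between locations of the same part is a per-location
  lognormal multiplier (unit mean, configurable CV) applied to the dispersion
  magnitudes and the static conductivity — relaxation times are left alone,
  treating them as tissue-type properties and keeping poles identifiable;
* repeat-to-repeat measurement noise is i.i.d. multiplicative Gaussian per
  frequency point on both quantities (CV calibrated so single-frequency SDs
  land in the range a real probe campaign shows);
* optional linear relative drift with time from excision (default zero: the
  study design checks for, and the emulated instrument has, no trend);
* measurement times spread over a 4 h to 8.5 h post-excision window and
  tissue temperatures are drawn around the reported room-temperature mean.

Everything is driven by one integer seed; fixed seed means bit-identical
campaigns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .campaign import CampaignPlan, MeasurementRecord, TissuePart, instrument_grid
from .models import DebyeParameters, PermittivitySpectrum, Pole, evaluate_model

__all__ = ["SyntheticConfig", "generate_campaign"]


def _default_ground_truth() -> dict[tuple[str, TissuePart], DebyeParameters]:
    from .io import load_heart_models

    return load_heart_models()


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters of the synthetic campaign generator.

    Attributes
    ----------
    ground_truth : mapping (heart_id, TissuePart) -> DebyeParameters
        Per-(heart, part) true dispersion models; defaults to the packaged
        fitted heart models.
    location_variability_cv : float
        CV of the per-location lognormal multipliers on delta_eps and sigma_s
        (biological variability between sites of one part).  Default 0.05.
    repeat_noise_cv : float
        CV of per-repeat, per-point multiplicative Gaussian noise on eps_r and
        sigma.  Default 0.03, which puts 2.4 GHz group SDs in the few-unit
        (permittivity) / few-hundredths-S/m (conductivity) range typical of
        repeated probe placements.
    drift_per_min : float
        True relative drift per minute applied to both quantities
        (value * (1 + drift * t)).  Default 0 (no dehydration trend).
    temperature_mean_c, temperature_sd_c : float
        Gaussian tissue-temperature draw, default 23.5 +/- 0.9 C.
    time_window_min : (float, float)
        Measurement window as minutes from excision, default 240-510 min
        (first to last measurement on a heart).
    seed : int
        RNG seed; the campaign is a pure function of (plan, config).
    """

    ground_truth: Mapping[tuple[str, TissuePart], DebyeParameters] = field(
        default_factory=_default_ground_truth
    )
    location_variability_cv: float = 0.05
    repeat_noise_cv: float = 0.03
    drift_per_min: float = 0.0
    temperature_mean_c: float = 23.5
    temperature_sd_c: float = 0.9
    time_window_min: tuple[float, float] = (240.0, 510.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.location_variability_cv < 0 or self.repeat_noise_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")


def _lognormal_unit_mean(rng: np.random.Generator, cv: float) -> float:
    """A lognormal multiplier with mean 1 and coefficient of variation cv."""
    if cv == 0.0:
        return 1.0
    s2 = np.log1p(cv * cv)
    return float(rng.lognormal(mean=-0.5 * s2, sigma=np.sqrt(s2)))


def generate_campaign(
    plan: CampaignPlan, config: SyntheticConfig | None = None
) -> list[MeasurementRecord]:
    """Generate one synthetic campaign for ``plan`` under ``config``.

    Raises ``KeyError`` naming the missing (heart, part) if the ground truth
    does not cover the plan.  With all CVs and drift at zero every record's
    spectrum equals its ground-truth model evaluation exactly.
    """
    config = config or SyntheticConfig()
    for heart in plan.hearts:
        for loc in plan.locations:
            if (heart, loc.part) not in config.ground_truth:
                raise KeyError(
                    f"no ground-truth model for heart {heart!r}, part {loc.part.value!r}"
                )
    rng = np.random.default_rng(config.seed)
    records: list[MeasurementRecord] = []
    t_lo, t_hi = config.time_window_min
    for heart in plan.hearts:
        instrument = plan.instruments[heart]
        grid = instrument_grid(instrument)
        n_meas = len(plan.locations) * plan.repeats_per_location
        # Measurements proceed location by location through the window.
        times = np.linspace(t_lo, t_hi, n_meas)
        i_meas = 0
        for loc in plan.locations:
            truth = config.ground_truth[(heart, loc.part)]
            m_de = _lognormal_unit_mean(rng, config.location_variability_cv)
            m_ss = _lognormal_unit_mean(rng, config.location_variability_cv)
            local = DebyeParameters(
                truth.eps_inf,
                truth.sigma_s * m_ss,
                tuple(Pole(p.delta_eps * m_de, p.tau) for p in truth.poles),
            )
            base = evaluate_model(local, grid)
            for repeat in range(1, plan.repeats_per_location + 1):
                t = float(times[i_meas])
                i_meas += 1
                drift = 1.0 + config.drift_per_min * t
                eps = base.eps_r * drift
                sig = base.sigma * drift
                if config.repeat_noise_cv > 0.0:
                    eps = eps * (
                        1.0 + config.repeat_noise_cv * rng.standard_normal(len(grid))
                    )
                    sig = sig * (
                        1.0 + config.repeat_noise_cv * rng.standard_normal(len(grid))
                    )
                sig = np.maximum(sig, 0.0)
                temp = config.temperature_mean_c + config.temperature_sd_c * rng.standard_normal()
                records.append(
                    MeasurementRecord(
                        heart_id=heart,
                        location=loc,
                        repeat_index=repeat,
                        time_from_excision_min=t,
                        temperature_c=float(temp),
                        instrument=instrument,
                        spectrum=PermittivitySpectrum(grid, eps, sig),
                    )
                )
    return records
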