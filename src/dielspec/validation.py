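"""Probe-calibration validation against a reference-liquid model.

After a one-port calibration (open, short, reference liquid), the probe is
checked by measuring a standard liquid with a known dielectric model — e.g.
0.9% NaCl solution — and comparing the measurement to the model.  The mean
absolute percentage difference over all frequencies, computed separately for
relative permittivity and conductivity, is the validation error of that
measurement; a campaign reports the mean and maximum across all validations.

No literature saline model is baked in: the reference is pluggable, either a
parametric model (Debye / Cole-Cole) or a tabulated spectrum, so any
concentration/temperature-specific literature model can be supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .models import (
    ColeColeParameters,
    DebyeParameters,
    FrequencyGrid,
    PermittivitySpectrum,
    evaluate_model,
    mean_percent_difference,
    value_at_frequency,
)

__all__ = ["ReferenceModel", "ValidationResult", "validate_measurement", "aggregate_validations"]


@dataclass(frozen=True)
class ReferenceModel:
    """A reference liquid's dielectric model plus identifying metadata.

    ``model`` is either a parametric dispersion (evaluated in closed form) or
    a tabulated :class:`PermittivitySpectrum` (interpolated in log-frequency
    onto the validation grid, which must lie inside the tabulated range).
    """

    model: Union[DebyeParameters, ColeColeParameters, PermittivitySpectrum]
    liquid: str = ""
    concentration: str = ""
    temperature_c: float = float("nan")

    def evaluate(self, grid: FrequencyGrid) -> PermittivitySpectrum:
        if isinstance(self.model, PermittivitySpectrum):
            vals = [value_at_frequency(self.model, f) for f in grid.frequencies]
            eps = np.array([v[0] for v in vals])
            sig = np.array([v[1] for v in vals])
            return PermittivitySpectrum(grid, eps, sig)
        return evaluate_model(self.model, grid)


@dataclass(frozen=True)
class ValidationResult:
    """Validation errors (%) of one standard-liquid measurement."""

    mpd_eps: float
    mpd_sigma: float
    temperature_c: float = float("nan")
    timestamp: str = ""

    def __post_init__(self) -> None:
        if self.mpd_eps < 0 or self.mpd_sigma < 0:
            raise ValueError("validation errors must be non-negative")


def validate_measurement(
    measured: PermittivitySpectrum,
    reference: ReferenceModel,
    temperature_c: float = float("nan"),
    timestamp: str = "",
) -> ValidationResult:
    """Mean % difference of a measured standard-liquid spectrum from its model.

    The reference model, evaluated on the measured grid, is the denominator;
    errors are absolute magnitudes, reported separately per quantity.
    """
    ref = reference.evaluate(measured.grid)
    mpd_eps, mpd_sigma = mean_percent_difference(measured, ref)
    return ValidationResult(mpd_eps, mpd_sigma, temperature_c, timestamp)


def aggregate_validations(
    results: list[ValidationResult],
) -> tuple[float, float, float, float]:
    """Aggregate validation errors: (mean_eps, max_eps, mean_sigma, max_sigma) in %."""
    if not results:
        raise ValueError("no validation results to aggregate")
    eps = np.array([r.mpd_eps for r in results])
    sig = np.array([r.mpd_sigma for r in results])
    return float(eps.mean()), float(eps.max()), float(sig.mean()), float(sig.max())
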