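"""Dispersion models for the complex permittivity of lossy dielectrics.

The central object is the multi-pole Debye relaxation model

    eps_hat(w) = eps_inf + sum_p delta_eps_p / (1 + j*w*tau_p)
                 + sigma_s / (j*w*eps0),

written in the engineering time convention ``exp(+j*w*t)``, so that a passive
material has a non-positive imaginary part.  Measured and modelled spectra are
stored canonically as the pair (relative permittivity ``eps_r``, total
effective conductivity ``sigma`` in S/m); the complex form is a view obtained
with :func:`to_complex`.  The effective conductivity combines static ionic
conduction (``sigma_s``) and dipolar relaxation losses, which is what an
open-ended coaxial probe measurement reports.

The Cole-Cole generalization replaces ``j*w*tau`` by ``(j*w*tau)**(1-alpha)``
to broaden each relaxation; ``alpha = 0`` recovers the Debye pole exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence, Union

import numpy as np

__all__ = [
    "EPS0",
    "ParameterError",
    "GridAlignmentError",
    "FrequencyGrid",
    "PermittivitySpectrum",
    "Pole",
    "DebyeParameters",
    "ColeColeParameters",
    "evaluate_model",
    "to_complex",
    "from_complex",
    "value_at_frequency",
    "mean_percent_difference",
]

#: Vacuum permittivity, F/m.
EPS0 = 8.8541878128e-12


class ParameterError(ValueError):
    """Non-physical dispersion-model parameters (negative delta_eps, tau <= 0, ...)."""


class GridAlignmentError(ValueError):
    """Two spectra that should share a frequency grid do not."""


@dataclass(frozen=True, eq=False)
class FrequencyGrid:
    """A strictly increasing grid of frequencies in Hz (all positive)."""

    frequencies: np.ndarray

    def __post_init__(self) -> None:
        f = np.atleast_1d(np.asarray(self.frequencies, dtype=float))
        if f.ndim != 1 or f.size < 1:
            raise ValueError("frequency grid must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(f)):
            raise ValueError("frequency grid contains non-finite values")
        if np.any(f <= 0.0):
            raise ValueError("all frequencies must be positive")
        if f.size > 1 and np.any(np.diff(f) <= 0.0):
            raise ValueError("frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies", f)

    def __len__(self) -> int:
        return int(self.frequencies.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrequencyGrid):
            return NotImplemented
        return np.array_equal(self.frequencies, other.frequencies)

    @property
    def f_min(self) -> float:
        return float(self.frequencies[0])

    @property
    def f_max(self) -> float:
        return float(self.frequencies[-1])

    @property
    def omega(self) -> np.ndarray:
        """Angular frequencies ``2*pi*f`` in rad/s."""
        return 2.0 * np.pi * self.frequencies


@dataclass(frozen=True, eq=False)
class PermittivitySpectrum:
    """Paired real relative permittivity and conductivity samples on a grid.

    ``sigma`` is total effective conductivity in S/m and must be non-negative.
    Physical tissue has ``eps_r >= 1``; values below 1 trigger a warning rather
    than a rejection because noisy measurements can dip below the physical
    bound (pass ``check_physical=False`` to silence, e.g. for SD spectra).
    """

    grid: FrequencyGrid
    eps_r: np.ndarray
    sigma: np.ndarray
    check_physical: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        eps = np.atleast_1d(np.asarray(self.eps_r, dtype=float))
        sig = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        n = len(self.grid)
        if eps.shape != (n,) or sig.shape != (n,):
            raise ValueError(
                f"eps_r and sigma must have the grid's length {n}; "
                f"got {eps.shape} and {sig.shape}"
            )
        if not (np.all(np.isfinite(eps)) and np.all(np.isfinite(sig))):
            raise ValueError("spectrum contains non-finite values")
        if np.any(sig < 0.0):
            raise ValueError("conductivity must be non-negative")
        if self.check_physical and np.any(eps < 1.0):
            warnings.warn(
                "relative permittivity below 1 (non-physical for tissue); "
                "keeping the values as-is",
                stacklevel=2,
            )
        object.__setattr__(self, "eps_r", eps)
        object.__setattr__(self, "sigma", sig)

    def __len__(self) -> int:
        return len(self.grid)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PermittivitySpectrum):
            return NotImplemented
        return (
            self.grid == other.grid
            and np.array_equal(self.eps_r, other.eps_r)
            and np.array_equal(self.sigma, other.sigma)
        )


class Pole(NamedTuple):
    """One relaxation pole: dispersion magnitude and relaxation time in seconds."""

    delta_eps: float
    tau: float


@dataclass(frozen=True)
class DebyeParameters:
    """Parameters of an n-pole Debye dispersion plus static ionic conductivity.

    Attributes
    ----------
    eps_inf : float
        High-frequency relative permittivity (dimensionless, >= 1).
    sigma_s : float
        Static ionic conductivity in S/m (>= 0).
    poles : tuple of Pole
        ``(delta_eps, tau)`` pairs; ``delta_eps >= 0`` dimensionless,
        ``tau > 0`` in seconds.  Canonical order is tau strictly descending
        (slowest relaxation first), which breaks the pole-label symmetry.
    """

    eps_inf: float
    sigma_s: float
    poles: tuple[Pole, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "poles", tuple(Pole(float(d), float(t)) for d, t in self.poles)
        )
        object.__setattr__(self, "eps_inf", float(self.eps_inf))
        object.__setattr__(self, "sigma_s", float(self.sigma_s))
        if not np.isfinite(self.eps_inf) or self.eps_inf < 1.0:
            raise ParameterError(f"eps_inf must be >= 1, got {self.eps_inf}")
        if not np.isfinite(self.sigma_s) or self.sigma_s < 0.0:
            raise ParameterError(f"sigma_s must be >= 0, got {self.sigma_s}")
        for p in self.poles:
            if not np.isfinite(p.delta_eps) or p.delta_eps < 0.0:
                raise ParameterError(f"delta_eps must be >= 0, got {p.delta_eps}")
            if not np.isfinite(p.tau) or p.tau <= 0.0:
                raise ParameterError(f"tau must be > 0, got {p.tau}")

    @property
    def n(self) -> int:
        """Pole count."""
        return len(self.poles)

    def canonical(self) -> "DebyeParameters":
        """Return a copy with poles sorted by descending relaxation time."""
        poles = tuple(sorted(self.poles, key=lambda p: -p.tau))
        return DebyeParameters(self.eps_inf, self.sigma_s, poles)


@dataclass(frozen=True)
class ColeColeParameters(DebyeParameters):
    """Cole-Cole dispersion: per-pole broadening exponents ``alpha`` in [0, 1).

    ``alphas`` aligns with ``poles``; every ``alpha = 0`` reduces the model
    exactly to :class:`DebyeParameters`.
    """

    alphas: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        super().__post_init__()
        object.__setattr__(self, "alphas", tuple(float(a) for a in self.alphas))
        if len(self.alphas) != len(self.poles):
            raise ParameterError(
                f"need one alpha per pole: {len(self.alphas)} alphas "
                f"for {len(self.poles)} poles"
            )
        for a in self.alphas:
            if not np.isfinite(a) or not (0.0 <= a < 1.0):
                raise ParameterError(f"alpha must lie in [0, 1), got {a}")


ModelParameters = Union[DebyeParameters, ColeColeParameters]


def evaluate_model(params: ModelParameters, grid: FrequencyGrid) -> PermittivitySpectrum:
    """Evaluate a Debye or Cole-Cole model on a frequency grid, closed form.

    For the Debye model, each pole contributes

        eps_r += delta_eps / (1 + (w*tau)**2)
        sigma += eps0 * delta_eps * w**2 * tau / (1 + (w*tau)**2)

    and the static term adds ``sigma_s`` to the conductivity.  The Cole-Cole
    pole uses the real/imaginary split of ``1 / (1 + (j*w*tau)**(1-alpha))``.
    """
    if not isinstance(params, DebyeParameters):
        raise TypeError(f"unsupported parameter type {type(params).__name__}")
    w = grid.omega
    eps = np.full_like(w, params.eps_inf)
    sig = np.full_like(w, params.sigma_s)
    if isinstance(params, ColeColeParameters):
        for (de, tau), alpha in zip(params.poles, params.alphas):
            if alpha == 0.0:
                _add_debye_pole(eps, sig, w, de, tau)
            else:
                x = (w * tau) ** (1.0 - alpha)
                phi = 0.5 * np.pi * (1.0 - alpha)
                re = 1.0 + x * np.cos(phi)
                im = x * np.sin(phi)
                mag2 = re * re + im * im
                eps += de * re / mag2
                sig += EPS0 * w * de * im / mag2
    else:
        for de, tau in params.poles:
            _add_debye_pole(eps, sig, w, de, tau)
    return PermittivitySpectrum(grid, eps, sig)


def _add_debye_pole(
    eps: np.ndarray, sig: np.ndarray, w: np.ndarray, de: float, tau: float
) -> None:
    wt2 = (w * tau) ** 2
    denom = 1.0 + wt2
    eps += de / denom
    sig += EPS0 * de * w * w * tau / denom


def to_complex(spectrum: PermittivitySpectrum) -> np.ndarray:
    """Complex relative permittivity ``eps_r - j*sigma/(w*eps0)`` per grid point."""
    w = spectrum.grid.omega
    return spectrum.eps_r - 1j * spectrum.sigma / (w * EPS0)


def from_complex(grid: FrequencyGrid, eps_hat: np.ndarray, **kwargs) -> PermittivitySpectrum:
    """Inverse of :func:`to_complex`: split eps_hat into (eps_r, sigma)."""
    eps_hat = np.asarray(eps_hat, dtype=complex)
    if eps_hat.shape != (len(grid),):
        raise ValueError("eps_hat length must match the grid")
    w = grid.omega
    return PermittivitySpectrum(grid, eps_hat.real, -eps_hat.imag * w * EPS0, **kwargs)


def value_at_frequency(spectrum: PermittivitySpectrum, f: float) -> tuple[float, float]:
    """Extract ``(eps_r, sigma)`` at one frequency.

    At a grid point this returns the stored values; between points it
    interpolates eps_r and sigma independently, linearly in log10(f), the
    natural interpolant on the log-spaced sweeps used for broadband probe
    measurements.
    """
    f = float(f)
    grid = spectrum.grid
    if not (grid.f_min <= f <= grid.f_max):
        raise ValueError(
            f"frequency {f:g} Hz outside the grid range "
            f"[{grid.f_min:g}, {grid.f_max:g}] Hz"
        )
    logf = np.log10(grid.frequencies)
    lq = np.log10(f)
    eps = float(np.interp(lq, logf, spectrum.eps_r))
    sig = float(np.interp(lq, logf, spectrum.sigma))
    return eps, sig


def mean_percent_difference(
    a: PermittivitySpectrum, b: PermittivitySpectrum
) -> tuple[float, float]:
    """Mean absolute percentage difference of ``a`` from reference ``b``.

    Returns ``(mpd_eps, mpd_sigma)`` where each is the mean over frequency of
    ``100 * |a - b| / b``; the second argument is the reference in the
    denominator.  Both spectra must share an identical grid.
    """
    if a.grid != b.grid:
        raise GridAlignmentError("spectra are not on the same frequency grid")
    if np.any(b.eps_r == 0.0) or np.any(b.sigma == 0.0):
        raise ZeroDivisionError("reference spectrum has zero values")
    mpd_eps = float(np.mean(100.0 * np.abs(a.eps_r - b.eps_r) / np.abs(b.eps_r)))
    mpd_sigma = float(np.mean(100.0 * np.abs(a.sigma - b.sigma) / np.abs(b.sigma)))
    return mpd_eps, mpd_sigma
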