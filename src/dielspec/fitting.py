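"""Least-squares fitting of multi-pole Debye models to measured spectra.

The fit minimizes the joint relative least-squares objective

    sum_f [ ((eps_model - eps_meas) / eps_meas)**2
          + ((sig_model - sig_meas) / sig_meas)**2 ]

over bound-constrained parameters (eps_inf, sigma_s, {delta_eps_p, tau_p}).
Relative residuals weight the two quantities equally even though permittivity
is O(50) and conductivity O(1), and treat all points of a log-spaced sweep
evenly.  The objective is multimodal in tau, so the optimizer is restarted
from ``n_starts`` seeded initial guesses with relaxation times spread across
(and jittered around) the band's period range; the best local minimum wins,
ties going to the lowest start index.  Optimization runs in a transformed
space (log10 tau, log10 delta_eps, linear eps_inf and sigma_s) so the poles'
decade-scale parameters are well conditioned.

Fitted poles are returned in canonical tau-descending order.  Note that
individual pole parameters of a multi-pole fit need not be identifiable (two
poles may trade off); the fitted *spectrum* is the reproducible object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .models import (
    DebyeParameters,
    PermittivitySpectrum,
    Pole,
    evaluate_model,
    mean_percent_difference,
)

__all__ = ["FitBounds", "FitConfig", "FitResult", "ConvergenceError", "fit_debye", "fit_error"]

_LOG_DE_FLOOR = 1e-12  # additive floor so delta_eps = 0 stays representable in log space


class ConvergenceError(RuntimeError):
    """No multistart run converged."""


@dataclass(frozen=True)
class FitBounds:
    """Box constraints for the fit, (lower, upper) per parameter kind."""

    eps_inf: tuple[float, float] = (1.0, 30.0)
    delta_eps: tuple[float, float] = (0.0, 1e6)
    tau: tuple[float, float] = (1e-13, 1e-6)
    sigma_s: tuple[float, float] = (0.0, 10.0)

    def __post_init__(self) -> None:
        for name in ("eps_inf", "delta_eps", "tau", "sigma_s"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"bounds for {name} must satisfy lower < upper")


@dataclass(frozen=True)
class FitConfig:
    """Configuration of the multistart Debye fit."""

    n_poles: int = 3
    n_starts: int = 32
    seed: int = 0
    bounds: FitBounds = field(default_factory=FitBounds)
    rel_tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.n_poles < 1:
            raise ValueError("n_poles must be >= 1")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")


@dataclass(frozen=True)
class FitResult:
    """Outcome of :func:`fit_debye`."""

    params: DebyeParameters
    fit_error_eps: float
    fit_error_sigma: float
    objective: float
    n_starts_converged: int
    best_start_index: int


def _unpack(x: np.ndarray, n_poles: int) -> DebyeParameters:
    eps_inf, sigma_s = x[0], x[1]
    des = 10.0 ** x[2 : 2 + n_poles] - _LOG_DE_FLOOR
    taus = 10.0 ** x[2 + n_poles :]
    poles = tuple(Pole(max(de, 0.0), tau) for de, tau in zip(des, taus))
    return DebyeParameters(max(eps_inf, 1.0), max(sigma_s, 0.0), poles)


def _model_arrays(x: np.ndarray, w: np.ndarray, n_poles: int) -> tuple[np.ndarray, np.ndarray]:
    from .models import EPS0

    eps = np.full_like(w, x[0])
    sig = np.full_like(w, x[1])
    des = 10.0 ** x[2 : 2 + n_poles] - _LOG_DE_FLOOR
    taus = 10.0 ** x[2 + n_poles :]
    for de, tau in zip(des, taus):
        wt2 = (w * tau) ** 2
        denom = 1.0 + wt2
        eps += de / denom
        sig += EPS0 * de * w * w * tau / denom
    return eps, sig


_LN10 = np.log(10.0)


def _jacobian(
    x: np.ndarray, w: np.ndarray, n_poles: int, meas_eps: np.ndarray, meas_sig: np.ndarray
) -> np.ndarray:
    """Analytic Jacobian of the relative residuals in the transformed space."""
    from .models import EPS0

    m = w.size
    J = np.zeros((2 * m, x.size))
    J[:m, 0] = 1.0 / meas_eps  # d eps / d eps_inf
    J[m:, 1] = 1.0 / meas_sig  # d sig / d sigma_s
    w2 = w * w
    for p in range(n_poles):
        u = x[2 + p]
        tau = 10.0 ** x[2 + n_poles + p]
        de = 10.0**u - _LOG_DE_FLOOR
        denom = 1.0 + w2 * tau * tau
        dde_du = _LN10 * 10.0**u
        # d/d log10(delta_eps + floor)
        J[:m, 2 + p] = dde_du / denom / meas_eps
        J[m:, 2 + p] = dde_du * EPS0 * w2 * tau / denom / meas_sig
        # d/d log10(tau); chain rule d tau / d v = ln10 * tau
        dtau_dv = _LN10 * tau
        J[:m, 2 + n_poles + p] = (-de * 2.0 * w2 * tau / denom**2) * dtau_dv / meas_eps
        J[m:, 2 + n_poles + p] = (
            EPS0 * de * w2 * (1.0 - w2 * tau * tau) / denom**2
        ) * dtau_dv / meas_sig
    return J


def _initial_guesses(
    spectrum: PermittivitySpectrum, config: FitConfig
) -> list[np.ndarray]:
    """Seeded multistart initial points, drawn as a prefix-stable stream.

    The guesses for ``n_starts = k`` are the first ``k`` of the stream for any
    larger ``n_starts``, so enlarging the multistart can only improve (never
    worsen) the best objective.
    """
    rng = np.random.default_rng(config.seed)
    b = config.bounds
    n = config.n_poles
    f = spectrum.grid.frequencies
    # Period range visible in the band; slow poles sit above it, so jitter wide.
    log_tau_lo = np.log10(1.0 / (2.0 * np.pi * f[-1]))
    log_tau_hi = np.log10(1.0 / (2.0 * np.pi * f[0]))
    tau_centers = (
        np.linspace(log_tau_lo, log_tau_hi, n) if n > 1 else np.array([0.5 * (log_tau_lo + log_tau_hi)])
    )
    span = max(float(spectrum.eps_r.max() - spectrum.eps_r.min()), 1.0)
    eps_tail = float(spectrum.eps_r.min())
    sig_head = float(spectrum.sigma.min())
    guesses = []
    for _ in range(config.n_starts):
        log_taus = tau_centers + rng.uniform(-1.0, 1.0, size=n)
        log_taus = np.clip(log_taus, np.log10(b.tau[0]), np.log10(b.tau[1]))
        log_des = np.log10(span * 10.0 ** rng.uniform(-1.0, 1.5, size=n) + _LOG_DE_FLOOR)
        log_des = np.clip(
            log_des, np.log10(_LOG_DE_FLOOR), np.log10(b.delta_eps[1] + _LOG_DE_FLOOR)
        )
        eps_inf0 = np.clip(eps_tail * rng.uniform(0.05, 0.5), b.eps_inf[0], b.eps_inf[1])
        sigma_s0 = np.clip(sig_head * rng.uniform(0.0, 1.0), b.sigma_s[0], b.sigma_s[1])
        guesses.append(np.concatenate([[eps_inf0, sigma_s0], log_des, np.sort(log_taus)[::-1]]))
    return guesses


def fit_debye(spectrum: PermittivitySpectrum, config: FitConfig | None = None) -> FitResult:
    """Fit an n-pole Debye model (plus static conductivity) to a spectrum.

    Deterministic for fixed ``(spectrum, config)`` including the seed.  Raises
    ``ValueError`` when the spectrum has fewer than ``2 * (2 * n_poles + 2)``
    points (under-determined) and :class:`ConvergenceError` when every start
    fails.
    """
    config = config or FitConfig()
    n_params = 2 * config.n_poles + 2
    if len(spectrum) < 2 * n_params:
        raise ValueError(
            f"need at least {2 * n_params} frequency points to fit "
            f"{config.n_poles} poles; got {len(spectrum)}"
        )
    if np.any(spectrum.eps_r <= 0.0):
        raise ValueError("measured eps_r must be positive for relative residuals")
    if np.any(spectrum.sigma <= 0.0):
        raise ValueError("measured sigma must be positive for relative residuals")

    w = spectrum.grid.omega
    meas_eps = spectrum.eps_r
    meas_sig = spectrum.sigma
    n = config.n_poles
    b = config.bounds
    lb = np.concatenate(
        [
            [b.eps_inf[0], b.sigma_s[0]],
            np.full(n, np.log10(b.delta_eps[0] + _LOG_DE_FLOOR)),
            np.full(n, np.log10(b.tau[0])),
        ]
    )
    ub = np.concatenate(
        [
            [b.eps_inf[1], b.sigma_s[1]],
            np.full(n, np.log10(b.delta_eps[1] + _LOG_DE_FLOOR)),
            np.full(n, np.log10(b.tau[1])),
        ]
    )

    def residuals(x: np.ndarray) -> np.ndarray:
        eps, sig = _model_arrays(x, w, n)
        return np.concatenate([(eps - meas_eps) / meas_eps, (sig - meas_sig) / meas_sig])

    def jacobian(x: np.ndarray) -> np.ndarray:
        return _jacobian(x, w, n, meas_eps, meas_sig)

    best_x = None
    best_obj = np.inf
    best_idx = -1
    n_converged = 0
    for idx, x0 in enumerate(_initial_guesses(spectrum, config)):
        x0 = np.clip(x0, lb, ub)
        try:
            res = least_squares(
                residuals,
                x0,
                jac=jacobian,
                bounds=(lb, ub),
                method="trf",
                ftol=config.rel_tol,
                xtol=config.rel_tol,
                gtol=None,
                max_nfev=400 * n_params,
            )
        except Exception:
            continue
        if not res.success:
            continue
        n_converged += 1
        obj = float(np.sum(res.fun**2))
        if obj < best_obj:  # strict: ties keep the lowest start index
            best_obj, best_x, best_idx = obj, res.x, idx
    if best_x is None:
        raise ConvergenceError(
            f"none of the {config.n_starts} starts converged; "
            "check the spectrum scale or widen the bounds"
        )
    params = _unpack(best_x, n).canonical()
    err_eps, err_sig = fit_error(spectrum, params)
    return FitResult(
        params=params,
        fit_error_eps=err_eps,
        fit_error_sigma=err_sig,
        objective=best_obj,
        n_starts_converged=n_converged,
        best_start_index=best_idx,
    )


def fit_error(
    spectrum: PermittivitySpectrum, params: DebyeParameters
) -> tuple[float, float]:
    """Mean percentage difference between a model and a measured spectrum.

    The model is evaluated on the spectrum's grid and compared per quantity
    with the *measured* spectrum as the reference denominator, i.e. the
    statistic used to verify the adequacy of a fitted broadband model.
    """
    model = evaluate_model(params, spectrum.grid)
    return mean_percent_difference(model, spectrum)
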