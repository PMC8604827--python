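"""Three-compartment systemic disposition with renal elimination.

A mammillary model: central compartment (plasma + rapidly equilibrating
tissue) exchanging first-order with two peripheral compartments;
elimination is renal and acts on the central compartment only.  Amounts
are propagated analytically through the eigen-decomposition of the
(constant) rate matrix, with a plain ODE route kept as an independent
cross-check, and parameters can be estimated from concentration-time data
by weighted nonlinear least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

__all__ = [
    "SystemicPKParams",
    "mtx_pk_preset",
    "rate_matrix",
    "simulate_iv_bolus",
    "simulate_iv_bolus_ode",
    "fit_three_compartment",
    "parameter_recovery_study",
    "FitResult",
    "IdentifiabilityWarning",
]

PARAM_NAMES = ("cl_renal", "vc", "k12", "k21", "k13", "k31")


class IdentifiabilityWarning(UserWarning):
    """Raised when fitted rate constants pile up on bounds (flat directions)."""


@dataclass
class SystemicPKParams:
    """Three-compartment disposition constants, normalised per kg.

    cl_renal : renal clearance, mL/h/kg
    vc       : central volume of distribution, mL/kg
    k12/k21  : central <-> shallow peripheral rate constants, 1/h
    k13/k31  : central <-> deep peripheral rate constants, 1/h
    body_weight : kg (converts per-kg values to whole-body ones)
    """

    cl_renal: float
    vc: float
    k12: float
    k21: float
    k13: float
    k31: float
    body_weight: float

    def __post_init__(self) -> None:
        for f in PARAM_NAMES + ("body_weight",):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be strictly positive")

    @property
    def cl_total(self) -> float:
        """Whole-body clearance, mL/h."""
        return self.cl_renal * self.body_weight

    @property
    def vc_total(self) -> float:
        """Whole-body central volume, mL."""
        return self.vc * self.body_weight

    @property
    def k10(self) -> float:
        """Elimination rate constant from the central compartment, 1/h."""
        return self.cl_total / self.vc_total

    def to_dict(self) -> dict:
        return asdict(self)

    def copy_with(self, **changes) -> "SystemicPKParams":
        return replace(self, **changes)


def mtx_pk_preset(body_weight: float = 70.0) -> SystemicPKParams:
    """Methotrexate disposition in RA patients (fitted to 15 mg IV bolus data)."""
    return SystemicPKParams(
        cl_renal=84.9,   # mL/h/kg
        vc=64.34,        # mL/kg
        k12=2.74,        # 1/h
        k21=0.895,
        k13=0.196,
        k31=0.035,
        body_weight=body_weight,
    )


def rate_matrix(pk: SystemicPKParams) -> np.ndarray:
    """First-order rate matrix A (1/h) for amounts [central, periph2, periph3]."""
    k10 = pk.k10
    return np.array(
        [
            [-(k10 + pk.k12 + pk.k13), pk.k21, pk.k31],
            [pk.k12, -pk.k21, 0.0],
            [pk.k13, 0.0, -pk.k31],
        ]
    )


def _propagate(pk: SystemicPKParams, dose_mg: float, times_h: np.ndarray) -> np.ndarray:
    """Amount matrix (n_times x 3, mg) after an IV bolus, by eigen-decomposition."""
    a = rate_matrix(pk)
    eigvals, eigvecs = np.linalg.eig(a)
    coeffs = np.linalg.solve(eigvecs, np.array([dose_mg, 0.0, 0.0]))
    expo = np.exp(np.outer(times_h, eigvals))  # n_times x 3
    amounts = (expo * coeffs) @ eigvecs.T
    return np.real(amounts)


def simulate_iv_bolus(pk: SystemicPKParams, dose_mg: float, duration_h: float,
                      n_points: int = 2501, times_h: np.ndarray | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Plasma concentration trace (ng/mL) after an IV bolus.

    Returns ``(times_h, conc_ng_ml)``; the trace is analytic (matrix
    exponential through the eigenbasis), so it is exact to floating point.
    """
    if dose_mg < 0 or duration_h <= 0:
        raise ValueError("dose must be >= 0 and duration positive")
    t = np.asarray(times_h, dtype=float) if times_h is not None else np.linspace(0.0, duration_h, n_points)
    amounts = _propagate(pk, dose_mg, t)
    conc = amounts[:, 0] / pk.vc_total * 1e6  # mg/mL -> ng/mL
    return t, conc


def simulate_iv_bolus_ode(pk: SystemicPKParams, dose_mg: float, duration_h: float,
                          n_points: int = 2501) -> tuple[np.ndarray, np.ndarray]:
    """Same trace integrated numerically; kept as a cross-check of the analytic path."""
    a = rate_matrix(pk)
    t = np.linspace(0.0, duration_h, n_points)
    sol = solve_ivp(
        lambda _, y: a @ y,
        (0.0, duration_h),
        [dose_mg, 0.0, 0.0],
        method="LSODA",
        t_eval=t,
        jac=lambda _, y: a,
        rtol=1e-11,
        atol=1e-14,
    )
    if not sol.success:
        raise RuntimeError(f"IV bolus integration failed: {sol.message}")
    conc = sol.y[0] / pk.vc_total * 1e6
    return t, conc


@dataclass
class FitResult:
    params: SystemicPKParams
    cost: float
    converged: bool
    n_starts: int
    message: str
    identifiability_flags: list[str]


def _pack(pk: SystemicPKParams) -> np.ndarray:
    return np.log([pk.cl_renal, pk.vc, pk.k12, pk.k21, pk.k13, pk.k31])


def _unpack(theta: np.ndarray, body_weight: float) -> SystemicPKParams:
    vals = np.exp(theta)
    return SystemicPKParams(*vals, body_weight=body_weight)


def fit_three_compartment(
    times: np.ndarray,
    concentrations: np.ndarray,
    dose_mg: float,
    body_weight: float,
    init: SystemicPKParams,
    n_starts: int = 5,
    seed: int = 0,
    bound_span: float = 1e3,
) -> FitResult:
    """Weighted NLS fit of the six disposition parameters to plasma data.

    Residuals are scaled by the model prediction (1/y-hat^2 weighting in the
    squared objective), appropriate for concentration data spanning several
    decades.  Parameters are fitted in log space within ``bound_span``-fold
    bounds around the initial guess; a deterministic set of log-spaced
    multi-starts around ``init`` guards against local minima.  Rate
    constants that finish within 1% of a bound are reported in
    ``identifiability_flags`` and trigger an :class:`IdentifiabilityWarning`
    (typical when the data carry fewer exponential phases than the model).
    """
    times = np.asarray(times, dtype=float)
    concentrations = np.asarray(concentrations, dtype=float)
    if times.size < 6:
        raise ValueError("need at least 6 time points to fit 6 parameters")
    if np.any(concentrations <= 0):
        raise ValueError("concentrations must be strictly positive for 1/y^2 weighting")

    theta0 = _pack(init)
    lb = theta0 - np.log(bound_span)
    ub = theta0 + np.log(bound_span)

    def residuals(theta: np.ndarray) -> np.ndarray:
        pk = _unpack(theta, body_weight)
        _, pred = simulate_iv_bolus(pk, dose_mg, float(times[-1]), times_h=times)
        pred = np.maximum(pred, 1e-12)
        return (concentrations - pred) / pred

    rng = np.random.default_rng(seed)
    starts = [theta0]
    # deterministic log-spaced jitter around the initial guess
    for i in range(1, n_starts):
        starts.append(theta0 + rng.uniform(-np.log(3.0), np.log(3.0), size=6))

    best = None
    for theta_start in starts:
        theta_start = np.clip(theta_start, lb, ub)
        try:
            res = least_squares(residuals, theta_start, bounds=(lb, ub),
                                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res

    if best is None:
        raise RuntimeError("three-compartment fit failed from every start")

    fitted = _unpack(best.x, body_weight)
    flags = []
    for name, value, lo, hi in zip(PARAM_NAMES, best.x, lb, ub):
        if value - lo < 0.01 * (hi - lo) or hi - value < 0.01 * (hi - lo):
            flags.append(name)
    if flags:
        warnings.warn(
            f"fitted parameters at bounds (possible identifiability problem): {flags}",
            IdentifiabilityWarning,
            stacklevel=2,
        )
    return FitResult(
        params=fitted,
        cost=float(best.cost),
        converged=bool(best.success),
        n_starts=len(starts),
        message=str(best.message),
        identifiability_flags=flags,
    )


def parameter_recovery_study(
    truth: SystemicPKParams,
    dose_mg: float = 15.0,
    n_points: int = 12,
    t_end: float = 48.0,
    noise_cv: float = 0.10,
    n_replicates: int = 100,
    seed: int = 0,
    n_starts: int = 3,
):
    """Monte-Carlo recovery of the six disposition parameters.

    Each replicate simulates an IV bolus sampled at ``n_points`` log-spaced
    times, multiplies the concentrations by lognormal noise with coefficient
    of variation ``noise_cv``, refits from an initial guess jittered off the
    truth, and records the relative error of every parameter.  Returns a
    dict of parameter name -> array of relative errors (one per replicate);
    fully deterministic for a fixed ``seed``.
    """
    times = np.geomspace(0.05, t_end, n_points)
    _, clean = simulate_iv_bolus(truth, dose_mg, t_end, times_h=times)
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log(1.0 + noise_cv**2))
    errors: dict[str, list[float]] = {name: [] for name in PARAM_NAMES}
    for rep in range(n_replicates):
        noisy = clean * np.exp(rng.normal(-sigma**2 / 2, sigma, clean.size))
        init = _unpack(_pack(truth) + rng.uniform(-np.log(2.0), np.log(2.0), 6),
                       truth.body_weight)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", IdentifiabilityWarning)
            fit = fit_three_compartment(
                times, noisy, dose_mg, truth.body_weight, init,
                n_starts=n_starts, seed=int(rng.integers(2**31 - 1)),
            )
        for name in PARAM_NAMES:
            errors[name].append(
                getattr(fit.params, name) / getattr(truth, name) - 1.0
            )
    return {name: np.asarray(v) for name, v in errors.items()}
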