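"""Closed-form expected SNR of a multi-pattern LIF coincidence detector.

Setting
-------
N afferents fire as independent homogeneous Poisson processes at rate f,
both inside and outside of P repeating spike patterns of duration L.  A
threshold-free LIF neuron with instantaneous unitary synapses is connected
to the M afferents that fire at least once during a chosen subsection of
duration dt of at least one pattern.  At each pattern presentation every
spike is independently jittered by a uniform shift in [-T, T].

The detector quality is the signal-to-noise ratio

    SNR = (V_max - V_noise_mean) / V_noise_sd,

where V_max is the peak potential reached during a pattern presentation and
the noise moments describe the potential under pure Poisson drive.  P, L,
N, f and T are imposed; tau (membrane time constant) and dt are free, and
this module maximizes the expected SNR over them subject to the
Gaussian-regime constraint tau*f*M >= 10.

Units: the public API takes times in ms and rates in Hz, as is conventional
for these quantities; conversions happen at computation boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import optimize as _opt

__all__ = [
    "TheoryParams",
    "DetectorGeometry",
    "SNRComponents",
    "DegenerateGeometryError",
    "InfeasibleConstraintError",
    "v_max",
    "expected_M",
    "expected_r",
    "noise_stats",
    "expected_snr",
    "optimize_snr",
    "OptimumResult",
    "reduced_snr_sample",
    "ReducedSnrSample",
]

#: below this jitter half-width (ms) the zero-jitter limit of the peak
#: formula is used to avoid catastrophic cancellation in (tau/2T)*log(...)
_T_ZERO_THRESHOLD = 1e-6


class DegenerateGeometryError(ValueError):
    """Raised when a geometry connects no afferents (expected M = 0)."""


class InfeasibleConstraintError(RuntimeError):
    """Raised when no (tau, dt) satisfies the mean-input-count constraint."""


@dataclass(frozen=True)
class TheoryParams:
    """Imposed variables of the detection problem.

    Parameters
    ----------
    N : int
        Number of afferent neurons.
    f : float
        Afferent firing rate in Hz (homogeneous Poisson, identical inside
        and outside patterns).
    T : float
        Maximal jitter half-width in ms; each spike is shifted by a uniform
        draw from [-T, T] at each presentation.
    P : int
        Number of independent repeating patterns.
    L : float
        Pattern duration in ms.
    """

    N: int
    f: float
    T: float
    P: int
    L: float

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")
        if self.P < 1:
            raise ValueError(f"P must be >= 1, got {self.P}")
        if self.f <= 0:
            raise ValueError(f"f must be > 0, got {self.f}")
        if self.T < 0:
            raise ValueError(f"T must be >= 0, got {self.T}")
        if self.L <= 0:
            raise ValueError(f"L must be > 0, got {self.L}")

    @property
    def f_per_ms(self) -> float:
        return self.f / 1000.0


@dataclass(frozen=True)
class DetectorGeometry:
    """Free variables of the detector plus the derived expected counts.

    tau and dt_window are in ms; M_expected is the expected number of
    connected afferents and r_expected the expected total input rate (Hz)
    during a pattern subsection.
    """

    tau: float
    dt_window: float
    M_expected: float
    r_expected: float

    @classmethod
    def from_params(cls, params: TheoryParams, tau: float, dt_window: float) -> "DetectorGeometry":
        if tau <= 0:
            raise ValueError(f"tau must be > 0, got {tau}")
        return cls(
            tau=float(tau),
            dt_window=float(dt_window),
            M_expected=expected_M(params, dt_window),
            r_expected=expected_r(params),
        )


@dataclass(frozen=True)
class SNRComponents:
    """All terms entering the expected-SNR formula.

    v_max is the peak potential reduced to [0, 1] by normalizing between
    the noise mean and the infinite-window steady state; V quantities are
    in potential units (one input spike through a unit weight raises V
    by 1); snr_reduced = (r - f M)/sqrt(M) carries the dependence on the
    Poisson pattern realization; snr is the full expected SNR.
    """

    v_max: float
    V_noise_mean: float
    V_noise_sd: float
    V_inf: float
    snr_reduced: float
    snr: float


def v_max(dt_window, T, tau):
    """Reduced peak potential of the LIF at the end of a pattern subsection.

    The peak is normalized between the noise-period mean and the steady
    state that an infinitely long subsection would reach, so the result is
    dimensionless in [0, 1]:

        v_max = min(1, dt/2T) - (tau/2T) * log(1 - e^{-max(dt,2T)/tau}
                                                 + e^{-|dt-2T|/tau})

    For T -> 0 this reduces to the LIF charging curve 1 - e^{-dt/tau},
    which is evaluated directly below a small-T threshold.

    Parameters are in ms; scalars or broadcastable arrays.
    """
    dt_window = np.asarray(dt_window, dtype=float)
    T = np.asarray(T, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if np.any(dt_window <= 0):
        raise ValueError("dt_window must be > 0")
    if np.any(tau <= 0):
        raise ValueError("tau must be > 0")
    if np.any(T < 0):
        raise ValueError("T must be >= 0")

    dt_window, T, tau = np.broadcast_arrays(dt_window, T, tau)
    small_T = T < _T_ZERO_THRESHOLD
    T_safe = np.where(small_T, 1.0, T)

    # zero-jitter limit: plain charging curve
    limit = -np.expm1(-dt_window / tau)

    a = np.maximum(dt_window, 2.0 * T_safe) / tau
    b = np.abs(dt_window - 2.0 * T_safe) / tau
    log_arg = -np.expm1(-a) + np.exp(-b)
    general = np.minimum(1.0, dt_window / (2.0 * T_safe)) - tau / (2.0 * T_safe) * np.log(log_arg)

    out = np.where(small_T, limit, general)
    out = np.clip(out, 0.0, 1.0)
    return out if out.ndim else float(out)


def expected_M(params: TheoryParams, dt_window) -> float:
    """Expected number of connected afferents for subsection duration dt.

    An afferent is connected when it fires at least once in at least one of
    the P subsections.  With per-subsection firing probability
    p = 1 - e^{-f dt} and independent patterns,

        <M> = N (1 - (1-p)^P) = N (1 - e^{-P f dt}).
    """
    dt_window = np.asarray(dt_window, dtype=float)
    if np.any(dt_window < 0):
        raise ValueError("dt_window must be >= 0")
    if np.any(dt_window > params.L):
        raise ValueError(f"dt_window must be <= L = {params.L} ms")
    out = params.N * -np.expm1(-params.P * params.f_per_ms * dt_window)
    return out if out.ndim else float(out)


def expected_r(params: TheoryParams) -> float:
    """Expected total input rate (Hz) during a subsection: <r> = f N.

    All N afferents fire at rate f inside patterns just as outside, so the
    expected spike count in a window of length dt is f N dt.
    """
    return params.f * params.N


def noise_stats(tau: float, f: float, M: float) -> tuple[float, float]:
    """Stationary potential moments under Poisson drive through M unit synapses.

    Each input spike causes a unit jump and decays with time constant tau,
    so the potential is a shot-noise process with

        mean = tau f M,   sd = sqrt(tau f M / 2)

    (tau in ms is converted to seconds against f in Hz; the product is
    dimensionless potential units).
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if f < 0 or M < 0:
        raise ValueError("f and M must be >= 0")
    tau_s = tau / 1000.0
    mean = tau_s * f * M
    sd = float(np.sqrt(tau_s * f * M / 2.0))
    return mean, sd


def expected_snr(params: TheoryParams, geometry: DetectorGeometry) -> SNRComponents:
    """Expected SNR of the detector at a given geometry.

        <SNR> ~= v_max * sqrt(2 tau / f) * (<r> - f <M>) / sqrt(<M>)

    The approximation replaces the average of (r - fM)/sqrt(M) over Poisson
    pattern realizations by its plug-in value at <M>, <r>; see
    :func:`reduced_snr_sample` for the numerical justification.
    """
    M = geometry.M_expected
    if M <= 0:
        raise DegenerateGeometryError("expected M = 0: no afferents connected")
    r = geometry.r_expected
    tau_s = geometry.tau / 1000.0
    vm = v_max(geometry.dt_window, params.T, geometry.tau)
    mean, sd = noise_stats(geometry.tau, params.f, M)
    snr_red = (r - params.f * M) / np.sqrt(M)
    snr = vm * np.sqrt(2.0 * tau_s / params.f) * snr_red
    return SNRComponents(
        v_max=float(vm),
        V_noise_mean=float(mean),
        V_noise_sd=float(sd),
        V_inf=float(tau_s * r),
        snr_reduced=float(snr_red),
        snr=float(snr),
    )


class OptimumResult(NamedTuple):
    """Constrained-optimum geometry, its SNR components, and whether the
    mean-input-count constraint is active at the optimum."""

    geometry: DetectorGeometry
    components: SNRComponents
    constraint_active: bool


def _neg_log_snr(x: np.ndarray, params: TheoryParams) -> float:
    tau, dt = np.exp(x)
    dt = min(dt, params.L)
    geom = DetectorGeometry.from_params(params, tau, dt)
    s = expected_snr(params, geom).snr
    return -np.log(s) if s > 0 else 1e6


def _mean_inputs(tau: float, dt: float, params: TheoryParams) -> float:
    return tau / 1000.0 * params.f * expected_M(params, dt)


def optimize_snr(
    params: TheoryParams,
    min_mean_inputs: float = 10.0,
    *,
    enforce_dt_bound: bool = True,
    tau_bounds: tuple[float, float] = (0.05, 1000.0),
    dt_min: float = 1e-3,
    n_grid: int = 40,
    n_starts: int = 6,
) -> OptimumResult:
    """Maximize the expected SNR over (tau, dt_window).

    The constraint tau*f*<M> >= ``min_mean_inputs`` keeps the neuron in the
    Gaussian (many-input) regime where the SNR is a meaningful false-alarm
    proxy.  dt_window <= L is enforced unless ``enforce_dt_bound`` is False
    (the bound is inactive whenever L is large compared to the optimum).

    Strategy: coarse log-spaced grid scan to locate the basin, then
    multi-start SLSQP refinement in log-space; relative tolerance ~1e-9 in
    the objective.  Raises :class:`InfeasibleConstraintError` when no
    feasible point exists.
    """
    dt_max = params.L if enforce_dt_bound else max(params.L, 10.0 * tau_bounds[1])
    taus = np.geomspace(tau_bounds[0], tau_bounds[1], n_grid)
    dts = np.geomspace(dt_min, dt_max, n_grid)
    tt, dd = np.meshgrid(taus, dts, indexing="ij")

    Ms = params.N * -np.expm1(-params.P * params.f_per_ms * dd)
    feasible = (tt / 1000.0) * params.f * Ms >= min_mean_inputs
    if not feasible.any():
        raise InfeasibleConstraintError(
            f"no (tau, dt) grid point satisfies tau*f*<M> >= {min_mean_inputs}"
        )
    vm = v_max(dd, params.T, tt)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr_grid = vm * np.sqrt(2.0 * tt / 1000.0 / params.f) * (
            params.f * params.N - params.f * Ms
        ) / np.sqrt(Ms)
    snr_grid = np.where(feasible & np.isfinite(snr_grid), snr_grid, -np.inf)

    order = np.argsort(snr_grid, axis=None)[::-1][:n_starts]
    starts = [np.log([tt.flat[i], dd.flat[i]]) for i in order]

    log_bounds = [
        (np.log(tau_bounds[0]), np.log(tau_bounds[1])),
        (np.log(dt_min), np.log(dt_max)),
    ]
    constraints = [
        {
            "type": "ineq",
            "fun": lambda x: _mean_inputs(np.exp(x[0]), min(np.exp(x[1]), dt_max), params)
            - min_mean_inputs,
        }
    ]

    best = None
    for x0 in starts:
        res = _opt.minimize(
            _neg_log_snr,
            x0,
            args=(params,),
            method="SLSQP",
            bounds=log_bounds,
            constraints=constraints,
            options={"maxiter": 500, "ftol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res

    tau_opt, dt_opt = np.exp(best.x)
    dt_opt = min(dt_opt, dt_max)
    geom = DetectorGeometry.from_params(params, tau_opt, dt_opt)
    comps = expected_snr(params, geom)
    slack = _mean_inputs(tau_opt, dt_opt, params) - min_mean_inputs
    active = bool(slack < 1e-3 * max(min_mean_inputs, 1.0))
    return OptimumResult(geometry=geom, components=comps, constraint_active=active)


class ReducedSnrSample(NamedTuple):
    """Per-realization reduced SNR draws plus the plug-in approximation."""

    samples: np.ndarray
    n_excluded: int
    plug_in: float


def reduced_snr_sample(
    params: TheoryParams, dt_window: float, n_draws: int, seed
) -> ReducedSnrSample:
    """Sample the realization-dependent factor (r - f M)/sqrt(M) of the SNR.

    For each draw, P pattern subsections of duration dt are realized as
    Poisson spike blocks over the N afferents; M counts the afferents with
    at least one spike in at least one subsection, and r is the total spike
    count divided by the total window length P*dt (in Hz).  Draws with
    M = 0 carry no detector and are excluded (their count is reported).

    Sampling uses the equivalence between N iid Poisson counts and a
    Poisson total multinomially scattered over afferents, so cost scales
    with the number of spikes rather than with N.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    lam_total = params.N * params.P * params.f_per_ms * dt_window
    totals = rng.poisson(lam_total, size=n_draws)
    window_ms = params.P * dt_window

    samples = np.empty(n_draws, dtype=float)
    n_excluded = 0
    kept = 0
    for k in totals:
        if k == 0:
            n_excluded += 1
            continue
        afferents = rng.integers(0, params.N, size=k)
        M = np.unique(afferents).size
        r_hz = k / window_ms * 1000.0
        samples[kept] = (r_hz - params.f * M) / np.sqrt(M)
        kept += 1

    M_exp = expected_M(params, dt_window)
    plug_in = (expected_r(params) - params.f * M_exp) / np.sqrt(M_exp)
    return ReducedSnrSample(samples=samples[:kept], n_excluded=n_excluded, plug_in=float(plug_in))
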