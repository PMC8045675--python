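"""Minimal activator-inhibitor model of the MBW anthocyanin network.

The model tracks two species on an arbitrary concentration scale:

* ``a`` — the activator, a proxy for the active MBW complex driven by the
  subgroup-6 R2R3 MYB (MYB5a/NEGAN).  It is autocatalytic (the MBW complex
  up-regulates its own MYB component) with optional saturation.
* ``i`` — the inhibitor, a proxy for the R3 MYB repressor (RTO), which is
  produced downstream of the activator and sequesters bHLH partners, so it
  appears in the denominator of the autocatalytic term.

Dynamics (Gierer-Meinhardt type)::

    da/dt = f * (sigma_a + rho_a * a**2 / ((1 + kappa * a**2) * i)) - mu_a * a
    di/dt = sigma_i + rho_i * a**n_coop - mu_i * i

``f`` is the RNAi knockdown factor: it multiplies *total* activator
production (basal plus autocatalytic), modelling transcript destruction
upstream of both production routes.  ``f = 1`` is wild type.

In the ``sigma = 0``, ``kappa = 0`` limit the positive steady state has the
closed form (for cooperativity ``n``)::

    a* = (f * rho_a * mu_i / (mu_a * rho_i)) ** (1 / (n - 1))
    i* = rho_i * a***n / mu_i

so a knockdown to factor ``f`` folds the activator down by
``FC_a = (1/f)**(1/(n-1))`` and the inhibitor by ``FC_i = FC_a**n``: the
repressor always falls *more* than the activator, which is the network-level
explanation for the dramatic RTO collapse seen under a modest MYB5a
knockdown.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "NetworkParams",
    "WellMixedState",
    "SteadyState",
    "StabilityReport",
    "Trajectory",
    "rhs",
    "jacobian",
    "steady_state",
    "steady_state_branches",
    "knockdown_foldchange",
    "knockdown_scan",
    "integrate_ode",
    "linear_stability",
]

#: Floor applied to the inhibitor concentration in the autocatalytic
#: denominator so that i = 0 does not divide by zero; concentrations above
#: it are used exactly.  Fixed by design, not configurable.
I_EPSILON = 1e-12

_POSITIVE = ("rho_a", "rho_i", "mu_a", "mu_i")
_NONNEGATIVE = ("sigma_a", "sigma_i", "kappa", "D_a", "D_i")


@dataclass(frozen=True)
class NetworkParams:
    """Kinetic, saturation, diffusion and knockdown parameters.

    Rates are per unit time on the model's arbitrary concentration scale.

    Parameters
    ----------
    sigma_a, sigma_i
        Basal (activator-independent) production rates, >= 0.
    rho_a
        Autocatalytic activator production coefficient, > 0.
    rho_i
        Activator-driven inhibitor production coefficient, > 0.
    mu_a, mu_i
        First-order decay rates, > 0.
    kappa
        Saturation constant of the autocatalytic term, >= 0 (0 disables
        saturation).
    n_coop
        Cooperativity exponent of activator-driven inhibitor production,
        >= 1.
    D_a, D_i
        Diffusivities (length^2 / time), >= 0, independently settable.
    f_knockdown
        Multiplicative RNAi factor on total activator production, in (0, 1].
    """

    sigma_a: float = 0.0
    sigma_i: float = 0.0
    rho_a: float = 1.0
    rho_i: float = 1.0
    mu_a: float = 1.0
    mu_i: float = 1.0
    kappa: float = 0.0
    n_coop: float = 2.0
    D_a: float = 0.0
    D_i: float = 0.0
    f_knockdown: float = 1.0

    def __post_init__(self) -> None:
        for name in fields(self):
            value = getattr(self, name.name)
            if not math.isfinite(value):
                raise ValueError(f"parameter {name.name!r} must be finite, got {value!r}")
        for name in _POSITIVE:
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name!r} must be > 0, got {getattr(self, name)}")
        for name in _NONNEGATIVE:
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name!r} must be >= 0, got {getattr(self, name)}")
        if self.n_coop < 1:
            raise ValueError(f"n_coop must be >= 1, got {self.n_coop}")
        if not (0 < self.f_knockdown <= 1):
            raise ValueError(f"f_knockdown must lie in (0, 1], got {self.f_knockdown}")

    def with_(self, **updates: float) -> "NetworkParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **updates)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, mapping: dict) -> "NetworkParams":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise KeyError(f"unknown network parameter(s): {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})


@dataclass
class WellMixedState:
    """Activator/inhibitor concentrations at a time point (all >= 0)."""

    a: float
    i: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a) and math.isfinite(self.i) and math.isfinite(self.t)):
            raise ValueError(f"non-finite state: a={self.a}, i={self.i}, t={self.t}")
        if self.a < 0 or self.i < 0 or self.t < 0:
            raise ValueError(f"state components must be >= 0: a={self.a}, i={self.i}, t={self.t}")


@dataclass(frozen=True)
class SteadyState:
    """A homogeneous steady state of the well-mixed system.

    ``trivial`` is True when no positive activator root exists and the
    system settles at the unpigmented state ``a = 0`` (only possible with
    ``sigma_a = 0``).  ``stable`` reports linear stability to uniform
    perturbations.
    """

    a: float
    i: float
    stable: bool
    trivial: bool = False

    def __iter__(self):
        return iter((self.a, self.i))


@dataclass
class StabilityReport:
    """Linearization of the model about its homogeneous steady state.

    ``dispersion`` holds ``(k, growth_rate)`` pairs where the growth rate is
    the maximal real part of the eigenvalues of ``J - k^2 diag(D_a, D_i)``.
    ``turing_unstable`` is True iff the homogeneous state is stable to
    uniform perturbations (trace < 0, det > 0) while some ``k > 0`` mode
    grows — the diffusion-driven (Turing) instability consistent with
    spotted petal phenotypes.
    """

    homogeneous_steady_state: tuple[float, float]
    trace_J: float
    det_J: float
    dispersion: list[tuple[float, float]] = field(default_factory=list)
    turing_unstable: bool = False
    k_max: float | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.dispersion, columns=["k", "growth_rate"])


def _check_finite_state(a: float, i: float) -> None:
    if not (math.isfinite(a) and math.isfinite(i)):
        raise ValueError(f"non-finite state passed to rhs: a={a}, i={i}")


def _production_a(a: float, i: float, p: NetworkParams) -> float:
    """Total activator production f*(sigma_a + autocatalysis)."""
    auto = p.rho_a * a * a / ((1.0 + p.kappa * a * a) * np.maximum(i, I_EPSILON))
    return p.f_knockdown * (p.sigma_a + auto)


def rhs(state: WellMixedState, params: NetworkParams) -> tuple[float, float]:
    """Instantaneous derivatives (da/dt, di/dt) of the well-mixed model.

    The derivative of ``a`` at ``a = 0`` equals ``f * sigma_a >= 0``, so the
    flow never leaves the non-negative quadrant.
    """
    a, i = state.a, state.i
    _check_finite_state(a, i)
    da = _production_a(a, i, params) - params.mu_a * a
    di = params.sigma_i + params.rho_i * a ** params.n_coop - params.mu_i * i
    return da, di


def jacobian(a: float, i: float, params: NetworkParams) -> np.ndarray:
    """Analytic Jacobian of the reaction terms at (a, i)."""
    p = params
    ii = max(i, I_EPSILON)
    denom = 1.0 + p.kappa * a * a
    j11 = p.f_knockdown * p.rho_a * 2.0 * a / (denom * denom * ii) - p.mu_a
    j12 = -p.f_knockdown * p.rho_a * a * a / (denom * ii * ii)
    j21 = p.rho_i * p.n_coop * a ** (p.n_coop - 1.0) if a > 0 else (
        p.rho_i * p.n_coop if p.n_coop == 1.0 else 0.0
    )
    j22 = -p.mu_i
    return np.array([[j11, j12], [j21, j22]])


def _inhibitor_nullcline(a: float, p: NetworkParams) -> float:
    return (p.sigma_i + p.rho_i * a ** p.n_coop) / p.mu_i


def _reduced(a: float, p: NetworkParams) -> float:
    """da/dt with i slaved to its nullcline; roots are steady states."""
    i = _inhibitor_nullcline(a, p)
    return _production_a(a, i, p) - p.mu_a * a


def steady_state_branches(params: NetworkParams) -> list[SteadyState]:
    """All positive steady states, ascending in activator level.

    Found by bracketing sign changes of the reduced 1-D equation on a log
    grid spanning twelve decades, refining each bracket with Brent's
    method, and classifying stability from the Jacobian eigenvalues.
    """
    p = params
    grid = np.logspace(-12, 12, 6000)
    vals = _reduced(grid, p)  # scalar arithmetic broadcasts over the grid
    roots: list[float] = []
    sign = np.sign(vals)
    for idx in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        root = brentq(_reduced, grid[idx], grid[idx + 1], args=(p,), xtol=1e-14, rtol=1e-12)
        if root > 0 and not any(abs(root - r) <= 1e-8 * max(root, r) for r in roots):
            roots.append(root)
    # exact zeros on the grid (rare)
    for a0 in grid[vals == 0.0]:
        if a0 > 0 and not any(abs(a0 - r) <= 1e-8 * max(a0, r) for r in roots):
            roots.append(float(a0))
    out = []
    for a_star in sorted(roots):
        i_star = _inhibitor_nullcline(a_star, p)
        eig = np.linalg.eigvals(jacobian(a_star, i_star, p))
        out.append(SteadyState(a=a_star, i=i_star, stable=bool(np.max(eig.real) < 0)))
    return out


def steady_state(params: NetworkParams) -> SteadyState:
    """The biologically relevant (pigmented) homogeneous steady state.

    Returns the largest positive stable root; if no positive root is stable
    the largest positive root is returned with ``stable=False``; if no
    positive root exists at all (possible only with ``sigma_a = 0``) the
    trivial state ``(0, sigma_i / mu_i)`` is returned with ``trivial=True``.
    """
    branches = steady_state_branches(params)
    stable = [b for b in branches if b.stable]
    if stable:
        return stable[-1]
    if branches:
        return branches[-1]
    i_triv = params.sigma_i / params.mu_i
    eig = np.linalg.eigvals(jacobian(0.0, i_triv, params))
    return SteadyState(a=0.0, i=i_triv, stable=bool(np.max(eig.real) < 0), trivial=True)


def knockdown_foldchange(params: NetworkParams, f: float) -> tuple[float, float]:
    """Fold-down of activator and inhibitor under knockdown to factor ``f``.

    ``FC_x = x*(f=1) / x*(f)``, both >= 1 for f <= 1.  If the perturbed
    system collapses to the trivial state, both fold-downs are reported as
    ``inf`` — total pattern/pigment loss, the strong-RNAi phenotype.

    In the sigma = 0, kappa = 0 limit the closed form gives
    ``FC_i = FC_a ** n_coop``: any knockdown of the activator is amplified
    into a larger collapse of the repressor.
    """
    if not (0 < f <= 1):
        raise ValueError(f"knockdown factor must lie in (0, 1], got {f}")
    base = steady_state(params.with_(f_knockdown=1.0))
    if base.trivial or base.a <= 0:
        raise ValueError("baseline (f=1) system has no positive steady state")
    pert = steady_state(params.with_(f_knockdown=f))
    if pert.trivial or pert.a <= 0:
        return math.inf, math.inf
    return base.a / pert.a, base.i / pert.i


def knockdown_scan(params: NetworkParams, f_values: Sequence[float]):
    """Fold-down table over a grid of knockdown factors.

    Returns a DataFrame with columns f, a_star, i_star, FC_a, FC_i,
    amplification (FC_i / FC_a).
    """
    import pandas as pd

    rows = []
    base = steady_state(params.with_(f_knockdown=1.0))
    for f in f_values:
        ss = steady_state(params.with_(f_knockdown=float(f)))
        if ss.trivial or ss.a <= 0:
            fca = fci = math.inf
        else:
            fca, fci = base.a / ss.a, base.i / ss.i
        amp = fci / fca if math.isfinite(fca) and fca > 0 else math.nan
        rows.append(
            {"f": float(f), "a_star": ss.a, "i_star": ss.i, "FC_a": fca, "FC_i": fci,
             "amplification": amp}
        )
    return pd.DataFrame(rows)


@dataclass
class Trajectory:
    """Time course of the well-mixed model at uniform output times."""

    t: np.ndarray
    a: np.ndarray
    i: np.ndarray

    def __len__(self) -> int:
        return len(self.t)

    def state(self, idx: int) -> WellMixedState:
        return WellMixedState(a=float(self.a[idx]), i=float(self.i[idx]), t=float(self.t[idx]))

    @property
    def terminal(self) -> WellMixedState:
        return self.state(len(self) - 1)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t": self.t, "a": self.a, "i": self.i})


def integrate_ode(
    params: NetworkParams,
    init: WellMixedState,
    t_end: float,
    dt: float,
    params_schedule: Sequence[tuple[float, NetworkParams]] | None = None,
) -> Trajectory:
    """Integrate the well-mixed model, sampling every ``dt``.

    Uses a stiffness-switching implicit solver (LSODA, rtol 1e-8).
    ``params_schedule`` optionally lists ``(t_switch, new_params)`` events,
    e.g. an RNAi induction switching ``f`` mid-run; segments are integrated
    piecewise so the discontinuity is honored exactly.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if t_end < dt:
        raise ValueError(f"t_end must be >= dt, got t_end={t_end}, dt={dt}")

    events = sorted(params_schedule or [], key=lambda e: e[0])
    segments: list[tuple[float, float, NetworkParams]] = []
    t0, p = init.t, params
    for t_sw, new_p in events:
        if t0 < t_sw < init.t + t_end:
            segments.append((t0, t_sw, p))
            t0, p = t_sw, new_p
    segments.append((t0, init.t + t_end, p))

    def f(_t, y, pp):
        return rhs(WellMixedState(a=max(y[0], 0.0), i=max(y[1], 0.0), t=_t), pp)

    ts = [np.array([init.t])]
    ys = [np.array([[init.a], [init.i]])]
    y0 = [init.a, init.i]
    for seg_t0, seg_t1, seg_p in segments:
        t_eval = np.arange(seg_t0, seg_t1 + 0.5 * dt, dt)
        t_eval = t_eval[(t_eval > seg_t0) & (t_eval <= seg_t1)]
        sol = solve_ivp(
            f, (seg_t0, seg_t1), y0, method="LSODA", rtol=1e-8, atol=1e-12,
            t_eval=t_eval if len(t_eval) else None, args=(seg_p,),
        )
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise RuntimeError(
                f"integration failed on [{seg_t0}, {seg_t1}] (dt={dt}): {sol.message}; "
                f"try a smaller dt or check parameter magnitudes"
            )
        ts.append(sol.t)
        ys.append(sol.y)
        y0 = sol.y[:, -1]
    t = np.concatenate(ts)
    y = np.concatenate(ys, axis=1)
    # clip solver round-off excursions below zero
    return Trajectory(t=t, a=np.maximum(y[0], 0.0), i=np.maximum(y[1], 0.0))


def linear_stability(params: NetworkParams, k_grid: Sequence[float]) -> StabilityReport:
    """Linear (Turing) stability analysis about the homogeneous steady state.

    For each wavenumber ``k`` the growth rate is the maximal real part of
    the eigenvalues of ``J - k^2 diag(D_a, D_i)``.  The Turing flag requires
    a homogeneous state that is stable without diffusion (trace < 0,
    det > 0) yet has a growing mode at some ``k > 0``.
    """
    ss = steady_state(params)
    if ss.trivial and ss.a == 0.0 and params.sigma_a == 0.0 and ss.i == 0.0:
        # fully trivial system: nothing to linearize against
        return StabilityReport(
            homogeneous_steady_state=(0.0, 0.0), trace_J=0.0, det_J=0.0,
            dispersion=[], turing_unstable=False, k_max=None,
        )
    J = jacobian(ss.a, ss.i, params)
    trace = float(np.trace(J))
    det = float(np.linalg.det(J))
    if ss.trivial:
        return StabilityReport(
            homogeneous_steady_state=(ss.a, ss.i), trace_J=trace, det_J=det,
            dispersion=[], turing_unstable=False, k_max=None,
        )
    D = np.diag([params.D_a, params.D_i])
    dispersion: list[tuple[float, float]] = []
    for k in k_grid:
        eig = np.linalg.eigvals(J - (k * k) * D)
        dispersion.append((float(k), float(np.max(eig.real))))
    homog_stable = trace < 0 and det > 0
    positive_k = [(k, g) for k, g in dispersion if k > 0]
    turing = bool(homog_stable and positive_k and max(g for _, g in positive_k) > 0)
    k_max = max(positive_k, key=lambda kg: kg[1])[0] if turing else None
    return StabilityReport(
        homogeneous_steady_state=(ss.a, ss.i), trace_J=trace, det_J=det,
        dispersion=dispersion, turing_unstable=turing, k_max=k_max,
    )
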