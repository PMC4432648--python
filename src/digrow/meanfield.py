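"""Mean-field kinetics and linear stability analysis of the lattice model.

Averaging the master equation of the seven elementary processes over an
ensemble of realisations, and factorising joint occupancies
``<A_i B_j> ~ <A_i><B_j>`` (the mean-field hypothesis), yields closed
kinetic equations for the average occupations x (xanthophores) and m
(melanophores).  With the neighborhood-average convention for the
neighbor-mediated processes, the homogeneous kinetics are

    dx/dt = b_X*s - d_X*x - s_M*x*m
    dm/dt = b_M*s - d_M*m - s_X*m*x + l_X*s*x,      s = 1 - x - m.

For a 1-D lattice, a plane-wave perturbation exp(i k a j) about a
homogeneous steady state picks up a factor cos(k a) on every short-range
neighbor-mediated coupling and cos(k h a) on the long-range one
(LATTICE mode).  Truncating these factors at second order in the lattice
spacing a, cos(z) -> 1 - z^2/2, gives the continuum PDE limit in which the
nonlocal interactions appear as cross-diffusion-like terms (CONTINUUM
mode).  The Turing bifurcation point, critical wavenumber and wavelength
follow from the leading eigenvalue w(k) of the resulting 2x2 problem.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .model import ModelParams

__all__ = [
    "MeanFieldState",
    "DispersionResult",
    "BifurcationPoint",
    "NoTuringBifurcation",
    "kinetics",
    "homogeneous_steady_states",
    "mixed_state",
    "jacobian_k",
    "growth_rate",
    "max_growth",
    "critical_h",
    "critical_h_closed_form",
    "bifurcation_diagram",
    "integrate_lattice_meanfield",
]

LATTICE = "lattice"
CONTINUUM = "continuum"


@dataclass(frozen=True)
class MeanFieldState:
    """Homogeneous average occupations and their admissibility."""

    x: float
    m: float
    admissible: bool
    label: str  # ALL_X | ALL_M | MIXED | OTHER

    @property
    def s(self) -> float:
        return 1.0 - self.x - self.m


@dataclass
class DispersionResult:
    """Growth rate w(k) over a wavenumber grid."""

    mode: str
    k_grid: np.ndarray
    omega: np.ndarray
    params: ModelParams
    base_state: MeanFieldState


@dataclass(frozen=True)
class BifurcationPoint:
    """Turing bifurcation: critical distance, wavenumber and wavelength."""

    h_T: float
    k_T: float
    lambda_T: float


@dataclass(frozen=True)
class NoTuringBifurcation:
    """Returned when no Turing bifurcation exists in the scanned range."""

    reason: str


def kinetics(state: MeanFieldState | tuple, params: ModelParams) -> tuple[float, float]:
    """Homogeneous mean-field rates (dx/dt, dm/dt)."""
    x, m = (state.x, state.m) if isinstance(state, MeanFieldState) else state
    s = 1.0 - x - m
    dx = params.b_X * s - params.d_X * x - params.s_M * x * m
    dm = params.b_M * s - params.d_M * m - params.s_X * m * x + params.l_X * s * x
    return dx, dm


def _label(x: float, m: float, tol: float = 1e-9) -> str:
    if abs(x - 1.0) < tol and abs(m) < tol:
        return "ALL_X"
    if abs(x) < tol and abs(m - 1.0) < tol:
        return "ALL_M"
    if x > tol and m > -tol and x + m <= 1.0 + tol:
        return "MIXED"
    return "OTHER"


def _make_state(x: float, m: float, label: str | None = None) -> MeanFieldState:
    admissible = (x >= -1e-12) and (m >= -1e-12) and (x + m <= 1.0 + 1e-12)
    return MeanFieldState(x=x, m=m, admissible=admissible,
                          label=label if label is not None else _label(x, m))


def mixed_state(params: ModelParams) -> MeanFieldState:
    """The mixed (coexistence) steady state of the simplified regime:
    x* = b_X/l_X, m* = (l_X - b_X)/(s + l_X); admissible iff l_X >= b_X."""
    if not params.is_simplified_regime:
        raise ValueError("closed-form mixed state requires the simplified regime")
    if params.l_X == 0:
        raise ValueError("mixed state degenerate at l_X = 0")
    s = params.s_X
    x = params.b_X / params.l_X
    m = (params.l_X - params.b_X) / (s + params.l_X)
    return _make_state(x, m, "MIXED")


def homogeneous_steady_states(params: ModelParams) -> list[MeanFieldState]:
    """All homogeneous steady states of the mean-field kinetics.

    In the simplified regime (d_X = d_M = b_M = 0, s_X = s_M) this is the
    exact triple {all-X, mixed, all-M}; the mixed state is admissible iff
    l_X >= b_X.  In the general case the stationarity system is solved
    numerically (polynomial elimination via sympy) and all real solutions
    are returned with admissibility flags.
    """
    if params.is_simplified_regime:
        out = [_make_state(1.0, 0.0, "ALL_X")]
        if params.l_X > 0:
            out.append(mixed_state(params))
        out.append(_make_state(0.0, 1.0, "ALL_M"))
        return out

    import sympy as sp

    x, m = sp.symbols("x m", real=True)
    s = 1 - x - m
    dx = params.b_X * s - params.d_X * x - params.s_M * x * m
    dm = params.b_M * s - params.d_M * m - params.s_X * m * x + params.l_X * s * x
    sols = sp.solve([sp.nsimplify(dx, rational=False), sp.nsimplify(dm, rational=False)],
                    [x, m], dict=True)
    out: list[MeanFieldState] = []
    for sol in sols:
        xv, mv = sp.nsimplify(sol[x]), sp.nsimplify(sol[m])
        xc, mc = complex(sp.N(xv)), complex(sp.N(mv))
        if abs(xc.imag) > 1e-9 or abs(mc.imag) > 1e-9:
            continue
        out.append(_make_state(float(xc.real), float(mc.real)))
    return out


def _nonlocal_factors(params: ModelParams, k: float, mode: str, h: float | None):
    ka = k * params.a
    kha = k * (params.h if h is None else h) * params.a
    if mode == LATTICE:
        return math.cos(ka), math.cos(kha)
    if mode == CONTINUUM:
        return 1.0 - ka * ka / 2.0, 1.0 - kha * kha / 2.0
    raise ValueError(f"unknown mode {mode!r}")


def jacobian_k(
    base: MeanFieldState,
    params: ModelParams,
    k: float,
    mode: str = LATTICE,
    h: float | None = None,
    check_stationary: bool = True,
) -> np.ndarray:
    """1-D linear-stability matrix J(k) about a homogeneous steady state.

    The Fourier factor c1 = cos(ka) (or its O(a^2) truncation) multiplies
    exactly the terms where the perturbed variable is a short-range
    *neighbor* occupancy; ch = cos(kha) multiplies the long-range
    activation term.  ``h`` may override ``params.h`` with a continuous
    value (the analysis treats the interaction distance as real).
    """
    if check_stationary:
        dx, dm = kinetics(base, params)
        if abs(dx) > 1e-8 or abs(dm) > 1e-8:
            raise ValueError(f"base state is not stationary: residual ({dx}, {dm})")
    x, m = base.x, base.m
    sig = 1.0 - x - m
    c1, ch = _nonlocal_factors(params, k, mode, h)
    j11 = -params.b_X - params.d_X - params.s_M * m
    j12 = -params.b_X - params.s_M * x * c1
    j21 = -params.b_M - params.s_X * m * c1 + params.l_X * (sig * ch - x)
    j22 = -params.b_M - params.d_M - params.s_X * x - params.l_X * x
    return np.array([[j11, j12], [j21, j22]])


def growth_rate(
    params: ModelParams,
    k: float,
    mode: str = LATTICE,
    base: MeanFieldState | None = None,
    h: float | None = None,
) -> float:
    """Leading (largest real part) eigenvalue of J(k); real part returned."""
    if base is None:
        base = mixed_state(params)
    jac = jacobian_k(base, params, k, mode, h=h)
    tr = jac[0, 0] + jac[1, 1]
    det = jac[0, 0] * jac[1, 1] - jac[0, 1] * jac[1, 0]
    disc = tr * tr - 4.0 * det
    if disc >= 0.0:
        return 0.5 * (tr + math.sqrt(disc))
    return 0.5 * tr


@dataclass(frozen=True)
class MaxGrowth:
    k_star: float
    omega_star: float
    boundary: bool = False   # maximum found at the edge of the scan range
    degenerate: bool = False  # several k share the global maximum


def max_growth(
    params: ModelParams,
    mode: str = LATTICE,
    base: MeanFieldState | None = None,
    h: float | None = None,
    n_grid: int = 10_000,
) -> MaxGrowth:
    """Global maximiser of w(k) over k > 0 (dense scan + local refinement).

    LATTICE mode scans (0, pi/a] (w is 2*pi/a-periodic and even in k);
    CONTINUUM mode extends the scan range until the maximum is interior.
    Degenerate multiple maxima (possible in LATTICE mode through cos(kha)
    harmonics) return the smallest maximising k.
    """
    if base is None:
        base = mixed_state(params)
    jacobian_k(base, params, 0.0, mode, h=h)  # validates stationarity once

    def omega(k: float) -> float:
        return growth_rate(params, k, mode, base, h=h)

    k_hi = math.pi / params.a
    boundary = False
    for _ in range(8):
        ks = np.linspace(k_hi / n_grid, k_hi, n_grid)
        om = np.array([omega(k) for k in ks])
        i = int(np.argmax(om))
        if mode == CONTINUUM and i == n_grid - 1:
            k_hi *= 2.0
            continue
        break
    else:
        boundary = True

    # local refinement on the bracketing interval
    lo = ks[max(i - 1, 0)]
    hi = ks[min(i + 1, n_grid - 1)]
    res = minimize_scalar(lambda k: -omega(k), bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-8})
    k_star, om_star = float(res.x), float(-res.fun)
    if om[i] > om_star:
        k_star, om_star = float(ks[i]), float(om[i])

    # degenerate maxima: any other local max within 1e-10 of the global one
    degenerate = False
    interior = (om[1:-1] >= om[:-2]) & (om[1:-1] >= om[2:])
    for j in np.nonzero(interior)[0] + 1:
        if j != i and om_star - om[j] < 1e-10:
            degenerate = True
            if ks[j] < k_star:
                k_star, om_star = float(ks[j]), float(om[j])
    if i in (0, n_grid - 1) and mode == LATTICE:
        boundary = i == 0  # pi/a is a legitimate interior point of the band
    return MaxGrowth(k_star, om_star, boundary=boundary, degenerate=degenerate)


def dispersion(
    params: ModelParams,
    mode: str = LATTICE,
    base: MeanFieldState | None = None,
    h: float | None = None,
    k_grid: np.ndarray | None = None,
) -> DispersionResult:
    """Tabulate w(k) over a wavenumber grid (default (0, pi/a], 2000 pts)."""
    if base is None:
        base = mixed_state(params)
    if k_grid is None:
        k_grid = np.linspace(1e-4, math.pi / params.a, 2000)
    om = np.array([growth_rate(params, k, mode, base, h=h) for k in k_grid])
    return DispersionResult(mode=mode, k_grid=np.asarray(k_grid, float), omega=om,
                            params=params, base_state=base)


def _quadratic_det_coeffs(params: ModelParams, h: float):
    """Coefficients of det J(k) = alpha - beta*u - gamma*u^2 (u = k^2) in the
    simplified CONTINUUM regime."""
    base = mixed_state(params)
    x, m, sig = base.x, base.m, base.s
    a2 = params.a * params.a
    s = params.s_X
    j11 = -params.b_X - s * m
    j22 = -(s + params.l_X) * x
    p0 = -params.b_X - s * x
    p1 = s * x * a2 / 2.0
    q0 = -s * m + params.l_X * (sig - x)
    q1 = a2 / 2.0 * (s * m - params.l_X * sig * h * h)
    alpha = j11 * j22 - p0 * q0
    beta = p0 * q1 + p1 * q0
    gamma = p1 * q1
    return alpha, -beta, -gamma  # det(u) = alpha - beta*u - gamma*u^2


def critical_h_closed_form(params: ModelParams) -> BifurcationPoint | NoTuringBifurcation:
    """Turing point of the simplified CONTINUUM regime in closed form.

    With u = k^2 the determinant of J(k) is the downward-opening-free
    quadratic det(u) = alpha - beta(h)*u - gamma(h)*u^2 whose minimum first
    touches zero at the bifurcation.  Since the trace is k-independent and
    negative, w(k) crosses zero exactly when det does, so the double-root
    (zero discriminant) condition beta^2 + 4*alpha*gamma = 0 defines h_T.
    In the simplified regime both beta and gamma are linear in w = h^2 - 1,
    making the condition a quadratic in w solved here explicitly; the
    critical wavenumber is k_T^2 = beta / (2*|gamma|).
    """
    if not params.is_simplified_regime:
        raise ValueError("closed form requires the simplified regime")
    if params.l_X < params.b_X or params.l_X <= 0:
        return NoTuringBifurcation("mixed state inadmissible: l_X < b_X")
    base = mixed_state(params)
    x, m = base.x, base.m
    s = params.s_X
    a2 = params.a * params.a
    b = params.b_X
    p0_abs = b + s * x
    p1 = s * x * a2 / 2.0
    Q = a2 * s * m / 2.0          # q1 = -Q*(h^2 - 1), since l_X*sigma* = s*m*
    alpha = (b + s * m) * (s + params.l_X) * x - p0_abs * b
    if Q == 0.0 or alpha <= 0.0:
        return NoTuringBifurcation("degenerate mixed state (l_X = b_X or alpha <= 0)")
    # (p0_abs*Q*w - p1*b)^2 - 4*alpha*p1*Q*w = 0, w = h^2 - 1
    A2 = (p0_abs * Q) ** 2
    A1 = -(2.0 * p0_abs * Q * p1 * b + 4.0 * alpha * p1 * Q)
    A0 = (p1 * b) ** 2
    disc = A1 * A1 - 4.0 * A2 * A0
    if disc < 0:
        return NoTuringBifurcation("double-root condition has no real solution")
    roots = sorted(((-A1 + sg * math.sqrt(disc)) / (2.0 * A2) for sg in (-1.0, 1.0)))
    for w in roots:  # smallest valid h first
        if w <= 0:
            continue
        beta = p0_abs * Q * w - p1 * b
        gamma_abs = p1 * Q * w
        if beta <= 0 or gamma_abs <= 0:
            continue  # minimum of det(u) not at positive u: no Turing point
        kT = math.sqrt(beta / (2.0 * gamma_abs))
        hT = math.sqrt(w + 1.0)
        return BifurcationPoint(h_T=hT, k_T=kT, lambda_T=2.0 * math.pi / kT)
    return NoTuringBifurcation("no root of the double-root condition yields k_T > 0")


def critical_h(
    params: ModelParams,
    mode: str = CONTINUUM,
    h_max: float = 100.0,
    rtol: float = 1e-6,
) -> BifurcationPoint | NoTuringBifurcation:
    """Smallest h > 1 at which max_k w(k) = 0 with maximiser k_T != 0.

    Treats h as a continuous parameter and bisects on the sign of the
    maximal growth rate; independent of (and tested against) the closed
    form of :func:`critical_h_closed_form`.
    """
    try:
        base = mixed_state(params)
    except ValueError as exc:
        return NoTuringBifurcation(str(exc))
    if not base.admissible or params.l_X <= params.b_X:
        return NoTuringBifurcation("mixed state inadmissible or marginal: l_X <= b_X")
    if growth_rate(params, 0.0, mode, base) >= 0:
        return NoTuringBifurcation("homogeneous state already unstable at k=0")

    def f(h: float) -> float:
        return max_growth(params, mode, base, h=h, n_grid=2000).omega_star

    h_lo = 1.0 + 1e-6
    if f(h_lo) > 0:
        return NoTuringBifurcation("unstable already at h -> 1")
    h_hi = None
    h = 2.0
    while h <= h_max:
        if f(h) > 0:
            h_hi = h
            break
        h_lo = h
        h *= 1.5
    if h_hi is None:
        return NoTuringBifurcation(f"no Turing bifurcation for h <= {h_max}")
    h_T = brentq(f, h_lo, h_hi, rtol=rtol)
    mg = max_growth(params, mode, base, h=h_T, n_grid=4000)
    if mg.k_star <= 1e-6:
        return NoTuringBifurcation("instability occurs at k = 0 (not a Turing mode)")
    return BifurcationPoint(h_T=float(h_T), k_T=mg.k_star,
                            lambda_T=2.0 * math.pi / mg.k_star)


def bifurcation_diagram(l_X_grid, params: ModelParams, mode: str = CONTINUUM):
    """Tabulate (l_X, h_T, k_T, lambda_T, lambda_T/2) over a grid of l_X.

    Grid points without a Turing bifurcation carry NaNs and
    ``bifurcation=False`` (e.g. l_X < b_X, mixed state inadmissible).
    Returns a pandas DataFrame.
    """
    import pandas as pd

    rows = []
    for l in l_X_grid:
        p = params.replace(l_X=float(l))
        res = critical_h(p, mode=mode)
        if isinstance(res, BifurcationPoint):
            rows.append(dict(l_X=float(l), h_T=res.h_T, k_T=res.k_T,
                             lambda_T=res.lambda_T, half_lambda=res.lambda_T / 2,
                             bifurcation=True, note=""))
        else:
            rows.append(dict(l_X=float(l), h_T=np.nan, k_T=np.nan,
                             lambda_T=np.nan, half_lambda=np.nan,
                             bifurcation=False, note=res.reason))
    return pd.DataFrame(rows)


def integrate_lattice_meanfield(
    x0_field: np.ndarray,
    m0_field: np.ndarray,
    params: ModelParams,
    t_end: float,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the site-wise mean-field ODEs on a 1-D ring (method of
    lines); the deterministic counterpart of the KMC.

    The vector field leaves the simplex {x,m >= 0, x+m <= 1} invariant, so
    with tight tolerances the solution stays in bounds without clipping;
    bound violations beyond integration error raise.
    """
    x0 = np.asarray(x0_field, dtype=float)
    m0 = np.asarray(m0_field, dtype=float)
    if x0.ndim != 1 or x0.shape != m0.shape:
        raise ValueError("fields must be matching 1-D arrays")
    if (x0 < 0).any() or (m0 < 0).any() or (x0 + m0 > 1).any():
        raise ValueError("initial fields must satisfy 0 <= x, m and x + m <= 1")
    n = x0.size
    h = params.h

    def rhs(_t, y):
        x = y[:n]
        m = y[n:]
        sig = 1.0 - x - m
        m_nb = 0.5 * (np.roll(m, 1) + np.roll(m, -1))
        x_nb = 0.5 * (np.roll(x, 1) + np.roll(x, -1))
        x_lr = 0.5 * (np.roll(x, h) + np.roll(x, -h))
        dx = params.b_X * sig - params.d_X * x - params.s_M * x * m_nb
        dm = (params.b_M * sig - params.d_M * m - params.s_X * m * x_nb
              + params.l_X * sig * x_lr)
        return np.concatenate([dx, dm])

    from scipy.integrate import solve_ivp

    sol = solve_ivp(rhs, (0.0, float(t_end)), np.concatenate([x0, m0]),
                    method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"mean-field integration failed: {sol.message}")
    x, m = sol.y[:n, -1], sol.y[n:, -1]
    tol = 1e-6
    if (x < -tol).any() or (m < -tol).any() or (x + m > 1 + tol).any():
        raise RuntimeError("integration left the admissible simplex")
    return x, m
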