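"""Biphasic and tensile mechanics of cartilage constructs.

Compression: a cylindrical disk of biphasic material (porous linear
elastic solid saturated with fluid, both constituents incompressible) is
compressed axially between frictionless impermeable platens; fluid
exudes radially through the free edge.  The axial stress for a ramp-hold
strain history is obtained from the classical radial-flow series
solution, and the three material constants — Young's modulus E of the
solid matrix, Poisson's ratio nu, and hydraulic permeability k — are
recovered from measured stress-relaxation records by bounded nonlinear
least squares.

Model summary.  With mu = E/(2(1+nu)) and aggregate modulus
H_A = E(1-nu)/((1+nu)(1-2nu)), the radial dilatation obeys a diffusion
equation with gel diffusivity c = H_A*k.  Separation of variables gives
eigenfunctions J1(alpha_n r/a) whose eigenvalues solve

    J1(alpha) = ((1-nu)/(1-2nu)) * alpha * J0(alpha),

and the stress response to a step strain eps0 is

    sigma(t) = eps0 [ E + mu (1-2nu) sum_n g_n exp(-t/tau_n) ],
    tau_n = a^2 / (H_A k alpha_n^2),
    g_n = 2 J2(alpha_n) J1(alpha_n) / (alpha_n D_n),
    D_n = (J0(alpha_n) - J1(alpha_n)/alpha_n)^2 + (1 - 1/alpha_n^2) J1(alpha_n)^2,

with sum_n g_n = 1, so sigma(0+) = 3 mu eps0 (instantaneous,
incompressible response) and sigma(inf) = E eps0 (drained equilibrium).
Ramp loading is handled by Duhamel superposition of the step response,
which is closed-form because each mode relaxes exponentially.

Tension: Young's modulus is the ordinary-least-squares slope of the
linear portion of the stress-strain curve, with an automatic search for
the most linear contiguous window.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import optimize, special
from scipy.linalg import lu_factor, lu_solve

__all__ = [
    "RampHoldProtocol",
    "BiphasicParams",
    "StressRecord",
    "TensileRecord",
    "FitDiagnostics",
    "LinearityError",
    "FitFailureError",
    "biphasic_forward",
    "biphasic_forward_fd",
    "fit_biphasic",
    "youngs_modulus_tensile",
]


class LinearityError(ValueError):
    """No sufficiently linear region found in a tensile record."""


class FitFailureError(RuntimeError):
    """Biphasic fit did not converge; carries the best iterate."""

    def __init__(self, message: str, best: "BiphasicParams | None" = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class RampHoldProtocol:
    """Ramp-hold unconfined-compression protocol.

    applied_strain is the final engineering strain magnitude (e.g. 0.1
    for 10% compression) reached after ``ramp_duration`` seconds and held
    for ``hold_duration`` seconds.  Geometry in meters.
    """

    applied_strain: float
    ramp_duration: float  # s
    hold_duration: float  # s
    specimen_radius: float  # m
    specimen_height: float  # m

    def __post_init__(self) -> None:
        if not 0 < self.applied_strain < 0.5:
            raise ValueError("applied_strain must lie in (0, 0.5)")
        if min(self.ramp_duration, self.hold_duration) <= 0:
            raise ValueError("durations must be positive")
        if min(self.specimen_radius, self.specimen_height) <= 0:
            raise ValueError("geometry must be positive")

    def time_grid(self, n: int = 400) -> np.ndarray:
        """Default evaluation grid covering ramp and hold."""
        return np.linspace(0.0, self.ramp_duration + self.hold_duration, n)


@dataclass(frozen=True)
class BiphasicParams:
    """Material constants of the biphasic solid."""

    youngs_modulus: float  # kPa
    poisson_ratio: float  # dimensionless, [0, 0.5)
    permeability: float  # m^4/(N s)

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise ValueError("youngs_modulus must be positive")
        if not 0.0 <= self.poisson_ratio < 0.5:
            raise ValueError("poisson_ratio must lie in [0, 0.5)")
        if self.permeability <= 0:
            raise ValueError("permeability must be positive")


@dataclass
class StressRecord:
    """Measured stress history of a stress-relaxation test."""

    time: np.ndarray  # s
    stress: np.ndarray  # kPa

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.time.shape != self.stress.shape or self.time.ndim != 1:
            raise ValueError("time and stress must be equal-length 1-D sequences")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class TensileRecord:
    """Stress-strain curve from a strain-to-failure tensile test."""

    strain: np.ndarray
    stress: np.ndarray  # kPa
    gauge_length: float = np.nan  # mm

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.strain.shape != self.stress.shape or self.strain.ndim != 1:
            raise ValueError("strain and stress must be equal-length 1-D sequences")


@dataclass(frozen=True)
class FitDiagnostics:
    residual_norm: float
    converged: bool
    low_confidence: bool = False
    message: str = ""


# ---------------------------------------------------------------------------
# series solution


@lru_cache(maxsize=64)
def _eigenvalues(nu: float, n_roots: int) -> tuple[float, ...]:
    """Positive roots of J1(a) - ((1-nu)/(1-2nu)) a J0(a) = 0.

    Roots are simple and asymptotically pi-spaced; a fine sign-change
    scan followed by Brent refinement finds the first ``n_roots``.
    """
    A = (1.0 - nu) / (1.0 - 2.0 * nu)

    def f(a):
        return special.j1(a) - A * a * special.j0(a)

    # 50 roots live below ~ (n_roots + 2) * pi
    grid = np.arange(1e-9, (n_roots + 3) * np.pi, 0.01)
    vals = f(grid)
    sign_change = np.nonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]
    roots = []
    for i in sign_change:
        r = optimize.brentq(f, grid[i], grid[i + 1], xtol=1e-12, rtol=1e-14)
        if r > 1e-6:
            roots.append(r)
        if len(roots) == n_roots:
            break
    if len(roots) < n_roots:
        raise RuntimeError(f"found only {len(roots)} of {n_roots} eigenvalues (nu={nu})")
    return tuple(roots)


def _mode_weights(nu: float, n_roots: int) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues alpha_n and dimensionless stress weights g_n."""
    alpha = np.array(_eigenvalues(round(nu, 12), n_roots))
    j0, j1 = special.j0(alpha), special.j1(alpha)
    j2 = special.jv(2, alpha)
    D = (j0 - j1 / alpha) ** 2 + (1.0 - 1.0 / alpha**2) * j1**2
    g = 2.0 * j2 * j1 / (alpha * D)
    return alpha, g


def _elastic_constants(p: BiphasicParams) -> tuple[float, float, float]:
    """(E, mu, H_A) in Pa."""
    E = p.youngs_modulus * 1e3
    nu = p.poisson_ratio
    mu = E / (2.0 * (1.0 + nu))
    H_A = E * (1.0 - nu) / ((1.0 + nu) * (1.0 - 2.0 * nu))
    return E, mu, H_A


def biphasic_forward(
    p: BiphasicParams,
    proto: RampHoldProtocol,
    t: np.ndarray,
    n_roots: int = 50,
) -> np.ndarray:
    """Axial stress history (kPa) of the biphasic disk under ramp-hold strain.

    The series is truncated at ``n_roots`` modes; the omitted tail is
    bounded by the geometric decay of g_n exp(-t/tau_n) and checked to be
    below 0.1% of the equilibrium stress at the first evaluated time
    (the ramp smooths the early-time response, where truncation bites).

    Raises a numeric error for parameter combinations whose series does
    not converge in the truncation budget.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0):
        raise ValueError("time grid must be non-negative")
    E, mu, H_A = _elastic_constants(p)
    a = proto.specimen_radius
    eps0 = proto.applied_strain
    tr = proto.ramp_duration
    rate = eps0 / tr
    alpha, g = _mode_weights(p.poisson_ratio, n_roots)
    tau = a**2 / (H_A * p.permeability * alpha**2)  # s, per mode

    # strain history
    eps_t = np.where(t < tr, rate * t, eps0)

    # Duhamel superposition of the exponential step response over the ramp:
    #  t <= tr:  sum g_n tau_n (1 - exp(-t/tau_n)) * rate
    #  t >  tr:  sum g_n tau_n (exp(-(t-tr)/tau_n) - exp(-t/tau_n)) * rate
    T = t[:, None]
    during = T <= tr
    # exponent clipped at 0: the ramp branch of the where() would otherwise
    # overflow harmlessly for T << tr
    decay = np.where(
        during,
        -np.expm1(-T / tau),
        np.exp(np.minimum(-(T - tr) / tau, 0.0)) - np.exp(-T / tau),
    )
    transient = mu * (1.0 - 2.0 * p.poisson_ratio) * rate * (decay * (g * tau)).sum(axis=1)

    # truncation check: mode weights g_n decay ~ 1/alpha_n^2; the last
    # retained weight must be a small fraction of their sum (ramp loading
    # already smooths the early-time response where truncation bites)
    tail_frac = abs(g[-1]) / max(np.abs(g).sum(), 1e-300)
    if not np.isfinite(transient).all() or tail_frac > 0.02:
        raise ArithmeticError(
            "biphasic series did not converge within the truncation budget "
            f"(last-mode weight fraction {tail_frac:.3g}); increase n_roots"
        )

    sigma = E * eps_t + transient
    return sigma / 1e3  # kPa


def biphasic_forward_fd(
    p: BiphasicParams,
    proto: RampHoldProtocol,
    t: np.ndarray,
    n_r: int = 80,
    n_steps: int = 6000,
) -> np.ndarray:
    """Finite-difference solution of the same boundary-value problem.

    Independent cross-check for :func:`biphasic_forward`: the radial
    displacement u(r, t) is discretized on a uniform radial grid and
    advanced by Crank-Nicolson time stepping of

        du/dt = c d/dr[(1/r) d(r u)/dr] - (d eps_z/dt) r / 2,

    with u(0) = 0, and the traction-free, free-draining edge imposed
    through the dilatation e(a) = (2 mu u(a)/a - lambda eps_z)/H_A.
    The mean axial stress is assembled from u and e exactly as in the
    continuum model, with no reference to the series solution.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    E, mu, H_A = _elastic_constants(p)
    lam = H_A - 2.0 * mu
    a = proto.specimen_radius
    c = H_A * p.permeability
    eps0, tr = proto.applied_strain, proto.ramp_duration

    h = a / n_r
    r = np.arange(1, n_r + 1) * h  # nodes 1..N (u=0 at r=0)
    N = n_r

    # e = D1 @ u + s_e * eps_z   (e at nodes 1..N; boundary row from BC)
    D1 = np.zeros((N, N))
    for i in range(N - 1):
        if i == 0:
            D1[0, 1] += 1.0 / (2 * h)  # u at node 0 (r=h*0? no: u_{i-1}=u(0)=0)
            D1[0, 0] += 1.0 / r[0]
        else:
            D1[i, i + 1] += 1.0 / (2 * h)
            D1[i, i - 1] -= 1.0 / (2 * h)
            D1[i, i] += 1.0 / r[i]
    D1[N - 1, N - 1] = 2.0 * mu / (H_A * a)  # BC row: e_N depends on u_N, eps_z
    s_e = np.zeros(N)
    s_e[N - 1] = -lam / H_A

    # du/dt = c * D2 @ e + forcing;  D2 = d/dr with one-sided 2nd-order ends
    D2 = np.zeros((N, N))
    D2[0, 1] = 1.0 / (2 * h)
    for i in range(1, N - 1):
        D2[i, i + 1] = 1.0 / (2 * h)
        D2[i, i - 1] = -1.0 / (2 * h)
    D2[N - 1, N - 1] = 3.0 / (2 * h)
    D2[N - 1, N - 2] = -4.0 / (2 * h)
    D2[N - 1, N - 3] = 1.0 / (2 * h)

    # e at the axis: regularity u ~ e(0) r/2 gives e(0) = 2 u_1/h, which
    # enters the node-1 stencil of d e/dr as -e(0)/(2h) = -u_1/h^2
    C = np.zeros((N, N))
    C[0, 0] = -1.0 / h**2

    M = c * (D2 @ D1 + C)
    f_eps = c * (D2 @ s_e)  # coefficient of eps_z(t)
    f_rate = -r / 2.0  # coefficient of d eps_z/dt

    t_end = float(t.max()) if t.max() > 0 else tr + proto.hold_duration

    def eps_z(tt):
        return min(tt, tr) * eps0 / tr

    def eps_rate(tt):
        return eps0 / tr if tt < tr else 0.0

    def stress(u, tt):
        e = D1 @ u + s_e * eps_z(tt)
        e_mean = 2.0 * u[N - 1] / a
        ez = eps_z(tt)
        return -H_A * (e_mean - e[N - 1]) + lam * (ez + e_mean) + 2.0 * mu * ez

    # two-stage Crank-Nicolson: fine steps through the ramp and early
    # relaxation, coarser steps over the long tail of the hold
    t_split = min(t_end, max(10.0 * tr, 0.05 * t_end))
    segments = [(0.0, t_split, n_steps // 2)]
    if t_split < t_end:
        segments.append((t_split, t_end, n_steps - n_steps // 2))

    I = np.eye(N)
    u = np.zeros(N)
    times_all = [np.array([0.0])]
    sig_all = [np.array([stress(u, 0.0)])]
    for seg_t0, seg_t1, seg_n in segments:
        dt = (seg_t1 - seg_t0) / seg_n
        lhs = lu_factor(I - 0.5 * dt * M)
        rhs_m = I + 0.5 * dt * M
        times = seg_t0 + np.arange(1, seg_n + 1) * dt
        sig = np.empty(seg_n)
        for n in range(seg_n):
            t0 = seg_t0 + n * dt
            t1 = times[n]
            f0 = f_eps * eps_z(t0) + f_rate * eps_rate(t0 + 1e-12)
            f1 = f_eps * eps_z(t1) + f_rate * eps_rate(t1 - 1e-12)
            u = lu_solve(lhs, rhs_m @ u + 0.5 * dt * (f0 + f1))
            sig[n] = stress(u, t1)
        times_all.append(times)
        sig_all.append(sig)

    return np.interp(t, np.concatenate(times_all), np.concatenate(sig_all)) / 1e3  # kPa


# ---------------------------------------------------------------------------
# fitting

_NU_MAX = 0.499


def _pack(p: BiphasicParams) -> np.ndarray:
    nu = min(max(p.poisson_ratio, 1e-6), _NU_MAX - 1e-6)
    return np.array(
        [
            np.log(p.youngs_modulus),
            np.log(nu / (_NU_MAX - nu)),  # logit on [0, 0.499)
            np.log(p.permeability),
        ]
    )


def _unpack(theta: np.ndarray) -> BiphasicParams:
    E = float(np.exp(theta[0]))
    nu = float(_NU_MAX / (1.0 + np.exp(-theta[1])))
    k = float(np.exp(theta[2]))
    return BiphasicParams(E, min(nu, _NU_MAX), k)


def _plateau_check(rec: StressRecord, tr: float) -> bool:
    """True if the record appears to have reached its relaxation plateau.

    Compares the mean stress around two-thirds of the hold with the mean
    over the final stretch: a record still relaxing shows a drop larger
    than both 1% of the final stress and 4x the noise of the window
    difference (noise estimated from first differences).
    """
    hold = rec.time > tr
    if hold.sum() < 30:
        return False
    s_h = rec.stress[hold]
    n = s_h.size
    w = max(5, n // 10)
    i23 = int(2 * n / 3)
    m_mid = float(s_h[max(0, i23 - w // 2) : i23 + w // 2 + 1].mean())
    m_end = float(s_h[-w:].mean())
    noise = float(np.std(np.diff(s_h)) / np.sqrt(2.0))
    se_drop = noise * np.sqrt(2.0 / w)
    drop = m_mid - m_end
    return drop <= max(0.01 * abs(m_end), 4.0 * se_drop)


def fit_biphasic(
    rec: StressRecord,
    proto: RampHoldProtocol,
    init: BiphasicParams | None = None,
    fix_nu: float | None = None,
    n_roots: int = 50,
    allow_incomplete: bool = False,
) -> tuple[BiphasicParams, FitDiagnostics]:
    """Fit E, nu, k to a stress-relaxation record by nonlinear least squares.

    Parameters are log-transformed (E, k) and logit-transformed (nu) so
    the trust-region solver works unconstrained inside the physical
    bounds.  Five deterministic multi-starts from a fixed design (nu in
    {0.05, 0.15, 0.25, 0.35} crossed with permeability scalings around a
    relaxation-time estimate, plus ``init`` if given) guard against local
    minima; the best final cost wins.

    ``fix_nu`` freezes Poisson's ratio at the given value and fits only E
    and k.  Records truncated before the relaxation plateau raise
    :class:`FitFailureError` (or return a low-confidence flag when
    ``allow_incomplete`` is true).
    """
    complete = _plateau_check(rec, proto.ramp_duration)
    if not complete and not allow_incomplete:
        raise FitFailureError(
            "record does not reach its relaxation plateau (final stress not "
            "within tolerance of a stable value); pass allow_incomplete=True "
            "to fit anyway"
        )

    # data-driven scales for starting points
    eps0 = proto.applied_strain
    plateau = float(np.median(rec.stress[-max(3, rec.stress.size // 10) :]))
    E0 = max(plateau / eps0, 1e-3)  # kPa
    a = proto.specimen_radius
    # relaxation-time scale: time after the peak at which the excess
    # stress has fallen to 1/e of (peak - plateau)
    ipk = int(np.argmax(rec.stress))
    pk = float(rec.stress[ipk])
    if pk > plateau:
        target = plateau + (pk - plateau) / np.e
        after = rec.stress[ipk:] <= target
        tau_est = (
            float(rec.time[ipk:][after].min() - rec.time[ipk])
            if after.any()
            else proto.hold_duration / 4
        )
    else:
        tau_est = proto.hold_duration / 4
    tau_est = max(tau_est, proto.ramp_duration / 2)

    def k_from(nu_s: float, mult: float) -> float:
        H_A = E0 * 1e3 * (1 - nu_s) / ((1 + nu_s) * (1 - 2 * nu_s))
        alpha1 = _eigenvalues(round(nu_s, 12), 1)[0]
        return mult * a**2 / (H_A * alpha1**2 * tau_est)

    # the instantaneous (undrained) response is 3*mu, so the
    # peak/plateau ratio ~ 3/(2(1+nu)) pins a data-driven nu start
    ratio = pk / max(plateau, 1e-12)
    nu_data = float(np.clip(1.5 / max(ratio, 1.01) - 1.0, 0.02, 0.45))

    design = [(nu_data, 0.3), (nu_data, 1.0), (nu_data, 3.0)] + [
        (0.05, 1.0), (0.15, 1.0), (0.25, 1.0), (0.35, 1.0), (0.15, 5.0)
    ]
    starts = []
    if init is not None:
        starts.append(init)
    for nu_s, mult in design:
        nu_eff = fix_nu if fix_nu is not None else nu_s
        starts.append(BiphasicParams(E0, nu_eff, k_from(nu_eff, mult)))

    t, y = rec.time, rec.stress

    if fix_nu is not None:

        def residuals(th):
            p = BiphasicParams(float(np.exp(th[0])), fix_nu, float(np.exp(th[1])))
            return biphasic_forward(p, proto, t, n_roots) - y

        def pack(p):
            return np.array([np.log(p.youngs_modulus), np.log(p.permeability)])

        def unpack(th):
            return BiphasicParams(float(np.exp(th[0])), fix_nu, float(np.exp(th[1])))

    else:

        def residuals(th):
            return biphasic_forward(_unpack(th), proto, t, n_roots) - y

        pack, unpack = _pack, _unpack

    best = None
    for p0 in starts:
        try:
            res = optimize.least_squares(
                residuals, pack(p0), method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-10
            )
        except (ArithmeticError, ValueError):
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.isfinite(best.cost):
        raise FitFailureError("all multi-starts failed", None)

    params = unpack(best.x)
    converged = bool(best.status > 0)
    diag = FitDiagnostics(
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        converged=converged,
        low_confidence=not complete,
        message=str(best.message),
    )
    if not converged:
        raise FitFailureError(f"fit did not converge: {best.message}", params)
    return params, diag


# ---------------------------------------------------------------------------
# tensile


def youngs_modulus_tensile(
    rec: TensileRecord,
    region: str | tuple[float, float] = "auto",
    min_r2: float = 0.9,
    min_window_frac: float = 0.3,
) -> tuple[float, dict]:
    """Young's modulus (kPa) from the linear portion of a tensile curve.

    ``region='auto'`` searches contiguous windows covering at least
    ``min_window_frac`` of the pre-failure points (failure = stress
    maximum) and selects the window maximizing R-squared; an explicit
    ``(strain_lo, strain_hi)`` range may be given instead.  The modulus
    is the OLS slope over the selected window.

    Raises
    ------
    LinearityError
        If no candidate window reaches ``min_r2`` in auto mode.
    """
    strain, stress = rec.strain, rec.stress
    if strain.size < 10:
        raise ValueError("need at least 10 points")

    if region != "auto":
        lo, hi = region
        sel = (strain >= lo) & (strain <= hi)
        if sel.sum() < 10:
            raise ValueError("fewer than 10 points in the requested strain range")
        return _ols_window(strain[sel], stress[sel], (lo, hi))

    n_fail = int(np.argmax(stress)) + 1  # pre-failure segment
    x, y = strain[:n_fail], stress[:n_fail]
    n = x.size
    if n < 10:
        raise LinearityError("too few pre-failure points")
    min_len = max(10, int(np.ceil(min_window_frac * n)))

    # prefix sums give O(1) OLS statistics per window
    Z = np.zeros
    sx = np.concatenate([Z(1), np.cumsum(x)])
    sy = np.concatenate([Z(1), np.cumsum(y)])
    sxx = np.concatenate([Z(1), np.cumsum(x * x)])
    sxy = np.concatenate([Z(1), np.cumsum(x * y)])
    syy = np.concatenate([Z(1), np.cumsum(y * y)])

    stride = max(1, n // 400)
    starts = np.arange(0, n - min_len + 1, stride)
    best = None
    for i in starts:
        ends = np.arange(i + min_len, n + 1, stride)
        m = (ends - i).astype(float)
        Sx = sx[ends] - sx[i]
        Sy = sy[ends] - sy[i]
        Sxx = sxx[ends] - sxx[i]
        Sxy = sxy[ends] - sxy[i]
        Syy = syy[ends] - syy[i]
        vx = Sxx - Sx * Sx / m
        vy = Syy - Sy * Sy / m
        cov = Sxy - Sx * Sy / m
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where((vx > 0) & (vy > 0), cov * cov / (vx * vy), 0.0)
        j = int(np.argmax(r2))
        if best is None or r2[j] > best[0]:
            slope = cov[j] / vx[j] if vx[j] > 0 else np.nan
            best = (float(r2[j]), float(slope), int(i), int(ends[j]))

    r2_best, slope, i0, i1 = best
    if not np.isfinite(slope) or r2_best < min_r2:
        raise LinearityError(
            f"no contiguous window of >= {min_len} points reaches R^2 >= {min_r2} "
            f"(best {r2_best:.3f})"
        )
    return _ols_window(x[i0:i1], y[i0:i1], (float(x[i0]), float(x[i1 - 1])))


def _ols_window(x: np.ndarray, y: np.ndarray, window: tuple[float, float]):
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss if ss > 0 else 1.0
    info = {
        "window_strain": window,
        "r2": r2,
        "intercept_kpa": float(intercept),
        "n_points": int(x.size),
    }
    return float(slope), info
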