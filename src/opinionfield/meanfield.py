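"""Mean-field reduction of the co-evolving opinion dynamics.

The stationary state is analysed through a representative-agent equation in
which the pairwise and long-range sums are replaced by slowly varying mean
terms ``Phi`` and ``M``::

    dx/dt = a_bar * x * M_abs + Phi + (h / 2) * (1 - x)

* ``a_bar`` is the effective attitude coefficient: negative-attitude agents'
  long-range reaction is self-damping, so only the destabilizing positive
  part survives the ensemble average, ``a_bar = E[max(alpha, 0)] = 1/4``
  for uniform attitudes on [-1, 1].
* ``M_abs = W * sqrt(m_bar**2 + v**2)`` is the mean magnitude of the
  weighted distant opinion: a coherent part ``m_bar`` (set by the expert /
  fundamentalist conversion fractions) plus a structural fluctuation floor
  ``v`` computed from the acyclic-network layer counts, which keeps the
  magnitude positive even at the symmetric point ``h = 0``.
* ``Phi`` collects expert, fundamentalist and undecided neighbour
  contributions, with opposite-sign decided neighbours discounted by the
  rewiring-induced assortativity (they end up connected mostly between
  themselves).

Holding the mean terms fixed, the linearized rate is
``lambda = a_bar * M_abs - h / 2``: trivially positive for ``h <= 0`` (a
repulsive fixed point, so every agent gets expelled to an extreme) and
negative for large positive ``h`` (an attractive fixed point that hinders
decisions), with the critical field ``h_c > 0`` defined by ``lambda = 0``.

Conversion fractions ``rho`` integrate the truncated-normal initial-opinion
density between the finite-horizon thresholds ``x_(+/-)``, the initial
opinions that just reach an extreme within one rewiring period ``T = g*dt``
of the exponential solution ``x(t) = x* + (x0 - x*) exp(lambda t)``.
Substituting a third-order expansion of the truncated-normal CDF turns the
fixed-point condition into a cubic equation for the scaled fixed point
``z = x* / sqrt(2)``, solved per sign branch with continuity tracking in
``h``.  The expansion coefficients are isolated below as named constants and
mirrored symbolically in the test suite to catch transcription slips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import Polynomial
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .errors import SolverError
from .model_core import ModelParams

__all__ = [
    "MeanFieldSolution",
    "ATTITUDE_CLOSURE_MEAN",
    "CDF_SLOPE",
    "CDF_CUBIC",
    "OPINION_SCALE",
    "truncated_normal",
    "layer_counts",
    "shell_fluctuation",
    "degree_decay",
    "undecided_fraction_linear",
    "rho_fractions",
    "mean_terms",
    "cubic_coefficients",
    "solve_fixed_point",
    "critical_field",
    "field_scan",
]

# ---------------------------------------------------------------------------
# named constants of the closure (kept separate for the dual-path tests)
# ---------------------------------------------------------------------------

#: effective attitude coefficient: E[max(alpha, 0)] for alpha ~ U[-1, 1]
ATTITUDE_CLOSURE_MEAN = 0.25

#: density of the standard normal truncated to (-1, 1) at the origin;
#: slope of its CDF in the cubic expansion F(x) ~ 1/2 + c (x - beta x^3)
CDF_SLOPE = float(truncnorm.pdf(0.0, -1.0, 1.0))

#: cubic coefficient of the CDF expansion (from exp(-t^2/2) ~ 1 - t^2/2)
CDF_CUBIC = 1.0 / 6.0

#: scale of the fixed point: z = x* / OPINION_SCALE writes the Gaussian
#: of initial opinions as exp(-z**2)
OPINION_SCALE = math.sqrt(2.0)

#: assortativity discount on opposite-sign decided neighbours in Phi
OPPOSITE_SIGN_DISCOUNT = 0.0

#: clamp on exp(-lambda T) inside the polynomial algebra (the expansion is
#: only meaningful while the thresholds sit near the support of the
#: truncated normal; the exact CDF quantities are never clamped)
EPS_CLAMP = 1.5

_REWIRE_TIME = lambda p: p.transactions_per_rewiring * p.step_size  # noqa: E731


def truncated_normal():
    """The initial-opinion distribution: standard normal on (-1, 1)."""
    return truncnorm(-1.0, 1.0)


def effective_shell_scale(params: ModelParams, mean_degree: float | None = None) -> float:
    """Population-mean multiplier of the normalized distant-opinion average.

    With degree-scaled weights the per-agent multiplier is
    ``scale * (degree + offset)``, so its mean-field counterpart replaces
    the degree by the (possibly field-dependent) mean degree.
    """
    k = params.mean_degree if mean_degree is None else mean_degree
    if params.shell_degree_scaled:
        return params.shell_scale * (k + params.shell_offset)
    return params.shell_scale


# ---------------------------------------------------------------------------
# network geometry
# ---------------------------------------------------------------------------

def layer_counts(mean_degree: float, n_agents: int) -> tuple[list[float], int, float]:
    """Layer sizes of the acyclic (tree) approximation of the network.

    Layer ``n`` holds ``k * (k - 1)**(n - 1)`` agents.  ``n_max`` is the
    largest layer index such that the cumulative count stays below the
    ``n_agents - 1`` available agents; the remainder is assigned to layer
    ``n_max + 1``.  Returns ``(layers, n_max, remainder)`` where ``layers``
    lists full layers ``1 .. n_max``.
    """
    if mean_degree <= 1.0:
        raise SolverError(
            f"tree approximation degenerate for mean degree {mean_degree} <= 1"
        )
    budget = n_agents - 1
    layers: list[float] = []
    total = 0.0
    n = 1
    while True:
        size = mean_degree * (mean_degree - 1.0) ** (n - 1)
        if total + size >= budget:
            break
        layers.append(size)
        total += size
        n += 1
    return layers, len(layers), budget - total


def shell_fluctuation(mean_degree: float, n_agents: int, decay: float) -> float:
    """Structural rms of the normalized distance-weighted opinion average.

    For decided opinions of unit magnitude placed independently on the tree
    layers at distance >= 2, the normalized weighted average has variance
    ``sum(w_n^2 L_n) / (sum(w_n L_n))^2`` with raw weights
    ``w_n = decay**(n-1)``.
    """
    layers, n_max, rem = layer_counts(mean_degree, n_agents)
    sizes = layers[1:] + [rem]  # layers at distance >= 2 (incl. remainder)
    dists = list(range(2, n_max + 1)) + [n_max + 1]
    w = np.array([decay ** (n - 1) for n in dists])
    sizes = np.array(sizes)
    z = float((w * sizes).sum())
    if z <= 0.0:
        return 0.0
    return float(math.sqrt((w**2 * sizes).sum()) / z)


# ---------------------------------------------------------------------------
# degree decay
# ---------------------------------------------------------------------------

def _early_decision_rate(h: float, params: ModelParams) -> float:
    """Sign-symmetric expulsion rate governing the first rewiring window."""
    v = shell_fluctuation(params.mean_degree, params.n_agents, params.shell_decay)
    return ATTITUDE_CLOSURE_MEAN * effective_shell_scale(params) * v + abs(h) / 2.0


def undecided_fraction_linear(x_star: float, lam: float, params: ModelParams) -> float:
    """First-order estimate of the undecided fraction after one rewiring
    period: density at the fixed point times the threshold gap
    ``2 exp(-lambda T)``."""
    dist = truncated_normal()
    width = 2.0 * math.exp(-lam * _REWIRE_TIME(params))
    return float(np.clip(dist.pdf(np.clip(x_star, -1.0, 1.0)) * width, 0.0, 1.0))


def degree_decay(h: float, params: ModelParams) -> float:
    """Predicted post-rewiring mean degree ``<k>(h)``.

    Simultaneous rewiring cuts shared bonds twice (a net degree gain linear
    in the undecided fraction ``s1``) while double-created bonds collapse
    (a loss quadratic in ``s1``), so ``<k>(h) = k0 * (1 + s1 - s1^2)``.
    The undecided fraction at the first rewiring decays exponentially with
    the expulsion rate, so the correction vanishes as ``|h|`` grows and the
    degree falls back to its initial value; a Pade saturation keeps
    ``s1 < 1/2`` (no agent pair can double-create more than once) while
    preserving strict monotonicity in ``|h|``.
    """
    raw = 2.0 * CDF_SLOPE * math.exp(-_early_decision_rate(h, params) * _REWIRE_TIME(params))
    s1 = raw / (1.0 + 2.0 * raw)
    return params.mean_degree * (1.0 + s1 - s1 * s1)


# ---------------------------------------------------------------------------
# conversion fractions
# ---------------------------------------------------------------------------

def decision_thresholds(x_star: float, lam: float, params: ModelParams) -> tuple[float, float]:
    """Initial opinions that just reach -1 / +1 within one rewiring period."""
    eps = math.exp(-lam * _REWIRE_TIME(params)) if lam * _REWIRE_TIME(params) > -50 else math.exp(50.0)
    x_plus = x_star + (1.0 - x_star) * eps
    x_minus = x_star + (-1.0 - x_star) * eps
    return x_minus, x_plus


def rho_fractions(
    x_star: float, params: ModelParams, lam: float
) -> dict[tuple[str, str], float]:
    """Fractions of agents converting from initial sign ``s`` to final
    extreme sign ``s'``, keyed ``(s, s')`` with ``s`` in ``{"+", "-"}``.

    Integrates the truncated standard normal between the finite-horizon
    thresholds.  Fractions are of the whole population, so
    ``rho[+,+] + rho[+,-] <= 1`` (the remainder being undecided starters).
    """
    dist = truncated_normal()
    x_minus, x_plus = decision_thresholds(x_star, lam, params)
    a = float(np.clip(x_minus, -1.0, 1.0))
    b = float(np.clip(x_plus, -1.0, 1.0))
    f = dist.cdf
    f0 = float(f(0.0))
    return {
        ("+", "+"): float(1.0 - f(max(b, 0.0))),
        ("+", "-"): float(max(f(max(a, 0.0)) - f0, 0.0)),
        ("-", "-"): float(f(min(a, 0.0))),
        ("-", "+"): float(max(f0 - f(min(b, 0.0)), 0.0)),
    }


def undecided_fraction_exact(x_star: float, lam: float, params: ModelParams) -> float:
    dist = truncated_normal()
    x_minus, x_plus = decision_thresholds(x_star, lam, params)
    a = float(np.clip(x_minus, -1.0, 1.0))
    b = float(np.clip(x_plus, -1.0, 1.0))
    return float(dist.cdf(b) - dist.cdf(a))


# ---------------------------------------------------------------------------
# mean interaction terms
# ---------------------------------------------------------------------------

def mean_terms(
    z: float, params: ModelParams, h: float = 0.0, lam: float = 1.0
) -> tuple[float, float]:
    """Mean short-range term ``Phi`` and coherent long-range part ``m_bar``.

    ``Phi`` sums expert, fundamentalist and undecided contributions felt by
    a representative agent sitting at the fixed point, with opposite-sign
    decided neighbours discounted by the assortativity factor.  ``m_bar``
    is the mean distant opinion: expert fraction minus fundamentalist
    fraction plus the undecided mass at the fixed point.
    """
    x_star = z * OPINION_SCALE
    rho = rho_fractions(x_star, params, lam)
    s = undecided_fraction_exact(x_star, lam, params)
    n_e = rho[("+", "+")] + rho[("-", "+")]
    n_f = rho[("-", "-")] + rho[("+", "-")]
    kbar = degree_decay(h, params)
    if kbar <= 1.0:
        raise SolverError(f"predicted degree {kbar} <= 1: tree approximation invalid")

    sigma = 1.0 if x_star >= 0.0 else -1.0
    a_e = 1.0 if sigma > 0 else OPPOSITE_SIGN_DISCOUNT
    a_f = OPPOSITE_SIGN_DISCOUNT if sigma > 0 else 1.0
    phi_e = kbar * a_e * n_e * abs(x_star)
    phi_f = -kbar * a_f * n_f * abs(x_star)
    phi_u = kbar * s * x_star
    m_bar = n_e - n_f + s * x_star
    return phi_e + phi_f + phi_u, m_bar


# ---------------------------------------------------------------------------
# the cubic fixed-point equation
# ---------------------------------------------------------------------------

def _truncate(p: Polynomial, deg: int = 3) -> Polynomial:
    return Polynomial(p.coef[: deg + 1])


def cubic_coefficients(
    h: float,
    eps: float,
    kbar: float,
    params: ModelParams,
    sigma: float,
    varsigma: float,
) -> np.ndarray:
    """Coefficients (ascending) of the cubic ``C(x)`` whose admissible root
    is the mean fixed point on the sign branch ``sigma``.

    ``eps = exp(-lambda T)`` (clamped), ``varsigma`` is the assumed sign of
    the coherent long-range part at the root (validated after solving).
    Built from the third-order CDF expansion
    ``F(y) = 1/2 + c (y - beta y^3)`` evaluated at the thresholds
    ``x(1 - eps) +/- eps``; products beyond degree three are truncated.
    """
    c, beta = CDF_SLOPE, CDF_CUBIC
    eps = float(np.clip(eps, 0.0, EPS_CLAMP))
    x = Polynomial([0.0, 1.0])
    xp = Polynomial([eps, 1.0 - eps])
    xm = Polynomial([-eps, 1.0 - eps])
    f_p = 0.5 + c * (xp - beta * xp**3)
    f_m = 0.5 + c * (xm - beta * xm**3)
    n_e = 1.0 - f_p
    n_f = f_m
    s = f_p - f_m
    m_bar = _truncate(n_e - n_f + s * x)

    v = shell_fluctuation(kbar, params.n_agents, params.shell_decay)
    m_abs = effective_shell_scale(params, kbar) * (v + varsigma * m_bar)

    delta = OPPOSITE_SIGN_DISCOUNT
    n_same, n_opp = (n_e, n_f) if sigma > 0 else (n_f, n_e)
    rhs = (
        ATTITUDE_CLOSURE_MEAN * _truncate(x * m_abs)
        + kbar * _truncate(x * (n_same - delta * n_opp + s))
        + (h / 2.0) * (1.0 - x)
    )
    out = np.zeros(4)
    coef = _truncate(rhs).coef
    out[: coef.size] = coef
    return out


def _admissible_roots(
    coeffs: np.ndarray, sigma: float
) -> list[float]:
    """Real roots of the cubic with sign ``sigma`` inside [-1.05, 1.05]."""
    poly = Polynomial(coeffs)
    roots = poly.roots()
    out = []
    for r in roots:
        if abs(r.imag) > 1e-9:
            continue
        xr = float(r.real)
        if sigma * xr < -1e-9 or abs(xr) > 1.05:
            continue
        out.append(xr)
    return out


@dataclass
class MeanFieldSolution:
    """Everything the analytic reduction knows about one field value."""

    field: float
    fixed_point: float
    scaled_fixed_point: float
    eigenvalue: float
    predicted_mean_degree: float
    phi: float
    m_bar: float
    m_abs: float
    rho: dict
    undecided_fraction: float
    cubic: tuple  # ascending coefficients of the solved branch cubic
    branch_sign: float


def _solve_at(
    h: float,
    params: ModelParams,
    x_ref: float,
) -> MeanFieldSolution:
    """Solve the coupled (lambda, cubic) system at a single field value.

    ``lambda`` enters the cubic through ``eps = exp(-lambda T)`` and the
    cubic root feeds back into ``lambda``; the scalar self-consistency is
    closed with a bracketed root search, which always succeeds because the
    feedback map is bounded.
    """
    kbar = degree_decay(h, params)
    if kbar <= 1.0:
        raise SolverError(f"predicted degree {kbar} <= 1 at h={h}")
    v = shell_fluctuation(kbar, params.n_agents, params.shell_decay)
    t_rw = _REWIRE_TIME(params)
    a_w = ATTITUDE_CLOSURE_MEAN * effective_shell_scale(params, kbar)

    sigmas = [1.0, -1.0] if abs(x_ref) < 1e-12 else [math.copysign(1.0, x_ref)]

    def pick_root(lam: float) -> tuple[float, np.ndarray, float, float] | None:
        eps = float(np.clip(math.exp(-np.clip(lam * t_rw, -50, 50)), 0.0, EPS_CLAMP))
        best = None
        for sg in sigmas:
            for vs in (1.0, -1.0):
                coeffs = cubic_coefficients(h, eps, kbar, params, sg, vs)
                for xr in _admissible_roots(coeffs, sg):
                    mb = _mbar_poly(eps)(xr)
                    if vs * mb < -1e-9:
                        continue  # inconsistent long-range sign assumption
                    cand = (xr, coeffs, sg, vs)
                    if best is None or abs(xr - x_ref) < abs(best[0] - x_ref):
                        best = cand
        return best

    def _mbar_poly(eps: float) -> Polynomial:
        c, beta = CDF_SLOPE, CDF_CUBIC
        x = Polynomial([0.0, 1.0])
        xp = Polynomial([eps, 1.0 - eps])
        xm = Polynomial([-eps, 1.0 - eps])
        f_p = 0.5 + c * (xp - beta * xp**3)
        f_m = 0.5 + c * (xm - beta * xm**3)
        return _truncate((1.0 - f_p) - f_m + (f_p - f_m) * x)

    def g_of(lam: float) -> float:
        eps = float(np.clip(math.exp(-np.clip(lam * t_rw, -50, 50)), 0.0, EPS_CLAMP))
        best = pick_root(lam)
        # at probe lambdas far from self-consistency the branch may have no
        # root; evaluate the feedback at the continuation reference instead
        # (the final solve below still requires a genuine root)
        x_eval = best[0] if best is not None else x_ref
        mb = _mbar_poly(eps)(x_eval)
        return a_w * math.sqrt(mb * mb + v * v) - h / 2.0

    def f_res(lam: float) -> float:
        return g_of(lam) - lam

    # the feedback g(lambda) is bounded by a_w * sqrt(1 + v^2) +- h/2, so
    # this bracket always contains the self-consistent point
    span = a_w * math.sqrt(4.0 + v * v) + abs(h) + 1.0
    lo, hi = -span, span
    flo, fhi = f_res(lo), f_res(hi)
    if flo < 0 or fhi > 0:  # pragma: no cover - defensive
        raise SolverError(f"lambda bracket failed at h={h}: f({lo})={flo}, f({hi})={fhi}")
    lam = brentq(f_res, lo, hi, xtol=1e-13)

    best = pick_root(lam)
    assert best is not None
    x_root, coeffs, sg, vs = best
    # one Newton polish so the reported residual is at machine level
    poly = Polynomial(coeffs)
    dpoly = poly.deriv()
    for _ in range(3):
        d = dpoly(x_root)
        if d != 0.0:
            x_root -= poly(x_root) / d
    if abs(poly(x_root)) > 1e-10:
        raise SolverError(f"cubic residual {poly(x_root)} too large at h={h}")

    z = x_root / OPINION_SCALE
    phi, m_bar = mean_terms(z, params, h=h, lam=lam)
    rho = rho_fractions(x_root, params, lam)
    s = undecided_fraction_exact(x_root, lam, params)
    return MeanFieldSolution(
        field=h,
        fixed_point=x_root,
        scaled_fixed_point=z,
        eigenvalue=lam,
        predicted_mean_degree=kbar,
        phi=phi,
        m_bar=m_bar,
        m_abs=effective_shell_scale(params, kbar) * math.sqrt(m_bar**2 + v**2),
        rho=rho,
        undecided_fraction=s,
        cubic=tuple(coeffs),
        branch_sign=sg,
    )


def solve_fixed_point(
    h: float, params: ModelParams, x_ref: float | None = None
) -> MeanFieldSolution:
    """Mean fixed point, eigenvalue and derived quantities at field ``h``.

    The physical branch is tracked by continuity: starting from the
    symmetric solution at ``h = 0`` the solver walks the field in small
    steps, always selecting the admissible cubic root closest to the
    previous one.  Passing ``x_ref`` skips the walk (used internally).
    """
    if x_ref is not None:
        return _solve_at(h, params, x_ref)
    ref = 0.0
    n_steps = max(1, int(math.ceil(abs(h) / 0.1)))
    sol = None
    for k in range(1, n_steps + 1):
        sol = _solve_at(h * k / n_steps, params, ref)
        ref = sol.fixed_point
    if sol is None:  # h == 0
        sol = _solve_at(0.0, params, 0.0)
    return sol


def field_scan(
    params: ModelParams, h_values
) -> list[MeanFieldSolution]:
    """Continuity-tracked solutions over an ordered field grid."""
    h_values = list(h_values)
    out = []
    # walk outward from the value closest to zero to keep continuity
    order = sorted(range(len(h_values)), key=lambda i: abs(h_values[i]))
    cache: dict[int, MeanFieldSolution] = {}
    for side in (1.0, -1.0):
        ref = 0.0
        for i in order:
            hv = h_values[i]
            if side * hv < 0 or (hv == 0 and side < 0):
                continue
            sol = _solve_at(hv, params, ref)
            cache[i] = sol
            ref = sol.fixed_point
    for i in range(len(h_values)):
        out.append(cache[i])
    return out


def critical_field(
    params: ModelParams, h_max: float = 6.0, n_grid: int = 61
) -> float:
    """Smallest positive field where the eigenvalue changes sign.

    Scans ``lambda(h)`` on a grid over ``(0, h_max]`` with continuity
    tracking, brackets the first sign change and bisects until
    ``|lambda(h_c)| < 1e-8``.  Raises :class:`SolverError` when no sign
    change is found (never extrapolates).
    """
    hs = np.linspace(0.0, h_max, n_grid)
    sols = field_scan(params, hs)
    lams = [s.eigenvalue for s in sols]
    if lams[0] <= 0.0:
        raise SolverError(f"lambda(0) = {lams[0]} is not positive")
    bracket = None
    for i in range(1, len(hs)):
        if lams[i] < 0.0 <= lams[i - 1]:
            bracket = (hs[i - 1], hs[i], sols[i - 1].fixed_point)
            break
    if bracket is None:
        raise SolverError(
            f"no eigenvalue sign change on (0, {h_max}]: lambda stays "
            f"in [{min(lams):.4g}, {max(lams):.4g}]"
        )
    lo, hi, ref = bracket
    sol_lo = _solve_at(lo, params, ref)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        sol_mid = _solve_at(mid, params, sol_lo.fixed_point)
        if abs(sol_mid.eigenvalue) < 1e-8:
            return mid
        if sol_mid.eigenvalue > 0.0:
            lo, sol_lo = mid, sol_mid
        else:
            hi = mid
    return 0.5 * (lo + hi)  # pragma: no cover - bisection always converges
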