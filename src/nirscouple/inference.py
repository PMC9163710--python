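"""Dynamical Bayesian inference of coupling functions between two phase oscillators.

The cardiac arterial-pressure phase phi_A and a slow hemoglobin phase
phi_O are modelled as coupled stochastic phase oscillators

    dphi_m/dt = sum_k c_k^(m) * Phi_k(phi_A, phi_O) + xi_m(t),

where {Phi_k} is a 2-D Fourier basis up to order K (a constant plus
sin/cos of a*phi_A + b*phi_O) and xi is Gaussian white noise with 2x2
intensity matrix E. Given windowed phase data, the posterior over the
coefficient vector c (Gaussian, parameterised by mean c and concentration
matrix Xi) and the noise matrix E are found by iterating the stationary
conditions of the negative log posterior:

    E   = (h/N) * sum_i r_i r_i^T,          r_i = phidot_i - c Phi(i)
    Xi  = Xi_prior + h * sum_i kron(E^-1, Phi_i Phi_i^T)
    rhs = Xi_prior c_prior
          + h * sum_i (E^-1 phidot_i) (x) Phi_i
          - (h/2) * sum_i dPhi/dphi_m(i)            (midpoint drift term)
    c   = Xi^-1 rhs

with phase velocities by forward differences over one sample and basis
functions evaluated at midpoint phases. Sequential windows propagate the
posterior as the next prior with covariance inflated by
prop_const**2 * diag(c**2), allowing the coupling to evolve in time.

Coupling strength in a direction is the Euclidean norm of the target
equation's coefficients on all basis terms that depend on the source
phase; the directionality index is their normalized asymmetry.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateInputError,
    InvalidArgumentError,
    NumericalConditioningError,
    TooShortError,
)
from .phases import PhaseSeries, common_valid_span

__all__ = [
    "FourierBasis", "build_basis",
    "CouplingPosterior", "CouplingMetrics", "CouplingSurface",
    "infer_window", "infer_sequence",
    "coupling_strength", "directionality", "coupling_surface",
    "DynamicalBayesianInference",
]


@dataclass(frozen=True)
class FourierBasis:
    """Ordered 2-D Fourier basis of order K on (phi_a, phi_o).

    ``terms`` lists (a, b, trig) with trig in {"const", "sin", "cos"}.
    Canonical representatives only: a > 0, or a == 0 and b > 0 (negating
    both indices is redundant up to sign), each with both sin and cos.
    Size = (2K+1)**2: 9 for K=1, 25 for K=2.
    """

    order: int
    terms: tuple[tuple[int, int, str], ...] = field(init=False, default=())

    def __post_init__(self) -> None:
        if self.order < 1:
            raise InvalidArgumentError("basis order K must be >= 1")
        terms: list[tuple[int, int, str]] = [(0, 0, "const")]
        K = self.order
        pairs = [(0, b) for b in range(1, K + 1)]
        pairs += [(a, b) for a in range(1, K + 1) for b in range(-K, K + 1)]
        for a, b in pairs:
            terms.append((a, b, "sin"))
            terms.append((a, b, "cos"))
        object.__setattr__(self, "terms", tuple(terms))

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def design(self, phi_a: np.ndarray, phi_o: np.ndarray) -> np.ndarray:
        """Basis functions evaluated at the given phases; shape (P, N)."""
        rows = []
        for a, b, trig in self.terms:
            if trig == "const":
                rows.append(np.ones_like(phi_a))
            else:
                arg = a * phi_a + b * phi_o
                rows.append(np.sin(arg) if trig == "sin" else np.cos(arg))
        return np.array(rows)

    def derivative(self, phi_a: np.ndarray, phi_o: np.ndarray,
                   wrt: str) -> np.ndarray:
        """d Phi_k / d phi_wrt, wrt in {"a", "o"}; shape (P, N)."""
        rows = []
        for a, b, trig in self.terms:
            coef = a if wrt == "a" else b
            if trig == "const" or coef == 0:
                rows.append(np.zeros_like(phi_a))
            else:
                arg = a * phi_a + b * phi_o
                rows.append(coef * np.cos(arg) if trig == "sin"
                            else -coef * np.sin(arg))
        return np.array(rows)

    def cross_mask(self, direction: str) -> np.ndarray:
        """Boolean mask of terms that depend on the source phase.

        direction "ao": influence of phi_a (terms with a != 0), read from
        the O equation. direction "oa": terms with b != 0, A equation.
        """
        if direction not in ("ao", "oa"):
            raise InvalidArgumentError("direction must be 'ao' or 'oa'")
        idx = 0 if direction == "ao" else 1
        return np.array([t[2] != "const" and t[idx] != 0 for t in self.terms])


def build_basis(K: int = 2) -> FourierBasis:
    """Fourier basis of order ``K`` (default 2, i.e. 25 terms per equation)."""
    return FourierBasis(K)


@dataclass
class CouplingPosterior:
    """Gaussian posterior over one window's model parameters.

    ``c`` stacks the A-equation then the O-equation coefficients (2P);
    ``xi`` is the joint concentration (inverse covariance) matrix;
    ``noise`` the 2x2 dynamical-noise intensity matrix (rad^2/s).
    """

    c: np.ndarray
    xi: np.ndarray
    noise: np.ndarray
    window_start: float = 0.0
    window_end: float = 0.0
    iterations: int = 0

    def coefficients(self, equation: str) -> np.ndarray:
        """Coefficient vector of one equation, 'a' or 'o'."""
        P = self.c.size // 2
        return self.c[:P] if equation == "a" else self.c[P:]

    def coefficient_sd(self) -> np.ndarray:
        """Posterior standard deviations of all 2P coefficients."""
        return np.sqrt(np.diag(np.linalg.inv(self.xi)))


@dataclass(frozen=True)
class CouplingMetrics:
    """Directed coupling strengths (rad/s) and the directionality index."""

    cs_ao: float
    cs_oa: float

    @property
    def cd(self) -> float:
        return directionality(self.cs_ao, self.cs_oa)


@dataclass
class CouplingSurface:
    """Coupling function q evaluated on a uniform [0, 2pi)^2 phase grid."""

    grid: np.ndarray            # 1-D phase grid, shared by both axes
    values: np.ndarray          # (res, res): q(phi_a[i], phi_o[j])


def _prepare(phi_a: PhaseSeries, phi_o: PhaseSeries,
             span: tuple[float, float] | None = None):
    if abs(phi_a.sampling_rate - phi_o.sampling_rate) > 1e-4 * phi_a.sampling_rate:
        raise InvalidArgumentError("phase series must share a sampling rate")
    if span is None:
        span = common_valid_span([phi_a, phi_o])
    a = phi_a.valid_slice(span)
    o = phi_o.valid_slice(span)
    n = min(a.size, o.size)
    return a[:n], o[:n], 1.0 / phi_a.sampling_rate


def infer_window(
    phi_a: PhaseSeries,
    phi_o: PhaseSeries,
    basis: FourierBasis,
    prior: CouplingPosterior | None = None,
    span: tuple[float, float] | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> CouplingPosterior:
    """Posterior of the coupled-phase-oscillator parameters on one window.

    With no ``prior``, starts from zero coefficients and a fully diffuse
    concentration (all information comes from the data). Deterministic:
    identical inputs give identical output.
    """
    a, o, h = _prepare(phi_a, phi_o, span)
    if a.size < 2 * basis.n_terms + 2:
        raise TooShortError("window too short for the basis size")
    dphi = np.vstack([np.diff(a), np.diff(o)]) / h          # (2, N)
    mid_a = 0.5 * (a[1:] + a[:-1])
    mid_o = 0.5 * (o[1:] + o[:-1])
    N = mid_a.size
    P = basis.n_terms

    Phi = basis.design(mid_a, mid_o)                        # (P, N)
    G = Phi @ Phi.T                                         # (P, P)
    B = Phi @ dphi.T                                        # (P, 2)
    v = np.concatenate([basis.derivative(mid_a, mid_o, "a").sum(axis=1),
                        basis.derivative(mid_a, mid_o, "o").sum(axis=1)])

    if prior is not None:
        xi0 = prior.xi
        c0 = prior.c
    else:
        xi0 = np.zeros((2 * P, 2 * P))
        c0 = np.zeros(2 * P)

    c = c0.copy()
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        res = dphi - c.reshape(2, P) @ Phi
        E = h * (res @ res.T) / N
        try:
            Einv = np.linalg.inv(E + 1e-14 * np.eye(2))
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise NumericalConditioningError(str(exc)) from exc
        xi = xi0 + h * np.kron(Einv, G)
        rhs = xi0 @ c0 + h * (Einv @ B.T).reshape(-1) - 0.5 * h * v
        try:
            c_new = np.linalg.solve(xi, rhs)
        except np.linalg.LinAlgError as exc:
            raise NumericalConditioningError(
                "singular concentration matrix; use a longer window or "
                "smaller basis order K"
            ) from exc
        delta = np.linalg.norm(c_new - c) / max(np.linalg.norm(c_new), 1e-300)
        c = c_new
        if delta < tol:
            break

    res = dphi - c.reshape(2, P) @ Phi
    E = h * (res @ res.T) / N
    xi = xi0 + h * np.kron(np.linalg.inv(E + 1e-14 * np.eye(2)), G)
    t0 = span[0] if span is not None else phi_a.valid_span[0]
    return CouplingPosterior(c, xi, E, window_start=t0,
                             window_end=t0 + N * h, iterations=n_iter)


def _propagate_prior(post: CouplingPosterior,
                     prop_const: float) -> CouplingPosterior:
    """Next window's prior: posterior with information diffusion applied."""
    sigma = np.linalg.inv(post.xi)
    sigma = sigma + prop_const ** 2 * np.diag(post.c ** 2)
    return CouplingPosterior(post.c.copy(), np.linalg.inv(sigma),
                             post.noise.copy())


def infer_sequence(
    phi_a: PhaseSeries,
    phi_o: PhaseSeries,
    basis: FourierBasis,
    window: float,
    prop_const: float = 0.2,
    tol: float = 1e-6,
    fallback_full_span: bool = True,
) -> list[CouplingPosterior]:
    """Sequential inference over consecutive non-overlapping windows.

    Each window's prior is the previous posterior with covariance inflated
    by prop_const**2 * diag(c**2), so the coefficients may drift between
    windows while information accumulates. If the common valid span is
    shorter than one window, falls back to a single full-span window
    (unless ``fallback_full_span`` is False, in which case it raises).
    """
    lo, hi = common_valid_span([phi_a, phi_o])
    if hi - lo < window:
        if not fallback_full_span:
            raise TooShortError(
                f"valid span {hi - lo:.0f} s < window {window:.0f} s"
            )
        return [infer_window(phi_a, phi_o, basis, span=(lo, hi), tol=tol)]
    posteriors: list[CouplingPosterior] = []
    prior = None
    t = lo
    while t + window <= hi + 1e-9:
        post = infer_window(phi_a, phi_o, basis, prior=prior,
                            span=(t, min(t + window, hi)), tol=tol)
        posteriors.append(post)
        prior = _propagate_prior(post, prop_const)
        t += window
    return posteriors


def coupling_strength(posterior: CouplingPosterior, direction: str,
                      basis: FourierBasis, squared: bool = False) -> float:
    """Directed coupling strength from one window's posterior.

    Euclidean norm (or, with ``squared=True``, sum of squares) of the
    coefficients, in the target oscillator's equation, of every basis term
    that depends on the source phase. Constant and self-dependence terms
    are excluded.
    """
    eq = "o" if direction == "ao" else "a"
    coef = posterior.coefficients(eq)[basis.cross_mask(direction)]
    ss = float(np.dot(coef, coef))
    return ss if squared else float(np.sqrt(ss))


def directionality(cs_ao: float, cs_oa: float) -> float:
    """Normalized coupling asymmetry (cs_ao - cs_oa) / (cs_ao + cs_oa).

    Positive when the pressure-to-hemoglobin direction dominates. Raises
    :class:`DegenerateInputError` when both strengths are zero.
    """
    if cs_ao < 0 or cs_oa < 0:
        raise InvalidArgumentError("coupling strengths must be >= 0")
    total = cs_ao + cs_oa
    if total == 0:
        raise DegenerateInputError("both coupling strengths are zero; "
                                   "direction undefined")
    return (cs_ao - cs_oa) / total


def coupling_surface(posterior: CouplingPosterior, basis: FourierBasis,
                     resolution: int = 64,
                     equation: str = "o") -> CouplingSurface:
    """Coupling function q evaluated on a uniform [0, 2pi)^2 grid.

    The constant term is excluded, so the surface shows pure phase
    dependence. ``values[i, j]`` = q(grid[i], grid[j]) with the first axis
    the source (pressure) phase.
    """
    if resolution < 16:
        raise InvalidArgumentError("resolution must be >= 16")
    grid = np.linspace(0.0, 2.0 * np.pi, resolution, endpoint=False)
    A, O = np.meshgrid(grid, grid, indexing="ij")
    Phi = basis.design(A.ravel(), O.ravel())
    coef = posterior.coefficients(equation).copy()
    coef[0] = 0.0  # drop the constant
    return CouplingSurface(grid, (coef @ Phi).reshape(resolution, resolution))


def mean_surface(surfaces: list[CouplingSurface]) -> CouplingSurface:
    """Pointwise mean of several subjects' coupling surfaces."""
    if not surfaces:
        raise InvalidArgumentError("no surfaces to average")
    grid = surfaces[0].grid
    return CouplingSurface(grid,
                           np.mean([s.values for s in surfaces], axis=0))


class DynamicalBayesianInference:
    """Convenience wrapper running windowed inference on a phase pair.

    Parameters mirror the module-level functions; after :meth:`fit`, the
    fitted attributes hold the windowed posteriors and summary metrics.

    Attributes
    ----------
    posteriors_ : list of CouplingPosterior
    cs_ao_, cs_oa_ : float
        Per-subject strengths, the mean of the windowed values.
    cd_ : float
        Directionality index computed from the mean strengths.
    """

    def __init__(self, K: int = 2, window: float = 400.0,
                 prop_const: float = 0.2, tol: float = 1e-6):
        self.K = K
        self.window = window
        self.prop_const = prop_const
        self.tol = tol

    def fit(self, phi_a: PhaseSeries, phi_o: PhaseSeries
            ) -> "DynamicalBayesianInference":
        basis = build_basis(self.K)
        self.basis_ = basis
        self.posteriors_ = infer_sequence(
            phi_a, phi_o, basis, window=self.window,
            prop_const=self.prop_const, tol=self.tol,
        )
        self.cs_ao_ = float(np.mean(
            [coupling_strength(p, "ao", basis) for p in self.posteriors_]))
        self.cs_oa_ = float(np.mean(
            [coupling_strength(p, "oa", basis) for p in self.posteriors_]))
        self.cd_ = directionality(self.cs_ao_, self.cs_oa_)
        return self

    def metrics(self) -> CouplingMetrics:
        return CouplingMetrics(self.cs_ao_, self.cs_oa_)
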