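"""Belief and message algebra for factor-graph inference.

Beliefs are *unnormalized* functions on a variable's domain.  Four families
are supported: multivariate Gaussian, finite categorical, point mass (delta)
and the vacuous (unit) belief.  Every belief tracks its absolute scale so
that closing the box around an entire graph yields the model evidence.

Gaussians are held in exponential form

    b(x) = exp(-1/2 x'Wx + h'x + g)

with ``W`` a symmetric matrix (possibly singular, i.e. an improper belief
such as a low-rank likelihood message), ``h`` a vector and ``g`` an absolute
log offset.  Products are then exact parameter additions; moment form is
derived on demand.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Union

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "Vacuous",
    "VACUOUS",
    "PointMass",
    "GaussianBelief",
    "CategoricalBelief",
    "Message",
    "Marginal",
    "combine",
    "gaussian_product",
    "kl",
    "entropy",
    "BeliefError",
    "NotNormalizableError",
    "SupportMismatchError",
    "DegenerateEntropyError",
]

_LOG_2PI = math.log(2.0 * math.pi)


class BeliefError(ValueError):
    """Base class for belief-algebra failures."""


class NotNormalizableError(BeliefError):
    """Raised when a product of beliefs has no finite normalizer."""


class SupportMismatchError(BeliefError):
    """Raised when two beliefs do not share a common support/domain."""


class DegenerateEntropyError(BeliefError):
    """Raised when an entropy is requested for a point mass (it is -inf)."""


class Vacuous:
    """The unit belief: identically 1.  Combining with any belief is a no-op."""

    _instance: Optional["Vacuous"] = None

    def __new__(cls) -> "Vacuous":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "Vacuous()"


#: Shared vacuous instance.
VACUOUS = Vacuous()


@dataclasses.dataclass(frozen=True)
class PointMass:
    """A delta belief at a fixed domain element.

    ``value`` is an ``int`` for finite domains (the alphabet index) and a
    float/vector for continuous domains.  ``log_scale`` multiplies the delta.
    """

    value: Union[int, float, np.ndarray]
    log_scale: float = 0.0

    @property
    def is_discrete(self) -> bool:
        return isinstance(self.value, (int, np.integer))

    def vector(self) -> np.ndarray:
        return np.atleast_1d(np.asarray(self.value, dtype=float))


class GaussianBelief:
    """Unnormalized Gaussian belief in exponential form ``(W, h, g)``."""

    __slots__ = ("W", "h", "g")

    def __init__(self, W: np.ndarray, h: np.ndarray, g: float = 0.0):
        W = np.atleast_2d(np.asarray(W, dtype=float))
        h = np.atleast_1d(np.asarray(h, dtype=float))
        if W.shape[0] != W.shape[1] or W.shape[0] != h.shape[0]:
            raise BeliefError(f"inconsistent Gaussian shapes W{W.shape} h{h.shape}")
        if not np.allclose(W, W.T, atol=1e-12, rtol=0.0):
            raise BeliefError("precision matrix must be symmetric")
        self.W = 0.5 * (W + W.T)
        self.h = h
        self.g = float(g)

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_moment(
        cls,
        mean: Union[float, np.ndarray],
        cov: Union[float, np.ndarray],
        log_scale: float = 0.0,
    ) -> "GaussianBelief":
        """Build from moments; ``log_scale`` is the log of the total mass."""
        m = np.atleast_1d(np.asarray(mean, dtype=float))
        V = np.atleast_2d(np.asarray(cov, dtype=float))
        d = m.shape[0]
        L = np.linalg.cholesky(V)  # raises LinAlgError if not PD
        W = np.linalg.inv(V)
        W = 0.5 * (W + W.T)
        h = W @ m
        logdet_2piV = 2.0 * np.sum(np.log(np.diag(L))) + d * _LOG_2PI
        g = log_scale - 0.5 * float(m @ h) - 0.5 * logdet_2piV
        return cls(W, h, g)

    @classmethod
    def from_canonical(cls, W, h, g: float = 0.0) -> "GaussianBelief":
        return cls(W, h, g)

    # -- structure --------------------------------------------------------
    @property
    def dim(self) -> int:
        return self.W.shape[0]

    @property
    def is_proper(self) -> bool:
        """True when the precision is positive definite (finite mass)."""
        try:
            np.linalg.cholesky(self.W)
            return True
        except np.linalg.LinAlgError:
            return False

    @property
    def mean(self) -> np.ndarray:
        return np.linalg.solve(self.W, self.h)

    @property
    def cov(self) -> np.ndarray:
        V = np.linalg.inv(self.W)
        return 0.5 * (V + V.T)

    @property
    def mean_scalar(self) -> float:
        return float(self.mean[0])

    @property
    def cov_scalar(self) -> float:
        return float(self.cov[0, 0])

    @property
    def log_integral(self) -> float:
        """log of the total mass ``\\int b(x) dx`` (proper beliefs only)."""
        L = np.linalg.cholesky(self.W)
        half_hWh = 0.5 * float(self.h @ np.linalg.solve(self.W, self.h))
        logdet_W = 2.0 * np.sum(np.log(np.diag(L)))
        return self.g + half_hWh + 0.5 * (self.dim * _LOG_2PI - logdet_W)

    # spec naming: the multiplicative constant of the belief
    log_scale = log_integral

    def logpdf_unnorm(self, x) -> float:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return float(-0.5 * x @ self.W @ x + self.h @ x + self.g)

    # -- algebra ----------------------------------------------------------
    def multiply(self, other: "GaussianBelief") -> "GaussianBelief":
        if self.dim != other.dim:
            raise SupportMismatchError("Gaussian dimensions differ")
        return GaussianBelief(self.W + other.W, self.h + other.h, self.g + other.g)

    def convolve(self, other: "GaussianBelief") -> "GaussianBelief":
        """Distribution of a sum of independent variables (addition node).

        Works even when one operand is improper (singular precision), via
        exact marginalization of the joint exponential form.
        """
        if self.is_proper and other.is_proper:
            try:
                m = self.mean + other.mean
                V = self.cov + other.cov
                return GaussianBelief.from_moment(
                    m, V, self.log_integral + other.log_integral
                )
            except np.linalg.LinAlgError:
                pass  # numerically singular despite the cholesky probe
        # joint over (x, s) with s = x + y: b_x(x) * b_y(s - x), marginalize x
        d = self.dim
        Wx, hx, gx = self.W, self.h, self.g
        Wy, hy, gy = other.W, other.h, other.g
        W = np.zeros((2 * d, 2 * d))
        W[:d, :d] = Wx + Wy
        W[d:, d:] = Wy
        W[:d, d:] = -Wy
        W[d:, :d] = -Wy
        h = np.concatenate([hx - hy, hy])
        return marginalize_exponential(W, h, gx + gy, keep=list(range(d, 2 * d)))

    def shift(self, b) -> "GaussianBelief":
        """Belief of ``x + b`` for a constant ``b``."""
        b = np.atleast_1d(np.asarray(b, dtype=float))
        return GaussianBelief.from_moment(self.mean + b, self.cov, self.log_integral)

    def pushforward(self, A: np.ndarray) -> "GaussianBelief":
        """Belief of ``y = A x`` (gain node, forward direction)."""
        A = np.atleast_2d(np.asarray(A, dtype=float))
        if A.shape[0] == A.shape[1]:
            try:
                Ainv = np.linalg.inv(A)
            except np.linalg.LinAlgError:
                Ainv = None
            if Ainv is not None:
                W = Ainv.T @ self.W @ Ainv
                h = Ainv.T @ self.h
                _, logdet = np.linalg.slogdet(A)
                return GaussianBelief(W, h, self.g - logdet)
        m = A @ self.mean
        V = A @ self.cov @ A.T
        return GaussianBelief.from_moment(m, V, self.log_integral)

    def pullback(self, A: np.ndarray) -> "GaussianBelief":
        """Belief ``x -> b(Ax)`` (gain node, backward direction).

        The result may be improper (singular precision) when ``A`` is not
        square; it still composes exactly with proper beliefs.
        """
        A = np.atleast_2d(np.asarray(A, dtype=float))
        return GaussianBelief(A.T @ self.W @ A, A.T @ self.h, self.g)

    def normalized(self) -> "GaussianBelief":
        return GaussianBelief(self.W, self.h, self.g - self.log_integral)

    def entropy(self) -> float:
        sign, logdet_W = np.linalg.slogdet(self.W)
        if sign <= 0:
            raise BeliefError("entropy of an improper Gaussian")
        return 0.5 * (self.dim * (1.0 + _LOG_2PI) - logdet_W)

    def __repr__(self) -> str:
        if self.is_proper:
            return f"GaussianBelief(m={self.mean}, V={self.cov})"
        return f"GaussianBelief(canonical W={self.W}, h={self.h})"


class CategoricalBelief:
    """Unnormalized belief over a finite alphabet, kept in log space."""

    __slots__ = ("log_weights",)

    def __init__(self, weights=None, *, log_weights=None):
        if (weights is None) == (log_weights is None):
            raise BeliefError("give exactly one of weights / log_weights")
        if weights is not None:
            w = np.asarray(weights, dtype=float)
            if np.any(w < 0):
                raise BeliefError("categorical weights must be nonnegative")
            with np.errstate(divide="ignore"):
                lw = np.log(w)
        else:
            lw = np.asarray(log_weights, dtype=float)
        if lw.ndim != 1 or lw.size == 0 or not np.any(lw > -np.inf):
            raise BeliefError("categorical belief needs >=1 positive weight")
        self.log_weights = lw

    @property
    def size(self) -> int:
        return self.log_weights.shape[0]

    @property
    def weights(self) -> np.ndarray:
        return np.exp(self.log_weights - self.log_scale_shift)

    @property
    def log_scale_shift(self) -> float:
        """Max-subtraction offset used when materializing weights."""
        return float(np.max(self.log_weights))

    @property
    def log_scale(self) -> float:
        """log of the total mass of the belief."""
        return float(logsumexp(self.log_weights))

    @property
    def probs(self) -> np.ndarray:
        p = np.exp(self.log_weights - self.log_scale)
        return p / p.sum()

    def multiply(self, other: "CategoricalBelief") -> "CategoricalBelief":
        if self.size != other.size:
            raise SupportMismatchError("categorical alphabets differ")
        return CategoricalBelief(log_weights=self.log_weights + other.log_weights)

    def normalized(self) -> "CategoricalBelief":
        return CategoricalBelief(log_weights=self.log_weights - self.log_scale)

    def entropy(self) -> float:
        p = self.probs
        nz = p > 0
        return float(-np.sum(p[nz] * np.log(p[nz])))

    def __repr__(self) -> str:
        return f"CategoricalBelief(probs={np.round(self.probs, 4)})"


Belief = Union[Vacuous, PointMass, GaussianBelief, CategoricalBelief]


@dataclasses.dataclass
class Message:
    """A directed belief on an edge.

    ``toward`` is the id of the node the message flows into, or ``None`` for
    the outward direction of a half-edge.
    """

    edge_id: str
    toward: Optional[str]
    belief: Belief


@dataclasses.dataclass
class Marginal:
    """A normalized belief on an edge together with its log normalizer."""

    edge_id: str
    belief: Belief
    log_normalizer: float


def marginalize_exponential(W, h, g: float, keep) -> GaussianBelief:
    """Integrate out the non-kept coordinates of exp(-x'Wx/2 + h'x + g).

    The dropped block of ``W`` must be positive definite (the integral over
    those coordinates must converge); the kept block may end up singular.
    """
    n = W.shape[0]
    keep = list(keep)
    drop = [i for i in range(n) if i not in keep]
    if not drop:
        return GaussianBelief(W, h, g)
    Wkk = W[np.ix_(keep, keep)]
    Wkd = W[np.ix_(keep, drop)]
    Wdd = W[np.ix_(drop, drop)]
    hk, hd = h[keep], h[drop]
    L = np.linalg.cholesky(Wdd)  # raises if the integral diverges
    Wdd_inv_Wdk = np.linalg.solve(Wdd, Wkd.T)
    Wp = Wkk - Wkd @ Wdd_inv_Wdk
    hp = hk - Wkd @ np.linalg.solve(Wdd, hd)
    logdet_Wdd = 2.0 * np.sum(np.log(np.diag(L)))
    gp = g + 0.5 * float(hd @ np.linalg.solve(Wdd, hd)) + 0.5 * (
        len(drop) * _LOG_2PI - logdet_Wdd
    )
    return GaussianBelief(Wp, hp, gp)


# ----------------------------------------------------------------------------
# products and combination


def _product(a: Belief, b: Belief):
    """Pointwise product of two beliefs -> (normalized belief, log integral)."""
    if isinstance(a, Vacuous) and isinstance(b, Vacuous):
        raise NotNormalizableError("product of two vacuous beliefs")
    if isinstance(a, Vacuous):
        return _normalize(b)
    if isinstance(b, Vacuous):
        return _normalize(a)
    if isinstance(a, PointMass) and isinstance(b, PointMass):
        if a.is_discrete and b.is_discrete and a.value == b.value:
            return PointMass(a.value), a.log_scale + b.log_scale
        raise NotNormalizableError("product of two point masses")
    if isinstance(a, PointMass) or isinstance(b, PointMass):
        pm, other = (a, b) if isinstance(a, PointMass) else (b, a)
        if isinstance(other, GaussianBelief):
            if pm.is_discrete:
                raise SupportMismatchError("discrete point mass on a Gaussian edge")
            logz = other.logpdf_unnorm(pm.value) + pm.log_scale
        elif isinstance(other, CategoricalBelief):
            if not pm.is_discrete:
                raise SupportMismatchError("continuous point mass on a finite edge")
            logz = float(other.log_weights[int(pm.value)]) + pm.log_scale
            if not np.isfinite(logz):
                raise NotNormalizableError("point mass outside categorical support")
        else:  # pragma: no cover - defensive
            raise SupportMismatchError(f"cannot combine point mass with {other!r}")
        return PointMass(pm.value), logz
    if isinstance(a, GaussianBelief) and isinstance(b, GaussianBelief):
        prod = a.multiply(b)
        if not prod.is_proper:
            raise NotNormalizableError("Gaussian product is improper")
        return prod.normalized(), prod.log_integral
    if isinstance(a, CategoricalBelief) and isinstance(b, CategoricalBelief):
        prod = a.multiply(b)
        return prod.normalized(), prod.log_scale
    raise SupportMismatchError(f"incompatible belief families {a!r} / {b!r}")


def _normalize(b: Belief):
    if isinstance(b, PointMass):
        return PointMass(b.value), b.log_scale
    if isinstance(b, GaussianBelief):
        if not b.is_proper:
            raise NotNormalizableError("improper Gaussian cannot be normalized")
        return b.normalized(), b.log_integral
    if isinstance(b, CategoricalBelief):
        return b.normalized(), b.log_scale
    raise NotNormalizableError("vacuous belief cannot be normalized")


def combine(forward: Message, backward: Message) -> Marginal:
    """Fuse the forward and backward messages on an edge into the marginal.

    The log normalizer accumulates both message scales plus the normalization
    constant, so that on a tree it equals the log evidence of the boxed graph.
    """
    if forward.edge_id != backward.edge_id:
        raise SupportMismatchError("messages live on different edges")
    if forward.toward is not None and forward.toward == backward.toward:
        raise SupportMismatchError("messages must point in opposite directions")
    belief, logz = _product(forward.belief, backward.belief)
    return Marginal(forward.edge_id, belief, logz)


def gaussian_product(a: GaussianBelief, b: GaussianBelief) -> GaussianBelief:
    """Unnormalized product of two Gaussians: precisions and weighted means add."""
    return a.multiply(b)


# ----------------------------------------------------------------------------
# divergences and entropies


def kl(q: Belief, p: Belief) -> float:
    """Kullback-Leibler divergence D(q || p) between normalized beliefs."""
    if isinstance(q, CategoricalBelief) and isinstance(p, CategoricalBelief):
        if q.size != p.size:
            raise SupportMismatchError("categorical alphabets differ")
        qp, pp = q.probs, p.probs
        if np.any((qp > 0) & (pp == 0)):
            raise SupportMismatchError("p is not absolutely continuous wrt q")
        nz = qp > 0
        return float(np.sum(qp[nz] * (np.log(qp[nz]) - np.log(pp[nz]))))
    if isinstance(q, GaussianBelief) and isinstance(p, GaussianBelief):
        if q.dim != p.dim:
            raise SupportMismatchError("Gaussian dimensions differ")
        mq, Vq = q.mean, q.cov
        mp_, Vp = p.mean, p.cov
        d = q.dim
        Vp_inv = np.linalg.inv(Vp)
        delta = mq - mp_
        _, logdet_q = np.linalg.slogdet(Vq)
        _, logdet_p = np.linalg.slogdet(Vp)
        val = 0.5 * (
            np.trace(Vp_inv @ Vq) + delta @ Vp_inv @ delta - d + logdet_p - logdet_q
        )
        return max(float(val), 0.0)
    raise SupportMismatchError(f"kl not defined for {q!r} vs {p!r}")


def entropy(b: Belief) -> float:
    """Shannon/differential entropy of the normalized belief."""
    if isinstance(b, PointMass):
        raise DegenerateEntropyError("entropy of a point mass is -inf")
    if isinstance(b, GaussianBelief):
        return b.entropy()
    if isinstance(b, CategoricalBelief):
        return b.entropy()
    raise BeliefError("entropy of a vacuous belief is undefined")
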