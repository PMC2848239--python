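"""The unified generative-discriminative objective and its training.

A single weighted objective interpolates between discriminative and
generative fitting of the two-PWM classifier:

    F(lambda) = b0 * log P(C | D, lambda)        (conditional likelihood)
              + b1 * log P(C, D | lambda)        (joint likelihood)
              + b2 * log Q(lambda | alpha)       (prior)

with nonnegative weights beta = (b0, b1, b2) summing to one.  The classical
learning principles are corners or edges of this simplex:

    ML  = (0, 1, 0)      MAP = (0, 0.5, 0.5)
    MCL = (1, 0, 0)      MSP = (0.5, 0, 0.5)
    GDT  : b2 = 0, the (1-g, g, 0) edge between MCL and ML
    PGDT : b2 = 0.5, the ((1-g)/2, g/2, 0.5) edge between MSP and MAP

Because the prior family is closed under powering (see :mod:`.model`), any
point with b0 + b1 > 0 can be rewritten as a penalized trade-off with
trade-off weight gamma = b1/(b0+b1) and prior power xi = b2/(b0+b1)
(:func:`pgdt_canonical`), and the generative-plus-prior part b1*log P(C,D|.)
+ b2*log Q can be absorbed into a single effective prior with pseudo-counts
b1*n + b2*alpha (:func:`effective_posterior_hyperparams`) — i.e. every
simplex point is a supervised-posterior fit under a data-informed prior.

For b0 = 0 the maximizer is available in closed form (pseudo-count
estimator); otherwise the objective is maximized numerically with an
analytic gradient and a limited-memory quasi-Newton method (L-BFGS-B),
warm-started from a smoothed generative estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .model import (
    ClassifierParams,
    Counts,
    DirichletHyper,
    prior_log_density,
    sufficient_counts,
)
from .seqdata import LabeledData

logger = logging.getLogger(__name__)

__all__ = [
    "BetaWeights",
    "beta_for_principle",
    "gdt_beta",
    "pgdt_beta",
    "parse_principle",
    "joint_log_likelihood",
    "conditional_log_likelihood",
    "unified_objective",
    "objective_gradient",
    "closed_form_generative",
    "pgdt_canonical",
    "effective_posterior_hyperparams",
    "TrainConfig",
    "TrainResult",
    "train",
]


@dataclass(frozen=True)
class BetaWeights:
    """Simplex weights (b0, b1, b2) over conditional, joint, and prior terms."""

    b0: float
    b1: float
    b2: float

    def __post_init__(self) -> None:
        if min(self.b0, self.b1, self.b2) < 0:
            raise ValueError("beta components must be nonnegative")
        if abs(self.b0 + self.b1 + self.b2 - 1.0) > 1e-12:
            raise ValueError("beta components must sum to 1 (use BetaWeights.normalized)")

    @classmethod
    def normalized(cls, b0: float, b1: float, b2: float) -> "BetaWeights":
        """Renormalize nonnegative weights to sum to one; exact zeros kept."""
        if min(b0, b1, b2) < 0:
            raise ValueError("beta components must be nonnegative")
        s = b0 + b1 + b2
        if s <= 0:
            raise ValueError("at least one beta component must be positive")
        b0, b1, b2 = b0 / s, b1 / s, b2 / s
        return cls(b0, b1, max(1.0 - b0 - b1, 0.0))

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.b0, self.b1, self.b2)


_PRINCIPLES = {
    "ML": (0.0, 1.0, 0.0),
    "MAP": (0.0, 0.5, 0.5),
    "MCL": (1.0, 0.0, 0.0),
    "MSP": (0.5, 0.0, 0.5),
}


def beta_for_principle(name: str) -> BetaWeights:
    """Beta weights of a named corner principle (ML, MAP, MCL, MSP)."""
    try:
        return BetaWeights(*_PRINCIPLES[name.upper()])
    except KeyError:
        raise ValueError(f"unknown learning principle {name!r}; expected one of {sorted(_PRINCIPLES)}")


def gdt_beta(gamma: float) -> BetaWeights:
    """Generative-discriminative trade-off: (1-g, g, 0); g=1 is ML, g=0 MCL."""
    if not 0 <= gamma <= 1:
        raise ValueError("gamma must lie in [0, 1]")
    return BetaWeights(1.0 - gamma, gamma, 0.0)


def pgdt_beta(gamma: float) -> BetaWeights:
    """Penalized trade-off: ((1-g)/2, g/2, 0.5); g=1 is MAP, g=0 MSP."""
    if not 0 <= gamma <= 1:
        raise ValueError("gamma must lie in [0, 1]")
    return BetaWeights((1.0 - gamma) / 2.0, gamma / 2.0, 0.5)


def parse_principle(spec: str) -> BetaWeights:
    """Parse 'ML' / 'MAP' / 'MCL' / 'MSP' / 'GDT:g' / 'PGDT:g'."""
    name, _, arg = spec.partition(":")
    name = name.upper()
    if name in _PRINCIPLES:
        return beta_for_principle(name)
    if name == "GDT":
        return gdt_beta(float(arg))
    if name == "PGDT":
        return pgdt_beta(float(arg))
    raise ValueError(f"unknown learning principle {spec!r}")


# ---------------------------------------------------------------------------
# Objective terms


def _class_scores(params: ClassifierParams, X: np.ndarray) -> np.ndarray:
    """(N, 2) matrix of log P(c) + log P(x_i | c) for both classes."""
    lcp = params.log_class_probs
    lpw = params.log_pwm_probs  # (2, L, K)
    L = X.shape[1]
    pos = np.arange(L)
    s = np.empty((X.shape[0], 2))
    for c in (0, 1):
        s[:, c] = lcp[c] + lpw[c][pos, X].sum(axis=1)
    return s


def joint_log_likelihood(params: ClassifierParams, data: LabeledData) -> float:
    """log P(C, D | lambda) = sum_i [log P(c_i) + log P(x_i | c_i)]."""
    if data.n == 0:
        raise ValueError("empty data set")
    counts = sufficient_counts(data)
    return _joint_from_counts(params, counts)


def _joint_from_counts(params: ClassifierParams, counts: Counts) -> float:
    val = float(np.dot(counts.class_counts, params.log_class_probs))
    K = params.K
    val += float((counts.pwm_counts[:, :, :K] * params.log_pwm_probs).sum())
    return val


def conditional_log_likelihood(params: ClassifierParams, data: LabeledData) -> float:
    """log P(C | D, lambda), evaluated in log space with log-sum-exp."""
    if data.n == 0:
        raise ValueError("empty data set")
    X = data.matrix()
    if X.shape[1] != params.L:
        raise ValueError(f"sequence length {X.shape[1]} != model length {params.L}")
    s = _class_scores(params, X)
    lse = logsumexp(s, axis=1)
    return float(s[np.arange(data.n), data.labels].sum() - lse.sum())


def unified_objective(
    params: ClassifierParams,
    data: LabeledData,
    beta: BetaWeights,
    hyper: DirichletHyper,
) -> float:
    """b0 * conditional + b1 * joint + b2 * prior log density."""
    val = 0.0
    if beta.b0:
        val += beta.b0 * conditional_log_likelihood(params, data)
    if beta.b1:
        val += beta.b1 * joint_log_likelihood(params, data)
    if beta.b2:
        val += beta.b2 * prior_log_density(params, hyper)
    return val


# ---------------------------------------------------------------------------
# Gradient
#
# Every term of the objective has, per simplex group, the form
# sum_a w_a log theta_a (+ const), whose gradient w.r.t. the unconstrained
# z_b is w_b - theta_b * sum_a w_a.  The weights w are:
#   joint      : observed counts (N_c for the class group, n[c,l,a] per column)
#   normalizer : posterior-expected counts sum_i P(c | x_i)
#   prior      : pseudo-counts alpha
# so all gradients are "counts minus expected counts" expressions and the
# per-group components sum to zero (the softmax gauge direction).


def _weighted_grad(w_class, w_pwm, params):
    """Gradient of sum-of-groups  w . log theta  w.r.t. flattened z."""
    gc = w_class - params.class_probs * w_class.sum()
    gp = w_pwm - params.pwm_probs * w_pwm.sum(axis=2, keepdims=True)
    return gc, gp


def _posterior_counts(params: ClassifierParams, X: np.ndarray):
    """Posterior class weights and expected per-column counts."""
    s = _class_scores(params, X)
    lse = logsumexp(s, axis=1)
    post = np.exp(s - lse[:, None])  # (N, 2)
    L, K = params.L, params.K
    m = np.zeros((2, L, K))
    for c in (0, 1):
        w = post[:, c]
        for l in range(L):
            m[c, l] = np.bincount(X[:, l], weights=w, minlength=K)[:K]
    return post.sum(axis=0), m, lse


def _objective_and_grad(
    zflat: np.ndarray,
    X: np.ndarray,
    counts: Counts,
    beta: BetaWeights,
    hyper: DirichletHyper,
    L: int,
    K: int,
):
    params = ClassifierParams.unflatten(zflat, L, K)
    lcp = params.log_class_probs
    lpw = params.log_pwm_probs

    joint = float(np.dot(counts.class_counts, lcp) + (counts.pwm_counts[:, :, :K] * lpw).sum())
    gc, gp = _weighted_grad(counts.class_counts, counts.pwm_counts[:, :, :K], params)
    w01 = beta.b0 + beta.b1
    val = w01 * joint
    grad_c = w01 * gc
    grad_p = w01 * gp

    if beta.b0:
        m_class, m_pwm, lse = _posterior_counts(params, X)
        val -= beta.b0 * float(lse.sum())
        mc, mp = _weighted_grad(m_class, m_pwm, params)
        grad_c -= beta.b0 * mc
        grad_p -= beta.b0 * mp

    if beta.b2:
        val += beta.b2 * prior_log_density(params, hyper)
        pc, pp = _weighted_grad(hyper.class_alpha, hyper.pwm_alpha, params)
        grad_c += beta.b2 * pc
        grad_p += beta.b2 * pp

    grad = np.concatenate([grad_c, grad_p.ravel()])
    return val, grad


def objective_gradient(
    params: ClassifierParams,
    data: LabeledData,
    beta: BetaWeights,
    hyper: DirichletHyper,
) -> np.ndarray:
    """Analytic gradient of the unified objective w.r.t. all unconstrained z.

    Layout matches :meth:`ClassifierParams.flatten`: class z first, then the
    two PWMs row by row.  Within every simplex group the components sum to
    zero (gauge direction).
    """
    X = data.matrix()
    counts = sufficient_counts(data)
    _, grad = _objective_and_grad(params.flatten(), X, counts, beta, hyper, params.L, params.K)
    return grad


# ---------------------------------------------------------------------------
# Closed forms and beta algebra


def closed_form_generative(counts: Counts, beta: BetaWeights, hyper: DirichletHyper) -> ClassifierParams:
    """Exact maximizer for b0 = 0: theta = (b1*n + b2*alpha) / (b1*N + b2*ESS).

    With b2 = 0 this is the relative-frequency (ML) estimate; with b1 = b2
    it is the pseudo-count posterior-mode/mean estimate; with b1 = 0 the
    prior base distribution.
    """
    if beta.b0 != 0:
        raise ValueError("closed form requires b0 = 0")
    if beta.b1 + beta.b2 <= 0:
        raise ValueError("b1 + b2 must be positive")
    K = hyper.K
    num_class = beta.b1 * counts.class_counts + beta.b2 * hyper.class_alpha
    class_probs = num_class / num_class.sum()
    num_pwm = beta.b1 * counts.pwm_counts[:, :, :K] + beta.b2 * hyper.pwm_alpha
    pwm_probs = num_pwm / num_pwm.sum(axis=2, keepdims=True)
    return ClassifierParams.from_probs(class_probs, pwm_probs)


def pgdt_canonical(beta: BetaWeights) -> tuple[float, float]:
    """Rewrite a simplex point as a penalized trade-off (gamma, xi).

    gamma = b1/(b0+b1) interpolates generative (1) to discriminative (0);
    xi = b2/(b0+b1) is the power applied to the prior.  The rescaled
    objective (b0+b1) * [(1-gamma)*cond + gamma*joint + log Q^xi] has the
    same maximizer as the original.
    """
    s = beta.b0 + beta.b1
    if s <= 0:
        raise ValueError("pure-prior point (b0 + b1 = 0) has no trade-off form")
    return beta.b1 / s, beta.b2 / s


def effective_posterior_hyperparams(beta: BetaWeights, counts: Counts, hyper: DirichletHyper) -> DirichletHyper:
    """Pseudo-counts of the weighted posterior alpha~ = b1*n + b2*alpha.

    Absorbing the generative and prior terms into one Dirichlet-type kernel
    shows every simplex point to be a supervised-posterior fit under this
    data-informed prior.  The composition is defined for all beta; for
    weights with zero components it remains the correct kernel algebra even
    though the "informative prior" reading presumes strictly positive
    weights.
    """
    K = hyper.K
    class_alpha = beta.b1 * counts.class_counts + beta.b2 * hyper.class_alpha
    pwm_alpha = beta.b1 * counts.pwm_counts[:, :, :K] + beta.b2 * hyper.pwm_alpha
    return DirichletHyper(class_alpha=class_alpha, pwm_alpha=pwm_alpha)


# ---------------------------------------------------------------------------
# Training


@dataclass
class TrainConfig:
    """Numerical-training settings.

    tol        : max-norm of the per-observation objective gradient
                 (gradient of F/N) declaring convergence
    ftol       : relative objective-change stopping criterion of L-BFGS-B
    max_iter   : iteration cap
    init       : 'generative' (smoothed closed form) or 'uniform'
    n_starts   : extra random restarts (0 = single deterministic start)
    seed       : seed for the random restarts
    """

    tol: float = 1e-6
    ftol: float = 1e-11
    max_iter: int = 1000
    init: str = "generative"
    n_starts: int = 0
    seed: int = 0


@dataclass
class TrainResult:
    params: ClassifierParams
    objective_value: float
    gradient_norm: float  # max-norm of the per-observation gradient (of F/N)
    iterations: int
    converged: bool  # gradient_norm <= config.tol


_INIT_EPS = 1e-3


def _initial_params(counts: Counts, beta: BetaWeights, hyper: DirichletHyper) -> ClassifierParams:
    # Smoothed generative warm start: closed form at (0, max(b1,eps), max(b2,eps)).
    b1p, b2p = max(beta.b1, _INIT_EPS), max(beta.b2, _INIT_EPS)
    smoothed = BetaWeights.normalized(0.0, b1p, b2p)
    return closed_form_generative(counts, smoothed, hyper)


def train(
    data: LabeledData,
    beta: BetaWeights,
    hyper: DirichletHyper,
    config: TrainConfig | None = None,
) -> TrainResult:
    """Maximize the unified objective by quasi-Newton ascent.

    Deterministic given (data, beta, hyper, config).  The returned objective
    value is never below the value at the initialization.  Non-convergence
    within ``max_iter`` is reported through ``converged=False``, not raised.
    """
    config = config or TrainConfig()
    sizes = data.class_sizes()
    if sizes.min() == 0:
        raise ValueError("training data must contain both classes")
    X = data.matrix()
    L, K = X.shape[1], hyper.K
    counts = sufficient_counts(data)
    # Optimize the per-observation objective F/N: tolerances then have a
    # size-independent meaning and L-BFGS-B's relative ftol is unaffected.
    scale = 1.0 / max(counts.N, 1)

    def neg(z):
        v, g = _objective_and_grad(z, X, counts, beta, hyper, L, K)
        return -v * scale, -g * scale

    starts = [_initial_params(counts, beta, hyper).flatten()]
    if config.n_starts:
        rng = np.random.default_rng(config.seed)
        starts += [starts[0] + rng.normal(scale=1.0, size=starts[0].size) for _ in range(config.n_starts)]

    best = None
    for z0 in starts:
        res = minimize(
            neg,
            z0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": config.max_iter, "ftol": config.ftol, "gtol": config.tol, "maxcor": 20},
        )
        if best is None or -res.fun > -best.fun:
            best = res
    gnorm = float(np.max(np.abs(best.jac)))
    params = ClassifierParams.unflatten(best.x, L, K)
    converged = gnorm <= config.tol
    if not converged:
        logger.debug("train: stopped with gradient max-norm %.3g (status %s)", gnorm, best.status)
    return TrainResult(
        params=params,
        objective_value=float(-best.fun / scale),
        gradient_norm=gnorm,
        iterations=int(best.nit),
        converged=converged,
    )
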