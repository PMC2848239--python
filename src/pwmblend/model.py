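"""PWM likelihood model and the transformed-Dirichlet prior with ESS semantics.

The classifier is a two-class naive-Bayes model: each class ``c`` has a
position weight matrix (PWM) of per-position nucleotide distributions
``theta[c][l]`` and the classes have probabilities ``P(c)``.  All simplex
parameters are represented by unconstrained reals ``z`` through the
normalized exponential (softmax)

    theta_a = exp(z_a) / sum_b exp(z_b),

which is over-parameterized (shifting all ``z`` of a group leaves ``theta``
unchanged); the objectives are invariant in this gauge direction and the
optimizer handles the flat direction, so no gauge fixing is applied.

The prior is a product of per-group Dirichlet-type densities on the
*transformed* (unconstrained) parameters.  Including the change-of-variables
correction, the log density of one group with pseudo-counts ``alpha`` is

    sum_a alpha_a * log theta_a  -  log Z(alpha),
    Z(alpha) = prod_a Gamma(alpha_a + 1) / Gamma(sum_a alpha_a + K),

i.e. the kernel exponent is ``alpha_a`` rather than ``alpha_a - 1``.  Two
consequences make this convention the natural one here: (i) raising the
prior to a power ``xi`` is again a prior of the same family with
hyper-parameters ``xi * alpha`` (power closure, exact up to a
parameter-independent normalization), and (ii) the penalized-generative
closed form is the pseudo-count estimator ``(n + alpha) / (N + ESS)``.

The total pseudo-count mass of a group is its *equivalent sample size*
(ESS); per-class defaults are 4 (foreground) and 1024 (background) with a
uniform base distribution ("uniform pseudo data").
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import gammaln, log_softmax, softmax

from .seqdata import LabeledData, Sequence

__all__ = [
    "SimplexGroup",
    "PWM",
    "ClassifierParams",
    "DirichletHyper",
    "Counts",
    "to_probabilities",
    "pwm_log_prob",
    "sufficient_counts",
    "hyperparams_from_ess",
    "prior_log_density",
    "power_prior",
    "virtual_ess",
    "save_model",
    "load_model",
]


@dataclass
class SimplexGroup:
    """Unconstrained reals ``z`` parameterizing a probability vector."""

    z: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)

    @property
    def theta(self) -> np.ndarray:
        return to_probabilities(self)

    @property
    def log_theta(self) -> np.ndarray:
        return log_softmax(self.z)


def to_probabilities(group: SimplexGroup) -> np.ndarray:
    """Normalized exponentials of ``z``, computed with a max shift."""
    z = np.asarray(group.z, dtype=float) if isinstance(group, SimplexGroup) else np.asarray(group, float)
    if not np.all(np.isfinite(z)):
        raise FloatingPointError("non-finite unconstrained parameters")
    return softmax(z)


@dataclass
class PWM:
    """Per-position multinomial model for fixed-length words; z is (L, K)."""

    z: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.atleast_2d(np.asarray(self.z, dtype=float))

    @property
    def L(self) -> int:
        return self.z.shape[0]

    @property
    def K(self) -> int:
        return self.z.shape[1]

    @property
    def theta(self) -> np.ndarray:
        return softmax(self.z, axis=1)

    @property
    def log_theta(self) -> np.ndarray:
        return log_softmax(self.z, axis=1)

    @classmethod
    def from_probs(cls, theta: np.ndarray) -> "PWM":
        theta = np.atleast_2d(np.asarray(theta, float))
        return cls(z=np.log(np.clip(theta, 1e-300, None)))


def pwm_log_prob(pwm: PWM, x: Sequence) -> float:
    """Log probability of a fixed-length word under a PWM."""
    res = x.residues if isinstance(x, Sequence) else np.asarray(x)
    if res.size != pwm.L:
        raise ValueError(f"sequence length {res.size} != PWM length {pwm.L}")
    lt = pwm.log_theta
    return float(lt[np.arange(pwm.L), res].sum())


@dataclass
class ClassifierParams:
    """Full parameter vector: class probabilities plus one PWM per class.

    Class 0 is background, class 1 foreground; both PWMs share ``L``.
    """

    class_z: np.ndarray  # shape (2,)
    pwm_z: np.ndarray    # shape (2, L, K)

    def __post_init__(self) -> None:
        self.class_z = np.asarray(self.class_z, dtype=float)
        self.pwm_z = np.asarray(self.pwm_z, dtype=float)
        if self.class_z.shape != (2,):
            raise ValueError("exactly two classes are supported")
        if self.pwm_z.ndim != 3 or self.pwm_z.shape[0] != 2:
            raise ValueError("pwm_z must have shape (2, L, K)")

    @property
    def L(self) -> int:
        return self.pwm_z.shape[1]

    @property
    def K(self) -> int:
        return self.pwm_z.shape[2]

    @property
    def class_group(self) -> SimplexGroup:
        return SimplexGroup(self.class_z)

    def pwm(self, c: int) -> PWM:
        return PWM(self.pwm_z[c])

    @property
    def class_probs(self) -> np.ndarray:
        return softmax(self.class_z)

    @property
    def log_class_probs(self) -> np.ndarray:
        return log_softmax(self.class_z)

    @property
    def pwm_probs(self) -> np.ndarray:
        return softmax(self.pwm_z, axis=2)

    @property
    def log_pwm_probs(self) -> np.ndarray:
        return log_softmax(self.pwm_z, axis=2)

    def flatten(self) -> np.ndarray:
        return np.concatenate([self.class_z, self.pwm_z.ravel()])

    @classmethod
    def unflatten(cls, vec: np.ndarray, L: int, K: int) -> "ClassifierParams":
        vec = np.asarray(vec, float)
        return cls(class_z=vec[:2], pwm_z=vec[2:].reshape(2, L, K))

    @classmethod
    def from_probs(cls, class_probs: np.ndarray, pwm_probs: np.ndarray) -> "ClassifierParams":
        return cls(
            class_z=np.log(np.clip(np.asarray(class_probs, float), 1e-300, None)),
            pwm_z=np.log(np.clip(np.asarray(pwm_probs, float), 1e-300, None)),
        )


@dataclass
class DirichletHyper:
    """Pseudo-count vectors for the class group and every PWM column.

    ``class_alpha`` is ``(ESS_bg, ESS_fg)``; ``pwm_alpha[c, l]`` sums to the
    per-class ESS for every column ``l``.
    """

    class_alpha: np.ndarray  # (2,)
    pwm_alpha: np.ndarray    # (2, L, K)

    def __post_init__(self) -> None:
        self.class_alpha = np.asarray(self.class_alpha, dtype=float)
        self.pwm_alpha = np.asarray(self.pwm_alpha, dtype=float)
        if np.any(self.class_alpha <= 0) or np.any(self.pwm_alpha <= 0):
            raise ValueError("all pseudo-counts must be positive")

    @property
    def L(self) -> int:
        return self.pwm_alpha.shape[1]

    @property
    def K(self) -> int:
        return self.pwm_alpha.shape[2]

    @property
    def ess_per_class(self) -> np.ndarray:
        """Per-class PWM-column ESS (identical across columns by construction)."""
        return self.pwm_alpha.sum(axis=2)[:, 0]


def hyperparams_from_ess(
    ess_fg: float, ess_bg: float, L: int, K: int = 4, q: np.ndarray | None = None
) -> DirichletHyper:
    """Pseudo-counts for uniform (or given) base distribution ``q``.

    Column ``l`` of class ``c`` receives ``alpha = ESS_c * q``; the class
    group receives ``(ESS_bg, ESS_fg)``.
    """
    if ess_fg <= 0 or ess_bg <= 0:
        raise ValueError("equivalent sample sizes must be positive")
    if q is None:
        q = np.full(K, 1.0 / K)
    q = np.asarray(q, float)
    pwm_alpha = np.empty((2, L, K))
    pwm_alpha[0] = ess_bg * q
    pwm_alpha[1] = ess_fg * q
    return DirichletHyper(class_alpha=np.array([ess_bg, ess_fg]), pwm_alpha=pwm_alpha)


def _group_log_norm(alpha: np.ndarray, axis: int = -1) -> np.ndarray:
    """log Z(alpha) with Z the multivariate Beta at parameters (alpha + 1)."""
    K = alpha.shape[axis]
    return gammaln(alpha + 1.0).sum(axis=axis) - gammaln(alpha.sum(axis=axis) + K)


def prior_log_density(params: ClassifierParams, hyper: DirichletHyper) -> float:
    """Log density of the transformed-Dirichlet prior at ``params``.

    Sum over all groups of ``alpha . log theta - log Z(alpha)``.  Returns
    ``-inf`` (not an exception) when some ``theta`` underflows to zero.
    """
    val = float(np.dot(hyper.class_alpha, params.log_class_probs))
    val -= float(_group_log_norm(hyper.class_alpha))
    val += float((hyper.pwm_alpha * params.log_pwm_probs).sum())
    val -= float(_group_log_norm(hyper.pwm_alpha, axis=2).sum())
    return val


def power_prior(hyper: DirichletHyper, xi: float) -> DirichletHyper:
    """The prior raised to the power ``xi``: every pseudo-count scaled by ``xi``.

    The per-group ESS of the result is ``xi`` times the original ESS (the
    "virtual" ESS of the weighted prior).
    """
    if xi <= 0:
        raise ValueError("prior power xi must be positive")
    return DirichletHyper(class_alpha=xi * hyper.class_alpha, pwm_alpha=xi * hyper.pwm_alpha)


def virtual_ess(beta, ess: float, axis: str) -> float:
    """ESS of the effectively applied prior on a simplex axis.

    On the ``b0`` axis (``b1 = 0``) the objective is a supervised-posterior
    fit with the prior powered by ``xi = b2/b0``; on the ``b1`` axis
    (``b0 = 0``) it is a posterior fit with ``xi = b2/b1``.  The virtual ESS
    is ``xi`` times the nominal ESS.
    """
    if axis == "b0":
        denom = beta.b0
    elif axis == "b1":
        denom = beta.b1
    else:
        raise ValueError("axis must be 'b0' or 'b1'")
    if denom == 0:
        raise ZeroDivisionError(f"axis weight {axis} is zero")
    return beta.b2 / denom * ess


@dataclass
class Counts:
    """Sufficient statistics of the labeled data for the naive-Bayes model."""

    class_counts: np.ndarray  # (2,) = N_c
    pwm_counts: np.ndarray    # (2, L, K) = n^{(c)}_{l,a}

    @property
    def N(self) -> int:
        return int(self.class_counts.sum())


def sufficient_counts(data: LabeledData, L: int | None = None) -> Counts:
    """Per-class symbol counts per position: n[c, l, a], and class sizes N_c."""
    if data.n == 0:
        L = L or 0
        return Counts(np.zeros(2), np.zeros((2, max(L, 1), 4)))
    X = data.matrix()
    if L is not None and X.shape[1] != L:
        raise ValueError(f"sequences have length {X.shape[1]}, expected {L}")
    L = X.shape[1]
    K = int(X.max()) + 1 if X.size else 4
    K = max(K, 4)
    y = data.labels
    counts = np.zeros((2, L, K))
    for c in (0, 1):
        Xc = X[y == c]
        for l in range(L):
            counts[c, l] = np.bincount(Xc[:, l], minlength=K)
    class_counts = np.bincount(y, minlength=2).astype(float)
    return Counts(class_counts=class_counts, pwm_counts=counts)


# ---------------------------------------------------------------------------
# Serialization

def save_model(path, params: ClassifierParams, hyper: DirichletHyper | None = None,
               beta=None, extra: dict | None = None) -> None:
    """Write a model as JSON (probabilities, hyper-parameters, training beta)."""
    doc = {
        "L": params.L,
        "K": params.K,
        "class_probs": params.class_probs.tolist(),
        "pwm_probs": params.pwm_probs.tolist(),
        "class_z": params.class_z.tolist(),
        "pwm_z": params.pwm_z.tolist(),
    }
    if hyper is not None:
        doc["class_alpha"] = hyper.class_alpha.tolist()
        doc["pwm_alpha"] = hyper.pwm_alpha.tolist()
    if beta is not None:
        doc["beta"] = [beta.b0, beta.b1, beta.b2]
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path) -> tuple[ClassifierParams, dict]:
    """Read a model JSON; returns the parameters and the raw document."""
    doc = json.loads(Path(path).read_text())
    params = ClassifierParams(class_z=np.array(doc["class_z"]), pwm_z=np.array(doc["pwm_z"]))
    return params, doc
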