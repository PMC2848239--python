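"""Hold-out evaluation protocol and the beta-simplex performance scan.

The protocol mirrors a repeated stratified hold-out study: in each of
``repeats`` rounds, 90% of each class is drawn uniformly at random for
training and the remainder is scored, and the headline measure is the mean
(plus standard error) of the sensitivity at a fixed specificity of 99.9%
across rounds.  The background class is partitioned at the level of
*chunks* (pieces of at most ~100 bp), and overlapping windows are extracted
within each side of the split, so that near-duplicate windows never
straddle the train/test boundary.

The simplex scan evaluates this protocol on a grid over the weights
beta = (b0, b1, b2), reusing the identical sequence of train/test
partitions at every grid point so that comparisons between beta values are
paired.

Auxiliary measures: ROC-AUC (rank statistic with tie correction),
trapezoidal area under the precision-recall curve, and the classification
rate at the natural threshold 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .classifier import llr_scores
from .model import DirichletHyper
from .objective import BetaWeights, TrainConfig, train
from .seqdata import LabeledData, SiteBackgroundData, extract_windows

logger = logging.getLogger(__name__)

__all__ = [
    "HoldoutConfig",
    "PerformanceResult",
    "SimplexGridResult",
    "stratified_holdout_split",
    "sensitivity_at_specificity",
    "auxiliary_measures",
    "holdout_evaluate",
    "simplex_grid",
    "simplex_scan",
]


@dataclass(frozen=True)
class HoldoutConfig:
    repeats: int = 1000
    train_fraction: float = 0.9
    seed: int = 0
    specificity: float = 0.999

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie strictly between 0 and 1")
        if not 0 < self.specificity <= 1:
            raise ValueError("specificity must lie in (0, 1]")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


MEASURES = ("sensitivity", "roc_auc", "pr_auc", "classification_rate")


@dataclass
class PerformanceResult:
    """Per-repeat performance values with mean and standard-error summaries."""

    sensitivity: np.ndarray
    roc_auc: np.ndarray
    pr_auc: np.ndarray
    classification_rate: np.ndarray
    n_converged: int = 0
    partitions: list | None = field(default=None, repr=False)

    @property
    def repeats(self) -> int:
        return self.sensitivity.size

    def mean(self, measure: str = "sensitivity") -> float:
        return float(np.mean(getattr(self, measure)))

    def se(self, measure: str = "sensitivity") -> float:
        """Standard error of the mean: sd / sqrt(repeats)."""
        vals = getattr(self, measure)
        if vals.size < 2:
            return 0.0
        return float(np.std(vals, ddof=1) / np.sqrt(vals.size))

    @property
    def mean_sensitivity(self) -> float:
        return self.mean("sensitivity")

    @property
    def se_sensitivity(self) -> float:
        return self.se("sensitivity")

    def summary(self) -> dict:
        out = {}
        for m in MEASURES:
            out[f"mean_{m}"] = self.mean(m)
            out[f"se_{m}"] = self.se(m)
        return out

    def to_dict(self) -> dict:
        d = {m: getattr(self, m).tolist() for m in MEASURES}
        d["n_converged"] = self.n_converged
        d.update(self.summary())
        return d


# ---------------------------------------------------------------------------
# Splitting


def _split_indices(n: int, train_fraction: float, rng: np.random.Generator):
    if n < 2:
        raise ValueError("each class needs at least 2 items to split")
    perm = rng.permutation(n)
    n_train = int(np.floor(train_fraction * n))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def stratified_holdout_split(data: LabeledData, train_fraction: float, seed: int):
    """One stratified random partition of a labeled data set.

    Within each class, floor(train_fraction * n_c) items go to training and
    the remainder to testing; the two sides are disjoint and their union is
    the input.  Reproducible given the seed.
    """
    rng = np.random.default_rng(seed)
    labels = data.labels
    train_idx, test_idx = [], []
    for c in (0, 1):
        idx_c = np.flatnonzero(labels == c)
        tr, te = _split_indices(idx_c.size, train_fraction, rng)
        train_idx.append(idx_c[tr])
        test_idx.append(idx_c[te])
    train_idx = np.concatenate(train_idx)
    test_idx = np.concatenate(test_idx)
    return data.subset(train_idx), data.subset(test_idx)


def _repeat_seed(seed: int, r: int) -> int:
    """Derived per-repeat seed; depends only on (seed, r) so that splits
    are identical across beta points of one scan (paired comparisons)."""
    state = np.random.SeedSequence([int(seed), int(r)]).generate_state(1)[0]
    return int(state & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# Measures


def sensitivity_at_specificity(pos_scores, neg_scores, specificity: float = 0.999) -> float:
    """Fraction of positives scored strictly above the specificity threshold.

    With m negatives, k = floor((1 - specificity) * m) false positives are
    allowed; the threshold t is the (k+1)-th largest negative score (or
    -inf when k >= m), and a positive is a call iff its score exceeds t.
    """
    pos = np.asarray(pos_scores, float)
    neg = np.asarray(neg_scores, float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one positive and one negative score")
    m = neg.size
    k = int(np.floor((1.0 - specificity) * m + 1e-9))
    if k >= m:
        t = -np.inf
    else:
        t = np.partition(neg, m - 1 - k)[m - 1 - k]
    return float(np.mean(pos > t))


def _roc_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    # Rank statistic: P(pos > neg) + 0.5 P(tie), via midranks.
    from scipy.stats import rankdata

    allscores = np.concatenate([pos, neg])
    ranks = rankdata(allscores)
    n_pos, n_neg = pos.size, neg.size
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _pr_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    # Trapezoid over the full precision-recall curve, one point per distinct
    # threshold, anchored at (recall 0, precision 1).
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    order = np.argsort(-scores, kind="stable")
    scores, labels = scores[order], labels[order]
    tp = np.cumsum(labels)
    fp = np.cumsum(1 - labels)
    distinct = np.flatnonzero(np.diff(scores) != 0)
    idx = np.r_[distinct, scores.size - 1]
    recall = tp[idx] / pos.size
    precision = tp[idx] / (tp[idx] + fp[idx])
    recall = np.r_[0.0, recall]
    precision = np.r_[1.0, precision]
    return float(np.trapezoid(precision, recall))


def _classification_rate(pos: np.ndarray, neg: np.ndarray) -> float:
    correct = np.sum(pos > 0) + np.sum(neg <= 0)
    return float(correct / (pos.size + neg.size))


def auxiliary_measures(pos_scores, neg_scores) -> dict:
    """ROC-AUC, trapezoidal PR-AUC, and classification rate at threshold 0."""
    pos = np.asarray(pos_scores, float)
    neg = np.asarray(neg_scores, float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one positive and one negative score")
    return {
        "roc_auc": _roc_auc(pos, neg),
        "pr_auc": _pr_auc(pos, neg),
        "classification_rate": _classification_rate(pos, neg),
    }


# ---------------------------------------------------------------------------
# Protocol


def holdout_evaluate(
    data: SiteBackgroundData,
    beta: BetaWeights,
    hyper: DirichletHyper,
    config: HoldoutConfig,
    train_config: TrainConfig | None = None,
    collect_partitions: bool = False,
) -> PerformanceResult:
    """Repeated stratified hold-out evaluation of one beta point.

    Each repeat r draws its partition from a seed derived from
    (config.seed, r), trains on the training side, scores the held-out
    foreground sites and background windows, and records all measures.
    Non-convergent training rounds are logged and still scored.
    """
    train_config = train_config or TrainConfig()
    n_fg, n_chunks = len(data.fg_sites), len(data.bg_chunks)
    vals = {m: np.empty(config.repeats) for m in MEASURES}
    n_converged = 0
    partitions = [] if collect_partitions else None

    for r in range(config.repeats):
        rng = np.random.default_rng(_repeat_seed(config.seed, r))
        fg_tr, fg_te = _split_indices(n_fg, config.train_fraction, rng)
        bg_tr, bg_te = _split_indices(n_chunks, config.train_fraction, rng)
        if partitions is not None:
            partitions.append((fg_tr.copy(), bg_tr.copy()))

        fg_train = [data.fg_sites[i] for i in fg_tr]
        bg_train = extract_windows([data.bg_chunks[i] for i in bg_tr], data.L)
        train_set = LabeledData.from_classes(bg_train, fg_train)

        result = train(train_set, beta, hyper, train_config)
        if result.converged:
            n_converged += 1
        else:
            logger.info(
                "holdout repeat %d: training stopped with gradient max-norm %.2g",
                r, result.gradient_norm,
            )

        pos = llr_scores(result.params, np.vstack([data.fg_sites[i].residues for i in fg_te]))
        neg_windows = extract_windows([data.bg_chunks[i] for i in bg_te], data.L)
        neg = llr_scores(result.params, np.vstack([w.residues for w in neg_windows]))

        vals["sensitivity"][r] = sensitivity_at_specificity(pos, neg, config.specificity)
        aux = auxiliary_measures(pos, neg)
        for m in ("roc_auc", "pr_auc", "classification_rate"):
            vals[m][r] = aux[m]

    return PerformanceResult(n_converged=n_converged, partitions=partitions, **vals)


# ---------------------------------------------------------------------------
# Simplex scan


@dataclass
class SimplexGridResult:
    points: list  # list of (BetaWeights, PerformanceResult)
    step: float

    def best(self, measure: str = "sensitivity"):
        return max(self.points, key=lambda bp: bp[1].mean(measure))


def simplex_grid(step: float = 0.05) -> list:
    """All beta grid points with b0, b1 on multiples of step, b0 + b1 <= 1."""
    n = round(1.0 / step)
    if abs(n * step - 1.0) > 1e-9:
        raise ValueError("step must divide 1")
    pts = []
    for i in range(n + 1):
        for j in range(n + 1 - i):
            b0, b1 = i * step, j * step
            pts.append(BetaWeights.normalized(b0, b1, max(1.0 - b0 - b1, 0.0)))
    return pts


def simplex_scan(
    data: SiteBackgroundData,
    hyper: DirichletHyper,
    step: float = 0.05,
    config: HoldoutConfig = HoldoutConfig(),
    train_config: TrainConfig | None = None,
    collect_partitions: bool = False,
) -> SimplexGridResult:
    """Hold-out evaluation at every point of the beta grid.

    All grid points share config.seed, hence the identical sequence of
    train/test partitions: differences between beta points are paired.
    """
    points = []
    for beta in simplex_grid(step):
        perf = holdout_evaluate(
            data, beta, hyper, config, train_config, collect_partitions=collect_partitions
        )
        points.append((beta, perf))
        logger.info(
            "scan beta=(%.2f, %.2f, %.2f): sensitivity %.4f +- %.4f",
            beta.b0, beta.b1, beta.b2, perf.mean_sensitivity, perf.se_sensitivity,
        )
    return SimplexGridResult(points=points, step=step)
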