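"""Decision rule and log-ratio scoring of fixed-length sequences.

A sequence is assigned to the class maximizing P(c) * P(x | c); for two
classes this reduces to the sign of the log joint ratio

    score(x) = [log P(fg) + log P(x | fg)] - [log P(bg) + log P(x | bg)],

a monotone transform of the posterior P(fg | x) = logistic(score).  Ties
(score exactly 0) go to the background class — the conservative call for a
rare-positive detection task.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .model import ClassifierParams
from .seqdata import Sequence

__all__ = ["ScoredSequence", "llr_score", "llr_scores", "decide", "classify_set"]

FG, BG = 1, 0


@dataclass
class ScoredSequence:
    id: str
    score: float
    predicted_class: int


def llr_scores(params: ClassifierParams, X: np.ndarray) -> np.ndarray:
    """Vectorized log joint-ratio scores for an (N, L) residue matrix."""
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] != params.L:
        raise ValueError(f"expected (N, {params.L}) residue matrix, got {X.shape}")
    lcp = params.log_class_probs
    lpw = params.log_pwm_probs
    pos = np.arange(params.L)
    s_fg = lcp[FG] + lpw[FG][pos, X].sum(axis=1)
    s_bg = lcp[BG] + lpw[BG][pos, X].sum(axis=1)
    return s_fg - s_bg


def llr_score(params: ClassifierParams, x: Sequence) -> float:
    """Log joint-ratio score of one sequence (positive favours foreground)."""
    res = x.residues if isinstance(x, Sequence) else np.asarray(x)
    if res.size != params.L:
        raise ValueError(f"sequence length {res.size} != model length {params.L}")
    return float(llr_scores(params, res[None, :])[0])


def decide(params: ClassifierParams, x: Sequence) -> int:
    """Class with maximal joint probability; score 0 breaks to background."""
    return FG if llr_score(params, x) > 0 else BG


def classify_set(params: ClassifierParams, seqs: Iterable[Sequence]) -> list:
    """Score and classify sequences element-wise, preserving order."""
    out = []
    for s in seqs:
        try:
            sc = llr_score(params, s)
        except ValueError as exc:
            raise ValueError(f"sequence {s.id!r}: {exc}") from exc
        out.append(ScoredSequence(id=s.id, score=sc, predicted_class=FG if sc > 0 else BG))
    return out
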