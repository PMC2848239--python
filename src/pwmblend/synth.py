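"""Synthetic benchmark generator: PWM-sampled sites plus i.i.d. background.

Emulates a small transcription-factor binding-site study: on the order of a
hundred verified sites of a fixed length L = 16 as the foreground, and a
few tens of kilobases of genomic background cut into chunks of at most
100 bp, from which every overlapping 16-mer is a negative instance.  Sites
are drawn column-wise from a ground-truth PWM; the background is an
order-0 (i.i.d.) symbol distribution, which matches the expressiveness of
the classifier's background PWM.  All sampling is bit-reproducible given
the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .seqdata import LabeledData, Sequence, SiteBackgroundData

__all__ = [
    "GeneratorSpec",
    "Benchmark",
    "random_pwm",
    "motif_pwm",
    "sample_pwm_dataset",
    "sample_background",
    "make_benchmark",
]


def random_pwm(L: int, K: int = 4, concentration: float = 1.0, seed: int | None = None) -> np.ndarray:
    """PWM with columns drawn from a symmetric Dirichlet(concentration)."""
    rng = np.random.default_rng(seed)
    return rng.dirichlet(np.full(K, concentration), size=L)


def motif_pwm(L: int, K: int = 4, strength: float = 0.7, seed: int | None = None) -> np.ndarray:
    """A conserved-motif PWM: one dominant symbol per column.

    Each column puts probability ``strength`` on a randomly chosen symbol
    and spreads the rest uniformly.  The default 0.7 gives roughly one bit
    of information per position, typical of well-characterized TF motifs.
    """
    if not 1.0 / K <= strength <= 1.0:
        raise ValueError("strength must lie in [1/K, 1]")
    rng = np.random.default_rng(seed)
    theta = np.full((L, K), (1.0 - strength) / (K - 1))
    theta[np.arange(L), rng.integers(K, size=L)] = strength
    return theta


@dataclass
class GeneratorSpec:
    """Ground truth and sizes for one synthetic benchmark.

    Defaults mirror a typical TRANSFAC-style study: ~10^2 sites of length
    16 and ~68 kb of background in chunks of at most 100 bp.
    """

    theta_fg: np.ndarray = None
    bg_probs: np.ndarray = None
    n_fg: int = 104
    bg_total_bp: int = 68141
    L: int = 16
    chunk_len: int = 100
    seed: int = 0
    motif_strength: float = 0.7

    def __post_init__(self) -> None:
        if self.theta_fg is None:
            self.theta_fg = motif_pwm(self.L, strength=self.motif_strength, seed=self.seed)
        self.theta_fg = np.asarray(self.theta_fg, float)
        if self.bg_probs is None:
            self.bg_probs = np.full(self.theta_fg.shape[1], 1.0 / self.theta_fg.shape[1])
        self.bg_probs = np.asarray(self.bg_probs, float)
        if not np.allclose(self.theta_fg.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("theta_fg rows must sum to 1")
        if not np.isclose(self.bg_probs.sum(), 1.0, atol=1e-12):
            raise ValueError("bg_probs must sum to 1")
        if self.n_fg < 0 or self.bg_total_bp < 0:
            raise ValueError("counts must be nonnegative")
        self.L = int(self.theta_fg.shape[0])

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "theta_fg": self.theta_fg.tolist(),
            "bg_probs": self.bg_probs.tolist(),
            "n_fg": self.n_fg,
            "bg_total_bp": self.bg_total_bp,
            "L": self.L,
            "chunk_len": self.chunk_len,
            "seed": self.seed,
        }, indent=1))


def sample_pwm_dataset(theta: np.ndarray, n: int, seed=None, prefix: str = "fg") -> list:
    """n independent fixed-length words, position l drawn from column l."""
    theta = np.atleast_2d(np.asarray(theta, float))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L, K = theta.shape
    cum = np.cumsum(theta, axis=1)
    u = rng.random((n, L))
    # inverse-CDF per column; searchsorted over each column's cumulative mass
    res = np.empty((n, L), dtype=np.int16)
    for l in range(L):
        res[:, l] = np.searchsorted(cum[l], u[:, l], side="right")
    res = np.minimum(res, K - 1)
    return [Sequence(id=f"{prefix}_{i:05d}", residues=res[i]) for i in range(n)]


def sample_background(bg_probs, total_bp: int, chunk_len: int = 100, seed=None,
                      prefix: str = "bg") -> list:
    """i.i.d. background symbols emitted as chunks of at most chunk_len bp."""
    bg_probs = np.asarray(bg_probs, float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    symbols = rng.choice(bg_probs.size, size=int(total_bp), p=bg_probs).astype(np.int16)
    chunks = []
    for i, start in enumerate(range(0, int(total_bp), chunk_len)):
        end = min(start + chunk_len, int(total_bp))
        chunks.append(Sequence(id=f"{prefix}_{i:05d}", residues=symbols[start:end]))
    return chunks


@dataclass
class Benchmark:
    """A generated data set together with its ground truth."""

    sites: SiteBackgroundData
    spec: GeneratorSpec

    @property
    def data(self) -> LabeledData:
        """Foreground L-mers labeled 1 plus background windows labeled 0."""
        return self.sites.to_labeled()


def make_benchmark(spec: GeneratorSpec) -> Benchmark:
    """Sample a full benchmark (sites + chunked background) from a spec."""
    rng = np.random.default_rng(spec.seed)
    fg = sample_pwm_dataset(spec.theta_fg, spec.n_fg, seed=rng)
    bg = sample_background(spec.bg_probs, spec.bg_total_bp, spec.chunk_len, seed=rng)
    return Benchmark(sites=SiteBackgroundData(fg_sites=fg, bg_chunks=bg, L=spec.L), spec=spec)
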