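"""Karlin-Altschul E-value statistics for local alignment scores.

The expected number of chance local alignments scoring >= S between
random sequences of lengths m and n is E = K * m * n * exp(-lambda * S).
For ungapped scoring, ``lambda`` solves sum_ij p_i p_j exp(lambda s_ij) = 1
and K follows from the classical renewal-theory series.  Gapped scores
have no closed form; :func:`calibrate_gapped` fits a Gumbel law to
simulated null scores instead, which is the default route for the
screen because it uses gapped alignments.

No edge-effect (finite-length) correction is applied to m and n: at the
window sizes this package targets, alignments are short relative to the
windows and the correction is negligible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .align import ScoringScheme, best_local_score

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class BackgroundModel:
    """I.i.d. base frequencies (A, C, G, T)."""

    p: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        arr = np.asarray(self.p, dtype=float)
        if arr.shape != (4,) or (arr < 0).any():
            raise ValueError("background must be 4 nonnegative frequencies")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError(f"background frequencies sum to {arr.sum()}, not 1")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.p, dtype=float)


@dataclass(frozen=True)
class KarlinParams:
    """Gumbel parameters of the local-score null distribution.

    ``lam`` is in nats per score unit; ``K`` is dimensionless.
    ``source`` records whether the values are the analytic ungapped
    solution or an empirical gapped calibration.
    """

    lam: float
    K: float
    source: str  # "analytic_ungapped" | "empirical_gapped"

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")


def _pair_score_distribution(
    scheme: ScoringScheme, bg: BackgroundModel
) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of the score of one random aligned base pair."""
    p = bg.as_array()
    scores: dict[int, float] = {}
    for i in range(4):
        for j in range(4):
            s = scheme.match if i == j else scheme.mismatch
            scores[s] = scores.get(s, 0.0) + p[i] * p[j]
    vals = np.array(sorted(scores), dtype=np.int64)
    probs = np.array([scores[v] for v in vals], dtype=float)
    return vals, probs


def solve_lambda(
    scheme: ScoringScheme, bg: BackgroundModel = BackgroundModel()
) -> KarlinParams:
    """Analytic ungapped Karlin-Altschul parameters.

    ``lambda`` is found by bisection on sum p_i p_j exp(lambda s_ij) = 1
    to residual < 1e-9; ``K`` by the classical partial-sum series over
    the score random walk, truncated when terms fall below 1e-6.

    Requires negative expected pair score and a positive maximum score.
    """
    vals, probs = _pair_score_distribution(scheme, bg)
    mean = float(np.dot(vals, probs))
    if mean >= 0:
        raise ValueError(
            f"expected pair score must be negative for E-value theory (got {mean:.4f})"
        )
    if vals.max() <= 0:
        raise ValueError("maximum pair score must be positive")

    def f(lam: float) -> float:
        return float(np.dot(probs, np.exp(lam * vals))) - 1.0

    lo, hi = 1e-12, 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e3:
            raise RuntimeError("lambda bracket search failed")
    while hi - lo > 1e-15 or abs(f((lo + hi) / 2)) > 1e-9:
        mid = (lo + hi) / 2
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-16:
            break
    lam = (lo + hi) / 2
    K = _karlin_k(vals, probs, lam)
    return KarlinParams(lam=lam, K=K, source="analytic_ungapped")


def _karlin_k(vals: np.ndarray, probs: np.ndarray, lam: float) -> float:
    """K via the renewal series on partial sums of the score walk.

    For a lattice score distribution with span d,
    K = d * lambda * exp(-2*sigma) / (H * (1 - exp(-lambda*d))) with
    H = lambda * E[S exp(lambda S)] and
    sigma = sum_k (1/k) [ sum_{s<0} P_k(s) e^{lambda s} + P(S_k >= 0) ].
    """
    d = int(np.gcd.reduce(np.abs(vals).astype(np.int64)))
    av = float(np.dot(vals * np.exp(lam * vals), probs))
    low, high = int(vals.min()), int(vals.max())
    # single-step pmf on an integer offset grid
    step = np.zeros(high - low + 1)
    for v, p in zip(vals, probs):
        step[int(v) - low] = p
    sigma = 0.0
    dist = None  # pmf of S_k; dist[idx] with offset k*low
    for k in range(1, 1001):
        dist = step.copy() if dist is None else np.convolve(dist, step)
        offset = k * low
        s_vals = np.arange(offset, offset + len(dist))
        neg = s_vals < 0
        term = float(np.dot(dist[neg], np.exp(lam * s_vals[neg]))) + float(dist[~neg].sum())
        sigma += term / k
        if term < 1e-6:
            break
    H = lam * av
    return d * lam * math.exp(-2.0 * sigma) / (H * (1.0 - math.exp(-lam * d)))


def evalue(score: float, m: int, n: int, params: KarlinParams) -> float:
    """E = K * m * n * exp(-lambda * score)."""
    if m <= 0 or n <= 0:
        raise ValueError("search space dimensions m, n must be positive")
    return params.K * m * n * math.exp(-params.lam * score)


def score_for_evalue(e: float, m: int, n: int, params: KarlinParams) -> float:
    """Smallest score with E-value <= e (inverse of :func:`evalue`)."""
    if e <= 0:
        raise ValueError("e must be positive")
    return math.log(params.K * m * n / e) / params.lam


def calibrate_gapped(
    scheme: ScoringScheme,
    bg: BackgroundModel = BackgroundModel(),
    seq_len: int = 500,
    n_sims: int = 1000,
    seed: int = 0,
    allow_small: bool = False,
) -> KarlinParams:
    """Empirical gapped Karlin-Altschul parameters from a Gumbel fit.

    Simulates ``n_sims`` i.i.d. sequence pairs of length ``seq_len``
    under ``bg``, records the best local alignment score of each pair,
    and fits a Gumbel law by maximum likelihood.  With location mu and
    scale beta, lambda = 1/beta and K = exp(mu/beta) / (seq_len^2).
    Deterministic given ``seed``.
    """
    if n_sims < 100:
        if not allow_small:
            raise ValueError(f"n_sims={n_sims} too small for a stable Gumbel fit (need >= 100)")
        warnings.warn(f"n_sims={n_sims} < 100: Gumbel fit will be noisy", stacklevel=2)
    rng = np.random.default_rng(seed)
    p = bg.as_array()
    scores = np.empty(n_sims)
    for i in range(n_sims):
        a = "".join(rng.choice(_BASES, size=seq_len, p=p))
        b = "".join(rng.choice(_BASES, size=seq_len, p=p))
        scores[i] = best_local_score(a, b, scheme)
    if scores.std() == 0:
        raise ValueError("degenerate calibration: simulated scores have zero variance")
    mu, beta = stats.gumbel_r.fit(scores)
    lam = 1.0 / beta
    K = math.exp(mu / beta) / (seq_len * seq_len)
    return KarlinParams(lam=lam, K=K, source="empirical_gapped")


_CACHE_COLUMNS = [
    "match", "mismatch", "gap_open", "gap_extend",
    "bg_a", "bg_c", "bg_g", "bg_t", "seq_len", "n_sims", "seed", "lambda", "K",
]


class CalibrationCache:
    """TSV-backed cache of gapped calibrations keyed by (scheme, bg, length)."""

    def __init__(self, path: str | Path | None = None):
        self.path = Path(path) if path else None
        self._mem: dict[tuple, KarlinParams] = {}
        if self.path and self.path.exists():
            self._load()

    @staticmethod
    def _key(scheme: ScoringScheme, bg: BackgroundModel, seq_len: int, n_sims: int, seed: int):
        return (
            scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend,
            tuple(round(x, 6) for x in bg.p), seq_len, n_sims, seed,
        )

    def _load(self) -> None:
        with open(self.path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != _CACHE_COLUMNS:
                raise ValueError(f"{self.path}: unexpected cache columns")
            for line in fh:
                f = line.rstrip("\n").split("\t")
                scheme = ScoringScheme(int(f[0]), int(f[1]), int(f[2]), int(f[3]))
                bg = BackgroundModel(tuple(float(x) for x in f[4:8]))
                key = self._key(scheme, bg, int(f[8]), int(f[9]), int(f[10]))
                self._mem[key] = KarlinParams(float(f[11]), float(f[12]), "empirical_gapped")

    def _save(self, key: tuple, params: KarlinParams) -> None:
        if not self.path:
            return
        new = not self.path.exists()
        with open(self.path, "a") as fh:
            if new:
                fh.write("\t".join(_CACHE_COLUMNS) + "\n")
            row = list(key[:4]) + list(key[4]) + list(key[5:]) + [params.lam, params.K]
            fh.write("\t".join(str(x) for x in row) + "\n")

    def get(
        self,
        scheme: ScoringScheme,
        bg: BackgroundModel = BackgroundModel(),
        seq_len: int = 500,
        n_sims: int = 1000,
        seed: int = 0,
    ) -> KarlinParams:
        key = self._key(scheme, bg, seq_len, n_sims, seed)
        if key not in self._mem:
            params = calibrate_gapped(scheme, bg, seq_len, n_sims, seed)
            self._mem[key] = params
            self._save(key, params)
        return self._mem[key]
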