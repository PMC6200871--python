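"""Scoring and inference for recovered spatial patterns.

Pattern divergence is one minus the absolute cosine similarity between two
topographies: 0 for collinear (perfect recovery up to scale and sign), 1
for orthogonal.  Recovered components come in no particular order, so a
greedy matcher pairs recovered with true patterns by repeatedly taking the
globally smallest remaining divergence; exhaustive (Hungarian) assignment
is available as an option.  Statistical significance of an observed
coupling is assessed with a segment-permutation surrogate test that re-runs
the full spatial-filter fit on time-shuffled fit-band data, preserving the
spectra and every optimization step under the null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .signal_core import FrequencyRatio
from .xpf import XPF

__all__ = [
    "DivergenceReport",
    "PermutationResult",
    "pattern_divergence",
    "divergence_matrix",
    "greedy_match",
    "permutation_test",
]


def pattern_divergence(p: np.ndarray, p_hat: np.ndarray) -> float:
    """1 - |p . p_hat| / (||p|| ||p_hat||), in [0, 1].

    Invariant under nonzero rescaling and sign flips of either argument.
    """
    p = np.asarray(p, dtype=float).ravel()
    p_hat = np.asarray(p_hat, dtype=float).ravel()
    if p.shape != p_hat.shape:
        raise ValueError(f"pattern length mismatch: {p.shape} vs {p_hat.shape}")
    np_, nh = np.linalg.norm(p), np.linalg.norm(p_hat)
    if np_ == 0 or nh == 0:
        raise ValueError("zero-norm pattern")
    cos = abs(float(p @ p_hat)) / (np_ * nh)
    return float(np.clip(1.0 - cos, 0.0, 1.0))


def divergence_matrix(recovered: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Pairwise divergences; inputs are (n_channels, n_patterns) matrices or
    sequences of vectors.  Entry [i, j] scores recovered i vs truth j."""
    rec = [np.asarray(c, dtype=float).ravel() for c in _columns(recovered)]
    tru = [np.asarray(c, dtype=float).ravel() for c in _columns(truth)]
    D = np.empty((len(rec), len(tru)))
    for i, r in enumerate(rec):
        for j, t in enumerate(tru):
            D[i, j] = pattern_divergence(r, t)
    return D


def _columns(patterns) -> list:
    arr = np.asarray(patterns, dtype=float)
    if arr.ndim == 2:
        return [arr[:, j] for j in range(arr.shape[1])]
    if arr.ndim == 1:
        return [arr]
    raise ValueError("patterns must be a matrix (channels x patterns) or list of vectors")


@dataclass
class DivergenceReport:
    """Matching of recovered to true patterns with per-pair divergences."""

    assignment: list  # (recovered index, truth index)
    divergences: np.ndarray
    method: str = "greedy"

    @property
    def median(self) -> float:
        return float(np.median(self.divergences))

    @property
    def mean(self) -> float:
        return float(np.mean(self.divergences))


def greedy_match(recovered, truth, method: str = "greedy") -> DivergenceReport:
    """Match recovered patterns to true patterns.

    Greedy (default): repeatedly take the pair with the smallest remaining
    divergence and remove both from play.  ``method="hungarian"`` instead
    minimizes the total divergence exactly.  With unequal list sizes,
    min(n_recovered, n_truth) pairs are formed; extras stay unmatched.
    """
    D = divergence_matrix(recovered, truth)
    if D.size == 0:
        raise ValueError("empty pattern lists")
    if method == "hungarian":
        # pad to square so extras may stay unmatched at zero cost
        n = max(D.shape)
        Dp = np.zeros((n, n))
        Dp[: D.shape[0], : D.shape[1]] = D
        rows, cols = linear_sum_assignment(Dp)
        pairs = [(int(i), int(j)) for i, j in zip(rows, cols) if i < D.shape[0] and j < D.shape[1]]
        divs = np.array([D[i, j] for i, j in pairs])
        return DivergenceReport(assignment=pairs, divergences=divs, method="hungarian")
    if method != "greedy":
        raise ValueError(f"unknown matching method {method!r}")
    work = D.copy()
    pairs = []
    divs = []
    for _ in range(min(D.shape)):
        i, j = np.unravel_index(np.argmin(work), work.shape)
        pairs.append((int(i), int(j)))
        divs.append(float(work[i, j]))
        work[i, :] = np.inf
        work[:, j] = np.inf
    return DivergenceReport(assignment=pairs, divergences=np.array(divs), method="greedy")


@dataclass
class PermutationResult:
    """Outcome of the segment-permutation significance test."""

    observed_plv: float
    null_plvs: np.ndarray
    p_value: float
    n_perm: int
    segment_length_s: float
    seed: int | None


def permutation_test(
    reference: np.ndarray,
    fit_data: np.ndarray,
    ratio,
    fs: float = 200.0,
    n_perm: int = 1000,
    segment_length_s: float = 3.0,
    seed=None,
    **xpf_kwargs,
) -> PermutationResult:
    """Null distribution of the fitted PLV under segment shuffling.

    The fit-band data is cut into ``segment_length_s`` segments whose order
    is randomly permuted while the reference keeps its original order; the
    full spatial-filter optimization is re-run on each surrogate, so the
    null captures overfitting by the optimizer itself.  The p-value uses
    the add-one estimator (never exactly zero).
    """
    ratio = FrequencyRatio.coerce(ratio)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    reference = np.asarray(reference, dtype=float).ravel()
    fit_data = np.atleast_2d(np.asarray(fit_data, dtype=float))
    if fit_data.shape[0] != reference.shape[0]:
        fit_data = fit_data.T
    seg = int(round(segment_length_s * fs))
    n_seg = fit_data.shape[0] // seg
    if n_seg < 10:
        raise ValueError(f"only {n_seg} segments of {segment_length_s} s; need >= 10")
    T = n_seg * seg
    ref = reference[:T]
    data = fit_data[:T]

    rng = np.random.default_rng(seed)
    def _fit(X, rs):
        kw = dict(fs=fs, random_state=rs)
        kw.update(xpf_kwargs)
        return XPF(ratio=ratio, **kw).fit(X, ref)

    observed = _fit(data, int(rng.integers(2**31))).plv_
    blocks = data.reshape(n_seg, seg, -1)
    null = np.empty(n_perm)
    for b in range(n_perm):
        order = rng.permutation(n_seg)
        shuffled = blocks[order].reshape(T, -1)
        null[b] = _fit(shuffled, int(rng.integers(2**31))).plv_
    p_value = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return PermutationResult(
        observed_plv=float(observed),
        null_plvs=null,
        p_value=float(p_value),
        n_perm=n_perm,
        segment_length_s=segment_length_s,
        seed=seed if not isinstance(seed, np.random.Generator) else None,
    )
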