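"""Bootstrap case-resampling reliability statistics for decoy sets.

A docking run is stochastic, and its headline result — N5, the number of
near-native decoys among the five best interface energies — is a noisy,
non-linear statistic of the decoy sample. Case resampling quantifies that
noise without distributional assumptions: draw B resampled decoy sets (same
size as the original, with replacement), recompute N5 for each, and report

* ``mu_n5``    — sample mean of the resampled N5 values,
* ``sigma_n5`` — sample standard deviation (denominator B - 1),
* ``p_success`` — fraction of resamples with N5 >= 3.

The score-randomized null additionally reassigns interface energies,
drawn with replacement from the original set, to the resampled decoys.
This breaks the decoy-score relationship while preserving the marginal
score distribution, giving the probability of observing a funnel by
chance.

Randomness: one seeded NumPy generator per call; the decoy-index draw is
consumed first, then (for the randomized variant) the score-index draw,
so results are reproducible for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .capri_metrics import NEAR_NATIVE_IRMSD
from .decoy_eval import DecoySet

__all__ = [
    "DEFAULT_B",
    "BootstrapSummary",
    "StatSuccessCriteria",
    "bootstrap_n5",
    "bootstrap_randomized",
    "statistical_success",
]

DEFAULT_B = 5000  # resamples; ample for convergence of mu/sigma/p on n=1000 sets


@dataclass(frozen=True)
class BootstrapSummary:
    """Summary of one bootstrap run over a decoy set."""

    B: int
    mu_n5: float
    sigma_n5: float
    p_success: float
    randomized: bool
    seed: int | None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_success <= 1.0 and 0.0 <= self.mu_n5 <= 5.0
                and self.sigma_n5 >= 0.0 and self.B >= 1):
            raise ValueError(f"inconsistent bootstrap summary: {self}")


@dataclass(frozen=True)
class StatSuccessCriteria:
    """Statistics-based success thresholds (both inclusive)."""

    mu_threshold: float = 2.5
    p_threshold: float = 0.3


def _sort_key_and_flags(ds: DecoySet) -> tuple[np.ndarray, np.ndarray]:
    """Per-record total-order rank (ascending I_sc, ties by description)
    and near-native flags, matching ``decoy_eval.rank_by_interface_energy``."""
    i_sc = np.array([r.i_sc for r in ds.records])
    desc = np.array([r.description for r in ds.records])
    order = np.lexsort((desc, i_sc))
    rank = np.empty(len(ds), dtype=np.int64)
    rank[order] = np.arange(len(ds))
    near = np.array([r.irmsd <= NEAR_NATIVE_IRMSD for r in ds.records])
    return rank, near


def _n5_per_resample(rank_matrix: np.ndarray, near_matrix: np.ndarray) -> np.ndarray:
    """N5 for each row: count near-native among the 5 smallest ranks."""
    top5 = np.argpartition(rank_matrix, 4, axis=1)[:, :5]
    return np.take_along_axis(near_matrix, top5, axis=1).sum(axis=1)


def _summarize(n5: np.ndarray, B: int, randomized: bool, seed) -> BootstrapSummary:
    sigma = float(np.std(n5, ddof=1)) if B > 1 else 0.0
    return BootstrapSummary(
        B=B,
        mu_n5=float(np.mean(n5)),
        sigma_n5=sigma,
        p_success=float(np.mean(n5 >= 3)),
        randomized=randomized,
        seed=seed,
    )


def bootstrap_n5(ds: DecoySet, B: int = DEFAULT_B, seed: int | None = None,
                 return_samples: bool = False):
    """Case-resampling bootstrap of N5.

    Each of the B resamples draws ``len(ds)`` decoys uniformly with
    replacement and recomputes N5. Returns a :class:`BootstrapSummary`
    (and the per-resample N5 array if ``return_samples``).
    """
    n = len(ds)
    if n < 5:
        raise ValueError(f"need >= 5 decoys, got {n}")
    if B < 1:
        raise ValueError("B must be >= 1")
    rank, near = _sort_key_and_flags(ds)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    n5 = _n5_per_resample(rank[idx], near[idx])
    summary = _summarize(n5, B, randomized=False, seed=seed)
    return (summary, n5) if return_samples else summary


def bootstrap_randomized(ds: DecoySet, B: int = DEFAULT_B, seed: int | None = None,
                         return_samples: bool = False):
    """Score-randomized bootstrap null of N5.

    Per resample: (1) draw decoys with replacement as in
    :func:`bootstrap_n5`; (2) draw interface energies with replacement from
    the ORIGINAL set and assign them to the resampled decoys, decoupling
    each decoy from its own score. Ties among assigned scores are broken by
    the receiving decoy's original rank, keeping the top-5 selection
    deterministic.
    """
    n = len(ds)
    if n < 5:
        raise ValueError(f"need >= 5 decoys, got {n}")
    if B < 1:
        raise ValueError("B must be >= 1")
    rank, near = _sort_key_and_flags(ds)
    i_sc = np.array([r.i_sc for r in ds.records])
    rng = np.random.default_rng(seed)
    decoy_idx = rng.integers(0, n, size=(B, n))
    score_idx = rng.integers(0, n, size=(B, n))
    assigned = i_sc[score_idx]
    # total order per row: assigned score, then the decoy's own rank
    order = np.lexsort((rank[decoy_idx], assigned), axis=1)
    top5 = order[:, :5]
    n5 = np.take_along_axis(near[decoy_idx], top5, axis=1).sum(axis=1)
    summary = _summarize(n5, B, randomized=True, seed=seed)
    return (summary, n5) if return_samples else summary


def statistical_success(bs: BootstrapSummary, criteria: StatSuccessCriteria = StatSuccessCriteria()) -> bool:
    """Statistics-based success call: mu(N5) >= 2.5 AND P_success >= 0.3
    (defaults; both thresholds inclusive). Only meaningful for the
    non-randomized bootstrap."""
    if bs.randomized:
        raise ValueError("statistical success applies to the non-randomized bootstrap")
    return bs.mu_n5 >= criteria.mu_threshold and bs.p_success >= criteria.p_threshold
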