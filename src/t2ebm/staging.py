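"""Maximum-likelihood subject staging under a fitted event sequence.

A subject at stage ``k`` has passed the first ``k`` events of the sequence:
the stage likelihood multiplies abnormal-component densities for passed
events and normal-component densities for pending ones.  An EM loop refines
the cohort-level stage prior (E-step: stage posteriors; M-step: prior =
mean posterior mass), and the reported per-subject summary is the
posterior-mean stage divided by K, a severity index on [0, 1].

Everything is computed in log space; stages remain well-defined for values
dozens of control-sds from either component mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .ebm import EventSequence, MixtureFit

__all__ = [
    "stage_log_likelihoods",
    "stage_likelihood",
    "stage_posterior",
    "em_refine",
    "StagingResult",
]


def stage_log_likelihoods(
    X: np.ndarray, sequence: EventSequence, fits: list[MixtureFit]
) -> np.ndarray:
    """(n, K+1) matrix of log L(stage k) for every subject.

    log L(k) = sum_{positions m <= k} log f_a(x at position m)
             + sum_{m > k} log f_n(x at position m).
    """
    X = np.asarray(X, dtype=float)
    ordering = np.asarray(sequence.ordering, dtype=int)
    K = len(ordering)
    log_n = np.column_stack(
        [stats.norm.logpdf(X[:, j], fits[j].mu_n, fits[j].sd_n) for j in ordering]
    )
    log_a = np.column_stack(
        [stats.norm.logpdf(X[:, j], fits[j].mu_a, fits[j].sd_a) for j in ordering]
    )
    # cumulative sums over sequence positions; stage k uses first k abnormal terms
    cum_a = np.concatenate([np.zeros((len(X), 1)), np.cumsum(log_a, axis=1)], axis=1)
    cum_n = np.concatenate([np.zeros((len(X), 1)), np.cumsum(log_n, axis=1)], axis=1)
    total_n = cum_n[:, -1][:, None]
    return cum_a + (total_n - cum_n)        # (n, K+1)


def stage_likelihood(
    x: np.ndarray, sequence: EventSequence, fits: list[MixtureFit], k: int
) -> float:
    """Likelihood of one subject's vector at stage ``k`` (linear scale)."""
    K = len(sequence.ordering)
    if not 0 <= k <= K:
        raise ValueError(f"stage k={k} out of range 0..{K}")
    ll = stage_log_likelihoods(np.atleast_2d(x), sequence, fits)
    return float(np.exp(ll[0, k]))


def stage_posterior(log_lik: np.ndarray, prior: np.ndarray) -> np.ndarray:
    """Row-normalized stage posteriors: posterior(k) proportional to pi_k L(k)."""
    prior = np.asarray(prior, dtype=float)
    if (prior < 0).any() or not np.isclose(prior.sum(), 1.0):
        raise ValueError("prior must be a probability vector over stages")
    with np.errstate(divide="ignore"):
        log_post = log_lik + np.log(prior)[None, :]
    norm = logsumexp(log_post, axis=1, keepdims=True)
    if not np.isfinite(norm).all():
        raise ValueError("all stage log-likelihoods are -inf for some subject")
    return np.exp(log_post - norm)


@dataclass
class StagingResult:
    prior: np.ndarray                 # converged stage prior over {0..K}
    posteriors: np.ndarray            # (n, K+1), rows sum to 1
    assignments: pd.DataFrame         # map_stage, mean_stage, normalized_stage
    loglik_trace: np.ndarray
    converged: bool


def em_refine(
    X: np.ndarray,
    sequence: EventSequence,
    fits: list[MixtureFit],
    max_iter: int = 200,
    tol: float = 1e-8,
) -> StagingResult:
    """EM over the stage prior with the sequence held fixed.

    Starts from the uniform prior; the total log-likelihood is non-decreasing
    and iteration stops when the prior moves less than ``tol`` in max norm.
    MAP ties break toward the smaller stage; the normalized stage is the
    posterior mean divided by K.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    K = len(sequence.ordering)
    log_lik = stage_log_likelihoods(X, sequence, fits)
    prior = np.full(K + 1, 1.0 / (K + 1))
    trace = []
    converged = False
    for _ in range(max_iter):
        post = stage_posterior(log_lik, prior)
        with np.errstate(divide="ignore"):
            trace.append(float(logsumexp(log_lik + np.log(prior)[None, :], axis=1).sum()))
        new_prior = post.mean(axis=0)
        if np.abs(new_prior - prior).max() < tol:
            prior = new_prior
            converged = True
            break
        prior = new_prior
    if not converged:
        warnings.warn("stage-prior EM did not converge; returning last iterate",
                      stacklevel=2)
    post = stage_posterior(log_lik, prior)
    stages = np.arange(K + 1)
    mean_stage = post @ stages
    map_stage = np.argmax(post, axis=1)     # argmax takes the first (smallest) tie
    assignments = pd.DataFrame(
        {
            "map_stage": map_stage,
            "mean_stage": mean_stage,
            "normalized_stage": mean_stage / K,
        }
    )
    return StagingResult(prior, post, assignments, np.asarray(trace), converged)
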