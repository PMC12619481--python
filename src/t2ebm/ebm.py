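"""Event-based model core: mixtures, sequence estimation, bootstrap.

An "event" is one biomarker's transition from its normal to its abnormal
distribution.  For each biomarker a two-component Gaussian mixture is
fitted by EM over the pooled cohort, with the normal component anchored to
the healthy-control moments; each subject's values then map to posterior
probabilities that each event has occurred.  The central ordering is the
permutation of biomarkers minimizing the summed probabilistic Kendall-tau
distance to the patients' posterior vectors — exactly (all K! permutations)
for small K, by local search above that.

Because controls may themselves sit at nonzero stages, marginal per-marker
mixtures are weakly identified for events that almost everyone (or almost
no one) has passed.  ``fit_ebm`` therefore refines the marginal fits
jointly: an EM over latent subject stages re-estimates every component and
each event's prevalence from information pooled across markers, alternating
with re-estimation of the ordering, from several data-driven starting
orderings; the refit with the best joint log-likelihood wins.  Event-centers
place the events on a [0,1] timeline, and subject-level bootstrap
quantifies ordering uncertainty as a positional-variance matrix.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import logsumexp
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "MixtureFit",
    "EventSequence",
    "fit_abnormality_model",
    "posterior_abnormality",
    "posterior_matrix",
    "quantize_severity",
    "prob_kendall_distance",
    "pairwise_cost",
    "total_distance",
    "central_ordering",
    "estimate_event_centers",
    "bootstrap_sequence",
    "fit_ebm",
    "EBMFit",
]

_SD_FLOOR = 1e-8
_LOG_2PI = np.log(2 * np.pi)


def _norm_logpdf(x, mu, sd):
    # hot path: avoids scipy call overhead inside EM loops
    z = (x - mu) / sd
    return -0.5 * z * z - np.log(sd) - 0.5 * _LOG_2PI


@dataclass
class MixtureFit:
    """Normal/abnormal component parameters for one biomarker."""

    mu_n: float
    sd_n: float
    mu_a: float
    sd_a: float
    w_a: float                       # mixing weight of the abnormal component
    log_likelihood: float
    loglik_trace: np.ndarray
    converged: bool


@dataclass
class EventSequence:
    """A fitted ordering with event-centers on the [0,1] timeline."""

    ordering: np.ndarray             # position -> biomarker index
    event_centers: np.ndarray | None
    total_distance: float

    def position_of(self) -> np.ndarray:
        pos = np.empty(len(self.ordering), dtype=int)
        pos[self.ordering] = np.arange(len(self.ordering))
        return pos


# --------------------------------------------------------------------------
# marginal per-biomarker mixture
# --------------------------------------------------------------------------

def _em_run(x, init, bounds, tol, max_iter):
    mu_n, sd_n, mu_a, sd_a, w_a = init
    mu_n_bounds, sd_n_bounds = bounds
    trace = []
    converged = False
    prev = -np.inf
    for _ in range(max_iter):
        log_n = np.log1p(-w_a) + _norm_logpdf(x, mu_n, sd_n)
        log_a = np.log(w_a) + _norm_logpdf(x, mu_a, sd_a)
        log_tot = np.logaddexp(log_n, log_a)
        r_a = np.exp(log_a - log_tot)       # responsibility of abnormal comp
        ll = float(log_tot.sum())
        trace.append(ll)
        if ll - prev < tol and np.isfinite(prev):
            converged = True
            break
        prev = ll
        s_a = r_a.sum()
        s_n = (1.0 - r_a).sum()
        w_a = float(np.clip(s_a / len(x), 1e-4, 1 - 1e-4))
        if s_a > 0:
            mu_a = float((r_a * x).sum() / s_a)
            sd_a = float(np.sqrt((r_a * (x - mu_a) ** 2).sum() / s_a))
        if s_n > 0:
            mu_n = float(((1 - r_a) * x).sum() / s_n)
            sd_n = float(np.sqrt(((1 - r_a) * (x - mu_n) ** 2).sum() / s_n))
        if mu_n_bounds is not None:
            mu_n = float(np.clip(mu_n, *mu_n_bounds))
        if sd_n_bounds is not None:
            sd_n = float(np.clip(sd_n, *sd_n_bounds))
        sd_n = max(sd_n, _SD_FLOOR)
        sd_a = max(sd_a, _SD_FLOOR)
        if mu_a <= mu_n:                     # keep the abnormal component above
            mu_a = mu_n + 1e-6
    return (mu_n, sd_n, mu_a, sd_a, w_a), np.asarray(trace), converged


def fit_abnormality_model(
    values: np.ndarray,
    is_control: np.ndarray,
    rng: np.random.Generator | None = None,
    n_restarts: int = 5,
    tol: float = 1e-6,
    max_iter: int = 500,
    bound_normal_to_controls: bool = True,
) -> MixtureFit:
    """Fit the two-component normal/abnormal mixture for one biomarker.

    The column must be harmonized (higher = more abnormal).  The normal
    component is initialized from the control moments and, by default,
    bounded by them (mean within +-1 control sd, sd within [0.5, 1.5] of
    the control sd) to prevent label switching; ``mu_a > mu_n`` is enforced
    after every M-step.  The best of ``n_restarts`` randomized EM runs (by
    final log-likelihood) is returned.

    The control anchor presumes a largely event-free control group; when
    controls are themselves staged, prefer the jointly refined fit of
    :func:`fit_ebm`, which uses this marginal fit only for initialization.
    """
    x = np.asarray(values, dtype=float)
    is_control = np.asarray(is_control, dtype=bool)
    if is_control.sum() < 10 or (~is_control).sum() < 10:
        raise ValueError("need at least 10 subjects per group to fit the mixture")
    rng = rng or np.random.default_rng(0)
    ctl = x[is_control]
    pat = x[~is_control]
    ctl_mu, ctl_sd = float(ctl.mean()), float(ctl.std(ddof=1))
    ctl_sd = max(ctl_sd, _SD_FLOOR)
    if bound_normal_to_controls:
        bounds = ((ctl_mu - ctl_sd, ctl_mu + ctl_sd), (0.5 * ctl_sd, 1.5 * ctl_sd))
    else:
        bounds = (None, None)

    fits: list[MixtureFit] = []
    for r in range(max(1, n_restarts)):
        if r == 0:
            hi = pat[pat > ctl_mu]
            mu_a0 = float(hi.mean()) if len(hi) else ctl_mu + 2 * ctl_sd
            sd_a0 = float(hi.std(ddof=1)) if len(hi) > 2 else ctl_sd
            init = (ctl_mu, ctl_sd, max(mu_a0, ctl_mu + 1e-6),
                    max(sd_a0, _SD_FLOOR), 0.3)
        else:
            init = (
                ctl_mu + 0.3 * ctl_sd * rng.standard_normal(),
                ctl_sd,
                ctl_mu + ctl_sd * (1.0 + 2.0 * rng.random()),
                ctl_sd * (0.5 + rng.random()),
                float(rng.uniform(0.1, 0.6)),
            )
        params, trace, converged = _em_run(x, init, bounds, tol, max_iter)
        mu_n, sd_n, mu_a, sd_a, w_a = params
        if mu_a <= mu_n:
            continue
        fits.append(MixtureFit(mu_n, sd_n, mu_a, sd_a, w_a,
                               trace[-1], trace, converged))
    if not fits:
        raise RuntimeError(
            "EM could not satisfy mu_abnormal > mu_normal after restarts; "
            "inspect this biomarker's distribution and direction flag"
        )
    # parsimony tie-break: among near-tied restarts (within 2 nats), claim
    # the weakest abnormal mixture — under null signal every split fits
    # about equally and the smallest w_a is the honest description
    best_ll = max(f.log_likelihood for f in fits)
    near = [f for f in fits if f.log_likelihood >= best_ll - 2.0]
    return min(near, key=lambda f: f.w_a)


def posterior_abnormality(fit: MixtureFit, x) -> np.ndarray | float:
    """Posterior P(event occurred | value) under the fitted mixture."""
    x = np.asarray(x, dtype=float)
    w = np.clip(fit.w_a, 1e-12, 1 - 1e-12)
    log_n = np.log1p(-w) + _norm_logpdf(x, fit.mu_n, fit.sd_n)
    log_a = np.log(w) + _norm_logpdf(x, fit.mu_a, fit.sd_a)
    p = np.exp(log_a - np.logaddexp(log_n, log_a))
    return float(p) if p.ndim == 0 else p


def posterior_matrix(X: np.ndarray, fits: list[MixtureFit]) -> np.ndarray:
    """Subject x biomarker matrix of event posteriors."""
    X = np.asarray(X, dtype=float)
    return np.column_stack(
        [posterior_abnormality(fit, X[:, j]) for j, fit in enumerate(fits)]
    )


def quantize_severity(p) -> np.ndarray | float:
    """Map posteriors to the 4-level severity scale {0, 33%, 67%, 100%}.

    Nearest level wins; exact ties round up.  Reporting convenience only —
    sequence fitting uses the continuous posteriors.
    """
    p = np.asarray(p, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("probabilities must lie in [0, 1]")
    level = np.floor(p * 3 + 0.5) / 3.0
    out = np.clip(level, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# probabilistic Kendall ordering
# --------------------------------------------------------------------------

def prob_kendall_distance(ordering: np.ndarray, p: np.ndarray) -> float:
    """Probabilistic Kendall-tau distance of one subject to an ordering.

    Sums |p_i - p_j| over ordered pairs (i before j) that the subject
    contradicts (p_j > p_i); confident discordances cost more, and for
    binary posteriors this reduces to the classic Kendall distance.
    """
    ordering = np.asarray(ordering, dtype=int)
    p = np.asarray(p, dtype=float)
    if len(ordering) != len(p):
        raise ValueError("ordering and posterior vector length mismatch")
    q = p[ordering]
    diff = q[None, :] - q[:, None]          # diff[u, v] = q_v - q_u
    return float(np.triu(np.maximum(diff, 0.0), k=1).sum())


def pairwise_cost(P: np.ndarray) -> np.ndarray:
    """C[a, b] = summed penalty for placing event a before event b.

    The total distance of any ordering is the sum of C over its ordered
    pairs, which turns sequence search into a linear ordering problem.
    """
    P = np.asarray(P, dtype=float)
    diff = P[:, None, :] - P[:, :, None]    # diff[s, a, b] = p_sb - p_sa
    return np.maximum(diff, 0.0).sum(axis=0)


def total_distance(ordering: np.ndarray, C: np.ndarray) -> float:
    sub = C[np.ix_(ordering, ordering)]
    return float(np.triu(sub, k=1).sum())


def _local_search(C: np.ndarray, ordering: np.ndarray) -> tuple[np.ndarray, float]:
    """Adjacent-swap + single-event-insertion descent until no improving move."""
    K = len(ordering)
    ordering = ordering.copy()
    best = total_distance(ordering, C)
    improved = True
    while improved:
        improved = False
        for u in range(K - 1):              # adjacent swaps
            cand = ordering.copy()
            cand[u], cand[u + 1] = cand[u + 1], cand[u]
            d = total_distance(cand, C)
            if d < best - 1e-12:
                ordering, best, improved = cand, d, True
        for u in range(K):                  # insertion moves
            for v in range(K):
                if v == u:
                    continue
                cand = np.delete(ordering, u)
                cand = np.insert(cand, v, ordering[u])
                d = total_distance(cand, C)
                if d < best - 1e-12:
                    ordering, best, improved = cand, d, True
    return ordering, best


def central_ordering(
    P: np.ndarray,
    patient_mask: np.ndarray | None = None,
    exhaustive_limit: int = 7,
) -> EventSequence:
    """Minimize the summed probabilistic Kendall distance over orderings.

    Only patient rows drive the fit.  For K <= ``exhaustive_limit`` every
    permutation is scored and the global minimizer returned (lexicographic
    tie-break); above that, the search starts from the descending-mean-
    posterior order and descends by adjacent swaps and insertions.
    """
    P = np.asarray(P, dtype=float)
    if patient_mask is not None:
        P = P[np.asarray(patient_mask, dtype=bool)]
    if P.shape[0] == 0:
        raise ValueError("no patient rows to fit the ordering on")
    K = P.shape[1]
    if K < 2:
        raise ValueError("need at least 2 biomarkers")
    C = pairwise_cost(P)
    if K <= exhaustive_limit:
        best_perm, best_d = None, np.inf
        for perm in itertools.permutations(range(K)):
            d = total_distance(np.asarray(perm), C)
            if d < best_d - 1e-15:
                best_perm, best_d = np.asarray(perm), d
        return EventSequence(best_perm, None, best_d)
    init = np.argsort(-P.mean(axis=0), kind="stable")
    d_init = total_distance(init, C)
    ordering, d = _local_search(C, init)
    assert d <= d_init + 1e-12
    return EventSequence(ordering, None, d)


def estimate_event_centers(
    ordering: np.ndarray, P: np.ndarray, patient_mask: np.ndarray | None = None
) -> np.ndarray:
    """Event-centers in [0,1] aligned to the ordering.

    Each event's center is the certainty-weighted mean over subjects of its
    normalized rank (rank - 0.5)/K in the subject's descending-posterior
    order, with weights c_s = mean |2 p - 1| (confident subjects count
    more).  Pool-adjacent-violators then enforces monotonicity along the
    fitted ordering.
    """
    P = np.asarray(P, dtype=float)
    if patient_mask is not None:
        P = P[np.asarray(patient_mask, dtype=bool)]
    ordering = np.asarray(ordering, dtype=int)
    n, K = P.shape
    ranks = np.apply_along_axis(lambda r: stats.rankdata(-r, method="average"), 1, P)
    c = np.abs(2 * P - 1).mean(axis=1)
    if c.sum() == 0:
        raise ValueError("all-zero certainty weights; posteriors are uninformative")
    centered = (ranks - 0.5) / K
    ec_marker = (c[:, None] * centered).sum(axis=0) / c.sum()
    along = ec_marker[ordering]
    iso = IsotonicRegression(y_min=0.0, y_max=1.0)
    return iso.fit_transform(np.arange(K), along)


# --------------------------------------------------------------------------
# joint refinement over latent stages
# --------------------------------------------------------------------------

@dataclass
class _Params:
    """Vectorized per-marker component parameters."""

    mu_n: np.ndarray
    sd_n: np.ndarray
    mu_a: np.ndarray
    sd_a: np.ndarray

    def copy(self) -> "_Params":
        return _Params(*(a.copy() for a in
                         (self.mu_n, self.sd_n, self.mu_a, self.sd_a)))


def _stage_loglik(X: np.ndarray, ordering: np.ndarray, par: _Params) -> np.ndarray:
    """(n, K+1) log-likelihood of each stage given ordering and components."""
    n, K = X.shape
    ln = _norm_logpdf(X, par.mu_n, par.sd_n)[:, ordering]
    la = _norm_logpdf(X, par.mu_a, par.sd_a)[:, ordering]
    cum_a = np.concatenate([np.zeros((n, 1)), np.cumsum(la, axis=1)], axis=1)
    cum_n = np.concatenate([np.zeros((n, 1)), np.cumsum(ln, axis=1)], axis=1)
    return cum_a + (cum_n[:, -1][:, None] - cum_n)


def _marker_posteriors(X: np.ndarray, par: _Params, w: np.ndarray) -> np.ndarray:
    w = np.clip(w, 1e-12, 1 - 1e-12)
    ln = np.log1p(-w) + _norm_logpdf(X, par.mu_n, par.sd_n)
    la = np.log(w) + _norm_logpdf(X, par.mu_a, par.sd_a)
    return np.exp(la - np.logaddexp(ln, la))


def _joint_ll(X: np.ndarray, ordering: np.ndarray, par: _Params,
              pi: np.ndarray) -> float:
    L = _stage_loglik(X, ordering, par)
    return float(logsumexp(L + np.log(np.maximum(pi, 1e-300)), axis=1).sum())


def _em_fixed_ordering(
    X: np.ndarray,
    ordering: np.ndarray,
    par: _Params,
    pi: np.ndarray,
    sd_floor: np.ndarray,
    n_rounds: int = 80,
    n_stage_em: int = 30,
    min_mass: float = 1.0,
    tol: float = 1e-4,
):
    """EM for components, prevalences and stage prior at a fixed ordering.

    E-step: stage posteriors.  M-step: prior = mean posterior mass; each
    component's moments from soft event-occurred labels; a component side
    with fewer than ``min_mass`` effective subjects is left untouched (that
    side of the mixture is unidentified at this position).  Runs until the
    joint log-likelihood moves less than ``tol`` (so fits started from
    different orderings are compared at equal convergence).
    Returns (par, pi, w, post, ll).
    """
    n, K = X.shape
    par = par.copy()
    pi = pi.copy()
    w = np.full(K, 0.5)
    post = None
    ll = prev_ll = -np.inf
    for _ in range(n_rounds):
        L = _stage_loglik(X, ordering, par)
        for _ in range(n_stage_em):
            lp = L + np.log(np.maximum(pi, 1e-300))
            norm = logsumexp(lp, axis=1, keepdims=True)
            post = np.exp(lp - norm)
            new_pi = post.mean(axis=0)
            if np.abs(new_pi - pi).max() < 1e-9:
                pi = new_pi
                break
            pi = new_pi
        ll = float(norm.sum())
        occ_pos = np.clip(post[:, ::-1].cumsum(axis=1)[:, ::-1][:, 1:], 0.0, 1.0)
        occ = np.empty_like(occ_pos)
        occ[:, ordering] = occ_pos
        s_a = occ.sum(axis=0)
        s_n = n - s_a
        for j in range(K):
            xj = X[:, j]
            if s_a[j] > min_mass:
                mu = (occ[:, j] * xj).sum() / s_a[j]
                par.mu_a[j] = mu
                par.sd_a[j] = max(
                    np.sqrt((occ[:, j] * (xj - mu) ** 2).sum() / s_a[j]),
                    sd_floor[j],
                )
            if s_n[j] > min_mass:
                mu = ((1 - occ[:, j]) * xj).sum() / s_n[j]
                par.mu_n[j] = mu
                par.sd_n[j] = max(
                    np.sqrt(((1 - occ[:, j]) * (xj - mu) ** 2).sum() / s_n[j]),
                    sd_floor[j],
                )
            if par.mu_a[j] <= par.mu_n[j]:
                par.mu_a[j] = par.mu_n[j] + 1e-6
        w = np.clip(occ.mean(axis=0), 1e-3, 1 - 1e-3)
        if abs(ll - prev_ll) < tol:
            break
        prev_ll = ll
    return par, pi, w, post, ll


def _moment_split(x, occ, sd_floor, min_mass=1.0):
    """One weighted-moment fit of a two-sided split; neutral fallback for
    an unidentified side.  Returns ((mu_n, sd_n, mu_a, sd_a), n_params)."""
    sa = occ.sum()
    sn = len(x) - sa
    have_a, have_n = sa > min_mass, sn > min_mass
    mu_a = mu_n = sd_a = sd_n = None
    if have_a:
        mu_a = (occ * x).sum() / sa
        sd_a = max(np.sqrt((occ * (x - mu_a) ** 2).sum() / sa), sd_floor)
    if have_n:
        mu_n = ((1 - occ) * x).sum() / sn
        sd_n = max(np.sqrt(((1 - occ) * (x - mu_n) ** 2).sum() / sn), sd_floor)
    if not have_a and not have_n:
        mu_n = mu_a = x.mean()
        sd_n = sd_a = max(x.std(), sd_floor)
    elif not have_a:
        mu_a, sd_a = mu_n, sd_n
    elif not have_n:
        mu_n, sd_n = mu_a, sd_a
    if mu_a < mu_n:
        mu_a = mu_n
    return (mu_n, sd_n, mu_a, sd_a), 2 * have_a + 2 * have_n


def _assignment_proposal(
    X: np.ndarray,
    ordering: np.ndarray,
    par: _Params,
    pi: np.ndarray,
    sd_floor: np.ndarray,
    skew: np.ndarray,
    penalty_per_param: float = 2.0,
    tie_scale: float = 1.0,
) -> np.ndarray:
    """Propose a new ordering by optimal assignment of events to positions.

    For each event the stage field of the *other* events (leave-one-out)
    yields, for every candidate position, soft occurred/not labels; a
    moment fit scores how well that split explains the event's values.  An
    AIC-style penalty stops saturated events from borrowing spurious
    mid-sequence splits, and a small skewness term breaks the otherwise
    exact tie between the two ends for events nearly everyone (or no one)
    has passed.  The Hungarian algorithm returns the jointly best
    event-to-position assignment.
    """
    from scipy.optimize import linear_sum_assignment

    n, K = X.shape
    pos = np.empty(K, dtype=int)
    pos[ordering] = np.arange(K)
    ln_all = _norm_logpdf(X, par.mu_n, par.sd_n)
    la_all = _norm_logpdf(X, par.mu_a, par.sd_a)
    L = _stage_loglik(X, ordering, par)
    log_pi = np.log(np.maximum(pi, 1e-300))
    stages = np.arange(K + 1)[None, :]
    score = np.empty((K, K))
    for j in range(K):
        contrib = np.where(stages >= pos[j] + 1,
                           la_all[:, j][:, None], ln_all[:, j][:, None])
        lp = (L - contrib) + log_pi
        post_wo = np.exp(lp - logsumexp(lp, axis=1, keepdims=True))
        occ_wo = np.clip(post_wo[:, ::-1].cumsum(axis=1)[:, ::-1][:, 1:], 0.0, 1.0)
        xj = X[:, j]
        for p in range(K):
            occ = occ_wo[:, p]
            (mu_n, sd_n, mu_a, sd_a), k_est = _moment_split(
                xj, occ, sd_floor[j])
            la = np.log(np.clip(occ, 1e-12, 1)) + _norm_logpdf(xj, mu_a, sd_a)
            ln = np.log(np.clip(1 - occ, 1e-12, 1)) + _norm_logpdf(xj, mu_n, sd_n)
            score[j, p] = (
                np.logaddexp(la, ln).sum()
                - penalty_per_param * k_est / 2.0
                + tie_scale * skew[j] * (p - (K - 1) / 2) / max(K - 1, 1)
            )
    rows, cols = linear_sum_assignment(-score)
    proposal = np.empty(K, dtype=int)
    proposal[cols] = rows
    return proposal


def _likelihood_ordering_descent(
    X: np.ndarray,
    ordering: np.ndarray,
    par: _Params,
    pi: np.ndarray,
    max_range: int | None = None,
    max_sweeps: int = 50,
) -> np.ndarray:
    """Single-event insertion ascent on the joint stage likelihood.

    At fixed component parameters and stage prior, greedily accepts the
    best-improving relocation of one event to another position until no
    move improves.  This escapes orderings that are self-consistent under
    the posterior-based Kendall objective but poorly supported by the data
    (e.g. a saturated event parked at the wrong end of the sequence).
    For long sequences ``max_range`` restricts relocations to nearby
    positions, keeping each sweep linear in K.
    """
    K = len(ordering)
    ordering = ordering.copy()
    best_ll = _joint_ll(X, ordering, par, pi)
    for _ in range(max_sweeps):
        improved = False
        best_move = None
        for u in range(K):
            targets = (range(K) if max_range is None else
                       range(max(0, u - max_range), min(K, u + max_range + 1)))
            for v in targets:
                if v == u:
                    continue
                cand = np.delete(ordering, u)
                cand = np.insert(cand, v, ordering[u])
                ll = _joint_ll(X, cand, par, pi)
                if ll > best_ll + 1e-9:
                    best_ll, best_move, improved = ll, cand, True
        if best_move is None:
            break
        ordering = best_move
        if not improved:
            break
    return ordering


def _joint_refine(
    X: np.ndarray,
    is_control: np.ndarray,
    ordering: np.ndarray,
    par: _Params,
    exhaustive_limit: int,
    n_outer: int = 8,
    n_stage_em: int = 25,
    min_mass: float = 1.0,
) -> tuple[np.ndarray, _Params, np.ndarray, np.ndarray, float]:
    """Likelihood-guarded coordinate ascent over orderings and parameters.

    The EM core (:func:`_em_fixed_ordering`) re-estimates components,
    prevalences and the stage prior at the current ordering.  Two kinds of
    ordering proposals are then evaluated — a global event-to-position
    assignment (:func:`_assignment_proposal`) and a single-event insertion
    descent — each re-fitted briefly by EM and accepted only if the joint
    log-likelihood improves, so a correct configuration can never be
    degraded by a proposal.  Returns ordering, parameters, prevalences,
    stage prior and the final joint log-likelihood.
    """
    n, K = X.shape
    sd_floor = np.maximum(0.1 * X.std(axis=0), _SD_FLOOR)
    skew = stats.skew(X, axis=0)
    pi = np.full(K + 1, 1.0 / (K + 1))
    state = _em_fixed_ordering(X, ordering, par, pi, sd_floor, min_mass=min_mass)
    par, pi, w, post, ll = state
    best = (ordering, par, pi, w, post, ll)
    for _ in range(n_outer):
        ordering, par, pi, w, post, ll = best
        proposals = []
        prop_a = _assignment_proposal(X, ordering, par, pi, sd_floor, skew)
        if not np.array_equal(prop_a, ordering):
            proposals.append(prop_a)
        prop_d = _likelihood_ordering_descent(
            X, ordering, par, pi, max_range=None if K <= 12 else 8)
        if not np.array_equal(prop_d, ordering) and not any(
            np.array_equal(prop_d, p) for p in proposals
        ):
            proposals.append(prop_d)
        improved = False
        for prop in proposals:
            par_p, pi_p, w_p, post_p, ll_p = _em_fixed_ordering(
                X, prop, par, pi, sd_floor, min_mass=min_mass
            )
            if ll_p > best[5] + 1e-6:
                best = (prop, par_p, pi_p, w_p, post_p, ll_p)
                improved = True
        if not improved:
            break
    ordering, par, pi, w, post, ll = best
    return ordering, par, w, pi, ll


def _severity_transition_ordering(X: np.ndarray) -> np.ndarray:
    """Initial ordering from where each marker transitions along severity.

    Subjects are ranked by a leave-one-marker-out mean abnormality score;
    each marker's transition point is where its running mean (along that
    ranking) crosses the midpoint of its range.  Markers without a real
    transition (range below one column sd) are saturated: negative skew
    suggests an almost-always-passed (early) event, positive skew a rare
    (late) one.
    """
    n, K = X.shape
    Z = (X - X.mean(axis=0)) / np.maximum(X.std(axis=0), _SD_FLOOR)
    total = Z.sum(axis=1)
    wlen = int(np.clip(n // 10, 5, 50))
    kernel = np.ones(wlen) / wlen
    cross = np.empty(K)
    flat = np.zeros(K, dtype=bool)
    skew = stats.skew(X, axis=0)
    for j in range(K):
        sev = (total - Z[:, j]) / (K - 1)    # leave-one-out severity
        run = np.convolve(X[np.argsort(sev), j], kernel, mode="valid")
        amp = run.max() - run.min()
        if amp < X[:, j].std():
            flat[j] = True
            cross[j] = -1.0 if skew[j] < 0 else n + 1.0
        else:
            mid = (run.min() + run.max()) / 2
            above = run >= mid
            cross[j] = float(np.argmax(above)) if above.any() else float(n)
    order = np.argsort(cross, kind="stable")
    return order, flat


def _candidate_orderings(
    X: np.ndarray,
    is_control: np.ndarray,
    P0: np.ndarray,
    max_variants: int,
    exhaustive_limit: int,
) -> list[np.ndarray]:
    """Diverse starting orderings for the joint refinement."""
    patients = ~is_control
    K = X.shape[1]
    cands: list[np.ndarray] = []
    trans, flat = _severity_transition_ordering(X)
    cands.append(trans)
    cands.append(np.argsort(-P0[patients].mean(axis=0), kind="stable"))
    cands.append(central_ordering(P0, patients, exhaustive_limit).ordering)
    if K <= 12:
        # saturated markers could belong at either end: try each flipped
        pos = np.empty(K, dtype=int)
        pos[trans] = np.arange(K)
        for j in np.flatnonzero(flat):
            var = trans[trans != j]
            var = (np.concatenate([var, [j]]) if pos[j] < K // 2
                   else np.concatenate([[j], var]))
            cands.append(var)
            if len(cands) >= max_variants:
                break
    uniq = []
    for c in cands:
        if not any(np.array_equal(c, u) for u in uniq):
            uniq.append(np.asarray(c, dtype=int))
    return uniq


def _init_params_from_ordering(
    X: np.ndarray, ordering: np.ndarray
) -> _Params:
    """Hard-label initialization: stages from severity ranks, moments from labels."""
    n, K = X.shape
    Z = (X - X.mean(axis=0)) / np.maximum(X.std(axis=0), _SD_FLOOR)
    sev = Z.mean(axis=1)
    rank = np.argsort(np.argsort(sev))
    k_s = np.floor((K + 1) * (rank + 0.5) / n).astype(int)
    pos = np.empty(K, dtype=int)
    pos[ordering] = np.arange(K)
    occurred = pos[None, :] < k_s[:, None]
    mu_n = np.empty(K); sd_n = np.empty(K)
    mu_a = np.empty(K); sd_a = np.empty(K)
    for j in range(K):
        xj = X[:, j]
        o = occurred[:, j]
        col_sd = max(xj.std(), _SD_FLOOR)
        if o.sum() > 2:
            mu_a[j], sd_a[j] = xj[o].mean(), max(xj[o].std(), 0.2 * col_sd)
        else:
            mu_a[j], sd_a[j] = xj.max() + col_sd, col_sd
        if (~o).sum() > 2:
            mu_n[j], sd_n[j] = xj[~o].mean(), max(xj[~o].std(), 0.2 * col_sd)
        else:
            mu_n[j], sd_n[j] = xj.min() - col_sd, col_sd
        if mu_a[j] <= mu_n[j]:
            mu_a[j] = mu_n[j] + 1e-6
    return _Params(mu_n, sd_n, mu_a, sd_a)


@dataclass
class EBMFit:
    """Complete fitted event-based model for one biomarker panel."""

    fits: list[MixtureFit]
    posteriors: np.ndarray           # all subjects x K
    sequence: EventSequence
    biomarkers: list[str] = field(default_factory=list)
    stage_prior: np.ndarray | None = None
    joint_log_likelihood: float | None = None


def fit_ebm(
    X: np.ndarray,
    is_control: np.ndarray,
    biomarkers: list[str] | None = None,
    rng: np.random.Generator | None = None,
    n_restarts: int = 5,
    exhaustive_limit: int = 7,
    refine: bool = True,
    max_variants: int = 8,
    init_ordering: np.ndarray | None = None,
) -> EBMFit:
    """Fit mixtures, posteriors, central ordering and event-centers.

    With ``refine`` (default) the marginal control-anchored mixtures only
    initialize a joint stage-EM refinement started from several candidate
    orderings; the refit with the best joint log-likelihood is kept.  Set
    ``refine=False`` for the plain marginal fit.  ``init_ordering`` warm-
    starts the refinement from a single known-good ordering (used by the
    bootstrap to refit resamples from the full-data solution) and skips the
    marginal fits.
    """
    X = np.asarray(X, dtype=float)
    is_control = np.asarray(is_control, dtype=bool)
    rng = rng or np.random.default_rng(0)
    n, K = X.shape
    if not refine:
        fits = [
            fit_abnormality_model(X[:, j], is_control, rng=rng,
                                  n_restarts=n_restarts)
            for j in range(K)
        ]
        P = posterior_matrix(X, fits)
        seq = central_ordering(P, ~is_control, exhaustive_limit=exhaustive_limit)
        seq.event_centers = estimate_event_centers(seq.ordering, P, ~is_control)
        return EBMFit(fits, P, seq, biomarkers or [])

    if init_ordering is not None:
        candidates = [np.asarray(init_ordering, dtype=int)]
    else:
        fits = [
            fit_abnormality_model(X[:, j], is_control, rng=rng,
                                  n_restarts=n_restarts)
            for j in range(K)
        ]
        P = posterior_matrix(X, fits)
        candidates = _candidate_orderings(X, is_control, P, max_variants,
                                          exhaustive_limit)
    best = None
    for cand in candidates:
        par0 = _init_params_from_ordering(X, cand)
        out = _joint_refine(X, is_control, cand, par0, exhaustive_limit)
        if best is None or out[4] > best[4]:
            best = out
    ordering, par, w, pi, ll = best
    fits = [
        MixtureFit(par.mu_n[j], par.sd_n[j], par.mu_a[j], par.sd_a[j],
                   float(w[j]), ll, np.asarray([ll]), True)
        for j in range(K)
    ]
    P = _marker_posteriors(X, par, w)
    seq = central_ordering(P, ~is_control, exhaustive_limit=exhaustive_limit)
    seq.event_centers = estimate_event_centers(seq.ordering, P, ~is_control)
    return EBMFit(fits, P, seq, biomarkers or [], stage_prior=pi,
                  joint_log_likelihood=ll)


def bootstrap_sequence(
    X: np.ndarray,
    is_control: np.ndarray,
    B: int = 100,
    rng: np.random.Generator | None = None,
    n_restarts: int = 5,
    exhaustive_limit: int = 7,
    refine: bool = True,
    init_ordering: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Subject-level bootstrap of the complete model.

    Each of ``B`` resamples (with replacement) refits every mixture and the
    central ordering.  ``init_ordering`` (typically the full-data fit)
    warm-starts each refit.  Returns the positional-variance matrix ``F``
    with ``F[i, m]`` = fraction of fits placing biomarker ``i`` at position
    ``m`` (rows and columns each sum to 1), plus the per-resample
    event-center of every biomarker (B x K).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    X = np.asarray(X, dtype=float)
    is_control = np.asarray(is_control, dtype=bool)
    rng = rng or np.random.default_rng(0)
    n, K = X.shape
    F = np.zeros((K, K))
    ec_samples = np.empty((B, K))
    for b in range(B):
        for _ in range(10):
            idx = rng.integers(0, n, size=n)
            ctl_b = is_control[idx]
            if ctl_b.any() and (~ctl_b).any():
                break
            warnings.warn("bootstrap resample missing a group; redrawing", stacklevel=2)
        else:
            raise RuntimeError("could not draw a resample containing both groups")
        Xb = X[idx]
        fit_b = fit_ebm(Xb, ctl_b, rng=rng, n_restarts=n_restarts,
                        exhaustive_limit=exhaustive_limit, refine=refine,
                        init_ordering=init_ordering)
        seq = fit_b.sequence
        F[seq.ordering, np.arange(K)] += 1.0
        ec_samples[b, seq.ordering] = seq.event_centers
    return F / B, ec_samples
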