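"""PCA of item-level battery z-scores, with sampling-adequacy diagnostics.

All decompositions act on the item correlation matrix (trace = p), so the
eigenvalue-threshold selection rules are meaningful: the Kaiser rule keeps
components with eigenvalue > 1, the Jolliffe variant keeps the smallest set
reaching 70% cumulative variance with every eigenvalue > 0.7.  Component
scores are z-items times unit-norm eigenvectors, with the sign fixed so the
largest-magnitude loading of each component is positive.  A per-battery
composite collapses the selected components into one scalar.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AdequacyReport",
    "PCAModel",
    "kmo",
    "bartlett_sphericity",
    "fit_pca",
    "select_components",
    "composite_score",
    "reduce_battery",
]


@dataclass
class AdequacyReport:
    kmo_overall: float
    kmo_per_item: np.ndarray
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float


@dataclass
class PCAModel:
    eigenvalues: np.ndarray        # descending, sums to p
    loadings: np.ndarray           # item x component unit-norm eigenvectors
    explained_fraction: np.ndarray
    n_selected: int
    scores: np.ndarray             # subject x selected component scores
    composite: np.ndarray | None
    columns: list[str]


def _check_correlation(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("R must be a square correlation matrix")
    if not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise ValueError("correlation matrix diagonal must be 1")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    return R


def kmo(R: np.ndarray) -> tuple[float, np.ndarray]:
    """Kaiser-Meyer-Olkin sampling adequacy from a correlation matrix.

    KMO = sum r_ij^2 / (sum r_ij^2 + sum q_ij^2) over off-diagonal pairs,
    where q_ij are the anti-image partial correlations obtained from the
    inverse of R; the per-item measure uses the same ratio restricted to
    row i.
    """
    R = _check_correlation(R)
    try:
        S = np.linalg.inv(R)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular correlation matrix") from err
    d = np.sqrt(np.diag(S))
    Q = -S / np.outer(d, d)
    np.fill_diagonal(Q, 0.0)
    R_off = R - np.eye(len(R))
    r2 = R_off**2
    q2 = Q**2
    denom_terms = r2.sum() + q2.sum()
    if r2.sum() == 0:
        raise ValueError("no off-diagonal correlation structure (R is the identity)")
    overall = r2.sum() / denom_terms
    per_item = r2.sum(axis=1) / (r2.sum(axis=1) + q2.sum(axis=1))
    return float(overall), per_item


def bartlett_sphericity(R: np.ndarray, n: int) -> tuple[float, int, float]:
    """Bartlett's test that the correlation matrix is the identity.

    chi2 = -(n - 1 - (2p + 5)/6) * ln det(R), df = p(p-1)/2.
    """
    R = _check_correlation(R)
    p = R.shape[0]
    if n <= p:
        raise ValueError(f"need n > p (got n={n}, p={p})")
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("correlation matrix has non-positive determinant")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), pval


def fit_pca(z_items: pd.DataFrame, n_components: int | None = None) -> PCAModel:
    """PCA of the item correlation matrix of an (already z-scored) item table."""
    X = np.asarray(z_items, dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least 2 items")
    if n <= p:
        raise ValueError(f"need more subjects than items (n={n}, p={p})")
    sds = X.std(axis=0, ddof=1)
    if (sds == 0).any():
        const = [z_items.columns[i] for i in np.flatnonzero(sds == 0)]
        raise ValueError(f"constant item column(s): {const}")
    R = np.corrcoef(X, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(R)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # deterministic sign: largest |loading| entry of each component positive
    for j in range(p):
        k = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[k, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    explained = eigvals / p
    Z = (X - X.mean(axis=0)) / sds
    n_selected = select_components_from_eigenvalues(eigvals, rule="kaiser")
    if n_components is not None:
        n_selected = n_components
    scores = Z @ eigvecs[:, :n_selected]
    model = PCAModel(
        eigenvalues=eigvals,
        loadings=eigvecs,
        explained_fraction=explained,
        n_selected=n_selected,
        scores=scores,
        composite=None,
        columns=list(z_items.columns),
    )
    if n_selected >= 1:
        model.composite = composite_score(model)
    return model


def select_components_from_eigenvalues(
    eigenvalues: np.ndarray, rule: str = "kaiser"
) -> int:
    """Component count by the Kaiser (eigenvalue > 1) or Jolliffe rule.

    Jolliffe: smallest m with cumulative explained fraction > 0.70 and all
    m eigenvalues > 0.7; returns 0 when no m satisfies both.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if rule == "kaiser":
        return int((ev > 1.0).sum())
    if rule == "jolliffe":
        frac = np.cumsum(ev) / ev.sum()
        for m in range(1, len(ev) + 1):
            if frac[m - 1] > 0.70 and (ev[:m] > 0.7).all():
                return m
        return 0
    raise ValueError(f"unknown rule {rule!r}")


def select_components(model: PCAModel, rule: str = "kaiser") -> int:
    n = select_components_from_eigenvalues(model.eigenvalues, rule)
    other = "jolliffe" if rule == "kaiser" else "kaiser"
    n_other = select_components_from_eigenvalues(model.eigenvalues, other)
    if n != n_other:
        warnings.warn(
            f"component-selection rules disagree: {rule}={n}, {other}={n_other}",
            stacklevel=2,
        )
    return n


def composite_score(model: PCAModel, weighting: str = "eigenvalue") -> np.ndarray:
    """Single per-subject battery score from the selected components.

    Default weights each selected component score by its eigenvalue
    (explained variance); ``weighting='equal'`` takes the plain mean.
    """
    if model.n_selected < 1:
        raise ValueError("no components selected; composite undefined")
    scores = model.scores[:, : model.n_selected]
    if weighting == "equal":
        return scores.mean(axis=1)
    if weighting == "eigenvalue":
        w = model.eigenvalues[: model.n_selected]
        return scores @ w / w.sum()
    raise ValueError(f"unknown weighting {weighting!r}")


def reduce_battery(
    items: pd.DataFrame,
    reference: np.ndarray,
    name: str,
    n_components: int | None = None,
) -> tuple[pd.DataFrame, PCAModel, AdequacyReport]:
    """Z-score a battery against the reference and reduce it to PC scores.

    Returns the per-subject component-score table (columns ``<name>_PC1``..)
    with the composite appended as ``<name>_PC``, the fitted model, and the
    KMO/Bartlett adequacy report.
    """
    from .preprocess import zscore_to_reference

    z = zscore_to_reference(items, reference)
    R = np.corrcoef(np.asarray(z, float), rowvar=False)
    kmo_overall, kmo_items = kmo(R)
    chi2, df, pval = bartlett_sphericity(R, n=len(z))
    report = AdequacyReport(kmo_overall, kmo_items, chi2, df, pval)
    model = fit_pca(z, n_components=n_components)
    cols = {f"{name}_PC{j + 1}": model.scores[:, j] for j in range(model.n_selected)}
    out = pd.DataFrame(cols, index=items.index)
    if model.composite is not None:
        out[f"{name}_PC"] = model.composite
    return out, model, report
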