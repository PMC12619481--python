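"""Harmonization, reference z-scoring, covariate residualization and ROI pooling.

The fixed pipeline order is: direction harmonization (so higher always means
more abnormal) -> z-score against the healthy-control reference -> OLS
residualization of age/sex/education fitted on the controls only.  Controls
are the reference because the event-based model's "normal" anchor must be
disease-free.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "zscore_to_reference",
    "harmonize_direction",
    "residualize_covariates",
    "aggregate_rois",
    "load_roi_scheme",
    "prepare_biomarkers",
]


def zscore_to_reference(values: pd.DataFrame, reference: np.ndarray) -> pd.DataFrame:
    """Z-score every column against the reference subset (n-1 sd).

    Reference rows end up with mean 0 and sd 1 in each column.
    """
    reference = np.asarray(reference, dtype=bool)
    if reference.sum() < 2:
        raise ValueError("reference subset needs at least 2 rows")
    ref = values.loc[reference]
    mean = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=1)
    bad = sd.index[(sd == 0) | ~np.isfinite(sd)]
    if len(bad):
        raise ValueError(f"zero reference sd in column(s): {list(bad)}")
    return (values - mean) / sd


def harmonize_direction(
    values: pd.DataFrame, higher_is_worse: dict[str, bool]
) -> pd.DataFrame:
    """Negate higher-is-better columns so that higher always means more abnormal.

    Idempotent when re-applied with all flags set to True.
    """
    missing = [c for c in values.columns if c not in higher_is_worse]
    if missing:
        raise ValueError(f"missing direction flag for column(s): {missing}")
    out = values.copy()
    for col in out.columns:
        if not higher_is_worse[col]:
            out[col] = -out[col]
    return out


def _design_matrix(cov: pd.DataFrame) -> np.ndarray:
    return np.column_stack(
        [
            np.ones(len(cov)),
            cov["age"].to_numpy(float),
            cov["sex"].to_numpy(float),
            cov["education"].to_numpy(float),
        ]
    )


def residualize_covariates(
    values: pd.DataFrame, covariates: pd.DataFrame, reference: np.ndarray
) -> pd.DataFrame:
    """Remove linear age/sex/education effects, fitted on the reference subset.

    The OLS fit uses reference rows only; the fitted prediction is subtracted
    from every row, so reference residuals have zero mean while non-reference
    rows keep their deviation from the reference norm.
    """
    reference = np.asarray(reference, dtype=bool)
    X = _design_matrix(covariates)
    X_ref = X[reference]
    if np.linalg.matrix_rank(X_ref) < X_ref.shape[1]:
        raise ValueError("rank-deficient design matrix on the reference subset")
    Y_ref = values.loc[reference].to_numpy(float)
    beta, *_ = np.linalg.lstsq(X_ref, Y_ref, rcond=None)
    predicted = X @ beta
    return pd.DataFrame(
        values.to_numpy(float) - predicted, index=values.index, columns=values.columns
    )


def load_roi_scheme() -> dict:
    with resources.files("t2ebm.manifests").joinpath("roi_scheme.json").open() as fh:
        return json.load(fh)


def aggregate_rois(
    regional: pd.DataFrame, scheme: dict | None = None
) -> pd.DataFrame:
    """Pool AAL region GMV into the 35-feature ROI table.

    17 features are computed per hemisphere (columns ``<feature>_L`` /
    ``<feature>_R``, mean of the member regions) plus the cerebellar
    vermis, giving 35 columns.  Raises if any member region is absent.
    """
    scheme = scheme or load_roi_scheme()
    suffixes = scheme["hemisphere_suffixes"]
    out = {}
    missing: list[str] = []
    for feature, members in scheme["features"].items():
        for hemi, suffix in suffixes.items():
            cols = [m + suffix for m in members]
            absent = [c for c in cols if c not in regional.columns]
            if absent:
                missing.extend(absent)
                continue
            out[feature + suffix] = regional[cols].mean(axis=1)
    for feature, members in scheme["midline"].items():
        absent = [c for c in members if c not in regional.columns]
        if absent:
            missing.extend(absent)
        else:
            out[feature] = regional[members].mean(axis=1)
    if missing:
        raise ValueError(f"missing region column(s): {missing}")
    return pd.DataFrame(out, index=regional.index)


def prepare_biomarkers(
    values: pd.DataFrame,
    covariates: pd.DataFrame,
    higher_is_worse: dict[str, bool],
    control_mask: np.ndarray,
    tiv: pd.Series | None = None,
) -> pd.DataFrame:
    """Full preprocessing: (TIV scaling) -> harmonize -> z-score -> residualize.

    ``tiv``, when given, divides every column first (GMV normalisation by
    total intracranial volume).  The control group is the reference for both
    the z-scoring and the covariate fit.
    """
    if tiv is not None:
        values = values.div(np.asarray(tiv, dtype=float), axis=0)
        higher_is_worse = dict(higher_is_worse)
    harmonized = harmonize_direction(values, higher_is_worse)
    z = zscore_to_reference(harmonized, control_mask)
    return residualize_covariates(z, covariates, control_mask)
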