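"""Model covariates: past pressure, recent pressure change, stream position.

Three drivers enter the trend models:

* ``X_past`` — the human footprint index in 1993 (0-50 composite of
  population, land-use and infrastructure pressures), centred and scaled;
* ``X_change`` — log2 of the 2009/1993 footprint ratio, so -1 and +1 mean
  a halving and a doubling of pressure; scaled but *not* centred, so main
  effects read as baseline (no-recent-change) effects;
* ``X_stream`` — the upstream-downstream gradient: a varimax-rotated PCA
  score over five log-transformed, standardized hydromorphological
  variables, signed so that downstream (large discharge, distance from
  source and Strahler order) is positive; centred and scaled.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import STREAM_VARIABLES

#: offset used in place of a zero footprint before the ratio (half the
#: index resolution); the index itself cannot distinguish 0 from <0.5
ZERO_HFI_OFFSET = 0.5


def log2_pressure_change(
    hfi_past: np.ndarray | float, hfi_recent: np.ndarray | float
) -> np.ndarray | float:
    """log2 ratio of recent to past human footprint.

    -1 is a halving, +1 a doubling.  Zero footprints are offset by
    ``ZERO_HFI_OFFSET`` so the ratio stays finite; negative inputs raise.
    """
    past = np.asarray(hfi_past, dtype=float)
    recent = np.asarray(hfi_recent, dtype=float)
    if np.any(past < 0) or np.any(recent < 0):
        raise ValueError("human footprint values cannot be negative")
    past = np.where(past == 0, ZERO_HFI_OFFSET, past)
    recent = np.where(recent == 0, ZERO_HFI_OFFSET, recent)
    out = np.log2(recent / past)
    return float(out) if out.ndim == 0 else out


def varimax_rotate(
    loadings: np.ndarray, tol: float = 1e-10, max_iter: int = 500
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation of a loading matrix.

    Iterative pairwise-SVD algorithm maximizing the sum of loading-column
    variances of squared loadings.  Returns ``(rotated, rotation)`` with
    ``rotated = loadings @ rotation`` and ``rotation`` orthogonal.
    """
    L = np.asarray(loadings, dtype=float)
    p, k = L.shape
    if k < 2:
        return L.copy(), np.eye(k)
    R = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lr ** 3 - Lr @ np.diag((Lr ** 2).sum(axis=0)) / p)
        )
        R = u @ vt
        var_new = s.sum()
        if var_new < var_old * (1 + tol):
            break
        var_old = var_new
    return L @ R, R


def varimax_criterion(loadings: np.ndarray) -> float:
    """The varimax objective: sum over columns of var(loading^2)."""
    L2 = np.asarray(loadings, dtype=float) ** 2
    return float(np.sum(L2.var(axis=0)))


class StreamPositionAxis(BaseEstimator, TransformerMixin):
    """Longitudinal stream-position score from hydromorphological variables.

    Fits a PCA on the log-transformed (shifted by ``|min| + 1`` where a
    variable has non-positive values) and standardized stream variables,
    varimax-rotates the first two components, and keeps the rotated
    component loading positively on discharge, distance from source and
    Strahler order.  The score's sign is fixed so that downstream sites
    score positive.

    Attributes
    ----------
    loadings_ : DataFrame, shape (5, 2)
        Rotated loadings of the two retained components.
    explained_variance_ratio_ : ndarray, shape (2,)
        Variance fractions of the two rotated components (of the total
        variance of the five standardized variables).
    axis_ : int
        Which rotated component (0 or 1) is the stream-position axis.
    """

    def __init__(self, variables: list[str] | None = None):
        self.variables = variables

    def _prepare(self, table: pd.DataFrame) -> np.ndarray:
        cols = self.variables or STREAM_VARIABLES
        X = table[cols].to_numpy(dtype=float)
        shift = np.where(X.min(axis=0) <= 0, np.abs(X.min(axis=0)) + 1.0, 0.0)
        X = np.log(X + shift)
        sd = X.std(axis=0, ddof=1)
        # log of identical values leaves rounding dust; treat as constant
        zero = [c for c, s in zip(cols, sd) if s < 1e-12]
        if zero:
            raise ValueError(f"constant stream variable(s): {zero}")
        self._shift = shift
        self._mean = X.mean(axis=0)
        self._sd = sd
        return (X - self._mean) / sd

    def fit(self, table: pd.DataFrame, y=None) -> "StreamPositionAxis":
        cols = self.variables or STREAM_VARIABLES
        if len(table) < 3:
            raise ValueError("need at least 3 sites for the stream-position PCA")
        Z = self._prepare(table)
        # PCA via SVD of the standardized matrix
        u, s, vt = np.linalg.svd(Z, full_matrices=False)
        eigvals = s ** 2 / (len(table) - 1)
        raw_loadings = vt[:2].T * np.sqrt(eigvals[:2])  # variable-component correlations
        rotated, R = varimax_rotate(raw_loadings)
        # the downstream axis loads positively on discharge, distance, order
        down = [cols.index(v) for v in ("discharge_m3s", "dist_source_km", "strahler")]
        score_by_axis = np.abs(rotated[down]).sum(axis=0)
        axis = int(np.argmax(score_by_axis))
        sign = 1.0 if rotated[cols.index("strahler"), axis] >= 0 else -1.0
        rotated[:, axis] *= sign

        self.components_raw_ = vt[:2].T
        self.rotation_ = R
        self.loadings_ = pd.DataFrame(rotated, index=cols, columns=["rc1", "rc2"])
        self.explained_variance_ratio_ = (rotated ** 2).sum(axis=0) / Z.shape[1]
        self.axis_ = axis
        self._sign = sign
        self.n_features_in_ = len(cols)
        return self

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        """Per-site stream-position scores (1-D array, downstream positive)."""
        check_is_fitted(self, "loadings_")
        cols = self.variables or STREAM_VARIABLES
        X = np.log(table[cols].to_numpy(dtype=float) + self._shift)
        Z = (X - self._mean) / self._sd
        # score on rotated components, standardized loadings convention:
        # regression scores T = Z V R with V the retained eigenvectors
        scores = Z @ self.components_raw_ @ self.rotation_
        return scores[:, self.axis_] * self._sign


def stream_position_axis(table: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """Fit the rotated-PCA stream axis; returns (scores, loading report)."""
    est = StreamPositionAxis().fit(table)
    return est.transform(table), est.loadings_


class PredictorScaler(BaseEstimator, TransformerMixin):
    """Centre/scale the driver columns the way the trend models expect.

    ``X_past`` and ``X_stream`` are centred and scaled to unit SD;
    ``X_change`` is scaled only, so that 0 keeps meaning "no recent
    change".  Means and SDs are stored for back-transformation.
    """

    CENTERED = ("X_past", "X_stream")
    SCALED_ONLY = ("X_change",)

    def fit(self, table: pd.DataFrame, y=None) -> "PredictorScaler":
        self.means_ = {}
        self.sds_ = {}
        for col in (*self.CENTERED, *self.SCALED_ONLY):
            x = table[col].to_numpy(dtype=float)
            sd = float(x.std(ddof=1))
            if sd == 0:
                raise ValueError(f"predictor {col} has zero variance")
            self.means_[col] = float(x.mean()) if col in self.CENTERED else 0.0
            self.sds_[col] = sd
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "means_")
        out = table.copy()
        for col in (*self.CENTERED, *self.SCALED_ONLY):
            out[col] = (table[col] - self.means_[col]) / self.sds_[col]
        return out

    def inverse_transform(self, table: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "means_")
        out = table.copy()
        for col in (*self.CENTERED, *self.SCALED_ONLY):
            out[col] = table[col] * self.sds_[col] + self.means_[col]
        return out


def build_drivers(covariates: pd.DataFrame, standardize: bool = True) -> pd.DataFrame:
    """Assemble the per-site driver table from raw covariates.

    Returns one row per site with raw driver values (``hfi_1993``,
    ``log2_hfi_ratio``, ``stream_position``) alongside the standardized
    model columns ``X_past``, ``X_change`` and ``X_stream``.
    """
    scores, _ = stream_position_axis(covariates)
    out = pd.DataFrame(
        {
            "site_id": covariates["site_id"].to_numpy(),
            "basin_id": covariates["basin_id"].to_numpy(),
            "hfi_1993": covariates["hfi_1993"].to_numpy(dtype=float),
            "log2_hfi_ratio": log2_pressure_change(
                covariates["hfi_1993"].to_numpy(), covariates["hfi_2009"].to_numpy()
            ),
            "stream_position": scores,
        }
    )
    out["X_past"] = out["hfi_1993"]
    out["X_change"] = out["log2_hfi_ratio"]
    out["X_stream"] = out["stream_position"]
    if standardize:
        scaler = PredictorScaler().fit(out)
        out = scaler.transform(out)
        out.attrs["scaler_means"] = scaler.means_
        out.attrs["scaler_sds"] = scaler.sds_
    return out


def spearman_driver_correlations(drivers: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlations among the three model drivers."""
    cols = ["X_past", "X_change", "X_stream"]
    return drivers[cols].corr(method="spearman")
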