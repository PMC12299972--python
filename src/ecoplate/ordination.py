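"""Ordination linking soil nutrients and community function.

* :func:`pca_biplot` — PCA on the correlation (default) or covariance matrix
  of a samples x variables table, with biplot loadings and a deterministic
  sign convention.
* :func:`rda_permutation_test` — redundancy analysis: the eigenanalysis of
  the fitted values of the multivariate least-squares regression of the
  (standardized) response table on the (standardized) predictor table, with
  a pseudo-F whose significance comes from unrestricted row permutation of
  the response.  The add-one convention p = (1 + #{F* >= F}) / (1 + m) keeps
  p strictly positive, with floor 1/(m+1).
* :func:`radar_normalize` — per-variable min-max scaling of treatment means
  onto [0, 1] for radar charts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import DegenerateDataError, ValidationError


@dataclass
class OrdinationResult:
    method: str  # "pca" or "rda"
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # variables x components
    explained_fraction: np.ndarray
    eigenvalues: np.ndarray
    dropped: list[str] = field(default_factory=list)
    pseudo_f: float | None = None
    permutation_p: float | None = None
    n_permutations: int = 0
    seed: int | None = None

    def summary(self) -> pd.DataFrame:
        """Tidy per-component summary for export."""
        df = pd.DataFrame(
            {
                "component": self.scores.columns,
                "eigenvalue": self.eigenvalues,
                "explained_fraction": self.explained_fraction,
            }
        )
        df["method"] = self.method
        df["pseudo_f"] = self.pseudo_f
        df["permutation_p"] = self.permutation_p
        df["n_permutations"] = self.n_permutations
        df["seed"] = self.seed
        return df


def _standardize(table: pd.DataFrame, what: str) -> tuple[np.ndarray, list[str], list[str]]:
    """z-score columns (ddof=1); drop zero-variance columns with a warning."""
    num = table.select_dtypes(include=[np.number])
    sd = num.std(ddof=1)
    keep = [c for c in num.columns if sd[c] > 0]
    dropped = [c for c in num.columns if c not in keep]
    if dropped:
        warnings.warn(f"dropping zero-variance {what} variables: {dropped}")
    if not keep:
        raise DegenerateDataError(f"all {what} variables are constant")
    X = num[keep].to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    return X, keep, dropped


def _fix_signs(vectors: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Make the largest-|loading| element of each component positive."""
    for j in range(vectors.shape[1]):
        i = int(np.argmax(np.abs(vectors[:, j])))
        if vectors[i, j] < 0:
            vectors[:, j] *= -1
            scores[:, j] *= -1
    return vectors, scores


def pca_biplot(table: pd.DataFrame, scale: str = "correlation") -> OrdinationResult:
    """PCA of a samples x variables table.

    Correlation-matrix PCA (the default) z-standardizes every variable first,
    appropriate when nutrients (g/kg, mg/kg) and diversity indices share one
    table.  Loadings are eigenvectors scaled by sqrt(eigenvalue), i.e. the
    variable-component correlations under the correlation scaling.
    """
    if scale not in ("correlation", "covariance"):
        raise ValidationError(f"unknown PCA scale {scale!r}")
    num = table.select_dtypes(include=[np.number])
    if num.shape[0] < 3:
        raise ValidationError("PCA needs at least 3 samples")
    if scale == "correlation":
        X, keep, dropped = _standardize(table, "PCA")
    else:
        sd = num.std(ddof=1)
        keep = [c for c in num.columns if sd[c] > 0]
        dropped = [c for c in num.columns if c not in keep]
        if dropped:
            warnings.warn(f"dropping zero-variance PCA variables: {dropped}")
        if not keep:
            raise DegenerateDataError("all PCA variables are constant")
        X = num[keep].to_numpy(dtype=float)
        X = X - X.mean(axis=0)

    n = X.shape[0]
    cov = X.T @ X / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    scores = X @ eigvecs
    eigvecs, scores = _fix_signs(eigvecs, scores)
    explained = eigvals / eigvals.sum()
    comp = [f"PC{i + 1}" for i in range(len(eigvals))]
    loadings = eigvecs * np.sqrt(eigvals)
    index = table.index if table.index.is_unique else pd.RangeIndex(n)
    return OrdinationResult(
        method="pca",
        scores=pd.DataFrame(scores, index=index, columns=comp),
        loadings=pd.DataFrame(loadings, index=keep, columns=comp),
        explained_fraction=explained,
        eigenvalues=eigvals,
        dropped=dropped,
    )


def _drop_collinear(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Greedy rank-preserving column selection via pivoted QR."""
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag[0] * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    keep_idx = sorted(piv[:rank])
    dropped = [names[i] for i in range(len(names)) if i not in keep_idx]
    if dropped:
        warnings.warn(f"dropping collinear predictor columns: {dropped}")
    return X[:, keep_idx], [names[i] for i in keep_idx], dropped


def rda_permutation_test(
    response: pd.DataFrame,
    predictors: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
) -> OrdinationResult:
    """Redundancy analysis with an unrestricted row-permutation test.

    pseudo-F = (SS_constrained / q) / (SS_residual / (n - q - 1)) with q the
    predictor rank; the response rows are permuted ``n_perm`` times and
    p = (1 + #{F* >= F}) / (1 + n_perm).
    """
    if list(response.index) != list(predictors.index):
        if len(response) != len(predictors):
            raise ValidationError("response and predictors must share sample rows")
    Y, y_names, y_dropped = _standardize(response, "response")
    X, x_names, x_dropped = _standardize(predictors, "predictor")
    X, x_names, collinear = _drop_collinear(X, x_names)
    n, q = X.shape
    if n <= q + 1:
        raise ValidationError(
            f"need more samples than predictors + 1 (n={n}, q={q})"
        )

    # hat matrix of the predictor column space
    H = X @ np.linalg.pinv(X.T @ X) @ X.T
    Yhat = H @ Y
    ss_total = float(np.sum(Y**2))
    ss_constrained = float(np.sum(Yhat**2))
    ss_resid = ss_total - ss_constrained

    with np.errstate(divide="ignore"):
        f_obs = (ss_constrained / q) / (ss_resid / (n - q - 1)) if ss_resid > 0 else np.inf

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Yp = Y[perm]
        ss_c = float(np.sum((H @ Yp) ** 2))
        ss_r = ss_total - ss_c
        f_p = (ss_c / q) / (ss_r / (n - q - 1)) if ss_r > 0 else np.inf
        if f_p >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)

    # constrained axes: eigenanalysis of the fitted values
    cov_fit = Yhat.T @ Yhat / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov_fit)
    order = np.argsort(eigvals)[::-1]
    n_axes = min(q, Y.shape[1])
    eigvals = np.clip(eigvals[order][:n_axes], 0.0, None)
    eigvecs = eigvecs[:, order][:, :n_axes]
    scores = Yhat @ eigvecs
    eigvecs, scores = _fix_signs(eigvecs, scores)
    total_var = ss_total / (n - 1)
    comp = [f"RDA{i + 1}" for i in range(n_axes)]
    index = response.index if response.index.is_unique else pd.RangeIndex(n)
    return OrdinationResult(
        method="rda",
        scores=pd.DataFrame(scores, index=index, columns=comp),
        loadings=pd.DataFrame(eigvecs * np.sqrt(eigvals), index=y_names, columns=comp),
        explained_fraction=eigvals / total_var,
        eigenvalues=eigvals,
        dropped=y_dropped + x_dropped + collinear,
        pseudo_f=float(f_obs),
        permutation_p=float(p),
        n_permutations=n_perm,
        seed=seed,
    )


def radar_normalize(treatment_means: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale each variable of a treatment-mean table onto [0, 1].

    A variable whose treatment means are all equal maps to 0.5 everywhere
    (with a warning) so it still draws as a mid-level polygon edge.
    """
    if treatment_means.shape[0] < 2:
        raise ValidationError("radar normalization needs >= 2 treatments")
    num = treatment_means.select_dtypes(include=[np.number])
    out = num.copy().astype(float)
    for c in num.columns:
        lo, hi = num[c].min(), num[c].max()
        if hi == lo:
            warnings.warn(f"variable {c!r}: identical treatment means, set to 0.5")
            out[c] = 0.5
        else:
            out[c] = (num[c] - lo) / (hi - lo)
    return out
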