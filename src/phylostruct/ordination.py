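"""Unconstrained (PCA) and constrained (RDA) ordination.

PCA eigen-decomposes the covariance of the centered (optionally
standardized, optionally Hellinger-transformed) data matrix. RDA first
regresses the standardized responses on the standardized predictors and
eigen-decomposes the covariance of the fitted values; constrained
eigenvalue proportions are reported relative to the total response
variance, and each predictor's correlation with each axis's site scores
gives the factor-axis ("intraset") correlation table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OrdinationResults",
    "PCAOrdination",
    "RDAOrdination",
    "pca",
    "rda",
    "axis_summary",
    "hellinger",
    "cumulative_percentages",
]


def hellinger(matrix: pd.DataFrame) -> pd.DataFrame:
    """Hellinger transform of a sample x species abundance matrix."""
    totals = matrix.sum(axis=1)
    if (totals <= 0).any():
        bad = list(matrix.index[totals <= 0])
        raise ValueError(f"samples with zero total abundance: {bad}")
    return np.sqrt(matrix.div(totals, axis=0))


def cumulative_percentages(proportions) -> np.ndarray:
    """Cumulative percentage series from per-axis variance proportions.

    Accepts proportions (0.44, 0.291, ...) or already-scaled percentages
    (44.0, 29.1, ...); values are summed exactly and rounded to 1 d.p. only
    for display by the callers.
    """
    arr = np.asarray(proportions, dtype=float)
    if arr.max() <= 1.0:
        arr = arr * 100.0
    return np.cumsum(arr)


@dataclass
class OrdinationResults:
    """Eigenvalues, scores and (for RDA) factor-axis correlations."""

    eigenvalues: np.ndarray          # descending, >= 0
    total_variance: float            # denominator for proportions
    site_scores: pd.DataFrame        # sample x axis
    response_scores: pd.DataFrame    # variable x axis loadings
    factor_correlations: pd.DataFrame | None = None  # predictor x axis (RDA)
    method: str = "PCA"

    @property
    def proportions(self) -> np.ndarray:
        return self.eigenvalues / self.total_variance

    @property
    def cumulative(self) -> np.ndarray:
        return cumulative_percentages(self.proportions)

    def summary(self, digits: int = 1) -> pd.DataFrame:
        return axis_summary(self, digits=digits)


def _star(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def axis_summary(result: OrdinationResults, digits: int = 1) -> pd.DataFrame:
    """Per-axis eigenvalue, percentage and cumulative percentage table.

    For RDA results, factor-axis correlations are appended with significance
    stars from the parametric (t-approximation) Pearson correlation test at
    the 0.05 / 0.01 levels.
    """
    axes = [f"AX{k + 1}" for k in range(len(result.eigenvalues))]
    rows = {
        "Eigenvalues": np.round(result.eigenvalues, 4),
        "Percentage variance": np.round(result.proportions * 100.0, digits),
        "Cumulative percentage variance": np.round(result.cumulative, digits),
    }
    out = pd.DataFrame(rows, index=axes).T
    if result.factor_correlations is not None:
        n = result.site_scores.shape[0]
        starred = result.factor_correlations.copy().astype(object)
        for pred in starred.index:
            for ax in starred.columns:
                r = float(result.factor_correlations.loc[pred, ax])
                if np.isnan(r) or abs(r) >= 1.0:
                    p = 0.0 if abs(r) >= 1.0 else 1.0
                else:
                    t = abs(r) * np.sqrt((n - 2) / (1.0 - r * r))
                    p = 2.0 * stats.t.sf(t, df=n - 2)
                starred.loc[pred, ax] = f"{r:.4f}{_star(p)}"
        starred.columns = out.columns[: starred.shape[1]]
        out = pd.concat([starred, out], axis=0)
    return out


class PCAOrdination:
    """Principal component analysis of a sample x variable table.

    Parameters
    ----------
    data : pandas.DataFrame
        Samples as rows, variables as columns.
    scale : bool
        Standardize columns to unit variance (correlation PCA).
    hellinger_transform : bool
        Apply the Hellinger transform first (for raw species abundances).
    """

    def __init__(self, data: pd.DataFrame, scale: bool = False,
                 hellinger_transform: bool = False):
        if data.shape[0] < 2 or data.shape[1] < 2:
            raise ValueError("need at least 2 samples and 2 variables")
        if hellinger_transform:
            data = hellinger(data)
        self.data = data.astype(float)
        self.scale = scale

    def fit(self, n_axes: int | None = None) -> OrdinationResults:
        x = self.data.values - self.data.values.mean(axis=0)
        if self.scale:
            sd = x.std(axis=0, ddof=1)
            if (sd == 0).any():
                bad = list(self.data.columns[sd == 0])
                raise ValueError(f"zero-variance variables: {bad}")
            x = x / sd
        n = x.shape[0]
        cov = x.T @ x / (n - 1)
        total = float(np.trace(cov))
        if total <= 0:
            raise ValueError("zero total variance: constant matrix")
        vals, vecs = np.linalg.eigh(cov)
        order = np.argsort(vals)[::-1]
        vals = np.clip(vals[order], 0.0, None)
        vecs = vecs[:, order]
        rank = min(n - 1, x.shape[1])
        k = rank if n_axes is None else min(n_axes, rank)
        vals, vecs = vals[:k], vecs[:, :k]
        # deterministic sign: largest-magnitude loading positive
        flip = np.sign(vecs[np.abs(vecs).argmax(axis=0), np.arange(k)])
        flip[flip == 0] = 1.0
        vecs = vecs * flip
        axes = [f"AX{j + 1}" for j in range(k)]
        return OrdinationResults(
            eigenvalues=vals,
            total_variance=total,
            site_scores=pd.DataFrame(x @ vecs, index=self.data.index, columns=axes),
            response_scores=pd.DataFrame(vecs, index=self.data.columns, columns=axes),
            method="PCA",
        )


class RDAOrdination:
    """Redundancy analysis: PCA of responses fitted on predictors.

    Both tables are column-standardized (correlation-based RDA) because the
    variables mix units. Collinear predictors are handled by the least-norm
    pseudo-inverse fit.
    """

    def __init__(self, responses: pd.DataFrame, predictors: pd.DataFrame,
                 scale: bool = True):
        responses, predictors = responses.align(predictors, join="inner", axis=0)
        if responses.shape[0] < 3:
            raise ValueError("need at least 3 shared samples")
        n, p = predictors.shape
        if p >= n:
            raise ValueError(
                f"{p} predictors for {n} samples: reduce the predictor set "
                "(need p < n)"
            )
        self.responses = responses.astype(float)
        self.predictors = predictors.astype(float)
        self.scale = scale

    @staticmethod
    def _standardize(df: pd.DataFrame) -> np.ndarray:
        x = df.values - df.values.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = list(df.columns[sd == 0])
            raise ValueError(f"zero-variance columns: {bad}")
        return x / sd

    def fit(self, n_axes: int | None = None) -> OrdinationResults:
        y = self._standardize(self.responses) if self.scale else (
            self.responses.values - self.responses.values.mean(axis=0)
        )
        x = self._standardize(self.predictors) if self.scale else (
            self.predictors.values - self.predictors.values.mean(axis=0)
        )
        n = y.shape[0]
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        fitted = x @ beta
        total = float(np.trace(y.T @ y) / (n - 1))
        cov_fit = fitted.T @ fitted / (n - 1)
        vals, vecs = np.linalg.eigh(cov_fit)
        order = np.argsort(vals)[::-1]
        vals = np.clip(vals[order], 0.0, None)
        vecs = vecs[:, order]
        rank = min(np.linalg.matrix_rank(x), y.shape[1])
        k = rank if n_axes is None else min(n_axes, max(rank, 1))
        vals, vecs = vals[:k], vecs[:, :k]
        flip = np.sign(vecs[np.abs(vecs).argmax(axis=0), np.arange(k)])
        flip[flip == 0] = 1.0
        vecs = vecs * flip
        axes = [f"AX{j + 1}" for j in range(k)]
        site = pd.DataFrame(fitted @ vecs, index=self.responses.index, columns=axes)
        corr = pd.DataFrame(
            np.zeros((x.shape[1], k)), index=self.predictors.columns, columns=axes
        )
        for j, ax in enumerate(axes):
            s = site[ax].values
            s_sd = s.std(ddof=1)
            for i, pred in enumerate(self.predictors.columns):
                if s_sd == 0:
                    corr.loc[pred, ax] = np.nan
                else:
                    corr.loc[pred, ax] = float(np.corrcoef(x[:, i], s)[0, 1])
        return OrdinationResults(
            eigenvalues=vals,
            total_variance=total,
            site_scores=site,
            response_scores=pd.DataFrame(
                vecs, index=self.responses.columns, columns=axes
            ),
            factor_correlations=corr,
            method="RDA",
        )


def pca(data: pd.DataFrame, n_axes: int | None = None, scale: bool = False,
        hellinger_transform: bool = False) -> OrdinationResults:
    """Functional wrapper over :class:`PCAOrdination`."""
    return PCAOrdination(data, scale=scale,
                         hellinger_transform=hellinger_transform).fit(n_axes)


def rda(responses: pd.DataFrame, predictors: pd.DataFrame,
        n_axes: int | None = None, scale: bool = True) -> OrdinationResults:
    """Functional wrapper over :class:`RDAOrdination`."""
    return RDAOrdination(responses, predictors, scale=scale).fit(n_axes)
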