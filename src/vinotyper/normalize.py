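"""Intensity normalization.

Two optional, sequential steps, both per array:

* Within-array covariate correction — cubic-spline fits (5 df by
  default) of log2 intensity against probe C+G content and against the
  NspI and StyI restriction-fragment lengths; the centered fitted
  effects are subtracted so the array's overall log2 mean is preserved,
  then intensities are exponentiated back to the linear scale.
* Quantile normalization against a pre-computed reference distribution
  (element-wise mean of sorted per-array vectors), applied to each
  array independently.  Tied input values receive the mean of the
  reference values at their shared ranks.

Quantile normalization assumes all samples share one intensity
distribution; for taxonomically diverse sample sets it should be
skipped, and both steps are individually optional.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

__all__ = [
    "SplineModel",
    "fit_covariate_spline",
    "apply_within_array_normalization",
    "ReferenceQuantiles",
    "build_reference_distribution",
    "quantile_normalize_to_reference",
    "QuantileNormalizer",
    "CovariateCorrector",
    "normalize_intensity_table",
]

DEFAULT_SPLINE_DF = 5
SPLINE_DEGREE = 3


@dataclass
class SplineModel:
    """A fitted cubic smooth of log2 intensity against one probe covariate."""

    covariate_name: str
    df: int
    knots: np.ndarray  # full knot vector (empty for df=0)
    coefficients: np.ndarray  # intercept first
    x_range: tuple[float, float]

    def predict(self, x) -> np.ndarray:
        """Evaluate the fitted mean curve; inputs are clamped to the fitted range."""
        x = np.clip(np.asarray(x, dtype=float), *self.x_range)
        if self.df == 0:
            return np.full(x.shape, self.coefficients[0])
        basis = BSpline.design_matrix(x, self.knots, SPLINE_DEGREE).toarray()
        return self.coefficients[0] + basis @ self.coefficients[1:]


def fit_covariate_spline(log2_intensities, covariate, df: int = DEFAULT_SPLINE_DF) -> SplineModel:
    """Least-squares cubic B-spline fit of log2 intensity on a covariate.

    ``df`` is the basis dimension beyond the intercept (df - 3 internal
    knots at covariate quantiles); df=0 fits the global mean only.
    Needs at least df + 2 distinct covariate values.
    """
    y = np.asarray(log2_intensities, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if y.shape != x.shape:
        raise ValueError("intensities and covariate must align")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    distinct = np.unique(x)
    name = getattr(covariate, "name", "covariate")
    if df == 0 or distinct.size == 1:
        if df > 0:
            raise ValueError(f"{name}: need >= {df + 2} distinct covariate values, got {distinct.size}")
        return SplineModel(name, 0, np.array([]), np.array([y.mean()]), (x.min(), x.max()))
    if distinct.size < df + 2:
        raise ValueError(f"{name}: need >= {df + 2} distinct covariate values, got {distinct.size}")
    n_internal = df - SPLINE_DEGREE
    internal = np.quantile(distinct, np.linspace(0, 1, n_internal + 2)[1:-1]) if n_internal > 0 else np.array([])
    lo, hi = distinct.min(), distinct.max()
    knots = np.concatenate([[lo] * (SPLINE_DEGREE + 1), internal, [hi] * (SPLINE_DEGREE + 1)])
    basis = BSpline.design_matrix(x, knots, SPLINE_DEGREE).toarray()
    design = np.column_stack([np.ones(len(x)), basis])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return SplineModel(name, df, knots, coef, (lo, hi))


def apply_within_array_normalization(intensities, covariates: pd.DataFrame, models: list[SplineModel]):
    """Subtract centered fitted covariate effects on the log2 scale.

    ``intensities`` are one array's linear values aligned with the rows
    of ``covariates`` (one column per model's covariate).  For each
    model the fitted effect, centered over probes with that covariate,
    is removed; probes missing a covariate pass through uncorrected and
    are counted in a warning.  The array's mean log2 intensity is
    preserved to numerical precision.
    """
    y = np.log2(np.asarray(intensities, dtype=float))
    corrected = y.copy()
    n_missing = 0
    for model in models:
        if model.covariate_name not in covariates.columns:
            raise ValueError(f"covariate {model.covariate_name!r} not provided")
        x = covariates[model.covariate_name].to_numpy(dtype=float)
        ok = np.isfinite(x)
        n_missing += int((~ok).sum())
        effect = model.predict(x[ok])
        corrected[ok] -= effect - effect.mean()
    if n_missing:
        warnings.warn(f"{n_missing} probe/covariate value(s) missing; passed through uncorrected")
    return 2.0**corrected


@dataclass
class ReferenceQuantiles:
    """Sorted target distribution for single-array quantile normalization."""

    values: np.ndarray
    source: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.values) < 0):
            raise ValueError("reference quantiles must be non-decreasing")

    def to_tsv(self, path):
        pd.Series(self.values, name="reference").to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, source=""):
        return cls(pd.read_csv(path, sep="\t")["reference"].to_numpy(), source or str(path))


def build_reference_distribution(arrays, source: str = "") -> ReferenceQuantiles:
    """Element-wise mean of the sorted per-array intensity vectors."""
    cols = [np.sort(np.asarray(a, dtype=float)) for a in arrays]
    if not cols:
        raise ValueError("need at least one array")
    n = len(cols[0])
    if any(len(c) != n for c in cols):
        raise ValueError("arrays must have equal probe counts")
    return ReferenceQuantiles(np.mean(cols, axis=0), source)


def quantile_normalize_to_reference(array, reference: ReferenceQuantiles):
    """Map one array onto the reference distribution, rank for rank.

    The multiset of outputs equals the reference values exactly except
    at ties, where tied inputs share the mean of the reference values
    at their ranks; input rank order is preserved.
    """
    x = np.asarray(array, dtype=float)
    ref = reference.values
    if x.size != ref.size:
        raise ValueError(f"array length {x.size} != reference length {ref.size}")
    order = np.argsort(x, kind="stable")
    out = np.empty_like(x)
    xs = x[order]
    i = 0
    while i < len(xs):
        j = i
        while j + 1 < len(xs) and xs[j + 1] == xs[i]:
            j += 1
        out[order[i : j + 1]] = ref[i : j + 1].mean()
        i = j + 1
    return out


class QuantileNormalizer:
    """Transformer: learn a reference distribution, normalize arrays to it.

    ``fit`` takes a probes x arrays matrix (or uses a pre-built
    :class:`ReferenceQuantiles`); ``transform`` maps each column of its
    input onto the reference, independently.
    """

    def __init__(self, reference: ReferenceQuantiles | None = None):
        self.reference = reference

    def get_params(self, deep=True):
        return {"reference": self.reference}

    def set_params(self, **kwargs):
        for k, v in kwargs.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        if self.reference is not None:
            self.reference_quantiles_ = self.reference
        else:
            X = np.asarray(X, dtype=float)
            self.reference_quantiles_ = build_reference_distribution([X[:, j] for j in range(X.shape[1])])
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        one_dim = X.ndim == 1
        if one_dim:
            X = X[:, None]
        out = np.column_stack(
            [quantile_normalize_to_reference(X[:, j], self.reference_quantiles_) for j in range(X.shape[1])]
        )
        return out[:, 0] if one_dim else out

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


class CovariateCorrector:
    """Transformer removing smooth covariate trends, fitted per array.

    Because the correction is within-array, ``transform`` refits the
    splines on each column it is given; ``fit`` only records the
    covariate frame and settings.
    """

    def __init__(self, covariates=("cg_content", "nsp_fragment", "sty_fragment"), df: int = DEFAULT_SPLINE_DF):
        self.covariates = covariates
        self.df = df

    def get_params(self, deep=True):
        return {"covariates": self.covariates, "df": self.df}

    def set_params(self, **kwargs):
        for k, v in kwargs.items():
            setattr(self, k, v)
        return self

    def fit(self, X, covariate_frame: pd.DataFrame = None, y=None):
        if covariate_frame is None:
            raise ValueError("covariate_frame is required")
        self.covariate_frame_ = covariate_frame
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        one_dim = X.ndim == 1
        if one_dim:
            X = X[:, None]
        out = np.empty_like(X)
        for j in range(X.shape[1]):
            y = np.log2(X[:, j])
            models = []
            # sequential fits: C+G first, fragment lengths on the residual trend
            resid = y.copy()
            for name in self.covariates:
                if name not in self.covariate_frame_.columns:
                    continue
                x = self.covariate_frame_[name]
                model = fit_covariate_spline(resid, x, self.df)
                ok = np.isfinite(x.to_numpy(dtype=float))
                effect = model.predict(x.to_numpy(dtype=float)[ok])
                resid[ok] -= effect - effect.mean()
                models.append(model)
            out[:, j] = 2.0**resid
        self.models_ = models  # models of the last array, for inspection
        return out[:, 0] if one_dim else out

    def fit_transform(self, X, covariate_frame=None, y=None):
        return self.fit(X, covariate_frame).transform(X)


def apply_correction_log2(log2_values, covariates, models):
    """log2-scale core of :func:`apply_within_array_normalization`."""
    corrected = np.asarray(log2_values, dtype=float).copy()
    for model in models:
        x = covariates[model.covariate_name].to_numpy(dtype=float)
        ok = np.isfinite(x)
        effect = model.predict(x[ok])
        corrected[ok] -= effect - effect.mean()
    return corrected


def normalize_intensity_table(table, probe_table=None, correct_covariates=True, quantile=False, reference=None):
    """Default pipeline over an IntensityTable: covariate correction, then
    optional quantile normalization against a reference.

    Probe-level covariates are broadcast to the table's
    (probe, strand, allele) rows.  Returns a new IntensityTable.
    """
    from .io import IntensityTable

    values = table.values.copy()
    X = values.to_numpy(dtype=float)
    if correct_covariates:
        if probe_table is None:
            raise ValueError("probe_table required for covariate correction")
        cov = probe_table.reindex(values.index.get_level_values(0))
        cov.index = values.index
        corrector = CovariateCorrector()
        X = corrector.fit_transform(X, cov)
    if quantile:
        qn = QuantileNormalizer(reference=reference)
        if reference is None:
            qn.fit(X)
        else:
            qn.fit(None)
        X = qn.transform(X)
    return IntensityTable(pd.DataFrame(X, index=values.index, columns=values.columns))
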