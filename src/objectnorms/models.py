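"""Item-wise memorability modeling.

Estimators in scikit-learn style:

* :class:`PredictorNormalizer` — distribution-correcting transformer: columns
  whose absolute skew exceeds a threshold get a log10 transform (with an
  offset when non-positive values are present); designated circular/bounded
  columns (hue, saturation, value by default) get a maximum-likelihood
  Box-Cox transform instead.
* :class:`MemorabilityRegression` — OLS with intercept on an item x predictor
  table, reporting unstandardized betas, SEs, t = beta/SE, p, adjusted R2 and
  per-predictor variance inflation factors (VIF).
* :class:`MediationAnalysis` — single-mediator path analysis with a seeded
  percentile bootstrap over items: a (m ~ x), b and c' (y ~ x + m),
  c (y ~ x), indirect effect ab = a*b, proportion mediated ab/c.

Missing rows are removed listwise per model (counts exposed on the fitted
estimator). p-values are descriptive; no multiple-testing correction is
applied by default (a Bonferroni/FDR switch exists on the regression).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

DEFAULT_BOXCOX_COLUMNS = ("hue", "saturation", "value")


# ---------------------------------------------------------------------------
# predictor normalization


@dataclass(frozen=True)
class TransformSpec:
    """Reproducible record of the transform applied to one predictor."""

    name: str
    transform: str  # none | log10 | boxcox
    lam: float | None = None
    offset: float = 0.0


class PredictorNormalizer(TransformerMixin, BaseEstimator):
    """Skew-driven normalization of a predictor table.

    Parameters
    ----------
    skew_threshold : float, default 1.0
        Columns with |sample skew| above this get a log10 transform.
    boxcox_columns : sequence of str or None
        Columns transformed with maximum-likelihood Box-Cox regardless of
        skew (default: hue, saturation, value). Offsets are applied and
        recorded when a column contains non-positive values.

    Attributes
    ----------
    transforms_ : dict of column name -> :class:`TransformSpec`
    """

    def __init__(self, skew_threshold: float = 1.0, boxcox_columns=DEFAULT_BOXCOX_COLUMNS):
        self.skew_threshold = skew_threshold
        self.boxcox_columns = boxcox_columns

    def fit(self, X: pd.DataFrame, y=None):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X))
        boxcox_cols = set(self.boxcox_columns or ())
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.transforms_ = {}
        for col in X.columns:
            x = X[col].dropna().to_numpy(dtype=float)
            if x.size == 0:
                self.transforms_[col] = TransformSpec(col, "none")
                continue
            if col in boxcox_cols:
                offset = self._offset(x)
                with np.errstate(all="ignore"):
                    _, lam = stats.boxcox(x + offset)
                self.transforms_[col] = TransformSpec(col, "boxcox", lam=float(lam), offset=offset)
            elif abs(stats.skew(x)) > self.skew_threshold:
                offset = self._offset(x)
                self.transforms_[col] = TransformSpec(col, "log10", offset=offset)
            else:
                self.transforms_[col] = TransformSpec(col, "none")
        return self

    @staticmethod
    def _offset(x: np.ndarray) -> float:
        """Offset making a column strictly positive: smallest positive value
        added beyond the minimum, 1.0 when everything is non-positive."""
        mn = x.min()
        if mn > 0:
            return 0.0
        pos = x[x > 0]
        bump = pos.min() if pos.size else 1.0
        return float(-mn + bump)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "transforms_")
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X), columns=self.feature_names_in_)
        out = X.copy().astype(float)
        for col, spec in self.transforms_.items():
            if col not in out.columns or spec.transform == "none":
                continue
            vals = out[col].to_numpy(dtype=float) + spec.offset
            if spec.transform == "log10":
                out[col] = np.log10(vals)
            elif spec.transform == "boxcox":
                lam = spec.lam
                out[col] = (vals**lam - 1) / lam if lam != 0 else np.log(vals)
        return out


def normalize_predictors(
    raw: pd.DataFrame,
    specs: dict[str, TransformSpec] | None = None,
    skew_threshold: float = 1.0,
    boxcox_columns=DEFAULT_BOXCOX_COLUMNS,
) -> tuple[pd.DataFrame, dict[str, TransformSpec]]:
    """Functional wrapper over :class:`PredictorNormalizer`.

    With ``specs`` given, re-applies previously fitted transforms instead of
    re-estimating them.
    """
    norm = PredictorNormalizer(skew_threshold=skew_threshold, boxcox_columns=boxcox_columns)
    if specs is None:
        out = norm.fit(raw).transform(raw)
        return out, dict(norm.transforms_)
    norm.transforms_ = dict(specs)
    norm.feature_names_in_ = np.asarray(raw.columns, dtype=object)
    return norm.transform(raw), dict(specs)


# ---------------------------------------------------------------------------
# OLS memorability regression


class CollinearityError(ValueError):
    """Raised when the predictor matrix is rank deficient."""


def _dependent_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns whose removal restores full rank (via QR pivot diagnostics)."""
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    return [names[i] for i in np.flatnonzero(diag <= tol)]


class MemorabilityRegression(RegressorMixin, BaseEstimator):
    """OLS with intercept over an item x predictor table.

    Parameters
    ----------
    standardize : bool, default False
        Report standardized coefficients (z-scored X and y) instead of
        unstandardized betas. t-statistics are unchanged by centering or
        scaling; the default matches unstandardized-beta reporting.
    p_adjust : None, "bonferroni" or "fdr_bh"
        Optional multiplicity correction of predictor p-values (off by
        default; reported p-values are descriptive).

    Attributes (after fit)
    ----------------------
    params_, se_, tvalues_, pvalues_ : Series indexed by predictor (+ const)
    adj_r2_, r2_ : float
    vif_ : Series of variance inflation factors
    n_ : int, rows used after listwise deletion (``n_dropped_`` removed)
    """

    def __init__(self, standardize: bool = False, p_adjust: str | None = None):
        self.standardize = standardize
        self.p_adjust = p_adjust

    def fit(self, X: pd.DataFrame, y):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        y = pd.Series(np.asarray(y, dtype=float), index=X.index, name="y")
        mask = X.notna().all(axis=1) & y.notna()
        Xc, yc = X.loc[mask].astype(float), y.loc[mask]
        self.n_dropped_ = int((~mask).sum())
        self.n_ = int(mask.sum())
        n, p = Xc.shape
        if n <= p + 1:
            raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
        names = list(map(str, Xc.columns))
        design = np.column_stack([np.ones(n), Xc.to_numpy()])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            bad = _dependent_columns(design, ["const"] + names)
            raise CollinearityError(f"rank-deficient predictors: {bad}")

        if self.standardize:
            Xs = (Xc - Xc.mean()) / Xc.std(ddof=1)
            ys = (yc - yc.mean()) / yc.std(ddof=1)
        else:
            Xs, ys = Xc, yc
        exog = sm.add_constant(Xs.to_numpy())
        res = sm.OLS(ys.to_numpy(), exog).fit()
        idx = pd.Index(["const"] + names)
        self.feature_names_in_ = np.asarray(Xc.columns, dtype=object)
        self.results_ = res
        self.params_ = pd.Series(res.params, index=idx)
        self.se_ = pd.Series(res.bse, index=idx)
        self.tvalues_ = pd.Series(res.tvalues, index=idx)
        pv = pd.Series(res.pvalues, index=idx)
        if self.p_adjust:
            pv.loc[names] = multipletests(pv.loc[names].to_numpy(), method=self.p_adjust)[1]
        self.pvalues_ = pv
        self.r2_ = float(res.rsquared)
        self.adj_r2_ = float(res.rsquared_adj)
        self.vif_ = compute_vif(Xc)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "params_")
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float), columns=self.feature_names_in_)
        X = X[list(self.feature_names_in_)]
        beta = self.params_
        return beta["const"] + X.to_numpy() @ beta.drop("const").to_numpy()

    def summary_frame(self) -> pd.DataFrame:
        """Per-predictor t, beta, SE, p, VIF in report layout."""
        check_is_fitted(self, "params_")
        rows = self.params_.index.drop("const")
        return pd.DataFrame(
            {
                "t": self.tvalues_.loc[rows],
                "beta": self.params_.loc[rows],
                "se": self.se_.loc[rows],
                "p": self.pvalues_.loc[rows],
                "VIF": self.vif_.reindex(rows),
            }
        )


def fit_memorability_model(X: pd.DataFrame, y, **kwargs) -> MemorabilityRegression:
    """Fit and return a :class:`MemorabilityRegression`."""
    return MemorabilityRegression(**kwargs).fit(X, y)


def compute_vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factors, VIF_j = 1 / (1 - R2_j).

    R2_j is from regressing predictor j on the remaining predictors (with
    intercept). Perfect collinearity yields +inf. The mean VIF is available
    as ``result.attrs['mean_vif']``.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
    X = X.dropna().astype(float)
    names = list(X.columns)
    arr = X.to_numpy()
    out = []
    for j in range(arr.shape[1]):
        others = np.delete(arr, j, axis=1)
        exog = np.column_stack([np.ones(len(arr)), others])
        r2 = sm.OLS(arr[:, j], exog).fit().rsquared if others.shape[1] else 0.0
        out.append(np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2))
    vif = pd.Series(out, index=names, name="VIF")
    finite = [v for v in out if np.isfinite(v)]
    vif.attrs["mean_vif"] = float(np.mean(finite)) if finite else np.nan
    return vif


# ---------------------------------------------------------------------------
# cross-test correlation


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float


def correlate_tests(
    scores_a: pd.Series, scores_b: pd.Series
) -> CorrelationResult:
    """Pearson correlation between two item-aligned score vectors.

    Items missing in either vector are dropped pairwise; zero variance in
    either vector is an error (the correlation is undefined).
    """
    a, b = scores_a.align(scores_b, join="inner")
    mask = a.notna() & b.notna()
    a, b = a[mask], b[mask]
    if len(a) < 3:
        raise ValueError("need >= 3 paired items")
    if a.std(ddof=0) == 0 or b.std(ddof=0) == 0:
        raise ValueError("correlation undefined for zero-variance scores")
    r, p = stats.pearsonr(a.to_numpy(), b.to_numpy())
    return CorrelationResult(r=float(r), n=int(len(a)), p=float(p))


# ---------------------------------------------------------------------------
# mediation


@dataclass
class MediationResult:
    """Single-mediator path estimates with a percentile bootstrap CI on ab."""

    a: float
    b: float
    c: float
    c_prime: float
    ab: float
    prop_mediated: float  # ab / c, NaN when c ~ 0
    r2: float  # of the y ~ x + m model
    ci_low: float
    ci_high: float
    reps: int
    seed: int
    ci_level: float = 0.95
    boot_ab: np.ndarray | None = field(default=None, repr=False)


def _paths(x: np.ndarray, m: np.ndarray, y: np.ndarray):
    """Closed-form OLS path coefficients (a, b, c, c')."""
    sxx = x.var()
    sxm = ((x - x.mean()) * (m - m.mean())).mean()
    smm = m.var()
    sxy = ((x - x.mean()) * (y - y.mean())).mean()
    smy = ((m - m.mean()) * (y - y.mean())).mean()
    a = sxm / sxx
    det = sxx * smm - sxm**2
    if det <= 1e-12 * sxx * smm:
        raise ValueError(
            "mediator is (near-)collinear with the predictor; the direct and "
            "indirect paths are not identifiable"
        )
    c_prime = (smm * sxy - sxm * smy) / det
    b = (sxx * smy - sxm * sxy) / det
    c = sxy / sxx
    return a, b, c, c_prime


class MediationAnalysis(BaseEstimator):
    """Percentile-bootstrap mediation of y on x through mediator m.

    ``fit(x, m, y)`` estimates a (m ~ x), b and c' (y ~ x + m), the total
    effect c (y ~ x), indirect effect ab, and the proportion mediated ab/c;
    the bootstrap resamples items with a fixed seed so the CI is
    bit-reproducible. c = c' + ab holds exactly for OLS path estimates on the
    same sample.
    """

    def __init__(self, reps: int = 5000, seed: int = 0, ci_level: float = 0.95):
        self.reps = reps
        self.seed = seed
        self.ci_level = ci_level

    def fit(self, x, m, y):
        if self.reps < 1000:
            raise ValueError("reps must be >= 1000 for a stable percentile CI")
        x, m, y = (np.asarray(v, dtype=float).ravel() for v in (x, m, y))
        if not (len(x) == len(m) == len(y)):
            raise ValueError("x, m, y must be item-aligned")
        mask = np.isfinite(x) & np.isfinite(m) & np.isfinite(y)
        x, m, y = x[mask], m[mask], y[mask]
        n = len(x)
        if n < 10:
            raise ValueError("too few complete items for mediation")

        a, b, c, c_prime = _paths(x, m, y)
        self.a_, self.b_, self.c_, self.c_prime_ = a, b, c, c_prime
        self.ab_ = a * b
        scale = max(abs(c_prime), abs(a * b), 1.0)
        self.prop_mediated_ = (a * b) / c if abs(c) > 1e-12 * scale else np.nan
        # R2 of the outcome model y ~ x + m
        resid = y - y.mean() - c_prime * (x - x.mean()) - b * (m - m.mean())
        self.r2_ = 1.0 - resid.var() / y.var()

        rng = np.random.default_rng(self.seed)
        boot = np.empty(self.reps)
        chunk = max(1, int(2e6 // n))
        done = 0
        while done < self.reps:
            k = min(chunk, self.reps - done)
            idx = rng.integers(0, n, size=(k, n))
            xb, mb, yb = x[idx], m[idx], y[idx]
            xc = xb - xb.mean(axis=1, keepdims=True)
            mc = mb - mb.mean(axis=1, keepdims=True)
            yc = yb - yb.mean(axis=1, keepdims=True)
            sxx = (xc * xc).mean(axis=1)
            sxm = (xc * mc).mean(axis=1)
            smm = (mc * mc).mean(axis=1)
            smy = (mc * yc).mean(axis=1)
            sxy = (xc * yc).mean(axis=1)
            a_b = sxm / sxx
            det = sxx * smm - sxm**2
            b_b = (sxx * smy - sxm * sxy) / det
            boot[done : done + k] = a_b * b_b
            done += k
        alpha = (1.0 - self.ci_level) / 2
        self.ci_ = (
            float(np.quantile(boot, alpha)),
            float(np.quantile(boot, 1 - alpha)),
        )
        self.boot_ab_ = boot
        self.n_ = n
        return self

    def result(self) -> MediationResult:
        check_is_fitted(self, "ab_")
        return MediationResult(
            a=self.a_, b=self.b_, c=self.c_, c_prime=self.c_prime_,
            ab=self.ab_, prop_mediated=self.prop_mediated_, r2=self.r2_,
            ci_low=self.ci_[0], ci_high=self.ci_[1],
            reps=self.reps, seed=self.seed, ci_level=self.ci_level,
            boot_ab=self.boot_ab_,
        )


def mediate(x, y, m, reps: int = 5000, seed: int = 0) -> MediationResult:
    """Functional wrapper: mediation of the x -> y relation through m."""
    return MediationAnalysis(reps=reps, seed=seed).fit(x, m, y).result()


def mediation_table(results: dict[str, MediationResult]) -> pd.DataFrame:
    """Mediator-per-row report (a, b, c', ab, R2, CI) layout."""
    rows = {
        name: {
            "a": r.a, "b": r.b, "c_prime": r.c_prime, "ab": r.ab,
            "R2": r.r2, "ci_low": r.ci_low, "ci_high": r.ci_high,
            "prop_mediated": r.prop_mediated,
        }
        for name, r in results.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def regression_table(models: dict[str, MemorabilityRegression]) -> pd.DataFrame:
    """Wide report: one (t, beta) column pair per fitted outcome."""
    frames = {}
    for outcome, model in models.items():
        sf = model.summary_frame()
        frames[outcome] = sf[["t", "beta"]]
    return pd.concat(frames, axis=1)
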