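"""Regularized maximum-entropy presence/background modelling.

The model is the Gibbs distribution over the background catchments,

    q_lambda(i) = exp(lambda . f_i) / Z(lambda),   Z = sum_background exp(lambda . f_i),

where f_i is a vector of feature transforms of catchment i's covariates.
Fitting maximizes the presence log-likelihood penalized by a weighted L1
norm,

    max_lambda  mean_presence[lambda . f] - log Z(lambda) - sum_j beta_j |lambda_j|,

with per-feature penalties beta_j = beta_multiplier * s_j / sqrt(n_presence),
s_j the feature's standard deviation over the background.  The objective is
convex; at the optimum the Karush-Kuhn-Tucker conditions pin every feature's
presence/background expectation gap inside [-beta_j, +beta_j], which is the
certificate :func:`fit_maxent` reports.  Larger multipliers shrink more
coefficients exactly to zero.

Feature classes follow the standard taxonomy: linear, quadratic, pairwise
product, forward/reverse hinge and step (threshold) at background-quantile
knots, and categorical indicators for binary covariates.  All features are
computed on covariates min-max rescaled to [0,1] over the background, and
prediction clamps to that range to avoid extrapolation artifacts.

Optimization is proximal gradient (FISTA with backtracking line search and
adaptive restart) on the convex penalized objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FitError, InvalidConfigError, NotFittedError

ALL_CLASSES = ("linear", "quadratic", "product", "hinge", "threshold", "categorical")


@dataclass(frozen=True)
class FeatureDef:
    """One feature: a named transform of one or two covariates."""

    kind: str
    covariate: str
    covariate2: str | None = None  # product features only
    knot: float | None = None  # hinge/threshold, in scaled [0,1] units
    level: float | None = None  # categorical

    @property
    def name(self) -> str:
        if self.kind == "product":
            return f"product({self.covariate},{self.covariate2})"
        if self.kind in ("hinge", "reverse_hinge", "threshold"):
            return f"{self.kind}({self.covariate}@{self.knot:.4f})"
        if self.kind == "categorical":
            return f"categorical({self.covariate}=={self.level:g})"
        return f"{self.kind}({self.covariate})"


@dataclass
class FeatureSet:
    """Feature definitions plus the background scaling constants."""

    features: list[FeatureDef]
    cov_min: dict[str, float]
    cov_max: dict[str, float]
    classes: tuple[str, ...]
    n_knots: int
    skipped_covariates: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.features)

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def _scaled(self, covariates: pd.DataFrame, clamp: bool) -> dict[str, np.ndarray]:
        out = {}
        for name in {f.covariate for f in self.features} | {
            f.covariate2 for f in self.features if f.covariate2
        }:
            x = covariates[name].to_numpy(dtype=float)
            lo, hi = self.cov_min[name], self.cov_max[name]
            if hi > lo:
                z = (x - lo) / (hi - lo)
            else:
                z = x  # binary covariates pass through
            if clamp:
                z = np.clip(z, 0.0, 1.0)
            out[name] = z
        return out

    def transform(self, covariates: pd.DataFrame, clamp: bool = True) -> np.ndarray:
        """Design matrix (rows = rows of ``covariates``, cols = features)."""
        scaled = self._scaled(covariates, clamp)
        cols = np.empty((len(covariates), len(self.features)))
        for j, f in enumerate(self.features):
            z = scaled[f.covariate]
            if f.kind == "linear":
                cols[:, j] = z
            elif f.kind == "quadratic":
                cols[:, j] = z**2
            elif f.kind == "product":
                cols[:, j] = z * scaled[f.covariate2]
            elif f.kind == "hinge":
                cols[:, j] = np.maximum(0.0, z - f.knot) / (1.0 - f.knot)
            elif f.kind == "reverse_hinge":
                cols[:, j] = np.maximum(0.0, f.knot - z) / f.knot
            elif f.kind == "threshold":
                cols[:, j] = (z > f.knot).astype(float)
            elif f.kind == "categorical":
                cols[:, j] = (covariates[f.covariate].to_numpy(dtype=float) == f.level).astype(float)
            else:  # pragma: no cover - guarded at construction
                raise InvalidConfigError(f"unknown feature kind {f.kind!r}")
        return cols


def expand_features(
    covariates: pd.DataFrame,
    background_ids: Sequence,
    kinds: dict[str, str],
    classes: Iterable[str] = ALL_CLASSES,
    n_knots: int = 10,
) -> FeatureSet:
    """Build the feature basis from background statistics.

    ``covariates`` is indexed by catchment id (one column per retained
    covariate); scaling min/max and hinge/threshold knots come from the
    background rows only.  Knots sit at ``n_knots`` evenly spaced background
    quantiles strictly inside (0,1) of the scaled range.  Covariates constant
    over the background contribute no features and are recorded in
    ``skipped_covariates``.  Binary covariates get categorical indicators
    only.
    """
    classes = tuple(classes)
    unknown = set(classes) - set(ALL_CLASSES)
    if unknown:
        raise InvalidConfigError(f"unknown feature classes: {sorted(unknown)}")
    if len(background_ids) == 0:
        raise DataError("background is empty")
    bg = covariates.loc[list(background_ids)]
    features: list[FeatureDef] = []
    skipped: list[str] = []
    cov_min: dict[str, float] = {}
    cov_max: dict[str, float] = {}
    continuous: list[str] = []
    for name in covariates.columns:
        x = bg[name].to_numpy(dtype=float)
        lo, hi = float(x.min()), float(x.max())
        if hi == lo:
            skipped.append(name)
            continue
        if kinds.get(name, "continuous") == "binary":
            cov_min[name], cov_max[name] = 0.0, 1.0
            if "categorical" in classes:
                for level in (0.0, 1.0):
                    features.append(FeatureDef("categorical", name, level=level))
            continue
        cov_min[name], cov_max[name] = lo, hi
        continuous.append(name)
        z = (x - lo) / (hi - lo)
        if "linear" in classes:
            features.append(FeatureDef("linear", name))
        if "quadratic" in classes:
            features.append(FeatureDef("quadratic", name))
        if "hinge" in classes or "threshold" in classes:
            qs = np.quantile(z, np.arange(1, n_knots + 1) / (n_knots + 1))
            knots = sorted({float(k) for k in qs if 0.0 < k < 1.0})
            for k in knots:
                if "hinge" in classes:
                    features.append(FeatureDef("hinge", name, knot=k))
                    features.append(FeatureDef("reverse_hinge", name, knot=k))
                if "threshold" in classes:
                    features.append(FeatureDef("threshold", name, knot=k))
    if "product" in classes:
        for i, a in enumerate(continuous):
            for b in continuous[i + 1 :]:
                features.append(FeatureDef("product", a, covariate2=b))
    return FeatureSet(
        features=features,
        cov_min=cov_min,
        cov_max=cov_max,
        classes=classes,
        n_knots=n_knots,
        skipped_covariates=skipped,
    )


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    """Fitted coefficients and the quantities needed for prediction."""

    lam: np.ndarray
    log_normalizer: float
    entropy: float
    beta_j: np.ndarray
    objective: float
    kkt_slack: float
    n_iter: int
    converged: bool


def _soft_threshold(v: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


def _log_partition(a: np.ndarray) -> float:
    amax = float(a.max())
    return amax + float(np.log(np.sum(np.exp(a - amax))))


def penalized_objective(
    lam: np.ndarray,
    presence_features: np.ndarray,
    background_features: np.ndarray,
    beta_j: np.ndarray,
) -> float:
    """Negative penalized mean presence log-likelihood (to be minimized)."""
    logz = _log_partition(background_features @ lam)
    return (
        logz
        - float(presence_features.mean(axis=0) @ lam)
        + float(beta_j @ np.abs(lam))
    )


def fit_maxent(
    presence_features: np.ndarray,
    background_features: np.ndarray,
    beta_multiplier: float = 1.0,
    lam0: np.ndarray | None = None,
    kkt_tol: float = 5e-5,
    obj_tol: float = 1e-9,
    max_iter: int = 20_000,
) -> FitResult:
    """Fit the penalized Gibbs model by FISTA with backtracking.

    Convergence requires both a small objective change and the KKT
    certificate ``max_j (|E_pres f_j - E_q f_j| - beta_j) <= kkt_tol``.
    """
    fp = np.asarray(presence_features, dtype=float)
    fb = np.asarray(background_features, dtype=float)
    if fp.ndim != 2 or fb.ndim != 2:
        raise DataError("feature matrices must be 2-D")
    if fp.shape[0] < 1:
        raise FitError("at least one presence is required")
    if fb.shape[0] < 2:
        raise FitError("at least two background points are required")
    if not (np.isfinite(fp).all() and np.isfinite(fb).all()):
        raise DataError("features contain non-finite values")
    if beta_multiplier < 0:
        raise InvalidConfigError("beta_multiplier must be nonnegative")
    n_pres, m = fp.shape
    p_mean = fp.mean(axis=0)
    s = fb.std(axis=0)
    beta_j = beta_multiplier * s / np.sqrt(n_pres)

    def smooth(lam: np.ndarray):
        a = fb @ lam
        amax = a.max()
        w = np.exp(a - amax)
        z = w.sum()
        q = w / z
        logz = amax + np.log(z)
        val = logz - lam @ p_mean
        return float(val), q

    def grad_from_q(q: np.ndarray) -> np.ndarray:
        return q @ fb - p_mean

    lam = np.zeros(m) if lam0 is None else np.asarray(lam0, dtype=float).copy()
    y = lam.copy()
    t = 1.0
    step = 1.0
    f_y, q_y = smooth(y)
    g_y = grad_from_q(q_y)
    obj = penalized_objective(lam, fp, fb, beta_j)
    converged = False
    kkt = np.inf
    it = 0
    diverged = False
    for it in range(1, max_iter + 1):
        # backtracking on the smooth part
        while True:
            cand = _soft_threshold(y - step * g_y, step * beta_j)
            d = cand - y
            f_cand, q_cand = smooth(cand)
            if np.isfinite(f_cand) and f_cand <= f_y + g_y @ d + 0.5 / step * (d @ d) + 1e-14:
                break
            step *= 0.5
            if step < 1e-14:
                raise FitError("line search failed; features may be ill-scaled")
        if np.abs(cand).max() > 1e8:
            # unbounded descent direction (presence mean outside the
            # background feature hull with a penalty too small to stop it)
            lam = cand
            diverged = True
            break
        new_obj = f_cand + float(beta_j @ np.abs(cand))
        if new_obj > obj + 1e-12:  # adaptive restart
            y = lam.copy()
            t = 1.0
            f_y, q_y = smooth(y)
            g_y = grad_from_q(q_y)
            continue
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        y = cand + ((t - 1.0) / t_new) * (cand - lam)
        lam_prev, lam = lam, cand
        obj_prev, obj = obj, new_obj
        t = t_new
        f_y, q_y = smooth(y)
        g_y = grad_from_q(q_y)
        step *= 1.1
        if it % 5 == 0 or abs(obj_prev - obj) <= obj_tol * max(1.0, abs(obj)):
            gap = np.abs(grad_from_q(q_cand))  # |E_q f - E_pres f| at lam
            kkt = float(np.max(gap - beta_j))
            if kkt <= kkt_tol and abs(obj_prev - obj) <= obj_tol * max(1.0, abs(obj)):
                converged = True
                break
    a = fb @ lam
    logz = _log_partition(a)
    q = np.exp(a - logz)
    entropy = float(-np.sum(q * np.log(np.maximum(q, 1e-300))))
    gap = np.abs(q @ fb - p_mean)
    kkt = float(np.max(gap - beta_j)) if m else 0.0
    if diverged:
        converged = False
    return FitResult(
        lam=lam,
        log_normalizer=logz,
        entropy=entropy,
        beta_j=beta_j,
        objective=penalized_objective(lam, fp, fb, beta_j),
        kkt_slack=kkt,
        n_iter=it,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# the species-level model


TRANSFORMS = ("raw", "logistic", "cloglog")


def _transform_scores(log_raw: np.ndarray, entropy: float, transform: str) -> np.ndarray:
    """Map log raw Gibbs densities to the requested output scale.

    Computed in log space so extreme coefficients cannot overflow:
    logistic = expit(H + log r), cloglog = 1 - exp(-exp(H + log r)).
    """
    from scipy.special import expit

    if transform == "raw":
        with np.errstate(over="ignore"):
            return np.exp(log_raw)
    eta = entropy + log_raw
    if transform == "logistic":
        return expit(eta)
    with np.errstate(over="ignore"):
        return -np.expm1(-np.exp(eta))


@dataclass
class SpeciesModel:
    """A fitted per-species distribution model."""

    species_id: str
    feature_set: FeatureSet
    lam: np.ndarray
    beta_multiplier: float
    log_normalizer: float
    entropy: float
    n_presence: int
    background_ids: list = field(default_factory=list)
    output_transform: str = "logistic"

    def predict(
        self,
        covariates: pd.DataFrame,
        transform: str | None = None,
    ) -> pd.Series:
        """Per-row prediction; covariates indexed by catchment id.

        raw values are the normalized Gibbs densities relative to the fitted
        background (they sum to one over the background rows); logistic and
        cloglog are the usual entropy-calibrated monotone rescalings into
        (0,1).
        """
        if self.lam is None:
            raise NotFittedError("model has no coefficients")
        transform = transform or self.output_transform
        if transform not in TRANSFORMS:
            raise InvalidConfigError(f"unknown transform {transform!r}")
        f = self.feature_set.transform(covariates, clamp=True)
        log_raw = f @ self.lam - self.log_normalizer
        out = _transform_scores(log_raw, self.entropy, transform)
        return pd.Series(out, index=covariates.index, name=self.species_id)

    def to_dict(self) -> dict:
        return {
            "species_id": self.species_id,
            "beta_multiplier": self.beta_multiplier,
            "log_normalizer": self.log_normalizer,
            "entropy": self.entropy,
            "n_presence": self.n_presence,
            "output_transform": self.output_transform,
            "coefficients": {
                name: float(c)
                for name, c in zip(self.feature_set.names, self.lam)
                if c != 0.0
            },
            "n_features": len(self.feature_set),
        }


def build_species_model(
    species_id: str,
    covariates: pd.DataFrame,
    kinds: dict[str, str],
    presence_ids: Sequence,
    background_ids: Sequence,
    beta_multiplier: float,
    classes: Iterable[str] = ALL_CLASSES,
    n_knots: int = 10,
    output_transform: str = "logistic",
    lam0: np.ndarray | None = None,
) -> tuple[SpeciesModel, FitResult]:
    """Expand features over the background and fit one species."""
    fs = expand_features(covariates, background_ids, kinds, classes, n_knots)
    fb = fs.transform(covariates.loc[list(background_ids)])
    fp = fs.transform(covariates.loc[list(presence_ids)])
    fit = fit_maxent(fp, fb, beta_multiplier, lam0=lam0)
    model = SpeciesModel(
        species_id=species_id,
        feature_set=fs,
        lam=fit.lam,
        beta_multiplier=beta_multiplier,
        log_normalizer=fit.log_normalizer,
        entropy=fit.entropy,
        n_presence=len(presence_ids),
        background_ids=list(background_ids),
        output_transform=output_transform,
    )
    return model, fit


# ---------------------------------------------------------------------------
# tuning and cross-validation


@dataclass
class TuningResult:
    grid: list[float]
    auc_per_beta: dict[float, float]
    chosen_beta: float
    fits: dict[float, FitResult] = field(default_factory=dict)
    failures: dict[float, str] = field(default_factory=dict)


def tune_beta(
    presence_features: np.ndarray,
    background_features: np.ndarray,
    grid: Iterable[float] = range(1, 16),
    contrast_features: np.ndarray | None = None,
) -> TuningResult:
    """Choose the regularization multiplier by training AUC over a grid.

    Fits run from the strongest penalty down, warm-starting each fit from the
    previous optimum.  The multiplier with the highest presence-vs-background
    AUC wins; ties go to the smallest value.  Individual fit failures are
    recorded and skipped; the call fails only if every fit fails.
    ``contrast_features`` lets the AUC contrast set differ from the fit's
    normalization pool (used when presences are folded into the pool).
    """
    from .evaluation import auc as _auc

    grid = sorted(set(float(b) for b in grid))
    if not grid:
        raise InvalidConfigError("beta grid is empty")
    if contrast_features is None:
        contrast_features = background_features
    aucs: dict[float, float] = {}
    fits: dict[float, FitResult] = {}
    failures: dict[float, str] = {}
    lam0 = None
    for b in reversed(grid):
        try:
            fit = fit_maxent(presence_features, background_features, b, lam0=lam0)
        except (FitError, DataError) as exc:
            failures[b] = str(exc)
            continue
        fits[b] = fit
        lam0 = fit.lam
        aucs[b] = _auc(presence_features @ fit.lam, contrast_features @ fit.lam)
    if not fits:
        raise FitError(f"every beta in the grid failed: {failures}")
    best = max(aucs.values())
    chosen = min(b for b, a in aucs.items() if a == best)
    return TuningResult(
        grid=grid, auc_per_beta=aucs, chosen_beta=chosen, fits=fits, failures=failures
    )


def kfold_sd(
    presence_features: np.ndarray,
    background_features: np.ndarray,
    target_features: np.ndarray,
    beta_multiplier: float,
    k: int = 10,
    seed: int = 0,
    lam0: np.ndarray | None = None,
) -> np.ndarray:
    """Per-target-row standard deviation of logistic predictions over k
    leave-one-fold-out refits (background held fixed).

    The SD is the population standard deviation across the k refit models'
    predictions at each target row.
    """
    n_pres = presence_features.shape[0]
    if n_pres < k:
        raise FitError(
            f"{n_pres} presences cannot be split into {k} folds; use a smaller k"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_pres)
    folds = np.array_split(order, k)
    preds = np.empty((k, target_features.shape[0]))
    for i, fold in enumerate(folds):
        keep = np.setdiff1d(order, fold)
        fit = fit_maxent(
            presence_features[keep], background_features, beta_multiplier, lam0=lam0
        )
        log_raw = target_features @ fit.lam - fit.log_normalizer
        preds[i] = _transform_scores(log_raw, fit.entropy, "logistic")
    return preds.std(axis=0)
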