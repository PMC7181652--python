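"""Weighted-averaging partial least squares (WA-PLS) transfer functions.

WA-PLS predicts an environmental variable (here salinity, usually on a
square-root scale) from species assemblage composition.  Components are
built iteratively: taxon scores are abundance-weighted averages of the
current environmental residual over samples, sample scores are
abundance-weighted averages of taxon scores, new sample scores are
orthogonalized to earlier components (weights proportional to assemblage
row totals), and the environmental variable is regressed on the component
scores by weighted least squares — the "inverse deshrinking" step.  With
one component the procedure collapses to classical weighted averaging
with inverse deshrinking.

Assemblages are closed to relative composition (rows divided by their
totals) before fitting, as is conventional for percentage diatom data;
row totals — and hence all sample weights — are then equal, and every
output is invariant to rescaling any assemblage by a positive constant.

Predictions are linear in *relative* composition, so the fitted model is
stored as one effective taxon-coefficient vector plus intercept per
component count:  x_hat = intercept_k + (y . beta_k) / sum(y).

Cross-validation follows the bootstrap: samples are resampled with
replacement, the model refit, and out-of-bag samples predicted; RMSEP is
the root mean square of out-of-bag errors pooled over cycles (the s1/s2
decomposition is reported alongside).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateComponentError,
    PredictionError,
    ValidationError,
)

__all__ = [
    "TrainingSet",
    "WAPLSModel",
    "CrossValidation",
    "ReconstructionResult",
    "fit_wapls",
    "predict",
    "bootstrap_validate",
    "reconstruct_salinity",
    "load_training_set",
    "load_fossil",
]

logger = logging.getLogger(__name__)

_TRANSFORMS = ("none", "sqrt")


@dataclass
class TrainingSet:
    """Species abundance matrix paired with an environmental vector.

    ``env`` is stored on the *raw* scale; ``transform`` ("none" or "sqrt")
    states the scale on which the model is fitted and reports.
    """

    abundances: np.ndarray            # (n_samples, n_taxa), non-negative
    env: np.ndarray                   # (n_samples,), raw scale
    taxon_names: list[str]
    sample_ids: list[str] | None = None
    transform: str = "none"

    def __post_init__(self):
        self.abundances = np.asarray(self.abundances, dtype=float)
        self.env = np.asarray(self.env, dtype=float)
        n, m = self.abundances.shape
        if self.env.shape != (n,):
            raise ValidationError("env length must equal n_samples")
        if len(self.taxon_names) != m:
            raise ValidationError("taxon_names length must equal n_taxa")
        if np.any(self.abundances < 0):
            raise ValidationError("abundances must be non-negative")
        if np.any(self.abundances.sum(axis=1) <= 0):
            raise ValidationError("every sample (row) must have a positive total")
        if np.any(self.abundances.sum(axis=0) <= 0):
            raise ValidationError("every taxon (column) must have a positive total")
        if self.transform not in _TRANSFORMS:
            raise ValidationError(f"unknown transform {self.transform!r}")
        if self.transform == "sqrt" and np.any(self.env < 0):
            raise ValidationError("sqrt transform requires non-negative env")

    @property
    def n_samples(self) -> int:
        return self.abundances.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.abundances.shape[1]

    def env_transformed(self) -> np.ndarray:
        return np.sqrt(self.env) if self.transform == "sqrt" else self.env


@dataclass
class WAPLSModel:
    """Fitted WA-PLS model: per-component-count prediction coefficients."""

    taxon_names: list[str]
    n_components: int
    beta: np.ndarray                  # (n_taxa, n_components)
    intercepts: np.ndarray            # (n_components,)
    apparent_rmse: np.ndarray         # weighted, transformed scale
    apparent_r2: np.ndarray
    transform: str = "none"
    taxon_scores: np.ndarray | None = None   # component-wise WA taxon scores


@dataclass
class CrossValidation:
    """Bootstrap cross-validation summaries, per component count."""

    n_boot: int
    rmsep_boot: np.ndarray            # pooled out-of-bag RMSE
    r2_boot: np.ndarray
    s1: np.ndarray                    # within-sample spread of boot predictions
    s2: np.ndarray                    # RMSE of per-sample mean prediction
    seed: int | None = None
    n_redraws: int = 0


@dataclass
class ReconstructionResult:
    """Back-transformed reconstructions as deviations from modern."""

    estimate: np.ndarray              # raw env units
    bootstrap_se: np.ndarray          # raw env units (delta method)
    deviation_from_modern: np.ndarray
    modern_reference: float
    k: int
    sample_ids: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "estimate": self.estimate,
            "bootstrap_se": self.bootstrap_se,
            "deviation_from_modern": self.deviation_from_modern,
        })
        if self.sample_ids is not None:
            df.insert(0, "sample_id", self.sample_ids)
        return df


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted least squares coefficients for y ~ X."""
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return coef


def _fit_engine(Y: np.ndarray, x: np.ndarray, n_components: int):
    """Core WA-PLS iteration on a clean matrix (positive row/col sums).

    Returns (beta, intercepts, rmse_w, r2, taxon_scores) where beta and
    intercepts give predictions from relative composition per component
    count, rmse_w is the row-total-weighted apparent RMSE and r2 the
    squared correlation of weighted fits with x.
    """
    n, m = Y.shape
    Y = Y / Y.sum(axis=1, keepdims=True)   # relative composition
    r = Y.sum(axis=1)                 # sample totals (all 1 after closure)
    s = Y.sum(axis=0)                 # taxon totals
    N = r.sum()
    w = r / N

    T = np.zeros((n, n_components))   # orthogonalized sample scores
    B = np.zeros((m, n_components))   # taxon coeffs reproducing T from Y
    beta = np.zeros((m, n_components))
    intercepts = np.zeros(n_components)
    rmse = np.zeros(n_components)
    r2 = np.zeros(n_components)
    U = np.zeros((m, n_components))   # raw WA taxon scores per component

    x_scale = float(np.sqrt(np.sum(w * (x - np.sum(w * x)) ** 2))) or 1.0
    resid = x - np.sum(w * x)
    for a in range(n_components):
        u = (Y.T @ resid) / s         # taxon scores: WA of residual
        U[:, a] = u
        t = (Y @ u) / r               # sample scores: WA of taxon scores
        b = u.copy()
        for j in range(a):            # orthogonalize to earlier components
            proj = float(np.sum(w * t * T[:, j]))
            t -= proj * T[:, j]
            b -= proj * B[:, j]
        norm = float(np.sqrt(np.sum(w * t * t)))
        if norm < 1e-10 * x_scale:
            raise DegenerateComponentError(a + 1)
        T[:, a] = t / norm
        B[:, a] = b / norm
        # inverse deshrinking: WLS of env on components fitted so far
        X = np.column_stack([np.ones(n), T[:, :a + 1]])
        coef = _wls(X, x, w)
        fitted = X @ coef
        resid = x - fitted
        intercepts[a] = coef[0]
        beta[:, a] = B[:, :a + 1] @ coef[1:]
        rmse[a] = float(np.sqrt(np.sum(w * resid ** 2)))
        c = np.corrcoef(fitted, x)[0, 1]
        r2[a] = float(c * c)
    return beta, intercepts, rmse, r2, U


def fit_wapls(ts: TrainingSet, n_components: int) -> WAPLSModel:
    """Fit a WA-PLS model with 1..n_components components."""
    if not 1 <= n_components <= min(ts.n_samples, ts.n_taxa):
        raise ValidationError(
            "n_components must be in [1, min(n_samples, n_taxa)]")
    x = ts.env_transformed()
    beta, intercepts, rmse, r2, U = _fit_engine(ts.abundances, x, n_components)
    return WAPLSModel(taxon_names=list(ts.taxon_names),
                      n_components=n_components, beta=beta,
                      intercepts=intercepts, apparent_rmse=rmse,
                      apparent_r2=r2, transform=ts.transform,
                      taxon_scores=U)


def predict(model: WAPLSModel, fossil, k: int | None = None,
            taxon_names: Sequence[str] | None = None) -> np.ndarray:
    """Predict (transformed) env values for fossil assemblages.

    ``fossil`` is a DataFrame with taxon columns or an array paired with
    ``taxon_names``.  Taxa absent from the training set are dropped with a
    logged warning; rows are implicitly renormalized because predictions
    use relative composition over the retained taxa.
    """
    if k is None:
        k = model.n_components
    if not 1 <= k <= model.n_components:
        raise ValidationError(f"k must be in [1, {model.n_components}]")
    if isinstance(fossil, pd.DataFrame):
        taxon_names = [str(c) for c in fossil.columns]
        Yf = fossil.to_numpy(dtype=float)
    else:
        Yf = np.asarray(fossil, dtype=float)
        if taxon_names is None:
            raise ValidationError("taxon_names required with array input")
        taxon_names = list(taxon_names)
    if Yf.ndim == 1:
        Yf = Yf[None, :]
    index = {t: i for i, t in enumerate(model.taxon_names)}
    unknown = [t for t in taxon_names if t not in index]
    if unknown:
        logger.warning("dropping %d fossil taxa absent from training: %s",
                       len(unknown), unknown[:10])
    aligned = np.zeros((Yf.shape[0], len(model.taxon_names)))
    for j, t in enumerate(taxon_names):
        i = index.get(t)
        if i is not None:
            aligned[:, i] += Yf[:, j]
    rows = aligned.sum(axis=1)
    bad = np.flatnonzero(rows <= 0)
    if bad.size:
        raise PredictionError(
            f"fossil rows {bad.tolist()} contain no taxa known to the model")
    return model.intercepts[k - 1] + (aligned @ model.beta[:, k - 1]) / rows


def bootstrap_validate(ts: TrainingSet, n_components: int,
                       n_boot: int = 1000,
                       seed: int | None = None) -> CrossValidation:
    """Bootstrap cross-validation of a WA-PLS model.

    Each cycle resamples the training samples with replacement, refits,
    and predicts the out-of-bag samples at every component count.  Cycles
    whose bootstrap sample has fewer than two distinct env values (or a
    degenerate component) are redrawn, at most 10 times each.
    """
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    n = ts.n_samples
    x = ts.env_transformed()
    Y = ts.abundances
    A = n_components

    sse = np.zeros(A)
    n_err = 0
    pred_sum = np.zeros((n, A))
    pred_sq = np.zeros((n, A))
    pred_cnt = np.zeros(n)
    n_redraws = 0
    for _ in range(n_boot):
        for attempt in range(11):
            idx = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), idx)
            if oob.size == 0 or np.unique(x[idx]).size < 2:
                n_redraws += 1
                continue
            Yb = Y[idx]
            keep = Yb.sum(axis=0) > 0
            try:
                beta, icpt, _, _, _ = _fit_engine(
                    Yb[:, keep], x[idx], min(A, int(keep.sum())))
            except DegenerateComponentError:
                n_redraws += 1
                continue
            break
        else:
            raise ValidationError(
                "bootstrap cycle redrawn more than 10 times; "
                "training set too degenerate to cross-validate")
        Yo = Y[oob][:, keep]
        rows = Yo.sum(axis=1)
        rows[rows == 0] = np.nan      # OOB sample with none of the boot taxa
        nb = beta.shape[1]
        preds = icpt[None, :] + (Yo @ beta) / rows[:, None]
        if nb < A:                    # fewer usable comps: carry last forward
            preds = np.column_stack(
                [preds] + [preds[:, -1]] * (A - nb))
        ok = ~np.isnan(preds[:, 0])
        err = preds[ok] - x[oob][ok, None]
        sse += np.sum(err ** 2, axis=0)
        n_err += int(ok.sum())
        pred_sum[oob[ok]] += preds[ok]
        pred_sq[oob[ok]] += preds[ok] ** 2
        pred_cnt[oob[ok]] += 1

    if n_err == 0:
        raise ValidationError("no out-of-bag predictions accumulated")
    rmsep = np.sqrt(sse / n_err)
    seen = pred_cnt > 0
    mean_pred = pred_sum[seen] / pred_cnt[seen, None]
    var_pred = np.maximum(
        pred_sq[seen] / pred_cnt[seen, None] - mean_pred ** 2, 0.0)
    s1 = np.sqrt(var_pred.mean(axis=0))
    s2 = np.sqrt(np.mean((mean_pred - x[seen, None]) ** 2, axis=0))
    r2_boot = np.array([
        np.corrcoef(mean_pred[:, a], x[seen])[0, 1] ** 2 for a in range(A)])
    return CrossValidation(n_boot=n_boot, rmsep_boot=rmsep, r2_boot=r2_boot,
                           s1=s1, s2=s2, seed=seed, n_redraws=n_redraws)


def reconstruct_salinity(model: WAPLSModel, cv: CrossValidation | None,
                         fossil, modern_reference: float,
                         k: int | None = None,
                         taxon_names: Sequence[str] | None = None,
                         sample_ids: list[str] | None = None
                         ) -> ReconstructionResult:
    """Reconstruct salinity and express it as deviation from modern.

    Predictions are made on the model's (possibly square-root) scale and
    back-transformed before subtracting ``modern_reference`` (raw scale).
    The bootstrap RMSEP at the chosen component count serves as the
    per-sample standard error on the transformed scale and is propagated
    by the delta method (se_raw ~= 2 * |estimate_sqrt| * se_sqrt).
    """
    if modern_reference is None:
        raise ValidationError("modern_reference is required")
    if k is None:
        k = model.n_components
    est_t = predict(model, fossil, k=k, taxon_names=taxon_names)
    se_t = float(cv.rmsep_boot[k - 1]) if cv is not None else np.nan
    if model.transform == "sqrt":
        est = est_t ** 2
        se = 2.0 * np.abs(est_t) * se_t
    else:
        est = est_t
        se = np.full_like(est_t, se_t)
    return ReconstructionResult(
        estimate=est, bootstrap_se=np.asarray(se, dtype=float),
        deviation_from_modern=est - float(modern_reference),
        modern_reference=float(modern_reference), k=k, sample_ids=sample_ids)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def load_training_set(path, transform: str = "none") -> TrainingSet:
    """CSV layout: sample_id, env, then one column per taxon."""
    df = pd.read_csv(path, comment="#")
    if df.shape[1] < 3:
        raise ValidationError("training CSV needs sample_id, env, taxa columns")
    return TrainingSet(
        abundances=df.iloc[:, 2:].to_numpy(dtype=float),
        env=df.iloc[:, 1].to_numpy(dtype=float),
        taxon_names=[str(c) for c in df.columns[2:]],
        sample_ids=[str(v) for v in df.iloc[:, 0]],
        transform=transform)


def load_fossil(path) -> tuple[pd.DataFrame, list[str], np.ndarray]:
    """CSV layout: sample_id, depth, then taxa. Returns (taxa df, ids, depths)."""
    df = pd.read_csv(path, comment="#")
    if df.shape[1] < 3:
        raise ValidationError("fossil CSV needs sample_id, depth, taxa columns")
    ids = [str(v) for v in df.iloc[:, 0]]
    depths = df.iloc[:, 1].to_numpy(dtype=float)
    return df.iloc[:, 2:], ids, depths
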