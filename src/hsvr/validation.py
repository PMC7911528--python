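"""Validation statistics for regression QSAR models.

Implements the full external-validation battery used for the Caco-2
permeability models: residual statistics (MAE, RMSE, s, max residual),
squared correlation coefficients under three conventions, the external
predictivity coefficients qF1^2/qF2^2/qF3^2, Lin's concordance correlation
coefficient (CCC), the Roy rm^2 family built on Golbraikh-Tropsha
through-origin regressions, k-fold cross-validation, Y-scrambling, and the
stringent joint criteria gate (Golbraikh-Tropsha / Ojha / Roy /
Chirico-Gramatica).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np

from . import errors
from .io import PredictionSet

Convention = Literal["pearson_sq", "eq_printed", "determination"]

#: default convention for r^2 / q^2 style statistics
DEFAULT_CONVENTION: Convention = "pearson_sq"


def _vectors(ps: PredictionSet) -> tuple[np.ndarray, np.ndarray]:
    return np.asarray(ps.observed, float), np.asarray(ps.predicted, float)


# ---------------------------------------------------------------------------
# residual statistics


def error_stats(ps: PredictionSet) -> dict[str, float | np.ndarray]:
    """Residuals Delta_i = y_i - yhat_i with MAE, RMSE, s, DeltaMax.

    ``s`` is the (n-1)-denominator sample standard deviation of the
    residuals and requires n >= 2.
    """
    y, yhat = _vectors(ps)
    if len(y) < 1:
        raise errors.ValidationError("empty prediction set")
    delta = y - yhat
    out: dict[str, float | np.ndarray] = {
        "residuals": delta,
        "mae": float(np.mean(np.abs(delta))),
        "rmse": float(np.sqrt(np.mean(delta**2))),
        "delta_max": float(np.max(np.abs(delta))),
        "mean_residual": float(np.mean(delta)),
    }
    if len(y) >= 2:
        out["s"] = float(np.std(delta, ddof=1))
    else:
        raise errors.ValidationError("s requires at least two samples")
    return out


# ---------------------------------------------------------------------------
# squared correlation


def pearson_r(a, b) -> float:
    """Plain Pearson correlation coefficient."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or len(a) < 3:
        raise errors.ValidationError("pearson_r needs two equal-length vectors of length >= 3")
    da, db = a - a.mean(), b - b.mean()
    va, vb = float(da @ da), float(db @ db)
    if va == 0.0 or vb == 0.0:
        raise errors.ValidationError("pearson_r undefined for a zero-variance vector")
    return float((da @ db) / math.sqrt(va * vb))


def squared_correlation(
    ps: PredictionSet, convention: Convention = DEFAULT_CONVENTION
) -> float:
    """r^2 (training) / q^2 (external) under a chosen convention.

    ``pearson_sq`` (default): squared Pearson coefficient of observed vs
    predicted.  ``determination``: 1 - SS_res / SS_tot with the observed
    mean in the denominator.  ``eq_printed``: same form but with the mean
    *predicted* value in the denominator.
    """
    y, yhat = _vectors(ps)
    if len(y) < 3:
        raise errors.ValidationError("squared correlation needs n >= 3")
    if convention == "pearson_sq":
        return pearson_r(y, yhat) ** 2
    ss_res = float(np.sum((yhat - y) ** 2))
    center = yhat.mean() if convention == "eq_printed" else y.mean()
    ss_tot = float(np.sum((y - center) ** 2))
    if ss_tot == 0.0:
        raise errors.ValidationError("zero variance of observed values")
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# external predictivity coefficients


def external_metrics(ps: PredictionSet) -> dict[str, float | None]:
    """qF1^2, qF2^2, qF3^2 and CCC for an external prediction set.

    qF1^2 references the training-set mean <y_TR>; qF3^2 scales the mean
    external squared error by the biased training-set variance
    sum((y_TR - <y_TR>)^2) / n_TR, so it additionally needs the training
    sum of squares and n_TR.  When a training reference is missing the
    coefficient is returned as ``None``.  CCC includes the location-shift
    penalty term n_EXT * (<y_EXT> - <yhat_EXT>)^2 in its denominator.
    """
    y, yhat = _vectors(ps)
    n_ext = len(y)
    if n_ext < 2:
        raise errors.ValidationError("external statistics need n_EXT >= 2")
    ss_res = float(np.sum((y - yhat) ** 2))
    y_mean = float(y.mean())
    yhat_mean = float(yhat.mean())

    out: dict[str, float | None] = {}
    if ps.train_mean is not None:
        denom1 = float(np.sum((y - ps.train_mean) ** 2))
        out["qf1"] = 1.0 - ss_res / denom1 if denom1 else None
    else:
        out["qf1"] = None
    denom2 = float(np.sum((y - y_mean) ** 2))
    out["qf2"] = 1.0 - ss_res / denom2 if denom2 else None
    if ps.train_ss is not None and ps.n_train:
        denom3 = ps.train_ss / ps.n_train
        out["qf3"] = 1.0 - (ss_res / n_ext) / denom3 if denom3 else None
    else:
        out["qf3"] = None

    sxy = float(np.sum((y - y_mean) * (yhat - yhat_mean)))
    sxx = float(np.sum((y - y_mean) ** 2))
    syy = float(np.sum((yhat - yhat_mean) ** 2))
    denom_ccc = sxx + syy + n_ext * (y_mean - yhat_mean) ** 2
    out["ccc"] = 2.0 * sxy / denom_ccc if denom_ccc else None
    return out


# ---------------------------------------------------------------------------
# Roy rm^2 family / through-origin regressions


def rm_metrics(ps: PredictionSet, radical: bool = True) -> dict[str, float]:
    """Through-origin slopes and Roy's modified squared correlations.

    k = sum(y*yhat)/sum(yhat^2) and k' = sum(y*yhat)/sum(y^2) are the
    slopes of the least-squares regressions through the origin of observed
    on predicted and predicted on observed.  r0^2 (resp. r0'^2) is the
    coefficient of determination of that through-origin line for observed
    (resp. predicted) values.  rm^2 = r^2 * (1 - sqrt(|r^2 - r0^2|)) in the
    standard (radical) form; ``radical=False`` selects the literal
    no-radical variant r^2 * (1 - |r^2 - r0^2|).
    """
    y, yhat = _vectors(ps)
    if len(y) < 3:
        raise errors.ValidationError("rm metrics need n >= 3")
    syy = float(np.sum(y**2))
    shh = float(np.sum(yhat**2))
    if syy == 0.0 or shh == 0.0:
        raise errors.ValidationError("rm metrics undefined for all-zero vectors")
    sxy = float(np.sum(y * yhat))
    k = sxy / shh
    k_prime = sxy / syy

    r2 = pearson_r(y, yhat) ** 2

    ss_tot_y = float(np.sum((y - y.mean()) ** 2))
    ss_tot_h = float(np.sum((yhat - yhat.mean()) ** 2))
    if ss_tot_y == 0.0 or ss_tot_h == 0.0:
        raise errors.ValidationError("rm metrics undefined for constant vectors")
    r0_sq = 1.0 - float(np.sum((y - k * yhat) ** 2)) / ss_tot_y
    r0_sq_prime = 1.0 - float(np.sum((yhat - k_prime * y) ** 2)) / ss_tot_h

    def _rm(r2_: float, r0_: float) -> float:
        gap = abs(r2_ - r0_)
        return r2_ * (1.0 - (math.sqrt(gap) if radical else gap))

    rm2 = _rm(r2, r0_sq)
    rm2_prime = _rm(r2, r0_sq_prime)
    return {
        "k": k,
        "k_prime": k_prime,
        "r0_sq": r0_sq,
        "r0_sq_prime": r0_sq_prime,
        "rm2": rm2,
        "rm2_prime": rm2_prime,
        "rm2_mean": 0.5 * (rm2 + rm2_prime),
        "rm2_delta": abs(rm2 - rm2_prime),
    }


# ---------------------------------------------------------------------------
# cross-validation and scrambling

FitPredict = Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]


def kfold_cv(
    fit_predict: FitPredict,
    X,
    y,
    k: int = 10,
    seed: int = 0,
    convention: Convention = DEFAULT_CONVENTION,
) -> dict:
    """q_CV^2 from seeded k-fold cross-validation.

    ``fit_predict(X_train, y_train, X_eval)`` refits the whole pipeline on
    the fold-training rows and returns predictions for the held-out rows;
    out-of-fold predictions are pooled into one prediction set before the
    squared correlation is computed.  ``k = n`` gives leave-one-out.
    """
    X = np.asarray(X, float) if not hasattr(X, "iloc") else X
    y = np.asarray(y, float)
    n = len(y)
    if not (2 <= k <= n):
        raise errors.ValidationError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    yhat = np.full(n, np.nan)
    for fold in folds:
        mask = np.ones(n, bool)
        mask[fold] = False
        X_tr = X.iloc[mask] if hasattr(X, "iloc") else X[mask]
        X_te = X.iloc[fold] if hasattr(X, "iloc") else X[fold]
        yhat[fold] = np.asarray(fit_predict(X_tr, y[mask], X_te), float)
    ps = PredictionSet(observed=y, predicted=yhat, label="cv")
    return {"q_cv2": squared_correlation(ps, convention), "oof_predictions": yhat, "folds": folds}


def y_scramble(
    fit_train_r2: Callable[[np.ndarray], float] | None = None,
    *,
    fit_predict_train: Callable[[np.ndarray], np.ndarray] | None = None,
    predictions=None,
    y=None,
    reps: int = 25,
    seed: int = 0,
    mode: str = "reapply",
    convention: Convention = DEFAULT_CONVENTION,
) -> dict:
    """Y-scrambling: permute the response and record the chance r_s^2.

    Two protocols are implemented.  ``mode="reapply"`` (default) keeps the
    already-developed model untouched: each permuted response vector is
    correlated against the model's fixed training predictions (pass them as
    ``predictions`` with ``y``), so <rs^2> estimates the pure chance
    correlation, of order 1/n.  ``mode="refit"`` re-trains the model per
    repetition with identical descriptors and hyperparameters (supply
    ``fit_train_r2(y_perm) -> r_s^2`` or ``fit_predict_train(y_perm) ->
    training predictions``) and additionally exposes the capacity of the
    frozen hyperparameters to memorize noise.  Failed refits are skipped;
    at least 80% of the repetitions must succeed.
    """
    if reps < 1:
        raise errors.ValidationError("reps must be >= 1")
    if mode not in ("reapply", "refit"):
        raise errors.ValidationError(f"mode must be 'reapply' or 'refit', got {mode!r}")
    if y is None:
        raise errors.ValidationError("y is required")
    y = np.asarray(y, float)
    n = len(y)

    if mode == "reapply":
        if predictions is None:
            raise errors.ValidationError("reapply mode needs the fixed model predictions")
        yhat = np.asarray(predictions, float)

        def fit_train_r2(y_perm):
            return squared_correlation(
                PredictionSet(observed=y_perm, predicted=yhat), convention
            )

    elif fit_train_r2 is None:
        if fit_predict_train is None:
            raise errors.ValidationError(
                "refit mode needs fit_train_r2 or fit_predict_train"
            )

        def fit_train_r2(y_perm):
            pred = np.asarray(fit_predict_train(y_perm), float)
            return squared_correlation(
                PredictionSet(observed=y_perm, predicted=pred), convention
            )

    rng = np.random.default_rng(seed)
    scores, failures = [], 0
    for _ in range(reps):
        y_perm = y[rng.permutation(n)]
        try:
            scores.append(float(fit_train_r2(y_perm)))
        except Exception:
            failures += 1
    if len(scores) < math.ceil(0.8 * reps):
        raise errors.ValidationError(
            f"Y-scrambling: only {len(scores)}/{reps} refits succeeded (need >= 80%)"
        )
    return {"rs2_mean": float(np.mean(scores)), "rs2": scores, "failures": failures}


# ---------------------------------------------------------------------------
# report assembly and criteria gate


@dataclass
class ValidationReport:
    """All statistics for one dataset; fields absent in a context are None."""

    context: str = "training"  # "training" or "external"
    n: int | None = None
    r2: float | None = None  # r^2 (training) or q^2 (external), default convention
    q_cv2: float | None = None
    rs2_mean: float | None = None
    qf1: float | None = None
    qf2: float | None = None
    qf3: float | None = None
    ccc: float | None = None
    rmse: float | None = None
    mae: float | None = None
    s: float | None = None
    delta_max: float | None = None
    mean_residual: float | None = None
    k: float | None = None
    k_prime: float | None = None
    r0_sq: float | None = None
    r0_sq_prime: float | None = None
    rm2: float | None = None
    rm2_prime: float | None = None
    rm2_mean: float | None = None
    rm2_delta: float | None = None
    criteria: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {k: v for k, v in self.__dict__.items()}
        return out


def validate_predictions(
    ps: PredictionSet,
    context: str = "training",
    q_cv2: float | None = None,
    rs2_mean: float | None = None,
    convention: Convention = DEFAULT_CONVENTION,
    input_decimals: int | None = None,
) -> ValidationReport:
    """Assemble the full ValidationReport for one prediction set."""
    err = error_stats(ps)
    rm = rm_metrics(ps)
    report = ValidationReport(
        context=context,
        n=len(ps),
        r2=squared_correlation(ps, convention),
        q_cv2=q_cv2,
        rs2_mean=rs2_mean,
        rmse=err["rmse"],
        mae=err["mae"],
        s=err["s"],
        delta_max=err["delta_max"],
        mean_residual=err["mean_residual"],
        **rm,
    )
    if context == "external":
        ext = external_metrics(ps)
        report.qf1, report.qf2, report.qf3 = ext["qf1"], ext["qf2"], ext["qf3"]
        report.ccc = ext["ccc"]
    report.criteria = check_criteria(report, context=context, input_decimals=input_decimals)
    return report


def _tol(input_decimals: int | None, operands: int = 1) -> float:
    # printed values rounded to d decimals carry +-0.5*10^-d each
    if input_decimals is None:
        return 0.0
    return operands * 0.5 * 10.0 ** (-input_decimals)


def check_criteria(
    report: ValidationReport,
    context: str | None = None,
    input_decimals: int | None = None,
) -> dict:
    """Evaluate the stringent joint validation criteria on a report.

    Returns a map with one entry per criterion; each value is True, False
    or "N/A" when the criterion does not apply to the context (the CCC
    bound is external-only, the cross-validation bounds training-only), or
    ``"cannot evaluate"`` when a required field is missing.  With
    ``input_decimals`` set, boundary comparisons are widened by the
    rounding half-ulp of values printed to that many decimals — use it when
    the report was populated from rounded published values rather than
    computed at full precision.

    Criteria: (r^2-r0^2)/r^2 < 0.10 with 0.85 <= k <= 1.15; all squared
    correlations >= 0.70; |r^2 - q_CV^2| < 0.10; |r0^2 - r0'^2| < 0.30;
    rm^2 >= 0.65; <rm^2> >= 0.65 with delta rm^2 < 0.20; CCC >= 0.85.
    """
    ctx = context or report.context
    if ctx not in ("training", "external"):
        raise errors.ValidationError(f"context must be training or external, got {ctx!r}")
    out: dict[str, object] = {}

    def need(*fields):
        missing = [f for f in fields if getattr(report, f) is None]
        return missing

    t1 = _tol(input_decimals, 1)
    t2 = _tol(input_decimals, 2)

    # slope / through-origin closeness
    if need("r2", "r0_sq", "k"):
        out["slope_r0"] = "cannot evaluate"
    else:
        ratio = (report.r2 - report.r0_sq) / report.r2
        out["slope_r0"] = bool(ratio < 0.10 + t2 and 0.85 - t1 <= report.k <= 1.15 + t1)

    # squared-correlation floor
    floors = []
    if report.r2 is not None:
        floors.append(report.r2)
    if ctx == "training":
        if report.q_cv2 is None:
            out["sq_corr_floor"] = "cannot evaluate"
        else:
            floors.append(report.q_cv2)
            out["sq_corr_floor"] = bool(all(v >= 0.70 - t1 for v in floors))
    else:
        for f in ("qf1", "qf2", "qf3"):
            v = getattr(report, f)
            if v is not None:
                floors.append(v)
        out["sq_corr_floor"] = bool(all(v >= 0.70 - t1 for v in floors)) if floors else "cannot evaluate"

    # overtraining gap (training only: needs q_CV^2)
    if ctx == "training":
        if need("r2", "q_cv2"):
            out["cv_gap"] = "cannot evaluate"
        else:
            out["cv_gap"] = bool(abs(report.r2 - report.q_cv2) < 0.10 + t2)
    else:
        out["cv_gap"] = "N/A"

    if need("r0_sq", "r0_sq_prime"):
        out["r0_gap"] = "cannot evaluate"
    else:
        out["r0_gap"] = bool(abs(report.r0_sq - report.r0_sq_prime) < 0.30 + t2)

    out["rm2_floor"] = (
        "cannot evaluate" if report.rm2 is None else bool(report.rm2 >= 0.65 - t1)
    )
    if need("rm2_mean", "rm2_delta"):
        out["rm2_mean_delta"] = "cannot evaluate"
    else:
        out["rm2_mean_delta"] = bool(
            report.rm2_mean >= 0.65 - t1 and report.rm2_delta < 0.20 + t2
        )

    if ctx == "external":
        out["ccc_floor"] = (
            "cannot evaluate" if report.ccc is None else bool(report.ccc >= 0.85 - t1)
        )
    else:
        out["ccc_floor"] = "N/A"

    applicable = [v for v in out.values() if isinstance(v, bool)]
    evaluable = not any(v == "cannot evaluate" for v in out.values())
    out["overall_pass"] = bool(applicable) and all(applicable) and evaluable
    return out
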