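"""End-to-end convenience layer: split, normalize, grid-search members,
assemble the hierarchical model, and validate.

This is the surface the CLI and the examples use.  Member descriptor
subsets default to three complementary local views of the standard
descriptor block (lipophilicity/polarity, polarity/ionization, and
size/aromaticity), mirroring how the ensemble members split the descriptor
space in the Caco-2 study design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import engine, errors, preprocess, validation
from .io import PredictionSet
from .preprocess import Normalizer, SplitResult

DEFAULT_MEMBER_SUBSETS = (
    ("log_p", "psa", "alpha", "pka_max", "mu_max"),
    ("log_p", "psa", "mu", "hbd", "ion_class_code"),
    ("n_ar", "mu_max", "n_ring", "v_m", "n_rot", "hbd", "pka_max"),
)


@dataclass
class StudyResult:
    """Fitted model plus the validation reports of one modeling run."""

    model: engine.HsvrModel
    split: SplitResult
    normalizer: Normalizer
    train_report: validation.ValidationReport
    test_report: validation.ValidationReport
    member_specs: list[engine.SvrSpec] = field(default_factory=list)

    @property
    def gate_passed(self) -> bool:
        return bool(
            self.model.gate_passed
            and self.train_report.criteria.get("overall_pass")
            and self.test_report.criteria.get("overall_pass")
        )


def _subset_columns(desc: pd.DataFrame, subsets) -> list[tuple[str, ...]]:
    out = []
    for subset in subsets:
        missing = [c for c in subset if c not in desc.columns]
        if missing:
            raise errors.SchemaError(f"descriptor column(s) {missing} absent from table")
        out.append(tuple(subset))
    return out


def _pipeline_refit_factory(member_specs, meta_spec, k_folds=5, seed=0):
    """Refit members + meta with fixed hyperparameters; used for CV/scrambling."""

    def fit_predict(X_tr: pd.DataFrame, y_tr: np.ndarray, X_te: pd.DataFrame) -> np.ndarray:
        members = [engine.fit_svr(spec, X_tr, y_tr) for spec in member_specs]
        meta = engine.fit_meta(
            members, X_tr, y_tr, meta_grid=[_meta_point(meta_spec)], k_folds=k_folds, seed=seed
        )
        model = engine.HsvrModel(members=members, meta=meta, seed=seed)
        return model.predict(X_te, normalized=True)

    return fit_predict


def _meta_point(spec: engine.SvrSpec) -> dict:
    point = {"cost": spec.cost, "gamma": spec.gamma}
    if spec.variant == "epsilon":
        point["epsilon"] = spec.epsilon
    else:
        point["nu"] = spec.nu
    return point


def fit_hsvr(
    desc: pd.DataFrame,
    y: pd.Series,
    subsets=DEFAULT_MEMBER_SUBSETS,
    variant: str = "epsilon",
    seed: int = 0,
    test_fraction: float = 0.2,
    grid=None,
    meta_grid=None,
    k_folds_grid: int = 5,
    k_folds_cv: int = 10,
    outlier_ids=(),
) -> StudyResult:
    """Full modeling run on a descriptor table and response series.

    Splits ~4:1, fits normalization on training rows only, grid-searches
    one SVR member per descriptor subset, assembles the minimal ensemble
    whose meta-model passes the external criteria gate, and returns both
    training (with 10-fold q_CV^2) and test validation reports.
    """
    subsets = _subset_columns(desc, subsets)
    y = y.astype(float)
    numeric = desc.select_dtypes(include=[np.number])

    split = preprocess.split_dataset(
        list(desc.index), ratio=test_fraction, seed=seed, outlier_ids=outlier_ids
    )
    normalizer = preprocess.fit_normalizer(numeric, fit_rows=split.train_ids)
    Xn = normalizer.transform(numeric)
    X_tr, X_te = Xn.loc[split.train_ids], Xn.loc[split.test_ids]
    y_tr, y_te = y.loc[split.train_ids].to_numpy(), y.loc[split.test_ids].to_numpy()

    grid = grid if grid is not None else engine.compact_grid(variant)
    members, specs = [], []
    for subset in subsets:
        spec, _ = engine.grid_search(
            variant, X_tr, y_tr, subset=subset, grid=grid, k_folds=k_folds_grid, seed=seed
        )
        members.append(engine.fit_svr(spec, X_tr, y_tr))
        specs.append(spec)

    model = engine.build_ensemble(
        members, X_tr, y_tr, X_te, y_te,
        meta_grid=meta_grid, k_folds=k_folds_grid, seed=seed, normalizer=normalizer,
    )

    member_specs = [m.spec for m in model.members]
    refit = _pipeline_refit_factory(member_specs, model.meta.spec, k_folds=k_folds_grid, seed=seed)
    cv = validation.kfold_cv(refit, X_tr, y_tr, k=min(k_folds_cv, len(y_tr)), seed=seed)

    yhat_tr = model.predict(X_tr, normalized=True)
    yhat_te = model.predict(X_te, normalized=True)
    train_report = validation.validate_predictions(
        PredictionSet(observed=y_tr, predicted=yhat_tr, label="training"),
        context="training",
        q_cv2=cv["q_cv2"],
    )
    test_report = validation.validate_predictions(
        PredictionSet(
            observed=y_te, predicted=yhat_te, label="test",
            train_mean=float(np.mean(y_tr)), n_train=len(y_tr),
            train_ss=float(np.sum((y_tr - np.mean(y_tr)) ** 2)),
        ),
        context="external",
    )
    return StudyResult(
        model=model, split=split, normalizer=normalizer,
        train_report=train_report, test_report=test_report, member_specs=member_specs,
    )


def fit_global_svr(
    desc: pd.DataFrame,
    y: pd.Series,
    subset=("log_p",),
    variant: str = "epsilon",
    seed: int = 0,
    test_fraction: float = 0.2,
    grid=None,
    k_folds_grid: int = 5,
    k_folds_cv: int = 10,
    outlier_ids=(),
) -> dict:
    """Single global SVR on one descriptor subset, same split and reports.

    The comparator for the local-plus-global claim: e.g. a log P-only
    model shares the split and normalization protocol with :func:`fit_hsvr`
    so the two runs are directly comparable.
    """
    subset = tuple(subset)
    y = y.astype(float)
    numeric = desc.select_dtypes(include=[np.number])
    split = preprocess.split_dataset(
        list(desc.index), ratio=test_fraction, seed=seed, outlier_ids=outlier_ids
    )
    normalizer = preprocess.fit_normalizer(numeric, fit_rows=split.train_ids)
    Xn = normalizer.transform(numeric)
    X_tr, X_te = Xn.loc[split.train_ids], Xn.loc[split.test_ids]
    y_tr, y_te = y.loc[split.train_ids].to_numpy(), y.loc[split.test_ids].to_numpy()

    grid = grid if grid is not None else engine.compact_grid(variant)
    spec, _ = engine.grid_search(
        variant, X_tr, y_tr, subset=subset, grid=grid, k_folds=k_folds_grid, seed=seed
    )
    fitted = engine.fit_svr(spec, X_tr, y_tr)

    def refit(X_a, y_a, X_b):
        return engine.fit_svr(spec, X_a, y_a).predict(X_b)

    cv = validation.kfold_cv(refit, X_tr, y_tr, k=min(k_folds_cv, len(y_tr)), seed=seed)
    train_report = validation.validate_predictions(
        PredictionSet(observed=y_tr, predicted=fitted.predict(X_tr), label="training"),
        context="training", q_cv2=cv["q_cv2"],
    )
    test_report = validation.validate_predictions(
        PredictionSet(
            observed=y_te, predicted=fitted.predict(X_te), label="test",
            train_mean=float(np.mean(y_tr)), n_train=len(y_tr),
            train_ss=float(np.sum((y_tr - np.mean(y_tr)) ** 2)),
        ),
        context="external",
    )
    return {
        "spec": spec, "model": fitted, "split": split, "normalizer": normalizer,
        "train_report": train_report, "test_report": test_report,
    }


def scramble_study(result: StudyResult, desc: pd.DataFrame, y: pd.Series,
                   reps: int = 25, seed: int = 0, mode: str = "reapply") -> dict:
    """Y-scrambling of a fitted study.

    In the default ``reapply`` protocol the permuted training responses are
    correlated against the developed model's fixed predictions (descriptors
    and model untouched).  ``mode="refit"`` instead re-trains members and
    meta per permutation with unchanged hyperparameters.
    """
    numeric = desc.select_dtypes(include=[np.number])
    Xn = result.normalizer.transform(numeric)
    X_tr = Xn.loc[result.split.train_ids]
    y_tr = y.loc[result.split.train_ids].to_numpy(float)
    if mode == "reapply":
        preds = result.model.predict(X_tr, normalized=True)
        return validation.y_scramble(
            predictions=preds, y=y_tr, reps=reps, seed=seed, mode="reapply"
        )
    refit = _pipeline_refit_factory(
        [m.spec for m in result.model.members], result.model.meta.spec, seed=seed
    )

    def fit_predict_train(y_perm):
        return refit(X_tr, y_perm, X_tr)

    return validation.y_scramble(
        fit_predict_train=fit_predict_train, y=y_tr, reps=reps, seed=seed, mode="refit"
    )
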