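"""Two-level SVR ensemble: member models, grid search, minimal-ensemble
assembly, and the meta-SVR.

Members are epsilon- or nu-SVR regressors with an RBF kernel, each trained
on its own descriptor subset of the normalized matrix, acting as local
models.  The meta-SVR consumes the member-prediction vector only (never the
raw descriptors) and plays the global role.  Ensemble assembly follows a
parsimony rule: all two-member combinations are tried first, then three-,
then four-member ones, and the first combination whose meta-model passes
the external criteria gate on the held-out test set is returned.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sklearn.svm import SVR, NuSVR

from . import errors, validation
from .io import PredictionSet
from .preprocess import Normalizer


@dataclass(frozen=True)
class SvrSpec:
    """Hyperparameters and descriptor subset of one SVR member."""

    variant: str  # "epsilon" or "nu"
    gamma: float
    cost: float
    epsilon: float | None = None
    nu: float | None = None
    descriptor_subset: tuple[str, ...] = ()

    def __post_init__(self):
        if self.variant not in ("epsilon", "nu"):
            raise errors.ValidationError(f"unknown SVR variant {self.variant!r}")
        if self.gamma <= 0 or self.cost <= 0:
            raise errors.ValidationError("gamma and cost must be positive")
        if self.variant == "epsilon":
            if self.epsilon is None or self.nu is not None:
                raise errors.ValidationError("epsilon variant requires epsilon and no nu")
            if self.epsilon < 0:
                raise errors.ValidationError("epsilon must be >= 0")
        else:
            if self.nu is None or self.epsilon is not None:
                raise errors.ValidationError("nu variant requires nu and no epsilon")
            if not (0 < self.nu <= 1):
                raise errors.ValidationError("nu must lie in (0, 1]")

    def make_estimator(self):
        if self.variant == "epsilon":
            return SVR(kernel="rbf", gamma=self.gamma, C=self.cost, epsilon=self.epsilon)
        return NuSVR(kernel="rbf", gamma=self.gamma, C=self.cost, nu=self.nu)


@dataclass
class FittedSvr:
    """A fitted member model bound to its spec."""

    spec: SvrSpec
    estimator: object

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        cols = list(self.spec.descriptor_subset)
        missing = [c for c in cols if c not in X.columns]
        if missing:
            raise errors.ValidationError(
                f"missing descriptor column(s) {missing} for member {cols}"
            )
        return np.asarray(self.estimator.predict(X[cols].to_numpy(float)), float)


def fit_svr(spec: SvrSpec, X: pd.DataFrame, y) -> FittedSvr:
    """Fit one SVR member on the normalized matrix restricted to its subset."""
    y = np.asarray(y, float)
    cols = list(spec.descriptor_subset)
    if not cols:
        raise errors.ValidationError("descriptor subset must be non-empty")
    if len(X) != len(y) or len(y) < 3:
        raise errors.ValidationError("need matching X rows and y of length >= 3")
    est = spec.make_estimator()
    est.fit(X[cols].to_numpy(float), y)
    return FittedSvr(spec=spec, estimator=est)


# ---------------------------------------------------------------------------
# grid search


def default_grid(variant: str = "epsilon") -> list[dict]:
    """libsvm-style lattice: C in 2^-5..2^15, gamma in 2^-15..2^3 (log2 step 2)."""
    costs = [2.0**e for e in range(-5, 16, 2)]
    gammas = [2.0**e for e in range(-15, 4, 2)]
    if variant == "epsilon":
        extras = [{"epsilon": v} for v in (0.01, 0.05, 0.1, 0.2, 0.5)]
    else:
        extras = [{"nu": v} for v in (0.1, 0.25, 0.5, 0.75)]
    return [
        {"cost": c, "gamma": g, **ex} for c in costs for g in gammas for ex in extras
    ]


def compact_grid(variant: str = "epsilon") -> list[dict]:
    """Smaller lattice for routine fits; same shape, coarser coverage."""
    costs = [2.0**e for e in (-1, 2, 5, 8)]
    gammas = [2.0**e for e in (-6, -4, -2, 0)]
    if variant == "epsilon":
        extras = [{"epsilon": v} for v in (0.05, 0.1, 0.2)]
    else:
        extras = [{"nu": v} for v in (0.25, 0.5)]
    return [
        {"cost": c, "gamma": g, **ex} for c in costs for g in gammas for ex in extras
    ]


def grid_search(
    variant: str,
    X: pd.DataFrame,
    y,
    subset: Sequence[str],
    grid: Iterable[dict] | None = None,
    k_folds: int = 5,
    seed: int = 0,
) -> tuple[SvrSpec, pd.DataFrame]:
    """Exhaustive grid search minimizing k-fold CV RMSE.

    Ties within 1e-12 are broken toward smaller C, then smaller gamma (then
    smaller epsilon/nu).  Returns the winning spec and the full CV table.
    """
    grid = list(grid) if grid is not None else default_grid(variant)
    if not grid:
        raise errors.ValidationError("empty hyperparameter lattice")
    y = np.asarray(y, float)
    Xs = X[list(subset)].to_numpy(float)
    kf = KFold(n_splits=min(k_folds, len(y)), shuffle=True, random_state=seed)
    splits = list(kf.split(Xs))

    rows = []
    failures = 0
    for point in grid:
        spec = SvrSpec(variant=variant, descriptor_subset=tuple(subset), **point)
        try:
            sq = 0.0
            for tr, te in splits:
                est = spec.make_estimator()
                est.fit(Xs[tr], y[tr])
                resid = y[te] - est.predict(Xs[te])
                sq += float(resid @ resid)
            rmse = float(np.sqrt(sq / len(y)))
        except Exception:
            failures += 1
            rmse = float("nan")
        rows.append({**point, "cv_rmse": rmse})
    table = pd.DataFrame(rows)
    if table["cv_rmse"].isna().all():
        raise errors.HsvrError("every grid point failed to fit")

    ok = table.dropna(subset=["cv_rmse"]).copy()
    best_rmse = ok["cv_rmse"].min()
    tied = ok[ok["cv_rmse"] <= best_rmse + 1e-12]
    sort_cols = ["cost", "gamma"] + (["epsilon"] if variant == "epsilon" else ["nu"])
    winner = tied.sort_values(sort_cols, kind="stable").iloc[0]
    point = {k: winner[k] for k in sort_cols}
    best = SvrSpec(variant=variant, descriptor_subset=tuple(subset), **point)
    return best, table


# ---------------------------------------------------------------------------
# hierarchical model


@dataclass
class HsvrModel:
    """Ordered member models plus the meta-SVR over their predictions."""

    members: list[FittedSvr]
    meta: FittedSvr
    normalizer: Normalizer | None = None
    seed: int = 0
    gate_passed: bool | None = None
    member_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        if len(self.members) < 2:
            raise errors.ValidationError("an HSVR model needs at least two members")
        if len(self.meta.spec.descriptor_subset) != len(self.members):
            raise errors.ValidationError("meta input dimension must equal member count")
        if not self.member_labels:
            # letters A, B, C ... matching the usual local-model naming
            self.member_labels = [chr(ord("A") + i) for i in range(len(self.members))]

    def member_predictions(self, X: pd.DataFrame, normalized: bool = False) -> pd.DataFrame:
        for lab, m in zip(self.member_labels, self.members):
            missing = [c for c in m.spec.descriptor_subset if c not in X.columns]
            if missing:
                raise errors.ValidationError(
                    f"missing descriptor column(s) {missing} for member {lab}"
                )
        if normalized or self.normalizer is None:
            Xn = X
        else:
            needed = sorted({c for m in self.members for c in m.spec.descriptor_subset})
            Xn = (X[needed] - self.normalizer.means[needed]) / self.normalizer.scales[needed]
        return pd.DataFrame(
            {f"member_{lab}": m.predict(Xn) for lab, m in zip(self.member_labels, self.members)},
            index=X.index,
        )

    def predict(self, X: pd.DataFrame, normalized: bool = False) -> np.ndarray:
        preds = self.member_predictions(X, normalized=normalized)
        preds.columns = list(self.meta.spec.descriptor_subset)
        out = self.meta.predict(preds)
        if not np.all(np.isfinite(out)):
            raise errors.HsvrError("non-finite prediction")
        return out


def fit_meta(
    members: Sequence[FittedSvr],
    X: pd.DataFrame,
    y,
    meta_grid: Iterable[dict] | None = None,
    k_folds: int = 5,
    seed: int = 0,
    variant: str = "epsilon",
) -> FittedSvr:
    """Grid-search and fit the second-level SVR on member predictions only."""
    if len(members) < 2:
        raise errors.ValidationError("need at least two members for a meta model")
    y = np.asarray(y, float)
    feats = {}
    for i, m in enumerate(members):
        try:
            feats[f"m{i}"] = m.predict(X)
        except Exception as exc:
            raise errors.HsvrError(f"member {i} failed to predict") from exc
    F = pd.DataFrame(feats, index=X.index)
    grid = meta_grid if meta_grid is not None else compact_grid(variant)
    spec, _ = grid_search(variant, F, y, subset=list(F.columns), grid=grid,
                          k_folds=k_folds, seed=seed)
    return fit_svr(spec, F, y)


def build_ensemble(
    pool: Sequence[FittedSvr],
    X_train: pd.DataFrame,
    y_train,
    X_test: pd.DataFrame,
    y_test,
    criteria_gate: Callable[[PredictionSet], bool] | None = None,
    max_members: int = 4,
    meta_grid: Iterable[dict] | None = None,
    k_folds: int = 5,
    seed: int = 0,
    normalizer: Normalizer | None = None,
) -> HsvrModel:
    """Assemble the smallest ensemble whose meta-model passes the gate.

    Combinations are enumerated at sizes 2, 3, ... ``max_members`` in pool
    order (lexicographic index tuples); for each, a meta-SVR is fitted on
    training member predictions and the gate is evaluated on the held-out
    test set.  The first passing combination wins; if none passes, the
    best-scoring combination overall (highest external q^2) is returned
    with ``gate_passed=False``.
    """
    pool = list(pool)
    if len(pool) < 2:
        raise errors.ValidationError("candidate pool must contain at least two fitted members")
    subsets = [tuple(sorted(m.spec.descriptor_subset)) for m in pool]
    if len(set(subsets)) < len(subsets):
        raise errors.ValidationError("candidate members must use distinct descriptor subsets")
    y_train = np.asarray(y_train, float)
    y_test = np.asarray(y_test, float)

    train_mean = float(y_train.mean())
    train_ss = float(np.sum((y_train - train_mean) ** 2))
    if criteria_gate is None:
        criteria_gate = external_gate(
            train_mean=train_mean, n_train=len(y_train), train_ss=train_ss
        )

    def assemble(combo: tuple[int, ...]) -> tuple[HsvrModel, PredictionSet]:
        members = [pool[i] for i in combo]
        meta = fit_meta(members, X_train, y_train, meta_grid=meta_grid,
                        k_folds=k_folds, seed=seed)
        model = HsvrModel(members=members, meta=meta, normalizer=normalizer, seed=seed)
        yhat = model.predict(X_test, normalized=True)
        ps = PredictionSet(observed=y_test, predicted=yhat, label="test",
                           train_mean=train_mean, n_train=len(y_train), train_ss=train_ss)
        return model, ps

    best_model, best_score = None, -np.inf
    for size in range(2, min(max_members, len(pool)) + 1):
        for combo in itertools.combinations(range(len(pool)), size):
            model, ps = assemble(combo)
            if criteria_gate(ps):
                model.gate_passed = True
                return model
            score = validation.squared_correlation(ps)
            if score > best_score:
                best_model, best_score = model, score
    best_model.gate_passed = False
    return best_model


def external_gate(
    train_mean: float, n_train: int, train_ss: float | None = None
) -> Callable[[PredictionSet], bool]:
    """Gate callable: all applicable external criteria must be fulfilled."""

    def gate(ps: PredictionSet) -> bool:
        ps = replace_refs(ps, train_mean, n_train, train_ss)
        try:
            report = validation.validate_predictions(ps, context="external")
        except errors.HsvrError:
            return False
        return bool(report.criteria.get("overall_pass"))

    return gate


def replace_refs(
    ps: PredictionSet, train_mean: float, n_train: int, train_ss: float | None = None
) -> PredictionSet:
    return PredictionSet(
        observed=ps.observed, predicted=ps.predicted, ids=ps.ids, label=ps.label,
        train_mean=train_mean, n_train=n_train, train_ss=train_ss,
    )
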