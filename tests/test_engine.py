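"""SVR members, grid search, minimal-ensemble assembly, meta model."""

import numpy as np
import pandas as pd
import pytest

from hsvr import engine, errors, validation
from hsvr.engine import HsvrModel, SvrSpec, build_ensemble, fit_meta, fit_svr, grid_search
from hsvr.io import PredictionSet


def frame(arr, cols=None):
    arr = np.atleast_2d(np.asarray(arr, float))
    cols = cols or [f"x{i}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, columns=cols)


def spec(subset=("x0",), **kw):
    base = dict(variant="epsilon", gamma=1.0, cost=10.0, epsilon=0.1)
    base.update(kw)
    return SvrSpec(descriptor_subset=tuple(subset), **base)


# ---------------------------------------------------------------------------
# spec validation


def test_spec_variant_invariants():
    with pytest.raises(errors.ValidationError):
        SvrSpec(variant="epsilon", gamma=1, cost=1, nu=0.5, descriptor_subset=("a",))
    with pytest.raises(errors.ValidationError):
        SvrSpec(variant="nu", gamma=1, cost=1, nu=1.5, descriptor_subset=("a",))
    with pytest.raises(errors.ValidationError):
        SvrSpec(variant="epsilon", gamma=-1, cost=1, epsilon=0.1, descriptor_subset=("a",))


# ---------------------------------------------------------------------------
# member fitting


def test_constant_response_stays_in_epsilon_tube():
    X = frame(np.linspace(0, 1, 20).reshape(-1, 1))
    y = np.full(20, 3.0)
    fitted = fit_svr(spec(epsilon=0.1), X, y)
    pred = fitted.predict(X)
    assert np.all(pred >= 2.9 - 1e-9) and np.all(pred <= 3.1 + 1e-9)


def test_sine_curve_fits_well_with_generous_grid():
    rng = np.random.default_rng(0)
    x = np.sort(rng.uniform(0, 2 * np.pi, 50))
    X = frame(x.reshape(-1, 1))
    y = np.sin(x)
    best, _ = grid_search("epsilon", X, y, subset=("x0",), k_folds=5, seed=0)
    fitted = fit_svr(best, X, y)
    rmse = float(np.sqrt(np.mean((fitted.predict(X) - y) ** 2)))
    assert rmse < 0.1


def test_duplicated_training_row_barely_moves_prediction():
    rng = np.random.default_rng(1)
    x = np.linspace(-1, 1, 25)
    y = x**2 + rng.normal(0, 0.01, 25)
    X = frame(x.reshape(-1, 1))
    s = spec(cost=1e4, gamma=1.0, epsilon=0.01)
    single = fit_svr(s, X, y).predict(frame([[0.5]]))
    X2 = frame(np.concatenate([x, [0.5]]).reshape(-1, 1))
    y2 = np.concatenate([y, [0.25]])
    doubled = fit_svr(s, X2, y2).predict(frame([[0.5]]))
    assert abs(single[0] - doubled[0]) < 1e-2


def test_nu_variant_fits():
    x = np.linspace(0, 1, 30)
    y = 2 * x
    fitted = fit_svr(spec(variant="nu", epsilon=None, nu=0.5), frame(x.reshape(-1, 1)), y)
    assert np.corrcoef(fitted.predict(frame(x.reshape(-1, 1))), y)[0, 1] > 0.99


# ---------------------------------------------------------------------------
# grid search


def test_single_point_lattice_returned():
    x = np.linspace(0, 1, 20)
    X, y = frame(x.reshape(-1, 1)), x
    best, table = grid_search(
        "epsilon", X, y, subset=("x0",), grid=[{"cost": 2.0, "gamma": 0.5, "epsilon": 0.1}]
    )
    assert (best.cost, best.gamma, best.epsilon) == (2.0, 0.5, 0.1)
    assert len(table) == 1


def test_better_gamma_selected_and_recomputable():
    rng = np.random.default_rng(2)
    x = np.sort(rng.uniform(-2, 2, 60))
    X, y = frame(x.reshape(-1, 1)), np.tanh(x)
    grid = [{"cost": 10.0, "gamma": g, "epsilon": 0.05} for g in (1e-3, 1e3)]
    best, table = grid_search("epsilon", X, y, subset=("x0",), grid=grid, k_folds=5, seed=0)

    # independent recomputation of both CV RMSEs with the same fold plan
    from sklearn.model_selection import KFold
    from sklearn.svm import SVR

    kf = KFold(n_splits=5, shuffle=True, random_state=0)
    recomputed = {}
    for g in (1e-3, 1e3):
        sq = 0.0
        for tr, te in kf.split(X):
            m = SVR(kernel="rbf", C=10.0, gamma=g, epsilon=0.05)
            m.fit(X.iloc[tr], y[tr])
            resid = y[te] - m.predict(X.iloc[te])
            sq += float(resid @ resid)
        recomputed[g] = float(np.sqrt(sq / len(y)))
    assert best.gamma == min(recomputed, key=recomputed.get)
    for g, want in recomputed.items():
        got = table.loc[table["gamma"] == g, "cv_rmse"].iloc[0]
        assert got == pytest.approx(want, abs=1e-12)


def test_tie_break_prefers_smaller_cost_then_gamma():
    # constant y: every grid point predicts the mean within epsilon -> exact ties
    X = frame(np.linspace(0, 1, 20).reshape(-1, 1))
    y = np.full(20, 1.0)
    grid = [
        {"cost": c, "gamma": g, "epsilon": 0.5}
        for c in (8.0, 2.0)
        for g in (4.0, 0.25)
    ]
    best, _ = grid_search("epsilon", X, y, subset=("x0",), grid=grid)
    assert (best.cost, best.gamma) == (2.0, 0.25)


# ---------------------------------------------------------------------------
# meta model


def _members_on(X, y, subsets):
    return [
        fit_svr(spec(subset=s, cost=100.0, gamma=0.5, epsilon=0.01), X, y) for s in subsets
    ]


def test_meta_on_two_perfect_members():
    rng = np.random.default_rng(3)
    X = frame(rng.normal(size=(60, 2)), cols=["a", "b"])
    y = X["a"].to_numpy() + 0.5 * X["b"].to_numpy()

    class Exact:
        def __init__(self, subset):
            self.spec = spec(subset=subset)

        def predict(self, F):
            return F["a"].to_numpy() + 0.5 * F["b"].to_numpy()

    members = [Exact(("a", "b")), Exact(("a", "b"))]
    tight = [{"cost": 1e4, "gamma": 1.0, "epsilon": 1e-4}]
    meta = fit_meta(members, X, y, meta_grid=tight, seed=0)
    model_pred = meta.predict(
        pd.DataFrame({"m0": members[0].predict(X), "m1": members[1].predict(X)})
    )
    rmse = float(np.sqrt(np.mean((model_pred - y) ** 2)))
    assert rmse < 5e-3  # bounded below by the solver's numerical tolerance


def test_meta_recovers_from_offset_members():
    rng = np.random.default_rng(4)
    X = frame(rng.normal(size=(80, 1)), cols=["a"])
    y = np.sin(X["a"].to_numpy() * 2)

    class Offset:
        def __init__(self, delta):
            self.delta = delta
            self.spec = spec(subset=("a",))

        def predict(self, F):
            return y_lookup(F) + self.delta

    def y_lookup(F):
        return np.sin(F["a"].to_numpy() * 2)

    meta = fit_meta([Offset(0.5), Offset(-0.5)], X, y, seed=0)
    F = pd.DataFrame({"m0": y + 0.5, "m1": y - 0.5})
    rmse = float(np.sqrt(np.mean((meta.predict(F) - y) ** 2)))
    assert rmse < 0.05


def test_meta_predictions_mostly_inside_straddling_member_envelope():
    # when local models err on opposite sides of the response (the regime the
    # hierarchical scheme is designed for), the meta prediction tracks the
    # response and hence stays inside the member min-max envelope
    rng = np.random.default_rng(13)
    X = frame(rng.normal(size=(120, 1)), cols=["a"])
    y = np.sin(2 * X["a"].to_numpy())

    class Offset:
        def __init__(self, delta):
            self.delta = delta
            self.spec = spec(subset=("a",))

        def predict(self, F):
            return np.sin(2 * F["a"].to_numpy()) + self.delta

    members = [Offset(0.4), Offset(-0.4)]
    meta = fit_meta(members, X, y, seed=0)
    model = HsvrModel(members=members, meta=meta)
    member_preds = model.member_predictions(X, normalized=True).to_numpy()
    meta_pred = model.predict(X, normalized=True)
    lo, hi = member_preds.min(axis=1), member_preds.max(axis=1)
    inside = np.mean((meta_pred >= lo - 1e-9) & (meta_pred <= hi + 1e-9))
    assert inside >= 0.9


# ---------------------------------------------------------------------------
# ensemble assembly


def _synthetic_pool_and_data(seed=5):
    """Three members with complementary local views of a 3-part response."""
    rng = np.random.default_rng(seed)
    n = 240
    X = frame(rng.normal(size=(n, 3)), cols=["a", "b", "c"])
    y = (
        np.tanh(2 * X["a"].to_numpy())
        + np.tanh(2 * X["b"].to_numpy())
        + np.tanh(2 * X["c"].to_numpy())
    )
    tr = slice(0, 200)
    te = slice(200, 240)
    members = _members_on(X.iloc[tr], y[tr], [("a",), ("b",), ("c",)])
    return X, y, tr, te, members


def test_no_pair_passes_but_triple_does():
    X, y, tr, te, members = _synthetic_pool_and_data()
    X_tr, y_tr, X_te, y_te = X.iloc[tr], y[tr], X.iloc[te], y[te]

    def rmse_gate(ps):
        return float(np.sqrt(np.mean((ps.observed - ps.predicted) ** 2))) < 0.8

    # oracle: evaluate every pair and the triple directly before assembly
    import itertools

    def combo_rmse(combo):
        meta = fit_meta([members[i] for i in combo], X_tr, y_tr, seed=0)
        model = HsvrModel(members=[members[i] for i in combo], meta=meta)
        pred = model.predict(X_te, normalized=True)
        return float(np.sqrt(np.mean((y_te - pred) ** 2)))

    pair_rmses = [combo_rmse(c) for c in itertools.combinations(range(3), 2)]
    triple_rmse = combo_rmse((0, 1, 2))
    assert all(r >= 0.8 for r in pair_rmses) and triple_rmse < 0.8

    model = build_ensemble(members, X_tr, y_tr, X_te, y_te, criteria_gate=rmse_gate, seed=0)
    assert len(model.members) == 3 and model.gate_passed


def test_first_passing_pair_stops_search():
    X, y, tr, te, members = _synthetic_pool_and_data()
    X_tr, y_tr, X_te, y_te = X.iloc[tr], y[tr], X.iloc[te], y[te]
    calls = []

    def generous_gate(ps):
        calls.append(len(ps))
        return True

    model = build_ensemble(members, X_tr, y_tr, X_te, y_te, criteria_gate=generous_gate, seed=0)
    assert len(model.members) == 2
    assert len(calls) == 1  # the very first pair passed; no further combinations tried
    assert [m.spec.descriptor_subset for m in model.members] == [("a",), ("b",)]


def test_no_combination_passes_returns_best_with_flag():
    X, y, tr, te, members = _synthetic_pool_and_data()
    model = build_ensemble(
        members, X.iloc[tr], y[tr], X.iloc[te], y[te],
        criteria_gate=lambda ps: False, seed=0,
    )
    assert model.gate_passed is False
    assert len(model.members) == 3  # the richest combination scores best here


def test_pool_of_identical_subsets_rejected():
    X, y, tr, te, members = _synthetic_pool_and_data()
    with pytest.raises(errors.ValidationError):
        build_ensemble([members[0], members[0]], X.iloc[tr], y[tr], X.iloc[te], y[te])


# ---------------------------------------------------------------------------
# prediction contract


def test_predict_row_permutation_and_unused_columns(small_study):
    result = small_study["result"]
    desc = small_study["desc"].select_dtypes("number").iloc[:20]
    base = result.model.predict(desc)

    perm = np.random.default_rng(0).permutation(20)
    permuted = result.model.predict(desc.iloc[perm])
    assert np.array_equal(permuted, base[perm])

    extra = desc.copy()
    extra["unused_descriptor"] = 1.234
    # an unused column changes nothing because members select their own subsets
    with_extra = result.model.predict(
        pd.concat([extra], axis=1)[list(desc.columns) + ["unused_descriptor"]]
    )
    assert np.array_equal(with_extra, base)


def test_missing_descriptor_column_named_in_error(small_study):
    result = small_study["result"]
    desc = small_study["desc"].select_dtypes("number").drop(columns=["psa"]).iloc[:5]
    with pytest.raises(errors.ValidationError, match="psa"):
        result.model.predict(desc)


def test_training_rows_within_delta_max(small_study):
    result = small_study["result"]
    desc = small_study["desc"].select_dtypes("number")
    Xn = result.normalizer.transform(desc)
    train = Xn.loc[result.split.train_ids]
    pred = result.model.predict(train, normalized=True)
    y_tr = small_study["y"].loc[result.split.train_ids].to_numpy()
    assert np.max(np.abs(y_tr - pred)) <= result.train_report.delta_max + 1e-12


def test_determinism_same_seed_same_predictions(small_study):
    from hsvr import pipeline

    desc, y = small_study["desc"], small_study["y"]
    again = pipeline.fit_hsvr(desc, y, seed=7, k_folds_cv=5)
    base = small_study["result"]
    X = desc.select_dtypes("number").iloc[:15]
    assert np.array_equal(base.model.predict(X), again.model.predict(X))
    assert base.train_report.r2 == again.train_report.r2
    assert base.train_report.q_cv2 == again.train_report.q_cv2
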