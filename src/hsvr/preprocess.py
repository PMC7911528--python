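"""Descriptor-matrix preparation: normalization, intercorrelation filtering,
GA and RFE subset selection, PCA chemical space, outlier rules, splitting.

Normalization is centering and scaling by the (n-1)-denominator sample
standard deviation; parameters are always fit on training rows only and
applied to every row, avoiding train/test leakage.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold

from . import descriptors as _desc
from . import errors


# ---------------------------------------------------------------------------
# normalization


@dataclass
class Normalizer:
    """Column means and sample-std scales fit on a set of rows."""

    means: pd.Series
    scales: pd.Series

    def transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        cols = self.means.index
        return (frame[cols] - self.means) / self.scales

    def inverse_transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        cols = self.means.index
        return frame[cols] * self.scales + self.means


def fit_normalizer(
    frame: pd.DataFrame,
    fit_rows: Sequence | None = None,
    lenient: bool = False,
) -> Normalizer:
    """Fit centering/scaling parameters on ``fit_rows`` (default: all rows).

    Scale is the sample standard deviation (n-1 denominator).  A
    zero-variance column raises naming the column; in lenient mode it is
    dropped from the normalizer instead.
    """
    sub = frame.loc[list(fit_rows)] if fit_rows is not None else frame
    if len(sub) < 2:
        raise errors.ValidationError("normalization needs at least two fit rows")
    means = sub.mean()
    scales = sub.std(ddof=1)
    dead = scales.index[(scales == 0) | scales.isna()].tolist()
    if dead:
        if not lenient:
            raise errors.ValidationError(f"zero-variance column(s): {dead}")
        means = means.drop(dead)
        scales = scales.drop(dead)
    return Normalizer(means=means, scales=scales)


def normalize(
    frame: pd.DataFrame, fit_rows: Sequence | None = None, lenient: bool = False
) -> tuple[pd.DataFrame, Normalizer]:
    """Return the normalized matrix and its fitted parameters."""
    norm = fit_normalizer(frame, fit_rows, lenient=lenient)
    return norm.transform(frame), norm


# ---------------------------------------------------------------------------
# intercorrelation filter


def filter_intercorrelated(
    frame: pd.DataFrame,
    response: pd.Series | np.ndarray,
    threshold_r2: float = 0.64,
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Drop one member of every descriptor pair with Spearman rho^2 >= threshold.

    Of a violating pair, the column with the smaller absolute Spearman
    correlation to the response is dropped (ties: the lexicographically
    later name goes).  Pairs are resolved from the strongest
    intercorrelation down, which makes the result insensitive to column
    order.  Returns the retained column names and a log of
    (dropped, kept_partner, rho^2) entries.
    """
    if len(frame) < 3:
        raise errors.ValidationError("intercorrelation filter needs >= 3 rows")
    y = np.asarray(response, float)
    cols = list(frame.columns)
    if len(cols) < 2:
        return cols, []

    rho = frame.corr(method="spearman").to_numpy()
    resp_corr = {
        c: abs(stats.spearmanr(frame[c].to_numpy(float), y).statistic) for c in cols
    }
    # NaN response-correlation (constant column) sorts as weakest
    resp_corr = {c: (0.0 if not np.isfinite(v) else v) for c, v in resp_corr.items()}

    pairs = []
    for i, j in itertools.combinations(range(len(cols)), 2):
        r2 = rho[i, j] ** 2
        if not np.isfinite(r2):
            r2 = 1.0  # constant columns are treated as perfectly redundant
        if r2 >= threshold_r2:
            pairs.append((r2, cols[i], cols[j]))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))

    dropped: dict[str, tuple[str, float]] = {}
    for r2, a, b in pairs:
        if a in dropped or b in dropped:
            continue
        ca, cb = resp_corr[a], resp_corr[b]
        if ca > cb:
            loser, keeper = b, a
        elif cb > ca:
            loser, keeper = a, b
        else:
            loser, keeper = max(a, b), min(a, b)
        dropped[loser] = (keeper, r2)
    retained = [c for c in cols if c not in dropped]
    log = [(loser, keeper, r2) for loser, (keeper, r2) in dropped.items()]
    return retained, log


# ---------------------------------------------------------------------------
# CV-RMSE fitness shared by GA and RFE


def _default_model_factory():
    return Ridge(alpha=1.0)


def cv_rmse(
    X: pd.DataFrame,
    y: np.ndarray,
    columns: Sequence[str],
    model_factory: Callable = _default_model_factory,
    k_folds: int = 5,
    seed: int = 0,
) -> float:
    """k-fold CV RMSE of a base learner restricted to ``columns``."""
    if not columns:
        return float("inf")
    Xs = X[list(columns)].to_numpy(float)
    y = np.asarray(y, float)
    kf = KFold(n_splits=min(k_folds, len(y)), shuffle=True, random_state=seed)
    sq = 0.0
    for tr, te in kf.split(Xs):
        model = model_factory()
        model.fit(Xs[tr], y[tr])
        resid = y[te] - model.predict(Xs[te])
        sq += float(resid @ resid)
    return math.sqrt(sq / len(y))


# ---------------------------------------------------------------------------
# GA subset selection


def ga_select(
    X: pd.DataFrame,
    y,
    population: int = 24,
    generations: int = 12,
    seed: int = 0,
    fitness: Callable[[Sequence[str]], float] | None = None,
    model_factory: Callable = _default_model_factory,
    k_folds: int = 5,
    mutation_rate: float | None = None,
    elite: int = 2,
    n_best: int = 5,
) -> list[tuple[list[str], float]]:
    """Elitist genetic algorithm over binary descriptor masks.

    Fitness (minimized) defaults to the k-fold CV RMSE of a cheap base
    learner on the selected columns.  Returns the ``n_best`` subsets seen
    over the whole run, ranked by fitness (ties broken by smaller subsets,
    then lexicographic names, for determinism).
    """
    cols = list(X.columns)
    if not cols:
        raise errors.ValidationError("ga_select needs at least one candidate column")
    if population < 2:
        raise errors.ValidationError("population must be >= 2")
    y = np.asarray(y, float)
    if fitness is None:
        cache: dict[tuple[str, ...], float] = {}

        def fitness(subset):
            key = tuple(sorted(subset))
            if key not in cache:
                cache[key] = cv_rmse(X, y, key, model_factory, k_folds, seed)
            return cache[key]

    if len(cols) == 1:
        return [([cols[0]], float(fitness(cols)))]

    p = len(cols)
    rng = np.random.default_rng(seed)
    mut = mutation_rate if mutation_rate is not None else 1.0 / p

    def mask_cols(mask):
        return [c for c, m in zip(cols, mask) if m]

    def score(mask):
        return float(fitness(mask_cols(mask))) if mask.any() else float("inf")

    pop = rng.integers(0, 2, size=(population, p)).astype(bool)
    for i in range(min(population, p)):  # guarantee some singletons for coverage
        pop[i] = False
        pop[i, i % p] = True
    scores = np.array([score(m) for m in pop])

    seen: dict[tuple[str, ...], float] = {}

    def record(mask, s):
        key = tuple(mask_cols(mask))
        if key and (key not in seen or s < seen[key]):
            seen[key] = s

    for m, s in zip(pop, scores):
        record(m, s)

    if np.all(scores == scores[0]):
        ranked = sorted(seen.items(), key=lambda kv: (kv[1], len(kv[0]), kv[0]))
        return [(list(k), v) for k, v in ranked[:n_best]]

    for _ in range(generations):
        order = np.argsort(scores, kind="stable")
        elite_masks = pop[order[:elite]].copy()
        children = [*elite_masks]
        while len(children) < population:
            # tournament selection of two parents
            cand = rng.integers(0, population, size=4)
            pa = pop[cand[0]] if scores[cand[0]] <= scores[cand[1]] else pop[cand[1]]
            pb = pop[cand[2]] if scores[cand[2]] <= scores[cand[3]] else pop[cand[3]]
            cross = rng.random(p) < 0.5  # uniform crossover
            child = np.where(cross, pa, pb)
            flip = rng.random(p) < mut
            child = child ^ flip
            if not child.any():
                child[rng.integers(0, p)] = True
            children.append(child)
        pop = np.array(children[:population])
        scores = np.array([score(m) for m in pop])
        for m, s in zip(pop, scores):
            record(m, s)

    ranked = sorted(seen.items(), key=lambda kv: (kv[1], len(kv[0]), kv[0]))
    return [(list(k), v) for k, v in ranked[:n_best]]


# ---------------------------------------------------------------------------
# recursive feature elimination


def rfe_select(
    X: pd.DataFrame,
    y,
    model_factory: Callable = _default_model_factory,
    target_size: int = 1,
    k_folds: int = 5,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Backward elimination by leave-one-column-out CV performance.

    At each round every remaining column is tentatively removed and the
    model refit; the column whose removal degrades CV RMSE least (i.e.
    yields the lowest RMSE without it) is permanently removed.  Equal
    degradations within 1e-9 remove the lexicographically later name.
    Returns (elimination order, final subset).
    """
    cols = list(X.columns)
    if not (1 <= target_size <= len(cols)):
        raise errors.ValidationError(
            f"need 1 <= target_size ({target_size}) <= n columns ({len(cols)})"
        )
    y = np.asarray(y, float)
    eliminated: list[str] = []
    current = list(cols)
    round_idx = 0
    while len(current) > target_size:
        round_idx += 1
        best_col, best_score = None, float("inf")
        for col in current:
            remaining = [c for c in current if c != col]
            try:
                s = cv_rmse(X, y, remaining, model_factory, k_folds, seed)
            except Exception as exc:
                raise errors.HsvrError(f"model fit failed in RFE round {round_idx}") from exc
            if s < best_score - 1e-9 or (
                abs(s - best_score) <= 1e-9 and (best_col is None or col > best_col)
            ):
                best_col, best_score = col, min(s, best_score)
        eliminated.append(best_col)
        current.remove(best_col)
    return eliminated, current


# ---------------------------------------------------------------------------
# PCA chemical space and outlier detection


def pca_space(frame: pd.DataFrame, n_components: int = 3) -> dict:
    """Principal-component chemical space of a (normalized) matrix.

    Returns loadings (columns x components), scores (rows x components)
    and explained-variance fractions, ordered by decreasing variance.
    """
    Xv = frame.to_numpy(float)
    n, p = Xv.shape
    if n <= n_components:
        raise errors.ValidationError("need more rows than components")
    rank = int(np.linalg.matrix_rank(Xv - Xv.mean(axis=0)))
    if n_components > rank:
        raise errors.ValidationError(
            f"n_components={n_components} exceeds effective rank {rank}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Xv)
    return {
        "loadings": pd.DataFrame(
            pca.components_.T,
            index=frame.columns,
            columns=[f"PC{i + 1}" for i in range(n_components)],
        ),
        "scores": pd.DataFrame(
            scores, index=frame.index, columns=[f"PC{i + 1}" for i in range(n_components)]
        ),
        "explained_variance_ratio": pca.explained_variance_ratio_,
    }


def detect_outliers(
    scores: pd.DataFrame,
    descriptor_frame: pd.DataFrame | None = None,
    quantile: float = 0.99,
) -> set:
    """Union of the structural rule and a Mahalanobis distance rule.

    Distance rule: points whose squared Mahalanobis distance in PC space
    exceeds the chi-square quantile (df = number of components).  The
    structural rule flags rows of ``descriptor_frame`` with more than nine
    rings or more than 12 HBAs, regardless of their position in PC space.
    With fewer than 4 rows the distance rule is disabled.
    """
    flagged: set = set()
    if descriptor_frame is not None and {"n_ring", "hba"} <= set(descriptor_frame.columns):
        for idx, row in descriptor_frame.iterrows():
            if _desc.flag_structural_outlier(row["n_ring"], row["hba"]):
                flagged.add(idx)

    S = scores.to_numpy(float)
    n, d = S.shape
    if n >= 4:
        center = S.mean(axis=0)
        cov = np.cov(S, rowvar=False)
        cov = np.atleast_2d(cov)
        # pseudo-inverse guards degenerate (e.g. all-identical) score clouds
        inv = np.linalg.pinv(cov)
        diff = S - center
        d2 = np.einsum("ij,jk,ik->i", diff, inv, diff)
        cut = stats.chi2.ppf(quantile, df=d)
        degenerate = np.allclose(cov, 0.0)
        if not degenerate:
            flagged |= set(scores.index[d2 > cut])
    return flagged


# ---------------------------------------------------------------------------
# train/test splitting


@dataclass
class SplitResult:
    train_ids: list
    test_ids: list
    outlier_ids: list
    seed: int
    similarity: pd.DataFrame | None = None  # per-variable two-sample KS report
    loadings: pd.DataFrame | None = None
    explained_variance_ratio: np.ndarray | None = None

    def role_map(self) -> dict:
        roles = {i: "train" for i in self.train_ids}
        roles.update({i: "test" for i in self.test_ids})
        roles.update({i: "outlier" for i in self.outlier_ids})
        return roles


def split_dataset(
    ids: Sequence,
    ratio: float = 0.2,
    seed: int = 0,
    stratify_on: pd.Series | None = None,
    n_bins: int = 5,
    outlier_ids: Iterable = (),
    similarity_frame: pd.DataFrame | None = None,
) -> SplitResult:
    """Seeded random train/test partition at roughly 4:1 (``ratio`` = test
    fraction).

    With ``stratify_on`` (a response series) the split is balanced across
    quantile bins so per-bin ratios stay within one compound of the global
    ratio.  ``similarity_frame`` columns (e.g. log_papp, MW, SA, PSA, HBA,
    HBD, log P) are compared between train and test by two-sample
    Kolmogorov-Smirnov statistics and reported in the result.
    """
    outlier_ids = list(outlier_ids)
    pool = [i for i in ids if i not in set(outlier_ids)]
    if len(pool) < 5:
        raise errors.ValidationError("need at least 5 non-outlier compounds to split 4:1")
    rng = np.random.default_rng(seed)

    def pick_test(sub: list) -> list:
        n_test = int(round(len(sub) * ratio))
        n_test = max(0, min(len(sub), n_test))
        order = rng.permutation(len(sub))
        return [sub[k] for k in order[:n_test]]

    if stratify_on is not None:
        series = stratify_on.loc[pool]
        bins = pd.qcut(series, q=min(n_bins, max(1, len(pool) // 5)), duplicates="drop")
        test_ids = []
        for _, grp in series.groupby(bins, observed=True):
            test_ids.extend(pick_test(list(grp.index)))
    else:
        test_ids = pick_test(pool)
    if not test_ids:  # tiny sets still get one test compound
        test_ids = [pool[int(rng.integers(len(pool)))]]
    test_set = set(test_ids)
    train_ids = [i for i in pool if i not in test_set]

    similarity = None
    if similarity_frame is not None:
        rows = []
        for col in similarity_frame.columns:
            a = similarity_frame.loc[train_ids, col].dropna()
            b = similarity_frame.loc[[t for t in test_ids if t in similarity_frame.index], col].dropna()
            if len(a) >= 2 and len(b) >= 2:
                ks = stats.ks_2samp(a, b)
                rows.append({"variable": col, "ks_stat": ks.statistic, "p_value": ks.pvalue})
        similarity = pd.DataFrame(rows)

    return SplitResult(
        train_ids=train_ids,
        test_ids=sorted(test_ids, key=list(ids).index),
        outlier_ids=outlier_ids,
        seed=seed,
        similarity=similarity,
    )
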