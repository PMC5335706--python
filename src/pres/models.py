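"""Per-regimen response models: random forests over clinical + top-k probes.

The full fit for one treatment arm is: Welch-t screen -> RSS shortlist ->
choose the probe count k by stratified 5-fold cross-validation maximising
the F0.5 score at a 0.5 threshold (k = 0 is the clinical-only model) ->
refit a forest on all arm patients with the clinical encoding plus the
top-k ranked probes.  Out-of-fold probabilities repeat that entire fit
inside each of 10 stratified folds, so a patient's predicted probability
never uses their own data — in screening, ranking, k-selection or the
forest itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .datasets import CLINICAL_COLUMNS, CohortDataset, encode_clinical
from .screening import RandomSamplingScreen, WelchTScreen

DEFAULT_K_GRID: tuple[int, ...] = (0, 2, 4, 8, 13, 16, 24, 32, 50, 100)


@dataclass(frozen=True)
class F05Inputs:
    """Confusion counts at a decision threshold."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")


def f_beta(counts: F05Inputs, beta: float = 0.5) -> float:
    """F-beta from confusion counts; beta < 1 weights precision over recall.

    Defined as 0 when there are no true positives; undefined (raises) when
    tp + fp + fn == 0, i.e. no positives exist on either side.
    """
    if counts.tp + counts.fp + counts.fn == 0:
        raise ValueError("F-beta undefined: no actual or predicted positives")
    if counts.tp == 0:
        return 0.0
    precision = counts.tp / (counts.tp + counts.fp)
    recall = counts.tp / (counts.tp + counts.fn)
    b2 = beta * beta
    return (1 + b2) * precision * recall / (b2 * precision + recall)


def f_beta_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, beta: float = 0.5
) -> float:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return f_beta(
        F05Inputs(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        ),
        beta=beta,
    )


class RegimenResponseModel(BaseEstimator, ClassifierMixin):
    """Full per-arm pipeline as a single scikit-learn classifier.

    ``fit`` expects a samples x features DataFrame whose columns are the
    clinical encoding (see ``clinical_columns``) followed by probe columns;
    only probe columns are screened, clinical covariates are always
    included.  ``predict_proba`` returns columns ``[P(RD), P(pCR)]``.

    Attributes (after fit)
    ----------------------
    screen_ : WelchTScreen over the probe columns
    ranked_candidates_ : RSS-ordered shortlist of passers
    k_star_ : chosen probe count (ties broken toward the smallest k)
    cv_trace_ : DataFrame (k, mean_f05) over the evaluated grid
    selected_probes_ : the top-``k_star_`` candidates
    forest_ : fitted RandomForestClassifier
    oof_ready feature bookkeeping: feature_names_in_, clinical_columns_
    """

    def __init__(
        self,
        alpha: float = 0.05,
        rss_draws: int = 200,
        rss_fraction: float = 0.7,
        rss_max_probes: int = 200,
        rss_top_q: int = 50,
        rss_trees: int = 200,
        k_grid: tuple[int, ...] = DEFAULT_K_GRID,
        select_folds: int = 5,
        threshold: float = 0.5,
        n_trees: int = 1000,
        clinical_columns: tuple[str, ...] = CLINICAL_COLUMNS,
        random_state: int | None = None,
    ):
        self.alpha = alpha
        self.rss_draws = rss_draws
        self.rss_fraction = rss_fraction
        self.rss_max_probes = rss_max_probes
        self.rss_top_q = rss_top_q
        self.rss_trees = rss_trees
        self.k_grid = k_grid
        self.select_folds = select_folds
        self.threshold = threshold
        self.n_trees = n_trees
        self.clinical_columns = clinical_columns
        self.random_state = random_state

    # -- internal helpers ---------------------------------------------------

    def _split_columns(self, X: pd.DataFrame) -> tuple[list[str], list[str]]:
        clinical = [c for c in self.clinical_columns if c in X.columns]
        probes = [c for c in X.columns if c not in set(clinical)]
        return clinical, probes

    def _forest(self, seed: int) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_trees, random_state=seed, n_jobs=1
        )

    def _rank_candidates(
        self, X_probes: pd.DataFrame, y: np.ndarray, rng: np.random.Generator
    ) -> tuple[WelchTScreen, tuple[str, ...]]:
        screen = WelchTScreen(alpha=self.alpha).fit(X_probes, y)
        passers = screen.passers_frame()
        if passers.empty:
            return screen, ()
        rss = RandomSamplingScreen(
            n_draws=self.rss_draws,
            subsample_fraction=self.rss_fraction,
            max_probes=self.rss_max_probes,
            top_q=self.rss_top_q,
            n_trees=self.rss_trees,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(
            X_probes[list(passers["probe_id"])],
            y,
            p_values=list(passers["p_value"]),
        )
        return screen, rss.ranking_

    def _cv_select_k(
        self,
        X: pd.DataFrame,
        y: np.ndarray,
        clinical: list[str],
        candidates: tuple[str, ...],
        rng: np.random.Generator,
    ) -> tuple[int, pd.DataFrame]:
        grid = sorted({k for k in self.k_grid if 0 <= k <= len(candidates)})
        if not grid:
            grid = [0]
        folds = StratifiedKFold(
            n_splits=self.select_folds,
            shuffle=True,
            random_state=int(rng.integers(2**31 - 1)),
        )
        splits = list(folds.split(X, y))
        scores = {k: [] for k in grid}
        for train_idx, test_idx in splits:
            fold_seed = int(rng.integers(2**31 - 1))
            for k in grid:
                cols = clinical + list(candidates[:k])
                forest = self._forest(fold_seed)
                forest.fit(X.iloc[train_idx][cols], y[train_idx])
                prob = forest.predict_proba(X.iloc[test_idx][cols])
                prob = prob[:, list(forest.classes_).index(1)]
                pred = (prob >= self.threshold).astype(int)
                scores[k].append(
                    f_beta_from_predictions(y[test_idx], pred, beta=0.5)
                )
        trace = pd.DataFrame(
            {"k": grid, "mean_f05": [float(np.mean(scores[k])) for k in grid]}
        )
        best = float(trace["mean_f05"].max())
        k_star = int(trace.loc[trace["mean_f05"] == best, "k"].min())
        return k_star, trace

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = np.asarray(y).astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both pCR and RD")
        rng = np.random.default_rng(self.random_state)
        clinical, probes = self._split_columns(X)
        self.screen_, self.ranked_candidates_ = self._rank_candidates(
            X[probes], y, rng
        )
        self.k_star_, self.cv_trace_ = self._cv_select_k(
            X, y, clinical, self.ranked_candidates_, rng
        )
        self.selected_probes_ = tuple(self.ranked_candidates_[: self.k_star_])
        cols = clinical + list(self.selected_probes_)
        self.model_columns_ = tuple(cols)
        self.clinical_columns_ = tuple(clinical)
        self.forest_ = self._forest(int(rng.integers(2**31 - 1)))
        self.forest_.fit(X[cols], y)
        self.classes_ = self.forest_.classes_
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.age_median_ = (
            float(X["age"].median()) if "age" in X.columns else 50.0
        )
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "forest_")
        X = pd.DataFrame(X)
        missing = [c for c in self.model_columns_ if c not in X.columns]
        if missing:
            raise KeyError(f"missing model variables: {missing}")
        return self.forest_.predict_proba(X[list(self.model_columns_)])

    def predict_pcr_probability(self, X) -> np.ndarray:
        """Probability of pCR (fraction of trees voting pCR)."""
        prob = self.predict_proba(X)
        return prob[:, list(self.classes_).index(1)]

    def predict(self, X) -> np.ndarray:
        return (self.predict_pcr_probability(X) >= self.threshold).astype(int)


# ---------------------------------------------------------------------------
# dataset-level wrappers and the out-of-fold protocol


def design_matrix(dataset: CohortDataset, age_fill: float | None = None) -> pd.DataFrame:
    """Clinical encoding followed by probe columns, one row per sample."""
    clin = encode_clinical(dataset.clinical, age_fill=age_fill)
    expr = dataset.expression.to_frame().T
    expr.index = list(dataset.sample_ids)
    return pd.concat([clin, expr], axis=1)


def fit_regimen_model(
    dataset: CohortDataset, regimen: str, seed: int | None = None, **params
) -> RegimenResponseModel:
    group = dataset.regimen_subset(regimen)
    X = design_matrix(group)
    model = RegimenResponseModel(random_state=seed, **params)
    return model.fit(X, group.response_vector())


def select_k(
    dataset: CohortDataset,
    regimen: str,
    ranked_candidates: tuple[str, ...],
    k_grid: tuple[int, ...] = DEFAULT_K_GRID,
    folds: int = 5,
    threshold: float = 0.5,
    seed: int | None = None,
    **params,
) -> tuple[int, pd.DataFrame]:
    """Probe-count selection alone (the inner CV of the full fit)."""
    group = dataset.regimen_subset(regimen)
    X = design_matrix(group)
    y = group.response_vector()
    model = RegimenResponseModel(
        k_grid=k_grid,
        select_folds=folds,
        threshold=threshold,
        random_state=seed,
        **params,
    )
    clinical, _ = model._split_columns(X)
    rng = np.random.default_rng(seed)
    return model._cv_select_k(X, y, clinical, tuple(ranked_candidates), rng)


def out_of_fold_probabilities(
    model: RegimenResponseModel,
    X: pd.DataFrame,
    y: np.ndarray,
    folds: int = 10,
    random_state: int | None = None,
) -> pd.Series:
    """Nested out-of-fold pCR probabilities.

    Each patient's probability comes from a clone of ``model`` fitted on the
    other folds only; the entire pipeline (screen, RSS, k-selection, forest)
    is re-run inside every fold.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y).astype(int)
    if len(y) < folds:
        raise ValueError("fewer patients than folds")
    splitter = StratifiedKFold(
        n_splits=folds, shuffle=True, random_state=random_state
    )
    rng = np.random.default_rng(random_state)
    oof = np.full(len(y), np.nan)
    for train_idx, test_idx in splitter.split(X, y):
        fold_model = clone(model)
        fold_model.set_params(random_state=int(rng.integers(2**31 - 1)))
        fold_model.fit(X.iloc[train_idx], y[train_idx])
        oof[test_idx] = fold_model.predict_pcr_probability(X.iloc[test_idx])
    return pd.Series(oof, index=X.index, name="oof_probability")


def oof_predict(
    dataset: CohortDataset,
    regimen: str,
    folds: int = 10,
    seed: int | None = None,
    **params,
) -> pd.Series:
    group = dataset.regimen_subset(regimen)
    X = design_matrix(group)
    model = RegimenResponseModel(random_state=seed, **params)
    return out_of_fold_probabilities(
        model, X, group.response_vector(), folds=folds, random_state=seed
    )
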