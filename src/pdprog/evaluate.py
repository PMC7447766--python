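"""Two-layered cross-validation and one-vs-rest AUC reporting.

The outer layer repeatedly holds out 25% of *subjects* (splitting by
subject, not visit-row, so within-subject correlation cannot leak);
the inner layer is a k-fold grid search over hyperparameters on the
training subjects.  One-vs-rest AUCs per class (and per horizon for
multitask models) are aggregated over outer iterations as mean, SD,
and quartiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import NCI, PDD, STATUS_LABELS, first_visits
from .mixed import DEFAULT_STATUS_COVARIATES, fit_ordinal_mixed, predict_status_proba
from .tgl import (
    DEFAULT_TGL_FEATURES,
    Hyperparams,
    WeightMatrix,
    average_weights,
    build_task_dataset,
    fit_tgl,
    horizon_labels,
    predict_ordinal_proba,
)


class SingleClassError(ValueError):
    """Labels contain a single class; the AUC is undefined."""


def auc_one_vs_rest(scores, labels) -> float:
    """Mann-Whitney AUC: (concordant + 0.5 * tied) / (n_pos * n_neg)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise SingleClassError("both classes must be present to compute an AUC")
    # rank-sum formulation with midranks for ties
    alls = np.concatenate([pos, neg])
    order = np.argsort(alls, kind="mergesort")
    ranks = np.empty(len(alls))
    ranks[order] = np.arange(1, len(alls) + 1)
    # midranks
    sorted_vals = alls[order]
    i = 0
    while i < len(alls):
        j = i
        while j + 1 < len(alls) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        if j > i:
            ranks[order[i : j + 1]] = (i + j + 2) / 2.0
        i = j + 1
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


@dataclass
class CVScheme:
    n_outer: int = 100
    holdout_fraction: float = 0.25
    inner_folds: int = 5
    seed: int = 0
    max_resample: int = 20

    def validate(self) -> None:
        if not 0.0 < self.holdout_fraction < 1.0:
            raise ValueError("holdout_fraction must be in (0, 1)")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")
        if self.n_outer < 1:
            raise ValueError("n_outer must be >= 1")


def subject_split(cohort: pd.DataFrame, holdout_fraction: float, rng) -> tuple:
    subjects = np.unique(cohort["subject_id"].to_numpy())
    n_hold = max(1, int(round(holdout_fraction * len(subjects))))
    held = rng.choice(subjects, size=n_hold, replace=False)
    held_set = set(held)
    test = cohort[cohort["subject_id"].isin(held_set)]
    train = cohort[~cohort["subject_id"].isin(held_set)]
    assert not set(train["subject_id"]) & set(test["subject_id"])
    return train, test


def _split_ok(train, test) -> bool:
    return (
        train["status"].nunique() == 3
        and test["status"].nunique() >= 2
    )


# --- model adapters --------------------------------------------------------


class MixedStatusModel:
    """Ordinal mixed model scored per visit-row (random intercept at 0)."""

    def __init__(self, covariates=None, n_quad: int = 21):
        self.covariates = covariates or DEFAULT_STATUS_COVARIATES
        self.n_quad = n_quad
        self.fit_ = None

    def fit(self, train: pd.DataFrame, rng=None, inner_folds: int = 5):
        self.fit_ = fit_ordinal_mixed(train, self.covariates, n_quad=self.n_quad)
        return self

    def score_frame(self, test: pd.DataFrame) -> pd.DataFrame:
        probs = predict_status_proba(self.fit_, test)
        rows = []
        for k, label in STATUS_LABELS.items():
            rows.append(pd.DataFrame({
                "class": label,
                "horizon": -1,
                "score": probs[:, k],
                "label": (test["status"].to_numpy() == k).astype(int),
            }))
        return pd.concat(rows, ignore_index=True)


class TGLStatusModel:
    """Ordinal TGL pair with inner-CV selection of (theta1, theta2, theta3)."""

    def __init__(self, features=None, horizons=range(6),
                 theta_grid=None, max_iter: int = 500):
        self.features = features or DEFAULT_TGL_FEATURES
        self.horizons = list(horizons)
        self.theta_grid = theta_grid  # iterable of Hyperparams, or None
        self.max_iter = max_iter
        self.models_: tuple[WeightMatrix, WeightMatrix] | None = None
        self.standardizer_ = None
        self.theta_ = None

    def _candidates(self):
        if self.theta_grid is not None:
            return list(self.theta_grid)
        vals = np.logspace(-3, 2, 6)
        # one shared magnitude per theta keeps the default grid affordable
        return [Hyperparams(v, v, v) for v in vals]

    def _fit_pair(self, cohort, standardizer):
        models = []
        for target in (NCI, PDD):
            ds = build_task_dataset(cohort, target, self.features, self.horizons, standardizer)
            models.append(fit_tgl(ds, self.theta_, max_iter=self.max_iter))
        return tuple(models)

    def _standardizer(self, cohort):
        base = first_visits(cohort)
        F = base[self.features].to_numpy(float)
        mu = F.mean(axis=0)
        sd = F.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        return mu, sd

    def fit(self, train: pd.DataFrame, rng=None, inner_folds: int = 5):
        rng = rng or np.random.default_rng(0)
        cands = self._candidates()
        if len(cands) == 1:
            self.theta_ = cands[0]
        else:
            subjects = np.unique(train["subject_id"].to_numpy())
            perm = rng.permutation(subjects)
            folds = np.array_split(perm, inner_folds)
            mean_auc = []
            for theta in cands:
                self.theta_ = theta
                aucs = []
                for k in range(inner_folds):
                    held = set(folds[k])
                    tr = train[~train["subject_id"].isin(held)]
                    te = train[train["subject_id"].isin(held)]
                    if tr["status"].nunique() < 3 or te.empty:
                        continue
                    std = self._standardizer(tr)
                    try:
                        models = self._fit_pair(tr, std)
                        sf = self._score(models, std, te)
                        for (_, _), grp in sf.groupby(["class", "horizon"]):
                            try:
                                aucs.append(auc_one_vs_rest(grp["score"], grp["label"]))
                            except SingleClassError:
                                pass
                    except ValueError:
                        continue
                mean_auc.append(np.mean(aucs) if aucs else -np.inf)
            self.theta_ = cands[int(np.argmax(mean_auc))]
        self.standardizer_ = self._standardizer(train)
        self.models_ = self._fit_pair(train, self.standardizer_)
        return self

    def _score(self, models, standardizer, test: pd.DataFrame) -> pd.DataFrame:
        base = first_visits(test)
        mu, sd = standardizer
        Z = (base[self.features].to_numpy(float) - mu) / sd
        probs = predict_ordinal_proba(models, Z)  # (n, t, 3)
        labels = horizon_labels(test, self.horizons)
        sid_to_row = {s: i for i, s in enumerate(base["subject_id"])}
        rows = []
        for h_i, h in enumerate(self.horizons):
            sub = labels[labels["horizon"] == h]
            if sub.empty:
                continue
            ridx = [sid_to_row[s] for s in sub["subject_id"]]
            truth = sub["status"].to_numpy()
            for k, label in STATUS_LABELS.items():
                rows.append(pd.DataFrame({
                    "class": label,
                    "horizon": h,
                    "score": probs[ridx, h_i, k],
                    "label": (truth == k).astype(int),
                }))
        return pd.concat(rows, ignore_index=True)

    def score_frame(self, test: pd.DataFrame) -> pd.DataFrame:
        return self._score(self.models_, self.standardizer_, test)


# --- harness ---------------------------------------------------------------


def run_nested_cv(cohort: pd.DataFrame, model, scheme: CVScheme,
                  imputer=None) -> tuple[pd.DataFrame, object]:
    """Outer holdout iterations around ``model``; returns (report, final).

    ``model`` must expose ``fit(train, rng, inner_folds)`` and
    ``score_frame(test) -> DataFrame[class, horizon, score, label]``.
    ``imputer``, if given, is called as ``imputer(train, test) ->
    (train, test)`` so fill-in statistics come from training data only.
    The final model is refit on the full cohort, except that TGL models
    are the average of the outer-iteration weights.
    """
    scheme.validate()
    rng = np.random.default_rng(scheme.seed)
    per_iter: list[pd.DataFrame] = []
    outer_models = []
    for it in range(scheme.n_outer):
        for attempt in range(scheme.max_resample):
            train, test = subject_split(cohort, scheme.holdout_fraction, rng)
            if _split_ok(train, test):
                break
        else:
            raise RuntimeError(
                f"could not find a class-complete split in {scheme.max_resample} attempts"
            )
        if imputer is not None:
            train, test = imputer(train, test)
        model.fit(train, rng=rng, inner_folds=scheme.inner_folds)
        sf = model.score_frame(test)
        rows = []
        for (cls, h), grp in sf.groupby(["class", "horizon"]):
            try:
                a = auc_one_vs_rest(grp["score"], grp["label"])
            except SingleClassError:
                continue
            rows.append({"iteration": it, "class": cls, "horizon": h, "auc": a})
        per_iter.append(pd.DataFrame(rows))
        if isinstance(getattr(model, "models_", None), tuple):
            outer_models.append(model.models_)
    detail = pd.concat(per_iter, ignore_index=True)
    report = (
        detail.groupby(["class", "horizon"])["auc"]
        .agg(
            mean_auc="mean",
            sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0,
            q1=lambda s: s.quantile(0.25),
            q2="median",
            q3=lambda s: s.quantile(0.75),
            n_iterations="count",
        )
        .reset_index()
    )
    report.attrs["aggregate_mean_auc"] = float(detail["auc"].mean())
    report.attrs["detail"] = detail

    if outer_models:
        final = (
            average_weights([m[0] for m in outer_models]),
            average_weights([m[1] for m in outer_models]),
        )
    else:
        if imputer is not None:
            full, _ = imputer(cohort, cohort.iloc[:0])
        else:
            full = cohort
        final = model.fit(full, rng=rng, inner_folds=scheme.inner_folds)
    return report, final


def median_fold_imputer(columns=None):
    """Imputer hook for run_nested_cv: training-fold medians fill both sides."""
    from .impute import DEFAULT_CONTEXT_COLUMNS, DEFAULT_IMPUTE_COLUMNS

    cols = columns or (DEFAULT_IMPUTE_COLUMNS + DEFAULT_CONTEXT_COLUMNS)

    def _imp(train, test):
        train = train.copy()
        test = test.copy()
        for c in cols:
            if c not in train.columns:
                continue
            med = train[c].median()
            train[c] = train[c].fillna(med)
            if len(test):
                test[c] = test[c].fillna(med)
        return train, test

    return _imp
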