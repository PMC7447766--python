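"""Temporal grouped LASSO (TGL) multitask logistic models.

Predicts cognitive status 0-5 years after the first visit from
first-visit data.  Each task i is a binary logistic model for one
horizon; tasks share a weight matrix W in R^{d x t} (column i = task i)
with per-task biases c in R^t, fitted by minimizing

    sum_i sum_j log(1 + exp(-Y_ij (W_i' X_ij + c_i)))
      + theta1 ||W||_F^2 + theta2 ||W H||_F^2 + theta3 ||W||_{2,1}

where H is the first-difference (temporal smoothness) matrix and
||W||_{2,1} = sum over feature rows of the Euclidean norm across tasks,
which selects features jointly across horizons.  The solver is FISTA:
proximal gradient on the smooth part with row-wise group
soft-thresholding for the theta3 term and backtracking line search.

The ordinal extension fits two such models -- P(NCI) and P(PDD) against
the rest -- and derives P(MCI) = 1 - P(NCI) - P(PDD), clipped and
renormalized when the subtraction leaves the simplex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import NCI, PDD, TEST_COLUMNS, first_visits

DEFAULT_TGL_FEATURES = TEST_COLUMNS + [
    "age_years",
    "sex",
    "education_years",
    "disease_duration_years",
    "ledd_mg",
    "gds15",
    "apoe4",
    "gba",
    "mapt_h1",
]

DEFAULT_THETA_GRID = tuple(np.logspace(-3, 2, 6))


@dataclass
class Hyperparams:
    theta1: float = 0.01  # ridge
    theta2: float = 0.01  # temporal smoothness
    theta3: float = 0.01  # group sparsity

    def __post_init__(self):
        if min(self.theta1, self.theta2, self.theta3) < 0:
            raise ValueError("regularization parameters must be nonnegative")


@dataclass
class TaskDataset:
    """Per-horizon design matrices and +/-1 labels sharing one feature set."""

    X: list[np.ndarray]  # task i -> (n_i, d)
    y: list[np.ndarray]  # task i -> (n_i,) in {-1, +1}
    feature_names: list[str]
    horizons: list[int]
    single_class_tasks: list[int] = field(default_factory=list)

    @property
    def t(self) -> int:
        return len(self.X)

    @property
    def d(self) -> int:
        return len(self.feature_names)

    def validate(self) -> None:
        for i, (Xi, yi) in enumerate(zip(self.X, self.y)):
            if Xi.shape[1] != self.d:
                raise ValueError(f"task {i}: feature count {Xi.shape[1]} != {self.d}")
            if Xi.shape[0] != yi.shape[0]:
                raise ValueError(f"task {i}: X/y length mismatch")
            if not np.all(np.isin(yi, (-1, 1))):
                raise ValueError(f"task {i}: labels must be -1/+1")


@dataclass
class WeightMatrix:
    W: np.ndarray  # (d, t)
    c: np.ndarray  # (t,)
    feature_names: list[str]
    horizons: list[int]
    converged: bool = True
    objective: float = np.nan

    def scores(self, X: np.ndarray) -> np.ndarray:
        """(n, t) decision values X W + c."""
        return X @ self.W + self.c


def build_smoothness_matrix(t: int) -> np.ndarray:
    """First-difference matrix H in R^{t x (t-1)}: H[i,i]=1, H[i+1,i]=-1."""
    if t < 2:
        raise ValueError("need at least 2 tasks for a temporal prior")
    H = np.zeros((t, t - 1))
    idx = np.arange(t - 1)
    H[idx, idx] = 1.0
    H[idx + 1, idx] = -1.0
    return H


def l21_norm(W: np.ndarray) -> float:
    return float(np.sqrt((W**2).sum(axis=1)).sum())


def tgl_objective(W: np.ndarray, c: np.ndarray, data: TaskDataset, theta: Hyperparams) -> float:
    """Full TGL objective (logistic loss + all three penalties)."""
    if W.shape != (data.d, data.t) or c.shape != (data.t,):
        raise ValueError("W/c shapes inconsistent with dataset")
    H = build_smoothness_matrix(data.t) if data.t >= 2 else None
    loss = 0.0
    for i in range(data.t):
        margin = data.y[i] * (data.X[i] @ W[:, i] + c[i])
        loss += float(np.logaddexp(0.0, -margin).sum())
    pen = theta.theta1 * float((W**2).sum())
    if H is not None:
        pen += theta.theta2 * float(((W @ H) ** 2).sum())
    pen += theta.theta3 * l21_norm(W)
    return loss + pen


def group_row_prox(row: np.ndarray, threshold: float) -> np.ndarray:
    """Proximal map of threshold * ||.||_2: group soft-thresholding.

    Rows with norm <= threshold (ties included) map to the zero row.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    nrm = float(np.linalg.norm(row))
    if nrm <= threshold:
        return np.zeros_like(row)
    return (1.0 - threshold / nrm) * row


def _row_prox_matrix(W: np.ndarray, threshold: float) -> np.ndarray:
    if threshold == 0:
        return W
    norms = np.linalg.norm(W, axis=1, keepdims=True)
    scale = np.where(norms > threshold, 1.0 - threshold / np.where(norms > 0, norms, 1.0), 0.0)
    return W * scale


def _smooth_value_grad(W, c, data: TaskDataset, theta: Hyperparams, H, HHt):
    """Value and gradient of the smooth part (loss + theta1 + theta2 terms)."""
    val = 0.0
    gW = np.zeros_like(W)
    gc = np.zeros_like(c)
    for i in range(data.t):
        z = data.X[i] @ W[:, i] + c[i]
        margin = data.y[i] * z
        val += float(np.logaddexp(0.0, -margin).sum())
        # d/dz log(1+exp(-y z)) = -y * sigmoid(-y z)
        gz = -data.y[i] * expit(-margin)
        gW[:, i] = data.X[i].T @ gz
        gc[i] = gz.sum()
    val += theta.theta1 * float((W**2).sum())
    gW += 2.0 * theta.theta1 * W
    if H is not None and theta.theta2 > 0:
        WH = W @ H
        val += theta.theta2 * float((WH**2).sum())
        gW += 2.0 * theta.theta2 * (W @ HHt)
    return val, gW, gc


def null_bias(data: TaskDataset) -> np.ndarray:
    """Per-task intercepts of the null (W = 0) logistic model: logit prevalence."""
    c = np.zeros(data.t)
    for i in range(data.t):
        p = float(np.mean(data.y[i] == 1))
        p = min(max(p, 1e-12), 1 - 1e-12)
        c[i] = np.log(p / (1 - p))
    return c


def theta3_max(data: TaskDataset, theta: Hyperparams | None = None) -> float:
    """Smallest theta3 for which W = 0 (with null biases) is optimal."""
    c = null_bias(data)
    # Both quadratic penalty gradients vanish at W = 0, so only the loss
    # gradient matters here.
    _, gW, _ = _smooth_value_grad(
        np.zeros((data.d, data.t)), c, data, Hyperparams(0.0, 0.0, 0.0), None, None
    )
    return float(np.linalg.norm(gW, axis=1).max())


def fit_tgl(
    data: TaskDataset,
    theta: Hyperparams,
    max_iter: int = 2000,
    tol: float = 1e-8,
    W0: np.ndarray | None = None,
    c0: np.ndarray | None = None,
) -> WeightMatrix:
    """FISTA with backtracking; monotone via restart on objective increase.

    Stops when the relative objective change falls below ``tol`` or after
    ``max_iter`` iterations (then flagged unconverged).
    """
    data.validate()
    d, t = data.d, data.t
    H = build_smoothness_matrix(t) if t >= 2 else None
    HHt = H @ H.T if H is not None else None
    W = np.zeros((d, t)) if W0 is None else W0.copy()
    c = null_bias(data) if c0 is None else c0.copy()
    Wy, cy = W.copy(), c.copy()
    L = 1.0
    tk = 1.0
    obj = tgl_objective(W, c, data, theta)
    converged = False
    for _ in range(max_iter):
        f_y, gW, gc = _smooth_value_grad(Wy, cy, data, theta, H, HHt)
        if not (np.all(np.isfinite(gW)) and np.all(np.isfinite(gc))):
            raise FloatingPointError("non-finite gradient in TGL solver")
        while True:
            W_new = _row_prox_matrix(Wy - gW / L, theta.theta3 / L)
            c_new = cy - gc / L
            f_new, _, _ = _smooth_value_grad(W_new, c_new, data, theta, H, HHt)
            dW, dc = W_new - Wy, c_new - cy
            quad = (
                f_y
                + float((gW * dW).sum())
                + float(gc @ dc)
                + 0.5 * L * (float((dW**2).sum()) + float(dc @ dc))
            )
            if f_new <= quad + 1e-12 * abs(quad):
                break
            L *= 2.0
            if L > 1e15:
                break
        obj_new = tgl_objective(W_new, c_new, data, theta)
        if obj_new > obj:  # monotone safeguard: restart momentum from (W, c)
            Wy, cy = W.copy(), c.copy()
            tk = 1.0
            f_y, gW, gc = _smooth_value_grad(Wy, cy, data, theta, H, HHt)
            W_new = _row_prox_matrix(Wy - gW / L, theta.theta3 / L)
            c_new = cy - gc / L
            obj_new = tgl_objective(W_new, c_new, data, theta)
            if obj_new > obj:
                converged = True  # cannot descend further at machine precision
                break
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tk**2))
        Wy = W_new + ((tk - 1.0) / t_new) * (W_new - W)
        cy = c_new + ((tk - 1.0) / t_new) * (c_new - c)
        W, c, tk = W_new, c_new, t_new
        if abs(obj - obj_new) <= tol * max(1.0, abs(obj)):
            obj = obj_new
            converged = True
            break
        obj = obj_new
    return WeightMatrix(
        W=W, c=c, feature_names=list(data.feature_names), horizons=list(data.horizons),
        converged=converged, objective=float(obj),
    )


# ---------------------------------------------------------------------------
# Horizon construction from a cohort table


def horizon_labels(
    cohort: pd.DataFrame, horizons: range | list[int] = range(6), window: float = 0.5
) -> pd.DataFrame:
    """Status of each subject at each integer-year horizon after first visit.

    Horizon n uses the visit whose time since first visit is nearest to n
    within +/- ``window`` years; subjects with no visit in the window are
    absent from that horizon.  Long format: subject_id, horizon, status.
    """
    rows = []
    for sid, grp in cohort.groupby("subject_id"):
        times = grp["visit_time_years"].to_numpy(float)
        t0 = times.min()
        rel = times - t0
        for n in horizons:
            dist = np.abs(rel - n)
            j = int(np.argmin(dist))
            if dist[j] <= window:
                rows.append({"subject_id": sid, "horizon": int(n),
                             "status": int(grp["status"].to_numpy()[j])})
    return pd.DataFrame(rows, columns=["subject_id", "horizon", "status"])


def build_task_dataset(
    cohort: pd.DataFrame,
    target: int,
    features: list[str] | None = None,
    horizons: range | list[int] = range(6),
    standardizer: tuple[np.ndarray, np.ndarray] | None = None,
) -> TaskDataset:
    """One-vs-rest task dataset for ``target`` status from first-visit data.

    Labels are +1 where the horizon status equals ``target``.  Features
    are z-scored with the provided (mean, sd) -- fit them on training
    data only -- or with this cohort's own statistics if none given.
    """
    features = DEFAULT_TGL_FEATURES if features is None else list(features)
    base = first_visits(cohort)
    F = base[features].to_numpy(float)
    if np.isnan(F).any():
        raise ValueError("first-visit features contain missing values; impute first")
    if standardizer is None:
        mu = F.mean(axis=0)
        sd = F.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
    else:
        mu, sd = standardizer
    Z = (F - mu) / sd
    feat_by_subject = dict(zip(base["subject_id"], Z))
    labels = horizon_labels(cohort, horizons)
    X, y, single = [], [], []
    horizons = list(horizons)
    for i, n in enumerate(horizons):
        sub = labels[labels["horizon"] == n]
        Xi = np.array([feat_by_subject[s] for s in sub["subject_id"]]) if len(sub) else np.empty((0, len(features)))
        yi = np.where(sub["status"].to_numpy() == target, 1.0, -1.0) if len(sub) else np.empty(0)
        X.append(Xi)
        y.append(yi)
        if len(np.unique(yi)) < 2:
            single.append(i)
    ds = TaskDataset(X=X, y=y, feature_names=features, horizons=horizons,
                     single_class_tasks=single)
    ds.validate()
    return ds


def fit_ordinal_tgl(
    cohort: pd.DataFrame,
    features: list[str] | None = None,
    theta: Hyperparams | None = None,
    horizons: range | list[int] = range(6),
    standardizer: tuple[np.ndarray, np.ndarray] | None = None,
    **solver_kwargs,
) -> tuple[WeightMatrix, WeightMatrix]:
    """Fit the NCI-vs-rest and PDD-vs-rest TGL models on first-visit data."""
    theta = theta or Hyperparams()
    models = []
    for target in (NCI, PDD):
        ds = build_task_dataset(cohort, target, features, horizons, standardizer)
        models.append(fit_tgl(ds, theta, **solver_kwargs))
    return models[0], models[1]


def predict_ordinal_proba(
    models: tuple[WeightMatrix, WeightMatrix], X: np.ndarray
) -> np.ndarray:
    """Per-horizon class probabilities (n, t, 3): NCI, MCI, PDD.

    P(MCI) = 1 - P(NCI) - P(PDD); if negative, the triple is clipped to
    [0, 1] and renormalized to sum to 1.
    """
    m_nci, m_pdd = models
    if m_nci.feature_names != m_pdd.feature_names or m_nci.horizons != m_pdd.horizons:
        raise ValueError("NCI and PDD models disagree on features/horizons")
    p_nci = expit(m_nci.scores(X))  # (n, t)
    p_pdd = expit(m_pdd.scores(X))
    p_mci = 1.0 - p_nci - p_pdd
    probs = np.stack([p_nci, p_mci, p_pdd], axis=-1)
    clipped = np.clip(probs, 0.0, 1.0)
    total = clipped.sum(axis=-1, keepdims=True)
    total[total == 0] = 1.0
    return clipped / total


def average_weights(models: list[WeightMatrix]) -> WeightMatrix:
    """Element-wise mean of weight matrices and biases."""
    if not models:
        raise ValueError("no models to average")
    ref = models[0]
    for m in models[1:]:
        if m.W.shape != ref.W.shape or m.c.shape != ref.c.shape:
            raise ValueError("weight matrices have mismatched shapes")
        if m.feature_names != ref.feature_names:
            raise ValueError("feature name mismatch")
    return WeightMatrix(
        W=np.mean([m.W for m in models], axis=0),
        c=np.mean([m.c for m in models], axis=0),
        feature_names=list(ref.feature_names),
        horizons=list(ref.horizons),
        converged=all(m.converged for m in models),
    )


def component_magnitudes(model: WeightMatrix) -> pd.DataFrame:
    """Signed weights per feature per horizon (heatmap export).

    Positive components are associated with a higher probability of the
    model's diagnosis.
    """
    return pd.DataFrame(model.W, index=model.feature_names,
                        columns=[f"year_{h}" for h in model.horizons])
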