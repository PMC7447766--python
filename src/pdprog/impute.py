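"""Missing-data imputation for cohort tables.

The primary imputer is a restricted Boltzmann machine with Gaussian
visible units for continuous columns and Bernoulli visible units for
binary columns, trained by contrastive divergence with missing cells
excluded from the gradient.  Missing entries are then filled by clamped
Gibbs sampling with a mean-field readout averaged over sweeps.  A
deterministic column-median fallback is provided so every downstream
stage can be exercised without the RBM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import TEST_COLUMNS

# Default visible layer: all per-visit measurements plus the stable
# covariates that carry information about them.
DEFAULT_IMPUTE_COLUMNS = TEST_COLUMNS + ["ledd_mg", "gds15"]
DEFAULT_CONTEXT_COLUMNS = [
    "age_years",
    "disease_duration_years",
    "education_years",
    "sex",
    "apoe4",
    "gba",
    "mapt_h1",
]
_BINARY = {"sex", "apoe4", "gba", "mapt_h1"}


@dataclass
class RBMConfig:
    n_hidden: int = 32
    learning_rate: float = 0.01
    cd_steps: int = 1
    epochs: int = 200
    gibbs_impute_steps: int = 50
    batch_size: int = 64
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_hidden", "cd_steps", "epochs", "gibbs_impute_steps", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class RBMState:
    """Trained RBM weights plus the column standardization used."""

    columns: list[str]
    binary_mask: np.ndarray  # True where the visible unit is Bernoulli
    means: np.ndarray
    sds: np.ndarray
    W: np.ndarray  # (d, n_hidden)
    vbias: np.ndarray  # (d,)
    hbias: np.ndarray  # (n_hidden,)
    reconstruction_mse: list[float] = field(default_factory=list)


def _design(table: pd.DataFrame, columns: list[str]) -> tuple[np.ndarray, np.ndarray]:
    X = table[columns].to_numpy(dtype=float)
    observed = ~np.isnan(X)
    return X, observed


def _hidden_mean(V: np.ndarray, state_W: np.ndarray, hbias: np.ndarray) -> np.ndarray:
    return expit(V @ state_W + hbias)


def _visible_mean(H: np.ndarray, W: np.ndarray, vbias: np.ndarray, binary: np.ndarray) -> np.ndarray:
    lin = H @ W.T + vbias
    out = lin.copy()
    out[:, binary] = expit(lin[:, binary])
    return out


def fit_rbm(
    table: pd.DataFrame,
    config: RBMConfig,
    columns: list[str] | None = None,
) -> RBMState:
    """Train a Gaussian/Bernoulli-visible RBM by CD-k on observed cells.

    Continuous columns are standardized internally; unit visible
    variance is assumed on that scale.  Missing cells contribute nothing
    to the gradient and are re-estimated by mean-field reconstruction at
    the start of each epoch.
    """
    config.validate()
    if columns is None:
        columns = DEFAULT_IMPUTE_COLUMNS + DEFAULT_CONTEXT_COLUMNS
    columns = [c for c in columns if c in table.columns]
    X, observed = _design(table, columns)
    if observed.sum(axis=1).max() < 2 or (observed.all(axis=1).sum() < 2 and observed.mean() < 0.5):
        raise ValueError("need at least 2 sufficiently complete rows to fit the RBM")
    dead = np.where(~observed.any(axis=0))[0]
    if dead.size:
        raise ValueError(f"column(s) entirely missing: {[columns[j] for j in dead]}")

    binary = np.array([c in _BINARY for c in columns])
    means = np.nanmean(X, axis=0)
    sds = np.nanstd(X, axis=0, ddof=0)
    sds[(sds == 0) | binary] = 1.0
    means[binary] = 0.0
    Z = (X - means) / sds
    Z[~observed] = 0.0  # initial fill at the (standardized) column mean

    rng = np.random.default_rng(config.seed)
    d, m = len(columns), config.n_hidden
    W = rng.normal(0.0, 0.01, size=(d, m))
    vbias = np.zeros(d)
    hbias = np.zeros(m)
    n = Z.shape[0]
    mse_curve: list[float] = []

    for _epoch in range(config.epochs):
        # EM-flavoured refresh of the missing cells under the current model.
        H = _hidden_mean(Z, W, hbias)
        V_hat = _visible_mean(H, W, vbias, binary)
        Z[~observed] = V_hat[~observed]

        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            v0 = Z[idx]
            obs = observed[idx]
            h0 = _hidden_mean(v0, W, hbias)
            vk, hk = v0, h0
            for _ in range(config.cd_steps):
                h_sample = (rng.random(hk.shape) < hk).astype(float)
                vk = _visible_mean(h_sample, W, vbias, binary)
                vk = np.where(obs, vk, v0)  # clamp nothing extra; keep model fill
                hk = _hidden_mean(vk, W, hbias)
            # Mask missing cells out of the positive and negative phases.
            v0m = np.where(obs, v0, 0.0)
            vkm = np.where(obs, vk, 0.0)
            lr = config.learning_rate / len(idx)
            W += lr * (v0m.T @ h0 - vkm.T @ hk)
            vbias += lr * (v0m - vkm).sum(axis=0)
            hbias += lr * (h0 - hk).sum(axis=0)

        H = _hidden_mean(Z, W, hbias)
        V_hat = _visible_mean(H, W, vbias, binary)
        err = (V_hat - Z)[observed]
        mse_curve.append(float(np.mean(err**2)))

    return RBMState(
        columns=columns,
        binary_mask=binary,
        means=means,
        sds=sds,
        W=W,
        vbias=vbias,
        hbias=hbias,
        reconstruction_mse=mse_curve,
    )


def impute_rbm(table: pd.DataFrame, state: RBMState, config: RBMConfig) -> pd.DataFrame:
    """Fill missing cells by clamped Gibbs sampling under a trained RBM.

    Observed cells are clamped at every sweep; the returned value for
    each missing cell is the mean-field visible mean averaged over
    ``gibbs_impute_steps`` sweeps, de-standardized.  Observed entries
    are returned bit-identical.
    """
    config.validate()
    missing_cols = [c for c in state.columns if c not in table.columns]
    if missing_cols:
        raise ValueError(f"table lacks columns the imputer was trained on: {missing_cols}")
    out = table.copy()
    X, observed = _design(table, state.columns)
    if observed.all():
        return out

    Z = (X - state.means) / state.sds
    Z[~observed] = 0.0
    rng = np.random.default_rng(config.seed + 1)
    acc = np.zeros_like(Z)
    for _ in range(config.gibbs_impute_steps):
        h_mean = _hidden_mean(Z, state.W, state.hbias)
        h_sample = (rng.random(h_mean.shape) < h_mean).astype(float)
        v_mean = _visible_mean(h_sample, state.W, state.vbias, state.binary_mask)
        Z = np.where(observed, Z, v_mean)
        # Mean-field readout: accumulate the deterministic visible mean.
        h_mf = _hidden_mean(Z, state.W, state.hbias)
        acc += _visible_mean(h_mf, state.W, state.vbias, state.binary_mask)
    V = acc / config.gibbs_impute_steps
    filled = V * state.sds + state.means
    for j, c in enumerate(state.columns):
        col = out[c].to_numpy(dtype=float)
        col[~observed[:, j]] = filled[~observed[:, j], j]
        out[c] = col
    return out


def impute_median(table: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Column-median fallback imputer (deterministic)."""
    cols = DEFAULT_IMPUTE_COLUMNS if columns is None else list(columns)
    out = table.copy()
    for c in cols:
        if c in out.columns and out[c].isna().any():
            med = out[c].median()
            if np.isnan(med):
                raise ValueError(f"column {c!r} entirely missing; no median")
            out[c] = out[c].fillna(med)
    return out


def impute(
    table: pd.DataFrame,
    method: str = "rbm",
    config: RBMConfig | None = None,
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Impute every missing numeric cell with the chosen imputer."""
    if method == "median":
        out = impute_median(table, columns)
        # Context columns may also carry holes; medians there too.
        return impute_median(out, DEFAULT_CONTEXT_COLUMNS)
    if method != "rbm":
        raise ValueError(f"unknown imputer {method!r}")
    config = config or RBMConfig()
    state = fit_rbm(table, config, columns)
    return impute_rbm(table, state, config)
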