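"""Model-performance metrics and cross-validation of the fused fields.

Metrics follow standard air-quality evaluation practice: mean bias (MB),
root-mean-square error (RMSE), normalized mean bias (NMB, percent) and R^2
computed as the squared Pearson correlation (a choice that matters under
bias and is therefore documented, not assumed).

Two cross-validation schemes:

* k-fold data withholding: random disjoint folds of monitor-day
  observations are withheld, the fusion is refitted on the remainder, and
  withheld observations are compared with fused predictions at their
  cells/days;
* leave-one-location-out (LOLO): one fold per monitor, the entire site
  withheld, testing spatial generalization.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np

from .fusion import build_weight_field, fit_fusion_params, fuse
from .grids import (
    ConcentrationField,
    MonitorSeries,
    collocate,
    monitor_cells,
    observation_matrix,
)

__all__ = ["EvalMetrics", "CVResult", "compute_metrics", "run_kfold_cv", "run_lolo_cv"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvalMetrics:
    r_squared: float
    mean_bias: float
    rmse: float
    nmb_percent: float
    n_pairs: int

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("metrics need at least one pair")


@dataclass
class CVResult:
    scheme: str
    fold_metrics: list[EvalMetrics]
    pooled: EvalMetrics
    pooled_model: EvalMetrics  # raw model vs the same withheld observations
    fold_sizes: list[int] = field(default_factory=list)


def compute_metrics(pred: np.ndarray, obs: np.ndarray) -> EvalMetrics:
    """MB, RMSE, NMB and R^2 with pairwise deletion of missing values."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("prediction and observation series differ in length")
    ok = np.isfinite(pred) & np.isfinite(obs)
    if ok.sum() < 2:
        raise ValueError("need at least 2 non-missing pairs")
    p, o = pred[ok], obs[ok]
    diff = p - o
    mb = float(diff.mean())
    rmse = float(np.sqrt((diff**2).mean()))
    if o.sum() == 0:
        raise ValueError("sum of observations is zero; NMB undefined")
    nmb = float(100.0 * diff.sum() / o.sum())
    if p.std() == 0 or o.std() == 0:
        r2 = 0.0 if not np.allclose(p, o) else 1.0
    else:
        r2 = float(np.corrcoef(p, o)[0, 1] ** 2)
    return EvalMetrics(
        r_squared=r2, mean_bias=mb, rmse=rmse, nmb_percent=nmb, n_pairs=int(ok.sum())
    )


def _withhold(
    obs: list[MonitorSeries], entries: np.ndarray
) -> list[MonitorSeries]:
    """Copy the monitor list with the given (monitor, day) entries masked."""
    out = [copy.deepcopy(s) for s in obs]
    for i, t in entries:
        out[i].values[t] = np.nan
    return [s for s in out if np.any(np.isfinite(s.values))]


def _predict_withheld(
    fused: ConcentrationField,
    obs: list[MonitorSeries],
    entries: np.ndarray,
) -> np.ndarray:
    cells = monitor_cells(obs, fused.grid)
    return fused.values[entries[:, 1], cells[entries[:, 0], 0], cells[entries[:, 0], 1]]


def run_kfold_cv(
    obs: list[MonitorSeries],
    model: ConcentrationField,
    k: int = 10,
    fraction: float = 0.1,
    seed: int = 0,
    floor: float | None = None,
) -> CVResult:
    """k-fold withholding of random monitor-day observations.

    Each fold withholds ``floor(fraction * N)`` monitor-days; folds are
    disjoint, so ``k * fraction <= 1`` is required. The fusion (bias
    parameters, weight field, ratio surfaces) is refitted per fold on the
    remaining observations only.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if not (0 < fraction and k * fraction <= 1.0 + 1e-9):
        raise ValueError("need 0 < fraction and k * fraction <= 1")
    grid = model.grid
    o = observation_matrix(obs, grid)
    entries = np.argwhere(np.isfinite(o))  # (N, 2) -> (monitor, day)
    n = len(entries)
    per_fold = int(fraction * n)
    if per_fold < 1:
        raise ValueError("fraction of monitor-days too small; nothing to withhold")
    if k * per_fold > n:
        raise ValueError("k * fraction exceeds the available observations")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)

    fold_metrics = []
    all_pred, all_raw, all_obs = [], [], []
    fold_sizes = []
    raw = observation_matrix(obs, grid)
    model_at = None
    for f in range(k):
        withheld = entries[order[f * per_fold : (f + 1) * per_fold]]
        train = _withhold(obs, withheld)
        params = fit_fusion_params(train, model, floor=floor)
        weights = build_weight_field(train, params, grid)
        fused = fuse(model, train, params, weights)
        pred = _predict_withheld(fused, obs, withheld)
        truth = raw[withheld[:, 0], withheld[:, 1]]
        if model_at is None:
            model_at = collocate(model, obs)
        raw_pred = model_at[withheld[:, 0], withheld[:, 1]]
        fold_metrics.append(compute_metrics(pred, truth))
        fold_sizes.append(len(withheld))
        all_pred.append(pred)
        all_raw.append(raw_pred)
        all_obs.append(truth)
        logger.info("kfold fold %d/%d: %d withheld", f + 1, k, len(withheld))

    pooled = compute_metrics(np.concatenate(all_pred), np.concatenate(all_obs))
    pooled_model = compute_metrics(np.concatenate(all_raw), np.concatenate(all_obs))
    return CVResult(
        scheme="kfold10",
        fold_metrics=fold_metrics,
        pooled=pooled,
        pooled_model=pooled_model,
        fold_sizes=fold_sizes,
    )


def run_lolo_cv(
    obs: list[MonitorSeries],
    model: ConcentrationField,
    floor: float | None = None,
) -> CVResult:
    """Leave-one-location-out: one fold per monitor, whole site withheld."""
    if len(obs) < 4:
        # refitting needs >= 3 remaining monitors
        raise ValueError("LOLO CV needs at least 4 monitors")
    grid = model.grid
    model_at = collocate(model, obs)
    cells = monitor_cells(obs, grid)

    fold_metrics, fold_sizes = [], []
    all_pred, all_raw, all_obs = [], [], []
    for i, site in enumerate(obs):
        train = obs[:i] + obs[i + 1 :]
        params = fit_fusion_params(train, model, floor=floor)
        weights = build_weight_field(train, params, grid)
        fused = fuse(model, train, params, weights)
        ok = np.isfinite(site.values)
        pred = fused.values[ok, cells[i, 0], cells[i, 1]]
        truth = site.values[ok]
        fold_metrics.append(compute_metrics(pred, truth))
        fold_sizes.append(int(ok.sum()))
        all_pred.append(pred)
        all_raw.append(model_at[i, ok])
        all_obs.append(truth)
        logger.info("LOLO fold %d/%d: site %s", i + 1, len(obs), site.site_id)

    pooled = compute_metrics(np.concatenate(all_pred), np.concatenate(all_obs))
    pooled_model = compute_metrics(np.concatenate(all_raw), np.concatenate(all_obs))
    return CVResult(
        scheme="lolo",
        fold_metrics=fold_metrics,
        pooled=pooled,
        pooled_model=pooled_model,
        fold_sizes=fold_sizes,
    )
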