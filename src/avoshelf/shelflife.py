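"""Forced-endpoint shelf-life regression, loss analysis, and loss KDE.

The shelf-life model is a regression through the origin of ``Days Left``
on the recentered Ripening Index ``x = RI - E``, where ``E`` is the
end-of-shelf-life stage (5 on the 5-stage index, 9 on the 10-stage index):

    Days Left = alpha * (RI - E),      alpha < 0 [days/stage].

Forcing the fit through the origin pins the estimate to exactly zero at
the endpoint stage.  The slope is the through-origin OLS estimator
``alpha = sum(x*y) / sum(x^2)`` with Student-t 95% confidence interval on
n - 1 degrees of freedom and the uncentered R^2.

Estimation loss is signed, ``loss = estimated - actual`` shelf-life (in
days); summary tables report mean absolute loss per storage group and an
overall average weighting each group equally.  Loss distributions are
summarized by a Gaussian kernel density estimate with a 1-day bandwidth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ShelfLifeModel", "fit_forced_endpoint", "estimate_days_left",
           "fit_group_models", "loss_table", "kde_loss"]


@dataclass(frozen=True)
class ShelfLifeModel:
    index_system: int        # 5 or 10
    endpoint: int            # 5 or 9
    alpha: float             # days/stage, negative
    alpha_se: float
    alpha_ci95: float        # half-width of the 95% CI
    r_squared: float         # uncentered
    n: int

    def estimate(self, ri) -> float:
        return estimate_days_left(self, ri)

    def summary(self) -> dict:
        return {"index_system": self.index_system, "endpoint": self.endpoint,
                "alpha": self.alpha, "alpha_se": self.alpha_se,
                "alpha_ci95": self.alpha_ci95, "r_squared": self.r_squared, "n": self.n}


def fit_forced_endpoint(points, E: int, index_system: int | None = None) -> ShelfLifeModel:
    """Through-origin OLS of Days Left on (RI - E).

    ``points`` is an iterable/array of (ri, days_left) pairs.  At least two
    points with ri != E are required; exactly collinear data yield SE = 0
    and R^2 = 1.
    """
    arr = np.asarray(list(points) if not isinstance(points, np.ndarray) else points,
                     dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be (ri, days_left) pairs")
    ri, y = arr[:, 0], arr[:, 1]
    x = ri - E
    n = len(x)
    usable = np.count_nonzero(x)
    if usable < 2:
        raise ValueError("need >= 2 points with ri != E (degenerate fit)")
    sxx = float(np.sum(x * x))
    alpha = float(np.sum(x * y) / sxx)
    resid = y - alpha * x
    sse = float(np.sum(resid ** 2))
    dof = n - 1                     # one fitted parameter
    se = float(np.sqrt(sse / (dof * sxx))) if dof > 0 else float("nan")
    tq = float(stats.t.ppf(0.975, dof)) if dof > 0 else float("nan")
    syy = float(np.sum(y ** 2))
    r2 = 1.0 - sse / syy if syy > 0 else 1.0
    if index_system is None:
        index_system = 5 if E == 5 else 10
    return ShelfLifeModel(index_system=index_system, endpoint=E, alpha=alpha,
                          alpha_se=se, alpha_ci95=tq * se, r_squared=r2, n=n)


def estimate_days_left(model: ShelfLifeModel, ri) -> float:
    """Estimated shelf-life (days) at Ripening Index ``ri``.

    alpha*(ri - E), clipped at 0 beyond the endpoint stage; exactly 0 at
    the endpoint by construction.
    """
    k = model.index_system
    if not (1 <= ri <= k):
        raise ValueError(f"ri {ri} outside 1..{k}")
    if ri >= model.endpoint:
        return 0.0
    return float(model.alpha * (ri - model.endpoint))


def fit_group_models(db_records: pd.DataFrame, index_system: int,
                     per_sample_day: bool = False) -> dict[str, ShelfLifeModel]:
    """Fit one forced-endpoint model per storage group from attributed stages.

    Uses non-censored records strictly before the endpoint stage.  With
    ``per_sample_day`` one record per (sample, day) is kept (the sides
    share a stage); default uses every photograph.
    """
    E = 5 if index_system == 5 else 9
    col, dcol = f"ri{index_system}", f"days_left{'5' if index_system == 5 else '9'}"
    df = db_records[~db_records["censored"] & (db_records[col] < E)
                    & db_records[dcol].notna()]
    if per_sample_day:
        df = df.drop_duplicates(subset=["sample_id", "day"])
    out = {}
    for gname, sub in df.groupby("group"):
        out[str(gname)] = fit_forced_endpoint(
            np.column_stack([sub[col].to_numpy(float), sub[dcol].to_numpy(float)]),
            E=E, index_system=index_system)
    return out


def loss_table(preds: pd.DataFrame, models: dict[str, ShelfLifeModel],
               aggregation: str = "by_picture",
               stage_col: str = "predicted_stage",
               actual_col: str = "actual_days_left"):
    """Shelf-life estimation losses and group-equal-weight averages.

    ``preds`` needs sample_id, side, day, group, the stage column to score
    (``predicted_stage`` for model output, or ``true_stage`` to score the
    attributed classifications), and the actual Days Left (censored records
    must be excluded upstream).  ``by_sample`` keeps, per (sample, day),
    the side with the smallest absolute loss — the best-performing side.

    Returns ``(records, averages)``: per-record signed losses, and mean
    absolute loss per storage group plus an overall row averaging the
    groups with equal weight.
    """
    if aggregation not in ("by_picture", "by_sample"):
        raise ValueError("aggregation must be 'by_picture' or 'by_sample'")
    missing = set(preds["group"]) - set(models)
    if missing:
        raise KeyError(f"no shelf-life model for group(s) {sorted(missing)}")
    df = preds.copy()
    df["estimated_days_left"] = [models[g].estimate(s)
                                 for g, s in zip(df["group"], df[stage_col])]
    df["loss"] = df["estimated_days_left"] - df[actual_col]
    if aggregation == "by_sample":
        df = (df.assign(_abs=df["loss"].abs())
              .sort_values(["sample_id", "day", "_abs", "side"], kind="stable")
              .drop_duplicates(subset=["sample_id", "day"], keep="first")
              .drop(columns="_abs"))
    rows = [{"group": g, "mean_abs_loss": float(sub["loss"].abs().mean()),
             "n": len(sub)} for g, sub in df.groupby("group")]
    overall = float(np.mean([r["mean_abs_loss"] for r in rows]))
    rows.append({"group": "Overall", "mean_abs_loss": overall,
                 "n": int(sum(r["n"] for r in rows))})
    return df, pd.DataFrame(rows)


def kde_loss(losses, bandwidth: float = 1.0, grid: np.ndarray | None = None):
    """Gaussian KDE of signed losses with an absolute bandwidth in days.

    Returns ``(grid, density)``; the density integrates to 1 (up to grid
    truncation).  For a single loss at 0 the density at 0 is the Gaussian
    peak 1/sqrt(2*pi) ~ 0.3989.
    """
    x = np.asarray(list(losses) if not isinstance(losses, np.ndarray) else losses,
                   dtype=float)
    if x.size == 0:
        raise ValueError("no losses")
    if grid is None:
        lo = x.min() - 4.0 * bandwidth
        hi = x.max() + 4.0 * bandwidth
        grid = np.linspace(lo, hi, 512)
    z = (grid[:, None] - x[None, :]) / bandwidth
    dens = np.exp(-0.5 * z ** 2).sum(axis=1) / (x.size * bandwidth * np.sqrt(2 * np.pi))
    return grid, dens
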