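"""Estimator-performance metrics for the Monte-Carlo comparison.

Per (estimator, grid-cell) vector of estimates over the S iterations:
the average estimate (absolute values first for sign-carrying
estimators such as the CV), min-max normalization, efficiency (the
population variance of the normalized estimates — smaller is more
precise), relative efficiency against a reference estimator, percentage
sensitivity to contamination (mean relative absolute error of the
contaminated vs the paired clean average), the sensitivity curve over
contamination levels, and the 5 %-relative-error resistance threshold
read off that curve by linear interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classical import coefficient_of_variation, population_std
from .errors import InvalidArgumentError
from .mirroring import named_preset, run_mirroring
from .simulate import SimulatedBatch

__all__ = [
    "average_estimate",
    "minmax_normalize",
    "efficiency",
    "relative_efficiency",
    "pct_sensitivity",
    "sensitivity_curve",
    "resistance_threshold",
    "compare_efficiencies",
    "compute_estimates",
    "default_estimators",
    "evaluate_mixture_batch",
    "plot_sensitivity_curves",
    "TTestResult",
]

# estimators whose raw sign is an artefact of the mean's direction:
# take |estimate| before averaging (CV only, in the default battery)
SIGNED_ESTIMATORS = frozenset({"cv"})


def default_estimators(kinds: tuple = ("std", "cv", "amm_pdev", "rmm_pdev")) -> dict:
    """The estimator battery keyed by short id.

    ``std``/``cv`` are the classical references; ``amm_*``/``rmm_*``
    are absolute/raw meanic mirroring outputs (kc, pprox, pdev,
    kcalt1, kcalt2).
    """
    amm = named_preset("absolute_meanic")
    rmm = named_preset("raw_meanic")
    table = {
        "std": population_std,
        "cv": lambda x: coefficient_of_variation(x, population=True),
    }
    for tag, cfg in (("amm", amm), ("rmm", rmm)):
        for out in ("kc", "pprox", "pdev", "kc_alt1", "kc_alt2"):
            short = out.replace("_", "")
            table[f"{tag}_{short}"] = (
                lambda x, cfg=cfg, out=out: getattr(run_mirroring(x, cfg), out)
            )
    unknown = [k for k in kinds if k not in table]
    if unknown:
        raise InvalidArgumentError(f"unknown estimator id(s): {unknown}")
    return {k: table[k] for k in kinds}


def average_estimate(estimates, absolute: bool = False) -> float:
    """Mean estimate over the S iterations, optionally of ``|beta|``."""
    arr = np.asarray(estimates, dtype=float)
    if arr.size == 0:
        raise InvalidArgumentError("empty estimate vector")
    if absolute:
        arr = np.abs(arr)
    return float(arr.mean())


def minmax_normalize(estimates) -> np.ndarray:
    """Affine map of the estimates onto [0, 1]; constant input yields a
    zero vector with a warning (no variability to normalize)."""
    arr = np.asarray(estimates, dtype=float)
    if arr.size == 0:
        raise InvalidArgumentError("empty estimate vector")
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        warnings.warn("constant estimate vector: min-max normalization undefined",
                      RuntimeWarning, stacklevel=2)
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def efficiency(estimates) -> float:
    """Population variance (divisor S) of the min-max-normalized
    estimates; 0 with a warning for a constant vector."""
    arr = np.asarray(estimates, dtype=float)
    if arr.size < 2:
        raise InvalidArgumentError("efficiency requires at least 2 estimates")
    return float(np.var(minmax_normalize(arr), ddof=0))


def relative_efficiency(eff_reference: float, eff_proposed: float) -> float:
    """``Eff_ref / Eff_proposed``; < 1 means the proposed estimator is
    the more efficient one."""
    if eff_proposed == 0.0:
        raise InvalidArgumentError("proposed efficiency is zero; ratio undefined")
    return eff_reference / eff_proposed


def pct_sensitivity(clean_mean: float, contaminated_mean: float) -> float:
    """Percentage sensitivity to contamination:
    ``100 * |contaminated - clean| / clean`` on the averaged |estimates|."""
    if clean_mean == 0.0:
        raise InvalidArgumentError("clean mean estimate is zero; sensitivity undefined")
    return 100.0 * abs(contaminated_mean - clean_mean) / clean_mean


def compute_estimates(batch: SimulatedBatch, estimators: dict) -> pd.DataFrame:
    """Apply every estimator to every dataset of a batch.

    Returns the long-format estimate matrix with one row per
    (combo, iteration, contaminated flag, estimator).
    """
    rows = []
    for rec in batch.records:
        base = {"combo_id": rec.combo_id, "iteration": rec.iteration,
                "contaminated": rec.contaminated}
        base.update(rec.params)
        for name, fn in estimators.items():
            row = dict(base)
            row["estimator"] = name
            row["estimate"] = float(fn(rec.data))
            rows.append(row)
    return pd.DataFrame(rows)


def sensitivity_curve(matrix: pd.DataFrame, estimator: str) -> pd.Series:
    """Mean percentage sensitivity per contamination level (percent).

    Within each grid cell the clean and contaminated |estimates| are
    averaged over iterations and compared; the curve value at a level is
    the mean across all parameter combinations at that level.  Index is
    the contamination level in percent.
    """
    sub = matrix[matrix["estimator"] == estimator]
    if sub.empty:
        raise InvalidArgumentError(f"no estimates for estimator {estimator!r}")
    if "level" not in sub.columns:
        raise InvalidArgumentError("estimate matrix carries no contamination level")
    absolute = estimator in SIGNED_ESTIMATORS
    values = []
    for (level, combo), cell in sub.groupby(["level", "combo_id"]):
        clean = cell.loc[~cell["contaminated"], "estimate"].to_numpy()
        dirty = cell.loc[cell["contaminated"], "estimate"].to_numpy()
        if clean.size == 0 or dirty.size == 0:
            raise InvalidArgumentError(
                f"combo {combo} at level {level} is missing its clean or "
                "contaminated partner"
            )
        values.append(
            (100.0 * level,
             pct_sensitivity(average_estimate(clean, absolute=absolute),
                             average_estimate(dirty, absolute=absolute)))
        )
    frame = pd.DataFrame(values, columns=["level_pct", "sensitivity"])
    curve = frame.groupby("level_pct")["sensitivity"].mean().sort_index()
    curve.name = estimator
    return curve


def resistance_threshold(curve: pd.Series, threshold_pct: float = 5.0) -> tuple[float, bool]:
    """Largest contamination level (percent) with mean sensitivity at or
    below ``threshold_pct``, linearly interpolated between bracketing
    simulated levels.

    Returns ``(threshold, saturated)`` — ``saturated`` is True when the
    whole curve stays below the threshold, so the value is only a lower
    bound (the grid's maximum level).
    """
    if len(curve) < 2:
        raise InvalidArgumentError("curve must cover at least 2 contamination levels")
    levels = curve.index.to_numpy(dtype=float)
    sens = curve.to_numpy(dtype=float)
    order = np.argsort(levels)
    levels, sens = levels[order], sens[order]
    if sens[0] > threshold_pct:
        return 0.0, False
    for i in range(1, len(levels)):
        if sens[i] > threshold_pct:
            lo_l, hi_l = levels[i - 1], levels[i]
            lo_s, hi_s = sens[i - 1], sens[i]
            frac = (threshold_pct - lo_s) / (hi_s - lo_s)
            return float(lo_l + frac * (hi_l - lo_l)), False
    return float(levels[-1]), True


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    pvalue: float
    df: int


def compare_efficiencies(effs_a, effs_b) -> TTestResult:
    """Two-tailed unpaired Student t-test (equal-variance form) between
    two groups of efficiency values."""
    a = np.asarray(effs_a, dtype=float)
    b = np.asarray(effs_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidArgumentError("each group needs at least 2 values")
    if np.all(a == a[0]) and np.all(b == b[0]):
        if a[0] == b[0]:
            return TTestResult(0.0, 1.0, a.size + b.size - 2)
        raise InvalidArgumentError("both groups are constant with different means")
    res = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(float(res.statistic), float(res.pvalue), a.size + b.size - 2)


def evaluate_mixture_batch(
    matrix: pd.DataFrame,
    estimators: tuple,
    reference: str = "std",
    threshold_pct: float = 5.0,
) -> pd.DataFrame:
    """Full report for a mixture run: per-estimator efficiency at the
    clean baseline, relative efficiency against ``reference``, the
    sensitivity curve, and the resistance threshold.

    One row per estimator; curve values are embedded as a dict column.
    """
    clean0 = matrix[(~matrix["contaminated"]) & (matrix["level"] == 0.0)]
    rows = []
    effs = {}
    for name in estimators:
        cell_effs = [
            efficiency(np.abs(g["estimate"].to_numpy())
                       if name in SIGNED_ESTIMATORS else g["estimate"].to_numpy())
            for _, g in clean0[clean0["estimator"] == name].groupby("combo_id")
        ]
        effs[name] = float(np.mean(cell_effs)) if cell_effs else float("nan")
    for name in estimators:
        curve = sensitivity_curve(matrix, name)
        thr, saturated = resistance_threshold(curve, threshold_pct)
        rows.append(
            {
                "estimator": name,
                "efficiency": effs[name],
                "relative_efficiency": (
                    effs[reference] / effs[name] if effs.get(name) else float("nan")
                ),
                "resistance_threshold_pct": thr,
                "threshold_saturated": saturated,
                "curve": curve.to_dict(),
            }
        )
    return pd.DataFrame(rows)


def plot_sensitivity_curves(curves: dict, path: str, threshold_pct: float = 5.0) -> None:
    """Plot sensitivity curves (level % vs mean sensitivity %) to file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, curve in curves.items():
        ax.plot(list(curve.index), list(curve.values), marker="o", label=name)
    ax.axhline(threshold_pct, color="grey", linestyle="--", linewidth=1)
    ax.set_xlabel("contamination level (%)")
    ax.set_ylabel("mean % sensitivity")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
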