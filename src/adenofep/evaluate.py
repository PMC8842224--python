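"""Scoring of predicted vs experimental binding free energies.

The predictivity metrics are the mean unsigned error (MUE) and root mean
squared error (RMSE) between predicted and experimental ΔG_bind, and the
convergence metric is the mean per-compound SEM of the underlying FEP
estimates, all in kcal/mol.  Confidence intervals are percentile
bootstrap over compounds.  Two candidate binding modes are compared by
their metric reports: lower MUE wins, ties fall through to RMSE and then
mean SEM.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "MetricsReport",
    "ModelComparison",
    "error_metrics",
    "bootstrap_ci",
    "compare_binding_modes",
]


@dataclass
class MetricsReport:
    n_compounds: int
    mue: float
    rmse: float
    mean_sem: float
    ci_mue: tuple[float, float] | None = None
    ci_rmse: tuple[float, float] | None = None
    binding_mode_label: str | None = None
    compound_ids: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "binding_mode_label": self.binding_mode_label,
            "n_compounds": self.n_compounds,
            "mue": self.mue,
            "rmse": self.rmse,
            "mean_sem": self.mean_sem,
            "ci_mue": list(self.ci_mue) if self.ci_mue else None,
            "ci_rmse": list(self.ci_rmse) if self.ci_rmse else None,
        }


def _matched_arrays(
    pred: Mapping[str, float], exp: Mapping[str, float]
) -> tuple[list[str], np.ndarray, np.ndarray]:
    if set(pred) != set(exp):
        only_p = sorted(set(pred) - set(exp))
        only_e = sorted(set(exp) - set(pred))
        raise ValueError(
            f"compound id mismatch: pred-only {only_p}, exp-only {only_e}"
        )
    ids = sorted(pred)
    if not ids:
        raise ValueError("empty compound overlap")
    return (
        ids,
        np.array([pred[i] for i in ids]),
        np.array([exp[i] for i in ids]),
    )


def error_metrics(
    pred: Mapping[str, float],
    exp: Mapping[str, float],
    sems: Mapping[str, float] | None = None,
    binding_mode_label: str | None = None,
) -> MetricsReport:
    """MUE / RMSE between matched predictions and experiments, plus the
    mean per-compound SEM (0 when no SEMs are supplied)."""
    ids, p, e = _matched_arrays(pred, exp)
    resid = p - e
    mue = float(np.abs(resid).mean())
    rmse = float(np.sqrt((resid**2).mean()))
    mean_sem = float(np.mean([sems[i] for i in ids])) if sems else 0.0
    return MetricsReport(
        n_compounds=len(ids),
        mue=mue,
        rmse=rmse,
        mean_sem=mean_sem,
        binding_mode_label=binding_mode_label,
        compound_ids=tuple(ids),
    )


def bootstrap_ci(
    pred: Mapping[str, float],
    exp: Mapping[str, float],
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict[str, tuple[float, float]]:
    """Percentile bootstrap intervals for MUE and RMSE.

    Compounds are resampled with replacement ``n_boot`` times; the
    2.5/97.5 percentiles (for the default ``alpha``) of each metric over
    the resamples form the interval.  Deterministic for a fixed seed.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    ids, p, e = _matched_arrays(pred, exp)
    resid = p - e
    rng = np.random.default_rng(seed)
    n = len(ids)
    idx = rng.integers(0, n, size=(n_boot, n))
    samples = resid[idx]
    mues = np.abs(samples).mean(axis=1)
    rmses = np.sqrt((samples**2).mean(axis=1))
    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    return {
        "mue": (float(np.percentile(mues, lo)), float(np.percentile(mues, hi))),
        "rmse": (float(np.percentile(rmses, lo)), float(np.percentile(rmses, hi))),
        "mue_halfwidth": float(mues.std(ddof=1)) if n_boot > 1 else 0.0,
        "rmse_halfwidth": float(rmses.std(ddof=1)) if n_boot > 1 else 0.0,
    }


@dataclass
class ModelComparison:
    report_A: MetricsReport
    report_B: MetricsReport
    winner: str  # label of the winning report, or "indeterminate"
    rationale: str

    def to_dict(self) -> dict:
        return {
            "winner": self.winner,
            "rationale": self.rationale,
            "report_A": self.report_A.to_dict(),
            "report_B": self.report_B.to_dict(),
        }


def compare_binding_modes(
    report_A: MetricsReport, report_B: MetricsReport
) -> ModelComparison:
    """Pick the better-supported binding mode.

    Decision rule: lower MUE wins; MUE ties broken by RMSE, then by mean
    SEM (better convergence); ties on all three are declared
    indeterminate.  Both reports must cover the same compound set.
    """
    if set(report_A.compound_ids) != set(report_B.compound_ids):
        raise ValueError("reports cover different compound sets")
    label_a = report_A.binding_mode_label or "A"
    label_b = report_B.binding_mode_label or "B"
    for metric in ("mue", "rmse", "mean_sem"):
        a, b = getattr(report_A, metric), getattr(report_B, metric)
        if not math.isclose(a, b, rel_tol=0.0, abs_tol=1e-12):
            winner = label_a if a < b else label_b
            return ModelComparison(
                report_A=report_A,
                report_B=report_B,
                winner=winner,
                rationale=f"lower {metric.upper().replace('_', ' ')} "
                f"({min(a, b):.3f} vs {max(a, b):.3f} kcal/mol)",
            )
    return ModelComparison(
        report_A=report_A,
        report_B=report_B,
        winner="indeterminate",
        rationale="identical MUE, RMSE and mean SEM",
    )


def write_comparison_json(comparison: ModelComparison, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(comparison.to_dict(), fh, indent=2)


def write_residual_csv(
    pred: Mapping[str, float],
    exp: Mapping[str, float],
    path: str | Path,
) -> None:
    ids, p, e = _matched_arrays(pred, exp)
    with open(path, "w") as fh:
        fh.write("compound_id,dg_pred_kcal,dg_exp_kcal,residual_kcal\n")
        for i, cid in enumerate(ids):
            fh.write(f"{cid},{p[i]:.4f},{e[i]:.4f},{p[i] - e[i]:.4f}\n")
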