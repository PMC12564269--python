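"""Regression metrics, global-statistics SSIM and stratified reporting.

Strata follow the TG-218-motivated intervals 95-100, 90-95 and <90 on the
ground-truth GPR of each criterion; R^2 is reported for "All" only (it is
unstable on sparse subgroups).  SSIM is computed from global means,
variances and covariance — no sliding window — with stabilizers
C1 = (0.01 L)^2 and C2 = (0.03 L)^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import PSQASample

CRITERION_LABELS = ("1%/1mm", "2%/2mm", "2%/3mm")
STRATA = ("All", "95-100", "90-95", "<90")

#: Criterion index used to stratify the dose-difference metrics (2%/2mm).
DDP_STRATIFY_CRITERION = 1


@dataclass
class RegressionMetrics:
    mae: float
    rmse: float
    r2: float | None  # None when target variance is zero

    def to_dict(self) -> dict:
        return {"mae": self.mae, "rmse": self.rmse, "r2": self.r2}


def compute_regression_metrics(y: np.ndarray, y_hat: np.ndarray
                               ) -> RegressionMetrics:
    """MAE, RMSE and R^2 of predictions against targets.

    R^2 may be negative; it is ``None`` (undefined) when the targets have
    zero variance — MAE and RMSE are still returned.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    y_hat = np.asarray(y_hat, dtype=np.float64).ravel()
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {y_hat.shape}")
    if y.size < 1:
        raise ValueError("empty input")
    resid = y - y_hat
    mae = float(np.mean(np.abs(resid)))
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = None if ss_tot == 0.0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return RegressionMetrics(mae, rmse, r2)


def ssim_global(x1: np.ndarray, x2: np.ndarray, dynamic_range: float) -> float:
    """Single global-statistics SSIM; symmetric in its arguments."""
    x1 = np.asarray(x1, dtype=np.float64)
    x2 = np.asarray(x2, dtype=np.float64)
    if x1.shape != x2.shape:
        raise ValueError(f"shape mismatch: {x1.shape} vs {x2.shape}")
    if dynamic_range <= 0:
        raise ValueError("dynamic_range must be > 0")
    c1 = (0.01 * dynamic_range) ** 2
    c2 = (0.03 * dynamic_range) ** 2
    mu1, mu2 = x1.mean(), x2.mean()
    var1, var2 = x1.var(), x2.var()
    cov = float(np.mean((x1 - mu1) * (x2 - mu2)))
    return float(
        (2 * mu1 * mu2 + c1) * (2 * cov + c2)
        / ((mu1**2 + mu2**2 + c1) * (var1 + var2 + c2))
    )


def _stratum_mask(gpr: np.ndarray, stratum: str) -> np.ndarray:
    if stratum == "All":
        return np.ones_like(gpr, dtype=bool)
    if stratum == "95-100":
        return gpr >= 95.0
    if stratum == "90-95":
        return (gpr >= 90.0) & (gpr < 95.0)
    if stratum == "<90":
        return gpr < 90.0
    raise ValueError(f"unknown stratum {stratum!r}")


def _per_sample_ddp_metrics(samples: Sequence[PSQASample],
                            dd_pred: np.ndarray
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample DD MAE in % of the planned map's global max, and
    per-sample global SSIM (L = ground-truth DD range, floored)."""
    mae_pct = np.empty(len(samples))
    ssim = np.empty(len(samples))
    for i, s in enumerate(samples):
        dd_true = s.targets.dd_map
        if dd_true is None:
            raise ValueError(f"sample {s.sample_id}: missing dd_map target")
        norm = float(s.fluence.values.max())
        if norm <= 0:
            norm = 1.0
        mae_pct[i] = 100.0 * np.mean(np.abs(dd_true - dd_pred[i])) / norm
        rng_ = float(dd_true.max() - dd_true.min())
        ssim[i] = ssim_global(dd_true, dd_pred[i], max(rng_, 1e-6))
    return mae_pct, ssim


def stratified_report(samples: Sequence[PSQASample], gpr_pred: np.ndarray,
                      dd_pred: np.ndarray | None = None) -> dict:
    """GPR-interval-stratified metrics report.

    GPR metrics are stratified per criterion by that criterion's
    ground-truth GPR; DD metrics are stratified by the 2%/2mm ground
    truth.  Empty strata are reported as ``None`` (absent, not zero).
    """
    if len(samples) == 0:
        raise ValueError("empty test set")
    gpr_true = np.stack([s.targets.gpr_percent for s in samples])
    gpr_pred = np.asarray(gpr_pred, dtype=np.float64)
    if gpr_pred.shape != gpr_true.shape:
        raise ValueError(
            f"gpr_pred shape {gpr_pred.shape} != targets {gpr_true.shape}"
        )

    report: dict = {"n_samples": len(samples), "gpr": {}, "ddp": None}
    for k, label in enumerate(CRITERION_LABELS):
        cells: dict[str, dict | None] = {}
        for stratum in STRATA:
            mask = _stratum_mask(gpr_true[:, k], stratum)
            if not mask.any():
                cells[stratum] = None
                continue
            m = compute_regression_metrics(gpr_true[mask, k], gpr_pred[mask, k])
            cell = {"mae": m.mae, "rmse": m.rmse, "n": int(mask.sum())}
            if stratum == "All":
                cell["r2"] = m.r2
            cells[stratum] = cell
        report["gpr"][label] = cells

    if dd_pred is not None:
        dd_pred = np.asarray(dd_pred, dtype=np.float64)
        mae_pct, ssim = _per_sample_ddp_metrics(samples, dd_pred)
        strat_gpr = gpr_true[:, DDP_STRATIFY_CRITERION]
        dd_true_flat = np.stack([s.targets.dd_map for s in samples]).ravel()
        cells = {}
        for stratum in STRATA:
            mask = _stratum_mask(strat_gpr, stratum)
            if not mask.any():
                cells[stratum] = None
                continue
            cell = {
                "mae_percent": float(mae_pct[mask].mean()),
                "ssim": float(ssim[mask].mean()),
                "n": int(mask.sum()),
            }
            if stratum == "All":
                m = compute_regression_metrics(dd_true_flat, dd_pred.ravel())
                cell["r2"] = m.r2
                cell["mae_raw"] = m.mae
            cells[stratum] = cell
        report["ddp"] = cells
    return report


def report_to_markdown(report: dict) -> str:
    """Render the report dict as Markdown tables (same cells as the JSON)."""
    lines = ["# QA metrics report", "", f"Test samples: {report['n_samples']}",
             "", "## GPR", "",
             "| Criterion | Stratum | n | MAE (%) | RMSE (%) | R2 |",
             "|---|---|---|---|---|---|"]

    def fmt(x) -> str:
        return "—" if x is None else f"{x:.4f}"

    for label, cells in report["gpr"].items():
        for stratum in STRATA:
            cell = cells[stratum]
            if cell is None:
                lines.append(f"| {label} | {stratum} | — | — | — | — |")
            else:
                lines.append(
                    f"| {label} | {stratum} | {cell['n']} | {fmt(cell['mae'])} "
                    f"| {fmt(cell['rmse'])} | {fmt(cell.get('r2'))} |"
                )
    if report.get("ddp") is not None:
        lines += ["", "## DDP", "",
                  "| Stratum | n | MAE (%) | SSIM | R2 |",
                  "|---|---|---|---|---|"]
        for stratum in STRATA:
            cell = report["ddp"][stratum]
            if cell is None:
                lines.append(f"| {stratum} | — | — | — | — |")
            else:
                lines.append(
                    f"| {stratum} | {cell['n']} | {fmt(cell['mae_percent'])} "
                    f"| {fmt(cell['ssim'])} | {fmt(cell.get('r2'))} |"
                )
    return "\n".join(lines) + "\n"
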