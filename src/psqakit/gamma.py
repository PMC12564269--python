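"""Gamma-index analysis between planned and measured 2-D dose grids.

Computes per-point gamma values and Gamma Passing Rates (GPR) under
dose/distance tolerance pairs in global absolute-dose mode: the dose
tolerance is a percentage of the reference grid's global maximum and
points at or below a global-max dose threshold are excluded from both the
numerator and the denominator.

By default the *measured* grid is the reference (evaluation points live on
the measurement) and the planned grid is searched; a flag swaps the roles.
The search is discrete (no sub-pixel interpolation) so that
:func:`gamma_map` and the exhaustive :func:`gamma_oracle` can agree
exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data_model import FluenceMap

#: Numeric slack on the "gamma <= 1 passes" rule, so that analytically
#: boundary cases (e.g. a uniform dose error exactly equal to the dose
#: tolerance) are not decided by float rounding.
PASS_TOL = 1e-9

#: The three clinical criteria, ordered (1%/1 mm, 2%/2 mm, 2%/3 mm), all at
#: a 10% global-max dose threshold.
DEFAULT_CRITERIA: tuple["GammaCriterion", ...]


@dataclass(frozen=True)
class GammaCriterion:
    """Dose tolerance (% of global max), distance tolerance (mm) and a
    global-max dose threshold (%); mode is fixed global absolute."""

    dose_tol_percent: float
    dist_tol_mm: float
    dose_threshold_percent: float = 10.0
    mode: str = "global absolute"

    def __post_init__(self) -> None:
        if not (self.dose_tol_percent > 0 and self.dist_tol_mm > 0):
            raise ValueError("dose_tol_percent and dist_tol_mm must be > 0")
        if not (0 <= self.dose_threshold_percent < 100):
            raise ValueError("dose_threshold_percent must be in [0, 100)")
        if self.mode != "global absolute":
            raise ValueError("only global absolute mode is supported")

    @property
    def label(self) -> str:
        def fmt(x: float) -> str:
            return f"{x:g}"

        return f"{fmt(self.dose_tol_percent)}%/{fmt(self.dist_tol_mm)}mm"


DEFAULT_CRITERIA = (
    GammaCriterion(1.0, 1.0),
    GammaCriterion(2.0, 2.0),
    GammaCriterion(2.0, 3.0),
)


@dataclass
class GammaResult:
    """Gamma map (NaN where below threshold) plus pass-rate bookkeeping."""

    gamma_map: np.ndarray
    evaluated_count: int
    passed_count: int
    gpr_percent: float
    criterion: GammaCriterion

    def to_dict(self) -> dict:
        return {
            "criterion": self.criterion.label,
            "evaluated_count": int(self.evaluated_count),
            "passed_count": int(self.passed_count),
            "gpr_percent": float(self.gpr_percent),
        }


def _check_inputs(reference: np.ndarray, compared: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    reference = np.asarray(reference, dtype=np.float64)
    compared = np.asarray(compared, dtype=np.float64)
    if reference.ndim != 2 or compared.ndim != 2:
        raise ValueError("dose grids must be 2-D")
    if reference.shape != compared.shape:
        raise ValueError(
            f"shape mismatch: reference {reference.shape} vs compared {compared.shape}"
        )
    if reference.max() <= 0:
        raise ValueError("global max of reference must be > 0")
    return reference, compared


def _threshold_mask(reference: np.ndarray, crit: GammaCriterion) -> np.ndarray:
    # Strictly greater: only points with dose > threshold% of global max.
    cut = crit.dose_threshold_percent / 100.0 * reference.max()
    mask = reference > cut
    if not mask.any():
        raise ValueError("all reference points at or below the dose threshold")
    return mask


def _finalize(gamma_sq: np.ndarray, mask: np.ndarray,
              crit: GammaCriterion) -> GammaResult:
    gmap = np.sqrt(np.where(mask, gamma_sq, np.nan))
    evaluated = int(mask.sum())
    passed = int(np.sum(gmap[mask] <= 1.0 + PASS_TOL))
    return GammaResult(
        gamma_map=gmap,
        evaluated_count=evaluated,
        passed_count=passed,
        gpr_percent=100.0 * passed / evaluated,
        criterion=crit,
    )


def gamma_map(reference: np.ndarray, compared: np.ndarray,
              crit: GammaCriterion, spacing_mm: float = 1.0,
              search_radius_factor: float = 3.0) -> GammaResult:
    """Discrete gamma analysis with a bounded spatial search.

    For each above-threshold reference point the minimum combined
    dose/distance metric is taken over compared-grid points within
    ``search_radius_factor * dist_tol_mm``.  A point passes iff
    gamma <= 1 (up to :data:`PASS_TOL`).
    """
    reference, compared = _check_inputs(reference, compared)
    if spacing_mm <= 0:
        raise ValueError("spacing_mm must be > 0")
    if search_radius_factor <= 0:
        raise ValueError("search_radius_factor must be > 0")
    mask = _threshold_mask(reference, crit)
    delta = crit.dose_tol_percent / 100.0 * reference.max()
    radius_mm = search_radius_factor * crit.dist_tol_mm

    h, w = reference.shape
    max_off = int(math.floor(radius_mm / spacing_mm))
    gamma_sq = np.full((h, w), np.inf)
    dist_tol_sq = crit.dist_tol_mm ** 2
    for di in range(-max_off, max_off + 1):
        for dj in range(-max_off, max_off + 1):
            dist_sq = (di * di + dj * dj) * spacing_mm ** 2
            if dist_sq > radius_mm ** 2:
                continue
            # reference[i, j] vs compared[i + di, j + dj], in-bounds only
            r_i0, r_i1 = max(0, -di), min(h, h - di)
            r_j0, r_j1 = max(0, -dj), min(w, w - dj)
            if r_i0 >= r_i1 or r_j0 >= r_j1:
                continue
            ref_blk = reference[r_i0:r_i1, r_j0:r_j1]
            cmp_blk = compared[r_i0 + di:r_i1 + di, r_j0 + dj:r_j1 + dj]
            cand = dist_sq / dist_tol_sq + ((cmp_blk - ref_blk) / delta) ** 2
            np.minimum(
                gamma_sq[r_i0:r_i1, r_j0:r_j1], cand,
                out=gamma_sq[r_i0:r_i1, r_j0:r_j1],
            )
    return _finalize(gamma_sq, mask, crit)


def gamma_oracle(reference: np.ndarray, compared: np.ndarray,
                 crit: GammaCriterion, spacing_mm: float = 1.0) -> GammaResult:
    """Exhaustive gamma: minimum over *all* compared points (no radius
    cutoff).  Verification oracle for :func:`gamma_map`; grids <= 64x64."""
    reference, compared = _check_inputs(reference, compared)
    if max(reference.shape) > 64:
        raise ValueError("gamma_oracle is restricted to grids <= 64x64")
    mask = _threshold_mask(reference, crit)
    delta = crit.dose_tol_percent / 100.0 * reference.max()

    h, w = reference.shape
    ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    cmp_flat = compared.ravel()
    ii_f = ii.ravel().astype(np.float64)
    jj_f = jj.ravel().astype(np.float64)
    gamma_sq = np.full((h, w), np.inf)
    dist_tol_sq = crit.dist_tol_mm ** 2
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            dist_sq = ((ii_f - i) ** 2 + (jj_f - j) ** 2) * spacing_mm ** 2
            dose_sq = ((cmp_flat - reference[i, j]) / delta) ** 2
            gamma_sq[i, j] = np.min(dist_sq / dist_tol_sq + dose_sq)
    return _finalize(gamma_sq, mask, crit)


def gpr_targets(planned: FluenceMap | np.ndarray, measured: np.ndarray,
                criteria: tuple[GammaCriterion, ...] = DEFAULT_CRITERIA,
                spacing_mm: float | None = None,
                search_radius_factor: float = 3.0,
                reference: str = "measured") -> np.ndarray:
    """GPR %-vector at the three clinical criteria, fixed order
    (1%/1mm, 2%/2mm, 2%/3mm).

    ``reference`` selects which grid hosts the evaluation points
    ("measured", the default, or "planned").
    """
    if isinstance(planned, FluenceMap):
        planned_vals = planned.values
        if spacing_mm is None:
            spacing_mm = planned.spacing_mm
    else:
        planned_vals = np.asarray(planned, dtype=np.float64)
        if spacing_mm is None:
            spacing_mm = 1.0
    measured = np.asarray(measured, dtype=np.float64)
    if reference == "measured":
        ref, cmp_ = measured, planned_vals
    elif reference == "planned":
        ref, cmp_ = planned_vals, measured
    else:
        raise ValueError("reference must be 'measured' or 'planned'")
    out = np.empty(3, dtype=np.float64)
    for k, crit in enumerate(criteria):
        out[k] = gamma_map(
            ref, cmp_, crit, spacing_mm=spacing_mm,
            search_radius_factor=search_radius_factor,
        ).gpr_percent
    return out
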