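"""Synthetic PSQA sample generation.

Emulates sliding-window IMRT delivery at desk scale: MLC-like aperture
sequences produce planned fluence maps, the same geometry yields the
33-slot complexity vector, a delivery perturbation model produces a
"measured" dose grid, and the gamma engine mints GPR targets.

The perturbation family is a stand-in for real measurement physics (which
the source protocol does not describe); it is parameterized so that

* ``rho_tab`` couples perturbation severity to the aperture geometry,
  making the tabular complexity metrics predictive of GPR, and
* ``rho_img`` scales a fixed spatial deformation (blurring) of the planned
  map whose signature in the dose-difference map is only recoverable from
  the image modality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from ._alloc import largest_remainder
from .data_model import (
    LESION_SITES,
    ComplexityVector,
    FluenceMap,
    PSQASample,
    QATargets,
)
from .gamma import gpr_targets

_JITTER_SEED = 20201207  # fixed: makes the proximal-layer copy deterministic
_OPEN_TOL = 1e-9


@dataclass
class ApertureSequence:
    """Sliding-window MLC aperture sequence for one beam.

    Leaf positions are in mm along the leaf-travel axis (grid columns);
    pair ``p`` covers a horizontal band of the field.
    """

    left_edges: np.ndarray   # (n_control_points, leaf_pairs)
    right_edges: np.ndarray  # (n_control_points, leaf_pairs)
    mu_per_cp: np.ndarray    # (n_control_points,)
    field_width_mm: float = 64.0
    leaf_width_mm: float = 4.0

    def __post_init__(self) -> None:
        self.left_edges = np.asarray(self.left_edges, dtype=np.float64)
        self.right_edges = np.asarray(self.right_edges, dtype=np.float64)
        self.mu_per_cp = np.asarray(self.mu_per_cp, dtype=np.float64)
        if self.left_edges.shape != self.right_edges.shape:
            raise ValueError("left/right edge arrays must share a shape")
        if self.left_edges.ndim != 2:
            raise ValueError("edge arrays must be (n_control_points, leaf_pairs)")
        if self.mu_per_cp.shape != (self.left_edges.shape[0],):
            raise ValueError("mu_per_cp length must equal n_control_points")
        if np.any(self.right_edges < self.left_edges - _OPEN_TOL):
            raise ValueError("right_edge < left_edge (negative leaf gap)")
        if np.any(self.mu_per_cp < 0):
            raise ValueError("mu_per_cp must be non-negative")

    @property
    def n_control_points(self) -> int:
        return self.left_edges.shape[0]

    @property
    def leaf_pairs(self) -> int:
        return self.left_edges.shape[1]

    @property
    def total_mu(self) -> float:
        return float(self.mu_per_cp.sum())

    def gaps(self) -> np.ndarray:
        return np.maximum(self.right_edges - self.left_edges, 0.0)


@dataclass
class DeliveryPerturbation:
    """Measured-dose error model: multiplicative gain, Gaussian blur,
    rigid shift and additive noise; deterministic given ``seed``."""

    gain: float = 1.0
    blur_sigma_mm: float = 0.0
    shift_mm: tuple[float, float] = (0.0, 0.0)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.blur_sigma_mm < 0 or self.noise_sd < 0:
            raise ValueError("blur_sigma_mm and noise_sd must be >= 0")


#: Per-site leaf-gap statistics (mm): (mean gap, per-beam mean spread,
#: within-beam gap sd).  H&N beams are the most modulated (small, variable
#: gaps); chest beams are the most open.
SITE_GAP_STATS: dict[str, tuple[float, float, float]] = {
    "H&N": (7.0, 2.0, 4.0),
    "C": (20.0, 3.0, 3.0),
    "A": (14.0, 2.5, 3.5),
    "P": (11.0, 2.5, 3.5),
}


def gen_aperture_sequence(site: str, seed: int | np.random.Generator,
                          n_control_points: int = 24, leaf_pairs: int = 16,
                          field_width_mm: float = 64.0,
                          leaf_width_mm: float | None = None) -> ApertureSequence:
    """Generate a sliding-window-style aperture sequence.

    A window of per-pair gaps sweeps across the field; gap statistics are
    site-dependent (H&N: smaller, more variable gaps than chest).
    """
    if site not in LESION_SITES:
        raise ValueError(f"unknown site {site!r}")
    if n_control_points < 1 or leaf_pairs < 1:
        raise ValueError("n_control_points and leaf_pairs must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if leaf_width_mm is None:
        leaf_width_mm = field_width_mm / leaf_pairs

    gap_mean, gap_spread, gap_sd = SITE_GAP_STATS[site]
    beam_gap_mean = max(1.0, rng.normal(gap_mean, gap_spread))

    # Open band of contiguous pairs ("target extent"); the rest stay closed.
    n_open = max(2, int(round(leaf_pairs * rng.uniform(0.55, 0.95))))
    n_open = min(n_open, leaf_pairs)
    first_open = rng.integers(0, leaf_pairs - n_open + 1)
    open_pairs = np.zeros(leaf_pairs, dtype=bool)
    open_pairs[first_open:first_open + n_open] = True

    margin = min(4.0, 0.1 * field_width_mm)
    if n_control_points == 1:
        centers = np.array([field_width_mm / 2.0])
    else:
        centers = np.linspace(margin, field_width_mm - margin, n_control_points)

    left = np.zeros((n_control_points, leaf_pairs))
    right = np.zeros((n_control_points, leaf_pairs))
    for k in range(n_control_points):
        gaps = np.maximum(rng.normal(beam_gap_mean, gap_sd, leaf_pairs), 0.0)
        wobble = rng.normal(0.0, 1.0, leaf_pairs)
        c = centers[k] + wobble
        lo = np.clip(c - gaps / 2.0, 0.0, field_width_mm)
        hi = np.clip(c + gaps / 2.0, 0.0, field_width_mm)
        lo[~open_pairs] = field_width_mm / 2.0
        hi[~open_pairs] = field_width_mm / 2.0
        left[k] = lo
        right[k] = np.maximum(hi, lo)

    mu = rng.gamma(shape=20.0, scale=1.0 / 20.0, size=n_control_points)
    mu = np.maximum(mu, 1e-3) * (100.0 / n_control_points)
    return ApertureSequence(left, right, mu, field_width_mm, leaf_width_mm)


def render_fluence(ap: ApertureSequence, grid: tuple[int, int],
                   spacing_mm: float = 1.0,
                   smoothing_sigma_px: float = 0.7) -> FluenceMap:
    """Accumulate MU-weighted open-aperture exposure, smooth and min-max
    normalize to [0, 1].

    Normalization guard: a constant non-zero exposure field maps to 1.0 on
    its support (all-closed sequences yield an all-zero map).
    """
    h, w = grid
    if h < 8 or w < 8:
        raise ValueError("grid must be at least 8x8")
    exposure = np.zeros((h, w), dtype=np.float64)
    # Pair p covers rows [bounds[p], bounds[p+1]).
    bounds = np.linspace(0, h, ap.leaf_pairs + 1).round().astype(int)
    xs = (np.arange(w) + 0.5) * spacing_mm  # pixel-center coordinates, mm
    for k in range(ap.n_control_points):
        mu = ap.mu_per_cp[k]
        if mu <= 0:
            continue
        for p in range(ap.leaf_pairs):
            lo, hi = ap.left_edges[k, p], ap.right_edges[k, p]
            if hi - lo <= _OPEN_TOL:
                continue
            cols = (xs >= lo) & (xs < hi)
            if cols.any():
                exposure[bounds[p]:bounds[p + 1], cols] += mu
    if smoothing_sigma_px > 0:
        exposure = ndimage.gaussian_filter(
            exposure, smoothing_sigma_px, mode="nearest"
        )
    lo, hi = exposure.min(), exposure.max()
    if hi > lo:
        values = (exposure - lo) / (hi - lo)
    elif hi > 0:
        values = (exposure > 0).astype(np.float64)
    else:
        values = np.zeros_like(exposure)
    return FluenceMap(values, spacing_mm=spacing_mm)


def _jittered_copy(ap: ApertureSequence) -> ApertureSequence:
    """Stand-in for the proximal MLC layer: same sequence with a small,
    deterministic edge jitter (fixed seed)."""
    rng = np.random.default_rng(_JITTER_SEED)
    left = ap.left_edges + rng.normal(0.0, 0.8, ap.left_edges.shape)
    right = ap.right_edges + rng.normal(0.0, 0.8, ap.right_edges.shape)
    left = np.clip(left, 0.0, ap.field_width_mm)
    right = np.clip(right, 0.0, ap.field_width_mm)
    right = np.maximum(right, left)
    return ApertureSequence(
        left, right, ap.mu_per_cp.copy(), ap.field_width_mm, ap.leaf_width_mm
    )


def _union_length(intervals: np.ndarray) -> float:
    """Total length covered by [lo, hi] intervals (rows of a (n, 2) array)."""
    ivs = intervals[intervals[:, 1] - intervals[:, 0] > _OPEN_TOL]
    if len(ivs) == 0:
        return 0.0
    ivs = ivs[np.argsort(ivs[:, 0])]
    total, cur_lo, cur_hi = 0.0, ivs[0, 0], ivs[0, 1]
    for lo, hi in ivs[1:]:
        if lo > cur_hi:
            total += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    return float(total + (cur_hi - cur_lo))


def _layer_metrics(ap: ApertureSequence) -> dict[str, float]:
    gaps = ap.gaps()                      # (n_cp, pairs), mm
    open_mask = gaps > _OPEN_TOL
    lw = ap.leaf_width_mm
    field_area = ap.field_width_mm * ap.leaf_pairs * lw

    areas = (gaps * open_mask).sum(axis=1) * lw          # per-CP aperture area
    perims = (open_mask * (2.0 * gaps + 2.0 * lw)).sum(axis=1)
    mean_area = float(areas.mean())
    max_area = float(areas.max())

    m: dict[str, float] = {}
    m["ALG"] = float(gaps.mean())
    m["SLG"] = float(gaps.std())
    n_open = int(open_mask.sum())
    for wdt in (2, 5, 10, 15):
        m[f"SAS-{wdt}mm"] = (
            float((open_mask & (gaps < wdt)).sum()) / n_open if n_open else 0.0
        )
    m["BA"] = mean_area / field_area
    union_area = 0.0
    for p in range(ap.leaf_pairs):
        ivs = np.stack([ap.left_edges[:, p], ap.right_edges[:, p]], axis=1)
        union_area += _union_length(ivs) * lw
    m["UAA"] = union_area / 100.0  # mm^2 -> cm^2
    m["CLS"] = float((~open_mask).sum()) / open_mask.size
    m["AAV"] = float(areas.std() / mean_area) if mean_area > 0 else 0.0
    lsv = 0.5 * (
        np.abs(np.diff(ap.left_edges, axis=1))
        + np.abs(np.diff(ap.right_edges, axis=1))
    )
    m["LSV"] = float(lsv.mean()) if lsv.size else 0.0
    cp_open = areas > 0
    m["C/A"] = float((perims[cp_open] / areas[cp_open]).mean()) if cp_open.any() else 0.0
    mid = 0.5 * (ap.left_edges + ap.right_edges)
    axis_x = ap.field_width_mm / 2.0
    m["MAD"] = float(np.abs(mid[open_mask] - axis_x).mean()) if n_open else 0.0
    m["PI"] = (
        float((perims[cp_open] ** 2 / (4.0 * np.pi * areas[cp_open])).mean())
        if cp_open.any() else 0.0
    )
    m["PM"] = 1.0 - mean_area / max_area if max_area > 0 else 0.0
    m["MCS"] = m["AAV"] * m["LSV"]
    return m


def compute_complexity_vector(ap: ApertureSequence) -> ComplexityVector:
    """Fill all 33 metric slots from the aperture geometry.

    Distal ("d-") slots are computed on the sequence itself and proximal
    ("p-") slots on a deterministically jittered copy standing in for the
    second MLC layer.  Raises on zero total MU.
    """
    if ap.total_mu <= 0:
        raise ValueError("aperture sequence has zero total MU")
    distal = _layer_metrics(ap)
    proximal = _layer_metrics(_jittered_copy(ap))
    values: list[float] = []
    for fam in ("AAV", "LSV", "MCS", "BA", "UAA", "PI", "PM", "C/A", "CLS", "MAD"):
        values.append(distal[fam])
        values.append(proximal[fam])
    for layer in (distal, proximal):
        for wdt in (2, 5, 10, 15):
            values.append(layer[f"SAS-{wdt}mm"])
    for fam in ("ALG", "SLG"):
        values.append(distal[fam])
        values.append(proximal[fam])
    values.append(ap.total_mu)
    return ComplexityVector(np.asarray(values))


def simulate_delivery(planned: FluenceMap, pert: DeliveryPerturbation,
                      spatial_error: np.ndarray | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Apply the perturbation model and return ``(measured, dd_map)`` with
    ``dd_map = measured - planned``; deterministic given ``pert.seed``."""
    x = planned.values.astype(np.float64, copy=True)
    if pert.blur_sigma_mm > 0:
        x = ndimage.gaussian_filter(
            x, pert.blur_sigma_mm / planned.spacing_mm, mode="nearest"
        )
    if any(s != 0.0 for s in pert.shift_mm):
        shift_px = tuple(s / planned.spacing_mm for s in pert.shift_mm)
        x = ndimage.shift(x, shift_px, order=1, mode="nearest")
    x = pert.gain * x
    if spatial_error is not None:
        x = x + spatial_error
    if pert.noise_sd > 0:
        rng = np.random.default_rng(pert.seed)
        x = x + rng.normal(0.0, pert.noise_sd, x.shape)
    measured = np.maximum(x, 0.0)
    return measured, measured - planned.values


@dataclass
class SimConfig:
    """Simulator configuration.

    ``rho_tab`` in [0, 1] couples perturbation severity to aperture
    complexity (tabular informativeness for GPR); ``rho_img`` in [0, 1]
    scales the fixed spatial blur whose dose-difference signature is only
    visible to the image modality.  ``site_difficulty`` multiplies the
    severity per lesion site (defaults equal, so site alone carries no
    signal when ``rho_tab = 0``).
    """

    n_samples: int = 40
    grid: tuple[int, int] = (64, 64)
    spacing_mm: float = 1.0
    lesion_mix: tuple[float, float, float, float] = (19 / 210, 138 / 210, 31 / 210, 22 / 210)
    site_difficulty: Mapping[str, float] = field(
        default_factory=lambda: {s: 1.0 for s in LESION_SITES}
    )
    rho_tab: float = 0.5
    rho_img: float = 0.5
    seed: int = 0
    # severity -> perturbation magnitudes (calibrated so GPRs populate the
    # <85 / 85-90 / 90-95 / >95 bins); localized "blob" errors carry most
    # of the GPR signal, gain/blur carry the image-predictable DD signal
    gain_dev_range: tuple[float, float] = (0.002, 0.015)
    noise_sd_range: tuple[float, float] = (0.0005, 0.002)
    blur_base_mm: float = 0.6
    blob_amp_range: tuple[float, float] = (0.02, 0.12)
    blob_sigma_mm: tuple[float, float] = (2.0, 4.0)
    # blobs per 1000 in-field pixels, so the failing *fraction* does not
    # depend on aperture size
    blob_density_range: tuple[float, float] = (1.0, 8.0)
    # saturated "hot" error spots (amplitude far above every dose
    # tolerance, hence unrescuable by the spatial search at any criterion):
    # their count scales with severity and in-field area, giving a
    # geometry-neutral GPR driver
    hot_density_max: float = 2.5
    hot_amp_range: tuple[float, float] = (0.4, 0.8)
    hot_sigma_mm: tuple[float, float] = (1.2, 2.2)
    n_control_points: int = 24
    leaf_pairs: int = 16

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise ValueError("n_samples must be >= 0")
        if not np.isclose(sum(self.lesion_mix), 1.0):
            raise ValueError("lesion_mix must sum to 1")
        for name in ("rho_tab", "rho_img"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "grid": list(self.grid),
            "spacing_mm": self.spacing_mm,
            "lesion_mix": list(self.lesion_mix),
            "site_difficulty": dict(self.site_difficulty),
            "rho_tab": self.rho_tab,
            "rho_img": self.rho_img,
            "seed": self.seed,
            "gain_dev_range": list(self.gain_dev_range),
            "noise_sd_range": list(self.noise_sd_range),
            "blur_base_mm": self.blur_base_mm,
            "blob_amp_range": list(self.blob_amp_range),
            "blob_sigma_mm": list(self.blob_sigma_mm),
            "blob_density_range": list(self.blob_density_range),
            "hot_density_max": self.hot_density_max,
            "hot_amp_range": list(self.hot_amp_range),
            "hot_sigma_mm": list(self.hot_sigma_mm),
            "n_control_points": self.n_control_points,
            "leaf_pairs": self.leaf_pairs,
        }


def _complexity_score(comp: ComplexityVector) -> float:
    """Severity driver in [0, 1]: small-aperture prevalence of the distal
    layer (d-SAS-5mm, a fraction), rescaled so typical beams span the
    whole range."""
    raw = comp.values[list(comp.names).index("d-SAS-5mm")]
    return float(np.clip(raw / 0.4, 0.0, 1.0))


def _blob_field(planned: np.ndarray, rng: np.random.Generator,
                amplitude: float, n_blobs: int, sigma_px: float) -> np.ndarray:
    """Localized dose-error field: Gaussian bumps (random sign, peak scale
    ``amplitude``) centred on in-field pixels.

    The error is *absolute* (confined to the field but not proportional to
    the local dose), so the failing fraction it induces under gamma
    analysis is nearly independent of the aperture geometry.
    """
    if n_blobs < 1 or amplitude <= 0:
        return np.zeros_like(planned)
    in_field = np.argwhere(planned > 0.1)
    if len(in_field) == 0:
        return np.zeros_like(planned)
    impulses = np.zeros_like(planned)
    centers = in_field[rng.integers(0, len(in_field), n_blobs)]
    for ci, cj in centers:
        amp = amplitude * rng.uniform(0.5, 1.5) * (1 if rng.uniform() < 0.5 else -1)
        impulses[ci, cj] += amp
    field = ndimage.gaussian_filter(impulses, sigma_px, mode="constant")
    field *= 2.0 * np.pi * sigma_px**2  # restore per-blob peak amplitude
    return field * (planned > 0.1)


def site_allocation(n: int, lesion_mix: Sequence[float]) -> list[int]:
    """Deterministic largest-remainder allocation of samples to the four
    lesion sites."""
    return largest_remainder(n, lesion_mix)


def crafted_imbalance_config(seed: int, n_samples: int = 400) -> SimConfig:
    """Simulator configuration with deliberate modality imbalance.

    Severity (and hence GPR) is driven almost entirely by the complexity
    metrics (``rho_tab = 0.9``) while a strong fixed blur puts spatial
    structure into the dose-difference maps that only the image modality
    can recover; localized error amplitudes are kept small so the
    image-predictable component dominates the DD signal.
    """
    return SimConfig(
        n_samples=n_samples, seed=seed, rho_tab=0.9, rho_img=1.0,
        blur_base_mm=1.5, blob_amp_range=(0.01, 0.08), hot_density_max=1.5,
    )


def generate_dataset(cfg: SimConfig) -> list[PSQASample]:
    """Generate ``cfg.n_samples`` valid PSQA samples, reproducibly.

    Severity ``t = (1 - rho_tab) * u + rho_tab * c`` mixes an iid uniform
    draw with the sample's own complexity score, then scales gain deviation
    and noise; GPR targets come from the gamma engine at the three clinical
    criteria (10% threshold).
    """
    rng = np.random.default_rng(cfg.seed)
    counts = site_allocation(cfg.n_samples, cfg.lesion_mix)
    sites: list[str] = []
    for site, c in zip(LESION_SITES, counts):
        sites.extend([site] * c)
    sites = [sites[i] for i in rng.permutation(len(sites))]

    h, w = cfg.grid
    field_width = w * cfg.spacing_mm
    samples: list[PSQASample] = []
    for i, site in enumerate(sites):
        ap_seed = int(rng.integers(0, 2**31 - 1))
        noise_seed = int(rng.integers(0, 2**31 - 1))
        ap = gen_aperture_sequence(
            site, ap_seed, n_control_points=cfg.n_control_points,
            leaf_pairs=cfg.leaf_pairs, field_width_mm=field_width,
        )
        fluence = render_fluence(ap, cfg.grid, cfg.spacing_mm)
        comp = compute_complexity_vector(ap)

        u = rng.uniform()
        c = _complexity_score(comp)
        t = (1.0 - cfg.rho_tab) * u + cfg.rho_tab * c
        t = float(np.clip(t * cfg.site_difficulty.get(site, 1.0), 0.0, 1.0))
        g0, g1 = cfg.gain_dev_range
        n0, n1 = cfg.noise_sd_range
        a0, a1 = cfg.blob_amp_range
        direction = 1.0 if rng.uniform() < 0.5 else -1.0
        pert = DeliveryPerturbation(
            gain=1.0 + direction * (g0 + g1 * t),
            blur_sigma_mm=cfg.rho_img * cfg.blur_base_mm,
            noise_sd=n0 + n1 * t,
            seed=noise_seed,
        )
        density = rng.uniform(*cfg.blob_density_range)
        in_field_px = int((fluence.values > 0.1).sum())
        n_blobs = max(1, int(round(density * in_field_px / 1000.0)))
        sigma_px = rng.uniform(*cfg.blob_sigma_mm) / cfg.spacing_mm
        blob = _blob_field(fluence.values, rng, a0 + a1 * t, n_blobs, sigma_px)
        hot_density = rng.uniform(0.0, cfg.hot_density_max) * t
        n_hot = int(round(hot_density * in_field_px / 1000.0))
        if n_hot > 0:
            hot_sigma = rng.uniform(*cfg.hot_sigma_mm) / cfg.spacing_mm
            hot_amp = rng.uniform(*cfg.hot_amp_range)
            blob = blob + np.abs(
                _blob_field(fluence.values, rng, hot_amp, n_hot, hot_sigma)
            )
        measured, dd = simulate_delivery(fluence, pert, spatial_error=blob)
        gpr = gpr_targets(fluence, measured, spacing_mm=cfg.spacing_mm)
        samples.append(
            PSQASample(
                sample_id=f"s{i:05d}",
                lesion_site=site,
                fluence=fluence,
                complexity=comp,
                targets=QATargets(gpr, dd),
                provenance={
                    "aperture_seed": ap_seed,
                    "noise_seed": noise_seed,
                    "severity": t,
                    "gain": pert.gain,
                    "noise_sd": pert.noise_sd,
                    "blur_sigma_mm": pert.blur_sigma_mm,
                },
            )
        )
    return samples
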