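"""Core domain types, validation and dataset persistence for PSQA samples.

A sample couples one beam's planned fluence map (image modality) with a
33-element plan-complexity vector (tabular modality) and its QA targets:
three Gamma Passing Rates and a dose-difference map.

Persistence is a single HDF5 container with one group per sample plus a
tabular index; the index can be exported to CSV.  Arrays round-trip
bit-exactly (float64 throughout).
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd
from h5py import h5g, h5p

logger = logging.getLogger(__name__)

#: Lesion sites (head & neck, chest, abdomen, pelvis).
LESION_SITES = ("H&N", "C", "A", "P")

#: Gamma criteria column labels used in the index, ordered
#: (1%/1 mm, 2%/2 mm, 2%/3 mm).
GPR_COLUMNS = ("gpr_1_1", "gpr_2_2", "gpr_2_3")

_METRIC_FAMILIES = (
    "AAV", "LSV", "MCS", "BA", "UAA", "PI", "PM", "C/A", "CLS", "MAD",
)


def _build_metric_names() -> tuple[str, ...]:
    names: list[str] = []
    for fam in _METRIC_FAMILIES:
        names.append(f"d-{fam}")
        names.append(f"p-{fam}")
    for layer in ("d", "p"):
        for w in (2, 5, 10, 15):
            names.append(f"{layer}-SAS-{w}mm")
    for fam in ("ALG", "SLG"):
        names.append(f"d-{fam}")
        names.append(f"p-{fam}")
    names.append("MU")
    return tuple(names)


#: Fixed ordering of the 33 complexity-metric slots.  Positional semantics
#: are preserved through persistence.
METRIC_NAMES: tuple[str, ...] = _build_metric_names()
assert len(METRIC_NAMES) == 33

_FORMAT_VERSION = 1


@dataclass
class FluenceMap:
    """A 2-D normalized dose-intensity grid.

    Row-major, index (0, 0) at the top-left; physical coordinates in mm are
    ``index * spacing_mm`` (0-based).
    """

    values: np.ndarray
    spacing_mm: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def violations(self) -> list[str]:
        out: list[str] = []
        v = self.values
        if v.ndim != 2:
            out.append(f"fluence: expected 2-D grid, got ndim={v.ndim}")
            return out
        h, w = v.shape
        if h < 8 or w < 8:
            out.append(f"fluence: grid {h}x{w} smaller than 8x8")
        if not np.all(np.isfinite(v)):
            out.append("fluence: non-finite values present")
        elif v.min() < 0.0 or v.max() > 1.0:
            out.append(
                f"fluence: values outside [0, 1] (min={v.min():.6g}, "
                f"max={v.max():.6g})"
            )
        if not (np.isfinite(self.spacing_mm) and self.spacing_mm > 0):
            out.append(f"fluence: spacing_mm must be positive, got {self.spacing_mm}")
        return out


@dataclass
class ComplexityVector:
    """Ordered 33-slot plan-complexity metric vector."""

    values: np.ndarray
    names: Sequence[str] = METRIC_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.names = tuple(self.names)

    def violations(self) -> list[str]:
        out: list[str] = []
        if self.values.ndim != 1 or self.values.shape[0] != 33:
            out.append(
                f"complexity: expected length-33 vector, got shape {self.values.shape}"
            )
        elif not np.all(np.isfinite(self.values)):
            out.append("complexity: non-finite values present")
        if len(self.names) != 33:
            out.append(f"complexity: expected 33 names, got {len(self.names)}")
        return out

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


@dataclass
class QATargets:
    """QA targets: GPR %-vector ordered (1%/1mm, 2%/2mm, 2%/3mm) and an
    optional dose-difference map at fluence resolution."""

    gpr_percent: np.ndarray
    dd_map: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gpr_percent = np.asarray(self.gpr_percent, dtype=np.float64)
        if self.dd_map is not None:
            self.dd_map = np.asarray(self.dd_map, dtype=np.float64)

    @property
    def has_dd(self) -> bool:
        return self.dd_map is not None

    def violations(self, fluence_shape: tuple[int, int] | None = None) -> list[str]:
        out: list[str] = []
        g = self.gpr_percent
        if g.shape != (3,):
            out.append(f"targets: gpr_percent must have shape (3,), got {g.shape}")
        elif not np.all(np.isfinite(g)):
            out.append("targets: non-finite GPR values")
        elif g.min() < 0.0 or g.max() > 100.0:
            out.append(
                f"targets: GPR outside [0, 100] (min={g.min():.6g}, max={g.max():.6g})"
            )
        if self.dd_map is not None:
            if self.dd_map.ndim != 2:
                out.append("targets: dd_map must be 2-D")
            elif fluence_shape is not None and self.dd_map.shape != fluence_shape:
                out.append(
                    f"targets: dd_map shape {self.dd_map.shape} does not match "
                    f"fluence shape {fluence_shape}"
                )
            if self.dd_map.ndim == 2 and not np.all(np.isfinite(self.dd_map)):
                out.append("targets: non-finite dd_map values")
        return out


@dataclass
class PSQASample:
    """One beam: fluence map, complexity vector, lesion site and QA targets."""

    sample_id: str
    lesion_site: str
    fluence: FluenceMap
    complexity: ComplexityVector
    targets: QATargets
    plan_id: str = ""
    provenance: dict = field(default_factory=dict)

    def violations(self) -> list[str]:
        out: list[str] = []
        if not self.sample_id:
            out.append("sample: empty sample_id")
        if self.lesion_site not in LESION_SITES:
            out.append(
                f"sample {self.sample_id!r}: lesion_site {self.lesion_site!r} "
                f"not in {LESION_SITES}"
            )
        out.extend(self.fluence.violations())
        out.extend(self.complexity.violations())
        shape = self.fluence.shape if self.fluence.values.ndim == 2 else None
        out.extend(self.targets.violations(shape))
        return out


def validate_sample(sample: PSQASample) -> list[str]:
    """Return every violated invariant as a human-readable string.

    An empty list means the sample is valid.  Pure: never mutates input.
    """
    return sample.violations()


def _create_group(parent, name: str):
    # no object-header timestamps, so identical content => identical bytes
    gcpl = h5p.create(h5p.GROUP_CREATE)
    gcpl.set_obj_track_times(False)
    return h5py.Group(h5g.create(parent.id, name.encode(), gcpl=gcpl))


def _write_array(group, name: str, data) -> None:
    group.create_dataset(name, data=data, track_times=False)


class DatasetFormatError(RuntimeError):
    """Raised when a container file does not conform to the expected layout."""


class DatasetValidationError(ValueError):
    """Raised when invalid samples are passed to :func:`save_dataset`."""


def save_dataset(samples: Iterable[PSQASample], path: str | os.PathLike,
                 provenance: dict | None = None) -> None:
    """Persist samples to one HDF5 container (atomic: temp file + rename).

    Raises :class:`DatasetValidationError` naming offending sample ids if
    any sample is invalid or ids collide; no file is written in that case.
    """
    samples = list(samples)
    bad: dict[str, list[str]] = {}
    seen: set[str] = set()
    for s in samples:
        v = validate_sample(s)
        if s.sample_id in seen:
            v = v + ["duplicate sample_id within dataset"]
        seen.add(s.sample_id)
        if v:
            bad[s.sample_id] = v
    if bad:
        detail = "; ".join(f"{k}: {v}" for k, v in bad.items())
        raise DatasetValidationError(
            f"refusing to save, invalid samples: {sorted(bad)} ({detail})"
        )

    path = os.fspath(path)
    dirname = os.path.dirname(os.path.abspath(path))
    os.makedirs(dirname, exist_ok=True)
    fd, tmp = tempfile.mkstemp(suffix=".h5", dir=dirname)
    os.close(fd)
    try:
        with h5py.File(tmp, "w") as f:
            f.attrs["format_version"] = _FORMAT_VERSION
            f.attrs["metric_names"] = json.dumps(list(METRIC_NAMES))
            if provenance:
                f.attrs["provenance"] = json.dumps(provenance)
            grp_samples = _create_group(f, "samples")
            for s in samples:
                g = _create_group(grp_samples, s.sample_id)
                _write_array(g, "fluence", s.fluence.values)
                g.attrs["spacing_mm"] = float(s.fluence.spacing_mm)
                g.attrs["lesion_site"] = s.lesion_site
                g.attrs["plan_id"] = s.plan_id
                _write_array(g, "complexity", s.complexity.values)
                _write_array(g, "gpr_percent", s.targets.gpr_percent)
                g.attrs["has_dd"] = bool(s.targets.has_dd)
                if s.targets.has_dd:
                    _write_array(g, "dd_map", s.targets.dd_map)
                if s.provenance:
                    g.attrs["sample_provenance"] = json.dumps(s.provenance)
            idx = _create_group(f, "index")
            ids = [s.sample_id for s in samples]
            sites = [s.lesion_site for s in samples]
            str_dt = h5py.string_dtype(encoding="utf-8")
            idx.create_dataset("sample_id", data=ids, dtype=str_dt,
                               track_times=False)
            idx.create_dataset("lesion_site", data=sites, dtype=str_dt,
                               track_times=False)
            metrics = (
                np.stack([s.complexity.values for s in samples])
                if samples else np.zeros((0, 33))
            )
            gprs = (
                np.stack([s.targets.gpr_percent for s in samples])
                if samples else np.zeros((0, 3))
            )
            _write_array(idx, "complexity", metrics)
            _write_array(idx, "gpr_percent", gprs)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def load_dataset(path: str | os.PathLike) -> list[PSQASample]:
    """Load a container written by :func:`save_dataset`.

    ``load(save(X))`` reproduces X with bit-identical arrays.  Unknown
    extra groups/attributes are ignored with a logged warning.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    out: list[PSQASample] = []
    with h5py.File(path, "r") as f:
        if "samples" not in f:
            raise DatasetFormatError("missing required group 'samples'")
        known_root = {"samples", "index"}
        extras = [k for k in f.keys() if k not in known_root]
        if extras:
            logger.warning("ignoring unknown groups in %s: %s", path, extras)
        for sid in f["samples"]:
            g = f["samples"][sid]
            for req in ("fluence", "complexity", "gpr_percent"):
                if req not in g:
                    raise DatasetFormatError(
                        f"sample {sid!r}: missing required field {req!r}"
                    )
            dd = g["dd_map"][()] if "dd_map" in g else None
            prov = {}
            if "sample_provenance" in g.attrs:
                prov = json.loads(g.attrs["sample_provenance"])
            out.append(
                PSQASample(
                    sample_id=sid,
                    lesion_site=str(g.attrs.get("lesion_site", "")),
                    fluence=FluenceMap(
                        g["fluence"][()],
                        spacing_mm=float(g.attrs.get("spacing_mm", 1.0)),
                    ),
                    complexity=ComplexityVector(g["complexity"][()]),
                    targets=QATargets(g["gpr_percent"][()], dd),
                    plan_id=str(g.attrs.get("plan_id", "")),
                    provenance=prov,
                )
            )
    out.sort(key=lambda s: s.sample_id)
    return out


def dataset_index(samples: Sequence[PSQASample]) -> pd.DataFrame:
    """Tabular index: sample_id, lesion_site, 33 metrics, 3 GPR columns."""
    rows = []
    for s in samples:
        row: dict[str, object] = {
            "sample_id": s.sample_id,
            "lesion_site": s.lesion_site,
        }
        row.update(s.complexity.as_dict())
        for col, val in zip(GPR_COLUMNS, s.targets.gpr_percent):
            row[col] = float(val)
        rows.append(row)
    cols = ["sample_id", "lesion_site", *METRIC_NAMES, *GPR_COLUMNS]
    return pd.DataFrame(rows, columns=cols)


def export_index_csv(samples: Sequence[PSQASample], path: str | os.PathLike) -> None:
    dataset_index(samples).to_csv(path, index=False, encoding="utf-8")
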