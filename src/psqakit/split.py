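"""Multi-factor stratified train/validation/test splitting.

Strata are the cross-product of a GPR bin (on a configurable criterion;
bins <85, 85-90, 90-95, >=95) and the lesion site.  Within each stratum
samples are canonically sorted by id, shuffled with the seed and allocated
7:1:2 by largest remainder with ties broken train > test > val.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
import numpy as np

from ._alloc import largest_remainder
from .data_model import PSQASample

SPLIT_NAMES = ("train", "val", "test")
#: Remainder tie-break ranks: train > test > val.
_TIE_PRIORITY = {"train": 0, "val": 2, "test": 1}

GPR_BIN_EDGES = (85.0, 90.0, 95.0)
GPR_BIN_LABELS = ("<85", "85-90", "90-95", ">=95")

#: Criterion used for binning (index into the GPR 3-vector): 2%/2mm.
DEFAULT_BIN_CRITERION = 1


def gpr_bin(gpr: float) -> str:
    """Half-open [lo, hi) bins, with >=95 closed at the top."""
    if gpr < 85.0:
        return "<85"
    if gpr < 90.0:
        return "85-90"
    if gpr < 95.0:
        return "90-95"
    return ">=95"


@dataclass
class SplitAssignment:
    """Mapping sample_id -> split plus the stratum label per sample."""

    assignment: dict[str, str]
    strata: dict[str, str]

    def ids(self, split: str) -> list[str]:
        if split not in SPLIT_NAMES:
            raise ValueError(f"unknown split {split!r}")
        return sorted(k for k, v in self.assignment.items() if v == split)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sample_id": sid, "stratum": self.strata[sid],
             "split": self.assignment[sid]}
            for sid in sorted(self.assignment)
        ]
        return pd.DataFrame(rows, columns=["sample_id", "stratum", "split"])

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load_csv(cls, path) -> "SplitAssignment":
        df = pd.read_csv(path)
        for col in ("sample_id", "stratum", "split"):
            if col not in df.columns:
                raise ValueError(f"split CSV missing column {col!r}")
        return cls(
            assignment=dict(zip(df["sample_id"], df["split"])),
            strata=dict(zip(df["sample_id"], df["stratum"])),
        )


def stratified_split(samples: Sequence[PSQASample],
                     ratios: tuple[float, float, float] = (0.7, 0.1, 0.2),
                     bin_criterion: int = DEFAULT_BIN_CRITERION,
                     seed: int = 0) -> SplitAssignment:
    """Deterministic stratified split by GPR bin x lesion site.

    Input order does not matter: samples are sorted by id before the
    seeded shuffle, so permutations of the input yield the same
    assignment.
    """
    if len(samples) == 0:
        raise ValueError("cannot split an empty sample collection")
    if not np.isclose(sum(ratios), 1.0):
        raise ValueError("ratios must sum to 1")

    strata: dict[str, list[str]] = {}
    stratum_of: dict[str, str] = {}
    for s in sorted(samples, key=lambda s: s.sample_id):
        label = f"{gpr_bin(float(s.targets.gpr_percent[bin_criterion]))}|{s.lesion_site}"
        strata.setdefault(label, []).append(s.sample_id)
        stratum_of[s.sample_id] = label

    rng = np.random.default_rng(seed)
    priority = [_TIE_PRIORITY[name] for name in SPLIT_NAMES]
    assignment: dict[str, str] = {}
    for label in sorted(strata):
        ids = strata[label]
        order = rng.permutation(len(ids))
        shuffled = [ids[i] for i in order]
        counts = largest_remainder(len(ids), ratios, priority=priority)
        pos = 0
        for name, c in zip(SPLIT_NAMES, counts):
            for sid in shuffled[pos:pos + c]:
                assignment[sid] = name
            pos += c
    return SplitAssignment(assignment=assignment, strata=stratum_of)


def split_samples(samples: Sequence[PSQASample], assignment: SplitAssignment
                  ) -> dict[str, list[PSQASample]]:
    """Partition samples according to an assignment (id-sorted)."""
    by_id = {s.sample_id: s for s in samples}
    missing = set(assignment.assignment) - set(by_id)
    if missing:
        raise ValueError(f"assignment references unknown ids: {sorted(missing)[:5]}")
    out: dict[str, list[PSQASample]] = {name: [] for name in SPLIT_NAMES}
    for sid in sorted(assignment.assignment):
        out[assignment.assignment[sid]].append(by_id[sid])
    return out
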