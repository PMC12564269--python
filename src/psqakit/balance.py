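"""Shapley-value modality attribution and dynamic task weighting.

The value of a modality subset is the negative validation MAE of the GPR
predictions restricted to that subset (the empty subset is fixed to zero).
The two-modality Shapley decomposition of that game yields per-modality
contributions; tabular dominance (phi_tab > phi_img) inflates the
dose-difference loss weight lambda = 1 + max(phi_tab - phi_img, 0) * r / 2.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .nn.model import BOTH, EMPTY, IMG, SUBSETS, TAB, SubsetPredictions


@dataclass
class SubsetValue:
    """Value function over the four modality subsets; v(empty) == 0."""

    v: dict[frozenset[str], float]

    def __post_init__(self) -> None:
        if set(self.v) != set(SUBSETS):
            raise ValueError("v must be defined on exactly the four subsets")
        if self.v[EMPTY] != 0.0:
            raise ValueError("v(empty) must be 0")
        for s, val in self.v.items():
            if not math.isfinite(val):
                raise ValueError(f"non-finite value for subset {set(s)}")

    def __getitem__(self, subset: frozenset[str]) -> float:
        return self.v[subset]


@dataclass
class ShapleyReport:
    """Per-epoch modality attribution record."""

    phi_img: float
    phi_tab: float
    lambda_ddp: float
    epoch: int
    v: SubsetValue

    def __post_init__(self) -> None:
        eff = self.phi_img + self.phi_tab - (self.v[BOTH] - self.v[EMPTY])
        if abs(eff) > 1e-9:
            raise ValueError(f"efficiency identity violated by {eff:.3g}")
        if self.lambda_ddp < 1.0:
            raise ValueError("lambda_ddp must be >= 1")

    def to_dict(self) -> dict:
        return {
            "epoch": self.epoch,
            "phi_img": self.phi_img,
            "phi_tab": self.phi_tab,
            "lambda_ddp": self.lambda_ddp,
            "v_img": self.v[IMG],
            "v_tab": self.v[TAB],
            "v_both": self.v[BOTH],
        }


def value_function(predictions: SubsetPredictions,
                   targets: np.ndarray) -> SubsetValue:
    """v(S) = -MAE over all validation samples and all three GPR
    components; v(empty) is forced to 0 (shared constant offset)."""
    targets = np.asarray(targets, dtype=np.float64)
    if targets.size == 0:
        raise ValueError("empty validation set")
    v: dict[frozenset[str], float] = {EMPTY: 0.0}
    for s in (IMG, TAB, BOTH):
        pred = predictions[s]
        if pred.shape != targets.shape:
            raise ValueError(
                f"prediction shape {pred.shape} != target shape {targets.shape}"
            )
        v[s] = float(-np.mean(np.abs(targets - pred)))
    return SubsetValue(v)


def shapley_two_modality(v: SubsetValue) -> tuple[float, float]:
    """Closed-form two-player Shapley decomposition of the modality game."""
    phi_img = 0.5 * (v[IMG] - v[EMPTY]) + 0.5 * (v[BOTH] - v[TAB])
    phi_tab = 0.5 * (v[TAB] - v[EMPTY]) + 0.5 * (v[BOTH] - v[IMG])
    return phi_img, phi_tab


def shapley_oracle(v: dict[frozenset, float], players: tuple) -> np.ndarray:
    """Exact Shapley values by enumerating all player orderings.

    ``v`` must be defined on the full power set of ``players`` (n <= 8).
    Verification oracle for :func:`shapley_two_modality`.
    """
    n = len(players)
    if n > 8:
        raise ValueError("oracle restricted to n <= 8 players")
    full = [frozenset(c) for r in range(n + 1)
            for c in itertools.combinations(players, r)]
    missing = [set(s) for s in full if s not in v]
    if missing:
        raise ValueError(f"value function incomplete, missing {missing}")
    phi = np.zeros(n)
    n_orders = math.factorial(n)
    for order in itertools.permutations(range(n)):
        coalition: frozenset = frozenset()
        for idx in order:
            with_i = coalition | {players[idx]}
            phi[idx] += v[with_i] - v[coalition]
            coalition = with_i
    return phi / n_orders


def compute_lambda(phi_img: float, phi_tab: float, r: float) -> float:
    """Dose-difference loss coefficient:
    lambda = 1 + max(phi_tab - phi_img, 0) * r / 2.

    Returns exactly 1 when phi_tab <= phi_img or r == 0.
    """
    if r < 0:
        raise ValueError("r must be >= 0")
    return 1.0 + max(phi_tab - phi_img, 0.0) * r / 2.0


def total_loss(l_gpr: float, l_ddp: float, lambda_ddp: float) -> float:
    """Overall objective L = L_gpr + lambda * L_ddp."""
    if l_gpr < 0 or l_ddp < 0:
        raise ValueError("losses must be >= 0")
    return l_gpr + lambda_ddp * l_ddp


def make_report(predictions: SubsetPredictions, targets: np.ndarray,
                r: float, epoch: int) -> ShapleyReport:
    """Convenience: value function -> Shapley -> lambda, as one record."""
    v = value_function(predictions, targets)
    phi_img, phi_tab = shapley_two_modality(v)
    lam = compute_lambda(phi_img, phi_tab, r)
    return ShapleyReport(phi_img=phi_img, phi_tab=phi_tab, lambda_ddp=lam,
                         epoch=epoch, v=v)
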