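"""Balanced multi-task training loop.

Each epoch minimizes ``L = L_gpr + lambda * L_ddp`` (both MAE) with the
lambda computed from the *previous* epoch's validation-set Shapley report
(lambda starts at 1).  With ``r = 0`` every lambda is 1 and the loop is the
unbalanced baseline — same code path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .balance import ShapleyReport, make_report
from .data_model import PSQASample
from .nn.autograd import Tensor
from .nn.layers import Adam
from .nn.model import (
    BOTH,
    SUBSETS,
    NetworkConfig,
    QAModel,
    SubsetPredictions,
    multi_subset_forward,
)

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults follow the reference protocol)."""

    r: float = 16.0
    lr: float = 5e-4
    epochs: int = 30
    batch_size: int = 32
    split: tuple[float, float, float] = (0.7, 0.1, 0.2)
    dropout: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValueError("r must be >= 0")
        if not np.isclose(sum(self.split), 1.0):
            raise ValueError("split must sum to 1")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")

    def to_dict(self) -> dict:
        return {
            "r": self.r, "lr": self.lr, "epochs": self.epochs,
            "batch_size": self.batch_size, "split": list(self.split),
            "dropout": self.dropout, "seed": self.seed,
        }


@dataclass
class ArrayDataset:
    """Dense array view of a sample collection."""

    x_img: np.ndarray   # (n, H, W)
    x_tab: np.ndarray   # (n, 33)
    y_gpr: np.ndarray   # (n, 3)
    y_dd: np.ndarray | None  # (n, H, W) or None
    sample_ids: tuple[str, ...] = ()

    def __len__(self) -> int:
        return self.x_img.shape[0]


def samples_to_arrays(samples: Sequence[PSQASample]) -> ArrayDataset:
    if not samples:
        raise ValueError("empty sample collection")
    x_img = np.stack([s.fluence.values for s in samples])
    x_tab = np.stack([s.complexity.values for s in samples])
    y_gpr = np.stack([s.targets.gpr_percent for s in samples])
    if all(s.targets.has_dd for s in samples):
        y_dd = np.stack([s.targets.dd_map for s in samples])
    else:
        y_dd = None
    return ArrayDataset(x_img, x_tab, y_gpr, y_dd,
                        tuple(s.sample_id for s in samples))


def _mae(pred: Tensor, target: np.ndarray) -> Tensor:
    return (pred - Tensor(target)).abs().mean()


def train_epoch(model: QAModel, data: ArrayDataset, lam: float,
                opt: Adam, rng: np.random.Generator,
                batch_size: int = 32) -> tuple[float, float]:
    """One shuffled pass over the training data; returns the mean GPR and
    DDP losses.  Aborts on non-finite loss."""
    if lam < 1.0:
        raise ValueError("lambda must be >= 1")
    if data.y_dd is None:
        raise ValueError("training requires dose-difference targets")
    n = len(data)
    order = rng.permutation(n)
    gpr_losses: list[float] = []
    ddp_losses: list[float] = []
    for start in range(0, n, batch_size):
        idx = order[start:start + batch_size]
        z_img, z_tab = model.encode(data.x_img[idx], data.x_tab[idx])
        pred_gpr = model.predict_gpr(z_img, z_tab, subset=BOTH, train=True,
                                     rng=rng)
        l_gpr = _mae(pred_gpr, data.y_gpr[idx])
        pred_dd = model.predict_ddp(z_img, z_tab)
        l_ddp = _mae(pred_dd, data.y_dd[idx])
        loss = l_gpr + Tensor(lam) * l_ddp
        if not np.isfinite(loss.data):
            raise RuntimeError(
                f"non-finite loss at batch starting {start}: "
                f"l_gpr={l_gpr.data}, l_ddp={l_ddp.data}, lambda={lam}"
            )
        opt.zero_grad()
        loss.backward()
        opt.step()
        gpr_losses.append(float(l_gpr.data))
        ddp_losses.append(float(l_ddp.data))
    return float(np.mean(gpr_losses)), float(np.mean(ddp_losses))


def predict_subsets(model: QAModel, data: ArrayDataset,
                    batch_size: int = 64) -> SubsetPredictions:
    """Batched multi-subset GPR predictions over a whole dataset
    (eval mode)."""
    chunks: dict[frozenset, list[np.ndarray]] = {s: [] for s in SUBSETS}
    for start in range(0, len(data), batch_size):
        sl = slice(start, start + batch_size)
        preds = multi_subset_forward(model, data.x_img[sl], data.x_tab[sl])
        for s in SUBSETS:
            chunks[s].append(preds[s])
    return SubsetPredictions(
        {s: np.concatenate(chunks[s], axis=0) for s in SUBSETS}
    )


def predict(model: QAModel, data: ArrayDataset, batch_size: int = 64,
            with_ddp: bool = True) -> tuple[np.ndarray, np.ndarray | None]:
    """Full-modality predictions: GPR (n, 3) and optionally DD maps."""
    gpr_out: list[np.ndarray] = []
    dd_out: list[np.ndarray] = []
    for start in range(0, len(data), batch_size):
        sl = slice(start, start + batch_size)
        z_img, z_tab = model.encode(data.x_img[sl], data.x_tab[sl])
        gpr_out.append(
            model.predict_gpr(z_img, z_tab, subset=BOTH, train=False).data
        )
        if with_ddp:
            dd_out.append(model.predict_ddp(z_img, z_tab).data)
    return (np.concatenate(gpr_out, axis=0),
            np.concatenate(dd_out, axis=0) if with_ddp else None)


@dataclass
class FitResult:
    model: QAModel
    reports: list[ShapleyReport]
    history: list[dict] = field(default_factory=list)


def fit(train_data: ArrayDataset, val_data: ArrayDataset,
        net_cfg: NetworkConfig, cfg: TrainConfig) -> FitResult:
    """Train for ``cfg.epochs`` epochs with dynamic DDP loss weighting.

    Per epoch: one training pass with the previous epoch's lambda
    (initialized to 1), then an eval-mode multi-subset validation forward
    producing the Shapley report that sets the next lambda.  The GPR head
    bias starts at the training-set mean GPR and the tabular encoder uses
    training-set standardization (both recorded in the history).
    """
    seeds = np.random.SeedSequence(cfg.seed).spawn(3)
    init_seed = int(seeds[0].generate_state(1)[0])
    model = QAModel(net_cfg, seed=init_seed)
    model.set_tab_stats(train_data.x_tab.mean(axis=0),
                        train_data.x_tab.std(axis=0))
    model.gpr_head.set_bias(train_data.y_gpr.mean(axis=0))

    shuffle_rng = np.random.default_rng(seeds[1])
    opt = Adam(model.parameters(), lr=cfg.lr)
    lam = 1.0
    reports: list[ShapleyReport] = []
    history: list[dict] = []
    for epoch in range(cfg.epochs):
        l_gpr, l_ddp = train_epoch(model, train_data, lam, opt, shuffle_rng,
                                   batch_size=cfg.batch_size)
        preds = predict_subsets(model, val_data)
        report = make_report(preds, val_data.y_gpr, cfg.r, epoch)
        reports.append(report)
        history.append({
            "epoch": epoch, "l_gpr": l_gpr, "l_ddp": l_ddp,
            "lambda_used": lam, **report.to_dict(),
        })
        logger.info(
            "epoch %d: L_gpr=%.4f L_ddp=%.5f lambda_used=%.3f "
            "phi_img=%.4f phi_tab=%.4f lambda_next=%.3f",
            epoch, l_gpr, l_ddp, lam, report.phi_img, report.phi_tab,
            report.lambda_ddp,
        )
        lam = report.lambda_ddp
    return FitResult(model=model, reports=reports, history=history)
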