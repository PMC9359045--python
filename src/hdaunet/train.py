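"""Cohort splitting, optimization protocol, model selection, prediction.

Training follows a fixed protocol: Adam (learning rate 1e-3, beta1 0.9,
beta2 0.999, epsilon 1e-7), batch size 1, a fixed number of epochs with the
case order reshuffled every epoch, no augmentation and no schedule. After
training, the returned weights are those of the epoch with the lowest
validation loss.

Doses are trained in min-max normalized form (per case, bounds
(0, case max dose)); the DVH term of the combined objective is evaluated in
Gy by rescaling the prediction with the same bounds, so one threshold grid
in Gy serves both training and evaluation. Predictions are mapped back to
Gy with the case's recorded bounds (or the prescription when no reference
dose is available).

Everything stochastic — weight initialization and epoch shuffling — derives
from the single ``TrainConfig.seed``, so runs are bit-reproducible.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .core import DivergenceError, DoseVolume, PlanCase
from .dvh import DVHSpec, LossWeights, combined_loss_tensor
from .models import ArchConfig, Module, build_model
from .preprocess import assemble_channels

__all__ = [
    "SplitSpec",
    "TrainConfig",
    "TrainedRun",
    "Adam",
    "split_cohort",
    "structure_order_for",
    "train",
    "predict",
]


@dataclass
class SplitSpec:
    """Fractional (train, val, test) split or explicit case-id lists."""

    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0
    train_ids: list[str] | None = None
    val_ids: list[str] | None = None
    test_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if self.explicit:
            return
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")

    @property
    def explicit(self) -> bool:
        return any(x is not None for x in (self.train_ids, self.val_ids, self.test_ids))


def split_cohort(case_ids: list[str], spec: SplitSpec) -> tuple[list[str], list[str], list[str]]:
    """Deterministic split; val/test sizes are round(n*f), remainder to train."""
    if spec.explicit:
        tr = list(spec.train_ids or [])
        va = list(spec.val_ids or [])
        te = list(spec.test_ids or [])
        seen: set[str] = set()
        for group in (tr, va, te):
            overlap = seen & set(group)
            if overlap:
                raise ValueError(f"explicit split lists overlap: {sorted(overlap)}")
            seen |= set(group)
        return tr, va, te
    n = len(case_ids)
    if n < 3:
        raise ValueError("fractional splits need at least 3 cases")
    n_val = round(n * spec.fractions[1])
    n_test = round(n * spec.fractions[2])
    n_train = n - n_val - n_test
    order = np.random.default_rng(spec.seed).permutation(n)
    ids = [case_ids[i] for i in order]
    return ids[:n_train], ids[n_train : n_train + n_val], ids[n_train + n_val :]


@dataclass
class TrainConfig:
    """Optimization protocol and loss selection."""

    arch: ArchConfig = field(default_factory=ArchConfig)
    learning_rate: float = 1e-3
    batch_size: int = 1
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-7
    epochs: int = 200
    seed: int = 0
    loss: str = "mse_dvh"  # "mse" or "mse_dvh"
    weights: LossWeights = field(default_factory=LossWeights)
    dvh: DVHSpec = field(default_factory=DVHSpec)
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.loss not in ("mse", "mse_dvh"):
            raise ValueError("loss must be 'mse' or 'mse_dvh'")
        if self.batch_size != 1:
            raise ValueError("this trainer processes one case per step (batch size 1)")

    @property
    def effective_weights(self) -> LossWeights:
        if self.loss == "mse":
            return LossWeights(self.weights.w1, 0.0)
        return self.weights


class Adam:
    """Adam optimizer over a list of autodiff parameters."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(p.shape, dtype=np.float64) for p in self.params]
        self.v = [np.zeros(p.shape, dtype=np.float64) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            update = (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p.data = p.data - (self.lr * update).astype(p.data.dtype)


def structure_order_for(cohort: list[PlanCase]) -> list[str]:
    """Cohort-wide channel order: structure names in first-appearance order."""
    order: list[str] = []
    for case in cohort:
        for name in case.structures.names:
            if name not in order:
                order.append(name)
    return order


@dataclass
class TrainedRun:
    """Best weights plus everything needed to reproduce and apply them."""

    model: Module
    config: TrainConfig
    structure_order: list[str]
    history: pd.DataFrame
    best_epoch: int
    best_state: dict[str, np.ndarray]
    normalization: str = "case_max"

    def final_train_mse(self) -> float:
        return float(self.history["train_mse"].iloc[-1])


class _CaseBatch:
    """Preassembled per-case training arrays."""

    def __init__(self, case: PlanCase, order: list[str], dtype):
        self.case = case
        self.x = Tensor(assemble_channels(case, order).astype(dtype))
        dose = case.reference_dose.values
        self.hi = float(dose.max())
        if self.hi <= 0:
            raise ValueError(f"case {case.case_id} has an all-zero reference dose")
        self.y_norm = Tensor((dose / self.hi).astype(dtype))
        self.y_gy = Tensor(dose.astype(dtype))


def _case_loss(model: Module, batch: _CaseBatch, cfg: TrainConfig):
    w = cfg.effective_weights
    pred = model(batch.x)
    pred = pred.reshape(*pred.shape[1:])  # (1, X, Y, Z) -> (X, Y, Z)
    mse = ((batch.y_norm - pred) ** 2).mean()
    loss = mse * w.w1
    dvh_val = 0.0
    if w.w2 > 0:
        from .dvh import dvh_loss_tensor

        pred_gy = pred * batch.hi
        dvh = dvh_loss_tensor(batch.y_gy, pred_gy, batch.case.structures, cfg.dvh)
        dvh_val = dvh.item()
        loss = loss + dvh * w.w2
    return loss, mse.item(), dvh_val


def train(
    cohort: list[PlanCase],
    cfg: TrainConfig,
    split: SplitSpec | None = None,
    structure_order: list[str] | None = None,
) -> TrainedRun:
    """Train one model on a cohort and return the best-validation weights.

    When ``split`` is None the whole cohort is used for both training and
    validation (the single-case overfitting regime).
    """
    by_id = {c.case_id: c for c in cohort}
    if split is None:
        train_ids = val_ids = [c.case_id for c in cohort]
    else:
        train_ids, val_ids, _ = split_cohort(list(by_id), split)
    if not train_ids or not val_ids:
        raise ValueError("training requires nonempty train and validation sets")

    order = structure_order or structure_order_for(cohort)
    dtype = np.float32 if cfg.dtype == "float32" else np.float64
    train_batches = [_CaseBatch(by_id[i], order, dtype) for i in train_ids]
    val_batches = [_CaseBatch(by_id[i], order, dtype) for i in val_ids]

    ss = np.random.SeedSequence(cfg.seed)
    init_seed, shuffle_seed = (int(s) for s in ss.generate_state(2) % (2**31))
    model = build_model(cfg.arch, seed=init_seed, dtype=dtype)
    opt = Adam(model.parameters(), cfg.learning_rate, cfg.beta1, cfg.beta2, cfg.epsilon)
    shuffler = np.random.default_rng(shuffle_seed)

    rows = []
    best_epoch, best_val, best_state = -1, np.inf, None
    for epoch in range(1, cfg.epochs + 1):
        model.train()
        perm = shuffler.permutation(len(train_batches))
        tr_loss = tr_mse = tr_dvh = 0.0
        for i in perm:
            model.zero_grad()
            loss, mse_val, dvh_val = _case_loss(model, train_batches[i], cfg)
            if not np.isfinite(loss.item()):
                raise DivergenceError(f"non-finite training loss at epoch {epoch}")
            loss.backward()
            opt.step()
            tr_loss += loss.item()
            tr_mse += mse_val
            tr_dvh += dvh_val
        n_tr = len(train_batches)

        model.eval()
        va_loss = 0.0
        for batch in val_batches:
            loss, _, _ = _case_loss(model, batch, cfg)
            va_loss += loss.item()
        va_loss /= len(val_batches)
        if not np.isfinite(va_loss):
            raise DivergenceError(f"non-finite validation loss at epoch {epoch}")
        rows.append(
            {
                "epoch": epoch,
                "train_loss": tr_loss / n_tr,
                "train_mse": tr_mse / n_tr,
                "train_dvh": tr_dvh / n_tr,
                "val_loss": va_loss,
            }
        )
        if va_loss < best_val:
            best_val, best_epoch = va_loss, epoch
            best_state = model.state_dict()

    model.load_state_dict(best_state)
    model.eval()
    return TrainedRun(
        model=model,
        config=cfg,
        structure_order=order,
        history=pd.DataFrame(rows),
        best_epoch=best_epoch,
        best_state=copy.deepcopy(best_state),
    )


def predict(run: TrainedRun, case: PlanCase) -> DoseVolume:
    """Single deterministic forward pass; output in Gy on the case grid."""
    extra = [n for n in case.structures.names if n not in run.structure_order]
    if extra:
        raise ValueError(
            "case structures missing from the training channel layout: " f"{sorted(extra)}"
        )
    dtype = np.float32 if run.config.dtype == "float32" else np.float64
    x = Tensor(assemble_channels(case, run.structure_order).astype(dtype))
    run.model.eval()
    pred = run.model(x).data[0]
    try:
        scale = float(case.reference_dose.values.max())
        if scale <= 0:
            scale = case.prescription
    except AttributeError:  # no reference dose attached
        scale = case.prescription
    gy = np.clip(pred.astype(np.float64) * scale, 0.0, None)
    return DoseVolume(gy, case.spacing)
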