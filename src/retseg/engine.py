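"""Training, checkpointing, full-image inference and dataset evaluation.

Training protocol: Adam at learning rate 0.001,
batch size 20, 500 epochs by default, with each batch contributing four
class-weighted cross-entropy terms (three supervision heads, one main
output) combined under the decaying supervision weight
beta = 1 - epoch/total_epochs.  Patches are re-augmented every epoch with
seeded randomness so each epoch sees a different rendition of the data;
shuffling is global across source images.

Inference composes the whole pipeline: preprocess -> pad -> 64x64/step-16
patches -> batched forward (main output only) -> overlap-averaged stitch ->
crop -> threshold.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import objective, patching, preprocessing
from .errors import DataError
from .network import ModelSpec, VesselSegNet, build_model
from .nn import tensor as T
from .nn.layers import Adam
from .nn.tensor import Tensor
from .patching import PatchSet
from .types import FundusImage


@dataclass
class TrainConfig:
    batch_size: int = 20
    epochs: int = 500
    learning_rate: float = 0.001
    optimizer: str = "adam"
    seed: int = 0
    augment: bool = True
    loss_mode: str = "default"  # or "beta-all"
    val_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1 or self.learning_rate <= 0:
            raise DataError("invalid training configuration")
        if self.loss_mode not in ("default", "beta-all"):
            raise DataError(f"unknown loss mode {self.loss_mode!r}")


@dataclass
class EpochRecord:
    epoch: int
    beta: float
    loss_total: float
    loss_components: tuple[float, float, float, float]
    val_loss: Optional[float] = None


@dataclass
class RunLog:
    config: dict
    records: list[EpochRecord] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {"config": self.config, "records": [asdict(r) for r in self.records]},
            indent=1,
        )


def _tensor_weighted_bce(y: np.ndarray, yhat: Tensor, alpha: float) -> Tensor:
    """Differentiable version of the class-weighted BCE used by objective."""
    yt = Tensor(y)
    one_minus_y = Tensor(1.0 - y)
    p = T.clip(yhat, objective.EPS, 1.0 - objective.EPS)
    q = T.clip(1.0 - yhat, objective.EPS, 1.0 - objective.EPS)
    ll = Tensor(alpha) * yt * T.log(p) + Tensor(1.0 - alpha) * one_minus_y * T.log(q)
    return -T.tmean(ll)


def _flatten_patchsets(
    patchsets: Sequence[PatchSet],
) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for ps in patchsets:
        if ps.labels is None:
            raise DataError("training patch sets must carry labels")
        xs.extend(ps.inputs)
        ys.extend(ps.labels)
    x = np.asarray(xs, dtype=np.float32)[:, None, :, :]
    y = (np.asarray(ys) > 0).astype(np.float32)[:, None, :, :]
    return x, y


def _batch_losses(
    model: VesselSegNet, xb: np.ndarray, yb: np.ndarray, training: bool
) -> tuple[Tensor, tuple[Tensor, Tensor, Tensor]]:
    main, sups = model.forward(xb, training=training)
    alpha = objective.ClassBalance.from_target(yb).alpha
    l4 = _tensor_weighted_bce(yb, main, alpha)
    ls = tuple(_tensor_weighted_bce(yb, s, alpha) for s in sups)
    while len(ls) < 3:  # reduced specs may carry fewer heads
        ls = ls + (Tensor(0.0),)
    return l4, ls[:3]


def train(
    cfg: TrainConfig,
    model_spec: ModelSpec,
    train_patches: Sequence[PatchSet],
    out_dir: str | Path | None = None,
) -> tuple[VesselSegNet, RunLog]:
    """Train a model on labeled patch sets; returns (model, run log).

    Writes ``final.npz`` / ``best.npz`` checkpoints and ``runlog.json`` when
    ``out_dir`` is given.  Best means lowest validation loss (or training
    loss when val_fraction = 0).  Deterministic for a given seed.
    """
    x, y = _flatten_patchsets(train_patches)
    n = x.shape[0]
    rng = np.random.default_rng(cfg.seed)
    model = build_model(model_spec, seed=cfg.seed)
    opt = Adam(
        model.parameters(),
        lr=cfg.learning_rate,
        l2=model_spec.l2_coeff,
        decay_params=model.decay_parameters(),
    )

    n_val = int(round(cfg.val_fraction * n)) if cfg.val_fraction > 0 else 0
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if tr_idx.size == 0:
        raise DataError("no training patches left after validation split")

    log = RunLog(config=asdict(cfg))
    best_loss = np.inf
    best_state: Optional[dict] = None
    strict = cfg.loss_mode == "beta-all"

    for epoch in range(cfg.epochs):
        beta = objective.beta_weight(
            objective.LossSchedule(epoch=epoch, total_epochs=cfg.epochs)
        )
        # fresh augmentation of every training patch each epoch
        if cfg.augment:
            xs = np.empty_like(x[tr_idx])
            ys = np.empty_like(y[tr_idx])
            for j, idx in enumerate(tr_idx):
                seed = int((cfg.seed * 1000003 + epoch * 9973 + int(idx)) % (2**31))
                p, lb = patching.augment(x[idx, 0], y[idx, 0], seed)
                xs[j, 0], ys[j, 0] = p, lb
        else:
            xs, ys = x[tr_idx], y[tr_idx]
        order = rng.permutation(xs.shape[0])
        comp_sums = np.zeros(4)
        tot_sum = 0.0
        n_batches = 0
        for b0 in range(0, xs.shape[0], cfg.batch_size):
            sel = order[b0 : b0 + cfg.batch_size]
            l4, (l1, l2, l3) = _batch_losses(model, xs[sel], ys[sel], training=True)
            if strict:
                total = Tensor(beta) * (l1 + l2 + l3 + l4)
            else:
                total = Tensor(beta) * (l1 + l2 + l3) + l4
            opt.zero_grad()
            total.backward()
            opt.step()
            comp_sums += [l1.item(), l2.item(), l3.item(), l4.item()]
            tot_sum += total.item()
            n_batches += 1
        val_loss = None
        if n_val > 0:
            l4v, (l1v, l2v, l3v) = _batch_losses(
                model, x[val_idx], y[val_idx], training=False
            )
            val_loss = float(
                objective.total_loss(
                    l1v.item(), l2v.item(), l3v.item(), l4v.item(), beta, strict
                )
            )
        rec = EpochRecord(
            epoch=epoch,
            beta=beta,
            loss_total=float(tot_sum / n_batches),
            loss_components=tuple(float(v) for v in comp_sums / n_batches),
            val_loss=val_loss,
        )
        log.records.append(rec)
        monitor = val_loss if val_loss is not None else rec.loss_total
        if monitor < best_loss:
            best_loss = monitor
            best_state = {k: v.copy() for k, v in model.state_dict().items()}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_checkpoint(out / "final.npz", model)
        if best_state is not None:
            save_checkpoint(out / "best.npz", model, state=best_state)
        (out / "runlog.json").write_text(log.to_json())
    return model, log


# -- checkpointing ----------------------------------------------------------


def save_checkpoint(
    path: str | Path, model: VesselSegNet, state: Optional[dict] = None
) -> None:
    """Write weights plus the serialized ModelSpec into one .npz file."""
    arrays = dict(state if state is not None else model.state_dict())
    arrays["__spec__"] = np.frombuffer(
        model.spec.to_json().encode("utf-8"), dtype=np.uint8
    )
    np.savez(Path(path), **arrays)


def load_checkpoint(path: str | Path) -> VesselSegNet:
    """Rebuild the architecture from the stored spec and load the weights."""
    with np.load(Path(path)) as z:
        arrays = {k: z[k] for k in z.files}
    spec_json = bytes(arrays.pop("__spec__")).decode("utf-8")
    model = build_model(ModelSpec.from_json(spec_json))
    model.load_state_dict(arrays)
    return model


# -- inference and evaluation ------------------------------------------------


def predict_image(
    model: VesselSegNet | str | Path,
    img: FundusImage,
    threshold: float = 0.5,
    window: int = 64,
    step: int = 16,
    batch_size: int = 32,
    preprocess_kwargs: Optional[dict] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Segment a full fundus image; returns (probability map, binary map)."""
    if not isinstance(model, VesselSegNet):
        model = load_checkpoint(model)
    g = preprocessing.preprocess(img, **(preprocess_kwargs or {}))
    ps = patching.extract_patches(g, window=window, step=step)
    patches = np.asarray(ps.inputs, dtype=np.float32)
    probs = model.predict(patches, batch_size=batch_size)
    prob_map = patching.stitch_predictions(list(probs), ps.grid, g.shape)
    return prob_map, (prob_map >= threshold).astype(np.uint8)


@dataclass
class EvalReport:
    """Per-image and mean metrics over a dataset."""

    per_image: list[dict]
    mean: dict

    def to_json(self) -> str:
        return json.dumps({"per_image": self.per_image, "mean": self.mean}, indent=1)


def evaluate_images(
    model: VesselSegNet | str | Path,
    images: Sequence[FundusImage],
    threshold: float = 0.5,
    fov_only: bool = True,
    window: int = 64,
    step: int = 16,
) -> EvalReport:
    """Segment each image and score it against its ground truth."""
    if not isinstance(model, VesselSegNet):
        model = load_checkpoint(model)
    rows = []
    for i, img in enumerate(images):
        if img.truth is None:
            raise DataError(f"image {i} has no ground truth")
        prob, binary = predict_image(model, img, threshold, window, step)
        mask = preprocessing.estimate_fov_mask(img) if fov_only else None
        c = objective.confusion(binary, img.truth, mask)
        acc, se, sp = objective.acc_se_sp(c)
        try:
            _, auc = objective.roc_auc(prob, img.truth, mask)
        except Exception:
            auc = None
        rows.append(
            {
                "image": i,
                "acc": acc,
                "se": se,
                "sp": sp,
                "auc": auc,
                "tp": c.tp,
                "tn": c.tn,
                "fp": c.fp,
                "fn": c.fn,
            }
        )
    mean = {}
    for key in ("acc", "se", "sp", "auc"):
        vals = [r[key] for r in rows if r[key] is not None]
        mean[key] = float(np.mean(vals)) if vals else None
    return EvalReport(per_image=rows, mean=mean)


def evaluate_dataset(
    model: VesselSegNet | str | Path,
    dataset_dir: str | Path,
    threshold: float = 0.5,
    fov_only: bool = True,
) -> EvalReport:
    from .io import load_dataset

    images = load_dataset(dataset_dir, require_truth=True)
    return evaluate_images(model, images, threshold=threshold, fov_only=fov_only)
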