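"""Training loop: Adam, plateau learning-rate decay, composite loss logging."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from ..datasets import DatasetManifest, TrainingSample
from ..forward import ProjectionSet
from .autograd import Tensor
from .layers import Adam
from .losses import SSIMParams, composite_loss_graph, mse_loss, roi_bounding_box, ssim_loss
from .network import (
    EncDec3D,
    NetworkConfig,
    build_network,
    network_config_from_json,
    network_config_to_json,
)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings: Adam, batch 64, 200 epochs, initial learning
    rate 2e-5 halved after 5 epochs without validation improvement.

    ``composite_from_epoch``/``composite_lr`` define an optional two-phase
    curriculum for short (CPU-scale) runs: the MSE terms alone drive the
    epochs before ``composite_from_epoch``, after which the full composite
    objective takes over at ``composite_lr``.  The logged and validated loss
    is always the full composite.  The default (1) trains the composite from
    the first epoch, the right setting for full-scale regimes (thousands of
    small steps); at a few hundred large steps the structural terms'
    flat-background optimum otherwise swallows training before target
    localization emerges.
    """

    batch_size: int = 64
    epochs: int = 200
    lr: float = 2e-5
    lr_decay: float = 0.5
    patience: int = 5
    composite_from_epoch: int = 1
    composite_lr: float | None = None
    augment_dihedral: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.batch_size, self.epochs, self.patience) < 1 or self.lr <= 0:
            raise ValueError("invalid training configuration")
        if not (0 < self.lr_decay < 1):
            raise ValueError("lr_decay must be in (0, 1)")
        if self.composite_from_epoch < 1:
            raise ValueError("composite_from_epoch must be >= 1")
        if self.composite_lr is not None and self.composite_lr <= 0:
            raise ValueError("composite_lr must be positive")


class PlateauSchedule:
    """Halve the learning rate after ``patience`` epochs without improvement."""

    def __init__(self, lr: float, decay: float = 0.5, patience: int = 5):
        self.lr = lr
        self.decay = decay
        self.patience = patience
        self.best = np.inf
        self.stall = 0

    def update(self, val: float) -> tuple[float, bool]:
        """Feed one validation value; returns (current lr, improved?)."""
        if val < self.best:
            self.best = val
            self.stall = 0
            return self.lr, True
        self.stall += 1
        if self.stall >= self.patience:
            self.lr *= self.decay
            self.stall = 0
        return self.lr, False


def scaled_train_config(seed: int = 0, **overrides) -> TrainConfig:
    """Training settings for the scaled-down study: batch 8, 12 epochs, an
    8-epoch MSE warm-start at 1e-3, then the full composite objective at the
    full-scale learning-rate scale (2e-5)."""
    base = dict(batch_size=8, epochs=12, lr=1e-3,
                composite_from_epoch=9, composite_lr=2e-5,
                augment_dihedral=True, seed=seed)
    base.update(overrides)
    return TrainConfig(**base)


@dataclass
class TrainedModel:
    """Network weights plus everything needed to reproduce inference."""

    net: EncDec3D
    net_config: NetworkConfig
    train_config: TrainConfig
    history: list[dict] = field(default_factory=list)
    normalization: str = "max"

    def reconstruct(self, projections: ProjectionSet | np.ndarray) -> np.ndarray:
        return reconstruct(self, projections)


def _loss_terms(out: Tensor, truth: Tensor, rois: list[np.ndarray],
                params: SSIMParams) -> dict[str, Tensor]:
    """Composite loss over a batch: full-volume terms batch-wise, ROI terms
    per sample on each sample's own bounding-box crop."""
    terms = {
        "mse_full": mse_loss(out, truth),
        "ssim_loss_full": ssim_loss(out, truth, params),
    }
    mse_roi = None
    ssim_roi = None
    for i, roi in enumerate(rois):
        bz, by, bx = roi_bounding_box(roi, params.window_size)
        o = out[i:i + 1, :, bz, by, bx]
        t = truth[i:i + 1, :, bz, by, bx]
        m = mse_loss(o, t)
        s = ssim_loss(o, t, params)
        mse_roi = m if mse_roi is None else mse_roi + m
        ssim_roi = s if ssim_roi is None else ssim_roi + s
    inv = 1.0 / len(rois)
    terms["mse_roi"] = mse_roi * inv
    terms["ssim_loss_roi"] = ssim_roi * inv
    terms["total"] = (terms["mse_full"] + terms["mse_roi"]
                      + 2.0 * (terms["ssim_loss_full"] + terms["ssim_loss_roi"]))
    return terms


def _stack_split(manifest: DatasetManifest, split: str, dtype):
    xs, ys, rois = [], [], []
    for i in manifest.split_indices(split):
        s = manifest.load(i)
        p, t = s.normalized()
        xs.append(p[None])     # channel axis
        ys.append(t[None])
        rois.append(s.roi_mask)
    if not xs:
        raise ValueError(f"manifest has no samples in split {split!r}")
    return (np.stack(xs).astype(dtype), np.stack(ys).astype(dtype), rois)


def dihedral_augment(proj: np.ndarray, vol: np.ndarray, k: int, mirror: bool):
    """Apply an exact symmetry of the cylinder imaging geometry.

    ``proj`` is a (..., n_views, H, W) stack with views equally spaced over
    360 deg and n_views divisible by 4; ``vol`` is a (..., Z, Y, X) volume on
    a square in-plane grid.  Rotating the scene by k * 90 deg equals
    cyclically shifting the view stack by k * n_views/4 and rotating the
    volume in-plane; mirroring x -> -x equals remapping view i to
    (n/2 - i) mod n with the detector u axis flipped, and flipping the
    volume's x axis.  Both are exact, so augmented pairs are physically
    valid samples (verified against the forward model in the test suite).
    """
    n = proj.shape[-3]
    if n % 4:
        raise ValueError("dihedral augmentation needs n_views divisible by 4")
    if mirror:
        idx = (n // 2 - np.arange(n)) % n
        proj = np.flip(proj[..., idx, :, :], axis=-1)
        vol = np.flip(vol, axis=-1)
    if k % 4:
        proj = np.roll(proj, k * (n // 4), axis=-3)
        vol = np.rot90(vol, -k, axes=(-2, -1))
    return np.ascontiguousarray(proj), np.ascontiguousarray(vol)


def train_model(manifest: DatasetManifest, net_config: NetworkConfig,
                train_config: TrainConfig | None = None,
                ssim_params: SSIMParams = SSIMParams(),
                verbose: bool = False) -> TrainedModel:
    """Train on the manifest's train split, validate on its val split.

    The best-validation parameters are retained; the learning rate halves
    whenever validation loss fails to improve for ``patience`` consecutive
    epochs.  Fixed seed gives a reproducible run.
    """
    tc = train_config or TrainConfig()
    net = build_network(net_config, seed=tc.seed)
    dtype = np.dtype(net_config.dtype).type
    x_tr, y_tr, roi_tr = _stack_split(manifest, "train", dtype)
    x_va, y_va, roi_va = _stack_split(manifest, "val", dtype)

    rng = np.random.default_rng(tc.seed)
    opt = Adam(net.parameters(), lr=tc.lr)
    schedule = PlateauSchedule(tc.lr, tc.lr_decay, tc.patience)
    history: list[dict] = []
    best_state = None
    step = 0
    n = len(x_tr)
    for epoch in range(tc.epochs):
        net.train()
        order = rng.permutation(n)
        tr_log: dict[str, float] = {}
        n_batches = 0
        for lo in range(0, n, tc.batch_size):
            idx = order[lo:lo + tc.batch_size]
            xb_np = x_tr[idx]
            yb_np = y_tr[idx]
            rois = [roi_tr[i] for i in idx]
            if tc.augment_dihedral:
                xb_np = xb_np.copy()
                yb_np = yb_np.copy()
                rois = list(rois)
                for b in range(len(idx)):
                    k = int(rng.integers(4))
                    mir = bool(rng.integers(2))
                    if k or mir:
                        xb_np[b], yb_np[b] = dihedral_augment(
                            xb_np[b], yb_np[b], k, mir)
                        _, roi_aug = dihedral_augment(
                            xb_np[b], rois[b].astype(np.float32), k, mir)
                        rois[b] = roi_aug > 0.5
            xb = Tensor(xb_np)
            yb = Tensor(yb_np)
            out = net(xb)
            terms = _loss_terms(out, yb, rois, ssim_params)
            if not np.isfinite(terms["total"].data):
                raise FloatingPointError(
                    f"training loss diverged at epoch {epoch}")
            if epoch + 1 >= tc.composite_from_epoch:
                if tc.composite_lr is not None and opt.lr != tc.composite_lr \
                        and epoch + 1 == tc.composite_from_epoch:
                    opt.lr = tc.composite_lr
                optimized = terms["total"]
            else:
                optimized = terms["mse_full"] + terms["mse_roi"]
            net.zero_grad()
            optimized.backward()
            opt.step()
            step += 1
            for k, v in terms.items():
                tr_log[k] = tr_log.get(k, 0.0) + float(v.data)
            n_batches += 1
        record = {f"train_{k}": v / n_batches for k, v in tr_log.items()}

        net.eval()
        va_log: dict[str, float] = {}
        n_vb = 0
        for lo in range(0, len(x_va), tc.batch_size):
            xb = Tensor(x_va[lo:lo + tc.batch_size])
            yb = Tensor(y_va[lo:lo + tc.batch_size])
            terms = _loss_terms(net(xb), yb, roi_va[lo:lo + tc.batch_size],
                                ssim_params)
            for k, v in terms.items():
                va_log[k] = va_log.get(k, 0.0) + float(v.data)
            n_vb += 1
        record.update({f"val_{k}": v / n_vb for k, v in va_log.items()})
        record["lr"] = opt.lr
        val = record["val_total"]
        schedule.lr = opt.lr  # composite-phase switches keep the schedule in sync
        opt.lr, improved = schedule.update(val)
        if improved:
            best_state = {k: v.copy() for k, v in net.state_arrays().items()}
        if verbose:
            print(f"epoch {epoch + 1:3d}: train {record['train_total']:.4f} "
                  f"val {val:.4f} lr {record['lr']:.2e}", flush=True)
        history.append(record)
    if best_state is not None:
        net.load_state_arrays(best_state)
    net.eval()
    return TrainedModel(net, net_config, tc, history)


def reconstruct(model: TrainedModel, projections: ProjectionSet | np.ndarray) -> np.ndarray:
    """Max-normalize the projection stack and run the network in eval mode.

    Returns a nonnegative (out_depth, H, W) volume on the normalized scale.
    """
    imgs = projections.images if isinstance(projections, ProjectionSet) \
        else np.asarray(projections)
    cfg = model.net_config
    if imgs.shape != (cfg.in_views, cfg.in_size, cfg.in_size):
        raise ValueError(f"projection stack {imgs.shape} does not match the "
                         f"model input ({cfg.in_views}, {cfg.in_size}, {cfg.in_size})")
    mx = imgs.max()
    x = (imgs / mx if mx > 0 else imgs).astype(np.dtype(cfg.dtype).type)
    model.net.eval()
    out = model.net(Tensor(x[None, None]))
    return np.asarray(out.data[0, 0], dtype=float)


def save_model(model: TrainedModel, path: str) -> None:
    """Single-file checkpoint: parameters/buffers + JSON-encoded configs."""
    meta = {
        "net_config": network_config_to_json(model.net_config),
        "train_config": dataclasses.asdict(model.train_config),
        "history": model.history,
        "normalization": model.normalization,
    }
    state = model.net.state_arrays()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)


def load_model(path: str) -> TrainedModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    net_config = network_config_from_json(meta["net_config"])
    net = build_network(net_config)
    net.load_state_arrays(state)
    net.eval()
    return TrainedModel(net, net_config, TrainConfig(**meta["train_config"]),
                        meta["history"], meta["normalization"])
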