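"""Training loop, augmentation, BCE loss, and the volume -> landmarks pipeline.

Training follows the heatmap-regression recipe: volumes are resampled to
1.6 mm isotropic spacing, augmented (random crops of up to 75% per axis,
local elastic deformation, rotation in +/-15 degrees, translation in +/-10%,
and contrast/brightness jitter), encoded as truncated Gaussian targets on the
network's half-resolution output grid, and optimized with voxelwise binary
cross-entropy under AdamW (lr 0.001, weight decay 0.01). Model selection
keeps the checkpoint with the lowest mean validation Euclidean distance over
all present landmarks; early stopping triggers after ``patience`` epochs
without improvement.

Volumes are z-score normalized before entering the network (train and
predict symmetrically). Batch size is one full volume. Landmarks absent from
an annotation are masked out of the loss channel-wise; validation averages
over landmarks present in both reference and prediction, counting
predicted-absent cases separately as misses rather than assigning a penalty
distance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .heatmap_codec import GridGeometry, HeatmapStack, decode, encode
from .hourglass3d import Network, NetworkConfig
from .imaging_io import LandmarkSet, Volume, resample_isotropic
from .nn import AdamW

__all__ = [
    "TrainConfig",
    "Checkpoint",
    "TrainingError",
    "augment",
    "bce_loss",
    "train",
    "predict",
]

logger = logging.getLogger(__name__)

_EPS = 1e-7


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    weight_decay: float = 0.01
    sigma_voxels: float = 1.5
    target_spacing: float = 1.6
    crop_max_fraction: float = 0.75
    rotation_range: tuple[float, float] = (-15.0, 15.0)  # degrees
    translation_range: tuple[float, float] = (-0.10, 0.10)  # fraction of extent
    elastic_grid_spacing: int = 8  # voxels between displacement knots
    elastic_max_displacement: float = 2.0  # voxels
    contrast_range: tuple[float, float] = (0.8, 1.2)
    brightness_range: tuple[float, float] = (-0.1, 0.1)  # in units of intensity sd
    patience: int = 20
    max_epochs: int = 100
    seed: int = 0
    rel_threshold: float = 0.5
    min_peak: float = 0.1

    def __post_init__(self) -> None:
        if not (0 <= self.crop_max_fraction < 1):
            raise ValueError("crop_max_fraction must be in [0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    def without_augmentation(self) -> "TrainConfig":
        """Copy with every augmentation range set to the identity."""
        return replace(
            self,
            crop_max_fraction=0.0,
            rotation_range=(0.0, 0.0),
            translation_range=(0.0, 0.0),
            elastic_max_displacement=0.0,
            contrast_range=(1.0, 1.0),
            brightness_range=(0.0, 0.0),
        )


@dataclass
class Checkpoint:
    network: Network
    net_config: NetworkConfig
    train_config: TrainConfig
    schema_ids: tuple[str, ...]
    best_val_distance: float
    best_epoch: int

    def save(self, path: str | Path) -> None:
        tc = asdict(self.train_config)
        self.network.save(
            path,
            extra={
                "train_config": json.dumps(tc),
                "schema_ids": json.dumps(list(self.schema_ids)),
                "best_val_distance": self.best_val_distance,
                "best_epoch": self.best_epoch,
            },
        )

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        net, meta = Network.load(path)
        tc = json.loads(meta["train_config"])
        for key in ("rotation_range", "translation_range", "contrast_range", "brightness_range"):
            tc[key] = tuple(tc[key])
        return cls(
            network=net,
            net_config=net.config,
            train_config=TrainConfig(**tc),
            schema_ids=tuple(json.loads(meta["schema_ids"])),
            best_val_distance=float(meta["best_val_distance"]),
            best_epoch=int(meta["best_epoch"]),
        )


# ---------------------------------------------------------------------------
# Augmentation


def _rigid_params(cfg: TrainConfig, rng: np.random.Generator):
    angles = np.radians(rng.uniform(*cfg.rotation_range, size=3))
    tfrac = rng.uniform(*cfg.translation_range, size=3)
    return angles, tfrac


def _rotation_matrix(angles: np.ndarray) -> np.ndarray:
    ax, ay, az = angles
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def augment(
    vol: Volume, landmarks: LandmarkSet, rng: np.random.Generator, cfg: TrainConfig
) -> tuple[Volume, LandmarkSet]:
    """Apply one random augmentation jointly to image and landmarks.

    Spatial transforms move image content and landmark coordinates
    identically; landmarks transported outside the (possibly cropped) field
    become absent. With all ranges zero the operation is the identity.
    """
    data = np.asarray(vol.data, dtype=float)
    spacing, origin, direction = vol.spacing.copy(), vol.origin.copy(), vol.direction.copy()
    fill = float(data.min())
    lms = landmarks

    # 1. random crop: per axis the retained window is uniform in
    #    [1 - crop_max_fraction, 1] of the axis, position uniform.
    if cfg.crop_max_fraction > 0:
        shape = np.array(data.shape)
        keep = np.maximum(
            1, np.round(shape * rng.uniform(1 - cfg.crop_max_fraction, 1.0, size=3)).astype(int)
        )
        lo = np.array([rng.integers(0, s - k + 1) for s, k in zip(shape, keep)])
        vol_tmp = Volume(data, spacing, origin, direction)
        origin = vol_tmp.voxel_to_world(lo.astype(float))
        data = data[lo[0] : lo[0] + keep[0], lo[1] : lo[1] + keep[1], lo[2] : lo[2] + keep[2]]
        logger.debug("crop keep=%s lo=%s", keep.tolist(), lo.tolist())

    work = Volume(data, spacing, origin, direction)

    # 2. rigid rotation + translation about the volume centre, in world mm.
    if np.any(np.asarray(cfg.rotation_range)) or np.any(np.asarray(cfg.translation_range)):
        angles, tfrac = _rigid_params(cfg, rng)
        rot = _rotation_matrix(angles)
        extent = (np.array(work.shape) - 1) * spacing
        t = tfrac * extent
        center = work.voxel_to_world((np.array(work.shape) - 1) / 2.0)
        # image: output index i -> world x -> inverse transform -> input index
        # j = A i + b with x = O + D S i and p = R^T (x - c - t) + c.
        ds = direction * spacing[np.newaxis, :]
        ds_inv = np.linalg.inv(ds)
        mat = ds_inv @ rot.T @ ds
        off = ds_inv @ (rot.T @ (origin - center - t) + center - origin)
        data = ndimage.affine_transform(
            work.data, mat, offset=off, order=1, mode="constant", cval=fill
        )
        work = Volume(data, spacing, origin, direction)
        lms = lms.transformed(lambda p: rot @ (p - center) + center + t)

    # 3. local elastic deformation: coarse zero-mean displacement knots,
    #    trilinearly interpolated; landmarks transported by the same field.
    if cfg.elastic_max_displacement > 0:
        shape = np.array(work.shape)
        knots = shape // max(1, cfg.elastic_grid_spacing) + 2
        coarse = rng.uniform(
            -cfg.elastic_max_displacement, cfg.elastic_max_displacement, size=(3, *knots)
        )
        coarse -= coarse.mean(axis=(1, 2, 3), keepdims=True)
        grids = np.meshgrid(*(np.arange(n, dtype=float) for n in shape), indexing="ij")
        scale = (knots - 1) / np.maximum(shape - 1, 1)
        disp = np.stack(
            [
                ndimage.map_coordinates(
                    coarse[k], [g * s for g, s in zip(grids, scale)], order=1, mode="nearest"
                )
                for k in range(3)
            ]
        )
        coords = np.stack(grids) + disp
        data = ndimage.map_coordinates(work.data, coords, order=1, mode="constant", cval=fill)
        work = Volume(data, spacing, origin, direction)

        def _transport(p: np.ndarray) -> np.ndarray:
            iv = work.world_to_voxel(p)
            d = np.array(
                [
                    ndimage.map_coordinates(
                        coarse[k], (iv * scale)[:, None], order=1, mode="nearest"
                    )[0]
                    for k in range(3)
                ]
            )
            return work.voxel_to_world(iv - d)

        lms = lms.transformed(_transport)

    # drop landmarks that left the (possibly cropped) field of view
    lms = lms.transformed(lambda p: p if work.contains_world(p) else None)

    # 4. intensity: contrast about the mean plus brightness in sd units.
    if tuple(cfg.contrast_range) != (1.0, 1.0) or tuple(cfg.brightness_range) != (0.0, 0.0):
        a = rng.uniform(*cfg.contrast_range)
        b = rng.uniform(*cfg.brightness_range)
        m, s = work.data.mean(), work.data.std()
        work = Volume(a * (work.data - m) + m + b * s, spacing, origin, direction)

    return work, lms


# ---------------------------------------------------------------------------
# Loss


def _bce_arrays(
    pred: np.ndarray, target: np.ndarray, mask: np.ndarray
) -> tuple[float, np.ndarray]:
    """Masked voxelwise BCE and its gradient w.r.t. the predictions."""
    if not mask.any():
        raise TrainingError("no supervised landmarks: every target channel is masked")
    p = np.clip(pred[mask].astype(np.float64), _EPS, 1.0 - _EPS)
    t = target[mask].astype(np.float64)
    n = p.size
    loss = float(-(t * np.log(p) + (1.0 - t) * np.log1p(-p)).sum() / n)
    grad = np.zeros_like(pred, dtype=np.float32)
    grad[mask] = ((p - t) / (p * (1.0 - p)) / n).astype(np.float32)
    return loss, grad


def bce_loss(pred: HeatmapStack, target: HeatmapStack) -> float:
    """Binary cross-entropy averaged over voxels of present target channels.

    Channels whose target ``present_mask`` is False contribute nothing;
    predictions are clamped to [eps, 1 - eps].
    """
    if pred.maps.shape != target.maps.shape:
        raise ValueError(
            f"prediction/target shape mismatch: {pred.maps.shape} vs {target.maps.shape}"
        )
    loss, _ = _bce_arrays(np.asarray(pred.maps), np.asarray(target.maps), target.present_mask)
    return loss


# ---------------------------------------------------------------------------
# Pipeline helpers


def _pad_to_network(vol: Volume, net_cfg: NetworkConfig) -> Volume:
    """Pad at the high end (minimum intensity) so dims satisfy the net's shape rule."""
    step = 2 ** (net_cfg.depth + 1)
    shape = np.array(vol.shape)
    target = np.maximum(net_cfg.min_input_size(), ((shape + step - 1) // step) * step)
    if np.all(target == shape):
        return vol
    pad = [(0, int(t - s)) for t, s in zip(target, shape)]
    data = np.pad(vol.data, pad, constant_values=float(np.min(vol.data)))
    return Volume(data, vol.spacing, vol.origin, vol.direction)


def _normalize(data: np.ndarray) -> np.ndarray:
    m, s = float(data.mean()), float(data.std())
    return (data - m) / (s if s > 0 else 1.0)


def _output_geometry(vol: Volume, out_shape: tuple[int, int, int]) -> GridGeometry:
    """Geometry of the network output grid: spacing doubled, origin preserved.

    Output voxel j is centred on input voxel 2j (stride-2 stem with 'same'
    padding), so the first output voxel centre coincides with the input
    origin.
    """
    return GridGeometry(out_shape, vol.spacing * 2.0, vol.origin, vol.direction)


def _prepare(vol: Volume, net_cfg: NetworkConfig, target_spacing: float):
    if not np.allclose(vol.spacing, target_spacing):
        vol = resample_isotropic(vol, target_spacing)
    vol = _pad_to_network(vol, net_cfg)
    x = _normalize(np.asarray(vol.data, dtype=np.float32))[None]
    out_shape = tuple(int(-(-n // 2)) for n in vol.shape)
    return vol, x, _output_geometry(vol, out_shape)


def predict(ckpt: Checkpoint, vol: Volume) -> tuple[LandmarkSet, dict[str, float]]:
    """Resample, run the network, decode; coordinates in the original world frame.

    Returns the landmark set plus per-landmark confidences; landmarks whose
    channel peak falls below ``min_peak`` are reported absent.
    """
    tc = ckpt.train_config
    _, x, geom = _prepare(vol, ckpt.net_config, tc.target_spacing)
    out = ckpt.network.forward(x)
    stack = HeatmapStack(
        maps=np.clip(out, 0.0, 1.0),
        geometry=geom,
        landmark_ids=ckpt.schema_ids,
        present_mask=np.ones(out.shape[0], dtype=bool),
    )
    return decode(stack, rel_threshold=tc.rel_threshold, min_peak=tc.min_peak)


# ---------------------------------------------------------------------------
# Training


def _validate(
    network: Network,
    val_set: list[tuple[Volume, LandmarkSet]],
    net_cfg: NetworkConfig,
    tc: TrainConfig,
    ids: tuple[str, ...],
) -> tuple[float, int]:
    """Mean Euclidean distance (mm) over present landmarks, plus miss count."""
    dists: list[float] = []
    misses = 0
    for vol, lms in val_set:
        _, x, geom = _prepare(vol, net_cfg, tc.target_spacing)
        out = network.forward(x)
        stack = HeatmapStack(
            maps=np.clip(out, 0.0, 1.0),
            geometry=geom,
            landmark_ids=ids,
            present_mask=np.ones(out.shape[0], dtype=bool),
        )
        pred, _ = decode(stack, rel_threshold=tc.rel_threshold, min_peak=tc.min_peak)
        for lid in lms.present_ids():
            p = pred.get(lid)
            if p is None:
                misses += 1
            else:
                dists.append(float(np.linalg.norm(p - lms.get(lid))))
    if not dists:
        return float("inf"), misses
    return float(np.mean(dists)), misses


def train(
    train_set: list[tuple[Volume, LandmarkSet]],
    val_set: list[tuple[Volume, LandmarkSet]],
    net_cfg: NetworkConfig,
    train_cfg: TrainConfig,
    log_path: str | Path | None = None,
) -> Checkpoint:
    """Train the hourglass and return the best-validation checkpoint.

    Deterministic given the seeds in ``net_cfg`` and ``train_cfg`` (single
    threaded reference mode). ``log_path`` optionally receives a JSONL line
    per epoch (epoch, mean loss, validation distance, misses).
    """
    if not val_set:
        raise ValueError("validation set must be non-empty")
    for vol, lms in train_set + val_set:
        if len(lms) == 0 and vol is None:  # pragma: no cover - defensive
            raise ValueError("every sample needs a volume and a landmark set")

    ids = train_set[0][1].schema_ids if train_set else val_set[0][1].schema_ids
    if net_cfg.out_channels != len(ids):
        raise ValueError(
            f"network out_channels {net_cfg.out_channels} != schema size {len(ids)}"
        )
    network = Network(net_cfg)
    opt = AdamW(
        network.params(), lr=train_cfg.learning_rate, weight_decay=train_cfg.weight_decay
    )
    rng = np.random.default_rng(train_cfg.seed)
    log_fh = open(log_path, "w", encoding="utf-8") if log_path else None

    best_vec = network.parameter_vector()
    best_val, misses = _validate(network, val_set, net_cfg, train_cfg, ids)
    best_epoch = -1  # untrained baseline
    if not np.isfinite(best_val) and train_cfg.max_epochs == 0:
        raise TrainingError("validation never produced a finite distance")
    since_best = 0
    try:
        for epoch in range(train_cfg.max_epochs):
            order = rng.permutation(len(train_set))
            losses = []
            for si in order:
                vol, lms = train_set[si]
                avol, alms = augment(vol, lms, rng, train_cfg)
                if not alms.present_ids():
                    continue  # crop removed every landmark; skip sample
                pvol, x, geom = _prepare(avol, net_cfg, train_cfg.target_spacing)
                target = encode(alms, geom, sigma_voxels=train_cfg.sigma_voxels)
                if not target.present_mask.any():
                    continue
                out = network.forward(x)
                loss, grad = _bce_arrays(out, target.maps, target.present_mask)
                opt.zero_grad()
                network.backward(grad)
                opt.step()
                losses.append(loss)
            val, misses = _validate(network, val_set, net_cfg, train_cfg, ids)
            if log_fh:
                log_fh.write(
                    json.dumps(
                        {
                            "epoch": epoch,
                            "loss": float(np.mean(losses)) if losses else None,
                            "val_mean_distance_mm": val,
                            "val_misses": misses,
                        }
                    )
                    + "\n"
                )
                log_fh.flush()
            if val < best_val:
                best_val = val
                best_vec = network.parameter_vector()
                best_epoch = epoch
                since_best = 0
            else:
                since_best += 1
                if since_best >= train_cfg.patience:
                    break
    finally:
        if log_fh:
            log_fh.close()
    if not np.isfinite(best_val):
        raise TrainingError("validation never produced a finite distance")
    network.set_parameter_vector(best_vec)
    return Checkpoint(
        network=network,
        net_config=net_cfg,
        train_config=train_cfg,
        schema_ids=ids,
        best_val_distance=best_val,
        best_epoch=best_epoch,
    )
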