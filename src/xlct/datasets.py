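"""Randomized, reproducible training-set generation.

A :class:`SampleSpec` describes the study conditions (phantom, target
randomization ranges, detector, grid, noise); :func:`generate_dataset` draws
per-sample seeds from a master seed via ``numpy.random.SeedSequence`` so any
sample can be regenerated bit-exactly from the manifest alone.

Two presets mirror the simulation study: the full-scale recipe (8000 samples
of 24 x 128 x 128 projections mapping to 128 x 128 x 7 volumes, split
6000/2000) and a scaled-down recipe sized for CPU runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import h5py
import numpy as np
import yaml
from skimage.transform import resize as _sk_resize

from .forward import DetectorModel, ForwardModel, ProjectionSet, XRaySource, add_gaussian_noise
from .geometry import (
    OpticalProperties,
    Phantom,
    Target,
    ValidationError,
    VoxelGrid,
    rasterize_targets,
    sample_targets,
)
from .mesh import mesh_cylinder


@dataclass(frozen=True)
class SampleSpec:
    """Study conditions for one randomized training sample.

    All ranges feed :func:`~xlct.geometry.sample_targets`.  ``snr_db = inf``
    means noise-free projections (the default for training data; noise is
    normally injected only in evaluation sweeps).
    """

    phantom_diameter_cm: float = 3.0
    phantom_height_cm: float = 2.3
    mu_a: float = 0.02
    mu_s_prime: float = 10.0
    xray_mu_t_cm: float = 0.3
    mesh_edge_cm: float = 0.12
    n_targets: tuple[int, ...] = (2, 3)
    diam_choices_mm: tuple[float, ...] = (3.0, 4.0)
    height_mm: float = 4.0
    center_range_mm: float = 10.0
    eed_range_mm: tuple[float, float] = (0.3, 2.5)
    concentration: float = 50.0
    gamma: float = 1.0
    z_jitter_mm: float = 1.0
    snr_db: float = np.inf
    detector_pixels: int = 128
    n_views: int = 24
    grid_nx: int = 128
    grid_nz: int = 7

    def phantom(self) -> Phantom:
        return Phantom(self.phantom_diameter_cm, self.phantom_height_cm,
                       OpticalProperties(self.mu_a, self.mu_s_prime),
                       self.xray_mu_t_cm)

    def detector(self) -> DetectorModel:
        return DetectorModel.for_phantom(self.phantom(), n_pix=self.detector_pixels,
                                         n_views=self.n_views)

    def grid(self) -> VoxelGrid:
        return VoxelGrid.for_phantom(self.phantom(), nx=self.grid_nx,
                                     ny=self.grid_nx, nz=self.grid_nz)

    def forward_model(self) -> ForwardModel:
        ph = self.phantom()
        return ForwardModel(ph, mesh_cylinder(ph, self.mesh_edge_cm),
                            self.detector(), XRaySource(), self.grid(), self.gamma)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def spec_to_yaml(spec: SampleSpec, path: str) -> None:
    """Write the study conditions as YAML (units are part of the key names)."""
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(spec), fh, sort_keys=True)


def spec_from_yaml(path: str) -> SampleSpec:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    for k in ("n_targets", "diam_choices_mm", "eed_range_mm"):
        d[k] = tuple(d[k])
    d["snr_db"] = float(d["snr_db"])
    return SampleSpec(**d)


def scaled_spec(**overrides) -> SampleSpec:
    """Scaled-down study conditions: 48 x 48 x 5 grid, 12 views at 30 deg,
    48 x 48 projections, coarser mesh — CPU-sized but the same physics.

    The z-jitter shrinks to 0.5 mm so 4 mm-high targets always stay inside
    the 5 mm output slab.
    """
    base = dict(mesh_edge_cm=0.2, detector_pixels=48, n_views=12,
                grid_nx=48, grid_nz=5, z_jitter_mm=0.5)
    base.update(overrides)
    return SampleSpec(**base)


@dataclass
class TrainingSample:
    """One (projections, truth volume, ROI mask) triple with provenance."""

    projections: ProjectionSet
    truth_volume: np.ndarray
    roi_mask: np.ndarray
    targets: list[Target]
    seed: int

    def normalized(self) -> tuple[np.ndarray, np.ndarray]:
        """Max-normalized (projections, truth) as float32 — applied at load
        time so raw physics units stay on disk."""
        p = self.projections.images.astype(np.float32)
        t = self.truth_volume.astype(np.float32)
        pm, tm = p.max(), t.max()
        return (p / pm if pm > 0 else p), (t / tm if tm > 0 else t)


def generate_sample(fm: ForwardModel, spec: SampleSpec, seed: int) -> TrainingSample:
    """Draw targets and run the forward chain; deterministic for fixed seed."""
    rng = np.random.default_rng(seed)
    n_t = int(rng.choice(spec.n_targets))
    targets = sample_targets(
        rng, fm.phantom, n_targets=n_t, diam_choices_mm=spec.diam_choices_mm,
        height_mm=spec.height_mm, center_range_mm=spec.center_range_mm,
        eed_range_mm=spec.eed_range_mm, concentration=spec.concentration,
        z_jitter_mm=spec.z_jitter_mm)
    projections = fm.simulate_projections(targets)
    if np.isfinite(spec.snr_db):
        projections = add_gaussian_noise(projections, spec.snr_db, rng)
    truth, roi = rasterize_targets(targets, fm.grid)
    return TrainingSample(projections, truth, roi, targets, seed)


def resize_projection(image: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Area-weighted (anti-aliased) resize; non-negative inputs stay non-negative."""
    image = np.asarray(image, dtype=float)
    if min(out_shape) < 1:
        raise ValidationError("output shape must be positive")
    if image.shape == tuple(out_shape):
        return image.copy()
    out = _sk_resize(image, out_shape, order=1, anti_aliasing=True,
                     preserve_range=True, mode="reflect")
    if image.min() >= 0:
        np.maximum(out, 0.0, out=out)
    return out


def resize_stack(images: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    return np.stack([resize_projection(im, out_shape) for im in images])


# ----------------------------------------------------------------------------
# Dataset on disk
# ----------------------------------------------------------------------------

@dataclass
class DatasetManifest:
    """Index of a generated dataset: per-sample seeds, splits, config hash."""

    master_seed: int
    config_hash: int | str
    spec: SampleSpec
    entries: list[dict] = field(default_factory=list)
    root: str | None = None
    _cache: list[TrainingSample] | None = field(default=None, repr=False)

    def paths(self, split: str | None = None) -> list[str]:
        return [e["path"] for e in self.entries
                if split is None or e["split"] == split]

    def split_indices(self, split: str) -> list[int]:
        return [i for i, e in enumerate(self.entries) if e["split"] == split]

    def load(self, index: int) -> TrainingSample:
        if self._cache is not None:
            return self._cache[index]
        return load_sample(os.path.join(self.root or "", self.entries[index]["path"]))

    def save(self, path: str) -> None:
        payload = {
            "master_seed": self.master_seed,
            "config_hash": self.config_hash,
            "spec": dataclasses.asdict(self.spec),
            "entries": self.entries,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=str)

    @classmethod
    def from_json(cls, path: str) -> "DatasetManifest":
        with open(path) as fh:
            payload = json.load(fh)
        spec_d = payload["spec"]
        for k in ("n_targets", "diam_choices_mm", "eed_range_mm"):
            spec_d[k] = tuple(spec_d[k])
        spec_d["snr_db"] = float(spec_d["snr_db"])
        return cls(payload["master_seed"], payload["config_hash"],
                   SampleSpec(**spec_d), payload["entries"],
                   root=os.path.dirname(path))


def save_sample(sample: TrainingSample, path: str) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("projections", data=sample.projections.images.astype(np.float32),
                          chunks=True)
        fh["angles_deg"] = sample.projections.angles_deg
        fh.create_dataset("truth", data=sample.truth_volume.astype(np.float32),
                          chunks=True)
        fh.create_dataset("roi_mask", data=sample.roi_mask)
        fh.attrs["seed"] = sample.seed
        fh.attrs["targets"] = json.dumps([dataclasses.asdict(t) for t in sample.targets])


def load_sample(path: str) -> TrainingSample:
    with h5py.File(path, "r") as fh:
        proj = ProjectionSet(fh["projections"][()].astype(float), fh["angles_deg"][()])
        truth = fh["truth"][()].astype(float)
        roi = fh["roi_mask"][()].astype(bool)
        seed = int(fh.attrs["seed"])
        targets = [Target(tuple(d.pop("center_mm")), **d)
                   for d in json.loads(fh.attrs["targets"])]
    return TrainingSample(proj, truth, roi, targets, seed)


def derive_sample_seeds(master_seed: int, n: int) -> list[int]:
    """Stable per-sample seeds spawned from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1, dtype=np.uint32)[0]) for child in ss.spawn(n)]


def generate_dataset(
    spec: SampleSpec,
    n_samples: int,
    split_fractions: dict[str, float] | None = None,
    master_seed: int = 0,
    out_dir: str | None = None,
    fm: ForwardModel | None = None,
) -> DatasetManifest:
    """Generate ``n_samples`` samples with disjoint train/val splits.

    With ``out_dir`` set, one HDF5 container per sample is written and the
    manifest references the files; otherwise samples stay in memory on the
    returned manifest.  Split sizes are exact: ``round(frac * n)`` with the
    last split absorbing the remainder.
    """
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    split_fractions = split_fractions or {"train": 0.75, "val": 0.25}
    if abs(sum(split_fractions.values()) - 1.0) > 1e-9:
        raise ValidationError("split fractions must sum to 1")
    names = list(split_fractions)
    counts = [int(round(split_fractions[s] * n_samples)) for s in names]
    counts[-1] = n_samples - sum(counts[:-1])
    if min(counts) < 0:
        raise ValidationError("split rounding produced a negative count")
    labels = [s for s, c in zip(names, counts) for _ in range(c)]

    fm = fm or spec.forward_model()
    seeds = derive_sample_seeds(master_seed, n_samples)
    manifest = DatasetManifest(master_seed, spec.config_hash(), spec, root=out_dir)
    cache: list[TrainingSample] | None = None if out_dir else []
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
    for i, (seed, split) in enumerate(zip(seeds, labels)):
        sample = generate_sample(fm, spec, seed)
        entry = {"index": i, "seed": seed, "split": split}
        if out_dir:
            fname = f"sample_{i:05d}.h5"
            save_sample(sample, os.path.join(out_dir, fname))
            entry["path"] = fname
        else:
            cache.append(sample)
        manifest.entries.append(entry)
    manifest._cache = cache
    if out_dir:
        manifest.save(os.path.join(out_dir, "manifest.json"))
    return manifest


def full_scale_phantom_recipe() -> dict:
    """The full-scale phantom recipe: 8000 samples split 6000/2000."""
    return {"spec": SampleSpec(), "n_samples": 8000,
            "split_fractions": {"train": 0.75, "val": 0.25}}


def full_scale_mouse_recipe() -> dict:
    """The mouse-geometry recipe: 4000 samples split 3000/1000, centres in
    +-8 mm, two targets (the cylinder stands in for the animal mesh)."""
    return {"spec": SampleSpec(center_range_mm=8.0, n_targets=(2,)),
            "n_samples": 4000, "split_fractions": {"train": 0.75, "val": 0.25}}
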