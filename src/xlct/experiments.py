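"""Simulation-study recipes: resolution, noise-robustness and multi-target
experiments at full or reduced scale.

A :class:`Study` bundles the geometry, two forward models (the camera-grid
model feeding the network and a coarser-detector model used to build the
weight matrix for the classical solvers) and cached operators, and exposes
case construction + method evaluation.  Classical solvers consume the
spectrally-normalized problem (max-normalized measurements, unit-spectral-
norm W) so the documented step/regularization settings are meaningful
regardless of the arbitrary photon-yield scale.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from .mesh import mesh_cylinder
from .classical import (LinearInverseProblem, ReconSettings, SOLVERS,
                        grid_neighbors, reconstruct_classical)
from .datasets import SampleSpec, scaled_spec
from .forward import DetectorModel, ForwardModel, ProjectionSet, XRaySource, add_gaussian_noise
from .geometry import Target, ValidationError, rasterize_targets, sample_targets
from .metrics import MetricReport, count_components, evaluate_volume
from .nn.training import TrainedModel

logger = logging.getLogger(__name__)

RESOLUTION_EEDS_MM = (2.0, 1.5, 1.0)
NOISE_SNRS_DB = (30.0, 25.0, 20.0, 15.0)


def spectral_norm(W: np.ndarray, n_iter: int = 30, seed: int = 0) -> float:
    """Largest singular value by power iteration on W^T W."""
    rng = np.random.default_rng(seed)
    v = rng.normal(size=W.shape[1]).astype(W.dtype)
    v /= np.linalg.norm(v)
    s = 0.0
    for _ in range(n_iter):
        u = W @ v
        s = np.linalg.norm(u)
        if s == 0:
            return 0.0
        v = W.T @ (u / s)
        v /= np.linalg.norm(v)
    return float(s)


@dataclass
class Case:
    """One evaluation scenario: targets plus matched projection stacks."""

    case_id: str
    targets: list[Target]
    truth: np.ndarray
    roi_mask: np.ndarray
    projections: ProjectionSet            # camera-grid stack (network input)
    projections_classical: ProjectionSet  # coarse-detector stack (matches W)
    eed_mm: float | None = None
    snr_db: float = float("inf")


class Study:
    """Geometry + cached operators for one set of study conditions."""

    def __init__(self, spec: SampleSpec | None = None,
                 classical_detector_pixels: int = 24):
        self.spec = spec or scaled_spec()
        self.phantom = self.spec.phantom()
        self.mesh = mesh_cylinder(self.phantom, self.spec.mesh_edge_cm)
        self.grid = self.spec.grid()
        self.fm = ForwardModel(self.phantom, self.mesh, self.spec.detector(),
                               XRaySource(), self.grid, self.spec.gamma)
        det_c = DetectorModel.for_phantom(self.phantom,
                                          n_pix=classical_detector_pixels,
                                          n_views=self.spec.n_views)
        self.fm_classical = ForwardModel(self.phantom, self.mesh, det_c,
                                         XRaySource(), self.grid, self.spec.gamma)
        self._W: np.ndarray | None = None
        self._W_norm: float | None = None
        self._W_scaled: np.ndarray | None = None
        self._active_rows: np.ndarray | None = None
        self._active_cols: np.ndarray | None = None
        self._reduced_neighbors: np.ndarray | None = None
        self._interior: np.ndarray | None = None

    @property
    def weight_matrix(self) -> np.ndarray:
        if self._W is None:
            logger.info("assembling weight matrix (%d x %d)",
                        self.fm_classical.detector.n_pixels * self.spec.n_views,
                        self.grid.n_voxels)
            self._W = self.fm_classical.build_weight_matrix(dtype=np.float32)
            self._W_norm = spectral_norm(self._W)
        return self._W

    @property
    def interior_mask(self) -> np.ndarray:
        if self._interior is None:
            centers = self.grid.voxel_centers_mm()
            self._interior = self.phantom.contains_mm(centers)
        return self._interior

    # -- case construction --------------------------------------------------
    def symmetric_pair(self, eed_mm: float, diameter_mm: float = 4.0,
                       concentration: float | None = None) -> list[Target]:
        """Two equal cylinders straddling the centre along x at a given EED."""
        conc = self.spec.concentration if concentration is None else concentration
        half = 0.5 * (eed_mm + diameter_mm)
        h = self.spec.height_mm
        return [Target((-half, 0.0, 0.0), diameter_mm, h, conc),
                Target((half, 0.0, 0.0), diameter_mm, h, conc)]

    def make_case(self, targets: list[Target], case_id: str,
                  snr_db: float = float("inf"), seed: int = 0,
                  eed_mm: float | None = None) -> Case:
        truth, roi = rasterize_targets(targets, self.grid)
        proj = self.fm.simulate_projections(targets)
        proj_c = self.fm_classical.simulate_projections(targets)
        if np.isfinite(snr_db):
            rng = np.random.default_rng(seed)
            proj = add_gaussian_noise(proj, snr_db, rng)
            proj_c = add_gaussian_noise(proj_c, snr_db, rng)
        return Case(case_id, targets, truth, roi, proj, proj_c, eed_mm, snr_db)

    def random_two_target_cases(self, n: int, seed: int,
                                snr_db: float = float("inf")) -> list[Case]:
        """Held-out random two-target scenarios drawn like the training data."""
        from .geometry import compute_eed
        ss = np.random.SeedSequence([seed, 0xE7A1])
        cases = []
        for i, child in enumerate(ss.spawn(n)):
            rng = np.random.default_rng(child)
            targets = sample_targets(
                rng, self.phantom, n_targets=2,
                diam_choices_mm=self.spec.diam_choices_mm,
                height_mm=self.spec.height_mm,
                center_range_mm=self.spec.center_range_mm,
                eed_range_mm=self.spec.eed_range_mm,
                concentration=self.spec.concentration,
                z_jitter_mm=self.spec.z_jitter_mm)
            cases.append(self.make_case(
                targets, f"rand2-{i:02d}", snr_db=snr_db,
                seed=int(rng.integers(2**31)),
                eed_mm=compute_eed(*targets)))
        return cases

    # -- evaluation ---------------------------------------------------------
    def _reduced_operator(self):
        """Spectrally-normalized W restricted to phantom-support voxels and
        detector pixels that actually receive light.

        Voxels outside the cylinder cannot emit (their W columns are
        structurally zero) and silhouette-exterior pixels carry no
        information, so the restriction changes nothing about the solution
        while shrinking the dense operator severalfold.
        """
        if self._W_scaled is None:
            W = self.weight_matrix
            self._active_cols = np.flatnonzero(self.interior_mask.reshape(-1))
            Wc = W[:, self._active_cols]
            self._active_rows = np.flatnonzero(np.abs(Wc).max(axis=1) > 0)
            self._W_scaled = np.ascontiguousarray(
                Wc[self._active_rows] / self._W_norm)
            nb_full = grid_neighbors(self.grid)
            remap = -np.ones(self.grid.n_voxels, dtype=np.int64)
            remap[self._active_cols] = np.arange(len(self._active_cols))
            nb = remap[nb_full[self._active_cols]]
            nb[nb_full[self._active_cols] < 0] = -1
            self._reduced_neighbors = nb
        return self._W_scaled, self._active_rows, self._active_cols

    def classical_problem(self, case: Case) -> LinearInverseProblem:
        W, rows, _ = self._reduced_operator()
        y = case.projections_classical.stacked().astype(np.float32)[rows]
        ymax = y.max()
        return LinearInverseProblem(W, y / (ymax if ymax > 0 else 1.0))

    def _embed(self, x_reduced: np.ndarray) -> np.ndarray:
        full = np.zeros(self.grid.n_voxels)
        full[self._active_cols] = np.asarray(x_reduced, dtype=float).reshape(-1)
        return full.reshape(self.grid.shape)

    def reconstruct(self, method: str, case: Case,
                    model: TrainedModel | None = None,
                    settings: ReconSettings | None = None) -> np.ndarray:
        if method == "network":
            if model is None:
                raise ValidationError("network evaluation requires a trained model")
            return model.reconstruct(case.projections)
        problem = self.classical_problem(case)
        if method == "map":
            result = SOLVERS[method](problem, settings,
                                     neighbors=self._reduced_neighbors)
        else:
            result = reconstruct_classical(method, problem, settings)
        return self._embed(result.x)

    def evaluate(self, method: str, case: Case,
                 model: TrainedModel | None = None,
                 settings: ReconSettings | None = None) -> MetricReport:
        recon = self.reconstruct(method, case, model, settings)
        report = evaluate_volume(recon, case.truth, self.interior_mask,
                                 method=method, case_id=case.case_id,
                                 eed_mm=case.eed_mm, snr_db=case.snr_db)
        report.extra["n_components_halfmax"] = count_components(recon)
        return report


# ----------------------------------------------------------------------------
# recipes
# ----------------------------------------------------------------------------

def _validate_methods(methods) -> list[str]:
    methods = list(methods)
    if not methods:
        raise ValidationError("method list is empty")
    for m in methods:
        if m != "network" and m not in SOLVERS:
            raise ValidationError(f"unknown method {m!r}")
    return methods


def run_resolution_experiment(study: Study, methods, model=None,
                              eeds_mm=RESOLUTION_EEDS_MM, snr_db: float = 30.0,
                              seed: int = 0) -> list[MetricReport]:
    """Symmetric two-target cases at decreasing edge-to-edge distance."""
    methods = _validate_methods(methods)
    reports = []
    for eed in eeds_mm:
        case = study.make_case(study.symmetric_pair(eed), f"eed{eed:g}mm",
                               snr_db=snr_db, seed=seed, eed_mm=eed)
        for m in methods:
            reports.append(study.evaluate(m, case, model))
    return reports


def run_noise_experiment(study: Study, methods, model=None,
                         snrs_db=NOISE_SNRS_DB, eed_mm: float = 1.5,
                         seed: int = 0) -> list[MetricReport]:
    """One geometry evaluated under the SNR sweep."""
    methods = _validate_methods(methods)
    reports = []
    for snr in snrs_db:
        case = study.make_case(study.symmetric_pair(eed_mm),
                               f"snr{snr:g}dB", snr_db=snr, seed=seed, eed_mm=eed_mm)
        for m in methods:
            reports.append(study.evaluate(m, case, model))
    return reports


def run_multi_target_experiment(study: Study, methods, model=None,
                                n_cases: int = 3, seed: int = 0,
                                snr_db: float = 30.0) -> list[MetricReport]:
    """Random three-target scenarios."""
    methods = _validate_methods(methods)
    reports = []
    ss = np.random.SeedSequence([seed, 0x3A11])
    for i, child in enumerate(ss.spawn(n_cases)):
        rng = np.random.default_rng(child)
        targets = sample_targets(
            rng, study.phantom, n_targets=3,
            diam_choices_mm=study.spec.diam_choices_mm,
            height_mm=study.spec.height_mm,
            center_range_mm=study.spec.center_range_mm,
            eed_range_mm=study.spec.eed_range_mm,
            concentration=study.spec.concentration,
            z_jitter_mm=study.spec.z_jitter_mm)
        case = study.make_case(targets, f"multi3-{i}", snr_db=snr_db,
                               seed=int(rng.integers(2**31)))
        for m in methods:
            reports.append(study.evaluate(m, case, model))
    return reports


def aggregate_reports(reports: list[MetricReport]) -> dict:
    """Mean DICE/CNR per method (per-case records stay intact)."""
    out: dict[str, dict] = {}
    for r in reports:
        d = out.setdefault(r.method, {"dice": [], "cnr": []})
        d["dice"].append(r.dice)
        d["cnr"].append(r.cnr)
    return {m: {"mean_dice": float(np.mean(v["dice"])),
                "mean_cnr": float(np.mean(v["cnr"])),
                "n_cases": len(v["dice"])}
            for m, v in out.items()}


def save_reports(reports: list[MetricReport], out_dir: str, stem: str) -> None:
    """Write per-case CSV and aggregate JSON."""
    os.makedirs(out_dir, exist_ok=True)
    rows = [dataclasses.asdict(r) for r in reports]
    import csv
    cols = ["method", "case_id", "dice", "cnr", "eed_mm", "snr_db", "threshold_frac"]
    with open(os.path.join(out_dir, f"{stem}.csv"), "w", newline="") as fh:
        wtr = csv.DictWriter(fh, fieldnames=cols, extrasaction="ignore")
        wtr.writeheader()
        wtr.writerows(rows)
    with open(os.path.join(out_dir, f"{stem}_aggregate.json"), "w") as fh:
        json.dump(aggregate_reports(reports), fh, indent=1)


EXPERIMENTS = {
    "resolution": run_resolution_experiment,
    "noise": run_noise_experiment,
    "multi": run_multi_target_experiment,
}


def run_experiment(recipe: dict, study: Study | None = None,
                   model: TrainedModel | None = None) -> list[MetricReport]:
    """Dispatch a recipe dict: {"experiment": ..., "methods": [...], ...}.

    Remaining keys are forwarded to the experiment function; reports are
    optionally written to ``recipe["out"]``.
    """
    recipe = dict(recipe)
    name = recipe.pop("experiment")
    if name not in EXPERIMENTS:
        raise ValidationError(f"unknown experiment {name!r}")
    methods = _validate_methods(recipe.pop("methods"))
    out = recipe.pop("out", None)
    study = study or Study()
    reports = EXPERIMENTS[name](study, methods, model=model, **recipe)
    if out:
        save_reports(reports, out, name)
    return reports
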