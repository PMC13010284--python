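"""Synthetic glioblastoma phantoms with known cell-density ground truth.

Each phantom subject is a set of co-registered volumes on one grid: three MRI
sequences (T1-weighted, T2-weighted, gadolinium-enhanced T1-weighted), a
methionine-PET SUV volume, and binary masks (brain, cerebellum, enhancing core,
whole tumor).  The geometry is deliberately simple — an ellipsoidal brain, a
posterior-inferior ellipsoidal cerebellum, and a concentric-shell tumor
(enhancing core, non-enhancing rim, peritumoral edema) — because the downstream
pipeline is intensity- and mask-driven, not anatomy-driven.

The PET forward model is affine in a latent tumor-cell-density map: the
tumor-to-normal uptake ratio is ``1 + slope * density`` with density decaying
linearly from a central peak to zero at the outer rim boundary, so PET uptake
is a graded surrogate for cell density.  Per-subject multiplicative gains on
each MRI sequence emulate the arbitrary intensity scales of different scanners
and institutions; a per-subject PET gain emulates injected-dose variability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

__all__ = [
    "PhantomSpec",
    "SamplingPoint",
    "SubjectVolumeSet",
    "generate_subject",
    "generate_cohort",
    "save_subject",
    "load_subject",
]

#: tissue classes -> (T1W, T2W, T1Gd-enhancement, PET handled separately)
DEFAULT_TISSUE_MEANS = {
    "background": (30.0, 30.0),
    "brain": (300.0, 250.0),
    "edema": (240.0, 420.0),
    "ncet": (260.0, 400.0),
    "core": (260.0, 330.0),
}

DEFAULT_NOISE_SD = {"t1w": 5.0, "t2w": 5.0, "t1gd": 5.0, "pet": 0.02}


@dataclass(frozen=True)
class TumorGeometry:
    """Concentric-shell tumor: enhancing core, nCET rim, edema halo (mm)."""

    center_mm: tuple[float, float, float] = (20.0, 25.0, 8.0)  # offset from brain center
    core_radius_mm: float = 8.0
    ncet_thickness_mm: float = 6.0
    edema_thickness_mm: float = 10.0


@dataclass(frozen=True)
class DensityParams:
    """Latent tumor-cell-density field: linear radial decay from a central peak.

    ``peak`` is in cells/mm²; density reaches zero at the outer nCET boundary.
    ``tn_slope`` converts density to a tumor-to-normal uptake ratio increment.
    """

    peak: float = 30_000.0
    tn_slope: float = 5.8e-5


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (96, 96, 64)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    tissue_means: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_MEANS))
    noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    gain_range: tuple[float, float] = (0.5, 2.0)
    pet_gain_range: tuple[float, float] = (0.8, 1.25)
    tumor_geometry: TumorGeometry = field(default_factory=TumorGeometry)
    density_params: DensityParams = field(default_factory=DensityParams)
    enhancement_signal: float = 150.0       # T1Gd minus T1W inside the enhancing core
    normal_suv: float = 1.5                 # cerebellar / normal-brain SUV baseline
    background_suv: float = 0.15
    brain_semiaxes_mm: tuple[float, float, float] = (70.0, 85.0, 55.0)
    cerebellum_center_mm: tuple[float, float, float] = (0.0, -55.0, -30.0)
    cerebellum_semiaxes_mm: tuple[float, float, float] = (28.0, 22.0, 16.0)
    geometry_jitter_mm: float = 4.0         # per-subject jitter of the tumor center
    radius_jitter_frac: float = 0.15        # relative jitter of shell radii
    n_sampling_points: int = 4
    seed: int = 0

    def validate(self) -> None:
        g = self.tumor_geometry
        if min(g.core_radius_mm, g.ncet_thickness_mm, g.edema_thickness_mm) <= 0:
            raise ValueError("tumor radii/thicknesses must be strictly positive")
        if self.gain_range[0] <= 0 or self.gain_range[1] < self.gain_range[0]:
            raise ValueError("gain_range bounds must be positive and ordered")
        outer = g.core_radius_mm + g.ncet_thickness_mm + g.edema_thickness_mm
        c = np.asarray(g.center_mm)
        ax = np.asarray(self.brain_semiaxes_mm)
        # sufficient containment check: tumor bounding sphere inside the brain
        # ellipsoid iff its center lies in the ellipsoid shrunk by the radius
        if outer >= ax.min() or np.sum(c**2 / (ax - outer) ** 2) > 1.0:
            raise ValueError("tumor (with edema halo) does not fit inside the brain")


@dataclass(frozen=True)
class SamplingPoint:
    """A tissue-sampling coordinate with its ground-truth cell density."""

    position_mm: tuple[float, float, float]
    true_density: float


@dataclass
class SubjectVolumeSet:
    subject_id: str
    t1w: np.ndarray
    t2w: np.ndarray
    t1gd: np.ndarray
    pet_suv: np.ndarray
    brain_mask: np.ndarray
    cerebellum_mask: np.ndarray
    enhancing_mask: np.ndarray
    tumor_mask: np.ndarray
    cell_density: np.ndarray
    sampling_points: list[SamplingPoint]
    voxel_size_mm: tuple[float, float, float]
    gains: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {
            v.shape
            for v in (self.t1w, self.t2w, self.t1gd, self.pet_suv, self.brain_mask,
                      self.cerebellum_mask, self.enhancing_mask, self.tumor_mask,
                      self.cell_density)
        }
        if len(shapes) != 1:
            raise ValueError(f"volumes of {self.subject_id} do not share a grid: {shapes}")

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.t1w.shape


def _coord_grids(spec: PhantomSpec):
    """Physical coordinates (mm) of voxel centers, origin at the grid center."""
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * dv
        for n, dv in zip(spec.grid_shape, spec.voxel_size_mm)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(grids, center, semiaxes) -> np.ndarray:
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return q <= 1.0


def generate_subject(spec: PhantomSpec, subject_index: int = 0) -> SubjectVolumeSet:
    """Generate one phantom subject; deterministic in (spec, subject_index)."""
    spec.validate()
    rng = np.random.default_rng([spec.seed, subject_index])
    g0 = spec.tumor_geometry

    jit = rng.uniform(-spec.geometry_jitter_mm, spec.geometry_jitter_mm, size=3)
    rscale = 1.0 + rng.uniform(-spec.radius_jitter_frac, spec.radius_jitter_frac)
    geom = TumorGeometry(
        center_mm=tuple(np.asarray(g0.center_mm) + jit),
        core_radius_mm=g0.core_radius_mm * rscale,
        ncet_thickness_mm=g0.ncet_thickness_mm * rscale,
        edema_thickness_mm=g0.edema_thickness_mm * rscale,
    )
    # re-check containment for the jittered geometry
    replace(spec, tumor_geometry=geom).validate()

    grids = _coord_grids(spec)
    brain = _ellipsoid(grids, (0.0, 0.0, 0.0), spec.brain_semiaxes_mm)
    cerebellum = _ellipsoid(grids, spec.cerebellum_center_mm, spec.cerebellum_semiaxes_mm) & brain

    r = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, geom.center_mm)))
    r_core = geom.core_radius_mm
    r_ncet = r_core + geom.ncet_thickness_mm
    r_edema = r_ncet + geom.edema_thickness_mm
    enhancing = (r <= r_core) & brain
    tumor = (r <= r_ncet) & brain
    edema = (r <= r_edema) & brain & ~tumor
    if np.any(cerebellum & tumor):
        raise ValueError("tumor overlaps the cerebellar reference region")

    # latent density: linear decay peak -> 0 at the outer nCET boundary
    dp = spec.density_params
    density = np.where(tumor, dp.peak * np.clip(1.0 - r / r_ncet, 0.0, 1.0), 0.0)

    tm = spec.tissue_means
    t1 = np.full(spec.grid_shape, tm["background"][0])
    t2 = np.full(spec.grid_shape, tm["background"][1])
    for mask, cls in ((brain, "brain"), (edema, "edema"),
                      (tumor & ~enhancing, "ncet"), (enhancing, "core")):
        t1[mask] = tm[cls][0]
        t2[mask] = tm[cls][1]

    enh = np.where(enhancing, spec.enhancement_signal, 0.0)
    tn_field = 1.0 + dp.tn_slope * density
    suv = np.where(brain, spec.normal_suv * tn_field, spec.background_suv)

    def noisy(x, sd):
        return np.clip(x + rng.normal(0.0, sd, x.shape), 0.0, None) if sd > 0 else x.copy()

    gains = {m: float(rng.uniform(*spec.gain_range)) for m in ("t1w", "t2w", "t1gd")}
    gains["pet"] = float(rng.uniform(*spec.pet_gain_range))

    t1w = gains["t1w"] * noisy(t1, spec.noise_sd["t1w"])
    t2w = gains["t2w"] * noisy(t2, spec.noise_sd["t2w"])
    t1gd = gains["t1gd"] * noisy(t1 + enh, spec.noise_sd["t1gd"])
    pet = gains["pet"] * noisy(suv, spec.noise_sd["pet"])

    points = _sample_points(rng, spec, brain, edema | tumor, density)

    return SubjectVolumeSet(
        subject_id=f"sub-s{spec.seed}-{subject_index:03d}",
        t1w=t1w, t2w=t2w, t1gd=t1gd, pet_suv=pet,
        brain_mask=brain, cerebellum_mask=cerebellum,
        enhancing_mask=enhancing, tumor_mask=tumor,
        cell_density=density, sampling_points=points,
        voxel_size_mm=spec.voxel_size_mm, gains=gains,
    )


def _sample_points(rng, spec, brain, region, density) -> list[SamplingPoint]:
    """Random sampling coordinates in the tumor/edema region (fallback: brain)."""
    candidates = np.argwhere(region & brain)
    if candidates.size == 0:
        candidates = np.argwhere(brain)
    idx = rng.choice(len(candidates), size=min(spec.n_sampling_points, len(candidates)),
                     replace=False)
    points = []
    for vox in candidates[idx]:
        pos = tuple(
            float((v - (n - 1) / 2.0) * dv)
            for v, n, dv in zip(vox, spec.grid_shape, spec.voxel_size_mm)
        )
        points.append(SamplingPoint(position_mm=pos, true_density=float(density[tuple(vox)])))
    return points


def generate_cohort(spec: PhantomSpec, n_subjects: int, seed: int | None = None
                    ) -> list[SubjectVolumeSet]:
    """Generate ``n_subjects`` phantoms differing in gain, geometry and noise."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if seed is not None:
        spec = replace(spec, seed=seed)
    return [generate_subject(spec, i) for i in range(n_subjects)]


# ---------------------------------------------------------------------------
# file layout: one NIfTI per volume + a JSON sidecar

_VOLUMES = ("t1w", "t2w", "t1gd", "pet_suv", "cell_density")
_MASKS = ("brain_mask", "cerebellum_mask", "enhancing_mask", "tumor_mask")


def save_subject(subject: SubjectVolumeSet, out_dir: str | Path) -> Path:
    from .io import write_volume

    out = Path(out_dir) / subject.subject_id
    out.mkdir(parents=True, exist_ok=True)
    for name in _VOLUMES:
        write_volume(getattr(subject, name).astype(np.float32), out / f"{name}.nii.gz",
                     voxel_size_mm=subject.voxel_size_mm)
    for name in _MASKS:
        write_volume(getattr(subject, name).astype(np.uint8), out / f"{name}.nii.gz",
                     voxel_size_mm=subject.voxel_size_mm)
    sidecar = {
        "subject_id": subject.subject_id,
        "voxel_size_mm": list(subject.voxel_size_mm),
        "gains": subject.gains,
        "sampling_points": [asdict(p) for p in subject.sampling_points],
    }
    (out / "subject.json").write_text(json.dumps(sidecar, indent=2))
    return out


def load_subject(subject_dir: str | Path) -> SubjectVolumeSet:
    from .io import read_volume

    d = Path(subject_dir)
    meta = json.loads((d / "subject.json").read_text())
    vols = {}
    for name in _VOLUMES + _MASKS:
        data, _ = read_volume(d / f"{name}.nii.gz")
        vols[name] = data.astype(bool) if name in _MASKS else data
    return SubjectVolumeSet(
        subject_id=meta["subject_id"],
        sampling_points=[SamplingPoint(tuple(p["position_mm"]), p["true_density"])
                         for p in meta["sampling_points"]],
        voxel_size_mm=tuple(meta["voxel_size_mm"]),
        gains=meta.get("gains", {}),
        **vols,
    )
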