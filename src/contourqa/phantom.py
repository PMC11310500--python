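"""Synthetic CT phantom cohorts for desk-scale testing.

Real planning CTs and clinical contours cannot ship with the package, so
every other module is exercised on phantoms: geometric organ primitives
(spheres, ellipsoids, z-axis tubes) filled with tissue-characteristic HU
draws (lung ~ -700 HU, soft tissue ~ 40 HU, ...) on a Gaussian-noise
background, plus controlled segmentation-error perturbations that emulate
the failure modes of atlas and neural-network auto-segmentation: boundary
dilation/erosion (size over/under-estimation), translation, and boundary
noise.

Everything is deterministic per integer seed; per-patient randomness is
derived as ``seed + patient_index`` so cohorts are reproducible and could
be generated in parallel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import binary_dilation, binary_erosion
from skimage.morphology import ball

from .overlap import DegenerateInputError
from .volumes import BinaryMask, ImageVolume, write_mask, write_volume

__all__ = [
    "OrganSpec",
    "PhantomSpec",
    "PerturbationSpec",
    "generate_phantom",
    "perturb_mask",
    "simulate_cohort",
    "example_spec",
    "load_spec_yaml",
]

_PRIMITIVES = ("sphere", "ellipsoid", "tube")
_PERTURBATION_KINDS = ("dilate", "erode", "translate", "boundary_noise", "mislabel_shift")


@dataclass(frozen=True)
class OrganSpec:
    """One organ primitive: geometry in mm plus its HU distribution."""

    organ: str
    primitive: str
    center: tuple[float, float, float]  # mm
    radii: tuple[float, float, float]  # mm; sphere uses radii[0]
    hu_mean: float
    hu_sd: float

    def __post_init__(self):
        if self.primitive not in _PRIMITIVES:
            raise ValueError(f"primitive must be one of {_PRIMITIVES}")
        if any(r <= 0 for r in self.radii):
            raise ValueError(f"radii must be positive, got {self.radii}")
        if not -1024.0 <= self.hu_mean <= 3000.0:
            raise ValueError(f"HU mean {self.hu_mean} outside [-1024, 3000]")
        if self.hu_sd < 0:
            raise ValueError("HU SD must be nonnegative")


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    background: tuple[float, float] = (-50.0, 20.0)  # (mean HU, SD HU)
    organs: tuple[OrganSpec, ...] = ()
    allow_overlap: bool = False  # later organs take precedence if True

    def scaled(self, factor: float) -> "PhantomSpec":
        """All organ radii scaled by *factor* (patient-size jitter)."""
        if factor <= 0:
            raise ValueError(f"size factor must be positive, got {factor}")
        organs = tuple(
            OrganSpec(
                o.organ,
                o.primitive,
                o.center,
                tuple(r * factor for r in o.radii),
                o.hu_mean,
                o.hu_sd,
            )
            for o in self.organs
        )
        return PhantomSpec(
            self.shape, self.spacing, self.origin, self.background, organs, self.allow_overlap
        )


@dataclass(frozen=True)
class PerturbationSpec:
    """A segmentation error to inject into a ground-truth mask.

    ``magnitude`` is in voxels (structuring-element radius for
    dilate/erode, shift for mislabel_shift), in mm for ``translate``
    (rounded to whole voxels per axis), and a flip probability in [0, 1]
    for ``boundary_noise``.
    """

    kind: str
    magnitude: float
    seed: int = 0
    direction: tuple[float, float, float] = (1.0, 0.0, 0.0)  # for translate

    def __post_init__(self):
        if self.kind not in _PERTURBATION_KINDS:
            raise ValueError(f"kind must be one of {_PERTURBATION_KINDS}")
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")


def _voxel_centers_mm(spec: PhantomSpec):
    sp = np.asarray(spec.spacing)
    og = np.asarray(spec.origin)
    axes = [og[a] + sp[a] * np.arange(spec.shape[a]) for a in range(3)]
    return np.meshgrid(*axes, indexing="ij")


def _rasterize(organ: OrganSpec, spec: PhantomSpec) -> np.ndarray:
    """Voxel-center-inside test for one primitive."""
    xx, yy, zz = _voxel_centers_mm(spec)
    cx, cy, cz = organ.center
    if organ.primitive == "sphere":
        rx = ry = rz = organ.radii[0]
    else:
        rx, ry, rz = organ.radii
    if organ.primitive == "tube":
        inside = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
        inside &= np.abs(zz - cz) <= rz
    else:
        inside = (
            ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 + ((zz - cz) / rz) ** 2
            <= 1.0
        )
    return inside


def generate_phantom(
    spec: PhantomSpec, seed: int
) -> tuple[ImageVolume, list[BinaryMask]]:
    """A CT-like image plus one ground-truth mask per organ.

    The image is a per-voxel Gaussian background draw, overwritten inside
    each organ primitive by that organ's HU draw.  Identical (spec, seed)
    give bit-identical output.  Overlapping primitives are an error unless
    ``spec.allow_overlap`` grants list-order precedence (later wins).
    """
    rng = np.random.default_rng(seed)
    bg_mean, bg_sd = spec.background
    img = rng.normal(bg_mean, bg_sd, size=spec.shape)
    masks: list[BinaryMask] = []
    occupied = np.zeros(spec.shape, dtype=bool)
    for organ in spec.organs:
        inside = _rasterize(organ, spec)
        if not inside.any():
            raise ValueError(f"organ {organ.organ!r} rasterizes to zero voxels")
        if inside[0].any() or inside[-1].any() or inside[:, 0].any() or inside[:, -1].any() \
                or inside[:, :, 0].any() or inside[:, :, -1].any():
            raise ValueError(f"organ {organ.organ!r} touches the grid edge")
        if (occupied & inside).any() and not spec.allow_overlap:
            raise ValueError(
                f"organ {organ.organ!r} overlaps a previous organ; set "
                "allow_overlap for list-order precedence"
            )
        occupied |= inside
        img[inside] = rng.normal(organ.hu_mean, organ.hu_sd, size=int(inside.sum()))
        masks.append(
            BinaryMask(
                voxels=inside,
                spacing=spec.spacing,
                origin=spec.origin,
                organ=organ.organ,
                role="ground_truth",
            )
        )
    return (
        ImageVolume(voxels=img, spacing=spec.spacing, origin=spec.origin),
        masks,
    )


def _shift_voxels(vox: np.ndarray, shift: tuple[int, int, int]) -> np.ndarray:
    out = np.zeros_like(vox)
    src = []
    dst = []
    for axis, s in enumerate(shift):
        n = vox.shape[axis]
        if abs(s) >= n:
            return out
        if s >= 0:
            src.append(slice(0, n - s))
            dst.append(slice(s, n))
        else:
            src.append(slice(-s, n))
            dst.append(slice(0, n + s))
    out[tuple(dst)] = vox[tuple(src)]
    return out


def perturb_mask(mask: BinaryMask, p: PerturbationSpec) -> BinaryMask:
    """Apply one segmentation-error perturbation; deterministic per seed.

    Raises :class:`DegenerateInputError` on an empty input mask or when an
    erosion empties the mask.
    """
    if mask.is_empty:
        raise DegenerateInputError("cannot perturb an empty mask")
    vox = mask.voxels
    rng = np.random.default_rng(p.seed)
    if p.magnitude == 0:
        out = vox.copy()
    elif p.kind in ("dilate", "erode"):
        selem = ball(int(round(p.magnitude)))
        op = binary_dilation if p.kind == "dilate" else binary_erosion
        out = op(vox, structure=selem)
        if p.kind == "erode" and not out.any():
            raise DegenerateInputError(
                f"erosion by {p.magnitude} voxels emptied the mask"
            )
    elif p.kind == "translate":
        d = np.asarray(p.direction, dtype=float)
        norm = np.linalg.norm(d)
        if norm == 0:
            raise ValueError("translate direction must be non-zero")
        shift_mm = p.magnitude * d / norm
        shift_vox = tuple(
            int(round(s / sp)) for s, sp in zip(shift_mm, mask.spacing)
        )
        out = _shift_voxels(vox, shift_vox)
    elif p.kind == "mislabel_shift":
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        shift_vox = tuple(int(round(p.magnitude * c)) for c in d)
        out = _shift_voxels(vox, shift_vox)
    elif p.kind == "boundary_noise":
        if not 0 <= p.magnitude <= 1:
            raise ValueError("boundary_noise magnitude is a probability in [0, 1]")
        inner = vox & ~binary_erosion(vox, border_value=0)
        outer = binary_dilation(vox) & ~vox
        boundary = inner | outer
        flips = boundary & (rng.random(vox.shape) < p.magnitude)
        out = vox ^ flips
    else:  # pragma: no cover - guarded by PerturbationSpec
        raise ValueError(p.kind)
    return BinaryMask(
        voxels=out,
        spacing=mask.spacing,
        origin=mask.origin,
        organ=mask.organ,
        role=mask.role,
    )


def simulate_cohort(
    spec: PhantomSpec,
    n_patients: int,
    out_dir: str | Path,
    size_jitter: float = 0.15,
    perturbations: dict[str, PerturbationSpec] | None = None,
    seed: int = 0,
) -> Path:
    """Write a cohort of phantom patients in the on-disk layout the
    ``compare``/``build-baseline``/``qa`` commands consume.

    Per patient: one size-jitter factor drawn uniformly from
    ``1 +/- size_jitter`` scales every organ radius (standing in for the
    pediatric size range), then a phantom image, ground-truth masks, and
    one perturbed mask set per named method are written as
    ``<patient>/<patient>_<organ>_<role>.nii.gz``.  A ``manifest.json``
    records the spec, seed and per-patient jitter.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    perturbations = perturbations or {}
    manifest = {"seed": seed, "n_patients": n_patients, "size_jitter": size_jitter,
                "methods": sorted(perturbations), "patients": {}}
    for i in range(n_patients):
        pid = f"p{i:03d}"
        p_seed = seed + i
        rng = np.random.default_rng(p_seed)
        factor = float(rng.uniform(1.0 - size_jitter, 1.0 + size_jitter))
        if factor <= 0:
            raise ValueError("size jitter produced a non-positive scale factor")
        image, gt_masks = generate_phantom(spec.scaled(factor), seed=p_seed)
        pdir = out_dir / pid
        pdir.mkdir(exist_ok=True)
        write_volume(image, pdir / f"{pid}_ct.nii.gz")
        for mask in gt_masks:
            write_mask(mask, pdir / f"{pid}_{mask.organ}_ground_truth.nii.gz")
            for method, pert in perturbations.items():
                seeded = PerturbationSpec(
                    kind=pert.kind,
                    magnitude=pert.magnitude,
                    seed=p_seed + pert.seed,
                    direction=pert.direction,
                )
                test = perturb_mask(mask, seeded)
                write_mask(test, pdir / f"{pid}_{mask.organ}_{method}.nii.gz")
        manifest["patients"][pid] = {"seed": p_seed, "size_factor": factor}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir


def example_spec(
    shape: tuple[int, int, int] = (48, 48, 32),
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0),
) -> PhantomSpec:
    """A small three-organ phantom: soft-tissue brain, air-filled lung,
    kidney — HU means chosen at tissue-typical values so their densities
    are well separated.  Organ geometry scales with the grid's physical
    extent so any reasonable shape/spacing stays valid."""
    ext = tuple(n * s for n, s in zip(shape, spacing))
    cx, cy, cz = (e / 2 for e in ext)
    r = 0.13 * min(ext)
    return PhantomSpec(
        shape=shape,
        spacing=spacing,
        background=(-50.0, 20.0),
        organs=(
            OrganSpec("brain", "sphere",
                      (cx - 0.21 * ext[0], cy - 0.19 * ext[1], cz), (r, r, r), 40.0, 10.0),
            OrganSpec("lung_L", "ellipsoid",
                      (cx + 0.21 * ext[0], cy - 0.15 * ext[1], cz),
                      (r, 0.85 * r, 1.1 * r), -700.0, 80.0),
            OrganSpec("kidney_L", "sphere",
                      (cx, cy + 0.23 * ext[1], cz), (0.85 * r,) * 3, 30.0, 15.0),
        ),
    )


def load_spec_yaml(path: str | Path) -> PhantomSpec:
    """Read a :class:`PhantomSpec` from a YAML config mirroring the fields."""
    cfg = yaml.safe_load(Path(path).read_text())
    organs = tuple(
        OrganSpec(
            organ=o["organ"],
            primitive=o.get("primitive", "sphere"),
            center=tuple(o["center"]),
            radii=tuple(o["radii"]) if hasattr(o["radii"], "__len__") else (o["radii"],) * 3,
            hu_mean=float(o["hu_mean"]),
            hu_sd=float(o.get("hu_sd", 10.0)),
        )
        for o in cfg.get("organs", [])
    )
    return PhantomSpec(
        shape=tuple(cfg["shape"]),
        spacing=tuple(cfg.get("spacing", (1.0, 1.0, 1.0))),
        origin=tuple(cfg.get("origin", (0.0, 0.0, 0.0))),
        background=tuple(cfg.get("background", (-50.0, 20.0))),
        organs=organs,
        allow_overlap=bool(cfg.get("allow_overlap", False)),
    )
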