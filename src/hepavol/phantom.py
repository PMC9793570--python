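"""Synthetic abdominal-CT phantoms with analytically known ground truth.

Each phantom emulates a portal-venous-phase scan of a traumatized liver: an
ellipsoidal "liver" of bright parenchyma on a darker soft-tissue background,
containing hypodense lesions (rotated ellipsoids for intraparenchymal
hematomas, thin discs for lacerations) clipped to the parenchyma.  The voxel
masks used to paint the volume ARE the ground truth, so liver volume, trauma
volume and LPDI are known exactly, and graded cohorts can be generated whose
lesion burden increases with a pseudo-AAST grade.

Lesion burden is targeted as an LPDI percentage: lesion sizes are scaled by
bisection until the trauma/liver voxel ratio lands within +/-1.5 percentage
points of the requested target (exact analytic targeting is impossible once
lesions are clipped to the liver and to each other).

The default grid is desk-scale, 96 x 96 x 48 voxels at (2, 2, 5) mm — it
keeps the strong through-plane anisotropy of 5 mm-slice abdominal CT while
staying small enough for CPU pipelines.  The default liver semi-axes
(60, 45, 55) mm give ~620 ml, a realistic pediatric liver volume.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import BinaryMask, CTVolume, GeometryError, voxel_center_coords
from .io import unit_voxel_volume_ml, write_mask, write_volume
from .stats import CohortRecord
from .volumetry import VolumetryResult, compute_lpdi

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "PhantomCase",
    "GRADE_LPDI_BANDS",
    "generate_phantom",
    "generate_cohort",
    "save_cohort",
]

#: Non-overlapping, monotone-increasing target-LPDI bands per pseudo-grade
#: (percent).  A design choice informed by the fact that trauma volume and
#: LPDI increase with AAST grade; not a claim of clinical equivalence.
GRADE_LPDI_BANDS: dict[int, tuple[float, float]] = {
    1: (0.5, 2.0),
    2: (2.0, 4.0),
    3: (4.0, 12.0),
    4: (12.0, 25.0),
    5: (25.0, 40.0),
}

_LPDI_TOL_PP = 1.5  # acceptable |achieved - target| in percentage points


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic phantom.

    Attenuation values are HU-like: parenchyma ~120 (enhanced liver),
    background ~30 (unenhanced soft tissue), lesions offset negatively
    (hypodense laceration/hematoma).  ``blur_sigma_mm`` adds Gaussian
    partial-volume smoothing (0 disables it); ``noise_sd`` adds Gaussian
    noise after the blur.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 48)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 5.0)
    liver_semiaxes_mm: tuple[float, float, float] = (60.0, 45.0, 55.0)
    liver_center: tuple[float, float, float] | None = None  # grid center if None
    liver_hu: float = 120.0
    background_hu: float = 30.0
    lesion_count: int = 3
    target_lpdi_pct: float = 8.0
    lesion_hu_offset: float = -60.0
    noise_sd: float = 5.0
    blur_sigma_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(s) <= 0 for s in self.grid_shape):
            raise GeometryError("grid_shape must be positive")
        if any(s <= 0 for s in self.spacing_mm):
            raise GeometryError("spacing_mm must be positive")
        if any(a <= 0 for a in self.liver_semiaxes_mm):
            raise GeometryError("liver semi-axes must be positive")
        if not 0 <= self.target_lpdi_pct <= 60:
            raise ValueError("target_lpdi_pct must be in [0, 60]")
        if self.target_lpdi_pct > 0 and self.lesion_hu_offset >= 0:
            raise ValueError("lesion_hu_offset must be negative (lesions are hypodense)")
        if self.lesion_count < 0:
            raise ValueError("lesion_count must be non-negative")
        if self.noise_sd < 0 or self.blur_sigma_mm < 0:
            raise ValueError("noise_sd and blur_sigma_mm must be >= 0")

    @property
    def center_mm(self) -> np.ndarray:
        if self.liver_center is not None:
            return np.asarray(self.liver_center, dtype=float)
        return np.array(
            [self.grid_shape[ax] * self.spacing_mm[ax] / 2.0 for ax in range(3)]
        )


@dataclass(frozen=True)
class PhantomTruth:
    """Exact ground truth of one phantom (the masks used for painting)."""

    liver_mask: BinaryMask
    trauma_mask: BinaryMask
    liver_volume_ml: float
    trauma_volume_ml: float
    lpdi_pct: float
    pseudo_grade: int

    def volumetry(self, case_id: str = "") -> VolumetryResult:
        return VolumetryResult(case_id, self.liver_volume_ml,
                               self.trauma_volume_ml, self.lpdi_pct)


class PhantomCase(NamedTuple):
    ct: CTVolume
    truth: PhantomTruth
    record: CohortRecord
    spec: PhantomSpec | None = None


def _grade_from_lpdi(lpdi_pct: float) -> int:
    for grade in (5, 4, 3, 2):
        if lpdi_pct >= GRADE_LPDI_BANDS[grade][0]:
            return grade
    return 1


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@dataclass(frozen=True)
class _Lesion:
    kind: str                  # "ellipsoid" (hematoma) or "slab" (laceration)
    center: np.ndarray         # mm
    rotation: np.ndarray       # 3x3, columns = lesion axes
    size_mm: np.ndarray        # ellipsoid semi-axes, or (radius, radius, half-thickness)

    def contains(self, points: np.ndarray, scale: float) -> np.ndarray:
        u = (points - self.center) @ self.rotation  # lesion frame
        s = self.size_mm * scale
        if self.kind == "ellipsoid":
            return (u / s).__pow__(2).sum(axis=1) <= 1.0
        # slab: thin disc |u_z| <= half-thickness, lateral radius bound
        return (np.abs(u[:, 2]) <= s[2]) & (u[:, 0] ** 2 + u[:, 1] ** 2 <= s[0] ** 2)


def _liver_mask_array(spec: PhantomSpec) -> np.ndarray:
    cx, cy, cz = voxel_center_coords(spec.grid_shape, spec.spacing_mm)
    c = spec.center_mm
    a = np.asarray(spec.liver_semiaxes_mm)
    q = (
        ((cx - c[0]) / a[0])[:, None, None] ** 2
        + ((cy - c[1]) / a[1])[None, :, None] ** 2
        + ((cz - c[2]) / a[2])[None, None, :] ** 2
    )
    return q <= 1.0


def _check_fits(spec: PhantomSpec) -> None:
    c = spec.center_mm
    extent = np.array([spec.grid_shape[ax] * spec.spacing_mm[ax] for ax in range(3)])
    a = np.asarray(spec.liver_semiaxes_mm)
    if np.any(c - a < 0) or np.any(c + a > extent):
        raise GeometryError(
            f"liver ellipsoid (center {tuple(c)}, semi-axes {tuple(a)}) exceeds "
            f"grid physical extent {tuple(extent)}"
        )


def _draw_lesions(spec: PhantomSpec, rng: np.random.Generator,
                  liver_points: np.ndarray) -> list[_Lesion]:
    # lesion seeds sit in the liver interior (normalized ellipsoid radius <= 0.8)
    c = spec.center_mm
    a = np.asarray(spec.liver_semiaxes_mm)
    r2 = ((liver_points - c) / a).__pow__(2).sum(axis=1)
    interior = liver_points[r2 <= 0.8**2]
    lesions = []
    for _ in range(spec.lesion_count):
        center = interior[rng.integers(len(interior))]
        rot = _random_rotation(rng)
        if rng.random() < 0.35:
            radius = rng.uniform(12.0, 30.0)
            half_thickness = rng.uniform(1.5, 4.0)
            size = np.array([radius, radius, half_thickness])
            kind = "slab"
        else:
            size = rng.uniform(5.0, 14.0, size=3)
            kind = "ellipsoid"
        lesions.append(_Lesion(kind, center, rot, size))
    return lesions


def _trauma_count(lesions, points, scale) -> np.ndarray:
    inside = np.zeros(len(points), dtype=bool)
    for les in lesions:
        inside |= les.contains(points, scale)
    return inside


def _target_lesion_scale(lesions, points, n_liver, target_pct) -> tuple[float, np.ndarray]:
    """Bisection on a global lesion-size scale until the trauma/liver voxel
    ratio enters the +/-1.5 pp band around the target."""
    def ratio(s):
        m = _trauma_count(lesions, points, s)
        return 100.0 * m.sum() / n_liver, m

    lo, hi = 1e-3, 1.0
    r_hi, m_hi = ratio(hi)
    grow = 0
    while r_hi < target_pct and grow < 40:
        lo = hi
        hi *= 1.35
        r_hi, m_hi = ratio(hi)
        grow += 1
    best = (abs(r_hi - target_pct), hi, m_hi)
    for _ in range(45):
        mid = 0.5 * (lo + hi)
        r_mid, m_mid = ratio(mid)
        if abs(r_mid - target_pct) < best[0]:
            best = (abs(r_mid - target_pct), mid, m_mid)
        if r_mid < target_pct:
            lo = mid
        else:
            hi = mid
        if best[0] <= 0.1:
            break
    err, scale, mask = best
    if err > _LPDI_TOL_PP:
        raise RuntimeError(
            f"could not reach target LPDI within {_LPDI_TOL_PP} pp "
            f"(target {target_pct}, best error {err:.2f} pp)"
        )
    return scale, mask


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, PhantomTruth]:
    """Generate one phantom volume plus its exact ground truth.

    The truth masks are the exact voxelizations used to paint the volume
    (before blur/noise).  Identical spec (including seed) reproduces
    bit-identical output.
    """
    _check_fits(spec)
    if spec.target_lpdi_pct > 0 and spec.lesion_count == 0:
        raise ValueError("target_lpdi_pct > 0 is unreachable with lesion_count = 0")

    rng = np.random.default_rng(spec.seed)
    liver = _liver_mask_array(spec)
    n_liver = int(liver.sum())
    if n_liver == 0:
        raise GeometryError("liver ellipsoid voxelizes to an empty mask")

    trauma = np.zeros(spec.grid_shape, dtype=bool)
    if spec.target_lpdi_pct > 0 and spec.lesion_count > 0:
        cx, cy, cz = voxel_center_coords(spec.grid_shape, spec.spacing_mm)
        ii, jj, kk = np.nonzero(liver)
        liver_points = np.column_stack([cx[ii], cy[jj], cz[kk]])
        lesions = _draw_lesions(spec, rng, liver_points)
        _, inside = _target_lesion_scale(
            lesions, liver_points, n_liver, spec.target_lpdi_pct
        )
        trauma[ii[inside], jj[inside], kk[inside]] = True

    vol = np.full(spec.grid_shape, spec.background_hu, dtype=np.float32)
    vol[liver] = spec.liver_hu
    vol[trauma] = spec.liver_hu + spec.lesion_hu_offset
    if spec.blur_sigma_mm > 0:
        sigma_vox = [spec.blur_sigma_mm / s for s in spec.spacing_mm]
        vol = ndimage.gaussian_filter(vol, sigma=sigma_vox).astype(np.float32)
    if spec.noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd, spec.grid_shape).astype(np.float32)

    uv = unit_voxel_volume_ml(spec.spacing_mm)
    liver_ml = n_liver * uv
    trauma_ml = int(trauma.sum()) * uv
    lpdi = compute_lpdi(trauma_ml, liver_ml) if trauma_ml > 0 else 0.0
    truth = PhantomTruth(
        liver_mask=BinaryMask(liver, spec.spacing_mm),
        trauma_mask=BinaryMask(trauma, spec.spacing_mm),
        liver_volume_ml=liver_ml,
        trauma_volume_ml=trauma_ml,
        lpdi_pct=lpdi,
        pseudo_grade=_grade_from_lpdi(lpdi),
    )
    ct = CTVolume(vol, spec.spacing_mm)
    return ct, truth


_LESION_COUNT_BY_GRADE = {1: 1, 2: 2, 3: 2, 4: 3, 5: 4}


def generate_cohort(n_cases: int, grade_mix, base_spec: PhantomSpec | None = None,
                    seed: int = 0) -> list[PhantomCase]:
    """Generate a graded cohort of phantoms.

    Each case draws a pseudo-grade from ``grade_mix`` (proportions over
    grades I-V), a target LPDI uniformly from that grade's band, and a
    jittered liver geometry; everything is deterministic under a fixed seed.
    The returned records carry the exact truth volumetry as the reference
    measurement; automated volumetry is filled in by the pipeline.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    mix = np.asarray(grade_mix, dtype=float)
    if mix.shape != (5,) or np.any(mix < 0) or not np.isclose(mix.sum(), 1.0):
        raise ValueError("grade_mix must be 5 non-negative proportions summing to 1")
    base = base_spec if base_spec is not None else PhantomSpec()

    rng = np.random.default_rng(seed)
    cases: list[PhantomCase] = []
    for i in range(n_cases):
        grade = int(rng.choice(np.arange(1, 6), p=mix))
        lo, hi = GRADE_LPDI_BANDS[grade]
        target = float(rng.uniform(lo, hi))
        semiaxes = tuple(np.asarray(base.liver_semiaxes_mm) * rng.uniform(0.85, 1.15, 3))
        center = tuple(base.center_mm + rng.uniform(-5.0, 5.0, 3))
        lesion_count = _LESION_COUNT_BY_GRADE[grade] + int(rng.integers(0, 2))
        case_seed = int(rng.integers(0, 2**31))
        spec = replace(
            base,
            liver_semiaxes_mm=semiaxes,
            liver_center=center,
            target_lpdi_pct=target,
            lesion_count=lesion_count,
            seed=case_seed,
        )
        ct, truth = generate_phantom(spec)
        truth = replace(truth, pseudo_grade=grade)
        case_id = f"case_{i:03d}"
        ct = replace(ct, case_id=case_id)
        record = CohortRecord(
            case_id=case_id,
            aast_grade=grade,
            reference_volumetry=truth.volumetry(case_id),
        )
        cases.append(PhantomCase(ct, truth, record, spec))
    return cases


def save_cohort(cases: list[PhantomCase], out_dir) -> Path:
    """Write volumes/masks as NIfTI and the truth table as CSV.

    Returns the path of the truth table.  Layout: ``<case_id>_ct.nii.gz``,
    ``<case_id>_liver.nii.gz``, ``<case_id>_trauma.nii.gz``, ``truth.csv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        ct, truth, record = case.ct, case.truth, case.record
        write_volume(ct, out / f"{record.case_id}_ct.nii.gz")
        write_mask(truth.liver_mask, out / f"{record.case_id}_liver.nii.gz")
        write_mask(truth.trauma_mask, out / f"{record.case_id}_trauma.nii.gz")
        rows.append({
            "case_id": record.case_id,
            "pseudo_grade": truth.pseudo_grade,
            "liver_volume_ml": truth.liver_volume_ml,
            "trauma_volume_ml": truth.trauma_volume_ml,
            "lpdi_pct": truth.lpdi_pct,
            "seed": case.spec.seed if case.spec is not None else "",
        })
    table = out / "truth.csv"
    pd.DataFrame(rows).to_csv(table, index=False)
    return table
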