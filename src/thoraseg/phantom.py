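"""Seeded synthetic thoracic CT phantoms with exact ground-truth masks.

Each phantom volume emulates the gross radiological layout of an axial chest
acquisition: a soft-tissue body ellipse surrounded by air, two low-density
lung fields, a very-low-density central airway (trachea plus short main
bronchi entering the lungs medially), a few bright vessel-like disks in the
hilum region, and optional well-defined higher-density nodules, some of which
abut the pleural border.  Every structure comes with an exact binary mask, so
downstream correction, augmentation, training and evaluation code can be
exercised without any clinical data.

Besides the coherent ground truth, each case carries an "original-protocol"
lung mask reproducing the kind of annotation defect found in public cohorts:
nodules carved out of the lung label, the trachea merged into it, or both
plus vessel-shaped holes (an automatic-segmentation artefact).  Dataset
profiles bundle a protocol with per-cohort voxel spacings so that a mixed
training set with heterogeneous geometry and label noise can be synthesised
from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .ct_io import CTVolume, MaskSet
from .errors import ConfigurationError, PlacementError

__all__ = [
    "PhantomSpec",
    "PhantomCase",
    "DATASET_PROFILES",
    "generate_case",
    "generate_dataset_profile",
]

PROTOCOLS = ("coherent", "nodules_excluded", "trachea_included", "auto_noisy")


@dataclass
class PhantomSpec:
    """Parameters of one synthetic thoracic case.

    HU defaults: lung parenchyma −900..−700 (aerated tissue), body soft
    tissue −60..80, airway lumen −1000 (air), nodules −50..100 (solid,
    clearly denser than parenchyma).  Gaussian texture noise sigma 30 HU.
    """

    shape: tuple[int, int, int] = (6, 128, 128)
    spacing: tuple[float, float, float] = (2.5, 1.0, 1.0)
    lung_hu_range: tuple[float, float] = (-900.0, -700.0)
    body_hu_range: tuple[float, float] = (-60.0, 80.0)
    airway_hu: float = -1000.0
    n_nodules: int = 2
    nodule_diameter_range: tuple[float, float] = (8.0, 20.0)
    nodule_hu_range: tuple[float, float] = (-50.0, 100.0)
    peripheral_fraction: float = 0.3
    noise_sigma: float = 30.0
    protocol: str = "coherent"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lung_hu_range[1] >= self.body_hu_range[0]:
            raise ConfigurationError("lung HU range must lie entirely below body HU range")
        if self.nodule_hu_range[0] <= self.lung_hu_range[1]:
            raise ConfigurationError("nodule HU range must lie above lung HU range")
        if not 0.0 <= self.peripheral_fraction <= 1.0:
            raise ConfigurationError("peripheral_fraction must be in [0, 1]")
        if self.protocol not in PROTOCOLS:
            raise ConfigurationError(f"unknown protocol {self.protocol!r}; choose from {PROTOCOLS}")
        if self.n_nodules < 0:
            raise ConfigurationError("n_nodules must be >= 0")


@dataclass
class PhantomCase:
    """A generated volume with coherent truth and protocol-defective masks."""

    volume: CTVolume
    truth: MaskSet
    original_masks: MaskSet
    spec: PhantomSpec | None = None


# Per-cohort profiles: (z, y, x) spacing near the published per-cohort means
# (slice thickness, in-plane pixel spacing) and the annotation-protocol defect
# characteristic of that cohort's original masks.
DATASET_PROFILES: dict[str, dict] = {
    # tumour cohort whose protocol excludes main bronchus and tumour masses
    "lctsc": dict(spacing=(2.65, 1.02, 1.02), protocol="nodules_excluded", n_nodules=2),
    # nodule-screening cohort with automatically generated masks
    "luna16": dict(spacing=(1.60, 0.69, 0.69), protocol="auto_noisy", n_nodules=3),
    # interstitial-disease cohort, undisclosed protocol; airway left in
    "hug_ild": dict(spacing=(1.00, 0.70, 0.70), protocol="trachea_included", n_nodules=0, noise_sigma=45.0),
    # vessel-segmentation cohort, automatic masks, mostly nodule-free
    "vessel12": dict(spacing=(0.88, 0.74, 0.74), protocol="trachea_included", n_nodules=0),
    # clinical lung-cancer cohort with an already coherent protocol
    "chusj": dict(spacing=(3.07, 0.71, 0.71), protocol="coherent", n_nodules=3),
}


def _ellipsoid(shape, center, radii) -> np.ndarray:
    """Binary ellipsoid; radii in voxels, any radius np.inf extrudes that axis."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, r in zip(grids, center, radii):
        if np.isinf(r):
            continue
        acc = acc + ((g - c) / r) ** 2
    return acc <= 1.0


def _sphere_mm(shape, spacing, center, diameter_mm) -> np.ndarray:
    radii = tuple((diameter_mm / 2.0) / s for s in spacing)
    return _ellipsoid(shape, center, radii)


def _capsule2d(h, w, p0, p1, radius) -> np.ndarray:
    """In-plane thick line segment (stadium shape) between two (y, x) points."""
    yy, xx = np.mgrid[0:h, 0:w]
    p0 = np.asarray(p0, dtype=float)
    d = np.asarray(p1, dtype=float) - p0
    denom = float(d @ d)
    if denom == 0.0:
        t = np.zeros((h, w))
    else:
        t = np.clip(((yy - p0[0]) * d[0] + (xx - p0[1]) * d[1]) / denom, 0.0, 1.0)
    cy = p0[0] + t * d[0]
    cx = p0[1] + t * d[1]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


# in-plane 4-connected structuring element embedded in 3D (no z coupling),
# so erosions on thin-z volumes do not wipe out the apical/basal slices
_INPLANE = np.zeros((3, 3, 3), dtype=bool)
_INPLANE[1] = [[0, 1, 0], [1, 1, 1], [0, 1, 0]]


def _inplane_erosion(mask: np.ndarray, width: int) -> np.ndarray:
    from scipy import ndimage

    return ndimage.binary_erosion(mask, structure=_INPLANE, iterations=width)


def _lung_border_band(lung: np.ndarray, width: int = 2) -> np.ndarray:
    return lung & ~_inplane_erosion(lung, width)


def generate_case(spec: PhantomSpec) -> PhantomCase:
    """Generate one phantom case; deterministic for a fixed ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    nz, h, w = spec.shape
    zc, yc, xc = (nz - 1) / 2.0, (h - 1) / 2.0, (w - 1) / 2.0

    # --- geometry (boolean scaffolds) -------------------------------------
    body = _ellipsoid(spec.shape, (zc, yc, xc), (np.inf, 0.40 * h, 0.46 * w))
    lungs = np.zeros(spec.shape, dtype=bool)
    for side in (-1.0, +1.0):
        lungs |= _ellipsoid(
            spec.shape,
            (zc, yc - 0.02 * h, xc + side * 0.22 * w),
            (0.95 * (nz / 2.0 + 0.5), 0.27 * h, 0.155 * w),
        )
    lungs &= body

    # central airway: trachea extruded through all slices plus short main
    # bronchi angling into the medial lung border (carved, so in-slice the
    # carved channel stays connected to the mediastinal background)
    trachea_c = (yc - 0.16 * h, xc)
    airway2d_list = []
    for k in range(nz):
        a = _capsule2d(h, w, trachea_c, trachea_c, 0.030 * w)
        if k >= nz // 2:  # bronchi present on the caudal half
            for side in (-1.0, +1.0):
                tip = (yc + 0.02 * h, xc + side * 0.13 * w)
                a |= _capsule2d(h, w, trachea_c, tip, 0.018 * w)
        airway2d_list.append(a)
    airway = np.stack(airway2d_list) & body

    lung_field = lungs & ~airway

    # hilar vessels: bright disks just lateral to the medial lung border,
    # strictly interior to the lung field in-slice and clear of the airway,
    # so a vessel-shaped annotation hole is always an enclosed hole
    from scipy import ndimage

    vessels = np.zeros(spec.shape, dtype=bool)
    for side in (-1.0, +1.0):
        for dy in (-0.05 * h, 0.06 * h):
            vessels |= _ellipsoid(
                spec.shape,
                (zc, yc + dy, xc + side * 0.115 * w),
                (np.inf, 0.016 * h, 0.016 * w),
            )
    vessels &= _inplane_erosion(lung_field, 2)
    vessels &= ~ndimage.binary_dilation(airway, structure=_INPLANE, iterations=2)

    # --- nodules ----------------------------------------------------------
    nodules: list[np.ndarray] = []
    n_peripheral = int(round(spec.peripheral_fraction * spec.n_nodules))
    placed_union = np.zeros(spec.shape, dtype=bool)
    border = _lung_border_band(lung_field, width=2)
    interior = lung_field & ~_lung_border_band(lung_field, width=3)
    for i in range(spec.n_nodules):
        peripheral = i < n_peripheral
        pool = np.argwhere(border if peripheral else interior)
        if pool.size == 0:
            raise PlacementError("lung field too small to host a nodule")
        ok = False
        for _ in range(500):
            d = rng.uniform(*spec.nodule_diameter_range)
            center = pool[rng.integers(len(pool))]
            cand = _sphere_mm(spec.shape, spec.spacing, center, d) & body
            if not cand.any():
                continue
            if (cand & airway).any() or (cand & placed_union).any() or (cand & vessels).any():
                continue
            inside = (cand & lung_field).sum() / cand.sum()
            if not peripheral and inside < 0.999:
                continue
            if peripheral and inside < 0.35:
                continue
            nodules.append(cand)
            placed_union |= cand
            ok = True
            break
        if not ok:
            raise PlacementError(
                f"could not place nodule {i} after bounded retries "
                f"(diameter range {spec.nodule_diameter_range} mm)"
            )

    truth_lung = (lung_field | placed_union) & ~airway

    # --- HU rendering -----------------------------------------------------
    hu = np.full(spec.shape, -1000.0)
    hu[body] = rng.uniform(*spec.body_hu_range)
    hu[lung_field] = rng.uniform(*spec.lung_hu_range)
    hu[vessels] = rng.uniform(30.0, 90.0)
    hu[airway] = spec.airway_hu
    for nod in nodules:
        hu[nod] = rng.uniform(*spec.nodule_hu_range)
    hu += rng.normal(0.0, spec.noise_sigma, size=spec.shape)
    hu = np.clip(np.rint(hu), -1024, 3071).astype(np.int16)

    case_id = f"phantom-{spec.protocol}-{spec.seed}"
    volume = CTVolume(voxels=hu, spacing=spec.spacing, id=case_id)
    truth = MaskSet(
        lung=truth_lung,
        airway=airway,
        nodules=[n.copy() for n in nodules],
        grid_id=case_id,
    )

    # --- original-protocol (defective) masks -------------------------------
    orig_lung = truth_lung.copy()
    if spec.protocol in ("nodules_excluded", "auto_noisy"):
        orig_lung = orig_lung & ~placed_union
    if spec.protocol in ("trachea_included", "auto_noisy"):
        orig_lung = orig_lung | airway
    if spec.protocol == "auto_noisy":
        orig_lung = orig_lung & ~vessels
    original = MaskSet(
        lung=orig_lung,
        airway=airway,
        nodules=[n.copy() for n in nodules],
        grid_id=case_id,
    )
    return PhantomCase(volume=volume, truth=truth, original_masks=original, spec=spec)


def generate_dataset_profile(
    name: str,
    n_cases: int,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
) -> list[PhantomCase]:
    """Generate ``n_cases`` phantoms with a named cohort profile.

    The profile fixes voxel spacing near the cohort's published mean and the
    annotation defect of its original mask protocol; case seeds are derived
    from ``seed`` so the whole dataset is reproducible.
    """
    key = name.lower().replace("-", "_")
    if key not in DATASET_PROFILES:
        raise ConfigurationError(
            f"unknown dataset profile {name!r}; choose from {sorted(DATASET_PROFILES)}"
        )
    if n_cases < 1:
        raise ConfigurationError("n_cases must be >= 1")
    profile = DATASET_PROFILES[key]
    base = base_spec if base_spec is not None else PhantomSpec()
    seeds = np.random.SeedSequence(seed).generate_state(n_cases) % (2**31)
    cases = []
    for i, s in enumerate(seeds):
        spec = replace(base, seed=int(s), **profile)
        case = generate_case(spec)
        case.volume.id = f"{key}-{i:03d}"
        case.truth.grid_id = case.volume.id
        case.original_masks.grid_id = case.volume.id
        cases.append(case)
    return cases
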