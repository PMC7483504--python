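"""Ground-truth phantoms for peri-implant bone-graft volumetry.

Seven study geometries are provided:

* ``R`` — a concentric-cylinder model: a titanium implant (4.1 x 10 mm)
  inside an outer cylinder whose annular gap is filled with graft material;
  the annulus is sized analytically so the designed graft volume is
  928.44 mm^3.
* ``S1`` / ``S2`` — curved-ridge models imitating an augmented alveolar
  ridge with an implant through it; ``S1`` is convex-dominated
  (954.77 mm^3), ``S2`` carries a lateral concavity (404.82 mm^3).
* ``BD5-1.5``, ``BD5-3``, ``BD6-1.5``, ``BD6-3`` — cylindrical trephine
  defects (5 or 6 mm diameter, 8 mm deep) in a bone block, grafted, with a
  parallel implant 1.5 or 3 mm away.  The volume of interest is the middle
  5 mm of the defect (top 1 mm and bottom 2 mm excluded).

All phantoms are generated with the graft/implant principal axis along
grid axis 0 (the slice-stack normal); mounting plates tilt that axis by
15-35 degrees via :func:`mount_at_angle`.

Voxel membership rule: a voxel belongs to a shape iff its *center* lies
inside the analytic surface (half-open intervals along the axis).  Voxel
centers sit at half-spacing offsets from the analytic reference planes so
that no center falls exactly on a boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import scipy.ndimage as ndi

from .errors import ConvergenceError, InvalidSpecError, ResolutionError
from .grid import BACKGROUND, BONE, GRAFT, IMPLANT, VoxelGrid

# Designed graft volumes (mm^3) and fabrication-error budgets (percent) of
# the three bench models.
DESIGNED_VOLUMES = {"R": 928.44, "S1": 954.77, "S2": 404.82}
FABRICATION_ERROR_PCT = {"R": 0.24, "S1": 0.31, "S2": 0.40}

MODEL_NAMES = ("R", "S1", "S2", "BD5-1.5", "BD5-3", "BD6-1.5", "BD6-3")
IN_VITRO = ("R", "S1", "S2")
EX_VIVO = ("BD5-1.5", "BD5-3", "BD6-1.5", "BD6-3")


@dataclass
class PhantomSpec:
    """Parametric description of one graft/implant geometry."""

    name: str
    kind: str  # concentric_cylinder | complex_ridge | exvivo_defect
    implant_diameter: float
    implant_length: float
    graft_params: dict = field(default_factory=dict)
    voi_top_exclusion: float = 0.0
    voi_bottom_exclusion: float = 0.0
    mount_angle: float = 0.0

    def __post_init__(self):
        if self.kind not in ("concentric_cylinder", "complex_ridge", "exvivo_defect"):
            raise InvalidSpecError(f"unknown phantom kind {self.kind!r}")
        if self.kind == "exvivo_defect":
            d = self.graft_params.get("defect_diameter")
            if d not in (5.0, 6.0):
                raise InvalidSpecError("defect diameter must be 5 or 6 mm")
            if self.graft_params.get("depth") != 8.0:
                raise InvalidSpecError("defect depth must be 8 mm")
            if self.graft_params.get("offset") not in (1.5, 3.0):
                raise InvalidSpecError("implant offset must be 1.5 or 3 mm")


@dataclass
class TruthRecord:
    """Ground-truth volume bookkeeping for one phantom.

    ``analytic_volume`` is the closed-form volume (mm^3) where one exists
    (annulus, defect cylinder VOI); ``voxel_volume`` is the voxel-count
    volume of the generated graft label.  ``fabrication_error_pct`` is the
    printed-model error budget and plays no role in the synthetic truth
    unless surface jitter is explicitly enabled.
    """

    analytic_volume: Optional[float]
    voxel_volume: float
    fabrication_error_pct: Optional[float] = None

    def __post_init__(self):
        if not (self.voxel_volume > 0 and np.isfinite(self.voxel_volume)):
            raise InvalidSpecError("truth volume must be strictly positive and finite")


def _centers(n_lo_mm: float, n_hi_mm: float, spacing: float) -> np.ndarray:
    """Voxel-center coordinates covering [lo, hi) at half-spacing offsets."""
    n = int(math.ceil((n_hi_mm - n_lo_mm) / spacing))
    return n_lo_mm + (np.arange(n) + 0.5) * spacing


def _make_grid(xc, yc, zc, spacing) -> VoxelGrid:
    data = np.zeros((len(xc), len(yc), len(zc)), dtype=np.uint8)
    origin = np.array([xc[0], yc[0], zc[0]])
    return VoxelGrid(data, spacing, origin)


# ---------------------------------------------------------------------------
# Concentric-cylinder model (R)


def build_concentric_cylinder(
    outer_diameter: float,
    graft_height: float,
    implant_diameter: float = 4.1,
    implant_length: float = 10.0,
    spacing: float = 0.25,
    wall: float = 1.5,
) -> tuple[VoxelGrid, TruthRecord]:
    """Voxelize an implant-in-annulus phantom.

    The graft occupies the annulus ``ri <= rho < Ro`` over ``0 <= x < h``;
    the implant the cylinder ``rho < ri`` over ``0 <= x < L``.  The
    surrounding model body (radius ``Ro + wall``) is labelled as bone-like
    material.  Returns the label grid and a :class:`TruthRecord` holding
    both the analytic annulus volume and the voxel-count volume.
    """
    if min(outer_diameter, graft_height, implant_diameter, implant_length) <= 0:
        raise InvalidSpecError("all cylinder dimensions must be positive")
    if outer_diameter <= implant_diameter:
        raise InvalidSpecError("outer cylinder must be wider than the implant")
    ri = implant_diameter / 2.0
    ro = outer_diameter / 2.0
    if spacing > ri or spacing > ro:
        raise ResolutionError(f"spacing {spacing} mm cannot resolve radii {ri}/{ro} mm")

    rm = ro + wall
    pad = 1.0
    hmax = max(graft_height, implant_length)
    xc = _centers(-pad - wall, hmax + pad + wall, spacing)
    yc = _centers(-rm - pad, rm + pad, spacing)
    zc = _centers(-rm - pad, rm + pad, spacing)
    grid = _make_grid(xc, yc, zc, spacing)
    X = xc[:, None, None]
    R2 = (yc[None, :, None] ** 2) + (zc[None, None, :] ** 2)

    body = (R2 < rm**2) & (X >= -wall) & (X < hmax + wall)
    implant = (R2 < ri**2) & (X >= 0) & (X < implant_length)
    graft = (R2 >= ri**2) & (R2 < ro**2) & (X >= 0) & (X < graft_height)
    grid.data[body] = BONE
    grid.data[graft] = GRAFT
    grid.data[implant] = IMPLANT

    analytic = math.pi * (ro**2 - ri**2) * graft_height
    voxel = int(graft.sum()) * spacing**3
    return grid, TruthRecord(analytic, voxel)


def annulus_outer_diameter(
    target_volume: float, graft_height: float, implant_diameter: float = 4.1
) -> float:
    """Outer diameter for which the annulus volume equals ``target_volume``."""
    ri = implant_diameter / 2.0
    return 2.0 * math.sqrt(target_volume / (math.pi * graft_height) + ri**2)


# ---------------------------------------------------------------------------
# Curved-ridge models (S1 / S2)

_RIDGE_SEMI_AXES = np.array([5.0, 6.5, 5.5])  # (x, y, z) mm at unit scale


def _ridge_mask(
    s: float, concave: bool, phases: np.ndarray, implant_radius: float, spacing: float
):
    """Graft mask of the ridge at scale ``s`` plus its coordinate arrays."""
    a, b, c = _RIDGE_SEMI_AXES * s
    lim = max(a, b, c) * 1.15 + 1.0
    xc = _centers(-lim, lim, spacing)
    yc = _centers(-lim, lim, spacing)
    zc = _centers(-lim, lim, spacing)
    X = xc[:, None, None]
    Y = yc[None, :, None]
    Z = zc[None, None, :]
    re = np.sqrt((X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2)
    # Smooth low-order radial modulation: the seeded "clinical case" shape.
    theta = np.arctan2(Z, Y)
    mod = 1.0 + 0.10 * np.sin(2 * theta + phases[0]) * np.cos(
        np.pi * X / (2 * a) + phases[1]
    )
    inside = re < mod
    if concave:
        # Lateral scoop producing a concave flank.
        cy, cz = 0.85 * b, 0.35 * c
        r_scoop = 0.60 * min(b, c)
        d2 = (X - 0.0) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2
        inside &= d2 > r_scoop**2
    hole = (Y**2 + Z**2) < implant_radius**2
    graft = inside & ~hole
    return graft, hole, (xc, yc, zc)


def build_complex_ridge(
    seed: int,
    concave: bool,
    target_volume: float,
    spacing: float = 0.25,
    implant_diameter: float = 4.1,
    implant_length: float = 10.0,
    tol: float = 0.002,
    max_iter: int = 60,
) -> tuple[VoxelGrid, TruthRecord]:
    """Voxelize a curved-ridge graft scaled to a target volume.

    A seeded smooth radial modulation makes each seed a distinct but
    reproducible "clinical" shape; ``concave=True`` scoops a lateral
    concavity (S2-like).  A uniform scale factor is bisected until the
    graft voxel volume is within ``tol`` of ``target_volume`` (the
    guaranteed bound is 2 %; convergence beyond that raises
    :class:`ConvergenceError` with the achieved volume).
    """
    if target_volume <= 0:
        raise InvalidSpecError("target volume must be positive")
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0, 2 * math.pi, size=2)
    ri = implant_diameter / 2.0

    def vol(s: float) -> float:
        graft, _, _ = _ridge_mask(s, concave, phases, ri, spacing)
        return int(graft.sum()) * spacing**3

    lo, hi = 0.3, 2.5
    vlo, vhi = vol(lo), vol(hi)
    if not (vlo < target_volume < vhi):
        raise ConvergenceError(
            f"target {target_volume} mm^3 outside reachable range", vlo
        )
    s = 1.0
    v = vol(s)
    for _ in range(max_iter):
        if abs(v - target_volume) / target_volume <= tol:
            break
        if v < target_volume:
            lo = s
        else:
            hi = s
        s = 0.5 * (lo + hi)
        v = vol(s)
    if abs(v - target_volume) / target_volume > 0.02:
        raise ConvergenceError(
            f"ridge scaling stalled at {v:.2f} mm^3 (target {target_volume})", v
        )

    graft, hole, (xc, yc, zc) = _ridge_mask(s, concave, phases, ri, spacing)
    grid = _make_grid(xc, yc, zc, spacing)
    X = xc[:, None, None]
    implant = hole & (X >= -implant_length / 2) & (X < implant_length / 2)
    grid.data[graft] = GRAFT
    grid.data[implant] = IMPLANT
    return grid, TruthRecord(None, int(graft.sum()) * spacing**3)


# ---------------------------------------------------------------------------
# Ex-vivo trephine-defect models (BD*)


def build_exvivo_defect(
    defect_diameter: float,
    offset: float,
    implant_diameter: float = 3.3,
    implant_length: float = 10.0,
    spacing: float = 0.25,
    voi_top_exclusion: float = 1.0,
    voi_bottom_exclusion: float = 2.0,
) -> tuple[VoxelGrid, TruthRecord, PhantomSpec]:
    """Voxelize a grafted cylindrical defect next to a parallel implant.

    The defect axis runs along grid axis 0, from the bone crest at x = 0 mm
    to 8 mm depth; the implant axis is parallel, ``offset`` mm of bone away
    (surface-to-surface).  The bone block is the textured background the
    graft cylinder is embedded in.  ``TruthRecord.analytic_volume`` refers
    to the middle-5-mm VOI portion of the defect.
    """
    if defect_diameter not in (5.0, 6.0):
        raise InvalidSpecError("defect diameter must be 5 or 6 mm")
    if offset not in (1.5, 3.0):
        raise InvalidSpecError("implant offset must be 1.5 or 3 mm")
    depth = 8.0
    rd = defect_diameter / 2.0
    ri = implant_diameter / 2.0
    dcc = rd + offset + ri  # defect-center to implant-center distance
    if dcc <= rd + ri:
        raise InvalidSpecError("defect and implant volumes overlap")

    pad = 1.5
    xc = _centers(-pad, implant_length + pad, spacing)
    yc = _centers(-rd - 2.5, dcc + ri + 2.5, spacing)
    zc = _centers(-rd - 2.5, rd + 2.5, spacing)
    grid = _make_grid(xc, yc, zc, spacing)
    X = xc[:, None, None]
    Y = yc[None, :, None]
    Z = zc[None, None, :]

    bone = np.broadcast_to(X >= 0, grid.shape)  # bone block below the crest plane
    graft = (Y**2 + Z**2 < rd**2) & (X >= 0) & (X < depth)
    implant = ((Y - dcc) ** 2 + Z**2 < ri**2) & (X >= 0) & (X < implant_length)
    grid.data[bone] = BONE
    grid.data[graft] = GRAFT
    grid.data[implant] = IMPLANT

    voi_height = depth - voi_top_exclusion - voi_bottom_exclusion
    analytic_voi = math.pi * rd**2 * voi_height
    voxel = int(graft.sum()) * spacing**3
    spec = PhantomSpec(
        name=f"BD{int(defect_diameter)}-{offset:g}",
        kind="exvivo_defect",
        implant_diameter=implant_diameter,
        implant_length=implant_length,
        graft_params={
            "defect_diameter": defect_diameter,
            "depth": depth,
            "offset": offset,
            "crest_x": 0.0,
        },
        voi_top_exclusion=voi_top_exclusion,
        voi_bottom_exclusion=voi_bottom_exclusion,
    )
    return grid, TruthRecord(analytic_voi, voxel), spec


# ---------------------------------------------------------------------------
# Mounting


def mount_at_angle(grid: VoxelGrid, angle: float, axes: tuple = (0, 2)) -> VoxelGrid:
    """Rigidly tilt a label grid by ``angle`` degrees about a horizontal axis.

    Nearest-neighbour label resampling onto an enlarged grid; ``axes`` names
    the in-plane pair the rotation turns (default: the stack axis is tilted
    toward z, i.e. rotation about y).  Label counts are preserved to within
    about one percent.
    """
    if not (0 <= angle < 90):
        raise InvalidSpecError("mounting angle must satisfy 0 <= angle < 90 degrees")
    if angle == 0:
        return grid.copy()
    rot = ndi.rotate(
        grid.data, angle, axes=axes, reshape=True, order=0, mode="constant", cval=0,
        prefilter=False,
    )
    return VoxelGrid(rot.astype(grid.data.dtype), grid.spacing, np.zeros(3))


# ---------------------------------------------------------------------------
# Model registry


def build_model(name: str, spacing: float = 0.25):
    """Build one of the seven named study phantoms.

    Returns ``(grid, truth, spec)``.  Ridge geometry seeds are fixed study
    conditions (seed 1), so repeated builds are bit-identical.
    """
    if name == "R":
        height = 10.0
        outer = annulus_outer_diameter(DESIGNED_VOLUMES["R"], height)
        grid, truth = build_concentric_cylinder(outer, height, spacing=spacing)
        truth.fabrication_error_pct = FABRICATION_ERROR_PCT["R"]
        spec = PhantomSpec(
            "R",
            "concentric_cylinder",
            implant_diameter=4.1,
            implant_length=10.0,
            graft_params={"outer_diameter": outer, "graft_height": height},
        )
        return grid, truth, spec
    if name in ("S1", "S2"):
        concave = name == "S2"
        grid, truth = build_complex_ridge(
            seed=1, concave=concave, target_volume=DESIGNED_VOLUMES[name], spacing=spacing
        )
        truth.fabrication_error_pct = FABRICATION_ERROR_PCT[name]
        spec = PhantomSpec(
            name,
            "complex_ridge",
            implant_diameter=4.1,
            implant_length=10.0,
            graft_params={"seed": 1, "concave": concave,
                          "target_volume": DESIGNED_VOLUMES[name]},
        )
        return grid, truth, spec
    if name in EX_VIVO:
        dia = 5.0 if name.startswith("BD5") else 6.0
        offset = 1.5 if name.endswith("1.5") else 3.0
        grid, truth, spec = build_exvivo_defect(dia, offset, spacing=spacing)
        return grid, truth, spec
    raise InvalidSpecError(f"unknown model {name!r}; choose one of {MODEL_NAMES}")
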