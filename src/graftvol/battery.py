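"""The desk-scale validation protocol.

For each of the seven study phantoms:

1. generate the truth label grid at 0.25 mm isotropic spacing (bench
   models additionally mounted at 15/25/35 degrees);
2. corrupt it into a CBCT-like intensity volume with the default metal
   artifact model and score per-slice artifact severities;
3. run the interpolation arm (artifact-aware sparse tracing + MCI gap
   filling, max_gap 5) and, optionally, the emulated manual arm, five
   repeats by two raters each, recording the across-rater mean per repeat;
4. pool repeats over mounting angles (bench models) and summarize volumes,
   CV, systematic and relative systematic error against the phantom's
   truth volume (the cylinder VOI truth for the trephine-defect phantoms).

All randomness is derived from one master seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import annotation, cbct_sim, mci_core, phantoms, surface_eval, volumetrics
from .grid import GRAFT, IMPLANT, VoxelGrid

DEFAULT_ANGLES = (15.0, 25.0, 35.0)
STACK_AXIS = 0


def default_artifact_model(seed: int = 0) -> cbct_sim.ArtifactModel:
    """The study's default artifact conditions (only the seed varies)."""
    return cbct_sim.ArtifactModel(seed=seed)


def voi_for(spec: phantoms.PhantomSpec, truth_grid: VoxelGrid):
    """Physical VOI along the stack axis for a phantom, or "all"."""
    if spec.kind != "exvivo_defect":
        return "all"
    x0 = spec.graft_params["crest_x"]
    depth = spec.graft_params["depth"]
    return (x0 + spec.voi_top_exclusion, x0 + depth - spec.voi_bottom_exclusion)


def truth_mask(grid: VoxelGrid) -> VoxelGrid:
    return VoxelGrid((grid.data == GRAFT).astype(np.uint8), grid.spacing,
                     grid.origin.copy())


def mci_measure(
    truth: VoxelGrid,
    severities,
    voi,
    max_gap: int = 5,
    jitter_seed: int | None = None,
    axis: int = STACK_AXIS,
) -> float:
    """One interpolation-arm measurement: select slices, trace, fill, count.

    ``jitter_seed`` perturbs the slice selection by +/- 1 index inside each
    severity window (the repeat-to-repeat variation of this arm); ``None``
    keeps the deterministic greedy selection.
    """
    lo, hi = annotation.graft_extent(truth, axis)
    sev = annotation._severity_array(
        severities, n=np.moveaxis(truth.data, axis, 0).shape[0]
    )
    indices = annotation.select_input_slices(sev, (lo, hi), max_gap)
    if jitter_seed is not None:
        rng = np.random.default_rng(jitter_seed)
        indices = annotation.jitter_selection(indices, (lo, hi), max_gap, rng)
    sparse = annotation.build_sparse_annotations(
        truth, sev, axis=axis, max_gap=max_gap, indices=indices
    )
    dense = mci_core.interpolate_volume(
        sparse, truth.shape, truth.spacing, truth.origin
    )
    return volumetrics.measure_volume(dense, voi, axis=axis)


def manual_measure(
    intensity: VoxelGrid,
    truth: VoxelGrid,
    severities,
    voi,
    rater_seed: int,
    rater: annotation.RaterModel | None = None,
    axis: int = STACK_AXIS,
) -> float:
    """One manual-arm measurement: trace every slice, count."""
    if rater is None:
        rater = annotation.RaterModel(seed=rater_seed)
    else:
        rater = annotation.RaterModel(
            rater.bias_per_severity, rater.jitter_sigma, rater.smoothing_scale,
            rater_seed,
        )
    mask = annotation.manual_segment_volume(intensity, truth, severities, rater, axis)
    return volumetrics.measure_volume(mask, voi, axis=axis)


@dataclass
class CaseResult:
    """Everything measured for one phantom.

    ``reports`` summarizes the angle-merged volumes (the published-table
    layout); ``per_angle_volumes`` keeps the five repeat volumes of every
    individual scan, from which per-scan repeatability is derived.
    """

    name: str
    control_volume: float
    reports: dict  # method -> MeasurementReport
    per_angle_volumes: dict  # method -> {angle: [volumes]}

    def repeat_cv(self, method: str) -> float:
        """Repeatability of the repeated measurements of each scan: the
        worst per-scan CV over this phantom's mounting angles."""
        return max(
            volumetrics.coefficient_of_variation(vols)
            for vols in self.per_angle_volumes[method].values()
        )


def _derive_seed(master: int, *key: int) -> int:
    return int(
        np.random.SeedSequence([int(master), *[int(k) for k in key]]).generate_state(1)[0]
        % (2**31 - 1)
    )


def run_case(
    name: str,
    seed: int,
    spacing: float = 0.25,
    angles=DEFAULT_ANGLES,
    n_repeats: int = 5,
    n_raters: int = 2,
    max_gap: int = 5,
    methods=("mci", "manual"),
) -> CaseResult:
    """Run the full protocol for one named phantom."""
    case_id = phantoms.MODEL_NAMES.index(name)
    grid, truth_rec, spec = phantoms.build_model(name, spacing=spacing)
    in_vitro = name in phantoms.IN_VITRO
    angle_list = list(angles) if in_vitro else [0.0]

    if in_vitro:
        control = (
            truth_rec.analytic_volume
            if truth_rec.analytic_volume is not None
            else truth_rec.voxel_volume
        )
    else:
        # voxelized truth restricted to the 5 mm VOI
        control = volumetrics.measure_volume(
            truth_mask(grid), voi_for(spec, grid), axis=STACK_AXIS
        )

    per_method_per_angle = {m: {} for m in methods}
    for a_idx, angle in enumerate(angle_list):
        mounted = phantoms.mount_at_angle(grid, angle) if angle else grid
        model = default_artifact_model(seed=_derive_seed(seed, case_id, a_idx, 0))
        intensity, severities = cbct_sim.simulate_cbct(mounted, model, axis=STACK_AXIS)
        voi = voi_for(spec, mounted)

        if "mci" in methods:
            def mci_pipeline(rater_idx: int, s: int) -> float:
                return mci_measure(mounted, severities, voi, max_gap, jitter_seed=s)

            per_method_per_angle["mci"][angle] = annotation.repeated_measurements(
                mci_pipeline, n_repeats, n_raters,
                seed=_derive_seed(seed, case_id, a_idx, 1),
            )
        if "manual" in methods:
            def manual_pipeline(rater_idx: int, s: int) -> float:
                return manual_measure(intensity, mounted, severities, voi, rater_seed=s)

            per_method_per_angle["manual"][angle] = annotation.repeated_measurements(
                manual_pipeline, n_repeats, n_raters,
                seed=_derive_seed(seed, case_id, a_idx, 2),
            )

    reports = {}
    for method in methods:
        pooled, per_angle_means = volumetrics.merge_angle_measurements(
            per_method_per_angle[method]
        )
        reports[method] = volumetrics.MeasurementReport(
            phantom=name,
            method=method,
            volumes=pooled,
            control_volume=control,
            per_angle_means=per_angle_means,
        )
    return CaseResult(name, control, reports, per_method_per_angle)


def run_battery(
    seed: int,
    spacing: float = 0.25,
    models=phantoms.MODEL_NAMES,
    angles=DEFAULT_ANGLES,
    n_repeats: int = 5,
    n_raters: int = 2,
    max_gap: int = 5,
    methods=("mci", "manual"),
) -> list[CaseResult]:
    """Run the protocol for every requested phantom."""
    return [
        run_case(
            name, seed, spacing=spacing, angles=angles, n_repeats=n_repeats,
            n_raters=n_raters, max_gap=max_gap, methods=methods,
        )
        for name in models
    ]


# ---------------------------------------------------------------------------
# Surface-deviation comparison (interpolation arm vs manual arm)


def _fiducials(grid: VoxelGrid) -> np.ndarray:
    """Analytically known landmark points shared by test and reference:
    implant-axis end points and graft bounding-box corners."""
    pts = []
    implant = np.argwhere(grid.data == IMPLANT)
    graft = np.argwhere(grid.data == GRAFT)
    for arr in (implant, graft):
        if len(arr) == 0:
            continue
        lo = grid.origin + arr.min(axis=0) * grid.spacing
        hi = grid.origin + arr.max(axis=0) * grid.spacing
        pts.extend([lo, hi, np.array([lo[0], hi[1], lo[2]])])
    return np.asarray(pts)


def surface_comparison(
    name: str,
    seed: int,
    spacing: float = 0.25,
    max_gap: int = 5,
) -> dict:
    """Mean absolute surface deviation of each arm from the truth surface.

    The truth-label mesh is the reference; both arms are registered to it
    through shared fiducial landmarks (an identity transform, since phantom
    and segmentation share one coordinate frame) before the deviation map
    is computed.
    """
    case_id = phantoms.MODEL_NAMES.index(name)
    grid, _, spec = phantoms.build_model(name, spacing=spacing)
    model = default_artifact_model(seed=_derive_seed(seed, case_id, 90))
    intensity, severities = cbct_sim.simulate_cbct(grid, model, axis=STACK_AXIS)

    sev = annotation._severity_array(
        severities, n=np.moveaxis(grid.data, STACK_AXIS, 0).shape[0]
    )
    sparse = annotation.build_sparse_annotations(grid, sev, STACK_AXIS, max_gap)
    dense = mci_core.interpolate_volume(sparse, grid.shape, grid.spacing, grid.origin)
    rater = annotation.RaterModel(seed=_derive_seed(seed, case_id, 91))
    manual = annotation.manual_segment_volume(intensity, grid, sev, rater, STACK_AXIS)

    reference = surface_eval.extract_surface(truth_mask(grid))
    fid = _fiducials(grid)
    result = {}
    for label, mask in (("mci", dense), ("manual", manual)):
        mesh = surface_eval.extract_surface(mask)
        transform = surface_eval.point_based_register(mesh, reference, (fid, fid))
        dev = surface_eval.deviation_map(mesh, reference, transform)
        result[label] = dev
    return result
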