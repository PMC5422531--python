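"""Subject-specific ROI definition via leave-one-subject-out (LOSO) group maps.

Selecting each subject's ROI peaks from a group t-map that excludes that
subject reduces the circularity of defining regions and extracting signal
from the same data.  For a cohort of N subjects this runs N one-sample
t-tests on the task-minus-control contrast (each over N-1 subjects),
locates the peak t within a search sphere around each catalog centre, and
places a small extraction sphere (default 6 mm radius) at that peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import ROICatalog, ROISpec
from .errors import ArgumentError, DegenerateRegionError, GeometryError
from .volume import StatMap, VolumeGrid, one_sample_tmap, sphere_mask, voxel_center_coords

__all__ = [
    "ROIPeak",
    "loso_tmap",
    "find_roi_peak",
    "define_subject_rois",
    "extract_roi_means",
    "build_beta_table",
]

BETA_COLUMNS = ["subject_id", "roi", "hemisphere", "category", "mean_task", "mean_control", "contrast"]


@dataclass(frozen=True)
class ROIPeak:
    """The located activation peak for one subject and one ROI."""

    subject_id: str
    name: str
    hemisphere: str
    peak_mm: tuple[float, float, float]
    peak_t: float


def contrast_volume(task: VolumeGrid, control: VolumeGrid) -> VolumeGrid:
    if not task.same_geometry(control):
        raise GeometryError("task and control volumes differ in geometry")
    return task.copy_with(task.data - control.data)


def loso_tmap(left_out: str, contrast_volumes: dict[str, VolumeGrid]) -> StatMap:
    """One-sample t-map over every subject's contrast volume except ``left_out``.

    With N subjects in total the map is built from N-1 volumes, df = N-2.
    """
    if left_out not in contrast_volumes:
        raise KeyError(f"subject {left_out!r} not in cohort")
    if len(contrast_volumes) < 3:
        raise ArgumentError("LOSO needs at least 3 subjects")
    retained = [v for sid, v in contrast_volumes.items() if sid != left_out]
    return one_sample_tmap(retained)


def find_roi_peak(stat_map: StatMap, roi: ROISpec, subject_id: str = "") -> ROIPeak:
    """Voxel of maximal t within the ROI's search sphere.

    Ties on t are broken by smallest Euclidean distance to the canonical
    centre, then by lexicographic voxel index, making the result
    deterministic across platforms.
    """
    grid = stat_map.grid
    mask = sphere_mask(grid, roi.canonical_center, roi.search_radius)
    idx = np.argwhere(mask)
    if idx.size == 0:
        raise DegenerateRegionError(
            f"search sphere for {roi.label} does not intersect the grid"
        )
    values = grid.data[mask]
    finite = np.isfinite(values)
    if not finite.any():
        raise DegenerateRegionError(f"all voxels missing in search region of {roi.label}")
    idx = idx[finite]
    values = values[finite]
    tmax = values.max()
    at_max = idx[values == tmax]
    coords = voxel_center_coords(grid, at_max)
    dist = np.linalg.norm(coords - np.asarray(roi.canonical_center), axis=1)
    # stable tie-break: distance, then lexicographic voxel index
    order = np.lexsort((at_max[:, 2], at_max[:, 1], at_max[:, 0], dist))
    best = at_max[order[0]]
    peak_mm = tuple(float(c) for c in grid.voxel_to_mm(best))
    return ROIPeak(
        subject_id=subject_id,
        name=roi.name,
        hemisphere=roi.hemisphere,
        peak_mm=peak_mm,  # type: ignore[arg-type]
        peak_t=float(tmax),
    )


def _mirror_x(point) -> tuple[float, float, float]:
    return (-point[0], point[1], point[2])


def define_subject_rois(
    task_volumes: dict[str, VolumeGrid],
    control_volumes: dict[str, VolumeGrid],
    catalog: ROICatalog,
    sphere_radius: float = 6.0,
    mirror: bool = False,
):
    """LOSO-based subject-specific ROI spheres for every subject.

    For each subject a group t-map excluding that subject is computed, the
    per-ROI peak located, and a sphere of ``sphere_radius`` mm placed at the
    peak.  With ``mirror=True`` right-hemisphere spheres are centred on the
    x-mirror of the corresponding left-hemisphere peak instead of an
    independent right-hemisphere search.

    Returns
    -------
    (peaks, masks)
        ``peaks``: dict subject_id -> dict (name, hemisphere) -> ROIPeak;
        ``masks``: dict subject_id -> dict (name, hemisphere) -> boolean mask.
    """
    subjects = list(task_volumes)
    if set(subjects) != set(control_volumes):
        raise ArgumentError("task and control cohorts list different subjects")
    if len(subjects) < 3:
        raise ArgumentError("LOSO needs at least 3 subjects")
    contrasts = {sid: contrast_volume(task_volumes[sid], control_volumes[sid]) for sid in subjects}

    peaks: dict[str, dict] = {}
    masks: dict[str, dict] = {}
    grid = next(iter(contrasts.values()))
    for sid in subjects:
        tmap = loso_tmap(sid, contrasts)
        sub_peaks: dict[tuple[str, str], ROIPeak] = {}
        for roi in catalog.select(hemisphere="L"):
            sub_peaks[roi.key] = find_roi_peak(tmap, roi, subject_id=sid)
        for roi in catalog.select(hemisphere="R"):
            if mirror:
                left_peak = sub_peaks[(roi.name, "L")]
                center = _mirror_x(left_peak.peak_mm)
                vox = tmap.grid.mm_to_voxel(center)
                sub_peaks[roi.key] = ROIPeak(
                    subject_id=sid,
                    name=roi.name,
                    hemisphere="R",
                    peak_mm=tuple(float(c) for c in tmap.grid.voxel_to_mm(vox)),  # type: ignore[arg-type]
                    peak_t=float(tmap.grid.data[vox]),
                )
            else:
                sub_peaks[roi.key] = find_roi_peak(tmap, roi, subject_id=sid)
        sub_masks = {
            key: sphere_mask(grid, pk.peak_mm, sphere_radius) for key, pk in sub_peaks.items()
        }
        for key, m in sub_masks.items():
            if not m.any():
                raise DegenerateRegionError(f"empty extraction sphere for {key} of {sid}")
        peaks[sid] = sub_peaks
        masks[sid] = sub_masks
    return peaks, masks


def extract_roi_means(
    subject_id: str,
    task: VolumeGrid,
    control: VolumeGrid,
    roi_masks: dict,
    catalog: ROICatalog,
) -> pd.DataFrame:
    """Mean task, control and task-minus-control value per ROI sphere.

    One row per catalog ROI, columns per :data:`BETA_COLUMNS`; the contrast
    column is exactly ``mean_task - mean_control``.
    """
    if not task.same_geometry(control):
        raise GeometryError("task and control volumes differ in geometry")
    rows = []
    for roi in catalog:
        mask = roi_masks[roi.key]
        if mask.shape != task.shape:
            raise GeometryError(f"mask geometry mismatch for {roi.label}")
        if not mask.any():
            raise DegenerateRegionError(f"empty mask for {roi.label} of {subject_id}")
        mt = float(task.data[mask].mean())
        mc = float(control.data[mask].mean())
        rows.append(
            {
                "subject_id": subject_id,
                "roi": roi.name,
                "hemisphere": roi.hemisphere,
                "category": roi.category,
                "mean_task": mt,
                "mean_control": mc,
                "contrast": mt - mc,
            }
        )
    return pd.DataFrame(rows, columns=BETA_COLUMNS)


def build_beta_table(
    task_volumes: dict[str, VolumeGrid],
    control_volumes: dict[str, VolumeGrid],
    catalog: ROICatalog,
    sphere_radius: float = 6.0,
    mirror: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Full LOSO definition + extraction for a cohort.

    Returns the N x 22 beta table (one row per subject per ROI) and the
    per-subject peaks.
    """
    peaks, masks = define_subject_rois(
        task_volumes, control_volumes, catalog, sphere_radius=sphere_radius, mirror=mirror
    )
    frames = [
        extract_roi_means(sid, task_volumes[sid], control_volumes[sid], masks[sid], catalog)
        for sid in task_volumes
    ]
    return pd.concat(frames, ignore_index=True), peaks
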