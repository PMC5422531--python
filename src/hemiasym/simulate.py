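"""Synthetic multi-subject cohort generator.

The generator emits everything the analysis consumes -- subject profiles,
trial-level naming behavior, and per-subject task/control contrast volumes
on an MNI-like grid -- with the statistical structure the analysis is
meant to detect:

* an age effect on the left anterior-posterior balance (older subjects get
  extra left-posterior amplitude, pushing L_AP more negative);
* a latency-coupled right-anterior boost within the older group (faster
  older subjects get more right-anterior amplitude, shrinking A_LR);
* naming behavior with high accuracy and older subjects ~100 ms slower.

Volumes are sums of Gaussian activation foci at the catalog's canonical
centres (with per-subject spatial jitter) plus smoothed voxel noise.
Focus coefficients are cross-talk compensated: a coupling operator M --
the sphere-mean each unit focus induces at the locations where the peak
search is expected to land -- is computed once per geometry, and a subject
with amplitude vector ``a`` is planted with coefficients solving
``M b = a``, so the expected define->extract output equals the planted
amplitudes.  Without this step, smoothing attenuation and overlap between
nearby foci (the right SFG and SMA centres are under 3 mm apart) would
distort extracted amplitudes by tens of percent.  One distortion remains
by construction: selecting the maximum of a noisy t-map lets the peak
wander within the zone where the signal's decrease is offset by sampling
fluctuation of the voxelwise standard deviation, which biases extracted
values downward by up to ~25% in the worst voxel draw.  This selection
loss is a property of peak-based ROI definition itself, not of the
generator; group comparisons of asymmetry indices, which difference such
losses away, are unaffected.

Determinism: one master seed; each subject's volumes and session use an
independent stream derived from (seed, stream-tag, subject-index) via
``numpy.random.SeedSequence``, so identical configs give bit-identical
cohorts regardless of generation order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import ROICatalog, default_catalog
from .config import CohortConfig, SessionDesign
from .errors import ConfigurationError, GenerationError
from .volume import VolumeGrid, gaussian_smooth, fwhm_to_sigma, mni_grid, sphere_mask, write_volume, read_volume

__all__ = [
    "SubjectProfile",
    "Cohort",
    "generate_cohort",
    "generate_subject_volumes",
    "generate_session",
    "generate_roi_contrast_table",
    "write_cohort",
    "read_cohort",
]

# log-space SD of single-trial latencies; subject means follow the config.
TRIAL_RT_LOGSD = 0.25
# minimum plausible latency: responses cannot precede perception.
MIN_LATENCY_MS = 150.0
# extraction sphere radius the cross-talk compensation is calibrated for.
COMPENSATION_RADIUS_MM = 6.0

_STREAM_PROFILES = 0
_STREAM_VOLUMES = 1
_STREAM_SESSION = 2
_STREAM_TABLE = 3


@dataclass(frozen=True)
class SubjectProfile:
    """Ground-truth description of one simulated subject."""

    subject_id: str
    index: int
    age: float
    true_group: str  # "young" or "old"
    mean_rt: float  # ms
    amplitudes: dict  # (name, hemisphere) -> contrast units


@dataclass
class Cohort:
    """A generated cohort: profiles, trials, and (optionally) volumes."""

    config: CohortConfig
    catalog: ROICatalog
    profiles: list
    trials: pd.DataFrame | None = None
    task_volumes: dict = field(default_factory=dict)
    control_volumes: dict = field(default_factory=dict)

    @property
    def participants(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "subject_id": p.subject_id,
                    "age": p.age,
                    "group": p.true_group,
                    "mean_rt": p.mean_rt,
                }
                for p in self.profiles
            ]
        )


def _rng(seed: int, stream: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, stream, index)))


def grid_from_config(config: CohortConfig) -> VolumeGrid:
    return mni_grid(shape=tuple(config.grid_shape), voxel_size=config.voxel_size)


def _truncated_normal_positive(rng, mean, sd):
    while True:
        v = rng.normal(mean, sd)
        if v > 0:
            return float(v)


def subject_amplitudes(config: CohortConfig, true_group: str, z_rt: float, catalog: ROICatalog) -> dict:
    """The amplitude model: base cell value + age and latency effects.

    amp(s, r) = base[hemi(r), cat(r)]
                + lapa_delta            if s old and r left posterior
                + harold_gain * z_s     if s old and r right anterior

    where ``z_s`` is the subject's negated standardized latency within the
    older group (faster subject => larger z => bigger right-anterior boost
    => smaller A_LR).
    """
    amps = {}
    for roi in catalog:
        cell = f"{roi.hemisphere}_{roi.category}"
        a = config.base_amplitude[cell]
        if true_group == "old":
            if roi.hemisphere == "L" and roi.category == "posterior":
                a += config.lapa_delta
            if roi.hemisphere == "R" and roi.category == "anterior":
                a += config.harold_gain * z_rt
        amps[roi.key] = float(a)
    return amps


def generate_profiles(config: CohortConfig, catalog: ROICatalog) -> list:
    """Subject profiles: ages uniform within group ranges, latencies normal."""
    rng = _rng(config.seed, _STREAM_PROFILES)
    profiles = []
    ages_young = rng.uniform(*config.age_range_young, size=config.n_young)
    rts_young = [
        _truncated_normal_positive(rng, config.rt_mean_young, config.rt_sd_young)
        for _ in range(config.n_young)
    ]
    ages_old = rng.uniform(*config.age_range_old, size=config.n_old)
    rts_old = np.array(
        [
            _truncated_normal_positive(rng, config.rt_mean_old, config.rt_sd_old)
            for _ in range(config.n_old)
        ]
    )
    # negated standardized latency within the older group drives the
    # right-anterior (HAROLD-like) boost
    z_old = -(rts_old - rts_old.mean()) / rts_old.std(ddof=1)

    idx = 0
    for age, rt in zip(ages_young, rts_young):
        sid = f"sub-{idx + 1:02d}"
        profiles.append(
            SubjectProfile(
                subject_id=sid, index=idx, age=float(age), true_group="young",
                mean_rt=rt, amplitudes=subject_amplitudes(config, "young", 0.0, catalog),
            )
        )
        idx += 1
    for age, rt, z in zip(ages_old, rts_old, z_old):
        sid = f"sub-{idx + 1:02d}"
        profiles.append(
            SubjectProfile(
                subject_id=sid, index=idx, age=float(age), true_group="old",
                mean_rt=float(rt),
                amplitudes=subject_amplitudes(config, "old", float(z), catalog),
            )
        )
        idx += 1
    return profiles


# ---------------------------------------------------------------------------
# volume synthesis

_coupling_cache: dict = {}


def _render_focus(data: np.ndarray, grid: VolumeGrid, center, sigma_mm: float, coeff: float) -> None:
    """Add ``coeff * exp(-d^2 / 2 sigma^2)`` around ``center``, in place.

    Evaluation is restricted to a 4-sigma bounding box for speed.
    """
    inv = np.linalg.inv(grid.affine)
    cvox = (inv[:3, :3] @ np.asarray(center, dtype=float)) + inv[:3, 3]
    halfwidth = 4.0 * sigma_mm / grid.spacing
    lo = np.maximum(np.floor(cvox - halfwidth).astype(int), 0)
    hi = np.minimum(np.ceil(cvox + halfwidth).astype(int) + 1, np.array(grid.shape))
    if np.any(lo >= hi):
        raise GenerationError(f"focus centre {tuple(center)} mm outside the grid")
    ax = [np.arange(lo[d], hi[d]) for d in range(3)]
    ii, jj, kk = np.meshgrid(*ax, indexing="ij")
    vox = np.stack([ii, jj, kk], axis=-1).astype(float)
    mm = vox @ grid.affine[:3, :3].T + grid.affine[:3, 3]
    d2 = np.sum((mm - np.asarray(center)) ** 2, axis=-1)
    data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += coeff * np.exp(-d2 / (2.0 * sigma_mm**2))


def _unit_focus_fields(config: CohortConfig, catalog: ROICatalog, grid: VolumeGrid):
    """Smoothed unit-amplitude focus field for every catalog ROI."""
    sigma_f = fwhm_to_sigma(config.focus_fwhm)
    fields = []
    for roi in catalog:
        if not grid.contains_mm(roi.canonical_center):
            raise GenerationError(f"catalog centre {roi.label} outside the grid")
        data = np.zeros(grid.shape)
        _render_focus(data, grid, roi.canonical_center, sigma_f, 1.0)
        fields.append(gaussian_smooth(grid.copy_with(data), config.smoothing_fwhm).data)
    return fields


def coupling_matrix(config: CohortConfig, catalog: ROICatalog) -> np.ndarray:
    """Coupling of planted foci to the sphere-means the pipeline extracts.

    Entry (r, r') is the mean, over a 6-mm sphere centred where the
    pipeline's peak search is expected to land for ROI r, of a
    unit-amplitude smoothed focus planted at ROI r'.  The expected peak
    locations are found by a fixed-point iteration: render the expected
    noiseless field for the base amplitude profile, locate each ROI's
    in-sphere maximum, recompute the coupling at those points, re-solve
    the coefficients, and repeat.  Solving ``M b = a`` against this
    operator makes the expected define->extract output equal the planted
    amplitudes.  Cached per geometry.
    """
    key = (
        tuple(config.grid_shape), config.voxel_size, config.focus_fwhm,
        config.smoothing_fwhm,
        tuple(sorted(config.base_amplitude.items())),
        tuple(r.key + tuple(r.canonical_center) + (r.search_radius,) for r in catalog),
    )
    if key in _coupling_cache:
        return _coupling_cache[key]
    grid = grid_from_config(config)
    fields = _unit_focus_fields(config, catalog, grid)
    search_masks = [sphere_mask(grid, r.canonical_center, r.search_radius) for r in catalog]
    a_base = np.array(
        [config.base_amplitude[f"{r.hemisphere}_{r.category}"] for r in catalog]
    )
    if np.all(a_base == 0.0):
        a_base = np.ones(len(catalog))
    n = len(catalog)
    b = a_base.copy()
    M = np.eye(n)
    for _ in range(4):
        expected = np.einsum("r,rijk->ijk", b, np.asarray(fields))
        M = np.zeros((n, n))
        for i in range(n):
            in_sphere = np.argwhere(search_masks[i])
            local = expected[search_masks[i]]
            peak = in_sphere[np.argmax(local)]
            peak_mm = grid.voxel_to_mm(peak)
            extraction = sphere_mask(grid, peak_mm, COMPENSATION_RADIUS_MM)
            for j in range(n):
                M[i, j] = fields[j][extraction].mean()
        b = np.linalg.pinv(M, rcond=1e-8) @ a_base
    _coupling_cache[key] = M
    return M


def generate_subject_volumes(
    profile: SubjectProfile,
    catalog: ROICatalog,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> tuple[VolumeGrid, VolumeGrid]:
    """Task and control contrast volumes for one subject.

    Task = cross-talk-compensated Gaussian foci (jittered centres) + voxel
    noise, smoothed; control = voxel noise, smoothed.
    """
    if rng is None:
        rng = _rng(config.seed, _STREAM_VOLUMES, profile.index)
    grid = grid_from_config(config)
    for roi in catalog:
        if not grid.contains_mm(roi.canonical_center):
            raise GenerationError(f"catalog centre {roi.label} outside the grid")
    amp = np.array([profile.amplitudes[r.key] for r in catalog])
    if np.any(amp != 0.0):
        M = coupling_matrix(config, catalog)
        # pseudoinverse: ROIs whose expected peaks coincide give duplicate
        # rows; the system stays consistent because such ROIs share a cell
        # amplitude
        coeff = np.linalg.pinv(M, rcond=1e-8) @ amp
    else:
        coeff = amp
    sigma_f = fwhm_to_sigma(config.focus_fwhm)

    task_data = np.zeros(grid.shape)
    for roi, c in zip(catalog, coeff):
        center = np.asarray(roi.canonical_center, dtype=float)
        if config.jitter_sd > 0:
            center = center + rng.normal(0.0, config.jitter_sd, size=3)
        if not grid.contains_mm(center):
            raise GenerationError(
                f"jittered focus for {roi.label} at {tuple(center)} mm left the grid"
            )
        if c != 0.0:
            _render_focus(task_data, grid, center, sigma_f, float(c))
    if config.noise_sd > 0:
        task_data = task_data + rng.normal(0.0, config.noise_sd, size=grid.shape)
    control_data = (
        rng.normal(0.0, config.noise_sd, size=grid.shape)
        if config.noise_sd > 0
        else np.zeros(grid.shape)
    )
    task = gaussian_smooth(grid.copy_with(task_data), config.smoothing_fwhm)
    control = gaussian_smooth(grid.copy_with(control_data), config.smoothing_fwhm)
    return task, control


# ---------------------------------------------------------------------------
# behavior synthesis

def generate_session(
    profile: SubjectProfile,
    design: SessionDesign,
    rng: np.random.Generator | None = None,
    accuracy_rate: float = 0.985,
) -> pd.DataFrame:
    """Trial table for one run: alternating task/control blocks on the TR grid.

    Latencies are lognormal with the subject's configured mean, truncated
    to [150 ms, TR] so responses stay inside their scan window.
    """
    design.validate()
    if rng is None:
        rng = _rng(0, _STREAM_SESSION, profile.index)
    if design.n_task_blocks != design.n_control_blocks:
        block_types = ["task"] * design.n_task_blocks + ["control"] * design.n_control_blocks
    else:
        block_types = []
        for _ in range(design.n_task_blocks):
            block_types += ["task", "control"]
    mu = np.log(profile.mean_rt) - TRIAL_RT_LOGSD**2 / 2.0
    upper_ms = design.tr * 1000.0

    rows = []
    trial_index = 0
    for btype in block_types:
        for _ in range(design.stimuli_per_block):
            onset = trial_index * design.tr
            latency = float(np.exp(rng.normal(mu, TRIAL_RT_LOGSD)))
            while not (MIN_LATENCY_MS <= latency <= upper_ms):
                latency = float(np.exp(rng.normal(mu, TRIAL_RT_LOGSD)))
            correct = bool(rng.random() < accuracy_rate)
            rows.append(
                {
                    "subject_id": profile.subject_id,
                    "block_type": btype,
                    "trial_index": trial_index,
                    "scan_onset": onset,
                    "response_onset": onset + latency / 1000.0,
                    "correct": correct,
                }
            )
            trial_index += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort assembly and I/O

def generate_cohort(
    config: CohortConfig,
    design: SessionDesign | None = None,
    catalog: ROICatalog | None = None,
    include_volumes: bool = True,
) -> Cohort:
    """Generate a full cohort: profiles, trials, and contrast volumes."""
    config.validate()
    if design is None:
        design = SessionDesign()
    design.validate()
    if catalog is None:
        catalog = default_catalog()
    profiles = generate_profiles(config, catalog)

    trial_frames = [
        generate_session(
            p, design, _rng(config.seed, _STREAM_SESSION, p.index), config.accuracy_rate
        )
        for p in profiles
    ]
    trials = pd.concat(trial_frames, ignore_index=True)

    task_volumes: dict[str, VolumeGrid] = {}
    control_volumes: dict[str, VolumeGrid] = {}
    if include_volumes:
        for p in profiles:
            task, control = generate_subject_volumes(
                p, catalog, config, _rng(config.seed, _STREAM_VOLUMES, p.index)
            )
            task_volumes[p.subject_id] = task
            control_volumes[p.subject_id] = control
    return Cohort(
        config=config, catalog=catalog, profiles=profiles, trials=trials,
        task_volumes=task_volumes, control_volumes=control_volumes,
    )


def generate_roi_contrast_table(
    config: CohortConfig, catalog: ROICatalog | None = None
) -> tuple[list, pd.DataFrame]:
    """Fast path: subject x ROI contrast table straight from the amplitude model.

    Skips volume synthesis entirely: contrast(s, r) = amp(s, r) + e with
    e ~ N(0, roi_noise_sd) i.i.d.  Used for Monte-Carlo calibration checks
    where rendering volumes would dominate the cost.
    """
    config.validate()
    if catalog is None:
        catalog = default_catalog()
    profiles = generate_profiles(config, catalog)
    rng = _rng(config.seed, _STREAM_TABLE)
    rows = []
    for p in profiles:
        noise = rng.normal(0.0, config.roi_noise_sd, size=len(catalog))
        for roi, e in zip(catalog, noise):
            c = p.amplitudes[roi.key] + float(e)
            rows.append(
                {
                    "subject_id": p.subject_id,
                    "roi": roi.name,
                    "hemisphere": roi.hemisphere,
                    "category": roi.category,
                    "mean_task": c,
                    "mean_control": 0.0,
                    "contrast": c,
                }
            )
    return profiles, pd.DataFrame(rows)


def write_cohort(cohort: Cohort, directory) -> dict:
    """Persist a cohort: NIfTI volumes, participants/trials TSV, JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    for p in cohort.profiles:
        if p.subject_id in cohort.task_volumes:
            for cond, vols in (("task", cohort.task_volumes), ("control", cohort.control_volumes)):
                fname = f"{p.subject_id}_{cond}.nii.gz"
                write_volume(vols[p.subject_id], directory / fname)
                files.append(fname)
    # default float serialization is the shortest exact repr, so tables
    # round-trip bit-exactly
    participants = cohort.participants
    participants.to_csv(directory / "participants.tsv", sep="\t", index=False)
    files.append("participants.tsv")
    if cohort.trials is not None:
        cohort.trials.to_csv(directory / "trials.tsv", sep="\t", index=False)
        files.append("trials.tsv")
    manifest = {
        "config": cohort.config.to_dict(),
        "seed": cohort.config.seed,
        "n_subjects": len(cohort.profiles),
        "files": files,
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def read_cohort(directory) -> Cohort:
    """Load a cohort previously written by :func:`write_cohort`."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {directory}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    config = CohortConfig.from_dict(manifest["config"])
    catalog = default_catalog()
    participants = pd.read_csv(directory / "participants.tsv", sep="\t")
    trials_path = directory / "trials.tsv"
    trials = pd.read_csv(trials_path, sep="\t") if trials_path.exists() else None

    profiles = []
    task_volumes, control_volumes = {}, {}
    for i, row in participants.iterrows():
        sid = row["subject_id"]
        profiles.append(
            SubjectProfile(
                subject_id=sid, index=int(i), age=float(row["age"]),
                true_group=str(row["group"]), mean_rt=float(row["mean_rt"]), amplitudes={},
            )
        )
        tpath = directory / f"{sid}_task.nii.gz"
        cpath = directory / f"{sid}_control.nii.gz"
        if tpath.exists() and cpath.exists():
            task_volumes[sid] = read_volume(tpath)
            control_volumes[sid] = read_volume(cpath)
    return Cohort(
        config=config, catalog=catalog, profiles=profiles, trials=trials,
        task_volumes=task_volumes, control_volumes=control_volumes,
    )
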