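"""Configuration objects for the synthetic cohort and the analysis pipeline.

Defaults are calibrated so that a default cohort reproduces the study
conditions the analysis is designed for: 13 younger + 14 older subjects,
group mean naming latencies near 818.6 / 917.6 ms, an expected left
anterior-posterior index (L_AP) near -0.21 in the younger and -0.48 in the
older group, and a latency-coupled right-anterior boost within the older
group.  See docs/methods.md for the calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .errors import ConfigurationError

__all__ = ["CohortConfig", "SessionDesign", "PipelineConfig", "AMPLITUDE_CELLS"]

#: the four hemisphere x category amplitude cells
AMPLITUDE_CELLS = ("L_anterior", "R_anterior", "L_posterior", "R_posterior")


def _default_base_amplitude() -> dict[str, float]:
    # Solved from the younger group's four target index means
    # (L_AP=-0.21, R_AP=-0.32, A_LR=0.13, P_LR=0.02) with the left
    # posterior cell anchored at 1.0 contrast unit.
    return {
        "L_anterior": 0.79,
        "R_anterior": 0.66,
        "L_posterior": 1.00,
        "R_posterior": 0.98,
    }


@dataclass
class CohortConfig:
    """Full parameterization of a synthetic cohort."""

    n_young: int = 13
    n_old: int = 14
    age_range_young: tuple[float, float] = (30.0, 55.0)
    age_range_old: tuple[float, float] = (60.0, 85.0)
    rt_mean_young: float = 818.59  # ms
    rt_sd_young: float = 72.06
    rt_mean_old: float = 917.56
    rt_sd_old: float = 107.83
    accuracy_rate: float = 0.985
    grid_shape: tuple[int, int, int] = (61, 73, 61)
    voxel_size: float = 3.0  # mm, isotropic
    base_amplitude: dict[str, float] = field(default_factory=_default_base_amplitude)
    lapa_delta: float = 0.27  # added to left-posterior amplitude in older subjects
    harold_gain: float = 0.08  # right-anterior boost per (negated) standardized RT, old only
    focus_fwhm: float = 12.0  # mm, width of each planted activation focus
    jitter_sd: float = 2.0  # mm, per-subject isotropic displacement of focus centres
    noise_sd: float = 2.5  # contrast units, i.i.d. voxel noise before smoothing
    smoothing_fwhm: float = 6.0  # mm
    roi_noise_sd: float = 0.4  # contrast units, per-ROI noise in the table-level fast path
    seed: int = 0

    def validate(self) -> None:
        if self.n_young < 2:
            raise ConfigurationError("n_young must be >= 2")
        if self.n_old < 2:
            raise ConfigurationError("n_old must be >= 2")
        for name in ("rt_sd_young", "rt_sd_old"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.voxel_size <= 0:
            raise ConfigurationError("voxel_size must be > 0")
        if not (0 < self.accuracy_rate <= 1):
            raise ConfigurationError("accuracy_rate must be in (0, 1]")
        for name in ("age_range_young", "age_range_old"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ConfigurationError(f"{name} must be an increasing pair")
        if set(self.base_amplitude) != set(AMPLITUDE_CELLS):
            raise ConfigurationError(f"base_amplitude must have keys {AMPLITUDE_CELLS}")
        for name in ("focus_fwhm",):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("jitter_sd", "noise_sd", "smoothing_fwhm", "roi_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if len(self.grid_shape) != 3 or any(int(s) < 2 for s in self.grid_shape):
            raise ConfigurationError("grid_shape must be a triple of counts >= 2")

    @property
    def n_subjects(self) -> int:
        return self.n_young + self.n_old

    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_range_young"] = list(self.age_range_young)
        d["age_range_old"] = list(self.age_range_old)
        d["grid_shape"] = list(self.grid_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        for key in ("age_range_young", "age_range_old", "grid_shape"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class SessionDesign:
    """Block design of one naming run: alternating task and control blocks."""

    n_task_blocks: int = 4
    n_control_blocks: int = 4
    stimuli_per_block: int = 20
    stimulus_duration: float = 2.0  # s
    isi: float = 0.5  # s
    tr: float = 2.5  # s

    def validate(self) -> None:
        for name in ("n_task_blocks", "n_control_blocks", "stimuli_per_block"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if abs(self.stimulus_duration + self.isi - self.tr) > 1e-9:
            raise ConfigurationError("stimulus_duration + isi must equal tr")

    @property
    def n_trials(self) -> int:
        return (self.n_task_blocks + self.n_control_blocks) * self.stimuli_per_block

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SessionDesign":
        design = cls(**d)
        design.validate()
        return design


@dataclass
class PipelineConfig:
    """End-to-end analysis parameters."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    design: SessionDesign = field(default_factory=SessionDesign)
    sphere_radius: float = 6.0  # mm, extraction sphere
    search_radius: float = 10.0  # mm, peak search around catalog centres
    mirror_mode: bool = False
    rt_split_within_old: bool = True
    alpha: float = 0.05

    def validate(self) -> None:
        self.cohort.validate()
        self.design.validate()
        if self.sphere_radius <= 0 or self.search_radius <= 0:
            raise ConfigurationError("radii must be > 0")
        if not (0 < self.alpha < 1):
            raise ConfigurationError("alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort.to_dict(),
            "design": self.design.to_dict(),
            "sphere_radius": self.sphere_radius,
            "search_radius": self.search_radius,
            "mirror_mode": self.mirror_mode,
            "rt_split_within_old": self.rt_split_within_old,
            "alpha": self.alpha,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        cohort = CohortConfig.from_dict(d.pop("cohort", {}))
        design = SessionDesign.from_dict(d.pop("design", {}))
        cfg = cls(cohort=cohort, design=design, **d)
        cfg.validate()
        return cfg
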