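"""The ROI catalog for the object-naming network.

Eleven regions per hemisphere, split into an anterior category (frontal
regions + insula, 5 ROIs) and a posterior category (temporo-parietal
regions, 6 ROIs).  Canonical centres are group-mean activation peaks in
MNI mm.  Subject-specific analyses search for each subject's own peak
within ``search_radius`` of the canonical centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ArgumentError

__all__ = [
    "ROISpec",
    "ROICatalog",
    "default_catalog",
    "ANTERIOR_ROIS",
    "POSTERIOR_ROIS",
]

#: anterior (frontal + insular) region names
ANTERIOR_ROIS = ("IFG", "MFG", "SFG", "SMA", "Insula")
#: posterior (temporo-parietal) region names
POSTERIOR_ROIS = ("FG", "ITG", "MTG", "ATL", "Hippocampus", "IPL")


@dataclass(frozen=True)
class ROISpec:
    """A named region of interest in one hemisphere."""

    name: str
    hemisphere: str  # "L" or "R"
    canonical_center: tuple[float, float, float]
    search_radius: float = 10.0

    def __post_init__(self) -> None:
        if self.name not in ANTERIOR_ROIS + POSTERIOR_ROIS:
            raise ArgumentError(f"unknown ROI name {self.name!r}")
        if self.hemisphere not in ("L", "R"):
            raise ArgumentError(f"hemisphere must be 'L' or 'R', got {self.hemisphere!r}")
        x = self.canonical_center[0]
        if self.hemisphere == "L" and x >= 0:
            raise ArgumentError(f"left ROI {self.name} must have x < 0, got {x}")
        if self.hemisphere == "R" and x <= 0:
            raise ArgumentError(f"right ROI {self.name} must have x > 0, got {x}")
        if self.search_radius <= 0:
            raise ArgumentError("search_radius must be > 0")

    @property
    def category(self) -> str:
        return "anterior" if self.name in ANTERIOR_ROIS else "posterior"

    @property
    def key(self) -> tuple[str, str]:
        return (self.name, self.hemisphere)

    @property
    def label(self) -> str:
        return f"{self.hemisphere}_{self.name}"


@dataclass(frozen=True)
class ROICatalog:
    """An ordered collection of 22 ROIs (11 per hemisphere)."""

    rois: tuple[ROISpec, ...]

    def __post_init__(self) -> None:
        keys = [r.key for r in self.rois]
        if len(set(keys)) != len(keys):
            raise ArgumentError("duplicate (name, hemisphere) in catalog")
        for hemi in ("L", "R"):
            n_ant = sum(1 for r in self.rois if r.hemisphere == hemi and r.category == "anterior")
            n_post = sum(1 for r in self.rois if r.hemisphere == hemi and r.category == "posterior")
            if (n_ant, n_post) != (5, 6):
                raise ArgumentError(
                    f"hemisphere {hemi} must have 5 anterior + 6 posterior ROIs, "
                    f"got {n_ant} + {n_post}"
                )

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    def get(self, name: str, hemisphere: str) -> ROISpec:
        for r in self.rois:
            if r.key == (name, hemisphere):
                return r
        raise KeyError((name, hemisphere))

    def select(self, hemisphere: str | None = None, category: str | None = None):
        out = [r for r in self.rois
               if (hemisphere is None or r.hemisphere == hemisphere)
               and (category is None or r.category == category)]
        return tuple(out)

    def with_search_radius(self, radius: float) -> "ROICatalog":
        return ROICatalog(tuple(replace(r, search_radius=radius) for r in self.rois))


# Canonical group-mean peak coordinates (MNI mm).  The right MTG is the
# x-mirror of the left MTG; other right-hemisphere entries have their own
# peaks (several frontal pairs happen to be exactly mirrored).
_CENTERS: dict[tuple[str, str], tuple[float, float, float]] = {
    # anterior
    ("Insula", "L"): (-33.7, 22.0, 9.0),
    ("Insula", "R"): (33.7, 22.0, 9.0),
    ("IFG", "L"): (-54.9, 24.0, 23.0),
    ("IFG", "R"): (54.9, 24.0, 23.0),
    ("MFG", "L"): (-29.8, 10.0, 32.3),
    ("MFG", "R"): (29.8, 10.0, 32.3),
    ("SFG", "L"): (-11.0, 20.4, 42.1),
    ("SFG", "R"): (14.0, 12.0, 47.0),
    ("SMA", "L"): (-8.7, 18.5, 47.3),
    ("SMA", "R"): (12.2, 13.9, 47.0),
    # posterior
    ("FG", "L"): (-46.2, -55.5, -15.7),
    ("FG", "R"): (45.3, -55.0, -16.0),
    ("ITG", "L"): (-50.0, -50.0, -16.0),
    ("ITG", "R"): (51.0, -54.1, -16.0),
    ("MTG", "L"): (-52.8, -35.0, -18.8),
    ("MTG", "R"): (52.8, -35.0, -18.8),
    ("ATL", "L"): (-32.0, 5.0, -25.0),
    ("ATL", "R"): (35.0, 5.0, -25.0),
    ("Hippocampus", "L"): (-26.8, -11.0, -22.0),
    ("Hippocampus", "R"): (25.0, -11.0, -22.0),
    ("IPL", "L"): (-49.8, -29.2, 31.5),
    ("IPL", "R"): (42.8, -31.8, 32.0),
}


def default_catalog(search_radius: float = 10.0) -> ROICatalog:
    """The canonical 22-ROI object-naming catalog.

    Ordered left hemisphere first, anterior before posterior, in the fixed
    region order of :data:`ANTERIOR_ROIS` / :data:`POSTERIOR_ROIS`.
    """
    rois = []
    for hemi in ("L", "R"):
        for name in ANTERIOR_ROIS + POSTERIOR_ROIS:
            rois.append(
                ROISpec(
                    name=name,
                    hemisphere=hemi,
                    canonical_center=_CENTERS[(name, hemi)],
                    search_radius=search_radius,
                )
            )
    return ROICatalog(tuple(rois))
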