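"""Hemispheric-reorganization (HR) asymmetry indices.

From the subject x ROI contrast table, each subject's 22 BOLD-contrast
values are collapsed into four category-region means -- left/right x
anterior/posterior -- and differenced into four indices:

    L_AP = LA - LP   (left anterior-posterior asymmetry)
    R_AP = RA - RP   (right anterior-posterior asymmetry)
    A_LR = LA - RA   (anterior left-right asymmetry)
    P_LR = LP - RP   (posterior left-right asymmetry)

where LA is the mean contrast over the 5 left anterior ROIs, LP over the
6 left posterior ROIs, and so on.  A negative L_AP means posterior-dominant
left-hemisphere activity.  The four indices satisfy the algebraic identity
``A_LR - P_LR == L_AP - R_AP``.

The category memberships are fixed (5 anterior, 6 posterior per
hemisphere); the module refuses partial tables rather than silently
renormalizing, since renormalization would change the statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import ANTERIOR_ROIS, POSTERIOR_ROIS
from .errors import ArgumentError, CompletenessError

__all__ = ["CategoryMeans", "HRIndexSet", "category_means", "compute_indices", "index_table",
           "INDEX_NAMES"]

#: reporting order of the four indices
INDEX_NAMES = ("L_AP", "R_AP", "A_LR", "P_LR")


@dataclass(frozen=True)
class CategoryMeans:
    """Per-subject mean contrast in the four category regions."""

    subject_id: str
    LA: float
    RA: float
    LP: float
    RP: float


@dataclass(frozen=True)
class HRIndexSet:
    """The four asymmetry indices for one subject."""

    subject_id: str
    L_AP: float
    R_AP: float
    A_LR: float
    P_LR: float

    def as_dict(self) -> dict[str, float]:
        return {"L_AP": self.L_AP, "R_AP": self.R_AP, "A_LR": self.A_LR, "P_LR": self.P_LR}


def _cell_mean(sub: pd.DataFrame, subject_id: str, hemisphere: str, names) -> float:
    values = []
    for name in names:
        rows = sub[(sub["roi"] == name) & (sub["hemisphere"] == hemisphere)]
        if len(rows) != 1:
            raise CompletenessError(
                f"subject {subject_id!r} lacks a unique row for ROI ({name}, {hemisphere})"
            )
        values.append(float(rows["contrast"].iloc[0]))
    return float(np.mean(values))


def category_means(table: pd.DataFrame, subject_id: str) -> CategoryMeans:
    """Collapse a subject's 22 ROI contrasts into the four category means."""
    sub = table[table["subject_id"] == subject_id]
    if sub.empty:
        raise CompletenessError(f"no rows for subject {subject_id!r}")
    means = CategoryMeans(
        subject_id=subject_id,
        LA=_cell_mean(sub, subject_id, "L", ANTERIOR_ROIS),
        RA=_cell_mean(sub, subject_id, "R", ANTERIOR_ROIS),
        LP=_cell_mean(sub, subject_id, "L", POSTERIOR_ROIS),
        RP=_cell_mean(sub, subject_id, "R", POSTERIOR_ROIS),
    )
    return means


def compute_indices(means: CategoryMeans) -> HRIndexSet:
    """The four asymmetry differences from the category means."""
    for field in ("LA", "RA", "LP", "RP"):
        if not np.isfinite(getattr(means, field)):
            raise ArgumentError(f"non-finite category mean {field} for {means.subject_id!r}")
    return HRIndexSet(
        subject_id=means.subject_id,
        L_AP=means.LA - means.LP,
        R_AP=means.RA - means.RP,
        A_LR=means.LA - means.RA,
        P_LR=means.LP - means.RP,
    )


def index_table(beta_table: pd.DataFrame) -> pd.DataFrame:
    """One row of four indices per subject, input subject order preserved.

    Vectorized equivalent of mapping :func:`category_means` and
    :func:`compute_indices` over every subject; refuses incomplete tables.
    """
    subjects = list(dict.fromkeys(beta_table["subject_id"]))
    pivot = beta_table.pivot_table(
        index="subject_id", columns=["hemisphere", "roi"], values="contrast", aggfunc="sum"
    )
    expected = [(h, r) for h in ("L", "R") for r in ANTERIOR_ROIS + POSTERIOR_ROIS]
    missing = [c for c in expected if c not in pivot.columns]
    counts = beta_table.groupby(["subject_id", "hemisphere", "roi"]).size()
    if missing or pivot.isna().any().any() or (counts != 1).any():
        # fall back to the per-subject path for a precise error message
        for sid in subjects:
            compute_indices(category_means(beta_table, sid))
    pivot = pivot.loc[subjects]
    la = pivot.loc[:, [("L", r) for r in ANTERIOR_ROIS]].mean(axis=1)
    ra = pivot.loc[:, [("R", r) for r in ANTERIOR_ROIS]].mean(axis=1)
    lp = pivot.loc[:, [("L", r) for r in POSTERIOR_ROIS]].mean(axis=1)
    rp = pivot.loc[:, [("R", r) for r in POSTERIOR_ROIS]].mean(axis=1)
    out = pd.DataFrame(
        {
            "subject_id": subjects,
            "L_AP": (la - lp).to_numpy(),
            "R_AP": (ra - rp).to_numpy(),
            "A_LR": (la - ra).to_numpy(),
            "P_LR": (lp - rp).to_numpy(),
        },
        columns=["subject_id", *INDEX_NAMES],
    )
    return out


def write_index_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_index_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
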