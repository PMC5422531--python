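"""The modelling surface: a fitted hemispheric-reorganization analysis.

:class:`HemisphericReorganization` holds a cohort's contrast volumes and
participant data; :meth:`~HemisphericReorganization.fit` runs the whole
analysis -- behavioral screening, LOSO subject-specific ROI definition,
BOLD-contrast extraction, asymmetry indices, median splits, Mann-Whitney
comparisons and the latency-adjusted ANCOVA -- and returns a
:class:`HRResults` carrying every table and test, with ``summary()`` and
JSON/TSV writers.  Everything is deterministic given the input data.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .behavior import BehavioralSummary, screen_outliers, summarize_behavior
from .catalog import ROICatalog, default_catalog
from .errors import ArgumentError
from .indices import INDEX_NAMES, index_table
from .roi import build_beta_table
from .stats import (
    GroupAssignment,
    ancova_group_effect,
    compare_groups,
    median_split,
)

__all__ = ["HemisphericReorganization", "HRResults"]

AGE_LABELS = ("YG", "OG")
RT_LABELS = ("OG/RT+", "OG/RT-")


class HemisphericReorganization:
    """Hemispheric-reorganization analysis of an object-naming fMRI cohort.

    Parameters
    ----------
    task_volumes, control_volumes
        Per-subject contrast volumes on a common grid, keyed by subject id.
    participants
        Table with columns ``subject_id``, ``age`` and (if no trial table
        is given) ``mean_rt`` in ms.
    trials
        Optional trial-level table (columns ``subject_id``, ``block_type``,
        ``scan_onset``, ``response_onset``, ``correct``); when present,
        per-subject latency and accuracy are derived from it.
    catalog
        ROI catalog; defaults to the canonical 22-ROI naming network.
    """

    def __init__(self, task_volumes, control_volumes, participants, trials=None, catalog=None):
        if set(task_volumes) != set(control_volumes):
            raise ArgumentError("task and control volumes list different subjects")
        missing = set(task_volumes) - set(participants["subject_id"])
        if missing:
            raise ArgumentError(f"participants table lacks subjects: {sorted(missing)}")
        self.task_volumes = dict(task_volumes)
        self.control_volumes = dict(control_volumes)
        self.participants = participants.reset_index(drop=True)
        self.trials = trials
        self.catalog = catalog if catalog is not None else default_catalog()

    @classmethod
    def from_cohort(cls, cohort) -> "HemisphericReorganization":
        """Build the model from a generated :class:`~hemiasym.simulate.Cohort`."""
        return cls(
            task_volumes=cohort.task_volumes,
            control_volumes=cohort.control_volumes,
            participants=cohort.participants,
            trials=cohort.trials,
            catalog=cohort.catalog,
        )

    @classmethod
    def from_directory(cls, directory) -> "HemisphericReorganization":
        """Build the model from a cohort directory written by ``write_cohort``."""
        from .simulate import read_cohort

        return cls.from_cohort(read_cohort(directory))

    def _behavior(self) -> list[BehavioralSummary]:
        if self.trials is not None:
            out = []
            for sid in self.task_volumes:
                sub = self.trials[self.trials["subject_id"] == sid]
                out.append(summarize_behavior(sid, sub))
            return out
        if "mean_rt" not in self.participants.columns:
            raise ArgumentError("need either a trial table or a mean_rt column")
        by_sid = dict(zip(self.participants["subject_id"], self.participants["mean_rt"]))
        return [
            BehavioralSummary(subject_id=sid, pct_correct=float("nan"),
                              mean_rt_correct=float(by_sid[sid]), n_trials=0)
            for sid in self.task_volumes
        ]

    def fit(
        self,
        sphere_radius: float = 6.0,
        search_radius: float = 10.0,
        mirror: bool = False,
        rt_split_within_old: bool = True,
        alpha: float = 0.05,
        screen: bool = True,
        log=None,
    ) -> "HRResults":
        """Run the full analysis and return the fitted results."""

        def _log(msg):
            if log is not None:
                log(msg)

        t0 = time.perf_counter()
        summaries = self._behavior()
        if screen:
            retained, exclusions = screen_outliers(summaries)
        else:
            retained, exclusions = [s.subject_id for s in summaries], []
        summaries = [s for s in summaries if s.subject_id in retained]
        _log(f"behavior: {len(retained)} retained, {len(exclusions)} excluded "
             f"({time.perf_counter() - t0:.1f}s)")

        task = {sid: self.task_volumes[sid] for sid in retained}
        control = {sid: self.control_volumes[sid] for sid in retained}
        catalog = self.catalog.with_search_radius(search_radius)
        betas, peaks = build_beta_table(
            task, control, catalog, sphere_radius=sphere_radius, mirror=mirror
        )
        _log(f"roi: {len(retained)} LOSO maps, {len(betas)} beta rows "
             f"({time.perf_counter() - t0:.1f}s)")
        indices = index_table(betas)

        ages = {
            row["subject_id"]: float(row["age"])
            for _, row in self.participants.iterrows()
            if row["subject_id"] in retained
        }
        rts = {s.subject_id: s.mean_rt_correct for s in summaries}
        age_split = median_split(ages, AGE_LABELS)
        comparisons = {"age": compare_groups(indices, age_split)}

        rt_split = None
        if rt_split_within_old:
            old = age_split.members(AGE_LABELS[1])
            if len(old) >= 4:
                rt_split = median_split({sid: rts[sid] for sid in old}, RT_LABELS)
                old_idx = indices[indices["subject_id"].isin(old)].reset_index(drop=True)
                comparisons["rt"] = compare_groups(old_idx, rt_split)

        order = list(indices["subject_id"])
        y = indices["L_AP"].to_numpy(dtype=float)
        group = np.array([age_split.assignment[sid] for sid in order])
        covariate = np.array([rts[sid] for sid in order], dtype=float)
        ancova = ancova_group_effect(y, group, covariate)
        _log(f"stats done ({time.perf_counter() - t0:.1f}s)")

        return HRResults(
            model=self,
            retained=retained,
            exclusions=exclusions,
            behavior=summaries,
            roi_betas=betas,
            roi_peaks=peaks,
            indices=indices,
            age_split=age_split,
            rt_split=rt_split,
            comparisons=comparisons,
            ancova=ancova,
            params={
                "sphere_radius": sphere_radius,
                "search_radius": search_radius,
                "mirror": mirror,
                "rt_split_within_old": rt_split_within_old,
                "alpha": alpha,
            },
        )


@dataclasses.dataclass
class HRResults:
    """Results of a fitted hemispheric-reorganization analysis."""

    model: HemisphericReorganization
    retained: list
    exclusions: list
    behavior: list
    roi_betas: pd.DataFrame
    roi_peaks: dict
    indices: pd.DataFrame
    age_split: GroupAssignment
    rt_split: GroupAssignment | None
    comparisons: dict
    ancova: object
    params: dict

    def comparison_frame(self, which: str = "age") -> pd.DataFrame:
        """Long-format table of descriptives and tests for one split."""
        block = self.comparisons[which]
        rows = []
        for name in INDEX_NAMES:
            cell = block[name]
            for lab, desc in cell["groups"].items():
                rows.append({"index": name, "group": lab, "n": desc.n,
                             "mean": desc.mean, "sd": desc.sd})
            t = cell["test"]
            rows.append({"index": name, "group": "test", "n": t.n1 + t.n2,
                         "mean": t.Z, "sd": t.p_two_sided})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        def _cmp(block):
            out = {}
            for name in INDEX_NAMES:
                cell = block[name]
                out[name] = {
                    "groups": {lab: dataclasses.asdict(d) for lab, d in cell["groups"].items()},
                    "test": dataclasses.asdict(cell["test"]),
                }
            return out

        n = len(self.retained)
        report = {
            "software": {"package": "hemiasym", "version": _version},
            "params": self.params,
            "n_subjects": n,
            "retained": list(self.retained),
            "exclusions": self.exclusions,
            "behavior": [dataclasses.asdict(b) for b in self.behavior],
            "age_split": {
                "labels": list(self.age_split.labels),
                "assignment": dict(self.age_split.assignment),
            },
            "comparisons": {k: _cmp(v) for k, v in self.comparisons.items()},
            "ancova_L_AP": {
                **dataclasses.asdict(self.ancova),
                # residual df under the alternative single-term-model
                # convention sometimes seen in reports (n - 1 - effect df)
                "df_residual_alternative": n - 2,
            },
            "notes": [
                "p-values are uncorrected across the four indices",
            ],
        }
        if self.rt_split is not None:
            report["rt_split"] = {
                "labels": list(self.rt_split.labels),
                "assignment": dict(self.rt_split.assignment),
            }
        return report

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, allow_nan=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def save(self, directory) -> None:
        """Write report JSON and TSV intermediates into a directory."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.roi_betas.to_csv(directory / "roi_betas.tsv", sep="\t", index=False,
                              float_format="%.12g")
        self.indices.to_csv(directory / "hr_indices.tsv", sep="\t", index=False,
                            float_format="%.12g")
        pd.DataFrame([dataclasses.asdict(b) for b in self.behavior]).to_csv(
            directory / "behavior.tsv", sep="\t", index=False, float_format="%.12g"
        )
        self.to_json(directory / "report.json")

    def summary(self) -> str:
        """Human-readable two-panel summary of the group comparisons."""
        lines = []
        lines.append("Hemispheric-reorganization analysis")
        lines.append("=" * 60)
        lines.append(f"subjects retained: {len(self.retained)} "
                     f"(excluded: {len(self.exclusions)})")
        panels = [("age", "(a) younger (YG) vs older (OG)")]
        if "rt" in self.comparisons:
            panels.append(("rt", "(b) faster (OG/RT+) vs slower (OG/RT-) older adults"))
        for key, title in panels:
            lines.append("")
            lines.append(title)
            lines.append("-" * 60)
            block = self.comparisons[key]
            labs = list(block[INDEX_NAMES[0]]["groups"])
            header = f"{'index':>6} " + "".join(f"{l + ' mean (sd)':>22}" for l in labs)
            lines.append(header + f"{'Z':>9}{'p':>9}")
            for name in INDEX_NAMES:
                cell = block[name]
                row = f"{name:>6} "
                for lab in labs:
                    d = cell["groups"][lab]
                    row += f"{d.mean:>13.3f} ({d.sd:.3f})"
                t = cell["test"]
                row += f"{t.Z:>9.3f}{t.p_two_sided:>9.3f}"
                lines.append(row)
        a = self.ancova
        lines.append("")
        lines.append(
            f"ANCOVA L_AP ~ age group + latency: F(1, {a.df_residual}) = "
            f"{a.F:.3f}, p = {a.p:.3f}"
        )
        lines.append("(p-values uncorrected across the four indices)")
        return "\n".join(lines)

    def plot_indices(self, ax=None):
        """Strip plot of the four indices by age group (needs matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        rng = np.random.default_rng(0)
        for i, name in enumerate(INDEX_NAMES):
            for j, lab in enumerate(self.age_split.labels):
                members = self.age_split.members(lab)
                vals = self.indices.set_index("subject_id").loc[members, name]
                x = i + (j - 0.5) * 0.3 + rng.normal(0, 0.03, size=len(vals))
                ax.scatter(x, vals, s=18, alpha=0.7,
                           label=lab if i == 0 else None)
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_xticks(range(len(INDEX_NAMES)), INDEX_NAMES)
        ax.set_ylabel("BOLD contrast asymmetry")
        ax.legend(frameon=False)
        return ax
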