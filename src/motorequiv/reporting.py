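"""End-to-end orchestration and summary reporting.

Composes the pipeline stages — filtering, cycle segmentation, cycle
selection, landmark extraction, aggregation, equivalence statistics —
and renders the summary quantities: the percentage of Holm-significant
correlations, the share of correlations above 0.80 / 0.90 (under both
denominator conventions: of all entries, and of significant entries
only), the range of the non-significant correlations, and the hammering
performance summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import MotorEquivError
from .io import Recording, read_manifest, read_trajectory_tsv, write_manifest, write_trajectory_tsv
from .kinematics import DEFAULT_CUTOFF_HZ, DEFAULT_ORDER, compute_kinematics
from .landmarks import LandmarkRecord, LandmarkTable, aggregate, extract_landmarks
from .model import MotorEquivalence, MotorEquivalenceResults
from .segmentation import FIRST_KEPT, LAST_KEPT, detect_cycles, select_cycles
from .simulate import Cohort, SimulatedRecording
from .stats import rm_anova

__all__ = [
    "SummaryReport",
    "PerformanceSummary",
    "process_recording",
    "extract_cohort",
    "summarize_correlations",
    "summarize_performance",
    "run_pipeline",
    "write_cohort",
]

THRESHOLDS = (0.80, 0.90)


@dataclass
class SummaryReport:
    """Aggregate description of a set of correlation matrices."""

    n_entries: int
    n_significant: int
    percent_significant: float
    #: {(threshold, denominator): percent}, denominator in {"all", "significant"}
    percent_above: dict[tuple[float, str], float]
    nonsig_min: float | None
    nonsig_max: float | None
    per_matrix: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "n_entries": self.n_entries,
            "n_significant": self.n_significant,
            "percent_significant": self.percent_significant,
            "percent_above": {
                f"{thr}|{denom}": v
                for (thr, denom), v in self.percent_above.items()
            },
            "nonsig_min": self.nonsig_min,
            "nonsig_max": self.nonsig_max,
        }


def _entries_frame(matrices_or_frame) -> pd.DataFrame:
    """Accept a list of CorrelationMatrix or a tidy entries frame."""
    if isinstance(matrices_or_frame, pd.DataFrame):
        df = matrices_or_frame.copy()
        required = {"tool", "parameter", "r", "holm_significant"}
        missing = required - set(df.columns)
        if missing:
            raise MotorEquivError(f"entries frame missing columns {sorted(missing)}")
        return df
    frames = [m.to_frame() for m in matrices_or_frame]
    if not frames:
        raise MotorEquivError("no correlation matrices to summarize")
    return pd.concat(frames, ignore_index=True)


def summarize_correlations(matrices_or_frame) -> SummaryReport:
    """Percent significant, percent above thresholds, non-significant range."""
    df = _entries_frame(matrices_or_frame)
    n = len(df)
    sig = df["holm_significant"].astype(bool)
    n_sig = int(sig.sum())
    percent_above = {}
    for thr in THRESHOLDS:
        percent_above[(thr, "all")] = 100.0 * float((df["r"] > thr).sum()) / n
        percent_above[(thr, "significant")] = (
            100.0 * float((df.loc[sig, "r"] > thr).sum()) / n_sig if n_sig else 0.0
        )
    nonsig = df.loc[~sig, "r"]
    per_matrix = (
        df.groupby(["tool", "parameter"])
        .agg(
            n=("r", "size"),
            n_significant=("holm_significant", "sum"),
            median_r=("r", "median"),
            min_r=("r", "min"),
            max_r=("r", "max"),
        )
        .reset_index()
    )
    return SummaryReport(
        n_entries=n,
        n_significant=n_sig,
        percent_significant=100.0 * n_sig / n,
        percent_above=percent_above,
        nonsig_min=float(nonsig.min()) if len(nonsig) else None,
        nonsig_max=float(nonsig.max()) if len(nonsig) else None,
        per_matrix=per_matrix,
    )


@dataclass
class PerformanceSummary:
    """Per-effector task-performance means with their grand mean (cm)."""

    per_effector: pd.DataFrame  # effector, mean_cm, se_cm
    grand_mean_cm: float
    anova: object | None = None

    @property
    def grand_mean_rounded(self) -> float:
        return round(self.grand_mean_cm, 1)


def summarize_performance(depths) -> PerformanceSummary:
    """Summarize task performance (e.g. nail depth, cm) per effector.

    ``depths`` is either a mapping effector -> (mean_cm, se_cm) of
    published summary values, or a participants x effectors DataFrame of
    raw per-participant values, in which case mean/SE are computed and a
    within-subject ANOVA across effectors is attached.  The grand mean is
    the unweighted mean of the effector means.
    """
    anova = None
    if isinstance(depths, pd.DataFrame):
        means = depths.mean(axis=0)
        ses = depths.std(axis=0, ddof=1) / np.sqrt(len(depths))
        per = pd.DataFrame({
            "effector": means.index,
            "mean_cm": means.to_numpy(),
            "se_cm": ses.to_numpy(),
        })
        anova = rm_anova(depths, effect="end-effector (performance)")
    else:
        per = pd.DataFrame(
            [{"effector": e, "mean_cm": m, "se_cm": s}
             for e, (m, s) in depths.items()]
        )
    return PerformanceSummary(
        per_effector=per,
        grand_mean_cm=float(per["mean_cm"].mean()),
        anova=anova,
    )


def process_recording(
    recording: Recording,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_ORDER,
    first_kept: int = FIRST_KEPT,
    last_kept: int = LAST_KEPT,
    prominence_frac: float = 0.20,
    min_separation_frac: float = 0.25,
) -> list[LandmarkRecord]:
    """Run one recording through filtering, segmentation and extraction."""
    series = compute_kinematics(recording, cutoff=cutoff, order=order)
    cycles = detect_cycles(series, recording.tool,
                           prominence_frac=prominence_frac,
                           min_separation_frac=min_separation_frac)
    kept = select_cycles(cycles, first_kept=first_kept, last_kept=last_kept)
    return extract_landmarks(
        series, kept,
        participant_id=recording.participant_id,
        tool=recording.tool,
        effector=recording.effector,
    )


def extract_cohort(
    recordings,
    **process_kwargs,
) -> tuple[LandmarkTable, list[LandmarkRecord]]:
    """Process a collection of recordings into an aggregated landmark table.

    ``recordings`` may contain :class:`Recording` or
    :class:`SimulatedRecording` items.
    """
    all_records: list[LandmarkRecord] = []
    for item in recordings:
        rec = item.recording if isinstance(item, SimulatedRecording) else item
        try:
            all_records.extend(process_recording(rec, **process_kwargs))
        except MotorEquivError as exc:
            raise type(exc)(
                f"{rec.participant_id}/{rec.tool}/{rec.effector}: {exc}"
            ) from exc
    return aggregate(all_records), all_records


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write a cohort's trajectories, manifest and ground truth to disk."""
    out_dir = Path(out_dir)
    traj_dir = out_dir / "trajectories"
    traj_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sim in cohort.recordings:
        rec = sim.recording
        fname = f"{rec.participant_id}_{rec.tool}_{rec.effector}.tsv"
        write_trajectory_tsv(rec, traj_dir / fname)
        rows.append({
            "participant": rec.participant_id,
            "tool": rec.tool,
            "effector": rec.effector,
            "path": str(Path("trajectories") / fname),
        })
    manifest_path = out_dir / "manifest.csv"
    write_manifest(pd.DataFrame(rows), manifest_path)
    cohort.ground_truth.to_csv(out_dir / "ground_truth.csv")
    return manifest_path


def load_cohort_recordings(manifest_path: str | Path) -> list[Recording]:
    """Read every recording referenced by a cohort manifest."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = read_manifest(manifest_path)
    recordings = []
    for _, row in manifest.iterrows():
        rec = read_trajectory_tsv(base / row["path"])
        # manifest labels win over file metadata
        rec.participant_id = str(row["participant"])
        rec.tool = row["tool"]
        rec.effector = row["effector"]
        recordings.append(rec)
    return recordings


@dataclass
class PipelineResult:
    table: LandmarkTable
    results: MotorEquivalenceResults
    summary: SummaryReport
    figure_paths: list[Path]


def run_pipeline(
    manifest_path: str | Path,
    out_dir: str | Path,
    alpha: float = 0.05,
    tails: int = 2,
    make_figures: bool = True,
    **process_kwargs,
) -> PipelineResult:
    """Full analysis of a cohort on disk; writes tidy CSV/JSON outputs.

    Deterministic given the input files and settings.  Emits
    ``landmarks.csv``, ``correlations.csv``, ``summary.json``,
    ``run_metadata.json`` and (optionally) bar-chart and pair-scatter
    figures under ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    recordings = load_cohort_recordings(manifest_path)
    table, _ = extract_cohort(recordings, **process_kwargs)
    results = MotorEquivalence(table, alpha=alpha, tails=tails).fit()
    summary = summarize_correlations(list(results.matrices.values()))

    table.to_csv(out_dir / "landmarks.csv")
    results.to_frame().to_csv(out_dir / "correlations.csv", index=False)
    (out_dir / "summary.json").write_text(
        json.dumps(summary.to_dict(), indent=2) + "\n"
    )
    metadata = {
        "n_recordings": len(recordings),
        "alpha": alpha,
        "tails": tails,
        "process_settings": {
            k: process_kwargs.get(k, default)
            for k, default in (
                ("cutoff", DEFAULT_CUTOFF_HZ), ("order", DEFAULT_ORDER),
                ("first_kept", FIRST_KEPT), ("last_kept", LAST_KEPT),
            )
        },
    }
    (out_dir / "run_metadata.json").write_text(json.dumps(metadata, indent=2) + "\n")

    figure_paths: list[Path] = []
    if make_figures:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig_dir = out_dir / "figures"
        fig_dir.mkdir(exist_ok=True)
        for parameter in results.parameters:
            fig, ax = plt.subplots(figsize=(7, 4))
            results.plot_parameter_means(parameter, ax=ax)
            p = fig_dir / f"means_{parameter}.png"
            fig.savefig(p, dpi=110)
            plt.close(fig)
            figure_paths.append(p)
        for (tool, parameter) in results.matrices:
            axes = results.plot_pair_scatter(tool, parameter)
            fig = axes[0].figure
            fig.tight_layout()
            p = fig_dir / f"pairs_{tool}_{parameter}.png"
            fig.savefig(p, dpi=110)
            plt.close(fig)
            figure_paths.append(p)
    return PipelineResult(table=table, results=results, summary=summary,
                          figure_paths=figure_paths)
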