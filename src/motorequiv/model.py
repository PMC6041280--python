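"""Model/Results interface over the equivalence statistics.

`MotorEquivalence` is constructed from an aggregated landmark table and
`fit()` computes every tool x parameter correlation matrix with Holm flags
and Fisher-z power; the returned `MotorEquivalenceResults` carries the
estimates, diagnostics (within-subject ANOVAs, tool comparisons), a
summary() table, and plotting helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conventions import LANDMARKS
from .landmarks import LandmarkRecord, LandmarkTable, aggregate
from .stats import (
    AnovaResult,
    CorrelationMatrix,
    PairedTestResult,
    compare_tools,
    effector_correlation_matrix,
    posthoc_paired_t_holm,
    rm_anova,
)

__all__ = ["MotorEquivalence", "MotorEquivalenceResults"]


class MotorEquivalence:
    """Cross-effector motor-equivalence analysis of a landmark table.

    Parameters
    ----------
    table : LandmarkTable
        Aggregated participant x tool x effector landmark means.
    alpha : float
        Overall family-wise level for each 6-entry Holm family.
    tails : int
        Tail convention for correlation p-values (2 by default).

    Examples
    --------
    >>> from motorequiv import simulate, reporting
    >>> cohort = simulate.generate_cohort(simulate.SimulationConfig(rng_seed=1))
    >>> table, _ = reporting.extract_cohort(cohort.recordings)
    >>> res = MotorEquivalence(table).fit()
    >>> print(res.summary())  # doctest: +SKIP
    """

    def __init__(self, table: LandmarkTable, alpha: float = 0.05, tails: int = 2):
        self.table = table
        self.alpha = alpha
        self.tails = tails

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "MotorEquivalence":
        """Build from a tidy frame (participant, tool, effector, parameter, value)."""
        return cls(LandmarkTable(data), **kwargs)

    @classmethod
    def from_records(cls, records: list[LandmarkRecord], **kwargs) -> "MotorEquivalence":
        """Build from raw per-cycle landmark records (aggregates them first)."""
        return cls(aggregate(records), **kwargs)

    def fit(self) -> "MotorEquivalenceResults":
        parameters = [
            p for p in LANDMARKS
            if p in set(self.table.data["parameter"])
        ]
        matrices = {
            (tool, parameter): effector_correlation_matrix(
                self.table, tool, parameter, alpha=self.alpha, tails=self.tails
            )
            for tool in self.table.tools
            for parameter in parameters
        }
        return MotorEquivalenceResults(
            model=self, matrices=matrices, parameters=parameters
        )


@dataclass
class MotorEquivalenceResults:
    """Fitted cross-effector correlation structure with diagnostics."""

    model: MotorEquivalence
    matrices: dict[tuple[str, str], CorrelationMatrix]
    parameters: list[str]
    _anova_cache: dict = field(default_factory=dict, repr=False)

    @property
    def table(self) -> LandmarkTable:
        return self.model.table

    def to_frame(self) -> pd.DataFrame:
        """All correlation entries as one tidy frame."""
        return pd.concat(
            [m.to_frame() for m in self.matrices.values()], ignore_index=True
        )

    # -- diagnostics -------------------------------------------------------
    def effector_anova(self, tool: str, parameter: str) -> AnovaResult:
        """Within-subject ANOVA comparing effector means for one cell."""
        key = (tool, parameter)
        if key not in self._anova_cache:
            wide = self.table.values_matrix(tool, parameter)
            self._anova_cache[key] = rm_anova(
                wide, effect=f"end-effector ({tool}, {parameter})"
            )
        return self._anova_cache[key]

    def effector_posthoc(self, tool: str, parameter: str) -> list[PairedTestResult]:
        wide = self.table.values_matrix(tool, parameter)
        return posthoc_paired_t_holm(wide, alpha=self.model.alpha)

    def tool_anova(self, parameter: str) -> AnovaResult:
        """Between-tool one-way ANOVA on per-participant effector means."""
        return compare_tools(self.table, parameter, alpha=self.model.alpha)

    # -- summaries ---------------------------------------------------------
    def summary_report(self):
        from .reporting import summarize_correlations

        return summarize_correlations(list(self.matrices.values()))

    def summary(self) -> str:
        """Human-readable summary table of all correlation matrices."""
        rep = self.summary_report()
        lines = []
        lines.append("Cross-effector motor-equivalence analysis")
        lines.append("=" * 72)
        lines.append(
            f"participants: {len(self.table.participants):>3}    "
            f"alpha: {self.model.alpha}    tails: {self.model.tails}"
        )
        lines.append(
            f"correlations: {rep.n_entries}  "
            f"significant (Holm): {rep.n_significant} "
            f"({rep.percent_significant:.1f}%)"
        )
        if rep.nonsig_min is not None:
            lines.append(
                f"non-significant r range: "
                f"[{rep.nonsig_min:.2f}, {rep.nonsig_max:.2f}]"
            )
        lines.append("-" * 72)
        lines.append(f"{'tool':<8} {'parameter':<26} {'pair':<24} "
                     f"{'r':>6} {'p':>8} {'sig':>4}")
        for (tool, parameter), m in self.matrices.items():
            for e in m.entries:
                pair = f"{e.pair[0]}~{e.pair[1]}"
                lines.append(
                    f"{tool:<8} {parameter:<26} {pair:<24} "
                    f"{e.r:>6.2f} {e.p:>8.4f} {'*' if e.holm_significant else '':>4}"
                )
        lines.append("=" * 72)
        return "\n".join(lines)

    # -- plotting ----------------------------------------------------------
    def plot_parameter_means(self, parameter: str, ax=None):
        """Bar chart of tool x effector cell means with SE error bars."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        data = self.table.data
        sub = data[data["parameter"] == parameter]
        tools = self.table.tools
        effectors = self.table.effectors
        width = 0.8 / len(effectors)
        x = np.arange(len(tools))
        for i, eff in enumerate(effectors):
            cells = sub[sub["effector"] == eff]
            means = [
                cells[cells["tool"] == t]["value"].mean() for t in tools
            ]
            ses = [
                cells[cells["tool"] == t]["value"].sem() for t in tools
            ]
            ax.bar(x + i * width, means, width, yerr=ses, capsize=2, label=eff)
        ax.set_xticks(x + 0.4 - width / 2)
        ax.set_xticklabels(tools)
        ax.set_ylabel(parameter)
        ax.legend(fontsize=7)
        return ax

    def plot_pair_scatter(self, tool: str, parameter: str, ax=None):
        """Scatter of each effector pair's participant values with r labels."""
        import matplotlib.pyplot as plt

        m = self.matrices[(tool, parameter)]
        wide = self.table.values_matrix(tool, parameter)
        if ax is None:
            fig, axes = plt.subplots(2, 3, figsize=(10, 6))
            axes = axes.ravel()
        else:
            axes = [ax] * 6
        for e, a in zip(m.entries, axes):
            a.scatter(wide[e.pair[0]], wide[e.pair[1]], s=14)
            a.set_xlabel(e.pair[0], fontsize=7)
            a.set_ylabel(e.pair[1], fontsize=7)
            a.set_title(f"r = {e.r:.2f}{'*' if e.holm_significant else ''}",
                        fontsize=8)
        return axes
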