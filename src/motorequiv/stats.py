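"""Cross-effector equivalence statistics.

The motor-equivalence question is operationalized as: do participants who
move with a large / fast / brisk signature with one end-effector do so with
every other end-effector?  For each tool and each landmark, the across-
participant Pearson correlation is computed for all six unordered effector
pairs; within each 6-entry matrix the Holm step-down correction controls
the family-wise error at an overall alpha.  Post-hoc power of the
correlation test is obtained from the Fisher z approximation.  Mean-level
effector and tool differences are assessed with a one-way within-subject
ANOVA (with Holm-corrected paired t post-hocs) and a between-tool one-way
ANOVA on per-participant effector means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multitest import multipletests

from .exceptions import CompletenessError, UndefinedCorrelationError
from .landmarks import LandmarkTable

__all__ = [
    "CorrelationEntry",
    "CorrelationMatrix",
    "AnovaResult",
    "PairedTestResult",
    "pearson_r",
    "r_to_p",
    "holm_adjust",
    "effector_correlation_matrix",
    "correlation_power",
    "rm_anova",
    "posthoc_paired_t_holm",
    "compare_tools",
]


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError(
            "correlation undefined for a zero-variance vector"
        )
    return float(sps.pearsonr(x, y).statistic)


def r_to_p(r: float, n: int, tails: int = 2) -> float:
    """Exact p-value of the zero-correlation t-test.

    t = r sqrt(n-2) / sqrt(1-r^2) with n-2 degrees of freedom; |r| = 1
    returns the boundary value p = 0.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    if abs(r) > 1:
        raise ValueError("|r| must be <= 1")
    if abs(r) == 1.0:
        return 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    return float(tails * sps.t.sf(abs(t), df=n - 2))


def holm_adjust(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Holm step-down significance flags, in input order.

    Sort ascending, compare the k-th smallest to alpha/(m-k+1), reject
    until the first failure.  Equal p-values always receive the same
    decision because the step-down thresholds increase with rank.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=alpha, method="holm")
    return reject


def correlation_power(rho: float, n: int, alpha: float = 0.05) -> float:
    """Power of the two-sided level-alpha test of zero correlation.

    Fisher z approximation: atanh(r) is approximately normal with mean
    atanh(rho) and SD 1/sqrt(n-3), so

        power = Phi(sqrt(n-3) atanh(rho) - z_{1-alpha/2})
              + Phi(-sqrt(n-3) atanh(rho) - z_{1-alpha/2})
    """
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    if n < 4:
        raise ValueError("need n >= 4")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    z_crit = sps.norm.ppf(1 - alpha / 2)
    shift = math.sqrt(n - 3) * math.atanh(rho)
    return float(sps.norm.cdf(shift - z_crit) + sps.norm.cdf(-shift - z_crit))


@dataclass(frozen=True)
class CorrelationEntry:
    pair: tuple[str, str]
    r: float
    p: float
    holm_significant: bool
    power: float


@dataclass
class CorrelationMatrix:
    """The six effector-pair correlations for one tool x parameter."""

    tool: str
    parameter: str
    n: int
    entries: list[CorrelationEntry]
    alpha: float = 0.05
    tails: int = 2

    def __post_init__(self) -> None:
        if len(self.entries) != 6:
            raise ValueError(f"expected 6 effector pairs, got {len(self.entries)}")

    @property
    def r_values(self) -> np.ndarray:
        return np.array([e.r for e in self.entries])

    @property
    def p_values(self) -> np.ndarray:
        return np.array([e.p for e in self.entries])

    @property
    def significant(self) -> np.ndarray:
        return np.array([e.holm_significant for e in self.entries])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "tool": self.tool,
                    "parameter": self.parameter,
                    "effector_a": e.pair[0],
                    "effector_b": e.pair[1],
                    "r": e.r,
                    "p": e.p,
                    "holm_significant": e.holm_significant,
                    "power": e.power,
                    "n": self.n,
                    "alpha": self.alpha,
                    "tails": self.tails,
                }
                for e in self.entries
            ]
        )


def effector_correlation_matrix(
    table: LandmarkTable,
    tool: str,
    parameter: str,
    alpha: float = 0.05,
    tails: int = 2,
) -> CorrelationMatrix:
    """All six pairwise across-participant correlations for one cell.

    Holm correction is applied within this 6-entry matrix at level
    ``alpha`` (not across matrices).
    """
    wide = table.values_matrix(tool, parameter)
    n = len(wide)
    if n < 3:
        raise CompletenessError(f"need >= 3 participants, have {n}")
    effectors = list(wide.columns)
    pairs = [
        (effectors[i], effectors[j])
        for i in range(len(effectors))
        for j in range(i + 1, len(effectors))
    ]
    rs = [pearson_r(wide[a].to_numpy(), wide[b].to_numpy()) for a, b in pairs]
    ps = [r_to_p(r, n, tails=tails) for r in rs]
    flags = holm_adjust(ps, alpha=alpha)
    entries = [
        CorrelationEntry(
            pair=pair,
            r=r,
            p=p,
            holm_significant=bool(flag),
            # Fisher z power needs n >= 4 (SD 1/sqrt(n-3))
            power=correlation_power(min(abs(r), 0.999999), n, alpha=alpha)
            if n >= 4 else math.nan,
        )
        for pair, r, p, flag in zip(pairs, rs, ps, flags)
    ]
    return CorrelationMatrix(tool=tool, parameter=parameter, n=n,
                             entries=entries, alpha=alpha, tails=tails)


@dataclass
class AnovaResult:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    posthoc: list["PairedTestResult"] | None = None


@dataclass(frozen=True)
class PairedTestResult:
    pair: tuple[str, str]
    t: float
    p: float
    holm_significant: bool
    degenerate: bool = False


def _as_condition_frame(values) -> pd.DataFrame:
    """Coerce a participants x conditions matrix to a DataFrame."""
    if isinstance(values, pd.DataFrame):
        df = values
    else:
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 2:
            raise ValueError("expected a 2-D participants x conditions matrix")
        df = pd.DataFrame(arr, columns=[f"c{i}" for i in range(arr.shape[1])])
    if df.isna().any().any():
        raise CompletenessError("missing cells in condition matrix")
    if df.shape[1] < 2 or df.shape[0] < 2:
        raise ValueError("need >= 2 conditions and >= 2 participants")
    return df


def rm_anova(values, effect: str = "condition") -> AnovaResult:
    """One-way within-subject (repeated-measures) ANOVA.

    F = MS_condition / MS_(condition x participant) with df (k-1),
    (k-1)(n-1); no sphericity correction is applied.
    """
    df = _as_condition_frame(values)
    n, k = df.shape
    # degenerate boundary: zero condition-by-participant interaction makes
    # MS_err = 0 and the F ratio undefined; by convention F = 0 when the
    # condition means are also equal
    mat = df.to_numpy(dtype=float)
    resid = mat - mat.mean(axis=0) - mat.mean(axis=1)[:, None] + mat.mean()
    scale = max(1.0, float(np.abs(mat).max()))
    if np.abs(resid).max() < 1e-12 * scale:
        cond_means = mat.mean(axis=0)
        if np.abs(cond_means - cond_means[0]).max() < 1e-12 * scale:
            return AnovaResult(effect=effect, F=0.0, df_num=k - 1,
                               df_den=(k - 1) * (n - 1), p=1.0)
        return AnovaResult(effect=effect, F=math.inf, df_num=k - 1,
                           df_den=(k - 1) * (n - 1), p=0.0)
    long = df.reset_index(names="subject").melt(
        id_vars="subject", var_name="condition", value_name="value"
    )
    res = AnovaRM(long, depvar="value", subject="subject",
                  within=["condition"]).fit()
    row = res.anova_table.iloc[0]
    return AnovaResult(
        effect=effect,
        F=float(row["F Value"]),
        df_num=int(row["Num DF"]),
        df_den=int(row["Den DF"]),
        p=float(row["Pr > F"]),
    )


def posthoc_paired_t_holm(values, alpha: float = 0.05) -> list[PairedTestResult]:
    """Paired t-tests for every condition pair, Holm-corrected."""
    df = _as_condition_frame(values)
    cols = list(df.columns)
    pairs = [
        (cols[i], cols[j])
        for i in range(len(cols))
        for j in range(i + 1, len(cols))
    ]
    ts, ps, degenerate = [], [], []
    for a, b in pairs:
        diff = df[a].to_numpy() - df[b].to_numpy()
        if np.std(diff) == 0:
            # zero-variance differences: no test possible; boundary result
            ts.append(0.0 if diff.mean() == 0 else math.inf)
            ps.append(1.0 if diff.mean() == 0 else 0.0)
            degenerate.append(True)
        else:
            t, p = sps.ttest_rel(df[a], df[b])
            ts.append(float(t))
            ps.append(float(p))
            degenerate.append(False)
    flags = holm_adjust(ps, alpha=alpha)
    return [
        PairedTestResult(pair=pair, t=t, p=p, holm_significant=bool(f),
                         degenerate=d)
        for pair, t, p, f, d in zip(pairs, ts, ps, flags, degenerate)
    ]


def compare_tools(
    table: LandmarkTable,
    parameter: str,
    alpha: float = 0.05,
    posthoc: bool = True,
) -> AnovaResult:
    """One-way ANOVA across tools on per-participant effector means.

    Each participant contributes one value per tool (the mean over the
    four effectors), giving 3 groups x n observations and df (2, 3n-3)
    for the three standard tools.  Pairwise post-hoc comparisons (Welch
    t with Holm correction) are attached when the omnibus test is
    significant.
    """
    groups = {}
    for tool in table.tools:
        wide = table.values_matrix(tool, parameter)
        groups[tool] = wide.mean(axis=1).to_numpy()
    if len(groups) < 2:
        raise ValueError("need at least 2 tools to compare")
    f, p = sps.f_oneway(*groups.values())
    k = len(groups)
    n_total = sum(len(v) for v in groups.values())
    result = AnovaResult(
        effect=f"tool ({parameter})",
        F=float(f),
        df_num=k - 1,
        df_den=n_total - k,
        p=float(p),
    )
    if posthoc and result.p < alpha:
        tools = list(groups)
        pairs = [
            (tools[i], tools[j])
            for i in range(len(tools))
            for j in range(i + 1, len(tools))
        ]
        ts, ps = [], []
        for a, b in pairs:
            t, pv = sps.ttest_ind(groups[a], groups[b])
            ts.append(float(t))
            ps.append(float(pv))
        flags = holm_adjust(ps, alpha=alpha)
        result.posthoc = [
            PairedTestResult(pair=pair, t=t, p=pv, holm_significant=bool(f_))
            for pair, t, pv, f_ in zip(pairs, ts, ps, flags)
        ]
    return result
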