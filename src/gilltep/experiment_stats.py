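"""Statistics for the paired / repeated-measures TEP design.

Each fish serves as its own control: TEP is read in triplicate in the
acclimation water, then again in each experimental medium.  Triplicates
are averaged and a junction-potential offset subtracted before analysis.
The inferential toolkit mirrors the design:

* two-tailed paired t-test on per-fish condition-minus-control differences,
* one-sample t-test from summary statistics (is the absolute TEP different
  from 0 mV?),
* two-sample t-test from summary statistics (Welch by default) for
  between-series comparisons,
* one-way repeated-measures ANOVA (subject-blocked) followed by Tukey's HSD
  on the within-subject error term, with a compact letter display (means
  not sharing a letter differ at p <= 0.05).

No sphericity correction is applied to the RM-ANOVA.  The significance
threshold for the letter display is fixed at alpha = 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM

from .exceptions import (
    DegenerateVarianceError,
    IncompleteDesignError,
    InvalidInputError,
)

__all__ = [
    "TEPMeasurement",
    "TEPSeries",
    "SummaryStat",
    "TTestResult",
    "RMAnovaResult",
    "collapse",
    "paired_t",
    "one_sample_t_summary",
    "unpaired_t_summary",
    "rm_anova_tukey",
    "compact_letters",
]

ALPHA = 0.05


@dataclass(frozen=True)
class TEPMeasurement:
    """One triplicate TEP reading of one fish in one condition."""

    fish_id: str
    series: str
    condition: str
    replicates: tuple[float, float, float]
    junction_offset: float = 0.0
    order_index: int = 0

    def __post_init__(self) -> None:
        if len(self.replicates) != 3:
            raise InvalidInputError(f"exactly 3 replicates required, got {len(self.replicates)}")
        if not all(math.isfinite(r) for r in self.replicates):
            raise InvalidInputError(f"replicates must be finite, got {self.replicates}")
        if not math.isfinite(self.junction_offset):
            raise InvalidInputError("junction offset must be finite")
        object.__setattr__(self, "replicates", tuple(float(r) for r in self.replicates))


@dataclass(frozen=True)
class TEPSeries:
    """A collection of measurements spanning fish x conditions in one design."""

    measurements: tuple[TEPMeasurement, ...]
    design: str = "repeated"  # "paired" | "repeated"

    def __post_init__(self) -> None:
        object.__setattr__(self, "measurements", tuple(self.measurements))
        conditions = {m.condition for m in self.measurements}
        if len(conditions) < 2:
            raise IncompleteDesignError("a series needs at least 2 conditions")

    def to_frame(self) -> pd.DataFrame:
        """Long-form table with one collapsed TEP value per fish x condition."""
        rows = [
            {
                "fish_id": m.fish_id,
                "series": m.series,
                "condition": m.condition,
                "order": m.order_index,
                "tep_mV": collapse(m),
            }
            for m in self.measurements
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SummaryStat:
    """Group mean +/- SEM with sample size (e.g. -22.3 +/- 0.8 mV, n = 78)."""

    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InvalidInputError(f"n must be >= 2, got {self.n}")
        if not (self.sem > 0.0 and math.isfinite(self.sem)):
            raise InvalidInputError(f"sem must be positive, got {self.sem}")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class RMAnovaResult:
    """Repeated-measures ANOVA with Tukey HSD and compact letter display."""

    f: float
    df_treatment: int
    df_error: int
    p: float
    ms_error: float
    condition_means: Mapping[str, float]
    tukey: pd.DataFrame  # columns: a, b, diff, q, p
    letters: Mapping[str, str]


def collapse(measurement: TEPMeasurement) -> float:
    """Average the triplicate readings and subtract the junction offset."""
    return float(np.mean(measurement.replicates)) - measurement.junction_offset


def paired_t(differences: Sequence[float]) -> TTestResult:
    """Two-tailed Student's paired t-test on condition-minus-control differences."""
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise InvalidInputError(f"need at least 2 paired differences, got {d.size}")
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise DegenerateVarianceError("all paired differences are identical; t is undefined")
    n = d.size
    t = d.mean() / (sd / math.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=df, p=float(p))


def one_sample_t_summary(stat: SummaryStat, mu0: float = 0.0) -> TTestResult:
    """Two-tailed one-sample t-test against *mu0* from mean/SEM/n."""
    t = (stat.mean - mu0) / stat.sem
    df = stat.n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=df, p=float(p))


def unpaired_t_summary(a: SummaryStat, b: SummaryStat, variant: str = "welch") -> TTestResult:
    """Two-tailed two-sample t-test from summary statistics.

    ``variant="welch"`` (default) uses the Welch-Satterthwaite df and does
    not pool variances; ``variant="pooled"`` is the classical equal-variance
    Student test.
    """
    se_a2 = a.sem**2
    se_b2 = b.sem**2
    if variant == "welch":
        se2 = se_a2 + se_b2
        t = (a.mean - b.mean) / math.sqrt(se2)
        df = se2**2 / (se_a2**2 / (a.n - 1) + se_b2**2 / (b.n - 1))
    elif variant == "pooled":
        var_a = se_a2 * a.n  # sample variance back-computed from the SEM
        var_b = se_b2 * b.n
        df = a.n + b.n - 2
        pooled = ((a.n - 1) * var_a + (b.n - 1) * var_b) / df
        t = (a.mean - b.mean) / math.sqrt(pooled * (1.0 / a.n + 1.0 / b.n))
    else:
        raise InvalidInputError(f"variant must be 'welch' or 'pooled', got {variant!r}")
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p=float(p))


def _design_matrix(series: TEPSeries) -> pd.DataFrame:
    """Validate completeness and pivot to a fish x condition value matrix."""
    frame = series.to_frame()
    dup = frame.duplicated(subset=["fish_id", "condition"])
    if dup.any():
        raise IncompleteDesignError("duplicate fish x condition cells in the series")
    matrix = frame.pivot(index="fish_id", columns="condition", values="tep_mV")
    if matrix.isna().any().any():
        missing = [
            f"{fish}/{cond}"
            for fish in matrix.index
            for cond in matrix.columns
            if pd.isna(matrix.loc[fish, cond])
        ]
        raise IncompleteDesignError(f"incomplete fish x condition table; missing cells: {missing}")
    if matrix.shape[0] < 2:
        raise IncompleteDesignError("need at least 2 fish for a repeated-measures analysis")
    return matrix


def compact_letters(
    order: Sequence[str],
    significant_pairs: Iterable[tuple[str, str]],
) -> dict[str, str]:
    """Compact letter display by the insert-and-absorb algorithm.

    *order* lists the groups in display order (typically sorted by mean);
    groups in *significant_pairs* must not share any letter.  Returns a
    mapping group -> letter string such as ``{"control": "a", "acid": "b"}``.
    """
    sig = {frozenset(p) for p in significant_pairs}
    columns: list[frozenset[str]] = [frozenset(order)]
    for pair in sig:
        i, j = tuple(pair)
        for col in [c for c in columns if i in c and j in c]:
            columns.remove(col)
            columns.extend([col - {i}, col - {j}])
        # deduplicate and absorb proper subsets
        columns = list(dict.fromkeys(columns))
        columns = [c for c in columns if not any(c < d for d in columns)]
    rank = {g: k for k, g in enumerate(order)}
    columns.sort(key=lambda c: min(rank[g] for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, list[str]] = {g: [] for g in order}
    for letter, col in zip(alphabet, columns):
        for g in col:
            letters[g].append(letter)
    return {g: "".join(sorted(ls)) for g, ls in letters.items()}


def rm_anova_tukey(series: TEPSeries, alpha: float = ALPHA) -> RMAnovaResult:
    """Subject-blocked one-way RM-ANOVA followed by Tukey's HSD.

    The omnibus F is computed by ``statsmodels`` (``AnovaRM``, no sphericity
    correction).  Tukey's test compares condition means using the
    within-subject error mean square: q = |mean_a - mean_b| / sqrt(MS_e/n),
    referred to the studentized-range distribution with k groups and the
    RM-ANOVA error df.  The compact letter display labels conditions so
    that means not sharing a letter differ at *alpha*.
    """
    matrix = _design_matrix(series)
    frame = series.to_frame()
    n_fish, k = matrix.shape

    fit = AnovaRM(
        data=frame, depvar="tep_mV", subject="fish_id", within=["condition"]
    ).fit()
    row = fit.anova_table.iloc[0]
    f_stat = float(row["F Value"])
    df_t = int(round(row["Num DF"]))
    df_e = int(round(row["Den DF"]))
    p = float(row["Pr > F"])

    # Within-subject error mean square (residual after removing fish and
    # condition effects), needed for the Tukey q statistics.
    values = matrix.to_numpy(dtype=float)
    resid = values - values.mean(axis=1, keepdims=True) - values.mean(axis=0, keepdims=True) + values.mean()
    ms_error = float((resid**2).sum() / df_e)

    means = matrix.mean(axis=0)
    if not math.isfinite(f_stat):  # 0/0 when conditions are exactly identical
        ss_treat = n_fish * float(((means - values.mean()) ** 2).sum())
        f_stat = 0.0 if ss_treat <= 1e-12 else math.inf
        p = 1.0 if f_stat == 0.0 else 0.0
    order = list(means.sort_values().index)
    rows = []
    sig_pairs = []
    for a, b in combinations(order, 2):
        diff = float(means[a] - means[b])
        if ms_error > 0.0:
            q = abs(diff) / math.sqrt(ms_error / n_fish)
            p_pair = float(stats.studentized_range.sf(q, k, df_e))
        else:  # identical conditions: nothing can be significant
            q, p_pair = 0.0, 1.0
        rows.append({"a": a, "b": b, "diff": diff, "q": q, "p": p_pair})
        if p_pair <= alpha:
            sig_pairs.append((a, b))
    tukey = pd.DataFrame(rows, columns=["a", "b", "diff", "q", "p"])
    letters = compact_letters(order, sig_pairs)

    return RMAnovaResult(
        f=f_stat,
        df_treatment=df_t,
        df_error=df_e,
        p=p,
        ms_error=ms_error,
        condition_means=dict(means),
        tukey=tukey,
        letters=letters,
    )
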