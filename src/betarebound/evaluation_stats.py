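"""Normality-gated statistical comparisons and QUEST satisfaction scoring.

Comparisons between conditions are gated on Shapiro–Wilk normality of each
group (reject normality when p < alpha): two related samples go to a
paired t-test when both groups look normal and to the Wilcoxon signed-rank
test otherwise; three related samples go to repeated-measures ANOVA or the
Friedman test by the same rule.

QUEST (Quebec User Evaluation of Satisfaction with Assistive Technology)
responses are 1–5 Likert scores over seven core device criteria plus four
extended ones; a subject's score is the mean over the answered criteria.
Scores are kept at full precision internally; the conventional display
rule for these tables truncates (not rounds) to two decimals, and group
averages for display are taken over the truncated subject totals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CORE_CRITERIA",
    "EXTENDED_CRITERIA",
    "QUESTResponses",
    "QuestScores",
    "ComparisonReport",
    "choose_and_compare",
    "score_quest",
    "truncate2",
]

CORE_CRITERIA = (
    "Dimensions",
    "Weight",
    "Adjustment",
    "Safety",
    "Ease of use",
    "Effectiveness",
    "Information/Instructions",
)
EXTENDED_CRITERIA = ("Reliability", "Speed", "Learning", "Aesthetic design")


@dataclass(frozen=True)
class QUESTResponses:
    subject: str
    scores: dict[str, int]

    def __post_init__(self) -> None:
        for crit, s in self.scores.items():
            if not 1 <= int(s) <= 5:
                raise ValueError(
                    f"subject {self.subject}: score {s} for {crit!r} outside 1..5"
                )


def truncate2(x: float) -> float:
    """Truncate toward zero at two decimals (the table display convention)."""
    return math.trunc(x * 100.0) / 100.0


@dataclass(frozen=True)
class QuestScores:
    """Per-subject and group QUEST totals, full precision and display."""

    core_totals: dict[str, float]
    extended_totals: dict[str, float]
    core_group_average: float            # full precision
    extended_group_average: float
    core_group_average_display: float    # truncated-total convention
    extended_group_average_display: float
    per_criterion_average: dict[str, float]

    def core_total_display(self, subject: str) -> float:
        return truncate2(self.core_totals[subject])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subject": s,
                "core_total": self.core_totals[s],
                "core_total_display": truncate2(self.core_totals[s]),
                "extended_total": self.extended_totals.get(s),
            }
            for s in self.core_totals
        ]
        return pd.DataFrame(rows)


def score_quest(responses: list[QUESTResponses]) -> QuestScores:
    """Score a cohort's QUEST responses.

    Every subject must have answered all seven core criteria; extended
    criteria are optional but must be uniform across subjects.
    """
    if not responses:
        raise ValueError("no QUEST responses given")
    have_extended = [
        all(c in r.scores for c in EXTENDED_CRITERIA) for r in responses
    ]
    if any(have_extended) and not all(have_extended):
        raise ValueError("extended criteria must be answered by all or none")

    core_totals: dict[str, float] = {}
    ext_totals: dict[str, float] = {}
    for r in responses:
        for crit in CORE_CRITERIA:
            if crit not in r.scores:
                raise ValueError(
                    f"subject {r.subject} is missing core criterion {crit!r}"
                )
        core_totals[r.subject] = float(
            np.mean([r.scores[c] for c in CORE_CRITERIA])
        )
        if all(have_extended):
            ext_totals[r.subject] = float(
                np.mean([r.scores[c] for c in EXTENDED_CRITERIA])
            )

    crit_avg = {}
    for crit in CORE_CRITERIA + (EXTENDED_CRITERIA if ext_totals else ()):
        vals = [r.scores[crit] for r in responses if crit in r.scores]
        crit_avg[crit] = float(np.mean(vals))

    core_disp = truncate2(float(np.mean([truncate2(v) for v in core_totals.values()])))
    ext_avg = float(np.mean(list(ext_totals.values()))) if ext_totals else float("nan")
    ext_disp = (
        truncate2(float(np.mean([truncate2(v) for v in ext_totals.values()])))
        if ext_totals else float("nan")
    )
    return QuestScores(
        core_totals=core_totals,
        extended_totals=ext_totals,
        core_group_average=float(np.mean(list(core_totals.values()))),
        extended_group_average=ext_avg,
        core_group_average_display=core_disp,
        extended_group_average_display=ext_disp,
        per_criterion_average=crit_avg,
    )


@dataclass(frozen=True)
class ComparisonReport:
    groups: tuple[str, ...]
    p_value: float
    test_used: str
    alpha: float
    normality_flags: dict[str, bool]     # True = compatible with normality
    shapiro_p: dict[str, float]
    statistic: float | None = None
    holm_adjusted: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _normality(samples: dict[str, np.ndarray], alpha: float):
    flags, pvals = {}, {}
    for name, x in samples.items():
        if np.ptp(x) == 0:
            # constant sample: Shapiro is undefined; cannot support normality
            flags[name], pvals[name] = False, 0.0
            continue
        p = float(stats.shapiro(x).pvalue)
        pvals[name] = p
        flags[name] = p >= alpha
    return flags, pvals


def choose_and_compare(
    samples: dict[str, np.ndarray],
    alpha: float = 0.05,
) -> ComparisonReport:
    """Paired comparison of 2 or 3 related samples with a normality gate.

    ``samples`` maps group name to equal-length arrays paired by subject.
    """
    if len(samples) not in (2, 3):
        raise ValueError("choose_and_compare handles 2 or 3 related samples")
    arrays = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    lengths = {len(v) for v in arrays.values()}
    if len(lengths) != 1:
        raise ValueError("related samples must be paired (equal lengths)")
    n = lengths.pop()
    if n < 3:
        raise ValueError(f"need at least 3 subjects per group, got {n}")

    flags, pvals = _normality(arrays, alpha)
    names = tuple(arrays)
    all_normal = all(flags.values())

    if len(arrays) == 2:
        a, b = (arrays[k] for k in names)
        diffs = a - b
        if np.all(diffs == 0):
            # no effect at all: maximal attainable p
            test = "paired_t" if all_normal else "wilcoxon"
            return ComparisonReport(names, 1.0, test, alpha, flags, pvals, 0.0)
        if all_normal:
            res = stats.ttest_rel(a, b)
            test = "paired_t"
        else:
            res = stats.wilcoxon(a, b)
            test = "wilcoxon"
        return ComparisonReport(
            names, float(res.pvalue), test, alpha, flags, pvals,
            float(res.statistic),
        )

    if all_normal:
        from statsmodels.stats.anova import AnovaRM

        df = pd.DataFrame(
            {
                "subject": np.tile(np.arange(n), len(names)),
                "condition": np.repeat(names, n),
                "value": np.concatenate([arrays[k] for k in names]),
            }
        )
        tbl = AnovaRM(df, "value", "subject", within=["condition"]).fit().anova_table
        return ComparisonReport(
            names, float(tbl["Pr > F"].iloc[0]), "repeated_anova", alpha,
            flags, pvals, float(tbl["F Value"].iloc[0]),
        )
    res = stats.friedmanchisquare(*(arrays[k] for k in names))
    return ComparisonReport(
        names, float(res.pvalue), "friedman", alpha, flags, pvals,
        float(res.statistic),
    )


def compare_channels(
    values: dict[str, dict[str, np.ndarray]],
    alpha: float = 0.05,
    holm: bool = False,
) -> pd.DataFrame:
    """Per-channel condition comparison (rows mirror a p-value table).

    ``values[channel][condition]`` is the per-subject vector.  ``holm``
    applies a Holm step-down adjustment across channels (off by default:
    raw p-values are the primary report).
    """
    rows = []
    for channel, groups in values.items():
        rep = choose_and_compare(groups, alpha)
        rows.append(
            {
                "channel": channel,
                "comparison": " vs ".join(rep.groups),
                "test": rep.test_used,
                "p_value": rep.p_value,
            }
        )
    df = pd.DataFrame(rows)
    if holm:
        from statsmodels.stats.multitest import multipletests

        df["p_holm"] = multipletests(df["p_value"], method="holm")[1]
    return df
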