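"""Group statistics for a challenge/validation study.

Implements the statistics used to validate the panels on an acute
inflammation model: baseline-normalized percent change, pooled-variance
two-sample t-tests between treated and control groups, an additive
two-way block x group ANOVA (the block factor is dropped downstream
when non-significant), a two-sided variance-ratio F-test, and the
clinical endpoint rule for daily welfare scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

CLINICAL_ITEMS = (
    "dehydration",
    "piloerection",
    "cleanliness",
    "lesions",
    "aggressiveness",
    "passivity",
    "repetitive_behaviors",
)

#: cumulative-score endpoint threshold (strictly greater than)
ENDPOINT_CUMULATIVE = 16
#: any single item at this score triggers the endpoint
ENDPOINT_ITEM_MAX = 4


@dataclass
class PairedChange:
    animal_id: str
    variable: str
    baseline: float
    followup: float
    pct_change: float | None  # None when baseline <= 0
    defined: bool


def percent_change(baseline: float, followup: float) -> float:
    """100 x (followup - baseline) / baseline; baseline must be > 0."""
    if baseline <= 0:
        raise ValueError("percent change undefined for baseline <= 0")
    return 100.0 * (followup - baseline) / baseline


def paired_changes(
    counts: pd.DataFrame,
    baseline: str,
    followup: str,
    value_col: str = "cells_per_uL",
    variable_col: str = "node",
) -> list[PairedChange]:
    """Per-animal percent change between two timepoints, flagging (not
    dropping) animals whose baseline is zero."""
    out = []
    piv = counts.pivot_table(
        index=["animal_id", variable_col], columns="timepoint", values=value_col
    )
    for (animal, var), row in piv.iterrows():
        b, f = row.get(baseline, np.nan), row.get(followup, np.nan)
        if np.isnan(b) or np.isnan(f):
            continue
        if b > 0:
            out.append(PairedChange(animal, var, b, f, percent_change(b, f), True))
        else:
            out.append(PairedChange(animal, var, b, f, None, False))
    return out


def two_sample_test(group_a, group_b) -> tuple[float, float, float]:
    """Two-sided pooled-variance Student's t-test.

    Returns (t, p, mean_a - mean_b).  Degenerate inputs (zero pooled
    variance) give p = 1 for equal means and p = 0 otherwise.
    Significance thresholds are applied by the caller, not here.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    diff = float(a.mean() - b.mean())
    sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
        len(a) + len(b) - 2
    )
    if sp2 == 0:
        return (0.0, 1.0, diff) if diff == 0 else (math_inf_sign(diff), 0.0, diff)
    t = diff / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
    p = 2 * stats.t.sf(abs(t), len(a) + len(b) - 2)
    return float(t), float(p), diff


def math_inf_sign(x: float) -> float:
    return float(np.inf) if x > 0 else float(-np.inf)


def welch_test(group_a, group_b) -> tuple[float, float, float]:
    """Unequal-variance alternative to :func:`two_sample_test`."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p), float(a.mean() - b.mean())


def block_group_anova(values, group_labels, block_labels):
    """Additive two-factor ANOVA (group + block) from scratch.

    Returns (F_group, p_group, F_block, p_block).  Sums of squares are
    the balanced-design mean-deviation sums; the residual absorbs the
    interaction.  A single block degenerates the design; every
    (block, group) cell must be non-empty.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(group_labels)
    b = np.asarray(block_labels)
    if not (len(y) == len(g) == len(b)):
        raise ValueError("values, group_labels, block_labels must align")
    groups, blocks = np.unique(g), np.unique(b)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if len(blocks) < 2:
        raise ValueError("single block: use a one-way test instead")
    for gg in groups:
        for bb in blocks:
            if not ((g == gg) & (b == bb)).any():
                raise ValueError(f"empty cell: group {gg!r}, block {bb!r}")
    grand = y.mean()
    n = len(y)
    ss_total = ((y - grand) ** 2).sum()
    ss_group = sum(((g == gg).sum()) * (y[g == gg].mean() - grand) ** 2 for gg in groups)
    ss_block = sum(((b == bb).sum()) * (y[b == bb].mean() - grand) ** 2 for bb in blocks)
    df_group = len(groups) - 1
    df_block = len(blocks) - 1
    df_resid = n - 1 - df_group - df_block
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    ss_resid = ss_total - ss_group - ss_block
    ms_resid = max(ss_resid, 0.0) / df_resid
    if ms_resid == 0:
        f_group = np.inf if ss_group > 0 else 0.0
        f_block = np.inf if ss_block > 0 else 0.0
    else:
        f_group = (ss_group / df_group) / ms_resid
        f_block = (ss_block / df_block) / ms_resid
    p_group = float(stats.f.sf(f_group, df_group, df_resid))
    p_block = float(stats.f.sf(f_block, df_block, df_resid))
    return float(f_group), p_group, float(f_block), p_block


def variance_ratio_test(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided F-test for equality of variances.

    Convention: the larger sample variance goes in the numerator;
    p = 2 x the upper tail, capped at 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per sample")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va >= vb:
        num_v, num_df, den_v, den_df = va, len(a) - 1, vb, len(b) - 1
    else:
        num_v, num_df, den_v, den_df = vb, len(b) - 1, va, len(a) - 1
    if den_v == 0:
        raise ValueError("zero variance in denominator sample")
    f = num_v / den_v
    p = min(1.0, 2 * float(stats.f.sf(f, num_df, den_df)))
    return float(f), p


@dataclass
class ClinicalScore:
    """Seven daily welfare item scores, each 0 (none) to 4 (high)."""

    scores: dict[str, int]

    def __post_init__(self):
        unknown = set(self.scores) - set(CLINICAL_ITEMS)
        if unknown:
            raise ValueError(f"unknown clinical items: {sorted(unknown)}")
        missing = set(CLINICAL_ITEMS) - set(self.scores)
        if missing:
            raise ValueError(f"missing clinical items: {sorted(missing)}")
        for item, s in self.scores.items():
            if not (isinstance(s, (int, np.integer)) and 0 <= s <= 4):
                raise ValueError(f"item {item!r} score {s!r} outside 0-4")

    @property
    def total(self) -> int:
        return int(sum(self.scores.values()))


def endpoint_reached(score: ClinicalScore) -> tuple[bool, str | None]:
    """Humane-endpoint rule for one day's scores.

    True when any single item reaches 4 or the cumulative score exceeds
    16 (strict); the reason names the rule that fired.  Monotone in
    every item.
    """
    maxed = [item for item, s in score.scores.items() if s == ENDPOINT_ITEM_MAX]
    if maxed:
        return True, f"single item at {ENDPOINT_ITEM_MAX}: {', '.join(sorted(maxed))}"
    if score.total > ENDPOINT_CUMULATIVE:
        return True, f"cumulative score {score.total} > {ENDPOINT_CUMULATIVE}"
    return False, None


@dataclass
class GroupComparison:
    """Per-variable group comparison results plus pipeline decisions."""

    table: pd.DataFrame
    block_significant: bool
    block_p: dict[str, float] = field(default_factory=dict)
    mode: str = "pct_change"
    notes: list[str] = field(default_factory=list)


def compare_groups(
    counts: pd.DataFrame,
    baseline: str,
    followup: str,
    group_col: str = "group",
    block_col: str = "block",
    value_col: str = "cells_per_uL",
    variable_col: str = "node",
    mode: str = "pct_change",
    alpha: float = 0.05,
    adjust: str | None = None,
) -> GroupComparison:
    """Treated-vs-control comparison for every subset variable.

    First checks the block factor with an additive block x group ANOVA
    per variable; when no variable shows a significant block effect the
    block is dropped from the downstream test (logged in ``notes``).
    Then compares groups per variable with a pooled-variance t-test on
    the percent change from baseline (``mode='pct_change'``) or on the
    raw follow-up values (``mode='followup'``).  ``adjust='bh'``
    optionally applies a Benjamini-Hochberg correction (off by default).
    """
    if mode not in ("pct_change", "followup"):
        raise ValueError(f"unknown mode {mode!r}")
    notes: list[str] = []
    meta = counts[["animal_id", group_col, block_col]].drop_duplicates("animal_id")
    meta = meta.set_index("animal_id")

    if mode == "pct_change":
        changes = paired_changes(counts, baseline, followup, value_col, variable_col)
        undefined = [c for c in changes if not c.defined]
        if undefined:
            notes.append(
                f"{len(undefined)} animal/variable pairs had zero baseline; flagged, excluded from tests"
            )
        data = pd.DataFrame(
            [(c.animal_id, c.variable, c.pct_change) for c in changes if c.defined],
            columns=["animal_id", "variable", "value"],
        )
    else:
        sub = counts[counts["timepoint"] == followup]
        data = sub.rename(columns={variable_col: "variable", value_col: "value"})[
            ["animal_id", "variable", "value"]
        ]

    data = data.join(meta, on="animal_id")

    # block screen across variables
    block_p: dict[str, float] = {}
    for var, sub in data.groupby("variable", sort=False):
        try:
            _, _, _, pb = block_group_anova(
                sub["value"], sub[group_col], sub[block_col]
            )
            block_p[var] = pb
        except ValueError:
            continue
    block_significant = any(p <= alpha for p in block_p.values())
    if not block_significant:
        notes.append(
            f"block factor non-significant for all {len(block_p)} variables at alpha={alpha}; "
            "dropped from group tests"
        )

    rows = []
    groups = sorted(data[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, found {groups}")
    ga, gb = groups
    for var, sub in data.groupby("variable", sort=False):
        va = sub.loc[sub[group_col] == ga, "value"].to_numpy()
        vb = sub.loc[sub[group_col] == gb, "value"].to_numpy()
        if len(va) < 2 or len(vb) < 2:
            rows.append((var, np.nan, np.nan, np.nan, np.nan, np.nan))
            continue
        t, p, diff = two_sample_test(va, vb)
        rows.append((var, float(np.mean(va)), float(np.mean(vb)), diff, t, p))
    table = pd.DataFrame(
        rows,
        columns=["variable", f"mean_{ga}", f"mean_{gb}", "mean_difference", "t", "p"],
    )
    if adjust == "bh":
        table["p_adjusted"] = _benjamini_hochberg(table["p"].to_numpy())
        notes.append("Benjamini-Hochberg adjustment applied (optional, off by default)")
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    table["significant"] = table["p"] <= alpha
    return GroupComparison(table, block_significant, block_p, mode, notes)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    ok = ~np.isnan(p)
    q = np.full_like(p, np.nan, dtype=float)
    pv = p[ok]
    m = len(pv)
    order = np.argsort(pv)
    ranked = pv[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q
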