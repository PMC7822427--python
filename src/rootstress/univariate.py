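"""Per-trait univariate screening: one-way ANOVA, Tukey HSD and compact
letter displays, mirroring the published summary-table layout.

Each trait of each root type is tested across the four stress treatments
with a classical one-way ANOVA; all pairwise treatment contrasts use the
studentized-range (Tukey HSD / Tukey–Kramer) test, and the all-pairs
pattern is summarised as a compact letter display in which two treatments
share a letter iff they do not differ significantly.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaResult",
    "one_way_anova",
    "tukey_hsd",
    "compact_letter_display",
    "trait_screen",
    "percent_change",
    "DegenerateVarianceError",
]


class DegenerateVarianceError(ValueError):
    """All observations identical: no variance to partition."""


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    trait: str = ""
    root_type: str = ""


def _check_groups(groups: list[np.ndarray]) -> list[np.ndarray]:
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least two observations")
    flat = np.concatenate(groups)
    if np.ptp(flat) == 0:
        raise DegenerateVarianceError("all observations identical")
    return groups


def one_way_anova(groups: list[np.ndarray], trait: str = "", root_type: str = "") -> AnovaResult:
    """Classical between/within variance decomposition with an F test."""
    groups = _check_groups(groups)
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    f, p = stats.f_oneway(*groups)
    return AnovaResult(F=float(f), df_between=k - 1, df_within=n_total - k,
                       p=float(p), trait=trait, root_type=root_type)


def tukey_hsd(groups: list[np.ndarray], labels: list[str] | None = None,
              alpha: float = 0.05) -> pd.DataFrame:
    """All k(k-1)/2 pairwise comparisons with studentized-range p-values.

    Unequal group sizes use the Tukey–Kramer form.  Returns a frame with
    columns ``group_a, group_b, diff, p, significant``.
    """
    groups = _check_groups(groups)
    if labels is None:
        labels = [f"g{i}" for i in range(len(groups))]
    if len(labels) != len(groups):
        raise ValueError("labels/groups length mismatch")
    res = stats.tukey_hsd(*groups)
    rows = []
    for i, j in combinations(range(len(groups)), 2):
        p = float(res.pvalue[i, j])
        rows.append({
            "group_a": labels[i],
            "group_b": labels[j],
            "diff": float(np.mean(groups[i]) - np.mean(groups[j])),
            "p": p,
            "significant": bool(p < alpha),
        })
    return pd.DataFrame(rows)


def compact_letter_display(pairwise: pd.DataFrame,
                           means: dict[str, float] | None = None) -> dict[str, str]:
    """Insert-and-absorb letter assignment from an all-pairs table.

    Two groups share a letter iff their comparison is not significant.
    Letters are assigned so that the group with the largest mean carries
    "a" (the convention of the published tables); without means, the
    order of first appearance is used.  Non-transitive significance
    patterns are representable (a group may carry several letters).
    """
    labels: list[str] = []
    for row in pairwise.itertuples():
        for g in (row.group_a, row.group_b):
            if g not in labels:
                labels.append(g)
    if means is not None:
        labels.sort(key=lambda g: -means[g])

    columns: list[set[str]] = [set(labels)]
    for row in pairwise.itertuples():
        if not row.significant:
            continue
        a, b = row.group_a, row.group_b
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            columns.extend([col - {a}, col - {b}])
        # absorb columns that became subsets of another
        columns = [c for c in columns
                   if c and not any(c < other for other in columns if other is not c)]
        # absorb exact duplicates
        dedup: list[set[str]] = []
        for c in columns:
            if c not in dedup:
                dedup.append(c)
        columns = dedup

    # order letter columns by the best-ranked group they contain
    rank = {g: i for i, g in enumerate(labels)}
    columns.sort(key=lambda c: min(rank[g] for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: [] for g in labels}
    for letter, col in zip(alphabet, columns):
        for g in col:
            out[g].append(letter)
    return {g: ",".join(sorted(ls)) for g, ls in out.items()}


def _share_letter(a: str, b: str) -> bool:
    return bool(set(a.split(",")) & set(b.split(",")))


def trait_screen(dataset, alpha: float = 0.05, control: str = "Control",
                 letters: bool = True) -> pd.DataFrame:
    """One ANOVA + Tukey + letter display per (root type, trait).

    Returns one row per trait with the F statistic, p-value, per-treatment
    ``mean (SE) letters`` summaries and two significance flags:

    ``anova_significant``
        the one-way ANOVA p-value is below ``alpha``;
    ``differs_from_control``
        the treatment shares no letter with the control for at least one
        non-control treatment (the published tables' reading).

    Degenerate traits (no variance) are flagged, not raised.  With
    ``letters=False`` the Tukey/letter step is skipped (fast ANOVA-only
    screening); letter columns are empty and ``differs_from_control``
    is not computed.
    """
    treatments = dataset.treatments
    rows = []
    for (root_type, trait), grp in dataset.traits.groupby(
            ["root_type", "trait"], sort=False):
        by_t = {t: grp.loc[grp["treatment"] == t, "value"].to_numpy()
                for t in treatments}
        groups = [by_t[t] for t in treatments]
        means = {t: float(np.mean(v)) for t, v in by_t.items()}
        ses = {t: float(np.std(v, ddof=1) / np.sqrt(len(v))) for t, v in by_t.items()}
        row = {"root_type": root_type, "trait": trait}
        try:
            anova = one_way_anova(groups, trait=trait, root_type=root_type)
            if letters:
                pairwise = tukey_hsd(groups, labels=list(treatments), alpha=alpha)
                cld = compact_letter_display(pairwise, means=means)
            else:
                cld = {t: "" for t in treatments}
            degenerate = False
        except DegenerateVarianceError:
            anova, cld, degenerate = None, {t: "a" for t in treatments}, True
        row.update({
            "F": anova.F if anova else np.nan,
            "p": anova.p if anova else np.nan,
            "degenerate": degenerate,
            "anova_significant": bool(anova and anova.p < alpha),
        })
        for t in treatments:
            row[f"{t}_mean"] = means[t]
            row[f"{t}_se"] = ses[t]
            row[f"{t}_letters"] = cld[t]
        row["differs_from_control"] = any(
            not _share_letter(cld[t], cld[control])
            for t in treatments if t != control
        ) if (letters and control in treatments) else False
        rows.append(row)
    return pd.DataFrame(rows)


def percent_change(summary: pd.DataFrame, treatment: str,
                   control: str = "Control") -> pd.DataFrame:
    """Percent change of each trait's mean under ``treatment`` vs control.

    ``summary`` is the per-cell frame of ``PlantDataset.summary()`` or
    ``FixtureCollection.to_frame()`` (columns root_type, trait,
    treatment, mean).  Positive values are increases.
    """
    wide = summary.pivot_table(index=["root_type", "trait"], columns="treatment",
                               values="mean", sort=False)
    out = wide[[control, treatment]].copy()
    out.columns = ["control_mean", "treatment_mean"]
    out["percent_change"] = 100.0 * (out["treatment_mean"] - out["control_mean"]) / out["control_mean"]
    return out.reset_index()


def render_table(screen: pd.DataFrame, treatments: list[str]) -> pd.DataFrame:
    """Published-style layout: one row per trait, ``mean (SE) letters``
    text per treatment column."""
    out = screen[["root_type", "trait"]].copy()
    for t in treatments:
        out[t] = [
            f"{m:.4g} ({s:.3g}) {l}"
            for m, s, l in zip(screen[f"{t}_mean"], screen[f"{t}_se"], screen[f"{t}_letters"])
        ]
    return out
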