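"""Additive / synergistic / antagonistic classification of combined stress.

For a trait with control mean ``m_c``, the observed effect size of each
combined-stress plant is ``Ob_i = |ob_i - m_c| / m_c``, and each single
stressor contributes an independent effect size
``Ind = |m_stress - m_c| / m_c``.  Under a multiplicative risk model the
expected additive effect of two stressors is

    Ex = Ind_D + Ind_H - Ind_D * Ind_H

which avoids the inflation of a plain sum (and saturates at 1 when both
single effects reach 1).  The combined response is classified from the
two-sided 95% confidence interval of mean(Ob_i - Ex):

* synergistic   — the whole CI is above zero (effect larger than expected)
* antagonistic  — the whole CI is below zero (smaller than expected)
* additive      — the CI crosses zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .univariate import trait_screen

__all__ = [
    "EffectSizes",
    "InteractionResult",
    "observed_effect_size",
    "independent_effect_size",
    "expected_additive",
    "classify_interaction",
    "interaction_screen",
    "point_interaction_from_means",
]


@dataclass(frozen=True)
class EffectSizes:
    """Dimensionless absolute effect sizes of one trait."""

    trait: str
    root_type: str
    ob: np.ndarray          # per combined-stress plant
    ind_d: float
    ind_h: float
    ex: float


@dataclass(frozen=True)
class InteractionResult:
    trait: str
    root_type: str
    mean_diff: float        # mean(Ob - Ex)
    ci_low: float
    ci_high: float
    label: str              # synergistic | additive | antagonistic
    direction: str = ""     # increase | decrease of the trait mean


def observed_effect_size(ob: float, control_mean: float) -> float:
    """Per-plant observed effect size |ob - control mean| / control mean."""
    if control_mean == 0:
        raise ZeroDivisionError("control mean must be nonzero")
    return abs(ob - control_mean) / abs(control_mean)


def independent_effect_size(stress_mean: float, control_mean: float) -> float:
    """Single-stressor effect size |stress mean - control mean| / control mean."""
    if control_mean == 0:
        raise ZeroDivisionError("control mean must be nonzero")
    return abs(stress_mean - control_mean) / abs(control_mean)


def expected_additive(ind_a: float, ind_b: float) -> float:
    """Multiplicative-risk expectation: sum of effects minus their product."""
    if ind_a < 0 or ind_b < 0:
        raise ValueError("independent effect sizes must be non-negative")
    return ind_a + ind_b - ind_a * ind_b


def classify_interaction(ob_values: np.ndarray, ex: float, alpha: float = 0.05,
                         method: str = "t", n_boot: int = 9999,
                         seed: int | None = None,
                         trait: str = "", root_type: str = "",
                         direction: str = "") -> InteractionResult:
    """Classify from the CI of the per-plant differences ``Ob_i - Ex``.

    ``method='t'`` uses a Student-t interval with n-1 df (default);
    ``method='bootstrap'`` a seeded percentile bootstrap of the mean.
    """
    diffs = np.asarray(ob_values, dtype=float) - ex
    n = len(diffs)
    if n < 2:
        raise ValueError("need at least two combined-stress plants to form a CI")
    mean = float(np.mean(diffs))
    if method == "t":
        sem = float(np.std(diffs, ddof=1) / np.sqrt(n))
        tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
        lo, hi = mean - tcrit * sem, mean + tcrit * sem
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        boot = rng.choice(diffs, size=(n_boot, n), replace=True).mean(axis=1)
        lo, hi = (float(np.quantile(boot, alpha / 2)),
                  float(np.quantile(boot, 1 - alpha / 2)))
    else:
        raise ValueError(f"unknown CI method {method!r}")
    if lo > 0:
        label = "synergistic"
    elif hi < 0:
        label = "antagonistic"
    else:
        label = "additive"
    return InteractionResult(trait=trait, root_type=root_type, mean_diff=mean,
                             ci_low=float(lo), ci_high=float(hi), label=label,
                             direction=direction)


def effect_sizes_from_dataset(dataset, root_type: str, trait: str,
                              control: str = "Control", drought: str = "Drought",
                              heat: str = "Heat", combined: str = "Combined") -> EffectSizes:
    """Effect sizes of one trait from a four-treatment dataset."""
    df = dataset.traits
    sel = (df["root_type"] == root_type) & (df["trait"] == trait)
    vals = {t: df.loc[sel & (df["treatment"] == t), "value"].to_numpy()
            for t in (control, drought, heat, combined)}
    missing = [t for t, v in vals.items() if len(v) == 0]
    if missing:
        raise ValueError(f"treatments absent for {root_type}/{trait}: {missing}")
    m_c = float(np.mean(vals[control]))
    ind_d = independent_effect_size(float(np.mean(vals[drought])), m_c)
    ind_h = independent_effect_size(float(np.mean(vals[heat])), m_c)
    ob = np.array([observed_effect_size(x, m_c) for x in vals[combined]])
    return EffectSizes(trait=trait, root_type=root_type, ob=ob,
                       ind_d=ind_d, ind_h=ind_h,
                       ex=expected_additive(ind_d, ind_h))


def interaction_screen(dataset, traits: list[tuple[str, str]] | None = None,
                       alpha: float = 0.05, method: str = "t",
                       seed: int | None = None,
                       control: str = "Control",
                       combined: str = "Combined") -> pd.DataFrame:
    """Classify every eligible (root type, trait) of a dataset.

    When ``traits`` is None, eligibility follows the published workflow:
    only traits whose combined-stress letter shares nothing with the
    control's in the univariate screen are classified.  Returns the
    tabular report: effect sizes, mean difference, CI, label, direction.
    """
    needed = {control, "Drought", "Heat", combined}
    present = set(dataset.treatments)
    if not needed <= present:
        raise ValueError(f"treatments missing from design: {sorted(needed - present)}")
    if traits is None:
        screen = trait_screen(dataset, alpha=alpha, control=control)
        disjoint = np.array([
            not (set(a.split(",")) & set(b.split(",")))
            for a, b in zip(screen[f"{combined}_letters"], screen[f"{control}_letters"])
        ])
        eligible = screen[~screen["degenerate"].to_numpy() & disjoint]
        traits = list(zip(eligible["root_type"], eligible["trait"]))
    rows = []
    for root_type, trait in traits:
        es = effect_sizes_from_dataset(dataset, root_type, trait,
                                       control=control, combined=combined)
        df = dataset.traits
        sel = (df["root_type"] == root_type) & (df["trait"] == trait)
        m_c = float(df.loc[sel & (df["treatment"] == control), "value"].mean())
        m_comb = float(df.loc[sel & (df["treatment"] == combined), "value"].mean())
        direction = "increase" if m_comb >= m_c else "decrease"
        res = classify_interaction(es.ob, es.ex, alpha=alpha, method=method,
                                   seed=seed, trait=trait, root_type=root_type,
                                   direction=direction)
        rows.append({
            "root_type": root_type, "trait": trait,
            "Ind_D": es.ind_d, "Ind_H": es.ind_h, "Ex": es.ex,
            "mean_Ob": float(np.mean(es.ob)), "mean_diff": res.mean_diff,
            "ci_low": res.ci_low, "ci_high": res.ci_high,
            "label": res.label, "direction": res.direction,
        })
    return pd.DataFrame(rows)


def point_interaction_from_means(control_mean: float, drought_mean: float,
                                 heat_mean: float, combined_mean: float) -> dict[str, float]:
    """Deterministic point version using only four treatment means.

    Returns Ob (of the combined mean), Ind_D, Ind_H, Ex and the
    difference Ob - Ex whose sign gives the nonadditive direction.
    """
    ob = observed_effect_size(combined_mean, control_mean)
    ind_d = independent_effect_size(drought_mean, control_mean)
    ind_h = independent_effect_size(heat_mean, control_mean)
    ex = expected_additive(ind_d, ind_h)
    return {"Ob": ob, "Ind_D": ind_d, "Ind_H": ind_h, "Ex": ex, "diff": ob - ex}
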