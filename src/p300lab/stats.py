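"""Crossover statistics: 2x2 within-subject ANOVA, paired t, Holm, change-score correlations.

For the 2x2 fully-within design each effect has 1 numerator df and n-1
denominator df, F equals the squared paired t of the corresponding
contrast, partial eta squared follows the identity
``eta_p^2 = F * df1 / (F * df1 + df2)``, and sphericity corrections are
moot (two-level factors).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multitest import multipletests

INTERVENTIONS = ("actual", "sham")
BLOCKS = ("pre", "post")


def eta_p_squared(f: float, df_effect: float, df_error: float) -> float:
    """Partial eta squared from an F statistic: F*df1 / (F*df1 + df2)."""
    return f * df_effect / (f * df_effect + df_error)


@dataclass
class EffectResult:
    F: float
    df_effect: float
    df_error: float
    p: float
    eta_p_sq: float


@dataclass
class AnovaResult:
    block: EffectResult
    intervention: EffectResult
    interaction: EffectResult
    n_subjects: int
    dropped_subjects: list = None

    def __getitem__(self, key: str) -> EffectResult:
        return getattr(self, key)


def _complete_cases(outcomes: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    counts = outcomes.groupby("subject").size()
    complete = counts[counts == 4].index
    dropped = sorted(set(counts.index) - set(complete))
    return outcomes[outcomes["subject"].isin(complete)], dropped


def rm_anova_2x2(outcomes: pd.DataFrame) -> AnovaResult:
    """Two-way repeated-measures ANOVA on a long outcome table.

    ``outcomes`` must have columns subject, intervention (actual/sham),
    block (pre/post) and value; subjects with missing cells are dropped
    listwise (and reported in ``dropped_subjects``).
    """
    data, dropped = _complete_cases(outcomes.dropna(subset=["value"]))
    n = data["subject"].nunique()
    if n < 2:
        raise ValueError("need at least 2 complete cases")
    fit = AnovaRM(data, depvar="value", subject="subject", within=["block", "intervention"]).fit()
    tab = fit.anova_table
    out = {}
    for source, name in (("block", "block"), ("intervention", "intervention"), ("block:intervention", "interaction")):
        row = tab.loc[source]
        f, df1, df2, p = float(row["F Value"]), float(row["Num DF"]), float(row["Den DF"]), float(row["Pr > F"])
        out[name] = EffectResult(F=f, df_effect=df1, df_error=df2, p=p, eta_p_sq=eta_p_squared(f, df1, df2))
    return AnovaResult(block=out["block"], intervention=out["intervention"], interaction=out["interaction"], n_subjects=n, dropped_subjects=dropped)


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    cohen_d: float


def paired_t(a: np.ndarray, b: np.ndarray) -> TTestResult:
    """Two-sided paired t test with Cohen's d = mean(a-b)/SD(a-b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    diff = a - b
    sd = diff.std(ddof=1)
    md = diff.mean()
    if sd == 0:
        t = 0.0 if md == 0 else float(np.sign(md) * np.inf)
        p = 1.0 if md == 0 else 0.0
        d = 0.0 if md == 0 else float(np.sign(md) * np.inf)
        return TTestResult(t=t, df=n - 1, p=p, cohen_d=d)
    t = md / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return TTestResult(t=float(t), df=n - 1, p=float(p), cohen_d=float(md / sd))


def holm_adjust(pvalues) -> np.ndarray:
    """Step-down Holm adjustment with monotonicity enforcement, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


@dataclass
class ChangeCorrMatrix:
    r: pd.DataFrame
    p_raw: pd.DataFrame
    p_holm: pd.DataFrame
    n: pd.DataFrame


def change_scores(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Post-minus-pre change per subject x intervention x measure (wide).

    Changes are pooled across both interventions, i.e. each subject
    contributes two rows per measure.
    """
    wide = outcomes.pivot_table(index=["subject", "intervention", "measure"], columns="block", values="value", aggfunc="first")
    wide["change"] = wide["post"] - wide["pre"]
    return wide.reset_index().pivot_table(index=["subject", "intervention"], columns="measure", values="change", aggfunc="first")


def correlate_changes(outcomes: pd.DataFrame, min_pairs: int = 3) -> ChangeCorrMatrix:
    """Pearson correlations between every pair of pre-to-post change scores.

    Holm correction runs over all upper-triangle pairs (the whole matrix is
    one family).  Pairs with constant vectors or fewer than ``min_pairs``
    complete observations are reported as missing.
    """
    table = change_scores(outcomes)
    measures = list(table.columns)
    k = len(measures)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    pairs = list(itertools.combinations(range(k), 2))
    raw_ps, pair_idx = [], []
    for i, j in pairs:
        x, y = table[measures[i]], table[measures[j]]
        ok = x.notna() & y.notna()
        n[i, j] = n[j, i] = int(ok.sum())
        if ok.sum() < min_pairs:
            continue
        xv, yv = x[ok].to_numpy(), y[ok].to_numpy()
        if xv.std() == 0 or yv.std() == 0:
            continue  # undefined correlation -> missing
        rr, pp = sps.pearsonr(xv, yv)
        r[i, j] = r[j, i] = rr
        p[i, j] = p[j, i] = pp
        raw_ps.append(pp)
        pair_idx.append((i, j))
    ph = np.full((k, k), np.nan)
    if raw_ps:
        adj = holm_adjust(raw_ps)
        for (i, j), a in zip(pair_idx, adj):
            ph[i, j] = ph[j, i] = a
    mk = lambda m: pd.DataFrame(m, index=measures, columns=measures)
    return ChangeCorrMatrix(r=mk(r), p_raw=mk(p), p_holm=mk(ph), n=mk(n))


def interaction_contrast(outcomes: pd.DataFrame) -> np.ndarray:
    """(postA - preA) - (postS - preS) per complete-case subject.

    The paired t on this contrast against zero squares to the ANOVA
    interaction F; it also serves as the direct estimate of the
    differential intervention effect in the measure's units.
    """
    data, _ = _complete_cases(outcomes.dropna(subset=["value"]))
    cell = data.pivot_table(index="subject", columns=["intervention", "block"], values="value", aggfunc="first")
    return (
        cell[("actual", "post")] - cell[("actual", "pre")] - (cell[("sham", "post")] - cell[("sham", "pre")])
    ).to_numpy()
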