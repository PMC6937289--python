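"""Field-trial statistics for split-plot lodging trials.

The trial layout is a split-plot (a.k.a. split-block) design: nitrogen
management on whole plots within replicate blocks, variety on subplots.
Whole-plot effects are tested against the block x nitrogen interaction mean
square; subplot effects against the residual.  Group summaries are mean +/-
standard error over replicate-plot means (culms are averaged within plot
first), percent changes compare the optimized management (OPT) to the
farmers' practice (FFP), and significance letters come from Fisher's LSD at
the 0.05 level.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "plot_means",
    "summarize",
    "percent_change",
    "average_percent_change",
    "split_plot_anova",
    "letter_groups",
    "harvest_index",
    "treatment_letters",
]

logger = logging.getLogger(__name__)


def plot_means(
    records: pd.DataFrame,
    trait: str,
    *,
    block: str = "replicate",
    whole: str = "treatment",
    sub: str = "variety",
) -> pd.DataFrame:
    """Average culm observations to one plot mean per block x whole x sub cell."""
    if trait not in records.columns:
        raise KeyError(f"trait column {trait!r} not found")
    return (
        records.dropna(subset=[trait])
        .groupby([block, whole, sub], observed=True)[trait]
        .mean()
        .reset_index()
    )


def summarize(
    records: pd.DataFrame,
    trait: str,
    by: Sequence[str] = ("variety", "treatment", "internode"),
    *,
    plot_col: str = "replicate",
) -> pd.DataFrame:
    """Group mean and standard error of a trait over replicate-plot means.

    Culm-level observations are first averaged within each replicate plot;
    the group mean and SE = sd/sqrt(n) are then taken over the n plot means.
    Groups with no non-missing observation are omitted with a warning.

    Returns a tidy frame with the ``by`` columns plus ``mean``, ``se``, ``n``.
    """
    if trait not in records.columns:
        raise KeyError(f"trait column {trait!r} not found")
    df = records.dropna(subset=[trait])
    dropped = records[trait].isna().groupby([records[c] for c in by]).all()
    for key in dropped[dropped].index.tolist():
        logger.warning("group %s has no %s values; omitted", key, trait)
        warnings.warn(f"group {key} has no {trait} values; omitted", stacklevel=2)

    plot_means = (
        df.groupby([*by, plot_col], observed=True)[trait].mean().reset_index()
    )
    out = (
        plot_means.groupby(list(by), observed=True)[trait]
        .agg(mean="mean", se=lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0, n="size")
        .reset_index()
    )
    out["trait"] = trait
    return out


def percent_change(opt_mean: float, ffp_mean: float, *, decimals: int | None = 1) -> float:
    """Relative change of OPT vs FFP in percent: (opt - ffp)/ffp * 100.

    Rounded to one decimal by default, matching table formatting;
    ``decimals=None`` returns full precision.
    """
    if ffp_mean == 0:
        raise ValueError("FFP mean is zero; percent change undefined")
    pc = (opt_mean - ffp_mean) / ffp_mean * 100.0
    return pc if decimals is None else round(pc, decimals)


def average_percent_change(
    pairs: Iterable[tuple[float, float]], *, decimals: int | None = 1
) -> float:
    """Unweighted mean of per-item percent changes over (opt, ffp) pairs.

    This is the mean of ratios, not the ratio of sums — the convention used
    when a text reports an 'average increase' across internodes.
    """
    pcs = [percent_change(o, f, decimals=None) for o, f in pairs]
    if not pcs:
        raise ValueError("need at least one (opt, ffp) pair")
    avg = float(np.mean(pcs))
    return avg if decimals is None else round(avg, decimals)


def split_plot_anova(
    plot_table: pd.DataFrame,
    *,
    response: str = "value",
    block: str = "replicate",
    whole: str = "treatment",
    sub: str = "variety",
) -> pd.DataFrame:
    """ANOVA table for a balanced split-plot design.

    ``plot_table`` holds one row per block x whole-plot x subplot cell (plot
    means).  The whole-plot factor (nitrogen management) is tested against
    the block x whole-plot interaction; the subplot factor (variety) and the
    interaction against the subplot residual.

    Returns a frame indexed by effect with columns df, ss, ms, F, p.
    Unbalanced layouts raise; no imputation is attempted.
    """
    df = plot_table[[block, whole, sub, response]].dropna()
    counts = df.groupby([block, whole, sub], observed=True).size()
    r = df[block].nunique()
    a = df[whole].nunique()
    b = df[sub].nunique()
    if len(counts) != r * a * b or counts.nunique() != 1 or counts.iloc[0] != 1:
        raise ValueError(
            "split-plot ANOVA requires a balanced layout with exactly one "
            "plot mean per block x whole x sub cell"
        )

    y = df[response].to_numpy(float)
    grand = y.mean()
    n = y.size
    ss_total = float(((y - grand) ** 2).sum())

    def ss_of(cols: list[str]) -> float:
        m = df.groupby(cols, observed=True)[response].mean()
        cnt = df.groupby(cols, observed=True)[response].size()
        return float((cnt * (m - grand) ** 2).sum())

    ss_block = ss_of([block])
    ss_whole = ss_of([whole])
    ss_sub = ss_of([sub])
    ss_bw = ss_of([block, whole]) - ss_block - ss_whole     # whole-plot error
    ss_ws = ss_of([whole, sub]) - ss_whole - ss_sub         # interaction
    ss_resid = ss_total - (ss_block + ss_whole + ss_bw + ss_sub + ss_ws)

    dfs = {
        "block": r - 1,
        "whole": a - 1,
        "whole_error": (r - 1) * (a - 1),
        "sub": b - 1,
        "whole:sub": (a - 1) * (b - 1),
        "residual": a * (r - 1) * (b - 1),
    }
    sss = {
        "block": ss_block,
        "whole": ss_whole,
        "whole_error": ss_bw,
        "sub": ss_sub,
        "whole:sub": ss_ws,
        "residual": ss_resid,
    }
    ms = {k: (sss[k] / dfs[k] if dfs[k] > 0 else np.nan) for k in sss}

    def ftest(effect: str, error: str) -> tuple[float, float]:
        if ms[error] == 0 or not np.isfinite(ms[error]):
            return (np.nan, np.nan)
        f = ms[effect] / ms[error]
        p = float(stats.f.sf(f, dfs[effect], dfs[error]))
        return (f, p)

    fs: dict[str, tuple[float, float]] = {k: (np.nan, np.nan) for k in sss}
    fs["whole"] = ftest("whole", "whole_error")
    fs["sub"] = ftest("sub", "residual")
    fs["whole:sub"] = ftest("whole:sub", "residual")

    out = pd.DataFrame(
        {
            "df": pd.Series(dfs),
            "ss": pd.Series(sss),
            "ms": pd.Series(ms),
            "F": pd.Series({k: v[0] for k, v in fs.items()}),
            "p": pd.Series({k: v[1] for k, v in fs.items()}),
        }
    )
    out.index.name = "effect"
    return out


def letter_groups(
    means: pd.Series | dict[str, float],
    error_ms: float,
    df: int,
    *,
    n: int | Sequence[int] = 4,
    alpha: float = 0.05,
) -> pd.Series:
    """Compact letter display from Fisher's LSD pairwise comparisons.

    Groups whose means differ by less than the least significant difference
    LSD = t(1-alpha/2, df) * sqrt(MS*(1/n_i + 1/n_j)) share a letter.
    Means are ranked descending (ties broken by label); letters are assigned
    to maximal runs of mutually non-significant groups.
    """
    if df < 1:
        raise ValueError("error degrees of freedom must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    m = pd.Series(means, dtype=float)
    if len(m) < 2:
        raise ValueError("need at least two groups")
    ns = pd.Series(n, index=m.index) if not np.isscalar(n) else pd.Series(n, index=m.index)
    tcrit = stats.t.ppf(1 - alpha / 2, df)

    order = m.sort_values(ascending=False, kind="mergesort").index.tolist()

    def differ(i: str, j: str) -> bool:
        lsd = tcrit * np.sqrt(error_ms * (1.0 / ns[i] + 1.0 / ns[j]))
        return abs(m[i] - m[j]) > lsd

    k = len(order)
    # maximal runs of consecutive (in rank order) mutually non-significant groups
    runs: list[tuple[int, int]] = []
    for i in range(k):
        j = i
        while j + 1 < k and not differ(order[i], order[j + 1]):
            j += 1
        runs.append((i, j))
    maximal = [r for r in runs if not any(s[0] <= r[0] and r[1] <= s[1] and s != r for s in runs)]
    maximal.sort()

    letters = {g: "" for g in order}
    for idx, (lo, hi) in enumerate(maximal):
        ch = chr(ord("a") + idx)
        for g in order[lo : hi + 1]:
            letters[g] += ch
    return pd.Series(letters).reindex(m.index)


def treatment_letters(
    plot_means: pd.DataFrame,
    *,
    response: str = "value",
    block: str = "replicate",
    whole: str = "treatment",
    sub: str = "variety",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-variety FFP-vs-OPT letters using the subplot residual error.

    Runs the split-plot ANOVA, then for each subplot level compares the
    whole-plot (nitrogen) means with LSD at ``alpha`` on the residual mean
    square.  Returns tidy rows (sub, whole, mean, letter).
    """
    aov = split_plot_anova(plot_means, response=response, block=block, whole=whole, sub=sub)
    ms_err = float(aov.loc["residual", "ms"])
    df_err = int(aov.loc["residual", "df"])
    rows = []
    for lev, grp in plot_means.groupby(sub, observed=True):
        cell = grp.groupby(whole, observed=True)[response].agg(["mean", "size"])
        lett = letter_groups(cell["mean"], ms_err, df_err, n=cell["size"].tolist(), alpha=alpha)
        for w in cell.index:
            rows.append({sub: lev, whole: w, "mean": cell.loc[w, "mean"], "letter": lett[w]})
    return pd.DataFrame(rows)


def harvest_index(grain_g_m2: float, biomass_g_m2: float) -> float:
    """Grain yield as a fraction of total above-ground biomass."""
    if biomass_g_m2 <= 0:
        raise ValueError("biomass must be positive")
    if grain_g_m2 < 0:
        raise ValueError("grain yield must be non-negative")
    return grain_g_m2 / biomass_g_m2
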