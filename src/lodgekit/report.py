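"""Render trait summaries in the layout of agronomy trial tables.

One block per variety: an FFP row and an OPT row of ``mean ± se letter``
cells (one column per internode), followed by a percent-change row.  Letters
compare the two nitrogen managements within a variety by LSD at the 0.05
level on the split-plot subplot residual.
"""

from __future__ import annotations

import pandas as pd

from .traits import percent_change, plot_means, summarize, treatment_letters

__all__ = ["render_trait_table"]


def _fmt(mean: float, se: float, letter: str, decimals: int) -> str:
    return f"{mean:.{decimals}f} ± {se:.{decimals}f}{letter}"


def render_trait_table(
    records: pd.DataFrame,
    trait: str,
    *,
    internodes: list[int] | None = None,
    decimals: int = 1,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tabulate a trait as ``mean ± se letter`` rows plus a percent-change row.

    Displayed precision is ``decimals``; all statistics are computed at full
    precision first.
    """
    summ = summarize(records, trait)
    if internodes is None:
        internodes = sorted(summ["internode"].unique())
    letters: dict[tuple[str, str, int], str] = {}
    for idx in internodes:
        pm = plot_means(records[records["internode"] == idx], trait)
        if pm["treatment"].nunique() < 2:
            continue
        lt = treatment_letters(pm, response=trait, alpha=alpha)
        for _, row in lt.iterrows():
            letters[(row["variety"], row["treatment"], idx)] = row["letter"]

    blocks = []
    for variety in sorted(summ["variety"].unique()):
        sub = summ[summ["variety"] == variety].set_index(["treatment", "internode"])
        rows: dict[str, dict[int, str]] = {"FFP": {}, "OPT": {}, "%": {}}
        for idx in internodes:
            try:
                ffp = sub.loc[("FFP", idx)]
                opt = sub.loc[("OPT", idx)]
            except KeyError:
                continue
            rows["FFP"][idx] = _fmt(
                ffp["mean"], ffp["se"], letters.get((variety, "FFP", idx), ""), decimals
            )
            rows["OPT"][idx] = _fmt(
                opt["mean"], opt["se"], letters.get((variety, "OPT", idx), ""), decimals
            )
            rows["%"][idx] = f"{percent_change(opt['mean'], ffp['mean']):.1f}"
        frame = pd.DataFrame(rows).T
        frame.columns = [f"I{c}" for c in frame.columns]
        frame.insert(0, "variety", variety)
        frame.insert(1, "row", frame.index)
        blocks.append(frame.reset_index(drop=True))
    return pd.concat(blocks, ignore_index=True)
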