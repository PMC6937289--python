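"""Independent reference implementations used only by the test suite.

Each oracle deliberately takes a different computational route than the
package: numerical integration instead of closed forms, exact rational
enumeration instead of scipy distributions, raw sums of squares instead of
the ANOVA bookkeeping.
"""

from fractions import Fraction
from math import comb, pi, sin

import numpy as np
import pandas as pd
from scipy.integrate import simpson


def annulus_second_moment(a: float, t: float, n_r: int = 801, n_th: int = 801) -> float:
    """I = integral of y^2 dA over the annular section, by Simpson quadrature.

    Polar coordinates: y = r sin(theta), dA = r dr dtheta, integrated over
    r in [a-t, a], theta in [0, 2*pi].
    """
    r = np.linspace(a - t, a, n_r)
    th = np.linspace(0.0, 2.0 * pi, n_th)
    integrand_r = r**3  # inner radial integrand before the angular factor
    radial = simpson(integrand_r, x=r)
    angular = simpson(np.sin(th) ** 2, x=th)
    return radial * angular


def hypergeom_upper_tail(n_universe: int, k_term: int, n_list: int, k_hit: int) -> float:
    """P(overlap >= k_hit) by exact rational enumeration over draws."""
    total = comb(n_universe, n_list)
    acc = Fraction(0)
    for j in range(k_hit, min(k_term, n_list) + 1):
        acc += Fraction(comb(k_term, j) * comb(n_universe - k_term, n_list - j), total)
    return float(acc)


def split_plot_ss(df: pd.DataFrame, response: str, block: str, whole: str, sub: str) -> dict:
    """Sums of squares by direct enumeration of cell means (balanced layout)."""
    y = df[response].to_numpy(float)
    grand = y.mean()
    blocks = sorted(df[block].unique())
    wholes = sorted(df[whole].unique())
    subs = sorted(df[sub].unique())
    r, a, b = len(blocks), len(wholes), len(subs)

    def mean_where(**kw):
        m = np.ones(len(df), bool)
        for col, val in kw.items():
            m &= df[col].to_numpy() == val
        return df.loc[m, response].mean()

    ss_block = a * b * sum((mean_where(**{block: i}) - grand) ** 2 for i in blocks)
    ss_whole = r * b * sum((mean_where(**{whole: j}) - grand) ** 2 for j in wholes)
    ss_sub = r * a * sum((mean_where(**{sub: k}) - grand) ** 2 for k in subs)
    ss_bw = (
        b
        * sum(
            (
                mean_where(**{block: i, whole: j})
                - mean_where(**{block: i})
                - mean_where(**{whole: j})
                + grand
            )
            ** 2
            for i in blocks
            for j in wholes
        )
    )
    ss_ws = (
        r
        * sum(
            (
                mean_where(**{whole: j, sub: k})
                - mean_where(**{whole: j})
                - mean_where(**{sub: k})
                + grand
            )
            ** 2
            for j in wholes
            for k in subs
        )
    )
    ss_total = float(((y - grand) ** 2).sum())
    return {
        "block": ss_block,
        "whole": ss_whole,
        "whole_error": ss_bw,
        "sub": ss_sub,
        "whole:sub": ss_ws,
        "residual": ss_total - (ss_block + ss_whole + ss_bw + ss_sub + ss_ws),
        "total": ss_total,
    }
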