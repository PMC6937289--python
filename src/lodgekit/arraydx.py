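"""Two-color microarray differential-expression pipeline.

One hybridization compares the two nitrogen managements on a single slide:
the control condition (FFP) is labelled Cy3, the optimized management (OPT)
Cy5.  The pipeline follows the classical two-channel workflow:

1. ``filter_features`` — drop flagged probes, floor intensities at 1;
2. ``ma_transform`` — M = log2(Cy5/Cy3), A = 0.5*log2(Cy5*Cy3);
3. ``loess_normalize`` — remove the intensity-dependent dye bias by robust
   local-linear regression of M on A (tricube weights, robustness
   reweighting); the normalized log-ratio is M minus the fitted trend;
4. ``ttest_features`` — per-probe mean normalized log2 ratio across
   biological replicates with a two-sided one-sample t-test against 0;
5. ``call_degs`` — joint criterion |mean log2FC| >= 1 (two-fold) and
   p <= 0.05;
6. ``go_enrichment`` — upper-tail hypergeometric over-representation of GO
   terms with Benjamini-Hochberg adjustment;
7. ``qpcr_concordance`` — OLS regression of qPCR log2 ratios on array log2
   ratios for a validation gene panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FC_THRESHOLD_LOG2",
    "P_THRESHOLD",
    "filter_features",
    "ma_transform",
    "loess_normalize",
    "normalize_replicate",
    "ttest_features",
    "call_degs",
    "go_enrichment",
    "qpcr_concordance",
    "ddct_log2fc",
    "run_pipeline",
]

#: DEG thresholds: two-fold change and raw p <= 0.05 across replicates.
FC_THRESHOLD_LOG2 = 1.0
P_THRESHOLD = 0.05

INTENSITY_FLOOR = 1.0


def filter_features(replicate: pd.DataFrame) -> pd.DataFrame:
    """Drop flagged probes and floor both channels at intensity 1.

    Expects columns ``probe_id``, ``cy3``, ``cy5`` and optionally ``flag``
    (values ``ok``/``bad``).  The number of dropped probes is stored in
    ``DataFrame.attrs['n_dropped']``.
    """
    required = {"probe_id", "cy3", "cy5"}
    missing = required - set(replicate.columns)
    if missing:
        raise ValueError(f"replicate table missing columns: {sorted(missing)}")
    out = replicate
    n0 = len(out)
    if "flag" in out.columns:
        out = out[out["flag"] != "bad"]
    if out.empty:
        raise ValueError("no probes left after filtering")
    out = out.copy()
    out["cy3"] = out["cy3"].clip(lower=INTENSITY_FLOOR)
    out["cy5"] = out["cy5"].clip(lower=INTENSITY_FLOOR)
    out.attrs["n_dropped"] = n0 - len(out)
    return out


def ma_transform(replicate: pd.DataFrame) -> pd.DataFrame:
    """MA representation: M = log2(Cy5/Cy3), A = 0.5*log2(Cy5*Cy3)."""
    cy3 = replicate["cy3"].to_numpy(float)
    cy5 = replicate["cy5"].to_numpy(float)
    if (cy3 <= 0).any() or (cy5 <= 0).any():
        raise ValueError("non-positive intensities; run filter_features first")
    out = replicate[["probe_id"]].copy()
    out["M"] = np.log2(cy5) - np.log2(cy3)
    out["A"] = 0.5 * (np.log2(cy5) + np.log2(cy3))
    return out


def loess_normalize(
    m: np.ndarray,
    a: np.ndarray,
    *,
    span: float = 0.3,
    robust_iters: int = 3,
) -> np.ndarray:
    """Normalized log ratios: M minus a robust loess fit of M on A.

    Local-linear regression with tricube weights and ``robust_iters``
    robustness reweighting passes, spanning a fraction ``span`` of the data
    per window.  Global fit (no print-tip stratification).
    """
    m = np.asarray(m, float)
    a = np.asarray(a, float)
    if m.shape != a.shape or m.ndim != 1:
        raise ValueError("M and A must be equal-length 1-D arrays")
    if m.size < 50:
        raise ValueError(f"need >=50 probes for loess normalization, got {m.size}")
    if span * m.size < 10:
        raise ValueError(f"span {span} yields <10 points per window for n={m.size}")
    # delta: interpolate over near-duplicate abscissae; standard speedup
    delta = 0.01 * (a.max() - a.min())
    fit = lowess(m, a, frac=span, it=robust_iters, delta=delta, return_sorted=False)
    return m - fit


def normalize_replicate(
    replicate: pd.DataFrame, *, span: float = 0.3, robust_iters: int = 3
) -> pd.DataFrame:
    """filter -> MA -> loess for one replicate; returns probe_id, M, A, M_norm."""
    ma = ma_transform(filter_features(replicate))
    ma["M_norm"] = loess_normalize(
        ma["M"].to_numpy(), ma["A"].to_numpy(), span=span, robust_iters=robust_iters
    )
    return ma


def ttest_features(m_norm: pd.DataFrame) -> pd.DataFrame:
    """Replicate-level test of each probe's normalized log ratio against 0.

    ``m_norm`` has one column per replicate (probes as index).  Returns a
    frame with ``mean_log2fc``, ``p_value``, ``n_reps`` and ``degenerate``
    (True where the across-replicate variance is zero or <2 replicates are
    finite, in which case the p-value is NaN — flagged, never fabricated).
    """
    x = m_norm.to_numpy(float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a probes x replicates matrix with >=2 replicates")
    nrep = np.sum(np.isfinite(x), axis=1)
    mean = np.where(nrep > 0, np.nanmean(np.where(np.isfinite(x), x, np.nan), axis=1), np.nan)
    with np.errstate(invalid="ignore"):
        sd = np.nanstd(np.where(np.isfinite(x), x, np.nan), axis=1, ddof=1)
    degenerate = (nrep < 2) | (sd == 0) | ~np.isfinite(sd)
    p = np.full(x.shape[0], np.nan)
    ok = ~degenerate
    if ok.any():
        se = sd[ok] / np.sqrt(nrep[ok])
        t = mean[ok] / se
        p[ok] = 2.0 * stats.t.sf(np.abs(t), nrep[ok] - 1)
    return pd.DataFrame(
        {
            "mean_log2fc": mean,
            "p_value": p,
            "n_reps": nrep,
            "degenerate": degenerate,
        },
        index=m_norm.index,
    )


def call_degs(
    feature_stats: pd.DataFrame,
    *,
    log2fc_threshold: float = FC_THRESHOLD_LOG2,
    p_threshold: float = P_THRESHOLD,
) -> pd.DataFrame:
    """Joint fold-change + p-value DEG call: up / down / none per probe.

    up: mean_log2fc >= threshold and p <= p_threshold; down symmetric.
    Degenerate probes (no valid p) are never called.
    """
    fc = feature_stats["mean_log2fc"]
    p = feature_stats["p_value"]
    sig = p.le(p_threshold) & p.notna()
    call = np.where(
        sig & fc.ge(log2fc_threshold),
        "up",
        np.where(sig & fc.le(-log2fc_threshold), "down", "none"),
    )
    out = feature_stats.copy()
    out["call"] = call
    return out


@dataclass
class GOResult:
    term: str
    universe_size: int
    term_size: int
    list_size: int
    overlap: int
    p_value: float
    p_adjusted: float


def go_enrichment(
    deg_list: list[str] | pd.Index,
    annotation_map: pd.DataFrame,
    universe: list[str] | pd.Index,
) -> pd.DataFrame:
    """GO term over-representation by the upper-tail hypergeometric test.

    ``annotation_map`` has columns ``gene_id`` and ``term``.  For each term
    with K annotated genes in the universe of size N, and a DEG list of size
    n with k members of the term, p = P(overlap >= k) under sampling without
    replacement.  Benjamini-Hochberg adjustment across terms; sorted by
    adjusted then raw p.
    """
    universe = pd.Index(universe).unique()
    degs = pd.Index(deg_list).unique()
    if len(degs) == 0 or len(universe) == 0:
        raise ValueError("DEG list and universe must be non-empty")
    stray = degs.difference(universe)
    if len(stray):
        raise ValueError(f"{len(stray)} DEG ids not in the universe (e.g. {stray[0]!r})")
    ann = annotation_map[annotation_map["gene_id"].isin(universe)]
    n_universe = len(universe)
    n_list = len(degs)
    rows = []
    for term, genes in ann.groupby("term", observed=True)["gene_id"]:
        members = pd.Index(genes).unique()
        k_term = len(members)
        k_hit = len(members.intersection(degs))
        p = float(stats.hypergeom.sf(k_hit - 1, n_universe, k_term, n_list))
        rows.append(
            {
                "term": term,
                "universe_size": n_universe,
                "term_size": k_term,
                "list_size": n_list,
                "overlap": k_hit,
                "p_value": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out.sort_values(["p_adjusted", "p_value"], kind="mergesort").reset_index(drop=True)


def qpcr_concordance(
    array_log2fc: np.ndarray, qpcr_log2fc: np.ndarray
) -> tuple[float, float, float]:
    """OLS of qPCR log2 ratios on array log2 ratios: (slope, intercept, R^2).

    The standard validation plot for a microarray experiment: each point is
    one gene measured by both platforms on the same RNA.
    """
    x = np.asarray(array_log2fc, float)
    y = np.asarray(qpcr_log2fc, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired 1-D vectors required")
    if x.size < 3:
        raise ValueError("need >=3 paired genes")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in array log2 ratios")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def ddct_log2fc(
    qpcr: pd.DataFrame,
    reference_gene: str,
    *,
    gene_col: str = "gene",
    treat_col: str = "treatment",
    ct_col: str = "ct",
    control: str = "FFP",
    treated: str = "OPT",
) -> pd.Series:
    """log2 fold changes from a tidy qPCR Ct table by the delta-delta-Ct rule.

    Per gene: dCt = Ct(gene) - Ct(reference) within each condition;
    ddCt = dCt(treated) - dCt(control); fold change = 2^(-ddCt), so the
    log2 fold change is simply -ddCt.
    """
    ct = qpcr.groupby([gene_col, treat_col], observed=True)[ct_col].mean().unstack(treat_col)
    if reference_gene not in ct.index:
        raise ValueError(f"reference gene {reference_gene!r} not in table")
    for cond in (control, treated):
        if cond not in ct.columns:
            raise ValueError(f"condition {cond!r} not in table")
    dct = ct.sub(ct.loc[reference_gene], axis=1)
    ddct = dct[treated] - dct[control]
    out = -ddct.drop(reference_gene)
    out.name = "log2fc"
    return out


def run_pipeline(
    replicates: list[pd.DataFrame],
    *,
    span: float = 0.3,
    robust_iters: int = 3,
    log2fc_threshold: float = FC_THRESHOLD_LOG2,
    p_threshold: float = P_THRESHOLD,
) -> pd.DataFrame:
    """Full per-probe pipeline over biological replicates.

    Each replicate is filtered, MA-transformed and loess-normalized
    independently; probes are joined on probe_id (probes missing from a
    replicate get NaN there) and tested across replicates.  Returns the
    feature-stats frame with DEG calls, indexed by probe_id.
    """
    if len(replicates) < 2:
        raise ValueError("need >=2 biological replicates")
    cols = {}
    for i, rep in enumerate(replicates):
        norm = normalize_replicate(rep, span=span, robust_iters=robust_iters)
        cols[f"rep{i + 1}"] = norm.set_index("probe_id")["M_norm"]
    m_norm = pd.DataFrame(cols)
    stats_df = ttest_features(m_norm)
    return call_degs(stats_df, log2fc_threshold=log2fc_threshold, p_threshold=p_threshold)
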