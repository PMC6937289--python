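import numpy as np
import pandas as pd
import pytest

from lodgekit.arraydx import (
    call_degs,
    ddct_log2fc,
    filter_features,
    go_enrichment,
    loess_normalize,
    ma_transform,
    qpcr_concordance,
    run_pipeline,
    ttest_features,
)
from lodgekit.synthgen import gen_go_universe

from oracles import hypergeom_upper_tail


class TestFilterAndMA:
    def test_all_ok_is_identity_with_floor(self, array_replicate):
        out = filter_features(array_replicate)
        assert len(out) == len(array_replicate)
        assert out.attrs["n_dropped"] == 0

    def test_bad_probe_dropped(self, array_replicate):
        rep = array_replicate.copy()
        rep.loc[rep.index[0], "flag"] = "bad"
        out = filter_features(rep)
        assert len(out) == len(rep) - 1
        assert out.attrs["n_dropped"] == 1

    def test_zero_intensity_floored_m_finite(self):
        rep = pd.DataFrame({"probe_id": ["p1"], "cy3": [0.0], "cy5": [1024.0], "flag": ["ok"]})
        ma = ma_transform(filter_features(rep))
        assert np.isfinite(ma["M"].iloc[0])
        assert ma["M"].iloc[0] == pytest.approx(10.0)  # log2(1024/1)

    def test_all_bad_rejected(self):
        rep = pd.DataFrame({"probe_id": ["p1"], "cy3": [1.0], "cy5": [1.0], "flag": ["bad"]})
        with pytest.raises(ValueError):
            filter_features(rep)

    @pytest.mark.parametrize(
        "cy5,cy3,m,a",
        [(100.0, 100.0, 0.0, None), (400.0, 100.0, 2.0, None), (1024.0, 256.0, 2.0, 9.0)],
    )
    def test_ma_values(self, cy5, cy3, m, a):
        rep = pd.DataFrame({"probe_id": ["p"], "cy3": [cy3], "cy5": [cy5]})
        ma = ma_transform(rep)
        assert ma["M"].iloc[0] == pytest.approx(m)
        if a is not None:
            assert ma["A"].iloc[0] == pytest.approx(a)

    def test_nonpositive_intensity_rejected(self):
        rep = pd.DataFrame({"probe_id": ["p"], "cy3": [-1.0], "cy5": [2.0]})
        with pytest.raises(ValueError):
            ma_transform(rep)


class TestLoess:
    def test_null_data_nearly_unchanged(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(6, 14, 2000)
        m = rng.normal(0, 0.2, 2000)
        m_norm = loess_normalize(m, a)
        assert np.max(np.abs(m - m_norm)) < 0.05  # fitted trend is ~0

    def test_constant_offset_absorbed(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(6, 14, 1000)
        m = np.full(1000, 0.7)
        m_norm = loess_normalize(m, a)
        assert np.max(np.abs(m_norm)) < 1e-6

    def test_sinusoidal_bias_removed_per_decile(self):
        rng = np.random.default_rng(2)
        n = 10_000
        a = rng.uniform(6, 14, n)
        m = 0.5 * np.sin(a / 2) + rng.normal(0, 0.2, n)
        m_norm = loess_normalize(m, a)
        deciles = pd.qcut(a, 10, labels=False)
        means = pd.Series(m_norm).groupby(deciles).mean()
        assert (means.abs() < 0.05).all()

    def test_too_few_probes_rejected(self):
        with pytest.raises(ValueError):
            loess_normalize(np.zeros(10), np.arange(10.0))

    def test_narrow_window_rejected(self):
        a = np.linspace(0, 1, 60)
        with pytest.raises(ValueError, match="window"):
            loess_normalize(np.zeros(60), a, span=0.1)


class TestFeatureTests:
    def test_three_replicate_t(self):
        stats = ttest_features(pd.DataFrame({"r1": [0.8], "r2": [1.0], "r3": [1.2]}))
        assert stats["mean_log2fc"].iloc[0] == pytest.approx(1.0)
        assert stats["p_value"].iloc[0] == pytest.approx(0.0131, abs=2e-4)

    def test_zero_variance_flagged_degenerate(self):
        stats = ttest_features(pd.DataFrame({"r1": [0.0], "r2": [0.0], "r3": [0.0]}))
        assert stats["degenerate"].iloc[0]
        assert np.isnan(stats["p_value"].iloc[0])

    def test_symmetric_pair_p_one(self):
        stats = ttest_features(pd.DataFrame({"r1": [1.0], "r2": [-1.0]}))
        assert stats["mean_log2fc"].iloc[0] == pytest.approx(0.0)
        assert stats["p_value"].iloc[0] == pytest.approx(1.0)

    def test_missing_replicate_uses_available(self):
        stats = ttest_features(pd.DataFrame({"r1": [0.8], "r2": [np.nan], "r3": [1.2]}))
        assert stats["n_reps"].iloc[0] == 2
        assert stats["mean_log2fc"].iloc[0] == pytest.approx(1.0)


class TestDEGCalls:
    def test_joint_criterion(self):
        stats = pd.DataFrame(
            {
                "mean_log2fc": [1.0, 0.9, -2.44, -0.5, 1.5],
                "p_value": [0.013, 0.001, 0.001, 0.001, 0.2],
            },
            index=list("abcde"),
        )
        out = call_degs(stats)
        assert out.loc["a", "call"] == "up"
        assert out.loc["b", "call"] == "none"  # fold-change gate fails
        assert out.loc["c", "call"] == "down"
        assert out.loc["d", "call"] == "none"
        assert out.loc["e", "call"] == "none"  # p gate fails

    def test_degenerate_never_called(self):
        stats = pd.DataFrame({"mean_log2fc": [3.0], "p_value": [np.nan]})
        assert call_degs(stats)["call"].iloc[0] == "none"

    def test_invariant_to_order_and_channel_rescaling(self, array_replicate):
        reps = []
        rng = np.random.default_rng(9)
        base = array_replicate.copy()
        spike = base.index[:5]
        for _ in range(3):
            r = base.copy()
            r["cy5"] = r["cy5"] * 2.0 ** rng.normal(0, 0.05, len(r))
            r.loc[spike, "cy5"] *= 8.0  # strong consistent up-spike
            reps.append(r)
        calls1 = run_pipeline(reps)["call"]
        shuffled = [r.sample(frac=1.0, random_state=1).reset_index(drop=True) for r in reps]
        calls2 = run_pipeline(shuffled)["call"]
        scaled = [r.assign(cy3=r.cy3 * 37.0, cy5=r.cy5 * 37.0) for r in reps]
        calls3 = run_pipeline(scaled)["call"]
        assert calls1.sort_index().equals(calls2.sort_index())
        assert calls1.sort_index().equals(calls3.sort_index())


class TestGOEnrichment:
    def test_worked_hypergeometric_example(self):
        # N=20 universe, one term of 5 genes, list of 5 with 4 hits
        ann, gene_list, universe = gen_go_universe(
            20, 4, genes_per_term=5, list_size=5, enriched={"GO:0000001": 4}, seed=0
        )
        res = go_enrichment(gene_list, ann, universe).set_index("term")
        assert res.loc["GO:0000001", "overlap"] == 4
        assert res.loc["GO:0000001", "p_value"] == pytest.approx(76 / 15504, rel=1e-9)

    def test_matches_enumeration_oracle_small_universes(self):
        rng = np.random.default_rng(3)
        for trial in range(20):
            n_univ = int(rng.integers(8, 26))
            ann, gene_list, universe = gen_go_universe(
                n_univ,
                3,
                genes_per_term=int(rng.integers(2, n_univ // 2 + 1)),
                list_size=int(rng.integers(2, n_univ // 2 + 1)),
                seed=trial,
            )
            res = go_enrichment(gene_list, ann, universe)
            for _, row in res.iterrows():
                expected = hypergeom_upper_tail(
                    row["universe_size"], row["term_size"], row["list_size"], row["overlap"]
                )
                assert row["p_value"] == pytest.approx(expected, rel=1e-9)

    def test_zero_overlap_p_at_most_one(self):
        ann = pd.DataFrame({"gene_id": ["g1", "g2"], "term": ["T", "T"]})
        res = go_enrichment(["g3"], ann, ["g1", "g2", "g3", "g4"])
        assert 0 < res["p_value"].iloc[0] <= 1.0

    def test_full_containment_minimum_p(self):
        # k = n = K << N: p = 1/C(N, K) with n = K draws
        genes = [f"g{i}" for i in range(12)]
        ann = pd.DataFrame({"gene_id": genes[:3], "term": "T"})
        res = go_enrichment(genes[:3], ann, genes)
        assert res["p_value"].iloc[0] == pytest.approx(
            hypergeom_upper_tail(12, 3, 3, 3), rel=1e-9
        )

    def test_bh_adjustment_monotone(self):
        ann, gene_list, universe = gen_go_universe(
            50, 8, genes_per_term=6, list_size=10, enriched={"GO:0000002": 5}, seed=1
        )
        res = go_enrichment(gene_list, ann, universe)
        assert (res["p_adjusted"] >= res["p_value"] - 1e-12).all()
        assert res["p_adjusted"].is_monotonic_increasing

    def test_empty_inputs_rejected(self):
        ann = pd.DataFrame({"gene_id": ["g1"], "term": ["T"]})
        with pytest.raises(ValueError):
            go_enrichment([], ann, ["g1"])
        with pytest.raises(ValueError):
            go_enrichment(["gX"], ann, ["g1"])  # not in universe


class TestQpcr:
    def test_identity_and_scaling(self):
        x = np.array([-2.0, -1.0, 0.5, 1.5, 2.5])
        assert qpcr_concordance(x, x) == pytest.approx((1.0, 0.0, 1.0))
        slope, intercept, r2 = qpcr_concordance(x, 2 * x)
        assert (slope, r2) == pytest.approx((2.0, 1.0))

    def test_twelve_gene_panel_r2(self):
        # 12 genes, array ratios spread sd 1, qPCR = array + N(0, 0.4)
        rng = np.random.default_rng(4)
        r2s = []
        for _ in range(500):
            x = rng.normal(0, 1, 12)
            y = x + rng.normal(0, 0.4, 12)
            r2s.append(qpcr_concordance(x, y)[2])
        assert np.mean(r2s) == pytest.approx(0.86, abs=0.1)

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(ValueError):
            qpcr_concordance(np.ones(5), np.arange(5.0))
        with pytest.raises(ValueError):
            qpcr_concordance(np.arange(2.0), np.arange(2.0))

    def test_ddct_log2fc(self):
        # target drops 1 cycle relative to reference under OPT -> log2FC = -(-1)?
        qpcr = pd.DataFrame(
            {
                "gene": ["ref", "ref", "t1", "t1"],
                "treatment": ["FFP", "OPT", "FFP", "OPT"],
                "ct": [20.0, 20.0, 25.0, 23.0],
            }
        )
        out = ddct_log2fc(qpcr, "ref")
        # ddCt = (23-20) - (25-20) = -2; log2FC = +2 (less cycles = more cDNA)
        assert out["t1"] == pytest.approx(2.0)
        with pytest.raises(ValueError):
            ddct_log2fc(qpcr, "missing")
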