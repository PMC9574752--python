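import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dubscreen import library_model as lib
from dubscreen import screen_quant as quant
from dubscreen import screen_score as sc
from dubscreen import synthetic_data as synth

from conftest import toy_catalog


def make_table(columns, samples=None, guide_ids=None):
    first = next(iter(columns.values()))
    guide_ids = guide_ids or [f"g{i}" for i in range(len(first))]
    df = pd.DataFrame(columns, index=guide_ids).astype("int64")
    if samples is None:
        samples = [quant._parse_sample_id(c) for c in columns]
    return quant.GuideCountTable(counts=df, samples=samples)


class TestNormalizeTotal:
    def test_uniform_counts(self):
        table = make_table({"T0_r1": [2, 2, 2, 2]})
        norm = sc.normalize_total(table, pseudocount=0)
        assert np.allclose(norm["T0_r1"], 250_000.0)

    def test_simple_proportions(self):
        table = make_table({"T0_r1": [1, 3]})
        norm = sc.normalize_total(table, pseudocount=0)
        assert np.allclose(norm["T0_r1"], [250_000.0, 750_000.0])

    def test_pseudocount_hand_arithmetic(self):
        # oracle: totals 0.5 + 1.5 + 3.5 = 5.5
        table = make_table({"T0_r1": [0, 1, 3]})
        norm = sc.normalize_total(table, pseudocount=0.5)
        expected = np.array([0.5, 1.5, 3.5]) / 5.5 * 1e6
        assert np.allclose(norm["T0_r1"], expected)

    def test_all_zero_sample_errors(self):
        table = make_table({"T0_r1": [0, 0]})
        with pytest.raises(ValueError, match="all-zero"):
            sc.normalize_total(table, pseudocount=0)

    def test_columns_sum_to_scale(self):
        table = make_table({"T0_r1": [5, 1, 9], "T14_r1": [2, 2, 2]})
        norm = sc.normalize_total(table, pseudocount=0)
        assert np.allclose(norm.sum(axis=0), 1e6)


class TestGuideLog2fc:
    def test_equal_is_zero(self):
        table = make_table({"T0_r1": [10, 20], "T14_r1": [10, 20]})
        g = sc.guide_log2fc(sc.normalize_total(table, 0), table)
        assert np.allclose(g["log2fc"], 0.0)

    def test_doubling_is_one(self):
        norm = pd.DataFrame({"T0_r1": [100.0], "T14_r1": [200.0]}, index=["g0"])
        g = sc.guide_log2fc(norm, [quant.SampleInfo("T0_r1", "T0"),
                                   quant.SampleInfo("T14_r1", "T14")])
        assert g["log2fc"].iloc[0] == pytest.approx(1.0)

    def test_quartering_is_minus_two(self):
        norm = pd.DataFrame({"T0_r1": [100.0], "T14_r1": [25.0]}, index=["g0"])
        g = sc.guide_log2fc(norm, [quant.SampleInfo("T0_r1", "T0"),
                                   quant.SampleInfo("T14_r1", "T14")])
        assert g["log2fc"].iloc[0] == pytest.approx(-2.0)

    def test_zero_t0_instructs_pseudocount(self):
        norm = pd.DataFrame({"T0_r1": [0.0], "T14_r1": [5.0]}, index=["g0"])
        with pytest.raises(ValueError, match="pseudocount"):
            sc.guide_log2fc(norm, [quant.SampleInfo("T0_r1", "T0"),
                                   quant.SampleInfo("T14_r1", "T14")])

    def test_missing_timepoint_errors(self):
        norm = pd.DataFrame({"T0_r1": [1.0]}, index=["g0"])
        with pytest.raises(ValueError, match="T0 and T14"):
            sc.guide_log2fc(norm, [quant.SampleInfo("T0_r1", "T0")])

    def test_replicates_averaged_before_ratio(self):
        norm = pd.DataFrame(
            {"T0_r1": [100.0], "T0_r2": [300.0], "T14_r1": [400.0]}, index=["g0"]
        )
        samples = [quant.SampleInfo("T0_r1", "T0", 1),
                   quant.SampleInfo("T0_r2", "T0", 2),
                   quant.SampleInfo("T14_r1", "T14", 1)]
        g = sc.guide_log2fc(norm, samples)
        assert g["fc"].iloc[0] == pytest.approx(2.0)  # 400 / mean(100, 300)


@pytest.fixture
def mini_manifest():
    return lib.build_library(
        {"A": ["AAAAAAAA", "CCCCCCCC", "GGGGGGGG"],
         "B": ["TTTTTTTT", "ACACACAC", "GTGTGTGT"]},
        n_nontargeting=3, seed=0,
    )


class TestAggregateGene:
    def _guide_frame(self, manifest, l2fc):
        gids = [r.guide_id for r in manifest.records]
        return pd.DataFrame(
            {"fc": np.exp2(l2fc), "log2fc": l2fc}, index=gids
        )

    def test_uniform_mean(self, mini_manifest):
        g = self._guide_frame(mini_manifest, [-1, -1, -1, 0, 0, 0, 0, 0, 0])
        out = sc.aggregate_gene(g, mini_manifest)
        assert out.loc["A", "score"] == pytest.approx(-1.0)

    def test_forced_mean(self, mini_manifest):
        g = self._guide_frame(mini_manifest, [-2, -1, 0, 0, 0, 0, 0, 0, 0])
        out = sc.aggregate_gene(g, mini_manifest)
        assert out.loc["A", "score"] == pytest.approx(-1.0)

    def test_order_invariance(self, mini_manifest):
        g = self._guide_frame(mini_manifest, [-2, -1, 0, 1, 2, 3, 0, 0, 0])
        shuffled = g.sample(frac=1, random_state=4)
        a = sc.aggregate_gene(g, mini_manifest)
        b = sc.aggregate_gene(shuffled, mini_manifest)
        assert a.sort_index().equals(b.sort_index())

    def test_nontargeting_excluded(self, mini_manifest):
        g = self._guide_frame(mini_manifest, [0.0] * 9)
        out = sc.aggregate_gene(g, mini_manifest)
        assert set(out.index) == {"A", "B"}

    def test_mean_ratio_option(self, mini_manifest):
        g = self._guide_frame(mini_manifest, [-2.0, 0.0, 1.0, 0, 0, 0, 0, 0, 0])
        out = sc.aggregate_gene(g, mini_manifest, gene_agg="mean_ratio")
        expected = np.log2((0.25 + 1.0 + 2.0) / 3)
        assert out.loc["A", "score"] == pytest.approx(expected)

    def test_unknown_guide_errors(self, mini_manifest):
        g = pd.DataFrame({"fc": [1.0], "log2fc": [0.0]}, index=["mystery"])
        with pytest.raises(ValueError, match="absent from manifest"):
            sc.aggregate_gene(g, mini_manifest)


class TestBuildNull:
    def test_exhaustive_count_c_12_3(self):
        # oracle: C(12, 3) = 220
        values = pd.Series(np.arange(12, dtype=float))
        null = sc.build_null(values, guides_per_gene=3, mode="exhaustive")
        assert null.n_pseudo == 220

    def test_all_zero_values(self):
        null = sc.build_null(np.zeros(12), mode="exhaustive")
        assert np.allclose(null.scores, 0.0)

    def test_resampled_determinism(self):
        values = np.random.default_rng(0).normal(size=30)
        a = sc.build_null(values, mode="resampled", n_pseudo=100, seed=5)
        b = sc.build_null(values, mode="resampled", n_pseudo=100, seed=5)
        assert np.array_equal(a.scores, b.scores)

    def test_too_few_guides_errors(self):
        with pytest.raises(ValueError, match="at least 3"):
            sc.build_null(np.zeros(2), guides_per_gene=3)


class TestCallHits:
    def _genes(self, scores):
        return pd.DataFrame(
            {"score": scores, "n_guides": 3},
            index=[f"G{i}" for i in range(len(scores))],
        )

    def test_median_score_p_half(self):
        null = sc.NullModel(np.linspace(-1, 1, 201), 3, "exhaustive")
        out = sc.call_hits(self._genes([0.0]), null)
        assert abs(out["p"].iloc[0] - 0.5) <= 1 / 202 + 1e-12

    def test_extreme_score_minimal_p(self):
        null = sc.NullModel(np.linspace(-1, 1, 100), 3, "exhaustive")
        out = sc.call_hits(self._genes([-5.0]), null, direction="depletion")
        assert out["p"].iloc[0] == pytest.approx(1 / 101)

    def test_bh_against_hand_computation(self):
        # oracle: BH by hand for p = (0.01, 0.02, 0.03, 0.5):
        # sorted q_i = min_{j>=i} p_j * n / j -> (0.04, 0.04, 0.04, 0.5)
        null = sc.NullModel(np.linspace(0, 1, 99), 3, "exhaustive")
        # add-one convention: p = (1 + k) / 100 when the score undercuts
        # exactly k null values
        scores = [null.scores[k] - 1e-9 for k in (0, 1, 2, 49)]
        out = sc.call_hits(self._genes(scores), null).sort_values("p")
        assert np.allclose(out["p"], [0.01, 0.02, 0.03, 0.5])
        assert np.allclose(out["q"], [0.04, 0.04, 0.04, 0.5])

    def test_enrichment_direction_mirrors(self):
        null = sc.NullModel(np.linspace(-1, 1, 100), 3, "exhaustive")
        out = sc.call_hits(self._genes([5.0]), null, direction="enrichment")
        assert out["p"].iloc[0] == pytest.approx(1 / 101)

    def test_sorted_by_score(self):
        null = sc.NullModel(np.linspace(-1, 1, 100), 3, "exhaustive")
        out = sc.call_hits(self._genes([0.5, -0.7, 0.1]), null)
        assert list(out["score"]) == sorted(out["score"])


class TestScreenProperties:
    def test_antisymmetry_timepoint_swap(self, sim_manifest):
        params = synth.ScreenSimParams(
            manifest=sim_manifest,
            gene_fitness={"G00000": -1.0}, seed=9,
        )
        counts, _ = synth.simulate_screen_counts(params)
        swapped = quant.GuideCountTable(
            counts=counts.counts.copy(),
            samples=[
                quant.SampleInfo(s.sample_id,
                                 "T0" if s.timepoint == "T14" else "T14",
                                 s.replicate)
                for s in counts.samples
            ],
            unassigned=dict(counts.unassigned),
        )
        norm = sc.normalize_total(counts)
        g1 = sc.guide_log2fc(norm, counts)
        g2 = sc.guide_log2fc(sc.normalize_total(swapped), swapped)
        assert np.allclose(g1["log2fc"], -g2["log2fc"])
        s1 = sc.aggregate_gene(g1, sim_manifest)
        s2 = sc.aggregate_gene(g2, sim_manifest)
        assert np.allclose(s1["score"], -s2["score"])

    def test_scale_invariance(self, sim_manifest):
        params = synth.ScreenSimParams(manifest=sim_manifest, seed=10)
        counts, _ = synth.simulate_screen_counts(params)
        scaled = quant.GuideCountTable(
            counts=counts.counts.assign(T0_r1=counts.counts["T0_r1"] * 10),
            samples=counts.samples,
            unassigned=dict(counts.unassigned),
        )
        g1 = sc.guide_log2fc(sc.normalize_total(counts, 0), counts)
        g2 = sc.guide_log2fc(sc.normalize_total(scaled, 0), scaled)
        assert np.allclose(g1["log2fc"], g2["log2fc"])

    def test_neutral_type_i_control(self, calibration_manifest):
        params = synth.ScreenSimParams(manifest=calibration_manifest, seed=11)
        counts, _ = synth.simulate_screen_counts(params)
        _, hits, _ = sc.score_screen(
            counts, calibration_manifest, null_mode="resampled",
            n_pseudo=500, seed=12,
        )
        frac = (hits["q"] < 0.1).mean()
        se = np.sqrt(0.1 * 0.9 / len(hits))
        assert frac <= 0.1 + 3 * se

    def test_dropout_recovery_small(self, sim_manifest):
        hits_frac = []
        genes = sim_manifest.genes("dub")
        fitness = {g: -0.5 for g in genes[: len(genes) // 10]}
        for seed in range(3):
            params = synth.ScreenSimParams(
                manifest=sim_manifest, gene_fitness=fitness, seed=200 + seed
            )
            counts, _ = synth.simulate_screen_counts(params)
            _, hits, _ = sc.score_screen(
                counts, sim_manifest, null_mode="resampled",
                n_pseudo=200, seed=seed,
            )
            n_top = int(np.ceil(0.1 * len(hits)))
            top = set(hits.sort_values("score").index[:n_top])
            hits_frac.append(len(top & set(fitness)) / len(fitness))
        assert np.mean(hits_frac) >= 0.8


class TestEssentialQc:
    def test_single_lowest_control_passes(self):
        manifest = lib.build_library(
            {"E": ["AAAAAAAA"], "X": ["CCCCCCCC"], "Y": ["GGGGGGGG"],
             "Z": ["TTTTTTTT"], "W": ["ACACACAC"]},
            n_nontargeting=1, essential_genes=["E"], seed=0,
        )
        scores = pd.DataFrame(
            {"score": [-3.0, 0.1, 0.0, 0.2, -0.1], "n_guides": 1},
            index=["E", "X", "Y", "Z", "W"],
        )
        report = sc.qc_essential_controls(scores, manifest)
        assert report.passed
        assert report.control_ranks["E"] == 1

    def test_no_essential_controls_errors(self, sim_manifest):
        scores = pd.DataFrame({"score": [0.0], "n_guides": 3}, index=["G00000"])
        with pytest.raises(ValueError, match="essential"):
            sc.qc_essential_controls(scores, sim_manifest)

    def test_strong_essentials_pass_over_seeds(self):
        catalog = toy_catalog(40)
        genes = list(catalog)
        manifest = lib.build_library(
            catalog, n_nontargeting=12, essential_genes=genes[:4], seed=1
        )
        fitness = {g: -1.0 for g in genes[:4]}
        passed = 0
        for seed in range(20):
            params = synth.ScreenSimParams(
                manifest=manifest, gene_fitness=fitness, seed=300 + seed
            )
            counts, _ = synth.simulate_screen_counts(params)
            norm = sc.normalize_total(counts)
            g = sc.guide_log2fc(norm, counts)
            scores = sc.aggregate_gene(g, manifest)
            passed += sc.qc_essential_controls(scores, manifest).passed
        assert passed == 20

    def test_neutral_pass_rate_matches_permutation_oracle(self):
        # oracle: under exchangeability the pass probability is that of both
        # controls scoring below the 25th percentile of the 38 others;
        # estimated by direct permutation of iid scores
        rng = np.random.default_rng(0)
        n_genes, n_controls = 40, 2
        oracle_pass = 0
        n_oracle = 20_000
        for _ in range(n_oracle):
            scores = rng.normal(size=n_genes)
            thr = np.quantile(scores[n_controls:], 0.25)
            oracle_pass += (scores[:n_controls] < thr).all()
        p_oracle = oracle_pass / n_oracle

        catalog = toy_catalog(n_genes)
        genes = list(catalog)
        manifest = lib.build_library(
            catalog, n_nontargeting=12, essential_genes=genes[:n_controls], seed=1
        )
        passed, n_sims = 0, 300
        for seed in range(n_sims):
            params = synth.ScreenSimParams(
                manifest=manifest, depth=100.0, seed=1000 + seed
            )
            counts, _ = synth.simulate_screen_counts(params)
            g = sc.guide_log2fc(sc.normalize_total(counts), counts)
            scores = sc.aggregate_gene(g, manifest)
            passed += sc.qc_essential_controls(scores, manifest).passed
        p_hat = passed / n_sims
        se = np.sqrt(p_oracle * (1 - p_oracle) / n_sims)
        assert abs(p_hat - p_oracle) <= 4 * se + 1e-9


class TestCompetitionNormalize:
    def test_constant_series(self):
        out = sc.competition_normalize({4: 0.7, 8: 0.7, 12: 0.7}, reference_time=4)
        assert all(v == pytest.approx(1.0) for v in out.values())

    def test_forced_values(self):
        out = sc.competition_normalize({"d4": 0.4, "d8": 0.2}, reference_time="d4")
        assert out == {"d4": pytest.approx(1.0), "d8": pytest.approx(0.5)}

    def test_missing_reference_errors(self):
        with pytest.raises(ValueError, match="absent"):
            sc.competition_normalize({"d8": 0.2}, reference_time="d4")

    def test_zero_reference_errors(self):
        with pytest.raises(ValueError, match="> 0"):
            sc.competition_normalize({"d4": 0.0, "d8": 0.2}, reference_time="d4")
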