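import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import bh_oracle, ks_oracle
from svscreen import (
    ConfigError,
    DataError,
    ScreenModel,
    SgRNALibrary,
    StatError,
    analyze_screen,
    bh_adjust,
    filter_sgrnas,
    gene_ks_test,
    gene_logfc,
    normalize_counts,
)
from svscreen.io import CountMatrix, NormalizedMatrix
from svscreen.screen import average_replicates, compute_log_ratios


class TestFilter:
    def test_worked_example(self, counts, library):
        # geneA loses its control-zero guide (5 -> 4), geneB keeps 4,
        # geneC (3 guides) falls below the "over 3" rule: 8 guides, 2 genes
        filtered, report = filter_sgrnas(counts, library)
        assert len(filtered.guides) == 8
        assert report.n_genes_out == 2
        assert report.guides_zero_in_control == ["geneA_sg3"]
        assert report.genes_too_few_guides == ["geneC"]
        assert "geneC_sg1" not in filtered.guides

    def test_clean_matrix_unchanged(self, counts, library):
        counts.counts.loc["geneA_sg3", "ctrl_2"] = 10  # remove the zero
        keep = [g for g in counts.guides if not g.startswith("geneC")]
        cm = counts.subset_guides(keep)
        filtered, report = filter_sgrnas(cm, library)
        assert list(filtered.guides) == keep
        assert report.guides_zero_in_control == []

    def test_control_zero_can_cascade_to_gene_removal(self, counts, library):
        # a second zero drops geneB to 3 guides -> the whole gene goes
        counts.counts.loc["geneB_sg1", "ctrl_1"] = 0
        filtered, report = filter_sgrnas(counts, library)
        assert set(report.genes_too_few_guides) == {"geneB", "geneC"}
        assert all(g.startswith("geneA") for g in filtered.guides)

    def test_no_control_samples_is_config_error(self, counts, library):
        counts.samples["condition"] = ["nt", "nt", "treated", "treated"]
        with pytest.raises(ConfigError):
            filter_sgrnas(counts, library)


class TestNormalize:
    def test_rpm_arithmetic(self, library):
        # 200 reads out of a 2e6-read sample -> 100 RPM
        counts = pd.DataFrame(
            {"s1": [200, 2_000_000 - 200] + [0] * 10}, index=library.guides
        ).astype(np.int64)
        samples = pd.DataFrame(
            {"condition": ["control"], "dose": [""], "timepoint": [1.0],
             "replicate": [1]},
            index=pd.Index(["s1"], name="sample_id"),
        )
        norm = normalize_counts(CountMatrix(counts, samples))
        assert norm.values.iloc[0, 0] == pytest.approx(100.0)

    def test_column_sums_are_one_million(self, counts):
        norm = normalize_counts(counts)
        assert np.allclose(norm.values.sum(axis=0), 1e6, rtol=1e-9)

    def test_zero_total_sample_rejected(self, counts):
        counts.counts["ctrl_1"] = 0
        with pytest.raises(DataError, match="ctrl_1"):
            normalize_counts(counts)


def _norm(values: dict, meta_rows: list) -> NormalizedMatrix:
    vals = pd.DataFrame(values)
    meta = pd.DataFrame(
        meta_rows,
        columns=["sample_id", "condition", "dose", "timepoint", "replicate"],
    ).set_index("sample_id")
    return NormalizedMatrix(vals, meta)


class TestAverageAndRatios:
    def test_replicate_mean(self):
        norm = _norm(
            {"a": [100.0], "b": [200.0]},
            [("a", "treated", "X", 1.0, 1), ("b", "treated", "X", 1.0, 2)],
        )
        avg = average_replicates(norm)
        assert avg.values.shape[1] == 1
        assert avg.values.iloc[0, 0] == pytest.approx(150.0)

    def test_single_replicate_identity(self):
        norm = _norm({"a": [100.0, 50.0]}, [("a", "treated", "X", 1.0, 1)])
        avg = average_replicates(norm)
        assert np.allclose(avg.values.to_numpy().ravel(), [100.0, 50.0])

    def test_replicate_order_invariance(self):
        rows = [("a", "treated", "X", 1.0, 1), ("b", "treated", "X", 1.0, 2)]
        n1 = _norm({"a": [100.0], "b": [200.0]}, rows)
        n2 = _norm({"b": [200.0], "a": [100.0]}, rows[::-1])
        assert average_replicates(n1).values.equals(average_replicates(n2).values)

    def test_log_ratio_arithmetic(self):
        norm = _norm(
            {"c": [100.0, 100.0, 100.0], "t": [100.0, 400.0, 0.0]},
            [("c", "control", "DMSO", 1.0, 1), ("t", "treated", "X", 1.0, 1)],
        )
        ratios = compute_log_ratios(norm, "control", pseudocount=0.5)
        col = ratios.iloc[:, 0]
        assert col.iloc[0] == pytest.approx(0.0)
        assert col.iloc[1] == pytest.approx(np.log2(400.5 / 100.5))
        assert col.iloc[2] == pytest.approx(np.log2(0.5 / 100.5))
        assert np.isfinite(col).all()

    def test_timepoint_matched_control(self):
        norm = _norm(
            {"c1": [100.0], "c2": [400.0], "t1": [200.0], "t2": [400.0]},
            [
                ("c1", "control", "DMSO", 1.0, 1),
                ("c2", "control", "DMSO", 2.0, 1),
                ("t1", "treated", "X", 1.0, 1),
                ("t2", "treated", "X", 2.0, 1),
            ],
        )
        ratios = compute_log_ratios(norm, "control", pseudocount=0.5)
        assert ratios["t1"].iloc[0] == pytest.approx(np.log2(200.5 / 100.5))
        assert ratios["t2"].iloc[0] == pytest.approx(np.log2(400.5 / 400.5))

    def test_missing_control_is_config_error(self):
        norm = _norm({"t": [1.0]}, [("t", "treated", "X", 1.0, 1)])
        with pytest.raises(ConfigError):
            compute_log_ratios(norm, "control")


def _ratio_lib(genes):
    return SgRNALibrary(
        pd.DataFrame({"gene": genes},
                     index=pd.Index([f"g{i}" for i in range(len(genes))],
                                    name="guide_id"))
    )


class TestGeneStats:
    def test_logfc_flat_mean(self):
        lib = _ratio_lib(["A", "A", "B", "B"])
        ratios = pd.DataFrame(
            {"c1": [2.0, 0.0, 1.0, 1.0], "c2": [1.0, 1.0, 1.0, 1.0]},
            index=lib.guides,
        )
        out = gene_logfc(ratios, lib)
        assert out["A"] == pytest.approx(1.0)
        assert out["B"] == pytest.approx(1.0)

    def test_logfc_zero_table(self):
        lib = _ratio_lib(["A", "A"])
        ratios = pd.DataFrame({"c1": [0.0, 0.0]}, index=lib.guides)
        assert (gene_logfc(ratios, lib) == 0).all()

    def test_ks_worked_example(self):
        # gene guides {2,3} vs background {0,1,2,3} -> sup gap 0.5
        lib = _ratio_lib(["B", "B", "A", "A"])
        ratios = pd.DataFrame({"c": [0.0, 1.0, 2.0, 3.0]}, index=lib.guides)
        stat, p = gene_ks_test(ratios, lib, "A")
        assert stat == pytest.approx(0.5)
        assert 0 < p <= 1

    def test_ks_gene_owning_all_guides(self):
        lib = _ratio_lib(["A", "A", "A"])
        ratios = pd.DataFrame({"c": [0.0, 1.0, 2.0]}, index=lib.guides)
        stat, p = gene_ks_test(ratios, lib, "A")
        assert stat == 0.0 and p == 1.0

    def test_ks_unknown_gene_rejected(self):
        lib = _ratio_lib(["A", "A"])
        ratios = pd.DataFrame({"c": [0.0, 1.0]}, index=lib.guides)
        with pytest.raises(StatError):
            gene_ks_test(ratios, lib, "Z")

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        x=st.lists(st.integers(-5, 5), min_size=2, max_size=20),
        extra=st.lists(st.integers(-5, 5), min_size=1, max_size=20),
    )
    def test_ks_stat_matches_bruteforce_oracle(self, x, extra):
        # background includes the gene's own guides, as in the pipeline
        y = x + extra
        lib = _ratio_lib(["A"] * len(x) + ["B"] * len(extra))
        ratios = pd.DataFrame({"c": [float(v) for v in y]}, index=lib.guides)
        stat, _ = gene_ks_test(ratios, lib, "A")
        assert stat == pytest.approx(ks_oracle([float(v) for v in x],
                                               [float(v) for v in y]))
        assert 0 <= stat <= 1


class TestBH:
    def test_single_p(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_worked_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_out_of_range_rejected(self):
        for bad in ([0.0], [1.5], [float("nan")]):
            with pytest.raises(StatError):
                bh_adjust(bad)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=100))
    def test_matches_stepup_oracle(self, p):
        assert np.allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.permutations(list(range(8))), st.data())
    def test_permutation_equivariance(self, perm, data):
        p = data.draw(st.lists(st.floats(1e-6, 1.0), min_size=8, max_size=8))
        q = bh_adjust(p)
        q_perm = bh_adjust([p[i] for i in perm])
        assert np.allclose([q[i] for i in perm], q_perm)

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(1e-6, 1, 50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestAnalyzeScreen:
    def test_deterministic(self, small_screen):
        cm, lib, _ = small_screen
        a = analyze_screen(cm, lib).gene_table
        b = analyze_screen(cm, lib).gene_table
        pd.testing.assert_frame_equal(a, b)

    def test_recovers_spiked_genes(self, small_screen):
        cm, lib, truth = small_screen
        res = analyze_screen(cm, lib)
        sv = set(truth.genes_with("synthetic_viable"))
        hits = set(res.hits["gene"])
        assert len(hits & sv) / len(sv) >= 0.9
        assert len(hits - sv) / max(len(hits), 1) <= 0.1

    def test_hit_rule_is_positive_and_significant(self, small_screen):
        cm, lib, _ = small_screen
        t = analyze_screen(cm, lib).gene_table
        assert (t["hit"] == ((t["logFC"] > 0) & (t["fdr"] < 0.05))).all()

    def test_logfc_invariant_to_sample_rescaling(self, small_screen):
        # depth normalization removes any per-sample scale factor
        cm, lib, _ = small_screen
        base = analyze_screen(cm, lib).gene_table
        scaled_counts = cm.counts.copy()
        scaled_counts.iloc[:, 0] = scaled_counts.iloc[:, 0] * 3
        scaled = analyze_screen(CountMatrix(scaled_counts, cm.samples), lib)
        assert np.allclose(base["logFC"], scaled.gene_table["logFC"])

    def test_summary_mentions_hits(self, small_screen):
        cm, lib, _ = small_screen
        res = analyze_screen(cm, lib)
        assert "hits" in res.summary()
        assert str(int(res.gene_table["hit"].sum())) in res.summary()

    def test_fdr_at_least_p(self, small_screen):
        cm, lib, _ = small_screen
        t = analyze_screen(cm, lib).gene_table
        assert (t["fdr"] >= t["p_value"] - 1e-15).all()

    def test_model_results_round_trip_tsv(self, small_screen, tmp_path):
        from svscreen import read_gene_results

        cm, lib, _ = small_screen
        res = analyze_screen(cm, lib)
        res.to_tsv(tmp_path / "r.tsv")
        back = read_gene_results(tmp_path / "r.tsv")
        assert list(back["gene"]) == list(res.gene_table["gene"])
        assert back["hit"].equals(res.gene_table["hit"])
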