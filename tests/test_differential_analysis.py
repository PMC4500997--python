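import itertools
import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from riccinet import (
    PipelineConfig,
    SyntheticSpec,
    delta_table,
    distribution_summary,
    generate_expression,
    run_differential_pipeline,
    top_bottom,
    wilcoxon_signed_rank_paired,
)
from riccinet.exceptions import (
    AlignmentError,
    ParameterError,
    PipelineError,
)


def series(d: dict) -> pd.Series:
    return pd.Series(d)


def enumerate_wilcoxon_p(diffs: np.ndarray) -> float:
    """Oracle: one-tailed p by full enumeration of the 2^n sign assignments."""
    d = diffs[diffs != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w >= w_obs - 1e-9:
            count += 1
    return count / 2**n


class TestDeltaTable:
    def test_identical_tables_all_zero(self):
        t = series({"e1": 0.4, "e2": 0.1})
        dt = delta_table(t, t)
        assert (dt.data["delta"] == 0).all()

    def test_swap_negates_and_reverses_ranks(self):
        t = series({"e1": 0.5, "e2": 0.1, "e3": 0.3})
        n = series({"e1": 0.2, "e2": 0.3, "e3": 0.05})
        fwd = delta_table(t, n)
        rev = delta_table(n, t)
        assert np.allclose(fwd.data["delta"], -rev.data["delta"])
        assert (fwd.data["rank"] + rev.data["rank"] == len(fwd) + 1).all()

    def test_two_row_example(self):
        dt = delta_table(series({"e1": 0.5, "e2": 0.1}), series({"e1": 0.2, "e2": 0.3}))
        assert dt.data.at["e1", "delta"] == pytest.approx(0.3)
        assert dt.data.at["e1", "rank"] == 1
        assert dt.data.at["e2", "delta"] == pytest.approx(-0.2)
        assert dt.data.at["e2", "rank"] == 2

    def test_key_mismatch_lists_offenders(self):
        with pytest.raises(AlignmentError, match="e3"):
            delta_table(series({"e1": 1.0, "e3": 2.0}), series({"e1": 1.0, "e2": 2.0}))

    def test_ties_break_lexicographically(self):
        dt = delta_table(
            series({"b": 1.0, "a": 1.0, "c": 0.0}), series({"b": 0.0, "a": 0.0, "c": 0.0})
        )
        assert dt.data.at["a", "rank"] == 1
        assert dt.data.at["b", "rank"] == 2


class TestTopBottom:
    def test_k_equals_size_returns_everything(self):
        dt = delta_table(series({"a": 1.0, "b": 2.0}), series({"a": 0.0, "b": 0.0}))
        top, bottom = top_bottom(dt, 2)
        assert len(top) == len(bottom) == 2

    def test_k_one_selects_extremes(self):
        dt = delta_table(series({"e1": 0.5, "e2": 0.1}), series({"e1": 0.2, "e2": 0.3}))
        top, bottom = top_bottom(dt, 1)
        assert top.index[0] == "e1"
        assert bottom.index[0] == "e2"

    def test_oversized_k_rejected(self):
        dt = delta_table(series({"a": 1.0}), series({"a": 0.0}))
        with pytest.raises(ParameterError):
            top_bottom(dt, 2)


class TestDistributionSummary:
    def test_identical_distributions_all_zero(self):
        vals = series({f"e{i}": i * 0.01 for i in range(40)})
        summary = distribution_summary(delta_table(vals, vals))
        assert summary["delta_average"] == 0
        for tails in summary["tails"].values():
            assert tails["left"] == 0 and tails["right"] == 0

    def test_constant_shift_appears_everywhere(self):
        rng = np.random.default_rng(0)
        base = series({f"e{i}": v for i, v in enumerate(rng.normal(size=60))})
        shifted = base + 0.25
        summary = distribution_summary(delta_table(shifted, base))
        assert summary["delta_average"] == pytest.approx(0.25, abs=1e-12)
        assert summary["mean_paired_difference"] == pytest.approx(0.25, abs=1e-12)
        for tails in summary["tails"].values():
            assert tails["left"] == pytest.approx(0.25, abs=1e-12)
            assert tails["right"] == pytest.approx(0.25, abs=1e-12)

    def test_reversed_pairing_same_marginals(self):
        # both distributions are {0..99}; pairing does not affect tail means
        t = series({f"e{i:02d}": float(i) for i in range(100)})
        n = series({f"e{i:02d}": float(99 - i) for i in range(100)})
        summary = distribution_summary(delta_table(t, n), tail_fractions=[0.05])
        # ceil(0.05*100) = 5 lowest values are 0..4 with mean 2 in both
        assert summary["tails"]["0.05"]["left"] == pytest.approx(0.0, abs=1e-12)
        assert summary["tails"]["0.05"]["right"] == pytest.approx(0.0, abs=1e-12)
        assert summary["delta_average"] == pytest.approx(0.0, abs=1e-12)

    def test_paired_mode_flag(self):
        t = series({"a": 1.0, "b": 5.0})
        n = series({"a": 0.0, "b": 0.0})
        summary = distribution_summary(
            delta_table(t, n), tail_fractions=[0.5], tail_mode="paired"
        )
        assert summary["tails"]["0.5"]["left"] == pytest.approx(1.0)
        assert summary["tails"]["0.5"]["right"] == pytest.approx(5.0)

    def test_invalid_tail_fraction(self):
        dt = delta_table(series({"a": 1.0}), series({"a": 0.0}))
        with pytest.raises(ParameterError):
            distribution_summary(dt, tail_fractions=[0.7])


class TestWilcoxon:
    def test_all_positive_n6_exact(self):
        # every sign assignment other than all-plus has smaller W+: p = 1/64
        p = wilcoxon_signed_rank_paired([2, 3, 4, 5, 6, 7], [1, 1, 1, 1, 1, 1])
        assert p == pytest.approx(1 / 64, abs=1e-12)

    def test_identical_inputs_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            p = wilcoxon_signed_rank_paired([1.0, 2.0], [1.0, 2.0])
        assert p == 1.0

    def test_symmetric_differences_near_half(self):
        # +v/-v pairs with equal magnitudes: W+ sits at the distribution center
        tumor = [1.0, -1.0, 2.0, -2.0, 3.0, -3.0]
        p = wilcoxon_signed_rank_paired(tumor, [0.0] * 6)
        assert p == pytest.approx(enumerate_wilcoxon_p(np.asarray(tumor)), abs=1e-12)
        assert 0.4 <= p <= 0.7

    @pytest.mark.parametrize("seed", range(12))
    def test_exact_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        diffs = np.round(rng.normal(size=n), 1)  # rounding forces occasional ties
        p = wilcoxon_signed_rank_paired(diffs, np.zeros(n))
        assert p == pytest.approx(enumerate_wilcoxon_p(diffs), abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_scipy_on_tie_free_data(self, seed):
        rng = np.random.default_rng(100 + seed)
        t = rng.normal(size=15)
        n = rng.normal(size=15)
        ours = wilcoxon_signed_rank_paired(t, n)
        theirs = stats.wilcoxon(t, n, alternative="greater", method="exact").pvalue
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_large_sample_normal_approximation_is_sane(self):
        rng = np.random.default_rng(7)
        t = rng.normal(0.5, 1.0, size=60)
        n = rng.normal(0.0, 1.0, size=60)
        p = wilcoxon_signed_rank_paired(t, n)
        theirs = stats.wilcoxon(
            t, n, alternative="greater", method="approx", correction=True
        ).pvalue
        assert p == pytest.approx(theirs, rel=1e-6)

    def test_null_p_values_approximately_uniform(self):
        # stochastic sanity check: under no shift the one-tailed p is ~U(0,1)
        rng = np.random.default_rng(2024)
        ps = [
            wilcoxon_signed_rank_paired(rng.normal(size=40), rng.normal(size=40))
            for _ in range(500)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestPipeline:
    @pytest.fixture(scope="class")
    def planted_run(self):
        spec0 = SyntheticSpec(seed=18)
        _, topo, _ = generate_expression(spec0)
        edge = sorted(topo)[0]
        spec = SyntheticSpec(seed=18, perturbed_edges={edge: 0.6})
        expr, topo, truth = generate_expression(spec)
        report = run_differential_pipeline(expr, topo, PipelineConfig(top_k=5))
        return edge, report

    def test_planted_edge_reaches_top_k(self, planted_run):
        edge, report = planted_run
        assert edge in set(report.top.index)

    def test_summary_structure(self, planted_run):
        _, report = planted_run
        assert set(report.summary["wilcoxon_p"]) == {
            "curvature_adjacent", "scalar_norm", "scalar_unnorm",
            "entropy_normal", "entropy_unnorm",
        }
        assert "delta_average" in report.summary["curvature"]
        assert set(report.summary["curvature"]["tails"]) == {
            "0.001", "0.005", "0.01", "0.03", "0.05"
        }

    def test_topologies_identical_across_phenotypes(self, planted_run):
        _, report = planted_run
        t_edges = set(map(tuple, report.curvature_tumor.adjacent()[["node_a", "node_b"]].to_numpy()))
        n_edges = set(map(tuple, report.curvature_normal.adjacent()[["node_a", "node_b"]].to_numpy()))
        assert t_edges == n_edges

    def test_unknown_phenotype_label_tagged(self):
        spec = SyntheticSpec(seed=2)
        expr, topo, _ = generate_expression(spec)
        with pytest.raises(PipelineError, match=r"\[phenotypes\]"):
            run_differential_pipeline(
                expr, topo, PipelineConfig(tumor_label="missing-label")
            )

    def test_identical_phenotypes_give_null_delta(self):
        # relabel one phenotype's samples into two halves: no real difference
        spec = SyntheticSpec(seed=5, n_samples_per_phenotype=120)
        expr, topo, _ = generate_expression(spec)
        normal_samples = expr.phenotype_samples("normal")
        sub = expr.values[normal_samples]
        pheno = pd.Series(
            ["tumor"] * 60 + ["normal"] * 60, index=normal_samples
        )
        from riccinet import ExpressionMatrix

        null_expr = ExpressionMatrix(sub, pheno)
        report = run_differential_pipeline(null_expr, topo)
        assert abs(report.summary["curvature"]["delta_average"]) < 0.05

    def test_report_bundle_files(self, planted_run, tmp_path):
        _, report = planted_run
        outdir = tmp_path / "bundle"
        report.write(outdir)
        expected = {
            "curvature_tumor.tsv", "curvature_normal.tsv",
            "entropy_tumor.tsv", "entropy_normal.tsv",
            "delta_curvature.tsv", "delta_nodal.tsv",
            "gene_differential_expression.tsv", "summary.json", "manifest.json",
        }
        assert expected <= {p.name for p in outdir.iterdir()}
        ranking = pd.read_csv(outdir / "delta_curvature.tsv", sep="\t")
        assert list(ranking.columns) == [
            "rank", "delta_kappa", "diff_coexpression", "gene_x", "gene_y"
        ]
        manifest = json.loads((outdir / "manifest.json").read_text())
        assert manifest["config"]["tumor_label"] == "tumor"
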