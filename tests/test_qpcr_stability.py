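"""qPCR processing and the four stability algorithms + aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from normgene.exceptions import (
    ConfigurationError,
    InputMismatchError,
    InsufficientDataError,
    ParameterError,
    UndefinedStatisticError,
)
from normgene.qpcr_stability import (
    QpcrDataset,
    bestkeeper,
    comprehensive_rank,
    delta_ct,
    genorm,
    normfinder,
    primer_efficiency_from_slope,
    quality_flags,
    relative_expression,
    standard_curve,
)

PERFECT_SLOPE = -1.0 / np.log10(2.0)  # ~ -3.321928: exact doubling per cycle


class TestPrimerEfficiency:
    def test_perfect_doubling_slope(self):
        e, pct = primer_efficiency_from_slope(-3.321928)
        assert e == pytest.approx(2.0, abs=1e-6)
        assert pct == pytest.approx(100.0, abs=0.01)

    def test_slope_minus_3_5(self):
        # closed form: (10^(1/3.5) - 1) * 100
        _, pct = primer_efficiency_from_slope(-3.5)
        assert pct == pytest.approx(93.0698, abs=0.01)

    def test_non_negative_slope_rejected(self):
        with pytest.raises(ParameterError):
            primer_efficiency_from_slope(0.0)
        with pytest.raises(ParameterError):
            primer_efficiency_from_slope(2.0)


class TestStandardCurve:
    def test_exact_line_passes_qc(self):
        # five-fold dilutions: log10 c = 0, -0.699, -1.398, ...
        logc = -np.log10(5.0) * np.arange(5)
        cq = 35.0 + PERFECT_SLOPE * logc
        out = standard_curve(zip(logc, cq))
        assert out["r_squared"] == pytest.approx(1.0, abs=1e-12)
        assert out["E"] == pytest.approx(2.0, abs=1e-9)
        assert out["qc_pass"]

    def test_noisy_line_fails_qc(self):
        logc = -np.log10(5.0) * np.arange(6)
        cq = 35.0 + PERFECT_SLOPE * logc + np.array([0, 2.5, -2.5, 2.5, -2.5, 0])
        out = standard_curve(zip(logc, cq))
        assert out["r_squared"] < 0.97
        assert not out["qc_pass"]

    def test_two_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            standard_curve([(0.0, 35.0), (-1.0, 38.3)])


def _dataset(records, ntc, eff):
    return QpcrDataset(
        records=pd.DataFrame(
            records, columns=["gene_id", "sample_id", "group", "replicate", "cq"]
        ),
        ntc_mean_cq=ntc,
        efficiencies=eff,
    )


class TestRelativeExpression:
    def test_cq_equal_to_ntc_gives_one(self):
        ds = _dataset(
            [("g1", "s1", "a", 1, 35.0)], {"g1": 35.0}, {"g1": 2.0}
        )
        expr = relative_expression(ds)
        assert expr.loc["g1", "s1"] == pytest.approx(1.0)

    def test_five_cycles_below_ntc_is_32fold(self):
        ds = _dataset(
            [("g1", "s1", "a", 1, 30.0)], {"g1": 35.0}, {"g1": 2.0}
        )
        expr = relative_expression(ds)
        assert expr.loc["g1", "s1"] == pytest.approx(32.0)

    def test_replicates_combined_by_geometric_mean(self):
        ds = _dataset(
            [("g1", "s1", "a", 1, 30.0), ("g1", "s1", "a", 2, 32.0)],
            {"g1": 35.0},
            {"g1": 2.0},
        )
        expr = relative_expression(ds)
        assert expr.loc["g1", "s1"] == pytest.approx(np.sqrt(32.0 * 8.0))

    def test_high_cq_flagged_but_still_computed(self):
        ds = _dataset(
            [("g1", "s1", "a", 1, 36.0)], {"g1": 38.0}, {"g1": 2.0}
        )
        flags = quality_flags(ds)
        assert len(flags) == 1 and flags.iloc[0]["flag"] == "no amplification"
        assert np.isfinite(relative_expression(ds).loc["g1", "s1"])

    def test_missing_ntc_without_calibrator_rejected(self):
        ds = _dataset([("g1", "s1", "a", 1, 30.0)], {}, {"g1": 2.0})
        with pytest.raises(ConfigurationError, match="g1"):
            relative_expression(ds)
        # calibrator option references the per-gene minimum Cq instead
        assert relative_expression(ds, calibrator=True).loc["g1", "s1"] == 1.0

    def test_cq_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            _dataset([("g1", "s1", "a", 1, 46.0)], {"g1": 35.0}, {"g1": 2.0})

    def test_missing_efficiency_rejected(self):
        with pytest.raises(ConfigurationError, match="g1"):
            _dataset([("g1", "s1", "a", 1, 30.0)], {"g1": 35.0}, {})


class TestReadQpcrDataset:
    def test_dilution_series_efficiency_input(self, tmp_path):
        cq_csv = tmp_path / "cq.csv"
        cq_csv.write_text(
            "gene_id,sample_id,group,replicate,cq\n"
            "g1,s1,a,1,30.0\n"
            "g1,NTC,,1,38.0\n"
        )
        # exact doubling curve: E fitted from the slope must be 2
        eff_csv = tmp_path / "eff.csv"
        slope = -1.0 / np.log10(2.0)
        rows = ["gene_id,log10_concentration,cq"] + [
            f"g1,{-0.699 * i},{22.0 + slope * (-0.699 * i)}" for i in range(4)
        ]
        eff_csv.write_text("\n".join(rows) + "\n")
        from normgene.qpcr_stability import read_qpcr_dataset

        ds = read_qpcr_dataset(cq_csv, eff_csv)
        assert ds.efficiencies["g1"] == pytest.approx(2.0, abs=1e-9)
        assert ds.ntc_mean_cq["g1"] == 38.0

    def test_unrecognized_efficiency_columns_rejected(self, tmp_path):
        cq_csv = tmp_path / "cq.csv"
        cq_csv.write_text("gene_id,sample_id,group,replicate,cq\ng1,s1,a,1,30.0\n")
        eff_csv = tmp_path / "eff.csv"
        eff_csv.write_text("gene_id,foo\ng1,2.0\n")
        from normgene.qpcr_stability import read_qpcr_dataset

        with pytest.raises(ConfigurationError):
            read_qpcr_dataset(cq_csv, eff_csv)


def _expr_frame(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i + 1}" for i in range(values.shape[0])]
    samples = samples or [f"s{j + 1}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestGenorm:
    def test_proportional_pair_has_zero_m(self):
        x = np.array([[1.0, 2.0, 4.0, 3.0]])
        expr = _expr_frame(np.vstack([x, 3.0 * x]))
        out = genorm(expr)
        assert np.allclose(out.ranking["m"], 0.0, atol=1e-12)

    def test_matches_direct_definition_oracle(self):
        rng = np.random.default_rng(12)
        expr = _expr_frame(rng.lognormal(0, 0.4, size=(4, 8)))
        out = genorm(expr)
        first_step = out.m_steps[out.m_steps["step"] == 0].set_index("gene_id")
        log2 = np.log2(expr.to_numpy())
        for j, gid in enumerate(expr.index):
            sds = [
                np.std(log2[j] - log2[k], ddof=1)
                for k in range(len(expr))
                if k != j
            ]
            assert first_step.loc[gid, "m"] == pytest.approx(
                np.mean(sds), abs=1e-12
            )

    def test_noisy_gene_excluded_first(self):
        rng = np.random.default_rng(7)
        base = np.exp(rng.normal(0, 0.05, size=(3, 10)))
        noisy = np.exp(rng.normal(0, 1.0, size=(1, 10)))
        expr = _expr_frame(np.vstack([base, noisy]))
        out = genorm(expr)
        assert out.exclusion_order[0] == "g4"

    def test_final_pair_shares_rank_one(self):
        rng = np.random.default_rng(3)
        expr = _expr_frame(rng.lognormal(0, 0.3, size=(5, 6)))
        ranks = out = genorm(expr).ranking["rank"]
        assert sorted(ranks) == [1.0, 1.0, 3.0, 4.0, 5.0]

    def test_rescaling_invariance(self):
        """Per-gene multiplicative factors cancel in the log-ratios."""
        rng = np.random.default_rng(5)
        expr = _expr_frame(rng.lognormal(0, 0.5, size=(4, 7)))
        scaled = expr.mul(pd.Series([2.0, 0.5, 10.0, 1.7], index=expr.index), axis=0)
        m1 = genorm(expr).ranking.set_index("gene_id")["m"]
        m2 = genorm(scaled).ranking.set_index("gene_id")["m"]
        assert np.allclose(m1, m2, atol=1e-12)

    def test_pairwise_variation_matches_definition(self):
        rng = np.random.default_rng(9)
        expr = _expr_frame(rng.lognormal(0, 0.4, size=(4, 8)))
        out = genorm(expr)
        order = list(
            out.ranking.sort_values(["rank", "gene_id"])["gene_id"]
        )  # most stable first; the final pair is ranks 1,1
        log2 = np.log2(expr)
        nf2 = log2.loc[order[:2]].mean(axis=0)
        nf3 = log2.loc[order[:3]].mean(axis=0)
        assert out.pairwise_variation["V2/3"] == pytest.approx(
            (nf2 - nf3).std(ddof=1), abs=1e-12
        )

    def test_non_positive_expression_rejected(self):
        expr = _expr_frame([[1.0, 0.0, 2.0], [1.0, 2.0, 3.0]])
        with pytest.raises(UndefinedStatisticError):
            genorm(expr)

    def test_single_gene_rejected(self):
        with pytest.raises(InsufficientDataError):
            genorm(_expr_frame([[1.0, 2.0, 3.0]]))


class TestNormfinder:
    def _groups(self, samples, split):
        return {s: ("a" if i < split else "b") for i, s in enumerate(samples)}

    def test_flat_gene_is_most_stable(self):
        rng = np.random.default_rng(4)
        vals = rng.lognormal(0, 0.3, size=(5, 8))
        vals[2] = 2.0  # identical across all samples in both groups
        expr = _expr_frame(vals)
        out = normfinder(expr, self._groups(expr.columns, 4))
        best = out.sort_values("stability").iloc[0]
        assert best["gene_id"] == "g3"

    def test_group_shifted_gene_less_stable_than_matched_flat_gene(self):
        """A gene whose mean differs 2 log2 units between groups always ranks
        below an unshifted gene with the same intragroup noise."""
        for seed in range(25):
            rng = np.random.default_rng(seed)
            n_per = 10
            base = rng.lognormal(1.0, 0.2, size=(6, 2 * n_per))
            shifted = base[0] * (2.0 ** np.r_[np.zeros(n_per), 2 * np.ones(n_per)])
            expr = _expr_frame(np.vstack([shifted, base[1:]]))
            out = normfinder(expr, self._groups(expr.columns, n_per)).set_index(
                "gene_id"
            )
            assert out.loc["g1", "stability"] > out.loc["g2", "stability"]

    def test_single_sample_group_rejected(self):
        expr = _expr_frame(np.ones((2, 3)) + np.arange(3))
        groups = {"s1": "a", "s2": "a", "s3": "b"}
        with pytest.raises(InsufficientDataError):
            normfinder(expr, groups)

    def test_single_group_falls_back_to_intragroup_variant(self, caplog):
        rng = np.random.default_rng(1)
        expr = _expr_frame(rng.lognormal(0, 0.3, size=(4, 6)))
        groups = {s: "only" for s in expr.columns}
        with caplog.at_level("INFO", logger="normgene.qpcr_stability"):
            out = normfinder(expr, groups)
        assert len(out) == 4 and out["stability"].ge(0).all()


class TestBestkeeper:
    def test_gene_equal_to_index_tops_correlation_ranking(self):
        rng = np.random.default_rng(6)
        cq = rng.uniform(20, 30, size=(3, 6))
        index = np.exp(np.log(np.vstack([cq, cq.mean(axis=0)])).mean(axis=0))
        # append a gene exactly equal to the resulting index of the 4-gene panel:
        # build iteratively instead -- use a fixed-point: gene 4 = geometric
        # mean of the first three genes; then the index is the geomean of all
        # four, and gene 4 is a monotone transform of it => r = 1.
        g4 = np.exp(np.log(cq).mean(axis=0))
        frame = _expr_frame(np.vstack([cq, g4]))
        out = bestkeeper(frame)
        stats_ = out.statistics.set_index("gene_id")
        assert stats_.loc["g4", "r"] == pytest.approx(1.0, abs=1e-12)
        assert stats_.loc["g4", "rank_correlation"] == 1.0

    def test_two_gene_toy_matches_hand_computation(self):
        cq = _expr_frame([[20.0, 21.0, 22.0], [30.0, 31.0, 32.0]])
        out = bestkeeper(cq)
        assert np.allclose(
            out.index.to_numpy(),
            [np.sqrt(600.0), np.sqrt(651.0), np.sqrt(704.0)],
            atol=1e-9,
        )
        stats_ = out.statistics.set_index("gene_id")
        for gid, row in zip(["g1", "g2"], cq.to_numpy()):
            sd = np.std(row, ddof=1)
            assert stats_.loc[gid, "sd_cq"] == pytest.approx(sd, abs=1e-9)
            assert stats_.loc[gid, "cv_pct"] == pytest.approx(
                100 * sd / row.mean(), abs=1e-9
            )
            r = stats.pearsonr(row, out.index.to_numpy()).statistic
            assert stats_.loc[gid, "r"] == pytest.approx(r, abs=1e-9)

    def test_constant_gene_conventions(self):
        cq = _expr_frame([[25.0, 25.0, 25.0], [20.0, 24.0, 28.0]])
        out = bestkeeper(cq)
        stats_ = out.statistics.set_index("gene_id")
        assert np.isnan(stats_.loc["g1", "r"])
        assert stats_.loc["g1", "rank_sd"] == 1.0
        assert np.isnan(stats_.loc["g1", "rank_correlation"])
        assert out.notices

    def test_common_scaling_leaves_r_unchanged(self):
        """Scaling every Cq by a common factor scales the geometric-mean
        index by the same factor, so Pearson r is exactly invariant."""
        rng = np.random.default_rng(10)
        cq = rng.uniform(20, 30, size=(4, 8))
        r1 = bestkeeper(_expr_frame(cq)).statistics.set_index("gene_id")["r"]
        r2 = bestkeeper(_expr_frame(1.3 * cq)).statistics.set_index("gene_id")["r"]
        assert np.allclose(r1, r2, atol=1e-12)

    def test_minimum_size_enforced(self):
        with pytest.raises(InsufficientDataError):
            bestkeeper(_expr_frame([[20.0, 21.0, 22.0]]))
        with pytest.raises(InsufficientDataError):
            bestkeeper(_expr_frame([[20.0, 21.0], [30.0, 31.0]]))


class TestDeltaCt:
    def test_offset_genes_have_zero_stability(self):
        base = np.array([20.0, 22.0, 21.0, 23.0])
        cq = _expr_frame([base, base + 5.0, base - 3.0])
        out = delta_ct(cq)
        assert np.allclose(out["stability"], 0.0, atol=1e-12)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(15)
        cq = _expr_frame(rng.uniform(18, 32, size=(4, 6)))
        out = delta_ct(cq).set_index("gene_id")
        X = cq.to_numpy()
        for j, gid in enumerate(cq.index):
            sds = [
                np.std(X[j] - X[k], ddof=1) for k in range(len(X)) if k != j
            ]
            assert out.loc[gid, "stability"] == pytest.approx(
                np.mean(sds), abs=1e-12
            )

    def test_single_gene_rejected(self):
        with pytest.raises(InsufficientDataError):
            delta_ct(_expr_frame([[20.0, 21.0, 22.0]]))


class TestComprehensiveRank:
    def test_all_rank_one_aggregates_to_one(self):
        r = pd.Series({"g1": 1.0, "g2": 2.0})
        out = comprehensive_rank([r, r, r, r]).set_index("gene_id")
        assert out.loc["g1", "geomean_rank"] == 1.0
        assert out.loc["g1", "rank"] == 1.0

    def test_geometric_mean_of_2_and_4(self):
        a = pd.Series({"g1": 2.0, "g2": 1.0})
        b = pd.Series({"g1": 4.0, "g2": 1.0})
        out = comprehensive_rank([a, b]).set_index("gene_id")
        assert out.loc["g1", "geomean_rank"] == pytest.approx(
            2 * np.sqrt(2), abs=1e-12
        )

    def test_mismatched_gene_sets_rejected(self):
        a = pd.Series({"g1": 1.0, "g2": 2.0})
        b = pd.Series({"g1": 1.0, "g3": 2.0})
        with pytest.raises(InputMismatchError, match="g2"):
            comprehensive_rank([a, b])

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(6)]
        rankings = [
            pd.Series(rng.permutation(np.arange(1.0, 7.0)), index=genes)
            for _ in range(4)
        ]
        out1 = comprehensive_rank(rankings)
        out2 = comprehensive_rank(rankings[::-1])
        pd.testing.assert_frame_equal(out1, out2)
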