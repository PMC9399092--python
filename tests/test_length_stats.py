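"""Mann-Whitney machinery and ORF-length summaries."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polyti import (
    GeneAnnotation,
    ParameterError,
    length_summary,
    mann_whitney,
    ti_length_correlation,
    ti_ratio_by_length_bin,
)
from polyti.ti import DifferentialCalls, TITable


def enumeration_oracle(x, y, alternative="two_sided"):
    """Independent exact Mann-Whitney p: U by direct pair counting over
    every assignment of the pooled values to the first sample."""
    pooled = list(x) + list(y)
    n = len(x)

    def u_of(sample_x, sample_y):
        u = 0.0
        for xi in sample_x:
            for yj in sample_y:
                u += 1.0 if xi > yj else (0.5 if xi == yj else 0.0)
        return u

    u_obs = u_of(x, y)
    mu = n * (len(pooled) - n) / 2.0
    hits = total = 0
    for idx in combinations(range(len(pooled)), n):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_of(xs, ys)
        total += 1
        if alternative == "two_sided":
            hits += abs(u - mu) >= abs(u_obs - mu) - 1e-9
        elif alternative == "greater":
            hits += u >= u_obs - 1e-9
        else:
            hits += u <= u_obs + 1e-9
    return u_obs, hits / total


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6], mode="exact")
        assert res.u == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2 / C(6,3) = 2/20
        assert res.mode == "exact"

    def test_identical_multisets_give_p_one(self):
        res = mann_whitney([1, 2, 2, 3], [1, 2, 2, 3], mode="exact")
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("alternative", ["two_sided", "less", "greater"])
    def test_matches_enumeration_oracle_with_ties(self, alternative):
        rng = np.random.default_rng(31)
        for _ in range(8):
            n = int(rng.integers(2, 6))
            m = int(rng.integers(2, 6))
            x = rng.integers(0, 4, n).tolist()  # small support forces ties
            y = rng.integers(0, 4, m).tolist()
            u_oracle, p_oracle = enumeration_oracle(x, y, alternative)
            res = mann_whitney(x, y, alternative=alternative, mode="exact")
            assert res.u == pytest.approx(u_oracle)
            assert res.p_value == pytest.approx(p_oracle)

    def test_exact_agrees_with_scipy_exact_without_ties(self):
        rng = np.random.default_rng(37)
        x, y = rng.normal(0, 1, 5), rng.normal(0.5, 1, 6)
        res = mann_whitney(x, y, mode="exact")
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert res.p_value == pytest.approx(float(ref.pvalue))

    def test_exact_and_normal_approx_agree_at_n30(self):
        rng = np.random.default_rng(41)
        x, y = rng.normal(0, 1, 30), rng.normal(0.3, 1, 30)
        # C(60,30) is far past the enumeration cap; use scipy's exact
        # distribution as the reference for the approximation instead
        approx = mann_whitney(x, y, mode="normal_approx")
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert approx.p_value == pytest.approx(float(ref.pvalue), abs=0.01)

    def test_empty_sample_rejected(self):
        with pytest.raises(ParameterError):
            mann_whitney([], [1.0])

    def test_infeasible_exact_enumeration_rejected(self):
        with pytest.raises(ParameterError):
            mann_whitney(list(range(30)), list(range(30)), mode="exact")


def _make_calls(deltas: dict) -> DifferentialCalls:
    call = {
        g: "over_translated" if d > 0.5 else ("under_translated" if d < -0.5 else "unchanged")
        for g, d in deltas.items()
    }
    table = pd.DataFrame(
        {"delta_log2_ti": pd.Series(deltas), "call": pd.Series(call)}
    ).rename_axis("gene_id")
    return DifferentialCalls(table, 0.5, ("t", "untreated"), ("r", "untreated"))


def _make_annotation(lengths: dict) -> GeneAnnotation:
    return GeneAnnotation(
        pd.DataFrame(
            {
                "orf_length_nt": pd.Series(lengths, dtype=np.int64),
                "start_context": None,
                "categories": [()] * len(lengths),
            }
        ).rename_axis("gene_id")
    )


class TestLengthSummary:
    def test_mean_ratio_arithmetic(self):
        deltas = {"o1": 2.0, "o2": 1.5, "u1": -2.0, "u2": -1.5, "u3": -1.0}
        ann = _make_annotation(
            {"o1": 6000, "o2": 6600, "u1": 400, "u2": 500, "u3": 900}
        )
        summary = length_summary(_make_calls(deltas), ann, top_n=3)
        # top_n shrinks to 2 on the over side with a warning
        assert summary.under_top_mean == pytest.approx(600.0)
        assert summary.over_top_mean == pytest.approx(6300.0)

    def test_exact_top_n_ratio(self):
        deltas = {"o1": 2.0, "o2": 1.5, "u1": -2.0, "u2": -1.5}
        ann = _make_annotation({"o1": 6000, "o2": 6600, "u1": 800, "u2": 1000})
        summary = length_summary(_make_calls(deltas), ann, top_n=2)
        assert summary.mean_ratio == pytest.approx(6300.0 / 900.0)

    def test_null_lengths_give_ratio_near_one(self):
        rng = np.random.default_rng(43)
        lengths = {}
        deltas = {}
        for i in range(200):
            deltas[f"o{i}"] = 0.6 + rng.random()
            deltas[f"u{i}"] = -0.6 - rng.random()
            lengths[f"o{i}"] = int(np.exp(rng.normal(7.2, 0.6)))
            lengths[f"u{i}"] = int(np.exp(rng.normal(7.2, 0.6)))
        summary = length_summary(_make_calls(deltas), _make_annotation(lengths), top_n=200)
        assert 0.7 < summary.mean_ratio < 1.4
        assert summary.over_vs_under.p_value >= 0.05


class TestTiRatioByLengthBin:
    def _table(self, ti_b, ti_a, genes):
        df = pd.DataFrame(
            {("bb", "untreated"): ti_b, ("WT", "untreated"): ti_a},
            index=pd.Index(genes, name="gene_id"),
        )
        df.columns = pd.MultiIndex.from_tuples(df.columns, names=["strain", "condition"])
        return TITable(df, df.astype(bool) & False, "mean_log2", 0.0)

    def test_identical_tables_give_zero_bins(self):
        genes = [f"g{i}" for i in range(20)]
        vals = np.linspace(0.5, 4.0, 20)
        table = self._table(vals, vals, genes)
        ann = _make_annotation({g: 300 * (i + 1) for i, g in enumerate(genes)})
        out = ti_ratio_by_length_bin(
            table, ("bb", "untreated"), ("WT", "untreated"), ann, [0, 3000, 10000],
            min_genes=1,
        )
        assert np.allclose(out["mean_delta_log2"], 0.0)

    def test_constructed_sign_split(self):
        genes = [f"g{i}" for i in range(10)]
        lengths = {g: 1000 if i < 5 else 5000 for i, g in enumerate(genes)}
        ti_b = [1.0] * 5 + [4.0] * 5  # delta -1 short, +1 long
        ti_a = [2.0] * 10
        out = ti_ratio_by_length_bin(
            self._table(ti_b, ti_a, genes),
            ("bb", "untreated"),
            ("WT", "untreated"),
            _make_annotation(lengths),
            [0, 3000, 10000],
            min_genes=1,
        )
        assert list(out["mean_delta_log2"]) == [-1.0, 1.0]

    def test_refined_bins_reaggregate_to_coarse(self):
        rng = np.random.default_rng(47)
        genes = [f"g{i}" for i in range(60)]
        lengths = {g: int(rng.integers(100, 5900)) for g in genes}
        ti_b = 2.0 ** rng.normal(0, 1, 60)
        ti_a = 2.0 ** rng.normal(0, 1, 60)
        table = self._table(ti_b, ti_a, genes)
        ann = _make_annotation(lengths)
        coarse = ti_ratio_by_length_bin(
            table, ("bb", "untreated"), ("WT", "untreated"), ann, [0, 3000, 6000],
            min_genes=1,
        )
        fine = ti_ratio_by_length_bin(
            table, ("bb", "untreated"), ("WT", "untreated"), ann,
            [0, 1500, 3000, 4500, 6000], min_genes=1,
        )
        for lo, hi, expect in zip(coarse["bin_lo_nt"], coarse["bin_hi_nt"],
                                  coarse["mean_delta_log2"]):
            sub = fine[(fine["bin_lo_nt"] >= lo) & (fine["bin_hi_nt"] <= hi)]
            weighted = np.average(sub["mean_delta_log2"], weights=sub["n_genes"])
            assert weighted == pytest.approx(expect)

    def test_nonmonotone_edges_rejected(self):
        table = self._table([1.0] * 10, [1.0] * 10, [f"g{i}" for i in range(10)])
        ann = _make_annotation({f"g{i}": 300 for i in range(10)})
        with pytest.raises(ParameterError):
            ti_ratio_by_length_bin(
                table, ("bb", "untreated"), ("WT", "untreated"), ann, [0, 3000, 2000]
            )


class TestTiLengthCorrelation:
    def _single(self, ti_vals, lengths):
        genes = list(lengths)
        df = pd.DataFrame({("WT", "untreated"): ti_vals}, index=pd.Index(genes, name="gene_id"))
        df.columns = pd.MultiIndex.from_tuples(df.columns, names=["strain", "condition"])
        return TITable(df, df.astype(bool) & False, "mean_log2", 0.0), _make_annotation(lengths)

    def test_strictly_decreasing_gives_minus_one(self):
        lengths = {f"g{i}": 300 * (i + 1) for i in range(15)}
        table, ann = self._single(np.linspace(8, 1, 15), lengths)
        rho, _ = ti_length_correlation(table, ann)
        assert rho == pytest.approx(-1.0)

    def test_matches_brute_force_rank_computation(self):
        rng = np.random.default_rng(53)
        lengths = {f"g{i}": int(rng.integers(100, 8000)) for i in range(50)}
        ti_vals = 2.0 ** rng.normal(0, 1, 50)
        table, ann = self._single(ti_vals, lengths)
        rho, _ = ti_length_correlation(table, ann)
        # brute force: Pearson correlation of the rank vectors
        r1 = stats.rankdata(np.log2(ti_vals))
        r2 = stats.rankdata(np.log(np.array(list(lengths.values()), dtype=float)))
        expected = np.corrcoef(r1, r2)[0, 1]
        assert rho == pytest.approx(expected)

    def test_constant_input_rejected(self):
        lengths = {f"g{i}": 300 * (i + 1) for i in range(12)}
        table, ann = self._single(np.ones(12), lengths)
        with pytest.raises(ParameterError):
            ti_length_correlation(table, ann)
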