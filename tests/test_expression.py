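"""Expression calling, ΔCt statistics and profile clustering."""

import numpy as np
import pandas as pd
import pytest

from dnmt3b_targets.expression import (
    CtTable,
    call_expressed,
    cluster_profiles,
    delta_ct,
    differential_expression,
)
from oracles import naive_upgma_heights, pooled_t_test


def make_table(ct_rows, groups=None):
    """ct_rows: dict gene -> list of Ct over samples s1..sn (NaN allowed)."""
    n = len(next(iter(ct_rows.values())))
    samples = [f"s{i}" for i in range(n)]
    if groups is None:
        groups = {s: ("case" if i < n // 2 else "control") for i, s in enumerate(samples)}
    genes = dict(ct_rows)
    genes.setdefault("S18", [15.0] * n)
    chemistry = {g: "probe_array" for g in genes}
    ct = pd.DataFrame(genes, index=samples, dtype=float)
    return CtTable(ct, groups, chemistry, {"probe_array": "S18"})


class TestCallExpressed:
    def test_all_below_ceiling_expressed(self):
        t = make_table({"A": [28.0] * 6})
        assert call_expressed(t) == {"A"}

    def test_ceiling_boundary_is_strict(self):
        t = make_table({"A": [32.0] * 6})
        assert call_expressed(t) == set()

    def test_dye_ceiling_is_35(self):
        n = 6
        samples = [f"s{i}" for i in range(n)]
        ct = pd.DataFrame({"L": [33.0] * n, "GAPDH": [16.0] * n}, index=samples)
        groups = {s: ("case" if i < 3 else "control") for i, s in enumerate(samples)}
        t = CtTable(ct, groups, {"L": "dye", "GAPDH": "dye"}, {"dye": "GAPDH"})
        assert call_expressed(t) == {"L"}

    def test_missing_counts_as_not_detected(self):
        t = make_table({"A": [28.0, np.nan, np.nan, 28.0, np.nan, np.nan]})
        # detected in 1/3 case and 1/3 control samples: below the 0.5 fraction
        assert call_expressed(t) == set()

    def test_requires_fraction_in_both_groups(self):
        # detected in every case sample but no control sample
        t = make_table({"A": [28.0, 28.0, 28.0, 36.0, 36.0, 36.0]})
        assert call_expressed(t) == set()

    def test_all_missing_not_expressed(self):
        t = make_table({"A": [np.nan] * 6})
        assert call_expressed(t) == set()

    def test_endogenous_control_not_reported(self):
        t = make_table({"A": [28.0] * 6})
        assert "S18" not in call_expressed(t)

    def test_monotone_in_ceiling(self):
        t = make_table({"A": [33.0] * 6, "B": [28.0] * 6})
        low = call_expressed(t, ceilings={"probe_array": 32.0})
        high = call_expressed(t, ceilings={"probe_array": 34.0})
        assert low <= high
        assert high == {"A", "B"}


class TestDeltaCt:
    def test_identity_when_equal_to_control(self):
        t = make_table({"A": [30.0] * 4})
        t.ct["S18"] = 30.0
        d = delta_ct(t)
        assert (d["A"] == 0).all()
        assert (2.0 ** -d["A"] == 1.0).all()

    def test_simple_difference(self):
        t = make_table({"A": [25.0] * 4})
        t.ct["S18"] = 20.0
        assert (delta_ct(t)["A"] == 5.0).all()

    def test_matches_elementwise_recomputation(self, rng):
        n = 10
        genes = {f"G{i}": list(rng.uniform(20, 30, n)) for i in range(5)}
        t = make_table(genes)
        t.ct["S18"] = rng.uniform(14, 16, n)
        d = delta_ct(t)
        for g in genes:
            for s in t.samples:
                assert d.at[s, g] == pytest.approx(t.ct.at[s, g] - t.ct.at[s, "S18"])

    def test_missing_ct_propagates(self):
        t = make_table({"A": [25.0, np.nan, 25.0, 25.0]})
        assert np.isnan(delta_ct(t)["A"].iloc[1])

    def test_missing_control_excludes_sample(self):
        t = make_table({"A": [25.0] * 4})
        t.ct.loc["s0", "S18"] = np.nan
        d = delta_ct(t)
        assert np.isnan(d.at["s0", "A"])
        assert d["A"].iloc[1:].notna().all()


def dct_frame(case_vals, control_vals, gene="A"):
    vals = list(case_vals) + list(control_vals)
    samples = [f"s{i}" for i in range(len(vals))]
    groups = pd.Series(
        ["case"] * len(case_vals) + ["control"] * len(control_vals), index=samples
    )
    return pd.DataFrame({gene: vals}, index=samples, dtype=float), groups


class TestDifferentialExpression:
    def test_identical_groups_null_result(self):
        dct, groups = dct_frame([5, 5, 5], [5, 5, 5])
        r = differential_expression(dct, groups)["A"]
        assert r.t_statistic == 0.0 and r.p_value == 1.0 and not r.significant

    def test_matches_closed_form_pooled_variance(self, rng):
        for _ in range(50):
            x = rng.normal(0, 1, 14)
            y = rng.normal(0.5, 1, 5)
            dct, groups = dct_frame(x, y)
            r = differential_expression(dct, groups)["A"]
            t_exp, p_exp = pooled_t_test(x, y)
            assert r.t_statistic == pytest.approx(t_exp, rel=1e-10)
            assert r.p_value == pytest.approx(p_exp, rel=1e-10)

    def test_zero_variance_different_means_maximally_significant(self):
        dct, groups = dct_frame([1, 1, 1, 1], [5, 5, 5])
        r = differential_expression(dct, groups)["A"]
        assert r.p_value == 0.0 and r.significant
        assert r.direction == "up"  # lower ΔCt in cases = higher expression
        # perturbed values approach the same conclusion via the exact formula
        t_exp, p_exp = pooled_t_test([1, 1 + 1e-9, 1, 1], [5, 5, 5 - 1e-9])
        assert p_exp < 1e-10

    def test_label_swap_flips_direction_keeps_p(self, rng):
        x, y = rng.normal(0, 1, 8), rng.normal(1, 1, 6)
        dct, groups = dct_frame(x, y)
        r1 = differential_expression(dct, groups)["A"]
        swapped = groups.map({"case": "control", "control": "case"})
        r2 = differential_expression(dct, swapped)["A"]
        assert r1.p_value == pytest.approx(r2.p_value)
        assert r1.t_statistic == pytest.approx(-r2.t_statistic)
        assert {r1.direction, r2.direction} == {"up", "down"}

    def test_location_shift_invariance(self, rng):
        x, y = rng.normal(0, 1, 10), rng.normal(0.8, 1, 5)
        d1, groups = dct_frame(x, y)
        d2, _ = dct_frame(x + 100.0, y + 100.0)
        r1 = differential_expression(d1, groups)["A"]
        r2 = differential_expression(d2, groups)["A"]
        assert r1.t_statistic == pytest.approx(r2.t_statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_fold_change_definition(self):
        dct, groups = dct_frame([2.0, 2.0, 2.0], [5.0, 5.0, 5.0])
        r = differential_expression(dct, groups)["A"]
        # ΔΔCt = 2 - 5 = -3 -> fold change 2^3 = 8, up-regulated
        assert r.fold_change == pytest.approx(8.0)
        assert r.direction == "up"

    def test_insufficient_samples_flagged_untestable(self):
        dct, groups = dct_frame([1.0], [2.0, 3.0])
        r = differential_expression(dct, groups)["A"]
        assert not r.testable and not r.significant
        assert np.isnan(r.p_value)

    def test_sem_matches_definition(self, rng):
        x, y = rng.normal(0, 1, 9), rng.normal(0, 1, 4)
        dct, groups = dct_frame(x, y)
        r = differential_expression(dct, groups)["A"]
        assert r.sem_case == pytest.approx(np.std(x, ddof=1) / np.sqrt(len(x)))
        assert r.sem_control == pytest.approx(np.std(y, ddof=1) / np.sqrt(len(y)))

    def test_welch_option_differs_under_unequal_variance(self, rng):
        x = rng.normal(0, 0.2, 14)
        y = rng.normal(1, 3.0, 5)
        dct, groups = dct_frame(x, y)
        student = differential_expression(dct, groups, equal_var=True)["A"]
        welch = differential_expression(dct, groups, equal_var=False)["A"]
        assert student.p_value != pytest.approx(welch.p_value, rel=1e-3)

    def test_bh_adjustment_monotone_and_bounded(self, rng):
        genes = {f"G{i}": list(rng.normal(i * 0.3, 1, 12)) for i in range(6)}
        samples = [f"s{i}" for i in range(12)]
        groups = pd.Series(["case"] * 7 + ["control"] * 5, index=samples)
        dct = pd.DataFrame(genes, index=samples)
        res = differential_expression(dct, groups, adjust="bh")
        df = res.to_frame()
        assert (df["p_adjusted"] >= df["p_value"] - 1e-12).all()
        assert (df["p_adjusted"] <= 1.0).all()


class TestClusterProfiles:
    def test_proportional_profiles_merge_first(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        dct = pd.DataFrame(
            {
                "A": base,
                "B": 2 * base + 1,  # r = 1 with A
                "C": [3.0, 1.0, 4.0, 1.0, 5.0, 9.0],
            },
            index=[f"s{i}" for i in range(6)],
        )
        result = cluster_profiles(dct)
        first_merge = result.gene_linkage[0]
        assert {int(first_merge[0]), int(first_merge[1])} == {0, 1}  # A with B
        assert first_merge[2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_profiles_distance_two(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        dct = pd.DataFrame(
            {"A": base, "B": -base},
            index=[f"s{i}" for i in range(4)],
        )
        result = cluster_profiles(dct)
        assert result.gene_linkage[0][2] == pytest.approx(2.0)

    def test_zero_variance_profile_gets_max_distance(self, caplog):
        dct = pd.DataFrame(
            {"A": [1.0, 2.0, 3.0, 4.0], "B": [5.0, 5.0, 5.0, 5.0]},
            index=[f"s{i}" for i in range(4)],
        )
        with caplog.at_level("WARNING"):
            result = cluster_profiles(dct)
        assert result.gene_linkage[0][2] == pytest.approx(2.0)

    def test_merge_heights_match_naive_upgma(self, rng):
        dct = pd.DataFrame(
            rng.normal(0, 1, (6, 5)),
            index=[f"s{i}" for i in range(6)],
            columns=[f"G{i}" for i in range(5)],
        )
        result = cluster_profiles(dct)
        X = dct.to_numpy().T
        D = 1 - np.corrcoef(X)
        np.fill_diagonal(D, 0.0)
        expected = naive_upgma_heights(D)
        got = sorted(result.gene_linkage[:, 2])
        assert got == pytest.approx(sorted(expected), rel=1e-9)

    def test_requires_two_complete_genes(self):
        dct = pd.DataFrame({"A": [1.0, np.nan]}, index=["s0", "s1"])
        with pytest.raises(ValueError):
            cluster_profiles(dct)

    def test_heatmap_renders_to_file(self, tmp_path, rng):
        from dnmt3b_targets.expression import plot_heatmap

        dct = pd.DataFrame(
            rng.normal(0, 1, (6, 4)),
            index=[f"s{i}" for i in range(6)],
            columns=[f"G{i}" for i in range(4)],
        )
        out = tmp_path / "heatmap.png"
        plot_heatmap(dct, path=out)
        assert out.stat().st_size > 0


class TestCtTableIO:
    def test_tsv_round_trip(self, tmp_path, rng):
        t = make_table({f"G{i}": list(rng.uniform(20, 30, 6)) for i in range(3)})
        t.ct.loc["s2", "G1"] = np.nan
        path = tmp_path / "ct.tsv"
        t.write_tsv(path)
        back = CtTable.read_tsv(path)
        assert back.genes == t.genes
        assert back.groups.equals(t.groups)
        assert np.allclose(back.ct, t.ct, atol=1e-4, equal_nan=True)
        assert back.endogenous_controls == t.endogenous_controls

    def test_missing_control_rejected(self):
        ct = pd.DataFrame({"A": [25.0, 26.0]}, index=["s0", "s1"])
        with pytest.raises(ValueError):
            CtTable(ct, {"s0": "case", "s1": "control"}, {"A": "probe_array"}, {})

    def test_nonpositive_ct_rejected(self):
        with pytest.raises(ValueError):
            make_table({"A": [0.0, 25.0, 25.0, 25.0]})
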