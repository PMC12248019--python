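"""Best-of reduction, trimmed Z-scores, category weights, summed ranking,
and bootstrap confidence intervals."""

import numpy as np
import pandas as pd
import pytest

from naassess.ranking import (ZScoreConfig, bootstrap_ci, category_z,
                              reduce_best, sum_ranking, trimmed_z,
                              trimmed_z_table)


def literal_trimmed_z(values: dict, outlier_sd=2.0) -> dict:
    """Independent literal re-implementation of the trimming procedure."""
    keys = list(values)
    x = np.array([values[k] for k in keys], dtype=float)
    if len(x) < 2:
        return {k: 0.0 for k in keys}
    m0, s0 = x.mean(), x.std(ddof=1)
    kept = x[x > m0 - outlier_sd * s0] if s0 > 0 else x
    m1 = kept.mean()
    s1 = kept.std(ddof=1) if len(kept) > 1 else 0.0
    if s1 == 0 or not np.isfinite(s1):
        return {k: 0.0 for k in keys}
    return {k: (values[k] - m1) / s1 for k in keys}


class TestReduceBest:
    def test_best_of_five_models(self):
        df = pd.DataFrame({
            "group": "g", "target": "T", "metric": "tm_score",
            "model": range(1, 6), "value": [0.2, 0.5, 0.4, 0.1, 0.3],
        })
        assert reduce_best(df)["value"].item() == 0.5

    def test_metrics_decoupled_across_models(self):
        rows = []
        for model, tm, ld in [(1, 0.3, 0.9), (2, 0.8, 0.2)]:
            rows.append(dict(group="g", target="T", metric="tm_score",
                             model=model, value=tm))
            rows.append(dict(group="g", target="T", metric="lddt",
                             model=model, value=ld))
        best = reduce_best(pd.DataFrame(rows)).set_index("metric")["value"]
        assert best["tm_score"] == 0.8 and best["lddt"] == 0.9

    def test_best_across_references(self):
        df = pd.DataFrame({
            "group": "g", "target": "T", "metric": "tm_score",
            "model": 1, "reference": [0, 1], "value": [0.4, 0.6],
        })
        assert reduce_best(df)["value"].item() == 0.6

    def test_missing_values_ignored(self):
        df = pd.DataFrame({
            "group": "g", "target": "T", "metric": "ics",
            "model": [1, 2], "value": [None, 0.7],
        })
        assert reduce_best(df)["value"].item() == 0.7


class TestTrimmedZ:
    def test_all_equal_scores_give_zero(self):
        z = trimmed_z({f"g{i}": 0.5 for i in range(6)})
        assert (z == 0.0).all()

    def test_worked_example_with_one_outlier(self):
        values = {f"g{i}": 0.8 for i in range(8)}
        values["g8"] = 0.75
        values["g9"] = 0.0
        z = trimmed_z(values)
        # trimmed mean 0.79444, sample SD 0.016667
        assert z["g0"] == pytest.approx(1 / 3, abs=1e-3)
        assert z["g8"] == pytest.approx(-8 / 3, abs=1e-3)
        assert z["g9"] == pytest.approx(-47.67, abs=0.01)

    def test_no_outliers_equals_plain_z(self):
        values = {"a": 0.5, "b": 0.6, "c": 0.7}
        s = pd.Series(values)
        plain = (s - s.mean()) / s.std(ddof=1)
        z = trimmed_z(values)
        for k in values:
            assert z[k] == pytest.approx(plain[k])

    def test_single_group_is_zero(self):
        assert trimmed_z({"only": 0.9}).item() == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_literal_reimplementation(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 30)
        values = {f"g{i}": float(v) for i, v in enumerate(rng.random(n))}
        mine = trimmed_z(values)
        oracle = literal_trimmed_z(values)
        for k in values:
            assert mine[k] == pytest.approx(oracle[k], abs=1e-12)

    def test_shift_and_scale_invariance(self):
        rng = np.random.default_rng(3)
        values = {f"g{i}": float(v) for i, v in enumerate(rng.random(9))}
        base = trimmed_z(values)
        shifted = trimmed_z({k: v + 5.0 for k, v in values.items()})
        scaled = trimmed_z({k: 3.0 * v for k, v in values.items()})
        for k in values:
            assert shifted[k] == pytest.approx(base[k])
            assert scaled[k] == pytest.approx(base[k])


def _ztable(rows):
    return pd.DataFrame(rows, columns=["group", "target", "metric", "z"])


class TestCategoryZ:
    def test_monomer_weights(self):
        zt = _ztable([("g", "T", m, 1.0)
                      for m in ("tm_score", "gdt_ts", "lddt")])
        out = category_z(zt, "monomer")
        assert out["z"].item() == pytest.approx(1.0)

    def test_multimer_split(self):
        rows = [("g", "T", m, 1.0) for m in ("tm_score", "gdt_ts", "lddt")]
        rows += [("g", "T", m, 0.0) for m in ("ics", "ips", "i_lddt")]
        out = category_z(_ztable(rows), "multimer")
        assert out["z"].item() == pytest.approx(0.3)

    def test_ligand_weights(self):
        zt = _ztable([("g", "T", "i_lddt", 2.0), ("g", "T", "lddt_pocket", 0.0)])
        out = category_z(zt, "ligand")
        assert out["z"].item() == pytest.approx(1.0)

    def test_missing_component_renormalized_and_flagged(self):
        rows = [("g", "T", m, 1.0) for m in ("tm_score", "gdt_ts", "lddt")]
        rows += [("g", "T", "ics", 1.0)]  # ips/i_lddt unscoreable
        out = category_z(_ztable(rows), "hybrid")
        assert out["z"].item() == pytest.approx(1.0)
        assert bool(out["renormalized"].item())

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            category_z(_ztable([("g", "T", "tm_score", 0.0)]), "nonsense")


def _catz(entries):
    return pd.DataFrame(entries, columns=["group", "target", "z"])


class TestSumRanking:
    def test_floor_at_zero(self):
        catz = _catz([("g", "T1", -1.0), ("g", "T2", 2.0), ("g", "T3", -0.5)])
        res = sum_ranking(catz)
        assert res.summed_z["g"] == pytest.approx(2.0)

    def test_same_sequence_grouping_counts_best_once(self):
        catz = _catz([("g", "T1", 0.5), ("g", "T2", 1.5), ("g", "T3", 1.0)])
        res = sum_ranking(catz, grouping=[["T1", "T2"]])
        assert res.summed_z["g"] == pytest.approx(1.5 + 1.0)

    def test_participation_filter(self):
        rows = [("busy", f"T{i}", 1.0) for i in range(10)]
        rows += [("half", f"T{i}", 5.0) for i in range(5)]
        res = sum_ranking(_catz(rows))
        assert res.excluded_groups == ["half"]
        assert list(res.summed_z.index) == ["busy"]

    def test_participation_counts_grouped_units(self):
        # 3 raw targets collapse into 2 units; a group covering 1 of 2
        # units sits at 50% and is excluded at the 60% threshold
        rows = [("a", "T1", 1.0), ("a", "T2", 1.0), ("a", "T3", 1.0),
                ("b", "T1", 1.0)]
        res = sum_ranking(_catz(rows), grouping=[["T1", "T2"]])
        assert res.excluded_groups == ["b"]

    def test_monotone_in_single_scores(self):
        rng = np.random.default_rng(1)
        base_rows = [(g, f"T{t}", float(rng.normal()))
                     for g in "abc" for t in range(4)]
        base = sum_ranking(_catz(base_rows)).summed_z
        improved_rows = [(g, t, z + (1.0 if (g, t) == ("b", "T2") else 0.0))
                         for g, t, z in base_rows]
        improved = sum_ranking(_catz(improved_rows)).summed_z
        assert improved["b"] >= base["b"]
        assert improved["a"] == base["a"] and improved["c"] == base["c"]


class TestBootstrap:
    def test_identical_contributions_degenerate_interval(self):
        per_unit = pd.DataFrame({f"T{i}": [0.7] for i in range(5)},
                                index=["g"])
        ci = bootstrap_ci(per_unit, seed=0)
        assert ci.loc["g", "lo"] == pytest.approx(3.5)
        assert ci.loc["g", "hi"] == pytest.approx(3.5)

    def test_single_unit_interval_is_point(self):
        per_unit = pd.DataFrame({"T0": [1.2, 0.4]}, index=["a", "b"])
        ci = bootstrap_ci(per_unit, seed=0)
        assert (ci["lo"] == ci["hi"]).all()

    def test_fixed_seed_reproducibility(self):
        rng = np.random.default_rng(2)
        per_unit = pd.DataFrame(rng.random((3, 12)),
                                index=list("abc"),
                                columns=[f"T{i}" for i in range(12)])
        c1 = bootstrap_ci(per_unit, seed=42)
        c2 = bootstrap_ci(per_unit, seed=42)
        pd.testing.assert_frame_equal(c1, c2)
        c3 = bootstrap_ci(per_unit, seed=43)
        assert not c1.equals(c3)

    def test_interval_tracks_closed_form_standard_error(self):
        """For Normal contributions the 68.2% central interval half-width
        approximates the standard error of the resampled sum."""
        k, mu, sd = 50, 1.0, 0.6
        ratios = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            contrib = rng.normal(mu, sd, size=k)
            per_unit = pd.DataFrame([contrib],
                                    index=["g"],
                                    columns=[f"T{i}" for i in range(k)])
            ci = bootstrap_ci(per_unit, replicates=1000, seed=seed)
            half = (ci.loc["g", "hi"] - ci.loc["g", "lo"]) / 2
            # SE of the bootstrap sum ~ sqrt(k) * sample SD
            expected = np.sqrt(k) * contrib.std(ddof=1)
            ratios.append(half / expected)
        assert abs(np.mean(ratios) - 1.0) < 0.25


class TestZScoreConfig:
    def test_weights_sum_to_one(self):
        from naassess.ranking import (INTERFACE_WEIGHTS, LIGAND_WEIGHTS,
                                      MONOMER_WEIGHTS)
        for weights in (MONOMER_WEIGHTS, INTERFACE_WEIGHTS, LIGAND_WEIGHTS):
            assert sum(weights.values()) == pytest.approx(1.0)

    def test_trimmed_z_table_shape(self):
        df = pd.DataFrame({
            "group": ["a", "b", "a", "b"],
            "target": ["T", "T", "T", "T"],
            "metric": ["tm_score", "tm_score", "lddt", "lddt"],
            "value": [0.2, 0.8, 0.5, 0.5],
        })
        zt = trimmed_z_table(df)
        assert len(zt) == 4
        tm = zt[zt["metric"] == "tm_score"].set_index("group")["z"]
        assert tm["a"] == pytest.approx(-tm["b"])
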