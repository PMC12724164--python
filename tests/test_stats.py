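"""Type-III effect sizes, slopes, bootstrap CIs, meaningful rule, epmf."""

import numpy as np
import pandas as pd
import pytest

from dendromorph import (ancova_slopes, anova_type3, asymmetric_mad,
                         bootstrap_ci, cohens_d, epmf, meaningful)


def two_factor_frame(rng, n_per_cell=100, type_effect=0.0, subtype_effect=0.0,
                     noise=1.0):
    rows = []
    for ti, type_ in enumerate(("T4", "T5")):
        for si, subtype in enumerate("abcd"):
            y = rng.normal(
                ti * type_effect + si * subtype_effect, noise, n_per_cell
            )
            rows.append(pd.DataFrame({"type": type_, "subtype": subtype,
                                      "y": y}))
    return pd.concat(rows, ignore_index=True)


class TestAnovaType3:
    def test_null_response_gives_zero_eta(self):
        df = two_factor_frame(np.random.default_rng(0), noise=0.0)
        df["y"] = 1.0
        reports = anova_type3(df, "y", reps=0)
        for r in reports:
            assert r.eta_p2 == pytest.approx(0.0, abs=1e-9)

    def test_balanced_two_group_half_split(self):
        # SS_effect == SS_error  ->  eta_p2 = 0.5
        df = pd.DataFrame({
            "type": ["T4"] * 4 + ["T5"] * 4,
            "subtype": ["a"] * 8,
            "y": [0, 0, 2, 2, 2, 2, 4, 4],
        })
        (rep,) = anova_type3(df, "y", factors=("type",), reps=0)
        assert rep.eta_p2 == pytest.approx(0.5)

    def test_covariate_slope_recovery(self):
        rng = np.random.default_rng(1)
        n = 4000
        df = pd.DataFrame({
            "type": rng.choice(["T4", "T5"], n),
            "subtype": rng.choice(list("abcd"), n),
            "x": rng.normal(0, 1, n),
        })
        df["y"] = 0.5 * df["x"] + (df["type"] == "T5") * 1.0 + rng.normal(0, 1, n)
        reports = anova_type3(df, "y", covariates=["x"], reps=0)
        slope = next(r.slope for r in reports if r.term == "x")
        assert 0.47 <= slope <= 0.53

    def test_planted_type_effect_is_meaningful(self):
        rng = np.random.default_rng(2)
        df = two_factor_frame(rng, n_per_cell=200, type_effect=0.8)
        reports = anova_type3(df, "y", reps=200, seed=1)
        type_rep = next(r for r in reports if "type" in r.term and ":" not in r.term)
        assert type_rep.eta_p2 > 0.06
        assert type_rep.meaningful is True

    def test_empty_cell_rejected(self):
        df = two_factor_frame(np.random.default_rng(3))
        df = df[~((df["type"] == "T4") & (df["subtype"] == "d"))]
        with pytest.raises(ValueError, match="empty factorial cells"):
            anova_type3(df, "y", reps=0)

    def test_type3_invariant_to_level_order(self):
        rng = np.random.default_rng(4)
        df = two_factor_frame(rng, n_per_cell=50, subtype_effect=0.4)
        base = {r.term: r.eta_p2 for r in anova_type3(df, "y", reps=0)}
        relabel = {"a": "z_last", "b": "b", "c": "c", "d": "d"}
        df2 = df.assign(subtype=df["subtype"].map(relabel))
        flipped = {r.term: r.eta_p2 for r in anova_type3(df2, "y", reps=0)}
        for (k1, v1), (k2, v2) in zip(sorted(base.items()), sorted(flipped.items())):
            assert v1 == pytest.approx(v2, rel=1e-9)


class TestAncovaSlopes:
    def test_exact_fit(self):
        df = pd.DataFrame({
            "g": ["a"] * 20 + ["b"] * 20,
            "x": np.tile(np.arange(20.0), 2),
        })
        df["y"] = 2.0 * df["x"]
        slopes, deltas = ancova_slopes(df, "y", "x", "g", reps=0)
        assert slopes["a"] == pytest.approx(2.0, abs=1e-9)
        assert deltas["delta_beta"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_planted_slope_difference(self):
        rng = np.random.default_rng(5)
        n = 2000
        x = rng.normal(0, 1, n)
        df = pd.DataFrame({
            "g": ["T4"] * n + ["T5"] * n,
            "x": np.concatenate([x, x]),
            "y": np.concatenate([
                -0.8 * x + rng.normal(0, 0.3, n),
                -0.7 * x + rng.normal(0, 0.3, n),
            ]),
        })
        slopes, deltas = ancova_slopes(df, "y", "x", "g", reps=200, seed=2)
        d = deltas.iloc[0]
        se = 0.3 / np.sqrt(n)  # per-slope SE with unit-variance x
        assert d["delta_beta"] == pytest.approx(-0.1, abs=3 * np.sqrt(2) * se)
        assert d["ci_low"] <= d["delta_beta"] <= d["ci_high"]

    def test_identical_groups_ci_covers_zero(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 500)
        y = 1.5 * x + rng.normal(0, 1, 500)
        df = pd.DataFrame({"g": ["a"] * 500 + ["b"] * 500,
                           "x": np.concatenate([x, x]),
                           "y": np.concatenate([y, y + rng.normal(0, 1, 500) * 0])})
        _, deltas = ancova_slopes(df, "y", "x", "g", reps=200, seed=3)
        d = deltas.iloc[0]
        assert d["ci_low"] <= 0.0 <= d["ci_high"]

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame({"g": ["a"] * 20 + ["b"] * 20,
                           "x": [1.0] * 20 + list(range(20)),
                           "y": np.arange(40.0)})
        with pytest.raises(ValueError, match="constant"):
            ancova_slopes(df, "y", "x", "g", reps=0)


class TestCohensD:
    def test_unit_separation(self):
        rng = np.random.default_rng(7)
        x = rng.normal(1.0, 1.0, 50000)
        y = rng.normal(0.0, 1.0, 50000)
        eff = cohens_d(x, y, reps=0)
        assert eff.cohens_d == pytest.approx(1.0, abs=0.03)

    def test_identical_groups_zero(self):
        x = np.arange(100.0)
        eff = cohens_d(x, x.copy(), reps=0)
        assert eff.cohens_d == 0.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(0.5, 1, 200), rng.normal(0, 1, 200)
        assert cohens_d(x, y, reps=0).cohens_d == pytest.approx(
            -cohens_d(y, x, reps=0).cohens_d
        )

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError, match="pooled"):
            cohens_d(np.ones(10), np.ones(10), reps=0)

    def test_planted_effect_recovered_and_meaningful(self):
        hits, flagged = 0, 0
        n_seeds = 30
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            x = rng.normal(0.8, 1.0, 200)
            y = rng.normal(0.0, 1.0, 200)
            eff = cohens_d(x, y, reps=500, seed=seed)
            hits += abs(eff.cohens_d - 0.8) <= 0.15
            flagged += bool(eff.meaningful)
        assert hits / n_seeds >= 0.8
        assert flagged / n_seeds >= 0.95

    def test_null_false_meaningful_rate(self):
        false_calls = 0
        n_sets = 200
        for seed in range(n_sets):
            rng = np.random.default_rng(10_000 + seed)
            x = rng.normal(0.0, 1.0, 200)
            y = rng.normal(0.0, 1.0, 200)
            false_calls += bool(cohens_d(x, y, reps=300, seed=seed).meaningful)
        assert false_calls / n_sets <= 0.05


class TestBootstrapCI:
    def test_constant_data_zero_width(self):
        df = pd.DataFrame({"v": np.ones(30), "s": ["a"] * 30})
        lo, hi = bootstrap_ci(lambda d: d["v"].mean(), df, strata="s",
                              reps=100, seed=0)
        assert lo == hi == 1.0

    def test_seed_determinism(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame({"v": rng.normal(size=200),
                           "s": ["a"] * 100 + ["b"] * 100})
        a = bootstrap_ci(lambda d: d["v"].mean(), df, strata="s", reps=200, seed=4)
        b = bootstrap_ci(lambda d: d["v"].mean(), df, strata="s", reps=200, seed=4)
        assert a == b

    def test_nominal_coverage_for_the_mean(self):
        covered = 0
        outer = 300
        for seed in range(outer):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame({"v": rng.normal(0, 1, 100)})
            lo, hi = bootstrap_ci(lambda d: d["v"].mean(), df, reps=300,
                                  seed=seed)
            covered += lo <= 0.0 <= hi
        assert 0.90 <= covered / outer <= 0.98

    def test_singleton_stratum_warns(self):
        df = pd.DataFrame({"v": [1.0, 2.0, 3.0], "s": ["a", "a", "b"]})
        with pytest.warns(UserWarning, match="single row"):
            bootstrap_ci(lambda d: d["v"].mean(), df, strata="s", reps=10, seed=0)


class TestMeaningfulRule:
    def test_reported_effect_pattern(self):
        # point and whole CI above the small threshold -> meaningful
        assert meaningful(0.028, 0.020, 0.038, threshold=0.01) is True

    def test_ci_crossing_threshold_fails(self):
        assert meaningful(0.02, 0.005, 0.04, threshold=0.01) is False

    def test_point_below_threshold_fails(self):
        assert meaningful(0.005, 0.004, 0.006, threshold=0.01) is False

    def test_signed_negative_effect(self):
        assert meaningful(-0.5, -0.7, -0.3, threshold=0.2, signed=True) is True
        assert meaningful(-0.5, -0.7, 0.1, threshold=0.2, signed=True) is False


class TestEPMF:
    def test_asymmetric_mad_hand_values(self):
        lo, hi = asymmetric_mad([1, 2, 3, 4, 10])
        assert lo == pytest.approx(1.5)  # median{|1-3|,|2-3|} = median{2,1}
        assert hi == pytest.approx(4.0)  # median{|4-3|,|10-3|} = median{1,7}

    def test_symmetric_data_balanced_mads(self):
        rng = np.random.default_rng(10)
        x = rng.normal(0, 1, 20000)
        lo, hi = asymmetric_mad(x)
        assert lo == pytest.approx(hi, rel=0.05)

    def test_pooled_masses_sum_to_one(self):
        rng = np.random.default_rng(11)
        groups = {"g1": rng.normal(0, 1, 500), "g2": rng.normal(1, 1, 400)}
        edges = np.linspace(-4, 5, 20)
        for e in epmf(groups, edges, reps=50, seed=0):
            assert e.mass.sum() == pytest.approx(1.0)
            assert np.all(e.err_low <= e.mass + 1e-12)

    def test_per_dendrite_mode(self):
        rng = np.random.default_rng(12)
        groups = {"g": [rng.normal(0, 1, 200) for _ in range(30)]}
        edges = np.linspace(-4, 4, 15)
        (e,) = epmf(groups, edges, per_dendrite=True)
        assert e.mode == "asymmetric_mad"
        assert e.mass.sum() == pytest.approx(1.0)
        assert e.bin_median is not None
        assert np.all(e.err_low >= 0) and np.all(e.err_high >= 0)
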