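"""Capability coding, RRPP Procrustes ANOVA, model selection, deviations."""

import numpy as np
import pandas as pd
import pytest

from columnmorph import (
    CAPABILITIES,
    build_capability_matrix,
    ecological_scan,
    encode_capabilities,
    group_deviation,
    procrustes_anova,
    select_best_model,
)
from columnmorph.ecomorph import significance_stratum, validate_capability_matrix
from columnmorph.errors import ConfigurationError, DesignError, VocabularyError

from conftest import random_rotation


class TestEncodeCapabilities:
    @pytest.mark.parametrize(
        "category,expected",
        [
            ("terrestrial", dict(terrestrial=1, cursorial=0, arboreal=0, aquatic=0, fossorial=0)),
            ("cursorial", dict(terrestrial=1, cursorial=1, arboreal=0, aquatic=0, fossorial=0)),
            ("scansorial", dict(terrestrial=1, cursorial=0, arboreal=1, aquatic=0, fossorial=0)),
            ("arboreal", dict(terrestrial=0, cursorial=0, arboreal=1, aquatic=0, fossorial=0)),
            ("semi-aquatic", dict(terrestrial=1, cursorial=0, arboreal=0, aquatic=1, fossorial=0)),
            ("aquatic", dict(terrestrial=0, cursorial=0, arboreal=0, aquatic=1, fossorial=0)),
            ("semi-fossorial", dict(terrestrial=1, cursorial=0, arboreal=0, aquatic=0, fossorial=1)),
            ("fossorial", dict(terrestrial=0, cursorial=0, arboreal=0, aquatic=0, fossorial=1)),
        ],
    )
    def test_category_mapping(self, category, expected):
        assert encode_capabilities(category) == expected

    def test_unknown_category_rejected(self):
        with pytest.raises(VocabularyError):
            encode_capabilities("volant")

    def test_cursorial_override_for_behavioural_cursors(self):
        """A terrestrially categorised pursuit hunter can be forced cursorial
        through the override list (configuration data, not code)."""
        m = build_capability_matrix(
            {"Chrysocyon_brachyurus": "terrestrial", "Vulpes_vulpes": "terrestrial"},
            cursorial_overrides=["Chrysocyon_brachyurus"],
        )
        assert m.loc["Chrysocyon_brachyurus", "cursorial"] == 1
        assert m.loc["Vulpes_vulpes", "cursorial"] == 0

    def test_matrix_invariants_enforced(self):
        bad = pd.DataFrame(
            {c: [0] for c in CAPABILITIES}, index=["sp1"]
        )
        with pytest.raises(ConfigurationError, match="no capability"):
            validate_capability_matrix(bad)
        bad2 = pd.DataFrame(
            {**{c: [0] for c in CAPABILITIES}, "cursorial": [1]}, index=["sp1"]
        )
        with pytest.raises(ConfigurationError, match="cursorial"):
            validate_capability_matrix(bad2)


def _binary_design(rng, n, p_effect=0.4):
    g = (rng.random(n) < p_effect).astype(float)
    while g.std() == 0:
        g = (rng.random(n) < p_effect).astype(float)
    return g


class TestProcrustesANOVA:
    def test_identical_group_means_give_null_result(self, rng):
        n = 30
        g = np.repeat([0.0, 1.0], n // 2)
        Y = rng.standard_normal((n, 5))
        Y[g == 1] -= Y[g == 1].mean(axis=0)
        Y[g == 0] -= Y[g == 0].mean(axis=0)  # group means exactly equal
        res = procrustes_anova(Y, [("grp", g)], n_perm=499, seed=0)
        assert res.rsq("grp") < 0.02
        assert res.p("grp") > 0.9

    def test_strong_separation_saturates(self, rng):
        n = 24
        g = np.repeat([0.0, 1.0], n // 2)
        Y = 0.01 * rng.standard_normal((n, 4))
        Y[g == 1] += 10.0
        res = procrustes_anova(Y, [("grp", g)], n_perm=999, seed=0)
        assert res.rsq("grp") > 0.99
        assert res.p("grp") == pytest.approx(1 / 1000)
        assert res.z("grp") > 3

    def test_table_bookkeeping(self, rng):
        n = 20
        Y = rng.standard_normal((n, 6))
        terms = [("a", _binary_design(rng, n)), ("b", _binary_design(rng, n))]
        res = procrustes_anova(Y, terms, n_perm=199, seed=1)
        t = res.table
        # sequential R^2 partitions the corrected total exactly
        assert t.loc[["a", "b", "Residuals"], "Rsq"].sum() == pytest.approx(1.0)
        assert t.loc[["a", "b", "Residuals"], "Df"].sum() == n - 1
        assert t.loc[["a", "b", "Residuals"], "SS"].sum() == pytest.approx(
            t.loc["Total", "SS"]
        )
        assert 0 < t.loc["a", "p"] <= 1

    def test_total_rsq_invariant_to_term_order(self, rng):
        n = 26
        Y = rng.standard_normal((n, 5))
        a, b = _binary_design(rng, n), _binary_design(rng, n)
        r1 = procrustes_anova(Y, [("a", a), ("b", b)], n_perm=99, seed=0)
        r2 = procrustes_anova(Y, [("b", b), ("a", a)], n_perm=99, seed=0)
        assert r1.rsq() == pytest.approx(r2.rsq(), rel=1e-10)

    def test_deterministic_given_seed(self, rng):
        Y = rng.standard_normal((18, 4))
        g = _binary_design(rng, 18)
        r1 = procrustes_anova(Y, [("g", g)], n_perm=199, seed=42)
        r2 = procrustes_anova(Y, [("g", g)], n_perm=199, seed=42)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_single_level_factor_rejected(self, rng):
        Y = rng.standard_normal((10, 3))
        with pytest.raises(DesignError, match="single level"):
            procrustes_anova(Y, [("f", np.array(["x"] * 10))], n_perm=99, seed=0)

    def test_low_permutation_count_warns(self, rng):
        Y = rng.standard_normal((10, 3))
        with pytest.warns(UserWarning, match="n_perm"):
            procrustes_anova(Y, [("g", _binary_design(rng, 10))], n_perm=19, seed=0)

    def test_permutation_p_uniform_under_null(self, rng):
        """Type-I error of the RRPP test is near nominal under a true null."""
        hits = 0
        reps = 200
        for rep in range(reps):
            Y = rng.standard_normal((20, 3))
            g = _binary_design(rng, 20)
            res = procrustes_anova(Y, [("g", g)], n_perm=99, seed=rep)
            hits += res.p("g") <= 0.05
        rate = hits / reps
        assert 0.01 <= rate <= 0.10


class TestGroupDeviation:
    def test_recovers_injected_shift_and_rotation_invariance(self, rng):
        n, p, delta = 40, 6, 0.8
        g = _binary_design(rng, n)
        u = rng.standard_normal(p)
        u /= np.linalg.norm(u)
        Y = 0.1 * rng.standard_normal((n, p)) + np.outer(g * delta, u)
        res = procrustes_anova(Y, [("cap", g)], n_perm=99, seed=0)
        d = group_deviation(res, "cap")
        assert d == pytest.approx(delta, rel=0.15)
        Q = np.linalg.qr(rng.standard_normal((p, p)))[0]
        res_rot = procrustes_anova(Y @ Q, [("cap", g)], n_perm=99, seed=0)
        assert group_deviation(res_rot, "cap") == pytest.approx(d, rel=1e-9)

    def test_missing_capability_rejected(self, rng):
        Y = rng.standard_normal((12, 3))
        res = procrustes_anova(Y, [("cap", _binary_design(rng, 12))], n_perm=99, seed=0)
        with pytest.raises(DesignError):
            group_deviation(res, "other")


def _caps_frame(rng, n, varying=CAPABILITIES):
    data = {}
    for c in CAPABILITIES:
        col = (rng.random(n) < 0.4).astype(int) if c in varying else np.zeros(n, int)
        data[c] = col
    df = pd.DataFrame(data, index=[f"sp{i:02d}" for i in range(n)])
    df["terrestrial"] |= df["cursorial"]  # coding invariant
    df.loc[df.sum(axis=1) == 0, "terrestrial"] = 1
    return df


class TestModelSelection:
    def test_ledger_has_all_31_subsets_with_five_capabilities(self, rng):
        n = 30
        caps = _caps_frame(rng, n)
        Y = rng.standard_normal((n, 5))
        sel = select_best_model(Y, caps, n_perm=99, seed=0)
        assert len(sel.ledger) == 31

    def test_single_true_effect_is_selected(self, rng):
        n = 40
        caps = _caps_frame(rng, n)
        u = np.zeros(6)
        u[2] = 1.0
        Y = 0.05 * rng.standard_normal((n, 6)) + np.outer(
            caps["aquatic"].to_numpy() * 0.5, u
        )
        sel = select_best_model(Y, caps, n_perm=199, seed=1)
        assert "aquatic" in sel.chosen

    def test_uninformative_capabilities_often_yield_empty_selection(self, rng):
        empties = 0
        for rep in range(20):
            caps = _caps_frame(rng, 24)
            Y = rng.standard_normal((24, 4))
            sel = select_best_model(Y, caps, n_perm=99, seed=rep)
            empties += sel.empty
        assert empties >= 8  # no admissible model most of the time under null

    def test_deterministic_given_seed(self, rng):
        caps = _caps_frame(rng, 25)
        Y = rng.standard_normal((25, 4))
        a = select_best_model(Y, caps, n_perm=99, seed=3)
        b = select_best_model(Y, caps, n_perm=99, seed=3)
        assert a.chosen == b.chosen
        pd.testing.assert_frame_equal(a.ledger, b.ledger)


class TestEcologicalScan:
    def test_excluding_aquatic_drops_the_capability(self, rng):
        n = 26
        caps = _caps_frame(rng, n)
        caps.loc[:, "aquatic"] = 0
        caps.iloc[:4, caps.columns.get_loc("aquatic")] = 1
        data = {"G1": (rng.standard_normal((n, 4)), list(caps.index))}
        aquatic_sp = list(caps.index[caps["aquatic"] == 1])
        scan = ecological_scan(
            data, caps, exclude=aquatic_sp, n_perm=99, seed=0
        )
        assert np.isnan(scan.grid_p.loc["G1", "aquatic"])
        assert "aquatic" not in scan.results["G1"].chosen

    def test_small_groups_skipped_with_log_entry(self, rng):
        caps = _caps_frame(rng, 10)
        data = {"tiny": (rng.standard_normal((2, 3)), list(caps.index[:2]))}
        scan = ecological_scan(data, caps, n_perm=99, seed=0)
        assert scan.skipped and scan.skipped[0][0] == "tiny"

    def test_repeated_runs_identical_with_same_seed(self, rng):
        caps = _caps_frame(rng, 20)
        data = {
            "A": (rng.standard_normal((20, 3)), list(caps.index)),
            "B": (rng.standard_normal((20, 3)), list(caps.index)),
        }
        s1 = ecological_scan(data, caps, n_perm=99, seed=5)
        s2 = ecological_scan(data, caps, n_perm=99, seed=5)
        pd.testing.assert_frame_equal(s1.grid_p, s2.grid_p)
        assert {g: r.chosen for g, r in s1.results.items()} == {
            g: r.chosen for g, r in s2.results.items()
        }


def test_significance_strata_boundaries():
    assert significance_stratum(0.005) == "p<0.01"
    assert significance_stratum(0.03) == "p<0.05"
    assert significance_stratum(0.09) == "p<0.1"
    assert significance_stratum(0.5) == "ns"
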