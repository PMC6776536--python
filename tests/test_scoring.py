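"""Scoring: plate normalization, ratios, Z-scores, linkage, set algebra."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ginpipe as gp
from ginpipe.exceptions import (
    DegenerateDistributionError,
    DegeneratePlateError,
    LayoutError,
)
from ginpipe.scoring import ColonyPlate, Position


def make_plate(sizes, border=None, genes=None):
    """Small 1-row plate helper."""
    n = len(sizes)
    pos = [Position(0, 0, c) for c in range(n)]
    return ColonyPlate(
        0,
        "vehicle",
        "bg",
        {p: float(s) for p, s in zip(pos, sizes)},
        {p: (genes[i] if genes else f"g{i}") for i, p in enumerate(pos)},
        {p: (border[i] if border else False) for i, p in enumerate(pos)},
    )


class TestNormalize:
    def test_constant_plate_normalizes_to_one(self):
        plate = gp.normalize_plate(make_plate([500.0] * 6))
        assert all(v == pytest.approx(1.0) for v in plate.grid.values())

    def test_scale_invariance(self):
        plate = gp.normalize_plate(make_plate([250, 500, 1000, 500, 500]))
        vals = sorted(plate.grid.values())
        assert vals[0] == pytest.approx(0.5) and vals[-1] == pytest.approx(2.0)

    def test_border_excluded_from_median(self):
        # interior colonies 500, inflated border colonies 1000
        sizes = [1000, 500, 500, 500, 1000]
        border = [True, False, False, False, True]
        plate = gp.normalize_plate(make_plate(sizes, border))
        interior = [
            v for p, v in plate.grid.items() if not plate.border_flags[p]
        ]
        assert np.median(interior) == pytest.approx(1.0, abs=1e-9)
        assert max(plate.grid.values()) == pytest.approx(2.0)

    def test_all_zero_plate_raises(self):
        with pytest.raises(DegeneratePlateError):
            gp.normalize_plate(make_plate([0.0] * 6))

    def test_mostly_empty_plate_raises(self):
        plate = make_plate([500] * 6, genes=[None, None, None, None, "g", None])
        with pytest.raises(DegeneratePlateError):
            gp.normalize_plate(plate)


class TestRatios:
    def test_identity(self):
        p = make_plate([1, 2, 3, 4])
        df = gp.compute_ratios(p, p)
        assert (df["ratio"] == 1.0).all()

    def test_division_and_zero_control(self):
        t = make_plate([0.3, 0.5, 1.0])
        c = make_plate([1.0, 0.0, 1.0])
        df = gp.compute_ratios(t, c)
        assert df.loc["g0", "ratio"] == pytest.approx(0.3)
        assert df.loc["g2", "ratio"] == pytest.approx(1.0)
        assert bool(df.loc["g1", "missing"]) and np.isnan(df.loc["g1", "ratio"])

    def test_mismatched_gene_maps_raise(self):
        t = make_plate([1, 2], genes=["a", "b"])
        c = make_plate([1, 2], genes=["a", "c"])
        with pytest.raises(LayoutError):
            gp.compute_ratios(t, c)

    def test_replicates_collapsed_by_median(self):
        genes = ["a", "a", "a", "a", "b"]
        t = make_plate([0.2, 0.3, 0.4, 0.9, 1.0], genes=genes)
        c = make_plate([1.0, 1.0, 1.0, 1.0, 1.0], genes=genes)
        df = gp.compute_ratios(t, c)
        assert df.loc["a", "ratio"] == pytest.approx(0.35)


class TestScoreProfile:
    def test_worked_example_plain_ratios(self):
        # oracle: mean 0.875, SD 0.25 (ddof=1) -> z(0.5-gene) = 1.5
        ratios = {"g1": 1.0, "g2": 1.0, "g3": 1.0, "g4": 0.5}
        config = gp.ScoringConfig(use_log_ratio=False)
        prof = gp.score_profile(ratios, config, min_scorable=4)
        assert prof.table.loc["g4", "z"] == pytest.approx(1.5)
        assert not prof.table.loc["g4", "hit"]

    def test_constant_ratios_raise(self):
        with pytest.raises(DegenerateDistributionError):
            gp.score_profile({f"g{i}": 1.0 for i in range(25)})

    def test_p_is_one_sided_normal_tail_of_z(self, screen50):
        t = screen50["profile"].table
        ok = np.isfinite(t["z"])
        np.testing.assert_allclose(
            t.loc[ok, "p"], stats.norm.sf(t.loc[ok, "z"]), atol=1e-12
        )

    def test_hit_conjunction_invariant(self, screen50):
        t = screen50["profile"].table
        cfg = screen50["profile"].config
        expected = (
            (t["z"] > cfg.z_threshold)
            & (t["p"] < cfg.p_threshold)
            & (t["excluded_reason"] == "none")
        )
        assert (t["hit"] == expected.fillna(False)).all()

    def test_z_scale_invariance(self, screen50):
        ratios = screen50["ratios"]
        scaled = ratios.copy()
        scaled["ratio"] = scaled["ratio"] * 3.7
        a = gp.score_profile(ratios)
        b = gp.score_profile(scaled)
        np.testing.assert_allclose(a.table["z"], b.table["z"], atol=1e-9)

    def test_threshold_is_z_driven(self):
        # one-sided p at z = 2 is ~0.023 < 0.05, so the hit boundary sits at z
        rng = np.random.default_rng(0)
        vals = rng.normal(1.0, 0.05, 200)
        ratios = {f"g{i}": float(v) for i, v in enumerate(vals)}
        prof = gp.score_profile(ratios, gp.ScoringConfig(use_log_ratio=False))
        t = prof.table
        assert (t.loc[t["z"] > 2.0, "hit"]).all()
        assert (~t.loc[t["z"] <= 2.0, "hit"]).all()


class TestLinkageExclusion:
    @pytest.fixture(scope="class")
    def profile(self, library1536):
        rng = np.random.default_rng(1)
        ratios = pd.DataFrame(
            {
                "ratio": rng.lognormal(0, 0.1, len(library1536.genes)),
                "border": False,
                "missing": False,
            },
            index=pd.Index(library1536.genes, name="gene"),
        )
        return gp.score_profile(ratios)

    def test_zero_window_excludes_only_query(self, profile, library1536):
        q = library1536.genes[10]
        out = gp.exclude_linkage(profile, q, library1536, window_bp=0)
        excl = out.table.index[out.table["excluded_reason"] == "linkage"]
        assert list(excl) == [q]

    def test_nearby_gene_excluded_within_window(self, profile, library1536):
        q = library1536.genes[10]
        qc, qs, _ = library1536.linkage[q]
        near = [
            g for g, (c, s, _) in library1536.linkage.items()
            if c == qc and 0 < abs(s - qs) <= 25_000
        ]
        assert near  # 12-kb spacing guarantees neighbors inside 25 kb
        out = gp.exclude_linkage(profile, q, library1536, window_bp=25_000)
        excl = set(out.table.index[out.table["excluded_reason"] == "linkage"])
        assert set(near) <= excl

    def test_same_position_other_chromosome_retained(self, profile, library1536):
        q = library1536.genes[10]
        qc, qs, _ = library1536.linkage[q]
        twin = [
            g for g, (c, s, _) in library1536.linkage.items()
            if c != qc and s == qs
        ]
        assert twin
        out = gp.exclude_linkage(profile, q, library1536, window_bp=25_000)
        assert (out.table.loc[twin, "excluded_reason"] == "none").all()

    def test_unknown_query_raises(self, profile, library1536):
        with pytest.raises(KeyError):
            gp.exclude_linkage(profile, "NOPE", library1536)


def _profile_from_hits(background, probe, hits, universe):
    table = pd.DataFrame(
        {
            "ratio": 1.0,
            "z": [3.0 if g in hits else 0.0 for g in universe],
            "p": 0.5,
            "hit": [g in hits for g in universe],
            "excluded_reason": "none",
            "border": False,
        },
        index=pd.Index(universe, name="gene"),
    )
    return gp.InteractionProfile(background, probe, table)


class TestHitSetAlgebra:
    universe = [f"g{i}" for i in range(30)] + [
        "c1", "c2", "p1", "u1", "u2", "u3", "u4"
    ]

    def test_identical_profiles(self):
        hits = {"g1", "g2", "g3"}
        profs = [
            _profile_from_hits(b, "drug", hits, self.universe)
            for b in ("b1", "b2", "b3")
        ]
        rep = gp.hit_set_algebra(profs)
        assert rep["common_all"] == hits
        assert all(not u for u in rep["unique"].values())

    def test_disjoint_profiles(self):
        profs = [
            _profile_from_hits("b1", "drug", {"g1"}, self.universe),
            _profile_from_hits("b2", "drug", {"g2"}, self.universe),
        ]
        rep = gp.hit_set_algebra(profs)
        assert rep["common_all"] == set()
        assert rep["unique"]["b1"] == {"g1"} and rep["unique"]["b2"] == {"g2"}

    def test_planted_overlap_design_counts(self):
        core = {"c1", "c2"}
        pair12 = {"p1"}
        sets = {
            "b1": core | pair12 | {"u1"},
            "b2": core | pair12 | {"u2", "u3"},
            "b3": core | {"u4"},
            "b4": core,
        }
        profs = [
            _profile_from_hits(b, "drug", h, self.universe)
            for b, h in sets.items()
        ]
        rep = gp.hit_set_algebra(profs)
        assert rep["union_size"] == 7
        assert rep["common_all"] == core
        assert rep["exact_patterns"][("b1", "b2")] == pair12
        assert rep["unique"]["b2"] == {"u2", "u3"}
        # partition identities
        total = sum(len(v) for v in rep["exact_patterns"].values())
        assert total == rep["union_size"]

    def test_probe_mismatch_raises(self):
        profs = [
            _profile_from_hits("b1", "drug", {"g1"}, self.universe),
            _profile_from_hits("b2", "other", {"g2"}, self.universe),
        ]
        with pytest.raises(ValueError):
            gp.hit_set_algebra(profs)


class TestPlantedRecovery:
    def test_single_screen_sensitivity_specificity(self, screen50):
        # a single screen can lose a couple of hits to ~2.5-sigma noise
        # excursions; the multi-seed averages are checked at study scale
        called = screen50["profile"].hits
        hits = screen50["hits"]
        tp = len(called & hits)
        fp = len(called - hits)
        assert tp / len(hits) >= 0.90
        assert 1 - fp / (1536 - len(hits)) >= 0.98
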