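"""Recombination fractions, phase correction, marker placement and
de novo mapping."""

import numpy as np
import pandas as pd
import pytest

import gbskit as gk
from conftest import geno


def brute_force_rf(G, i, j):
    """Independent pair-count oracle: loop over lines."""
    rec = tot = 0
    for line in G.lines:
        a = int(G.calls.at[line, i])
        b = int(G.calls.at[line, j])
        if a in (gk.HOM_A, gk.HOM_B) and b in (gk.HOM_A, gk.HOM_B):
            tot += 1
            rec += a != b
    return (rec / tot if tot else float("nan")), tot


class TestEstimateRF:
    def test_identical_columns_zero(self):
        G = geno(["AA", "BB", "AA", "BB"])
        r, n = gk.estimate_rf(G, "m0", "m1")
        assert r == 0.0 and n == 4

    def test_hand_counted_fraction(self):
        rows = ["AB"] * 10 + ["AA"] * 40  # 10 recombinant of 50 informative
        r, n = gk.estimate_rf(geno(rows), "m0", "m1")
        assert r == pytest.approx(0.2) and n == 50

    def test_opposite_phase_apparent_complement(self):
        G = geno(["AB", "BA", "AB", "BA"])
        r, _ = gk.estimate_rf(G, "m0", "m1")
        assert r == 1.0

    def test_het_and_missing_excluded(self):
        G = geno(["AA", "HB", "NA", "BB"])
        r, n = gk.estimate_rf(G, "m0", "m1")
        assert n == 2 and r == 0.0

    def test_no_informative_lines_flagged(self):
        G = geno(["HH", "NN"])
        r, n = gk.estimate_rf(G, "m0", "m1")
        assert n == 0 and np.isnan(r)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        chars = np.array(list("ABHN"))
        rows = ["".join(rng.choice(chars, size=6)) for _ in range(15)]
        G = geno(rows)
        r_mat, n_mat = gk.rf_matrix(G)
        for i in G.loci:
            for j in G.loci:
                if i == j:
                    continue
                r_ref, n_ref = brute_force_rf(G, i, j)
                assert n_mat.at[i, j] == n_ref
                if n_ref:
                    assert r_mat.at[i, j] == pytest.approx(r_ref)
                else:
                    assert np.isnan(r_mat.at[i, j])


class TestAssignPhase:
    def test_parents_polymorphic_orients(self):
        prog = geno(["AB", "BA"])
        p1 = pd.Series({"m0": gk.HOM_A, "m1": gk.HOM_B})
        p2 = pd.Series({"m0": gk.HOM_B, "m1": gk.HOM_A})
        phased, report = gk.assign_phase(prog, p1, p2)
        # m1 had parent1 = B, so calls flip
        assert list(phased.loci) == ["m0", "m1"]
        assert phased.calls["m1"].tolist() == [gk.HOM_A, gk.HOM_B]
        assert report.set_index("locus").at["m1", "parental_status"] == "flipped"

    def test_monomorphic_parents_duplicate_locus(self):
        prog = geno(["A", "B"], loci=["m0"])
        p1 = pd.Series({"m0": gk.HOM_A})
        p2 = pd.Series({"m0": gk.HOM_A})
        phased, report = gk.assign_phase(prog, p1, p2)
        assert list(phased.loci) == ["m0~p0", "m0~p1"]
        assert phased.calls["m0~p1"].tolist() == [gk.HOM_B, gk.HOM_A]

    def test_missing_parent_duplicates(self):
        prog = geno(["A", "B"], loci=["m0"])
        phased, _ = gk.assign_phase(prog, None, None)
        assert list(phased.loci) == ["m0~p0", "m0~p1"]


def flip_column(G, locus):
    calls = G.calls.copy()
    col = calls[locus].to_numpy().copy()
    a, b = col == gk.HOM_A, col == gk.HOM_B
    col[a], col[b] = gk.HOM_B, gk.HOM_A
    calls[locus] = col
    return gk.GenotypeMatrix(calls)


class TestCorrectPhases:
    def _tight_population(self, seed=0, n_markers=6, n_lines=80):
        table = pd.DataFrame(
            {
                "locus": [f"m{j}" for j in range(n_markers)],
                "linkage_group": 1,
                "position_cm": np.arange(n_markers) * 2.0,
                "status": "framework",
            }
        )
        cfg = gk.SimConfig(rng_seed=seed, outcross_rate=0.0)
        G, _ = gk.simulate_ril_population(gk.GeneticMap(table), n_lines, 6, cfg)
        return G

    def test_planted_flip_recovered_first_iteration(self):
        G = self._tight_population()
        bad = flip_column(G, "m3")
        fixed, report = gk.correct_phases(bad)
        assert fixed == G
        row = report.set_index("locus").loc["m3"]
        assert row["action"] == "flipped" and row["iteration"] == 1

    def test_unlinked_locus_kept_on_tie(self):
        G = self._tight_population()
        rng = np.random.default_rng(1)
        calls = G.calls.copy()
        calls["solo"] = rng.choice([gk.HOM_A, gk.HOM_B], size=G.n_lines)
        fixed, report = gk.correct_phases(gk.GenotypeMatrix(calls))
        assert "solo" in fixed.loci

    def test_duplicated_twins_resolved_to_one(self):
        G = self._tight_population()
        prog = gk.GenotypeMatrix(G.calls[["m0", "m1", "m2", "m3", "m4"]])
        # duplicate m2 into both phases, as assign_phase does for
        # parent-uninformative loci
        calls = prog.calls.rename(columns={"m2": "m2~p0"})
        calls["m2~p1"] = flip_column(prog, "m2").calls["m2"]
        fixed, report = gk.correct_phases(gk.GenotypeMatrix(calls))
        survivors = [l for l in fixed.loci if l.startswith("m2")]
        assert survivors == ["m2~p0"]
        actions = report.set_index("locus")
        assert actions.at["m2~p1", "action"] == "eliminated"

    @pytest.mark.parametrize("seed", range(3))
    def test_recovery_rate_on_planted_flips(self, seed):
        """>= 95% of planted phase flips are recovered when each locus has
        several tightly linked neighbours."""
        G = self._tight_population(seed=seed, n_markers=40, n_lines=100)
        rng = np.random.default_rng(seed)
        flipped = rng.choice(G.loci, size=8, replace=False)
        bad = G
        for locus in flipped:
            bad = flip_column(bad, locus)
        fixed, report = gk.correct_phases(bad)
        actions = report.set_index("locus")["action"]
        recovered = sum(
            locus in fixed.loci
            and actions.get(locus) == "flipped"
            and (fixed.calls[locus] == G.calls[locus]).all()
            for locus in flipped
        )
        assert recovered / len(flipped) >= 0.95


def _framework_map():
    return gk.GeneticMap(
        pd.DataFrame(
            {
                "locus": ["f0", "f1", "f2"],
                "linkage_group": 1,
                "position_cm": [0.0, 10.0, 30.0],
                "status": "framework",
            }
        )
    )


def _rf_df(values, index, columns):
    return pd.DataFrame(values, index=index, columns=columns, dtype=float)


class TestPlaceMarkers:
    def test_interpolation_between_anchors(self):
        fw = _framework_map()
        rf = _rf_df(
            [[0.4, 0.05, 0.15]], index=["c"], columns=["f0", "f1", "f2"]
        )
        placed, report = gk.place_markers(fw, ["c"], {"pop1": rf})
        row = placed.table.set_index("locus").loc["c"]
        assert row["position_cm"] == pytest.approx(10 + 20 * (0.05 / 0.20))
        assert row["anchor1"] == "f1" and row["anchor2"] == "f2"
        assert report.empty

    def test_zero_rf_lands_on_anchor(self):
        fw = _framework_map()
        rf = _rf_df([[0.4, 0.0, 0.2]], index=["c"], columns=["f0", "f1", "f2"])
        placed, _ = gk.place_markers(fw, ["c"], {"pop1": rf})
        assert placed.table.set_index("locus").at["c", "position_cm"] == pytest.approx(10.0)

    def test_distal_placement_negative_position(self):
        fw = _framework_map()
        # f0 terminal at 0 cM; candidate closer to f0 than f1 is to f0
        cand = _rf_df([[0.05, 0.25, 0.45]], index=["c"], columns=["f0", "f1", "f2"])
        full = pd.DataFrame(
            np.nan, index=["c", "f0", "f1", "f2"], columns=["c", "f0", "f1", "f2"]
        )
        full.loc["c"] = cand.reindex(columns=full.columns).iloc[0]
        full.at["f0", "f1"] = full.at["f1", "f0"] = 0.18  # rf(f0,f1) < rf(c,f1)
        placed, _ = gk.place_markers(fw, ["c"], {"pop1": full})
        assert placed.table.set_index("locus").at["c", "position_cm"] == pytest.approx(-5.0)

    def test_min_rf_across_populations_wins(self):
        fw = _framework_map()
        rf_a = _rf_df([[0.3, 0.2, 0.4]], index=["c"], columns=["f0", "f1", "f2"])
        rf_b = _rf_df([[0.3, 0.04, 0.12]], index=["c"], columns=["f0", "f1", "f2"])
        placed, _ = gk.place_markers(fw, ["c"], {"a": rf_a, "b": rf_b})
        row = placed.table.set_index("locus").loc["c"]
        assert row["source_population"] == "b"
        assert row["rf1"] == pytest.approx(0.04)

    def test_unlinked_candidate_reported(self):
        fw = _framework_map()
        rf = _rf_df([[0.5, 0.5, np.nan]], index=["c"], columns=["f0", "f1", "f2"])
        placed, report = gk.place_markers(fw, ["c"], {"pop1": rf})
        assert "c" not in list(placed.table["locus"])
        assert report["locus"].tolist() == ["c"]


class TestMapSummaries:
    def test_density_half_open_bins(self):
        m = gk.GeneticMap(
            pd.DataFrame(
                {
                    "locus": ["a", "b", "c"],
                    "linkage_group": 1,
                    "position_cm": [0.0, 4.9, 5.0],
                    "status": "placed",
                }
            )
        )
        d = gk.map_density(m, bin_cm=5.0)
        assert dict(zip(d["bin"], d["count"])) == {0: 2, 1: 1}
        assert d["count"].sum() == 3

    def test_density_negative_bins(self):
        m = gk.GeneticMap(
            pd.DataFrame(
                {"locus": ["a"], "linkage_group": 1, "position_cm": [-2.0],
                 "status": "placed"}
            )
        )
        d = gk.map_density(m, bin_cm=5.0)
        assert d["bin"].tolist() == [-1]

    def test_gap_stats(self):
        m = gk.GeneticMap(
            pd.DataFrame(
                {"locus": list("abc"), "linkage_group": 1,
                 "position_cm": [0.0, 8.0, 10.0], "status": "framework"}
            )
        )
        n_over, max_gap = gk.gap_stats(m, threshold_cm=5.0)
        assert n_over == 1 and max_gap == pytest.approx(8.0)

    def test_uniform_spacing_no_gaps(self):
        m = gk.GeneticMap(
            pd.DataFrame(
                {"locus": [f"l{i}" for i in range(11)], "linkage_group": 1,
                 "position_cm": np.arange(11.0), "status": "framework"}
            )
        )
        assert gk.gap_stats(m, 5.0)[0] == 0

    def test_placement_never_increases_gap_count(self, small_map, small_cfg):
        fw = small_map.framework()
        pops = {}
        for i in range(2):
            G, _ = gk.simulate_ril_population(small_map, 100, 6, small_cfg, stream=20 + i)
            pops[f"pop{i}"], _ = gk.rf_matrix(G)
        candidates = [l for l in small_map.table[small_map.table["status"] == "placed"]["locus"]]
        placed, _ = gk.place_markers(fw, candidates, pops)
        assert gk.gap_stats(placed, 5.0)[0] <= gk.gap_stats(fw, 5.0)[0]


class TestMapFunctions:
    @pytest.mark.parametrize(
        "r,expected", [(0.0, 0.0), (0.2, 21.182), (0.25, 27.465)]
    )
    def test_kosambi_closed_form(self, r, expected):
        assert gk.kosambi_cm(r) == pytest.approx(expected, abs=1e-3)

    def test_kosambi_undefined_at_half(self):
        with pytest.raises(gk.ConfigurationError):
            gk.kosambi_cm(0.5)

    def test_kosambi_round_trip(self):
        r = np.linspace(0.0, 0.45, 10)
        assert np.allclose(gk.kosambi_inverse(gk.kosambi_cm(r)), r)

    def test_haldane_inverse_limits(self):
        assert gk.haldane_inverse(0.0) == 0.0
        assert gk.haldane_inverse(1e6) == pytest.approx(0.5)


class TestDenovoMap:
    def _two_chromosome_population(self, n_markers=15, n_lines=150, seed=0):
        rows = []
        for lg in (1, 2):
            for j in range(n_markers):
                rows.append((f"c{lg}m{j:02d}", lg, j * 4.0, "framework"))
        gmap = gk.GeneticMap(
            pd.DataFrame(rows, columns=["locus", "linkage_group", "position_cm", "status"])
        )
        cfg = gk.SimConfig(rng_seed=seed, outcross_rate=0.0)
        G, _ = gk.simulate_ril_population(gmap, n_lines, 7, cfg)
        return G, gmap

    def test_recovers_chromosome_count(self):
        G, _ = self._two_chromosome_population()
        dm = gk.denovo_map(G)
        assert len(dm.linkage_groups) == 2
        groups = {
            lg: set(dm.group(lg)["locus"]) for lg in dm.linkage_groups
        }
        for members in groups.values():
            prefixes = {l[:2] for l in members}
            assert len(prefixes) == 1  # no chimeric group

    def test_two_locus_group_dropped(self):
        G, _ = self._two_chromosome_population(n_markers=8)
        calls = G.calls.copy()
        rng = np.random.default_rng(3)
        pair = rng.choice([gk.HOM_A, gk.HOM_B], size=G.n_lines)
        calls["iso1"] = pair
        calls["iso2"] = pair  # perfectly linked pair, unlinked to the rest
        dm = gk.denovo_map(gk.GenotypeMatrix(calls))
        placed = set(dm.table["locus"])
        assert "iso1" not in placed and "iso2" not in placed

    def test_adjacent_distances_near_truth(self):
        rows = [(f"m{j:02d}", 1, j * 3.0, "framework") for j in range(30)]
        gmap = gk.GeneticMap(
            pd.DataFrame(rows, columns=["locus", "linkage_group", "position_cm", "status"])
        )
        cfg = gk.SimConfig(rng_seed=5, outcross_rate=0.0)
        G, _ = gk.simulate_ril_population(gmap, 150, 7, cfg)
        dm = gk.denovo_map(G)
        assert len(dm.linkage_groups) == 1
        sub = dm.group(1)
        order = [int(l[1:]) for l in sub["locus"]]
        if order[0] > order[-1]:
            order = order[::-1]
        # a greedy order may misplace a marker locally but must be
        # globally co-linear with the truth
        tau = np.corrcoef(order, np.arange(len(order)))[0, 1]
        assert tau > 0.99
        gaps = np.diff(sub["position_cm"].to_numpy())
        # RIL rf overestimates single-meiosis distance, so compare loosely
        assert np.median(np.abs(gaps - 3.0)) < 3.0
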