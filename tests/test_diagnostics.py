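"""Allele-matching dissimilarity, UPGMA and the two diagnostic cases."""

import numpy as np
import pandas as pd
import pytest

import gbskit as gk
from conftest import geno


def brute_force_d(G, i, j):
    """Reference allele-matching dissimilarity for one pair."""
    m_sum = L = 0
    for locus in G.loci:
        a = int(G.calls.at[i, locus])
        b = int(G.calls.at[j, locus])
        if a == gk.MISSING or b == gk.MISSING:
            continue
        L += 1
        m_sum += 2 - abs(a - b)
    return 1 - m_sum / (2 * L) if L else float("nan")


def brute_force_upgma(d):
    """O(n^3) UPGMA with size-weighted average linkage; returns the
    sequence of merge heights (half the cluster distance)."""
    clusters = {i: [i] for i in range(len(d))}
    dist = {(i, j): d[i][j] for i in clusters for j in clusters if i < j}
    heights = []
    nxt = len(d)
    while len(clusters) > 1:
        (a, b), h = min(dist.items(), key=lambda kv: kv[1])
        heights.append(h / 2)
        na, nb = len(clusters[a]), len(clusters[b])
        merged = clusters.pop(a) + clusters.pop(b)
        newd = {}
        for c in clusters:
            da = dist.get((min(a, c), max(a, c)))
            db = dist.get((min(b, c), max(b, c)))
            newd[c] = (na * da + nb * db) / (na + nb)
        clusters[nxt] = merged
        dist = {k: v for k, v in dist.items() if a not in k and b not in k}
        for c, v in newd.items():
            dist[(min(c, nxt), max(c, nxt))] = v
        nxt += 1
    return heights


class TestDissimilarity:
    def test_identical_lines_zero(self):
        D = gk.allele_match_dissimilarity(geno(["ABAB", "ABAB"]))
        assert D.d.iloc[0, 1] == 0.0

    def test_opposite_homozygotes_one(self):
        D = gk.allele_match_dissimilarity(geno(["AAAA", "BBBB"]))
        assert D.d.iloc[0, 1] == 1.0

    def test_het_vs_hom_half(self):
        D = gk.allele_match_dissimilarity(geno(["HHHH", "ABAB"]))
        assert D.d.iloc[0, 1] == 0.5

    def test_pairwise_complete_loci_only(self):
        D = gk.allele_match_dissimilarity(geno(["ABN", "ANB", "NBB"]))
        assert D.shared_loci.iloc[0, 1] == 1  # only m0 shared
        assert D.d.iloc[0, 1] == 0.0

    def test_no_shared_loci_flagged(self):
        D = gk.allele_match_dissimilarity(geno(["AN", "NA"]))
        assert np.isnan(D.d.iloc[0, 1])

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_reference_and_is_pseudometric(self, seed):
        rng = np.random.default_rng(seed)
        chars = np.array(list("ABH"))  # complete data: d is a pseudo-metric
        rows = ["".join(rng.choice(chars, size=12)) for _ in range(6)]
        G = geno(rows)
        D = gk.allele_match_dissimilarity(G)
        d = D.d.to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        for i in G.lines:
            for j in G.lines:
                assert D.d.at[i, j] == pytest.approx(
                    brute_force_d(G, i, j) if i != j else 0.0)
        # triangle inequality on complete data
        n = len(rows)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestUPGMA:
    def test_hand_worked_three_lines(self):
        d = pd.DataFrame(
            [[0.0, 0.2, 0.6], [0.2, 0.0, 0.6], [0.6, 0.6, 0.0]],
            index=list("ABC"), columns=list("ABC"),
        )
        D = gk.DissimilarityMatrix(d=d, shared_loci=d * 0 + 1)
        tree = gk.upgma(D)
        assert tree.heights() == pytest.approx([0.1, 0.3])

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(1)
        x = rng.random((7, 4))
        d = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
        labels = [f"l{i}" for i in range(7)]
        D = gk.DissimilarityMatrix(
            d=pd.DataFrame(d, index=labels, columns=labels),
            shared_loci=pd.DataFrame(1, index=labels, columns=labels),
        )
        h = gk.upgma(D).heights()
        assert (np.diff(h) >= -1e-12).all()

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_reference(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 9)
        x = rng.random((n, 3))
        d = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
        labels = [f"l{i}" for i in range(n)]
        D = gk.DissimilarityMatrix(
            d=pd.DataFrame(d, index=labels, columns=labels),
            shared_loci=pd.DataFrame(1, index=labels, columns=labels),
        )
        assert gk.upgma(D).heights() == pytest.approx(
            brute_force_upgma(d.tolist()), abs=1e-10)

    def test_newick_export_parses_and_preserves_leaves(self):
        d = pd.DataFrame(
            [[0.0, 0.2, 0.6], [0.2, 0.0, 0.6], [0.6, 0.6, 0.0]],
            index=list("ABC"), columns=list("ABC"),
        )
        D = gk.DissimilarityMatrix(d=d, shared_loci=d * 0 + 1)
        nwk = gk.upgma(D).to_newick()
        from io import StringIO
        from Bio import Phylo
        tree = Phylo.read(StringIO(nwk), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == ["A", "B", "C"]
        depths = tree.depths()
        leaf_depths = [v for k, v in depths.items() if k.name]
        assert leaf_depths == pytest.approx([0.3, 0.3, 0.3])

    def test_undefined_entries_rejected(self):
        d = pd.DataFrame([[0.0, np.nan], [np.nan, 0.0]], index=list("AB"),
                         columns=list("AB"))
        D = gk.DissimilarityMatrix(d=d, shared_loci=d * 0)
        with pytest.raises(gk.ConfigurationError):
            gk.upgma(D)


class TestMatchUnknowns:
    def _panel_with_duplicate(self, error_rate=0.01, seed=0):
        rng = np.random.default_rng(seed)
        rows = ["".join(rng.choice(list("AB"), size=400)) for _ in range(5)]
        dup = list(rows[2])
        miscall = rng.random(400) < error_rate
        for i in np.flatnonzero(miscall):
            dup[i] = "A" if dup[i] == "B" else "B"
        rows.append("".join(dup))
        labels = [f"k{i}" for i in range(5)] + ["u0"]
        return gk.allele_match_dissimilarity(geno(rows, lines=labels)), labels

    def test_planted_duplicate_matched(self):
        D, labels = self._panel_with_duplicate()
        rep = gk.match_unknowns(D, labels[:5], ["u0"])
        assert rep["known"].tolist() == ["k2"]
        assert rep["d"].iloc[0] == pytest.approx(0.01, abs=0.01)

    def test_unrelated_unknown_unmatched(self):
        D, labels = self._panel_with_duplicate()
        rep = gk.match_unknowns(D, labels[:2], ["u0"])  # true match excluded
        assert rep["known"].isna().all()

    def test_equidistant_knowns_both_reported(self):
        rows = ["AAAA", "AAAA", "AAAB"]
        D = gk.allele_match_dissimilarity(
            geno(rows, lines=["k0", "k1", "u0"]))
        rep = gk.match_unknowns(D, ["k0", "k1"], ["u0"], max_d=0.3)
        assert sorted(rep["known"]) == ["k0", "k1"]

    def test_overlapping_labels_rejected(self):
        D, labels = self._panel_with_duplicate()
        with pytest.raises(gk.ConfigurationError):
            gk.match_unknowns(D, labels, labels[:1])


class TestVerifyCross:
    def test_identical_progeny_selfed(self):
        parent = geno(["ABAB"]).calls.iloc[0]
        progeny = geno(["ABAB", "ABAB", "ABAB"])
        verdict, frac = gk.verify_cross(progeny, parent)
        assert verdict == "selfed" and frac == 0.0

    def test_low_rate_miscalls_within_tolerance(self):
        rng = np.random.default_rng(0)
        base = "".join(rng.choice(list("AB"), size=1000))
        rows = []
        for _ in range(5):
            row = list(base)
            for i in np.flatnonzero(rng.random(1000) < 0.005):
                row[i] = "A" if row[i] == "B" else "B"
            rows.append("".join(row))
        verdict, _ = gk.verify_cross(geno(rows), geno([base]).calls.iloc[0])
        assert verdict == "selfed"

    def test_f2_progeny_segregate(self):
        """An F2 from parents differing at ~30% of loci shows variation far
        above scoring-error tolerance."""
        rng = np.random.default_rng(1)
        L = 600
        differs = rng.random(L) < 0.3
        p1 = np.where(differs, gk.HOM_A, gk.HOM_A)
        p2 = np.where(differs, gk.HOM_B, gk.HOM_A)
        rows = []
        for _ in range(10):
            draw = rng.integers(0, 4, size=L)  # F2 ratios 1:2:1
            f2 = np.where(draw == 0, gk.HOM_A,
                          np.where(draw == 3, gk.HOM_B, gk.HET))
            rows.append(np.where(differs, f2, gk.HOM_A))
        progeny = gk.GenotypeMatrix(pd.DataFrame(
            rows, index=[f"p{i}" for i in range(10)],
            columns=[f"m{j}" for j in range(L)]))
        parent = pd.Series(p2, index=progeny.loci)
        verdict, frac = gk.verify_cross(progeny, parent)
        assert verdict == "segregating"
        assert frac > 0.25

    def test_requires_two_progeny_and_shared_loci(self):
        parent = geno(["AB"]).calls.iloc[0]
        with pytest.raises(gk.ConfigurationError):
            gk.verify_cross(geno(["AB"]), parent)
        progeny = geno(["NN", "NN"])
        with pytest.raises(gk.ConfigurationError):
            gk.verify_cross(progeny, parent)
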