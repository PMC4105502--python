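"""Recombination-fraction linkage analysis and consensus-map saturation.

Recombination fractions (rf) are simple recombination counts over
lines homozygous at both loci — appropriate for near-inbred RIL
populations where heterozygotes are rare and uninformative.  Raw
apparent rf can exceed 0.5 when two loci are scored in opposite
parental phases; this is exploited both to detect and fix phase errors
(:func:`correct_phases`) and, after correction, to place new candidate
loci on a framework map by interpolation against the two closest
anchors (:func:`place_markers`).

Map distances are reported with the Kosambi mapping function,
``d = 25 ln((1+2r)/(1-2r))`` cM, which allows for partial crossover
interference; the Haldane inverse is provided for simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import networkx as nx

from .core import (
    FRAMEWORK,
    PLACED,
    HET,
    HOM_A,
    HOM_B,
    MISSING,
    ConfigurationError,
    GeneticMap,
    GenotypeMatrix,
)

PHASE_SUFFIXES = ("~p0", "~p1")


# ---------------------------------------------------------------------------
# recombination fractions
# ---------------------------------------------------------------------------

def _signed_homozygotes(G: GenotypeMatrix) -> np.ndarray:
    """+1 for hom-A, -1 for hom-B, 0 for het/missing (lines x loci)."""
    calls = G.calls.to_numpy()
    x = np.zeros(calls.shape, dtype=np.float64)
    x[calls == HOM_A] = 1.0
    x[calls == HOM_B] = -1.0
    return x


def rf_matrix(G: GenotypeMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs recombination fractions by simple recombination count.

    Only lines homozygous (and called) at both loci are informative.
    Returns ``(r, n_informative)`` as locus x locus DataFrames; ``r`` is
    NaN where no line is informative.  Apparent r > 0.5 signals a
    phase conflict between the two loci.
    """
    x = _signed_homozygotes(G)
    informative = np.abs(x)
    n = informative.T @ informative
    agree = x.T @ x  # concordant minus discordant counts
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (n - agree) / (2.0 * n)
    r[n == 0] = np.nan
    np.fill_diagonal(r, 0.0)
    loci = G.loci
    return (
        pd.DataFrame(r, index=loci, columns=loci),
        pd.DataFrame(n.astype(int), index=loci, columns=loci),
    )


def estimate_rf(G: GenotypeMatrix, i: str, j: str) -> tuple[float, int]:
    """Recombination fraction between loci ``i`` and ``j``.

    r = (# informative lines with a non-parental two-locus genotype) /
    (# lines homozygous at both loci).  Returns ``(nan, 0)`` when no
    line is informative.
    """
    sub = G.subset(loci=[i, j])
    r, n = rf_matrix(sub)
    return float(r.iloc[0, 1]), int(n.iloc[0, 1])


# ---------------------------------------------------------------------------
# parental phase
# ---------------------------------------------------------------------------

def assign_phase(
    progeny: GenotypeMatrix,
    parent1: pd.Series | None = None,
    parent2: pd.Series | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Orient progeny calls so allele A descends from parent 1.

    Where both parents are called and polymorphic (hom-A / hom-B), the
    locus is oriented by the parents.  Where parental data are missing
    or monomorphic — which can reflect genotyping error or heterogeneity
    within the parent stocks — the locus is emitted in both candidate
    phases under suffixed names (``locus~p0`` as scored, ``~p1``
    complemented), to be resolved later against linked loci.

    Returns the phased matrix and a per-locus report with columns
    ``parental_status`` ({oriented, flipped, duplicated}) and source.
    """
    calls = progeny.calls
    out_cols: dict[str, np.ndarray] = {}
    report_rows = []
    flip = {HOM_A: HOM_B, HOM_B: HOM_A, HET: HET, MISSING: MISSING}
    for locus in progeny.loci:
        col = calls[locus].to_numpy()
        p1 = parent1.get(locus, MISSING) if parent1 is not None else MISSING
        p2 = parent2.get(locus, MISSING) if parent2 is not None else MISSING
        informative = {p1, p2} == {HOM_A, HOM_B}
        if informative:
            if p1 == HOM_A:
                out_cols[locus] = col
                report_rows.append((locus, "oriented"))
            else:
                out_cols[locus] = np.vectorize(flip.get)(col).astype(np.int8)
                report_rows.append((locus, "flipped"))
        else:
            out_cols[locus + PHASE_SUFFIXES[0]] = col
            out_cols[locus + PHASE_SUFFIXES[1]] = np.vectorize(flip.get)(col).astype(
                np.int8
            )
            report_rows.append((locus, "duplicated"))
    phased = GenotypeMatrix(pd.DataFrame(out_cols, index=progeny.lines))
    report = pd.DataFrame(report_rows, columns=["locus", "parental_status"])
    return phased, report


def _flip_locus(calls: pd.DataFrame, locus: str) -> None:
    col = calls[locus].to_numpy()
    flipped = col.copy()
    flipped[col == HOM_A] = HOM_B
    flipped[col == HOM_B] = HOM_A
    calls[locus] = flipped


def _phase_twin(locus: str) -> str | None:
    for s, other in zip(PHASE_SUFFIXES, reversed(PHASE_SUFFIXES)):
        if locus.endswith(s):
            return locus[: -len(s)] + other
    return None


def correct_phases(
    G: GenotypeMatrix,
    low: float = 0.20,
    high: float = 0.80,
    max_iter: int = 10,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Recursively detect and fix parental-phase errors.

    For each locus, linked loci with apparent r < ``low`` count as
    in-phase and those with r > ``high`` as out-of-phase.  A locus with
    more out-of-phase than in-phase matches is rescored in the opposite
    phase; if after flipping it still has more out-of-phase matches it
    is eliminated.  A tie (including 0 == 0 for unlinked loci) keeps
    the locus unchanged.  Loci carrying a both-phase twin (from
    :func:`assign_phase`) are eliminated rather than flipped, since
    their complement is already present.

    Returns the corrected matrix and a :class:`PhaseReport`-style table
    (locus, in_phase, out_phase, action, iteration).
    """
    calls = G.calls.copy()
    r, _n = rf_matrix(GenotypeMatrix(calls))
    rmat = r.to_numpy()
    loci = list(calls.columns)
    index = {l: k for k, l in enumerate(loci)}
    flipped_once: set[str] = set()
    eliminated: set[str] = set()
    report = []

    def counts(k: int, active: np.ndarray) -> tuple[int, int]:
        row = rmat[k]
        with np.errstate(invalid="ignore"):
            in_p = int(np.nansum((row < low) & active))
            out_p = int(np.nansum((row > high) & active))
        if row[k] < low:  # self never counts
            in_p -= 1
        return in_p, out_p

    it = 0
    for it in range(1, max_iter + 1):
        active = np.array([l not in eliminated for l in loci])
        changed = False
        for locus in loci:
            if locus in eliminated:
                continue
            k = index[locus]
            in_p, out_p = counts(k, active)
            if out_p <= in_p:
                continue
            twin = _phase_twin(locus)
            if (twin is not None and twin in index and twin not in eliminated) or (
                locus in flipped_once
            ):
                eliminated.add(locus)
                active[k] = False
                report.append((locus, in_p, out_p, "eliminated", it))
            else:
                _flip_locus(calls, locus)
                # flipping complements every informative rf involving the locus
                row = rmat[k]
                mask = ~np.isnan(row)
                mask[k] = False
                rmat[k, mask] = 1.0 - rmat[k, mask]
                rmat[mask, k] = rmat[k, mask]
                flipped_once.add(locus)
                report.append((locus, in_p, out_p, "flipped", it))
            changed = True
        if not changed:
            break
    else:
        # did not converge: eliminate whatever is still conflicted
        active = np.array([l not in eliminated for l in loci])
        for locus in loci:
            if locus in eliminated:
                continue
            k = index[locus]
            in_p, out_p = counts(k, active)
            if out_p > in_p:
                eliminated.add(locus)
                report.append((locus, in_p, out_p, "eliminated", max_iter))
        warnings.warn("phase correction did not converge; conflicted loci eliminated")

    kept = [l for l in loci if l not in eliminated]
    for locus in kept:
        if locus not in {row[0] for row in report}:
            report.append((locus, *counts(index[locus], np.array([l not in eliminated for l in loci])), "kept", it))
    out = GenotypeMatrix(calls[kept])
    rep = pd.DataFrame(
        report, columns=["locus", "in_phase", "out_phase", "action", "iteration"]
    )
    return out, rep


# ---------------------------------------------------------------------------
# consensus-map placement
# ---------------------------------------------------------------------------

@dataclass
class Placement:
    locus: str
    linkage_group: object
    position_cm: float
    anchor1: str
    rf1: float
    anchor2: str
    rf2: float
    source_population: str
    distal: bool


def _best_anchor_rfs(
    candidate: str,
    rf_by_population: Mapping[str, pd.DataFrame],
    framework_loci: Sequence[str],
) -> pd.DataFrame:
    """Per framework locus: minimum rf to the candidate over populations."""
    rows = []
    for locus in framework_loci:
        best = np.inf
        src = None
        n_src = -1
        for pop, rf in rf_by_population.items():
            if candidate not in rf.index or locus not in rf.columns:
                continue
            v = rf.at[candidate, locus]
            if np.isnan(v):
                continue
            if v < best - 1e-12:
                best, src = v, pop
        if src is not None:
            rows.append((locus, best, src))
    return pd.DataFrame(rows, columns=["locus", "rf", "population"])


def _framework_rf(
    f1: str,
    f2: str,
    rf_by_population: Mapping[str, pd.DataFrame],
    fallback_cm: float,
) -> float:
    """Minimum observed rf between two framework loci; falls back to the
    inverse Kosambi of their map separation when never co-genotyped."""
    best = np.inf
    for rf in rf_by_population.values():
        if f1 in rf.index and f2 in rf.columns:
            v = rf.at[f1, f2]
            if not np.isnan(v):
                best = min(best, float(v))
    if np.isfinite(best):
        return best
    return kosambi_inverse(fallback_cm)


def place_markers(
    framework: GeneticMap,
    candidates: Sequence[str],
    rf_by_population: Mapping[str, pd.DataFrame],
    max_rf: float = 0.5,
) -> tuple[GeneticMap, pd.DataFrame]:
    """Place candidate loci on a framework map by rf interpolation.

    For each candidate the two framework loci with the smallest rf in
    any population are taken as anchors (f1 the closer, f2 the next
    closest on f1's linkage group; ties broken by locus name).  If f1
    is interior, or the candidate is closer to f2 than the two anchors
    are to each other, the position interpolates between the anchors
    proportionally to the rf values::

        pos = pos(f1) + (pos(f2) - pos(f1)) * rf1 / (rf1 + rf2)

    If f1 is terminal and rf(c, f2) > rf(f1, f2), the candidate lies
    beyond the end of the group and is placed distal at 1 cM per 1% rf
    outside f1 — positions before the first anchor are negative.

    Candidates with no framework rf below ``max_rf`` in any population
    are left unplaced and reported.
    """
    fw = framework.framework()
    fw_pos = fw.positions()
    fw_lg = fw.table.set_index("locus")["linkage_group"]
    placements: list[Placement] = []
    unplaced: list[str] = []

    for cand in candidates:
        table = _best_anchor_rfs(cand, rf_by_population, list(fw_pos.index))
        table = table[table["rf"] < max_rf]
        if table.empty:
            unplaced.append(cand)
            continue
        table = table.sort_values(["rf", "locus"], kind="stable")
        f1 = table.iloc[0]["locus"]
        lg = fw_lg[f1]
        same_lg = table[table["locus"].map(fw_lg) == lg]
        others = same_lg[same_lg["locus"] != f1]
        if others.empty:
            unplaced.append(cand)
            continue
        f2 = others.iloc[0]["locus"]
        rf1 = float(table.set_index("locus").at[f1, "rf"])
        rf2 = float(others.set_index("locus").at[f2, "rf"])
        src = str(table.set_index("locus").at[f1, "population"])
        p1, p2 = float(fw_pos[f1]), float(fw_pos[f2])

        group_pos = fw.table.loc[fw.table["linkage_group"] == lg, "position_cm"]
        terminal_low = p1 <= group_pos.min() + 1e-9
        terminal_high = p1 >= group_pos.max() - 1e-9
        rf_f1f2 = _framework_rf(f1, f2, rf_by_population, abs(p2 - p1))

        distal = (terminal_low or terminal_high) and rf2 > rf_f1f2
        if distal:
            offset = 100.0 * rf1  # 1 cM per 1% rf
            pos = p1 - offset if terminal_low else p1 + offset
        else:
            denom = rf1 + rf2
            frac = 0.0 if denom == 0 else rf1 / denom
            pos = p1 + (p2 - p1) * frac
        placements.append(
            Placement(cand, lg, float(pos), f1, rf1, f2, rf2, src, distal)
        )

    placed_rows = [
        {
            "locus": p.locus,
            "linkage_group": p.linkage_group,
            "position_cm": p.position_cm,
            "status": PLACED,
            "anchor1": p.anchor1,
            "rf1": p.rf1,
            "anchor2": p.anchor2,
            "rf2": p.rf2,
            "source_population": p.source_population,
        }
        for p in placements
    ]
    if placed_rows:
        placed_df = pd.DataFrame(placed_rows, columns=list(fw.table.columns) + [
            "anchor1", "rf1", "anchor2", "rf2", "source_population"])
        table = pd.concat([fw.table, placed_df], ignore_index=True)
    else:
        table = fw.table.copy()
    table = table.sort_values(["linkage_group", "position_cm"], kind="stable")
    report = pd.DataFrame({"locus": unplaced, "reason": "no linked framework locus"})
    return GeneticMap(table.reset_index(drop=True)), report


# ---------------------------------------------------------------------------
# map summaries
# ---------------------------------------------------------------------------

def map_density(gmap: GeneticMap, bin_cm: float = 5.0, status: str = PLACED) -> pd.DataFrame:
    """Counts of loci per half-open [k*bin, (k+1)*bin) position bin.

    Negative positions (distal placements) fall in negative-index bins.
    Returns a tidy table (linkage_group, bin, count).
    """
    sub = gmap.table[gmap.table["status"] == status]
    rows = []
    for lg, grp in sub.groupby("linkage_group", sort=True):
        bins = np.floor(grp["position_cm"].to_numpy(float) / bin_cm).astype(int)
        for b, c in pd.Series(bins).value_counts().sort_index().items():
            rows.append((lg, int(b), int(c)))
    return pd.DataFrame(rows, columns=["linkage_group", "bin", "count"])


def gap_stats(gmap: GeneticMap, threshold_cm: float = 5.0) -> tuple[int, float]:
    """Number of adjacent-marker intervals above the threshold, and the
    maximum interval, across all linkage groups."""
    n_over = 0
    max_gap = 0.0
    for lg in gmap.linkage_groups:
        pos = np.sort(gmap.group(lg)["position_cm"].to_numpy(float))
        if len(pos) < 2:
            continue
        gaps = np.diff(pos)
        n_over += int((gaps > threshold_cm).sum())
        max_gap = max(max_gap, float(gaps.max()))
    return n_over, max_gap


# ---------------------------------------------------------------------------
# map functions
# ---------------------------------------------------------------------------

def kosambi_cm(r) -> np.ndarray | float:
    """Kosambi map distance d = 25 ln((1+2r)/(1-2r)) cM for 0 <= r < 0.5."""
    r = np.asarray(r, float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ConfigurationError("Kosambi distance undefined for r outside [0, 0.5)")
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_inverse(d_cm) -> np.ndarray | float:
    """Recombination fraction for a Kosambi distance in cM."""
    d = np.asarray(d_cm, float)
    e = np.exp(d / 25.0)
    r = 0.5 * (e - 1.0) / (e + 1.0)
    return float(r) if r.ndim == 0 else r


def haldane_inverse(d_cm) -> np.ndarray | float:
    """Recombination fraction for a Haldane distance in cM."""
    r = 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, float) / 100.0))
    return float(r) if r.ndim == 0 else r


# ---------------------------------------------------------------------------
# de novo mapping
# ---------------------------------------------------------------------------

def _mst_path_order(nodes: list[str], rf: pd.DataFrame) -> list[str]:
    """Greedy minimum-spanning-path order: traverse the MST of the rf
    graph from one end of its diameter."""
    if len(nodes) <= 2:
        return sorted(nodes)
    g = nx.Graph()
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            w = rf.at[a, b]
            if not np.isnan(w):
                g.add_edge(a, b, weight=float(w))
    mst = nx.minimum_spanning_tree(g)
    # diameter endpoint: farthest node from an arbitrary start, twice
    start = sorted(mst.nodes)[0]
    dist = nx.single_source_dijkstra_path_length(mst, start)
    far = max(sorted(dist), key=lambda n: dist[n])
    order = list(nx.dfs_preorder_nodes(mst, source=far))
    return order


def denovo_map(
    G: GenotypeMatrix,
    link_threshold_r: float = 0.25,
    min_group: int = 3,
    max_distal_cm: float = 15.0,
) -> GeneticMap:
    """Build a de novo linkage map from a phased, filtered matrix.

    Linkage groups are connected components of the graph joining locus
    pairs with r < ``link_threshold_r``.  Loci more than
    ``max_distal_cm`` (Kosambi) from every other locus, and groups with
    fewer than ``min_group`` loci, are excluded as unlinked.  Within a
    group, loci are ordered by a greedy minimum-spanning-path heuristic
    on rf, and adjacent distances are Kosambi distances of the rf
    re-estimated from the data for the final order.
    """
    r, _n = rf_matrix(G)
    rv = r.to_numpy().copy()
    np.fill_diagonal(rv, np.nan)
    max_r = kosambi_inverse(max_distal_cm)
    with np.errstate(invalid="ignore"):
        nearest = np.nanmin(np.where(np.isnan(rv), np.inf, rv), axis=1)
    keep = nearest <= max_r
    loci = [l for l, k in zip(G.loci, keep) if k]

    g = nx.Graph()
    g.add_nodes_from(loci)
    sub_r = r.loc[loci, loci]
    arr = sub_r.to_numpy()
    ii, jj = np.where(np.triu(arr < link_threshold_r, k=1))
    for a, b in zip(ii, jj):
        g.add_edge(loci[a], loci[b])

    rows = []
    lg_id = 0
    for comp in sorted(nx.connected_components(g), key=lambda c: sorted(c)[0]):
        if len(comp) < min_group:
            continue
        lg_id += 1
        order = _mst_path_order(sorted(comp), r)
        pos = 0.0
        prev = None
        for locus in order:
            if prev is not None:
                rr = min(float(r.at[prev, locus]), 0.499)
                pos += kosambi_cm(rr)
            rows.append((locus, lg_id, pos, FRAMEWORK))
            prev = locus
    return GeneticMap(
        pd.DataFrame(rows, columns=["locus", "linkage_group", "position_cm", "status"])
    )
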