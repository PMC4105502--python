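"""Germplasm-identity diagnostics.

Breeding programs regularly face sample mix-ups: a tray of unknown
plots that must be matched back to named varieties, or a putative
cross whose progeny look suspiciously uniform.  Both are resolved with
an allele-matching dissimilarity over bi-allelic diploid loci::

    d_ij = 1 - (1/L) * sum_l (m_l / 2)

where L counts the informative loci shared by lines i and j and
m_l in {0, 1, 2} the matching alleles at locus l (2 for identical
calls, 1 for het vs hom, 0 for opposite homozygotes).  Clustering uses
UPGMA (average linkage), whose merge heights are non-decreasing on
metric input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .core import HET, HOM_A, HOM_B, MISSING, ConfigurationError, GenotypeMatrix


@dataclass
class DissimilarityMatrix:
    """Pairwise allele-matching dissimilarity and shared-locus counts."""

    d: pd.DataFrame
    shared_loci: pd.DataFrame

    @property
    def lines(self) -> pd.Index:
        return self.d.index


def allele_match_dissimilarity(G: GenotypeMatrix) -> DissimilarityMatrix:
    """Pairwise d over loci called in both lines.

    Pairs sharing no informative locus get NaN (flagged, not guessed).
    """
    calls = G.calls.to_numpy()
    called = calls != MISSING
    # matching alleles per locus pair: 2 - |dosage difference|
    dos = calls.astype(float)
    n = G.n_lines
    d = np.zeros((n, n))
    L = np.zeros((n, n), dtype=int)
    for i in range(n):
        both = called[i] & called
        diff = np.abs(dos[i][None, :] - dos)
        m = 2.0 - np.where(both, diff, np.nan)
        Li = both.sum(axis=1)
        with np.errstate(invalid="ignore"):
            d[i] = 1.0 - np.nansum(m, axis=1) / (2.0 * np.where(Li > 0, Li, 1))
        d[i, Li == 0] = np.nan
        L[i] = Li
    np.fill_diagonal(d, 0.0)
    lines = G.lines
    return DissimilarityMatrix(
        d=pd.DataFrame(d, index=lines, columns=lines),
        shared_loci=pd.DataFrame(L, index=lines, columns=lines),
    )


@dataclass
class Dendrogram:
    """UPGMA merge tree.

    ``merges`` follows the scipy linkage layout (two cluster ids, merge
    height, cluster size) but heights use the ultrametric convention:
    half the average between-cluster dissimilarity, so a pair of lines
    at d = 0.2 merges at height 0.1 and leaves sit at depth equal to
    the merge height.
    """

    merges: np.ndarray
    labels: list

    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_newick(self) -> str:
        """Newick string with branch lengths = height differences."""
        n = len(self.labels)
        node_h = {i: 0.0 for i in range(n)}
        node_s = {i: self.labels[i] for i in range(n)}
        for k, (a, b, h, _size) in enumerate(self.merges):
            a, b = int(a), int(b)
            sa = f"{node_s[a]}:{h - node_h[a]:.6g}"
            sb = f"{node_s[b]}:{h - node_h[b]:.6g}"
            node_s[n + k] = f"({sa},{sb})"
            node_h[n + k] = h
        return node_s[n + len(self.merges) - 1] + ";"


def upgma(D: DissimilarityMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) clustering of a complete dissimilarity
    matrix; merge order for exactly tied distances follows input order,
    with lines pre-sorted by label for reproducibility."""
    if D.d.isna().to_numpy().any():
        raise ConfigurationError("dissimilarity matrix has undefined entries")
    order = sorted(D.d.index)
    dd = D.d.loc[order, order].to_numpy(float)
    dd = (dd + dd.T) / 2.0  # enforce exact symmetry for squareform
    merges = linkage(squareform(dd, checks=False), method="average")
    merges = merges.copy()
    merges[:, 2] /= 2.0  # ultrametric height convention
    return Dendrogram(merges=merges, labels=list(order))


def match_unknowns(
    D: DissimilarityMatrix,
    known_labels: list,
    unknown_labels: list,
    max_d: float = 0.05,
) -> pd.DataFrame:
    """Pair each unknown sample with the known line(s) within ``max_d``.

    Returns a table (unknown, known, d) sorted by dissimilarity within
    each unknown; unknowns with no match appear once with known=None.
    """
    overlap = set(known_labels) & set(unknown_labels)
    if overlap:
        raise ConfigurationError(f"labels in both groups: {sorted(overlap)}")
    rows = []
    for u in unknown_labels:
        dists = D.d.loc[u, known_labels].sort_values()
        hits = dists[dists <= max_d]
        if hits.empty:
            rows.append({"unknown": u, "known": None, "d": float("nan")})
        else:
            for k, v in hits.items():
                rows.append({"unknown": u, "known": k, "d": float(v)})
    return pd.DataFrame(rows, columns=["unknown", "known", "d"])


def verify_cross(
    progeny: GenotypeMatrix,
    parent: pd.Series,
    error_tolerance: float = 0.01,
) -> tuple[str, float]:
    """Decide whether putative progeny are a true cross or selfed seed.

    ``fraction_variable`` is the proportion of loci at which any
    progeny call (missing excluded) differs from the parent — a
    het-vs-hom difference counts, since F2s are diagnosed chiefly by
    segregating heterozygosity.  The verdict is ``'selfed'`` when the
    fraction of discordant progeny x locus calls stays within the
    scoring-error tolerance, ``'segregating'`` otherwise.
    """
    if progeny.n_lines < 2:
        raise ConfigurationError("need at least two progeny")
    par = parent.reindex(progeny.loci)
    calls = progeny.calls.to_numpy()
    parr = par.to_numpy()
    informative = (calls != MISSING) & (parr[None, :] != MISSING)
    if not informative.any():
        raise ConfigurationError("no shared loci between progeny and parent")
    differs = (calls != parr[None, :]) & informative
    loci_with_calls = informative.any(axis=0)
    fraction_variable = float(differs.any(axis=0)[loci_with_calls].mean())
    call_discordance = float(differs.sum() / informative.sum())
    verdict = "selfed" if call_discordance <= error_tolerance else "segregating"
    return verdict, fraction_variable
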