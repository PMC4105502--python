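"""Reference-free SNP calling from sequence tags.

A *tag* is a unique fixed-length (64 bp) sequence representing a group
of identical reads at a restriction site.  Without a reference genome,
SNPs are discovered as pairs of tags that differ at a small number of
positions.  Two complementary routes are supported:

* a pairwise route: tags within ``max_mismatch`` of each other are
  paired, and tags that fall into complex multi-tag mismatch families
  (connected components of size > 2) are discarded as likely
  multi-locus repeats or homoeologue collapses;

* a population-level route: for each putative pair, lines are tallied
  in a 2x2 table (tag 1 only / tag 2 only / both / neither) and a
  Fisher exact test of independence is applied.  True allelic tags at a
  single bi-allelic locus in an inbred population are strongly
  negatively associated across lines, so independence is rejected;
  tags from unlinked duplicated loci look independent and are dropped.

Genotypes are called from the paired read counts with a small error
tolerance so that a stray miscalled read does not turn a homozygote
into a heterozygote.
"""

from __future__ import annotations

import itertools
import math
from collections import defaultdict

import numpy as np
import pandas as pd
import networkx as nx
from scipy.stats import fisher_exact

from .core import (
    HET,
    HOM_A,
    HOM_B,
    MISSING,
    FormatError,
    GenotypeMatrix,
    SnpCall,
    TagCatalog,
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

NAME_PREFIX = "GBS"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_context(seq: str) -> str:
    """Strand-canonical form: lexicographic min of sequence and reverse
    complement (bracket alleles sorted)."""
    return min(seq, revcomp(seq))


def _mismatch_offsets(a: str, b: str) -> list[int]:
    return [i for i, (x, y) in enumerate(zip(a, b)) if x != y]


def _bracket_context(tag1: str, tag2: str, offset: int) -> str:
    a, b = sorted((tag1[offset], tag2[offset]))
    return f"{tag1[:offset]}[{a}/{b}]{tag1[offset + 1:]}"


# ---------------------------------------------------------------------------
# pairwise route
# ---------------------------------------------------------------------------

def pair_tags(
    catalog: TagCatalog,
    max_mismatch: int = 1,
    min_tag_count: int = 10,
) -> list[SnpCall]:
    """Pair tags differing at <= ``max_mismatch`` positions.

    Tags with fewer than ``min_tag_count`` total reads are ignored.
    Mismatch relations are treated as a graph; only connected
    components of exactly two tags yield candidate SNPs — larger
    families are discarded as complex multi-locus groups.
    """
    lengths = {len(t) for t in catalog.tags}
    if len(lengths) > 1:
        raise FormatError("tags of unequal length")
    totals = catalog.counts.sum(axis=0)
    kept = [t for t in catalog.tags if totals.get(t, 0) >= min_tag_count]

    g = nx.Graph()
    g.add_nodes_from(kept)
    # bucket by sequence with one position masked so near-identical tags meet
    buckets: dict[str, list[str]] = defaultdict(list)
    if max_mismatch == 1 and kept:
        L = len(kept[0])
        for t in kept:
            for i in range(L):
                buckets[t[:i] + "." + t[i + 1:]].append(t)
        for group in buckets.values():
            for a, b in itertools.combinations(sorted(set(group)), 2):
                g.add_edge(a, b)
    else:
        for a, b in itertools.combinations(kept, 2):
            if len(_mismatch_offsets(a, b)) <= max_mismatch:
                g.add_edge(a, b)

    calls: list[SnpCall] = []
    idx = 0
    for comp in sorted(nx.connected_components(g), key=lambda c: sorted(c)[0]):
        if len(comp) != 2:
            continue  # singles carry no SNP; >2 = complex family, discarded
        t1, t2 = sorted(comp)
        offsets = _mismatch_offsets(t1, t2)
        for off in offsets:
            calls.append(
                SnpCall(
                    name=f"{NAME_PREFIX}{idx:06d}",
                    context=_bracket_context(t1, t2, off),
                    alleles=tuple(sorted((t1[off], t2[off]))),
                    source_pipeline="pairwise",
                )
            )
            idx += 1
    return calls


# ---------------------------------------------------------------------------
# population-level Fisher filter
# ---------------------------------------------------------------------------

def presence_table(
    tag1_counts: np.ndarray,
    tag2_counts: np.ndarray,
    drop_double_absent: bool = False,
) -> np.ndarray:
    """2x2 table [[both, tag1 only], [tag2 only, neither]] over lines.

    ``drop_double_absent`` excludes lines with zero reads at both tags
    (uncovered lines) from the 'neither' cell.
    """
    p1 = np.asarray(tag1_counts) > 0
    p2 = np.asarray(tag2_counts) > 0
    both = int(np.sum(p1 & p2))
    only1 = int(np.sum(p1 & ~p2))
    only2 = int(np.sum(~p1 & p2))
    neither = 0 if drop_double_absent else int(np.sum(~p1 & ~p2))
    return np.array([[both, only1], [only2, neither]])


def fisher_population_filter(
    table: np.ndarray,
    alpha: float = 0.001,
) -> tuple[bool, float]:
    """Fisher exact test of independence on the presence/absence table.

    Returns ``(accepted, p_value)`` where acceptance means the two tags
    are non-independent across lines (p < alpha), as expected of the
    two alleles of a single bi-allelic locus in an inbred population.
    A degenerate table (any margin zero) cannot reject independence.
    """
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2):
        raise FormatError("expected a 2x2 table")
    if table.sum() == 0:
        raise FormatError("empty presence table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return False, 1.0
    _, p = fisher_exact(table, alternative="two-sided")
    return bool(p < alpha), float(p)


def population_filter_catalog(
    catalog: TagCatalog,
    candidates: list[SnpCall],
    alpha: float = 0.001,
    drop_double_absent: bool = False,
) -> list[SnpCall]:
    """Apply the Fisher population filter to pairwise candidates."""
    pair_by_context = {
        _bracket_context(t1, t2, off): (t1, t2) for t1, t2, off, _, _ in catalog.pairs
    }
    accepted = []
    for snp in candidates:
        pair = pair_by_context.get(snp.context)
        if pair is None:
            continue
        t1, t2 = pair
        tab = presence_table(
            catalog.counts[t1].to_numpy(),
            catalog.counts[t2].to_numpy(),
            drop_double_absent=drop_double_absent,
        )
        ok, p = fisher_population_filter(tab, alpha=alpha)
        if ok:
            accepted.append(
                SnpCall(
                    name=snp.name,
                    context=snp.context,
                    alleles=snp.alleles,
                    p_value=p,
                    source_pipeline="population",
                )
            )
    return accepted


# ---------------------------------------------------------------------------
# genotype calling
# ---------------------------------------------------------------------------

def call_genotypes(catalog: TagCatalog, error_tolerance: float = 0.02) -> GenotypeMatrix:
    """Call co-dominant genotypes from paired tag counts.

    Per line and tag pair with counts (c1, c2): missing when both are
    zero; heterozygous when both alleles are seen and the minor-read
    fraction min(c1,c2)/(c1+c2) strictly exceeds ``error_tolerance``
    (so a fraction exactly at the tolerance is scored homozygous for the
    majority tag); otherwise homozygous for the majority tag.
    """
    if not catalog.pairs:
        raise FormatError("catalog has no tag pairs")
    n = catalog.counts.shape[0]
    L = len(catalog.pairs)
    c1 = np.column_stack([catalog.counts[t1].to_numpy() for t1, *_ in catalog.pairs])
    c2 = np.column_stack(
        [catalog.counts[t2].to_numpy() for _, t2, *_ in catalog.pairs]
    )
    total = c1 + c2
    with np.errstate(invalid="ignore", divide="ignore"):
        minor = np.minimum(c1, c2) / np.where(total > 0, total, 1)
    calls = np.full((n, L), MISSING, dtype=np.int8)
    covered = total > 0
    het = covered & (c1 > 0) & (c2 > 0) & (minor > error_tolerance)
    hom_a = covered & ~het & (c1 >= c2)
    hom_b = covered & ~het & (c2 > c1)
    calls[het] = HET
    calls[hom_a] = HOM_A
    calls[hom_b] = HOM_B
    loci = [f"{t1[:4]}_{i:05d}" for i, (t1, *_rest) in enumerate(catalog.pairs)]
    return GenotypeMatrix(pd.DataFrame(calls, index=catalog.counts.index, columns=loci))


# ---------------------------------------------------------------------------
# multi-allelic detection and catalog merging
# ---------------------------------------------------------------------------

def _context_key(context: str) -> tuple[str, bool]:
    """Context with the bracketed site masked, strand-canonicalised.

    Returns ``(key, flipped)`` where ``flipped`` indicates the reverse
    complement was the lexicographically smaller strand (alleles must
    then be complemented to compare across catalogs).
    """
    lo = context.index("[")
    hi = context.index("]")
    masked = context[:lo] + "?" + context[hi + 1:]
    rc = revcomp(masked.replace("?", "N"))
    rc = rc.replace("N", "?")
    if rc < masked:
        return rc, True
    return masked, False


def _strand_alleles(alleles, flipped: bool) -> tuple:
    if not flipped:
        return tuple(sorted(alleles))
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return tuple(sorted(comp[a] for a in alleles))


def detect_multiallelic(snps: list[SnpCall]) -> tuple[list[set], list[set]]:
    """Group bi-allelic SNPs sharing a context into multi-allele sets.

    Two bi-allelic SNPs with identical context except at the variant
    site jointly reveal a third (or fourth) allele.  Returns the lists
    of tri-allelic and tetra-allelic allele sets; duplicated SNPs (same
    context, same alleles) form no set.
    """
    groups: dict[str, set] = defaultdict(set)
    for snp in snps:
        key, flipped = _context_key(snp.context)
        groups[key].update(_strand_alleles(snp.alleles, flipped))
    tri = [a for a in groups.values() if len(a) == 3]
    tetra = [a for a in groups.values() if len(a) == 4]
    return tri, tetra


def _canonical_identity(snp: SnpCall) -> tuple[str, tuple]:
    key, flipped = _context_key(snp.context)
    return key, _strand_alleles(snp.alleles, flipped)


def merge_catalogs(a: list[SnpCall], b: list[SnpCall]) -> list[SnpCall]:
    """Merge two SNP catalogs under a stable cumulative nomenclature.

    SNPs with the same strand-canonical context and alleles are unified
    under the earlier-assigned name; records found by both routes get
    ``source_pipeline='both'``.  Novel SNPs from ``b`` are appended with
    fresh sequential names, so repeated merges are idempotent.
    """
    for cat, label in ((a, "a"), (b, "b")):
        names = [s.name for s in cat]
        if len(set(names)) != len(names):
            raise FormatError(f"duplicate names within catalog {label}")
    by_name_a = {s.name: s for s in a}
    for snp in b:
        prev = by_name_a.get(snp.name)
        if prev is not None and _canonical_identity(prev) != _canonical_identity(snp):
            raise FormatError(
                f"name {snp.name!r} refers to different SNPs in the two catalogs"
            )
    merged: dict[tuple, SnpCall] = {}
    max_index = -1
    for snp in a:
        key = _canonical_identity(snp)
        if key in merged and merged[key].context != snp.context:
            raise FormatError(f"name collision with differing context: {snp.name}")
        merged.setdefault(key, SnpCall(**vars(snp)))
        if snp.name.startswith(NAME_PREFIX):
            try:
                max_index = max(max_index, int(snp.name[len(NAME_PREFIX):]))
            except ValueError:
                pass
    for snp in b:
        key = _canonical_identity(snp)
        if key in merged:
            prev = merged[key]
            if prev.source_pipeline != snp.source_pipeline:
                prev.source_pipeline = "both"
            if math.isnan(prev.p_value) and not math.isnan(snp.p_value):
                prev.p_value = snp.p_value
        else:
            max_index += 1
            merged[key] = SnpCall(
                name=f"{NAME_PREFIX}{max_index:06d}",
                context=snp.context,
                alleles=snp.alleles,
                p_value=snp.p_value,
                source_pipeline=snp.source_pipeline,
            )
    return list(merged.values())
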