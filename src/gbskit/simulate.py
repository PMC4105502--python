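"""Synthetic GBS study generator.

Emulates the data a multi-population GBS study of an inbred crop
produces: a multi-linkage-group consensus map, recombinant inbred line
(RIL) populations with residual heterozygosity, a diversity panel with
a gradient of coancestry, and tag-level read counts whose missingness
scales with sequencing depth.

The meiosis model is a no-interference (Haldane) crossover process:
between adjacent loci `d` cM apart a gamete recombines with probability
``r = (1 - exp(-2 d / 100)) / 2``.  Selfing an F1 for ``k - 1``
generations leaves an expected residual heterozygosity of
``(1/2)**(k-1)`` per locus at generation F_k.

Sequencing coverage is parameterised by a *depth index* — good barcoded
reads per sample divided by 2x10^6, the share a sample receives in a
standard 95-plex lane.  Read counts per line and locus are Poisson with
mean proportional to the depth index; a locus with zero reads becomes a
missing call downstream.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawns, so identical seeds give bitwise
identical outputs and every simulator draws from an independent stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    HET,
    HOM_A,
    HOM_B,
    MISSING,
    FRAMEWORK,
    PLACED,
    ConfigurationError,
    GeneticMap,
    GenotypeMatrix,
    TagCatalog,
)

BASES = np.array(list("ACGT"))

#: Mean total reads per line and locus at depth index 1.0, averaged over
#: tags.  GBS coverage sits deep in the unsaturated regime — most
#: restriction fragments receive well under one read per sample per lane
#: share — so the default is low and per-locus abundance varies (see
#: ``SimConfig.tag_abundance_cv``), which is what makes SNP yield climb
#: with sequencing depth across completeness thresholds.
BASE_DEPTH = 1.0


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults follow the study design being emulated: a 21-linkage-group
    consensus map of ~100 cM groups, F4-F8 RIL populations of 52-145
    lines, and per-sample depth indices around 1.
    """

    n_linkage_groups: int = 21
    lg_length: float = 100.0
    n_framework_loci: int = 20
    n_candidate_loci: int = 30
    population_sizes: Sequence[int] = (98, 98, 53, 52, 53, 52)
    generation: int = 6
    outcross_rate: float = 0.005
    seq_error_rate: float = 0.002
    depth_index: float = 1.0
    tag_abundance_cv: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("outcross_rate", "seq_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.generation < 2:
            raise ConfigurationError("generation must be >= 2 (F2 or later)")
        if self.lg_length <= 0:
            raise ConfigurationError("lg_length must be positive")
        if self.n_linkage_groups < 1 or self.n_framework_loci < 1:
            raise ConfigurationError("counts must be positive")
        if self.n_candidate_loci < 0 or self.depth_index < 0:
            raise ConfigurationError("counts must be non-negative")
        if self.tag_abundance_cv < 0:
            raise ConfigurationError("tag_abundance_cv must be >= 0")

    def rng(self, *key: int) -> np.random.Generator:
        """Independent substream derived from the global seed."""
        return np.random.default_rng(np.random.SeedSequence(self.rng_seed, spawn_key=key))


@dataclass
class SimTruth:
    """Ground truth retained alongside each simulated dataset."""

    true_map: GeneticMap | None = None
    true_phases: pd.Series | None = None
    true_kinship: pd.DataFrame | None = None
    true_genotypes: GenotypeMatrix | None = None
    family_labels: pd.Series | None = None


def haldane_r(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction between loci `d_cm` apart (no interference)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, float) / 100.0))


# ---------------------------------------------------------------------------
# maps
# ---------------------------------------------------------------------------

def simulate_consensus_map(cfg: SimConfig) -> GeneticMap:
    """Simulate a consensus map of framework anchors plus candidate loci.

    Framework loci are uniformly spaced with jitter along each linkage
    group; candidate loci fall uniformly at random.  Positions ascend
    within each group.
    """
    rng = cfg.rng(0)
    rows = []
    for lg in range(1, cfg.n_linkage_groups + 1):
        spacing = cfg.lg_length / max(cfg.n_framework_loci - 1, 1)
        base = np.linspace(0.0, cfg.lg_length, cfg.n_framework_loci)
        jitter = rng.uniform(-0.3, 0.3, cfg.n_framework_loci) * spacing
        pos = np.sort(np.clip(base + jitter, 0.0, cfg.lg_length))
        for i, p in enumerate(pos):
            rows.append((f"F{lg:02d}_{i:03d}", lg, float(p), FRAMEWORK))
        cand = np.sort(rng.uniform(0.0, cfg.lg_length, cfg.n_candidate_loci))
        for i, p in enumerate(cand):
            rows.append((f"C{lg:02d}_{i:03d}", lg, float(p), PLACED))
    table = pd.DataFrame(rows, columns=["locus", "linkage_group", "position_cm", "status"])
    table = table.sort_values(["linkage_group", "position_cm"], kind="stable")
    return GeneticMap(table.reset_index(drop=True))


# ---------------------------------------------------------------------------
# meiosis and RIL populations
# ---------------------------------------------------------------------------

def _group_slices(gmap: GeneticMap) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per linkage group: (column indices into locus order, positions)."""
    table = gmap.table.sort_values(["linkage_group", "position_cm"], kind="stable")
    out = []
    for lg, sub in table.groupby("linkage_group", sort=True):
        out.append((sub.index.to_numpy(), sub["position_cm"].to_numpy(float)))
    return out


def _gametes(hap0: np.ndarray, hap1: np.ndarray, r_by_group, rng) -> np.ndarray:
    """One gamete per individual from paired haplotypes (n, L) each."""
    n, L = hap0.shape
    gam = np.empty((n, L), dtype=np.int8)
    for cols, r in r_by_group:
        k = len(cols)
        start = rng.integers(0, 2, size=(n, 1))
        if k > 1:
            xo = rng.random((n, k - 1)) < r
            sel = np.concatenate([start, xo], axis=1).cumsum(axis=1) % 2
        else:
            sel = start
        gam[:, cols] = np.where(sel == 0, hap0[:, cols], hap1[:, cols])
    return gam


def simulate_ril_population(
    gmap: GeneticMap,
    n_lines: int,
    generation: int,
    cfg: SimConfig,
    stream: int = 1,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate an F_k RIL population by selfing from an F1.

    Parent 1 is fixed for the A allele and parent 2 for the B allele at
    every locus; the F1 is heterozygous throughout.  Each generation
    every line produces two gametes from its own haplotypes (selfing);
    with probability ``cfg.outcross_rate`` the second gamete instead
    comes from a random other line, inflating heterozygosity slightly.
    Expected per-locus heterozygosity before errors is (1/2)**(k-1).
    """
    if generation < 2:
        raise ConfigurationError("generation must be >= 2")
    if len(gmap) == 0:
        raise ConfigurationError("empty map")
    rng = cfg.rng(stream)
    order = gmap.table.sort_values(["linkage_group", "position_cm"], kind="stable")
    loci = order["locus"].to_list()
    L = len(loci)
    groups = []
    col = 0
    for lg, sub in order.groupby("linkage_group", sort=True):
        pos = sub["position_cm"].to_numpy(float)
        cols = np.arange(col, col + len(pos))
        r = haldane_r(np.diff(pos))
        groups.append((cols, r))
        col += len(pos)

    hap0 = np.zeros((n_lines, L), dtype=np.int8)  # F1: one A, one B haplotype
    hap1 = np.ones((n_lines, L), dtype=np.int8)
    for _ in range(generation - 1):
        g1 = _gametes(hap0, hap1, groups, rng)
        g2 = _gametes(hap0, hap1, groups, rng)
        if cfg.outcross_rate > 0 and n_lines > 1:
            out = rng.random(n_lines) < cfg.outcross_rate
            if out.any():
                donors = rng.integers(0, n_lines - 1, size=int(out.sum()))
                donors = np.where(donors >= np.flatnonzero(out), donors + 1, donors)
                g_off = _gametes(hap0[donors], hap1[donors], groups, rng)
                g2[out] = g_off
        hap0, hap1 = g1, g2

    calls = (hap0 + hap1).astype(np.int8)  # 0 -> hom A, 1 -> het, 2 -> hom B
    line_names = [f"L{stream}_{i:04d}" for i in range(n_lines)]
    G = GenotypeMatrix(pd.DataFrame(calls, index=line_names, columns=loci))
    truth = SimTruth(
        true_map=gmap,
        true_phases=pd.Series("parent1_A", index=pd.Index(loci, name="locus")),
        true_genotypes=G.copy(),
    )
    return G, truth


# ---------------------------------------------------------------------------
# diversity panel
# ---------------------------------------------------------------------------

#: Size of the ancestral haplotype pool behind a diversity panel and the
#: number of historical meioses each founder's mosaic represents.  The
#: pool gives loci shared ancestral LD blocks (LD that genuinely decays
#: with map distance and is not explained by recent family kinship);
#: more meioses shorten the blocks.
N_ANCESTRAL_HAPLOTYPES = 24
ANCESTRAL_MEIOSES = 10


def simulate_diversity_panel(
    n_families: int,
    lines_per_family: int,
    cfg: SimConfig,
    n_loci: int | None = None,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate an inbred diversity panel with family structure.

    Founders are inbred lines built as recombination mosaics of a small
    ancestral haplotype pool (itself drawn locus-by-locus from
    panel-wide allele frequencies ~ U(0.1, 0.9)), so nearby loci carry
    ancestral LD that decays with map distance.  Consecutive families
    share one founder (family f crosses founders f and f+1), producing
    a gradient of coancestry rather than discrete clusters; members are
    near-inbred offspring of their family cross (selfed to F5).
    Expected kinship is recorded blockwise: 0.5 within a family, 0.25
    between families that share a founder, 0 otherwise.
    """
    if n_families < 1 or lines_per_family < 1:
        raise ConfigurationError("counts must be >= 1")
    rng = cfg.rng(2)
    gmap = simulate_consensus_map(cfg)
    order = gmap.table.sort_values(["linkage_group", "position_cm"], kind="stable")
    if n_loci is not None:
        order = order.iloc[:n_loci]
    loci = order["locus"].to_list()
    L = len(loci)
    freqs = rng.uniform(0.1, 0.9, L)

    pool = (rng.random((N_ANCESTRAL_HAPLOTYPES, L)) < freqs).astype(np.int8)
    n_founders = n_families + 1
    founders = np.empty((n_founders, L), dtype=np.int8)
    for f in range(n_founders):
        col = 0
        for lg, sub in order.groupby("linkage_group", sort=True):
            pos = sub["position_cm"].to_numpy(float)
            k = len(pos)
            switch = haldane_r(np.diff(pos) * ANCESTRAL_MEIOSES)
            idx = np.empty(k, dtype=int)
            idx[0] = rng.integers(N_ANCESTRAL_HAPLOTYPES)
            for j in range(1, k):
                if rng.random() < switch[j - 1]:
                    idx[j] = rng.integers(N_ANCESTRAL_HAPLOTYPES)
                else:
                    idx[j] = idx[j - 1]
            founders[f, col:col + k] = pool[idx, col + np.arange(k)]
            col += k

    groups = []
    col = 0
    for lg, sub in order.groupby("linkage_group", sort=True):
        pos = sub["position_cm"].to_numpy(float)
        cols = np.arange(col, col + len(pos))
        groups.append((cols, haldane_r(np.diff(pos))))
        col += len(pos)

    all_calls = []
    labels = []
    for fam in range(n_families):
        n = lines_per_family
        hap0 = np.repeat(founders[fam][None, :], n, axis=0)
        hap1 = np.repeat(founders[fam + 1][None, :], n, axis=0)
        for _ in range(4):  # self F1 -> F5: members nearly inbred
            g1 = _gametes(hap0, hap1, groups, rng)
            g2 = _gametes(hap0, hap1, groups, rng)
            hap0, hap1 = g1, g2
        all_calls.append(hap0 + hap1)
        labels.extend([fam] * n)

    calls = np.concatenate(all_calls, axis=0).astype(np.int8)
    names = [f"P{lab:02d}_{i:03d}" for i, lab in enumerate(labels)]
    G = GenotypeMatrix(pd.DataFrame(calls, index=names, columns=loci))

    fam_arr = np.asarray(labels)
    kin = np.zeros((len(names), len(names)))
    same = fam_arr[:, None] == fam_arr[None, :]
    adjacent = np.abs(fam_arr[:, None] - fam_arr[None, :]) == 1
    kin[same] = 0.5
    kin[adjacent] = 0.25
    np.fill_diagonal(kin, 1.0)
    truth = SimTruth(
        true_map=GeneticMap(order.reset_index(drop=True)),
        true_kinship=pd.DataFrame(kin, index=names, columns=names),
        true_genotypes=G.copy(),
        family_labels=pd.Series(fam_arr, index=names),
    )
    return G, truth


# ---------------------------------------------------------------------------
# tag-level reads
# ---------------------------------------------------------------------------

def _random_tag_pair(rng: np.random.Generator, length: int = 64) -> tuple[str, str, int, str, str]:
    seq = rng.choice(BASES, size=length)
    offset = int(rng.integers(0, length))
    a1 = seq[offset]
    a2 = rng.choice(BASES[BASES != a1])
    t1 = seq.copy()
    t2 = seq.copy()
    t1[offset] = a1
    t2[offset] = a2
    return "".join(t1), "".join(t2), offset, str(a1), str(a2)


def simulate_tag_reads(G: GenotypeMatrix, cfg: SimConfig, stream: int = 3) -> TagCatalog:
    """Simulate per-line tag read counts for each locus of ``G``.

    Each locus gets a pair of 64 bp tags differing at one position; the
    A allele maps to the first tag.  Total reads per line and locus are
    Poisson with mean ``BASE_DEPTH * cfg.depth_index * a_l`` where the
    per-locus relative abundance ``a_l`` is Gamma-distributed with mean
    1 and coefficient of variation ``cfg.tag_abundance_cv`` (0 gives
    uniform abundance; the default, 1, is exponential, emulating the
    uneven amplification of restriction fragments).  Heterozygotes
    split reads binomially between the two tags; each read is flipped
    to the other tag with probability ``cfg.seq_error_rate``.
    """
    if cfg.depth_index < 0:
        raise ConfigurationError("depth_index must be >= 0")
    rng = cfg.rng(stream)
    n, L = G.n_lines, G.n_loci
    tags: list[str] = []
    pairs = []
    seen = set()
    for _ in range(L):
        while True:
            t1, t2, off, a1, a2 = _random_tag_pair(rng)
            if t1 not in seen and t2 not in seen:
                break
        seen.update((t1, t2))
        tags.extend((t1, t2))
        pairs.append((t1, t2, off, a1, a2))

    if cfg.tag_abundance_cv > 0:
        shape = 1.0 / cfg.tag_abundance_cv**2
        abundance = rng.gamma(shape, cfg.tag_abundance_cv**2, size=L)
    else:
        abundance = np.ones(L)
    lam = BASE_DEPTH * cfg.depth_index * abundance
    total = rng.poisson(np.broadcast_to(lam, (n, L)))
    calls = G.calls.to_numpy()
    # reads carrying the B-allele tag before errors
    p_b = np.select(
        [calls == HOM_A, calls == HET, calls == HOM_B],
        [0.0, 0.5, 1.0],
        default=0.0,
    )
    total = np.where(calls == MISSING, 0, total)
    b_reads = rng.binomial(total, p_b)
    a_reads = total - b_reads
    if cfg.seq_error_rate > 0:
        a_to_b = rng.binomial(a_reads, cfg.seq_error_rate)
        b_to_a = rng.binomial(b_reads, cfg.seq_error_rate)
        a_reads = a_reads - a_to_b + b_to_a
        b_reads = b_reads - b_to_a + a_to_b

    counts = np.empty((n, 2 * L), dtype=np.int64)
    counts[:, 0::2] = a_reads
    counts[:, 1::2] = b_reads
    df = pd.DataFrame(counts, index=G.lines, columns=tags)
    return TagCatalog(tags=tags, counts=df, pairs=pairs)
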