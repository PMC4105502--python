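"""Per-locus statistics and population-specific filtering.

GBS call sets are noisy and incomplete, so every downstream analysis
starts from three per-locus statistics computed inside each population:

* completeness — fraction of lines with a call (100% minus % missing);
* MAF — minor allele frequency, heterozygotes contributing one copy of
  each allele, missing calls excluded;
* heterozygosity — fraction of called lines that are heterozygous.

Filters are inclusive (>= completeness, >= MAF, <= heterozygosity).
The module also implements the two design experiments used to choose
operating parameters: SNP yield as a function of sequencing depth, and
as a function of panel sample size.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .core import HET, HOM_A, HOM_B, MISSING, ConfigurationError, GenotypeMatrix
from . import simulate as sim
from . import tags as tg

#: Reads per unit of depth index (one 95-plex share of a sequencing lane).
READS_PER_DEPTH_UNIT = 2_000_000


def locus_stats(G: GenotypeMatrix) -> pd.DataFrame:
    """Completeness, MAF and heterozygosity per locus.

    A locus with zero calls gets completeness 0 and NaN for MAF and
    heterozygosity (flagged rather than guessed).
    """
    if G.n_lines == 0:
        raise ConfigurationError("genotype matrix has no lines")
    if G.n_loci == 0:
        return pd.DataFrame(columns=["completeness", "maf", "het"], index=G.loci)
    calls = G.calls.to_numpy()
    called = calls != MISSING
    n_called = called.sum(axis=0)
    completeness = n_called / G.n_lines
    n_het = (calls == HET).sum(axis=0)
    n_a = 2 * (calls == HOM_A).sum(axis=0) + n_het
    n_b = 2 * (calls == HOM_B).sum(axis=0) + n_het
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.minimum(n_a, n_b) / np.where(n_called > 0, 2 * n_called, 1)
        het = n_het / np.where(n_called > 0, n_called, 1)
    maf = np.where(n_called > 0, maf, np.nan)
    het = np.where(n_called > 0, het, np.nan)
    return pd.DataFrame(
        {"completeness": completeness, "maf": maf, "het": het},
        index=G.loci,
    )


def filter_loci(
    G: GenotypeMatrix,
    min_completeness: float = 0.5,
    min_maf: float = 0.35,
    max_het: float = 0.08,
) -> GenotypeMatrix:
    """Keep loci with completeness >= min, MAF >= min and het <= max.

    All comparisons are inclusive; locus order and names are preserved.
    The defaults are the mapping-population criteria (>=50%
    completeness, MAF >=35%, heterozygosity <=8%).
    """
    for v in (min_completeness, min_maf, max_het):
        if not 0.0 <= v <= 1.0:
            raise ConfigurationError(f"threshold {v} outside [0, 1]")
    stats = locus_stats(G)
    keep = (
        (stats["completeness"] >= min_completeness)
        & (stats["maf"] >= min_maf)
        & (stats["het"] <= max_het)
    ).fillna(False)
    return G.subset(loci=G.loci[keep.to_numpy()])


def depth_index(reads_per_sample) -> pd.Series:
    """Depth index = good barcoded reads / 2x10^6, per sample."""
    reads = pd.Series(reads_per_sample, dtype=float)
    if (reads < 0).any():
        raise ConfigurationError("negative read count")
    return reads / READS_PER_DEPTH_UNIT


def depth_experiment(
    G_truth: GenotypeMatrix,
    depth_levels: Sequence[float],
    completeness_levels: Sequence[float] = (0.25, 0.50, 0.75, 0.90),
    cfg: sim.SimConfig | None = None,
    max_het: float = 0.10,
    min_maf: float = 0.30,
) -> pd.DataFrame:
    """SNP yield vs sequencing depth at several completeness thresholds.

    For each depth level, tag reads are simulated from the true
    genotypes, genotypes re-called, and SNPs counted after filtering at
    each completeness level (heterozygosity and MAF held fixed).
    Returns a tidy table (depth_index, completeness, snp_count).
    """
    if list(depth_levels) != sorted(depth_levels) or list(
        completeness_levels
    ) != sorted(completeness_levels):
        raise ConfigurationError("levels must be sorted ascending")
    cfg = cfg or sim.SimConfig()
    rows = []
    for d_i, depth in enumerate(depth_levels):
        level_cfg = sim.SimConfig(
            **{**vars(cfg), "depth_index": float(depth)}
        )
        if depth == 0:
            counts = {c: 0 for c in completeness_levels}
        else:
            catalog = sim.simulate_tag_reads(G_truth, level_cfg, stream=100 + d_i)
            called = tg.call_genotypes(catalog)
            stats = locus_stats(called)
            ok = (stats["maf"] >= min_maf) & (stats["het"] <= max_het)
            counts = {
                c: int(((stats["completeness"] >= c) & ok).fillna(False).sum())
                for c in completeness_levels
            }
        for c, n in counts.items():
            rows.append((float(depth), float(c), n))
    return pd.DataFrame(rows, columns=["depth_index", "completeness", "snp_count"])


def samplesize_experiment(
    G: GenotypeMatrix,
    sizes: Sequence[int],
    replicates: int = 2,
    max_het: float = 0.10,
    min_maf: float = 0.05,
    completeness_levels: Sequence[float] = (0.25, 0.50, 0.75, 0.90),
    seed: int = 0,
) -> pd.DataFrame:
    """SNP yield vs number of lines sampled from a diversity panel.

    For each sample size, lines are drawn without replacement
    (``replicates`` independent subsets), loci filtered at fixed MAF
    and heterozygosity, and SNPs counted per completeness threshold.
    Returns a tidy table (n, completeness, replicate, snp_count).
    """
    if max(sizes) > G.n_lines:
        raise ConfigurationError(
            f"requested sample size {max(sizes)} exceeds panel size {G.n_lines}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7,)))
    rows = []
    for size in sizes:
        for rep in range(replicates):
            idx = rng.choice(G.n_lines, size=size, replace=False)
            sub = G.subset(lines=G.lines[np.sort(idx)])
            stats = locus_stats(sub)
            ok = (stats["maf"] >= min_maf) & (stats["het"] <= max_het)
            for c in completeness_levels:
                n = int(((stats["completeness"] >= c) & ok).fillna(False).sum())
                rows.append((int(size), float(c), rep, n))
    return pd.DataFrame(rows, columns=["n", "completeness", "replicate", "snp_count"])
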