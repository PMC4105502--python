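# gbskit

A genotyping-by-sequencing (GBS) discovery toolkit for inbred,
reference-free crops, built around the workflow used to characterise
cultivated oat (*Avena sativa* L., an allohexaploid, 2n = 6x = 42):
reference-free SNP calling from 64 bp sequence tags, population-level
filtering, saturation of a consensus genetic map by
recombination-fraction interpolation, structure- and kinship-corrected
linkage-disequilibrium (LD) decay modelling, and germplasm-identity
diagnostics. A synthetic-data module generates mapping populations,
diversity panels and tag-level reads with the statistical structure
the analyses assume, so the full pipeline runs and is tested without
any sequence downloads. (The oat study's raw reads are in the NCBI SRA
under accession SRP037730; they are not required here.)

The package is a library: import it from Python, or start from the
narrative scripts in `examples/`, one per capability.

## What it computes

**Tag-pair SNP calling.** A tag is a unique 64 bp sequence representing
a group of reads at a restriction site. Candidate SNPs are pairs of
tags differing at ≤1 position; tags in larger mismatch families are
discarded as multi-locus repeats. The population-level filter tallies,
over lines, a 2×2 presence table (tag₁ only / tag₂ only / both /
neither) and applies a Fisher exact test: the two alleles of a real
bi-allelic locus in an inbred population are strongly negatively
associated, so independence is rejected (p < 0.001) while collapsed
homoeologues and repeats are not. Genotypes are called co-dominantly
from paired read counts with a 2% minor-read error tolerance.

**Filtering.** Per-locus completeness (fraction of lines called), minor
allele frequency (heterozygotes contribute one copy of each allele) and
heterozygosity, with inclusive thresholds — e.g. the mapping filter
keeps loci with completeness ≥50%, MAF ≥35% and heterozygosity ≤8%.
Sequencing effort is expressed as a *depth index*: good barcoded reads
per sample divided by 2×10⁶ (one 95-plex lane share).

**Linkage and map saturation.** Recombination fractions are simple
recombination counts over lines homozygous at both loci. Apparent
rf > 0.5 flags parental-phase conflicts, which are repaired by
recursively flipping loci with more out-of-phase (r > 0.8) than
in-phase (r < 0.2) linked neighbours. Candidate loci are placed on a
framework map between the two anchors with the smallest rf in any
population,

    pos = pos(f₁) + (pos(f₂) − pos(f₁)) · rf₁ / (rf₁ + rf₂),

or distal to the group end (possibly at negative cM) when the closest
anchor is terminal. Reported distances use the Kosambi map function
d = 25 ln((1+2r)/(1−2r)).

**Structure and LD decay.** Kinship is the VanRaden realized
relationship K = WWᵀ / (2Σpⱼ(1−pⱼ)). PCA can be preceded by an
ldregress-style step that replaces each marker by its residual on up
to k preceding markers. Pairwise LD r² comes in four flavours: plain,
structure-corrected (r²ₛ, residuals on scaled PCs),
kinship-corrected (r²ᵥ, whitening by K^(−1/2) around the GLS mean) and
both (r²ₛᵥ). Decay with distance c (Morgans) is fit with C = 4·Nₑ·c
under the Sved drift-recombination model E[r²] = 1/(1+C) and the
Hill–Weir model with mutation and a sample-size adjustment; each fit
reports Nₑ ± SE and the distance at which E[r²] = 0.1 — the marker
spacing needed for association scans.

**Diagnostics.** Allele-matching dissimilarity
d = 1 − (1/L)·Σ(mₗ/2) with mₗ ∈ {0,1,2} matching alleles per shared
locus, UPGMA clustering with Newick export, unknown-sample matching,
and a selfed-vs-segregating verdict for suspect crosses under a 1%
scoring-error tolerance.

## Worked example

`python examples/04_structure_and_ld_decay.py` simulates a 160-line
panel (8 families sharing founders, founders mosaics of an ancestral
haplotype pool) and prints:

```
panel: 160 lines in 8 families; PC1-4 explain 37.5% of variation
LD records within 30 cM: 5793
mean r2 0.099  vs  kinship-corrected r2_v 0.018
r2: Hill-Weir Ne=29+/-0.8 (r2=0.1 at 7.0 cM); Sved Ne=49+/-1.3 (4.6 cM)
r2_v: Hill-Weir Ne=243+/-8.3 (r2=0.1 at 0.8 cM); Sved Ne=222+/-6.0 (1.0 cM)
```

Coancestry inflates raw r² between unlinked loci; whitening by the
realized kinship removes that inflation, so r²ᵥ is far below r², the
fitted effective population size rises, and the marker spacing needed
to keep E[r²] ≥ 0.1 shrinks — the reasoning that sets the marker
density target for genome-wide association work.

`python examples/03_saturate_consensus_map.py` shows phase repair and
placement ("median placement error: 0.76 cM; gaps > 5 cM: framework 31
-> saturated 13"); the other examples cover SNP calling, the
depth/sample-size experiments and the two identity diagnostics.

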