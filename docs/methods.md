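# Methods

This note documents the models behind each module, the defaults and
why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical choices a maintainer would want to know.

## Genotype representation

Calls are integers on a pandas DataFrame (lines × loci): 0 = hom-A,
1 = het, 2 = hom-B, −1 = missing; A/B are parental-phase alleles after
phasing and arbitrary-but-fixed tag order before it. On disk the
characters A/H/B/N are used. Map positions are continuous cM, bins are
half-open [lo, hi), tag offsets 0-based.

## Synthetic data (`simulate`)

**Meiosis.** A no-interference (Haldane) crossover process per
chromosome per meiosis: between adjacent loci d cM apart a gamete
recombines with probability r = (1 − e^(−2d/100))/2. Kosambi is used
only for reporting distances, so a crossover model without
interference keeps the simulator simple and matches standard RIL
simulators. RIL populations descend from an F1 (parent 1 fixed A,
parent 2 fixed B) by k−1 rounds of selfing; residual heterozygosity at
F_k is (1/2)^(k−1) in expectation, which the calibration tests verify
at F4 (12.5%) and F5 (6.25%). Outcrossing replaces the second selfing
gamete with one from a random other line at rate `outcross_rate`
(default 0.005 — the study treats outcrossing only as a small
heterozygosity inflator and states no rate, so a typical small-cereal
value is used).

**Diversity panel.** Founders are inbred mosaics of a 24-haplotype
ancestral pool (switch probability per interval from 10 historical
meioses), so nearby loci carry ancestral LD that decays with map
distance — without this, every r² in the panel would be explained by
recent kinship and the corrected estimators would degenerate to zero.
Consecutive families share one founder, giving a coancestry gradient
rather than discrete clusters, mirroring breeding germplasm; members
are family-cross offspring selfed to F5. Truth kinship is recorded
blockwise (0.5 within family, 0.25 for founder-sharing families, 0
otherwise) next to the realized matrix.

**Reads.** Total reads per line and locus are Poisson with mean
`BASE_DEPTH · depth_index · a_l`, BASE_DEPTH = 1 read per lane-share,
with per-locus relative abundance a_l ~ Gamma(mean 1,
CV = `tag_abundance_cv`, default 1, i.e. exponential). GBS coverage is
deep in the unsaturated regime and restriction fragments amplify very
unevenly; the abundance spread is what makes SNP yield climb with
depth at every completeness threshold instead of saturating. Setting
the CV to 0 gives uniform coverage (used by exactness tests).
Heterozygotes split reads binomially; each read flips to the partner
tag with probability `seq_error_rate` (default 0.002). A negative
binomial overdispersion hook is deliberately left out — Poisson plus
abundance mixing already gives marginal overdispersion.

**Seeding.** One integer seed; every simulator draws from an
independent `SeedSequence` spawn (map = key 0, RIL populations = their
`stream` argument, panel = 2, reads = 3 or the caller's stream), so
identical seeds give bitwise-identical outputs and adding one stage
never perturbs another.

## Tag-level SNP calling (`tags`)

The mismatch relation over tags (≤ `max_mismatch`, default 1) is a
graph; only connected components of exactly two tags become
candidates, a deliberate simplification of full network-topology
pruning: larger families are discarded wholesale as putative repeats
or homoeologue collapses. Tags need ≥10 reads in total.

The population filter's 2×2 table counts lines with tag 1 only, tag 2
only, both, or neither; lines with no reads at either tag sit in
"neither" by default (`drop_double_absent` excludes them — whether
uncovered lines belong in the table is genuinely ambiguous, so both
are offered). The test is two-sided Fisher (sum of all tables with
probability ≤ observed); allelic tags produce extreme *negative*
association, detected either way, and two-sided is the conservative
default. A margin of zero returns p = 1 (independence can never be
rejected).

Genotype calls: missing at 0 reads; heterozygous only when both tags
are seen and the minor-read fraction strictly exceeds the 2% error
tolerance; the boundary case (exactly 2%) is homozygous for the
majority tag.

Catalog merging canonicalises context on the lexicographically smaller
strand (alleles complemented when the reverse complement wins — strand
is unknowable without a reference) and keeps the earlier-assigned name;
names are a zero-padded sequential index with a fixed prefix, so merges
are idempotent and the cumulative index is stable across assays.

## Filtering and experiments (`filtering`)

Thresholds are inclusive, matching the ≥/≤ phrasing of the filter
definitions. MAF counts a heterozygote as one copy of each allele
(standard diploid counting). The depth experiment re-simulates reads
at each depth level and counts loci passing each completeness level
with MAF and heterozygosity held fixed; the sample-size experiment
subsamples lines without replacement with a documented seed schedule
(two replicates by default). SNP counts are non-increasing in the
completeness threshold by construction and rise with depth because of
the coverage model above.

## Linkage mapping (`linkage`)

rf is a simple recombination count over lines homozygous at both loci.
Heterozygous lines are excluded: in near-inbred RILs they are rare and
their gametic phase is unknown. No RIL-generation correction is
applied to rf by default (raw counts are what the placement
interpolation consumes, and the inflation largely cancels in the
rf₁/(rf₁+rf₂) ratio); `kosambi_cm`/`kosambi_inverse` are exposed for
reporting.

Phase correction counts, per locus, linked loci with r < 0.20
(in-phase) versus r > 0.80 (out-of-phase), flips the locus when out >
in, recomputes its rf row as 1 − r, and iterates (≤10 rounds); a locus
still conflicted after one flip is eliminated. Ties — including the
0 = 0 of an unlinked locus — keep the locus unchanged: flipping on no
evidence is unjustified. Loci carrying a both-phase twin (emitted when
parents were missing or monomorphic) are eliminated rather than
flipped, since their complement is already present; exactly one twin
survives.

Placement: for each candidate the per-anchor rf is the minimum over
populations (ties broken by locus name); the closest anchor f₁ fixes
the linkage group and the next-closest anchor on that group is f₂. If
f₁ is interior, or rf(c,f₂) ≤ rf(f₁,f₂), the position interpolates
proportionally to the two rf values and therefore always lies between
the anchors. If f₁ is terminal and the candidate is farther from f₂
than the anchors are from each other, it is placed distal at 1 cM per
1% rf beyond the end (the small-distance equivalence of all map
functions; positions before the first anchor are negative).
rf(f₁,f₂) falls back to the inverse Kosambi of the anchors' map
separation when the anchors were never co-genotyped. Candidates with
no anchor rf < 0.5 are reported unplaced.

De novo mapping: linkage groups are connected components of the
r < 0.25 graph; loci > 15 cM (Kosambi) from everything and groups of
< 3 loci are dropped as unlinked. Within a group the order is a greedy
minimum-spanning-path heuristic (DFS from one end of the MST
diameter) — a documented stand-in for a full ordering algorithm, good
enough to recover co-linearity on well-sampled simulations — and
adjacent distances are Kosambi distances of the rf re-estimated for
the final order.

## Structure (`structure`)

Kinship follows VanRaden: dosage coded {−1,0,1}, columns centred by
2(p−0.5), K = WWᵀ/(2Σp(1−p)); missing values are mean-imputed per
locus (the panels this is used on are filtered at ≥90% completeness,
so imputation touches little), monomorphic loci are excluded. PCA
standardizes markers by √(p(1−p)) by default (a flag disables it) and
uses an SVD; the first four components, each rescaled to [0,1], serve
as structure covariates. The ldregress pre-step regresses each marker
on up to k preceding markers within `ldlimit` map distance
(interpreted in Morgans, 0.001 M = 0.1 cM, following the smartpca
convention), falling back to the pseudoinverse when singular.
Model-based cluster-number selection is out of scope; PC coordinates
are exported for external clustering.

## LD decay (`lddecay`)

The corrected estimators follow the LDcorSV family: r²ₛ uses OLS
residuals on [1, S]; r²ᵥ whitens by K^(−1/2) (eigendecomposition,
eigenvalue floor 10⁻⁸; ridge 10⁻⁶ if K is not positive definite)
around the GLS mean; r²ₛᵥ whitens GLS residuals on [1, S]. Corrected
correlations are uncentred after the transform (the GLS fit already
removes the mean), which reduces exactly to plain r² when K = I and
S is empty. A practical caveat verified in testing: the whitening is
only meaningful when markers comfortably outnumber lines — otherwise
the realized K is rank-deficient and the transform amplifies its null
space.

Pair distances are averaged and minimised over the population maps in
which both loci share a linkage group; pairs never co-mapped are
excluded, as are pairs beyond 30 cM (inclusive cap) and pairs with
undefined r². Fits are unweighted nonlinear least squares in Nₑ with
C = 4·Nₑ·c for both models; the Hill–Weir sample size n is the number
of inbred lines in the panel (340 for the oat panel — this choice
round-trips the published distance/Nₑ pairs, whereas counting
chromosomes does not). The distance at E[r²] = 0.1 is closed-form for
Sved (c = 9/(4Nₑ)) and a Brent root-solve in C for Hill–Weir. Note the
adjusted Hill–Weir expectation decays to the 1/n sampling floor, not
zero. At very small Nₑ the printed Nₑ's rounding dominates the
distance round-trip (e.g. Nₑ printed 17 vs unrounded ≈16.5), so
such rows are not used for exact checks.

## Diagnostics (`diagnostics`)

d uses pairwise-complete loci only (L varies per pair; pairs with
L = 0 are NaN, never guessed). mₗ = 2 − |dosage difference|, so
het-vs-het identical calls match fully. UPGMA is size-weighted average
linkage (delegated to scipy's linkage with lines pre-sorted by label
for reproducible tie order); heights are reported on the ultrametric
convention (half the merged-cluster dissimilarity) and exported to
Newick with branch lengths as height differences. `verify_cross`
counts het-vs-hom as variable — F2s are diagnosed chiefly by
segregating heterozygosity — and calls "selfed" when overall call
discordance stays within the 1% scoring-error tolerance.

## I/O (`gbsio`)

All interchange is plain text (TSV/CSV, minimal VCF 4.2 write-only on
a placeholder contig, Newick, HTML placement report). Parsers reject
malformed rows naming the offending line/locus; writers are
deterministic. The demultiplexer is a desk-scale reference
implementation: exact barcode match followed by the PstI cut-site
remnant TGCAG (inferred from the enzyme's CTGCA^G cut), reads with any
'N' rejected, barcodes within a lane required to be prefix-free. The
package's interface is its importable API plus the `examples/`
scripts; no shell CLI is provided because every workflow here is a few
lines of Python over in-memory tables.

## Problem sizes in tests

Calibration tests use 10⁵ line-locus draws (heterozygosity), 10⁵ null
tag pairs (type-I control), an exhaustive sweep of all 2×2 tables with
N ≤ 30 against an integer-arithmetic enumeration oracle, 100-marker ×
100-line × 3-seed phase-recovery simulations, ~500 placed candidates
over five linkage groups from two 100-line populations, and 2000-pair
decay fits at Nₑ ∈ {20, 100} with Gaussian noise (sd 0.05) over three
seeds. These sizes keep every Monte-Carlo tolerance a small multiple
of its standard error.

## Known limitations

The simulator does not model hexaploid homoeologue confounding beyond
what the tag-family filter discards, nor coalescent ancestry (the
ancestral-pool mosaic is a phenomenological stand-in with the right
LD-decay shape), nor per-sample depth heterogeneity within a lane
(supported by re-running `simulate_tag_reads` per sample group).
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated models, not robustness to homoeologous
mis-pairing or library-preparation artefacts in real data. Imputation,
haplotype-phase-aware D/D′, bootstrap support values and full
consensus-map re-estimation are out of scope.
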