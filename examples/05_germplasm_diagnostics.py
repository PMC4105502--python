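"""Germplasm identity: matching unknown samples and verifying a cross.

Case 1 — a planting mix-up: unknown plots are matched back to named
varieties by allele-matching dissimilarity and UPGMA clustering.
Case 2 — a suspect F2: progeny uniformity against the intended parent
distinguishes selfed seed from a true segregating cross.
"""

import numpy as np
import pandas as pd

import gbskit as gk

rng = np.random.default_rng(5)
L = 800

# five named varieties plus two unknowns that are mislabelled copies
varieties = (rng.random((5, L)) < 0.5).astype(np.int8) * 2
unknown0 = varieties[1].copy()
unknown1 = varieties[3].copy()
for u in (unknown0, unknown1):  # ~1% scoring errors
    flip = rng.random(L) < 0.01
    u[flip] = 2 - u[flip]
calls = pd.DataFrame(
    np.vstack([varieties, unknown0, unknown1]),
    index=[f"var{i}" for i in range(5)] + ["unknown0", "unknown1"],
    columns=[f"m{j}" for j in range(L)],
)
G = gk.GenotypeMatrix(calls)
D = gk.allele_match_dissimilarity(G)
report = gk.match_unknowns(D, [f"var{i}" for i in range(5)],
                           ["unknown0", "unknown1"], max_d=0.05)
print("unknown-sample pairing (d = allele-matching dissimilarity):")
print(report.to_string(index=False))
print("UPGMA tree:", gk.upgma(D).to_newick()[:80], "...")

# suspect F2: progeny identical to the male parent up to scoring error
parent = calls.iloc[0]
progeny = pd.DataFrame(
    np.repeat(parent.to_numpy()[None, :], 6, axis=0),
    index=[f"f2_{i}" for i in range(6)], columns=calls.columns)
noise = rng.random(progeny.shape) < 0.004
progeny = progeny.mask(noise, 2 - progeny)
verdict, frac = gk.verify_cross(
    gk.GenotypeMatrix(progeny.astype(np.int8)), parent, error_tolerance=0.01)
print(f"\nsuspect cross verdict: {verdict} "
      f"(fraction of loci variable among progeny: {frac:.3f})")
# A true F2 would segregate at every locus where the parents differed
# (~50% het plus both homozygote classes); variation within the 1%
# scoring-error tolerance instead indicates selfed seed of the parent.
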