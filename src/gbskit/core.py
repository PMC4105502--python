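"""Core data containers shared across the toolkit.

Genotype calls are stored as small integers on a pandas DataFrame
(lines as rows, loci as columns):

==========  =====  ========================================
constant    code   meaning
==========  =====  ========================================
``HOM_A``   0      homozygous for the A (parent-1) allele
``HET``     1      heterozygous
``HOM_B``   2      homozygous for the B (parent-2) allele
``MISSING`` -1     no call
==========  =====  ========================================

On disk the same calls are written as the characters A/H/B/N.
Genetic maps are tables of (locus, linkage_group, position in cM,
status), where status distinguishes fixed framework anchors from loci
placed by recombination-fraction interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

HOM_A: int = 0
HET: int = 1
HOM_B: int = 2
MISSING: int = -1

CODE_TO_CHAR: Mapping[int, str] = {HOM_A: "A", HET: "H", HOM_B: "B", MISSING: "N"}
CHAR_TO_CODE: Mapping[str, int] = {v: k for k, v in CODE_TO_CHAR.items()}

FRAMEWORK = "framework"
PLACED = "placed"


class GBSError(Exception):
    """Base error for the toolkit."""


class ConfigurationError(GBSError):
    """Invalid configuration or parameters."""


class FormatError(GBSError):
    """Malformed input data or file."""


class GenotypeMatrix:
    """Lines x loci genotype calls.

    Parameters
    ----------
    calls
        DataFrame of integer codes (HOM_A/HET/HOM_B/MISSING); the index
        holds line names and the columns locus names.
    """

    def __init__(self, calls: pd.DataFrame):
        arr = calls.to_numpy()
        bad = ~np.isin(arr, (HOM_A, HET, HOM_B, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"invalid genotype code {arr[i, j]!r} at line "
                f"{calls.index[i]!r}, locus {calls.columns[j]!r}"
            )
        self.calls = calls.astype(np.int8)

    # -- basic introspection -------------------------------------------------
    @property
    def lines(self) -> pd.Index:
        return self.calls.index

    @property
    def loci(self) -> pd.Index:
        return self.calls.columns

    @property
    def n_lines(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GenotypeMatrix({self.n_lines} lines x {self.n_loci} loci)"

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GenotypeMatrix) and self.calls.equals(other.calls)

    # -- views ---------------------------------------------------------------
    def dosage(self) -> pd.DataFrame:
        """B-allele dosage in {0, 1, 2} with missing as NaN."""
        d = self.calls.astype(float)
        return d.mask(self.calls.to_numpy() == MISSING)

    def subset(
        self,
        lines: Sequence | None = None,
        loci: Sequence | None = None,
    ) -> "GenotypeMatrix":
        calls = self.calls
        if lines is not None:
            calls = calls.loc[list(lines)]
        if loci is not None:
            calls = calls[list(loci)]
        return GenotypeMatrix(calls.copy())

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.calls.copy())

    @classmethod
    def from_chars(cls, chars: pd.DataFrame) -> "GenotypeMatrix":
        """Build from a DataFrame of A/H/B/N characters."""
        try:
            codes = chars.map(lambda c: CHAR_TO_CODE[c])
        except KeyError as exc:  # pragma: no cover - defensive
            raise FormatError(f"invalid genotype character {exc.args[0]!r}") from exc
        return cls(codes)

    def to_chars(self) -> pd.DataFrame:
        return self.calls.map(lambda c: CODE_TO_CHAR[int(c)])


MAP_COLUMNS = ["locus", "linkage_group", "position_cm", "status"]


@dataclass
class GeneticMap:
    """A genetic map: loci with linkage-group assignment and cM position.

    ``table`` has at least the columns in :data:`MAP_COLUMNS`; placement
    provenance columns (anchor1, rf1, anchor2, rf2, source_population)
    are present for placed loci when known.  Framework loci are strictly
    ordered within each linkage group; placed loci may carry negative
    positions when they fall distal to the first framework anchor.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MAP_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"genetic map missing columns: {missing}")
        if not np.isfinite(self.table["position_cm"].to_numpy(float)).all():
            raise FormatError("non-finite map position")
        self.table = self.table.reset_index(drop=True)

    @property
    def linkage_groups(self) -> list:
        return sorted(self.table["linkage_group"].unique())

    @property
    def loci(self) -> pd.Index:
        return pd.Index(self.table["locus"])

    def group(self, lg) -> pd.DataFrame:
        sub = self.table[self.table["linkage_group"] == lg]
        return sub.sort_values("position_cm").reset_index(drop=True)

    def positions(self) -> pd.Series:
        """Series of cM positions indexed by locus name."""
        return self.table.set_index("locus")["position_cm"]

    def framework(self) -> "GeneticMap":
        return GeneticMap(
            self.table[self.table["status"] == FRAMEWORK].reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class SnpCall:
    """A called SNP with its tag context.

    ``context`` uses bracket notation, e.g. ``"ACGT[A/C]TT..."`` with the
    variant site spelled inside the brackets; ``alleles`` is the tuple of
    observed bases; ``p_value`` is the population-association probability
    (NaN when the pairwise route produced the call without a test).
    """

    name: str
    context: str
    alleles: tuple
    p_value: float = float("nan")
    source_pipeline: str = "pairwise"


@dataclass
class TagCatalog:
    """Sequence tags with per-line read counts and allelic pairings.

    ``tags`` are unique fixed-length DNA strings; ``counts`` is a lines x
    tags DataFrame of non-negative integer read counts; ``pairs`` lists
    ``(tag_i, tag_j, snp_offset, allele_i, allele_j)`` for tag pairs that
    differ at exactly the recorded offset(s).
    """

    tags: list
    counts: pd.DataFrame
    pairs: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.tags)) != len(self.tags):
            raise FormatError("tags must be unique")
        lengths = {len(t) for t in self.tags}
        if len(lengths) > 1:
            raise FormatError(f"tags have mixed lengths: {sorted(lengths)}")
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("negative read count")

    @property
    def tag_length(self) -> int:
        return len(self.tags[0]) if self.tags else 0
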