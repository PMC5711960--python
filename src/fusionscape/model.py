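"""Core data model for the fusion-landscape pipeline.

The pipeline works at three levels:

* :class:`FusionCall` — one caller's report of one candidate fusion in one
  sample, after normalisation to a common schema.
* :class:`ConsensusFusion` — a fusion reported by both callers for the same
  sample with the same ordered gene pair, carrying filter flags, the
  breakpoint-flank homology E-score and classification flags.
* :class:`CohortTable` — all consensus fusions across a cohort together with
  per-sample metadata.

Ordered gene pairs are identity: (A, B) and (B, A) are two different fusions,
because the 5'/3' orientation of the chimeric transcript is part of the event.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "Caller",
    "IgClass",
    "FusionCall",
    "GeneRecord",
    "GeneAnnotation",
    "GeneFamilyTable",
    "SampleMeta",
    "ConsensusFusion",
    "CohortTable",
    "FormatError",
    "ConsistencyError",
    "DataError",
    "ig_class_for_symbol",
]


class FormatError(ValueError):
    """An input file does not match the declared dialect or format."""


class ConsistencyError(ValueError):
    """Inputs are individually valid but mutually inconsistent."""


class DataError(ValueError):
    """A value violates a data invariant (e.g. negative read count)."""


class Caller(str, enum.Enum):
    """Provenance of a fusion call.

    ``A`` is the TopHat-style caller whose breakpoint predictions are kept
    for downstream homology scoring; ``B`` is the MapSplice-style caller.
    """

    A = "callerA"
    B = "callerB"


class IgClass(str, enum.Enum):
    IGH = "IGH"
    IGK = "IGK"
    IGL = "IGL"
    NONE = "none"


# Immunoglobulin locus symbols follow the HGNC pattern locus prefix plus a
# segment / constant-region designator (IGHM, IGHG1, IGKC, IGKV3-20, ...).
# Non-locus genes that merely start with the prefix (IGHMBP2, IGLL1, IGLON5)
# must not be classified as Ig; the designator whitelist plus an explicit
# exclusion list keeps the rule auditable.
_IG_PATTERN = re.compile(r"^(IGH[ADEGMJV]|IGK[CJV]|IGL[CJV])")
DEFAULT_IG_EXCLUSIONS = frozenset({"IGHMBP2", "IGJ"})


def ig_class_for_symbol(symbol: str, exclusions: frozenset[str] = DEFAULT_IG_EXCLUSIONS) -> IgClass:
    """Classify a gene symbol into an immunoglobulin locus (or ``NONE``)."""
    if symbol in exclusions:
        return IgClass.NONE
    m = _IG_PATTERN.match(symbol)
    if m is None:
        return IgClass.NONE
    return IgClass(m.group(1)[:3])


@dataclass
class FusionCall:
    """One caller's candidate fusion in one sample (normalised schema).

    ``bp5`` is the genomic position (1-based) of the last transcribed base of
    the 5' segment; ``bp3`` the first base of the 3' segment.
    ``junction_pairs`` is the number of read pairs with one end covering the
    junction (for the MapSplice-style caller this is the sum of the multiple-
    and unique-mapped paired read counts).
    """

    sample_id: str
    caller: Caller
    gene5: str
    gene3: str
    chrom5: str
    chrom3: str
    bp5: int
    bp3: int
    strand5: str
    strand3: str
    junction_pairs: int

    def __post_init__(self) -> None:
        if not self.gene5 or not self.gene3:
            raise DataError("fusion partners must have non-empty gene symbols")
        if self.junction_pairs < 0:
            raise DataError(
                f"negative junction_pairs ({self.junction_pairs}) for "
                f"{self.gene5}-{self.gene3} in {self.sample_id}"
            )

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene5, self.gene3)


@dataclass(frozen=True)
class GeneRecord:
    symbol: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    ig_class: IgClass = IgClass.NONE

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DataError(f"gene {self.symbol}: start {self.start} > end {self.end}")

    @property
    def is_ig(self) -> bool:
        return self.ig_class is not IgClass.NONE


class GeneAnnotation:
    """Gene records plus chromosome lengths, with alias-aware lookup."""

    def __init__(
        self,
        genes: Iterable[GeneRecord],
        chrom_lengths: Mapping[str, int] | None = None,
        aliases: Mapping[str, str] | None = None,
    ) -> None:
        self.genes: dict[str, GeneRecord] = {}
        for g in genes:
            prev = self.genes.get(g.symbol)
            if prev is not None:
                # duplicated symbol: keep the widest span
                g = replace(
                    g,
                    start=min(g.start, prev.start),
                    end=max(g.end, prev.end),
                )
            self.genes[g.symbol] = g
        self.aliases = dict(aliases or {})
        if chrom_lengths is None:
            chrom_lengths = {}
            for g in self.genes.values():
                chrom_lengths[g.chrom] = max(chrom_lengths.get(g.chrom, 0), g.end)
        self.chrom_lengths = dict(chrom_lengths)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return self.resolve(symbol) is not None

    def resolve(self, symbol: str) -> GeneRecord | None:
        """Look a symbol up, following the alias table if needed."""
        rec = self.genes.get(symbol)
        if rec is None and symbol in self.aliases:
            rec = self.genes.get(self.aliases[symbol])
        return rec

    @property
    def uses_chr_prefix(self) -> bool:
        return any(c.startswith("chr") for c in self.chrom_lengths)

    def chromosomes(self) -> list[str]:
        return list(self.chrom_lengths)

    def genes_per_chromosome(self) -> pd.Series:
        counts = pd.Series(0, index=list(self.chrom_lengths), dtype=int)
        for g in self.genes.values():
            counts[g.chrom] += 1
        return counts


class GeneFamilyTable:
    """Mapping of gene symbol to the set of its HGNC-style family ids.

    Symbols absent from the table map to the empty set, so two genes with no
    family annotation never count as same-family.
    """

    def __init__(self, mapping: Mapping[str, Iterable[object]] | None = None) -> None:
        self._map: dict[str, frozenset] = {
            sym: frozenset(fams) for sym, fams in (mapping or {}).items()
        }

    def families(self, symbol: str) -> frozenset:
        return self._map.get(symbol, frozenset())

    def shared(self, sym1: str, sym2: str) -> frozenset:
        return self.families(sym1) & self.families(sym2)

    def add(self, symbol: str, family: object) -> None:
        self._map[symbol] = self.families(symbol) | {family}

    def __len__(self) -> int:
        return len(self._map)

    def items(self):
        return self._map.items()


_POPULATIONS = ("patient", "cell_line")


@dataclass
class SampleMeta:
    sample_id: str
    population: str
    light_chain: str = "unknown"  # kappa / lambda / unknown
    ploidy_group: str = "unknown"  # high_hyperdiploid / other / unknown
    fish_translocation: bool | None = None
    age: float | None = None

    def __post_init__(self) -> None:
        if self.population not in _POPULATIONS:
            raise DataError(
                f"population must be one of {_POPULATIONS}, got {self.population!r}"
            )


@dataclass
class ConsensusFusion:
    """A caller-intersected fusion event.

    Coordinates and strands come from caller A's prediction (the TopHat-style
    caller), which is also what the homology module aligns flanks around.
    Filter flags record, rather than delete: fusions failing a filter stay in
    the table with ``passed_* = False`` so the homology score can still be
    reported for them.
    """

    sample_id: str
    gene5: str
    gene3: str
    chrom5: str
    bp5: int
    chrom3: str
    bp3: int
    strand5: str
    strand3: str
    junction_pairs_a: int
    junction_pairs_b: int
    passed_support_filter: bool = True
    passed_family_filter: bool = True
    homology_escore: float | None = None
    is_ig: bool = False
    ig_class: IgClass = IgClass.NONE
    is_recurrent: bool = False
    is_same_chr_lt10mb: bool = False
    unresolved: bool = False  # a partner symbol missing from the annotation

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene5, self.gene3)

    @property
    def passed_all(self) -> bool:
        return self.passed_support_filter and self.passed_family_filter


#: Stable column order of the normalised fusion table (TSV on disk).
FUSION_TABLE_COLUMNS = [
    "sample_id",
    "gene5",
    "gene3",
    "chrom5",
    "bp5",
    "chrom3",
    "bp3",
    "strand5",
    "strand3",
    "junction_pairs_a",
    "junction_pairs_b",
    "passed_support_filter",
    "passed_family_filter",
    "homology_escore",
    "is_ig",
    "ig_class",
    "is_recurrent",
    "is_same_chr_lt10mb",
    "unresolved",
]


def consensus_to_frame(fusions: Iterable[ConsensusFusion]) -> pd.DataFrame:
    rows = []
    for f in fusions:
        rows.append(
            {
                **{c: getattr(f, c) for c in FUSION_TABLE_COLUMNS if c != "ig_class"},
                "ig_class": f.ig_class.value,
            }
        )
    df = pd.DataFrame(rows, columns=FUSION_TABLE_COLUMNS)
    return df


def frame_to_consensus(df: pd.DataFrame) -> list[ConsensusFusion]:
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        d["ig_class"] = IgClass(d["ig_class"])
        d["homology_escore"] = (
            None if pd.isna(d["homology_escore"]) else float(d["homology_escore"])
        )
        out.append(ConsensusFusion(**d))
    return out


class CohortTable:
    """All consensus fusions across a cohort plus sample metadata.

    ``fusions`` keeps every intersected event including ones that failed a
    filter (flagged, not deleted). ``retained()`` gives the analysis set.
    """

    def __init__(
        self,
        fusions: Iterable[ConsensusFusion],
        meta: Mapping[str, SampleMeta],
    ) -> None:
        self.fusions: list[ConsensusFusion] = list(fusions)
        self.meta: dict[str, SampleMeta] = dict(meta)
        for f in self.fusions:
            if f.sample_id not in self.meta:
                raise ConsistencyError(
                    f"fusion sample {f.sample_id!r} absent from sample metadata"
                )

    def retained(self, population: str | None = None) -> list[ConsensusFusion]:
        out = [f for f in self.fusions if f.passed_all]
        if population is not None:
            out = [f for f in out if self.meta[f.sample_id].population == population]
        return out

    def samples(self, population: str | None = None) -> list[str]:
        ids = list(self.meta)
        if population is not None:
            ids = [s for s in ids if self.meta[s].population == population]
        return ids

    def to_frame(self) -> pd.DataFrame:
        return consensus_to_frame(self.fusions)

    def meta_frame(self) -> pd.DataFrame:
        rows = [vars(m).copy() for m in self.meta.values()]
        return pd.DataFrame(rows).set_index("sample_id")

    def __len__(self) -> int:
        return len(self.fusions)
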