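"""Readers and writers for the pipeline's external formats.

Two fusion-caller report dialects are built in:

* ``tophat`` — one fusion per row with separate gene / chromosome / position
  columns for each partner and a single junction-spanning mate-pair count
  (0-based coordinates, ``chr``-prefixed chromosome names).
* ``mapsplice`` — combined ``chrom`` (``"1~2"``) and ``strand`` (``"+-"``)
  columns, donor/acceptor coordinates (1-based, no ``chr`` prefix) and two
  read-count columns whose sum is the junction-pair support.

Both are normalised to :class:`~fusionscape.model.FusionCall` with 1-based
coordinates and the annotation's chromosome naming.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .model import (
    Caller,
    ConsensusFusion,
    FormatError,
    FusionCall,
    FUSION_TABLE_COLUMNS,
    GeneAnnotation,
    GeneFamilyTable,
    GeneRecord,
    IgClass,
    SampleMeta,
    consensus_to_frame,
    frame_to_consensus,
    ig_class_for_symbol,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ReportDialect",
    "TOPHAT_DIALECT",
    "MAPSPLICE_DIALECT",
    "dialect_for",
    "read_caller_report",
    "collapse_calls",
    "read_gene_annotation",
    "read_gene_families",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_expression",
    "write_fusion_table",
    "read_fusion_table",
    "normalize_chrom",
]


@dataclass(frozen=True)
class ReportDialect:
    """Column mapping from one caller's report format to the common schema.

    ``junction_cols`` lists the source read-count columns; their sum becomes
    ``junction_pairs``. ``chrom_pair_col``/``strand_pair_col`` handle dialects
    that pack both partners into one column (``"chr1~chr2"``, ``"+-"``).
    ``coord_base`` declares the source coordinate convention (0 or 1); the
    reader converts to 1-based.
    """

    name: str
    gene5_col: str
    gene3_col: str
    bp5_col: str
    bp3_col: str
    junction_cols: tuple[str, ...]
    chrom5_col: str | None = None
    chrom3_col: str | None = None
    chrom_pair_col: str | None = None
    chrom_pair_sep: str = "~"
    strand5_col: str | None = None
    strand3_col: str | None = None
    strand_pair_col: str | None = None
    coord_base: int = 1
    chrom_style: str = "chr"  # "chr" or "plain": naming used in the file

    def required_columns(self) -> list[str]:
        cols = [self.gene5_col, self.gene3_col, self.bp5_col, self.bp3_col]
        cols += list(self.junction_cols)
        if self.chrom_pair_col:
            cols.append(self.chrom_pair_col)
        else:
            cols += [self.chrom5_col, self.chrom3_col]
        if self.strand_pair_col:
            cols.append(self.strand_pair_col)
        else:
            cols += [self.strand5_col, self.strand3_col]
        return [c for c in cols if c]


TOPHAT_DIALECT = ReportDialect(
    name="tophat",
    gene5_col="gene_left",
    gene3_col="gene_right",
    chrom5_col="chr_left",
    chrom3_col="chr_right",
    bp5_col="pos_left",
    bp3_col="pos_right",
    strand5_col="strand_left",
    strand3_col="strand_right",
    junction_cols=("spanning_mate_pairs",),
    coord_base=0,
    chrom_style="chr",
)

MAPSPLICE_DIALECT = ReportDialect(
    name="mapsplice",
    gene5_col="annotated_gene_donor",
    gene3_col="annotated_gene_acceptor",
    chrom_pair_col="chrom",
    bp5_col="doner_end",
    bp3_col="acceptor_start",
    strand_pair_col="strand",
    junction_cols=("multiple_paired_read_count", "unique_paired_read_count"),
    coord_base=1,
    chrom_style="plain",
)

_BUILTIN_DIALECTS = {Caller.A: TOPHAT_DIALECT, Caller.B: MAPSPLICE_DIALECT}


def dialect_for(caller: Caller) -> ReportDialect:
    return _BUILTIN_DIALECTS[caller]


def normalize_chrom(chrom: str, use_chr_prefix: bool) -> str:
    """Strip or add the ``chr`` prefix to match the annotation's namespace."""
    chrom = str(chrom)
    has = chrom.startswith("chr")
    if use_chr_prefix and not has:
        return "chr" + chrom
    if not use_chr_prefix and has:
        return chrom[3:]
    return chrom


def _bad_symbol(sym: object) -> bool:
    if sym is None or (isinstance(sym, float) and pd.isna(sym)):
        return True
    s = str(sym).strip()
    return s in ("", "-", ".", "nan", "NA")


def collapse_calls(calls: Iterable[FusionCall]) -> list[FusionCall]:
    """Collapse multiple rows for the same (sample, ordered gene pair).

    Callers may report the same gene pair several times with different
    breakpoints; the consensus rule is defined at gene-pair level, so only the
    row with the maximum junction-pair support is kept (its breakpoints come
    with it). Order of first appearance is preserved.
    """
    best: dict[tuple[str, str, str], FusionCall] = {}
    order: list[tuple[str, str, str]] = []
    for c in calls:
        key = (c.sample_id, c.gene5, c.gene3)
        if key not in best:
            best[key] = c
            order.append(key)
        elif c.junction_pairs > best[key].junction_pairs:
            best[key] = c
    return [best[k] for k in order]


def read_caller_report(
    path: str | Path,
    caller: Caller,
    sample_id: str,
    dialect: ReportDialect | None = None,
    use_chr_prefix: bool = True,
    collapse: bool = True,
) -> list[FusionCall]:
    """Read one caller's fusion report for one sample.

    Rows whose gene symbols are unparseable are dropped (a count is logged);
    an empty or header-only file yields an empty list. A mandatory column
    missing from the header raises :class:`FormatError` naming the column.
    """
    if dialect is None:
        dialect = dialect_for(caller)
    path = Path(path)
    if path.stat().st_size == 0:
        return []
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty and len(df.columns) <= 1:
        return []
    for col in dialect.required_columns():
        if col not in df.columns:
            raise FormatError(
                f"{path}: required column {col!r} missing for dialect "
                f"{dialect.name!r}"
            )
    calls: list[FusionCall] = []
    n_dropped = 0
    shift = 1 - dialect.coord_base
    for row in df.itertuples(index=False):
        rec = row._asdict()
        g5, g3 = rec[dialect.gene5_col], rec[dialect.gene3_col]
        if _bad_symbol(g5) or _bad_symbol(g3):
            n_dropped += 1
            continue
        if dialect.chrom_pair_col:
            c5, c3 = str(rec[dialect.chrom_pair_col]).split(dialect.chrom_pair_sep, 1)
        else:
            c5, c3 = rec[dialect.chrom5_col], rec[dialect.chrom3_col]
        if dialect.strand_pair_col:
            s = str(rec[dialect.strand_pair_col])
            s5, s3 = s[0], s[1]
        else:
            s5, s3 = rec[dialect.strand5_col], rec[dialect.strand3_col]
        junction = sum(int(rec[c]) for c in dialect.junction_cols)
        calls.append(
            FusionCall(
                sample_id=sample_id,
                caller=caller,
                gene5=str(g5).strip(),
                gene3=str(g3).strip(),
                chrom5=normalize_chrom(c5, use_chr_prefix),
                chrom3=normalize_chrom(c3, use_chr_prefix),
                bp5=int(rec[dialect.bp5_col]) + shift,
                bp3=int(rec[dialect.bp3_col]) + shift,
                strand5=str(s5),
                strand3=str(s3),
                junction_pairs=junction,
            )
        )
    if n_dropped:
        logger.warning(
            "%s: dropped %d rows with unparseable gene symbols", path, n_dropped
        )
    return collapse_calls(calls) if collapse else calls


def read_gene_annotation(
    path: str | Path,
    aliases: Mapping[str, str] | None = None,
    ig_exclusions: frozenset[str] | None = None,
) -> GeneAnnotation:
    """Read gene records from a GFF3/GTF file.

    One :class:`GeneRecord` per gene symbol (widest span if duplicated);
    chromosome lengths come from ``##sequence-region`` pragmas when present,
    otherwise from the rightmost gene end per chromosome. ``Alias`` attributes
    feed the annotation's alias table (an explicit ``aliases`` mapping wins).
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    from .model import DEFAULT_IG_EXCLUSIONS

    excl = DEFAULT_IG_EXCLUSIONS if ig_exclusions is None else ig_exclusions
    genes: list[GeneRecord] = []
    alias_map: dict[str, str] = {}
    for feat in db.features_of_type("gene"):
        sym = None
        for key in ("gene_name", "Name", "gene_id", "ID"):
            if key in feat.attributes:
                sym = feat.attributes[key][0]
                break
        if sym is None:
            continue
        genes.append(
            GeneRecord(
                symbol=sym,
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                ig_class=ig_class_for_symbol(sym, excl),
            )
        )
        if "Alias" in feat.attributes:
            for alias in feat.attributes["Alias"]:
                for a in alias.split(","):
                    if a and a != sym:
                        alias_map[a] = sym
    if not genes:
        raise FormatError(f"{path}: no gene features found")
    chrom_lengths: dict[str, int] = {}
    for d in db.directives:
        parts = d.split()
        if parts and parts[0] == "sequence-region" and len(parts) >= 4:
            chrom_lengths[parts[1]] = int(parts[3])
    if aliases:
        alias_map.update(aliases)
    return GeneAnnotation(
        genes, chrom_lengths=chrom_lengths or None, aliases=alias_map
    )


def write_gene_annotation(annotation: GeneAnnotation, path: str | Path) -> None:
    """Write the annotation as GFF3 with ``##sequence-region`` pragmas."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in annotation.chrom_lengths.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        rev_alias: dict[str, list[str]] = {}
        for a, s in annotation.aliases.items():
            rev_alias.setdefault(s, []).append(a)
        for g in annotation.genes.values():
            attrs = f"ID={g.symbol};Name={g.symbol}"
            if g.symbol in rev_alias:
                attrs += ";Alias=" + ",".join(sorted(rev_alias[g.symbol]))
            fh.write(
                f"{g.chrom}\tfusionscape\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


def read_gene_families(
    path: str | Path,
    symbol_col: str = "symbol",
    family_col: str = "family_id",
) -> GeneFamilyTable:
    """Read an HGNC-style gene-family TSV (symbol, family id per row).

    Malformed rows are logged and skipped; a symbol appearing in several rows
    accumulates the union of its family ids.
    """
    table = GeneFamilyTable()
    n_bad = 0
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return table
        for col in (symbol_col, family_col):
            if col not in reader.fieldnames:
                raise FormatError(f"{path}: required column {col!r} missing")
        for row in reader:
            sym = (row.get(symbol_col) or "").strip()
            fam = (row.get(family_col) or "").strip()
            if not sym or not fam:
                n_bad += 1
                continue
            table.add(sym, fam)
    if n_bad:
        logger.warning("%s: skipped %d malformed family rows", path, n_bad)
    return table


def write_gene_families(table: GeneFamilyTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("symbol\tfamily_id\n")
        for sym, fams in sorted(table.items()):
            for fam in sorted(fams):
                fh.write(f"{sym}\t{fam}\n")


_META_COLUMNS = [
    "sample_id",
    "population",
    "light_chain",
    "ploidy_group",
    "fish_translocation",
    "age",
]


def read_sample_metadata(path: str | Path) -> dict[str, SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns or "population" not in df.columns:
        raise FormatError(f"{path}: sample_id and population columns are mandatory")
    meta: dict[str, SampleMeta] = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        fish = d.get("fish_translocation")
        age = d.get("age")
        meta[d["sample_id"]] = SampleMeta(
            sample_id=d["sample_id"],
            population=d["population"],
            light_chain=d.get("light_chain") or "unknown",
            ploidy_group=d.get("ploidy_group") or "unknown",
            fish_translocation=None if pd.isna(fish) else fish == "True",
            age=None if pd.isna(age) else float(age),
        )
    return meta


def write_sample_metadata(meta: Mapping[str, SampleMeta], path: str | Path) -> None:
    rows = []
    for m in meta.values():
        d = vars(m).copy()
        rows.append(d)
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples matrix of log-scaled normalised expression."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(float)


def write_fusion_table(fusions: Iterable[ConsensusFusion], path: str | Path) -> None:
    """Write the normalised fusion table as TSV with a stable column order.

    Round-trips losslessly through :func:`read_fusion_table` (an empty list
    yields a header-only file).
    """
    df = consensus_to_frame(fusions)
    df.to_csv(path, sep="\t", index=False)


def read_fusion_table(path: str | Path) -> list[ConsensusFusion]:
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        return []
    for col in FUSION_TABLE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: required column {col!r} missing")
    for col in (
        "passed_support_filter",
        "passed_family_filter",
        "is_ig",
        "is_recurrent",
        "is_same_chr_lt10mb",
        "unresolved",
    ):
        df[col] = df[col].astype(bool)
    return frame_to_consensus(df[FUSION_TABLE_COLUMNS])
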