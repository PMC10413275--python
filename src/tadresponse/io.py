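"""Readers and writers for the on-disk formats the pipeline consumes.

Input formats
-------------
* TADs and chromatin states: BED3/BED4 (states carry the label in column 4).
* Differential regions: BED6+2 (``chrom start end name score strand
  occ_log2fc occ_fdr``) or a headered TSV with at least the columns
  ``chrom, start, end, region_id, occ_log2fc, occ_fdr``.
* Interactions: BEDPE (``chrom1 start1 end1 chrom2 start2 end2 [name
  [score]]``); the score column, when present, is read as the interaction
  significance.
* Genes: headered TSV (``gene_id, chrom, tss, strand``) or GTF (1-based,
  converted on read; ``gene`` features only).

All writers emit tab-separated, newline-terminated text: headerless BED
dialects and headered TSVs.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .core import (
    ChromatinStateSegment,
    DifferentialRegion,
    Gene,
    GenomicInterval,
    Interaction,
    Tad,
    ValidationError,
    validate_tads,
)

__all__ = [
    "ParseError",
    "STANDARD_CHROM_PATTERN",
    "read_bed",
    "read_bedpe",
    "read_genes",
    "read_expression",
    "read_expression_per_timepoint",
    "read_counts",
    "write_tads",
    "write_states",
    "write_regions",
    "write_bedpe",
    "write_genes",
]

#: Chromosomes retained by default: autosomes and sex chromosomes, with or
#: without the ``chr`` prefix. Scaffolds, alternate haplotypes and
#: mitochondrial contigs are dropped, mirroring standard practice.
STANDARD_CHROM_PATTERN = r"^(chr)?([0-9]+|[XY])$"


class ParseError(ValueError):
    """A malformed line in an input file; the message names the line."""


def _standard(chrom: str, pattern: str) -> bool:
    return re.match(pattern, chrom) is not None


def _bed_fields(path: Path, min_cols: int) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_cols:
                raise ParseError(
                    f"{path}:{lineno}: expected >= {min_cols} tab-separated "
                    f"columns, got {len(fields)}"
                )
            yield lineno, fields


def _interval(path: Path, lineno: int, chrom: str, start: str, end: str) -> GenomicInterval:
    try:
        s, e = int(start), int(end)
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
    try:
        return GenomicInterval(chrom, s, e)
    except ValidationError as exc:
        raise ValidationError(f"{path}:{lineno}: {exc}") from exc


def read_bed(
    path: str | Path,
    kind: str,
    *,
    standard_chroms_only: bool = True,
    chrom_pattern: str = STANDARD_CHROM_PATTERN,
    refilter_fdr: float | None = None,
):
    """Read a BED-dialect file into typed records.

    Parameters
    ----------
    kind
        ``"tad"`` (BED3/4; column 4 is the TAD id, autogenerated when
        absent), ``"region"`` (BED6+2, see module docstring) or
        ``"state"`` (BED4 with an 18-state label in column 4).
    standard_chroms_only
        Drop records on non-standard chromosomes (default on).
    refilter_fdr
        For regions only: re-apply an FDR cutoff on read. The differential
        table is normally already thresholded upstream (FDR < 5% in the
        occupancy analysis), so the default is no refiltering.

    Input order is preserved. TADs are additionally validated for pairwise
    non-overlap per chromosome.
    """
    path = Path(path)
    if kind not in ("tad", "region", "state"):
        raise ValueError(f"unknown kind {kind!r}")
    if kind == "region" and _looks_headered(path):
        return _read_regions_tsv(path, standard_chroms_only, chrom_pattern, refilter_fdr)

    min_cols = {"tad": 3, "state": 4, "region": 8}[kind]
    records: list = []
    for lineno, fields in _bed_fields(path, min_cols):
        chrom = fields[0]
        if standard_chroms_only and not _standard(chrom, chrom_pattern):
            continue
        iv = _interval(path, lineno, chrom, fields[1], fields[2])
        if kind == "tad":
            tad_id = fields[3] if len(fields) > 3 and fields[3] else f"tad_{lineno}"
            records.append(Tad(tad_id, iv))
        elif kind == "state":
            try:
                records.append(ChromatinStateSegment(iv, fields[3]))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
        else:
            try:
                lfc, fdr = float(fields[6]), float(fields[7])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric occ_log2fc/occ_fdr"
                ) from exc
            if refilter_fdr is not None and fdr >= refilter_fdr:
                continue
            try:
                records.append(DifferentialRegion(fields[3], iv, lfc, fdr))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    if kind == "tad":
        validate_tads(records)
    return records


def _looks_headered(path: Path) -> bool:
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                return "chrom" in line.split("\t")
    return False


def _read_regions_tsv(path, standard_only, pattern, refilter_fdr):
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "region_id", "occ_log2fc", "occ_fdr"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: region TSV missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        if standard_only and not _standard(str(row.chrom), pattern):
            continue
        if refilter_fdr is not None and row.occ_fdr >= refilter_fdr:
            continue
        records.append(
            DifferentialRegion(
                str(row.region_id),
                GenomicInterval(str(row.chrom), int(row.start), int(row.end)),
                float(row.occ_log2fc),
                float(row.occ_fdr),
            )
        )
    return records


def read_bedpe(
    path: str | Path,
    *,
    standard_chroms_only: bool = True,
    chrom_pattern: str = STANDARD_CHROM_PATTERN,
) -> list[Interaction]:
    """Read paired anchors from BEDPE; intra- and inter-chromosomal both kept.

    Column 8 (BEDPE score) is read as the interaction significance when
    present and numeric; column 7 is the pair name and is ignored.
    """
    path = Path(path)
    out: list[Interaction] = []
    for lineno, fields in _bed_fields(path, 6):
        c1, c2 = fields[0], fields[3]
        if standard_chroms_only and not (
            _standard(c1, chrom_pattern) and _standard(c2, chrom_pattern)
        ):
            continue
        a1 = _interval(path, lineno, c1, fields[1], fields[2])
        a2 = _interval(path, lineno, c2, fields[4], fields[5])
        sig: float | None = None
        if len(fields) > 7 and fields[7] not in ("", "."):
            try:
                sig = float(fields[7])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
        elif len(fields) == 7 and fields[6] not in ("", "."):
            # 7-column variant: the trailing column is the significance.
            try:
                sig = float(fields[6])
            except ValueError:
                sig = None
        try:
            out.append(Interaction(a1, a2, sig))
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return out


_GTF_GENE_ID = re.compile(r'gene_id "([^"]+)"')


def read_genes(
    path: str | Path,
    *,
    standard_chroms_only: bool = True,
    chrom_pattern: str = STANDARD_CHROM_PATTERN,
) -> list[Gene]:
    """Read genes from a headered TSV or a GTF.

    TSV columns: ``gene_id, chrom, tss, strand`` (tss 0-based). GTF input
    uses ``gene`` features; the TSS is the 1-based ``start`` for ``+``
    strand genes and ``end`` for ``-`` strand genes, converted to 0-based.
    """
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff"):
        genes: list[Gene] = []
        for lineno, fields in _bed_fields(path, 9):
            if fields[2] != "gene":
                continue
            chrom = fields[0]
            if standard_chroms_only and not _standard(chrom, chrom_pattern):
                continue
            m = _GTF_GENE_ID.search(fields[8])
            if not m:
                raise ParseError(f"{path}:{lineno}: gene feature without gene_id")
            strand = fields[6]
            start1, end1 = int(fields[3]), int(fields[4])
            tss = start1 - 1 if strand == "+" else end1 - 1
            genes.append(Gene(m.group(1), chrom, tss, strand))
        return genes
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "tss", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: gene TSV missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        if standard_chroms_only and not _standard(str(row.chrom), chrom_pattern):
            continue
        out.append(Gene(str(row.gene_id), str(row.chrom), int(row.tss), str(row.strand)))
    return out


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a long-format differential-expression table.

    Required columns: ``gene_id, timepoint, log2fc, padj`` (padj may be NA;
    timepoints are hours after stimulation and must be positive — the 0 h
    baseline is the fold-change reference, never a row).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "timepoint", "log2fc", "padj"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: expression TSV missing columns {sorted(missing)}")
    if (df["timepoint"] <= 0).any():
        raise ValidationError(
            f"{path}: non-positive timepoint rows present; fold changes are "
            "relative to 0 h, which must not appear as a row"
        )
    return df


def read_expression_per_timepoint(tables: "dict[float, str | Path]") -> pd.DataFrame:
    """Combine one-table-per-timepoint DE output into the long format.

    ``tables`` maps the timepoint in hours to a headered TSV with columns
    ``gene_id, log2fc, padj``. Returns the same frame
    :func:`read_expression` produces.
    """
    frames = []
    for timepoint, path in sorted(tables.items()):
        if timepoint <= 0:
            raise ValidationError(
                f"per-timepoint table at {timepoint} h: timepoints must be > 0"
            )
        df = pd.read_csv(path, sep="\t")
        missing = {"gene_id", "log2fc", "padj"} - set(df.columns)
        if missing:
            raise ParseError(f"{path}: missing columns {sorted(missing)}")
        df = df[["gene_id", "log2fc", "padj"]].copy()
        df.insert(1, "timepoint", float(timepoint))
        frames.append(df)
    if not frames:
        raise ValueError("read_expression_per_timepoint: no tables given")
    return pd.concat(frames, ignore_index=True)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample count matrix (first column ``gene_id``)."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ParseError(f"{path}: counts TSV must have a gene_id column")
    return df.set_index("gene_id")


# ---------------------------------------------------------------------------
# writers


def _write_lines(path, rows) -> None:
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(f) for f in row) + "\n")


def write_tads(path: str | Path, tads: Sequence[Tad]) -> None:
    _write_lines(
        path,
        ((t.interval.chrom, t.interval.start, t.interval.end, t.tad_id) for t in tads),
    )


def write_states(path: str | Path, segments: Sequence[ChromatinStateSegment]) -> None:
    _write_lines(
        path,
        (
            (s.interval.chrom, s.interval.start, s.interval.end, s.state)
            for s in segments
        ),
    )


def write_regions(path: str | Path, regions: Sequence[DifferentialRegion]) -> None:
    """BED6+2: name in column 4, placeholder score, '.' strand, then
    occ_log2fc and occ_fdr with full precision (repr round-trips floats)."""
    _write_lines(
        path,
        (
            (
                r.interval.chrom,
                r.interval.start,
                r.interval.end,
                r.region_id,
                0,
                ".",
                repr(r.occ_log2fc),
                repr(r.occ_fdr),
            )
            for r in regions
        ),
    )


def write_bedpe(path: str | Path, interactions: Sequence[Interaction]) -> None:
    _write_lines(
        path,
        (
            (
                i.anchor1.chrom,
                i.anchor1.start,
                i.anchor1.end,
                i.anchor2.chrom,
                i.anchor2.start,
                i.anchor2.end,
                ".",
                "." if i.significance is None else repr(i.significance),
            )
            for i in interactions
        ),
    )


def write_genes(path: str | Path, genes: Sequence[Gene]) -> None:
    rows = [("gene_id", "chrom", "tss", "strand")]
    rows += [(g.gene_id, g.chrom, g.tss, g.strand) for g in genes]
    _write_lines(path, rows)
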