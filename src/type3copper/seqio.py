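"""Record model and I/O for the formats the pipeline touches.

Sequences travel as :class:`ProteinRecord`, gene coordinates as
:class:`GeneLocus`.  All genomic coordinates are 0-based half-open
internally; conversion from 1-based GFF3 happens here and only here.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .errors import DataError, FormatError

log = logging.getLogger(__name__)

#: The 20 canonical amino acids; everything else is sanitized to X.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = set(AMINO_ACIDS) | {"X"}


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with species/lineage metadata.

    ``lineage`` is a controlled-vocabulary tag naming the phylogenetic
    group the species belongs to (eubacteria, plantae, mollusca, ...).
    """

    id: str
    sequence: str
    species: str = ""
    lineage: str = ""

    def __post_init__(self):
        if not self.id:
            raise DataError("protein record with empty id")
        if not self.sequence:
            raise DataError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneLocus:
    """A gene location, 0-based half-open on a scaffold."""

    protein_id: str
    scaffold: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise DataError(
                f"locus for {self.protein_id!r}: invalid interval "
                f"[{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise DataError(
                f"locus for {self.protein_id!r}: strand must be + or -")


def sanitize_sequence(raw: str, record_id: str = "?") -> str:
    """Upper-case a sequence and replace out-of-alphabet characters by X."""
    seq = raw.upper().replace(" ", "").replace("\t", "")
    cleaned = []
    bad = set()
    for ch in seq:
        if ch in ALPHABET:
            cleaned.append(ch)
        else:
            bad.add(ch)
            cleaned.append("X")
    if bad:
        log.warning("record %s: replaced characters %s by X",
                    record_id, "".join(sorted(bad)))
    return "".join(cleaned)


def _parse_header_metadata(description: str) -> dict:
    """Extract ``species=...;lineage=...`` key-value tail from a header."""
    meta = {}
    parts = description.split(None, 1)
    if len(parts) == 2:
        for chunk in parts[1].split(";"):
            chunk = chunk.strip()
            if "=" in chunk:
                key, value = chunk.split("=", 1)
                meta[key.strip()] = value.strip()
    return meta


def read_metadata(path: str | Path) -> dict[str, dict]:
    """Read a companion metadata TSV (columns: id, species, lineage)."""
    table = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "id" not in reader.fieldnames:
            raise FormatError("metadata TSV needs an 'id' column",
                              path=str(path))
        for row in reader:
            table[row["id"]] = {k: v for k, v in row.items() if k != "id"}
    return table


def read_fasta(path: str | Path,
               metadata: str | Path | Mapping[str, dict] | None = None,
               ) -> list[ProteinRecord]:
    """Read protein FASTA, sanitizing sequences and attaching metadata.

    Metadata is parsed from a ``species=...;lineage=...`` header tail; a
    companion TSV (path or pre-read mapping) overrides header values, with
    a logged warning on conflict.
    """
    meta_table: Mapping[str, dict] = {}
    if metadata is not None:
        meta_table = (read_metadata(metadata)
                      if isinstance(metadata, (str, Path)) else metadata)

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate record id {rec.id!r}",
                              path=str(path))
        seen.add(rec.id)
        meta = _parse_header_metadata(rec.description)
        if rec.id in meta_table:
            for key, value in meta_table[rec.id].items():
                if key in meta and meta[key] != value:
                    log.warning("record %s: metadata TSV overrides header "
                                "%s=%r with %r", rec.id, key, meta[key], value)
                meta[key] = value
        records.append(ProteinRecord(
            id=rec.id,
            sequence=sanitize_sequence(str(rec.seq), rec.id),
            species=meta.get("species", ""),
            lineage=meta.get("lineage", ""),
        ))
    if not records:
        raise FormatError("no FASTA records found", path=str(path))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records with metadata embedded in the header tail."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            tail = ""
            if rec.species or rec.lineage:
                tail = f" species={rec.species};lineage={rec.lineage}"
            fh.write(f">{rec.id}{tail}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i:i + 60] + "\n")


def read_gene_coords(path: str | Path, dialect: str) -> list[GeneLocus]:
    """Read gene loci from GFF3 (1-based inclusive) or BED (0-based).

    Coordinates are normalized to 0-based half-open.  The feature name is
    taken from the GFF3 ``ID=`` attribute (``Name=`` fallback) or the BED
    name column, and must cross-reference a protein id.
    """
    if dialect not in ("gff3", "bed"):
        raise FormatError(f"unknown coordinate dialect {dialect!r}")
    loci: list[GeneLocus] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "gff3":
                    if len(fields) < 9:
                        raise ValueError("expected 9 GFF3 columns")
                    scaffold, _, _, start_s, end_s, _, strand, _, attrs = \
                        fields[:9]
                    if int(start_s) >= int(end_s):
                        raise ValueError(
                            f"degenerate GFF3 interval {start_s}..{end_s}")
                    start = int(start_s) - 1          # 1-based -> 0-based
                    end = int(end_s)                  # inclusive -> half-open
                    name = _gff3_id(attrs)
                else:
                    if len(fields) < 4:
                        raise ValueError("expected >= 4 BED columns")
                    scaffold = fields[0]
                    start, end = int(fields[1]), int(fields[2])
                    name = fields[3]
                    strand = fields[5] if len(fields) >= 6 else "+"
                if strand not in ("+", "-"):
                    strand = "+"
                if start >= end:
                    raise ValueError(
                        f"empty interval after normalization "
                        f"[{start}, {end})")
                loci.append(GeneLocus(protein_id=name, scaffold=scaffold,
                                      start=start, end=end, strand=strand))
            except (ValueError, DataError) as exc:
                raise FormatError(str(exc), path=str(path), line=lineno)
    return loci


def _gff3_id(attrs: str) -> str:
    pairs = dict(chunk.split("=", 1) for chunk in attrs.split(";")
                 if "=" in chunk)
    name = pairs.get("ID") or pairs.get("Name")
    if not name:
        raise ValueError("GFF3 attributes carry neither ID= nor Name=")
    return name


def write_gff3(loci: Iterable[GeneLocus], path: str | Path) -> None:
    """Write loci as GFF3 gene features (internal 0-based -> 1-based)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for loc in loci:
            fh.write("\t".join([
                loc.scaffold, "type3copper", "gene",
                str(loc.start + 1), str(loc.end), ".", loc.strand, ".",
                f"ID={loc.protein_id}",
            ]) + "\n")


def write_report(rows: Sequence[Mapping], path: str | Path,
                 columns: Sequence[str] | None = None) -> None:
    """Write tabular records as a TSV with a deterministic column order.

    Column order follows the first row's key order unless given.  Tabs are
    forbidden inside cells.
    """
    rows = list(rows)
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            cells = []
            for col in columns:
                cell = str(row.get(col, ""))
                if "\t" in cell:
                    raise DataError(
                        f"tab character inside cell for column {col!r}")
                cells.append(cell)
            fh.write("\t".join(cells) + "\n")
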