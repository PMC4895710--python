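"""Readers and writers for the pipeline's file formats.

Sequence databases travel as FASTA with structured headers
(``SOURCE|ID|chr:start-end:strand``), peptide-spectrum matches as TSV
tables with a fixed column order, transcript models as a GTF subset
(CDS features only) and expression values as long-format TSV.

Genomic loci are 1-based inclusive in every file format, matching
genome-browser convention; all internal interval arithmetic is 0-based
half-open, and the conversion happens exactly once, here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """A file or header did not conform to the expected dialect."""


#: database entry categories
CATEGORIES = frozenset(
    {"cds", "lncrna", "pseudogene", "utr5", "prediction", "rnaseq_orf",
     "contaminant", "decoy"}
)

#: categories that count as annotated coding space for novelty classification
CDS_CATEGORIES = frozenset({"cds"})

#: canonical lowercase names for the search modifications
CANONICAL_MODS = (
    "acetylation",
    "carbamidomethyl",
    "deamidation",
    "oxidation",
    "pyro-glu",
)

_PSM_COLUMNS = [
    "spectrum_id", "sample_id", "tissue", "engine", "peptide",
    "modifications", "charge", "score", "delta_score", "pep", "accessions",
]


@dataclass(frozen=True, order=True)
class Locus:
    """Genomic interval, 1-based inclusive, stranded."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(f"locus start > end: {self}")
        if self.strand not in ("+", "-"):
            raise FormatError(f"locus strand must be +/-: {self.strand!r}")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"

    def overlaps(self, other: "Locus") -> bool:
        """Same-chromosome, same-strand interval intersection."""
        return (
            self.chrom == other.chrom
            and self.strand == other.strand
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass(frozen=True, order=True)
class Accession:
    """Structured database accession: source, identifier, optional locus."""

    source_db: str
    identifier: str
    locus: Locus | None = None

    def __str__(self) -> str:
        if self.locus is None:
            return f"{self.source_db}|{self.identifier}"
        return f"{self.source_db}|{self.identifier}|{self.locus}"


_LOCUS_RE = re.compile(r"^(?P<chrom>.+):(?P<start>\d+)-(?P<end>\d+):(?P<strand>[+-])$")


def parse_accession(header: str) -> Accession:
    """Parse ``SOURCE|ID`` or ``SOURCE|ID|chr:start-end:strand``."""
    if not header:
        raise FormatError("empty accession header")
    parts = header.split("|")
    if len(parts) == 2:
        source, ident = parts
        if not source or not ident:
            raise FormatError(f"malformed accession header: {header!r}")
        return Accession(source, ident)
    if len(parts) == 3:
        source, ident, locus_str = parts
        m = _LOCUS_RE.match(locus_str)
        if not source or not ident or m is None:
            raise FormatError(f"malformed accession header: {header!r}")
        locus = Locus(m["chrom"], int(m["start"]), int(m["end"]), m["strand"])
        return Accession(source, ident, locus)
    raise FormatError(f"malformed accession header: {header!r}")


@dataclass(frozen=True)
class SearchSpaceEntry:
    """One protein in the composite search database."""

    accession: Accession
    sequence: str
    category: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"empty sequence for {self.accession}")
        if self.category not in CATEGORIES:
            raise FormatError(f"unknown category {self.category!r}")
        if self.category == "decoy" and self.accession.source_db != "DECOY":
            raise FormatError("decoy entries must carry source_db DECOY")


@dataclass(frozen=True)
class PSMRecord:
    """A single engine's assignment of a peptide to a spectrum."""

    spectrum_id: str
    sample_id: str
    tissue: str
    engine: str
    peptide: str
    modifications: frozenset[tuple[str, int]]
    charge: int
    score: float
    delta_score: float
    pep: float
    matched_accessions: frozenset[str]

    def __post_init__(self) -> None:
        if not (0.0 <= self.pep <= 1.0):
            raise FormatError(f"pep outside [0,1]: {self.pep}")
        for name, pos in self.modifications:
            if pos < 0 or pos > len(self.peptide):
                raise FormatError(
                    f"modification {name}@{pos} outside peptide of length "
                    f"{len(self.peptide)}"
                )
        if not self.matched_accessions:
            raise FormatError("PSM with no matched accessions")


@dataclass(frozen=True)
class TranscriptModel:
    """Coding transcript: ordered CDS segments in transcription order."""

    transcript_id: str
    gene_id: str
    protein_accession: str
    strand: str
    cds_segments: tuple[Locus, ...]

    def __post_init__(self) -> None:
        if sum(s.end - s.start + 1 for s in self.cds_segments) % 3 != 0:
            raise FormatError(
                f"CDS length of {self.transcript_id} not divisible by 3"
            )

    @property
    def cds_length_nt(self) -> int:
        return sum(s.end - s.start + 1 for s in self.cds_segments)


@dataclass
class RPKMTable:
    """Expression support: (gene_id, tissue) -> RPKM."""

    values: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, v in self.values.items():
            if v < 0:
                raise FormatError(f"negative RPKM for {key}: {v}")

    def tissues_for(self, gene_id: str) -> dict[str, float]:
        return {t: v for (g, t), v in self.values.items() if g == gene_id}

    def genes(self) -> set[str]:
        return {g for g, _ in self.values}


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(
    path: str | Path,
    category: str = "cds",
    permissive: bool = False,
) -> list[SearchSpaceEntry]:
    """Read a protein FASTA whose headers follow the accession grammar.

    With ``permissive=True`` free-text headers are mapped to source_db
    ``UNKNOWN``. A terminal ``*`` is stripped; an internal ``*`` is an
    error for protein FASTA. Duplicate accessions are rejected.
    """
    entries: list[SearchSpaceEntry] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            acc = parse_accession(rec.id)
        except FormatError:
            if not permissive:
                raise
            acc = Accession("UNKNOWN", rec.id)
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if "*" in seq:
            raise FormatError(f"internal stop '*' in protein entry {acc}")
        entries.append(SearchSpaceEntry(acc, seq, category))
        seen[str(acc)] = seen.get(str(acc), 0) + 1
    dupes = sorted(a for a, n in seen.items() if n > 1)
    if dupes:
        raise FormatError(f"duplicate accessions: {', '.join(dupes)}")
    return entries


def read_nt_fasta(path: str | Path, permissive: bool = False) -> list[tuple[Accession, str]]:
    """Read a nucleotide FASTA (transcript models to be translated)."""
    out: list[tuple[Accession, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            acc = parse_accession(rec.id)
        except FormatError:
            if not permissive:
                raise
            acc = Accession("UNKNOWN", rec.id)
        if str(acc) in seen:
            raise FormatError(f"duplicate accession {acc}")
        seen.add(str(acc))
        out.append((acc, str(rec.seq).upper()))
    return out


def write_fasta(entries: Iterable[SearchSpaceEntry], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(e.sequence), id=str(e.accession), description="")
        for e in entries
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# PSM tables

def _parse_mods(text: str, peptide: str, where: str) -> frozenset[tuple[str, int]]:
    if not text or text in (".", "-"):
        return frozenset()
    mods = set()
    for token in text.split(";"):
        token = token.strip()
        if not token:
            continue
        try:
            name, pos_s = token.rsplit("@", 1)
            pos = int(pos_s)
        except ValueError as exc:
            raise FormatError(f"{where}: bad modification token {token!r}") from exc
        if pos < 0 or pos > len(peptide):
            raise FormatError(
                f"{where}: modification position {pos} outside peptide "
                f"of length {len(peptide)}"
            )
        mods.add((name, pos))
    return frozenset(mods)


def format_mods(mods: Iterable[tuple[str, int]]) -> str:
    return ";".join(f"{n}@{p}" for n, p in sorted(mods))


def read_psm_table(path: str | Path, engine: str | None = None) -> list[PSMRecord]:
    """Read a per-engine PSM TSV (fixed column dialect).

    ``engine``, when given, overrides the table's engine column (used when
    one file per engine is supplied without the column filled in).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _PSM_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing PSM columns {missing}")
    records: list[PSMRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        where = f"{path}:{i + 2}"  # +1 header, +1 one-based
        peptide = row.peptide
        try:
            pep = float(row.pep)
            if not (0.0 <= pep <= 1.0):
                raise FormatError(f"{where}: pep outside [0,1]: {pep}")
            rec = PSMRecord(
                spectrum_id=row.spectrum_id,
                sample_id=row.sample_id,
                tissue=row.tissue,
                engine=engine or row.engine,
                peptide=peptide,
                modifications=_parse_mods(row.modifications, peptide, where),
                charge=int(row.charge),
                score=float(row.score),
                delta_score=float(row.delta_score),
                pep=pep,
                matched_accessions=frozenset(
                    a for a in row.accessions.split(";") if a
                ),
            )
        except FormatError:
            raise
        except ValueError as exc:
            raise FormatError(f"{where}: {exc}") from exc
        records.append(rec)
    return records


def write_psm_table(records: Sequence[PSMRecord], path: str | Path) -> None:
    rows = [
        {
            "spectrum_id": r.spectrum_id,
            "sample_id": r.sample_id,
            "tissue": r.tissue,
            "engine": r.engine,
            "peptide": r.peptide,
            "modifications": format_mods(r.modifications),
            "charge": r.charge,
            "score": r.score,
            "delta_score": r.delta_score,
            "pep": r.pep,
            "accessions": ";".join(sorted(r.matched_accessions)),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_PSM_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GTF subset (CDS features only)

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_transcript_models(path: str | Path) -> list[TranscriptModel]:
    """Read CDS features from a GTF, one model per transcript.

    Segments are ordered 5'->3' in transcription direction (descending
    genomic start on the minus strand); total CDS length must be a
    multiple of three.
    """
    per_transcript: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _, feature, start, end, _, strand, _, attrs = fields
            if feature != "CDS":
                continue
            a = dict(_ATTR_RE.findall(attrs))
            for key in ("gene_id", "transcript_id"):
                if key not in a:
                    raise FormatError(f"{path}:{lineno}: missing {key}")
            tid = a["transcript_id"]
            info = per_transcript.setdefault(
                tid,
                {
                    "gene_id": a["gene_id"],
                    "protein_accession": a.get("protein_id", tid),
                    "strand": strand,
                    "segments": [],
                },
            )
            info["segments"].append(Locus(chrom, int(start), int(end), strand))
    models = []
    for tid, info in per_transcript.items():
        reverse = info["strand"] == "-"
        segs = tuple(
            sorted(info["segments"], key=lambda s: s.start, reverse=reverse)
        )
        total = sum(s.end - s.start + 1 for s in segs)
        if total % 3 != 0:
            raise FormatError(
                f"transcript {tid}: CDS length {total} not divisible by 3"
            )
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=info["gene_id"],
                protein_accession=info["protein_accession"],
                strand=info["strand"],
                cds_segments=segs,
            )
        )
    return models


# ---------------------------------------------------------------------------
# RPKM tables

def read_rpkm_table(path: str | Path) -> RPKMTable:
    """Read a long-format TSV with columns gene_id, tissue, rpkm."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "tissue", "rpkm"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col}")
    values = {
        (str(r.gene_id), str(r.tissue)): float(r.rpkm)
        for r in df.itertuples(index=False)
    }
    return RPKMTable(values)


def write_rpkm_table(table: RPKMTable, path: str | Path) -> None:
    rows = [
        {"gene_id": g, "tissue": t, "rpkm": v}
        for (g, t), v in sorted(table.values.items())
    ]
    pd.DataFrame(rows, columns=["gene_id", "tissue", "rpkm"]).to_csv(
        path, sep="\t", index=False
    )
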