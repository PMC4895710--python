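"""Composite target+decoy search-space construction.

The database combines annotated protein sequences (CDS), non-coding and
predicted sequences, three-frame translations of nucleotide transcript
models, and contaminants. Isoleucine is indistinguishable from leucine
by standard MS/MS, so every I is rewritten to L before searching; on the
reporting side L is rewritten to the ambiguity code J. Decoys are
per-protein tryptic-peptide shuffles that preserve length, composition
and cleavage structure, giving an exactly 1:1 target:decoy database for
false-discovery estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import Seq

from .io_formats import (
    Accession,
    FormatError,
    SearchSpaceEntry,
)

_NT = frozenset("ACGTN")


def normalize_ile(seq: str, direction: str = "to_L") -> str:
    """I/L ambiguity normalization: ``to_L`` (database side) maps I->L,
    ``to_J`` (reporting side) maps both I and L to J. Both idempotent."""
    if direction == "to_L":
        return seq.replace("I", "L")
    if direction == "to_J":
        return seq.replace("I", "J").replace("L", "J")
    raise ValueError(f"unknown direction {direction!r}")


def to_J(seq: str) -> str:
    return normalize_ile(seq, "to_J")


def three_frame_translate(
    nt_sequence: str, min_orf_len: int = 10
) -> list[tuple[int, int, str]]:
    """Translate the three forward frames, splitting at stop codons.

    Returns (frame, orf_index, peptide) for every stop-free fragment of at
    least ``min_orf_len`` residues. N codons translate to X; trailing
    partial codons are ignored.
    """
    nt_sequence = nt_sequence.upper()
    bad = set(nt_sequence) - _NT
    if bad:
        raise FormatError(f"non-nucleotide characters: {sorted(bad)}")
    out: list[tuple[int, int, str]] = []
    for frame in range(3):
        sub = nt_sequence[frame:]
        sub = sub[: len(sub) - len(sub) % 3]
        if not sub:
            continue
        aa = str(Seq(sub).translate())
        idx = 0
        for fragment in aa.split("*"):
            if len(fragment) >= min_orf_len:
                out.append((frame, idx, fragment))
                idx += 1
    return out


# ---------------------------------------------------------------------------
# Tryptic digestion

TERMINUS = "-"


@dataclass(frozen=True)
class DigestPeptide:
    """A tryptic peptide with positional and flanking context."""

    sequence: str
    start: int  # 1-based position in the parent protein
    missed_cleavages: int
    nterm_flanking: str  # preceding residue or '-' at protein N-terminus
    cterm_flanking: str  # following residue or '-' at protein C-terminus


def cleavage_sites(seq: str) -> list[int]:
    """0-based positions *after* which trypsin cleaves (K/R not before P)."""
    return [
        i
        for i in range(len(seq) - 1)
        if seq[i] in "KR" and seq[i + 1] != "P"
    ]


def count_missed_cleavages(peptide: str) -> int:
    """Internal uncut K/R sites within a peptide (C-terminal residue is
    the cleavage product, not a missed site)."""
    return len(cleavage_sites(peptide))


def digest(protein_seq: str, max_missed: int = 3) -> list[DigestPeptide]:
    """Tryptic digestion emitting peptides with 0..max_missed missed
    cleavages, with 1-based start positions and flanking residues."""
    if not protein_seq:
        raise ValueError("empty protein sequence")
    sites = cleavage_sites(protein_seq)
    # fragment boundaries as 0-based half-open intervals
    starts = [0] + [s + 1 for s in sites]
    ends = [s + 1 for s in sites] + [len(protein_seq)]
    n = len(starts)
    peptides: list[DigestPeptide] = []
    for i in range(n):
        for mc in range(min(max_missed, n - 1 - i) + 1):
            j = i + mc
            s, e = starts[i], ends[j]
            peptides.append(
                DigestPeptide(
                    sequence=protein_seq[s:e],
                    start=s + 1,
                    missed_cleavages=mc,
                    nterm_flanking=protein_seq[s - 1] if s > 0 else TERMINUS,
                    cterm_flanking=(
                        protein_seq[e] if e < len(protein_seq) else TERMINUS
                    ),
                )
            )
    return peptides


def is_fully_tryptic(peptide: DigestPeptide, parent_starts_with_met: bool = True) -> bool:
    """Both termini consistent with trypsin or the protein's own termini.

    The N-terminus also passes at parent position 2 when the initiator
    methionine has been lost.
    """
    seq = peptide.sequence
    nt_ok = (
        peptide.nterm_flanking == TERMINUS
        or (peptide.nterm_flanking in "KR" and seq[0] != "P")
        or (peptide.start == 2 and parent_starts_with_met
            and peptide.nterm_flanking == "M")
    )
    ct_ok = peptide.cterm_flanking == TERMINUS or (
        seq[-1] in "KR" and peptide.cterm_flanking != "P"
    )
    return nt_ok and ct_ok


# ---------------------------------------------------------------------------
# Decoys

def generate_decoys(
    entries: Sequence[SearchSpaceEntry], seed: int
) -> list[SearchSpaceEntry]:
    """One shuffled decoy per target, preserving length, composition and
    tryptic cleavage structure.

    Each fully-cleaved tryptic fragment is shuffled in place with its
    C-terminal K/R fixed; accessions become ``DECOY|<original id>``.
    Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    decoys: list[SearchSpaceEntry] = []
    for entry in entries:
        seq = entry.sequence
        sites = cleavage_sites(seq)
        starts = [0] + [s + 1 for s in sites]
        ends = [s + 1 for s in sites] + [len(seq)]
        parts: list[str] = []
        for s, e in zip(starts, ends):
            frag = seq[s:e]
            if frag and frag[-1] in "KR":
                body, tail = frag[:-1], frag[-1]
            else:
                body, tail = frag, ""
            letters = list(body)
            rng.shuffle(letters)
            parts.append("".join(letters) + tail)
        decoys.append(
            SearchSpaceEntry(
                accession=Accession("DECOY", entry.accession.identifier),
                sequence="".join(parts),
                category="decoy",
            )
        )
    return decoys


# ---------------------------------------------------------------------------
# Database assembly

@dataclass
class DatabaseStats:
    """Per-category protein, residue and distinct-tryptic-peptide counts.

    Peptides are counted at length >= 7 with <= 2 missed cleavages in
    I/L-collapsed (J) space, mirroring how peptide uniqueness is
    evaluated downstream.
    """

    proteins: dict[str, int] = field(default_factory=dict)
    residues: dict[str, int] = field(default_factory=dict)
    tryptic_peptides: dict[str, int] = field(default_factory=dict)

    @property
    def total_proteins(self) -> int:
        return sum(self.proteins.values())

    @property
    def total_residues(self) -> int:
        return sum(self.residues.values())

    def as_dict(self) -> dict:
        return {
            "proteins": dict(sorted(self.proteins.items())),
            "residues": dict(sorted(self.residues.items())),
            "tryptic_peptides": dict(sorted(self.tryptic_peptides.items())),
            "total_proteins": self.total_proteins,
            "total_residues": self.total_residues,
        }


def compute_stats(
    entries: Sequence[SearchSpaceEntry],
    min_len: int = 7,
    max_missed: int = 2,
) -> DatabaseStats:
    stats = DatabaseStats()
    peptide_sets: dict[str, set[str]] = {}
    for e in entries:
        stats.proteins[e.category] = stats.proteins.get(e.category, 0) + 1
        stats.residues[e.category] = (
            stats.residues.get(e.category, 0) + len(e.sequence)
        )
        bucket = peptide_sets.setdefault(e.category, set())
        for p in digest(e.sequence, max_missed=max_missed):
            if len(p.sequence) >= min_len:
                bucket.add(to_J(p.sequence))
    stats.tryptic_peptides = {c: len(s) for c, s in peptide_sets.items()}
    return stats


def _translate_models(
    nt_models: Iterable[tuple[Accession, str]], min_orf_len: int = 10
) -> list[SearchSpaceEntry]:
    entries = []
    for acc, nt in nt_models:
        for frame, idx, orf in three_frame_translate(nt, min_orf_len):
            entries.append(
                SearchSpaceEntry(
                    accession=Accession(
                        acc.source_db,
                        f"{acc.identifier}.f{frame}.o{idx}",
                        acc.locus,
                    ),
                    sequence=orf,
                    category="rnaseq_orf",
                )
            )
    return entries


def build_search_space(
    cds: Sequence[SearchSpaceEntry],
    noncoding: Sequence[SearchSpaceEntry] = (),
    nt_models: Sequence[tuple[Accession, str]] = (),
    contaminants: Sequence[SearchSpaceEntry] = (),
    seed: int = 0,
    min_orf_len: int = 10,
) -> tuple[list[SearchSpaceEntry], DatabaseStats]:
    """Assemble the final target+decoy database.

    Nucleotide models are three-frame translated; everything is I->L
    normalized; non-CDS entries overlapping annotated coding space are
    removed (locus intersection when a locus is available, otherwise
    sequence containment in a CDS protein); decoys are appended 1:1 and
    stats are computed on the final database.
    """
    if not cds:
        raise ValueError("empty CDS input: downstream classification "
                         "requires an annotated coding set")

    def norm(e: SearchSpaceEntry) -> SearchSpaceEntry:
        return SearchSpaceEntry(
            e.accession, normalize_ile(e.sequence, "to_L"), e.category
        )

    cds_n = [norm(e) for e in cds]
    contam_n = [norm(e) for e in contaminants]
    candidates = [norm(e) for e in noncoding]
    candidates += [norm(e) for e in _translate_models(nt_models, min_orf_len)]

    cds_loci = [e.accession.locus for e in cds_n if e.accession.locus]
    cds_seqs = [e.sequence for e in cds_n]

    kept: list[SearchSpaceEntry] = []
    for e in candidates:
        if e.accession.locus is not None:
            if any(e.accession.locus.overlaps(l) for l in cds_loci):
                continue
        elif any(e.sequence in s for s in cds_seqs):
            continue
        kept.append(e)

    targets = cds_n + kept + contam_n
    seen: dict[str, int] = {}
    for e in targets:
        key = str(e.accession)
        seen[key] = seen.get(key, 0) + 1
    dupes = sorted(k for k, n in seen.items() if n > 1)
    if dupes:
        raise FormatError(f"duplicate accessions in database: {dupes}")

    decoys = generate_decoys(targets, seed)
    final = targets + decoys
    return final, compute_stats(final)
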