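"""Parsimony protein inference, gene mapping and transcript analysis.

Protein inference follows the classic parsimony recipe: proteins with
identical peptide evidence are clustered into one group, groups whose
evidence is strictly contained in another's are subsumed, and the
remaining groups are reduced to the shortest list that still explains
every peptide. Instances with few candidate groups are solved exactly
(subset enumeration); larger ones fall back to the deterministic greedy
set-cover heuristic.

The transcript-level analysis projects peptides through CDS segment
coordinates to find exon-junction-crossing identifications and genes
with peptide evidence for more than one transcript (alternative
splicing), the latter under a stricter evidence regime.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

from .io_formats import Locus, SearchSpaceEntry, TranscriptModel
from .psm_processing import PeptideEvidence
from .search_space import count_missed_cleavages, to_J

#: instance size up to which the minimal cover is computed exactly
EXACT_COVER_LIMIT = 15


@dataclass(frozen=True)
class ProteinGroup:
    member_accessions: frozenset[str]
    peptides: frozenset[str]
    unique_peptides: frozenset[str]
    subsumed_accessions: frozenset[str] = frozenset()


@dataclass(frozen=True)
class GeneCluster:
    gene_ids: frozenset[str]
    peptides: frozenset[str]
    unique_peptides: frozenset[str]

    @property
    def n_unique(self) -> int:
        return len(self.unique_peptides)


def map_peptides_to_entries(
    peptides: Sequence[str],
    database: Sequence[SearchSpaceEntry],
    skip_categories: frozenset[str] = frozenset({"decoy"}),
) -> dict[str, frozenset[str]]:
    """J-space substring matching of peptides against database entries."""
    db = [
        (str(e.accession), to_J(e.sequence))
        for e in database
        if e.category not in skip_categories
    ]
    mapping: dict[str, frozenset[str]] = {}
    for p in peptides:
        pj = to_J(p)
        mapping[p] = frozenset(acc for acc, seq in db if pj in seq)
    return mapping


def _minimal_cover_exact(
    sets: list[tuple[str, frozenset[str]]], universe: frozenset[str]
) -> list[str]:
    """Smallest sub-collection covering the universe; lexicographically
    smallest member tuple among ties. Exhaustive by increasing size."""
    ids = [i for i, _ in sets]
    by_id = dict(sets)
    for k in range(1, len(sets) + 1):
        best: tuple[str, ...] | None = None
        for combo in combinations(ids, k):
            covered = frozenset().union(*(by_id[i] for i in combo))
            if covered >= universe:
                if best is None or combo < best:
                    best = combo
        if best is not None:
            return list(best)
    return ids


def _minimal_cover_greedy(
    sets: list[tuple[str, frozenset[str]]], universe: frozenset[str]
) -> list[str]:
    remaining = set(universe)
    available = dict(sets)
    chosen: list[str] = []
    while remaining:
        best_id = min(
            available,
            key=lambda i: (-len(available[i] & remaining), i),
        )
        if not available[best_id] & remaining:
            break  # unreachable when sets jointly cover the universe
        chosen.append(best_id)
        remaining -= available[best_id]
        del available[best_id]
    return chosen


def infer_protein_groups(
    peptide_evidence: Sequence[PeptideEvidence],
    database: Sequence[SearchSpaceEntry],
) -> list[ProteinGroup]:
    """Parsimony inference: the shortest protein list explaining all
    peptides, with identical-evidence clustering and strict-subset
    subsumption. Every emitted group keeps at least one peptide unique
    to it among the emitted groups."""
    peptides = [ev.peptide_j for ev in peptide_evidence]
    mapping = map_peptides_to_entries(peptides, database)
    orphans = sorted(p for p, accs in mapping.items() if not accs)
    if orphans:
        raise ValueError(
            f"peptides match no database entry (upstream inconsistency): "
            f"{orphans[:5]}"
        )

    by_protein: dict[str, set[str]] = {}
    for p, accs in mapping.items():
        for acc in accs:
            by_protein.setdefault(acc, set()).add(to_J(p))

    # (a) identical peptide sets -> one cluster
    by_evidence: dict[frozenset[str], set[str]] = {}
    for acc, peps in by_protein.items():
        by_evidence.setdefault(frozenset(peps), set()).add(acc)
    clusters = [
        (frozenset(accs), peps) for peps, accs in by_evidence.items()
    ]
    clusters.sort(key=lambda c: sorted(c[0]))

    # (b) strict-subset subsumption
    subsumed_into: dict[frozenset[str], set[str]] = {}
    alive: list[tuple[frozenset[str], frozenset[str]]] = []
    for accs, peps in clusters:
        supersets = [
            (a2, p2)
            for a2, p2 in clusters
            if peps < p2
        ]
        if supersets:
            host = min(supersets, key=lambda c: sorted(c[0]))
            subsumed_into.setdefault(host[0], set()).update(accs)
        else:
            alive.append((accs, peps))

    # (c) minimum set cover over the surviving clusters
    universe = frozenset(to_J(p) for p in peptides)
    labelled = [
        ("\x1f".join(sorted(accs)), peps) for accs, peps in alive
    ]
    if len(labelled) <= EXACT_COVER_LIMIT:
        chosen_ids = _minimal_cover_exact(labelled, universe)
    else:
        chosen_ids = _minimal_cover_greedy(labelled, universe)
    chosen = set(chosen_ids)
    cover = [
        (frozenset(i.split("\x1f")), peps)
        for i, peps in labelled
        if i in chosen
    ]

    # (d) unique peptides relative to the emitted cover
    groups: list[ProteinGroup] = []
    for accs, peps in sorted(cover, key=lambda c: sorted(c[0])):
        others = frozenset().union(
            *(p2 for a2, p2 in cover if a2 != accs)
        ) if len(cover) > 1 else frozenset()
        groups.append(
            ProteinGroup(
                member_accessions=accs,
                peptides=peps,
                unique_peptides=peps - others,
                subsumed_accessions=frozenset(subsumed_into.get(accs, ())),
            )
        )
    return groups


def map_groups_to_genes(
    groups: Sequence[ProteinGroup],
    accession_to_gene: Mapping[str, str],
) -> tuple[list[GeneCluster], dict[int, int], list[ProteinGroup]]:
    """Map protein groups to gene clusters.

    Returns (clusters, counts, unmapped_groups) where counts reports the
    number of clusters with at least 1, 2 and 3 unique peptides and
    unmapped_groups are groups with no accession in the mapping (routed
    to the novelty analysis, not an error). Genes whose peptide set is a
    strict subset of another gene's are not counted; genes with
    identical evidence merge into one cluster.
    """
    gene_peptides: dict[str, set[str]] = {}
    unmapped: list[ProteinGroup] = []
    for g in groups:
        genes = {
            accession_to_gene[a]
            for a in g.member_accessions
            if a in accession_to_gene
        }
        if not genes:
            unmapped.append(g)
            continue
        for gene in genes:
            gene_peptides.setdefault(gene, set()).update(g.peptides)

    # drop strict-subset genes
    items = sorted(gene_peptides.items())
    alive = [
        (gene, frozenset(peps))
        for gene, peps in items
        if not any(
            frozenset(peps) < frozenset(p2) for _, p2 in items
        )
    ]
    by_evidence: dict[frozenset[str], set[str]] = {}
    for gene, peps in alive:
        by_evidence.setdefault(peps, set()).add(gene)

    clusters = []
    entries = sorted(by_evidence.items(), key=lambda kv: sorted(kv[1]))
    for peps, genes in entries:
        others = (
            frozenset().union(*(p for p, g2 in entries if g2 != genes))
            if len(entries) > 1
            else frozenset()
        )
        clusters.append(
            GeneCluster(
                gene_ids=frozenset(genes),
                peptides=peps,
                unique_peptides=peps - others,
            )
        )
    counts = {
        k: sum(1 for c in clusters if c.n_unique >= k) for k in (1, 2, 3)
    }
    return clusters, counts, unmapped


# ---------------------------------------------------------------------------
# Genomic projection

def map_peptide_to_genome(
    peptide_start_aa: int,
    peptide_len: int,
    model: TranscriptModel,
) -> tuple[list[Locus], bool]:
    """Project a peptide (1-based start within the encoded protein) onto
    genomic coordinates through the model's CDS segments.

    Returns the genomic segments in ascending coordinate order (strand
    carried on each Locus) and whether the peptide crosses an exon
    junction (touches two or more CDS segments).
    """
    nt_start = 3 * (peptide_start_aa - 1) + 1
    nt_end = 3 * (peptide_start_aa - 1 + peptide_len)
    if peptide_start_aa < 1 or nt_end > model.cds_length_nt:
        raise ValueError(
            f"peptide ({peptide_start_aa}, len {peptide_len}) extends "
            f"beyond CDS of transcript {model.transcript_id}"
        )
    pieces: list[Locus] = []
    offset = 0  # CDS nucleotides consumed so far, transcription order
    for seg in model.cds_segments:
        seg_len = seg.end - seg.start + 1
        lo = max(nt_start, offset + 1)
        hi = min(nt_end, offset + seg_len)
        if lo <= hi:
            if model.strand == "+":
                g_lo = seg.start + (lo - offset - 1)
                g_hi = seg.start + (hi - offset - 1)
            else:
                g_hi = seg.end - (lo - offset - 1)
                g_lo = seg.end - (hi - offset - 1)
            pieces.append(Locus(seg.chrom, g_lo, g_hi, model.strand))
        offset += seg_len
    pieces.sort(key=lambda l: l.start)
    return pieces, len(pieces) >= 2


def detect_alternative_splicing(
    peptide_evidence: Sequence[PeptideEvidence],
    models: Sequence[TranscriptModel],
    protein_sequences: Mapping[str, str],
    strict: bool = True,
    pep_max: float = 0.01,
    max_len: int = 30,
    max_missed: int = 2,
) -> dict[str, list[str]]:
    """Genes with peptide evidence for two or more distinct transcripts.

    ``protein_sequences`` maps each model's protein accession to its
    translated sequence. Under the strict regime peptides must reach
    best PEP <= 0.01, carry at least one unmodified PSM, be at most
    30 aa and have at most 2 missed cleavages. A transcript counts as
    identified when at least one surviving peptide maps uniquely to it
    (at the transcript-protein sequence level).
    """
    surviving = []
    for ev in peptide_evidence:
        if strict:
            if ev.P > pep_max or ev.U < 1 or ev.L > max_len:
                continue
            if count_missed_cleavages(ev.peptide_j) > max_missed:
                continue
        surviving.append(ev.peptide_j)

    proteins = [
        (m, to_J(protein_sequences[m.protein_accession]))
        for m in models
        if m.protein_accession in protein_sequences
    ]
    identified: dict[str, set[str]] = {}
    for pj in surviving:
        hits = [m for m, seq in proteins if pj in seq]
        if len(hits) == 1:
            m = hits[0]
            identified.setdefault(m.gene_id, set()).add(m.transcript_id)
    return {
        gene: sorted(tids)
        for gene, tids in sorted(identified.items())
        if len(tids) >= 2
    }
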