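"""High-stringency filtering of non-CDS (putative novel) peptides.

Peptides matching nothing in annotated coding space are the interesting
output of a proteogenomic search and also where false positives
concentrate, so they pass through a cascade that (1) restricts to
peptides uniquely matching a single non-CDS sequence, (2) discards
supporting PSMs carrying deamidation or N-terminal carbamidomethylation
(empirically enriched among spurious novel matches) and mislocated
pyro-glutamate, (3) re-filters at best PEP <= 0.01, length <= 29 aa,
fully tryptic termini and at most two missed cleavages, (4) removes
peptides already present in updated annotation releases and (5) removes
peptides within one substitution of a known protein, which a single
amino-acid variant (SAV) would explain. Every violated rule is recorded
on the verdict, not just the first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .io_formats import RPKMTable, SearchSpaceEntry
from .psm_processing import PeptideEvidence, QValuedPSM
from .search_space import (
    DigestPeptide,
    TERMINUS,
    count_missed_cleavages,
    is_fully_tryptic,
    to_J,
)

#: modifications whose presence on a PSM disqualifies it from novel evidence
BANNED_MODS = ("deamidation",)
#: modifications banned only at the peptide N-terminus (position 0)
BANNED_NTERM_MODS = ("carbamidomethyl",)
#: N-terminal-only modification whose placement is validated
PYROGLU = "pyro-glu"

RULES = (
    "pep",
    "length",
    "semi_tryptic",
    "missed_cleavages",
    "banned_mod",
    "known_match",
    "sav_distance",
    "ambiguous_mapping",
)


@dataclass
class NoveltyVerdict:
    peptide_j: str
    status: str  # cds | novel_candidate | rejected
    rejection_reasons: list[str] = field(default_factory=list)
    supporting_psm_count: int = 0


@dataclass(frozen=True)
class ModEnrichment:
    modification: str
    novel_count: int
    novel_total: int
    cds_count: int
    cds_total: int
    ratio: float
    p_value: float
    p_adjusted: float


def classify_non_cds(
    peptide_evidence: Sequence[PeptideEvidence],
    database: Sequence[SearchSpaceEntry],
) -> dict[str, list[PeptideEvidence]]:
    """Partition peptides into cds / non_cds / ambiguous.

    A peptide matching any annotated coding entry is ``cds``; one
    uniquely matching a single non-CDS entry is ``non_cds``; one
    matching several non-CDS entries and no coding entry is
    ``ambiguous`` (excluded from annotation candidates but reported).
    """
    cds_seqs = [
        to_J(e.sequence) for e in database if e.category == "cds"
    ]
    noncds = [
        (str(e.accession), to_J(e.sequence))
        for e in database
        if e.category not in ("cds", "decoy", "contaminant")
    ]
    parts: dict[str, list[PeptideEvidence]] = {
        "cds": [], "non_cds": [], "ambiguous": []
    }
    for ev in peptide_evidence:
        pj = ev.peptide_j
        if any(pj in s for s in cds_seqs):
            parts["cds"].append(ev)
            continue
        hits = [acc for acc, s in noncds if pj in s]
        if len(hits) == 1:
            parts["non_cds"].append(ev)
        elif len(hits) >= 2:
            parts["ambiguous"].append(ev)
        else:
            # matched only contaminants/decoys upstream; treat as cds-like
            parts["cds"].append(ev)
    return parts


def _psm_banned(psm: QValuedPSM) -> bool:
    for name, pos in psm.merged.modifications:
        if name in BANNED_MODS:
            return True
        if name in BANNED_NTERM_MODS and pos == 0:
            return True
        if name == PYROGLU:
            peptide = psm.merged.peptide_j
            if pos != 0 or peptide[0] not in ("Q", "E"):
                return True
    return False


def _tryptic_context(
    peptide_j: str, database_j: Sequence[tuple[str, str]]
) -> DigestPeptide | None:
    """Find an occurrence of the peptide in the database and return it
    with flanking context; prefers a fully tryptic occurrence."""
    best: DigestPeptide | None = None
    for _, seq in database_j:
        start = seq.find(peptide_j)
        while start != -1:
            dp = DigestPeptide(
                sequence=peptide_j,
                start=start + 1,
                missed_cleavages=count_missed_cleavages(peptide_j),
                nterm_flanking=seq[start - 1] if start > 0 else TERMINUS,
                cterm_flanking=(
                    seq[start + len(peptide_j)]
                    if start + len(peptide_j) < len(seq)
                    else TERMINUS
                ),
            )
            if is_fully_tryptic(dp):
                return dp
            best = best or dp
            start = seq.find(peptide_j, start + 1)
    return best


def stringent_filter(
    non_cds_evidence: Sequence[PeptideEvidence],
    database: Sequence[SearchSpaceEntry],
    pep_max: float = 0.01,
    max_len: int = 29,
    max_missed: int = 2,
) -> list[NoveltyVerdict]:
    """Apply the confidence tier of the novelty cascade.

    Supporting PSMs with banned or mislocated modifications are
    discarded first; the peptide then passes only if at least one PSM
    remains, the best remaining PEP is <= 0.01, the length is <= 29, the
    peptide is fully tryptic in its matched sequence and it has at most
    two missed cleavages. All violated rules are recorded.
    """
    database_j = [
        (str(e.accession), to_J(e.sequence))
        for e in database
        if e.category not in ("decoy", "contaminant")
    ]
    verdicts = []
    for ev in non_cds_evidence:
        reasons: list[str] = []
        kept = [p for p in ev.psms if not _psm_banned(p)]
        if not kept:
            reasons.append("banned_mod")
        else:
            best_pep = min(p.merged.pep for p in kept)
            if best_pep > pep_max:
                reasons.append("pep")
        if ev.L > max_len:
            reasons.append("length")
        ctx = _tryptic_context(ev.peptide_j, database_j)
        if ctx is None or not is_fully_tryptic(ctx):
            reasons.append("semi_tryptic")
        if count_missed_cleavages(ev.peptide_j) > max_missed:
            reasons.append("missed_cleavages")
        verdicts.append(
            NoveltyVerdict(
                peptide_j=ev.peptide_j,
                status="novel_candidate" if not reasons else "rejected",
                rejection_reasons=reasons,
                supporting_psm_count=len(kept),
            )
        )
    return verdicts


def match_updated_annotation(
    candidates: Sequence[NoveltyVerdict],
    updated_proteomes: Iterable[SearchSpaceEntry],
) -> list[NoveltyVerdict]:
    """Reject candidates found verbatim (J-space substring) in updated
    annotation releases."""
    updated = [to_J(e.sequence) for e in updated_proteomes]
    out = []
    for v in candidates:
        if v.status == "novel_candidate" and any(
            v.peptide_j in s for s in updated
        ):
            v.status = "rejected"
            v.rejection_reasons.append("known_match")
        out.append(v)
    return out


def min_hamming_to_proteome(peptide_j: str, proteome_j: Sequence[str]) -> int:
    """Minimum Hamming distance between the peptide and any equal-length
    window of the (J-space) proteome."""
    L = len(peptide_j)
    pep = np.frombuffer(peptide_j.encode(), dtype=np.uint8)
    best = L
    for seq in proteome_j:
        n = len(seq)
        if n < L:
            continue
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(arr, L)
        dists = (windows != pep).sum(axis=1)
        m = int(dists.min())
        if m < best:
            best = m
            if best == 0:
                return 0
    return best


def sav_filter(
    candidates: Sequence[NoveltyVerdict],
    known_proteome: Iterable[SearchSpaceEntry],
    min_distance: int = 2,
) -> list[NoveltyVerdict]:
    """Reject candidates within ``min_distance - 1`` substitutions of a
    known protein window: a single amino-acid variant of an annotated
    gene is the likelier explanation."""
    proteome_j = [to_J(e.sequence) for e in known_proteome]
    out = []
    for v in candidates:
        if v.status == "novel_candidate":
            if min_hamming_to_proteome(v.peptide_j, proteome_j) < min_distance:
                v.status = "rejected"
                v.rejection_reasons.append("sav_distance")
        out.append(v)
    return out


def novelty_cascade(
    peptide_evidence: Sequence[PeptideEvidence],
    database: Sequence[SearchSpaceEntry],
    updated_proteomes: Sequence[SearchSpaceEntry] = (),
    apply_sav_filter: bool = True,
    pep_max: float = 0.01,
    max_len: int = 29,
    max_missed: int = 2,
) -> list[NoveltyVerdict]:
    """Run the full cascade, returning a verdict for every peptide."""
    parts = classify_non_cds(peptide_evidence, database)
    verdicts = [
        NoveltyVerdict(ev.peptide_j, "cds", [], ev.n_psms)
        for ev in parts["cds"]
    ]
    verdicts += [
        NoveltyVerdict(ev.peptide_j, "rejected", ["ambiguous_mapping"], ev.n_psms)
        for ev in parts["ambiguous"]
    ]
    stage = stringent_filter(
        parts["non_cds"], database, pep_max, max_len, max_missed
    )
    stage = match_updated_annotation(stage, updated_proteomes)
    known = [e for e in database if e.category == "cds"]
    if apply_sav_filter:
        stage = sav_filter(stage, known)
    return verdicts + stage


# ---------------------------------------------------------------------------
# Diagnostics

def modification_enrichment(
    novel_psms: Sequence[QValuedPSM],
    cds_psms: Sequence[QValuedPSM],
) -> list[ModEnrichment]:
    """Per-modification enrichment of novel vs CDS PSMs.

    Two-sided Fisher exact test on the carrying/not-carrying 2x2 table,
    Benjamini-Hochberg adjusted across modification types.
    """
    if not cds_psms:
        raise ValueError("empty CDS PSM set: no enrichment baseline")
    if not novel_psms:
        raise ValueError("empty novel PSM set")

    def carriers(psms: Sequence[QValuedPSM]) -> dict[str, int]:
        counts: dict[str, int] = {}
        for p in psms:
            for name in {n for n, _ in p.merged.modifications}:
                counts[name] = counts.get(name, 0) + 1
        return counts

    novel_c = carriers(novel_psms)
    cds_c = carriers(cds_psms)
    names = sorted(set(novel_c) | set(cds_c))
    n_novel, n_cds = len(novel_psms), len(cds_psms)
    rows = []
    pvals = []
    for name in names:
        a = novel_c.get(name, 0)
        c = cds_c.get(name, 0)
        table = [[a, n_novel - a], [c, n_cds - c]]
        _, p = fisher_exact(table, alternative="two-sided")
        ratio = (
            (a / n_novel) / (c / n_cds) if c > 0 else float("inf")
        )
        rows.append((name, a, c, ratio))
        pvals.append(p)
    adjusted = (
        multipletests(pvals, method="fdr_bh")[1] if pvals else []
    )
    return [
        ModEnrichment(
            modification=name,
            novel_count=a,
            novel_total=n_novel,
            cds_count=c,
            cds_total=n_cds,
            ratio=ratio,
            p_value=p,
            p_adjusted=padj,
        )
        for (name, a, c, ratio), p, padj in zip(rows, pvals, adjusted)
    ]


def rnaseq_support(
    novel_genes: Iterable[str],
    rpkm: RPKMTable,
    threshold: float = 0.75,
) -> dict[str, dict]:
    """Transcriptional support per gene: supported when RPKM exceeds the
    threshold (strictly) in at least one tissue; genes absent from the
    table are flagged ``no_data`` rather than unsupported."""
    out: dict[str, dict] = {}
    for gene in novel_genes:
        tissues = rpkm.tissues_for(gene)
        if not tissues:
            out[gene] = {"status": "no_data", "tissues": {}}
            continue
        flags = {t: v > threshold for t, v in sorted(tissues.items())}
        out[gene] = {
            "status": "supported" if any(flags.values()) else "unsupported",
            "tissues": flags,
        }
    return out
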