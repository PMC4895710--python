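"""Multi-engine PSM consensus, target-decoy q-values and first-tier filters.

A spectrum assignment is accepted only when at least two search engines
report the same identification (peptide in I/L-collapsed J-space with an
identical modification set). The merged PSM carries the worst (highest)
posterior error probability among the agreeing engines, a deliberately
conservative choice. q-values are then estimated by simple target-decoy
competition and the significance filter keeps PSMs at q <= 0.01,
PEP <= 0.05 and length >= 7, discarding contaminant and decoy matches.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .io_formats import PSMRecord, parse_accession
from .search_space import to_J

logger = logging.getLogger(__name__)

#: source_db labels treated as non-biological matches
DECOY_SOURCE = "DECOY"
CONTAMINANT_SOURCE = "CONTAM"


@dataclass(frozen=True)
class MergedPSM:
    """Cross-engine consensus PSM (J-space peptide, worst PEP)."""

    spectrum_id: str
    sample_id: str
    tissue: str
    peptide_j: str
    modifications: frozenset[tuple[str, int]]
    engines: frozenset[str]
    pep: float
    delta_score: float
    is_decoy: bool
    matched_accessions: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.engines) < 2:
            raise ValueError("merged PSM requires >= 2 agreeing engines")


@dataclass(frozen=True)
class QValuedPSM:
    merged: MergedPSM
    q: float

    # convenience passthroughs
    @property
    def spectrum_id(self) -> str:
        return self.merged.spectrum_id

    @property
    def peptide_j(self) -> str:
        return self.merged.peptide_j

    @property
    def pep(self) -> float:
        return self.merged.pep

    @property
    def is_decoy(self) -> bool:
        return self.merged.is_decoy


@dataclass
class PeptideEvidence:
    """Peptide-level aggregate of its significant PSMs.

    Houses the priority-score features: best PEP (P), unmodified and
    modified significant PSM counts (U, M), length (L), delta score of
    the best-PEP PSM (D), replicate count (R) and sequence entropy (E).
    """

    peptide_j: str
    P: float
    U: int
    M: int
    D: float
    R: int
    E: float
    tissues: frozenset[str]
    modifications_seen: frozenset[str]
    matched_accessions: frozenset[str]
    psms: tuple[QValuedPSM, ...] = ()

    @property
    def L(self) -> int:
        return len(self.peptide_j)

    @property
    def n_psms(self) -> int:
        return self.U + self.M


def _all_decoy(accessions: Iterable[str]) -> bool:
    accs = list(accessions)
    return bool(accs) and all(
        a.split("|", 1)[0] == DECOY_SOURCE for a in accs
    )


def _any_contaminant(accessions: Iterable[str]) -> bool:
    return any(a.split("|", 1)[0] == CONTAMINANT_SOURCE for a in accessions)


def merge_engines(
    per_engine_psms: Sequence[Sequence[PSMRecord]],
    min_engines: int = 2,
    sequence_only: bool = False,
) -> list[MergedPSM]:
    """Consensus-merge per-engine PSM lists.

    Agreement is evaluated on (spectrum, J-space peptide, modification
    set); ``sequence_only=True`` relaxes agreement to the peptide
    sequence alone. Within one engine only the rank-1 assignment per
    spectrum (best engine score) is considered; duplicates trigger a
    warning. The merged PEP is the maximum over agreeing engines and the
    delta score is taken from the agreeing engine with the best PEP.
    """
    # rank-1 per (spectrum, engine)
    best: dict[tuple[str, str], PSMRecord] = {}
    for records in per_engine_psms:
        for rec in records:
            key = (rec.spectrum_id, rec.engine)
            prev = best.get(key)
            if prev is None:
                best[key] = rec
            else:
                warnings.warn(
                    f"duplicate assignment for spectrum {rec.spectrum_id} "
                    f"engine {rec.engine}; keeping rank-1 by score"
                )
                if rec.score > prev.score:
                    best[key] = rec

    groups: dict[tuple, list[PSMRecord]] = {}
    for rec in best.values():
        pj = to_J(rec.peptide)
        mods = frozenset() if sequence_only else rec.modifications
        groups.setdefault((rec.spectrum_id, pj, mods), []).append(rec)

    merged: list[MergedPSM] = []
    for (spectrum_id, pj, _mods), members in sorted(
        groups.items(), key=lambda kv: (kv[0][0], kv[0][1])
    ):
        engines = frozenset(m.engine for m in members)
        if len(engines) < min_engines:
            continue
        best_member = min(members, key=lambda m: (m.pep, m.engine))
        accessions = frozenset().union(*(m.matched_accessions for m in members))
        merged.append(
            MergedPSM(
                spectrum_id=spectrum_id,
                sample_id=best_member.sample_id,
                tissue=best_member.tissue,
                peptide_j=pj,
                modifications=best_member.modifications,
                engines=engines,
                pep=max(m.pep for m in members),
                delta_score=best_member.delta_score,
                is_decoy=_all_decoy(accessions),
                matched_accessions=accessions,
            )
        )
    return merged


def compute_qvalues(merged: Sequence[MergedPSM]) -> list[QValuedPSM]:
    """Target-decoy q-values: FDR = #decoys/#targets at each PEP
    threshold, monotonized from the bottom of the ranking.

    Ties at equal PEP rank targets before decoys, then by spectrum id,
    for determinism. Decoy PSMs receive q-values too (diagnostics); the
    significance filter removes them later.
    """
    order = sorted(merged, key=lambda m: (m.pep, m.is_decoy, m.spectrum_id))
    fdrs: list[float] = []
    n_targets = n_decoys = 0
    for m in order:
        if m.is_decoy:
            n_decoys += 1
        else:
            n_targets += 1
        fdrs.append(n_decoys / n_targets if n_targets else 0.0)
    out: list[QValuedPSM] = [None] * len(order)  # type: ignore[list-item]
    running = float("inf")
    for i in range(len(order) - 1, -1, -1):
        running = min(running, fdrs[i])
        out[i] = QValuedPSM(order[i], running)
    return out


def filter_significant(
    qvalued: Sequence[QValuedPSM],
    q_max: float = 0.01,
    pep_max: float = 0.05,
    min_len: int = 7,
) -> list[QValuedPSM]:
    """First-tier significance filter.

    Keeps PSMs with q <= q_max, PEP <= pep_max and length >= min_len;
    removes decoy-only matches and, conservatively, anything matching a
    contaminant even when a real entry is also matched.
    """
    kept = []
    for qp in qvalued:
        m = qp.merged
        if qp.q > q_max or m.pep > pep_max or len(m.peptide_j) < min_len:
            continue
        if m.is_decoy or _any_contaminant(m.matched_accessions):
            continue
        kept.append(qp)
    return kept


def aggregate_peptides(
    significant_psms: Sequence[QValuedPSM],
) -> list[PeptideEvidence]:
    """Collapse significant PSMs into per-peptide evidence records."""
    from .scoring import sequence_entropy  # deferred: scoring owns entropy

    by_peptide: dict[str, list[QValuedPSM]] = {}
    for qp in significant_psms:
        by_peptide.setdefault(qp.merged.peptide_j, []).append(qp)

    evidence = []
    for pj in sorted(by_peptide):
        members = by_peptide[pj]
        best = min(members, key=lambda qp: (qp.merged.pep, qp.spectrum_id))
        unmodified = [m for m in members if not m.merged.modifications]
        accessions = frozenset().union(
            *(m.merged.matched_accessions for m in members)
        )
        evidence.append(
            PeptideEvidence(
                peptide_j=pj,
                P=best.merged.pep,
                U=len(unmodified),
                M=len(members) - len(unmodified),
                D=best.merged.delta_score,
                R=len({m.merged.sample_id for m in members}),
                E=sequence_entropy(pj),
                tissues=frozenset(m.merged.tissue for m in members),
                modifications_seen=frozenset(
                    name for m in members for name, _ in m.merged.modifications
                ),
                matched_accessions=accessions,
                psms=tuple(members),
            )
        )
    return evidence
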