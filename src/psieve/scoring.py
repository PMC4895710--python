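"""Priority annotation score.

Ranks novel peptide identifications for manual annotation. The peptide
score combines evidence features that ordinary PSM scores ignore:

    S_i = -log10(P_i) + U_i + M_i/Wm + L_i + D_i/Wd + R_i/Wr + E_i

where P_i is the best PEP over the peptide's significant PSMs, U_i and
M_i the unmodified/modified significant PSM counts, L_i the peptide
length, D_i the delta score of the best-PEP PSM, R_i the number of
replicate samples and E_i the Shannon entropy of the amino-acid
composition in bits. The weights Wm=5, Wd=10, Wr=5 scale each feature to
a comparable magnitude so no single one dominates; they can be tuned for
other data sets. A protein's score is the sum over its distinct
unambiguous peptides; a total around 100 marked the point where
annotation became probable in the human survey this implements, but the
score ranks candidates — it is not a calibrated probability.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from .psm_processing import PeptideEvidence

#: smallest PEP admitted into the -log10 term
DEFAULT_PEP_FLOOR = 1e-20


@dataclass(frozen=True)
class ScoreWeights:
    """Feature down-weights: modified PSMs (Wm), delta score (Wd),
    replicates (Wr)."""

    Wm: float = 5.0
    Wd: float = 10.0
    Wr: float = 5.0

    def __post_init__(self) -> None:
        if min(self.Wm, self.Wd, self.Wr) <= 0:
            raise ValueError("score weights must be positive")


@dataclass(frozen=True)
class PeptideScore:
    peptide_j: str
    features: PeptideEvidence
    score: float


@dataclass(frozen=True)
class ProteinScore:
    identifier: str
    peptide_scores: tuple[PeptideScore, ...]
    total: float
    rank: int


def sequence_entropy(peptide: str) -> float:
    """Shannon entropy of the amino-acid composition, in bits.

    J counts as a single residue type. Bounded by log2(min(N, #types)).
    """
    if not peptide:
        raise ValueError("empty peptide")
    n = len(peptide)
    return -sum(
        (c / n) * math.log2(c / n) for c in Counter(peptide).values()
    )


def peptide_priority_score(
    evidence: PeptideEvidence,
    weights: ScoreWeights = ScoreWeights(),
    pep_floor: float = DEFAULT_PEP_FLOOR,
) -> PeptideScore:
    """Score one peptide from its evidence features.

    Monotone non-decreasing in U, M, L, D, R and E; non-increasing in P.
    A PEP of exactly zero is clamped to ``pep_floor`` with a warning.
    """
    p = evidence.P
    if p > 1.0:
        raise ValueError(f"PEP > 1 for {evidence.peptide_j}: {p}")
    if p <= 0.0:
        warnings.warn(
            f"PEP of {p} for {evidence.peptide_j} clamped to {pep_floor}"
        )
        p = pep_floor
    score = (
        -math.log10(p)
        + evidence.U
        + evidence.M / weights.Wm
        + evidence.L
        + evidence.D / weights.Wd
        + evidence.R / weights.Wr
        + evidence.E
    )
    return PeptideScore(evidence.peptide_j, evidence, score)


def protein_priority_score(
    groups: Mapping[str, frozenset[str] | set[str]],
    peptide_scores: Sequence[PeptideScore],
) -> list[ProteinScore]:
    """Rank proteins (or genes) by the summed scores of their distinct
    unambiguous peptides.

    A peptide matching more than one group is ambiguous and contributes
    to none. Groups left with no unambiguous peptide are excluded with a
    warning. Output is sorted by descending total with a lexicographic
    tie-break on the identifier; ranks are 1-based.
    """
    score_by_peptide = {ps.peptide_j: ps for ps in peptide_scores}
    counts: Counter[str] = Counter()
    for peptides in groups.values():
        counts.update(set(peptides))
    ambiguous = {p for p, c in counts.items() if c > 1}

    scored: list[tuple[str, tuple[PeptideScore, ...], float]] = []
    for ident in sorted(groups):
        members = tuple(
            score_by_peptide[p]
            for p in sorted(groups[ident])
            if p not in ambiguous and p in score_by_peptide
        )
        if not members:
            warnings.warn(f"group {ident} has no unambiguous scored peptide; excluded")
            continue
        scored.append((ident, members, sum(ps.score for ps in members)))

    scored.sort(key=lambda t: (-t[2], t[0]))
    return [
        ProteinScore(ident, members, total, rank)
        for rank, (ident, members, total) in enumerate(scored, 1)
    ]
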