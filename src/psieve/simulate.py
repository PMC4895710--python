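"""Synthetic proteogenomic data with known ground truth.

Generates a toy composite search space (annotated proteins, noncoding
transcript models with planted translatable ORFs, planted single-
substitution variant peptides, contaminants, decoys) and per-engine PSM
tables, so that every pipeline stage — consensus merging, target-decoy
FDR, parsimony inference, the novelty cascade — can be exercised and its
error rates measured against truth without any external download.

PEPs are simulated directly rather than via spectra: correct matches
draw from a Beta distribution concentrated near zero, incorrect matches
from the uniform distribution, the standard mixture picture behind
posterior error probabilities. Incorrect matches are mostly
engine-private while correct matches replicate across engines, which is
precisely the behaviour the two-engine consensus rule exploits.
Deamidation is sprinkled at a boosted rate on incorrect matches,
emulating the artefact enrichment observed among spurious novel
identifications.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import (
    Accession,
    PSMRecord,
    SearchSpaceEntry,
    write_fasta,
    write_psm_table,
)
from .novelty import NoveltyVerdict
from .psm_processing import QValuedPSM
from .search_space import (
    DatabaseStats,
    build_search_space,
    digest,
    normalize_ile,
)

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: substitution targets for variant peptides: excludes I/L (J-ambiguous)
#: and K/R (would change the cleavage structure)
_SAV_TARGETS = "ACDEFGHMNPQSTVWY"

_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic data.

    Defaults emulate a small multi-tissue survey: a few dozen annotated
    proteins, a handful of noncoding models with planted novel ORFs and
    planted single-substitution (SAV-like) peptides, three search
    engines, and a realistic share of incorrect assignments.
    """

    seed: int = 0
    n_cds_proteins: int = 30
    n_noncoding_models: int = 6
    n_planted_novel_orfs: int = 4
    n_sav_variants: int = 5
    n_contaminants: int = 2
    n_spectra_per_sample: int = 500
    samples: tuple[tuple[str, str], ...] = (
        ("S1", "testis"), ("S2", "liver"), ("S3", "brain"), ("S4", "testis"),
    )
    engines: tuple[str, ...] = ("mascot", "msgfplus", "sequest")
    incorrect_match_fraction: float = 0.2
    #: Beta(a, b) for correct-match PEPs (concentrated near zero)
    pep_correct_beta: tuple[float, float] = (0.3, 60.0)
    engine_detect_prob_correct: float = 0.9
    #: probability an incorrect match is replicated in a second engine
    engine_agreement_prob_incorrect: float = 0.15
    #: share of correct spectra drawn from planted novel / SAV peptides
    novel_peptide_fraction: float = 0.06
    sav_peptide_fraction: float = 0.04
    modification_rates: tuple[tuple[str, float], ...] = (
        ("oxidation", 0.06),
        ("deamidation", 0.04),
        ("acetylation", 0.015),
        ("carbamidomethyl", 0.015),
        ("pyro-glu", 0.01),
    )
    deamidation_incorrect_boost: float = 4.0

    def __post_init__(self) -> None:
        for name, value in (
            ("incorrect_match_fraction", self.incorrect_match_fraction),
            ("engine_detect_prob_correct", self.engine_detect_prob_correct),
            ("engine_agreement_prob_incorrect",
             self.engine_agreement_prob_incorrect),
        ):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} outside [0,1]: {value}")


@dataclass(frozen=True)
class GroundTruth:
    """Truth for one simulated spectrum's assignment."""

    spectrum_id: str
    generating_accession: str
    correct: bool
    origin: str  # cds | planted_novel | sav_variant | random_wrong


@dataclass
class SimTruth:
    """Ground truth for a whole simulation."""

    psm_truth: dict[str, GroundTruth] = field(default_factory=dict)
    planted_proteins: dict[str, str] = field(default_factory=dict)  # id -> seq (L-space)
    sav_peptides: dict[str, str] = field(default_factory=dict)  # peptide -> parent CDS acc


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_AA20), size=length))


def _reverse_translate(protein: str) -> str:
    return "".join(_CODON[a] for a in protein)


def _embed_orf(rng: np.random.Generator, protein: str) -> str:
    """Nucleotide model carrying the protein as a frame-0 ORF bounded by
    stop codons, with random padding."""
    pad5 = "".join(rng.choice(list("ACGT"), size=3 * int(rng.integers(3, 10))))
    pad3 = "".join(rng.choice(list("ACGT"), size=3 * int(rng.integers(3, 10))))
    return pad5 + "TAA" + _reverse_translate(protein) + "TAA" + pad3


def simulate_search_space(
    config: SimConfig,
) -> tuple[list[SearchSpaceEntry], DatabaseStats, SimTruth]:
    """Build the synthetic target+decoy database with planted content."""
    if config.n_cds_proteins < 1:
        raise ValueError("n_cds_proteins must be >= 1")
    rng = np.random.default_rng(config.seed)
    truth = SimTruth()

    cds = [
        SearchSpaceEntry(
            Accession("GENCODE", f"SIMCDS{i:04d}"),
            _random_protein(rng, int(rng.integers(100, 601))),
            "cds",
        )
        for i in range(config.n_cds_proteins)
    ]
    contaminants = [
        SearchSpaceEntry(
            Accession("CONTAM", f"SIMCONT{i:02d}"),
            _random_protein(rng, int(rng.integers(100, 301))),
            "contaminant",
        )
        for i in range(config.n_contaminants)
    ]

    nt_models: list[tuple[Accession, str]] = []
    model_idx = 0

    # planted novel ORFs: tryptic-peptide-rich small proteins
    for i in range(config.n_planted_novel_orfs):
        pieces = ["M"]
        for _ in range(int(rng.integers(3, 6))):
            pieces.append(_random_protein(rng, int(rng.integers(8, 16))))
            pieces.append(rng.choice(["K", "R"]))
        protein = "".join(pieces)
        ident = f"MODEL{model_idx:04d}"
        model_idx += 1
        nt_models.append((Accession("RNASEQ", ident), _embed_orf(rng, protein)))
        truth.planted_proteins[ident] = normalize_ile(protein, "to_L")

    # planted SAV variants: one substitution away from a CDS tryptic peptide
    n_sav_made = 0
    guard = 0
    while n_sav_made < config.n_sav_variants and guard < 1000:
        guard += 1
        parent = cds[int(rng.integers(len(cds)))]
        peps = [
            p.sequence
            for p in digest(parent.sequence, max_missed=0)
            if 9 <= len(p.sequence) <= 24 and p.sequence[-1] in "KR"
        ]
        if not peps:
            continue
        original = peps[int(rng.integers(len(peps)))]
        if original[0] == "P":  # would break the tryptic context downstream
            continue
        pos = int(rng.integers(1, len(original) - 1))
        if original[pos] in "KR":
            continue
        choices = [a for a in _SAV_TARGETS if a != original[pos]]
        variant = (
            original[:pos]
            + str(rng.choice(choices))
            + original[pos + 1:]
        )
        # embed in a tryptic context so the variant peptide digests out cleanly
        carrier = (
            _random_protein(rng, 6).replace("K", "A").replace("R", "A")
            + "K" + variant
            + _random_protein(rng, 6).replace("K", "A").replace("R", "A")
        )
        ident = f"MODEL{model_idx:04d}"
        model_idx += 1
        nt_models.append((Accession("RNASEQ", ident), _embed_orf(rng, carrier)))
        truth.sav_peptides[normalize_ile(variant, "to_L")] = str(parent.accession)
        n_sav_made += 1

    # background noncoding models with no planted content
    for _ in range(config.n_noncoding_models):
        ident = f"MODEL{model_idx:04d}"
        model_idx += 1
        nt = "".join(rng.choice(list("ACGT"), size=int(rng.integers(300, 900))))
        nt_models.append((Accession("RNASEQ", ident), nt))

    entries, stats = build_search_space(
        cds,
        noncoding=(),
        nt_models=nt_models,
        contaminants=contaminants,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return entries, stats, truth


def _digest_index(
    entries: Sequence[SearchSpaceEntry],
    min_len: int = 7,
    max_len: int = 30,
    max_missed: int = 2,
) -> dict[str, set[str]]:
    index: dict[str, set[str]] = {}
    for e in entries:
        for p in digest(e.sequence, max_missed=max_missed):
            if min_len <= len(p.sequence) <= max_len:
                index.setdefault(p.sequence, set()).add(str(e.accession))
    return index


def _sprinkle_mods(
    rng: np.random.Generator,
    peptide: str,
    rates: dict[str, float],
    deamidation_boost: float = 1.0,
) -> frozenset[tuple[str, int]]:
    mods: set[tuple[str, int]] = set()
    for name, rate in rates.items():
        if name == "deamidation":
            rate = min(1.0, rate * deamidation_boost)
        if rng.random() >= rate:
            continue
        if name == "oxidation":
            sites = [i + 1 for i, a in enumerate(peptide) if a == "M"]
            if sites:
                mods.add((name, int(rng.choice(sites))))
        elif name == "deamidation":
            sites = [i + 1 for i, a in enumerate(peptide) if a in "NQ"]
            if sites:
                mods.add((name, int(rng.choice(sites))))
        elif name in ("acetylation", "carbamidomethyl"):
            mods.add((name, 0))
        elif name == "pyro-glu":
            if peptide[0] in "QE":
                mods.add((name, 0))
    return frozenset(mods)


def simulate_psm_tables(
    entries: Sequence[SearchSpaceEntry],
    truth: SimTruth,
    config: SimConfig,
) -> tuple[dict[str, list[PSMRecord]], SimTruth]:
    """Emit per-engine PSM tables for the simulated spectra.

    Correct matches sample target tryptic peptides (annotated, planted
    novel or planted variant) with low PEPs replicated across engines;
    incorrect matches sample decoy or mismatched annotated peptides with
    uniform PEPs, mostly confined to a single engine.
    """
    rng = np.random.default_rng(config.seed + 1)
    rates = dict(config.modification_rates)

    index = _digest_index(entries)
    planted_set = set(truth.planted_proteins.values())
    cds_accs = {
        str(e.accession) for e in entries if e.category == "cds"
    }
    decoy_accs = {
        str(e.accession) for e in entries if e.category == "decoy"
    }

    def pool(predicate) -> list[str]:
        return sorted(p for p, accs in index.items() if predicate(p, accs))

    cds_pool = pool(lambda p, accs: accs & cds_accs)
    decoy_pool = pool(lambda p, accs: accs <= decoy_accs)
    sav_pool = sorted(p for p in truth.sav_peptides if p in index)
    novel_pool = pool(
        lambda p, accs: not (accs & cds_accs)
        and not (accs & decoy_accs)
        and p not in truth.sav_peptides
        and any(p in prot for prot in planted_set)
    )

    a_correct, b_correct = config.pep_correct_beta
    tables: dict[str, list[PSMRecord]] = {e: [] for e in config.engines}
    engines = list(config.engines)

    for sample_id, tissue in config.samples:
        for scan in range(config.n_spectra_per_sample):
            spectrum_id = f"{sample_id}:scan{scan:06d}"
            incorrect = rng.random() < config.incorrect_match_fraction
            if incorrect:
                if decoy_pool and (not cds_pool or rng.random() < 0.5):
                    peptide = decoy_pool[int(rng.integers(len(decoy_pool)))]
                else:
                    peptide = cds_pool[int(rng.integers(len(cds_pool)))]
                origin = "random_wrong"
                pep_base = float(rng.uniform(0.0, 1.0))
                first = int(rng.integers(len(engines)))
                engine_mask = [i == first for i in range(len(engines))]
                if rng.random() < config.engine_agreement_prob_incorrect:
                    second = int(rng.integers(len(engines)))
                    if second != first:
                        engine_mask[second] = True
                delta = float(rng.gamma(2.0, 5.0))
            else:
                u = rng.random()
                if sav_pool and u < config.sav_peptide_fraction:
                    peptide = sav_pool[int(rng.integers(len(sav_pool)))]
                    origin = "sav_variant"
                elif novel_pool and u < (
                    config.sav_peptide_fraction + config.novel_peptide_fraction
                ):
                    peptide = novel_pool[int(rng.integers(len(novel_pool)))]
                    origin = "planted_novel"
                else:
                    peptide = cds_pool[int(rng.integers(len(cds_pool)))]
                    origin = "cds"
                pep_base = float(
                    np.clip(rng.beta(a_correct, b_correct), 1e-12, 1.0)
                )
                engine_mask = [
                    rng.random() < config.engine_detect_prob_correct
                    for _ in engines
                ]
                delta = float(rng.gamma(3.0, 15.0))
            if not any(engine_mask):
                continue  # spectrum went unidentified

            mods = _sprinkle_mods(
                rng,
                peptide,
                rates,
                config.deamidation_incorrect_boost if incorrect else 1.0,
            )
            accessions = frozenset(index[peptide])
            charge = int(rng.integers(2, 4))
            for engine, present in zip(engines, engine_mask):
                if not present:
                    continue
                pep_e = float(
                    np.clip(pep_base * np.exp(rng.normal(0.0, 0.3)),
                            1e-12, 1.0)
                )
                tables[engine].append(
                    PSMRecord(
                        spectrum_id=spectrum_id,
                        sample_id=sample_id,
                        tissue=tissue,
                        engine=engine,
                        peptide=peptide,
                        modifications=mods,
                        charge=charge,
                        score=-10.0 * np.log10(pep_e),
                        delta_score=delta,
                        pep=pep_e,
                        matched_accessions=accessions,
                    )
                )
            hit_accs = sorted(accessions)
            truth.psm_truth[spectrum_id] = GroundTruth(
                spectrum_id=spectrum_id,
                generating_accession=hit_accs[0],
                correct=not incorrect,
                origin=origin,
            )
    return tables, truth


# ---------------------------------------------------------------------------
# Truth-based evaluation

def evaluate_truth(
    survivors: Sequence[QValuedPSM],
    truth: SimTruth,
    verdicts: Sequence[NoveltyVerdict] = (),
) -> dict[str, float]:
    """Measure realized error rates of pipeline outputs against truth.

    Returns realized FDR among surviving target PSMs, the planted
    novel-ORF recovery rate, and the SAV leak rate (variant peptides
    surviving the SAV filter over variant peptides reaching it).
    """
    n_false = 0
    for qp in survivors:
        gt = truth.psm_truth.get(qp.spectrum_id)
        if gt is None:
            raise ValueError(f"spectrum {qp.spectrum_id} missing from truth")
        if not gt.correct:
            n_false += 1
    realized_fdr = n_false / len(survivors) if survivors else 0.0

    # verdicts live in J-space; truth sequences are kept in database
    # (L) space, so compare after collapsing
    from .search_space import to_J

    candidates = {
        v.peptide_j for v in verdicts if v.status == "novel_candidate"
    }
    recovered = sum(
        1
        for protein in truth.planted_proteins.values()
        if any(p in to_J(protein) for p in candidates)
    )
    recovery = (
        recovered / len(truth.planted_proteins)
        if truth.planted_proteins
        else float("nan")
    )

    sav_set = {to_J(p) for p in truth.sav_peptides}
    reaching = [
        v
        for v in verdicts
        if v.peptide_j in sav_set
        and not (set(v.rejection_reasons) - {"sav_distance"})
    ]
    leaked = [v for v in reaching if v.status == "novel_candidate"]
    sav_leak = len(leaked) / len(reaching) if reaching else float("nan")

    return {
        "realized_fdr": realized_fdr,
        "n_survivors": float(len(survivors)),
        "n_false_survivors": float(n_false),
        "novel_orf_recovery": recovery,
        "sav_leak_rate": sav_leak,
        "n_sav_reaching": float(len(reaching)),
    }


def write_simulation(
    outdir: str | Path,
    config: SimConfig,
) -> tuple[list[SearchSpaceEntry], dict[str, list[PSMRecord]], SimTruth]:
    """Run a simulation and write db FASTA, per-engine PSM TSVs, a truth
    TSV and a GTF of planted models under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries, stats, truth = simulate_search_space(config)
    tables, truth = simulate_psm_tables(entries, truth, config)
    write_fasta(entries, outdir / "db.fa")
    for engine, records in tables.items():
        write_psm_table(records, outdir / f"psm_{engine}.tsv")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("spectrum_id\tgenerating_accession\tcorrect\torigin\n")
        for sid in sorted(truth.psm_truth):
            gt = truth.psm_truth[sid]
            fh.write(
                f"{gt.spectrum_id}\t{gt.generating_accession}\t"
                f"{int(gt.correct)}\t{gt.origin}\n"
            )
    with open(outdir / "models.gtf", "w") as fh:
        pos = 1000
        for ident, protein in sorted(truth.planted_proteins.items()):
            start, end = pos, pos + 3 * len(protein) - 1
            fh.write(
                f"chrSIM\tpsieve_sim\tCDS\t{start}\t{end}\t.\t+\t0\t"
                f'gene_id "GSIM_{ident}"; transcript_id "TSIM_{ident}"; '
                f'protein_id "RNASEQ|{ident}";\n'
            )
            pos = end + 1000
    return entries, tables, truth
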