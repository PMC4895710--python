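"""Parsimony grouping, gene clustering and genomic projection."""

from itertools import combinations

import numpy as np
import pytest

import psieve as ps
from psieve.io_formats import Accession, Locus, SearchSpaceEntry, TranscriptModel
from psieve.psm_processing import PeptideEvidence


def evidence_for(peptide):
    return PeptideEvidence(
        peptide_j=ps.to_J(peptide), P=0.001, U=2, M=0, D=10.0, R=1,
        E=ps.sequence_entropy(ps.to_J(peptide)), tissues=frozenset({"t"}),
        modifications_seen=frozenset(), matched_accessions=frozenset(),
    )


def db_entry(ident, seq, category="cds", source="GENCODE"):
    return SearchSpaceEntry(Accession(source, ident), seq, category)


def exhaustive_min_cover(sets, universe):
    """Oracle: smallest number of sets covering the universe."""
    ids = sorted(sets)
    for k in range(1, len(ids) + 1):
        for combo in combinations(ids, k):
            if set().union(*(sets[i] for i in combo)) >= universe:
                return k
    return len(ids)


class TestInferProteinGroups:
    def test_subset_protein_is_subsumed(self):
        # p1 only in A; p2 in both A and B -> B's evidence is a subset
        db = [
            db_entry("A", "AAAWWWKCCCYYYK"),
            db_entry("B", "CCCYYYK"),
        ]
        evidence = [evidence_for("AAAWWWK"), evidence_for("CCCYYYK")]
        groups = ps.infer_protein_groups(evidence, db)
        assert len(groups) == 1
        (g,) = groups
        assert g.member_accessions == {"GENCODE|A"}
        assert g.subsumed_accessions == {"GENCODE|B"}
        assert g.peptides == {"AAAWWWK", "CCCYYYK"}

    def test_identical_evidence_clusters(self):
        db = [
            db_entry("C", "AAAWWWKGGG"),
            db_entry("D", "TTTAAAWWWKE"),
        ]
        evidence = [evidence_for("AAAWWWK")]
        (g,) = ps.infer_protein_groups(evidence, db)
        assert g.member_accessions == {"GENCODE|C", "GENCODE|D"}

    def test_unmatched_peptide_is_an_error(self):
        db = [db_entry("A", "AAAWWWK")]
        with pytest.raises(ValueError, match="no database entry"):
            ps.infer_protein_groups([evidence_for("CCCCCCK")], db)

    def _random_instance(self, rng):
        n_prot = int(rng.integers(2, 9))
        n_pep = int(rng.integers(2, 16))
        alphabet = "ACDEFGHKMNPQSTVWY"
        peptides = []
        while len(peptides) < n_pep:
            p = "".join(rng.choice(list(alphabet), size=8)) + "K"
            if p not in peptides:
                peptides.append(p)
        db = []
        membership = {}
        for i in range(n_prot):
            chosen = [
                p for p in peptides if rng.random() < 0.45
            ] or [peptides[int(rng.integers(n_pep))]]
            membership[f"GENCODE|P{i}"] = set(chosen)
            db.append(db_entry(f"P{i}", "".join(chosen)))
        covered = set().union(*membership.values())
        evidence = [evidence_for(p) for p in sorted(covered)]
        return db, membership, covered, evidence

    def test_group_count_matches_exact_cover_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            db, membership, covered, evidence = self._random_instance(rng)
            groups = ps.infer_protein_groups(evidence, db)
            # oracle on distinct evidence sets (clusters)
            distinct = {frozenset(v) for v in membership.values()}
            sets = {i: s for i, s in enumerate(sorted(distinct, key=sorted))}
            assert len(groups) == exhaustive_min_cover(sets, covered)

    def test_cover_completeness_and_irredundancy(self):
        rng = np.random.default_rng(21)
        for _ in range(40):
            db, _, covered, evidence = self._random_instance(rng)
            groups = ps.infer_protein_groups(evidence, db)
            assert set().union(*(g.peptides for g in groups)) == covered
            for g in groups:
                rest = [h for h in groups if h is not g]
                if rest:
                    others = set().union(*(h.peptides for h in rest))
                    assert g.peptides - others, "removing a group orphans nothing"
                assert g.unique_peptides, "group without a unique peptide"
                assert g.unique_peptides <= g.peptides


class TestMapGroupsToGenes:
    def _group(self, accs, peps):
        return ps.ProteinGroup(
            member_accessions=frozenset(accs),
            peptides=frozenset(peps),
            unique_peptides=frozenset(peps),
        )

    def test_isoforms_collapse_to_one_gene(self):
        groups = [self._group({"A1", "A2"}, {"p1", "p2"})]
        mapping = {"A1": "G1", "A2": "G1"}
        clusters, counts, unmapped = ps.map_groups_to_genes(groups, mapping)
        assert len(clusters) == 1
        assert clusters[0].gene_ids == {"G1"}
        assert not unmapped

    def test_paralog_family_forms_multi_gene_cluster(self):
        groups = [self._group({"A1", "B1"}, {"p1"})]
        mapping = {"A1": "G1", "B1": "G2"}
        clusters, _, _ = ps.map_groups_to_genes(groups, mapping)
        assert clusters[0].gene_ids == {"G1", "G2"}

    def test_subset_gene_not_counted(self):
        groups = [
            self._group({"A1"}, {"p1", "p2"}),
            self._group({"B1"}, {"p1"}),
        ]
        mapping = {"A1": "G1", "B1": "G2"}
        clusters, counts, _ = ps.map_groups_to_genes(groups, mapping)
        assert len(clusters) == 1
        assert clusters[0].gene_ids == {"G1"}

    def test_counts_non_increasing_with_threshold(self, small_sim_survivors):
        entries, _, _, _, _, evidence = small_sim_survivors
        groups = ps.infer_protein_groups(evidence, entries)
        mapping = {
            str(e.accession): f"GENE_{e.accession.identifier}"
            for e in entries if e.category == "cds"
        }
        _, counts, unmapped = ps.map_groups_to_genes(groups, mapping)
        assert counts[1] >= counts[2] >= counts[3]
        assert all(
            not (g.member_accessions & set(mapping)) for g in unmapped
        )

    def test_unmapped_groups_routed_not_raised(self):
        groups = [self._group({"RNASEQ|M1"}, {"p1"})]
        clusters, _, unmapped = ps.map_groups_to_genes(groups, {})
        assert clusters == []
        assert len(unmapped) == 1


def naive_projection(peptide_start_aa, peptide_len, model):
    """Per-base oracle: walk every CDS nucleotide in transcription order."""
    genome_positions = []
    for seg in model.cds_segments:
        rng = (
            range(seg.start, seg.end + 1)
            if model.strand == "+"
            else range(seg.end, seg.start - 1, -1)
        )
        genome_positions.extend((seg.chrom, p) for p in rng)
    lo = 3 * (peptide_start_aa - 1)
    hi = 3 * (peptide_start_aa - 1 + peptide_len)
    hit = genome_positions[lo:hi]
    segments_touched = set()
    for chrom, pos in hit:
        for i, seg in enumerate(model.cds_segments):
            if seg.start <= pos <= seg.end:
                segments_touched.add(i)
    return {p for _, p in hit}, len(segments_touched) >= 2


def model_from_segments(segs, strand, tid="T1"):
    reverse = strand == "-"
    ordered = tuple(
        sorted((Locus("chr1", s, e, strand) for s, e in segs),
               key=lambda l: l.start, reverse=reverse)
    )
    return TranscriptModel(tid, "G1", f"PROT_{tid}", strand, ordered)


class TestMapPeptideToGenome:
    def test_single_segment_never_crosses(self):
        model = model_from_segments([(101, 160)], "+")
        segs, crosses = ps.map_peptide_to_genome(3, 4, model)
        assert not crosses
        assert len(segs) == 1

    def test_two_segment_crossing_derived(self):
        # 30+30 nt segments; residues 9-12 occupy nt 25-36, spanning both
        model = model_from_segments([(101, 130), (201, 230)], "+")
        segs, crosses = ps.map_peptide_to_genome(9, 4, model)
        assert crosses
        assert [(s.start, s.end) for s in segs] == [(125, 130), (201, 206)]

    def test_first_segment_only(self):
        model = model_from_segments([(101, 130), (201, 230)], "+")
        segs, crosses = ps.map_peptide_to_genome(1, 5, model)
        assert not crosses
        assert [(s.start, s.end) for s in segs] == [(101, 115)]

    def test_minus_strand_projection(self):
        model = model_from_segments([(101, 130), (201, 230)], "-")
        # first codon sits at the top of the downstream (higher) segment
        segs, crosses = ps.map_peptide_to_genome(1, 5, model)
        assert not crosses
        assert [(s.start, s.end) for s in segs] == [(216, 230)]

    def test_peptide_beyond_cds_rejected(self):
        model = model_from_segments([(101, 130)], "+")
        with pytest.raises(ValueError, match="T1"):
            ps.map_peptide_to_genome(9, 4, model)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_agrees_with_per_base_oracle(self, strand):
        rng = np.random.default_rng(5 if strand == "+" else 6)
        for _ in range(150):
            n_seg = int(rng.integers(1, 5))
            pos = 100
            segs = []
            total = 0
            for _ in range(n_seg):
                length = 3 * int(rng.integers(3, 30))
                segs.append((pos, pos + length - 1))
                total += length
                pos += length + int(rng.integers(50, 200))
            model = model_from_segments(segs, strand)
            n_aa = total // 3
            start = int(rng.integers(1, n_aa + 1))
            plen = int(rng.integers(1, n_aa - start + 2))
            got_segs, got_cross = ps.map_peptide_to_genome(start, plen, model)
            oracle_pos, oracle_cross = naive_projection(start, plen, model)
            got_pos = {
                p for s in got_segs for p in range(s.start, s.end + 1)
            }
            assert got_pos == oracle_pos
            assert got_cross == oracle_cross


class TestAlternativeSplicing:
    def _setup(self):
        # gene G with transcripts T1, T2 sharing a core and each having
        # a unique region
        shared = "AAAGGGTTTKCCCWWWR"
        t1 = shared + "MMMEEEDDDK"
        t2 = shared + "HHHFFFSSSR"
        models = [
            model_from_segments([(101, 100 + 3 * len(t1))], "+", "T1"),
            model_from_segments([(501, 500 + 3 * len(t2))], "+", "T2"),
        ]
        proteins = {"PROT_T1": t1, "PROT_T2": t2}
        return models, proteins

    def test_transcript_unique_evidence_flags_gene(self):
        models, proteins = self._setup()
        evidence = [evidence_for("MMMEEEDDDK"), evidence_for("HHHFFFSSSR")]
        flagged = ps.detect_alternative_splicing(evidence, models, proteins)
        assert flagged == {"G1": ["T1", "T2"]}

    def test_shared_peptides_do_not_flag(self):
        models, proteins = self._setup()
        evidence = [evidence_for("AAAGGGTTTK")]
        assert ps.detect_alternative_splicing(evidence, models, proteins) == {}

    def test_strict_length_rule_drops_long_unique_peptide(self):
        models, proteins = self._setup()
        long_unique = "HHHFFFSSSR"
        # lengthen T2's unique peptide beyond 30 aa
        t2 = proteins["PROT_T2"] + "A" * 24
        proteins = {**proteins, "PROT_T2": t2}
        models[1] = model_from_segments([(501, 500 + 3 * len(t2))], "+", "T2")
        ev31 = evidence_for(long_unique + "A" * 21)  # 31-mer
        evidence = [evidence_for("MMMEEEDDDK"), ev31]
        assert ps.detect_alternative_splicing(evidence, models, proteins) == {}
        relaxed = ps.detect_alternative_splicing(
            evidence, models, proteins, strict=False
        )
        assert relaxed == {"G1": ["T1", "T2"]}

    def test_strict_requires_unmodified_evidence(self):
        models, proteins = self._setup()
        ev = evidence_for("MMMEEEDDDK")
        modified_only = ps.PeptideEvidence(
            peptide_j="HHHFFFSSSR", P=0.001, U=0, M=2, D=10.0, R=1,
            E=3.0, tissues=frozenset(), modifications_seen=frozenset({"oxidation"}),
            matched_accessions=frozenset(),
        )
        assert ps.detect_alternative_splicing(
            [ev, modified_only], models, proteins
        ) == {}
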