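# Methods

This note records the models, conventions and numerical choices behind
`psieve`, and what the synthetic data does and does not establish.

## Search-space construction

Nucleotide transcript models are translated in the three forward frames
only (the models are stranded transcripts, so reverse frames would
manufacture biologically meaningless sequence). Each frame is split at
stop codons and fragments of ≥ 10 amino acids are kept; `N` bases
translate to `X`, and trailing partial codons are ignored.

I/L handling follows the two-sided convention used throughout: the
database is normalized I→L before searching (isoleucine and leucine are
isobaric and indistinguishable by standard MS/MS), and all reporting and
peptide comparison collapse L→J. Both maps are idempotent, and every
sequence comparison in the pipeline (engine agreement, protein matching,
novelty classification, SAV distance) is performed in J-space.

Tryptic digestion cleaves after K/R except before P. The exception is
applied because it is the default of the search engines this pipeline is
designed to consume results from; it is configurable only in the sense
that the digestion functions are public and small. A peptide is fully
tryptic when both termini are cleavage-consistent or coincide with the
protein termini, with the initiator-methionine-loss case (peptide
starting at residue 2 of an M-initiated protein) admitted.

Decoys are generated one per target, shuffling each fully-cleaved
tryptic fragment in place with its C-terminal K/R fixed. This preserves
protein length, residue composition and (for fragments without internal
K/R-before-P context) the cleavage structure, so decoy peptides resemble
target peptides in length distribution — the property target-decoy FDR
estimation relies on. The shuffle is driven by a single seeded
integer-state RNG; identical seeds give byte-identical databases.

Overlap removal for non-coding entries uses genomic interval
intersection (same chromosome and strand) when a locus is available, and
falls back to sequence containment in any coding protein otherwise.
Same-strand-only intersection is one reading of "overlapping coding
regions"; antisense overlaps are kept, since an antisense ORF is a
distinct translation product.

Database statistics count distinct tryptic peptides at length ≥ 7 with
≤ 2 missed cleavages in J-space, mirroring how peptide uniqueness is
evaluated downstream.

## Consensus merging and FDR

Engine agreement is evaluated on (spectrum, J-space peptide,
modification set); requiring identical modification sets is the strict
reading of "the same identification", and a sequence-only mode exists
behind a flag. The merged PEP is the maximum over agreeing engines —
the most conservative member — and the delta score is taken from the
agreeing engine with the best PEP (the aggregation is otherwise
unspecified; the best-PEP engine is the one whose assignment the merged
record effectively represents). Decoy PSMs pass through the same
two-engine agreement before entering FDR estimation (symmetric
treatment).

The FDR estimator is #decoys/#targets without the +1 correction, i.e.
plain target-decoy competition. Ties at equal PEP rank targets before
decoys, then spectrum id; this is a determinism convention, not a
statistical claim. q-values are the running minimum of FDR from the
bottom of the ranking; decoys receive q-values for diagnostics but are
excluded by the significance filter. PSMs matching both a real entry
and a contaminant are removed (conservative: contamination is the
cheaper explanation).

## Parsimony inference

Identical-evidence proteins merge; strict-subset evidence is subsumed
(reported on the covering group, not counted); the remaining groups are
reduced to a minimum set cover. Instances with ≤ 15 candidate groups
are solved exactly by subset enumeration with a lexicographic tie-break,
which keeps minimality assertable against an exhaustive oracle where it
matters; larger instances use greedy largest-remaining-set with the same
deterministic tie-break. Every emitted group retains at least one
peptide unique to it among emitted groups — a consequence of cover
irredundancy.

Gene clustering removes genes whose peptide set is a strict subset of
another gene's and merges genes with identical evidence into one
cluster; summaries report clusters at ≥ 1, ≥ 2 and ≥ 3 unique peptides.

Peptide-to-genome projection converts a 1-based protein position to the
CDS nucleotide span [3(start−1)+1, 3(start−1+len)] and walks it through
the CDS segments in transcription order, reporting genomic segments in
ascending coordinate order with a strand flag. A peptide crosses a
junction when its projection touches ≥ 2 segments.

The alternative-splicing screen uses a length cap of 30 aa while the
novelty cascade caps at 29 aa; both limits are kept as independently
configurable parameters of their respective functions rather than
unified, because they serve different analyses with different stringency
rationales.

## Novelty cascade

Classification requires a peptide to match *no* coding entry and
*exactly one* non-coding entry; multi-non-coding matches are set aside
as ambiguous (reported with an `ambiguous_mapping` reason) because an
annotation candidate must point at a single locus. Supporting PSMs with
deamidation anywhere, carbamidomethyl at the N-terminus, or pyro-glu
anywhere other than an N-terminal Q/E are discarded before the peptide
is judged; then best remaining PEP ≤ 0.01, length ≤ 29 aa, fully tryptic
context, ≤ 2 missed cleavages. All violated rules are recorded, not just
the first, so filter attrition can be audited per rule.

Updated-annotation matching is exact substring search in J-space. For
peptide-length queries the decision-relevant outcome of a short-sequence
protein alignment is the exact match; near-misses are precisely what the
SAV rule handles next. The SAV filter computes the minimum Hamming
distance between the candidate and every equal-length window of the
known proteome (J-space) and removes candidates at distance < 2 —
"two amino acids different" read as substitutions, with indels out of
scope. All windows are scanned, not just tryptic peptides, which is the
stricter reading.

Modification enrichment (novel vs coding PSMs per modification type)
uses a two-sided Fisher exact test with Benjamini–Hochberg adjustment
across types. It is a diagnostic; only deamidation and N-terminal
carbamidomethylation are hard-coded exclusions.

RNAseq support is a strict threshold: RPKM > 0.75 in at least one
tissue. Genes absent from the table are flagged `no_data`, distinct from
unsupported.

## Priority annotation score

The peptide score is additive:

    S_i = −log10(P_i) + U_i + M_i/Wm + L_i + D_i/Wd + R_i/Wr + E_i

The −log10 transform of the best PEP is the only unbounded term and is
what lets a single exceptional peptide cross the ~100 guidance line; the
remaining features are each O(10) at the defaults Wm = 5, Wd = 10,
Wr = 5, which were chosen to scale the features to comparable magnitude.
Entropy uses log base 2 (bits), so E is bounded by log2(min(N, 20)).
A PEP of exactly 0 (some engines floor their PEPs) is clamped to 1e−20
with a warning rather than propagating an infinity. The score is
monotone non-decreasing in U, M, L, D, R, E and non-increasing in P,
and is a deterministic function of the features and weights.

Protein totals sum the scores of *distinct unambiguous* peptides: a
peptide matching more than one group contributes to none, so totals are
conserved across the grouping. Ranking is descending by total with a
lexicographic identifier tie-break. Weight optimization from labelled
annotations is deliberately out of scope.

## Synthetic data

The generator emulates the *statistical structure* of a multi-engine
proteogenomic study, not spectra: random annotated proteins (100–600
aa), noncoding transcript models carrying planted frame-0 ORFs
(tryptic-peptide-rich, 30–70 aa) and planted variant peptides (one
substitution away from an annotated tryptic peptide, embedded in a
clean tryptic context, substitutions avoiding I/L and K/R so the
distance survives J-collapsing and the cleavage structure is unchanged),
contaminants, and 1:1 decoys.

PEPs are drawn directly: Beta(0.3, 60) for correct matches
(concentrated near zero), uniform for incorrect — the two-component
mixture that PEPs estimate. Incorrect matches split evenly between
decoy and mismatched-target peptides (the equal-chance assumption
underlying target-decoy estimation) and are engine-private with
probability 0.85, while correct matches replicate across engines with
probability 0.9 each; this differential is what makes the two-engine
consensus informative, and both knobs are configurable so the rule's
effect is measurable. Deamidation is sprinkled at a 4× rate on
incorrect matches, emulating the artefact enrichment the cascade's
modification exclusions target. Default study size is 4 samples × 500
spectra; calibration checks use 2,500 spectra per sample (10,000 PSMs),
a size at which realized FDR estimates are stable while a full
20-replicate calibration stays cheap.

What passing tests show: the q-value machinery is exactly the
enumerated target-decoy competition; under the generator's assumptions
(decoys exchangeable with false targets, PEP mixture as above) the
q ≤ 0.01 cut controls the realized false-match proportion; planted novel
ORFs are recovered and planted variants are caught. What they do not
show: robustness to correlated spectra, PEP miscalibration by real
engines, homologous sequence families, or chimeric spectra — none of
which the generator models. Real-data behaviour additionally depends on
search-engine rescoring quality, which is upstream of this pipeline.

## Degenerate inputs and tie-breaks

Empty merged-PSM input yields empty q-value output; an empty coding set
is an error everywhere classification is involved (the pipeline is
meaningless without it). FDR is defined as 0 before the first target.
All orderings that affect output (cover tie-breaks, ranking ties, q-value
ties) are resolved lexicographically so identical inputs give
bit-identical outputs on any platform; the generator uses a single
seeded PCG64 stream and sorted iteration, so a seed fully determines
every artifact.
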