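# Methods

## IMGT position algebra

Variable-domain positions are pairs (number, insertion index) with number in
1–128 and insertion indices stored as integers, rendered as letters
(1 → A, 27 → AA), which keeps ordering well defined past Z. Insertions are
accepted at the loop anchors 32/33, 60/61 (CDR1/CDR2 length variants) and
111/112 (CDR3). The total order is numeric on the base number with the
CDR3-specific asymmetry: insertions at 111 ascend after 111 and insertions
at 112 descend before 112 (… 111, 111A, 111B, …, 112B, 112A, 112 …);
insertions at every other anchor ascend. Region spans are fixed to the IMGT
standard (CDR1 27–38, CDR2 56–65, CDR3 105–117, frameworks the complement
of 1–128) and are deliberately not configurable: the profile and search
semantics are defined in terms of these spans.

For a CDR3 junction of length L ≤ 13 the positions 105–117 are filled
symmetrically, the left arm taking the extra slot at odd lengths; for
L > 13 the extra slots alternate between the 112 side and the 111 side
starting with 112 (L = 14 adds 112A; L = 15 adds 112A and 111A), matching
the canonical rearranged-junction convention. The test suite checks this
ladder for every length 5–30 against an independent construction that
assigns each slot a rational coordinate and sorts numerically.

## Input model

Two on-disk dialects are read: OAS-style CSV (first line a JSON object of
study metadata; rows carry the numbering either as a JSON map — flat
`position → residue` or nested `region → position → residue` — or as flat
per-position columns) and AIRR rearrangement TSV (standard column names;
numbering from an IMGT-gapped `sequence_alignment_aa`, valid only for
insertion-free sequences, or from per-position columns). Other historical
schema generations are rejected explicitly rather than guessed at.

Numbered residues are authoritative. CDR strings stored in files are
advisory: they are recomputed from the numbering on load and discrepancies
logged, so profiling and search always operate on one CDR definition. Rows
with malformed numbering or out-of-range positions are skipped per record
and counted (`rows_read = loaded + skipped`), never fatal, because real
unit files occasionally carry numbering artifacts. `X` residues are
tolerated on read, excluded from frequency counts, and count as mismatches
in every distance computation — ambiguous calls must neither inflate
frequencies nor manufacture matches. V/J calls are parsed as
`GENE*ALLELE`; multiple comma-separated assignments use the first.

Raw (un-numbered) amino-acid queries are accepted only through a pluggable
numbering hook (`abrep.io.set_numbering_hook`); no numbering engine is
bundled, and the default refuses raw input with an explanatory error.

## Profiling

Grouping is by (chain, V group, J group) at gene or allele resolution; both
V and J must match — there is no V-only fallback. Allele resolution
requires an allele on both calls; sequences with gene-only calls are
excluded from allele-resolution profiles. Per study and position, residue
counts (X excluded) yield frequencies, Shannon entropy in bits, and
competition ranks (ties share the minimal rank, so rank 1 is always the
modal residue). Bits were chosen as the entropy unit as the
information-theory default; any other base is a constant rescaling.

The `min_observations` filter (default 100) applies per (study, group,
position) before any aggregation. Aggregation across studies is
mean/median/standard deviation with equal weight per study; the standard
deviation is the population form (divide by n), so a single contributing
study reports 0 rather than an undefined value. A residue's rank/proportion
aggregates run over the studies that observed it, with coverage recorded in
`n_studies_observed`; an optional switch instead scores unobserved studies
with the convention rank = n_observed + 1 and proportion 0. Per-study raw
frequencies are retained in the profile store for drill-down export.

Query annotation selects the profile matching the query's calls; an
allele-resolution request falls back to the gene profile with a recorded
note when no allele profile exists. Positions absent from the profile and
residues never observed are flagged (`position_not_in_profile`,
`residue_unobserved`), never dropped, so an annotation always has one row
per query position.

## Retrieval

CDR3s are bucketed by length and indexed by k-mers (k = 5). "One residue
discrepancy" is implemented as Hamming distance at equal length — no
indels — which is the only reading consistent with length-bucketed search;
candidate generation from shared k-mers is provably complete for one
substitution when L ≥ 2k, and shorter CDR3s (or larger mismatch budgets
that void the pigeonhole bound, i.e. L − k + 1 ≤ k·m) fall back to an
exhaustive scan of the length bucket. Every candidate is verified by
Hamming distance, so results equal the exhaustive scan by construction;
tests assert this equivalence on random queries rather than trusting it.

Full variable-region matching adds the chain-type constraint and the
CDR1/CDR2 rule — identical strings by default, with a `length_only`
relaxation — and ranks hits by identity over the IMGT positions shared by
query and hit. Clonotypes are (gene-level V call, CDR3 string); the J gene
and the V allele are deliberately ignored, and CDR3 identity is at the
amino-acid level (the only level modeled here). Hit ordering is
deterministic: ascending CDR3 mismatches, then descending identity, then
sequence id.

Alignment display places query and hits on the union of their IMGT
positions in scheme order with `-` at absent positions. Theme summaries
count hits and distinct studies per metadata value, with missing values
pooled under `unspecified`.

The index file embeds the indexed sequences and metadata as versioned JSON
and rebuilds postings on load; since building is order-independent and
deterministic, a reload reproduces the postings exactly, which the round-trip
tests check byte-for-byte through a second save.

## Synthetic data

The generator emulates the statistical shape of public unit files, not
their biology: toy germline sets (3 V genes × 2 alleles and 2 J genes for
each of chains H and K, generated deterministically from a fixed internal
seed; alleles differ at IMGT position 50), uniform substitutions at a
configurable per-position rate over template-derived positions (V 1–104,
J 118–128), and a de-novo CDR3 junction — uniform residues with the 105
cysteine fixed and the conserved 118 Trp/Phe in the J template — at lengths
drawn from a configurable distribution (default mass on 12–17, the typical
heavy-chain range). Because the junction is sampled rather than mutated,
the recorded clonotype ground truth is exact by construction. Study
metadata cycles through configurable disease/vaccine themes. All
randomness flows from a single seeded generator; identical configurations
are bit-reproducible, and the OAS-style writer/reader round-trips the
output exactly.

What this does not model — shared-mutation hotspots, clonal lineages,
indel-bearing repertoires, paired chains, nucleotide-level information —
bounds what green tests show: they validate the statistics and search
semantics, not robustness to every artifact of real sequencing data.

## Problem sizes and numerics

Default test and acceptance scales (a few studies of 150–2000 sequences;
1000-CDR3 indexes; 200-query oracle comparisons) were chosen so each
property is measured at the scale where its guarantee is meaningful while
the whole suite stays interactive. Statistical recovery checks use
3-standard-error bands; the per-position mutation-rate calibration uses a
simultaneous 4-SE band across its ~115 positions plus a 3-SE test of the
pooled rate, since 115 independent 3-sigma tests would fail by chance in a
quarter of runs. Frequency sums are validated to 1e-9; profile JSON stores
full float precision. The CLI defaults mirror the method's stated values
(k = 5, min-observations = 100, max-mismatches = 1).

## Known limitations

- No IMGT numbering engine: raw sequences require an external hook.
- Light-chain kappa and lambda are never pooled; chain type is part of
  every profile key.
- CDR3 search tolerates substitutions only; a length±1 (indel) neighbor is
  invisible by design.
- Profiles require both V and J to match; queries with novel gene calls
  fail with an explicit lookup error rather than a nearest-gene guess.
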