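# Methods

This note documents the models and procedures implemented in
`barcodeverify`, the parameters that matter, the choices made where the
design was genuinely open, and what the test suite does and does not
establish.

## Problem setting

A specimen enters a genome-sequencing pipeline with a morphology-based
species identification. A short standardized marker (COI, rbcL, ITS/ITS2,
18S, ...) is amplified, sequenced in both directions, and compared against a
taxon-annotated reference library. The question is never "what species is
this?" in isolation but "is the barcode *consistent with the declared
name*, given how well the library samples the relevant taxa?" — the answer
decides whether the specimen proceeds to sequencing, proceeds with a flag,
or is held for verification.

## Read QC and merging (`seqqc`)

**Trimming.** `trim_quality` returns the longest contiguous run in which
every sliding window of `trim_window` bases (default 10) has mean phred
quality ≥ `trim_min_q` (default 20). Runs shorter than the window are
judged on their whole-run mean and used only when no window-sized run
qualifies; ties go to the leftmost run. Trimming is idempotent and never
lengthens a read.

**Merging.** The reverse read is reverse-complemented and slid against the
forward read over all ungapped offsets. The layout maximising
IUPAC-compatible columns wins, provided the overlap is ≥ `merge_min_overlap`
(default 20) columns and ≥ 80% of them are compatible; otherwise a merge
failure is signalled and the specimen is reported for single-read fallback.
Per overlap column: agreement keeps the base (the more specific code when
one read reports N; quality breaks remaining ties); a conflict resolves to
the base with quality advantage ≥ `merge_q_margin` (default 10), else to the
IUPAC union code, counted as a wobble. Ungapped merging is a deliberate
restriction — Sanger amplicon reads essentially never need gapped merging,
and it keeps the column-wise consensus oracle exact. Gapped merging is out
of scope.

**Wobbles and hybrid flagging.** `count_wobbles` counts two-base ambiguity
codes {R,Y,S,W,K,M}; N and three-base codes signal low quality, not
heterozygosity, and are excluded. A nuclear ribosomal consensus with ≥
`wobble_hybrid_min` wobbles (default 3) flags a putative hybrid; no
published count threshold exists for this call (the motivating cases are
qualitative), so the default is deliberately conservative and configurable.
The same signal in a plastid or mitochondrial locus cannot be
heterozygosity and is reported as probable contamination instead.

## In-silico PCR (`insilico_pcr`)

Primer sites are found under a degenerate-aware Hamming model: a primer
base matches a template base when their IUPAC base sets intersect (inosine
and N match everything); up to `max_mismatch` (default 2) incompatible
positions are allowed, with no indels. M13 sequencing tails recorded in the
catalogue are trimmed to the gene-specific 3' portion before matching.
Amplicons are primer-inclusive, in 0-based half-open forward-strand
coordinates, both strands scanned; per forward site the shortest span
within the expected length window ± 20% slack is taken (published amplicon
sizes are approximate, and whether they include primers is not stated — we
treat them as primer-inclusive, configurable via `strip_primers`). Primer
cocktails are expanded to all forward × reverse pairs and the pair with the
fewest total mismatches wins per template.

The shipped catalogue (`data/primer_catalogue.tsv`) lists the standard
barcoding primer pairs per taxon group with expected spans. Rows without a
published size were given conventional ranges (e.g. plant ITS2 300–500 nt);
in-cell whitespace in primer sequences is preserved in the file and
stripped on load.

`recover_barcode` extracts one best amplicon per genome-scale read and
takes the majority: identical extracted sequences are grouped and the modal
sequence becomes the consensus with its count as support; minority
sequences are reported. This is exact-grouping majority rule, not
column-wise voting — adequate for high-fidelity long reads, but a single
sequencing error inside the amplicon removes that read from the consensus
group (a documented limitation; support counts make such cases visible).

## Matching strategies (`matchlib`)

**Percent identity.** Queries and references are compared by overlap
(semi-global) alignment: end gaps are free and excluded; internal gaps
count as mismatched columns (scored −2, linear); IUPAC-compatible columns
count as matches (+1; incompatible −1). Among score-optimal alignments the
one with most matches, then fewest columns, defines the reported
`(identity, overlap)` — a three-level lexicographic objective folded into a
single integer per DP cell, making the value independent of traceback
tie-breaking and directly checkable against a brute-force oracle. Raw
(uncorrected) identity is used for threshold decisions; the divergence
metric behind published group thresholds is not specified anywhere, and raw
identity is the convention of the search interfaces practitioners read.

**Hit tables and bands.** All records for the locus are scored (libraries
are desk-scale snapshots; no heuristic seeding). Hits below
`near_match_floor` (default 0.80 identity) or overlapping less than
`min_overlap_fraction` (default 0.5) of the query are dropped; ties are
broken by record id. The *top band* — species within `top_band_width`
(default 0.001, i.e. ties at 3-decimal identity) of the best hit — is the
machine reading of "the closest matches in the results table".

**Group thresholds.** `species_threshold` is a per-taxon-group divergence
mapping; defaults are the field's conventions, not measured values: 2% for
animal COI, 1% for plant plastid loci, 3% for fungal/lichen ITS, 2%
fallback. The boundary is inclusive.

**BIN-style clustering.** `bin_cluster` performs single-linkage clustering
at `bin_threshold` (default 2.2% divergence, the conventional barcode-gap
value): sequences link when pairwise divergence ≤ threshold and clusters
are connected components, so chains merge. This is an explicit, documented
proxy for the RESL algorithm behind BOLD BINs, which is out of scope.

**Phylogenetic placement.** K2P distances
(d = −½ ln(1−2P−Q) − ¼ ln(1−2Q), transitions P and transversions Q over
unambiguous aligned columns; saturated pairs capped at 5.0 with a warning)
feed neighbor joining (scikit-bio, taxa pre-sorted for input-order
invariance, negative branch estimates clamped to zero). The query's
attachment node splits the unrooted tree into sides; the smallest side is
its neighborhood: all-conspecific → species-level placement, single genus →
genus-level, otherwise none. A query whose nearest reference exceeds 0.15
substitutions/site (between-genus scale, tunable) is reported as `none`
outright — an outlier's long branch attaches wherever NJ can absorb it and
carries no placement signal.

## Classification (`classify`)

`assess_coverage` counts, for the expected species' genus at one locus, the
congeners present in the library versus those on the regional checklist
(the checklist defines "all relevant congeners"); `completeness` is their
ratio, 1.0 with a note when the checklist is silent about the genus.

`classify_locus` is a total, deterministic decision procedure:

1. no retained hits and no congeners in the library → **no_match**;
2. best identity ≥ `exact_identity_min` (default 1.0 — "exact" is an
   identity bar, not string equality, because trimmed query lengths vary)
   and expected in the top band:
   a. band = {expected} and completeness ≥ `completeness_min` (default 1.0)
      → **definitive**; b. otherwise → **consistent(a)** (an exact match
      with incomplete congener sampling is read conservatively);
3. expected outside the band but congeners in it: a. expected species in
   the library → **inconsistent(a)**; b. expected absent →
   **consistent(b)**;
4. band entirely outside the genus with best identity within the group
   threshold of full → **inconsistent(b)**;
5. residual: a near match to the expected species (within the group
   threshold but below the exact bar) → **consistent(a)**; anything else →
   **no_match** (weak hits only). The first clause is a deliberate
   refinement: a 99% match to the expected species is a near match with
   congeneric context and cannot honestly be called "no match".

Genus membership is the operational boundary between "closely related"
(inconsistent-a) and "distantly related" (inconsistent-b); no numeric
definition exists for it.

`combine_loci` implements the dual-locus rules with precedence
inconsistent > definitive > consistent > no_match: any wrong-taxon locus
forces the combined verdict (a conflict between loci may indicate a sample
switch or contamination and must be looked at); a definitive locus carries
the specimen only if every other scored locus is at least consistent *and*
that lower resolution is expected for the locus (`locus_expectations`,
e.g. rbcL → genus); loci that failed QC enter as missing and do not block a
consistent verdict.

`decide_action`: exempt specimens (taxa with reliable morphology but
persistently failing barcodes) skip barcoding entirely; definitive →
proceed; consistent → proceed flagged (or verify when
`consistent_requires_verification` is set — review of consistent matches
is a hub-level discretion surfaced as a flag); no_match → proceed flagged;
inconsistent → verify. Hybrid or contamination flags force verify
regardless. A replacement name is suggested only when a single non-expected
species dominates every informative locus; disagreement defers to expert
referral.

## Tracking (`tracking`)

At the genome-sequencing stage the barcode is recovered from long reads or
contigs by in-silico PCR and (1) compared with the specimen's own verified
barcode and (2) searched against the library. verdict `pass` requires the
top match to be the declared species (after synonym canonicalisation) and
identity ≥ `tracking_identity_min` (default 0.99; the production cutoff is
not published, so it is configurable). Failures to recover the region give
`recovery_failed`, not an exception.

## The synthetic world (`synthetic_data`)

The generator states one coherent world rather than tunable realism:

* Each locus has a random root sequence whose first and last 20 nt are held
  invariant and double as universal primer sites (real barcode primers
  target conserved flanks).
* Genus ancestors are the root with `between_genus_divergence/2 · L`
  substitutions (default 0.15 pairwise scale); species receive
  `between_species_divergence/2 · L` substitutions (default 0.05 pairwise)
  at sites *disjoint across congeners*, so pairwise congener divergence
  equals the configured value exactly. Within-species divergence defaults
  to 0 — the noise-free world in which the classifier's scenario mapping is
  analytically forced.
* Scenarios: correct label; congeneric mislabel; cross-genus switch; novel
  species absent from library and checklist (congeners present); hybrid
  (two congeneric alleles at nuclear loci, maternal parent at organellar
  loci); contamination (a congeneric contaminant in the extract, mixing
  every locus). Mixed templates are rendered as double peaks: both
  sequences are co-reported per column as IUPAC union codes in *both*
  directional reads, which is how a mixed Sanger trace actually reads and
  makes the wobble-derived flags structural rather than probabilistic.
* Trace reads carry a linear quality profile (default 60→30, above the
  trimming threshold so noise-free runs keep full-length reads) and
  substitution errors at `read_error_rate` (default 0) biased toward
  low-quality positions.
* Library incompleteness withholds the configured fraction of species from
  both the library and the checklist (never a genus's last species). Keeping
  withheld species on the checklist would silently degrade *other* correct
  specimens of the same genus from definitive to consistent(a) through the
  completeness clause, conflating two different failure modes in the
  benchmark; the checklist-incompleteness pathway is instead exercised
  directly in the classifier's unit tests.

**What a green benchmark establishes** — and does not. In this world the
end-to-end mapping is exact: correct → definitive, congener mislabel →
inconsistent(a), cross-genus switch → inconsistent(b), missing species →
consistent(b), hybrid → verify with hybrid flag, contamination → verify
with contamination flag. That verifies the *logic* of the pipeline, not its
field performance: the simulator has no indels (so alignment and K2P
oracles stay exact), no chromatogram artifacts, no intraspecific variation
by default, no reference mislabels, and planted-site evolution instead of a
proper substitution process. Campaign-level statistics from real programmes
(match rates, renaming rates) depend on live databases and real specimens
and are expressly not reproduced here.

## Numerical choices

* Identity/overlap from a lexicographic (score, matches, −columns) DP;
  encoded in int64 with base 8192, limiting pairwise comparisons to ~4000 nt
  per side (ample for barcodes).
* K2P saturation (log argument ≤ 0) capped at 5.0 substitutions/site with a
  `SaturationWarning`.
* Deterministic tie-breaking everywhere by lexicographic record id / taxon
  label; all simulation randomness flows from a single integer seed through
  `numpy.random.default_rng`.
* Threshold boundaries are inclusive, with 1e-9 tolerance against float
  noise in `1 − identity`.

## Known limitations

* No indel handling in primer matching or merging (by design; documented
  above).
* `recover_barcode` majority rule is exact-grouping, weak under per-read
  error; column-wise consensus would be the upgrade path.
* Placement levels depend on NJ resolution of near-degenerate distance
  matrices; conspecific references at ~zero distance can attach arbitrarily
  (the distance ceiling and smallest-side rule mitigate but do not remove
  this).
* The BIN proxy is single linkage at a fixed threshold, without RESL's
  refinement step.
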