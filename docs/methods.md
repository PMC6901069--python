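# Methods

`tagcascade` re-implements, at desk scale, the processing core of rRNA
gene amplicon profiling: raw demultiplexed FASTQ in, annotated and
normalized OTU tables plus diversity matrices out.  This note records the
models and procedures, the parameters that matter, the numerical choices,
and what the synthetic mock communities do and do not establish.

## Read quality control

Reads pass six stages, each of which can only discard (never modify a
read it keeps, except to trim it):

1. **Contaminant/PhiX screening.** Each read is decomposed into canonical
   k-mers (a k-mer and its reverse complement collapse to the
   lexicographically smaller string, so orientation is irrelevant) and
   compared against indexed reference sets.  A read sharing at least
   `min_hits` (default 1) canonical k-mers with the PhiX reference is
   binned as PhiX; otherwise a hit against any adapter reference bins it
   as contaminant.  `k = 21` balances specificity (a random 21-mer
   collision has probability ~4^-21 per position) against robustness to
   sequencing error.  Reads shorter than k cannot be screened; they are
   kept and tallied separately.  Contaminated reads are dropped whole,
   not clipped: the stage is a decontamination filter, not an adapter
   trimmer.
2. **Pair synchronization.** Screening one mate of a pair orphans the
   other; orphans are counted and discarded.  Ids match after stripping
   `/1`/`/2` or whitespace suffixes.
3. **Fixed-length trimming** (optional; typical for single-end data).
   3' bases beyond the target length are removed; shorter reads are
   discarded, never padded.
4. **Overlap merging.** The reverse mate is reverse-complemented and
   candidate overlaps are scanned from the longest possible down to
   `min_overlap` (10).  The overlap minimizing the mismatch ratio wins
   (ties go to the longest, which the longest-first scan provides), and
   the merge is accepted iff that ratio is at most 0.25.  Within the
   overlap a disputed base takes the higher-quality call (ties favor the
   forward read) and the merged quality is the per-position maximum.
   Like all greedy overlap merging, a chance short perfect overlap can
   occasionally beat the true longer one; such mis-merges are rare
   (~1e-4/pair at 2x250) and are later removed by the abundance filter.
5. **Primer handling.** The forward primer is searched 5'-anchored within
   a window of 1.5x its length (a global search would produce internal
   false hits), allowing up to 2 mismatches, with IUPAC degeneracies
   expanded.  If absent and orientation is enabled (PacBio CCS reads come
   off the instrument in both directions), the reverse complement of the
   read is searched.  On success the read is emitted forward-oriented
   with the forward primer — and, when found in the mirrored 3' window,
   the reverse-complemented reverse primer — clipped; otherwise it is
   discarded.  An ambiguous read base (N) counts as a mismatch unless the
   primer position itself is fully degenerate.
6. **Quality filter.** Three criteria, checked in a fixed order that also
   defines the recorded failure reason: mean phred below `min_avg_q`
   (default 27, the permissive end of the conventional 27–33 range);
   more than `max_n` undefined bases (default 1); strictly more than
   `max_low_q_bases` (5) bases below `low_q_threshold` (Q15).

## The clustering cascade

Quality-filtered reads are dereplicated at 100% identity (unique
sequences carry their counts and member read ids), then greedily
clustered.  **Identity** between two sequences is end-gap-free
(semi-global): the shorter sequence is aligned anywhere within the longer
with free terminal gaps, `d` is the minimal number of edit operations,
and identity = 1 − d/len(shorter).  Free terminal gaps let
length-variable amplicons (ITS-like) join clusters seeded by longer
representatives.  The production path computes `d` with edlib; the test
suite checks it against an independent full-DP implementation.

**Greedy clustering** scans sequences in decreasing abundance (ties
broken by lexicographic sequence, making results deterministic); each
sequence joins the *first* existing centroid at or above the threshold,
else founds a new cluster.  First-fit in abundance order matches the
behavior of the greedy centroid clusterers used in production amplicon
pipelines and is the normative rule here — membership is checked against
a brute-force oracle in the tests.

Short-read mode: dereplicate → cluster at 99% ("denoising"; centroids
re-emitted with aggregate sizes) → discard clusters with abundance < 25 →
chimera scan, de novo then reference → final clustering at 97%.  The
abundance floor is applied to the 99% clusters; since reads with three or
more errors found their own 99% clusters, the floor is what removes the
error cloud (and, as a side effect, near-unique artifacts such as rare
chimeras and mis-merges).  PacBio mode: dereplicate → cluster at 97% →
discard clusters with fewer than 2 reads → reference chimera scan only
(long CCS libraries are far shallower, so a floor of 25 would erase
them).  Externally produced ASV tables get the same post-filters
(abundance floor, then de novo + reference scans for Deblur-style input,
reference-only for DADA2-style input whose internal bimera removal is
assumed done).

## Chimera detection

A PCR chimera is a two-parent recombinant.  The detector asks whether a
two-parent model explains the query better than any single parent: the
query is aligned to each of the top-4 most similar candidate parents,
per-position match profiles are extracted, and for every ordered parent
pair (A, B) and crossover position the model identity is (matches to A
left of the crossover + matches to B right of it) / query length,
maximized by prefix sums.  The query is chimeric iff

* the best model identity strictly exceeds the best single-parent
  identity by at least `min_div` (0.8 percentage points), **and**
* the best model identity is at least `min_model_identity` (0.97).

The second condition is essential: maximizing the gain over parent pairs
and crossovers extracts 1–2 points of chance gain from any moderately
diverse pool, so the gain criterion alone flags pure sequences.  A
genuine recombinant, by contrast, differs from its two-parent model only
by sequencing error, so its model identity is near 1.  The floor should
be lowered for data types with error rates above ~3%.  In de novo mode
candidate parents are restricted to already-accepted sequences at least
`min_parent_ratio` (2.0) fold more abundant than the query, processed in
decreasing abundance (templates out-amplify their chimeras); reference
mode admits the whole reference set.  Chimeras formed from parents more
than ~99% identical, or with a crossover in the terminal ~10% of the
molecule, are not reliably detectable by any two-parent criterion — the
gain is smaller than the error noise.  This is a deliberate
simplification of chunked-voting chimera scores: the cascade needs the
contract "detect two-parent recombinants between more-abundant parents",
and every threshold is exposed.

## Taxonomy

The classifier is a word-presence naive Bayes over a ranked taxonomy
(default kingdom…genus), in the RDP style: references are grouped into
genus-level leaves; for word size `w = 8`, the per-leaf conditional
probability of a word is (number of leaf references containing it + 1) /
(leaf size + 2) (add-one smoothing keeps probabilities in (0,1)); a
query is scored per leaf by the sum of log probabilities over a random
1/8 subsample (with replacement) of its distinct words; each of 100
bootstrap trials assigns the arg-max leaf (ties to the lexicographically
first).  The assigned name at each rank is the modal name across trials
and its confidence the fraction of trials descending through that name.

Training lineages are first made unique and non-conflicting: a name
occurring under two different parent paths is renamed
`<name>_<parent>` in all occurrences, and empty rank values become
`<parent>_unclassified`.  Uniqueness is what makes confidence provably
monotone non-increasing with depth (trials carrying the modal name at
rank r+1 all carry its unique parent at rank r, whose count is bounded by
the modal count there); the suite asserts monotonicity on every
classification.

Lineage reconstruction keeps the maximal *prefix* of ranks with
confidence ≥ 0.5; once a rank falls below the cutoff all deeper ranks are
dropped even if a later one rebounds, because a path with a missing
middle rank is not a valid lineage.  Domain filtering of feature tables
(16S → Bacteria/Archaea, ITS → Fungi, 18S → Eukaryota) drops features
unclassified at the kingdom rank.

## Consensus multi-rarefaction

One rarefaction draws exactly `depth` reads per sample without
replacement (a multivariate hypergeometric draw; samples below the depth
are excluded and reported).  A single draw stochastically zeroes
low-abundance features, so the normalized table is the cell-wise mean of
`n_reps = 500` independent rarefactions.  Means are kept fractional:
each replicate column sums to the depth exactly, hence so does the
consensus (rounding would break this conservation), and each cell
converges to depth × (cell / column total) with hypergeometric standard
error / √n_reps.  Per-replicate generators are derived from the master
seed by counter (`SeedSequence(seed, spawn_key=(rep,))`), so the result
is bit-reproducible and independent of execution order.  The depth is a
per-run choice (1,000 in the worked example and acceptance run); there
is no auto-selection.

## Diversity

* **Observed features**: count of features with abundance strictly > 0 —
  no epsilon, since any positive consensus mean reflects presence in at
  least one replicate.
* **Bray-Curtis**: 1 − 2·Σmin(xᵢ,yᵢ)/(Σx+Σy), computed from the closed
  form (fractional abundances accepted; two empty samples get distance 0
  with a warning).
* **UniFrac** (delegated to scikit-bio on a supplied tree): unweighted =
  fraction of observed branch length unique to one community; weighted =
  Σ branch length × |p_A − p_B|, non-normalized by default.  Features
  missing from the tree are an error in strict mode, dropped with a
  warning in lenient mode.  The pipeline does not build trees; the
  simulator emits a genus-labeled template tree, so the pipeline's
  UniFrac step aggregates the consensus table to genus before computing.
* **Mantel**: Pearson r over upper triangles; p =
  (1 + #{permutations with r′ ≥ r}) / (1 + n_perm) under joint
  row/column permutation of the second matrix, with an explicit seeded
  generator.  When n! ≤ n_perm all permutations are enumerated exactly.

## The runner

Steps form a DAG executed in deterministic (lexicographic-topological)
order with per-step state persisted as JSON.  Each step's fingerprint
hashes its resolved parameters, the content digests of its declared
input files (content, not timestamps — timestamps do not survive
copies), and the fingerprints of its dependencies.  On resume a step is
skipped iff it is recorded done under an identical fingerprint; because
fingerprints chain, editing one parameter invalidates exactly that step
and its downstream cone.  Failures halt dependents while independent
branches continue.  Execution is local and in-process: the contract kept
from HPC workflow managers is dependency ordering plus smart restart,
not scheduler submission.

## The simulator, and what passing tests do not show

`simulate` generates even or staggered mixtures of templates produced by
mutating a common random root at half the requested divergence (pairwise
divergence ≈ the request, rejection-checked), with nested synthetic
lineages; amplicons are primer-flanked (degenerate primer positions are
resolved per molecule, as in a real primer pool), sequenced as
overlapping 2×250 pairs, single-end reads, or full-length CCS-like reads
with per-taxon lengths drawn from N(1470, 220); substitutions (5% of
which are ambiguous N calls) and indels occur per base at configurable
rates; chimeras splice two templates at a uniform crossover within the
middle 80% of the molecule (so detection is well-posed); PhiX and
adapter spike-ins come from deterministic *synthetic* stand-in sequences
generated in code.  Quality profiles are an Illumina-like linear decay
Q38→Q25 with Gaussian jitter (σ=3), or flat Q30 for CCS.  All randomness
flows from one seed.

Deliberate idealizations: errors are i.i.d. per base and uncorrelated
with the emitted quality scores; there are no homopolymer-specific indel
modes, no quality-correlated error spectra, no PCR abundance bias, and
template divergence is uniform rather than hypervariable-region
structured.  Consequently the end-to-end checks (20 ± 2 OTUs from 20
templates, ≥95% of retained reads assigned to the correct genus, ≥90%
chimera sensitivity at zero false positives on pure centroids)
demonstrate the correctness of the machinery under its stated model, not
field performance on real instrument data, where error structure and
database incompleteness dominate.

## Problem sizes and defaults

The reference study conditions (simulator defaults, also used by
`scripts/acceptance.py`) are 20 templates at 10% divergence, 4 samples ×
5,000 pairs of 2×250 reads, 0.5% substitution, 2% chimeras, 1% PhiX,
0.5% adapter contamination, rarefaction depth 1,000 × 500 replicates —
small enough to process on one CPU in under two minutes while leaving
every stage a non-trivial job.  Unit and property tests use smaller
fixtures (hundreds to thousands of reads) chosen so that expected
outcomes are exactly derivable.
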