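# Methods

## Scope and data model

`hervkit` operates purely on annotation tables — RepeatMasker fragment
records and transcript models — never on nucleotide sequence. All genomic
intervals are 0-based half-open internally (UCSC table convention); the
1-based inclusive RepeatMasker `.out` dialect is converted at the read
boundary and restored on write, and the conversion is involutive.
"Main chromosomes" means exactly chr1–chr22, chrX, chrY; the read-time
allowlist drops haplotype and unplaced contigs by default but can be
disabled to read everything.

RepeatMasker consensus coordinates arrive in a signed encoding in which
the "bases remaining past the match" field is negative and swaps position
with the consensus begin on minus-strand hits. Fragments keep the raw
signed triple (for lossless re-serialisation) and expose normalised
`consensus_start < consensus_end` plus the full model length
(`consensus_end + remaining`) for both strands, which is what the
intactness arithmetic needs.

## Defragmentation model

A provirus is 5′‑LTR–internal–LTR‑3′; RepeatMasker splits it into
fragments wherever later insertions interrupted the alignment, and the two
LTRs match a different model than the internal genes. Reconstruction joins
fragments that plausibly derive from one insertion:

* **Streams.** Fragments are partitioned by (chromosome, strand, canonical
  family) and sorted by start (ties: longer fragment first, then input
  order). Family canonicalisation maps both an LTR model and its internal
  partner (e.g. LTR7 and HERVH-int) to the same family key, so they share
  a stream; fragments of *other* families interleaved inside a gap live in
  their own stream and neither join nor break the chain. This
  nested-insertion tolerance is the main reason defragmentation exists.
* **Join predicate.** A fragment extends the open chain when the gap to
  the running chain end is ≤ `max_distance` (default 500 bp,
  CLI-overridable) and, if it matches the same consensus model as the
  immediately preceding fragment and both carry consensus data, their
  consensus starts are non-strictly ordered with the genomic direction
  (reversed on the minus strand). The colinearity check is advisory —
  skipped when consensus fields are absent — and non-strict because the
  5′ and 3′ LTRs of a complete element cover the *same* consensus span and
  must still chain.
* **Determinism and monotonicity.** Because the break decision between two
  consecutive stream fragments does not depend on anything downstream,
  the set of break points can only shrink as `max_distance` grows; the
  total element count is therefore non-increasing in the distance
  parameter (property-tested), and the output is a pure function of the
  input.

Runs of adjacent fragments of the same model merge into one *component*;
a component's intactness ratio is the length of the union of its matched
consensus intervals divided by the model length (union, not sum, so
overlapping pieces are not double-counted; capped at 1 for the rare
alignment that overshoots the declared model length). The element-level
aggregate is the mean of component ratios weighted by genomic span, over
components that carry consensus data; elements with none report no
aggregate rather than a guessed one.

**Truncation classification** reads component roles in element (5′→3′)
orientation — genomic order on the plus strand, reversed on the minus
strand: no internal component → solo LTR (including two LTRs that merged
with no internal sequence left between them, the recombinant-solo case;
the five-class scheme is closed); internal with LTRs on both sides →
complete; LTR only 3′ of the internal → 5′-truncated; LTR only 5′ →
3′-truncated; neither → both-truncated.

The distance sweep re-runs defragmentation at each requested distance and
reports defragmented (n_fragments > 1) and non-defragmented counts, with
coverage normalised by the sweep's maximum defragmented count.

## Neighbor mapping

Each element is related to every gene isoform it overlaps or lies within a
window of; there is deliberately no nearest-gene exclusivity, because the
downstream statistic is per-gene HERV content. Overlapping elements are
exonic if they intersect any exon, intronic if wholly inside the
transcript span without touching an exon, and boundary if they straddle a
transcript edge; boundary counts as intragenic for query purposes, since
the intragenic/intergenic split is binary. Intergenic distance is the
half-open gap between the element edge and the nearer transcript edge,
and upstream/downstream are defined in the gene's orientation with
separate windows (defaults 100 kb, hard-capped at 100 kb — the range over
which LTRs have been reported to act on genes). One corner is worth
noting: an element abutting a transcript edge exactly (gap 0) is reported
as upstream/downstream with distance 0, so distance 0 does not by itself
imply overlap.

Lookup uses a per-chromosome interval tree over window-extended transcript
spans; the result is contract-identical to a brute-force all-pairs scan
(tested against one). The profile summary reports location counts both
per (element, isoform) record and per distinct element, because an
element near several isoforms can relate to them differently.

Characteristic queries are conjunctions over seven optional fields
(superfamily, family, group/name, orientation, distance bound, location,
completeness). A gene symbol matches when *any* of its isoforms has at
least one matching record. The distance bound applies to intergenic
records only; combining it with `location="intragenic"` is rejected as
contradictory. Adding a constraint can therefore never enlarge the result
set (property-tested).

## Enrichment statistics

The 2×2 table counts gene symbols: list ∩ characteristic (a), list only
(b), characteristic only (c), neither (d), over a universe that defaults
to every symbol in the loaded annotation (a platform-restricted universe
can be supplied instead). Symbols are uppercased; list symbols outside
the universe are dropped with a logged count.

The p-value is Fisher's exact. For N ≤ 2000 it is computed by direct
hypergeometric enumeration in integer arithmetic: every table sharing the
observed margins has probability C(r,x)·C(N−r,c−x)/C(N,c), numerators are
built by an exact integer recurrence, the two-sided p sums numerators ≤
the observed one (integer comparison, so ties are exact) and the one-sided
(greater) p sums the upper tail; the single final division is correctly
rounded. Margin-level results are memoised, which is what makes the
exhaustive all-tables-to-N=60 validation cheap. Above N = 2000 the
implementation delegates to `scipy.stats.fisher_exact`; the two paths
agree to ~1e-9 at the switchover (tested). The two-sided p is the
headline number — the direction gate is the OR > 1 filter, so two-sided p
plus the OR gate reproduces the standard decision rule — with the
one-sided p exposed for power studies.

Odds ratios use raw counts; when any cell is zero all four cells get the
Haldane–Anscombe +0.5 and the result is flagged, keeping batch matrices
finite while the raw table remains available. Default significance is
raw p < 0.001 AND OR > 1 with no multiple-testing correction;
Benjamini–Hochberg (via statsmodels, adjusted p ≤ alpha) is offered
because batch mode invites it. Batch results are list-major and
deterministic, and export as a −log10(p) matrix signed by each list's
up/down tag.

## Synthetic data: what it emulates and what it does not

The generator plants elements with chosen family, truncation pattern,
strand, fragmentation plan (pieces per component, gaps drawn between
50 bp and the plan's `max_gap`) and relation to a host gene, then emits
the corresponding UCSC-dialect rmsk rows, a genePred table and an xref
map, plus a truth table. Fragment consensus coordinates are carved
deterministically from the planted model geometry (contiguous chunks, so
every planted component is fully intact and intactness has exact expected
values); genomic gaps model inserted sequence. Minus-strand elements are
exact mirror images of the plus-strand layout. Model lengths (e.g. LTR7
450 bp / HERVH-int 5.8 kb) are typical consensus sizes for each family.

Genes sit on a fixed grid with 450 kb pitch — more than twice the 100 kb
window plus element sizes — so a planted relation to one host gene
provably cannot create accidental relations to others, and "far"
intergenic elements are provably outside every window. Decoy fragments of
a different family are dropped into chain gaps to exercise
nested-insertion tolerance.

Gene lists with a planted odds ratio ρ are Bernoulli samples: inclusion
probability p₁ inside the characteristic set and p₀ outside, with
odds(p₁) = ρ·odds(p₀) and expected size solved by bisection. The realised
list size fluctuates around the target; the *expected* table has exactly
the planted OR.

The fixtures emulate annotation geometry, not biology: no sequence, no
divergence, no overlapping genes, no chromosome-scale density gradients,
and planted families are balanced rather than ERVL-MaLR-dominated as in a
real genome. Passing tests therefore demonstrate algorithmic correctness
(exact reconstruction, labelling, counting and calibrated statistics on
known ground truth), not recovery of any particular genome's element
census — for that, the `run` pipeline accepts the real UCSC dumps.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `max_distance` | 500 bp | largest joinable gap between fragments; the standard operating point, chosen where the defragmented-element count approaches its plateau |
| `window_up`, `window_down` | 100,000 bp | intergenic search range, gene-oriented, capped at 100 kb |
| `alpha` | 0.001 | raw p-value cutoff of the decision rule |
| `or_min` | 1 | odds-ratio gate (direction of association) |
| `EXACT_MAX_N` | 2000 | largest table total for the exact integer Fisher path |

## Validation problem sizes

The shipped validation uses a 20-element planted fixture (4 per
truncation type, fragments split in two with gaps ≤ 300 bp, nested
decoys) reconstructed at 500 bp; exhaustive Fisher-vs-enumeration
checking over all ~628,000 tables with N ≤ 60; calibration at a
2,000-symbol universe with a 600-symbol characteristic set and expected
list size 400 (1,000 null replicates; 200 replicates each at OR 2 and 4);
100 random 30-fragment fixtures for sweep monotonicity and 25 random
scenes for window/strand symmetry. These sizes make every check exact or
tightly calibrated while keeping the whole suite interactive.

## Known limitations

* The chaining heuristic is greedy left-to-right; it does not attempt
  global optimisation or model-aware pairing of 5′/3′ LTRs, so
  pathological interleavings of one family can in principle chain
  differently than a combinatorial optimum. Whether tandem solo LTRs
  within the join window should count as one or two elements is genuinely
  ambiguous; here they merge (and remain solo LTR).
* Superfamily assignment for models missing from the taxonomy falls back
  to the rmsk `repFamily` string; unknown LTR-class families become their
  own one-member family under `Unclassified`.
* The bundled taxonomy is minimal by design (25 LTR names plus internal
  partners); genome-scale runs on real annotations should extend it via
  `--taxonomy` for families outside that set, otherwise family-level
  grouping degrades gracefully to per-model families.
* No sequence-level features: no LTR-divergence dating, no liftover, no
  FASTA handling, no expression calling — gene lists are an input.
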