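# Methods

`altej` analyses repair-product junctions from a double-strand break (DSB)
with a defined substrate: two broken arms written 5′→3′ on the top strand,
the left arm ending at the break and the right arm beginning at it.  The
packaged construct is a P-element excision gap in which each arm carries an
8-bp target-site duplication (lowercase in display) and a 17-nt 3′
single-stranded tail (uppercase); the two tails are mutual reverse
complements.  Case is annotation only — all matching is case-insensitive.

## Junction decomposition

A junction read spanning the break is decomposed by **maximal retention**:

- `p` = length of the longest read prefix equal to a prefix of the left arm;
- `s` = length of the longest read suffix equal to a suffix of the right arm;
- if `p + s > |read|`, the overlap of length `mh = p + s − |read|` is a
  **microhomology** (MH), sequence attributable to either side of the break;
- if `p + s = |read|` the join is **blunt**; otherwise the middle segment is
  an **insertion**, sequence present at neither end of the original break.

Deletion extents are reported as `[min, max]` ranges with width `mh`,
because an MH can be assigned to either arm.  A deletion is flagged *past
the target* when its minimal extent exceeds the overhang plus the
target-site duplication on that side (17 + 8 = 25 nt for the packaged
construct).  `flank_exhausted` is set when the maximal deletion range
reaches the outer end of a supplied arm, i.e. the true deletion may exceed
what the supplied sequence can represent.  Reads that retain no sequence
from one arm (deletions running past the supplied flank) are not
decomposable and are rejected (`unanchored`); rows of the packaged tables
in that situation carry their class by annotation only.

Coordinates are 0-based, half-open, on the read's top strand.  Everything
is top-strand; the `BreakConstruct.swapped()` view exists only to express
the invariant that MH length is preserved under bottom-strand viewing.

### Mismatch-tolerant microhomology refinement

Imperfect microhomologies are found by scanning every junction-spanning
read span `[i, j)` such that the read outside the span matches the arms
exactly, the span matches **one** arm's continuation exactly, and the other
arm's corresponding positions with at most `max_mismatch` substitutions
(default 1), none at a terminal span position.  Ties break by length
(descending), then fewer mismatches, then left arm exact before right.

Only calls of at least `min_len` (default **6**) upgrade the exact call.
The rationale: an imperfect MH is only invoked when it is strictly longer
than any perfect microhomology the substrate offers (the longest perfect MH
in the packaged construct is 5 nt).  With a floor of 5, spurious 5-nt
one-mismatch overlaps (e.g. read `…AACAT…` against left `AACAT` / right
`ATCAT`) would reclassify junctions whose annealing is fully explained by a
short perfect MH, and the packaged tables would no longer reproduce.  The
floor is a parameter; 5 remains selectable.

Insertion-bearing junctions are not scanned for MH (insertion and MH are
mutually exclusive in this decomposition); an override flag exists.

## Five-way classification

With thresholds (`long_mh_min = 5`, `short_mh_max = 4`, `small_ins_max = 3`):
a non-empty insertion yields `small_insertion` (≤ 3 nt) or
`large_insertion` (≥ 4 nt); otherwise the refined MH length yields
`long_mh` (≥ 5 nt), `short_mh` (1–4 nt), or `blunt`.  Long microhomologies
and large insertions are the two alternative end-joining (alt-EJ)
signatures; the other three classes are typical of classical NHEJ.  The
short-MH ceiling of 4 nt is observationally neutral on the packaged tables
(no printed junction has a 4-nt MH); 3 is selectable.  Insertion class
takes precedence over MH class, and no upper bound is enforced on long MH.

Cohort summaries are multiplicity-weighted.  Mean insertion length is
computed over insertion-class isolates and reported to one decimal,
rounding half away from zero; percentages are rounded the same way.  The
fraction of junctions with > 3 bp insertions is taken over **all** isolates
of the cohort.

## Exact contingency testing

Two-cohort class comparisons use the two-sided Fisher's exact test under
the point-probability rule: the p-value sums hypergeometric probabilities
of all same-margin tables whose point probability is at most the observed
one times (1 + 1e-7).  The implementation uses exact integer binomial
arithmetic (`math.comb`); tables with a zero margin return p = 1, and
all-zero tables are rejected.  The test suite cross-checks against
`scipy.stats.fisher_exact` and against an independent vectorised
hypergeometric enumeration for every 2×2 table with total ≤ 40.  No
multiple-testing correction is applied.

## Template search and insertion segmentation

Insertions are scanned against the break-proximal windows of both arms
(window default 100 nt; the packaged arms are shorter and used in full) in
both orientations for **maximal ungapped** matches with at most
`max_mismatch` substitutions (default 1) and length ≥ `min_len` (default
4).  A hit is maximal when it cannot be extended on either end within the
mismatch budget; terminal positions of a hit must match, since a mismatched
terminal adds no template evidence.  Hits are ordered by length
(descending), mismatches (ascending), leftmost insertion span, leftmost
source span, left arm before right, direct before reverse complement.
Note that under maximal-only reporting the *number* of hits is not
monotone in the mismatch budget (two exact hits can merge into one longer
imperfect hit); what is monotone — and property-tested — is the set of
insertion positions covered by at least one hit.

Complex insertions are segmented greedily: repeatedly place the best
remaining hit that fits entirely within still-uncovered positions, with
the already-placed insertion prefix offered as an additional template
source (snap-back copying, default on); leftover positions become
untemplated runs.  `templated_fraction` is templated nucleotides over
insertion length (0 for an empty insertion).  Greedy longest-first tiling
does not guarantee full coverage of a perfectly templated insertion for
arbitrary `min_len` (a long cross-boundary hit can orphan a residue shorter
than `min_len`); with `min_len = 1` and exact matching, full coverage is
guaranteed whenever the arms contain all four bases, which is the setting
used to validate error-free simulator output.  There is no null model for
template significance, and no genome-wide search beyond the supplied arms.

## The junction simulator (synthetic-data generator)

The generator implements a mechanistic alt-EJ model: unwinding exposes
single-stranded flank; ends either anneal at a pre-existing microhomology
(long or short), join bluntly, or receive an insertion synthesised in
iterative rounds before joining.

- **Pathways** are drawn from `pathway_weights` over
  {long_mh_anneal, short_mh_anneal, blunt, templated_insertion,
  untemplated_insertion}.
- **Resection** per end is geometric (support 0, 1, 2, …; default
  parameter 0.25, mean 3 nt) — the distribution is a modelling assumption,
  not a measured quantity.
- **Annealing/blunt** outcomes are sampled from a precomputed catalog of
  all left-prefix/right-suffix joins within `unwind_window` (default 25 nt)
  of the break, bucketed by the class their decomposition-plus-refinement
  receives and weighted by the geometric resection probabilities of the
  implied end losses.  If the long-MH pathway is drawn but the substrate
  offers no long MH, the draw falls back to short MH (then blunt), recorded
  in the trace.  Sampling from decomposition-consistent buckets makes the
  generative label and the classifier label agree by construction.
- **Templated insertions** concatenate 1 + Geometric(`rounds_geom_p`)
  rounds; each round copies a uniform 3–8 nt run from a uniform position of
  either arm's window (reverse complement with probability 0.5; from the
  nascent insertion with probability `snapback_prob` = 0.15), mutating each
  base with probability `error_rate` = 0.02.  Untemplated insertions are
  1–3 random nucleotides.  Insertion boundary bases are resampled to differ
  from the arm continuations: a boundary base equal to the continuation is,
  by the decomposition's own definition, retained flank rather than
  insertion.  Resampling counts are recorded in the trace.
- **Presets**: `wildtype`/`spnA` weights follow the baseline alt-EJ
  spectrum of the Rad51-deficient cohort (long 0.30 / short 0.40 / blunt
  0.02 / templated 0.14 / untemplated 0.14); `mus308_D5` removes long-MH
  annealing but keeps (and lengthens, via `rounds_geom_p` = 0.35) complex
  insertions; `mus308_D2` removes long-MH annealing and reduces templated
  insertion to 0.005 (≤ 5 % of wildtype).  `wildtype` and `spnA` share
  weights because the baseline junction spectrum is only characterised in
  the Rad51-deficient background.
- **RNG**: one seeded `numpy` generator threaded through all sampling; no
  global state.  Every read retains ≥ 1 nt of each arm.  Traces replay to
  the exact read sequence.

What the generator emulates: the class spectrum, MH lengths (including the
possibility of imperfect long MH via the catalog's refinement), insertion
lengths from 1 to ~50 nt including composite templated insertions, and
resection within the overhang/target region.  What it does not emulate:
sequencing error outside the junction, clonal correlation between isolates,
kilobase-scale deletions past the supplied flank, and any sequence bias of
the polymerase.  Passing end-to-end tests therefore demonstrates internal
consistency of decomposition, classification, and statistics on realistic
junction structures — not performance on raw chromatogram data.

Because the two insertion pathways produce the same two observable classes,
pathway-weight recovery is assessed on long/short/blunt individually and on
the two insertion pathways pooled.

## Numerical and interface choices

- Rounding of reported means/percentages: decimal half-away-from-zero.
- All TSV writers emit a fixed column order with LF line endings;
  fixed input and seed give byte-identical output.
- FASTA multiplicity uses a `mult=N` header tag (default 1).
- The construct config is a flat `key = value` text file; fixtures are
  plain TSVs packaged with the code.
- Degenerate inputs: empty cohorts summarise to `n = 0` with undefined-safe
  (None) means; reads lying wholly in one arm raise a degenerate-read
  error (checked before the unanchored case, as it is the more specific
  diagnosis); all-zero contingency tables are rejected.

## Known limitations

- Four printed rows of the packaged tables are internally inconsistent
  with maximal retention (one is byte-identical to a row printed with a
  different microhomology; in three others a boundary base of the printed
  middle field extends an arm match).  The fixture regression suite pins
  their actual maximal decompositions; the strict row-identity acceptance
  test reports them as failures by design.
- Gapped alignment, reads with errors outside the junction, and
  double-strand representation are out of scope.
- Template assignments are validated against the package's own exhaustive
  oracle; the original per-row template annotations (typographic
  underlining) are not machine-readable and cannot serve as ground truth.
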