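# Methods

## Model

A STARR-seq experiment yields two fragment libraries on the same genome: the
input insert pool (control, the abundance baseline) and the reporter cDNA
(treat, abundance ∝ regulatory activity). At a silencer the reporter is
depleted. `fastnr` treats the reporter count at a single nucleotide as the
number of "failures" of a negative-binomial process whose success
probability is estimated from the control library at that base:

- m = treatCount (reporter depth at the base)
- n = treatTotal − treatCount ("successes": the rest of the reporter library)
- p = (controlTotal − controlCount)/controlTotal

site p-value = P(X ≤ m) for X ~ NB(n, p), the probability of seeing a
reporter depth this low or lower if the base behaved like the control
baseline. The defining series Σ_{i=0..m} C(i+n−1, n−1) pⁿ (1−p)ⁱ includes the
i = m term, i.e. the CDF is inclusive; it is evaluated as the regularized
incomplete beta I_p(n, m+1) (`scipy.special.betainc`), which is accurate for
n up to at least 10⁹ where literal summation is infeasible. The exact-rational
summation survives only as a test oracle.

Degenerate parameterizations cannot support a depletion claim and are never
called: controlCount = controlTotal gives p = 0 (the scalar API raises; the
vectorized track records 1.0), and treatCount = treatTotal gives n = 0
(likewise 1.0 in tracks). Totals are library-wide fragment counts, not
per-contig counts, because the test compares a site against its whole
library.

The model assumes independent fragment placement; no dispersion is estimated
from replicates and no sequencing/GC bias correction is attempted
(deliberately out of scope).

## Calling pipeline

All coordinates are 0-based half-open. Coverage is unstranded per-base
fragment depth; fragments are template spans of proper pairs (TLEN), read
spans otherwise. Stages, in order, each deterministic:

1. **Prescreen.** Sites with controlCount − treatCount ≥ `min_diff`
   (default 12 — the count difference that corresponds to the 10⁻⁵ p-value
   threshold at typical depths; a fixed knob, not auto-derived) *and*
   site p < `p_thresh` (10⁻⁵) become anchors.
2. **Windows.** Each anchor centers a `window_size` = 601-bp window
   (odd ⇒ symmetric, 300 bp each side), clamped at contig edges; the
   clamped length is what later fractions are computed against. Runs of
   adjacent anchors deliberately seed many overlapping windows;
   deduplication happens at overlap resolution.
3. **Fraction filter.** Keep windows where ≥ `min_fraction` = 3/4 of bases
   have p < `p_thresh` (≥ at exact equality).
4. **Window p-value.** The per-window aggregate is configurable — minimum
   per-base p (default; order-consistent with anchor strength) or median.
5. **Overlap resolution.** Global greedy by ascending window p (ties:
   leftmost start, then smallest end): keep a window iff it overlaps no
   already-kept window. Greedy-by-p is order-independent, unlike pairwise
   elimination, and always retains the best window of an overlap chain.
6. **Curve-similarity filter.** Over each surviving window, the treat and
   control per-base coverage curves (raw counts, not library-normalized —
   the metrics are scale-free where that matters) are compared with the
   configured metric; a window is discarded when its score on the common
   higher-is-more-similar scale (cosine: 1 − distance; Euclidean:
   1/(1+d); Pearson/gradient: the correlation) exceeds
   `similarity_threshold` = 0.9. Cosine is the default metric. The common
   scale is a design choice of this package: a single 0.9 threshold must
   apply to four metrics with different native ranges, and mapping each to
   [−1, 1]/[0, 1] with 1 = identical is the least surprising way to do it;
   the metric and threshold remain configurable. An all-zero reporter
   curve makes the cosine undefined; it is scored as maximal distance
   (score 0, kept) since total depletion is the strongest silencer signal.
   Zero-variance curves make correlations undefined; they score 0 (kept)
   with a warning.
7. **Correction & report.** The surviving window p-values are corrected
   across windows — BH step-up by default, Bonferroni available — and
   calls require corrected p < `report_thresh` = 10⁻⁵. Correction happens
   last, across final candidate windows only, matching the pipeline order
   of screening first and correcting what survives.

Each call carries the window p, corrected p, similarity score, the
similarity index −log₂(cosine distance) (∞ at distance 0; capped only for
display), and the strength ratio −log₂((treat+ε)/(control+ε)) with
pseudocount ε = 1 guarding zero coverage.

The caller consumes no randomness: fixed input and config give byte-identical
BED output. Tightening any threshold can only shrink the candidate set at
every stage, which the suite checks as a monotonicity property.

## Spike-in benchmark

The simulator reproduces the standard read-removal protocol: tile the contig
into 400-bp bins, keep bins overlapped by ≥ 100 fragments (any overlap, not
containment), sample truth bins uniformly without replacement, and build the
reporter library by deleting round(r·k) of each truth bin's k fragments
(round half to even) at removal level r ∈ {0.3, 0.5, 0.7, 0.9}; fragments
outside truth bins are untouched. Whole fragments are removed (a sequenced
pair disappears together); a fragment overlapping two truth bins is assigned
to the bin containing its midpoint — largest overlap, leftmost on ties, when
the midpoint falls in a gap — so nothing is removed twice. One truth set is
shared across the four levels.

The synthetic base library draws per-bin fragment counts from a negative
binomial (genome-wide counts are overdispersed relative to Poisson; size
parameter `dispersion` = 20, a moderate overdispersion typical of
plasmid-input sequencing), fragment starts uniform within the bin and
lengths uniform on 200–600 bp (the span captured by paired-end mapping with
a wide insert limit). The packaged benchmark uses a 400-kb contig
(1,000 bins), ~200 fragments/bin and 50 truth regions — a desk-scale
rendition of the chr22 protocol (which uses 1,000 truth regions on a ~51-Mb
chromosome, the `SimConfig` default `n_regions`); a real insert BAM can be
substituted as the base library to run the protocol at full scale.

What the generator does *not* emulate: mappability and GC bias, PCR
duplicates, chimeric fragments, biological silencers already present in the
base library, and inter-replicate dispersion. Passing benchmark tests
therefore demonstrates that the pipeline recovers engineered depletion under
its own model assumptions, not that real-data call sets are complete or
uncontaminated.

Because fragments (not base-wise signal) are removed, depletion bleeds up to
one fragment length beyond a truth bin; coverage is exactly equal to the
base library only beyond that shoulder, and calls may extend past the bin
they detect.

Random streams are split per stage (base generation / truth sampling /
removal) from one integer seed via `SeedSequence`, so e.g. regenerating the
base library does not perturb which fragments are removed.

## Evaluation statistics

Detection power = truth bins overlapped by ≥ 1 call, over total truth bins;
each bin counts once. All overlap rules are ≥ 1 bp with no reciprocal
fraction. Venn counts between two call sets require each set to be internally
disjoint and report (only A, only B, both-from-A's-perspective). The
similarity–strength correlation is the Pearson correlation of the similarity
index against the strength ratio across ≥ 3 calls with finite values of
both; fewer calls or zero variance is reported as not available rather than
a number.

At the packaged depth (~200× ), power rises steeply with removal level:
90% removal is almost fully recovered while 30–50% removal yields few or no
calls — gentle depletion rarely clears both the 3/4-fraction rule (its
sub-10⁻⁵ footprint is narrower than 3/4 of a 601-bp window) and the
similarity filter (a mildly scaled-down curve still tracks the input). The
suite asserts the monotone ordering, not absolute power at the gentle
levels.

## Numerical choices and edge cases

- p-values computed in linear space; the quantities thresholded (10⁻⁵)
  are far above double underflow, and betainc is monotone in m as the
  tests verify against exact arithmetic to 10⁻¹⁰.
- BED score column = min(1000, round(−10·log₁₀ adjusted p)), 1000 at
  adjusted p = 0.
- Empty anchor set, empty candidate set or a fully-filtered window list
  each yield an empty call list, not an error.
- bedGraph input must be non-overlapping; loaders report the offending
  line number. chrom.sizes is the authority for contig lengths in the
  CLI; the library infers the maximum fragment end when no length is
  given.

## Known limitations

- Single-contig pipeline per invocation unit; the CLI loops contigs and
  corrects per contig rather than genome-wide.
- No replicate handling: one treat/control pair per run.
- The Euclidean metric's common-scale mapping 1/(1+d) depends on depth
  (d is unbounded), so its 0.9 threshold is far stricter than cosine's;
  cosine is the recommended and default metric.
- The per-window aggregate p and the per-metric threshold scale are
  package design choices (documented above), kept configurable.
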