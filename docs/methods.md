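# Methods

This note records the models, conventions and numerical choices behind
`isomirseq`, and what the simulation-based tests do and do not establish.

## Reference model

Mature miRNAs are intervals on precursor hairpins, held internally in
0-based half-open coordinates (GFF3/TSV I/O converts from the miRBase
1-based inclusive convention at the boundary). Sequences are normalised
to the DNA alphabet (U→T, uppercase) so reads and references compare
directly. Each hairpin carries at most one 5p and one 3p mature; when a
mature id lacks a `-5p`/`-3p` suffix the arm is inferred from which
hairpin half its midpoint falls in (toy references need not follow
miRBase naming). The hairpin is the source of *templated flanks*: the
nucleotides adjacent to a mature end, against which end extensions are
classified as templated (shifted-cleavage-consistent) or non-templated.

## Preprocessing

Filters run in a fixed order per read — quality, then adapter, then
insert length — and each read is counted in exactly one bucket (first
failing rule wins), so reports always partition the input. The order is a
deliberate choice: prose descriptions of such pipelines rarely pin it
down, and a single deterministic order keeps accounting auditable. The
quality rule is the FASTX `fastq_quality_filter` semantics, boundary
inclusive: pass iff ≥ `percent`% of bases have Phred ≥ `cutoff`
(defaults 90/30), evaluated on the untrimmed read. Adapter matching is
exact — a full-adapter match anywhere, or an adapter *prefix* of ≥ 5 nt
running to the read's 3′ end (reads that terminate mid-adapter); no
mismatch tolerance, since tolerant matching would make the kept-read set
depend on an error model the data cannot confirm. Quality strings are
Sanger Phred+33 only; other encodings are rejected rather than guessed.

## IsomiR calling

A read is explained as a hairpin-anchored variant of a mature: 5′ offset
in [−3, +3] (negative = trimming; positive extensions must be templated,
i.e. drawn from the hairpin — non-templated 5′ additions are not
modelled, as 3′-specific tailing dominates biologically), 3′ offset in
[−3, +3], ≤ 1 substitution in the templated body. A 3′ extension is
compared against the hairpin flank; a mismatching suffix is a
*non-templated tail*, which counts as an addition event, never as
substitutions. Tails are accepted only as pure extensions (starting at or
beyond the canonical 3′ end); a hypothetical "trim then tail" read is
handled by the mismatch tolerance or left unassigned, keeping the
invariant that a tail implies a positive net 3′ offset.

Candidates are scored lexicographically: fewest mismatches, smallest
|offset5|+|offset3|, templated before tailed, shortest tail. Ties across
different matures mark the read ambiguous; ambiguous reads are dropped by
default (conservative and reproducible; no fractional assignment).

Labels project calls onto the conventional one-axis nomenclature:
canonical `0`, 3′-only variants `-3`…`+3`, any 5′ change `5p:±k` (reads
varying at both ends are reported under the 5′ compound label, since a
single-axis label cannot encode both), non-templated tails `nt:<seq>`.
Calls carrying substitutions get a `|m<k>` suffix so that `0` always
means an exact canonical match; these SNP-like classes stay in the miRNA
total (they pass the mapping tolerance) but never merge with clean
classes. One consequence worth knowing: at error rate ε each clean class
is shadowed by a `|m1` twin holding ≈ Lε of its reads.

Calling is memoised per unique read sequence. Small-RNA libraries are
massively redundant, so the pipeline's cost is linear in *unique* reads;
the same collapsing trick underlies the simulator's output format.

### Validation oracle

`isomirseq.bruteforce` answers the same question by materialising every
variant string in the window (all offsets, all 4^t tails) and
string-comparing, sharing no code with the anchored enumerator.
Agreement on 1 000 random reads (in-window constructions, mutated reads,
tails, and random sequences) is asserted in the acceptance suite. The
oracle is exponential in tail length and exists only for toy references.

## Quantification

RPM uses total miRNA-mapped reads per sample as denominator (standard
for miRNA-seq and robust to non-miRNA contamination; clean-read totals
are available as an alternative via `library_sizes`). Abundance filters
take the *mean* RPM per condition and keep a feature if any condition
passes (miRNA ≥ 10 RPM, isomiR ≥ 1 RPM, inclusive), since a per-condition
rule needs an aggregation choice and the replicate mean is the least
surprising one.

IsomiR proportions divide each label by its miRNA's total in that
sample, restricted by default to templated labels — non-templated tails
are removed from numerator *and* denominator, reflecting the view that
only templated end variation reads on Dicer cleavage position. Cells
with a zero denominator are missing (NaN), never zero, and missing cells
drop out of downstream tests rather than biasing them toward null.

Arm ratios log₂((RPM₅ₚ+ε)/(RPM₃ₚ+ε)) use ε = 0.5 RPM (configurable); the
pseudocount bounds the ratio for dropout arms and cancels under arm
swap, keeping the table antisymmetric.

## Differential testing

`t_test` implements the spreadsheet nomenclature directly: type 2 =
pooled-variance two-sample t (df = n₁+n₂−2), type 3 = Welch with
Satterthwaite df, both two-tailed. With `paired=True` (the default) the
classic paired test runs on per-experiment differences; pairing is the
default because treated and control libraries are prepared from the same
culture in each experiment. Zero-spread degenerate input returns
p = 1 (equal means) rather than NaN. Both variants are asserted equal to
scipy's `ttest_ind` to 1e-12.

Fold changes are mean per-experiment log₂((treated+ε)/(control+ε)) on
RPM with ε = 0.5. Significance is per-feature p < α with α = 0.05 and no
multiple-testing correction — the per-feature convention common in
small-n replicate designs of this kind — but a Benjamini–Hochberg
`q_value` column is emitted alongside as a clearly separate extension.

## Simulator

The generator emulates: mature-derived inserts with designed (offset5,
offset3, tail) classes; read-through into the literal 3′ adapter at a
fixed 50-cycle read length (so trimming is genuinely exercised), with a
fixed filler sequence after the adapter so identical inserts collapse to
identical reads; constant Q38 quality strings, with a designed fraction
(default 2 %) of reads failing the 90/30 rule via low-quality 3′ cycles;
substitution-only errors at 0.001/base applied to the insert (indels and
adapter errors are out of scope — they would break the window semantics
the caller defines); and per-replicate biological variability as
multiplicative log-normal jitter (σ = 0.02) on abundance weights and
mixture probabilities, with multinomial sampling on top. Everything is
deterministic under a seed.

Toy references place a 5p and 3p mature (20–23 nt) with ≥ 5 nt flanks and
an 8–12 nt loop, and enforce pairwise edit distance ≥ 6 (edlib) between
all canonical sequences so the ±3/1-mismatch window cannot collide
across matures. Designs are validated before any I/O: every designed
class must reconstruct to an insert the caller resolves unambiguously
back to its own (mature, label).

The default base design uses 200 000 reads per library, 3 replicates per
condition, abundance weights 1/(rank+1) across matures, and the mixture
{0: 0.60, −1: 0.25, −3: 0.10, nt: 0.05} for every mature; the tail base
is chosen per mature to differ from the hairpin flank. Scenarios derived
from it: *null* (conditions identical); *proportion shift* (canonical
0.60 → 0.45 compensated by the −3 class — canonical down, shorter
isoform up); *abundance* (×0.5 on one miRNA). The abundance scenario
targets the *least* abundant mature: RPM is compositional, and halving a
miRNA that owns a large share of a 6-mature toy library drags the
denominator with it, understating the absolute effect; at a ~7 % share
the distortion stays below ~0.04 log₂ units, the regime a real library
(hundreds of species) is in.

### What the simulations do and do not show

The truth table records, per class, emitted reads, designed low-quality
reads, and errored reads, so recovery is always measured against an
honest denominator. With error rate 0 the pipeline must reproduce the
truth *exactly* (asserted at 6 × 200 000 reads); with defaults, the null
scenario calibrates both t-tests (rejection within the exact binomial
95 % band around 0.05 at 200 features) and the effect scenarios are
recovered (shift pattern in ≥ 90 % of 20 repeats; mean log₂ fold change
within 0.1 of −1). These checks validate the pipeline's logic and
statistics under its own generative model; they do not establish
performance on real libraries, where ligation bias, PCR duplication,
indels, heteroscedastic quality, multi-mapping across paralogous miRNA
families, and non-miRNA content all exist and are not simulated.
Ambiguity in particular is rare by construction here (edit-distance
separation) but common in real miRNA families.

## Problem sizes

Default test and acceptance runs use 3-hairpin references (6 matures)
for round-trip and effect checks, a 10-hairpin reference × 10 repeats
(200 features) for calibration, 200 000 reads per library for effect
recovery and 100 000 for calibration, and 1 000 reads for the oracle
comparison — sizes chosen so the whole suite exercises every claim at
full read depth while remaining comfortably interactive.

## Known limitations

- Single-end, 3′-ligation protocols only; no UMIs, no paired-end.
- The caller targets curated hairpin sets, not genomes; no SAM/BAM.
- Non-templated 5′ additions and trim-then-tail reads are not modelled.
- The t-test route assumes approximate normality of replicate log-RPM
  and proportions; count-model alternatives (NB GLMs) are out of scope.
- No multiple-testing correction in the headline significance calls
  (by design, see above); use the `q_value` column when screening many
  features.
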