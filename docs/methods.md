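# Methods

This note records the models implemented in `hdramp`, the conventions
chosen where several were defensible, and what the simulation-based
tests do and do not establish.

## Target-site geometry and template design

Coordinates are 0-based; `cut_index` is an inter-base coordinate on the
reference, with SpCas9 assumed to cut bluntly 3 bp upstream of the PAM
on the protospacer strand. Substitution positions are cut-relative on
the protospacer strand with no position 0: +1 is the first base 3′ of
the cut. The PAM occupies +4…+6.

The design panel is the ten-member grid {non-target, target} ×
{60 S, 120 S, 180 S, 120 A left, 120 A right}. "Non-target" (NT) donors
share sequence with the protospacer strand (the strand the sgRNA does
not bind); target (T) donors are their reverse complements. Arms are
measured on the protospacer strand drawn 5′→3′ with the PAM to the
right, so "left" is the PAM-distal side; asymmetric designs carry a
30 nt short arm and a 90 nt long arm, "A left" placing the long arm
PAM-distal. Symmetric designs split their length evenly around the cut.

The substitution plan places five changes in the window −15…+11
(PAM positions excluded — the PAM guanine mask is its own, separately
flagged substitution) and always includes the admissible position
closest to the cut, since that position defines the HDR read-out.
Remaining picks spread across the window by farthest-point selection, a
deterministic stand-in for the hand-curated spacing of published
designs. When a reading frame is supplied every change must be
synonymous; among synonymous options we prefer transversions (maximally
distinct from the reference base) with alphabetical tie-breaking. The
published designs used a codon-optimisation webtool whose rule is not
stated; this rule is declared, not inferred.

The sgRNA gBlock is `T7 leader (25 nt) + GG + last 18 nt of the
protospacer + invariant scaffold (80 nt)` = 125 nt.

## Read simulation

`simulate_sample` draws each molecule's outcome from a multinomial over
{WT, NHEJ, HDR_perfect, HDR_erroneous}. Defaults sit at embryo-pool
magnitudes: 4% perfect, 4% erroneous, 40% NHEJ, the rest wild type,
with per-base sequencing error 0.1% (substitutions only; quality
strings are a constant Q30 because the classifier does not model
qualities). Single-end mode emits full molecules — these represent
overlap-merged 2×250 amplicon pairs; paired mode emits mates from the
molecule ends and requires the amplicon to be spannable with ≥ 20 nt
overlap.

* **Perfect** molecules apply a sampled subset of the planned
  substitutions; the cut-proximal one is always incorporated (it defines
  the category). Default incorporation declines linearly from 1.0 next
  to the cut to 0.25 at 15 nt — the several-fold positional decay seen
  in embryo data.
* **NHEJ** molecules carry one indel centred on the cut: sizes
  geometric (p = 0.25) capped at 30, deletions twice as common as
  insertions. Real indel spectra are locus-specific; this is a
  plausible stand-in, not an estimate.
* **Erroneous** molecules insert 1–3 donor substrings at the cut, each
  forward or reverse-complement (P(reverse) = 0.3), lengths uniform
  from 20 nt to full length, optionally interleaved with 3–8 nt of
  random filler (kept below the fragment-assignment threshold so that
  filler reads back as unassigned) and with an optional one-sided locus
  deletion of up to 20 nt. The first fragment is constrained to cover
  the cut-proximal substitution — SDSA initiates at the cut — so every
  generated erroneous molecule is a genuine HDR-erroneous product.
  With microhomology weight w > 0, switch landing sites with ≥ 2 nt of
  homology to the preceding junction context are favoured (w = 0 gives
  uniform switching; the default w = 4 reflects that observed junctions
  tend to carry short homologies). Every read records its fragment
  chain, and reconstructing the molecule from the chain is exact: the
  generator is its own decoder, which is what makes downstream stages
  testable.

What the simulator does **not** emulate: PCR duplicates and chimeras,
instrument error profiles and quality decay, coverage bias, and any
locus-specific indel or integration spectrum. Passing tests therefore
demonstrate correctness of the analysis given the assumed generative
structure, not calibration against a particular sequencing run.

## Read classification

Reads are aligned to the reference amplicon with a local
(free-end-clip) affine-gap aligner (Biopython's `PairwiseAligner`):
match +2, mismatch −4, gap of length L costs 12 + L. These scores make
a ≥ 10 nt foreign insertion clip or gap out rather than force-align.
Both read orientations are tried (the reverse only when the forward
score is below 90% of the maximum attainable), so a read and its
reverse complement always classify identically.

Novel sequence = internal insertions plus terminal soft clips of
≥ 10 nt. It is decomposed against three sources — donor forward, donor
reverse-complement, local reference — by an exact DP whose objective is
lexicographic: (1) maximise assigned bases, (2) minimise fragment
count, (3) canonical tie-break (donor before reference, forward before
reverse, smallest oriented source offset). Assigned fragments need
≥ 10 matching nt (below that, provenance in a 4-letter alphabet is
statistically unreliable) at mismatch rate ≤ 5%. The objective order
matters: count-first would collapse everything into a single unassigned
fragment, so assigned-bases-first is the only non-degenerate reading.

Substitution calling is read-level by default (`anywhere`): a planned
substitution counts as present if the aligned genomic base carries it
*or* a donor-derived fragment of the read's chain covers its donor
offset. This mirrors counting reads "containing" the substitution; a
`genomic_only` mode restricts to the aligned position. Categories:

* `ambiguous` — unplanned mismatch rate above 5× the configured
  sequencing-error estimate (default estimate 1%, i.e. ceiling 5%);
* `HDR_erroneous` — closest substitution present, ≥ 1 donor fragment;
* `integration_without_hdr` — donor fragment without the closest
  substitution (reported separately rather than folded into erroneous);
* `HDR_perfect` — closest substitution, no donor fragment. The default
  (read-level) definition tolerates co-occurring indels; `strict` mode
  routes those to `mixed_hdr_indel`;
* `NHEJ` — indels or novel sequence without donor fragments or
  substitutions; `WT` — none of the above. Reads carrying only
  cut-distal substitutions (no closest, no fragments, no indels) have
  no natural category in this scheme and are counted as WT; their
  presence vectors still feed the position curve.

Known limitation: donor homology arms are reference-identical up to the
planned substitutions, so insertion boundaries are genuinely ambiguous
and the extracted novel segment can be a rotation of the generated one.
Category calls and substitution coverage are robust to this; exact
chain-versus-truth identity is not guaranteed and is not claimed.

## Rates and statistics

Percentages are over reads passing QC. Perfect + erroneous = total HDR
holds exactly on counts by construction. The position curve reports,
per planned position, the percentage of reads that are non-erroneous
and carry that substitution.

Group comparisons mirror the study designs: one-way ANOVA with the
replicate experiment as a blocking factor (via statsmodels OLS);
Kruskal–Wallis with hand-implemented Dunn pairwise z tests
(tie-corrected) and Bonferroni adjustment (no post-hoc package is
assumed available); and two-sample t / Mann–Whitney with an optional
Shapiro–Wilk gate at α = 0.05 — the normality-assessment procedure is a
declared convention, not something the study specifies. Founder
screening flags samples whose scarless percentage exceeds a threshold
(default 10%).

## Microhomology and template switching

`junction_mh` is the maximal exact suffix–prefix overlap of two
sequences. For fragments with a known source, junction homology is
instead measured against the source bases immediately 5′ of the
fragment's start in its oriented source — the bases a re-priming 3′ end
would anneal to; for unassigned filler the literal overlap with the
filler sequence is recorded. Homology is exact-match (the defensible
default given only qualitative published evidence of "short
microhomologies"); contexts are capped at 30 nt.

A chain of k fragments yields k + 1 junctions (entry from the genome,
k − 1 internal switches, resumption of the genome). The enrichment
statistic is the mean microhomology over *internal* junctions into
assigned sources only: entry and resumption positions are pinned by the
cut site, carry no information about switch-site choice, and would
miscalibrate the null. The null redraws each junction's landing
position uniformly over the admissible starts of its oriented source,
holding source, orientation, fragment length and upstream context
fixed; the one-sided p-value uses the (1 + exceedances)/(n + 1)
small-sample form. The study articulates no null model; uniform
redrawing is declared here. Under the generator's own uniform switching
the test is calibrated (conservatively, as the +1 form implies), and a
strong bias (w = 50) is rejected at p < 0.05 with 1000 permutations.

## Problem sizes and numerical choices

Simulated samples use 4,000–10,000 reads; mixture recovery is judged
against 3-binomial-SD bands, per-read truth agreement against a 99%
floor at zero sequencing error, and the calibration check uses 40–50
replicate simulations at 200 permutations. The amplicon fixture is
240 bp with the cut mid-amplicon so that 180 nt templates fit with
margin. Decomposition is exact DP (no heuristics), so its oracle test
is equality, not approximation; alignment is checked for score equality
against an independent full-matrix Gotoh implementation. Seeds are
fixed everywhere; identical seeds give byte-identical FASTQ.
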