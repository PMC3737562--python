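# Methods

This note records the models, conventions and numerical choices behind
`allele4c`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Restriction geometry and the fragment-end database

Coordinates are 0-based half-open throughout; BED and bedGraph exports
follow the same convention. Cut offsets are fixed by enzyme chemistry:
HindIII cuts `A^AGCTT` (offset 1) and DpnII cuts `^GATC` (offset 0), so a
fragment downstream of a HindIII cut begins with the `AGCTT` remnant and a
DpnII-terminated piece begins with `GATC`. Digestion scans every position,
so overlapping recognition-site occurrences all cut.

A fragment end runs from a first-cutter boundary to the nearest internal
second-cutter cut, or to the opposite boundary when the fragment is
*blind* (no internal site). Chromosome-terminal fragments contribute one
end (only a cut boundary is a ligatable 4C end); interior fragments
contribute two. End sequences are stored on the plus strand once; reads
arriving from the 3′ side are matched against the reverse complement at
lookup time. Uniqueness is computed over oriented mapping prefixes
(`map_prefix_len`, default 36 bp, set to the post-trim read length in the
pipeline); ends sharing a prefix are flagged non-unique and excluded —
together with blind ends — from all profile statistics. Blind ends stay in
the database so that reads hitting them are accounted as
`blind_discarded` rather than silently lost.

Mapping is an exact hash lookup rather than an external aligner: the
assay's contract is "no mismatches", which makes exact matching both
faithful and dependency-free. Reads shorter than the prefix match only
ends whose full oriented sequence equals the read; the minimum post-trim
length is 12 bp, below which exact matches stop being unique even in toy
genomes.

## Allele assignment

PE pairs are assigned by the single read-2 base at the viewpoint SNP
offset (case-insensitive exact match). Pairs matching neither allele's
base — or with read 2 too short to cover the SNP, a distinct reason code —
are *ambiguous* and discarded from both profiles rather than split
proportionally: allele purity is the point of the assay. With a
substitution error rate `e` and a uniform error model, the read leaves the
correct pool at rate `e`: one third of substitutions at the SNP base
produce the other allele's base (mis-assignment `e/3`), two thirds produce
a base matching neither (ambiguous `2e/3`). The accounting identity
`mapped + unmapped + multi + blind + primer-mismatch + too-short +
ambiguous = input` holds for every run and is asserted in the tests.

For the SE strategy the allele selectivity is a property of the template,
not a software filter: the extra DpnII site on the excluded allele severs
the primer-to-junction segment, so that allele yields no amplifiable
ligation product. The simulator realizes this by placing the RFLP SNP
inside the viewpoint trim region: excluded-allele reads differ there and
fail the exact viewpoint-sequence match (and their captures are junk for
the retained-allele database anyway). `enforce_se_allele` therefore only
tags reads with the retained allele and records provenance.

## Contact model and simulator

Per allele, cis contact probability decays as `|x − x_vp|^−α` (default
α = 1, the generic polymer-decay scale), is multiplied by an attenuation
factor (default 0.1) once per topological-domain boundary crossed, and by
a fold factor (default 8) inside enriched regions; trans ends share a
fixed `trans_rate` of total mass uniformly before enrichment, reflecting
the strong intra-chromosomal preference of 4C captures. The viewpoint's
own fragment and its two immediate neighbours get probability zero —
self-ligation and undigested-template territory, masked from analysis as
standard 4C practice. Alleles are sampled 50/50 (F1 diploid); errors are
substitutions only (mapping is exact-match, so indels would only lower
yield without adding test power); seeds are mandatory arguments, never
global state.

Two canned studies fix the conditions used throughout the tests:

- **default study** — chr12 10 Mb (viewpoint mid-chromosome inside a 3 Mb
  domain at 3.5–6.5 Mb), chr2 6 Mb trans, trans_rate 0.15, four far-cis
  and three trans enriched regions for the "lymphoid" condition, disjoint
  regions for "brain", plus a domain-only condition for boundary work;
  reads: 10⁵ pairs, 36 bp, 20 bp P1 primer (16 bp mapped capture).
- **sparse-background study** — chr12 6 Mb plus a 78 Mb trans chromosome
  at trans_rate 0.08, sized so that 10⁵ reads leave the per-allele trans
  coverage near π ≈ 0.1, the regime where binarized window statistics are
  informative; six 1 Mb lymphoid and five disjoint brain enriched regions.

Uniform base composition makes restriction-site spacing analytically
predictable (expected HindIII fragment 4⁶ = 4096 bp, verified within 20%
on 10 Mb). The generator plants SNPs only where they neither create nor
destroy a first-cutter site on either haplotype, so both alleles share one
fragment grid; one SNP always completes a GATC on allele B only,
exercising RFLP detection. The expression track lays transcription down
in 1 kb blocks sampled without replacement, so realized fractions match
their targets to within one block per region.

What the simulator does **not** emulate: PCR duplicates, base-quality
degradation, indels, GC or mappability bias, chromatin heterogeneity
between cells, and real mammalian genome size. Passing tests therefore
demonstrate correctness of the analysis logic under the stated generative
model, not performance on real libraries.

## Profiles and boundaries

Normalization is reads per million mapped (all mapped reads, cis + trans,
per viewpoint/allele): the simplest scale that is invariant to sequencing
depth and comparable across samples. The running median uses window
w = 21 fragments with a symmetric shrinking window at the edges (the
largest centered odd window that fits), keeping output length equal to
input without inventing data; w = 1 is the identity and even windows are
rejected.

Boundary candidates are local maxima of
`log2((mean left flank + ε)/(mean right flank + ε))` on the smoothed
profile (flank 10 ends, ε = 0.5 normalized units, threshold |score| ≥ 1,
i.e. a two-fold drop). Because the running median smears a step across
its window, the peak of this contrast drifts by a few fragments; each
candidate is therefore refined with a two-segment Poisson change-point
fit on the raw counts within ±2 flanks, which restores fragment-level
localization. Scores are antisymmetric under profile reversal.

## Domainogram and domain calling

Coverage is binarized at `c_i ≥ 1`; the background rate π is estimated
separately for far-cis (beyond an exclusion radius of 244 fragments,
~1 Mb at the expected fragment spacing — near-cis decay would saturate
coverage and swamp π) and trans. Windows advance over analyzable ends
only, so mappability holes cannot masquerade as depletion; edge windows
shrink and are scored at their actual size. The p-value is the exact
binomial upper tail; the 10⁻¹⁰ floor is applied at rendering only and raw
p-values are retained. The display ladder of window sizes is
{1, 2, 3, 5, 8, 12, 21, 30, 50}.

Because coverage is Bernoulli, p-values are discrete and the null is
conservative: the empirical false-positive rate never exceeds the nominal
α, and `null_calibration` reports empirical rate, Monte-Carlo standard
error and the exact attainable tail mass per window size.

Calling uses Benjamini–Hochberg FDR (default 0.05) at a single window
size, then merges significant positions into maximal runs and converts
them to genomic intervals; the complement of the calls over the
analyzable territory defines the non-interacting regions. The default
calling window is 50: at a sparse background (π ≈ 0.1) and fold-8
enrichment the covered rate inside true regions is ≈ 0.4, and a window of
21 then has only ~80% per-position power (fragmenting calls), while a
window of 50 is near-fully powered at the cost of ~25-end boundary smear —
a good trade at megabase-scale domains. The multi-scale display itself is
uncorrected, as a raw p-value colour map.

## Correlation and activity

Profiles are compared by Spearman rank correlation of running-median-
smoothed normalized values (window 21 by default) over a chosen scope
(cis, trans, or all analyzable ends); zero-count ends stay in the ranks —
they carry information — and ties get average ranks. Matrices are
symmetric with unit diagonal; failed cells are recorded as NaN.

Activity is the exact base-pair proportion of transcribed bases (merged
expression intervals) inside interacting domains versus the
non-interacting complement, reported separately per compartment; it is
invariant to splitting intervals into adjacent pieces. The contrast
(interacting − non-interacting) carries a 95% percentile bootstrap CI
over 1000 seeded resamples whose unit is the domain — bases within a
domain are not independent — with interacting and complement interval
sets resampled independently; with fewer than five domains only the point
estimate is reported. The non-interacting territory is bounded by the
analyzable fragment-end territory of the same compartment.

## Pipeline and reproducibility

A single JSON config drives `run-all`
(simulate → digest → demux → map → profile → domainogram → correlate →
activity); validation happens before any computation, every stage records
parameters and outputs in a JSON manifest, and outputs of an interrupted
stage keep a `.partial` suffix. All randomness flows from explicit seeds,
so identical configs give byte-identical tables; the timestamped run log
is the only output that differs between reruns.

Problem sizes in the shipped tests — 10⁵ reads, 16–84 Mb toy genomes,
1000-replicate calibrations and bootstraps — were chosen so the entire
suite exercises every stage end-to-end in about a minute of CPU while
keeping every statistical check well-powered at its stated tolerance.

## Known limitations

- Exact matching cannot use reads with any error in the primer or capture
  prefix; real pipelines trade this against aligner-based mapping.
- The binomial window null assumes i.i.d. coverage within a compartment;
  residual distance trends in far-cis can inflate local significance (the
  exclusion radius mitigates, not eliminates, this).
- The boundary detector assumes piecewise-constant Poisson rates within
  its refinement window; closely spaced boundaries (< 2 flanks apart) can
  merge.
- Enriched-region edges and topological boundaries are both
  contact-frequency steps; the detector reports both, and distinguishing
  them is left to the caller (as in the worked README example).
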