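# allele4c

Allele-specific 4C-seq analysis: from a diploid genome, a viewpoint
definition and sequencing reads to per-allele genome-wide contact profiles,
multi-scale domainogram significance maps, cross-sample correlation
matrices, and transcriptional-activity quantification of contacted
chromatin.

## The problem

4C-seq (circular chromosome conformation capture with sequencing) measures
which genomic loci touch one chosen restriction fragment — the *viewpoint* —
in the nucleus. In an F1 hybrid (e.g. C57BL/6 × FVB mouse), the two
parental chromosomes differ at known SNPs, and this package implements the
two strategies that turn 4C-seq into an *allele-specific* assay:

- **PE-4Cseq** — paired-end sequencing where read 1 (primer P1) crosses the
  ligation junction into the captured partner sequence and read 2 (primer
  P2) stays inside the viewpoint fragment and covers a SNP, so every
  captured contact is attributed to one parental allele;
- **SE-4Cseq** — single-end sequencing from a viewpoint where a SNP creates
  an extra second-cutter (DpnII) site on one allele, severing the primer
  from the ligation junction on that allele, so only the other allele is
  read.

The mappable unit is the *fragment end*: the stretch of a first-cutter
(HindIII, `A^AGCTT`) fragment between its boundary and the nearest internal
second-cutter (DpnII, `^GATC`) site. Reads are mapped to an in-silico
database of these ends, exactly and with no mismatches.

## The statistics

For one (viewpoint, allele, sample), per-end capture counts `c_i` are
normalized to reads per million mapped, `x_i = 10^6 c_i / Σc`, and smoothed
with a running median over `w = 21` fragments. Topological-domain
boundaries appear as rapid drops of the smoothed signal; they are ranked by
the log2 contrast of flanking means and localized with a two-segment
Poisson change-point fit on the raw counts.

Long-range significance uses the *domainogram*: coverage is binarized
(`c_i ≥ 1`), the background rate `π` is the covered fraction of analyzable
ends per compartment (far-cis beyond an exclusion radius around the
viewpoint, and trans), and a running window of `w` analyzable ends with `k`
covered ends is scored with the binomial upper tail
`P[w,i] = P(Bin(w, π) ≥ k)`, displayed on the 1…10⁻¹⁰ scale across a ladder
of window sizes. Interacting domains are called at one window size under
Benjamini–Hochberg FDR control and merged into genomic intervals.

Profiles are compared by Spearman rank correlation after smoothing;
activity of contacted chromatin is the proportion of transcribed bases
inside interacting domains versus the non-interacting remainder, with a
domain-level bootstrap for the contrast.

A first-class synthetic-data module generates diploid genomes (shared
HindIII grid, planted SNPs and RFLPs), polymer-decay contact models with a
~3 Mb attenuated domain, enriched far-cis/trans regions, V(D)J-like
deletions, FASTQ read sets with per-read ground truth, and transcribed-
interval tracks — so every stage is testable without external data.

## Worked example

```python
from allele4c import (default_scenario, simulate_reads, ReadSimSpec,
                      demultiplex_and_map, ContactProfile, detect_boundaries)

scen = default_scenario(seed=1)                       # 10 Mb cis + 6 Mb trans diploid
sim = simulate_reads(scen.hap, scen.models["lymphoid"], scen.dbs,
                     ReadSimSpec(n_reads=100_000, seed=111), scen.viewpoint)
tables = demultiplex_and_map(sim.pairs(), scen.viewpoint, scen.dbs, sample="Bcell")
for allele, t in tables.items():
    print(f"allele {allele}: {t.totals['mapped']} mapped of {t.totals['input']} pairs")

prof = ContactProfile.from_capture(tables["A"], scen.viewpoint, scen.dbs["A"], w=21)
for b in detect_boundaries(prof, flank=10)[:2]:
    print(f"boundary near {b.chrom}:{b.coord} ({b.direction}, log2 contrast {b.score:.1f})")
```

prints

```
allele A: 46624 mapped of 49964 pairs
allele B: 46692 mapped of 50036 pairs
boundary near chr12:7873418 (drop, log2 contrast 6.4)
boundary near chr12:3501723 (rise, log2 contrast -6.4)
```

The ~100 000 simulated pairs split almost exactly 50/50 between alleles
(the viewpoint SNP in read 2 is read without error here), and ~93% map
exactly to unique, non-blind fragment ends — the remainder hit blind ends
or carry captures shorter than the 12 bp minimum. The two strongest
contrasts on the smoothed allele-A profile are the 5′ boundary of the
simulated 3.5–6.5 Mb topological domain (signal *rises* moving toward the
viewpoint at 5 Mb) and the sharp edge of an enriched far-cis contact region
at 7.4–7.9 Mb.

A thin CLI mirrors the library
(`allele4c run-all config.json`, plus `simulate / digest / demux / map /
profile / domainogram / correlate / activity` subcommands); `run-all`
writes every table, bedGraph and BED track together with a JSON manifest,
and re-running an identical config reproduces identical tables.

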