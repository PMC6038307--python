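# fivec

Anchored 5C (chromosome conformation capture carbon copy) analysis of a gene
locus: from restriction maps, primer design and raw amplicon reads to
normalized, binned promoter interaction profiles, strong-contact calls,
regulatory-track annotation and reporter-assay statistics.

## The problem

Enhancers regulate genes across tens to hundreds of kilobases by looping
into physical contact with their promoters. 5C measures those contacts for
one locus at restriction-fragment resolution: a 3C proximity-ligation
library is converted into countable junctions by annealing and ligating
forward and reverse primers across ligated fragment ends, so that each
sequenced read is one (forward primer, reverse primer) contact. In an
*anchored* design, a couple of reverse "bait" primers mark the promoter and
forward primers tile the surrounding locus, yielding the promoter's
interaction profile across the region. The package is written for people
analysing such experiments — or building and testing methods for them — and
ships a fully specified synthetic locus with planted structure so every
stage can be validated against ground truth.

## The model

Contact frequency between fragments i and j is modelled (and simulated) as

    w_ij = (|mid_i − mid_j| + d0)^(−α) · β^(#TAD boundaries crossed) · λ_ij

a power-law distance decay (exponent α, short-range offset d0), attenuated
by β per topological-domain boundary between the fragments, and enriched by
λ ≥ 1 for specific loops. Libraries are normalized in two stages: by
sequencing depth (read fractions), then by a compaction factor estimated as
the median per-contact ratio of control-region signal against a reference
library. Strong promoter contacts are called as windows whose signal
exceeds a fitted monotone decay (log v = a − α·log(d + c), plus a local
median background), scored in robust Poisson standard-deviation units. See
`docs/methods.md` for the full account.

## Worked example

Simulate the default synthetic study (a 280 kb locus, 26 EcoRI fragments,
2 promoter baits × 24 forward primers, one TAD boundary, three planted
loops at λ = 8), count the reads back, and call strong contacts:

```python
from fivec import synthetic_locus as sl, normalization as nz
from fivec.junction_quant import count_junctions
from fivec.workflow import profile_and_call

study = sl.build_study(seed=1)
lib = sl.LibrarySpec("sample1", total_reads=100_000, seed=42)
records, truth = sl.simulate_library(study.design, study.fragments, study.model, lib)
ifl = count_junctions((seq for _, seq, _ in records), study.design, library_id="sample1")
print(f"assigned {ifl.total_run_reads - ifl.unassigned_reads}/{ifl.total_run_reads} reads "
      f"over {len(ifl.counts)} promoter contacts")

result = profile_and_call(study, nz.depth_normalize(ifl), lib.total_reads)
print(f"{len(result.regions)} strong contact regions (z >= 3):")
for k, r in enumerate(result.regions, 1):
    print(f"  {k}. {r.interval.chrom}:{r.interval.start}-{r.interval.end}  "
          f"z={r.score:5.1f}  TSS{r.tss_distance/1000.0:+.1f} kb")
```

which prints:

```
assigned 100000/100000 reads over 48 promoter contacts
4 strong contact regions (z >= 3):
  1. chrSim:48934-108740  z= 38.9  TSS-63.6 kb
  2. chrSim:5438-65244  z= 36.6  TSS-101.6 kb
  3. chrSim:212044-271850  z= 16.4  TSS+121.3 kb
  4. chrSim:168548-217480  z=  5.7  TSS+56.0 kb
```

Every error-free read was assigned to a contact, and the three top-ranked
regions contain the three planted loop fragments (at 37.5, 80.5 and
241.9 kb in this locus — the third sits across the TAD boundary, where the
insulation dip makes it hardest to see against a global decay). The fourth,
weaker region flanks a loop window. The signed TSS distances are how such
regions are reported against the promoter (negative = upstream).

The same stages are available from the shell:

```sh
fivec simulate --seed 7 --reads 100000 --outdir sim/
fivec count sim/sim.fastq --primers sim/primers.tsv --out sim/ifl.tsv
fivec reporter assay.csv --basal P_promoter --out activity.tsv
```

plus `digest`, `design`, `normalize`, `profile` and `annotate`.

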