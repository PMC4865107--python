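# topomap

Genome-wide mapping of bacterial **Topoisomerase IV** binding and cleavage
from stranded sequencing-coverage tracks.

Topo IV (ParC₂ParE₂) is the main decatenase of *E. coli*: it removes the
catenation links that form between sister chromatids behind replication
forks and resolves the last links between fully replicated chromosomes,
most prominently at the dimer-resolution site *dif*. Two genomic assays
probe it: conventional ChIP-seq reports where the enzyme **binds**
(symmetric ~200 bp IP/input peaks), and quinolone-trapped IP ("NorflIP")
reports where it **cleaves** — the drug freezes the enzyme covalently on
the 5′ ends it creates, which leaves a diagnostic strand-asymmetric
fingerprint in the read coverage: a ~170 bp forward-read block, a ~130 bp
non-enriched gap, a ~170 bp reverse-read block, and a ~100 bp central
window where raw reads vanish because the blocked 5′ ends cannot be ligated
into the library.

`topomap` implements the full analysis as a reusable, tested pipeline:

* **profiles** — coverage processing: reads-per-million scaling, 200 bp
  circular smoothing, strand combination, IP/input ratio with median
  centering, mock-IP artifact masking, GC- and copy-number normalization,
  sliding means, track correlations.
* **norflip** — the cleavage-site caller. The strand-differential signal
  `smooth(fwd) − smooth(rev)` is scanned with a biphasic template in 100 bp
  steps; windows with Pearson *r* ≥ 0.72 and an IP/input fold ≥ 2 become
  sites; the cleavage point is the center of the raw-read gap, ~150 bp
  downstream of the forward-peak center for canonical geometry.
* **chip** — binding-site calling by correlating every enriched region with
  a trusted reference peak shape (*r* ≥ 0.7, fold ≥ 2), plus origin/terminus
  bias quantification.
* **replication** — marker-frequency analysis with segmented-linear fork
  localization, circular fork-distance arithmetic, and the "comet" null
  model: if Topo IV merely trailed replication forks (a comet of length
  `c`, optional persistence `τ_p`, fork speed `v = L/C`, steady exponential
  growth), the expected occupancy would obey
  `O(s) = 2(1 − 2^(−τ/T)) · D(s)` with dosage
  `D(s) = 2^((C + D − s/v)/T)` — i.e. O/D is flat, so an occupancy gap over
  the terminus falsifies the model.
* **context** — site statistics against annotation: consecutive-site
  spacing, 50 kb density, gene/intergenic localization, distance to highly
  expressed transcription units (ANOVA vs a seeded random control),
  gene-level Fisher overlap tests, GC-dinucleotide profiles, GATC-motif
  spacing.
* **synthetic** — a first-class generator that plants cleavage/binding
  sites with the canonical geometry, rRNA/tRNA/IS-like artifacts shared
  with the mock IP, GC bias, replication dosage gradients and Poisson
  backgrounds, with exact noise-free mode and byte-reproducible seeding.

Callers are exposed statsmodels-style: a model object built from the data
whose `fit()` returns a results object with the site table, the tracks it
used, and a `summary()`.

## Worked example

Plant three cleavage sites (a *dif*-like 30× site and two weaker ones) plus
an rRNA-like artifact on a 1 Mb genome at 5 reads/bp, then call sites:

```python
import numpy as np
from topomap import (GenomeSpec, PlantedSite, ArtifactRegion,
                     plant_norflip_experiment, add_artifacts, NorflipPeakModel)

genome = GenomeSpec(length=1_000_000, oriC=846_000, dif=342_000)
sites = [PlantedSite(150_000, fold=30.0),
         PlantedSite(480_000, fold=8.0),
         PlantedSite(760_000, fold=5.0)]
exp = plant_norflip_experiment(genome, sites, depth=5.0, bg_rate=5.0, seed=1)
exp = add_artifacts(exp, [ArtifactRegion(600_000, 604_000, 20.0, "rRNA-like")])

result = NorflipPeakModel.from_experiment(exp).fit()
print(result.summary())
print(result.sites.to_string(index=False))
```

```
NorflIP cleavage-site calls
===========================
sites called        : 3
r threshold         : 0.72
fold threshold      : 2.0
template window (bp): 600
masked genome (bp)  : 4273
strongest sites (center, fold, r):
     150,000    13.8x  r=1.000
     479,999     4.0x  r=1.000
     760,001     2.7x  r=1.000

 center  fwd_peak_center        r      fold  fwd_span  gap  depletion  flagged
 150000           149849 0.999992 13.788161       169  132        100    False
 479999           479848 0.999969  4.042661       166  137        100    False
 760001           759850 0.999873  2.698480       166  136        100    False
```

All three planted sites are recovered at (or within 1 bp of) their true
cleavage points; the artifact region is masked out via the mock IP rather
than called. Each site's measured geometry reproduces the canonical shape —
forward span ~170 bp, gap ~130 bp, raw-read depletion 100 bp — and the
cleavage point sits ~150 bp downstream of the forward-peak center. The
`fold` column is the enrichment of the 200 bp-smoothed combined IP/input
ratio, which for this strand-split geometry reads lower than the planted
per-strand fold (a planted 30× site measures ~14×).

A command-line interface mirrors the pipeline stages:

```bash
topomap simulate --config sim.yaml --outdir sim/
topomap norflip-call --genome sim/genome.fasta --ip-fwd sim/ip.fwd.bedgraph ... --out sites.tsv
topomap replication --genome genome.fasta --sample-fwd ... --bin 10000 --out mf.tsv
topomap comet-sim --params comet.yaml --out occupancy.tsv
```

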