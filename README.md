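# promsig

Most active human promoters keep an "open" chromatin region between
−150 bp and +50 bp of the transcription start site (TSS), and a small set
of *cardinal* cis-regulatory elements — TATA, Sp1/GC-rich, NFY/CCAAT,
ETS/GABP, NRF1, CREB/E-box, YY1, Clus1, GFY — dominates these windows.
`promsig` is a tested, reusable pipeline for the statistics behind this
picture: it scans promoter windows for cardinal motifs, tests their
pairwise co-occurrence (and multi-copy self-co-occurrence), positions ChIP
peaks relative to TSSs, builds experiment × motif *cofactor signature*
matrices, classifies promoters as focused or dispersed from 5′ read
profiles, and assigns the eight-class taxonomy of responses to two
knockdowns with fold-over-background binding enrichment. A synthetic-data
module generates every input with planted ground truth, so the whole
pipeline is testable without any downloads.

It is aimed at regulatory genomicists who want the statistical core of a
promoter-signature analysis — enrichment, co-occurrence, signature, and
response-class calls — on their own TSS catalogs, peak sets and expression
tables, or on simulated data with known truth.

## The statistics at the core

All significance tests share one currency: the hypergeometric tail. For a
foreground promoter set of size $n$ with $x$ motif-positive members inside
a universe of size $N$ with $K$ positives, enrichment is
$P(X \ge x)$ and depletion $P(X \le x)$ for
$X \sim \mathrm{Hypergeom}(N, K, n)$; the directional $-\log_{10} p$ is
signed by whether $x$ exceeds $nK/N$. On that base:

- **Co-occurrence** (motifs $A, B$ over $N$ windows with $a$, $b$ positives
  and $x$ shared): signed $\log_2 p$, positive for co-occurrence, negative
  for avoidance, white/masked when neither tail clears $\alpha = 0.05$.
  The diagonal tests multi-copy clustering against a truncated-Poisson
  null.
- **Signatures**: each experiment's promoter set (peaks within 500 bp of a
  TSS) gets a vector of signed $-\log_{10} p$ motif enrichments; rows are
  z-scored and mean-centered so each row expresses *preferences*, then
  clustered (average linkage, deterministic tie-breaks).
- **TSS shape**: focused iff ≥ 90 % of 5′ reads fall within ±5 bp of the
  read-maximal position, relative to the 100-bp context centered on it.
- **Response classes**: the cross of {down, up, none} calls under two
  knockdowns gives Classes I–VIII plus Unaffected; per class and factor,
  occupancy is expressed as fold over the rate in unaffected genes.
- **Motif enrichment backgrounds** are sampled from the genome matched for
  GC% in 2.5 % bins.

## Worked example

Simulate 1,000 promoters in which Sp1 and NFY co-occur (odds ratio 4)
while everything else is independent, scan with the shipped cardinal
library, and test co-occurrence:

```python
from promsig.synthetic_data import SimulationConfig, generate_promoters
from promsig.motif_engine import build_occurrence_matrix, default_motif_library
from promsig.cooccurrence import pairwise_cooccurrence

config = SimulationConfig(n_promoters=1000,
                          odds_ratios={("Sp1", "NFY"): 4.0})
genome, catalog, windows, seqs, truth = generate_promoters(config, seed=42)
occ = build_occurrence_matrix(seqs, default_motif_library())
print((occ >= 1).mean().round(3).to_string())
result = pairwise_cooccurrence(occ)
print("Sp1-NFY score:", round(result.scores.loc["Sp1", "NFY"], 2),
      "masked:", bool(result.mask.loc["Sp1", "NFY"]))
print("NRF1-NFY score:", round(result.scores.loc["NRF1", "NFY"], 2),
      "masked:", bool(result.mask.loc["NRF1", "NFY"]))
```

prints

```
TATA     0.153
Sp1      0.240
NFY      0.208
ETS      0.139
NRF1     0.111
CREB     0.108
YY1      0.076
Clus1    0.047
GFY      0.050
Sp1-NFY score: 16.04 masked: False
NRF1-NFY score: 0.0 masked: True
```

The per-motif fractions track the configured marginals (plus a small
excess from chance matches in background sequence). The planted Sp1–NFY
dependence stands out as a strongly positive signed $\log_2 p$ of ~16,
while the independent NRF1–NFY pair is correctly masked as
non-significant — the qualitative pattern expected of proximal promoters,
where only Sp1 and NFY/CCAAT show a real tendency to co-occur.

The same stages are available from a shell via the `promsig` CLI
(`simulate`, `scan`, `cooccur`, `peaks`, `signature`, `shape`, `classes`,
`report`), each writing its outputs plus a run manifest into a run
directory.

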