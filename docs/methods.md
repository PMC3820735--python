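# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `promsig`, in the order the pipeline runs.

## Coordinates and promoter windows

All internal coordinates are 0-based half-open. The field's "+1 = TSS"
display convention (no position 0; −1 abuts +1) is applied only at I/O and
reporting. A promoter window with `upstream=150, downstream=50` covers
TSS-relative offsets −150…+49 where offset 0 is the TSS base — i.e.
display positions −150…−1 and +1…+50, 200 bp total. For a minus-strand
TSS at genomic position *t* the window is [t−49, t+150] and its sequence is
returned reverse-complemented, so index 0 is always the most upstream base.
Windows overlapping a contig edge are **retained but flagged** `clipped`
and excluded from GC-matched background sampling by default; dropping them
instead is a one-line filter for users who prefer a strictly fixed-length
universe.

## Motif model

Motifs are IUPAC consensus strings matched exactly (`max_mismatches = 0`
by default); a sequence `N` matches only a consensus `N`. Scanning covers
both strands, reporting reverse-strand matches at the forward offset of
the leftmost matched base, and reports each offset once. Exact consensus
matching was chosen over PWMs because the nine cardinal elements are
short, high-information motifs, and a consensus library in a plain TSV is
reproducible and user-overridable; a mismatch budget per motif provides
the coarse sensitivity dial.

The shipped library (`v1`) is:

| motif | consensus | basis |
|---|---|---|
| TATA | TATAWAWR | canonical TATA-box |
| Sp1 | GGGGCGGGG | GC-box |
| NFY | RRCCAAT | CCAAT-box; matches all three ATTGG-context copies of the canonical 3× reporter insert on the reverse strand |
| ETS | RCCGGAAGY | GABP/ETS core |
| NRF1 | RCGCRTGCGY | palindromic NRF1 site; matches the FMR1-derived 3× wild-type insert, rejects its binding-disrupting mutant |
| CREB | TGACGTCA | CRE palindrome |
| YY1 | GCCATNTT | YY1 core |
| Clus1 | TCTCGCGAGA | CGCG element associated with ZBTB33/Kaiso |
| GFY | ACTACAATTCCC | GFY/Ronin site |

Only the NRF1 and NFY entries are pinned by sequences with known match
behavior; the other seven are literature approximations and should be
re-versioned if changed. Whether promoter "presence" should count one or
both strands is not settled usage; both strands is the default because
most of these elements are functionally orientation-independent, and
`both_strands=False` is available.

## Enrichment and backgrounds

All enrichment is a directional hypergeometric test on presence/absence
(not copy number): the urn is foreground ∪ background, the draw is the
foreground. p-values are floored at 1e-300 before logs so matrices stay
finite. Background windows for motif enrichment are sampled from the
genome, rejecting positions that overlap any foreground window, and
matched to the foreground GC histogram in bins of width 2.5 % at a
background:foreground ratio of 2 — conventional values, both
configurable. A bin that cannot be filled borrows from its immediate
neighbors after a warning; if still short, sampling fails loudly rather
than silently distorting the GC match.

## Co-occurrence

Pairwise scores over N promoters with a, b positives and x shared are
signed log2 p-values: −log2 of the upper tail when x ≥ ab/N, +log2 of the
lower tail otherwise (so avoidance is negative), masked to 0 ("white")
when neither tail clears α = 0.05. α is deliberately uncorrected by
default to mirror the usual display convention; a Benjamini–Hochberg mode
across the off-diagonal cells is available for stricter control. Presence
drives the pairwise statistic; copy number drives only the diagonal.

The diagonal (self) statistic is this package's construction: under the
null that occurrences land independently across windows with pooled rate
λ = total/N, the chance that an occupied window holds ≥ 2 copies is
q = P(Pois(λ) ≥ 2)/P(Pois(λ) ≥ 1), and the observed number of multi-copy
windows among the m occupied ones is referred to Binomial(m, q) tails.
Output metadata flags this so the diagonal is not mistaken for an
externally standard test.

## Peak analysis

A peak's location is its summit when provided, else the interval midpoint
(floor). Peaks are assigned to the nearest TSS on their contig; exact ties
go to the lower genomic coordinate (determinism). Positional histograms
bin gene-oriented TSS offsets: the −150/+50 window itself, 200-bp bins to
±2 kb, 1-kb bins to ±10 kb, and aggregate distal bins. Genomic annotation
uses priority promoter > TTS > exon > intron > intergenic with flanks
[TSS−1000, TSS+100] and [TTS−100, TTS+1000] — common annotation-tool
defaults, all four configurable. Window-level Venn overlap counts a
promoter window positive for a set iff ≥ 1 peak center falls inside it;
an RNA PolII mode instead counts a peak within ±1 kb of the TSS.
Meta-profiles average per-base signal in 25-bp bins around anchors,
flipping minus-strand anchors, and exclude (rather than zero-fill) bins
that run off a contig.

## Signature matrices

"Normalized and centered" is interpreted as division by the row standard
deviation followed by subtraction of the row mean (z-score), recorded in
output metadata; unit-norm and max-norm alternatives are provided because
the convention is not universal. Constant rows map to zero. Clustering
runs on the transformed rows (the preference scale), uses Euclidean
average linkage, breaks ties by input order, and orders leaves by visiting
the smaller subtree first; the merge tree is exported as Newick.
Directional (signed) p-values are used throughout rather than
enrichment-only, so depletion is visible as negative preference.

## TSS shape

The primary TSS is the read-maximal position, ties going 5′ (favoring the
annotated-start side). The focus ratio divides reads in the 11 positions
[t−5, t+5] by reads in the 100 positions [t−50, t+49]; ≥ 0.90 is focused
(boundary inclusive). Profiles with fewer than 10 context reads are
labeled `unclassified` because the ratio is unstable at low depth; the
filter is explicit and reported rather than silent. Both window extents,
the threshold and the depth filter are configurable.

## Response classes

Differential calls use Welch's two-sample t-test plus a fold-change filter
(defaults α = 0.05, |log2FC| ≥ 0.585, i.e. 1.5-fold) on log2 expression —
pragmatic defaults for replicate-level synthetic tables; pre-called DE
tables can be supplied instead when the upstream platform has its own
criteria. The I–VIII taxonomy is the full 3×3 cross of {down, up, none}
under two treatments, so it is total and exhaustive by construction.
Fold-over-background divides a class's factor-occupancy rate by the rate
among Unaffected genes; a zero background rate flags the ratio infinite
rather than erroring. The "same direction" share of dual responders is
(|I|+|II|)/(|I|+|II|+|III|+|IV|), rounded to integer percent. Overlap
percentages between two affected-gene sets are universe-free; the
significance p requires a user-supplied universe size.

## Synthetic data

The generators define the study conditions and are pure functions of
(config, seed):

- **Presence model.** Marginal presence probabilities per motif with
  pairwise dependence specified as odds ratios, realized by a Gaussian
  copula: each pair's target joint probability is solved from the 2×2
  odds-ratio equation, the matching bivariate-normal correlation found by
  root-finding, and the full correlation matrix checked for positive
  semi-definiteness (an infeasible request fails loudly). Default
  marginals (Sp1 0.25, NFY/ETS 0.15, TATA/NRF1/CREB 0.10, YY1/Clus1/GFY
  0.05) are round numbers in the range reported for cardinal-element
  frequencies in proximal promoters; all odds ratios default to 1
  (independence), matching the headline observation that cardinal motifs
  avoid fixed combinations.
- **Sequences.** Windows are i.i.d. background at the configured GC
  (default 0.5) written into a spaced synthetic genome (TSSs every 2 kb,
  alternating strand); planted instances resolve IUPAC codes uniformly,
  are placed uniformly over valid offsets, never straddle window edges,
  and do not overlap one another. Copy number given presence defaults to
  {1: 0.8, 2: 0.15, 3: 0.05}.
- **Peaks.** Each promoter binds a factor with its conditional rate given
  motif status (else the base rate); peak centers are TSS + Normal(0, σ)
  with σ = 50–60 bp by default, the scale of real ChIP peak-summit
  scatter at promoters.
- **5′ profiles.** A 35 % focused / 65 % dispersed mixture (the observed
  promoter-shape split), focused reads from a discretized Normal(0, 1),
  dispersed reads uniform over 80 positions, 50 reads per promoter.
- **Expression.** Planted Classes I–VIII (100 genes each by default, 800
  unaffected) shift the two treatment arms by ±1.5 log2 units against
  noise σ = 0.2 with 3 replicates — a strong-effect, low-noise regime in
  which the default caller should recover ≥ 90 % of planted labels.

What the generator does **not** emulate: dinucleotide structure, CpG
islands and real GC heterogeneity, motif positional preference within the
window, peak width/intensity distributions, read-level noise, and
correlated expression replicates. Passing tests therefore demonstrate the
statistics are implemented and calibrated correctly under the declared
model, not that real data meets that model's assumptions.

## Problem sizes in the test and acceptance runs

The statistical suites run on the generator's presence-matrix fast path
(the same joint law as sequence planting, without sequence emission):
type-I calibration on 100 catalogs of 2,000 promoters, odds-ratio sign
recovery at n = 5,000 over 100 seeds, signature-row maximality at
n = 1,000 over 100 seeds, TSS-shape accuracy on 2,000 profiles, class
recovery on 1,600 genes. Sequence-level integration (plant → scan →
recover) runs at 60–1,000 promoters. The acceptance script uses 50 seeds
per calibration; these sizes put Monte-Carlo error comfortably inside the
asserted tolerances while keeping the full suite under a minute.

## Known limitations

- The seven unpinned consensus strings are approximations; absolute
  per-motif promoter fractions on real genomes will differ from any
  specific published scan.
- The pairwise co-occurrence null conditions on marginal counts but, like
  any presence/absence test, ignores within-window position and copy
  number.
- The self-co-occurrence null assumes a single pooled occurrence rate
  across windows; strong rate heterogeneity inflates its positive scores.
- GC matching is univariate; backgrounds are not matched for CpG or
  repeat content.
- `call_reporter_selectivity` assumes reporter measurements are already
  normalized within reporter (e.g. firefly/renilla), as is standard for
  dual-luciferase screens.
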