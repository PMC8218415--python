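# Methods

## Problem setting

Targeted amplicon bisulfite sequencing reads a PCR-amplified region at very
high depth, so every read reports the methylation state of every CpG it
covers on a single DNA molecule. `ampliconmeth` analyses such data at two
levels:

1. **Per-CpG level** — the fraction of molecules modified at each CpG, with
   a binomial confidence interval; supported for two conversion chemistries:
   - **BS-seq** (sodium bisulfite): unmodified C, 5fC and 5caC read as T;
     5mC and 5hmC read as C. The reported proportion is
     p = nC/(nC+nT), the percentage of (5mC+5hmC)/total C.
   - **PB-seq** (pyridine borane, TAPS-style chemistry): 5fC/5caC are
     converted to dihydrouracil and read as T; C/5mC/5hmC read as C. The
     reported proportion is p = nT/(0.5·nC+nT), the percentage of
     (5fC+5caC)/total C (see the 0.5 compensation below).
2. **Read (epiallele) level** — whether demethylation at nearby CpGs
   co-occurs on the same molecule, quantified per CpG pair by the odds ratio
   of the 2×2 table of reads that are both methylated (MM), both
   unmethylated (UU), or discordant (MU/UM):

   OR = MM·UU / (UM·MU).

   OR = 0, 1, and +∞ correspond to exclusive, independent, and perfectly
   concordant demethylation of the pair. The statistic is the within-read
   analogue of linkage disequilibrium and extends directly to long-read
   methylation calls.

## Calling model

A read contributes a call at a CpG only when its conversion strand matches
the amplicon's analysed strand (one cytosine per CpG dinucleotide is
quantified; the default analysed strand is "+"). The converted strand is
taken from mapper tags (BSMAP `ZS`, Bismark-style `XG`) when present,
otherwise from SAM orientation flags, with a config override. At each site
the observed base maps C→C, T→T; anything else — another base, a deletion,
a base below `min_base_quality` (default 30), an uncovered site — is N
(uninformative). Mate pairs are merged one fragment per row; overlapping
calls that agree are counted once and disagreements become N
(`consensus_or_N`), so a fragment is never counted twice. All-N rows are
dropped and counted in the run manifest. Amplicon libraries are by nature
PCR duplicates of few template molecules, so no deduplication is ever
attempted; depth should be interpreted accordingly.

## Confidence intervals

The binomial CI is the exact Clopper–Pearson interval, computed through
beta quantiles: lower = B(α/2; k, n−k+1), upper = B(1−α/2; k+1, n−k). The
beta form is well defined for real-valued k and n, which matters for
PB-seq, where the effective denominator 0.5·nC+nT is generally not an
integer; the continuous generalization is used rather than rounding.
Wilson score intervals are available via `method="wilson"`. Sites with zero
informative depth are reported as missing (NA), never as 0% — a 0% is a
biological claim the data cannot support at zero depth.

## The PB-seq 0.5 compensation

A protected cytosine (C/5mC/5hmC) retains a normal C:G pair, so amplicons
from both strands carry its evidence; a converted 5fC/5caC becomes
dihydrouracil and only the converted strand reads T at that position. The
compensation halves the C count before forming the proportion. The package
formalizes the generative assumption under which this is exact as
`PBStrandModel`: each molecule contributes 2 countable C units when
protected and 1 countable T unit when converted, giving the identity
nT/(0.5·nC+nT) = f for a true 5fC/5caC molecule fraction f. This rule is
an assumption of the published correction, not a derivation from chemistry;
the simulator encodes it at the count level (`simulate_pb_counts`), and
aligned-read simulation emits analysed-strand reads only — a uniform
per-read strand draw would be unobservable downstream because
opposite-strand reads are excluded at call time anyway.

## Conversion-efficiency QC

BS efficiency is estimated from non-CpG cytosines inside the amplicons
(essentially unmethylated in mammalian somatic DNA, so every C call there
is a conversion failure); PB efficiency from an unmethylated spike-in.
Efficiency = converted/(converted+unconverted) over all QC positions ×
reads.

## Synthetic data generator

The generator draws truth-labelled molecules under four regimes, each a
different dependency structure at (optionally) fixed per-site marginals:

- **independent** — site s demethylated with probability u_s, independently.
- **exclusive** — at most one site per molecule demethylated (site s with
  probability u_s, no site with 1−Σu; requires Σu ≤ 1). UU is impossible.
- **concordant** — a latent per-molecule epiallele state D ~ Bernoulli(π):
  demethylated epialleles (D=1) lose site s with probability u_s,
  methylated ones only with the leak rate leak_s.
- **mixture** — with weight ρ the concordant channel, otherwise an
  independent channel with the same marginals π·u_s+(1−π)·leak_s, so ρ
  tunes concordance strength without moving per-site methylation levels.

The latent-state construction is the simplest generative realization of
"concordant" with tunable strength; no canonical equations exist for it in
the amplicon literature. Noise applies only to the observed matrix —
conversion failure (U read as C, default 0.005), inappropriate conversion
(M read as T, default 0), sequencing error (call lost to N, default
0.001); the defaults are placeholders of the magnitude seen in
well-converted libraries, and controlled runs set them explicitly. The
truth matrix stays noise-free so statistic correctness and noise effects
can be tested separately.

A separate distance-decay generator (`simulate_distance_decay_matrix`)
draws site states as a stationary binary Markov chain along the amplicon
with neighbour correlation exp(−d/L), so any two sites at distance D have
correlation exp(−D/L) and the expected OR declines smoothly with distance —
the pattern expected when a locally recruited demethylation machinery acts
on nearby CpGs together.

`simulate_alignments` writes real SAM records (full-length amplicon reads,
Q40 bases, `XG` strand tags) whose sequences encode the observed calls at
CpG sites (N as a non-informative A) and the conversion state of every
non-CpG cytosine, so the entire calling stack can be exercised and, at zero
noise, must reproduce the truth matrix byte-for-byte. Output is
byte-identical for a fixed model and seed.

### What the generator does not emulate

Primer bias, PCR stochasticity and chimeras, quality-score heterogeneity,
indels, mapping ambiguity, within-sample mixtures of cell populations, and
replication-dependent dilution dynamics. Passing tests therefore
demonstrate correctness of the statistics and the pipeline plumbing under
the stated generative models, not robustness to every artefact of real
amplicon libraries.

## Expectation oracle

`expected_contingency` computes exact MM/MU/UM/UU probabilities for any
pair by enumerating the latent state and multiplying per-site Bernoulli
terms; `expected_or` forms the odds ratio from those cells (0 and +∞
permitted). The oracle shares no code with the samplers and is used to
check them: simulated log-ORs must land within 3 standard errors
(Woolf: √(1/MM+1/MU+1/UM+1/UU)) of the exact value, the expected OR is
exactly 1 under independence, 0 under exclusivity, and strictly increasing
in ρ at fixed marginals.

## Numerical and policy choices

- Odds ratios use no correction by default, preserving the raw 0/1/+∞
  semantics; Haldane–Anscombe (+0.5 per cell) is available for log-scale
  work. 0/0 forms are missing with a reason, not coerced.
- Pairs with fewer than `min_informative` reads (default 10) are reported
  missing: tiny tables produce noise ORs.
- Pairs are computed within amplicons (reads rarely span amplicons).
- +∞ serializes as the literal `inf` in TSVs; infinite pairs are excluded
  from the numeric OR-vs-distance export and counted separately.
- All internal coordinates are 0-based half-open; BED is ingested natively,
  SAM positions converted by pysam on read.
- Locus-wide CpG numbering is 1-based in genomic coordinate order.

## Problem sizes

Default verification runs use: 100,000 reads for limiting-value OR checks;
10 replicate simulations of 10,000 reads for block-structure ranking;
5,000 reads × 10 CpGs for distance decay; 50,000 molecules per point for
PB fraction recovery; 200 replicates at depth 500 for CI coverage; 20
seeds × 100 reads for SAM round-trip fidelity and 5,000 reads for QC-rate
recovery. These sizes give sampling errors comfortably inside the asserted
tolerances while keeping the whole suite fast.

## Known limitations

- 5mC cannot be separated from 5hmC (BS) nor 5fC from 5caC (PB) — that
  requires paired oxidative/protection chemistries out of scope here.
- The minus-strand calling path supports single-amplicon analysis but the
  aligned-read simulator emits plus-strand amplicons only.
- The PB strand-redundancy rule is exact by assumption; real libraries may
  deviate (e.g., strand-biased PCR), which would bias the 0.5 compensation.
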