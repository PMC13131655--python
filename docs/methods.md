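# Methods

This note documents the models and procedures notokit implements, the
parameter defaults and why they hold, what the synthetic-data generators
do and do not emulate, and the numerical choices made where the design was
genuinely open.

## Coordinate conventions

All coordinates are 0-based, half-open `[start, end)` internally; GFF3
(1-based, inclusive) is converted at I/O. Two reading rules are applied
consistently: *"closer than N bp"* merges on a strict inequality
(`gap < N`), and *"at least 75%"* thresholds are inclusive (`>= 0.75`).
Score-based overlap resolution keeps, at every base, the hit with the
higher alignment score; ties break by earlier start, then input order —
the upstream annotation tools delegate this to external scripts without
documenting a tie rule, so notokit fixes a deterministic one. Interval
shuffling is uniform over all permitted start positions genome-wide,
excluding assembly gaps by default (a `preserve_chromosome` flag restricts
placement to the source chromosome; whether real shuffled controls should
exclude gaps is not a settled convention, so both behaviours are exposed
and the gap-excluding one is the default, matching how SV callers never
emit calls inside gaps).

## Haplotype comparison

**Hemizygous fraction** is the union (not the sum) of heterozygous
insertion and deletion footprints divided by genome size; an insertion's
footprint is its anchor position projected over the inserted length. This
projection is also the coordinate convention for intersecting insertions
with the carrier haplotype's repeat annotation: deletions (sequence
present on Hap1 only) are intersected with the Hap1 repeats, insertions
with the Hap2 repeats.

**Heterozygous-TE calling** reports an (SV, repeat copy) pair when both
reciprocal fractions reach the threshold (default 0.75, inclusive); an SV
matching several copies keeps the one with the most overlapping bases.

**Callset concordance**: assembly and read-based SVs strictly larger than
50 bp are matched one-to-one (greedy by breakpoint distance) when they
share type and chromosome, lie within 1,000 bp, and have a length ratio
≥ 0.7. The distance and ratio defaults mirror common SV-merging practice
(the upstream merger is typically run with defaults) and are
configurable. A matched read call genotyped hom-alt flags the assembly SV
as a putative mis-assembly; unmatched assembly SVs are "unsupported".

**Feature association** contrasts observed SVs (response 1) with an equal
number of length-preserved shuffled control intervals (response 0).
Predictors: distance to the nearest chromosome end, distance to the
closest assembly gap, SV length, and the fraction of bases annotated as
TE / tandem repeat / LINE / gene within 50-kb windows around the
breakpoint midpoint (windows clipped at chromosome ends with the clipped
length as denominator). All predictors are standardized before fitting;
notokit standardizes to the *control-sample* mean and SD so that
coefficients read as log-odds per SD of the genomic background and the
scale does not depend on the observed SV set. SV length is included even
though controls inherit case lengths (making it uninformative on its
own); it is retained for completeness and its coefficient should be read
with that caveat. The model is a binomial GLMM with a chromosome-level
random intercept, fitted by a Laplace (MAP) approximation to the
posterior with weak priors; the Laplace covariance supplies standard
errors that remain calibrated under the strong collinearity between the
positional predictors (a mean-field variational fit underestimates them).
If that fit fails, the implementation falls back to fixed chromosome
effects and flags the method in the output. Odds ratios and 95% CIs are
`exp(coef)` and `exp(coef ± 1.96·SE)`.

**Divergence shift test**: one-sided Wilcoxon rank-sum with the
alternative "heterozygous-TE divergences stochastically smaller". The
implementation uses the exact permutation distribution (valid under ties
via midranks) for `min(n, m) ≤ 8` and the normal approximation with tie
and continuity corrections otherwise; when every value is tied the test
is declared uninformative (p = 0.5, with a warning) rather than raising.

## Repeat landscapes

Per-copy divergence *K* (%) converts to age as `(K/100) / divisor`. The
divisor is `2r` by default with `r = 3.2e-3` substitutions/site/MY: the
family consensus approximates the ancestral sequence, and divergence
accrues on the copy lineage alone under one convention (`r`) or is read
as a pairwise distance (`2r`) under the other; both exist in practice, so
the mode is an explicit, recorded configuration rather than a guess.
Each copy contributes its full interval length to the single bin
containing its age, so total bp is conserved exactly; copies older than
the last bin accumulate in an overflow bin rather than being dropped.
Coverage summaries resolve overlapping hits by score first, so duplicated
annotations never double count and class coverages sum to ≤ 100%.

## Branch dynamics

Net gain per branch is inserted bp minus deleted bp (exact integer sums);
the rate divides by the branch duration in MY (Mb = 1e6 bp). Lifted
insertion fragments merge when they are < 100 bp apart *and* share both
branch and ancestral event id; deletions are not lifted or merged — their
bp comes from the mutation table directly. TE attribution applies the
75% reciprocal rule to the *merged* interval (the merged record is the
reconstructed ancestral insertion, so it — not the fragments — is what a
genuine TE insertion should match); class composition is computed over
attributed insertions only. The rate curve is the raw per-branch step
function along the root-to-leaf path; smoothing is off by default, with
an optional moving average whose window is recorded in the output.

Internal branches are identified by the sorted, `+`-joined leaf names of
their subtending clade; leaf ages anchor at 0 MYA and a parent's age is
the maximum over children of child age + branch length, so the machinery
does not require ultrametric trees.

## Conserved elements

Raw elements merge at a strict < 5 bp gap. Ancestry uses per-species
alignment presence (a base is covered when its depth value is positive —
"covered by a species" is treated as presence/absence, the weakest
reading, since no stricter depth rule is documented): *ancestral* iff
every species covers ≥ 75% of the element (inclusive), *clade-specific*
iff every focal-clade member does and at least one non-clade species does
not, otherwise *other*. Feature assignment is decided at the element
midpoint with priority exon > promoter > TTS > intron > intergenic;
promoter and TTS windows are strand-aware with defaults of 2,000 bp
upstream + 200 bp downstream of the TSS and ±200 bp around the
termination site (conventional peak-annotation defaults; all
configurable, since the original assignment is delegated to an external
annotator without stated parameters). Gene association for intergenic
CNEs is nearest-gene by bp distance to transcript bounds (ties report all
tied genes; a window mode with a distance cap is available).

## Gene-tree filter

A tree is kept iff its unrooted topology contains a bipartition isolating
exactly the focal clade AND one isolating clade + sister species. Both
conditions are required by default — the conservative reading of
"discarded … not monophyletic and not in a sister relationship" — with an
either/or mode exposed. Only bipartitions are inspected, so decisions are
invariant to rooting and leaf order. With multiple gene copies per
species, strict mode (default) demands every copy of every clade species
inside the clade side; a relaxed mode accepts a side whose *species* set
matches. Background subtraction is plain set difference of gene ids.

## Afgp locus analytics

A gene copy is functional iff all applicable checks pass: exon-1 signal
peptide present; exon-2 length divisible by 3 with no internal stop
(frameshift detection); translated exon-2 ending in the AARG terminal
motif; and, for chimeric afgp/tlp copies, the XLF spacer present ('X'
treated as a wildcard residue — the motif is named as a tripeptide, so
presence is tested in the translated exon-2) and at least one tlp-derived
exon retained. Reasons enumerate every failed check, so planted
pseudogenization events map one-to-one to reason codes.

Haplotype comparison matches gene copies positionally within runs of
constant strand (the two haplotypes of the locus are expected to be
nearly identical in structure); a fallback mode pairs genes by best
exon-1 sequence similarity when the order is perturbed. Each matched pair
reports the exon-2 length difference Δ and `frame_preserving = (|Δ| mod 3
== 0)`; unmatched genes are presence/absence candidates.

Alternating-array detection scans the ordered *gene* tokens (interleaved
repeat tokens do not break a run, matching the gene+TE architecture) for
maximal strictly-alternating strand runs of length ≥ 4; note the flanking
anchor genes participate when their strand happens to continue the
alternation. The duplication-unit detector collapses repeats to family
names and genes to (type, strand), then finds the tandem exact-token
repeat `U^k` (unit ≥ 2 tokens with ≥ 2 gene tokens, k ≥ 2) maximizing
copies × unit length, tie-breaking toward more copies, then earlier
start; genomic coordinates stay attached to tokens so reported spans are
genomic.

## Synthetic data: what it emulates, and what it does not

Every generator is a deterministic function of (parameters, seed); a
single root seed feeds fixed per-component sub-streams, so adding a
generator never perturbs another's draws. The default scenario is a
deliberately scaled-down genome — 20 chromosomes × 1 Mb with one 5-kb
assembly gap each — chosen so every stage (including 50-kb flank
windows) is exercised at realistic densities while the whole pipeline
runs in seconds. Background annotation densities (~22% TE, ~4.5% tandem
repeat, ~20 genes/Mb with multi-exon structure) are in the range of a
repeat-rich fish genome.

* **Diploid SV scenario**: 500 heterozygous TE insertions (half DEL /
  half INS), each backed by a repeat copy at reciprocal overlap
  `1 − jitter` on the appropriate haplotype table, with recent
  (exponential, mean 0.5%) divergences against an older background
  (gamma, mean 6%); 500 non-TE SVs placed by rejection sampling with
  acceptance ∝ `exp(β·z)` in the standardized 50-kb flank densities —
  in this low-acceptance regime the case-vs-uniform-control log-density
  ratio is exactly `β·z`, so a planted β is the estimand of the
  association model on the control-standardized scale. Planted non-TE
  indels are re-drawn if they happen to reciprocally match a repeat, so
  noiseless precision/recall of the het-TE caller is exactly 1 by
  construction. A read-based callset re-detects 66.6% of assembly SVs as
  het and 1.7% as hom-alt with ±200 bp breakpoint and ±10% length noise.
* **Branch mutations**: compound-Poisson insertion/deletion events per
  branch (default 300 kb/MY in, 50 kb/MY out — scaled-down rates chosen
  so the 5-taxon scenario fits the reference layout), event sizes uniform
  in [0.5, 1.5]× the 1-kb mean; each insertion fragments into ≤ 3 pieces
  with gaps < 100 bp sharing an event id; TE events (60%) get a repeat
  copy spanning exactly their merged interval. Lifted intervals are
  packed disjointly with 200-bp spacing, so attribution is exact by
  construction — the generator tests bookkeeping, not overlap ambiguity.
* **Depth tracks** realize a planted ancestry label per element with a
  configurable margin from the 75% boundary (margin 0 places positives
  exactly on the inclusive boundary).
* **Repeat divergences** invert the dating formula over a Gaussian
  mixture of ages (default components at 2 and 9 MY — a recent burst
  against an older peak).
* **Afgp locus**: each duplication unit is two gene pairs in `+ − + −`
  orientation plus a two-repeat TE motif; exon-2 is a real coding
  sequence of (Thr-Ala-Ala) repeats with ALF spacers and an AARG
  terminus, so validation runs on actual translation, not flags.
  Pseudogene events edit the sequence (drop exon-1, delete 1 bp, replace
  the terminal codons, delete tlp exons).
* **Gene trees** plant keep/discard truth by construction: kept trees
  nest the clade sister to the sister taxon; violations either swap a
  clade member out or interpose an outgroup.

What passing these tests shows is that the *procedures* are correct —
thresholds inclusive where stated, merges strict, sums exact, estimators
calibrated. What they cannot show is robustness to everything real data
adds: annotation errors, nested/fragmented repeats beyond the planted
fragmentation, non-uniform SV ascertainment, alignment artifacts in depth
tracks, and gene-tree estimation error. Token-level locus simulation
deliberately stops short of nucleotide-level homology (no sequence-level
duplication decay), so the duplication detector is exercised on exact
token repeats only.

## Numerical choices and known limitations

* CI multiplier fixed at 1.96 (Wald); random-effect SD is reported from
  the posterior mode and should be read qualitatively.
* The mixed-model optimizer's start point draws from the legacy global
  NumPy RNG; notokit pins and restores that state around the fit so runs
  are bit-reproducible.
* Degenerate (zero-variance) predictors are dropped before fitting;
  perfect separation raises an error naming the predictor.
* `distance_to_nearest` returns an absent value (None), never an
  exception, when a chromosome carries no target.
* Exact rank-sum enumeration is capped at 500,000 subsets; beyond that
  the normal approximation is used even for `min(n, m) ≤ 8` (only
  reachable with very unbalanced samples).
* Problem sizes in the test suite and acceptance script (20 Mb layouts,
  500–2,000 SVs per fit, 50 replicates for calibration, 5,000 repeat
  copies, 200 gene trees) were chosen as the smallest scales at which
  the statistical checks have adequate power.
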