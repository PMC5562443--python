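# Methods

This note records the models and conventions behind each analysis, the
parameters that matter, what the synthetic generators do and do not
emulate, and the choices made where the design was genuinely open.

## Signature screen

**Model.** Two cell states (naïve ESC, primed EpiSC) are summarised by a
per-gene mean-expression comparison. A gene joins the state-A signature
when `(mean_a + pc) / (mean_b + pc) > fold_threshold`, and symmetrically
for state B; the comparison is strict, the threshold must exceed 1, and a
gene can therefore never satisfy both directions, making the sets
disjoint by construction. Defaults: `fold_threshold = 10` (the classical
ten-fold rule for these state signatures), `pseudocount = 0`. With a zero
pseudocount, 0/0 genes are excluded (no evidence either way) and x/0
genes count as enriched; a positive pseudocount is the recommended
setting for count-like data.

**Scoring.** A knockdown's effect on a signature set is the signed net
percentage `100·(n_up − n_down)/n_evaluable`, where up/down require both
an FDR gate (`q < 0.05`) and a fold-change gate (`FC > 2` or `< 0.5`),
conjunctively — a significant gene inside the fold-change window counts
as unchanged. Profiles may carry raw p-values (BH-adjusted across the
whole profile, not the signature subset, since significance is a
profile-level property) or inherited q-values used as-is. Signature
genes missing from a profile are excluded from the denominator and
reported (`n_eval_a/b`); an empty evaluable set yields NaN, never 0 —
"no information" must not masquerade as "no effect".

The axes are *signed* even though a percentage-of-genes-altered readout
could be reported unsigned: the quadrant interpretation (maintenance
factors lose ESC and gain EpiSC signature; exit facilitators the
reverse) requires direction, and signed nets reproduce exactly that
behaviour for the archetypes. The quadrant boundary is exact zero by
default (`dead_zone = 0`); a dead zone is exposed because any boundary
rule here is a convention, and axes within ±dead_zone (or undefined)
give the label `null`.

**BH adjustment** is the standard step-up procedure, implemented
vectorised in-package; tests compare it to two independent routes (a
loop-based textbook restatement and statsmodels' `fdr_bh`) at 1e-12.

**DE intersection** retains a gene only if it passes `adj_p < 0.05` and
`FC > 1.5 or < 0.7` in *every* condition table, optionally requiring the
direction to agree; genes absent from any table are never retained.

## Dynamics

"Highest expressed across all time points" is interpreted as the highest
mean over the shared grid (robust to a single spiky timepoint); a
`min_rank` alternative — the best per-timepoint rank achieved — is
exposed as a flag. Ranks are ordinal with ties broken lexicographically
by candidate id and logged.

The transient rule: a course is transiently induced iff its maximum is
at an interior timepoint, strictly exceeds the initial value, and the
final value has declined to ≤ `decline_fraction` × peak. The default
`decline_fraction = 0.6` encodes "declined substantially after the
peak"; no sharper numeric rule is inherent in the phenotype, so the
parameter is exposed. Courses with fewer than three timepoints return an
explicit `unevaluable` status. Sorted-fraction differentials are
`log2((high + pc)/(low + pc))` with `pc = 1` expression unit; no
direction is asserted a priori for any given candidate.

## Methylation

Coordinates are 0-based half-open internally; clone-panel display
positions are accepted 1-based (as drawn in lollipop figures) and
converted by the reader. Window percentages **pool counts**
(coverage-weighted: `100·Σmeth/Σtotal`) rather than averaging per-site
percentages; pooling weights every read equally and is the convention
chosen here, with `per_site=True` available. The discriminating case
(0/10 and 5/5 → 33.33% pooled vs 50% per-site) is pinned in tests.
Promoter windows are strand-aware 2-kb upstream intervals clipped to
chromosome bounds; promoter and genome summaries are **unweighted means
of per-window percentages** (matching an "averaged over all windows"
summary, not a pooled genome-wide count), tiles anchored at 0 with the
last tile truncated, `min_coverage = 1` read by default. Records
duplicated at one position (two strands of a CpG dyad) are merged by
summing counts. Undefined windows (no eligible CpG) are excluded from
averages and reported via the contributor count.

## TE composition

Exons and repeats are merged independently before coverage, so
overlapping records never double-count; the TE fraction is covered
exonic bases over total exonic bases of the **exon union** (not summed
per-transcript bases). Overlap is strand-agnostic — TE content is a
positional property. When repeat names carry RepeatMasker-style classes
(prefix before the first `/`), a per-class breakdown is computed; bases
claimed by several classes are counted once in the total and surfaced as
`multi_class_bases`.

## miRNA targeting

The scanner implements canonical seed matching only: a 6mer core
(reverse complement of miRNA positions 2–7) optionally extended by the
m8 match and/or the A1 adenosine — which must be A in the target
regardless of the miRNA's first base, per the canonical convention.
Each seed-match locus is reported once with the strongest satisfied
type. This is a deliberate, declared simplification relative to
pattern/energy-based predictors: site lists are not comparable with such
tools and no claim is made about their predictions. Scanning is on the
given (sense) strand; DNA input is converted T→U. Every emitted site is
re-validated by direct reverse-complement comparison before being
returned.

Escape analysis aligns wild-type and mutant sites by position (reporter
mutations are substitutions, so coordinates are shared); a mutant
retaining none of the wild sites is flagged `escape`. Loop-motif
occurrences must lie entirely within the stated loop interval —
boundary-straddling matches are not loop-presented in the hairpin and
are excluded. Fold repression is mean(firefly/Renilla | scramble) ÷
mean(... | mimic), arithmetic mean of replicate ratios by default with a
geometric option; it is invariant to rescaling both channels of a
condition but deliberately not to rescaling one channel alone.

## Synthetic data

One root seed drives all generators through named substreams
(`SeedSequence(seed, spawn_key=(crc32(name),))`), so outputs are
bit-for-bit reproducible and adding a generator never perturbs another's
stream. Every generator returns machine-readable truth; recovery tests
consume only that truth.

Defaults state the simulated study conditions: 1,000 genes with 182/131
planted signature genes; per-gene enrichment folds drawn strictly above
the ten-fold threshold (`10·exp(Exp(0.5))`, so noiseless derivation at
threshold 10 is exact); multiplicative log-normal noise with natural-log
sd 0.2 on expression tables. Knockdown panels plant four archetypes —
maintenance (−ESC, +EpiSC), dual-requirement (−, −), exit-facilitator
(+, −) and null — each shifting 60% of the affected signature set
four-fold across six replicates; fold change is the ratio of replicate
means and the p-value a Welch two-sample t-test on log expression (any
standard test satisfies the screen's input contract, which inherits
statistics from upstream in real use).

Time courses run over 0–48 h with the planted transient peaking at 12 h
and declining to a quarter of its peak; decoys are flat, steadily rising
(peri-implantation-marker-like) or rapidly collapsing
(naïve-marker-like). Time-course values emulate replicate-mean RT-qPCR,
hence a lower noise default (sd 0.1); exact isolation of the planted
transient is guaranteed only for noise sd ≲ 0.05 and is tested at that
bound, since at higher noise a noisy monotone profile can genuinely
satisfy the transient rule.

Clone panels draw each call independently at its region's planted
probability (defaults 0.40 and 0.05, a methylation-gaining and a
refractory promoter region; 20 clones × 10 CpGs per region), with an
optional missing-call rate. The simulated genome plants a focal
three-exon transcript whose exons are 76.4% repeat-covered by
construction (prefix-tiled, realised fraction recorded as truth) and a
CpG landscape with hypomethylated promoters (10%) against a 70%
background, Poisson(10)+1 coverage. UTRs are rejection-sampled free of
spurious seed matches before sites are written in, the assembled
sequence re-scanned against the planted truth, and mutant copies carry
two non-complementary substitutions per site, verified to escape.
Luciferase tables plant per-construct fold repressions (2.8/3.0 for the
site-carrying UTRs — "more than 60% repression" territory — and 1.0 for
the empty control) with ~8% CV replicate noise.

What the generators do **not** emulate: transcriptome-wide correlation
structure, count-based (negative-binomial) sampling noise,
read-level/bisulfite-conversion artefacts, linked CpG methylation
states, realistic repeat length/nesting distributions, or
position-dependent UTR composition. Passing recovery tests therefore
demonstrates correctness of the analysis logic under the stated
statistical structure, not performance on real sequencing data.

## Pipeline

Configuration is YAML (nested key/value) with the screen, DE,
methylation and annotation thresholds surfaced at their standard
defaults (fold 10; FDR 0.05; FC 2/0.5; DE 0.05 with 1.5/0.7; 2,000 bp
upstream; 50,000 bp tiles). Input validation is header-level plus spot
value checks (e.g. meth ≤ total), reporting file and message per error.
Analysis stages are mutually independent and all read the shared input
directory; a stage failure is recorded in the report while peers
complete, and stages that would consume a failed `simulate`'s outputs
are skipped. Logging goes to stderr; results only to files/stdout.
Outputs carry the tool version, seed and config digest, contain no
timestamps or absolute paths, and rerunning an identical config
reproduces every file byte for byte. The full default-scale synthetic
run (1,000 genes, one 300-kb chromosome, 16 candidates) completes in
about a second on one CPU; problem sizes were chosen so the whole suite
and the acceptance script each run in well under a minute of compute.

## Known limitations

- The screen consumes precomputed differential tables; it does not model
  the upstream negative-control construction or re-fit count models.
- Signature axes assume the profile's q-values (or BH over its raw
  p-values) are exchangeable across genes; gene-length or expression-
  dependent power is not modelled.
- The seed scanner ignores 3'-supplementary pairing, duplex folding
  energy and site context/accessibility entirely.
- Genome/promoter methylation averages treat every window equally; a
  CpG-count-weighted mean is not offered because the chosen summary is
  the per-window average.
- Interval coverage is quadratic per chromosome pair-block after
  merging; adequate for annotation-scale inputs, not for tens of
  millions of intervals.
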