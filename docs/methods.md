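# Methods

This note documents the models and procedures implemented in `lncsig`, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not establish.

## Probe reannotation

Arrays designed for coding genes are repurposed for lncRNA expression by
assigning probes to lncRNA genes. A probe is assigned by **exact,
full-length, mismatch-free substring search** against every transcript.
Because only perfect full-length matches are accepted, a seeded aligner
with a stringent e-value pre-filter (the conventional setup for this task)
would retain exactly the same matches; the `evalue_cutoff` parameter
(default 1e−6) is therefore documentary and inert, and no external aligner
is needed.

The filter chain is:

1. keep full-length perfect matches only;
2. remove **every** hit of any probe that matches both a lncRNA and a
   protein-coding transcript (such probes measure a mixture);
3. collapse transcript hits to genes; probes matching transcripts of more
   than one distinct lncRNA gene are dropped (`drop_multi_gene`) — the
   conservative choice for unambiguous gene-level quantification, and
   logged so it is auditable;
4. discard lncRNA genes with fewer than `min_probes_per_gene` probes
   (default 3) — too few probes give unstable summaries.

Whether probe files store the sense or antisense sequence varies by
platform, so matching is performed on both strands by default
(`strand_mode="both"`); `forward`/`revcomp` restrict it. "Gene-level"
assignment uses the transcript→gene mapping of the annotation table rather
than a genomic alignment: that mapping is exactly the information the step
consumes. Probe length is validated at load (default 25 nt), not
hard-coded.

Provenance counters record the probe count entering and surviving each
stage and always balance (in = retained + removed).

## Signatures and drug-induced lncRNA sets

Probe-level log2 intensities are summarized to genes by the **median**
(default; mean optional) over each gene's assigned probes. Upstream
preprocessing of raw arrays (background correction, normalization) is out
of scope; the pipeline consumes any log2-scale matrix.

Per instance, `log2fc(g) = mean(treatment) − mean(control)`. With several
controls the mean is the standard contrast. A gene is a **DEL**
(differentially expressed lncRNA) when `|log2fc| ≥ log2(fc_threshold)`
with `fc_threshold > 1` (conventional values 1.5 and 2.0; default 1.5).
The cutoff is the exact binary logarithm — at threshold 1.5 that is
0.58496…, displayed as ±0.58; a gene at exactly 0.58 is *not* called, which
avoids boundary drift between the displayed and the effective rule.

A drug's induced lncRNA set is the **unsigned union** of DELs over its
instances, the unit both enrichment engines test; signed direction flags
are retained in the signature export. DEL sets shrink monotonically as the
threshold rises, and swapping treatment/control labels negates every
log2fc and mirrors up- and down-DELs.

## ORA

The overlap r between a query list (n of m universe lncRNAs) and a drug
set (t of m) is scored with the hypergeometric upper tail
`p = P(X ≥ r) = 1 − Σ_{x<r} C(t,x)C(m−t,n−x)/C(m,n)`. The tail is summed
directly in log space (log-binomials via `lgamma`, combined by
log-sum-exp), which is exact to double precision over the ranges used and
stable for large counts; r = 0 returns exactly 1. The universe defaults to
the genes of the reannotation map — the measurable lncRNA universe — and
is overridable. Multiple testing across drug sets uses Benjamini–Hochberg
q-values (Benjamini–Yekutieli optional). Set-size bounds for testing are
permissive by default (min 1, max = universe).

## LSEA

Given a two-class profile, genes are ranked by **signal-to-noise**
`(μ1−μ0)/(σ1+σ0)` with each class σ floored at `max(0.2·|μ|, 0.2)` — the
floor keeps near-constant genes from dominating the ranking; Welch t and
difference of means are alternatives, and metrics needing ≥2 samples per
class fall back to difference of means (logged). Ties in the ranking are
broken by gene id so results are fully deterministic.

Walking down the ranked list, the running sum rises at members and falls
at non-members; **ES is the signed value of maximal |running sum|** (first
such position on ties). With `weight_exponent=0` steps are uniform (+1/Nh,
−1/(N−Nh)) and the walk terminates at exactly zero — this is the classical
unweighted statistic. With `weight_exponent=1` (the default, matching
modern GSEA practice) member steps are proportional to |ranking score|;
when all member scores are zero the weights collapse to uniform. The
leading edge is the members at or before the extremum for positive ES, and
strictly after it for negative ES.

**Permutation null.** Phenotype mode permutes the 0/1 sample labels,
re-ranks and recomputes every set's ES, preserving inter-gene correlation;
gene-set mode keeps the observed ranking and redraws same-size member
sets. The default `auto` mode uses phenotype permutation when both classes
have ≥ 7 samples and gene-set permutation otherwise: with fewer samples
the label space is tiny and sets containing genuinely differential genes
inherit inflated permutation nulls, which destroys power precisely for the
true positives.

**Statistics.** NES divides each ES (observed and null alike) by the
set's mean |null ES| of matching sign; nominal p is the add-one
same-sign tail fraction `(1 + #{|null| ≥ |ES|})/(1 + #null)`, so no
reported p is zero; FWER p compares |NES| with the per-permutation maximum
|null NES| over all sets; FDR q is the sign-stratified ratio of pooled-null
to observed NES tail fractions, clipped to [0, 1] and made monotone in
|NES| within each sign (BH on nominal p is available as an option). A set
with no matching-sign null samples has undefined NES; it is flagged and
ranked last rather than given a fabricated score. Output is ordered by
nominal p, then |NES| descending, then drug name.

## Synthetic data

The generator emulates, at desk scale, a perturbation-database study: a
transcriptome of 60 lncRNA and 30 coding genes (1–3 isoforms of 150–400 nt,
i.i.d. uniform nucleotides), 8 probes of 25 nt per lncRNA gene plus 10% of
probes additionally planted into coding transcripts (cross-biotype by
construction) and 10 decoys verified absent from every transcript on both
strands; 8 drugs × 3 instances (one treatment, two controls), each drug
shifting 10 effect genes by ±1.5 log2 units over Normal(7, 1) gene
baselines with Normal(0, 0.3) probe-level noise; and a two-class disease
profile of 6 + 6 samples in which 8 members of one target drug's set are
shifted by the same effect size. The universe of 60 lncRNA genes with
10-member drug sets keeps expected between-drug set overlap near 1–2
genes, so drugs are distinguishable — the regime the method is meant for.

Ground truth (gene→probe assignments, per-probe filter fate, per-drug
effect sets, shifted disease genes) is recorded at generation and verified
against the emitted sequences: planting a probe into a coding transcript
can make an *overlapping sibling probe* match coding sequence too, so
fates are re-derived by scanning the final sequences rather than trusted
from the planting bookkeeping. All randomness derives from one seed via
`SeedSequence` spawning — one child generator per artifact — so every
stage is independently reproducible and byte-identical across runs.

The noise model is Gaussian on the log2 scale by design transparency; it
does not emulate microarray error structure (intensity-dependent variance,
background, spatial artifacts), probe GC effects, or correlated gene
modules. Passing tests therefore establish algorithmic correctness and
statistical calibration under exchangeable Gaussian noise, not performance
on real arrays.

## Test and verification scale

Correctness is checked against independent oracles: a sliding-window
matcher for probe hits, exact rational arithmetic and outright draw
enumeration for the hypergeometric tail (the full m ≤ 20 grid and sampled
m ≤ 60 cases at 1e−12 relative tolerance), and a step-by-step Python walk
for ES (200 random lists up to N = 200 at 1e−9). Calibration uses 100
label-exchangeable datasets of 20 genes × 12 samples with 10 sets and 200
permutations each — small enough to run routinely, large enough for the
binomial error band (±3 SE around 0.05) to be meaningful. Planted-drug
recovery uses 100 full pipeline runs at the default study conditions. The
acceptance script scales these to 20 fixtures / 40 datasets / 50 runs,
sizes chosen to keep a full from-scratch reproduction under a minute.

## Known limitations

- No raw-array preprocessing; inputs must already be log2 intensities.
- Exact matching admits no mismatches or indels; probes with even one
  mismatch to the transcriptome are unassigned by design.
- The permutation FDR follows the GSEA convention and can be 0 when no
  pooled null NES exceeds an observed one; it is a Monte-Carlo estimate,
  not a closed-form bound.
- Gene identifiers are opaque strings; no cross-annotation id mapping.
- Phenotype permutation with very unbalanced or tiny classes yields few
  distinct relabelings; the add-one estimators keep p-values valid but
  coarse.
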