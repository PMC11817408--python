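# Methods

This note documents the statistical procedures implemented in `rd3d`,
the synthetic data they are validated on, and the design choices made
where several reasonable conventions exist.

## 1. Data model and conventions

All coordinates are 0-based, half-open (BED convention); GTF input is
converted on read. Strand is parsed and stored but never conditions any
statistic. Hi-C matrices are sparse upper-triangular bin-pair counts per
chromosome pair, read from plain tab-separated triplet text
(`chrom_a bin_a chrom_b bin_b count`); optional balancing weights are
accepted per bin and folded into expected values (mean-normalised,
multiplicative per anchor) rather than applied to observed counts.
Cis contacts are contacts on the RNA gene's chromosome, trans contacts
all others; cis contacts further split into *close* (< 20 Mb from the
nearest gene edge) and *distant*.

Defaults throughout (`AnalysisConfig`): 10 kb intra- / 50 kb
interchromosomal bins, Hi-C peak FDR 0.05 (intra) / 0.2 (inter), 2 Mb
background shift, per-RNA q-threshold 0.05, 5-bin expanded loop
anchors, ±500 kb anchor metaplot window, 20 kb loop-match tolerance,
top 6000 RNAs by peak count, top 100 RNAs per chromosome for TAD
metaplots, ≥ 10 cis contacts per gene for OutInDR, 10% peak-contact
fraction preset (20% for the softer cross-species preset, exposed as a
parameter rather than a separate code path).

## 2. Statistical kernels

**Fisher exact test (two-sided).** The probability-mass rule: p is the
sum of hypergeometric probabilities, over tables with the observed
margins, of every table whose probability does not exceed the observed
table's times (1 + 1e-7); the relative tolerance makes floating-point
ties deterministic. The implementation computes the whole conditional
family at once (`_family_pvalues`), which both serves the scalar API
and allows exhaustive verification: the test suite and acceptance
script compare it against an exact integer-arithmetic oracle
(binomial-coefficient enumeration) on every 2×2 table with all margins
≤ 30, and against `scipy.stats.fisher_exact` on random tables. The
odds ratio is the cross-product ad/bc, undefined (NaN) when bc = 0.
Degenerate margins give p = 1.

**Benjamini–Hochberg.** The standard step-up procedure
(q(i) = min over j ≥ i of p(j)·m/j on the sorted family, capped at 1),
applied strictly within the families stated per stage and never pooled
across analyses: all RNA × chromosome tests of one association run form
one family, intra and inter separately; all RNAs within one direction
of one experiment pair (conservation); all RNAs per contact class
(loop association); all biotype pairs (OutInDR comparisons); each
chromosome or chromosome pair separately for Hi-C peak calling.
q-values that underflow are reported as "< 1e-300" in text output
rather than 0.

Mann–Whitney U (exact null for small untied samples, tie-corrected
normal approximation otherwise; identical samples report p = 1),
Spearman correlation and the 1-df χ² go through scipy; the t-SNE
embedding through scikit-learn with a fixed random state and a
perplexity that adapts to small inputs.

## 3. Hi-C significant interactions and the shifted null

The caller is deliberately a simplified distance-stratified count
model, not a spline fit. For an intrachromosomal matrix the expected
count at bin separation d is the mean raw count over *all* pairs at
that separation, zeros included (optionally pooled into log-spaced
strata for sparse matrices); interchromosomal matrices use the global
mean over all possible cross pairs. Each stored pair is assigned the
upper-tail Poisson probability P(X ≥ observed | λ = expected), BH is
applied within the matrix, and pairs with q ≤ the FDR threshold are
retained. When expected = 0 with observed > 0 the model's smallest
positive expected value is substituted to avoid zero p-values.
Externally called significant-interaction tables (FitHiC2-style text)
are accepted verbatim, bypassing the caller, with provenance recorded.

**Shifted background.** Every significant pair moves `shift`
nucleotides along the main diagonal (intra: separation exactly
preserved) or along each axis independently (inter: the two axes may
take opposite directions). A shifted pair is kept only when both new
anchors carry the same A/B compartment label as their originals (label
= compartment covering the bin midpoint); if +shift fails, −shift is
tried; otherwise the pair is dropped, so the background is never larger
than the foreground. Without a compartment track the shift degrades to
a pure translation with a warning — except for loop-anchor analysis,
where the compartment track is required because the uncorrected
background systematically underestimates contact density in open
chromatin.

## 4. Per-RNA structural association

Candidate pairs are pairs of *occupied bins* (the support), not
contact-weighted pairs: duplicate contacts in one bin are collapsed
before pair enumeration, making all counts invariant to contact order
and amplification multiplicity (both properties are asserted by tests).
Scopes below minimum support (< 2 occupied bins intra; an empty side
inter) are excluded from the BH family rather than tested. Counting is
done by scanning the sparse peak set for pairs whose anchors are both
occupied, so the full candidate set is never enumerated. Significance
additionally requires odds ratio > 1: the two-sided test alone would
also flag depletion, which is reported but not called "associated".
The 2×2 layout (rows real/shifted, columns paired/non-paired) is this
package's fixed convention.

## 5. Chromatin-state enrichment

A bin belongs to a state when ≥ 1 bp of a state interval falls in it,
so bins can carry several states of one annotation; a bin pair belongs
to a state when both bins do, and only same-label pairs are evaluated.
Because labels are not mutually exclusive, rows are not normalised
across labels. The expected in-state fraction e is the share of
significant Hi-C interactions *on the same chromosome* whose both
anchors carry the label (per-chromosome rather than genome-wide,
matching the per-chromosome reporting of the enrichment profiles); the
observed count o of a RNA's T paired pairs is tested by a 1-df χ² of
[o, T−o] against [eT, (1−e)T]. log2(o/eT) profiles over all labels of
all annotations, with undefined cells imputed as 0 alongside a mask,
feed the embedding. Grouping maps (raw → grouped label) are user
config; the shipped SPIN default keeps Interior_Repr2 as its own
NAD-like group, reflecting its nucleolar association.

## 6. Cross-experiment conservation

For one RNA, the target experiment's candidate pairs are
cross-classified by pairing (target Hi-C) and presence in the reference
(the same unordered bin pair occurs among the reference's candidate
pairs for the same RNA, at identical resolution; an optional ±1-bin
tolerance flag exists but exact matching is the default and the
conservative choice). Intra pairs are pooled over chromosomes per RNA.
Both directions are computed and logged separately, never averaged;
the conserved set keeps RNAs with q < 0.05 in both directions and odds
ratios on the same side of 1.

## 7. Loops and TADs

Loop BEDPE records reduce to linear anchors (midpoints). Metaplots
average contact counts per 10 kb offset bin over ±500 kb around
anchors (101 offsets), observed versus compartment-preserving 2 Mb
shifted anchors; anchors whose shifted image is dropped are excluded
from both sides so the comparison stays paired. The per-RNA association
test counts contacts (with multiplicity — here exposure matters, unlike
the support-based pairing statistic) inside anchors expanded to 5 bins
(the midpoint bin ± 2), tested against the same background. A
wild-type loop is *common* when some mutant loop has both anchor
midpoints within 20 kb of its respective anchors (both-anchor matching
is the strict reading), else *differential*; per-anchor contact-count
distributions of the two classes are compared by two-sided
Mann–Whitney.

The parental TAD is the TAD overlapping strictly more than half the
gene (ties and boundary-spanning genes are unassigned). TAD metaplots
rescale each parental TAD and a one-TAD-length neighbourhood to the
relative axis [−1, 2], histogram each RNA's cis contacts there (90
bins), normalise each RNA's histogram to unit mean so heavily
contacting RNAs do not dominate, and average the top 100 RNAs per
chromosome by in-window contact count. Run on the full contact set the
profile is dominated by RD-scaling decay; run on peak-filtered contacts
it exposes residual structure such as TAD-boundary enrichment.

**OutInDR** = (n_out / (chromosome length − TAD length)) /
(n_in / TAD length), cis contacts only — densities per bp, with
"outside" the entire rest of the gene's chromosome. Genes with < 10
cis contacts, no inside or no outside contacts are excluded with
reason codes rather than pseudocounted, since only finite −log10
values are meaningful downstream. The ratio is exactly invariant to
uniform scaling of contact counts (asserted), i.e. independent of
expression level. The name follows the outside/inside-density
definition; an inner/outer reading of the same quantity is simply its
reciprocal, and −log10(OutInDR) is reported so either orientation is a
sign flip. Cross-experiment and cross-species comparisons are Spearman
correlations of −log10(OutInDR) over shared genes (identity mapping or
a supplied two-column ortholog table).

## 8. Synthetic data and validation cohorts

`rd3d.simulate` generates coupled toy datasets: Hi-C counts are
independent Poisson draws around base·(1 + d/d0)^(−α) modulated by a
TAD factor (both bins in one planted TAD), a dot factor (planted loop
pairs) and a compartment factor (same checkerboard label); RNA cis
contacts follow the RD-scaling law p(x) ∝ (1 + |x − gene|/s)^(−γ)
sampled on a 1 kb grid, trans contacts are uniform. Poisson is the
simplest count model consistent with the downstream upper-tail test;
the parametric RD law is a stand-in for spline-fitted scaling profiles
and suffices for testing. Planted effects:

- `hic_paired` — a fraction f of the RNA's cis contacts are placed as
  pairs whose bins are drawn from the called significant-interaction
  list (one contact in each end bin), giving a tunable, interpretable
  effect size for power analysis;
- `loop_anchor` — placement density multiplied inside 5-bin expanded
  anchors;
- `state_pref` — peak-pair placement with sampling odds multiplied by
  m when both peak anchors carry the chosen label. This plants at the
  *pair* level deliberately: multiplying single-contact density by m
  would inflate both ends and push the pair-level observed/expected
  toward m², whereas pair-level planting makes the multiplier equal
  the expected enrichment up to the normalisation 1/(1 + (m−1)e).

Multiplier 1 (or f = 0) reduces every planted mechanism to its null
form, and a fixed seed fixes every output byte.

**Scale conventions.** The validation cohorts run on deliberately small
genomes so that multi-seed recovery studies complete in seconds; the
background shift scales with the chromosome (400 kb on the 2 Mb
association chromosome, the standard 2 Mb on the 10–40 Mb cohorts) and
is always an even multiple of the planted TAD and compartment periods,
so the shifted map is statistically exchangeable with the original.
Two further conditions that hold automatically on real genomes are
imposed explicitly at toy scale: planted dot separations are capped so
every significant pair has a valid shift image, and study genes sit at
least one shift away from chromosome ends so no RNA's neighbourhood
falls in a shift-edge zone where the real and background peak fields
differ. Contact budgets (200–600 per RNA) correspond to the
well-covered regime of highly contacting RNAs. The conservation null
uses diffuse RD scales: with sharply peaked RD decay, distance to the
gene confounds pairing with reference presence even for independent
experiments — a structural property of the test construction, not an
implementation artifact — so null calibration is defined on diffuse
RNAs.

What the cohorts do *not* emulate: polymer-physics contact structure,
sequence context, mappability and coverage biases, peak-caller
behaviour upstream of the contact table, or inter-chromosomal planted
effects. Passing recovery tests therefore demonstrates correctness and
calibration of the statistics under the stated generative model, not
performance on any particular experimental dataset.

## 9. Numerical choices and degenerate inputs

Fisher tie tolerance 1e-7 relative; BH families as in §2; expected = 0
with observed > 0 → smallest positive expected; undefined odds ratios
(zero cross-product) are NaN and never pass significance or
concordance filters; undefined log2 O/E imputed as 0 with a mask only
for the embedding; per-RNA scopes below support, genes without a
parental TAD and degenerate OutInDR records are excluded with reasons
rather than filled. Top-N selections break ties lexicographically by
RNA identifier so every ranking is deterministic. All randomness flows
from explicit integer seeds through `numpy.random.default_rng`.

## 10. Known limitations

The Hi-C caller is a distance-stratified Poisson test, not a spline
model with fragment-level biases; it accepts, but does not compute,
balancing weights. Loop and TAD annotations are inputs (or synthetic
ground truth) — no loop or TAD calling is performed. Interchromosomal
state enrichment uses the same per-scope machinery but has no planted
validation cohort. The conservation statistic inherits the
distance-confounding described in §8 for sharply localised RNAs. The
t-SNE embedding is a visualisation aid only; no statistic is computed
from its coordinates.
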