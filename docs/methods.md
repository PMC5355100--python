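# Methods

## Study design being modeled

The package models a paired biomarker-discovery funnel: a small number
of matched tumor / adjacent-normal tissue pairs profiled on a combined
lncRNA + mRNA microarray; volcano filtering of differential probes;
positional association of DE lncRNAs with coding genes; gene-set
over-representation of the DE mRNAs; a raw-intensity stability filter
that promotes a handful of lncRNAs to candidate biomarkers; qPCR
re-measurement of the candidates in larger training and validation
cohorts; and ROC evaluation of single markers and of their logistic
combination. Every stage is implemented against explicit contracts and
exercised on synthetic data with planted truth, because the interesting
guarantees (recall of planted effects, false-positive control, exact
recovery of planted genomic relations) are only checkable when the
truth is known.

## Differential expression

Quantile normalization replaces each sample's sorted values by the
row-wise mean of all sorted columns, preserving within-column ranks;
ties receive the mean of the reference values they span, which makes
the map deterministic and idempotent. Fold change is the mean of
per-pair log2 ratios (with pseudocount, default 1.0, added to both
members); this respects the paired design, and ratio-of-means is
available since array software differs on this point. The test is a
two-tailed Student *t* on log2(intensity + 1): pooled two-sample by
default (matching the generic "Student's t-test" most studies report),
paired as an option since the design supports it. A probe whose groups
have zero variance everywhere gets p = 1 with a logged warning rather
than NaN, keeping the pipeline total; this deliberately treats a
zero-noise measurement as untestable rather than infinitely
significant. BH adjustment is delegated to statsmodels and applied per
probe class (lncRNA and mRNA as separate universes, the convention when
the two are reported separately), joint adjustment being one flag away.
Volcano filtering is strict on both sides (fold change > 2.0, FDR <
0.05); an `fdr_threshold >= 1` disables the FDR gate, because adjusted
values of exactly 1.0 are common and a strict comparison would
otherwise make the filter impossible to turn off.

## Positional association

Coordinates are 0-based half-open throughout (BED convention).
Overlap on the same strand is `sense_overlap`, or `intronic_sense` when
the lncRNA lies inside the gene and is not identical to it; opposite
strands give `antisense_overlap`. Disjoint intervals on one chromosome
are neighbors when the gap (facing-end distance) is strictly below
300 kb. Enhancer-like vs plain intergenic neighbors cannot be told
apart from coordinates; the label comes from the lncRNA's annotation
class, as it does on commercial arrays. The concordance summary counts,
per relation class, pairs where both partners pass the DE filter and
the fraction changing in the same direction; lncRNAs with several
partners contribute one count per partner pair (the alternative —
counting lncRNAs once — is not well defined when partners disagree).

## Enrichment

The over-representation p-value is the exact upper tail P[X ≥ x] of
the hypergeometric distribution (the observed overlap included, so
overlap 0 gives exactly 1), summed from log-space mass terms for
stability at large universes. No multiple-testing correction is applied
by default — the classic vendor-tool convention of a raw 0.05 cutoff —
with BH available as an option. Sets are ranked by p with
lexicographic tie-breaks so output order is deterministic.

## Candidate selection

Computed on raw, un-normalized intensities, since the point of the
filter is measurement stability of the physical probe signal: T̄, N̄,
A = |T̄ − N̄|, the within-group ranges, an inclusive [100, 20000]
per-sample intensity gate ("between" is read inclusively; the bounds
are configurable), and selection when at least one group's range is
strictly smaller than A/10. The either/or is a logical OR — one stable
group suffices — with a stricter AND mode available. The rule is scale
equivariant apart from the gate (A and both ranges scale together),
which the tests check with the gate disabled. Pair counts generalize
from the historical three to any n ≥ 1 without changing the formulas.
Output is ordered by descending A with probe-id tie-breaks.

## qPCR quantification

Replicates are averaged on the Cp scale (the convention of the
2^−ΔΔCt literature; averaging expressions instead would change values
whenever replicates disagree). ΔCp = Cp_target − Cp_reference within a
sample removes sample-loading effects, which is why a sample-wide Cp
shift cancels exactly. Two calibrators ship because published
group-level tables do not pin the choice down: the matched normal
sample of the same pair (default for the standalone operation — natural
in a paired design, and it makes every normal sample's relative
expression exactly 1), or the normal-group mean ΔCp per gene (used by
the pipeline's ROC stage, precisely because the paired calibrator's
degenerate normals would make group separation trivial). Amplification
efficiency is fixed at 2; efficiency-corrected variants are out of
scope.

## ROC and the panel

AUC is computed by midranks (ties count half), identical to the
trapezoidal area under the empirical ROC; its SE uses Hanley–McNeil
with Q1 = A/(2−A) and Q2 = 2A²/(1+A). The operating point maximizes
Youden's J over observed cut-points under the rule score ≥ threshold ⇒
positive, breaking J ties toward the higher (more specific) threshold.
How published five-marker panels combine their markers is typically
unstated; the conventional choice — binary logistic regression on the
marker values, ROC on the fitted score — is implemented with a small
ridge (1e-6) so separable data keep finite coefficients, via
scikit-learn's lbfgs solver with a tight tolerance so the fit is
deterministic. The panel is always fit on the training cohort only and
applied with frozen coefficients to validation. `binormal_auc` is the
closed-form bridge Φ(Δμ/√(σ₀²+σ₁²)) from group summary statistics to
an AUC; it is exact when scores are normal within groups and degrades
for strongly skewed relative-expression distributions (group SD of the
order of the mean or larger), which is visible in published rows whose
empirical AUC exceeds the binormal value.

## Synthetic data generator

`SimConfig` defaults are the emulated study conditions: 3 discovery
pairs, 600 + 600 probes, 10% planted DE with |log2FC| uniform in
[1, 3] and balanced signs, log2 baselines N(9.5, 1.5²) (so typical
intensities span roughly the [100, 20000] gate), a per-pair random
effect (SD 0.2 log2 units) shared by both members of a pair, residual
noise SD 0.3, and 83% same-direction concordance for planted
lncRNA–gene links. Planting uses deterministic counts
(round(frac · n)) so count assertions are exact, not binomial.
Intensities are clipped at 1 so logs are always defined. Each linked
lncRNA–gene pair is placed on its own pseudo-chromosome with geometry
realizing the planted relation exactly (neighbor gaps drawn in
[10 kb, 290 kb)); unlinked probes live on background
pseudo-chromosomes, so no relation holds by accident. Five "ideal
biomarker" probes (mid-gate baseline in 2^[10,11], |log2FC| = 3, no
pair effect, residual SD 0.02) are planted as the known recovery target
for the end-to-end funnel test. Cp tables follow Cp = c0 − log2(expr) +
noise (c0 = 30, replicate SD 0.15, triplicates) plus a constant
reference gene. qPCR cohorts (24 training / 39 validation pairs) draw a
shared per-sample log2 factor (SD 1.2) that correlates markers within a
tissue plus marker-specific noise (SD 1.6), sized so single markers are
imperfect classifiers and the panel is visibly better.

What the generator does **not** model: probe sequence effects,
background/hybridization physics, batch effects, array spatial
artifacts, qPCR efficiency differences between genes, or inter-gene
correlation structure beyond the single shared factor. Passing tests
therefore demonstrate the correctness and calibration of the
statistical machinery under the stated model, not performance on any
real cohort.

## Pipeline and reproducibility

Stages communicate only via files (TSV/CSV/GMT), so each is
independently runnable, inspectable and resumable; the manifest records
the package version, full config, seed, per-stage record counts
(the funnel shape) and SHA-256 checksums of every output. Stage seeds
are small fixed offsets from the run seed so toggling one stage does
not reshuffle another. A rerun with identical config and seed
reproduces every checksum.

## Numerical and degenerate-input choices

Strict inequalities wherever the rule says "greater than" / "smaller
than" (fold change > 2, FDR < 0.05, gap < 300 kb, range < A/10);
boundary cases are excluded and tested. Zero-variance t-tests give
p = 1 (see above). A = 0 can never select (no range is < 0). Empty
association lists give an empty summary, not an error; a dangling
partner id is an error naming the ids. `binormal_auc` with two
identical point masses is undefined and raises; with distinct point
masses it returns 0 or 1. BH input outside [0, 1] raises. Hypergeometric
tails are clipped into (0, 1]. Problem sizes in the test-suite
simulations (hundreds of probes, ≤ 10 pairs, n = 2000 for coefficient
recovery, n = 10⁵ for the binormal convergence check) were chosen as
the smallest sizes at which the corresponding statistical property is
comfortably away from its sampling noise.

## Known limitations

The t-test assumes approximate log-normality of intensities; no probe
summarization, background correction or array QC is performed. The
association stage is purely positional — no expression-correlation
networks. Enrichment has no GO-DAG propagation and term databases are
user-supplied. The candidate filter's gate bounds are a convention
(inclusive) where the prose it models is ambiguous. Panel evaluation
offers no DeLong test, confidence bands or cross-validated model
selection.
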