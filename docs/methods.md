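# Methods

## The measurement being modelled

Pollen-typing amplifies single crossover or parental molecules from the pollen
genomic DNA of an F1 hybrid using nested allele-specific PCR: one
allele-specific oligonucleotide (ASO) anneals to a parent-A polymorphism on
one side of the amplicon and another to a parent-B polymorphism on the other
side, so only recombinant molecules amplify in the crossover configuration.
Three measurements follow, and `pollenmap` implements the analysis of each:
(1) limiting-dilution titration of crossover and parental molecules, giving
genetic distance; (2) Sanger sequencing of individual crossover molecules,
giving breakpoint intervals at polymorphism resolution; (3) short-read
sequencing of pooled, sonicated crossover molecules, giving a quantitative
per-base breakpoint profile.

## Panmolecule coordinates

Because the two parental alleles differ by indels, neither parent's
coordinates can carry crossovers from both. The panmolecule assigns one
coordinate per alignment column of a global alignment of the two alleles:
shared columns carry both parental coordinates, B-only bases carry
insertion code 1, A-only bases code 2, and mismatch columns are SNPs. Its
length therefore equals each parent's length plus the other parent's inserted
bases, and liftover in either direction is a strictly monotone partial
bijection.

Alignment uses Needleman–Wunsch with affine gaps (match +1, mismatch −2, gap
open −6, gap extend −1 by default; a gap of length L costs open + L·extend).
The scoring is configurable because published key tables derive from
hand-curated Sanger templates and no single scoring convention is implied by
them. Ties are broken deterministically in favour of gaps placed rightmost in
parent A (implemented by aligning the reversed sequences and reversing the
result). Mismatch columns are always annotated as SNPs, never merged into
adjacent indels, and ambiguous bases are rejected at load: downstream
exact-match read alignment is undefined over IUPAC codes.

Polymorphism weight counts a SNP as 1 and an indel as its length in base
pairs; maximal runs of one-parent bases collapse to single indel records.

## Titration estimator

At dilution factor d, a reaction is positive when it received at least one
amplifiable molecule, so with stock concentration λ the positive probability
is 1 − e^(−λ/d). Each informative level (0 < positives < reactions) yields
the zero-class MLE λ̂ = −d·ln(1 − k/n) with delta-method variance
d²·p/((1−p)n); levels combine by inverse-variance weighting (a
most-informative-level rule is available as `method="best_level"`). Saturated
or empty series raise an error instructing re-dilution rather than returning
a boundary estimate. Genetic distance cM = 100·x/(x+p) carries a
delta-method SD from both variances; simulation shows <2% bias and ≈95%
nominal coverage when positive fractions sit in the 20–80% range. The 2×2 χ²
genotype comparison uses integer-rounded per-µl means, df = 1 and no
continuity correction.

## Breakpoint calling and interval rates

Transitions are counted over consecutive informative allele calls, so calls
are invariant to interspersed unknowns. Exactly one A→B transition makes a
simple crossover; its interval is closed on the flanking markers and the true
breakpoint lies strictly between them. Zero transitions is parental. Multiple
transitions — or a single B→A transition, which the ASO selection geometry
cannot produce — are classed complex, reported, and excluded from rate tables
with a logged count. Interval length is the open panmolecule span between the
flanking markers (q − p − 1); interval cM is the crossover fraction times the
titration total, so rows conserve both total cM and total crossover count
exactly. Rates for zero-length intervals (adjacent markers) are reported as
NaN rather than divided by zero.

## Read-pair classification

Reads align to both parental templates by exhaustive exact substring search
on both strands (`str.find` stepping; an every-offset slice-comparison scan
serves as the independent oracle in tests). The cascade records a ledger of
pairs surviving each stage: Mapped (both ends hit at least once), Unique
(each end exactly one hit in exactly one template — reads from
non-polymorphic segments hit both templates and are discarded here), Matched
(ends hit different templates), Orientate (the lower-pan-coordinate end
belongs to the configured lower parent; default parent B, matching the
published Ler-lower coordinate rule, and configurable because the
proximal/distal wording of orientation is locus-dependent), Strand (ends on
opposite strands). Each rejected pair is attributed to exactly the first
stage it fails, so stage counts are non-increasing by construction.

The breakpoint span of an accepted pair is the open pan interval between the
inner read ends — the only region where the junction can lie given that both
reads matched their templates exactly; a configuration using the full
fragment footprint instead can be derived from the recorded `fragment_span`.
Coverage assigns 1 to every pan position of each span (difference-array
accumulation), is normalized by the number of accepted pairs and weighted by
cM, bounding the weighted profile by cM everywhere. When a read crosses the
junction inside a tract identical between parents it can still match one
template exactly; such pairs yield spans displaced from the junction, which
is why span-level guarantees are stated for pairs whose reads avoid the
junction.

## Windows, correlation and the divergence model

Windows are adjacent and fixed-size (defaults: 500 bp for Sanger counts,
250 bp for profiles); the trailing partial window is flagged and excluded
from correlations and fits. A simple crossover contributes to each window the
fraction of its open marker interval covered by that window (2 crossovers in
a 150 bp interval split 50/100 contribute 0.67 and 1.33), so totals are
conserved exactly; an empty open interval (adjacent markers) is split 0.5/0.5
between the windows holding its two flanking markers. Indel polymorphism
weight splits per base across boundaries, making windowing at w then merging
pairs identical to windowing at 2w.

The divergence model y = log(a) + b·x^(−c) is fitted by `scipy`
trust-region-reflective least squares with a > 0, c > 0 bounds, from a
deterministic grid of starts (a ∈ {0.1, 1, 10}, b ∈ {0.1, 1, 10, 100},
c ∈ {0.25, 0.5, 1, 2}); the lowest-cost converged solution wins. Windows with
zero polymorphism are excluded (x^(−c) undefined at 0) and counted. On flat
data b collapses toward 0 and c is flagged unidentifiable. Noiseless
model-generated windows are recovered to ≤1e−4 relative error; under
Gaussian noise σ = 0.1 over 200 seeded replicates the median per-parameter
relative error stays within the pre-registered 20% tolerance. Over the
narrow polymorphism range a single real amplicon offers (roughly 10–25
bp-equivalents per 500 bp window), (a, b, c) trade off against one another
and only the fitted curve — not the individual parameters — is well
determined; end-to-end tests therefore assert agreement of predicted values.
Spearman correlation uses mid-rank ties and a two-sided p-value and refuses
constant vectors.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study geometry: amplicon-scale haplotype pairs
(default 6 kb) at 30 SNPs/kb (within the reported 20–35 SNPs/kb band) with
indel events at 0.002/bp and geometric mean length 3; recombinant molecules
with exactly one breakpoint, placed between polymorphisms (never inside an
indel — the resolution at which breakpoints are observable); sonication
fragments uniform on 300–400 bp (the gel size-selection window) sequenced as
75 bp ends; and binomial titration outcomes with Poisson positive
probabilities. Haplotype B derives from A by explicit edits, so the true
alignment, panmolecule and marker set are known by construction and do not
depend on the alignment code under test. `make_haplotypes_exact` places an
exact polymorphism budget (e.g. 195 B-only and 100 A-only bases on a 5,431 bp
parent) at well-separated positions so the optimal alignment is unambiguous.

Simulated molecules run parent A left of the breakpoint, the ASO orientation
assumed by the Sanger caller; classification of reads from these molecules
therefore uses `lower_parent="A"`. Default sequencing error is zero, keeping
exact-match classification lossless; a substitution-error option exists to
study robustness (reads with errors simply fail exact matching — no
mismatch-tolerant rescue is modelled). Not emulated: PCR chimeras, quality
scores, polymerase error spectra, GC-biased fragmentation, and library-size
heterogeneity. Passing tests on this generator therefore demonstrate the
correctness of the coordinate arithmetic, filters and estimators, not
robustness to those artefacts of real libraries.

Default problem sizes in the test suite (10⁴ read pairs for the
false-positive screen, 10³ molecules for bracketing, 200 replicates for fit
recovery, 10⁴ reactions for titration recovery) were chosen to make the
statistical assertions sharp at desk scale.

## Known limitations

- Exactly two haplotypes; no multi-parent panmolecules or pangenome graphs.
- Exact-match classification discards reads crossing the junction unless an
  identical tract lets them match one template; profiles are therefore
  conservative near polymorphism-dense junctions.
- The χ² comparison treats per-µl mean counts as observed counts, as in the
  published tables; it does not propagate titration uncertainty.
- Complex molecules are excluded from interval tables rather than modelled as
  gene-conversion-like tracts.
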