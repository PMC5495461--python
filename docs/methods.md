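# Methods

## The statistical model

All differential calls are made between two pooled libraries without
replicates.  The model treats a tag's count in each library as Poisson
sampling from the library at an unknown per-tag rate; conditional on the
CK count *x*, the stage count *y* then follows the exact mass

P(y|x) = (N₂/N₁)^y · (x+y)!/(x!·y!) · (1+N₂/N₁)^−(x+y+1),

a negative binomial with x+1 successes and success probability
N₁/(N₁+N₂).  The exponent of the last factor is negative: that is the only
reading under which the masses sum to one, and the test suite asserts this
normalization directly.  The mass is evaluated in log space with
`scipy.special.gammaln`, so it is finite for counts beyond 10⁶.

Two-sided p-values are defined symmetrically: the one-sided tail for
enrichment in the stage library, P(K ≥ y | x; N₁,N₂), and the same tail
with the roles of the samples exchanged, P(K′ ≥ x | y; N₂,N₁); the
reported p is twice the smaller of the two, capped at 1.  This
construction is invariant under swapping (x, N₁) with (y, N₂) — a property
a two-library test should have, and one the naive "both tails conditioned
on x" definition lacks.  Tails are computed in closed form through the
regularized incomplete beta function, so there is no series truncation and
no truncation error to track.  One-sided modes are available
(`alternative="greater"/"less"`).

Because the design has no replication, the test captures counting
(sampling) noise only.  Biological variance between conditions is
absorbed into the fold-change threshold, not the p-value — the reason the
siRNA call combines p < 0.01 with |log₂FC| ≥ 1.  The type-I behaviour
under the null is checked empirically in the acceptance suite
(≈1% raw-p rate at the 0.01 threshold on 10,000 null features).

## Thresholds (defaults, all config-exposed)

| stage | parameter | default | rationale |
|---|---|---|---|
| catalog | tag length window | 18–30 nt | small-RNA size range after preprocessing |
| duplex | overhang geometry | +2/+2 offsets | canonical Dicer 2-nt 3′ overhang on both ends |
| duplex | support | > 5 raw reads (strict) | either tag, any library |
| duplex | minimum paired overlap | 15 nt | excludes degenerate short overlaps (disable with `min_overlap=None`) |
| siRNA DE | raw p / \|log₂FC\| | 0.01 / ≥ 1 | RPM with 0.5 pseudocount on both sides |
| gene DE | BH q / \|log₂FC\| | 0.001 / > 1 | same statistic, BH across genes per stage |
| methylation | BH q / signal / ratio | 0.05 / 0.25 RPM / 2 | ratio is direction-agnostic max(stage/CK, CK/stage), RPM floored at 0.01 |
| association | profile correlation | < −0.4 | Pearson on log₂(RPM+0.5) over the four libraries |
| scoring | penalty cutoff | 4.0 | mismatch 1.0, G:U 0.5, ×2 over guide positions 2–13 |
| clustering | k / restarts | 3 / 50 | k-means++ best-of-restarts, seeded |
| enrichment | raw p flag | 0.05 | BH q always reported alongside |

With n = 4 libraries the −0.4 correlation threshold is lenient (it is far
inside the null distribution of a 4-point Pearson coefficient); it is kept
as the pipeline's convention and documented rather than tightened.

Coordinates are 0-based half-open internally; GFF3 (1-based inclusive) is
converted exactly on read and write, BED is native.  The 24-nt exclusion
rule in the cleavage route considers DE 24-nt siRNAs by default;
`exclude_24nt="all"` widens it to every cataloged 24-nt tag.  Predicted
slicing positions follow the canonical geometry — the downstream
fragment's 5′ end sits opposite guide position 10 from the siRNA 5′ end —
and degradome confirmation requires the 5′-end count there to strictly
dominate every other position within ±20 nt, so flat or tied coverage
never confirms.

## The complementarity scorer

Target prediction uses a single in-repo, ungapped position-weighted
penalty scan (Allen-style weights: core doubling over guide positions
2–13, G:U wobble 0.5).  Gaps and bulges are not modeled and no
thermodynamic term is included; the association filter chain, not the
scorer, is the analytical core, and the cutoff is exposed.  With the
penalty cutoff at 0 the scanner provably returns exactly the
perfect-complement windows (property-tested against brute-force string
search).

## What the synthetic generator emulates

The generator reproduces the study *design*: one random genome
(default 300 kb) with non-overlapping gene models (30 nt 5′UTR, 99 nt CDS,
51 nt 3′UTR), structural-RNA intervals for subtraction, four libraries
(CK, I, II, III), duplex loci whose two tags satisfy the overhang
geometry by construction, near-miss pairs (3-nt overhang) and
single-stranded decoys for specificity, negative-binomial tag and gene
counts, and Poisson-with-lognormal-mean methylation signal.  Planted
links: cleavage-linked loci sit antisense in a target gene's CDS with
lengths 21/22 (so the 24-nt exclusion rule never fires on their genes);
methylation-linked loci are 24-nt duplexes in the 3′ UTR.  Linked genes
receive stage means anti-proportional to their siRNA (noiseless profile
correlation exactly −1) following three pattern archetypes — sustained up,
sustained down, transient up in Stage I.

Key defaults and why:

- `baseline_mean = 50` reads/tag/library, `library_sizes = 1e6` each: a
  modest clean-read depth with tags deep enough that the exact test has
  power at 4-fold changes.
- `dispersion = 0.001` (Var = m + 0.001·m²): pooled single libraries
  without biological replicates are dominated by counting noise, which is
  the regime the exact test models; the generator accepts any dispersion,
  and moment tests exercise larger values explicitly.
- `planted_lfc = 2` (4-fold), `ratio_planted = 4` for methylation: clear
  but not extreme effects.
- `region_baseline_mean = 50` RPM-scale counts: deep enough that a 4-fold
  *drop* (hypo-methylation) remains detectable after BH — at shallow
  region coverage the exact test is asymmetric in power between increases
  and decreases.
- `noise_sd = 0.05` lognormal scale on methylation means.

What it deliberately does not emulate: sequencing errors, adapters and
quality strings; multi-mapping ambiguity (planted tags are effectively
unique at these genome sizes); replicate variance; realistic genome
composition, repeat structure, or intron-containing gene models; ontology
structure in the annotation map.  Passing recovery tests therefore
demonstrates the correctness of the calling logic under the stated noise
model, not performance on real maize libraries.

## Numerical and engineering choices

- BH adjustment delegates to `statsmodels.stats.multitest.multipletests`
  behind `bh_adjust`; the test suite holds it equal to a literal step-up
  implementation.
- K-means uses scikit-learn (k-means++, `n_init` restarts, fixed
  `random_state`); clusters are relabeled by descending mean Stage-I
  feature so labels are stable across runs.
- Hypergeometric enrichment uses `scipy.stats.hypergeom`, held equal to an
  exact rational counting oracle for all backgrounds up to 15 genes.
- Profile correlation returns NaN when either profile has zero variance;
  NaN never satisfies the < −0.4 filter, so flat profiles drop out.
- All randomness flows from one seed through named
  `numpy.random.SeedSequence` child streams (genome, loci, srna, gene,
  methyl, degradome, annot), so adding a component does not perturb the
  draws of another.
- TSVs are reloaded with round-trip float parsing, so resumed stages
  reproduce byte-identical downstream outputs; the run manifest records
  per-stage output checksums and record counts.

## Problem sizes used in the test and acceptance runs

Unit and integration tests run on a reduced study (120 kb genome,
30 genes, 30 duplex loci, 9 cleavage + 6 methylation links).  The
acceptance checks use: the full default study (300 kb, 40 genes, 60 duplex
loci) for integration recovery; ten 50-kb genomes for brute-force duplex
equivalence; 10,500 features (500 planted, 10,000 null) for differential
recall and null calibration; 1,000 permutations × 10 terms for enrichment
calibration; and a 51×51 count grid × 3 depth ratios for the statistic's
rational-arithmetic oracle.

## Known limitations

- The exact test is anti-conservative if real libraries carry biological
  overdispersion; with replicates available, a negative-binomial GLM is
  the better tool and is out of scope here by design.
- The scorer's penalty scale is not calibrated against external target
  predictors; only its internal conventions are guaranteed.
- Methylation is modeled at region level (MeDIP-style counts), not at
  single-cytosine resolution.
- The K-means distance and initialization are documented choices, not a
  claim of equivalence to any particular historical clustering tool.
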