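# Methods

## Overview

`cpgrates` estimates human-branch dinucleotide substitution rates from
three-species intron alignments and relates their variation to germ-line
genomic covariates. The chain is:

1. filter triplet alignments (human, rhesus macaque, mouse) to introns with
   enough unambiguous sites;
2. fit a per-intron GTR model on the fixed ((human, rhesus), mouse)
   topology and reconstruct the human–rhesus ancestor marginally;
3. count CpG transitions/transversions and CpH transitions between the MAP
   ancestor and the human leaf, strand-resolved, by parsimony;
4. compute per-intron covariates (methylation, GC, CpG o/e, expression,
   recombination) and the A/B/C dataset classification from CGI/DHS
   annotation overlap;
5. fit binomial logit regressions with Z-scored covariates, OLS for the
   transition/transversion ratio κ, Spearman panels, and the
   X-vs-autosome one-way ANOVA on raw and covariate-corrected rates.

A context-dependent sequence simulator with methylation-modulated CpG
hypermutability generates every input with known ground truth, so each
stage is testable without external data.

## Substitution model and ancestral reconstruction

The nucleotide model is GTR: `Q_ij = s_ij π_j` with six symmetric
exchangeabilities `s` and stationary frequencies `π`, normalized so one
unit of branch length is one expected substitution per site at
stationarity. No within-intron rate variation is modeled. Because GTR is
reversible, the unrooted three-leaf star is rooted at the internal node —
the human–rhesus ancestor — without changing the likelihood; likelihoods
are computed by Felsenstein pruning over the 64 unambiguous site patterns
(columns with N or a gap in any species are excluded throughout).

Branch lengths (and, by default, exchangeabilities, with GT fixed at 1 as
the scale reference) are optimized per intron with L-BFGS-B in log space,
branch bounds [1e-8, 10], initialized from Jukes–Cantor-corrected pairwise
mismatch fractions via the three-point formula. `π` is set to the observed
base frequencies with a half-count pseudofrequency. Matrix exponentials
use the symmetric eigendecomposition of the `π^{1/2}`-similarity transform
of Q, which is stable for reversible matrices; the decomposition is cached
across branch-length iterations. Non-convergence is flagged on the result
(`converged` column), never silent.

Ancestral reconstruction is marginal: per column, the posterior over the
four ancestor states given all three leaves under the fitted model. The
MAP base (ties broken alphabetically, A < C < G < T) feeds the counting
stage, because the counting step compares a *called* ancestral sequence
with the human sequence; the full posterior is retained on the profile for
sensitivity analyses.

## Event counting

All overlapping ancestral dinucleotides with both positions unambiguous are
scanned. A CpG dinucleotide is self-complementary, so a C→T deamination on
either strand is a CpG transition: ancestral CpG with human TpG is
attributed to the coding (written) strand, human CpA to the non-coding
strand. Ancestral CpG with human ApG/GpG (C mutated) or CpC/CpT (G
mutated) is a CpG transversion. CpH transitions are ancestral CpH → human
TpH on the written strand plus ancestral DpG → human DpA on the opposite
strand (H ≠ G, D ≠ C); the CpH site denominator counts both context
orientations, so a CpH site carries one mutable cytosine while a CpG site
carries two. Dinucleotides where both positions changed cannot be oriented
by parsimony; they are excluded from events and tallied separately. Site
denominators always count the ancestral (MAP) sequence.

Non-CpG divergence masks both positions of every dinucleotide that is CpG
in *any* of the three leaf sequences, then counts MAP-ancestor/human
mismatches per remaining site. An outgroup-free counting estimator (sites
CpG in rhesus and TpG/CpA in human per rhesus CpG site) is provided as a
cross-check only.

Parsimony counting cannot see multiple hits. With a hypermutable CpG and a
long outgroup branch, many ancestral CpGs leave no CpG evidence in mouse,
which biases MAP reconstruction toward the derived state and *under*-counts
CpG events. The event-log tests quantify this: scanned counts are exact at
singly-hit, correctly reconstructed ancestral CpGs, and the pooled bias
shrinks when branch lengths shrink. Because the regression analyses model
*variation* in the rate, not its absolute level, a roughly proportional
underestimate does not change the sign structure of the slopes.

## Statistical layer

Rate responses are (events, sites) binomial pairs fit with a logit link by
IRLS (statsmodels GLM; convergence tolerance 1e-10). Covariates are
Z-transformed (mean 0, sample n−1 SD 1) so slopes are standardized.
Per-covariate p-values are two-sided Wald tests reported as −log10(p)
capped at 15.70, the double-precision floor near 2e-16. Explained deviance
is null minus residual deviance; the percentage version is the binomial
analogue of R². Variance inflation factors come from auxiliary OLS of each
covariate on the others. Rows with any missing covariate are dropped
listwise; the pipeline ledger records counts at every stage.

κ (CpG transition/transversion rate ratio) is modeled on its raw scale by
OLS over introns with positive transversion rate. The CpG-specific rate is
the response residual (observed minus fitted rate) of the five-covariate
binomial GLM. The sex-bias analysis is a one-way ANOVA of rates grouped by
chromosome, parameterized so the intercept is the X mean and each autosome
coefficient its difference from X. Gene-level concatenation sums event and
site counts across a gene's introns and recomputes covariates as
site-weighted means (methylation weighted by ancestral CpG-site counts).

Recombination covariates are log10(cM/Mb + 0.01), the offset admitting
zero rates; expression is the mean natural log of the three replicate
indices (log base configurable). CGI detection follows the Gardiner-Garden
criteria — 200-bp windows, step 1, GC ≥ 0.5 and CpG o/e ≥ 0.6, overlapping
qualifying windows merged and the merged region re-checked against both
thresholds — with the dialect parameters configurable. Intron
classification uses CGI/DHS interval tracks as given: A = neither,
B = DHS only, C = both, CGI-only introns are discarded.

## The simulator

Sequences evolve by an exact event-driven (Gillespie) process: single-
nucleotide GTR rates plus a CpG-context multiplier, with contexts
re-evaluated after every event, so there is no time-discretization bias.
The CpG transition multiplier is linear in the intron's methylation level
m: λ(m) = 1 + (λ_max − 1)·m, applied to C→T and, strand-symmetrically, G→A
in CpG context; transversions at CpG get a constant multiplier. An
asymmetric mode restricts the multipliers to the written-strand C, for
power checks of the strand-bias statistic. The kernel is JIT-compiled
(numba) with per-site rates, block partial sums for event sampling, and
periodic rebuilds of the partial sums to bound floating-point drift.
Event logs (site, time, from, to, context) are complete and replayable:
re-applying a log to the root must reproduce the leaf exactly, and this is
asserted in tests.

Root sequences are drawn at context equilibrium by burn-in from an i.i.d.
draw at the single-site stationary frequencies, because the
context-dependent stationary distribution has no closed form. Burn-in runs
3 expected substitutions/site, then extends in 10% increments until CpG
o/e changes by less than 2% (plus a three-binomial-SE sampling-noise floor
that governs short sequences, whose per-intron o/e is intrinsically noisy).

Default study conditions, chosen once to emulate the intron data the
analysis assumes:

| parameter | default | rationale |
|---|---|---|
| introns × length | 2,000 × 1,500 bp | introns pass the 1,000-site filter; acceptance-scale runs stay tractable |
| branch lengths (human, rhesus, mouse) | 0.020, 0.025, 0.35 | human-specific non-CpG divergence ≈ 0.02; distant rodent outgroup |
| λ_max | 12 | order-of-magnitude CpG transition elevation at full methylation |
| CpG transversion multiplier | 2 (methylation-independent) | mild elevation; κ then grows with methylation |
| methylation mixtures | A, B high/narrow Beta; C an even mixture of a low and a high component | CGI-containing introns show a much broader, bimodal methylation spread |
| GC targets | Beta around 0.40–0.47 by class | intronic GC range |
| rate scalar | lognormal, σ = 0.3, mean 1 | regional mutation-rate variation driving non-CpG divergence (CV ≈ 0.3) |
| GC effect on log rate | −2 per GC unit | thermodynamic-stability-style negative GC–rate link |
| dataset weights | A 0.337, B 0.560, C 0.100, discard 0.003 | observed A/B/C intron proportions |
| male bias α | 1 (off); X/A branch scale 2(2+α)/(3(1+α)) when on | standard male-driven replication bias |

Methylation windows are 100-bp, grid-aligned, fully contained in the
intron, with the true intron methylation plus Gaussian noise (SD 0.05),
true CpG counts from the human sequence, and 10% of windows dropped to
exercise the ≥ 5-window filter. CGI/DHS interval tracks are emitted
consistent with the class labels; expression tables carry three replicate
indices whose log-mean is the gene's true level; female/male recombination
rates fill 1-Mb windows.

What the simulator does *not* emulate: isochore structure, repeats, CpG
island birth/death (so equilibrium CpG o/e is lower than in real genomes,
where CpG content is not at mutational equilibrium), selection, indels
(alignments are gap-free by construction; gap handling is tested on hand
fixtures), and correlated female/male recombination. Passing tests
demonstrate the estimators recover the planted structure under these
idealized conditions; they do not certify behavior under alignment error
or selection.

## Test problem sizes and power-check conditions

Event-log exactness and the regression sign structure are checked at 2,000
introns × 1,500 bp (20 replicates for the regression criteria); GLM
calibration uses 500 null replicates at n = 1,000. The strand-bias power
check uses 200 × 10-kb introns at full methylation with a shorter tree
(human 0.06, rhesus 0.01, mouse 0.10): with the realistic long mouse
branch, multi-hit loss of ancestral CpGs plus symmetric reconstruction
errors dilute the per-intron strand difference toward zero, so the shorter
tree is the regime in which the statistic has power — the symmetric
control is run under the same conditions. The male-bias check similarly
uses λ_max = 6 and 4-kb introns so that per-intron CpG site counts give
the ANOVA contrasts adequate power. These choices are power-analysis
conditions, not claims about the biological magnitudes.

## Numerical choices

- Argmax ties in MAP calls broken alphabetically; deterministic.
- Optimizer restarts (up to 2) from a jittered start when the first
  L-BFGS-B run fails; the best solution is kept and flagged.
- Pattern likelihoods floored at 1e-300 before logs; transition-matrix
  rows clipped to [0, 1] and renormalized after eigen-reconstruction.
- Binomial GLM quasi-separation flagged when any |slope| > 25 on the Z
  scale.
- All randomness flows from one `numpy.random.Generator` seeded by the
  study seed; kernel calls draw 31-bit subseeds from it, so every artifact
  is byte-reproducible for a fixed seed.

## Known limitations

- Parsimony counting underestimates absolute CpG rates at realistic
  primate–rodent distances (quantified above); analyses of rate
  *variation* are the supported use.
- Per-intron GTR fits on ~1.5-kb introns have noisy exchangeabilities;
  fixing them (`fit_exchangeabilities=False`) is faster and is the setting
  used for the large simulation studies.
- The strand-bias interval is an empirical percentile interval of the
  per-intron standardized difference d = (n_c − n_nc)/(n_c + n_nc); only
  its covering/excluding zero is interpreted.
- CpH transition counting attributes a change only when the partner base
  is conserved; double changes in CpH context are ignored rather than
  tallied.
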