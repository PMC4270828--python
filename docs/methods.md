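# Methods

## Model

A subject is described by six genotypes g ∈ {0,1,2}⁶ at the loci TF1, TF2,
enhancer, promoter, coding and microRNA, and an environment value
e ∈ {−2,…,2}. Liability is the deterministic fold of these values through
six function slots in the fixed wiring

r1 = f1(TF1, enhancer), r2 = f2(r1, TF2), r3 = f3(r2, promoter),
r4 = f4(r3, coding), r5 = f5(r4, microRNA), X = f6(r5, environment).

All inputs are mutually independent. Genetic loci default to Hardy-Weinberg
genotype probabilities at equal allele frequencies (0.25/0.5/0.25); each
locus's distribution is configurable (per-SNP minor allele frequencies give
(1−q)², 2q(1−q), q²). The environment defaults to the uniform distribution
on {−2,…,2}; nothing in the framework pins this choice, but it reproduces
the reference additive model's published information gain and MDR accuracy
almost exactly, which is strong evidence the original prototype used it.

## Function semantics

The 25 slot functions are total maps ℤ×ℤ→ℤ. Names only are fixed by the
framework; exact semantics here are:

- ADD/SUB/MULT as usual; DIV is truncated (toward-zero) integer division
  with x/0 = 0; MOD is the remainder with the sign of the divisor, x mod 0
  = 0; MOD2 is (a+b) mod 2.
- GT/LT are indicators; AND/OR treat any non-zero operand as true and
  return 0/1.
- **XOR is arithmetic parity, (a+b) mod 2, identical to MOD2.** A
  truthiness XOR (1 iff exactly one operand non-zero) would give the
  genotype distribution P(out=1 | one genotype known) ∈ {0.25, 0.75} — a
  strong main effect — whereas the defining property of the XOR models in
  this framework is that a single variant carries *no* information about
  the output. Parity delivers exactly that: for HWE genotypes, parity of a
  single genotype is an exact 50/50 coin, so (a+b) mod 2 is independent of
  either operand alone yet determined by both. Under this reading the four
  published parity-headed reference models (XOR,XOR / MOD2,XOR / BITX,XOR /
  BITX,MOD2) collapse to the same liability law — consistent with their
  published accuracies being statistically indistinguishable.
- BITA/BITO/BITX are two's-complement bitwise and/or/xor.
- ABS, NOT (bitwise complement, −(a+1)), FAC and LOG are unary in the left
  operand and ignore the right, consistent with LEFT/RIGHT being operand
  selectors (LEFT returns a, RIGHT returns b). FAC returns 0 for negative
  arguments and saturates above 12!.
- POW is a^b for b ≥ 0 (0⁰ = 1), 0 for negative exponents; LOG is
  floor(log₂|a|) for |a| ≥ 1, else 0; PER and CHS are the falling factorial
  a!/(a−b)! and binomial coefficient C(a,b) for 0 ≤ b ≤ a, else 0;
  MIN/MAX as usual.
- Every result saturates at the 32-bit two's-complement range
  [−2³¹, 2³¹−1]. This bounds chained FAC/POW growth, keeps liability
  supports finite and small, and makes every function total: no arithmetic
  error can escape a model evaluation.

## Exact liability and the disease threshold

The liability distribution is computed exactly two ways — folding the
pushforward P(f(A,B)=x) = Σ_{f(u,v)=x} P(u)P(v) along the chain, and
enumerating all 3⁶·5 = 3,645 input combinations with product weights — and
the two routes are required to agree to 1e-12 in tests. Tail probabilities
are computed as suffix sums from the top of the support to avoid
cancellation error.

Disease is the upper tail, X ≥ t. The default threshold rule is the
discrete upper quantile: the largest support value t with P(X ≥ t) ≥
target, i.e. the achieved prevalence is the smallest attainable value not
below the target. The alternative rule `mode="closest"` (support value
whose tail is nearest the target, ties toward the smaller prevalence) is
also provided. The quantile rule is the package default because it is the
convention under which the reference parity models reproduce their
published three-way interaction information; for the additive reference
model the two rules coincide. Degenerate (single-point) liability
distributions admit no two-class split and raise an error.

## Simulation

Populations are drawn i.i.d. from the locus distributions; liability is
evaluated through a precomputed 3,645-entry lookup table; case status is
liability ≥ t with t selected beforehand on the exact distribution, never
re-estimated from the sample. Cases and controls are sampled without
replacement within class (population-then-sample reproduces the
finite-population variability of a real study; requesting more cases or
controls than the population produced is an error reporting the achieved
counts). The environment contributes to liability but is not exported —
datasets contain only the six functional genotype columns, as if the
exposure had not been measured, plus optional noise SNPs: genotypes drawn
under HWE at a minor allele frequency uniform in a user range,
independent of status. Datasets are written as MDR-format tab-delimited
text (variant columns plus a final `Class` column, 0 control / 1 case);
reading validates genotype and class ranges with line numbers. Replicate
datasets use the seed sequence seed, seed+1, ….

## Interaction metrics, MDR and permutation tests

All information quantities are plug-in estimates in bits from empirical
contingency tables. Pairwise interaction information is
IG(A;B;Y) = I(A,B;Y) − I(A;Y) − I(B;Y), and the pure three-way interaction
information subtracts all one- and two-way terms from I(A,B,C;Y). Plug-in
estimates are upward-biased at finite n (roughly (cells−1)/(2n ln 2) per MI
term); with n = 2,000 and 27 genotype cells the three-way IG of truly
additive data sits near +0.005 rather than 0. The tests therefore check
additive-model IG against a small band rather than zero, while the
noiseless parity fixture — 27 genotype combinations replicated with HWE
multiplicities (64 rows), class = (A+B+C) mod 2 — is exactly balanced by
construction and must give main and pairwise IG of exactly 0 and three-way
IG of exactly 1 bit.

MDR labels a genotype cell high-risk iff (cases in cell)/(controls in cell)
≥ overall case:control ratio, with ratio ties high-risk and empty cells
low-risk (no evidence ⇒ baseline); subjects in high-risk cells are
predicted cases. Reported accuracy is training accuracy on the full
dataset — on balanced null data the 27-cell fit overfits to ≈ 0.55 rather
than 0.5, and training accuracy can never fall below the majority-class
rate. Optional cross-validation is deliberately not the default since the
reference quantities are training-accuracy-like.

Both permutation tests use the add-one estimator
p = (1 + #{permuted statistic ≥ observed}) / (n_perm + 1) with MDR accuracy
as the statistic and 1,000 permutations by default. The standard test
permutes status labels. The explicit test of epistasis instead shuffles
each variant's genotype column within cases and within controls separately,
preserving every marginal genotype-status association exactly while
destroying inter-variant structure. Two behaviours are worth noting. First,
the add-one estimator is mildly conservative when the observed accuracy
ties permuted accuracies (accuracy lives on a 1/n grid), so null p-values
are only approximately uniform; the uniformity check in the tests uses
1,000 subjects, where the artifact is small. Second, data simulated from
the *all-additive chain* is not null for the explicit test: thresholding an
additive liability induces real (if small) two-way interactions on the
case-control scale, so the explicit test on such data is usually
significant — matching the marginal-to-significant published p-values of
the additive and multiplicative reference models. A genuinely null case for
the explicit test requires penetrance that depends on one locus only, which
is how the tests construct it.

## Search

Candidates are 30-bit strings, five bits per slot decoded modulo 25, so
decoding is total; the canonical function order fixes the index map. The
modulo decoding makes indices 0–6 slightly more likely (7/32 vs 6/32 per
5-bit field) — accepted and documented. Fitness builds the decoded model,
selects the threshold at the configured prevalence, simulates one
case-control dataset (defaults: 1,000/1,000 from 100,000 at prevalence
0.10), and returns the three-way IG of (TF1, TF2, enhancer). Fitness is
deliberately stochastic — each evaluation consumes a fresh sub-seed from
the master stream, as when each candidate is judged by a single simulated
study — and the hall of fame stores realized fitness. Models whose
liability collapses to a point, or which cannot supply the requested
numbers of cases and controls at their achievable prevalence, receive
fitness −inf.

The genetic algorithm is generational with tournament-2 selection, uniform
crossover (rate 0.9), per-bit mutation (rate 1/30) and elitism 1; elites
are carried unchanged with their stored fitness, all varied offspring are
re-evaluated, and total evaluations never exceed population_size ×
generations. With elitism ≥ 1 the best-so-far trace is non-decreasing.
These operator choices are standard for 30-bit encodings and are all
configurable; nothing in the framework prescribes them.

## Problem sizes used by the tests and acceptance script

The acceptance script and the table-reproduction tests run at the study
scale (1,000/1,000 from 100,000; medians over 5 seeds; ~1 s per
configuration). The GA acceptance test uses population 50 for 30
generations with a reduced fitness dataset (500/500 from 20,000), which
preserves the ordering of epistatic vs additive fitness while keeping the
run to a couple of minutes; unit tests of search mechanics use smaller
budgets still. The null-uniformity check uses 200 replicates of 199
permutations at 500 cases/controls.

## What the generator does and does not emulate

The generator reproduces i.i.d. genotypes under HWE, exact liability
thresholding, balanced retrospective sampling, and unlinked noise SNPs. It
does **not** simulate linkage disequilibrium, haplotype structure,
population stratification, genotyping error or missingness — variants are
independent by construction, so passing tests say nothing about robustness
to correlated markers. Effect sizes of the built-in models are moderate to
large (single-gene scaffold, unscaled 0/1/2 coding); realistic common-
disease effect sizes would need genotype recoding or function-level
coefficients, which the framework does not currently include.

## Known limitations

- The published Model 8 configuration (CHS, BITA head) does not reproduce
  its published row under any operand convention tried; it was discovered
  by a search whose full configuration is not recoverable from the two
  printed function names. The eight-model accuracy extrema are insensitive
  to this (Model 8 is interior to the range both here and as published).
- Three-way IG of the parity reference models is compared against
  published values that are themselves single stochastic draws of the same
  statistic; the package's medians sit inside the published spread but not
  within a tight band of every individual draw.
- Liability supports stay small for the built-in scaffold, but saturation
  means extreme function chains (nested FAC/POW) pile probability mass at
  ±2³¹−1; such models are valid but scientifically uninteresting.
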