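# Methods

## Model and assumptions

All quantities are probabilities for a two-locus haplotype drawn from a
multiparent population, as functions of the meiotic recombination
fraction `r ∈ [0, 1/2]` between the loci and the generation number `s`.
The generative model assumes

* an effectively infinite number of mating pairs at each generation
  (so haplotype frequencies evolve deterministically, and the two
  haplotypes of an individual are independent from the first generation
  at which its parents are unrelated);
* no sex difference in recombination, no selection, no mutation, no
  crossover interference within the two-locus gamete model (each
  parental haplotype is transmitted intact with probability `(1-r)/2`,
  each recombinant combination with probability `r/2`);
* for the eight-way designs, complete balance of funnel orders: every
  founder is equally likely to occupy every funnel position, making the
  eight intact haplotypes exchangeable and the 56 recombinant haplotypes
  equally likely.

Under founder exchangeability all tables are determined by the `AA`
frequency; the recombinant mass is `1 - 2·AA` (two founders) or
`1 - 8·AA` (eight).  The only non-exchangeable case is the unbalanced
AIL X (all F1s from female A × male B), where the full 2×2 table is
reconstructed from the AA entry and the sex-specific allele frequency
`q_s = 2/3 + (1/3)(-1/2)^s` (females; males carry `q_{s-1}`; the
pre-cross boundary is `q_{-1} = 0`).

## Recurrences and their anchors

The coupled male/female X recurrence

```
m_{s+1} = (1-r) f_s + c_m      f_{s+1} = m_s/2 + (1-r) f_s/2 + c_f
```

shares its homogeneous matrix `T = [[0, 1-r], [1/2, (1-r)/2]]` across
all designs; its eigenvalues are `w, y = (1-r ± z)/4` with
`z = sqrt((1-r)(9-r))`.  Closed forms are obtained by eigendecomposition
(fixed point plus `A w^n + B y^n`), never by transcribing printed
formulas, and the recurrence is always the reference path; the two are
tested to agree at 1e-12.  At `r = 0`, `T` has eigenvalue 1 and no
unique fixed point, so the closed-form path falls back to plain
iteration there.

A point that is easy to get wrong: the recombinant source terms (`r/4`,
`r/64`, ...) assume the transmitting parent's two chromosomes carry
independent founder alleles.  That is false for F1 hybrids, whose
haplotypes are the perfectly correlated `AA` and `BB` — a recombinant F1
gamete is never `AA`.  The AIL recurrences therefore apply from `s = 2`
onward, anchored at the exact first-meiosis values `p_2 = (1-r)/2`
(equivalently, the classic result that the F2 recombinant fraction
equals `r`), and on the balanced X at `m_2 = (1-r)/2`,
`f_2 = (2-r)/4`.  The unbalanced X needs no special anchor because its
source term `r·q_0·q_{-1} = 0` vanishes at the F1 step, and the DO/HS
recurrences hold from `s = 1` because progenitor lines are independent.

## Pre-CC chains (DO/HS initialisation)

The DO is founded from pre-CC mice at sib-mating generations G2:F_k with
user-supplied weights α_k (HS: α_1 = 1).  Their haplotype frequencies
are computed by exact propagation of a Markov chain over sib-pair
two-locus genotype configurations, starting from the founding mating
pair of the eight-way funnel, with meiosis applied transition by
transition.  On the autosome the state is lumped by founder-label
permutation, individual order, and within-individual chromosome order —
all true symmetries of the dynamics — leaving 671 canonical states; the
lumping is unit-tested against an unlumped propagation.  On the X the
state is (female maternal X, female paternal X, male X) over the five
founder roles visible to an X in an eight-way funnel, with no lumping.
Transition rows are cached as exact monomial counts in `(1-r)^a r^b`, so
each `r` reuses the same structure.

Key exact outputs (all verified against hand derivations and forward
simulation): `q_1 = (1-r)^2/8`, `q_2 = (1-r)^3/8` (the transmitted
gamete of an eight-way G2:F1 individual has passed three fully
heterozygous meioses — hence the HS map expansion `M_1 = 3`), and on the
X the G2:F1 progenitor frequencies `m = (2-3r+r^2)/16`,
`f = (4-5r+r^2)/32`.

### X initialisation convention

Two conventions are possible for "generation 1" on the X: the
progenitor-generation frequencies above, or the frequencies in the first
outcross offspring (one maternal meiosis deeper, with the paternal X
transmitted intact).  The autosomal initialisation `p_1 = Σ α_k q_{k+1}`
uses the transmitted gamete, so this package uses the outcross
convention on the X as well:

```
m_1 = Σ_k α_k · P(gamete of a G2:F_k dam is AA)
f_1 = Σ_k α_k · [that + P(G2:F_k sire X is AA)]/2
```

For HS this gives `m_1 = (1-r)^2 (4-r)/32` and
`f_1 = (1-r)(8-7r+r^2)/64`.  Note the first outcross meiosis is *not*
`(1-r) f + r/64`: a progenitor dam's two X's carry founder alleles of a
single funnel, so the within-funnel recombinant term differs from the
random-mating one; the chain computes it exactly.  Three independent
checks select this convention: (i) it makes the X map expansion exactly
2/3 of the autosomal value at every generation (the per-generation
identity `(7s+17)/12` vs `(7s+17)/8` holds exactly for all s), whereas
initialising with the progenitor-generation forms breaks that ratio
(4/3 vs 2 at s = 1); (ii) the forward simulator reproduces the outcross
values to within Monte-Carlo error and excludes the alternative by ~50
standard errors; (iii) the two conventions coincide as they must at
r = 0.  The progenitor-generation frequencies remain available as
`precc_x_progenitor_freqs`, and the classical weighting identity
`f_prog = [(2-r)·h^AA + (1-r)·h^CC]/8` linking them to the four-way
sib-mating X frequencies (`precc_x_freqs`) is verified exactly for all
tested k, not just k = 1.

## Map expansion

Defined as `dR/dr` at `r = 0` for the recombinant-haplotype frequency
`R(r)`.  Closed forms: AIL autosome `s/2` and balanced X `s/3` (valid
from `s = 2`; an F1 chromosome has passed through no meiosis, so the
value at `s = 1` is 0); HS autosome `(7s+17)/8` with `M_1 = 3`; DO
autosome `(7/8)(s-1) + M_1(α)` with `M_1(α)` computed numerically from
the chain; X always 2/3 of the autosome.  The superseded HS assumption
`(7/8)(s+2)` is kept as `hs_map_expansion_legacy`; the corrected value
exceeds it by exactly 3/8 at every `s`.

For the unbalanced AIL X, differentiating the haplotype recurrences
gives the exact recurrence
`M'_{s+1} = M'_s + (4/3)(q_s − q_{s-1} q_{s-2})`, `M'_1 = 0`,
`M'_2 = 2/3`.  The derivation shows `M'_s` is the *overall* map
expansion (2/3 female + 1/3 male weighting, since two-thirds of X
chromosomes are in females); this is confirmed numerically against
per-sex and overall derivatives.  The per-generation increment tends to
`(4/3)(2/3 − 4/9) = 8/27`, below the balanced 1/3, because unequal
allele frequencies (2/3 : 1/3) hide a fraction of crossovers.

Numerical derivatives use forward differences with one Richardson
refinement at steps 1e-6 and 5e-7 (R is defined only for r ≥ 0), and
agree with closed forms to 1e-4 across the test grid.

## Independent verification paths

* **Full-table propagator** (`propagate_exact`): evolves whole
  n×n haplotype tables per sex using only marginalisation and the gamete
  mixture `G = (1-r)(T1+T2)/2 + (r/2)(u1⊗v2 + u2⊗v1)`; written
  independently of the scalar recurrences and required to agree with
  them to 1e-12 on every entry — the main defence against algebra and
  transcription errors.
* **Forward Monte-Carlo** (`simulate_freqs`): simulates the actual
  breeding designs (funnels with per-line random founder permutations,
  sib mating, random-mating populations with sexes tracked on the X),
  pooling 16 independent replicate populations with 200,000 counted
  gametes by default.  Standard errors come from the replicate spread:
  chromosomes within one finite population share genetic drift, so the
  naive binomial SE understates the sampling variance (by roughly 2× at
  s = 10), whereas replicate-based SEs are calibrated (checked across 40
  seeds).  Finite-population inbreeding bias is O(s/N), well below one
  SE at the default sizes.  Twelve conditions spanning every design and
  chromosome agree with the analytic values within 3 SE.

What the simulator does *not* emulate about real populations: finite
numbers of mating pairs in the actual colonies (inbreeding and sibship
structure at the final generation), overlapping generations in the real
DO, crossover interference, and sex-specific recombination maps.
Passing tests therefore validate the mathematics under the stated
idealisation, not those finite-population effects.

## Parameters and defaults

* `r` — recombination fraction per meiosis, unitless in [0, 0.5]; both
  endpoints are legal everywhere (no division by zero: normalisations
  like `(1-8p)/56` are plain arithmetic).
* `s`, `k` — generation indices, ≥ 1 (`s = 1` is the F1 for AIL and the
  first outcross generation for DO/HS; `k` counts pre-CC sib-mating
  generations, G2:F1 being the eight-way cross offspring).
* `α` — DO progenitor weights; must be non-negative and sum to 1
  (1e-12 in the API; JSON input is accepted at 1e-6 and renormalised).
  `example_alpha()` (uniform on k = 4..8, mean 6) is an illustrative
  stand-in only — the real DO progenitor distribution is not shipped and
  should be supplied by the user.
* `n_gametes = 200_000`, `n_replicates = 16` in the simulator: gives
  ~0.1–0.3% standard errors, small enough to separate every design
  contrast tested while keeping the full verification sweep at a few
  seconds.
* Map functions: Haldane `r = (1 − e^(−2d))/2` (default, matches the
  interference-free model) and Kosambi, for converting cM positions to
  interval `r`.

## Numerical conventions and degenerate inputs

Probabilities are double precision; chain probabilities are exact up to
rounding (conservation to 1e-12 is asserted in tests).  Closed forms vs
recurrences: 1e-12; allele-frequency closed form: 1e-14; convergence
tests iterate to s = 1000–1500 with tolerances 1e-8–1e-10 (r > 0
required; at r = 0 the limits do not apply).  Tables validate
non-negativity and unit mass at 1e-12 on construction.  Transition
matrices are emitted together with their locus-1 founder distribution
because on the unbalanced X both are sex-specific and must not be mixed.

## Known limitations

* Two loci only; no three-locus or interference modelling.
* Haplotype-level (not diplotype-level) transition matrices — adequate
  under the large-population independence assumption.
* The DO pedigree idealisation above; exact finite-population
  corrections are out of scope.
* The unbalanced AIL X has no closed form (recurrence only), matching
  the state of the theory.
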