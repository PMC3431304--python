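# Methods

## Model

Hosts, symbionts and parasites are haploid with one biallelic locus each;
hosts and parasites reproduce asexually and symbionts are maternally
inherited, so a host and its symbiont state form a single transmissible
unit, the *association*.  Six associations (H1∅, H1S1, H1S2, H2∅, H2S1,
H2S2 — this canonical ordering is fixed everywhere, including serialised
files) face two parasite genotypes.  Populations are infinite: the state is
a frequency vector `f` on the 6-simplex and `q` on the 2-simplex.

All genetics enters through the 6×2 **master matrix** `M`, whose entry
`m[a][p] ∈ [0,1]` is the degree of resistance of association `a` to
parasite `p` (`m = 0.8` means the host suffers only 20% of the maximal
potential damage).  Fitness matrices derive from `M` and three parameters:

    wH[(i,s)][p] = (1 − s_H·(1 − m[(i,s)][p])) · (1 − c·1[s≠∅])
    wP[p][(i,s)] = 1 − s_P·m[(i,s)][p]

`s_H = 1` means parasites can sterilise or kill fully susceptible hosts;
`s_P` is the penalty for failing to infect; `c` is the physiological cost
of carrying symbionts, applied multiplicatively to symbiont-bearing rows
only, so a fully resistant symbiont-free host has fitness exactly 1.  With
`c = 0` and `s_H = s_P = s`, `wH + wPᵀ ≡ 2 − s`: the two species'
fitnesses are fully anti-correlated.  The exact algebraic form is a
reconstruction (the displayed equations in the source material are images);
it is the unique simple form consistent with every printed worked example,
and is validated as such in the test suite.

### Generation cycle

Each generation applies, in this order:

1. **Horizontal transmission** — symbionts colonise symbiont-free hosts by
   mass action: flux from (i,∅) to (i,s) is `τ·f[(i,∅)]·F_s`, with `F_s`
   the total frequency of carriers of symbiont allele s regardless of host
   background.  Acquisition preserves the host allele; infected hosts are
   never superinfected.  If `τ·(F_S1+F_S2) > 1` the flux is capped
   proportionally (with a warning); at the default rates this never occurs.
2. **Selection** — simultaneous discrete replicator update:
   `f'ₐ ∝ fₐ·Σ_p wH[a][p]·q_p` and `q'_p ∝ q_p·Σ_a wP[p][a]·fₐ`, both
   using the antagonist's pre-selection frequencies; the normalising
   denominators are the mean host and parasite fitnesses recorded in the
   trajectory.
3. **Symbiont loss** — a constant fraction `1 − v` of symbiont-bearing
   hosts loses the symbiont and joins the matching symbiont-free class.

The recorded state is post-loss.  Both simplices are conserved to 10⁻¹²
after every sub-step (tested).  The dynamics are fully deterministic;
randomness enters only through matrix generation and initial frequencies.

### Parameters

| parameter | meaning | default grid |
|---|---|---|
| `s_H` | maximal selection on hosts | 0.2, 0.5, 1.0 |
| `s_P` | maximal selection on parasites | 0.2, 0.5, 1.0 |
| `c` | cost of harbouring symbionts | 0.05, 0.2, 0.5 |
| `v` | vertical-transmission fidelity | 0.99, 1.0 |
| `τ` | horizontal-transmission basal rate | 0, 0.01 |

The 3×3×3 fitness grid gives 27 fitness pairs per master matrix; crossing
with the 2×2 transmission values gives 108 models.  The grid *structure* is
fixed by the study design; the *values* are reconstructions (the printed
table is an image) chosen to span weak-to-maximal selection and
cheap-to-prohibitive cost.  The `APHID_WASP_PRESET`
(s_H=1.0, s_P=0.5, c=0.05, v=0.99, τ=0.01) loosely matches
defensive-symbiont aphid–parasitoid systems: parasitoids kill, symbionts
are cheap, maternal transmission is near-perfect, lateral transfer rare.

A parameter combination is **trivial** when `c ≥ s_H`: the symbiont's cost
then reaches the worst damage parasites can inflict, protection can never
pay, and (with rare horizontal transfer) symbionts go extinct — proven
empirically for random matrices in the tests.  Trivial combinations are
flagged and excluded from summaries by default.  The boundary `c = s_H` is
classified trivial, since the cost can then never be strictly outweighed.

## Specificity

An interaction matrix is *specific* when reaction norms cross: genotypes
`x₁, x₂` of one species and `y₁, y₂` of the other exist with `x₁` better
adapted than `x₂` to `y₁` but worse to `y₂` — on either axis (host-side or
parasite-side crossings both count; this keeps the index invariant under
transposition).  Non-specific matrices are exactly those whose rows *and*
columns each form a chain under coordinatewise weak dominance, i.e. those
that some row and column permutation makes monotone along both axes.  Ties
never count as crossings.

The **index** is the minimal entrywise-L1 disturbance onto the
non-specific set.  Design choices:

- *Norm*: L1 is isolated behind one solver; it makes the 2×2 index range
  exactly [0,1] for entries in [0,1], attained only at the MA matrix and
  its mirror image, with GFG at 0 — the stated extremal behaviour.  For a
  2×2 matrix the closed form is the larger of the two axis costs
  `min(|d₁|,|d₂|)·1[d₁d₂<0]` (rows) and the analogous column term; each
  axis's crossing must be cancelled and the larger cost always suffices
  (validated against the exact solver on hundreds of random instances).
- *General matrices*: the exact solver enumerates row/column orders (up to
  4 000 order pairs, covering all matrices up to 4×5 and most beyond) and
  solves an LP projection onto each doubly-monotone cone with HiGHS at
  10⁻¹⁰ feasibility tolerance; beyond the enumeration limit a sorted-order
  neighbourhood search is used and the result flagged as an upper bound
  (`converged=False`).  Perturbed matrices are not constrained to [0,1]:
  for L1 the optimum never needs to leave the box when the input is inside
  it, so the relaxation is free.
- *Oracle*: an exhaustive search over grid-valued matrices provides
  independent lower/upper bounds (grid-rounding preserves dominance, so the
  bracket width is `m·n·step/2`); for inputs already on the grid the grid
  minimum is exact.

The master matrix is scored through three 2×2 projections, each averaging
out one species.  The host–parasite (HP) projection averages over all
*three* symbiont states — symbiont-free hosts are associations in their own
right — with the two-state variant available behind
`include_symbiont_free=False`; the SP and HS projections average over the
two host alleles and two parasites respectively and are necessarily 2×2
over symbiont alleles.

## Random-matrix ensembles

Entries are sampled i.i.d. either uniformly on [0,1] (i.u.d.) or from a
symmetric bimodal density with modes at 0 and 1.  Every matrix is subject
to whole-matrix rejection until the **protection constraint** holds —
`m[(i,s)][p] ≥ m[(i,∅)][p]` for all i, s, p (symbionts never impair innate
resistance).  Under i.u.d. entries, each of the four (host, parasite) cells
independently requires its symbiont-free entry to be the minimum of three
uniforms, so the acceptance probability is (1/3)⁴ = 1/81 ≈ 0.0123
(Monte-Carlo-verified).  Whole-matrix rejection (rather than conditional
resampling of symbiont rows) is the simplest distributional reading of the
constraint and is documented as such.

The stratified builder fills ten specificity bins of width 0.1 with a fixed
number of matrices each, classifying each accepted draw by the index of its
target projection (HP or SP): bins [0,0.1) through [0.6,0.7) from the
i.u.d. sampler, the top three bins from the bimodal sampler (i.u.d.
sampling essentially never produces high-specificity matrices: their
entries must be polarised and strongly interdependent).  Bins are half-open
with [0.9,1.0] closed; a draw budget (default 10⁸) makes unreachable bins
fail loudly instead of hanging.

The bimodal density is a mixture: weight 0.9 uniform on [0,0.1]∪[0.9,1]
plus weight 0.1 uniform on [0,1] (density 4.6 on the mode intervals, 0.1
between).  The uniform floor is not cosmetic: with support confined to the
mode intervals, SP-projection entries (averages of two entries) can never
produce index values inside (0.55, 0.8), which would make the [0.7,0.8)
bin unreachable.

What the generator emulates — and does not.  The ensembles cover the space
of *protective* genetic architectures approximately uniformly in one
specificity coordinate; they are not calibrated to any empirical
distribution of resistance matrices, entries are independent (real
architectures are structured), and population sizes are infinite.  Passing
ensemble-level tests therefore demonstrates properties of the model class,
not of any particular biological system.

## Outcome classification

All computed on the assessment window (generations 10 000–20 000 of a
20 000-generation run; both run length and the 50% burn-in are defaults of
`SimParams`):

- **Loss**: an association is lost if its window-mean frequency is below
  10⁻³ (strict); an allele survives iff the summed frequency of classes
  carrying it meets the same threshold — one coherent cutoff, even though
  the source defines it only for associations.
- **Cycling**: some association series has ≥6 local extrema whose
  amplitudes do not decrease.  Extrema are strict sign changes of first
  differences, ignoring steps ≤10⁻⁶; "does not decrease" is
  mean(last 3 amplitudes) ≥ 0.999·mean(first 3), robust to floating-point
  ripple on neutral cycles.  The detector is insensitive to trajectory
  thinning up to 5× on smooth signals (tested).
- **Ambiguity**: each model is run under 10 random initial frequency
  vectors (symmetric Dirichlet(1) on both simplices — the uniform
  distribution on the simplex; seeds derived per run from the global seed)
  plus one equal-frequency run used for evaluation.  A model is ambiguous
  when the 11 discrete outcome tuples (surviving associations, surviving
  parasite alleles, cycling flag, degeneracy) are not all identical —
  a categorical, not numerical, comparison.
- **Degeneracy**: a mean fitness of exactly zero (possible when `s_H = 1`
  or `s_P = 1`) freezes the run and is recorded as its own outcome class,
  never a crash.

Analysis summaries use eleven bins: bin 0 holds exactly the non-specific
matrices (index = 0), bins 1–10 cover (0, 1] in steps of 0.1.  This is
deliberately distinct from the ten half-open *sampling* bins above.

## Numerical choices

- **Frequency floor**: frequencies below 10⁻³⁰⁰ are clamped to zero and the
  simplex renormalised.  The floor sits just above the subnormal range
  because discrete-generation Red Queen oscillations grow in amplitude and
  legitimately visit astronomically small frequencies before recovering; a
  higher floor (e.g. 10⁻¹⁵) converts sustained canonical MA cycles into
  spurious fixations.
- **Batched engine**: ensemble sweeps advance all runs in lock-step with
  vectorised numpy and accumulate window means and extremum/amplitude
  statistics online, so no trajectory is ever materialised; the scalar
  trajectory path and the batched path are asserted equivalent in the test
  suite (window means to 10⁻¹², extremum counts exactly).
- **Determinism**: identical seeds give bit-identical ensembles,
  trajectories and outcome tables; per-run seeds derive from
  `SeedSequence([seed, matrix, combo, run])`, so results are independent of
  chunking and execution order.

## Canonical MA/GFG study

Innate resistance follows MA (host i resists parasite i) or GFG (H1 resists
the avirulent P1 only; H2 resists nothing); symbiont s grants resistance δ
against parasite s where innate resistance is absent, combined as
max(innate, granted) — protection matters only where innate resistance is
missing, and entries stay in [0,1].  The study runs under perfect maternal
inheritance (v=1) and no horizontal transfer (τ=0), with defaults
δ ∈ {0.2,…,0.8}, c ∈ {0,…,0.4} and s_H = s_P = 0.5.  Two defaults deserve
comment:

- *Initialisation*: the equal-frequency start lies on the invariant
  symmetric manifold of these exactly symmetric matrices, on which
  antagonist frequencies never move; the canonical study therefore uses a
  seeded random start, as trajectory studies of these models do.
- *Selection strength*: at s_H = 1 fully susceptible symbiont-free hosts
  reach literal zero fitness whenever one parasite fixes, and are
  annihilated in a single generation regardless of cost, destroying the
  cost–benefit threshold structure; moderate selection (0.5) exhibits it
  cleanly.

At these defaults the MA models cycle for every tested (δ, c) while the
GFG models stabilise; symbionts fix below an empirical cost threshold
c\*(δ) and go extinct above it, with c\*_GFG(δ) ≥ c\*_MA(δ) (GFG hosts
have no innate defence against the virulent parasite, so symbiont
protection is essential and tolerates a higher cost), and S2 — the
symbiont protecting against the otherwise-unstoppable P2 — outnumbers S1
in GFG.  With full protection (δ=1) the universally resistant associations
H1S2/H2S1 weakly dominate all others, freeze parasite frequencies and
stabilise even the MA model; this is a structural property of the
max-composition, so cycling claims apply to partial protection (δ < 1).

## Known limitations

- Haploid, single-locus, two-allele genetics only; the canonical square
  constructors (MA/IMA/GFG patterns for n ≥ 2) exist for index studies,
  not for simulation.
- No genetic drift or finite-population effects; deterministic dynamics
  can keep astronomically rare lineages alive that drift would remove.
- The loss threshold makes association *counts* sensitive to weak
  horizontal transmission: re-colonisation holds near-threshold symbiont
  classes above 10⁻³ at v < 1, shifting mean surviving-association counts
  by a fraction of a class between τ=0 and τ=0.01 while cycling prevalence
  and allelic diversity are unaffected.
- Equation forms, grid values and the bimodal density constants are
  documented reconstructions, constrained by printed statements and by the
  qualitative results they must reproduce, not transcriptions.

## Problem sizes

The test suite and the acceptance script run desk-scale versions of the
full design: ensembles of 20–150 matrices (vs 4 000), 4–12 parameter
combinations (vs 108), with the full 20 000-generation runs retained
wherever trajectories are classified.  The ambiguity study uses 50
matrices × 12 combinations × 11 runs (600 models, 6 600 simulations).
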