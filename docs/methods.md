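# Methods

`matesim` is an individual-based, forward-in-time population-genetic
simulator whose purpose is to quantify how social mating rules — marriage
systems and inbreeding avoidance — shape neutral genetic diversity on the
four inheritance systems that respond differently to sex-specific behaviour:
autosomes, the X chromosome, the Y chromosome and mitochondrial DNA.  This
note documents the model, the defaults and the numerical choices, in the
package's own words.

## The population model

A deme is a set of N individuals with non-overlapping, discrete generations.
Each generation:

1. the next census size N′ is read off a piecewise demography schedule
   (constant phases and linear-growth phases of ±k individuals/generation;
   the schedule is deterministic in t, and running past its end or shrinking
   a deme below 2 is an error, never silent truncation);
2. unions are formed among the current adults under the configured marriage
   rule;
3. N′ offspring are created: parents per offspring are drawn according to
   the rule (below), offspring sex is i.i.d. Bernoulli(1/2), and genomes are
   transmitted with mutation;
4. the offspring replace the parents wholesale.

Offspring sex vectors that would leave the deme single-sex are redrawn
whole.  This conditioning keeps very small demes viable; it is applied
identically under every mating system, so cross-system contrasts are not
biased by it.  Parent draws are with replacement across offspring, so family
sizes are multinomial given the unions and the offspring-number variance is
Wright-Fisher-like under random mating.

### Marriage rules

* **Monogamy** — a uniform-random perfect matching of min(N_f, N_m)
  exclusive couples; excess adults of the commoner sex stay unmated that
  generation.  Each offspring draws a couple uniformly.
* **Polygyny** — every female independently takes a uniformly random
  husband.  An offspring draws its mother uniformly; the father is her
  husband.  This parameter-free construction raises the variance of male
  offspring numbers (some males hold several wives, many hold none), the
  mechanism behind the loss of Y-chromosome diversity.  Harem-size caps
  would be an extension point.
* **Polyandry** — the exact mirror of polygyny.
* **Polygamy** — classical random mating: each offspring draws an
  independent uniform mother and father; no unions are precomputed.

Unions are re-formed every generation; there are no persistent pair bonds.

**Sibling avoidance** (optional, any system) rejects a candidate pair that
shares at least one parent id — full and half siblings, one generation of
pedigree depth — and redraws, up to `max_rejections` (default 1000) times per
offspring.  Exhausting the cap raises an error naming the generation rather
than silently permitting the mating.  Parent-offspring matings are
structurally impossible with non-overlapping generations, so one generation
of pedigree is exactly the reachable close-kin set.

## Genetics

Loci are organised in four classes — autosomal (two copies), X (two copies
in females, one in males), Y (one copy, males), mtDNA (one copy, maternal) —
with a user-chosen number of loci and sites per class.  Loci are fully
unlinked: every autosomal locus segregates independently, and there is no
recombination within a locus.  Transmission follows the standard rules: one
of the mother's two copies and one of the father's two per autosomal locus
(each uniform); a uniformly chosen maternal X, plus the father's X for
daughters; the father's Y for sons; the mother's mtDNA for everyone.

Sequences are binary-packed: 2 bits per base (A=00, C=01, G=10, T=11), 32
bases per 64-bit word, site 0 in the lowest bits of word 0.  The layout is
fixed and documented so that state files are portable.  Hamming distances
are XOR + bit-pair collapse + popcount; the whole offspring cohort is
transmitted in a handful of vectorised array operations per locus class.

### Mutation

Mutation follows Kimura's two-parameter model, parameterised by the total
per-site per-generation rate μ and the transition:transversion
probability-mass ratio R (default 2.0; the event is a transition with
probability R/(R+1), else one of the two transversions equiprobably).  Per
transmitted copy the number of hits is exactly Binomial(L, μ) with positions
uniform without replacement — not a Poisson approximation, and no multiple
hits within one transmission (a negligible difference at realistic μL that
buys a simpler contract: a hit always changes the base).  Under the 2-bit
code every transition is `XOR 0b10` and the transversions `XOR 0b01`/`XOR
0b11`, so the operator is a scatter of XORs; its stationary distribution is
uniform over the four bases for any R.  The alphabet is strict ACGT — the
simulator never produces gaps or ambiguity codes, so none are accepted.

## Founding and the buffering phase

Founders are monomorphic by default (all-'A' sequences, all-zero words);
neither "all identical" nor "all distinct" is a biologically meaningful
starting state, so standing variation is injected by an optional buffering
phase rather than by a long burn-in: every class's μ is multiplied by
`boost` (default 100, with the boosted per-site rate capped at 0.1 to stay
clear of K2P saturation) and the deme evolves, with the demography frozen at
its current size, until whole-deme θ_π on a designated class (default mtDNA)
first reaches the user's target.  Rates are then restored and the generation
counter reset to zero — buffer generations are preparation, not part of the
run.  The stopping rule is evaluated on the whole deme each generation so
that stopping is deterministic given the trajectory; the recorded π
trajectory is kept on the population object.

Buffering reproduces equilibrium-like variation best when the boosted rate's
implied equilibrium diversity (for mtDNA, 2 N_f μ′ L) is near the target: the
population then spends enough coalescent time near the target for its
genealogy to equilibrate before the first crossing.  Targets far below the
boosted equilibrium are reached in a handful of generations and leave a
star-like excess of singletons.  The fidelity study in
`matesim.studies.buffering_fidelity` measures this directly, comparing
buffered haplotype-count distributions against matched standard-rate
equilibrium runs.  Note one structural caveat it exposes: an ensemble
observed at its *first* upward crossing of the target is conditioned on
recent rapid diversification, so even in the best-matched regime buffered
populations retain a modest excess of young haplotypes relative to a true
equilibrium ensemble at the same mean diversity — the two distributions are
close in mean but statistically distinguishable with enough replicates.
Users for whom haplotype-age structure is critical should follow buffering
with a stretch of standard-rate generations before treating the deme as
equilibrated.

## Summary statistics

Per locus, on the whole deme or on a without-replacement sample of
individuals (sampling counts chromosomes: s diploid individuals give n = 2s
autosomal sequences): segregating sites S; Watterson's θ_w = S/a_n with
a_n = Σ_{i=1}^{n−1} 1/i; mean pairwise difference θ_π (computed through
per-site allele counts, an exact identity with the pairwise-Hamming average);
haplotype count h (exact sequence identity); unbiased haplotype diversity
H_A = n/(n−1)(1 − Σ p_k²); and Nei's per-site heterozygosity
H_N = (1/L) Σ_sites (1 − Σ q²), without sample-size correction.  θ_w and θ_π
are reported in per-locus units with per-site variants available.  A naive
string-based implementation of all six statistics ships in
`matesim.stats_naive` and the test suite requires exact agreement on
randomized panels.

## Reproducibility contracts

Replicate r of a run with master seed s uses the stream
`SeedSequence([s, r])` (plus a separate stream for statistical subsampling,
so sampling never perturbs a trajectory).  Output bytes are a function of
(config, seed) only — worker count and scheduling cannot change them.  State
files are versioned, checksummed JSON carrying the full packed genotypes,
pedigree arrays and exact RNG state; a resumed run continues bit-exactly,
and a restart may override the mating system, demography or rates to chain
scenario segments (e.g. monogamy → polygyny, or constant size → growth).

## Validation studies and problem sizes

`matesim.studies` packages the validation battery; defaults are sized so the
whole battery runs in minutes on one CPU, as the package's own choice of
default study size, and every study is deterministic given its seed:

* **Coalescent expectations** — random mating, N=100 (50/50), mtDNA and Y of
  1 kb at μ=1e-5, 200 replicates of 2000 generations (≥20·N): whole-deme
  E[θ_π] ≈ 2 N_f μL (mtDNA) and 2 N_m μL (Y); E[S] in samples of 10 ≈ θ·a_10.
* **Mating-system contrast** — Y, 10 kb, μ=2e-6, N=100, both arms buffered
  to θ_π=5 then 300 generations, 200 replicates per arm; Welch test on
  haplotype counts.
* **Mating shift** — the same locus, 200 generations of monogamy then an
  in-place switch to polygyny for 200 more; θ_w averaged over the last 50
  generations of each phase.
* **Growth lag** — X, 2 kb, μ=2e-5; 50 individuals for 500 generations, +2
  per generation for 25, then 100 for 400; θ_π at the three phase ends.
* **Avoidance contrast** — polygamy, N=100, ten 3200-bp autosomal loci at
  μ=3e-7, 300 generations, 500 replicates per arm; Welch test on the
  across-locus mean θ_w.
* **Buffering fidelity** — one full-size buffering run (16 kb mtDNA, N=200,
  target 25) checking the first-crossing contract, plus 100 buffered vs 100
  equilibrium replicates at 1 kb, matched on diversity as described above,
  compared by a two-sample KS test on h.
* **Engineering** — worker-count byte-invariance and save/restart splice
  equivalence across a demography phase boundary.

## What the synthetic conditions do and do not show

All studies run on simulated data generated by the package itself, under
neutrality, with deterministic demography, a single panmictic deme, strict
ACGT sequences and free recombination between loci.  Passing them shows the
engine's internal consistency and its agreement with neutral theory — not
that any particular natural population satisfies those assumptions.
Selection, age structure, migration and population structure, linkage,
indels and rate heterogeneity are out of scope; sizes and rates in the
studies are deliberately small so the battery is cheap, and contrasts driven
by small effective-size differences (notably sibling avoidance, whose effect
on N_e is of order a few individuals) are correspondingly subtle at these
scales.

## Known limitations

* True haplodiploid reproduction (e.g. arrhenotoky) is not modelled; haploid
  systems are emulated by configuring only mtDNA and/or Y loci.
* Monogamy leaves excess same-sex adults unmated rather than recycling them;
  polygyny/polyandry have no harem-size law beyond uniform assignment.
* The buffering stopping rule is whole-deme and per-generation; targets far
  above the boosted equilibrium will hit the generation cap and error.
* State files store genotypes uncompressed (base64) — convenient and
  portable, not compact.
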