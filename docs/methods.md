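# Methods

`selexkit` implements the analytical stack of a parallel-and-serial SELEX
campaign against a small-molecule family (synthetic cathinones): pool
enrichment tracking from sequencing reads, gel-elution affinity
estimation, competitive ITC binding models for racemic targets, and
dye-displacement assay calibration. This note records the models, the
conventions chosen where the problem left them open, and what the
synthetic generators do and do not emulate.

## Pool enrichment analysis

Library strands are 73-nt stem-loops: a forward primer region and 8-nt
stem (the *forward flank*), a 30-nt random loop, then the complementary
stem and reverse primer region (the *reverse flank*). Analysis uses the
random region only.

**Trimming.** A read is kept when the forward flank, then the reverse
flank, are found on the sense strand and the region between them has
exactly the design's random length. Matching is exact substring search
by default; a Hamming-distance tolerance (no indels) is available but
off, because the exactness makes synthetic fixtures verifiable
count-for-count and no mismatch policy is forced by the data model.
Reads are used as-is — no quality filtering and no reverse-complement
rescue — and the trim report exposes kept/discarded counts so users can
diagnose a library/design mismatch.

**Counting.** Identity is exact string equality of the random region;
no clustering or UMI handling, since family membership downstream is
defined by motif containment, not cluster membership. Fractions are
reported over *trimmed* reads (the untrimmed total is retained
separately); reads-per-million is fraction x 1e6. Ranked output orders
by reads descending with lexicographic tie-break, so golden files are
deterministic.

**Families and trajectories.** A family is the set of unique sequences
containing a defining motif (for this campaign, the 20-nt SCA2.1 core
`AGTGGGGTTCGGGTGGAGTT`) as an exact substring at any offset, sense
strand only. The family fraction is the summed fraction of those
sequences; it is invariant to read order and to whether duplicates are
collapsed before or after matching. Pool mixtures combine per-sequence
fractions weighted by the stated mixing weights (equal weights =
equimolar pooling). Diversity summaries report the 5th/50th/95th
percentiles of the per-unique-sequence fraction distribution using
linear interpolation between closest ranks — a convention that had to
be fixed for exact oracle tests; results at these pool sizes are
insensitive to the interpolation rule.

## Gel-elution statistic and Langmuir fitting

The eluted fraction is

    theta = 100% * V1 c_s / (V2 c_s + V3 c_b)

with band concentrations `c_s` (target-eluted supernatant) and `c_b`
(formamide strip) and volumes V1 = 62 ul (pre-collection volume, with
~8 ul of the nominal 70 occupied by agarose beads), V2 = 40 ul
(collected supernatant), V3 = 80 ul (after formamide addition). The
volumes are configurable per observation; the defaults mirror the assay
geometry above, including the bead-volume estimate. theta > 100% is
physically impossible and triggers a warning (volume-model mismatch)
rather than an error, since the fit tolerates mild overshoot.

Affinity is estimated by least squares on the Langmuir isotherm
`theta(c) = theta_max * c / (K_D + c)` with `theta_max` free: partially
enriched pools saturate well below 100% elution (about 30% for the
nine-round single-target pool, >70% after serial selection), so pinning
theta_max = 1 would bias K_D. A `fix_theta_max` option exists for fully
eluting systems. Multi-start initialization places K_D at 0.1x, 1x and
10x the median nonzero concentration in a fixed order, and the best SSE
wins, making the fit deterministic. Standard errors are asymptotic
(Gauss-Newton covariance at the optimum).

## ITC models

**Geometry and units.** Heats are microjoules, concentrations uM,
volumes ul, enthalpies kJ/mol. Injections follow the perfusion
(overflow) convention for fixed-volume cells: injection i of volume v
scales every pre-existing cell concentration by V0/(V0+v) and adds
titrant at X_syr * v/(V0+v). The cell volume is configurable; the
default 1400 ul is a standard fixed-volume calorimeter cell and, with
the 25 x 10 ul schedule of 350 uM titrant into 20 uM aptamer, drives
the molar ratio past 3 — enough overshoot to determine the plateau.

**One-site model.** Bound complex per injection comes from the exact
quadratic mass balance on N*M_t sites (stable product-form root), and
the injection heat is V0 * dH * (bound_i - d_i * bound_{i-1}) plus a
constant per-injection baseline representing titrant dilution heat.

**Racemic (two-sets-of-sites) model.** Chiral targets titrated as a
racemate contain two enantiomers that bind the same site with different
affinities. The model has both species, at fixed syringe mole fractions
phi and 1-phi (default phi = 0.5 for a racemate; fitting phi is
deliberately not default, as it is confounded with N), competing for
one class of N*M_t sites. The coupled equilibrium reduces to one
monotone equation in the free-site concentration S,

    S * (1 + L1/(K1+S) + L2/(K2+S)) = N*M_t,

solved by bracketed Brent iteration on [0, N*M_t]; mass conservation of
the solution holds to 1e-9 relative. When the two affinities differ
strongly (here ~78-fold), the isotherm loses its single sharp sigmoidal
transition — the observed signature that motivates this model over the
one-site fit. With equal parameters the model collapses to the one-site
curve to < 1e-9 uJ.

**Fitting.** Damped least squares (scipy `least_squares`) over
per-injection heats with K_D on a log10 scale, multi-started over K_D
decades in a fixed order; the racemic fit initializes from a one-site
pre-fit with the two K_D seeded +/-1.5 decades around it. Tight
termination tolerances (1e-15) give noiseless round-trip recovery to
<1e-6 relative for the one-site model and <1e-4 for the racemic model.
Seeds affect only simulated noise, never the optimizer. An option
down-weights or drops the first injection (standard practice for
syringe-tip diffusion); the default keeps all injections. K_D standard
errors are delta-method back-transforms from the log scale; a free-
energy column RT ln K_D is provided for convenience. Dilution-heat
correction subtracts either the trailing-mean of the last k = 3
injections (idempotent, the default) or the fitted one-site baseline.
Enthalpies for simulation are user-specified; the -40 kJ/mol used in
examples and round-trip checks is an arbitrary placeholder, and
noiseless K_D/N recovery is independent of its value.

## Dye-displacement assay

The readout is R = A670/A775 (dimer vs aptamer-bound monomer
absorbance). Signal gain is defined as the *relative* change
G = 100% * (R - R0)/R0 against the same-matrix blank — chosen because
reported gains are percentages anchored at zero with no target; the
absolute variant (R - R0) is available by flag. Blanks are never shared
across matrices (buffer / 50% urine / 50% saliva). Cross-reactivity of
a ligand is 100% * G_ligand / G_reference.

Dye-aptamer affinity is fitted on the exact 1:1 ligand-depletion
(quadratic) isotherm, because the dye concentration (2 uM) is of the
same order as K_D (~1.6 uM) and the hyperbolic free-ligand
approximation is visibly biased there (the test suite demonstrates the
divergence). Calibration is ordinary least squares of G vs
concentration inside the linear range; the detection limit solves
predicted G(c) = blank_mean + 3 * blank_sd from the fitted line (on
noise-free linear data with a zero blank mean this is exactly
3*sd/slope). The alternative "lowest tested concentration above
threshold" rule is available by flag. At least three blank replicates
are required for the blank SD.

## Synthetic data

Generators exist for every input: spiked selection pools (multinomial
draw over family and background categories, motif embedded at seeded
random offsets, optional flank-truncated malformed reads), round series
following a stated enrichment trajectory, Langmuir elution curves, one-
site and racemic isotherms, and dye titrations. All are deterministic
under a fixed seed (byte-identical FASTQ), and each returns a truth
manifest from which expected downstream statistics can be computed
exactly. Noise-free expectations use closed forms independent of the
fitting code paths.

What they do *not* emulate: sequencing error (no homopolymer or
substitution model — background reads are uniform i.i.d. 30-mers), PCR
bias, selection dynamics, correlated assay noise, or matrix-specific
absorbance backgrounds. Passing tests therefore demonstrate estimator
correctness under the stated statistical model, not robustness to
instrument artifacts. The shipped flank sequences are synthetic
stand-ins (the campaign's primer/stem sequences are not public) and are
recorded in every manifest.

## Problem sizes

Round-trip and oracle tests run at the assay's native sizes (7
concentrations, 25 injections, 8-11 titration points). Pool-pipeline
checks use 5e5 reads per round — large enough that the 3-multinomial-SD
recovery band is a sub-percent relative test at the trajectory's
smallest fraction — and the final-pool reproduction uses the reported
read total of 1,575,678. Replicated noise studies use 100-200 seeded
replicates and compare medians.

## Known limitations

- Flank matching has no indel tolerance; indel-containing reads are
  discarded rather than rescued.
- The racemic fit fixes phi; enantiomeric excess in the titrant maps
  into biased K_D estimates.
- Asymptotic standard errors understate uncertainty near parameter
  bounds or when the transition is barely sampled.
- The elution statistic trusts the stated volume model; deviations
  (bead-volume variation) surface only as the >100% warning.
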