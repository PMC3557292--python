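# Methods

## The physical model

`tilecall` treats each 21-mer probe site on a resequencing tiling array as
a four-state equilibrium: unbound, self-folded, bound to its specific
genomic target, or bound to an effective pool of non-specific targets.
With reaction coefficients

    K_s  = exp(alpha * G_s),   K_ns = exp(alpha * G_ns),   K_f = exp(alpha * G_f)

the expected signal of probe *p* is

    I_p = A * (K_s + K_ns * C_ns) / (1 + K_f + K_s + K_ns * C_ns) + B .

`A` (optical counts at probe saturation), `B` (optical background),
`C_ns` (effective non-specific target concentration) and `alpha` (a
fitted scale absorbing RT — all free energies are on a dimensionless
fitted scale, larger G meaning stronger binding) are global scalars.
The finite denominator is what distinguishes this finite-hybridization
form from a simple Langmuir isotherm: probe sites saturate, and folding
competes with binding.  Log intensities are always evaluated with
`logaddexp`/log-space arithmetic so extreme energies cannot overflow;
predicted linear intensities lie strictly inside `(B, A + B)`.

### Sequence energies

`G_s` and `G_ns` are position-weighted sums of local triplet energies
over the probe: for probe positions k = 2..20 (1-based), the triplet
(base k-1, k, k+1) indexes a table of 64 values, weighted by a per-position
weight `w_k` in [0, 1] that is intended to decay toward the probe ends.
The weights are shared between the specific and non-specific terms; this
sharing is what makes the parameter count come out at

    64 (specific) + 64 (non-specific) + 192 (penalties) + 19 (weights) + 4 (scalars) = 343.

### Mismatch penalties

Every probe-target mismatch subtracts one penalty from `G_s`.  Penalties
are indexed by the reference (PM) triplet context at the mismatch site
and the substituted base (64 triplets x 3 alternatives = 192 values).
The bookkeeping under a single-substitution hypothesis:

| situation                                   | mismatches |
|---------------------------------------------|------------|
| PM probe, no substitution in span           | 0          |
| MM probe, no substitution                   | 1 (center) |
| PM probe spanning the substitution          | 1          |
| MM probe spanning it off-center             | 2          |
| MM probe whose central alt IS the mutant    | 0          |

Two conventions the model statement leaves open are fixed here and
matter only at the margins: (i) a mismatch at probe position 1 or 21 has
no triplet context and carries zero penalty (the position weights vanish
toward the ends anyway, so such probes contribute essentially no signal
change); (ii) if both the probe center and the target differ from the
reference at the same site, the penalty is looked up by the probe's
base.  Both are deterministic and exercised by tests.

### Probe self-folding

The folding energy `G_f >= 0` is a deliberately simple single-stem
estimator: enumerate every hairpin with two reverse-complementary arms of
length >= 2 separated by a loop of >= 3 nt, score it as the sum of
nearest-neighbor stacking terms (unified DNA/DNA -dG37 table,
kcal/mol) minus a fixed loop penalty (default 3.5), and keep
`max(0, best)`.  This is not a partition-function calculation — no
multi-branch loops, bulges, or temperature/salt corrections — but it is
deterministic, exhaustively testable, and fast in its vectorised form.
Precomputed per-probe energies (TSV: `probe_id`, `energy`) can replace it
wherever a folding argument is accepted.

## Parameter estimation

The 343 parameters are fitted to the log intensities of the *reference*
(wild-type) sample: residual `log I_obs - log I_pred` per probe, summed
squared over the design.  PM probes constrain the triplet energies and
weights, MM probes additionally constrain the penalties (one mismatch
each under the reference hypothesis).  Fitting absolute reference
intensities rather than mutant/wild-type ratios keeps the problem
well-posed with a single sample while exercising all parameter groups.

The optimizer is a seeded population search (scipy differential
evolution over the full vector, global scalars searched in log space)
followed by a bounded trust-region least-squares polish run from both
the best population member and the deterministic data-driven start, with
the better endpoint kept.  The polish does nearly all the numerical
work; the population stage guards against a bad heuristic start.  The
whole fit is a pure function of (data, `FitConfig`), and the best-so-far
objective trajectory is non-increasing by construction.  Default bounds:
energies and penalties in [0, 10], weights in [0, 1], scalars positive
on generous log-scale intervals.  Genome-scale designs are fitted on a
seeded uniform probe subset (`subset_fraction`); ~6,000 probes determine
the 343 parameters to predictive machine precision on noise-free data.

The parameterization is deliberately redundant (a common rescaling of
weights against energies, compensated through `alpha`, leaves predictions
unchanged), so fit quality is always judged on predicted intensities:
noise-free synthetic data are reproduced with RMSE < 1e-10 log units,
and at noise sd 0.05 the fit RMSE sits at the noise floor while predicted
mutant/wild-type log ratios around substitutions correlate with the
generating model's at r > 0.95.

## Detection

For genome position *i*, let `r_p = log(I_mut,p / I_wt,p)` over the 84
probes (full design: 21 PM + 63 MM) whose span contains *i*.  The null
residual and the residual under substitution hypothesis (i -> b) are

    D_i = sum_p r_p^2 ,      E_i(b) = sum_p (r_p - rhat_p(i, b))^2 ,

where `rhat` is the model-predicted log ratio (zero under the reference
hypothesis).  Under Gaussian ratio errors with constant variance, the
log-likelihood ratio for the substitution is `L_i(b) = D_i - E_i(b)` up
to a constant.

Screening: a centered running average of `D` (window 11, configurable)
is compared with `theta_R = mean(D) + k_sd * sd(D)` (k_sd default 2).
Maximal runs above threshold become candidate regions; runs under 10 bp
are discarded as noise, runs of 80 bp or more are flagged *structural*
(deletion-scale) and excluded from substitution calling (they are
reported as BED).  Because a deletion drives `D` so high over so many
positions that it would dominate the genome-wide statistics and mask
every substitution, the threshold is re-estimated iteratively with
structural-run positions removed (at most 5 passes; it converges in 2
in practice).  This mirrors taking deletion regions out of the analysis
before screening for point substitutions; `exclude_structural=False`
restores the single-pass genome-wide statistic.

Calling: within each non-structural region the single (i, b) maximising
`L_i(b)` is found; it becomes a call iff `L > theta_L` (strict), with
ties broken toward the smaller position and then base order A<C<G<T.
`theta_L` has no default — it is user-supplied or calibrated on
simulated data by maximising TP - FP (`evaluate.best_threshold`).

## The simulator

`simulate_dataset(SimConfig)` is the package's test bed standing in for
undeposited array data.  It draws an i.i.d. random genome at a given GC
content, samples a ground-truth `EnergyModel` uniformly within per-group
ranges (weights arranged to peak at the probe center), implants
substitutions uniformly with a pairwise circular spacing >= `min_spacing`
(>= 22 bp, so no probe spans two), and evaluates the forward model for
both samples with multiplicative log-normal noise
(`I = exp(log I_model + eps)`, `eps ~ N(0, noise_sd^2)`).  Deletions are
emulated by switching off the specific-binding term for every probe
whose span intersects the deleted interval — the mutant sample then
shows non-specific signal plus background there.  Substitutions are kept
100 bp clear of deletion edges so point and structural regions never
merge.  Every artifact is a pure function of the config (seeds are
spawned from one `SeedSequence`).

Default conditions: 50 kbp circular genome, GC 0.5, 20 substitutions,
spacing 100 bp, noise sd 0.05, seed 17.  The model ranges are set so
that probes sit on the responsive part of the isotherm and one mismatch
drops the predicted intensity by a factor of roughly 2-10, in line with
real short-oligo arrays.

What the simulator does *not* emulate — spatial chip artifacts, scanner
saturation, batch and wash effects, replicate arrays, cross-hybridization
between specific targets, position-correlated noise — bounds what
passing tests show: they validate the algorithmic pipeline (model
arithmetic, screening, calling, calibration) under the model's own noise
assumptions, not performance on a physical chip.

## Evaluation

Truth records that a 21-mer tiling array cannot resolve are filtered
before scoring: a neighboring record within 21 bp (both removed), a
centered 21-mer occurring more than once in the genome or its reverse
complement, or a centered-window GC fraction outside [0.2, 0.8] (both GC
bounds and the +-2 bp matching tolerance are configurable defaults; the
source procedure's exact values are not stated).  Calls are matched to
truth greedily by increasing distance within the tolerance, one use per
record; exact-position and exact-position-plus-base counts are reported
separately.

## Numerical notes and limitations

- Coordinates are 1-based and closed; the genome is circular by default
  (linear genomes lose the 10 terminal positions from the design and use
  truncated running-average windows).
- Strand alternation is fixed as even tiled index = forward.  MM
  substitution is defined in probe space (the probe-sequence character is
  replaced), also for reverse-strand probes.
- `sd(D)` uses the population convention (ddof 0).
- Candidate regions may wrap the circular origin (represented with
  end < start).
- Reduced resolutions r in {1,3,5,7,9,11,13} keep PM probes with tiled
  index = 0 mod r; if r does not divide the genome length the wrap
  junction is one tile short, which is immaterial at desk scale.
- The caller assumes at most one substitution per probe length; the
  simulator enforces the spacing, the caller does not check it.
- Structural regions are flagged, not resolved: no breakpoint
  refinement, no copy-number quantification, haploid targets only.

## Problem sizes used in the shipped tests

Oracle comparisons run on a 2-kb genome (8,000 probes), predictive
recovery on 30 kbp (120k probes, fitting on a 5% subset), and the
end-to-end recovery and resolution studies on the 50-kbp default
configuration with a 1-kbp deletion, fitted on a 3% subset.  These sizes
keep the full suite to a few minutes while leaving every statistic
genuinely computed from simulated data.
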