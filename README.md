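# tilecall

Single-nucleotide substitution calling from high-density resequencing
tiling microarrays, built on a physical model of probe hybridization.

Resequencing tiling arrays cover a genome at 1-bp resolution with 21-mer
perfect-match (PM) probes — one per position, alternating strands — plus
up to three mismatch (MM) probes per position in which the central
(11th) base is substituted.  Comparing the probe intensities of a mutant
sample against the reference sample reveals single-base substitutions:
probes spanning a substitution lose signal, while the one MM probe whose
central base *is* the mutant base becomes a perfect match and gains
signal.  Exploiting that pattern quantitatively requires a model of how
intensity depends on probe sequence, and that is what this package
provides, for anyone benchmarking array-based variant detection or
studying probe-level hybridization models.

## The model and the caller

Each probe site is a four-state equilibrium (unbound / self-folded /
specifically bound / non-specifically bound) with predicted intensity

    I = A (K_s + K_ns C_ns) / (1 + K_f + K_s + K_ns C_ns) + B,
    K_x = exp(alpha G_x),

a finite-hybridization form in which probe sites saturate and
self-folding competes with binding.  The specific and non-specific
energies G_s, G_ns are position-weighted sums of local triplet energies
over the probe, and every probe–target mismatch subtracts a
context-dependent penalty from G_s.  The model has exactly 343 free
parameters (64 + 64 specific/non-specific triplet energies, 192 mismatch
penalties, 19 position weights, 4 global scalars), estimated from the
reference sample alone by a seeded population search with a trust-region
least-squares polish.

Substitutions are then called in two stages from the per-position
residual statistics of the observed mutant/wild-type log ratios:

1. **screen** — positions where the running average of the null residual
   D_i exceeds `theta_R = mean + k sd` form candidate regions; 10–79 bp
   regions are substitution candidates, regions of 80 bp or more are
   flagged structural (deletion-scale) and set aside;
2. **call** — within each candidate region, the (position, base)
   maximising the log-likelihood ratio `L_i(b) = D_i − E_i(b)` is called
   iff it exceeds a threshold `theta_L`.

A fully seeded forward-model simulator (random genomes, implanted
substitutions and deletions, log-normal intensity noise) provides the
test bed, and an evaluation module scores calls against truth sets with
the platform-specific truth filters (close pairs, repeated 21-mer
context, extreme GC) applied first.  See `docs/methods.md` for the full
treatment.

## Worked example

```python
import numpy as np
import tilecall as tc

config = tc.SimConfig(genome_length=10_000, n_substitutions=5,
                      min_spacing=100, noise_sd=0.05, seed=17)
data = tc.simulate_dataset(config)

fh = tc.FiniteHybridizationModel(data.design, data.wt, data.folding)
results = fh.fit(tc.FitConfig(seed=5, population_size=16, generations=10,
                              subset_fraction=0.15))
print(results.summary())

calls, regions, profile = results.call_substitutions(data.mut, theta_L=-np.inf)
curve = tc.threshold_curve(calls, data.truth, genome_length=config.genome_length)
theta = tc.best_threshold(curve)
final = [c for c in calls if c.llr > theta]
scored = tc.match_calls(final, data.truth, tol_bp=2,
                        genome_length=config.genome_length)
print(f"calibrated theta_L = {theta:.2f}")
for c in final:
    print(f"  pos {c.position:>6}  {c.ref_base}->{c.alt_base}  LLR {c.llr:7.2f}")
print(f"sensitivity {scored.sensitivity:.2f}  "
      f"({scored.tp} TP, {scored.fp} FP, {scored.fn} FN)")
```

prints (about a minute, single core):

```
Finite-hybridization model fit
==============================================
Genome                      sim17 (10,000 bp, circular)
Probes in design            40,000 (resolution 1 bp)
Free parameters             343
Probes used in fit          6,000
Objective (RSS, log units)  13.7321
Fit RMSE (log units)        0.0478402
Generations run             10
Seed                        5
----------------------------------------------
parameter group                  min    mean     max
specific energies (64)         0.164   0.617   1.095
non-specific energies (64)     0.000   1.240   3.984
mismatch penalties (192)       0.841   2.077   2.987
position weights (19)          0.168   0.411   0.628
alpha                         0.9311
intensity scale A               1051
background B                   50.46
non-specific conc C_ns         1e-05

calibrated theta_L = 11.00
  pos    831  T->G  LLR   11.00
  pos   2472  G->T  LLR   19.67
  pos   4699  A->G  LLR   23.63
  pos   7612  A->G  LLR   22.40
  pos   9997  C->T  LLR   34.94
sensitivity 1.00  (5 TP, 0 FP, 0 FN)
```

The fit RMSE (0.048 log units) sits at the simulated noise floor
(noise sd 0.05): the model explains everything but the injected noise.
All five implanted substitutions are recovered at their exact positions
and base types with no false positives once `theta_L` is calibrated to
maximise TP − FP.

## Command line

The same pipeline is exposed as `tilecall design | simulate | fit |
call | evaluate`, exchanging plain-text formats: design TSV, intensity
TSV, model JSON, calls VCF, structural-region BED.  For example:

```
tilecall simulate --length 20000 --n-substitutions 10 --seed 17 --outdir sim/
tilecall fit --design sim/design.tsv --intensities sim/wt.tsv \
             --folding sim/folding.tsv --seed 5 --out model.json
tilecall call --wt sim/wt.tsv --mut sim/mut.tsv --model model.json \
              --design sim/design.tsv --theta-l 10 \
              --out-vcf calls.vcf --out-bed structural.bed
tilecall evaluate --calls calls.vcf --truth sim/truth.vcf --out eval.json
```

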