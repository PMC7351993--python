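# ramansort

A virtual Raman image-activated cell sorter: a simulation and analysis
toolkit for label-free, image-based cell sorting with stimulated Raman
scattering (SRS) contrast. It is aimed at instrument builders and
quantitative biologists who want to study, before touching hardware, how
acquisition geometry, spectral unmixing, gating and sorter timing jointly
determine throughput, sort purity and yield.

The package contains four coupled pieces:

1. **Synthetic flow acquisition** (`ramansort.flowsim`) — cells arrive as a
   Poisson stream at rate λ (events/s), each independently a *target* with
   probability *r*, and cross a 1-D line focus sampled at 48 kHz over 24
   lateral detector pixels in 4 spectral channels. Specimens are rendered as
   disks (optionally with bright internal droplets) into a line-scan stream
   plus a forward-scatter (FSC) trace, with additive Gaussian noise at a
   configurable SNR and full ground truth.
2. **Real-time image pipeline** (`ramansort.pipeline`) — threshold
   triggering on the FSC trace, 122-line event frames, square-pixel
   normalization (122 × 24 → 122 × 89 for a 33 × 24 µm field of view),
   masking (background correction → Gaussian → top-hat → Canny → contour
   closing → convex hull), per-pixel linear unmixing, within-mask feature
   extraction, and 2-D gating for the sort/unsort decision.
3. **Spectral unmixing** (`ramansort.spectral`) — each pixel's 4-color
   measurement **d**ⱼ is modeled as a linear superposition of constituent
   responses, **d**ⱼ = Σᵢ c_{ji} **s**ᵢ; the concentrations c_{ji} are
   recovered by applying the Moore–Penrose pseudo-inverse of
   [**s**₁ … **s**ₙ]. Bases are built by sampling constituent spectra at
   chosen acquisition wavenumbers (default 2899, 2954, 3006, 3034 cm⁻¹).
4. **Sorter timing model** (`ramansort.sorter`) — the dual-membrane
   push-pull sorter with alternating actuation directions, both as a
   Monte-Carlo event-stream simulation and as an analytic nearest-neighbour
   model: a particle's fate depends on five binary parameters (itself, its
   two neighbours, and whether each adjacent inter-arrival gap is shorter
   than τ, half the sort window), giving a 2⁵ = 32-scenario sample space
   with factorized probabilities — target/nontarget with probability r/(1−r)
   per particle and short/long gap with probability p = 1 − e^(−λτ) per
   interval. Sort purity is ΣP_TP / (ΣP_TP + ΣP_FP). Throughput is tracked
   with the sliding event rate eᵢ = 50 / (tᵢ − tᵢ₋₅₀) (i ≥ 51), with the
   histogram mode as the nominal value, and sorted fractions are scored as
   purity = N_target,collection / (N_target,collection + N_nontarget,collection),
   yield = N_target,collection / (N_target,collection + N_target,waste).

## Worked example

```python
import numpy as np
import ramansort as rs

# 1. four-color basis for a PS/PMMA-like two-polymer mixture
basis = rs.default_polymer_basis()
print("basis condition number:", round(basis.condition_number, 2))

# 2. simulate a 2 s acquisition at 50.2 events/s, 60% targets
acq = rs.AcquisitionConfig(seed=1)
truth = rs.simulate_arrivals(rate=50.2, r=0.6, duration=2.0, seed=1)
stream, fsc = rs.render_stream(truth, basis, acq)
print("specimens:", len(truth.specimens))

# 3. run the real-time analysis chain with a density gate
gate = rs.Gate("PS_density", "PMMA_density", (-2.0, 2.0, 4.0, 40.0))
table = rs.process_stream(stream, fsc, basis, acq, gate=gate)
print("events detected:", len(table), "| sorted:", int(table["sort"].sum()))

# 4. analytic vs Monte-Carlo sort purity at this operating point
tau = 1.5e-3
print("analytic purity: %.1f%%" % (100 * rs.purity_analytic(50.2, tau, 0.6)))
rng = np.random.default_rng(1)
times = np.cumsum(rng.exponential(1 / 50.2, 100_000))
labels = rng.random(100_000) < 0.6
run = rs.simulate_sorting(times, labels, rs.SortTimingConfig(2 * tau))
print("Monte-Carlo purity: %.1f%% | yield: %.1f%%"
      % (100 * run.purity, 100 * run.yield_))
```

Output:

```
basis condition number: 1.48
specimens: 88
events detected: 88 | sorted: 51
analytic purity: 94.3%
Monte-Carlo purity: 94.3% | yield: 91.7%
```

The 88 simulated specimens are all detected; 51 fall inside the
PMMA-density gate (≈ 60% targets). At 50.2 events/s with τ = 1.5 ms the
scenario model predicts 94.3% sort purity — coincident arrivals within the
sort window, not classification errors, set this ceiling — and the
event-stream simulation agrees to the binomial noise floor. The yield is
lower than the purity because a target whose own push is cancelled by a
neighbouring actuation is lost to waste (a false negative) more often than
a nontarget is carried into the collection.

The same experiments can be driven from the shell:

```sh
ramansort simulate --seed 1 --outdir runs/sim
ramansort process --indir runs/sim --outdir runs/proc
ramansort sort-model --rates 1,2,5,10,20,50,100,200 --out curves.csv
ramansort end-to-end --seed 1 --outdir runs/e2e
```

Every run writes a `manifest.json` with the seed, config echo and output
checksums; identical seeds give bit-identical outputs.

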