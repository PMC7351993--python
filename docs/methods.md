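# Methods

This note documents the models behind `ramansort`, the defaults and why
they were chosen, the numerical conventions, and what the synthetic data do
and do not emulate.

## Acquisition model

The simulated instrument images cells in flow with a line-focusing
multi-color SRS microscope. One line of `n_lateral_pixels` (default 24)
pixels in `n_colors` (default 4) spectral channels is acquired per line
period (default 48 kHz, i.e. 20.83 µs ≈ 21 µs per line). The lateral pixel
pitch is `lateral_fov / n_lateral_pixels` = 1 µm; travel along the flow
direction is `flow_speed / line_rate` = 0.833 µm per line at the default
0.04 m/s. Event frames are `frame_lines` = 122 consecutive lines.

Two geometry figures deliberately coexist: the *nominal* frame coverage
(`flow_fov` = 33 µm, used for square-pixel normalization, giving the
122 × 89 normalized grid at a 0.2705 µm pitch) and the *kinematic* line
pitch above (which makes 122 lines cover ~102 µm of travel at 0.04 m/s).
The two are only consistent at an imaging magnification that the simulator
does not model, so `flow_speed` and `frame_lines` are independent knobs and
the normalization uses the nominal field of view. Densities and gating are
unaffected: they are consistent within a run by construction.

The four colors are treated as co-registered channels of the same line.
The instrument's time-domain wavelength multiplexing operates at sub-µs
scale, far below the line period, and its demultiplexing happens in lock-in
hardware outside the scope of this package.

Noise is additive i.i.d. Gaussian per pixel per channel with SD
`noise_sigma` (default 1/30 of the unit peak signal, an SNR-30 operating
point typical of shot-noise-limited SRS detection). Real SRS noise is
approximately Gaussian at these photon fluxes; correlated noise (laser RIN,
lock-in filtering) is not modeled. The FSC event-detection trace is
rendered noiseless with amplitude proportional to the occluded chord
length: event detection hardware is high-SNR by design, and the trace's
role here is timing, not intensity measurement.

Specimens are uniform disks (radius default U(2.5, 5) µm, lateral offset
N(0, 1.5 µm) truncated to the field of view), optionally carrying circular
internal droplets with a concentration multiplier to emulate e.g. lipid
droplets. Real cells have irregular shapes, graded edges and organelle
texture; passing tests therefore demonstrate the pipeline's correctness on
well-posed inputs and its noise robustness, not segmentation performance on
morphologically complex cells.

## Spectral unmixing

Per pixel, **d** = S **c** with S the (colors × constituents) response
matrix; the solver returns the minimum-norm least-squares solution via the
pseudo-inverse (exact inverse when square). Bases are built by linearly
interpolating tabulated constituent spectra at the acquisition wavenumbers;
construction rejects rank-deficient matrices using a singular-value cutoff
of 1e-10 times the largest singular value. Negative coefficients are
retained — the pseudo-inverse is linear and clipping would bias within-mask
statistics — with optional clipping (`clip_negative`) at the feature stage
only. The bundled two-polymer spectra are synthetic Gaussian-peak stand-ins
whose four-wavenumber sampling yields a well-conditioned 4 × 2 basis
(condition number ≈ 1.5); no measured spectra ship with the package.
Constrained methods (NNLS, MCR-ALS) are out of scope.

## Image pipeline

Events are threshold crossings of the FSC trace with a refractory dead time
(default 200 µs) against re-triggering. Because the simulator colocates the
detection spot and the imaging line, the end-to-end runner uses a negative
acquisition delay of `-frame_lines/2` line periods to centre specimens in
their frames; a physical instrument instead applies a positive delay
matching the detector-to-imaging-line transit. Frames that would extend
beyond either end of the stream are marked aborted and carried through the
accounting (detected = feature rows + aborted).

Square-pixel normalization keeps the flow pitch `flow_fov / frame_lines`
and linearly resamples the lateral axis to `round(lateral_fov / pitch)`
columns, rounding half up (24 µm / 0.2705 µm = 88.7 → 89).

Masking chain and defaults (all in `SegmentationParams`):

1. background correction — subtract the per-column median of the first and
   last 5 rows (assumed specimen-free margins; median for robustness);
2. Gaussian smoothing, σ = 1 px;
3. white top-hat with a disk of radius 15 px (larger than the specimen
   scale along the flow axis, so it flattens background without eroding the
   cell);
4. Canny edge detection, σ = 1 px, hysteresis thresholds (0.1, 0.3) × the
   filtered-image maximum;
5. contour closing: dilation and erosion with a disk of radius 2 around a
   hole fill;
6. spur trim, convex hull of the largest connected component, spur trim.

The spur trim removes pixels with fewer than 5 of 8 neighbours set. It
addresses a digital quantization bias: the Canny ring straddles the true
boundary by up to half a pixel, and filling it over-counts area by roughly
a one-pixel shell — a +25–37% error at 3–4 px radii, where the ±15% area
band demands sub-half-pixel placement. With the trim, disk areas are
recovered within ±8% for radii 3–15 px. The price is that the final mask
can differ from its exact convex hull by single boundary-layer pixels; it
is convex up to that one-pixel layer. Components below `min_area_px`
(default 20 px) are discarded so noise-born contours cannot produce
spurious micro-masks; an empty mask is a valid outcome and such events are
never sorted.

The mask channel defaults to the constituent with the largest total frame
signal after decomposition (overridable). Multi-object frames yield one
mask (the largest component); splitting coincident cells in one frame is
out of scope. Features are computed over mask pixels only: area, and per
constituent the total, mean, maximum and standard deviation, plus the
density (total / area in µm²) used for gating. The within-mask SD of a
constituent doubles as a texture feature: droplet-bearing specimens have
strictly larger SD than uniform ones of the same composition. Gates are
rectangles or polygons in a 2-D feature plane with an inclusive boundary (a
fixed convention chosen for determinism).

## Sorter model

Displacement rules (shared by the analytic and Monte-Carlo views): every
particle decided a target triggers an actuation at its sort-point arrival
time; directions alternate globally (+1, −1, …) so the membrane pumps need
no re-initialisation and both side branches feed the collection outlet; an
actuation at time t displaces every particle with |tᵢ − t| < τ by one
lateral step in its direction; a particle on a side stays under a
same-direction push, returns to centre under an opposite push; destination
is collection iff the accumulated lateral state is non-zero. Sort timing is
treated as perfectly predictable (latency jitter defaults to zero, with a
seed hook reserved).

These rules are a reconstruction from the sorter's narrated working
principles. The one case whose outcome depends on the reading — a target
preceded by an in-window actuation, whose own opposite-direction push
cancels the displacement — is exposed as `rule_variant`: `"alternating"`
(default; the case is a false negative) versus `"own_dominant"` (a
particle's own actuation always lands it on a side; the case is a true
positive). The default reproduces the narrated nontarget-between-targets
case: near gap short, far gap long → the nontarget exits through a side
channel, a false positive, including the counterfactual that a short far
gap would push it back to the centre.

The analytic model assumes only nearest neighbours matter, giving the
32-scenario space with factorized probabilities; under the alternating
rules it admits the closed form (used as an independent oracle in tests)

    P_TP = r[(1−q)² + q²],  P_FP = (1−r)·2q(1−q),  q = r(1 − e^(−λτ)).

The Monte-Carlo simulator applies the rules over the whole stream, so
second-neighbour coincidences (probability ~p²) are included; the two
agree within Monte-Carlo noise for λτ ≲ 0.1 and within ~p² beyond. On the
tested grid (λ up to 200 events/s, τ up to 3 ms, r in 0.1–0.9) purity is
monotone non-increasing in λ and in τ, approaches 1 as λτ → 0, and faster
flow (smaller τ = sort-region length / flow speed / 2) dominates pointwise
at fixed throughput.

The nominal throughput is the histogram mode (1 event/s bins) of the
sliding 50-event rate series; the bin width is a convention where the
underlying definition ("most frequent value") does not fix one. Count-based
purity is flagged undefined (NaN), not zero, when the collection is empty.

## Problem sizes and determinism

The test suite and acceptance script use 10⁵-event streams for Monte-Carlo
purity (binomial SE ≈ 0.1%, resolving the model's percent-level structure),
10⁴ rendered frames for the gating experiment (enough to bound accuracy
below 1% error at the 99% criterion), and 10⁴-event streams for throughput
statistics. One seeded `numpy.random.Generator` drives each run; identical
seeds and configs give bit-identical streams, feature tables and manifests.

## Known limitations

- No optical PSF, lock-in demodulation, or acoustic-focusing physics; disks
  with droplets are the entire morphological repertoire.
- One mask per frame; coincident cells in a frame are not split.
- The analytic purity model ignores second-neighbour effects by design;
  use the Monte-Carlo path at high λτ.
- Classification is classical gating only; no learned classifiers.
- Sorted-cell viability, membrane-pump fluid dynamics, and flush/boost
  protocols are not modeled.
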