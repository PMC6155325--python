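# Methods

This note records the models, parameter choices and numerical conventions
behind `spraydep`, and what the synthetic-data validation does and does not
demonstrate about real AFM data.

## The ordering statistic

**Model.**  If particles are deposited isotropically, the bond angle between
a particle and its nearest neighbour is uniform on `[−π/2, π/2]` (only
orientation matters, not direction).  With `N` retained pairs binned into
`N_bin = 8` equal orientation bins, each count `Cᵢ` is binomial(N, p = 1/8):
`μ_bin = Np`, `σ²_bin = Np(1−p)`.  Alignment of particles along preferred
directions over-fills some bins, inflating the sample variance
`σ²_Sample = (1/N_bin) Σ(Cᵢ − μ_bin)²` beyond `σ²_bin`.  The order parameter
is the normalized excess

    O = (σ²_Sample − σ²_bin) / μ²_bin,

with analytic bounds `−σ²_bin/μ²_bin = −7/N` (perfectly flat counts, a
finite-sample fluctuation below the null) and `7(1 − 1/N)` (all pairs in one
bin).  By the central limit theorem `Var[σ²_Sample] ≈ 2σ⁴_bin/N_bin`, giving
`σ_O = (σ²_bin/μ²_bin)√(2/N_bin) = 3.5/N`.  Estimates from several images
are pooled by inverse-variance weighting, `Ô = Σ(Oᵢ/σ²ᵢ)/Σ(1/σ²ᵢ)`,
`σ̂² = 1/Σ(1/σ²ᵢ)`.

**Definition of N.**  The bin counts count *pairs*, so the binomial null is
self-consistent only with `N` = number of retained pairs (`ΣCᵢ = N`); that is
the definition used everywhere, including in `μ_bin` and `σ²_bin`.

**The p-value.**  Counts are standardized, `Xᵢ = (Cᵢ − μ_bin)/σ_bin`, their
mean square `σ²_x` formed, and the upper normal tail
`p = 1 − ½[1 + erf(σ_x/√2)]` reported.  Under the null `E[σ²_x] ≈ 1`, so the
null p-value concentrates near `1 − Φ(1) ≈ 0.16` instead of being uniform;
the expression is nevertheless the field's convention for this statistic and
is implemented exactly as stated, with the caveat documented here.  Small
values (≤ 0.01) still indicate strong departures from isotropy.

**Pair extraction.**  Nearest neighbours come from a KD-tree; exact-distance
ties (which occur on constructed grids) are broken toward the lowest index.
Each unordered pair is examined once, at the first (lowest-index) centre that
finds it, and is discarded there if its length exceeds that centre's distance
to the nearest image border — the true nearest neighbour might lie outside
the frame.  Coincident maxima are excluded and counted.  Discard counts are
carried through to the output so the effective N is auditable.

**Binning.**  Eight bins of width π/8, centred on multiples of π/8 and
aligned with the pixel-grid axes (this minimizes discretization artefacts in
rasterized positions); the two half bins at ±π/2 are merged; `p_x = 0` maps
to +π/2; an angle exactly on a bin edge goes to the higher bin.

**Maxima detection.**  The map is median-filtered (3×3 default), then local
maxima are kept when their filtered height exceeds a threshold and their
prominence (the drop required before any connected path reaches a higher
pixel, computed via h-maxima morphological reconstruction) exceeds a noise
tolerance.  Both default to 3× a robust noise estimate, `1.4826 × MAD` of
the residual between the raw and median-filtered map.  These two knobs are
the detection contract; they are deliberately explicit because interactive
image-analysis tools leave them implicit.

## Droplet physics

All internal physics is SI; interfaces use fL (= µm³), µm, ms, µl/h.

* **Air.**  Saturation vapour pressure from the Magnus relation
  `e_s(T) = 610.94·exp(17.625T/(T+243.04))` Pa (T in °C), converted to mass
  concentration by the ideal gas law; at 25 °C, `c_sat ≈ 0.023 kg/m³`.
  Water-vapour diffusivity default `D_v = 2.5×10⁻⁵ m²/s`.  Default ambient
  state 25 °C, RH 0.5 (air-conditioned laboratory).
* **Cap geometry.**  `a = √(area/π)`, `h = a·tan(θ/2)`,
  `V = πh(3a² + h²)/6`; the inverse gives `a(V, θ)` in closed form.  Valid
  because `Bo = ρgL²/γ ≈ 10⁻⁵ ≪ 1` at these scales.  Round-trips are exact
  to better than 1 part in 10⁹.
* **Flight.**  Maxwell quasi-steady evaporation integrated as the R²-law,
  `R(t)² = R₀² − 2D_vΔc t/ρ`, over `t = distance/velocity`.  Constant
  velocity (no Stokes drag), no evaporative cooling — order-of-magnitude
  treatment.  Droplets that run out of radius are flagged fully evaporated.
* **Sessile drying.**  Pinned contact line (θ < 90°), diffusion-limited:
  `dV/dt = −(πaD_vΔc/ρ)(0.27θ² + 1.30)`, the standard small-angle result for
  vapour diffusion around a cap.  The rate is constant under pinning, so
  `t_dry = V/|dV/dt|`, linear in landed volume.  The angular factor is
  isolated in one function and documented as replaceable.
* **Droplet population.**  Lognormal, parameterized by the measured (median,
  IQR) of imprint-derived volumes: `μ = ln(median)` keeps the median exact
  and `σ = ln(q3/q1)/(2z₀.₇₅)` matches the quartile *ratio*.  A
  two-parameter lognormal cannot match the median and both quartiles of the
  calibration data simultaneously (100 fL is not the geometric mean of 40
  and 210 fL); preserving the median was chosen because downstream drying
  times are reported as medians.
* **Pipeline air state.**  The drying-time pipeline and its acceptance check
  are run in dry air (RH 0) — the condition under which the ~5 ms sessile
  benchmark is reproduced.  At RH 0.5 every drying time scales by
  `1/(1−RH) = 2`; the humidity/temperature sensitivity report
  (`drying_time_sensitivity`, ΔT = 2 °C, ΔRH = 10 %) quantifies this as a
  first-class output rather than asserting a fixed bound.
* **Coverage/coalescence.**  Arrival rate `Q/V_median` over the cone
  footprint `π(d·tan(α/2))²` (18° full apex angle by default; the half-angle
  interpretation is configurable).  Expected wet coverage during one drying
  window = rate × t_dry × mean imprint area / footprint; below a 5 %
  threshold the deposit is classified as individual droplets (regime I),
  above it as coalescing streams (regime II), with a Poisson overlap
  probability `1 − e^{−coverage}` attached.

## The synthetic generator

The generator emulates fields of protein-scale particles: default amplitude
0.4 nm and lateral sigma 5 nm (monomeric α-synuclein cross-sections are
~0.2–0.6 nm), placed on extents of a few µm at densities of tens to hundreds
per µm².  Particle counts are Poisson(density × area); positions are
continuous nm coordinates, so ground truth is exact and rasterization
happens only at render time (Gaussian bumps summed linearly at pixel
centres + iid Gaussian pixel noise, default sd 0.05 nm).  One master seed is
split via `SeedSequence` into independent streams for count, positions,
chain geometry and pixel noise.

Ordering strength `s ∈ [0, 1]` does two things at once: a fraction `s` of
the particles is placed in chains (sequential steps of 15 nm along an
orientation drawn from the lattice set {0°, 60°, 120°}), and the per-bond
angular jitter shrinks linearly from 10° at `s = 0` to exactly 0 at
`s = 1`.  This gives a single interpretable knob that provably reduces to
the uniform field at `s = 0` (draw-for-draw identical) and to perfectly
aligned bonds at `s = 1`.  The mapping from `s` to the order-parameter values
of any particular instrument dataset is deliberately uncalibrated — the knob
is for power analysis, not for mimicking a specific specimen.

**What passing tests show — and don't.**  The synthetic maps contain no tip
convolution, scan-line artefacts, drift, or height-dependent noise, and the
generator does not simulate aggregation kinetics.  Null calibration, power
monotonicity and recovery results therefore validate the *statistics*
(detection, pairing, binning, O and its uncertainty) under known ground
truth; they do not certify detection performance on instrument data with
correlated noise or strongly overlapping aggregates.

## Problem sizes and numerical choices

Monte Carlo sizes were chosen to keep each statistical check well-resolved
at interactive runtimes: 200 random fields (~280 pairs each, density
50/µm² on 3×3 µm) for null calibration, 10 seeds per point on the 5-point
`s` grid for power, 20 fields at 25/µm² on 20×20 µm for the Poisson
nearest-neighbour law (≈10⁴ points each), and 4000 droplets for the drying
distribution.  At these sizes the weighted null mean resolves 0 to ~±0.001
(3σ̂) and the NN-distance check resolves 1 % deviations.

Degenerate inputs are contracts, not crashes: fewer than two maxima yields
an empty pair set with a warning; an empty histogram, empty ensemble or
empty result list raises `ValueError`; saturated air gives zero evaporation
and infinite drying time (serialized as null in JSON).  Local background for
particle heights is the median of an annulus (inner radius ~3× particle
sigma, 4 px wide, cropped at map edges) — median rather than mean so that a
neighbouring particle inside the annulus does not bias the baseline.

## Surface occupancy

The deposition model is the minimal linear one: every sprayed molecule
within the cone footprint sticks, `λ = C·N_A·V·ε/footprint`, with the
sticking efficiency `ε` an explicit parameter (default 1) fit by bounded
least squares when observed nearest-neighbour distances are supplied.
Nearest-neighbour distances are compared against the Poisson law
`⟨r⟩ = 1/(2√λ)`; the border rule is shared with the ordering module so the
two analyses count the same points.

## Known limitations

* The sessile evaporation model assumes pure water; solutes, Marangoni flows
  and contact-angle dynamics during drying are ignored.
* The constant-velocity flight neglects deceleration, so flight times (and
  hence in-flight losses) are lower bounds for the smallest droplets.
* The order parameter is orientation-based only: it detects alignment, not
  chain length, persistence or periodicity.
* The p-value's null distribution is not uniform (see above); use it as a
  departure score, not a calibrated tail probability.
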