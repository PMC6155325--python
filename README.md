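# spraydep

Quantitative analysis of **microfluidic spray deposition for atomic force
microscopy (AFM)** of biomolecules.

Spray deposition transfers a protein solution to a substrate as subpicolitre
microdroplets that dry in milliseconds — faster than proteins can diffuse on
the liquid–solid interface — so the deposited molecules are a faithful,
unbiased snapshot of the solution's assembly state.  Validating that claim
takes three pieces of quantitative analysis, all implemented here for anyone
doing AFM sample preparation or spray-deposition method development:

1. **Surface ordering statistic.**  Particles (local height maxima) are
   detected in AFM maps; nearest-neighbour bond angles
   `θᵢ = arctan(p_y/p_x)` are histogrammed into `N_bin = 8` orientation bins,
   and the **order parameter**

   ```
   O ≡ (σ²_Sample − σ²_bin) / μ²_bin,
   μ_bin = Np,  σ²_bin = Np(1−p),  p = 1/8,
   σ²_Sample = (1/N_bin) Σᵢ (Cᵢ − μ_bin)²
   ```

   measures the excess variance of the angle distribution over the binomial
   null of randomly placed particles.  `O ≈ 0` for isotropic deposits and
   grows toward `(N_bin−1)(1−1/N)` when all bonds align (e.g. molecules
   self-organized along mica/HOPG lattice directions during slow drying).
   The statistic comes with its analytic uncertainty
   `σ_O = (σ²_bin/μ²_bin)√(2/N_bin)`, inverse-variance pooling across
   images, and a normal-tail p-value for the isotropy null.

2. **Droplet physics.**  Spherical-cap geometry (valid because the Bond
   number `Bo = ρgL²/γ ≈ 10⁻⁵`), Maxwell in-flight evaporation
   (`dV/dt = 4πR·D_v·Δc/ρ`, the R²-law), pinned-contact-line sessile drying
   (`dV/dt = −(πaD_vΔc/ρ)(0.27θ² + 1.30)`), Monte Carlo drying-time
   distributions for a lognormal droplet population, the diffusion
   displacement bound `√(4Dt)`, and a wet-coverage coalescence-regime
   classifier.

3. **Surface occupancy.**  Predicted surface density
   `λ = C·N_A·V_sprayed·efficiency / footprint`, the Poisson
   nearest-neighbour law `⟨r⟩ = 1/(2√λ)`, measured NN distance
   distributions, and per-particle cross-sectional heights against a local
   annulus background.

A `synthetic_afm` module generates particle fields with a tunable ordering
strength and renders them into noisy height maps, giving exact ground truth
for every statistic.

## Worked example

```python
import numpy as np
from spraydep import (
    AirState, Droplet, GenerationParams,
    generate_random_field, render_height_map, detect_maxima,
    nearest_neighbor_pairs, angle_histogram, order_parameter,
    diffusion_displacement, sessile_drying_time,
)
from spraydep.droplet_physics import contact_radius_from_volume

# deposit 50 molecules/um^2 on a 3x3 um field, render and re-detect
field = generate_random_field(50.0, (3000.0, 3000.0), GenerationParams(seed=1))
afm = render_height_map(field, pixel_size=4.0, noise_sd=0.05, seed=1)
maxima = detect_maxima(afm, threshold=0.2, noise_tolerance=0.1)
pairs = nearest_neighbor_pairs(maxima, afm.pixel_size)
result = order_parameter(angle_histogram(pairs))
print(f"O = {result.O:+.4f} +/- {result.sigma_O:.4f}  (N = {result.n_pairs} pairs)")

# how long does a 100 fL droplet live on the surface, and how far can a
# protein diffuse in that time?
a = contact_radius_from_volume(100.0, contact_angle_deg=15.3)
droplet = Droplet(volume_fl=100.0, contact_radius_um=a, contact_angle_deg=15.3)
t_dry = sessile_drying_time(droplet, AirState(temperature_c=25.0, relative_humidity=0.0))
print(f"t_dry = {t_dry:.1f} ms, diffusion bound = {diffusion_displacement(0.2, 2.0):.0f} nm")
```

Output:

```
O = -0.0046 +/- 0.0124  (N = 283 pairs)
t_dry = 5.4 ms, diffusion bound = 40 nm
```

The order parameter is zero within one standard deviation — the rendered
random deposit is isotropic, as it should be.  A 100 fL droplet (~200 µm²
imprint at a 15.3° contact angle) dries in ~5 ms, and during a typical 2 ms
drying window a protein with interfacial diffusivity 0.2 µm²/s can move at
most ~40 nm: deposition outruns surface mass transport.

A CLI wraps the same functions:

```bash
spraydep simulate --density 100 --order-strength 0 --seed 1 --out demo
spraydep order demo.tif --pixel-size 4.0 --threshold 0.2 --noise-tolerance 0.1
spraydep droplets --flow-rate 100 --distance 4 --rh 0.0
spraydep run --config run.yaml
```

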