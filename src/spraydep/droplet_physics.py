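"""Droplet geometry, evaporation, drying times and the coalescence regime.

A microfluidic spray nozzle emits subpicolitre water droplets that fly a few
centimetres to the substrate and dry in milliseconds.  Whether the deposition
preserves the solution state of the sprayed biomolecules hinges on a few
order-of-magnitude estimates, all implemented here:

* **Spherical-cap geometry.**  Droplet imprints of 50–250 µm² and a contact
  angle of ~15° have Bond numbers ``Bo = ρ g L² / γ`` of order 1e-5, so
  gravity is negligible and a sessile droplet is a spherical cap: contact
  radius ``a = sqrt(area/π)``, cap height ``h = a·tan(θ/2)``, volume
  ``V = π h (3a² + h²)/6``.

* **In-flight (Maxwell) evaporation.**  A sphere of radius R evaporating
  into still air loses volume at ``dV/dt = 4π R D_v Δc / ρ`` with
  ``Δc = c_sat(T)(1 − RH)``; equivalently R² decreases linearly in time
  (the R²-law), which is integrated in closed form over the flight.

* **Sessile (pinned contact line) evaporation.**  For contact angles below
  90° the contact line pins, and the diffusion-limited loss rate is
  ``dV/dt = −(π a D_v Δc / ρ)(0.27 θ² + 1.30)`` (θ in radians), constant in
  time, giving a drying time linear in the landed volume.

* **Diffusion displacement bound.**  The rms 2D displacement ``sqrt(4 D t)``
  of a protein on the liquid–solid interface during the drying window — the
  number that must stay small for the deposition to be artefact-free.

* **Coverage/coalescence regime.**  The fraction of the spray footprint that
  is wet at any instant decides whether droplets stay individual (regime I)
  or merge into streams (regime II).

Units contract: at the interface volumes are fL (= µm³), lengths µm (nozzle
distances cm, map coordinates nm), times ms, flow rates µl/h; internal
physics is SI with conversions at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AirState",
    "Droplet",
    "SprayConfig",
    "DropletEnsemble",
    "cap_volume",
    "cap_height",
    "imprint_area",
    "contact_radius_from_volume",
    "bond_number",
    "flight_evaporation_rate",
    "evolve_in_flight",
    "sessile_drying_time",
    "sessile_evaporation_rate",
    "drying_time_distribution",
    "drying_time_sensitivity",
    "diffusion_displacement",
    "coverage_and_regime",
    "sample_lognormal_volumes",
]

G = 9.81                    # m s^-2
R_GAS = 8.314462618         # J mol^-1 K^-1
M_WATER = 0.018015          # kg mol^-1
RHO_WATER = 997.0           # kg m^-3, ~25 degC
GAMMA_WATER = 0.072         # N m^-1, ~25 degC
D_VAPOR_DEFAULT = 2.5e-5    # m^2 s^-1, water vapour in air

# interquartile half-width of the standard normal, for lognormal (median, IQR) fits
_Z_QUARTILE = 0.6744897501960817


def saturation_vapor_pressure(temperature_c: float) -> float:
    """Saturation vapour pressure of water in Pa (Magnus relation)."""
    t = temperature_c
    return 610.94 * math.exp(17.625 * t / (t + 243.04))


@dataclass(frozen=True)
class AirState:
    """Ambient air driving evaporation.

    Defaults emulate standard air-conditioned laboratory conditions.
    """

    temperature_c: float = 25.0
    relative_humidity: float = 0.5
    vapor_diffusivity: float = D_VAPOR_DEFAULT  # m^2 s^-1

    def __post_init__(self) -> None:
        if not 0.0 <= self.relative_humidity <= 1.0:
            raise ValueError(
                f"relative_humidity must be in [0, 1], got {self.relative_humidity}"
            )
        if self.temperature_c <= -273.15:
            raise ValueError("temperature below absolute zero")

    @property
    def saturation_concentration(self) -> float:
        """Saturation vapour mass concentration c_sat in kg m^-3 (ideal gas)."""
        t_k = self.temperature_c + 273.15
        return saturation_vapor_pressure(self.temperature_c) * M_WATER / (R_GAS * t_k)

    @property
    def vapor_deficit(self) -> float:
        """Δc = c_sat (1 − RH) in kg m^-3, the driving force of evaporation."""
        return self.saturation_concentration * (1.0 - self.relative_humidity)


@dataclass(frozen=True)
class Droplet:
    """A single droplet, airborne (volume only) or sessile (with a, θ)."""

    volume_fl: float
    contact_radius_um: float | None = None
    contact_angle_deg: float | None = None
    density: float = RHO_WATER
    surface_tension: float = GAMMA_WATER

    def __post_init__(self) -> None:
        if self.volume_fl < 0:
            raise ValueError(f"volume must be >= 0, got {self.volume_fl}")
        if self.contact_angle_deg is not None and not 0 < self.contact_angle_deg < 90:
            raise ValueError(
                f"contact angle must be in (0, 90) deg for the pinned regime, "
                f"got {self.contact_angle_deg}"
            )

    @property
    def radius_um(self) -> float:
        """Equivalent spherical radius in µm (1 fL = 1 µm³)."""
        return (3.0 * self.volume_fl / (4.0 * math.pi)) ** (1.0 / 3.0)

    @property
    def fully_evaporated(self) -> bool:
        return self.volume_fl == 0.0


@dataclass(frozen=True)
class SprayConfig:
    """Nozzle-to-surface geometry and source droplet population."""

    flow_rate_ul_h: float = 100.0
    nozzle_distance_cm: float = 4.0
    cone_full_angle_deg: float = 18.0        # full apex angle; half-angle 9 deg
    droplet_velocity_m_s: float = 20.0       # measured range 10-30 m/s
    volume_median_fl: float = 100.0          # imprint-derived, 2 cm fluorescein
    volume_iqr_fl: tuple[float, float] = (40.0, 210.0)
    contact_angle_deg: float = 15.3          # fluorescein solution on glass

    def __post_init__(self) -> None:
        if self.flow_rate_ul_h < 0:
            raise ValueError("flow rate must be >= 0")
        if self.nozzle_distance_cm <= 0:
            raise ValueError("nozzle distance must be positive")
        if not 0 < self.cone_full_angle_deg < 90:
            raise ValueError("cone angle must be in (0, 90) degrees")

    @property
    def footprint_area_um2(self) -> float:
        """Area of the spray cone's intersection with the substrate, µm²."""
        r_um = self.nozzle_distance_cm * 1e4 * math.tan(
            math.radians(self.cone_full_angle_deg / 2.0)
        )
        return math.pi * r_um**2


@dataclass
class DropletEnsemble:
    """A droplet population with recomputable summary statistics."""

    droplets: list[Droplet] = field(default_factory=list)

    @property
    def volumes_fl(self) -> np.ndarray:
        return np.array([d.volume_fl for d in self.droplets])

    def summary(self) -> dict:
        v = self.volumes_fl
        landed = v[v > 0]
        out = {"n": len(self.droplets), "n_landed": int(landed.size)}
        if landed.size:
            q1, med, q3 = np.percentile(landed, [25, 50, 75])
            out.update(
                volume_median_fl=float(med),
                volume_iqr_fl=(float(q1), float(q3)),
            )
        return out


# ---------------------------------------------------------------------------
# spherical-cap geometry


def cap_height(contact_radius_um: float, contact_angle_deg: float) -> float:
    """Cap height h = a·tan(θ/2) in µm."""
    return contact_radius_um * math.tan(math.radians(contact_angle_deg) / 2.0)


def cap_volume(imprint_area_um2: float, contact_angle_deg: float) -> float:
    """Spherical-cap volume (fL) from the imprint area and contact angle.

    ``a = sqrt(area/π)``, ``h = a tan(θ/2)``, ``V = π h (3a² + h²)/6``.
    Valid for Bo ≪ 1, which holds for all spray droplets here.
    """
    if imprint_area_um2 <= 0:
        raise ValueError(f"imprint area must be positive, got {imprint_area_um2}")
    if not 0 < contact_angle_deg < 180:
        raise ValueError(f"contact angle must be in (0, 180), got {contact_angle_deg}")
    a = math.sqrt(imprint_area_um2 / math.pi)
    h = cap_height(a, contact_angle_deg)
    return math.pi * h * (3.0 * a**2 + h**2) / 6.0


def contact_radius_from_volume(volume_fl: float, contact_angle_deg: float) -> float:
    """Contact radius a (µm) of a spherical cap of given volume and angle.

    Inverse of :func:`cap_volume`: with t = tan(θ/2),
    ``V = (π a³ t / 6)(3 + t²)`` so ``a = (6V / (π t (3 + t²)))^{1/3}``.
    """
    if volume_fl <= 0:
        raise ValueError(f"volume must be positive, got {volume_fl}")
    t = math.tan(math.radians(contact_angle_deg) / 2.0)
    return (6.0 * volume_fl / (math.pi * t * (3.0 + t**2))) ** (1.0 / 3.0)


def imprint_area(volume_fl: float, contact_angle_deg: float) -> float:
    """Imprint (base) area in µm² of a sessile spherical cap."""
    a = contact_radius_from_volume(volume_fl, contact_angle_deg)
    return math.pi * a**2


def bond_number(
    length_scale_um: float,
    density: float = RHO_WATER,
    surface_tension: float = GAMMA_WATER,
) -> float:
    """Bond number Bo = ρ g L² / γ — gravity vs. capillarity.

    Bo ≪ 1 justifies the spherical-cap shape; the capillary length of water
    (~2.7 mm) is three orders of magnitude above spray-droplet scales.
    """
    if length_scale_um <= 0 or density <= 0 or surface_tension <= 0:
        raise ValueError("all Bond-number arguments must be positive")
    length_m = length_scale_um * 1e-6
    return density * G * length_m**2 / surface_tension


# ---------------------------------------------------------------------------
# evaporation


def flight_evaporation_rate(radius_um: float, air: AirState, density: float = RHO_WATER) -> float:
    """Diffusion-limited evaporation rate of an airborne sphere, fL/ms.

    Maxwell's quasi-steady result: ``dV/dt = 4π R D_v Δc / ρ``.  Saturated
    air (RH = 1) gives zero.
    """
    if radius_um <= 0:
        raise ValueError(f"radius must be positive, got {radius_um}")
    dv_dt_m3_s = 4.0 * math.pi * (radius_um * 1e-6) * air.vapor_diffusivity * air.vapor_deficit / density
    return dv_dt_m3_s * 1e18 / 1e3  # m^3/s -> fL/ms


def evolve_in_flight(
    droplet: Droplet,
    distance_cm: float,
    velocity_m_s: float,
    air: AirState,
) -> Droplet:
    """Shrink an airborne droplet over its flight using the R²-law.

    ``R(t)² = R₀² − K t`` with ``K = 2 D_v Δc / ρ`` follows from the Maxwell
    rate; the flight time is ``distance / velocity`` at constant velocity
    (drag-induced deceleration is neglected, consistent with an
    order-of-magnitude treatment).  A droplet that runs out of radius is
    returned with zero volume and flagged through ``fully_evaporated``.
    """
    if distance_cm < 0:
        raise ValueError("distance must be >= 0")
    if velocity_m_s <= 0:
        raise ValueError("velocity must be positive")
    if distance_cm == 0 or droplet.volume_fl == 0:
        return droplet
    t_s = (distance_cm * 1e-2) / velocity_m_s
    k_m2_s = 2.0 * air.vapor_diffusivity * air.vapor_deficit / droplet.density
    r0_m = droplet.radius_um * 1e-6
    r2 = r0_m**2 - k_m2_s * t_s
    if r2 <= 0:
        return replace(droplet, volume_fl=0.0)
    r_um = math.sqrt(r2) * 1e6
    return replace(droplet, volume_fl=(4.0 / 3.0) * math.pi * r_um**3)


def sessile_evaporation_rate(droplet: Droplet, air: AirState) -> float:
    """|dV/dt| of a pinned sessile cap, fL/ms.

    Diffusion-limited pinned-contact-line model:
    ``dV/dt = −(π a D_v Δc / ρ)(0.27 θ² + 1.30)`` with θ in radians — the
    standard small-angle expansion of the vapour-diffusion problem around a
    spherical cap.  The contact radius stays fixed, so the rate is constant
    throughout drying.
    """
    if droplet.contact_radius_um is None or droplet.contact_angle_deg is None:
        raise ValueError("sessile evaporation needs contact_radius_um and contact_angle_deg")
    theta = math.radians(droplet.contact_angle_deg)
    a_m = droplet.contact_radius_um * 1e-6
    rate_m3_s = (
        math.pi * a_m * air.vapor_diffusivity * air.vapor_deficit / droplet.density
    ) * (0.27 * theta**2 + 1.30)
    return rate_m3_s * 1e18 / 1e3


def sessile_drying_time(droplet: Droplet, air: AirState) -> float:
    """Time in ms for a pinned sessile droplet to dry completely.

    With a pinned line the loss rate is constant, so
    ``t_dry = V / |dV/dt|`` — linear in the landed volume.  In saturated air
    the result is ``inf``.
    """
    if air.vapor_deficit == 0.0:
        return math.inf
    rate = sessile_evaporation_rate(droplet, air)
    return droplet.volume_fl / rate


def drying_time_sensitivity(
    droplet: Droplet,
    air: AirState,
    delta_t_c: float = 2.0,
    delta_rh: float = 0.10,
) -> dict:
    """Change in drying time under (ΔT, ΔRH) ambient perturbations.

    Reports the drying time at the nominal state and at the four one-sided
    perturbations, plus the largest absolute excursion — the quantity that
    decides whether day-to-day laboratory drift matters for deposition.
    """
    base = sessile_drying_time(droplet, air)
    out = {"drying_time_ms": base}
    excursions = []
    for name, st in {
        "t_plus": replace(air, temperature_c=air.temperature_c + delta_t_c),
        "t_minus": replace(air, temperature_c=air.temperature_c - delta_t_c),
        "rh_plus": replace(air, relative_humidity=min(1.0, air.relative_humidity + delta_rh)),
        "rh_minus": replace(air, relative_humidity=max(0.0, air.relative_humidity - delta_rh)),
    }.items():
        t = sessile_drying_time(droplet, st)
        out[f"drying_time_ms_{name}"] = t
        if math.isfinite(t) and math.isfinite(base):
            excursions.append(abs(t - base))
    out["max_abs_change_ms"] = max(excursions) if excursions else math.inf
    return out


def sample_lognormal_volumes(
    median_fl: float,
    iqr_fl: tuple[float, float],
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample droplet volumes from a lognormal fit to (median, IQR) summaries.

    ``μ = ln(median)``; σ is chosen so the fitted quartiles reproduce the
    ratio q3/q1 (quantile matching): ``σ = ln(q3/q1) / (2 z_0.75)``.
    """
    if median_fl <= 0 or iqr_fl[0] <= 0 or iqr_fl[1] <= iqr_fl[0]:
        raise ValueError("need 0 < q1 < q3 and a positive median")
    mu = math.log(median_fl)
    sigma = math.log(iqr_fl[1] / iqr_fl[0]) / (2.0 * _Z_QUARTILE)
    return rng.lognormal(mean=mu, sigma=sigma, size=n)


def drying_time_distribution(
    ensemble: DropletEnsemble,
    config: SprayConfig,
    air: AirState,
) -> dict:
    """Per-droplet flight + landing + sessile-drying pipeline, summarized.

    Each source droplet evaporates in flight over ``config.nozzle_distance_cm``
    at ``config.droplet_velocity_m_s``; survivors land, conserve volume into a
    spherical cap at ``config.contact_angle_deg``, and dry with a pinned
    contact line.  Returns the median and interquartile range of landed volume
    (fL) and drying time (ms), plus the count of droplets lost in flight.
    """
    if not ensemble.droplets:
        raise ValueError("cannot process an empty ensemble")
    landed_v, times = [], []
    n_lost = 0
    for d in ensemble.droplets:
        flown = evolve_in_flight(d, config.nozzle_distance_cm, config.droplet_velocity_m_s, air)
        if flown.fully_evaporated:
            n_lost += 1
            continue
        a = contact_radius_from_volume(flown.volume_fl, config.contact_angle_deg)
        sessile = replace(
            flown, contact_radius_um=a, contact_angle_deg=config.contact_angle_deg
        )
        landed_v.append(sessile.volume_fl)
        times.append(sessile_drying_time(sessile, air))
    out = {
        "n": len(ensemble.droplets),
        "n_landed": len(landed_v),
        "n_fully_evaporated": n_lost,
    }
    if landed_v:
        v = np.asarray(landed_v)
        t = np.asarray(times)
        vq = np.percentile(v, [25, 50, 75])
        tq = np.percentile(t, [25, 50, 75])
        out.update(
            landed_volume_median_fl=float(vq[1]),
            landed_volume_iqr_fl=(float(vq[0]), float(vq[2])),
            drying_time_median_ms=float(tq[1]),
            drying_time_iqr_ms=(float(tq[0]), float(tq[2])),
        )
    return out


def diffusion_displacement(diffusivity_um2_s: float, time_ms: float) -> float:
    """RMS 2D displacement √(4Dt) in nm.

    Upper bound on how far a protein can move on the liquid–solid interface
    during the drying window; D of 0.1–0.3 µm²/s is typical for a ~10 nm
    polypeptide chain or small aggregate at the interface.
    """
    if diffusivity_um2_s < 0 or time_ms < 0:
        raise ValueError("diffusivity and time must be >= 0")
    return math.sqrt(4.0 * diffusivity_um2_s * time_ms * 1e-3) * 1e3  # um -> nm


def coverage_and_regime(
    config: SprayConfig,
    median_volume_fl: float,
    mean_imprint_area_um2: float,
    drying_time_ms: float,
    coalescence_threshold: float = 0.05,
) -> dict:
    """Wet-area coverage of the spray footprint and the coalescence regime.

    Droplets arrive at rate Q/V_median; during one drying window each wets
    ``mean_imprint_area`` of the footprint ``π (d tanα)²``.  The expected
    fractional wet coverage is ``rate × t_dry × area / footprint``.  Below
    ``coalescence_threshold`` the deposit stays as well-resolved individual
    droplets (regime I); above it incoming droplets overlap ones still wet
    and merge into streams (regime II).  The overlap probability for a single
    arriving droplet follows a Poisson area-overlap model,
    ``p = 1 − exp(−coverage)``.
    """
    if config.footprint_area_um2 <= 0:
        raise ValueError("spray footprint must be positive")
    if median_volume_fl <= 0:
        raise ValueError("median droplet volume must be positive")
    q_fl_ms = config.flow_rate_ul_h * 1e9 / 3.6e6  # ul/h -> fL/ms
    arrival_per_ms = q_fl_ms / median_volume_fl
    n_wet = arrival_per_ms * drying_time_ms
    coverage = n_wet * mean_imprint_area_um2 / config.footprint_area_um2
    return {
        "arrival_rate_per_ms": arrival_per_ms,
        "droplets_per_drying_window": n_wet,
        "wet_coverage_fraction": coverage,
        "coalescence_probability": 1.0 - math.exp(-coverage),
        "regime": "I" if coverage < coalescence_threshold else "II",
    }
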