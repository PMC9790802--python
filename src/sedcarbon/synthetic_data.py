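"""Synthetic core-sample surveys with the structure of a small mangrove
blue-carbon field campaign.

The generator emulates a bay-scale survey: a handful of mangrove locations,
sampling sites nested within location (random blocks), two or three depth
strata per core, and up to four instruments (soil probe, open-faced corer,
Russian peat corer, spade-cut reference aggregate) that do not always
penetrate every substrate — the Russian corer refuses wet sand, and spade
aggregates can only be dug from non-waterlogged surface layers.  With the
default design (3 locations, 7 sites, shallow/mid everywhere plus a deep
stratum at two sites) the expected yield is ~52 samples.

True bulk density at a site x depth comes from the mixing model at the
generating parameters, plus small additive site and instrument offsets;
gravimetric measurement applies multiplicative noise to the bulk density,
and the elemental-analyzer carbon fraction gets small additive noise.  Dry
mass is back-computed as measured density x corer volume, so a written CSV
round-trips to exactly the generated measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_model import (
    CorerGeometry,
    MixingParams,
    STANDARD_CORERS,
    bulk_density_from_carbon,
    corer_sample_volume,
)

__all__ = ["CoreSample", "SurveySpec", "generate_survey", "generate_loi_calibration"]


@dataclass
class CoreSample:
    """One dated core segment: hierarchy labels, instrument, geometry, dry
    mass and carbon fraction.  Bulk density is derived, never stored:
    dry mass / corer segment volume."""

    sample_id: str
    location: str
    site: str
    depth_label: str
    depth_cm: float
    instrument: str
    geometry: CorerGeometry
    dry_mass_g: float
    carbon_fraction: float
    loi_fraction: float | None = None
    true_bulk_density: float | None = None

    def __post_init__(self) -> None:
        if self.dry_mass_g < 0:
            raise ValueError("dry mass must be non-negative")
        if not (0.0 <= self.carbon_fraction <= 1.0):
            raise ValueError("carbon fraction must be a proportion in [0, 1]")

    @property
    def volume_cm3(self) -> float:
        return corer_sample_volume(self.geometry)

    @property
    def bulk_density(self) -> float:
        """Gravimetric bulk density, g cm^-3."""
        return self.dry_mass_g / self.volume_cm3


@dataclass(frozen=True)
class SurveySpec:
    """Design and error structure of a synthetic survey.

    ``locations`` maps location code to its site codes; every site gets the
    shallow and mid strata, and sites listed in ``deep_sites`` also get the
    deep one.  ``availability`` is the per-stratum probability that an
    instrument yields a sample (the spade additionally being restricted to
    the shallow stratum).  Carbon fractions are drawn per site x depth from
    a two-component Beta family on [0, 1/f] — carbon-poor for mineral
    (sand/clay/mud) sites, carbon-rich for the peaty sites listed in
    ``peaty_sites`` — so organic-content-dependent dispersion is visible at
    survey scale.  Offsets are additive on bulk density in g cm^-3.
    """

    locations: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {"C": ("C1", "C2", "C3"), "M": ("M1", "M2"), "X": ("X1", "X2")}
    )
    depth_strata: tuple[tuple[str, float], ...] = (
        ("shallow", 15.0),
        ("mid", 40.0),
        ("deep", 85.0),
    )
    deep_sites: tuple[str, ...] = ("C1", "M1")
    instruments: tuple[str, ...] = ("soil_probe", "open_faced", "russian", "spade")
    availability: dict[str, float] = field(
        default_factory=lambda: {
            "soil_probe": 1.0,
            "open_faced": 1.0,
            "russian": 0.875,
            "spade": 6.0 / 7.0,
        }
    )
    true_params: MixingParams = field(default_factory=MixingParams)
    peaty_sites: tuple[str, ...] = ("C1", "C2", "M1")
    c_beta_mineral: tuple[float, float] = (1.5, 8.0)
    c_beta_peaty: tuple[float, float] = (6.0, 2.5)
    instrument_offsets: dict[str, float] = field(
        default_factory=lambda: {"soil_probe": 0.03, "spade": 0.03}
    )
    site_offsets: dict[str, float] = field(default_factory=lambda: {"M2": -0.05})
    cv_delta_measurement: float = 0.10
    sd_c_measurement: float = 0.005
    cv_c_measurement: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.cv_delta_measurement, self.sd_c_measurement, self.cv_c_measurement) < 0:
            raise ValueError("noise magnitudes must be non-negative")
        for instr in self.instruments:
            if instr not in STANDARD_CORERS:
                raise ValueError(f"unknown instrument {instr!r}")
            p = self.availability.get(instr, 1.0)
            if not (0.0 <= p <= 1.0):
                raise ValueError("availability must be a probability")
        # an offset combination that can push bulk density to zero or below
        # makes the spec physically meaningless; reject it up front
        worst = (
            self.true_params.delta_p
            + min([0.0, *self.site_offsets.values()])
            + min([0.0, *self.instrument_offsets.values()])
        )
        if worst <= 0:
            raise ValueError(
                "site/instrument offsets can drive bulk density below zero; "
                "reduce the offsets or raise delta_p"
            )


def generate_survey(spec: SurveySpec, oracle: bool = False) -> list[CoreSample]:
    """Generate one survey according to ``spec``; seed-deterministic.

    Per site x depth stratum one true carbon fraction is drawn and the true
    bulk density computed from the mixing model plus the site offset; every
    available instrument then measures that stratum with its own additive
    offset, multiplicative bulk-density noise and additive carbon-fraction
    noise.  When ``oracle`` is true each sample also carries the noise-free
    bulk density for ground-truth tests.
    """
    rng = np.random.default_rng(spec.seed)
    params = spec.true_params
    cmax = params.c_max
    samples: list[CoreSample] = []

    for location, sites in spec.locations.items():
        for site in sites:
            a, b = spec.c_beta_peaty if site in spec.peaty_sites else spec.c_beta_mineral
            for depth_label, depth_cm in spec.depth_strata:
                if depth_label == "deep" and site not in spec.deep_sites:
                    continue
                true_c = float(rng.beta(a, b) * cmax)
                base_delta = bulk_density_from_carbon(true_c, params) + spec.site_offsets.get(
                    site, 0.0
                )
                for instrument in spec.instruments:
                    if instrument == "spade" and depth_label != "shallow":
                        continue
                    if rng.random() >= spec.availability.get(instrument, 1.0):
                        continue
                    true_delta = base_delta + spec.instrument_offsets.get(instrument, 0.0)
                    measured_delta = true_delta * (
                        1.0 + rng.normal(0.0, spec.cv_delta_measurement)
                    )
                    measured_delta = max(measured_delta, 1e-6)
                    # carbon-fraction error: an additive analyzer floor plus
                    # an optional relative (CV) component
                    c_noise = true_c * rng.normal(0.0, spec.cv_c_measurement) + rng.normal(
                        0.0, spec.sd_c_measurement
                    )
                    measured_c = float(np.clip(true_c + c_noise, 0.0, cmax))
                    geometry = STANDARD_CORERS[instrument]
                    samples.append(
                        CoreSample(
                            sample_id=f"{site}-{depth_label}-{instrument}",
                            location=location,
                            site=site,
                            depth_label=depth_label,
                            depth_cm=depth_cm,
                            instrument=instrument,
                            geometry=geometry,
                            dry_mass_g=measured_delta * corer_sample_volume(geometry),
                            carbon_fraction=measured_c,
                            true_bulk_density=true_delta if oracle else None,
                        )
                    )
    return samples


def generate_loi_calibration(
    n: int, f_true: float = 2.2, noise_sd: float = 0.05, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Paired (carbon fraction, loss-on-ignition) calibration data.

    LOI = f_true * C plus additive Gaussian noise, clipped to [0, 1];
    carbon fractions are uniform on the valid domain.  Returns ``(c, loi)``.
    """
    if n < 3:
        raise ValueError("need at least 3 calibration pairs")
    rng = np.random.default_rng(seed)
    c = rng.uniform(0.0, 1.0 / f_true, n)
    loi = np.clip(f_true * c + rng.normal(0.0, noise_sd, n), 0.0, 1.0)
    return c, loi
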