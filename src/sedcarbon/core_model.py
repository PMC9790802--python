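"""Ideal mixing model for waterlogged-sediment bulk density, and corer geometry.

The bulk density of a peat-mineral sediment mixture follows a harmonic
(ideal volumetric) mixing law: a sample that is a proportion ``O`` organic
matter by mass occupies the summed volumes of its organic and mineral
components, each at its own self-packing density.  With ``delta_p`` the
self-packing bulk density of pure peat and ``delta_m`` that of pure mineral
sediment,

    delta(O) = delta_p * delta_m / (delta_m * O + delta_p * (1 - O))

equivalently  1/delta = O/delta_p + (1 - O)/delta_m.

Organic-matter proportion is obtained from elemental carbon fraction ``C``
through a conversion factor ``f`` (organic matter ~ f * C, f ~ 2.2, i.e.
organic matter is ~45% carbon), so bulk density and carbon density
(D = C * delta) become functions of the carbon fraction alone.

Everything in this module is deterministic and vectorised over numpy
arrays; it is the mathematical core every other module calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MixingParams",
    "CorerGeometry",
    "DEFAULT_PARAMS",
    "STANDARD_CORERS",
    "DOMAIN_TOL",
    "organic_from_carbon",
    "bulk_density_from_organic",
    "bulk_density_from_carbon",
    "carbon_density_mixing",
    "carbon_density_gravimetric",
    "carbon_density_slope",
    "corer_sample_volume",
]

#: Tolerance for domain checks on proportions (f*C may exceed 1 by at most this).
DOMAIN_TOL = 1e-9


@dataclass(frozen=True)
class MixingParams:
    """Parameters of the peat-mineral mixing model.

    Attributes
    ----------
    delta_p : float
        Self-packing bulk density of pure peat, g cm^-3.
    delta_m : float
        Self-packing bulk density of pure mineral sediment, g cm^-3.
    f : float
        Carbon-fraction -> organic-matter conversion factor (dimensionless,
        >= 1).  ``f = 2.2`` corresponds to organic matter that is ~45% carbon.

    The defaults (0.085, 1.65, 2.2) are conservative literature-consensus
    values for coastal wetland sediments.
    """

    delta_p: float = 0.085
    delta_m: float = 1.65
    f: float = 2.2

    def __post_init__(self) -> None:
        if not (0.0 < self.delta_p < self.delta_m):
            raise ValueError(
                f"require 0 < delta_p < delta_m, got delta_p={self.delta_p}, "
                f"delta_m={self.delta_m}"
            )
        if self.f < 1.0:
            raise ValueError(f"conversion factor f must be >= 1, got {self.f}")

    @property
    def c_max(self) -> float:
        """Largest admissible carbon fraction, 1/f (pure organic matter)."""
        return 1.0 / self.f


#: Module-wide default parameterisation.
DEFAULT_PARAMS = MixingParams()


@dataclass(frozen=True)
class CorerGeometry:
    """Geometry of one corer's sample segment.

    ``shape`` is one of ``cylinder``, ``half_cylinder``, ``constant_area``,
    ``rectangular_prism``.  Only the fields relevant to the shape need be
    set; all lengths in cm, areas in cm^2.
    """

    shape: str
    segment_length_cm: float
    diameter_cm: float | None = None
    cross_section_cm2: float | None = None
    edge_lengths_cm: tuple[float, float] | None = None

    _SHAPES = ("cylinder", "half_cylinder", "constant_area", "rectangular_prism")

    def __post_init__(self) -> None:
        if self.shape not in self._SHAPES:
            raise ValueError(f"unknown corer shape {self.shape!r}; one of {self._SHAPES}")
        if self.segment_length_cm <= 0:
            raise ValueError("segment_length_cm must be positive")
        if self.shape in ("cylinder", "half_cylinder"):
            if self.diameter_cm is None or self.diameter_cm <= 0:
                raise ValueError(f"{self.shape} requires positive diameter_cm")
        elif self.shape == "constant_area":
            if self.cross_section_cm2 is None or self.cross_section_cm2 <= 0:
                raise ValueError("constant_area requires positive cross_section_cm2")
        else:  # rectangular_prism
            if self.edge_lengths_cm is None or any(e <= 0 for e in self.edge_lengths_cm):
                raise ValueError("rectangular_prism requires two positive edge lengths")


#: Geometries of the four standard instruments: a 17 mm soil probe cutting
#: 5 cm segments, a 6 cm open-faced corer and an 8.81 cm^2 Russian peat
#: corer cutting 3 cm segments, and a spade-cut 3 cm reference cube.
STANDARD_CORERS: dict[str, CorerGeometry] = {
    "soil_probe": CorerGeometry("cylinder", segment_length_cm=5.0, diameter_cm=1.7),
    "open_faced": CorerGeometry("half_cylinder", segment_length_cm=3.0, diameter_cm=6.0),
    "russian": CorerGeometry("constant_area", segment_length_cm=3.0, cross_section_cm2=8.81),
    "spade": CorerGeometry("rectangular_prism", segment_length_cm=3.0, edge_lengths_cm=(3.0, 3.0)),
}


def _check_carbon(c, params: MixingParams):
    c = np.asarray(c, dtype=float)
    if np.any(c < -DOMAIN_TOL):
        raise ValueError("carbon fraction must be non-negative")
    fc = params.f * c
    if np.any(fc > 1.0 + DOMAIN_TOL):
        bad = float(np.max(c))
        raise ValueError(
            f"carbon fraction {bad:g} implies organic matter f*C = {params.f * bad:g} > 1 "
            f"(more than 100% organic matter); valid domain is [0, {params.c_max:g}]. "
            "If values are percentages, convert to proportions first."
        )
    return c


def organic_from_carbon(c, params: MixingParams = DEFAULT_PARAMS):
    """Organic-matter proportion O = f*C, for carbon fraction ``c`` in [0, 1/f].

    Values of ``f*C`` beyond 1 by more than ``DOMAIN_TOL`` are rejected
    (a silent clamp would hide percent-vs-proportion unit mistakes);
    overshoot within tolerance is clipped to 1.
    """
    c = _check_carbon(c, params)
    o = np.clip(params.f * c, 0.0, 1.0)
    return float(o) if o.ndim == 0 else o


def bulk_density_from_organic(o, params: MixingParams = DEFAULT_PARAMS):
    """Mixing-model bulk density (g cm^-3) at organic-matter proportion ``o``.

    Lies between ``delta_p`` (pure peat, o=1) and ``delta_m`` (pure
    mineral, o=0) and decreases monotonically in ``o``.
    """
    o = np.asarray(o, dtype=float)
    if np.any(o < -DOMAIN_TOL) or np.any(o > 1.0 + DOMAIN_TOL):
        raise ValueError("organic-matter proportion must lie in [0, 1]")
    o = np.clip(o, 0.0, 1.0)
    dp, dm = params.delta_p, params.delta_m
    delta = dp * dm / (dm * o + dp * (1.0 - o))
    return float(delta) if delta.ndim == 0 else delta


def bulk_density_from_carbon(c, params: MixingParams = DEFAULT_PARAMS):
    """Mixing-model bulk density (g cm^-3) at carbon fraction ``c``:
    delta_p*delta_m / (delta_m*f*C + delta_p*(1 - f*C))."""
    return bulk_density_from_organic(organic_from_carbon(c, params), params)


def carbon_density_mixing(c, params: MixingParams = DEFAULT_PARAMS):
    """Carbon density D = C * delta(C) (g C cm^-3) predicted from carbon
    fraction alone through the mixing model.  Strictly increasing in C,
    from 0 at C=0 to delta_p/f at the pure-peat endpoint C=1/f."""
    c = _check_carbon(c, params)
    d = c * bulk_density_from_carbon(c, params)
    return float(d) if np.ndim(d) == 0 else d


def carbon_density_gravimetric(c, bulk_density):
    """Carbon density D = C * delta_measured (g C cm^-3) from a measured
    (gravimetric) bulk density: the conventional product estimator."""
    c = np.asarray(c, dtype=float)
    delta = np.asarray(bulk_density, dtype=float)
    if np.any(c < 0) or np.any(c > 1):
        raise ValueError("carbon fraction must lie in [0, 1]")
    if np.any(delta <= 0):
        raise ValueError("bulk density must be positive")
    d = c * delta
    return float(d) if d.ndim == 0 else d


def carbon_density_slope(c, params: MixingParams = DEFAULT_PARAMS):
    """First derivative dD/dC of the mixing-model carbon density.

    Differentiating D = C * delta_p*delta_m / (delta_p + f*C*(delta_m - delta_p))
    gives dD/dC = delta_C**2 / delta_m, where delta_C is the model-predicted
    bulk density at carbon fraction C.  (Equivalent forms with delta_p in the
    denominator circulate in the literature; the delta_m form is the one that
    matches finite differences of D.)  Positive everywhere on the valid
    domain and decreasing in C: errors in the carbon fraction propagate least
    in peaty, carbon-rich sediments.
    """
    c = _check_carbon(c, params)
    delta_c = bulk_density_from_carbon(c, params)
    slope = np.asarray(delta_c, dtype=float) ** 2 / params.delta_m
    return float(slope) if slope.ndim == 0 else slope


def corer_sample_volume(geometry: CorerGeometry) -> float:
    """Volume in cm^3 of one core segment for the given geometry.

    cylinder: pi (d/2)^2 L;  half_cylinder: half that;
    constant_area: cross-section x L;  rectangular_prism: product of edges x L.
    """
    L = geometry.segment_length_cm
    if geometry.shape == "cylinder":
        return float(np.pi * (geometry.diameter_cm / 2.0) ** 2 * L)
    if geometry.shape == "half_cylinder":
        return float(np.pi * (geometry.diameter_cm / 2.0) ** 2 * L / 2.0)
    if geometry.shape == "constant_area":
        return float(geometry.cross_section_cm2 * L)
    e1, e2 = geometry.edge_lengths_cm
    return float(e1 * e2 * L)
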