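"""CSV input/output for core-sample tables and run configuration.

The on-disk format is a plain UTF-8, comma-separated table with one row
per core segment and columns

    sample_id, location, site, depth_label, depth_cm, instrument, shape,
    diameter_cm, cross_section_cm2, segment_length_cm, dry_mass_g,
    carbon_fraction [, loi_fraction, true_bulk_density]

Optional fields are left blank.  For rectangular-prism (spade) samples the
horizontal cross-section is stored as an area in ``cross_section_cm2``.
Carbon fraction is a proportion; files recorded in percent are accepted
only with an explicit flag so that unit mistakes fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core_model import CorerGeometry, MixingParams
from .synthetic_data import CoreSample

__all__ = [
    "CSV_COLUMNS",
    "RunConfig",
    "samples_to_frame",
    "read_samples",
    "write_samples",
    "read_pairs",
    "carbon_stock_per_hectare",
]

CSV_COLUMNS = [
    "sample_id",
    "location",
    "site",
    "depth_label",
    "depth_cm",
    "instrument",
    "shape",
    "diameter_cm",
    "cross_section_cm2",
    "segment_length_cm",
    "dry_mass_g",
    "carbon_fraction",
    "loi_fraction",
]

_REQUIRED = [
    "sample_id",
    "location",
    "site",
    "depth_label",
    "depth_cm",
    "instrument",
    "shape",
    "segment_length_cm",
    "dry_mass_g",
    "carbon_fraction",
]


def samples_to_frame(samples: list[CoreSample]) -> pd.DataFrame:
    """Tidy DataFrame view of a sample list, with derived ``bulk_density``."""
    rows = []
    for s in samples:
        g = s.geometry
        cross = g.cross_section_cm2
        if g.shape == "rectangular_prism":
            cross = g.edge_lengths_cm[0] * g.edge_lengths_cm[1]
        rows.append(
            {
                "sample_id": s.sample_id,
                "location": s.location,
                "site": s.site,
                "depth_label": s.depth_label,
                "depth_cm": s.depth_cm,
                "instrument": s.instrument,
                "shape": g.shape,
                "diameter_cm": g.diameter_cm,
                "cross_section_cm2": cross,
                "segment_length_cm": g.segment_length_cm,
                "dry_mass_g": s.dry_mass_g,
                "carbon_fraction": s.carbon_fraction,
                "loi_fraction": s.loi_fraction,
                "true_bulk_density": s.true_bulk_density,
                "bulk_density": s.bulk_density,
            }
        )
    return pd.DataFrame(rows)


def write_samples(samples: list[CoreSample], path: str | Path) -> None:
    """Write samples as CSV.  Derived and oracle columns are dropped unless
    any sample actually carries a true bulk density."""
    frame = samples_to_frame(samples)
    cols = list(CSV_COLUMNS)
    if frame["true_bulk_density"].notna().any():
        cols.append("true_bulk_density")
    # 17 significant digits reproduce an IEEE double exactly, so measured
    # bulk densities survive a write -> read round trip bit-for-bit
    frame[cols].to_csv(path, index=False, float_format="%.17g")


def _geometry_from_row(row: pd.Series) -> CorerGeometry:
    shape = row["shape"]
    L = float(row["segment_length_cm"])
    if shape in ("cylinder", "half_cylinder"):
        return CorerGeometry(shape, segment_length_cm=L, diameter_cm=float(row["diameter_cm"]))
    if shape == "constant_area":
        return CorerGeometry(
            shape, segment_length_cm=L, cross_section_cm2=float(row["cross_section_cm2"])
        )
    if shape == "rectangular_prism":
        # only the horizontal area is stored; edges are recovered as a
        # square of the same area (the volume is what downstream code uses)
        area = float(row["cross_section_cm2"])
        edge = float(np.sqrt(area))
        return CorerGeometry(shape, segment_length_cm=L, edge_lengths_cm=(edge, edge))
    raise ValueError(f"unknown corer shape {shape!r} in file")


def read_samples(path: str | Path, percent: bool = False) -> list[CoreSample]:
    """Read a core-sample CSV into validated :class:`CoreSample` records.

    ``percent=True`` divides carbon (and LOI) fractions by 100.  Without
    it, any carbon fraction above 1 raises with advice to pass the flag —
    a silent rescale would corrupt every downstream density.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _REQUIRED if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in ("depth_cm", "segment_length_cm", "dry_mass_g", "carbon_fraction"):
        if not np.issubdtype(frame[col].dtype, np.number):
            raise ValueError(f"{path}: column {col!r} contains non-numeric values")

    c = frame["carbon_fraction"].to_numpy(dtype=float)
    if percent:
        c = c / 100.0
    elif np.any(c > 1.0):
        raise ValueError(
            f"{path}: carbon_fraction values above 1 look like percentages; "
            "pass percent=True (CLI: --percent) if so"
        )

    samples = []
    for i, row in frame.iterrows():
        loi = row.get("loi_fraction")
        if loi is not None and pd.isna(loi):
            loi = None
        elif loi is not None and percent:
            loi = float(loi) / 100.0
        true_bd = row.get("true_bulk_density")
        if true_bd is not None and pd.isna(true_bd):
            true_bd = None
        samples.append(
            CoreSample(
                sample_id=str(row["sample_id"]),
                location=str(row["location"]),
                site=str(row["site"]),
                depth_label=str(row["depth_label"]),
                depth_cm=float(row["depth_cm"]),
                instrument=str(row["instrument"]),
                geometry=_geometry_from_row(row),
                dry_mass_g=float(row["dry_mass_g"]),
                carbon_fraction=float(c[i]),
                loi_fraction=None if loi is None else float(loi),
                true_bulk_density=None if true_bd is None else float(true_bd),
            )
        )
    return samples


def read_pairs(path: str | Path, percent: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Read a bare two-column (carbon_fraction, bulk_density) CSV for
    fit-only use.  Headerless files are accepted if they have two numeric
    columns."""
    frame = pd.read_csv(path, float_precision="round_trip")
    cols = [c.strip().lower() for c in frame.columns]
    if "carbon_fraction" in cols and "bulk_density" in cols:
        frame.columns = cols
        c = frame["carbon_fraction"].to_numpy(dtype=float)
        d = frame["bulk_density"].to_numpy(dtype=float)
    elif frame.shape[1] == 2:
        frame = pd.read_csv(path, header=None, float_precision="round_trip")
        c = frame.iloc[:, 0].to_numpy(dtype=float)
        d = frame.iloc[:, 1].to_numpy(dtype=float)
    else:
        raise ValueError(
            f"{path}: expected columns (carbon_fraction, bulk_density) or a bare two-column file"
        )
    if percent:
        c = c / 100.0
    elif np.any(c > 1.0):
        raise ValueError(f"{path}: carbon fractions above 1 look like percentages")
    return c, d


def carbon_stock_per_hectare(carbon_density_g_cm3, depth_interval_cm) -> float:
    """Display helper: Mg C ha^-1 contributed by a depth interval at a given
    carbon density (x100 per cm of depth).  Provided for reporting
    convenience only; depth-integrated stocks are outside the estimation
    machinery of this package."""
    return float(carbon_density_g_cm3) * float(depth_interval_cm) * 100.0


@dataclass
class RunConfig:
    """Pipeline configuration (YAML-loadable).

    Numeric defaults mirror the package defaults: mixing parameters
    (0.085, 1.65, 2.2), Gauss-Newton tolerances, the sequential factor
    order for the variance decomposition, and the Monte Carlo spec fields.
    """

    input: str | None = None
    output: str | None = None
    delta_p: float = 0.085
    delta_m: float = 1.65
    f: float = 2.2
    fit_init: tuple[float, float] = (0.1, 1.6)
    fit_tol_ss: float = 1e-10
    fit_tol_step: float = 1e-8
    fit_max_iter: int = 100
    factor_order: tuple[str, ...] = ("instrument", "site", "location", "depth_label")
    mc: dict = field(default_factory=dict)
    seed: int = 0
    verbosity: str = "INFO"

    @property
    def params(self) -> MixingParams:
        return MixingParams(self.delta_p, self.delta_m, self.f)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        if "fit_init" in known:
            known["fit_init"] = tuple(known["fit_init"])
        if "factor_order" in known:
            known["factor_order"] = tuple(known["factor_order"])
        return cls(**known)
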