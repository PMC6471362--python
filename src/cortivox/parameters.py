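"""Microstructural and macrostructural parameter model.

Cortical (compact) bone is organised around osteons: roughly cylindrical
units, aligned with the long axis of the bone, each carrying a central
Haversian canal and wrapped in a thin mineralised cement line.  Transverse
Volkmann's canals interconnect the Haversian canals.  The generator is
driven by eight microstructural inputs (diameter ranges, densities,
inclination angles, canal spacing) plus a macroscopic generation volume
and a master seed.

This module defines those inputs, their healthy admissible ranges from the
histomorphometry literature, the deterministic seed-substream schema, and
the uniform-sampling contract used for every stochastic draw.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from shapely.geometry import Point, Polygon

__all__ = [
    "Range",
    "ParameterSet",
    "MacroShape",
    "SeedSchema",
    "AdmissibleRanges",
    "Violation",
    "validate_parameters",
    "resolve_macroshape",
    "sample_from_range",
    "load_config",
    "dump_config",
]


@dataclass(frozen=True)
class Range:
    """Closed interval [lo, hi] a parameter value is drawn from.

    Units are those of the parameter the range belongs to (micrometres for
    lengths and diameters, degrees for angles).
    """

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lo) and math.isfinite(self.hi)):
            raise ValueError(f"Range bounds must be finite, got ({self.lo}, {self.hi})")
        if self.lo > self.hi:
            raise ValueError(f"Range requires lo <= hi, got ({self.lo}, {self.hi})")
        if self.lo < 0:
            raise ValueError(f"Range bounds must be non-negative, got ({self.lo}, {self.hi})")

    @property
    def width(self) -> float:
        return self.hi - self.lo

    @property
    def mid(self) -> float:
        return 0.5 * (self.lo + self.hi)

    def __contains__(self, x: float) -> bool:
        return self.lo <= x <= self.hi

    @classmethod
    def coerce(cls, value: "Range | Sequence[float] | float") -> "Range":
        """Accept a Range, a (lo, hi) pair, or a scalar (degenerate range)."""
        if isinstance(value, Range):
            return value
        if isinstance(value, (int, float)):
            return cls(float(value), float(value))
        lo, hi = value
        return cls(float(lo), float(hi))


@dataclass(frozen=True)
class ParameterSet:
    """The eight microstructural inputs of the generator.

    Attributes
    ----------
    osteon_diameter : Range
        Osteon diameter range (OnDr), µm.
    osteon_density : float
        Osteon density (OnDn), osteons per mm² of transverse cross-section.
    osteon_inclination : Range
        Osteon inclination angle range from the longitudinal Z axis
        (thetaOn), degrees.
    cement_thickness : Range
        Cement line thickness range (CLT), µm.
    haversian_diameter : Range
        Haversian canal diameter range (HCDR), µm.
    volkmann_diameter : Range
        Volkmann's canal diameter range (VCDR), µm.
    volkmann_spacing : Range
        Distance between Volkmann's canals measured along the osteon axis
        (DBVC), µm; sets the spacing of interconnection points.
    volkmann_inclination_max : float
        Maximum inclination of a Volkmann's canal from the transverse
        (XY) plane (thetaVC), degrees.
    """

    osteon_diameter: Range
    osteon_density: float
    osteon_inclination: Range
    cement_thickness: Range
    haversian_diameter: Range
    volkmann_diameter: Range
    volkmann_spacing: Range
    volkmann_inclination_max: float

    def __post_init__(self) -> None:
        if self.osteon_density <= 0:
            raise ValueError("osteon_density must be > 0")
        if not (0.0 <= self.osteon_inclination.lo and self.osteon_inclination.hi < 90.0):
            raise ValueError("osteon_inclination must lie within [0, 90) degrees")
        if not (0.0 < self.volkmann_inclination_max < 90.0):
            raise ValueError("volkmann_inclination_max must lie within (0, 90) degrees")
        if self.haversian_diameter.hi >= self.osteon_diameter.hi:
            raise ValueError(
                "haversian_diameter.hi must be < osteon_diameter.hi "
                "(a Haversian canal must fit inside some admissible osteon)"
            )
        for name in ("osteon_diameter", "haversian_diameter", "volkmann_diameter", "volkmann_spacing"):
            r: Range = getattr(self, name)
            if r.hi <= 0:
                raise ValueError(f"{name} must have a positive upper bound")

    # Short field aliases used in config files, matching the symbols a
    # bone histomorphometry reader expects.
    _ALIASES = {
        "OnDr": "osteon_diameter",
        "OnDn": "osteon_density",
        "thetaOn": "osteon_inclination",
        "CLT": "cement_thickness",
        "HCDR": "haversian_diameter",
        "VCDR": "volkmann_diameter",
        "DBVC": "volkmann_spacing",
        "thetaVC": "volkmann_inclination_max",
    }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        kwargs = {}
        for short, long in cls._ALIASES.items():
            if short in d:
                value = d[short]
            elif long in d:
                value = d[long]
            else:
                raise KeyError(f"missing parameter {short!r} ({long})")
            if long in ("osteon_density", "volkmann_inclination_max"):
                kwargs[long] = float(value)
            else:
                kwargs[long] = Range.coerce(value)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out: dict = {}
        for short, long in self._ALIASES.items():
            v = getattr(self, long)
            out[short] = [v.lo, v.hi] if isinstance(v, Range) else v
        return out


@dataclass(frozen=True)
class MacroShape:
    """Generation volume: rectangular prism or tubular cortical cross-section.

    The longitudinal axis of the bone runs along Z; the base cross-section
    lies in the z=0 plane.  Dimensions are in millimetres.
    """

    variant: str  # "prism" | "tube"
    prism_dims: tuple[float, float, float] | None = None  # (width, depth, length)
    outer: Polygon | None = None
    inner: Polygon | None = None
    length: float | None = None

    def __post_init__(self) -> None:
        if self.variant == "prism":
            if self.prism_dims is None or any(d <= 0 for d in self.prism_dims):
                raise ValueError("prism requires three positive dimensions")
        elif self.variant == "tube":
            if self.outer is None or self.inner is None or self.length is None:
                raise ValueError("tube requires outer and inner polygons and a length")
            if self.length <= 0:
                raise ValueError("tube length must be > 0")
            if not (self.outer.is_simple and self.inner.is_simple):
                raise ValueError("cross-section polygons must be simple")
            if not self.outer.contains(self.inner):
                raise ValueError("inner polygon must be strictly contained in the outer polygon")
        else:
            raise ValueError(f"unknown variant {self.variant!r}")

    @property
    def model_length(self) -> float:
        """Extent along Z, mm."""
        return self.prism_dims[2] if self.variant == "prism" else float(self.length)

    @property
    def base_area(self) -> float:
        """Area of the transverse cross-section at z=0, mm²."""
        if self.variant == "prism":
            return self.prism_dims[0] * self.prism_dims[1]
        return self.outer.area - self.inner.area

    @property
    def base_region(self) -> Polygon:
        """The base cross-section as a shapely polygon (annular for tube)."""
        if self.variant == "prism":
            w, d, _ = self.prism_dims
            return Polygon([(0, 0), (w, 0), (w, d), (0, d)])
        return self.outer.difference(self.inner)

    def contains_xy(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorised point-in-cross-section test (boundary counts inside)."""
        import shapely

        if self.variant == "prism":
            w, d, _ = self.prism_dims
            return (x >= 0) & (x <= w) & (y >= 0) & (y <= d)
        region = self.base_region
        return shapely.contains_xy(region, x, y) | shapely.intersects_xy(region.boundary, x, y)

    def contains_point(self, x: float, y: float, z: float) -> bool:
        if not (0.0 <= z <= self.model_length):
            return False
        return bool(self.contains_xy(np.asarray([x]), np.asarray([y]))[0])

    def bounding_box_xy(self) -> tuple[float, float, float, float]:
        if self.variant == "prism":
            w, d, _ = self.prism_dims
            return 0.0, 0.0, w, d
        return self.outer.bounds


class SeedSchema:
    """Deterministic named substreams derived from a single master seed.

    Each class of stochastic choice (osteon position, osteon diameter, ...)
    gets its own substream; the i-th uniform variate of a substream is a
    pure function of ``(master_seed, substream_name, i)``.  Re-creating the
    schema with the same master seed therefore reproduces every draw, and
    draws for one purpose never perturb those for another.
    """

    SUBSTREAMS = (
        "osteon_position",
        "osteon_diameter",
        "osteon_tilt",
        "osteon_azimuth",
        "cement_thickness",
        "haversian_diameter",
        "haversian_redraw",
        "volkmann_spacing",
        "volkmann_diameter",
    )

    def __init__(self, master_seed: int):
        self.master_seed = int(master_seed)

    def _rng(self, name: str, subkey: int = 0) -> np.random.Generator:
        # crc32 gives a stable, platform-independent hash of the name.
        tag = zlib.crc32(name.encode("utf-8"))
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.master_seed, spawn_key=(tag, subkey))
        )

    def uniforms(self, name: str, n: int, start: int = 0, subkey: int = 0) -> np.ndarray:
        """Uniform(0,1) variates of substream `name` at indices start..start+n-1."""
        u = self._rng(name, subkey).random(start + n)
        return u[start:]

    def uniform(self, name: str, index: int, subkey: int = 0) -> float:
        return float(self.uniforms(name, 1, start=index, subkey=subkey)[0])


def sample_from_range(r: Range, seeds: SeedSchema, substream: str, index: int) -> float:
    """Draw the index-th value from `r` on the named substream.

    Inverse-transform contract: the value is ``lo + u * (hi - lo)`` where u
    depends only on (master_seed, substream, index).  Widening a range under
    the same seed therefore maps every draw monotonically.
    """
    u = seeds.uniform(substream, index)
    return r.lo + u * r.width


def sample_many(r: Range, seeds: SeedSchema, substream: str, n: int) -> np.ndarray:
    """Vectorised draws at indices 0..n-1 (same contract as sample_from_range)."""
    u = seeds.uniforms(substream, n)
    return r.lo + u * r.width


@dataclass(frozen=True)
class AdmissibleRanges:
    """Healthy admissible input ranges and output porosity bands.

    Input bounds follow the reported histomorphometry of healthy human
    cortical bone.  Output bands are (mean, half-width) in percent of total
    cortical volume: overall canal porosity 14 ± 6 %, Haversian 8 ± 3 %,
    Volkmann 6 ± 3 %.  The literature tabulations are inconsistent about
    which canal system carries 8 % and which 6 %; we follow the assignment
    consistent with healthy-model porosity outcomes (Haversian the larger
    share), and report both bands explicitly so the reader can swap them.
    """

    osteon_diameter: Range = Range(100.0, 250.0)
    osteon_density: Range = Range(10.0, 25.0)
    osteon_inclination: Range = Range(0.0, 15.0)
    cement_thickness: Range = Range(0.0, 5.0)
    haversian_diameter: Range = Range(40.0, 90.0)
    volkmann_diameter: Range = Range(40.0, 50.0)
    volkmann_spacing: Range = Range(150.0, 500.0)
    volkmann_inclination_max: Range = Range(0.0, 15.0)

    haversian_band: tuple[float, float] = (8.0, 3.0)
    volkmann_band: tuple[float, float] = (6.0, 3.0)
    overall_band: tuple[float, float] = (14.0, 6.0)

    @staticmethod
    def band_contains(band: tuple[float, float], value: float) -> bool:
        mean, half = band
        return mean - half <= value <= mean + half


@dataclass(frozen=True)
class Violation:
    """One admissibility check failure for a parameter."""

    parameter: str
    admissible: str
    given: str
    severity: str  # "warning" | "error"

    def __str__(self) -> str:
        return f"[{self.severity}] {self.parameter} = {self.given} (admissible: {self.admissible})"


def _range_str(r: Range) -> str:
    return f"{r.lo:g}-{r.hi:g}"


def validate_parameters(
    p: ParameterSet, ranges: AdmissibleRanges | None = None
) -> list[Violation]:
    """Check a ParameterSet against the healthy admissible values.

    Out-of-range inputs are *warnings*: generation proceeds, which is how
    osteoporotic structures are produced on purpose.  Structural
    impossibilities (a Haversian canal that cannot fit in any admissible
    osteon) are *errors* and block generation.
    """
    ranges = ranges or AdmissibleRanges()
    out: list[Violation] = []

    def check_range(name: str, given: Range, adm: Range) -> None:
        if given.lo < adm.lo or given.hi > adm.hi:
            out.append(Violation(name, _range_str(adm), _range_str(given), "warning"))

    def check_scalar(name: str, given: float, adm: Range) -> None:
        if given not in adm:
            out.append(Violation(name, _range_str(adm), f"{given:g}", "warning"))

    check_range("OnDr", p.osteon_diameter, ranges.osteon_diameter)
    check_scalar("OnDn", p.osteon_density, ranges.osteon_density)
    check_range("thetaOn", p.osteon_inclination, ranges.osteon_inclination)
    check_range("CLT", p.cement_thickness, ranges.cement_thickness)
    check_range("HCDR", p.haversian_diameter, ranges.haversian_diameter)
    check_range("VCDR", p.volkmann_diameter, ranges.volkmann_diameter)
    check_range("DBVC", p.volkmann_spacing, ranges.volkmann_spacing)
    check_scalar("thetaVC", p.volkmann_inclination_max, ranges.volkmann_inclination_max)

    if p.haversian_diameter.lo >= p.osteon_diameter.hi:
        out.append(
            Violation(
                "HCDR",
                f"lo < OnDr.hi = {p.osteon_diameter.hi:g}",
                _range_str(p.haversian_diameter),
                "error",
            )
        )
    return out


def resolve_macroshape(
    prism_dims: Sequence[float] | None = None,
    cross_sections: tuple[Sequence[tuple[float, float]], Sequence[tuple[float, float]], float] | None = None,
) -> MacroShape:
    """Build the generation volume, with prism dimensions taking precedence.

    If non-zero prism dimensions are given, any cross-section curves are
    dismissed and a rectangular prism is built.  Otherwise the tube variant
    is assembled from (outer vertices, inner vertices, length).
    """
    dims_given = prism_dims is not None and any(d != 0 for d in prism_dims)
    if dims_given:
        w, d, l = (float(x) for x in prism_dims)
        if w <= 0 or d <= 0 or l <= 0:
            raise ValueError(f"prism dimensions must be positive, got {prism_dims}")
        return MacroShape(variant="prism", prism_dims=(w, d, l))
    if cross_sections is None:
        raise ValueError("neither prism dimensions nor cross-section curves were given")
    outer_pts, inner_pts, length = cross_sections
    outer = Polygon(outer_pts)
    inner = Polygon(inner_pts)
    return MacroShape(variant="tube", outer=outer, inner=inner, length=float(length))


# ---------------------------------------------------------------------------
# Config file I/O


def load_config(path) -> dict:
    """Read a TOML (or JSON) run configuration.

    Returns a dict with keys: parameters (ParameterSet), shape (MacroShape),
    master_seed, voxel_size_um, scale_factor, neighbor_k.
    """
    import tomllib
    from pathlib import Path

    path = Path(path)
    text = path.read_bytes()
    if path.suffix == ".json":
        raw = json.loads(text)
    else:
        raw = tomllib.loads(text.decode("utf-8"))

    params = ParameterSet.from_dict(raw["parameters"])
    ms = raw.get("macroshape", {})
    prism_dims = ms.get("prism_dims")
    cross = None
    if "outer" in ms:
        cross = (
            [tuple(v) for v in ms["outer"]],
            [tuple(v) for v in ms["inner"]],
            float(ms["length"]),
        )
    shape = resolve_macroshape(prism_dims, cross)
    return {
        "parameters": params,
        "shape": shape,
        "master_seed": int(raw.get("master_seed", 0)),
        "voxel_size_um": float(raw.get("voxel_size_um", 5.0)),
        "scale_factor": float(raw.get("scale_factor", 1.0)),
        "neighbor_k": int(raw["neighbor_k"]) if "neighbor_k" in raw else None,
    }


def dump_config(params: ParameterSet, shape: MacroShape, master_seed: int, **extra) -> str:
    """Serialise a run configuration to a TOML string (round-trips load_config)."""
    lines = [f"master_seed = {int(master_seed)}"]
    for k, v in extra.items():
        lines.append(f"{k} = {v}")
    lines.append("")
    lines.append("[parameters]")
    for short, val in params.to_dict().items():
        lines.append(f"{short} = {list(val) if isinstance(val, list) else val}")
    lines.append("")
    lines.append("[macroshape]")
    if shape.variant == "prism":
        lines.append(f"prism_dims = {list(shape.prism_dims)}")
    else:
        lines.append(f"outer = {[list(c) for c in shape.outer.exterior.coords[:-1]]}")
        lines.append(f"inner = {[list(c) for c in shape.inner.exterior.coords[:-1]]}")
        lines.append(f"length = {shape.length}")
    return "\n".join(lines) + "\n"
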