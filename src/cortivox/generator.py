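"""Vector skeleton of the bone model.

The generation sequence mirrors how the microstructure is organised:

1. the base plane (z=0) of the volume is seeded with circles — the
   osteons — with random positions and diameters;
2. an inclined axis is cast from each circle centre towards the top of the
   volume (tilt drawn from the osteon inclination range, azimuth uniform),
   clipped at its first exit through the top or a lateral wall;
3. each osteon receives a cement-line thickness and a Haversian canal
   diameter;
4. equally spaced interconnection points (IPs) are laid along each axis at
   an osteon-specific spacing drawn from the Volkmann-spacing range;
5. IPs on neighbouring osteons are linked by straight segments; candidates
   steeper than the maximum Volkmann inclination (measured from the
   transverse plane) are discarded, the survivors become Volkmann canals.

Osteon circles may overlap: merged osteons are a deliberate feature, as
they are in remodelling bone.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .parameters import MacroShape, ParameterSet, SeedSchema, sample_many

__all__ = [
    "OsteonSpec",
    "InterconnectionPoint",
    "VolkmannSegment",
    "CanalNetwork",
    "place_osteons",
    "build_axes",
    "assign_canal_dimensions",
    "make_interconnection_points",
    "link_interconnection_points",
    "generate_network",
    "DEFAULT_NEIGHBOR_K",
    "OSTEON_CAP",
]

# Number of surrounding osteons each interconnection point may link to.
# Calibrated once so the healthy validation model's Volkmann porosity lands
# inside the physiological 6 ± 3 % band; it tunes the connectivity density
# of the transverse canal network.
DEFAULT_NEIGHBOR_K = 9
OSTEON_CAP = 100_000

UM_PER_MM = 1000.0


@dataclass
class OsteonSpec:
    """One osteon: base circle, inclined axis and canal dimensions.

    Lengths in the axis/base fields are mm; diameters and thicknesses µm.
    """

    id: int
    base_center: tuple[float, float]
    diameter: float  # µm
    tilt: float | None = None  # degrees from Z
    azimuth: float | None = None  # degrees in [0, 360)
    cement_thickness: float | None = None  # µm
    haversian_diameter: float | None = None  # µm
    axis_end: tuple[float, float, float] | None = None  # mm
    axis_length: float | None = None  # mm

    @property
    def axis_start(self) -> tuple[float, float, float]:
        return (self.base_center[0], self.base_center[1], 0.0)

    @property
    def direction(self) -> tuple[float, float, float]:
        """Unit axis direction (positive Z component)."""
        t = math.radians(self.tilt)
        a = math.radians(self.azimuth)
        return (math.sin(t) * math.cos(a), math.sin(t) * math.sin(a), math.cos(t))

    def point_at(self, s: float) -> tuple[float, float, float]:
        """Point at arc length s (mm) from the base along the axis."""
        d = self.direction
        x0, y0, z0 = self.axis_start
        return (x0 + s * d[0], y0 + s * d[1], z0 + s * d[2])


@dataclass(frozen=True)
class InterconnectionPoint:
    """Candidate attachment point for a Volkmann canal on an osteon axis."""

    osteon_id: int
    arc_position: float  # mm from base along the axis
    coordinate: tuple[float, float, float]  # mm


@dataclass(frozen=True)
class VolkmannSegment:
    """A transverse canal linking interconnection points on two osteons."""

    ip_a: int  # index into CanalNetwork.ips
    ip_b: int
    diameter: float  # µm
    inclination: float  # degrees from the transverse (XY) plane


@dataclass
class CanalNetwork:
    """Complete vector skeleton plus the inputs that produced it."""

    osteons: list[OsteonSpec]
    ips: list[InterconnectionPoint]
    segments: list[VolkmannSegment]
    shape: MacroShape
    parameters: ParameterSet
    master_seed: int
    neighbor_k: int = DEFAULT_NEIGHBOR_K

    def to_json_dict(self) -> dict:
        return {
            "master_seed": self.master_seed,
            "neighbor_k": self.neighbor_k,
            "parameters": self.parameters.to_dict(),
            "shape": {
                "variant": self.shape.variant,
                "prism_dims": list(self.shape.prism_dims) if self.shape.variant == "prism" else None,
            },
            "osteons": [
                {
                    "id": o.id,
                    "base_center": list(o.base_center),
                    "diameter_um": o.diameter,
                    "tilt_deg": o.tilt,
                    "azimuth_deg": o.azimuth,
                    "cement_thickness_um": o.cement_thickness,
                    "haversian_diameter_um": o.haversian_diameter,
                    "axis_end": list(o.axis_end),
                    "axis_length_mm": o.axis_length,
                }
                for o in self.osteons
            ],
            "interconnection_points": [
                {"osteon_id": ip.osteon_id, "arc_position_mm": ip.arc_position, "coordinate": list(ip.coordinate)}
                for ip in self.ips
            ],
            "volkmann_segments": [
                {"ip_a": s.ip_a, "ip_b": s.ip_b, "diameter_um": s.diameter, "inclination_deg": s.inclination}
                for s in self.segments
            ],
        }


def place_osteons(
    p: ParameterSet, shape: MacroShape, seeds: SeedSchema, cap: int = OSTEON_CAP
) -> list[OsteonSpec]:
    """Seed the base cross-section with osteon circles.

    The count is deterministic: N = round(osteon density × base area).
    Centres are uniform over the base cross-section (rejection sampling for
    the tubular variant); diameters are drawn from the osteon diameter
    range.  Overlapping circles are retained — merging is intended.
    """
    n = int(math.floor(p.osteon_density * shape.base_area + 0.5))
    if n == 0:
        warnings.warn("osteon density and base area give zero osteons; model will be empty")
        return []
    if n > cap:
        raise ValueError(f"osteon count {n} exceeds cap {cap}")

    x0, y0, x1, y1 = shape.bounding_box_xy()
    rng_pos = seeds._rng("osteon_position")
    centers = np.empty((n, 2))
    filled = 0
    # Rejection-sample uniform positions over the (possibly annular) base.
    while filled < n:
        m = max(2 * (n - filled), 64)
        xs = x0 + rng_pos.random(m) * (x1 - x0)
        ys = y0 + rng_pos.random(m) * (y1 - y0)
        ok = shape.contains_xy(xs, ys)
        take = min(int(ok.sum()), n - filled)
        centers[filled : filled + take, 0] = xs[ok][:take]
        centers[filled : filled + take, 1] = ys[ok][:take]
        filled += take

    diameters = sample_many(p.osteon_diameter, seeds, "osteon_diameter", n)
    return [
        OsteonSpec(id=i, base_center=(float(centers[i, 0]), float(centers[i, 1])), diameter=float(diameters[i]))
        for i in range(n)
    ]


def _clip_axis(shape: MacroShape, start: tuple[float, float, float], direction: tuple[float, float, float]) -> float:
    """Arc length from `start` along `direction` to the first boundary exit."""
    dz = direction[2]
    t_top = (shape.model_length - start[2]) / dz
    if shape.variant == "prism":
        w, d, _ = shape.prism_dims
        t = t_top
        for x0c, dxc, hi in ((start[0], direction[0], w), (start[1], direction[1], d)):
            if dxc > 0:
                t = min(t, (hi - x0c) / dxc)
            elif dxc < 0:
                t = min(t, (0.0 - x0c) / dxc)
        return max(t, 0.0)
    # Tube: march along the ray, then bisect the first lateral crossing.
    steps = 256
    ts = np.linspace(0.0, t_top, steps + 1)
    xs = start[0] + ts * direction[0]
    ys = start[1] + ts * direction[1]
    inside = shape.contains_xy(xs, ys)
    if inside.all():
        return t_top
    first_out = int(np.argmin(inside))  # first False
    lo, hi = ts[first_out - 1], ts[first_out]
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        x = start[0] + mid * direction[0]
        y = start[1] + mid * direction[1]
        if shape.contains_xy(np.asarray([x]), np.asarray([y]))[0]:
            lo = mid
        else:
            hi = mid
    return lo


def build_axes(
    osteons: list[OsteonSpec], p: ParameterSet, shape: MacroShape, seeds: SeedSchema
) -> list[OsteonSpec]:
    """Attach an inclined axis to each osteon, clipped at the volume boundary."""
    n = len(osteons)
    tilts = sample_many(p.osteon_inclination, seeds, "osteon_tilt", n)
    azimuths = seeds.uniforms("osteon_azimuth", n) * 360.0
    out = []
    for o, tilt, az in zip(osteons, tilts, azimuths):
        o = replace(o, tilt=float(tilt), azimuth=float(az))
        d = o.direction
        t = _clip_axis(shape, o.axis_start, d)
        o.axis_length = float(t)
        o.axis_end = o.point_at(t)
        out.append(o)
    return out


def assign_canal_dimensions(
    osteons: list[OsteonSpec], p: ParameterSet, seeds: SeedSchema, max_redraws: int = 100
) -> list[OsteonSpec]:
    """Draw the cement-line thickness and Haversian canal diameter per osteon.

    A canal must fit inside its osteon: a draw at or above 0.9 × the osteon
    diameter is redrawn (on a dedicated per-osteon substream, so later
    osteons keep their aligned draws) and, failing that, clamped with a
    warning.
    """
    n = len(osteons)
    cements = sample_many(p.cement_thickness, seeds, "cement_thickness", n)
    canal_draws = sample_many(p.haversian_diameter, seeds, "haversian_diameter", n)
    out = []
    for o, clt, hc in zip(osteons, cements, canal_draws):
        limit = 0.9 * o.diameter
        if hc >= limit:
            r = p.haversian_diameter
            for j in range(max_redraws):
                hc = r.lo + seeds.uniform("haversian_redraw", j, subkey=o.id + 1) * r.width
                if hc < limit:
                    break
            else:
                warnings.warn(
                    f"osteon {o.id}: Haversian diameter clamped to 0.9 x osteon diameter ({limit:.1f} um)"
                )
                hc = limit
        out.append(replace(o, cement_thickness=float(clt), haversian_diameter=float(hc)))
    return out


def make_interconnection_points(
    osteons: list[OsteonSpec], p: ParameterSet, seeds: SeedSchema
) -> list[InterconnectionPoint]:
    """Lay equally spaced IPs along each axis.

    One spacing s is drawn per osteon from the Volkmann-spacing range; IPs
    sit at arc lengths s, 2s, 3s, ... strictly inside the axis length.
    """
    n = len(osteons)
    spacings_um = sample_many(p.volkmann_spacing, seeds, "volkmann_spacing", n)
    ips: list[InterconnectionPoint] = []
    for o, s_um in zip(osteons, spacings_um):
        s = s_um / UM_PER_MM
        if s <= 0:
            continue
        k = 1
        while k * s < o.axis_length and not math.isclose(k * s, o.axis_length):
            ips.append(
                InterconnectionPoint(
                    osteon_id=o.id, arc_position=k * s, coordinate=o.point_at(k * s)
                )
            )
            k += 1
    return ips


def _osteon_neighbors(centers: np.ndarray, k: int) -> list[np.ndarray]:
    """Surrounding osteons per osteon: the k nearest by base-centre distance.

    Volkmann canals in real tissue connect Haversian canals beyond
    immediate neighbours, so the neighbourhood is a plain k-nearest-centre
    query rather than first-ring (Delaunay) adjacency; k tunes the
    connectivity density of the canal network.
    """
    n = len(centers)
    if n < 2:
        return [np.empty(0, dtype=int) for _ in range(n)]
    tree = cKDTree(centers)
    kk = min(k + 1, n)
    _, idx = tree.query(centers, k=kk)
    idx = np.atleast_2d(idx)
    return [np.array([j for j in idx[i] if j != i][:k], dtype=int) for i in range(n)]


def link_interconnection_points(
    ips: list[InterconnectionPoint],
    osteons: list[OsteonSpec],
    p: ParameterSet,
    seeds: SeedSchema,
    neighbor_k: int = DEFAULT_NEIGHBOR_K,
) -> list[VolkmannSegment]:
    """Connect IPs on neighbouring osteons into Volkmann canal segments.

    For each IP, the candidate partners are the nearest IP (3D distance) on
    each of up to `neighbor_k` neighbouring osteons.  Unordered duplicates
    are removed; candidates inclined more than the maximum Volkmann
    inclination from the transverse plane are omitted; each survivor gets a
    diameter drawn from the Volkmann diameter range.
    """
    if not ips or len(osteons) < 2:
        return []
    centers = np.array([o.base_center for o in osteons])
    neighbors = _osteon_neighbors(centers, neighbor_k)

    coords = np.array([ip.coordinate for ip in ips])
    owner = np.array([ip.osteon_id for ip in ips])
    by_osteon: dict[int, np.ndarray] = {
        oid: np.flatnonzero(owner == oid) for oid in np.unique(owner)
    }

    pairs: set[tuple[int, int]] = set()
    for i in range(len(ips)):
        for nb in neighbors[owner[i]]:
            cand = by_osteon.get(int(nb))
            if cand is None or len(cand) == 0:
                continue
            d2 = np.sum((coords[cand] - coords[i]) ** 2, axis=1)
            j = int(cand[int(np.argmin(d2))])
            pairs.add((i, j) if i < j else (j, i))

    theta_max = p.volkmann_inclination_max
    kept: list[tuple[int, int, float]] = []
    for a, b in sorted(pairs):
        dx, dy, dz = (coords[b] - coords[a]).tolist()
        horiz = math.hypot(dx, dy)
        incl = math.degrees(math.atan2(abs(dz), horiz))
        if incl <= theta_max:
            kept.append((a, b, incl))

    diameters = sample_many(p.volkmann_diameter, seeds, "volkmann_diameter", len(kept))
    return [
        VolkmannSegment(ip_a=a, ip_b=b, diameter=float(d), inclination=incl)
        for (a, b, incl), d in zip(kept, diameters)
    ]


def generate_network(
    p: ParameterSet,
    shape: MacroShape,
    master_seed: int,
    neighbor_k: int = DEFAULT_NEIGHBOR_K,
) -> CanalNetwork:
    """Run the full skeleton-generation sequence for one master seed."""
    seeds = SeedSchema(master_seed)
    osteons = place_osteons(p, shape, seeds)
    osteons = build_axes(osteons, p, shape, seeds)
    osteons = assign_canal_dimensions(osteons, p, seeds)
    ips = make_interconnection_points(osteons, p, seeds)
    segments = link_interconnection_points(ips, osteons, p, seeds, neighbor_k=neighbor_k)
    return CanalNetwork(
        osteons=osteons,
        ips=ips,
        segments=segments,
        shape=shape,
        parameters=p,
        master_seed=master_seed,
        neighbor_k=neighbor_k,
    )
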