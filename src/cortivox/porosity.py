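"""Canal porosity check and healthy / out-of-range classification.

Vascular porosity of cortical bone is the volume fraction taken up by the
Haversian and Volkmann canal systems.  In healthy tissue the canals occupy
14 ± 6 % of the total cortical volume (Haversian ≈ 8 ± 3 %, Volkmann
≈ 6 ± 3 %); overall porosity above 20 % is characteristic of osteoporotic
bone.  The check counts labelled voxels, so by the label partition the
overall fraction is exactly the Haversian plus the Volkmann fraction.

Cement lines are mineralised tissue: they belong to the solid denominator,
never to the porosity numerator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

from .parameters import AdmissibleRanges, ParameterSet
from .solid import Label, LabeledVolume

__all__ = [
    "PorosityReport",
    "compute_porosity",
    "classify_condition",
    "analytic_haversian_expectation",
    "OSTEOPOROTIC_THRESHOLD_PCT",
]

OSTEOPOROTIC_THRESHOLD_PCT = 20.0


@dataclass
class PorosityReport:
    """Canal volume fractions of one labelled volume, with band verdicts."""

    haversian_pct: float
    volkmann_pct: float
    overall_pct: float
    total_bone_volume_mm3: float
    voxel_counts: dict[str, int]
    classification: str  # "healthy" | "out_of_range"
    band_check: dict[str, bool]
    summary: str = ""

    def to_json_dict(self) -> dict:
        return {
            "haversian_pct": self.haversian_pct,
            "volkmann_pct": self.volkmann_pct,
            "overall_pct": self.overall_pct,
            "total_bone_volume_mm3": self.total_bone_volume_mm3,
            "voxel_counts": self.voxel_counts,
            "classification": self.classification,
            "band_check": self.band_check,
            "summary": self.summary,
        }


def classify_condition(
    haversian_pct: float,
    volkmann_pct: float,
    overall_pct: float,
    ranges: AdmissibleRanges | None = None,
) -> tuple[str, dict[str, bool], str]:
    """Band verdicts and the healthy / out-of-range call.

    The verdict keys on the overall band (14 ± 6 %, edges inclusive); the
    per-canal bands are reported as advisory pass/fail.  Overall porosity
    above 20 % additionally gets an osteoporosis-suggestive note.
    """
    ranges = ranges or AdmissibleRanges()
    band_check = {
        "haversian": ranges.band_contains(ranges.haversian_band, haversian_pct),
        "volkmann": ranges.band_contains(ranges.volkmann_band, volkmann_pct),
        "overall": ranges.band_contains(ranges.overall_band, overall_pct),
    }
    classification = "healthy" if band_check["overall"] else "out_of_range"
    mean, half = ranges.overall_band
    parts = [
        f"Haversian {haversian_pct:.2f}% ({'in' if band_check['haversian'] else 'out of'} "
        f"{ranges.haversian_band[0]:g} ± {ranges.haversian_band[1]:g}% band)",
        f"Volkmann {volkmann_pct:.2f}% ({'in' if band_check['volkmann'] else 'out of'} "
        f"{ranges.volkmann_band[0]:g} ± {ranges.volkmann_band[1]:g}% band)",
        f"overall {overall_pct:.2f}% ({'within' if band_check['overall'] else 'outside'} "
        f"{mean:g} ± {half:g}%)",
    ]
    summary = "; ".join(parts) + f" -> {classification}"
    if overall_pct > OSTEOPOROTIC_THRESHOLD_PCT:
        summary += f"; exceeds {OSTEOPOROTIC_THRESHOLD_PCT:g}% (osteoporotic-range porosity)"
    return classification, band_check, summary


def compute_porosity(
    volume: LabeledVolume, ranges: AdmissibleRanges | None = None
) -> PorosityReport:
    """Canal volume fractions of the total cortical (non-OUTSIDE) volume."""
    counts = volume.label_counts()
    bone_voxels = int(counts[Label.MATRIX] + counts[Label.CEMENT] + counts[Label.HAVERSIAN] + counts[Label.VOLKMANN])
    if bone_voxels == 0:
        raise ValueError("volume contains no bone voxels (all OUTSIDE)")

    hav = int(counts[Label.HAVERSIAN])
    vol = int(counts[Label.VOLKMANN])
    haversian_pct = 100.0 * hav / bone_voxels
    volkmann_pct = 100.0 * vol / bone_voxels
    overall_pct = haversian_pct + volkmann_pct  # exact by the label partition

    classification, band_check, summary = classify_condition(
        haversian_pct, volkmann_pct, overall_pct, ranges
    )
    return PorosityReport(
        haversian_pct=haversian_pct,
        volkmann_pct=volkmann_pct,
        overall_pct=overall_pct,
        total_bone_volume_mm3=bone_voxels * volume.voxel_volume_mm3,
        voxel_counts={Label.NAMES[i]: int(counts[i]) for i in range(5)},
        classification=classification,
        band_check=band_check,
        summary=summary,
    )


def analytic_haversian_expectation(p: ParameterSet) -> float:
    """Closed-form expected Haversian porosity (%), ignoring overlap and edges.

    Each osteon contributes a canal of volume (π/4) d² · L sec θ inside a
    volume of base area A and height L, and there are OnDn · A osteons, so
    the expected fraction is

        OnDn · (π/4) · E[d²] · E[sec θ]

    with d uniform on the Haversian diameter range (E[d²] =
    (lo² + lo·hi + hi²)/3) and θ uniform on the osteon inclination range.
    Valid in the limit of non-overlapping, fully interior canals; wall
    clipping and canal merging make the simulated value slightly smaller.
    """
    r = p.haversian_diameter
    e_d2_um2 = (r.lo**2 + r.lo * r.hi + r.hi**2) / 3.0
    e_d2_mm2 = e_d2_um2 * 1e-6

    a = math.radians(p.osteon_inclination.lo)
    b = math.radians(p.osteon_inclination.hi)
    if b > a:
        e_sec = quad(lambda t: 1.0 / math.cos(t), a, b)[0] / (b - a)
    else:
        e_sec = 1.0 / math.cos(a)

    return p.osteon_density * (math.pi / 4.0) * e_d2_mm2 * e_sec * 100.0
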