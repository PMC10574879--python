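"""Per-tubercle trait measurement.

Six variables are measured on each tubercle: width at the base W (microns),
height H (microns), the dimensionless steepness index S = 200 * H / W, the
maximum and mean absolute curvature of the fitted Bézier profile
(micron^-1 * 1000) and the max/mean curvature ratio.

The baseline of a :class:`TubercleProfile` is the chord through its two base
points; profiles produced by :func:`tuberkit.extraction.segment_tubercle`
and by the synthetic generator are normalised so this chord is the x axis.
H is measured perpendicular to the base chord (identical to the image
vertical for upright profiles).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .geometry import (
    BezierProfileModel,
    as_planar_points,
    curvature_ratio,
    fit_bezier_regular,
)

__all__ = [
    "TubercleProfile",
    "TubercleRecord",
    "measure_width_height",
    "slope",
    "analyze_tubercle",
    "records_to_frame",
    "MEASUREMENT_VARIABLES",
]

#: canonical column order of the per-tubercle measurement tables
MEASUREMENT_VARIABLES = ("W", "H", "S", "max_curvature", "mean_curvature", "ratio")


@dataclass(frozen=True)
class TubercleProfile:
    """Ordered, calibrated planar points for one tubercle (microns).

    The first and last points are the base points; the baseline is the chord
    through them (y = 0 after normalisation).  ``meta`` carries provenance
    such as the source image and threshold.
    """

    points: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "points", as_planar_points(self.points))

    @property
    def base_points(self) -> tuple[np.ndarray, np.ndarray]:
        return self.points[0], self.points[-1]

    def scaled(self, factor: float) -> "TubercleProfile":
        return TubercleProfile(self.points * float(factor), dict(self.meta))


@dataclass
class TubercleRecord:
    """One tubercle's six measured variables plus provenance labels."""

    species: str
    seed_id: str
    tubercle_no: int
    W: float
    H: float
    S: float
    max_curvature: float
    mean_curvature: float
    ratio: float
    type_label: str | None = None
    subgenus: str | None = None

    def as_dict(self) -> dict:
        return asdict(self)


def measure_width_height(profile: TubercleProfile) -> tuple[float, float]:
    """Width along the base chord and maximum perpendicular height above it.

    Raises ``ValueError`` for a degenerate (flat, H == 0) profile.
    """
    pts = profile.points
    p0, p1 = pts[0], pts[-1]
    chord = p1 - p0
    width = float(np.linalg.norm(chord))
    if width == 0:
        raise ValueError("base points coincide: width undefined")
    # perpendicular (signed) distance of every point from the base chord
    normal = np.array([-chord[1], chord[0]]) / width
    heights = (pts - p0) @ normal
    height = float(np.abs(heights).max())
    if height <= 1e-9 * width:
        raise ValueError("flat profile: height is zero")
    return width, height


def slope(W: float, H: float) -> float:
    """Steepness index S = 200 * H / W (dimensionless).

    A tubercle twice as wide as tall scores 100; reference tables report S to
    one decimal place.
    """
    if W <= 0:
        raise ValueError("width must be positive")
    return 200.0 * H / W


def analyze_tubercle(
    profile: TubercleProfile,
    degree=5,
    n_samples: int = 200,
    species: str = "",
    seed_id: str = "",
    tubercle_no: int = 0,
    type_label: str | None = None,
    subgenus: str | None = None,
) -> TubercleRecord:
    """Measure all six variables of one tubercle profile.

    Combines the width/height/slope measurements with the Bézier curvature
    pipeline (degree-``degree`` fit, ``n_samples`` uniform curvature samples).
    """
    W, H = measure_width_height(profile)
    S = slope(W, H)
    if degree == "auto":
        result = BezierProfileModel(profile.points, degree="auto").fit()
    else:
        # escalate past near-cusp fits so very sharp apices get a meaningful
        # curvature instead of a parameterisation artifact
        result = fit_bezier_regular(profile.points, degree=degree)
    prof = result.curvature_profile(n_samples=n_samples)
    kmax = prof.max_abs()
    kmean = prof.mean_abs()
    return TubercleRecord(
        species=species,
        seed_id=seed_id,
        tubercle_no=int(tubercle_no),
        W=W,
        H=H,
        S=S,
        max_curvature=kmax,
        mean_curvature=kmean,
        ratio=curvature_ratio(kmax, kmean),
        type_label=type_label,
        subgenus=subgenus,
    )


def records_to_frame(records) -> pd.DataFrame:
    """Per-tubercle table (one row per tubercle, canonical column order)."""
    df = pd.DataFrame([r.as_dict() for r in records])
    cols = ["species", "seed_id", "tubercle_no", *MEASUREMENT_VARIABLES, "type_label", "subgenus"]
    return df[cols]
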