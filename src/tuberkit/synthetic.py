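"""Synthetic tubercle profiles, species datasets and rendered test images.

The generator emulates the two tubercle morphologies seen on tuberculate
seed coats: *rounded* bumps (the rugose seed type — wide, low, gently
curved) and *acute* bumps (the echinate type — narrow, tall, sharply
peaked), plus *compound* bumps carrying a secondary excrescence and pure
circular *arcs* used as curvature calibration targets.  Class parameter
defaults are the published pooled group means for the two seed types
(rugose W 83.3, H 20.7; echinate W 72.0, H 43.6 microns) with log-normal
between-tubercle variation at the published coefficient-of-variation
magnitudes.

Everything is reproducible: a dataset seed deterministically derives one
seed per tubercle, so the same configuration always yields identical
profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .measurement import TubercleProfile

__all__ = [
    "BumpSpec",
    "SpeciesSpec",
    "SyntheticDataset",
    "make_profile",
    "make_species_dataset",
    "render_profile_image",
    "default_rugose_spec",
    "default_echinate_spec",
    "default_two_type_dataset",
]

_SHAPES = ("rounded", "acute", "compound", "arc")


@dataclass(frozen=True)
class BumpSpec:
    """Parameters of one synthetic tubercle profile.

    W and H are the base width and height in microns; ``noise_sd`` is the
    standard deviation of additive Gaussian y-noise (microns, roughly
    sub-pixel at typical image scales).  ``secondary_amp`` sets the height of
    the off-centre excrescence of compound bumps; ``arc_radius`` and
    ``arc_span_deg`` define circular arcs (W and H are then implied).
    """

    shape: str = "rounded"
    W: float = 83.3
    H: float = 20.7
    noise_sd: float = 0.5
    secondary_amp: float | None = None
    arc_radius: float | None = None
    arc_span_deg: float = 120.0
    seed: int | None = None

    def __post_init__(self):
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}; choose from {_SHAPES}")
        if self.shape != "arc" and (self.W <= 0 or self.H <= 0):
            raise ValueError("W and H must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.shape == "arc" and not (self.arc_radius and self.arc_radius > 0):
            raise ValueError("arc shape requires a positive arc_radius")


def _rounded(x: np.ndarray, W: float, H: float) -> np.ndarray:
    """Raised-cosine bump on [-W/2, W/2], zero at the base, peak H at centre."""
    return H * 0.5 * (1.0 + np.cos(2.0 * np.pi * x / W))


def _acute(x: np.ndarray, W: float, H: float) -> np.ndarray:
    """Acute (echinate-like) bump: a raised cosine sharpened by an exponent
    chosen so the apex osculating radius is W/20.

    With y = H * ((1 + cos(2 pi x / W)) / 2)^q the apex curvature is
    2 q pi^2 H / W^2, so q = 10 W / (pi^2 H) pins the apex radius at W/20.
    Unlike a literal triangle, the flanks stay curved, which is what real
    acute tubercles look like and what keeps their mean curvature above the
    rounded class.
    """
    q = 10.0 * W / (np.pi**2 * H)
    return H * (0.5 * (1.0 + np.cos(2.0 * np.pi * x / W))) ** q


def make_profile(spec: BumpSpec, n_points: int = 120) -> TubercleProfile:
    """Generate one synthetic tubercle profile (baseline on the x axis).

    Shapes: ``rounded`` raised cosine, ``acute`` smoothed triangle (corner
    radius W/20), ``compound`` rounded bump plus an off-centre secondary
    bump, ``arc`` circular arc of the given radius and angular span.
    Gaussian y-noise of sd ``noise_sd`` is added using ``spec.seed``.
    """
    if n_points < 30:
        raise ValueError("n_points must be at least 30")
    rng = np.random.default_rng(spec.seed)
    if spec.shape == "arc":
        R = float(spec.arc_radius)
        half = np.radians(spec.arc_span_deg) / 2.0
        phi = np.linspace(-half, half, n_points)
        x = R * np.sin(phi)
        y = R * (np.cos(phi) - np.cos(half))
    else:
        x = np.linspace(-spec.W / 2.0, spec.W / 2.0, n_points)
        if spec.shape == "rounded":
            y = _rounded(x, spec.W, spec.H)
        elif spec.shape == "acute":
            y = _acute(x, spec.W, spec.H)
        else:  # compound
            amp = spec.secondary_amp if spec.secondary_amp is not None else 0.35 * spec.H
            y = _rounded(x, spec.W, spec.H)
            # secondary excrescence on the flank, a quarter-width wide
            y = y + amp * np.clip(_rounded(x - spec.W / 4.0, spec.W / 2.0, 1.0), 0.0, None) * (
                np.abs(x - spec.W / 4.0) <= spec.W / 4.0
            )
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=n_points)
    return TubercleProfile(
        np.column_stack([x, y]),
        meta={"shape": spec.shape, "true_W": None if spec.shape == "arc" else spec.W,
              "true_H": None if spec.shape == "arc" else spec.H, "spec": spec},
    )


@dataclass(frozen=True)
class SpeciesSpec:
    """Distributional description of one synthetic species.

    Per-tubercle base width W and slope S = 200 H / W are drawn
    independently log-normally with the given means and coefficients of
    variation (percent); the height follows as H = S * W / 200.  Drawing
    (W, S) rather than (W, H) keeps all three printed dispersions consistent
    at once — real tubercle width and height co-vary, and independent W, H
    draws would inflate the slope spread well past observed values.
    """

    name: str
    shape: str = "rounded"
    type_label: str = "rugose"
    subgenus: str = "Silene"
    n_tubercles: int = 20
    n_seeds: int = 2
    W_mean: float = 83.3
    W_cv: float = 24.8
    S_mean: float = 49.8
    S_cv: float = 25.8
    noise_sd: float = 0.5
    compound_fraction: float = 0.0

    @property
    def H_mean(self) -> float:
        """Implied mean height (microns), S_mean * W_mean / 200."""
        return self.S_mean * self.W_mean / 200.0


@dataclass(frozen=True)
class SyntheticDataset:
    """A collection of species specs plus a global seed."""

    species: tuple
    seed: int = 0


@dataclass(frozen=True)
class SyntheticTubercle:
    """One generated profile with its ground-truth labels."""

    profile: TubercleProfile
    species: str
    seed_id: str
    tubercle_no: int
    type_label: str
    subgenus: str
    true_W: float
    true_H: float
    shape: str


def _lognormal(rng, mean: float, cv_percent: float, size=None):
    cv = cv_percent / 100.0
    sigma2 = np.log(1.0 + cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def default_rugose_spec(name: str = "synthetic rugose", **overrides) -> SpeciesSpec:
    """Rounded-bump class at the published rugose pooled means and CVs
    (W 83.3 micron at 24.8%, slope 49.8 at 25.8%, implied mean height
    20.7 micron)."""
    kw = dict(name=name, shape="rounded", type_label="rugose", subgenus="Silene",
              W_mean=83.3, W_cv=24.8, S_mean=49.8, S_cv=25.8)
    kw.update(overrides)
    return SpeciesSpec(**kw)


def default_echinate_spec(name: str = "synthetic echinate", **overrides) -> SpeciesSpec:
    """Acute-bump class at the published echinate pooled means and CVs
    (W 72.0 micron at 23.1%, slope 124.3 at 52.2%, implied mean height
    44.7 micron)."""
    kw = dict(name=name, shape="acute", type_label="echinate", subgenus="Behenantha",
              W_mean=72.0, W_cv=23.1, S_mean=124.3, S_cv=52.2)
    kw.update(overrides)
    return SpeciesSpec(**kw)


def default_two_type_dataset(n_per_species: int = 50, seed: int = 0) -> SyntheticDataset:
    """One rugose plus one echinate synthetic species (the basic two-group
    study design)."""
    return SyntheticDataset(
        species=(
            default_rugose_spec(n_tubercles=n_per_species),
            default_echinate_spec(n_tubercles=n_per_species),
        ),
        seed=seed,
    )


def make_species_dataset(dataset: SyntheticDataset, n_points: int = 120) -> list[SyntheticTubercle]:
    """Generate labelled profiles for every species in the dataset.

    Deterministic in ``dataset.seed``: parameter draws and per-profile noise
    seeds all derive from one seed sequence.
    """
    root = np.random.default_rng(dataset.seed)
    out = []
    for sp in dataset.species:
        rng = np.random.default_rng(root.integers(2**31))
        Ws = _lognormal(rng, sp.W_mean, sp.W_cv, sp.n_tubercles)
        Ss = _lognormal(rng, sp.S_mean, sp.S_cv, sp.n_tubercles)
        Hs = Ss * Ws / 200.0
        for i, (W, H) in enumerate(zip(Ws, Hs), start=1):
            shape = sp.shape
            if sp.compound_fraction > 0 and rng.random() < sp.compound_fraction:
                shape = "compound"
            spec = BumpSpec(shape=shape, W=float(W), H=float(H), noise_sd=sp.noise_sd,
                            seed=int(rng.integers(2**31)))
            seed_id = f"seed{1 + (i - 1) * sp.n_seeds // sp.n_tubercles}"
            out.append(
                SyntheticTubercle(
                    profile=make_profile(spec, n_points=n_points),
                    species=sp.name,
                    seed_id=seed_id,
                    tubercle_no=i,
                    type_label=sp.type_label,
                    subgenus=sp.subgenus,
                    true_W=float(W),
                    true_H=float(H),
                    shape=shape,
                )
            )
    return out


def render_profile_image(
    profile: TubercleProfile,
    microns_per_pixel: float = 1.0,
    ruler_length: float = 1000.0,
    margin_px: int = 10,
    ruler_height_px: int = 4,
) -> tuple[np.ndarray, dict]:
    """Render a profile as an 8-bit image fixture with a scale ruler.

    The area under the profile is drawn as bright foreground on a dark
    background; a horizontal ruler bar of physical length ``ruler_length``
    microns sits in the bottom-left corner, separated from the bump.
    Returns the image and ground-truth metadata (scale, base points, bump
    bounding box, ruler bar position).
    """
    pts = profile.points / microns_per_pixel  # now in pixels
    x_px = pts[:, 0] - pts[:, 0].min()
    y_px = pts[:, 1] - min(pts[:, 1].min(), 0.0)
    bump_w = int(np.ceil(x_px.max())) + 1
    bump_h = int(np.ceil(y_px.max())) + 1
    ruler_px = int(round(ruler_length / microns_per_pixel))
    width = max(bump_w, ruler_px) + 2 * margin_px
    ruler_zone = 3 * ruler_height_px + 2 * margin_px
    height = bump_h + ruler_zone + 2 * margin_px
    if width > 20000 or height > 20000:
        raise ValueError("profile exceeds canvas limits at this scale")
    img = np.zeros((height, width), dtype=np.uint8)

    x0, y0 = margin_px, margin_px + ruler_zone  # bump origin in y-up coords
    cols = np.arange(bump_w, dtype=float)
    heights = np.interp(cols, x_px, y_px)
    for c, h in zip(cols.astype(int), heights):
        top_row = height - 1 - int(round(y0 + h))
        base_row = height - 1 - y0
        img[top_row : base_row + 1, x0 + c] = 255

    ruler_row0 = height - 1 - margin_px - ruler_height_px
    img[ruler_row0 : ruler_row0 + ruler_height_px, margin_px : margin_px + ruler_px] = 255

    meta = {
        "microns_per_pixel": float(microns_per_pixel),
        "ruler_px": ruler_px,
        "ruler_length": float(ruler_length),
        "base_points_px": ((x0, y0), (x0 + bump_w - 1, y0)),
        "bump_bbox": (x0, y0, x0 + bump_w, y0 + bump_h + 2),  # x-y-up box (x0, y0, x1, y1)
        "true_W": profile.meta.get("true_W"),
        "true_H": profile.meta.get("true_H"),
    }
    return img, meta
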