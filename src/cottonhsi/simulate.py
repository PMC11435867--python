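"""Synthetic hyperspectral scene generator.

Emulates a laboratory push-broom acquisition of seed cotton carrying
foreign-fiber contaminants: each material class has a smooth reflectance
curve over a 400-1000 nm grid; every pixel sees a per-pixel affine scatter
distortion (multiplicative gain around 1 plus an additive baseline — the
component that multiplicative scatter correction exists to remove), a
dark-current offset shared with the dark reference, and additive sensor
noise. Contaminants are laid out as elliptical blobs over a cotton
background; a tray/background class fills the scene margin so that every
pixel carries a class.

The generator is a pure function of its :class:`SceneSpec` — identical
seeds give bit-identical scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cube import HsiCube, LabelMap

__all__ = ["SceneSpec", "simulate_scene", "default_signatures", "DEFAULT_CLASS_NAMES"]

# The nine materials of the seed-cotton contaminant setting. The last
# entry (tray background) is the fill class of the scene.
DEFAULT_CLASS_NAMES = [
    "plastic_film",
    "seed_cotton",
    "paper_scrap",
    "black_film",
    "white_rope",
    "red_rope",
    "transparent_rope",
    "foam_board",
    "background",
]


def default_signatures(n_classes: int, wavelengths: np.ndarray) -> np.ndarray:
    """Smooth per-class reflectance curves in [0, 1]: sums of 2-3 Gaussian bumps.

    Bump centers are staggered deterministically per class so that any two
    classes differ somewhere on the grid; curves are smooth on the scale of
    the sensor's spectral resolution.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    lo, hi = wavelengths[0], wavelengths[-1]
    span = hi - lo
    sig = np.empty((n_classes, wavelengths.size))
    for c in range(n_classes):
        # class-specific base level and 2-3 bumps with staggered centers
        base = 0.12 + 0.05 * ((c * 3) % 5) / 4.0
        n_bumps = 2 + (c % 2)
        curve = np.full_like(wavelengths, base)
        for b in range(n_bumps):
            center = lo + span * ((c / n_classes + (b + 1) / (n_bumps + 1) + 0.07 * ((c * 5 + b) % 3)) % 1.0)
            width = span * (0.08 + 0.03 * ((c + b) % 3))
            height = 0.35 + 0.25 * (((c * 7 + b * 3) % 5) / 4.0)
            curve = curve + height * np.exp(-0.5 * ((wavelengths - center) / width) ** 2)
        peak = curve.max()
        if peak > 0.95:
            curve *= 0.95 / peak
        sig[c] = curve
    return sig


@dataclass
class SceneSpec:
    """Parameters of a synthetic acquisition.

    Noise defaults are modest laboratory-plausible values: a ~10% pixelwise
    scatter gain spread, a small additive baseline, ~1% sensor noise and a
    5% dark-current floor (all in reflectance units with the white board at 1).
    """

    rows: int = 96
    cols: int = 96
    bands: int = 32
    class_signatures: np.ndarray | None = None  # (n_classes, bands), built if None
    n_classes: int = 9
    blob_count: int = 24
    blob_size_range: tuple = (5, 14)  # semi-axis bounds, pixels
    scatter_mult_sd: float = 0.10
    scatter_add_sd: float = 0.02
    noise_sd: float = 0.01
    dark_level: float = 0.05
    wavelengths: np.ndarray | None = None
    class_names: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("scatter_mult_sd", "scatter_add_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.wavelengths is None:
            self.wavelengths = np.linspace(400.0, 1000.0, self.bands)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.class_signatures is None:
            self.class_signatures = default_signatures(self.n_classes, self.wavelengths)
        self.class_signatures = np.asarray(self.class_signatures, dtype=float)
        self.n_classes = self.class_signatures.shape[0]
        if self.class_signatures.shape != (self.n_classes, self.bands):
            raise ValueError("class_signatures must have shape (n_classes, bands)")
        if self.class_signatures.min() < 0 or self.class_signatures.max() > 1:
            raise ValueError("class signatures must lie in [0, 1]")
        if not self.class_names:
            if self.n_classes == len(DEFAULT_CLASS_NAMES):
                self.class_names = list(DEFAULT_CLASS_NAMES)
            else:
                self.class_names = [f"class_{i + 1}" for i in range(self.n_classes)]
        lo, hi = self.blob_size_range
        if 2 * hi >= min(self.rows, self.cols):
            raise ValueError(
                f"largest blob (diameter ~{2 * hi}) does not fit a {self.rows}x{self.cols} scene"
            )


def _paint_blobs(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Elliptical contaminant blobs (classes 1..C-1) over the background class C."""
    labels = np.full((spec.rows, spec.cols), spec.n_classes, dtype=np.int32)
    rr, cc = np.mgrid[0 : spec.rows, 0 : spec.cols]
    lo, hi = spec.blob_size_range
    n_fg = spec.n_classes - 1
    for i in range(spec.blob_count):
        # cycle through foreground classes so every material appears
        cls = (i % n_fg) + 1
        a = rng.uniform(lo, hi)
        b = rng.uniform(lo, hi)
        theta = rng.uniform(0, np.pi)
        r0 = rng.uniform(hi, spec.rows - hi)
        c0 = rng.uniform(hi, spec.cols - hi)
        dr, dc = rr - r0, cc - c0
        u = dr * np.cos(theta) + dc * np.sin(theta)
        v = -dr * np.sin(theta) + dc * np.cos(theta)
        labels[(u / a) ** 2 + (v / b) ** 2 <= 1.0] = cls
    return labels


def simulate_scene(spec: SceneSpec) -> tuple:
    """Simulate one acquisition.

    Returns
    -------
    raw, dark, white : HsiCube
        Raw intensity cube, dark reference (shutter closed) and white
        reference (reflectance-1 board), all on the same grid:
        ``raw = dark_level + a_px * signature + c_px + noise`` with the
        per-pixel scalars ``a_px ~ N(1, scatter_mult_sd)`` and
        ``c_px ~ N(0, scatter_add_sd)`` shared across bands.
    truth : LabelMap
        Per-pixel class, covering every pixel (background is a class).
    """
    rng = np.random.default_rng(spec.seed)
    labels = _paint_blobs(spec, rng)

    sig = spec.class_signatures[labels - 1]  # (rows, cols, bands)
    a_px = 1.0 + spec.scatter_mult_sd * rng.standard_normal((spec.rows, spec.cols, 1))
    c_px = spec.scatter_add_sd * rng.standard_normal((spec.rows, spec.cols, 1))

    shape = (spec.rows, spec.cols, spec.bands)
    raw = spec.dark_level + a_px * sig + c_px
    if spec.noise_sd > 0:
        raw = raw + spec.noise_sd * rng.standard_normal(shape)
    dark = np.full(shape, spec.dark_level)
    white = np.full(shape, spec.dark_level + 1.0)
    if spec.noise_sd > 0:
        dark = dark + spec.noise_sd * rng.standard_normal(shape)
        white = white + spec.noise_sd * rng.standard_normal(shape)

    meta = {"description": "synthetic seed-cotton scene", "seed": spec.seed}
    return (
        HsiCube(raw, spec.wavelengths, dict(meta)),
        HsiCube(dark, spec.wavelengths, dict(meta)),
        HsiCube(white, spec.wavelengths, dict(meta)),
        LabelMap(labels, list(spec.class_names)),
    )
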