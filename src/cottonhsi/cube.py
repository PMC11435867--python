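"""Core raster containers for hyperspectral scenes.

All arrays in this package use the axis order ``(row, col, band)``.
ENVI interleaves (BSQ/BIL/BIP) are converted to this order on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HsiCube", "LabelMap"]


@dataclass
class HsiCube:
    """A hyperspectral raster: ``rows x cols x bands`` with wavelength metadata.

    Parameters
    ----------
    data : ndarray
        Real-valued array of shape ``(rows, cols, bands)``.
    wavelengths : ndarray
        Band-center wavelengths in nanometres, strictly increasing,
        length equal to the number of bands.
    meta : dict
        Free-form header key/value pairs carried through I/O.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3-D (rows, cols, bands), got ndim={self.data.ndim}")
        if self.data.shape[2] < 1:
            raise ValueError("cube must have at least one band")
        if self.wavelengths is None:
            self.wavelengths = np.arange(self.data.shape[2], dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.wavelengths.shape != (self.data.shape[2],):
            raise ValueError(
                f"wavelengths length {self.wavelengths.shape} does not match band count {self.data.shape[2]}"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def rows(self) -> int:
        return self.data.shape[0]

    @property
    def cols(self) -> int:
        return self.data.shape[1]

    @property
    def bands(self) -> int:
        return self.data.shape[2]

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def pixels(self) -> np.ndarray:
        """Flatten to a ``(rows * cols, bands)`` spectral matrix (view when possible)."""
        return self.data.reshape(-1, self.bands)

    def with_data(self, data: np.ndarray, wavelengths: np.ndarray | None = None) -> "HsiCube":
        """Return a new cube sharing metadata, with replaced data (and optionally wavelengths)."""
        wl = self.wavelengths if wavelengths is None else np.asarray(wavelengths, dtype=float)
        if data.shape[2] != wl.shape[0]:
            wl = np.arange(data.shape[2], dtype=float)
        return HsiCube(data=data, wavelengths=wl, meta=dict(self.meta))

    def __eq__(self, other) -> bool:
        if not isinstance(other, HsiCube):
            return NotImplemented
        return (
            self.data.shape == other.data.shape
            and np.array_equal(self.data, other.data)
            and np.array_equal(self.wavelengths, other.wavelengths)
        )


@dataclass
class LabelMap:
    """Per-pixel integer class map aligned to a cube.

    Class indices run from 1 to ``n_classes``; 0 marks pixels excluded
    from training ("unlabeled").
    """

    labels: np.ndarray
    class_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label map must be 2-D (rows, cols)")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be >= 0 (0 = unlabeled)")

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    @property
    def n_classes(self) -> int:
        return len(self.class_names) if self.class_names else int(self.labels.max())

    def check_matches(self, cube: HsiCube) -> None:
        if self.labels.shape != cube.data.shape[:2]:
            raise ValueError(
                f"label map shape {self.labels.shape} does not match cube spatial shape {cube.data.shape[:2]}"
            )

    def __eq__(self, other) -> bool:
        if not isinstance(other, LabelMap):
            return NotImplemented
        return np.array_equal(self.labels, other.labels) and self.class_names == other.class_names
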