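"""Shared data model for Mueller-matrix imaging.

A Mueller matrix is a real 4x4 matrix acting on Stokes vectors (I, Q, U, V).
Element indexing in documentation follows the optics convention m11..m44
(1-based, row-major); in code the native 0-based numpy indexing is used and
the mapping happens exactly once, at the I/O boundary.

Azimuths are measured counterclockwise from the laboratory x-axis looking
toward the source and reported in degrees on [0, 180).
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MuellerImage",
    "PixelMask",
    "MaskReason",
    "MuellerError",
    "FormatError",
    "DataError",
    "DegeneratePixelError",
    "CorrectionError",
    "FilterError",
    "DecompositionError",
    "ContractError",
    "as_mueller",
]

DEFAULT_WAVELENGTH_NM = 550.0
DEFAULT_PIXEL_SIZE_UM = 1.0


class MuellerError(Exception):
    """Base class for errors raised by this package."""


class FormatError(MuellerError):
    """A file does not conform to the declared on-disk layout."""


class DataError(MuellerError):
    """File contents are structurally valid but numerically unusable."""


class DegeneratePixelError(MuellerError):
    """A pixel cannot be normalized (m11 <= 0); it should be masked."""


class CorrectionError(MuellerError):
    """Reference (substrate) correction failed, e.g. singular reference."""


class FilterError(MuellerError):
    """Physical-realizability filtering failed for a pixel."""


class DecompositionError(MuellerError):
    """A pixel-wise decomposition failed (e.g. log of a negative eigenvalue)."""


class ContractError(MuellerError):
    """An API precondition was violated by the caller."""


class MaskReason(enum.IntEnum):
    """Per-pixel reason codes attached to a :class:`PixelMask`."""

    VALID = 0
    NON_PHYSICAL = 1
    DECOMPOSITION_FAILED = 2
    BELOW_NOISE_FLOOR = 3
    NO_TISSUE = 4


def as_mueller(m: np.ndarray) -> np.ndarray:
    """Validate and return a single 4x4 real, finite Mueller matrix."""
    m = np.asarray(m, dtype=float)
    if m.shape != (4, 4):
        raise ContractError(f"expected a 4x4 Mueller matrix, got shape {m.shape}")
    if not np.all(np.isfinite(m)):
        raise DataError("Mueller matrix contains non-finite entries")
    return m


@dataclass
class MuellerImage:
    """An H x W grid of 4x4 Mueller matrices with acquisition metadata.

    Parameters
    ----------
    pixels
        Array of shape (H, W, 4, 4), float. Every entry must be finite.
    wavelength_nm
        Illumination wavelength; 550 nm in all emulated scenarios.
    pixel_size_um
        Physical pixel pitch in the sample plane.
    provenance
        Free-text record of where the image came from.
    """

    pixels: np.ndarray
    wavelength_nm: float = DEFAULT_WAVELENGTH_NM
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    provenance: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 4 or self.pixels.shape[2:] != (4, 4):
            raise ContractError(
                f"pixels must have shape (H, W, 4, 4), got {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ContractError("image must contain at least one pixel")
        if not np.all(np.isfinite(self.pixels)):
            bad = np.argwhere(~np.isfinite(self.pixels).all(axis=(2, 3)))
            raise DataError(
                f"non-finite Mueller elements at pixel(s) {bad[:10].tolist()}"
            )
        if not self.wavelength_nm > 0:
            raise ContractError("wavelength_nm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def field_of_view_um(self) -> float:
        """Horizontal field of view implied by the pixel pitch."""
        return self.pixels.shape[1] * self.pixel_size_um


@dataclass
class PixelMask:
    """Validity mask annotating an image, with per-pixel reason codes.

    ``valid`` marks pixels whose decomposition products are usable.
    ``reason`` carries a :class:`MaskReason` code; a pixel may be valid yet
    flagged (e.g. BELOW_NOISE_FLOOR pixels keep their retardance but are
    excluded from azimuth statistics by default).
    """

    valid: np.ndarray
    reason: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.reason is None:
            self.reason = np.zeros(self.valid.shape, dtype=np.uint8)
        self.reason = np.asarray(self.reason, dtype=np.uint8)
        if self.reason.shape != self.valid.shape:
            raise ContractError("mask and reason grids must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.valid.shape

    def n_valid(self) -> int:
        return int(self.valid.sum())

    @classmethod
    def all_valid(cls, shape: tuple[int, int]) -> "PixelMask":
        return cls(np.ones(shape, dtype=bool))
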