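"""Reading, writing, normalization and reference correction of Mueller images.

On-disk dialects
----------------
TIFF (``tiff16``)
    16-band band-sequential float32 TIFF, band order m11, m12, m13, m14,
    m21, ..., m44 (row-major over the 1-based optics indices). Metadata
    (wavelength_nm, pixel_size_um, provenance) is stored as a JSON object in
    the ImageDescription tag of the first page.
HDF5 (``hdf5``)
    Dataset ``"mueller"`` of shape (H, W, 4, 4) with attributes
    ``wavelength_nm``, ``pixel_size_um`` and ``provenance``.

Derived maps are written as multi-band float32 TIFF with NaN at masked
pixels plus a trailing mask band, and a CSV sidecar of box-whisker rows.
"""
from __future__ import annotations

import json
import os
from typing import Mapping

import h5py
import numpy as np
import tifffile

from .core import (
    CorrectionError,
    ContractError,
    DataError,
    DegeneratePixelError,
    FormatError,
    MuellerImage,
    PixelMask,
    as_mueller,
    DEFAULT_PIXEL_SIZE_UM,
    DEFAULT_WAVELENGTH_NM,
)

__all__ = [
    "read_mueller_image",
    "write_mueller_image",
    "normalize_m11",
    "normalize_image",
    "substrate_correct",
    "write_maps",
    "read_maps",
]

_N_BANDS = 16


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("tiff16", "hdf5"):
            raise ContractError(f"unknown format {fmt!r}; use 'tiff16' or 'hdf5'")
        return fmt
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".tif", ".tiff"):
        return "tiff16"
    if ext in (".h5", ".hdf5"):
        return "hdf5"
    raise ContractError(f"cannot infer format from extension {ext!r}")


def write_mueller_image(img: MuellerImage, path: str, format: str | None = None) -> None:
    """Write *img* to *path* in one of the documented dialects."""
    fmt = _infer_format(path, format)
    if fmt == "tiff16":
        h, w = img.shape
        bands = img.pixels.reshape(h, w, 16).transpose(2, 0, 1).astype(np.float32)
        meta = {
            "wavelength_nm": img.wavelength_nm,
            "pixel_size_um": img.pixel_size_um,
            "provenance": img.provenance,
            "band_order": "m11..m44 row-major",
        }
        tifffile.imwrite(path, bands, photometric="minisblack",
                         description=json.dumps(meta))
    else:
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("mueller", data=img.pixels.astype(np.float32))
            ds.attrs["wavelength_nm"] = img.wavelength_nm
            ds.attrs["pixel_size_um"] = img.pixel_size_um
            ds.attrs["provenance"] = img.provenance


def read_mueller_image(path: str, format: str | None = None) -> MuellerImage:
    """Read a Mueller image; missing metadata falls back to documented defaults
    (550 nm, 1.0 um/px) and is flagged in ``provenance``."""
    fmt = _infer_format(path, format)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if fmt == "tiff16":
        with tifffile.TiffFile(path) as tf:
            bands = tf.asarray()
            desc = tf.pages[0].description
        if bands.ndim != 3 or bands.shape[0] != _N_BANDS:
            raise FormatError(
                f"expected {_N_BANDS} bands (m11..m44), got array shape {bands.shape}"
            )
        pixels = bands.transpose(1, 2, 0).reshape(bands.shape[1], bands.shape[2], 4, 4)
        meta: dict = {}
        if desc:
            try:
                meta = json.loads(desc)
            except (TypeError, ValueError):
                meta = {}
    else:
        with h5py.File(path, "r") as f:
            if "mueller" not in f:
                raise FormatError("HDF5 file lacks the 'mueller' dataset")
            ds = f["mueller"]
            if ds.ndim != 4 or ds.shape[2:] != (4, 4):
                raise FormatError(
                    f"'mueller' dataset must have shape (H, W, 4, 4), got {ds.shape}"
                )
            pixels = ds[()]
            meta = {k: ds.attrs[k] for k in ds.attrs}

    pixels = np.asarray(pixels, dtype=float)
    if not np.all(np.isfinite(pixels)):
        bad = np.argwhere(~np.isfinite(pixels).all(axis=(2, 3)))
        raise DataError(f"non-finite Mueller elements at pixel(s) {bad[:10].tolist()}")

    flagged = []
    wavelength = meta.get("wavelength_nm")
    if wavelength is None:
        wavelength = DEFAULT_WAVELENGTH_NM
        flagged.append("wavelength_nm=default")
    pixel_size = meta.get("pixel_size_um")
    if pixel_size is None:
        pixel_size = DEFAULT_PIXEL_SIZE_UM
        flagged.append("pixel_size_um=default")
    provenance = str(meta.get("provenance", ""))
    if flagged:
        provenance = (provenance + " " if provenance else "") + f"[{', '.join(flagged)}]"
    return MuellerImage(pixels, float(wavelength), float(pixel_size), provenance)


def normalize_m11(M: np.ndarray) -> np.ndarray:
    """Return M / m11 so that element (1,1) is exactly 1.

    Normalization is what makes the isotropic-absorption term of the
    differential decomposition vanish (alpha0 = 0). Idempotent.
    """
    M = as_mueller(M)
    if not M[0, 0] > 0:
        raise DegeneratePixelError(f"m11 = {M[0, 0]} is not positive; mask this pixel")
    return M / M[0, 0]


def normalize_image(pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched m11-normalization of an (..., 4, 4) stack.

    Returns (normalized, degenerate) where *degenerate* marks pixels with
    m11 <= 0 (left untouched; callers must mask them).
    """
    pixels = np.asarray(pixels, dtype=float)
    m11 = pixels[..., 0, 0]
    degenerate = ~(m11 > 0)
    safe = np.where(degenerate, 1.0, m11)
    return pixels / safe[..., None, None], degenerate


def substrate_correct(M_meas: np.ndarray, M_ref: np.ndarray | None) -> np.ndarray:
    """Factor the blank-substrate response out of a measured matrix.

    In transmission the beam traverses the glass substrate before (or after)
    the sample, so the measured sequence is M_sample @ M_ref; the sample is
    recovered by right-multiplying with M_ref^-1. With no reference the
    measurement is returned unchanged.
    """
    M_meas = as_mueller(M_meas)
    if M_ref is None:
        return M_meas
    M_ref = as_mueller(M_ref)
    try:
        ref_inv = np.linalg.inv(M_ref)
    except np.linalg.LinAlgError as exc:
        raise CorrectionError("reference (substrate) matrix is singular") from exc
    if not np.all(np.isfinite(ref_inv)):
        raise CorrectionError("reference (substrate) matrix is singular")
    return M_meas @ ref_inv


def write_maps(
    maps: Mapping[str, np.ndarray],
    mask: PixelMask,
    path: str,
    summaries=None,
) -> None:
    """Write named per-pixel maps as a multi-band float32 TIFF plus sidecar CSV.

    Invalid pixels are stored as NaN. A final band holds the mask (1=valid).
    The sidecar ``<stem>_summary.csv`` stores one box-whisker row per map
    (computed here unless precomputed *summaries* are passed).
    """
    from .maps import boxwhisker_summary, summaries_to_frame  # local import: avoid cycle

    if not maps:
        raise ContractError("no maps to write")
    shapes = {m.shape for m in maps.values()}
    if len(shapes) != 1:
        raise ContractError(f"maps have mismatched shapes: {shapes}")
    (shape,) = shapes
    if shape != mask.shape:
        raise ContractError(f"mask shape {mask.shape} does not match maps {shape}")

    names = list(maps)
    bands = np.empty((len(names) + 1,) + shape, dtype=np.float32)
    for i, name in enumerate(names):
        band = np.asarray(maps[name], dtype=np.float32).copy()
        band[~mask.valid] = np.nan
        bands[i] = band
    bands[-1] = mask.valid.astype(np.float32)
    meta = {"bands": names + ["mask"]}
    tifffile.imwrite(path, bands, photometric="minisblack",
                     description=json.dumps(meta))

    if summaries is None:
        summaries = [boxwhisker_summary(maps[name], mask, map_name=name) for name in names]
    frame = summaries_to_frame(summaries)
    base, _ = os.path.splitext(str(path))
    frame.to_csv(base + "_summary.csv", index=False)


def read_maps(path: str) -> tuple[dict[str, np.ndarray], PixelMask]:
    """Read back maps written by :func:`write_maps`."""
    with tifffile.TiffFile(path) as tf:
        bands = tf.asarray()
        desc = tf.pages[0].description
    names = json.loads(desc)["bands"]
    if bands.shape[0] != len(names):
        raise FormatError("band count does not match the band-name list")
    mask = PixelMask(bands[-1] > 0.5)
    return {name: bands[i] for i, name in enumerate(names[:-1])}, mask
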