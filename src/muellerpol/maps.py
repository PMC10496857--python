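"""Pixel-wise decomposition of images and the paper-style reporting layer:
box-whisker summaries, azimuth statistics with a low-retardance floor,
quiver-field export, and cross-method comparison diagnostics.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .cloude import cloude_filter
from .core import ContractError, MaskReason, MuellerImage, PixelMask
from .differential import extract_property_grids, gl_split, matrix_log_stack
from .io import normalize_image, substrate_correct
from .lu_chipman import lu_chipman_grids

__all__ = [
    "MapSummary",
    "QuiverField",
    "ImageDecomposition",
    "decompose_image",
    "boxwhisker_summary",
    "azimuth_summary",
    "quiver_export",
    "compare_methods",
    "summaries_to_frame",
    "circular_median_deg",
]

DEFAULT_NOISE_FLOOR_DEG = 3.0

_DIFF_KEYS = (
    "p1", "p2", "p3", "p4", "p5", "p6",
    "alpha0", "alpha1", "alpha2", "alpha3",
    "d1", "d2", "d3", "d4", "d5", "d6",
)


@dataclass
class MapSummary:
    """Tukey box-whisker statistics of one map over its valid pixels.

    Whiskers sit at the most extreme data points within 1.5 x IQR of the
    quartiles; points beyond are counted as outliers. Quartiles use linear
    interpolation. An all-masked map yields an ``empty`` summary with NaN
    statistics.
    """

    map_name: str
    n_valid: int
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    n_outliers: int

    @property
    def empty(self) -> bool:
        return self.n_valid == 0

    @classmethod
    def empty_summary(cls, map_name: str) -> "MapSummary":
        nan = float("nan")
        return cls(map_name, 0, nan, nan, nan, nan, nan, 0)


@dataclass
class QuiverField:
    """Sparse azimuth sticks for visualization.

    Each stick is (row, col, angle_deg, length_norm) with length_norm the
    pixel's scalar retardance divided by the maximum retardance over all
    valid pixels.
    """

    grid_step_px: int
    sticks: list[tuple[int, int, float, float]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.sticks, columns=["row", "col", "angle_deg", "length_norm"]
        )


@dataclass
class ImageDecomposition:
    """Per-pixel property grids of one image for one or both methods."""

    mask: PixelMask
    differential: dict[str, np.ndarray] | None = None
    lu_chipman: dict[str, np.ndarray] | None = None
    min_coherency_eig: np.ndarray | None = None


def decompose_image(
    img: MuellerImage,
    method: str = "both",
    *,
    substrate_ref: np.ndarray | None = None,
    cloude_tol: float = 1e-6,
    noise_floor_deg: float = DEFAULT_NOISE_FLOOR_DEG,
) -> ImageDecomposition:
    """Normalize, filter and decompose every pixel of an image.

    Each pixel is m11-normalized, optionally substrate-corrected,
    Cloude-filtered, re-normalized and decomposed with the requested
    method(s). Per-pixel failures are masked with reason codes rather than
    aborting; with ``method='both'`` the two property sets share one mask
    (a pixel is valid only if every requested decomposition succeeded).
    Deterministic given its input.
    """
    if method not in ("differential", "lu_chipman", "both"):
        raise ContractError(f"unknown method {method!r}")
    pixels = img.pixels
    if substrate_ref is not None:
        ref_inv = np.linalg.inv(np.asarray(substrate_ref, dtype=float))
        pixels = pixels @ ref_inv

    pixels, degenerate = normalize_image(pixels)
    filtered, min_eig = cloude_filter(pixels, tol=cloude_tol)
    filtered, degen2 = normalize_image(filtered)
    degenerate = degenerate | degen2

    reason = np.zeros(img.shape, dtype=np.uint8)
    reason[degenerate] = MaskReason.NON_PHYSICAL
    valid = ~degenerate

    out = ImageDecomposition(mask=PixelMask(valid, reason), min_coherency_eig=min_eig)

    if method in ("differential", "both"):
        L, failed = matrix_log_stack(filtered)
        grids = extract_property_grids(*gl_split(L))
        diff = {f"{k}": grids[k] for k in _DIFF_KEYS}
        diff["Rt_deg"] = grids["Rt"]
        diff["theta_deg"] = grids["theta"]
        diff["alpha_t"] = grids["alpha_t"]
        out.differential = diff
        _mask_update(valid, reason, failed & valid, MaskReason.DECOMPOSITION_FAILED)

    if method in ("lu_chipman", "both"):
        lc, failed = lu_chipman_grids(filtered)
        out.lu_chipman = {k: lc[k] for k in
                          ("Rt_deg", "theta_deg", "alpha_t", "D", "P", "a", "b", "c",
                           "MD", "MR", "MDelta")}
        _mask_update(valid, reason, failed & valid, MaskReason.DECOMPOSITION_FAILED)

    # flag (but keep valid) pixels whose retardance sits below the noise floor
    rt = None
    for grids in (out.differential, out.lu_chipman):
        if grids is not None:
            rt = grids["Rt_deg"] if rt is None else np.fmax(rt, grids["Rt_deg"])
    if rt is not None:
        low = valid & (rt < noise_floor_deg)
        reason[low & (reason == MaskReason.VALID)] = MaskReason.BELOW_NOISE_FLOOR

    # NaN-out everything invalid so downstream maps agree with the mask
    for grids in (out.differential, out.lu_chipman):
        if grids is None:
            continue
        for k, v in grids.items():
            if v.ndim == 2:
                grids[k] = np.where(valid, v, np.nan)

    out.mask = PixelMask(valid, reason)
    return out


def _mask_update(valid, reason, newly_failed, code) -> None:
    reason[newly_failed] = code
    valid &= ~newly_failed


def _valid_values(map_grid: np.ndarray, mask: PixelMask | None) -> np.ndarray:
    values = np.asarray(map_grid, dtype=float)
    keep = np.isfinite(values)
    if mask is not None:
        if mask.shape != values.shape:
            raise ContractError("mask shape does not match map shape")
        keep &= mask.valid
    return values[keep]


def boxwhisker_summary(
    map_grid: np.ndarray, mask: PixelMask | None = None, map_name: str = "map"
) -> MapSummary:
    """Tukey 1.5 x IQR box-whisker summary of one map over valid pixels."""
    values = _valid_values(map_grid, mask)
    if values.size == 0:
        return MapSummary.empty_summary(map_name)
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    return MapSummary(
        map_name=map_name,
        n_valid=int(values.size),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        n_outliers=int(values.size - inside.size),
    )


def circular_median_deg(theta_deg: np.ndarray) -> float:
    """Median of 180-degree-periodic angles: the sample value minimizing the
    summed circular distances (folded to [-90, 90))."""
    theta = np.asarray(theta_deg, dtype=float)
    theta = theta[np.isfinite(theta)]
    if theta.size == 0:
        return float("nan")
    diffs = (theta[:, None] - theta[None, :] + 90.0) % 180.0 - 90.0
    cost = np.abs(diffs).sum(axis=1)
    return float(theta[np.argmin(cost)] % 180.0)


def azimuth_summary(
    theta_map: np.ndarray,
    rt_map: np.ndarray,
    mask: PixelMask | None = None,
    floor_deg: float = DEFAULT_NOISE_FLOOR_DEG,
    circular: bool = False,
) -> MapSummary:
    """Box-whisker summary of the optical-axis azimuth.

    Pixels whose scalar retardance falls below *floor_deg* (instrument
    accuracy, default 3 deg) are excluded first: their azimuth is noise.
    Default quantiles are linear on [0, 180) to match the usual box plots;
    ``circular=True`` substitutes the 180-degree-periodic median.
    """
    theta_map = np.asarray(theta_map, dtype=float)
    rt_map = np.asarray(rt_map, dtype=float)
    if theta_map.shape != rt_map.shape:
        raise ContractError("azimuth and retardance maps must share one shape")
    above = np.where(np.isfinite(rt_map) & (rt_map >= floor_deg), theta_map, np.nan)
    summary = boxwhisker_summary(above, mask, map_name="theta_deg")
    if circular and summary.n_valid:
        summary.median = circular_median_deg(_valid_values(above, mask))
    return summary


def quiver_export(
    theta_map: np.ndarray,
    rt_map: np.ndarray,
    mask: PixelMask | None = None,
    grid_step_px: int = 20,
) -> QuiverField:
    """One azimuth stick per sparse-grid node at valid pixels; stick length is
    the pixel's retardance over the image maximum (zero image -> all zero)."""
    theta_map = np.asarray(theta_map, dtype=float)
    rt_map = np.asarray(rt_map, dtype=float)
    if theta_map.shape != rt_map.shape:
        raise ContractError("azimuth and retardance maps must share one shape")
    if grid_step_px < 1:
        raise ContractError("grid_step_px must be >= 1")
    valid = np.isfinite(theta_map) & np.isfinite(rt_map)
    if mask is not None:
        valid &= mask.valid
    rt_valid = rt_map[valid]
    max_rt = float(rt_valid.max()) if rt_valid.size else 0.0
    out = QuiverField(grid_step_px=grid_step_px)
    h, w = theta_map.shape
    for r in range(0, h, grid_step_px):
        for c in range(0, w, grid_step_px):
            if not valid[r, c]:
                continue
            length = rt_map[r, c] / max_rt if max_rt > 0 else 0.0
            out.sticks.append((r, c, float(theta_map[r, c]), float(length)))
    return out


def fold_angle_difference_deg(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """a - b on the 180-degree circle, folded to [-90, 90)."""
    return (np.asarray(a) - np.asarray(b) + 90.0) % 180.0 - 90.0


def compare_methods(
    diff: dict[str, np.ndarray],
    lc: dict[str, np.ndarray],
    mask: PixelMask | None = None,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Difference maps and agreement statistics between the two decompositions.

    Returns (maps, summary) where maps hold per-pixel dRt (differential minus
    Lu-Chipman, degrees) and dtheta (folded to [-90, 90) degrees), and the
    one-row summary records the maximum absolute differences and the Spearman
    rank correlation of the two depolarization maps (the Lu-Chipman values
    run higher through 1 - exp(-x), but co-monotonically).
    """
    d_rt = diff["Rt_deg"] - lc["Rt_deg"]
    d_theta = fold_angle_difference_deg(diff["theta_deg"], lc["theta_deg"])
    valid = np.isfinite(d_rt)
    if mask is not None:
        valid &= mask.valid
    # round before ranking: piecewise-constant depolarization scenes would
    # otherwise have their ties broken inconsistently by float noise
    a_d = np.round(diff["alpha_t"][valid], 9)
    a_l = np.round(lc["alpha_t"][valid], 9)
    theta_vals = d_theta[valid & np.isfinite(d_theta)]
    if a_d.size > 1 and np.ptp(a_d) > 0 and np.ptp(a_l) > 0:
        rho = float(spearmanr(a_d, a_l).statistic)
    else:
        rho = float("nan")
    summary = pd.DataFrame(
        [
            {
                "n_valid": int(valid.sum()),
                "max_abs_dRt_deg": float(np.abs(d_rt[valid]).max()) if valid.any() else float("nan"),
                "max_abs_dtheta_deg": float(np.abs(theta_vals).max()) if theta_vals.size else float("nan"),
                "median_dRt_deg": float(np.median(d_rt[valid])) if valid.any() else float("nan"),
                "depol_spearman": rho,
            }
        ]
    )
    return {"dRt_deg": d_rt, "dtheta_deg": d_theta}, summary


def summaries_to_frame(summaries) -> pd.DataFrame:
    """MapSummary rows -> the documented CSV layout."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "map_name": s.map_name,
                "n_valid": s.n_valid,
                "median": s.median,
                "q1": s.q1,
                "q3": s.q3,
                "whisker_low": s.whisker_low,
                "whisker_high": s.whisker_high,
                "n_outliers": s.n_outliers,
            }
        )
    return pd.DataFrame(rows)
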