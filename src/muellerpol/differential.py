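"""Differential (logarithmic) decomposition of Mueller matrices.

For a medium acting continuously along the propagation direction, the
measured Mueller matrix satisfies dM = m M dz, so L = ln M accumulates the
differential matrix over the optical path. The Minkowski metric
G = diag(1, -1, -1, -1) splits L into

    mm = (L - G L^T G) / 2   (G-antisymmetric: mean polarization properties)
    mu = (L + G L^T G) / 2   (G-symmetric: depolarization and uncertainties)

The polarizing tensor mm carries the six elementary properties: linear
dichroism p1 (x-y) and p2 (+/-45 deg), circular dichroism p3, linear
birefringence p4 (x-y) and p5 (+/-45 deg), and circular birefringence p6.
The depolarizing tensor mu carries the diagonal depolarization factors
alpha0..alpha3 (alpha0 = 0 for m11-normalized input; alpha1..alpha3 <= 0 for
physical media) and the uncertainties d1..d6 of the six properties.

Summaries: net scalar retardance Rt = sqrt(p4^2 + p5^2 + p6^2) (reported in
degrees), total depolarization alpha_t = |alpha1 + alpha2 + alpha3| / 3, and
the optical-axis azimuth theta = (1/2) atan2(p5, p4) on [0, 180) degrees.

Sign conventions: all retardances are cumulative over the sample (the path
length z is absorbed); a pure linear retarder of retardance delta at azimuth
theta yields p4 = delta cos 2theta and p5 = delta sin 2theta, consistent with
the azimuth read off the Lu-Chipman retarder factor. The printed tensor
layouts in the literature disagree on the sign placement of p4/p5; here the
extraction positions are fixed by that retarder identity (see docs/methods).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .core import DecompositionError, as_mueller

__all__ = [
    "DifferentialProperties",
    "matrix_log",
    "matrix_log_stack",
    "gl_split",
    "extract_properties",
    "extract_property_grids",
    "differential_decompose",
    "G_METRIC",
]

G_METRIC = np.diag([1.0, -1.0, -1.0, -1.0])

#: below this retardance (degrees) the azimuth is undefined and reported NaN
AZIMUTH_UNDEFINED_DEG = 1e-6

#: eigenvector-matrix condition number beyond which the eigen-route log is
#: distrusted and the Schur fallback is used
_EIGBASIS_COND_LIMIT = 1e6


@dataclass
class DifferentialProperties:
    """Elementary polarization properties extracted from one pixel.

    p1..p3 are dimensionless dichroisms, p4..p6 birefringences in radians
    over the full sample path, alpha0..alpha3 dimensionless depolarizing
    factors (<= 0 for physical media after normalization), d1..d6 the
    uncertainties of the six elementary properties. Rt is in degrees,
    alpha_t dimensionless >= 0, theta in degrees on [0, 180) (NaN when the
    retardance vanishes and the axis is undefined).
    """

    p1: float
    p2: float
    p3: float
    p4: float
    p5: float
    p6: float
    alpha0: float
    alpha1: float
    alpha2: float
    alpha3: float
    d1: float
    d2: float
    d3: float
    d4: float
    d5: float
    d6: float
    Rt: float
    alpha_t: float
    theta: float
    valid: bool

    @classmethod
    def invalid(cls) -> "DifferentialProperties":
        nan = float("nan")
        return cls(*([nan] * 19), valid=False)


def _principal_branch_ok(eigvals: np.ndarray) -> np.ndarray:
    """False where an eigenvalue sits on the closed negative real axis."""
    mag = np.abs(eigvals)
    on_neg_axis = (eigvals.real <= 0) & (np.abs(eigvals.imag) <= 1e-9 * np.maximum(mag, 1.0))
    near_zero = mag < 1e-12
    return ~(on_neg_axis | near_zero)


def matrix_log(M: np.ndarray) -> np.ndarray:
    """Principal matrix logarithm via the eigenvalue-eigenvector problem.

    L = V diag(ln d_i) V^-1 with the eigenpairs of M; complex-conjugate
    eigenvalue pairs combine to a real L (imaginary residue below 1e-9 is
    discarded after checking). Eigenvector-degenerate matrices fall back to
    the Schur-based inverse-scaling-and-squaring routine.

    Raises
    ------
    DecompositionError
        If an eigenvalue lies on the closed negative real axis (the
        "logarithm of a negative number" failure mode) or the result cannot
        be made real. Callers flag the pixel invalid rather than aborting.
    """
    M = as_mueller(M)
    eigvals, V = np.linalg.eig(M)
    if not np.all(_principal_branch_ok(eigvals)):
        raise DecompositionError(
            f"eigenvalue on the negative real axis: {eigvals}; principal log undefined"
        )
    scale = max(1.0, float(np.abs(M).max()))
    resid = np.inf
    # an ill-conditioned eigenbasis (defective or nearly defective M) makes
    # V Lambda V^-1 unreliable -- and for repeated eigenvalues it can be
    # silently wrong, so gate on cond(V), not only on the residue
    if np.linalg.cond(V) < _EIGBASIS_COND_LIMIT:
        try:
            L = V @ np.diag(np.log(eigvals)) @ np.linalg.inv(V)
            resid = float(np.abs(L.imag).max())
        except np.linalg.LinAlgError:
            resid = np.inf
    if not np.isfinite(resid) or resid > 1e-9 * scale:
        # Schur-based inverse-scaling-and-squaring fallback
        L = scipy.linalg.logm(M)
        resid = float(np.abs(np.asarray(L).imag).max()) if np.iscomplexobj(L) else 0.0
        if resid > 1e-9 * scale:
            raise DecompositionError(
                f"matrix logarithm has imaginary residue {resid:.3e}"
            )
    return np.asarray(L).real


def matrix_log_stack(Ms: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched principal log of an (..., 4, 4) stack.

    Returns ``(L, failed)``; failed pixels hold NaN. Pixels whose vectorized
    eigen-route is unreliable are retried individually through
    :func:`matrix_log` (which may use the Schur fallback).
    """
    Ms = np.asarray(Ms, dtype=float)
    eigvals, V = np.linalg.eig(Ms)
    ok = np.all(_principal_branch_ok(eigvals), axis=-1)
    with np.errstate(all="ignore"):
        well_conditioned = np.linalg.cond(V) < _EIGBASIS_COND_LIMIT

    logw = np.where(ok[..., None], np.log(np.where(ok[..., None], eigvals, 1.0)), 0.0)
    with np.errstate(all="ignore"):
        try:
            Vinv = np.linalg.inv(V)
            L = (V * logw[..., None, :]) @ Vinv
        except np.linalg.LinAlgError:
            L = np.full(Ms.shape, np.nan, dtype=complex)
    scale = np.maximum(1.0, np.abs(Ms).max(axis=(-2, -1)))
    resid = np.abs(L.imag).max(axis=(-2, -1))
    good = ok & well_conditioned & np.isfinite(resid) & (resid <= 1e-9 * scale)

    out = np.where(good[..., None, None], L.real, np.nan)
    failed = ~ok
    retry = np.argwhere(ok & ~good)
    for idx in retry:
        i = tuple(idx)
        try:
            out[i] = matrix_log(Ms[i])
        except DecompositionError:
            failed[i] = True
    return out, failed


def gl_split(L: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split L into (mm, mu): G-antisymmetric and G-symmetric parts.

    mm + mu == L exactly; works on stacked (..., 4, 4) input.
    """
    L = np.asarray(L, dtype=float)
    GLTG = G_METRIC @ np.swapaxes(L, -2, -1) @ G_METRIC
    mm = 0.5 * (L - GLTG)
    mu = 0.5 * (L + GLTG)
    return mm, mu


def extract_property_grids(mm: np.ndarray, mu: np.ndarray) -> dict[str, np.ndarray]:
    """Read the elementary properties from stacked (..., 4, 4) tensors.

    Positions follow the standard polarizing/depolarizing tensor layout with
    the p4/p5 signs fixed so that a linear retarder at azimuth theta gives
    (p4, p5) = delta (cos 2theta, sin 2theta).
    """
    mm = np.asarray(mm, dtype=float)
    mu = np.asarray(mu, dtype=float)
    out = {
        "p1": mm[..., 0, 1],
        "p2": mm[..., 0, 2],
        "p3": mm[..., 0, 3],
        "p4": mm[..., 3, 2],
        "p5": mm[..., 1, 3],
        "p6": mm[..., 1, 2],
        "alpha0": mu[..., 0, 0],
        "alpha1": mu[..., 1, 1],
        "alpha2": mu[..., 2, 2],
        "alpha3": mu[..., 3, 3],
        "d1": mu[..., 0, 1],
        "d2": mu[..., 0, 2],
        "d3": mu[..., 0, 3],
        "d4": mu[..., 2, 3],
        "d5": mu[..., 1, 3],
        "d6": mu[..., 1, 2],
    }
    rt_rad = np.sqrt(out["p4"] ** 2 + out["p5"] ** 2 + out["p6"] ** 2)
    out["Rt"] = np.degrees(rt_rad)
    out["alpha_t"] = np.abs(out["alpha1"] + out["alpha2"] + out["alpha3"]) / 3.0
    theta = np.degrees(0.5 * np.arctan2(out["p5"], out["p4"])) % 180.0
    out["theta"] = np.where(out["Rt"] < AZIMUTH_UNDEFINED_DEG, np.nan, theta)
    return out


def extract_properties(mm: np.ndarray, mu: np.ndarray) -> DifferentialProperties:
    """Single-pixel extraction returning a :class:`DifferentialProperties`."""
    if not (np.all(np.isfinite(mm)) and np.all(np.isfinite(mu))):
        return DifferentialProperties.invalid()
    g = extract_property_grids(mm, mu)
    return DifferentialProperties(
        **{k: float(g[k]) for k in (
            "p1", "p2", "p3", "p4", "p5", "p6",
            "alpha0", "alpha1", "alpha2", "alpha3",
            "d1", "d2", "d3", "d4", "d5", "d6",
            "Rt", "alpha_t", "theta",
        )},
        valid=True,
    )


def differential_decompose(M: np.ndarray) -> DifferentialProperties:
    """Full chain matrix_log -> gl_split -> extract_properties for one pixel.

    Input must be physical (post-filter) and m11-normalized. On logarithm
    failure a record with ``valid=False`` is returned instead of raising.
    """
    try:
        L = matrix_log(M)
    except DecompositionError:
        return DifferentialProperties.invalid()
    mm, mu = gl_split(L)
    return extract_properties(mm, mu)
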