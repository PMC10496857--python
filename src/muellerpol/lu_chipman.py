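"""Forward Lu-Chipman polar decomposition M = M_Delta M_R M_D.

The measured Mueller matrix is factored into a diattenuator M_D (built from
the diattenuation vector read off the first row), a retarder M_R (a proper
rotation of the Poincare sphere) and a depolarizer M_Delta (symmetric 3x3
block m_Delta plus a polarizance vector), applied in that sequence.

Summaries: net scalar retardance Rt = arccos[tr(M_R)/2 - 1], net
depolarization alpha_t = 1 - (|a|+|b|+|c|)/3 with a, b, c the principal
values of m_Delta, and the optical-axis azimuth theta on [0, 180) degrees.
The azimuth is extracted from the retardance vector, i.e. the antisymmetric
part of the retarder block (sin R * axis); for a pure linear retarder this
reduces to the familiar element-ratio form tan 2theta = MR(2,4)/MR(4,3).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import DegeneratePixelError, as_mueller
from .differential import AZIMUTH_UNDEFINED_DEG

__all__ = [
    "LuChipmanProducts",
    "diattenuation_polarizance",
    "diattenuator_matrix",
    "strip_diattenuator",
    "depolarizer_retarder_split",
    "lu_chipman_summaries",
    "lu_chipman_decompose",
    "lu_chipman_grids",
]

# diattenuation above this is treated as a singular diattenuator (pixel masked)
_D_SINGULAR = 1.0 - 1e-12
# smallest |det m'| for which the retarder factor is still defined
_DET_FLOOR = 1e-300


@dataclass
class LuChipmanProducts:
    """Factors and summaries of the forward polar decomposition of one pixel."""

    MD: np.ndarray
    MR: np.ndarray
    MDelta: np.ndarray
    D: float
    Dvec: np.ndarray
    P: float
    Pvec: np.ndarray
    a: float
    b: float
    c: float
    Rt: float
    alpha_t: float
    theta: float
    valid: bool

    @classmethod
    def invalid(cls) -> "LuChipmanProducts":
        nan = float("nan")
        nan4 = np.full((4, 4), np.nan)
        nan3 = np.full(3, np.nan)
        return cls(nan4, nan4, nan4, nan, nan3, nan, nan3,
                   nan, nan, nan, nan, nan, nan, valid=False)


def diattenuation_polarizance(
    M: np.ndarray,
) -> tuple[float, np.ndarray, float, np.ndarray]:
    """Net diattenuation/polarizance scalars and vectors from row/column one.

    Dvec = (m12, m13, m14)/m11 and Pvec = (m21, m31, m41)/m11 (optics 1-based
    indices). Emits a non-physical warning when D exceeds 1 (such pixels
    should have been removed by the Cloude filter).
    """
    M = as_mueller(M)
    m11 = M[0, 0]
    if not m11 > 0:
        raise DegeneratePixelError("m11 must be positive")
    Dvec = M[0, 1:] / m11
    Pvec = M[1:, 0] / m11
    D = float(np.linalg.norm(Dvec))
    P = float(np.linalg.norm(Pvec))
    if D > 1.0 + 1e-9:
        warnings.warn(
            f"diattenuation D = {D:.6f} > 1: non-physical pixel (filter first)",
            RuntimeWarning,
            stacklevel=2,
        )
    return D, Dvec, P, Pvec


def diattenuator_matrix(D: float, Dvec: np.ndarray) -> np.ndarray:
    """Assemble the (normalized) diattenuator from its diattenuation vector.

    mD = sqrt(1-D^2) I + (1 - sqrt(1-D^2)) Dhat Dhat^T; MD is symmetric and
    equals the identity for D = 0. Requires D < 1 for invertibility.
    """
    Dvec = np.asarray(Dvec, dtype=float)
    if D >= _D_SINGULAR:
        raise DegeneratePixelError(
            f"D = {D} >= 1: singular diattenuator, retarder/depolarizer undefined"
        )
    MD = np.eye(4)
    MD[0, 1:] = Dvec
    MD[1:, 0] = Dvec
    root = np.sqrt(max(1.0 - D * D, 0.0))
    if D > 0:
        Dhat = Dvec / D
        mD = root * np.eye(3) + (1.0 - root) * np.outer(Dhat, Dhat)
    else:
        mD = np.eye(3)
    MD[1:, 1:] = mD
    return MD


def strip_diattenuator(M: np.ndarray, MD: np.ndarray) -> np.ndarray:
    """M' = M MD^-1, the remaining depolarizer-retarder product.

    The first row of M' is (1, 0, 0, 0) up to numerical tolerance.
    """
    return as_mueller(M) @ np.linalg.inv(as_mueller(MD))


def depolarizer_retarder_split(
    Mprime: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float, float, float]:
    """Split M' = M_Delta M_R via the symmetric square root of m' m'^T.

    m_Delta = sign(det m') (m' m'^T)^(1/2) computed by eigendecomposition of
    m' m'^T (the symmetric factor of the polar decomposition of m'; the sign
    prescription keeps the retarder a proper rotation). Returns
    (M_Delta, M_R, a, b, c) with a, b, c the principal values of m_Delta.

    Raises
    ------
    DegeneratePixelError
        If m' is singular (complete depolarization along an axis): the
        retarder factor is undefined.
    """
    Mprime = as_mueller(Mprime)
    mp = Mprime[1:, 1:]
    det = np.linalg.det(mp)
    sign = 1.0 if det >= 0 else -1.0
    lam, V = np.linalg.eigh(mp @ mp.T)
    lam = np.clip(lam, 0.0, None)
    roots = np.sqrt(lam)
    mdelta = sign * (V * roots) @ V.T
    # principal values, descending by magnitude
    abc = sign * roots[::-1]

    MDelta = np.eye(4)
    MDelta[1:, 0] = Mprime[1:, 0]
    MDelta[1:, 1:] = mdelta
    if abs(det) < _DET_FLOOR or np.any(roots < 1e-14):
        raise DegeneratePixelError(
            "m' is singular: retarder undefined (depolarizer still available)"
        )
    mdelta_inv = sign * (V * (1.0 / roots)) @ V.T
    MR = np.eye(4)
    MR[1:, 1:] = mdelta_inv @ mp
    return MDelta, MR, float(abc[0]), float(abc[1]), float(abc[2])


def _retardance_deg(MR: np.ndarray) -> np.ndarray:
    arg = np.trace(MR, axis1=-2, axis2=-1) / 2.0 - 1.0
    if np.any(np.abs(arg) > 1.0 + 1e-9):
        raise DegeneratePixelError(f"tr(MR)/2 - 1 = {arg} outside [-1, 1]")
    return np.degrees(np.arccos(np.clip(arg, -1.0, 1.0)))


def _azimuth_deg(MR: np.ndarray, Rt_deg: np.ndarray) -> np.ndarray:
    # retardance vector = antisymmetric part of mR: (sin R) * rotation axis
    n1 = 0.5 * (MR[..., 3, 2] - MR[..., 2, 3])
    n2 = 0.5 * (MR[..., 1, 3] - MR[..., 3, 1])
    theta = np.degrees(0.5 * np.arctan2(n2, n1)) % 180.0
    undefined = (Rt_deg < AZIMUTH_UNDEFINED_DEG) | (
        (np.abs(n1) < 1e-12) & (np.abs(n2) < 1e-12)
    )
    return np.where(undefined, np.nan, theta)


def lu_chipman_summaries(
    MDelta: np.ndarray, MR: np.ndarray
) -> tuple[float, float, float]:
    """(Rt degrees, alpha_t, theta degrees) from the retarder and depolarizer.

    alpha_t = 1 - (|a|+|b|+|c|)/3 with a, b, c the principal values of the
    3x3 depolarizer block; theta is NaN when the retardance vanishes.
    """
    MDelta = as_mueller(MDelta)
    MR = as_mueller(MR)
    Rt = float(_retardance_deg(MR))
    abc = np.linalg.eigvalsh(0.5 * (MDelta[1:, 1:] + MDelta[1:, 1:].T))
    alpha_t = float(1.0 - np.abs(abc).sum() / 3.0)
    theta = float(_azimuth_deg(MR, np.asarray(Rt)))
    return Rt, alpha_t, theta


def lu_chipman_decompose(M: np.ndarray) -> LuChipmanProducts:
    """Full forward decomposition of one physical, m11-normalized pixel.

    Failure modes (singular diattenuator, singular m') return a record with
    ``valid=False`` rather than raising.
    """
    M = as_mueller(M)
    try:
        D, Dvec, P, Pvec = diattenuation_polarizance(M)
        MD = diattenuator_matrix(D, Dvec)
        Mprime = strip_diattenuator(M, MD)
        MDelta, MR, a, b, c = depolarizer_retarder_split(Mprime)
        Rt, alpha_t, theta = lu_chipman_summaries(MDelta, MR)
    except DegeneratePixelError:
        return LuChipmanProducts.invalid()
    return LuChipmanProducts(
        MD=MD, MR=MR, MDelta=MDelta, D=D, Dvec=Dvec, P=P, Pvec=Pvec,
        a=a, b=b, c=c, Rt=Rt, alpha_t=alpha_t, theta=theta, valid=True,
    )


def lu_chipman_grids(Ms: np.ndarray) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Batched decomposition of an (..., 4, 4) stack of normalized matrices.

    Returns ``(grids, failed)`` with grids Rt_deg / theta_deg / alpha_t /
    D / P / a / b / c and reconstruction factors stacked as MD, MR, MDelta.
    Failed pixels (singular diattenuator or singular m') hold NaN.
    """
    Ms = np.asarray(Ms, dtype=float)
    lead = Ms.shape[:-2]
    m11 = Ms[..., 0, 0]
    Dvec = Ms[..., 0, 1:] / m11[..., None]
    Pvec = Ms[..., 1:, 0] / m11[..., None]
    D = np.linalg.norm(Dvec, axis=-1)
    P = np.linalg.norm(Pvec, axis=-1)
    failed = ~(m11 > 0) | (D >= _D_SINGULAR)

    root = np.sqrt(np.clip(1.0 - D * D, 0.0, None))
    Dsafe = np.where(D > 0, D, 1.0)
    Dhat = Dvec / Dsafe[..., None]
    outer = Dhat[..., :, None] * Dhat[..., None, :]
    mD = root[..., None, None] * np.eye(3) + (1.0 - root)[..., None, None] * outer
    MD = np.zeros(lead + (4, 4))
    MD[..., 0, 0] = 1.0
    MD[..., 0, 1:] = Dvec
    MD[..., 1:, 0] = Dvec
    MD[..., 1:, 1:] = mD

    MD_safe = np.where(failed[..., None, None], np.eye(4), MD)
    Mprime = (Ms / np.where(failed, 1.0, m11)[..., None, None]) @ np.linalg.inv(MD_safe)

    mp = Mprime[..., 1:, 1:]
    det = np.linalg.det(mp)
    sign = np.where(det >= 0, 1.0, -1.0)
    lam, V = np.linalg.eigh(mp @ np.swapaxes(mp, -2, -1))
    lam = np.clip(lam, 0.0, None)
    roots = np.sqrt(lam)
    singular = roots[..., 0] < 1e-14
    failed = failed | singular

    Vt = np.swapaxes(V, -2, -1)
    mdelta = sign[..., None, None] * (V * roots[..., None, :]) @ Vt
    roots_safe = np.where(roots < 1e-14, 1.0, roots)
    mdelta_inv = sign[..., None, None] * (V * (1.0 / roots_safe)[..., None, :]) @ Vt
    mR = mdelta_inv @ mp

    MDelta = np.zeros(lead + (4, 4))
    MDelta[..., 0, 0] = 1.0
    MDelta[..., 1:, 0] = Mprime[..., 1:, 0]
    MDelta[..., 1:, 1:] = mdelta
    MR = np.zeros(lead + (4, 4))
    MR[..., 0, 0] = 1.0
    MR[..., 1:, 1:] = mR

    arg = np.clip(np.trace(MR, axis1=-2, axis2=-1) / 2.0 - 1.0, -1.0, 1.0)
    Rt = np.degrees(np.arccos(arg))
    theta = _azimuth_deg(MR, Rt)
    abc = sign[..., None] * roots[..., ::-1]
    alpha_t = 1.0 - np.abs(abc).sum(axis=-1) / 3.0

    grids = {
        "Rt_deg": np.where(failed, np.nan, Rt),
        "theta_deg": np.where(failed, np.nan, theta),
        "alpha_t": np.where(failed, np.nan, alpha_t),
        "D": np.where(failed, np.nan, D),
        "P": np.where(failed, np.nan, P),
        "a": np.where(failed, np.nan, abc[..., 0]),
        "b": np.where(failed, np.nan, abc[..., 1]),
        "c": np.where(failed, np.nan, abc[..., 2]),
        "MD": MD,
        "MR": MR,
        "MDelta": MDelta,
    }
    return grids, failed
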