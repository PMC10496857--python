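"""Cloude physical-realizability filtering of Mueller matrices.

A 4x4 real matrix is a physical Mueller matrix iff its Hermitian coherency
matrix H = (1/4) sum_ij m_ij (sigma_i x sigma_j*) is positive semidefinite,
where sigma_0..sigma_3 are the identity and the Pauli matrices ordered to
match the (I, Q, U, V) Stokes convention. Measurement noise routinely pushes
one or more coherency eigenvalues slightly negative; the filter clamps them
to zero and maps back, which is the minimal projection onto the physical
cone in the coherency eigenbasis.

All functions accept either a single (4, 4) matrix or a stacked
(..., 4, 4) array and vectorize over leading axes.
"""
from __future__ import annotations

import numpy as np

from .core import DataError, FilterError

__all__ = [
    "coherency_from_mueller",
    "mueller_from_coherency",
    "cloude_filter",
    "is_physical",
]

_PAULI = np.array(
    [
        [[1, 0], [0, 1]],
        [[1, 0], [0, -1]],
        [[0, 1], [1, 0]],
        [[0, -1j], [1j, 0]],
    ],
    dtype=complex,
)

# basis[i, j] = sigma_i kron sigma_j^*, shape (4, 4, 4, 4)
_BASIS = np.einsum("iab,jcd->ijacbd", _PAULI, _PAULI.conj()).reshape(4, 4, 4, 4)


def coherency_from_mueller(M: np.ndarray) -> np.ndarray:
    """Map Mueller matrices to Hermitian coherency matrices (linear, invertible)."""
    M = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(M)):
        raise DataError("non-finite Mueller elements")
    H = 0.25 * np.einsum("...ij,ijab->...ab", M, _BASIS)
    return H


def mueller_from_coherency(H: np.ndarray, imag_tol: float = 1e-8) -> np.ndarray:
    """Exact inverse of :func:`coherency_from_mueller`.

    The reconstructed Mueller matrix must be real; an imaginary residue above
    *imag_tol* (relative to the coherency trace) signals a non-Hermitian input
    and raises.
    """
    H = np.asarray(H, dtype=complex)
    M = np.einsum("ijab,...ba->...ij", _BASIS, H)
    scale = np.maximum(np.abs(np.trace(H, axis1=-2, axis2=-1)), 1.0)
    resid = np.abs(M.imag).max(axis=(-2, -1)) / scale
    if np.any(resid > imag_tol):
        raise DataError(
            f"imaginary residue {float(np.max(resid)):.3e} exceeds {imag_tol:.1e}; "
            "input coherency is not Hermitian"
        )
    return M.real


def _coherency_spectrum(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    H = coherency_from_mueller(M)
    w, V = np.linalg.eigh(0.5 * (H + np.swapaxes(H, -2, -1).conj()))
    return w, V


def is_physical(M: np.ndarray, tol: float = 1e-6) -> bool | np.ndarray:
    """True iff the minimum coherency eigenvalue is >= -tol * trace(H)."""
    w, _ = _coherency_spectrum(M)
    trace = np.clip(w.sum(axis=-1), 0.0, None)
    ok = w[..., 0] >= -tol * np.maximum(trace, np.finfo(float).tiny)
    return bool(ok) if ok.ndim == 0 else ok


def cloude_filter(
    M: np.ndarray, tol: float = 1e-6, renormalize: bool = False
) -> tuple[np.ndarray, float | np.ndarray]:
    """Project onto the physical cone by clamping negative coherency eigenvalues.

    Returns ``(M_filtered, min_eigenvalue)`` where *min_eigenvalue* is the
    pre-clamp minimum (diagnostic; >= 0 means the input was already physical
    and is returned unchanged, making the filter idempotent).

    With ``renormalize=True`` the clamped spectrum is rescaled to preserve the
    coherency trace (total intensity); the default keeps the clamped spectrum
    as-is so that filtering never adds energy.
    """
    M = np.asarray(M, dtype=float)
    w, V = _coherency_spectrum(M)
    if not np.all(np.isfinite(w)):
        raise FilterError("non-finite coherency eigenvalues; mask this pixel")
    min_eig = w[..., 0]
    trace = w.sum(axis=-1)
    physical = min_eig >= -tol * np.maximum(np.abs(trace), np.finfo(float).tiny)

    w_cl = np.clip(w, 0.0, None)
    if renormalize:
        new_tr = w_cl.sum(axis=-1)
        scale = np.where(new_tr > 0, trace / np.where(new_tr > 0, new_tr, 1.0), 1.0)
        w_cl = w_cl * scale[..., None]
    H_cl = (V * w_cl[..., None, :]) @ np.swapaxes(V, -2, -1).conj()
    M_cl = mueller_from_coherency(H_cl)
    out = np.where(physical[..., None, None], M, M_cl)
    if out.ndim == 2:
        return out, float(min_eig)
    return out, min_eig
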