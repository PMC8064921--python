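"""Small numerical helpers shared across modules."""

from __future__ import annotations

import numpy as np

from .errors import NotPSDError


def check_psd(mat: np.ndarray, name: str = "matrix", tol: float = 1e-8) -> None:
    """Raise :class:`NotPSDError` if ``mat`` is not symmetric PSD.

    ``tol`` is an absolute tolerance on the most negative eigenvalue,
    scaled by the largest absolute diagonal entry so the check is
    meaningful for covariance matrices of any magnitude.
    """
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise NotPSDError(f"{name} must be square, got shape {mat.shape}")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise NotPSDError(f"{name} is not symmetric")
    w = np.linalg.eigvalsh(mat)
    scale = max(np.abs(np.diag(mat)).max(), 1.0)
    if w.min() < -tol * scale:
        raise NotPSDError(
            f"{name} is not positive semidefinite: "
            f"smallest eigenvalue {w.min():.6g}",
            min_eigenvalue=float(w.min()),
        )


def bend_psd(
    mat: np.ndarray, floor: float = 1e-6, preserve_diagonal: bool = True
) -> tuple[np.ndarray, float]:
    """Clip eigenvalues of a symmetric matrix at ``floor`` and, optionally,
    rescale rows/columns so the original diagonal is preserved.

    Returns the bent matrix and the spectral norm of the perturbation
    ``||bent - mat||_2``.
    """
    mat = np.asarray(mat, dtype=float)
    sym = 0.5 * (mat + mat.T)
    w, v = np.linalg.eigh(sym)
    bent = (v * np.clip(w, floor, None)) @ v.T
    if preserve_diagonal:
        target = np.diag(sym).copy()
        # a clipped-to-floor diagonal entry cannot be restored below floor
        target = np.maximum(target, floor)
        d = np.sqrt(target / np.diag(bent))
        bent = bent * np.outer(d, d)
    bent = 0.5 * (bent + bent.T)
    perturbation = float(np.linalg.norm(bent - mat, 2))
    return bent, perturbation


def rng_from_seed(seed: int) -> np.random.Generator:
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    return np.random.default_rng(int(seed))
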