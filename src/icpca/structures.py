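"""Mass-weighted rigid-body superposition and ensemble summaries.

The optimal rotation is the weighted Kabsch solution (reflections
excluded, so chirality — mandatory for a sterol — is preserved). The
mean structure is obtained by fitting every frame onto a reference and
averaging; the "most representative" frame is the one with minimum
mass-weighted RMSD from that mean.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import InputError
from .io import Ensemble, Structure

__all__ = ["superpose", "mean_structure", "EnsembleSummary", "weighted_rmsd"]


def _check_weights(n: int, weights) -> np.ndarray:
    if weights is None:
        return np.ones(n)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise InputError(f"weights have shape {w.shape}, expected ({n},)")
    if np.any(w < 0) or w.sum() <= 0:
        raise InputError("weights must be nonnegative with positive sum")
    return w


def weighted_rmsd(a: np.ndarray, b: np.ndarray, weights=None) -> float:
    """Mass-weighted RMSD between two already-aligned coordinate sets."""
    w = _check_weights(a.shape[0], weights)
    d2 = np.sum((a - b) ** 2, axis=1)
    return float(np.sqrt(np.sum(w * d2) / np.sum(w)))


def _kabsch(mobile: np.ndarray, reference: np.ndarray,
            weights: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted optimal rotation/translation, reflection excluded.

    Returns (rotation matrix, mobile centroid, reference centroid) such
    that R @ (mobile - cm) + cr best fits reference.
    """
    wsum = weights.sum()
    cm = (weights[:, None] * mobile).sum(axis=0) / wsum
    cr = (weights[:, None] * reference).sum(axis=0) / wsum
    rot, _ = Rotation.align_vectors(reference - cr, mobile - cm, weights=weights)
    return rot.as_matrix(), cm, cr


def superpose(mobile: Structure | np.ndarray, reference: Structure | np.ndarray,
              weights=None) -> tuple[np.ndarray, float]:
    """Optimally fit ``mobile`` onto ``reference``.

    Returns the transformed mobile coordinates and the minimized
    weighted RMSD. Pass atom masses as ``weights`` for mass weighting;
    ``None`` means uniform weights.
    """
    mob = mobile.coords if isinstance(mobile, Structure) else np.asarray(mobile, float)
    ref = reference.coords if isinstance(reference, Structure) else np.asarray(reference, float)
    if mob.shape != ref.shape:
        raise InputError(
            f"atom count mismatch: mobile {mob.shape[0]} vs reference {ref.shape[0]}"
        )
    if weights is None and isinstance(mobile, Structure):
        weights = mobile.masses
    w = _check_weights(mob.shape[0], weights)
    R, cm, cr = _kabsch(mob, ref, w)
    fitted = (mob - cm) @ R.T + cr
    return fitted, weighted_rmsd(fitted, ref, w)


@dataclasses.dataclass
class EnsembleSummary:
    """Mean structure, per-frame RMSDs to it, and the representative frame."""

    reference_frame: int
    mean: Structure
    rmsd_to_mean: np.ndarray       # Angstrom, one per frame
    representative_frame: int
    iterations: int = 1

    def __post_init__(self) -> None:
        if np.any(self.rmsd_to_mean < 0):
            raise InputError("RMSD values must be nonnegative")
        if int(np.argmin(self.rmsd_to_mean)) != self.representative_frame:
            raise InputError("representative frame does not minimize RMSD")


def mean_structure(ensemble: Ensemble, reference: int = 0,
                   iterative: bool = False, tol: float = 1e-6,
                   max_iter: int = 100) -> EnsembleSummary:
    """Superpose all frames onto a reference frame and average.

    Every frame is mass-weighted-fitted onto frame ``reference`` (all
    atoms, hydrogens included), coordinates are averaged, then each
    original frame is re-fitted onto the mean to obtain its RMSD. The
    representative frame is the argmin (ties -> lowest index). With
    ``iterative=True`` the fit-average cycle repeats against the current
    mean until it moves less than ``tol`` Angstrom per coordinate.
    """
    if not 0 <= reference < ensemble.n_frames:
        raise InputError(f"reference frame {reference} out of range")
    w = ensemble.masses
    target = ensemble.coords[reference]
    iterations = 0
    while True:
        iterations += 1
        fitted = np.empty_like(ensemble.coords)
        for f in range(ensemble.n_frames):
            fitted[f], _ = superpose(ensemble.coords[f], target, weights=w)
        mean_coords = fitted.mean(axis=0)
        shift = np.max(np.abs(mean_coords - target)) if iterative else 0.0
        target = mean_coords
        if not iterative or shift < tol or iterations >= max_iter:
            break
    rmsds = np.empty(ensemble.n_frames)
    for f in range(ensemble.n_frames):
        _, rmsds[f] = superpose(ensemble.coords[f], mean_coords, weights=w)
    rep = int(np.argmin(rmsds))
    mean = Structure(ensemble.labels, ensemble.elements, ensemble.masses, mean_coords)
    return EnsembleSummary(reference, mean, rmsds, rep, iterations)
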