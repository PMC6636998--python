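"""Schlitter upper bound on configurational entropy.

The entropy of a trajectory is estimated from the mass-weighted positional
covariance matrix sigma (sigma_ij = <(x_i - <x_i>)(x_j - <x_j>)>, SI
units) via Schlitter's determinant bound

    S' = (k_B / 2) * ln det( 1 + (k_B T e^2 / hbar^2) M sigma )

evaluated through the eigenvalues of the symmetrically mass-weighted
covariance M^1/2 sigma M^1/2.  S' is an upper bound to the true
configurational entropy and is exact for a harmonic system in the
high-temperature limit.  Rigid-body translation/rotation is removed by
least-squares superposition onto the mean structure before the covariance
is accumulated (optional but on by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import constants

from .traj_io import Trajectory

__all__ = [
    "EntropyResult",
    "mass_weighted_covariance",
    "schlitter_entropy",
    "trajectory_entropy",
]

_NM = 1e-9  # m per nm


@dataclass
class EntropyResult:
    """Schlitter entropy estimate."""

    S_per_molecule: float  # J/K
    S_per_mole: float  # J/(K mol)
    S_kB: float  # dimensionless, units of k_B per molecule
    temperature: float  # K
    n_modes: int
    n_clipped: int  # negative covariance eigenvalues clipped to zero
    frames_used: int
    superposed: bool


def _kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Proper rotation aligning centred ``mobile`` onto centred ``reference``."""
    h = mobile.T @ reference
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    return vt.T @ np.diag([1.0, 1.0, d]) @ u.T


def _superpose_frames(coords: np.ndarray, n_iter: int = 2) -> np.ndarray:
    """Least-squares fit all frames onto their mean structure (iterated)."""
    fitted = coords - coords.mean(axis=1, keepdims=True)
    reference = fitted[0]
    for _ in range(n_iter):
        aligned = np.empty_like(fitted)
        for f in range(fitted.shape[0]):
            rot = _kabsch_rotation(fitted[f], reference)
            aligned[f] = fitted[f] @ rot.T
        reference = aligned.mean(axis=0)
        fitted = aligned
    return fitted


def mass_weighted_covariance(
    traj: Trajectory,
    atom_indices: np.ndarray | None = None,
    superpose: bool = True,
) -> np.ndarray:
    """Mass-weighted positional covariance M^1/2 sigma M^1/2 (kg m^2).

    Coordinates are converted nm -> m and masses Da -> kg.  The covariance
    uses the maximum-likelihood normalisation 1/n_frames, so duplicating
    frames leaves it unchanged.  With ``superpose`` the frames are first
    least-squares fitted onto the mean structure, removing rigid-body
    translation and rotation (requires >= 2 atoms not collinear; disable
    for toy one-particle systems).
    """
    if traj.n_frames < 2:
        raise ValueError("covariance needs at least 2 frames")
    if atom_indices is None:
        atom_indices = np.arange(traj.n_atoms)
    atom_indices = np.asarray(atom_indices, dtype=int)
    coords = traj.coords[:, atom_indices, :] * _NM
    masses_kg = (
        traj.topology["mass"].to_numpy()[atom_indices] * constants.atomic_mass
    )

    if superpose:
        coords = _superpose_frames(coords)

    n_frames, n_atoms, _ = coords.shape
    x = coords.reshape(n_frames, n_atoms * 3)
    dx = x - x.mean(axis=0)
    sigma = dx.T @ dx / n_frames  # ML normalisation: duplication-invariant
    w = np.sqrt(np.repeat(masses_kg, 3))
    return sigma * np.outer(w, w)


def schlitter_entropy(
    covariance: np.ndarray, temperature: float = 300.0
) -> EntropyResult:
    """Schlitter entropy from a mass-weighted covariance matrix.

    ``covariance`` must be symmetric, in kg m^2 (as produced by
    :func:`mass_weighted_covariance`); negative eigenvalues (numerical
    noise) are clipped to zero, which leaves ln(1 + 0) = 0 contributions.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive (K)")
    cov = np.asarray(covariance, dtype=float)
    if cov.ndim == 0:
        cov = cov.reshape(1, 1)
    if cov.shape[0] != cov.shape[1] or not np.allclose(cov, cov.T, atol=1e-30):
        raise ValueError("covariance must be a symmetric square matrix")

    eigvals = np.linalg.eigvalsh(cov)
    n_clipped = int(np.count_nonzero(eigvals < 0))
    eigvals = np.clip(eigvals, 0.0, None)

    kb = constants.Boltzmann
    alpha = kb * temperature * np.e**2 / constants.hbar**2
    s_molecule = 0.5 * kb * float(np.sum(np.log1p(alpha * eigvals)))
    return EntropyResult(
        S_per_molecule=s_molecule,
        S_per_mole=s_molecule * constants.Avogadro,
        S_kB=s_molecule / kb,
        temperature=float(temperature),
        n_modes=cov.shape[0],
        n_clipped=n_clipped,
        frames_used=-1,
        superposed=False,
    )


def trajectory_entropy(
    traj: Trajectory,
    atom_indices: np.ndarray | None = None,
    temperature: float = 300.0,
    superpose: bool = True,
) -> EntropyResult:
    """Convenience wrapper: covariance + Schlitter bound in one call."""
    cov = mass_weighted_covariance(traj, atom_indices, superpose=superpose)
    res = schlitter_entropy(cov, temperature)
    res.frames_used = traj.n_frames
    res.superposed = superpose
    return res
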