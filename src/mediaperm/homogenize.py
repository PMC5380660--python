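"""Effective permeability tensor by volume-average homogenisation.

Three directional Brinkman solves give volume averages (<u>, <grad p>).
Darcy's law <u> = (k / mu) <grad p> with a symmetric 3x3 permeability
tensor k has six unknowns (k_rr, k_rz, k_rt, k_zz, k_zt, k_tt); the three
samples supply nine scalar equations, and the over-determined system is
solved by least squares. Diagonalising k yields the principal
permeabilities: K11 is the component whose eigenvector lies closest to the
radial direction (the dominant transmural transport direction), K12 and
K13 the two transverse components in descending order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .brinkman import HomogenizationSample

__all__ = ["DarcySystem", "PermeabilityTensor", "assemble_darcy_system",
           "solve_permeability_tensor", "principal_permeabilities"]

# (row, col) of each of the 6 symmetric unknowns in the 3x3 tensor
_SYM_INDEX = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]


def tensor_from_vector(x: np.ndarray) -> np.ndarray:
    """Symmetric 3x3 tensor from its 6-vector (rr, rz, rt, zz, zt, tt)."""
    k = np.zeros((3, 3))
    for val, (i, j) in zip(x, _SYM_INDEX):
        k[i, j] = k[j, i] = val
    return k


@dataclass
class DarcySystem:
    """Over-determined linear system M x = rhs for the 6 symmetric tensor
    components, with conditioning diagnostics."""

    matrix: np.ndarray  # (9, 6)
    rhs: np.ndarray  # (9,)
    viscosity_mu: float
    condition_number: float


@dataclass
class PermeabilityTensor:
    k: np.ndarray  # symmetric 3x3, m^2
    principal_values: tuple[float, float, float]  # (K11, K12, K13)
    principal_axes: np.ndarray  # rows: axes of K11, K12, K13
    residual: float

    @property
    def k11(self) -> float:
        return self.principal_values[0]


def assemble_darcy_system(samples: list[HomogenizationSample],
                          viscosity_mu: float) -> DarcySystem:
    """Stack the Darcy relations of three directional samples.

    Each sample contributes three equations
        <u>_i = (1/mu) * sum_j k_ij <grad p>_j,
    parameterised by the six symmetric unknowns. The three mean gradients
    must be linearly independent.
    """
    if len(samples) != 3:
        raise ValueError("exactly three directional samples are required")
    if viscosity_mu <= 0:
        raise ValueError("viscosity must be positive")
    grads = np.array([s.mean_pressure_gradient for s in samples])
    if np.linalg.matrix_rank(grads, tol=1e-9 * np.abs(grads).max()) < 3:
        raise ValueError("mean pressure gradients are not linearly "
                         "independent (rank-deficient gradient set)")

    M = np.zeros((9, 6))
    rhs = np.zeros(9)
    for s_idx, s in enumerate(samples):
        g = s.mean_pressure_gradient
        for i in range(3):
            row = 3 * s_idx + i
            for col, (a, b) in enumerate(_SYM_INDEX):
                # k_ab contributes to component i when a == i or b == i
                if a == i:
                    M[row, col] += g[b] / viscosity_mu
                elif b == i:
                    M[row, col] += g[a] / viscosity_mu
            rhs[row] = s.mean_velocity[i]
    cond = float(np.linalg.cond(M))
    return DarcySystem(matrix=M, rhs=rhs, viscosity_mu=viscosity_mu,
                       condition_number=cond)


def solve_permeability_tensor(system: DarcySystem) -> PermeabilityTensor:
    """Minimum-norm least-squares solution for the symmetric tensor;
    symmetry is exact by parameterisation, not post-hoc symmetrisation."""
    x, *_ = np.linalg.lstsq(system.matrix, system.rhs, rcond=None)
    k = tensor_from_vector(x)
    residual = float(np.linalg.norm(system.matrix @ x - system.rhs))
    vals, axes = principal_permeabilities(k)
    return PermeabilityTensor(k=k, principal_values=vals,
                              principal_axes=axes, residual=residual)


def principal_permeabilities(k: np.ndarray) -> tuple[tuple[float, float, float], np.ndarray]:
    """Eigendecomposition of the symmetric permeability tensor.

    Returns ((K11, K12, K13), axes): K11 is the eigenvalue whose
    eigenvector has the largest |component| along the radial unit vector
    (ties broken toward the smaller eigenvalue); K12 >= K13 are the
    remaining eigenvalues. axes[i] is the unit eigenvector of the i-th
    returned value.
    """
    k = np.asarray(k, dtype=float)
    if k.shape != (3, 3) or not np.allclose(k, k.T, rtol=0, atol=1e-12 * max(1.0, np.abs(k).max())):
        raise ValueError("k must be a symmetric 3x3 tensor")
    w, v = np.linalg.eigh(k)  # ascending eigenvalues, columns are vectors
    radial_weight = np.abs(v[0, :])
    best = radial_weight.max()
    # tie-break: among (near-)maximal radial alignment take the smallest
    # eigenvalue; eigh returns ascending order so the first hit wins
    candidates = np.nonzero(np.isclose(radial_weight, best, rtol=1e-9, atol=1e-12))[0]
    i11 = int(candidates[0])
    rest = [i for i in range(3) if i != i11]
    rest.sort(key=lambda i: -w[i])  # K12 >= K13
    order = [i11] + rest
    vals = tuple(float(w[i]) for i in order)
    axes = np.array([v[:, i] for i in order])
    return vals, axes
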