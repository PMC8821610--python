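"""Interacting-dipole (Applequist-Thole) polarizability engine.

Each atom i carries an isotropic polarizability volume ``alpha_i`` (A^3) and
acquires an induced dipole from the applied field plus the fields of all
other induced dipoles:

    mu_i = alpha_i * (E(r_i) - sum_{j != i} T_ij mu_j)

where ``T_ij`` is the dipole field tensor (A^-3).  At short range the tensor
is damped with Thole's smearing function (damping length
``s = 1.662 (alpha_i alpha_j)^(1/6)``) to avoid the polarization
catastrophe.  Collecting the N coupled 3-vectors gives a symmetric 3N x 3N
linear system ``A mu = E`` whose diagonal blocks are ``alpha_i^-1 I`` and
whose off-diagonal blocks are ``T_ij``; pairs farther apart than a threshold
radius may be dropped, sparsifying the system.

Solving for unit fields along x, y, z yields the polarizability vectors
``alpha_k = sum_i mu_i(E_k)``, the 3x3 molecular polarizability tensor
(column k = alpha_k), and the orientation-invariant average polarizability
(mean of the tensor eigenvalues).  All polarizabilities are volumes in A^3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from scipy.sparse.linalg import minres
from scipy.spatial import cKDTree

from .errors import ComputationError, ConvergenceError, ValidationError
from .structures import MIN_SEPARATION, PolarizableSystem

#: Thole smearing constant multiplying (alpha_i alpha_j)^(1/6).
THOLE_SMEAR_FACTOR = 1.662

#: Atom count below which a dense direct solve is faster than Krylov
#: iteration.
DENSE_CROSSOVER = 700

#: Default relative residual tolerance for the iterative solver.
DEFAULT_TOL = 1e-6

#: Without a threshold radius the matrix is dense in blocks; refuse sizes
#: whose all-pair assembly cannot fit in ordinary memory.
_MAX_UNTHRESHOLDED_ATOMS = 20_000

_I3 = np.eye(3)


def damping_length(alpha_i: float, alpha_j: float) -> float:
    """Thole damping length s = 1.662 (alpha_i alpha_j)^(1/6), in A."""
    return THOLE_SMEAR_FACTOR * (alpha_i * alpha_j) ** (1.0 / 6.0)


@dataclass(frozen=True)
class DipoleFieldTensor:
    """One 3x3 dipole-dipole coupling block (A^-3)."""

    matrix: np.ndarray
    separation: float
    damping_length: float

    @property
    def damped(self) -> bool:
        return self.separation < self.damping_length


def _pair_blocks(dr: np.ndarray, r: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Vectorized Thole tensors for pair separation vectors ``dr`` (P, 3).

    Damped branch is used for r <= s (the two branches are continuous at
    r = s, so the tie-break is arbitrary).
    """
    damped = r <= s
    v = np.where(damped, r / s, 1.0)
    v3 = v ** 3
    iso = np.where(damped, 4.0 * v3 - 3.0 * v3 * v, 1.0) / r ** 3
    aniso = np.where(damped, 3.0 * v3 * v, 3.0) / r ** 5
    return (iso[:, None, None] * _I3
            - aniso[:, None, None] * dr[:, :, None] * dr[:, None, :])


def thole_tensor(pos_i, pos_j, alpha_i: float, alpha_j: float
                 ) -> DipoleFieldTensor:
    """Dipole field tensor between two polarizable atoms.

    Beyond the damping length this is the bare point-dipole tensor
    ``I/r^3 - 3 (dr dr^T)/r^5``; inside it the isotropic part is scaled by
    ``4v^3 - 3v^4`` and the anisotropic part by ``v^4`` (v = r/s), smearing
    the interaction so mutual polarization stays finite.
    """
    dr = np.asarray(pos_i, dtype=float) - np.asarray(pos_j, dtype=float)
    r = float(np.linalg.norm(dr))
    if r < MIN_SEPARATION:
        raise ValidationError(
            f"atoms coincide (dr = {r:.4f} A): polarization catastrophe risk")
    if not (alpha_i > 0 and alpha_j > 0):
        raise ValidationError("polarizabilities must be positive")
    s = damping_length(alpha_i, alpha_j)
    block = _pair_blocks(dr[None, :], np.array([r]), np.array([s]))[0]
    return DipoleFieldTensor(matrix=block, separation=r, damping_length=s)


@dataclass
class InteractionSystem:
    """Assembled symmetric sparse 3N x 3N relay system."""

    matrix: sp.bsr_matrix
    alpha: np.ndarray
    threshold_radius: float | None
    n_pairs: int

    @property
    def n_atoms(self) -> int:
        return len(self.alpha)

    @property
    def nnz(self) -> int:
        """Stored scalar elements (9 per retained 3x3 block)."""
        return self.matrix.nnz


def assemble_system(system: PolarizableSystem) -> InteractionSystem:
    """Build the sparse block system for a polarizable structure.

    Off-diagonal Thole blocks are kept only for pairs with separation at or
    below the system's threshold radius (all pairs when the threshold is
    ``None``).  Neighbour pairs come from a k-d tree, so assembly cost scales
    with the retained pairs, not with N^2.
    """
    structure = system.structure
    n = structure.n_atoms
    pos = structure.positions
    alpha = system.alpha
    structure.check_separations()

    threshold = system.threshold_radius
    if threshold is None:
        if n > _MAX_UNTHRESHOLDED_ATOMS:
            raise ValidationError(
                f"N = {n} is too large for an unthresholded (all-pair) "
                "system; set a threshold radius")
        iu, ju = np.triu_indices(n, k=1)
        pairs = np.column_stack([iu, ju]).astype(np.int64)
    else:
        pairs = cKDTree(pos).query_pairs(threshold, output_type="ndarray")

    n_pairs = len(pairs)
    diag = (1.0 / alpha)[:, None, None] * _I3

    if n_pairs == 0:
        data = diag
        rows = np.arange(n, dtype=np.int64)
        cols = rows
    else:
        i, j = pairs[:, 0], pairs[:, 1]
        dr = pos[i] - pos[j]
        r = np.linalg.norm(dr, axis=1)
        s = THOLE_SMEAR_FACTOR * (alpha[i] * alpha[j]) ** (1.0 / 6.0)
        blocks = _pair_blocks(dr, r, s)
        data = np.empty((2 * n_pairs + n, 3, 3))
        data[:n_pairs] = blocks
        data[n_pairs:2 * n_pairs] = blocks  # T_ji = T_ij for this tensor
        data[2 * n_pairs:] = diag
        del blocks
        rows = np.concatenate([i, j, np.arange(n, dtype=np.int64)])
        cols = np.concatenate([j, i, np.arange(n, dtype=np.int64)])

    order = np.lexsort((cols, rows))
    indices = cols[order].astype(np.int32)
    data = data[order]
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(np.bincount(rows, minlength=n), out=indptr[1:])
    matrix = sp.bsr_matrix((data, indices, indptr), shape=(3 * n, 3 * n),
                           blocksize=(3, 3))
    return InteractionSystem(matrix=matrix, alpha=alpha,
                             threshold_radius=threshold, n_pairs=n_pairs)


@dataclass
class DipoleSolution:
    """Induced dipoles (A^3 x field unit) for one applied field."""

    mu: np.ndarray            # (N, 3)
    applied_field: np.ndarray  # (N, 3)
    solver: str
    iterations: int
    residual: float

    @property
    def total_dipole(self) -> np.ndarray:
        return self.mu.sum(axis=0)


def _expand_field(field_in, n: int) -> np.ndarray:
    field_arr = np.asarray(field_in, dtype=float)
    if field_arr.shape == (3,):
        field_arr = np.tile(field_arr, (n, 1))
    if field_arr.shape != (n, 3):
        raise ValidationError(
            f"field must be a 3-vector or (N, 3) array, got {field_arr.shape}")
    if not np.all(np.isfinite(field_arr)):
        raise ValidationError("field must be finite")
    return field_arr


def _pick_solver(solver: str, n: int) -> str:
    if solver == "auto":
        return "dense" if n < DENSE_CROSSOVER else "minres"
    if solver not in ("dense", "minres"):
        raise ValidationError(f"unknown solver {solver!r}")
    return solver


def _solve_columns(interaction: InteractionSystem, rhs: np.ndarray,
                   solver: str, tol: float, maxiter: int | None,
                   precondition: bool):
    """Solve A x = rhs for one or more right-hand-side columns.

    Returns (X, iterations, max relative residual).  The dense path
    factorizes once and reuses the factorization across columns; the
    iterative path runs symmetric MINRES per column.
    """
    A = interaction.matrix
    rhs2d = rhs if rhs.ndim == 2 else rhs[:, None]
    if solver == "dense":
        try:
            lu, piv = scipy.linalg.lu_factor(A.toarray())
            X = scipy.linalg.lu_solve((lu, piv), rhs2d)
        except scipy.linalg.LinAlgError as exc:
            raise ComputationError(f"singular dense system: {exc}") from exc
        if not np.all(np.isfinite(X)):
            raise ComputationError("dense solve produced non-finite dipoles")
        iterations = 0
    else:
        M = None
        if precondition:
            # Block-Jacobi: inverse of the diagonal blocks is alpha_i * I.
            M = sp.diags(np.repeat(interaction.alpha, 3))
        X = np.empty_like(rhs2d)
        iterations = 0
        for col in range(rhs2d.shape[1]):
            b = rhs2d[:, col]
            bnorm = np.linalg.norm(b)
            count = [0]

            def _cb(_xk):
                count[0] += 1

            # The contract is a residual relative to ||b|| (MATLAB-style);
            # scipy's MINRES stops on a ||A||*||x||-scaled estimate, so
            # restart with a tighter rtol until the contract is met.
            x = None
            rtol = tol
            res = np.inf
            for _ in range(5):
                x, info = minres(A, b, x0=x, rtol=rtol, maxiter=maxiter,
                                 M=M, callback=_cb)
                res = float(np.linalg.norm(A @ x - b) / bnorm)
                if res <= tol:
                    break
                if info > 0:  # hit maxiter without converging
                    break
                rtol *= 1e-2
            if res > tol:
                raise ConvergenceError(
                    f"MINRES failed to reach relative residual {tol:.1e} "
                    f"(got {res:.3e})", residual=res, iterations=count[0])
            X[:, col] = x
            iterations = max(iterations, count[0])
    resid = np.linalg.norm(A @ X - rhs2d, axis=0) / np.linalg.norm(rhs2d, axis=0)
    residual = float(resid.max())
    return (X if rhs.ndim == 2 else X[:, 0]), iterations, residual


def solve_dipoles(interaction: InteractionSystem, field,
                  solver: str = "auto", tol: float = DEFAULT_TOL,
                  maxiter: int | None = None,
                  precondition: bool = False) -> DipoleSolution:
    """Solve ``A mu = E`` for the induced dipole of every atom.

    ``field`` is either a single 3-vector (uniform illumination, replicated
    at every atom) or an (N, 3) per-atom field, supporting non-uniform
    illumination such as plasmonic hot spots.
    """
    n = interaction.n_atoms
    field_arr = _expand_field(field, n)
    chosen = _pick_solver(solver, n)
    x, iterations, residual = _solve_columns(
        interaction, field_arr.ravel(), chosen, tol, maxiter, precondition)
    return DipoleSolution(mu=x.reshape(n, 3), applied_field=field_arr,
                          solver=chosen, iterations=iterations,
                          residual=residual)


@dataclass
class PolarizabilityResult:
    """Molecular polarizability from three orthogonal unit-field solves."""

    alpha_vectors: np.ndarray      # (3, 3); column k = alpha_k for field k
    alpha_tensor: np.ndarray       # (3, 3) symmetrized
    eigenvalues: np.ndarray        # ascending, A^3
    alpha_avg: float               # mean eigenvalue, A^3
    vector_magnitudes: np.ndarray  # ||alpha_k|| for k = x, y, z, A^3
    n_atoms: int
    nnz: int
    threshold_radius: float | None
    solver: str
    iterations: int
    residual: float
    asymmetry: float = 0.0

    def to_dict(self) -> dict:
        """JSON-ready summary with deterministic key order and units in keys."""
        return {
            "n_atoms": self.n_atoms,
            "alpha_avg_A3": self.alpha_avg,
            "eigenvalues_A3": [float(v) for v in self.eigenvalues],
            "alpha_tensor_A3_row_major": [float(v) for v in
                                          self.alpha_tensor.ravel()],
            "alpha_vector_magnitudes_A3": {
                k: float(self.vector_magnitudes[i])
                for i, k in enumerate("xyz")},
            "threshold_radius_A": self.threshold_radius,
            "solver": self.solver,
            "nnz": self.nnz,
            "iterations": self.iterations,
            "residual": self.residual,
        }


def compute_polarizability(system: PolarizableSystem | InteractionSystem,
                           solver: str = "auto", tol: float = DEFAULT_TOL,
                           maxiter: int | None = None,
                           precondition: bool = False) -> PolarizabilityResult:
    """Polarizability tensor, vectors and eigenvalue average of a molecule.

    Solves the relay system for unit uniform fields along x, y and z.  The
    polarizability vector for direction k is the summed induced dipole per
    unit field; the three vectors are the columns of the tensor, which is
    symmetrized before eigen-decomposition (floating-point asymmetry above
    1e-4 relative triggers a warning, usually a sign of an unconverged
    solve).
    """
    if isinstance(system, PolarizableSystem):
        interaction = assemble_system(system)
    else:
        interaction = system
    n = interaction.n_atoms
    chosen = _pick_solver(solver, n)

    rhs = np.zeros((3 * n, 3))
    for k in range(3):
        rhs[k::3, k] = 1.0
    X, iterations, residual = _solve_columns(
        interaction, rhs, chosen, tol, maxiter, precondition)

    tensor_raw = np.empty((3, 3))
    for k in range(3):
        tensor_raw[:, k] = X[:, k].reshape(n, 3).sum(axis=0)

    scale = float(np.abs(tensor_raw).max()) or 1.0
    asymmetry = float(np.abs(tensor_raw - tensor_raw.T).max()) / scale
    if asymmetry > 1e-4:
        warnings.warn(
            f"polarizability tensor asymmetry {asymmetry:.2e} exceeds 1e-4; "
            "the solve may be unconverged", RuntimeWarning, stacklevel=2)
    tensor = 0.5 * (tensor_raw + tensor_raw.T)
    eigenvalues = scipy.linalg.eigh(tensor, eigvals_only=True)
    return PolarizabilityResult(
        alpha_vectors=tensor_raw,
        alpha_tensor=tensor,
        eigenvalues=eigenvalues,
        alpha_avg=float(eigenvalues.mean()),
        vector_magnitudes=np.linalg.norm(tensor_raw, axis=0),
        n_atoms=n,
        nnz=interaction.nnz,
        threshold_radius=interaction.threshold_radius,
        solver=chosen,
        iterations=iterations,
        residual=residual,
        asymmetry=asymmetry,
    )


@dataclass
class ThresholdScanPoint:
    threshold_radius: float
    alpha_avg: float
    ratio: float


@dataclass
class ThresholdScan:
    points: list[ThresholdScanPoint]
    reference_alpha_avg: float
    reference: str  # 'unthresholded' or 'largest_radius'

    def to_dict(self) -> dict:
        return {
            "reference": self.reference,
            "reference_alpha_avg_A3": self.reference_alpha_avg,
            "points": [
                {"threshold_radius_A": p.threshold_radius,
                 "alpha_avg_A3": p.alpha_avg, "ratio": p.ratio}
                for p in self.points],
        }


def threshold_convergence_scan(system: PolarizableSystem,
                               radii, solver: str = "auto",
                               tol: float = DEFAULT_TOL) -> ThresholdScan:
    """Average polarizability as a function of the threshold radius.

    The reference is the exact (unthresholded) value when the system is
    small enough for an all-pair assembly (N <= 5000); otherwise the largest
    requested radius serves as the reference.
    """
    radii = [float(r) for r in radii]
    if not radii or any(r <= 0 for r in radii):
        raise ValidationError("radii must be positive")
    if sorted(radii) != radii:
        raise ValidationError("radii must be ascending")

    if system.n_atoms <= 5000:
        ref_sys = PolarizableSystem(system.structure, system.alpha, None)
        ref_alpha = compute_polarizability(ref_sys, solver=solver, tol=tol
                                           ).alpha_avg
        reference = "unthresholded"
        ref_radius = None
    else:
        reference = "largest_radius"
        ref_radius = radii[-1]
        ref_alpha = None

    points = []
    for r in radii:
        sub = PolarizableSystem(system.structure, system.alpha, r)
        avg = compute_polarizability(sub, solver=solver, tol=tol).alpha_avg
        points.append([r, avg])
        if ref_radius is not None and r == ref_radius:
            ref_alpha = avg

    return ThresholdScan(
        points=[ThresholdScanPoint(r, a, a / ref_alpha) for r, a in points],
        reference_alpha_avg=ref_alpha,
        reference=reference,
    )
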