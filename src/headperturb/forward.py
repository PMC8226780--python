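"""EEG forward problem on the voxelized conductivity volume.

``compute_fdm_leadfield`` discretizes the quasi-static potential equation
∇·(σ∇φ) = 0 with a 7-point finite-difference stencil (harmonic-mean face
conductivities, correct for piecewise-constant isotropic σ) and assembles
the leadfield by reciprocity: one current-injection solve per electrode
against a reference electrode, with gain rows read off the potential
gradient at the source nodes.

``analytic_sphere_leadfield`` is the classical concentric-spheres
Legendre-series solution and serves as the independent validation oracle.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import sparse
from scipy.ndimage import map_coordinates
from scipy.sparse.linalg import cg, splu

from .types import ConductivityVolume, ElectrodeMontage, Leadfield, SourceGrid

__all__ = [
    "compute_fdm_leadfield",
    "analytic_sphere_leadfield",
    "rdm_and_magnitude_error",
]

#: µV per nA·m, given potentials in V per A·m
_UNIT_SCALE = 1e-3


def _laplacian(sigma: np.ndarray, h_m: float):
    """Sparse FD Laplacian over head voxels (σ>0) with harmonic-mean face
    conductances g = σ_face · h. Returns (A, index_volume, head_indices)."""
    head = sigma > 0
    n = int(head.sum())
    index = -np.ones(sigma.shape, dtype=np.int64)
    index[head] = np.arange(n)

    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        sa = sigma[tuple(sl_a)]
        sb = sigma[tuple(sl_b)]
        with np.errstate(divide="ignore", invalid="ignore"):
            g = 2.0 * sa * sb / (sa + sb)
        g = np.nan_to_num(g) * h_m                      # S
        ia = index[tuple(sl_a)]
        ib = index[tuple(sl_b)]
        ok = (ia >= 0) & (ib >= 0) & (g > 0)
        ga = g[ok]
        ra, rb = ia[ok], ib[ok]
        rows.extend([ra, rb])
        cols.extend([rb, ra])
        vals.extend([-ga, -ga])
        np.add.at(diag, ra, ga)
        np.add.at(diag, rb, ga)
    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    A = sparse.csc_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return A, index, head


def _electrode_voxels(montage: ElectrodeMontage, vol: ConductivityVolume,
                      index: np.ndarray) -> np.ndarray:
    """Nearest head voxel (as unknown index) for each electrode."""
    from .types import TissueLabelVolume  # for coordinate helpers only

    helper = TissueLabelVolume((vol.sigma > 0).astype(np.int16), vol.voxel_size,
                               vol.affine, {1: "head"})
    vox = np.rint(helper.world_to_voxel(montage.positions)).astype(int)
    shape = vol.sigma.shape
    out = np.empty(len(vox), dtype=np.int64)
    for k, v in enumerate(vox):
        found = -1
        for radius in range(0, 4):
            lo = np.maximum(v - radius, 0)
            hi = np.minimum(v + radius + 1, shape)
            sub = index[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            cand = np.argwhere(sub >= 0)
            if len(cand):
                cand_abs = cand + lo
                d = np.linalg.norm(cand_abs - v, axis=1)
                best = cand_abs[np.argmin(d)]
                found = index[best[0], best[1], best[2]]
                break
        if found < 0:
            raise ValueError(f"electrode {montage.names[k]} is not near any head voxel")
        out[k] = found
    return out


def compute_fdm_leadfield(
    conductivity_volume: ConductivityVolume,
    montage: ElectrodeMontage,
    grid: SourceGrid,
    solver_tol: float = 1e-8,
    max_iter: int = 3000,
    solver: str = "cg",
    reference_channel: int = 0,
) -> Leadfield:
    """Finite-difference leadfield by reciprocity.

    For each electrode a unit current is injected against the reference
    electrode and ∇·(σ∇φ) = 0 is solved on the head voxels (the reference
    electrode's voxel is grounded to fix the singular system). Gain rows are
    the (negated) potential gradients interpolated at the grid nodes,
    converted to µV per nA·m; the returned ``gain`` is average-referenced
    and ``gain_unref`` keeps the reference-electrode convention.

    ``solver`` is "cg" (Jacobi-preconditioned conjugate gradients at
    relative tolerance ``solver_tol``; default) or "direct" (sparse LU,
    one factorization reused across all electrodes).
    """
    vol = conductivity_volume
    h_m = vol.voxel_size * 1e-3
    A, index, head = _laplacian(vol.sigma, h_m)
    # degraded segmentations can leave isolated conducting islands; restrict
    # the solve to the main connected component (no current reaches islands)
    from scipy.sparse.csgraph import connected_components
    n_comp, comp = connected_components(A, directed=False)
    if n_comp > 1:
        main = np.bincount(comp).argmax()
        sigma2 = vol.sigma.copy()
        drop = np.zeros_like(sigma2, dtype=bool)
        drop[head] = comp != main
        sigma2[drop] = 0.0
        A, index, head = _laplacian(sigma2, h_m)
    n = A.shape[0]
    elec_idx = _electrode_voxels(montage, vol, index)
    ref = int(elec_idx[reference_channel])

    # ground the reference voxel: drop its row/column
    keep = np.ones(n, dtype=bool)
    keep[ref] = False
    Ar = A[keep][:, keep].tocsc()
    remap = -np.ones(n, dtype=np.int64)
    remap[keep] = np.arange(n - 1)

    lu = None
    if solver == "direct":
        lu = splu(Ar, permc_spec="MMD_AT_PLUS_A")
    elif solver != "cg":
        raise ValueError("solver must be 'direct' or 'cg'")
    inv_diag = 1.0 / Ar.diagonal()
    precond = sparse.linalg.LinearOperator(
        Ar.shape, matvec=lambda x: inv_diag * x)

    # fractional voxel coordinates of grid nodes for gradient interpolation
    inv_aff = np.linalg.inv(vol.affine)
    node_vox = (np.c_[grid.positions, np.ones(len(grid.positions))] @ inv_aff.T)[:, :3]

    n_ch = montage.n_channels
    gain = np.zeros((n_ch, 3 * grid.n_nodes))
    phi_vol = np.zeros(vol.sigma.shape)
    for c in range(n_ch):
        if c == reference_channel:
            continue
        b = np.zeros(n)
        b[int(elec_idx[c])] += 1.0
        b[ref] -= 1.0
        br = b[keep]
        if lu is not None:
            x = lu.solve(br)
        else:
            x, info = cg(Ar, br, rtol=solver_tol, maxiter=max_iter, M=precond)
            if info != 0:
                resid = np.linalg.norm(Ar @ x - br) / np.linalg.norm(br)
                raise RuntimeError(
                    f"CG failed for electrode {montage.names[c]} "
                    f"(info={info}, relative residual {resid:.2e})")
        phi = np.zeros(n)
        phi[keep] = x
        phi_vol[:] = 0.0
        phi_vol[head] = phi
        grads = np.gradient(phi_vol, h_m)
        for axis in range(3):
            comp = map_coordinates(grads[axis], node_vox.T, order=1, mode="nearest")
            gain[c, axis::3] = comp * _UNIT_SCALE

    gain_avg = gain - gain.mean(axis=0, keepdims=True)
    return Leadfield(
        gain=gain_avg,
        channel_names=list(montage.names),
        node_positions=grid.positions.copy(),
        reference="average",
        gain_unref=gain,
    )


def _shell_transfer_factor(n: int, radii_scaled: np.ndarray,
                           sigmas: np.ndarray) -> float:
    """Surface-potential factor for harmonic order n.

    Solves the per-order radial coefficient system for shells listed
    innermost to outermost (radii scaled by the outer radius), with the
    primary-source coefficient in the innermost shell set to 1. Returns
    a_N + b_N evaluated at the outer surface.
    """
    N = len(radii_scaled)
    if N == 1:
        return (2 * n + 1) / n
    # unknowns: a_1, (a_j, b_j) for j=2..N  -> 2N-1
    m = 2 * N - 1
    A = np.zeros((m, m))
    rhs = np.zeros(m)

    def a_col(j):  # 1-based shell
        return 0 if j == 1 else 2 * j - 3

    def b_col(j):
        return 2 * j - 2  # j >= 2

    row = 0
    for j in range(1, N):               # interface between shell j and j+1
        x = radii_scaled[j - 1]
        xn = x**n
        xm = x ** (-(n + 1))
        # potential continuity
        A[row, a_col(j)] += xn
        if j == 1:
            rhs[row] -= xm              # b_1 = 1 (primary)
        else:
            A[row, b_col(j)] += xm
        A[row, a_col(j + 1)] -= xn
        A[row, b_col(j + 1)] -= xm
        row += 1
        # radial current continuity: sigma * dphi/dx
        dxn = n * x ** (n - 1)
        dxm = -(n + 1) * x ** (-(n + 2))
        A[row, a_col(j)] += sigmas[j - 1] * dxn
        if j == 1:
            rhs[row] -= sigmas[0] * dxm
        else:
            A[row, b_col(j)] += sigmas[j - 1] * dxm
        A[row, a_col(j + 1)] -= sigmas[j] * dxn
        A[row, b_col(j + 1)] -= sigmas[j] * dxm
        row += 1
    # insulating outer boundary at x = 1
    A[row, a_col(N)] = n
    A[row, b_col(N)] = -(n + 1)
    sol = np.linalg.solve(A, rhs)
    return float(sol[a_col(N)] + sol[b_col(N)])


def analytic_sphere_leadfield(
    shell_radii: np.ndarray,
    shell_sigmas: np.ndarray,
    montage: ElectrodeMontage,
    grid: SourceGrid,
    term_tol: float = 1e-8,
    n_max: int = 2000,
    boundary_margin: float = 0.02,
) -> Leadfield:
    """Concentric-spheres Legendre-series leadfield (validation oracle).

    ``shell_radii``/``shell_sigmas`` are listed innermost to outermost
    (at most 4 shells). Electrodes are radially projected onto the outer
    sphere; every node must lie strictly inside the innermost shell with a
    2% radial margin (series convergence guard). The series is truncated
    adaptively once the term ratio drops below ``term_tol``.
    """
    radii = np.asarray(shell_radii, dtype=float)
    sigmas = np.asarray(shell_sigmas, dtype=float)
    if len(radii) != len(sigmas) or not 1 <= len(radii) <= 4:
        raise ValueError("need 1-4 shells with matching conductivities")
    if np.any(np.diff(radii) <= 0):
        raise ValueError("shell radii must increase innermost to outermost")
    R = radii[-1]
    x_scaled = radii / R

    # electrodes on the outer sphere
    e_dirs = montage.positions - montage.head_center
    e_norms = np.linalg.norm(e_dirs, axis=1, keepdims=True)
    if np.any(e_norms < 1e-9):
        raise ValueError("electrode at head center")
    e_dirs = e_dirs / e_norms

    b_vec = grid.positions - montage.head_center
    b = np.linalg.norm(b_vec, axis=1)
    if np.any(b > (1.0 - boundary_margin) * radii[0]):
        worst = b.max()
        raise ValueError(
            f"node at radius {worst:.1f} mm too close to the innermost shell "
            f"boundary ({radii[0]:.1f} mm, margin {boundary_margin:.0%})")

    R_m = R * 1e-3
    C0 = 1.0 / (4.0 * math.pi * sigmas[0] * R_m**2)
    n_ch = montage.n_channels
    gain = np.zeros((n_ch, 3 * grid.n_nodes))

    factors: list[float] = []

    def factor(n: int) -> float:
        while len(factors) < n:
            factors.append(_shell_transfer_factor(len(factors) + 1, x_scaled, sigmas))
        return factors[n - 1]

    for k in range(grid.n_nodes):
        beta = b[k] / R
        if b[k] < 1e-9:
            rd = np.array([0.0, 0.0, 1.0])
        else:
            rd = b_vec[k] / b[k]
        u = e_dirs @ rd                                  # (n_ch,)
        # Legendre recurrences for P_n(u) and P_n'(u)
        P_prev = np.ones_like(u)                         # P_0
        P_cur = u.copy()                                 # P_1
        dP_prev = np.zeros_like(u)                       # P_0'
        dP_cur = np.ones_like(u)                         # P_1'
        acc = np.zeros((n_ch, 3))
        peak = 0.0
        n = 1
        beta_pow = 1.0                                   # beta^(n-1)
        while n <= n_max:
            f = factor(n)
            # angular factor per unit dipole along each axis:
            #   n * p_r * P_n + P_n'(u) * (ê_axis · r̂_e  -  u * p_r)
            term = np.empty((n_ch, 3))
            for axis in range(3):
                p_r = rd[axis]
                term[:, axis] = n * p_r * P_cur + dP_cur * (e_dirs[:, axis] - u * p_r)
            term *= f * beta_pow
            acc += term
            t_mag = np.abs(term).max()
            peak = max(peak, t_mag)
            if n >= 10 and t_mag < term_tol * max(peak, 1e-300):
                break
            # advance recurrences
            P_next = ((2 * n + 1) * u * P_cur - n * P_prev) / (n + 1)
            dP_next = dP_prev + (2 * n + 1) * P_cur
            P_prev, P_cur = P_cur, P_next
            dP_prev, dP_cur = dP_cur, dP_next
            beta_pow *= beta
            n += 1
        gain[:, 3 * k:3 * k + 3] = C0 * acc * _UNIT_SCALE

    gain_avg = gain - gain.mean(axis=0, keepdims=True)
    return Leadfield(
        gain=gain_avg,
        channel_names=list(montage.names),
        node_positions=grid.positions.copy(),
        reference="average",
        gain_unref=gain,
    )


def rdm_and_magnitude_error(lf_a: Leadfield, lf_b: Leadfield):
    """Topography and magnitude error per dipole column.

    RDM = ‖a/‖a‖ − b/‖b‖‖ (0 = identical topography, √2 = orthogonal,
    2 = sign-flipped); lnMAG = ln(‖a‖/‖b‖). Returned with shape
    (n_nodes, 3): one value per node and dipole orientation.
    """
    if lf_a.gain.shape != lf_b.gain.shape:
        raise ValueError("leadfields must share montage and grid")
    a = lf_a.gain
    bm = lf_b.gain
    na = np.linalg.norm(a, axis=0)
    nb = np.linalg.norm(bm, axis=0)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("zero-norm leadfield column")
    rdm = np.linalg.norm(a / na - bm / nb, axis=0)
    lnmag = np.log(na / nb)
    n_nodes = lf_a.n_nodes
    return rdm.reshape(n_nodes, 3), lnmag.reshape(n_nodes, 3)
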