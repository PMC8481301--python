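"""Complete-electrode-model FEM forward solver and Jacobian for 2-D EIT.

Solves the conductivity equation div(sigma grad u) = 0 on a triangulated
thorax cross-section with the complete electrode model (CEM): each
electrode is a boundary patch with contact impedance z, carrying a
prescribed net current, with current shunting along the electrode surface.
Linear (P1) elements, piecewise-constant conductivity.

The stimulation protocol is adjacent drive / adjacent measurement: 16
adjacent electrode pairs inject current in turn and, for each injection,
voltages are read from the 13 adjacent pairs that share no electrode with
the drive pair — 208 measurements per frame.

The measurement Jacobian is computed with the adjoint (lead-field) method:
dV_m/dsigma_e = -integral_e grad(u_drive) . grad(u_meas), where u_meas is
the potential produced by driving unit current through the measurement
pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import Mesh2D, N_ELECTRODES, _cross2


class ForwardSolveError(RuntimeError):
    """Raised when the CEM system cannot be solved (degenerate mesh/input)."""


@dataclass(frozen=True)
class StimulationProtocol:
    """Adjacent drive, adjacent measurement stimulation pattern.

    ``drive_pairs[d] = (d, d+1 mod 16)``; for each drive the measurement
    pairs are the adjacent pairs ``(m, m+1 mod 16)`` whose electrodes are
    both outside the drive pair (13 of the 16), in increasing order of
    ``m``.  Measured voltage is ``U[m] - U[m+1]``.
    """

    current_amplitude: float = 5e-3  # A
    frequency: float = 1e5          # Hz, metadata only (real-valued model)
    n_electrodes: int = N_ELECTRODES

    @property
    def drive_pairs(self) -> list:
        n = self.n_electrodes
        return [(d, (d + 1) % n) for d in range(n)]

    @property
    def measure_pairs(self) -> list:
        """For each drive, the list of 13 measurement pairs."""
        n = self.n_electrodes
        out = []
        for a, b in self.drive_pairs:
            pairs = [
                (m, (m + 1) % n)
                for m in range(n)
                if m not in (a, b) and (m + 1) % n not in (a, b)
            ]
            out.append(pairs)
        return out

    @property
    def n_measurements(self) -> int:
        return sum(len(p) for p in self.measure_pairs)  # 16 * 13 = 208


@dataclass(frozen=True)
class ElectrodeModel:
    """Electrode boundary condition parameters.

    ``contact_impedance`` is the CEM contact impedance per electrode in the
    unit-depth 2-D model (ohm * m), uniform across electrodes.  The default
    1e-4 models well-gelled, strongly coupled electrodes: it sits in the
    near-shunt regime where the forward map is Ohmic (uniform conductivity
    scaling inverts voltages) to ~0.2%, while still regularising the
    current-density singularity at electrode edges.
    """

    contact_impedance: float = 1e-4

    def __post_init__(self):
        if self.contact_impedance <= 0:
            raise ValueError("contact impedance must be positive")


@dataclass
class JacobianMatrix:
    """Sensitivity of the 208 measurements to per-element conductivity.

    ``entries[m, e]`` approximates dV_m/dsigma_e at the baseline
    conductivity ``sigma0``.
    """

    entries: np.ndarray
    sigma0: np.ndarray
    baseline_frame: np.ndarray


class CEMForwardSolver:
    """Assembles and solves the CEM system for one mesh and protocol.

    Geometry-dependent quantities (P1 stiffness triplets, electrode
    boundary matrices) are precomputed once so that repeated solves with
    different conductivity fields — one per simulated frame — only rebuild
    the sparse matrix data vector and refactorise.
    """

    def __init__(
        self,
        mesh: Mesh2D,
        protocol: StimulationProtocol | None = None,
        electrodes: ElectrodeModel | None = None,
    ):
        self.mesh = mesh
        self.protocol = protocol or StimulationProtocol()
        self.electrodes = electrodes or ElectrodeModel()
        self.n_el = self.protocol.n_electrodes
        if mesh.n_electrodes != self.n_el:
            raise ValueError("mesh electrode count does not match protocol")
        self._precompute()

    # -- assembly ---------------------------------------------------------

    def _precompute(self) -> None:
        mesh, n = self.mesh, self.mesh.n_nodes
        pts = mesh.nodes
        tri = mesh.elements
        p = pts[tri]                                  # (ne, 3, 2)
        # P1 gradients: grad(phi_i) = rot90(edge opposite i) / (2A)
        e0 = p[:, 2] - p[:, 1]
        e1 = p[:, 0] - p[:, 2]
        e2 = p[:, 1] - p[:, 0]
        areas = 0.5 * _cross2(e2, -e1)
        if np.any(areas <= 0):
            raise ForwardSolveError("mesh has non-positive element areas")
        self.areas = areas
        edges = np.stack([e0, e1, e2], axis=1)        # (ne, 3, 2)
        grads = np.stack([-edges[:, :, 1], edges[:, :, 0]], axis=2)
        grads /= (2 * areas)[:, None, None]
        self.grads = grads                            # (ne, 3, 2) grad phi_i
        # local stiffness at unit sigma: K_ij = A * grad_i . grad_j
        k_local = np.einsum("eid,ejd->eij", grads, grads) * areas[:, None, None]
        ii = np.repeat(tri, 3, axis=1).ravel()        # rows
        jj = np.tile(tri, (1, 3)).ravel()             # cols
        self._k_rows = ii
        self._k_cols = jj
        self._k_vals = k_local.transpose(0, 2, 1).reshape(mesh.n_elements, 9)
        # element id per triplet entry (for sigma scaling)
        self._k_elem = np.repeat(np.arange(mesh.n_elements), 9)

        # electrode boundary integrals
        z = self.electrodes.contact_impedance
        rows_e, cols_e, vals_e = [], [], []
        B = np.zeros((n, self.n_el))
        D = np.zeros(self.n_el)
        for l, edge_ids in enumerate(mesh.electrode_edges):
            for eid in edge_ids:
                a, b = mesh.boundary_edges[eid]
                length = np.linalg.norm(pts[b] - pts[a])
                # int phi_i phi_j ds = L/6 [[2,1],[1,2]]
                m = (length / (6 * z)) * np.array([[2.0, 1.0], [1.0, 2.0]])
                for i, gi in enumerate((a, b)):
                    for j, gj in enumerate((a, b)):
                        rows_e.append(gi)
                        cols_e.append(gj)
                        vals_e.append(m[i, j])
                B[a, l] -= length / (2 * z)
                B[b, l] -= length / (2 * z)
                D[l] += length / z
        self._A_elec = sp.coo_matrix(
            (vals_e, (rows_e, cols_e)), shape=(n, n)
        ).tocsr()
        self._B = sp.csr_matrix(B)
        self._D = D

    def _system(self, sigma: np.ndarray) -> sp.csc_matrix:
        mesh, n = self.mesh, self.mesh.n_nodes
        vals = (self._k_vals * sigma[:, None]).ravel()
        A = sp.coo_matrix((vals, (self._k_rows, self._k_cols)), shape=(n, n))
        A = (A.tocsr() + self._A_elec)
        ne = self.n_el
        ones = np.ones(ne)
        # KKT-style block system with a Lagrange multiplier grounding sum(U)=0
        top = sp.hstack([A, self._B, sp.csr_matrix((n, 1))])
        midl = sp.hstack(
            [self._B.T, sp.diags(self._D), sp.csr_matrix(ones[:, None])]
        )
        bot = sp.hstack(
            [sp.csr_matrix((1, n)), sp.csr_matrix(ones[None, :]),
             sp.csr_matrix((1, 1))]
        )
        return sp.vstack([top, midl, bot]).tocsc()

    def _check_sigma(self, sigma: np.ndarray) -> np.ndarray:
        sigma = np.asarray(sigma, dtype=float)
        if sigma.shape != (self.mesh.n_elements,):
            raise ValueError(
                f"sigma must have length {self.mesh.n_elements}, "
                f"got shape {sigma.shape}"
            )
        if np.any(sigma <= 0) or not np.all(np.isfinite(sigma)):
            raise ValueError("conductivity must be finite and strictly positive")
        return sigma

    def _factorise(self, sigma: np.ndarray):
        try:
            return spla.splu(self._system(sigma))
        except RuntimeError as exc:  # pragma: no cover - degenerate input
            raise ForwardSolveError(f"CEM system factorisation failed: {exc}")

    def solve_fields(self, sigma: np.ndarray, currents: np.ndarray):
        """Solve the CEM system for a matrix of electrode current patterns.

        Parameters
        ----------
        sigma : (n_elements,) array
        currents : (n_electrodes, n_patterns) array of net electrode currents.

        Returns
        -------
        u : (n_nodes, n_patterns) node potentials
        U : (n_electrodes, n_patterns) electrode voltages (sum U = 0)
        """
        sigma = self._check_sigma(sigma)
        lu = self._factorise(sigma)
        n = self.mesh.n_nodes
        rhs = np.zeros((n + self.n_el + 1, currents.shape[1]))
        rhs[n:n + self.n_el] = currents
        sol = lu.solve(rhs)
        return sol[:n], sol[n:n + self.n_el]

    def _drive_currents(self) -> np.ndarray:
        amp = self.protocol.current_amplitude
        c = np.zeros((self.n_el, self.n_el))
        for d, (a, b) in enumerate(self.protocol.drive_pairs):
            c[a, d] = amp
            c[b, d] = -amp
        return c

    def measurements_from_U(self, U: np.ndarray) -> np.ndarray:
        """Extract the 208-vector of pair voltages from per-drive electrode
        voltages ``U`` of shape (n_electrodes, n_drives)."""
        out = []
        for d, pairs in enumerate(self.protocol.measure_pairs):
            for m, mn in pairs:
                out.append(U[m, d] - U[mn, d])
        return np.array(out)

    def solve(self, sigma: np.ndarray) -> np.ndarray:
        """Forward-solve one frame: 208 boundary voltages (V)."""
        _, U = self.solve_fields(sigma, self._drive_currents())
        return self.measurements_from_U(U)

    def jacobian(self, sigma0: np.ndarray) -> JacobianMatrix:
        """Adjoint-method measurement Jacobian at baseline ``sigma0``."""
        sigma0 = self._check_sigma(sigma0)
        lu = self._factorise(sigma0)
        n = self.mesh.n_nodes
        # drive fields at the protocol amplitude
        drives = self._drive_currents()
        # lead fields: unit current through each adjacent pair (m, m+1)
        leads = np.zeros((self.n_el, self.n_el))
        for m in range(self.n_el):
            leads[m, m] = 1.0
            leads[(m + 1) % self.n_el, m] = -1.0
        rhs = np.zeros((n + self.n_el + 1, 2 * self.n_el))
        rhs[n:n + self.n_el, : self.n_el] = drives
        rhs[n:n + self.n_el, self.n_el:] = leads
        sol = lu.solve(rhs)
        u_d = sol[:n, : self.n_el]
        u_m = sol[:n, self.n_el:]
        U_d = sol[n:n + self.n_el, : self.n_el]

        tri = self.mesh.elements
        # per-element gradients of each field: (ne, 2, n_patterns)
        gd = np.einsum("eid,eip->edp", self.grads, u_d[tri])
        gm = np.einsum("eid,eip->edp", self.grads, u_m[tri])
        nm = self.protocol.n_measurements
        J = np.empty((nm, self.mesh.n_elements))
        row = 0
        for d, pairs in enumerate(self.protocol.measure_pairs):
            for m, _mn in pairs:
                J[row] = -self.areas * np.einsum(
                    "ed,ed->e", gd[:, :, d], gm[:, :, m]
                )
                row += 1
        frame = self.measurements_from_U(U_d)
        return JacobianMatrix(entries=J, sigma0=sigma0.copy(), baseline_frame=frame)


def solve_forward(
    mesh: Mesh2D,
    sigma: np.ndarray,
    protocol: StimulationProtocol | None = None,
    electrodes: ElectrodeModel | None = None,
) -> np.ndarray:
    """One-shot forward solve; see :class:`CEMForwardSolver` for reuse."""
    return CEMForwardSolver(mesh, protocol, electrodes).solve(sigma)


def compute_jacobian(
    mesh: Mesh2D,
    sigma0: np.ndarray,
    protocol: StimulationProtocol | None = None,
    electrodes: ElectrodeModel | None = None,
) -> JacobianMatrix:
    """One-shot Jacobian computation at baseline ``sigma0``."""
    return CEMForwardSolver(mesh, protocol, electrodes).jacobian(sigma0)


def solve_point_electrodes(
    mesh: Mesh2D,
    sigma: np.ndarray,
    protocol: StimulationProtocol | None = None,
) -> np.ndarray:
    """Point-electrode forward solve (test fallback).

    Currents are injected at the boundary node closest to each electrode
    centre and voltages read as node-potential differences.  This mode
    matches the analytic boundary-voltage series for the homogeneous disk
    and is used to validate the FEM assembly; the CEM solver is the
    production path.
    """
    protocol = protocol or StimulationProtocol()
    n = mesh.n_nodes
    sigma = np.asarray(sigma, dtype=float)
    # electrode centre angles -> nearest boundary node
    node_ids = []
    for k in range(protocol.n_electrodes):
        centre = -np.pi / 2 + 2 * np.pi * k / protocol.n_electrodes
        target = np.array([
            mesh.semi_axes[0] * np.cos(centre),
            mesh.semi_axes[1] * np.sin(centre),
        ])
        b_nodes = np.unique(mesh.boundary_edges.ravel())
        node_ids.append(b_nodes[np.argmin(
            np.linalg.norm(mesh.nodes[b_nodes] - target, axis=1))])
    solver = CEMForwardSolver.__new__(CEMForwardSolver)
    solver.mesh = mesh
    solver.protocol = protocol
    solver.electrodes = ElectrodeModel()
    solver.n_el = protocol.n_electrodes
    solver._precompute()
    vals = (solver._k_vals * sigma[:, None]).ravel()
    A = sp.coo_matrix((vals, (solver._k_rows, solver._k_cols)),
                      shape=(n, n)).tolil()
    # ground node 0 (origin)
    A[0, :] = 0.0
    A[0, 0] = 1.0
    A = A.tocsc()
    amp = protocol.current_amplitude
    rhs = np.zeros((n, protocol.n_electrodes))
    for d, (a, b) in enumerate(protocol.drive_pairs):
        rhs[node_ids[a], d] += amp
        rhs[node_ids[b], d] -= amp
    rhs[0] = 0.0
    u = spla.splu(A).solve(rhs)
    U = u[node_ids]
    return solver.measurements_from_U(U)
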