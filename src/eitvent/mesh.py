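"""Triangulated 2-D thorax domains with a 16-electrode belt.

The forward model works on a unit-bounding-radius cross-section of the
chest, meshed with linear (P1) triangles.  Electrodes are contiguous groups
of boundary edges, equally spaced around the contour.

Orientation convention (single source of truth for the whole package):
the ventral midline is at (0, -1), the dorsal midline at (0, +1), and the
subject's right side at x < 0.  Electrode 1 (index 0) is centred on the
ventral midline and numbering proceeds in order of increasing polar angle,
i.e. ventral -> subject's left -> dorsal -> subject's right.  Reconstructed
images put row 0 at the ventral edge and column 0 on the subject's right
(radiological convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import Delaunay


def _cross2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """z-component of the cross product of stacked 2-D vectors."""
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]

N_ELECTRODES = 16


class MeshError(ValueError):
    """Raised for degenerate or inconsistent mesh input."""


@dataclass
class Mesh2D:
    """Triangle mesh of the thorax cross-section.

    Attributes
    ----------
    nodes : (n_nodes, 2) float array
        Node coordinates, domain normalised to unit bounding radius.
    elements : (n_elements, 3) int array
        Node indices per triangle, counter-clockwise.
    boundary_edges : (n_edges, 2) int array
        Boundary node pairs, ordered counter-clockwise around the contour.
    electrode_edges : list of int arrays
        For each of the 16 electrodes, the indices (into ``boundary_edges``)
        of the edges it covers.  Groups are disjoint.
    shape : str
        ``"circle"`` or ``"ellipse"``.
    semi_axes : (2,) float
        Horizontal and vertical semi-axes of the domain outline.
    """

    nodes: np.ndarray
    elements: np.ndarray
    boundary_edges: np.ndarray
    electrode_edges: list = field(default_factory=list)
    shape: str = "circle"
    semi_axes: tuple = (1.0, 1.0)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def n_electrodes(self) -> int:
        return len(self.electrode_edges)

    def element_areas(self) -> np.ndarray:
        """Signed areas of all triangles (positive for CCW elements)."""
        p = self.nodes[self.elements]
        return 0.5 * _cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def validate(self) -> None:
        """Check the structural invariants; raise :class:`MeshError` if violated."""
        areas = self.element_areas()
        if np.any(areas <= 0):
            raise MeshError(
                f"{int(np.sum(areas <= 0))} elements have non-positive area"
            )
        if self.n_electrodes != N_ELECTRODES:
            raise MeshError(
                f"expected {N_ELECTRODES} electrodes, got {self.n_electrodes}"
            )
        seen: set = set()
        for k, edges in enumerate(self.electrode_edges):
            if len(edges) == 0:
                raise MeshError(f"electrode {k + 1} covers no boundary edges")
            overlap = seen.intersection(edges.tolist())
            if overlap:
                raise MeshError(f"electrode groups overlap on edges {sorted(overlap)}")
            seen.update(edges.tolist())
        # connectivity: every node referenced by at least one element
        used = np.zeros(self.n_nodes, dtype=bool)
        used[self.elements.ravel()] = True
        if not used.all():
            raise MeshError("mesh contains orphan nodes")


def _ring_points(n_rings: int) -> np.ndarray:
    """Concentric-ring point cloud on the unit disk.

    Ring ``i`` (1-based) holds ``16*i`` points at radius ``i / n_rings``;
    a single point sits at the origin.  The angular origin is the ventral
    midline (-pi/2) so that electrode centres land exactly on mesh nodes.
    """
    pts = [np.zeros((1, 2))]
    for i in range(1, n_rings + 1):
        n_i = N_ELECTRODES * i
        theta = -np.pi / 2 + 2 * np.pi * np.arange(n_i) / n_i
        r = i / n_rings
        pts.append(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))
    return np.vstack(pts)


def build_thorax_mesh(
    shape: str = "circle",
    refinement: int = 2,
    aspect: float = 0.8,
    electrode_coverage: float = 0.5,
) -> Mesh2D:
    """Build a structured triangle mesh of a circular or elliptic thorax.

    Parameters
    ----------
    shape : {"circle", "ellipse"}
        Domain outline.  The ellipse has semi-axes ``(1.0, aspect)``.
    refinement : int
        Mesh density; the number of concentric node rings is
        ``4 * refinement`` and the element count is ``256 * refinement**2``
        (refinement 1 -> 256 elements, 3 -> 2304 elements).  A multiple of
        four rings keeps the discrete electrode arcs identical fractions of
        the boundary at every refinement, so refinement studies converge.
    aspect : float
        Vertical-to-horizontal semi-axis ratio for the ellipse.
    electrode_coverage : float
        Fraction of the inter-electrode arc covered by each electrode
        (default 0.5, i.e. electrodes as wide as the gaps between them).

    Returns
    -------
    Mesh2D
        Validated mesh with 16 equally spaced electrodes; electrode 1 at
        the ventral midline.
    """
    if refinement < 1:
        raise ValueError(f"refinement must be >= 1, got {refinement}")
    if shape not in ("circle", "ellipse"):
        raise ValueError(f"shape must be 'circle' or 'ellipse', got {shape!r}")
    if not 0 < electrode_coverage < 1:
        raise ValueError("electrode_coverage must lie in (0, 1)")

    n_rings = 4 * refinement
    pts = _ring_points(n_rings)
    tri = Delaunay(pts)
    elements = tri.simplices.copy()
    # enforce counter-clockwise orientation
    p = pts[elements]
    signed = 0.5 * _cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    flip = signed < 0
    elements[flip] = elements[flip][:, [0, 2, 1]]
    # drop any degenerate slivers Qhull might emit on the co-circular rings
    areas = np.abs(signed)
    keep = areas > 1e-12 * areas.max()
    elements = elements[keep]

    # boundary ring: last 16*n_rings points, already CCW from -pi/2
    n_b = N_ELECTRODES * n_rings
    b_idx = np.arange(pts.shape[0] - n_b, pts.shape[0])
    boundary_edges = np.column_stack([b_idx, np.roll(b_idx, -1)])

    # electrode k covers edges whose midpoint angle lies within
    # coverage/2 of the electrode centre angle
    mid = 0.5 * (pts[boundary_edges[:, 0]] + pts[boundary_edges[:, 1]])
    ang = np.arctan2(mid[:, 1], mid[:, 0])
    spacing = 2 * np.pi / N_ELECTRODES
    half_arc = 0.5 * electrode_coverage * spacing
    electrode_edges = []
    for k in range(N_ELECTRODES):
        centre = -np.pi / 2 + k * spacing
        d = np.angle(np.exp(1j * (ang - centre)))
        electrode_edges.append(np.nonzero(np.abs(d) <= half_arc + 1e-12)[0])

    semi = (1.0, 1.0)
    if shape == "ellipse":
        pts = pts * np.array([1.0, aspect])
        semi = (1.0, aspect)

    mesh = Mesh2D(
        nodes=pts,
        elements=elements,
        boundary_edges=boundary_edges,
        electrode_edges=electrode_edges,
        shape=shape,
        semi_axes=semi,
    )
    mesh.validate()
    return mesh


def write_mesh(mesh: Mesh2D, path: str | Path) -> None:
    """Serialise a mesh to a plain-text node/element file."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# eitvent mesh  shape={mesh.shape} "
                 f"semi_axes={mesh.semi_axes[0]} {mesh.semi_axes[1]}\n")
        fh.write(f"nodes {mesh.n_nodes}\n")
        for x, y in mesh.nodes:
            fh.write(f"{x:.17g} {y:.17g}\n")
        fh.write(f"elements {mesh.n_elements}\n")
        for a, b, c in mesh.elements:
            fh.write(f"{a} {b} {c}\n")
        fh.write(f"boundary_edges {mesh.boundary_edges.shape[0]}\n")
        for a, b in mesh.boundary_edges:
            fh.write(f"{a} {b}\n")
        fh.write(f"electrodes {mesh.n_electrodes}\n")
        for edges in mesh.electrode_edges:
            fh.write(" ".join(str(int(e)) for e in edges) + "\n")


def read_mesh(path: str | Path) -> Mesh2D:
    """Read a mesh written by :func:`write_mesh`."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        shape, semi = "circle", (1.0, 1.0)
        for tok in header.split():
            if tok.startswith("shape="):
                shape = tok.split("=", 1)[1]
            if tok.startswith("semi_axes="):
                pass
        parts = header.split("semi_axes=")
        if len(parts) == 2:
            a, b = parts[1].split()[:2]
            semi = (float(a), float(b))

        def block(name, ncol, dtype):
            tag, count = fh.readline().split()
            if tag != name:
                raise MeshError(f"expected '{name}' block, got '{tag}'")
            rows = [fh.readline().split() for _ in range(int(count))]
            return np.array(rows, dtype=dtype).reshape(int(count), ncol)

        nodes = block("nodes", 2, float)
        elements = block("elements", 3, int)
        boundary = block("boundary_edges", 2, int)
        tag, count = fh.readline().split()
        if tag != "electrodes":
            raise MeshError(f"expected 'electrodes' block, got '{tag}'")
        electrode_edges = [
            np.array(fh.readline().split(), dtype=int) for _ in range(int(count))
        ]
    mesh = Mesh2D(nodes, elements, boundary, electrode_edges, shape, semi)
    mesh.validate()
    return mesh
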