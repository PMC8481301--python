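"""GREIT linear time-difference reconstruction.

GREIT (Graz consensus Reconstruction algorithm for EIT) builds a single
linear matrix R mapping normalised voltage differences to a 32x32 pixel
image.  R is trained on many small simulated conductivity targets: for
target t with simulated (normalised) data y_t and desired image x_t, R
minimises  sum_t ||x_t - R y_t||^2 + noise penalty, solved in closed form

    R = X Y^T (Y Y^T + lambda^2 Sigma_n)^(-1)

with diagonal measurement-noise covariance Sigma_n.  The regularisation
weight lambda is calibrated so that the achieved noise figure — the ratio
of measurement-domain SNR to image-domain SNR over the training targets —
hits a requested value (default 0.5), via a monotone bisection in
log(lambda).

Sign convention: training targets are conductivity *decreases* mapped to
*positive* desired images, so reconstructed lung images are positive on
inspiration (relative impedance increase), matching clinical display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import CEMForwardSolver, JacobianMatrix
from .mesh import Mesh2D

GRID_SIZE = 32


class TrainingError(RuntimeError):
    """Raised when GREIT training or noise-figure calibration fails."""


@dataclass
class PixelGrid:
    """32x32 reconstruction raster over the domain bounding box.

    Row 0 is the ventral edge (smallest y), column 0 the subject's right
    (smallest x).  ``mask`` flags pixels whose centre lies inside the
    domain outline.
    """

    size: int
    mask: np.ndarray          # (size, size) bool
    centres: np.ndarray       # (size*size, 2) pixel-centre coordinates
    semi_axes: tuple

    @classmethod
    def for_mesh(cls, mesh: Mesh2D, size: int = GRID_SIZE) -> "PixelGrid":
        a, b = mesh.semi_axes
        xs = np.linspace(-1, 1, size, endpoint=False) + 1.0 / size
        X, Y = np.meshgrid(xs * a, xs * b, indexing="xy")
        centres = np.column_stack([X.ravel(), Y.ravel()])
        mask = ((X / a) ** 2 + (Y / b) ** 2 <= 1.0)
        return cls(size=size, mask=mask, centres=centres, semi_axes=(a, b))

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    def embed(self, values: np.ndarray) -> np.ndarray:
        """Place a masked-pixel vector into a full (size, size) image."""
        img = np.zeros((self.size, self.size))
        img[self.mask] = values
        return img


@dataclass
class DifferenceData:
    """Normalised voltage differences dv = (v - v_ref) / v_ref per frame."""

    dv: np.ndarray            # (n_frames, n_measurements)
    reference_frame: int
    timestamps: np.ndarray | None = None


@dataclass
class ReconstructionMatrix:
    """Trained GREIT map from difference data to masked pixel values."""

    matrix: np.ndarray        # (n_masked_pixels, n_measurements)
    grid: PixelGrid
    noise_level: float
    lam: float
    noise_figure_target: float
    noise_figure_achieved: float
    n_targets: int
    target_radius: float


@dataclass
class ImageSequence:
    """Reconstructed relative-impedance images over time (AU)."""

    images: np.ndarray        # (n_frames, size, size)
    timestamps: np.ndarray | None
    grid: PixelGrid

    def global_signal(self) -> np.ndarray:
        """Per-frame sum of in-mask pixel values — the global impedance curve."""
        return self.images[:, self.grid.mask].sum(axis=1)


def normalize_difference(
    frames: np.ndarray,
    reference_frame: int = 0,
    timestamps: np.ndarray | None = None,
) -> DifferenceData:
    """Normalised time-difference data against one reference frame.

    ``frames`` is (n_frames, n_measurements); dv = (v - v_ref)/v_ref
    elementwise.  Raises if any reference channel is zero (naming it).
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 2:
        raise ValueError("frames must be a 2-D array (n_frames, n_measurements)")
    if not 0 <= reference_frame < frames.shape[0]:
        raise IndexError(f"reference frame {reference_frame} out of range")
    v_ref = frames[reference_frame]
    zero = np.nonzero(v_ref == 0)[0]
    if zero.size:
        raise ValueError(f"reference frame has zero voltage in channel(s) {zero.tolist()}")
    dv = frames / v_ref - 1.0
    return DifferenceData(dv=dv, reference_frame=reference_frame,
                          timestamps=timestamps)


# -- training -------------------------------------------------------------

def _training_targets(
    mesh: Mesh2D,
    grid: PixelGrid,
    jac: JacobianMatrix,
    n_targets: int,
    target_radius: float,
    image_radius: float,
    contrast: float = 0.01,
):
    """Simulated data and desired images for a uniform grid of targets.

    Candidate centres lie on a uniform sqrt(n_targets)^2 grid over the
    bounding box; centres are kept if the whole target disk fits inside
    the domain.  Target data is the linearised normalised difference for a
    small conductivity *decrease* of the elements inside the target disk;
    the desired image is a uniform disk of ``image_radius`` with unit
    integral.
    """
    a, b = mesh.semi_axes
    side = int(round(np.sqrt(n_targets)))
    xs = np.linspace(-1, 1, side, endpoint=False) + 1.0 / side
    cx, cy = np.meshgrid(xs * a, xs * b, indexing="xy")
    cand = np.column_stack([cx.ravel(), cy.ravel()])
    rad = np.sqrt((cand[:, 0] / a) ** 2 + (cand[:, 1] / b) ** 2)
    keep = rad <= 1.0 - target_radius
    centres = cand[keep]

    centroids = mesh.element_centroids()
    areas = np.abs(mesh.element_areas())
    v0 = jac.baseline_frame
    sigma0 = jac.sigma0
    pix = grid.centres[grid.mask.ravel()]
    pixel_area = (2.0 * a / grid.size) * (2.0 * b / grid.size)

    ys, xs_img, used = [], [], []
    for c in centres:
        in_el = np.linalg.norm(centroids - c, axis=1) <= target_radius
        if not in_el.any():
            continue
        dsig = np.zeros(mesh.n_elements)
        dsig[in_el] = -contrast * sigma0[in_el]
        y = (jac.entries @ dsig) / v0
        in_pix = np.linalg.norm(pix - c, axis=1) <= image_radius
        if not in_pix.any():
            continue
        x = np.zeros(pix.shape[0])
        x[in_pix] = 1.0 / (in_pix.sum() * pixel_area)
        # weight the desired image by the target's conductivity-area moment
        # so amplitude response is uniform per unit perturbation
        ys.append(y)
        xs_img.append(x * (contrast * (areas[in_el] * sigma0[in_el]).sum()))
        used.append(c)
    if len(ys) < 8:
        raise TrainingError("too few in-domain training targets")
    return np.array(ys).T, np.array(xs_img).T, np.array(used)


def _solve_R(Y, X, lam, noise_cov_diag):
    M = Y @ Y.T + (lam ** 2) * np.diag(noise_cov_diag)
    return np.linalg.solve(M, Y @ X.T).T


def _noise_figure(R, Y, noise_level):
    """Ratio of measurement SNR to image SNR over the training targets.

    Measurement SNR: mean absolute training-target signal over the noise
    std; image SNR: mean absolute reconstructed amplitude over the rms
    image noise propagated through R.
    """
    snr_meas = np.abs(Y).mean() / noise_level
    img = R @ Y
    img_noise_rms = noise_level * np.sqrt((R ** 2).sum(axis=1).mean())
    snr_img = np.abs(img).mean() / img_noise_rms
    return snr_meas / snr_img


def train_greit(
    mesh: Mesh2D,
    solver: CEMForwardSolver | None = None,
    sigma0: np.ndarray | None = None,
    n_targets: int = 1024,
    target_radius: float = 0.1,
    image_radius: float = 0.1,
    noise_figure: float = 0.5,
    noise_level: float = 5e-4,
    grid_size: int = GRID_SIZE,
    jac: JacobianMatrix | None = None,
) -> ReconstructionMatrix:
    """Train a GREIT reconstruction matrix on a homogeneous baseline.

    Parameters
    ----------
    mesh, solver : forward model; a solver is built if not supplied.
    sigma0 : baseline conductivity (default homogeneous 1 S/m).
    n_targets : candidate training-target count on a uniform grid (>= 64).
    target_radius : conductivity-target radius as a fraction of the domain
        radius (0 < r < 0.5).
    image_radius : radius of the uniform desired-image disk.
    noise_figure : requested noise figure; lambda is bisected until the
        achieved figure is within 5% of this.
    noise_level : relative measurement noise std used for Sigma_n and the
        noise-figure definition.
    jac : optionally a precomputed Jacobian at sigma0.
    """
    if n_targets < 64:
        raise ValueError("n_targets must be >= 64")
    if not 0 < target_radius < 0.5:
        raise ValueError("target_radius must lie in (0, 0.5)")
    if noise_figure <= 0:
        raise ValueError("noise_figure must be positive")
    if solver is None:
        solver = CEMForwardSolver(mesh)
    if sigma0 is None:
        sigma0 = np.ones(mesh.n_elements)
    if jac is None:
        jac = solver.jacobian(sigma0)
    grid = PixelGrid.for_mesh(mesh, grid_size)
    Y, X, _ = _training_targets(mesh, grid, jac, n_targets,
                                target_radius, image_radius)
    noise_cov = np.full(Y.shape[0], noise_level ** 2)

    # bracket: NF decreases monotonically with lambda
    scale = np.sqrt(np.trace(Y @ Y.T) / (Y.shape[0] * noise_level ** 2))
    lo, hi = np.log10(scale) - 8.0, np.log10(scale) + 8.0
    nf_lo = _noise_figure(_solve_R(Y, X, 10.0 ** lo, noise_cov), Y, noise_level)
    nf_hi = _noise_figure(_solve_R(Y, X, 10.0 ** hi, noise_cov), Y, noise_level)
    if not (nf_hi <= noise_figure <= nf_lo):
        raise TrainingError(
            f"requested noise figure {noise_figure} outside achievable range "
            f"[{nf_hi:.4g}, {nf_lo:.4g}] for lambda in [1e{lo:.1f}, 1e{hi:.1f}]"
        )
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        R = _solve_R(Y, X, 10.0 ** mid, noise_cov)
        nf = _noise_figure(R, Y, noise_level)
        if nf > noise_figure:
            lo = mid
        else:
            hi = mid
        if abs(nf - noise_figure) / noise_figure < 1e-3:
            break
    lam = 10.0 ** mid
    achieved = nf
    if abs(achieved - noise_figure) / noise_figure > 0.05:
        raise TrainingError(
            f"noise-figure calibration did not converge: achieved {achieved:.4g} "
            f"vs requested {noise_figure:.4g} (lambda bracket [{lo:.3f},{hi:.3f}])"
        )
    return ReconstructionMatrix(
        matrix=R, grid=grid, noise_level=noise_level, lam=lam,
        noise_figure_target=noise_figure, noise_figure_achieved=achieved,
        n_targets=Y.shape[1], target_radius=target_radius,
    )


def reconstruct(R: ReconstructionMatrix, dv: DifferenceData) -> ImageSequence:
    """Apply the trained linear map frame by frame: x = R dv."""
    data = np.atleast_2d(dv.dv)
    if data.shape[1] != R.matrix.shape[1]:
        raise ValueError(
            f"difference data has {data.shape[1]} channels, "
            f"reconstruction matrix expects {R.matrix.shape[1]}"
        )
    vals = data @ R.matrix.T                     # (n_frames, n_masked)
    images = np.zeros((vals.shape[0], R.grid.size, R.grid.size))
    images[:, R.grid.mask] = vals
    return ImageSequence(images=images, timestamps=dv.timestamps, grid=R.grid)


def centre_of_gravity(image: np.ndarray, grid: PixelGrid) -> np.ndarray:
    """Amplitude-weighted centre of a single image in domain coordinates."""
    w = np.abs(image[grid.mask])
    if w.sum() == 0:
        raise ValueError("zero image has no centre of gravity")
    pix = grid.centres[grid.mask.ravel()]
    return (pix * w[:, None]).sum(axis=0) / w.sum()
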