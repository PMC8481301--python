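"""Synthetic breathing-phantom and bench data generation.

Generates every input the evaluation pipeline consumes:

* a two-lung conductivity phantom on the FEM thorax mesh, with lung
  conductivity coupled linearly to lung volume (air lowers conductivity),
* a breathing protocol of relaxed tidal breaths followed by one slow
  vital capacity (SVC) maneuver, sampled at the EIT frame rate (50 Hz),
* a matched spirometry trace at its own (lower) sampling rate,
* paired "device" recordings with independent multiplicative Gaussian
  noise realisations, emulating the four-measurement sequence
  (device A, device B, device A, device B),
* a constant-baseline resistor-network recording with configurable noise
  and linear drift for bench QC.

Ground truth (regional ventilation fractions, per-region volume signals,
per-frame lung volume) is returned alongside every simulated sequence so
that downstream index estimates can be scored against it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .forward import CEMForwardSolver, ElectrodeModel, StimulationProtocol
from .mesh import Mesh2D, build_thorax_mesh

logger = logging.getLogger(__name__)


# -- configuration --------------------------------------------------------

@dataclass(frozen=True)
class LungRegion:
    """One elliptic lung region: centre and semi-axes in domain units."""

    centre: tuple = (0.0, 0.0)
    semi_axes: tuple = (0.28, 0.45)

    def contains(self, pts: np.ndarray) -> np.ndarray:
        dx = (pts[:, 0] - self.centre[0]) / self.semi_axes[0]
        dy = (pts[:, 1] - self.centre[1]) / self.semi_axes[1]
        return dx ** 2 + dy ** 2 <= 1.0


@dataclass(frozen=True)
class PhantomConfig:
    """Breathing-thorax phantom: geometry, conductivities, ventilation split.

    Conductivities are in S/m.  ``conductivity_per_litre`` is the linear
    volume->conductivity coupling k: each lung element follows
    sigma(t) = sigma_exp - k * w_region * V_region(t), so conductivity
    falls on inspiration.  ``right_weight`` is the fraction of ventilation
    delivered to the right lung (subject's right, x < 0); weights sum to 1.
    ``tau_right``/``tau_left`` are optional first-order lag time constants
    (s) on the regional volume signal, used to inject regional ventilation
    delay.  ``dorsal_weight`` optionally skews amplitude towards the dorsal
    half of each lung (0.5 = no skew).
    """

    background_conductivity: float = 0.48
    lung_conductivity_exp: float = 0.24
    conductivity_per_litre: float = 0.05
    right_weight: float = 0.5
    right_lung: LungRegion = LungRegion(centre=(-0.42, 0.0))
    left_lung: LungRegion = LungRegion(centre=(0.42, 0.0))
    tau_right: float = 0.0
    tau_left: float = 0.0
    dorsal_weight: float = 0.5

    def __post_init__(self):
        if not 0 < self.right_weight < 1:
            raise ValueError("right_weight must lie in (0, 1)")
        if self.conductivity_per_litre <= 0:
            raise ValueError("conductivity_per_litre must be positive "
                             "(conductivity falls on inspiration)")
        for lung in (self.right_lung, self.left_lung):
            cx, cy = lung.centre
            ax, ay = lung.semi_axes
            if abs(cx) + ax > 1.0 or abs(cy) + ay > 1.0:
                raise ValueError("lung ellipse extends outside the unit domain")
        # non-overlap along the lateral axis
        gap = (self.left_lung.centre[0] - self.left_lung.semi_axes[0]) - (
            self.right_lung.centre[0] + self.right_lung.semi_axes[0])
        if gap <= 0:
            raise ValueError("lung ellipses overlap")

    @property
    def left_weight(self) -> float:
        return 1.0 - self.right_weight


@dataclass(frozen=True)
class BreathingProtocol:
    """Tidal breathing followed by one slow vital capacity maneuver.

    Tidal cycles are sinusoidal at ``tidal_volume`` litres peak-to-trough;
    the SVC is a half-cosine inspiration from FRC to FRC + 0.6*VC followed
    by a half-cosine expiration down to FRC - 0.4*VC, so the SVC
    peak-to-trough excursion equals ``vital_capacity`` exactly.  Volumes
    are litres relative to FRC.
    """

    n_tidal_breaths: int = 3
    tidal_volume: float = 0.5
    tidal_period: float = 4.0
    vital_capacity: float = 4.0
    svc_insp_duration: float = 8.0
    svc_exp_duration: float = 10.0
    frame_rate: float = 50.0
    insp_fraction_above_frc: float = 0.6

    def __post_init__(self):
        if self.frame_rate <= 0:
            raise ValueError("frame rate must be positive")
        for name in ("tidal_period", "svc_insp_duration", "svc_exp_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tidal_volume < 0 or self.vital_capacity < 0:
            raise ValueError("volumes must be non-negative")

    @property
    def duration(self) -> float:
        return (self.n_tidal_breaths * self.tidal_period
                + self.svc_insp_duration + self.svc_exp_duration)

    @property
    def svc_start_time(self) -> float:
        return self.n_tidal_breaths * self.tidal_period

    @property
    def svc_peak_time(self) -> float:
        return self.svc_start_time + self.svc_insp_duration

    def volume_at(self, t: np.ndarray) -> np.ndarray:
        """Lung volume (L above FRC) at times ``t`` (s)."""
        t = np.asarray(t, dtype=float)
        v = np.zeros_like(t)
        t0 = self.svc_start_time
        tidal = t < t0
        v[tidal] = 0.5 * self.tidal_volume * (
            1.0 - np.cos(2 * np.pi * t[tidal] / self.tidal_period))
        top = self.insp_fraction_above_frc * self.vital_capacity
        bottom = top - self.vital_capacity
        insp = (t >= t0) & (t < t0 + self.svc_insp_duration)
        ph = (t[insp] - t0) / self.svc_insp_duration
        v[insp] = top * 0.5 * (1.0 - np.cos(np.pi * ph))
        expi = t >= t0 + self.svc_insp_duration
        ph = np.clip((t[expi] - t0 - self.svc_insp_duration)
                     / self.svc_exp_duration, 0.0, 1.0)
        v[expi] = bottom + (top - bottom) * 0.5 * (1.0 + np.cos(np.pi * ph))
        return v


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative Gaussian noise and linear drift.

    ``relative_noise`` is the per-measurement multiplicative std (5e-4
    corresponds to a 66 dB channel SNR); ``drift_per_hour`` is the
    fractional linear gain change over one hour.
    """

    relative_noise: float = 5e-4
    drift_per_hour: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.relative_noise < 0:
            raise ValueError("noise level must be non-negative")


@dataclass
class SpirometryTrace:
    """Volume-time trace as a spirometer would record it."""

    timestamps: np.ndarray    # s, strictly increasing
    volume: np.ndarray        # L relative to FRC
    sampling_rate: float      # Hz


@dataclass
class EITFrameSequence:
    """Time-stamped frames of boundary-voltage measurements."""

    frames: np.ndarray        # (n_frames, n_measurements) V
    timestamps: np.ndarray    # s
    frame_rate: float
    device: str = "A"
    seed: int | None = None
    current_amplitude: float = 5e-3
    frequency: float = 1e5

    def __post_init__(self):
        if self.frames.shape[0] != self.timestamps.shape[0]:
            raise ValueError("frame count and timestamp count differ")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite values")


@dataclass
class GroundTruth:
    """What the phantom actually did, for scoring recovered indices."""

    right_fraction: float
    volume: np.ndarray            # L above FRC per frame
    volume_right: np.ndarray      # lagged regional volume signals
    volume_left: np.ndarray
    tau_right: float
    tau_left: float
    cov_percent: float            # ventral->dorsal centroid of the true swing
    svc_start_frame: int
    svc_peak_frame: int
    svc_end_frame: int


# -- generators -----------------------------------------------------------

def volume_waveform(protocol: BreathingProtocol,
                    sampling_rate: float = 25.0) -> SpirometryTrace:
    """Spirometry-style volume trace for the breathing protocol.

    Sampled at ``sampling_rate`` (default 25 Hz, deliberately different
    from the 50 Hz EIT frame rate so downstream interpolation is real).
    """
    if sampling_rate <= 0:
        raise ValueError("sampling rate must be positive")
    n = int(np.floor(protocol.duration * sampling_rate)) + 1
    t = np.arange(n) / sampling_rate
    return SpirometryTrace(timestamps=t, volume=protocol.volume_at(t),
                           sampling_rate=sampling_rate)


def _first_order_lag(x: np.ndarray, tau: float, dt: float) -> np.ndarray:
    """Discrete first-order low-pass with time constant ``tau`` seconds."""
    if tau <= 0:
        return x.copy()
    y = np.empty_like(x)
    y[0] = x[0]
    alpha = dt / (tau + dt)
    for i in range(1, len(x)):
        y[i] = y[i - 1] + alpha * (x[i] - y[i - 1])
    return y


class PhantomSimulator:
    """Couples a phantom + protocol to the CEM forward solver.

    Reusable across noise realisations: the noiseless frame sequence is
    computed once and cached; each call to :meth:`noisy_frames` draws a
    fresh multiplicative-noise realisation.
    """

    def __init__(
        self,
        phantom: PhantomConfig,
        protocol: BreathingProtocol,
        mesh: Mesh2D | None = None,
        stim: StimulationProtocol | None = None,
        electrodes: ElectrodeModel | None = None,
        refinement: int = 2,
    ):
        self.phantom = phantom
        self.protocol = protocol
        self.mesh = mesh if mesh is not None else build_thorax_mesh(
            "circle", refinement)
        self.stim = stim or StimulationProtocol()
        self.solver = CEMForwardSolver(self.mesh, self.stim, electrodes)
        cent = self.mesh.element_centroids()
        self.right_elems = phantom.right_lung.contains(cent)
        self.left_elems = phantom.left_lung.contains(cent)
        if not self.right_elems.any() or not self.left_elems.any():
            raise ValueError("mesh too coarse: a lung region contains no elements")
        self._dorsal = cent[:, 1] > 0
        self._cache: dict = {}

    def conductivity_at(self, v_right: float, v_left: float) -> np.ndarray:
        """Element conductivity for given regional volumes (L above FRC)."""
        ph = self.phantom
        sigma = np.full(self.mesh.n_elements, ph.background_conductivity)
        sigma[self.right_elems] = ph.lung_conductivity_exp
        sigma[self.left_elems] = ph.lung_conductivity_exp
        k = ph.conductivity_per_litre
        dw = ph.dorsal_weight
        for elems, w, v in ((self.right_elems, ph.right_weight, v_right),
                            (self.left_elems, ph.left_weight, v_left)):
            scale = np.where(self._dorsal[elems], 2 * dw, 2 * (1 - dw))
            sigma[elems] -= k * w * v * scale
        return sigma

    def regional_volumes(self):
        """Per-frame regional volume signals (with lag) and timestamps."""
        n = int(np.floor(self.protocol.duration * self.protocol.frame_rate)) + 1
        t = np.arange(n) / self.protocol.frame_rate
        v = self.protocol.volume_at(t)
        dt = 1.0 / self.protocol.frame_rate
        vr = _first_order_lag(v, self.phantom.tau_right, dt)
        vl = _first_order_lag(v, self.phantom.tau_left, dt)
        return t, v, vr, vl

    def noiseless_frames(self) -> tuple:
        """(timestamps, frames) of the noiseless voltage sequence (cached)."""
        if "frames" in self._cache:
            return self._cache["t"], self._cache["frames"]
        t, v, vr, vl = self.regional_volumes()
        frames = np.empty((len(t), self.stim.n_measurements))
        for i in range(len(t)):
            sigma = self.conductivity_at(vr[i], vl[i])
            if np.any(sigma <= 0):
                raise ValueError(
                    f"conductivity driven non-positive at frame {i} "
                    f"(t={t[i]:.2f} s); reduce conductivity_per_litre or volumes"
                )
            frames[i] = self.solver.solve(sigma)
        self._cache.update(t=t, frames=frames, v=v, vr=vr, vl=vl)
        return t, frames

    def ground_truth(self) -> GroundTruth:
        t, _ = self.noiseless_frames()
        ph, c = self.phantom, self._cache
        # true ventral->dorsal centroid of the conductivity swing
        cent = self.mesh.element_centroids()
        areas = np.abs(self.mesh.element_areas())
        swing = np.zeros(self.mesh.n_elements)
        dw = ph.dorsal_weight
        for elems, w in ((self.right_elems, ph.right_weight),
                         (self.left_elems, ph.left_weight)):
            scale = np.where(self._dorsal[elems], 2 * dw, 2 * (1 - dw))
            swing[elems] = ph.conductivity_per_litre * w * scale
        wts = swing * areas
        b = self.mesh.semi_axes[1]
        y01 = (cent[:, 1] + b) / (2 * b)
        cov = 100.0 * (wts * y01).sum() / wts.sum()
        fr = 1.0 / self.protocol.frame_rate
        return GroundTruth(
            right_fraction=(wts[self.right_elems].sum() / wts.sum()),
            volume=c["v"], volume_right=c["vr"], volume_left=c["vl"],
            tau_right=ph.tau_right, tau_left=ph.tau_left,
            cov_percent=cov,
            svc_start_frame=int(round(self.protocol.svc_start_time / fr)),
            svc_peak_frame=int(round(self.protocol.svc_peak_time / fr)),
            svc_end_frame=len(t) - 1,
        )

    def noisy_frames(self, noise: NoiseModel, device: str = "A") -> EITFrameSequence:
        t, clean = self.noiseless_frames()
        rng = np.random.default_rng(noise.seed)
        frames = clean.copy()
        if noise.relative_noise > 0:
            frames = frames * (1.0 + noise.relative_noise
                               * rng.standard_normal(frames.shape))
        if noise.drift_per_hour != 0.0:
            gain = 1.0 + noise.drift_per_hour * t / 3600.0
            frames = frames * gain[:, None]
        return EITFrameSequence(
            frames=frames, timestamps=t, frame_rate=self.protocol.frame_rate,
            device=device, seed=noise.seed,
            current_amplitude=self.stim.current_amplitude,
            frequency=self.stim.frequency,
        )


def simulate_sequence(
    phantom: PhantomConfig,
    protocol: BreathingProtocol,
    noise: NoiseModel,
    mesh: Mesh2D | None = None,
    refinement: int = 2,
    spirometry_rate: float = 25.0,
    device: str = "A",
    simulator: PhantomSimulator | None = None,
):
    """Simulate one EIT recording with matched spirometry and ground truth.

    Returns ``(EITFrameSequence, SpirometryTrace, GroundTruth)``.
    """
    sim = simulator or PhantomSimulator(phantom, protocol, mesh,
                                        refinement=refinement)
    seq = sim.noisy_frames(noise, device=device)
    spiro = volume_waveform(protocol, spirometry_rate)
    return seq, spiro, sim.ground_truth()


def emulate_two_devices(
    phantom: PhantomConfig,
    protocol: BreathingProtocol,
    seeds: tuple,
    noise_a: NoiseModel | None = None,
    noise_b: NoiseModel | None = None,
    mesh: Mesh2D | None = None,
    refinement: int = 2,
    simulator: PhantomSimulator | None = None,
) -> list:
    """Emulate the four-measurement sequence A, B, A, B on one phantom.

    Returns four :class:`EITFrameSequence` (device labels "A","B","A","B"),
    sharing the identical noiseless core but with independent noise
    realisations from the four ``seeds``.  Device B may use a distinct
    noise level via ``noise_b``.
    """
    if len(seeds) != 4:
        raise ValueError("exactly four seeds required")
    if len(set(seeds)) < 4:
        logger.warning("duplicate seeds in emulate_two_devices: %s", seeds)
    noise_a = noise_a or NoiseModel()
    noise_b = noise_b or noise_a
    sim = simulator or PhantomSimulator(phantom, protocol, mesh,
                                        refinement=refinement)
    out = []
    for seed, (dev, base) in zip(
            seeds, [("A", noise_a), ("B", noise_b),
                    ("A", noise_a), ("B", noise_b)]):
        out.append(sim.noisy_frames(replace(base, seed=int(seed)), device=dev))
    return out


def resistor_network_recording(
    duration_s: float = 3600.0,
    frame_rate: float = 20.0,
    noise: NoiseModel | None = None,
    n_channels: int = 16,
    baseline_voltage: float = 0.5,
) -> EITFrameSequence:
    """Constant-baseline bench recording from a 100-ohm resistor network.

    The nominal per-channel voltage is 0.5 V (100 ohm x 5 mA drive).
    Multiplicative Gaussian noise and a linear gain drift
    (``noise.drift_per_hour`` fractional change per hour) are applied.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    noise = noise or NoiseModel()
    n = int(np.floor(duration_s * frame_rate)) + 1
    t = np.arange(n) / frame_rate
    rng = np.random.default_rng(noise.seed)
    frames = np.full((n, n_channels), baseline_voltage)
    if noise.relative_noise > 0:
        frames = frames * (1.0 + noise.relative_noise
                           * rng.standard_normal(frames.shape))
    if noise.drift_per_hour != 0.0:
        frames = frames * (1.0 + noise.drift_per_hour * t / 3600.0)[:, None]
    return EITFrameSequence(frames=frames, timestamps=t, frame_rate=frame_rate,
                            device="bench", seed=noise.seed)
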