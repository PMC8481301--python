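"""Clinical ventilation indices from reconstructed EIT image sequences.

Implements the standard measure set for comparing ventilation imaging
devices:

(a, b) linearity — the ratio of tidal variation to the impedance change
    during a slow vital capacity (SVC) maneuver, and the Pearson
    correlation between spirometry volume (linearly interpolated onto the
    EIT time base) and the global impedance curve over the SVC;
(c, d) global ventilation distribution — the fractions of tidal variation
    in the right/left and ventral/dorsal image halves;
(e, f) spatial ventilation distribution — the global inhomogeneity (GI)
    index and the centre of ventilation (CoV);
(g) temporal ventilation distribution — the standard deviation of regional
    ventilation delay (RVD-SD) over the SVC inspiration.

Tidal variation (TV) images are the pixelwise difference between
end-inspiration and end-expiration; impedance amplitudes may be
normalised to the SVC volume in millilitres.  All ratio-type indices (GI,
CoV, RVD-SD, regional fractions) are invariant under global positive
scaling of the images.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import pearsonr

from .greit import ImageSequence, ReconstructionMatrix, normalize_difference, reconstruct
from .synthetic import EITFrameSequence, SpirometryTrace

logger = logging.getLogger(__name__)


class AnalysisError(RuntimeError):
    """Raised when a curve or image does not support the requested measure."""


@dataclass
class GlobalCurve:
    """Per-frame sum of in-mask pixel values (AU) with timestamps."""

    values: np.ndarray
    timestamps: np.ndarray

    @classmethod
    def from_images(cls, images: ImageSequence) -> "GlobalCurve":
        t = images.timestamps
        if t is None:
            t = np.arange(images.images.shape[0], dtype=float)
        return cls(values=images.global_signal(), timestamps=np.asarray(t))


@dataclass
class BreathSegmentation:
    """Alternating breath extrema plus the SVC maneuver segment."""

    end_expiration: np.ndarray    # frame indices of minima
    end_inspiration: np.ndarray   # frame indices of maxima
    svc_start: int                # trough preceding the SVC inspiration
    svc_peak: int                 # SVC end-inspiration
    svc_end: int                  # trough ending the SVC expiration


@dataclass
class TidalImage:
    """End-inspiration minus end-expiration image for one breath (AU)."""

    image: np.ndarray
    breath_id: int
    mask: np.ndarray
    volume_factor: float | None = None    # mL per AU if normalised


@dataclass
class LungROI:
    """Functional-lung pixel mask derived by thresholding a TV image."""

    mask: np.ndarray
    threshold_fraction: float


@dataclass
class VentilationIndices:
    """Per-maneuver index set consumed by the device-comparison statistics."""

    tv: float                     # mean tidal variation (AU)
    dz_svc: float                 # SVC impedance excursion (AU)
    tv_svc_ratio: float
    volume_impedance_r: float
    right_fraction: float
    ventral_fraction: float
    gi: float
    cov_percent: float
    rvd_sd: float
    volume_factor: float | None = None   # mL per AU

    INDEX_NAMES = ("tv_svc_ratio", "volume_impedance_r", "right_fraction",
                   "ventral_fraction", "gi", "cov_percent", "rvd_sd")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("tv", "dz_svc") + self.INDEX_NAMES + ("volume_factor",)}


# -- breath segmentation --------------------------------------------------

def detect_breaths(curve: GlobalCurve,
                   prominence_fraction: float = 0.1) -> BreathSegmentation:
    """Segment a global impedance curve into breaths and the SVC maneuver.

    Extrema are found with a prominence filter of ``prominence_fraction``
    of the curve's global excursion, then reduced to a strictly
    alternating min/max sequence.  The SVC segment is the adjacent
    trough -> peak -> trough triple with the maximum peak-to-trough
    amplitude.
    """
    y = np.asarray(curve.values, dtype=float)
    excursion = y.max() - y.min()
    if excursion <= 0 or not np.isfinite(excursion):
        raise AnalysisError("no breaths detected: flat global curve")
    prom = prominence_fraction * excursion
    maxima, _ = find_peaks(y, prominence=prom)
    minima, _ = find_peaks(-y, prominence=prom)
    # endpoints are always candidate troughs (recordings start at FRC and
    # end at the bottom of the SVC expiration); the alternating merge below
    # discards them when an adjacent interior extremum is deeper
    minima = np.concatenate([[0], minima, [len(y) - 1]])
    if maxima.size == 0 or minima.size == 0:
        raise AnalysisError("no breaths detected: fewer than two extrema")

    # merge into a strictly alternating sequence, keeping the more extreme
    # of consecutive same-type extrema
    ext = sorted([(i, +1) for i in maxima] + [(i, -1) for i in minima])
    alt: list = []
    for idx, kind in ext:
        if alt and alt[-1][1] == kind:
            prev = alt[-1][0]
            better = idx if (kind * y[idx] > kind * y[prev]) else prev
            alt[-1] = (better, kind)
        else:
            alt.append((idx, kind))
    maxima = np.array([i for i, k in alt if k == +1])
    minima = np.array([i for i, k in alt if k == -1])

    # SVC: the trough->peak->trough triple with largest amplitude
    best, best_amp = None, -np.inf
    for pk in maxima:
        before = minima[minima < pk]
        after = minima[minima > pk]
        if before.size == 0 or after.size == 0:
            continue
        lo, hi = before[-1], after[0]
        amp = y[pk] - min(y[lo], y[hi])
        if amp > best_amp:
            best, best_amp = (int(lo), int(pk), int(hi)), amp
    if best is None:
        raise AnalysisError("no complete trough-peak-trough excursion found")
    return BreathSegmentation(end_expiration=minima, end_inspiration=maxima,
                              svc_start=best[0], svc_peak=best[1],
                              svc_end=best[2])


# -- tidal images and normalisation ---------------------------------------

def tidal_image(images: ImageSequence, end_insp: int, end_exp: int,
                breath_id: int = 0) -> TidalImage:
    """Pixelwise end-inspiration minus end-expiration image."""
    n = images.images.shape[0]
    for idx in (end_insp, end_exp):
        if not 0 <= idx < n:
            raise IndexError(f"frame index {idx} out of range [0, {n})")
    return TidalImage(image=images.images[end_insp] - images.images[end_exp],
                      breath_id=breath_id, mask=images.grid.mask)


def normalize_to_volume(values, svc_volume_ml: float, dz_svc: float):
    """Scale impedance quantities to millilitre equivalents.

    The factor is ``svc_volume_ml / dz_svc`` (mL per AU); ratios and all
    scale-invariant indices are unchanged by this.  Returns
    ``(scaled_values, factor)``.
    """
    if svc_volume_ml <= 0:
        raise ValueError("SVC volume must be positive")
    if dz_svc <= 0:
        raise ValueError("SVC impedance excursion must be positive")
    factor = svc_volume_ml / dz_svc
    if isinstance(values, TidalImage):
        return TidalImage(image=values.image * factor, breath_id=values.breath_id,
                          mask=values.mask, volume_factor=factor), factor
    return np.asarray(values, dtype=float) * factor, factor


# -- measures -------------------------------------------------------------

def linearity(curve: GlobalCurve, spiro: SpirometryTrace,
              seg: BreathSegmentation, tidal_tvs: np.ndarray):
    """TV/SVC ratio and the volume-impedance Pearson correlation.

    Spirometry volume is linearly interpolated onto the EIT timestamps of
    the SVC segment; r is computed there.  ``tv_svc_ratio`` is the mean
    tidal TV over the SVC impedance excursion.
    """
    t_eit = curve.timestamps[seg.svc_start:seg.svc_end + 1]
    if t_eit[0] > spiro.timestamps[-1] or t_eit[-1] < spiro.timestamps[0]:
        raise AnalysisError("spirometry does not overlap the SVC segment in time")
    vol = np.interp(t_eit, spiro.timestamps, spiro.volume)
    z = curve.values[seg.svc_start:seg.svc_end + 1]
    r = float(pearsonr(vol, z).statistic)
    dz_svc = curve.values[seg.svc_peak] - min(curve.values[seg.svc_start],
                                              curve.values[seg.svc_end])
    ratio = float(np.mean(tidal_tvs) / dz_svc) if len(tidal_tvs) else np.nan
    return ratio, r, dz_svc


def lung_roi(tv: TidalImage, threshold_fraction: float = 0.2) -> LungROI:
    """Functional-lung ROI: pixels with TV >= threshold * max(TV)."""
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold fraction must lie in (0, 1)")
    img = tv.image
    peak = img[tv.mask].max() if tv.mask.any() else 0.0
    if peak <= 0:
        raise AnalysisError("all-zero tidal image: cannot build lung ROI")
    mask = tv.mask & (img >= threshold_fraction * peak)
    return LungROI(mask=mask, threshold_fraction=threshold_fraction)


def gi_index(tv: TidalImage, roi: LungROI) -> float:
    """Global inhomogeneity index.

    GI = sum_{p in ROI} |TV_p - median_ROI(TV)| / sum_{p in ROI} TV_p;
    zero iff ventilation is perfectly homogeneous over the ROI.
    """
    vals = tv.image[roi.mask]
    if vals.size == 0:
        raise AnalysisError("empty lung ROI")
    total = vals.sum()
    if total <= 0:
        raise AnalysisError("non-positive total tidal variation in ROI")
    return float(np.abs(vals - np.median(vals)).sum() / total)


def center_of_ventilation(tv: TidalImage) -> float:
    """Amplitude-weighted centroid along ventral->dorsal, in % (0 = ventral).

    Pixel-row centres are placed at (row + 0.5)/n_rows of the
    ventral->dorsal extent; row 0 is the ventral edge.
    """
    img = np.where(tv.mask, tv.image, 0.0)
    total = img.sum()
    if total <= 0:
        raise AnalysisError("zero image: centre of ventilation undefined")
    n_rows = img.shape[0]
    y = (np.arange(n_rows) + 0.5) / n_rows
    return float(100.0 * (img.sum(axis=1) * y).sum() / total)


def regional_fractions(tv: TidalImage):
    """(right_fraction, ventral_fraction) from midline image splits.

    Column 0 is the subject's right and row 0 the ventral edge, so the
    right half is columns [0, n/2) and the ventral half rows [0, n/2).
    """
    img = np.where(tv.mask, tv.image, 0.0)
    total = img.sum()
    if total <= 0:
        raise AnalysisError("zero image: regional fractions undefined")
    half = img.shape[1] // 2
    right = img[:, :half].sum() / total
    ventral = img[:half, :].sum() / total
    return float(right), float(ventral)


def rvd_sd(images: ImageSequence, seg: BreathSegmentation, roi: LungROI,
           threshold: float = 0.4) -> float:
    """Standard deviation of regional ventilation delay over the SVC
    inspiration.

    For each ROI pixel, the time at which its impedance rise first crosses
    ``threshold`` of its total inspiratory change is found by linear
    interpolation between frames and expressed as a percentage of the
    global inspiration time; RVD-SD is the population standard deviation
    over pixels.  Pixels that never cross are excluded (logged).
    """
    i0, i1 = seg.svc_start, seg.svc_peak
    if i1 - i0 < 2:
        raise AnalysisError("SVC inspiration shorter than 3 frames")
    t = images.timestamps
    if t is None:
        t = np.arange(images.images.shape[0], dtype=float)
    sub = images.images[i0:i1 + 1][:, roi.mask]      # (n_frames, n_pixels)
    rise = sub - sub[0]
    final = rise[-1]
    target = threshold * final
    valid = final > 0
    crossed = rise >= target[None, :]
    crossed[:, ~valid] = False
    first = np.argmax(crossed, axis=0)
    has_crossing = crossed.any(axis=0) & (first > 0)
    n_excluded = int(roi.mask.sum() - has_crossing.sum())
    if not has_crossing.any():
        raise AnalysisError("no ROI pixel crosses the RVD threshold")
    if n_excluded:
        logger.info("rvd_sd: excluded %d of %d ROI pixels without a "
                    "threshold crossing", n_excluded, int(roi.mask.sum()))
    k = first[has_crossing]
    ts = t[i0:i1 + 1]
    y1 = rise[k - 1, np.nonzero(has_crossing)[0]]
    y2 = rise[k, np.nonzero(has_crossing)[0]]
    tgt = target[has_crossing]
    frac = np.where(y2 > y1, (tgt - y1) / np.where(y2 > y1, y2 - y1, 1.0), 0.0)
    t_cross = ts[k - 1] + frac * (ts[k] - ts[k - 1])
    rvd = 100.0 * (t_cross - ts[0]) / (ts[-1] - ts[0])
    return float(np.std(rvd))


# -- full per-recording pipeline ------------------------------------------

def analyze_recording(
    seq: EITFrameSequence,
    spiro: SpirometryTrace,
    R: ReconstructionMatrix,
    svc_volume_ml: float | None = None,
    roi_threshold: float = 0.2,
    rvd_threshold: float = 0.4,
    prominence_fraction: float = 0.1,
) -> VentilationIndices:
    """Run the whole index pipeline on one recording.

    Reconstructs against frame 0, detects breaths on the global curve,
    re-references to the first detected end-expiration frame, then
    computes all measures.  ``svc_volume_ml`` (default: the spirometry SVC
    excursion in mL) sets the impedance-to-millilitre factor.
    """
    dv = normalize_difference(seq.frames, 0, timestamps=seq.timestamps)
    images = reconstruct(R, dv)
    curve = GlobalCurve.from_images(images)
    seg = detect_breaths(curve, prominence_fraction)
    ref = int(seg.end_expiration[0]) if seg.end_expiration.size else 0
    if ref != 0:
        dv = normalize_difference(seq.frames, ref, timestamps=seq.timestamps)
        images = reconstruct(R, dv)
        curve = GlobalCurve.from_images(images)
        seg = detect_breaths(curve, prominence_fraction)

    # complete tidal breaths before the SVC: min -> max -> next extremum
    tidal_pairs = []
    for pk in seg.end_inspiration:
        if pk >= seg.svc_peak:
            continue
        lows = seg.end_expiration[seg.end_expiration < pk]
        if lows.size and pk < seg.svc_start + 1:
            tidal_pairs.append((int(pk), int(lows[-1])))
    tvs, tv_imgs = [], []
    for bid, (pk, lo) in enumerate(tidal_pairs):
        ti = tidal_image(images, pk, lo, breath_id=bid)
        tv_imgs.append(ti)
        tvs.append(curve.values[pk] - curve.values[lo])
    tvs = np.asarray(tvs)

    ratio, r, dz_svc = linearity(curve, spiro, seg, tvs)

    if tv_imgs:
        mean_tv = TidalImage(
            image=np.mean([ti.image for ti in tv_imgs], axis=0),
            breath_id=-1, mask=images.grid.mask)
    else:  # fall back to the SVC tidal image
        mean_tv = tidal_image(images, seg.svc_peak, seg.svc_start, breath_id=-1)

    if svc_volume_ml is None:
        svc_volume_ml = 1000.0 * float(spiro.volume.max() - spiro.volume.min())
    _, factor = normalize_to_volume(np.array([dz_svc]), svc_volume_ml, dz_svc)

    roi = lung_roi(mean_tv, roi_threshold)
    gi = gi_index(mean_tv, roi)
    cov = center_of_ventilation(mean_tv)
    right, ventral = regional_fractions(mean_tv)
    rvd = rvd_sd(images, seg, roi, rvd_threshold)

    return VentilationIndices(
        tv=float(np.mean(tvs)) if tvs.size else np.nan,
        dz_svc=float(dz_svc), tv_svc_ratio=ratio, volume_impedance_r=r,
        right_fraction=right, ventral_fraction=ventral, gi=gi,
        cov_percent=cov, rvd_sd=rvd, volume_factor=factor,
    )
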