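"""Per-beat fiducial location and ST-T loop extraction from the VCG.

The repolarization segment of each beat — J point to T-wave end — traces a
loop in (X, Y, Z) space.  This module finds R peaks with a Pan-Tompkins-style
detector on the VCG magnitude, resolves J point, T apex and T end per beat,
and resamples each J→Tend segment to a fixed number of points.

Detection and localization rules (all configurable):

* R peaks: bandpass 5–15 Hz, derivative, squaring, 150 ms moving-window
  integration, adaptive threshold, 200 ms refractory; peak refined to the
  local magnitude maximum.  Either the magnitude signal (default) or the
  single VCG lead with the largest median |R| can drive detection.
* J point: first time after R where the magnitude slope stays below 5% of the
  peak QRS slope for 10 ms, searched in R+20..R+80 ms.
* T apex: largest |deflection| of the dominant T lead in R+120..R+500 ms.
* T end: tangent method — the steepest descending tangent after the apex,
  projected to the isoelectric baseline (PR-segment level).

Beats whose fiducials cannot be resolved (e.g. a truncated final beat) are
dropped.  Indices are 0-based; segments are half-open ``[j_point, t_end)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import FiducialError, NoBeatsError
from .vcg import VCGRecord

logger = logging.getLogger(__name__)


@dataclass
class FiducialSet:
    """Per-beat (r_peak, j_point, t_apex, t_end) sample indices."""

    beats: list  # of (r, j, t_apex, t_end) int tuples
    fs: float
    reference_lead: str = "magnitude"

    def __post_init__(self):
        for r, j, ta, te in self.beats:
            if not (r < j < ta < te):
                raise FiducialError(f"fiducial ordering violated: {(r, j, ta, te)}")
        rs = [b[0] for b in self.beats]
        if any(b >= a for a, b in zip(rs[1:], rs)):
            raise FiducialError("beats not strictly ordered")

    def __len__(self):
        return len(self.beats)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.beats, columns=["r_peak", "j_point", "t_apex", "t_end"]
        ).rename_axis("beat")


@dataclass
class STTLoopSet:
    """Per-beat ST-T trajectories resampled to L points in (X, Y, Z).

    ``loops`` has shape (n_beats, L, 3) in mV.
    """

    loops: np.ndarray
    fs: float
    subject_id: str = ""

    def __post_init__(self):
        self.loops = np.asarray(self.loops, dtype=float)
        if self.loops.ndim != 3 or self.loops.shape[2] != 3:
            raise FiducialError("loops must have shape (n_beats, L, 3)")
        if not np.all(np.isfinite(self.loops)):
            raise FiducialError("non-finite loop values")

    @property
    def n_beats(self) -> int:
        return self.loops.shape[0]

    @property
    def L(self) -> int:
        return self.loops.shape[1]

    def concatenated(self) -> np.ndarray:
        """All loops in beat order as one (n_beats * L, 3) orbit."""
        return self.loops.reshape(-1, 3)


def detect_r_peaks(vcg: VCGRecord, use_lead: str = "magnitude",
                   refractory_s: float = 0.2) -> np.ndarray:
    """Locate one sample index per QRS complex.

    ``use_lead`` is ``"magnitude"`` (default), one of ``"x"/"y"/"z"``, or
    ``"auto"`` to pick the lead with the largest median absolute R amplitude.
    """
    fs = vcg.fs
    if vcg.n_samples < 2 * fs:
        raise NoBeatsError("record shorter than 2 s")
    sig = _detection_signal(vcg, use_lead)
    if np.var(sig) < 1e-12:
        raise NoBeatsError("flat signal: variance below threshold")

    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    f = sps.sosfiltfilt(sos, sig)
    energy = np.gradient(f) ** 2
    win = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(energy, np.ones(win) / win, mode="same")

    dist = max(1, int(round(refractory_s * fs)))
    cand, _ = sps.find_peaks(mwi, distance=dist)
    if cand.size == 0:
        raise NoBeatsError("no QRS-energy peaks found")
    # adaptive threshold: reject peaks far below the typical QRS energy
    thr = 0.20 * np.percentile(mwi[cand], 90)
    cand = cand[mwi[cand] >= thr]
    if cand.size == 0:
        raise NoBeatsError("no peaks above adaptive threshold")

    # refine to the local magnitude maximum
    half = int(round(0.060 * fs))
    mag = np.abs(sig)
    peaks = []
    for c in cand:
        lo, hi = max(0, c - half), min(len(mag), c + half + 1)
        peaks.append(lo + int(np.argmax(mag[lo:hi])))
    peaks = np.unique(peaks)
    # enforce refractory spacing after refinement
    keep = [int(peaks[0])]
    for p in peaks[1:]:
        if p - keep[-1] >= dist:
            keep.append(int(p))
        elif mag[p] > mag[keep[-1]]:
            keep[-1] = int(p)
    return np.array(keep, dtype=int)


def _detection_signal(vcg: VCGRecord, use_lead: str) -> np.ndarray:
    if use_lead == "magnitude":
        return vcg.magnitude
    if use_lead in ("x", "y", "z"):
        return getattr(vcg, use_lead)
    if use_lead == "auto":
        arr = vcg.as_array()
        best = int(np.argmax([np.percentile(np.abs(a), 99) for a in arr]))
        return arr[best]
    raise ValueError(f"unknown detection lead {use_lead!r}")


def locate_beat_fiducials(
    vcg: VCGRecord,
    r_peaks: np.ndarray,
    j_search_s: tuple = (0.020, 0.080),
    j_slope_frac: float = 0.05,
    j_hold_s: float = 0.010,
    t_search_s: tuple = (0.120, 0.500),
) -> FiducialSet:
    """Resolve (J point, T apex, T end) for every detected beat.

    Beats where any rule fails (typically the truncated last beat) are dropped
    and logged; an empty result raises :class:`FiducialError`.
    """
    if len(r_peaks) == 0:
        raise FiducialError("no R peaks supplied")
    fs = vcg.fs
    n = vcg.n_samples
    mag = vcg.magnitude
    # lightly smoothed slope of the magnitude for J-point search
    smooth = max(1, int(round(0.005 * fs)))
    kernel = np.ones(smooth) / smooth
    mslope = np.abs(np.gradient(np.convolve(mag, kernel, mode="same")))

    t_lead = _dominant_t_lead(vcg, r_peaks, t_search_s)
    series = getattr(vcg, t_lead)
    sseries = np.convolve(series, np.ones(max(1, int(0.010 * fs))) / max(1, int(0.010 * fs)),
                          mode="same")

    hold = max(1, int(round(j_hold_s * fs)))
    beats = []
    for i, r in enumerate(r_peaks):
        nxt = r_peaks[i + 1] if i + 1 < len(r_peaks) else n
        j = _find_j(mslope, r, fs, j_search_s, j_slope_frac, hold, nxt)
        if j is None:
            logger.info("beat %d at %d: J point unresolved, dropped", i, r)
            continue
        fid = _find_t(sseries, r, j, fs, t_search_s, min(nxt, n))
        if fid is None:
            logger.info("beat %d at %d: T wave unresolved, dropped", i, r)
            continue
        t_apex, t_end = fid
        if not (r < j < t_apex < t_end <= n) or t_end > nxt:
            logger.info("beat %d at %d: fiducials out of bounds, dropped", i, r)
            continue
        beats.append((int(r), int(j), int(t_apex), int(t_end)))
    if not beats:
        raise FiducialError("no beat yielded a full fiducial set")
    return FiducialSet(beats, fs, reference_lead="magnitude")


def _find_j(mslope, r, fs, j_search_s, frac, hold, limit):
    lo = r + int(round(j_search_s[0] * fs))
    hi = min(r + int(round(j_search_s[1] * fs)), limit - 1)
    if lo >= hi or hi + hold >= len(mslope):
        return None
    ref = np.max(mslope[max(0, r - int(0.060 * fs)): r + int(0.060 * fs)])
    thr = frac * ref
    below = mslope[lo: hi + hold] < thr
    # first index where the slope stays below threshold for `hold` samples
    run = 0
    for k, b in enumerate(below):
        run = run + 1 if b else 0
        if run >= hold:
            return lo + k - hold + 1
    # slope never settles: take the slope minimum in the window as fallback
    return lo + int(np.argmin(mslope[lo:hi]))


def _find_t(series, r, j, fs, t_search_s, limit):
    lo = max(j + 1, r + int(round(t_search_s[0] * fs)))
    hi = min(r + int(round(t_search_s[1] * fs)), limit - 1)
    if hi - lo < int(0.040 * fs):
        return None
    # isoelectric baseline from the PR segment
    blo, bhi = max(0, r - int(0.090 * fs)), max(1, r - int(0.050 * fs))
    baseline = float(np.median(series[blo:bhi]))
    seg = series[lo:hi] - baseline
    apex_rel = int(np.argmax(np.abs(seg)))
    t_apex = lo + apex_rel
    sign = 1.0 if seg[apex_rel] >= 0 else -1.0
    # steepest tangent on the descending limb after the apex
    dhi = min(hi + int(0.120 * fs), limit - 1)
    if t_apex + 2 >= dhi:
        return None
    tail = sign * (series[t_apex:dhi] - baseline)
    slope = np.gradient(tail)
    m_rel = int(np.argmin(slope))
    m = t_apex + m_rel
    s_m = slope[m_rel]
    if s_m >= 0:
        return None
    t_end = m + tail[m_rel] / (-s_m)
    t_end = int(round(t_end))
    if t_end <= t_apex or t_end > limit:
        return None
    return t_apex, t_end


def _dominant_t_lead(vcg, r_peaks, t_search_s):
    """Lead with the largest median |T| deflection across beats."""
    fs = vcg.fs
    scores = {}
    for name in ("x", "y", "z"):
        s = getattr(vcg, name)
        amps = []
        for r in r_peaks:
            lo = r + int(round(t_search_s[0] * fs))
            hi = min(r + int(round(t_search_s[1] * fs)), len(s))
            if hi - lo > 4:
                amps.append(np.max(np.abs(s[lo:hi])))
        scores[name] = np.median(amps) if amps else 0.0
    return max(scores, key=scores.get)


def extract_stt_loops(vcg: VCGRecord, fids: FiducialSet, L: int = 100) -> STTLoopSet:
    """Resample each [j_point, t_end) segment to L points per axis.

    Uniform linear interpolation over the segment; L may exceed the raw
    segment length (upsampling), in which case a warning is logged.
    """
    if len(fids) == 0:
        raise FiducialError("empty fiducial set")
    if L < 16:
        raise ValueError("L must be at least 16")
    arr = vcg.as_array()
    loops = np.empty((len(fids), L, 3))
    for b, (_, j, _, te) in enumerate(fids.beats):
        raw = arr[:, j:te]
        if raw.shape[1] < 2:
            raise FiducialError(f"beat {b}: degenerate ST-T segment [{j}, {te})")
        if L > raw.shape[1]:
            logger.warning(
                "beat %d: upsampling %d-sample ST-T segment to %d points",
                b, raw.shape[1], L,
            )
        src = np.linspace(0.0, 1.0, raw.shape[1])
        dst = np.linspace(0.0, 1.0, L)
        for a in range(3):
            loops[b, :, a] = np.interp(dst, src, raw[a])
    return STTLoopSet(loops, vcg.fs, vcg.subject_id)
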