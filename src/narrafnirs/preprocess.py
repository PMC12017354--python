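"""Optical-density to z-scored hemoglobin preprocessing.

Stages, in the order the pipeline applies them:

1. motion artifact correction, in optical-density space (moving-SD plus
   amplitude-deviation detection, cubic-spline interpolation across
   flagged runs);
2. modified Beer-Lambert inversion to Oxy-Hb / Deoxy-Hb concentration
   changes (per-sample 2x2 linear solve);
3. z-scoring of each channel against the mean and SD of its own resting
   segment, computed on the unfiltered concentration series — the rest
   reference deliberately includes the full physiological fluctuation
   budget (drift, cardiac, respiratory), which is what makes task-evoked
   z-values of order 0.1 meaningful;
4. 0.01-0.20 Hz zero-phase Butterworth band-pass to strip drift and
   cardiac/respiratory pulsations from the z-scored series.

Each stage is exposed both as a function and as a stateless
transformer-style class so chains can be composed explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sg
from scipy.interpolate import CubicSpline

from .datatypes import (ConfigurationError, HemoSeries, InputError,
                        OpticalRecording)

log = logging.getLogger(__name__)

# Molar extinction coefficients, cm^-1 mM^-1, from the standard compiled
# in-vivo tables used by CW-NIRS vendors.  Keyed by wavelength (nm);
# values are (epsilon_HbO, epsilon_HbR).
EXTINCTION_MM_CM: dict[float, tuple[float, float]] = {
    690.0: (0.2764, 2.0513),
    730.0: (0.3900, 1.1022),
    760.0: (0.5862, 1.5485),
    805.0: (0.8536, 0.7861),
    850.0: (1.0580, 0.6913),
}


@dataclass
class MbllConstants:
    """Constants of the modified Beer-Lambert model for one channel set.

    delta_OD(lambda) = [eps_HbO(lambda) * dHbO + eps_HbR(lambda) * dHbR]
                       * L * DPF(lambda)

    with L the source-detector separation (cm) and DPF the differential
    pathlength factor (dimensionless; 6.0 is a common adult-forehead
    default at both measurement wavelengths).
    """

    wavelengths_nm: tuple[float, float] = (730.0, 850.0)
    dpf: tuple[float, float] = (6.0, 6.0)
    pathlength_cm: float = 3.0
    extinction: dict[float, tuple[float, float]] = field(
        default_factory=lambda: dict(EXTINCTION_MM_CM))

    def matrix(self) -> np.ndarray:
        """2x2 map (dHbO, dHbR) -> (dOD at each wavelength)."""
        rows = []
        for lam, dpf in zip(self.wavelengths_nm, self.dpf):
            if lam not in self.extinction:
                raise ConfigurationError(f"no extinction entry for {lam} nm")
            e_hbo, e_hbr = self.extinction[lam]
            rows.append([e_hbo * self.pathlength_cm * dpf,
                         e_hbr * self.pathlength_cm * dpf])
        mat = np.asarray(rows, float)
        if np.linalg.cond(mat) > 1e3:
            raise ConfigurationError("extinction matrix is near-singular")
        return mat

    def forward(self, hbo: np.ndarray, hbr: np.ndarray) -> np.ndarray:
        """Concentration changes -> delta-OD, shape (..., 2, n_samples)."""
        mat = self.matrix()
        conc = np.stack([np.asarray(hbo, float), np.asarray(hbr, float)],
                        axis=-2)
        return np.einsum("wk,...kn->...wn", mat, conc)

    def invert(self, od: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """delta-OD (..., 2, n_samples) -> (dHbO, dHbR)."""
        od = np.asarray(od, float)
        if od.shape[-2] != 2:
            raise InputError("expected two wavelength series")
        inv = np.linalg.inv(self.matrix())
        conc = np.einsum("kw,...wn->...kn", inv, od)
        return conc[..., 0, :], conc[..., 1, :]


def _moving_stats(x: np.ndarray, win: int) -> tuple[np.ndarray, np.ndarray]:
    """Centered moving mean and SD via cumulative sums."""
    win = max(3, win | 1)  # odd, >= 3
    kernel = np.ones(win) / win
    pad = win // 2
    xp = np.pad(x, pad, mode="edge")
    m = np.convolve(xp, kernel, mode="valid")
    m2 = np.convolve(xp * xp, kernel, mode="valid")
    var = np.maximum(m2 - m * m, 0.0)
    return m, np.sqrt(var)


def motion_correct(x: np.ndarray, fs_hz: float, window_s: float = 1.0,
                   z_thresh: float = 5.0, spike_amp: float = 5.0
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Detect and interpolate motion artifacts in one series.

    A sample is flagged when it sits in a window whose moving SD exceeds
    ``z_thresh`` times the typical (median) moving SD *and* its own
    deviation from the local rolling median exceeds ``spike_amp`` times
    that typical moving SD; the rolling median is immune to short spikes,
    so only the spike run itself is flagged.
    Flagged runs are replaced by cubic-spline interpolation through the
    surrounding clean samples (clipped to the clean amplitude range, so
    correction can never add new extremes).

    Returns (corrected series, boolean artifact mask).
    """
    from scipy.ndimage import median_filter

    x = np.asarray(x, float)
    n = x.size
    win = int(round(window_s * fs_hz))
    if n <= win:
        raise InputError("series shorter than the detection window")
    mov_mean, mov_sd = _moving_stats(x, win)
    typ_sd = np.median(mov_sd)
    dev = np.abs(x - median_filter(x, size=max(3, win | 1), mode="nearest"))
    if typ_sd == 0:
        typ_sd = np.finfo(float).eps
    mask = (mov_sd > z_thresh * typ_sd) & (dev > spike_amp * typ_sd)
    if not mask.any():
        return x.copy(), mask
    if mask.mean() > 0.5:
        log.warning("motion_correct: >50%% of samples flagged; passing "
                    "series through uncorrected")
        return x.copy(), mask
    good = ~mask
    idx = np.arange(n)
    spline = CubicSpline(idx[good], x[good])
    out = x.copy()
    interp = spline(idx[mask])
    out[mask] = np.clip(interp, x[good].min(), x[good].max())
    return out, mask


def bandpass(x: np.ndarray, fs_hz: float, low: float = 0.01,
             high: float = 0.20, order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    if not (0 < low < high < fs_hz / 2):
        raise ConfigurationError("band must satisfy 0 < low < high < fs/2")
    sos = sg.butter(order, [low, high], btype="bandpass", fs=fs_hz,
                    output="sos")
    return sg.sosfiltfilt(sos, np.asarray(x, float), axis=-1)


def mbll_invert(od: np.ndarray, constants: MbllConstants
                ) -> tuple[np.ndarray, np.ndarray]:
    """Invert two-wavelength delta-OD to (dHbO, dHbR) concentration changes."""
    return constants.invert(od)


def zscore_by_rest(hemo: HemoSeries, min_rest_s: float = 30.0) -> HemoSeries:
    """Z-score each channel against its resting-segment mean and SD.

    Channels with (numerically) zero rest SD are flagged bad and zeroed.
    Re-z-scoring an already z-scored series is rejected.
    """
    if hemo.zscored:
        raise InputError("series is already z-scored")
    if "rest" not in hemo.segments:
        raise InputError("no rest segment")
    sl = hemo.segment_slice("rest")
    if (sl.stop - sl.start) / hemo.fs_hz < min_rest_s:
        raise InputError(f"rest segment shorter than {min_rest_s} s")

    def _z(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        rest = arr[:, sl]
        mu = rest.mean(axis=1, keepdims=True)
        sd = rest.std(axis=1, ddof=0, keepdims=True)
        bad = sd[:, 0] <= 0
        sd_safe = np.where(sd > 0, sd, 1.0)
        z = (arr - mu) / sd_safe
        z[bad] = 0.0
        return z, bad

    zo, bad_o = _z(hemo.hbo)
    zr, bad_r = _z(hemo.hbr)
    bad = tuple(sorted(set(np.flatnonzero(bad_o)) | set(np.flatnonzero(bad_r))
                       | set(hemo.bad_channels)))
    if bad:
        log.warning("zscore_by_rest: flagged bad channels %s", bad)
    return HemoSeries(fs_hz=hemo.fs_hz, hbo=zo, hbr=zr,
                      segments=dict(hemo.segments), zscored=True,
                      bad_channels=bad, subject_id=hemo.subject_id)


def preprocess_recording(rec: OpticalRecording,
                         constants: MbllConstants | None = None,
                         motion: bool = True,
                         band: tuple[float, float] | None = (0.01, 0.20),
                         zscore: bool = True,
                         motion_params: dict | None = None) -> HemoSeries:
    """Full chain: motion (OD) -> MBLL -> rest z-score -> band-pass."""
    if constants is None:
        constants = MbllConstants(wavelengths_nm=rec.wavelengths_nm,
                                  pathlength_cm=rec.sd_separation_cm)
    od = rec.od
    if motion:
        mp = motion_params or {}
        od = od.copy()
        flat = od.reshape(-1, od.shape[-1])
        for i in range(flat.shape[0]):
            flat[i], _ = motion_correct(flat[i], rec.fs_hz, **mp)
    hbo, hbr = constants.invert(od)
    hemo = HemoSeries(fs_hz=rec.fs_hz, hbo=hbo, hbr=hbr,
                      segments=dict(rec.segments), zscored=False,
                      subject_id=rec.subject_id)
    if zscore:
        hemo = zscore_by_rest(hemo)
    if band is not None:
        hemo.hbo = bandpass(hemo.hbo, rec.fs_hz, *band)
        hemo.hbr = bandpass(hemo.hbr, rec.fs_hz, *band)
        if hemo.bad_channels:
            hemo.hbo[list(hemo.bad_channels)] = 0.0
            hemo.hbr[list(hemo.bad_channels)] = 0.0
    if not (np.isfinite(hemo.hbo).all() and np.isfinite(hemo.hbr).all()):
        raise InputError("non-finite values after preprocessing")
    return hemo


class MotionCorrector:
    """Transformer-style wrapper around :func:`motion_correct`."""

    def __init__(self, fs_hz: float, window_s: float = 1.0,
                 z_thresh: float = 5.0, spike_amp: float = 5.0):
        self.fs_hz = fs_hz
        self.window_s = window_s
        self.z_thresh = z_thresh
        self.spike_amp = spike_amp

    def fit(self, X, y=None):
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        out = np.empty_like(X)
        masks = np.zeros(X.shape, bool)
        for i, row in enumerate(X):
            out[i], masks[i] = motion_correct(row, self.fs_hz, self.window_s,
                                              self.z_thresh, self.spike_amp)
        self.mask_ = masks
        return out


class BandpassFilter:
    def __init__(self, fs_hz: float, low: float = 0.01, high: float = 0.20,
                 order: int = 3):
        self.fs_hz, self.low, self.high, self.order = fs_hz, low, high, order

    def fit(self, X, y=None):
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return bandpass(X, self.fs_hz, self.low, self.high, self.order)
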