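"""Epoching, the fixed filter chain, and the two artifact-removal strategies.

The recording is epoched into non-overlapping 6-s segments after a 10-s
discard.  Each epoch then passes through a 50 Hz notch, a fourth-order
Butterworth band-stop (60-100 Hz) and a linear-phase FIR band-pass at the
band edges, all applied zero-phase.  Two alternative cleaners are available:

* ASR (artifact subspace reconstruction): eigenspace variance thresholding of
  0.5-s sliding windows (50% overlap) against mean eigenvalue + cutoff x SD
  of eigenvalues (cutoff 5), with flagged windows reconstructed in a reduced
  subspace that retains at least ``floor(maxdims * n_channels)`` dimensions.
* ICA: FastICA decomposition with rejection of components whose
  |excess kurtosis| exceeds 1.25 or whose peak amplitude exceeds 4 component
  standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import FastICA

from .cohort import Recording


@dataclass
class BandDefinition:
    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise ValueError("require 0 < lo < hi")


#: Canonical band table (Hz).
BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 0.5, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 13.0),
    "beta": BandDefinition("beta", 13.0, 30.0),
    "gamma": BandDefinition("gamma", 30.0, 60.0),
    "full": BandDefinition("full", 0.5, 60.0),
}


@dataclass
class Epoch:
    """One fixed-length segment of a recording (channels x samples, µV)."""

    data: np.ndarray
    fs: float
    index: int                       # 1-based epoch index
    band: str | None = None
    subject_id: str = ""
    group: str = ""
    state: str = ""

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def epoch_recording(
    rec: Recording,
    discard_s: float = 10.0,
    epoch_s: float = 6.0,
    analysis_s: float = 240.0,
) -> list[Epoch]:
    """Cut contiguous non-overlapping epochs starting after the discard.

    Defaults reproduce the study layout: discard the first 10 s, analyze the
    next 240 s as 40 epochs of 6 s.
    """
    required = discard_s + analysis_s
    if rec.duration_s + 1e-9 < required:
        raise ValueError(
            f"recording of {rec.duration_s:.1f} s too short: needs "
            f"{required:.1f} s (discard {discard_s} s + analysis {analysis_s} s)"
        )
    fs = rec.fs
    n_epochs = int(np.floor(analysis_s / epoch_s))
    samp_per = int(round(epoch_s * fs))
    start = int(round(discard_s * fs))
    epochs = []
    for i in range(n_epochs):
        sl = rec.data[:, start + i * samp_per: start + (i + 1) * samp_per]
        epochs.append(Epoch(sl.copy(), fs, i + 1, None,
                            rec.subject_id, rec.group, rec.state))
    return epochs


# ---------------------------------------------------------------------------
# filter chain
# ---------------------------------------------------------------------------

def design_fir_bandpass(
    lo: float, hi: float, fs: float, n_samples: int,
    stop_atten_db: float = 80.0,
) -> np.ndarray:
    """Kaiser-window linear-phase FIR band-pass at the band edges.

    Transition bandwidth is 25% of the lower edge with a 1 Hz floor.  The tap
    count is capped at a third of the segment length so that zero-phase
    application on a 6-s epoch stays well-posed; for the lowest bands the
    realized transition is correspondingly wider.
    """
    transition = max(1.0, 0.25 * lo)
    numtaps, beta = sps.kaiserord(stop_atten_db, transition / (0.5 * fs))
    numtaps = min(numtaps, max(33, n_samples // 3))
    if numtaps % 2 == 0:
        numtaps += 1
    return sps.firwin(numtaps, [lo, hi], pass_zero=False,
                      window=("kaiser", beta), fs=fs)


def _zero_phase(b, a, x: np.ndarray) -> np.ndarray:
    padlen = min(3 * (max(len(np.atleast_1d(b)), len(np.atleast_1d(a))) - 1),
                 x.shape[-1] - 1)
    return sps.filtfilt(b, a, x, axis=-1, padlen=padlen)


def apply_filter_chain(ep: Epoch, band: BandDefinition,
                       notch_freq: float = 50.0, notch_q: float = 35.0,
                       stop_band: tuple[float, float] = (60.0, 100.0)) -> Epoch:
    """Notch -> Butterworth band-stop -> FIR band-pass, all zero-phase."""
    nyq = ep.fs / 2.0
    if band.hi >= nyq:
        raise ValueError(f"band upper edge {band.hi} Hz >= Nyquist {nyq} Hz")
    x = ep.data
    b, a = sps.iirnotch(notch_freq, notch_q, fs=ep.fs)
    x = _zero_phase(b, a, x)
    if stop_band[1] < nyq:
        sos = sps.butter(4, stop_band, btype="bandstop", fs=ep.fs, output="sos")
        padlen = min(3 * 2 * sos.shape[0], x.shape[-1] - 1)
        x = sps.sosfiltfilt(sos, x, axis=-1, padlen=padlen)
    fir = design_fir_bandpass(band.lo, band.hi, ep.fs, ep.n_samples)
    x = _zero_phase(fir, 1.0, x)
    return replace(ep, data=x, band=band.name)


class FilterChain(BaseEstimator, TransformerMixin):
    """sklearn-style wrapper around :func:`apply_filter_chain`."""

    def __init__(self, band: str = "full", notch_freq: float = 50.0,
                 notch_q: float = 35.0,
                 stop_band: tuple[float, float] = (60.0, 100.0)):
        self.band = band
        self.notch_freq = notch_freq
        self.notch_q = notch_q
        self.stop_band = stop_band

    def fit(self, X, y=None):
        return self

    def transform(self, X: list[Epoch]) -> list[Epoch]:
        band = BANDS[self.band] if isinstance(self.band, str) else self.band
        return [apply_filter_chain(ep, band, self.notch_freq, self.notch_q,
                                   self.stop_band) for ep in X]


# ---------------------------------------------------------------------------
# ASR
# ---------------------------------------------------------------------------

def asr_clean(
    data: np.ndarray,
    fs: float,
    cutoff: float = 5.0,
    window_s: float = 0.5,
    overlap: float = 0.5,
    maxdims: float = 0.66,
    mode: str = "multichannel",
) -> tuple[np.ndarray, dict]:
    """Artifact subspace reconstruction of one epoch.

    The epoch covariance is eigendecomposed once; sliding windows whose
    per-component variance exceeds ``mean(eig) + cutoff * std(eig)`` are
    reconstructed with the offending high-variance components projected out
    (never dropping below ``floor(maxdims * n_channels)`` retained
    dimensions).  Corrections are blended in with a raised-cosine taper so
    unflagged samples are untouched.  ``mode="per_channel"`` applies a
    channel-wise variant that thresholds window variances against a robust
    (median/MAD) center and scale and rescales flagged windows instead.
    """
    data = np.asarray(data, dtype=float)
    n_ch, n_samp = data.shape
    w = int(round(window_s * fs))
    hop = max(1, int(round(w * (1.0 - overlap))))
    if n_samp < w:
        return data.copy(), {"flagged_windows": [], "n_windows": 0}
    starts = list(range(0, n_samp - w + 1, hop))
    taper = np.hanning(w)

    out = data.copy()
    flagged = []

    if mode == "per_channel":
        # robust center/scale: a lone burst must not inflate its own threshold
        for ch in range(n_ch):
            win_vars = np.array([np.var(data[ch, s:s + w]) for s in starts])
            center = np.median(win_vars)
            scale = 1.4826 * np.median(np.abs(win_vars - center))
            thr = center + cutoff * scale
            for wi, s in enumerate(starts):
                if win_vars[wi] > thr and win_vars[wi] > 0:
                    scale = np.sqrt(thr / win_vars[wi])
                    delta = (scale - 1.0) * data[ch, s:s + w]
                    out[ch, s:s + w] += delta * taper
                    flagged.append((wi, ch))
        return out, {"flagged_windows": sorted(set(i for i, _ in flagged)),
                     "n_windows": len(starts)}

    cov = np.cov(data)
    eigvals, eigvecs = np.linalg.eigh(cov)
    thr = eigvals.mean() + cutoff * eigvals.std()
    keep_min = int(np.floor(maxdims * n_ch))
    for wi, s in enumerate(starts):
        seg = data[:, s:s + w]
        y = eigvecs.T @ seg
        comp_var = np.mean(y**2, axis=1)
        over = np.where(comp_var > thr)[0]
        if over.size == 0:
            continue
        flagged.append(wi)
        max_remove = n_ch - keep_min
        if over.size > max_remove:
            order = over[np.argsort(comp_var[over])[::-1]]
            over = order[:max_remove]
        y_clean = y.copy()
        y_clean[over] = 0.0
        delta = eigvecs @ y_clean - seg
        out[:, s:s + w] += delta * taper[None, :]
    return out, {"flagged_windows": flagged, "n_windows": len(starts)}


class ASRCleaner(BaseEstimator, TransformerMixin):
    """Per-epoch ASR as a transformer over lists of epochs."""

    def __init__(self, cutoff: float = 5.0, window_s: float = 0.5,
                 overlap: float = 0.5, maxdims: float = 0.66,
                 mode: str = "multichannel"):
        self.cutoff = cutoff
        self.window_s = window_s
        self.overlap = overlap
        self.maxdims = maxdims
        self.mode = mode

    def fit(self, X, y=None):
        return self

    def transform(self, X: list[Epoch]) -> list[Epoch]:
        out = []
        self.logs_ = []
        for ep in X:
            cleaned, log = asr_clean(ep.data, ep.fs, self.cutoff,
                                     self.window_s, self.overlap,
                                     self.maxdims, self.mode)
            self.logs_.append(log)
            out.append(replace(ep, data=cleaned))
        return out


# ---------------------------------------------------------------------------
# ICA
# ---------------------------------------------------------------------------

def ica_clean(
    data: np.ndarray,
    kurtosis_thresh: float = 1.25,
    amp_thresh_sd: float = 4.0,
    seed: int = 0,
    max_retries: int = 5,
    max_iter: int = 1000,
    tol: float = 0.05,
) -> tuple[np.ndarray, int]:
    """FastICA decomposition with kurtosis / amplitude component rejection.

    Components with |excess kurtosis| above the threshold or with a peak
    amplitude above ``amp_thresh_sd`` component standard deviations are
    zeroed before back-projection.  Returns the cleaned data and the number
    of rejected components.  Deterministic given ``seed``; retries with a new
    seed on non-convergence.
    """
    import warnings

    data = np.asarray(data, dtype=float)
    n_ch = data.shape[0]
    if n_ch < 2:
        raise ValueError("ICA requires at least 2 channels")
    last_err: Exception | None = None
    for attempt in range(max_retries):
        ica = FastICA(n_components=n_ch, whiten="unit-variance",
                      random_state=seed + attempt, max_iter=max_iter, tol=tol)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            sources = ica.fit_transform(data.T)           # samples x comps
        converged = not any("did not converge" in str(c.message).lower()
                            for c in caught)
        if converged:
            break
        last_err = RuntimeError("FastICA did not converge")
    else:
        raise RuntimeError(
            f"FastICA failed to converge after {max_retries} seeds") from last_err

    kurt = spstats.kurtosis(sources, axis=0, fisher=True)
    sd = sources.std(axis=0)
    peak = np.max(np.abs(sources - sources.mean(axis=0)), axis=0)
    reject = (np.abs(kurt) > kurtosis_thresh) | (peak > amp_thresh_sd * np.maximum(sd, 1e-30))
    cleaned_sources = sources.copy()
    cleaned_sources[:, reject] = 0.0
    recon = cleaned_sources @ ica.mixing_.T + ica.mean_
    return recon.T, int(reject.sum())


class ICACleaner(BaseEstimator, TransformerMixin):
    def __init__(self, kurtosis_thresh: float = 1.25, amp_thresh_sd: float = 4.0,
                 seed: int = 0, max_retries: int = 5, max_iter: int = 1000,
                 tol: float = 0.05):
        self.kurtosis_thresh = kurtosis_thresh
        self.amp_thresh_sd = amp_thresh_sd
        self.seed = seed
        self.max_retries = max_retries
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None):
        return self

    def transform(self, X: list[Epoch]) -> list[Epoch]:
        out = []
        self.rejected_counts_ = []
        for i, ep in enumerate(X):
            cleaned, n_rej = ica_clean(ep.data, self.kurtosis_thresh,
                                       self.amp_thresh_sd,
                                       seed=self.seed + 17 * i,
                                       max_retries=self.max_retries,
                                       max_iter=self.max_iter, tol=self.tol)
            self.rejected_counts_.append(n_rej)
            out.append(replace(ep, data=cleaned))
        return out


def power_ratio(clean: Epoch | np.ndarray, raw: Epoch | np.ndarray) -> np.ndarray:
    """Per-channel mean-square power ratio clean / raw (NaN where raw is flat)."""
    c = clean.data if isinstance(clean, Epoch) else np.asarray(clean)
    r = raw.data if isinstance(raw, Epoch) else np.asarray(raw)
    if c.shape != r.shape:
        raise ValueError("clean and raw epochs must have the same shape")
    p_raw = np.mean(r**2, axis=-1)
    p_clean = np.mean(c**2, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(p_raw > 0, p_clean / p_raw, np.nan)
    return ratio
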