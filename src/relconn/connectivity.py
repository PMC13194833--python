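"""Per-epoch, per-band connectivity estimators: DTF, iCOH and wPLI.

DTF is derived from a BIC-selected MVAR model of the broadband epoch: the
transfer matrix ``H(f) = [I - sum_k A_k e^{-i 2 pi f k / fs}]^{-1}`` is
evaluated on a fixed frequency grid and the directed transfer function

    DTF_{j->i}(f) = |H_ij(f)|^2 / sum_k |H_ik(f)|^2

is averaged over the band's frequency bins.  The sink-row normalization makes
inflows into every channel sum to one at each bin.

iCOH and wPLI come from Welch-averaged cross-spectra (1-s Hann segments, 50%
overlap within each epoch):

    iCOH_ij(f) = | Im( S_ij / sqrt(S_ii S_jj) ) |
    wPLI_ij(f) = | E[Im S_ij] | / E[ |Im S_ij| ]

with the wPLI expectation taken over the Welch segments of the epoch.  Both
are symmetric with zero diagonal and insensitive to zero-lag (volume
conducted) coupling, whose cross-spectrum is purely real.

Connectivity matrices use the adjacency convention ``W[i, j]`` = strength of
the directed edge i -> j (source row, sink column).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocessing import BANDS, BandDefinition, Epoch


@dataclass
class MVARModel:
    """Least-squares MVAR(p) fit with BIC and stability bookkeeping."""

    order: int
    coeffs: np.ndarray            # (p, n, n); x_t = sum_k A_k x_{t-k} + e_t
    noise_cov: np.ndarray
    bic: float
    stable: bool


@dataclass
class TransferMatrix:
    H: np.ndarray                 # (n_freqs, n, n) complex
    freqs: np.ndarray


@dataclass
class CrossSpectrum:
    S: np.ndarray                 # (n_freqs, n, n) complex, Hermitian per bin
    freqs: np.ndarray
    n_segments: int


@dataclass
class ConnectivityMatrix:
    W: np.ndarray                 # (n, n) weights; W[i, j] = edge i -> j
    directed: bool
    measure: str                  # DTF | iCOH | wPLI
    band: str
    epoch_index: int = 0


def default_freq_grid(lo: float = 0.5, hi: float = 60.0,
                      step: float = 0.5) -> np.ndarray:
    """Frequency grid for H(f) evaluation (0.5 Hz spacing by default)."""
    return np.arange(lo, hi + step / 2, step)


def _band_bins(freqs: np.ndarray, band: BandDefinition) -> np.ndarray:
    mask = (freqs >= band.lo) & (freqs < band.hi)
    if not mask.any():
        raise ValueError(f"band {band.name} [{band.lo}, {band.hi}) Hz has no "
                         "bins on the frequency grid")
    return mask


# ---------------------------------------------------------------------------
# MVAR fitting
# ---------------------------------------------------------------------------

def _companion_radius(A: np.ndarray) -> float:
    p, n, _ = A.shape
    comp = np.zeros((n * p, n * p))
    comp[:n, :] = np.concatenate(list(A), axis=1)
    if p > 1:
        comp[n:, :-n] = np.eye(n * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def fit_mvar(ep: Epoch | np.ndarray, p_min: int = 1, p_max: int = 30,
             rank_tol: float = 1e-8) -> MVARModel:
    """Fit MVAR models for orders p_min..p_max and return the BIC minimizer.

    All candidate orders are fitted by least squares on the common sample span
    starting at ``p_max`` so their BICs are comparable.  BIC uses the residual
    covariance log-determinant with the standard ``p n^2 log N`` parameter
    penalty.  Unstable candidates (companion spectral radius >= 1) are
    excluded; if no candidate is stable an error reports the radii.

    Rank-deficient epochs (as produced e.g. by component rejection during
    cleaning) are handled by fitting in the principal subspace spanned by
    directions whose singular value exceeds ``rank_tol`` times the leading
    one; coefficients are mapped back to channel space, which leaves the
    transfer matrix and DTF well defined.
    """
    X = ep.data if isinstance(ep, Epoch) else np.asarray(ep, dtype=float)
    X = X - X.mean(axis=1, keepdims=True)
    n_ch, n_samp = X.shape
    if n_samp <= p_max * n_ch:
        raise ValueError("epoch too short for the requested maximum order")

    U, sv, _ = np.linalg.svd(X, full_matrices=False)
    r = int(np.sum(sv > rank_tol * sv[0]))
    P = U[:, :r]                                         # (n, r), orthonormal
    Xs = P.T @ X if r < n_ch else X
    n_fit = Xs.shape[0]

    N = n_samp - p_max
    Y = Xs[:, p_max:].T                                  # (N, r)
    lags = [Xs[:, p_max - k: n_samp - k].T for k in range(1, p_max + 1)]

    best: MVARModel | None = None
    radii: dict[int, float] = {}
    for p in range(p_min, p_max + 1):
        Z = np.concatenate(lags[:p], axis=1)             # (N, r*p)
        B, *_ = np.linalg.lstsq(Z, Y, rcond=None)        # (r*p, r)
        resid = Y - Z @ B
        sigma = resid.T @ resid / N
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            continue
        bic = N * logdet + p * n_fit**2 * np.log(N)
        A = B.T.reshape(n_fit, p, n_fit).transpose(1, 0, 2)
        radius = _companion_radius(A)
        radii[p] = radius
        if radius >= 1.0:
            continue
        if best is None or bic < best.bic:
            best = MVARModel(p, A, sigma, bic, True)
    if best is None:
        raise ValueError(
            "no stable MVAR candidate in range "
            f"p={p_min}..{p_max}; spectral radii: "
            + ", ".join(f"p={p}: {r:.3f}" for p, r in radii.items()))
    if r < n_ch:
        best = MVARModel(
            best.order,
            np.einsum("ia,kab,jb->kij", P, best.coeffs, P),
            P @ best.noise_cov @ P.T, best.bic, best.stable)
    return best


def transfer_matrix(m: MVARModel, freqs: np.ndarray, fs: float) -> TransferMatrix:
    """H(f) = [I - sum_k A_k exp(-i 2 pi f k / fs)]^{-1} on the grid."""
    if not m.stable:
        raise ValueError("transfer matrix requires a stable model")
    freqs = np.asarray(freqs, dtype=float)
    p, n, _ = m.coeffs.shape
    k = np.arange(1, p + 1)
    # phase[f, k] = exp(-i 2 pi f k / fs)
    phase = np.exp(-2j * np.pi * np.outer(freqs, k) / fs)
    Af = np.tensordot(phase, m.coeffs, axes=(1, 0))      # (nf, n, n)
    I = np.eye(n)
    H = np.empty_like(Af)
    for fi in range(len(freqs)):
        M = I - Af[fi]
        try:
            H[fi] = np.linalg.inv(M)
        except np.linalg.LinAlgError as err:
            raise ValueError(
                f"singular spectral matrix at bin {fi} "
                f"(f = {freqs[fi]:.3g} Hz)") from err
    return TransferMatrix(H, freqs)


def dtf(H: TransferMatrix, band: BandDefinition,
        epoch_index: int = 0) -> ConnectivityMatrix:
    """Band-averaged directed transfer function.

    ``W[j, i] = mean_f |H_ij(f)|^2 / sum_k |H_ik(f)|^2`` so inflow into each
    sink i sums to one at every bin.  The diagonal (self-inflow) is part of
    the normalization but is excluded from network edges downstream.
    """
    mask = _band_bins(H.freqs, band)
    mag2 = np.abs(H.H[mask]) ** 2                        # (nb, sink, source)
    denom = mag2.sum(axis=2, keepdims=True)
    if np.any(denom == 0):
        raise ValueError("all-zero transfer row: DTF undefined")
    D = mag2 / denom                                     # D[f, i, j] = DTF_{j->i}
    W = D.mean(axis=0).T                                 # W[source, sink]
    return ConnectivityMatrix(W, True, "DTF", band.name, epoch_index)


def dtf_spectrum(H: TransferMatrix) -> np.ndarray:
    """Per-bin DTF array ``D[f, i, j] = DTF_{j->i}(f)`` (for normalization checks)."""
    mag2 = np.abs(H.H) ** 2
    return mag2 / mag2.sum(axis=2, keepdims=True)


def analytic_dtf(coeffs: np.ndarray, fs: float, band: BandDefinition,
                 freqs: np.ndarray | None = None) -> np.ndarray:
    """Closed-form band DTF of a known coefficient stack (ground-truth oracle)."""
    if freqs is None:
        freqs = default_freq_grid()
    model = MVARModel(coeffs.shape[0], np.asarray(coeffs, dtype=float),
                      np.eye(coeffs.shape[1]), 0.0, True)
    return dtf(transfer_matrix(model, freqs, fs), band).W


# ---------------------------------------------------------------------------
# cross-spectra
# ---------------------------------------------------------------------------

def _segment_ffts(X: np.ndarray, fs: float, seg_s: float,
                  overlap: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment windowed rFFTs: returns (n_seg, n_ch, n_freqs) and freqs."""
    n_ch, n_samp = X.shape
    nper = int(round(seg_s * fs))
    hop = max(1, int(round(nper * (1.0 - overlap))))
    starts = range(0, n_samp - nper + 1, hop)
    if len(starts) == 0:
        raise ValueError(
            f"epoch of {n_samp} samples yields no {seg_s}-s Welch segment")
    win = np.hanning(nper)
    segs = np.stack([X[:, s:s + nper] for s in starts])
    segs = (segs - segs.mean(axis=2, keepdims=True)) * win[None, None, :]
    F = np.fft.rfft(segs, axis=2)
    freqs = np.fft.rfftfreq(nper, 1.0 / fs)
    # one-sided spectral density scaling (Parseval-consistent)
    scale = 1.0 / (fs * np.sum(win**2))
    F = F * np.sqrt(scale)
    return F, freqs


def cross_spectrum(ep: Epoch | np.ndarray, fs: float | None = None,
                   seg_s: float = 1.0, overlap: float = 0.5,
                   return_segments: bool = False):
    """Welch-averaged cross-spectral density of one epoch.

    Hermitian at every bin by construction.  With ``return_segments=True`` a
    list of single-segment :class:`CrossSpectrum` objects is returned as well
    (the wPLI expectation is taken over these).
    """
    if isinstance(ep, Epoch):
        X, fs = ep.data, ep.fs
    else:
        X = np.asarray(ep, dtype=float)
        if fs is None:
            raise ValueError("fs required for array input")
    F, freqs = _segment_ffts(X, fs, seg_s, overlap)
    n_seg = F.shape[0]
    if n_seg < 2:
        raise ValueError(
            f"epoch yields {n_seg} Welch segment(s); need >= 2 "
            "(wPLI undefined otherwise)")
    # S_seg[s, f, i, j] = F_i F_j^*
    S_seg = np.einsum("sif,sjf->sfij", F, np.conj(F))
    # double all bins but DC/Nyquist for one-sided density
    w = np.full(len(freqs), 2.0)
    w[0] = 1.0
    if X.shape[1] % 2 == 0:
        w[-1] = 1.0
    S_seg *= w[None, :, None, None]
    S = S_seg.mean(axis=0)
    cs = CrossSpectrum(S, freqs, n_seg)
    if return_segments:
        seg_list = [CrossSpectrum(S_seg[s], freqs, 1) for s in range(n_seg)]
        return cs, seg_list
    return cs


def icoh(S: CrossSpectrum, band: BandDefinition,
         epoch_index: int = 0) -> ConnectivityMatrix:
    """Band-mean |imaginary coherency|; symmetric, zero diagonal."""
    mask = _band_bins(S.freqs, band)
    Sb = S.S[mask]
    auto = np.real(np.einsum("fii->fi", Sb))
    if np.any(auto <= 0):
        raise ValueError("zero auto-spectrum: coherency undefined")
    denom = np.sqrt(auto[:, :, None] * auto[:, None, :])
    C = Sb / denom
    W = np.abs(np.imag(C)).mean(axis=0)
    np.fill_diagonal(W, 0.0)
    W = (W + W.T) / 2.0
    return ConnectivityMatrix(W, False, "iCOH", band.name, epoch_index)


def coherence_magnitude(S: CrossSpectrum, band: BandDefinition) -> np.ndarray:
    """Band-mean |coherency| (volume-conduction-sensitive reference measure)."""
    mask = _band_bins(S.freqs, band)
    Sb = S.S[mask]
    auto = np.real(np.einsum("fii->fi", Sb))
    denom = np.sqrt(auto[:, :, None] * auto[:, None, :])
    W = np.abs(Sb / denom).mean(axis=0)
    np.fill_diagonal(W, 0.0)
    return W


def wpli(S_per_segment: list[CrossSpectrum], band: BandDefinition,
         epoch_index: int = 0, debias: bool = False) -> ConnectivityMatrix:
    """Weighted phase lag index over within-epoch Welch segments.

    ``wPLI_ij = |mean_s Im S_ij^(s)| / mean_s |Im S_ij^(s)|`` per bin, then
    band-averaged; pairs whose imaginary cross-spectrum vanishes in every
    segment are set to 0.  The debiased variant subtracts the squared-term
    bias of the numerator (Vinck-style) when requested.
    """
    if len(S_per_segment) < 2:
        raise ValueError("wPLI requires at least 2 segments")
    freqs = S_per_segment[0].freqs
    mask = _band_bins(freqs, band)
    imS = np.stack([np.imag(s.S[mask]) for s in S_per_segment])  # (s, f, i, j)
    num = np.abs(imS.sum(axis=0))
    den = np.abs(imS).sum(axis=0)
    if debias:
        sq = (imS**2).sum(axis=0)
        num2 = num**2 - sq
        den2 = den**2 - sq
        with np.errstate(divide="ignore", invalid="ignore"):
            Wf = np.where(den2 > 0, num2 / den2, 0.0)
        Wf = np.clip(Wf, 0.0, None)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            Wf = np.where(den > 0, num / den, 0.0)
    W = Wf.mean(axis=0)
    np.fill_diagonal(W, 0.0)
    W = (W + W.T) / 2.0
    return ConnectivityMatrix(W, False, "wPLI", band.name, epoch_index)


def wpli_from_epoch(ep: Epoch | np.ndarray, band: BandDefinition,
                    fs: float | None = None, seg_s: float = 1.0,
                    overlap: float = 0.5, **kw) -> ConnectivityMatrix:
    _, segs = cross_spectrum(ep, fs=fs, seg_s=seg_s, overlap=overlap,
                             return_segments=True)
    idx = ep.index if isinstance(ep, Epoch) else 0
    return wpli(segs, band, epoch_index=idx, **kw)


# ---------------------------------------------------------------------------
# estimator classes
# ---------------------------------------------------------------------------

class DTFEstimator(BaseEstimator, TransformerMixin):
    """Directed transfer function from BIC-selected MVAR fits.

    ``transform`` maps a list of broadband epochs to a dict
    ``{band_name: [ConnectivityMatrix, ...]}``; band selectivity is explicit
    in the frequency grid, so no per-band filtering is performed.
    """

    def __init__(self, bands: tuple[str, ...] = ("full",), p_min: int = 1,
                 p_max: int = 30, freq_step: float = 0.5):
        self.bands = bands
        self.p_min = p_min
        self.p_max = p_max
        self.freq_step = freq_step

    def fit(self, X, y=None):
        return self

    def transform(self, X: list[Epoch]) -> dict[str, list[ConnectivityMatrix]]:
        out: dict[str, list[ConnectivityMatrix]] = {b: [] for b in self.bands}
        self.orders_ = []
        freqs = default_freq_grid(step=self.freq_step)
        for ep in X:
            model = fit_mvar(ep, self.p_min, self.p_max)
            self.orders_.append(model.order)
            H = transfer_matrix(model, freqs, ep.fs)
            for b in self.bands:
                out[b].append(dtf(H, BANDS[b], epoch_index=ep.index))
        return out


class CoherencyEstimator(BaseEstimator, TransformerMixin):
    """iCOH or wPLI from Welch cross-spectra of broadband epochs."""

    def __init__(self, measure: str = "iCOH", bands: tuple[str, ...] = ("full",),
                 seg_s: float = 1.0, overlap: float = 0.5, debias: bool = False):
        self.measure = measure
        self.bands = bands
        self.seg_s = seg_s
        self.overlap = overlap
        self.debias = debias

    def fit(self, X, y=None):
        return self

    def transform(self, X: list[Epoch]) -> dict[str, list[ConnectivityMatrix]]:
        if self.measure not in ("iCOH", "wPLI"):
            raise ValueError("measure must be 'iCOH' or 'wPLI'")
        out: dict[str, list[ConnectivityMatrix]] = {b: [] for b in self.bands}
        for ep in X:
            S, segs = cross_spectrum(ep, seg_s=self.seg_s, overlap=self.overlap,
                                     return_segments=True)
            for b in self.bands:
                if self.measure == "iCOH":
                    out[b].append(icoh(S, BANDS[b], epoch_index=ep.index))
                else:
                    out[b].append(wpli(segs, BANDS[b], epoch_index=ep.index,
                                       debias=self.debias))
        return out
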