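"""Feature extraction for MMG movement segments.

Four feature families are computed per channel:

* **TD** — ten time-domain statistics (RMS, VAR, ZC, WL, SSC, LOG, MAV,
  v-order, SSI, AAC), the workhorse descriptors of EMG/MMG pattern
  recognition.
* **FD** — mean power frequency and median frequency of the Welch PSD.
* **WE** — wavelet-packet node energies: a 4-level full decomposition yields
  16 terminal bands of width fs/32; the energies of the 11 bands contained
  in the 5-100 Hz passband (7.8125-93.75 Hz at fs = 250) are retained.
* **NLD** — approximate, sample and fuzzy entropy plus normalized
  Lempel-Ziv complexity, regularity measures sensitive to the disorder of
  the contraction.

``build_feature_matrix`` assembles segments x features matrices for
arbitrary channel/family subsets with a deterministic channel-major column
order, giving 27 features per channel (108 for 4 channels, all families).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal
from scipy.spatial.distance import cdist

from .preprocess import LabeledSegment

FAMILY_ORDER = ("TD", "FD", "WE", "NLD")
FAMILY_SIZES = {"TD": 10, "FD": 2, "WE": 11, "NLD": 4}

TD_NAMES = ("RMS", "VAR", "ZC", "WL", "SSC", "LOG", "MAV", "V3", "SSI", "AAC")
FD_NAMES = ("MPF", "MF")
NLD_NAMES = ("AEn", "SEn", "FEn", "LZC")


@dataclass
class FeatureVector:
    """Parallel arrays of feature values and their registry names."""

    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.names):
            raise ValueError("values and names must be parallel")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")


@dataclass
class FeatureMatrix:
    """Segments x features matrix with a name registry and labels."""

    X: np.ndarray
    names: list[str]
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.shape != (len(self.y), len(self.names)):
            raise ValueError("X shape must be (len(y), len(names))")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if not np.isfinite(self.X).all():
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass
class WPTEnergy:
    """Energies of the passband terminal nodes of a wavelet packet tree."""

    node_energies: np.ndarray
    level: int
    band_edges: list[tuple[float, float]]


@dataclass
class FeatureParams:
    """Tunables for the per-channel extractors.

    zc/ssc dead-bands default to 0 (pure sign/slope changes); v-order uses
    v = 3 so it is distinct from RMS; entropies use the field-standard
    m = 2, r = 0.2 x SD; the wavelet is db4.
    """

    zc_threshold: float = 0.0
    ssc_threshold: float = 0.0
    v: float = 3.0
    wavelet: str = "db4"
    wpt_level: int = 4
    entropy_m: int = 2
    entropy_r: float = 0.2
    fuzzy_n: float = 2.0


# --------------------------------------------------------------------------
# time domain
# --------------------------------------------------------------------------

def extract_td(
    x: np.ndarray,
    zc_threshold: float = 0.0,
    ssc_threshold: float = 0.0,
    v: float = 3.0,
) -> FeatureVector:
    """Ten time-domain features of a single-channel segment.

    RMS = sqrt(mean x^2); VAR = unbiased variance; ZC counts sign changes
    whose jump exceeds ``zc_threshold``; WL = total variation
    sum |x[i+1] - x[i]|; SSC counts slope-sign changes whose product of
    successive differences exceeds ``ssc_threshold``; LOG = exp(mean log|x|)
    (|x| floored at machine epsilon); MAV = mean |x|; V{v} = (mean |x|^v)^(1/v);
    SSI = sum x^2; AAC = WL / (n - 1).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("time-domain features need at least 3 samples (SSC)")
    dx = np.diff(x)
    wl = float(np.abs(dx).sum())
    absx = np.abs(x)

    zc = int(np.count_nonzero((x[:-1] * x[1:] < 0) & (np.abs(dx) > zc_threshold)))
    ssc = int(np.count_nonzero(dx[:-1] * -dx[1:] > ssc_threshold))
    log_det = float(np.exp(np.mean(np.log(np.maximum(absx, np.finfo(float).eps)))))

    values = np.array(
        [
            np.sqrt(np.mean(x**2)),           # RMS
            np.var(x, ddof=1),                # VAR
            zc,                               # ZC
            wl,                               # WL
            ssc,                              # SSC
            log_det,                          # LOG
            absx.mean(),                      # MAV
            np.mean(absx**v) ** (1.0 / v),    # v-order
            np.sum(x**2),                     # SSI
            wl / (n - 1),                     # AAC
        ]
    )
    names = [f"V{v:g}" if nm == "V3" else nm for nm in TD_NAMES]
    return FeatureVector(values, names)


# --------------------------------------------------------------------------
# frequency domain
# --------------------------------------------------------------------------

def extract_fd(x: np.ndarray, fs: float) -> FeatureVector:
    """Mean power frequency and median frequency from the Welch PSD.

    MPF is the spectral centroid sum(f P) / sum(P); MF is the smallest
    frequency at which the cumulative power reaches half the total.
    Welch settings: Hann window, segment length min(256, n), 50% overlap.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 16:
        raise ValueError("frequency-domain features need at least 16 samples")
    nperseg = min(256, n)
    f, p = signal.welch(x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2)
    total = p.sum()
    if total <= 0:
        raise ValueError("degenerate input: zero-power signal has no spectrum")
    mpf = float((f * p).sum() / total)
    mf = float(f[np.searchsorted(np.cumsum(p), total / 2.0)])
    return FeatureVector(np.array([mpf, mf]), list(FD_NAMES))


# --------------------------------------------------------------------------
# wavelet packet node energy
# --------------------------------------------------------------------------

def _wpt_node_energy(x: np.ndarray, wavelet: str, level: int) -> np.ndarray:
    """Energy of every frequency-ordered terminal node, by reconstruction.

    Each node's coefficients are placed alone into an empty tree and the
    signal reconstructed; the energy is the sum of squared reconstructed
    amplitudes.  The signal is zero-padded to a multiple of 2^level and
    decomposed with periodized extension, which keeps the transform
    orthogonal: the 2^level node energies then sum to the signal energy to
    machine precision rather than drifting with border effects.
    """
    pad = (-len(x)) % 2**level
    x = np.pad(x, (0, pad))
    wp = pywt.WaveletPacket(data=x, wavelet=wavelet, mode="periodization", maxlevel=level)
    energies = np.empty(2**level)
    for k, node in enumerate(wp.get_level(level, order="freq")):
        solo = pywt.WaveletPacket(
            data=None, wavelet=wavelet, mode="periodization", maxlevel=level
        )
        solo[node.path] = node.data
        recon = solo.reconstruct(update=False)[: len(x)]
        energies[k] = np.sum(recon**2)
    return energies


def passband_nodes(fs: float, level: int, low_hz: float = 5.0, high_hz: float = 100.0):
    """Indices and band edges of terminal nodes contained in [low, high] Hz.

    Frequency-ordered node k at decomposition level L covers
    [k fs / 2^(L+1), (k+1) fs / 2^(L+1)] Hz; a node is kept when its whole
    band lies inside the preprocessing passband.  At fs = 250 and L = 4 this
    keeps the 11 nodes spanning 7.8125-93.75 Hz.
    """
    width = fs / 2 ** (level + 1)
    keep, edges = [], []
    for k in range(2**level):
        lo, hi = k * width, (k + 1) * width
        if lo >= low_hz and hi <= high_hz:
            keep.append(k)
            edges.append((lo, hi))
    return keep, edges


def extract_wpt_energy(
    x: np.ndarray, fs: float, wavelet: str = "db4", level: int = 4
) -> WPTEnergy:
    """Wavelet-packet node energies of the passband terminal nodes."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2**level:
        raise ValueError(f"signal shorter than 2^level = {2**level} samples")
    energies = _wpt_node_energy(x, wavelet, level)
    keep, edges = passband_nodes(fs, level)
    return WPTEnergy(node_energies=energies[keep], level=level, band_edges=edges)


# --------------------------------------------------------------------------
# nonlinear dynamics
# --------------------------------------------------------------------------

def _templates(x: np.ndarray, m: int) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(x, m)


def _tolerance(x: np.ndarray, r: float) -> float:
    return r * float(np.std(x))


def approximate_entropy(x: np.ndarray, m: int = 2, r: float = 0.2) -> float:
    """Approximate entropy (Pincus): Phi_m(r) - Phi_{m+1}(r).

    ``r`` is a fraction of the segment's standard deviation.  Self-matches
    are included, as the statistic requires.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 10 * m:
        raise ValueError("signal too short for reliable entropy (need >= 10 m)")
    tol = _tolerance(x, r)

    def phi(mm: int) -> float:
        t = _templates(x, mm)
        d = cdist(t, t, metric="chebyshev")
        c = (d <= tol).mean(axis=1)
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def sample_entropy(x: np.ndarray, m: int = 2, r: float = 0.2) -> float:
    """Sample entropy (Richman & Moorman): -ln(A/B), self-matches excluded.

    A and B count template pairs within tolerance at lengths m+1 and m,
    both over the first n - m templates.  If no pair matches at m+1 the
    statistic is unbounded; the match count's log ``ln(B)`` is returned as a
    finite ceiling, with a warning.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 10 * m:
        raise ValueError("signal too short for reliable entropy (need >= 10 m)")
    tol = _tolerance(x, r)
    n_t = len(x) - m

    tm = _templates(x, m)[:n_t]
    tm1 = _templates(x, m + 1)
    db = cdist(tm, tm, metric="chebyshev")
    da = cdist(tm1, tm1, metric="chebyshev")
    iu = np.triu_indices(n_t, k=1)
    b = int(np.count_nonzero(db[iu] <= tol))
    iua = np.triu_indices(len(tm1), k=1)
    a = int(np.count_nonzero(da[iua] <= tol))
    if b == 0:
        warnings.warn("sample entropy: no m-length matches; returning 0.0")
        return 0.0
    if a == 0:
        warnings.warn("sample entropy: no (m+1)-length matches; returning ln(B) ceiling")
        return float(np.log(b))
    return float(-np.log(a / b))


def fuzzy_entropy(
    x: np.ndarray, m: int = 2, r: float = 0.2, n_exp: float = 2.0
) -> float:
    """Fuzzy entropy (Chen): soft template matching with exponential membership.

    Templates are baseline-removed (their own mean subtracted) and matched
    with membership exp(-(d/r)^n_exp) under the Chebyshev distance d;
    FEn = ln Phi_m - ln Phi_{m+1}.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 10 * m:
        raise ValueError("signal too short for reliable entropy (need >= 10 m)")
    tol = _tolerance(x, r)
    n_t = len(x) - m

    def phi(mm: int) -> float:
        t = _templates(x, mm)[:n_t]
        t = t - t.mean(axis=1, keepdims=True)
        d = cdist(t, t, metric="chebyshev")
        if tol > 0:
            mu = np.exp(-((d / tol) ** n_exp))
        else:  # degenerate constant-like signal: exact ties count as matches
            mu = (d <= 0).astype(float)
        np.fill_diagonal(mu, 0.0)
        return float(mu.sum() / (n_t * (n_t - 1)))

    return float(np.log(phi(m)) - np.log(phi(m + 1)))


def lzc(x: np.ndarray) -> float:
    """Normalized Lempel-Ziv complexity after median binarization.

    The signal is binarized at its median (x > median -> 1), parsed by the
    LZ76 scheme into c(n) distinct phrases, and normalized as
    c(n) log2(n) / n so white noise tends to ~1 and regular signals to ~0.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("LZC needs at least 2 samples")
    s = (x > np.median(x)).astype(np.uint8)
    c = lz76_complexity(s)
    return float(c * np.log2(n) / n)


def lz76_complexity(s: np.ndarray) -> int:
    """Number of distinct phrases in the LZ76 parsing of a symbol sequence."""
    s = np.asarray(s)
    n = len(s)
    c = 1
    ell = 1
    i = 0
    k = 1
    k_max = 1
    while True:
        if s[i + k - 1] == s[ell + k - 1]:
            k += 1
            if ell + k > n:
                c += 1
                break
        else:
            if k > k_max:
                k_max = k
            i += 1
            if i == ell:
                c += 1
                ell += k_max
                if ell + 1 > n:
                    break
                i = 0
                k = 1
                k_max = 1
            else:
                k = 1
    return c


# --------------------------------------------------------------------------
# matrix assembly
# --------------------------------------------------------------------------

def _channel_features(
    x: np.ndarray, fs: float, families: tuple[str, ...], params: FeatureParams
) -> FeatureVector:
    values: list[np.ndarray] = []
    names: list[str] = []
    for family in FAMILY_ORDER:
        if family not in families:
            continue
        if family == "TD":
            fv = extract_td(x, params.zc_threshold, params.ssc_threshold, params.v)
            values.append(fv.values)
            names.extend(f"TD:{nm}" for nm in fv.names)
        elif family == "FD":
            fv = extract_fd(x, fs)
            values.append(fv.values)
            names.extend(f"FD:{nm}" for nm in fv.names)
        elif family == "WE":
            we = extract_wpt_energy(x, fs, params.wavelet, params.wpt_level)
            values.append(we.node_energies)
            names.extend(f"WE:E{lo:g}-{hi:g}Hz" for lo, hi in we.band_edges)
        elif family == "NLD":
            m, r = params.entropy_m, params.entropy_r
            values.append(
                np.array(
                    [
                        approximate_entropy(x, m, r),
                        sample_entropy(x, m, r),
                        fuzzy_entropy(x, m, r, params.fuzzy_n),
                        lzc(x),
                    ]
                )
            )
            names.extend(f"NLD:{nm}" for nm in NLD_NAMES)
    return FeatureVector(np.concatenate(values), names)


def build_feature_matrix(
    segments: list[LabeledSegment],
    fs: float,
    channels: list[int] | None = None,
    families: tuple[str, ...] = FAMILY_ORDER,
    params: FeatureParams | None = None,
) -> FeatureMatrix:
    """Assemble a segments x features matrix for channel/family subsets.

    ``channels`` are 0-based column indices into each segment's data
    (default: all).  Column order is channel-major with family order
    TD, FD, WE, NLD; names follow ``ch{c}:{family}:{feature}`` with 1-based
    channel numbers.

    Raises
    ------
    ValueError
        If no segments are given, an unknown family is requested, or a
        segment yields a non-finite feature (reported by segment and name).
    """
    if not segments:
        raise ValueError("no segments given")
    unknown = set(families) - set(FAMILY_ORDER)
    if unknown:
        raise ValueError(f"unknown feature families: {sorted(unknown)}")
    params = params or FeatureParams()
    n_ch = segments[0].segment.data.shape[1]
    if channels is None:
        channels = list(range(n_ch))
    if any(c < 0 or c >= n_ch for c in channels):
        raise ValueError("channel index out of range")

    rows, labels = [], []
    names: list[str] = []
    for si, ls in enumerate(segments):
        row_vals, row_names = [], []
        for c in channels:
            fv = _channel_features(ls.segment.data[:, c], fs, tuple(families), params)
            row_vals.append(fv.values)
            row_names.extend(f"ch{c + 1}:{nm}" for nm in fv.names)
        row = np.concatenate(row_vals)
        if not np.isfinite(row).all():
            bad = row_names[int(np.flatnonzero(~np.isfinite(row))[0])]
            raise ValueError(f"segment {si} produced non-finite feature {bad}")
        rows.append(row)
        labels.append(ls.label)
        if not names:
            names = row_names
    return FeatureMatrix(X=np.vstack(rows), names=names, y=np.asarray(labels))
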