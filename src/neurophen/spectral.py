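"""Multitaper power spectra and magnitude-squared coherence for LFP pairs.

The estimator follows the standard segmented multitaper scheme: the
recording is cut into 1-s segments, each segment is demeaned and multiplied
by K orthogonal DPSS (Slepian) tapers of time-bandwidth product NW, and the
tapered Fourier transforms are accumulated into auto- and cross-spectra.
Magnitude-squared coherence between channels a and b is

    C_ab(f) = |S_ab(f)|^2 / (S_aa(f) S_bb(f)),   0 <= C_ab <= 1,

with the spectra averaged over all tapers and segments before the ratio is
formed (``average="pooled"``, the default; the per-segment variant that
forms a coherence per segment and averages those is available as
``average="per_segment"`` but carries a ~1/K positive bias under
independence).  PSD is reported in dB as 10*log10 of the taper- and
segment-averaged power, on a 1-Hz grid restricted to 1-90 Hz, with the
canonical frequency-band summaries (delta 1-4, theta 4-12, beta 12-20,
low gamma 20-40, high gamma 40-90 Hz; band edges half-open [low, high),
the last band closed at 90 Hz).

PSD normalisation: tapers are unit-energy, and one-sided powers are scaled
so that the sum of the linear-scale PSD over all FFT bins equals the mean
squared value of the (demeaned) signal — Parseval's identity in discrete
form.  Coherence is invariant to this choice and to any per-channel gain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.fft import rfft, rfftfreq
from scipy.signal.windows import dpss

from .datamodel import LFPRecording

#: Floor applied to linear power before taking the logarithm, to avoid -inf
#: on near-silent bins.  A warning is emitted when it engages.
PSD_FLOOR = 1e-20

#: Canonical LFP frequency bands (Hz), half-open [low, high).
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 12.0),
    "beta": (12.0, 20.0),
    "low_gamma": (20.0, 40.0),
    "high_gamma": (40.0, 90.0),
}


@dataclass(frozen=True)
class BandSet:
    """Ordered, non-overlapping named frequency intervals in Hz.

    Under the half-open convention [low, high) — the final band closed at
    its upper edge — shared edges such as 4, 12, 20 and 40 Hz belong to
    exactly one band.
    """

    bands: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )

    def __post_init__(self) -> None:
        items = list(self.bands.items())
        for name, (lo, hi) in items:
            if not lo < hi:
                raise ValueError(f"band {name!r}: need low < high")
        for (_, (_, hi_prev)), (name, (lo, _)) in zip(items, items[1:]):
            if lo < hi_prev:
                raise ValueError(f"band {name!r} overlaps its predecessor")
        object.__setattr__(self, "bands", dict(items))

    def items(self):
        return self.bands.items()

    @property
    def max_edge(self) -> float:
        return max(hi for _, hi in self.bands.values())


@dataclass(frozen=True)
class SpectralParams:
    """Multitaper estimation parameters.

    ``segment_length`` in seconds (default 1 s, giving a 1-Hz grid),
    ``time_bandwidth`` NW and ``n_tapers`` K with K <= 2*NW - 1 (default
    NW=3, K=5, the Chronux-style default), ``freq_range`` the analysis band
    in Hz, ``overlap`` the fractional overlap between segments (default 0).
    """

    segment_length: float = 1.0
    time_bandwidth: float = 3.0
    n_tapers: int = 5
    freq_range: tuple[float, float] = (1.0, 90.0)
    overlap: float = 0.0
    average: str = "pooled"  # or "per_segment"

    def __post_init__(self) -> None:
        if self.segment_length <= 0:
            raise ValueError("segment_length must be positive")
        if self.n_tapers > 2 * self.time_bandwidth - 1:
            raise ValueError("need n_tapers <= 2*time_bandwidth - 1")
        lo, hi = self.freq_range
        if not 0 <= lo < hi:
            raise ValueError("freq_range must satisfy 0 <= low < high")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")
        if self.average not in ("pooled", "per_segment"):
            raise ValueError("average must be 'pooled' or 'per_segment'")

    def validate_against(self, fs: float) -> None:
        if self.freq_range[1] >= fs / 2:
            raise ValueError(
                f"upper analysis frequency {self.freq_range[1]} Hz requires fs > "
                f"{2 * self.freq_range[1]} Hz, got {fs}"
            )


@dataclass(frozen=True)
class CoherenceSpectrum:
    """A frequency-indexed spectrum with band summaries.

    ``kind`` is "coherence" (values in [0, 1]) or "psd_db".  ``band_means``
    are averages over the in-band grid frequencies; for PSD they are
    computed on the linear scale and then converted to dB.
    """

    freqs: np.ndarray
    values: np.ndarray
    n_segments: int
    kind: str
    band_means: dict[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "freqs", np.asarray(self.freqs, float))
        object.__setattr__(self, "values", np.asarray(self.values, float))
        if self.freqs.shape != self.values.shape:
            raise ValueError("freqs and values must align")


# --------------------------------------------------------------------------
# Segmentation and tapered spectra
# --------------------------------------------------------------------------


def segment(rec: LFPRecording, params: SpectralParams | None = None) -> np.ndarray:
    """Cut a recording into equal demeaned windows.

    Returns an array of shape (n_segments, segment_samples).  With zero
    overlap there are floor(duration / segment_length) windows; the trailing
    remainder is discarded.  Each window is demeaned independently.
    """
    params = params or SpectralParams()
    n_per = int(round(params.segment_length * rec.fs))
    if rec.n_samples < n_per:
        raise ValueError(
            f"recording of {rec.duration:.3f} s is shorter than one "
            f"{params.segment_length} s segment"
        )
    step = max(1, int(round(n_per * (1.0 - params.overlap))))
    starts = range(0, rec.n_samples - n_per + 1, step)
    wins = np.stack([rec.samples[s : s + n_per] for s in starts])
    return wins - wins.mean(axis=1, keepdims=True)


def _tapered_ffts(windows: np.ndarray, params: SpectralParams) -> np.ndarray:
    """rFFT of each window under each unit-energy DPSS taper.

    Shape: (n_segments, n_tapers, n_freqs).
    """
    n = windows.shape[1]
    tapers = dpss(n, params.time_bandwidth, Kmax=params.n_tapers)  # (K, n), unit energy
    return rfft(windows[:, None, :] * tapers[None, :, :], axis=-1)


def _grid_mask(n: int, fs: float, freq_range: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    freqs = rfftfreq(n, d=1.0 / fs)
    lo, hi = freq_range
    mask = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
    return freqs, mask


def _onesided_scale(n: int, n_freqs: int) -> np.ndarray:
    """Scale so the one-sided power sum equals the mean-square of the window."""
    scale = np.full(n_freqs, 2.0 / n)
    scale[0] = 1.0 / n
    if n % 2 == 0:
        scale[-1] = 1.0 / n  # Nyquist bin is not doubled
    return scale


# --------------------------------------------------------------------------
# PSD
# --------------------------------------------------------------------------


def mt_psd(
    rec: LFPRecording,
    params: SpectralParams | None = None,
    bands: BandSet | None = None,
) -> CoherenceSpectrum:
    """Multitaper PSD of one channel, in dB, with band summaries.

    Per segment and taper the raw power |F(x*w)|^2 is formed; powers are
    averaged over tapers then segments, scaled to the one-sided
    Parseval-consistent convention, restricted to ``freq_range``, and
    reported as 10*log10.  Band means are linear-scale averages converted
    to dB.  Raises on an all-zero signal rather than returning -inf.
    """
    params = params or SpectralParams()
    bands = bands or BandSet()
    params.validate_against(rec.fs)
    wins = segment(rec, params)
    if not np.any(wins):
        raise ValueError("degenerate signal: zero power in every segment")
    X = _tapered_ffts(wins, params)
    power = (np.abs(X) ** 2).mean(axis=(0, 1))  # average tapers then segments
    n = wins.shape[1]
    freqs, mask = _grid_mask(n, rec.fs, params.freq_range)
    power = power * _onesided_scale(n, freqs.size)

    linear = power[mask]
    if np.any(linear < PSD_FLOOR):
        warnings.warn(
            "PSD floor engaged on near-silent bins; dB values there are clipped",
            RuntimeWarning,
            stacklevel=2,
        )
        linear = np.maximum(linear, PSD_FLOOR)
    values_db = 10.0 * np.log10(linear)

    band_means = {
        name: 10.0 * np.log10(max(PSD_FLOOR, float(np.mean(linear[_band_mask(freqs[mask], lo, hi, bands)]))))
        for name, (lo, hi) in bands.items()
        if _check_band_coverage(freqs[mask], lo, hi)
    }
    return CoherenceSpectrum(
        freqs=freqs[mask],
        values=values_db,
        n_segments=wins.shape[0],
        kind="psd_db",
        band_means=band_means,
    )


# --------------------------------------------------------------------------
# Coherence
# --------------------------------------------------------------------------


def mt_coherence(
    a: LFPRecording,
    b: LFPRecording,
    params: SpectralParams | None = None,
    bands: BandSet | None = None,
) -> CoherenceSpectrum:
    """Magnitude-squared coherence between two simultaneous recordings.

    Requires equal sampling rate and length.  Auto- and cross-spectra are
    averaged over all tapers and segments before forming
    |S_ab|^2 / (S_aa S_bb) (default); ``average="per_segment"`` instead
    forms a coherence per segment from its taper-averaged spectra and
    averages those across segments.  Raises if any segment of either channel
    has zero power.
    """
    params = params or SpectralParams()
    bands = bands or BandSet()
    if a.fs != b.fs:
        raise ValueError(f"sampling rates differ: {a.fs} vs {b.fs}")
    if a.n_samples != b.n_samples:
        raise ValueError(f"lengths differ: {a.n_samples} vs {b.n_samples}")
    params.validate_against(a.fs)

    wa = segment(a, params)
    wb = segment(b, params)
    for name, w in (("a", wa), ("b", wb)):
        power = (w**2).sum(axis=1)
        dead = np.nonzero(power == 0)[0]
        if dead.size:
            raise ValueError(f"zero-power segment {int(dead[0])} in channel {name}")

    Xa = _tapered_ffts(wa, params)
    Xb = _tapered_ffts(wb, params)
    # cross-spectrum via explicit real arithmetic: the real part and the
    # squared imaginary part are bit-identical under channel swap, making
    # coherence exactly symmetric
    cross_re = Xa.real * Xb.real + Xa.imag * Xb.imag
    cross_im = Xa.imag * Xb.real - Xa.real * Xb.imag
    Saa = Xa.real**2 + Xa.imag**2
    Sbb = Xb.real**2 + Xb.imag**2

    if params.average == "pooled":
        num = cross_re.mean(axis=(0, 1)) ** 2 + cross_im.mean(axis=(0, 1)) ** 2
        den = Saa.mean(axis=(0, 1)) * Sbb.mean(axis=(0, 1))
        with np.errstate(invalid="ignore", divide="ignore"):
            coh = np.where(den > 0, num / den, 0.0)
    else:  # per-segment coherence, then mean across segments
        num = cross_re.mean(axis=1) ** 2 + cross_im.mean(axis=1) ** 2
        den = Saa.mean(axis=1) * Sbb.mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            coh = np.where(den > 0, num / den, 0.0).mean(axis=0)

    coh = np.clip(coh, 0.0, 1.0)
    n = wa.shape[1]
    freqs, mask = _grid_mask(n, a.fs, params.freq_range)
    f_sel = freqs[mask]
    v_sel = coh[mask]
    band_means = {
        name: float(np.mean(v_sel[_band_mask(f_sel, lo, hi, bands)]))
        for name, (lo, hi) in bands.items()
        if _check_band_coverage(f_sel, lo, hi)
    }
    return CoherenceSpectrum(
        freqs=f_sel,
        values=v_sel,
        n_segments=wa.shape[0],
        kind="coherence",
        band_means=band_means,
    )


# --------------------------------------------------------------------------
# Band summaries
# --------------------------------------------------------------------------


def band_summary(spec: CoherenceSpectrum, bands: BandSet | None = None) -> dict[str, float]:
    """Mean spectrum value per named band.

    Band membership is half-open [low, high); the band whose upper edge is
    the global maximum is closed there, so every shared edge belongs to
    exactly one band.  PSD summaries are averaged on the linear scale and
    converted back to dB.  Raises if a band extends beyond the spectrum.
    """
    bands = bands or BandSet()
    f = spec.freqs
    out: dict[str, float] = {}
    for name, (lo, hi) in bands.items():
        if not _check_band_coverage(f, lo, hi):
            raise ValueError(
                f"band {name!r} [{lo}, {hi}] extends beyond the spectrum "
                f"range [{f.min()}, {f.max()}]"
            )
        m = _band_mask(f, lo, hi, bands)
        if spec.kind == "psd_db":
            out[name] = 10.0 * np.log10(float(np.mean(10 ** (spec.values[m] / 10.0))))
        else:
            out[name] = float(np.mean(spec.values[m]))
    return out


def _band_mask(f: np.ndarray, lo: float, hi: float, bands: BandSet) -> np.ndarray:
    closed_top = hi >= bands.max_edge - 1e-9
    upper = f <= hi + 1e-9 if closed_top else f < hi - 1e-9
    return (f >= lo - 1e-9) & upper


def _check_band_coverage(f: np.ndarray, lo: float, hi: float) -> bool:
    return bool(f.size) and f.min() <= lo + 1e-9 and f.max() >= hi - 1e-9
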