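"""Band-resolved LFP power (multitaper) and extracellular spike detection.

Bands are implemented exactly as printed — closed intervals with gaps
between them (e.g. 3-4 Hz) excluded from every band and from the total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import ContractError

__all__ = [
    "BANDS",
    "BandPower",
    "SpikeDetection",
    "MultitaperParams",
    "SpikeDetectParams",
    "band_power",
    "detect_spikes",
]

#: named frequency bands, closed intervals in Hz
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 3.0),
    "theta": (4.0, 10.0),
    "alpha": (11.0, 15.0),
    "beta": (16.0, 30.0),
    "low_gamma": (31.0, 70.0),
    "high_gamma": (71.0, 100.0),
}


@dataclass(frozen=True)
class MultitaperParams:
    window_s: float = 2.0
    overlap: float = 0.5
    time_bandwidth: float = 3.0
    n_tapers: int = 5
    highpass_hz: float = 0.1
    lowpass_hz: float = 250.0


@dataclass(frozen=True)
class BandPower:
    """Per-band spectral power; ``total_power`` sums the six bands."""

    band_powers: dict[str, float]
    total_power: float
    freqs: np.ndarray = field(repr=False, default=None)
    psd: np.ndarray = field(repr=False, default=None)

    def __getitem__(self, band: str) -> float:
        return self.band_powers[band]

    @property
    def relative_powers(self) -> dict[str, float]:
        t = self.total_power
        return {b: (p / t if t > 0 else float("nan"))
                for b, p in self.band_powers.items()}


@dataclass(frozen=True)
class SpikeDetection:
    spike_times_s: np.ndarray
    n_spikes: int
    firing_rate_hz: float
    noise_sd: float
    waveforms: np.ndarray            # (n_spikes, snippet_len)


@dataclass(frozen=True)
class SpikeDetectParams:
    threshold_sd: float = 5.0        # negative-range threshold
    artifact_sd: float = 30.0        # peaks beyond this are excluded
    band_hz: tuple[float, float] = (300.0, 3000.0)
    dead_time_ms: float = 1.0
    snippet_pre_ms: float = 0.5
    snippet_post_ms: float = 3.0
    robust_sd: bool = True           # median(|x|)/0.6745 instead of plain SD


def _multitaper_psd(x: np.ndarray, fs: float, p: MultitaperParams):
    nperseg = int(round(p.window_s * fs))
    if len(x) < nperseg:
        raise ContractError(
            f"trace too short for the {p.window_s} s taper window "
            f"(minimum duration {p.window_s} s)")
    step = max(1, int(round(nperseg * (1.0 - p.overlap))))
    tapers = signal.windows.dpss(nperseg, p.time_bandwidth, Kmax=p.n_tapers)
    # normalize each taper for a density estimate in units^2/Hz
    norms = (tapers**2).sum(axis=1)
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    acc = np.zeros(len(freqs))
    n_seg = 0
    for start in range(0, len(x) - nperseg + 1, step):
        seg = x[start:start + nperseg]
        spec = np.fft.rfft(tapers * seg[None, :], axis=1)
        pxx = (np.abs(spec) ** 2) / (fs * norms[:, None])
        # one-sided: double everything except DC and Nyquist
        pxx[:, 1:] *= 2.0
        if nperseg % 2 == 0:
            pxx[:, -1] /= 2.0
        acc += pxx.mean(axis=0)
        n_seg += 1
    return freqs, acc / n_seg


def band_power(trace: np.ndarray, fs_hz: float = 20_000.0,
               params: MultitaperParams | None = None) -> BandPower:
    """Multitaper band power of an LFP trace.

    The trace is band-pass filtered 0.1-250 Hz, a DPSS multitaper PSD is
    averaged over 2 s windows with 50 % overlap, and each band's power is
    the PSD integrated over the band's closed frequency interval.
    """
    params = params or MultitaperParams()
    x = np.asarray(trace, dtype=np.float64)
    if len(x) < 2 * fs_hz:
        raise ContractError("trace must be at least 2 s long")
    sos = signal.butter(4, [params.highpass_hz, params.lowpass_hz],
                        btype="band", fs=fs_hz, output="sos")
    filt = signal.sosfiltfilt(sos, x)
    freqs, psd = _multitaper_psd(filt, fs_hz, params)
    df = freqs[1] - freqs[0]
    powers = {}
    for name, (lo, hi) in BANDS.items():
        sel = (freqs >= lo) & (freqs <= hi)
        powers[name] = float(psd[sel].sum() * df)
    total = float(sum(powers.values()))
    return BandPower(band_powers=powers, total_power=total,
                     freqs=freqs, psd=psd)


def detect_spikes(trace: np.ndarray, fs_hz: float = 20_000.0,
                  params: SpikeDetectParams | None = None) -> SpikeDetection:
    """Detect extracellular spikes by negative-range amplitude thresholding.

    The wideband signal is band-pass filtered 300-3000 Hz; the noise SD is
    estimated robustly (median(|x|)/0.6745); local minima below
    -threshold_sd x SD are detected, peaks whose magnitude exceeds
    artifact_sd x SD are excluded, and a -0.5 to +3 ms snippet is cut
    around each retained peak.
    """
    params = params or SpikeDetectParams()
    if fs_hz < 10_000:
        raise ContractError("sampling rate must be >= 10 kHz")
    x = np.asarray(trace, dtype=np.float64)
    if len(x) < fs_hz // 10:
        raise ContractError("trace too short")

    # clipping / saturation check: runs of samples pinned at the extremes
    peak = np.abs(x).max()
    clipped = np.zeros(len(x), dtype=bool)
    if peak > 0:
        pinned = np.abs(x) >= peak * (1.0 - 1e-12)
        run = np.convolve(pinned.astype(int), np.ones(3, int), mode="same")
        if (run >= 3).any():
            warnings.warn("clipped/saturated samples detected; "
                          "excluding those regions", RuntimeWarning,
                          stacklevel=2)
            guard = int(round(1e-3 * fs_hz))
            bad = np.nonzero(run >= 3)[0]
            for b in bad:
                clipped[max(0, b - guard):b + guard + 1] = True

    lo, hi = params.band_hz
    sos = signal.butter(4, [lo, min(hi, 0.45 * fs_hz)], btype="band",
                        fs=fs_hz, output="sos")
    filt = signal.sosfiltfilt(sos, x)

    if params.robust_sd:
        sd = float(np.median(np.abs(filt)) / 0.6745)
    else:
        sd = float(np.std(filt))
    if sd == 0:
        empty = np.empty((0, _snippet_len(fs_hz, params)))
        return SpikeDetection(np.array([]), 0, 0.0, 0.0, empty)

    dead = max(1, int(round(params.dead_time_ms * 1e-3 * fs_hz)))
    peaks, props = signal.find_peaks(-filt, height=params.threshold_sd * sd,
                                     distance=dead)
    heights = props["peak_heights"]
    keep = heights <= params.artifact_sd * sd   # retained in (5 SD, 30 SD]
    peaks = peaks[keep & ~clipped[peaks]] if clipped.any() else peaks[keep]

    pre = int(round(params.snippet_pre_ms * 1e-3 * fs_hz))
    n_snip = _snippet_len(fs_hz, params)
    post = n_snip - pre - 1
    in_bounds = (peaks >= pre) & (peaks + post < len(filt))
    peaks = peaks[in_bounds]
    waveforms = np.stack([filt[p - pre: p + post + 1] for p in peaks]) \
        if len(peaks) else np.empty((0, n_snip))

    duration = len(x) / fs_hz
    return SpikeDetection(spike_times_s=peaks / fs_hz,
                          n_spikes=int(len(peaks)),
                          firing_rate_hz=len(peaks) / duration,
                          noise_sd=sd, waveforms=waveforms)


def _snippet_len(fs_hz: float, params: SpikeDetectParams) -> int:
    total_ms = params.snippet_pre_ms + params.snippet_post_ms
    return int(round(total_ms * 1e-3 * fs_hz)) + 1
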