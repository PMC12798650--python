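"""Raw simulator output -> analysis-ready signals.

The Granger analysis operates on signals low-passed at 50 Hz and sampled at
100 Hz (twice the post-filter Nyquist frequency).  Raw traces are integrated
at 10 kHz, so the pipeline is: discard the initial transient, zero-phase
low-pass, decimate, and normalize each channel to zero mean / unit variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .neural_mass import SimOutput

__all__ = ["TimeSeriesSet", "from_sim_output", "lowpass_decimate", "normalize_variance", "preprocess_sim"]


@dataclass
class TimeSeriesSet:
    """A multichannel time series with sampling rate and channel labels."""

    data: np.ndarray  # (n_samples, n_channels)
    fs: float
    labels: tuple[str, ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 1:
            self.data = self.data[:, None]
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if not np.isfinite(self.data).all():
            raise ValueError("time series contains non-finite values")
        if not self.labels:
            self.labels = tuple(f"ch{i}" for i in range(self.data.shape[1]))
        if len(self.labels) != self.data.shape[1]:
            raise ValueError("one label per channel required")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


def from_sim_output(out: SimOutput, burn_in: float = 1.0) -> TimeSeriesSet:
    """Wrap the pyramidal potentials of a simulation, dropping ``burn_in`` s."""
    i0 = round(burn_in / out.dt_raw)
    if i0 >= out.n_samples:
        raise ValueError("burn-in longer than the simulation")
    labels = tuple(f"roi{r}_{roi.rhythm}" for r, roi in enumerate(out.network.rois))
    return TimeSeriesSet(
        out.vp[i0:], fs=out.fs_raw, labels=labels, meta={"seed": out.seed}
    )


def _stage_factors(factor: int) -> list[int]:
    # decimate in steps of <= 10 so no single-stage filter is too sharp
    stages = []
    while factor > 10:
        for d in (10, 8, 5, 4, 2, 3, 7, 6, 9):
            if factor % d == 0:
                stages.append(d)
                factor //= d
                break
        else:  # prime factor > 10: take it in one go
            break
    stages.append(factor)
    return stages


def lowpass_decimate(ts: TimeSeriesSet, cutoff: float, fs_out: float, order: int = 8) -> TimeSeriesSet:
    """Zero-phase low-pass at ``cutoff`` Hz, then decimate to ``fs_out`` Hz.

    The filter is an order-``order`` Butterworth applied forward-backward
    (no phase distortion, so lag structure used by the Granger analysis is
    preserved).  ``ts.fs`` must be an integer multiple of ``fs_out``; large
    factors are decimated in stages of at most 10 to keep each anti-alias
    filter numerically benign.
    """
    if not (cutoff <= fs_out / 2 <= ts.fs / 2):
        raise ValueError(f"need cutoff <= fs_out/2 <= fs/2, got cutoff={cutoff}, fs_out={fs_out}, fs={ts.fs}")
    ratio = ts.fs / fs_out
    factor = round(ratio)
    if abs(ratio - factor) > 1e-9:
        raise ValueError(f"fs={ts.fs} is not an integer multiple of fs_out={fs_out}")
    x = ts.data
    fs = ts.fs
    for d in _stage_factors(factor):
        if d == 1:
            continue
        fs_next = fs / d
        # intermediate stages only guard against aliasing; the final stage
        # applies the requested cutoff
        fc = cutoff if fs_next == fs_out else 0.4 * fs_next
        sos = sps.butter(order, fc, btype="low", fs=fs, output="sos")
        x = sps.sosfiltfilt(sos, x, axis=0)
        x = x[::d]
        fs = fs_next
    meta = dict(ts.meta, cutoff_hz=cutoff, filter=f"butter{order}-sosfiltfilt")
    return TimeSeriesSet(np.ascontiguousarray(x), fs=fs_out, labels=ts.labels, meta=meta)


def normalize_variance(ts: TimeSeriesSet) -> TimeSeriesSet:
    """Mean-center each channel and scale it to unit sample variance."""
    x = ts.data
    sd = x.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance channel(s): {[ts.labels[i] for i in bad]}")
    z = (x - x.mean(axis=0)) / sd
    return replace(ts, data=z, meta=dict(ts.meta, normalized=True))


def preprocess_sim(
    out: SimOutput,
    burn_in: float = 1.0,
    cutoff: float = 50.0,
    fs_out: float = 100.0,
    normalize: bool = True,
) -> TimeSeriesSet:
    """Full pipeline: burn-in removal, low-pass + decimation, normalization."""
    ts = from_sim_output(out, burn_in=burn_in)
    ts = lowpass_decimate(ts, cutoff=cutoff, fs_out=fs_out)
    return normalize_variance(ts) if normalize else ts
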