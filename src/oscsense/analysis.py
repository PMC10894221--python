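"""Observable extraction from multichannel oscillator waveforms.

The network's information code is the *phase pattern*: once the coupled
oscillators lock onto a common frequency, each channel's spike peaks sit at
a stationary time offset from the reference channel's peaks, and the
offsets expressed as angles (360 * dt / T) are the encoded stimulus.

This module finds spike peaks, measures dominant frequencies by FFT,
decides synchronization, aggregates peak-time offsets into phase patterns
with circular statistics, and extracts post-transient limit-cycle
trajectories for phase-plane views.  Peak timing (not instantaneous phase
via analytic signals) is used throughout: relaxation spikes have sharp,
well-defined peaks, which is exactly how the hardware measurements define
the phase difference.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "WaveformSet",
    "PhasePattern",
    "AnalysisError",
    "detect_peaks",
    "dominant_frequency",
    "is_synchronized",
    "phase_pattern",
    "limit_cycle",
    "circular_median_deg",
    "circular_distance_deg",
]

#: Default relative frequency tolerance for the synchronization verdict.
DEFAULT_REL_TOL = 0.01
#: Default transient to discard before analysis (the physical network locks
#: in about 20 us); the per-call default is max(this, 3 reference periods).
DEFAULT_TRANSIENT_CUT = 20e-6
#: Circular spread bound above which a phase estimate is deemed unstable.
UNSTABLE_PHASE_BOUND_DEG = 20.0


class AnalysisError(ValueError):
    """Raised when a waveform does not support the requested observable."""


@dataclass
class WaveformSet:
    """Uniformly sampled multichannel voltage record.

    ``channels`` maps node id to a voltage series; all series share
    ``time``, which must be strictly increasing and uniform to 1 ppm.
    """

    time: np.ndarray
    channels: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)
    label: str | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        if self.time.ndim != 1 or self.time.size < 2:
            raise ValueError("time grid needs at least 2 samples")
        steps = np.diff(self.time)
        if np.any(steps <= 0):
            raise ValueError("time grid must be strictly increasing")
        mean_step = steps.mean()
        if np.max(np.abs(steps - mean_step)) > 1e-6 * mean_step:
            raise ValueError("time grid must be uniform within 1 ppm")
        for k, v in self.channels.items():
            if v.shape != self.time.shape:
                raise ValueError(f"channel {k} length does not match time grid")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    @property
    def channel_ids(self) -> list[str]:
        return list(self.channels)

    def window(self, t_start: float, t_stop: float | None = None) -> "WaveformSet":
        """Sub-record restricted to [t_start, t_stop]."""
        t_stop = self.time[-1] if t_stop is None else t_stop
        mask = (self.time >= t_start) & (self.time <= t_stop)
        if mask.sum() < 2:
            raise AnalysisError("empty window: fewer than 2 samples selected")
        return WaveformSet(
            time=self.time[mask],
            channels={k: v[mask] for k, v in self.channels.items()},
            meta=self.meta,
            label=self.label,
        )

    # -- CSV dialect: header "time_s,node_<id>,...", one row per sample ----
    def to_csv(self, path_or_buf) -> None:
        df = pd.DataFrame({"time_s": self.time})
        for k, v in self.channels.items():
            df[f"node_{k}"] = v
        df.to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf, meta: dict | None = None, label: str | None = None) -> "WaveformSet":
        df = pd.read_csv(path_or_buf)
        if "time_s" not in df.columns:
            raise ValueError("waveform CSV must have a 'time_s' column")
        channels = {
            c.removeprefix("node_"): df[c].to_numpy()
            for c in df.columns
            if c.startswith("node_")
        }
        if not channels:
            raise ValueError("waveform CSV has no node_<id> columns")
        return cls(time=df["time_s"].to_numpy(), channels=channels,
                   meta=meta or {}, label=label)

    def to_csv_bytes(self) -> bytes:
        buf = io.StringIO()
        self.to_csv(buf)
        return buf.getvalue().encode()


@dataclass
class PhasePattern:
    """Per-channel phase offsets (degrees in [0, 360)) at a common frequency."""

    ref_channel: str
    common_frequency: float
    phase_deg: dict[str, float]
    synchronized: bool
    natural_frequencies: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.ref_channel not in self.phase_deg:
            raise ValueError("ref_channel missing from phase_deg")
        if self.phase_deg[self.ref_channel] != 0.0:
            raise ValueError("reference channel phase must be 0")
        for k, p in self.phase_deg.items():
            if not 0.0 <= p < 360.0:
                raise ValueError(f"phase for {k} outside [0, 360)")
        if self.synchronized and not self.common_frequency > 0:
            raise ValueError("synchronized pattern needs common_frequency > 0")

    def vector(self, order: list[str] | None = None) -> np.ndarray:
        order = order or list(self.phase_deg)
        return np.array([self.phase_deg[k] for k in order])

    def to_json(self) -> str:
        return json.dumps({
            "ref_channel": self.ref_channel,
            "common_frequency": self.common_frequency,
            "phase_deg": self.phase_deg,
            "synchronized": self.synchronized,
            "natural_frequencies": self.natural_frequencies,
        })

    @classmethod
    def from_json(cls, s: str) -> "PhasePattern":
        return cls(**json.loads(s))


# ---------------------------------------------------------------------------
# circular statistics on angles in degrees

def circular_distance_deg(a, b) -> np.ndarray:
    """Shortest angular distance |a - b| on the circle, in [0, 180]."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    return np.minimum(d, 360.0 - d)


def circular_median_deg(angles: np.ndarray) -> float:
    """Circular median: the sample minimizing total circular distance.

    Exact search over the samples (n is the number of oscillation periods,
    so small); ties resolve to the first minimizer.  Avoids the wrap bias a
    linear median would suffer near 0/360.
    """
    angles = np.asarray(angles, dtype=float) % 360.0
    if angles.size == 0:
        raise ValueError("no angles")
    costs = circular_distance_deg(angles[:, None], angles[None, :]).sum(axis=1)
    return float(angles[np.argmin(costs)])


def circular_spread_deg(angles: np.ndarray) -> float:
    """Circular standard deviation in degrees (via resultant length)."""
    rad = np.deg2rad(np.asarray(angles, dtype=float))
    r = np.abs(np.mean(np.exp(1j * rad)))
    r = min(max(r, 1e-12), 1.0)
    return float(np.rad2deg(np.sqrt(-2.0 * np.log(r))))


# ---------------------------------------------------------------------------

def detect_peaks(
    channel: np.ndarray,
    time: np.ndarray,
    min_prominence: float | None = None,
    min_distance: float | None = None,
) -> np.ndarray:
    """Times of prominent local maxima, refined by parabolic interpolation.

    ``min_prominence`` defaults to 10% of the channel's peak-to-peak range.
    ``min_distance`` (seconds) suppresses noise-induced secondary maxima
    closer than that to a larger peak.  Raises :class:`AnalysisError` when
    fewer than 2 peaks are found.
    """
    channel = np.asarray(channel, dtype=float)
    time = np.asarray(time, dtype=float)
    if channel.size < 3:
        raise AnalysisError("need at least 3 samples for peak detection")
    if min_prominence is None:
        ptp = float(channel.max() - channel.min())
        min_prominence = 0.1 * ptp if ptp > 0 else 1.0
    if min_prominence <= 0:
        raise ValueError("min_prominence must be > 0")
    dist = None
    if min_distance is not None:
        dist = max(int(round(min_distance / (time[1] - time[0]))), 1)
    idx, _ = sps.find_peaks(channel, prominence=min_prominence, distance=dist)
    if idx.size < 2:
        raise AnalysisError(
            f"no-peaks: found {idx.size} peak(s) with prominence >= {min_prominence:.3g}"
        )
    dt = time[1] - time[0]
    times = []
    for i in idx:
        if 0 < i < channel.size - 1:
            y0, y1, y2 = channel[i - 1], channel[i], channel[i + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        times.append(time[i] + delta * dt)
    return np.asarray(times)


def dominant_frequency(channel: np.ndarray, time: np.ndarray) -> float:
    """Frequency of the largest non-DC bin of the magnitude spectrum.

    The peak bin is refined by quadratic interpolation across its
    neighbours.  Warns when the record is shorter than ~8 periods of the
    estimate; raises on (near-)constant input.
    """
    channel = np.asarray(channel, dtype=float)
    time = np.asarray(time, dtype=float)
    n = channel.size
    if n < 4:
        raise AnalysisError("need at least 4 samples for a spectrum")
    x = channel - channel.mean()
    if np.max(np.abs(x)) < 1e-12 * max(1.0, np.max(np.abs(channel))):
        raise AnalysisError("degenerate-spectrum: constant input")
    dt = time[1] - time[0]
    mag = np.abs(np.fft.rfft(x))
    mag[0] = 0.0
    k = int(np.argmax(mag))
    if mag[k] == 0.0:
        raise AnalysisError("degenerate-spectrum: empty spectrum")
    # Coupling kinks can push a harmonic above the fundamental for
    # relaxation waveforms; step down to a subharmonic bin while it holds
    # at least half the peak magnitude.
    for div in (2, 3):
        sub = int(round(k / div))
        if sub < 1:
            continue
        lo, hi = max(sub - 1, 1), min(sub + 2, mag.size)
        if mag[lo:hi].max() >= 0.5 * mag[k]:
            k = lo + int(np.argmax(mag[lo:hi]))
            break
    # Quadratic interpolation of log-magnitude across adjacent bins.
    if 0 < k < mag.size - 1 and mag[k - 1] > 0 and mag[k + 1] > 0:
        a, b, c = np.log(mag[k - 1]), np.log(mag[k]), np.log(mag[k + 1])
        denom = a - 2 * b + c
        delta = 0.5 * (a - c) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    freq = (k + delta) / (n * dt)
    if freq > 0 and (n * dt) * freq < 8:
        import warnings

        warnings.warn(
            f"record holds only {(n * dt) * freq:.1f} periods at the dominant "
            "frequency; estimate may be coarse (8+ recommended)",
            stacklevel=2,
        )
    return float(freq)


def _analysis_window(wset: WaveformSet, transient_cut: float | None) -> WaveformSet:
    """Discard the synchronization transient (default: max of 20 us and 3
    reference-channel periods, estimated from the first channel)."""
    if transient_cut is None:
        ref = wset.channels[wset.channel_ids[0]]
        try:
            f = dominant_frequency(ref, wset.time)
            transient_cut = max(DEFAULT_TRANSIENT_CUT, 3.0 / f)
        except AnalysisError:
            transient_cut = DEFAULT_TRANSIENT_CUT
    if transient_cut >= wset.duration:
        raise AnalysisError("empty-window: transient cut exceeds the record")
    return wset.window(wset.time[0] + transient_cut)


def is_synchronized(
    wset: WaveformSet,
    rel_tol: float = DEFAULT_REL_TOL,
    transient_cut: float | None = None,
) -> bool:
    """True iff all channels share a dominant frequency within ``rel_tol``.

    Compares per-channel FFT dominant frequencies over the post-transient
    window: ``max_i |f_i - mean| / mean < rel_tol``.
    """
    win = _analysis_window(wset, transient_cut)
    freqs = np.array([dominant_frequency(v, win.time) for v in win.channels.values()])
    fbar = freqs.mean()
    return bool(np.max(np.abs(freqs - fbar)) / fbar < rel_tol)


def natural_frequencies(wset: WaveformSet, transient_cut: float | None = None) -> dict[str, float]:
    """Per-channel dominant frequencies over the post-transient window."""
    win = _analysis_window(wset, transient_cut)
    return {k: dominant_frequency(v, win.time) for k, v in win.channels.items()}


def phase_pattern(
    wset: WaveformSet,
    ref_channel: str | None = None,
    rel_tol: float = DEFAULT_REL_TOL,
    transient_cut: float | None = None,
    spread_bound_deg: float = UNSTABLE_PHASE_BOUND_DEG,
) -> PhasePattern:
    """Phase offsets of every channel relative to the reference.

    The common period ``T`` is the median inter-peak interval of the
    reference channel.  For each channel, every reference peak is matched
    to the next peak of that channel and the offsets ``(t_i - t_ref) mod T``
    are aggregated by circular median; ``phase = 360 * dt / T``.

    Raises ``not-synchronized`` when the synchronization test fails and
    ``unstable-phase`` when the per-period offsets spread by more than
    ``spread_bound_deg`` (circular std).
    """
    ref_channel = ref_channel or wset.channel_ids[0]
    if ref_channel not in wset.channels:
        raise ValueError(f"unknown ref_channel {ref_channel!r}")
    win = _analysis_window(wset, transient_cut)
    if not is_synchronized(wset, rel_tol=rel_tol, transient_cut=transient_cut):
        raise AnalysisError("not-synchronized: channels do not share a frequency")

    # Guard peak matching against noise-induced spurious maxima by keeping
    # peaks at least 60% of the dominant period apart.
    f0 = dominant_frequency(win.channels[ref_channel], win.time)
    min_dist = 0.6 / f0
    ref_peaks = detect_peaks(win.channels[ref_channel], win.time, min_distance=min_dist)
    period = float(np.median(np.diff(ref_peaks)))
    phases: dict[str, float] = {ref_channel: 0.0}
    for cid, v in win.channels.items():
        if cid == ref_channel:
            continue
        peaks = detect_peaks(v, win.time, min_distance=min_dist)
        # Match each ref peak to that channel's next peak at or after it.
        offsets = []
        for tr in ref_peaks:
            j = int(np.searchsorted(peaks, tr))
            if j >= peaks.size:
                break
            offsets.append(((peaks[j] - tr) % period) / period * 360.0)
        if len(offsets) < 2:
            raise AnalysisError(f"no-peaks: too few matched peaks on channel {cid}")
        offsets = np.asarray(offsets)
        if circular_spread_deg(offsets) > spread_bound_deg:
            raise AnalysisError(
                f"unstable-phase: channel {cid} offsets spread "
                f"{circular_spread_deg(offsets):.1f} deg > {spread_bound_deg} deg"
            )
        phases[cid] = circular_median_deg(offsets) % 360.0
    return PhasePattern(
        ref_channel=ref_channel,
        common_frequency=1.0 / period,
        phase_deg=phases,
        synchronized=True,
    )


def limit_cycle(
    wset: WaveformSet, transient_cut: float | None = None
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Post-transient phase-space trajectory.

    Returns ``(points, projections)`` where ``points`` is an (n_samples, N)
    array of simultaneous channel voltages and ``projections`` holds the
    three 2-D projections (x-y, x-z, y-z) when N = 3, the single x-y plane
    when N = 2.
    """
    if len(wset.channels) < 2:
        raise AnalysisError("limit cycle needs at least 2 channels")
    if transient_cut is not None and transient_cut >= wset.duration:
        raise AnalysisError("empty-window: transient cut exceeds the record")
    win = _analysis_window(wset, transient_cut)
    ids = win.channel_ids
    pts = np.column_stack([win.channels[k] for k in ids])
    proj: dict[str, np.ndarray] = {}
    if len(ids) >= 2:
        proj[f"{ids[0]}-{ids[1]}"] = pts[:, [0, 1]]
    if len(ids) >= 3:
        proj[f"{ids[0]}-{ids[2]}"] = pts[:, [0, 2]]
        proj[f"{ids[1]}-{ids[2]}"] = pts[:, [1, 2]]
    return pts, proj
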