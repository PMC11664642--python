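"""Minimal epoch preprocessing.

The pipeline applied to each subject is fixed and logged in order:
epoching -> average reference -> deviant-channel interpolation ->
linear detrend + zero-phase FIR band-pass -> pre-stimulus time-domain
baseline. Trials are never reordered; only epoching may drop trials
(those flagged invalid at acquisition).

Time conventions: t = 0 ms is stimulus onset, sample windows are half-open
``[start, stop)`` and 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from ._montage import Montage

__all__ = [
    "ContinuousRecording",
    "EpochSet",
    "PrepConfig",
    "epochize",
    "rereference_average",
    "interpolate_deviant_channels",
    "fir_bandpass_detrend",
    "apply_time_baseline",
    "preprocess",
]

FIRST = "first"
SECOND = "second"


@dataclass(frozen=True)
class ContinuousRecording:
    """Continuous multi-channel voltage trace with stimulus events.

    ``data`` is channels x samples in microvolts; ``events`` are
    ``(label, sample_index)`` pairs.
    """

    labels: tuple[str, ...]
    fs: float
    data: np.ndarray = field(repr=False)
    events: tuple[tuple[str, int], ...]
    montage: Montage | None = None

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.shape[0] != len(self.labels):
            raise ValueError("data must be (n_channels, n_samples)")
        object.__setattr__(self, "data", data)
        n = data.shape[1]
        for lab, idx in self.events:
            if not 0 <= idx < n:
                raise ValueError(f"event {lab!r} at sample {idx} outside recording")


@dataclass(frozen=True)
class EpochSet:
    """Per-subject epoched EEG: trials x channels x samples, microvolts.

    ``presentation`` tags each trial as the first or second showing of an
    object (odd trials are first presentations); ``valid`` flags trials
    usable for analysis. ``log`` records the preprocessing steps applied,
    in order.
    """

    subject: str
    group: str
    data: np.ndarray = field(repr=False)
    fs: float
    labels: tuple[str, ...]
    montage: Montage | None = None
    tmin_ms: float = -500.0
    presentation: tuple[str, ...] = ()
    valid: tuple[bool, ...] = ()
    log: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_samples)")
        if data.shape[1] != len(self.labels):
            raise ValueError("channel dimension does not match labels")
        object.__setattr__(self, "data", data)
        n_trials = data.shape[0]
        if not self.presentation:
            # trial parity: odd trial index (0-based even) = first showing
            pres = tuple(FIRST if i % 2 == 0 else SECOND for i in range(n_trials))
            object.__setattr__(self, "presentation", pres)
        if not self.valid:
            object.__setattr__(self, "valid", (True,) * n_trials)
        if len(self.presentation) != n_trials or len(self.valid) != n_trials:
            raise ValueError("presentation/valid length must equal n_trials")
        if any(p not in (FIRST, SECOND) for p in self.presentation):
            raise ValueError("presentation entries must be 'first' or 'second'")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Time axis in ms, strictly increasing with uniform step 1000/fs."""
        return self.tmin_ms + np.arange(self.n_samples) * (1000.0 / self.fs)

    def with_data(self, data: np.ndarray, step: str) -> "EpochSet":
        return replace(self, data=data, log=self.log + (step,))


@dataclass(frozen=True)
class PrepConfig:
    """Preprocessing parameters (defaults mirror the study pipeline)."""

    epoch_span_ms: tuple[float, float] = (-500.0, 1500.0)
    deviance_k: float = 2.0
    band_hz: tuple[float, float] = (0.25, 30.0)
    baseline_ms: tuple[float, float] = (-500.0, -300.0)

    def __post_init__(self) -> None:
        lo, hi = self.band_hz
        if not 0 < lo < hi:
            raise ValueError("band edges must satisfy 0 < lo < hi")
        b0, b1 = self.baseline_ms
        e0, e1 = self.epoch_span_ms
        if not (e0 <= b0 < b1 <= e1):
            raise ValueError("baseline window must lie inside the epoch span")


def _window_samples(times_ms: np.ndarray, fs: float, window_ms: tuple[float, float]):
    """Half-open sample slice covering ``window_ms`` on the epoch time axis."""
    t0 = times_ms[0]
    lo = int(round((window_ms[0] - t0) * fs / 1000.0))
    hi = int(round((window_ms[1] - t0) * fs / 1000.0))
    if lo < 0 or hi > len(times_ms) or lo >= hi:
        raise ValueError(f"window {window_ms} ms outside epoch span")
    return slice(lo, hi)


def epochize(
    rec: ContinuousRecording,
    event_label: str,
    span_ms: tuple[float, float] = (-500.0, 1500.0),
    valid_mask: tuple[bool, ...] | None = None,
    subject: str = "s01",
    group: str = "NA",
) -> EpochSet:
    """Cut one epoch per event carrying ``event_label``.

    The sample window is ``[t0 + round(lo*fs/1000), t0 + round(hi*fs/1000))``
    half-open. Events flagged invalid in ``valid_mask`` are dropped (and
    logged); events too close to the recording edge raise.
    """
    onsets = [idx for lab, idx in rec.events if lab == event_label]
    if not onsets:
        raise ValueError(f"no events labelled {event_label!r}")
    if valid_mask is None:
        valid_mask = (True,) * len(onsets)
    if len(valid_mask) != len(onsets):
        raise ValueError("valid_mask length must match event count")
    off_lo = int(round(span_ms[0] * rec.fs / 1000.0))
    off_hi = int(round(span_ms[1] * rec.fs / 1000.0))
    n = rec.data.shape[1]
    bad_edge = [
        t0 for t0 in onsets if t0 + off_lo < 0 or t0 + off_hi > n
    ]
    if bad_edge:
        raise ValueError(
            f"events at samples {bad_edge} do not fit span {span_ms} ms"
        )
    kept, pres = [], []
    n_dropped = 0
    for i, (t0, ok) in enumerate(zip(onsets, valid_mask)):
        if not ok:
            n_dropped += 1
            continue
        kept.append(rec.data[:, t0 + off_lo : t0 + off_hi])
        pres.append(FIRST if i % 2 == 0 else SECOND)
    log = (f"epochize span={span_ms} n={len(kept)} dropped={n_dropped}",)
    return EpochSet(
        subject=subject,
        group=group,
        data=np.stack(kept),
        fs=rec.fs,
        labels=rec.labels,
        montage=rec.montage,
        tmin_ms=span_ms[0],
        presentation=tuple(pres),
        log=log,
    )


def rereference_average(e: EpochSet) -> EpochSet:
    """Re-reference every trial to the instantaneous channel average."""
    if e.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    data = e.data - e.data.mean(axis=1, keepdims=True)
    return e.with_data(data, "rereference_average")


def interpolate_deviant_channels(
    e: EpochSet, k: float = 2.0
) -> tuple[EpochSet, list[str]]:
    """Replace channels whose overall voltage SD deviates from the channel
    population by more than ``k`` population SDs.

    The replacement is the inverse-distance-weighted mean of the 4 nearest
    non-deviant channels on the montage sphere. More than 25% flagged
    channels aborts (data quality).
    """
    if e.montage is None:
        raise ValueError("montage required for interpolation")
    flat = e.data.transpose(1, 0, 2).reshape(e.n_channels, -1)
    scores = flat.std(axis=1)
    dev = np.abs(scores - scores.mean()) > k * scores.std()
    bad = np.flatnonzero(dev)
    if bad.size > 0.25 * e.n_channels:
        raise ValueError(
            f"{bad.size}/{e.n_channels} channels deviant; data unusable"
        )
    if bad.size == 0:
        return e.with_data(e.data.copy(), f"interpolate k={k} none"), []
    pos = np.stack([e.montage.positions[e.montage.index(l)] for l in e.labels])
    good = np.flatnonzero(~dev)
    data = e.data.copy()
    for ch in bad:
        d = np.linalg.norm(pos[good] - pos[ch], axis=1)
        nearest = good[np.argsort(d)[:4]]
        w = 1.0 / np.maximum(np.linalg.norm(pos[nearest] - pos[ch], axis=1), 1e-12)
        w /= w.sum()
        data[:, ch, :] = np.tensordot(w, e.data[:, nearest, :], axes=(0, 1))
    names = [e.labels[ch] for ch in bad]
    return e.with_data(data, f"interpolate k={k} {','.join(names)}"), names


def _fir_taps(fs: float, lo: float, hi: float, n_samples: int) -> np.ndarray:
    """Hamming-windowed sinc band-pass.

    Nominal transition widths are 0.25 Hz at the low edge and 7.5 Hz at the
    high edge; the filter length is capped so forward-backward filtering of
    an ``n_samples`` epoch remains well-posed (the 0.25 Hz transition is not
    realizable on a 2 s epoch).
    """
    trans = min(0.25, 2 * lo)  # keep the passband edge above 0
    numtaps = int(np.ceil(3.3 * fs / trans)) | 1
    cap = max(((n_samples - 1) // 3) | 1, 5)
    numtaps = min(numtaps, cap)
    return sps.firwin(numtaps, [lo, hi], pass_zero=False, window="hamming", fs=fs)


def fir_bandpass_detrend(e: EpochSet, lo: float = 0.25, hi: float = 30.0) -> EpochSet:
    """Linear detrend then zero-phase (forward-backward) FIR band-pass,
    applied per trial and channel."""
    if hi >= e.fs / 2:
        raise ValueError("high edge must be below Nyquist")
    data = sps.detrend(e.data, axis=-1, type="linear")
    taps = _fir_taps(e.fs, lo, hi, e.n_samples)
    data = sps.filtfilt(taps, [1.0], data, axis=-1)
    return e.with_data(data, f"fir_bandpass_detrend {lo}-{hi}Hz ntaps={len(taps)}")


def apply_time_baseline(
    e: EpochSet, window_ms: tuple[float, float] = (-500.0, -300.0)
) -> EpochSet:
    """Subtract the per-trial, per-channel mean voltage over ``window_ms``."""
    sl = _window_samples(e.times_ms, e.fs, window_ms)
    data = e.data - e.data[:, :, sl].mean(axis=-1, keepdims=True)
    return e.with_data(data, f"time_baseline {window_ms}ms")


def preprocess(e: EpochSet, cfg: PrepConfig | None = None) -> EpochSet:
    """Run the fixed post-epoching chain: average reference, deviant-channel
    interpolation, detrend + band-pass, time-domain baseline."""
    cfg = cfg or PrepConfig()
    e = rereference_average(e)
    e, _ = interpolate_deviant_channels(e, cfg.deviance_k)
    e = fir_bandpass_detrend(e, *cfg.band_hz)
    return apply_time_baseline(e, cfg.baseline_ms)
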