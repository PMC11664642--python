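"""Synthetic EEG cohorts with known evoked/induced structure.

Each simulated epoch is a sum of four parts, all in microvolts:

* an **evoked** theta burst — Gaussian-windowed sinusoid with *fixed*
  latency and *fixed* phase across trials, so it survives time-domain
  trial averaging;
* an **induced** theta burst — same envelope shape but with a per-trial
  uniform latency jitter and a per-trial uniform random phase, so it
  cancels in the trial average and is only recoverable after subtracting
  the ERP from every trial;
* an ongoing 10 Hz **alpha** rhythm with random phase per trial;
* **1/f noise**, synthesized per channel by spectral shaping of white
  noise (power spectrum proportional to 1/f^exponent).

Component amplitudes differ by group (the experiment's between factor) and
by subject (a Gaussian between-subject spread), which makes downstream
effect sizes exactly computable from the configuration. Topographies are
Gaussian kernels on the electrode sphere: evoked activity is posterior
(centred on Oz), induced activity is midfrontal (centred on FCz), matching
the scalp distributions the analysis clusters target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._montage import Montage, make_montage, REQUIRED_LABELS
from .prep import EpochSet

__all__ = [
    "Montage",
    "make_montage",
    "REQUIRED_LABELS",
    "BurstComponent",
    "AlphaComponent",
    "NoiseSpec",
    "SimConfig",
    "GroundTruth",
    "simulate_epochs",
    "simulate_cohort",
    "export_cohort",
]

GROUPS = ("PC", "VR", "RL")


@dataclass(frozen=True)
class BurstComponent:
    """A Gaussian-enveloped oscillatory burst.

    ``amplitude_uv`` maps group -> mean peak amplitude; ``subject_sd_uv``
    is the between-subject SD of that amplitude. ``jitter_ms = 0`` together
    with ``random_phase = False`` makes the component phase-locked
    (evoked); a positive jitter half-range with random phase makes it
    induced.
    """

    freq_hz: float
    amplitude_uv: dict[str, float]
    latency_ms: float
    envelope_sd_ms: float
    jitter_ms: float = 0.0
    random_phase: bool = False
    phase_rad: float = 0.0
    subject_sd_uv: float = 1.0
    topo_center: str = "Oz"
    topo_sigma_rad: float = 0.7

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.amplitude_uv.values()):
            raise ValueError("amplitudes must be non-negative")
        if self.jitter_ms < 0:
            raise ValueError("jitter half-range must be non-negative")

    @property
    def phase_locked(self) -> bool:
        return self.jitter_ms == 0.0 and not self.random_phase


@dataclass(frozen=True)
class AlphaComponent:
    """Ongoing alpha rhythm, random phase per trial, posterior topography."""

    freq_hz: float = 10.0
    amplitude_uv: float = 1.0
    subject_sd_uv: float = 0.3
    topo_center: str = "Oz"
    topo_sigma_rad: float = 1.0


@dataclass(frozen=True)
class NoiseSpec:
    """1/f background noise: power spectrum ~ 1/f**exponent, target RMS."""

    exponent: float = 1.0
    rms_uv: float = 1.0


def _default_evoked() -> BurstComponent:
    # posterior evoked theta: RL > VR > PC
    return BurstComponent(
        freq_hz=6.0,
        amplitude_uv={"PC": 2.0, "VR": 2.5, "RL": 3.0},
        latency_ms=200.0,
        envelope_sd_ms=80.0,
        jitter_ms=0.0,
        random_phase=False,
        phase_rad=0.0,
        subject_sd_uv=1.0,
        topo_center="Oz",
        topo_sigma_rad=0.7,
    )


def _default_induced() -> BurstComponent:
    # midfrontal induced theta: PC > VR ~= RL, true d ~ 0.9 for PC contrasts
    return BurstComponent(
        freq_hz=6.5,
        amplitude_uv={"PC": 3.0, "VR": 2.1, "RL": 2.1},
        latency_ms=375.0,
        envelope_sd_ms=120.0,
        jitter_ms=150.0,
        random_phase=True,
        subject_sd_uv=1.0,
        topo_center="FCz",
        topo_sigma_rad=0.7,
    )


@dataclass(frozen=True)
class SimConfig:
    """Full description of a synthetic cohort."""

    n_per_group: int = 33
    n_trials: int = 80
    fs: float = 512.0
    epoch_span_ms: tuple[float, float] = (-500.0, 1500.0)
    groups: tuple[str, ...] = GROUPS
    n_channels: int = 32
    evoked: BurstComponent = field(default_factory=_default_evoked)
    induced: BurstComponent = field(default_factory=_default_induced)
    alpha: AlphaComponent = field(default_factory=AlphaComponent)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.epoch_span_ms
        if not lo < 0 < hi:
            raise ValueError("epoch span must straddle stimulus onset")
        if self.n_trials % 2:
            raise ValueError("n_trials must be even (first/second split)")
        for comp in (self.evoked, self.induced):
            missing = set(self.groups) - set(comp.amplitude_uv)
            if missing:
                raise ValueError(f"component lacks amplitudes for {sorted(missing)}")

    def montage(self) -> Montage:
        return make_montage(self.n_channels)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually injected, per group and component."""

    band_amplitude_uv: dict[str, dict[str, float]]  # component -> group -> amp
    latency_ms: dict[str, tuple[float, float]]      # component -> (mean, half-range)
    phase_locked: dict[str, bool]
    subject_sd_uv: dict[str, float]

    def true_cohens_d(self, component: str, g1: str, g2: str) -> float:
        """Population standardized mean difference of subject amplitudes."""
        amp = self.band_amplitude_uv[component]
        return (amp[g1] - amp[g2]) / self.subject_sd_uv[component]


def _topo_weights(montage: Montage, center: str, sigma_rad: float) -> np.ndarray:
    c = montage.positions[montage.index(center)]
    ang = np.arccos(np.clip(montage.positions @ c, -1.0, 1.0))
    return np.exp(-(ang**2) / (2.0 * sigma_rad**2))


def _one_over_f(rng: np.random.Generator, n_ch: int, n_t: int,
                fs: float, spec: NoiseSpec) -> np.ndarray:
    white = rng.standard_normal((n_ch, n_t))
    if spec.rms_uv == 0:
        return np.zeros((n_ch, n_t))
    spec_w = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_t, 1.0 / fs)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-spec.exponent / 2.0)
    x = np.fft.irfft(spec_w * shape, n=n_t, axis=-1)
    rms = np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
    return x / np.maximum(rms, 1e-300) * spec.rms_uv


def simulate_epochs(config: SimConfig, group: str, subject_seed: int,
                    subject: str | None = None) -> EpochSet:
    """Simulate one subject's epoched EEG.

    The evoked burst is identical across trials; the induced burst draws a
    fresh uniform latency (within the jitter half-range) and uniform phase
    per trial. Odd trials (0-based even indices) are first presentations.
    Bit-reproducible for a given (config, group, subject_seed).
    """
    if group not in config.groups:
        raise ValueError(f"unknown group {group!r}; expected one of {config.groups}")
    rng = np.random.default_rng(subject_seed)
    montage = config.montage()
    n_ch = len(montage)
    lo, hi = config.epoch_span_ms
    n_t = int(round((hi - lo) * config.fs / 1000.0))
    t = (lo + np.arange(n_t) * 1000.0 / config.fs) / 1000.0  # seconds

    # between-subject amplitude draws (order fixed: evoked, induced, alpha);
    # a zero configured amplitude switches the component off entirely
    def draw_amp(base: float, sd: float) -> float:
        if base == 0.0:
            return 0.0
        return max(0.0, base + sd * rng.standard_normal())

    amp_ev = draw_amp(config.evoked.amplitude_uv[group],
                      config.evoked.subject_sd_uv)
    amp_in = draw_amp(config.induced.amplitude_uv[group],
                      config.induced.subject_sd_uv)
    amp_al = draw_amp(config.alpha.amplitude_uv, config.alpha.subject_sd_uv)

    data = np.zeros((config.n_trials, n_ch, n_t))

    def burst(comp: BurstComponent, amp: float, lat_s: float, phase: float):
        env = np.exp(-((t - lat_s) ** 2) / (2.0 * (comp.envelope_sd_ms / 1000.0) ** 2))
        return amp * env * np.cos(2.0 * np.pi * comp.freq_hz * (t - lat_s) + phase)

    w_ev = _topo_weights(montage, config.evoked.topo_center,
                         config.evoked.topo_sigma_rad)
    w_in = _topo_weights(montage, config.induced.topo_center,
                         config.induced.topo_sigma_rad)
    w_al = _topo_weights(montage, config.alpha.topo_center,
                         config.alpha.topo_sigma_rad)

    if amp_ev > 0:
        ev = burst(config.evoked, amp_ev, config.evoked.latency_ms / 1000.0,
                   config.evoked.phase_rad)
        data += w_ev[None, :, None] * ev[None, None, :]

    for trial in range(config.n_trials):
        if amp_in > 0 and config.induced.amplitude_uv[group] > 0:
            jit = rng.uniform(-config.induced.jitter_ms, config.induced.jitter_ms) \
                if config.induced.jitter_ms > 0 else 0.0
            ph = rng.uniform(0.0, 2.0 * np.pi) if config.induced.random_phase \
                else config.induced.phase_rad
            lat = (config.induced.latency_ms + jit) / 1000.0
            data[trial] += w_in[:, None] * burst(config.induced, amp_in, lat, ph)
        if amp_al > 0 and config.alpha.amplitude_uv > 0:
            ph = rng.uniform(0.0, 2.0 * np.pi)
            wave = amp_al * np.cos(2.0 * np.pi * config.alpha.freq_hz * t + ph)
            data[trial] += w_al[:, None] * wave[None, :]
        if config.noise.rms_uv > 0:
            data[trial] += _one_over_f(rng, n_ch, n_t, config.fs, config.noise)

    return EpochSet(
        subject=subject or f"{group}_{subject_seed}",
        group=group,
        data=data,
        fs=config.fs,
        labels=montage.labels,
        montage=montage,
        tmin_ms=lo,
        log=(f"simulate seed={subject_seed}",),
    )


def _subject_seed(master_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0])


def simulate_cohort(config: SimConfig) -> tuple[list[EpochSet], GroundTruth]:
    """Simulate ``n_per_group`` subjects per group with distinct derived
    seeds; returns the cohort plus the injected ground truth."""
    cohort: list[EpochSet] = []
    idx = 0
    for group in config.groups:
        for s in range(config.n_per_group):
            seed = _subject_seed(config.seed, idx)
            cohort.append(
                simulate_epochs(config, group, seed,
                                subject=f"{group}{s + 1:02d}")
            )
            idx += 1
    truth = GroundTruth(
        band_amplitude_uv={
            "evoked": dict(config.evoked.amplitude_uv),
            "induced": dict(config.induced.amplitude_uv),
        },
        latency_ms={
            "evoked": (config.evoked.latency_ms, config.evoked.jitter_ms),
            "induced": (config.induced.latency_ms, config.induced.jitter_ms),
        },
        phase_locked={
            "evoked": config.evoked.phase_locked,
            "induced": config.induced.phase_locked,
        },
        subject_sd_uv={
            "evoked": config.evoked.subject_sd_uv,
            "induced": config.induced.subject_sd_uv,
        },
    )
    return cohort, truth


def export_cohort(cohort: list[EpochSet], out_dir: str | Path) -> list[Path]:
    """Write one ``.npz`` array container per subject plus a JSON sidecar
    (subject, group, fs, time axis, channel labels)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for e in cohort:
        base = out / e.subject
        np.savez(base.with_suffix(".npz"), data=e.data)
        meta = {
            "subject": e.subject,
            "group": e.group,
            "fs": e.fs,
            "tmin_ms": e.tmin_ms,
            "times_ms": e.times_ms.tolist(),
            "labels": list(e.labels),
            "presentation": list(e.presentation),
        }
        base.with_suffix(".json").write_text(json.dumps(meta))
        paths.append(base.with_suffix(".npz"))
    return paths
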