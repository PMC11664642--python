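"""Shared fixtures: small synthetic configurations and wavelet banks.

All EEG fixtures are generated programmatically; nothing is read from
disk. Session scope is used for the objects that are expensive to build.
"""

from dataclasses import replace

import pytest

from thetaband import simkit, tfr

FS = 512.0


def zero_amps(cfg: simkit.SimConfig) -> dict[str, float]:
    return {g: 0.0 for g in cfg.groups}


@pytest.fixture(scope="session")
def montage32():
    return simkit.make_montage(32)


@pytest.fixture(scope="session")
def bank_theta():
    """4-9 Hz bank covering both analysis bands, 0.5 Hz grid."""
    return tfr.build_wavelet_bank(FS, 4.0, 9.0)


@pytest.fixture(scope="session")
def base_config():
    return simkit.SimConfig()


@pytest.fixture(scope="session")
def phase_locked_config(base_config):
    """Evoked component only: fixed latency and phase, no jitter, no noise."""
    z = zero_amps(base_config)
    return replace(
        base_config,
        induced=replace(base_config.induced, amplitude_uv=z),
        alpha=replace(base_config.alpha, amplitude_uv=0.0),
        noise=replace(base_config.noise, rms_uv=0.0),
    )


@pytest.fixture(scope="session")
def jitter_only_config(base_config):
    """Induced component only: latency jitter and random phase per trial.

    The burst envelope (SD 500 ms) is long relative to the theta wavelets
    so the amplitude-recovery contract of the transform applies.
    """
    z = zero_amps(base_config)
    return replace(
        base_config,
        evoked=replace(base_config.evoked, amplitude_uv=z),
        induced=replace(
            base_config.induced,
            amplitude_uv={"PC": 3.0, "VR": 3.0, "RL": 3.0},
            envelope_sd_ms=500.0,
            latency_ms=500.0,
            subject_sd_uv=0.0,
        ),
        alpha=replace(base_config.alpha, amplitude_uv=0.0),
        noise=replace(base_config.noise, rms_uv=0.0),
    )


@pytest.fixture(scope="session")
def phase_locked_subject(phase_locked_config):
    return simkit.simulate_epochs(phase_locked_config, "RL", 42)


@pytest.fixture(scope="session")
def jitter_only_subject(jitter_only_config):
    return simkit.simulate_epochs(jitter_only_config, "PC", 7)


@pytest.fixture(scope="session")
def noisy_subject(base_config):
    """Default generator output for one subject (all components + noise)."""
    return simkit.simulate_epochs(base_config, "PC", 1)


def make_tiny_config(**over) -> simkit.SimConfig:
    """Small, fast cohort config used where only structure matters."""
    cfg = simkit.SimConfig()
    defaults = dict(n_per_group=2, n_trials=8)
    defaults.update(over)
    return replace(cfg, **defaults)
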