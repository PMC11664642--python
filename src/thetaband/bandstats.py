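"""Regional band/window means — the dependent variable of the analysis.

A regional mean is the arithmetic mean of TFR amplitude over an electrode
cluster, an inclusive frequency band, and a half-open time window. The
default specification reproduces the five cluster-by-band analyses of the
study design: evoked theta (4-7.5 Hz) at central, parietal and posterior
clusters in two 300 ms windows, and induced theta (5-8 Hz) at midfrontal
and posterior clusters in three 250 ms windows.

Cluster membership uses the explicitly documented electrodes. The central
cluster ("eleven electrodes including and neighbouring Cz") is a
reconstruction: Cz plus its ten immediate 10-10 neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .prep import _window_samples
from .tfr import TFRMap

__all__ = [
    "ClusterSpec",
    "BandWindowSpec",
    "DEFAULT_CLUSTERS",
    "DEFAULT_BANDS",
    "default_analyses",
    "regional_mean",
    "build_regional_table",
    "TABLE_COLUMNS",
]

TABLE_COLUMNS = (
    "subject", "group", "cluster", "band", "window", "presentation", "amplitude",
)


@dataclass(frozen=True)
class ClusterSpec:
    """A named electrode cluster."""

    name: str
    electrodes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.electrodes:
            raise ValueError("cluster must contain at least one electrode")


@dataclass(frozen=True)
class BandWindowSpec:
    """Frequency band (inclusive, Hz) with analysis windows (half-open, ms)
    for one response kind."""

    label: str
    band_hz: tuple[float, float]
    windows_ms: tuple[tuple[float, float], ...]
    kind: str  # evoked | induced

    def __post_init__(self) -> None:
        if self.kind not in ("evoked", "induced"):
            raise ValueError("kind must be 'evoked' or 'induced'")
        if self.band_hz[0] > self.band_hz[1]:
            raise ValueError("band must be (lo, hi) with lo <= hi")


DEFAULT_CLUSTERS: dict[str, ClusterSpec] = {
    # reconstruction: Cz and ten immediate neighbours (not individually
    # documented in the source design)
    "central": ClusterSpec(
        "central",
        ("Cz", "C1", "C2", "C3", "C4", "FC1", "FCz", "FC2", "CP1", "CPz", "CP2"),
    ),
    "parietal": ClusterSpec(
        "parietal",
        ("CP3", "CP1", "CPz", "CP2", "CP4", "P3", "P1", "Pz", "P2", "P4"),
    ),
    "posterior_evoked": ClusterSpec("posterior_evoked", ("O1", "O2", "Oz")),
    "midfrontal": ClusterSpec(
        "midfrontal", ("Cz", "Fz", "FC1", "FC2", "F1", "F2")
    ),
    "posterior_induced": ClusterSpec(
        "posterior_induced",
        ("O1", "Oz", "O2", "Pz", "PO3", "PO4", "PO7", "PO8"),
    ),
}

DEFAULT_BANDS: dict[str, BandWindowSpec] = {
    "eTBR": BandWindowSpec(
        "eTBR", (4.0, 7.5), ((0.0, 300.0), (300.0, 600.0)), "evoked"
    ),
    "iTBR": BandWindowSpec(
        "iTBR", (5.0, 8.0), ((0.0, 250.0), (250.0, 500.0), (500.0, 750.0)),
        "induced",
    ),
}


def default_analyses() -> list[tuple[ClusterSpec, BandWindowSpec]]:
    """The five cluster-by-band analyses (3 evoked + 2 induced)."""
    c, b = DEFAULT_CLUSTERS, DEFAULT_BANDS
    return [
        (c["central"], b["eTBR"]),
        (c["parietal"], b["eTBR"]),
        (c["posterior_evoked"], b["eTBR"]),
        (c["midfrontal"], b["iTBR"]),
        (c["posterior_induced"], b["iTBR"]),
    ]


def regional_mean(
    m: TFRMap,
    cluster: ClusterSpec,
    band_hz: tuple[float, float],
    window_ms: tuple[float, float],
) -> float:
    """Mean amplitude over (band frequencies, inclusive) x (cluster
    channels) x (window samples, half-open)."""
    missing = [el for el in cluster.electrodes if el not in m.labels]
    if missing:
        raise ValueError(f"electrodes missing from map: {', '.join(missing)}")
    ch_idx = [m.labels.index(el) for el in cluster.electrodes]
    f_idx = np.flatnonzero(
        (m.freqs >= band_hz[0] - 1e-9) & (m.freqs <= band_hz[1] + 1e-9)
    )
    if f_idx.size == 0:
        raise ValueError(f"band {band_hz} Hz outside map frequency axis")
    sl = _window_samples(m.times_ms, m.fs, window_ms)
    return float(m.amplitude[np.ix_(f_idx, ch_idx)][:, :, sl].mean())


def _window_label(w: tuple[float, float]) -> str:
    return f"{int(w[0])}-{int(w[1])}ms"


def build_regional_table(
    maps: dict[tuple[str, str, str], TFRMap],
    subjects: dict[str, str],
    analyses: list[tuple[ClusterSpec, BandWindowSpec]],
) -> pd.DataFrame:
    """Assemble the tidy regional-mean table.

    Parameters
    ----------
    maps
        ``(subject, kind, presentation) -> TFRMap`` with kind 'evoked' or
        'induced' and presentation 'first' or 'second'.
    subjects
        ``subject -> group`` label.
    analyses
        Cluster/band pairs to evaluate (e.g. :func:`default_analyses`).

    Returns a balanced DataFrame with one row per subject x cluster x
    window x presentation; raises if any subject lacks a required map.
    """
    presentations = sorted({k[2] for k in maps})
    rows = []
    for cluster, spec in analyses:
        for subject, group in subjects.items():
            for pres in presentations:
                key = (subject, spec.kind, pres)
                if key not in maps:
                    raise ValueError(
                        f"unbalanced cohort: missing {spec.kind}/{pres} map "
                        f"for subject {subject}"
                    )
                for w in spec.windows_ms:
                    rows.append(
                        {
                            "subject": subject,
                            "group": group,
                            "cluster": cluster.name,
                            "band": spec.label,
                            "window": _window_label(w),
                            "presentation": pres,
                            "amplitude": regional_mean(
                                maps[key], cluster, spec.band_hz, w
                            ),
                        }
                    )
    return pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
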