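"""Electrode montage on a unit sphere.

Labels follow the extended international 10-20 (10-10) nomenclature. Each
electrode is stored as a point on the unit sphere; coordinates are derived
from the conventional flat polar layout (radius fraction from the vertex,
azimuth from the front midline, positive toward the right ear), with the
ears at an inclination of 90 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Montage", "make_montage", "REQUIRED_LABELS"]

# (radius fraction of the vertex->ear arc, azimuth degrees from front midline,
#  positive clockwise toward the right). radius 0.5 corresponds to the
#  ear/nasion/inion circle (inclination 90 deg).
_POLAR: dict[str, tuple[float, float]] = {
    # midline
    "Fpz": (0.4, 0.0), "AFz": (0.3, 0.0), "Fz": (0.2, 0.0), "FCz": (0.1, 0.0),
    "Cz": (0.0, 0.0), "CPz": (0.1, 180.0), "Pz": (0.2, 180.0),
    "POz": (0.3, 180.0), "Oz": (0.4, 180.0), "Iz": (0.5, 180.0),
    # central coronal arc
    "C1": (0.1, -90.0), "C2": (0.1, 90.0), "C3": (0.2, -90.0), "C4": (0.2, 90.0),
    "C5": (0.3, -90.0), "C6": (0.3, 90.0), "T7": (0.4, -90.0), "T8": (0.4, 90.0),
    # frontal
    "F1": (0.22, -21.0), "F2": (0.22, 21.0), "F3": (0.26, -39.0),
    "F4": (0.26, 39.0), "F5": (0.32, -49.0), "F6": (0.32, 49.0),
    "F7": (0.4, -54.0), "F8": (0.4, 54.0),
    # frontocentral
    "FC1": (0.15, -45.0), "FC2": (0.15, 45.0), "FC3": (0.22, -62.0),
    "FC4": (0.22, 62.0), "FC5": (0.31, -69.0), "FC6": (0.31, 69.0),
    "FT7": (0.41, -72.0), "FT8": (0.41, 72.0),
    # centroparietal
    "CP1": (0.15, -135.0), "CP2": (0.15, 135.0), "CP3": (0.22, -118.0),
    "CP4": (0.22, 118.0), "CP5": (0.31, -111.0), "CP6": (0.31, 111.0),
    "TP7": (0.41, -108.0), "TP8": (0.41, 108.0),
    # parietal
    "P1": (0.22, -159.0), "P2": (0.22, 159.0), "P3": (0.26, -141.0),
    "P4": (0.26, 141.0), "P5": (0.32, -131.0), "P6": (0.32, 131.0),
    "P7": (0.4, -126.0), "P8": (0.4, 126.0),
    # parieto-occipital and occipital
    "PO3": (0.33, -161.0), "PO4": (0.33, 161.0), "PO7": (0.42, -144.0),
    "PO8": (0.42, 144.0), "O1": (0.41, -162.0), "O2": (0.41, 162.0),
    # frontopolar / anterior-frontal fillers
    "Fp1": (0.4, -18.0), "Fp2": (0.4, 18.0), "AF3": (0.32, -21.0),
    "AF4": (0.32, 21.0), "AF7": (0.4, -36.0), "AF8": (0.4, 36.0),
    "F9": (0.48, -58.0), "F10": (0.48, 58.0),
}

#: Electrodes every default analysis cluster relies on; make_montage always
#: places these first so any montage of >= 32 channels contains them.
REQUIRED_LABELS: tuple[str, ...] = (
    "Cz", "Fz", "FCz", "FC1", "FC2", "F1", "F2",
    "C1", "C2", "C3", "C4",
    "CP1", "CP2", "CP3", "CP4", "CPz",
    "P1", "P2", "P3", "P4", "Pz",
    "O1", "O2", "Oz", "PO3", "PO4", "PO7", "PO8",
)

_FILLERS: tuple[str, ...] = (
    "T7", "T8", "F3", "F4",
    "Fp1", "Fp2", "Fpz", "AFz", "AF3", "AF4", "AF7", "AF8",
    "F5", "F6", "F7", "F8", "FC3", "FC4", "FC5", "FC6", "FT7", "FT8",
    "C5", "C6", "CP5", "CP6", "TP7", "TP8",
    "P5", "P6", "P7", "P8", "POz", "Iz", "F9", "F10",
)


def _polar_to_xyz(radius_frac: float, azimuth_deg: float) -> np.ndarray:
    incl = radius_frac * np.pi            # 0.5 -> 90 deg
    az = np.deg2rad(azimuth_deg)
    return np.array(
        [np.sin(incl) * np.sin(az), np.sin(incl) * np.cos(az), np.cos(incl)]
    )


@dataclass(frozen=True)
class Montage:
    """Named electrodes with unit-sphere positions (x right, y front, z up)."""

    labels: tuple[str, ...]
    positions: np.ndarray = field(repr=False)  # (n, 3), unit norm

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("montage labels must be unique")
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.labels), 3):
            raise ValueError("positions must be (n_labels, 3)")
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("positions must lie on the unit sphere")
        object.__setattr__(self, "positions", pos)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"electrode {label!r} not in montage") from None

    def __len__(self) -> int:
        return len(self.labels)


def make_montage(n_channels: int = 32) -> Montage:
    """Build an ``n_channels`` montage guaranteed to contain every electrode
    used by the default analysis clusters.

    Parameters
    ----------
    n_channels
        Number of electrodes, at least 32 and at most the size of the
        built-in 10-10 table (64).
    """
    if n_channels < len(REQUIRED_LABELS):
        missing = REQUIRED_LABELS[n_channels:]
        raise ValueError(
            f"{n_channels} channels cannot host required electrodes; "
            f"missing {', '.join(missing)}"
        )
    order = REQUIRED_LABELS + _FILLERS
    if n_channels > len(order):
        raise ValueError(f"at most {len(order)} channels supported")
    labels = order[:n_channels]
    pos = np.stack([_polar_to_xyz(*_POLAR[lab]) for lab in labels])
    return Montage(labels=labels, positions=pos)
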