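"""Idealized 10-20 electrode geometry for the 32-channel montage.

Positions are unit-sphere coordinates (x: right, y: anterior, z: superior)
constructed from the standard 10-20 angular layout: the outer ring sits at
72 deg inclination from the vertex, the inferior temporal row (FT9/FT10,
TP9/TP10) at 90 deg, and intermediate 10-10 sites are spherical midpoints of
their four grid neighbours. These idealized coordinates serve distance-based
channel interpolation and schematic topography rendering; they are not
digitized head-shape positions.
"""

from __future__ import annotations

import math

import numpy as np

#: Channel order of the 32-channel cap (10-20 extended with FT9/FT10, TP9/TP10).
CHANNELS_32: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "FT9", "FT10",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6", "TP9", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
)

#: Left/right homologous frontal pairs used for the asymmetry index.
FAA_PAIRS: tuple[tuple[str, str], ...] = (
    ("F3", "F4"),
    ("F7", "F8"),
    ("FC5", "FC6"),
    ("FT9", "FT10"),
)

#: Frontal channels (theta fear modulation in the simulator).
FRONTAL_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz",
    "FC1", "FC2", "FC5", "FC6", "FT9", "FT10",
)

#: Right-frontal channels whose alpha is suppressed under fear.
RIGHT_FRONTAL_CHANNELS: tuple[str, ...] = ("F4", "F8", "FC6", "FT10")


def _sph(incl_deg: float, az_deg: float) -> np.ndarray:
    """Unit vector from inclination (from vertex) and azimuth (from nose,
    positive toward the right ear)."""
    incl = math.radians(incl_deg)
    az = math.radians(az_deg)
    return np.array(
        [math.sin(incl) * math.sin(az), math.sin(incl) * math.cos(az), math.cos(incl)]
    )


def _mid(*points: np.ndarray) -> np.ndarray:
    """Spherical midpoint: normalized mean of unit vectors."""
    v = np.mean(points, axis=0)
    return v / np.linalg.norm(v)


def _build_positions() -> dict[str, np.ndarray]:
    p: dict[str, np.ndarray] = {}
    # anchors: midline and the 10-20 outer ring (inclination 72 deg)
    p["Cz"] = _sph(0, 0)
    p["Fz"] = _sph(36, 0)
    p["Pz"] = _sph(36, 180)
    ring = {
        "Fp1": -18, "Fp2": 18, "F7": -54, "F8": 54, "T7": -90, "T8": 90,
        "P7": -126, "P8": 126, "O1": -162, "O2": 162, "Oz": 180,
    }
    for label, az in ring.items():
        p[label] = _sph(72, az)
    # inferior temporal row, 10% below the ring
    for label, az in {"FT9": -72, "FT10": 72, "TP9": -108, "TP10": 108}.items():
        p[label] = _sph(90, az)
    # central row and intermediate 10-10 sites as spherical midpoints
    p["C3"] = _sph(36, -90)
    p["C4"] = _sph(36, 90)
    p["F3"] = _mid(p["Fz"], p["F7"])
    p["F4"] = _mid(p["Fz"], p["F8"])
    p["P3"] = _mid(p["Pz"], p["P7"])
    p["P4"] = _mid(p["Pz"], p["P8"])
    p["FC5"] = _mid(p["F3"], p["F7"], p["C3"], p["T7"])
    p["FC6"] = _mid(p["F4"], p["F8"], p["C4"], p["T8"])
    p["FC1"] = _mid(p["Fz"], p["F3"], p["Cz"], p["C3"])
    p["FC2"] = _mid(p["Fz"], p["F4"], p["Cz"], p["C4"])
    p["CP5"] = _mid(p["C3"], p["T7"], p["P3"], p["P7"])
    p["CP6"] = _mid(p["C4"], p["T8"], p["P4"], p["P8"])
    p["CP1"] = _mid(p["Cz"], p["C3"], p["Pz"], p["P3"])
    p["CP2"] = _mid(p["Cz"], p["C4"], p["Pz"], p["P4"])
    return p


_POSITIONS = _build_positions()


def channel_positions(labels=CHANNELS_32) -> np.ndarray:
    """Return an (n_channels, 3) array of unit-sphere positions.

    Raises
    ------
    MontageError
        If any label is unknown to the idealized montage.
    """
    from .errors import MontageError

    try:
        return np.stack([_POSITIONS[lab] for lab in labels])
    except KeyError as exc:  # pragma: no cover - message formatting
        raise MontageError(f"no idealized position for channel {exc}") from exc
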