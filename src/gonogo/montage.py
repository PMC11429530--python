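"""Standard 19-channel 10-20 montage on a unit sphere.

Positions use the classic polar scheme (azimuth in degrees, polar radius in
units where 0.5 corresponds to 90 degrees from the vertex).  Only relative
geometry matters downstream (spherical-spline interpolation and synthetic
topography construction), not absolute head size.
"""

from __future__ import annotations

import numpy as np

#: the 19 scalp sites, in recording order
EEG_CHANNELS = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
]

#: the 4 periocular channels: above/below left eye, left/right outer canthus
EOG_CHANNELS = ["VEOGU", "VEOGL", "HEOGL", "HEOGR"]

# (azimuth deg, radius) — azimuth 0 at nose, positive clockwise (right);
# radius 0 at vertex, 0.5 at the equatorial ring.
_POLAR = {
    "Fp1": (-18.0, 0.511), "Fp2": (18.0, 0.511),
    "F7": (-54.0, 0.511), "F3": (-39.0, 0.333), "Fz": (0.0, 0.256),
    "F4": (39.0, 0.333), "F8": (54.0, 0.511),
    "T7": (-90.0, 0.511), "C3": (-90.0, 0.256), "Cz": (0.0, 0.0),
    "C4": (90.0, 0.256), "T8": (90.0, 0.511),
    "P7": (-126.0, 0.511), "P3": (-141.0, 0.333), "Pz": (180.0, 0.256),
    "P4": (141.0, 0.333), "P8": (126.0, 0.511),
    "O1": (-162.0, 0.511), "O2": (162.0, 0.511),
}


def positions(channels: list[str] | None = None) -> np.ndarray:
    """Unit-sphere Cartesian coordinates, shape (n_channels, 3).

    x: left(-) to right(+), y: back(-) to front(+), z: up.
    """
    channels = EEG_CHANNELS if channels is None else channels
    out = np.empty((len(channels), 3))
    for i, ch in enumerate(channels):
        try:
            az_deg, radius = _POLAR[ch]
        except KeyError:
            raise KeyError(f"no montage position for channel {ch!r}") from None
        az = np.deg2rad(az_deg)
        pol = radius * np.pi  # radius 0.5 -> pi/2
        out[i] = (np.sin(pol) * np.sin(az), np.sin(pol) * np.cos(az), np.cos(pol))
    return out


def gaussian_topography(center: str, spread: float = 1.0,
                        channels: list[str] | None = None) -> np.ndarray:
    """Unit-max weight per channel, falling off with angular distance from
    ``center``.  ``spread`` is the angular SD in radians."""
    channels = EEG_CHANNELS if channels is None else channels
    pos = positions(channels)
    c = positions([center])[0]
    ang = np.arccos(np.clip(pos @ c, -1.0, 1.0))
    w = np.exp(-0.5 * (ang / spread) ** 2)
    return w / w.max()
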