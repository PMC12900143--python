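"""The 14-electrode consumer-headset montage (10-20 naming).

Channel order follows the headset's export order: AF3, F7, F3, FC5, T7,
P7, O1, O2, P8, T8, FC6, F4, F8, AF4. Letters encode scalp region
(AF/F frontal, FC fronto-central, T temporal, P parietal, O occipital);
odd digits are left-hemisphere sites, even digits right-hemisphere.

Two coordinate sets are exposed:

* ``pos2d`` — unit-head-disk projections used for topographic maps,
  derived from the standard 10-20 montage shipped with MNE via an
  azimuthal-equidistant projection and symmetrized across homologous
  left/right pairs so mirrored inputs render mirrored maps exactly.
* ``mni`` — MNI152 coordinates (mm) for region annotation. Seven sites
  carry published per-study coordinates (provenance ``"paper"``); the
  remainder are filled by mirroring a contralateral published homologue
  or from a standard rounded 10-20→MNI atlas (provenance ``"standard"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .errors import MontageError

__all__ = ["CHANNELS", "Montage", "mni_lookup", "MNI_TABLE", "HOMOLOGOUS_PAIRS"]

CHANNELS = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

HOMOLOGOUS_PAIRS = (
    ("AF3", "AF4"), ("F7", "F8"), ("F3", "F4"), ("FC5", "FC6"),
    ("T7", "T8"), ("P7", "P8"), ("O1", "O2"),
)

# MNI152 coordinates in mm. "paper" entries are pinned study values;
# "mirror" marks sign-flipped x of a paper homologue, "atlas" a rounded
# standard 10-20 -> MNI table; both are reported with provenance "standard".
_MNI_RAW = {
    "FC6": ((12.0, 34.0, 52.0), "paper"),
    "FC5": ((-52.0, 12.0, 34.0), "paper"),
    "AF4": ((30.0, 50.0, 36.0), "paper"),
    "P7": ((-52.0, -73.0, 12.0), "paper"),
    "T8": ((64.0, -18.0, 8.0), "paper"),
    "F4": ((36.0, 34.0, 50.0), "paper"),
    "F7": ((-52.0, 32.0, 2.0), "paper"),
    "AF3": ((-30.0, 50.0, 36.0), "mirror"),   # from AF4
    "F3": ((-36.0, 34.0, 50.0), "mirror"),    # from F4
    "F8": ((52.0, 32.0, 2.0), "mirror"),      # from F7
    "T7": ((-64.0, -18.0, 8.0), "mirror"),    # from T8
    "P8": ((52.0, -73.0, 12.0), "mirror"),    # from P7
    "O1": ((-26.0, -94.0, 8.0), "atlas"),
    "O2": ((26.0, -94.0, 8.0), "atlas"),
}

MNI_TABLE = {
    label: {"xyz": xyz, "provenance": "paper" if kind == "paper" else "standard"}
    for label, (xyz, kind) in _MNI_RAW.items()
}


def mni_lookup(label: str) -> tuple:
    """MNI152 ``(x, y, z)`` in mm for a montage electrode."""
    try:
        return MNI_TABLE[label]["xyz"]
    except KeyError:
        raise MontageError(f"unknown electrode label {label!r}") from None


@lru_cache(maxsize=1)
def _standard_positions_2d() -> dict:
    """Project the standard 10-20 3-D positions onto the unit head disk.

    Azimuthal-equidistant projection about the vertex: radius is
    proportional to the polar angle from the +z axis, direction is the
    (x, y) azimuth. Homologous pairs are averaged with their mirror so
    the layout is exactly left-right symmetric; radii are scaled so the
    outermost electrode sits at 1.0.
    """
    import warnings

    import mne  # local import: montage data ships with the package

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        try:  # renamed across MNE versions, identical positions
            montage = mne.channels.make_standard_montage("colin27_1020")
        except ValueError:
            montage = mne.channels.make_standard_montage("standard_1020")
    pos3d = montage.get_positions()["ch_pos"]
    raw = {}
    for label in CHANNELS:
        x, y, z = pos3d[label]
        rho = np.hypot(x, y)
        polar = np.arctan2(rho, z)  # angle from vertex
        if rho == 0:
            raw[label] = (0.0, 0.0)
        else:
            raw[label] = (polar * x / rho, polar * y / rho)
    # enforce exact mirror symmetry
    sym = dict(raw)
    for left, right in HOMOLOGOUS_PAIRS:
        lx, ly = raw[left]
        rx, ry = raw[right]
        x = (abs(lx) + abs(rx)) / 2.0
        y = (ly + ry) / 2.0
        sym[left] = (-x, y)
        sym[right] = (x, y)
    scale = max(np.hypot(x, y) for x, y in sym.values())
    return {label: (x / scale, y / scale) for label, (x, y) in sym.items()}


@dataclass(frozen=True)
class Montage:
    """Ordered 14-channel montage with 2-D and MNI coordinates."""

    labels: tuple = CHANNELS

    def __post_init__(self) -> None:
        if len(self.labels) != 14 or len(set(self.labels)) != 14:
            raise MontageError("montage requires exactly 14 unique labels")
        unknown = [lb for lb in self.labels if lb not in CHANNELS]
        if unknown:
            raise MontageError(f"labels not in the 14-channel montage: {unknown}")

    @property
    def pos2d(self) -> dict:
        """Label → (x, y) on the unit head disk (x > 0 is right)."""
        return {label: _standard_positions_2d()[label] for label in self.labels}

    @property
    def mni(self) -> dict:
        """Label → MNI152 (x, y, z) in mm."""
        return {label: mni_lookup(label) for label in self.labels}

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise MontageError(f"unknown electrode label {label!r}") from None

    def indices(self, labels) -> list:
        return [self.index(label) for label in labels]
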