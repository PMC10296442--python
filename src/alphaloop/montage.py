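"""The 16-channel 10-20 montage used throughout the package.

Channel groups follow the conventional functional split: the
occipitoparietal set drives the real-time feedback signal (eyes-closed
alpha is strongest there), the central set is reported separately in the
offline summaries.
"""

from __future__ import annotations

MONTAGE_16: tuple[str, ...] = (
    "O1", "Oz", "O2", "P3", "Pz", "P4", "C3", "Cz", "C4",
    "T3", "T4", "F7", "F3", "Fz", "F4", "F8",
)

#: channels whose mean IAF is the self-regulated feedback parameter
OCCIPITOPARIETAL: tuple[str, ...] = ("P3", "Pz", "P4", "O1", "Oz", "O2")

CENTRAL: tuple[str, ...] = ("C3", "Cz", "C4")

FRONTOTEMPORAL: tuple[str, ...] = ("T3", "T4", "F7", "F3", "Fz", "F4", "F8")

# Azimuthal-equidistant projection of the idealized 10-20 sphere
# (x: right, y: anterior; head circumference at r = 1, outer electrode
# ring at r = 0.8). Derived-position electrodes (F3/F4/P3/P4) sit midway
# on the great-circle arcs between their 10-20 anchor electrodes.
ELECTRODE_XY: dict[str, tuple[float, float]] = {
    "O1": (-0.2472, -0.7608),
    "Oz": (0.0000, -0.8000),
    "O2": (0.2472, -0.7608),
    "P3": (-0.3158, -0.4706),
    "Pz": (0.0000, -0.4000),
    "P4": (0.3158, -0.4706),
    "C3": (-0.4000, 0.0000),
    "Cz": (0.0000, 0.0000),
    "C4": (0.4000, 0.0000),
    "T3": (-0.8000, 0.0000),
    "T4": (0.8000, 0.0000),
    "F7": (-0.6472, 0.4702),
    "F3": (-0.3158, 0.4706),
    "Fz": (0.0000, 0.4000),
    "F4": (0.3158, 0.4706),
    "F8": (0.6472, 0.4702),
}
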