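"""Electrode montage geometry and channel-set selection.

Electrode positions are computed on an idealized spherical head following the
10-20 / 10-10 placement scheme: the nasion-inion and left-right preauricular
arcs are divided in 10 % steps (18 degrees), intermediate rows are placed by
great-circle interpolation between their midline and outer-ring anchors.
Coordinates are expressed in a vertex-origin frame: Cz at (0, 0, 0),
+x toward the right preauricular point, +y toward the nasion, +z up, in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

HEAD_RADIUS_MM = 90.0

#: Sphere center in the vertex-origin frame (Cz sits on top of the sphere).
SPHERE_CENTER = np.array([0.0, 0.0, -HEAD_RADIUS_MM])


class Hemisphere(str, Enum):
    LEFT = "left"
    RIGHT = "right"


class HotspotSource(str, Enum):
    TMS_GROUND_TRUTH = "tms_ground_truth"
    PREDICTED = "predicted"
    SYNTHETIC_TRUTH = "synthetic_truth"


@dataclass(frozen=True)
class HotspotLocation:
    """A 3D point in the vertex-origin head frame (mm)."""

    x: float
    y: float
    z: float
    hemisphere: Hemisphere
    source: HotspotSource

    @classmethod
    def from_array(cls, xyz, source) -> "HotspotLocation":
        x, y, z = (float(v) for v in np.asarray(xyz, dtype=float))
        hemi = Hemisphere.LEFT if x < 0 else Hemisphere.RIGHT
        return cls(x, y, z, hemi, HotspotSource(source))

    def to_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


def _direction(polar_deg: float, azimuth_deg: float) -> np.ndarray:
    """Unit vector on the head sphere.

    polar: angle from the vertex axis (+z). azimuth: 0 = anterior (+y),
    +90 = right (+x), -90 = left, 180 = posterior.
    """
    th = np.deg2rad(polar_deg)
    az = np.deg2rad(azimuth_deg)
    return np.array([np.sin(th) * np.sin(az), np.sin(th) * np.cos(az), np.cos(th)])


def _slerp(u: np.ndarray, v: np.ndarray, t: float) -> np.ndarray:
    omega = np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))
    if omega < 1e-12:
        return u
    return (np.sin((1 - t) * omega) * u + np.sin(t * omega) * v) / np.sin(omega)


def _build_unit_positions() -> dict[str, np.ndarray]:
    """Unit-sphere direction for every 10-10 label the montages use."""
    pos: dict[str, np.ndarray] = {}

    # Sagittal midline, 18 degrees per 10 % step.
    midline = {
        "Fpz": (72, 0), "AFz": (54, 0), "Fz": (36, 0), "FCz": (18, 0),
        "Cz": (0, 0),
        "CPz": (18, 180), "Pz": (36, 180), "POz": (54, 180), "Oz": (72, 180),
    }
    # Central coronal arc (through the preauricular points).
    coronal = {"C1": 18, "C3": 36, "C5": 54, "T7": 72}
    # Outer 10 % ring at 72 degrees polar, parametrized by azimuth;
    # left-hemisphere azimuths are negative.
    ring = {
        "Fp1": -18, "AF7": -36, "F7": -54, "FT7": -72, "TP7": -108,
        "P7": -126, "PO7": -144, "O1": -162,
    }
    # Inferior ring 10 % below (90 degrees polar).
    lower = {"FT9": -72, "TP9": -108, "PO9": -144}

    for lab, (polar, az) in midline.items():
        pos[lab] = _direction(polar, az)
    for lab, polar in coronal.items():
        pos[lab] = _direction(polar, -90)
        pos[_mirror_label(lab)] = _direction(polar, 90)
    for lab, az in ring.items():
        pos[lab] = _direction(72, az)
        pos[_mirror_label(lab)] = _direction(72, -az)
    for lab, az in lower.items():
        pos[lab] = _direction(90, az)
        pos[_mirror_label(lab)] = _direction(90, -az)

    # Intermediate rows: great-circle interpolation between the midline
    # anchor and the outer-ring anchor of the same row.
    rows = [
        ("AFz", "AF7", {"AF3": 0.5}),
        ("Fz", "F7", {"F1": 0.25, "F3": 0.5, "F5": 0.75}),
        ("FCz", "FT7", {"FC1": 0.25, "FC3": 0.5, "FC5": 0.75}),
        ("CPz", "TP7", {"CP1": 0.25, "CP3": 0.5, "CP5": 0.75}),
        ("Pz", "P7", {"P1": 0.25, "P3": 0.5, "P5": 0.75}),
        ("POz", "PO7", {"PO3": 0.5}),
    ]
    for mid, outer, members in rows:
        for lab, t in members.items():
            pos[lab] = _slerp(pos[mid], pos[outer], t)
            pos[_mirror_label(lab)] = pos[lab] * np.array([-1.0, 1.0, 1.0])
    return pos


def _mirror_label(label: str) -> str:
    """C3 -> C4, FT9 -> FT10, odd left-hemisphere index -> even right."""
    head = label.rstrip("0123456789")
    num = int(label[len(head):])
    return f"{head}{num + 1}" if num % 2 == 1 else f"{head}{num - 1}"


# 63 recorded channels of the healthy-cohort cap (ground Fpz and reference
# FCz are not data channels).
HEALTHY63_LABELS = [
    "Fp1", "Fp2", "AF7", "AF3", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT9", "FT7", "FC5", "FC3", "FC1", "FC2", "FC4", "FC6", "FT8", "FT10",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "TP10",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO9", "PO7", "PO3", "PO4", "PO8", "PO10",
    "O1", "Oz", "O2",
]

# 29 recorded channels of the stroke-cohort cap.
STROKE29_LABELS = [
    "Fp1", "Fp2",
    "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CPz", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
]


@dataclass(frozen=True)
class ElectrodeMontage:
    name: str
    labels: tuple[str, ...]
    positions: dict[str, np.ndarray] = field(repr=False)
    head_radius: float = HEAD_RADIUS_MM

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate channel labels in montage")
        if set(self.positions) != set(self.labels):
            raise ValueError("positions must have exactly one entry per label")
        for lab in ("Fpz", "FCz"):
            if lab in self.labels:
                raise ValueError(f"{lab} is a ground/reference site, not a data channel")

    @property
    def cohort(self) -> str:
        return "healthy" if len(self.labels) > 32 else "stroke"

    def position(self, label: str) -> np.ndarray:
        return self.positions[label]

    def position_matrix(self, labels=None) -> np.ndarray:
        labels = self.labels if labels is None else labels
        return np.stack([self.positions[lab] for lab in labels])


def load_montage(name: str) -> ElectrodeMontage:
    """Build one of the two shipped montages ('healthy63' or 'stroke29')."""
    layouts = {"healthy63": HEALTHY63_LABELS, "stroke29": STROKE29_LABELS}
    if name not in layouts:
        raise ValueError(
            f"unknown montage {name!r}; valid options: {sorted(layouts)}"
        )
    unit = _build_unit_positions()
    labels = tuple(layouts[name])
    # Scale to the head sphere, then shift the origin to the vertex (0, 0, R).
    positions = {
        lab: unit[lab] * HEAD_RADIUS_MM - np.array([0.0, 0.0, HEAD_RADIUS_MM])
        for lab in labels
    }
    return ElectrodeMontage(name=name, labels=labels, positions=positions)


# ---------------------------------------------------------------------------
# Channel sets


@dataclass(frozen=True)
class ChannelSet:
    set_id: str
    labels: tuple[str, ...]
    hand: str  # left | right | both

    def __len__(self):
        return len(self.labels)


def _rows(montage: ElectrodeMontage, prefixes: tuple[str, ...]) -> list[str]:
    def row_of(label: str) -> str:
        return label.rstrip("0123456789").rstrip("z")
    return [lab for lab in montage.labels if row_of(lab) in prefixes]


def _lateralize(labels: list[str], hemisphere: str) -> list[str]:
    """Keep midline plus one hemisphere (odd index = left, even = right)."""
    out = []
    for lab in labels:
        digits = lab.lstrip("ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz")
        if not digits:
            continue  # midline excluded from hand-specific motor sets
        odd = int(digits) % 2 == 1
        if (hemisphere == "left") == odd:
            out.append(lab)
    return out


# Hand-specific membership of the small motor sets, given for the right hand
# (contralateral = left hemisphere); mirrored for the left hand.
_HEALTHY_SET5_RIGHT = ["FC5", "FC3", "FC1", "C5", "C3", "C1", "CP5", "CP3", "CP1"]
_STROKE_SET3_RIGHT = ["FC5", "FC1", "C3", "CP5", "CP1"]


def _mirror_set(labels: list[str]) -> list[str]:
    return [_mirror_label(lab) for lab in labels]


def select_channel_set(
    montage: ElectrodeMontage,
    set_id: str,
    hand: str = "both",
    overrides: dict[str, list[str]] | None = None,
) -> ChannelSet:
    """Return the configured label subset, in montage order.

    Healthy cohort: Set1 (63) .. Set5 (9 channels around the contralateral
    motor area); stroke cohort: Set1 (29) .. Set3 (5 channels).  `overrides`
    maps set_id to an explicit label list.
    """
    if hand not in ("left", "right", "both"):
        raise ValueError(f"hand must be left/right/both, got {hand!r}")
    cohort = montage.cohort
    valid = {"healthy": ["Set1", "Set2", "Set3", "Set4", "Set5"],
             "stroke": ["Set1", "Set2", "Set3"]}[cohort]
    if set_id not in valid:
        raise ValueError(
            f"channel set {set_id!r} is not defined for the {cohort} montage; "
            f"valid: {valid}"
        )

    if overrides and set_id in overrides:
        members = list(overrides[set_id])
    elif cohort == "healthy":
        if set_id == "Set1":
            members = list(montage.labels)
        elif set_id == "Set2":
            members = _rows(montage, ("F", "FC", "C", "CP", "P", "FT", "T", "TP"))
        elif set_id == "Set3":
            members = _rows(montage, ("FC", "C", "CP", "FT", "T", "TP"))
        elif set_id == "Set4":
            base = _rows(montage, ("FC", "C", "CP", "FT", "T", "TP"))
            members = _pick_hand(base, hand, lateralized=True)
        else:  # Set5
            members = _pick_hand_explicit(_HEALTHY_SET5_RIGHT, hand)
    else:
        if set_id == "Set1":
            members = list(montage.labels)
        elif set_id == "Set2":
            members = _rows(montage, ("FC", "C", "CP", "T"))
        else:  # Set3
            members = _pick_hand_explicit(_STROKE_SET3_RIGHT, hand)

    unknown = [m for m in members if m not in montage.labels]
    if unknown:
        raise ValueError(f"channel-set members not in montage: {unknown}")
    ordered = tuple(lab for lab in montage.labels if lab in set(members))
    return ChannelSet(set_id=set_id, labels=ordered, hand=hand)


def _pick_hand(base: list[str], hand: str, lateralized: bool) -> list[str]:
    if hand == "both":
        return _lateralize(base, "left") + _lateralize(base, "right")
    # right hand -> contralateral (left) hemisphere
    hemisphere = "left" if hand == "right" else "right"
    return _lateralize(base, hemisphere)


def _pick_hand_explicit(right_hand_members: list[str], hand: str) -> list[str]:
    if hand == "right":
        return list(right_hand_members)
    if hand == "left":
        return _mirror_set(right_hand_members)
    return list(right_hand_members) + _mirror_set(right_hand_members)
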