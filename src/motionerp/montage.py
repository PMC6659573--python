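"""Idealized 10:10 electrode montage on the unit sphere.

The montage is constructed geometrically from the proportional 10:10
placement system rather than loaded from a digitized cap file: midline and
circumferential ("10%" ring) electrodes are placed at multiples of 18 deg of
arc, and intermediate electrodes are placed by great-circle (slerp)
interpolation between their midline and ring anchors.  This reproduces the
standard idealized spherical layout used by ERP software for spline
interpolation and current-source-density estimation, and removes any runtime
dependency on external electrode files.

Coordinate convention (documented and enforced): unit sphere, +x toward the
right ear, +y anterior (nasion), +z superior (vertex).  Left-hemisphere
labels (odd digits, "7"/"9" suffixes) therefore have x < 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MontageError, ParseError

# Polar angle (deg from vertex) of the circumferential 10% ring.
_RING_POLAR = 72.0

# Ring electrodes: azimuth in degrees measured from the anterior midline,
# positive toward the right ear.  20 positions, 18 deg apart.
_RING_AZIMUTH = {
    "Fpz": 0.0, "Fp2": 18.0, "AF8": 36.0, "F8": 54.0, "FT8": 72.0,
    "T8": 90.0, "TP8": 108.0, "P8": 126.0, "PO8": 144.0, "O2": 162.0,
    "Oz": 180.0, "O1": -162.0, "PO7": -144.0, "P7": -126.0, "TP7": -108.0,
    "T7": -90.0, "FT7": -72.0, "F7": -54.0, "AF7": -36.0, "Fp1": -18.0,
}

# Midline electrodes: (polar angle deg from vertex, azimuth 0=anterior or
# 180=posterior).  10% steps of the nasion-inion arc are 18 deg.
_MIDLINE = {
    "Fpz": (72.0, 0.0), "AFz": (54.0, 0.0), "Fz": (36.0, 0.0),
    "FCz": (18.0, 0.0), "Cz": (0.0, 0.0), "CPz": (18.0, 180.0),
    "Pz": (36.0, 180.0), "POz": (54.0, 180.0), "Oz": (72.0, 180.0),
}

# Inferior ring (10% below the T7/T8 line): polar angle 90 deg.
_INFERIOR = {
    "FT9": (90.0, -72.0), "FT10": (90.0, 72.0),
    "TP9": (90.0, -108.0), "TP10": (90.0, 108.0),
}

# Intermediate electrodes: (midline anchor, ring anchor, arc fraction from
# the midline anchor).  One entry per hemisphere.
_INTERMEDIATE = {
    "AF3": ("AFz", "AF7", 0.5), "AF4": ("AFz", "AF8", 0.5),
    "F1": ("Fz", "F7", 0.25), "F3": ("Fz", "F7", 0.5), "F5": ("Fz", "F7", 0.75),
    "F2": ("Fz", "F8", 0.25), "F4": ("Fz", "F8", 0.5), "F6": ("Fz", "F8", 0.75),
    "FC1": ("FCz", "FT7", 0.25), "FC3": ("FCz", "FT7", 0.5), "FC5": ("FCz", "FT7", 0.75),
    "FC2": ("FCz", "FT8", 0.25), "FC4": ("FCz", "FT8", 0.5), "FC6": ("FCz", "FT8", 0.75),
    "C1": ("Cz", "T7", 0.25), "C3": ("Cz", "T7", 0.5), "C5": ("Cz", "T7", 0.75),
    "C2": ("Cz", "T8", 0.25), "C4": ("Cz", "T8", 0.5), "C6": ("Cz", "T8", 0.75),
    "CP1": ("CPz", "TP7", 0.25), "CP3": ("CPz", "TP7", 0.5), "CP5": ("CPz", "TP7", 0.75),
    "CP2": ("CPz", "TP8", 0.25), "CP4": ("CPz", "TP8", 0.5), "CP6": ("CPz", "TP8", 0.75),
    "P1": ("Pz", "P7", 0.25), "P3": ("Pz", "P7", 0.5), "P5": ("Pz", "P7", 0.75),
    "P2": ("Pz", "P8", 0.25), "P4": ("Pz", "P8", 0.5), "P6": ("Pz", "P8", 0.75),
    "PO3": ("POz", "PO7", 0.5), "PO4": ("POz", "PO8", 0.5),
}

#: The 63-electrode recording set used throughout this package (an actiCAP
#: style 10:10 layout; AFz and Fpz positions are reserved for ground/cap
#: landmarks and are not recorded).
STANDARD_63 = (
    "Fp1", "Fp2",
    "AF7", "AF3", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT9", "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8", "FT10",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "TP10",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
)


def _sph_to_xyz(polar_deg: float, azimuth_deg: float) -> np.ndarray:
    th = np.deg2rad(polar_deg)
    az = np.deg2rad(azimuth_deg)
    return np.array([np.sin(th) * np.sin(az), np.sin(th) * np.cos(az), np.cos(th)])


def _slerp(p0: np.ndarray, p1: np.ndarray, t: float) -> np.ndarray:
    omega = np.arccos(np.clip(p0 @ p1, -1.0, 1.0))
    if omega < 1e-12:
        return p0.copy()
    return (np.sin((1 - t) * omega) * p0 + np.sin(t * omega) * p1) / np.sin(omega)


def _build_positions() -> dict[str, np.ndarray]:
    pos: dict[str, np.ndarray] = {}
    for label, (polar, az) in _MIDLINE.items():
        pos[label] = _sph_to_xyz(polar, az)
    for label, az in _RING_AZIMUTH.items():
        pos[label] = _sph_to_xyz(_RING_POLAR, az)
    for label, (polar, az) in _INFERIOR.items():
        pos[label] = _sph_to_xyz(polar, az)
    for label, (mid, ring, frac) in _INTERMEDIATE.items():
        pos[label] = _slerp(pos[mid], pos[ring], frac)
    return {k: v / np.linalg.norm(v) for k, v in pos.items()}


_ALL_POSITIONS = _build_positions()


@dataclass(frozen=True)
class Montage:
    """Electrode labels with unit-sphere positions.

    Attributes
    ----------
    labels : tuple of str
        Electrode labels, in canonical order.
    positions : ndarray, shape (n, 3)
        Unit-norm cartesian positions (+x right, +y anterior, +z superior).
    """

    labels: tuple[str, ...]
    positions: np.ndarray = field(repr=False)

    def __post_init__(self):
        if len(self.labels) != len(set(self.labels)):
            raise MontageError("duplicate electrode labels in montage")
        norms = np.linalg.norm(self.positions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise MontageError("montage positions must be unit-norm")

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    def position(self, label: str) -> np.ndarray:
        """Return the unit-sphere position of ``label`` (raises on unknown)."""
        try:
            i = self.labels.index(label)
        except ValueError:
            raise MontageError(f"electrode {label!r} not in montage") from None
        return self.positions[i]

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise MontageError(f"electrode {label!r} not in montage") from None

    def subset(self, labels) -> "Montage":
        idx = [self.index(lb) for lb in labels]
        return Montage(tuple(labels), self.positions[idx])

    def cosines(self, other: "Montage | None" = None) -> np.ndarray:
        """Matrix of cosine angular distances between electrode pairs."""
        q = self.positions if other is None else other.positions
        return np.clip(self.positions @ q.T, -1.0, 1.0)

    def to_table(self) -> str:
        """Plain-text table ``label\\tx\\ty\\tz`` (one electrode per line)."""
        lines = ["label\tx\ty\tz"]
        for lb, p in zip(self.labels, self.positions):
            lines.append(f"{lb}\t{p[0]:.6f}\t{p[1]:.6f}\t{p[2]:.6f}")
        return "\n".join(lines) + "\n"


def load_montage(name_or_path: str = "standard-63") -> Montage:
    """Load a montage by name or from a plain-text position table.

    ``"standard-63"`` (the default) is the package's built-in idealized 10:10
    layout with 63 recorded electrodes.  Any other argument is read as a
    whitespace-separated table with a ``label x y z`` header; positions are
    projected to the unit sphere.
    """
    if name_or_path == "standard-63":
        pos = np.array([_ALL_POSITIONS[lb] for lb in STANDARD_63])
        return Montage(STANDARD_63, pos)
    labels: list[str] = []
    rows: list[list[float]] = []
    with open(name_or_path) as fh:
        header = fh.readline().split()
        if header[:1] != ["label"]:
            raise ParseError("montage table must start with a 'label' header", line=1)
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ParseError(f"expected 4 columns, got {len(parts)}", line=ln)
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    p = np.asarray(rows, dtype=float)
    norms = np.linalg.norm(p, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise MontageError("zero-length electrode position in montage table")
    return Montage(tuple(labels), p / norms)
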