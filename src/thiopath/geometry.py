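"""XYZ transition-state structures and bond-elongation checks.

A located transition state should show its breaking/forming bonds stretched
to roughly 20-40 % beyond the covalent single-bond length — e.g. a forming
C...S contact near 2.4 A against the 1.82 A single bond. This module reads
plain XYZ files (single- or multi-frame), measures interatomic distances
and classifies each watched contact against a configurable window.

Distances are angstrom throughout; no unit auto-detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import numpy as np
import pandas as pd

from .constants import COVALENT_SINGLE_BOND_A, ELONGATION_WINDOW_DEFAULT

__all__ = [
    "XYZStructure",
    "BondChangeSpec",
    "BondReferenceConfig",
    "ElongationVerdict",
    "XYZParseError",
    "GeometryError",
    "read_xyz",
    "read_xyz_file",
    "write_xyz",
    "distance",
    "elongation_check",
    "check_structure",
]


class XYZParseError(ValueError):
    """Malformed XYZ input; message carries the 1-based line number."""


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class XYZStructure:
    """One frame of a standard XYZ file."""

    comment: str
    symbols: tuple[str, ...]
    coordinates: np.ndarray  # (n, 3) float, angstrom

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise GeometryError(f"coordinates must be (n, 3), got {coords.shape}")
        if coords.shape[0] != len(self.symbols):
            raise GeometryError(
                f"{len(self.symbols)} symbols but {coords.shape[0]} coordinate rows"
            )
        if not np.all(np.isfinite(coords)):
            raise GeometryError("non-finite coordinates")
        object.__setattr__(self, "coordinates", coords)

    def __len__(self) -> int:
        return len(self.symbols)


def read_xyz(stream: TextIO | str) -> list[XYZStructure]:
    """Parse single- or multi-frame XYZ text into a list of structures.

    Errors name the offending 1-based line number.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()
    frames: list[XYZStructure] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():  # tolerate blank separator lines
            i += 1
            continue
        try:
            count = int(lines[i].strip())
        except ValueError:
            raise XYZParseError(
                f"line {i + 1}: expected atom count, got {lines[i]!r}"
            ) from None
        if count <= 0:
            raise XYZParseError(f"line {i + 1}: atom count must be positive")
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        symbols: list[str] = []
        coords: list[list[float]] = []
        for k in range(count):
            ln = i + 2 + k
            if ln >= len(lines):
                raise XYZParseError(
                    f"line {i + 1}: header declares {count} atoms but input "
                    f"ends after {k} atom line(s)"
                )
            parts = lines[ln].split()
            if len(parts) < 4:
                raise XYZParseError(
                    f"line {ln + 1}: expected 'symbol x y z', got {lines[ln]!r}"
                )
            try:
                xyz = [float(p) for p in parts[1:4]]
            except ValueError:
                raise XYZParseError(
                    f"line {ln + 1}: non-numeric coordinate in {lines[ln]!r}"
                ) from None
            symbols.append(parts[0])
            coords.append(xyz)
        frames.append(XYZStructure(comment, tuple(symbols), np.array(coords)))
        i += 2 + count
    if not frames:
        raise XYZParseError("line 1: empty XYZ input")
    return frames


def read_xyz_file(path) -> list[XYZStructure]:
    with open(path) as fh:
        return read_xyz(fh)


def write_xyz(frames: XYZStructure | Iterable[XYZStructure], stream: TextIO) -> None:
    """Write one or more frames in standard XYZ layout (fixed 10-dp floats)."""
    if isinstance(frames, XYZStructure):
        frames = [frames]
    for frame in frames:
        stream.write(f"{len(frame)}\n{frame.comment}\n")
        for sym, (x, y, z) in zip(frame.symbols, frame.coordinates):
            stream.write(f"{sym} {x:.10f} {y:.10f} {z:.10f}\n")


def distance(s: XYZStructure, i: int, j: int) -> float:
    """Euclidean distance between atoms i and j (angstrom)."""
    n = len(s)
    for idx in (i, j):
        if not 0 <= idx < n:
            raise GeometryError(f"atom index {idx} out of range for {n} atoms")
    return float(np.linalg.norm(s.coordinates[i] - s.coordinates[j]))


@dataclass(frozen=True)
class BondChangeSpec:
    """A breaking or forming contact to watch in a TS structure."""

    i: int
    j: int
    role: str  # "breaking" | "forming"
    bond_class: str  # e.g. "C-S"

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise GeometryError("bond indices must be distinct")
        if self.role not in ("breaking", "forming"):
            raise GeometryError(f"role must be breaking|forming, got {self.role!r}")


@dataclass(frozen=True)
class BondReferenceConfig:
    """Reference single-bond lengths and elongation windows.

    Proton-transfer contacts (H on both windows' donor/acceptor axis) tend
    to sit closer to the covalent length than heavy-atom breaking/forming
    bonds, so transfer classes may carry their own window via
    ``class_windows``.
    """

    reference_lengths: dict[str, float] = field(
        default_factory=lambda: dict(COVALENT_SINGLE_BOND_A)
    )
    window: tuple[float, float] = ELONGATION_WINDOW_DEFAULT
    class_windows: dict[str, tuple[float, float]] = field(default_factory=dict)

    def window_for(self, bond_class: str) -> tuple[float, float]:
        return self.class_windows.get(bond_class, self.window)


def _normalize_class(bond_class: str) -> str:
    parts = bond_class.replace("...", "-").replace("…", "-").split("-")
    if len(parts) != 2:
        raise GeometryError(f"cannot parse bond class {bond_class!r}")
    return "-".join(sorted(p.strip() for p in parts))


@dataclass(frozen=True)
class ElongationVerdict:
    bond_class: str
    distance: float
    reference: float
    ratio: float
    verdict: str  # "within-window" | "short" | "long"


def elongation_check(
    dist: float,
    bond_class: str,
    config: BondReferenceConfig | None = None,
) -> ElongationVerdict:
    """Classify a TS contact by its elongation ratio over the single bond.

    ratio = distance / reference; the default window is [1.20, 1.40].
    """
    config = config or BondReferenceConfig()
    key = _normalize_class(bond_class)
    lookup = {_normalize_class(k): v for k, v in config.reference_lengths.items()}
    if key not in lookup:
        raise GeometryError(
            f"no reference length configured for bond class {bond_class!r}"
        )
    if dist <= 0 or not math.isfinite(dist):
        raise GeometryError(f"invalid distance {dist!r}")
    ref = lookup[key]
    ratio = dist / ref
    lo, hi = config.window_for(key)
    if ratio < lo:
        verdict = "short"
    elif ratio > hi:
        verdict = "long"
    else:
        verdict = "within-window"
    return ElongationVerdict(key, dist, ref, ratio, verdict)


def check_structure(
    structure: XYZStructure,
    specs: Sequence[BondChangeSpec],
    config: BondReferenceConfig | None = None,
    name: str = "",
) -> pd.DataFrame:
    """Measure and classify every watched contact of one structure.

    Returns a tidy frame: (structure, pair, role, class, distance_A, ratio,
    verdict) — the CSV report schema.
    """
    rows = []
    for spec in specs:
        d = distance(structure, spec.i, spec.j)
        v = elongation_check(d, spec.bond_class, config)
        rows.append(
            {
                "structure": name or structure.comment,
                "pair": f"{spec.i}-{spec.j}",
                "role": spec.role,
                "bond_class": v.bond_class,
                "distance_A": v.distance,
                "ratio": v.ratio,
                "verdict": v.verdict,
            }
        )
    return pd.DataFrame(rows)
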