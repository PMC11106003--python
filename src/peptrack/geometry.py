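"""Cylindrical PET scanner geometry.

A scanner is modelled as ``n_rings`` rings of ``n_transaxial`` crystals whose
front faces sit on a cylinder of given radius. Crystal indices map to
millimetre positions in a right-handed frame with the scanner axis along
``z`` and azimuth measured counter-clockwise from ``+x``. The mapping is
fully config-driven: vendor crystal-numbering conventions are proprietary,
so nothing here hard-codes a particular scanner.

Units are millimetres, radians and seconds throughout the package.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import yaml

from .errors import DegenerateLoRError, GeometryBoundsError, OutOfFieldError

__all__ = [
    "ScannerGeometry",
    "CrystalIndex",
    "LoR",
    "DEFAULT_GEOMETRY",
    "load_geometry",
    "save_geometry",
]


class CrystalIndex(NamedTuple):
    """0-based (ring, transaxial) crystal address."""

    ring: int
    transaxial: int


class LoR(NamedTuple):
    """One coincidence: timestamp (s) and the two crystal-face endpoints (mm)."""

    t: float
    p1: np.ndarray
    p2: np.ndarray


@dataclass(frozen=True)
class ScannerGeometry:
    """Cylindrical detector model.

    Parameters
    ----------
    radius_mm:
        Radius of the crystal-face cylinder.
    n_transaxial:
        Crystals per ring (>= 3).
    n_rings:
        Number of rings (>= 1).
    axial_pitch_mm:
        Ring-centre spacing along z.
    axial_origin_mm:
        z of the centre of ring 0.
    angular_origin_rad:
        Azimuth of transaxial index 0.
    """

    radius_mm: float
    n_transaxial: int
    n_rings: int
    axial_pitch_mm: float
    axial_origin_mm: float = 0.0
    angular_origin_rad: float = 0.0

    def __post_init__(self) -> None:
        if not self.radius_mm > 0:
            raise ValueError(f"radius_mm must be > 0, got {self.radius_mm}")
        if self.n_transaxial < 3:
            raise ValueError(f"n_transaxial must be >= 3, got {self.n_transaxial}")
        if self.n_rings < 1:
            raise ValueError(f"n_rings must be >= 1, got {self.n_rings}")
        if not self.axial_pitch_mm > 0:
            raise ValueError(f"axial_pitch_mm must be > 0, got {self.axial_pitch_mm}")

    # ------------------------------------------------------------------ #
    # derived extents

    @property
    def axial_extent_mm(self) -> float:
        """Total axial coverage: n_rings x axial_pitch_mm."""
        return self.n_rings * self.axial_pitch_mm

    @property
    def z_min_mm(self) -> float:
        """Lower axial edge (half a pitch below ring 0's centre)."""
        return self.axial_origin_mm - 0.5 * self.axial_pitch_mm

    @property
    def z_max_mm(self) -> float:
        """Upper axial edge (half a pitch above the last ring's centre)."""
        return (
            self.axial_origin_mm
            + (self.n_rings - 1) * self.axial_pitch_mm
            + 0.5 * self.axial_pitch_mm
        )

    # ------------------------------------------------------------------ #
    # index <-> position

    def _check_index(self, c: CrystalIndex) -> None:
        ring, transaxial = int(c[0]), int(c[1])
        if not 0 <= ring < self.n_rings:
            raise GeometryBoundsError(
                f"ring index {ring} out of bounds [0, {self.n_rings})"
            )
        if not 0 <= transaxial < self.n_transaxial:
            raise GeometryBoundsError(
                f"transaxial index {transaxial} out of bounds [0, {self.n_transaxial})"
            )

    def crystal_to_position(self, c: CrystalIndex | tuple[int, int]) -> np.ndarray:
        """Millimetre position of a crystal centre on the detector cylinder."""
        self._check_index(c)  # type: ignore[arg-type]
        ring, transaxial = int(c[0]), int(c[1])
        theta = self.angular_origin_rad + 2.0 * math.pi * transaxial / self.n_transaxial
        return np.array(
            [
                self.radius_mm * math.cos(theta),
                self.radius_mm * math.sin(theta),
                self.axial_origin_mm + ring * self.axial_pitch_mm,
            ]
        )

    def crystals_to_positions(
        self, rings: np.ndarray, transaxials: np.ndarray
    ) -> np.ndarray:
        """Vectorised :meth:`crystal_to_position` -> (n, 3) array."""
        rings = np.asarray(rings, dtype=np.int64)
        transaxials = np.asarray(transaxials, dtype=np.int64)
        if rings.size and (rings.min() < 0 or rings.max() >= self.n_rings):
            bad = rings[(rings < 0) | (rings >= self.n_rings)][0]
            raise GeometryBoundsError(
                f"ring index {bad} out of bounds [0, {self.n_rings})"
            )
        if transaxials.size and (
            transaxials.min() < 0 or transaxials.max() >= self.n_transaxial
        ):
            bad = transaxials[(transaxials < 0) | (transaxials >= self.n_transaxial)][0]
            raise GeometryBoundsError(
                f"transaxial index {bad} out of bounds [0, {self.n_transaxial})"
            )
        theta = self.angular_origin_rad + 2.0 * np.pi * transaxials / self.n_transaxial
        return np.column_stack(
            [
                self.radius_mm * np.cos(theta),
                self.radius_mm * np.sin(theta),
                self.axial_origin_mm + rings * self.axial_pitch_mm,
            ]
        )

    def lor_from_crystals(
        self,
        t: float,
        c1: CrystalIndex | tuple[int, int],
        c2: CrystalIndex | tuple[int, int],
    ) -> LoR:
        """Build a line of response between two distinct crystals."""
        if tuple(c1) == tuple(c2):
            raise DegenerateLoRError(f"coincident crystals {tuple(c1)} give no line")
        if t < 0:
            raise ValueError(f"timestamp must be >= 0, got {t}")
        return LoR(float(t), self.crystal_to_position(c1), self.crystal_to_position(c2))

    def nearest_crystal(self, p: np.ndarray) -> CrystalIndex:
        """Crystal whose centre is closest in azimuth and z.

        Azimuth and z are rounded independently; exact half-way ties break
        toward the lower index. Points further than half a pitch outside the
        axial extent raise :class:`OutOfFieldError`.
        """
        ring, transaxial = self.nearest_crystals(np.asarray(p, dtype=float)[None, :])
        return CrystalIndex(int(ring[0]), int(transaxial[0]))

    def nearest_crystals(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised :meth:`nearest_crystal` -> (rings, transaxials)."""
        points = np.asarray(points, dtype=float)
        az = np.arctan2(points[:, 1], points[:, 0])
        v = (az - self.angular_origin_rad) / (2.0 * np.pi / self.n_transaxial)
        transaxial = _round_half_down(v) % self.n_transaxial

        w = (points[:, 2] - self.axial_origin_mm) / self.axial_pitch_mm
        if w.size:
            out = (w < -0.5 - 1e-12) | (w > self.n_rings - 0.5 + 1e-12)
            if out.any():
                raise OutOfFieldError(
                    f"z = {points[out, 2][0]:.6g} mm outside axial extent "
                    f"[{self.z_min_mm:.6g}, {self.z_max_mm:.6g}] mm"
                )
        ring = np.clip(_round_half_down(w), 0, self.n_rings - 1)
        return ring, transaxial

    def snap_to_crystals(self, points: np.ndarray) -> np.ndarray:
        """Replace each point by its nearest crystal centre."""
        ring, transaxial = self.nearest_crystals(points)
        return self.crystals_to_positions(ring, transaxial)

    # ------------------------------------------------------------------ #
    # config I/O

    def to_dict(self) -> dict:
        return asdict(self)


def _round_half_down(v: np.ndarray) -> np.ndarray:
    """Round to nearest integer, exact .5 ties toward the lower integer."""
    k = np.floor(v + 0.5)
    halfway = (v + 0.5) == k
    k = np.where(halfway, k - 1, k)
    return k.astype(np.int64)


#: Desk-scale stand-in approximating a pre-clinical small-animal scanner
#: (radius 120 mm, 480 crystals/ring, 80 rings at 1.2 mm pitch, axially
#: centred on z = 0). Plausible for tests; not a claim about any real scanner.
DEFAULT_GEOMETRY = ScannerGeometry(
    radius_mm=120.0,
    n_transaxial=480,
    n_rings=80,
    axial_pitch_mm=1.2,
    axial_origin_mm=-47.4,
    angular_origin_rad=0.0,
)


_GEOMETRY_KEYS = {
    "radius_mm",
    "n_transaxial",
    "n_rings",
    "axial_pitch_mm",
    "axial_origin_mm",
    "angular_origin_rad",
}


def load_geometry(path: str | Path) -> ScannerGeometry:
    """Read a geometry config (JSON or YAML by extension)."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: geometry config must be a mapping")
    unknown = set(data) - _GEOMETRY_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown geometry keys {sorted(unknown)}")
    return ScannerGeometry(**data)


def save_geometry(geom: ScannerGeometry, path: str | Path) -> None:
    """Write a geometry config (JSON or YAML by extension)."""
    path = Path(path)
    data = geom.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
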