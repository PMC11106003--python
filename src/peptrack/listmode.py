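"""List-mode coincidence stream I/O.

Three dialects are supported:

``crystal``
    CSV with header ``t_s,ring1,cry1,ring2,cry2`` — the native "timestamp plus
    crystal index" export; needs a :class:`~peptrack.geometry.ScannerGeometry`
    to turn indices into millimetre endpoints.
``physical``
    CSV with header ``t_s,x1_mm,y1_mm,z1_mm,x2_mm,y2_mm,z2_mm`` — endpoints
    already in scanner coordinates.
``binary``
    Little-endian records of float64 timestamp + 6 x float32 endpoints behind
    a 16-byte header (8-byte magic ``PEPTLM01`` + uint64 record count).

Both CSV dialects accept an optional trailing boolean ``rejected`` column
(delayed-window randoms flagged upstream); flagged rows are dropped on read.
Gzip-compressed CSV is accepted transparently by a ``.gz`` extension.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ListModeParseError, ListModeValidationError
from .geometry import LoR, ScannerGeometry

__all__ = ["ListModeStream", "read_listmode", "write_listmode", "DIALECTS"]

DIALECTS = ("crystal", "physical", "binary")

_MAGIC = b"PEPTLM01"
_RECORD = struct.Struct("<d6f")  # float64 t + 6 x float32 endpoint coords

_CRYSTAL_COLS = ["t_s", "ring1", "cry1", "ring2", "cry2"]
_PHYSICAL_COLS = ["t_s", "x1_mm", "y1_mm", "z1_mm", "x2_mm", "y2_mm", "z2_mm"]

#: relative tolerance for the endpoint-on-cylinder check of physical streams
_CYLINDER_RTOL = 1e-6


@dataclass
class ListModeStream:
    """Time-ordered coincidence events.

    ``t`` is seconds from acquisition start; ``p1``/``p2`` are (n, 3) endpoint
    arrays in mm. ``crystals`` is an optional (n, 4) int array
    ``(ring1, cry1, ring2, cry2)`` kept when the stream came from (or was
    snapped to) crystal indices.
    """

    t: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    crystals: np.ndarray | None = None
    dialect: str = "physical"
    geometry: ScannerGeometry | None = None
    source: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.ascontiguousarray(self.t, dtype=np.float64)
        self.p1 = np.ascontiguousarray(self.p1, dtype=np.float64).reshape(-1, 3)
        self.p2 = np.ascontiguousarray(self.p2, dtype=np.float64).reshape(-1, 3)
        n = self.t.shape[0]
        if self.p1.shape[0] != n or self.p2.shape[0] != n:
            raise ListModeValidationError(
                f"inconsistent lengths: t={n}, p1={self.p1.shape[0]}, p2={self.p2.shape[0]}"
            )
        if self.crystals is not None:
            self.crystals = np.ascontiguousarray(self.crystals, dtype=np.int32).reshape(
                -1, 4
            )
            if self.crystals.shape[0] != n:
                raise ListModeValidationError("crystals length mismatch")

    def __len__(self) -> int:
        return int(self.t.shape[0])

    def lor(self, i: int) -> LoR:
        """The i-th event as a single :class:`LoR`."""
        return LoR(float(self.t[i]), self.p1[i].copy(), self.p2[i].copy())

    def sort_by_time(self) -> "ListModeStream":
        """Stable in-place sort by timestamp (equal times keep order)."""
        order = np.argsort(self.t, kind="stable")
        self.t = self.t[order]
        self.p1 = self.p1[order]
        self.p2 = self.p2[order]
        if self.crystals is not None:
            self.crystals = self.crystals[order]
        return self

    def validate(self) -> None:
        """Raise if any invariant is violated."""
        if not np.isfinite(self.t).all():
            raise ListModeValidationError("non-finite timestamp")
        if not (np.isfinite(self.p1).all() and np.isfinite(self.p2).all()):
            raise ListModeValidationError("non-finite endpoint coordinate")
        if len(self) and self.t.min() < 0:
            raise ListModeValidationError("negative timestamp")
        if len(self) and (np.diff(self.t) < 0).any():
            raise ListModeValidationError("timestamps not non-decreasing")
        if len(self) and (self.p1 == self.p2).all(axis=1).any():
            raise ListModeValidationError("degenerate LoR with p1 == p2")
        if self.geometry is not None and len(self):
            r2 = self.geometry.radius_mm**2
            for p in (self.p1, self.p2):
                rho2 = p[:, 0] ** 2 + p[:, 1] ** 2
                if not np.allclose(rho2, r2, rtol=_CYLINDER_RTOL, atol=0):
                    raise ListModeValidationError(
                        "endpoint off the detector cylinder surface"
                    )


# ---------------------------------------------------------------------- #
# reading


def read_listmode(
    path: str | Path,
    dialect: str,
    geometry: ScannerGeometry | None = None,
) -> ListModeStream:
    """Read a list-mode file, validate it, and return it time-sorted."""
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if not path.exists():
        raise FileNotFoundError(path)

    if dialect == "binary":
        stream = _read_binary(path)
    elif dialect == "crystal":
        if geometry is None:
            raise ValueError("crystal dialect requires a scanner geometry")
        stream = _read_crystal_csv(path, geometry)
    else:
        stream = _read_physical_csv(path, geometry)
    stream.source = str(path)
    stream.sort_by_time()
    stream.validate()
    return stream


def _read_csv(path: Path, columns: list[str], int_cols: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # malformed row
        line = None
        msg = str(exc)
        # pandas reports "... in line N" or "Expected x fields in line N, saw y"
        for token in msg.replace(",", " ").split():
            if token.isdigit():
                line = int(token)
        raise ListModeParseError(msg, line=line) from exc
    got = list(df.columns)
    has_rejected = got and got[-1] == "rejected"
    expected = columns + (["rejected"] if has_rejected else [])
    if got != expected:
        raise ListModeParseError(
            f"{path}: expected header {','.join(columns)}[,rejected], got {','.join(got)}",
            line=1,
        )
    if has_rejected:
        df = df[~df["rejected"].astype(bool)].drop(columns=["rejected"])
    for col in columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            # +2: 1-based with header line
            raise ListModeParseError(
                f"non-numeric value {df[col][bad].iloc[0]!r} in column {col}",
                line=int(np.flatnonzero(bad.to_numpy())[0]) + 2,
            )
        if vals.isna().any():
            raise ListModeParseError(
                f"missing value in column {col}",
                line=int(np.flatnonzero(vals.isna().to_numpy())[0]) + 2,
            )
        df[col] = vals
    for col in int_cols:
        as_int = df[col].to_numpy()
        if not np.array_equal(as_int, np.floor(as_int)):
            raise ListModeValidationError(f"non-integer value in column {col}")
        df[col] = as_int.astype(np.int64)
    return df


def _read_crystal_csv(path: Path, geometry: ScannerGeometry) -> ListModeStream:
    df = _read_csv(path, _CRYSTAL_COLS, int_cols=_CRYSTAL_COLS[1:])
    crystals = df[["ring1", "cry1", "ring2", "cry2"]].to_numpy(dtype=np.int64)
    p1 = geometry.crystals_to_positions(crystals[:, 0], crystals[:, 1])
    p2 = geometry.crystals_to_positions(crystals[:, 2], crystals[:, 3])
    return ListModeStream(
        t=df["t_s"].to_numpy(),
        p1=p1,
        p2=p2,
        crystals=crystals.astype(np.int32),
        dialect="crystal",
        geometry=geometry,
    )


def _read_physical_csv(path: Path, geometry: ScannerGeometry | None) -> ListModeStream:
    df = _read_csv(path, _PHYSICAL_COLS, int_cols=[])
    return ListModeStream(
        t=df["t_s"].to_numpy(),
        p1=df[["x1_mm", "y1_mm", "z1_mm"]].to_numpy(),
        p2=df[["x2_mm", "y2_mm", "z2_mm"]].to_numpy(),
        dialect="physical",
        geometry=geometry,
    )


def _read_binary(path: Path) -> ListModeStream:
    raw = path.read_bytes()
    if len(raw) < 16 or raw[:8] != _MAGIC:
        raise ListModeParseError(f"{path}: missing {_MAGIC!r} magic header")
    (count,) = struct.unpack("<Q", raw[8:16])
    expected = 16 + count * _RECORD.size
    if len(raw) != expected:
        raise ListModeParseError(
            f"{path}: expected {expected} bytes for {count} records, got {len(raw)}"
        )
    rec = np.frombuffer(
        raw,
        offset=16,
        dtype=np.dtype([("t", "<f8"), ("p", "<f4", (6,))]),
        count=count,
    )
    p = rec["p"].astype(np.float64)
    return ListModeStream(
        t=rec["t"].copy(), p1=p[:, :3], p2=p[:, 3:], dialect="binary"
    )


# ---------------------------------------------------------------------- #
# writing


def write_listmode(stream: ListModeStream, path: str | Path, dialect: str) -> Path:
    """Write a stream in the requested dialect; returns the path."""
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    stream.validate()

    if dialect == "binary":
        buf = bytearray(_MAGIC)
        buf += struct.pack("<Q", len(stream))
        p = np.hstack([stream.p1, stream.p2]).astype("<f4")
        rec = np.empty(len(stream), dtype=np.dtype([("t", "<f8"), ("p", "<f4", (6,))]))
        rec["t"] = stream.t
        rec["p"] = p
        buf += rec.tobytes()
        path.write_bytes(bytes(buf))
        return path

    if dialect == "crystal":
        crystals = stream.crystals
        if crystals is None:
            if stream.geometry is None:
                raise ValueError(
                    "crystal dialect needs stored crystal indices or a geometry "
                    "to snap endpoints"
                )
            r1, c1 = stream.geometry.nearest_crystals(stream.p1)
            r2, c2 = stream.geometry.nearest_crystals(stream.p2)
            crystals = np.column_stack([r1, c1, r2, c2])
        df = pd.DataFrame(
            {
                "t_s": stream.t,
                "ring1": crystals[:, 0],
                "cry1": crystals[:, 1],
                "ring2": crystals[:, 2],
                "cry2": crystals[:, 3],
            }
        )
    else:
        df = pd.DataFrame(
            np.hstack([stream.t[:, None], stream.p1, stream.p2]),
            columns=_PHYSICAL_COLS,
        )
    df.to_csv(path, index=False, float_format="%.15g")
    return path
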