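"""Phase-space file I/O.

A phase space is a collection of particle records (type, energy, position,
direction, statistical weight) tallied on a plane in the linac head, used as
the source for downstream dose simulation.  Files come in pairs: a plain-text
``<name>.header`` with the tally geometry and bookkeeping, and a binary
``<name>.phsp`` with fixed-size little-endian records.

Record layout (25 bytes, little-endian):

======  =======  ==============================================
offset  type     meaning
======  =======  ==============================================
0       int8     particle code; |code| 1=photon 2=electron
                 3=positron; sign = sign of the z direction
                 cosine (w_sign)
1       float32  kinetic energy in MeV; a NEGATIVE stored value
                 marks the first particle of a new primary
                 history (the magnitude is the energy)
5..21   float32  x, y (cm), u, v (direction cosines), weight
======  =======  ==============================================

z is constant over a file and lives in the header.  The beam axis is +z from
target toward isocenter; x is crossline, y inline.  The magnitude of the z
direction cosine is derived as sqrt(1 - u^2 - v^2).

Reading streams the binary file in chunks so multi-GB files are processed at
constant memory.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, NamedTuple, Optional, Sequence, Union

import numpy as np

__all__ = [
    "PHOTON",
    "ELECTRON",
    "POSITRON",
    "KIND_NAMES",
    "ParticleRecord",
    "PhaseSpaceHeader",
    "PhaseSpace",
    "PhaseSpaceFormatError",
    "PhaseSpaceIntegrityError",
    "read_header",
    "read_records",
    "iter_record_chunks",
    "write_phasespace",
]

PHOTON = 1
ELECTRON = 2
POSITRON = 3
KIND_NAMES = {PHOTON: "photon", ELECTRON: "electron", POSITRON: "positron"}
_KIND_CODES = {v: k for k, v in KIND_NAMES.items()}

#: on-disk record layout, 25 bytes
RECORD_DTYPE = np.dtype(
    [
        ("code", "i1"),
        ("energy", "<f4"),
        ("x", "<f4"),
        ("y", "<f4"),
        ("u", "<f4"),
        ("v", "<f4"),
        ("weight", "<f4"),
    ]
)
BYTES_PER_RECORD = RECORD_DTYPE.itemsize  # 25

#: decoded in-memory layout used by the analysis modules
DECODED_DTYPE = np.dtype(
    [
        ("kind", "i1"),
        ("energy", "<f8"),
        ("x", "<f8"),
        ("y", "<f8"),
        ("u", "<f8"),
        ("v", "<f8"),
        ("w", "<f8"),
        ("weight", "<f8"),
        ("new_history", "?"),
    ]
)

_COS_TOL = 1e-6  # permitted u^2+v^2 overshoot before a record counts as corrupt


class PhaseSpaceFormatError(ValueError):
    """Malformed header: missing or unparsable mandatory key."""


class PhaseSpaceIntegrityError(ValueError):
    """Binary payload inconsistent with the header (size, checksum, corrupt record)."""


class ParticleRecord(NamedTuple):
    """One particle crossing the tally plane."""

    kind: int  # PHOTON / ELECTRON / POSITRON
    energy: float  # MeV, > 0
    x: float  # cm
    y: float  # cm
    u: float  # direction cosine along x
    v: float  # direction cosine along y
    w_sign: int  # +1 forward, -1 backward
    weight: float  # statistical weight, > 0
    new_history: bool  # first particle of a primary history

    @property
    def w(self) -> float:
        """Signed z direction cosine derived from u, v."""
        return self.w_sign * float(np.sqrt(max(0.0, 1.0 - self.u**2 - self.v**2)))


@dataclass
class PhaseSpaceHeader:
    """Metadata carried by the plain-text companion header file.

    z_plane is the distance (cm) of the tally plane from the target; it is
    metadata only and never enters any statistic.
    """

    z_plane: float
    n_original_histories: int
    n_records: int
    constant_variables: dict = field(default_factory=dict)

    @property
    def checksum(self) -> int:
        return BYTES_PER_RECORD * self.n_records


@dataclass
class PhaseSpace:
    """Header plus decoded records (a DECODED_DTYPE structured array)."""

    header: PhaseSpaceHeader
    records: np.ndarray

    def __post_init__(self):
        if self.records.dtype != DECODED_DTYPE:
            raise TypeError("records must be a DECODED_DTYPE structured array")

    @classmethod
    def from_records(
        cls,
        records: Union[np.ndarray, Sequence[ParticleRecord]],
        z_plane: float,
        n_original_histories: int,
    ) -> "PhaseSpace":
        arr = _to_decoded(records)
        hdr = PhaseSpaceHeader(
            z_plane=z_plane,
            n_original_histories=n_original_histories,
            n_records=len(arr),
        )
        return cls(header=hdr, records=arr)

    @classmethod
    def load(cls, path: str, kinds: Optional[Iterable] = None) -> "PhaseSpace":
        """Read a whole .phsp/.header pair into memory."""
        hdr = read_header(path)
        chunks = list(iter_record_chunks(path, hdr, kinds=kinds))
        if chunks:
            arr = np.concatenate(chunks)
        else:
            arr = np.empty(0, dtype=DECODED_DTYPE)
        if kinds is not None:
            hdr = replace(hdr, n_records=len(arr))
        return cls(header=hdr, records=arr)

    def __len__(self) -> int:
        return len(self.records)

    def iter_particles(self) -> Iterator[ParticleRecord]:
        for r in self.records:
            w_sign = 1 if r["w"] >= 0 else -1
            yield ParticleRecord(
                int(r["kind"]), float(r["energy"]), float(r["x"]), float(r["y"]),
                float(r["u"]), float(r["v"]), w_sign, float(r["weight"]),
                bool(r["new_history"]),
            )


def _to_decoded(records) -> np.ndarray:
    if isinstance(records, np.ndarray) and records.dtype == DECODED_DTYPE:
        return records
    arr = np.empty(len(records), dtype=DECODED_DTYPE)
    for i, r in enumerate(records):
        if not isinstance(r, ParticleRecord):
            r = ParticleRecord(*r)
        arr[i] = (r.kind, r.energy, r.x, r.y, r.u, r.v, r.w, r.weight, r.new_history)
    return arr


def _paths(path: str) -> tuple:
    """Resolve (phsp_path, header_path) from either file of the pair."""
    base, ext = os.path.splitext(path)
    if ext in (".phsp", ".header"):
        return base + ".phsp", base + ".header"
    return path + ".phsp", path + ".header"


_MANDATORY_KEYS = ("Z_PLANE_CM", "N_ORIGINAL_HISTORIES", "N_RECORDS", "BYTES_PER_RECORD")


def read_header(path: str) -> PhaseSpaceHeader:
    """Parse the plain-text companion header.

    Raises
    ------
    PhaseSpaceFormatError
        on a missing or unparsable mandatory key.
    PhaseSpaceIntegrityError
        when the declared record size or checksum disagrees with this
        format's 25-byte records.
    """
    phsp_path, header_path = _paths(path)
    if not os.path.exists(header_path):
        raise FileNotFoundError(header_path)
    kv = {}
    with open(header_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise PhaseSpaceFormatError(f"unparsable header line: {line!r}")
            key, _, value = line.partition("=")
            kv[key.strip()] = value.strip()
    for key in _MANDATORY_KEYS:
        if key not in kv:
            raise PhaseSpaceFormatError(f"missing mandatory header key: {key}")
    try:
        z_plane = float(kv["Z_PLANE_CM"])
        n_hist = int(kv["N_ORIGINAL_HISTORIES"])
        n_records = int(kv["N_RECORDS"])
        bpr = int(kv["BYTES_PER_RECORD"])
    except ValueError as exc:
        raise PhaseSpaceFormatError(f"unparsable header value: {exc}") from exc
    if z_plane <= 0:
        raise PhaseSpaceFormatError("Z_PLANE_CM must be > 0")
    if bpr != BYTES_PER_RECORD:
        raise PhaseSpaceIntegrityError(
            f"BYTES_PER_RECORD={bpr} does not match this dialect ({BYTES_PER_RECORD})"
        )
    if "CHECKSUM" in kv:
        declared = int(kv["CHECKSUM"])
        if declared != bpr * n_records:
            raise PhaseSpaceIntegrityError(
                f"checksum {declared} != BYTES_PER_RECORD*N_RECORDS = {bpr * n_records}"
            )
    constants = {}
    raw = kv.get("RECORD_CONSTANTS", "")
    if raw:
        for item in raw.split(","):
            name, _, val = item.partition("=")
            if not val:
                raise PhaseSpaceFormatError(f"unparsable RECORD_CONSTANTS item: {item!r}")
            constants[name.strip()] = float(val)
    return PhaseSpaceHeader(
        z_plane=z_plane,
        n_original_histories=n_hist,
        n_records=n_records,
        constant_variables=constants,
    )


def _decode_chunk(raw: np.ndarray, index_offset: int) -> np.ndarray:
    """Decode raw on-disk records into DECODED_DTYPE, deriving w and flags."""
    out = np.empty(len(raw), dtype=DECODED_DTYPE)
    code = raw["code"].astype(np.int64)
    kind = np.abs(code).astype(np.int8)
    bad_kind = ~np.isin(kind, list(KIND_NAMES))
    if bad_kind.any():
        idx = index_offset + int(np.flatnonzero(bad_kind)[0])
        raise PhaseSpaceIntegrityError(f"unknown particle code at record {idx}")
    out["kind"] = kind
    e = raw["energy"].astype(np.float64)
    out["new_history"] = e < 0
    out["energy"] = np.abs(e)
    out["x"] = raw["x"]
    out["y"] = raw["y"]
    u = raw["u"].astype(np.float64)
    v = raw["v"].astype(np.float64)
    s = u * u + v * v
    over = s > 1.0 + _COS_TOL
    if over.any():
        idx = index_offset + int(np.flatnonzero(over)[0])
        raise PhaseSpaceIntegrityError(
            f"corrupt record {idx}: u^2+v^2 = {s[over][0]:.8f} > 1"
        )
    out["u"] = u
    out["v"] = v
    w_sign = np.where(code >= 0, 1.0, -1.0)
    out["w"] = w_sign * np.sqrt(np.maximum(0.0, 1.0 - s))
    out["weight"] = raw["weight"]
    return out


def iter_record_chunks(
    path: str,
    header: Optional[PhaseSpaceHeader] = None,
    kinds: Optional[Iterable] = None,
    chunk_records: int = 1 << 18,
) -> Iterator[np.ndarray]:
    """Stream decoded record chunks (DECODED_DTYPE arrays) from a .phsp file.

    ``kinds`` is an optional set of particle kinds (codes or names) to keep.
    """
    phsp_path, _ = _paths(path)
    if header is None:
        header = read_header(path)
    size = os.path.getsize(phsp_path)
    if size % BYTES_PER_RECORD != 0:
        raise PhaseSpaceIntegrityError(
            f"{phsp_path}: file size {size} not a multiple of {BYTES_PER_RECORD} "
            "(truncated final record?)"
        )
    n_in_file = size // BYTES_PER_RECORD
    if n_in_file != header.n_records:
        raise PhaseSpaceIntegrityError(
            f"{phsp_path}: file holds {n_in_file} records, header declares "
            f"{header.n_records}"
        )
    keep = None
    if kinds is not None:
        keep = {_KIND_CODES.get(k, k) for k in kinds}
    offset = 0
    with open(phsp_path, "rb") as fh:
        while True:
            buf = fh.read(chunk_records * BYTES_PER_RECORD)
            if not buf:
                break
            raw = np.frombuffer(buf, dtype=RECORD_DTYPE)
            chunk = _decode_chunk(raw, offset)
            offset += len(raw)
            if keep is not None:
                chunk = chunk[np.isin(chunk["kind"], list(keep))]
            yield chunk


def read_records(
    path: str,
    header: Optional[PhaseSpaceHeader] = None,
    kinds: Optional[Iterable] = None,
) -> Iterator[ParticleRecord]:
    """Yield ParticleRecord tuples in file order, optionally filtered by kind."""
    for chunk in iter_record_chunks(path, header, kinds=kinds):
        for r in chunk:
            w_sign = 1 if r["w"] >= 0 else -1
            yield ParticleRecord(
                int(r["kind"]), float(r["energy"]), float(r["x"]), float(r["y"]),
                float(r["u"]), float(r["v"]), w_sign, float(r["weight"]),
                bool(r["new_history"]),
            )


def write_phasespace(ps: PhaseSpace, path: str) -> tuple:
    """Write the .phsp/.header pair; returns (phsp_path, header_path).

    Every stored field survives a write -> read round trip bit-exactly
    (fields are stored as float32; inputs are cast once on write).
    """
    phsp_path, header_path = _paths(path)
    rec = ps.records
    if (rec["energy"] <= 0).any():
        raise ValueError("all record energies must be > 0")
    if (rec["weight"] <= 0).any():
        raise ValueError("all record weights must be > 0")
    raw = np.empty(len(rec), dtype=RECORD_DTYPE)
    w_sign = np.where(rec["w"] >= 0, 1, -1)
    raw["code"] = (rec["kind"] * w_sign).astype(np.int8)
    e32 = rec["energy"].astype(np.float32)
    raw["energy"] = np.where(rec["new_history"], -e32, e32)
    for name in ("x", "y", "u", "v", "weight"):
        raw[name] = rec[name].astype(np.float32)
    with open(phsp_path, "wb") as fh:
        fh.write(raw.tobytes())
    hdr = ps.header
    constants = dict(hdr.constant_variables)
    constants.setdefault("z", hdr.z_plane)
    const_str = ",".join(f"{k}={v:g}" for k, v in constants.items())
    with open(header_path, "w") as fh:
        fh.write(f"Z_PLANE_CM = {hdr.z_plane!r}\n")
        fh.write(f"N_ORIGINAL_HISTORIES = {hdr.n_original_histories}\n")
        fh.write(f"N_RECORDS = {len(rec)}\n")
        fh.write(f"BYTES_PER_RECORD = {BYTES_PER_RECORD}\n")
        fh.write(f"CHECKSUM = {BYTES_PER_RECORD * len(rec)}\n")
        fh.write(f"RECORD_CONSTANTS = {const_str}\n")
    return phsp_path, header_path
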