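"""Minimal NRRD (Nearly Raw Raster Data) reader/writer.

Covers the subset this package emits and consumes: 3D attached-data NRRD,
little-endian, raw or gzip encoding, isotropic-or-not spacing given either by
``spacings`` or by a diagonal ``space directions`` field.
"""

from __future__ import annotations

import gzip
import re
from pathlib import Path

import numpy as np

_TYPES = {
    "uint8": np.uint8, "uchar": np.uint8, "unsigned char": np.uint8,
    "int16": np.int16, "short": np.int16,
    "uint16": np.uint16, "unsigned short": np.uint16,
    "int32": np.int32, "int": np.int32,
    "float": np.float32, "float32": np.float32,
    "double": np.float64, "float64": np.float64,
}
_TYPE_NAMES = {np.dtype(v): k for k, v in [
    ("uint8", np.uint8), ("int16", np.int16), ("uint16", np.uint16),
    ("int32", np.int32), ("float", np.float32), ("double", np.float64),
]}


def read(path) -> tuple[np.ndarray, dict]:
    """Read an NRRD file -> (array in index order sizes[0]..sizes[-1], header).

    The returned array is Fortran-ordered with respect to the on-disk raster
    (fastest axis first), i.e. shape == sizes and ``arr[i0, i1, i2]`` addresses
    the raster element NRRD addresses with those indices.
    """
    raw = Path(path).read_bytes()
    m = re.match(rb"NRRD000\d", raw)
    if m is None:
        raise ValueError(f"{path}: not an NRRD file (bad magic)")
    end = raw.find(b"\n\n")
    if end < 0:
        raise ValueError(f"{path}: truncated NRRD header")
    header: dict[str, str] = {}
    for line in raw[m.end():end].decode("ascii").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition(":")
        header[key.strip().lower()] = value.lstrip("= ").strip()
    body = raw[end + 2:]

    sizes = [int(s) for s in header["sizes"].split()]
    dtype = np.dtype(_TYPES[header["type"]])
    encoding = header.get("encoding", "raw")
    if encoding in ("gzip", "gz"):
        body = gzip.decompress(body)
    elif encoding != "raw":
        raise ValueError(f"unsupported NRRD encoding {encoding!r}")
    endian = header.get("endian", "little")
    dt = dtype.newbyteorder("<" if endian == "little" else ">")
    count = int(np.prod(sizes))
    if len(body) < count * dt.itemsize:
        raise ValueError(f"{path}: NRRD data shorter than sizes promise")
    arr = np.frombuffer(body, dtype=dt, count=count)
    # NRRD raster order: first axis fastest
    arr = arr.reshape(sizes[::-1]).transpose(range(len(sizes) - 1, -1, -1))
    return np.ascontiguousarray(arr), header


def spacings_from_header(header: dict) -> np.ndarray | None:
    """Per-axis spacing from `spacings` or diagonal `space directions`."""
    if "spacings" in header:
        return np.array([float(s) for s in header["spacings"].split()])
    if "space directions" in header:
        vecs = []
        for tok in re.findall(r"\(([^)]*)\)", header["space directions"]):
            vecs.append([float(x) for x in tok.split(",")])
        if vecs:
            return np.linalg.norm(np.array(vecs), axis=1)
    return None


def origin_from_header(header: dict) -> np.ndarray | None:
    if "space origin" in header:
        tok = re.search(r"\(([^)]*)\)", header["space origin"])
        if tok:
            return np.array([float(x) for x in tok.group(1).split(",")])
    return None


def write(path, arr: np.ndarray, spacing: float | np.ndarray,
          origin=None, encoding: str = "gzip") -> None:
    """Write `arr` (index order = axis order) as an attached-data NRRD."""
    arr = np.asarray(arr)
    dt = arr.dtype.newbyteorder("<")
    name = _TYPE_NAMES.get(np.dtype(arr.dtype.name))
    if name is None:
        raise ValueError(f"unsupported dtype {arr.dtype} for NRRD")
    sp = np.broadcast_to(np.asarray(spacing, float), (arr.ndim,))
    lines = [
        "NRRD0004",
        f"type: {name}",
        f"dimension: {arr.ndim}",
        "sizes: " + " ".join(str(s) for s in arr.shape),
        "spacings: " + " ".join(f"{s:.9g}" for s in sp),
        "endian: little",
        f"encoding: {encoding}",
    ]
    if origin is not None:
        o = ", ".join(f"{x:.9g}" for x in np.asarray(origin, float))
        lines.append("space: left-posterior-superior")
        lines.append(
            "space directions: " + " ".join(
                "(" + ",".join(f"{s if i == j else 0:.9g}"
                               for j in range(arr.ndim)) + ")"
                for i, s in enumerate(sp))
        )
        lines.append(f"space origin: ({o})")
    # first axis fastest on disk
    body = np.ascontiguousarray(
        arr.transpose(range(arr.ndim - 1, -1, -1))).astype(dt).tobytes()
    if encoding == "gzip":
        body = gzip.compress(body)
    elif encoding != "raw":
        raise ValueError(f"unsupported NRRD encoding {encoding!r}")
    with open(path, "wb") as fh:
        fh.write(("\n".join(lines) + "\n\n").encode("ascii"))
        fh.write(body)
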