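"""Minimal NRRD reader/writer (raw, ascii and gzip encodings).

Covers the subset of NRRD needed for segmented label volumes: a single
integer-typed array, ``space directions`` restricted to a diagonal matrix
(per-axis spacing) and ``space origin``. This is deliberately small; it
is not a general NRRD implementation.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np

_TYPE_TO_DTYPE = {
    "signed char": "i1", "int8": "i1", "int8_t": "i1",
    "uchar": "u1", "unsigned char": "u1", "uint8": "u1", "uint8_t": "u1",
    "short": "i2", "signed short": "i2", "int16": "i2", "int16_t": "i2",
    "ushort": "u2", "unsigned short": "u2", "uint16": "u2", "uint16_t": "u2",
    "int": "i4", "signed int": "i4", "int32": "i4", "int32_t": "i4",
    "uint": "u4", "unsigned int": "u4", "uint32": "u4", "uint32_t": "u4",
    "longlong": "i8", "int64": "i8", "int64_t": "i8",
    "ulonglong": "u8", "uint64": "u8", "uint64_t": "u8",
    "float": "f4", "double": "f8",
}

_DTYPE_TO_TYPE = {
    np.dtype(np.int8): "int8", np.dtype(np.uint8): "uint8",
    np.dtype(np.int16): "int16", np.dtype(np.uint16): "uint16",
    np.dtype(np.int32): "int32", np.dtype(np.uint32): "uint32",
    np.dtype(np.int64): "int64", np.dtype(np.uint64): "uint64",
}


def _parse_vector(text: str) -> list[float]:
    return [float(t) for t in text.strip().lstrip("(").rstrip(")").split(",")]


def read(path) -> tuple[np.ndarray, dict]:
    """Read a NRRD file; returns (array in index order, header dict).

    The header dict exposes ``spacing`` (per-axis, mm) and ``origin``
    when the file provides space information.
    """
    path = Path(path)
    raw = path.read_bytes()
    nl = raw.find(b"\n")
    if nl < 0 or not raw[:nl].strip().startswith(b"NRRD"):
        raise ValueError(f"{path}: not a NRRD file (missing magic)")

    fields: dict[str, str] = {}
    pos = nl + 1
    while True:
        nl = raw.find(b"\n", pos)
        if nl < 0:
            raise ValueError(f"{path}: truncated NRRD header")
        line = raw[pos:nl].rstrip(b"\r")
        pos = nl + 1
        if line == b"":
            break  # blank line terminates the header
        text = line.decode("ascii")
        if text.startswith("#"):
            continue
        if ":" not in text:
            raise ValueError(f"{path}: malformed header line {text!r}")
        key, _, value = text.partition(":")
        fields[key.strip().lower()] = value.lstrip("=").strip()

    for required in ("type", "dimension", "sizes", "encoding"):
        if required not in fields:
            raise ValueError(f"{path}: NRRD header missing '{required}'")

    type_name = fields["type"].lower()
    if type_name not in _TYPE_TO_DTYPE:
        raise ValueError(f"{path}: unsupported NRRD type {fields['type']!r}")
    endian = fields.get("endian", "little")
    dtype = np.dtype(("<" if endian == "little" else ">") + _TYPE_TO_DTYPE[type_name])

    sizes = [int(s) for s in fields["sizes"].split()]
    if len(sizes) != int(fields["dimension"]):
        raise ValueError(f"{path}: sizes/dimension mismatch")

    encoding = fields["encoding"].lower()
    payload = raw[pos:]
    if encoding == "raw":
        data = np.frombuffer(payload, dtype=dtype, count=int(np.prod(sizes)))
    elif encoding in ("gzip", "gz"):
        data = np.frombuffer(gzip.decompress(payload), dtype=dtype,
                             count=int(np.prod(sizes)))
    elif encoding in ("ascii", "text", "txt"):
        data = np.array(payload.split(), dtype=dtype)
    else:
        raise ValueError(f"{path}: unsupported NRRD encoding {encoding!r}")
    if data.size < int(np.prod(sizes)):
        raise ValueError(f"{path}: NRRD payload shorter than sizes imply")
    data = data[: int(np.prod(sizes))]

    # NRRD stores the fastest axis first; C order with reversed shape.
    array = data.reshape(sizes[::-1]).transpose(range(len(sizes))[::-1])

    header: dict = {"sizes": sizes, "type": fields["type"], "encoding": encoding}
    if "space directions" in fields:
        dirs = [_parse_vector(v) for v in fields["space directions"].split(") (")]
        spacing = []
        for axis, d in enumerate(dirs):
            off_diag = [abs(x) for i, x in enumerate(d) if i != axis]
            if any(x > 1e-9 for x in off_diag):
                raise ValueError(
                    f"{path}: non-axis-aligned space directions are not supported"
                )
            spacing.append(abs(d[axis]))
        header["spacing"] = spacing
    elif "spacings" in fields:
        header["spacing"] = [float(s) for s in fields["spacings"].split()]
    if "space origin" in fields:
        header["origin"] = _parse_vector(fields["space origin"])
    return array, header


def write(path, array: np.ndarray, spacing, origin=(0.0, 0.0, 0.0),
          encoding: str = "gzip") -> None:
    """Write ``array`` (index order (x, y, z)) as a NRRD file."""
    path = Path(path)
    array = np.ascontiguousarray(np.asarray(array))
    if array.dtype not in _DTYPE_TO_TYPE:
        raise ValueError(f"unsupported dtype {array.dtype} for NRRD output")
    ndim = array.ndim
    if len(tuple(spacing)) != ndim:
        raise ValueError("spacing length must match array dimension")

    dirs = " ".join(
        "(" + ",".join(str(float(spacing[a]) if a == i else 0.0)
                       for i in range(ndim)) + ")"
        for a in range(ndim)
    )
    header_lines = [
        "NRRD0004",
        "# generated by sonomargin",
        f"type: {_DTYPE_TO_TYPE[array.dtype]}",
        f"dimension: {ndim}",
        f"sizes: {' '.join(str(s) for s in array.shape)}",
        f"encoding: {encoding}",
        "endian: little",
        f"space dimension: {ndim}",
        f"space directions: {dirs}",
        f"space origin: ({','.join(str(float(o)) for o in origin)})",
        "",
    ]
    # fastest axis first on disk: write Fortran-ordered bytes
    body = np.asfortranarray(array.astype(array.dtype.newbyteorder("<"))).tobytes(order="F")
    if encoding == "raw":
        payload = body
    elif encoding == "gzip":
        payload = gzip.compress(body, compresslevel=1)
    elif encoding == "ascii":
        payload = " ".join(str(int(v)) for v in array.flatten(order="F")).encode("ascii")
    else:
        raise ValueError(f"unsupported NRRD encoding {encoding!r}")
    path.write_bytes("\n".join(header_lines).encode("ascii") + b"\n" + payload)
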