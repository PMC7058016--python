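"""CSV/JSON interchange for traces, spectra and run manifests.

The trace dialect is plain CSV prefixed by ``# key=value`` metadata lines:

    # type=phosphorescence
    # irradiation_time_s=375.0
    # filter_window=1250-1300
    # n_pulses=2500
    t_us,counts
    0.025,312
    ...

``type`` selects the record class on read.  Files written on any platform
parse identically (CRLF and LF line endings are equivalent).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

from . import __version__
from .exceptions import ParseError
from .signals import (
    EmissionSpectrum,
    KineticTrace,
    NetPhosphorescenceTrace,
    PhosphorescenceTrace,
    TripletDecayCurve,
)

__all__ = ["write_trace", "read_trace", "RunManifest", "sha256_of"]

Record = Union[TripletDecayCurve, PhosphorescenceTrace, NetPhosphorescenceTrace,
               EmissionSpectrum, KineticTrace]


def _fmt(v):
    if isinstance(v, float):
        return repr(v)
    return str(v)


def _write_table(path, meta: dict, header: str, columns, int_cols=()):
    lines = [f"# {k}={_fmt(v)}" for k, v in meta.items()]
    lines.append(header)
    cols = [np.asarray(c) for c in columns]
    for row in zip(*cols):
        cells = []
        for j, v in enumerate(row):
            if j in int_cols:
                cells.append(str(int(v)))
            else:
                cells.append(repr(float(v)))
        lines.append(",".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def write_trace(path, record: Record) -> None:
    """Serialize a trace/spectrum record to the documented CSV dialect."""
    if isinstance(record, TripletDecayCurve):
        meta = {"type": "triplet", "irradiation_time_s": record.irradiation_time,
                "noise_sigma": record.noise_sigma}
        _write_table(path, meta, "t_us,value", (record.t, record.absorbance))
    elif isinstance(record, PhosphorescenceTrace):
        meta = {"type": "phosphorescence", "irradiation_time_s": record.irradiation_time,
                "filter_window": record.filter_window, "n_pulses": record.n_pulses}
        if record.meta.get("expectation"):
            meta["expectation"] = "true"
            _write_table(path, meta, "t_us,counts", (record.t, record.counts))
        else:
            _write_table(path, meta, "t_us,counts", (record.t, record.counts),
                         int_cols=(1,))
    elif isinstance(record, NetPhosphorescenceTrace):
        meta = {"type": "net_phosphorescence",
                "irradiation_time_s": record.irradiation_time,
                "n_pulses": record.n_pulses}
        if "background_subtraction" in record.meta:
            meta["background_subtraction"] = record.meta["background_subtraction"]
        _write_table(path, meta, "t_us,value", (record.t, record.value))
    elif isinstance(record, EmissionSpectrum):
        meta = {"type": "spectrum", "label": record.label}
        _write_table(path, meta, "wavelength_nm,intensity",
                     (record.wavelength, record.intensity))
    elif isinstance(record, KineticTrace):
        meta = {"type": "kinetic", "label": record.label}
        _write_table(path, meta, "t_s,value", (record.t, record.value))
    else:
        raise ParseError(f"cannot serialize records of type {type(record).__name__}")


_REQUIRED_META = {
    "triplet": ("irradiation_time_s",),
    "phosphorescence": ("irradiation_time_s", "filter_window", "n_pulses"),
    "net_phosphorescence": ("irradiation_time_s",),
    "spectrum": ("label",),
    "kinetic": ("label",),
}

_HEADERS = {
    "triplet": "t_us,value",
    "phosphorescence": "t_us,counts",
    "net_phosphorescence": "t_us,value",
    "spectrum": "wavelength_nm,intensity",
    "kinetic": "t_s,value",
}


def read_trace(path) -> Record:
    """Parse a trace/spectrum file; raises ParseError naming the bad line."""
    path = Path(path)
    meta = {}
    rows = []
    header_line = None
    with open(path, "r", newline=None) as fh:   # universal newlines: CRLF == LF
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if header_line is not None:
                    raise ParseError("metadata after the column header", path, lineno)
                body = line[1:].strip()
                if "=" not in body:
                    raise ParseError(f"malformed metadata line {line!r}", path, lineno)
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
            elif header_line is None:
                header_line = (lineno, line)
            else:
                rows.append((lineno, line))
    if "type" not in meta:
        raise ParseError("missing '# type=' metadata", path)
    kind = meta["type"]
    if kind not in _REQUIRED_META:
        raise ParseError(f"unknown trace type {kind!r}", path)
    for key in _REQUIRED_META[kind]:
        if key not in meta:
            raise ParseError(f"missing '# {key}=' metadata for type {kind!r}", path)
    if header_line is None:
        raise ParseError("missing column header", path)
    if header_line[1].replace(" ", "") != _HEADERS[kind]:
        raise ParseError(
            f"expected column header {_HEADERS[kind]!r}, got {header_line[1]!r}",
            path, header_line[0],
        )

    col_a, col_b = [], []
    expectation = meta.get("expectation", "").lower() == "true"
    for lineno, line in rows:
        parts = line.split(",")
        if len(parts) != 2:
            raise ParseError(f"expected 2 columns, got {len(parts)}", path, lineno)
        try:
            a = float(parts[0])
        except ValueError:
            raise ParseError(f"bad numeric value {parts[0]!r}", path, lineno) from None
        if kind == "phosphorescence" and not expectation:
            try:
                b = int(parts[1])
            except ValueError:
                raise ParseError(
                    f"non-integer photon count {parts[1]!r}", path, lineno
                ) from None
        else:
            try:
                b = float(parts[1])
            except ValueError:
                raise ParseError(f"bad numeric value {parts[1]!r}", path, lineno) from None
        col_a.append(a)
        col_b.append(b)
    if len(col_a) < 2:
        raise ParseError("trace needs at least two rows", path)
    a = np.asarray(col_a)
    b = np.asarray(col_b)

    if kind == "triplet":
        return TripletDecayCurve(
            irradiation_time=float(meta["irradiation_time_s"]), t=a, absorbance=b,
            noise_sigma=float(meta.get("noise_sigma", 0.0)),
        )
    if kind == "phosphorescence":
        return PhosphorescenceTrace(
            irradiation_time=float(meta["irradiation_time_s"]),
            filter_window=meta["filter_window"], t=a,
            counts=b if expectation else b.astype(np.int64),
            n_pulses=int(meta["n_pulses"]),
            meta={"expectation": True} if expectation else {},
        )
    if kind == "net_phosphorescence":
        return NetPhosphorescenceTrace(
            irradiation_time=float(meta["irradiation_time_s"]), t=a, value=b,
            n_pulses=int(meta.get("n_pulses", 2500)),
            meta={k: v for k, v in meta.items() if k not in ("type",)},
        )
    if kind == "spectrum":
        return EmissionSpectrum(wavelength=a, intensity=b, label=meta["label"])
    return KineticTrace(t=a, value=b, label=meta["label"])


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run.

    Lists the configuration echo, every input and output file with its SHA-256
    checksum, the seed registry and the package version; the manifest alone
    suffices to re-run the pipeline.
    """

    config: dict
    seed: int
    version: str = __version__
    inputs: dict = field(default_factory=dict)    # path -> sha256
    outputs: dict = field(default_factory=dict)   # path -> sha256
    stages: list = field(default_factory=list)    # per-stage status dicts

    def register_output(self, path) -> None:
        self.outputs[str(path)] = sha256_of(path)

    def register_input(self, path) -> None:
        self.inputs[str(path)] = sha256_of(path)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         default=str) + "\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        return cls(**d)
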