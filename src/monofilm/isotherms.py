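"""Isotherm containers and delimited-text I/O.

An :class:`Isotherm` is one compression (or expansion) branch of a Langmuir
trough record: paired samples of area per molecule (Å²/molecule) and
surface pressure (mN/m) at a fixed subphase temperature.  A
:class:`PotentialIsotherm` pairs the same areas with the electric surface
potential ΔV (mV) measured by a Kelvin probe.

Files are plain delimited text with the default columns ``area_A2`` and
``pi_mN_m`` (or ``dV_mV``); ``#``-prefixed header lines may carry
``temperature_K``, ``direction`` and ``label`` metadata.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Isotherm",
    "PotentialIsotherm",
    "CsvDialect",
    "read_isotherm",
    "write_isotherm",
    "read_potential",
    "write_potential",
]

COMPRESSION = "compression"
EXPANSION = "expansion"


def _validate_pair(area: np.ndarray, other: np.ndarray, other_name: str, min_len: int = 3) -> None:
    if area.ndim != 1 or other.ndim != 1:
        raise ValueError("area and %s must be one-dimensional" % other_name)
    if len(area) != len(other):
        raise ValueError(
            f"area and {other_name} must have equal length, got {len(area)} vs {len(other)}"
        )
    if len(area) < min_len:
        raise ValueError(f"need at least {min_len} points, got {len(area)}")
    if not np.all(np.isfinite(area)) or not np.all(np.isfinite(other)):
        raise ValueError(f"area and {other_name} must be finite")
    if np.any(area <= 0):
        bad = np.nonzero(area <= 0)[0].tolist()
        raise ValueError(f"non-positive area at sample index(es) {bad}")


@dataclass
class Isotherm:
    """One branch of a π–A record at fixed temperature."""

    area: np.ndarray
    pressure: np.ndarray
    temperature: float = 293.15
    direction: str = COMPRESSION
    label: str = ""

    def __post_init__(self) -> None:
        self.area = np.asarray(self.area, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        _validate_pair(self.area, self.pressure, "pressure")
        if self.direction not in (COMPRESSION, EXPANSION):
            raise ValueError(f"direction must be compression or expansion, got {self.direction!r}")

    def __len__(self) -> int:
        return len(self.area)

    def canonical(self) -> "Isotherm":
        """Return a copy in canonical orientation with duplicate areas averaged.

        Compression branches run from large to small area, expansion
        branches the other way round; instrument exports vary, so records
        are sorted here once and every analysis assumes this orientation.
        """
        order = np.argsort(self.area)
        a_sorted = self.area[order]
        p_sorted = self.pressure[order]
        # average pressures at exactly duplicated areas
        uniq, inverse, counts = np.unique(a_sorted, return_inverse=True, return_counts=True)
        if len(uniq) != len(a_sorted):
            p_avg = np.bincount(inverse, weights=p_sorted) / counts
            a_sorted, p_sorted = uniq, p_avg
        if self.direction == COMPRESSION:
            a_sorted, p_sorted = a_sorted[::-1], p_sorted[::-1]
        return replace(self, area=a_sorted.copy(), pressure=p_sorted.copy())


@dataclass
class PotentialIsotherm:
    """ΔV–A record: electric surface potential (mV) versus area."""

    area: np.ndarray
    potential: np.ndarray
    temperature: float = 293.15
    direction: str = COMPRESSION
    label: str = ""

    def __post_init__(self) -> None:
        self.area = np.asarray(self.area, dtype=float)
        self.potential = np.asarray(self.potential, dtype=float)
        _validate_pair(self.area, self.potential, "potential", min_len=2)

    def __len__(self) -> int:
        return len(self.area)

    def canonical(self) -> "PotentialIsotherm":
        order = np.argsort(self.area)
        a, v = self.area[order], self.potential[order]
        if self.direction == COMPRESSION:
            a, v = a[::-1], v[::-1]
        return replace(self, area=a.copy(), potential=v.copy())


@dataclass(frozen=True)
class CsvDialect:
    """Column mapping and text conventions for delimited isotherm files."""

    area: str = "area_A2"
    value: str = "pi_mN_m"
    delimiter: str = ","
    decimal: str = "."


POTENTIAL_DIALECT = CsvDialect(value="dV_mV")


def _read_table(path, dialect: CsvDialect):
    path = Path(path)
    meta: dict[str, str] = {}
    lines = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.lstrip().startswith("#"):
                body = line.lstrip()[1:].strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            lines.append(line)
    df = pd.read_csv(
        _io.StringIO("".join(lines)),
        sep=dialect.delimiter,
        decimal=dialect.decimal,
        skipinitialspace=True,
        float_precision="round_trip",
    )
    for col in (dialect.area, dialect.value):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r} (found {list(df.columns)})")
    sub = df[[dialect.area, dialect.value]].apply(pd.to_numeric, errors="coerce")
    bad = sub.index[sub.isna().any(axis=1)].tolist()
    if bad:
        raise ValueError(f"{path}: non-numeric entries in data row(s) {bad}")
    area = sub[dialect.area].to_numpy(float)
    if np.any(area <= 0):
        rows = sub.index[area <= 0].tolist()
        raise ValueError(f"{path}: non-positive area in data row(s) {rows}")
    return area, sub[dialect.value].to_numpy(float), meta


def _meta_kwargs(meta: dict[str, str]) -> dict:
    kwargs: dict = {}
    if "temperature_K" in meta:
        kwargs["temperature"] = float(meta["temperature_K"])
    if "direction" in meta:
        kwargs["direction"] = meta["direction"]
    if "label" in meta:
        kwargs["label"] = meta["label"]
    return kwargs


def read_isotherm(path, dialect: CsvDialect = CsvDialect()) -> Isotherm:
    """Read a π–A branch from delimited text; see module docstring for format."""
    area, pressure, meta = _read_table(path, dialect)
    return Isotherm(area, pressure, **_meta_kwargs(meta))


def read_potential(path, dialect: CsvDialect = POTENTIAL_DIALECT) -> PotentialIsotherm:
    """Read a ΔV–A branch from delimited text."""
    area, pot, meta = _read_table(path, dialect)
    return PotentialIsotherm(area, pot, **_meta_kwargs(meta))


def _write(path, area, values, value_col: str, temperature: float, direction: str, label: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# temperature_K = {float(temperature)!r}\n")
        fh.write(f"# direction = {direction}\n")
        if label:
            fh.write(f"# label = {label}\n")
        fh.write(f"area_A2,{value_col}\n")
        for a, v in zip(area, values):
            fh.write(f"{float(a)!r},{float(v)!r}\n")


def write_isotherm(iso: Isotherm, path) -> None:
    """Write an isotherm at full float precision (round-trips exactly)."""
    _write(path, iso.area, iso.pressure, "pi_mN_m", iso.temperature, iso.direction, iso.label)


def write_potential(pot: PotentialIsotherm, path) -> None:
    _write(path, pot.area, pot.potential, "dV_mV", pot.temperature, pot.direction, pot.label)
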