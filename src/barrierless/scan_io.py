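"""Input/output for dissociation scans, descriptor series, geometries and reports.

All energies are stored internally in kJ/mol with the separated-fragment
asymptote at exactly 0; re-referencing happens at read time.  Tables are
comma- or whitespace-separated text with optional ``#`` comment lines.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._elements import atomic_weight

#: CODATA conversion factor, 1 Hartree in kJ/mol.
HARTREE_TO_KJ_PER_MOL = 2625.499639

MIN_SCAN_POINTS = 5


class ScanFormatError(ValueError):
    """Raised when a scan/descriptor/geometry file violates its format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class DissociationScan:
    """Electronic energy along one bond elongation.

    ``distances`` are bond lengths in Å (strictly increasing); ``energies``
    are electronic energies in kJ/mol relative to the separated fragments
    (the value at infinite separation is 0 by convention).
    """

    distances: np.ndarray
    energies: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.distances.ndim != 1 or self.distances.shape != self.energies.shape:
            raise ValueError("distances and energies must be 1-D and equal length")
        if self.distances.size < MIN_SCAN_POINTS:
            raise ValueError(
                f"scan needs at least {MIN_SCAN_POINTS} points, got {self.distances.size}"
            )
        if not (np.isfinite(self.distances).all() and np.isfinite(self.energies).all()):
            raise ValueError("scan contains non-finite values")
        if not np.all(np.diff(self.distances) > 0):
            raise ValueError("distances must be strictly increasing")

    def __len__(self) -> int:
        return int(self.distances.size)


@dataclass
class DescriptorSeries:
    """A bond-strength descriptor (IBSI, MBO, LBO, ELF, LIE, LED, ...) sampled
    along the same scan grid as the energies.

    ``normalized_values`` is populated by :func:`barrierless.core.normalize_descriptor`
    and maps the raw series affinely onto [0, 1].
    """

    name: str
    distances: np.ndarray
    raw_values: np.ndarray
    normalized_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.raw_values = np.asarray(self.raw_values, dtype=float)
        if self.distances.shape != self.raw_values.shape:
            raise ValueError("distances and raw_values must have equal length")
        if not np.isfinite(self.raw_values).all():
            raise ValueError("descriptor values must be finite")
        if self.normalized_values is not None:
            self.normalized_values = np.asarray(self.normalized_values, dtype=float)
            if self.normalized_values.shape != self.distances.shape:
                raise ValueError("normalized_values length mismatch")
            lo, hi = self.normalized_values.min(), self.normalized_values.max()
            if lo < -1e-12 or hi > 1 + 1e-12:
                raise ValueError("normalized_values must lie in [0, 1]")


@dataclass
class SpeciesInput:
    """Geometry, frequencies and metadata of one species (complex or fragment)."""

    element_symbols: list[str]
    coordinates: np.ndarray  # (N, 3), Å
    frequencies: np.ndarray  # cm^-1
    multiplicity: int = 1
    symmetry_number: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        n = len(self.element_symbols)
        if self.coordinates.shape[0] != n:
            raise ValueError("coordinate count does not match element count")
        for sym in self.element_symbols:
            atomic_weight(sym)  # validates the symbol
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")
        if self.symmetry_number < 1:
            raise ValueError("symmetry number must be >= 1")
        max_modes = max(3 * n - 5, 0)  # linear bound; the looser of the two
        if n >= 2 and self.frequencies.size > max_modes:
            raise ValueError(
                f"{self.frequencies.size} frequencies exceed the {max_modes} "
                f"internal modes of a {n}-atom species"
            )

    @property
    def molar_mass(self) -> float:
        """Molar mass in kg/mol from standard atomic weights."""
        return sum(atomic_weight(s) for s in self.element_symbols) / 1000.0


# ---------------------------------------------------------------------------
# table reading
# ---------------------------------------------------------------------------

def _parse_table(path: str | Path, ncols: int) -> np.ndarray:
    """Parse a comma- or whitespace-separated numeric table, skipping '#' comments
    and an optional single header row."""
    rows: list[list[float]] = []
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        text = line.split("#", 1)[0].strip()
        if not text:
            continue
        tokens = [t for t in text.replace(",", " ").split() if t]
        try:
            values = [float(t) for t in tokens]
        except ValueError:
            if not rows and lineno <= 2:  # tolerate one header line
                continue
            raise ScanFormatError(
                f"{path}: non-numeric cell on line {lineno}: {line.strip()!r}"
            ) from None
        if len(values) != ncols:
            raise ScanFormatError(
                f"{path}: expected {ncols} columns on line {lineno}, got {len(values)}"
            )
        rows.append(values)
    return np.asarray(rows, dtype=float).reshape(-1, ncols)


def read_scan_table(
    path: str | Path,
    energy_unit: str = "kj_per_mol",
    reference: str = "separated_fragments",
    separated_energy: float | None = None,
    label: str = "",
) -> DissociationScan:
    """Read a two-column (distance Å, electronic energy) scan table.

    Parameters
    ----------
    energy_unit
        ``"hartree"`` or ``"kj_per_mol"``; hartrees are converted with
        1 Eh = 2625.499639 kJ/mol.
    reference
        ``"separated_fragments"`` if the energies are already zero at infinite
        separation, ``"raw"`` if they are absolute — then ``separated_energy``
        (same unit as the file) is subtracted to re-reference them.
    """
    if energy_unit not in ("hartree", "kj_per_mol"):
        raise ValueError(f"unknown energy unit: {energy_unit!r}")
    if reference not in ("separated_fragments", "raw"):
        raise ValueError(f"unknown reference: {reference!r}")
    data = _parse_table(path, 2)
    if data.shape[0] < MIN_SCAN_POINTS:
        raise ScanFormatError(
            f"{path}: scan has {data.shape[0]} rows, need at least {MIN_SCAN_POINTS}"
        )
    r, e = data[:, 0], data[:, 1]
    if np.unique(r).size != r.size:
        raise ScanFormatError(f"{path}: duplicate distances in scan")
    if reference == "raw":
        if separated_energy is None:
            raise ValueError("reference='raw' requires separated_energy")
        e = e - separated_energy
    if energy_unit == "hartree":
        e = e * HARTREE_TO_KJ_PER_MOL
    order = np.argsort(r)
    return DissociationScan(r[order], e[order], label=label or str(path))


def read_descriptor_table(path: str | Path, name: str = "descriptor") -> DescriptorSeries:
    """Read a two-column (distance Å, raw descriptor value) table."""
    data = _parse_table(path, 2)
    order = np.argsort(data[:, 0])
    return DescriptorSeries(name, data[order, 0], data[order, 1])


def write_scan_table(scan: DissociationScan, path: str | Path) -> None:
    """Write a scan as a two-column table (full double precision)."""
    with open(path, "w") as fh:
        fh.write("# distance_angstrom  energy_kj_per_mol\n")
        for r, e in zip(scan.distances, scan.energies):
            fh.write(f"{float(r)!r} {float(e)!r}\n")


def write_descriptor_table(series: DescriptorSeries, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# distance_angstrom  {series.name}\n")
        for r, v in zip(series.distances, series.raw_values):
            fh.write(f"{float(r)!r} {float(v)!r}\n")


# ---------------------------------------------------------------------------
# geometries and frequencies
# ---------------------------------------------------------------------------

def read_xyz(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a standard XYZ file: atom count, comment, then ``symbol x y z``."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ScanFormatError(f"{path}: empty XYZ file")
    try:
        natoms = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ScanFormatError(f"{path}: first line must be the atom count") from None
    body = [ln for ln in lines[2:] if ln.strip()]
    if len(body) < natoms:
        raise ScanFormatError(
            f"{path}: declared {natoms} atoms but found {len(body)} coordinate lines"
        )
    symbols: list[str] = []
    coords = np.empty((natoms, 3), dtype=float)
    for i, line in enumerate(body[:natoms]):
        parts = line.split()
        if len(parts) < 4:
            raise ScanFormatError(f"{path}: malformed coordinate line: {line!r}")
        sym = parts[0].capitalize()
        atomic_weight(sym)  # unknown symbol -> ValueError
        symbols.append(sym)
        try:
            coords[i] = [float(p) for p in parts[1:4]]
        except ValueError:
            raise ScanFormatError(f"{path}: non-numeric coordinate: {line!r}") from None
    return symbols, coords


def write_xyz(symbols: Sequence[str], coordinates: np.ndarray, path: str | Path,
              comment: str = "") -> None:
    coordinates = np.asarray(coordinates, dtype=float).reshape(-1, 3)
    with open(path, "w") as fh:
        fh.write(f"{len(symbols)}\n{comment}\n")
        for sym, (x, y, z) in zip(symbols, coordinates):
            fh.write(f"{sym} {x: .10f} {y: .10f} {z: .10f}\n")


def read_frequencies(path: str | Path) -> np.ndarray:
    """Read harmonic frequencies in cm^-1: one per line, or a JSON list."""
    text = Path(path).read_text().strip()
    if text.startswith("["):
        return np.asarray(json.loads(text), dtype=float)
    return _parse_table(path, 1)[:, 0]


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonify(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def write_report(result, path: str | Path, timestamp: str | None = None) -> dict:
    """Serialize a :class:`barrierless.core.FreeEnergyResult` to JSON.

    The report contains every fit parameter, the free-energy grid, both
    barriers (or an explicit no-barrier marker), the run parameters and the
    package version; it round-trips losslessly through :func:`read_report`.
    """
    from . import __version__

    doc = {
        "software": {"name": "barrierless", "version": __version__},
        "timestamp": timestamp,
        "result": _jsonify(result.to_dict()),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return doc


def read_report(path: str | Path):
    """Load a report written by :func:`write_report` back into a FreeEnergyResult."""
    from .core import FreeEnergyResult

    with open(path) as fh:
        doc = json.load(fh)
    return FreeEnergyResult.from_dict(doc["result"])
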