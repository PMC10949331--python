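"""Core domain containers and plain-text readers/writers.

Unit conventions, shared by every analysis stage:

* scattering vector ``q`` in inverse Angstrom (SAXS convention);
* real-space lengths reported in nanometres; the single conversion
  factor lives in :data:`INV_ANGSTROM_PER_INV_NM`;
* residue numbering is 1-based inclusive.

All containers validate their invariants at construction, so downstream
code never re-checks monotonicity, lengths, or positivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

logger = logging.getLogger("gelkit")

#: multiply q in 1/nm by this to get q in 1/Angstrom (and vice versa).
INV_ANGSTROM_PER_INV_NM = 0.1
#: nanometres per Angstrom.
NM_PER_ANGSTROM = 0.1

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


class ParseError(ValueError):
    """Malformed input file (names the offending line where possible)."""


class ValidationError(ValueError):
    """Data violates a container invariant."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be 1-D, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class ScatteringCurve:
    """Small-angle scattering curve: q (1/A), intensity, optional 1-sigma."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self):
        q = _as_float_array(self.q, "q")
        i = _as_float_array(self.intensity, "intensity")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "intensity", i)
        if q.size != i.size:
            raise ValidationError("q and intensity lengths differ")
        if q.size and q[0] <= 0:
            raise ValidationError("q must be positive")
        if np.any(np.diff(q) <= 0):
            raise ValidationError("q must be strictly increasing")
        if self.sigma is not None:
            s = _as_float_array(self.sigma, "sigma")
            object.__setattr__(self, "sigma", s)
            if s.size != q.size:
                raise ValidationError("sigma length differs from q")
            if np.any(s <= 0):
                raise ValidationError("sigma must be positive")

    def __len__(self) -> int:
        return self.q.size


@dataclass(frozen=True)
class Spectrum:
    """Optical spectrum: abscissa in nm (CD) or 1/cm (FTIR), plus metadata.

    ``meta`` may carry temperature (degC), concentration (mM), path length
    (cm) and amide-bond count, as needed by MRE conversion.
    """

    abscissa: np.ndarray
    signal: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        x = _as_float_array(self.abscissa, "abscissa")
        y = _as_float_array(self.signal, "signal")
        object.__setattr__(self, "abscissa", x)
        object.__setattr__(self, "signal", y)
        if x.size != y.size:
            raise ValidationError("abscissa and signal lengths differ")
        d = np.diff(x)
        if d.size and not (np.all(d > 0) or np.all(d < 0)):
            raise ValidationError("abscissa must be strictly monotone")

    def __len__(self) -> int:
        return self.abscissa.size

    def ascending(self) -> "Spectrum":
        """Return a copy with strictly increasing abscissa."""
        if self.abscissa.size < 2 or self.abscissa[1] > self.abscissa[0]:
            return self
        return Spectrum(self.abscissa[::-1].copy(), self.signal[::-1].copy(), dict(self.meta))


@dataclass(frozen=True)
class KineticTrace:
    """Time course: t (s or min, non-negative, increasing) vs signal y.

    For survival traces y is dimensionless and should stay in [0, 1]
    up to the noise allowance; that is diagnosed, not enforced, since
    experimental noise legitimately overshoots 1 slightly.
    """

    t: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        t = _as_float_array(self.t, "t")
        y = _as_float_array(self.y, "y")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)
        if t.size != y.size:
            raise ValidationError("t and y lengths differ")
        if t.size and t[0] < 0:
            raise ValidationError("t must be non-negative")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("t must be strictly increasing")

    def __len__(self) -> int:
        return self.t.size


def _read_columns(path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.replace(",", " ").split()
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                raise ParseError(f"{path}: non-numeric data on line {lineno}: {stripped!r}")
    if not rows:
        raise ParseError(f"{path}: no data rows")
    width = len(rows[0])
    for i, r in enumerate(rows, start=1):
        if len(r) != width:
            raise ParseError(f"{path}: row {i} has {len(r)} columns, expected {width}")
    return np.array(rows, dtype=float)


def read_curve(path, kind: str = "saxs", meta: dict | None = None):
    """Read a 2- or 3-column delimited text file into the typed container.

    Parameters
    ----------
    path : path-like
        Whitespace- or comma-delimited text; ``#`` starts a comment line.
    kind : {"saxs", "spectrum", "trace"}
        Chooses :class:`ScatteringCurve`, :class:`Spectrum` or
        :class:`KineticTrace`.
    meta : dict, optional
        Metadata attached to spectra (temperature, concentration, ...).
    """
    data = _read_columns(path)
    ncol = data.shape[1]
    if kind == "saxs":
        if ncol == 2:
            return ScatteringCurve(data[:, 0], data[:, 1])
        if ncol == 3:
            return ScatteringCurve(data[:, 0], data[:, 1], data[:, 2])
        raise ParseError(f"{path}: expected 2 or 3 columns for SAXS, got {ncol}")
    if kind == "spectrum":
        if ncol != 2:
            raise ParseError(f"{path}: expected 2 columns for a spectrum, got {ncol}")
        return Spectrum(data[:, 0], data[:, 1], meta or {})
    if kind == "trace":
        if ncol != 2:
            raise ParseError(f"{path}: expected 2 columns for a trace, got {ncol}")
        return KineticTrace(data[:, 0], data[:, 1])
    raise ValueError(f"unknown kind {kind!r}")


def write_curve(obj, path, header: str = "") -> None:
    """Write any of the three containers back to delimited text (repr precision)."""
    if isinstance(obj, ScatteringCurve):
        cols = [obj.q, obj.intensity] + ([obj.sigma] if obj.sigma is not None else [])
    elif isinstance(obj, Spectrum):
        cols = [obj.abscissa, obj.signal]
    elif isinstance(obj, KineticTrace):
        cols = [obj.t, obj.y]
    else:
        raise TypeError(f"cannot write {type(obj).__name__}")
    data = np.column_stack(cols)
    lines = []
    if header:
        lines.extend("# " + h for h in header.splitlines())
    for row in data:
        lines.append(" ".join(repr(float(v)) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_fasta(path, regions: dict | None = None) -> list:
    """Read a FASTA file into :class:`~gelkit.sequence.SequenceRecord` objects.

    Residues are uppercased and validated against the 20-letter alphabet.
    ``regions`` maps record id -> {name: (start, stop)} (1-based inclusive)
    and is attached where ids match.
    """
    from gelkit.sequence import SequenceRecord

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        if not residues:
            raise ParseError(f"{path}: empty record {rec.id!r}")
        bad = sorted(set(residues) - AMINO_ACIDS)
        if bad:
            raise ParseError(
                f"{path}: record {rec.id!r} has non-amino-acid characters: {''.join(bad)}"
            )
        reg = (regions or {}).get(rec.id, {})
        records.append(SequenceRecord(id=rec.id, residues=residues, regions=dict(reg)))
    if not records:
        raise ParseError(f"{path}: no FASTA records")
    return records


def read_ensemble(path):
    """Read a multi-frame XYZ-style file (one bead per residue per frame).

    Each frame: a count line, a comment line, then ``count`` lines of
    ``label x y z``. Coordinates are in nm. Weights are uniform.
    """
    from gelkit.ensemble import Ensemble

    frames = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i, frame_idx = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"{path}: expected bead count at line {i + 1}")
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ParseError(f"{path}: frame {frame_idx} truncated")
        coords = np.empty((n, 3))
        for j, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise ParseError(f"{path}: frame {frame_idx}, bead line {j + 1} malformed")
            coords[j] = [float(p) for p in parts[1:4]]
        frames.append(coords)
        i += 2 + n
        frame_idx += 1
    if not frames:
        raise ParseError(f"{path}: no frames")
    n0 = frames[0].shape[0]
    for k, fr in enumerate(frames):
        if fr.shape[0] != n0:
            raise ParseError(f"{path}: ragged frame {k} ({fr.shape[0]} beads, expected {n0})")
    return Ensemble(coords=np.stack(frames))


def write_ensemble(ens, path, label: str = "CA") -> None:
    """Write an Ensemble to multi-frame XYZ text (coordinates in nm)."""
    lines = []
    for f in range(ens.n_frames):
        lines.append(str(ens.n_beads))
        lines.append(f"frame {f}")
        for bead in ens.coords[f]:
            lines.append(
                f"{label} {float(bead[0])!r} {float(bead[1])!r} {float(bead[2])!r}"
            )
    Path(path).write_text("\n".join(lines) + "\n")
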