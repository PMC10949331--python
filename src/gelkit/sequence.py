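"""Sequence-level descriptors for charged disordered proteins.

The central quantity is the Das–Pappu charge-patterning parameter
``kappa``: 0 for linearly well-mixed charge, 1 for fully segregated
blocks of like charge.  A gel-forming CAHS-family protein partitions
into an N-terminal region, a central linker, and a C-terminal region;
region arithmetic here is 1-based inclusive throughout.

Conventions (matching the reference kappa implementations in the field):
aspartate/glutamate carry −1, lysine/arginine +1, histidine 0 at
neutral pH, termini charges ignored; blob sizes 5 and 6 are averaged;
the normalizing delta_max comes from a deterministic scan of maximally
segregated arrangements of the same composition (charge blocks separated
by the neutral block).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gelkit.io import AMINO_ACIDS, ValidationError

NEGATIVE = set("DE")
POSITIVE = set("KR")

#: Fauchere–Pliska octanol/water hydropathy scale.
FAUCHERE_PLISKA = {
    "A": 0.31, "R": -1.01, "N": -0.60, "D": -0.77, "C": 1.54,
    "Q": -0.22, "E": -0.64, "G": 0.00, "H": 0.13, "I": 1.80,
    "L": 1.70, "K": -0.99, "M": 1.23, "F": 1.79, "P": 0.72,
    "S": -0.04, "T": 0.26, "W": 2.25, "Y": 0.96, "V": 1.22,
}

RESIDUE_CLASSES = {
    "aliphatic": set("MVIL"),
    "aromatic": set("FWY"),
    "polar_amide": set("QN"),
    "negative": NEGATIVE,
    "positive": POSITIVE,
    "small": set("AGSTC"),
    "proline": set("P"),
    "histidine": set("H"),
}


@dataclass(frozen=True)
class SequenceRecord:
    """Amino-acid sequence with named regions (1-based inclusive spans)."""

    id: str
    residues: str
    regions: dict = field(default_factory=dict)

    def __post_init__(self):
        bad = sorted(set(self.residues) - AMINO_ACIDS)
        if bad:
            raise ValidationError(f"invalid residues: {''.join(bad)}")
        if not self.residues:
            raise ValidationError("empty sequence")
        for name, (start, stop) in self.regions.items():
            if not (1 <= start <= stop <= len(self.residues)):
                raise ValidationError(
                    f"region {name!r} span ({start}, {stop}) outside [1, {len(self.residues)}]"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def region_seq(self, name: str) -> str:
        if name not in self.regions:
            raise KeyError(f"unknown region {name!r}; have {sorted(self.regions)}")
        start, stop = self.regions[name]
        return self.residues[start - 1 : stop]


@dataclass(frozen=True)
class ChargePattern:
    """Charge-patterning summary: kappa, FCR, NCPR and the blob sizes used."""

    kappa: float
    fcr: float
    ncpr: float
    blob_sizes: tuple = (5, 6)

    def __post_init__(self):
        if not (0.0 <= self.kappa <= 1.0 + 1e-12):
            raise ValidationError(f"kappa {self.kappa} outside [0, 1]")
        if abs(self.ncpr) > self.fcr + 1e-12:
            raise ValidationError("|NCPR| cannot exceed FCR")


def _charges(seq: str) -> np.ndarray:
    return np.array([1 if r in POSITIVE else -1 if r in NEGATIVE else 0 for r in seq])


def _sigma(charges: np.ndarray) -> float:
    """Local charge asymmetry (f+ - f-)^2 / (f+ + f-); 0 if no charges."""
    n = charges.size
    fpos = np.count_nonzero(charges > 0) / n
    fneg = np.count_nonzero(charges < 0) / n
    if fpos + fneg == 0:
        return 0.0
    return (fpos - fneg) ** 2 / (fpos + fneg)


def _delta(charges: np.ndarray, blob: int) -> float:
    """Mean squared deviation of blob asymmetry from global asymmetry."""
    sig_global = _sigma(charges)
    n = charges.size
    n_blobs = n - blob + 1
    devs = np.empty(n_blobs)
    for i in range(n_blobs):
        devs[i] = (_sigma(charges[i : i + blob]) - sig_global) ** 2
    return float(devs.mean())


def _delta_max(charges: np.ndarray, blob: int) -> float:
    """delta of the maximally segregated arrangement, found deterministically.

    Candidates place the negative block, then s neutrals, then the
    positive block, with the remaining neutrals appended, for every
    split s — the in-between neutrals maximally separate the opposing
    charge blocks.  This scan keeps kappa <= 1 where the plain
    charges-first arrangement would not, while staying reproducible
    (no stochastic permutation search).
    """
    neg = np.count_nonzero(charges < 0)
    pos = np.count_nonzero(charges > 0)
    neu = charges.size - neg - pos
    best = 0.0
    for split in range(neu + 1):
        arrangement = np.concatenate(
            [
                -np.ones(neg, int),
                np.zeros(split, int),
                np.ones(pos, int),
                np.zeros(neu - split, int),
            ]
        )
        best = max(best, _delta(arrangement, blob))
    return best


def kappa(seq, blob_sizes: tuple = (5, 6)) -> ChargePattern:
    """Das–Pappu charge-patterning kappa of a sequence or region string.

    kappa = mean over blob sizes of delta/delta_max, with delta the mean
    squared deviation of sliding-blob charge asymmetry from the global
    asymmetry, and delta_max from a deterministic scan over maximally
    segregated arrangements of the same composition.

    Parameters
    ----------
    seq : str or SequenceRecord
        Sequence; a :class:`SequenceRecord` uses its full residue string.
    blob_sizes : tuple of int
        Sliding-window sizes to average over (default ``(5, 6)``).

    Raises
    ------
    ValidationError
        If the sequence is shorter than ``max(blob)+1`` residues or
        carries no charged residues (kappa undefined).
    """
    residues = seq.residues if isinstance(seq, SequenceRecord) else str(seq).upper()
    charges = _charges(residues)
    if len(residues) < max(blob_sizes) + 1:
        raise ValidationError(f"sequence too short for blob sizes {blob_sizes}")
    if not np.any(charges != 0):
        raise ValidationError("kappa undefined: no charged residues")
    ratios = []
    for blob in blob_sizes:
        dmax = _delta_max(charges, blob)
        if dmax == 0:
            continue
        ratios.append(_delta(charges, blob) / dmax)
    if not ratios:
        raise ValidationError("kappa undefined: delta_max is zero for all blob sizes")
    # rare dilute-charge arrangements can marginally exceed the deterministic
    # delta_max scan; clip so kappa stays a [0, 1] patterning index
    value = min(1.0, float(np.mean(ratios)))
    n = charges.size
    fcr = float(np.count_nonzero(charges) / n)
    ncpr = float(charges.sum() / n)
    return ChargePattern(kappa=value, fcr=fcr, ncpr=ncpr, blob_sizes=tuple(blob_sizes))


def expected_helix_fraction(seq: SequenceRecord, helical_region_names) -> float:
    """Percent of residues inside the named regions, assuming they are fully helical.

    For a 227-residue protein whose linker (residues 91-195) is fully
    helical this gives 100*105/227 ~ 46%.
    Additive over disjoint regions; overlapping regions raise.
    """
    if not helical_region_names:
        return 0.0
    covered = np.zeros(len(seq), dtype=bool)
    for name in helical_region_names:
        if name not in seq.regions:
            raise KeyError(f"unknown region {name!r}")
        start, stop = seq.regions[name]
        span = slice(start - 1, stop)
        if covered[span].any():
            raise ValidationError(f"region {name!r} overlaps another helical region")
        covered[span] = True
    return 100.0 * covered.sum() / len(seq)


def hydrophobic_moment(
    seq_span: str, angle_per_residue: float = 100.0, scale: dict | None = None
):
    """Mean-vector hydrophobic moment of a helical segment.

    Each residue's hydropathy is placed on a helical wheel at
    ``angle_per_residue`` degrees per step (100 deg for an alpha helix);
    the moment is the magnitude of the mean hydropathy vector.  Residues
    are labelled 'hydrophobic' when their wheel position falls in the
    half-plane of the moment vector, 'hydrophilic' otherwise.

    Returns
    -------
    (moment, faces) : (float, list of str)
    """
    span = str(seq_span).upper()
    if len(span) < 2:
        raise ValidationError("hydrophobic moment needs at least 2 residues")
    scale = scale or FAUCHERE_PLISKA
    angles = np.deg2rad(angle_per_residue) * np.arange(len(span))
    h = np.array([scale[r] for r in span])
    mx = float(np.sum(h * np.cos(angles)) / len(span))
    my = float(np.sum(h * np.sin(angles)) / len(span))
    moment = float(np.hypot(mx, my))
    if moment < 1e-12:
        faces = ["hydrophilic"] * len(span)
    else:
        direction = np.arctan2(my, mx)
        delta = np.angle(np.exp(1j * (angles - direction)))
        faces = ["hydrophobic" if abs(d) <= np.pi / 2 else "hydrophilic" for d in delta]
    return moment, faces


def composition_profile(seq) -> dict:
    """Per-class residue fractions; classes overlap-free, remainder explicit.

    Classes: aliphatic (MVIL), aromatic (FWY), polar amide (QN),
    negative (DE), positive (KR), small (AGSTC), proline, histidine.
    Fractions sum to 1 over classes + remainder.
    """
    residues = seq.residues if isinstance(seq, SequenceRecord) else str(seq).upper()
    if not residues:
        raise ValidationError("empty sequence")
    n = len(residues)
    fractions = {}
    assigned = 0
    for cls, members in RESIDUE_CLASSES.items():
        count = sum(1 for r in residues if r in members)
        fractions[cls] = count / n
        assigned += count
    fractions["remainder"] = (n - assigned) / n
    return fractions
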