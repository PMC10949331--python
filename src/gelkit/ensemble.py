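"""Coarse polymer ensembles and ensemble observables.

One bead per residue at the C-alpha-equivalent position, coordinates in
nanometres.  Reference states:

* Gaussian chain — i.i.d. Gaussian bond vectors with <r_ij^2> = b^2 |i-j|,
  the ideal-chain stand-in for an analytical Flory random coil;
* self-avoiding random coil (SARC) — excluded-volume-only conformers
  sampled by the pivot Monte Carlo algorithm with hard-sphere rejection;
* dumbbell — a Gaussian chain whose terminal spans are compacted, which
  emulates a disordered protein with two collapsed termini joined by an
  expanded linker.

Observables (Rg statistics, normalized distance maps against a reference
state, per-residue contact order, Debye scattering with unit form
factors) all honour per-frame weights, so reweighted ensembles are
analysed with the same code paths as raw ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.spatial.transform import Rotation

from gelkit.io import ScatteringCurve, ValidationError

logger = logging.getLogger("gelkit")

DEFAULT_BOND_NM = 0.55
DEFAULT_CONTACT_CUTOFF_NM = 0.8
DEFAULT_NEIGHBOR_EXCLUSION = 2


@dataclass(frozen=True)
class Ensemble:
    """Conformer ensemble: coords (frames, beads, 3) in nm plus frame weights."""

    coords: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValidationError(f"coords must be (frames, beads, 3), got {coords.shape}")
        object.__setattr__(self, "coords", coords)
        if self.weights is None:
            w = np.full(coords.shape[0], 1.0 / coords.shape[0])
        else:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (coords.shape[0],):
                raise ValidationError("weights length must equal frame count")
            if np.any(w < 0):
                raise ValidationError("weights must be non-negative")
            total = w.sum()
            if total <= 0:
                raise ValidationError("weights sum to zero")
            if abs(total - 1.0) > 1e-9:
                w = w / total
        object.__setattr__(self, "weights", w)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_beads(self) -> int:
        return self.coords.shape[1]

    def with_weights(self, weights) -> "Ensemble":
        return Ensemble(self.coords, np.asarray(weights, dtype=float))

    def subsample(self, step: int) -> "Ensemble":
        """Keep one frame in every ``step`` (weights renormalized)."""
        return Ensemble(self.coords[::step], self.weights[::step])


@dataclass(frozen=True)
class DistanceMap:
    """Mean inter-bead distances vs a reference state, and their ratio."""

    mean_dij: np.ndarray
    reference_dij: np.ndarray
    ratio: np.ndarray


@dataclass(frozen=True)
class ContactOrderProfile:
    """Per-residue weighted fraction of frames with a non-neighbour contact."""

    fractions: np.ndarray
    cutoff: float
    neighbor_exclusion: int

    def flagged(self, threshold: float = 0.02) -> np.ndarray:
        """1-based residue indices whose contact fraction exceeds ``threshold``."""
        return np.nonzero(self.fractions > threshold)[0] + 1


# ---------------------------------------------------------------------------
# generators


def _chain_from_bonds(bonds: np.ndarray) -> np.ndarray:
    coords = np.concatenate([np.zeros((bonds.shape[0], 1, 3)), np.cumsum(bonds, axis=1)], axis=1)
    return coords - coords.mean(axis=1, keepdims=True)


def gaussian_chain_ensemble(
    n: int, bond: float = DEFAULT_BOND_NM, frames: int = 1000, seed: int = 0
) -> Ensemble:
    """Ideal (Gaussian) chain: i.i.d. Gaussian bond vectors, <r_ij^2> = b^2|i-j|.

    Each bond component is N(0, b^2/3) so the bond length RMS is ``bond``.
    """
    if n < 2:
        raise ValidationError("need at least 2 beads")
    rng = np.random.default_rng(seed)
    bonds = rng.normal(0.0, bond / np.sqrt(3.0), size=(frames, n - 1, 3))
    return Ensemble(_chain_from_bonds(bonds))


def dumbbell_ensemble(
    n: int,
    termini_spans,
    compaction_factor: float,
    bond: float = DEFAULT_BOND_NM,
    frames: int = 1000,
    seed: int = 0,
) -> Ensemble:
    """Gaussian chain with compacted terminal spans (a dumbbell topology).

    Bond vectors whose both endpoints lie inside a terminus span (1-based
    inclusive residue indices) are scaled by ``compaction_factor`` in
    (0, 1]; factor 1 recovers the plain Gaussian chain.
    """
    if not (0.0 < compaction_factor <= 1.0):
        raise ValidationError("compaction_factor must be in (0, 1]")
    spans = [tuple(s) for s in termini_spans]
    for a, (s1, e1) in enumerate(spans):
        if not (1 <= s1 <= e1 <= n):
            raise ValidationError(f"span {(s1, e1)} outside [1, {n}]")
        for s2, e2 in spans[a + 1 :]:
            if not (e1 < s2 or e2 < s1):
                raise ValidationError("termini spans must be disjoint")
    rng = np.random.default_rng(seed)
    bonds = rng.normal(0.0, bond / np.sqrt(3.0), size=(frames, n - 1, 3))
    scale = np.ones(n - 1)
    for start, stop in spans:
        # bond i joins residues i+1 and i+2 (1-based)
        scale[start - 1 : stop - 1] = compaction_factor
    bonds *= scale[None, :, None]
    return Ensemble(_chain_from_bonds(bonds))


class PivotConvergenceError(RuntimeError):
    """No pivot move accepted over the patience window."""


def sarc_ensemble(
    n: int,
    bond: float = DEFAULT_BOND_NM,
    bead_radius: float = 0.2,
    frames: int = 200,
    seed: int = 0,
    burn_in_sweeps: int = 10,
    thin_sweeps: int = 5,
    patience: int = 2000,
) -> Ensemble:
    """Self-avoiding random coil via pivot Monte Carlo with hard-sphere rejection.

    Starts from a straight rod; each move picks a random internal bead
    and rotates the downstream tail by a uniform random rotation,
    rejecting any conformation with two beads (|i-j| > 1) closer than
    ``2 * bead_radius``.  One pivot attempt per bead per sweep; frames
    are recorded every ``thin_sweeps`` sweeps after ``burn_in_sweeps``.

    Raises
    ------
    PivotConvergenceError
        If ``patience`` consecutive moves are all rejected.
    """
    if n < 3:
        raise ValidationError("need at least 3 beads for pivot moves")
    if 2 * bead_radius > bond:
        logger.warning(
            "bead diameter %.3f nm exceeds bond length %.3f nm; sampling may stall",
            2 * bead_radius,
            bond,
        )
    rng = np.random.default_rng(seed)
    coords = np.zeros((n, 3))
    coords[:, 0] = bond * np.arange(n)
    min_d2 = (2.0 * bead_radius) ** 2

    accepted = rejected_streak = 0
    out = np.empty((frames, n, 3))
    collected = 0
    sweeps_done = 0
    while collected < frames:
        for _ in range(n):  # one sweep
            p = int(rng.integers(1, n - 1))
            rot = Rotation.random(rng=rng).as_matrix()
            pivot = coords[p]
            tail = (coords[p + 1 :] - pivot) @ rot.T + pivot
            # overlap check tail vs head (bonded neighbour p/p+1 excluded)
            head = coords[: p + 1]
            d2 = np.sum((tail[:, None, :] - head[None, :, :]) ** 2, axis=-1)
            d2[0, p] = np.inf  # bonded pair
            if np.min(d2) >= min_d2:
                coords = np.concatenate([head, tail])
                accepted += 1
                rejected_streak = 0
            else:
                rejected_streak += 1
                if rejected_streak >= patience:
                    raise PivotConvergenceError(
                        f"no accepted pivot in {patience} consecutive moves"
                    )
        sweeps_done += 1
        if sweeps_done > burn_in_sweeps and (sweeps_done - burn_in_sweeps) % thin_sweeps == 0:
            out[collected] = coords - coords.mean(axis=0)
            collected += 1
    total_moves = sweeps_done * n
    logger.info(
        "sarc_ensemble n=%d: %d/%d pivots accepted (%.1f%%)",
        n,
        accepted,
        total_moves,
        100.0 * accepted / total_moves,
    )
    return Ensemble(out)


# ---------------------------------------------------------------------------
# observables


def rg_statistics(ens: Ensemble):
    """Per-frame radius of gyration and weighted mean/SD (nm).

    Returns
    -------
    dict with keys ``rg`` (per-frame array), ``mean``, ``sd``.
    """
    centered = ens.coords - ens.coords.mean(axis=1, keepdims=True)
    rg = np.sqrt(np.mean(np.sum(centered**2, axis=2), axis=1))
    mean = float(np.sum(ens.weights * rg))
    var = float(np.sum(ens.weights * (rg - mean) ** 2))
    return {"rg": rg, "mean": mean, "sd": float(np.sqrt(max(var, 0.0)))}


def _weighted_mean_distance_matrix(ens: Ensemble) -> np.ndarray:
    n = ens.n_beads
    acc = np.zeros(n * (n - 1) // 2)
    for w, frame in zip(ens.weights, ens.coords):
        acc += w * pdist(frame)
    return squareform(acc)


def normalized_distance_map(ens: Ensemble, reference: Ensemble) -> DistanceMap:
    """Elementwise ratio of mean inter-residue distances to a reference state.

    Ratio < 1 marks pairs closer than the reference (compaction); ratio
    is 1 on the diagonal by convention.
    """
    if ens.n_beads != reference.n_beads:
        raise ValidationError(
            f"bead count mismatch: {ens.n_beads} vs {reference.n_beads}"
        )
    mean_dij = _weighted_mean_distance_matrix(ens)
    ref_dij = _weighted_mean_distance_matrix(reference)
    ratio = np.ones_like(mean_dij)
    mask = ref_dij > 0
    ratio[mask] = mean_dij[mask] / ref_dij[mask]
    return DistanceMap(mean_dij=mean_dij, reference_dij=ref_dij, ratio=ratio)


def contact_order_profile(
    ens: Ensemble,
    cutoff: float = DEFAULT_CONTACT_CUTOFF_NM,
    neighbor_exclusion: int = DEFAULT_NEIGHBOR_EXCLUSION,
) -> ContactOrderProfile:
    """Weighted fraction of frames in which each residue has a contact.

    A contact is any bead within ``cutoff`` (nm) whose sequence
    separation exceeds ``neighbor_exclusion``.
    """
    if cutoff <= 0:
        raise ValidationError("cutoff must be positive")
    n = ens.n_beads
    sep = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    allowed = sep > neighbor_exclusion
    fractions = np.zeros(n)
    for w, frame in zip(ens.weights, ens.coords):
        d = squareform(pdist(frame))
        contact = (d < cutoff) & allowed
        fractions += w * contact.any(axis=1)
    return ContactOrderProfile(
        fractions=fractions, cutoff=cutoff, neighbor_exclusion=neighbor_exclusion
    )


def debye_scattering(ens: Ensemble, q_grid) -> ScatteringCurve:
    """Debye scattering of unit point scatterers, weighted over frames.

    I(q) = sum_f w_f sum_{i,j} sinc(q * r_ij), so I(0) = n_beads^2
    exactly.  q is in 1/Angstrom, coordinates in nm (converted
    internally).
    """
    q = np.asarray(q_grid, dtype=float)
    if np.any(q < 0):
        raise ValidationError("q must be non-negative")
    n = ens.n_beads
    intensity = np.zeros_like(q)
    for w, frame in zip(ens.weights, ens.coords):
        r_ang = 10.0 * pdist(frame)  # nm -> Angstrom
        x = np.outer(q, r_ang)
        # np.sinc(x/pi) = sin(x)/x with the x=0 limit handled
        intensity += w * (n + 2.0 * np.sinc(x / np.pi).sum(axis=1))
    # return on a strictly positive, increasing grid if q[0] == 0 is passed
    if q.size and q[0] == 0.0:
        return ScatteringCurve(q[1:], intensity[1:]) if q.size > 1 else _point_curve(intensity)
    return ScatteringCurve(q, intensity)


def _point_curve(intensity):
    raise ValidationError("q grid must contain at least one positive point")


def guinier_rg_check(ens: Ensemble, n_q: int = 20) -> float:
    """Rg (nm) from a Guinier fit of the ensemble's own Debye curve.

    Small-q consistency helper: the grid is chosen so q_max * Rg ~ 1.
    """
    from gelkit.saxs import GuinierModel

    rg_nm = rg_statistics(ens)["mean"]
    q_max = 1.0 / (10.0 * rg_nm)  # 1/A
    q = np.linspace(q_max / n_q, q_max, n_q)
    curve = debye_scattering(ens, q)
    return GuinierModel(curve).fit().rg_nm
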