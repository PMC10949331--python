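"""Sequence descriptors, with a brute-force kappa oracle written from the
definitions (plain Python, independent of the package implementation)."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gelkit.io import ValidationError
from gelkit.sequence import (
    FAUCHERE_PLISKA,
    SequenceRecord,
    composition_profile,
    expected_helix_fraction,
    hydrophobic_moment,
    kappa,
)


# --- independent oracle -----------------------------------------------------


def charge_of(r):
    return {"D": -1, "E": -1, "K": 1, "R": 1}.get(r, 0)


def sigma_oracle(seq):
    fp = sum(1 for r in seq if charge_of(r) > 0) / len(seq)
    fm = sum(1 for r in seq if charge_of(r) < 0) / len(seq)
    return 0.0 if fp + fm == 0 else (fp - fm) ** 2 / (fp + fm)


def delta_oracle(seq, blob):
    g = sigma_oracle(seq)
    blobs = [seq[i : i + blob] for i in range(len(seq) - blob + 1)]
    return sum((sigma_oracle(b) - g) ** 2 for b in blobs) / len(blobs)


def delta_max_oracle(seq, blob):
    """Deterministic segregated-arrangement scan: neg block, s neutrals,
    pos block, remaining neutrals, maximized over s."""
    neg = seq.count("E") + seq.count("D")
    pos = seq.count("K") + seq.count("R")
    neu = len(seq) - neg - pos
    return max(
        delta_oracle("E" * neg + "A" * s + "K" * pos + "A" * (neu - s), blob)
        for s in range(neu + 1)
    )


def kappa_oracle(seq, blob_sizes=(5, 6)):
    vals = []
    for b in blob_sizes:
        dmax = delta_max_oracle(seq, b)
        if dmax > 0:
            vals.append(delta_oracle(seq, b) / dmax)
    return min(1.0, sum(vals) / len(vals))


# --- kappa ------------------------------------------------------------------


class TestKappa:
    def test_fully_segregated_is_one(self):
        assert kappa("E" * 25 + "K" * 25).kappa == pytest.approx(1.0)

    def test_perfectly_alternating_is_nearly_zero(self):
        val = kappa("EK" * 25).kappa
        assert val < 0.01
        assert val == pytest.approx(kappa_oracle("EK" * 25), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle_on_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("EKAGSDRQ"), size=40))
        if all(charge_of(r) == 0 for r in seq):
            pytest.skip("no charges drawn")
        assert kappa(seq).kappa == pytest.approx(kappa_oracle(seq), abs=1e-12)

    def test_segregated_scan_nearly_dominates_every_permutation(self):
        # the deterministic delta_max scan tracks the exhaustive maximum
        # over all distinct arrangements of 3 E, 3 K, 2 A to within a few
        # percent (exact dominance is impossible for any deterministic
        # block arrangement; kappa is clipped at 1 for those rare cases)
        residues = "EEEKKKAA"
        for blob in (5, 6):
            dmax = delta_max_oracle(residues, blob)
            exhaustive = max(
                delta_oracle("".join(perm), blob)
                for perm in set(itertools.permutations(residues))
            )
            assert dmax >= 0.95 * exhaustive

    def test_reversal_invariance_and_bounds(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            seq = "".join(rng.choice(list("EKAG"), size=30))
            if all(charge_of(r) == 0 for r in seq):
                continue
            cp = kappa(seq)
            assert cp.kappa == pytest.approx(kappa(seq[::-1]).kappa, abs=1e-12)
            assert 0.0 <= cp.kappa <= 1.0

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.text(alphabet="EKDRAGSQ", min_size=10, max_size=60))
    def test_kappa_of_any_charged_sequence_is_in_unit_interval(self, seq):
        if all(charge_of(r) == 0 for r in seq):
            return
        cp = kappa(seq)
        assert 0.0 <= cp.kappa <= 1.0 + 1e-12
        assert abs(cp.ncpr) <= cp.fcr + 1e-12

    def test_uncharged_sequence_raises(self):
        with pytest.raises(ValidationError, match="no charged"):
            kappa("AAAAAGGGGG")

    def test_too_short_raises(self):
        with pytest.raises(ValidationError):
            kappa("EKEK")

    def test_fcr_and_ncpr(self):
        cp = kappa("EEKKAAAAAA")
        assert cp.fcr == pytest.approx(0.4)
        assert cp.ncpr == pytest.approx(0.0)


# --- regions / helix fraction ----------------------------------------------


@pytest.fixture
def three_region_record():
    n = 227
    return SequenceRecord(
        id="demo",
        residues="".join("EKAG"[i % 4] for i in range(n)),
        regions={"nterm": (1, 90), "linker": (91, 195), "cterm": (196, 227)},
    )


class TestHelixFraction:
    def test_fully_helical_linker_gives_46_percent(self, three_region_record):
        frac = expected_helix_fraction(three_region_record, ["linker"])
        assert frac == pytest.approx(100 * 105 / 227)
        assert round(frac) == 46

    def test_whole_protein_helical_is_100(self, three_region_record):
        assert expected_helix_fraction(
            three_region_record, ["nterm", "linker", "cterm"]
        ) == pytest.approx(100.0)

    def test_empty_region_set_is_zero(self, three_region_record):
        assert expected_helix_fraction(three_region_record, []) == 0.0

    def test_additive_over_disjoint_regions(self, three_region_record):
        parts = sum(
            expected_helix_fraction(three_region_record, [r]) for r in ("nterm", "cterm")
        )
        assert expected_helix_fraction(
            three_region_record, ["nterm", "cterm"]
        ) == pytest.approx(parts)

    def test_unknown_region_raises(self, three_region_record):
        with pytest.raises(KeyError):
            expected_helix_fraction(three_region_record, ["nope"])

    def test_span_outside_sequence_rejected(self):
        with pytest.raises(ValidationError):
            SequenceRecord(id="x", residues="MKVL", regions={"r": (2, 9)})


# --- hydrophobic moment -----------------------------------------------------


class TestHydrophobicMoment:
    def test_homopolymer_wheel_cancels(self):
        moment, _ = hydrophobic_moment("L" * 18, 100.0)
        assert moment < 0.05 * abs(FAUCHERE_PLISKA["L"])

    def test_alternating_at_180_degrees_equals_scale_difference(self):
        # at 180 deg/res the wheel alternates between two opposite points;
        # I (+1.80) at even, K (-0.99) at odd positions add constructively
        moment, _ = hydrophobic_moment("IK" * 10, 180.0)
        expected = (FAUCHERE_PLISKA["I"] - FAUCHERE_PLISKA["K"]) / 2
        assert moment == pytest.approx(expected, abs=1e-9)

    def test_perfect_amphipathic_face_by_vector_sum_oracle(self):
        # hydrophobic L at heptad positions i, i+3, i+4; charged K elsewhere
        seq = "".join("L" if i % 7 in (0, 3, 4) else "K" for i in range(21))
        moment, faces = hydrophobic_moment(seq, 100.0)
        # independent direct vector sum
        ang = np.deg2rad(100.0) * np.arange(len(seq))
        h = np.array([FAUCHERE_PLISKA[r] for r in seq])
        expected = abs(np.sum(h * np.exp(1j * ang))) / len(seq)
        assert moment == pytest.approx(expected, abs=1e-12)
        assert moment > 0.8  # strong amphipathy on this scale
        # the hydrophobic face is mostly leucines
        hydrophobic_residues = {s for s, f in zip(seq, faces) if f == "hydrophobic"}
        assert "L" in hydrophobic_residues

    def test_phase_rotation_invariance(self):
        seq = "LKKLLKA" * 3
        m1, _ = hydrophobic_moment(seq, 100.0)
        # rotating the starting phase means cycling the sequence start angle:
        # magnitude of the vector sum is unchanged by a global rotation
        ang = np.deg2rad(100.0) * (np.arange(len(seq)) + 5)
        h = np.array([FAUCHERE_PLISKA[r] for r in seq])
        m2 = abs(np.sum(h * np.exp(1j * ang))) / len(seq)
        assert m1 == pytest.approx(m2, abs=1e-12)

    def test_single_residue_raises(self):
        with pytest.raises(ValidationError):
            hydrophobic_moment("L", 100.0)


# --- composition ------------------------------------------------------------


class TestComposition:
    def test_pure_aliphatic(self):
        assert composition_profile("MMMM")["aliphatic"] == 1.0

    def test_all_twenty_residues_each_counted_once(self):
        prof = composition_profile("ACDEFGHIKLMNPQRSTVWY")
        assert prof["aliphatic"] == pytest.approx(4 / 20)
        assert prof["negative"] == pytest.approx(2 / 20)
        assert prof["positive"] == pytest.approx(2 / 20)

    @pytest.mark.parametrize("seq", ["MKVL", "EEEE", "ACDEFGHIKLMNPQRSTVWY", "GGGG"])
    def test_fractions_sum_to_one(self, seq):
        assert math.fsum(composition_profile(seq).values()) == pytest.approx(1.0)
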