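"""Shape engine: canonicalization, prediction, symmetrization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motifshape.shape_engine import (
    PentamerRecord,
    PentamerTable,
    all_canonical_pentamers,
    canonical_pentamer,
    load_pentamer_table,
    predict_shape,
    reverse_complement,
    symmetrize_profile,
    write_pentamer_table,
)
from motifshape.simulate import SimulationConfig, make_pentamer_table

from conftest import random_dna

dna = st.text(alphabet="ACGT", min_size=5, max_size=40)


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("CACGTG", "CACGTG"),  # the palindromic E-box
        ("AAAAA", "TTTTT"),
        ("ACGTN", "NACGT"),
    ],
)
def test_reverse_complement(seq, expected):
    assert reverse_complement(seq) == expected


def test_reverse_complement_rejects_bad_characters():
    with pytest.raises(ValueError, match="non-nucleotide"):
        reverse_complement("ACGU!")


@pytest.mark.parametrize(
    "p,canon,rev",
    [("TTTTT", "AAAAA", True), ("AAAAA", "AAAAA", False)],
)
def test_canonical_pentamer(p, canon, rev):
    assert canonical_pentamer(p) == (canon, rev)


def test_canonical_classes_number_512():
    """All 1024 pentamers collapse into exactly 512 strand classes."""
    assert len(all_canonical_pentamers()) == 512


@pytest.mark.parametrize("bad", ["ACGT", "ACGTAA", "ACGNA"])
def test_canonical_pentamer_rejects(bad):
    with pytest.raises(ValueError):
        canonical_pentamer(bad)


class TestTableIO:
    def test_round_trip_bit_exact(self, table, tmp_path):
        path = tmp_path / "table.tsv"
        write_pentamer_table(table, path)
        loaded = load_pentamer_table(path)
        assert loaded.entries == table.entries

    def test_incomplete_table_rejected(self, table, tmp_path):
        path = tmp_path / "short.tsv"
        write_pentamer_table(table, path)
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[:-1]) + "\n")  # 511 rows
        with pytest.raises(ValueError, match="512"):
            load_pentamer_table(path)

    def test_non_canonical_key_rejected(self, table, tmp_path):
        path = tmp_path / "bad.tsv"
        write_pentamer_table(table, path)
        text = path.read_text().replace("AAAAA", "TTTTT", 1)
        path.write_text(text)
        with pytest.raises(ValueError, match="(non-canonical|duplicate)"):
            load_pentamer_table(path)

    def test_non_numeric_cell_rejected(self, table, tmp_path):
        path = tmp_path / "nan.tsv"
        write_pentamer_table(table, path)
        lines = path.read_text().splitlines()
        parts = lines[1].split("\t")
        parts[1] = "wide"
        lines[1] = "\t".join(parts)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="non-numeric"):
            load_pentamer_table(path)


class TestPredictShape:
    def test_single_window(self, table):
        prof = predict_shape("ACGTA", table)
        rec = table["ACGTA"]
        assert np.isnan(prof.mgw).sum() == 4 and prof.mgw[2] == rec.mgw
        assert np.isnan(prof.prot).sum() == 4 and prof.prot[2] == rec.prot
        # the single window defines exactly the two central steps
        assert list(np.isnan(prof.roll)) == [True, False, False, True]
        assert list(np.isnan(prof.helt)) == [True, False, False, True]

    def test_constant_table_identity(self):
        entries = {
            p: PentamerRecord(mgw=5.0, prot=-7.0, roll=(1.0, 1.0), helt=(34.0, 34.0))
            for p in all_canonical_pentamers()
        }
        t = PentamerTable(entries)
        prof = predict_shape("ACGTACGTACGT", t)
        assert np.all(prof.mgw[2:-2] == 5.0)
        assert np.all(prof.roll[1:-1] == 1.0)

    def test_coverage_arithmetic(self, table):
        """An unflanked core defines L-4 positions; 2-bp flanks define all."""
        rng = np.random.default_rng(7)
        for L in range(6, 15):
            core = random_dna(rng, L)
            prof = predict_shape(core, table)
            assert (~np.isnan(prof.mgw)).sum() == L - 4
            assert np.isnan(prof.mgw[[0, 1, -2, -1]]).all()
            flanked = random_dna(rng, 2) + core + random_dna(rng, 2)
            prof_f = predict_shape(flanked, table)
            assert not np.isnan(prof_f.mgw[2 : 2 + L]).any()

    def test_too_short(self, table):
        with pytest.raises(ValueError, match="too short"):
            predict_shape("ACGT", table)

    def test_ambiguous_default_error(self, table):
        with pytest.raises(ValueError, match="ambiguous"):
            predict_shape("ACGNACGT", table)

    def test_ambiguous_mask_mode(self, table):
        # windows touching the N (centres 2..6) are undefined
        prof = predict_shape("ACGTNACGTA", table, ambiguous="mask")
        assert np.isnan(prof.mgw[2:7]).all()
        assert not np.isnan(prof.mgw[7])

    @settings(max_examples=60, deadline=None)
    @given(seq=dna)
    def test_strand_invariance(self, seq):
        table = _MODULE_TABLE
        a = predict_shape(seq, table)
        b = predict_shape(reverse_complement(seq), table)
        for f in ("mgw", "prot", "roll", "helt"):
            assert np.array_equal(
                getattr(a, f)[::-1], getattr(b, f), equal_nan=True
            ), f

    def test_locality(self, table):
        """A point change only perturbs tracks within the pentamer reach."""
        rng = np.random.default_rng(3)
        seq = random_dna(rng, 30)
        base = predict_shape(seq, table)
        k = 14
        mutated = seq[:k] + ("A" if seq[k] != "A" else "C") + seq[k + 1 :]
        mut = predict_shape(mutated, table)
        bp_diff = np.nonzero(~np.isclose(base.mgw, mut.mgw, equal_nan=True))[0]
        step_diff = np.nonzero(~np.isclose(base.roll, mut.roll, equal_nan=True))[0]
        assert set(bp_diff) <= set(range(k - 2, k + 3))
        assert set(step_diff) <= set(range(k - 3, k + 3))

    def test_brute_force_1024_oracle(self, table):
        """Canonicalized engine equals lookup in an expanded 1024-row table."""
        expanded = {}
        for canon, rec in table.entries.items():
            expanded[canon] = (rec.mgw, rec.prot, rec.roll, rec.helt)
            rc = reverse_complement(canon)
            expanded[rc] = (
                rec.mgw,
                rec.prot,
                (rec.roll[1], rec.roll[0]),
                (rec.helt[1], rec.helt[0]),
            )
        assert len(expanded) == 1024

        def brute(seq):
            L = len(seq)
            mgw = np.full(L, np.nan)
            prot = np.full(L, np.nan)
            roll_sum = np.zeros(L - 1)
            roll_n = np.zeros(L - 1)
            helt_sum = np.zeros(L - 1)
            helt_n = np.zeros(L - 1)
            for i in range(2, L - 2):
                m, p, r, h = expanded[seq[i - 2 : i + 3]]
                mgw[i] = m
                prot[i] = p
                for step, rv, hv in ((i - 1, r[0], h[0]), (i, r[1], h[1])):
                    roll_sum[step] += rv
                    roll_n[step] += 1
                    helt_sum[step] += hv
                    helt_n[step] += 1
            with np.errstate(invalid="ignore"):
                roll = np.where(roll_n > 0, roll_sum / roll_n, np.nan)
                helt = np.where(helt_n > 0, helt_sum / helt_n, np.nan)
            return mgw, prot, roll, helt

        rng = np.random.default_rng(11)
        for _ in range(50):
            seq = random_dna(rng, int(rng.integers(5, 30)))
            prof = predict_shape(seq, table)
            m, p, r, h = brute(seq)
            assert np.array_equal(prof.mgw, m, equal_nan=True)
            assert np.array_equal(prof.prot, p, equal_nan=True)
            assert np.allclose(prof.roll, r, equal_nan=True)
            assert np.allclose(prof.helt, h, equal_nan=True)


class TestSymmetrize:
    def test_arithmetic(self, table):
        prof = predict_shape("AACACGTGTT", table)
        prof.mgw[:] = np.nan
        prof.mgw[2:5] = [4.0, 5.0, 6.0]
        out = symmetrize_profile(prof, 3)
        assert np.allclose(out.mgw[2:5], [5.0, 5.0, 5.0])

    def test_fixed_point_and_idempotence(self, table):
        rng = np.random.default_rng(5)
        seq = random_dna(rng, 12)
        prof = predict_shape(seq, table)
        once = symmetrize_profile(prof, 5.5)
        twice = symmetrize_profile(once, 5.5)
        assert once == twice

    def test_palindrome_already_symmetric(self, table):
        # E-box with reverse-complement-symmetric flanks: strand invariance
        # forces a mirror-symmetric profile, so symmetrization is a no-op
        seq = "AACACGTGTT"
        assert reverse_complement(seq) == seq
        prof = predict_shape(seq, table)
        assert prof == symmetrize_profile(prof, 4.5)

    def test_centre_outside_profile(self, table):
        prof = predict_shape("ACGTACGT", table)
        with pytest.raises(ValueError, match="outside"):
            symmetrize_profile(prof, 12)


# module-level table for the hypothesis property (session fixtures cannot be
# combined with @given)
_MODULE_TABLE = make_pentamer_table(SimulationConfig(seed=2024))
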