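"""Tandem-repeat unit discovery and decomposition."""

from functools import lru_cache

import numpy as np
import pytest

from mitotx.repeats import (
    RepeatUnitType,
    compare_decompositions,
    decompose,
    find_repeat_units,
)
from mitotx.synthetic import (
    LNCRNA_5243673_ARCHITECTURE,
    RepeatArchitecture,
    build_repeat_sequence,
    make_repeat_units,
)


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(7)
    units = make_repeat_units(rng, {"I": 19, "II": 18, "III": 37})
    cr_seq, cr_truth = build_repeat_sequence(units, RepeatArchitecture())
    return units, cr_seq, cr_truth


def by_length(found):
    return {u.length: u for u in found}


class TestUnitDiscovery:
    def test_minimal_exact_tandem(self):
        units = find_repeat_units("ACGTACGTACGT", min_unit=4)
        assert len(units) == 1 and units[0].consensus == "ACGT"

    def test_planted_unit_lengths_recovered(self, planted):
        units, cr_seq, _ = planted
        found = by_length(find_repeat_units(cr_seq))
        assert set(found) >= {19, 18, 37}
        for length, key in ((19, "I"), (18, "II"), (37, "III")):
            assert found[length].consensus == units[key], length

    def test_random_sequence_has_no_units(self):
        # oracle: exhaustive exact-periodicity scan finds no tandem of any
        # period in this sequence, and neither does the detector
        rng = np.random.default_rng(12)
        seq = "".join(rng.choice(list("ACGT"), size=200))

        def exact_tandem_exists(s, lo, hi):
            for p in range(lo, hi + 1):
                for i in range(len(s) - 2 * p + 1):
                    if s[i: i + p] == s[i + p: i + 2 * p]:
                        return True
            return False

        assert not exact_tandem_exists(seq, 10, 50)
        assert find_repeat_units(seq, max_edits=0) == []


class TestDecomposition:
    def test_exact_toy_tiling(self):
        unit = RepeatUnitType("I", "ACG")
        dec = decompose("ACGACGACG", [unit], max_edits=0)
        assert len(dec.blocks) == 3
        assert dec.partial_tail is None
        assert dec.left_flank == dec.right_flank == ""
        assert dec.reconstruct() == "ACGACGACG"

    def test_genomic_cr_architecture(self, planted):
        units, cr_seq, _ = planted
        found = find_repeat_units(cr_seq)
        dec = decompose(cr_seq, found, max_edits=0)
        counts = {}
        lengths = {u.id: u.length for u in found}
        for b in dec.blocks:
            counts[lengths[b.unit_id]] = counts.get(lengths[b.unit_id], 0) + 1
        assert counts == {19: 15, 18: 10, 37: 7}
        assert dec.partial_tail is not None
        assert lengths[dec.partial_tail[0]] == 37
        assert dec.partial_tail[1] == 35
        assert dec.reconstruct() == cr_seq

    def test_lncrna_architecture_with_polymorphic_copies(self, planted):
        units, cr_seq, _ = planted
        found = find_repeat_units(cr_seq)
        rng = np.random.default_rng(3)
        seq, _ = build_repeat_sequence(units, LNCRNA_5243673_ARCHITECTURE,
                                       rng=rng, apply_polymorphism=True)
        dec = decompose(seq, found, max_edits=3)
        lengths = {u.id: u.length for u in found}
        counts = {}
        for b in dec.blocks:
            counts[lengths[b.unit_id]] = counts.get(lengths[b.unit_id], 0) + 1
        assert counts == {19: 17, 18: 3, 37: 2}
        assert lengths[dec.partial_tail[0]] == 37
        assert dec.partial_tail[1] == 33
        assert dec.reconstruct() == seq

    @pytest.mark.parametrize("n", [2, 3, 10, 25, 50])
    def test_pure_tandem_yields_n_blocks_no_flanks(self, n):
        rng = np.random.default_rng(n)
        unit = "".join(rng.choice(list("ACGT"), size=17))
        dec = decompose(unit * n, [RepeatUnitType("I", unit)], max_edits=0)
        assert len(dec.blocks) == n
        assert dec.left_flank == dec.right_flank == ""
        assert dec.partial_tail is None

    def test_reconstruction_identity_with_noisy_copies(self):
        rng = np.random.default_rng(9)
        unit = "".join(rng.choice(list("ACGT"), size=20))
        copies = []
        for _ in range(8):
            c = list(unit)
            pos = int(rng.integers(0, 20))
            c[pos] = "ACGT"[(("ACGT".index(c[pos])) + 1) % 4]
            copies.append("".join(c))
        seq = "TTT" + "".join(copies) + "GG"
        dec = decompose(seq, [RepeatUnitType("I", unit)], max_edits=2)
        assert dec.reconstruct() == seq
        assert len(dec.blocks) == 8
        assert all(b.copy_seq in seq for b in dec.blocks)

    def test_planted_polymorphic_site_recovered(self):
        rng = np.random.default_rng(21)
        unit = "".join(rng.choice(list("ACGT"), size=19))
        offset = 7
        alt = "T" if unit[offset] != "T" else "G"
        copies = [unit] * 6
        for i in (1, 4):
            copies[i] = unit[:offset] + alt + unit[offset + 1:]
        dec = decompose("".join(copies), [RepeatUnitType("I", unit)],
                        max_edits=2)
        sites = [(u, off) for u, off, alleles in dec.polymorphic_sites]
        assert ("I", offset) in sites
        alleles = dict(
            ((u, off), a) for u, off, a in dec.polymorphic_sites
        )[("I", offset)]
        assert set(alleles) == {unit[offset], alt}

    def test_length_variant_allele_absorbed(self):
        # a G -> TTA allele (3 edits) stays a single copy of its unit
        rng = np.random.default_rng(22)
        unit = "".join(rng.choice(list("ACGT"), size=19))
        variant = unit[:11] + "TTA" + unit[12:]
        seq = unit + variant + unit
        dec = decompose(seq, [RepeatUnitType("I", unit)], max_edits=3)
        assert len(dec.blocks) == 3
        assert dec.blocks[1].copy_seq == variant
        assert dec.reconstruct() == seq

    def test_low_coverage_flagged(self):
        dec = decompose("T" * 200 + "ACGTACGTACG" * 2,
                        [RepeatUnitType("I", "ACGTACGTACG")], max_edits=0)
        assert dec.low_coverage


@pytest.fixture(scope="module")
def units():
    rng = np.random.default_rng(5)
    return make_repeat_units(rng, {"I": 19, "II": 18, "III": 37})


class TestHeterogeneity:
    def build(self, blocks, units):
        arch = RepeatArchitecture(blocks=blocks, partial=None,
                                  polymorphic_sites=())
        seq, _ = build_repeat_sequence(units, arch)
        found = [RepeatUnitType(k, v) for k, v in units.items()]
        return decompose(seq, found, max_edits=0)

    def test_copy_number_range(self, units):
        d1 = self.build([("I", 17), ("II", 3)], units)
        d2 = self.build([("I", 15), ("II", 3)], units)
        stats, orders, dist = compare_decompositions([d1, d2])
        assert (stats["I"]["min"], stats["I"]["max"]) == (15, 17)

    def test_identical_patterns_distance_zero(self, units):
        d1 = self.build([("I", 5), ("II", 2)], units)
        d2 = self.build([("I", 5), ("II", 2)], units)
        _, _, dist = compare_decompositions([d1, d2])
        assert dist[0, 1] == 0

    def test_pattern_distance_matches_bruteforce(self, units):
        rng = np.random.default_rng(8)
        decomps = []
        for _ in range(5):
            blocks = [(rng.choice(["I", "II", "III"]), int(rng.integers(1, 4)))
                      for _ in range(4)]
            decomps.append(self.build([(str(u), c) for u, c in blocks], units))
        _, _, dist = compare_decompositions(decomps)

        @lru_cache(maxsize=None)
        def lev(a, b):
            if not a:
                return len(b)
            if not b:
                return len(a)
            return min(
                lev(a[1:], b) + 1,
                lev(a, b[1:]) + 1,
                lev(a[1:], b[1:]) + (a[0] != b[0]),
            )

        tokens = [tuple(b.unit_id for b in d.blocks) for d in decomps]
        for i in range(5):
            for j in range(i + 1, 5):
                assert dist[i, j] == lev(tokens[i], tokens[j])

    def test_disjoint_unit_sets_rejected(self, units):
        d1 = self.build([("I", 5)], units)
        d2 = self.build([("II", 5)], units)
        with pytest.raises(ValueError, match="share no"):
            compare_decompositions([d1, d2])
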