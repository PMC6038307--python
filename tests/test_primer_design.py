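"""Primer design: tails, melting temperature, scheme structure, exclusions."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fivec.genome_model import digest, reverse_complement
from fivec.primer_design import (
    A_KEY_TAIL,
    P1_KEY_TAIL,
    DesignConfig,
    FiveCPrimer,
    add_tails,
    design_primers,
    dinucleotide_entropy,
    melting_temperature,
)

# --------------------------------------------------------------------------
# Independent Tm oracle: Allawi & SantaLucia (1997) unified nearest-neighbor
# parameters with the SantaLucia (1998) entropy-based monovalent salt
# correction at 50 mM Na+ and 25 nM of each strand.
_NN = {
    "AA": (-7.9, -22.2), "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "GT": (-8.4, -22.4), "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
_INIT = {"A": (2.3, 4.1), "T": (2.3, 4.1), "G": (0.1, -2.8), "C": (0.1, -2.8)}


def tm_oracle(seq: str) -> float:
    dh = ds = 0.0
    for end in (seq[0], seq[-1]):
        h, s = _INIT[end]
        dh, ds = dh + h, ds + s
    for i in range(len(seq) - 1):
        pair = seq[i : i + 2]
        h, s = _NN[pair] if pair in _NN else _NN[reverse_complement(pair)]
        dh, ds = dh + h, ds + s
    ds += 0.368 * (len(seq) - 1) * math.log(0.05)
    k = (25 - 25 / 2) * 1e-9
    return 1000 * dh / (ds + 1.987 * math.log(k)) - 273.15


class TestMeltingTemperature:
    @given(seq=st.text(alphabet="ACGT", min_size=15, max_size=35))
    @settings(max_examples=100, deadline=None)
    def test_matches_independent_nn_table(self, seq):
        assert melting_temperature(seq) == pytest.approx(tm_oracle(seq), abs=0.1)

    @given(seq=st.text(alphabet="ACGT", min_size=8, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_duplex_symmetry(self, seq):
        assert melting_temperature(seq) == pytest.approx(
            melting_temperature(reverse_complement(seq)), abs=1e-9
        )

    def test_gc_ordering(self):
        assert melting_temperature("AT" * 15) < melting_temperature("GC" * 15)

    def test_gc_count_rank_correlates_with_tm(self):
        # composition is not the whole story in a stacking model, but over
        # random 30-mers GC content must dominate the ranking
        rng = random.Random(0)
        seqs = ["".join(rng.choice("ACGT") for _ in range(30)) for _ in range(200)]
        gc = np.array([s.count("G") + s.count("C") for s in seqs])
        tm = np.array([melting_temperature(s) for s in seqs])
        from scipy.stats import spearmanr

        rho = spearmanr(gc, tm).statistic
        assert rho > 0.9

    @pytest.mark.parametrize("bad", ["ACGTACG", "ACGTNACGTACG", "ACGRACGTACGT"])
    def test_rejects_short_or_ambiguous(self, bad):
        with pytest.raises(ValueError):
            melting_temperature(bad)


class TestTails:
    def test_tail_constants_are_verbatim(self):
        assert A_KEY_TAIL == "CCATCTCATCCCTGCGTGTCTCCGACTCAG"
        assert P1_KEY_TAIL == "ATCACCGACTGCCCATAGAGAGG"
        assert len(A_KEY_TAIL) == 30 and len(P1_KEY_TAIL) == 23

    def _primer(self, orientation, seq):
        return FiveCPrimer("p", 0, orientation, seq, 60.0, "")

    def test_forward_oligo_starts_with_a_key(self):
        oligo = add_tails(self._primer("forward", "ACGTACGTACGT"))
        assert oligo == A_KEY_TAIL + "ACGTACGTACGT"

    def test_reverse_oligo_ends_with_p1_key(self):
        oligo = add_tails(self._primer("reverse", "ACGTACGTACGT"))
        assert oligo == "ACGTACGTACGT" + P1_KEY_TAIL

    def test_empty_payload_gives_bare_tail(self):
        assert add_tails(self._primer("forward", "")) == A_KEY_TAIL
        assert add_tails(self._primer("reverse", "")) == P1_KEY_TAIL

    def test_unset_orientation_raises(self):
        with pytest.raises(ValueError):
            add_tails(self._primer("", "ACGT"))


def _toy_locus(n_fragments=10, frag_len=600, seed=0):
    """Random fragments separated by planted cut sites, no spurious sites."""
    rng = random.Random(seed)
    chunks = []
    for _ in range(n_fragments):
        while True:
            piece = "".join(rng.choice("ACGT") for _ in range(frag_len - 6))
            if "GAATTC" not in piece and "GAATT" not in piece[:5]:
                break
        chunks.append(piece)
    seq = chunks[0] + "".join("GAATTC" + c for c in chunks[1:])
    while "GAATTC" in seq:
        frags = digest(seq)
        if len(frags) == n_fragments:
            break
        seq = seq.replace("GAATTC", "GACTTC", 1)  # should not happen with clean chunks
    return seq, digest(seq)


class TestDesignPrimers:
    config = DesignConfig()

    def test_oversized_fragment_excluded_as_too_long(self):
        rng = random.Random(1)
        seq = "".join(rng.choice("ACGT") for _ in range(25_000)).replace("GAATTC", "GACTTC")
        frags = digest(seq)
        assert len(frags) == 1 and frags[0].length > 20_000
        design = design_primers(frags, seq, self.config, scheme="alternating")
        assert design.primers == ()
        assert design.exclusions == ((0, "too_long"),)

    def test_anchored_scheme_orientation_counts(self):
        seq, frags = _toy_locus(10)
        design = design_primers(frags, seq, self.config, scheme="anchored", anchors=[3, 4])
        assert len(design.reverse_primers) == 2
        assert len(design.forward_primers) == 8
        assert {p.fragment_index for p in design.reverse_primers} == {3, 4}

    def test_homopolymer_fragment_excluded_as_low_complexity(self):
        seq, frags = _toy_locus(3, seed=2)
        # replace the middle fragment's interior with a homopolymer
        # keep the flanking AATTC / G of the planted cut sites intact
        f = frags[1]
        lo, hi = f.interval.start - 1, f.interval.end
        seq2 = seq[: lo + 5] + "A" * (hi - lo - 6) + seq[hi - 1 :]
        frags2 = digest(seq2)
        assert len(frags2) == 3
        design = design_primers(frags2, seq2, self.config, scheme="alternating")
        assert (1, "low_complexity") in design.exclusions

    def test_duplicated_primer_region_excluded_as_multi_target(self):
        seq, frags = _toy_locus(4, seed=3)
        # fragment 1 is a reverse primer in the alternating scheme, so its
        # candidate region is the fragment prefix; duplicate it elsewhere
        f1 = frags[1]
        probe = seq[f1.interval.start - 1 : f1.interval.start - 1 + 40]
        f3 = frags[3]
        mid = (f3.interval.start + f3.interval.end) // 2
        seq2 = seq[: mid - 20] + probe + seq[mid + 20 :]
        frags2 = digest(seq2)
        assert len(frags2) == 4
        design = design_primers(frags2, seq2, self.config, scheme="alternating")
        assert any(reason == "multi_target" for _, reason in design.exclusions)

    def test_at_most_one_primer_per_fragment_and_full_coverage(self, study):
        seen = [p.fragment_index for p in study.design.primers]
        assert len(seen) == len(set(seen))
        covered = set(seen) | {idx for idx, _ in study.design.exclusions}
        assert covered == {f.index for f in study.fragments}

    def test_primer_ends_abut_restriction_site(self):
        seq, frags = _toy_locus(6, seed=4)
        design = design_primers(frags, seq, self.config, scheme="anchored", anchors=[2])
        by_index = {f.index: f for f in frags}
        for p in design.primers:
            f = by_index[p.fragment_index]
            frag_seq = seq[f.interval.start - 1 : f.interval.end]
            if p.orientation == "forward":
                assert frag_seq.endswith(p.genomic_seq)
            else:
                assert frag_seq.startswith(p.genomic_seq)
            assert abs(len(p.genomic_seq) - self.config.optimal_length) <= 5

    def test_alternating_orientations_alternate(self):
        seq, frags = _toy_locus(8, seed=5)
        design = design_primers(frags, seq, self.config, scheme="alternating")
        orientations = [p.orientation for p in sorted(design.primers, key=lambda p: p.fragment_index)]
        assert all(a != b for a, b in zip(orientations, orientations[1:]))
        flipped = design_primers(
            frags, seq, self.config, scheme="alternating", alternating_start="reverse"
        )
        assert flipped.primers[0].orientation == "reverse"

    def test_anchor_errors(self):
        seq, frags = _toy_locus(5, seed=6)
        with pytest.raises(IndexError):
            design_primers(frags, seq, self.config, scheme="anchored", anchors=[99])
        with pytest.raises(ValueError):
            design_primers(frags, seq, self.config, scheme="anchored", anchors=[])

    def test_excluded_anchor_raises(self):
        rng = random.Random(7)
        left = "".join(rng.choice("ACGT") for _ in range(600)).replace("GAATTC", "GACTTC")
        seq = left + "GAATTC" + "A" * 600  # anchor fragment is a homopolymer
        frags = digest(seq)
        with pytest.raises(ValueError, match="anchor fragment 1 excluded"):
            design_primers(frags, seq, self.config, scheme="anchored", anchors=[1])

    def test_dinucleotide_entropy_degenerate_cases(self):
        assert dinucleotide_entropy("A" * 30) == 0.0
        assert dinucleotide_entropy("AT" * 15) == pytest.approx(1.0, abs=0.05)
        rng = random.Random(8)
        rand = "".join(rng.choice("ACGT") for _ in range(30))
        assert dinucleotide_entropy(rand) > 2.0
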