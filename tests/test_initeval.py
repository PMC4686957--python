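import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motifpoim.datasets import LabeledSequenceSet
from motifpoim.initeval import (
    MotifRegion,
    clamp_nonpolymorphic,
    consensus,
    estimate_regions,
    greedy_pwm_init,
    mrq,
    one_hot_pwm,
    read_pfm,
    write_meme,
    write_pfm,
)
from motifpoim.motifmodel import Ppm
from motifpoim.poim import DifferentialPoim, Poim


def block_diff_poim(L=30, k_max=6, start=11, k=6, value=1.0, noise=0.0, seed=0):
    """Differential POIM of a single planted motif of extent [start, start+k-1]."""
    rng = np.random.default_rng(seed)
    omega = noise * np.abs(rng.normal(size=(k_max, L)))
    for l in range(2, k_max + 1):
        omega[l - 1, L - l + 1 :] = 0.0
        width = k - l + 1
        if width >= 1:
            omega[l - 1, start - 1 : start - 1 + width] = value * l
    omega[0] = 0.0
    return DifferentialPoim(values=omega, L=L)


class TestEstimateRegions:
    def test_single_block_recovers_planted_extent(self):
        regions = estimate_regions(block_diff_poim(noise=0.02))
        assert len(regions) == 1
        assert (regions[0].start, regions[0].length) == (11, 6)

    def test_all_zero_omega_yields_no_regions(self):
        diff = DifferentialPoim(values=np.zeros((5, 20)), L=20)
        assert estimate_regions(diff) == []

    def test_overlapping_motifs_split_at_top_row_drop(self):
        # two overlapping motifs: [5,15] (k=11) and [10,24] (k=15); the l=7
        # row has runs 5..9 and 11..18 with a drop at 10
        L, k_max = 30, 7
        omega = np.zeros((k_max, L))
        for l in range(2, k_max + 1):
            for s, k in ((5, 11), (10, 15)):
                omega[l - 1, s - 1 : s + k - l] += 1.0 * l
        omega[6, 9] = 0.0  # the drop cell at position 10, row l=7
        diff = DifferentialPoim(values=omega, L=L)
        regions = estimate_regions(diff)
        assert [(r.start, r.length) for r in regions] == [(5, 11), (10, 15)]

    def test_stronger_region_carries_larger_score(self):
        L = 40
        omega = np.zeros((5, L))
        for l in range(2, 5 + 1):
            omega[l - 1, 4:8] = 3.0
            omega[l - 1, 24:28] = 1.5
        diff = DifferentialPoim(values=omega, L=L)
        regions = estimate_regions(diff)
        assert len(regions) == 2
        assert regions[0].score > regions[1].score


class TestGreedyInit:
    def make_q1(self, motif="CCTATA", start=11, L=30):
        vals = np.zeros((4, L))
        truth = one_hot_pwm(motif)
        vals[:, start - 1 : start - 1 + len(motif)] = truth
        return Poim(order=1, values=vals, L=L)

    def test_columns_follow_leading_nucleotide(self):
        Q1 = self.make_q1()
        ppm = greedy_pwm_init(Q1, MotifRegion(start=11, length=6, score=0.0))
        assert consensus(ppm) == "CCTATA"
        assert np.allclose(ppm.r.sum(axis=0), 1.0)
        assert np.all(np.isin(np.round(ppm.r, 6), (0.1, 0.7)))
        assert ppm.mu == 11.0 and ppm.sigma == 1.0 and ppm.lam == 1.0

    def test_tie_breaks_alphabetically(self):
        Q1 = Poim(order=1, values=np.zeros((4, 10)), L=10)
        ppm = greedy_pwm_init(Q1, MotifRegion(start=2, length=3, score=0.0))
        assert consensus(ppm) == "AAA"

    def test_out_of_range_region_rejected(self):
        Q1 = self.make_q1()
        with pytest.raises(ValueError):
            greedy_pwm_init(Q1, MotifRegion(start=28, length=6, score=0.0))


class TestClampNonpolymorphic:
    def test_invariant_position_becomes_one_hot(self):
        seqs = ["AGGT", "CGAT", "TGCT"]  # position 2 always G
        data = LabeledSequenceSet(seqs, np.array([1, -1, 1]))
        ppm = Ppm(r=np.full((4, 3), 0.25), mu=1.0, sigma=1.0)
        out = clamp_nonpolymorphic(ppm, data)
        assert np.argmax(out.r[:, 1]) == 2  # G
        assert out.r[2, 1] == pytest.approx(1.0 - 3e-3)
        assert np.allclose(out.r[:, 0], 0.25)

    def test_polymorphic_data_unchanged(self):
        seqs = ["ACGT", "TGCA", "CATG"]
        data = LabeledSequenceSet(seqs, np.array([1, -1, 1]))
        ppm = Ppm(r=np.full((4, 4), 0.25), mu=1.0, sigma=1.0)
        out = clamp_nonpolymorphic(ppm, data)
        assert np.allclose(out.r, ppm.r)

    def test_empty_dataset_warns_and_passes_through(self):
        data = LabeledSequenceSet([], np.array([]))
        ppm = Ppm(r=np.full((4, 2), 0.25), mu=1.0, sigma=1.0)
        with pytest.warns(UserWarning):
            out = clamp_nonpolymorphic(ppm, data)
        assert np.allclose(out.r, ppm.r)


class TestMrq:
    def test_identical_pwms_score_one(self):
        t = one_hot_pwm("CCTATA")
        assert mrq(t, t).value == pytest.approx(1.0)
        assert mrq(t, t, sqrt=True).value == pytest.approx(1.0)

    def test_all_columns_different_one_hot(self):
        t = one_hot_pwm("AAAA")
        c = one_hot_pwm("CCCC")
        assert mrq(t, c).value == pytest.approx(0.0)  # squared-distance form
        assert mrq(t, c, sqrt=True).value == pytest.approx(1 - np.sqrt(2) / 2)

    def test_single_flipped_column_euclidean_variant(self):
        t = one_hot_pwm("CCTATA")
        c = one_hot_pwm("CCTGTA")
        expected = 5 / 6 + (1 / 6) * (1 - np.sqrt(2) / 2)
        assert mrq(t, c, sqrt=True).value == pytest.approx(expected)
        assert mrq(t, c).value == pytest.approx(5 / 6)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_symmetry_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(1, 8))
        a = rng.dirichlet(np.ones(4), size=k).T
        b = rng.dirichlet(np.ones(4), size=k).T
        ab, ba = mrq(a, b).value, mrq(b, a).value
        assert ab == pytest.approx(ba)
        assert 0.0 - 1e-12 <= ab <= 1.0 + 1e-12
        e = mrq(a, b, sqrt=True).value
        assert 1 - np.sqrt(2) / 2 - 1e-12 <= e <= 1.0 + 1e-12

    def test_unequal_lengths_use_best_offset(self):
        t = one_hot_pwm("ACGTAC")
        c = one_hot_pwm("GTA")  # matches at offset 2
        rep = mrq(t, c)
        assert rep.offset == 2
        assert rep.value == pytest.approx(3 / 6)  # overhangs score zero

    def test_scale100_presentation(self):
        t = one_hot_pwm("ACG")
        assert mrq(t, t, scale100=True).value == pytest.approx(100.0)

    def test_non_simplex_input_rejected(self):
        t = one_hot_pwm("ACG")
        with pytest.raises(ValueError):
            mrq(t, np.full((4, 3), 0.3))


class TestConsensusAndIo:
    def test_consensus_examples(self):
        assert consensus(one_hot_pwm("CCTATA")) == "CCTATA"
        assert consensus(np.full((4, 3), 0.25)) == "AAA"
        r = np.full((4, 6), 0.1)
        r[[1, 1, 3, 0, 3, 0], np.arange(6)] = 0.7
        assert consensus(r) == "CCTATA"

    def test_pfm_roundtrip(self, tmp_path):
        rng = np.random.default_rng(3)
        r = rng.dirichlet(np.ones(4), size=5).T
        path = str(tmp_path / "m.pfm")
        write_pfm(r, path, "m1")
        back = read_pfm(path)
        assert np.allclose(back, r, atol=1e-6)

    def test_meme_output_is_parseable_matrix(self, tmp_path):
        r = one_hot_pwm("ACGT")
        path = str(tmp_path / "m.meme")
        write_meme(r, path)
        text = open(path).read()
        assert "letter-probability matrix" in text and "w= 4" in text
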