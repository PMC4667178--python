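"""Genotype I/O, frequency estimation, HWE exact test and marker QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import comb

from autozyg.genotypes import (
    GenotypeMatrix,
    QCConfig,
    apply_qc,
    estimate_frequencies,
    hwe_exact_test,
    interpolate_cM,
    read_genotypes,
    write_vcf,
)


def make_matrix(calls, pops=None, chrom=None):
    calls = np.asarray(calls, dtype=np.int8)
    n_ind, n_mark = calls.shape
    markers = pd.DataFrame(
        {
            "chrom": chrom or ["1"] * n_mark,
            "pos_bp": np.arange(1, n_mark + 1) * 1000,
            "pos_cM": np.arange(n_mark, dtype=float),
            "ref": ["A"] * n_mark,
            "alt": ["G"] * n_mark,
        }
    )
    individuals = pd.DataFrame(
        {
            "id": [f"I{i}" for i in range(n_ind)],
            "population": pops or ["P1"] * n_ind,
        }
    )
    return GenotypeMatrix(markers=markers, individuals=individuals, calls=calls)


class TestReadGenotypes:
    def test_structural_filters_and_cells(self, toy_vcf, toy_pops):
        g = read_genotypes(toy_vcf, toy_pops)
        # triallelic 1:250 and chrX:500 dropped; 5 sites remain, sorted
        assert g.n_markers == 5
        assert list(g.markers["pos_bp"]) == [50, 100, 400, 150, 900]
        assert list(g.markers["chrom"]) == ["1", "1", "1", "2", "2"]
        # hand-read dosages per individual (I1, I2, I3)
        expected = np.array(
            [
                [1, 0, -1, 1, 2],
                [0, 1, 0, 1, 2],
                [0, 2, 2, 0, 2],
            ],
            dtype=np.int8,
        )
        np.testing.assert_array_equal(g.calls, expected)

    def test_unlabelled_individual_is_an_error(self, toy_vcf):
        with pytest.raises(ValueError, match="I3"):
            read_genotypes(toy_vcf, {"I1": "P1", "I2": "P1"})

    def test_vcf_round_trip(self, toy_vcf, toy_pops, tmp_path):
        g = read_genotypes(toy_vcf, toy_pops)
        out = tmp_path / "rt.vcf"
        write_vcf(g, out)
        g2 = read_genotypes(out, toy_pops)
        np.testing.assert_array_equal(g.calls, g2.calls)
        assert list(g.markers["pos_bp"]) == list(g2.markers["pos_bp"])


class TestFrequencies:
    def test_simple_counts(self):
        g = make_matrix([[0], [1], [2]])
        assert estimate_frequencies(g).freqs[0] == pytest.approx(0.5)

    def test_monomorphic_site(self):
        g = make_matrix([[0], [0], [0]])
        assert estimate_frequencies(g).freqs[0] == 0.0

    def test_hand_tally_with_missing(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 3, size=(10, 6)).astype(np.int8)
        calls[2, 1] = -1
        calls[7, 1] = -1
        g = make_matrix(calls)
        freqs = estimate_frequencies(g).freqs
        for j in range(6):
            col = calls[:, j]
            obs = col[col >= 0]
            assert freqs[j] == pytest.approx(obs.sum() / (2 * len(obs)))

    def test_population_scope_and_exclusions(self):
        g = make_matrix([[0], [2], [2]], pops=["P1", "P1", "P2"])
        assert estimate_frequencies(g, scope="P1").freqs[0] == pytest.approx(0.5)
        assert (
            estimate_frequencies(g, scope="P1", exclude=["I0"]).freqs[0] == 1.0
        )

    def test_all_missing_marker_is_an_error(self):
        g = make_matrix([[-1], [-1]])
        with pytest.raises(ValueError, match="all-missing"):
            estimate_frequencies(g)


def hwe_oracle(n_aa, n_ab, n_bb):
    """Independent enumeration of the exact conditional HWE test."""
    n = n_aa + n_ab + n_bb
    nb = n_ab + 2 * n_bb
    nb = min(nb, 2 * n - nb)
    probs = {}
    for het in range(nb % 2, nb + 1, 2):
        hom_rare = (nb - het) // 2
        hom_com = n - het - hom_rare
        # multinomial coefficient x 2^het (unnormalised conditional mass)
        probs[het] = (
            comb(n, het, exact=True)
            * comb(n - het, hom_rare, exact=True)
            * 2**het
        )
    total = sum(probs.values())
    p_obs = probs[n_ab]
    return sum(v for v in probs.values() if v <= p_obs) / total


class TestHWEExactTest:
    def test_perfect_proportions(self):
        assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0)

    @pytest.mark.parametrize("counts", [(50, 0, 50), (0, 100, 0)])
    def test_extreme_departures_are_tiny(self, counts):
        assert hwe_exact_test(*counts) < 1e-5

    def test_negative_count_is_an_error(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)

    def test_matches_enumeration_exhaustively_small(self):
        for n_aa in range(0, 7):
            for n_ab in range(0, 7):
                for n_bb in range(0, 7):
                    if n_aa + n_ab + n_bb == 0:
                        continue
                    assert hwe_exact_test(n_aa, n_ab, n_bb) == pytest.approx(
                        hwe_oracle(n_aa, n_ab, n_bb), rel=1e-9
                    )

    @settings(max_examples=60, deadline=None)
    @given(
        st.integers(0, 30),
        st.integers(0, 30),
        st.integers(0, 30),
    )
    def test_matches_enumeration_up_to_30(self, n_aa, n_ab, n_bb):
        if n_aa + n_ab + n_bb == 0 or n_aa + n_ab + n_bb > 30:
            return
        assert hwe_exact_test(n_aa, n_ab, n_bb) == pytest.approx(
            hwe_oracle(n_aa, n_ab, n_bb), rel=1e-9
        )


class TestApplyQC:
    def _two_pop_matrix(self, rng, n_markers=20, maf_bad=(), hwe_bad=()):
        """60 individuals in 2 populations; selected markers violate one
        rule in one population."""
        n = 60
        calls = np.empty((n, n_markers), dtype=np.int8)
        for j in range(n_markers):
            p = 0.4
            calls[:, j] = rng.binomial(1, p, n) + rng.binomial(1, p, n)
            if j in maf_bad:  # nearly monomorphic in population 2
                calls[30:, j] = 0
                calls[58:, j] = 1  # MAF 2/60 < 0.05 in P2
            if j in hwe_bad:  # all heterozygous in population 1
                calls[:30, j] = 1
        pops = ["P1"] * 30 + ["P2"] * 30
        return make_matrix(calls, pops=pops)

    def test_planted_violations(self):
        rng = np.random.default_rng(5)
        g = self._two_pop_matrix(rng, maf_bad={1, 5, 9, 13}, hwe_bad={2, 7, 18})
        kept, log = apply_qc(g, QCConfig())
        assert kept.n_markers == 13
        flagged = set(log["marker_index"])
        assert flagged == {1, 5, 9, 13, 2, 7, 18}
        assert set(log[log["rule"] == "maf"]["marker_index"]) == {1, 5, 9, 13}
        assert set(log[log["rule"] == "hwe"]["marker_index"]) == {2, 7, 18}

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        g = self._two_pop_matrix(rng, maf_bad={0}, hwe_bad={3})
        once, _ = apply_qc(g)
        twice, log2 = apply_qc(once)
        assert twice.n_markers == once.n_markers
        assert len(log2) == 0

    def test_retained_frequencies_within_bounds(self):
        rng = np.random.default_rng(7)
        g = self._two_pop_matrix(rng, maf_bad={2, 4})
        cfg = QCConfig(maf_min=0.05)
        kept, _ = apply_qc(g, cfg)
        for pop in ("P1", "P2"):
            f = estimate_frequencies(kept, scope=pop).freqs
            assert np.all(f >= cfg.maf_min) and np.all(f <= 1 - cfg.maf_min)


class TestInterpolateCM:
    def test_midpoint_and_anchor(self):
        cm = interpolate_cM([5e5, 1e6], [0, 1e6], [0.0, 1.0])
        assert cm[0] == pytest.approx(0.5)
        assert cm[1] == pytest.approx(1.0)

    def test_hand_computed_five_markers(self):
        anchors_bp = np.array([1e6, 2e6, 4e6])
        anchors_cm = np.array([1.0, 3.0, 4.0])
        got = interpolate_cM([5e5, 1.5e6, 2e6, 3e6, 5e6], anchors_bp, anchors_cm)
        # terminal-rate extrapolation: 2 cM/Mb below, 0.5 cM/Mb above
        np.testing.assert_allclose(got, [0.0, 2.0, 3.0, 3.5, 4.5])

    def test_extrapolation_floored_non_negative_and_monotone(self):
        got = interpolate_cM([1e5, 9e5, 1.1e6], [1e6, 2e6], [0.5, 1.5])
        assert got[0] == 0.0  # would be negative, floored
        assert np.all(np.diff(got) >= 0)

    def test_missing_chromosome_is_an_error(self, small_genome):
        gmap, _ = small_genome
        with pytest.raises(ValueError, match="absent"):
            gmap.interpolate("99", np.array([1000]))
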