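"""Positional Gaussian components, transcript mixtures and the locus
superposition."""

import numpy as np
import pytest
from scipy.stats import norm

from mixsquare import (
    FragmentLengthModel,
    FragmentObservation,
    Mix2Parameters,
    build_position_components,
    fragment_probability,
    locus_probability,
    start_probability,
)


class TestPositionComponents:
    def test_equidistant_placement_2000_4(self):
        pm = build_position_components(2000, 4)
        assert pm.means == pytest.approx([250, 750, 1250, 1750])
        assert pm.sd == pytest.approx(250.0)

    def test_single_component_centers_at_half_length(self):
        pm = build_position_components(2000, 1)
        assert pm.means == pytest.approx([1000.0])
        assert pm.sd == pytest.approx(1000.0)

    def test_tables_match_renormalized_gaussian_density(self):
        pm = build_position_components(300, 3)
        s = np.arange(1, 301)
        for j in range(3):
            dens = norm.pdf(s, loc=pm.means[j], scale=pm.sd)
            np.testing.assert_allclose(pm.tables[j], dens / dens.sum(), rtol=1e-12)

    @pytest.mark.parametrize("length", [50, 300, 2000, 20000])
    @pytest.mark.parametrize("M", range(1, 11))
    def test_each_component_sums_to_one(self, length, M):
        pm = build_position_components(length, M)
        np.testing.assert_allclose(pm.tables.sum(axis=1), 1.0, atol=1e-9)

    @pytest.mark.parametrize("length,M", [(100, 2), (2000, 4), (999, 5)])
    def test_mirror_symmetry_of_placement(self, length, M):
        # means of components j and M+1-j sum to l, so the (unnormalized)
        # densities mirror exactly under s <-> l-s; on the integer grid
        # 1..l the normalized tables mirror to within a half-position shift
        pm = build_position_components(length, M)
        assert pm.means[::-1] + pm.means == pytest.approx(
            np.full(M, float(length))
        )
        for j in range(M):
            g_j = norm.pdf(np.arange(1, length), loc=pm.means[j], scale=pm.sd)
            g_mirror = norm.pdf(
                length - np.arange(1, length), loc=pm.means[M - 1 - j], scale=pm.sd
            )
            np.testing.assert_allclose(g_j, g_mirror, rtol=1e-10)
            l1 = np.abs(pm.tables[j] - pm.tables[M - 1 - j][::-1]).sum()
            assert l1 < 0.05

    @pytest.mark.parametrize("length,M", [(0, 3), (-5, 2), (100, 0)])
    def test_invalid_arguments_rejected(self, length, M):
        with pytest.raises(ValueError):
            build_position_components(length, M)


class TestStartProbability:
    def test_degenerate_mixture_returns_first_component(self):
        pm = build_position_components(500, 3)
        beta = np.array([1.0, 0.0, 0.0])
        for s in (1, 250, 500):
            assert start_probability(pm, beta, s) == pytest.approx(pm.tables[0, s - 1])

    def test_uniform_weights_are_mirror_symmetric(self):
        # symmetric weights render a distribution that mirrors to within
        # the half-position discretization offset of the component grid
        pm = build_position_components(800, 4)
        beta = np.full(4, 0.25)
        dist = pm.render(beta)
        assert np.abs(dist - dist[::-1]).sum() < 0.02

    def test_rendered_distribution_sums_to_one(self):
        pm = build_position_components(2000, 8)
        beta = np.random.default_rng(0).dirichlet(np.ones(8))
        assert pm.render(beta).sum() == pytest.approx(1.0, abs=1e-9)

    def test_five_prime_weights_put_mass_in_first_half(self):
        # front-loaded weights as in a 5'-biased model render a distribution
        # with more than half its mass before the midpoint
        pm = build_position_components(2000, 8)
        beta = np.array([0.35, 0.25, 0.15, 0.1, 0.06, 0.04, 0.03, 0.02])
        dist = pm.render(beta)
        brute = sum(b * pm.tables[j] for j, b in enumerate(beta))
        np.testing.assert_allclose(dist, brute, rtol=1e-12)
        assert dist[:1000].sum() > 0.5

    def test_out_of_range_start_rejected(self):
        pm = build_position_components(100, 2)
        with pytest.raises(ValueError):
            start_probability(pm, [0.5, 0.5], 0)
        with pytest.raises(ValueError):
            start_probability(pm, [0.5, 0.5], 101)


class TestFragmentProbability:
    def _setup(self, locus, M=2, single_end=False):
        mixtures = {
            t.id: build_position_components(t.length, M) for t in locus.transcripts
        }
        N = locus.n_transcripts
        params = Mix2Parameters(
            alpha=np.full(N, 1.0 / N),
            beta=np.full((N, M), 1.0 / M),
            group_of=np.arange(N),
        )
        lm = FragmentLengthModel(mode="single_end_unit" if single_end else "gaussian")
        tindex = {t.id: i for i, t in enumerate(locus.transcripts)}
        return mixtures, params, lm, tindex

    def test_single_end_equals_start_probability(self, two_isoform_locus):
        mixtures, params, lm, tindex = self._setup(two_isoform_locus, single_end=True)
        t = two_isoform_locus.transcripts[0]
        frag = FragmentObservation("r1", {t.id: (321, None)})
        expected = start_probability(mixtures[t.id], params.beta[0], 321)
        got = fragment_probability(frag, t, mixtures, params, tindex, lm)
        assert got == pytest.approx(expected)

    def test_length_factor_peaks_at_the_mean(self, two_isoform_locus):
        mixtures, params, lm, tindex = self._setup(two_isoform_locus)
        t = two_isoform_locus.transcripts[0]
        at_mean = fragment_probability(
            FragmentObservation("a", {t.id: (100, 200)}), t, mixtures, params, tindex, lm
        )
        off_mean = fragment_probability(
            FragmentObservation("b", {t.id: (100, 360)}), t, mixtures, params, tindex, lm
        )
        assert at_mean > off_mean

    def test_matches_hand_summed_mixture(self, two_isoform_locus):
        t = two_isoform_locus.transcripts[1]  # length 1000
        M = 2
        mixtures, params, lm, tindex = self._setup(two_isoform_locus, M=M, single_end=True)
        frag = FragmentObservation("r", {t.id: (25, None)})
        pm = mixtures[t.id]
        by_hand = 0.5 * pm.tables[0, 24] + 0.5 * pm.tables[1, 24]
        got = fragment_probability(frag, t, mixtures, params, tindex, lm)
        assert got == pytest.approx(by_hand)

    def test_incompatible_fragment_scores_zero(self, two_isoform_locus):
        mixtures, params, lm, tindex = self._setup(two_isoform_locus)
        t0, t1 = two_isoform_locus.transcripts
        frag = FragmentObservation("r", {t0.id: (10, 150)})
        assert fragment_probability(frag, t1, mixtures, params, tindex, lm) == 0.0


class TestLocusProbability:
    def test_single_transcript_superposition_is_identity(self, two_isoform_locus):
        from mixsquare import GeneLocus

        t = two_isoform_locus.transcripts[0]
        locus = GeneLocus(gene_id="G1", transcripts=[t])
        M = 3
        mixtures = {t.id: build_position_components(t.length, M)}
        params = Mix2Parameters(
            alpha=np.array([1.0]), beta=np.full((1, M), 1 / M), group_of=np.array([0])
        )
        lm = FragmentLengthModel()
        frag = FragmentObservation("r", {t.id: (42, 180)})
        whole = locus_probability(frag, locus, mixtures, params, lm)
        single = fragment_probability(frag, t, mixtures, params, {t.id: 0}, lm)
        assert whole == pytest.approx(single)

    def test_alpha_weighted_sum_on_shared_junction_locus(self, two_isoform_locus):
        M = 4
        mixtures = {
            t.id: build_position_components(t.length, M)
            for t in two_isoform_locus.transcripts
        }
        params = Mix2Parameters(
            alpha=np.array([0.7, 0.3]),
            beta=np.full((2, M), 1 / M),
            group_of=np.array([0, 1]),
        )
        lm = FragmentLengthModel(mode="single_end_unit")
        # a start inside the shared region maps to both isoforms
        frag = FragmentObservation(
            "r", {"tx_long": (700, None), "tx_short": (200, None)}
        )
        tindex = {"tx_long": 0, "tx_short": 1}
        expected = 0.7 * fragment_probability(
            frag, two_isoform_locus.transcripts[0], mixtures, params, tindex, lm
        ) + 0.3 * fragment_probability(
            frag, two_isoform_locus.transcripts[1], mixtures, params, tindex, lm
        )
        got = locus_probability(frag, two_isoform_locus, mixtures, params, lm)
        assert got == pytest.approx(expected)

    def test_fragment_matching_no_isoform_scores_zero(self, two_isoform_locus):
        M = 2
        mixtures = {
            t.id: build_position_components(t.length, M)
            for t in two_isoform_locus.transcripts
        }
        params = Mix2Parameters(
            alpha=np.array([0.5, 0.5]),
            beta=np.full((2, M), 0.5),
            group_of=np.array([0, 1]),
        )
        frag = FragmentObservation("r", {})
        assert locus_probability(
            frag, two_isoform_locus, mixtures, params, FragmentLengthModel()
        ) == 0.0

    def test_joint_start_length_distribution_normalizes(self):
        # with the truncated length factor, summing alpha_i p(s, l | t=i)
        # over all admissible (s, l) gives exactly 1
        from mixsquare import GeneLocus, TranscriptModel

        t1 = TranscriptModel("a", "G", "c", "+", ((1, 120),))
        t2 = TranscriptModel("b", "G", "c", "+", ((1, 80),))
        locus = GeneLocus("G", [t1, t2])
        M = 2
        lm = FragmentLengthModel(mean=40, sd=15)
        params = Mix2Parameters(
            alpha=np.array([0.6, 0.4]),
            beta=np.array([[0.3, 0.7], [0.5, 0.5]]),
            group_of=np.array([0, 1]),
        )
        total = 0.0
        for i, t in enumerate(locus.transcripts):
            pm = build_position_components(t.length, M)
            dist = pm.render(params.beta[i])
            for s in range(1, t.length + 1):
                max_l = t.length - s + 1
                lens = np.arange(1, max_l + 1)
                total += params.alpha[i] * dist[s - 1] * lm.probabilities(
                    lens, np.full(max_l, max_l)
                ).sum()
        assert total == pytest.approx(1.0, abs=1e-9)
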