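"""EM updates, tying groups, convergence and the Model/Results surface."""

import numpy as np
import pytest

from mixsquare import (
    EMConfig,
    FragmentLengthModel,
    GeneLocus,
    Mix2Model,
    Mix2Parameters,
    TranscriptModel,
    build_position_components,
)
from mixsquare.model import (
    GROUP_BOUNDARIES,
    DegenerateInputError,
    FragmentTable,
    GroupAssignment,
    build_length_groups,
    e_step,
    fpkm_from_result,
    group_distance,
    initialize_parameters,
    merge_groups,
    update_alpha,
    update_beta,
)
from mixsquare.simulate import BiasModel, sample_locus_dataset


def _locus_of_lengths(lengths, gene_id="G"):
    transcripts = []
    pos = 1000
    for k, L in enumerate(lengths):
        transcripts.append(
            TranscriptModel(f"t{k}", gene_id, "c", "+", ((pos, pos + L - 1),))
        )
        pos += L + 10000  # far apart: no cross-compatibility
    return GeneLocus(gene_id, transcripts)


class TestInitialization:
    def test_uniform_alpha_and_beta(self):
        p = initialize_parameters(4, np.zeros(4, dtype=int), 3)
        np.testing.assert_allclose(p.alpha, 0.25)
        np.testing.assert_allclose(p.beta, 1 / 3)

    def test_single_transcript(self):
        p = initialize_parameters(1, [0], 5)
        assert p.alpha == pytest.approx([1.0])

    def test_initial_start_distribution_is_near_uniform(self):
        # uniform beta renders a nearly flat distribution: bounded ripple
        # over the central 90% and small total deviation from uniform
        pm = build_position_components(2000, 4)
        dist = pm.render(np.full(4, 0.25))
        core = dist[100:1900]
        assert core.max() / core.min() < 1.5
        assert np.abs(dist - 1 / 2000).sum() < 0.2


class TestEStep:
    def _toy(self):
        locus = _locus_of_lengths([100, 80])
        table = FragmentTable(
            compat=np.array([[True, True], [True, False], [False, True]]),
            starts=np.array([[10, 10], [50, 0], [0, 20]]),
            lengths=np.array([[30, 30], [20, 0], [0, 40]]),
        )
        params = Mix2Parameters(
            alpha=np.array([0.6, 0.4]),
            beta=np.array([[0.7, 0.3], [0.2, 0.8]]),
            group_of=np.array([0, 1]),
        )
        return locus, table, params

    def test_rows_sum_to_one(self):
        locus, table, params = self._toy()
        res = e_step(locus, table, params)
        np.testing.assert_allclose(res.posteriors.sum(axis=(1, 2)), 1.0, atol=1e-9)

    def test_matches_brute_force_joint_enumeration(self):
        locus, table, params = self._toy()
        lm = FragmentLengthModel()
        res = e_step(locus, table, params, lm)
        mixtures = [build_position_components(t.length, 2) for t in locus.transcripts]
        for r in range(3):
            joint = np.zeros((2, 2))
            for i, t in enumerate(locus.transcripts):
                if not table.compat[r, i]:
                    continue
                s, l = int(table.starts[r, i]), int(table.lengths[r, i])
                p_len = lm.probability(l, t.length - s + 1)
                for j in range(2):
                    joint[i, j] = (
                        params.alpha[i]
                        * params.beta[params.group_of[i], j]
                        * p_len
                        * mixtures[i].tables[j, s - 1]
                    )
            joint /= joint.sum()
            np.testing.assert_allclose(res.posteriors[r], joint, rtol=1e-10)

    def test_single_transcript_posterior_mass(self):
        locus = _locus_of_lengths([200])
        table = FragmentTable(
            compat=np.ones((4, 1), bool),
            starts=np.array([[5], [50], [100], [150]]),
            lengths=np.array([[40], [40], [40], [40]]),
        )
        params = initialize_parameters(1, [0], 3)
        res = e_step(locus, table, params)
        np.testing.assert_allclose(res.posteriors.sum(axis=(1, 2)), 1.0)

    def test_all_dropped_raises(self):
        locus, table, params = self._toy()
        empty = FragmentTable(
            compat=np.zeros((2, 2), bool),
            starts=np.zeros((2, 2), int),
            lengths=np.zeros((2, 2), int),
        )
        with pytest.raises(DegenerateInputError):
            e_step(locus, empty, params)


class TestUpdates:
    def test_alpha_is_posterior_mean(self):
        post = np.zeros((2, 2, 1))
        post[0, 0, 0], post[0, 1, 0] = 0.4, 0.6
        post[1, 0, 0], post[1, 1, 0] = 0.8, 0.2
        np.testing.assert_allclose(update_alpha(post), [0.6, 0.4])

    def test_alpha_concentrates_when_posterior_does(self):
        post = np.zeros((3, 2, 2))
        post[:, 0, 0] = 1.0
        np.testing.assert_allclose(update_alpha(post), [1.0, 0.0])

    def test_alpha_sums_to_one(self, rng):
        post = rng.dirichlet(np.ones(6), size=10).reshape(10, 3, 2)
        assert update_alpha(post).sum() == pytest.approx(1.0)

    def test_beta_rows_sum_to_one(self, rng):
        post = rng.dirichlet(np.ones(8), size=20).reshape(20, 4, 2)
        beta = update_beta(post, [0, 0, 1, 1])
        np.testing.assert_allclose(beta.sum(axis=1), 1.0, atol=1e-12)

    def test_beta_moves_toward_loaded_component(self):
        # all mass on component 1 of a single-transcript locus
        locus = _locus_of_lengths([400])
        pm = build_position_components(400, 2)
        peak = int(np.argmax(pm.tables[0])) + 1
        table = FragmentTable(
            compat=np.ones((50, 1), bool),
            starts=np.full((50, 1), peak),
            lengths=np.full((50, 1), 30),
        )
        params = initialize_parameters(1, [0], 2)
        res = e_step(locus, table, params)
        beta = update_beta(res.posteriors, [0])
        assert beta[0, 0] > 0.5

    def test_tied_group_equals_pooled_computation(self, rng):
        # two transcripts tied in one group == the single-group update on
        # their pooled posteriors
        post = rng.dirichlet(np.ones(6), size=30).reshape(30, 2, 3)
        tied = update_beta(post, [0, 0])
        pooled = post.sum(axis=1, keepdims=True)
        pooled_beta = update_beta(pooled, [0])
        np.testing.assert_allclose(tied, pooled_beta, rtol=1e-12)

    def test_zero_mass_group_keeps_previous_row(self):
        post = np.zeros((2, 2, 2))
        post[:, 0, 0] = 1.0  # transcript 1 never seen
        prev = np.array([[0.5, 0.5], [0.9, 0.1]])
        beta = update_beta(post, [0, 1], previous_beta=prev)
        np.testing.assert_allclose(beta[1], prev[1])


class TestLengthGroups:
    def test_boundaries_are_log_equidistant_300_to_5000(self):
        expected = np.exp(np.linspace(np.log(300), np.log(5000), 7))
        np.testing.assert_allclose(GROUP_BOUNDARIES, expected, rtol=1e-12)
        np.testing.assert_allclose(
            GROUP_BOUNDARIES,
            [300.0, 479.5, 766.3, 1224.7, 1957.4, 3128.4, 5000.0],
            atol=0.1,
        )

    def test_binning_rules(self):
        locus = _locus_of_lengths([350, 400, 300, 5000, 250, 6000, 600])
        ga = build_length_groups(locus)
        groups = {frozenset(int(i) for i in g) for g in ga.groups}
        # 350 and 400 share the first bin with 300 and the below-range 250;
        # 5000 and the above-range 6000 share the last bin; 600 sits alone
        assert frozenset({0, 1, 2, 4}) in groups
        assert frozenset({3, 5}) in groups
        assert frozenset({6}) in groups

    def test_single_transcript_single_group(self):
        ga = build_length_groups(_locus_of_lengths([1234]))
        assert ga.groups == [[0]]


class TestMergeGroups:
    def _assignment(self, groups, means):
        return GroupAssignment(groups=[list(g) for g in groups], mean_length=list(means), valid_read_count=[0] * len(groups))

    def test_distance_formula(self):
        assert group_distance(400, 500) == pytest.approx(25.0)
        assert group_distance(500, 400) == pytest.approx(25.0)

    def test_already_satisfied_is_unchanged(self):
        locus = _locus_of_lengths([400, 450, 2000, 2100])
        ga = self._assignment([[0, 1], [2, 3]], [425, 2050])
        compat = np.zeros((50, 4), bool)
        compat[:25, :2] = True
        compat[25:, 2:] = True
        table = FragmentTable(compat, np.ones((50, 4), int), np.ones((50, 4), int))
        out = merge_groups(ga, table, locus=locus)
        assert [sorted(g) for g in out.groups] == [[0, 1], [2, 3]]

    def test_starved_locus_collapses_to_one_group(self):
        locus = _locus_of_lengths([400, 900, 2000])
        ga = self._assignment([[0], [1], [2]], [400, 900, 2000])
        compat = np.zeros((15, 3), bool)
        compat[:, 0] = True
        table = FragmentTable(compat, np.ones((15, 3), int), np.ones((15, 3), int))
        out = merge_groups(ga, table, locus=locus)
        assert out.n_groups == 1
        assert sorted(out.groups[0]) == [0, 1, 2]

    def test_merges_closest_pair_first(self):
        # singleton surplus forces one merge; 400-500 (25%) is closer than
        # 500-2000 (300%)
        locus = _locus_of_lengths([400, 500, 2000])
        ga = self._assignment([[0], [1], [2]], [400, 500, 2000])
        compat = np.ones((200, 3), bool)
        table = FragmentTable(compat, np.ones((200, 3), int), np.ones((200, 3), int))
        out = merge_groups(ga, table, locus=locus)
        assert sorted(sorted(g) for g in out.groups) == [[0, 1], [2]]


class TestRunEM:
    def test_single_transcript_alpha_one(self, gene_panel):
        locus = GeneLocus("SYNF1", [gene_panel[0].transcripts[0]])
        ds = sample_locus_dataset(locus, BiasModel("cufflinks"), 200, seed=3)
        res = Mix2Model(locus, ds.fragments, tying="none").fit()
        assert res.alpha == pytest.approx([1.0])

    def test_parameter_recovery_two_transcripts(self):
        locus = _locus_of_lengths([2000, 1000])
        ds = sample_locus_dataset(
            locus, BiasModel("cufflinks"), 10000, seed=11, alpha=np.array([0.7, 0.3])
        )
        res = Mix2Model(locus, ds.fragments, tying="group").fit()
        assert np.abs(res.alpha - [0.7, 0.3]).max() < 0.05

    def test_loglik_monotone_on_random_fixtures(self, gene_panel):
        for k in range(20):
            locus = gene_panel[k % len(gene_panel)]
            ds = sample_locus_dataset(
                locus, BiasModel(["cufflinks", "five_prime"][k % 2]), 300, seed=k
            )
            res = Mix2Model(locus, ds.fragments, tying="group").fit()
            diffs = np.diff(res.loglik_path)
            assert (diffs >= -1e-8).all()

    def test_none_tying_equals_singleton_groups(self, gene_panel):
        locus = gene_panel[1]
        ds = sample_locus_dataset(locus, BiasModel("five_prime"), 2000, seed=5)
        res_none = Mix2Model(locus, ds.fragments, tying="none", n_components=3).fit()

        class _SingletonModel(Mix2Model):
            def build_groups(self):
                N = self.locus.n_transcripts
                ga = GroupAssignment(
                    groups=[[i] for i in range(N)],
                    mean_length=[float(t.length) for t in self.locus.transcripts],
                    valid_read_count=[0] * N,
                )
                return ga

        res_single = _SingletonModel(
            locus, ds.fragments, tying="group", n_components=3
        ).fit()
        np.testing.assert_allclose(res_none.alpha, res_single.alpha, atol=1e-10)
        np.testing.assert_allclose(res_none.beta, res_single.beta, atol=1e-10)

    def test_invariants_after_every_iteration(self, gene_panel):
        locus = gene_panel[2]
        ds = sample_locus_dataset(locus, BiasModel("three_prime"), 1000, seed=9)
        res = Mix2Model(locus, ds.fragments, tying="group").fit()
        assert res.alpha.sum() == pytest.approx(1.0, abs=1e-9)
        assert (res.alpha >= 0).all()
        np.testing.assert_allclose(res.beta.sum(axis=1), 1.0, atol=1e-9)
        assert (res.beta >= 0).all()
        assert res.expected_counts.sum() == pytest.approx(res.n_fragments)

    def test_no_fragments_raises(self, gene_panel):
        with pytest.raises(DegenerateInputError):
            Mix2Model(gene_panel[0], [], tying="group").fit()

    def test_recovery_error_decreases_with_sample_size(self):
        # median abundance L1 over seeds shrinks from n=500 to n=10000
        locus = _locus_of_lengths([1500, 900, 600])
        errs = {}
        for n in (500, 10000):
            per_seed = []
            for seed in range(50):
                ds = sample_locus_dataset(locus, BiasModel("cufflinks"), n, seed=seed)
                res = Mix2Model(locus, ds.fragments, tying="none").fit()
                per_seed.append(np.abs(res.alpha - ds.alpha).sum())
            errs[n] = np.median(per_seed)
        assert errs[10000] < errs[500]

    def test_summary_mentions_locus_and_tying(self, gene_panel):
        locus = gene_panel[0]
        ds = sample_locus_dataset(locus, BiasModel("cufflinks"), 500, seed=2)
        res = Mix2Model(locus, ds.fragments, tying="group").fit()
        text = res.summary()
        assert locus.gene_id in text and "tying=group" in text


class TestFpkm:
    def _result_stub(self, counts, lengths):
        locus = _locus_of_lengths(lengths)
        ds = sample_locus_dataset(locus, BiasModel("cufflinks"), 100, seed=1)
        res = Mix2Model(locus, ds.fragments, tying="none").fit()
        res.n_fragments = sum(counts)
        res.params.alpha = np.array(counts) / sum(counts)
        return res

    def test_formula(self):
        # c * 1e9 / (l * total): 10 fragments on a 1 kb transcript out of
        # one million mapped fragments -> FPKM 10
        res = self._result_stub([10, 0], [1000, 500])
        fpkm = fpkm_from_result(res, 10**6)
        assert fpkm[0] == pytest.approx(10.0)
        assert fpkm[1] == pytest.approx(0.0)

    def test_doubling_total_halves_fpkm(self):
        res = self._result_stub([10, 5], [1000, 500])
        np.testing.assert_allclose(
            fpkm_from_result(res, 2 * 10**6), fpkm_from_result(res, 10**6) / 2
        )

    def test_invalid_total_rejected(self):
        res = self._result_stub([10, 5], [1000, 500])
        with pytest.raises(ValueError):
            fpkm_from_result(res, 0)
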