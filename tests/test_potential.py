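import json
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pairpot.fixtures import FixtureSpec, make_chain, make_training_set, \
    perturb_chain
from pairpot.potential import (
    DegenerateSamplesError,
    DistanceDistribution,
    PotentialModel,
    TrainingConfig,
    collect_pairs,
    fit_distribution,
    information_gain,
    score_pmf,
    score_tig,
    scott_bandwidth,
    train,
)
from pairpot.representation import RepresentationSpec, Site, \
    canonical_pair_key, enumerate_pair_classes, project

from conftest import ca_only_chain


def make_sites(positions, ordinals, res_type="ALA", label="CA"):
    return [Site(np.array(p, dtype=float), res_type, label, o)
            for p, o in zip(positions, ordinals)]


class TestCollectPairs:
    def test_close_ordinals_excluded(self):
        sites = make_sites([[0, 0, 0], [1, 0, 0]], [1, 2])
        assert collect_pairs(sites, 15.0, 3) == []

    def test_separated_pair_within_cutoff(self):
        sites = make_sites([[0, 0, 0], [10, 0, 0]], [1, 4])
        obs = collect_pairs(sites, 15.0, 3)
        assert len(obs) == 1
        assert obs[0].distance == pytest.approx(10.0)

    def test_collinear_fixture_matches_brute_force(self):
        # 5 CA sites spaced 3.8 A along x, ordinals 1..5
        positions = [[i * 3.8, 0, 0] for i in range(5)]
        sites = make_sites(positions, [1, 2, 3, 4, 5])

        # brute-force oracle over all 10 unordered pairs
        expected = []
        for i in range(5):
            for j in range(i + 1, 5):
                d = abs(i - j) * 3.8
                if abs(i - j) >= 3 and d <= 17.0:
                    expected.append(d)
        assert sorted(expected) == pytest.approx([11.4, 11.4, 15.2])

        obs = collect_pairs(sites, 17.0, 3)
        assert sorted(o.distance for o in obs) == pytest.approx(sorted(expected))
        assert len(obs) == 3

    def test_each_pair_once(self, mixed_chain):
        sites = project(mixed_chain, RepresentationSpec("CA"))
        obs = collect_pairs(sites, 17.0, 3)
        brute = 0
        for i in range(len(sites)):
            for j in range(i + 1, len(sites)):
                d = np.linalg.norm(sites[i].coords - sites[j].coords)
                if d <= 17.0 and abs(sites[i].seq_ordinal
                                     - sites[j].seq_ordinal) >= 3:
                    brute += 1
        assert len(obs) == brute


class TestScottBandwidth:
    def test_closed_form(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        x = (x - x.mean()) / np.std(x, ddof=1)  # sample sd exactly 1
        assert scott_bandwidth(x) == pytest.approx(100 ** (-0.2), abs=1e-12)

    def test_single_sample_rejected(self):
        with pytest.raises(DegenerateSamplesError):
            scott_bandwidth([1.0])

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateSamplesError):
            scott_bandwidth([2.0] * 50)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(5, 2, size=500)
        assert scott_bandwidth(3.0 * x) == pytest.approx(
            3.0 * scott_bandwidth(x), rel=1e-12)


class TestFitDistribution:
    config = TrainingConfig()

    def test_mode_matches_sampling_oracle(self):
        from scipy.stats import truncnorm
        rng = np.random.default_rng(42)
        a, b = (0.0 - 8.0) / 1.0, (17.0 - 8.0) / 1.0
        samples = truncnorm.rvs(a, b, loc=8.0, scale=1.0, size=10_000,
                                random_state=rng)
        dist = fit_distribution(samples, 17.0, self.config)
        mode_bin = int(np.argmax(dist.probs))
        assert dist.bin_edges[mode_bin] <= 8.0 <= dist.bin_edges[mode_bin + 1]

    def test_empty_gives_uniform(self):
        dist = fit_distribution([], 17.0, self.config)
        assert dist.low_confidence
        assert np.allclose(dist.probs, 1.0 / 34)

    def test_identical_samples_concentrate(self):
        dist = fit_distribution([7.1] * 25, 17.0, self.config)
        assert dist.probs[dist.bin_index(7.1)] == pytest.approx(1.0, abs=1e-6)

    def test_normalization_invariant(self):
        rng = np.random.default_rng(3)
        for n in (2, 5, 100, 5000):
            samples = np.clip(rng.normal(9, 2, size=n), 0.01, 17.0)
            dist = fit_distribution(samples, 17.0, self.config)
            assert abs(dist.probs.sum() - 1.0) <= 1e-9
            assert dist.probs.min() >= self.config.probability_floor * (1 - 1e-6)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fit_distribution([18.0], 17.0, self.config)


class TestTrainingConfig:
    def test_defaults(self):
        cfg = TrainingConfig()
        assert (cfg.train_cutoff, cfg.score_cutoff) == (17.0, 15.0)
        assert cfg.bin_width == 0.5
        assert cfg.min_separation == 3

    def test_cutoff_order_enforced(self):
        with pytest.raises(ValueError):
            TrainingConfig(train_cutoff=10.0, score_cutoff=12.0)

    def test_bin_divisibility_enforced(self):
        with pytest.raises(ValueError):
            TrainingConfig(bin_width=0.7)


def hand_model():
    """Two-bin, two-class model with simple round probabilities."""
    config = TrainingConfig(train_cutoff=1.0, score_cutoff=1.0, bin_width=0.5)
    edges = np.array([0.0, 0.5, 1.0])
    key_aa = (("ALA", "CA"), ("ALA", "CA"))
    key_ag = (("ALA", "CA"), ("GLY", "CA"))
    conditional = {
        key_aa: DistanceDistribution(edges, [0.2, 0.8], 10),
        key_ag: DistanceDistribution(edges, [0.6, 0.4], 10),
    }
    reference = DistanceDistribution(edges, [0.1, 0.9], 100)
    spec = RepresentationSpec("CA")
    return PotentialModel(spec, config, conditional, reference)


def brute_force_score(model, chain, formalism):
    """Independent pair enumeration + direct probability lookup."""
    sites = project(chain, model.spec)
    cfg = model.config
    total = 0.0
    n = 0
    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            if abs(sites[i].seq_ordinal - sites[j].seq_ordinal) \
                    < cfg.min_separation:
                continue
            d = float(np.linalg.norm(sites[i].coords - sites[j].coords))
            if d > cfg.score_cutoff:
                continue
            key = canonical_pair_key(sites[i], sites[j])
            b = min(int(d / cfg.bin_width), cfg.n_bins(cfg.score_cutoff) - 1)
            if key in model.conditional:
                p1 = model.conditional[key].probs[b]
            else:
                p1 = 1.0 / cfg.n_bins(cfg.score_cutoff)
            p2 = model.reference.probs[b]
            r = p1 / p2
            total += -math.log(r) if formalism == "pmf" else -(r - 1.0)
            n += 1
    return total, n


class TestScoring:
    def test_hand_model_pmf_matches_arithmetic(self):
        model = hand_model()
        # separation counts ordinal rank, so residues 2 and 3 are spacers
        # parked far away; scorable pairs are (1,4) at 0.4 A and (1,5) at
        # 0.45 A, both in bin 0
        chain = ca_only_chain(
            [[0, 0, 0], [50, 0, 0], [60, 0, 0], [0.4, 0, 0], [0, 0.45, 0]],
            seq_indices=[1, 2, 3, 4, 5])
        result = score_pmf(model, chain)
        assert result.n_pairs == 2
        expected = -math.log(0.2 / 0.1) * 2
        assert result.total == pytest.approx(expected, abs=1e-12)

    def test_hand_model_tig_single_pair(self):
        model = hand_model()
        chain = ca_only_chain(
            [[0, 0, 0], [50, 0, 0], [60, 0, 0], [0.3, 0, 0]],
            seq_indices=[1, 2, 3, 4])
        # P1 = 0.2, P2 = 0.1 -> term -(0.2/0.1 - 1) = -1
        result = score_tig(model, chain)
        assert result.n_pairs == 1
        assert result.total == pytest.approx(-1.0, abs=1e-12)

    def test_brute_force_equivalence(self):
        model = hand_model()
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = rng.integers(4, 11)
            positions = rng.uniform(0, 3, size=(n, 3))
            res_types = rng.choice(["ALA", "GLY"], size=n)
            chain = ca_only_chain(positions)
            for res, rt in zip(chain.residues, res_types):
                res.res_type = str(rt)
            for formalism, scorer in (("pmf", score_pmf), ("tig", score_tig)):
                expected, n_pairs = brute_force_score(model, chain, formalism)
                result = scorer(model, chain)
                assert result.n_pairs == n_pairs
                assert result.total == pytest.approx(expected, abs=1e-12)

    def test_identical_models_score_zero(self):
        config = TrainingConfig(train_cutoff=1.0, score_cutoff=1.0,
                                bin_width=0.5)
        edges = np.array([0.0, 0.5, 1.0])
        reference = DistanceDistribution(edges, [0.5, 0.5], 10)
        model = PotentialModel(RepresentationSpec("CA"), config, {}, reference)
        chain = ca_only_chain(
            [[0, 0, 0], [50, 0, 0], [60, 0, 0], [0.3, 0, 0], [0, 0.8, 0]],
            seq_indices=[1, 2, 3, 4, 5])
        result = score_pmf(model, chain)
        assert result.n_pairs >= 2
        assert result.total == 0.0
        assert score_tig(model, chain).total == 0.0

    def test_zero_pairs_flagged(self):
        model = hand_model()
        chain = ca_only_chain([[0, 0, 0], [0.4, 0, 0]], res_type="ALA",
                              seq_indices=[1, 2])  # separation 1 < 3
        result = score_pmf(model, chain)
        assert result.empty and result.n_pairs == 0 and result.total == 0.0

    def test_unknown_key_counted(self):
        model = hand_model()
        chain = ca_only_chain(
            [[0, 0, 0], [50, 0, 0], [60, 0, 0], [0.4, 0, 0]],
            res_type="SER", seq_indices=[1, 2, 3, 4])
        result = score_pmf(model, chain)
        assert result.n_pairs == 1
        assert result.n_unknown_pairs == 1

    def test_per_pair_terms_sum_to_total(self, small_training_set,
                                         mixed_chain):
        model = train(small_training_set, RepresentationSpec("CB"))
        result = score_pmf(model, mixed_chain, keep_terms=True)
        assert result.total == pytest.approx(sum(result.per_pair_terms),
                                             abs=1e-9)


class TestInformationGain:
    def test_equal_probs_zero(self):
        model = hand_model()
        # reference bin 1 = 0.9; craft a key with matching conditional
        edges = np.array([0.0, 0.5, 1.0])
        key = (("SER", "CA"), ("SER", "CA"))
        model.conditional[key] = DistanceDistribution(edges, [0.1, 0.9], 5)
        assert information_gain(0.7, key, model) == pytest.approx(0.0)

    def test_factor_two_gain(self):
        model = hand_model()
        key = (("ALA", "CA"), ("ALA", "CA"))
        # P1 = 0.2, P2 = 0.1 in bin 0
        assert information_gain(0.3, key, model) \
            == pytest.approx(math.log(2), abs=1e-12)

    def test_pmf_equals_negated_gain_sum(self, small_training_set,
                                         mixed_chain):
        model = train(small_training_set, RepresentationSpec("CB"))
        sites = project(mixed_chain, model.spec)
        obs = collect_pairs(sites, model.config.score_cutoff,
                            model.config.min_separation)
        gain = sum(information_gain(o.distance, o.key, model) for o in obs)
        assert score_pmf(model, mixed_chain).total \
            == pytest.approx(-gain, abs=1e-9)


class TestTrain:
    def test_class_count_bounded(self, small_training_set):
        spec = RepresentationSpec("CB")
        model = train(small_training_set, spec)
        assert 0 < len(model.conditional) <= enumerate_pair_classes(spec)
        for dist in model.conditional.values():
            assert abs(dist.probs.sum() - 1.0) <= 1e-9

    def test_representation_prior_uses_own_pairs(self, small_training_set):
        spec_aa = RepresentationSpec("CB")
        spec_rp = RepresentationSpec("CB",
                                     reference_mode="representation_prior")
        m_aa = train(small_training_set, spec_aa)
        m_rp = train(small_training_set, spec_rp)
        # the CB-only reference pools far fewer observations than all-atom
        assert m_rp.reference.n_samples < m_aa.reference.n_samples
        assert m_rp.reference.n_samples \
            == m_rp.provenance["n_observations"]

    def test_glycine_exclusion_class_bound(self, small_training_set):
        spec = RepresentationSpec("CB", glycine_policy="exclude")
        model = train(small_training_set, spec)
        assert len(model.conditional) <= 190
        assert not any("GLY" in (k[0][0], k[1][0]) for k in model.conditional)

    def test_serialization_round_trip(self, tmp_path, small_training_set,
                                      mixed_chain):
        model = train(small_training_set, RepresentationSpec("CB"))
        path = tmp_path / "model.json"
        model.save(path)
        back = PotentialModel.load(path)
        assert back.spec == model.spec
        assert back.config == model.config
        assert set(back.conditional) == set(model.conditional)
        for key in model.conditional:
            assert np.array_equal(back.conditional[key].probs,
                                  model.conditional[key].probs)
        assert score_pmf(back, mixed_chain).total \
            == score_pmf(model, mixed_chain).total

    def test_no_chains_rejected(self):
        with pytest.raises(ValueError):
            train([], RepresentationSpec("CB"))


@pytest.fixture(scope="module")
def cb_model(small_training_set):
    return train(small_training_set, RepresentationSpec("CB"))


class TestScoreInvariances:
    def test_rigid_body_invariance(self, cb_model, mixed_chain):
        model = cb_model
        from scipy.spatial.transform import Rotation
        R = Rotation.random(random_state=5).as_matrix()
        moved = mixed_chain.transformed(R, np.array([10.0, -4.0, 2.0]))
        for scorer in (score_pmf, score_tig):
            assert scorer(model, moved).total \
                == pytest.approx(scorer(model, mixed_chain).total, abs=1e-9)

    def test_permutation_invariance(self, cb_model, mixed_chain):
        residues = [r.copy() for r in mixed_chain.residues]
        rng = np.random.default_rng(0)
        rng.shuffle(residues)
        for res in residues:
            rng.shuffle(res.atoms)
        from pairpot.structure_io import Chain
        shuffled = Chain(mixed_chain.chain_id, residues)  # sorts by seq_index
        for scorer in (score_pmf, score_tig):
            assert scorer(cb_model, shuffled).total \
                == pytest.approx(scorer(cb_model, mixed_chain).total,
                                 abs=1e-12)


class TestDiscriminationSmoke:
    """Reduced-size ladder ordering check; the full-size version is an
    acceptance criterion."""

    def test_ladder_ordering_mostly_correct(self):
        chains = make_training_set(
            20, FixtureSpec(150, "random", "strand"), seed=7)
        config = TrainingConfig(bandwidth_scope="global",
                                renormalize_truncated=False)
        model = train(chains, RepresentationSpec("CB"), config)
        ok_pmf = ok_tig = 0
        n_rep = 10
        for rep in range(n_rep):
            native = make_chain(FixtureSpec(40, "random", "strand",
                                            seed=900 + rep))
            rng = np.random.default_rng(500 + rep)
            pmf, tig = [], []
            for sigma in (0.5, 1, 2, 4, 8):
                ps, ts = [], []
                for _ in range(9):
                    decoy = perturb_chain(native, sigma, rng)
                    ps.append(score_pmf(model, decoy).total)
                    ts.append(score_tig(model, decoy).total)
                pmf.append(np.mean(ps))
                tig.append(np.mean(ts))
            ok_pmf += pmf == sorted(pmf)
            ok_tig += tig == sorted(tig)
        assert ok_pmf >= 8
        assert ok_tig >= 8
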