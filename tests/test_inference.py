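"""Posterior computations: oracle equivalence, entropy, novelty, symmetries."""

import copy

import numpy as np
import pytest

import brute_force as bf
from conftest import mini_exemplars
from eyewrite import (
    GeneratorConfig,
    Posterior,
    classify,
    cross_validate,
    curated_templates,
    disability_posterior,
    discretize_aux,
    featurize,
    generate_trajectory,
    is_novel,
    learn_model,
    letter_posterior_final,
    letter_posterior_incremental,
    novelty_posterior,
    posterior_sequence,
    shannon_entropy,
    simulate_disability,
)
from eyewrite.model import _discretize_sequence
from eyewrite.simulate import LabeledTrajectory


class TestOracleEquivalence:
    """Log-space inference must equal linear-space enumeration of the joint."""

    def test_letter_posterior_all_prefixes(self, mini_model):
        for ex in mini_exemplars()[:4]:
            dvps = _discretize_sequence(ex.via_points, mini_model.config)
            for k in range(mini_model.config.n_via_points + 1):
                ours = letter_posterior_incremental(mini_model, ex.via_points, k=k)
                oracle = bf.oracle_letter_posterior(mini_model, dvps[:k])
                np.testing.assert_allclose(ours.probs, oracle, rtol=1e-10, atol=1e-12)

    def test_letter_posterior_final_with_aux(self, mini_model):
        for ex in mini_exemplars()[:4]:
            dvps = _discretize_sequence(ex.via_points, mini_model.config)
            bins = discretize_aux(ex.aux, mini_model.config)
            ours = letter_posterior_final(mini_model, ex.via_points, ex.aux)
            oracle = bf.oracle_letter_posterior(
                mini_model, dvps, {k: bins[k] for k in ("Sx", "Sy", "A")}
            )
            np.testing.assert_allclose(ours.probs, oracle, rtol=1e-10, atol=1e-12)

    def test_novelty_posterior_is_incremental_with_unknown(self, mini_model):
        ex = mini_exemplars()[0]
        ours = novelty_posterior(mini_model, ex.via_points)
        ref = letter_posterior_incremental(mini_model, ex.via_points)
        np.testing.assert_array_equal(ours.probs, ref.probs)
        assert "$" in ours.labels

    def test_disability_posterior(self, mini_model):
        for ex in mini_exemplars()[:4]:
            dvps = _discretize_sequence(ex.via_points, mini_model.config)
            bins = discretize_aux(ex.aux, mini_model.config)
            ours = disability_posterior(mini_model, ex.via_points, ex.aux)
            oracle = bf.oracle_disability_posterior(
                mini_model,
                dvps,
                {k: bins[k] for k in ("Sx", "Sy", "A")},
                {k: bins[k] for k in ("mu_p", "sigma_p")},
            )
            np.testing.assert_allclose(ours.probs, oracle, rtol=1e-10, atol=1e-12)


class TestPosterior:
    def test_no_evidence_is_uniform_prior(self, mini_model):
        post = letter_posterior_incremental(mini_model, [], k=0)
        np.testing.assert_allclose(post.probs, 1.0 / 3)

    def test_posteriors_normalized(self, mini_model):
        for ex in mini_exemplars():
            for post in posterior_sequence(mini_model, ex.via_points, ex.aux):
                assert post.probs.sum() == pytest.approx(1.0, abs=1e-9)
                assert np.all(post.probs >= 0)

    def test_uniform_aux_terms_are_neutral(self, mini_model):
        """With uniform size/energy terms, the final posterior is the k=15 one."""
        model = copy.copy(mini_model)
        model.tables = dict(mini_model.tables)
        for name in ("Sx", "Sy", "A"):
            model.tables[name] = np.full_like(model.tables[name], 1.0 / model.tables[name].shape[0])
        ex = mini_exemplars()[0]
        final = letter_posterior_final(model, ex.via_points, ex.aux)
        incr = letter_posterior_incremental(model, ex.via_points, k=model.config.n_via_points)
        np.testing.assert_allclose(final.probs, incr.probs, atol=1e-12)

    def test_width_evidence_flips_twin_symbols(self, mini_config):
        """Symbols identical in via-points but trained at different widths."""
        from conftest import _vp
        from eyewrite import AuxFeatures
        from eyewrite.model import Exemplar

        vps = (_vp(1, 0, 0, 1, 1), _vp(2, 1, 1, 0, 1))
        narrow = AuxFeatures(sx=1.0, sy=2.0, a=1.0, mu_p=0.0, sigma_p=1.0)
        wide = AuxFeatures(sx=4.0, sy=2.0, a=1.0, mu_p=0.0, sigma_p=1.0)
        exs = [Exemplar(vps, narrow, "u", lv) for lv in (1, 2)] + [
            Exemplar(vps, wide, "n", lv) for lv in (1, 2)
        ]
        model = learn_model(exs, mini_config)
        post_narrow = letter_posterior_final(model, vps, narrow)
        post_wide = letter_posterior_final(model, vps, wide)
        assert post_narrow.argmax == "u"
        assert post_wide.argmax == "n"

    def test_class_relabeling_permutes_posterior(self, mini_model):
        """Permuting the symbol axis of every table permutes posterior entries."""
        cfg = mini_model.config
        perm = [1, 0, 2]  # swap the two real symbols, keep "$"
        permuted = copy.copy(mini_model)
        permuted.config = copy.copy(cfg)
        object.__setattr__(permuted.config, "symbols", tuple(cfg.symbols[i] for i in perm))
        permuted.tables = {}
        for key, arr in mini_model.tables.items():
            if key.startswith(("first_", "trans_")) or key in ("Sx", "Sy", "A"):
                axis = arr.ndim - 2
                permuted.tables[key] = np.take(arr, perm, axis=axis)
            elif key == "L":
                permuted.tables[key] = arr[perm]
            else:
                permuted.tables[key] = arr
        ex = mini_exemplars()[0]
        p1 = letter_posterior_final(mini_model, ex.via_points, ex.aux)
        p2 = letter_posterior_final(permuted, ex.via_points, ex.aux)
        for lab in cfg.symbols:
            assert p1[lab] == p2[lab]

    def test_symmetric_model_gives_uniform_disability(self, mini_config):
        """Identical training per level leaves nothing to distinguish levels."""
        import dataclasses

        exs = [e for e in mini_exemplars() if e.level == 1]
        exs += [dataclasses.replace(e, level=2) for e in exs]
        model = learn_model(exs, mini_config)
        ex = exs[0]
        post = disability_posterior(model, ex.via_points, ex.aux)
        np.testing.assert_allclose(post.probs, 0.5, atol=1e-9)


class TestEntropyAndClassify:
    def test_uniform_entropy_closed_form(self):
        p = Posterior(tuple(str(i) for i in range(36)), np.full(36, 1 / 36))
        assert shannon_entropy(p) == pytest.approx(np.log(36), abs=1e-12)

    def test_delta_entropy_zero(self):
        probs = np.zeros(5)
        probs[2] = 1.0
        assert shannon_entropy(Posterior(("a", "b", "c", "d", "e"), probs)) == 0.0

    def test_two_point_entropy(self):
        probs = np.zeros(6)
        probs[:2] = 0.5
        assert shannon_entropy(probs) == pytest.approx(np.log(2), abs=1e-12)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            shannon_entropy(np.array([0.5, 0.2]))

    def test_classify_unique_max(self):
        probs = np.array([0.1, 0.7, 0.2])
        assert classify(Posterior(("g", "h", "i"), probs)) == "h"

    def test_classify_tie_goes_to_earlier_label(self):
        probs = np.array([0.25, 0.25, 0.5]) / 1.0
        probs = np.array([0.4, 0.4, 0.2])
        assert classify(Posterior(("b", "a", "c"), probs)) == "b"

    def test_classify_uniform_gives_first(self):
        assert classify(Posterior(("x", "y", "z"), np.full(3, 1 / 3))) == "x"


class TestOnSyntheticData:
    def test_training_exemplar_recognized_as_itself(self, db10, symbols10):
        """A distinctive trained shape is the argmax of its own final posterior."""
        model = learn_model(db10)
        for ex in db10[:10]:
            post = letter_posterior_final(model, ex.via_points, ex.aux)
            assert post.argmax == ex.label

    def test_monotone_evidence_accumulation(self, symbols10):
        """Across seeds, the true class wins from some prefix onward and its
        mean posterior keeps growing as via-points accumulate."""
        templates = curated_templates()
        target = "zigzag"
        cfg = GeneratorConfig(pursuit_noise_sd=0.3, saccade_prob=0.0, omt_amplitude=0.0)
        from eyewrite import featurize_database, generate_database

        train = featurize_database(generate_database(symbols10, 6, cfg, seed=21))
        model = learn_model(train)
        curves = []
        for seed in range(100):
            traj = generate_trajectory(templates[target], cfg, rng=1000 + seed)
            vps, aux = featurize(traj)
            posts = posterior_sequence(model, vps)
            curves.append([p[target] for p in posts[1:]])
        mean_curve = np.mean(np.array(curves), axis=0)
        k_star = 3
        assert np.argmax(mean_curve) >= k_star - 1
        assert mean_curve[-1] >= mean_curve[k_star - 1] - 1e-9
        assert mean_curve[-1] > 0.9

    def test_novelty_detection_on_unseen_shape(self, db10):
        """A model trained on 3 shapes flags a geometrically different one."""
        known = {"loop", "zigzag", "arc"}
        model = learn_model([e for e in db10 if e.label in known])
        unseen = next(e for e in db10 if e.label == "spiral")
        post = novelty_posterior(model, unseen.via_points)
        assert post.argmax == "$"
        assert is_novel(post)

    def test_trained_exemplar_beats_unknown(self, db10):
        known = {"loop", "zigzag", "arc"}
        model = learn_model([e for e in db10 if e.label in known])
        ex = next(e for e in db10 if e.label == "loop")
        post = novelty_posterior(model, ex.via_points)
        assert post.argmax == "loop"
        assert post["loop"] > post["$"]

    def test_novelty_with_no_evidence_uniform(self, db10):
        model = learn_model([e for e in db10 if e.label == "loop"])
        post = novelty_posterior(model, [], k=0)
        np.testing.assert_allclose(post.probs, 1.0 / len(post.labels))
        assert post["$"] == pytest.approx(1.0 / len(post.labels))


class TestCrossValidation:
    def test_degenerate_two_alphabets_perfect(self):
        """Two alphabets of two noise-free characters: 4 trials, all correct."""
        templates = curated_templates()
        cfg = GeneratorConfig(pursuit_noise_sd=0.0, omt_amplitude=0.0, saccade_prob=0.0)
        db = []
        for alphabet in range(2):
            for sym in ("loop", "vee"):
                traj = generate_trajectory(templates[sym], cfg, rng=0)
                db.append(LabeledTrajectory(traj, label=sym, alphabet=alphabet))
        from eyewrite import featurize_database

        result = cross_validate(featurize_database(db))
        assert result.n_trials == 4
        assert result.rate == 1.0

    def test_entropy_curve_starts_at_uniform(self, db10):
        subset = [e for e in db10 if e.label in ("loop", "vee", "arc")]
        result = cross_validate(subset)
        n_symbols = 4  # three trained + "$"
        assert result.entropy_curve[0] == pytest.approx(np.log(n_symbols), abs=1e-9)
        assert result.entropy_curve[-1] < result.entropy_curve[0]

    def test_single_group_rejected(self, db10):
        with pytest.raises(ValueError):
            cross_validate([e for e in db10 if e.alphabet == 0])
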