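"""Isoscape classifier, jackknife validation, natal assignment and
natal-exit detection."""

import numpy as np
import pandas as pd
import pytest

from otoscape import natal
from otoscape import synthetic as syn

STA = {"mean": 0.70660, "sd": 0.00008}   # focal river signature
SJR = {"mean": 0.70716, "sd": 0.00013}   # downstream mainstem signature


def _refs(rng, sites):
    rows = [{"site": name, "ratio": rng.normal(m["mean"], m["sd"])}
            for name, m in sites.items() for _ in range(m.get("n", 50))]
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def two_site_clf():
    rng = np.random.default_rng(1)
    return natal.train_isoscape(_refs(rng, {"sta": STA, "sjr": SJR}))


class TestClassifier:
    def test_point_at_site_mean_is_confident(self, two_site_clf):
        post = two_site_clf.posterior([STA["mean"]])[0]
        assert post[two_site_clf.sites.index("sta")] > 0.99

    def test_midpoint_is_maximally_uncertain(self, two_site_clf):
        mid = (two_site_clf.means[0] + two_site_clf.means[1]) / 2
        post = two_site_clf.posterior([mid])[0]
        assert post == pytest.approx([0.5, 0.5], abs=1e-9)

    def test_posteriors_normalized(self, references):
        clf = natal.train_isoscape(references)
        rng = np.random.default_rng(2)
        post = clf.posterior(rng.uniform(0.703, 0.7095, 500))
        assert np.allclose(post.sum(axis=1), 1.0)

    def test_equals_nearest_mean_oracle(self, references):
        # with equal priors and shared variance, 1-D LDA must reduce to the
        # nearest-mean rule
        clf = natal.train_isoscape(references)
        rng = np.random.default_rng(3)
        x = rng.uniform(0.7035, 0.7095, 1000)
        nearest = [clf.sites[i] for i in
                   np.argmin(np.abs(x[:, None] - clf.means[None, :]), axis=1)]
        assert list(clf.classify(x)) == nearest

    def test_matches_sklearn_lda(self, references):
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        clf = natal.train_isoscape(references)
        lda = sklearn.LinearDiscriminantAnalysis(
            priors=np.full(len(clf.sites), 1 / len(clf.sites)))
        lda.fit(references[["ratio"]], references["site"])
        rng = np.random.default_rng(4)
        x = rng.uniform(0.7035, 0.7095, 300)
        assert list(clf.classify(x)) == list(lda.predict(x[:, None]))

    def test_rejects_degenerate_references(self):
        with pytest.raises(ValueError):
            natal.train_isoscape(pd.DataFrame({"site": ["a"] * 4,
                                               "ratio": [0.706] * 4}))
        with pytest.raises(ValueError):  # no spread at all
            natal.train_isoscape(pd.DataFrame(
                {"site": ["a", "a", "b", "b"], "ratio": [0.706] * 4}))


class TestJackknife:
    def test_perfect_separation(self):
        rng = np.random.default_rng(5)
        refs = _refs(rng, {"a": {"mean": 0.7040, "sd": 1e-5, "n": 20},
                           "b": {"mean": 0.7090, "sd": 1e-5, "n": 20}})
        conf, correct = natal.jackknife_scores(refs)
        assert (correct == 1.0).all()

    def test_identical_sites_near_chance(self):
        rng = np.random.default_rng(6)
        refs = _refs(rng, {"a": {"mean": 0.7060, "sd": 1e-4, "n": 150},
                           "b": {"mean": 0.7060, "sd": 1e-4, "n": 150}})
        _, correct = natal.jackknife_scores(refs)
        assert correct.mean() == pytest.approx(0.5, abs=0.12)

    def test_focal_vs_downstream_classification_high(self):
        rng = np.random.default_rng(7)
        refs = _refs(rng, {"sta": STA, "sjr": SJR})  # n=50 each
        _, correct = natal.jackknife_scores(refs)
        assert correct["sta"] > 0.95

    def test_single_sample_site_excluded(self):
        rng = np.random.default_rng(8)
        refs = pd.concat([_refs(rng, {"a": {"mean": 0.7040, "sd": 1e-4, "n": 10},
                                      "b": {"mean": 0.7090, "sd": 1e-4, "n": 10}}),
                          pd.DataFrame({"site": ["c"], "ratio": [0.7060]})])
        with pytest.warns(UserWarning, match="single-sample"):
            conf, _ = natal.jackknife_scores(refs)
        assert "c" not in conf.index


class TestAssignNatal:
    def _profile(self, ratio, n=8, fish="f1"):
        spots = [natal.IsotopeSpot(130.0 + 10 * k, ratio, 5e-5, k)
                 for k in range(n)]
        return natal.OtolithProfile(fish, spots, 400.0)

    def test_focal_fish_not_stray(self, references):
        clf = natal.train_isoscape(references)
        a = natal.assign_natal(self._profile(0.70660), clf, "stanislaus")
        assert a.predicted_site == "stanislaus" and not a.is_stray
        assert sum(a.posterior.values()) == pytest.approx(1.0)

    def test_other_source_flagged_stray(self, references):
        clf = natal.train_isoscape(references)
        a = natal.assign_natal(self._profile(0.70585), clf, "stanislaus")
        assert a.is_stray and a.predicted_site == "mokelumne_hatchery"

    def test_stray_mixture_recovered(self, references):
        clf = natal.train_isoscape(references)
        rng = np.random.default_rng(9)
        n, stray_frac = 200, 0.5
        n_stray = int(n * stray_frac)
        flags = []
        for i in range(n):
            mu = 0.70585 if i < n_stray else 0.70660
            prof = self._profile(rng.normal(mu, 3e-5), fish=f"m{i}")
            flags.append(natal.assign_natal(prof, clf, "stanislaus").is_stray)
        # binomial 95% band around 0.5 at n=200 is ~ +-0.07
        assert np.mean(flags) == pytest.approx(stray_frac, abs=0.07)

    def test_requires_enough_postcore_spots(self, references):
        clf = natal.train_isoscape(references)
        spots = [natal.IsotopeSpot(50.0 + 30 * k, 0.7066, 0.0, k)
                 for k in range(3)]
        prof = natal.OtolithProfile("f", spots, 200.0)
        with pytest.raises(ValueError, match="core"):
            natal.assign_natal(prof, clf, "stanislaus", natal_window=3,
                               core_radius=120.0)


class TestDetectExit:
    def test_two_plateau_profile(self, references):
        # natal plateau at the focal mean, then the downstream value: exit is
        # the last focal-plateau spot
        clf = natal.train_isoscape(references)
        vals = [0.70660] * 6 + [0.70716] * 6
        spots = [natal.IsotopeSpot(130.0 + 10 * k, v, 5e-5, k)
                 for k, v in enumerate(vals)]
        prof = natal.OtolithProfile("f1", spots, 300.0)
        e = natal.detect_exit(prof, clf, "stanislaus")
        assert e.defined and e.exit_index == 5
        assert e.exit_radius == pytest.approx(180.0)

    def test_constant_profile_flagged_undefined(self, references):
        clf = natal.train_isoscape(references)
        spots = [natal.IsotopeSpot(130.0 + 10 * k, 0.70660, 5e-5, k)
                 for k in range(10)]
        e = natal.detect_exit(natal.OtolithProfile("f2", spots, 300.0),
                              clf, "stanislaus")
        assert not e.defined and e.exit_index is None

    @pytest.mark.parametrize("ramp_um", [4.0, 8.0, 15.0])
    def test_ramped_transition_within_one_spacing(self, references, ramp_um):
        clf = natal.train_isoscape(references)
        spacing, true_exit = 10.0, 431.0
        adults = pd.DataFrame([{"fish_id": "r1", "natal_site": "stanislaus",
                                "exit_radius_um": true_exit}])
        (prof,) = syn.generate_profiles(adults, spot_spacing_um=spacing,
                                        ramp_width_um=ramp_um, noise_sd=1e-5,
                                        seed=10)
        e = natal.detect_exit(prof, clf, "stanislaus")
        assert e.defined
        assert abs(e.exit_radius - true_exit) <= spacing

    def test_idempotent_and_bounded(self, references, small_cohort):
        clf = natal.train_isoscape(references)
        world = syn.generate_escapement(small_cohort, n_sample=20, seed=11)
        profiles = syn.generate_profiles(world.adults, seed=12)
        for prof in profiles:
            e1 = natal.detect_exit(prof, clf, "stanislaus")
            e2 = natal.detect_exit(prof, clf, "stanislaus")
            assert (e1.exit_index, e1.exit_radius) == (e2.exit_index, e2.exit_radius)
            if e1.defined:
                assert e1.exit_radius <= prof.otolith_radius
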