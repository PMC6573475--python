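"""ABC-RF model choice and parameter estimation."""

import numpy as np
import pytest

from msypop.abc import (
    ABCModelChoice,
    ABCParameterEstimator,
    ReferenceTable,
    build_reference_table,
    estimate_parameters,
    prior_error_rate,
    rf_model_choice,
    run_model_comparison,
)
from msypop.coalescent import DemographicModel, ParameterDraw, simulate_sfs
from msypop.synth import generate_observed_for_abc

SEP_PRIORS = {"AA": (1e3, 5e3), "DAI": (5e4, 1e5), "TARGET": (5e3, 2e4)}


def separated_model(scenario, L=500_000, n=10):
    """Separated test regime: disjoint source-size priors and split times
    deep relative to deme sizes, so scenario topology marks the spectra."""
    return DemographicModel(
        scenario,
        t_target_years=30_000,
        t_root_years=300_000,
        size_priors={k: tuple(v) for k, v in SEP_PRIORS.items()},
        migration_prior=(5e-3, 5e-2)
        if scenario == "continuous_migration"
        else None,
        locus_length_bp=L,
        sample_sizes={"AA": n, "DAI": n, "TARGET": n},
    )


@pytest.fixture(scope="module")
def separated_table():
    models = {sc: separated_model(sc) for sc in
              ("demic", "cultural", "continuous_migration")}
    return models, build_reference_table(models, 400, base_seed=1000)


class TestReferenceTable:
    def test_balanced_labels(self, separated_table):
        _, table = separated_table
        labels, counts = np.unique(table.model_labels, return_counts=True)
        assert len(labels) == 3 and set(counts) == {400}

    def test_rebuild_is_identical(self, tmp_path):
        models = {sc: separated_model(sc, L=50_000, n=5)
                  for sc in ("demic", "cultural")}
        t1 = build_reference_table(models, 20, base_seed=5)
        t2 = build_reference_table(models, 20, base_seed=5)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        t1.to_tsv(p1)
        t2.to_tsv(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_tsv_roundtrip(self, tmp_path):
        models = {sc: separated_model(sc, L=50_000, n=5)
                  for sc in ("demic", "continuous_migration")}
        t = build_reference_table(models, 10, base_seed=3)
        t.to_tsv(tmp_path / "t.tsv")
        back = ReferenceTable.from_tsv(tmp_path / "t.tsv")
        np.testing.assert_allclose(back.summaries, t.summaries)
        assert list(back.model_labels) == list(t.model_labels)

    def test_mismatched_sample_sizes_rejected(self):
        models = {
            "demic": separated_model("demic", n=5),
            "cultural": separated_model("cultural", n=8),
        }
        with pytest.raises(ValueError, match="sample sizes"):
            build_reference_table(models, 5, base_seed=0)

    def test_single_model_rejected_by_classifier(self):
        models = {"demic": separated_model("demic", L=50_000, n=5)}
        table = build_reference_table(models, 20, base_seed=0)
        with pytest.raises(ValueError, match=">= 2"):
            rf_model_choice(table, table.summaries[0], n_trees=60, seed=0)


class TestModelChoice:
    def test_indistinguishable_models_split_votes(self):
        # two labels over rows simulated from the SAME model: a coin flip
        model = separated_model("demic")
        t1 = build_reference_table({"demic": model}, 500, base_seed=0)
        t2 = build_reference_table({"demic": model}, 500, base_seed=50_000)
        X = np.vstack([t1.summaries, t2.summaries])
        y = np.array(["A"] * 500 + ["B"] * 500)
        clf = ABCModelChoice(n_trees=300, random_state=0).fit(X, y)
        assert abs(clf.oob_prior_error_ - 0.5) < 0.05
        obs = build_reference_table({"demic": model}, 40, base_seed=999_000)
        votes = clf.vote_fractions(obs.summaries)
        assert abs(votes.mean(axis=0)[0] - 0.5) < 0.05

    def test_separated_models_recovered(self, separated_table):
        models, table = separated_table
        clf = ABCModelChoice(n_trees=300, random_state=0)
        clf.fit(table.summaries, table.model_labels)
        correct = {}
        for sc in ("demic", "cultural"):
            hits = 0
            for rep in range(25):
                rng = np.random.default_rng(7_000 + rep)
                from msypop.coalescent import sample_prior

                draw = sample_prior(models[sc], rng)
                sfs = simulate_sfs(models[sc], draw, rng)
                hits += clf.predict(sfs.flatten().reshape(1, -1))[0] == sc
            correct[sc] = hits / 25
        assert correct["demic"] >= 0.75
        assert correct["cultural"] >= 0.75

    def test_posterior_probability_clamped(self, separated_table):
        _, table = separated_table
        clf = ABCModelChoice(n_trees=100, random_state=0)
        clf.fit(table.summaries, table.model_labels)
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 50, size=(100, table.summaries.shape[1]))
        post = clf.posterior_probability(pts)
        assert ((post >= 0) & (post <= 1)).all()

    def test_vote_fractions_sum_to_one_and_argmax_selected(self, separated_table):
        _, table = separated_table
        res = rf_model_choice(table, table.summaries[0], n_trees=100, seed=0)
        assert sum(res.vote_fractions.values()) == pytest.approx(1.0, abs=1e-12)
        assert res.selected_model == max(
            res.vote_fractions, key=res.vote_fractions.get
        )
        assert res.vote_fractions[res.selected_model] >= 1 / 3

    def test_forest_deterministic_given_seed(self, separated_table):
        _, table = separated_table
        obs = table.summaries[3]
        r1 = rf_model_choice(table, obs, n_trees=100, seed=11)
        r2 = rf_model_choice(table, obs, n_trees=100, seed=11)
        assert r1.vote_fractions == r2.vote_fractions
        assert r1.posterior_probability == r2.posterior_probability

    def test_calibration_of_posterior_probability(self, separated_table):
        # predicted posterior probability should track empirical accuracy
        models, table = separated_table
        clf = ABCModelChoice(n_trees=200, random_state=1)
        clf.fit(table.summaries, table.model_labels)
        from msypop.coalescent import sample_prior

        scs = ("demic", "cultural", "continuous_migration")
        preds, posts, truths = [], [], []
        for rep in range(150):
            sc = scs[rep % 3]
            rng = np.random.default_rng(80_000 + rep)
            sfs = simulate_sfs(models[sc], sample_prior(models[sc], rng), rng)
            x = sfs.flatten().reshape(1, -1)
            preds.append(clf.predict(x)[0])
            posts.append(clf.posterior_probability(x)[0])
            truths.append(sc)
        posts = np.array(posts)
        ok = np.array([p == t for p, t in zip(preds, truths)])
        lo, hi = posts < np.median(posts), posts >= np.median(posts)
        assert ok[hi].mean() >= ok[lo].mean() - 0.05

    def test_accuracy_degrades_as_migration_prior_blurs_demic(self):
        # with m -> 0 the continuous-migration model converges to demic, so
        # shrinking the migration prior's upper bound must blur the pair
        accs = []
        for j, bounds in enumerate([(5e-3, 5e-2), (1e-6, 1e-5)]):
            models = {
                "demic": separated_model("demic"),
                "continuous_migration": separated_model("continuous_migration"),
            }
            models["continuous_migration"].migration_prior = bounds
            table = build_reference_table(models, 300, base_seed=j * 100_000)
            err, conf = prior_error_rate(table, n_trees=200, seed=0)
            accs.append(1 - err)
        assert accs[0] >= accs[1] - 0.02


class TestPriorErrorRate:
    def test_separated_confusion_diagonal_dominant(self, separated_table):
        _, table = separated_table
        err, conf = prior_error_rate(table, n_trees=200, seed=0)
        c = conf.to_numpy()
        assert np.all(np.diag(c) > c.sum(axis=1) / 3)
        assert err < 0.5

    def test_degenerate_table_rejected(self, separated_table):
        _, table = separated_table
        tiny = ReferenceTable(
            model_labels=table.model_labels[[0, 400, 800]],
            params=table.params.iloc[[0, 400, 800]].reset_index(drop=True),
            summaries=table.summaries[[0, 400, 800]],
            summary_names=table.summary_names,
        )
        with pytest.raises(ValueError):
            prior_error_rate(tiny, n_trees=60, seed=0)


class TestParameterEstimation:
    def test_degenerate_prior_estimated_exactly(self):
        model = DemographicModel(
            "demic",
            size_priors={"AA": (2e3, 2e3), "DAI": (2e3, 2e3),
                         "TARGET": (7e3, 7e3)},
            locus_length_bp=100_000,
            sample_sizes={"AA": 5, "DAI": 5, "TARGET": 5},
        )
        table = build_reference_table({"demic": model}, 50, base_seed=0)
        with pytest.warns(UserWarning):
            ests = estimate_parameters(
                table.restrict_to("demic"), table.summaries[0],
                n_trees=60, seed=0,
            )
        by = {e.name: e for e in ests}
        assert by["ne_TARGET"].point == 7e3
        assert by["ne_TARGET"].q05 == by["ne_TARGET"].q95 == 7e3

    def test_quantile_ordering_always_holds(self, separated_table):
        _, table = separated_table
        sub = table.restrict_to("demic")
        ests = estimate_parameters(sub, sub.summaries[7], n_trees=100, seed=0)
        for e in ests:
            assert e.q05 <= e.q50 <= e.q95
            lo, hi = SEP_PRIORS[e.name.removeprefix("ne_")]
            assert lo <= e.point <= hi

    def test_target_size_recovery_in_separated_regime(self, separated_table):
        models, table = separated_table
        sub = table.restrict_to("demic")
        est = ABCParameterEstimator(n_trees=200, random_state=0)
        est.fit(sub.summaries, sub.params["ne_TARGET"].to_numpy())
        truth = 1.2e4
        points = []
        for rep in range(20):
            rng = np.random.default_rng(30_000 + rep)
            draw = ParameterDraw(
                ne={"AA": 3e3, "DAI": 7.5e4, "TARGET": truth})
            sfs = simulate_sfs(models["demic"], draw, rng)
            points.append(est.predict(sfs.flatten().reshape(1, -1))[0])
        assert abs(np.median(points) - truth) / truth < 0.25


class TestRunModelComparison:
    def test_end_to_end_recovers_demic(self, separated_table):
        models, table = separated_table
        truth = ParameterDraw(ne={"AA": 2e3, "DAI": 8e4, "TARGET": 1e4})
        _, sfs, manifest = generate_observed_for_abc(
            models["demic"], truth, seed=77
        )
        report = run_model_comparison(
            models, sfs.flatten(), n_trees=200, seed=0, table=table
        )
        assert report["selected_model"] == "demic"
        assert 0 <= report["posterior_probability"] <= 1
        assert sum(report["vote_fractions"].values()) == pytest.approx(1.0)

    def test_report_reproducible(self, separated_table):
        models, table = separated_table
        obs = table.summaries[42]
        r1 = run_model_comparison(models, obs, n_trees=100, seed=3, table=table)
        r2 = run_model_comparison(models, obs, n_trees=100, seed=3, table=table)
        assert r1 == r2
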