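import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from nucleotype.abundance import (
    aggregate_species,
    bayes_r2,
    counts_to_relative,
    filter_prevalence,
    fit_gamma_abundance,
    predict_interaction,
    significance,
)
from nucleotype.simulate import sim_abundance_dataset, sim_tree


@pytest.fixture
def otu_long():
    return pd.DataFrame(
        {
            "otu_id": ["o1", "o2", "o3", "o1", "o2"],
            "sample_id": ["s1", "s1", "s1", "s2", "s2"],
            "count": [2, 3, 5, 1, 1],
            "species": ["spA", "spA", "spB", "spA", None],
        }
    )


class TestRelativeAbundance:
    def test_normalization(self, otu_long):
        out = counts_to_relative(otu_long)
        s1 = out[out.sample_id == "s1"]["proportion"]
        assert s1.tolist() == pytest.approx([0.2, 0.3, 0.5])
        sums = out.groupby("sample_id")["proportion"].sum()
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_single_otu_sample(self):
        df = pd.DataFrame({"otu_id": ["o1"], "sample_id": ["s1"], "count": [7]})
        assert counts_to_relative(df)["proportion"].iloc[0] == 1.0

    def test_zero_total_sample_rejected(self):
        df = pd.DataFrame(
            {"otu_id": ["o1", "o2"], "sample_id": ["s1", "s2"], "count": [3, 0]})
        with pytest.raises(ValueError, match="s2"):
            counts_to_relative(df)


class TestAggregateSpecies:
    def test_sums_otus_within_species(self, otu_long):
        agg = aggregate_species(otu_long)
        row = agg[(agg.species == "spA") & (agg.sample_id == "s1")]
        assert row["rel_abundance"].iloc[0] == pytest.approx(0.5)

    def test_unassigned_otus_dropped(self, otu_long):
        agg = aggregate_species(otu_long)
        # o2 in s2 has no species: spA in s2 keeps only o1's proportion
        row = agg[(agg.species == "spA") & (agg.sample_id == "s2")]
        assert row["rel_abundance"].iloc[0] == pytest.approx(0.5)

    def test_otu_order_invariance(self, otu_long):
        a1 = aggregate_species(otu_long)
        a2 = aggregate_species(otu_long.iloc[::-1].reset_index(drop=True))
        pd.testing.assert_frame_equal(a1, a2)

    def test_mass_conservation_when_fully_assigned(self, otu_long):
        full = otu_long.assign(species=["spA", "spA", "spB", "spA", "spB"])
        agg = aggregate_species(full)
        sums = agg.groupby("sample_id")["rel_abundance"].sum()
        assert np.allclose(sums, 1.0, atol=1e-12)


class TestPrevalenceFilter:
    def _table(self, n_samples_present):
        rows = []
        for sp, k in n_samples_present.items():
            for i in range(k):
                rows.append({"species": sp, "sample_id": f"s{i}",
                             "rel_abundance": 0.1})
        return pd.DataFrame(rows)

    def test_boundary_inclusive(self):
        t = self._table({"nine": 9, "ten": 10, "many": 20})
        kept = set(filter_prevalence(t, 10)["species"])
        assert kept == {"ten", "many"}

    def test_zero_threshold_identity(self):
        t = self._table({"a": 1, "b": 3})
        pd.testing.assert_frame_equal(filter_prevalence(t, 0), t)


def _quick_fit(table, tree, **kw):
    kw.setdefault("chains", 2)
    kw.setdefault("iterations", 2000)
    kw.setdefault("seed", 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return fit_gamma_abundance(table, tree, **kw)


class TestGammaFit:
    def test_zero_abundance_rejected(self):
        tree = sim_tree(5, seed=1)
        table, _ = sim_abundance_dataset(tree, n_stations=4, seed=1)
        table.loc[0, "rel_abundance"] = 0.0
        with pytest.raises(ValueError, match="positive"):
            fit_gamma_abundance(table, tree)

    def test_seeded_determinism(self):
        tree = sim_tree(8, seed=2)
        table, _ = sim_abundance_dataset(tree, n_stations=10, seed=2)
        f1 = _quick_fit(table, tree, iterations=500)
        f2 = _quick_fit(table, tree, iterations=500)
        assert np.array_equal(f1.beta, f2.beta)
        assert np.array_equal(f1.gamma_shape, f2.gamma_shape)

    def test_intercept_only_matches_grid_posterior(self):
        """Single species, no random effect, constant covariates (their
        centered columns are zero, so only the intercept touches the
        likelihood): the sampler's intercept posterior mean matches a
        dense-grid numerical posterior to 2 significant figures."""
        rng = np.random.default_rng(42)
        y = rng.gamma(shape=4.0, scale=math.exp(-2.0) / 4.0, size=120)
        table = pd.DataFrame(
            {"species": "sp1", "sample_id": [f"s{i}" for i in range(120)],
             "rel_abundance": y, "genome_size_log10": 7.5,
             "temperature_c": 15.0})
        fit = _quick_fit(table, None, variant="temperature", iterations=8000)
        b0 = fit.draws("intercept")

        # independent oracle: joint grid over (b0, alpha) with the same
        # priors (Normal(0,5) intercept, Exponential(1) shape), alpha
        # integrated out numerically
        tgrid = np.linspace(-2.6, -1.4, 241)
        agrid = np.linspace(1.0, 9.0, 161)
        n = len(y)
        logpost = np.empty((len(tgrid), len(agrid)))
        for i, b in enumerate(tgrid):
            for j, a in enumerate(agrid):
                ll = (n * (a * math.log(a) - special.gammaln(a))
                      - a * b * n + (a - 1) * np.log(y).sum()
                      - a * math.exp(-b) * y.sum())
                logpost[i, j] = ll - 0.5 * (b / 5) ** 2 - a
        post = np.exp(logpost - logpost.max())
        marg = post.sum(axis=1)
        grid_mean = float((tgrid * marg).sum() / marg.sum())
        assert np.mean(b0) == pytest.approx(grid_mean, abs=0.005)

    def test_interaction_recovery_single(self):
        tree = sim_tree(30, seed=13)
        table, _ = sim_abundance_dataset(
            tree, n_stations=40, interaction_beta=-0.5, seed=13)
        fit = _quick_fit(table, tree, iterations=4000, seed=13)
        lo, hi = fit.credible_interval("temperature_c:genome_size")
        assert lo <= -0.5 <= hi
        assert significance(fit, "temperature_c:genome_size")

    def test_phylo_sd_regimes_separate(self):
        """Posterior phylo_sd distinguishes sd=1 from sd=0 generation."""
        tree = sim_tree(25, seed=3)
        means = {}
        for true_sd in (0.0, 1.0):
            vals = []
            for rep in range(3):
                table, _ = sim_abundance_dataset(
                    tree, n_stations=30, phylo_sd=true_sd, seed=50 + rep)
                fit = _quick_fit(table, tree, iterations=3000, seed=rep)
                vals.append(fit.draws("phylo_sd").mean())
            means[true_sd] = np.mean(vals)
        assert means[1.0] > 3 * means[0.0]

    def test_region_and_latitude_variants_run(self):
        tree = sim_tree(12, seed=4)
        table, _ = sim_abundance_dataset(tree, n_stations=30, seed=4)
        for variant in ("region", "latitude"):
            fit = _quick_fit(table, tree, variant=variant, iterations=1000)
            assert set(fit.rhat.index) >= {"intercept", "genome_size"}
            pred = predict_interaction(fit)
            assert (pred["mean"] > 0).all()


class TestSignificance:
    def _fit_with_draws(self, draws):
        tree = sim_tree(6, seed=5)
        table, _ = sim_abundance_dataset(tree, n_stations=8, seed=5)
        fit = _quick_fit(table, tree, iterations=400)
        fit.beta[:, :, fit.coef_names.index("genome_size")] = np.reshape(
            draws, fit.beta.shape[:2])
        return fit

    def test_interval_sign_rule(self):
        n = 400
        rng = np.random.default_rng(0)
        fit = self._fit_with_draws(rng.uniform(0.1, 0.5, size=n))
        assert significance(fit, "genome_size")
        fit = self._fit_with_draws(rng.uniform(-0.1, 0.5, size=n))
        assert not significance(fit, "genome_size")
        fit = self._fit_with_draws(rng.uniform(-0.5, -0.1, size=n))
        assert significance(fit, "genome_size")

    def test_unknown_parameter(self):
        tree = sim_tree(6, seed=5)
        table, _ = sim_abundance_dataset(tree, n_stations=8, seed=5)
        fit = _quick_fit(table, tree, iterations=400)
        with pytest.raises(KeyError):
            significance(fit, "no_such_parameter")


class TestPrediction:
    def test_default_temperature_grid(self):
        tree = sim_tree(10, seed=6)
        table, _ = sim_abundance_dataset(tree, n_stations=25, seed=6)
        fit = _quick_fit(table, tree, iterations=1000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            pred = predict_interaction(fit)
        assert sorted(pred["temperature_c"].unique()) == [0.0, 10.0, 20.0, 30.0]
        assert (pred["mean"] > 0).all()
        assert (pred["q2.5"] > 0).all()

    def test_negative_interaction_steeper_slope_when_cold(self):
        tree = sim_tree(20, seed=7)
        table, _ = sim_abundance_dataset(
            tree, n_stations=40, interaction_beta=-0.5, seed=7)
        fit = _quick_fit(table, tree, iterations=3000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            pred = predict_interaction(fit)
        slopes = {}
        for t in (0.0, 30.0):
            sub = pred[pred.temperature_c == t]
            dlogmu = np.log(sub["mean"].iloc[-1]) - np.log(sub["mean"].iloc[0])
            dg = sub["genome_size_log10"].iloc[-1] - sub["genome_size_log10"].iloc[0]
            slopes[t] = dlogmu / dg
        assert slopes[0.0] > slopes[30.0]


class TestBayesR2:
    def test_strong_signal_high_r2(self):
        tree = sim_tree(15, seed=8)
        table, _ = sim_abundance_dataset(
            tree, n_stations=30, gamma_shape=1e4, interaction_beta=-0.5, seed=8)
        fit = _quick_fit(table, tree, iterations=3000)
        assert bayes_r2(fit) > 0.95

    def test_bounded(self):
        tree = sim_tree(8, seed=9)
        table, _ = sim_abundance_dataset(tree, n_stations=10, seed=9)
        fit = _quick_fit(table, tree, iterations=500)
        assert 0.0 <= bayes_r2(fit) <= 1.0
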