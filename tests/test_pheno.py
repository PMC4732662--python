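"""BLUEs, REML variance components, heritability, GCA and correlations."""

import numpy as np
import pandas as pd
import pytest

import tcross_gs as t
from tcross_gs.pheno import PhenotypeError


def make_trials(values: dict, trait="yield"):
    """values: {(pollinator, tester, location): value}"""
    rows = [
        {"pollinator": p, "tester": te, "location": l, "trait": trait, "value": v}
        for (p, te, l), v in values.items()
    ]
    return pd.DataFrame(rows)


def balanced_trials(genos: dict, loc_effects: dict, noise=None, trait="yield"):
    """Complete hybrid x location grid: value = genotypic + location (+ noise)."""
    vals = {}
    for (p, te), g in genos.items():
        for l, le in loc_effects.items():
            vals[(p, te, l)] = g + le
    df = make_trials(vals, trait)
    if noise is not None:
        df["value"] += noise
    return df


class TestBlues:
    def test_balanced_data_equals_hybrid_means(self):
        genos = {("P1", "T1"): 10.0, ("P2", "T1"): 12.0, ("P3", "T1"): 8.0}
        trials = balanced_trials(genos, {"L1": -1.0, "L2": 0.5, "L3": 0.5})
        blues = t.fit_blues(trials, "yield")
        raw_means = trials.groupby(["pollinator", "tester"])["value"].mean()
        for _, row in blues.iterrows():
            assert row["blue"] == pytest.approx(
                raw_means[(row["pollinator"], row["tester"])], abs=1e-9
            )

    def test_matches_brute_force_two_way_decomposition(self, rng):
        """Balanced BLUEs equal row means of the column-centered table."""
        hybrids = [(f"P{i}", "T1") for i in range(6)]
        genos = {h: g for h, g in zip(hybrids, rng.normal(10, 2, 6))}
        locs = {f"L{j}": e for j, e in enumerate(rng.normal(0, 1, 4))}
        trials = balanced_trials(genos, locs, noise=rng.normal(0, 0.3, 24))
        blues = t.fit_blues(trials, "yield").set_index("pollinator")["blue"]

        wide = trials.pivot_table(index="pollinator", columns="location", values="value")
        col_centered = wide - wide.mean(axis=0) + wide.to_numpy().mean()
        brute = col_centered.mean(axis=1)
        for p in brute.index:
            assert blues[p] == pytest.approx(brute[p], abs=1e-9)

    def test_missing_cell_adjusted_exactly_without_noise(self):
        genos = {("P1", "T1"): 10.0, ("P2", "T1"): 14.0, ("P3", "T1"): 6.0}
        locs = {"L1": -2.0, "L2": 0.0, "L3": 2.0}
        trials = balanced_trials(genos, locs)
        trials = trials[~((trials.pollinator == "P2") & (trials.location == "L3"))]
        blues = t.fit_blues(trials, "yield").set_index("pollinator")["blue"]
        # additive model is exact here: the missing high-yield location is restored
        assert blues["P2"] == pytest.approx(14.0, abs=1e-9)

    def test_blue_unbiased_under_noise(self):
        errs = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            genos = {(f"P{i}", "T1"): 10.0 + i for i in range(5)}
            locs = {"L1": -2.0, "L2": 1.0, "L3": 1.0}
            trials = balanced_trials(genos, locs, noise=rng.normal(0, 1.0, 15))
            trials = trials[~((trials.pollinator == "P0") & (trials.location == "L1"))]
            blues = t.fit_blues(trials, "yield").set_index("pollinator")["blue"]
            errs.append(blues["P0"] - 10.0)
        assert np.mean(errs) == pytest.approx(0.0, abs=0.2)

    def test_single_location_returns_observed(self):
        trials = make_trials({("P1", "T1", "L1"): 5.0, ("P2", "T1", "L1"): 7.0})
        with pytest.warns(UserWarning, match="single location"):
            blues = t.fit_blues(trials, "yield")
        assert sorted(blues["blue"]) == [5.0, 7.0]

    def test_missing_trait_rejected(self):
        trials = make_trials({("P1", "T1", "L1"): 5.0})
        with pytest.raises(PhenotypeError):
            t.fit_blues(trials, "oil")

    def test_duplicate_records_rejected(self):
        trials = make_trials({("P1", "T1", "L1"): 5.0})
        dup = pd.concat([trials, trials], ignore_index=True)
        with pytest.raises(PhenotypeError, match="duplicate"):
            t.fit_blues(dup, "yield")


class TestVarianceComponents:
    def test_zero_residual_noise(self, rng):
        genos = {(f"P{i}", "T1"): g for i, g in enumerate(rng.normal(0, 2, 40))}
        locs = {"L1": -1.0, "L2": 0.0, "L3": 1.0, "L4": 0.5}
        trials = balanced_trials(genos, locs)
        vc = t.estimate_variance_components(trials, "yield")
        true_var = np.var(list(genos.values()), ddof=1)
        assert vc.sigma2_e == pytest.approx(0.0, abs=1e-6)
        assert vc.sigma2_g == pytest.approx(true_var, rel=0.05)

    def test_identical_hybrids_zero_genetic_variance(self):
        estimates = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            genos = {(f"P{i}", "T1"): 5.0 for i in range(200)}
            locs = {"L1": 0.0, "L2": 1.0, "L3": -0.5, "L4": 0.5}
            trials = balanced_trials(genos, locs, noise=rng.normal(0, 1, 800))
            vc = t.estimate_variance_components(trials, "yield")
            estimates.append(vc.sigma2_g)
        assert np.mean(estimates) == pytest.approx(0.0, abs=0.05)

    def test_matches_statsmodels_mixedlm_oracle(self, rng):
        """Profiled REML agrees with an independent mixed-model fit."""
        import warnings

        import statsmodels.formula.api as smf

        genos = {(f"P{i}", "T1"): g for i, g in enumerate(rng.normal(0, 1.2, 80))}
        locs = {"L1": -1.0, "L2": 0.0, "L3": 1.0, "L4": 0.5}
        trials = balanced_trials(genos, locs, noise=rng.normal(0, 1.5, 320))
        vc = t.estimate_variance_components(trials, "yield")

        sub = trials.copy()
        sub["hybrid"] = sub["pollinator"] + "::" + sub["tester"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = smf.mixedlm(
                "value ~ C(location)", data=sub, groups=sub["hybrid"]
            ).fit(reml=True)
        assert vc.sigma2_g == pytest.approx(float(ref.cov_re.iloc[0, 0]), rel=1e-3)
        assert vc.sigma2_e == pytest.approx(float(ref.scale), rel=1e-3)

    def test_single_location_refused(self):
        trials = make_trials({("P1", "T1", "L1"): 5.0, ("P2", "T1", "L1"): 7.0})
        with pytest.raises(PhenotypeError):
            t.estimate_variance_components(trials, "yield")

    def test_reml_recovery_at_table_scale(self):
        """sigma2_g=1.56, sigma2_e=7.95, 4 locations: mean estimates within 10%."""
        gs, es = [], []
        for seed in range(12):
            rng = np.random.default_rng(seed)
            n_h = 300
            genos = {(f"P{i}", "T1"): g for i, g in enumerate(rng.normal(31, np.sqrt(1.56), n_h))}
            locs = {f"L{j}": e for j, e in enumerate([-1.0, -0.3, 0.3, 1.0])}
            trials = balanced_trials(genos, locs, noise=rng.normal(0, np.sqrt(7.95), 4 * n_h))
            vc = t.estimate_variance_components(trials, "yield")
            gs.append(vc.sigma2_g)
            es.append(vc.sigma2_e)
        assert np.mean(gs) == pytest.approx(1.56, rel=0.10)
        assert np.mean(es) == pytest.approx(7.95, rel=0.10)


class TestHeritability:
    @pytest.mark.parametrize(
        "sigma2_g, sigma2_e, expected_pct",
        [
            (1.56, 7.95, 44),    # seed yield
            (0.56, 0.95, 70),    # oil yield
            (1.91, 0.81, 90),    # oil content
            (1.35, 3.12, 63),    # glucosinolate
            (0.048, 0.41, 32),   # emergence
            (0.119, 0.47, 50),   # lodging
            (0.808, 5.26, 38),   # days to flowering
        ],
    )
    def test_four_location_worked_examples(self, sigma2_g, sigma2_e, expected_pct):
        vc = t.VarianceComponents("x", sigma2_g, sigma2_e, 4)
        assert round(t.broad_sense_heritability(vc)) == expected_pct

    def test_no_residual_variance_is_full_heritability(self):
        vc = t.VarianceComponents("x", 2.0, 0.0, 4)
        assert t.broad_sense_heritability(vc) == 100.0

    def test_undefined_when_both_zero(self):
        vc = t.VarianceComponents("x", 0.0, 0.0, 4)
        with pytest.raises(PhenotypeError):
            t.broad_sense_heritability(vc)


class TestGca:
    def test_hand_arithmetic_example(self):
        # pollinator P: tester BLUEs 32 and 30; grand mean fixed at 31.17
        blues = pd.DataFrame(
            {
                "pollinator": ["P", "P", "Q", "Q"],
                "tester": ["T1", "T2", "T1", "T2"],
                "trait": "yield",
                "blue": [32.0, 30.0, 31.34, 31.34],
            }
        )
        gca = t.compute_gca(blues, "yield").set_index("pollinator")["gca"]
        assert gca["P"] == pytest.approx(31.0 - 31.17, abs=1e-9)

    def test_identical_hybrids_all_zero(self):
        blues = pd.DataFrame(
            {
                "pollinator": list("ABC") * 2,
                "tester": ["T1"] * 3 + ["T2"] * 3,
                "trait": "yield",
                "blue": 7.0,
            }
        )
        gca = t.compute_gca(blues, "yield")
        assert np.allclose(gca["gca"], 0.0)

    def test_sums_to_zero_with_complete_testers(self, small_study):
        blues = t.fit_blues(small_study["trials"], small_study["config"].trait)
        gca = t.compute_gca(blues, small_study["config"].trait)
        assert gca["gca"].sum() == pytest.approx(0.0, abs=1e-8)

    def test_recovers_true_breeding_values_in_additive_noiseless_study(self):
        cfg = t.SimConfig(
            n_lines=60, subpop_sizes=(60,), n_markers=200, fst=0.0, n_qtl=20,
            h2_target=1.0, sca_variance_fraction=0.0, missing_rate=0.0, seed=2,
        )
        panel, trials, truth = t.simulate_study(cfg)
        blues = t.fit_blues(trials, cfg.trait)
        gca = t.compute_gca(blues, cfg.trait).set_index("pollinator")["gca"]
        r = np.corrcoef(gca.loc[truth.true_gca.index], truth.true_gca)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_missing_trait_rejected(self):
        blues = pd.DataFrame(
            {"pollinator": ["P"], "tester": ["T1"], "trait": ["yield"], "blue": [1.0]}
        )
        with pytest.raises(PhenotypeError):
            t.compute_gca(blues, "oil")


class TestTraitCorrelations:
    def _blues(self, traits: dict):
        frames = []
        for trait, vals in traits.items():
            frames.append(
                pd.DataFrame(
                    {
                        "pollinator": [f"P{i}" for i in range(len(vals))],
                        "tester": "T1",
                        "trait": trait,
                        "blue": vals,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def test_self_correlation_and_sign_flip(self, rng):
        y = rng.normal(size=30)
        corr = t.trait_correlations(self._blues({"a": y, "b": -y}))
        assert corr.loc["a", "a"] == 1.0
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_known_correlation_recovered(self, rng):
        n = 950
        cov = np.array([[1.0, 0.66], [0.66, 1.0]])
        xy = rng.multivariate_normal([0, 0], cov, size=n)
        corr = t.trait_correlations(self._blues({"oil": xy[:, 0], "oy": xy[:, 1]}))
        assert corr.loc["oil", "oy"] == pytest.approx(0.66, abs=0.05)

    def test_zero_variance_trait_flagged(self, rng):
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = t.trait_correlations(
                self._blues({"a": rng.normal(size=10), "b": np.full(10, 3.0)})
            )
        assert np.isnan(corr.loc["a", "b"])
        assert corr.loc["b", "b"] == 1.0

    def test_single_trait_rejected(self, rng):
        with pytest.raises(PhenotypeError):
            t.trait_correlations(self._blues({"a": rng.normal(size=5)}))
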