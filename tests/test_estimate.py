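"""Estimator tests: exact recovery on clean data, generator-truth
fixtures, estimator-bias ordering under heteroscedastic noise, and a
brute-force grid-search oracle for the nonlinear fit."""

import numpy as np
import pytest

import ivtwin as iv
from ivtwin.estimate import ALL_METHODS, LINEAR_METHODS, fit
from ivtwin.synthetic import (
    ASSAY_LEVELS_UM,
    FIXTURES,
    NoiseSpec,
    gen_initial_rate_dataset,
)
from ivtwin.transcript import BASES

LEVELS = np.array(ASSAY_LEVELS_UM)


def clean_dataset(base="A", Km=100.0, vmax=0.5, levels=LEVELS) -> iv.InitialRateDataset:
    return iv.InitialRateDataset(
        base=base, levels=levels, rates=vmax * levels / (Km + levels)
    )


def dataset_from_table(table) -> iv.InitialRateDataset:
    return iv.InitialRateDataset(
        base=table["base"].iloc[0],
        levels=table["c_uM"].to_numpy(),
        rates=table["v_uM_per_min"].to_numpy(),
    )


class TestExtractInitialRate:
    def test_exactly_linear_series(self):
        t = np.arange(10.0)
        rate, se, info = iv.extract_initial_rate(t, 0.3 * t)
        assert rate == pytest.approx(0.3, rel=1e-12)
        assert info["window_n"] == 10

    def test_constant_series(self):
        t = np.arange(5.0)
        rate, _, _ = iv.extract_initial_rate(t, np.zeros_like(t) + 2.0)
        assert rate == pytest.approx(0.0, abs=1e-15)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            iv.extract_initial_rate(np.array([0.0, 1.0]), np.array([0.0, 0.1]))

    def test_window_respects_substrate_budget(self):
        # linear early phase then plateau; consumption cap cuts the window
        t = np.linspace(0.0, 100.0, 21)
        c = np.minimum(0.5 * t, 12.0)
        rate, _, info = iv.extract_initial_rate(
            t, c, c_substrate0=1000.0, stoich=10.0
        )
        # 10% of 1000 uM substrate = 100 uM = 10 uM product
        assert info["window_n"] < 21
        assert rate == pytest.approx(0.5, rel=1e-6)

    def test_recovers_simulated_initial_rate(self, ref_params, bnt_transcript, ppiase_strong):
        """Noise-free simulated progress curve at 2.5 mM ATP (others in
        excess) must give back the reduced-law rate within 2%."""
        c0 = 2500.0
        init = iv.ReactionState(
            t=0.0, c_NTP={"A": c0, "C": 40000.0, "G": 40000.0, "U": 40000.0}
        )
        t = np.linspace(0.0, 0.5, 11)  # early linear range
        traj = iv.simulate_batch(init, ref_params, ppiase_strong, bnt_transcript, t)
        rate, _, _ = iv.extract_initial_rate(
            t, traj["c_mRNA_uM"],
            c_substrate0=c0,
            stoich=bnt_transcript.f["A"] * bnt_transcript.n_mRNA,
        )
        assert rate == pytest.approx(
            iv.rate_simple(c0, 140.4, 0.358), rel=0.02
        )


class TestCleanRecovery:
    @pytest.mark.parametrize("method", ALL_METHODS)
    @pytest.mark.parametrize("Km,vmax", [(50.0, 0.1), (100.0, 0.5), (200.0, 1.0)])
    def test_exact_recovery(self, method, Km, vmax):
        r = fit(clean_dataset(Km=Km, vmax=vmax), method)
        assert r.Km == pytest.approx(Km, rel=1e-6)
        assert r.vmax == pytest.approx(vmax, rel=1e-6)

    def test_linearizations_agree_on_clean_data(self):
        d = clean_dataset(Km=137.2, vmax=0.42)
        results = [fit(d, m) for m in LINEAR_METHODS]
        for a, b in zip(results, results[1:]):
            assert a.Km == pytest.approx(b.Km, rel=1e-9)
            assert a.vmax == pytest.approx(b.vmax, rel=1e-9)

    @pytest.mark.parametrize("name", sorted(FIXTURES))
    def test_fixture_truth_recovered_exactly(self, name):
        table, truth = gen_initial_rate_dataset(name, noise=NoiseSpec.none())
        d = dataset_from_table(table)
        for method in ALL_METHODS:
            r = fit(d, method)
            assert r.Km == pytest.approx(truth["Km"], rel=1e-6)
            assert r.vmax == pytest.approx(truth["vmax"], rel=1e-6)

    def test_vmax_invariant_to_base_relabeling(self):
        for base in BASES:
            r = fit(clean_dataset(base=base), "nonlinear")
            assert r.vmax == pytest.approx(0.5, rel=1e-9)


class TestDegenerateInputs:
    def test_two_point_dataset_flagged(self):
        with pytest.warns(UserWarning):
            d = iv.InitialRateDataset(
                base="A", levels=np.array([2500.0, 10000.0]),
                rates=np.array([0.33, 0.35]),
            )
        r = iv.fit_lineweaver_burk(d)
        assert "degenerate_no_dof" in r.flags
        assert np.isnan(r.Km_se)

    def test_nonpositive_rate_rejected_by_linearizations(self):
        d = clean_dataset()
        bad = iv.InitialRateDataset(
            base="A", levels=d.levels, rates=np.array([0.0, 0.1, 0.2, 0.3])
        )
        for m in LINEAR_METHODS:
            with pytest.raises(ValueError):
                fit(bad, m)

    def test_duplicate_levels_are_replicates(self):
        levels = np.array([2500.0, 2500.0, 5000.0, 7500.0, 10000.0])
        d = iv.InitialRateDataset(
            base="A", levels=levels, rates=0.5 * levels / (100.0 + levels)
        )
        r = iv.fit_nonlinear(d)
        assert r.Km == pytest.approx(100.0, rel=1e-6)


class TestNoisyBehaviour:
    def test_hanes_woolf_less_biased_than_lineweaver_burk(self):
        """Constant-sd rate noise is heteroscedastic after the reciprocal
        transform: Lineweaver-Burk's 1/v blows up the low-rate errors and
        biases Km far more than Hanes-Woolf (classic estimator property,
        200 replicates at a fixed seed)."""
        Km, vmax = 120.0, 0.4
        # levels spanning Km so Km is identified and the estimator-bias
        # ordering is attributable to the transforms
        levels = np.array([30.0, 60.0, 180.0, 540.0, 1620.0])
        rng = np.random.default_rng(42)
        km_lb, km_hw = [], []
        for _ in range(200):
            v = vmax * levels / (Km + levels)
            v = np.abs(v + 0.008 * rng.standard_normal(v.shape))
            d = iv.InitialRateDataset(base="A", levels=levels, rates=v)
            km_lb.append(iv.fit_lineweaver_burk(d).Km)
            km_hw.append(iv.fit_hanes_woolf(d).Km)
        bias_lb = abs(np.mean(km_lb) - Km)
        bias_hw = abs(np.mean(km_hw) - Km)
        assert bias_hw < bias_lb

    def test_nonlinear_matches_grid_search_oracle(self):
        """Profile-vmax grid search over Km (step 0.1) as a brute-force
        SSE oracle for the optimizer on noisy datasets."""
        rng = np.random.default_rng(7)
        levels = np.array([50.0, 150.0, 450.0, 1350.0])  # spanning Km
        for _ in range(10):
            Km = rng.uniform(50.0, 250.0)
            vmax = rng.uniform(0.2, 0.8)
            v = vmax * levels / (Km + levels)
            v = np.abs(v * (1.0 + 0.05 * rng.standard_normal(v.shape)))
            d = iv.InitialRateDataset(base="A", levels=levels, rates=v)
            r = iv.fit_nonlinear(d)

            km_grid = np.arange(1.0, 500.0, 0.1)
            g = levels[None, :] / (km_grid[:, None] + levels[None, :])
            vhat = (g @ v) / np.einsum("ij,ij->i", g, g)  # profiled vmax
            sse = np.sum((v[None, :] - vhat[:, None] * g) ** 2, axis=1)
            km_star = km_grid[np.argmin(sse)]
            assert 1.0 < km_star < 499.0  # interior optimum, oracle valid
            assert r.Km == pytest.approx(km_star, abs=0.1 + 1e-9)

    def test_estimate_all_flags_poor_fits(self):
        rng = np.random.default_rng(3)
        clean = clean_dataset()
        noisy_rates = np.abs(
            clean.rates * (1.0 + 0.5 * rng.standard_normal(clean.rates.shape))
        )
        datasets = {
            "A": clean,
            "C": iv.InitialRateDataset(base="C", levels=LEVELS, rates=noisy_rates),
        }
        table = iv.estimate_all(datasets)
        assert len(table) == len(datasets) * len(ALL_METHODS)
        a_rows = table[table["base"] == "A"]
        assert not a_rows["flag_low_R2"].any()
        assert table[table["base"] == "C"]["flag_low_R2"].any()
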