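"""deltaCt computation, weighted line fits, collapse analysis, gene classing."""

import logging

import numpy as np
import pandas as pd
import pytest

import somitewave as sw
from somitewave.qpcr import DEFAULT_FLOOR_SD


def ct_rows(sample, gene, cts, stage=5.0, T=27.0):
    return [
        {"sample": sample, "gene": gene, "temperature_C": T, "stage": stage,
         "time_h": np.nan, "replicate": i + 1, "ct": ct}
        for i, ct in enumerate(cts)
    ]


def wls_oracle(x, y, sd):
    """Hand-written normal-equation solution of min sum(((y-ax-b)/sd)^2)."""
    w = 1.0 / np.asarray(sd, float) ** 2
    x, y = np.asarray(x, float), np.asarray(y, float)
    S, Sx, Sy = w.sum(), (w * x).sum(), (w * y).sum()
    Sxx, Sxy = (w * x * x).sum(), (w * x * y).sum()
    delta = S * Sxx - Sx**2
    a = (S * Sxy - Sx * Sy) / delta
    b = (Sxx * Sy - Sx * Sxy) / delta
    chi2 = (w * (y - a * x - b) ** 2).sum()
    return a, b, chi2, np.sqrt(S / delta), np.sqrt(Sxx / delta)


class TestDeltaCt:
    def test_replicate_means_differenced(self):
        records = pd.DataFrame(
            ct_rows("s1", "fgf8", [20.0, 20.0, 20.0]) + ct_rows("s1", "rpl13a", [16.0, 16.0, 16.0])
        )
        pts = sw.delta_ct_table(records, "fgf8", "rpl13a")
        assert len(pts) == 1
        assert pts.loc[0, "delta_ct"] == pytest.approx(4.0)
        assert pts.loc[0, "sd"] == 0.0
        assert pts.loc[0, "n_replicates"] == 3

    def test_doubling_concentration_shifts_one_cycle(self):
        base = pd.DataFrame(
            ct_rows("s1", "fgf8", [20.0, 20.2, 19.8]) + ct_rows("s1", "rpl13a", [16.0, 16.1, 15.9])
        )
        doubled = base.copy()
        doubled.loc[doubled["gene"] == "fgf8", "ct"] -= 1.0
        d0 = sw.delta_ct_table(base, "fgf8", "rpl13a").loc[0, "delta_ct"]
        d1 = sw.delta_ct_table(doubled, "fgf8", "rpl13a").loc[0, "delta_ct"]
        assert d0 - d1 == pytest.approx(1.0, abs=1e-12)

    def test_noise_free_generator_round_trip(self):
        cfg = sw.SynthConfig(seed=0, ct_noise_sd=0.0, temperatures=(27.0,))
        pts = sw.delta_ct_table(sw.gen_ct_table(cfg), "fgf8", "rpl13a")
        expected = 0.122 * pts["stage"].to_numpy() + 3.955
        assert np.allclose(pts["delta_ct"].to_numpy(), expected, atol=1e-12)

    def test_missing_reference_sample_dropped_with_warning(self, caplog):
        records = pd.DataFrame(
            ct_rows("s1", "fgf8", [20.0] * 3)
            + ct_rows("s1", "rpl13a", [16.0] * 3)
            + ct_rows("s2", "fgf8", [21.0] * 3, stage=7.0)
        )
        with caplog.at_level(logging.WARNING, logger="somitewave"):
            pts = sw.delta_ct_table(records, "fgf8", "rpl13a")
        assert len(pts) == 1
        assert "s2" in caplog.text

    def test_no_overlap_is_error(self):
        records = pd.DataFrame(
            ct_rows("s1", "fgf8", [20.0] * 3) + ct_rows("s2", "rpl13a", [16.0] * 3)
        )
        with pytest.raises(ValueError, match="reference"):
            sw.delta_ct_table(records, "fgf8", "rpl13a")

    def test_single_replicate_uses_floor_sd(self):
        records = pd.DataFrame(
            ct_rows("s1", "fgf8", [20.0]) + ct_rows("s1", "rpl13a", [16.0])
        )
        pts = sw.delta_ct_table(records, "fgf8", "rpl13a")
        assert pts.loc[0, "sd"] == pytest.approx(np.sqrt(2) * DEFAULT_FLOOR_SD)

    @pytest.mark.parametrize(
        "dct,expected", [(4.0, 0.0625), (0.0, 1.0), (3.955, 2.0**-3.955)]
    )
    def test_relative_concentration(self, dct, expected):
        assert sw.relative_concentration(dct) == pytest.approx(expected, rel=1e-12)

    def test_relative_concentration_inverts_known_ratio(self):
        # a gene at 1/10 the reference concentration: deltaCt = log2(10)
        records = pd.DataFrame(
            ct_rows("s1", "goi", [16.0 + np.log2(10)] * 3) + ct_rows("s1", "ref", [16.0] * 3)
        )
        pts = sw.delta_ct_table(records, "goi", "ref")
        assert sw.relative_concentration(pts.loc[0, "delta_ct"]) == pytest.approx(0.1)


class TestWeightedLine:
    def test_perfect_line(self):
        fit = sw.fit_weighted_line([0, 1, 2], [1, 2, 3], [1, 1, 1])
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-15)
        assert fit.df == 1

    def test_hand_solved_example(self):
        fit = sw.fit_weighted_line([0, 1, 2], [1, 2, 4], [1, 1, 1])
        assert fit.slope == pytest.approx(1.5)
        assert fit.intercept == pytest.approx(5 / 6)
        assert fit.chi2 == pytest.approx(1 / 6)

    def test_agreement_with_normal_equation_oracle(self, rng):
        for _ in range(50):
            n = rng.integers(3, 30)
            x = rng.uniform(-5, 5, n)
            if np.ptp(x) == 0:
                continue
            y = rng.uniform(-10, 10, n)
            sd = rng.uniform(0.1, 2.0, n)
            fit = sw.fit_weighted_line(x, y, sd)
            a, b, chi2, se_a, se_b = wls_oracle(x, y, sd)
            assert fit.slope == pytest.approx(a, abs=1e-8)
            assert fit.intercept == pytest.approx(b, abs=1e-8)
            assert fit.chi2 == pytest.approx(chi2, abs=1e-8)
            assert fit.slope_se == pytest.approx(se_a, abs=1e-8)
            assert fit.intercept_se == pytest.approx(se_b, abs=1e-8)

    def test_common_sd_rescaling_invariance(self, rng):
        x = rng.uniform(0, 10, 12)
        y = rng.uniform(0, 5, 12)
        sd = rng.uniform(0.2, 1.0, 12)
        f1 = sw.fit_weighted_line(x, y, sd)
        f3 = sw.fit_weighted_line(x, y, 3.0 * sd)
        assert f3.slope == pytest.approx(f1.slope, rel=1e-12)
        assert f3.intercept == pytest.approx(f1.intercept, rel=1e-12)
        assert f3.chi2 == pytest.approx(f1.chi2 / 9.0, rel=1e-12)
        assert f3.slope_se == pytest.approx(3.0 * f1.slope_se, rel=1e-12)

    def test_singular_and_invalid_inputs(self):
        with pytest.raises(ValueError, match="singular"):
            sw.fit_weighted_line([2, 2, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            sw.fit_weighted_line([0], [1])
        with pytest.raises(ValueError, match="positive"):
            sw.fit_weighted_line([0, 1, 2], [1, 2, 3], [1.0, 0.0, 1.0])

    def test_unit_weight_fallback_flagged(self):
        fit = sw.fit_weighted_line([0, 1, 2, 3], [1.0, 2.1, 2.9, 4.2])
        assert fit.unit_weights
        resid = np.array([1.0, 2.1, 2.9, 4.2]) - fit.predict([0, 1, 2, 3])
        assert fit.chi2 == pytest.approx(float(resid @ resid))


class TestStageFits:
    def test_noise_free_slope_exact(self):
        cfg = sw.SynthConfig(
            seed=0, ct_noise_sd=0.0, temperatures=(27.0,),
            genes=(sw.GeneSpec("fgf8", 0.094, 3.955),),
        )
        pts = sw.delta_ct_table(sw.gen_ct_table(cfg), "fgf8", "rpl13a")
        fit = sw.fit_dct_vs_stage(pts)
        assert fit.slope == pytest.approx(0.094, rel=1e-12)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-18)

    def test_too_few_points_rejected(self):
        pts = pd.DataFrame({"stage": [5.0, 6.0], "delta_ct": [4.0, 4.2], "sd": [0.1, 0.1]})
        with pytest.raises(ValueError):
            sw.fit_dct_vs_stage(pts)

    def test_monte_carlo_recovery(self):
        """Triplicates, 9 stages, 0.3-cycle noise: small bias, >=90% 2-se coverage."""
        hits, slopes, ses = 0, [], []
        n_seeds = 300
        for seed in range(n_seeds):
            cfg = sw.SynthConfig(
                seed=seed, temperatures=(27.0,),
                stages=tuple(float(s) for s in range(5, 22, 2)),
                genes=(sw.GeneSpec("fgf8", 0.094, 3.955),),
            )
            pts = sw.delta_ct_table(sw.gen_ct_table(cfg), "fgf8", "rpl13a")
            fit = sw.fit_dct_vs_stage(pts)
            hits += abs(fit.slope - 0.094) <= 2 * fit.slope_se
            slopes.append(fit.slope)
            ses.append(fit.slope_se)
        assert hits / n_seeds >= 0.90
        assert abs(np.mean(slopes) - 0.094) < 0.1 * np.mean(ses)

    def test_constant_gene_reads_flat(self):
        """A constant transcript's slope stays within 2 se of 0 at near-nominal rate.

        With the scale estimated from the data the z ratio is t-distributed,
        so even a perfectly calibrated fit keeps |slope| <= 2 se in ~94.7%
        of runs (P(|t_36| <= 2)); we require at least 93%.
        """
        hits = 0
        n_seeds = 300
        for seed in range(n_seeds):
            cfg = sw.SynthConfig(
                seed=seed, temperatures=(27.0,),
                stages=tuple(float(s) for s in range(5, 22, 2)),
                genes=(sw.GeneSpec("wnt3", 0.0, 2.0),),
            )
            pts = sw.delta_ct_table(sw.gen_ct_table(cfg), "wnt3", "rpl13a")
            fit = sw.fit_dct_vs_stage(pts)
            hits += abs(fit.slope) <= 2 * fit.slope_se
        assert hits / n_seeds >= 0.93


def staged_series(cfg):
    ct = sw.gen_ct_table(cfg)
    return {
        float(T): sw.delta_ct_table(sub, cfg.genes[0].name, cfg.reference_gene)
        for T, sub in ct.groupby("temperature_C")
    }


class TestCollapse:
    def test_noise_free_pooled_slope_exact(self):
        cfg = sw.SynthConfig(seed=0, ct_noise_sd=0.0)
        pooled = sw.pooled_collapse_fit(staged_series(cfg))
        assert pooled.fit.slope == pytest.approx(0.122, rel=1e-10)
        assert all(
            chi2 == pytest.approx(0.0, abs=1e-16)
            for chi2 in pooled.per_temperature_chi2.values()
        )

    def test_pooled_df_bookkeeping(self):
        cfg = sw.SynthConfig(seed=3)
        pooled = sw.pooled_collapse_fit(staged_series(cfg))
        assert pooled.fit.df == pooled.n_points - 2

    def test_rescaling_always_reduces_pooled_chi2(self):
        """Stage rescaling vs raw time: pooled chi2 strictly smaller, 100 seeds."""
        for seed in range(100):
            cfg = sw.SynthConfig(seed=seed, temperatures=(23.0, 31.0))
            series = staged_series(cfg)
            pooled = sw.pooled_collapse_fit(series)
            raw = pd.concat(series.values(), ignore_index=True)
            unscaled = sw.fit_dct_vs_stage(raw, x="time_h")
            assert pooled.fit.chi2 < unscaled.chi2

    def test_single_temperature_rejected(self):
        cfg = sw.SynthConfig(seed=0, temperatures=(27.0,))
        with pytest.raises(ValueError):
            sw.collapse_test(staged_series(cfg))
        with pytest.raises(ValueError):
            sw.pooled_collapse_fit(staged_series(cfg))

    def test_type_one_error_rate_near_nominal(self):
        """Same law at all temperatures: rejection rate at alpha=0.05 is 0.05+/-0.03."""
        rej = 0
        n_seeds = 200
        for seed in range(n_seeds):
            test = sw.collapse_test(staged_series(sw.SynthConfig(seed=seed)))
            rej += test.p_value < 0.05
        assert 0.02 <= rej / n_seeds <= 0.08

    def test_power_against_broken_collapse(self):
        """One temperature with doubled slope is detected in >=80% of runs."""
        rej = 0
        n_seeds = 200
        stages = np.arange(5.0, 22.0, 2.0)
        for seed in range(n_seeds):
            rng = np.random.default_rng(10_000 + seed)
            series = {}
            for T, slope in ((23.0, 0.122), (31.0, 0.244)):
                series[T] = pd.DataFrame(
                    {
                        "stage": stages,
                        "delta_ct": slope * stages + 3.955 + rng.normal(0, 0.2, stages.size),
                        "sd": 0.2,
                    }
                )
            rej += sw.collapse_test(series).p_value < 0.05
        assert rej / n_seeds >= 0.80


class TestClassification:
    @pytest.mark.parametrize(
        "slope,se,label",
        [
            (0.094, 0.013, "time-varying"),
            (0.01, 0.02, "constant"),
            (-0.08, 0.02, "time-varying"),  # myog-like increasing transcript
        ],
    )
    def test_z_rule(self, slope, se, label):
        fit = sw.LinearFitResult(slope, se, 0.0, 0.1, 1.0, 5, np.eye(2))
        cls = sw.classify_gene(fit, gene="g")
        assert cls.label == label

    def test_zero_se_edge_cases(self):
        varying = sw.LinearFitResult(0.1, 0.0, 0.0, 0.0, 0.0, 1, np.eye(2))
        flat = sw.LinearFitResult(0.0, 0.0, 0.0, 0.0, 0.0, 1, np.eye(2))
        assert sw.classify_gene(varying).label == "time-varying"
        assert sw.classify_gene(flat).label == "constant"

    def test_fgf8_like_z_score(self):
        fit = sw.LinearFitResult(0.094, 0.013, 0.0, 0.1, 22.0, 36, np.eye(2))
        assert sw.classify_gene(fit).z_score == pytest.approx(7.23, abs=0.01)


class TestDecayTime:
    def test_conventions_differ_by_ln2(self):
        assert sw.decay_time_from_slope(0.094, "reciprocal") == pytest.approx(10.64, abs=0.01)
        assert sw.decay_time_from_slope(0.094, "log2") == pytest.approx(
            1 / (0.094 * np.log(2)), rel=1e-12
        )
        assert sw.decay_time_from_slope(1.0, "reciprocal") == 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sw.decay_time_from_slope(-0.1, "reciprocal")
        with pytest.raises(ValueError):
            sw.decay_time_from_slope(0.1, "halving")


class TestReferenceStability:
    def candidates_table(self, rng, drift_gene=None):
        stages = np.arange(5.0, 22.0)
        rows = []
        for s in stages:
            for gene in ("rpl13a", "actb2", "eef1a"):
                drift = 0.1 * s if gene == drift_gene else 0.0
                for rep in range(1, 4):
                    rows.append(
                        {"sample": f"s{s:g}", "gene": gene, "stage": s,
                         "replicate": rep, "ct": 16.0 + drift + rng.normal(0, 0.05)}
                    )
        return pd.DataFrame(rows)

    def test_identical_gene_ranked_first(self, rng):
        df = self.candidates_table(rng)
        df.loc[df["gene"] == "rpl13a", "ct"] = 16.0
        ranked = sw.reference_stability(df, ["rpl13a", "actb2", "eef1a"])
        assert ranked.loc[0, "gene"] == "rpl13a"
        assert ranked.loc[0, "ct_sd"] == 0.0

    def test_covarying_candidates_correlate(self, rng):
        stages = np.arange(5.0, 15.0)
        shared = rng.normal(0, 1.0, stages.size)
        rows = []
        for i, s in enumerate(stages):
            rows.append({"sample": f"s{s:g}", "gene": "a", "ct": 16 + shared[i]})
            rows.append({"sample": f"s{s:g}", "gene": "b", "ct": 18 + shared[i]})
        ranked = sw.reference_stability(pd.DataFrame(rows), ["a", "b"])
        assert np.allclose(ranked["mean_pairwise_r"], 1.0)

    def test_drifting_candidate_ranked_last(self, rng):
        df = self.candidates_table(rng, drift_gene="eef1a")
        ranked = sw.reference_stability(df, ["rpl13a", "actb2", "eef1a"])
        assert ranked.iloc[-1]["gene"] == "eef1a"

    def test_sparse_candidate_excluded(self, rng, caplog):
        df = self.candidates_table(rng)
        df = df[~((df["gene"] == "eef1a") & (df["stage"] > 7))]
        with caplog.at_level(logging.WARNING, logger="somitewave"):
            ranked = sw.reference_stability(df, ["rpl13a", "actb2", "eef1a"])
        assert "eef1a" not in set(ranked["gene"])
        assert "eef1a" in caplog.text
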