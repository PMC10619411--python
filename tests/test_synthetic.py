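"""Synthetic cohort generator: template, calibration, determinism, recovery."""

import dataclasses

import numpy as np
import pytest

from memnet.connectome import tally_to_probability
from memnet.synthetic import (
    CalibrationError,
    CohortConfig,
    Subject,
    calibrate_effects,
    cohort_to_frame,
    generate_cohort,
    make_template,
    read_cohort,
    write_cohort,
)

from conftest import cohort_transitivity, small_cohort_config


class TestTemplate:
    def test_uniform_complete_template_enrichment_is_uniform(self):
        # with equal weights everywhere, symmetry forces equal triangle
        # support: T0 proportional to W0
        model = make_template(6, n_blocks=2, w_within=0.5, w_between=0.5, jitter=0.0)
        off = ~np.eye(6, dtype=bool)
        assert np.allclose(model.w0[off], model.w0[off][0])
        assert np.allclose(model.t0[off], model.t0[off][0])

    def test_equal_levels_erase_block_structure(self):
        model = make_template(8, n_blocks=4, w_within=0.4, w_between=0.4, jitter=0.0)
        off = ~np.eye(8, dtype=bool)
        assert np.unique(model.w0[off]).size == 1

    def test_template_symmetric_zero_diagonal(self):
        model = make_template(12, n_blocks=3, seed=5)
        for m in (model.w0, model.t0):
            assert np.allclose(m, m.T)
            assert not np.diag(m).any()

    def test_transitivity_increases_with_dial(self):
        model = make_template(40, n_blocks=5, seed=2)
        grid = np.linspace(0.2, 0.8, 9)
        t_vals = [model.transitivity(a) for a in grid]
        assert np.all(np.diff(t_vals) > 0)

    def test_mix_extremes_ordered(self):
        # default-style template: full mixing raises transitivity
        model = make_template(82, n_blocks=7, seed=1)
        assert model.transitivity(1.0) > model.transitivity(0.0)

    def test_mix_stays_in_unit_interval(self):
        model = make_template(10, n_blocks=2, seed=3)
        for a in (-0.5, 0.0, 0.5, 1.0, 1.5):
            m = model.mix(a)
            assert m.min() >= 0 and m.max() <= 1

    def test_invalid_levels_rejected(self):
        with pytest.raises(ValueError):
            make_template(10, w_within=0.2, w_between=0.5)
        with pytest.raises(ValueError):
            make_template(10, w_within=0.0, w_between=0.0)
        with pytest.raises(ValueError):
            make_template(10, n_blocks=1)


class TestCalibration:
    def test_null_targets_give_zero_coefficients(self):
        cfg = small_cohort_config(
            d_transitivity=0.0, r_age_transitivity=0.0,
            r_transitivity_memory=0.0, direct_sex_memory_r=0.0,
        )
        coef = calibrate_effects(cfg, n_pilot=5000, n_noise=200)
        assert coef.beta_sex == 0.0
        assert coef.beta_age == 0.0
        assert coef.gamma_memory == 0.0
        assert coef.theta_sex == 0.0

    def test_achieved_d_within_tolerance(self, default_config, default_model):
        coef = calibrate_effects(
            default_config, n_pilot=2000, model=default_model, n_noise=300
        )
        assert abs(coef.achieved["d_transitivity"] - 0.42) <= 0.03

    def test_larger_d_target_needs_larger_sex_coefficient(self, small_model):
        base = small_cohort_config(r_transitivity_memory=0.0, direct_sex_memory_r=0.0)
        lo = dataclasses.replace(base, d_transitivity=0.2)
        hi = dataclasses.replace(base, d_transitivity=0.6)
        c_lo = calibrate_effects(lo, n_pilot=2000, model=small_model, n_noise=250)
        c_hi = calibrate_effects(hi, n_pilot=2000, model=small_model, n_noise=250)
        assert c_hi.beta_sex > c_lo.beta_sex > 0

    def test_infeasible_target_raises_with_trace(self, small_model):
        cfg = small_cohort_config(d_transitivity=0.42, lambda_sd=3.0)
        with pytest.raises(CalibrationError) as err:
            calibrate_effects(cfg, n_pilot=2000, model=small_model, n_noise=150)
        assert err.value.trace  # diagnostics preserved


class TestGenerateCohort:
    def test_deterministic_under_fixed_seed(self, small_config, small_model,
                                            small_coefficients):
        subs1, tal1 = generate_cohort(small_config, small_model, small_coefficients)
        subs2, tal2 = generate_cohort(small_config, small_model, small_coefficients)
        assert [s.recall for s in subs1] == [s.recall for s in subs2]
        assert [s.icv for s in subs1] == [s.icv for s in subs2]
        for t1, t2 in zip(tal1, tal2):
            assert np.array_equal(t1.counts, t2.counts)

    def test_different_seeds_differ(self, small_config, small_model,
                                    small_coefficients):
        subs1, _ = generate_cohort(small_config, small_model, small_coefficients)
        cfg2 = dataclasses.replace(small_config, seed=small_config.seed + 1)
        subs2, _ = generate_cohort(cfg2, small_model, small_coefficients)
        assert [s.icv for s in subs1] != [s.icv for s in subs2]

    def test_cohort_structure(self, small_cohort, small_config):
        subjects, tallies = small_cohort
        assert len(subjects) == small_config.n_subjects
        df = cohort_to_frame(subjects)
        assert set(df.loc[df.sex == "male", "hc_use"]) == {"na"}
        assert df[["recall_neg", "recall_neu", "recall_pos"]].max().max() <= 24
        assert df[["recall_neg", "recall_neu", "recall_pos"]].min().min() >= 0
        for t in tallies:
            assert t.counts.shape == (small_config.n_nodes, small_config.n_nodes)
            assert (t.counts <= t.waytotal[:, None]).all()

    def test_null_sex_effect_recovers_zero(self, small_model):
        """With d target 0 the fitted sex effect is within MC error of 0."""
        from memnet.stats import fit_ols

        cfg = small_cohort_config(
            n_subjects=150, d_transitivity=0.0, r_age_transitivity=0.0,
            r_transitivity_memory=0.0, direct_sex_memory_r=0.0,
        )
        coef = calibrate_effects(cfg, n_pilot=3000, model=small_model, n_noise=200)
        d_vals = []
        for seed in range(20):
            c = dataclasses.replace(cfg, seed=100 + seed)
            df = cohort_transitivity(*generate_cohort(c, small_model, coef))
            res = fit_ols(df, "transitivity", ["male", "age", "icv"])
            d_vals.append(res["male"].cohens_d)
        mc_se = np.std(d_vals, ddof=1) / np.sqrt(len(d_vals))
        assert abs(np.mean(d_vals)) < 3 * mc_se + 0.02

    def test_sex_icv_correlation_recovered(self, small_config, small_model,
                                           small_coefficients):
        rs = []
        for seed in range(30):
            cfg = dataclasses.replace(small_config, n_subjects=200, seed=300 + seed)
            subs, _ = generate_cohort(cfg, small_model, small_coefficients)
            df = cohort_to_frame(subs)
            rs.append(np.corrcoef(1 - df.male, df.icv)[0, 1])
        mc_se = np.std(rs, ddof=1) / np.sqrt(len(rs))
        assert np.mean(rs) == pytest.approx(small_config.icv_sex_r, abs=2 * mc_se + 0.01)

    def test_binomial_tallies_unbiased(self, small_config, small_model,
                                       small_coefficients):
        """N_ij / waytotal is unbiased for the latent weight (one subject)."""
        from memnet.synthetic import _edge_noise, _subject_weights

        rng = np.random.default_rng(17)
        w = _subject_weights(
            small_model, small_config.mix_base,
            _edge_noise(small_config, small_model.n_nodes, rng),
        )
        acc = np.zeros_like(w)
        n_rep = 400
        for _ in range(n_rep):
            acc += rng.binomial(small_config.waytotal, w) / small_config.waytotal
        est = acc / n_rep
        se = np.sqrt(w * (1 - w) / small_config.waytotal / n_rep)
        off = ~np.eye(len(w), dtype=bool)
        z = np.abs(est - w)[off] / np.maximum(se[off], 1e-12)
        assert np.mean(z < 3) > 0.99


class TestSubjectValidation:
    def test_male_with_hc_label_rejected(self):
        with pytest.raises(ValueError, match="na"):
            Subject(id="x", sex="male", age=25, icv=17, batch="room1",
                    hc_use="yes", mc_phase="na")

    def test_recall_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="recall"):
            Subject(id="x", sex="female", age=25, icv=15, batch="room1",
                    hc_use="no", mc_phase="first-half", recall={"negative": 25})


class TestCohortIO:
    def test_round_trip(self, small_cohort, tmp_path):
        subjects, tallies = small_cohort
        write_cohort(subjects, tallies, tmp_path / "cohort")
        subs2, tal2 = read_cohort(tmp_path / "cohort")
        assert [s.id for s in subs2] == [s.id for s in subjects]
        assert [s.recall for s in subs2] == [s.recall for s in subjects]
        assert [s.hc_use for s in subs2] == [s.hc_use for s in subjects]
        for t1, t2 in zip(tallies, tal2):
            assert np.array_equal(t1.counts, t2.counts)
            assert np.array_equal(t1.waytotal, t2.waytotal)
        # probabilities recompute identically after the round trip
        assert np.allclose(
            tally_to_probability(tallies[0]), tally_to_probability(tal2[0])
        )

    def test_empty_directory_error(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="cohort"):
            read_cohort(tmp_path)

    def test_truncated_matrix_error_names_subject(self, small_cohort, tmp_path):
        subjects, tallies = small_cohort
        write_cohort(subjects[:3], tallies[:3], tmp_path / "c")
        bad = tmp_path / "c" / f"{tallies[1].subject_id}_counts.tsv"
        lines = bad.read_text().splitlines()
        bad.write_text("\n".join(lines[:-2]) + "\n")
        with pytest.raises(ValueError, match=tallies[1].subject_id):
            read_cohort(tmp_path / "c")

    def test_missing_tally_file_error(self, small_cohort, tmp_path):
        subjects, tallies = small_cohort
        write_cohort(subjects[:3], tallies[:3], tmp_path / "c")
        (tmp_path / "c" / f"{tallies[2].subject_id}_waytotal.tsv").unlink()
        with pytest.raises(FileNotFoundError, match=tallies[2].subject_id):
            read_cohort(tmp_path / "c")


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_subjects": 0},
            {"prop_female": 1.0},
            {"n_nodes": 2},
            {"waytotal": 0},
            {"icv_sex_r": -1.0},
            {"w_within": 0.1, "w_between": 0.5},
            {"age_range": (35.0, 18.0)},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CohortConfig(**kwargs)

    def test_implied_mediation_consistency(self):
        cfg = CohortConfig()
        med = cfg.implied_mediation()
        assert med["indirect"] == pytest.approx(med["a"] * med["b"])
        assert med["c"] == pytest.approx(med["c_prime"] + med["indirect"])
        # male-coded positive d with negative memory paths: indirect < 0
        assert med["a"] > 0 and med["b"] < 0 and med["indirect"] < 0
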