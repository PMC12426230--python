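import numpy as np
import pytest
from scipy import stats

import pleioscan as ps
from pleioscan._errors import ConfigurationError, DataError
from pleioscan.assay import ProteinAssay, read_cohort, write_panel, write_participants
from pleioscan.association_models import build_model_frame, fit_linear_model
from pleioscan.synthetic_cohort import CohortConfig


def _minimal_cfg(**kw):
    base = dict(
        n_participants=200, n_proteins=2, lod_quantile_map={}, duplicate_spec=[],
        contamination=(0.0, 0.0), missing_fraction=0.0, seed=0,
    )
    base.update(kw)
    return ps.discovery_default_config(**base)


class TestConfigValidation:
    def test_bad_prevalence_names_field(self):
        with pytest.raises(ConfigurationError, match="statin_prevalence"):
            ps.generate_cohort(_minimal_cfg(statin_prevalence=1.5))

    def test_unknown_effect_protein(self):
        # CohortConfig is strict (the default-config factories prune instead)
        with pytest.raises(ConfigurationError, match="effect_map"):
            ps.generate_cohort(CohortConfig(n_proteins=2, effect_map={"NOPE": 0.2}))

    def test_bad_missing_fraction(self):
        with pytest.raises(ConfigurationError, match="missing_fraction"):
            ps.generate_cohort(_minimal_cfg(missing_fraction=1.0))


class TestGenerateCohort:
    def test_fixed_seed_determinism(self):
        cfg = ps.discovery_default_config(seed=7, n_proteins=10)
        a = ps.generate_cohort(cfg)
        b = ps.generate_cohort(ps.discovery_default_config(seed=7, n_proteins=10))
        assert a.participants.equals(b.participants)
        for x, y in zip(a.panel, b.panel):
            assert x.protein_name == y.protein_name
            np.testing.assert_array_equal(x.values, y.values)
            np.testing.assert_array_equal(x.below_lod_mask, y.below_lod_mask)

    def test_prevalence_within_binomial_bounds_no_confounding(self):
        # central 99% binomial(855, 0.161) interval
        lo, hi = stats.binom.ppf([0.005, 0.995], 855, 0.161)
        cfg = ps.discovery_default_config(
            seed=3, n_proteins=1, confounding_weights={}, missing_fraction=0.0,
        )
        cohort = ps.generate_cohort(cfg)
        assert lo <= cohort.participants["statin_use"].sum() <= hi

    def test_noise_free_effect_exact(self):
        cfg = _minimal_cfg(
            protein_noise_sd=0.0, covariate_effect_sd=0.0, protein_intercept_sd=0.0,
            confounding_weights={}, effect_map={"TRANCE": 0.21},
        )
        cohort = ps.generate_cohort(cfg)
        statin = cohort.participants["statin_use"].to_numpy() == 1
        y = cohort.assay("TRANCE").values
        diff = y[statin].mean() - y[~statin].mean()
        assert diff == pytest.approx(0.21, abs=1e-12)

    def test_truth_stored_for_all_proteins(self):
        cohort = ps.generate_cohort(_minimal_cfg(effect_map={"TRANCE": 0.3}))
        assert cohort.truth["TRANCE"] == 0.3
        assert cohort.truth["TRAIL"] == 0.0

    def test_missingness_rate(self):
        cfg = _minimal_cfg(n_participants=2000, missing_fraction=0.05)
        cohort = ps.generate_cohort(cfg)
        cov_cols = [c for c in cohort.participants.columns
                    if c not in ("participant_id", "statin_use")]
        frac = cohort.participants[cov_cols].isna().to_numpy().mean()
        assert frac == pytest.approx(0.05, abs=0.01)

    def test_covariate_balance_without_confounding(self):
        # with zero confounding weights the two exposure groups are exchangeable
        for seed in range(8):
            cfg = _minimal_cfg(n_participants=855, confounding_weights={}, seed=seed)
            cohort = ps.generate_cohort(cfg)
            g = cohort.participants["statin_use"] == 1
            t, _ = stats.ttest_ind(
                cohort.participants.loc[g, "age"], cohort.participants.loc[~g, "age"]
            )
            assert abs(t) < 4

    def test_duplicate_spec_creates_group(self):
        cfg = ps.discovery_default_config(seed=2, n_proteins=12)
        cohort = ps.generate_cohort(cfg)
        grouped = [a for a in cohort.panel if a.duplicate_group == "IL8"]
        assert {a.protein_name for a in grouped} == {"IL8", "IL8_dup"}
        cvs = {a.protein_name: a.inter_assay_cv for a in grouped}
        assert cvs["IL8"] == 8.0 and cvs["IL8_dup"] == 12.0


class TestConfoundingStructure:
    def test_naive_estimate_biased_adjusted_not(self):
        # structural confounding through age/diabetes: the crude group
        # difference is biased away from truth, the adjusted fit is not
        truth = 0.2
        naive_err, adj_err = [], []
        for seed in range(60):
            cfg = _minimal_cfg(
                n_participants=600, n_proteins=1, seed=seed,
                protein_noise_sd=0.3, effect_map={"TRANCE": truth},
                confounding_weights={"age": 1.0, "diabetes": 1.5},
                covariate_effect_map={"TRANCE": {"age": 0.5, "diabetes": 0.8}},
            )
            cohort = ps.generate_cohort(cfg)
            statin = cohort.participants["statin_use"].to_numpy() == 1
            y = cohort.assay("TRANCE").values
            naive_err.append(y[statin].mean() - y[~statin].mean() - truth)
            frame = build_model_frame(cohort, cohort.assay("TRANCE"))
            fit = fit_linear_model(frame, compute_diagnostics=False)
            adj_err.append(fit.beta - truth)
        assert abs(np.mean(naive_err)) > 3 * abs(np.mean(adj_err))
        assert abs(np.mean(adj_err)) < 0.05


class TestCensorAtLod:
    def test_zero_fraction_boundary(self, rng):
        assay = ProteinAssay("p", rng.normal(size=50))
        out = ps.censor_at_lod(assay, 0.0)
        assert out.lod <= out.values.min()
        assert not out.below_lod_mask.any()

    def test_full_fraction_boundary(self, rng):
        assay = ProteinAssay("p", rng.normal(size=50))
        out = ps.censor_at_lod(assay, 1.0)
        expected = out.values < out.values.max()
        np.testing.assert_array_equal(out.below_lod_mask, expected)

    def test_empirical_fraction(self, rng):
        assay = ProteinAssay("p", rng.standard_normal(1000))
        out = ps.censor_at_lod(assay, 0.3)
        assert out.below_lod_mask.mean() == pytest.approx(0.3, abs=1.5 / 1000)
        np.testing.assert_array_equal(out.values, assay.values)  # values untouched

    def test_empty_values_error(self):
        assay = ProteinAssay("p", np.array([np.nan, np.nan]))
        with pytest.raises(DataError):
            ps.censor_at_lod(assay, 0.5)


class TestInjectOutliers:
    def test_zero_fraction_identity(self, rng):
        assay = ProteinAssay("p", rng.normal(size=40))
        out = ps.inject_outliers(assay, 0.0, 10.0, seed=1)
        np.testing.assert_array_equal(out.values, assay.values)

    def test_ceiling_count(self, rng):
        assay = ProteinAssay("p", rng.normal(size=100))
        out = ps.inject_outliers(assay, 0.01, 10.0, seed=5)
        assert out.modified_idx.size == 1
        changed = np.flatnonzero(out.values != assay.values)
        np.testing.assert_array_equal(changed, out.modified_idx)

    def test_fraction_half_rejected(self, rng):
        assay = ProteinAssay("p", rng.normal(size=10))
        with pytest.raises(ConfigurationError):
            ps.inject_outliers(assay, 0.5, 10.0, seed=1)

    def test_detector_flags_injected_point(self):
        r = np.random.default_rng(11)
        assay = ProteinAssay("p", r.standard_normal(100))
        out = ps.inject_outliers(assay, 0.01, 10.0, seed=11)
        flags, _ = ps.detect_outliers(out.values)
        assert flags[out.modified_idx[0]]


class TestSerialization:
    def test_roundtrip_through_tsv(self, tmp_path, small_discovery_cohort):
        c = small_discovery_cohort
        write_participants(c, tmp_path / "p.tsv")
        write_panel(c, tmp_path / "m.tsv", tmp_path / "a.tsv")
        back = read_cohort(tmp_path / "p.tsv", tmp_path / "m.tsv", tmp_path / "a.tsv", "discovery")
        assert back.n == c.n
        assert [a.protein_name for a in back.panel] == [a.protein_name for a in c.panel]
        for orig, rt in zip(c.panel, back.panel):
            np.testing.assert_allclose(rt.values, orig.values, rtol=0, atol=1e-9)
            assert rt.lod == pytest.approx(orig.lod) or (
                np.isinf(orig.lod) and np.isinf(rt.lod)
            )
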