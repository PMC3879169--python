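"""Mating-type closed forms, the adjusted-rate mixed model, death-fraction
estimation and lethal-equivalents arithmetic."""

import numpy as np
import pandas as pd
import pytest

from lethalmap import lethality, simpop
from tests.conftest import tiny_population_config


class TestClosedForms:
    @pytest.mark.parametrize("mt,expect", [
        ("I", 0.0), ("II", 0.0), ("III", 0.25 * 0.128),
    ])
    def test_homozygote_fractions(self, mt, expect):
        assert lethality.expected_homozygote_fraction(mt, 0.128) == pytest.approx(expect)

    def test_type_iv_conditioning_variants(self):
        cond = lethality.expected_homozygote_fraction("IV", 0.128)
        assert cond == pytest.approx(0.25 * 0.5 / (1 - 0.064))
        flat = lethality.expected_homozygote_fraction("IV", 0.128,
                                                      conditioned=False)
        assert flat == pytest.approx(0.125)
        assert lethality.expected_homozygote_fraction("IV", 0.0) == pytest.approx(0.125)

    def test_expected_extra_failure_arithmetic(self):
        # delta=1, type III: 0.25 (1-f) p
        got = lethality.expected_extra_failure("III", 0.128, 0.278, 1.0)
        assert got == pytest.approx(0.25 * 0.722 * 0.128, abs=1e-12)
        for mt in lethality.MATING_TYPES:
            assert lethality.expected_extra_failure(mt, 0.128, 0.3, 0.0) == 0.0

    def test_limits_reduce_correctly(self):
        for mt in lethality.MATING_TYPES:
            if mt in ("I", "II"):
                continue
            assert lethality.expected_extra_failure(mt, 0.0, 0.3, 1.0) == \
                pytest.approx(0.0 if mt == "III" else 0.25 * 0.5 * 0.7)
        assert lethality.expected_extra_failure("III", 0.0, 0.3, 1.0) == 0.0
        assert lethality.expected_extra_failure("IV", 0.2, 1.0 - 1e-12, 1.0) \
            == pytest.approx(0.0, abs=1e-9)

    def test_monte_carlo_matches_closed_form_per_type(self, rng):
        p, f, delta = 0.128, 0.35, 0.6
        n = 1_000_000
        for mt in lethality.MATING_TYPES:
            sire_c = mt in ("III", "IV")
            mgs_c = mt in ("II", "IV")
            mgs_gam = rng.random(n) < (0.5 if mgs_c else 0.0)
            gd_gam = rng.random(n) < p
            dam = mgs_gam.astype(int) + gd_gam.astype(int)
            # viability: redraw homozygous dams
            dead = dam == 2
            while dead.any():
                k = dead.sum()
                dam[dead] = ((rng.random(k) < (0.5 if mgs_c else 0.0)).astype(int)
                             + (rng.random(k) < p).astype(int))
                dead = dam == 2
            s_gam = rng.random(n) < (0.5 if sire_c else 0.0)
            d_gam = rng.random(n) < dam / 2.0
            hom = s_gam & d_gam
            extra = hom.mean() * delta * (1 - f)
            expect = lethality.expected_extra_failure(mt, p, f, delta)
            se = 3 * delta * (1 - f) * np.sqrt(0.25 / n)
            assert abs(extra - expect) < max(se, 1e-9), mt


class TestDeathFraction:
    def test_printed_inputs_reproduce_twenty_percent(self):
        est = lethality.estimate_death_fraction(0.02, "IV", 0.128, 0.278)
        assert est.death_fraction == pytest.approx(0.2074, abs=5e-4)
        est_u = lethality.estimate_death_fraction(0.02, "IV", 0.128, 0.278,
                                                  conditioned=False)
        assert est_u.death_fraction == pytest.approx(0.2216, abs=5e-4)

    def test_identity_and_zero_cases(self):
        exp = lethality.expected_extra_failure("IV", 0.128, 0.278, 1.0)
        assert lethality.estimate_death_fraction(exp, "IV", 0.128, 0.278) \
            .death_fraction == pytest.approx(1.0)
        assert lethality.estimate_death_fraction(0.0, "IV", 0.128, 0.278) \
            .death_fraction == 0.0

    def test_exceeding_one_flagged_not_truncated(self):
        est = lethality.estimate_death_fraction(0.5, "IV", 0.128, 0.278)
        assert est.death_fraction > 1.0 and est.exceeds_one

    def test_zero_expected_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            lethality.estimate_death_fraction(0.02, "I", 0.128, 0.278)


class TestLethalEquivalents:
    def test_discussion_rescalings(self):
        assert lethality.rescale_equivalents(7.5, 0.10, 0.01) == pytest.approx(750.0)
        assert lethality.rescale_equivalents(7.5, 0.10, 0.05) == pytest.approx(30.0)
        assert lethality.rescale_equivalents(3.3, 0.2, 0.2) == pytest.approx(3.3)

    def test_budget_arithmetic(self):
        assert lethality.lethal_equivalents(0.075, 0.1) == pytest.approx(7.5)
        with pytest.raises(ValueError):
            lethality.lethal_equivalents(0.075, 0.0)


class TestClassifyMatings:
    def test_definition_table(self):
        table = pd.DataFrame({
            "cow_id": [1, 2, 3, 4], "sire_id": [10, 10, 11, 11],
            "mgs_id": [20, 21, 20, 21], "parity": 1, "month_year": 0,
            "failure_35": 0, "failure_56": 0, "failure_100": 0,
            "failure_150": 0})
        rec = simpop.InseminationRecords(table=table)
        status = {10: False, 11: True, 20: False, 21: True}
        annotated, counts = lethality.classify_matings(rec, status)
        assert list(annotated["mating_type"]) == ["I", "II", "III", "IV"]
        assert sum(counts[k] for k in lethality.MATING_TYPES) == 4
        assert counts["unresolved"] == 0

    def test_unresolved_records_excluded_and_counted(self):
        table = pd.DataFrame({
            "cow_id": [1, 2], "sire_id": [10, 99], "mgs_id": [20, 20],
            "parity": 1, "month_year": 0, "failure_35": 0, "failure_56": 0,
            "failure_100": 0, "failure_150": 0})
        rec = simpop.InseminationRecords(table=table)
        annotated, counts = lethality.classify_matings(rec, {10: True, 20: False})
        assert len(annotated) == 1 and counts["unresolved"] == 1

    def test_type_frequencies_match_gene_dropping(self, small_cohort):
        ins = simpop.simulate_inseminations(small_cohort,
                                            small_cohort.config.repro, seed=71)
        status = dict(zip(small_cohort.phased.animal_ids,
                          small_cohort.phased.deletion_copies >= 1))
        annotated, counts = lethality.classify_matings(ins, status)
        ped = small_cohort.pedigree.table
        males = ped[ped["sex"] == "M"]["animal_id"]
        c = np.mean([status[a] for a in males])
        n = sum(counts[k] for k in lethality.MATING_TYPES)
        # male pool carrier fraction c: P(IV) = c^2 etc.
        for mt, expect in (("I", (1 - c) ** 2), ("II", (1 - c) * c),
                           ("III", c * (1 - c)), ("IV", c * c)):
            se = np.sqrt(expect * (1 - expect) / n)
            # sires/MGS are resampled from a finite pool: allow extra slack
            assert abs(counts[mt] / n - expect) < max(5 * se, 0.02)


class TestAdjustedRates:
    def _cohort_records(self, p, seed, n_records=80_000, zero_effects=True,
                        lethal=True):
        cfg = tiny_population_config(p=p, n_offspring=150)
        cfg.repro.n_records = n_records
        if not lethal:
            cfg.deletion.lethality = {35: 0.0, 56: 0.0, 100: 0.0, 150: 0.0,
                                      "term": 0.0}
        if zero_effects:
            cfg.repro.parity_effect_sd = 0.0
            cfg.repro.month_effect_sd = 0.0
            cfg.repro.mgs_effect_sd = 0.0
        cohort = simpop.simulate_population(cfg, seed)
        ins = simpop.simulate_inseminations(cohort, cfg.repro, seed + 1)
        status = dict(zip(cohort.phased.animal_ids,
                          cohort.phased.deletion_copies >= 1))
        return lethality.classify_matings(ins, status)

    def test_harmless_deletion_rates_all_equal_background(self):
        # with the lethality schedule switched off, no mating type shows
        # extra failure
        annotated, _ = self._cohort_records(p=0.128, seed=81, lethal=False)
        adj = lethality.adjusted_failure_rates(annotated, 56)
        f = adj["background"].iloc[0]
        for _, row in adj.iterrows():
            se = np.sqrt(0.25 / row["n_records"])
            assert abs(row["adjusted_rate"] - f) < 3 * se

    def test_collapses_to_raw_means_without_covariate_variation(self):
        annotated, _ = self._cohort_records(p=0.128, seed=83,
                                            n_records=20_000)
        annotated["parity"] = 1
        annotated["month_year"] = 0
        adj = lethality.adjusted_failure_rates(annotated, 35, mgs_lambda=0.0)
        raw = annotated.groupby("mating_type")["failure_35"].mean()
        for _, row in adj.iterrows():
            assert row["adjusted_rate"] == pytest.approx(
                raw[row["mating_type"]], abs=1e-8)

    def test_type_iv_extra_rate_matches_closed_form(self):
        annotated, _ = self._cohort_records(p=0.128, seed=85,
                                            n_records=120_000,
                                            zero_effects=False)
        adj = lethality.adjusted_failure_rates(annotated, 150)
        row = adj[adj["mating_type"] == "IV"].iloc[0]
        expect = lethality.expected_extra_failure(
            "IV", 0.128, row["background"], 0.79)
        se = np.sqrt(0.25 / row["n_records"]) + np.sqrt(
            0.25 / adj[adj["mating_type"].isin(["I", "II"])]["n_records"].sum())
        assert row["extra_rate"] > 0
        assert abs(row["extra_rate"] - expect) < 3 * se

    def test_death_fraction_monotone_in_day_on_average(self):
        annotated, _ = self._cohort_records(p=0.128, seed=87,
                                            n_records=150_000)
        _, estimates = lethality.death_fraction_curve(annotated, p=0.128,
                                                      n_bootstrap=0)
        vals = [e.death_fraction for e in estimates]
        # noise allows small inversions; require a clearly increasing trend
        assert vals[-1] > vals[0]
        assert all(b > a - 0.12 for a, b in zip(vals, vals[1:]))


class TestAbsenceOfHomozygotes:
    def test_minimum_in_one_copy_regime_without_homozygotes(
            self, study_scale_cohort):
        d = study_scale_cohort.deletion
        rep = lethality.absence_of_homozygotes_summary(
            study_scale_cohort.array, (d.chromosome, d.start_bp, d.end_bp))
        assert rep["homozygote_free"]
        assert rep["min_mean_lrr"] > -2.5

    def test_planted_homozygote_flagged(self, study_scale_cohort):
        cohort = study_scale_cohort
        d = cohort.deletion
        arr = cohort.array
        lrr = arr.lrr.copy()
        mask = cohort.markers.in_interval(d.start_bp, d.end_bp)
        lrr[0, mask] = -5.0  # zero-copy intensity
        ds = simpop.ArrayDataset(arr.animal_ids, arr.markers, arr.calls,
                                 lrr, arr.quality)
        rep = lethality.absence_of_homozygotes_summary(
            ds, (d.chromosome, d.start_bp, d.end_bp))
        assert not rep["homozygote_free"]
        assert rep["minimum_regime"] == "zero-copy"

    def test_empty_region_rejected(self, study_scale_cohort):
        with pytest.raises(ValueError, match="no markers"):
            lethality.absence_of_homozygotes_summary(
                study_scale_cohort.array, ("12", 1, 2))
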