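"""Simulator invariants: reproducibility, Mendelian consistency, viability
selection, hemizygote masking, and the closed-form mating-type algebra."""

import numpy as np
import pandas as pd
import pytest

from lethalmap import simpop
from tests.conftest import tiny_population_config


def test_same_seed_reproduces_cohort_exactly():
    cfg = tiny_population_config()
    a = simpop.simulate_cohort_full(cfg, seed=5)
    b = simpop.simulate_cohort_full(cfg, seed=5)
    assert np.array_equal(a.phased.haplotypes, b.phased.haplotypes)
    assert np.array_equal(a.array.lrr, b.array.lrr)
    assert a.inseminations.table.equals(b.inseminations.table)
    assert a.traits.table.equals(b.traits.table)


def test_founder_only_cohort_has_binomial_carrier_fraction():
    p = 0.2
    cfg = tiny_population_config(p=p, n_offspring=0, n_founder_m=1500,
                                 n_founder_f=1500)
    cfg.n_generations = 0
    cohort = simpop.simulate_population(cfg, seed=11)
    copies = cohort.phased.deletion_copies
    # founders are drawn at allele frequency p with homozygotes rejected
    expect_carrier = 2 * p * (1 - p) / (1 - p * p)
    n = len(copies)
    se = np.sqrt(expect_carrier * (1 - expect_carrier) / n)
    assert abs((copies == 1).mean() - expect_carrier) < 3 * se
    assert (copies == 2).sum() == 0


def test_allele_frequency_recovered_from_many_founder_gametes():
    p = 0.128
    cfg = tiny_population_config(p=p, n_offspring=0, n_founder_m=12_500,
                                 n_founder_f=12_500, n_markers_50k=12)
    cfg.n_generations = 0
    cohort = simpop.simulate_population(cfg, seed=13)
    # count deletion alleles over 50,000 founder gametes before viability
    # selection is not observable; among live animals the expectation is
    # p/(1+p) per gamete
    freq_live = cohort.phased.del_flags.mean()
    expect = p / (1 + p)
    se = np.sqrt(expect * (1 - expect) / cohort.phased.del_flags.size)
    assert abs(freq_live - expect) < 3 * se


def test_no_live_homozygote_under_full_lethality(small_cohort):
    assert small_cohort.deletion.lethality["term"] == 1.0
    assert (small_cohort.phased.deletion_copies == 2).sum() == 0


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="frequency"):
        tiny_population_config(p=0.7)
    cfg = tiny_population_config()
    cfg.deletion.lethality = {35: 0.5, 56: 0.3, "term": 1.0}
    with pytest.raises(ValueError, match="monotone"):
        simpop.PopulationConfig(breeds=cfg.breeds, deletion=cfg.deletion)
    with pytest.raises(ValueError, match="breed"):
        simpop.PopulationConfig(breeds=[])


class TestGeneDrop:
    def _setup(self, n_markers=50, seed=0):
        rng = np.random.default_rng(seed)
        rows = [(1, 0, 0, "M", "X", 0), (2, 0, 0, "F", "X", 0)]
        rows += [(i, 1, 2, "M" if i % 2 else "F", "X", 1) for i in range(3, 103)]
        ped = simpop.Pedigree(pd.DataFrame(
            rows, columns=["animal_id", "sire_id", "dam_id", "sex", "breed",
                           "generation"]))
        pos = np.sort(rng.choice(np.arange(1, 10**8), size=n_markers,
                                 replace=False))
        markers = simpop.MarkerMap(pd.DataFrame({
            "marker_id": [f"m{i}" for i in range(n_markers)],
            "chromosome": "1", "position": pos, "panel": "50K",
            "allele_a": "A", "allele_b": "B"}))
        founders = {1: rng.integers(0, 2, (2, n_markers)).astype(np.uint8),
                    2: rng.integers(0, 2, (2, n_markers)).astype(np.uint8)}
        return ped, markers, founders

    def test_zero_recombination_copies_a_parental_haplotype(self):
        ped, markers, founders = self._setup()
        phased = simpop.gene_drop(ped, founders, markers, seed=1,
                                  cm_per_mb=0.0)
        parents = {1: founders[1], 2: founders[2]}
        for i, aid in enumerate(phased.animal_ids):
            if aid in (1, 2):
                continue
            for h, parent in ((0, parents[1]), (1, parents[2])):
                child = phased.haplotypes[i, h]
                assert (np.array_equal(child, parent[0])
                        or np.array_equal(child, parent[1]))

    def test_mean_crossover_count_matches_map_length(self):
        # 1 Morgan map; mean crossovers per meiosis should be ~1
        rng = np.random.default_rng(3)
        pos = np.array([1, 100_000_001])
        markers = simpop.MarkerMap(pd.DataFrame({
            "marker_id": ["a", "b"], "chromosome": "1", "position": pos,
            "panel": "50K", "allele_a": "A", "allele_b": "B"}))
        # haplotype identity switch between the two ends indicates an odd
        # number of crossovers; P(odd) = (1 - exp(-2L))/2 for Poisson(L=1)
        rows = [(1, 0, 0, "M", "X", 0), (2, 0, 0, "F", "X", 0)]
        rows += [(i, 1, 2, "M", "X", 1) for i in range(3, 5003)]
        ped = simpop.Pedigree(pd.DataFrame(
            rows, columns=["animal_id", "sire_id", "dam_id", "sex", "breed",
                           "generation"]))
        founders = {1: np.array([[0, 0], [1, 1]], dtype=np.uint8),
                    2: np.array([[0, 0], [1, 1]], dtype=np.uint8)}
        phased = simpop.gene_drop(ped, founders, markers, seed=4,
                                  cm_per_mb=1.0)
        kids = phased.haplotypes[2:]
        p_odd_obs = (kids[:, :, 0] != kids[:, :, 1]).mean()
        p_odd = (1 - np.exp(-2.0)) / 2
        se = np.sqrt(p_odd * (1 - p_odd) / (2 * 5000))
        assert abs(p_odd_obs - p_odd) < 3 * se

    def test_child_alleles_are_mendelian_consistent(self, small_cohort):
        ph = small_cohort.phased
        idx = {a: i for i, a in enumerate(ph.animal_ids)}
        t = small_cohort.pedigree.table
        kids = t[t["sire_id"] != simpop.UNKNOWN].head(50)
        for _, row in kids.iterrows():
            ci, si, di = (idx[row["animal_id"]], idx[row["sire_id"]],
                          idx[row["dam_id"]])
            for h, pi in ((0, si), (1, di)):
                child = ph.haplotypes[ci, h]
                par = ph.haplotypes[pi]
                assert np.all((child == par[0]) | (child == par[1]))

    def test_marker_map_mismatch_rejected(self):
        ped, markers, founders = self._setup()
        bad = {k: v[:, :-1] for k, v in founders.items()}
        with pytest.raises(ValueError, match="cover"):
            simpop.gene_drop(ped, bad, markers, seed=1)


class TestArraySignals:
    def test_carriers_never_called_heterozygous_in_deletion(self, small_cohort,
                                                            small_cohort_array):
        d = small_cohort.deletion
        mask = small_cohort.markers.in_interval(d.start_bp, d.end_bp)
        carriers = small_cohort.phased.deletion_copies == 1
        calls = small_cohort_array.calls[np.ix_(carriers, mask)]
        assert (calls == 1).sum() == 0

    def test_carrier_lrr_in_one_copy_regime(self):
        # with >= 50 in-deletion markers, every carrier's mean LRR sits in
        # the heterozygous-deletion band
        cfg = tiny_population_config(n_offspring=150, n_markers_50k=120,
                                     n_in_del=60)
        cohort = simpop.simulate_population(cfg, seed=77)
        arr = simpop.emit_array_signals(cohort.phased, cohort.markers,
                                        cohort.deletion, cfg.noise, seed=78)
        d = cohort.deletion
        mask = cohort.markers.in_interval(d.start_bp, d.end_bp)
        carriers = cohort.phased.deletion_copies == 1
        mean_lrr = arr.lrr[np.ix_(carriers, mask)].mean(axis=1)
        assert np.all(mean_lrr > -1.5) and np.all(mean_lrr < -0.3)

    def test_wild_type_lrr_centred_on_zero(self, small_cohort,
                                           small_cohort_array):
        d = small_cohort.deletion
        mask = small_cohort.markers.in_interval(d.start_bp, d.end_bp)
        wt = small_cohort.phased.deletion_copies == 0
        vals = small_cohort_array.lrr[np.ix_(wt, mask)]
        se = vals.std() / np.sqrt(vals.size)
        assert abs(vals.mean()) < 3 * se

    def test_heterozygosity_outside_deletion_unaffected(self, small_cohort,
                                                        small_cohort_array):
        d = small_cohort.deletion
        mask = ~small_cohort.markers.in_interval(d.start_bp, d.end_bp)
        carriers = small_cohort.phased.deletion_copies == 1
        wt = ~carriers
        het_c = (small_cohort_array.calls[np.ix_(carriers, mask)] == 1).mean()
        het_w = (small_cohort_array.calls[np.ix_(wt, mask)] == 1).mean()
        assert abs(het_c - het_w) < 0.02


class TestInseminations:
    def test_background_rates_recovered_without_deletion(self):
        cfg = tiny_population_config(p=0.0, n_offspring=100)
        cfg.repro.n_records = 60_000
        cfg.repro.parity_effect_sd = 0.0
        cfg.repro.month_effect_sd = 0.0
        cfg.repro.mgs_effect_sd = 0.0
        cohort = simpop.simulate_population(cfg, seed=21)
        ins = simpop.simulate_inseminations(cohort, cfg.repro, seed=22)
        rates = ins.failure_matrix().mean(axis=0)
        for got, want in zip(rates, (0.278, 0.396, 0.475, 0.493)):
            se = np.sqrt(want * (1 - want) / len(ins.table))
            assert abs(got - want) < 3 * se

    def test_failure_coding_is_cumulative(self, small_cohort):
        ins = simpop.simulate_inseminations(small_cohort,
                                            small_cohort.config.repro, seed=23)
        f = ins.failure_matrix()
        assert np.all(np.diff(f, axis=1) >= 0)

    def test_carrier_stratum_extra_failure_matches_closed_form(self):
        # carrier sire x daughter-of-carrier-MGS, full lethality by term:
        # extra failure at 150 d = delta(150) (1 - f150) 0.25 P_damcarrier
        cfg = tiny_population_config(p=0.128, n_offspring=200)
        cfg.repro.n_records = 100_000
        cfg.repro.parity_effect_sd = 0.0
        cfg.repro.month_effect_sd = 0.0
        cfg.repro.mgs_effect_sd = 0.0
        cohort = simpop.simulate_population(cfg, seed=31)
        ins = simpop.simulate_inseminations(cohort, cfg.repro, seed=32)
        tr = ins.truth
        iv = (tr["sire_copies"] >= 1) & (tr["mgs_copies"] >= 1)
        y150 = ins.table["failure_150"].to_numpy()
        bg = ins.table["failure_150"][(tr["sire_copies"] == 0)
                                      & (tr["mgs_copies"] == 0)].mean()
        extra = y150[iv].mean() - bg
        p = 0.128
        p_dam = 0.5 / (1 - 0.5 * p)
        expect = 0.79 * (1 - 0.493) * 0.25 * p_dam
        se = np.sqrt(0.25 / iv.sum()) + np.sqrt(0.25 / (~iv).sum())
        assert abs(extra - expect) < 3 * se

    def test_non_monotone_background_rejected(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            simpop.ReproConfig(background_failure={35: 0.3, 56: 0.2})


class TestTraitProofs:
    def test_zero_effect_gives_no_carrier_contrast(self, small_cohort):
        tc = simpop.TraitConfig(fertility_effect=0.0, milk_effect=0.0)
        tr = simpop.simulate_trait_proofs(small_cohort, tc, seed=41)
        milk = tr.trait("milk")
        copies = dict(zip(small_cohort.phased.animal_ids,
                          small_cohort.phased.deletion_copies))
        c = np.array([copies[a] for a in milk["animal_id"]])
        v = milk["value"].to_numpy()
        diff = v[c == 1].mean() - v[c == 0].mean()
        se = np.sqrt(v[c == 1].var() / max((c == 1).sum(), 1)
                     + v[c == 0].var() / max((c == 0).sum(), 1))
        assert abs(diff) < 3 * se

    def test_planted_milk_effect_recovered_by_regression(self):
        cfg = tiny_population_config(n_offspring=1700, n_markers_50k=12)
        cfg.traits.milk_effect = 0.3
        cohort = simpop.simulate_population(cfg, seed=42)
        tr = simpop.simulate_trait_proofs(cohort, cfg.traits, seed=43)
        milk = tr.trait("milk")
        copies = dict(zip(cohort.phased.animal_ids,
                          cohort.phased.deletion_copies))
        c = np.array([float(copies[a]) for a in milk["animal_id"]])
        v = milk["value"].to_numpy()
        X = np.column_stack([np.ones_like(c), c])
        beta, res_ss, *_ = np.linalg.lstsq(X, v, rcond=None)
        resid = v - X @ beta
        se = np.sqrt(resid.var() / ((c - c.mean()) ** 2).sum())
        assert abs(beta[1] - 0.3) < 3 * se

    def test_equal_reliabilities_give_equal_weights(self):
        from lethalmap.assoc import reliability_weights

        w = reliability_weights(np.full(10, 0.8))
        assert np.allclose(w, w[0])

    def test_fertility_index_is_weighted_component_sum(self, small_cohort):
        tr = simpop.simulate_trait_proofs(small_cohort,
                                          small_cohort.config.traits, seed=44)
        wide = tr.table.pivot(index="animal_id", columns="trait",
                              values="value")
        w = small_cohort.config.traits.index_weights
        recon = sum(w[t] * wide[t] for t in w)
        assert np.allclose(recon, wide["fertility_index"], atol=1e-10)
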