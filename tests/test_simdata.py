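"""Gene-drop simulator: structure, Mendelian transmission, liability model,
determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from famprs import scoring, simdata
from famprs.simdata import (
    SimConfig,
    check_mendelian,
    gene_drop,
    inject_lof,
    liability_status,
    liability_threshold,
    simulate_case_control,
    simulate_cohort,
    simulate_pedigrees,
)


def small_cfg(**kw):
    base = dict(n_families=20, n_prs_variants=30, or_per_sd=None, beta_prs=0.2,
                target_prevalence=0.1, n_lof_variants=5, seed=7)
    base.update(kw)
    return SimConfig(**base)


class TestPedigreeTemplate:
    def test_two_generation_trio(self):
        cfg = small_cfg(n_families=1, generations=2, sibship_sizes=(1,), sibship_probs=(1.0,))
        ped = simulate_pedigrees(cfg)
        assert len(ped) == 3
        assert len(ped.founders) == 2

    def test_default_template_structure(self):
        ped = simulate_pedigrees(small_cfg(n_families=100, seed=3))
        ped.validate()  # acyclic, consistent parent sexes
        for iid in ped.founders:
            assert ped.parents(iid) == (None, None)
        # every family contributes at least one female child
        for fam in ped.family_ids():
            assert any(
                ped[i].sex == "female" and not ped[i].is_founder
                for i in ped.family_members(fam)
            )

    def test_same_seed_same_structure(self):
        a = simulate_pedigrees(small_cfg(seed=9))
        b = simulate_pedigrees(small_cfg(seed=9))
        assert list(a.members) == list(b.members)
        for iid in a.members:
            assert a.parents(iid) == b.parents(iid)
            assert a[iid].age == b[iid].age

    def test_ages_follow_generation_bands(self):
        ped = simulate_pedigrees(small_cfg(n_families=50, seed=2))
        depths = ped._compute_depths()
        by_gen = {}
        for iid, m in ped.members.items():
            by_gen.setdefault(depths[iid], []).append(m.age)
        assert np.mean(by_gen[0]) > np.mean(by_gen[1]) > np.mean(by_gen[2])


class TestGeneDrop:
    def test_monomorphic_frequency_zero(self, ped7):
        rng = np.random.default_rng(1)
        panel = gene_drop(ped7, np.zeros(4), rng)
        assert (panel.dosages.to_numpy() == 0).all()

    def test_founder_dosage_mean_binomial(self):
        cfg = small_cfg(n_families=1, generations=2, sibship_sizes=(1,), sibship_probs=(1.0,))
        ped = simulate_pedigrees(cfg)
        rng = np.random.default_rng(4)
        n_var = 25_000  # many unlinked variants stand in for many founders
        panel = gene_drop(ped, np.full(n_var, 0.3), rng)
        founder_dos = panel.dosages.loc[ped.founders].to_numpy()
        se = np.sqrt(2 * 0.3 * 0.7 / founder_dos.size)
        assert abs(founder_dos.mean() - 0.6) < 3 * se

    def test_het_cross_segregation_ratios(self):
        """het x het parents give offspring dosages 0:1:2 at 1/4:1/2:1/4."""
        ped = simulate_pedigrees(
            small_cfg(n_families=1, generations=2, sibship_sizes=(1,), sibship_probs=(1.0,))
        )
        child = next(i for i in ped.members if not ped[i].is_founder)
        rng = np.random.default_rng(5)
        counts = np.zeros(3)
        n_drops, done = 10_000, 0
        while done < n_drops:
            panel = gene_drop(ped, np.full(64, 0.5), rng)
            d = panel.dosages
            for v in panel.variant_ids:
                fa, mo = ped.parents(child)
                if d.loc[fa, v] == 1 and d.loc[mo, v] == 1:
                    counts[int(d.loc[child, v])] += 1
                    done += 1
                    if done == n_drops:
                        break
        chi2, p = stats.chisquare(counts, n_drops * np.array([0.25, 0.5, 0.25]))
        assert p > 0.001

    def test_mendelian_consistency_exhaustive(self, sim_cohort):
        check_mendelian(sim_cohort.pedigree, sim_cohort.panel)
        check_mendelian(sim_cohort.pedigree, sim_cohort.lof_panel)

    def test_mendelian_checker_detects_violation(self, ped7):
        rng = np.random.default_rng(6)
        panel = gene_drop(ped7, np.full(3, 0.5), rng)
        bad = panel.dosages.copy()
        v = panel.variant_ids[0]
        bad.loc["A", v] = 2.0
        bad.loc[["GF", "GM"], v] = 0.0
        with pytest.raises(AssertionError, match="Mendelian"):
            check_mendelian(ped7, scoring.GenotypePanel(bad, panel.alleles))

    def test_single_known_parent_rejected(self, ped7):
        ped7["D1"].mother_id = None
        with pytest.raises(ValueError, match="one known parent"):
            gene_drop(ped7, np.full(2, 0.5), np.random.default_rng(0))


class TestLiabilityModel:
    def test_threshold_is_normal_quantile(self):
        assert liability_threshold(0.0122) == pytest.approx(stats.norm.isf(0.0122))

    def test_pure_noise_prevalence(self):
        rng = np.random.default_rng(10)
        n, K = 200_000, 0.0122
        zeros = np.zeros(n)
        _, hit = liability_status(zeros, zeros, 0.0, 0.0, K, rng)
        se = np.sqrt(K * (1 - K) / n)
        assert abs(hit.mean() - K) < 3 * se

    def test_positive_slope_separates_groups(self):
        rng = np.random.default_rng(11)
        n = 10_000
        z = rng.standard_normal(n)
        _, hit = liability_status(z, np.zeros(n), 0.4, 0.0, 0.1, rng)
        assert z[hit].mean() > z[~hit].mean()

    def test_overloaded_variance_rejected(self):
        rng = np.random.default_rng(12)
        with pytest.raises(ValueError, match="variance"):
            liability_status(np.zeros(5), np.zeros(5), 0.9, 0.5, 0.1, rng)

    def test_slope_calibration_hits_target_or(self):
        from famprs.cohort import fit_logistic

        b = simdata.liability_slope_for_or(1.24, 0.0122)
        rng = np.random.default_rng(13)
        z = rng.standard_normal(400_000)
        _, hit = liability_status(z, np.zeros(z.size), b, 0.0, 0.0122, rng)
        est = fit_logistic(z, hit.astype(int)).or_per_sd
        assert est == pytest.approx(1.24, abs=0.05)

    def test_case_control_sampler_counts(self):
        rng = np.random.default_rng(14)
        z, y = simulate_case_control(72, 2603, 1.24, rng)
        assert y.sum() == 72 and y.size == 2675


class TestCohortAssembly:
    def test_seed_determinism_bit_identical(self):
        a = simulate_cohort(small_cfg(seed=21))
        b = simulate_cohort(small_cfg(seed=21))
        pd.testing.assert_frame_equal(a.panel.dosages, b.panel.dosages)
        pd.testing.assert_frame_equal(a.roster, b.roster)
        pd.testing.assert_frame_equal(a.lof_annotations, b.lof_annotations)
        assert list(a.pedigree.members) == list(b.pedigree.members)

    def test_different_seeds_differ(self):
        a = simulate_cohort(small_cfg(seed=21))
        b = simulate_cohort(small_cfg(seed=22))
        assert not a.panel.dosages.equals(b.panel.dosages)

    def test_roster_flags_consistent(self, sim_cohort):
        roster = sim_cohort.roster
        cases = roster[roster.bc_status == "case"]
        assert (cases.sex == "female").all()
        assert cases.personal_history.all()
        assert (roster.loc[roster.sex == "male", "bc_status"] == "ineligible").all()
        # family history flags every member of a family with another case
        fam_cases = roster.groupby("family_id")["personal_history"].sum()
        for _, row in roster.iterrows():
            expect = fam_cases[row.family_id] - int(row.personal_history) > 0
            assert row.family_history == expect

    def test_lof_injection_bounds_and_count(self, sim_cohort):
        ann = sim_cohort.lof_annotations
        cfg = sim_cohort.config
        assert len(ann) == cfg.n_lof_variants
        lo, hi = cfg.lof_freq_range
        assert ((ann["af"] >= lo) & (ann["af"] <= hi)).all()
        from famprs.monogenic import LOF_CLASSES

        assert set(ann["consequence"]) <= LOF_CLASSES
        assert set(ann["gene"]) <= set(simdata.CANDIDATE_GENES)

    def test_affection_matches_liability_rule_exactly(self, sim_cohort):
        thr = liability_threshold(sim_cohort.config.target_prevalence)
        roster = sim_cohort.roster.set_index("sample_id")
        liab = sim_cohort.truth["liability"]
        for iid, row in roster.iterrows():
            if row.sex == "female":
                assert (row.bc_status == "case") == (liab[iid] > thr)

    def test_written_files_roundtrip_through_loaders(self, tmp_path):
        sim = simulate_cohort(small_cfg(seed=30))
        paths = sim.write(tmp_path)
        sf = scoring.load_score_file(paths["weights"])
        assert sf.variant_ids == sim.score.variant_ids
        panel = scoring.GenotypePanel.from_dosage_tsv(paths["dosages"], paths["variants"])
        pd.testing.assert_frame_equal(panel.dosages, sim.panel.dosages)
        from famprs.pedigree import parse_pedigree

        ped = parse_pedigree(paths["fam"], roster=pd.read_csv(paths["roster"], sep="\t"))
        assert list(ped.members) == list(sim.pedigree.members)
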