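"""Synthetic-data generator: determinism, ground-truth consistency, fixture."""

import math

import numpy as np
import pytest

from kinsites.extract import aggregate_sites, filter_sites
from kinsites.motifs import assign_category, tally_categories
from kinsites.differential import LOST_OR_REDUCED, differential_table
from kinsites.simulate import (
    GenerationError,
    SimConfig,
    TABLE1_LOST_OR_REDUCED,
    TABLE1_ROWS,
    simulate,
    table1_fixture,
)


class TestDeterminism:
    def test_identical_config_identical_outputs(self, tmp_path):
        config = SimConfig(seed=11, n_proteins=5, n_sites={"Mps1": 3, "Other": 2},
                           n_decoy_lowpsm=1, n_decoy_lowconf=1)
        a, b = simulate(config), simulate(config)
        assert a.proteins.sequences == b.proteins.sequences
        assert a.psm_tables == b.psm_tables
        assert a.ground_truth == b.ground_truth
        assert a.known_sites == b.known_sites
        # byte-identical files too
        a.write(tmp_path / "a")
        b.write(tmp_path / "b")
        for name in sorted(p.name for p in (tmp_path / "a").iterdir()):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_different_seeds_differ(self):
        a = simulate(SimConfig(seed=1, n_proteins=4, n_sites={"Mps1": 2}))
        b = simulate(SimConfig(seed=2, n_proteins=4, n_sites={"Mps1": 2}))
        assert a.proteins.sequences != b.proteins.sequences


class TestGroundTruthConsistency:
    def test_planted_counts_match_aggregation(self, small_sim):
        sites, skipped = aggregate_sites(small_sim.all_records(), small_sim.proteins)
        assert not skipped
        by_key = {(s.protein_id, s.protein_pos): s for s in sites}
        for truth in small_sim.ground_truth:
            key = (truth.protein_id, truth.position)
            total_phospho = truth.wt_phospho + truth.mut_phospho
            if total_phospho == 0:
                assert key not in by_key
                continue
            site = by_key[key]
            wt = site.evidence.get("wt")
            mut = site.evidence.get("mut")
            assert (truth.wt_phospho, truth.wt_total) == (
                (wt.phospho_psms, wt.total_psms) if wt else (0, 0)
            )
            assert (truth.mut_phospho, truth.mut_total) == (
                (mut.phospho_psms, mut.total_psms) if mut else (0, 0)
            )

    def test_planted_class_recovery_exact_at_full_occupancy(self):
        """occupancy 1, no decoys: extraction + assignment recovers every
        planted site that passes the filter with its planted category."""
        for seed in (0, 5, 9):
            config = SimConfig(
                seed=seed, n_proteins=8, protein_length=(150, 400),
                n_sites={"Mps1": 4, "Ipl1": 3, "Cdk1": 2, "Other": 1},
                occupancy_wt=1.0, occupancy_mut_dependent=1.0,
                occupancy_mut_independent=1.0,
                n_decoy_lowpsm=0, n_decoy_lowconf=0,
            )
            ds = simulate(config)
            sites, _ = aggregate_sites(ds.all_records(), ds.proteins)
            kept = filter_sites(sites)
            expected = {
                (s.protein_id, s.position): s.category
                for s in ds.ground_truth
                if s.should_pass_filter
            }
            observed = {
                (s.protein_id, s.protein_pos): assign_category(s.context).category
                for s in kept
            }
            assert observed == expected
            tally = tally_categories([assign_category(s.context) for s in kept])
            planted_tally = {"Mps1": 4, "Ipl1": 3, "Cdk1": 2, "Other": 1}
            for cat, n in planted_tally.items():
                assert tally[cat] == sum(
                    1 for k, c in expected.items() if c == cat
                ) == n

    def test_filter_specificity(self, small_sim):
        """Every decoy is removed by the default thresholds; every site
        labelled passing is retained."""
        sites, _ = aggregate_sites(small_sim.all_records(), small_sim.proteins)
        kept_keys = {(s.protein_id, s.protein_pos) for s in filter_sites(sites)}
        for truth in small_sim.ground_truth:
            key = (truth.protein_id, truth.position)
            if truth.is_decoy:
                assert key not in kept_keys
            assert (key in kept_keys) == truth.should_pass_filter

    def test_fraction_recovery(self):
        """Mean wildtype phospho fraction converges to the configured
        occupancy (within 3 standard errors)."""
        config = SimConfig(
            seed=13, n_proteins=20, protein_length=(300, 700),
            n_sites={"Other": 120}, coverage_lambda=40.0,
            occupancy_wt=0.3, n_decoy_lowpsm=0, n_decoy_lowconf=0,
        )
        ds = simulate(config)
        fractions = [
            s.wt_phospho / s.wt_total for s in ds.ground_truth if s.wt_total > 0
        ]
        mean = float(np.mean(fractions))
        se = float(np.std(fractions, ddof=1) / math.sqrt(len(fractions)))
        assert abs(mean - config.occupancy_wt) <= 3 * se

    def test_dependent_sites_lose_occupancy(self):
        config = SimConfig(
            seed=21, n_proteins=12, n_sites={"Mps1": 15, "Other": 10},
            coverage_lambda=20.0, occupancy_wt=0.5,
            occupancy_mut_dependent=0.0, occupancy_mut_independent=0.5,
            n_decoy_lowpsm=0, n_decoy_lowconf=0,
        )
        ds = simulate(config)
        sites, _ = aggregate_sites(ds.all_records(), ds.proteins)
        results = differential_table(sites, "wt", "mut", min_wt_total=1)
        by_key = {(r.site.protein_id, r.site.protein_pos): r.status for r in results}
        dependent = [s for s in ds.ground_truth if s.mps1_dependent]
        assert dependent
        flagged = sum(
            1
            for s in dependent
            if s.wt_phospho > 0
            and by_key.get((s.protein_id, s.position)) == LOST_OR_REDUCED
        )
        detectable = sum(1 for s in dependent if s.wt_phospho > 0)
        assert flagged == detectable  # mutant occupancy is exactly zero


class TestValidation:
    def test_too_many_sites_is_generation_error(self):
        with pytest.raises(GenerationError):
            simulate(SimConfig(seed=0, n_proteins=1, protein_length=(60, 60),
                               n_sites={"Mps1": 50}))

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(occupancy_wt=1.5)

    def test_unsupported_category_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_sites={"Cdc5": 3})


class TestTable1Fixture:
    def test_reproduces_all_printed_count_pairs(self, table1):
        by_key = {(s.protein_id, s.protein_pos): s for s in table1["sites"]}
        assert len(by_key) == 12
        for (protein, residue, pos, wt, mut, _lost, _primed) in TABLE1_ROWS:
            site = by_key[(protein, pos)]
            assert site.residue == residue
            wt_ev = site.evidence.get("wt")
            assert (wt_ev.phospho_psms, wt_ev.total_psms) == wt
            mut_ev = site.evidence.get("mut")
            if mut is None:
                assert mut_ev is None  # "no PSMs"
            else:
                assert (mut_ev.phospho_psms, mut_ev.total_psms) == mut

    def test_partition_matches_bold_typography(self, table1):
        results = differential_table(table1["sites"], "wt", "mut")
        lost = {
            (r.site.protein_id, r.site.protein_pos)
            for r in results
            if r.status == LOST_OR_REDUCED
        }
        assert lost == set(TABLE1_LOST_OR_REDUCED) and len(results) == 12

    def test_sites_fit_mps1_motif_strict_or_primed(self, table1):
        for site in table1["sites"]:
            a = assign_category(site.context)
            assert a.category == "Mps1" or a.mps1_primed, site.label

    def test_fixture_idempotent(self):
        p1, t1, s1 = table1_fixture()
        p2, t2, s2 = table1_fixture()
        assert p1.sequences == p2.sequences and t1 == t2 and s1 == s2

    def test_all_fixture_sites_pass_default_filter(self, table1):
        assert len(filter_sites(table1["sites"])) == 12
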