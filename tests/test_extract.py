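"""Peptide-to-protein mapping, site aggregation, filtering and novelty."""

import pytest
from hypothesis import given, settings, strategies as st

from kinsites.extract import (
    FilterThresholds,
    PhosphoSite,
    SampleEvidence,
    aggregate_sites,
    annotate_known,
    extract_context,
    filter_sites,
    map_peptide,
)
from kinsites.io import KnownSiteList, PhosphoMod, ProteinDb, PsmRecord

IMMUNOGEN = "INQNTQEITILSQP"


class TestMapPeptide:
    def test_immunogen_peptide_centers_thr248(self):
        """The anti-pT248 immunogen peptide maps so that its 5th residue is
        protein position 248."""
        protein = "A" * 243 + IMMUNOGEN + "A" * 20
        offsets = map_peptide(IMMUNOGEN, protein)
        assert offsets == [244]
        assert offsets[0] + 5 - 1 == 248
        assert protein[247] == "T" and protein[251] == "T"  # T248, T252

    def test_whole_protein_maps_at_one(self):
        assert map_peptide("MKTAY", "MKTAY") == [1]

    def test_overlapping_matches(self):
        assert map_peptide("AAA", "AAAA") == [1, 2]

    def test_no_match_is_empty(self):
        assert map_peptide("WWW", "MKTAY") == []

    @given(st.text(alphabet="AC", min_size=1, max_size=6),
           st.text(alphabet="AC", min_size=1, max_size=30))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_scan(self, peptide, protein):
        brute = [
            i + 1
            for i in range(len(protein) - len(peptide) + 1)
            if protein[i : i + len(peptide)] == peptide
        ]
        assert map_peptide(peptide, protein) == brute


class TestContext:
    def test_window_and_padding(self):
        assert extract_context("MKTAY", 1, 2) == "--MKT"
        assert extract_context("MKTAY", 3, 2) == "MKTAY"
        assert extract_context("MKTAY", 5, 2) == "TAY--"

    def test_stripped_context_is_substring(self, small_sim):
        from kinsites.extract import aggregate_sites

        sites, _ = aggregate_sites(small_sim.all_records(), small_sim.proteins)
        for site in sites:
            core = site.context.strip("-")
            assert core in small_sim.proteins[site.protein_id]
            center = len(site.context) // 2
            assert site.context[center] == site.residue


def _rec(sample, protein, peptide, mods=()):
    return PsmRecord(sample, protein, peptide, tuple(mods))


class TestAggregate:
    def test_phospho_and_covering_counts(self):
        """2 phospho PSMs + 9 plain covering PSMs -> evidence (2, 11)."""
        db = ProteinDb({"P1": "MKTAYQRSVWLN"})
        peptide = "TAYQRSV"  # starts at protein position 3
        recs = [
            _rec("wt", "P1", peptide, [PhosphoMod(6, "S", 95.0)]),
            _rec("wt", "P1", peptide, [PhosphoMod(6, "S", 91.0)]),
        ] + [_rec("wt", "P1", peptide) for _ in range(9)]
        sites, skipped = aggregate_sites(recs, db)
        assert not skipped
        (site,) = sites
        assert (site.protein_pos, site.residue) == (8, "S")
        assert site.evidence["wt"] == SampleEvidence(2, 11, 95.0)

    def test_no_records_no_sites(self):
        db = ProteinDb({"P1": "MKT"})
        assert aggregate_sites([], db) == ([], [])

    def test_overlapping_peptides_sum_evidence(self):
        """The same site seen via two different peptides pools its counts."""
        db = ProteinDb({"P1": "MKTAYQRSVWLN"})
        pep_a, pep_b = "TAYQRSV", "YQRSVWLN"  # both cover S at position 8
        recs = [
            _rec("wt", "P1", pep_a, [PhosphoMod(6, "S", 90.0)]),
            _rec("wt", "P1", pep_b, [PhosphoMod(4, "S", 97.0)]),
            _rec("wt", "P1", pep_a),
            _rec("wt", "P1", pep_b),
        ]
        sites, _ = aggregate_sites(recs, db)
        (site,) = sites
        assert site.evidence["wt"] == SampleEvidence(2, 4, 97.0)

    def test_ambiguous_and_unmapped_peptides_excluded(self):
        db = ProteinDb({"P1": "TATATAY"})
        recs = [
            _rec("wt", "P1", "TAT", [PhosphoMod(1, "T", 99.0)]),  # maps twice
            _rec("wt", "P1", "WWW"),  # maps nowhere
        ]
        sites, skipped = aggregate_sites(recs, db)
        assert sites == []
        assert sorted(s.reason for s in skipped) == ["ambiguous", "unmapped"]
        assert skipped[0].n_matches == 2

    def test_unknown_protein_is_hard_error_listing_offenders(self):
        db = ProteinDb({"P1": "MKT"})
        recs = [_rec("wt", "P9", "MKT"), _rec("wt", "P8", "MKT")]
        with pytest.raises(KeyError, match=r"P8.*P9"):
            aggregate_sites(recs, db)

    def test_phospho_count_conservation(self, small_sim):
        """Per sample+protein, summed site phospho counts equal the number of
        unambiguously mapped phospho-mod occurrences."""
        records = small_sim.all_records()
        sites, skipped = aggregate_sites(records, small_sim.proteins)
        skipped_ids = {id(s.record) for s in skipped}
        expected: dict[tuple[str, str], int] = {}
        for rec in records:
            if id(rec) in skipped_ids:
                continue
            key = (rec.sample_id, rec.protein_id)
            expected[key] = expected.get(key, 0) + len(rec.phospho_mods)
        observed: dict[tuple[str, str], int] = {}
        for site in sites:
            for sample, ev in site.evidence.items():
                key = (sample, site.protein_id)
                observed[key] = observed.get(key, 0) + ev.phospho_psms
        assert {k: v for k, v in expected.items() if v} == {
            k: v for k, v in observed.items() if v
        }


def _site(phospho, total, conf, pos=10):
    return PhosphoSite(
        protein_id="P1", protein_pos=pos, residue="S", context="AAAAASAAAAA",
        evidence={"wt": SampleEvidence(phospho, total, conf)},
    )


class TestFilter:
    def test_inclusion_rule(self):
        assert filter_sites([_site(2, 5, 80.0)]) != []
        assert filter_sites([_site(1, 5, 99.0)]) == []  # below PSM floor
        assert filter_sites([_site(3, 5, 74.9)]) == []  # below confidence floor

    def test_thresholds_apply_jointly_per_sample(self):
        site = PhosphoSite(
            protein_id="P1", protein_pos=10, residue="S", context="AAAAASAAAAA",
            evidence={
                "a": SampleEvidence(5, 8, 60.0),   # enough PSMs, low confidence
                "b": SampleEvidence(1, 8, 99.0),   # confident, single PSM
            },
        )
        assert filter_sites([site]) == []

    def test_planted_pass_fail_labels(self, small_sim):
        sites, _ = aggregate_sites(small_sim.all_records(), small_sim.proteins)
        kept = filter_sites(sites)
        expected = {
            (s.protein_id, s.position)
            for s in small_sim.ground_truth
            if s.should_pass_filter
        }
        assert {(s.protein_id, s.protein_pos) for s in kept} == expected
        assert not any(
            (s.protein_id, s.position) in {(k.protein_id, k.protein_pos) for k in kept}
            for s in small_sim.ground_truth
            if s.is_decoy
        )

    @given(
        psms=st.lists(st.integers(0, 6), min_size=1, max_size=8),
        confs=st.lists(st.floats(0, 100, allow_nan=False), min_size=8, max_size=8),
        min_psms=st.integers(1, 5),
        min_conf=st.floats(0, 100, allow_nan=False),
    )
    @settings(max_examples=150, deadline=None)
    def test_filter_monotonicity(self, psms, confs, min_psms, min_conf):
        """Raising either threshold never increases the retained count."""
        sites = [
            _site(p, p + 2, c, pos=i + 1)
            for i, (p, c) in enumerate(zip(psms, confs))
        ]
        base = FilterThresholds(min_psms=min_psms, min_confidence=min_conf)
        n_base = len(filter_sites(sites, base))
        stricter_psms = FilterThresholds(min_psms=min_psms + 1, min_confidence=min_conf)
        stricter_conf = FilterThresholds(
            min_psms=min_psms, min_confidence=min(100.0, min_conf + 5.0)
        )
        assert len(filter_sites(sites, stricter_psms)) <= n_base
        assert len(filter_sites(sites, stricter_conf)) <= n_base

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            FilterThresholds(min_psms=0)
        with pytest.raises(ValueError):
            FilterThresholds(min_confidence=101.0)


class TestAnnotateKnown:
    def test_empty_list_all_novel(self):
        sites = [_site(2, 4, 90.0)]
        assert annotate_known(sites, KnownSiteList()) == [False]

    def test_listed_site_flagged_known(self):
        sites = [_site(2, 4, 90.0)]
        known = KnownSiteList(frozenset({("P1", 10, "S")}))
        assert annotate_known(sites, known) == [True]

    def test_planted_known_flags(self, small_sim):
        sites, _ = aggregate_sites(small_sim.all_records(), small_sim.proteins)
        flags = annotate_known(sites, small_sim.known_sites)
        expected_known = {
            (s.protein_id, s.position) for s in small_sim.ground_truth if s.known
        }
        observed_known = {
            (s.protein_id, s.protein_pos)
            for s, f in zip(sites, flags)
            if f
        }
        # every planted-known site that produced any phospho evidence is flagged
        detected = {(s.protein_id, s.protein_pos) for s in sites}
        assert observed_known == expected_known & detected
        assert len(expected_known) == sum(1 for s in small_sim.ground_truth if s.known)
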