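"""Arm matching, pair consensus, repeat measurement, and profiling."""

import random

import pytest

import smmip_msi as sm
from smmip_msi.extraction import (
    MASK,
    ArmMatcher,
    annotate_insert,
    consensus_insert,
    revcomp,
)

from conftest import build_pair


def _sub(seq, pos, base=None):
    alternatives = [b for b in "ACGT" if b != seq[pos]]
    return seq[:pos] + (base or alternatives[0]) + seq[pos + 1 :]


class TestArmMatching:
    def test_exact_arms_assign_with_umi(self, fixture_panel):
        m3 = fixture_panel.markers[2]
        r1, r2 = build_pair(m3, umi="ACGTTG")
        name, umi, f1, f2 = ArmMatcher(fixture_panel).match(r1, r2)
        assert (name, umi) == (m3.name, "ACGTTG")
        assert f1 == f2  # error-free pair agrees everywhere

    def test_swapped_reads_still_assign(self, fixture_panel):
        m = fixture_panel.markers[1]
        r1, r2 = build_pair(m)
        name, umi, _, _ = ArmMatcher(fixture_panel).match(r2, r1)
        assert name == m.name

    def test_unrelated_sequence_unassigned(self, fixture_panel):
        rng = random.Random(3)
        junk = "".join(rng.choice("ACGT") for _ in range(100))
        assert ArmMatcher(fixture_panel).match(junk, revcomp(junk)) == "unassigned"

    def test_single_substitution_matches_nearest_marker(self, fixture_panel):
        # oracle: exhaustive hamming scan over every arm of every marker
        def oracle(r1, r2):
            best = []
            for m in fixture_panel.markers:
                d1 = sum(
                    a != b
                    for a, b in zip(r1[m.umi_length :], m.extension_arm)
                )
                d2 = sum(a != b for a, b in zip(r2, revcomp(m.ligation_arm)))
                if d1 <= 1 and d2 <= 1:
                    best.append((d1 + d2, m.name))
            best.sort()
            return best[0][1] if best else None

        matcher = ArmMatcher(fixture_panel)
        for m in fixture_panel.markers:
            r1, r2 = build_pair(m)
            # one substitution inside the ligation-arm portion of read 2
            r2_mut = _sub(r2, 3)
            hit = matcher.match(r1, r2_mut)
            assert hit[0] == oracle(r1, r2_mut) == m.name

    def test_two_arm_errors_unassigned(self, fixture_panel):
        m = fixture_panel.markers[0]
        r1, r2 = build_pair(m)
        r2_mut = _sub(_sub(r2, 2), 5)
        assert ArmMatcher(fixture_panel).match(r1, r2_mut) == "unassigned"


class TestConsensus:
    def test_identical_reads_unmasked(self):
        assert consensus_insert("ACGTACGT", "ACGTACGT") == "ACGTACGT"

    def test_single_disagreement_masked(self):
        cons = consensus_insert("ACGTACGT", "ACGAACGT")
        assert cons == "ACG" + MASK + "ACGT"

    def test_orientation_symmetry(self, fixture_panel):
        # agreement computed after reorientation equals forward/forward
        m = fixture_panel.markers[0]
        r1, r2 = build_pair(m)
        matcher = ArmMatcher(fixture_panel)
        _, _, f1, f2 = matcher.match(r1, r2)
        assert consensus_insert(f1, f2) == consensus_insert(f1, f1)

    def test_length_mismatch_discarded(self):
        assert consensus_insert("ACGT", "ACG") is None
        assert consensus_insert("", "ACGT") is None


class TestAnnotate:
    def test_reference_length_and_snp(self, marker):
        cons = marker.reference_insert
        length, allele = annotate_insert(cons, marker)
        assert length == marker.reference_repeat_length
        assert allele == "ref"

    def test_one_bp_deletion(self, marker):
        from smmip_msi.simulate import _marker_insert

        cons = _marker_insert(marker, "alt", 1)
        length, allele = annotate_insert(cons, marker)
        assert length == marker.reference_repeat_length - 1
        assert allele == "alt"

    def test_interrupted_tract_unmeasurable(self, marker):
        rs, _ = marker.repeat_span
        other = "G" if marker.repeat_unit != "G" else "C"
        cons = _sub(marker.reference_insert, rs + 2, other)
        length, _ = annotate_insert(cons, marker)
        assert length is None

    def test_masked_tract_base_unmeasurable(self, marker):
        rs, _ = marker.repeat_span
        cons = (
            marker.reference_insert[: rs + 1]
            + MASK
            + marker.reference_insert[rs + 2 :]
        )
        assert annotate_insert(cons, marker)[0] is None

    def test_masked_snp_uncalled(self, marker):
        cons = (
            marker.reference_insert[: marker.snp_offset]
            + MASK
            + marker.reference_insert[marker.snp_offset + 1 :]
        )
        assert annotate_insert(cons, marker)[1] == "uncalled"

    def test_chimeric_overlong_repeat_excluded(self, marker):
        rs, _ = marker.repeat_span
        cons = (
            marker.reference_insert[:rs]
            + marker.repeat_unit * (marker.reference_repeat_length + 11)
            + marker.reference_insert[marker.repeat_span[1] :]
        )
        assert annotate_insert(cons, marker)[0] is None

    def test_insertion_measured(self, marker):
        rs, re_ = marker.repeat_span
        cons = (
            marker.reference_insert[:rs]
            + marker.repeat_unit * (marker.reference_repeat_length + 1)
            + marker.reference_insert[re_:]
        )
        assert annotate_insert(cons, marker)[0] == marker.reference_repeat_length + 1


class TestProfiling:
    def test_conservation_invariants(self, small_cohort):
        panel = small_cohort["panel"]
        sid = "MSS_001"
        records = small_cohort["records"][sid]
        profiles = sm.profiles_from_records(records, panel)
        for name, prof in profiles.items():
            assert prof.measured_pairs + prof.pairs_discarded == prof.total_pairs_assigned
            table_total = sum(sum(row) for row in prof.allele_deletion_table)
            assert table_total <= prof.measured_pairs
            assert prof.distinct_umi_count <= prof.total_pairs_assigned

    def test_error_free_mss_has_zero_deletions(self, fixture_panel):
        cfg = sm.SyntheticCohortConfig(
            seed=7,
            n_mss=1,
            panel=fixture_panel,
            base_error=0.0,
            stutter_range=(0.0, 0.0),
            poisson_reads=False,
        )
        panel, reads, truth = sm.generate_cohort(cfg)
        sr = sm.extract_read_pairs(reads["MSS_001"], panel)
        profiles = sm.profiles_from_records(sr.records, panel)
        for m in panel.markers:
            prof = profiles[m.name]
            assert prof.length_histogram == {
                m.reference_repeat_length: prof.measured_pairs
            }
            assert sm.deletion_frequency(
                prof.length_histogram, m.reference_repeat_length
            ) == 0.0

    def test_configured_deletion_rate_recovered(self, fixture_panel):
        # ~30% of templates carry a deletion: measured frequency within
        # binomial error of the generated truth
        cfg = sm.SyntheticCohortConfig(
            seed=13,
            n_msih=1,
            panel=fixture_panel,
            mutant_fraction_range=(0.3, 0.3),
            tumor_content_range=(1.0, 1.0),
            stutter_range=(0.0, 0.0),
            base_error=0.0,
            poisson_reads=False,
        )
        panel, reads, truth = sm.generate_cohort(cfg)
        sr = sm.extract_read_pairs(reads["MSIH_001"], panel)
        profiles = sm.profiles_from_records(sr.records, panel)
        for m in panel.markers:
            row = truth.marker_truth.query(f"marker == '{m.name}'").iloc[0]
            expected = row.n_mutant_templates / row.n_templates
            d = sm.deletion_frequency(
                profiles[m.name].length_histogram, m.reference_repeat_length
            )
            assert d == pytest.approx(expected, abs=1e-9)

    def test_umi_census_matches_truth(self, fixture_panel):
        cfg = sm.SyntheticCohortConfig(
            seed=23,
            n_mss=1,
            panel=fixture_panel,
            base_error=0.0,
            templates_per_marker=80,
            reads_per_template=3,
            poisson_reads=False,
        )
        panel, reads, truth = sm.generate_cohort(cfg)
        sr = sm.extract_read_pairs(reads["MSS_001"], panel)
        profiles = sm.profiles_from_records(sr.records, panel)
        for m in panel.markers:
            assert profiles[m.name].distinct_umi_count == 80
            assert profiles[m.name].total_pairs_assigned == 240

    def test_read_order_permutation_invariant(self, fixture_panel):
        cfg = sm.SyntheticCohortConfig(seed=5, n_msih=1, panel=fixture_panel,
                                       templates_per_marker=40)
        panel, reads, _ = sm.generate_cohort(cfg)
        pairs = reads["MSIH_001"]
        shuffled = list(pairs)
        random.Random(0).shuffle(shuffled)
        p1 = sm.profiles_from_records(
            sm.extract_read_pairs(pairs, panel).records, panel
        )
        p2 = sm.profiles_from_records(
            sm.extract_read_pairs(shuffled, panel).records, panel
        )
        assert p1 == p2

    def test_counter_conservation(self, small_cohort):
        panel = small_cohort["panel"]
        cfg = sm.SyntheticCohortConfig(seed=9, n_mss=1, panel=panel,
                                       templates_per_marker=30)
        _, reads, _ = sm.generate_cohort(cfg)
        sr = sm.extract_read_pairs(reads["MSS_001"], panel)
        c = sr.counters
        assert c.assigned + c.unassigned + c.ambiguous == c.total_pairs


class TestProfileFiles:
    def test_tsv_round_trip(self, small_cohort, tmp_path):
        panel = small_cohort["panel"]
        records = small_cohort["records"]["MSIH_001"]
        profiles = sm.profiles_from_records(records, panel)
        path = tmp_path / "s.profile.tsv"
        sm.write_profiles(profiles, path)
        loaded, braf = sm.read_profiles(path)
        assert loaded == profiles
        assert braf is None

    def test_fastq_round_trip(self, fixture_panel, tmp_path):
        from smmip_msi.extraction import iter_fastq_pairs
        from smmip_msi.simulate import write_fastq_pair

        cfg = sm.SyntheticCohortConfig(seed=4, n_mss=1, panel=fixture_panel,
                                       templates_per_marker=20)
        panel, reads, _ = sm.generate_cohort(cfg)
        pairs = reads["MSS_001"]
        p1, p2 = write_fastq_pair(pairs, tmp_path, "MSS_001", gz=True)
        back = list(iter_fastq_pairs(p1, p2))
        assert back == pairs

    def test_empty_fastq_gives_zero_profiles(self, fixture_panel, tmp_path):
        f1 = tmp_path / "e_R1.fastq"
        f2 = tmp_path / "e_R2.fastq"
        f1.write_text("")
        f2.write_text("")
        profiles, sr = sm.profile_sample(f1, f2, fixture_panel)
        assert all(p.total_pairs_assigned == 0 for p in profiles.values())
        assert sr.counters.total_pairs == 0
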