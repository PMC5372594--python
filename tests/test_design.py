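"""Analog enumeration, resistance validation, binding-energy screening."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from cleavemap.datasets import (
    analog_records,
    analog_sequences,
    candidate_sites_extended,
    candidate_sites_top3,
    ex4c as load_ex4c,
)
from cleavemap.design import (
    AnalogRecord,
    SiteSubstitutionCandidates,
    SubstitutionCandidate,
    enumerate_analogs,
    select_by_binding_energy,
    validate_resistance,
)
from cleavemap.digestion import TRYPSIN, find_cleavage_sites
from cleavemap.peptide import parse_peptide

TSME1_SEQ = "HGEGTFTSDLSMQMEEEAVLLFIEWLMNGGPSSGAPPPSC"


class TestEnumerate:
    def test_top3_sets_give_27_analogs_including_tsme1(self, ex4c):
        analogs = enumerate_analogs(ex4c, candidate_sites_top3())
        assert len(analogs) == 27  # 3 x 3 x 3
        assert TSME1_SEQ in {a.sequence.to_string() for a in analogs}

    def test_extended_sets_contain_all_l_type_analogs(self, ex4c):
        analogs = enumerate_analogs(ex4c, candidate_sites_extended())
        assert len(analogs) == 48  # 3 x 4 x 4
        produced = {a.sequence.to_string() for a in analogs}
        for name, seq in analog_sequences().items():
            if name.startswith("TSME") and int(name.split("-")[1]) <= 6:
                assert seq.to_string() in produced, name

    def test_single_site_single_candidate(self):
        base = parse_peptide("AKA")
        analogs = enumerate_analogs(
            base, SiteSubstitutionCandidates.from_simple({2: ["M"]})
        )
        assert len(analogs) == 1
        assert analogs[0].sequence.to_string() == "AMA"
        assert analogs[0].substitutions == {2: ("K", "M", False)}

    def test_d_candidates_serialize_lowercase(self):
        base = parse_peptide("AKA")
        analogs = enumerate_analogs(
            base, SiteSubstitutionCandidates.from_simple({2: ["v"]})
        )
        assert analogs[0].sequence.to_string() == "AvA"

    def test_invalid_position_rejected(self):
        base = parse_peptide("AKA")
        with pytest.raises(ValueError):
            enumerate_analogs(
                base, SiteSubstitutionCandidates.from_simple({5: ["M"]})
            )

    def test_identity_substitution_rejected(self):
        base = parse_peptide("AKA")
        with pytest.raises(ValueError):
            enumerate_analogs(
                base, SiteSubstitutionCandidates.from_simple({2: ["K"]})
            )

    @settings(max_examples=50, deadline=None)
    @given(data=st.data())
    def test_count_is_product_of_set_sizes(self, data):
        base = parse_peptide("GAVLKTSERW")
        positions = data.draw(
            st.lists(st.integers(1, 10), min_size=1, max_size=3, unique=True)
        )
        mapping = {}
        for pos in positions:
            options = [aa for aa in "MFYIVW" if aa != base.residue(pos)]
            mapping[pos] = data.draw(
                st.lists(st.sampled_from(options), min_size=1, max_size=4, unique=True)
            )
        analogs = enumerate_analogs(
            base, SiteSubstitutionCandidates.from_simple(mapping)
        )
        assert len(analogs) == math.prod(len(v) for v in mapping.values())
        for a in analogs:
            diffs = {
                i
                for i in range(1, 11)
                if a.sequence.residue(i) != base.residue(i)
                or a.sequence.is_d(i) != base.is_d(i)
            }
            assert diffs == set(mapping)  # differs exactly at candidate sites


class TestResistance:
    def test_all_27_analogs_trypsin_resistant(self, ex4c):
        analogs = enumerate_analogs(ex4c, candidate_sites_top3())
        resistant, non_resistant = validate_resistance(analogs, TRYPSIN)
        assert len(resistant) == 27 and not non_resistant

    def test_parent_is_not_resistant(self, ex4c):
        record = AnalogRecord("Ex4C", ex4c)
        _, non_resistant = validate_resistance([record], TRYPSIN)
        assert non_resistant == [record]

    def test_adversarial_k_to_r_stays_cleavable(self, ex4c):
        analogs = enumerate_analogs(
            ex4c, SiteSubstitutionCandidates.from_simple({12: ["R"]})
        )
        resistant, non_resistant = validate_resistance(analogs, TRYPSIN)
        assert not resistant and len(non_resistant) == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            validate_resistance([], TRYPSIN)

    def test_base_with_kr_only_at_substituted_sites_always_resistant(self, ex4c):
        # Ex4C's only K/R are at 12, 20, 27; any non-K/R product is site-free
        analogs = enumerate_analogs(ex4c, candidate_sites_extended())
        for a in analogs:
            assert find_cleavage_sites(a.sequence, TRYPSIN) == []


class TestBindingEnergyScreen:
    def test_threshold_minus_42_selects_five(self):
        tsme = [r for r in analog_records() if r.name != "Exendin4-C"]
        selected = select_by_binding_energy(tsme, -42.0)
        assert [a.name for a in selected] == [
            "TSME-1", "TSME-2", "TSME-3", "TSME-4", "TSME-5"
        ]

    def test_stricter_threshold_selects_none(self):
        tsme = [r for r in analog_records() if r.name != "Exendin4-C"]
        assert select_by_binding_energy(tsme, -50.0) == []  # best analog is -45.88

    def test_empty_input(self):
        assert select_by_binding_energy([], -42.0) == []

    def test_missing_score_names_analog(self, ex4c):
        with pytest.raises(ValueError, match="nameless"):
            select_by_binding_energy([AnalogRecord("nameless", ex4c)], -42.0)

    def test_monotone_in_threshold(self):
        tsme = [r for r in analog_records() if r.name != "Exendin4-C"]
        previous: set[str] = set()
        for threshold in (-50.0, -45.0, -42.0, -40.0, -30.0):
            current = {a.name for a in select_by_binding_energy(tsme, threshold)}
            assert previous <= current
            previous = current


def test_packaged_analog_table_is_consistent(ex4c):
    """Every packaged analog differs from the parent only at sites 12/20/27."""
    del ex4c
    parent = load_ex4c()
    for record in analog_records():
        if record.name == "Exendin4-C":
            assert record.sequence == parent
            continue
        assert len(record.sequence) == 40
        diffs = {
            i
            for i in range(1, 41)
            if record.sequence.residue(i) != parent.residue(i)
            or record.sequence.is_d(i)
        }
        assert diffs <= {12, 20, 27}
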