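"""Peak-to-span mass matching against a brute-force oracle."""

import pytest
from hypothesis import given, settings, strategies as st

from cleavemap.assignment import (
    FragmentMatch,
    ObservedPeak,
    assign_peaks,
    enumerate_subpeptides,
    match_peak,
)
from cleavemap.datasets import digest_peaks, reported_assignments
from cleavemap.peptide import FragmentSpan, parse_peptide, protonated_mass

AA = "ACDEFGHIKLMNPQRSTVWY"
peptide_strings = st.text(alphabet=AA, min_size=1, max_size=25)


def brute_force_matches(peak, p, tolerance):
    """Oracle: scan every span independently of the production path."""
    hits = []
    for n in range(1, len(p) + 1):
        for start in range(1, len(p) - n + 2):
            span = FragmentSpan(start, start + n - 1)
            theo = protonated_mass(p, span)
            if abs(peak.apparent_mass - theo) <= tolerance:
                hits.append((span, theo))
    return sorted(
        ((s, t) for s, t in hits),
        key=lambda x: (abs(peak.apparent_mass - x[1]), x[0].start, x[0].end),
    )


class TestEnumerate:
    def test_length_40_gives_820_spans(self, ex4c):
        spans = enumerate_subpeptides(ex4c)
        assert len(spans) == 820  # n(n+1)/2
        assert spans == sorted(spans)

    def test_single_residue(self):
        assert enumerate_subpeptides(parse_peptide("G")) == [FragmentSpan(1, 1)]

    def test_length_bounds(self):
        assert enumerate_subpeptides(parse_peptide("GAV"), 2, 2) == [
            FragmentSpan(1, 2), FragmentSpan(2, 3)
        ]
        with pytest.raises(ValueError):
            enumerate_subpeptides(parse_peptide("GAV"), 0, 2)
        with pytest.raises(ValueError):
            enumerate_subpeptides(parse_peptide("GAV"), 2, 4)


class TestMatchPeak:
    def test_trypsin_fragment_examples(self, ex4c):
        best = match_peak(ObservedPeak(991.4494), ex4c, 0.05)[0]
        assert tuple(best.span) == (13, 20)
        best = match_peak(ObservedPeak(1024.4663), ex4c, 0.05)[0]
        assert tuple(best.span) == (28, 39)

    def test_mass_beyond_parent_matches_nothing(self, ex4c):
        assert match_peak(ObservedPeak(10000.0), ex4c, 1.0) == []

    def test_match_error_within_tolerance(self, ex4c):
        for m in match_peak(ObservedPeak(991.4494), ex4c, 0.05):
            assert abs(m.error) <= 0.05
            assert m.error_ppm == pytest.approx(1e6 * m.error / m.theoretical_mass)

    def test_candidate_span_restriction(self, ex4c):
        peak = ObservedPeak(707.3790)
        unrestricted = {tuple(m.span) for m in match_peak(peak, ex4c, 0.05)}
        assert unrestricted == {(21, 25), (22, 26)}
        restricted = match_peak(
            peak, ex4c, 0.05, candidate_spans=[FragmentSpan(22, 26)]
        )
        assert [tuple(m.span) for m in restricted] == [(22, 26)]

    def test_bad_tolerance_rejected(self, ex4c):
        with pytest.raises(ValueError):
            match_peak(ObservedPeak(500.0), ex4c, 0.0)

    @settings(max_examples=75, deadline=None)
    @given(
        seq=peptide_strings,
        mass=st.floats(min_value=76.0, max_value=3000.0),
        tol=st.floats(min_value=1e-3, max_value=0.5),
    )
    def test_equals_brute_force_oracle(self, seq, mass, tol):
        p = parse_peptide(seq)
        peak = ObservedPeak(mass)
        got = match_peak(peak, p, tol)
        oracle = brute_force_matches(peak, p, tol)
        # same span set; near-identical masses (summation order may differ
        # in the last float digits); output sorted by |error|
        assert {tuple(m.span) for m in got} == {tuple(s) for s, _ in oracle}
        by_span = dict((tuple(s), t) for s, t in oracle)
        for m in got:
            assert m.theoretical_mass == pytest.approx(by_span[tuple(m.span)], abs=1e-9)
        errs = [abs(m.error) for m in got]
        assert errs == sorted(errs)

    @settings(max_examples=50, deadline=None)
    @given(seq=peptide_strings, mass=st.floats(min_value=76.0, max_value=3000.0))
    def test_shrinking_tolerance_never_adds_matches(self, seq, mass):
        p = parse_peptide(seq)
        peak = ObservedPeak(mass)
        wide = {tuple(m.span) for m in match_peak(peak, p, 0.5)}
        narrow = {tuple(m.span) for m in match_peak(peak, p, 0.05)}
        assert narrow <= wide

    @settings(max_examples=50, deadline=None)
    @given(seq=peptide_strings, data=st.data())
    def test_exact_mass_round_trip(self, seq, data):
        """A span's own [M+H]+ mass always matches at least itself."""
        p = parse_peptide(seq)
        start = data.draw(st.integers(1, len(p)))
        end = data.draw(st.integers(start, len(p)))
        span = FragmentSpan(start, end)
        peak = ObservedPeak(protonated_mass(p, span))
        assert span in [m.span for m in match_peak(peak, p, 0.001)]


class TestAssignPeaks:
    def test_trypsin_block_assignments(self, ex4c):
        report = assign_peaks(digest_peaks("trypsin"), ex4c, 0.05)
        spans = {tuple(m.span) for m in report.matches}
        assert spans == {(1, 12), (13, 20), (21, 27), (28, 39)}
        assert report.unassigned == ()

    def test_ppm_mode(self, ex4c):
        report = assign_peaks(digest_peaks("trypsin"), ex4c, tolerance=50, ppm=True)
        assert {tuple(m.span) for m in report.matches} == {
            (1, 12), (13, 20), (21, 27), (28, 39)
        }

    def test_unassignable_peak_reported(self, ex4c):
        report = assign_peaks([ObservedPeak(500.0)], ex4c, 0.001)
        assert report.matches == ()
        assert len(report.unassigned) == 1

    def test_ambiguity_reported_not_resolved(self, ex4c):
        # 707.379 fits both 21-25 and 22-26 (composition permutations)
        report = assign_peaks([ObservedPeak(707.3790)], ex4c, 0.05, unique_only=False)
        assert len(report.ambiguous) == 1
        assert {tuple(m.span) for m in report.matches} == {(21, 25), (22, 26)}

    def test_empty_peak_list_rejected(self, ex4c):
        with pytest.raises(ValueError):
            assign_peaks([], ex4c)

    def test_all_17_published_peaks_recoverable(self, ex4c):
        """Every published peak's span is a minimal-error match at <= 0.1 Da."""
        reported = reported_assignments()
        for peak in digest_peaks():
            cands = match_peak(peak, ex4c, 0.1)
            best_err = abs(cands[0].error)
            tied = {tuple(m.span) for m in cands if abs(m.error) == pytest.approx(best_err)}
            assert tuple(reported[peak.label]) in tied
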