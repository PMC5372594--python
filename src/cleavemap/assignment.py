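"""Assignment of observed LC-MS peak masses to candidate subpeptide spans.

The matching strategy mirrors manual peptide-mass fingerprinting of a known
parent: enumerate *all* contiguous subpeptides (not only protease-consistent
ones), compute their theoretical [M+H]+ masses, and accept every span whose
mass lies within an absolute (Da) or relative (ppm) tolerance of the
observed apparent mass.  The best match is the smallest absolute error;
ambiguity (two or more candidates inside the tolerance window) is reported,
never silently resolved.  Retention time is carried through for reporting
but plays no role in scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .peptide import (
    DEFAULT_MASS_TABLE,
    AminoAcidMassTable,
    FragmentSpan,
    PeptideSequence,
)

__all__ = [
    "DEFAULT_TOLERANCE_DA",
    "ObservedPeak",
    "FragmentMatch",
    "AssignmentReport",
    "enumerate_subpeptides",
    "match_peak",
    "assign_peaks",
]

#: Default absolute matching tolerance in Da.
DEFAULT_TOLERANCE_DA = 0.05


@dataclass(frozen=True)
class ObservedPeak:
    """A deconvoluted LC-MS peak on the [M+H]+ mass convention."""

    apparent_mass: float
    retention_time: float | None = None
    label: int | None = None

    def __post_init__(self) -> None:
        if not self.apparent_mass > 0:
            raise ValueError(f"apparent_mass must be > 0, got {self.apparent_mass}")


@dataclass(frozen=True)
class FragmentMatch:
    """An observed peak paired with a candidate span within tolerance."""

    peak: ObservedPeak
    span: FragmentSpan
    theoretical_mass: float
    error: float  # apparent - theoretical, Da

    @property
    def error_ppm(self) -> float:
        return 1e6 * self.error / self.theoretical_mass


@dataclass(frozen=True)
class AssignmentReport:
    """Per-peak assignment outcome for a peak list.

    ``matches`` holds the retained FragmentMatch objects (best-only or all
    candidates, per ``unique_only``); ``unassigned`` the peaks with no
    candidate within tolerance; ``ambiguous`` the peaks with two or more.
    """

    matches: tuple[FragmentMatch, ...]
    unassigned: tuple[ObservedPeak, ...]
    ambiguous: tuple[ObservedPeak, ...]

    def best_span(self, peak: ObservedPeak) -> FragmentSpan | None:
        for m in self.matches:
            if m.peak == peak:
                return m.span
        return None


def enumerate_subpeptides(
    p: PeptideSequence, min_len: int = 1, max_len: int | None = None
) -> list[FragmentSpan]:
    """All contiguous spans of ``p`` with length in [min_len, max_len],
    ordered by (start, end)."""
    n = len(p)
    if max_len is None:
        max_len = n
    if not 1 <= min_len <= max_len <= n:
        raise ValueError(
            f"need 1 <= min_len <= max_len <= {n}, got [{min_len}, {max_len}]"
        )
    return [
        FragmentSpan(s, e)
        for s in range(1, n + 1)
        for e in range(s + min_len - 1, min(s + max_len, n + 1))
    ]


def _tolerance_da(mass: float, tolerance: float, ppm: bool) -> float:
    return mass * tolerance * 1e-6 if ppm else tolerance


def match_peak(
    peak: ObservedPeak,
    p: PeptideSequence,
    tolerance: float = DEFAULT_TOLERANCE_DA,
    ppm: bool = False,
    table: AminoAcidMassTable = DEFAULT_MASS_TABLE,
    candidate_spans: Sequence[FragmentSpan] | None = None,
) -> list[FragmentMatch]:
    """All spans whose [M+H]+ mass lies within ``tolerance`` of the peak,
    sorted by (|error|, start, end).

    ``tolerance`` is Da by default, parts-per-million of the theoretical
    mass when ``ppm`` is True.  By default every contiguous span of ``p``
    is a candidate; pass ``candidate_spans`` (e.g. a partial-digest span
    list) to restrict the search to protease-consistent fragments, which
    sharply reduces mass-degenerate ambiguity when the enzyme is known.
    """
    if not tolerance > 0:
        raise ValueError(f"tolerance must be > 0, got {tolerance}")
    # Prefix sums give every span mass in O(n^2) total.
    prefix = [0.0]
    for aa in p.residues:
        prefix.append(prefix[-1] + table.residue_mass(aa))
    offset = table.water_mass + table.proton_mass
    if candidate_spans is None:
        spans = (
            FragmentSpan(s, e)
            for s in range(1, len(p) + 1)
            for e in range(s, len(p) + 1)
        )
    else:
        spans = iter(candidate_spans)
    out = []
    for span in spans:
        p.check_span(span)
        theo = prefix[span.end] - prefix[span.start - 1] + offset
        err = peak.apparent_mass - theo
        if abs(err) <= _tolerance_da(theo, tolerance, ppm):
            out.append(FragmentMatch(peak, span, theo, err))
    out.sort(key=lambda m: (abs(m.error), m.span.start, m.span.end))
    return out


def assign_peaks(
    peaks: Sequence[ObservedPeak],
    p: PeptideSequence,
    tolerance: float = DEFAULT_TOLERANCE_DA,
    ppm: bool = False,
    unique_only: bool = True,
    table: AminoAcidMassTable = DEFAULT_MASS_TABLE,
    candidate_spans: Sequence[FragmentSpan] | None = None,
) -> AssignmentReport:
    """Assign every peak in a list to its best-matching span.

    With ``unique_only`` (default) one best match is kept per peak; with
    ``unique_only=False`` every candidate within tolerance is kept.  Peaks
    with >= 2 candidates are listed as ambiguous either way.
    """
    if not peaks:
        raise ValueError("peak list is empty")
    matches: list[FragmentMatch] = []
    unassigned: list[ObservedPeak] = []
    ambiguous: list[ObservedPeak] = []
    for peak in peaks:
        cands = match_peak(peak, p, tolerance, ppm, table, candidate_spans)
        if not cands:
            unassigned.append(peak)
            continue
        if len(cands) > 1:
            ambiguous.append(peak)
        matches.extend(cands[:1] if unique_only else cands)
    return AssignmentReport(tuple(matches), tuple(unassigned), tuple(ambiguous))
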