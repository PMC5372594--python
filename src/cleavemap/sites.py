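"""Cleavage-site inference by splicing assigned fragments.

Each assigned fragment implies up to two candidate cut positions: one at
its last residue (a fragment *ending* at position i evidences a cut after
i) and one just before its first residue (a fragment *starting* at i+1
evidences the same cut).  Splicing tallies this start-side and end-side
support over the whole match set.  A cut supported from both sides —
some fragment ends there and another begins right after — is the strong
call; one-sided mode keeps every implied boundary and exists for
sensitivity analysis.

``observed_terminus`` handles parents whose terminal residues are never
covered by any fragment (e.g. a C-terminal cysteine tag that is not seen
in the digest): boundaries at or beyond it are suppressed rather than
called as cleavages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .assignment import FragmentMatch
from .peptide import FragmentSpan, PeptideSequence

__all__ = ["CleavageEvidence", "infer_cleavage_sites", "site_report"]


@dataclass(frozen=True)
class CleavageEvidence:
    """An inferred cut-after position with fragment support counts."""

    position: int
    end_support: int
    start_support: int

    @property
    def both_sided(self) -> bool:
        return self.end_support > 0 and self.start_support > 0


def _spans(matches: Iterable[FragmentMatch | FragmentSpan]) -> list[FragmentSpan]:
    out = []
    for m in matches:
        out.append(m.span if isinstance(m, FragmentMatch) else FragmentSpan(*m))
    return out


def infer_cleavage_sites(
    matches: Iterable[FragmentMatch | FragmentSpan],
    parent_length: int,
    require_both_sided: bool = True,
    observed_terminus: int | None = None,
) -> list[CleavageEvidence]:
    """Splice fragment spans into cleavage evidence, sorted by position.

    Accepts FragmentMatch objects or bare spans.  Every internal boundary
    implied by a fragment start or end becomes a candidate; with
    ``require_both_sided`` (default) only positions supported by both a
    fragment end and an adjacent fragment start are returned.  Positions
    >= ``observed_terminus`` (when given) are suppressed — they reflect
    the edge of fragment coverage, not a cleavage.
    """
    end_support: dict[int, int] = {}
    start_support: dict[int, int] = {}
    for span in _spans(matches):
        if not (1 <= span.start <= span.end <= parent_length):
            raise ValueError(
                f"span {span} exceeds parent length {parent_length}"
            )
        if span.end < parent_length:  # cut after span.end
            end_support[span.end] = end_support.get(span.end, 0) + 1
        if span.start > 1:  # cut after span.start - 1
            pos = span.start - 1
            start_support[pos] = start_support.get(pos, 0) + 1
    limit = observed_terminus if observed_terminus is not None else parent_length
    evidence = [
        CleavageEvidence(pos, end_support.get(pos, 0), start_support.get(pos, 0))
        for pos in sorted(end_support.keys() | start_support.keys())
        if pos < limit
    ]
    if require_both_sided:
        evidence = [ev for ev in evidence if ev.both_sided]
    return evidence


def site_report(
    evidence: Iterable[CleavageEvidence], p: PeptideSequence
) -> pd.DataFrame:
    """Tabulate inferred sites with the residue each cut follows.

    Columns: position, residue, end_support, start_support, both_sided.
    """
    rows = []
    for ev in evidence:
        if not 1 <= ev.position < len(p):
            raise ValueError(f"evidence position {ev.position} invalid for parent")
        rows.append(
            {
                "position": ev.position,
                "residue": p.residue(ev.position),
                "end_support": ev.end_support,
                "start_support": ev.start_support,
                "both_sided": ev.both_sided,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["position", "residue", "end_support", "start_support", "both_sided"],
    )
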