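"""Rule-based protease cleavage prediction and in-silico digestion.

A :class:`ProteaseRule` is the classic declarative specificity model: the
enzyme hydrolyzes the backbone after any residue in ``cleave_after`` unless
the next residue is in ``blocked_by_next`` (the proline block of trypsin).
D-residues are invisible to proteases by default (``d_residue_immune``),
which is the mechanism exploited by D-substituted analogs.

``predict_intact_percent`` implements the complete-digestion limit model:
at assay endpoint a peptide carrying at least one recognition site is fully
hydrolyzed (0% intact) and a site-free peptide is untouched (100%).  No
kinetic model is attempted; the rule set carries no rate constants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .peptide import STANDARD_CODES, FragmentSpan, PeptideSequence

__all__ = [
    "ProteaseRule",
    "DigestResult",
    "TRYPSIN",
    "CHYMOTRYPSIN",
    "ELASTASE",
    "BUILTIN_RULES",
    "get_rule",
    "find_cleavage_sites",
    "digest_complete",
    "digest_partial",
    "predict_intact_percent",
]


@dataclass(frozen=True)
class ProteaseRule:
    """Declarative cleavage specificity: cut after P1 unless P1' blocks."""

    name: str
    cleave_after: frozenset[str]
    blocked_by_next: frozenset[str] = frozenset()
    d_residue_immune: bool = True

    def __post_init__(self) -> None:
        cleave = frozenset(self.cleave_after)
        blocked = frozenset(self.blocked_by_next)
        object.__setattr__(self, "cleave_after", cleave)
        object.__setattr__(self, "blocked_by_next", blocked)
        if not cleave:
            raise ValueError("cleave_after must be non-empty")
        bad = (cleave | blocked) - STANDARD_CODES
        if bad:
            raise ValueError(f"invalid residue codes in rule {self.name!r}: {sorted(bad)}")

    @classmethod
    def from_json(cls, path: str | Path) -> "ProteaseRule":
        with open(path) as fh:
            cfg = json.load(fh)
        return cls(
            name=cfg["name"],
            cleave_after=frozenset(cfg["cleave_after"]),
            blocked_by_next=frozenset(cfg.get("blocked_by_next", [])),
            d_residue_immune=cfg.get("d_residue_immune", True),
        )


TRYPSIN = ProteaseRule("trypsin", frozenset("KR"), frozenset("P"))
CHYMOTRYPSIN = ProteaseRule("chymotrypsin", frozenset("FYWL"))
ELASTASE = ProteaseRule("elastase", frozenset("AVLIGS"))

BUILTIN_RULES: dict[str, ProteaseRule] = {
    r.name: r for r in (TRYPSIN, CHYMOTRYPSIN, ELASTASE)
}


def get_rule(name: str) -> ProteaseRule:
    """Look up a built-in protease rule by name (case-insensitive)."""
    try:
        return BUILTIN_RULES[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown protease {name!r}; built-ins: {sorted(BUILTIN_RULES)}"
        ) from None


@dataclass(frozen=True)
class DigestResult:
    """Fragments of a digest plus the missed-cleavage budget used."""

    fragments: tuple[FragmentSpan, ...]
    missed_cleavages: int = 0


def find_cleavage_sites(p: PeptideSequence, rule: ProteaseRule) -> list[int]:
    """Predicted cut positions ("cut after residue i"), ascending.

    Position i is a site iff residue i is in the cleave-after set, is
    L-chirality (when the rule treats D-residues as immune), is not the
    C-terminal residue, and residue i+1 is not a blocking residue.
    """
    sites = []
    for i in range(1, len(p)):
        if p.residue(i) not in rule.cleave_after:
            continue
        if rule.d_residue_immune and p.is_d(i):
            continue
        if p.residue(i + 1) in rule.blocked_by_next:
            continue
        sites.append(i)
    return sites


def digest_complete(p: PeptideSequence, rule: ProteaseRule) -> DigestResult:
    """Exhaustive digest: maximal spans between consecutive cut positions."""
    bounds = [0, *find_cleavage_sites(p, rule), len(p)]
    frags = tuple(
        FragmentSpan(lo + 1, hi) for lo, hi in zip(bounds[:-1], bounds[1:])
    )
    return DigestResult(fragments=frags, missed_cleavages=0)


def digest_partial(
    p: PeptideSequence, rule: ProteaseRule, max_missed: int
) -> list[FragmentSpan]:
    """All spans bounded by termini/cut sites with at most ``max_missed``
    internal (uncleaved) sites; ordered by (start, end)."""
    if max_missed < 0:
        raise ValueError(f"max_missed must be >= 0, got {max_missed}")
    bounds = [0, *find_cleavage_sites(p, rule), len(p)]
    spans = []
    for i, lo in enumerate(bounds[:-1]):
        for j in range(i + 1, min(i + 2 + max_missed, len(bounds))):
            spans.append(FragmentSpan(lo + 1, bounds[j]))
    spans.sort()
    return spans


def predict_intact_percent(p: PeptideSequence, rule: ProteaseRule) -> float:
    """Intact fraction (%) under the complete-digestion limit model."""
    return 100.0 if not find_cleavage_sites(p, rule) else 0.0
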