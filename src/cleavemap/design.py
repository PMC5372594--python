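"""Enumeration and screening of cleavage-site-mutated peptide analogs.

Given a parent peptide and, per cleavage site, a list of candidate
replacement residues (optionally D-enantiomers, optionally carrying an
external per-mutation stability score), ``enumerate_analogs`` builds the
full Cartesian product of substitutions.  Structure-based scores —
per-mutation stability and per-analog ligand-receptor binding energies
(kcal/mol scale, lower = more stable) — are *ingested as data*, typically
from structure-prediction or MD pipelines run elsewhere; this module never
computes them.  Screening is then a pair of filters: rule-based protease
resistance (no remaining recognition site) and a binding-energy threshold.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .digestion import ProteaseRule, find_cleavage_sites
from .peptide import STANDARD_CODES, PeptideSequence, parse_peptide

__all__ = [
    "SubstitutionCandidate",
    "SiteSubstitutionCandidates",
    "AnalogRecord",
    "enumerate_analogs",
    "validate_resistance",
    "select_by_binding_energy",
    "load_candidates_json",
    "load_analog_scores_csv",
]


@dataclass(frozen=True)
class SubstitutionCandidate:
    """One replacement option at a site: residue, chirality, optional score."""

    residue: str
    is_d: bool = False
    score: float | None = None

    def __post_init__(self) -> None:
        aa = self.residue.upper()
        if aa not in STANDARD_CODES:
            raise ValueError(f"invalid candidate residue {self.residue!r}")
        object.__setattr__(self, "residue", aa)


@dataclass(frozen=True)
class SiteSubstitutionCandidates:
    """Candidate replacements keyed by 1-based site position."""

    sites: dict[int, tuple[SubstitutionCandidate, ...]]

    def validate_for(self, base: PeptideSequence) -> None:
        for pos, cands in self.sites.items():
            if not 1 <= pos <= len(base):
                raise ValueError(f"candidate site {pos} outside 1..{len(base)}")
            if not cands:
                raise ValueError(f"empty candidate list at site {pos}")
            for c in cands:
                if c.residue == base.residue(pos) and c.is_d == base.is_d(pos):
                    raise ValueError(
                        f"candidate at site {pos} equals the base residue "
                        f"{base.residue(pos)!r}"
                    )

    @classmethod
    def from_simple(
        cls, mapping: dict[int, Sequence[str]]
    ) -> "SiteSubstitutionCandidates":
        """Build from ``{position: ["M", "v", ...]}`` (lowercase = D)."""
        return cls(
            {
                pos: tuple(
                    SubstitutionCandidate(aa.upper(), is_d=aa.islower())
                    for aa in residues
                )
                for pos, residues in mapping.items()
            }
        )


@dataclass(frozen=True)
class AnalogRecord:
    """A designed analog: sequence, its substitutions, optional binding energy."""

    name: str
    sequence: PeptideSequence
    substitutions: dict[int, tuple[str, str, bool]] = field(default_factory=dict)
    binding_energy: float | None = None

    def with_binding_energy(self, value: float) -> "AnalogRecord":
        return AnalogRecord(self.name, self.sequence, self.substitutions, value)


def enumerate_analogs(
    base: PeptideSequence,
    candidates: SiteSubstitutionCandidates,
    include_base: bool = False,
    name_prefix: str = "analog",
) -> list[AnalogRecord]:
    """Cartesian product of substitutions: every site gets one candidate.

    The result count is the product of candidate-list sizes (plus the base
    when ``include_base``).  Order is deterministic: sites ascending, then
    candidate-list order, last site varying fastest.
    """
    candidates.validate_for(base)
    positions = sorted(candidates.sites)
    records = []
    if include_base:
        records.append(AnalogRecord(f"{name_prefix}-base", base, {}))
    for k, combo in enumerate(
        itertools.product(*(candidates.sites[pos] for pos in positions)), start=1
    ):
        subs = {
            pos: (base.residue(pos), cand.residue, cand.is_d)
            for pos, cand in zip(positions, combo)
        }
        seq = base.with_substitutions(
            {pos: (cand.residue, cand.is_d) for pos, cand in zip(positions, combo)}
        )
        records.append(AnalogRecord(f"{name_prefix}-{k}", seq, subs))
    return records


def validate_resistance(
    analogs: Sequence[AnalogRecord], rule: ProteaseRule
) -> tuple[list[AnalogRecord], list[AnalogRecord]]:
    """Partition analogs into (resistant, non_resistant) under a rule.

    Resistant means the rule predicts zero cleavage sites in the analog.
    """
    if not analogs:
        raise ValueError("no analogs to validate")
    resistant, non_resistant = [], []
    for a in analogs:
        (resistant if not find_cleavage_sites(a.sequence, rule) else non_resistant).append(a)
    return resistant, non_resistant


def select_by_binding_energy(
    analogs: Iterable[AnalogRecord], threshold: float = -42.0
) -> list[AnalogRecord]:
    """Keep analogs whose binding energy is at or below ``threshold``
    (lower = more stable complex); order preserved."""
    selected = []
    for a in analogs:
        if a.binding_energy is None:
            raise ValueError(f"analog {a.name!r} has no binding energy")
        if a.binding_energy <= threshold:
            selected.append(a)
    return selected


def load_candidates_json(path: str | Path) -> SiteSubstitutionCandidates:
    """Load candidate sets from JSON: ``{"12": ["M", "V", "i"], ...}``
    or ``{"12": [{"residue": "M", "is_d": false, "score": -22.5}, ...]}``."""
    with open(path) as fh:
        raw = json.load(fh)
    sites = {}
    for pos, cands in raw.items():
        parsed = []
        for c in cands:
            if isinstance(c, str):
                parsed.append(SubstitutionCandidate(c.upper(), is_d=c.islower()))
            else:
                parsed.append(
                    SubstitutionCandidate(
                        c["residue"], c.get("is_d", False), c.get("score")
                    )
                )
        sites[int(pos)] = tuple(parsed)
    return SiteSubstitutionCandidates(sites)


def load_analog_scores_csv(path: str | Path) -> pd.DataFrame:
    """Read an analog score table (columns: name, sequence, binding_energy)."""
    df = pd.read_csv(path)
    required = {"name", "binding_energy"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"score table missing columns: {sorted(missing)}")
    return df


def analogs_from_score_table(df: pd.DataFrame) -> list[AnalogRecord]:
    """Build AnalogRecord objects from a score table with sequences."""
    records = []
    for row in df.itertuples(index=False):
        records.append(
            AnalogRecord(
                name=str(row.name),
                sequence=parse_peptide(str(row.sequence)),
                binding_energy=float(row.binding_energy),
            )
        )
    return records
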