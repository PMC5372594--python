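"""Peptide sequences, fragment spans and exact mass arithmetic.

Every downstream stage (digestion, peak assignment, site inference, analog
design) operates on :class:`PeptideSequence` objects.  Positions are 1-based
and spans are inclusive on both ends throughout the package, matching the
convention used in peptide-mapping tables ("fragment 1-12" covers residues
1 through 12).

Masses are residue (dehydrated monomer) masses; a peptide's neutral mass is
the sum of its residue masses plus one water.  The singly protonated ion
mass [M+H]+ adds one proton on top of that.  D-amino acids are mass-identical
to their L counterparts and are tracked only as a per-residue chirality flag
(serialized as lowercase letters, a documented FASTA dialect).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

__all__ = [
    "WATER_MONO",
    "PROTON_MASS",
    "AminoAcidMassTable",
    "DEFAULT_MASS_TABLE",
    "FragmentSpan",
    "PeptideSequence",
    "parse_peptide",
    "neutral_mass",
    "protonated_mass",
    "read_fasta",
    "write_fasta",
]

#: Monoisotopic mass of H2O in Da.
WATER_MONO = 18.010565
#: Mass of a proton in Da ([M+H]+ = M + PROTON_MASS).
PROTON_MASS = 1.007276

# Standard residue masses, 5-decimal monoisotopic / 2-4 decimal average.
_MONO = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
_AVG = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167,
    "V": 99.1326, "T": 101.1051, "C": 103.1388, "L": 113.1594,
    "I": 113.1594, "N": 114.1038, "D": 115.0886, "Q": 128.1307,
    "K": 128.1741, "E": 129.1155, "M": 131.1926, "H": 137.1411,
    "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

#: Average mass of H2O in Da (used only in ``mode="average"``).
WATER_AVG = 18.01528

STANDARD_CODES = frozenset(_MONO)


@dataclass(frozen=True)
class AminoAcidMassTable:
    """Per-residue monoisotopic and average masses plus the water/proton constants.

    The default table covers the 20 standard residues.  A custom table (e.g.
    with fixed modifications folded into a residue mass) can be loaded from a
    JSON file of the form ``{"monoisotopic": {"G": 57.02146, ...},
    "average": {...}}``; missing sections fall back to the defaults.
    """

    monoisotopic: dict[str, float] = field(default_factory=lambda: dict(_MONO))
    average: dict[str, float] = field(default_factory=lambda: dict(_AVG))
    water_mass: float = WATER_MONO
    proton_mass: float = PROTON_MASS

    def __post_init__(self) -> None:
        for name, table in (("monoisotopic", self.monoisotopic), ("average", self.average)):
            missing = STANDARD_CODES - table.keys()
            if missing:
                raise ValueError(f"{name} table missing residues: {sorted(missing)}")
            bad = [aa for aa, m in table.items() if not m > 0]
            if bad:
                raise ValueError(f"{name} table has non-positive masses for {sorted(bad)}")

    def residue_mass(self, code: str, mode: str = "monoisotopic") -> float:
        table = self._table(mode)
        try:
            return table[code]
        except KeyError:
            raise KeyError(f"no mass for residue code {code!r}") from None

    def _table(self, mode: str) -> dict[str, float]:
        if mode == "monoisotopic":
            return self.monoisotopic
        if mode == "average":
            return self.average
        raise ValueError(f"mode must be 'monoisotopic' or 'average', got {mode!r}")

    @classmethod
    def from_json(cls, path: str | Path) -> "AminoAcidMassTable":
        with open(path) as fh:
            cfg = json.load(fh)
        mono = dict(_MONO)
        mono.update(cfg.get("monoisotopic", {}))
        avg = dict(_AVG)
        avg.update(cfg.get("average", {}))
        return cls(
            monoisotopic=mono,
            average=avg,
            water_mass=cfg.get("water_mass", WATER_MONO),
            proton_mass=cfg.get("proton_mass", PROTON_MASS),
        )


DEFAULT_MASS_TABLE = AminoAcidMassTable()


class FragmentSpan(NamedTuple):
    """A contiguous subpeptide, 1-based and inclusive at both ends."""

    start: int
    end: int

    def __len__(self) -> int:  # type: ignore[override]
        return self.end - self.start + 1

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __str__(self) -> str:
        return f"{self.start}-{self.end}"

    @classmethod
    def parse(cls, text: str) -> "FragmentSpan":
        """Parse ``"1-12"`` (also accepts en-dash) into a span."""
        parts = text.replace("–", "-").split("-")
        if len(parts) != 2:
            raise ValueError(f"cannot parse span {text!r}; expected 'start-end'")
        return cls(int(parts[0]), int(parts[1]))


@dataclass(frozen=True)
class PeptideSequence:
    """An ordered peptide with a per-residue chirality flag.

    ``residues`` holds uppercase one-letter codes; ``d_flags[i]`` is True when
    residue i+1 is the D enantiomer.  Chirality never changes mass.
    """

    residues: str
    d_flags: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("peptide must contain at least one residue")
        if len(self.d_flags) != len(self.residues):
            raise ValueError("d_flags length must equal sequence length")
        for i, aa in enumerate(self.residues, start=1):
            if aa not in STANDARD_CODES:
                raise ValueError(f"invalid amino acid code {aa!r} at position {i}")

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[str]:
        return iter(self.residues)

    def residue(self, position: int) -> str:
        """One-letter code at a 1-based position."""
        self._check_position(position)
        return self.residues[position - 1]

    def is_d(self, position: int) -> bool:
        self._check_position(position)
        return self.d_flags[position - 1]

    def _check_position(self, position: int) -> None:
        if not 1 <= position <= len(self):
            raise IndexError(f"position {position} outside 1..{len(self)}")

    def full_span(self) -> FragmentSpan:
        return FragmentSpan(1, len(self))

    def check_span(self, span: FragmentSpan) -> None:
        if not (1 <= span.start <= span.end <= len(self)):
            raise ValueError(
                f"span {span.start}-{span.end} invalid for length-{len(self)} peptide"
            )

    def subsequence(self, span: FragmentSpan) -> "PeptideSequence":
        self.check_span(span)
        return PeptideSequence(
            self.residues[span.start - 1 : span.end],
            self.d_flags[span.start - 1 : span.end],
        )

    def to_string(self) -> str:
        """Serialize with D-residues as lowercase (round-trips via parse_peptide)."""
        return "".join(
            aa.lower() if d else aa for aa, d in zip(self.residues, self.d_flags)
        )

    def with_substitutions(
        self, substitutions: dict[int, tuple[str, bool]]
    ) -> "PeptideSequence":
        """Return a copy with ``{position: (new_residue, is_d)}`` applied."""
        residues = list(self.residues)
        flags = list(self.d_flags)
        for pos, (aa, is_d) in substitutions.items():
            self._check_position(pos)
            aa = aa.upper()
            if aa not in STANDARD_CODES:
                raise ValueError(f"invalid replacement residue {aa!r} at position {pos}")
            residues[pos - 1] = aa
            flags[pos - 1] = is_d
        return PeptideSequence("".join(residues), tuple(flags))


def parse_peptide(text: str, allow_d: bool = True) -> PeptideSequence:
    """Parse a one-letter sequence string; lowercase letters mark D-residues.

    Raises ``ValueError`` naming the 1-based offending position for any
    character that is not a standard amino acid code, and for lowercase input
    when ``allow_d`` is False.
    """
    text = "".join(text.split())
    if not text:
        raise ValueError("empty peptide string")
    residues = []
    flags = []
    for i, ch in enumerate(text, start=1):
        upper = ch.upper()
        if upper not in STANDARD_CODES:
            raise ValueError(f"invalid amino acid code {ch!r} at position {i}")
        if ch.islower() and not allow_d:
            raise ValueError(
                f"lowercase (D-residue) code {ch!r} at position {i} but allow_d=False"
            )
        residues.append(upper)
        flags.append(ch.islower())
    return PeptideSequence("".join(residues), tuple(flags))


def neutral_mass(
    p: PeptideSequence,
    span: FragmentSpan | None = None,
    mode: str = "monoisotopic",
    table: AminoAcidMassTable = DEFAULT_MASS_TABLE,
) -> float:
    """Neutral mass in Da of ``p`` (or a span of it): residue masses + water."""
    if span is None:
        span = p.full_span()
    p.check_span(span)
    residues = p.residues[span.start - 1 : span.end]
    water = table.water_mass if mode == "monoisotopic" else WATER_AVG
    return sum(table.residue_mass(aa, mode) for aa in residues) + water


def protonated_mass(
    p: PeptideSequence,
    span: FragmentSpan | None = None,
    table: AminoAcidMassTable = DEFAULT_MASS_TABLE,
) -> float:
    """Singly protonated monoisotopic ion mass [M+H]+ in Da."""
    return neutral_mass(p, span, "monoisotopic", table) + table.proton_mass


# ---------------------------------------------------------------------------
# FASTA dialect: lowercase letters encode D-residues.

def read_fasta(path: str | Path, allow_d: bool = True) -> dict[str, PeptideSequence]:
    """Read peptides from FASTA; returns ``{record id: PeptideSequence}``.

    Case is significant: lowercase residues are parsed as D-amino acids.
    """
    from Bio import SeqIO

    out: dict[str, PeptideSequence] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        out[record.id] = parse_peptide(str(record.seq), allow_d=allow_d)
    if not out:
        raise ValueError(f"no FASTA records found in {path}")
    return out


def write_fasta(path: str | Path, peptides: dict[str, PeptideSequence] | Iterable[tuple[str, PeptideSequence]]) -> None:
    """Write peptides to FASTA, serializing D-residues as lowercase."""
    items = peptides.items() if isinstance(peptides, dict) else peptides
    with open(path, "w") as fh:
        for name, pep in items:
            fh.write(f">{name}\n")
            seq = pep.to_string()
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
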