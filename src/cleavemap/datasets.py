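"""Packaged reference data for the exendin4-cysteine (Ex4C) case study.

Ex4C is a 40-residue GLP-1 receptor agonist: exendin-4 extended with a
C-terminal cysteine.  The packaged files transcribe the published digest
peak list (17 LC-MS peaks from trypsin / chymotrypsin / elastase digests
with their reported span assignments), the per-site substitution candidate
sets for the three trypsin sites (Lys12, Arg20, Lys27), and the
MD-derived ligand-receptor binding energies of the eight TSME analogs
("Trypsin cleavage Site Mutated Exendin4-cysteine"; TSME-7/8 carry
D-residues, serialized lowercase).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .design import (
    AnalogRecord,
    SiteSubstitutionCandidates,
    load_candidates_json,
)
from .peptide import FragmentSpan, PeptideSequence, parse_peptide
from .assignment import ObservedPeak

__all__ = [
    "EX4C_SEQUENCE",
    "ex4c",
    "analog_records",
    "analog_sequences",
    "digest_peaks",
    "reported_assignments",
    "candidate_sites_top3",
    "candidate_sites_extended",
]

#: Exendin4-cysteine one-letter sequence (40 residues).
EX4C_SEQUENCE = "HGEGTFTSDLSKQMEEEAVRLFIEWLKNGGPSSGAPPPSC"


def _data_path(name: str):
    return resources.files("cleavemap.data").joinpath(name)


def ex4c() -> PeptideSequence:
    """The Ex4C parent peptide."""
    return parse_peptide(EX4C_SEQUENCE)


def _analog_table() -> pd.DataFrame:
    with resources.as_file(_data_path("analog_binding_energies.csv")) as path:
        return pd.read_csv(path)


def analog_records() -> list[AnalogRecord]:
    """The parent plus the eight TSME analogs with their binding energies."""
    records = []
    for row in _analog_table().itertuples(index=False):
        records.append(
            AnalogRecord(
                name=str(row.name),
                sequence=parse_peptide(str(row.sequence)),
                binding_energy=float(row.binding_energy),
            )
        )
    return records


def analog_sequences() -> dict[str, PeptideSequence]:
    """``{analog name: sequence}`` including the Ex4C parent."""
    return {r.name: r.sequence for r in analog_records()}


def digest_peaks(protease: str | None = None) -> list[ObservedPeak]:
    """The 17 published digest peaks, optionally restricted to one protease."""
    df = _peaks_table()
    if protease is not None:
        df = df[df["protease"] == protease.lower()]
        if df.empty:
            raise KeyError(f"no peaks for protease {protease!r}")
    return [
        ObservedPeak(
            apparent_mass=float(r.apparent_mass_da),
            retention_time=float(r.retention_time_min),
            label=int(r.no),
        )
        for r in df.itertuples(index=False)
    ]


def _peaks_table() -> pd.DataFrame:
    with resources.as_file(_data_path("ex4c_digest_peaks.csv")) as path:
        return pd.read_csv(path)


def reported_assignments(protease: str | None = None) -> dict[int, FragmentSpan]:
    """Published span assignment per peak label ("No." column)."""
    df = _peaks_table()
    if protease is not None:
        df = df[df["protease"] == protease.lower()]
    return {
        int(r.no): FragmentSpan.parse(str(r.reported_span))
        for r in df.itertuples(index=False)
    }


def candidate_sites_top3() -> SiteSubstitutionCandidates:
    """Top-3 stabilizing substitutions per trypsin site (12, 20, 27)."""
    with resources.as_file(_data_path("site_candidates_top3.json")) as path:
        return load_candidates_json(path)


def candidate_sites_extended() -> SiteSubstitutionCandidates:
    """Union of residues appearing across the published L-type analogs."""
    with resources.as_file(_data_path("site_candidates_extended.json")) as path:
        return load_candidates_json(path)
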