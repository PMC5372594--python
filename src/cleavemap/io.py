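"""Tabular I/O: peak lists, assignment reports, evidence tables, fit reports.

Dialects (all plain text, diff-able):

* peak list CSV — columns ``no, retention_time_min, apparent_mass_da``
  (extra columns are ignored on read, preserved nowhere);
* assignment report TSV — ``peak_no, retention_time_min, apparent_mass_da,
  span, theoretical_mass_da, error_da, error_ppm, ambiguous``;
* evidence TSV — the ``site_report`` table;
* dose-response CSV — ``concentration, response``;
* PK CSV — ``time_h, conc_ng_ml``;
* fit report JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .assignment import AssignmentReport, FragmentMatch, ObservedPeak
from .peptide import FragmentSpan
from .pharmacology import DoseResponseDataset, DoseResponseFit, PKSeries

__all__ = [
    "read_peaks_csv",
    "write_peaks_csv",
    "write_assignment_tsv",
    "read_spans_tsv",
    "read_dose_response_csv",
    "read_pk_csv",
    "write_fit_json",
]


def read_peaks_csv(path: str | Path) -> list[ObservedPeak]:
    df = pd.read_csv(path)
    if "apparent_mass_da" not in df.columns:
        raise ValueError(f"{path}: peak CSV must have an 'apparent_mass_da' column")
    if df.empty:
        raise ValueError(f"{path}: peak CSV contains no rows")
    peaks = []
    for row in df.itertuples(index=False):
        rt = getattr(row, "retention_time_min", None)
        no = getattr(row, "no", None)
        peaks.append(
            ObservedPeak(
                apparent_mass=float(row.apparent_mass_da),
                retention_time=None if rt is None or pd.isna(rt) else float(rt),
                label=None if no is None or pd.isna(no) else int(no),
            )
        )
    return peaks


def write_peaks_csv(path: str | Path, peaks: Sequence[ObservedPeak]) -> None:
    df = pd.DataFrame(
        {
            "no": [p.label for p in peaks],
            "retention_time_min": [p.retention_time for p in peaks],
            "apparent_mass_da": [p.apparent_mass for p in peaks],
        }
    )
    df.to_csv(path, index=False)


def write_assignment_tsv(path: str | Path, report: AssignmentReport) -> None:
    """Write matches plus explicit rows for unassigned peaks."""
    ambiguous = set(report.ambiguous)
    rows = []
    for m in report.matches:
        rows.append(
            {
                "peak_no": m.peak.label,
                "retention_time_min": m.peak.retention_time,
                "apparent_mass_da": m.peak.apparent_mass,
                "span": str(m.span),
                "theoretical_mass_da": round(m.theoretical_mass, 4),
                "error_da": round(m.error, 4),
                "error_ppm": round(m.error_ppm, 2),
                "ambiguous": m.peak in ambiguous,
            }
        )
    for p in report.unassigned:
        rows.append(
            {
                "peak_no": p.label,
                "retention_time_min": p.retention_time,
                "apparent_mass_da": p.apparent_mass,
                "span": "",
                "theoretical_mass_da": np.nan,
                "error_da": np.nan,
                "error_ppm": np.nan,
                "ambiguous": False,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_spans_tsv(path: str | Path) -> list[FragmentSpan]:
    """Read spans from an assignment report (or any TSV with a 'span' column)."""
    df = pd.read_csv(path, sep="\t")
    if "span" not in df.columns:
        raise ValueError(f"{path}: expected a 'span' column")
    spans = []
    for text in df["span"]:
        if isinstance(text, str) and text.strip():
            spans.append(FragmentSpan.parse(text.strip()))
    return spans


def read_dose_response_csv(path: str | Path) -> DoseResponseDataset:
    df = pd.read_csv(path)
    for col in ("concentration", "response"):
        if col not in df.columns:
            raise ValueError(f"{path}: dose-response CSV must have a {col!r} column")
    return DoseResponseDataset(
        concentrations=df["concentration"].to_numpy(float),
        responses=df["response"].to_numpy(float),
    )


def read_pk_csv(path: str | Path, route: str = "", dose: float | None = None) -> PKSeries:
    df = pd.read_csv(path)
    for col in ("time_h", "conc_ng_ml"):
        if col not in df.columns:
            raise ValueError(f"{path}: PK CSV must have a {col!r} column")
    return PKSeries(
        times=df["time_h"].to_numpy(float),
        concentrations=df["conc_ng_ml"].to_numpy(float),
        route=route,
        dose=dose,
    )


def write_fit_json(path: str | Path, fit: DoseResponseFit) -> None:
    payload = {
        "ec50": fit.ec50,
        "emax": fit.emax,
        "baseline": fit.baseline,
        "hill": fit.hill,
        "se": {k: float(v) for k, v in fit.se.items()},
        "converged": fit.converged,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
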