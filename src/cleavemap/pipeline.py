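"""The find-locate-design pipeline: assign peaks, infer sites, design analogs.

``run_pipeline`` chains the four analysis stages on file inputs and writes
a bundle of machine-readable artifacts plus a human-readable summary:

1. assign   — match observed peak masses to subpeptide spans of the parent;
2. infer    — splice matched spans into cleavage-site evidence;
3. design   — enumerate substitution analogs at the inferred (or supplied)
              sites and validate protease resistance;
4. screen   — optional binding-energy threshold selection when a score
              table is provided.

Outputs are deterministic for a fixed config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .assignment import DEFAULT_TOLERANCE_DA, assign_peaks
from .design import (
    SiteSubstitutionCandidates,
    analogs_from_score_table,
    enumerate_analogs,
    load_analog_scores_csv,
    load_candidates_json,
    select_by_binding_energy,
    validate_resistance,
)
from .digestion import ProteaseRule, get_rule
from .io import read_peaks_csv, write_assignment_tsv
from .peptide import read_fasta, write_fasta
from .sites import infer_cleavage_sites, site_report

logger = logging.getLogger("cleavemap.pipeline")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """File paths and parameters for one pipeline run."""

    sequence_path: str | Path
    peaks_path: str | Path
    protease: str | ProteaseRule = "trypsin"
    tolerance: float = DEFAULT_TOLERANCE_DA
    both_sided: bool = True
    observed_terminus: int | None = None
    candidates_path: str | Path | None = None
    scores_path: str | Path | None = None
    threshold: float = -42.0
    out_dir: str | Path = "cleavemap_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tolerance > 0:
            raise ValueError("tolerance must be > 0")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute assign -> infer-sites -> design -> screen; return the summary.

    Raises with a stage-labeled message on the first failing stage; no
    downstream artifacts are written after a failure.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rule = (
        config.protease
        if isinstance(config.protease, ProteaseRule)
        else get_rule(config.protease)
    )
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "protease": rule.name,
        "tolerance_da": config.tolerance,
    }

    # stage 1: assign
    try:
        peptides = read_fasta(config.sequence_path)
        name, parent = next(iter(peptides.items()))
        peaks = read_peaks_csv(config.peaks_path)
        report = assign_peaks(peaks, parent, tolerance=config.tolerance)
    except Exception as exc:
        raise RuntimeError(f"[assign] {exc}") from exc
    write_assignment_tsv(out / "assignments.tsv", report)
    summary["parent"] = name
    summary["n_peaks"] = len(peaks)
    summary["n_assigned"] = len({m.peak for m in report.matches})
    summary["n_unassigned"] = len(report.unassigned)
    summary["n_ambiguous"] = len(report.ambiguous)

    # stage 2: infer sites
    try:
        evidence = infer_cleavage_sites(
            report.matches,
            parent_length=len(parent),
            require_both_sided=config.both_sided,
            observed_terminus=config.observed_terminus,
        )
    except Exception as exc:
        raise RuntimeError(f"[infer-sites] {exc}") from exc
    site_report(evidence, parent).to_csv(out / "sites.tsv", sep="\t", index=False)
    summary["sites"] = [ev.position for ev in evidence]

    # stage 3: design + validate
    analogs = []
    if config.candidates_path is not None:
        try:
            candidates = load_candidates_json(config.candidates_path)
            analogs = enumerate_analogs(parent, candidates)
            resistant, non_resistant = validate_resistance(analogs, rule)
        except Exception as exc:
            raise RuntimeError(f"[design] {exc}") from exc
        write_fasta(
            out / "analogs.fasta", [(a.name, a.sequence) for a in analogs]
        )
        summary["n_analogs"] = len(analogs)
        summary["n_resistant"] = len(resistant)
        summary["n_non_resistant"] = len(non_resistant)

    # stage 4: binding-energy screen
    if config.scores_path is not None:
        try:
            scored = analogs_from_score_table(load_analog_scores_csv(config.scores_path))
            selected = select_by_binding_energy(scored, config.threshold)
        except Exception as exc:
            raise RuntimeError(f"[screen] {exc}") from exc
        with open(out / "screen.tsv", "w") as fh:
            fh.write("name\tbinding_energy\tselected\n")
            keep = {a.name for a in selected}
            for a in scored:
                fh.write(f"{a.name}\t{a.binding_energy}\t{a.name in keep}\n")
        summary["n_scored"] = len(scored)
        summary["n_selected"] = len(selected)
        summary["selected"] = sorted(keep)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete: %s", summary)
    return summary
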