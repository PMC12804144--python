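"""End-to-end antigenic-strength reporting.

For each ligand the pipeline runs the trajectory stage (strided Gly1
ASA -> state classification -> occupancy, per run and pooled) and the
kinetics stage (reference subtraction -> global 1:1 fit -> K_D or a
poor-fit reason), optionally measures the static crystal-structure Gly1
ASA and the E101-Gly1 reachability distance, and combines everything
into a ranked report.

The antigenicity call is an operationalisation: a ligand is called
``high`` iff its pooled epitope-exposed fraction reaches the call
threshold (default 0.5) AND a K_D could be determined from an
acceptable global fit; it is labelled as a rule-based call in the
output.
"""

from __future__ import annotations

import datetime
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import kinetics, traj_analysis
from .errors import ConfigError, EpidynError
from .geometry import ContactMeasurement, measure_contact
from .kinetics import Sensorgram, frame_to_sensorgrams
from .sasa import SasaParams, compute_sasa
from .structure_io import Structure, Trajectory, parse_multimodel, parse_pdb
from .traj_analysis import (
    AnalysisParams,
    OccupancySummary,
    StateThresholds,
    classify_states,
    occupancy,
    rank_ligands,
    residue_asa_series,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "LigandInput", "LigandReport", "run_report", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """Run-wide parameters; defaults mirror the study protocol."""

    target_residue: tuple[str, int] = ("C", 1)
    stride: int = 10
    sasa_params: SasaParams = field(default_factory=SasaParams)
    thresholds: StateThresholds = field(default_factory=StateThresholds)
    call_threshold: float = 0.5  # pooled exposed fraction for a "high" call
    r2_threshold: float = 0.9
    hbond_cutoff: float = 3.5


@dataclass
class LigandInput:
    """Inputs for one ligand; file paths or in-memory objects."""

    label: str
    trajectories: list[Trajectory | str] = field(default_factory=list)
    sensorgrams: list[Sensorgram] | str | None = None
    reference: Sensorgram | None = None
    structure: Structure | str | None = None
    donor: tuple[str, int, str] | None = None
    acceptors: list[tuple[str, int, str]] = field(default_factory=list)


@dataclass
class LigandReport:
    """Assembled per-ligand results."""

    label: str
    per_run: list[OccupancySummary] = field(default_factory=list)
    pooled: OccupancySummary | None = None
    kD: float | None = None  # M
    kD_reason: str = ""
    fit: kinetics.GlobalFitResult | None = None
    static_gly1_asa: float | None = None
    reachability: ContactMeasurement | None = None
    antigenicity: str = "not called"
    failed: bool = False
    error: str = ""

    @property
    def pooled_exposed_fraction(self) -> float:
        return self.pooled.exposed_fraction if self.pooled else float("nan")

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "per_run": [
                {
                    "label": s.label,
                    "fractions": s.fractions,
                    "counts": s.counts,
                    "n_changes": s.n_changes,
                    "mean_asa_A2": s.mean_asa,
                }
                for s in self.per_run
            ],
            "pooled_exposed_fraction": self.pooled_exposed_fraction,
            "KD_M": self.kD,
            "KD_reason": self.kD_reason,
            "fit_r_squared": self.fit.r_squared if self.fit else None,
            "static_gly1_asa_A2": self.static_gly1_asa,
            "reachability": (
                {
                    "distance_A": self.reachability.distance,
                    "reachable": self.reachability.reachable,
                }
                if self.reachability
                else None
            ),
            "antigenicity_call": self.antigenicity,
            "failed": self.failed,
            "error": self.error,
        }


def load_config(path: str | Path) -> tuple[PipelineConfig, list[LigandInput]]:
    """Read a declarative TOML run configuration.

    ``[defaults]`` overrides pipeline parameters; each ``[[ligands]]``
    table names a ligand and its input files (paths are resolved
    relative to the config file).
    """
    path = Path(path)
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    d = raw.get("defaults", {})
    config = PipelineConfig(
        target_residue=(
            d.get("target_chain", "C"),
            int(d.get("target_residue", 1)),
        ),
        stride=int(d.get("stride", 10)),
        sasa_params=SasaParams(
            probe_radius=float(d.get("probe_radius", 1.4)),
            n_points=int(d.get("n_points", 960)),
        ),
        thresholds=StateThresholds(
            exposed_min=float(d.get("exposed_min", 50.0)),
            buried_max=float(d.get("buried_max", 25.0)),
        ),
        call_threshold=float(d.get("call_threshold", 0.5)),
        r2_threshold=float(d.get("r2_threshold", 0.9)),
        hbond_cutoff=float(d.get("hbond_cutoff", 3.5)),
    )
    base = path.parent

    def resolve(p):
        return str(base / p) if isinstance(p, str) else p

    ligands = []
    for entry in raw.get("ligands", []):
        if "label" not in entry:
            raise ConfigError("every [[ligands]] entry needs a label")
        ligands.append(
            LigandInput(
                label=entry["label"],
                trajectories=[resolve(p) for p in entry.get("trajectories", [])],
                sensorgrams=resolve(entry.get("sensorgrams")),
                structure=resolve(entry.get("structure")),
                donor=_parse_atom_ref(entry["donor"]) if "donor" in entry else None,
                acceptors=[_parse_atom_ref(a) for a in entry.get("acceptors", [])],
            )
        )
    return config, ligands


def _parse_atom_ref(text: str) -> tuple[str, int, str]:
    try:
        chain, resi, name = text.split(":")
        return chain, int(resi), name
    except ValueError as exc:
        raise ConfigError(f"bad atom reference {text!r}; expected CHAIN:RESI:NAME") from exc


def _load_trajectory(item, label: str) -> Trajectory:
    if isinstance(item, Trajectory):
        return item
    p = Path(item)
    if not p.exists():
        raise ConfigError(f"ligand {label!r}: trajectory file {item} not found")
    return parse_multimodel(p.read_text())


def _load_structure(item, label: str) -> Structure:
    if isinstance(item, Structure):
        return item
    p = Path(item)
    if not p.exists():
        raise ConfigError(f"ligand {label!r}: structure file {item} not found")
    return parse_pdb(p.read_text())


def _load_sensorgrams(item, label: str) -> list[Sensorgram]:
    if isinstance(item, list):
        return item
    p = Path(item)
    if not p.exists():
        raise ConfigError(f"ligand {label!r}: sensorgram file {item} not found")
    import pandas as pd

    return frame_to_sensorgrams(pd.read_csv(p))


def _analyse_ligand(lig: LigandInput, config: PipelineConfig) -> LigandReport:
    report = LigandReport(label=lig.label)
    params = AnalysisParams(
        target_residue=config.target_residue,
        stride=config.stride,
        sasa_params=config.sasa_params,
    )

    all_states: list[np.ndarray] = []
    all_values: list[np.ndarray] = []
    for run_idx, item in enumerate(lig.trajectories, start=1):
        traj = _load_trajectory(item, lig.label)
        series = residue_asa_series(traj, params, label=f"{lig.label}/run{run_idx}")
        states = classify_states(series, config.thresholds)
        report.per_run.append(
            occupancy(states, series.values, label=f"{lig.label}/run{run_idx}")
        )
        all_states.append(states)
        all_values.append(series.values)
    if all_states:
        report.pooled = occupancy(
            np.concatenate(all_states), np.concatenate(all_values), label=lig.label
        )

    if lig.sensorgrams is not None:
        curves = _load_sensorgrams(lig.sensorgrams, lig.label)
        if lig.reference is not None:
            curves = [kinetics.reference_subtract(c, lig.reference) for c in curves]
        fit = kinetics.global_fit(curves, r2_threshold=config.r2_threshold)
        report.fit = fit
        if fit.poor_fit:
            report.kD_reason = (
                f"poor global fitting (R2={fit.r_squared:.3f} "
                f"< {config.r2_threshold} or no convergence)"
            )
        else:
            report.kD = fit.kD
    else:
        report.kD_reason = "no sensorgrams"

    if lig.structure is not None:
        structure = _load_structure(lig.structure, lig.label)
        result = compute_sasa(structure, config.sasa_params)
        chain, resi = config.target_residue
        report.static_gly1_asa = result.residue_areas.get((chain, resi, ""))
        if lig.donor and lig.acceptors:
            report.reachability = measure_contact(
                structure, lig.donor, lig.acceptors, config.hbond_cutoff
            )

    if report.pooled is not None:
        high = (
            report.pooled.exposed_fraction >= config.call_threshold
            and report.kD is not None
        )
        report.antigenicity = "high" if high else "low"
    return report


def run_report(
    ligands: list[LigandInput],
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[list[LigandReport], dict]:
    """Execute the study analogue for every configured ligand.

    Stage failures mark the ligand as failed and the run continues.
    Returns the reports and a machine-readable summary; with
    ``out_dir`` set, ``report.json`` and ``report.txt`` are written
    there (the timestamp is isolated in the summary's ``generated_at``
    field, everything else is deterministic).
    """
    config = config or PipelineConfig()
    if not ligands:
        raise ConfigError("configuration lists no ligands")
    for lig in ligands:
        if not lig.trajectories and lig.sensorgrams is None:
            raise ConfigError(
                f"ligand {lig.label!r} has neither trajectories nor sensorgrams"
            )

    reports = []
    for lig in ligands:
        t0 = time.perf_counter()
        try:
            report = _analyse_ligand(lig, config)
        except ConfigError:
            raise
        except EpidynError as exc:
            logger.error("ligand %s failed: %s", lig.label, exc)
            report = LigandReport(label=lig.label, failed=True, error=str(exc))
        logger.info("ligand %s analysed in %.2f s", lig.label, time.perf_counter() - t0)
        reports.append(report)

    rankable = {
        r.label: r.pooled for r in reports if r.pooled is not None and not r.failed
    }
    ranking = rank_ligands(rankable) if len(rankable) >= 2 else sorted(rankable)

    summary = {
        "generated_at": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "parameters": {
            "target_residue": list(config.target_residue),
            "stride": config.stride,
            "probe_radius_A": config.sasa_params.probe_radius,
            "n_points": config.sasa_params.n_points,
            "exposed_min_A2": config.thresholds.exposed_min,
            "buried_max_A2": config.thresholds.buried_max,
            "call_threshold": config.call_threshold,
            "r2_threshold": config.r2_threshold,
        },
        "call_rule": (
            "high iff pooled exposed fraction >= call_threshold and K_D determined "
            "(rule-based operationalisation)"
        ),
        "ranking_by_exposed_fraction": ranking,
        "ligands": [r.to_dict() for r in reports],
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(summary, indent=2))
        (out / "report.txt").write_text(_format_text(reports, ranking))
    return reports, summary


def _format_text(reports: list[LigandReport], ranking: list[str]) -> str:
    lines = ["epidyn antigenic-strength report", "=" * 34, ""]
    for r in reports:
        lines.append(f"ligand {r.label}")
        if r.failed:
            lines.append(f"  FAILED: {r.error}")
            lines.append("")
            continue
        for s in r.per_run:
            lines.append(
                f"  {s.label}: exposed {s.fractions['exposed']:.3f} "
                f"transition {s.fractions['transition']:.3f} "
                f"buried {s.fractions['buried']:.3f} "
                f"({s.n_changes} changes, mean ASA {s.mean_asa:.1f} A^2)"
            )
        if r.pooled is not None:
            lines.append(f"  pooled exposed fraction: {r.pooled_exposed_fraction:.3f}")
        if r.kD is not None:
            lines.append(f"  K_D: {r.kD * 1e6:.1f} uM (R2 {r.fit.r_squared:.3f})")
        else:
            lines.append(f"  K_D: not determined ({r.kD_reason})")
        if r.static_gly1_asa is not None:
            lines.append(f"  static Gly1 ASA: {r.static_gly1_asa:.1f} A^2")
        if r.reachability is not None:
            lines.append(
                f"  E101-Gly1 distance: {r.reachability.distance:.2f} A "
                f"({'reachable' if r.reachability.reachable else 'unreachable'})"
            )
        lines.append(f"  antigenicity call: {r.antigenicity}")
        lines.append("")
    lines.append("ranking by exposed fraction: " + ", ".join(ranking))
    lines.append("")
    return "\n".join(lines)
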