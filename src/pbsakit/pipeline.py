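"""End-to-end MM-PBSA orchestration: preparation, energy calculation, analysis.

The pipeline walks a trajectory frame by frame under the
single-trajectory protocol, computing for each snapshot the inter-group
electrostatic (optionally Debye-Hueckel screened) and Lennard-Jones
energies, the polar solvation difference from the linear
Poisson-Boltzmann solver and the non-polar difference from the SASA
model; it then assembles

    dH(i)  = dE_elec(i) + dE_vdW(i) + ddG_polar(i) + ddG_nonpolar(i),
    dG     = <dH> + (-T dS),

with the entropy term from the interaction-entropy method, and writes a
summary, per-frame and per-residue tables, a B-factor PDB and a
machine-readable results file.  Frame evaluations are independent, so the
reduction order is fixed and results do not depend on evaluation order.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .decomposition import residue_table, write_bfactor_pdb
from .errors import ResultsCompatibilityError, ValidationError
from .mm import ScreeningParams, mm_terms
from .pb import PBParams, binding_polar
from .sasa import SasaParams, binding_nonpolar
from .thermo import FrameSeries, Summary, correlations, ki_to_dg, summarize
from .topology import Topology, load_topology, resolve_groups
from .trajectory import Frame, check_pbc_artifacts, read_frames

logger = logging.getLogger(__name__)

RESULTS_FORMAT_VERSION = 1


@dataclass
class RunConfig:
    """Fully resolved run settings (mirrors the YAML configuration file)."""

    trajectory_path: str
    topology_path: str
    index_path: str | None = None
    receptor_spec: str = "receptor"
    ligand_spec: str = "ligand"
    frame_range: tuple[int, int | None, int] | None = None
    temperature: float = 298.15
    screening: ScreeningParams = field(default_factory=ScreeningParams)
    pb: PBParams = field(default_factory=PBParams)
    sasa: SasaParams = field(default_factory=SasaParams)
    combining: str = "geometric"
    alanine_scan: list[int] = field(default_factory=list)
    output_dir: str = "pbsakit_out"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["screening"]["ion_species"] = [list(s) for s in self.screening.ion_species]
        d["pb"]["ion_species"] = [list(s) for s in self.pb.ion_species]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, typ in (("screening", ScreeningParams), ("pb", PBParams), ("sasa", SasaParams)):
            if isinstance(d.get(key), dict):
                sub = dict(d[key])
                if "ion_species" in sub:
                    sub["ion_species"] = [tuple(s) for s in sub["ion_species"]]
                d[key] = typ(**sub)
        if d.get("frame_range") is not None:
            d["frame_range"] = tuple(d["frame_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


DEFAULT_CONFIG_TEMPLATE = """\
# pbsakit configuration (all energies kcal/mol, lengths Angstrom)
trajectory_path: traj.pdb        # multi-MODEL PDB or concatenated GRO
topology_path: system.top        # per-atom sidecar (charges, LJ, radii, groups)
index_path: null                 # optional GROMACS .ndx with receptor/ligand
receptor_spec: receptor          # ndx group name or "resid A-B"
ligand_spec: ligand
frame_range: null                # e.g. [0, null, 10] for every 10th frame
temperature: 298.15
screening:
  enabled: false                 # Debye-Hueckel damping of the Coulomb term
  epsilon_in: 1.0
  epsilon_solvent: 80.0
  ion_species: [[0.15, 1], [0.15, -1]]   # mol/L, integer charge
pb:
  epsilon_in: 2.0
  epsilon_solvent: 80.0
  ion_species: []
  grid_spacing: 0.5
  grid_margin: 10.0
  probe_radius_ion: 2.0
  tolerance: 1.0e-6
sasa:
  probe_radius: 1.4
  n_sphere_points: 960
  gamma: 0.00542
  offset_b: 0.92
  offset_mode: per_species
combining: geometric             # LJ cross terms: geometric | lorentz_berthelot
alanine_scan: []                 # receptor residue_ids to truncate, e.g. [12, 47]
output_dir: pbsakit_out
"""


@dataclass
class ResultBundle:
    """Everything a run produces, recomputable from the embedded config."""

    series: FrameSeries
    summary: Summary
    residues: pd.DataFrame
    per_atom_terms: dict[str, dict[int, float]]
    config: RunConfig
    output_dir: Path | None = None


def compute_series(
    frames: Sequence[Frame],
    topology: Topology,
    screening: ScreeningParams | None = None,
    pb_params: PBParams | None = None,
    sasa_params: SasaParams | None = None,
    combining: str = "geometric",
    collect_per_atom: bool = False,
):
    """Per-frame energy terms for a resolved system.

    Returns a FrameSeries, or ``(FrameSeries, per_atom_terms)`` with
    trajectory-averaged per-atom maps when ``collect_per_atom`` is set.
    """
    topology.require_groups()
    screening = screening or ScreeningParams()
    pb_params = pb_params or PBParams()
    sasa_params = sasa_params or SasaParams()

    times, elec_s, vdw_s, polar_s, np_s = [], [], [], [], []
    acc: dict[str, dict[int, float]] = {
        t: {a.atom_id: 0.0 for a in topology.atoms}
        for t in ("elec", "vdw", "polar", "nonpolar")
    }
    for frame in frames:
        check_pbc_artifacts(frame, topology)
        elec, vdw, _ = mm_terms(frame, topology, screening, combining)
        dg_pol, pol_atoms = binding_polar(frame, topology, pb_params)
        dg_np, np_atoms = binding_nonpolar(frame, topology, sasa_params)
        times.append(frame.time)
        elec_s.append(elec.total)
        vdw_s.append(vdw.total)
        polar_s.append(dg_pol)
        np_s.append(dg_np)
        if collect_per_atom:
            for term, per in (
                ("elec", elec.per_atom),
                ("vdw", vdw.per_atom),
                ("polar", pol_atoms),
                ("nonpolar", np_atoms),
            ):
                for aid, v in per.items():
                    acc[term][aid] += v
    series = FrameSeries(
        times=np.array(times),
        elec=np.array(elec_s),
        vdw=np.array(vdw_s),
        polar=np.array(polar_s),
        nonpolar=np.array(np_s),
    )
    if not collect_per_atom:
        return series
    n = len(frames)
    per_atom_terms = {
        term: {aid: v / n for aid, v in per.items()} for term, per in acc.items()
    }
    return series, per_atom_terms


def _summary_text(summary: Summary) -> str:
    labels = {
        "dh": "dH",
        "e_mm": "dE_MM",
        "polar": "ddG_polar",
        "nonpolar": "ddG_nonpolar",
        "elec": "dE_elec",
        "vdw": "dE_vdW",
    }
    lines = ["term            mean (kcal/mol)        sd", "-" * 48]
    for key, label in labels.items():
        lines.append(
            f"{label:<14s}{summary.mean[key]:>14.4f}{summary.sd[key]:>12.4f}"
        )
    lines.append(f"{'-T dS':<14s}{summary.minus_t_delta_s:>14.4f}{'':>12s}")
    lines.append(f"{'dG':<14s}{summary.delta_g:>14.4f}{'':>12s}")
    return "\n".join(lines)


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Execute the full three-step workflow and write all outputs."""
    topology = load_topology(config.topology_path)
    topology.temperature = config.temperature
    if topology.receptor_group is None or config.index_path:
        topology = resolve_groups(
            topology, config.receptor_spec, config.ligand_spec, config.index_path
        )
    frames = read_frames(config.trajectory_path, frame_range=config.frame_range)
    if frames[0].n_atoms != topology.n_atoms:
        raise ValidationError(
            f"trajectory has {frames[0].n_atoms} atoms but topology has "
            f"{topology.n_atoms}"
        )

    series, per_atom_terms = compute_series(
        frames,
        topology,
        config.screening,
        config.pb,
        config.sasa,
        config.combining,
        collect_per_atom=True,
    )
    summary = summarize(series, config.temperature)
    residues = residue_table(per_atom_terms, topology)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "summary.txt").write_text(_summary_text(summary) + "\n")
    pd.DataFrame(
        {
            "time_ps": series.times,
            "elec": series.elec,
            "vdw": series.vdw,
            "polar": series.polar,
            "nonpolar": series.nonpolar,
            "e_mm": series.e_mm,
            "dh": series.dh,
        }
    ).to_csv(out / "frames.csv", index=False, float_format="%.4f")
    residues.to_csv(out / "residues.csv", index=False, float_format="%.4f")

    total_per_atom = {
        a.atom_id: sum(per_atom_terms[t][a.atom_id] for t in per_atom_terms)
        for a in topology.atoms
    }
    from .decomposition import residue_decompose

    write_bfactor_pdb(
        frames[0],
        topology,
        residue_decompose(total_per_atom, topology),
        out / "bfactor.pdb",
    )

    results = {
        "format_version": RESULTS_FORMAT_VERSION,
        "pbsakit_version": __version__,
        "config": config.to_dict(),
        "series": {
            k: [float(v) for v in getattr(series, k)]
            for k in ("times", "elec", "vdw", "polar", "nonpolar")
        },
        "summary": {
            "mean": summary.mean,
            "sd": summary.sd,
            "minus_t_delta_s": summary.minus_t_delta_s,
            "delta_g": summary.delta_g,
            "temperature": summary.temperature,
        },
        "residues": residues.to_dict(orient="records"),
    }
    (out / "results.yaml").write_text(yaml.safe_dump(results, sort_keys=False))

    if config.alanine_scan:
        from .alanine import alanine_scan

        wt, mutants = alanine_scan(
            frames,
            topology,
            config.alanine_scan,
            config.screening,
            config.pb,
            config.sasa,
            config.combining,
        )
        rows = []
        for rid, mut in mutants.items():
            if mut is None:
                rows.append({"residue_id": rid, "term": "all", "wt": np.nan,
                             "mutant": np.nan, "delta": np.nan})
                continue
            for term in ("elec", "vdw", "polar", "nonpolar", "dh"):
                rows.append(
                    {
                        "residue_id": rid,
                        "term": term,
                        "wt": wt.mean[term],
                        "mutant": mut.mean[term],
                        "delta": mut.mean[term] - wt.mean[term],
                    }
                )
            rows.append(
                {
                    "residue_id": rid,
                    "term": "dg",
                    "wt": wt.delta_g,
                    "mutant": mut.delta_g,
                    "delta": mut.delta_g - wt.delta_g,
                }
            )
        pd.DataFrame(rows).to_csv(out / "alanine_scan.csv", index=False,
                                  float_format="%.4f")

    return ResultBundle(
        series=series,
        summary=summary,
        residues=residues,
        per_atom_terms=per_atom_terms,
        config=config,
        output_dir=out,
    )


def analyze(
    results_path: str | Path, experimental: pd.DataFrame | str | Path | None = None
) -> dict:
    """Re-render a previous run's summary without recomputation.

    Optionally correlates predicted dG/dH against an experimental table
    holding either a ``dg_expr`` column or a ``ki`` column (mol/L, converted
    via dG = RT ln K_i).  The table must carry one row per system keyed in
    file order; correlation needs >= 3 systems.
    """
    results_path = Path(results_path)
    if not results_path.exists():
        raise FileNotFoundError(f"results file not found: {results_path}")
    data = yaml.safe_load(results_path.read_text())
    if data.get("format_version") != RESULTS_FORMAT_VERSION:
        raise ResultsCompatibilityError(
            f"results file format {data.get('format_version')} != "
            f"{RESULTS_FORMAT_VERSION}"
        )
    series = FrameSeries(
        times=np.array(data["series"]["times"]),
        elec=np.array(data["series"]["elec"]),
        vdw=np.array(data["series"]["vdw"]),
        polar=np.array(data["series"]["polar"]),
        nonpolar=np.array(data["series"]["nonpolar"]),
    )
    summary = summarize(series, data["summary"]["temperature"])
    report = {
        "summary_text": _summary_text(summary),
        "summary": data["summary"],
        "recomputed_delta_g": summary.delta_g,
        "residues": data["residues"],
    }
    if experimental is not None:
        table = (
            experimental
            if isinstance(experimental, pd.DataFrame)
            else pd.read_csv(experimental)
        )
        if "dg_expr" not in table.columns:
            if "ki" not in table.columns:
                raise ValidationError("experimental table needs a 'ki' or 'dg_expr' column")
            temp = data["summary"]["temperature"]
            table = table.assign(dg_expr=[ki_to_dg(k, temp) for k in table["ki"]])
        report["experimental"] = table.to_dict(orient="records")
        if "dg_pred" in table.columns and len(table) >= 3:
            report["correlations"] = dict(
                zip(
                    ("pearson", "spearman", "kendall_tau"),
                    correlations(table["dg_pred"], table["dg_expr"]),
                )
            )
    return report
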