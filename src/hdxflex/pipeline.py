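"""End-to-end orchestration.

The HDX differential pipeline (state table -> ΔHDX records -> global
threshold -> protection calls -> per-residue map -> B-factor PDB), the
trajectory geometry pipeline (RMSD/RMSF, distance/angle probability
curves, bond occupancy), experiment-design helpers for 1:1 binding
occupancy, and the optional crystal-structure cross-validation.

Pipelines are pure functions of (inputs, config, seed): reruns produce
byte-identical outputs, and every numeric decision (alpha, thresholds,
cutoffs) is recorded in the run log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import differential as diff
from . import geometry as geom
from .hdx import PeptideRecord, UptakeMeasurement, read_state_table
from .differential import DeltaRecord, SignificanceConfig

__all__ = [
    "RunConfig",
    "BindingParameters",
    "fraction_bound",
    "ligand_for_occupancy",
    "run_hdx_pipeline",
    "run_traj_pipeline",
    "validate_crystal",
]

log = logging.getLogger("hdxflex")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (file < CLI-override precedence)."""

    input_paths: list[str] = field(default_factory=list)
    free_state: str = "free"
    bound_state: str = "bound"
    exposures: list[float] | None = None
    alpha: float = 0.05
    threshold_da: float | None = None
    domains: geom.DomainDefinition = field(default_factory=geom.DomainDefinition)
    out_dir: str = "results"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        dom = data.pop("domains", None)
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        if dom is not None:
            cfg.domains = geom.DomainDefinition(
                tuple(dom["ntd"]), tuple(dom["linker"]), tuple(dom["ctd"])
            )
        return cfg


# ---------------------------------------------------------------------------
# binding occupancy design helpers (1:1 model)


@dataclass(frozen=True)
class BindingParameters:
    """1:1 binding system: dissociation constant and total concentrations,
    all in molar."""

    kd: float
    protein_conc: float
    ligand_conc: float

    def __post_init__(self) -> None:
        if self.kd <= 0 or self.protein_conc <= 0 or self.ligand_conc < 0:
            raise ValueError("Kd and protein_conc must be > 0; ligand_conc >= 0")


def fraction_bound(params: BindingParameters) -> float:
    """Equilibrium fraction of protein in complex from the 1:1 binding
    quadratic: [PL] is the physical root of
    ``PL^2 - (P+L+Kd) PL + P L = 0`` and ``f = [PL]/P``."""
    p, l, kd = params.protein_conc, params.ligand_conc, params.kd
    if l == 0:
        return 0.0
    s = p + l + kd
    pl = (s - np.sqrt(s * s - 4.0 * p * l)) / 2.0
    return float(pl / p)


def ligand_for_occupancy(kd: float, protein_conc: float, target_f: float) -> float:
    """Total ligand concentration achieving a target bound fraction:
    ``L = f P + Kd f / (1 - f)`` (e.g. the molar excess ensuring >90%
    occupancy in a binding HDX experiment)."""
    if not (0.0 < target_f < 1.0):
        raise ValueError("target fraction must lie in (0, 1)")
    if kd <= 0 or protein_conc <= 0:
        raise ValueError("Kd and protein_conc must be positive")
    return target_f * protein_conc + kd * target_f / (1.0 - target_f)


# ---------------------------------------------------------------------------
# HDX differential pipeline


def _measurements_from_rows(rows: pd.DataFrame) -> list[UptakeMeasurement]:
    out = []
    for _, r in rows.iterrows():
        pep = PeptideRecord(r["sequence"], int(r["start"]), int(r["end"]))
        out.append(
            UptakeMeasurement(
                peptide=pep,
                state=str(r["state"]),
                exposure_s=float(r["exposure_s"]),
                replicate=int(r["replicate"]),
                uptake_da=float(r["uptake_da"]),
            )
        )
    return out


def run_hdx_pipeline(
    config: RunConfig,
    table: pd.DataFrame | None = None,
    structure: geom.Structure | None = None,
) -> dict:
    """Differential HDX pipeline on a peptide state table.

    Groups the table by (peptide, exposure), forms ΔHDX records between
    the configured free and bound states, derives the global confidence
    threshold from replicate scatter (unless overridden), makes
    protection/deprotection calls per peptide, consolidates the summed
    fractional differences onto residues, and writes tidy CSVs (plus a
    B-factor-annotated PDB when a structure is supplied) under
    ``config.out_dir``.  Returns the result bundle as a dict.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if table is None:
        frames = [read_state_table(p) for p in config.input_paths]
        table = pd.concat(frames, ignore_index=True)

    states = set(table["state"])
    for s in (config.free_state, config.bound_state):
        if s not in states:
            raise ValueError(f"state {s!r} absent from table (found {sorted(states)})")

    exposures = (
        config.exposures
        if config.exposures is not None
        else sorted(table["exposure_s"].unique())
    )

    deltas: list[DeltaRecord] = []
    keys: list[tuple] = []
    for (seq, start, end), pep_rows in table.groupby(["sequence", "start", "end"]):
        for t in exposures:
            rows_t = pep_rows[pep_rows["exposure_s"] == t]
            free_rows = rows_t[rows_t["state"] == config.free_state]
            bound_rows = rows_t[rows_t["state"] == config.bound_state]
            if len(free_rows) < 2 or len(bound_rows) < 2:
                continue
            rec = diff.delta_hdx(
                _measurements_from_rows(free_rows),
                _measurements_from_rows(bound_rows),
            )
            deltas.append(rec)
            keys.append((seq, int(start), int(end)))
    if not deltas:
        raise ValueError("no (peptide, exposure) groups with n >= 2 in both states")

    threshold = (
        config.threshold_da
        if config.threshold_da is not None
        else diff.global_confidence_threshold(deltas, alpha=config.alpha)
    )
    sig = SignificanceConfig(alpha=config.alpha, threshold_da=threshold)
    for rec in deltas:
        rec.significant = (rec.p_value < sig.alpha) and (
            abs(rec.delta_da) > threshold
        )

    # per-peptide protection calls over the exposure ladder
    calls = {}
    by_pep: dict[tuple, list[DeltaRecord]] = {}
    for key, rec in zip(keys, deltas):
        by_pep.setdefault(key, []).append(rec)
    for key, recs in sorted(by_pep.items(), key=lambda kv: (kv[0][1], kv[0][2])):
        label, flag = diff.classify_protection(recs, sig)
        calls[key] = (label, flag, recs)

    # summed fractional differences -> per-residue map
    map_exposures = [t for t in (60.0, 600.0) if t in set(exposures)] or list(
        exposures
    )
    pep_values = []
    summary_rows = []
    for (seq, start, end), (label, flag, recs) in calls.items():
        pep = recs[0].peptide
        have = [t for t in map_exposures if any(r.exposure_s == t for r in recs)]
        sfd = (
            diff.summed_fractional_difference(recs, have) if have else float("nan")
        )
        pep_values.append((pep, sfd))
        summary_rows.append(
            {
                "sequence": seq,
                "start": start,
                "end": end,
                "call": label,
                "flag": flag,
                "summed_fractional_diff_pct": sfd,
                "min_p": min(r.p_value for r in recs),
                "max_abs_delta_da": max(abs(r.delta_da) for r in recs),
            }
        )
    protein_length = int(table["end"].max())
    per_residue = diff.residue_consolidate(
        [(p, v) for p, v in pep_values if np.isfinite(v)], protein_length
    )

    delta_df = diff.delta_table(deltas)
    summary_df = pd.DataFrame(summary_rows)
    residue_df = per_residue.rename("summed_fractional_diff_pct").reset_index()

    delta_df.to_csv(out_dir / "delta_records.csv", index=False, float_format="%.6f")
    summary_df.to_csv(
        out_dir / "protection_summary.csv", index=False, float_format="%.6f"
    )
    residue_df.to_csv(out_dir / "per_residue.csv", index=False, float_format="%.6f")

    bfactor_path = None
    if structure is not None:
        bfactor_path = out_dir / "per_residue_map.pdb"
        scores = {
            int(r): float(v) for r, v in per_residue.items() if np.isfinite(v)
        }
        geom.write_bfactor(structure, scores, bfactor_path)

    run_log = {
        "alpha": config.alpha,
        "threshold_da": float(threshold),
        "threshold_source": "override" if config.threshold_da is not None else "computed",
        "exposures": [float(t) for t in exposures],
        "map_exposures": [float(t) for t in map_exposures],
        "free_state": config.free_state,
        "bound_state": config.bound_state,
        "n_delta_records": len(deltas),
        "seed": config.seed,
    }
    with open(out_dir / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True)
        fh.write("\n")
    for k, v in run_log.items():
        log.info("hdx-pipeline %s = %s", k, v)

    return {
        "deltas": deltas,
        "delta_table": delta_df,
        "summary": summary_df,
        "per_residue": per_residue,
        "threshold_da": float(threshold),
        "bfactor_pdb": bfactor_path,
        "run_log": run_log,
    }


# ---------------------------------------------------------------------------
# trajectory geometry pipeline


def run_traj_pipeline(
    traj: geom.Trajectory,
    config: RunConfig | None = None,
    reference: geom.Structure | None = None,
    bonds: Sequence[tuple] = (),
    out_dir: str | Path | None = None,
) -> dict:
    """Trajectory geometry pipeline: RMSD to a reference (first frame by
    default), per-residue RMSF, interdomain distance/angle series with
    ECDF probability curves and summary statistics, and bond-occupancy
    entries for ``bonds`` given as
    ``(resid_i, atoms_i, resid_j, atoms_j, kind)`` tuples.
    """
    config = config or RunConfig()
    out = Path(out_dir) if out_dir is not None else Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ref = reference if reference is not None else traj.frame(0)

    rmsd = geom.rmsd_series(traj, ref)
    rmsf = geom.rmsf_per_residue(traj)
    dist = geom.geometry_series(traj, "distance", config.domains)
    ang = geom.geometry_series(traj, "angle", config.domains)

    series_df = pd.DataFrame(
        {
            "time_ns": np.arange(traj.n_frames) * traj.frame_spacing_ns,
            "rmsd_A": rmsd.values,
            "distance_A": dist.values,
            "angle_deg": ang.values,
        }
    )
    series_df.to_csv(out / "geometry_series.csv", index=False, float_format="%.6f")
    rmsf.to_csv(out / "rmsf.csv", index=False, float_format="%.6f")
    geom.probability_curve(dist).to_csv(
        out / "distance_ecdf.csv", index=False, float_format="%.6f"
    )
    geom.probability_curve(ang).to_csv(
        out / "angle_ecdf.csv", index=False, float_format="%.6f"
    )

    occupancy_rows = []
    for resid_i, atoms_i, resid_j, atoms_j, kind in bonds:
        occ, dseries = geom.bond_occupancy(
            traj, resid_i, resid_j, kind=kind, atoms_i=atoms_i, atoms_j=atoms_j
        )
        occupancy_rows.append(
            {
                "resid_i": resid_i,
                "resid_j": resid_j,
                "kind": kind,
                "occupancy": occ,
                "mean_distance_A": dseries.mean(),
            }
        )
    occupancy_df = pd.DataFrame(occupancy_rows)
    if len(occupancy_df):
        occupancy_df.to_csv(
            out / "bond_occupancy.csv", index=False, float_format="%.6f"
        )

    summary = {
        "n_frames": traj.n_frames,
        "rmsd_mean_A": rmsd.mean(),
        "distance_mean_A": dist.mean(),
        "distance_sd_A": dist.sd(),
        "angle_mean_deg": ang.mean(),
        "angle_sd_deg": ang.sd(),
        "hbond_cutoff_A": geom.HBOND_CUTOFF_A,
        "saltbridge_cutoff_A": geom.SALTBRIDGE_CUTOFF_A,
    }
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    for k, v in summary.items():
        log.info("traj-pipeline %s = %s", k, v)

    return {
        "rmsd": rmsd,
        "rmsf": rmsf,
        "distance": dist,
        "angle": ang,
        "occupancy": occupancy_df,
        "summary": summary,
    }


# ---------------------------------------------------------------------------
# crystal-structure cross validation


def validate_crystal(
    complex_a_path, complex_b_path, chain_pairing: str = "aligned"
) -> dict:
    """Cα RMSD comparison of two homologous complexes (e.g. the same
    inhibitor bound to two related enzymes).

    Reports both pairing options: the whole complexes superposed on all
    common Cα atoms, and the inhibitor chains alone (first chain of each
    file) superposed on their own Cα atoms.  Requires local PDB files.
    """
    ta = geom.read_pdb(complex_a_path)
    tb = geom.read_pdb(complex_b_path)
    sa, sb = ta.frame(0), tb.frame(0)
    _, _, rmsd_complex = geom.superpose_structures(
        sa, sb, mode=chain_pairing, atom_names=("CA",)
    )
    chain_a = sa.subset(sa.chains == sa.chains[0])
    chain_b = sb.subset(sb.chains == sb.chains[0])
    _, _, rmsd_chain = geom.superpose_structures(
        chain_a, chain_b, mode=chain_pairing, atom_names=("CA",)
    )
    return {
        "rmsd_all_ca_complex_A": rmsd_complex,
        "rmsd_first_chain_ca_A": rmsd_chain,
        "pairing": chain_pairing,
    }
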