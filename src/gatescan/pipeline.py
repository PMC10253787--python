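"""Two-state comparison pipeline: one config in, one report out.

Runs every analysis stage (superposition/RMSF, pore profile and
permeability, gyration, twist angles, distance matrices, H-bond
occupancy, dihedral PCA) for each labeled state, then all pairwise state
comparisons (ΔRMSF/RMSF̄, distance-difference and correlation maps,
differential H-bonds), writing stage CSVs under ``out_dir/<state>/`` and
a consolidated ``report.json``.  A stage failure is recorded in the
report and does not abort the other stages.  Given fixed inputs the run
is deterministic.
"""

from __future__ import annotations

import json
import logging
import traceback
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    dihedral_pca,
    domain_geometry,
    hbond,
    pore_profile,
    structure_io,
    superpose_fluct,
)
from .errors import EmptySelectionError, GatescanError

logger = logging.getLogger(__name__)

__all__ = ["StateInput", "RunConfig", "Report", "snapshot_select", "run_pipeline",
           "load_config"]


@dataclass
class StateInput:
    label: str
    topology: str
    trajectory: str


@dataclass
class RunConfig:
    """Analysis constants with defaults mirroring the studied system."""

    states: list = field(default_factory=list)          # StateInput items
    out_dir: str = "gatescan_out"
    fit_spec: str = superpose_fluct.DEFAULT_FIT_SPEC    # residues 432-713, backbone
    s6_range: tuple = domain_geometry.DEFAULT_S6_RANGE  # residues 658-692
    pore_spec: str = "protein"
    rg_regions: dict = field(default_factory=dict)      # label -> selection spec
    z_range: tuple = (-10.0, 10.0)
    z_step: float = 0.25
    lateral_bound: float = 8.0
    permeability_threshold: float = pore_profile.DEFAULT_PERMEABILITY_THRESHOLD
    hbond_max_ad: float = 3.0
    hbond_min_angle: float = 135.0
    differential_threshold: float = hbond.DEFAULT_DIFFERENTIAL_THRESHOLD
    temperature: float = dihedral_pca.DEFAULT_TEMPERATURE_K
    last_ns: float | None = None
    stride_ps: float | None = None
    pca_chains: list | None = None
    distance_chain: str = "A"
    upper_gate_z: float | None = None
    lower_gate_z: float | None = None
    upper_gate_residues: tuple = (643, 644)   # selectivity filter G643–M644
    lower_gate_residue: int = 679             # S6 bundle crossing I679
    seed: int = 0
    plots: bool = False


@dataclass
class Report:
    per_state: dict
    comparisons: dict
    stages: dict

    def to_json(self) -> str:
        return json.dumps({"per_state": self.per_state,
                           "comparisons": self.comparisons,
                           "stages": self.stages}, indent=1, sort_keys=True)


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML; unspecified keys keep their defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    states = [StateInput(**s) for s in raw.pop("states", [])]
    cfg = RunConfig(states=states)
    for key, value in raw.items():
        if not hasattr(cfg, key):
            raise GatescanError(f"unknown config key '{key}'")
        if key in ("s6_range", "z_range") and value is not None:
            value = tuple(value)
        setattr(cfg, key, value)
    return cfg


def snapshot_select(traj: structure_io.Trajectory, last_ns: float,
                    stride_ps: float | None = None) -> structure_io.Trajectory:
    """Frames from the trailing ``last_ns`` window at the requested stride.

    A window longer than the trajectory keeps the whole trajectory with a
    warning; ``last_ns = 0`` is an error.
    """
    if last_ns <= 0:
        raise EmptySelectionError("snapshot window must be positive")
    total_ps = traj.n_frames * traj.stride_ps
    window_ps = last_ns * 1000.0
    if window_ps >= total_ps:
        if window_ps > total_ps:
            warnings.warn("snapshot window longer than trajectory; keeping all frames")
        start = 0
    else:
        start = traj.n_frames - int(round(window_ps / traj.stride_ps))
    n_window = traj.n_frames - start
    if stride_ps is None or stride_ps <= traj.stride_ps:
        return traj.slice(start, None, 1)
    # map target times onto the nearest stored frames (the requested cadence
    # need not be an integer multiple of the stored one)
    n_out = int(round(n_window * traj.stride_ps / stride_ps))
    idx = np.round(np.arange(n_out) * stride_ps / traj.stride_ps).astype(int)
    idx = start + idx[idx < n_window]
    if idx.size == 0:
        raise EmptySelectionError("restriding selected no frames")
    return structure_io.Trajectory(traj.topology, traj.coordinates[idx].copy(),
                                   stride_ps=float(stride_ps))


def _mean_gate_z(traj, residues) -> float:
    top = traj.topology
    mask = np.isin(top.residue_number, np.atleast_1d(residues))
    if not mask.any():
        raise EmptySelectionError(f"gate residues {residues} not found")
    return float(traj.coordinates[:, mask, 2].mean())


def _run_stage(stages: dict, state: str, name: str, fn):
    try:
        result = fn()
        stages[f"{state}/{name}"] = "ok"
        return result
    except Exception as exc:
        logger.error("stage %s failed for %s: %s", name, state, exc)
        stages[f"{state}/{name}"] = f"failed: {exc}"
        stages[f"{state}/{name}/traceback"] = traceback.format_exc(limit=3)
        return None


def run_pipeline(config: RunConfig) -> Report:
    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    criteria = hbond.HBondCriteria(config.hbond_max_ad, config.hbond_min_angle)
    per_state: dict = {}
    stages: dict = {}
    cache: dict = {}

    for st in config.states:
        out = out_root / st.label
        out.mkdir(parents=True, exist_ok=True)
        summary: dict = {}
        traj = structure_io.read_trajectory(st.topology, st.trajectory,
                                            stride_ps=config.stride_ps)
        if config.last_ns:
            traj = snapshot_select(traj, config.last_ns, config.stride_ps)
        logger.info("state %s: %d frames, %d atoms, stride %.1f ps",
                    st.label, traj.n_frames, traj.n_atoms, traj.stride_ps)

        fit = structure_io.resolve_selection(traj.topology, config.fit_spec)
        sup = superpose_fluct.superpose(traj, fit)
        cache[st.label] = {"traj": sup}

        def stage_rmsf(sup=sup, fit=fit, out=out, label=st.label):
            prof = superpose_fluct.rmsf_profile(sup, state_label=label)
            avg = superpose_fluct.chain_average(prof)
            pd.DataFrame({"chain": [k[0] for k in prof.residue_keys],
                          "residue": [k[1] for k in prof.residue_keys],
                          "rmsf": prof.rmsf}).to_csv(out / "rmsf.csv", index=False)
            pd.DataFrame({"residue": [k[1] for k in avg.residue_keys],
                          "rmsf": avg.rmsf}).to_csv(out / "rmsf_chain_mean.csv", index=False)
            rmsd = superpose_fluct.rmsd_series(sup, fit)
            pd.DataFrame({"frame": np.arange(len(rmsd)), "rmsd": rmsd}
                         ).to_csv(out / "rmsd.csv", index=False)
            return prof, avg, rmsd

        res = _run_stage(stages, st.label, "fluct", stage_rmsf)
        if res:
            prof, avg, rmsd = res
            cache[st.label]["rmsf"] = prof
            cache[st.label]["rmsf_mean"] = avg
            summary["mean_rmsd"] = float(rmsd.mean())

        def stage_pore(sup=sup, out=out):
            psel = structure_io.resolve_selection(sup.topology, config.pore_spec)
            radii = structure_io.assign_vdw(sup.topology)
            profile = pore_profile.min_radius_series(
                sup, psel, radii, config.z_range, z_step=config.z_step,
                lateral_bound=config.lateral_bound)
            stats = pore_profile.permeable_fraction(profile, config.permeability_threshold)
            rows = []
            for f in range(profile.radius.shape[0]):
                for zi, z in enumerate(profile.z_grid):
                    rows.append((f, z, profile.radius[f, zi], profile.capped[f, zi]))
            pd.DataFrame(rows, columns=["frame", "z", "radius", "capped"]
                         ).to_csv(out / "pore.csv", index=False)
            pd.DataFrame({"frame": np.arange(len(profile.min_radius)),
                          "min_radius": profile.min_radius,
                          "min_radius_z": profile.min_radius_z}
                         ).to_csv(out / "pore_min.csv", index=False)
            return profile, stats

        res = _run_stage(stages, st.label, "pore", stage_pore)
        if res:
            profile, stats = res
            summary["mean_min_radius"] = float(profile.min_radius.mean())
            summary["permeable_fraction"] = stats.permeable_fraction

        def stage_flux(traj=traj, sup=sup, out=out):
            wsel = structure_io.resolve_selection(traj.topology, "water, atoms OW")
            uz = config.upper_gate_z
            lz = config.lower_gate_z
            if uz is None:
                uz = _mean_gate_z(sup, list(config.upper_gate_residues))
            if lz is None:
                lz = _mean_gate_z(sup, [config.lower_gate_residue])
            flux = pore_profile.count_permeations(traj, wsel, uz, lz)
            pd.DataFrame([vars(e) for e in flux.events]).to_csv(
                out / "permeations.csv", index=False)
            return flux

        res = _run_stage(stages, st.label, "water_flux", stage_flux)
        if res:
            summary["n_permeation_events"] = res.n_permeation_events

        def stage_rg(sup=sup, out=out):
            regions = config.rg_regions or {"all_heavy": "heavy"}
            rows = []
            out_rg = {}
            for label, spec in regions.items():
                sel = structure_io.resolve_selection(sup.topology, spec, label=label)
                series = domain_geometry.rg_series(sup, sel, label=label)
                out_rg[label] = float(series.rg.mean())
                rows.extend((f, label, v) for f, v in enumerate(series.rg))
            pd.DataFrame(rows, columns=["frame", "region", "rg"]
                         ).to_csv(out / "rg.csv", index=False)
            return out_rg

        res = _run_stage(stages, st.label, "rg", stage_rg)
        if res:
            summary["mean_rg"] = res

        def stage_twist(sup=sup, out=out):
            angles, chains = domain_geometry.twist_series(sup, config.s6_range)
            df = pd.DataFrame(angles, columns=chains)
            df.insert(0, "frame", np.arange(len(df)))
            df["mean"] = angles.mean(axis=1)
            df.to_csv(out / "twist.csv", index=False)
            return angles

        res = _run_stage(stages, st.label, "twist", stage_twist)
        if res is not None:
            summary["mean_twist_angle"] = float(res.mean())

        def stage_distance(sup=sup, out=out, label=st.label):
            dm = domain_geometry.distance_matrix(sup, config.distance_chain,
                                                 state_label=label)
            pd.DataFrame(dm.matrix, index=dm.residue_numbers,
                         columns=dm.residue_numbers).to_csv(out / "distance_matrix.csv")
            return dm

        res = _run_stage(stages, st.label, "distance", stage_distance)
        if res:
            cache[st.label]["distance"] = res

        def stage_hbond(traj=traj, out=out, label=st.label):
            records = hbond.occupancy(traj, criteria, state_label=label)
            pd.DataFrame([{"donor": r.donor, "hydrogen": r.hydrogen,
                           "acceptor": r.acceptor, "occupancy": r.occupancy}
                          for r in records]).to_csv(out / "hbonds.csv", index=False)
            return records

        res = _run_stage(stages, st.label, "hbond", stage_hbond)
        if res is not None:
            cache[st.label]["hbonds"] = res
            summary["n_hbonds"] = len(res)

        def stage_pca(sup=sup, out=out):
            series = dihedral_pca.extract_dihedrals(sup, chains=config.pca_chains)
            result = dihedral_pca.dpca(series, n_components=2)
            pd.DataFrame({"eigenvalue": result.eigenvalues}).to_csv(
                out / "eigenvalues.csv", index=False)
            proj = pd.DataFrame(result.projections, columns=["PC1", "PC2"])
            proj.insert(0, "frame", np.arange(len(proj)))
            proj.to_csv(out / "pca_projections.csv", index=False)
            fes = dihedral_pca.free_energy_surface(result.projections,
                                                   temperature=config.temperature)
            np.savetxt(out / "free_energy_surface.csv", fes.free_energy, delimiter=",")
            if config.plots:
                from .plots import plot_free_energy_surface
                plot_free_energy_surface(fes, out / "free_energy_surface.png")
            return result

        res = _run_stage(stages, st.label, "pca", stage_pca)
        if res:
            summary["pc_variance_fractions"] = [float(v) for v in
                                                res.explained_variance_ratio]
        per_state[st.label] = summary

    comparisons: dict = {}
    labels = [s.label for s in config.states]
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            pair = f"{a}_vs_{b}"
            out = out_root / pair
            out.mkdir(parents=True, exist_ok=True)
            comp: dict = {}

            if "rmsf_mean" in cache.get(a, {}) and "rmsf_mean" in cache.get(b, {}):
                def stage_drmsf(a=a, b=b, out=out):
                    fc = superpose_fluct.delta_rmsf(cache[a]["rmsf_mean"],
                                                    cache[b]["rmsf_mean"])
                    pd.DataFrame({"residue": [k[1] for k in fc.residue_keys],
                                  "delta_frac": fc.delta_frac}
                                 ).to_csv(out / "delta_rmsf.csv", index=False)
                    return fc
                fc = _run_stage(stages, pair, "delta_rmsf", stage_drmsf)
                if fc:
                    k = int(np.argmax(np.abs(fc.delta_frac)))
                    comp["max_abs_delta_rmsf"] = float(np.abs(fc.delta_frac).max())
                    comp["peak_residue"] = int(fc.residue_keys[k][1])

            if "distance" in cache.get(a, {}) and "distance" in cache.get(b, {}):
                def stage_dd(a=a, b=b, out=out):
                    sc = domain_geometry.compare_states(cache[a]["distance"],
                                                        cache[b]["distance"])
                    pd.DataFrame(sc.delta, index=sc.residue_numbers,
                                 columns=sc.residue_numbers
                                 ).to_csv(out / "distance_difference.csv")
                    pd.DataFrame(sc.correlation, index=sc.residue_numbers,
                                 columns=sc.residue_numbers
                                 ).to_csv(out / "correlation_map.csv")
                    if config.plots:
                        from .plots import plot_heatmap
                        plot_heatmap(sc.delta, sc.residue_numbers,
                                     out / "distance_difference.png",
                                     title=f"ΔD {a} − {b} (Å)")
                    return sc
                sc = _run_stage(stages, pair, "distance_difference", stage_dd)
                if sc:
                    comp["max_abs_delta_distance"] = float(np.abs(sc.delta).max())

            if "hbonds" in cache.get(a, {}) and "hbonds" in cache.get(b, {}):
                def stage_dh(a=a, b=b, out=out):
                    df = hbond.differential(cache[a]["hbonds"], cache[b]["hbonds"],
                                            config.differential_threshold)
                    df.to_csv(out / "differential_hbonds.csv", index=False)
                    return df
                df = _run_stage(stages, pair, "differential_hbonds", stage_dh)
                if df is not None:
                    comp["n_differential_hbonds"] = int(len(df))

            comparisons[pair] = comp

    report = Report(per_state, comparisons, stages)
    (out_root / "report.json").write_text(report.to_json())
    return report
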