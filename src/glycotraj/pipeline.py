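"""End-to-end analysis orchestration on one simulated system.

Runs the full table/figure suite over one or more runs (replica
trajectories) of a system: RMSD series, RMSF profile (with B-factor
comparison when the reference carries B-factors), Schlitter entropy under
both fit conventions with between-run standard deviations, ligand-
surrounding energies with block-averaged, propagated errors, the
hydrogen-bond occupancy table with its grand total, and virtual-HC/N5 and
histidine-hydroxyl distance distributions with below-cutoff fractions.

Aggregation conventions over runs, encoded once: entropies as mean +/-
between-run SD; energies as mean of run means with errors propagated in
quadrature; occupancies as arithmetic means of row percentages.

Every stage appends one structured entry (seed, package version,
parameters) to ``log.jsonl`` in the bundle directory; any stage failure
aborts the bundle and removes partial outputs.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import energetics, entropy, interactions, superpose
from ._version import __version__ as _version
from .model_io import FrameStream, Selection, Topology, read_pdb, \
    read_trajectory, select
from .synthetic import TwoPoseSpec, gen_two_pose_trajectory

__all__ = ["AnalysisConfig", "run_paper_suite", "load_config"]

_DEFAULT_SELECTIONS = {
    "ligand": "resname GLC",
    "backbone": "backbone",
    "fad_n5": "resname FAD and name N5",
    "his_512": "resid 512 and name ND1 NE2",
    "his_556": "resid 556 and name ND1 NE2",
}


@dataclass
class AnalysisConfig:
    """Configuration of one system's analysis (YAML-loadable)."""

    system: str = "PP_A"
    runs: list[dict] = field(default_factory=lambda: [{"seed": 1}, {"seed": 2}])
    output_dir: str = "results/pipeline"
    temperature: float = 300.0
    n_frames: int = 2000
    pose_fraction: float = 0.85
    selections: dict = field(default_factory=dict)
    hc_sites: list[str] = field(default_factory=lambda: ["HC1", "HC2", "HC3", "HC4"])
    hbond_distance: float = 0.25
    hbond_angle: float = 135.0
    proximity_cutoff: float = 0.3
    histogram_bin: float = 0.005

    def __post_init__(self):
        merged = dict(_DEFAULT_SELECTIONS)
        merged.update(self.selections)
        self.selections = merged
        if not self.runs:
            raise ValueError("at least one run is required")


def load_config(path) -> AnalysisConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return AnalysisConfig(**data)


def _load_run(cfg: AnalysisConfig, run: dict) -> tuple[Topology, FrameStream]:
    if "traj" in run:
        topology, _ = read_pdb(run["topology"])
        return topology, read_trajectory(run["traj"], topology)
    spec = TwoPoseSpec(n_frames=cfg.n_frames, pose_fraction=cfg.pose_fraction,
                       seed=int(run.get("seed", 0)))
    topology, stream, _ = gen_two_pose_trajectory(spec)
    return topology, stream


def run_paper_suite(config: AnalysisConfig) -> Path:
    """Run every stage for every run of the system; returns the bundle dir."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "log.jsonl"
    log_fh = open(log_path, "w")

    def log(stage: str, **params):
        entry = {"stage": stage, "system": config.system,
                 "version": _version, **params}
        log_fh.write(json.dumps(entry, sort_keys=True) + "\n")

    try:
        runs = []
        for run in config.runs:
            topology, stream = _load_run(config, run)
            runs.append((run, topology, stream))

        # fail fast: all selections must resolve before any stage runs
        sels_per_run: list[dict[str, Selection]] = []
        for run, topology, _ in runs:
            sels = {}
            for key, expr in config.selections.items():
                sel = select(expr, topology)
                if len(sel) == 0:
                    raise ValueError(
                        f"selection {key!r} = {expr!r} resolves to no atoms")
                sels[key] = sel
            sels_per_run.append(sels)
        log("validate", selections=config.selections,
            runs=[r[0] for r in runs])

        entropy_rows = []
        energy_es, energy_vdw = [], []
        occupancy_tables = []
        rmsf_profiles = []
        fraction_rows = []

        for i, ((run, topology, stream), sels) in enumerate(
                zip(runs, sels_per_run), start=1):
            seed = run.get("seed", run.get("traj", i))
            reference = next(iter(stream))
            masses_lig = topology.masses()[sels["ligand"].indices]

            # --- RMSD of the ligand after a backbone fit
            t, r = superpose.rmsd_series(stream, reference, sels["backbone"],
                                         sels["ligand"])
            pd.DataFrame({"time_ps": t, "rmsd_nm": r}).to_csv(
                outdir / f"rmsd_ligand_run{i}.tsv", sep="\t", index=False)
            log("rmsd", run=i, seed=seed, fit="backbone", calc="ligand",
                n_frames=len(r))

            # --- backbone RMSF
            prof = superpose.rmsf_profile(stream, sels["backbone"],
                                          fit_sel=sels["backbone"],
                                          reference=reference)
            rmsf_profiles.append(prof)
            log("rmsf", run=i, seed=seed, n_atoms=len(prof.rmsf))

            # --- Schlitter entropy, both fit conventions
            results = {}
            for mode, fit_sel in (("protein_fit", sels["backbone"]),
                                  ("self_fit", None)):
                res = entropy.entropy_convergence(
                    stream, sels["ligand"], masses_lig, config.temperature,
                    checkpoints=[len(stream)],
                    fit_mode="subset" if fit_sel is not None else "self",
                    fit_selection=fit_sel, reference=reference)[-1]
                results[mode] = res.s
            entropy_rows.append(results)
            log("entropy", run=i, seed=seed, **{k: round(v, 3)
                                                for k, v in results.items()})

            # --- ligand-surrounding energies per frame, block-averaged
            surrounding = Selection(
                "not ligand", np.setdiff1d(np.arange(topology.n_atoms),
                                           sels["ligand"].indices))
            es, vdw = [], []
            for frame in stream:
                e, v = energetics.pair_energies(frame, sels["ligand"],
                                                surrounding, topology)
                es.append(e)
                vdw.append(v)
            energy_es.append(energetics.block_average(np.array(es)))
            energy_vdw.append(energetics.block_average(np.array(vdw)))
            log("energy", run=i, seed=seed, n_frames=len(es))

            # --- hydrogen-bond occupancy
            spec = interactions.cross_hbond_spec(
                topology, sels["ligand"], surrounding,
                distance_cutoff=config.hbond_distance,
                angle_cutoff=config.hbond_angle)
            occupancy_tables.append(
                interactions.occupancy_table(stream, spec, topology,
                                             sels["ligand"]))
            log("hbonds", run=i, seed=seed,
                distance_cutoff=config.hbond_distance,
                angle_cutoff=config.hbond_angle)

            # --- HC-N5 and histidine-hydroxyl distances
            glc_res = topology.atom_resname[sels["ligand"].indices[0]]
            hc_sites = interactions.resolve_sites(config.hc_sites, topology,
                                                  resname=str(glc_res))
            n5_site = interactions.atom_sites(sels["fad_n5"], topology)
            for site in hc_sites:
                series = interactions.distance_series(
                    stream, [site], n5_site, topology)
                frac = interactions.fraction_below(series,
                                                   config.proximity_cutoff)
                hist = interactions.histogram(series, config.histogram_bin)
                pd.DataFrame({
                    "bin_left_nm": hist.bin_edges[:-1],
                    "density": hist.density,
                }).to_csv(outdir / f"hist_{series.label}_run{i}.tsv",
                          sep="\t", index=False)
                fraction_rows.append({"run": i, "pair": series.label,
                                      "fraction_below": frac})
            for his_key, oxy in (("his_512", "O3"), ("his_556", "O2")):
                his_sites = interactions.atom_sites(sels[his_key], topology)
                oxy_site = interactions.resolve_sites([oxy], topology,
                                                      resname=str(glc_res))
                series = interactions.distance_series(
                    stream, his_sites, oxy_site, topology, mode="min_over_a")
                fraction_rows.append({
                    "run": i, "pair": f"{his_key}-{oxy}",
                    "fraction_below": interactions.fraction_below(
                        series, config.proximity_cutoff)})
            log("distances", run=i, seed=seed,
                proximity_cutoff=config.proximity_cutoff)

        # ---------------- aggregation over runs ----------------
        mean_prof = superpose.average_profiles(rmsf_profiles)
        pd.DataFrame({"atom_index": mean_prof.atom_indices,
                      "rmsf_nm": mean_prof.rmsf}).to_csv(
            outdir / "rmsf_mean.tsv", sep="\t", index=False)

        ent = pd.DataFrame(entropy_rows)
        ent_summary = pd.DataFrame({
            "fit_mode": ent.columns,
            "s_mean_J_per_molK": ent.mean().values,
            "s_sd_between_runs": ent.std(ddof=1).fillna(0.0).values
            if len(ent) > 1 else np.zeros(len(ent.columns)),
        })
        ent_summary.to_csv(outdir / "entropy.tsv", sep="\t", index=False)

        comb_es = energetics.combine_runs(energy_es)
        comb_vdw = energetics.combine_runs(energy_vdw)
        pd.DataFrame([
            {"term": "V_ES_ligand_surrounding", "mean_kJ_per_mol": comb_es.mean,
             "error_kJ_per_mol": comb_es.error},
            {"term": "V_vdW_ligand_surrounding", "mean_kJ_per_mol": comb_vdw.mean,
             "error_kJ_per_mol": comb_vdw.error},
        ]).to_csv(outdir / "energies.tsv", sep="\t", index=False)

        mean_table = interactions.average_tables(occupancy_tables)
        occ_rows = [{"partner": row.partner,
                     "occupancy_percent": round(row.percentage, 1),
                     "ligand_atoms": "/".join(row.ligand_atoms)}
                    for row in mean_table.rows]
        occ_rows.append({"partner": "Total",
                         "occupancy_percent": round(mean_table.total, 1),
                         "ligand_atoms": ""})
        pd.DataFrame(occ_rows).to_csv(outdir / "occupancy.tsv", sep="\t",
                                      index=False)

        pd.DataFrame(fraction_rows).to_csv(outdir / "fractions.tsv", sep="\t",
                                           index=False)
        log("aggregate", n_runs=len(runs),
            entropy_mean=ent.mean().round(3).to_dict(),
            total_occupancy=round(mean_table.total, 2))
        log_fh.close()
        return outdir
    except Exception as exc:
        log_fh.close()
        # partial outputs are removed; the stage name travels in the message
        shutil.rmtree(outdir, ignore_errors=True)
        raise RuntimeError(f"analysis bundle aborted: {exc}") from exc
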