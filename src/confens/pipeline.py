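"""End-to-end analyses driven by a config file, with reproducible outputs.

Three analyses are orchestrated: ``rank`` (score ensembles by torsion
entropy and globule energy, Pareto-rank them), ``mobility`` (per-replica
RMSF profiles and comparative mobility-region calls between two
conditions) and ``features`` (H-bond occupancy, per-frame secondary
structure, β-turns, stacking contacts and disulfides, with a focused
sub-report for a residue range such as a C-terminal region).

The fully resolved configuration (defaults + overrides) is echoed into the
output directory; re-running from the echoed config reproduces all
TSV/JSON outputs bitwise. All numeric defaults that affect results (bin
width, compressor, cutoffs, thresholds) appear in the echo.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import ensemble as ens_mod
from . import features as feat_mod
from . import scoring, torsion
from .structio import detect_disulfides, read_energy_log, read_ensemble_pdb

__all__ = ["RunConfig", "load_config", "run", "run_rank", "run_mobility",
           "run_features", "DEFAULT_PARAMETERS"]

DEFAULT_PARAMETERS = {
    "angle_set": "I",
    "bin_width": 10.0,
    "compressor": "zstd",
    "equilibration": 0.1,
    "fold_symmetric_chi": True,
    "rank_tolerance": 0.0,
    "rmsf_selection": "CA",
    "abs_floor": 0.2,
    "k": 1.0,
    "min_len": 4,
    "gap_tol": 1,
    "two_sided": False,
    "hb_dist": 3.5,
    "hb_angle_tol": 30.0,
    "stack_dist": 5.5,
    "stable_threshold": 0.5,
    "disulfide_cutoff": 2.3,
}


@dataclass
class RunConfig:
    analysis: str  # rank | mobility | features
    inputs: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "confens_out"

    def resolved_parameters(self) -> dict:
        params = dict(DEFAULT_PARAMETERS)
        params.update(self.parameters)
        return params


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig(
        analysis=raw["analysis"],
        inputs=raw.get("inputs", {}),
        parameters=raw.get("parameters", {}),
        seed=int(raw.get("seed", 0)),
        output_dir=raw.get("output_dir", "confens_out"),
    )


def _echo_config(config: RunConfig, outdir: Path) -> None:
    resolved = {
        "analysis": config.analysis,
        "inputs": config.inputs,
        "parameters": config.resolved_parameters(),
        "seed": config.seed,
        "output_dir": str(outdir),
    }
    with open(outdir / "config.resolved.yaml", "w") as fh:
        yaml.safe_dump(resolved, fh, sort_keys=True)


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def run(config: RunConfig) -> dict:
    """Dispatch an analysis; returns the machine-readable summary."""
    runners = {"rank": run_rank, "mobility": run_mobility,
               "features": run_features}
    if config.analysis not in runners:
        raise ValueError(f"unknown analysis {config.analysis!r}")
    return runners[config.analysis](config)


def run_rank(config: RunConfig) -> dict:
    """Score ≥2 (ensemble, energy) pairs and report the Pareto ranking."""
    params = config.resolved_parameters()
    models = config.inputs.get("models", [])
    if len(models) < 2:
        raise ValueError("rank analysis requires >= 2 models")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _echo_config(config, outdir)

    scores_by_set: dict[str, list[scoring.ModelScore]] = {"I": [], "II": []}
    for entry in models:
        model_id = entry["model_id"]
        try:
            ens = read_ensemble_pdb(entry["ensemble"])
            energy = read_energy_log(entry["energy"])
            records = torsion.extract_torsions(
                ens, "II", fold_symmetric_chi=params["fold_symmetric_chi"])
            for set_id in ("I", "II"):
                scores_by_set[set_id].append(scoring.score_model(
                    ens, records, set_id, energy, model_id=model_id,
                    bin_width=params["bin_width"],
                    equilibration=params["equilibration"],
                    compressor=params["compressor"],
                ))
        except Exception as exc:
            raise RuntimeError(f"model {model_id!r}: {exc}") from exc

    with open(outdir / "scores.tsv", "w") as fh:
        fh.write("model_id\tset\ts_tors_mean\ts_tors_rmsd\te_glob_mean\t"
                 "e_glob_rmsd\tn_frames\tn_angles\n")
        for set_id in ("I", "II"):
            for s in scores_by_set[set_id]:
                fh.write("\t".join([
                    s.model_id, set_id, _fmt(s.s_tors_mean),
                    _fmt(s.s_tors_spread), _fmt(s.e_glob_mean),
                    _fmt(s.e_glob_spread), str(s.n_frames), str(s.n_angles),
                ]) + "\n")

    rankings = {}
    for set_id in ("I", "II"):
        rep = scoring.rank_models(scores_by_set[set_id],
                                  tol=params["rank_tolerance"])
        rankings[set_id] = {"front": rep.front, "best": rep.best,
                            "ties": [list(t) for t in rep.ties],
                            "dominated": rep.dominated}

    summary = {
        "analysis": "rank",
        "rankings": rankings,
        "scatter": {
            set_id: [
                {"model_id": s.model_id, "s_tors": s.s_tors_mean,
                 "e_glob": s.e_glob_mean,
                 "s_tors_rmsd": s.s_tors_spread,
                 "e_glob_rmsd": s.e_glob_spread}
                for s in scores_by_set[set_id]
            ] for set_id in ("I", "II")
        },
        "provenance": {
            "bin_width": params["bin_width"],
            "compressor": params["compressor"],
            "equilibration": params["equilibration"],
            "fold_symmetric_chi": params["fold_symmetric_chi"],
            "spread_convention": "entropy: RMSD across angle records; "
                                 "energy: RMSD across frames",
        },
    }
    _write_json(summary, outdir / "rank_summary.json")
    return summary


def run_mobility(config: RunConfig) -> dict:
    """RMSF per replica for two conditions plus mobility-region calls."""
    params = config.resolved_parameters()
    ref_paths = config.inputs.get("ref", [])
    alt_paths = config.inputs.get("alt", [])
    if not ref_paths or not alt_paths:
        raise ValueError("mobility analysis requires ref and alt ensembles")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _echo_config(config, outdir)

    def profiles(paths, tag):
        out = []
        for i, p in enumerate(paths):
            ens = read_ensemble_pdb(p)
            out.append(ens_mod.rmsf(ens, selection=params["rmsf_selection"],
                                    replica_id=f"{tag}{i + 1}"))
        return out

    ref_profiles = profiles(ref_paths, "ref")
    alt_profiles = profiles(alt_paths, "alt")

    ref_keys = set(ref_profiles[0].residue_keys)
    alt_keys = set(alt_profiles[0].residue_keys)
    if ref_keys != alt_keys:
        warnings.warn(
            "conditions cover different residue ranges; comparison "
            "restricted to the intersection", stacklevel=2,
        )

    for tag, profs in (("ref", ref_profiles), ("alt", alt_profiles)):
        with open(outdir / f"rmsf_{tag}.tsv", "w") as fh:
            fh.write("chain\tres_seq\t"
                     + "\t".join(p.replica_id for p in profs) + "\n")
            for i, (chain, res) in enumerate(profs[0].residue_keys):
                fh.write(f"{chain}\t{res}\t"
                         + "\t".join(_fmt(p.values[i]) for p in profs) + "\n")

    mob = ens_mod.MobilityParams(
        abs_floor=params["abs_floor"], k=params["k"],
        min_len=params["min_len"], gap_tol=params["gap_tol"],
        two_sided=params["two_sided"])
    calls = ens_mod.call_mobility_regions(ref_profiles, alt_profiles, mob)

    with open(outdir / "mobility_calls.tsv", "w") as fh:
        fh.write("start_res\tend_res\tdelta\treproducibility\n")
        for c in calls:
            fh.write(f"{c.start_res}\t{c.end_res}\t{_fmt(c.delta)}\t"
                     f"{_fmt(c.reproducibility)}\n")

    summary = {
        "analysis": "mobility",
        "n_ref_replicas": len(ref_profiles),
        "n_alt_replicas": len(alt_profiles),
        "calls": [
            {"start_res": c.start_res, "end_res": c.end_res,
             "delta": c.delta, "reproducibility": c.reproducibility}
            for c in calls
        ],
        "parameters": {k: params[k] for k in
                       ("abs_floor", "k", "min_len", "gap_tol", "two_sided",
                        "rmsf_selection")},
    }
    _write_json(summary, outdir / "mobility_summary.json")
    return summary


def run_features(config: RunConfig) -> dict:
    """Feature occupancy report, optionally focused on a residue range."""
    params = config.resolved_parameters()
    path = config.inputs.get("ensemble")
    if not path:
        raise ValueError("features analysis requires an ensemble input")
    focus = config.inputs.get("focus_range")  # [lo, hi] res_seq, optional
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _echo_config(config, outdir)

    ens = read_ensemble_pdb(path)
    if focus is not None:
        lo, hi = int(focus[0]), int(focus[1])
        in_range = [r for _, r, _ in ens.topology.residues if lo <= r <= hi]
        if not in_range:
            raise ValueError(f"focus range {focus} selects no residues")

    hbonds = feat_mod.hbond_occupancy(
        ens, d_cut=params["hb_dist"], a_cut=params["hb_angle_tol"],
        stable_threshold=params["stable_threshold"])
    ss = feat_mod.assign_ss_ensemble(ens)
    turns = feat_mod.detect_beta_turns(
        ens, stable_threshold=params["stable_threshold"])
    stacks = feat_mod.detect_stacking(ens, d_cut=params["stack_dist"])
    disulfides = detect_disulfides(ens.topology,
                                   cutoff=params["disulfide_cutoff"])

    with open(outdir / "hbonds.tsv", "w") as fh:
        fh.write("donor_chain\tdonor_res\tdonor_atom\tacceptor_chain\t"
                 "acceptor_res\tacceptor_atom\tdistance\toccupancy\tstable\n")
        for b in hbonds:
            fh.write("\t".join([
                b.donor[0][0], str(b.donor[0][1]), b.donor[1],
                b.acceptor[0][0], str(b.acceptor[0][1]), b.acceptor[1],
                _fmt(b.distance), _fmt(b.occupancy),
                str(bool(b.stable)).lower(),
            ]) + "\n")

    with open(outdir / "ss_per_frame.txt", "w") as fh:
        for line in ss.codes:
            fh.write(line + "\n")

    with open(outdir / "turns.tsv", "w") as fh:
        fh.write("chain\tstart_res\ttype\toccupancy\tstability\n")
        for t in turns:
            fh.write(f"{t.start_res[0]}\t{t.start_res[1]}\t{t.turn_type}\t"
                     f"{_fmt(t.occupancy)}\t{t.stability}\n")

    with open(outdir / "stacking.tsv", "w") as fh:
        fh.write("chain_a\tres_a\tchain_b\tres_b\tdistance\tangle\t"
                 "geometry\toccupancy\n")
        for s in stacks:
            fh.write(f"{s.res_a[0]}\t{s.res_a[1]}\t{s.res_b[0]}\t{s.res_b[1]}"
                     f"\t{_fmt(s.centroid_distance)}"
                     f"\t{_fmt(s.interplanar_angle)}\t{s.geometry}"
                     f"\t{_fmt(s.occupancy)}\n")

    with open(outdir / "disulfides.tsv", "w") as fh:
        fh.write("chain_a\tres_a\tchain_b\tres_b\tsg_distance\n")
        for d in disulfides:
            fh.write(f"{d.cys_a[0]}\t{d.cys_a[1]}\t{d.cys_b[0]}\t{d.cys_b[1]}"
                     f"\t{_fmt(d.sg_distance)}\n")

    def in_focus(res_seq: int) -> bool:
        return focus is None or (int(focus[0]) <= res_seq <= int(focus[1]))

    summary = {
        "analysis": "features",
        "n_frames": ens.n_frames,
        "n_residues": len(ens.topology.residues),
        "counts": {
            "hbonds": len(hbonds),
            "stable_hbonds": sum(1 for b in hbonds if b.stable),
            "turns": len(turns),
            "stable_turns": sum(1 for t in turns
                                if t.stability == "stable"),
            "stacking_contacts": len(stacks),
            "disulfides": len(disulfides),
        },
        "focus": None if focus is None else {
            "range": [int(focus[0]), int(focus[1])],
            "hbonds": [
                {"donor": [list(b.donor[0]), b.donor[1]],
                 "acceptor": [list(b.acceptor[0]), b.acceptor[1]],
                 "occupancy": b.occupancy, "stable": bool(b.stable)}
                for b in hbonds
                if in_focus(b.donor[0][1]) or in_focus(b.acceptor[0][1])
            ],
            "turns": [
                {"start_res": list(t.start_res), "type": t.turn_type,
                 "occupancy": t.occupancy, "stability": t.stability}
                for t in turns if in_focus(t.start_res[1])
            ],
            "stacking": [
                {"res_a": list(s.res_a), "res_b": list(s.res_b),
                 "geometry": s.geometry, "occupancy": s.occupancy}
                for s in stacks
                if in_focus(s.res_a[1]) or in_focus(s.res_b[1])
            ],
            "disulfides": [
                {"cys_a": list(d.cys_a), "cys_b": list(d.cys_b),
                 "sg_distance": d.sg_distance}
                for d in disulfides
                if in_focus(d.cys_a[1]) or in_focus(d.cys_b[1])
            ],
        },
        "parameters": {k: params[k] for k in
                       ("hb_dist", "hb_angle_tol", "stack_dist",
                        "stable_threshold", "disulfide_cutoff")},
    }
    _write_json(summary, outdir / "features_summary.json")
    return summary
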