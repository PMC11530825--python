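"""End-to-end analysis pipeline binding every stage into one workflow:
ensemble in (or synthetic scene), descriptor traces, filtered contact
networks, block-wise contact evolution, energy decomposition, geometry
distributions and base-pair persistence out, all as provenance-stamped
CSV/JSON.  Identical config + seed give byte-identical outputs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, contacts, descriptors, energy, geometry, pairing
from . import synthetic, topology as topo
from .config import ConfigError, RunConfig, validate_config

FLOAT_FORMAT = "%.6g"


class PipelineError(RuntimeError):
    """A stage failure, wrapped with the stage name."""


def _provenance(config: RunConfig) -> list[str]:
    return [
        f"# rnacontactdyn {__version__}",
        f"# config_hash: {config.digest()}",
        f"# seed: {config.seed}",
        f"# config: {json.dumps(config.to_dict(), sort_keys=True)}",
    ]


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig,
               extra: dict | None = None) -> None:
    lines = _provenance(config)
    for k, v in (extra or {}).items():
        lines.append(f"# {k}: {v}")
    with open(path, "w", newline="") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FORMAT)


def _write_json(obj, path: Path, config: RunConfig) -> None:
    payload = {
        "provenance": {
            "version": __version__,
            "config_hash": config.digest(),
            "seed": config.seed,
        },
        **obj,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def load_ensemble(config: RunConfig):
    """Input ensemble + parameterized topology per the config.

    Without an input file the built-in synthetic demo scene is generated
    from the seed; without a parameter table the synthetic parameter set
    covers the topology.
    """
    if config.input_pdb is None:
        ens, truth = synthetic.demo_scene(config.seed, config.simulate_frames)
    else:
        ens = topo.read_multimodel_pdb(
            config.input_pdb,
            config.region_scheme(),
            renumber=config.renumber,
        )
        truth = None
    table = (
        synthetic.synthetic_param_table(ens.topology)
        if config.params_table is None
        else config.params_table
    )
    ens.topology = topo.attach_nonbonded_params(ens.topology, table)
    return ens, truth


def _frame_window(ens, config: RunConfig) -> tuple[int, int]:
    if config.window_ns is None:
        return (0, ens.n_frames)
    lo, hi = config.window_ns
    idx = np.nonzero((ens.times >= lo) & (ens.times <= hi))[0]
    if idx.size == 0:
        raise ConfigError(
            f"window {config.window_ns} ns selects no frames "
            f"(trajectory spans {ens.times[0]}-{ens.times[-1]} ns)"
        )
    return (int(idx[0]), int(idx[-1]) + 1)


def _smooth_frames(ens, config: RunConfig) -> int:
    if ens.n_frames < 2:
        return 1
    dt = float(np.median(np.diff(ens.times)))
    return max(1, int(round(config.smooth_ns / dt)))


def stage_descriptors(ens, config: RunConfig, out: Path) -> list[Path]:
    win = _frame_window(ens, config)
    smooth = _smooth_frames(ens, config)
    rmsd = descriptors.rmsd_trace(ens)
    rg = descriptors.rg_trace(ens)
    df = pd.DataFrame(
        {
            "time_ns": rmsd.times,
            "rmsd_A": rmsd.values,
            "rmsd_A_smooth": descriptors.moving_average(rmsd.values, smooth),
            "rg_A": rg.values,
            "rg_A_smooth": descriptors.moving_average(rg.values, smooth),
        }
    )
    p1 = out / "descriptors.csv"
    _write_csv(df, p1, config, {"smooth_frames": smooth})

    rmsf = descriptors.rmsf_per_residue(ens, window=win)
    p2 = out / "rmsf.csv"
    _write_csv(rmsf.reset_index(), p2, config, {"window_frames": win})

    pca = descriptors.pca(ens)
    k = min(config.pca_modes, len(pca.eigenvalues))
    p3 = out / "pca.json"
    _write_json(
        {
            "eigenvalues_A2": [float(v) for v in pca.eigenvalues[:k]],
            "variance_fractions": [float(v) for v in pca.variance_fractions[:k]],
            "cumulative_top3": float(pca.variance_fractions[:3].sum()),
        },
        p3,
        config,
    )
    # mode animation along PC1 as a multi-model PDB
    sel = pca.selection_indices
    frames = np.repeat(ens.frames[:1], 21, axis=0)
    frames[:, sel] = descriptors.pc_interpolation(pca, 0, n_frames=21)
    anim = topo.Ensemble(ens.topology, frames, np.arange(21, dtype=float))
    p4 = out / "pca_mode1.pdb"
    topo.write_multimodel_pdb(anim, p4)
    return [p1, p2, p3, p4]


def stage_contacts(ens, config: RunConfig, out: Path) -> list[Path]:
    win = _frame_window(ens, config)
    criteria = contacts.ContactCriteria(
        hbond_heavy_dist_max=config.hbond_dist,
        hbond_angle_min=config.hbond_angle,
        salt_bridge_dist_max=config.salt_dist,
        apolar_dist_max=config.apolar_dist,
    )
    series = contacts.build_series(ens, criteria, win)
    kept = contacts.occupancy_filter(series, config.occupancy_threshold)
    evo = contacts.contact_evolution(kept, min(config.n_blocks, win[1] - win[0]))
    rows = []
    for s in kept:
        rows.append(
            {
                "residue_i": s.residue_pair[0],
                "residue_j": s.residue_pair[1],
                "occupancy": s.occupancy,
                "mean_strength": s.mean_strength,
                "mean_specific": s.mean_strength_mode("specific"),
                "mean_nonspecific": s.mean_strength_mode("nonspecific"),
            }
        )
    df = pd.DataFrame(
        rows, columns=["residue_i", "residue_j", "occupancy", "mean_strength",
                       "mean_specific", "mean_nonspecific"]
    )
    p1 = out / "contacts.csv"
    _write_csv(df, p1, config, {
        "threshold": config.occupancy_threshold,
        "hbond_mode": contacts.hbond_mode(ens.topology),
        "window_frames": win,
    })
    p2 = out / "contact_evolution.csv"
    _write_csv(evo, p2, config)
    network = {
        "nodes": sorted({int(r) for s in kept for r in s.residue_pair}),
        "edges": [
            {
                "source": int(s.residue_pair[0]),
                "target": int(s.residue_pair[1]),
                "occupancy": round(s.occupancy, 6),
                "mean_strength": round(s.mean_strength, 6),
            }
            for s in kept
        ],
    }
    p3 = out / "contact_network.json"
    _write_json(network, p3, config)
    return [p1, p2, p3]


def stage_energies(ens, config: RunConfig, out: Path) -> list[Path]:
    win = _frame_window(ens, config)
    dec = energy.four_group_decomposition(ens, win, config.cutoff_A)
    rows = [
        {"component": c, "mean_kcal_mol": dec.means[c], "sd_kcal_mol": dec.sds[c]}
        for c in energy.COMPONENTS
    ]
    rows.append(
        {"component": "total", "mean_kcal_mol": dec.total,
         "sd_kcal_mol": dec.total_sd}
    )
    p1 = out / "energy_decomposition.csv"
    _write_csv(pd.DataFrame(rows), p1, config, {
        "cutoff_A": config.cutoff_A,
        "note": "force-field nonbonded energies (no solvation term)",
    })
    mat = energy.per_residue_pair_matrix(ens, win, config.cutoff_A)
    p2 = out / "energy_matrix.csv"
    _write_csv(mat.reset_index(names="aso_residue"), p2, config, {
        "note": "force-field nonbonded analogue of a residue-pair "
                "free-energy map (no solvation term)",
    })
    ts = energy.energy_timeseries(ens, _smooth_frames(ens, config), win,
                                  config.cutoff_A)
    p3 = out / "energy_timeseries.csv"
    _write_csv(ts, p3, config)
    return [p1, p2, p3]


def stage_geometry(ens, config: RunConfig, out: Path,
                   pairing_list=None) -> list[Path]:
    win = _frame_window(ens, config)
    if pairing_list is None:
        detected = pairing.detect_base_pairs(ens.frames[win[0]], ens.topology)
        pairing_list = [bp.residue_pair for bp in detected
                        if bp.category == "watson_crick"]
    prof = geometry.geometry_profiles(ens, pairing_list, win)
    paths = []
    for key in ("torsions", "puckers", "bp_params", "step_params"):
        p = out / f"geometry_{key}.csv"
        _write_csv(prof[key], p, config)
        paths.append(p)
    return paths


def stage_pairs(ens, config: RunConfig, out: Path) -> list[Path]:
    win = _frame_window(ens, config)
    n_blocks = min(config.n_blocks, win[1] - win[0])
    df = pairing.pair_persistence(ens, n_blocks=n_blocks, window=win)
    pairs0 = pairing.detect_base_pairs(ens.frames[win[0]], ens.topology)
    triples = pairing.detect_triples(pairs0)
    p1 = out / "pair_persistence.csv"
    _write_csv(df, p1, config)
    p2 = out / "triples.json"
    _write_json(
        {
            "first_window_frame": win[0],
            "triples": [
                {
                    "central": int(t.central),
                    "partners": [int(p) for p in t.partners],
                    "edges": {
                        str(p): list(e) for p, e in sorted(t.edges.items())
                    },
                    "closed": bool(t.closed),
                }
                for t in triples
            ],
        },
        p2,
        config,
    )
    return [p1, p2]


STAGES = {
    "descriptors": stage_descriptors,
    "contacts": stage_contacts,
    "energies": stage_energies,
    "geometry": stage_geometry,
    "pairs": stage_pairs,
}


def run_pipeline(config: RunConfig) -> dict[str, list[str]]:
    """Run every stage; returns {stage: [output paths]}.

    Config problems abort before any computation; stage errors propagate
    wrapped with the stage name.
    """
    errors = validate_config(config)
    if errors:
        raise ConfigError("; ".join(errors))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ens, truth = load_ensemble(config)
    manifest: dict[str, list[str]] = {}
    if truth is not None:
        p = out / "ground_truth.json"
        _write_json({"ground_truth": truth}, p, config)
        manifest["simulate"] = [str(p)]
    for name, stage in STAGES.items():
        try:
            paths = stage(ens, config, out)
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        manifest[name] = [str(p) for p in paths]
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
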