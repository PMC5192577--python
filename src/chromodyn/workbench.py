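"""Configuration handling and end-to-end pipeline orchestration.

Two pipelines tie the modules together:

* the structure pipeline: domain-grammar configuration -> lattice Monte
  Carlo ensemble -> contact map -> loop-base calls -> ensemble gyration
  radius; and
* the dynamics pipeline: (synthetic or supplied) intensity traces ->
  windowed correlation -> window-size scan -> polymer-relaxation fit ->
  relaxation time, gyration radius and genomic content.

Configurations are YAML mappings with per-module blocks; unknown keys
are rejected and the resolved configuration is written next to the
outputs so every run is reproducible from its artifacts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from . import binding, fcs, polymer, synthetic
from .contact_map import contact_map_from_ensemble, write_map
from .lattice import LatticeSpec, chain_statistics, sample_ensemble
from .map_analysis import call_loop_bases, extract_domain

__all__ = ["load_config", "run_structure_pipeline", "run_dynamics_pipeline"]

_KNOWN_BLOCKS = {
    "polymer",
    "chain",
    "map",
    "fcs",
    "binding",
    "accessibility",
    "synth",
    "seed",
    "out_dir",
    "log_level",
}


class ConfigError(ValueError):
    pass


def load_config(path_or_dict) -> dict:
    """Load and validate a pipeline configuration."""
    if isinstance(path_or_dict, dict):
        cfg = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - _KNOWN_BLOCKS
    if unknown:
        raise ConfigError(f"unknown config blocks: {sorted(unknown)}")
    if "seed" not in cfg:
        raise ConfigError("config must set a global 'seed'")
    return cfg


def _resolve_out(cfg: dict, out_dir) -> Path:
    out = Path(out_dir or cfg.get("out_dir", "chromodyn_out"))
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh)
    return out


def run_structure_pipeline(cfg: dict, out_dir=None) -> dict:
    """Configuration -> ensemble -> contact map -> loop calls -> R_g."""
    cfg = load_config(cfg)
    chain_cfg = cfg.get("chain", {})
    map_cfg = cfg.get("map", {})
    if "config" not in chain_cfg:
        raise ConfigError("chain block must provide a domain-grammar 'config' string")
    out = _resolve_out(cfg, out_dir)
    seed = int(cfg["seed"])
    lattice = LatticeSpec(
        a=float(chain_cfg.get("a", 30.0)),
        bp_per_bond=int(chain_cfg.get("bp_per_bond", 2500)),
    )
    ens = sample_ensemble(
        chain_cfg["config"],
        n_conformations=int(chain_cfg.get("n_conformations", 50)),
        seed=seed,
        sweeps_burn_in=chain_cfg.get("sweeps_burn_in"),
        sweeps_between=chain_cfg.get("sweeps_between"),
        lattice=lattice,
        self_avoiding=bool(chain_cfg.get("self_avoiding", True)),
    )
    stats = chain_statistics(ens)
    cmap = contact_map_from_ensemble(
        ens, capture_radius=map_cfg.get("capture_radius"), start=0
    )
    write_map(cmap, out / "contact_map.tsv")
    n_bp = cmap.n_bins * cmap.bin_size
    dom = extract_domain(
        cmap,
        tuple(map_cfg.get("domain_interval", (0, n_bp))),
        diag_mask_halfwidth=float(map_cfg.get("diag_mask_halfwidth", 30_000.0)),
    )
    calls = call_loop_bases(dom)
    with open(out / "loop_calls.tsv", "w") as fh:
        fh.write("# chrom\tstart_i\tend_i\tchrom\tstart_j\tend_j\tconfidence\n")
        for c in calls:
            b = cmap.bin_size
            fh.write(
                f"sim\t{int(c.site_i - b / 2)}\t{int(c.site_i + b / 2)}\t"
                f"sim\t{int(c.site_j - b / 2)}\t{int(c.site_j + b / 2)}\t{c.confidence}\n"
            )
    report = {
        "pipeline": "structure",
        "seed": seed,
        "n_conformations": ens.n,
        "mc_acceptance": ens.acceptance,
        "rg_mean_nm": stats.rg_mean,
        "rg_sd_nm": stats.rg_sd,
        "mean_bond_nm": stats.mean_bond,
        "n_loop_calls": len(calls),
        "loop_calls": [
            {"site_i": c.site_i, "site_j": c.site_j, "confidence": c.confidence}
            for c in calls
        ],
    }
    with open(out / "structure_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def run_dynamics_pipeline(cfg: dict, out_dir=None) -> dict:
    """Synthetic traces -> correlate -> window scan -> relaxation fit."""
    cfg = load_config(cfg)
    fcs_cfg = cfg.get("fcs", {})
    synth_cfg = cfg.get("synth", {})
    pol_cfg = cfg.get("polymer", {})
    out = _resolve_out(cfg, out_dir)
    seed = int(cfg["seed"])
    conformation = pol_cfg.get("conformation", "theta_rosette")
    env = polymer.PhysicalEnvironment(
        eta_s=float(pol_cfg.get("eta_s", polymer.DEFAULT_ETA_S)),
        T=float(pol_cfg.get("T", polymer.DEFAULT_T)),
    )
    focus = fcs.FocusModel(
        w_0=float(fcs_cfg.get("w_0", 200.0)), z_0=float(fcs_cfg.get("z_0", 1000.0))
    )
    tau_1_true = float(synth_cfg.get("tau_1", 0.161))
    geom = polymer.rg_from_relaxation(tau_1_true, conformation, env)
    spectrum = polymer.mode_spectrum(geom.R_g, conformation, env)
    n_traces = int(synth_cfg.get("n_traces", 4))
    windows = fcs_cfg.get("windows", [1.0, 2.0, 4.0, 8.0, 12.0])
    results = []
    valid_taus = []
    for i in range(n_traces):
        trace, truth = synthetic.simulate_ou_trace(
            spectrum,
            focus,
            n_emitters=int(synth_cfg.get("n_emitters", 100)),
            dt=float(synth_cfg.get("dt", 2e-4)),
            duration=float(synth_cfg.get("duration", 30.0)),
            seed=seed + i,
        )
        scan = fcs.window_scan(
            trace,
            lambda cf: fcs.fit_relaxation(
                cf, conformation, focus, env, include_free=False
            ).tau_1,
            windows,
        )
        rec = {"trace": i, "valid": scan.valid}
        if scan.valid:
            cf = fcs.correlate(trace, scan.selected_window)
            fit = fcs.fit_relaxation(cf, conformation, focus, env, include_free=False)
            calib = polymer.ChromatinCalibration(
                rel_density=float(pol_cfg.get("rel_density", 0.91))
            )
            g = polymer.rg_from_relaxation(fit.tau_1, conformation, env, calib)
            rec.update(
                {
                    "window_s": scan.selected_window,
                    "tau_1_ms": fit.tau_1 * 1e3,
                    "R_g_nm": g.R_g,
                    "gc_Mb": [v / 1e6 for v in g.gc_range],
                    "truth_tau_1_ms": truth["tau_1"] * 1e3,
                }
            )
            valid_taus.append(fit.tau_1)
        results.append(rec)
    report = {
        "pipeline": "dynamics",
        "seed": seed,
        "conformation": str(conformation),
        "n_traces": n_traces,
        "n_valid": len(valid_taus),
        "tau_1_ms_mean": float(np.mean(valid_taus) * 1e3) if valid_taus else None,
        "traces": results,
    }
    with open(out / "dynamics_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
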