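"""End-to-end analysis pipeline: build/load → fit → packing → crosslinks →
composition → CD/melt → assembly, with every output written to disk.

The pipeline is driven by a YAML/dict config and is deterministic given the
config (all randomness is seeded from it).  In synthetic mode no input
files are needed: the Crick builder generates the structure and simulated
observables, so the whole report can be produced self-contained.

Config schema (all sections optional except one of structure/synthetic)::

    seed: 0
    output_dir: out/
    structure: path.pdb          # or:
    synthetic:
      r0: 5.8                    # Å
      pitch: 153.0               # Å
      n_res: 168
      orientations: [U, D, U, D]
      noise_sd: 0.0              # Å
    crosslinks: links.csv        # or synthetic_crosslinks: {n_links, decoy_fraction}
    cutoffs:
      xlms: 30.0                 # Å
      salt_bridge: 4.0           # Å
      kih: 7.0                   # Å
    melt: {tm: 63.0, width: 2.0, noise_frac: 0.02}    # simulated, or melt_csv: path
    cd: {ratios: [0.8, 0.95]}
    assembly: {F1: 1.0, F2: 1.2, F3: 1.0, F4: 1.2}
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assembly as asm
from . import cd_thermo, crick_synth, geometry, packing, seqstats, xlms
from .structure_io import read_structure

__all__ = ["run_pipeline", "load_config"]

DEFAULT_CUTOFFS = {"xlms": 30.0, "salt_bridge": 4.0, "kih": 7.0}


class PipelineError(RuntimeError):
    """A stage failure, labeled with the stage name."""


def load_config(source: str | Path | dict) -> dict:
    if isinstance(source, dict):
        return dict(source)
    with open(source) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{source}: config must be a mapping")
    return cfg


def _validate(cfg: dict) -> dict:
    if ("structure" in cfg) == ("synthetic" in cfg):
        raise ValueError("config needs exactly one of 'structure'/'synthetic'")
    known = {
        "seed", "output_dir", "structure", "synthetic", "crosslinks",
        "synthetic_crosslinks", "cutoffs", "melt", "melt_csv", "cd",
        "assembly",
    }
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cutoffs = dict(DEFAULT_CUTOFFS)
    cutoffs.update(cfg.get("cutoffs") or {})
    cfg["cutoffs"] = cutoffs
    cfg.setdefault("seed", 0)
    return cfg


def _stage(name):
    def wrap(fn):
        def run(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r}: {exc}") from exc
        return run
    return wrap


@_stage("structure")
def _get_model(cfg: dict):
    if "structure" in cfg:
        return read_structure(cfg["structure"]), None
    syn = cfg["synthetic"] or {}
    params = crick_synth.CrickParams(
        n_chains=len(syn.get("orientations", ["U", "D", "U", "D"])),
        orientations=tuple(syn.get("orientations", ["U", "D", "U", "D"])),
        r0=float(syn.get("r0", 5.8)),
        pitch=float(syn.get("pitch", 153.0)),
        n_res=int(syn.get("n_res", 168)),
    )
    model, truth = crick_synth.build_bundle(
        params, sequence_seed=int(cfg["seed"])
    )
    noise = float(syn.get("noise_sd", 0.0))
    if noise > 0:
        model = crick_synth.perturb(model, noise, seed=int(cfg["seed"]) + 1)
    return model, truth


def run_pipeline(config: str | Path | dict,
                 output_dir: str | Path | None = None) -> dict:
    """Run the full pipeline; returns a summary dict (also written to disk).

    Outputs under ``output_dir``: fit.json, kih.tsv, bridges.tsv,
    xlms_report.tsv, composition.csv, cd_ratios.json, melt_fit.json,
    assembly.json, summary.txt.
    """
    cfg = _validate(load_config(config))
    outdir = Path(output_dir or cfg.get("output_dir", "coilspect_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    summary: dict = {"config": {k: v for k, v in cfg.items()}}

    model, truth = _get_model(cfg)
    fit = geometry.fit_coiled_coil(model)
    (outdir / "fit.json").write_text(json.dumps(fit.to_dict(), indent=2))
    summary["fit"] = fit.to_dict()
    register_txt = "\n".join(
        f">{cid}\n{fit.register[cid]}" for cid in model.chain_ids
    )
    (outdir / "register.txt").write_text(register_txt + "\n")

    kih = packing.detect_kih(model, fit, center_cutoff=cfg["cutoffs"]["kih"])
    pd.DataFrame(
        [
            {
                "knob_chain": c.knob[0], "knob_res": c.knob[1],
                "knob_register": c.knob_register,
                "hole_chain": c.hole[0][0],
                "hole_res": ",".join(str(h[1]) for h in c.hole),
                "axial": c.axial,
            }
            for c in kih
        ]
    ).to_csv(outdir / "kih.tsv", sep="\t", index=False)
    bridges = packing.detect_salt_bridges(
        model, fit, cutoff=cfg["cutoffs"]["salt_bridge"]
    )
    pd.DataFrame(
        [
            {
                "basic": f"{b.basic[0]}:{b.basic[2]}{b.basic[1]}",
                "acidic": f"{b.acidic[0]}:{b.acidic[2]}{b.acidic[1]}",
                "min_distance": b.min_distance, "class": b.position_class,
                "intermolecular": b.is_intermolecular,
            }
            for b in bridges
        ]
    ).to_csv(outdir / "bridges.tsv", sep="\t", index=False)
    summary["packing"] = {"n_kih": len(kih), "n_salt_bridges": len(bridges)}

    links = None
    if "crosslinks" in cfg:
        links = xlms.read_crosslinks(cfg["crosslinks"])
    elif "synthetic_crosslinks" in cfg:
        sx = cfg["synthetic_crosslinks"] or {}
        table = crick_synth.sample_crosslinks(
            model,
            n_links=int(sx.get("n_links", 50)),
            max_dist=cfg["cutoffs"]["xlms"],
            decoy_fraction=float(sx.get("decoy_fraction", 0.0)),
            seed=seed + 2,
        )
        table.to_csv(outdir / "crosslinks_input.csv", index=False)
        links = xlms.read_crosslinks(outdir / "crosslinks_input.csv")
    if links is not None:
        mapped = xlms.map_crosslinks(
            links, model, fit, cutoff=cfg["cutoffs"]["xlms"]
        )
        xlms.mapped_to_frame(mapped).to_csv(
            outdir / "xlms_report.tsv", sep="\t", index=False
        )
        rep = xlms.restraint_report(mapped)
        summary["xlms"] = {
            "n_unique_inter": rep.n_unique_inter,
            "n_unique_intra": rep.n_unique_intra,
            "satisfied_fraction": rep.satisfied_fraction,
            "surface_fraction": rep.surface_fraction,
        }

    table = seqstats.per_position_stats(
        seqstats.registered_sequences(model, fit)
    )
    table.to_csv(outdir / "composition.csv")
    summary["composition"] = table.to_dict()

    cd_cfg = cfg.get("cd") or {"ratios": [0.8, 0.95]}
    ratios_out = {}
    for r in cd_cfg.get("ratios", []):
        spec = crick_synth.simulate_cd(
            kind="coiled_coil" if r > 0.9 else "single_helix",
            ratio_222_209=float(r),
        )
        res = cd_thermo.ratio_222_209(spec)
        ratios_out[str(r)] = {
            "ratio": res.ratio, "coiled_coil": res.coiled_coil
        }
    (outdir / "cd_ratios.json").write_text(json.dumps(ratios_out, indent=2))
    summary["cd"] = ratios_out

    melt_curve = None
    if "melt_csv" in cfg:
        melt_curve = cd_thermo.read_melt(cfg["melt_csv"])
    elif "melt" in cfg:
        mc = cfg["melt"] or {}
        spec = crick_synth.MeltSimSpec(
            tm=float(mc.get("tm", 63.0)),
            width=float(mc.get("width", 2.0)),
            seed=seed + 3,
        )
        spec.noise_sd = float(mc.get("noise_frac", 0.0)) * spec.amplitude
        melt_curve = crick_synth.simulate_melt(spec)
    if melt_curve is not None:
        mf = cd_thermo.fit_two_state_melt(melt_curve)
        (outdir / "melt_fit.json").write_text(
            json.dumps(
                {
                    "tm": mf.tm, "width": mf.width,
                    "r_squared": mf.r_squared,
                    "cooperative": mf.cooperative,
                },
                indent=2,
            )
        )
        summary["melt"] = {"tm": mf.tm, "cooperative": mf.cooperative}

    if "assembly" in cfg:
        amounts = {k: float(v) for k, v in (cfg["assembly"] or {}).items()}
        mix = asm.order_invariance_check(amounts)
        out = mix.to_dict()
        try:
            profile = asm.predict_sec(mix)
            out["sec_peaks"] = profile.peaks.to_dict(orient="records")
        except ValueError:
            out["sec_peaks"] = None
        (outdir / "assembly.json").write_text(json.dumps(out, indent=2))
        summary["assembly"] = out

    lines = [
        "coilspect pipeline report",
        f"seed: {seed}",
        f"cutoffs: {cfg['cutoffs']}",
        f"chains: {model.chain_ids}",
        f"r0_fit: {fit.r0_fit:.3f} A   pitch_fit: {fit.pitch_fit:.2f} A   "
        f"handedness: {fit.handedness}",
        f"orientation: {fit.orientation}   arrangement: {fit.arrangement}",
        f"n_heptads: {fit.n_heptads}   extent: {fit.extent:.1f} A",
        f"KIH contacts: {len(kih)}   salt bridges: {len(bridges)}",
    ]
    if "xlms" in summary:
        lines.append(f"crosslinks: {summary['xlms']}")
    if "melt" in summary:
        lines.append(f"melt: {summary['melt']}")
    if "assembly" in summary:
        lines.append(f"assembly: {summary['assembly']}")
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    return summary
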