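"""End-to-end orchestration of the analysis stages from a config file.

A run config (YAML or JSON) selects stages and their parameters; each stage
writes its tables to the output directory and contributes to a single
``summary.json``.  Reruns with the same config and seed are deterministic.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from . import __version__, electrochem, io, kinetics, lectin, phquant, synthetic_data

__all__ = ["StageError", "load_config", "run_pipeline"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError("run config must be a mapping")
    cfg.setdefault("seed", 0)
    cfg.setdefault("stages", [])
    if "outdir" not in cfg:
        raise ValueError("run config requires an 'outdir'")
    return cfg


def _stage_electro(cfg: dict, seed: int, outdir: Path) -> dict:
    p = cfg.get("electro", {})
    cond = electrochem.MembraneConditions(
        temperature=p.get("temp", 310.15),
        ph_lumen=p.get("ph_lumen", 6.0),
        ph_cytosol=p.get("ph_cyto", 7.0),
    )
    k = electrochem.IonSpecies(
        "K+", 1, p.get("k_cyto", 140.0), p.get("k_lumen", 107.0)
    )
    dec = electrochem.decompose_proton_motive(k, p.get("cl_cyto", 4.0), cond)
    out = dec.as_dict()
    out["rounded"] = {
        "slope_mV_per_decade": round(dec.slope_mV_per_decade, 1),
        "potassium_term_mV": round(dec.potassium_term),
        "chloride_lumen_equilibrium_mM": round(dec.chloride_lumen_equilibrium, 1),
    }
    return out


def _stage_calibration(cfg: dict, seed: int, outdir: Path) -> dict:
    p = cfg.get("calibration", {})
    spec = synthetic_data.CalibrationSpec(cv=p.get("cv", 0.02))
    table = synthetic_data.gen_calibration(spec, seed)
    io.write_table(table, outdir / "calibration.csv", schema="calibration",
                   metadata={"seed": seed, "cv": spec.cv})
    curve = phquant.fit_calibration(list(zip(table["ph"], table["ratio"])))
    return {
        "midpoint_ph": curve.midpoint_ph,
        "hill_slope": curve.hill_slope,
        "r_min": curve.r_min,
        "r_max": curve.r_max,
        "residual_sd": curve.residual_sd,
        "_curve": curve,
    }


def _stage_cells(cfg: dict, seed: int, outdir: Path, curve) -> dict:
    p = cfg.get("cells", {})
    spec = synthetic_data.CellPopulationSpec(
        n_cells=p.get("n_cells", 2000), bimodal=p.get("bimodal", False)
    )
    table = synthetic_data.gen_cell_population(spec, seed + 1)
    io.write_table(
        table.drop(columns=["true_ph"]), outdir / "cells.csv", schema="cells",
        metadata={"seed": seed + 1, "n_cells": spec.n_cells},
    )
    ph = phquant.ratio_to_ph(curve, table["ratio"].to_numpy())
    ok = ~np.isnan(ph)
    out: dict = {
        "n_cells": int(ok.sum()),
        "resting_ph": dataclasses.asdict(phquant.box_summary(ph[ok])),
    }
    if not spec.bimodal:
        reg = phquant.bin_and_regress(table["expression_au"].to_numpy()[ok], ph[ok])
        out["bin_regression"] = {"slope": reg.slope, "r_squared": reg.r_squared}
    mix = phquant.detect_populations(ph[ok], seed=seed)
    out["mixture"] = {
        "n_components": mix.n_components,
        "means": [float(m) for m in mix.means],
        "weights": [float(w) for w in mix.weights],
    }
    return out


def _stage_rates(cfg: dict, seed: int, outdir: Path) -> dict:
    p = cfg.get("rates", {})
    spec = synthetic_data.TimecourseSpec(
        kinetic_preset=p.get("preset"), protocol=p.get("protocol", "acidify"),
        t_end=p.get("t_end", 10.0),
    )
    table = synthetic_data.gen_timecourse(spec, seed + 2)
    io.write_table(table, outdir / "timecourse.csv", schema="timecourse",
                   metadata={"seed": seed + 2})
    est = phquant.estimate_initial_rate(
        np.column_stack([table["time_min"], table["true_ph"]])
    )
    return {
        "initial_rate_ph_per_min": est.initial_rate,
        "plateau_ph": est.plateau_ph,
        "rate_constant": est.rate_constant,
    }


def _stage_simulate(cfg: dict, seed: int, outdir: Path) -> dict:
    p = cfg.get("simulate", {})
    preset = p.get("preset", "cos7_control")
    comp, params, cyto = kinetics.load_preset(preset)
    bath = kinetics.permeabilized_bath(p.get("bath", "cl_hco3"))
    protocol = kinetics.Protocol(
        [(0.0, "permeabilize", bath), (p.get("t_atp", 1.0), "add_atp", 10.0)]
    )
    traj = kinetics.simulate(
        comp, params, protocol, t_end=p.get("t_end", 30.0), dt_out=0.25, initial_bath=cyto
    )
    frame = traj.to_frame()
    frame.columns = [c.lower() for c in frame.columns]
    io.write_table(frame, outdir / f"trajectory_{preset}.csv", schema="trajectory",
                   metadata={"preset": preset})
    return {"preset": preset, "plateau_ph": float(traj.ph[-1])}


def _stage_lectin(cfg: dict, seed: int, outdir: Path) -> dict:
    p = cfg.get("lectin", {})
    fold_map_1 = {k: float(v) for k, v in p.get(
        "fold_map_pair1", {"L01": 2.0, "L05": 2.0, "L09": 0.5, "L13": 2.0, "L17": 0.5}
    ).items()}
    fold_map_2 = {k: float(v) for k, v in p.get(
        "fold_map_pair2", {"L01": 2.0, "L05": 0.5, "L09": 0.5, "L21": 2.0}
    ).items()}
    alpha = p.get("alpha", 0.05)

    results = {}
    sfs = []
    for tag, fold_map, s in (("pair1", fold_map_1, seed + 3), ("pair2", fold_map_2, seed + 4)):
        spec = synthetic_data.LectinArraySpec(fold_map=fold_map)
        spots = synthetic_data.gen_lectin_arrays(spec, s)
        io.write_table(spots, outdir / f"lectin_spots_{tag}.tsv", schema="lectin",
                       metadata={"seed": s, "fold_map": fold_map})
        fps = lectin.aggregate(spots)
        sf = lectin.subtract(fps[spec.condition_b], fps[spec.condition_a], alpha=alpha)
        sf.table.to_csv(outdir / f"subtracted_{tag}.csv", index=False)
        sfs.append(sf)
        results[tag] = {
            "significant": sorted(sf.significant_lectins),
            "n_significant": len(sf.significant_lectins),
        }
    cross = lectin.intersect_pairs(sfs[0], sfs[1])
    results["common_significant"] = list(cross.common_significant)
    results["concordant"] = list(cross.concordant)
    return results


def run_pipeline(config: dict | str | Path) -> dict:
    """Execute the configured stages in order and write ``summary.json``.

    A stage failure aborts the run with :class:`StageError` naming the
    stage; outputs of completed stages are left on disk.
    """
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    if "outdir" not in cfg:
        raise ValueError("run config requires an 'outdir'")
    seed = int(cfg.get("seed", 0))
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)

    summary: dict = {"version": __version__, "seed": seed, "stages": list(cfg.get("stages", []))}
    curve = None
    for stage in cfg.get("stages", []):
        try:
            if stage == "electro":
                summary["electro"] = _stage_electro(cfg, seed, outdir)
            elif stage == "calibration":
                res = _stage_calibration(cfg, seed, outdir)
                curve = res.pop("_curve")
                summary["calibration"] = res
            elif stage == "cells":
                if curve is None:
                    raise RuntimeError("'cells' requires the 'calibration' stage first")
                summary["cells"] = _stage_cells(cfg, seed, outdir, curve)
            elif stage == "rates":
                summary["rates"] = _stage_rates(cfg, seed, outdir)
            elif stage == "simulate":
                summary["simulate"] = _stage_simulate(cfg, seed, outdir)
            elif stage == "lectin":
                summary["lectin"] = _stage_lectin(cfg, seed, outdir)
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as exc:  # noqa: BLE001 - stage name context matters
            (outdir / "summary.json").write_text(
                json.dumps(summary, indent=2, sort_keys=True) + "\n"
            )
            raise StageError(stage, exc) from exc
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
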