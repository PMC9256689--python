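"""End-to-end run orchestration: fixtures -> CG -> phantom -> tracks -> damage.

A run is described by a YAML config (see :class:`RunConfig`); every
stochastic stage derives its own seed from the master seed through a
``numpy`` SeedSequence spawn, so a run is fully reproducible from its
config alone.  Each LET point of the beam ladder is simulated either for
a fixed number of primaries or until a target absorbed dose is reached
(events are generated in batches so deposition arrays never grow with
the whole run).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial import cKDTree

from . import __version__
from .cgbuild import BeadArray, build_cg_model, write_cg
from .damage import find_breaks, tally_damage, yields, ALL_CLASSES
from .fixtures import build_bdna, write_pdb
from .phantom import bp_density, flatten_beads, place_segments, write_layout
from .tracks import BeamSpec, absorbed_dose, generate_events, score_events, write_events


@dataclass
class RunConfig:
    bp_per_segment: int = 436
    topology: str = "circular"
    form_fractions: dict = field(default_factory=lambda: {"supercoiled": 0.9, "relaxed": 0.1})
    n_segments: int = 20
    phantom_radius_um: float = 0.1
    scoring_radius_mode: str = "hydration"
    let_points_kev_um: list = field(default_factory=lambda: [10.0, 40.0, 160.0])
    n_events: int = 2000
    target_dose_gy: float | None = None
    mean_energy_per_deposit_ev: float = 40.0
    radial_sigma_nm: float = 2.0
    max_separation_bp: int = 10
    seed: int = 1
    save_events: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def run_pipeline(config: RunConfig, outdir: str | Path) -> "pd.DataFrame":
    """Execute the full damage-estimation pipeline into ``outdir``.

    Writes per-form model PDBs and CG files, the phantom layout, a
    per-LET damage summary CSV and a JSON log (versions, seeds, timings).
    Returns the summary as a DataFrame.
    """
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    seeds = np.random.SeedSequence(config.seed).spawn(3 + len(config.let_points_kev_um))
    seed_ints = [int(s.generate_state(1)[0] % 2**31) for s in seeds]
    log: dict = {
        "version": __version__,
        "master_seed": config.seed,
        "stage_seeds": seed_ints,
        "stages": {},
    }
    config.to_yaml(outdir / "config.yaml")

    # 1-2: atomic fixtures and CG models per form
    forms = list(config.form_fractions)
    cg_models: dict[str, BeadArray] = {}
    for form in forms:
        model = build_bdna(
            config.bp_per_segment, config.topology, form, rng_seed=seed_ints[0]
        )
        beads = build_cg_model(
            model, scoring_radius_mode=config.scoring_radius_mode, rng_seed=seed_ints[0]
        )
        write_pdb(model, outdir / f"model_{form}.pdb")
        write_cg(beads, outdir / f"model_{form}.cg")
        cg_models[form] = BeadArray.from_beads(beads)
    log["stages"]["cg_build"] = {"elapsed_s": round(time.time() - t0, 3)}

    # 3: phantom
    t1 = time.time()
    phantom = place_segments(
        config.n_segments,
        config.phantom_radius_um,
        cg_models,
        form_fractions=config.form_fractions,
        rng_seed=seed_ints[1],
        bp_per_segment=config.bp_per_segment,
    )
    write_layout(phantom, outdir / "phantom.tsv")
    flat = flatten_beads(phantom, cg_models)
    tree = cKDTree(flat.centers)
    log["stages"]["phantom"] = {
        "elapsed_s": round(time.time() - t1, 3),
        "n_segments": len(phantom.placements),
        "bp_density_per_nm3": bp_density(phantom),
    }

    # 4-5: per-LET tracks, scoring, damage
    rows = []
    batch = 500
    for k, let in enumerate(config.let_points_kev_um):
        t2 = time.time()
        let_seed = seed_ints[3 + k]
        breaks_all = []
        total_energy_ev = 0.0
        n_done = 0
        dose = 0.0
        saved = []
        while True:
            if config.target_dose_gy is None and n_done >= config.n_events:
                break
            if config.target_dose_gy is not None and dose >= config.target_dose_gy:
                break
            n_batch = batch if config.target_dose_gy is not None else min(
                batch, config.n_events - n_done
            )
            spec = BeamSpec(
                nominal_let_kev_um=let,
                mean_energy_per_deposit_ev=config.mean_energy_per_deposit_ev,
                radial_sigma_nm=config.radial_sigma_nm,
                n_events=n_batch,
                rng_seed=(let_seed + n_done) % 2**31,
            )
            events = generate_events(spec, config.phantom_radius_um)
            for ev in events:  # global event ids
                ev.event_id += n_done
            scores = score_events(events, flat, tree=tree)
            breaks_all.extend(find_breaks(scores, flat))
            total_energy_ev += scores.total_energy
            if config.save_events:
                saved.extend(events)
            n_done += n_batch
            dose = absorbed_dose(total_energy_ev, config.phantom_radius_um)
        if config.save_events:
            write_events(saved, outdir / f"events_let{let:g}.tsv")
        tally = tally_damage(
            breaks_all,
            max_separation=config.max_separation_bp,
            topology=config.topology,
            n_bp=config.bp_per_segment,
        )
        y = yields(tally, dose, phantom.total_bp, nominal_let=let) if dose > 0 else None
        row = {
            "let_kev_um": let,
            "n_events": n_done,
            "dose_gy": dose,
            "ssb_yield_gy_gbp": y.ssb_yield if y else float("nan"),
            "dsb_yield_gy_gbp": y.dsb_yield if y else float("nan"),
            "ssb_dsb_ratio": (
                y.ssb_yield / y.dsb_yield if y and y.dsb_yield > 0 else float("nan")
            ),
        }
        for c in ALL_CLASSES:
            row[f"n_{c}"] = tally.counts[c]
        rows.append(row)
        log["stages"][f"let_{let:g}"] = {
            "elapsed_s": round(time.time() - t2, 3),
            "seed": let_seed,
            "n_events": n_done,
        }
    summary = pd.DataFrame(rows)
    summary.to_csv(outdir / "summary.csv", index=False)
    log["elapsed_total_s"] = round(time.time() - t0, 3)
    with open(outdir / "log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    return summary


def let_ladder_study(
    lets=(20.0, 40.0, 80.0, 160.0, 320.0),
    seeds=(1, 2, 3, 4, 5),
    n_segments: int = 20,
    phantom_radius_um: float = 0.11,
    bp_per_segment: int = 436,
    target_dose_gy: float = 6e5,
    mean_energy_per_deposit_ev: float = 40.0,
):
    """SSB/DSB yields over a deposit-clustering (LET surrogate) ladder.

    Runs the synthetic-track pipeline at each LET rung for each seed,
    generating primaries until the target absorbed dose is reached, and
    returns one row per (seed, LET) with yields and the SSB/DSB ratio.
    The DNA density is raised well above the dilute plasmid reference so
    that break statistics accumulate at desk scale; the LET trend, not
    the absolute yield, is the object of this study.
    """
    import pandas as pd
    from scipy.spatial import cKDTree as _KDTree

    cg_models = {
        form: BeadArray.from_beads(
            build_cg_model(build_bdna(bp_per_segment, "circular", form))
        )
        for form in ("supercoiled", "relaxed")
    }
    rows = []
    for seed in seeds:
        phantom = place_segments(
            n_segments,
            phantom_radius_um,
            cg_models,
            rng_seed=seed,
            bp_per_segment=bp_per_segment,
        )
        flat = flatten_beads(phantom, cg_models)
        tree = _KDTree(flat.centers)
        for k, let in enumerate(lets):
            breaks_all = []
            total_energy = 0.0
            n_done = 0
            dose = 0.0
            while dose < target_dose_gy:
                spec = BeamSpec(
                    nominal_let_kev_um=let,
                    mean_energy_per_deposit_ev=mean_energy_per_deposit_ev,
                    n_events=500,
                    rng_seed=(seed * 100_003 + k * 1009 + n_done) % 2**31,
                )
                events = generate_events(spec, phantom_radius_um)
                for ev in events:
                    ev.event_id += n_done
                scores = score_events(events, flat, tree=tree)
                breaks_all.extend(find_breaks(scores, flat))
                total_energy += scores.total_energy
                n_done += 500
                dose = absorbed_dose(total_energy, phantom_radius_um)
            tally = tally_damage(
                breaks_all, topology="circular", n_bp=bp_per_segment
            )
            y = yields(tally, dose, phantom.total_bp, nominal_let=let)
            rows.append(
                {
                    "seed": seed,
                    "let_kev_um": let,
                    "n_events": n_done,
                    "dose_gy": dose,
                    "ssb_yield_gy_gbp": y.ssb_yield,
                    "dsb_yield_gy_gbp": y.dsb_yield,
                    "ssb_dsb_ratio": (
                        y.ssb_yield / y.dsb_yield if y.dsb_yield > 0 else float("nan")
                    ),
                    "total_breaks": tally.total_breaks,
                }
            )
    return pd.DataFrame(rows)
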