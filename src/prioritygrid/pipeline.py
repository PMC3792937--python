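"""Orchestration: run the full two-level analysis from a config.

Stages, in order: predictor prep (aggregation + VIF screening), per-species
ensemble SDM, range construction, priority maps, reserve gap analysis, and
— when both levels run — the cross-scale congruence report. All randomness
fans out from one master seed via numpy SeedSequence spawning, keyed by
stage and species index, so species-level work never shares streams.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import crossscale, gap, priority, sdm, synthetic
from .grids import GridSpec, Layer, read_ascii_grid, write_ascii_grid
from .predictors import PredictorStack, aggregate_stack, vif_screen
from .sdm import default_learners

logger = logging.getLogger("prioritygrid")

SCHEMA_VERSION = 1

_DEFAULTS: dict[str, Any] = {
    "schema_version": SCHEMA_VERSION,
    "mode": "synthetic",
    "seed": 0,
    "out_dir": "prioritygrid_out",
    "paths": {"records": None, "predictor_dir": None, "reserves": None},
    "synthetic": {
        "fine": {"origin_lon": 10.0, "origin_lat": 0.0, "cell_size": 0.1,
                 "n_rows": 48, "n_cols": 48},
        "nesting_factor": 4,
        "n_species": 5,
        "n_predictors": 4,
        "records_per_species": 25,
        "reserve_fraction": 0.1,
    },
    "sdm": {
        "pseudo_absences_coarse": 500,
        "pseudo_absences_fine": 200,
        "folds": 10,
        "auc_cutoff": 0.7,
        "sensitivity_floor": 0.9,
        "min_records_for_model": 2,
        "learners": ["logistic", "boosted_trees", "random_forest"],
    },
    "priority": {"exact_limit": 20, "n_samples": 10000},
    "targets": {"pct_smallest": 100.0, "pct_largest": 5.0},
    "envelope_fraction": 0.01,
    "n_perm": 30000,
}


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for key, val in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(val, Mapping):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = val
    return out


@dataclass
class RunConfig:
    """Fully-resolved run settings; defaults match the reference analysis
    (500/200 pseudo-absences, AUC cutoff 0.7, sensitivity floor 0.9,
    targets 100%/5%, best-1% envelopes, 30000 permutations)."""

    data: dict[str, Any] = field(default_factory=lambda: dict(_DEFAULTS))

    @classmethod
    def from_dict(cls, override: Mapping | None = None) -> "RunConfig":
        return cls(_deep_merge(_DEFAULTS, override or {}))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        return cls.from_dict(loaded)

    def __getitem__(self, key: str) -> Any:
        return self.data[key]

    def hash(self) -> str:
        canon = json.dumps(self.data, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()


def validate_config(config: RunConfig) -> list[str]:
    """Accumulate every problem found; never raises, never mutates."""
    errors: list[str] = []
    d = config.data
    if d.get("mode") not in ("synthetic", "files"):
        errors.append(f"mode must be 'synthetic' or 'files', got {d.get('mode')!r}")
    syn = d.get("synthetic", {})
    fine = syn.get("fine", {})
    try:
        spec = GridSpec(**fine)
        k = int(syn.get("nesting_factor", 0))
        if k < 2:
            errors.append(f"nesting_factor must be >= 2, got {k}")
        elif spec.n_rows % k or spec.n_cols % k:
            errors.append(
                f"fine grid {spec.shape} is not divisible by nesting_factor "
                f"{k}: grids would not nest"
            )
    except (TypeError, ValueError) as exc:
        errors.append(f"invalid fine grid spec: {exc}")
    frac = d.get("envelope_fraction")
    if not (isinstance(frac, (int, float)) and 0 < frac < 1):
        errors.append(f"envelope_fraction must be in (0, 1), got {frac!r}")
    sdm_cfg = d.get("sdm", {})
    if not 0 <= sdm_cfg.get("auc_cutoff", 0.7) < 1:
        errors.append("sdm.auc_cutoff must be in [0, 1)")
    if not 0 < sdm_cfg.get("sensitivity_floor", 0.9) <= 1:
        errors.append("sdm.sensitivity_floor must be in (0, 1]")
    known = {l.name for l in default_learners()}
    unknown = set(sdm_cfg.get("learners", [])) - known
    if unknown:
        errors.append(f"unknown learners: {sorted(unknown)} (available: {sorted(known)})")
    for key in ("pseudo_absences_coarse", "pseudo_absences_fine", "folds"):
        if sdm_cfg.get(key, 1) < 1:
            errors.append(f"sdm.{key} must be >= 1")
    if d.get("priority", {}).get("n_samples", 10000) < 1000:
        errors.append("priority.n_samples must be >= 1000")
    if d.get("n_perm", 1) < 1:
        errors.append("n_perm must be >= 1")
    if not syn.get("reserve_fraction", 0) <= 0.5:
        errors.append("synthetic.reserve_fraction must be <= 0.5")
    if d.get("mode") == "files":
        paths = d.get("paths", {})
        for key in ("records", "predictor_dir", "reserves"):
            if not paths.get(key):
                errors.append(f"paths.{key} required in files mode")
    return errors


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stage_seeds: dict[str, int]
    outputs: dict[str, str]  # path -> sha256 of contents

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def _spawn_seed(master: int, *key: int) -> int:
    """Deterministic child seed from the master seed and an integer key path."""
    ss = np.random.SeedSequence(entropy=master, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0])


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class LevelResult:
    name: str
    spec: GridSpec
    stack: PredictorStack
    ranges: dict[str, sdm.SpeciesRange]
    model_report: pd.DataFrame
    maps: priority.PriorityMaps
    gap_report: pd.DataFrame
    protected: set
    coverage_threshold: float


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> RunManifest:
    errors = validate_config(config)
    if errors:
        raise StageError("validate_config", "; ".join(errors))
    d = config.data
    master = int(d["seed"])
    out = Path(out_dir or d["out_dir"])
    out.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    if d["mode"] == "synthetic":
        world = _build_world(d, master)
    else:
        world = _load_world(d)
    logger.info("stage inputs done in %.1fs", time.perf_counter() - t0)

    stage_seeds = {"world": _spawn_seed(master, 0)}
    outputs: dict[str, str] = {}

    fine_stack = PredictorStack(world.fine_spec, world.predictors)
    levels: list[LevelResult] = []
    for level_idx, (name, spec) in enumerate(
        [("coarse", world.coarse_spec), ("fine", world.fine_spec)]
    ):
        t0 = time.perf_counter()
        try:
            stack = (aggregate_stack(fine_stack, spec)
                     if name == "coarse" else fine_stack)
            stack = vif_screen(stack)
        except Exception as exc:
            raise StageError(f"predictor_prep[{name}]", str(exc)) from exc

        levels.append(_run_level(name, level_idx, spec, stack, world, d,
                                 master, out, outputs))
        logger.info("level %s done in %.1fs", name, time.perf_counter() - t0)

    try:
        _cross_scale_report(levels, world, d, master, out, outputs)
    except Exception as exc:
        raise StageError("cross_scale", str(exc)) from exc

    manifest = RunManifest(
        config_hash=config.hash(),
        seed=master,
        version=_version(),
        stage_seeds=stage_seeds,
        outputs=outputs,
    )
    manifest.to_json(out / "manifest.json")
    return manifest


def _version() -> str:
    from . import __version__
    return __version__


def _build_world(d: dict, master: int) -> synthetic.SyntheticWorld:
    syn = d["synthetic"]
    fine = GridSpec(**syn["fine"])
    return synthetic.make_world(
        seed=_spawn_seed(master, 0),
        fine_spec=fine,
        nesting_factor=syn["nesting_factor"],
        n_species=syn["n_species"],
        n_predictors=syn["n_predictors"],
        records_per_species=syn["records_per_species"],
        reserve_fraction=syn["reserve_fraction"],
    )


def _load_world(d: dict) -> synthetic.SyntheticWorld:
    paths = d["paths"]
    pred_dir = Path(paths["predictor_dir"])
    if not pred_dir.is_dir():
        raise StageError("predictor_prep", f"predictor directory not found: {pred_dir}")
    layers = []
    for asc in sorted(pred_dir.glob("*.asc")):
        layers.append(read_ascii_grid(asc, categorical=asc.stem == "landcover"))
    if not layers:
        raise StageError("predictor_prep", f"no .asc layers in {pred_dir}")
    fine_spec = layers[0].spec
    records: dict[str, list[tuple[float, float]]] = {}
    with open(paths["records"]) as fh:
        for row in csv.DictReader(fh):
            records.setdefault(row["species"], []).append(
                (float(row["lon"]), float(row["lat"])))
    reserves = gap.read_reserves_geojson(paths["reserves"])
    k = int(d["synthetic"]["nesting_factor"])
    return synthetic.SyntheticWorld(
        fine_spec=fine_spec,
        coarse_spec=fine_spec.coarsen(k),
        nesting_factor=k,
        predictors=layers,
        true_suitability={},
        true_range={},
        records=records,
        reserves=reserves,
        reserve_fraction=float("nan"),
    )


def _run_level(name, level_idx, spec, stack, world, d, master, out,
               outputs) -> LevelResult:
    sdm_cfg = d["sdm"]
    n_pa = (sdm_cfg["pseudo_absences_coarse"] if name == "coarse"
            else sdm_cfg["pseudo_absences_fine"])
    learners = [l for l in default_learners() if l.name in sdm_cfg["learners"]]
    min_records = sdm_cfg["min_records_for_model"]

    ranges: dict[str, sdm.SpeciesRange] = {}
    report_rows = []
    for sp_idx, (sp, pts) in enumerate(sorted(world.records.items())):
        try:
            record_cells = {spec.cell_of(lon, lat) for lon, lat in pts}
            if len(pts) < min_records:
                ranges[sp] = sdm.single_cell_range(spec, pts[0], name=f"{sp}_range")
                report_rows.append({"species": sp, "level": name,
                                    "modeled": False, "threshold": np.nan,
                                    "criterion": "single_record"})
                continue
            pa_seed = _spawn_seed(master, 1, level_idx, sp_idx)
            n_pa_sp = min(n_pa, spec.n_cells - len(record_cells) - 1)
            pas = sdm.sample_pseudo_absences(spec, record_cells, n_pa_sp, pa_seed)
            result = sdm.fit_ensemble(
                stack, record_cells, pas, learners,
                folds=sdm_cfg["folds"],
                seed=_spawn_seed(master, 2, level_idx, sp_idx),
                species=sp, auc_cutoff=sdm_cfg["auc_cutoff"],
            )
            if not result.usable:
                ranges[sp] = sdm.single_cell_range(spec, pts[0], name=f"{sp}_range")
                report_rows.append({"species": sp, "level": name,
                                    "modeled": False, "threshold": np.nan,
                                    "criterion": "no_learner_passed"})
                continue
            cells = sorted(record_cells) + sorted(pas)
            labels = [1] * len(record_cells) + [0] * len(pas)
            scores = [result.consensus.values[r, c] for r, c in cells]
            theta, criterion = sdm.select_threshold(
                labels, scores, sdm_cfg["sensitivity_floor"])
            binary = sdm.binarize_with_override(result.consensus, theta,
                                                record_cells)
            ranges[sp] = sdm.barrier_clip(binary, pts)
            row = {"species": sp, "level": name, "modeled": True,
                   "threshold": theta, "criterion": criterion}
            for lname, a in result.learner_aucs.items():
                row[f"auc_{lname}"] = a
            report_rows.append(row)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"sdm[{name}]", f"species {sp}: {exc}") from exc

    model_report = pd.DataFrame(report_rows)

    try:
        range_cells = {sp: rng.cells for sp, rng in ranges.items()}
        range_sizes = {sp: len(c) for sp, c in range_cells.items()}
        targets = gap.set_targets(range_sizes,
                                  d["targets"]["pct_smallest"],
                                  d["targets"]["pct_largest"])
        coverage = gap.reserve_coverage(spec, world.reserves)
        total_area = sum(p.area for p in world.reserves)
        if world.reserves:
            theta_cov = gap.coverage_threshold(coverage, spec.cell_area, total_area)
            protected = gap.protected_cells(coverage, theta_cov)
        else:
            theta_cov, protected = 1.0, set()
        gap_report = gap.gap_analysis(range_cells, protected, targets)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"reserve_gap[{name}]", str(exc)) from exc

    try:
        rich = priority.richness({sp: rng.binary for sp, rng in ranges.items()})
        tset = priority.TargetSet(
            {sp: frozenset(c) for sp, c in range_cells.items()},
            targets, frozenset(protected))
        pr_cfg = d["priority"]
        cv_layer = priority.conservation_value(
            spec, tset, pr_cfg["exact_limit"], pr_cfg["n_samples"],
            _spawn_seed(master, 3, level_idx, 0))
        comp_layer = priority.complementarity(
            spec, tset, pr_cfg["exact_limit"], pr_cfg["n_samples"],
            _spawn_seed(master, 3, level_idx, 1))
        maps = priority.PriorityMaps(rich, cv_layer, comp_layer)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"priority_mapping[{name}]", str(exc)) from exc

    level_dir = out / name
    level_dir.mkdir(exist_ok=True)
    for layer, fname in ((rich, "richness.asc"),
                         (cv_layer, "conservation_value.asc"),
                         (comp_layer, "complementarity.asc")):
        path = level_dir / fname
        write_ascii_grid(layer, path)
        outputs[str(path)] = _digest(path)
    for sp, rng in ranges.items():
        path = level_dir / f"range_{sp}.asc"
        write_ascii_grid(rng.binary, path)
        outputs[str(path)] = _digest(path)
    path = level_dir / "model_report.csv"
    model_report.to_csv(path, index=False)
    outputs[str(path)] = _digest(path)
    path = level_dir / "gap_report.csv"
    gap.write_gap_report(gap_report, path)
    outputs[str(path)] = _digest(path)

    return LevelResult(name, spec, stack, ranges, model_report, maps,
                       gap_report, protected, theta_cov)


def _cross_scale_report(levels, world, d, master, out, outputs) -> None:
    if len(levels) < 2:
        return
    coarse, fine = levels[0], levels[1]
    k = world.nesting_factor
    n_perm = d["n_perm"]
    frac = d["envelope_fraction"]
    rows = []

    # per-species: arcsine-transformed % protected range and % target met,
    # for species with ranges at both levels
    common = sorted(set(coarse.gap_report.index) & set(fine.gap_report.index))
    if len(common) >= 3:
        for col, label in (("pct_range_protected", "pct_protected"),
                           ("pct_target_met", "pct_target_met")):
            x = crossscale.arcsine_pct(coarse.gap_report.loc[common, col].to_numpy())
            y = crossscale.arcsine_pct(fine.gap_report.loc[common, col].to_numpy())
            try:
                res = crossscale.permutation_correlation(
                    x, y, n_perm, _spawn_seed(master, 4, 0, len(rows)))
                rows.append({"comparison": f"species:{label}", "r_obs": res.r_obs,
                             "p_value": res.p_value, "n": len(common),
                             "n_perm": n_perm})
            except ValueError as exc:
                rows.append({"comparison": f"species:{label}", "note": str(exc)})

    # per-cell: the three indices, fine value vs parent value
    index_layers = {
        "richness": (coarse.maps.richness, fine.maps.richness),
        "conservation_value": (coarse.maps.conservation_value,
                               fine.maps.conservation_value),
        "complementarity": (coarse.maps.complementarity,
                            fine.maps.complementarity),
    }
    nested_rows = []
    for idx_name, (c_layer, f_layer) in index_layers.items():
        try:
            xc, xf = crossscale.cross_scale_cell_pairs(c_layer, f_layer)
            res = crossscale.permutation_correlation(
                xc, xf, n_perm, _spawn_seed(master, 4, 1, len(rows)))
            rows.append({"comparison": f"cells:{idx_name}", "r_obs": res.r_obs,
                         "p_value": res.p_value, "n": len(xc), "n_perm": n_perm})
        except ValueError as exc:
            rows.append({"comparison": f"cells:{idx_name}", "note": str(exc)})
        try:
            c_env, c_frac = crossscale.priority_envelope(c_layer, frac)
            f_env, f_frac = crossscale.priority_envelope(f_layer, frac)
            nest = crossscale.nestedness(f_env, c_env, k)
            nested_rows.append({"index": idx_name,
                                "coarse_envelope_fraction": c_frac,
                                "fine_envelope_fraction": f_frac,
                                "nestedness_pct": nest})
        except ValueError as exc:
            nested_rows.append({"index": idx_name, "note": str(exc)})

    path = out / "cross_scale_correlations.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    outputs[str(path)] = _digest(path)
    path = out / "cross_scale_nestedness.csv"
    pd.DataFrame(nested_rows).to_csv(path, index=False)
    outputs[str(path)] = _digest(path)

    summary = out / "cross_scale_summary.txt"
    with open(summary, "w") as fh:
        for row in rows:
            if "r_obs" in row:
                fh.write(f"{row['comparison']}: r_obs={row['r_obs']:.3f} "
                         f"P={row['p_value']:.4g} (n={row['n']}, "
                         f"{row['n_perm']} permutations)\n")
            else:
                fh.write(f"{row['comparison']}: skipped ({row['note']})\n")
        for row in nested_rows:
            if "nestedness_pct" in row:
                fh.write(
                    f"{row['index']}: {row['nestedness_pct']:.1f}% of the best "
                    f"{100 * row['fine_envelope_fraction']:.1f}% fine cells fall in the "
                    f"best {100 * row['coarse_envelope_fraction']:.1f}% coarse cells\n")
            else:
                fh.write(f"{row['index']}: envelope skipped ({row['note']})\n")
    outputs[str(summary)] = _digest(summary)
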