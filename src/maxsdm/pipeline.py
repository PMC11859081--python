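"""End-to-end study pipeline.

One seeded run goes: synthetic world (or user rasters) -> occurrence
thinning -> variable screening -> RM x FC tuning -> current prediction
-> scenario projections -> classification and area tables -> niche
metrics -> priority-area gap analysis -> centroid tracks, writing CSV/
JSON artifacts and a manifest sufficient to re-run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import conservation, habitat, niche, synth
from .features import FEATURE_COMBINATIONS
from .grids import EnvStack, read_raster, write_raster
from .maxent import fit_occurrence_model, percent_contribution, predict
from .occurrences import OccurrenceSet, read_occurrences, thin_to_grid
from .screening import screen_variables
from .synth import ScenarioDelta, TrueModel
from .tuning import DEFAULT_RM_GRID, tune

logger = logging.getLogger(__name__)

__all__ = [
    "SpeciesConfig",
    "RunConfig",
    "RunManifest",
    "default_species",
    "default_scenarios",
    "run_pipeline",
]


@dataclass
class SpeciesConfig:
    """One species' synthetic truth and sampling conditions."""

    name: str
    n_occurrences: int
    noise: float = 0.05
    true_model: TrueModel | None = None


def default_species() -> list[SpeciesConfig]:
    """Three species mirroring the study structure: a narrow-niche
    species with 41 records, a very sparsely recorded one with 12, and
    a broad-niche species with 79."""
    return [
        SpeciesConfig(
            "species_narrow", 41,
            true_model=TrueModel(
                intercept=-5.5,
                linear_coeffs={"bio2": -5.0, "Ele": -4.5},
                quadratic_coeffs={"bio9": -4.5},
            ),
        ),
        SpeciesConfig(
            "species_rare", 12,
            true_model=TrueModel(
                intercept=-6.0,
                linear_coeffs={"bio2": -4.0, "Ele": -5.5, "bio9": 2.5},
                quadratic_coeffs={"bio9": -3.5},
            ),
        ),
        SpeciesConfig(
            "species_broad", 79,
            true_model=TrueModel(
                intercept=-2.5,
                linear_coeffs={"Ele": -2.0},
                quadratic_coeffs={"bio4": -3.0, "bio9": -2.5},
            ),
        ),
    ]


def default_scenarios() -> list[ScenarioDelta]:
    """Nine scenario deltas (3 forcing pathways x 3 periods).

    Warming raises the temperature-like layers (bio9 in deg C, bio2
    diurnal range slightly, bio4 seasonality); the high-forcing pathway
    also dries the precipitation-like layers (multiplicative).
    """
    warming = {
        "SSP126": {"2050": 1.0, "2070": 1.4, "2090": 1.5},
        "SSP245": {"2050": 1.5, "2070": 2.5, "2090": 3.2},
        "SSP585": {"2050": 2.2, "2070": 3.8, "2090": 5.5},
    }
    dry = {"SSP126": 1.0, "SSP245": 0.97, "SSP585": 0.92}
    out = []
    for ssp, periods in warming.items():
        for period, dt in periods.items():
            out.append(
                ScenarioDelta(
                    label=f"{ssp}-{period}",
                    shift={"bio9": dt, "bio2": 0.15 * dt, "bio4": 20.0 * dt},
                    scale={"bio12": dry[ssp], "bio17": dry[ssp]},
                )
            )
    return out


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    seed: int = 0
    mode: str = "synthetic"  # or "files"
    out_dir: str = "maxsdm_run"
    # synthetic world
    n_rows: int = 90
    n_cols: int = 120
    cell_size: float = 0.25
    origin: tuple[float, float] = (92.0, 18.5)
    species: list[SpeciesConfig] = field(default_factory=default_species)
    scenarios: list[ScenarioDelta] = field(default_factory=default_scenarios)
    pa_coverage: float = 0.03
    # files mode
    raster_paths: list[str] = field(default_factory=list)
    occurrence_csv: str | None = None
    pa_geojson: str | None = None
    # modelling
    rm_grid: tuple = DEFAULT_RM_GRID
    fc_grid: tuple = FEATURE_COMBINATIONS
    class_cuts: tuple = habitat.DEFAULT_CLASS_CUTS
    range_threshold: float = 0.4
    priority_min_species: int = 2
    centroid_threshold: float = 0.2
    write_rasters: bool = True

    def __post_init__(self) -> None:
        cuts = tuple(self.class_cuts)
        if not all(0.0 < a < b < 1.0 for a, b in zip(cuts, cuts[1:])) or not (
            0.0 < cuts[0] < 1.0
        ):
            raise ValueError("class cuts must be strictly increasing in (0, 1)")
        if not self.rm_grid or not self.fc_grid:
            raise ValueError("rm_grid and fc_grid must be non-empty")


@dataclass
class RunManifest:
    """Echo of the config plus everything needed to audit a run."""

    config: dict
    chosen: dict  # species -> {"fc": ..., "rm": ..., "mean_test_auc": ...}
    timings_s: dict
    outputs: dict  # logical name -> file name
    output_sha256: dict

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=1, default=str)
        if path is not None:
            Path(path).write_text(text)
        return text


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["rm_grid"] = [float(r) for r in config.rm_grid]
    return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _build_world(config: RunConfig):
    """Return (stack, {species: OccurrenceSet}, PAMask, {species: TrueModel})."""
    if config.mode == "synthetic":
        stack = synth.generate_env_stack(
            n_rows=config.n_rows, n_cols=config.n_cols,
            cell_size=config.cell_size, origin=config.origin, seed=config.seed,
        )
        occs, truths = {}, {}
        for i, sp in enumerate(config.species):
            model = sp.true_model or synth.default_true_model()
            truth = synth.true_suitability(model, stack)
            occs[sp.name] = synth.sample_occurrences(
                truth, sp.n_occurrences, seed=config.seed * 1000 + i,
                noise=sp.noise, species=sp.name,
            )
            truths[sp.name] = model
        pa = synth.generate_pa_mask(
            stack.grid, config.pa_coverage, seed=config.seed + 7919
        )
        return stack, occs, pa, truths
    if config.mode == "files":
        if not config.raster_paths or config.occurrence_csv is None:
            raise ValueError("files mode needs raster_paths and occurrence_csv")
        from .grids import assemble_stack

        stack = assemble_stack([read_raster(p) for p in config.raster_paths])
        df = pd.read_csv(config.occurrence_csv)
        occs = {
            str(name): read_occurrences(config.occurrence_csv, species=str(name))
            for name in df["species"].unique()
        }
        if config.pa_geojson:
            pa = conservation.pa_mask_from_geojson(config.pa_geojson, stack.grid)
        else:
            pa = synth.PAMask(grid=stack.grid, member=np.zeros(stack.grid.shape, bool))
        return stack, occs, pa, {}
    raise ValueError(f"unknown mode {config.mode!r}")


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute every stage in order and write all artifacts.

    Stage failures abort with the stage name; the partial manifest is
    still written.  Same config and seed -> byte-identical CSV output.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    outputs: dict[str, str] = {}
    chosen: dict[str, dict] = {}
    manifest = RunManifest(
        config=_config_dict(config), chosen=chosen,
        timings_s=timings, outputs=outputs, output_sha256={},
    )
    stage = "init"

    def tic() -> float:
        return time.perf_counter()

    def save_csv(key: str, df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=True, float_format="%.10g")
        outputs[key] = name

    try:
        stage = "world"
        t0 = tic()
        stack, occs, pa, _truths = _build_world(config)
        timings[stage] = tic() - t0

        stage = "thin"
        t0 = tic()
        thinned = {
            name: thin_to_grid(occ, stack.grid, stack.joint_mask)
            for name, occ in occs.items()
        }
        for name, occ in thinned.items():
            save_csv(f"occurrences_{name}", occ.to_frame(), f"occurrences_{name}.csv")
        timings[stage] = tic() - t0

        current_maps: dict[str, "object"] = {}
        class_current: dict[str, habitat.ClassMap] = {}
        for name, occ in thinned.items():
            logger.info("species %s: %d thinned records", name, len(occ))
            stage = f"screen[{name}]"
            t0 = tic()
            screened, contrib, corr, prune_report = screen_variables(
                occ, stack, seed=config.seed
            )
            save_csv(f"contributions_{name}",
                     contrib.to_frame("percent_contribution"),
                     f"contributions_{name}.csv")
            save_csv(f"correlation_{name}", corr, f"correlation_{name}.csv")
            timings[stage] = tic() - t0
            logger.info("species %s: screened to %s", name, screened.names)

            stage = f"tune[{name}]"
            t0 = tic()
            result = tune(
                occ, screened, rm_grid=config.rm_grid, fc_grid=config.fc_grid,
                seed=config.seed,
            )
            save_csv(f"tuning_{name}", result.table, f"tuning_{name}.csv")
            row = result.chosen
            chosen[name] = {
                "fc": row["fc"], "rm": float(row["rm"]), "k": int(row["k"]),
                "aicc": float(row["aicc"]),
                "mean_test_auc": float(row["mean_test_auc"]),
                "variables": screened.names,
            }
            timings[stage] = tic() - t0
            logger.info(
                "species %s: chose FC=%s RM=%.1f (k=%d, AICc=%.2f, test AUC=%.3f)",
                name, row["fc"], row["rm"], row["k"], row["aicc"],
                row["mean_test_auc"],
            )

            stage = f"predict[{name}]"
            t0 = tic()
            model = result.chosen_model
            model.to_json(out / f"model_{name}.json")
            outputs[f"model_{name}"] = f"model_{name}.json"
            smap = predict(model, screened)
            smap.label = "current"
            current_maps[name] = smap
            cmap = habitat.classify(smap, cuts=config.class_cuts)
            class_current[name] = cmap
            if config.write_rasters:
                from .grids import EnvLayer

                lyr = EnvLayer(name=f"hsi_{name}", grid=smap.grid,
                               values=smap.values, mask=smap.mask)
                write_raster(lyr, out / f"suitability_current_{name}.asc")
                outputs[f"suitability_current_{name}"] = f"suitability_current_{name}.asc"
            timings[stage] = tic() - t0

            stage = f"project[{name}]"
            t0 = tic()
            scen_cmaps: dict[str, list[habitat.ClassMap]] = {}
            scen_centroids: dict[str, list[tuple[float, float]]] = {}
            for delta in config.scenarios:
                future = synth.make_future_stack(stack, delta).subset(screened.names)
                fmap = habitat.project_future(model, future)
                scen = delta.label.split("-")[0]
                scen_cmaps.setdefault(scen, []).append(
                    habitat.classify(fmap, cuts=config.class_cuts)
                )
                scen_centroids.setdefault(scen, []).append(
                    conservation.suitable_centroid(fmap, config.centroid_threshold)
                )
            table = habitat.area_table(cmap, scen_cmaps)
            save_csv(f"areas_{name}", table, f"areas_{name}.csv")
            c0 = conservation.suitable_centroid(smap, config.centroid_threshold)
            tracks = []
            for scen, cents in scen_centroids.items():
                periods = ["current"] + [
                    d.label.split("-")[1] for d in config.scenarios
                    if d.label.startswith(scen)
                ]
                tracks.append(
                    conservation.centroid_track(scen, periods, [c0] + cents)
                )
            save_csv(f"centroids_{name}", pd.concat(tracks, ignore_index=True),
                     f"centroids_{name}.csv")
            timings[stage] = tic() - t0

        stage = "niche"
        t0 = tic()
        metrics = niche.niche_metrics(current_maps, threshold=config.range_threshold)
        save_csv("niche_metrics", metrics.to_table(), "niche_metrics.csv")
        timings[stage] = tic() - t0

        stage = "gaps"
        t0 = tic()
        priority = conservation.priority_areas(
            class_current, min_species=config.priority_min_species
        )
        if priority.any():
            gap = conservation.gap_analysis(priority, pa, stack.grid)
            gap.to_json(out / "gap_report.json")
            logger.info("gap analysis: %.2f%% of priority area unprotected",
                        gap.percent_unprotected)
        else:
            # no cell is moderately+ suitable for enough species
            (out / "gap_report.json").write_text(json.dumps(
                {"priority_area_1e4_km2": 0.0, "protected_overlap_1e4_km2": 0.0,
                 "percent_unprotected": None, "note": "empty priority area"},
                indent=1))
            logger.info("gap analysis: empty priority area")
        outputs["gap_report"] = "gap_report.json"
        timings[stage] = tic() - t0
    except Exception as exc:
        manifest.to_json(out / "manifest.json")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    stage = "manifest"
    manifest.output_sha256 = {k: _sha256(out / v) for k, v in outputs.items()}
    manifest.to_json(out / "manifest.json")
    return manifest
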