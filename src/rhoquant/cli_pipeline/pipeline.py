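"""End-to-end pipeline: generate synthetic scenes, run every quantification,
write CSV/TIFF outputs plus a structured log.

A single global seed fans out into per-stage named substreams
(``substream(seed, "stage", name)``), so adding or reordering stages never
perturbs the randomness any other stage sees.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .. import __version__
from ..aux_quant import (
    GelBand,
    classify_annexin_pi,
    densitometry_fold,
    gate_cell_cycle,
)
from ..fret_ratio import (
    correct_background,
    estimate_background_mask,
    fret_fold_change,
    make_cell_mask,
    ratio_image,
)
from ..img_io import write_raster, write_tracks
from ..img_io.rasterio import write_mask
from ..matrix_degradation import background_roi, degradation_fold, degradation_index
from ..motility import closure_rate, cohort_speed, wound_widths
from ..puncta_detect import clahe, detect_puncta, invadopodia_count
from ..scene_sim import (
    CytometrySimParams,
    FretSceneParams,
    MatrixSceneParams,
    MotilitySceneParams,
    PunctaSceneParams,
    WoundSceneParams,
    make_cytometry_events,
    make_fret_scene,
    make_gel_lanes,
    make_matrix_scene,
    make_puncta_scene,
    make_track_set,
    make_wound_series,
)
from ..scene_sim.streams import substream

logger = logging.getLogger(__name__)

KNOWN_STAGES = (
    "fret",
    "matrix",
    "puncta",
    "wound",
    "motility",
    "cellcycle",
    "annexin",
    "densitometry",
)
_TOP_KEYS = {"experiment", "seed", "outdir", "stages"}


class ConfigError(ValueError):
    pass


@dataclasses.dataclass
class RunConfig:
    experiment: str
    seed: int
    outdir: str
    stages: dict[str, dict]

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        stages = raw.get("stages", {})
        bad = set(stages) - set(KNOWN_STAGES)
        if bad:
            raise ConfigError(f"unknown stages: {sorted(bad)}")
        return cls(
            experiment=str(raw.get("experiment", "run")),
            seed=int(raw.get("seed", 0)),
            outdir=str(raw.get("outdir", "results")),
            stages={k: dict(v or {}) for k, v in stages.items()},
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError("config must be a YAML mapping")
        return cls.from_dict(raw)


def _stage_seed(seed: int, stage: str) -> int:
    return int(substream(seed, "stage", stage).integers(0, 2**31 - 1))


# ------------------------------------------------------------------ stages


def _run_fret(params: dict, seed: int, outdir: Path) -> list[dict]:
    n = int(params.get("n_cells", 5))
    true_ratio = float(params.get("true_ratio", 1.6))
    sigma = float(params.get("noise_sigma", 50.0))

    def cell_means(ratio: float, tag: str) -> list[float]:
        means = []
        for i in range(n):
            p = FretSceneParams(
                ratio_baseline=ratio,
                gaussian_sigma=sigma,
                seed=_stage_seed(seed, f"fret-{tag}-{i}"),
            )
            image_set, _, _ = make_fret_scene(p)
            mask = make_cell_mask(image_set.acceptor)
            bg = estimate_background_mask(mask)
            donor = correct_background(image_set.donor, bg)
            fret = correct_background(image_set.fret, bg)
            corrected = dataclasses.replace(image_set, donor=donor, fret=fret)
            ri = ratio_image(corrected, mask, donor_floor=3.0 * sigma)
            if i == 0 and tag == "sample":
                out = np.where(np.isnan(ri.pixels), 0.0, ri.pixels)
                write_raster(
                    dataclasses.replace(donor, pixels=out), outdir / "fret_ratio.tif"
                )
            means.append(ri.mean_ratio)
        return means

    sample = cell_means(true_ratio, "sample")
    control = cell_means(1.0, "control")
    fold = fret_fold_change(sample, control)
    pd.DataFrame(
        {"condition": ["sample"] * n + ["control"] * n, "mean_ratio": sample + control}
    ).to_csv(outdir / "fret_cells.csv", index=False)
    return [
        {"stage": "fret", "metric": "mean_ratio_sample", "value": float(np.mean(sample))},
        {"stage": "fret", "metric": "fold_vs_control", "value": fold},
    ]


def _run_matrix(params: dict, seed: int, outdir: Path) -> list[dict]:
    n = int(params.get("n_cells", 4))
    frac = float(params.get("degraded_fraction", 0.3))

    def indices(f: float, tag: str) -> list[float]:
        out = []
        for i in range(n):
            p = MatrixSceneParams(
                degraded_fraction=f if f > 0 else None,
                seed=_stage_seed(seed, f"matrix-{tag}-{i}"),
                noise_sigma=float(params.get("noise_sigma", 20.0)),
            )
            raster, footprint, _ = make_matrix_scene(p)
            roi = background_roi(footprint)
            out.append(degradation_index(raster, footprint, roi, cell_id=i).index)
        return out

    sample = indices(frac, "sample")
    control = indices(0.0, "control")
    fold = degradation_fold(sample, control)
    pd.DataFrame(
        {"condition": ["sample"] * n + ["control"] * n, "index": sample + control}
    ).to_csv(outdir / "degradation.csv", index=False)
    return [
        {"stage": "matrix", "metric": "mean_index_sample", "value": float(np.mean(sample))},
        {"stage": "matrix", "metric": "fold_vs_control", "value": fold},
    ]


def _run_puncta(params: dict, seed: int, outdir: Path) -> list[dict]:
    n_cells = int(params.get("n_cells", 5))
    n_puncta = int(params.get("n_puncta", 6))
    sets = []
    for i in range(n_cells):
        p = PunctaSceneParams(
            n_puncta=n_puncta,
            noise_sigma=float(params.get("noise_sigma", 30.0)),
            seed=_stage_seed(seed, f"puncta-{i}"),
        )
        raster, mask, _ = make_puncta_scene(p)
        enhanced = clahe(raster)
        sets.append(detect_puncta(enhanced, mask))
    counts, mean = invadopodia_count(sets)
    pd.concat([s.to_frame(cell_id=i) for i, s in enumerate(sets)]).to_csv(
        outdir / "puncta.csv", index=False
    )
    return [{"stage": "puncta", "metric": "mean_count_per_cell", "value": mean}]


def _run_wound(params: dict, seed: int, outdir: Path) -> list[dict]:
    p = WoundSceneParams(
        initial_width_um=float(params.get("initial_width_um", 500.0)),
        closure_rate_um_hr=float(params.get("closure_rate_um_hr", 5.0)),
        roughness_um=float(params.get("roughness_um", 5.0)),
        frame_times_hr=tuple(params.get("frame_times_hr", (0.0, 48.0))),
        seed=_stage_seed(seed, "wound"),
    )
    masks, truth = make_wound_series(p)
    w0 = wound_widths(masks[0], pixel_size_um=p.pixel_size_um)
    w1 = wound_widths(masks[-1], pixel_size_um=p.pixel_size_um)
    elapsed = p.frame_times_hr[-1] - p.frame_times_hr[0]
    rate = closure_rate(w0, w1, elapsed)
    write_mask(masks[0], outdir / "wound_t0.tif")
    write_mask(masks[-1], outdir / "wound_t1.tif")
    pd.DataFrame(
        {"line": range(len(w0.widths_um)), "width_t0_um": w0.widths_um, "width_t1_um": w1.widths_um}
    ).to_csv(outdir / "wound_widths.csv", index=False)
    return [{"stage": "wound", "metric": "closure_rate_um_hr", "value": rate}]


def _run_motility(params: dict, seed: int, outdir: Path) -> list[dict]:
    p = MotilitySceneParams(
        n_cells=int(params.get("n_cells", 15)),
        step_len_um=float(params.get("step_len_um", 0.3)),
        persistence=float(params.get("persistence", 0.5)),
        seed=_stage_seed(seed, "motility"),
    )
    tracks, _ = make_track_set(p)
    mean_speed, table = cohort_speed(tracks)
    write_tracks(tracks, outdir / "tracks.csv")
    table.to_csv(outdir / "speeds.csv", index=False)
    return [{"stage": "motility", "metric": "mean_speed_um_min", "value": mean_speed}]


def _run_cellcycle(params: dict, seed: int, outdir: Path) -> list[dict]:
    p = CytometrySimParams(
        n_events=int(params.get("n_events", 10_000)),
        fractions=tuple(params.get("fractions", (0.6, 0.2, 0.2))),
        seed=_stage_seed(seed, "cellcycle"),
    )
    events, _ = make_cytometry_events(p, mode="cellcycle")
    fr = gate_cell_cycle(events["pi"].to_numpy())
    events.to_csv(outdir / "cellcycle_events.csv", index=False)
    return [
        {"stage": "cellcycle", "metric": "frac_g0g1", "value": fr.g0g1},
        {"stage": "cellcycle", "metric": "frac_s", "value": fr.s},
        {"stage": "cellcycle", "metric": "frac_g2m", "value": fr.g2m},
    ]


def _run_annexin(params: dict, seed: int, outdir: Path) -> list[dict]:
    p = CytometrySimParams(
        n_events=int(params.get("n_events", 10_000)),
        apoptosis_fractions=tuple(params.get("fractions", (0.7, 0.2, 0.1))),
        seed=_stage_seed(seed, "annexin"),
    )
    events, _ = make_cytometry_events(p, mode="annexin")
    fr = classify_annexin_pi(events[["annexin", "pi"]].to_numpy())
    events.to_csv(outdir / "annexin_events.csv", index=False)
    return [
        {"stage": "annexin", "metric": "frac_live", "value": fr.live},
        {"stage": "annexin", "metric": "frac_early_apoptotic", "value": fr.early_apoptotic},
        {"stage": "annexin", "metric": "frac_necrotic", "value": fr.necrotic},
    ]


def _run_densitometry(params: dict, seed: int, outdir: Path) -> list[dict]:
    bands = list(params.get("band_intensities", (1.0, 2.5)))
    loads = list(params.get("loading_intensities", (1.0, 1.0)))
    table, _ = make_gel_lanes(
        bands, loads, noise_cv=float(params.get("noise_cv", 0.0)),
        seed=_stage_seed(seed, "densitometry"),
    )
    gel = [GelBand(r.lane, r.band, r.loading) for r in table.itertuples()]
    folds = densitometry_fold(gel, control_lane=table["lane"].iloc[0])
    table.to_csv(outdir / "gel_lanes.csv", index=False)
    return [
        {"stage": "densitometry", "metric": f"fold_{lane}", "value": f}
        for lane, f in folds.items()
    ]


_STAGE_RUNNERS = {
    "fret": _run_fret,
    "matrix": _run_matrix,
    "puncta": _run_puncta,
    "wound": _run_wound,
    "motility": _run_motility,
    "cellcycle": _run_cellcycle,
    "annexin": _run_annexin,
    "densitometry": _run_densitometry,
}


def paperlike_config(seed: int = 0, outdir: str = "results") -> RunConfig:
    """Demo config exercising all quantifications on synthetic scenes."""
    return RunConfig.from_dict(
        {
            "experiment": "paperlike",
            "seed": seed,
            "outdir": outdir,
            "stages": {name: {} for name in KNOWN_STAGES},
        }
    )


def run_pipeline(config: RunConfig | str | Path) -> Path:
    """Execute the configured stages; returns the results directory.

    Writes per-stage CSV/TIFF outputs, a consolidated ``summary.csv`` and
    ``run.log`` recording versions, seed and parameters.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig.from_yaml(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log_lines = [
        f"experiment={config.experiment}",
        f"seed={config.seed}",
        f"rhoquant={__version__}",
        f"numpy={np.__version__}",
        f"pandas={pd.__version__}",
    ]
    rows: list[dict] = []
    for stage, params in config.stages.items():
        log_lines.append(f"stage={stage} params={params!r}")
        try:
            rows.extend(_STAGE_RUNNERS[stage](params, config.seed, outdir))
        except Exception as exc:
            log_lines.append(f"stage={stage} status=failed error={exc!r}")
            (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        log_lines.append(f"stage={stage} status=ok")

    summary = pd.DataFrame(rows, columns=["stage", "metric", "value"])
    summary.to_csv(outdir / "summary.csv", index=False)
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    logger.info("pipeline finished: %s", outdir)
    return outdir


def make_demo_dataset(seed: int, outdir: str | Path) -> Path:
    """Write a small self-contained fixture set with ground-truth sidecars.

    Seven fixture groups: FRET triplet, matrix scene, puncta field, wound
    series, tracks, cytometry events (both modes) and gel lanes.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    truth_record: dict = {"seed": seed}

    image_set, mask, ft = make_fret_scene(
        FretSceneParams(shape=(128, 128), center=(64, 64), axes=(40, 24),
                        gaussian_sigma=20.0, ratio_baseline=1.6,
                        seed=_stage_seed(seed, "demo-fret"))
    )
    write_raster(image_set.donor, out / "fret_donor.tif")
    write_raster(image_set.fret, out / "fret_fret.tif")
    write_raster(image_set.acceptor, out / "fret_acceptor.tif")
    write_mask(mask, out / "fret_mask.tif")
    truth_record["fret"] = {"mean_ratio": ft.mean_ratio}

    raster, footprint, mt = make_matrix_scene(
        MatrixSceneParams(shape=(128, 128), center=(64, 64), axes=(40, 30),
                          degraded_fraction=0.3, noise_sigma=10.0,
                          seed=_stage_seed(seed, "demo-matrix"))
    )
    write_raster(raster, out / "matrix.tif")
    write_mask(footprint, out / "matrix_footprint.tif")
    truth_record["matrix"] = {
        "degraded_fraction": mt.degraded_fraction,
        "degradation_index": mt.degradation_index,
    }

    praster, pmask, pt = make_puncta_scene(
        PunctaSceneParams(shape=(128, 128), center=(64, 64), axes=(56, 56),
                          n_puncta=8, noise_sigma=20.0,
                          seed=_stage_seed(seed, "demo-puncta"))
    )
    write_raster(praster, out / "puncta.tif")
    write_mask(pmask, out / "puncta_mask.tif")
    truth_record["puncta"] = {"n_puncta": int(pt.n_puncta)}

    masks, wt = make_wound_series(
        WoundSceneParams(shape=(128, 256), roughness_um=5.0,
                         seed=_stage_seed(seed, "demo-wound"))
    )
    for i, m in enumerate(masks):
        write_mask(m, out / f"wound_t{i}.tif")
    truth_record["wound"] = {
        "nominal_width_um": wt.nominal_width_um,
        "closure_rate_um_hr": wt.closure_rate_um_hr,
    }

    tracks, tt = make_track_set(
        MotilitySceneParams(n_cells=5, n_frames=30, seed=_stage_seed(seed, "demo-tracks"))
    )
    write_tracks(tracks, out / "tracks.csv")
    truth_record["tracks"] = {"mean_speed_um_min": tt.mean_speed_um_min}

    for mode in ("cellcycle", "annexin"):
        events, ct = make_cytometry_events(
            CytometrySimParams(n_events=2000, seed=_stage_seed(seed, f"demo-{mode}")),
            mode=mode,
        )
        events.to_csv(out / f"{mode}_events.csv", index=False)
        truth_record[mode] = {"fractions": list(ct.fractions)}

    lanes, gt = make_gel_lanes([1.0, 2.5], [1.0, 1.0],
                               seed=_stage_seed(seed, "demo-gel"))
    lanes.to_csv(out / "gel_lanes.csv", index=False)
    truth_record["gel"] = {"fold_vs_first": gt.fold_vs_first.tolist()}

    (out / "truth.yaml").write_text(yaml.safe_dump(truth_record, sort_keys=True))
    return out
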