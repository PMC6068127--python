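"""End-to-end orchestration: phantom -> image processing -> FE -> statistics.

``run_subject`` carries one synthetic subject through the full chain for
each repeat scan: rod calibration, HMH segmentation, re-alignment to
neutral standing orientation, meshing, density-modulus mapping, the
single-leg-stance solve scaled to one body weight, regional aggregation,
and the two compartmental stiffness models.  ``run_study`` assembles a full
two-group study (default 7 OA + 7 normal subjects, 3 repeat scans each)
into precision (CV%RMS) and OA-vs-normal comparison tables.

A run is reproducible from the configuration plus master seed alone; all
derived seeds are drawn from the master seed by counter.  Stiffness is
computed from the unscaled displacement-driven solves: it is a
geometry/material property, independent of body weight.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import imageproc, meshmat, regions, solver, stats, tables
from .phantom import (
    LABEL_ROD_BASE,
    GroundTruth,
    PhantomSpec,
    RepeatNoiseSpec,
    draw_cohort,
    generate_knee_phantom,
    generate_repeat_scans,
)
from .volume import DensityVolume

__all__ = ["StudyConfig", "StudyTables", "PipelineError", "process_scan", "run_subject", "run_study"]

METRIC_TABLES = {
    "min_principal_stress": "stress",
    "von_mises_stress": "stress",
    "min_principal_strain": "strain",
    "von_mises_strain": "strain",
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str, subject=None, repeat=None):
        self.stage, self.subject, self.repeat = stage, subject, repeat
        super().__init__(f"stage={stage} subject={subject} repeat={repeat}: {detail}")


@dataclass
class StudyConfig:
    """Fully serializable study configuration; a run is reproducible from
    this plus the master seed alone."""

    n_per_group: int = 7
    n_repeats: int = 3
    voxel_size: float = 0.625  # mm
    element_size: float = 2.0  # mm, bone
    mesh_mode: str = "hex_voxel"
    translation_sd: float = 1.0  # mm, repeat repositioning
    rotation_sd: float = 1.0  # degrees
    intensity_sd: float = 10.0  # HU
    coeff_a: float = meshmat.GOULET_COEFF_A
    exponent: float = meshmat.GOULET_EXPONENT
    e_floor: float = meshmat.E_FLOOR
    seed: int = 0
    out_dir: str | None = None

    def law(self) -> meshmat.MaterialLaw:
        return meshmat.MaterialLaw(coeff_a=self.coeff_a, exponent=self.exponent, floor=self.e_floor)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class ScanResult:
    """FE outcomes for one scan of one subject."""

    regional: pd.DataFrame  # region x metric volume-weighted means
    stiffness: dict  # {"medial": N/mm, "lateral": N/mm}
    reaction_force: float
    scale_factor: float
    n_elements: int
    threshold: float
    calibration_r2: float
    inter_axis_angle: float


@dataclass
class StudyTables:
    precision: pd.DataFrame
    stress_comparison: pd.DataFrame
    strain_comparison: pd.DataFrame
    stiffness_comparison: pd.DataFrame
    summary: dict
    excluded: list = field(default_factory=list)


def _stage(name, fn, subject=None, repeat=None):
    try:
        return fn()
    except PipelineError:
        raise
    except Exception as err:  # propagate with stage context
        raise PipelineError(name, str(err), subject, repeat) from err


def process_scan(
    volume: DensityVolume,
    labels: np.ndarray,
    truth: GroundTruth,
    body_mass: float,
    config: StudyConfig,
    subject=None,
    repeat=None,
) -> ScanResult:
    """Run the full single-scan chain on one (possibly repositioned) volume."""
    rod_masks = [labels == LABEL_ROD_BASE + i for i in range(len(truth.rod_densities))]
    rod_masks = [m for m in rod_masks if m.any()]
    cal, model = _stage(
        "calibrate",
        lambda: imageproc.calibrate(volume, rod_masks, truth.rod_densities[: len(rod_masks)]),
        subject, repeat,
    )

    def _threshold():
        peak, bg = imageproc.auto_probe_regions(cal)
        return imageproc.hmh_threshold(cal, peak, bg)

    threshold = _stage("hmh_threshold", _threshold, subject, repeat)

    def _segment():
        seeds = imageproc.auto_seeds(cal, threshold)
        return imageproc.segment_bones(cal, threshold, seeds)

    seg = _stage("segment", _segment, subject, repeat)
    axes = _stage("fit_axes", lambda: imageproc.fit_bone_axes(seg, cal), subject, repeat)
    cal_r, seg_r, align = _stage(
        "realign", lambda: imageproc.realign(cal, seg, axes), subject, repeat
    )

    mesh = _stage(
        "build_mesh",
        lambda: meshmat.build_mesh(seg_r, cal_r, element_size=config.element_size, mode=config.mesh_mode),
        subject, repeat,
    )
    mats = _stage(
        "map_materials", lambda: meshmat.map_materials(mesh, cal_r, law=config.law()), subject, repeat
    )
    load = solver.LoadCase.from_body_mass(body_mass)
    result = _stage("solve", lambda: solver.assemble_and_solve(mesh, mats, load), subject, repeat)
    scaled = _stage(
        "scale", lambda: solver.scale_to_bodyweight(result, load.body_weight), subject, repeat
    )

    def _regional():
        inputs = regions.derive_region_inputs(seg_r, cal_r)
        return regions.aggregate_voxel(scaled, mesh, inputs, volume=cal_r, law=config.law())

    regional = _stage("regions", _regional, subject, repeat)
    stiff = {
        side: _stage(
            f"stiffness_{side}",
            lambda side=side: regions.compartment_stiffness(mesh, mats, load, side),
            subject, repeat,
        )
        for side in ("medial", "lateral")
    }
    cos = float(np.clip(np.dot(*axes), -1, 1))
    return ScanResult(
        regional=regional,
        stiffness=stiff,
        reaction_force=result.reaction_force,
        scale_factor=scaled.scale_factor,
        n_elements=mesh.n_elements,
        threshold=threshold,
        calibration_r2=model.r_squared,
        inter_axis_angle=180.0 - float(np.degrees(np.arccos(cos))),
    )


def run_subject(
    spec: PhantomSpec, noise: RepeatNoiseSpec, config: StudyConfig, subject=None
) -> list[ScanResult]:
    """Generate one subject's phantom, its repeat scans, and process each."""
    volume, truth = _stage("phantom", lambda: generate_knee_phantom(spec), subject)
    if spec.side == "left":  # mirror so downstream logic is side-agnostic
        volume = volume.with_data(volume.data[::-1].copy())
        truth.labels = truth.labels[::-1].copy()
        truth.axis_femur = truth.axis_femur * np.array([-1.0, 1.0, 1.0])
    scans = _stage("repeat_scans", lambda: generate_repeat_scans(volume, truth, noise), subject)
    return [
        process_scan(s.volume, s.labels, truth, spec.body_mass, config, subject, i)
        for i, s in enumerate(scans)
    ]


def _collect(results: dict, metric: str) -> pd.DataFrame:
    """Long frame: subject, group, repeat, region, value for one metric."""
    recs = []
    for (sid, group), reps in results.items():
        for r, res in enumerate(reps):
            for region, row in res.regional.iterrows():
                recs.append((sid, group, r, region, row[metric]))
    return pd.DataFrame(recs, columns=["subject", "group", "repeat", "region", "value"])


def mesh_convergence_study(
    spec: PhantomSpec,
    config: StudyConfig | None = None,
    element_sizes: tuple = (2.0, 1.8),
) -> dict:
    """One-step mesh-refinement study on a phantom knee.

    Generates the phantom, runs the image chain once, then builds and solves
    FE models at each element size and compares the 17-region means of all
    four field metrics (computed on the fixed voxel grid, so region
    definitions are identical across meshes).  Returns the per-region
    relative changes and their maximum in percent.
    """
    config = config or StudyConfig()
    volume, truth = generate_knee_phantom(spec)
    rod_masks = [m for m in truth.rod_masks() if m.any()]
    cal, _ = imageproc.calibrate(volume, rod_masks, truth.rod_densities[: len(rod_masks)])
    peak, bg = imageproc.auto_probe_regions(cal)
    threshold = imageproc.hmh_threshold(cal, peak, bg)
    seg = imageproc.segment_bones(cal, threshold, imageproc.auto_seeds(cal, threshold))
    axes = imageproc.fit_bone_axes(seg, cal)
    cal_r, seg_r, _ = imageproc.realign(cal, seg, axes)
    inputs = regions.derive_region_inputs(seg_r, cal_r)
    law = config.law()
    load = solver.LoadCase.from_body_mass(spec.body_mass)

    aggs = {}
    sizes = {}
    for h in element_sizes:
        mesh = meshmat.build_mesh(seg_r, cal_r, element_size=h, mode=config.mesh_mode)
        mats = meshmat.map_materials(mesh, cal_r, law=law)
        res = solver.assemble_and_solve(mesh, mats, load)
        scaled = solver.scale_to_bodyweight(res, load.body_weight)
        aggs[h] = regions.aggregate_voxel(scaled, mesh, inputs, volume=cal_r, law=law)
        sizes[h] = mesh.n_elements
    metrics = list(solver.FieldResult.METRICS)
    a, b = aggs[element_sizes[0]], aggs[element_sizes[1]]
    rel = (b[metrics] - a[metrics]).abs() / a[metrics].abs()
    return {
        "relative_change": rel,
        "max_percent": float(100.0 * rel.max().max()),
        "regional": aggs,
        "n_elements": sizes,
    }


def run_study(config: StudyConfig) -> StudyTables:
    """Full two-group precision + comparison study on synthetic cohorts."""
    if config.n_per_group < 2:
        raise ValueError("need at least 2 subjects per group for comparisons")
    specs = {
        "OA": draw_cohort("OA", config.n_per_group, config.seed, config.voxel_size),
        "normal": draw_cohort("normal", config.n_per_group, config.seed, config.voxel_size),
    }
    results: dict = {}
    masses: dict = {}
    excluded = []
    sid = 0
    for group in ("OA", "normal"):
        for spec in specs[group]:
            noise = RepeatNoiseSpec(
                translation_sd=config.translation_sd,
                rotation_sd=config.rotation_sd,
                intensity_sd=config.intensity_sd,
                n_repeats=config.n_repeats,
                seed=(config.seed * 1009 + sid) % (2**31),
            )
            try:
                results[(sid, group)] = run_subject(spec, noise, config, subject=sid)
                masses[(sid, group)] = spec.body_mass
            except PipelineError as err:
                excluded.append({"subject": sid, "group": group, "error": str(err)})
            sid += 1
    if not results:
        raise RuntimeError("all subjects failed")

    # ---- precision ------------------------------------------------------
    precision_rows = []
    for metric in solver.FieldResult.METRICS:
        long = _collect(results, metric)
        for region, sub in long.groupby("region", sort=False):
            per_subject = [g["value"].to_numpy() for _, g in sub.groupby("subject")]
            per_subject = [v for v in per_subject if len(v) >= 2]
            if not per_subject:
                continue
            precision_rows.append(
                {
                    "metric": metric,
                    "region": region,
                    "cv_rms_percent": stats.cv_rms(per_subject),
                    "n_subjects": len(per_subject),
                    "n_repeats": config.n_repeats,
                }
            )
    # stiffness precision
    for side in ("medial", "lateral"):
        per_subject = [
            np.array([res.stiffness[side] for res in reps]) for reps in results.values()
        ]
        per_subject = [v for v in per_subject if len(v) >= 2]
        if per_subject:
            precision_rows.append(
                {
                    "metric": "structural_stiffness",
                    "region": f"{side.capitalize()} compartment",
                    "cv_rms_percent": stats.cv_rms(per_subject),
                    "n_subjects": len(per_subject),
                    "n_repeats": config.n_repeats,
                }
            )
    precision = pd.DataFrame(precision_rows)

    # ---- comparisons ----------------------------------------------------
    def _comparison(metric: str) -> pd.DataFrame:
        long = _collect(results, metric)
        rows = []
        for region, sub in long.groupby("region", sort=False):
            per = sub.groupby(["subject", "group"])["value"].mean().reset_index()
            oa = per[per["group"] == "OA"]["value"].to_numpy()
            no = per[per["group"] == "normal"]["value"].to_numpy()
            if len(oa) < 2 or len(no) < 2:
                continue
            all_scans_sd = float(sub["value"].std(ddof=1))
            rows.append(
                stats.compare_groups(
                    oa, no, region=region, metric=metric, all_scans_sd=all_scans_sd
                )
            )
        df = tables.comparison_dataframe(rows)
        cv = precision[precision["metric"] == metric].set_index("region")["cv_rms_percent"]
        df["cv_rms"] = df["region"].map(cv)
        return df

    stress_cmp = _comparison("min_principal_stress")
    strain_cmp = _comparison("min_principal_strain")

    stiff_rows = []
    for side in ("medial", "lateral"):
        per = {
            "OA": [np.mean([r.stiffness[side] for r in reps]) for (s, g), reps in results.items() if g == "OA"],
            "normal": [np.mean([r.stiffness[side] for r in reps]) for (s, g), reps in results.items() if g == "normal"],
        }
        all_vals = [r.stiffness[side] for reps in results.values() for r in reps]
        stiff_rows.append(
            stats.compare_groups(
                per["OA"], per["normal"],
                region=f"{side.capitalize()} compartment",
                metric="structural_stiffness",
                all_scans_sd=float(np.std(all_vals, ddof=1)),
            )
        )
    stiffness_cmp = tables.comparison_dataframe(stiff_rows)
    cv = precision[precision["metric"] == "structural_stiffness"].set_index("region")[
        "cv_rms_percent"
    ]
    stiffness_cmp["cv_rms"] = stiffness_cmp["region"].map(cv)

    summary = {
        "cv_mean_min_principal_stress": float(
            precision[precision["metric"] == "min_principal_stress"]["cv_rms_percent"].mean()
        ),
        "cv_mean_min_principal_strain": float(
            precision[precision["metric"] == "min_principal_strain"]["cv_rms_percent"].mean()
        ),
        "cv_max_min_principal_stress": float(
            precision[precision["metric"] == "min_principal_stress"]["cv_rms_percent"].max()
        ),
        "n_subjects": len(results),
        "n_excluded": len(excluded),
        "mass_comparison": asdict(
            stats.compare_groups(
                [masses[k] for k in results if k[1] == "OA"],
                [masses[k] for k in results if k[1] == "normal"],
                region="cohort", metric="body_mass",
            )
        )
        if len({k[1] for k in results}) == 2
        else None,
    }

    out = StudyTables(
        precision=precision,
        stress_comparison=stress_cmp,
        strain_comparison=strain_cmp,
        stiffness_comparison=stiffness_cmp,
        summary=summary,
        excluded=excluded,
    )
    if config.out_dir:
        import os

        os.makedirs(config.out_dir, exist_ok=True)
        precision.to_csv(os.path.join(config.out_dir, "precision.csv"), index=False)
        tables.write_comparison_csv(stress_cmp, os.path.join(config.out_dir, "stress_comparison.csv"))
        tables.write_comparison_csv(strain_cmp, os.path.join(config.out_dir, "strain_comparison.csv"))
        tables.write_comparison_csv(
            stiffness_cmp, os.path.join(config.out_dir, "stiffness_comparison.csv")
        )
        with open(os.path.join(config.out_dir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
        config.to_json(os.path.join(config.out_dir, "config.json"))
    return out
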