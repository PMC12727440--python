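"""End-to-end orchestration: phantoms → simulation → fill → parcellation →
metrics → statistics, with the exclusion ledger threaded through.

Every stage failure is recorded against the set and the run continues; only
configuration errors abort a run.  A fixed master seed reproduces every
output bit-exactly (CSV bytes included).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import graft, io, metrics, parcellate, simulate
from .config import LesionProfile, RunConfig, subseed
from .image import Volume
from .phantom import (
    LesionSpec,
    PhantomSpec,
    TissueProbabilityMaps,
    make_lesion_mask,
    make_subject,
    make_template,
)
from .simulate import SimulatedSet
from .stats import (
    IMAGE_TYPES,
    SetStatus,
    StudyLedger,
    compile_ledger,
    iqr_outlier_screen,
    paired_t,
    spearman,
)

logger = logging.getLogger(__name__)

__all__ = ["StudyResult", "run_study", "simulate_set", "make_tbi_case"]


@dataclass
class StudyResult:
    config: RunConfig
    ledger: StudyLedger
    roi_metrics: pd.DataFrame
    image_summaries: pd.DataFrame
    group_stats: pd.DataFrame
    sensitivity: pd.DataFrame
    sets: list[SimulatedSet] = field(default_factory=list)


def make_tbi_case(
    template: Volume,
    labels: Volume,
    profile: LesionProfile,
    config: RunConfig,
    index: int,
) -> tuple[Volume, Volume]:
    """Build one simulated patient image and its repair mask.

    The patient volume is an independently warped subject whose lesion voxels
    are painted hypointense, with a profile-specific global gain emulating a
    scanner-intensity difference to the control images.
    """
    seed = subseed(config.master_seed, "tbi-subject", index)
    subject, subject_labels, _ = make_subject(
        template,
        labels,
        max_magnitude_mm=config.warp_max_magnitude_mm,
        noise_sd=config.noise_sd,
        smooth_sigma_vox=config.warp_smooth_sigma_vox,
        seed=seed,
    )
    lesion_spec = LesionSpec(
        n_clusters=profile.n_clusters,
        target_volume_mm3=profile.target_volume_mm3,
        laterality=profile.laterality,
        intensity_level=profile.lesion_intensity,
        intensity_noise_sd=profile.lesion_noise_sd,
        seed=subseed(config.master_seed, "lesion-mask", index),
    )
    mask = make_lesion_mask(lesion_spec, subject_labels)

    rng = np.random.default_rng(subseed(config.master_seed, "lesion-intensity", index))
    data = subject.data.copy()
    m = mask.data.astype(bool)
    data[m] = profile.lesion_intensity + rng.normal(
        0.0, profile.lesion_noise_sd, int(m.sum())
    )
    data *= profile.intensity_gain
    return subject.with_data(data), mask


def simulate_set(
    hc_subject: Volume,
    tbi_image: Volume,
    repair_mask: Volume,
    set_id: str,
    tbi_id: str,
    hc_id: str,
    config: RunConfig,
) -> SimulatedSet:
    """Build one lesion-free / lesioned pair and run simulation QC."""
    lesion_free = hc_subject
    head = graft.brain_extract(lesion_free).data
    tbi_matched, scale = simulate.histmatch_scale(tbi_image, lesion_free, head)
    lesioned, w = simulate.insert_lesion(
        lesion_free, tbi_matched, repair_mask, fwhm_mm=config.fwhm_mm
    )
    sim = SimulatedSet(
        set_id=set_id,
        tbi_id=tbi_id,
        hc_id=hc_id,
        lesion_free=lesion_free,
        lesioned=lesioned,
        repair_mask=repair_mask,
        smoothed_mask=w,
        provenance={"histmatch_scale": scale},
    )
    simulate.simulation_qc(sim, contrast_threshold=config.contrast_threshold)
    return sim


def _parcellate_set(
    sim: SimulatedSet,
    template_labels: Volume,
    hc_field,
    config: RunConfig,
    indices: tuple[int, int],
) -> dict[str, parcellate.ParcellationResult]:
    results: dict[str, parcellate.ParcellationResult] = {}
    images = {
        "lesion_free": sim.lesion_free,
        "lesioned": sim.lesioned,
        "filled": sim.filled,
    }
    for image_type, image in images.items():
        if image is None:
            continue
        res = parcellate.run_with_retry(
            image,
            template_labels,
            hc_field,
            attempts=config.parcellation_attempts,
            # one seed per set: parcellation stays a pure function of image
            # content, so bit-identical images parcellate identically
            base_seed=subseed(config.master_seed, "parc-ties", *indices),
            gm_band=config.gm_band,
            reassign_radius=config.reassign_radius,
            coverage_floor=config.coverage_floor,
        )
        results[image_type] = res
        sim.parcellation[image_type] = {
            "attempts": res.attempts_used,
            "ok": res.succeeded,
            "coverage": res.coverage,
        }
    return results


def run_study(
    config: RunConfig,
    out_dir: str | Path | None = None,
    write_volumes: bool = False,
) -> StudyResult:
    """Execute the whole benchmark for one configuration.

    Stages per set: simulate the pair, QC, fill, parcellate all three images
    (two attempts each), mask-excluded ROI comparison; then the outlier
    screen, paired tests and Spearman sensitivity analysis over sets.
    """
    if not config.profiles:
        raise ValueError("run configuration lists no lesion profiles")

    phantom_spec = PhantomSpec(
        grid_shape=config.grid_shape,
        voxel_size_mm=config.voxel_size_mm,
        tissue_means=config.tissue_means,
        noise_sd=config.noise_sd,
        n_roi_pairs=config.n_roi_pairs,
        seed=config.master_seed,
    )
    template, template_labels, tpms = make_template(phantom_spec)
    roi_ids = sorted(int(v) for v in np.unique(template_labels.data) if v != 0)

    sets: list[SimulatedSet] = []
    statuses: list[SetStatus] = []
    roi_rows: list[pd.DataFrame] = []
    summary_rows: list[dict] = []

    for i, profile in enumerate(config.profiles):
        try:
            tbi_image, repair_mask = make_tbi_case(
                template, template_labels, profile, config, i
            )
        except ValueError as exc:
            logger.warning("profile %s skipped: %s", profile.tbi_id, exc)
            for j in range(config.n_hc_per_tbi):
                statuses.append(
                    SetStatus(
                        set_id=f"{profile.tbi_id}x{_hc_id(j)}",
                        tbi_id=profile.tbi_id,
                        hc_id=_hc_id(j),
                        simulation_ok=False,
                    )
                )
            continue
        lesion_volume = float(repair_mask.data.sum()) * repair_mask.voxel_volume_mm3

        for j in range(config.n_hc_per_tbi):
            hc_id = _hc_id(j)
            set_id = f"{profile.tbi_id}x{hc_id}"
            hc_subject, _, hc_field = make_subject(
                template,
                template_labels,
                max_magnitude_mm=config.warp_max_magnitude_mm,
                noise_sd=config.noise_sd,
                smooth_sigma_vox=config.warp_smooth_sigma_vox,
                seed=subseed(config.master_seed, "hc-subject", i, j),
            )
            sim = simulate_set(
                hc_subject, tbi_image, repair_mask, set_id, profile.tbi_id, hc_id, config
            )
            sets.append(sim)
            status = SetStatus(
                set_id=set_id,
                tbi_id=profile.tbi_id,
                hc_id=hc_id,
                simulation_ok=bool(sim.simulation_ok),
            )
            statuses.append(status)
            if not sim.simulation_ok:
                logger.warning("set %s failed simulation QC: %s", set_id, sim.qc_reasons)
                continue

            graft.fill(sim, template, tpms, fwhm_mm=config.fwhm_mm, rmse_bins=config.hist_bins)
            parc = _parcellate_set(sim, template_labels, hc_field, config, (i, j))
            status.parcellation = {
                t: {"attempts": r["attempts"], "ok": r["ok"]}
                for t, r in sim.parcellation.items()
            }
            if not status.parcellation_ok:
                logger.warning("set %s excluded: parcellation failure", set_id)
                continue

            # identical repair-mask exclusion on all three label maps
            excl = {
                t: parcellate.exclude_mask_region(parc[t].labels, sim.repair_mask)
                for t in IMAGE_TYPES
            }
            head = graft.brain_extract(sim.lesion_free).data
            for image_type in ("lesioned", "filled"):
                table = metrics.roi_table(
                    excl["lesion_free"], excl[image_type], roi_ids,
                    set_id=set_id, image_type=image_type,
                )
                roi_rows.append(table)
                summary = metrics.summarize_image(table)
                summary.update(
                    set_id=set_id,
                    tbi_id=profile.tbi_id,
                    image_type=image_type,
                    lesion_volume_mm3=lesion_volume,
                    hist_rmse_to_ref=metrics.histogram_rmse(
                        _image_of(sim, image_type), sim.lesion_free, head,
                        n_bins=config.hist_bins,
                    ),
                )
                summary_rows.append(summary)

    roi_table_df = (
        pd.concat(roi_rows, ignore_index=True)
        if roi_rows
        else pd.DataFrame(
            columns=["set_id", "image_type", "roi_id", "dsc", "vol_ref_mm3",
                     "vol_test_mm3", "pvd", "excluded_reason"]
        )
    )
    summaries = pd.DataFrame(summary_rows)

    # ---- outlier screen (joint over both metrics and image types) ----------
    outlier_ids: set[str] = set()
    if len(summaries):
        by_type = {t: g.sort_values("set_id") for t, g in summaries.groupby("image_type")}
        n_sets = min(len(g) for g in by_type.values())
        if n_sets >= 4:
            for g in by_type.values():
                for col in ("mean_dsc", "mean_pvd"):
                    flags = iqr_outlier_screen(g[col].to_numpy(), k=config.outlier_k)
                    outlier_ids.update(g["set_id"].to_numpy()[flags])
    for status in statuses:
        if status.set_id in outlier_ids:
            status.outlier = True
    ledger = compile_ledger(statuses)

    if len(summaries):
        summaries["outlier"] = summaries["set_id"].isin(outlier_ids)
        summaries["included"] = ~summaries["outlier"]

    # ---- group comparisons --------------------------------------------------
    group_rows = []
    sensitivity_rows = []
    if len(summaries):
        kept = summaries[summaries["included"]]
        wide = kept.pivot(index="set_id", columns="image_type",
                          values=["mean_dsc", "mean_pvd", "hist_rmse_to_ref",
                                  "lesion_volume_mm3"])
        if len(wide) >= 3:
            for metric in ("mean_dsc", "mean_pvd"):
                x = wide[(metric, "lesioned")].to_numpy()
                y = wide[(metric, "filled")].to_numpy()
                try:
                    res = paired_t(x, y)
                    group_rows.append({
                        "metric": metric, "comparison": "lesioned_vs_filled",
                        "t": res.t, "df": res.df, "p": res.p, "d": res.d,
                        "ci95_lo": res.ci95[0], "ci95_hi": res.ci95[1],
                        "mean_diff": res.mean_diff, "n": res.n,
                    })
                except ValueError as exc:
                    logger.warning("paired test on %s skipped: %s", metric, exc)
        if len(wide) >= 4:
            for image_type in ("lesioned", "filled"):
                vol = wide[("lesion_volume_mm3", image_type)].to_numpy()
                rmse = wide[("hist_rmse_to_ref", image_type)].to_numpy()
                for pred_name, pred in (("lesion_volume_mm3", vol), ("hist_rmse", rmse)):
                    for metric in ("mean_dsc", "mean_pvd"):
                        try:
                            rho, p = spearman(pred, wide[(metric, image_type)].to_numpy())
                            sensitivity_rows.append({
                                "image_type": image_type, "predictor": pred_name,
                                "metric": metric, "rho": rho, "p": p, "n": len(wide),
                            })
                        except ValueError as exc:
                            logger.warning("spearman skipped: %s", exc)
                try:
                    rho, p = spearman(vol, rmse)
                    sensitivity_rows.append({
                        "image_type": image_type, "predictor": "lesion_volume_mm3",
                        "metric": "hist_rmse", "rho": rho, "p": p, "n": len(wide),
                    })
                except ValueError as exc:
                    logger.warning("spearman skipped: %s", exc)

    result = StudyResult(
        config=config,
        ledger=ledger,
        roi_metrics=roi_table_df,
        image_summaries=summaries,
        group_stats=pd.DataFrame(group_rows),
        sensitivity=pd.DataFrame(sensitivity_rows),
        sets=sets,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir), write_volumes=write_volumes)
    return result


def _hc_id(j: int) -> str:
    return f"HC{j + 1:02d}"


def _image_of(sim: SimulatedSet, image_type: str) -> Volume:
    vol = {"lesion_free": sim.lesion_free, "lesioned": sim.lesioned,
           "filled": sim.filled}[image_type]
    assert vol is not None
    return vol


def _write_outputs(result: StudyResult, out_dir: Path, write_volumes: bool) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    files["roi_metrics.csv"] = out_dir / "roi_metrics.csv"
    result.roi_metrics.to_csv(files["roi_metrics.csv"], index=False)
    files["image_summaries.csv"] = out_dir / "image_summaries.csv"
    result.image_summaries.to_csv(files["image_summaries.csv"], index=False)
    files["group_stats.csv"] = out_dir / "group_stats.csv"
    result.group_stats.to_csv(files["group_stats.csv"], index=False)
    files["sensitivity.csv"] = out_dir / "sensitivity.csv"
    result.sensitivity.to_csv(files["sensitivity.csv"], index=False)
    files["ledger.json"] = out_dir / "ledger.json"
    files["ledger.json"].write_text(json.dumps(result.ledger.to_dict(), indent=2))

    if write_volumes:
        for sim in result.sets:
            set_dir = out_dir / "sets" / sim.tbi_id / sim.hc_id
            io.write_volume(sim.lesion_free, set_dir / "lesion_free.nii.gz")
            io.write_volume(sim.lesioned, set_dir / "lesioned.nii.gz")
            if sim.filled is not None:
                io.write_volume(sim.filled, set_dir / "filled.nii.gz")
            io.write_labels(
                sim.repair_mask.with_data(sim.repair_mask.data.astype(np.uint8)),
                set_dir / "repair_mask.nii.gz",
            )
            status = {
                "set_id": sim.set_id,
                "simulation_ok": sim.simulation_ok,
                "qc_reasons": sim.qc_reasons,
                "parcellation": sim.parcellation,
                "provenance": sim.provenance,
            }
            (set_dir / "status.json").write_text(json.dumps(status, indent=2))

    manifest = {
        "config": result.config.to_dict(),
        "master_seed": result.config.master_seed,
        "files": {
            name: hashlib.sha256(path.read_bytes()).hexdigest()
            for name, path in files.items()
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
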