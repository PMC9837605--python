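"""End-to-end orchestration over an on-disk cohort directory.

Each stage consumes and produces documented files inside the cohort
directory, so stages can be re-run independently (the CLI maps one
subcommand to each):

    simulate -> events.tsv, sub-*/responses.tsv, sub-*/bold.nii.gz, traits.tsv
    classify -> sub-*/outcomes.tsv
    behave   -> behavior_subjects.tsv, behavior_summary.tsv
    glm      -> sub-*/pct_<condition>.nii.gz, glm_info.tsv
    group    -> group_tmap.nii.gz, cluster_table.tsv, cluster_labels.nii.gz
    roi      -> roi_means.tsv, roi_behavior_correlations.tsv
    lasso    -> trait_lasso.tsv
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .behavior import cohort_table, summarize_behavior
from .classify import (
    AWARE_ERROR,
    CORRECT_INHIBITION,
    UNAWARE_ERROR,
    OutcomeTable,
    SubjectResponses,
    classify_trials,
)
from .cluster import extract_clusters, paired_t_map, simulate_null_clusters
from .cohort import simulate_cohort
from .deconvolve import (
    RankDeficientDesignError,
    activation_maps,
    build_design_matrix,
    estimate_fwhm,
)
from .roi import behavior_correlations
from .stability import bootstrap_stability
from .task import TaskConfig, TrialSequence

CONDITIONS = (AWARE_ERROR, UNAWARE_ERROR, CORRECT_INHIBITION)


def load_cohort(cohort_dir: str | Path) -> tuple[TrialSequence, dict, list[Path]]:
    """Rebuild the shared sequence and subject folder list from disk."""
    d = Path(cohort_dir)
    truth = json.loads((d / "ground_truth.json").read_text())
    cfg = TaskConfig(**truth["task"])
    seq = eio.frame_to_sequence(eio.read_events_tsv(d / "events.tsv"), cfg)
    subs = sorted(p for p in d.glob("sub-*") if p.is_dir())
    return seq, truth, subs


def _read_responses(sub_dir: Path) -> SubjectResponses:
    df = eio.read_table(
        sub_dir / "responses.tsv", required=["button", "rt_ms"], what="responses"
    )
    return SubjectResponses(
        subject_id=sub_dir.name,
        button=[str(b) for b in df["button"]],
        rt_ms=df["rt_ms"].to_numpy(),
    )


def run_classify(cohort_dir: str | Path) -> list[OutcomeTable]:
    seq, _, subs = load_cohort(cohort_dir)
    outcomes = []
    for sd in subs:
        out = classify_trials(seq, _read_responses(sd))
        eio.write_table(out.to_frame(), sd / "outcomes.tsv")
        outcomes.append(out)
    return outcomes


def run_behavior(cohort_dir: str | Path) -> pd.DataFrame:
    seq, _, subs = load_cohort(cohort_dir)
    summaries = []
    for sd in subs:
        resp = _read_responses(sd)
        out = classify_trials(seq, resp)
        summaries.append(summarize_behavior(seq, out, resp))
    per_subject = pd.DataFrame([s.__dict__ for s in summaries])
    eio.write_table(per_subject, Path(cohort_dir) / "behavior_subjects.tsv")
    eio.write_table(cohort_table(summaries), Path(cohort_dir) / "behavior_summary.tsv")
    return per_subject


def run_glm(
    cohort_dir: str | Path,
    fir_window_s: float | None = None,
    drift_order: int = 3,
) -> pd.DataFrame:
    """Subject-level deconvolution, gamma fits, and percent-area maps."""
    seq, truth, subs = load_cohort(cohort_dir)
    neuro = truth["neuro"]
    window = fir_window_s if fir_window_s is not None else neuro["window_s"]
    info_rows = []
    for sd in subs:
        bold, _, voxel_mm, tr_s = eio.load_nifti(sd / "bold.nii.gz")
        tr_s = tr_s or neuro["tr_s"]
        out = classify_trials(seq, _read_responses(sd))
        try:
            design = build_design_matrix(
                seq, out, bold.shape[3], tr_s,
                fir_window_s=window, drift_order=drift_order,
            )
        except RankDeficientDesignError as exc:
            # too few events to separate the regressors: exclude the subject
            warnings.warn(f"{sd.name} excluded: {exc}", stacklevel=2)
            info_rows.append(
                {
                    "subject_id": sd.name,
                    "fwhm_mm": np.nan,
                    "mean_beta0": np.nan,
                    "dropped_conditions": "EXCLUDED",
                }
            )
            continue
        maps, glm = activation_maps(bold.astype(float), design, window_s=window)
        for cond, m in maps.items():
            eio.save_nifti(
                m.astype(np.float32), sd / f"pct_{cond}.nii.gz", voxel_mm=voxel_mm
            )
            irf_map = glm.irf(cond).reshape(*glm.spatial_shape, design.n_lags)
            eio.save_nifti(
                irf_map.astype(np.float32), sd / f"irf_{cond}.nii.gz", voxel_mm=voxel_mm
            )
        eio.save_nifti(
            glm.beta0.reshape(glm.spatial_shape).astype(np.float32),
            sd / "beta0.nii.gz",
            voxel_mm=voxel_mm,
        )
        sm = estimate_fwhm(glm.residual_maps(), voxel_mm)
        info_rows.append(
            {
                "subject_id": sd.name,
                "fwhm_mm": sm.geometric_mean,
                "mean_beta0": float(np.nanmean(glm.beta0)),
                "dropped_conditions": ",".join(design.dropped_conditions),
            }
        )
    info = pd.DataFrame(info_rows)
    eio.write_table(info, Path(cohort_dir) / "glm_info.tsv")
    return info


def run_group(
    cohort_dir: str | Path,
    voxel_p: float = 0.001,
    alpha: float = 0.010,
    n_iter: int = 10_000,
    connectivity: int = 6,
    min_volume_uL: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired t-map, Monte Carlo extent threshold, and cluster table.

    Subjects missing either condition map (no events of a class) are
    excluded, as in studies that drop participants without aware-error
    signals. ``min_volume_uL`` overrides the simulated extent threshold
    (e.g. the conventional hard 250 uL rule).
    """
    d = Path(cohort_dir)
    _, truth, subs = load_cohort(d)
    info = eio.read_table(d / "glm_info.tsv", required=["fwhm_mm"], what="glm_info")
    aware, unaware = [], []
    for sd in subs:
        try:
            a, _, voxel_mm, _ = eio.load_nifti(sd / f"pct_{AWARE_ERROR}.nii.gz")
            u, _, _, _ = eio.load_nifti(sd / f"pct_{UNAWARE_ERROR}.nii.gz")
        except FileNotFoundError:
            continue
        if np.isfinite(a).all() and np.isfinite(u).all():
            aware.append(a)
            unaware.append(u)
    if len(aware) < 2:
        raise ValueError("fewer than 2 subjects with both condition maps")
    tmap = paired_t_map(np.stack(aware), np.stack(unaware), voxel_mm=voxel_mm)
    fwhm = float(np.nanmean(info["fwhm_mm"]))
    null = simulate_null_clusters(
        tmap.t.shape,
        voxel_mm,
        fwhm,
        voxel_p=voxel_p,
        n_iter=n_iter,
        alpha=alpha,
        seed=seed,
        connectivity=connectivity,
    )
    extent_uL = min_volume_uL if min_volume_uL is not None else null.threshold_uL
    table, labels = extract_clusters(
        tmap,
        tmap.threshold_for_p(voxel_p),
        extent_uL,
        connectivity=connectivity,
    )
    eio.save_nifti(tmap.t.astype(np.float32), d / "group_tmap.nii.gz", voxel_mm=voxel_mm)
    eio.save_nifti(labels.astype(np.int16), d / "cluster_labels.nii.gz", voxel_mm=voxel_mm)
    eio.write_table(table, d / "cluster_table.tsv")
    eio.write_json(
        {
            "n_subjects": len(aware),
            "fwhm_mm": fwhm,
            "voxel_p": voxel_p,
            "alpha": alpha,
            "extent_threshold_uL": extent_uL,
            "simulated_threshold_vox": null.threshold_vox,
        },
        d / "group_info.json",
    )
    return table


def run_roi(cohort_dir: str | Path, fir_window_s: float | None = None) -> pd.DataFrame:
    """Per-subject cluster activity and its behavioral correlates.

    Cluster activity is estimated by averaging each subject's FIR
    impulse response over the cluster's voxels and gamma-fitting that
    mean IRF (see :func:`erroraware.deconvolve.roi_activation`), which
    is far less noise-inflated than averaging per-voxel percent-area
    values for sparse conditions.
    """
    d = Path(cohort_dir)
    seq, truth, subs = load_cohort(d)
    window = fir_window_s if fir_window_s is not None else truth["neuro"]["window_s"]
    labels, _, _, _ = eio.load_nifti(d / "cluster_labels.nii.gz")
    labels = labels.astype(int)
    if labels.max() == 0:
        eio.write_table(pd.DataFrame(), d / "roi_means.tsv")
        return pd.DataFrame()
    cluster_ids = [int(c) for c in np.unique(labels) if c > 0]
    rows = []
    ids = []
    for sd in subs:
        try:
            irfs = {c: eio.load_nifti(sd / f"irf_{c}.nii.gz")[0] for c in CONDITIONS}
            beta0, _, _, tr_s = eio.load_nifti(sd / "beta0.nii.gz")
        except FileNotFoundError:
            continue
        if not all(np.isfinite(m).all() for m in irfs.values()):
            continue
        ids.append(sd.name)
        tr = truth["neuro"]["tr_s"]
        from .deconvolve import fit_gamma_variate, gamma_auc, percent_signal

        for cid in cluster_ids:
            m = labels == cid
            b0 = float(beta0[m].mean())
            for cond in CONDITIONS:
                irf = irfs[cond][m].mean(axis=0)
                fit = fit_gamma_variate(irf.astype(float), tr)
                auc = 0.0 if fit.flagged else gamma_auc(fit.hrf)
                rows.append(
                    {
                        "subject_id": sd.name,
                        "cluster_id": cid,
                        "condition": cond,
                        "mean": float(percent_signal(auc, b0, window)),
                    }
                )
    means = pd.DataFrame(rows)
    eio.write_table(means, d / "roi_means.tsv")

    beh_path = d / "behavior_subjects.tsv"
    if beh_path.exists():
        beh = eio.read_table(beh_path).set_index("subject_id")
        wide = means.pivot_table(
            index="subject_id", columns=["condition", "cluster_id"], values="mean"
        )
        wide.columns = [f"{c}@cluster{k}" for c, k in wide.columns]
        pairs = [
            (col, idx, idx)
            for idx in ("inhibition_pct", "awareness_pct")
            for col in wide.columns
            if col.startswith(AWARE_ERROR)
        ]
        if pairs and len(wide) >= 10:
            corr = behavior_correlations(wide, beh, pairs)
            eio.write_table(corr, d / "roi_behavior_correlations.tsv")
    return means


def run_lasso(
    cohort_dir: str | Path, n_boot: int = 500, n_folds: int = 10, seed: int = 0
) -> pd.DataFrame:
    """Trait stability selection for awareness and per-cluster activity."""
    d = Path(cohort_dir)
    traits = eio.read_table(d / "traits.tsv").set_index("subject_id")
    beh = eio.read_table(d / "behavior_subjects.tsv").set_index("subject_id")
    outcomes: dict[str, pd.Series] = {"error_awareness": beh["awareness_pct"]}
    roi_path = d / "roi_means.tsv"
    if roi_path.exists() and roi_path.stat().st_size > 1:
        means = eio.read_table(roi_path)
        if len(means):
            aware_means = means[means["condition"] == AWARE_ERROR]
            for cid, grp in aware_means.groupby("cluster_id"):
                outcomes[f"aware_cluster{cid}"] = grp.set_index("subject_id")["mean"]
    frames = []
    for name, y in outcomes.items():
        aligned = traits.join(y.rename("__y__"), how="inner")
        n_complete = int(
            (aligned[traits.columns].notna().all(axis=1) & aligned["__y__"].notna()).sum()
        )
        # tiny cohorts fall back towards leave-one-out
        folds = max(2, min(n_folds, n_complete))
        res = bootstrap_stability(
            aligned[traits.columns],
            aligned["__y__"].to_numpy(),
            n_boot=n_boot,
            n_folds=folds,
            seed=eio.substream(seed, f"lasso:{name}"),
        )
        f = res.to_frame()
        f.insert(0, "outcome", name)
        frames.append(f)
    out = pd.concat(frames, ignore_index=True)
    eio.write_table(out, d / "trait_lasso.tsv")
    return out


def run_all(
    n_subjects: int,
    cohort_dir: str | Path,
    seed: int = 0,
    task: TaskConfig | None = None,
    behavior=None,
    neuro=None,
    traits=None,
    voxel_p: float = 0.001,
    alpha: float = 0.010,
    n_iter: int = 2_000,
    n_boot: int = 200,
) -> dict:
    """Simulate a cohort and run every stage in order."""
    simulate_cohort(
        n_subjects,
        cohort_dir,
        seed=seed,
        task=task,
        behavior=behavior,
        neuro=neuro,
        traits=traits,
    )
    run_classify(cohort_dir)
    run_behavior(cohort_dir)
    run_glm(cohort_dir)
    table = run_group(
        cohort_dir,
        voxel_p=voxel_p,
        alpha=alpha,
        n_iter=n_iter,
        seed=eio.substream(seed, "clustsim"),
    )
    if len(table):
        run_roi(cohort_dir)
    lasso = run_lasso(cohort_dir, n_boot=n_boot, seed=seed)
    return {"clusters": table, "lasso": lasso}
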