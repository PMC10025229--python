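"""End-to-end orchestration: simulate -> morphometry -> DCE fit -> features ->
curve typing -> statistics.

Every stage is a pure function of the previous stage's tabular outputs, so a
stage can be re-run standalone on serialized CSVs and reproduce the
orchestrated result.  A single global seed is expanded into independent
per-stage seeds through ``numpy.random.SeedSequence.spawn``, so enabling or
disabling one stage leaves the others' randomness untouched.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import curve_typing as ct
from . import stats as st
from .dce import AIF, CTC, tofts_fit
from .features import extract_features
from .morphometry import RATIO_PAIRS, relative_area_ratio
from .synthetic import SimulationConfig, SyntheticCohort, generate_cohort, write_cohort

__all__ = [
    "features_stage",
    "fit_stage",
    "morphometry_stage",
    "run_pipeline",
    "stats_stage",
    "typing_stage",
]

log = logging.getLogger("glymphflow")

# stage order for seed splitting; stable across stage toggling
_STAGE_NAMES = ("simulate", "fit", "typing_pre", "typing_post")


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGE_NAMES))
    return {
        name: int(child.generate_state(1, np.uint32)[0]) % (2**31)
        for name, child in zip(_STAGE_NAMES, children)
    }


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def morphometry_stage(cohort: SyntheticCohort) -> pd.DataFrame:
    """Relative area ratios per subject from the slice masks."""
    rows = []
    for sid, levels in cohort.slices.items():
        for ss in levels.values():
            for num_label, den_label in RATIO_PAIRS.items():
                if num_label in ss.masks and den_label in ss.masks:
                    res = relative_area_ratio(ss.masks[num_label], ss.masks[den_label])
                    rows.append({
                        "subject_id": sid,
                        "label": num_label,
                        "numerator_area_mm2": res.numerator_area_mm2,
                        "denominator_area_mm2": res.denominator_area_mm2,
                        "ratio": res.ratio,
                    })
    return pd.DataFrame(rows)


def _ctcs_from_frame(df: pd.DataFrame) -> list[CTC]:
    out = []
    for (sid, rid), sub in df.groupby(["subject_id", "roi_id"], sort=False):
        out.append(CTC(subject_id=sid, roi_id=rid,
                       t=sub["t_seconds"].to_numpy(),
                       C=sub["concentration"].to_numpy()))
    return out


def fit_stage(ctc_frame: pd.DataFrame, aif: AIF, vp_enabled: bool = True) -> pd.DataFrame:
    """Fit the extended Tofts model to every curve."""
    rows = []
    for c in _ctcs_from_frame(ctc_frame):
        fit = tofts_fit(c, aif, vp_enabled=vp_enabled)
        rows.append({
            "subject_id": c.subject_id, "roi_id": c.roi_id,
            "Ktrans": fit.params.Ktrans, "kep": fit.params.kep,
            "vp": fit.params.vp, "ve": fit.params.ve,
            "residual_rms": fit.residual_rms, "converged": fit.converged,
        })
    return pd.DataFrame(rows)


def features_stage(
    ctc_frame: pd.DataFrame, baseline_frames: int = 5, smooth_window: int = 3
) -> pd.DataFrame:
    """Semi-quantitative features for every curve."""
    rows = []
    for c in _ctcs_from_frame(ctc_frame):
        f = extract_features(c, baseline_frames=baseline_frames,
                             smooth_window=smooth_window)
        rows.append({
            "subject_id": c.subject_id, "roi_id": c.roi_id,
            "peak_concentration": f.peak_concentration,
            "time_to_peak_s": f.time_to_peak_s,
            "wash_in_rate": f.wash_in_rate,
            "wash_out_rate": f.wash_out_rate,
        })
    return pd.DataFrame(rows)


def typing_stage(
    features: pd.DataFrame,
    subjects: pd.DataFrame,
    groups: tuple[str, str],
    seed: int,
    k_range: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
    standardize: bool = True,
) -> dict:
    """One pooled K-means typing run over two comparison groups.

    Curves of both groups are pooled, the elbow method reports its selected
    k over ``k_range``, clustering for type assignment uses k = 2 (the two
    perivascular flow patterns), and clusters are labelled type I / II from
    their centroids.
    """
    subj = subjects[subjects["group"].isin(groups)]
    feats = features[features["subject_id"].isin(subj["subject_id"])].reset_index(drop=True)
    x = feats[["wash_in_rate", "peak_concentration"]].to_numpy()
    selected_k, wcss = ct.select_k_elbow(x, k_range=k_range, seed=seed,
                                         standardize=standardize)
    assignment = ct.label_types(
        ct.cluster_ctcs(x, k=2, seed=seed, standardize=standardize)
    )
    feats = feats.assign(cluster=assignment.cluster, type=assignment.types)
    summary = ct.type_summary(feats["type"].to_numpy(),
                              feats["subject_id"].to_numpy(), subj)
    return {
        "groups": list(groups),
        "selected_k": int(selected_k),
        "wcss": {int(k): float(v) for k, v in wcss.items()},
        "curves": feats,
        "summary": summary,
    }


def _mw_row(name: str, x: np.ndarray, y: np.ndarray) -> dict:
    u, p = st.mann_whitney(x, y)
    return {"comparison": name, "n_x": len(x), "n_y": len(y),
            "U": u, "p": p,
            "median_x": float(np.median(x)), "median_y": float(np.median(y))}


def stats_stage(
    subjects: pd.DataFrame,
    area_ratios: pd.DataFrame,
    typing_pre: dict,
    typing_post: dict | None = None,
) -> dict:
    """Group comparisons, ROC diagnostics and the correlation matrix."""
    out: dict = {"group_tests": [], "roc": [], "severity": {}}

    curves = typing_pre["curves"]
    merged = curves.merge(subjects[["subject_id", "group"]], on="subject_id")
    feature_cols = ("peak_concentration", "wash_in_rate", "wash_out_rate")

    # type I / II feature comparisons, OSA_pre vs NC (per-curve, as reported)
    for typ in ("I", "II"):
        sub = merged[merged["type"] == typ]
        nc = sub[sub["group"] == "NC"]
        osa = sub[sub["group"] == "OSA_pre"]
        if len(nc) and len(osa):
            for col in feature_cols:
                out["group_tests"].append(
                    _mw_row(f"type{typ}_{col}_OSA_pre_vs_NC",
                            osa[col].to_numpy(), nc[col].to_numpy())
                )

    # ROC: each feature distinguishing type II from type I (pooled curves)
    for col in feature_cols:
        roc = st.roc_analysis(merged[col].to_numpy(),
                              (merged["type"] == "II").to_numpy())
        out["roc"].append({
            "score": col, "task": "typeII_vs_typeI",
            "auroc": roc.auroc, "sensitivity": roc.sensitivity,
            "specificity": roc.specificity, "threshold": roc.threshold,
            "p": roc.p_value, "direction": roc.direction,
        })

    # morphometry: area-ratio comparisons and ROC, OSA_pre vs NC
    if len(area_ratios):
        ar = area_ratios.merge(subjects[["subject_id", "group"]], on="subject_id")
        for label, sub in ar.groupby("label"):
            nc = sub[sub["group"] == "NC"]["ratio"].to_numpy()
            osa = sub[sub["group"] == "OSA_pre"]["ratio"].to_numpy()
            if len(nc) and len(osa):
                out["group_tests"].append(_mw_row(f"{label}_ratio_OSA_pre_vs_NC", osa, nc))
                roc = st.roc_analysis(
                    np.concatenate([osa, nc]),
                    np.r_[np.ones(len(osa), bool), np.zeros(len(nc), bool)],
                )
                out["roc"].append({
                    "score": f"{label}_ratio", "task": "OSA_pre_vs_NC",
                    "auroc": roc.auroc, "sensitivity": roc.sensitivity,
                    "specificity": roc.specificity, "threshold": roc.threshold,
                    "p": roc.p_value, "direction": roc.direction,
                })

    # post-CPAP comparisons from the second pooled typing run
    if typing_post is not None:
        curves_post = typing_post["curves"]
        mp = curves_post.merge(subjects[["subject_id", "group"]], on="subject_id")
        for typ in ("I", "II"):
            sub = mp[mp["type"] == typ]
            nc = sub[sub["group"] == "NC"]
            osa = sub[sub["group"] == "OSA_post"]
            if len(nc) and len(osa):
                for col in feature_cols:
                    out["group_tests"].append(
                        _mw_row(f"type{typ}_{col}_OSA_post_vs_NC",
                                osa[col].to_numpy(), nc[col].to_numpy())
                    )

    # Spearman correlations within OSA_pre: per-subject mean type-I wash-out,
    # morphometry ratios and clinical covariates
    osa_subj = subjects[subjects["group"] == "OSA_pre"].copy()
    type1 = merged[(merged["type"] == "I") & (merged["group"] == "OSA_pre")]
    washout = type1.groupby("subject_id")["wash_out_rate"].mean().rename("typeI_wash_out_rate")
    table = osa_subj.set_index("subject_id").join(washout)
    if len(area_ratios):
        ar_wide = area_ratios.pivot_table(index="subject_id", columns="label",
                                          values="ratio")
        table = table.join(ar_wide.add_suffix("_ratio"))
    corr_vars = [v for v in (
        "typeI_wash_out_rate", "AHI", "ODI", "MMSE", "MoCA", "PSQI", "ESS",
        "frontal_PVS_ratio", "basal_ganglia_PVS_ratio",
        "lateral_ventricles_ratio", "fourth_ventricle_ratio",
    ) if v in table.columns and table[v].notna().sum() >= 3]
    corr = None
    if len(table) >= 3 and len(corr_vars) >= 2:
        corr = st.spearman_matrix(table.reset_index(), variables=corr_vars)
        out["correlations"] = {
            "variables": corr.variables,
            "rho": corr.rho.to_dict(),
            "p": corr.p.to_dict(),
            "strength": corr.strength.to_dict(),
        }
    out["_correlation_matrix"] = corr

    # clinical severity grouping tallies
    classes = [
        st.severity_grouping(st.Subject(
            subject_id=row.subject_id, group=row.group,
            AHI=row.AHI, LSaO2=row.LSaO2,
        ))
        for row in subjects.itertuples()
    ]
    osa_counts = pd.Series([c[0] for c in classes]).value_counts().to_dict()
    hyp_counts = pd.Series([c[1] for c in classes]).value_counts().to_dict()
    out["severity"] = {"osa_classes": osa_counts, "hypoxemia_classes": hyp_counts}
    return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_pipeline(
    config: SimulationConfig | str | Path | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    fit_tofts: bool = True,
) -> dict:
    """Run the full analysis on a synthetic cohort and return the report.

    The report carries the config echo, the seed, every stage's outputs and
    per-stage timings, and is bit-identical across runs with the same config
    and seed.  With ``out_dir`` the stage tables, the report JSON and a
    correlation heatmap are written to disk.
    """
    if config is None:
        config = SimulationConfig()
    elif isinstance(config, (str, Path)):
        config = SimulationConfig.from_yaml(config)
    config.validate()
    seeds = _stage_seeds(seed)
    timings: dict[str, float] = {}
    report_warnings: list[str] = []

    def timed(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
            def __exit__(self, *exc):
                timings[name] = round(time.perf_counter() - self.t0, 4)
        return _T()

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        with timed("simulate"):
            cohort = generate_cohort(config, seed=seeds["simulate"])
            subjects = cohort.subjects_frame()
            ctc_frame = cohort.ctc_frame()
        log.info("simulated %d subjects, %d curves", len(subjects), len(cohort.ctcs))

        with timed("morphometry"):
            area_ratios = morphometry_stage(cohort)

        fits = None
        if fit_tofts:
            with timed("fit_dce"):
                fits = fit_stage(ctc_frame, cohort.aif)

        with timed("features"):
            feats = features_stage(ctc_frame)

        with timed("typing"):
            typing_pre = typing_stage(feats, subjects, ("NC", "OSA_pre"),
                                      seed=seeds["typing_pre"])
            typing_post = typing_stage(feats, subjects, ("NC", "OSA_post"),
                                       seed=seeds["typing_post"])

        with timed("stats"):
            stats_out = stats_stage(subjects, area_ratios, typing_pre, typing_post)

        report_warnings = [str(w.message) for w in caught]

    corr = stats_out.pop("_correlation_matrix", None)

    def typing_section(t: dict) -> dict:
        return {
            "groups": t["groups"], "selected_k": t["selected_k"],
            "wcss": t["wcss"], "summary": t["summary"],
        }

    report = {
        "config": config.to_dict(),
        "seed": seed,
        "stage_seeds": seeds,
        "n_subjects": int(len(subjects)),
        "n_curves": int(len(cohort.ctcs)),
        "area_ratios": area_ratios.to_dict(orient="list"),
        "tofts_fits": fits.to_dict(orient="list") if fits is not None else None,
        "features": feats.to_dict(orient="list"),
        "typing_pre": typing_section(typing_pre),
        "typing_post": typing_section(typing_post),
        "stats": stats_out,
        "timings_s": timings,
        "warnings": report_warnings,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_cohort(cohort, out / "cohort", write_nifti=config.include_slices)
        area_ratios.to_csv(out / "area_ratios.csv", index=False)
        feats.to_csv(out / "features.csv", index=False)
        if fits is not None:
            fits.to_csv(out / "tofts_fits.csv", index=False)
        typing_pre["curves"].to_csv(out / "curve_types_pre.csv", index=False)
        typing_post["curves"].to_csv(out / "curve_types_post.csv", index=False)
        with open(out / "typing_summary.json", "w") as fh:
            json.dump({"pre": typing_section(typing_pre),
                       "post": typing_section(typing_post)}, fh, indent=1)
        pd.DataFrame(stats_out["group_tests"]).to_csv(out / "group_tests.csv", index=False)
        pd.DataFrame(stats_out["roc"]).to_csv(out / "roc_results.csv", index=False)
        if corr is not None:
            corr.rho.to_csv(out / "correlations.csv")
            st.plot_correlation_heatmap(corr, str(out / "correlation_heatmap.png"))
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=float)
    return report
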