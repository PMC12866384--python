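"""End-to-end orchestration: generate -> calibrate -> segment -> quantify ->
classify -> report, reproducible from one serializable configuration + seed.

Outputs are tidy long-format tables (pandas), optionally written as CSV with
regenerated figures when an output directory is configured.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import CalibrationFactor, apply_calibration, \
    compute_calibration_factor, simulate_uniform_cylinder
from .diagnostics import DiagnosisRecord, PerformanceSummary, POSITIVE, \
    classify_blood_pool_grade, classify_pid, cohen_kappa, \
    diagnostic_performance
from .images import DynamicImage
from .phantom import AcquisitionModel, CohortConfig, NOISELESS_ACQUISITION, \
    SyntheticSubject, generate_cohort
from .quantitation import QuantResult, decay_correct_image, \
    net_injected_activity, percent_id_per_ml, suv, uptake_ratios
from .segmentation import EmptySegmentationError, VoiMask, segment_myocardium, \
    voi_statistics
from .temporal import extract_tac, synthesize_static

#: The study's analysis windows (min post-injection): three synthetic statics
#: from the dynamic series plus the 90- and 150-min static acquisitions.
DEFAULT_WINDOWS = ((10.0, 25.0), (30.0, 45.0), (45.0, 60.0),
                   (90.0, 105.0), (150.0, 165.0))
EARLY_WINDOWS = ((10.0, 25.0), (30.0, 45.0), (45.0, 60.0))


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable run description; a run is reproducible from the
    persisted config plus its seed."""

    n_attr: int = 8
    n_non: int = 11
    seed: int = 0
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 4.92
    noise: bool = True
    subject_variability: bool = True
    psf_fwhm_mm: float = 0.0
    sensitivity: float = 2e-5          # cps per (Bq/mL) per voxel
    k_threshold: float = 1.0           # myocardial segmentation threshold
    pid_threshold: float = 0.003       # %ID/mL rule-in threshold
    windows: tuple[tuple[float, float], ...] = DEFAULT_WINDOWS
    calibration_activity_MBq: float = 100.0
    calibration_volume_mL: float = 5000.0
    output_dir: str | None = None

    def acquisition(self) -> AcquisitionModel:
        if not self.noise and self.psf_fwhm_mm == 0:
            return NOISELESS_ACQUISITION
        return AcquisitionModel(
            psf_fwhm_mm=self.psf_fwhm_mm,
            sensitivity_cps_per_Bq_per_mL_per_voxel=self.sensitivity,
            noise=self.noise)

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(
            grid_shape=self.grid_shape, voxel_size_mm=self.voxel_size_mm,
            acquisition=self.acquisition(),
            subject_cv_scale=1.0 if self.subject_variability else 0.0)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["windows"] = [list(w) for w in self.windows]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["grid_shape"] = tuple(d.get("grid_shape", (64, 64, 64)))
        d["windows"] = tuple(tuple(w) for w in d.get("windows", DEFAULT_WINDOWS))
        return cls(**d)

    def config_hash(self) -> str:
        """Hash of the scientific run parameters (where outputs land is
        not part of the run identity)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        payload = json.dumps(d, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def noiseless_run_config(**overrides) -> RunConfig:
    """Idealized limit: no count noise, no blur, no inter-subject spread."""
    return RunConfig(noise=False, subject_variability=False,
                     psf_fwhm_mm=0.0, **overrides)


@dataclass
class SubjectAnalysis:
    """All per-subject pipeline products."""

    subject_id: str
    group: str
    quant: list[QuantResult]
    diagnoses: list[DiagnosisRecord]
    myo_mask_provenance: str
    tac_frames: pd.DataFrame


@dataclass
class CohortReport:
    """Cohort-level pipeline products as tidy tables."""

    config: RunConfig
    config_hash: str
    calibration: CalibrationFactor | None
    subjects: pd.DataFrame        # one row per subject (bookkeeping)
    quant: pd.DataFrame           # (subject, window, voi) metric rows
    group_summary: pd.DataFrame   # mean/SD/95% CI per group/voi/metric/window
    diagnoses: pd.DataFrame       # rule applications
    performance: pd.DataFrame     # per window x rule confusion + rates
    tacs: pd.DataFrame            # per-frame SUV series


def _window_label(window: tuple[float, float]) -> str:
    return f"{window[0]:g}-{window[1]:g}min"


def _segment_for_window(images: dict[str, DynamicImage],
                        window: tuple[float, float]) -> DynamicImage:
    """The acquisition segment overlapping a window (error if none)."""
    for image in images.values():
        starts, ends = image.schedule.starts, image.schedule.ends
        if (np.minimum(ends, window[1]) - np.maximum(starts, window[0]) > 0).any():
            return image
    raise ValueError(f"no acquisition segment overlaps window {window}")


def analyze_subject(subject: SyntheticSubject,
                    cf: CalibrationFactor | None,
                    config: RunConfig) -> SubjectAnalysis:
    """Calibrate, decay-correct, segment, and quantify one subject."""
    geometry = subject.geometry
    record = subject.record
    dose = net_injected_activity(record)

    images = {}
    for key, image in subject.images.items():
        if image.units != "Bq/mL":
            if cf is None:
                raise ValueError("count-rate images require a calibration factor")
            image = apply_calibration(image, cf)
        images[key] = decay_correct_image(image, dose.reference_time_min)

    statics = {w: synthesize_static(_segment_for_window(images, w), *w)
               for w in config.windows}

    # Myocardial contour from the latest window's static; anatomical prior
    # as the search region.  Where thresholding excludes everything (typical
    # for non-ATTR subjects, whose myocardium sits below blood pool), fall
    # back to the anatomical contour, as CT-guided drawing would.
    late_window = max(config.windows, key=lambda w: w[0])
    try:
        myo_voi = segment_myocardium(
            statics[late_window], geometry.labels["LA_bp"],
            geometry.labels["LV_myo"], k=config.k_threshold,
            min_component_voxels=30)
        myo_provenance = f"blood_pool_threshold|{myo_voi.source_image_id}"
    except EmptySegmentationError as err:
        myo_voi = VoiMask(label="LV_myo", mask=geometry.labels["LV_myo"],
                          source_image_id="anatomical_prior")
        myo_provenance = f"anatomical_prior|threshold={err.threshold:.4g}"

    masks = {"LV_myo": myo_voi.mask, "LA_bp": geometry.labels["LA_bp"],
             "LS": geometry.labels["LS"]}

    quant: list[QuantResult] = []
    diagnoses: list[DiagnosisRecord] = []
    for window in config.windows:
        static = statics[window]
        result = QuantResult(subject_id=record.subject_id, window=window)
        for label, mask in masks.items():
            vstats = voi_statistics(static, mask)
            result.suv_mean[label] = float(suv(vstats.mean, dose, record.weight_kg))
            result.suv_max[label] = float(suv(vstats.max, dose, record.weight_kg))
        result.pid_per_ml = float(percent_id_per_ml(result.suv_mean["LV_myo"],
                                                    record.weight_kg))
        result.ratio_myo_bone, result.ratio_myo_bp = uptake_ratios(
            result.suv_mean["LV_myo"], result.suv_mean["LS"],
            result.suv_mean["LA_bp"])
        quant.append(result)
        diagnoses.append(classify_blood_pool_grade(
            result.suv_mean["LV_myo"], result.suv_mean["LA_bp"],
            subject_id=record.subject_id, window=window))
        diagnoses.append(classify_pid(
            result.pid_per_ml, threshold=config.pid_threshold,
            subject_id=record.subject_id, window=window))

    tac_rows = []
    for key, image in images.items():
        if image.n_frames < 2:
            continue
        for label, tac in extract_tac(image, masks, dose,
                                      record.weight_kg).items():
            for t, sm, sx in zip(tac.times_min, tac.suv_mean, tac.suv_max):
                tac_rows.append({"subject_id": record.subject_id,
                                 "group": record.group, "segment": key,
                                 "voi": label, "time_min": t,
                                 "suv_mean": sm, "suv_max": sx})
    return SubjectAnalysis(
        subject_id=record.subject_id, group=record.group, quant=quant,
        diagnoses=diagnoses, myo_mask_provenance=myo_provenance,
        tac_frames=pd.DataFrame(tac_rows))


def summarize_groups(quant: pd.DataFrame) -> pd.DataFrame:
    """Group mean, SD, and t-based 95% CI per (group, window, voi, metric).

    Single-subject groups get NaN SD/CI bounds and ci_defined = False.
    """
    if quant.empty:
        raise ValueError("empty quantitation table")
    rows = []
    metric_cols = ["suv_mean", "suv_max", "pid_per_ml", "ratio_myo_bone",
                   "ratio_myo_bp"]
    for (group, window, voi), sub in quant.groupby(["group", "window", "voi"],
                                                   sort=True):
        for metric in metric_cols:
            if metric not in sub or sub[metric].isna().all():
                continue
            values = sub[metric].dropna().to_numpy()
            n = len(values)
            mean = float(np.mean(values))
            sd = float(np.std(values, ddof=1)) if n > 1 else float("nan")
            if n > 1:
                half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
                ci_lo, ci_hi, defined = mean - half, mean + half, True
            else:
                ci_lo = ci_hi = float("nan")
                defined = False
            rows.append({"group": group, "window": window, "voi": voi,
                         "metric": metric, "n": n, "mean": mean, "sd": sd,
                         "ci95_lo": ci_lo, "ci95_hi": ci_hi,
                         "ci_defined": defined})
    return pd.DataFrame(rows)


def _quant_frame(analyses: list[SubjectAnalysis],
                 groups: dict[str, str]) -> pd.DataFrame:
    rows = []
    for analysis in analyses:
        for q in analysis.quant:
            for voi in q.suv_mean:
                rows.append({
                    "subject_id": q.subject_id,
                    "group": groups[q.subject_id],
                    "window": _window_label(q.window),
                    "window_start": q.window[0], "window_end": q.window[1],
                    "voi": voi,
                    "suv_mean": q.suv_mean[voi], "suv_max": q.suv_max[voi],
                    "pid_per_ml": q.pid_per_ml if voi == "LV_myo" else np.nan,
                    "ratio_myo_bone": q.ratio_myo_bone if voi == "LV_myo" else np.nan,
                    "ratio_myo_bp": q.ratio_myo_bp if voi == "LV_myo" else np.nan,
                })
    return pd.DataFrame(rows).sort_values(
        ["subject_id", "window_start", "voi"]).reset_index(drop=True)


def run_pipeline(config: RunConfig | None = None) -> CohortReport:
    """Run the full study emulation and return tidy tables.

    Deterministic given the configured seed; the config hash is recorded in
    the report and every CSV written.
    """
    config = config or RunConfig()
    seeds = np.random.SeedSequence(config.seed).spawn(2)

    cohort = generate_cohort(config.n_attr, config.n_non,
                             config.cohort_config(), seed=seeds[0])

    cf = None
    if config.acquisition().sensitivity_cps_per_Bq_per_mL_per_voxel is not None:
        phantom_img, phantom_mask = simulate_uniform_cylinder(
            config.calibration_activity_MBq, config.calibration_volume_mL,
            grid_shape=config.grid_shape, voxel_size_mm=config.voxel_size_mm,
            acquisition=config.acquisition(), seed=seeds[1])
        cf = compute_calibration_factor(
            phantom_img, phantom_mask, config.calibration_activity_MBq,
            config.calibration_volume_mL)

    analyses = [analyze_subject(subject, cf, config) for subject in cohort]
    groups = {s.record.subject_id: s.record.group for s in cohort}

    subjects_df = pd.DataFrame([{
        "subject_id": s.record.subject_id, "group": s.record.group,
        "weight_kg": s.record.weight_kg,
        "assay_activity_MBq": s.record.assay_activity_MBq,
        "residual_activity_MBq": s.record.residual_activity_MBq,
        "net_injected_MBq": net_injected_activity(s.record).injected_activity_Bq / 1e6,
        "myo_mask": a.myo_mask_provenance,
    } for s, a in zip(cohort, analyses)]).sort_values("subject_id")

    quant_df = _quant_frame(analyses, groups)
    summary_df = summarize_groups(quant_df)

    diag_rows = []
    for analysis in analyses:
        for d in analysis.diagnoses:
            diag_rows.append({"subject_id": d.subject_id,
                              "group": groups[d.subject_id],
                              "window": _window_label(d.window),
                              "window_start": d.window[0],
                              "rule": d.rule, "label": d.label,
                              "inputs": json.dumps(d.inputs_used, sort_keys=True)})
    diagnoses_df = pd.DataFrame(diag_rows).sort_values(
        ["subject_id", "window_start", "rule"]).reset_index(drop=True)

    perf_rows = []
    truth = {sid: (POSITIVE if g == "ATTR" else "negative")
             for sid, g in groups.items()}
    order = sorted(groups)
    for window in config.windows:
        wlabel = _window_label(window)
        sub = diagnoses_df[diagnoses_df.window == wlabel]
        labels_by_rule = {}
        for rule, rsub in sub.groupby("rule"):
            rsub = rsub.set_index("subject_id").loc[order]
            predicted = rsub["label"].tolist()
            labels_by_rule[rule] = predicted
            perf = diagnostic_performance(predicted, [truth[s] for s in order])
            perf_rows.append({"window": wlabel, "rule": rule,
                              "tp": perf.tp, "fp": perf.fp, "tn": perf.tn,
                              "fn": perf.fn, "sensitivity": perf.sensitivity,
                              "specificity": perf.specificity,
                              "accuracy": perf.accuracy})
        if len(labels_by_rule) == 2:
            a, b = (labels_by_rule[r] for r in sorted(labels_by_rule))
            perf_rows.append({"window": wlabel, "rule": "kappa_between_rules",
                              "tp": np.nan, "fp": np.nan, "tn": np.nan,
                              "fn": np.nan, "sensitivity": np.nan,
                              "specificity": np.nan,
                              "accuracy": np.nan,
                              "kappa": cohen_kappa(a, b)})
    performance_df = pd.DataFrame(perf_rows)

    tacs_df = pd.concat([a.tac_frames for a in analyses],
                        ignore_index=True) if analyses else pd.DataFrame()

    report = CohortReport(
        config=config, config_hash=config.config_hash(), calibration=cf,
        subjects=subjects_df.reset_index(drop=True), quant=quant_df,
        group_summary=summary_df, diagnoses=diagnoses_df,
        performance=performance_df, tacs=tacs_df)

    if config.output_dir:
        write_report(report, Path(config.output_dir))
    return report


# ---------------------------------------------------------------------------
# Persistence and figures
# ---------------------------------------------------------------------------

def write_report(report: CohortReport, out_dir: Path) -> None:
    """Write all tables as CSV (config hash in a header comment) and the
    figures regenerated from those tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.json").write_text(
        json.dumps(report.config.to_dict(), indent=1, sort_keys=True))
    if report.calibration is not None:
        report.calibration.to_json(out_dir / "calibration.json")
    tables = {"subjects": report.subjects, "quant": report.quant,
              "group_summary": report.group_summary,
              "diagnoses": report.diagnoses,
              "performance": report.performance, "tacs": report.tacs}
    for name, df in tables.items():
        path = out_dir / f"{name}.csv"
        with open(path, "w") as fh:
            fh.write(f"# config_hash={report.config_hash}\n")
            df.to_csv(fh, index=False, float_format="%.10g")
    _write_figures(report, out_dir)


def _write_figures(report: CohortReport, out_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not report.tacs.empty:
        fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
        for ax, group in zip(axes, ["non-ATTR", "ATTR"]):
            sub = report.tacs[(report.tacs.group == group)
                              & (report.tacs.time_min <= 65)]
            for voi, color in [("LA_bp", "tab:red"), ("LV_myo", "tab:blue"),
                               ("LS", "tab:green")]:
                vs = sub[sub.voi == voi].groupby("time_min")["suv_mean"]
                ax.plot(vs.mean().index, vs.mean().values, color=color,
                        label=voi)
            ax.set_title(group)
            ax.set_xlabel("time post-injection (min)")
            ax.legend()
        axes[0].set_ylabel("SUVmean (g/mL)")
        fig.tight_layout()
        fig.savefig(out_dir / "tac_suvmean.png", dpi=120)
        plt.close(fig)

    summary = report.group_summary
    sub = summary[(summary.metric == "suv_mean")]
    if not sub.empty:
        fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
        windows = sorted(sub.window.unique(),
                         key=lambda w: float(w.split("-")[0]))
        xs = np.arange(len(windows))
        for ax, group in zip(axes, ["non-ATTR", "ATTR"]):
            for voi, color in [("LA_bp", "tab:red"), ("LV_myo", "tab:blue"),
                               ("LS", "tab:green")]:
                rows = sub[(sub.group == group) & (sub.voi == voi)]
                rows = rows.set_index("window").reindex(windows)
                err = np.nan_to_num(rows["mean"] - rows["ci95_lo"])
                ax.errorbar(xs, rows["mean"], yerr=err, marker="o",
                            color=color, capsize=3, label=voi)
            ax.set_xticks(xs, windows, rotation=30)
            ax.set_title(group)
        axes[0].set_ylabel("SUVmean (g/mL)")
        axes[1].legend()
        fig.tight_layout()
        fig.savefig(out_dir / "group_suvmean.png", dpi=120)
        plt.close(fig)
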