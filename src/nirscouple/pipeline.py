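"""End-to-end orchestration: preprocess -> oxygenation -> phases -> coupling
inference per subject, then cohort statistics.

The per-subject product is one row of the SubjectMetrics table: the
time-mean tissue-oxygenation indices and the pressure-to-oxyhemoglobin
coupling strength per prefrontal channel and frequency band. The cohort
product is a GroupReport: distributional checks, one-way ANOVA with
Bonferroni pairwise flags, Pearson correlations against the cognitive
score, and ROC/Youden discrimination of mild impairment from normal
cognition.
"""
from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import stats as cstats
from .errors import NirsCoupleError, PipelineError
from .inference import DynamicalBayesianInference
from .oxygenation import summarize_toi, toi_series
from .phases import CARDIAC, LF, VLF, Band, extract_band_phase
from .preprocess import preprocess_recording
from .timeseries import Recording

__all__ = ["PipelineConfig", "subject_metrics", "group_report", "run_pipeline"]

#: Coupling-strength columns of the SubjectMetrics table.
CS_COLUMNS = ("cs_vlf_lpfc", "cs_lf_lpfc", "cs_vlf_rpfc", "cs_lf_rpfc")
TOI_COLUMNS = ("ltoi", "rtoi", "mean_toi")


@dataclass
class PipelineConfig:
    """All tunable parameters, with defaults matching the documented choices."""

    # bands
    vlf: tuple[float, float] = (0.02, 0.07)
    lf: tuple[float, float] = (0.07, 0.2)
    cardiac: tuple[float, float] = (0.6, 2.0)
    voices_per_octave: int = 16
    # preprocessing
    smoothing_window: float = 5.0
    detection_window: float = 2.0
    threshold_sd: float = 4.0
    target_rate: float = 20.0
    min_overlap: float = 600.0
    # inference
    K: int = 2
    window_vlf: float = 400.0
    window_lf: float = 200.0
    prop_const: float = 0.2
    tol: float = 1e-6
    # statistics
    family_alpha: float = 0.05
    n_boot: int = 2000
    # seeds / paths
    seed: int = 0
    input_dir: str = ""
    output_dir: str = ""

    def bands(self) -> dict[str, Band]:
        return {"VLF": Band("VLF", *self.vlf), "LF": Band("LF", *self.lf),
                "CARDIAC": Band("CARDIAC", *self.cardiac)}

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        for k in ("vlf", "lf", "cardiac"):
            if k in data and isinstance(data[k], list):
                data[k] = tuple(data[k])
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def subject_metrics(recording: Recording,
                    config: PipelineConfig | None = None) -> dict:
    """Process one recording into its SubjectMetrics row.

    Raises a :class:`~nirscouple.errors.NirsCoupleError` subclass when the
    recording cannot be analyzed (too short, degenerate, ...); the cohort
    runner records such subjects as excluded instead of failing.
    """
    cfg = config or PipelineConfig()
    bands = cfg.bands()
    smoothed, corrected = preprocess_recording(
        recording,
        smoothing_window=cfg.smoothing_window,
        detection_window=cfg.detection_window,
        threshold_sd=cfg.threshold_sd,
        target_rate=cfg.target_rate,
        min_overlap=cfg.min_overlap,
    )

    # TOI on artifact-corrected, unsmoothed concentrations
    toi_l = toi_series(corrected.channels["O2Hb_L"], corrected.channels["HHb_L"])
    toi_r = toi_series(corrected.channels["O2Hb_R"], corrected.channels["HHb_R"])
    toi = summarize_toi(toi_l, toi_r)

    phi_abp = extract_band_phase(smoothed.channels["ABP"], bands["CARDIAC"],
                                 cfg.voices_per_octave)
    row = {"subject_id": recording.subject_id,
           "ltoi": toi.ltoi, "rtoi": toi.rtoi, "mean_toi": toi.mean_toi}
    for side, tag in (("L", "lpfc"), ("R", "rpfc")):
        o2hb = smoothed.channels[f"O2Hb_{side}"]
        for band_name, window in (("VLF", cfg.window_vlf), ("LF", cfg.window_lf)):
            phi_o = extract_band_phase(o2hb, bands[band_name],
                                       cfg.voices_per_octave)
            dbi = DynamicalBayesianInference(
                K=cfg.K, window=window, prop_const=cfg.prop_const, tol=cfg.tol,
            ).fit(phi_abp, phi_o)
            row[f"cs_{band_name.lower()}_{tag}"] = dbi.cs_ao_
            row[f"cd_{band_name.lower()}_{tag}"] = dbi.cd_
    return row


def _roc_labels(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    sub = df[df["group"].isin(["NC", "MCI"])]
    return sub, (sub["group"] == "MCI").to_numpy().astype(int)


def group_report(metrics: pd.DataFrame,
                 config: PipelineConfig | None = None) -> dict:
    """Cohort statistics over a SubjectMetrics table.

    Requires ``group`` and ``moca`` columns. Produces, per variable,
    normality/homogeneity checks, ANOVA with the three Bonferroni-corrected
    pairwise comparisons, and the Pearson correlation with the MoCA score;
    plus ROC analyses distinguishing mild impairment from normal cognition
    using mean TOI (low values positive) and the bilateral mean coupling
    strength (high values positive).
    """
    cfg = config or PipelineConfig()
    variables = [c for c in TOI_COLUMNS + CS_COLUMNS if c in metrics.columns]
    report: dict = {"n_per_group": metrics["group"].value_counts().to_dict(),
                    "corrected_alpha": cfg.family_alpha / 3.0,
                    "variables": {}}
    groups_present = set(metrics["group"])
    for var in variables:
        entry: dict = {}
        values = {g: metrics.loc[metrics["group"] == g, var].to_numpy()
                  for g in ("NC", "MCI", "CI") if g in groups_present}
        if len(values) == 3 and all(v.size >= 3 for v in values.values()):
            try:
                entry["checks"] = cstats.distribution_checks(values)
            except NirsCoupleError as exc:
                entry["checks"] = {"error": str(exc)}
            res = cstats.anova_bonferroni(values, cfg.family_alpha)
            entry["anova"] = {
                "f": res.f, "p": res.p,
                "pairwise": {f"{a}-{b}": d
                             for (a, b), d in res.pairwise.items()},
            }
        try:
            r, p = cstats.pearson(metrics["moca"], metrics[var])
            entry["pearson_moca"] = {"r": r, "p": p}
        except NirsCoupleError as exc:
            entry["pearson_moca"] = {"error": str(exc)}
        report["variables"][var] = entry

    sub, labels = _roc_labels(metrics)
    if labels.size and 0 < labels.sum() < labels.size:
        roc = {}
        if "mean_toi" in sub:
            r = cstats.roc_youden(sub["mean_toi"].to_numpy(), labels,
                                  direction="lower", n_boot=cfg.n_boot,
                                  seed=cfg.seed)
            roc["mean_toi"] = asdict(r)
        cs_cols = [c for c in CS_COLUMNS if c in sub.columns]
        if cs_cols:
            mean_cs = sub[cs_cols].mean(axis=1).to_numpy()
            r = cstats.roc_youden(mean_cs, labels, direction="higher",
                                  n_boot=cfg.n_boot, seed=cfg.seed)
            roc["mean_cs"] = asdict(r)
        report["roc_nc_vs_mci"] = roc
    return report


def run_pipeline(
    cohort=None,
    config: PipelineConfig | None = None,
    input_dir=None,
    output_dir=None,
) -> tuple[pd.DataFrame, dict]:
    """Run the full analysis on a cohort (in memory or from ``input_dir``).

    Per-subject failures are recorded in the report's ``excluded`` list
    with a warning rather than aborting the run. Returns the
    SubjectMetrics table and the GroupReport (which embeds a manifest with
    the config digest for provenance).
    """
    cfg = config or PipelineConfig()
    if cohort is None:
        from .io import read_cohort
        if input_dir is None:
            input_dir = cfg.input_dir
        cohort = read_cohort(input_dir)

    meta = cohort.metadata.set_index("subject_id")
    rows = []
    excluded = []
    for rec in cohort.recordings:
        try:
            row = subject_metrics(rec, cfg)
        except NirsCoupleError as exc:
            warnings.warn(f"subject {rec.subject_id}: excluded ({exc})")
            excluded.append({"subject_id": rec.subject_id, "reason": str(exc)})
            continue
        row["group"] = meta.loc[rec.subject_id, "group"]
        row["moca"] = int(meta.loc[rec.subject_id, "moca"])
        rows.append(row)
    if not rows:
        raise PipelineError("no subject processed successfully")
    metrics = pd.DataFrame(rows)

    report = group_report(metrics, cfg)
    report["excluded"] = excluded
    report["manifest"] = {"config": asdict(cfg), "config_digest": cfg.digest(),
                          "seed": cfg.seed}

    out = output_dir or cfg.output_dir
    if out:
        from pathlib import Path
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        metrics.to_csv(out / "subject_metrics.csv", index=False)
        (out / "group_report.json").write_text(json.dumps(report, indent=2))
    return metrics, report
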