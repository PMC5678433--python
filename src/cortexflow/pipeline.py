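"""End-to-end orchestration: per-subject metrics, cohort statistics, and
the reproducible phantom-cohort demonstration.

A run is described by a :class:`RunConfig` (JSON on disk).  For each
subject the pipeline computes regional volumes and gyrification indices
from the labelled volume and, when phase-contrast data are present, CBF
and cerebral oxygen delivery; the cohort stage then performs
case-control matching, per-outcome ANCOVA (with a Bonferroni-flagged
four-lobe GI family), and regressions of brain metrics on CDO2/rScO2.
All outputs are plain CSV plus a JSON run manifest; identical config and
seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import flow as flowmod
from . import phantoms, stats
from .surface import GI_REGIONS, GIParameters, regional_gyrification
from .volumes import RegionScheme, read_label_volume, tissue_volumes, write_label_volume

log = logging.getLogger("cortexflow")

__all__ = ["RunConfig", "run_subject", "run_cohort", "make_demo_cohort"]

LOBE_GI_FAMILY = ("gi_frontal", "gi_parietal", "gi_temporal", "gi_occipital")


@dataclass
class RunConfig:
    """Fully serialisable description of a pipeline run."""

    cohort_csv: str
    output_dir: str
    volumes_dir: str | None = None
    flow_dir: str | None = None
    scheme_path: str | None = None
    gi: GIParameters = field(default_factory=GIParameters)
    cdo2_mode: str = "as_printed"
    covariates: tuple[str, ...] = ("pma_wk",)
    extra_covariates: tuple[str, ...] = ()
    alpha: float = 0.05
    regional_family_size: int = 4
    seed: int = 0

    def validate(self) -> None:
        if not Path(self.cohort_csv).exists():
            raise FileNotFoundError(self.cohort_csv)
        for p in (self.volumes_dir, self.flow_dir, self.scheme_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gi"] = dataclasses.asdict(self.gi)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("gi"), dict):
            d["gi"] = GIParameters(**d["gi"])
        for key in ("covariates", "extra_covariates"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _find_volume(volumes_dir: Path, subject_id: str) -> Path | None:
    for suffix in ("_labels.nii.gz", "_labels.nii", ".nii.gz", ".nii"):
        p = volumes_dir / f"{subject_id}{suffix}"
        if p.exists():
            return p
    return None


def run_subject(config: RunConfig, subject_id: str, covariates: dict | None = None) -> dict:
    """Compute one subject's metric row.

    Always attempts volumes and GI; CBF/CDO2 only when the subject's flow
    directory exists and the cohort row carries SaO2 and haemoglobin.
    Failures are recorded in the ``error`` field, never silently dropped.
    """
    row: dict = {"subject_id": subject_id, "error": ""}
    covariates = covariates or {}
    try:
        if config.volumes_dir is None or config.scheme_path is None:
            raise FileNotFoundError("volumes_dir/scheme_path not configured")
        vol_path = _find_volume(Path(config.volumes_dir), subject_id)
        if vol_path is None:
            raise FileNotFoundError(f"no label volume for {subject_id}")
        scheme = (
            RegionScheme.from_json(config.scheme_path)
            if str(config.scheme_path).endswith(".json")
            else RegionScheme.from_csv(config.scheme_path)
        )
        lv = read_label_volume(vol_path)
        for name, ml in tissue_volumes(lv, scheme).items():
            row[f"vol_{name}"] = ml
        for res in regional_gyrification(lv, scheme, config.gi):
            row[f"gi_{res.region}"] = res.gi
            row[f"pial_area_{res.region}_mm2"] = res.pial_area_mm2
            row[f"hull_area_{res.region}_mm2"] = res.hull_area_mm2
    except Exception as exc:  # per-subject failure record
        row["error"] = f"volumes/gi: {exc}"
        log.warning("subject %s: %s", subject_id, row["error"])

    row.update(_subject_flow_metrics(config, subject_id, covariates, row))
    return row


def _subject_flow_metrics(config, subject_id, covariates, row) -> dict:
    out = {"cbf_ml_min": np.nan, "cdo2": np.nan, "cdo2_indexed": np.nan}
    if config.flow_dir is None:
        return out
    subj_dir = Path(config.flow_dir) / subject_id
    series_path = subj_dir / "series.nii.gz"
    if not series_path.exists():
        return out  # partial-data contract: CDO2 fields stay empty
    try:
        series = flowmod.read_phase_contrast_series(series_path)
        rois = flowmod.read_roi_masks(subj_dir)
        cbf = flowmod.total_cbf(series, rois)
        out["cbf_ml_min"] = cbf
        sao2, hb = covariates.get("sao2"), covariates.get("hb_g_dl")
        if sao2 is not None and hb is not None and np.isfinite(sao2) and np.isfinite(hb):
            rec = flowmod.cdo2(float(sao2), float(hb), cbf, mode=config.cdo2_mode)
            out["cdo2"] = rec.cdo2
            brain_ml = row.get("vol_whole_brain")
            if brain_ml is not None and np.isfinite(brain_ml) and brain_ml > 0:
                rec.brain_volume_ml = float(brain_ml)
                out["cdo2_indexed"] = flowmod.indexed_cdo2(rec)
    except Exception as exc:
        out["flow_error"] = str(exc)
        log.warning("subject %s flow: %s", subject_id, exc)
    return out


def _ancova_rows(metrics: pd.DataFrame, config: RunConfig, outcomes) -> list[dict]:
    rows = []
    thresh = stats.bonferroni_threshold(config.alpha, config.regional_family_size)
    for outcome in outcomes:
        try:
            res = stats.ancova_group_effect(
                metrics, outcome, config.covariates, config.extra_covariates
            )
        except ValueError as exc:
            log.warning("ANCOVA skipped for %s: %s", outcome, exc)
            continue
        in_family = outcome in LOBE_GI_FAMILY
        threshold = thresh if in_family else config.alpha
        rows.append(
            {
                "outcome": outcome,
                "group_effect": res.group_effect,
                "p_value": res.group_p,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "n_chd": res.n_case,
                "n_control": res.n_control,
                "n_dropped": res.n_dropped,
                "bonferroni_family": "lobar_gi" if in_family else "",
                "threshold": threshold,
                "significant": res.group_p < threshold,
            }
        )
    return rows


def run_cohort(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run every subject, then the cohort statistics; write the report
    bundle (cohort_metrics / group_comparisons / regressions / matching
    CSVs plus manifest.json) into the output directory."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = pd.read_csv(config.cohort_csv)
    if "subject_id" not in cohort.columns or "group" not in cohort.columns:
        raise ValueError("cohort CSV needs subject_id and group columns")

    # per-subject image metrics, if imaging inputs are configured
    if config.volumes_dir is not None:
        rows = [
            run_subject(config, r["subject_id"], r.to_dict())
            for _, r in cohort.iterrows()
        ]
        metrics = cohort.merge(pd.DataFrame(rows), on="subject_id", how="left")
    else:
        metrics = cohort.copy()

    metrics = metrics.sort_values("subject_id").reset_index(drop=True)
    bundle: dict[str, pd.DataFrame] = {"cohort_metrics": metrics}

    cases = metrics[metrics["group"] == "CHD"]
    controls = metrics[metrics["group"] == "control"]
    enough = min(len(cases), len(controls)) >= 3

    # matching
    if enough and len(controls) >= len(cases):
        match = stats.match_controls(cases, controls)
        bundle["matching"] = match.pairs
    else:
        log.warning("matching skipped: need >= 3 per group and pool >= cases")

    # group comparisons (ANCOVA per outcome)
    candidate = [
        c
        for c in metrics.columns
        if (c.startswith("vol_") or c.startswith("gi_") or c in ("gi", "gmv_ml"))
        and pd.api.types.is_numeric_dtype(metrics[c])
    ]
    if enough:
        rows = _ancova_rows(metrics, config, candidate)
        if "physiology" in metrics.columns:
            gi_col = "gi_whole" if "gi_whole" in metrics.columns else (
                "gi" if "gi" in metrics.columns else None
            )
            if gi_col:
                for subgroup in sorted(metrics.loc[cases.index, "physiology"].dropna().unique()):
                    sub = pd.concat(
                        [controls, cases[cases["physiology"] == subgroup]]
                    )
                    try:
                        res = stats.ancova_group_effect(
                            sub, gi_col, config.covariates, config.extra_covariates
                        )
                        rows.append(
                            {
                                "outcome": f"{gi_col}[{subgroup} vs control]",
                                "group_effect": res.group_effect,
                                "p_value": res.group_p,
                                "ci_low": res.ci_low,
                                "ci_high": res.ci_high,
                                "n_chd": res.n_case,
                                "n_control": res.n_control,
                                "n_dropped": res.n_dropped,
                                "bonferroni_family": "",
                                "threshold": config.alpha,
                                "significant": res.group_p < config.alpha,
                            }
                        )
                    except ValueError as exc:
                        log.warning("physiology subgroup %s skipped: %s", subgroup, exc)
        bundle["group_comparisons"] = pd.DataFrame(rows)
    else:
        log.warning("group statistics skipped: fewer than 3 subjects per group")

    # regressions of brain metrics on oxygen-delivery measures (within CHD)
    xs = [c for c in ("cdo2", "cdo2_indexed", "rsco2") if c in metrics.columns]
    ys = [
        c
        for c in ("gi_whole", "gi", "vol_whole_brain", "vol_cortical_grey_matter", "gmv_ml")
        if c in metrics.columns
    ]
    reg_rows = []
    for x in xs:
        for y in ys:
            try:
                res = stats.linreg(cases, x, y)
            except (ValueError, KeyError):
                continue
            reg_rows.append(dataclasses.asdict(res))
    if reg_rows:
        bundle["regressions"] = pd.DataFrame(reg_rows)

    # NIRS repeatability, when repeated readings exist
    if {"rsco2", "rsco2_repeat"} <= set(metrics.columns):
        paired = metrics[["rsco2", "rsco2_repeat"]].dropna()
        if len(paired) >= 3:
            rep = stats.repeatability(paired["rsco2"], paired["rsco2_repeat"])
            bundle["repeatability"] = pd.DataFrame([dataclasses.asdict(rep)])

    for name, df in bundle.items():
        df.to_csv(out_dir / f"{name}.csv", index=False)
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "n_subjects": len(metrics),
        "outputs": sorted(f"{k}.csv" for k in bundle),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    config.to_json(out_dir / "config.json")
    return bundle


# ---------------------------------------------------------------------------
# phantom-cohort demonstration
# ---------------------------------------------------------------------------


def make_demo_cohort(
    out_dir,
    n_per_group: int = 6,
    seed: int = 0,
    gi_group_deficit_mm: float = 1.0,
    base_amplitude_mm: float = 3.0,
) -> RunConfig:
    """Write a small, fully synthetic cohort the pipeline can run end to end.

    Each subject gets a folded-brain label volume (the CHD group's fold
    amplitude is reduced by ``gi_group_deficit_mm``, injecting a known
    negative GI offset), a pulsatile flow phantom, and covariates (GA,
    PMA, SaO2, haemoglobin, repeated NIRS readings).  Returns a RunConfig
    pointing at the generated inputs.
    """
    out_dir = Path(out_dir)
    vol_dir = out_dir / "volumes"
    flow_dir = out_dir / "flow"
    vol_dir.mkdir(parents=True, exist_ok=True)
    flow_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    scheme = phantoms.folded_brain_scheme()
    scheme_path = out_dir / "scheme.json"
    scheme.to_json(scheme_path)

    rows = []
    for group, amp in (("control", base_amplitude_mm), ("CHD", base_amplitude_mm - gi_group_deficit_mm)):
        for i in range(n_per_group):
            sid = f"{group}-{i + 1:03d}"
            a = float(np.clip(amp + rng.normal(0.0, 0.15), 0.5, 4.0))
            spec = phantoms.FoldedBrainSpec(
                base_radius_mm=16.0,
                fold_amplitude_mm=a,
                fold_frequency=8,
                cortical_thickness_mm=2.5,
                voxel_size_mm=1.0,
                grid_shape=(48, 48, 48),
                seed=seed,
            )
            write_label_volume(phantoms.make_folded_brain(spec), vol_dir / f"{sid}_labels.nii.gz")

            subj_flow = flow_dir / sid
            subj_flow.mkdir(exist_ok=True)
            vscale = float(rng.uniform(0.8, 1.2))
            fspec = phantoms.FlowPhantomSpec(
                peak_velocities_cm_s=tuple(v * vscale for v in (60.0, 60.0, 50.0)),
                grid_shape=(64, 64),
            )
            series, rois, analytic = phantoms.make_phase_contrast_phantom(fspec)
            flowmod.write_phase_contrast_series(series, subj_flow / "series.nii.gz")
            flowmod.write_roi_masks(rois, subj_flow, spacing_mm=series.pixel_spacing_mm)
            (subj_flow / "analytic_flows.json").write_text(json.dumps(analytic, indent=1))

            rsco2 = float(np.clip(rng.normal(70.0, 8.0), 40.0, 95.0))
            rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "ga_wk": rng.normal(38.7, 0.8),
                    "pma_wk": rng.normal(39.2, 0.7),
                    "sao2": float(np.clip(rng.normal(0.93, 0.05), 0.6, 1.0)),
                    "hb_g_dl": float(np.clip(rng.normal(16.1, 2.1), 8.0, 22.0)),
                    "rsco2": rsco2,
                    "rsco2_repeat": rsco2 + float(rng.normal(0.0, 3.0)),
                }
            )
    cohort_csv = out_dir / "cohort.csv"
    pd.DataFrame(rows).sort_values("subject_id").to_csv(cohort_csv, index=False)

    return RunConfig(
        cohort_csv=str(cohort_csv),
        output_dir=str(out_dir / "results"),
        volumes_dir=str(vol_dir),
        flow_dir=str(flow_dir),
        scheme_path=str(scheme_path),
        seed=seed,
    )
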