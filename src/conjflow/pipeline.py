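"""End-to-end composition: registration -> morphology -> velocimetry ->
hemodynamics -> cohort statistics, with provenance."""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .io import ImageSequence, read_sequence, validate_subjects, write_image
from .registration import register_sequence
from .morphology import (DiametryError, extract_centerlines,
                         filter_by_variance, find_bifurcations_and_split,
                         label_vessel_type, measure_diameter, segment_vessels)
from .velocimetry import VelocimetryError, measure_velocity
from .hemodynamics import audit_records, dedupe_longest, hemodynamic_record
from .stats import (fit_mixed_model, group_anova, model_result_frame,
                    slope_result_frame, velocity_diameter_slopes)

DESCRIPTORS = ("D", "V", "Q", "WSR", "WSS")


@dataclass
class StageLog:
    """Per-sequence accounting of what each stage kept and rejected."""

    subject_id: str = ""
    n_frames: int = 0
    run: tuple[int, int] = (0, 0)
    n_segments_raw: int = 0
    n_discarded_short: int = 0
    n_diametry_failed: int = 0
    n_out_of_range: int = 0
    n_no_flow: int = 0
    n_velocimetry_failed: int = 0
    n_records: int = 0
    messages: list = field(default_factory=list)


def process_sequence(seq: ImageSequence, subject_id: str, hct: float,
                     config: PipelineConfig | None = None,
                     annotations: dict | None = None,
                     outdir: str | Path | None = None):
    """Run the imaging stages on one sequence; returns (records, log).

    ``records`` is a vessel-level DataFrame (already de-duplicated to the
    longest segment per skeleton component / vessel).
    """
    cfg = config or PipelineConfig()
    log = StageLog(subject_id=subject_id, n_frames=seq.n_frames)

    registered, quality = register_sequence(seq, cfg.quality, cfg.registration)
    log.run = registered.run

    avg = registered.time_averaged
    mask = segment_vessels(avg, cfg.segmentation)
    skel = extract_centerlines(mask)
    segments, n_short = find_bifurcations_and_split(
        skel, seq.pixel_size_um, min_length_um=cfg.diametry.min_length_um,
        prune_px=cfg.segmentation.prune_px)
    log.n_segments_raw = len(segments) + n_short
    log.n_discarded_short = n_short

    filter_by_variance(segments, registered, mask, cfg.variance_filter)

    rows = []
    for seg in segments:
        try:
            measure_diameter(seg, avg, seq.pixel_size_um, cfg.diametry)
        except DiametryError:
            log.n_diametry_failed += 1
            continue
        if not seg.admissible(cfg.diametry):
            log.n_out_of_range += 1
            continue
        label_vessel_type(seg, annotations)
        if not seg.flow_detected:
            log.n_no_flow += 1
            continue
        try:
            sti = measure_velocity(registered, seg, cfg.velocimetry)
        except VelocimetryError as exc:
            log.n_velocimetry_failed += 1
            log.messages.append(str(exc))
            continue
        if not sti.reliable or sti.aliased:
            log.n_velocimetry_failed += 1
            continue
        rows.append(hemodynamic_record(
            subject_id=subject_id, vessel_id=seg.parent_vessel_id,
            segment_id=seg.segment_id, vessel_type=seg.vessel_type,
            d_um=seg.mean_diameter_um, v_mm_s=sti.velocity_mm_s, hct=hct,
            length_um=seg.length_um, n_stations=seg.n_stations,
            cfg=cfg.hemodynamics))

    records = dedupe_longest(pd.DataFrame(rows))
    log.n_records = len(records)
    audit_records(records)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_image(outdir / f"{subject_id}_avg.tiff", avg)
        write_image(outdir / f"{subject_id}_mask.tiff", mask.astype(np.float32))
        quality.to_csv(outdir / f"{subject_id}_quality.csv", index=False)
        pd.DataFrame(registered.translations,
                     columns=["dy_px", "dx_px"]).to_csv(
            outdir / f"{subject_id}_translations.csv", index=False)
    return records, log


def analyze_cohort(vessels: pd.DataFrame, subjects: pd.DataFrame,
                   config: PipelineConfig | None = None) -> dict:
    """Cohort statistics on a vessel-level table joined with subject data."""
    cfg = config or PipelineConfig()
    subjects = validate_subjects(subjects)
    dup = [c for c in subjects.columns
           if c in vessels.columns and c != "subject_id"]
    merged = vessels.merge(subjects.drop(columns=dup), on="subject_id",
                           how="left")
    report: dict = {"anova": {}, "models": [], "slopes": []}
    descriptors = [d for d in DESCRIPTORS if d in merged.columns]
    enough = merged.groupby("group", observed=True)["subject_id"].nunique()
    if (enough >= 2).sum() < 2:
        report["skipped"] = "fewer than 2 groups with 2+ subjects"
        return report

    model_results = []
    for d in descriptors:
        p, summary = group_anova(merged, d)
        report["anova"][d] = {"p": p, "summary": summary}
        for adjusted in (False, True):
            if adjusted and not set(cfg.stats.covariates) <= set(merged.columns):
                continue
            model_results.append(fit_mixed_model(merged, d, adjusted, cfg.stats))
    report["models"] = model_results
    report["model_table"] = model_result_frame(model_results)

    slope_results = []
    if {"V", "D"} <= set(merged.columns):
        for adjusted in (False, True):
            if adjusted and not set(cfg.stats.covariates) <= set(merged.columns):
                continue
            slope_results.extend(velocity_diameter_slopes(merged, adjusted,
                                                          cfg.stats))
    report["slopes"] = slope_results
    report["slope_table"] = slope_result_frame(slope_results)
    return report


def run_pipeline(sequence_inputs, subjects: pd.DataFrame,
                 config: PipelineConfig | None = None,
                 annotations: dict | None = None,
                 outdir: str | Path | None = None):
    """Full pipeline over ``[(subject_id, sequence-or-path), ...]``.

    Returns ``(records, report, provenance)``.  Fails fast on an invalid
    subject table; per-sequence stage errors propagate with attribution.
    """
    cfg = config or PipelineConfig()
    subjects = validate_subjects(subjects)
    hct_by_subject = (subjects.set_index("subject_id")["hct"].to_dict()
                      if "hct" in subjects.columns else {})

    all_records, logs = [], []
    for subject_id, item in sequence_inputs:
        seq = item if isinstance(item, ImageSequence) else read_sequence(
            item, pixel_size_um=cfg.acquisition.pixel_size_um,
            frame_rate_hz=cfg.acquisition.frame_rate_hz)
        ann = (annotations or {}).get(subject_id)
        try:
            recs, log = process_sequence(
                seq, subject_id, hct=hct_by_subject.get(subject_id, 0.45),
                config=cfg, annotations=ann, outdir=outdir)
        except Exception as exc:
            raise RuntimeError(f"subject {subject_id}: {exc}") from exc
        all_records.append(recs)
        logs.append(log)

    records = (pd.concat(all_records, ignore_index=True)
               if all_records else pd.DataFrame())
    report = analyze_cohort(records, subjects, cfg) if not records.empty else {}

    provenance = {
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "version": __version__,
        "python": platform.python_version(),
        "config": json.loads(json.dumps(cfg.to_dict(), default=str)),
        "n_sequences": len(logs),
        "n_records": len(records),
        "stage_logs": [vars(l) for l in logs],
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        records.to_csv(outdir / "hemodynamics.csv", index=False)
        Path(outdir, "provenance.json").write_text(
            json.dumps(provenance, indent=2, default=str))
    return records, report, provenance
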