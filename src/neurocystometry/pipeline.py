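"""End-to-end analysis drive.

Runs the stages in acquisition order — envelope reduction, artifact and
SNR screening, phase segmentation, decay and afferent-model fits, summary
assembly, and the two-group comparison — over a cohort of recordings
(loaded from disk or freshly simulated), with per-recording failures
logged and skipped rather than aborting the cohort.  Exclusion accounting
(artifact verdicts, SNR below threshold, failed segmentations) is kept so
that total = analyzed + excluded always balances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .config import PipelineConfig
from .model import MeasurementSummary, summarize_measurement
from .processing import RawRecording, SignalError, compute_snr, reduce_recording
from .segmentation import SegmentationError, annotate_recording
from .stats import GroupComparison, StatsError, compare_groups, comparisons_to_frame
from . import io as ncio

__all__ = ["PipelineResult", "analyze_recording", "run_pipeline"]

logger = logging.getLogger("neurocystometry")


@dataclass
class PipelineResult:
    summaries: list[MeasurementSummary] = field(default_factory=list)
    names: list[str] = field(default_factory=list)
    comparisons: list[GroupComparison] = field(default_factory=list)
    #: recording name -> exclusion/skip reason
    exclusions: dict[str, str] = field(default_factory=dict)
    n_total: int = 0

    @property
    def n_analyzed(self) -> int:
        return sum(1 for s in self.summaries if not s.excluded)

    @property
    def n_excluded(self) -> int:
        return self.n_total - self.n_analyzed


def analyze_recording(rec: RawRecording,
                      cfg: PipelineConfig | None = None) -> MeasurementSummary:
    """Process -> screen -> segment -> fit -> summarize one recording.

    A measurement failing the artifact verdict or the SNR inclusion rule
    (or whose segmentation fails) is returned as an excluded summary row
    carrying the reason; it keeps whatever quantities were computable.
    """
    cfg = (cfg or PipelineConfig()).validate()
    avg, artifacts = reduce_recording(rec, cfg.signal)

    if artifacts.exclude:
        return MeasurementSummary(
            condition=rec.condition, excluded=True,
            exclusion_reason=(f"artifacts: {artifacts.flagged_fraction:.1%} "
                              f"of samples flagged"),
        )

    snr = compute_snr(avg.ra_nerve, mask=avg.artifact_mask,
                      snr_min=cfg.signal.snr_min)
    if not snr.include:
        out = MeasurementSummary(
            condition=rec.condition, excluded=True,
            exclusion_reason=f"SNR {snr.snr:.2f} <= {cfg.signal.snr_min}",
        )
        out.snr = snr.snr
        return out

    try:
        annotation = annotate_recording(avg.pressure, fs=avg.rate_hz,
                                        cfg=cfg.segmentation)
    except SegmentationError as err:
        out = MeasurementSummary(
            condition=rec.condition, excluded=True,
            exclusion_reason=f"segmentation failed: {err}",
        )
        out.snr = snr.snr
        out.snr_ok = True
        return out

    return summarize_measurement(rec, avg, annotation, snr,
                                 signal_cfg=cfg.signal, model_cfg=cfg.model)


def run_pipeline(recordings: Sequence[tuple[str, RawRecording]] | None = None,
                 paths: Sequence[str | Path] | None = None,
                 cfg: PipelineConfig | None = None,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Analyze a cohort and compare the two conditions.

    ``recordings`` is a sequence of ``(name, RawRecording)``; alternatively
    ``paths`` gives container stems to load.  Per-recording read or
    analysis errors are logged as skips.  When ``outdir`` is given, the
    summary table, the comparison table and the exclusion log are written
    there as CSV/text.
    """
    cfg = (cfg or PipelineConfig()).validate()
    items: list[tuple[str, RawRecording | None, str]] = []
    if recordings is not None:
        items.extend((name, rec, "") for name, rec in recordings)
    for p in paths or []:
        try:
            items.append((str(p), ncio.read_recording(p), ""))
        except (ncio.FormatError, OSError, ValueError) as err:
            logger.warning("skipping %s: %s", p, err)
            items.append((str(p), None, f"unreadable: {err}"))

    result = PipelineResult(n_total=len(items))
    for name, rec, problem in items:
        if rec is None:
            result.exclusions[name] = problem
            continue
        try:
            summary = analyze_recording(rec, cfg)
        except (SignalError, SegmentationError, ValueError) as err:
            logger.warning("skipping %s: %s", name, err)
            result.exclusions[name] = f"analysis failed: {err}"
            continue
        result.summaries.append(summary)
        result.names.append(name)
        if summary.excluded:
            result.exclusions[name] = summary.exclusion_reason

    try:
        result.comparisons = compare_groups(result.summaries, cfg.stats)
    except StatsError as err:
        logger.warning("group comparison not possible: %s", err)

    logger.info("pipeline: %d recordings, %d analyzed, %d excluded",
                result.n_total, result.n_analyzed, result.n_excluded)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ncio.write_summaries(result.summaries, outdir / "summaries.csv",
                             names=result.names)
        comparisons_to_frame(result.comparisons).to_csv(
            outdir / "comparison.csv", index=False)
        with open(outdir / "exclusions.log", "w") as fh:
            fh.write(f"total={result.n_total} analyzed={result.n_analyzed} "
                     f"excluded={result.n_excluded}\n")
            for name, reason in result.exclusions.items():
                fh.write(f"{name}\t{reason}\n")
    return result
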