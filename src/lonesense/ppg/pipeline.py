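"""The full per-segment PPG chain: SQA -> reconstruction -> peaks -> HRV."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hrv import HRV_FEATURES, HRVFeatures, compute_hrv_features
from .peaks import detect_systolic_peaks
from .reconstruct import reconstruct_segment
from .segment import IBISeries, PPGSegment
from .sqa import DEFAULT_THRESHOLDS, SQAThresholds, apply_sqa


@dataclass
class PPGPipelineConfig:
    sqa_window_s: float = 5.0
    sqa_rule: str = "majority"
    thresholds: SQAThresholds = field(default_factory=lambda: DEFAULT_THRESHOLDS)
    reconstruct: bool = True


def process_segment(segment: PPGSegment,
                    config: PPGPipelineConfig | None = None
                    ) -> tuple[HRVFeatures, IBISeries, PPGSegment]:
    """Run the cleaning chain on one segment and extract HRV features."""
    config = config or PPGPipelineConfig()
    seg = apply_sqa(segment, config.thresholds, config.sqa_window_s, config.sqa_rule)
    if config.reconstruct:
        seg = reconstruct_segment(seg)
    ibi = detect_systolic_peaks(seg)
    feats = compute_hrv_features(ibi, seg.duration_s)
    return feats, ibi, seg


def hrv_from_beats(beat_times: np.ndarray, duration_s: float) -> HRVFeatures:
    """HRV features straight from known beat times (bypasses the waveform)."""
    return compute_hrv_features(IBISeries.from_beats(np.asarray(beat_times, float)),
                                duration_s)


def hrv_stream(segments: list[PPGSegment],
               config: PPGPipelineConfig | None = None) -> pd.DataFrame:
    """Process many segments into a long feature-stream table.

    One row per segment: ``participant_id``, ``t`` (segment start) and the
    HRV feature columns prefixed ``hrv_``.
    """
    rows = []
    for seg in segments:
        feats, _, _ = process_segment(seg, config)
        getattr(seg, "_cache", {}).clear()  # free the per-segment filter cache
        row = {"participant_id": seg.participant_id, "t": seg.start_time}
        row.update({f"hrv_{k}": v for k, v in feats.to_dict().items() if k in HRV_FEATURES})
        rows.append(row)
    return pd.DataFrame(rows)
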