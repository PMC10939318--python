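"""End-to-end gait analysis: raw sensor-frame recording → per-stride parameters.

Chains the package's stages with sensible defaults:

1. gravity alignment (optional — simulated data is already aligned),
2. sensor→body frame conversion,
3. stride segmentation (subsequence DTW against a stride template),
4. event detection (tc, ic, min_vel) and re-segmentation to
   min_vel strides,
5. ZUPT detection,
6. trajectory reconstruction (RTS-smoothed error-state Kalman filter),
7. temporal and spatial parameter calculation.

Each stage's output is kept on the result object so intermediate
quantities can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gaitkit.core_types import EventList, ImuRecording, IntervalList, Trajectory, to_body_frame
from gaitkit.event_detection import EventDetectionConfig, detect_events, to_min_vel_strides
from gaitkit.parameters import spatial_parameters, temporal_parameters
from gaitkit.stride_segmentation import DtwConfig, StrideTemplate, subsequence_dtw
from gaitkit.trajectory import KalmanConfig, rts_kalman
from gaitkit.zupt_detection import ZuptConfig, detect_zupt


@dataclass
class PipelineResult:
    segmented_strides: IntervalList
    events: EventList
    min_vel_strides: IntervalList
    min_vel_events: EventList
    zupts: IntervalList
    trajectory: Trajectory
    temporal: pd.DataFrame
    spatial: pd.DataFrame

    @property
    def mean_gait_velocity(self) -> float:
        return float(np.nanmean(self.spatial["gait_velocity"]))


@dataclass
class GaitPipeline:
    """Configurable end-to-end pipeline over a sensor-frame recording."""

    template: StrideTemplate
    # the local warping constraint keeps match borders from drifting
    # through flat stance stretches, so it is on by default here
    dtw: DtwConfig = field(default_factory=lambda: DtwConfig(max_local_run=3))
    event: EventDetectionConfig = field(default_factory=EventDetectionConfig)
    zupt: ZuptConfig = field(default_factory=ZuptConfig)
    kalman: KalmanConfig = field(default_factory=KalmanConfig)

    def run(self, rec: ImuRecording, side: str = "left") -> PipelineResult:
        body = to_body_frame(rec, side) if rec.frame == "sensor" else rec
        template = self.template.resample(rec.sampling_rate)
        strides, _ = subsequence_dtw(body.gyr[:, 1], template, self.dtw)
        events = detect_events(body, strides, self.event)
        mv_strides, mv_events = to_min_vel_strides(events, strides)
        zupts = detect_zupt(rec, self.zupt)
        result = rts_kalman(rec, zupts, self.kalman)
        temporal = temporal_parameters(events, rec.sampling_rate) \
            if len(events) >= 2 else pd.DataFrame()
        spatial = spatial_parameters(result.trajectory, mv_strides)
        return PipelineResult(
            segmented_strides=strides,
            events=events,
            min_vel_strides=mv_strides,
            min_vel_events=mv_events,
            zupts=zupts,
            trajectory=result.trajectory,
            temporal=temporal,
            spatial=spatial,
        )
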