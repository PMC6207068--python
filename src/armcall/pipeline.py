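"""End-to-end convenience driver: normalize -> segment -> call -> arm flags."""

from __future__ import annotations

import pandas as pd

from .arms import flags_table
from .calling import call_table, default_platform_model
from .genome import ArmTable
from .preprocess import drop_chrY, median_normalize
from .segmentation import SegmentationConfig, segment_profile


def run_pipeline(
    probes: pd.DataFrame,
    annotations: pd.DataFrame,
    arms: ArmTable | None = None,
    segmentation_config: SegmentationConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Process a probe-level cohort into called segments and arm flags.

    Each sample is median-normalized, stripped of Y, segmented, and
    called with its platform's default cutoffs (the platform comes from
    the annotation table). Returns (called segment table, flag table).
    """
    arms = arms or ArmTable.hg19()
    platform_of = annotations.set_index("sample_id").platform.to_dict()
    called = []
    for sample, profile in probes.groupby("sample_id", sort=False):
        profile = drop_chrY(median_normalize(profile))
        segments = segment_profile(profile, segmentation_config)
        model = default_platform_model(platform_of[sample])
        called.append(call_table(segments, model))
    called_df = pd.concat(called, ignore_index=True)
    return called_df, flags_table(called_df, arms)
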