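"""Chromosome-arm-level aberration scoring and profile classification.

For each sample the eight recurrent segmental lesions of high-risk
neuroblastoma are flagged: loss of 1p, 3p, 4p, 11q, 14q and gain of 1q,
2p, 17q. A segmental aberration is a gain or loss larger than 3 Mb that
is neither a whole-chromosome aberration nor an amplification. An
aberration spanning the centromere belongs to the arm carrying its
longer part.

Adjacent same-direction aberrant segments are merged into runs before
the 3 Mb test, so fragmentation by the segmenter cannot hide a lesion.
Homozygous deletions count toward loss flags; amplifications merge into
gain-direction runs but a run consisting only of amplified segments
never counts as segmental.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .calling import GAIN_CLASS, LOSS_CLASS
from .errors import CallingError
from .genome import FLAGGED_ARMS, ArmTable, GeneTable, assign_arm

MIN_SEGMENTAL_BP = 3_000_000
FOCAL_MAX_BP = 5_000_000

FLAG_NAMES = [name for name, *_ in FLAGGED_ARMS]

PROFILE_CLASSES = ("segmental", "numerical_only", "silent")


@dataclass
class ArmAberrationFlags:
    """Per-sample presence of the 8 recurrent lesions plus profile class."""

    flags: dict = field(default_factory=lambda: {name: False for name in FLAG_NAMES})
    any_segmental: bool = False
    profile_class: str = "silent"

    def as_dict(self) -> dict:
        return {**self.flags, "any_segmental": self.any_segmental, "profile_class": self.profile_class}


def _direction(label: str) -> str | None:
    if label in GAIN_CLASS:
        return "gain"
    if label in LOSS_CLASS:
        return "loss"
    if label == "normal":
        return None
    raise CallingError(f"segment has no call label ({label!r}); run calling first")


@dataclass
class _Run:
    chrom: str
    start: int
    end: int
    direction: str
    covered: int  # bp covered by member segments
    has_nonamp: bool  # at least one member that is not an amplification
    whole_chromosome: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


def _aberrant_runs(sample_segments: pd.DataFrame) -> list[_Run]:
    """Merge adjacent same-direction aberrant segments into maximal runs."""
    runs: list[_Run] = []
    for chrom, grp in sample_segments.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        current: _Run | None = None
        for seg in grp.itertuples():
            direction = _direction(seg.annotation)
            if direction is None:
                current = None
                continue
            if current is not None and current.direction == direction:
                current.end = int(seg.end)
                current.covered += int(seg.end - seg.start)
                current.has_nonamp |= seg.annotation != "amplification"
            else:
                current = _Run(
                    chrom=str(chrom),
                    start=int(seg.start),
                    end=int(seg.end),
                    direction=direction,
                    covered=int(seg.end - seg.start),
                    has_nonamp=seg.annotation != "amplification",
                )
                runs.append(current)
    return runs


def _mark_whole_chromosome(runs: list[_Run], sample_segments: pd.DataFrame, coverage_fraction: float) -> None:
    covered_by_chrom = (
        (sample_segments.end - sample_segments.start).groupby(sample_segments.chrom).sum().to_dict()
    )
    for run in runs:
        total = covered_by_chrom.get(run.chrom, 0)
        run.whole_chromosome = total > 0 and run.covered >= coverage_fraction * total


def is_whole_chromosome(
    chrom_segments: pd.DataFrame,
    arms: ArmTable,
    coverage_fraction: float = 0.95,
) -> bool:
    """True iff a maximal same-direction aberrant run covers >=
    ``coverage_fraction`` of the chromosome's segment-covered extent."""
    runs = _aberrant_runs(chrom_segments)
    _mark_whole_chromosome(runs, chrom_segments, coverage_fraction)
    return any(run.whole_chromosome for run in runs)


def segmental_flags(
    sample_segments: pd.DataFrame,
    arms: ArmTable,
    coverage_fraction: float = 0.95,
    min_length: int = MIN_SEGMENTAL_BP,
) -> ArmAberrationFlags:
    """Score one called sample against the 8 recurrent arm lesions.

    A flag is set iff a merged aberrant run longer than ``min_length``
    bp, not part of a whole-chromosome aberration and not purely an
    amplification, is assigned to that arm (longer-overlap rule) with
    matching direction. ``any_segmental`` applies the same criteria on
    every arm, not just the flagged eight.
    """
    if (sample_segments.annotation == "").any():
        raise CallingError("segments are uncalled; run calling first")
    runs = _aberrant_runs(sample_segments)
    _mark_whole_chromosome(runs, sample_segments, coverage_fraction)

    result = ArmAberrationFlags()
    segmental_runs = [
        r for r in runs if r.has_nonamp and not r.whole_chromosome and r.length > min_length
    ]
    result.any_segmental = bool(segmental_runs)
    for run in segmental_runs:
        arm = assign_arm(run.chrom, run.start, run.end, arms)
        for name, chrom, flag_arm, direction in FLAGGED_ARMS:
            if run.chrom == chrom and arm == flag_arm and run.direction == direction:
                result.flags[name] = True
    result.profile_class = _classify(runs)
    return result


def _classify(runs: list[_Run]) -> str:
    if not runs:
        return "silent"
    if all(run.whole_chromosome for run in runs):
        return "numerical_only"
    return "segmental"


def classify_profile(
    sample_segments: pd.DataFrame,
    arms: ArmTable,
    coverage_fraction: float = 0.95,
) -> str:
    """'silent' (no aberrant segment), 'numerical_only' (only whole-chromosome
    aberrations) or 'segmental'."""
    runs = _aberrant_runs(sample_segments)
    _mark_whole_chromosome(runs, sample_segments, coverage_fraction)
    return _classify(runs)


def flags_table(cohort_segments: pd.DataFrame, arms: ArmTable, **kwargs) -> pd.DataFrame:
    """Per-sample flag rows for a called multi-sample segment table."""
    rows = []
    for sample, segs in cohort_segments.groupby("sample_id", sort=False):
        flags = segmental_flags(segs, arms, **kwargs)
        rows.append({"sample_id": sample, **flags.as_dict()})
    return pd.DataFrame(rows)


def focal_aberrations(cohort_segments: pd.DataFrame, genes: GeneTable | None = None) -> pd.DataFrame:
    """Aberrant segments < 5 Mb overlapping a known gene.

    Focal events often pinpoint drivers (ALK, LIN28B, MYCN/ODC1
    amplicons); they are reported per (sample, gene) with the call label.
    """
    genes = genes or GeneTable.hg19()
    seg = cohort_segments[
        cohort_segments.annotation.ne("normal")
        & cohort_segments.annotation.ne("")
        & ((cohort_segments.end - cohort_segments.start) < FOCAL_MAX_BP)
    ]
    rows = []
    for gene, chrom, gstart, gend in genes:
        hits = seg[(seg.chrom.astype(str) == chrom) & (seg.start < gend) & (seg.end > gstart)]
        for h in hits.itertuples():
            rows.append(
                {
                    "sample_id": h.sample_id,
                    "gene": gene,
                    "chrom": chrom,
                    "start": int(h.start),
                    "end": int(h.end),
                    "annotation": h.annotation,
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "gene", "chrom", "start", "end", "annotation"])
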