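"""Platform-faithful synthetic neuroblastoma cohorts with known truth.

Each simulated sample follows one of four copy-number archetypes seen in
high-risk neuroblastoma:

* ``mna_type`` — focal MYCN amplification (< 1 Mb, at the platform's
  amplification dynamic-range center), distal 1p loss and 17q gain;
* ``11q_type`` — 11q loss, 3p loss and 17q gain;
* ``numerical_only`` — whole-chromosome gains/losses only;
* ``silent`` — a flat profile, as seen with normal-cell contamination.

Probe-level log2 ratios are the noiseless truth plus Gaussian probe
noise at the platform's sd. Platform families differ in dynamic range:
aCGH segmental events sit further from zero than SNP events, and
amplifications center at ~1 (Illumina), ~2 (Affymetrix/NimbleGen) or ~3
(Agilent), mirroring the compression of Illumina data. A few probes are
placed inside each catalogued driver gene, as targeted designs do, so
focal amplicons are always interrogated.

Survival times are exponential with archetype-specific hazard
multipliers and administrative censoring, enough to support log-rank
power checks. All numbers are reproducible from one master seed;
per-sample substreams make cohorts stable under subsetting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arms import FLAG_NAMES
from .calling import GAIN_CLASS, LOSS_CLASS, PlatformModel, call_segment, default_platform_model
from .errors import ValidationError
from .genome import ArmTable, GeneTable

ARCHETYPES = ("mna_type", "11q_type", "numerical_only", "silent")

#: truth aberrations per archetype: (chrom, start, end, kind)
_MNA_EVENTS = [
    ("2", 15_950_000, 16_850_000, "amplification"),
    ("1", 0, 25_000_000, "loss"),
    ("17", 30_000_000, 81_195_210, "gain"),
]
_11Q_EVENTS = [
    ("11", 60_000_000, 135_006_516, "loss"),
    ("3", 0, 45_000_000, "loss"),
    ("17", 30_000_000, 81_195_210, "gain"),
]
#: pool of whole-chromosome events for the numerical archetype
_NUMERICAL_POOL = [("7", "gain"), ("17", "gain"), ("6", "gain"), ("14", "loss"), ("4", "loss"), ("21", "loss")]

_TRUE_FLAGS = {
    "mna_type": {"1p_loss", "17q_gain"},
    "11q_type": {"11q_loss", "3p_loss", "17q_gain"},
    "numerical_only": set(),
    "silent": set(),
}
_TRUE_CLASS = {
    "mna_type": "segmental",
    "11q_type": "segmental",
    "numerical_only": "numerical_only",
    "silent": "silent",
}


@dataclass
class SimulationConfig:
    """Study-condition defaults for the synthetic cohort.

    ``n_samples`` totals 200 across the four families at defaults.
    Segmental-event log2 means are wider for aCGH (+0.45/-0.55) than for
    SNP arrays (+0.35/-0.45); probe noise and amplification centers come
    from the platform models.
    """

    n_samples: dict = field(
        default_factory=lambda: {
            "affymetrix_snp": 60,
            "illumina_snp": 50,
            "agilent_acgh": 60,
            "nimblegen_acgh": 30,
        }
    )
    archetype_weights: dict = field(
        default_factory=lambda: {"mna_type": 0.40, "11q_type": 0.35, "numerical_only": 0.15, "silent": 0.10}
    )
    probe_spacing: dict = field(
        default_factory=lambda: {
            "affymetrix_snp": 350_000,
            "illumina_snp": 400_000,
            "agilent_acgh": 450_000,
            "nimblegen_acgh": 500_000,
        }
    )
    gain_mean: dict = field(
        default_factory=lambda: {
            "affymetrix_snp": 0.35,
            "illumina_snp": 0.35,
            "agilent_acgh": 0.45,
            "nimblegen_acgh": 0.45,
        }
    )
    loss_mean: dict = field(
        default_factory=lambda: {
            "affymetrix_snp": -0.45,
            "illumina_snp": -0.45,
            "agilent_acgh": -0.55,
            "nimblegen_acgh": -0.55,
        }
    )
    hazard_multipliers: dict = field(
        default_factory=lambda: {"mna_type": 3.0, "11q_type": 2.0, "numerical_only": 0.7, "silent": 1.0}
    )
    baseline_hazard: float = 1.0 / 60.0  # events per month
    censor_time: float = 120.0  # months of administrative follow-up
    noise_scale: float = 1.0  # multiplies each platform's noise sd (0 -> noiseless)
    seed: int = 0

    def __post_init__(self):
        total = sum(self.archetype_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError("archetype weights must sum to 1")
        if set(self.archetype_weights) != set(ARCHETYPES):
            raise ValidationError(f"archetype weights must cover {ARCHETYPES}")


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated sample."""

    sample_id: str
    platform: str
    archetype: str
    aberrations: list  # (chrom, start, end, kind)
    flags: dict  # the 8 arm-flag booleans
    any_segmental: bool
    profile_class: str
    mycn_status: str
    os_time: float
    os_event: int
    efs_time: float
    efs_event: int


@dataclass
class SimulatedCohort:
    probes: pd.DataFrame
    truth_segments: pd.DataFrame  # noiseless truth, called
    annotations: pd.DataFrame
    truths: list


def _archetype_events(archetype: str, rng: np.random.Generator, arms: ArmTable) -> list:
    if archetype == "mna_type":
        return list(_MNA_EVENTS)
    if archetype == "11q_type":
        return list(_11Q_EVENTS)
    if archetype == "numerical_only":
        k = int(rng.integers(2, 5))
        idx = rng.choice(len(_NUMERICAL_POOL), size=k, replace=False)
        return [
            (chrom, 0, arms.chrom_length(chrom), kind)
            for chrom, kind in (_NUMERICAL_POOL[i] for i in sorted(idx))
        ]
    if archetype == "silent":
        return []
    raise ValidationError(f"unknown archetype {archetype!r}")


def _probe_positions(chrom: str, arms: ArmTable, spacing: int, genes: GeneTable) -> np.ndarray:
    length = arms.chrom_length(chrom)
    grid = np.arange(spacing // 2, length, spacing)
    targeted = []
    for _, gchrom, gstart, gend in genes:
        if gchrom == chrom:
            targeted.extend(np.linspace(gstart, gend, 5)[1:-1].astype(int))
    return np.unique(np.concatenate([grid, np.array(targeted, dtype=int)])) if targeted else grid


def _truth_values(positions: np.ndarray, chrom: str, events: list, config: SimulationConfig, family: str,
                  model: PlatformModel) -> np.ndarray:
    values = np.zeros(len(positions))
    level = {"gain": config.gain_mean[family], "loss": config.loss_mean[family], "amplification": model.amp_center}
    for echrom, start, end, kind in events:
        if echrom != chrom or kind == "amplification":
            continue
        values[(positions >= start) & (positions < end)] = level[kind]
    for echrom, start, end, kind in events:  # amplifications override underlying events
        if echrom == chrom and kind == "amplification":
            values[(positions >= start) & (positions < end)] = level[kind]
    return values


def simulate_profile(
    sample_id: str,
    archetype: str,
    model: PlatformModel,
    config: SimulationConfig,
    rng: np.random.Generator,
    arms: ArmTable | None = None,
    genes: GeneTable | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """One sample: probe rows, noiseless truth segments (called), and truth."""
    arms = arms or ArmTable.hg19()
    genes = genes or GeneTable.hg19()
    if archetype not in ARCHETYPES:
        raise ValidationError(f"unknown archetype {archetype!r}")
    family = model.family
    events = _archetype_events(archetype, rng, arms)
    probe_rows, seg_rows = [], []
    sd = model.noise_sd * config.noise_scale
    for chrom in arms.chromosomes:
        positions = _probe_positions(chrom, arms, config.probe_spacing[family], genes)
        truth = _truth_values(positions, chrom, events, config, family, model)
        observed = truth + rng.normal(0.0, sd, size=len(positions)) if sd > 0 else truth.copy()
        probe_rows.append(
            pd.DataFrame(
                {"sample_id": sample_id, "chrom": chrom, "position": positions, "log2_ratio": observed}
            )
        )
        # noiseless truth segments: runs of constant truth value
        boundaries = np.flatnonzero(np.diff(truth) != 0) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [len(truth)]])
        for i, j in zip(starts, ends):
            value = float(truth[i])
            seg_rows.append(
                {
                    "sample_id": sample_id,
                    "chrom": chrom,
                    "start": int(positions[i]),
                    "end": int(positions[j - 1]) + 1,
                    "n_probes": int(j - i),
                    "log2_ratio": value,
                    "annotation": call_segment(value, model),
                }
            )
    multiplier = config.hazard_multipliers[archetype]
    os_time = float(rng.exponential(1.0 / (config.baseline_hazard * multiplier)))
    os_event = 1
    if os_time > config.censor_time:
        os_time, os_event = config.censor_time, 0
    efs_time = float(rng.exponential(1.0 / (config.baseline_hazard * multiplier * 1.4)))
    efs_event = 1
    if efs_time > config.censor_time:
        efs_time, efs_event = config.censor_time, 0
    truth = SyntheticTruth(
        sample_id=sample_id,
        platform=family,
        archetype=archetype,
        aberrations=events,
        flags={name: name in _TRUE_FLAGS[archetype] for name in FLAG_NAMES},
        any_segmental=bool(_TRUE_FLAGS[archetype]),
        profile_class=_TRUE_CLASS[archetype],
        mycn_status="amplified" if archetype == "mna_type" else "nonamplified",
        os_time=os_time,
        os_event=os_event,
        efs_time=efs_time,
        efs_event=efs_event,
    )
    return pd.concat(probe_rows, ignore_index=True), pd.DataFrame(seg_rows), truth


def simulate_cohort(config: SimulationConfig | None = None) -> SimulatedCohort:
    """Simulate all four platforms; annotations carry MYCN truth and survival.

    Event-free survival is withheld for the NimbleGen samples, emulating
    a contributing dataset without EFS follow-up.
    """
    config = config or SimulationConfig()
    arms = ArmTable.hg19()
    genes = GeneTable.hg19()
    master = np.random.SeedSequence(config.seed)
    n_total = sum(config.n_samples.values())
    streams = master.spawn(n_total)
    archetype_names = list(config.archetype_weights)
    weights = np.array([config.archetype_weights[a] for a in archetype_names])

    probes, truth_segs, ann_rows, truths = [], [], [], []
    idx = 0
    for family in sorted(config.n_samples):
        model = default_platform_model(family)
        for i in range(config.n_samples[family]):
            rng = np.random.default_rng(streams[idx])
            idx += 1
            sample_id = f"{family.split('_')[0][:4]}_{i:03d}"
            archetype = archetype_names[int(rng.choice(len(archetype_names), p=weights))]
            probe_df, seg_df, truth = simulate_profile(sample_id, archetype, model, config, rng, arms, genes)
            probes.append(probe_df)
            truth_segs.append(seg_df)
            truths.append(truth)
            efs_missing = family == "nimblegen_acgh"
            ann_rows.append(
                {
                    "sample_id": sample_id,
                    "platform": family,
                    "lab": f"lab_{family.split('_')[0]}",
                    "mycn_status": truth.mycn_status,
                    "stage": "4",
                    "age_group": ["<18m", "18m-5y", ">5y"][int(rng.choice(3, p=[0.25, 0.5, 0.25]))],
                    "os_time": truth.os_time,
                    "os_event": truth.os_event,
                    "efs_time": np.nan if efs_missing else truth.efs_time,
                    "efs_event": np.nan if efs_missing else truth.efs_event,
                }
            )
    return SimulatedCohort(
        probes=pd.concat(probes, ignore_index=True),
        truth_segments=pd.concat(truth_segs, ignore_index=True),
        annotations=pd.DataFrame(ann_rows),
        truths=truths,
    )


def recovery_rate(truths: list, called_segments: pd.DataFrame, min_length: int = 3_000_000) -> float:
    """Fraction of true gain/loss aberrations > ``min_length`` recovered.

    An aberration counts as recovered when called segments of the
    matching direction class cover at least half of its extent.
    """
    n_total = n_hit = 0
    by_sample = dict(tuple(called_segments.groupby("sample_id", sort=False)))
    for truth in truths:
        segs = by_sample.get(truth.sample_id)
        for chrom, start, end, kind in truth.aberrations:
            if kind == "amplification" or (end - start) <= min_length:
                continue
            n_total += 1
            if segs is None:
                continue
            cls = GAIN_CLASS if kind == "gain" else LOSS_CLASS
            sub = segs[
                (segs.chrom.astype(str) == chrom)
                & segs.annotation.isin(cls)
                & (segs.start < end)
                & (segs.end > start)
            ]
            covered = (np.minimum(sub.end, end) - np.maximum(sub.start, start)).sum()
            if covered >= 0.5 * (end - start):
                n_hit += 1
    if n_total == 0:
        raise ValidationError("no qualifying truth aberrations")
    return n_hit / n_total
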