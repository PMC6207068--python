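"""hg19 chromosome and arm geometry.

The genome model covers chromosomes 1-22 and X. Y is absent by design:
profiles were generated partly without gender-matched references, so Y
values are uninterpretable and are dropped upstream (see
:func:`armcall.preprocess.drop_chrY`).

Arm boundaries derive from the UCSC hg19 cytoBand acen bands: the p arm is
``[0, cen_start)``, the q arm ``[cen_end, chrom_length)``, and
``[cen_start, cen_end)`` is the centromeric gap that belongs to neither
arm. All coordinates are 0-based half-open internally.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .errors import UnknownChromosomeError, ValidationError

CHROMOSOMES = [str(c) for c in range(1, 23)] + ["X"]

#: The eight recurrent segmental lesions scored per sample:
#: (flag name, chromosome, arm, direction)
FLAGGED_ARMS = [
    ("1p_loss", "1", "p", "loss"),
    ("3p_loss", "3", "p", "loss"),
    ("4p_loss", "4", "p", "loss"),
    ("11q_loss", "11", "q", "loss"),
    ("14q_loss", "14", "q", "loss"),
    ("1q_gain", "1", "q", "gain"),
    ("2p_gain", "2", "p", "gain"),
    ("17q_gain", "17", "q", "gain"),
]


class ArmTable:
    """Chromosome lengths and centromere intervals for hg19.

    Parameters
    ----------
    table
        DataFrame with columns ``chrom``, ``length``, ``cen_start``,
        ``cen_end``, one row per chromosome, indexed by ``chrom``.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"chrom", "length", "cen_start", "cen_end"}
        if not required.issubset(table.columns):
            raise ValidationError(f"arm table missing columns: {sorted(required - set(table.columns))}")
        tbl = table.set_index("chrom", drop=False)
        bad = tbl[~((0 < tbl.cen_start) & (tbl.cen_start <= tbl.cen_end) & (tbl.cen_end < tbl.length))]
        if len(bad):
            raise ValidationError(f"invalid centromere geometry for chromosomes {list(bad.chrom)}")
        if "Y" in tbl.index:
            raise ValidationError("chromosome Y is not part of the genome model")
        self._table = tbl

    @classmethod
    def hg19(cls) -> "ArmTable":
        """The built-in hg19 arm table."""
        with resources.files("armcall").joinpath("data/arms_hg19.tsv").open() as fh:
            return cls(pd.read_csv(fh, sep="\t", dtype={"chrom": str}))

    @property
    def chromosomes(self) -> list[str]:
        return list(self._table.chrom)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._table.index

    def _row(self, chrom: str) -> pd.Series:
        try:
            return self._table.loc[str(chrom)]
        except KeyError:
            raise UnknownChromosomeError(f"chromosome {chrom!r} not in the arm table") from None

    def chrom_length(self, chrom: str) -> int:
        return int(self._row(chrom).length)

    def centromere(self, chrom: str) -> tuple[int, int]:
        row = self._row(chrom)
        return int(row.cen_start), int(row.cen_end)

    def as_frame(self) -> pd.DataFrame:
        return self._table.reset_index(drop=True).copy()


class GeneTable:
    """hg19 intervals for neuroblastoma-relevant genes (MYCN, ALK, ...)."""

    def __init__(self, table: pd.DataFrame):
        required = {"gene", "chrom", "start", "end"}
        if not required.issubset(table.columns):
            raise ValidationError(f"gene table missing columns: {sorted(required - set(table.columns))}")
        if (table.start >= table.end).any():
            raise ValidationError("gene intervals must have start < end")
        self._table = table.set_index("gene", drop=False)

    @classmethod
    def hg19(cls) -> "GeneTable":
        with resources.files("armcall").joinpath("data/genes_hg19.tsv").open() as fh:
            return cls(pd.read_csv(fh, sep="\t", dtype={"chrom": str}))

    def interval(self, gene: str) -> tuple[str, int, int]:
        try:
            row = self._table.loc[gene]
        except KeyError:
            raise ValidationError(f"gene {gene!r} not in gene table") from None
        return str(row.chrom), int(row.start), int(row.end)

    def as_frame(self) -> pd.DataFrame:
        return self._table.reset_index(drop=True).copy()

    def __iter__(self):
        for row in self._table.itertuples(index=False):
            yield row.gene, str(row.chrom), int(row.start), int(row.end)


def arm_overlap(chrom: str, start: int, end: int, arms: ArmTable) -> tuple[int, int]:
    """Base-pair overlap of ``[start, end)`` with the p and q arms of ``chrom``.

    Returns ``(p_length, q_length)``; the part falling into the centromeric
    gap contributes to neither, so the sum may be smaller than the interval.
    """
    if end <= start:
        raise ValidationError(f"empty interval {chrom}:{start}-{end}")
    cen_start, cen_end = arms.centromere(chrom)
    length = arms.chrom_length(chrom)
    p = max(0, min(end, cen_start) - max(start, 0))
    q = max(0, min(end, length) - max(start, cen_end))
    return p, q


def assign_arm(chrom: str, start: int, end: int, arms: ArmTable) -> str:
    """Assign an interval to the arm carrying the larger part of it.

    Centromere-spanning aberrations go to p only when the p part is
    strictly longer; ties and q-majorities go to q.
    """
    p, q = arm_overlap(chrom, start, end, arms)
    if p == 0 and q == 0:
        raise ValidationError(f"interval {chrom}:{start}-{end} lies entirely within the centromeric gap")
    return "p" if p > q else "q"
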