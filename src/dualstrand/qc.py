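"""Sample quality control: ΔQc triage and depth-cutoff determination.

ΔQc is the qPCR cycle difference between a sample and an undamaged control
DNA; each extra cycle means the sample has half the amplifiable template.
Samples above the triage threshold (conventionally 4) are flagged as
degraded but still processed — interpretability is decided after
sequencing, from the median per-amplicon read depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

STANDARD = "STANDARD"
DEGRADED_ATTEMPT = "DEGRADED_ATTEMPT"

DEFAULT_TRIAGE_THRESHOLD = 4.0
DEFAULT_MAX_INPUT_SCALING = 16.0


@dataclass
class QCRecord:
    """Per-sample quality record accumulated through the workflow."""

    sample_id: str
    cq_sample: float = math.nan
    cq_control: float = math.nan
    delta_qc: float = math.nan
    triage: str = STANDARD
    input_scaling: float = 1.0
    median_depth_lib1: float | None = None
    median_depth_lib2: float | None = None
    interpretable: bool | None = None


@dataclass(frozen=True)
class DilutionPoint:
    """One point of a serial-dilution experiment."""

    concentration: float  # nM
    median_depth: float
    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def concordant(self) -> bool:
        return self.fp == 0 and self.fn == 0


def delta_qc(cq_sample: float, cq_control: float) -> float:
    """ΔQc = Cq(sample) - Cq(control); infinity propagates."""
    return cq_sample - cq_control


def triage(
    dqc: float,
    threshold: float = DEFAULT_TRIAGE_THRESHOLD,
    max_scaling: float = DEFAULT_MAX_INPUT_SCALING,
) -> tuple[str, float]:
    """Classify a sample by ΔQc and derive the input-scaling factor.

    ΔQc <= threshold (boundary inclusive) is STANDARD with scaling 1.
    Above it the sample is a DEGRADED_ATTEMPT — still sequenced — with its
    DNA input scaled by 2**(ΔQc - threshold), capped at ``max_scaling``;
    this stands in for the fold-dilution lookup of the library-prep kit.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if dqc <= threshold:
        return STANDARD, 1.0
    if math.isinf(dqc):
        return DEGRADED_ATTEMPT, max_scaling
    return DEGRADED_ATTEMPT, min(2.0 ** (dqc - threshold), max_scaling)


def determine_depth_cutoff(series: list[DilutionPoint]) -> float:
    """Smallest median depth of the maximal fully concordant dilution prefix.

    The series must be sorted by concentration descending; the cutoff is
    the lowest realized median depth among the leading points that have
    neither false positives nor false negatives against the control truth
    set.  Raises if even the most concentrated point is discordant.
    """
    if not series:
        raise ValueError("empty dilution series")
    if list(series) != sorted(series, key=lambda p: -p.concentration):
        raise ValueError("series must be sorted by concentration descending")
    concordant: list[DilutionPoint] = []
    for point in series:
        if not point.concordant:
            break
        concordant.append(point)
    if not concordant:
        raise ValueError(
            "no concordant dilution point; sequence deeper before setting a cutoff"
        )
    return min(p.median_depth for p in concordant)


# ---------------------------------------------------------------------------
# QC table input/output

_COLUMNS = [
    "sample_id",
    "cq_sample",
    "cq_control",
    "delta_qc",
    "triage",
    "median_depth_lib1",
    "median_depth_lib2",
    "interpretable",
]


def write_qc_tsv(records: list[QCRecord], path, meta: dict | None = None) -> None:
    with Path(path).open("w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        fh.write("\t".join(_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.sample_id}\t{r.cq_sample:.4f}\t{r.cq_control:.4f}\t{r.delta_qc:.4f}\t"
                f"{r.triage}\t{r.median_depth_lib1}\t{r.median_depth_lib2}\t{r.interpretable}\n"
            )


def read_qc_tsv(path) -> list[QCRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    records = []
    for row in df.itertuples():
        records.append(
            QCRecord(
                sample_id=str(row.sample_id),
                cq_sample=float(row.cq_sample),
                cq_control=float(row.cq_control),
                delta_qc=float(row.delta_qc),
                triage=str(row.triage),
                median_depth_lib1=None if pd.isna(row.median_depth_lib1) else float(row.median_depth_lib1),
                median_depth_lib2=None if pd.isna(row.median_depth_lib2) else float(row.median_depth_lib2),
                interpretable=None if pd.isna(row.interpretable) else bool(row.interpretable),
            )
        )
    return records
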