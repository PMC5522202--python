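"""Assay validation statistics.

Performance is assessed per interrogated nucleotide: every truth-variant
anchor position that is called is a true positive, every other interrogated
position that stays uncalled is a true negative.  Diagnostic metrics carry
Wilson score 95% confidence intervals (the score interval remains
informative at proportions of exactly 0 or 1, where a normal-approximation
interval collapses).  VAF concordance between expected and observed allele
fractions uses the Pearson correlation, with per-variant replicate
mean/SD/CV% summaries.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .panel import GenomicInterval


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (report convention; Python's round is banker's)."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Per-base confusion


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


def per_base_confusion(calls, truth, interrogated: list[GenomicInterval]) -> ConfusionCounts:
    """Confusion counts over a set of interrogated nucleotide positions.

    ``calls`` are PASS consensus calls, ``truth`` the spiked variants; both
    are counted at their (left-normalized) anchor position.  Every truth
    position must be interrogated, and every call must land inside the
    interrogated region (anything else indicates a region mismatch and is
    an error, not a false positive).
    """
    region = {(iv.contig, p) for iv in interrogated for p in range(iv.start, iv.end)}
    truth_pos = {(v.contig, v.pos) for v in truth}
    call_pos = {(c.contig, c.pos) for c in calls}
    missing = truth_pos - region
    if missing:
        raise ValueError(f"truth positions outside interrogated region: {sorted(missing)[:3]}")
    outside = call_pos - region
    if outside:
        raise ValueError(f"calls outside interrogated region: {sorted(outside)[:3]}")
    tp = len(truth_pos & call_pos)
    fn = len(truth_pos - call_pos)
    fp = len(call_pos - truth_pos)
    tn = len(region) - tp - fn - fp
    counts = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
    assert counts.total == len(region)  # conservation invariant
    return counts


# ---------------------------------------------------------------------------
# Diagnostic metrics with Wilson confidence intervals


@dataclass(frozen=True)
class MetricWithCI:
    value_pct: float | None
    ci_low_pct: float | None
    ci_high_pct: float | None
    defined: bool = True


@dataclass(frozen=True)
class PerformanceReport:
    sensitivity: MetricWithCI
    specificity: MetricWithCI
    accuracy: MetricWithCI
    precision: MetricWithCI
    confusion: ConfusionCounts
    confidence: float = 0.95


def wilson_interval(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for k successes out of n (fractions in [0, 1])."""
    if n <= 0:
        raise ValueError("n must be positive")
    low, high = proportion_confint(k, n, alpha=1 - confidence, method="wilson")
    return float(low), float(high)


def _metric(k: int, n: int, confidence: float) -> MetricWithCI:
    if n == 0:
        return MetricWithCI(None, None, None, defined=False)
    low, high = wilson_interval(k, n, confidence)
    return MetricWithCI(100.0 * k / n, 100.0 * low, 100.0 * high)


def metrics_with_ci(confusion: ConfusionCounts, confidence: float = 0.95) -> PerformanceReport:
    """Sensitivity, specificity, accuracy and precision with Wilson CIs.

    A metric whose denominator is zero is reported as undefined rather
    than silently evaluating 0/0.
    """
    c = confusion
    return PerformanceReport(
        sensitivity=_metric(c.tp, c.tp + c.fn, confidence),
        specificity=_metric(c.tn, c.tn + c.fp, confidence),
        accuracy=_metric(c.tp + c.tn, c.total, confidence),
        precision=_metric(c.tp, c.tp + c.fp, confidence),
        confusion=c,
        confidence=confidence,
    )


# ---------------------------------------------------------------------------
# VAF concordance


@dataclass(frozen=True)
class ConcordanceStats:
    pearson_r: float | None
    r_squared: float | None
    p_value: float | None
    per_variant_mean: tuple
    per_variant_sd: tuple
    per_variant_cv_pct: tuple
    defined: bool = True


def vaf_concordance(expected, observed) -> ConcordanceStats:
    """Pearson concordance between expected VAFs and replicate means.

    ``observed`` is an (n_variants, n_replicates) array of estimated VAFs.
    Per-variant SD uses the n-1 denominator; CV% = 100*SD/mean.  With a
    single replicate the SD/CV are reported as 0.  Zero variance in either
    correlated vector makes the correlation undefined (flagged, not NaN).
    """
    expected = np.asarray(expected, dtype=float)
    observed = np.atleast_2d(np.asarray(observed, dtype=float))
    if observed.shape[0] != expected.shape[0]:
        raise ValueError("observed matrix must have one row per variant")
    if expected.shape[0] < 3:
        raise ValueError("need at least 3 variants for a correlation")
    means = observed.mean(axis=1)
    if observed.shape[1] > 1:
        sds = observed.std(axis=1, ddof=1)
    else:
        sds = np.zeros_like(means)
    with np.errstate(divide="ignore", invalid="ignore"):
        cvs = np.where(means != 0, 100.0 * sds / np.abs(means), np.nan)
    if np.ptp(expected) == 0 or np.ptp(means) == 0:
        return ConcordanceStats(
            None, None, None, tuple(means), tuple(sds), tuple(cvs), defined=False
        )
    r, p = stats.pearsonr(expected, means)
    return ConcordanceStats(
        pearson_r=float(r),
        r_squared=float(r) ** 2,
        p_value=float(p),
        per_variant_mean=tuple(means),
        per_variant_sd=tuple(sds),
        per_variant_cv_pct=tuple(cvs),
    )


# ---------------------------------------------------------------------------
# Cohort summary


@dataclass
class CohortSummary:
    """Cohort-level rates; percentages use round-half-up at one decimal.

    Two candidate diagnosis-rate denominators are reported because cohort
    conventions differ on whether non-interpretable samples count: the
    fraction of *interpretable* samples with at least one PASS variant, and
    the same count over *all* samples.
    """

    n_samples: int
    n_interpretable: int
    analyzability_pct: float | None
    n_degraded: int
    n_degraded_interpretable: int
    degraded_rescue_pct: float | None
    n_mutated: int
    diagnosis_rate_interpretable_pct: float | None
    diagnosis_rate_all_pct: float | None
    n_routine_mutated: int
    routine_rate_interpretable_pct: float | None
    mutation_counts: dict = field(default_factory=dict)  # {"snv": n, "mnv": n, "indel": n}
    raw: dict = field(default_factory=dict)


def _pct(num: int, den: int) -> float | None:
    return None if den == 0 else round_half_up(100.0 * num / den, 1)


def cohort_summary(
    qc_records,
    call_sets: dict,
    routine_flags: dict | None = None,
    triage_threshold: float = 4.0,
) -> CohortSummary:
    """Summarize a cohort of QC records and per-sample PASS call sets.

    ``call_sets`` maps sample_id to that sample's PASS consensus variants;
    ``routine_flags`` optionally marks samples mutated by the routine
    comparator techniques.
    """
    routine_flags = routine_flags or {}
    n = len(qc_records)
    interp = [r for r in qc_records if r.interpretable]
    degraded = [r for r in qc_records if r.delta_qc > triage_threshold]
    degraded_ok = [r for r in degraded if r.interpretable]
    mutated = [r for r in interp if len(call_sets.get(r.sample_id, [])) > 0]
    routine_mutated = [r for r in interp if routine_flags.get(r.sample_id)]

    counts = {"snv": 0, "mnv": 0, "indel": 0}
    for r in interp:
        for call in call_sets.get(r.sample_id, []):
            kind = call.kind
            counts["indel" if kind in ("ins", "del", "complex") else kind] += 1

    return CohortSummary(
        n_samples=n,
        n_interpretable=len(interp),
        analyzability_pct=_pct(len(interp), n),
        n_degraded=len(degraded),
        n_degraded_interpretable=len(degraded_ok),
        degraded_rescue_pct=_pct(len(degraded_ok), len(degraded)),
        n_mutated=len(mutated),
        diagnosis_rate_interpretable_pct=_pct(len(mutated), len(interp)),
        diagnosis_rate_all_pct=_pct(len(mutated), n),
        n_routine_mutated=len(routine_mutated),
        routine_rate_interpretable_pct=_pct(len(routine_mutated), len(interp)),
        mutation_counts=counts,
        raw={
            "interpretable": len(interp),
            "total": n,
            "degraded": len(degraded),
            "degraded_interpretable": len(degraded_ok),
            "mutated": len(mutated),
        },
    )
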