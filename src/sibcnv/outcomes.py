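"""Phenotype labeling and diagnostic predictive statistics.

Implements the outcome classification used for prospectively phenotyped
infant siblings (BSRC-style clinician best-estimate plus psychometric
thresholds, and the SSC-style three-instrument screen for atypical
development), 2x2 contingency construction for CNV carrier status versus
outcome, and sensitivity / specificity / PPV / NPV with exact binomial
(Clopper-Pearson) confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping

from scipy import stats

ASD = "ASD"
ATYPICAL = "atypical"
TYPICAL = "typical"
LABELS = (ASD, ATYPICAL, TYPICAL)

CONDITION_ASD = "ASD"
CONDITION_ASD_OR_ATYPICAL = "ASD_or_atypical"


class OutcomeError(ValueError):
    pass


@dataclass(frozen=True)
class PsychometricRecord:
    """Per-individual instrument scores; fields are optional per cohort mode.

    MSEL and VABS composites are standard scores (mean 100, SD 15); SRS and
    CBCL totals are T-scores (mean 50, SD 10, atypical above 60); ADOS CSS
    is the 1-10 calibrated severity score.
    """

    individual_id: str
    ados_css: int | None = None
    msel_elc: float | None = None
    msel_receptive_language: float | None = None
    msel_expressive_language: float | None = None
    vabs_abc: float | None = None
    vabs_subscale_min: float | None = None
    srs_t: float | None = None
    cbcl_t: float | None = None
    clinician_asd_flag: bool | None = None
    clinician_atypical_flag: bool | None = None
    adir_positive: bool | None = None


@dataclass(frozen=True)
class OutcomeLabel:
    label: str
    criteria_met: tuple[str, ...]


def assign_outcome_label(rec: PsychometricRecord, mode: str = "BSRC") -> OutcomeLabel:
    """Classify an infant sibling as ASD / atypical / typical.

    BSRC mode follows the clinician best-estimate design: ASD iff the
    clinician flag is set (ADOS CSS >= 4 is the supporting threshold);
    otherwise the child is atypical if ANY subthreshold criterion is met:
    elevated ASD symptoms (CSS >= 3 with ADI-R/clinical support),
    developmental delay (MSEL ELC < 85), language delay (either MSEL
    language subscale < 85), adaptive deficits (VABS composite or lowest
    subscale < 85), or a clinician-noted atypical behavior pattern.

    SSC mode applies the three-instrument screen to non-ASD siblings:
    atypical iff SRS T > 60 OR CBCL T > 60 OR VABS ABC < 85 (strict
    comparisons; a sibling must meet the cutoff on at least one test).
    """
    if mode not in ("BSRC", "SSC"):
        raise OutcomeError(f"unknown cohort mode {mode!r}")

    criteria: list[str] = []
    if mode == "BSRC":
        if rec.clinician_asd_flag is None:
            raise OutcomeError(f"{rec.individual_id}: BSRC mode requires clinician_asd_flag")
        if rec.clinician_asd_flag:
            crit = ["clinician_best_estimate_asd"]
            if rec.ados_css is not None and rec.ados_css >= 4:
                crit.append("ados_css>=4")
            return OutcomeLabel(ASD, tuple(crit))
        if (
            rec.ados_css is not None
            and rec.ados_css >= 3
            and (rec.adir_positive or rec.clinician_atypical_flag)
        ):
            criteria.append("elevated_asd_symptoms")
        if rec.msel_elc is not None and rec.msel_elc < 85:
            criteria.append("developmental_delay")
        for name, score in (
            ("receptive", rec.msel_receptive_language),
            ("expressive", rec.msel_expressive_language),
        ):
            if score is not None and score < 85:
                criteria.append(f"language_delay_{name}")
        if (rec.vabs_abc is not None and rec.vabs_abc < 85) or (
            rec.vabs_subscale_min is not None and rec.vabs_subscale_min < 85
        ):
            criteria.append("adaptive_behavior_deficit")
        if rec.clinician_atypical_flag:
            criteria.append("clinician_atypical_pattern")
    else:  # SSC
        if rec.clinician_asd_flag:
            return OutcomeLabel(ASD, ("clinician_best_estimate_asd",))
        available = [s for s in (rec.srs_t, rec.cbcl_t, rec.vabs_abc) if s is not None]
        if not available:
            raise OutcomeError(
                f"{rec.individual_id}: SSC mode requires at least one of srs_t, cbcl_t, vabs_abc"
            )
        if rec.srs_t is not None and rec.srs_t > 60:
            criteria.append("srs_t>60")
        if rec.cbcl_t is not None and rec.cbcl_t > 60:
            criteria.append("cbcl_t>60")
        if rec.vabs_abc is not None and rec.vabs_abc < 85:
            criteria.append("vabs_abc<85")

    if criteria:
        return OutcomeLabel(ATYPICAL, tuple(criteria))
    return OutcomeLabel(TYPICAL, ())


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 carrier-by-condition counts (tp = CNV+/condition+)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise OutcomeError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def build_contingency(
    carrier: Mapping[str, bool],
    labels: Mapping[str, str],
    condition: str = CONDITION_ASD,
) -> ContingencyTable:
    """Cross-tabulate carrier status against the chosen condition.

    ``condition`` is ``ASD`` (affected only) or ``ASD_or_atypical``
    (affected plus atypically developing).
    """
    if condition == CONDITION_ASD:
        positive = {ASD}
    elif condition == CONDITION_ASD_OR_ATYPICAL:
        positive = {ASD, ATYPICAL}
    else:
        raise OutcomeError(f"unknown condition {condition!r}")
    missing = set(carrier) - set(labels)
    if missing:
        raise OutcomeError(f"unlabeled individuals: {sorted(missing)[:5]}")
    tp = fp = fn = tn = 0
    for ind, is_carrier in carrier.items():
        cond = labels[ind] in positive
        if is_carrier and cond:
            tp += 1
        elif is_carrier:
            fp += 1
        elif cond:
            fn += 1
        else:
            tn += 1
    return ContingencyTable(tp, fp, fn, tn)


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval via beta-distribution quantiles."""
    if n < 1:
        raise OutcomeError("n must be >= 1")
    if not 0 <= k <= n:
        raise OutcomeError(f"k must be in [0, n]; got k={k}, n={n}")
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


@dataclass(frozen=True)
class Estimate:
    """A proportion with its exact CI, tracking the defining fraction."""

    point: float
    lo: float
    hi: float
    k: int
    n: int


@dataclass(frozen=True)
class DiagnosticStats:
    sensitivity: Estimate | None
    specificity: Estimate | None
    ppv: Estimate | None
    npv: Estimate | None
    ci_level: float
    table: ContingencyTable


def _estimate(k: int, n: int, level: float) -> Estimate | None:
    if n == 0:
        return None  # undefined measure, reported as such
    lo, hi = clopper_pearson(k, n, level)
    return Estimate(k / n, lo, hi, k, n)


def diagnostic_stats(t: ContingencyTable, level: float = 0.95) -> DiagnosticStats:
    """Sensitivity, specificity, PPV and NPV with exact 95% CIs.

    A measure with a zero denominator is reported as ``None`` (undefined),
    never as 0.
    """
    return DiagnosticStats(
        sensitivity=_estimate(t.tp, t.tp + t.fn, level),
        specificity=_estimate(t.tn, t.tn + t.fp, level),
        ppv=_estimate(t.tp, t.tp + t.fp, level),
        npv=_estimate(t.tn, t.tn + t.fn, level),
        ci_level=level,
        table=t,
    )


def round2(x: float) -> float:
    """Round-half-up to 2 decimal places, for report-style comparison."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
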