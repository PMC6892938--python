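"""Polygenic transmission disequilibrium test (pTDT) and power analysis.

The pTDT asks whether affected children carry systematically more
polygenic risk than expected from their parents: for each complete trio
the deviation is the child's polygenic risk score (PRS) minus the
midparent mean, standardized by the SD of the midparent distribution, and
a one-sample t-test checks whether the group mean deviation differs from
zero. Because the expectation is conditioned on the parents, the test is
robust to population stratification.

Power is estimated by Monte-Carlo simulation under the liability
threshold model: standardized parental scores are independent N(0, 1),
the child score is midparent plus Mendelian segregation noise N(0, 1/2),
liability is sqrt(r2) * PRS + N(0, 1 - r2), and a child is affected when
liability exceeds the (1 - K) quantile of the standard normal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

CHILD_GROUPS = ("proband", "affected_sibling", "atypical_sibling", "unaffected_sibling")


class PtdtError(ValueError):
    pass


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if seed is None:
        raise PtdtError("an explicit seed (or Generator) is required for reproducibility")
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class TrioPrs:
    """Child + both-parent polygenic scores on a common scale."""

    family_id: str
    child_id: str
    child_group: str
    prs_child: float
    prs_mother: float
    prs_father: float

    def __post_init__(self) -> None:
        if self.child_group not in CHILD_GROUPS:
            raise PtdtError(f"unknown child group {self.child_group!r}")
        for v in (self.prs_child, self.prs_mother, self.prs_father):
            if not math.isfinite(v):
                raise PtdtError("trio scores must be finite (complete trios only)")


@dataclass(frozen=True)
class PtdtResult:
    group: str
    n: int
    mean_deviation: float
    t_stat: float
    p_value: float


@dataclass(frozen=True)
class LiabilityModelParams:
    """Liability threshold model parameters.

    prevalence_K: population prevalence of the affected state;
    h2g: narrow-sense (SNP) heritability of liability;
    r2_prs: fraction of liability variance explained by the PRS;
    alpha: two-sided test size used for power.
    """

    prevalence_K: float = 0.015
    h2g: float = 0.60
    r2_prs: float = 0.0245
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("prevalence_K", "h2g", "r2_prs", "alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise PtdtError(f"{name} must be in (0, 1), got {v}")
        if self.r2_prs > self.h2g:
            raise PtdtError("r2_prs cannot exceed h2g")

    @property
    def liability_threshold(self) -> float:
        return float(stats.norm.ppf(1.0 - self.prevalence_K))


@dataclass(frozen=True)
class PrsWeights:
    """Per-variant additive effect weights with a GWAS p-value cut."""

    weights: Mapping[str, float]  # variant_id -> weight (effect-allele scale)
    gwas_p: Mapping[str, float] = field(default_factory=dict)
    p_threshold: float = 0.1

    def included(self) -> set[str]:
        return {
            v for v, w in self.weights.items()
            if math.isfinite(w) and self.gwas_p.get(v, 0.0) <= self.p_threshold
        }


@dataclass(frozen=True)
class PrsScore:
    score: float
    n_variants: int
    n_skipped: int


def compute_prs(dosages: Mapping[str, float], weights: PrsWeights) -> PrsScore:
    """Additive PRS: sum of weight x effect-allele dosage over included variants.

    Variants with a missing dosage are skipped and counted; it is an error
    if no included variant has a dosage at all.
    """
    included = weights.included()
    score = 0.0
    used = skipped = 0
    for variant in included:
        dose = dosages.get(variant)
        if dose is None or not math.isfinite(dose):
            skipped += 1
            continue
        if not 0.0 <= dose <= 2.0:
            raise PtdtError(f"dosage out of [0, 2] for {variant}: {dose}")
        score += weights.weights[variant] * dose
        used += 1
    if used == 0:
        raise PtdtError("no overlap between dosages and included weight variants")
    return PrsScore(score, used, skipped)


def ptdt_deviations(trios: Sequence[TrioPrs]) -> np.ndarray:
    """Standardized transmission deviations for one analysis group.

    deviation_i = (child_i - midparent_i) / SD(midparent over the group),
    with the sample SD (ddof=1). The group's trios define the
    standardization; a degenerate group (zero midparent SD) is an error.
    """
    if len(trios) < 2:
        raise PtdtError("need >= 2 trios")
    child = np.array([t.prs_child for t in trios], dtype=float)
    mid = np.array([(t.prs_mother + t.prs_father) / 2.0 for t in trios], dtype=float)
    sd = mid.std(ddof=1)
    if sd == 0:
        raise PtdtError("midparent SD is zero (degenerate cohort)")
    return (child - mid) / sd


def ptdt_test(deviations: Iterable[float], group: str = "") -> PtdtResult:
    """Two-sided one-sample t-test of mean transmission deviation = 0."""
    dev = np.asarray(list(deviations), dtype=float)
    if dev.size < 2:
        raise PtdtError("need >= 2 deviations")
    if dev.std(ddof=1) == 0:
        raise PtdtError("zero variance in deviations")
    res = stats.ttest_1samp(dev, 0.0)
    return PtdtResult(
        group=group,
        n=int(dev.size),
        mean_deviation=float(dev.mean()),
        t_stat=float(res.statistic),
        p_value=float(res.pvalue),
    )


def _simulate_children(
    rng: np.random.Generator, params: LiabilityModelParams, n: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized draw of n independent trios; returns (mother, father, child, affected)."""
    mother = rng.standard_normal(n)
    father = rng.standard_normal(n)
    child = (mother + father) / 2.0 + rng.normal(0.0, math.sqrt(0.5), n)
    residual_sd = math.sqrt(1.0 - params.r2_prs)
    liability = math.sqrt(params.r2_prs) * child + rng.normal(0.0, residual_sd, n)
    affected = liability > params.liability_threshold
    return mother, father, child, affected


def simulate_liability_cohort(
    params: LiabilityModelParams,
    n_families: int,
    seed: int | np.random.Generator,
) -> tuple[list[TrioPrs], list[bool]]:
    """Simulate unascertained trios with affection status under the model."""
    if n_families < 1:
        raise PtdtError("n_families must be >= 1")
    rng = _rng(seed)
    mother, father, child, affected = _simulate_children(rng, params, n_families)
    trios = [
        TrioPrs(f"F{i}", f"F{i}-C", "proband", float(child[i]), float(mother[i]), float(father[i]))
        for i in range(n_families)
    ]
    return trios, [bool(a) for a in affected]


def _ascertained_trios(
    rng: np.random.Generator, params: LiabilityModelParams, n_needed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (midparent, child) pairs for affected children only, by rejection."""
    mids: list[np.ndarray] = []
    childs: list[np.ndarray] = []
    got = 0
    while got < n_needed:
        # Expected yield per batch is K * batch; batches capped to bound memory.
        batch = min(
            5_000_000,
            max(100_000, int(1.3 * (n_needed - got) / params.prevalence_K)),
        )
        mother, father, child, affected = _simulate_children(rng, params, batch)
        mid = (mother + father) / 2.0
        mids.append(mid[affected])
        childs.append(child[affected])
        got += int(affected.sum())
    mid_all = np.concatenate(mids)[:n_needed]
    child_all = np.concatenate(childs)[:n_needed]
    return mid_all, child_all


def _reject_rates(
    mid: np.ndarray, child: np.ndarray, alpha: float
) -> np.ndarray:
    """Vectorized two-sided one-sample pTDT t-tests, one per row of the inputs."""
    n = mid.shape[1]
    sd_mid = mid.std(axis=1, ddof=1)
    dev = (child - mid) / sd_mid[:, None]
    mean = dev.mean(axis=1)
    sd = dev.std(axis=1, ddof=1)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    return p < alpha


@dataclass(frozen=True)
class PowerEstimate:
    power: float
    mc_se: float
    n_trios: int
    n_reps: int


def estimate_power(
    params: LiabilityModelParams,
    n_trios: int,
    n_reps: int,
    seed: int | np.random.Generator,
) -> PowerEstimate:
    """Monte-Carlo pTDT power for cohorts of affected, ascertained children.

    Simulates ``n_reps`` independent cohorts of ``n_trios`` trios whose
    child is affected under the liability threshold model, runs the pTDT
    on each, and reports the rejection fraction at ``params.alpha`` with
    its binomial Monte-Carlo standard error.
    """
    if n_trios < 2:
        raise PtdtError("n_trios must be >= 2")
    if n_reps < 100:
        raise PtdtError("n_reps must be >= 100")
    rng = _rng(seed)
    mid, child = _ascertained_trios(rng, params, n_trios * n_reps)
    mid = mid.reshape(n_reps, n_trios)
    child = child.reshape(n_reps, n_trios)
    rejected = _reject_rates(mid, child, params.alpha)
    power = float(rejected.mean())
    se = math.sqrt(power * (1.0 - power) / n_reps)
    return PowerEstimate(power, se, n_trios, n_reps)


def estimate_type1_error(
    params: LiabilityModelParams,
    n_trios: int,
    n_reps: int,
    seed: int | np.random.Generator,
) -> PowerEstimate:
    """Empirical pTDT rejection rate on unascertained (null) cohorts."""
    if n_trios < 2:
        raise PtdtError("n_trios must be >= 2")
    rng = _rng(seed)
    mother = rng.standard_normal((n_reps, n_trios))
    father = rng.standard_normal((n_reps, n_trios))
    mid = (mother + father) / 2.0
    child = mid + rng.normal(0.0, math.sqrt(0.5), (n_reps, n_trios))
    rejected = _reject_rates(mid, child, params.alpha)
    rate = float(rejected.mean())
    se = math.sqrt(rate * (1.0 - rate) / n_reps)
    return PowerEstimate(rate, se, n_trios, n_reps)
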