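"""Sample QC, multi-algorithm consensus, stringency filtering, rarity and
trio inheritance annotation for microarray CNV calls.

The chain implements the stringent-CNV strategy used in high-risk ASD
cohort studies: a variant is kept only when at least two detection
algorithms agree (one of them a designated required caller), it is large
enough and probe-supported, lies mostly outside segmental duplications and
mostly inside copy-number-stable sequence, and is absent from (or very
rare in) a platform-matched control cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .genomic import (
    AnnotationTrack,
    CnvCall,
    GenomicInterval,
    coverage_fraction,
    reciprocal_overlap,
)

DEFAULT_CALLERS = frozenset({"ChAS", "iPattern", "Nexus", "Partek"})

DE_NOVO = "de_novo"
MATERNAL = "maternal"
PATERNAL = "paternal"
BIPARENTAL = "biparental"
UNKNOWN = "unknown"


class PipelineError(ValueError):
    pass


@dataclass(frozen=True)
class FilterConfig:
    """Every numeric threshold of the detection/filtering chain.

    Defaults mirror the stringent criteria for the CytoScan HD
    four-caller design; ``ssc_mode()`` gives the three-caller variant used
    for Illumina-based cohorts where iPattern is the required algorithm.
    """

    min_size_bp: int = 15_000
    min_probes: int = 10
    max_segdup_fraction: float = 0.70
    min_stable_fraction: float = 0.75
    consensus_ro: float = 0.50
    min_algorithms: int = 2
    callers: frozenset[str] = DEFAULT_CALLERS
    required_algorithms: frozenset[str] = frozenset({"ChAS", "iPattern"})
    x_callers: frozenset[str] = frozenset({"ChAS", "iPattern"})
    rarity_ro: float = 0.50
    rarity_max_freq: float = 0.001
    max_waviness_sd: float = 0.12
    max_mapd: float = 0.25
    min_snp_qc: float = 15.0

    def __post_init__(self) -> None:
        for name in ("max_segdup_fraction", "min_stable_fraction", "consensus_ro", "rarity_ro"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise PipelineError(f"{name} must be in (0, 1], got {v}")
        if self.min_size_bp <= 0:
            raise PipelineError("min_size_bp must be positive")
        if not self.required_algorithms <= self.callers:
            raise PipelineError("required_algorithms must be a subset of callers")

    @classmethod
    def ssc_mode(cls) -> "FilterConfig":
        callers = frozenset({"PennCNV", "QuantiSNP", "iPattern"})
        return cls(
            callers=callers,
            required_algorithms=frozenset({"iPattern"}),
            x_callers=callers,
        )


@dataclass(frozen=True)
class SampleQcMetrics:
    sample_id: str
    waviness_sd: float | None
    mapd: float | None
    snp_qc: float | None


@dataclass(frozen=True)
class QcResult:
    sample_id: str
    passed: bool
    failed_criteria: tuple[str, ...]


@dataclass
class ConsensusCnv:
    """A merged per-sample CNV with its downstream annotations."""

    sample_id: str
    interval: GenomicInterval
    copy_state: str
    algorithms: frozenset[str]
    n_probes: int
    filter_flags: set[str] = field(default_factory=set)
    rarity: str = UNKNOWN  # rare | common | unknown
    control_frequency: float | None = None
    inheritance: str = UNKNOWN

    @property
    def survives_filters(self) -> bool:
        return not self.filter_flags


def sample_qc(metrics: SampleQcMetrics, cfg: FilterConfig) -> QcResult:
    """Array-level quality control: waviness SD, MAPD, SNP QC thresholds."""
    failed: list[str] = []
    checks = [
        ("waviness_sd", metrics.waviness_sd, lambda v: v <= cfg.max_waviness_sd),
        ("mapd", metrics.mapd, lambda v: v <= cfg.max_mapd),
        ("snp_qc", metrics.snp_qc, lambda v: v >= cfg.min_snp_qc),
    ]
    for name, value, ok in checks:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            failed.append(f"{name}:missing")
        elif not ok(value):
            failed.append(name)
    return QcResult(metrics.sample_id, not failed, tuple(failed))


def _single_linkage_clusters(calls: Sequence[CnvCall], ro_threshold: float) -> list[list[CnvCall]]:
    """Cluster same-sample/chrom/copy-state calls by pairwise reciprocal overlap."""
    n = len(calls)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    order = sorted(range(n), key=lambda i: calls[i].interval.start)
    for ai in range(n):
        for bi in range(ai + 1, n):
            i, j = order[ai], order[bi]
            if calls[j].interval.start >= calls[i].interval.end:
                break  # sorted by start: no further overlap with i possible
            if reciprocal_overlap(calls[i].interval, calls[j].interval) >= ro_threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list[CnvCall]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(calls[i])
    return list(groups.values())


def build_consensus(calls: Iterable[CnvCall], cfg: FilterConfig) -> list[ConsensusCnv]:
    """Merge per-algorithm calls into stringent consensus CNVs.

    Calls of the same sample, chromosome and copy state are clustered by
    single-linkage reciprocal overlap at ``consensus_ro``. A cluster is
    emitted iff it is supported by ``min_algorithms`` distinct algorithms,
    at least one of which is a required algorithm. X-chromosome calls are
    considered only from the designated X callers and require agreement of
    all of them; Y-chromosome calls are dropped unconditionally. The
    emitted interval is the union span of the supporting calls and the
    probe count is the maximum over supporters.
    """
    by_key: dict[tuple[str, str, str], list[CnvCall]] = {}
    for call in calls:
        if call.algorithm not in cfg.callers:
            raise PipelineError(f"unknown algorithm {call.algorithm!r} (configured: {sorted(cfg.callers)})")
        if call.interval.chrom == "Y":
            continue
        if call.interval.chrom == "X" and call.algorithm not in cfg.x_callers:
            continue
        by_key.setdefault((call.sample_id, call.interval.chrom, call.copy_state), []).append(call)

    out: list[ConsensusCnv] = []
    for (sample_id, chrom, copy_state), group in sorted(by_key.items()):
        for cluster in _single_linkage_clusters(group, cfg.consensus_ro):
            algos = frozenset(c.algorithm for c in cluster)
            if chrom == "X":
                if algos != cfg.x_callers:
                    continue
            else:
                if len(algos) < cfg.min_algorithms or not (algos & cfg.required_algorithms):
                    continue
            out.append(
                ConsensusCnv(
                    sample_id=sample_id,
                    interval=GenomicInterval(
                        chrom,
                        min(c.interval.start for c in cluster),
                        max(c.interval.end for c in cluster),
                    ),
                    copy_state=copy_state,
                    algorithms=algos,
                    n_probes=max(c.n_probes for c in cluster),
                )
            )
    out.sort(key=lambda c: (c.sample_id, c.interval, c.copy_state))
    return out


SIZE_FAIL = "size_fail"
PROBE_FAIL = "probe_fail"
SEGDUP_FAIL = "segdup_fail"
UNSTABLE_FAIL = "unstable_fail"


def apply_stringency_filters(
    cnvs: Iterable[ConsensusCnv],
    segdup: AnnotationTrack,
    stable: AnnotationTrack,
    cfg: FilterConfig,
) -> list[ConsensusCnv]:
    """Annotate each CNV with the stringency filters it fails.

    A CNV survives iff it is >= ``min_size_bp`` long, supported by
    >= ``min_probes`` probes, <= ``max_segdup_fraction`` of its span lies
    in segmental duplications and >= ``min_stable_fraction`` lies in
    copy-number-stable sequence.
    """
    annotated = []
    for cnv in cnvs:
        flags = set()
        if cnv.interval.length < cfg.min_size_bp:
            flags.add(SIZE_FAIL)
        if cnv.n_probes < cfg.min_probes:
            flags.add(PROBE_FAIL)
        if coverage_fraction(cnv.interval, segdup) > cfg.max_segdup_fraction:
            flags.add(SEGDUP_FAIL)
        if coverage_fraction(cnv.interval, stable) < cfg.min_stable_fraction:
            flags.add(UNSTABLE_FAIL)
        cnv.filter_flags = flags
        annotated.append(cnv)
    return annotated


def control_frequency(
    cnv: ConsensusCnv,
    control_calls: Iterable[CnvCall],
    n_control_individuals: int,
    cfg: FilterConfig,
) -> float:
    """Carrier frequency of the CNV in a control cohort.

    Counts distinct control individuals having >= 1 same-copy-state CNV
    matching at reciprocal overlap >= ``rarity_ro``; the denominator is
    the number of control individuals, not control CNV events.
    """
    if n_control_individuals < 1:
        raise PipelineError("n_control_individuals must be >= 1")
    carriers = {
        c.sample_id
        for c in control_calls
        if c.copy_state == cnv.copy_state
        and reciprocal_overlap(c.interval, cnv.interval) >= cfg.rarity_ro
    }
    return len(carriers) / n_control_individuals


def is_rare(
    cnv: ConsensusCnv,
    control_calls: Iterable[CnvCall],
    n_control_individuals: int,
    cfg: FilterConfig,
) -> bool:
    """Rare iff the control carrier frequency is strictly below ``rarity_max_freq``.

    Sets the CNV's ``control_frequency`` and ``rarity`` fields as a side
    effect. With an 873-individual control cohort and the 0.1% default
    threshold this is operationally "absent from controls".
    """
    freq = control_frequency(cnv, control_calls, n_control_individuals, cfg)
    cnv.control_frequency = freq
    cnv.rarity = "rare" if freq < cfg.rarity_max_freq else "common"
    return cnv.rarity == "rare"


def infer_inheritance(
    child_cnv: ConsensusCnv,
    mother_cnvs: Sequence[ConsensusCnv] | None,
    father_cnvs: Sequence[ConsensusCnv] | None,
    cfg: FilterConfig,
) -> str:
    """Trio inheritance of a child CNV from parental consensus calls.

    ``None`` for a parent means that parent was not genotyped; an empty
    list means genotyped with no CNV calls. A parental match requires the
    same copy state and reciprocal overlap >= ``rarity_ro``. De novo is
    only claimed when both parents are genotyped and neither matches;
    a match in both parents is reported as ``biparental``.
    """

    def matches(parent_cnvs: Sequence[ConsensusCnv]) -> bool:
        return any(
            p.copy_state == child_cnv.copy_state
            and reciprocal_overlap(p.interval, child_cnv.interval) >= cfg.rarity_ro
            for p in parent_cnvs
        )

    mom = matches(mother_cnvs) if mother_cnvs is not None else None
    dad = matches(father_cnvs) if father_cnvs is not None else None
    if mom and dad:
        result = BIPARENTAL
    elif mom:
        result = MATERNAL
    elif dad:
        result = PATERNAL
    elif mom is None or dad is None:
        result = UNKNOWN
    else:
        result = DE_NOVO
    child_cnv.inheritance = result
    return result


def annotate_inheritance(
    cnvs: Iterable[ConsensusCnv],
    consensus_by_sample: Mapping[str, Sequence[ConsensusCnv]],
    parents: Mapping[str, tuple[str | None, str | None]],
    genotyped: set[str],
    cfg: FilterConfig,
) -> None:
    """Annotate inheritance for every CNV given (mother_id, father_id) per sample."""
    for cnv in cnvs:
        mother_id, father_id = parents.get(cnv.sample_id, (None, None))
        mother = (
            list(consensus_by_sample.get(mother_id, []))
            if mother_id is not None and mother_id in genotyped
            else None
        )
        father = (
            list(consensus_by_sample.get(father_id, []))
            if father_id is not None and father_id in genotyped
            else None
        )
        infer_inheritance(cnv, mother, father, cfg)
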