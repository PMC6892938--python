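"""ACMG-adapted, tiered ASD-relevance classification of rare CNVs.

A surviving rare CNV is classified against a knowledge base of genomic
disorder regions, high-confidence ASD-susceptibility genes, candidate
ASD / neuropsychiatric genes, noncoding exception elements (e.g. a
PTCHD1-AS-like lncRNA or noncoding critical-region exons), and a DGV-like
population frequency table. Classification is blind to phenotype by
construction: no phenotype ever enters this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .genomic import (
    GenomicInterval,
    interval_overlap_length,
    parse_copy_state,
    reciprocal_overlap,
)
from .io import FileFormatError, _parse_int
from .pipeline import ConsensusCnv, DE_NOVO, UNKNOWN

PATHOGENIC = "pathogenic"
LIKELY_PATHOGENIC = "likely_pathogenic"
VUS = "VUS"
NOT_RELEVANT = "not_relevant"

TIERS = (PATHOGENIC, LIKELY_PATHOGENIC, VUS, NOT_RELEVANT)

#: Tier filters used for carrier status (Table-1 column structure).
ALL_RELEVANT = frozenset({PATHOGENIC, LIKELY_PATHOGENIC, VUS})
EXCLUDING_VUS = frozenset({PATHOGENIC, LIKELY_PATHOGENIC})

HC = "hc"
CANDIDATE = "candidate"
NONCODING = "noncoding_exception"


class ClassificationError(ValueError):
    pass


@dataclass(frozen=True)
class GeneModel:
    """A gene (or noncoding element) as the set of its coding/listed exons."""

    gene_id: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ClassificationError(f"gene {self.gene_id} has no exons")


@dataclass(frozen=True)
class DisorderRegion:
    """A recurrent genomic-disorder locus with its pathogenic copy states."""

    name: str
    interval: GenomicInterval
    copy_states: frozenset[str]


@dataclass(frozen=True)
class PopulationFreqRecord:
    interval: GenomicInterval
    copy_state: str
    frequency: float


@dataclass
class KnowledgeBase:
    disorder_regions: list[DisorderRegion] = field(default_factory=list)
    hc_genes: list[GeneModel] = field(default_factory=list)
    candidate_genes: list[GeneModel] = field(default_factory=list)
    noncoding_exceptions: list[GeneModel] = field(default_factory=list)
    population_freq: list[PopulationFreqRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        hc = {g.gene_id for g in self.hc_genes}
        cand = {g.gene_id for g in self.candidate_genes}
        nc = {g.gene_id for g in self.noncoding_exceptions}
        shared = (hc & cand) | (hc & nc) | (cand & nc)
        if shared:
            raise ClassificationError(f"genes present in more than one tier: {sorted(shared)}")


@dataclass(frozen=True)
class Classification:
    tier: str
    basis: tuple[str, ...]


def _read_gene_bed(path: Path) -> list[GeneModel]:
    """BED with a name column; one row per exon, grouped into gene models."""
    exons: dict[str, list[GenomicInterval]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FileFormatError(path, line_no, "row", "gene BED needs chrom/start/end/gene_id")
            iv = GenomicInterval(
                parts[0],
                _parse_int(parts[1], path, line_no, "start"),
                _parse_int(parts[2], path, line_no, "end"),
            )
            exons.setdefault(parts[3], []).append(iv)
    return [GeneModel(g, tuple(sorted(ivs))) for g, ivs in sorted(exons.items())]


def load_knowledge_base(directory: str | Path) -> KnowledgeBase:
    """Load a knowledge-base directory.

    Expected files: ``disorder_regions.bed`` (chrom, start, end, name,
    copy_states with ``,``-separated states or ``both``), ``hc_genes.bed``,
    ``candidate_genes.bed``, ``noncoding_exceptions.bed`` (per-exon rows),
    and ``population_freq.tsv`` (chrom, start, end, type, frequency).
    """
    d = Path(directory)
    for required in ("disorder_regions.bed", "hc_genes.bed", "candidate_genes.bed",
                     "noncoding_exceptions.bed", "population_freq.tsv"):
        if not (d / required).exists():
            raise ClassificationError(f"knowledge base incomplete: missing {required} in {d}")

    regions = []
    with open(d / "disorder_regions.bed") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise FileFormatError(d / "disorder_regions.bed", line_no, "row",
                                      "needs chrom/start/end/name/copy_states")
            states = (
                frozenset({"deletion", "duplication"})
                if parts[4] == "both"
                else frozenset(parse_copy_state(s) for s in parts[4].split(","))
            )
            regions.append(
                DisorderRegion(
                    parts[3],
                    GenomicInterval(parts[0],
                                    _parse_int(parts[1], d, line_no, "start"),
                                    _parse_int(parts[2], d, line_no, "end")),
                    states,
                )
            )

    freqs = []
    with open(d / "population_freq.tsv") as fh:
        header = fh.readline()
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            freqs.append(
                PopulationFreqRecord(
                    GenomicInterval(parts[0],
                                    _parse_int(parts[1], d, line_no, "start"),
                                    _parse_int(parts[2], d, line_no, "end")),
                    parse_copy_state(parts[3]),
                    float(parts[4]),
                )
            )

    return KnowledgeBase(
        disorder_regions=regions,
        hc_genes=_read_gene_bed(d / "hc_genes.bed"),
        candidate_genes=_read_gene_bed(d / "candidate_genes.bed"),
        noncoding_exceptions=_read_gene_bed(d / "noncoding_exceptions.bed"),
        population_freq=freqs,
    )


def _exonic_hits(cnv: ConsensusCnv, genes: Sequence[GeneModel]) -> list[str]:
    hits = []
    for gene in genes:
        if any(interval_overlap_length(cnv.interval, exon) > 0 for exon in gene.exons):
            hits.append(gene.gene_id)
    return hits


def genes_hit(cnv: ConsensusCnv, kb: KnowledgeBase) -> dict[str, list[str]]:
    """Genes whose exons the CNV overlaps by >= 1 bp, keyed by tier.

    Intronic-only overlap is not a hit; noncoding-exception elements count
    through their listed exons.
    """
    return {
        HC: _exonic_hits(cnv, kb.hc_genes),
        CANDIDATE: _exonic_hits(cnv, kb.candidate_genes),
        NONCODING: _exonic_hits(cnv, kb.noncoding_exceptions),
    }


def _population_frequency(cnv: ConsensusCnv, kb: KnowledgeBase, ro: float) -> float:
    """Highest matching DGV-like frequency; 0.0 when the CNV is unlisted."""
    best = 0.0
    for rec in kb.population_freq:
        if rec.copy_state == cnv.copy_state and reciprocal_overlap(rec.interval, cnv.interval) >= ro:
            best = max(best, rec.frequency)
    return best


def _disorder_match(cnv: ConsensusCnv, region: DisorderRegion, rule: str, ro: float) -> bool:
    if cnv.copy_state not in region.copy_states:
        return False
    if rule == "reciprocal_overlap":
        return reciprocal_overlap(cnv.interval, region.interval) >= ro
    if rule == "containment":  # CNV spans the whole critical region
        return (
            interval_overlap_length(cnv.interval, region.interval)
            == region.interval.length
        )
    raise ClassificationError(f"unknown disorder match rule: {rule!r}")


def classify_variant(
    cnv: ConsensusCnv,
    kb: KnowledgeBase,
    *,
    match_rule: str = "reciprocal_overlap",
    match_ro: float = 0.50,
    vus_max_freq: float = 0.001,
) -> Classification:
    """Assign a clinical tier to a rare, filter-surviving CNV.

    Rule order (first match wins):

    1. matches a genomic-disorder region with compatible copy state
       -> pathogenic;
    2. exonic hit of a high-confidence gene (or noncoding exception):
       de novo -> pathogenic; inherited or unknown -> likely pathogenic;
    3. exonic hit of a candidate gene with population frequency
       <= ``vus_max_freq`` -> VUS;
    4. otherwise not relevant.

    Non-rare CNVs are never classified above ``not_relevant``. The CNV
    must already carry rarity and inheritance annotations.
    """
    if cnv.rarity == UNKNOWN:
        raise ClassificationError(
            f"CNV {cnv.sample_id} {cnv.interval.chrom}:{cnv.interval.start} lacks rarity annotation"
        )
    if cnv.rarity != "rare":
        return Classification(NOT_RELEVANT, ())

    for region in kb.disorder_regions:
        if _disorder_match(cnv, region, match_rule, match_ro):
            return Classification(PATHOGENIC, (f"disorder_region:{region.name}",))

    hits = genes_hit(cnv, kb)
    hc_like = [f"hc_gene:{g}" for g in hits[HC]] + [f"noncoding_exception:{g}" for g in hits[NONCODING]]
    if hc_like:
        if cnv.inheritance == DE_NOVO:
            return Classification(PATHOGENIC, tuple(hc_like) + ("inheritance:de_novo",))
        tag = f"inheritance:{cnv.inheritance}"
        return Classification(LIKELY_PATHOGENIC, tuple(hc_like) + (tag,))

    if hits[CANDIDATE]:
        freq = _population_frequency(cnv, kb, match_ro)
        if freq <= vus_max_freq:
            return Classification(
                VUS,
                tuple(f"candidate_gene:{g}" for g in hits[CANDIDATE])
                + (f"population_freq:{freq:g}",),
            )

    return Classification(NOT_RELEVANT, ())


def carrier_status(
    classifications: Iterable[Classification],
    class_filter: frozenset[str] | set[str] = ALL_RELEVANT,
) -> bool:
    """True iff the individual carries >= 1 CNV whose tier is in ``class_filter``."""
    return any(c.tier in class_filter for c in classifications)
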