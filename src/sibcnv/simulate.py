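"""Synthetic cohort generator.

Builds a complete, self-consistent high-risk infant-sibling study offline:
a pedigree of ASD-proband families with longitudinally phenotyped younger
siblings, per-algorithm microarray CNV call tables with caller jitter and
caller-specific artifacts, segmental-duplication and copy-number-stable
tracks, a miniature knowledge base (genomic-disorder regions,
high-confidence and candidate ASD genes, noncoding exception elements,
a DGV-like frequency table), a platform-matched control cohort, per-sibling
psychometric scores, and trio polygenic scores under the liability
threshold model.

The generator is deterministic given its seed and satisfies the configured
carrier-by-phenotype cells and phenotype margins by construction (labels
are assigned, then shuffled), so the downstream contingency tables are an
exact function of the configuration rather than of sampling luck. The
defaults emulate a 253-family consortium cohort with 288 infant siblings
(103 ASD / 54 atypical / 131 typical), 13 sibling CNV carriers
(6 pathogenic or likely pathogenic, 7 VUS-only), 13 of 253 probands with
ASD-relevant CNVs, and an 873-individual control cohort.

The miniature genome uses 22 autosomes plus X and Y of 10 Mb each; real
genome builds are unnecessary for the statistics the pipeline computes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genomic import (
    AnnotationTrack,
    CnvCall,
    DELETION,
    DUPLICATION,
    GenomicInterval,
    TrackRecord,
)
from .io import (
    PedigreeRecord,
    write_cnv_calls,
    write_pedigree,
    write_psychometrics,
    write_qc_metrics,
    write_track,
    write_trio_prs,
)
from .outcomes import ASD, ATYPICAL, TYPICAL, PsychometricRecord
from .pipeline import SampleQcMetrics
from .ptdt import LiabilityModelParams, TrioPrs, _ascertained_trios, _rng

CHROM_LENGTH = 10_000_000
CALLERS = ("ChAS", "iPattern", "Nexus", "Partek")
X_CALLERS = ("ChAS", "iPattern")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CommonLocus:
    """A common CNV polymorphism shared by cases and controls."""

    interval: GenomicInterval
    copy_state: str
    frequency: float


@dataclass(frozen=True)
class PlantSpec:
    """One intended ASD-relevant CNV: who carries it, where, and why."""

    carrier_role: str  # "sibling" or "proband"
    phenotype: str  # sibling phenotype the carrier is assigned (ignored for probands)
    mechanism: str  # disorder_region | hc_gene | noncoding_exception | candidate_gene
    target: str  # name of the knowledge-base entry hit
    copy_state: str
    inheritance: str  # de_novo | maternal | paternal
    expected_tier: str


def _default_sibling_plants() -> tuple[PlantSpec, ...]:
    # 6 pathogenic/likely-pathogenic carriers: 3 ASD, 2 atypical, 1 typical;
    # 7 VUS-only carriers: 3 ASD, 3 atypical, 1 typical.
    s = "sibling"
    return (
        PlantSpec(s, ASD, "disorder_region", "DR_16p11-like", DELETION, "maternal", "pathogenic"),
        PlantSpec(s, ASD, "hc_gene", "HC_A", DELETION, "de_novo", "pathogenic"),
        PlantSpec(s, ASD, "hc_gene", "HC_B", DUPLICATION, "paternal", "likely_pathogenic"),
        PlantSpec(s, ATYPICAL, "hc_gene", "HC_C", DELETION, "maternal", "likely_pathogenic"),
        PlantSpec(s, ATYPICAL, "noncoding_exception", "NC_PTCHD1AS-like", DELETION, "maternal",
                  "likely_pathogenic"),
        PlantSpec(s, TYPICAL, "disorder_region", "DR_16p13-like", DUPLICATION, "de_novo",
                  "pathogenic"),
        PlantSpec(s, ASD, "candidate_gene", "CAND_A", DELETION, "maternal", "VUS"),
        PlantSpec(s, ASD, "candidate_gene", "CAND_B", DUPLICATION, "de_novo", "VUS"),
        PlantSpec(s, ASD, "candidate_gene", "CAND_C", DELETION, "paternal", "VUS"),
        PlantSpec(s, ATYPICAL, "candidate_gene", "CAND_D", DUPLICATION, "maternal", "VUS"),
        PlantSpec(s, ATYPICAL, "candidate_gene", "CAND_E", DELETION, "maternal", "VUS"),
        PlantSpec(s, ATYPICAL, "candidate_gene", "CAND_A", DUPLICATION, "paternal", "VUS"),
        PlantSpec(s, TYPICAL, "candidate_gene", "CAND_B", DELETION, "maternal", "VUS"),
    )


def _default_proband_plants() -> tuple[PlantSpec, ...]:
    p = "proband"
    mechanisms = (
        ("disorder_region", "DR_16p11-like", DELETION, "de_novo", "pathogenic"),
        ("disorder_region", "DR_16p13-like", DUPLICATION, "maternal", "pathogenic"),
        ("hc_gene", "HC_A", DELETION, "de_novo", "pathogenic"),
        ("hc_gene", "HC_B", DELETION, "maternal", "likely_pathogenic"),
        ("hc_gene", "HC_C", DUPLICATION, "paternal", "likely_pathogenic"),
        ("hc_gene", "HC_D", DELETION, "maternal", "likely_pathogenic"),
        ("hc_gene", "HC_E", DUPLICATION, "de_novo", "pathogenic"),
        ("noncoding_exception", "NC_MBD5-like", DELETION, "maternal", "likely_pathogenic"),
        ("candidate_gene", "CAND_A", DELETION, "maternal", "VUS"),
        ("candidate_gene", "CAND_B", DUPLICATION, "paternal", "VUS"),
        ("candidate_gene", "CAND_C", DELETION, "de_novo", "VUS"),
        ("candidate_gene", "CAND_D", DUPLICATION, "maternal", "VUS"),
        ("candidate_gene", "CAND_E", DELETION, "maternal", "VUS"),
    )
    return tuple(PlantSpec(p, "", m, t, cs, inh, tier) for m, t, cs, inh, tier in mechanisms)


def _default_common_loci() -> tuple[CommonLocus, ...]:
    return (
        CommonLocus(GenomicInterval("5", 4_000_000, 4_060_000), DELETION, 0.05),
        CommonLocus(GenomicInterval("9", 4_500_000, 4_580_000), DUPLICATION, 0.02),
        CommonLocus(GenomicInterval("12", 2_500_000, 2_550_000), DELETION, 0.01),
    )


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of the synthetic cohort."""

    n_families: int = 253
    # infant siblings per family -> number of families (253 families, 288 sibs)
    family_sizes: tuple[tuple[int, int], ...] = ((1, 223), (2, 25), (3, 5))
    n_asd: int = 103
    n_atypical: int = 54
    sibling_plants: tuple[PlantSpec, ...] = field(default_factory=_default_sibling_plants)
    proband_plants: tuple[PlantSpec, ...] = field(default_factory=_default_proband_plants)
    jitter_bp: int = 500
    probe_spacing_bp: int = 1_000
    consensus_ro: float = 0.50
    n_controls: int = 873
    common_loci: tuple[CommonLocus, ...] = field(default_factory=_default_common_loci)
    liability: LiabilityModelParams = field(default_factory=LiabilityModelParams)
    n_proband_trios: int = 189
    n_affected_sib_trios: int = 93
    n_atypical_sib_trios: int = 44
    n_unaffected_sib_trios: int = 112

    @property
    def n_siblings(self) -> int:
        return sum(k * n for k, n in self.family_sizes)

    @property
    def n_typical(self) -> int:
        return self.n_siblings - self.n_asd - self.n_atypical

    def validate(self) -> None:
        if sum(n for _, n in self.family_sizes) != self.n_families:
            raise ConfigError("family_sizes must account for every family")
        if self.n_typical < 0:
            raise ConfigError("phenotype margins exceed the number of siblings")
        margins = {ASD: self.n_asd, ATYPICAL: self.n_atypical, TYPICAL: self.n_typical}
        cells: dict[str, int] = {ASD: 0, ATYPICAL: 0, TYPICAL: 0}
        for spec in self.sibling_plants:
            cells[spec.phenotype] += 1
        for pheno, count in cells.items():
            if count > margins[pheno]:
                raise ConfigError(
                    f"carrier plan requires {count} {pheno} siblings but margin is {margins[pheno]}"
                )
        if len(self.sibling_plants) > self.n_families - len(self.proband_plants):
            raise ConfigError("not enough families to host sibling and proband carriers disjointly")
        for loc in self.common_loci:
            if not 0 < loc.frequency < 1:
                raise ConfigError("common locus frequencies must be in (0, 1)")
        # Caller jitter must keep mutual reciprocal overlap above the consensus
        # threshold: two copies shifted oppositely by j have RO >= (L-2j)/(L+2j).
        min_len = 50_000  # shortest planted CNV (smallest common locus)
        worst_ro = (min_len - 2 * self.jitter_bp) / (min_len + 2 * self.jitter_bp)
        if worst_ro < self.consensus_ro:
            raise ConfigError(
                f"jitter_bp={self.jitter_bp} too large for consensus RO {self.consensus_ro}"
            )


# --- fixed miniature-genome annotation geometry ------------------------------

DISORDER_REGIONS = {
    "DR_16p11-like": (GenomicInterval("16", 1_000_000, 1_610_000), "both"),
    "DR_16p13-like": (GenomicInterval("1", 2_000_000, 2_400_000), "both"),
}

_GENE_CHROMS = {
    "HC_A": "2", "HC_B": "3", "HC_C": "4", "HC_D": "6", "HC_E": "7",
    "CAND_A": "8", "CAND_B": "10", "CAND_C": "11", "CAND_D": "13", "CAND_E": "14",
}
_GENE_START = 3_000_000
_EXON_OFFSETS = (0, 25_000, 50_000)
_EXON_LEN = 2_000

NONCODING_ELEMENTS = {
    "NC_PTCHD1AS-like": ("X", 3_000_000),
    "NC_MBD5-like": ("2", 5_000_000),
}


def _gene_exons(chrom: str, start: int) -> list[GenomicInterval]:
    return [GenomicInterval(chrom, start + o, start + o + _EXON_LEN) for o in _EXON_OFFSETS]


def knowledge_base_geometry() -> dict[str, object]:
    """The fixed positions of every synthetic knowledge-base element."""
    genes = {name: _gene_exons(chrom, _GENE_START) for name, chrom in _GENE_CHROMS.items()}
    noncoding = {name: _gene_exons(chrom, start) for name, (chrom, start) in NONCODING_ELEMENTS.items()}
    return {"disorder_regions": DISORDER_REGIONS, "genes": genes, "noncoding": noncoding}


def _target_interval(spec: PlantSpec) -> GenomicInterval:
    """The true CNV interval for a planted variant (spans its target's exons)."""
    if spec.mechanism == "disorder_region":
        return DISORDER_REGIONS[spec.target][0]
    if spec.mechanism == "noncoding_exception":
        chrom, start = NONCODING_ELEMENTS[spec.target]
    else:
        chrom, start = _GENE_CHROMS[spec.target], _GENE_START
    # 72 kb CNV covering all three exons with flanks
    return GenomicInterval(chrom, start - 10_000, start + 62_000)


@dataclass
class GroundTruthEntry:
    sample_id: str
    interval: GenomicInterval
    copy_state: str
    category: str  # relevant | common | artifact | filtered
    expected_tier: str
    inheritance: str
    mechanism: str


@dataclass
class SyntheticBundle:
    """Paths and ground truth of one generated cohort."""

    root: Path
    pedigree: Path
    call_tables: dict[str, Path]
    qc_metrics: Path
    segdup_track: Path
    stable_track: Path
    kb_dir: Path
    controls: Path
    n_control_individuals: int
    psychometrics: Path
    trio_prs: Path
    ground_truth: Path
    ground_truth_entries: list[GroundTruthEntry]
    manifest: Path


def _jittered_call(
    rng: np.random.Generator,
    sample_id: str,
    interval: GenomicInterval,
    copy_state: str,
    algorithm: str,
    jitter_bp: int,
    probe_spacing: int,
) -> CnvCall:
    js = int(rng.integers(-jitter_bp, jitter_bp + 1))
    je = int(rng.integers(-jitter_bp, jitter_bp + 1))
    start = max(0, interval.start + js)
    end = max(start + 1_000, interval.end + je)
    iv = GenomicInterval(interval.chrom, start, end)
    return CnvCall(sample_id, iv, copy_state, math.ceil(iv.length / probe_spacing), algorithm)


def _caller_subset(rng: np.random.Generator, chrom: str) -> tuple[str, ...]:
    """Supporting callers for a true variant: >= 2, >= 1 required; X uses both X callers."""
    if chrom == "X":
        return X_CALLERS
    n = int(rng.integers(2, 5))  # 2..4 supporting algorithms
    required = CALLERS[int(rng.integers(0, 2))]  # ChAS or iPattern
    others = [c for c in CALLERS if c != required]
    rng.shuffle(others)
    return tuple(sorted([required] + others[: n - 1]))


def generate_algorithm_calls(
    true_cnvs: list[tuple[str, GenomicInterval, str]],
    cfg: CohortConfig,
    seed: int | np.random.Generator,
) -> dict[str, list[CnvCall]]:
    """Emit per-algorithm call lists for a set of true (sample, interval, state) CNVs."""
    cfg.validate()
    rng = _rng(seed)
    calls: dict[str, list[CnvCall]] = {c: [] for c in CALLERS}
    for sample_id, interval, copy_state in true_cnvs:
        for algo in _caller_subset(rng, interval.chrom):
            calls[algo].append(
                _jittered_call(rng, sample_id, interval, copy_state, algo,
                               cfg.jitter_bp, cfg.probe_spacing_bp)
            )
    return calls


def generate_control_cohort(
    cfg: CohortConfig, seed: int | np.random.Generator
) -> tuple[list[CnvCall], int]:
    """Control-cohort calls: common loci at their configured carrier frequencies.

    Planted rare (ASD-relevant) loci never appear in controls, so every
    planted variant is rare by construction.
    """
    rng = _rng(seed)
    calls: list[CnvCall] = []
    for locus in cfg.common_loci:
        n_carriers = int(rng.binomial(cfg.n_controls, locus.frequency))
        carriers = rng.choice(cfg.n_controls, size=n_carriers, replace=False)
        for idx in sorted(carriers):
            sample_id = f"CTRL{idx + 1:04d}"
            calls.append(
                _jittered_call(rng, sample_id, locus.interval, locus.copy_state,
                               "ChAS", cfg.jitter_bp, cfg.probe_spacing_bp)
            )
    return calls, cfg.n_controls


def _write_knowledge_base(kb_dir: Path, cfg: CohortConfig) -> None:
    kb_dir.mkdir(parents=True, exist_ok=True)
    with open(kb_dir / "disorder_regions.bed", "w") as fh:
        for name, (iv, states) in sorted(DISORDER_REGIONS.items()):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{states}\n")

    def write_genes(path: Path, names: list[str], noncoding: bool = False) -> None:
        with open(path, "w") as fh:
            for name in names:
                if noncoding:
                    chrom, start = NONCODING_ELEMENTS[name]
                    exons = _gene_exons(chrom, start)
                else:
                    exons = _gene_exons(_GENE_CHROMS[name], _GENE_START)
                for exon in exons:
                    fh.write(f"{exon.chrom}\t{exon.start}\t{exon.end}\t{name}\n")

    write_genes(kb_dir / "hc_genes.bed", [g for g in sorted(_GENE_CHROMS) if g.startswith("HC_")])
    write_genes(kb_dir / "candidate_genes.bed",
                [g for g in sorted(_GENE_CHROMS) if g.startswith("CAND_")])
    write_genes(kb_dir / "noncoding_exceptions.bed", sorted(NONCODING_ELEMENTS), noncoding=True)
    with open(kb_dir / "population_freq.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\ttype\tfrequency\n")
        for locus in cfg.common_loci:
            short = "del" if locus.copy_state == DELETION else "dup"
            fh.write(
                f"{locus.interval.chrom}\t{locus.interval.start}\t{locus.interval.end}"
                f"\t{short}\t{locus.frequency:g}\n"
            )


def _tracks(cfg: CohortConfig) -> tuple[AnnotationTrack, AnnotationTrack]:
    autosomes = [str(i) for i in range(1, 23)]
    segdup = AnnotationTrack(
        "segdup",
        [TrackRecord(GenomicInterval(c, 8_000_000, 8_300_000)) for c in autosomes],
    )
    stable = AnnotationTrack(
        "cn_stable",
        [TrackRecord(GenomicInterval(c, 0, 7_000_000)) for c in autosomes + ["X"]],
    )
    return segdup, stable


def _psychometrics_for_label(
    rng: np.random.Generator, individual_id: str, label: str
) -> PsychometricRecord:
    """Scores drawn on the correct side of every threshold for the label."""

    def u(lo: float, hi: float) -> float:
        return float(np.round(rng.uniform(lo, hi), 1))

    if label == ASD:
        return PsychometricRecord(
            individual_id=individual_id,
            ados_css=int(rng.integers(4, 11)),
            msel_elc=u(55, 95),
            msel_receptive_language=u(55, 95),
            msel_expressive_language=u(55, 95),
            vabs_abc=u(60, 95),
            vabs_subscale_min=u(60, 95),
            srs_t=u(66, 90),
            cbcl_t=u(55, 80),
            clinician_asd_flag=True,
            clinician_atypical_flag=False,
            adir_positive=True,
        )
    if label == ATYPICAL:
        # rotate through the subthreshold criteria; SRS kept elevated so the
        # SSC-style screen agrees with the BSRC-style label
        criterion = int(rng.integers(0, 5))
        rec = dict(
            individual_id=individual_id,
            ados_css=int(rng.integers(0, 3)),
            msel_elc=u(90, 115),
            msel_receptive_language=u(90, 115),
            msel_expressive_language=u(90, 115),
            vabs_abc=u(90, 115),
            vabs_subscale_min=u(90, 115),
            srs_t=u(61, 75),
            cbcl_t=u(40, 55),
            clinician_asd_flag=False,
            clinician_atypical_flag=False,
            adir_positive=False,
        )
        if criterion == 0:
            rec.update(ados_css=int(rng.integers(3, 4)), adir_positive=True)
        elif criterion == 1:
            rec.update(msel_elc=u(70, 84.5))
        elif criterion == 2:
            rec.update(msel_expressive_language=u(70, 84.5))
        elif criterion == 3:
            rec.update(vabs_abc=u(70, 84.5), vabs_subscale_min=u(70, 84.5))
        else:
            rec.update(clinician_atypical_flag=True)
        return PsychometricRecord(**rec)
    return PsychometricRecord(
        individual_id=individual_id,
        ados_css=int(rng.integers(0, 3)),
        msel_elc=u(90, 115),
        msel_receptive_language=u(90, 115),
        msel_expressive_language=u(90, 115),
        vabs_abc=u(90, 115),
        vabs_subscale_min=u(90, 115),
        srs_t=u(40, 55),
        cbcl_t=u(40, 55),
        clinician_asd_flag=False,
        clinician_atypical_flag=False,
        adir_positive=False,
    )


def _trio_prs_tables(cfg: CohortConfig, rng: np.random.Generator) -> list[TrioPrs]:
    """Ascertained (affected) trios for probands/ASD sibs, null trios otherwise."""
    trios: list[TrioPrs] = []
    groups = (
        ("proband", cfg.n_proband_trios, True),
        ("affected_sibling", cfg.n_affected_sib_trios, True),
        ("atypical_sibling", cfg.n_atypical_sib_trios, False),
        ("unaffected_sibling", cfg.n_unaffected_sib_trios, False),
    )
    for group, n, ascertained in groups:
        if ascertained:
            mid, child = _ascertained_trios(rng, cfg.liability, n)
            # recover exchangeable parents from the midparent value
            half_diff = rng.normal(0.0, math.sqrt(0.5), n)
            mother = mid + half_diff
            father = mid - half_diff
        else:
            mother = rng.standard_normal(n)
            father = rng.standard_normal(n)
            child = (mother + father) / 2.0 + rng.normal(0.0, math.sqrt(0.5), n)
        for i in range(n):
            trios.append(
                TrioPrs(f"F{i + 1:03d}", f"F{i + 1:03d}-{group}", group,
                        float(child[i]), float(mother[i]), float(father[i]))
            )
    return trios


def generate_cohort(
    cfg: CohortConfig, out_dir: str | Path, seed: int | np.random.Generator
) -> SyntheticBundle:
    """Write a complete synthetic study bundle under ``out_dir``.

    Deterministic given the seed: identical seeds produce byte-identical
    bundles. The configuration is validated before any file is written.
    """
    cfg.validate()
    rng = _rng(seed)
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    (root / "tracks").mkdir(exist_ok=True)

    # -- pedigree -------------------------------------------------------------
    ped: list[PedigreeRecord] = []
    sibling_ids: list[str] = []
    proband_ids: list[str] = []
    family_sibs: list[int] = []
    for k, n in cfg.family_sizes:
        family_sibs.extend([k] * n)
    for fi, n_sibs in enumerate(family_sibs, start=1):
        fid = f"F{fi:03d}"
        father, mother = f"{fid}-father", f"{fid}-mother"
        ped.append(PedigreeRecord(fid, father, None, None, 1, "father", "unknown"))
        ped.append(PedigreeRecord(fid, mother, None, None, 2, "mother", "unknown"))
        pid = f"{fid}-proband"
        proband_ids.append(pid)
        ped.append(PedigreeRecord(fid, pid, father, mother, 1, "proband", "ASD"))
        for si in range(1, n_sibs + 1):
            sid = f"{fid}-sib{si}"
            sibling_ids.append(sid)
            sex = 1 if rng.random() < 0.5 else 2
            ped.append(PedigreeRecord(fid, sid, father, mother, sex, "sibling", "unknown"))

    # -- carrier placement: probands in the first families, sibling carriers
    # in the following ones, one carrier per family --------------------------
    n_prob = len(cfg.proband_plants)
    proband_carrier_fams = [f"F{i + 1:03d}" for i in range(n_prob)]
    sibling_carrier_fams = [f"F{i + 1:03d}" for i in range(n_prob, n_prob + len(cfg.sibling_plants))]

    truth: list[GroundTruthEntry] = []
    true_cnvs: list[tuple[str, GenomicInterval, str]] = []

    def plant(spec: PlantSpec, fid: str, carrier_id: str) -> None:
        iv = _target_interval(spec)
        true_cnvs.append((carrier_id, iv, spec.copy_state))
        if spec.inheritance in ("maternal", "paternal"):
            parent_id = f"{fid}-mother" if spec.inheritance == "maternal" else f"{fid}-father"
            true_cnvs.append((parent_id, iv, spec.copy_state))
        truth.append(
            GroundTruthEntry(carrier_id, iv, spec.copy_state, "relevant",
                             spec.expected_tier, spec.inheritance, spec.mechanism)
        )

    sibling_carrier_pheno: dict[str, str] = {}
    for spec, fid in zip(cfg.proband_plants, proband_carrier_fams):
        plant(spec, fid, f"{fid}-proband")
    for spec, fid in zip(cfg.sibling_plants, sibling_carrier_fams):
        carrier_id = f"{fid}-sib1"
        plant(spec, fid, carrier_id)
        sibling_carrier_pheno[carrier_id] = spec.phenotype

    # -- phenotype labels: carriers fixed, the rest fill the margins ---------
    labels: dict[str, str] = dict(sibling_carrier_pheno)
    remaining = [s for s in sibling_ids if s not in labels]
    cells = {ASD: 0, ATYPICAL: 0, TYPICAL: 0}
    for p in sibling_carrier_pheno.values():
        cells[p] += 1
    pool = (
        [ASD] * (cfg.n_asd - cells[ASD])
        + [ATYPICAL] * (cfg.n_atypical - cells[ATYPICAL])
        + [TYPICAL] * (cfg.n_typical - cells[TYPICAL])
    )
    rng.shuffle(pool)
    labels.update(dict(zip(remaining, pool)))

    # -- common variants and caller artifacts (negative controls) ------------
    non_carrier_sibs = [s for s in sibling_ids if s not in sibling_carrier_pheno]
    common_hosts = list(rng.choice(non_carrier_sibs, size=10, replace=False))
    for i, host in enumerate(common_hosts):
        locus = cfg.common_loci[i % len(cfg.common_loci)]
        true_cnvs.append((host, locus.interval, locus.copy_state))
        truth.append(GroundTruthEntry(host, locus.interval, locus.copy_state,
                                      "common", "not_relevant", "unknown", "common_locus"))

    calls = generate_algorithm_calls(true_cnvs, cfg, rng)

    def artifact(sample: str, iv: GenomicInterval, state: str, algos: tuple[str, ...],
                 category: str, note: str) -> None:
        for algo in algos:
            calls[algo].append(
                _jittered_call(rng, sample, iv, state, algo, cfg.jitter_bp, cfg.probe_spacing_bp)
            )
        truth.append(GroundTruthEntry(sample, iv, state, category, "not_relevant",
                                      "unknown", note))

    artifact_hosts = list(rng.choice(non_carrier_sibs, size=9, replace=False))
    for i, host in enumerate(artifact_hosts[:3]):  # single-caller artifacts
        iv = GenomicInterval(str(17 + i), 1_000_000 + 40_000 * i, 1_050_000 + 40_000 * i)
        artifact(host, iv, DELETION, (CALLERS[i % 4],), "artifact", "single_caller")
    for i, host in enumerate(artifact_hosts[3:5]):  # no required caller
        iv = GenomicInterval(str(19 + i), 2_000_000, 2_060_000)
        artifact(host, iv, DUPLICATION, ("Nexus", "Partek"), "artifact", "no_required_caller")
    for i, host in enumerate(artifact_hosts[5:7]):  # below size threshold
        iv = GenomicInterval(str(21 + i), 3_000_000, 3_010_000)
        artifact(host, iv, DELETION, ("ChAS", "Nexus"), "filtered", "too_small")
    host = artifact_hosts[7]  # inside a segmental duplication
    artifact(host, GenomicInterval("18", 8_010_000, 8_120_000), DELETION,
             ("ChAS", "Partek"), "filtered", "segdup")
    host = artifact_hosts[8]  # Y-chromosome call, dropped unconditionally
    artifact(host, GenomicInterval("Y", 1_000_000, 1_100_000), DELETION,
             ("ChAS", "iPattern"), "artifact", "y_chromosome")

    for algo, algo_calls in calls.items():
        algo_calls.sort(key=lambda c: (c.sample_id, c.interval))

    # -- write the bundle -----------------------------------------------------
    pedigree_path = root / "pedigree.tsv"
    write_pedigree(ped, pedigree_path)

    call_tables = {}
    for algo in CALLERS:
        path = root / f"calls_{algo}.tsv"
        write_cnv_calls(calls[algo], path)
        call_tables[algo] = path

    all_samples = [p.individual_id for p in ped]
    qc = [
        SampleQcMetrics(s, float(np.round(rng.uniform(0.02, 0.10), 4)),
                        float(np.round(rng.uniform(0.10, 0.22), 4)),
                        float(np.round(rng.uniform(15.5, 25.0), 2)))
        for s in all_samples
    ]
    qc_path = root / "qc_metrics.tsv"
    write_qc_metrics(qc, qc_path)

    segdup, stable = _tracks(cfg)
    segdup_path = root / "tracks" / "segdup.bed"
    stable_path = root / "tracks" / "cn_stable.bed"
    write_track(segdup, segdup_path)
    write_track(stable, stable_path)

    kb_dir = root / "kb"
    _write_knowledge_base(kb_dir, cfg)

    control_calls, n_controls = generate_control_cohort(cfg, rng)
    controls_path = root / "controls.tsv"
    write_cnv_calls(control_calls, controls_path)

    psych = [_psychometrics_for_label(rng, sid, labels[sid]) for sid in sibling_ids]
    psych_path = root / "psychometrics.tsv"
    write_psychometrics(psych, psych_path)

    trios = _trio_prs_tables(cfg, rng)
    prs_path = root / "trio_prs.tsv"
    write_trio_prs(trios, prs_path)

    truth_path = root / "ground_truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("sample_id\tchrom\tstart\tend\tcopy_state\tcategory\texpected_tier"
                 "\tinheritance\tmechanism\n")
        for t in truth:
            fh.write(f"{t.sample_id}\t{t.interval.chrom}\t{t.interval.start}\t{t.interval.end}"
                     f"\t{t.copy_state}\t{t.category}\t{t.expected_tier}\t{t.inheritance}"
                     f"\t{t.mechanism}\n")

    manifest_path = root / "manifest.json"
    manifest = {
        "n_families": cfg.n_families,
        "n_siblings": cfg.n_siblings,
        "n_probands": cfg.n_families,
        "phenotype_margins": {ASD: cfg.n_asd, ATYPICAL: cfg.n_atypical, TYPICAL: cfg.n_typical},
        "n_sibling_carriers": len(cfg.sibling_plants),
        "n_proband_carriers": len(cfg.proband_plants),
        "n_control_individuals": n_controls,
        "callers": list(CALLERS),
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return SyntheticBundle(
        root=root,
        pedigree=pedigree_path,
        call_tables=call_tables,
        qc_metrics=qc_path,
        segdup_track=segdup_path,
        stable_track=stable_path,
        kb_dir=kb_dir,
        controls=controls_path,
        n_control_individuals=n_controls,
        psychometrics=psych_path,
        trio_prs=prs_path,
        ground_truth=truth_path,
        ground_truth_entries=truth,
        manifest=manifest_path,
    )
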