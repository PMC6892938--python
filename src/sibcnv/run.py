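"""End-to-end pipeline orchestration and report assembly.

Chains sample QC -> multi-algorithm consensus -> stringency filters ->
rarity vs controls -> trio inheritance -> tiered classification ->
phenotype labeling -> 2x2 predictive statistics, with per-stage attrition
accounting (records in = records out + itemized drops at every stage).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from .classify import (
    ALL_RELEVANT,
    Classification,
    EXCLUDING_VUS,
    classify_variant,
    carrier_status,
    load_knowledge_base,
)
from .genomic import CnvCall
from .io import (
    read_cnv_calls,
    read_pedigree,
    read_psychometrics,
    read_qc_metrics,
    read_track,
    read_trio_prs,
)
from .outcomes import (
    CONDITION_ASD,
    CONDITION_ASD_OR_ATYPICAL,
    ContingencyTable,
    DiagnosticStats,
    assign_outcome_label,
    build_contingency,
    diagnostic_stats,
)
from .pipeline import (
    ConsensusCnv,
    FilterConfig,
    annotate_inheritance,
    build_consensus,
    is_rare,
    sample_qc,
)
from .ptdt import ptdt_deviations, ptdt_test

logger = logging.getLogger("sibcnv")

CLASS_FILTERS = {
    "all_relevant": ALL_RELEVANT,
    "excluding_vus": EXCLUDING_VUS,
}
CONDITIONS = (CONDITION_ASD, CONDITION_ASD_OR_ATYPICAL)

#: The four Table-style analysis columns: (class filter, condition).
ANALYSIS_COLUMNS = (
    ("all_relevant", CONDITION_ASD),
    ("all_relevant", CONDITION_ASD_OR_ATYPICAL),
    ("excluding_vus", CONDITION_ASD),
    ("excluding_vus", CONDITION_ASD_OR_ATYPICAL),
)


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Paths and knobs for one pipeline run."""

    call_tables: dict[str, Path]
    pedigree: Path
    qc_metrics: Path
    segdup_track: Path
    stable_track: Path
    kb_dir: Path
    controls: Path
    n_control_individuals: int
    psychometrics: Path
    trio_prs: Path | None = None
    out_dir: Path = Path("sibcnv_out")
    cohort_mode: str = "BSRC"
    filters: FilterConfig = field(default_factory=FilterConfig)
    qc_override: set[str] = field(default_factory=set)

    @classmethod
    def from_bundle(cls, bundle, out_dir: str | Path, **kwargs) -> "RunConfig":
        """Build a run configuration straight from a synthetic bundle."""
        return cls(
            call_tables=dict(bundle.call_tables),
            pedigree=bundle.pedigree,
            qc_metrics=bundle.qc_metrics,
            segdup_track=bundle.segdup_track,
            stable_track=bundle.stable_track,
            kb_dir=bundle.kb_dir,
            controls=bundle.controls,
            n_control_individuals=bundle.n_control_individuals,
            psychometrics=bundle.psychometrics,
            trio_prs=bundle.trio_prs,
            out_dir=Path(out_dir),
            **kwargs,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a JSON or YAML run configuration file."""
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yml", ".yaml"):
            try:
                import yaml
            except ImportError as exc:  # pragma: no cover
                raise StageError("config", exc)
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        base = path.parent

        def p(key, default=None):
            v = data.get(key, default)
            return None if v is None else base / v

        filters = FilterConfig(**{
            k: (frozenset(v) if isinstance(v, list) else v)
            for k, v in data.get("filters", {}).items()
        })
        return cls(
            call_tables={a: base / f for a, f in data["call_tables"].items()},
            pedigree=p("pedigree"),
            qc_metrics=p("qc_metrics"),
            segdup_track=p("segdup_track"),
            stable_track=p("stable_track"),
            kb_dir=p("kb_dir"),
            controls=p("controls"),
            n_control_individuals=int(data["n_control_individuals"]),
            psychometrics=p("psychometrics"),
            trio_prs=p("trio_prs"),
            out_dir=Path(data.get("out_dir", "sibcnv_out")),
            cohort_mode=data.get("cohort_mode", "BSRC"),
            qc_override=set(data.get("qc_override", [])),
        )

    def validate(self) -> None:
        required = {
            "pedigree": self.pedigree,
            "qc_metrics": self.qc_metrics,
            "segdup_track": self.segdup_track,
            "stable_track": self.stable_track,
            "kb_dir": self.kb_dir,
            "controls": self.controls,
            "psychometrics": self.psychometrics,
            **{f"calls[{a}]": p for a, p in self.call_tables.items()},
        }
        missing = [name for name, p in required.items() if p is None or not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing inputs: {', '.join(sorted(missing))}")
        if self.cohort_mode not in ("BSRC", "SSC"):
            raise ValueError(f"unknown cohort mode {self.cohort_mode!r}")
        if self.n_control_individuals < 1:
            raise ValueError("n_control_individuals must be >= 1")


@dataclass
class PipelineResult:
    consensus: list[ConsensusCnv]
    classifications: dict[int, Classification]  # index into consensus
    labels: dict[str, str]
    carrier_flags: dict[str, dict[str, bool]]  # class filter -> sibling -> carrier
    tables: dict[tuple[str, str], ContingencyTable]
    stats: dict[tuple[str, str], DiagnosticStats]
    attrition: dict[str, dict]
    ptdt: dict[str, dict] | None


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(name, exc) from exc

    return wrap


def run_pipeline(cfg: RunConfig, write_outputs: bool = True) -> PipelineResult:
    """Execute the full chain and (optionally) write reports to ``cfg.out_dir``."""
    cfg.validate()
    attrition: dict[str, dict] = {}

    # -- sample QC ------------------------------------------------------------
    metrics = _stage("qc")(read_qc_metrics, cfg.qc_metrics)
    qc_results = [sample_qc(m, cfg.filters) for m in metrics]
    passed = {r.sample_id for r in qc_results if r.passed} | cfg.qc_override
    failed = {r.sample_id: list(r.failed_criteria) for r in qc_results
              if not r.passed and r.sample_id not in cfg.qc_override}
    for sid, reasons in failed.items():
        logger.info("qc sample=%s action=excluded reason=%s", sid, ",".join(reasons))
    attrition["sample_qc"] = {
        "in": len(qc_results), "out": len(passed),
        "dropped": {sid: r for sid, r in sorted(failed.items())},
    }

    # -- raw calls -> consensus ----------------------------------------------
    calls: list[CnvCall] = []
    for algo, path in sorted(cfg.call_tables.items()):
        calls.extend(_stage("read_calls")(read_cnv_calls, path))
    kept_calls = [c for c in calls if c.sample_id in passed]
    consensus = _stage("consensus")(build_consensus, kept_calls, cfg.filters)
    attrition["consensus"] = {
        "in_calls": len(calls),
        "in_calls_qc_passed": len(kept_calls),
        "out_consensus_cnvs": len(consensus),
    }

    # -- stringency filters ---------------------------------------------------
    segdup = _stage("filters")(read_track, cfg.segdup_track, "segdup")
    stable = _stage("filters")(read_track, cfg.stable_track, "cn_stable")
    from .pipeline import apply_stringency_filters

    consensus = apply_stringency_filters(consensus, segdup, stable, cfg.filters)
    survivors = [c for c in consensus if c.survives_filters]
    flag_counts: dict[str, int] = {}
    for c in consensus:
        for f in c.filter_flags:
            flag_counts[f] = flag_counts.get(f, 0) + 1
            logger.info("filter sample=%s locus=%s:%d-%d action=flagged reason=%s",
                        c.sample_id, c.interval.chrom, c.interval.start, c.interval.end, f)
    attrition["stringency_filters"] = {
        "in": len(consensus), "out": len(survivors),
        "dropped_by_flag": dict(sorted(flag_counts.items())),
    }

    # -- rarity ---------------------------------------------------------------
    control_calls = _stage("rarity")(read_cnv_calls, cfg.controls)
    rare = [c for c in survivors
            if is_rare(c, control_calls, cfg.n_control_individuals, cfg.filters)]
    attrition["rarity"] = {
        "in": len(survivors), "out": len(rare),
        "dropped_common": len(survivors) - len(rare),
    }

    # -- inheritance ----------------------------------------------------------
    ped = _stage("inheritance")(read_pedigree, cfg.pedigree)
    parents = {r.individual_id: (r.mother_id, r.father_id) for r in ped}
    by_sample: dict[str, list[ConsensusCnv]] = {}
    for c in consensus:
        by_sample.setdefault(c.sample_id, []).append(c)
    annotate_inheritance(rare, by_sample, parents, passed, cfg.filters)

    # -- classification (blind to phenotype by construction) ------------------
    kb = _stage("classify")(load_knowledge_base, cfg.kb_dir)
    classifications: dict[int, Classification] = {}
    tier_counts: dict[str, int] = {}
    rare_ids = {id(c) for c in rare}
    for idx, cnv in enumerate(consensus):
        if id(cnv) in rare_ids:
            cls = classify_variant(cnv, kb)
            classifications[idx] = cls
            tier_counts[cls.tier] = tier_counts.get(cls.tier, 0) + 1
    attrition["classification"] = {"in": len(rare), "by_tier": dict(sorted(tier_counts.items()))}

    # -- phenotype labels ------------------------------------------------------
    psych = _stage("labels")(read_psychometrics, cfg.psychometrics)
    labels = {
        rec.individual_id: assign_outcome_label(rec, cfg.cohort_mode).label for rec in psych
    }
    siblings = [r.individual_id for r in ped if r.role == "sibling"]
    unlabeled = [s for s in siblings if s not in labels]
    if unlabeled:
        raise StageError("labels", ValueError(f"unlabeled siblings: {unlabeled[:5]}"))

    # -- carrier flags, contingency tables, statistics -------------------------
    per_sibling: dict[str, list[Classification]] = {s: [] for s in siblings}
    for idx, cls in classifications.items():
        sid = consensus[idx].sample_id
        if sid in per_sibling:
            per_sibling[sid].append(cls)

    carrier_flags = {
        name: {s: carrier_status(per_sibling[s], tiers) for s in siblings}
        for name, tiers in CLASS_FILTERS.items()
    }
    tables: dict[tuple[str, str], ContingencyTable] = {}
    stats: dict[tuple[str, str], DiagnosticStats] = {}
    for cf_name, condition in ANALYSIS_COLUMNS:
        t = build_contingency(carrier_flags[cf_name], labels, condition)
        tables[(cf_name, condition)] = t
        stats[(cf_name, condition)] = diagnostic_stats(t)

    # -- optional pTDT ---------------------------------------------------------
    ptdt_out = None
    if cfg.trio_prs is not None and Path(cfg.trio_prs).exists():
        trios = _stage("ptdt")(read_trio_prs, cfg.trio_prs)
        groups: dict[str, list] = {}
        for t in trios:
            groups.setdefault(t.child_group, []).append(t)
        ptdt_out = {}
        for group, gts in sorted(groups.items()):
            res = ptdt_test(ptdt_deviations(gts), group)
            ptdt_out[group] = {
                "n": res.n,
                "mean_deviation": res.mean_deviation,
                "t_stat": res.t_stat,
                "p_value": res.p_value,
            }

    result = PipelineResult(
        consensus=consensus,
        classifications=classifications,
        labels=labels,
        carrier_flags=carrier_flags,
        tables=tables,
        stats=stats,
        attrition=attrition,
        ptdt=ptdt_out,
    )
    if write_outputs:
        _write_reports(cfg, result)
    return result


def _estimate_dict(e) -> dict | None:
    if e is None:
        return {"undefined": True}
    return {"point": e.point, "ci_lo": e.lo, "ci_hi": e.hi, "k": e.k, "n": e.n}


def stats_payload(result: PipelineResult) -> dict:
    """Machine-readable summary of all contingency tables and measures."""
    columns = []
    for cf_name, condition in ANALYSIS_COLUMNS:
        t = result.tables[(cf_name, condition)]
        s = result.stats[(cf_name, condition)]
        columns.append({
            "class_filter": cf_name,
            "condition": condition,
            "table": {"tp": t.tp, "fp": t.fp, "fn": t.fn, "tn": t.tn, "total": t.total},
            "measures": {
                "sensitivity": _estimate_dict(s.sensitivity),
                "specificity": _estimate_dict(s.specificity),
                "ppv": _estimate_dict(s.ppv),
                "npv": _estimate_dict(s.npv),
            },
            "ci_level": 0.95,
        })
    payload = {"columns": columns, "attrition": result.attrition}
    if result.ptdt is not None:
        payload["ptdt"] = result.ptdt
    return payload


def _write_reports(cfg: RunConfig, result: PipelineResult) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with open(out / "stats.json", "w") as fh:
        json.dump(stats_payload(result), fh, indent=2, sort_keys=True)
        fh.write("\n")

    with open(out / "classified_variants.tsv", "w") as fh:
        fh.write("sample_id\tchrom\tstart\tend\tcopy_state\talgorithms\tn_probes"
                 "\tfilter_flags\trarity\tcontrol_frequency\tinheritance\ttier\tbasis\n")
        for idx, cnv in enumerate(result.consensus):
            cls = result.classifications.get(idx)
            fh.write("\t".join([
                cnv.sample_id, cnv.interval.chrom, str(cnv.interval.start),
                str(cnv.interval.end), cnv.copy_state, ",".join(sorted(cnv.algorithms)),
                str(cnv.n_probes), ",".join(sorted(cnv.filter_flags)) or ".",
                cnv.rarity,
                "NA" if cnv.control_frequency is None else f"{cnv.control_frequency:.6f}",
                cnv.inheritance,
                cls.tier if cls else ".",
                ";".join(cls.basis) if cls and cls.basis else ".",
            ]) + "\n")

    # Table-1-shaped TSV: one row per statistic, one column per analysis cell
    headers = [f"{cf}:{cond}" for cf, cond in ANALYSIS_COLUMNS]
    rows: list[list[str]] = []
    for measure in ("sensitivity", "specificity", "ppv", "npv"):
        row = [measure]
        for key in ANALYSIS_COLUMNS:
            e = getattr(result.stats[key], measure)
            row.append("undefined" if e is None else f"{e.point:.2f} ({e.lo:.2f}-{e.hi:.2f})")
        rows.append(row)
    for count in ("tp", "fp", "fn", "tn", "total"):
        row = [count]
        for key in ANALYSIS_COLUMNS:
            row.append(str(getattr(result.tables[key], count)))
        rows.append(row)
    with open(out / "table1.tsv", "w") as fh:
        fh.write("\t".join(["statistic"] + headers) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")
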