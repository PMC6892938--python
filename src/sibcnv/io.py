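"""Readers and writers for the plain-text formats the pipeline consumes.

CNV call tables are TSVs with a header line
``sample_id chrom start end type n_probes algorithm`` whose coordinates are
1-based inclusive (array-software convention); they are converted to the
package-internal 0-based half-open representation on read, and converted
back on write, so a write/read round trip is lossless. BED tracks are
0-based half-open and kept as-is. Pedigrees are PED-like TSVs extended with
``role`` and ``phenotype`` columns.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .genomic import (
    AnnotationTrack,
    CnvCall,
    GenomicInterval,
    GenomicsError,
    TrackRecord,
    parse_copy_state,
)

CNV_TSV_COLUMNS = ["sample_id", "chrom", "start", "end", "type", "n_probes", "algorithm"]
PED_COLUMNS = [
    "family_id",
    "individual_id",
    "father_id",
    "mother_id",
    "sex",
    "role",
    "phenotype",
]

ROLES = frozenset({"proband", "sibling", "mother", "father"})
PHENOTYPES = frozenset({"ASD", "atypical", "typical", "unknown"})


class FileFormatError(ValueError):
    """A malformed row; the message names the file, line and offending field."""

    def __init__(self, path: str | Path, line_no: int, field: str, detail: str):
        super().__init__(f"{path}:{line_no}: bad field {field!r}: {detail}")
        self.path = str(path)
        self.line_no = line_no
        self.field = field


@dataclass(frozen=True)
class PedigreeRecord:
    family_id: str
    individual_id: str
    father_id: str | None
    mother_id: str | None
    sex: int  # 1 = male, 2 = female, 0 = unknown
    role: str
    phenotype: str


def _parse_int(value: str, path, line_no: int, field: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise FileFormatError(path, line_no, field, f"not an integer: {value!r}") from None


def read_cnv_calls(path: str | Path) -> list[CnvCall]:
    """Read a 1-based-inclusive CNV call TSV into internal coordinates."""
    calls: list[CnvCall] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != CNV_TSV_COLUMNS:
            raise FileFormatError(path, 1, "header", f"expected {CNV_TSV_COLUMNS}, got {header}")
        for line_no, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(CNV_TSV_COLUMNS):
                raise FileFormatError(path, line_no, "row", f"expected {len(CNV_TSV_COLUMNS)} columns")
            start1 = _parse_int(row[2], path, line_no, "start")
            end1 = _parse_int(row[3], path, line_no, "end")
            if end1 < start1:
                raise FileFormatError(path, line_no, "end", f"end {end1} < start {start1}")
            try:
                # 1-based inclusive -> 0-based half-open: shift start only.
                interval = GenomicInterval(row[1], start1 - 1, end1)
                copy_state = parse_copy_state(row[4])
            except GenomicsError as exc:
                raise FileFormatError(path, line_no, "chrom/type", str(exc)) from None
            calls.append(
                CnvCall(
                    sample_id=row[0],
                    interval=interval,
                    copy_state=copy_state,
                    n_probes=_parse_int(row[5], path, line_no, "n_probes"),
                    algorithm=row[6],
                )
            )
    return calls


def write_cnv_calls(calls: Iterable[CnvCall], path: str | Path) -> None:
    """Write calls as a 1-based-inclusive TSV (inverse of :func:`read_cnv_calls`)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CNV_TSV_COLUMNS)
        for c in calls:
            short = "del" if c.copy_state == "deletion" else "dup"
            writer.writerow(
                [c.sample_id, c.interval.chrom, c.interval.start + 1, c.interval.end,
                 short, c.n_probes, c.algorithm]
            )


def read_track(path: str | Path, name: str | None = None) -> AnnotationTrack:
    """Read a BED (3+ column, 0-based half-open) file as an annotation track."""
    records: list[TrackRecord] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FileFormatError(path, line_no, "row", "BED needs >= 3 columns")
            start = _parse_int(parts[1], path, line_no, "start")
            end = _parse_int(parts[2], path, line_no, "end")
            try:
                interval = GenomicInterval(parts[0], start, end)
            except GenomicsError as exc:
                raise FileFormatError(path, line_no, "interval", str(exc)) from None
            rec_name = parts[3] if len(parts) > 3 else None
            records.append(TrackRecord(interval, rec_name, tuple(parts[4:])))
    return AnnotationTrack(name or Path(path).stem, records)


def write_track(track: AnnotationTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in track.records:
            cols = [rec.interval.chrom, str(rec.interval.start), str(rec.interval.end)]
            if rec.name is not None or rec.fields:
                cols.append(rec.name or ".")
            cols.extend(rec.fields)
            fh.write("\t".join(cols) + "\n")


def read_pedigree(path: str | Path) -> list[PedigreeRecord]:
    records: list[PedigreeRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != PED_COLUMNS:
            raise FileFormatError(path, 1, "header", f"expected {PED_COLUMNS}, got {header}")
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(PED_COLUMNS):
                raise FileFormatError(path, line_no, "row", f"expected {len(PED_COLUMNS)} columns")
            sex = _parse_int(row[4], path, line_no, "sex")
            if sex not in (0, 1, 2):
                raise FileFormatError(path, line_no, "sex", f"must be 0/1/2, got {sex}")
            if row[5] not in ROLES:
                raise FileFormatError(path, line_no, "role", f"unknown role {row[5]!r}")
            if row[6] not in PHENOTYPES:
                raise FileFormatError(path, line_no, "phenotype", f"unknown phenotype {row[6]!r}")
            records.append(
                PedigreeRecord(
                    family_id=row[0],
                    individual_id=row[1],
                    father_id=row[2] if row[2] != "0" else None,
                    mother_id=row[3] if row[3] != "0" else None,
                    sex=sex,
                    role=row[5],
                    phenotype=row[6],
                )
            )
    return records


def write_pedigree(records: Iterable[PedigreeRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PED_COLUMNS)
        for r in records:
            writer.writerow(
                [r.family_id, r.individual_id, r.father_id or "0", r.mother_id or "0",
                 r.sex, r.role, r.phenotype]
            )


# --- tabular side inputs (QC metrics, psychometrics, trio PRS) ---------------

QC_COLUMNS = ["sample_id", "waviness_sd", "mapd", "snp_qc"]

PSYCHOMETRIC_COLUMNS = [
    "individual_id", "ados_css", "msel_elc", "msel_receptive_language",
    "msel_expressive_language", "vabs_abc", "vabs_subscale_min", "srs_t",
    "cbcl_t", "clinician_asd_flag", "clinician_atypical_flag", "adir_positive",
]

TRIO_PRS_COLUMNS = ["family_id", "child_id", "child_group",
                    "prs_child", "prs_mother", "prs_father"]


def _opt_float(value: str) -> float | None:
    return None if value in ("", "NA", ".") else float(value)


def _opt_int(value: str) -> int | None:
    return None if value in ("", "NA", ".") else int(value)


def _opt_bool(value: str) -> bool | None:
    return None if value in ("", "NA", ".") else value in ("1", "True", "true")


def read_qc_metrics(path):
    """Read a sample QC metrics TSV into SampleQcMetrics records."""
    from .pipeline import SampleQcMetrics

    out = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != QC_COLUMNS:
            raise FileFormatError(path, 1, "header", f"expected {QC_COLUMNS}, got {header}")
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(QC_COLUMNS):
                raise FileFormatError(path, line_no, "row", f"expected {len(QC_COLUMNS)} columns")
            out.append(SampleQcMetrics(row[0], _opt_float(row[1]), _opt_float(row[2]),
                                       _opt_float(row[3])))
    return out


def write_qc_metrics(metrics, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(QC_COLUMNS)
        for m in metrics:
            writer.writerow([m.sample_id,
                             "NA" if m.waviness_sd is None else f"{m.waviness_sd:.4f}",
                             "NA" if m.mapd is None else f"{m.mapd:.4f}",
                             "NA" if m.snp_qc is None else f"{m.snp_qc:.2f}"])


def read_psychometrics(path):
    """Read a psychometric score TSV into PsychometricRecord objects."""
    from .outcomes import PsychometricRecord

    out = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != PSYCHOMETRIC_COLUMNS:
            raise FileFormatError(path, 1, "header",
                                  f"expected {PSYCHOMETRIC_COLUMNS}, got {header}")
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(PSYCHOMETRIC_COLUMNS):
                raise FileFormatError(path, line_no, "row",
                                      f"expected {len(PSYCHOMETRIC_COLUMNS)} columns")
            out.append(PsychometricRecord(
                individual_id=row[0],
                ados_css=_opt_int(row[1]),
                msel_elc=_opt_float(row[2]),
                msel_receptive_language=_opt_float(row[3]),
                msel_expressive_language=_opt_float(row[4]),
                vabs_abc=_opt_float(row[5]),
                vabs_subscale_min=_opt_float(row[6]),
                srs_t=_opt_float(row[7]),
                cbcl_t=_opt_float(row[8]),
                clinician_asd_flag=_opt_bool(row[9]),
                clinician_atypical_flag=_opt_bool(row[10]),
                adir_positive=_opt_bool(row[11]),
            ))
    return out


def write_psychometrics(records, path) -> None:
    def fmt(v):
        if v is None:
            return "NA"
        if isinstance(v, bool):
            return "1" if v else "0"
        if isinstance(v, float):
            return f"{v:g}"
        return str(v)

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PSYCHOMETRIC_COLUMNS)
        for r in records:
            writer.writerow([r.individual_id, fmt(r.ados_css), fmt(r.msel_elc),
                             fmt(r.msel_receptive_language), fmt(r.msel_expressive_language),
                             fmt(r.vabs_abc), fmt(r.vabs_subscale_min), fmt(r.srs_t),
                             fmt(r.cbcl_t), fmt(r.clinician_asd_flag),
                             fmt(r.clinician_atypical_flag), fmt(r.adir_positive)])


def read_trio_prs(path):
    """Read a trio PRS TSV into TrioPrs records."""
    from .ptdt import TrioPrs

    out = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != TRIO_PRS_COLUMNS:
            raise FileFormatError(path, 1, "header",
                                  f"expected {TRIO_PRS_COLUMNS}, got {header}")
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(TRIO_PRS_COLUMNS):
                raise FileFormatError(path, line_no, "row",
                                      f"expected {len(TRIO_PRS_COLUMNS)} columns")
            out.append(TrioPrs(row[0], row[1], row[2],
                               float(row[3]), float(row[4]), float(row[5])))
    return out


def write_trio_prs(trios, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TRIO_PRS_COLUMNS)
        for t in trios:
            writer.writerow([t.family_id, t.child_id, t.child_group,
                             f"{t.prs_child:.6f}", f"{t.prs_mother:.6f}",
                             f"{t.prs_father:.6f}"])
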