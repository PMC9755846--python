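"""File formats, run configuration and report writing.

Two deletion-interval dialects are supported and must be named explicitly
(no auto-detection — silent off-by-one coordinate errors are worse than a
flag):

* ``bed0`` — BED3+: chrom, start, end (0-based half-open), name=sample_id,
  optional source and zygosity columns; converted on read to the package's
  1-based inclusive convention (start + 1, end unchanged).
* ``tsv1`` — sample_id, chrom, start, end already 1-based inclusive,
  optional source column (mirrors how published coordinate tables are
  printed).

Ct plate data is a CSV with columns sample_id, assay (target|reference),
replicate, ct (float or NA); pairs are a CSV with tumor_id, normal_id.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Any, Iterable

import pandas as pd
import yaml

from .errors import InputError
from .intervals import (
    DeletionCohort,
    DeletionRecord,
    GenomicInterval,
    Source,
    Zygosity,
)
from .qpcr import Assay, CtMeasurement, INFORMATIVE_CT_CUTOFF

__all__ = [
    "RunConfig",
    "load_config",
    "parse_region",
    "read_deletion_bed",
    "write_deletion_bed",
    "read_ct_csv",
    "read_pairs_csv",
    "round_half_up",
    "write_json_report",
]


@dataclass(frozen=True)
class RunConfig:
    """All analysis thresholds in one place; defaults are the assay's
    published operating constants."""

    seed: int = 20220917
    alpha: float = 0.05
    efficiency: float = 2.0
    min_fraction: float = 0.8
    min_length: int = 1000
    informative_ct_cutoff: float = INFORMATIVE_CT_CUTOFF

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise InputError("alpha must be in (0, 1)")
        if self.informative_ct_cutoff <= 0:
            raise InputError("informative_ct_cutoff must be > 0")


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config; unknown keys are rejected."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise InputError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


_REGION_RE = re.compile(r"^([^:]+):([\d,]+)-([\d,]+)$")


def parse_region(text: str) -> GenomicInterval:
    """Parse ``chrom:start-end`` (1-based inclusive, commas allowed)."""
    m = _REGION_RE.match(text.strip())
    if not m:
        raise InputError(f"cannot parse region {text!r} (expected chrom:start-end)")
    chrom, start, end = m.group(1), m.group(2), m.group(3)
    return GenomicInterval(chrom, int(start.replace(",", "")), int(end.replace(",", "")))


def _parse_enum(cls, value: str, line_no: int):
    try:
        return cls(value)
    except ValueError as exc:
        raise InputError(f"line {line_no}: unknown {cls.__name__.lower()} {value!r}") from exc


def read_deletion_bed(
    path: str | Path,
    dialect: str,
    locus: GenomicInterval | None = None,
    genome_build: str = "hg19",
) -> DeletionCohort:
    """Read a deletion cohort; ``dialect`` is ``bed0`` or ``tsv1``.

    Coordinates are normalized to 1-based inclusive.  When ``locus`` is
    omitted it is inferred as the span of the records (single-chromosome
    files only).  Malformed rows raise with their line number.
    """
    if dialect not in ("bed0", "tsv1"):
        raise InputError(f"unknown dialect {dialect!r} (use bed0 or tsv1)")
    records: list[DeletionRecord] = []
    path = Path(path)
    for line_no, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        try:
            if dialect == "bed0":
                if len(fields) < 4:
                    raise InputError("expected >= 4 columns (chrom start end sample)")
                chrom, b_start, b_end, sid = fields[0], int(fields[1]), int(fields[2]), fields[3]
                start, end = b_start + 1, b_end
            else:
                if len(fields) < 4:
                    raise InputError("expected >= 4 columns (sample chrom start end)")
                sid, chrom, start, end = fields[1 - 1], fields[1], int(fields[2]), int(fields[3])
            source = _parse_enum(Source, fields[4], line_no) if len(fields) > 4 else Source.UNKNOWN
            zyg = _parse_enum(Zygosity, fields[5], line_no) if len(fields) > 5 else Zygosity.UNKNOWN
            if end < start:
                raise InputError(f"coordinate inversion {chrom}:{start}-{end}")
            records.append(DeletionRecord(sid, GenomicInterval(chrom, start, end), source, zyg))
        except (ValueError, InputError) as exc:
            raise InputError(f"{path.name} line {line_no}: {exc}") from exc
    if not records:
        raise InputError(f"{path.name}: no deletion records")
    if locus is None:
        chroms = {r.interval.chrom for r in records}
        if len(chroms) != 1:
            raise InputError("multiple chromosomes present; give an explicit locus")
        locus = GenomicInterval(
            chroms.pop(),
            min(r.interval.start for r in records),
            max(r.interval.end for r in records),
        )
    return DeletionCohort(tuple(records), locus, genome_build)


def write_deletion_bed(cohort: DeletionCohort, path: str | Path, dialect: str = "bed0") -> None:
    """Write a cohort back out in either dialect (inverse of the reader)."""
    if dialect not in ("bed0", "tsv1"):
        raise InputError(f"unknown dialect {dialect!r}")
    lines = []
    for r in cohort.records:
        iv = r.interval
        if dialect == "bed0":
            cols = [iv.chrom, str(iv.start - 1), str(iv.end), r.sample_id]
        else:
            cols = [r.sample_id, iv.chrom, str(iv.start), str(iv.end)]
        cols += [r.source.value, r.zygosity.value]
        lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + "\n")


def read_ct_csv(path: str | Path) -> list[CtMeasurement]:
    """Read per-well Ct values: sample_id, assay, replicate, ct (float or NA)."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    required = {"sample_id", "assay", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"Ct CSV missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        ct = None if pd.isna(row.ct) else float(row.ct)
        try:
            assay = Assay(str(row.assay))
        except ValueError as exc:
            raise InputError(f"unknown assay {row.assay!r}") from exc
        out.append(CtMeasurement(str(row.sample_id), assay, int(row.replicate), ct))
    return out


def read_pairs_csv(path: str | Path) -> dict[str, str]:
    """Read the tumor-to-paired-normal sample map (tumor_id, normal_id)."""
    df = pd.read_csv(path, dtype=str)
    if not {"tumor_id", "normal_id"} <= set(df.columns):
        raise InputError("pairs CSV needs tumor_id and normal_id columns")
    return dict(zip(df["tumor_id"], df["normal_id"]))


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding, matching how reports print values."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _stable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _stable(obj[k]) for k in obj}
    if isinstance(obj, (list, tuple)):
        return [_stable(v) for v in obj]
    if isinstance(obj, float):
        return round(obj, 6)
    return obj


def write_json_report(report: dict[str, Any], path: str | Path) -> None:
    """Serialize a run report with stable field order and fixed precision,
    so identical runs produce byte-identical files."""
    payload = dict(report)
    payload.setdefault("warnings", [])
    Path(path).write_text(json.dumps(_stable(payload), indent=2, sort_keys=False) + "\n")
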