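"""Readers and writers for the on-disk formats the pipeline touches.

Supported genotype dialects:

* ``genepop`` — 2- or 3-digit allele codes, one locus per line, ``POP``
  sections; code ``00``/``000`` is missing.
* ``vcf`` — diallelic SNP records; REF maps to allele 0, ALT to allele 1;
  read via :mod:`pysam`.
* ``dosage_csv`` — samples x loci table of ALT-allele dosages 0/1/2/NA.
* ``tworow_csv`` — two consecutive rows per sample, one allele per row,
  values are microsatellite allele lengths; 0/NA is missing.

``genepop`` and ``dosage_csv`` round-trip bit-identically (allele pairs are
stored unordered and written in sorted order).
"""

from __future__ import annotations

import csv
import io as _stdio
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import MISSING, GenotypeMatrix, LifeTable, Pedigree, SampleRecord

__all__ = [
    "ParseError",
    "read_genotypes",
    "write_genotypes",
    "read_samples",
    "write_samples",
    "read_life_table",
    "write_life_table",
    "write_pedigree",
    "write_truth",
]

DIALECTS = ("genepop", "vcf", "dosage_csv", "tworow_csv")


class ParseError(ValueError):
    """Malformed input file; carries the offending line number."""

    def __init__(self, path, line_no, message):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = str(path)
        self.line_no = line_no


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def read_genotypes(path, dialect: str) -> GenotypeMatrix:
    """Read a genotype file in the named dialect."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    return {
        "genepop": _read_genepop,
        "vcf": _read_vcf,
        "dosage_csv": _read_dosage_csv,
        "tworow_csv": _read_tworow_csv,
    }[dialect](Path(path))


def write_genotypes(matrix: GenotypeMatrix, path, dialect: str) -> None:
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    {
        "genepop": _write_genepop,
        "vcf": _write_vcf,
        "dosage_csv": _write_dosage_csv,
        "tworow_csv": _write_tworow_csv,
    }[dialect](matrix, Path(path))


# ---------------------------------------------------------------------------
# genepop
# ---------------------------------------------------------------------------

def _read_genepop(path: Path) -> GenotypeMatrix:
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise ParseError(path, 1, "genepop file too short")
    locus_ids: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        # loci may be one per line or comma-separated
        locus_ids.extend(t.strip() for t in lines[i].split(",") if t.strip())
        i += 1
    if i == len(lines):
        raise ParseError(path, i, "no POP line found")
    sample_ids: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    digits = None
    for line_no in range(i, len(lines)):
        line = lines[line_no]
        if not line.strip():
            continue
        if line.strip().upper() == "POP":
            continue
        if "," not in line:
            raise ParseError(path, line_no + 1, "expected 'sample_id , genotypes'")
        name, geno = line.split(",", 1)
        codes = geno.split()
        if len(codes) != len(locus_ids):
            raise ParseError(
                path, line_no + 1,
                f"expected {len(locus_ids)} genotype codes, got {len(codes)}",
            )
        calls = []
        for code in codes:
            if len(code) not in (4, 6) or not code.isdigit():
                raise ParseError(path, line_no + 1, f"bad genotype code {code!r}")
            d = len(code) // 2
            if digits is None:
                digits = d
            elif d != digits:
                raise ParseError(path, line_no + 1, "mixed 2- and 3-digit codes")
            a, b = int(code[:d]), int(code[d:])
            if (a == 0) != (b == 0):
                raise ParseError(
                    path, line_no + 1,
                    f"half-missing genotype code {code!r} (mixed ploidy unsupported)",
                )
            calls.append((MISSING, MISSING) if a == 0 else (a - 1, b - 1))
        sample_ids.append(name.strip())
        rows.append(calls)
    arr = np.array(rows, dtype=np.int16) if rows else np.empty((0, len(locus_ids), 2), np.int16)
    arr = np.sort(arr, axis=2)
    n_alleles = [max(2, int(arr[:, j][arr[:, j] >= 0].max(initial=1)) + 1) for j in range(len(locus_ids))]
    meta = pd.DataFrame({"alleles": [tuple(range(k)) for k in n_alleles]})
    return GenotypeMatrix(sample_ids, locus_ids, arr, meta)


def _write_genepop(matrix: GenotypeMatrix, path: Path) -> None:
    max_allele = int(matrix.calls.max(initial=0))
    digits = 3 if max_allele + 1 > 99 else 2
    fmt = f"0{digits}d"
    out = ["cohortnb genotypes"]
    out.extend(matrix.locus_ids)
    out.append("POP")
    for i, sid in enumerate(matrix.sample_ids):
        codes = []
        for j in range(matrix.n_loci):
            a, b = sorted(matrix.calls[i, j])
            if a == MISSING:
                codes.append("0" * (2 * digits))
            else:
                codes.append(f"{a + 1:{fmt}}{b + 1:{fmt}}")
        out.append(f"{sid} , " + " ".join(codes))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# dosage CSV
# ---------------------------------------------------------------------------

def _read_dosage_csv(path: Path) -> GenotypeMatrix:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(path, 1, "empty file") from None
        locus_ids = header[1:]
        sample_ids, rows = [], []
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ParseError(path, line_no, f"expected {len(header)} fields, got {len(row)}")
            sample_ids.append(row[0])
            calls = []
            for val in row[1:]:
                v = val.strip()
                if v in ("NA", "", "."):
                    calls.append((MISSING, MISSING))
                elif v in ("0", "1", "2"):
                    d = int(v)
                    calls.append(((0, 0), (0, 1), (1, 1))[d])
                else:
                    raise ParseError(path, line_no, f"bad dosage value {v!r}")
            rows.append(calls)
    arr = np.array(rows, dtype=np.int16) if rows else np.empty((0, len(locus_ids), 2), np.int16)
    meta = pd.DataFrame({"alleles": [(0, 1)] * len(locus_ids)})
    return GenotypeMatrix(sample_ids, locus_ids, arr, meta)


def _write_dosage_csv(matrix: GenotypeMatrix, path: Path) -> None:
    buf = _stdio.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["sample_id"] + list(matrix.locus_ids))
    dos = matrix.dosage()
    for i, sid in enumerate(matrix.sample_ids):
        row = [sid] + ["NA" if np.isnan(v) else str(int(v)) for v in dos[i]]
        writer.writerow(row)
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# two-row CSV (microsatellite allele lengths)
# ---------------------------------------------------------------------------

def _read_tworow_csv(path: Path) -> GenotypeMatrix:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(path, 1, "empty file") from None
        locus_ids = header[1:]
        raw_rows = [(ln, row) for ln, row in enumerate(reader, start=2) if row]
    if len(raw_rows) % 2:
        raise ParseError(path, raw_rows[-1][0], "odd number of allele rows")
    sample_ids: list[str] = []
    allele_rows: list[list[Optional[int]]] = []
    for ln, row in raw_rows:
        if len(row) != len(locus_ids) + 1:
            raise ParseError(path, ln, f"expected {len(locus_ids) + 1} fields, got {len(row)}")
        vals: list[Optional[int]] = []
        for v in row[1:]:
            v = v.strip()
            if v in ("NA", "", "0", "."):
                vals.append(None)
            else:
                try:
                    vals.append(int(v))
                except ValueError:
                    raise ParseError(path, ln, f"bad allele length {v!r}") from None
        allele_rows.append(vals)
        sample_ids.append(row[0])
    for i in range(0, len(sample_ids), 2):
        if sample_ids[i] != sample_ids[i + 1]:
            raise ParseError(path, raw_rows[i + 1][0],
                             f"row pair mismatch: {sample_ids[i]!r} vs {sample_ids[i + 1]!r}")
    ids = sample_ids[::2]
    n, L = len(ids), len(locus_ids)
    lengths = [sorted({r[j] for r in allele_rows if r[j] is not None}) for j in range(L)]
    index = [{v: k for k, v in enumerate(lv)} for lv in lengths]
    arr = np.full((n, L, 2), MISSING, dtype=np.int16)
    for i in range(n):
        for j in range(L):
            a, b = allele_rows[2 * i][j], allele_rows[2 * i + 1][j]
            if (a is None) != (b is None):
                raise ParseError(path, raw_rows[2 * i][0],
                                 f"half-missing genotype at locus {locus_ids[j]}")
            if a is not None:
                arr[i, j] = sorted((index[j][a], index[j][b]))
    meta = pd.DataFrame({"alleles": [tuple(lv) if lv else (0, 1) for lv in lengths]})
    return GenotypeMatrix(ids, locus_ids, arr, meta)


def _write_tworow_csv(matrix: GenotypeMatrix, path: Path) -> None:
    labels = []
    for j in range(matrix.n_loci):
        al = matrix.locus_meta["alleles"].iloc[j] if "alleles" in matrix.locus_meta else None
        # allele labels usable as microsatellite lengths must be positive
        # integers (0 is the missing code in this dialect)
        if al and all(isinstance(a, (int, np.integer)) and a > 0 for a in al):
            labels.append(list(al))
        else:
            labels.append(None)
    buf = _stdio.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["sample_id"] + list(matrix.locus_ids))
    for i, sid in enumerate(matrix.sample_ids):
        for slot in (0, 1):
            row = [sid]
            for j in range(matrix.n_loci):
                a = sorted(matrix.calls[i, j])[slot]
                if a == MISSING:
                    row.append("NA")
                else:
                    lab = labels[j][a] if labels[j] is not None else a + 1
                    row.append(str(lab))
            writer.writerow(row)
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _read_vcf(path: Path) -> GenotypeMatrix:
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        sample_ids = list(vf.header.samples)
        locus_ids, rows, meta_rows = [], [], []
        for rec in vf.fetch() if vf.index else vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(f"{path}: record {rec.id or rec.pos} is not diallelic")
            locus_ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
            calls = []
            for sid in sample_ids:
                gt = rec.samples[sid].get("GT")
                if gt is None or any(a is None for a in gt):
                    calls.append((MISSING, MISSING))
                elif len(gt) != 2:
                    raise ValueError(f"{path}: non-diploid GT for {sid} at {rec.pos}")
                else:
                    calls.append(tuple(sorted(gt)))
            rows.append(calls)
            meta_rows.append({"alleles": (rec.ref, rec.alts[0])})
    arr = (
        np.array(rows, dtype=np.int16).transpose(1, 0, 2)
        if rows
        else np.empty((len(sample_ids), 0, 2), np.int16)
    )
    return GenotypeMatrix(sample_ids, locus_ids, arr, pd.DataFrame(meta_rows))


def _write_vcf(matrix: GenotypeMatrix, path: Path) -> None:
    lines = [
        "##fileformat=VCFv4.2",
        "##source=cohortnb",
        "##contig=<ID=synthetic>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.sample_ids),
    ]
    for j, lid in enumerate(matrix.locus_ids):
        al = None
        if "alleles" in matrix.locus_meta:
            al = matrix.locus_meta["alleles"].iloc[j]
        ref, alt = (al[0], al[1]) if al and isinstance(al[0], str) else ("A", "T")
        gts = []
        for i in range(matrix.n_samples):
            a, b = sorted(matrix.calls[i, j])
            gts.append("./." if a == MISSING else f"{a}/{b}")
        lines.append(f"synthetic\t{j + 1}\t{lid}\t{ref}\t{alt}\t.\t.\t.\tGT\t" + "\t".join(gts))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

_ID_ALIASES = ("sample_id", "id", "sample")
_YEAR_ALIASES = ("capture_year", "year")
_FL_ALIASES = ("fork_length_cm", "fl", "fork_length")
_TL_ALIASES = ("total_length_cm", "tl", "total_length")


def _pick(header: Sequence[str], aliases) -> Optional[int]:
    lowered = [h.strip().lower() for h in header]
    for a in aliases:
        if a in lowered:
            return lowered.index(a)
    return None


def read_samples(path) -> list[SampleRecord]:
    """Read per-sample metadata (id, capture year, FL, optional TL/sex/locality)."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(path, 1, "empty file") from None
        id_col = _pick(header, _ID_ALIASES)
        yr_col = _pick(header, _YEAR_ALIASES)
        fl_col = _pick(header, _FL_ALIASES)
        tl_col = _pick(header, _TL_ALIASES)
        sex_col = _pick(header, ("sex",))
        loc_col = _pick(header, ("locality", "location"))
        if id_col is None or yr_col is None:
            raise ParseError(path, 1, "header must name a sample id and capture year column")
        records, seen = [], set()
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            sid = row[id_col].strip()
            if sid in seen:
                raise ParseError(path, line_no, f"duplicate sample_id {sid!r}")
            seen.add(sid)

            def _num(col, what):
                if col is None or col >= len(row) or row[col].strip() in ("", "NA", "."):
                    return None
                try:
                    return float(row[col])
                except ValueError:
                    raise ParseError(path, line_no, f"non-numeric {what} {row[col]!r}") from None

            year = _num(yr_col, "capture year")
            if year is None:
                raise ParseError(path, line_no, "missing capture year")
            records.append(
                SampleRecord(
                    sample_id=sid,
                    capture_year=int(year),
                    fork_length_cm=_num(fl_col, "fork length"),
                    total_length_cm=_num(tl_col, "total length"),
                    sex=row[sex_col].strip() or None if sex_col is not None and sex_col < len(row) else None,
                    locality=row[loc_col].strip() or None if loc_col is not None and loc_col < len(row) else None,
                )
            )
    return records


def write_samples(records: Sequence[SampleRecord], path) -> None:
    buf = _stdio.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["sample_id", "capture_year", "fork_length_cm", "total_length_cm", "sex", "locality"])
    for r in records:
        writer.writerow(
            [
                r.sample_id,
                r.capture_year,
                "" if r.fork_length_cm is None else f"{r.fork_length_cm:.4f}",
                "" if r.total_length_cm is None else f"{r.total_length_cm:.4f}",
                r.sex or "",
                r.locality or "",
            ]
        )
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# life table / pedigree / truth
# ---------------------------------------------------------------------------

def read_life_table(path, n1: Optional[int] = None) -> LifeTable:
    """Read a life-table CSV with columns age, sex, survival, fecundity.

    A comment line ``# n1=<int>`` sets the recruits-per-cycle; the ``n1``
    argument overrides it.
    """
    path = Path(path)
    file_n1 = None
    body = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            stripped = line.lstrip("# ").replace(" ", "")
            if stripped.lower().startswith("n1="):
                file_n1 = int(stripped[3:])
        elif line.strip():
            body.append(line)
    df = pd.read_csv(_stdio.StringIO("\n".join(body)))
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"age", "sex", "survival", "fecundity"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: life table needs columns {sorted(required)}")
    ages = sorted(df["age"].unique())
    surv, fec = {}, {}
    for sex in LifeTable.SEXES:
        sub = df[df["sex"].str.upper().str.startswith(sex)].sort_values("age")
        if len(sub) != len(ages):
            raise ValueError(f"{path}: sex {sex} must have one row per age")
        surv[sex] = sub["survival"].to_numpy()
        fec[sex] = sub["fecundity"].to_numpy()
    n1_final = n1 if n1 is not None else file_n1
    if n1_final is None:
        raise ValueError(f"{path}: recruits per cycle not given (add '# n1=...' or pass n1=)")
    return LifeTable(ages, surv, fec, n1_final)


def write_life_table(table: LifeTable, path) -> None:
    lines = [f"# n1={table.n1}", "age,sex,survival,fecundity"]
    for sex in LifeTable.SEXES:
        for i, a in enumerate(table.ages):
            lines.append(f"{a},{sex},{table.survival[sex][i]},{table.fecundity[sex][i]}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_pedigree(ped: Pedigree, path) -> None:
    df = ped.to_frame()
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_truth(truth: dict, path) -> None:
    """Write the synthetic-truth JSON (true Nb per cycle, Ne, k-bar, Vk ...)."""
    Path(path).write_text(json.dumps(truth, indent=2, default=float) + "\n")
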