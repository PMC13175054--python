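"""Genotype data model and file I/O for diploid microsatellite panels.

Two on-disk layouts are supported:

* a project CSV dialect — one individual per row with metadata columns
  (``barcode``, ``birth_year``, ``sex``, ``sexmk_1``, ``sexmk_2``) followed by
  two columns per autosomal locus (``<locus>_1``, ``<locus>_2``) holding
  integer allele sizes in base pairs;
* the Genepop 4.x text format used by most population-genetics tools
  (3-digit per-allele coding, ``000`` for a missing allele).

Allele calls are stored as integers; the value :data:`MISSING` (``-1``) is
the in-memory missing sentinel.  Genotypes are unordered: every pair is kept
sorted ascending (with a missing slot sorting first), so heterozygosity tests
only ever compare the two values.

Sex-determination markers are metadata — they never enter the autosomal
panel and therefore never contribute to any statistic.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

#: In-memory sentinel for a missing allele call.
MISSING = -1

SEX_FEMALE = "F"
SEX_MALE = "M"
SEX_UNKNOWN = "U"

#: Sex-marker call values.  Anything else (non-empty) is an anomalous OTHER call.
MARKER_X = "X"
MARKER_Y = "Y"
MARKER_MISSING = ""

META_COLUMNS = ("barcode", "birth_year", "sex", "sexmk_1", "sexmk_2")

_YEAR_RE = re.compile(r"^(19|20)\d\d$")


class GenotypeIOError(ValueError):
    """Raised on malformed input files (always names the offending line)."""


@dataclass(frozen=True)
class CsvSchema:
    """Dialect configuration for the project CSV format.

    Parameters
    ----------
    missing_tokens : cell values read as a missing allele call (default: the
        empty string and ``"0"``).
    panel : optional expected locus list; when given, the file header must
        contain exactly these loci (unknown locus columns are a hard error).
    missing_out : token written for a missing allele call.
    """

    missing_tokens: tuple[str, ...] = ("", "0")
    panel: tuple[str, ...] | None = None
    missing_out: str = ""


@dataclass
class IndividualRecord:
    """One genotyped animal: metadata plus its multi-locus genotype."""

    barcode: str
    birth_year: int
    registered_sex: str
    sex_markers: tuple[str, str]
    genotypes: dict[str, tuple[int, int]]


def _sort_pairs(alleles: np.ndarray) -> np.ndarray:
    """Sort every allele pair ascending (missing ``-1`` first)."""
    return np.sort(alleles, axis=-1)


class GenotypeTable:
    """Rectangular store of individuals x loci diploid allele calls.

    Backed by numpy arrays: ``alleles`` has shape ``(n_records, n_loci, 2)``
    with :data:`MISSING` for untyped calls.  Barcodes need not be unique on
    input — duplicate handling is a QC concern, not an I/O concern.  The
    panel (locus) order is stable and preserved through round-trips.
    """

    def __init__(
        self,
        panel: Sequence[str],
        alleles: np.ndarray,
        barcodes: Sequence[str],
        birth_years: Sequence[int],
        registered_sex: Sequence[str],
        sex_markers: Sequence[tuple[str, str]] | np.ndarray,
        cohort_names: Mapping[int, str] | None = None,
    ) -> None:
        self.panel: list[str] = list(panel)
        alleles = np.asarray(alleles, dtype=np.int32)
        if alleles.ndim != 3 or alleles.shape[1] != len(self.panel) or alleles.shape[2] != 2:
            raise ValueError(
                f"alleles must have shape (n, {len(self.panel)}, 2), got {alleles.shape}"
            )
        self.alleles = _sort_pairs(alleles)
        n = alleles.shape[0]
        self.barcodes = np.asarray(barcodes, dtype=object)
        self.birth_years = np.asarray(birth_years, dtype=np.int32)
        self.registered_sex = np.asarray(registered_sex, dtype=object)
        self.sex_markers = np.asarray(sex_markers, dtype=object).reshape(n, 2)
        #: optional mapping from synthetic cohort codes to original POP labels
        self.cohort_names: dict[int, str] = dict(cohort_names or {})
        for name, arr in (
            ("barcodes", self.barcodes),
            ("birth_years", self.birth_years),
            ("registered_sex", self.registered_sex),
        ):
            if arr.shape[0] != n:
                raise ValueError(f"{name} length {arr.shape[0]} != n_records {n}")

    # ------------------------------------------------------------------ basic
    @property
    def n_records(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return len(self.panel)

    def locus_index(self, locus: str) -> int:
        try:
            return self.panel.index(locus)
        except ValueError:
            raise KeyError(f"locus {locus!r} not in panel") from None

    def cohorts(self) -> np.ndarray:
        """Sorted unique birth years present in the table."""
        return np.unique(self.birth_years)

    def cohort_sizes(self) -> dict[int, int]:
        years, counts = np.unique(self.birth_years, return_counts=True)
        return {int(y): int(c) for y, c in zip(years, counts)}

    def subset(self, index: np.ndarray) -> "GenotypeTable":
        """Row-subset by boolean mask or integer index array."""
        index = np.asarray(index)
        return GenotypeTable(
            self.panel,
            self.alleles[index],
            self.barcodes[index],
            self.birth_years[index],
            self.registered_sex[index],
            self.sex_markers[index],
            self.cohort_names,
        )

    def copy(self) -> "GenotypeTable":
        return GenotypeTable(
            self.panel,
            self.alleles.copy(),
            self.barcodes.copy(),
            self.birth_years.copy(),
            self.registered_sex.copy(),
            self.sex_markers.copy(),
            self.cohort_names,
        )

    def equals(self, other: "GenotypeTable") -> bool:
        return (
            self.panel == other.panel
            and np.array_equal(self.alleles, other.alleles)
            and np.array_equal(self.barcodes, other.barcodes)
            and np.array_equal(self.birth_years, other.birth_years)
            and np.array_equal(self.registered_sex, other.registered_sex)
            and np.array_equal(self.sex_markers, other.sex_markers)
        )

    # ---------------------------------------------------------------- records
    def iter_records(self) -> Iterator[IndividualRecord]:
        for i in range(self.n_records):
            genotypes = {
                locus: (int(self.alleles[i, j, 0]), int(self.alleles[i, j, 1]))
                for j, locus in enumerate(self.panel)
            }
            yield IndividualRecord(
                barcode=str(self.barcodes[i]),
                birth_year=int(self.birth_years[i]),
                registered_sex=str(self.registered_sex[i]),
                sex_markers=(str(self.sex_markers[i, 0]), str(self.sex_markers[i, 1])),
                genotypes=genotypes,
            )

    @property
    def records(self) -> list[IndividualRecord]:
        return list(self.iter_records())

    @classmethod
    def from_records(
        cls, panel: Sequence[str], records: Iterable[IndividualRecord]
    ) -> "GenotypeTable":
        records = list(records)
        panel = list(panel)
        n = len(records)
        alleles = np.full((n, len(panel), 2), MISSING, dtype=np.int32)
        barcodes, years, sexes, markers = [], [], [], []
        for i, rec in enumerate(records):
            if set(rec.genotypes) != set(panel):
                raise ValueError(
                    f"record {rec.barcode!r}: genotype loci do not match panel"
                )
            for j, locus in enumerate(panel):
                alleles[i, j] = rec.genotypes[locus]
            barcodes.append(rec.barcode)
            years.append(rec.birth_year)
            sexes.append(rec.registered_sex)
            markers.append(rec.sex_markers)
        return cls(panel, alleles, barcodes, years, sexes, markers)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"GenotypeTable(n_records={self.n_records}, n_loci={self.n_loci})"


# ============================================================== CSV dialect
def _parse_header(header: list[str], schema: CsvSchema) -> list[str]:
    if tuple(header[: len(META_COLUMNS)]) != META_COLUMNS:
        raise GenotypeIOError(
            f"CSV header must start with {','.join(META_COLUMNS)}; got {header[:5]}"
        )
    rest = header[len(META_COLUMNS):]
    if len(rest) % 2 != 0:
        raise GenotypeIOError("locus columns must come in <locus>_1/<locus>_2 pairs")
    panel = []
    for i in range(0, len(rest), 2):
        c1, c2 = rest[i], rest[i + 1]
        if not (c1.endswith("_1") and c2.endswith("_2") and c1[:-2] == c2[:-2]):
            raise GenotypeIOError(f"malformed locus column pair: {c1!r}, {c2!r}")
        panel.append(c1[:-2])
    if schema.panel is not None and list(schema.panel) != panel:
        unknown = sorted(set(panel) - set(schema.panel))
        if unknown:
            raise GenotypeIOError(f"unknown locus column(s): {unknown}")
        raise GenotypeIOError(
            f"panel mismatch: expected {list(schema.panel)}, file has {panel}"
        )
    return panel


def _parse_allele(token: str, schema: CsvSchema, lineno: int) -> int:
    token = token.strip()
    if token in schema.missing_tokens:
        return MISSING
    try:
        value = int(token)
    except ValueError:
        raise GenotypeIOError(f"line {lineno}: non-integer allele {token!r}") from None
    if value <= 0:
        raise GenotypeIOError(f"line {lineno}: allele size must be positive, got {value}")
    return value


def read_csv(path, schema: CsvSchema | None = None) -> GenotypeTable:
    """Read a project-dialect CSV file into a :class:`GenotypeTable`.

    Empty cells and the configurable sentinel (default ``"0"``) map to
    :data:`MISSING`.  A row with the wrong column count is a hard error that
    names the line number; no record is ever silently dropped.
    """
    schema = schema or CsvSchema()
    with open(path, "r", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise GenotypeIOError(f"{path}: empty file") from None
        panel = _parse_header([h.strip() for h in header], schema)
        ncol = len(META_COLUMNS) + 2 * len(panel)
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != ncol:
                raise GenotypeIOError(
                    f"line {lineno}: expected {ncol} columns, got {len(row)}"
                )
            rows.append((lineno, row))

    n = len(rows)
    alleles = np.full((n, len(panel), 2), MISSING, dtype=np.int32)
    barcodes, years, sexes, markers = [], [], [], []
    for i, (lineno, row) in enumerate(rows):
        barcodes.append(row[0].strip())
        try:
            years.append(int(row[1]))
        except ValueError:
            raise GenotypeIOError(
                f"line {lineno}: birth_year must be an integer, got {row[1]!r}"
            ) from None
        sex = row[2].strip().upper()
        sexes.append(sex if sex in (SEX_FEMALE, SEX_MALE) else SEX_UNKNOWN)
        markers.append((row[3].strip(), row[4].strip()))
        for j in range(len(panel)):
            a = _parse_allele(row[5 + 2 * j], schema, lineno)
            b = _parse_allele(row[6 + 2 * j], schema, lineno)
            alleles[i, j] = (a, b)
    return GenotypeTable(panel, alleles, barcodes, years, sexes, markers)


def write_csv(table: GenotypeTable, path, schema: CsvSchema | None = None) -> None:
    """Write ``table`` in the project CSV dialect (lossless round-trip)."""
    schema = schema or CsvSchema()

    def fmt(v: int) -> str:
        return schema.missing_out if v == MISSING else str(int(v))

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        header = list(META_COLUMNS)
        for locus in table.panel:
            header += [f"{locus}_1", f"{locus}_2"]
        writer.writerow(header)
        for i in range(table.n_records):
            row = [
                str(table.barcodes[i]),
                str(int(table.birth_years[i])),
                str(table.registered_sex[i]),
                str(table.sex_markers[i, 0]),
                str(table.sex_markers[i, 1]),
            ]
            for j in range(table.n_loci):
                row += [fmt(table.alleles[i, j, 0]), fmt(table.alleles[i, j, 1])]
            writer.writerow(row)


# ============================================================== Genepop 4.x
def _decode_genepop_token(token: str, lineno: int) -> tuple[int, int]:
    if not token.isdigit() or len(token) not in (4, 6):
        raise GenotypeIOError(
            f"line {lineno}: genotype token {token!r} is not 4 or 6 digits"
        )
    w = len(token) // 2
    a, b = int(token[:w]), int(token[w:])
    return (MISSING if a == 0 else a, MISSING if b == 0 else b)


def read_genepop(path) -> GenotypeTable:
    """Read a Genepop 4.x file.

    POP blocks map to cohorts: when the text following the ``POP`` keyword
    parses as a calendar year it is stored as ``birth_year``; otherwise a
    synthetic cohort code (1, 2, ...) is assigned and the original label kept
    in ``cohort_names``.  The all-zero code maps to :data:`MISSING`.
    Genepop carries no sex information, so registered sex is UNKNOWN and the
    sex markers are missing.
    """
    with open(path, "r") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GenotypeIOError(f"{path}: empty file")

    # title line, then locus names (one per line or comma-separated) until POP
    panel: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower().split()[0:1] != ["pop"]:
        chunk = lines[i].strip()
        if chunk:
            panel += [t.strip() for t in chunk.split(",") if t.strip()]
        i += 1
    if not panel:
        raise GenotypeIOError(f"{path}: no locus names before first POP")

    records: list[IndividualRecord] = []
    cohort_names: dict[int, str] = {}
    synthetic = 0
    cohort: int | None = None
    for lineno in range(i, len(lines)):
        line = lines[lineno].strip()
        if not line:
            continue
        if line.lower() == "pop" or line.lower().startswith("pop "):
            label = line[3:].strip()
            if _YEAR_RE.match(label):
                cohort = int(label)
            else:
                synthetic += 1
                cohort = synthetic
                cohort_names[cohort] = label or f"pop{synthetic}"
            continue
        if cohort is None:
            raise GenotypeIOError(f"line {lineno + 1}: individual before first POP")
        if "," not in line:
            raise GenotypeIOError(f"line {lineno + 1}: missing ',' id separator")
        ident, geno = line.split(",", 1)
        tokens = geno.split()
        if len(tokens) != len(panel):
            raise GenotypeIOError(
                f"line {lineno + 1}: expected {len(panel)} genotypes, got {len(tokens)}"
            )
        genotypes = {
            locus: _decode_genepop_token(tok, lineno + 1)
            for locus, tok in zip(panel, tokens)
        }
        records.append(
            IndividualRecord(
                barcode=ident.strip(),
                birth_year=cohort,
                registered_sex=SEX_UNKNOWN,
                sex_markers=(MARKER_MISSING, MARKER_MISSING),
                genotypes=genotypes,
            )
        )
    table = GenotypeTable.from_records(panel, records)
    table.cohort_names = cohort_names
    return table


def write_genepop(
    table: GenotypeTable, path, cohort_key: str = "birth_year", title: str | None = None
) -> None:
    """Write ``table`` as Genepop 4.x with 3-digit per-allele coding.

    One POP block per cohort, cohorts ascending, individuals sorted by
    barcode within each block; a missing call is emitted as ``000``.  Allele
    sizes above 999 cannot be represented in 3-digit coding and are a hard
    error instructing re-coding.
    """
    if cohort_key != "birth_year":
        raise ValueError("only birth_year cohorts are supported as Genepop POPs")
    if table.n_records == 0:
        raise GenotypeIOError("refusing to write an empty Genepop file")
    if np.any(table.alleles > 999):
        bad = int(table.alleles.max())
        raise GenotypeIOError(
            f"allele size {bad} exceeds 999; re-code alleles to <=999 bp before "
            "writing Genepop (3-digit per-allele coding)"
        )

    def code(v: int) -> str:
        return "000" if v == MISSING else f"{int(v):03d}"

    with open(path, "w") as fh:
        fh.write((title or "strpopgen export") + "\n")
        for locus in table.panel:
            fh.write(locus + "\n")
        for year in sorted(table.cohort_sizes()):
            fh.write(f"Pop {year}\n")
            idx = np.flatnonzero(table.birth_years == year)
            idx = idx[np.argsort(table.barcodes[idx].astype(str), kind="stable")]
            for i in idx:
                toks = [
                    code(table.alleles[i, j, 0]) + code(table.alleles[i, j, 1])
                    for j in range(table.n_loci)
                ]
                fh.write(f"{table.barcodes[i]} , " + " ".join(toks) + "\n")
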