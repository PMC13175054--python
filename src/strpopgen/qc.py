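"""Genotype quality-control cascade with per-stage counted drops.

The cascade runs in a fixed canonical order:

1. remove records with any missing autosomal allele call,
2. remove records with any allele outside its locus size range,
3. remove records with anomalous sex markers (an OTHER value, a missing
   value, or a marker pair inconsistent with the registered sex),
4. collapse duplicated barcodes (concordant duplicate groups merge into a
   single recovered record; discordant groups are dropped entirely),
5. remove whole birth-year cohorts smaller than a minimum size.

Every drop is counted, and the final head count satisfies the exact ledger
identity ``final = raw - missing - range - sex - dup_dropped + recovered -
small_cohort``.  Permuting stages can change the counts; the canonical order
above is the one all reports assume.  The cascade is idempotent: a second
pass over its own output removes nothing.
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

from .io import (
    MARKER_MISSING,
    MARKER_X,
    MARKER_Y,
    MISSING,
    SEX_FEMALE,
    SEX_MALE,
    GenotypeTable,
)

#: amelogenin-style interpretation: females carry X/X, males X/Y
DEFAULT_SEX_RULE: dict[str, tuple[str, str]] = {
    SEX_FEMALE: (MARKER_X, MARKER_X),
    SEX_MALE: (MARKER_X, MARKER_Y),
}


@dataclass
class QcConfig:
    """Configuration for the QC cascade.

    ``allele_ranges`` maps every panel locus to its inclusive ``(min_bp,
    max_bp)`` size range (instrument calling ranges are lab configuration,
    not constants).  ``sex_rule`` maps a registered sex to the required
    sex-marker multiset; ``None`` disables the sex stage entirely (useful
    for formats like Genepop that carry no sex information).
    """

    allele_ranges: dict[str, tuple[int, int]]
    min_cohort_size: int = 100
    sex_rule: Mapping[str, tuple[str, str]] | None = field(
        default_factory=lambda: dict(DEFAULT_SEX_RULE)
    )
    duplicate_policy: str = "merge_if_concordant"

    def __post_init__(self) -> None:
        if self.min_cohort_size < 1:
            raise ValueError("min_cohort_size must be >= 1")
        if self.duplicate_policy != "merge_if_concordant":
            raise ValueError(f"unknown duplicate_policy {self.duplicate_policy!r}")
        self.allele_ranges = {
            k: (int(lo), int(hi)) for k, (lo, hi) in self.allele_ranges.items()
        }

    @classmethod
    def from_file(cls, path) -> "QcConfig":
        """Load from YAML (or JSON, a YAML subset)."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sex_rule = raw.get("sex_rule", dict(DEFAULT_SEX_RULE))
        if sex_rule is not None:
            sex_rule = {k: tuple(v) for k, v in sex_rule.items()}
        return cls(
            allele_ranges={k: tuple(v) for k, v in raw["allele_ranges"].items()},
            min_cohort_size=int(raw.get("min_cohort_size", 100)),
            sex_rule=sex_rule,
        )

    def to_file(self, path) -> None:
        data = {
            "allele_ranges": {k: list(v) for k, v in self.allele_ranges.items()},
            "min_cohort_size": self.min_cohort_size,
            "sex_rule": None
            if self.sex_rule is None
            else {k: list(v) for k, v in self.sex_rule.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class QcReport:
    """Counted ledger of one QC run (one row structure per cascade stage)."""

    raw: int = 0
    missing_removed: int = 0
    range_removed: int = 0
    sex_removed: int = 0
    sex_subcounts: dict[str, int] = field(
        default_factory=lambda: {"no_xy": 0, "no_marker": 0, "mismatch": 0}
    )
    duplicates_found: dict[int, int] = field(default_factory=dict)
    duplicate_records_dropped: int = 0
    duplicates_recovered: int = 0
    small_cohort_removed: int = 0
    final: int = 0

    def identity_holds(self) -> bool:
        """Exact ledger identity over the counts this run actually produced."""
        expected = (
            self.raw
            - self.missing_removed
            - self.range_removed
            - self.sex_removed
            - self.duplicate_records_dropped
            + self.duplicates_recovered
            - self.small_cohort_removed
        )
        return expected == self.final and self.sex_removed == sum(
            self.sex_subcounts.values()
        )

    def to_dict(self) -> dict:
        return {
            "raw": self.raw,
            "missing_removed": self.missing_removed,
            "range_removed": self.range_removed,
            "sex_removed": self.sex_removed,
            "sex_subcounts": dict(self.sex_subcounts),
            "duplicates_found": {str(k): v for k, v in sorted(self.duplicates_found.items())},
            "duplicate_records_dropped": self.duplicate_records_dropped,
            "duplicates_recovered": self.duplicates_recovered,
            "small_cohort_removed": self.small_cohort_removed,
            "final": self.final,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_text(self) -> str:
        """Render the stage ledger as a fixed-layout text table."""
        rows = [
            ("Raw data", "", f"{self.raw:,} (i)"),
            ("Missing allele value", "", f"{self.missing_removed:,} (ii)"),
            ("Allele value outlier", "", f"{self.range_removed:,} (iii)"),
            ("Sex marker outlier", "No X, Y value", f"{self.sex_subcounts['no_xy']:,}"),
            ("", "No sex marker", f"{self.sex_subcounts['no_marker']:,}"),
            ("", "Mismatch sex marker", f"{self.sex_subcounts['mismatch']:,}"),
            ("", "Total", f"{self.sex_removed:,} (iv)"),
        ]
        for mult in sorted(self.duplicates_found):
            rows.append(
                ("Duplicate barcode ID", f"{mult} duplication",
                 f"{self.duplicates_found[mult]:,}")
            )
        rows += [
            ("Duplicate records dropped", "", f"{self.duplicate_records_dropped:,}"),
            ("Recovered from duplicates", "", f"{self.duplicates_recovered:,} (v)"),
            ("Small birth-year cohorts", "", f"{self.small_cohort_removed:,} (vi)"),
            ("Analysis data", "i-ii-iii-iv-dup+v-vi", f"{self.final:,}"),
        ]
        w0 = max(len(r[0]) for r in rows)
        w1 = max(len(r[1]) for r in rows)
        return "\n".join(f"{a:<{w0}}  {b:<{w1}}  {c}" for a, b, c in rows)


# ------------------------------------------------------------------ stages
def filter_missing(table: GenotypeTable) -> tuple[GenotypeTable, int]:
    """Remove every record with >= 1 missing autosomal allele call."""
    keep = ~np.any(table.alleles == MISSING, axis=(1, 2))
    return table.subset(keep), int(np.sum(~keep))


def filter_allele_range(
    table: GenotypeTable, ranges: Mapping[str, tuple[int, int]]
) -> tuple[GenotypeTable, int]:
    """Remove records with any allele outside its locus range (inclusive).

    Missing calls are not range violations.  Every panel locus must have a
    range; a missing locus is a hard error.
    """
    absent = [loc for loc in table.panel if loc not in ranges]
    if absent:
        raise KeyError(f"allele_ranges missing panel locus/loci: {absent}")
    lo = np.array([ranges[loc][0] for loc in table.panel], dtype=np.int32)
    hi = np.array([ranges[loc][1] for loc in table.panel], dtype=np.int32)
    a = table.alleles
    typed = a != MISSING
    bad = typed & ((a < lo[None, :, None]) | (a > hi[None, :, None]))
    keep = ~np.any(bad, axis=(1, 2))
    return table.subset(keep), int(np.sum(~keep))


def filter_sex_markers(
    table: GenotypeTable, sex_rule: Mapping[str, tuple[str, str]] | None = None
) -> tuple[GenotypeTable, int, dict[str, int]]:
    """Remove records with anomalous sex markers.

    Removal reasons, disjoint and in priority order:

    ``no_xy``     the marker pair contains a value other than X or Y,
    ``no_marker`` the pair contains a missing value,
    ``mismatch``  the pair (as a multiset) differs from the rule for the
                  registered sex (a registered sex without a rule entry is a
                  mismatch).
    """
    sex_rule = dict(DEFAULT_SEX_RULE) if sex_rule is None else sex_rule
    expected = {sex: tuple(sorted(pair)) for sex, pair in sex_rule.items()}
    sub = {"no_xy": 0, "no_marker": 0, "mismatch": 0}
    keep = np.ones(table.n_records, dtype=bool)
    for i in range(table.n_records):
        m1, m2 = table.sex_markers[i]
        pair = (str(m1), str(m2))
        if any(v not in (MARKER_X, MARKER_Y, MARKER_MISSING) for v in pair):
            sub["no_xy"] += 1
        elif MARKER_MISSING in pair:
            sub["no_marker"] += 1
        elif expected.get(str(table.registered_sex[i])) != tuple(sorted(pair)):
            sub["mismatch"] += 1
        else:
            continue
        keep[i] = False
    return table.subset(keep), int(np.sum(~keep)), sub


def _merge_pair(
    pa: tuple[int, int], pb: tuple[int, int]
) -> tuple[int, int] | None:
    """Merge two sorted genotype pairs; ``None`` if they disagree.

    A fully missing pair defers to the other; a half-missing pair is
    compatible with a full pair containing its typed allele.  Two distinct
    half-missing pairs are ambiguous and treated as discordant.
    """
    if pa == pb:
        return pa
    ma = sum(v == MISSING for v in pa)
    mb = sum(v == MISSING for v in pb)
    if ma == 2:
        return pb
    if mb == 2:
        return pa
    if ma == 1 and mb == 0:
        return pb if pa[1] in pb else None
    if mb == 1 and ma == 0:
        return pa if pb[1] in pa else None
    return None


def merge_duplicates(
    table: GenotypeTable,
) -> tuple[GenotypeTable, dict[int, int], int]:
    """Collapse duplicated barcodes.

    Singleton barcodes pass through untouched.  A multi-record group merges
    to one record iff all members agree at every non-missing call and share
    birth year and registered sex (missing calls are filled from any member
    that has the call); discordant groups are dropped entirely.  Returns the
    new table, group counts by multiplicity, and the number of merged
    records retained.
    """
    groups: dict[str, list[int]] = defaultdict(list)
    for i, bc in enumerate(table.barcodes):
        groups[str(bc)].append(i)

    found: Counter[int] = Counter()
    recovered = 0
    out_rows: list[tuple[int, int, np.ndarray | None]] = []  # (first_idx, src, merged)
    for bc, idx in groups.items():
        if len(idx) == 1:
            out_rows.append((idx[0], idx[0], None))
            continue
        found[len(idx)] += 1
        first = idx[0]
        concordant = (
            len({int(table.birth_years[i]) for i in idx}) == 1
            and len({str(table.registered_sex[i]) for i in idx}) == 1
        )
        merged = table.alleles[first].copy()
        if concordant:
            for i in idx[1:]:
                for j in range(table.n_loci):
                    m = _merge_pair(tuple(merged[j]), tuple(table.alleles[i, j]))
                    if m is None:
                        concordant = False
                        break
                    merged[j] = m
                if not concordant:
                    break
        if concordant:
            recovered += 1
            out_rows.append((first, first, merged))
        # discordant group: all members dropped, nothing appended

    out_rows.sort(key=lambda t: t[0])
    keep_idx = np.array([src for _, src, _ in out_rows], dtype=np.int64)
    result = table.subset(keep_idx) if len(keep_idx) else table.subset(
        np.zeros(0, dtype=np.int64)
    )
    for row, (_, _, merged) in enumerate(out_rows):
        if merged is not None:
            result.alleles[row] = merged
    return result, dict(found), recovered


def filter_min_cohort(
    table: GenotypeTable, min_size: int
) -> tuple[GenotypeTable, int]:
    """Drop every record whose birth-year cohort has < ``min_size`` members."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    sizes = table.cohort_sizes()
    keep = np.array(
        [sizes[int(y)] >= min_size for y in table.birth_years], dtype=bool
    )
    return table.subset(keep), int(np.sum(~keep))


def run_qc(table: GenotypeTable, config: QcConfig) -> tuple[GenotypeTable, QcReport]:
    """Run the full cascade in canonical order and return table + ledger."""
    report = QcReport(raw=table.n_records)
    t, report.missing_removed = filter_missing(table)
    t, report.range_removed = filter_allele_range(t, config.allele_ranges)
    if config.sex_rule is not None:
        before = t.n_records
        t, report.sex_removed, report.sex_subcounts = filter_sex_markers(
            t, config.sex_rule
        )
        assert before - t.n_records == report.sex_removed
    before = t.n_records
    t, report.duplicates_found, report.duplicates_recovered = merge_duplicates(t)
    report.duplicate_records_dropped = before - t.n_records + report.duplicates_recovered
    t, report.small_cohort_removed = filter_min_cohort(t, config.min_cohort_size)
    report.final = t.n_records
    if not report.identity_holds():  # pragma: no cover - internal invariant
        raise AssertionError(f"QC ledger identity violated: {report.to_dict()}")
    return t, report


class QcPipeline(TransformerMixin, BaseEstimator):
    """sklearn-style transformer wrapping :func:`run_qc`.

    ``fit`` runs the cascade and stores the cleaned table and report as
    fitted attributes; ``transform`` applies the same cascade to any table.
    """

    def __init__(self, config: QcConfig | None = None):
        self.config = config

    def _config(self) -> QcConfig:
        if self.config is None:
            raise ValueError("QcPipeline requires a QcConfig")
        return self.config

    def fit(self, X: GenotypeTable, y=None) -> "QcPipeline":
        self.clean_table_, self.report_ = run_qc(X, self._config())
        return self

    def transform(self, X: GenotypeTable) -> GenotypeTable:
        clean, _ = run_qc(X, self._config())
        return clean

    def fit_transform(self, X: GenotypeTable, y=None) -> GenotypeTable:
        return self.fit(X).clean_table_
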