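"""The QC cascade: per-stage counted drops and the exact ledger identity."""

import numpy as np
import pytest

from strpopgen.io import MISSING
from strpopgen.qc import (
    QcConfig,
    filter_allele_range,
    filter_min_cohort,
    filter_missing,
    filter_sex_markers,
    merge_duplicates,
    run_qc,
    QcPipeline,
)
from strpopgen.simulate import (
    DefectRates,
    Locus,
    SimulationConfig,
    default_qc_config,
    simulate,
)

from .conftest import build_table

PANEL = ["L1", "L2"]


def row(bc, year=2010, sex="F", mks=("X", "X"), g1=(100, 102), g2=(200, 200)):
    return (bc, year, sex, mks, [g1, g2])


class TestStages:
    def test_filter_missing_counts_each_record_once(self):
        rows = [row(f"A{i}") for i in range(7)]
        rows.append(row("B0", g1=(MISSING, 102)))
        rows.append(row("B1", g2=(MISSING, MISSING)))  # both calls missing
        rows.append(row("B2", g1=(MISSING, 100)))
        table = build_table(PANEL, rows)
        clean, n = filter_missing(table)
        assert (clean.n_records, n) == (7, 3)
        # identity on already-clean input
        clean2, n2 = filter_missing(clean)
        assert n2 == 0 and clean2.equals(clean)

    def test_allele_range_inclusive_bounds(self):
        table = build_table(
            PANEL,
            [
                row("A", g1=(100, 150)),   # both at/inside bounds
                row("B", g1=(100, 152)),   # 152 > max -> removed
                row("C", g1=(150, 150)),   # at max -> retained
            ],
        )
        ranges = {"L1": (100, 150), "L2": (190, 210)}
        clean, n = filter_allele_range(table, ranges)
        assert n == 1 and list(clean.barcodes) == ["A", "C"]
        with pytest.raises(KeyError, match="L2"):
            filter_allele_range(table, {"L1": (100, 150)})

    def test_sex_marker_reasons_are_disjoint_priority_ordered(self):
        table = build_table(
            PANEL,
            [
                row("ok_f"),                                  # F with X,X
                row("ok_m", sex="M", mks=("X", "Y")),         # M with X,Y
                row("mm", sex="F", mks=("X", "Y")),           # mismatch
                row("other", mks=("N", "")),                  # OTHER wins over missing
                row("nomk", mks=("X", "")),                   # missing marker
                row("unreg", sex="U", mks=("X", "X")),        # no rule -> mismatch
            ],
        )
        clean, n, sub = filter_sex_markers(table)
        assert n == 4
        assert sub == {"no_xy": 1, "no_marker": 1, "mismatch": 2}
        assert set(clean.barcodes) == {"ok_f", "ok_m"}

    def test_merge_duplicates_concordant_and_discordant(self):
        table = build_table(
            PANEL,
            [
                row("dup2"),
                row("dup2"),
                row("bad"),
                row("bad", g1=(100, 104)),        # one allele differs
                row("dup3"),
                row("dup3"),
                row("dup3"),
                row("solo"),
            ],
        )
        merged, found, recovered = merge_duplicates(table)
        assert found == {2: 2, 3: 1}
        assert recovered == 2
        assert sorted(merged.barcodes) == ["dup2", "dup3", "solo"]

    def test_merge_fills_missing_from_concordant_member(self):
        table = build_table(
            PANEL,
            [
                row("d", g1=(MISSING, 102)),
                row("d", g1=(100, 102)),
            ],
        )
        merged, _, recovered = merge_duplicates(table)
        assert recovered == 1
        assert tuple(merged.alleles[0, 0]) == (100, 102)

    def test_min_cohort_boundary(self):
        rows = [row(f"A{i}", year=2001) for i in range(99)] + [
            row(f"B{i}", year=2002) for i in range(100)
        ]
        table = build_table(PANEL, rows)
        clean, n = filter_min_cohort(table, 100)
        assert n == 99 and set(clean.birth_years) == {2002}
        same, n0 = filter_min_cohort(table, 1)
        assert n0 == 0 and same.equals(table)


def small_config(seed, n=400):
    panel = [Locus(f"L{i}", tuple(100 + 2 * j for j in range(6))) for i in range(4)]
    rng = np.random.default_rng(seed)
    rates = DefectRates(
        missing_call=float(rng.uniform(0, 0.1)),
        out_of_range=float(rng.uniform(0, 0.05)),
        sex_other=float(rng.uniform(0, 0.03)),
        sex_missing=float(rng.uniform(0, 0.05)),
        sex_mismatch=float(rng.uniform(0, 0.05)),
        duplicate_2fold=float(rng.uniform(0, 0.05)),
        duplicate_3fold=float(rng.uniform(0, 0.02)),
        duplicate_concordant_fraction=float(rng.uniform(0, 1)),
    )
    sizes = {2001 + i: int(rng.integers(20, n)) for i in range(3)}
    return SimulationConfig(
        seed=seed, panel=panel, cohort_sizes=sizes, defect_rates=rates
    ), panel


class TestRunQc:
    def test_clean_table_passes_untouched(self):
        table = build_table(PANEL, [row(f"A{i}") for i in range(5)])
        cfg = QcConfig(
            allele_ranges={"L1": (100, 110), "L2": (190, 210)}, min_cohort_size=1
        )
        clean, report = run_qc(table, cfg)
        assert report.final == report.raw == 5
        assert report.missing_removed == report.sex_removed == 0
        assert clean.equals(table)

    def test_report_matches_generator_ledger(self):
        cfg, panel = small_config(seed=42)
        table, ledger = simulate(cfg)
        qc_cfg = QcConfig(
            allele_ranges={
                loc.name: (min(loc.alleles), max(loc.alleles)) for loc in panel
            },
            min_cohort_size=100,
        )
        clean, report = run_qc(table, qc_cfg)
        expected = ledger.expected_qc_counts(100)
        assert report.raw == expected["raw"]
        assert report.missing_removed == expected["missing_removed"]
        assert report.range_removed == expected["range_removed"]
        assert report.sex_removed == expected["sex_removed"]
        assert report.sex_subcounts == expected["sex_subcounts"]
        assert report.duplicates_found == expected["duplicates_found"]
        assert report.duplicate_records_dropped == expected["duplicate_records_dropped"]
        assert report.duplicates_recovered == expected["duplicates_recovered"]
        assert report.small_cohort_removed == expected["small_cohort_removed"]
        assert report.final == expected["final"] == clean.n_records

    def test_ledger_identity_over_random_configs(self):
        """Stage counts are non-negative and satisfy the ledger identity."""
        for seed in range(30):
            cfg, panel = small_config(seed=seed, n=150)
            table, ledger = simulate(cfg)
            qc_cfg = QcConfig(
                allele_ranges={
                    loc.name: (min(loc.alleles), max(loc.alleles)) for loc in panel
                },
                min_cohort_size=50,
            )
            _, report = run_qc(table, qc_cfg)
            d = report.to_dict()
            assert report.identity_holds()
            assert all(
                v >= 0 for k, v in d.items() if isinstance(v, int)
            ), d
            expected = ledger.expected_qc_counts(50)
            assert d["final"] == expected["final"]
            assert d["missing_removed"] == expected["missing_removed"]

    def test_idempotent(self, preset_clean):
        clean, _, _ = preset_clean
        clean2, report2 = run_qc(clean, default_qc_config())
        assert clean2.equals(clean)
        assert report2.raw == report2.final
        assert (
            report2.missing_removed
            == report2.range_removed
            == report2.sex_removed
            == report2.duplicate_records_dropped
            == report2.small_cohort_removed
            == 0
        )

    def test_report_text_layout(self):
        table = build_table(PANEL, [row("A")])
        cfg = QcConfig(
            allele_ranges={"L1": (100, 110), "L2": (190, 210)}, min_cohort_size=1
        )
        _, report = run_qc(table, cfg)
        text = report.to_text()
        for tag in ("(i)", "(ii)", "(iii)", "(iv)", "(v)", "(vi)", "Analysis data"):
            assert tag in text

    def test_pipeline_estimator_surface(self):
        table = build_table(PANEL, [row(f"A{i}") for i in range(3)])
        cfg = QcConfig(
            allele_ranges={"L1": (100, 110), "L2": (190, 210)}, min_cohort_size=1
        )
        pipe = QcPipeline(config=cfg)
        out = pipe.fit_transform(table)
        assert pipe.report_.final == 3
        assert out.equals(pipe.clean_table_)
        assert QcPipeline(**pipe.get_params()).get_params() == pipe.get_params()
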