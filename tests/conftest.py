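import numpy as np
import pytest

from strpopgen.io import GenotypeTable
from strpopgen.qc import run_qc
from strpopgen.simulate import default_qc_config, preset_hanwoo_like, simulate


def build_table(panel, rows):
    """Hand-build a GenotypeTable.

    ``rows``: iterable of (barcode, birth_year, sex, (mk1, mk2), genotypes)
    where genotypes is a list of (a, b) allele pairs in panel order
    (-1 = missing).
    """
    n = len(rows)
    alleles = np.zeros((n, len(panel), 2), dtype=np.int32)
    barcodes, years, sexes, markers = [], [], [], []
    for i, (bc, year, sex, mks, genos) in enumerate(rows):
        barcodes.append(bc)
        years.append(year)
        sexes.append(sex)
        markers.append(mks)
        for j, pair in enumerate(genos):
            alleles[i, j] = pair
    return GenotypeTable(panel, alleles, barcodes, years, sexes, markers)


@pytest.fixture(scope="session")
def preset_clean():
    """QC'd desk-scale preset simulation shared across test modules."""
    table, ledger = simulate(preset_hanwoo_like(7))
    clean, report = run_qc(table, default_qc_config())
    return clean, report, ledger
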