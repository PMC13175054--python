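"""Birth-year cohort trend tables: per-year per-locus diversity statistics.

Groups a QC'd table by birth year and applies the per-locus diversity
statistics to each cohort independently, producing the long-format table
behind annual-trend line charts, plus a cohort census (counts by year and
registered sex with column percentages).

Both the ratio inbreeding coefficient and the Weir-Cockerham
within-population ``f`` are reported per year, since the two estimators
differ slightly and either may be wanted for a trend plot.  The CSV is the
contract; the optional PNG line charts are a thin convenience layer.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .diversity import allele_frequencies, f_is_simple, h_exp, h_obs, pic
from .fstats import _single_pop_bc
from .io import MISSING, SEX_FEMALE, SEX_MALE, GenotypeTable


class CohortTrends(BaseEstimator):
    """Per-birth-year per-locus diversity statistics and cohort census.

    Attributes
    ----------
    trend_ : long-format DataFrame with one row per (birth_year, locus)
        and columns ``n_ind, h_obs, h_exp, pic, f_is_simple, f_is_wc``
    census_ : counts by birth year and registered sex with percentages
    """

    def __init__(self, cohort_key: str = "birth_year"):
        self.cohort_key = cohort_key

    def fit(self, X: GenotypeTable, y=None) -> "CohortTrends":
        if self.cohort_key != "birth_year":
            raise ValueError("only birth_year cohorts are supported")
        if X.n_records == 0:
            raise ValueError("empty table")
        rows = []
        for year in X.cohorts():
            cohort = X.subset(X.birth_years == year)
            for j, locus in enumerate(X.panel):
                lf = allele_frequencies(cohort, locus)
                ho = h_obs(cohort, locus)
                he = h_exp(lf)
                geno = cohort.alleles[:, j, :]
                geno = geno[np.all(geno != MISSING, axis=1)]
                if geno.shape[0] >= 2:
                    b, c = _single_pop_bc(geno)
                    f_wc = float("nan") if b + c == 0 else 1.0 - c / (b + c)
                else:
                    f_wc = float("nan")
                rows.append(
                    {
                        "birth_year": int(year),
                        "locus": locus,
                        "n_ind": lf.n_ind,
                        "h_obs": ho,
                        "h_exp": he,
                        "pic": pic(lf),
                        "f_is_simple": f_is_simple(he, ho),
                        "f_is_wc": f_wc,
                    }
                )
        self.trend_ = pd.DataFrame(rows)
        self.census_ = cohort_census(X)
        return self


def trend_statistics(table: GenotypeTable, cohort_key: str = "birth_year") -> pd.DataFrame:
    """Long-format per-year per-locus statistics (thin estimator wrapper)."""
    return CohortTrends(cohort_key=cohort_key).fit(table).trend_


def cohort_census(table: GenotypeTable) -> pd.DataFrame:
    """Counts by birth year and registered sex with column percentages.

    Rows are the years present in the table (empty cohorts are simply
    absent); a Total row closes the table.  Percentages are of the grand
    total, rounded to one decimal.
    """
    years = [int(y) for y in table.cohorts()]
    rows = []
    for year in years:
        mask = table.birth_years == year
        n_f = int(np.sum(mask & (table.registered_sex == SEX_FEMALE)))
        n_m = int(np.sum(mask & (table.registered_sex == SEX_MALE)))
        total = int(np.sum(mask))
        rows.append({"birth_year": year, "cow": n_f, "bull": n_m, "total": total})
    df = pd.DataFrame(rows)
    grand = int(df["total"].sum())
    df["percent"] = (100.0 * df["total"] / grand).round(1)
    total_row = {
        "birth_year": "Total",
        "cow": int(df["cow"].sum()),
        "bull": int(df["bull"].sum()),
        "total": grand,
        "percent": round(float(df["percent"].sum()), 1),
    }
    return pd.concat([df, pd.DataFrame([total_row])], ignore_index=True)


def plot_trends(trend: pd.DataFrame, path, statistic: str = "h_exp") -> None:
    """Write a per-locus annual line chart for one statistic (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 5))
    for locus, grp in trend.groupby("locus"):
        ax.plot(grp["birth_year"], grp[statistic], marker="o", ms=3, label=locus)
    ax.set_xlabel("birth year")
    ax.set_ylabel(statistic)
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
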