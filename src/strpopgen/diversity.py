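"""Per-locus allele frequencies and diversity statistics.

For a locus with allele frequencies :math:`p_i` estimated from :math:`N`
fully typed individuals (:math:`2N` calls):

* observed heterozygosity ``H_obs`` — fraction of typed individuals whose
  two calls differ;
* expected heterozygosity (gene diversity) ``H_exp = 1 - sum(p_i^2)``, with
  an optional small-sample multiplier ``2N/(2N-1)``;
* polymorphic information content (Botstein form)
  ``PIC = 1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2``;
* the simple inbreeding coefficient ``F_IS = (H_exp - H_obs)/H_exp``.

An individual counts as typed at a locus only when both calls are present;
half-missing genotypes are excluded from numerator and denominator alike.
A Weir-Cockerham within-population ``f`` is exposed as an alternative F_IS
column, because the ratio definition and the variance-component estimator
differ in the third decimal at typical sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import MISSING, GenotypeTable


@dataclass
class LocusFrequencies:
    """Allele-frequency vector for one locus with its sample size."""

    locus: str
    n_ind: int
    freqs: dict[int, float]

    def __post_init__(self) -> None:
        total = float(sum(self.freqs.values()))
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"{self.locus}: frequencies sum to {total}, not 1")
        if any(p <= 0 for p in self.freqs.values()):
            raise ValueError(f"{self.locus}: every frequency must be > 0")

    @property
    def k(self) -> int:
        return len(self.freqs)

    @property
    def p(self) -> np.ndarray:
        return np.array(list(self.freqs.values()), dtype=float)


def _as_p(freqs) -> np.ndarray:
    if isinstance(freqs, LocusFrequencies):
        return freqs.p
    if isinstance(freqs, Mapping):
        return np.array(list(freqs.values()), dtype=float)
    return np.asarray(freqs, dtype=float)


def _typed_genotypes(table: GenotypeTable, locus: str) -> np.ndarray:
    j = table.locus_index(locus)
    g = table.alleles[:, j, :]
    typed = np.all(g != MISSING, axis=1)
    return g[typed]


def allele_frequencies(table: GenotypeTable, locus: str) -> LocusFrequencies:
    """Observed allele frequencies at ``locus`` over fully typed individuals."""
    g = _typed_genotypes(table, locus)
    if g.shape[0] == 0:
        raise ValueError(f"{locus}: zero typed individuals")
    values, counts = np.unique(g.ravel(), return_counts=True)
    total = counts.sum()
    freqs = {int(v): float(c) / total for v, c in zip(values, counts)}
    return LocusFrequencies(locus=locus, n_ind=g.shape[0], freqs=freqs)


def h_obs(table: GenotypeTable, locus: str) -> float:
    """Fraction of typed individuals heterozygous at ``locus``."""
    g = _typed_genotypes(table, locus)
    if g.shape[0] == 0:
        raise ValueError(f"{locus}: zero typed individuals")
    return float(np.mean(g[:, 0] != g[:, 1]))


def h_exp(freqs, correction: str = "none") -> float:
    """Expected heterozygosity ``1 - sum(p_i^2)``.

    ``correction="unbiased"`` applies the ``2N/(2N-1)`` small-sample
    multiplier and therefore requires a :class:`LocusFrequencies` input
    (it needs N).
    """
    p = _as_p(freqs)
    he = 1.0 - float(np.sum(p**2))
    if correction == "none":
        return he
    if correction == "unbiased":
        if not isinstance(freqs, LocusFrequencies):
            raise TypeError("unbiased correction needs LocusFrequencies (for N)")
        two_n = 2 * freqs.n_ind
        if two_n < 2:
            raise ValueError("unbiased correction needs N >= 1")
        return he * two_n / (two_n - 1)
    raise ValueError(f"unknown correction {correction!r}")


def pic(freqs) -> float:
    """Polymorphic information content (Botstein et al. form)."""
    p = _as_p(freqs)
    s2 = float(np.sum(p**2))
    s4 = float(np.sum(p**4))
    # sum_{i<j} 2 p_i^2 p_j^2 = (sum p^2)^2 - sum p^4
    return 1.0 - s2 - (s2**2 - s4)


def f_is_simple(h_exp_value: float, h_obs_value: float) -> float:
    """Ratio inbreeding coefficient ``(H_exp - H_obs)/H_exp``.

    Undefined (NaN) at a monomorphic locus where ``H_exp == 0``.
    """
    if h_exp_value == 0:
        return float("nan")
    return (h_exp_value - h_obs_value) / h_exp_value


@dataclass
class DiversitySummary:
    """Per-locus diversity rows plus an unweighted mean row.

    ``per_locus`` is indexed by locus (panel order) with columns
    ``k, n, h_obs, h_exp, pic, f_is`` and optionally ``f_is_wc``.
    """

    per_locus: pd.DataFrame

    NUMERIC_COLUMNS = ("k", "n", "h_obs", "h_exp", "pic", "f_is", "f_is_wc")

    @property
    def mean_row(self) -> pd.Series:
        """Unweighted column means over loci (the summary's Mean row)."""
        cols = [c for c in self.NUMERIC_COLUMNS if c in self.per_locus.columns]
        return self.per_locus[cols].mean(axis=0).rename("Mean")

    @classmethod
    def from_per_locus(cls, per_locus: pd.DataFrame) -> "DiversitySummary":
        return cls(per_locus=per_locus.copy())

    def to_frame(self) -> pd.DataFrame:
        """Per-locus rows with the Mean row appended."""
        mean = self.mean_row.to_frame().T
        return pd.concat([self.per_locus, mean], axis=0)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="locus")

    def to_text(self) -> str:
        df = self.to_frame().copy()
        df["k"] = df["k"].map(lambda v: f"{v:.3f}".rstrip("0").rstrip(".")
                              if v != int(v) else f"{int(v)}")
        df["n"] = df["n"].map(lambda v: f"{int(v):,}" if v == int(v) else f"{v:,.1f}")
        for c in df.columns:
            if c in ("h_obs", "h_exp", "pic"):
                df[c] = df[c].map(lambda v: f"{v:.3f}")
            elif c.startswith("f_is"):
                df[c] = df[c].map(lambda v: f"{v:.4f}")
        return df.to_string()


class DiversityEstimator(BaseEstimator):
    """Fit per-locus diversity statistics on a genotype table.

    Parameters
    ----------
    h_exp_correction : ``"none"`` (exact gene diversity, the default) or
        ``"unbiased"`` (``2N/(2N-1)`` multiplier; at N in the hundreds of
        thousands the difference is below 1e-5).
    include_wc_fis : also report the Weir-Cockerham within-population ``f``
        per locus (uses birth-year cohorts when >= 2 are present, else the
        single-population variance components).
    cohort_key : grouping column for the WC ``f`` (only birth_year exists).

    Attributes
    ----------
    frequencies_ : dict locus -> LocusFrequencies
    per_locus_ : DataFrame of per-locus statistics in panel order
    summary_ : DiversitySummary (per-locus rows + mean row)
    """

    def __init__(
        self,
        h_exp_correction: str = "none",
        include_wc_fis: bool = True,
        cohort_key: str = "birth_year",
    ):
        self.h_exp_correction = h_exp_correction
        self.include_wc_fis = include_wc_fis
        self.cohort_key = cohort_key

    def fit(self, X: GenotypeTable, y=None) -> "DiversityEstimator":
        from . import fstats  # deferred: fstats imports nothing from here

        rows = []
        self.frequencies_ = {}
        for locus in X.panel:
            lf = allele_frequencies(X, locus)
            self.frequencies_[locus] = lf
            ho = h_obs(X, locus)
            he = h_exp(lf, self.h_exp_correction)
            row = {
                "k": lf.k,
                "n": lf.n_ind,
                "h_obs": ho,
                "h_exp": he,
                "pic": pic(lf),
                "f_is": f_is_simple(he, ho),
            }
            if self.include_wc_fis:
                row["f_is_wc"] = fstats.wc_f_within(
                    X, locus, X.birth_years, allow_single_population=True
                )
            rows.append(row)
        self.per_locus_ = pd.DataFrame(rows, index=pd.Index(X.panel, name="locus"))
        self.summary_ = DiversitySummary(per_locus=self.per_locus_)
        return self


def summarize(
    table: GenotypeTable,
    h_exp_correction: str = "none",
    include_wc_fis: bool = True,
) -> DiversitySummary:
    """Per-locus diversity summary with mean row (thin estimator wrapper)."""
    est = DiversityEstimator(
        h_exp_correction=h_exp_correction, include_wc_fis=include_wc_fis
    )
    return est.fit(table).summary_
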