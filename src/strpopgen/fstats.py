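"""Weir-Cockerham (1984) variance-component F-statistics.

For each locus the observed genotypes are decomposed, allele by allele,
into three variance components:

* ``a`` — between populations,
* ``b`` — among individuals within populations,
* ``c`` — within individuals (the heterozygosity term),

using the sample-size weights ``n_bar`` and ``n_c`` of the unbalanced
design.  Summing components over alleles (and over loci as a ratio of
sums, never a mean of ratios) gives

* ``theta = a / (a + b + c)`` — the F_ST analogue,
* ``f = 1 - c / (b + c)``     — the within-population inbreeding
  coefficient (F_IS analogue).

``a`` and ``b`` are unbiased estimators and may be negative; small negative
``theta`` values around zero are expected under no differentiation and are
retained (a display floor at 0 is available for reports).

The simpler Nei-style ``(H_T - H_S)/H_T`` ratio is also provided; on large
balanced samples it tracks ``theta`` closely but the two are different
estimators and are never asserted equal.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import MISSING, GenotypeTable


@dataclass
class VarianceComponents:
    """Per-locus WC84 components summed over alleles."""

    locus: str
    a: float
    b: float
    c: float

    @property
    def theta(self) -> float:
        denom = self.a + self.b + self.c
        return float("nan") if denom == 0 else self.a / denom


def _counts_by_population(
    geno: np.ndarray, pops: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tally per-population sample sizes, allele counts and het-carrier counts.

    ``geno`` is ``(n, 2)`` with no missing calls; ``pops`` integer codes
    ``0..r-1``.  Returns ``n`` (r,), allele counts ``ac`` (r, k) and
    heterozygote-carrier counts ``hc`` (r, k) over the locus's allele set.
    """
    alleles, inv = np.unique(geno.ravel(), return_inverse=True)
    inv = inv.reshape(geno.shape)
    r = int(pops.max()) + 1
    k = alleles.size
    n = np.bincount(pops, minlength=r).astype(float)
    ac = np.zeros((r, k))
    np.add.at(ac, (pops, inv[:, 0]), 1)
    np.add.at(ac, (pops, inv[:, 1]), 1)
    het = inv[:, 0] != inv[:, 1]
    hc = np.zeros((r, k))
    np.add.at(hc, (pops[het], inv[het, 0]), 1)
    np.add.at(hc, (pops[het], inv[het, 1]), 1)
    return n, ac, hc


def wc_components_from_counts(
    n: np.ndarray, ac: np.ndarray, hc: np.ndarray
) -> tuple[float, float, float]:
    """WC84 ``(a, b, c)`` summed over alleles from per-population tallies.

    Direct transcription of the 1984 estimators for the multi-population,
    multi-allele case with unequal sample sizes; no missing data assumed.
    """
    n = np.asarray(n, dtype=float)
    r = n.size
    if r < 2:
        raise ValueError("need >= 2 populations for variance components")
    if np.any(n < 2):
        raise ValueError("every population needs >= 2 typed individuals")
    N = n.sum()
    n_bar = N / r
    n_c = (N - np.sum(n**2) / N) / (r - 1)

    p = ac / (2.0 * n[:, None])                    # (r, k) within-pop freqs
    p_bar = ac.sum(axis=0) / (2.0 * N)             # (k,) weighted mean freq
    s2 = (n[:, None] * (p - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = hc.sum(axis=0) / N                     # (k,) weighted het freq

    pq = p_bar * (1.0 - p_bar)
    a = (n_bar / n_c) * (
        s2 - (pq - (r - 1) / r * s2 - h_bar / 4.0) / (n_bar - 1.0)
    )
    b = (n_bar / (n_bar - 1.0)) * (
        pq - (r - 1) / r * s2 - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar
    )
    c = h_bar / 2.0
    return float(a.sum()), float(b.sum()), float(c.sum())


def _single_pop_bc(geno: np.ndarray) -> tuple[float, float]:
    """Within-population ``(b, c)`` for a single sample (r = 1).

    The between-population terms vanish; used for per-cohort inbreeding
    estimates where no second population exists.
    """
    nind = geno.shape[0]
    if nind < 2:
        raise ValueError("need >= 2 typed individuals")
    alleles, inv = np.unique(geno.ravel(), return_inverse=True)
    inv = inv.reshape(geno.shape)
    k = alleles.size
    ac = np.bincount(inv.ravel(), minlength=k).astype(float)
    het = inv[:, 0] != inv[:, 1]
    hc = np.zeros(k)
    np.add.at(hc, inv[het, 0], 1)
    np.add.at(hc, inv[het, 1], 1)
    p = ac / (2.0 * nind)
    h_bar = hc / nind
    b = (nind / (nind - 1.0)) * (
        p * (1.0 - p) - (2.0 * nind - 1.0) / (4.0 * nind) * h_bar
    )
    c = h_bar / 2.0
    return float(b.sum()), float(c.sum())


def _locus_arrays(
    table: GenotypeTable, locus: str, pop_labels
) -> tuple[np.ndarray, np.ndarray]:
    j = table.locus_index(locus)
    geno = table.alleles[:, j, :]
    labels = np.asarray(pop_labels)
    if labels.shape[0] != table.n_records:
        raise ValueError("pop_labels length must match table records")
    typed = np.all(geno != MISSING, axis=1)
    geno, labels = geno[typed], labels[typed]
    uniq, codes = np.unique(labels, return_inverse=True)
    counts = np.bincount(codes)
    usable = counts >= 2
    if not np.all(usable):
        dropped = [str(u) for u in uniq[~usable]]
        warnings.warn(
            f"{locus}: excluding population(s) with <2 typed individuals: {dropped}",
            stacklevel=3,
        )
        keep = usable[codes]
        geno, labels = geno[keep], labels[keep]
        uniq, codes = np.unique(labels, return_inverse=True)
    return geno, codes


def wc_components(
    table: GenotypeTable, locus: str, pop_labels
) -> VarianceComponents:
    """WC84 per-locus components for the populations in ``pop_labels``.

    Populations with fewer than 2 typed individuals at the locus are
    excluded with a warning; fewer than 2 usable populations is an error.
    """
    geno, codes = _locus_arrays(table, locus, pop_labels)
    if codes.size == 0 or codes.max() < 1:
        raise ValueError(f"{locus}: need >= 2 usable populations")
    n, ac, hc = _counts_by_population(geno, codes)
    a, b, c = wc_components_from_counts(n, ac, hc)
    return VarianceComponents(locus=locus, a=a, b=b, c=c)


def multilocus_theta(components: list[VarianceComponents]) -> float:
    """Multilocus theta as a ratio of sums (not a mean of per-locus ratios)."""
    if not components:
        raise ValueError("need >= 1 locus")
    num = sum(vc.a for vc in components)
    den = sum(vc.a + vc.b + vc.c for vc in components)
    return float("nan") if den == 0 else num / den


def wc_f_within(
    table: GenotypeTable,
    locus: str,
    pop_labels,
    allow_single_population: bool = False,
) -> float:
    """WC within-population inbreeding coefficient ``f = 1 - c/(b + c)``."""
    geno, codes = _locus_arrays(table, locus, pop_labels)
    r = 0 if codes.size == 0 else int(codes.max()) + 1
    if r >= 2:
        n, ac, hc = _counts_by_population(geno, codes)
        _, b, c = wc_components_from_counts(n, ac, hc)
    elif allow_single_population and geno.shape[0] >= 2:
        b, c = _single_pop_bc(geno)
    else:
        raise ValueError(f"{locus}: need >= 2 usable populations")
    return float("nan") if b + c == 0 else 1.0 - c / (b + c)


def ht_hs_fst(table: GenotypeTable, pop_labels) -> float:
    """Multilocus Nei-style ``(H_T - H_S)/H_T`` over the given populations.

    ``H_T`` uses the unweighted mean of population allele frequencies;
    loci are combined as a ratio of sums.
    """
    labels = np.asarray(pop_labels)
    ht_sum = hs_sum = 0.0
    for locus in table.panel:
        j = table.locus_index(locus)
        geno = table.alleles[:, j, :]
        typed = np.all(geno != MISSING, axis=1)
        g, lab = geno[typed], labels[typed]
        uniq = np.unique(lab)
        if uniq.size < 2:
            raise ValueError(f"{locus}: need >= 2 populations")
        alleles = np.unique(g.ravel())
        freqs = []
        for u in uniq:
            sub = g[lab == u].ravel()
            counts = np.array([(sub == a).sum() for a in alleles], dtype=float)
            freqs.append(counts / counts.sum())
        freqs = np.array(freqs)
        hs = np.mean(1.0 - np.sum(freqs**2, axis=1))
        p_bar = freqs.mean(axis=0)
        ht = 1.0 - float(np.sum(p_bar**2))
        ht_sum += ht
        hs_sum += hs
    return float("nan") if ht_sum == 0 else (ht_sum - hs_sum) / ht_sum


@dataclass
class FstMatrix:
    """Symmetric cohort x cohort matrix of pairwise multilocus theta."""

    cohorts: list[int]
    theta: pd.DataFrame
    per_pair_components: dict[tuple[int, int], tuple[float, float]] = field(
        default_factory=dict
    )

    def floored(self) -> pd.DataFrame:
        """Copy with negative estimates floored at 0 (display convention)."""
        return self.theta.clip(lower=0.0)

    def to_csv(self, path, floor_negative: bool = False, decimals: int = 4) -> None:
        """Upper-triangle layout: cohorts on both axes, blank diagonal/lower."""
        df = (self.floored() if floor_negative else self.theta).round(decimals)
        out = df.astype(object)
        n = len(self.cohorts)
        for i in range(n):
            for j in range(i + 1):
                out.iat[i, j] = ""
        for i in range(n):
            for j in range(i + 1, n):
                out.iat[i, j] = f"{df.iat[i, j]:.{decimals}f}"
        out.to_csv(path, index_label="birth_year")


class PairwiseFst(BaseEstimator):
    """Pairwise multilocus WC84 theta between birth-year cohorts.

    Each cohort pair is analysed in isolation: per-locus components over
    the two cohorts, combined across loci as a ratio of sums.  Unequal
    cohort sizes are handled by the WC84 ``n_c`` weighting — no
    subsampling.

    Attributes
    ----------
    matrix_ : FstMatrix with the symmetric theta DataFrame
    theta_ : the DataFrame itself (NaN diagonal)
    """

    def __init__(self, cohort_key: str = "birth_year", floor_negative: bool = False):
        self.cohort_key = cohort_key
        self.floor_negative = floor_negative

    def fit(self, X: GenotypeTable, y=None) -> "PairwiseFst":
        if self.cohort_key != "birth_year":
            raise ValueError("only birth_year cohorts are supported")
        cohorts = [int(y_) for y_ in X.cohorts()]
        if len(cohorts) < 2:
            raise ValueError("need >=2 cohorts for pairwise F_ST")

        # per-cohort per-locus tallies computed once, reused for every pair
        tallies: dict[int, list[tuple[np.ndarray, np.ndarray, int, np.ndarray]]] = {}
        for year in cohorts:
            sub = X.subset(X.birth_years == year)
            per_locus = []
            for j in range(X.n_loci):
                geno = sub.alleles[:, j, :]
                typed = np.all(geno != MISSING, axis=1)
                g = geno[typed]
                alleles, inv = np.unique(g.ravel(), return_inverse=True)
                inv = inv.reshape(g.shape)
                ac = np.bincount(inv.ravel(), minlength=alleles.size).astype(float)
                het = inv[:, 0] != inv[:, 1]
                hc = np.zeros(alleles.size)
                np.add.at(hc, inv[het, 0], 1)
                np.add.at(hc, inv[het, 1], 1)
                per_locus.append((alleles, ac, g.shape[0], hc))
            tallies[year] = per_locus

        theta = pd.DataFrame(
            np.full((len(cohorts), len(cohorts)), np.nan),
            index=cohorts,
            columns=cohorts,
        )
        comps: dict[tuple[int, int], tuple[float, float]] = {}
        for y1, y2 in itertools.combinations(cohorts, 2):
            a_sum = abc_sum = 0.0
            for j in range(X.n_loci):
                al1, ac1, n1, hc1 = tallies[y1][j]
                al2, ac2, n2, hc2 = tallies[y2][j]
                if n1 < 2 or n2 < 2:
                    continue
                alleles = np.union1d(al1, al2)
                k = alleles.size
                ac = np.zeros((2, k))
                hc = np.zeros((2, k))
                ac[0, np.searchsorted(alleles, al1)] = ac1
                ac[1, np.searchsorted(alleles, al2)] = ac2
                hc[0, np.searchsorted(alleles, al1)] = hc1
                hc[1, np.searchsorted(alleles, al2)] = hc2
                a, b, c = wc_components_from_counts(
                    np.array([n1, n2], dtype=float), ac, hc
                )
                a_sum += a
                abc_sum += a + b + c
            t = float("nan") if abc_sum == 0 else a_sum / abc_sum
            theta.loc[y1, y2] = theta.loc[y2, y1] = t
            comps[(y1, y2)] = (a_sum, abc_sum)

        self.matrix_ = FstMatrix(cohorts=cohorts, theta=theta, per_pair_components=comps)
        self.theta_ = theta
        return self


def pairwise_fst(
    table: GenotypeTable,
    cohort_key: str = "birth_year",
    floor_negative: bool = False,
) -> FstMatrix:
    """Pairwise cohort theta matrix (thin estimator wrapper)."""
    est = PairwiseFst(cohort_key=cohort_key, floor_negative=floor_negative)
    return est.fit(table).matrix_
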