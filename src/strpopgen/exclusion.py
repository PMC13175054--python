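"""Non-exclusion probabilities for identity and parentage testing.

For a locus with allele frequencies :math:`p_i`, five non-exclusion
probabilities (NE) are computed under a shared model: genotypes drawn under
Hardy-Weinberg equilibrium, candidates unrelated, zero genotyping error,
exclusion judged on genotype compatibility alone:

* ``NE-I``  — a random individual has the same genotype as another random
  individual (probability of identity);
* ``NE-SI`` — two full sibs share a genotype (sib identity);
* ``NE-1P`` — a random non-parent is not excluded as a parent of a random
  offspring when the other parent is unknown (excluded iff candidate and
  offspring share no allele);
* ``NE-2P`` — a random non-parent is not excluded as the second parent
  given the offspring and one true parent (excluded iff the candidate
  carries no admissible transmitted allele);
* ``NE-PP`` — a random unrelated pair is not excluded as the parent pair
  (excluded iff no choice of one allele from each candidate reproduces the
  offspring genotype).

The normative computation is exact enumeration over all genotype
combinations weighted by their HWE probabilities (k alleles give
k(k+1)/2 genotypes; candidate sums are carried out with exact genotype-mass
algebra, never Monte Carlo).  Where a closed form exists (NE-I, NE-SI) it
is evaluated alongside the enumeration and the two must agree to 1e-12 —
a live guard against formula-transcription mistakes.

Loci combine multiplicatively (the panel loci are unlinked by design), and
identification accuracy is ``1 - combined NE``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .diversity import LocusFrequencies, _as_p, allele_frequencies
from .io import GenotypeTable

NE_COLUMNS = ("ne_1p", "ne_2p", "ne_pp", "ne_i", "ne_si")

_AGREEMENT_TOL = 1e-12


def _validate_p(freqs) -> np.ndarray:
    p = _as_p(freqs)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("frequency vector must be 1-D and non-empty")
    if np.any(p <= 0):
        raise ValueError("every frequency must be > 0")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"frequencies sum to {p.sum()}, not 1")
    return p / p.sum()


def _genotype_grid(p: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All unordered genotypes (i <= j) with their HWE probabilities."""
    k = p.size
    gi, gj = np.triu_indices(k)
    w = np.where(gi == gj, p[gi] ** 2, 2.0 * p[gi] * p[gj])
    return gi, gj, w


def _carries(k: int, gi: np.ndarray, gj: np.ndarray) -> np.ndarray:
    """Boolean (k, G): does genotype g carry allele x."""
    G = gi.size
    carr = np.zeros((k, G), dtype=bool)
    carr[gi, np.arange(G)] = True
    carr[gj, np.arange(G)] = True
    return carr


def ne_identity(freqs) -> float:
    """Probability two random HWE individuals share a genotype (NE-I).

    Enumeration ``sum_g P(g)^2`` and the closed form
    ``2 (sum p^2)^2 - sum p^4`` are both computed and must agree.
    """
    p = _validate_p(freqs)
    _, _, w = _genotype_grid(p)
    enum = float(np.sum(w**2))
    s2, s4 = float(np.sum(p**2)), float(np.sum(p**4))
    closed = 2.0 * s2**2 - s4
    if abs(enum - closed) > _AGREEMENT_TOL:  # pragma: no cover - guard
        raise RuntimeError(f"NE-I enumeration {enum} != closed form {closed}")
    return enum


def ne_sib_identity(freqs) -> float:
    """Probability two full sibs share a genotype (NE-SI).

    Enumeration over HWE parent pairs with two independent Mendelian
    offspring; the closed form
    ``1/4 + (1/2) sum p^2 + (1/2)(sum p^2)^2 - (1/4) sum p^4``
    must agree to 1e-12.
    """
    p = _validate_p(freqs)
    gi, gj, w = _genotype_grid(p)
    G = gi.size
    # offspring genotypes for the 4 equiprobable transmissions of each
    # parent-pair combination, as sorted pairs
    tm = np.stack([gi, gj])  # (2, G): the two transmittable alleles
    off_a = tm[:, None, :, None]          # parent-1 allele choice (2, 1, G, 1)
    off_b = tm[None, :, None, :]          # parent-2 allele choice (1, 2, 1, G)
    lo = np.minimum(off_a, off_b)         # (2, 2, G, G) broadcast
    hi = np.maximum(off_a, off_b)
    lo = np.transpose(lo, (2, 3, 0, 1)).reshape(G, G, 4)
    hi = np.transpose(hi, (2, 3, 0, 1)).reshape(G, G, 4)
    same = (lo[:, :, :, None] == lo[:, :, None, :]) & (
        hi[:, :, :, None] == hi[:, :, None, :]
    )
    p_same = same.sum(axis=(2, 3)) / 16.0  # (G, G)
    enum = float(w @ p_same @ w)
    s2, s4 = float(np.sum(p**2)), float(np.sum(p**4))
    closed = 0.25 + 0.5 * s2 + 0.5 * s2**2 - 0.25 * s4
    if abs(enum - closed) > _AGREEMENT_TOL:  # pragma: no cover - guard
        raise RuntimeError(f"NE-SI enumeration {enum} != closed form {closed}")
    return enum


def ne_first_parent(freqs) -> float:
    """NE-1P: candidate not excluded as single parent (no second parent).

    Exact enumeration over (offspring, candidate) genotype pairs; the
    candidate survives iff it shares at least one allele with the
    offspring.
    """
    p = _validate_p(freqs)
    gi, gj, w = _genotype_grid(p)
    carr = _carries(p.size, gi, gj)
    share = carr[gi] | carr[gj]  # (G offspring, G candidate)
    return float(w @ share @ w)


def ne_second_parent(freqs) -> float:
    """NE-2P: candidate not excluded as second parent given one true parent.

    Enumeration over the true parent's genotype, its transmitted allele,
    the second parent's transmitted allele (its HWE genotype marginalised
    exactly to the allele frequencies), and the candidate's genotype.  The
    admissible transmitted-allele set is the offspring minus what the known
    parent can explain: if both offspring alleles could come from the known
    parent, either allele is admissible; otherwise only the obligate one.
    """
    p = _validate_p(freqs)
    k = p.size
    gi, gj, w = _genotype_grid(p)
    carr = _carries(k, gi, gj)
    # q1[x]   : P(candidate carries allele x)
    # q2[x,y] : P(candidate carries x or y)
    q1 = w @ carr.T                       # (k,)
    q2 = w @ (carr[:, None, :] | carr[None, :, :]).reshape(k * k, -1).T
    q2 = q2.reshape(k, k)
    G = gi.size
    # candidate-survival probability for known parent g transmitting t and
    # the other parent transmitting u: admissible = {t, u} if g carries u
    # else {u}
    carried = np.zeros((G, k), dtype=bool)
    carried[np.arange(G), gi] = True
    carried[np.arange(G), gj] = True
    total = 0.0
    for t_slot in (gi, gj):
        surv = np.where(carried, q2[t_slot, :], q1[None, :])  # (G, k)
        total += 0.5 * float(w @ (surv @ p))
    return total


def ne_parent_pair(freqs) -> float:
    """NE-PP: unrelated pair not excluded as the parent pair.

    Enumeration over (offspring, candidate1, candidate2): the pair survives
    iff one allele from each candidate can reproduce the offspring
    genotype.  The double candidate sum is carried out exactly via
    genotype-mass inclusion-exclusion.
    """
    p = _validate_p(freqs)
    k = p.size
    gi, gj, w = _genotype_grid(p)
    carr = _carries(k, gi, gj)
    q1 = w @ carr.T                                       # P(carries x)
    qboth = np.einsum("g,xg,yg->xy", w, carr, carr)       # P(carries x and y)
    # offspring (i, j): survive iff (c1 has i and c2 has j) or swapped
    i, j = gi, gj
    het = i != j
    surv = np.where(
        het,
        2.0 * q1[i] * q1[j] - qboth[i, j] ** 2,
        q1[i] * q1[i],
    )
    return float(np.sum(w * surv))


def exclusion_probabilities(freqs) -> dict[str, float]:
    """All five NE values for one locus's allele frequencies."""
    return {
        "ne_1p": ne_first_parent(freqs),
        "ne_2p": ne_second_parent(freqs),
        "ne_pp": ne_parent_pair(freqs),
        "ne_i": ne_identity(freqs),
        "ne_si": ne_sib_identity(freqs),
    }


def combine_loci(per_locus: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Combine per-locus NE rows across unlinked loci.

    Returns the per-column product (combined NE) and ``1 - product``
    (identification accuracy).
    """
    if per_locus.shape[0] < 1:
        raise ValueError("need >= 1 locus")
    cols = [c for c in NE_COLUMNS if c in per_locus.columns]
    combined = per_locus[cols].prod(axis=0).rename("combined")
    accuracy = (1.0 - combined).rename("accuracy")
    return combined, accuracy


@dataclass
class ExclusionReport:
    """Per-locus NE rows, the combined product row and the accuracy row."""

    per_locus: pd.DataFrame
    combined: pd.Series
    accuracy: pd.Series

    def to_frame(self) -> pd.DataFrame:
        frame = self.per_locus.copy()
        frame.loc["Combined"] = self.combined
        frame.loc["Accuracy"] = self.accuracy
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="locus")

    def to_text(self) -> str:
        df = self.per_locus.copy().map(lambda v: f"{v:.3f}")
        df.loc["Combined"] = self.combined.map(lambda v: f"{v:.2E}")
        df.loc["Accuracy"] = self.accuracy.map(lambda v: f"{v:.8f}")
        return df.to_string()


class ExclusionPower(BaseEstimator):
    """Panel-wide identity/parentage exclusion power from a genotype table.

    Frequencies are computed from the entire (QC'd) table — the exclusion
    report describes the population the candidates are drawn from.

    Attributes
    ----------
    frequencies_ : dict locus -> LocusFrequencies
    report_ : ExclusionReport (per-locus, combined, accuracy)
    """

    def fit(self, X: GenotypeTable, y=None) -> "ExclusionPower":
        self.frequencies_ = {loc: allele_frequencies(X, loc) for loc in X.panel}
        rows = {
            loc: exclusion_probabilities(lf)
            for loc, lf in self.frequencies_.items()
        }
        per_locus = pd.DataFrame.from_dict(rows, orient="index").loc[
            list(X.panel), list(NE_COLUMNS)
        ]
        per_locus.index.name = "locus"
        combined, accuracy = combine_loci(per_locus)
        self.report_ = ExclusionReport(
            per_locus=per_locus, combined=combined, accuracy=accuracy
        )
        return self


def exclusion_report(table: GenotypeTable) -> ExclusionReport:
    """Panel exclusion report (thin estimator wrapper)."""
    return ExclusionPower().fit(table).report_
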