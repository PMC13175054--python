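"""Synthetic microsatellite cohort generator with a ground-truth ledger.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage can be tested by parameter recovery without any
external data:

* ancestral allele frequencies per locus drawn from a symmetric Dirichlet
  (or supplied explicitly);
* per-cohort drift under the Balding-Nichols model — cohort frequencies
  drawn from ``Dirichlet(p * (1 - F)/F)`` so the drift parameter *is* the
  expected pairwise F_ST, making the F-statistics estimators testable by
  recovery.  Two drift geometries are available: ``"star"`` (each cohort
  an independent draw around the ancestral; every cohort pair targets F)
  and ``"chain"`` (a year-on-year random walk; divergence accumulates with
  the birth-year gap);
* genotypes drawn with inbreeding coefficient ``f``:
  ``P(ii) = p_i^2 + f p_i (1 - p_i)``, ``P(ij) = 2 p_i p_j (1 - f)``;
  negative ``f`` (heterozygote excess) is supported down to the per-locus
  bound ``-p_min/(1 - p_min)``;
* sex-determination markers consistent with the drawn sex (females X/X,
  males X/Y) except where anomalies are injected;
* QC defects injected last — missing calls, out-of-range alleles, three
  kinds of sex-marker anomaly, and duplicated barcodes (2- and 3-fold,
  concordant or discordant) — with every injection recorded in a
  :class:`TruthLedger` that predicts the QC cascade's stage counts exactly.

A single RNG stream keyed by ``seed`` drives all randomness in a fixed
documented order (frequencies -> genotypes -> sex -> defect selection ->
defect content -> final shuffle), so the same seed reproduces the same
table bitwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .io import (
    MARKER_MISSING,
    MARKER_X,
    MARKER_Y,
    MISSING,
    SEX_FEMALE,
    SEX_MALE,
    GenotypeTable,
)
from .qc import QcConfig


@dataclass(frozen=True)
class Locus:
    """A microsatellite locus: name plus its allele-size ladder (bp)."""

    name: str
    alleles: tuple[int, ...]

    @property
    def k(self) -> int:
        return len(self.alleles)


@dataclass
class DefectRates:
    """Per-record injection probabilities for QC defects.

    ``sex_*`` are the three disjoint sex-marker anomaly sub-rates (an OTHER
    value, a missing marker, a registered-sex mismatch).  ``duplicate_*``
    are per-record probabilities of spawning a duplicated-barcode group of
    that multiplicity; ``duplicate_concordant_fraction`` is the fraction of
    those groups whose members agree (and are therefore recoverable by
    merging).
    """

    missing_call: float = 0.0
    out_of_range: float = 0.0
    sex_other: float = 0.0
    sex_missing: float = 0.0
    sex_mismatch: float = 0.0
    duplicate_2fold: float = 0.0
    duplicate_3fold: float = 0.0
    duplicate_concordant_fraction: float = 1.0

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class SimulationConfig:
    """Everything that defines one synthetic cohort table."""

    seed: int
    panel: list[Locus]
    cohort_sizes: dict[int, int]
    dirichlet_alpha: float = 1.0
    ancestral_freqs: dict[str, dict[int, float]] | None = None
    f_drift: float = 0.0
    drift_model: str = "star"
    f_is: float = 0.0
    sex_ratio: float = 0.68
    defect_rates: DefectRates = field(default_factory=DefectRates)

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_drift < 1.0:
            raise ValueError("f_drift must be in [0, 1)")
        if self.drift_model not in ("star", "chain"):
            raise ValueError("drift_model must be 'star' or 'chain'")
        if any(n < 0 for n in self.cohort_sizes.values()):
            raise ValueError("cohort sizes must be >= 0")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be in [0, 1]")


@dataclass
class TruthLedger:
    """Ground truth for one simulated table.

    Holds the true frequencies and inbreeding coefficient (for recovery
    tests) and the exact identity of every injected defect (the oracle for
    the QC cascade's counted drops).
    """

    f_is: float
    ancestral_freqs: dict[str, dict[int, float]]
    cohort_freqs: dict[int, dict[str, dict[int, float]]]
    n_raw: int = 0
    missing_ids: list[str] = field(default_factory=list)
    range_ids: list[str] = field(default_factory=list)
    sex_other_ids: list[str] = field(default_factory=list)
    sex_missing_ids: list[str] = field(default_factory=list)
    sex_mismatch_ids: list[str] = field(default_factory=list)
    #: one entry per duplicated-barcode group: (barcode, multiplicity, concordant)
    duplicate_groups: list[tuple[str, int, bool]] = field(default_factory=list)
    #: per-year count of records that survive stages ii-v (clean singletons
    #: plus one merged record per concordant duplicate group)
    survivors_by_year: dict[int, int] = field(default_factory=dict)

    def expected_qc_counts(self, min_cohort_size: int) -> dict:
        """Predict the QC report's stage counts for a given cohort floor."""
        found: dict[int, int] = {}
        dropped = recovered = 0
        for _, mult, concordant in self.duplicate_groups:
            found[mult] = found.get(mult, 0) + 1
            dropped += mult
            recovered += int(concordant)
        small = sum(
            n for n in self.survivors_by_year.values() if n < min_cohort_size
        )
        final = sum(self.survivors_by_year.values()) - small
        return {
            "raw": self.n_raw,
            "missing_removed": len(self.missing_ids),
            "range_removed": len(self.range_ids),
            "sex_removed": len(self.sex_other_ids)
            + len(self.sex_missing_ids)
            + len(self.sex_mismatch_ids),
            "sex_subcounts": {
                "no_xy": len(self.sex_other_ids),
                "no_marker": len(self.sex_missing_ids),
                "mismatch": len(self.sex_mismatch_ids),
            },
            "duplicates_found": found,
            "duplicate_records_dropped": dropped,
            "duplicates_recovered": recovered,
            "small_cohort_removed": small,
            "final": final,
        }

    def to_json(self, path) -> None:
        data = {
            "f_is": self.f_is,
            "n_raw": self.n_raw,
            "ancestral_freqs": {
                loc: {str(a): p for a, p in f.items()}
                for loc, f in self.ancestral_freqs.items()
            },
            "cohort_freqs": {
                str(y): {loc: {str(a): p for a, p in f.items()} for loc, f in d.items()}
                for y, d in self.cohort_freqs.items()
            },
            "missing_ids": self.missing_ids,
            "range_ids": self.range_ids,
            "sex_other_ids": self.sex_other_ids,
            "sex_missing_ids": self.sex_missing_ids,
            "sex_mismatch_ids": self.sex_mismatch_ids,
            "duplicate_groups": [list(g) for g in self.duplicate_groups],
            "survivors_by_year": {str(y): n for y, n in self.survivors_by_year.items()},
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2)


# ----------------------------------------------------------------- drawing
def _genotype_probs(p: np.ndarray, f: float, locus: str, year: int) -> np.ndarray:
    """Unordered-genotype probability vector with inbreeding ``f``."""
    k = p.size
    gi, gj = np.triu_indices(k)
    hom = gi == gj
    probs = np.where(
        hom,
        p[gi] ** 2 + f * p[gi] * (1.0 - p[gi]),
        2.0 * p[gi] * p[gj] * (1.0 - f),
    )
    if np.any(probs < -1e-12):
        pmin = float(p.min())
        raise ValueError(
            f"f_is={f} below the lower bound -p_min/(1-p_min)="
            f"{-pmin / (1.0 - pmin):.4f} at locus {locus} (cohort {year})"
        )
    probs = np.clip(probs, 0.0, None)
    return probs / probs.sum()


def _draw_freqs(rng: np.random.Generator, center: np.ndarray, F: float) -> np.ndarray:
    """One Balding-Nichols draw around ``center`` with drift parameter F."""
    if F == 0.0:
        return center.copy()
    conc = center * (1.0 - F) / F
    draw = rng.dirichlet(conc)
    # guard against numerically zero categories from extreme draws
    draw = np.clip(draw, 1e-12, None)
    return draw / draw.sum()


def simulate(config: SimulationConfig) -> tuple[GenotypeTable, TruthLedger]:
    """Generate a genotype table plus its ground-truth ledger."""
    rng = np.random.default_rng(config.seed)
    panel = config.panel
    years = sorted(config.cohort_sizes)

    # 1. ancestral frequencies
    ancestral: dict[str, np.ndarray] = {}
    for locus in panel:
        if config.ancestral_freqs is not None:
            given = config.ancestral_freqs[locus.name]
            p = np.array([given[a] for a in locus.alleles], dtype=float)
            p = p / p.sum()
        else:
            p = rng.dirichlet(np.full(locus.k, config.dirichlet_alpha))
            p = np.clip(p, 1e-9, None)
            p = p / p.sum()
        ancestral[locus.name] = p

    # 2. per-cohort frequencies under the chosen drift geometry
    cohort_freqs: dict[int, dict[str, np.ndarray]] = {}
    prev = ancestral
    for year in years:
        current: dict[str, np.ndarray] = {}
        for locus in panel:
            center = ancestral[locus.name] if config.drift_model == "star" else prev[
                locus.name
            ]
            current[locus.name] = _draw_freqs(rng, center, config.f_drift)
        cohort_freqs[year] = current
        prev = current

    # 3. genotypes, sex, metadata
    blocks_alleles, blocks_years, blocks_sex = [], [], []
    for year in years:
        n = config.cohort_sizes[year]
        if n == 0:
            continue
        geno = np.empty((n, len(panel), 2), dtype=np.int32)
        for j, locus in enumerate(panel):
            p = cohort_freqs[year][locus.name]
            probs = _genotype_probs(p, config.f_is, locus.name, year)
            gi, gj = np.triu_indices(locus.k)
            draw = rng.choice(gi.size, size=n, p=probs)
            sizes = np.asarray(locus.alleles, dtype=np.int32)
            geno[:, j, 0] = sizes[gi[draw]]
            geno[:, j, 1] = sizes[gj[draw]]
        blocks_alleles.append(geno)
        blocks_years.append(np.full(n, year, dtype=np.int32))
        blocks_sex.append(
            np.where(rng.random(n) < config.sex_ratio, SEX_FEMALE, SEX_MALE)
        )

    alleles = np.concatenate(blocks_alleles) if blocks_alleles else np.empty(
        (0, len(panel), 2), dtype=np.int32
    )
    birth_years = np.concatenate(blocks_years) if blocks_years else np.empty(
        0, dtype=np.int32
    )
    sexes = np.concatenate(blocks_sex) if blocks_sex else np.empty(0, dtype=object)
    n_base = alleles.shape[0]
    barcodes = np.array([f"H{i:07d}" for i in range(n_base)], dtype=object)
    markers = np.empty((n_base, 2), dtype=object)
    markers[sexes == SEX_FEMALE] = (MARKER_X, MARKER_X)
    markers[sexes == SEX_MALE] = (MARKER_X, MARKER_Y)

    ledger = TruthLedger(
        f_is=config.f_is,
        ancestral_freqs={
            loc.name: {
                int(a): float(p)
                for a, p in zip(loc.alleles, ancestral[loc.name])
            }
            for loc in panel
        },
        cohort_freqs={
            int(year): {
                loc.name: {
                    int(a): float(p)
                    for a, p in zip(loc.alleles, cohort_freqs[year][loc.name])
                }
                for loc in panel
            }
            for year in years
        },
    )

    # 4. defect injection: disjoint record sets chosen in priority order
    rates = config.defect_rates
    order = rng.permutation(n_base)
    cursor = 0

    def take(rate: float) -> np.ndarray:
        nonlocal cursor
        want = int(rng.binomial(n_base, rate)) if rate > 0 else 0
        got = order[cursor : cursor + min(want, n_base - cursor)]
        cursor += got.size
        return got

    missing_idx = take(rates.missing_call)
    range_idx = take(rates.out_of_range)
    sex_other_idx = take(rates.sex_other)
    sex_missing_idx = take(rates.sex_missing)
    sex_mismatch_idx = take(rates.sex_mismatch)
    dup2_idx = take(rates.duplicate_2fold)
    dup3_idx = take(rates.duplicate_3fold)

    loc_sizes = [np.asarray(loc.alleles, dtype=np.int32) for loc in panel]

    for i in missing_idx:
        j = int(rng.integers(len(panel)))
        slots = (0, 1) if rng.random() < 0.5 else (int(rng.integers(2)),)
        for s in slots:
            alleles[i, j, s] = MISSING
    for i in range_idx:
        j = int(rng.integers(len(panel)))
        alleles[i, j, int(rng.integers(2))] = int(loc_sizes[j].max()) + 2 * int(
            rng.integers(1, 6)
        )
    for i in sex_other_idx:
        markers[i, int(rng.integers(2))] = "N"
    for i in sex_missing_idx:
        markers[i, int(rng.integers(2))] = MARKER_MISSING
    for i in sex_mismatch_idx:
        markers[i] = (
            (MARKER_X, MARKER_Y) if sexes[i] == SEX_FEMALE else (MARKER_X, MARKER_X)
        )

    extra_alleles, extra_years, extra_sex, extra_markers, extra_barcodes = (
        [], [], [], [], []
    )

    def spawn_duplicates(idx: np.ndarray, multiplicity: int) -> None:
        for i in idx:
            concordant = bool(rng.random() < rates.duplicate_concordant_fraction)
            for copy_no in range(multiplicity - 1):
                copy = alleles[i].copy()
                if not concordant and copy_no == 0:
                    j = int(rng.integers(len(panel)))
                    slot = int(rng.integers(2))
                    choices = loc_sizes[j][loc_sizes[j] != copy[j, slot]]
                    copy[j, slot] = int(choices[int(rng.integers(choices.size))])
                extra_alleles.append(copy)
                extra_years.append(int(birth_years[i]))
                extra_sex.append(sexes[i])
                extra_markers.append(tuple(markers[i]))
                extra_barcodes.append(str(barcodes[i]))
            ledger.duplicate_groups.append(
                (str(barcodes[i]), multiplicity, concordant)
            )

    spawn_duplicates(dup2_idx, 2)
    spawn_duplicates(dup3_idx, 3)

    ledger.missing_ids = [str(barcodes[i]) for i in missing_idx]
    ledger.range_ids = [str(barcodes[i]) for i in range_idx]
    ledger.sex_other_ids = [str(barcodes[i]) for i in sex_other_idx]
    ledger.sex_missing_ids = [str(barcodes[i]) for i in sex_missing_idx]
    ledger.sex_mismatch_ids = [str(barcodes[i]) for i in sex_mismatch_idx]

    # survivors of stages ii-v: clean singletons + 1 per concordant group
    defective = np.zeros(n_base, dtype=bool)
    for idx in (
        missing_idx, range_idx, sex_other_idx, sex_missing_idx, sex_mismatch_idx,
        dup2_idx, dup3_idx,
    ):
        defective[idx] = True
    survivors: dict[int, int] = {}
    for year in years:
        mask = (birth_years == year) & ~defective
        survivors[int(year)] = int(mask.sum())
    for bc, mult, concordant in ledger.duplicate_groups:
        if concordant:
            i = int(bc[1:])
            survivors[int(birth_years[i])] += 1
    ledger.survivors_by_year = survivors

    if extra_alleles:
        alleles = np.concatenate([alleles, np.stack(extra_alleles)])
        birth_years = np.concatenate(
            [birth_years, np.array(extra_years, dtype=np.int32)]
        )
        sexes = np.concatenate([sexes, np.array(extra_sex, dtype=object)])
        markers = np.concatenate(
            [markers, np.array(extra_markers, dtype=object).reshape(-1, 2)]
        )
        barcodes = np.concatenate(
            [barcodes, np.array(extra_barcodes, dtype=object)]
        )

    ledger.n_raw = alleles.shape[0]

    # 5. final shuffle so record order carries no information
    perm = rng.permutation(alleles.shape[0])
    table = GenotypeTable(
        [loc.name for loc in panel],
        alleles[perm],
        barcodes[perm],
        birth_years[perm],
        sexes[perm],
        markers[perm],
    )
    return table, ledger


# ------------------------------------------------------------------ presets
#: the 11 autosomal loci of the national cattle parentage panel with their
#: reported allele counts; ladders are plausible even-spaced dinucleotide
#: size ranges (the true size bins are instrument configuration)
_PANEL_K = {
    "BM1824": (11, 176),
    "BM2113": (17, 122),
    "ETH10": (12, 207),
    "ETH225": (11, 140),
    "ETH3": (15, 103),
    "INRA023": (16, 195),
    "SPS115": (15, 234),
    "TGLA122": (28, 136),
    "TGLA126": (9, 115),
    "TGLA227": (19, 75),
    "TGLA53": (19, 152),
}

#: post-QC cohort-size profile of the national dataset (heads per birth year)
_COHORT_TOTALS = {
    2001: 107, 2002: 198, 2003: 342, 2004: 547, 2005: 1001, 2006: 1672,
    2007: 2652, 2008: 4229, 2009: 6679, 2010: 11719, 2011: 16543,
    2012: 25588, 2013: 31267, 2014: 38457, 2015: 47925, 2016: 61112,
    2017: 77225, 2018: 91083, 2019: 87444, 2020: 105384, 2021: 93300,
    2022: 71733, 2023: 2337,
}


def default_panel() -> list[Locus]:
    """The 11-locus cattle parentage panel with plausible size ladders."""
    return [
        Locus(name, tuple(base + 2 * i for i in range(k)))
        for name, (k, base) in _PANEL_K.items()
    ]


def default_qc_config(panel: list[Locus] | None = None, **kwargs) -> QcConfig:
    """QC config whose allele ranges are the panel's own size ladders."""
    panel = panel or default_panel()
    ranges = {loc.name: (min(loc.alleles), max(loc.alleles)) for loc in panel}
    return QcConfig(allele_ranges=ranges, **kwargs)


def preset_hanwoo_like(seed: int, cohort_scale: int = 100) -> SimulationConfig:
    """Desk-scale preset mimicking the national Hanwoo cow dataset's shape.

    Cohort sizes are the dataset's birth-year profile divided by
    ``cohort_scale`` (floor 50 heads); the panel carries the real locus
    names and allele counts.  This mimics the *shape* of the data —
    unequal cohorts, a 9-28 allele panel, realistic defect rates — not the
    study population's actual allele frequencies, which are not public.
    Drift uses the star geometry at F = 0.003 (the mid-range of the
    observed between-cohort differentiation) and genotypes are drawn at
    Hardy-Weinberg equilibrium (the analyzed population's inbreeding
    coefficient is indistinguishable from zero at this scale).
    """
    return SimulationConfig(
        seed=seed,
        panel=default_panel(),
        cohort_sizes={
            year: max(total // cohort_scale, 50)
            for year, total in _COHORT_TOTALS.items()
        },
        # E[1 - sum p^2] = 1 - (a+1)/(ka+1): alpha 0.35 puts the panel's
        # expected gene diversity in the 0.65-0.9 band typical of these loci
        dirichlet_alpha=0.35,
        f_drift=0.003,
        drift_model="star",
        f_is=0.0,
        sex_ratio=0.68,
        defect_rates=DefectRates(
            missing_call=0.041,
            out_of_range=0.0004,
            sex_other=0.0001,
            sex_missing=0.094,
            sex_mismatch=0.024,
            duplicate_2fold=0.019,
            duplicate_3fold=0.0005,
            duplicate_concordant_fraction=0.12,
        ),
    )
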