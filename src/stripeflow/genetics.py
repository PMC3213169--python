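"""Mendelian cross expectations and viability statistics.

The viability assays score adult (or larval) offspring of crosses between
flies carrying an eve-null chromosome 2 (R13, Df(eve) or the
enhancer-deleted allele) balanced over CyO, and a chromosome-3 rescue
transgene balanced over TM3.  Balancer homozygotes (CyO/CyO, TM3/TM3) die
as embryos and are removed from the expectation before renormalization;
eve-null "rescue" classes are never auto-removed — their depletion relative
to Mendelian expectation is the measurand.

Relative viability of a rescue class is reported as a rescue percentage:
100 x observed / expected, where the expected count is scaled from the
control classes (flies carrying one copy of the endogenous eve locus and
one or two transgene-bearing third chromosomes, which segregate 2:1 and are
fully viable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "CrossSchema",
    "ViabilityEstimate",
    "BALANCERS",
    "cross_expectation",
    "class_label",
    "class_frequency",
    "rescue_percentage",
    "ratio_test",
    "sex_ratio_test",
    "parasegment_ratio",
]

#: Balancer chromosomes whose homozygotes are embryonic lethal.
BALANCERS = frozenset({"CyO", "TM3"})


def _genotype(a: str, b: str) -> str:
    """Canonical unordered genotype label for one chromosome."""
    return "/".join(sorted((a, b)))


@dataclass(frozen=True)
class CrossSchema:
    """Parental genotypes as per-chromosome allele pairs.

    ``chromosomes`` maps a chromosome name to ``(maternal, paternal)`` allele
    pairs, e.g. ``{"chr2": (("R13", "CyO"), ("R13", "R13"))}``.  Alleles are
    free-form strings; names in ``lethal_balancers`` mark chromosomes whose
    homozygotes are removed from the expectation.
    """

    chromosomes: dict[str, tuple[tuple[str, str], tuple[str, str]]]
    lethal_balancers: frozenset[str] = BALANCERS

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("cross schema needs at least one chromosome")
        for chrom, pairs in self.chromosomes.items():
            if len(pairs) != 2 or any(len(p) != 2 for p in pairs):
                raise ValueError(f"malformed genotype for {chrom}: {pairs!r}")

    @classmethod
    def from_yaml(cls, path) -> "CrossSchema":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        chroms = {
            chrom: (tuple(v["maternal"]), tuple(v["paternal"]))
            for chrom, v in doc["chromosomes"].items()
        }
        lethal = frozenset(doc.get("lethal_balancers", BALANCERS))
        return cls(chromosomes=chroms, lethal_balancers=lethal)


def cross_expectation(cross: CrossSchema) -> pd.DataFrame:
    """Expected offspring genotype frequencies after lethality filtering.

    Mendelian segregation per chromosome, independent assortment across
    chromosomes, balancer-homozygote classes removed, frequencies
    renormalized over the surviving classes (they sum to 1).
    """
    per_chrom: dict[str, dict[str, float]] = {}
    for chrom, (mat, pat) in cross.chromosomes.items():
        freqs: dict[str, float] = {}
        for a, b in product(mat, pat):
            g = _genotype(a, b)
            freqs[g] = freqs.get(g, 0.0) + 0.25
        per_chrom[chrom] = freqs

    chrom_names = sorted(per_chrom)
    rows = []
    for combo in product(*(per_chrom[c].items() for c in chrom_names)):
        genos = {c: g for c, (g, _) in zip(chrom_names, combo)}
        f = float(np.prod([fr for _, fr in combo]))
        lethal = any(
            g.split("/")[0] == g.split("/")[1] and g.split("/")[0] in cross.lethal_balancers
            for g in genos.values()
        )
        if not lethal:
            rows.append({**genos, "frequency": f})
    if not rows:
        raise ValueError("no surviving offspring classes (zero total frequency)")
    df = pd.DataFrame(rows)
    total = df["frequency"].sum()
    if total <= 0:
        raise ValueError("no surviving offspring classes (zero total frequency)")
    df["frequency"] /= total
    # merge identical classes arising from distinct gamete combinations
    df = df.groupby(chrom_names, as_index=False)["frequency"].sum()
    df["class"] = [class_label({c: r[c] for c in chrom_names}) for _, r in df.iterrows()]
    return df[["class", *chrom_names, "frequency"]]


def class_label(genotypes: dict[str, str]) -> str:
    """Canonical string for an offspring class, e.g. ``'R13/R13; +/tg'``."""
    parts = []
    for chrom in sorted(genotypes):
        a, b = genotypes[chrom].split("/")
        parts.append(_genotype(a, b))
    return "; ".join(parts)


def class_frequency(expectation: pd.DataFrame, **genotypes: str) -> float:
    """Frequency of the class matching the given per-chromosome genotypes."""
    mask = np.ones(len(expectation), dtype=bool)
    for chrom, g in genotypes.items():
        mask &= expectation[chrom] == _genotype(*g.split("/"))
    sub = expectation[mask]
    if len(sub) == 0:
        return 0.0
    return float(sub["frequency"].sum())


@dataclass(frozen=True)
class ViabilityEstimate:
    """Rescue percentage with its binomial standard deviation."""

    genotype_class: str
    observed: int
    expected: float
    rescue_percent: float
    binomial_sd: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def rescue_percentage(
    counts: pd.DataFrame,
    expectation: pd.DataFrame,
    rescue_class: str,
    control_classes: list[str],
) -> ViabilityEstimate:
    """Relative viability of a rescue class scaled from control classes.

    ``counts`` needs ``class`` and ``count`` columns (a ``sex`` column, if
    present, is summed over).  The expected rescue count is the combined
    control count times the ratio of Mendelian frequencies
    (rescue / combined controls).  The binomial SD of the percentage is
    ``100 * sqrt(p(1-p)/n)`` with ``p = observed/expected`` capped to [0, 1]
    and ``n`` the expected count.
    """
    by_class = counts.groupby("class")["count"].sum()
    missing = [c for c in control_classes if c not in by_class.index]
    if missing:
        raise ValueError(f"control classes missing from counts: {missing}")
    freq = expectation.set_index("class")["frequency"]
    f_rescue = float(freq.get(rescue_class, 0.0))
    f_controls = float(sum(freq.get(c, 0.0) for c in control_classes))
    if f_rescue <= 0 or f_controls <= 0:
        raise ValueError("rescue and control classes must have positive expected frequency")
    n_controls = int(by_class[control_classes].sum())
    expected = n_controls * f_rescue / f_controls
    if expected <= 0:
        raise ValueError("expected rescue count is zero")
    observed = int(by_class.get(rescue_class, 0))
    p_hat = min(max(observed / expected, 0.0), 1.0)
    sd = 100.0 * float(np.sqrt(p_hat * (1.0 - p_hat) / expected))
    return ViabilityEstimate(
        genotype_class=rescue_class,
        observed=observed,
        expected=float(expected),
        rescue_percent=100.0 * observed / expected,
        binomial_sd=sd,
    )


def ratio_test(observed, expected_freqs) -> tuple[float, float]:
    """Pearson chi-squared test of observed counts against expected ratios.

    ``expected_freqs`` need not be normalized; they are scaled to the
    observed total.  df = number of classes - 1; no continuity correction.
    """
    obs = np.asarray(observed, dtype=float)
    f = np.asarray(expected_freqs, dtype=float)
    if obs.size < 2:
        raise ValueError("need at least two classes")
    if np.any(f <= 0):
        raise ValueError("expected frequencies must be positive")
    exp = f / f.sum() * obs.sum()
    stat, p = stats.chisquare(obs, exp)
    return float(stat), float(p)


def sex_ratio_test(counts_by_sex) -> tuple[float, float]:
    """Chi-squared test of male/female counts against a 1:1 expectation."""
    obs = np.asarray(counts_by_sex, dtype=float)
    if obs.size != 2:
        raise ValueError("sex-ratio test expects exactly two counts")
    return ratio_test(obs, np.array([1.0, 1.0]))


def parasegment_ratio(len_ps3: float, len_ps4: float) -> float:
    """Parasegment-3 share of the parasegment 3+4 span (ventral midline).

    Reports Engrailed-stripe spacing as ps3 / (ps3 + ps4); a vestigial,
    anterior-shifted En stripe 4 shrinks this ratio.
    """
    if len_ps3 <= 0 or len_ps4 <= 0:
        raise ValueError("parasegment lengths must be positive")
    return float(len_ps3 / (len_ps3 + len_ps4))
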