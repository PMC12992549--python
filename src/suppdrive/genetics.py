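"""Single-locus, three-allele genetics of a CRISPR homing suppression drive.

The model tracks one effective target site with three allele classes:

* ``W`` — wild-type,
* ``D`` — the drive allele (gRNA cassette inserted in a female-fertility gene),
* ``R`` — a nonfunctional resistance allele (end-joining repair product that
  disrupts the target gene and can no longer be cut).

Germline drive conversion: in the germline of an individual carrying both a
drive allele and Cas9, each wild-type allele is cleaved with probability
``germline_cut_rate`` (g); a cleaved allele is converted to ``D`` by
homology-directed repair with probability ``c`` (sex-specific) and otherwise
becomes ``R``.  A D/W germline therefore transmits

    P(D) = 1/2 + g*c/2,   P(R) = g*(1-c)/2,   P(W) = (1-g)/2.

Embryo resistance: a mother carrying Cas9 and a drive allele deposits
Cas9/gRNA into her eggs; each wild-type allele in the zygote is independently
converted to ``R`` with probability ``e``.

Fertility: the target gene is haplosufficient and recessive female-sterile,
so females with at least one ``W`` allele are fertile, females carrying only
``D``/``R`` alleles are sterile, and D/W heterozygous females may pay a
fitness cost ``f_het`` (relative fecundity).  Males are unaffected.

No functional resistance class is modelled: multiplexed gRNAs make functional
repair at every site jointly unlikely, so end-joining products are treated as
uniformly nonfunctional.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

__all__ = [
    "Allele",
    "Genotype",
    "DriveParams",
    "GameteDistribution",
    "gamete_distribution",
    "apply_embryo_resistance",
    "offspring_genotype_distribution",
    "female_fertility",
    "expected_inheritance_rate",
    "enumerate_cross",
    "GENOTYPE_PAIRS",
    "genotype_index",
    "offspring_tensor",
    "fertility_weights",
    "CARRIER_MASK",
]


class Allele(Enum):
    """Allele classes at the drive locus."""

    W = "W"
    D = "D"
    R = "R"

    def __repr__(self) -> str:  # compact in distro dicts
        return self.value


# Canonical unordered allele pairs, used as the genotype index space
# throughout the cage model: 0 W/W, 1 D/W, 2 R/W, 3 D/D, 4 D/R, 5 R/R.
_ORDER = {Allele.W: 0, Allele.D: 1, Allele.R: 2}
GENOTYPE_PAIRS: tuple[tuple[Allele, Allele], ...] = (
    (Allele.W, Allele.W),
    (Allele.W, Allele.D),
    (Allele.W, Allele.R),
    (Allele.D, Allele.D),
    (Allele.D, Allele.R),
    (Allele.R, Allele.R),
)
_PAIR_INDEX = {frozenset_or_pair: i for i, frozenset_or_pair in enumerate(GENOTYPE_PAIRS)}

#: boolean mask over the 6 genotype indices: carries >= 1 drive allele
CARRIER_MASK = np.array([False, True, False, True, True, False])


def _canonical(a1: Allele, a2: Allele) -> tuple[Allele, Allele]:
    return (a1, a2) if _ORDER[a1] <= _ORDER[a2] else (a2, a1)


@dataclass(frozen=True)
class Genotype:
    """A diploid individual at the drive locus.

    The allele pair is unordered (``D/W`` == ``W/D``); ``cas9_present`` marks
    whether the individual carries Cas9 (in a split drive, Cas9 segregates at
    an unlinked locus and is tracked as a flag, not a second locus);
    ``maternal_cas9`` records whether the individual's mother carried Cas9,
    which matters when maternal Cas9 deposition itself carries a fitness cost.
    """

    a1: Allele
    a2: Allele
    sex: str | None = None  # "female", "male" or None (unsexed zygote)
    cas9_present: bool = True
    maternal_cas9: bool = True

    def __post_init__(self) -> None:
        a1, a2 = _canonical(self.a1, self.a2)
        object.__setattr__(self, "a1", a1)
        object.__setattr__(self, "a2", a2)
        if self.sex not in (None, "female", "male"):
            raise ValueError(f"sex must be 'female', 'male' or None, got {self.sex!r}")

    @property
    def alleles(self) -> tuple[Allele, Allele]:
        return (self.a1, self.a2)

    @property
    def carries_drive(self) -> bool:
        return Allele.D in self.alleles

    @property
    def has_wildtype(self) -> bool:
        return Allele.W in self.alleles

    def __str__(self) -> str:
        tag = f"{self.a1.value}/{self.a2.value}"
        return tag


def genotype_index(g: Genotype | tuple[Allele, Allele]) -> int:
    """Index of a genotype's allele pair in :data:`GENOTYPE_PAIRS`."""
    pair = g.alleles if isinstance(g, Genotype) else _canonical(*g)
    return _PAIR_INDEX[pair]


def _check_prob(name: str, x: float) -> None:
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {x}")


@dataclass(frozen=True)
class DriveParams:
    """All rates the drive model uses.

    Parameters
    ----------
    c_f, c_m
        Germline drive-conversion probability (per cut wild-type allele) in
        females and males.
    germline_cut_rate
        Probability a wild-type allele in a drive-carrier germline is cleaved
        at all.  Default 1: with four multiplexed gRNAs essentially no target
        escapes cleavage, so every uncut survivor class is dropped.
    e
        Embryo resistance probability per inherited wild-type allele, applied
        when the mother carried both Cas9 and a drive allele.
    f_het
        Relative fecundity of D/W females (wild-type = 1).
    f_het_no_maternal_cas9
        Optional distinct fitness for D/W females whose mother lacked Cas9
        (complete-drive scenario without maternal deposition).  Defaults to
        ``f_het``.
    split_mode
        Cas9 at an unlinked, population-fixed locus (True) versus linked to
        the drive cassette (False).  Either way Cas9 carriage is the
        ``cas9_present`` flag on genotypes.
    fertility_target
        True (default) when the construct sits inside a recessive
        female-fertility gene, so females with no wild-type allele are
        sterile.  False models an inert marker at a neutral site — the
        correct null for drift calibration, since with the default even a
        conversion-free drive allele is weakly selected against through
        sterile D/D daughters.
    """

    c_f: float
    c_m: float
    e: float
    f_het: float = 1.0
    germline_cut_rate: float = 1.0
    f_het_no_maternal_cas9: float | None = None
    split_mode: bool = True
    fertility_target: bool = True

    def __post_init__(self) -> None:
        _check_prob("c_f", self.c_f)
        _check_prob("c_m", self.c_m)
        _check_prob("e", self.e)
        _check_prob("germline_cut_rate", self.germline_cut_rate)
        if self.f_het < 0:
            raise ValueError(f"f_het must be non-negative, got {self.f_het}")
        if self.f_het_no_maternal_cas9 is not None and self.f_het_no_maternal_cas9 < 0:
            raise ValueError("f_het_no_maternal_cas9 must be non-negative")

    @property
    def f_het_maternal(self) -> float:
        return self.f_het

    @property
    def f_het_nonmaternal(self) -> float:
        return self.f_het if self.f_het_no_maternal_cas9 is None else self.f_het_no_maternal_cas9

    def with_fitness(self, f_het: float) -> "DriveParams":
        return replace(self, f_het=f_het)


GameteDistribution = dict[Allele, float]


def _validate_distribution(d: dict, tol: float = 1e-12) -> None:
    total = sum(d.values())
    if abs(total - 1.0) > 1e-9 or any(p < -tol for p in d.values()):
        raise AssertionError(f"invalid probability distribution (sum={total})")


def gamete_distribution(parent: Genotype, params: DriveParams) -> GameteDistribution:
    """Probability mass over alleles transmitted by ``parent``.

    Germline conversion requires both a drive allele (the gRNA source) and
    Cas9 in the parent; otherwise segregation is Mendelian-fair.
    """
    c = params.c_f if parent.sex != "male" else params.c_m
    g = params.germline_cut_rate
    active = parent.carries_drive and parent.cas9_present
    out: GameteDistribution = {Allele.W: 0.0, Allele.D: 0.0, Allele.R: 0.0}
    for allele in parent.alleles:
        if allele is Allele.W and active:
            # cut with prob g, then HDR conversion (c) vs end-joining (1-c)
            out[Allele.D] += 0.5 * g * c
            out[Allele.R] += 0.5 * g * (1.0 - c)
            out[Allele.W] += 0.5 * (1.0 - g)
        else:
            out[allele] += 0.5
    _validate_distribution(out)
    return out


def apply_embryo_resistance(
    offspring: Genotype, mother: Genotype, params: DriveParams
) -> dict[Genotype, float]:
    """Distribution over zygote genotypes after maternal Cas9/gRNA deposition.

    Each wild-type allele in the zygote independently becomes ``R`` with
    probability ``e`` when the mother carried both Cas9 and a drive allele;
    mosaic outcomes are collapsed to all-or-nothing per allele.
    """
    deposits = mother.carries_drive and mother.cas9_present
    if not deposits or params.e == 0.0 or not offspring.has_wildtype:
        return {offspring: 1.0}
    e = params.e
    out: dict[Genotype, float] = {}
    for fates in itertools.product(
        *[
            ((Allele.R, e), (Allele.W, 1.0 - e)) if a is Allele.W else ((a, 1.0),)
            for a in offspring.alleles
        ]
    ):
        alleles = tuple(a for a, _ in fates)
        p = 1.0
        for _, q in fates:
            p *= q
        geno = replace(offspring, a1=alleles[0], a2=alleles[1])
        out[geno] = out.get(geno, 0.0) + p
    _validate_distribution(out)
    return out


def offspring_genotype_distribution(
    mother: Genotype, father: Genotype, params: DriveParams
) -> dict[Genotype, float]:
    """Distribution over offspring genotypes for a mother x father cross.

    Convolves the two parental gamete distributions, then applies embryo
    resistance from maternal deposition.  The returned genotypes are unsexed;
    the sex ratio is 1:1 and the genotype distribution is identical in
    daughters and sons.  Offspring flags: ``maternal_cas9`` is the mother's
    ``cas9_present``; ``cas9_present`` is True when either parent can
    transmit Cas9 (the Cas9 locus is modelled as a background flag, not a
    segregating locus — in the cage populations it is fixed).
    """
    gm = gamete_distribution(
        mother if mother.sex else replace(mother, sex="female"), params
    )
    gf = gamete_distribution(
        father if father.sex else replace(father, sex="male"), params
    )
    cas9 = mother.cas9_present or father.cas9_present
    out: dict[Genotype, float] = {}
    for (am, pm), (af, pf) in itertools.product(gm.items(), gf.items()):
        if pm * pf == 0.0:
            continue
        zygote = Genotype(
            am, af, sex=None, cas9_present=cas9, maternal_cas9=mother.cas9_present
        )
        for geno, pe in apply_embryo_resistance(zygote, mother, params).items():
            out[geno] = out.get(geno, 0.0) + pm * pf * pe
    _validate_distribution(out)
    return out


def female_fertility(g: Genotype, params: DriveParams) -> float:
    """Relative fecundity weight of a genotype.

    Females with no wild-type allele (D/D, D/R, R/R) are sterile (weight 0);
    D/W females have weight ``f_het`` (or ``f_het_no_maternal_cas9`` when the
    mother lacked Cas9); W/W and W/R females have weight 1.  Males always
    return 1 — the target genes are female-specific.
    """
    if g.sex == "male" or not params.fertility_target:
        return 1.0
    if not g.has_wildtype:
        return 0.0
    if g.carries_drive:  # D/W
        return params.f_het_maternal if g.maternal_cas9 else params.f_het_nonmaternal
    return 1.0


def expected_inheritance_rate(c: float, g: float = 1.0) -> float:
    """Expected drive-carrier fraction among offspring of a D/W x W/W cross.

    Equals ``1/2 + g*c/2``: the Mendelian half plus the converted share of
    the wild-type homolog.  With no conversion this is exactly the 50%
    Mendelian expectation.
    """
    _check_prob("c", c)
    _check_prob("g", g)
    return 0.5 + g * c / 2.0


# ---------------------------------------------------------------------------
# brute-force oracle


def enumerate_cross(
    mother: Genotype, father: Genotype, params: DriveParams
) -> dict[Genotype, float]:
    """Exhaustive event-tree enumeration of a single cross.

    Walks every discrete outcome — which parental allele segregates, whether
    a wild-type allele is cut and how it is repaired, and the embryo fate of
    each zygotic wild-type allele — and accumulates path probabilities.
    Shares no code with the closed-form operations; used to validate them.
    """
    mother = mother if mother.sex else replace(mother, sex="female")
    father = father if father.sex else replace(father, sex="male")
    out: dict[Genotype, float] = {}

    def germline_branches(parent: Genotype, c: float) -> list[tuple[Allele, float]]:
        g = params.germline_cut_rate
        active = parent.carries_drive and parent.cas9_present
        branches: list[tuple[Allele, float]] = []
        for allele in parent.alleles:  # segregation: each homolog w.p. 1/2
            if allele is Allele.W and active:
                branches.append((Allele.W, 0.5 * (1 - g)))  # escapes cleavage
                branches.append((Allele.D, 0.5 * g * c))  # cut, HDR
                branches.append((Allele.R, 0.5 * g * (1 - c)))  # cut, end-joining
            else:
                branches.append((allele, 0.5))
        return branches

    deposits = mother.carries_drive and mother.cas9_present
    cas9 = mother.cas9_present or father.cas9_present
    for am, pm in germline_branches(mother, params.c_f):
        for af, pf in germline_branches(father, params.c_m):
            # embryo fate of each zygotic allele, independently
            fates_m = (
                [(Allele.R, params.e), (Allele.W, 1 - params.e)]
                if deposits and am is Allele.W
                else [(am, 1.0)]
            )
            fates_f = (
                [(Allele.R, params.e), (Allele.W, 1 - params.e)]
                if deposits and af is Allele.W
                else [(af, 1.0)]
            )
            for (fm, qm), (ff, qf) in itertools.product(fates_m, fates_f):
                p = pm * pf * qm * qf
                if p == 0.0:
                    continue
                geno = Genotype(
                    fm, ff, cas9_present=cas9, maternal_cas9=mother.cas9_present
                )
                out[geno] = out.get(geno, 0.0) + p
    _validate_distribution(out)
    return out


# ---------------------------------------------------------------------------
# vectorised tables for the population model


def offspring_tensor(params: DriveParams) -> np.ndarray:
    """``T[m, f, o]``: P(offspring pair ``o`` | mother pair ``m``, father ``f``).

    Indices follow :data:`GENOTYPE_PAIRS`.  All individuals are assumed to
    carry Cas9 (the cage background is Cas9-fixed); the tensor depends on the
    conversion/embryo-resistance rates but not on fitness.
    """
    T = np.zeros((6, 6, 6))
    for i, (m1, m2) in enumerate(GENOTYPE_PAIRS):
        mother = Genotype(m1, m2, sex="female")
        for j, (f1, f2) in enumerate(GENOTYPE_PAIRS):
            father = Genotype(f1, f2, sex="male")
            for geno, p in offspring_genotype_distribution(mother, father, params).items():
                T[i, j, genotype_index(geno)] += p
    return T


def fertility_weights(params: DriveParams, maternal_cas9: bool = True) -> np.ndarray:
    """Female fecundity weight per genotype index (males all weigh 1)."""
    return np.array(
        [
            female_fertility(
                Genotype(a1, a2, sex="female", maternal_cas9=maternal_cas9), params
            )
            for a1, a2 in GENOTYPE_PAIRS
        ]
    )
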