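"""Fixed combinatorial structure of the two-locus diploid model.

Two autosomal loci each carry a susceptible (S) or resistant (R) allele,
giving three single-locus genotypes (SS, RS, RR) and ten distinct two-locus
genotypes: the double heterozygote is tracked as two types, *coupling*
(R alleles on the same chromosome, i.e. one chromosome RR and the other SS)
and *repulsion* (R alleles on opposite chromosomes), because recombination
interconverts them.

Mosquitoes encounter insecticide in one of nine "niches": each of the two
insecticides may be absent, present at low concentration, or present at
high concentration.

Everything in this module is a constant of the model: genotype/haplotype/
niche enumerations, the Mendelian segregation table (gamete production with
recombination) and the gamete-union table (random mating).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

__all__ = [
    "Sex",
    "Level",
    "LOCUS_GENOTYPES",
    "HAPLOTYPES",
    "NICHES",
    "NICHE_LABELS",
    "NICHE_INDEX",
    "TwoLocusGenotype",
    "GENOTYPES",
    "GENOTYPE_LABELS",
    "GENOTYPE_INDEX",
    "COUPLING",
    "REPULSION",
    "G1_INDEX",
    "G2_INDEX",
    "DOSE1",
    "DOSE2",
    "segregation_matrix",
    "UNION",
    "swap_loci_genotype_permutation",
    "swap_loci_niche_permutation",
    "swap_loci_haplotype_permutation",
]


class Sex(IntEnum):
    """Array index for the two sexes (females first, matching the
    convention that female frequencies drive mean population fitness)."""

    FEMALE = 0
    MALE = 1


class Level(IntEnum):
    """Concentration of an insecticide in a niche."""

    NONE = 0
    LOW = 1
    HIGH = 2


LOCUS_GENOTYPES = ("SS", "RS", "RR")

#: Haplotype order: allele at locus 1 first, then allele at locus 2.
HAPLOTYPES = ("SS", "SR", "RS", "RR")

#: The nine niches, ordered by (locus-1 level, locus-2 level); index 3*l1+l2.
NICHES = tuple((Level(i), Level(j)) for i in range(3) for j in range(3))

_SYM1 = {Level.NONE: "-", Level.LOW: "a", Level.HIGH: "A"}
_SYM2 = {Level.NONE: "-", Level.LOW: "b", Level.HIGH: "B"}

NICHE_LABELS = tuple(f"{_SYM1[l1]},{_SYM2[l2]}" for l1, l2 in NICHES)
NICHE_INDEX = {n: k for k, n in enumerate(NICHES)}
NICHE_INDEX.update({lab: k for k, lab in enumerate(NICHE_LABELS)})


@dataclass(frozen=True)
class TwoLocusGenotype:
    """One of the ten tracked diploid genotypes.

    ``phase`` is ``"coupling"`` or ``"repulsion"`` for the double
    heterozygote and ``"na"`` otherwise.
    """

    locus1: str
    locus2: str
    phase: str = "na"

    def __post_init__(self):
        if self.locus1 not in LOCUS_GENOTYPES or self.locus2 not in LOCUS_GENOTYPES:
            raise ValueError(f"invalid locus genotype in {self!r}")
        double_het = self.locus1 == "RS" and self.locus2 == "RS"
        if double_het and self.phase not in ("coupling", "repulsion"):
            raise ValueError("double heterozygote must have a phase")
        if not double_het and self.phase != "na":
            raise ValueError("phase only applies to the double heterozygote")

    @property
    def label(self) -> str:
        suffix = {"coupling": "(c)", "repulsion": "(r)", "na": ""}[self.phase]
        return f"{self.locus1}1{self.locus2}2{suffix}"


GENOTYPES = (
    TwoLocusGenotype("SS", "SS"),
    TwoLocusGenotype("SS", "RS"),
    TwoLocusGenotype("SS", "RR"),
    TwoLocusGenotype("RS", "SS"),
    TwoLocusGenotype("RS", "RS", "coupling"),
    TwoLocusGenotype("RS", "RS", "repulsion"),
    TwoLocusGenotype("RS", "RR"),
    TwoLocusGenotype("RR", "SS"),
    TwoLocusGenotype("RR", "RS"),
    TwoLocusGenotype("RR", "RR"),
)

GENOTYPE_LABELS = tuple(g.label for g in GENOTYPES)
GENOTYPE_INDEX = {g: k for k, g in enumerate(GENOTYPES)}
GENOTYPE_INDEX.update({g.label: k for k, g in enumerate(GENOTYPES)})

COUPLING = 4
REPULSION = 5

#: Single-locus genotype index (0=SS, 1=RS, 2=RR) of each two-locus genotype.
G1_INDEX = np.array([0, 0, 0, 1, 1, 1, 1, 2, 2, 2])
G2_INDEX = np.array([0, 1, 2, 0, 1, 1, 2, 0, 1, 2])

#: Number of R alleles carried at each locus (dose), used for allele
#: frequencies; numerically equal to the genotype index at that locus.
DOSE1 = G1_INDEX.astype(float)
DOSE2 = G2_INDEX.astype(float)

# Per-locus transmission probabilities of (S, R) for SS/RS/RR parents.
_TRANSMIT = np.array([[1.0, 0.0], [0.5, 0.5], [0.0, 1.0]])


def segregation_matrix(r: float) -> np.ndarray:
    """Mendelian gamete-production table, shape ``(10, 4)``.

    Entry ``[g, h]`` is the probability that a parent of genotype ``g``
    produces a gamete of haplotype ``h`` given recombination rate ``r``
    between the loci.  For genotypes heterozygous at no more than one
    locus the two loci segregate independently; the coupling double
    heterozygote emits the parental SS/RR haplotypes at (1-r)/2 each and
    the recombinant SR/RS at r/2 each, and the repulsion double
    heterozygote the reverse.  ``r = 0.5`` corresponds to unlinked loci.
    """
    if not 0.0 <= r <= 0.5:
        raise ValueError(f"recombination rate must be in [0, 0.5], got {r}")
    m = np.empty((10, 4))
    for g in range(10):
        if g == COUPLING:
            m[g] = [(1 - r) / 2, r / 2, r / 2, (1 - r) / 2]
        elif g == REPULSION:
            m[g] = [r / 2, (1 - r) / 2, (1 - r) / 2, r / 2]
        else:
            m[g] = np.outer(_TRANSMIT[G1_INDEX[g]], _TRANSMIT[G2_INDEX[g]]).ravel()
    return m


def _offspring_index(hap_f: int, hap_m: int) -> int:
    """Genotype formed by the union of a female and a male gamete."""
    a1 = (hap_f >> 1) + (hap_m >> 1)  # R-allele count at locus 1
    a2 = (hap_f & 1) + (hap_m & 1)
    if a1 == 1 and a2 == 1:
        # SS x RR gametes put both R alleles on one chromosome: coupling.
        return COUPLING if {hap_f, hap_m} == {0, 3} else REPULSION
    phase = "na"
    return GENOTYPE_INDEX[
        TwoLocusGenotype(LOCUS_GENOTYPES[a1], LOCUS_GENOTYPES[a2], phase)
    ]


#: One-hot union table, shape ``(4, 4, 10)``: ``UNION[i, j, g]`` is 1 when a
#: female gamete of haplotype ``i`` and a male gamete of haplotype ``j``
#: form offspring genotype ``g``.
UNION = np.zeros((4, 4, 10))
for _i in range(4):
    for _j in range(4):
        UNION[_i, _j, _offspring_index(_i, _j)] = 1.0
del _i, _j


def swap_loci_genotype_permutation() -> np.ndarray:
    """Permutation p with p[g] = index of genotype g with loci swapped."""
    out = np.empty(10, dtype=int)
    for k, g in enumerate(GENOTYPES):
        out[k] = GENOTYPE_INDEX[TwoLocusGenotype(g.locus2, g.locus1, g.phase)]
    return out


def swap_loci_niche_permutation() -> np.ndarray:
    """Permutation of niches under exchanging insecticide 1 and 2."""
    return np.array([NICHE_INDEX[(l2, l1)] for l1, l2 in NICHES])


def swap_loci_haplotype_permutation() -> np.ndarray:
    """Permutation of haplotypes under exchanging the loci (SR <-> RS)."""
    return np.array([0, 2, 1, 3])
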