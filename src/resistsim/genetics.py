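"""Deterministic one-generation recursion of the two-locus selection model.

The model tracks the relative frequencies of the ten two-locus genotypes in
each sex.  A generation consists of:

1. *Selection*: each genotype's marginal fitness is the exposure-weighted
   average, over the nine insecticide niches, of its niche fitness; niche
   fitness is the product of the two single-locus fitnesses (multiplicative
   action of the insecticides in a mixture), optionally scaled by an
   interaction factor Λ in the four dual-insecticide niches.
2. *Gamete production*: fitness-weighted genotype frequencies are pushed
   through the Mendelian segregation table (with recombination rate ``r``
   between the loci) and normalised, separately per sex, to give the four
   haplotype frequencies.
3. *Random union*: female and male gametes pair at random; both loci are
   autosomal so female and male offspring genotype frequencies are
   identical.

Fitnesses are frequency-independent, so the marginal fitness table is
computed once per deployment phase and reused every generation.

Single-locus fitnesses follow the standard effectiveness/dominance/
selection parameterisation.  In a niche where an insecticide is present at
concentration level c:

    w(SS) = 1 - phi_c          (phi = proportion of SS killed)
    w(RS) = w(SS) + h_c * s_c  (h = dominance of resistance)
    w(RR) = w(SS) + s_c        (s = selection coefficient of RR)

and in a niche where it is absent (z = fitness cost of resistance):

    w(SS) = 1,  w(RS) = 1 - h_cost * z,  w(RR) = 1 - z.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import (
    LOCUS_GENOTYPES,
    COUPLING,
    DOSE1,
    DOSE2,
    G1_INDEX,
    G2_INDEX,
    GENOTYPE_INDEX,
    HAPLOTYPES,
    Level,
    NICHE_INDEX,
    NICHE_LABELS,
    NICHES,
    REPULSION,
    Sex,
    UNION,
    segregation_matrix,
)

__all__ = [
    "CalibrationError",
    "ExtinctionError",
    "InsecticideParams",
    "InteractionFactors",
    "LocusNicheFitness",
    "NicheGenotypeFitness",
    "MarginalFitness",
    "ExposureProfile",
    "GenotypeFrequencies",
    "GameteFrequencies",
    "AlleleFrequencies",
    "init_from_allele_freqs",
    "init_from_genotype_freqs",
    "single_locus_fitness_table",
    "two_locus_fitness_tables",
    "marginal_fitness",
    "gamete_frequencies",
    "next_generation",
    "step",
    "allele_frequencies",
    "linkage_disequilibrium",
    "mean_population_fitness",
]

_SUM_TOL = 1e-9


class CalibrationError(ValueError):
    """A fitness parameterisation produced a fitness outside [0, 1]."""


class ExtinctionError(RuntimeError):
    """Total fitness-weighted mass is zero: the population is extinct."""


def _check_unit(name: str, value: float) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")
    return value


@dataclass(frozen=True)
class InsecticideParams:
    """Per-insecticide calibration.

    ``effectiveness`` (phi), ``dominance`` (h) and ``selection`` (s) apply
    in niches where the insecticide is present at high concentration; the
    ``*_low`` variants apply at low concentration and default to the high
    values.  ``cost`` (z) and ``cost_dominance`` apply in insecticide-free
    niches.  The constraint s <= phi keeps w(RR) = 1 - phi + s <= 1.
    """

    effectiveness: float
    dominance: float
    selection: float
    effectiveness_low: float | None = None
    dominance_low: float | None = None
    selection_low: float | None = None
    cost: float = 0.0
    cost_dominance: float = 0.0

    def __post_init__(self):
        _check_unit("effectiveness", self.effectiveness)
        _check_unit("dominance", self.dominance)
        _check_unit("cost", self.cost)
        _check_unit("cost_dominance", self.cost_dominance)
        if self.selection < 0:
            raise ValueError(f"selection must be >= 0, got {self.selection}")
        for level in (Level.LOW, Level.HIGH):
            phi, h, s = self.level_params(level)
            if s > phi + 1e-12:
                raise CalibrationError(
                    f"selection {s} exceeds effectiveness {phi} "
                    f"(level {level.name}): w(RR) would exceed 1"
                )

    @classmethod
    def from_restoration(
        cls,
        effectiveness: float,
        dominance: float,
        restoration: float,
        *,
        effectiveness_low: float | None = None,
        dominance_low: float | None = None,
        restoration_low: float | None = None,
        cost: float = 0.0,
        cost_dominance: float = 0.0,
    ) -> "InsecticideParams":
        """Calibrate via the restoration coefficient: s = restoration * phi.

        ``restoration`` quantifies the fraction of the insecticide-induced
        fitness loss that the RR genotype recovers; the construction
        guarantees w(RR) <= 1 for any restoration in [0, 1].
        """
        _check_unit("restoration", restoration)
        sel_low = None
        if effectiveness_low is not None or restoration_low is not None:
            phi_low = effectiveness if effectiveness_low is None else effectiveness_low
            r_low = restoration if restoration_low is None else restoration_low
            _check_unit("restoration_low", r_low)
            sel_low = r_low * phi_low
        return cls(
            effectiveness=effectiveness,
            dominance=dominance,
            selection=restoration * effectiveness,
            effectiveness_low=effectiveness_low,
            dominance_low=dominance_low,
            selection_low=sel_low,
            cost=cost,
            cost_dominance=cost_dominance,
        )

    def level_params(self, level: Level) -> tuple[float, float, float]:
        """(phi, h, s) at the given concentration level."""
        if level == Level.HIGH:
            return self.effectiveness, self.dominance, self.selection
        if level == Level.LOW:
            phi = self.effectiveness if self.effectiveness_low is None else self.effectiveness_low
            h = self.dominance if self.dominance_low is None else self.dominance_low
            s = self.selection if self.selection_low is None else self.selection_low
            return phi, h, s
        raise ValueError("level_params is defined for LOW and HIGH only")


@dataclass(frozen=True)
class InteractionFactors:
    """Λ scaling of fitness in the four dual-insecticide niches.

    Λ < 1 models synergy between the insecticides, Λ > 1 antagonism or
    cross-resistance; the default 1 is plain multiplicative action.
    """

    ab: float = 1.0
    Ab: float = 1.0
    aB: float = 1.0
    AB: float = 1.0

    def __post_init__(self):
        for name in ("ab", "Ab", "aB", "AB"):
            if getattr(self, name) <= 0:
                raise ValueError(f"interaction factor {name} must be positive")

    def as_vector(self) -> np.ndarray:
        """Per-niche scaling, 1 outside dual-insecticide niches."""
        lam = np.ones(len(NICHES))
        lam[NICHE_INDEX[(Level.LOW, Level.LOW)]] = self.ab
        lam[NICHE_INDEX[(Level.HIGH, Level.LOW)]] = self.Ab
        lam[NICHE_INDEX[(Level.LOW, Level.HIGH)]] = self.aB
        lam[NICHE_INDEX[(Level.HIGH, Level.HIGH)]] = self.AB
        return lam


@dataclass(frozen=True)
class LocusNicheFitness:
    """Single-locus fitness table ``w[locus, genotype, niche]``, shape (2, 3, 9)."""

    w: np.ndarray

    def value(self, locus: int, genotype: str, niche) -> float:
        return float(self.w[locus - 1, LOCUS_GENOTYPES.index(genotype), NICHE_INDEX[niche]])


@dataclass(frozen=True)
class NicheGenotypeFitness:
    """Two-locus fitness table ``w[genotype, niche]``, shape (10, 9)."""

    w: np.ndarray

    def value(self, genotype, niche) -> float:
        return float(self.w[GENOTYPE_INDEX[genotype], NICHE_INDEX[niche]])


@dataclass(frozen=True)
class MarginalFitness:
    """Exposure-weighted genotype fitness ``w[sex, genotype]``, shape (2, 10)."""

    w: np.ndarray

    def value(self, sex: Sex, genotype) -> float:
        return float(self.w[sex, GENOTYPE_INDEX[genotype]])


@dataclass(frozen=True)
class ExposureProfile:
    """Per-sex exposure proportions across the nine niches, shape (2, 9)."""

    alpha: np.ndarray

    def __post_init__(self):
        alpha = np.asarray(self.alpha, dtype=float)
        if alpha.shape != (2, len(NICHES)):
            raise ValueError(f"exposure must have shape (2, 9), got {alpha.shape}")
        if np.any(alpha < -1e-12):
            raise ValueError("exposure proportions must be non-negative")
        sums = alpha.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > _SUM_TOL):
            raise ValueError(f"per-sex exposure must sum to 1, got {sums}")
        alpha = np.clip(alpha, 0.0, None)
        alpha = alpha / alpha.sum(axis=1, keepdims=True)
        object.__setattr__(self, "alpha", alpha)

    @classmethod
    def unexposed(cls) -> "ExposureProfile":
        alpha = np.zeros((2, len(NICHES)))
        alpha[:, NICHE_INDEX[(Level.NONE, Level.NONE)]] = 1.0
        return cls(alpha)

    @classmethod
    def from_dict(cls, female: dict, male: dict | None = None) -> "ExposureProfile":
        """Build from ``{niche label: proportion}`` mappings; omitted mass
        is assigned to the insecticide-free niche."""
        alpha = np.zeros((2, len(NICHES)))
        for sex, table in ((Sex.FEMALE, female), (Sex.MALE, male if male is not None else female)):
            for key, value in table.items():
                alpha[sex, NICHE_INDEX[key]] = value
            none_idx = NICHE_INDEX[(Level.NONE, Level.NONE)]
            if none_idx not in [NICHE_INDEX[k] for k in table]:
                alpha[sex, none_idx] = 1.0 - alpha[sex].sum() + alpha[sex, none_idx]
        return cls(alpha)

    def value(self, sex: Sex, niche) -> float:
        return float(self.alpha[sex, NICHE_INDEX[niche]])


@dataclass(frozen=True)
class GenotypeFrequencies:
    """Per-sex frequencies of the ten genotypes, shape (2, 10).

    This is the simulator's state.  Frequencies are validated to be
    non-negative and to sum to one within each sex, and are renormalised
    exactly on construction to absorb floating-point drift.
    """

    freq: np.ndarray

    def __post_init__(self):
        freq = np.asarray(self.freq, dtype=float)
        if freq.shape != (2, 10):
            raise ValueError(f"genotype frequencies must have shape (2, 10), got {freq.shape}")
        if np.any(freq < -1e-12):
            raise ValueError("genotype frequencies must be non-negative")
        sums = freq.sum(axis=1)
        # accept sums within 1e-8 of 1 and renormalise; the engine itself
        # keeps per-generation drift well below 1e-9
        if np.any(np.abs(sums - 1.0) > 1e-8):
            raise ValueError(f"per-sex genotype frequencies must sum to 1, got {sums}")
        freq = np.clip(freq, 0.0, None)
        freq = freq / freq.sum(axis=1, keepdims=True)
        object.__setattr__(self, "freq", freq)

    def value(self, sex: Sex, genotype) -> float:
        return float(self.freq[sex, GENOTYPE_INDEX[genotype]])


@dataclass(frozen=True)
class GameteFrequencies:
    """Per-sex haplotype frequencies after selection, shape (2, 4), plus the
    per-sex normalisation coefficients (total fitness-weighted mass)."""

    freq: np.ndarray
    normaliser: np.ndarray

    def value(self, sex: Sex, haplotype: str) -> float:
        return float(self.freq[sex, HAPLOTYPES.index(haplotype)])


@dataclass(frozen=True)
class AlleleFrequencies:
    """R-allele frequencies per sex and locus, with the sex-averaged values."""

    female: tuple[float, float]
    male: tuple[float, float]
    mean: tuple[float, float]


# ---------------------------------------------------------------------------
# initialisation


def init_from_allele_freqs(p1: float, p2: float) -> GenotypeFrequencies:
    """HWE/LE start from the two R-allele frequencies, identical in both
    sexes; the double-heterozygote mass is split equally between coupling
    and repulsion (linkage equilibrium)."""
    for name, p in (("p1", p1), ("p2", p2)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"allele frequency {name} must be in [0, 1], got {p}")
    v1 = np.array([(1 - p1) ** 2, 2 * p1 * (1 - p1), p1**2])
    v2 = np.array([(1 - p2) ** 2, 2 * p2 * (1 - p2), p2**2])
    f = v1[G1_INDEX] * v2[G2_INDEX]
    f[COUPLING] *= 0.5
    f[REPULSION] *= 0.5
    return GenotypeFrequencies(np.tile(f, (2, 1)))


def init_from_genotype_freqs(freqs) -> GenotypeFrequencies:
    """Explicit per-sex 10-genotype table (renormalised to sum exactly 1)."""
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape == (10,):
        freqs = np.tile(freqs, (2, 1))
    return GenotypeFrequencies(freqs)


# ---------------------------------------------------------------------------
# fitness construction


def single_locus_fitness_table(
    params1: InsecticideParams, params2: InsecticideParams
) -> LocusNicheFitness:
    """Single-locus fitnesses in every niche.

    Raises :class:`CalibrationError` naming the offending cell if any
    computed fitness falls outside [0, 1] (mis-calibrations are loud, never
    silently clamped).
    """
    w = np.empty((2, 3, len(NICHES)))
    for locus, params in ((0, params1), (1, params2)):
        for k, niche in enumerate(NICHES):
            level = niche[locus]
            if level == Level.NONE:
                z, hc = params.cost, params.cost_dominance
                col = (1.0, 1.0 - hc * z, 1.0 - z)
            else:
                phi, h, s = params.level_params(level)
                col = (1.0 - phi, 1.0 - phi + h * s, 1.0 - phi + s)
            for gi, value in enumerate(col):
                if not -1e-12 <= value <= 1.0 + 1e-12:
                    raise CalibrationError(
                        f"fitness w({LOCUS_GENOTYPES[gi]}) = {value} at locus "
                        f"{locus + 1}, niche {NICHE_LABELS[k]} is outside [0, 1]"
                    )
            w[locus, :, k] = np.clip(col, 0.0, 1.0)
    return LocusNicheFitness(w)


def two_locus_fitness_tables(
    w: LocusNicheFitness, lam: InteractionFactors | None = None
) -> NicheGenotypeFitness:
    """Two-locus niche fitness: product of the single-locus fitnesses,
    scaled by Λ in the dual-insecticide niches.  Coupling and repulsion
    double heterozygotes have equal fitness by construction."""
    if lam is None:
        lam = InteractionFactors()
    table = w.w[0, G1_INDEX, :] * w.w[1, G2_INDEX, :] * lam.as_vector()
    return NicheGenotypeFitness(table)


def marginal_fitness(Wn: NicheGenotypeFitness, exposure: ExposureProfile) -> MarginalFitness:
    """Exposure-weighted average fitness of each genotype, per sex.

    Frequency-independent: computed once per deployment phase.
    """
    return MarginalFitness(exposure.alpha @ Wn.w.T)


# ---------------------------------------------------------------------------
# the recursion (array kernels support leading batch dimensions)


def _gamete_kernel(freq: np.ndarray, w: np.ndarray, m: np.ndarray):
    """(..., 2, 10) frequencies and fitnesses -> (..., 2, 4) gametes + norms."""
    weighted = freq * w
    numer = weighted @ m
    norm = numer.sum(axis=-1)
    return numer, norm


def _union_kernel(gametes: np.ndarray) -> np.ndarray:
    """(..., 2, 4) normalised gametes -> (..., 10) offspring frequencies."""
    return np.einsum(
        "...i,...j,ijg->...g", gametes[..., Sex.FEMALE, :], gametes[..., Sex.MALE, :], UNION
    )


def step_kernel(freq: np.ndarray, w: np.ndarray, m: np.ndarray) -> np.ndarray:
    """One generation on raw arrays with leading batch dimensions.

    ``freq``/``w`` have shape (..., 2, 10), ``m`` is a segregation matrix.
    Returns the offspring frequencies (..., 2, 10) (identical per sex).
    Used by the vectorised sensitivity-analysis engine; the public
    :func:`step` wraps it for single populations with validation.
    """
    numer, norm = _gamete_kernel(freq, w, m)
    if np.any(norm <= 0):
        raise ExtinctionError("total fitness-weighted mass is zero")
    gametes = numer / norm[..., None]
    offspring = _union_kernel(gametes)
    offspring = offspring / offspring.sum(axis=-1, keepdims=True)
    return np.repeat(offspring[..., None, :], 2, axis=-2)


def gamete_frequencies(
    F: GenotypeFrequencies, W: MarginalFitness, r: float = 0.5
) -> GameteFrequencies:
    """Selection followed by gamete production with recombination rate ``r``."""
    numer, norm = _gamete_kernel(F.freq, W.w, segregation_matrix(r))
    if np.any(norm <= 0):
        raise ExtinctionError(
            "population extinct under selection: fitness-weighted mass is zero"
        )
    return GameteFrequencies(numer / norm[:, None], norm)


def next_generation(G: GameteFrequencies) -> GenotypeFrequencies:
    """Random union of female and male gametes (both loci autosomal, so
    female and male offspring frequencies are identical)."""
    offspring = _union_kernel(G.freq)
    total = offspring.sum()
    if abs(total - 1.0) > _SUM_TOL:
        raise RuntimeError(f"offspring frequencies drifted to sum {total}")
    return GenotypeFrequencies(np.tile(offspring / total, (2, 1)))


def step(F: GenotypeFrequencies, W: MarginalFitness, r: float = 0.5) -> GenotypeFrequencies:
    """One complete, non-overlapping generation: selection, gamete
    production with recombination, random union."""
    return next_generation(gamete_frequencies(F, W, r))


# ---------------------------------------------------------------------------
# summaries


def allele_frequencies(F: GenotypeFrequencies) -> AlleleFrequencies:
    """Per-sex, per-locus R-allele frequencies and their sex averages."""
    q = np.stack([F.freq @ DOSE1 / 2.0, F.freq @ DOSE2 / 2.0], axis=1)  # (2 sexes, 2 loci)
    mean = q.mean(axis=0)
    return AlleleFrequencies(
        female=(float(q[Sex.FEMALE, 0]), float(q[Sex.FEMALE, 1])),
        male=(float(q[Sex.MALE, 0]), float(q[Sex.MALE, 1])),
        mean=(float(mean[0]), float(mean[1])),
    )


def linkage_disequilibrium(G: GameteFrequencies) -> float:
    """Sex-averaged gametic LD: D = f(RR) - f(R1) f(R2) per sex, then the
    male/female mean (both sexes contribute equal numbers of gametes)."""
    rr = G.freq[:, HAPLOTYPES.index("RR")]
    r1 = G.freq[:, HAPLOTYPES.index("RS")] + rr
    r2 = G.freq[:, HAPLOTYPES.index("SR")] + rr
    return float(np.mean(rr - r1 * r2))


def mean_population_fitness(F: GenotypeFrequencies, W: MarginalFitness) -> float:
    """Mean fitness of the female population (relative egg lay compared to a
    fully susceptible population without insecticide)."""
    return float(F.freq[Sex.FEMALE] @ W.w[Sex.FEMALE])
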