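"""Deployment strategies: building exposure profiles from operational
parameters and running sequential, mixture and adaptive-mixture policies.

Time to resistance is measured in mosquito generations until the
sex-averaged R-allele frequency *strictly exceeds* a threshold (50%
throughout the headline analyses).  Sequential deployment switches
insecticides one generation *after* the threshold is crossed (the model
uses one-generation timesteps, so the exhausted insecticide inevitably
"overshoots" the threshold by one generation before the replacement is
deployed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import genetics as gen
from .genetics import (
    ExposureProfile,
    GenotypeFrequencies,
    InsecticideParams,
    InteractionFactors,
    MarginalFitness,
)
from .genotypes import Level, NICHE_INDEX, NICHES, Sex

__all__ = [
    "Calibration",
    "DeploymentSpec",
    "Span",
    "Schedule",
    "StrategyOutcome",
    "selection_from_restoration",
    "build_exposure_profile",
    "run_schedule",
    "run_single",
    "run_sequential",
    "run_mixture",
    "derive_adaptive",
]

_NONE = NICHE_INDEX[(Level.NONE, Level.NONE)]
_A_HIGH = NICHE_INDEX[(Level.HIGH, Level.NONE)]
_B_HIGH = NICHE_INDEX[(Level.NONE, Level.HIGH)]
_AB_HIGH = NICHE_INDEX[(Level.HIGH, Level.HIGH)]


def selection_from_restoration(restoration: float, phi: float) -> float:
    """Selection coefficient of the RR genotype, s = restoration * phi.

    Parameterising s through the restoration coefficient guarantees
    w(RR) = 1 - phi + s <= 1: restoration 1 means RR is completely
    unaffected by the insecticide, restoration 0 means the resistance
    mutation is completely ineffective.
    """
    if not 0.0 <= restoration <= 1.0:
        raise ValueError(f"restoration must be in [0, 1], got {restoration}")
    if not 0.0 <= phi <= 1.0:
        raise ValueError(f"effectiveness must be in [0, 1], got {phi}")
    return restoration * phi


@dataclass(frozen=True)
class Calibration:
    """Full genetic calibration of a two-insecticide scenario."""

    insecticide1: InsecticideParams
    insecticide2: InsecticideParams
    interaction: InteractionFactors = field(default_factory=InteractionFactors)
    recombination: float = 0.5
    start_freq1: float = 0.01
    start_freq2: float = 0.001
    start_genotypes: GenotypeFrequencies | None = None

    def initial_state(self) -> GenotypeFrequencies:
        if self.start_genotypes is not None:
            return self.start_genotypes
        return gen.init_from_allele_freqs(self.start_freq1, self.start_freq2)

    def niche_fitness(self) -> gen.NicheGenotypeFitness:
        w = gen.single_locus_fitness_table(self.insecticide1, self.insecticide2)
        return gen.two_locus_fitness_tables(w, self.interaction)


@dataclass(frozen=True)
class DeploymentSpec:
    """Operational parameters of one deployment phase.

    ``strategy`` is one of ``single``, ``sequential``, ``mixture``,
    ``adaptive_mixture`` or ``none``; ``exposure`` is the proportion of
    females encountering insecticide; ``male_exposure_prop`` scales male
    exposure relative to females; ``correct_mix_deploy`` is the fraction of
    intended mixture deployment actually delivered as a mixture (the
    remainder is split equally between the two single insecticides) and
    only applies to mixture phases.
    """

    strategy: str
    exposure: float
    male_exposure_prop: float = 1.0
    correct_mix_deploy: float = 1.0
    insecticide: int | None = None  # for strategy="single": 1 or 2
    insecticide_order: tuple[int, int] = (1, 2)

    def __post_init__(self):
        if self.strategy not in ("single", "sequential", "mixture", "adaptive_mixture", "none"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not 0.0 <= self.exposure <= 1.0:
            raise ValueError(f"exposure must be in [0, 1], got {self.exposure}")
        if not 0.0 <= self.male_exposure_prop <= 1.0:
            raise ValueError("male_exposure_prop must be in [0, 1]")
        if not 0.0 <= self.correct_mix_deploy <= 1.0:
            raise ValueError("correct_mix_deploy must be in [0, 1]")
        if self.strategy == "single" and self.insecticide not in (1, 2):
            raise ValueError("single deployment requires insecticide 1 or 2")
        if sorted(self.insecticide_order) != [1, 2]:
            raise ValueError("insecticide_order must be a permutation of (1, 2)")


def build_exposure_profile(spec: DeploymentSpec) -> ExposureProfile:
    """Exposure across the nine niches implied by a deployment phase.

    Females under a mixture: exposure * correct_mix_deploy encounters the
    high-concentration mixture niche and the incorrectly-deployed remainder
    is split equally between the two single-insecticide niches.  Males:
    every exposed-niche proportion is multiplied by ``male_exposure_prop``
    and the removed mass returns to the insecticide-free niche.
    """
    female = np.zeros(len(NICHES))
    e = spec.exposure
    if spec.strategy == "none" or e == 0.0:
        female[_NONE] = 1.0
    elif spec.strategy == "single":
        female[_A_HIGH if spec.insecticide == 1 else _B_HIGH] = e
        female[_NONE] = 1.0 - e
    elif spec.strategy in ("mixture", "adaptive_mixture"):
        c = spec.correct_mix_deploy
        female[_AB_HIGH] = e * c
        female[_A_HIGH] = female[_B_HIGH] = e * (1.0 - c) / 2.0
        female[_NONE] = 1.0 - e
    else:
        raise ValueError(
            f"strategy {spec.strategy!r} does not define a single exposure profile"
        )
    male = female * spec.male_exposure_prop
    male[_NONE] = 0.0
    male[_NONE] = 1.0 - male.sum()
    alpha = np.empty((2, len(NICHES)))
    alpha[Sex.FEMALE] = female
    alpha[Sex.MALE] = male
    if np.any(np.abs(alpha.sum(axis=1) - 1.0) > 1e-9):
        raise RuntimeError("internal error: exposure profile does not sum to 1")
    return ExposureProfile(alpha)


@dataclass(frozen=True)
class Span:
    """A contiguous block of generations governed by one deployment phase."""

    start: int
    end: int  # inclusive
    spec: DeploymentSpec

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid span {self.start}..{self.end}")


@dataclass(frozen=True)
class Schedule:
    """Ordered, contiguous, non-overlapping spans starting at generation 1."""

    spans: tuple[Span, ...]

    def __post_init__(self):
        spans = tuple(self.spans)
        if not spans:
            raise ValueError("schedule must contain at least one span")
        if spans[0].start != 1:
            raise ValueError("schedule must start at generation 1")
        for prev, nxt in zip(spans, spans[1:]):
            if nxt.start != prev.end + 1:
                raise ValueError("schedule spans must be contiguous and non-overlapping")
        object.__setattr__(self, "spans", spans)

    @property
    def end(self) -> int:
        return self.spans[-1].end

    def spec_at(self, generation: int) -> DeploymentSpec:
        for span in self.spans:
            if span.start <= generation <= span.end:
                return span.spec
        raise ValueError(f"generation {generation} is outside the schedule")


@dataclass
class StrategyOutcome:
    """Trajectory and times-to-threshold of one strategy run.

    ``crossing_time`` maps locus (1 or 2) to the first generation whose
    post-update sex-averaged R frequency strictly exceeds the threshold
    (None if never).  ``t_first``/``t_both`` are the first/last of those
    times; censored outcomes carry no finite ``t_both``.
    """

    strategy: str
    threshold: float
    max_generations: int
    trajectory: pd.DataFrame | None
    crossing_time: dict[int, int | None]
    t_first: int | None
    t_both: int | None
    censored: bool
    extras: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "strategy": self.strategy,
            "t_first": self.t_first,
            "t_both": self.t_both,
            "censored": self.censored,
            "cross_locus1": self.crossing_time.get(1),
            "cross_locus2": self.crossing_time.get(2),
        }


# ---------------------------------------------------------------------------
# simulation driver


class _Recorder:
    def __init__(self, calibration: Calibration):
        self.rows: list[dict] = []
        self.r = calibration.recombination

    def record(self, generation: int, F: GenotypeFrequencies, W: MarginalFitness, label: str):
        af = gen.allele_frequencies(F)
        G = gen.gamete_frequencies(F, W, self.r)
        self.rows.append(
            {
                "generation": generation,
                "freq_R1_m": af.male[0],
                "freq_R1_f": af.female[0],
                "freq_R2_m": af.male[1],
                "freq_R2_f": af.female[1],
                "LD": gen.linkage_disequilibrium(G),
                "mean_fitness": gen.mean_population_fitness(F, W),
                "deployment_label": label,
            }
        )

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def _marginal(calibration: Calibration, spec: DeploymentSpec) -> MarginalFitness:
    return gen.marginal_fitness(calibration.niche_fitness(), build_exposure_profile(spec))


def _run(
    calibration: Calibration,
    spec_for_gen,
    threshold: float,
    max_generations: int,
    stop_when,
    strategy: str,
    record: bool = True,
) -> StrategyOutcome:
    """Shared iteration loop.

    ``spec_for_gen(generation, crossing)`` returns the deployment spec
    active in that generation (may depend on crossings so far);
    ``stop_when(crossing)`` says when to stop early.
    """
    F = calibration.initial_state()
    crossing: dict[int, int | None] = {1: None, 2: None}
    af = gen.allele_frequencies(F)
    for locus in (1, 2):
        if af.mean[locus - 1] > threshold:
            crossing[locus] = 0
    recorder = _Recorder(calibration) if record else None
    cache: dict[DeploymentSpec, MarginalFitness] = {}

    spec0 = spec_for_gen(1, crossing)
    if record:
        W0 = cache.setdefault(spec0, _marginal(calibration, spec0))
        recorder.record(0, F, W0, spec0.strategy if spec0.strategy != "single" else _label(spec0))

    generation = 0
    while generation < max_generations and not stop_when(crossing):
        generation += 1
        spec = spec_for_gen(generation, crossing)
        W = cache.get(spec)
        if W is None:
            W = cache[spec] = _marginal(calibration, spec)
        F = gen.step(F, W, calibration.recombination)
        af = gen.allele_frequencies(F)
        for locus in (1, 2):
            if crossing[locus] is None and af.mean[locus - 1] > threshold:
                crossing[locus] = generation
        if record:
            recorder.record(generation, F, W, _label(spec))

    times = [t for t in crossing.values() if t is not None]
    t_first = min(times) if times else None
    t_both = max(times) if len(times) == 2 else None
    return StrategyOutcome(
        strategy=strategy,
        threshold=threshold,
        max_generations=max_generations,
        trajectory=recorder.frame() if record else None,
        crossing_time=crossing,
        t_first=t_first,
        t_both=t_both,
        censored=t_both is None,
        extras={"final_state": F},
    )


def _label(spec: DeploymentSpec) -> str:
    if spec.strategy == "single":
        return f"insecticide{spec.insecticide}"
    return spec.strategy


# ---------------------------------------------------------------------------
# strategies


def run_schedule(
    calibration: Calibration,
    schedule: Schedule,
    threshold: float = 0.5,
    max_generations: int | None = None,
    record: bool = True,
) -> StrategyOutcome:
    """Run an explicit schedule of deployment phases.

    State carries over across span boundaries: genotype frequencies are
    retained, including any deviations from HWE/LE accumulated under
    selection.  The run ends at the schedule's final generation (or
    ``max_generations`` if smaller); threshold crossings are recorded but
    do not stop the run.
    """
    end = schedule.end if max_generations is None else min(schedule.end, max_generations)
    return _run(
        calibration,
        lambda g, crossing: schedule.spec_at(g),
        threshold,
        end,
        stop_when=lambda crossing: False,
        strategy="schedule",
        record=record,
    )


def run_single(
    calibration: Calibration,
    spec: DeploymentSpec,
    threshold: float = 0.5,
    max_generations: int = 500,
    record: bool = True,
) -> StrategyOutcome:
    """Deploy one insecticide alone until its resistance allele crosses the
    threshold (or the generation cap)."""
    if spec.strategy != "single":
        spec = replace(spec, strategy="single")
    locus = spec.insecticide
    out = _run(
        calibration,
        lambda g, crossing: spec,
        threshold,
        max_generations,
        stop_when=lambda crossing: crossing[locus] is not None,
        strategy="single",
        record=record,
    )
    t = out.crossing_time[locus]
    out.t_first = t
    out.t_both = None
    out.censored = t is None
    out.extras["t_single"] = t
    return out


def run_mixture(
    calibration: Calibration,
    spec: DeploymentSpec,
    threshold: float = 0.5,
    max_generations: int = 500,
    record: bool = True,
) -> StrategyOutcome:
    """Deploy both insecticides together until both resistance alleles
    exceed the threshold (or the generation cap).

    ``crossing_time`` holds the raw threshold-crossing generations;
    ``t_both`` is the reported time to resistance, which includes the
    one-generation detection lag before the failed mixture would be
    replaced (threshold events take effect the generation after they are
    crossed, exactly as at the sequential switch), so ``t_both`` equals
    the last raw crossing plus one.
    """
    if spec.strategy not in ("mixture", "adaptive_mixture"):
        spec = replace(spec, strategy="mixture")
    out = _run(
        calibration,
        lambda g, crossing: spec,
        threshold,
        max_generations,
        stop_when=lambda crossing: crossing[1] is not None and crossing[2] is not None,
        strategy="mixture",
        record=record,
    )
    out.extras["t_both_crossing"] = out.t_both
    if out.t_both is not None:
        reported = out.t_both + 1
        if reported > max_generations:
            out.t_both = None
            out.censored = True
        else:
            out.t_both = reported
    return out


def run_sequential(
    calibration: Calibration,
    spec: DeploymentSpec,
    threshold: float = 0.5,
    max_generations: int = 500,
    record: bool = True,
) -> StrategyOutcome:
    """Deploy the first insecticide alone until its resistance allele
    crosses the threshold; it remains deployed for one further generation
    (the switch is only triggered the generation after the crossing), then
    the second insecticide is deployed alone until its allele crosses.

    Total time is t1 + 1 + t2 where t1 and t2 are the selective generations
    under each insecticide.
    """
    first, second = spec.insecticide_order
    spec1 = replace(spec, strategy="single", insecticide=first)
    spec2 = replace(spec, strategy="single", insecticide=second)

    def spec_for_gen(g, crossing):
        t1 = crossing[first]
        if t1 is None or g <= t1 + 1:  # switch lag: one extra generation
            return spec1
        return spec2

    out = _run(
        calibration,
        spec_for_gen,
        threshold,
        max_generations,
        stop_when=lambda crossing: crossing[first] is not None
        and crossing[second] is not None,
        strategy="sequential",
        record=record,
    )
    t1 = out.crossing_time[first]
    out.extras["t_phase1"] = t1
    out.extras["switch_generation"] = None if t1 is None else t1 + 1
    if out.crossing_time[second] is not None and t1 is not None:
        out.extras["t_phase2"] = out.crossing_time[second] - (t1 + 1)
    return out


def derive_adaptive(
    mixture_out: StrategyOutcome,
    calibration: Calibration,
    spec: DeploymentSpec,
    threshold: float = 0.5,
    max_generations: int = 500,
) -> StrategyOutcome:
    """Adaptive mixture: the mixture is withdrawn once the first allele
    crosses the threshold and the surviving insecticide is deployed alone.

    The mixture is replaced the generation *after* the first allele
    crosses (the same one-generation detection lag as at the sequential
    switch), so the total time is t_first + 1 + the solo time-to-threshold
    of the surviving insecticide started from an HWE/LE population at the
    surviving allele's frequency at the replacement generation
    (deliberately ignoring the HWE/LD deviations accrued under the
    mixture, which decay within a few generations once selection on the
    exhausted locus is withdrawn).
    """
    t_first = mixture_out.t_first
    if t_first is None:
        return StrategyOutcome(
            strategy="adaptive_mixture",
            threshold=threshold,
            max_generations=max_generations,
            trajectory=None,
            crossing_time={1: None, 2: None},
            t_first=None,
            t_both=None,
            censored=True,
        )
    c1, c2 = mixture_out.crossing_time[1], mixture_out.crossing_time[2]
    if c1 is not None and c2 is not None and c1 == c2:
        # both alleles crossed in the same generation: nothing to withdraw
        out = StrategyOutcome(
            strategy="adaptive_mixture",
            threshold=threshold,
            max_generations=max_generations,
            trajectory=mixture_out.trajectory,
            crossing_time=dict(mixture_out.crossing_time),
            t_first=t_first,
            t_both=mixture_out.t_both,
            censored=False,
        )
        return out
    exhausted = 1 if (c1 is not None and (c2 is None or c1 <= c2)) else 2
    survivor = 2 if exhausted == 1 else 1
    traj = mixture_out.trajectory
    if traj is None:
        raise ValueError("derive_adaptive requires a recorded mixture trajectory")
    switch = t_first + 1  # the mixture remains deployed during detection
    rows = traj.loc[traj["generation"] == switch]
    if rows.empty:  # first crossing at the cap: nothing left to run
        return StrategyOutcome(
            strategy="adaptive_mixture",
            threshold=threshold,
            max_generations=max_generations,
            trajectory=None,
            crossing_time={exhausted: t_first, survivor: None},
            t_first=t_first,
            t_both=None,
            censored=True,
        )
    row = rows.iloc[0]
    q_surv = (row[f"freq_R{survivor}_m"] + row[f"freq_R{survivor}_f"]) / 2.0
    q_exh = (row[f"freq_R{exhausted}_m"] + row[f"freq_R{exhausted}_f"]) / 2.0
    restart = replace(
        calibration,
        start_freq1=q_surv if survivor == 1 else q_exh,
        start_freq2=q_surv if survivor == 2 else q_exh,
        start_genotypes=None,
    )
    solo = run_single(
        restart,
        replace(spec, strategy="single", insecticide=survivor),
        threshold,
        max_generations,
        record=False,
    )
    t_solo = solo.extras["t_single"]
    crossing = {exhausted: t_first, survivor: None}
    t_both = None
    censored = True
    if t_solo is not None and switch + t_solo <= max_generations:
        crossing[survivor] = switch + t_solo
        t_both = switch + t_solo
        censored = False
    return StrategyOutcome(
        strategy="adaptive_mixture",
        threshold=threshold,
        max_generations=max_generations,
        trajectory=None,
        crossing_time=crossing,
        t_first=t_first,
        t_both=t_both,
        censored=censored,
        extras={"survivor": survivor, "restart_freq": float(q_surv), "t_solo": t_solo},
    )
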