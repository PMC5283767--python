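"""Plain-text calibration files and shipped scenario fixtures.

The configuration format is an INI-style key/value file with sections
``[locus1]``/``[locus2]`` (per-insecticide effectiveness, dominance,
rr_restoration or explicit selection, cost, cost_dominance, optionally
with ``_low`` variants for low-concentration niches), ``[exposure]``
(deployment exposure parameters), ``[interaction]`` (Λ factors) and
``[simulation]`` (strategy, starting frequencies, recombination,
threshold, generation cap and an optional relaxed-selection span).
Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

from .deployment import Calibration, DeploymentSpec, Schedule, Span
from .genetics import InsecticideParams, InteractionFactors

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "write_config",
    "fixture_path",
    "curtis_idealised",
    "curtis_mixture_spec",
    "curtis_single_spec",
    "curtis_sequential_spec",
    "curtis_fig1_relaxed_schedule",
    "curtis_table3_grid",
    "GENERATIONS_PER_YEAR",
]

#: Labelling convenience only (one mosquito generation per month); never
#: used in any computation.
GENERATIONS_PER_YEAR = 12


class ConfigError(ValueError):
    """A configuration file failed validation; the message names the
    offending section and key."""


_LOCUS_KEYS = {
    "effectiveness",
    "dominance",
    "rr_restoration",
    "selection",
    "effectiveness_low",
    "dominance_low",
    "rr_restoration_low",
    "selection_low",
    "cost",
    "cost_dominance",
}
_EXPOSURE_KEYS = {"exposure", "male_exposure_prop", "correct_mix_deploy"}
_INTERACTION_KEYS = {"lambda_ab", "lambda_Ab", "lambda_aB", "lambda_AB"}
_SIMULATION_KEYS = {
    "strategy",
    "insecticide",
    "insecticide_order",
    "start_freq_1",
    "start_freq_2",
    "recombination",
    "threshold",
    "max_generations",
    "relax_generations",
}


@dataclass(frozen=True)
class RunConfig:
    """A validated calibration plus deployment settings."""

    calibration: Calibration
    deployment: DeploymentSpec
    threshold: float = 0.5
    max_generations: int = 500
    relax_span: tuple[int, int] | None = None

    def schedule(self) -> Schedule:
        """Expand into an explicit schedule (supports relaxed-selection
        interruptions where no insecticide is deployed)."""
        end = self.max_generations
        if self.relax_span is None:
            return Schedule((Span(1, end, self.deployment),))
        lo, hi = self.relax_span
        relax = DeploymentSpec(strategy="none", exposure=0.0)
        spans = []
        if lo > 1:
            spans.append(Span(1, lo - 1, self.deployment))
        spans.append(Span(max(lo, 1), hi, relax))
        if hi < end:
            spans.append(Span(hi + 1, end, self.deployment))
        return Schedule(tuple(spans))


def _getfloat(section, key, name, default=None):
    if key not in section:
        if default is None:
            raise ConfigError(f"missing key {key!r} in section [{name}]")
        return default
    try:
        return float(section[key])
    except ValueError as exc:
        raise ConfigError(f"key {key!r} in section [{name}] is not a number") from exc


def _check_keys(section, allowed, name):
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section [{name}]")


def _locus_params(section, name) -> InsecticideParams:
    _check_keys(section, _LOCUS_KEYS, name)
    phi = _getfloat(section, "effectiveness", name)
    h = _getfloat(section, "dominance", name)
    cost = _getfloat(section, "cost", name, 0.0)
    cost_dom = _getfloat(section, "cost_dominance", name, 0.0)
    if "selection" in section and "rr_restoration" in section:
        raise ConfigError(f"[{name}] must give either rr_restoration or selection, not both")
    kw = {}
    for suffix in ("effectiveness_low", "dominance_low"):
        if suffix in section:
            kw[suffix] = _getfloat(section, suffix, name)
    try:
        if "selection" in section:
            sel_low = (
                _getfloat(section, "selection_low", name)
                if "selection_low" in section
                else None
            )
            return InsecticideParams(
                effectiveness=phi,
                dominance=h,
                selection=_getfloat(section, "selection", name),
                selection_low=sel_low,
                cost=cost,
                cost_dominance=cost_dom,
                **kw,
            )
        restoration = _getfloat(section, "rr_restoration", name)
        r_low = (
            _getfloat(section, "rr_restoration_low", name)
            if "rr_restoration_low" in section
            else None
        )
        return InsecticideParams.from_restoration(
            phi,
            h,
            restoration,
            restoration_low=r_low,
            cost=cost,
            cost_dominance=cost_dom,
            **kw,
        )
    except ValueError as exc:
        raise ConfigError(f"invalid calibration in section [{name}]: {exc}") from exc


def _parse_span(text: str) -> tuple[int, int]:
    try:
        lo, hi = (int(p) for p in text.split("-"))
    except ValueError as exc:
        raise ConfigError(
            f"relax_generations must look like '4-12', got {text!r}"
        ) from exc
    if lo < 1 or hi < lo:
        raise ConfigError(f"invalid relax_generations span {text!r}")
    return lo, hi


def load_config(path) -> RunConfig:
    """Read and validate a calibration file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = configparser.ConfigParser()
    parser.optionxform = str  # keys are case sensitive (lambda_Ab vs lambda_aB)
    with open(path) as fh:
        parser.read_file(fh)
    known_sections = {"locus1", "locus2", "exposure", "interaction", "simulation"}
    unknown = set(parser.sections()) - known_sections
    if unknown:
        raise ConfigError(f"unknown section(s) {sorted(unknown)}")
    for required in ("locus1", "locus2", "simulation"):
        if required not in parser:
            raise ConfigError(f"missing section [{required}]")

    params1 = _locus_params(parser["locus1"], "locus1")
    params2 = _locus_params(parser["locus2"], "locus2")

    lam = InteractionFactors()
    if "interaction" in parser:
        sec = parser["interaction"]
        _check_keys(sec, _INTERACTION_KEYS, "interaction")
        lam = InteractionFactors(
            ab=_getfloat(sec, "lambda_ab", "interaction", 1.0),
            Ab=_getfloat(sec, "lambda_Ab", "interaction", 1.0),
            aB=_getfloat(sec, "lambda_aB", "interaction", 1.0),
            AB=_getfloat(sec, "lambda_AB", "interaction", 1.0),
        )

    exposure = 0.0
    male_prop = 1.0
    correct = 1.0
    if "exposure" in parser:
        sec = parser["exposure"]
        _check_keys(sec, _EXPOSURE_KEYS, "exposure")
        exposure = _getfloat(sec, "exposure", "exposure", 0.0)
        male_prop = _getfloat(sec, "male_exposure_prop", "exposure", 1.0)
        correct = _getfloat(sec, "correct_mix_deploy", "exposure", 1.0)

    sim = parser["simulation"]
    _check_keys(sim, _SIMULATION_KEYS, "simulation")
    strategy = sim.get("strategy", "mixture")
    insecticide = int(sim["insecticide"]) if "insecticide" in sim else None
    order = (1, 2)
    if "insecticide_order" in sim:
        parts = [int(p) for p in sim["insecticide_order"].split(",")]
        order = tuple(parts)
    try:
        spec = DeploymentSpec(
            strategy=strategy,
            exposure=exposure,
            male_exposure_prop=male_prop,
            correct_mix_deploy=correct,
            insecticide=insecticide,
            insecticide_order=order,
        )
        calibration = Calibration(
            insecticide1=params1,
            insecticide2=params2,
            interaction=lam,
            recombination=_getfloat(sim, "recombination", "simulation", 0.5),
            start_freq1=_getfloat(sim, "start_freq_1", "simulation"),
            start_freq2=_getfloat(sim, "start_freq_2", "simulation"),
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    relax = _parse_span(sim["relax_generations"]) if "relax_generations" in sim else None
    return RunConfig(
        calibration=calibration,
        deployment=spec,
        threshold=_getfloat(sim, "threshold", "simulation", 0.5),
        max_generations=int(_getfloat(sim, "max_generations", "simulation", 500)),
        relax_span=relax,
    )


def write_config(config: RunConfig, path) -> None:
    """Write a RunConfig back to the plain-text format (round-trips through
    :func:`load_config`)."""
    parser = configparser.ConfigParser()
    parser.optionxform = str
    cal = config.calibration
    for name, p in (("locus1", cal.insecticide1), ("locus2", cal.insecticide2)):
        section = {
            "effectiveness": repr(p.effectiveness),
            "dominance": repr(p.dominance),
            "selection": repr(p.selection),
            "cost": repr(p.cost),
            "cost_dominance": repr(p.cost_dominance),
        }
        if p.effectiveness_low is not None:
            section["effectiveness_low"] = repr(p.effectiveness_low)
        if p.dominance_low is not None:
            section["dominance_low"] = repr(p.dominance_low)
        if p.selection_low is not None:
            section["selection_low"] = repr(p.selection_low)
        parser[name] = section
    parser["exposure"] = {
        "exposure": repr(config.deployment.exposure),
        "male_exposure_prop": repr(config.deployment.male_exposure_prop),
        "correct_mix_deploy": repr(config.deployment.correct_mix_deploy),
    }
    lam = cal.interaction
    parser["interaction"] = {
        "lambda_ab": repr(lam.ab),
        "lambda_Ab": repr(lam.Ab),
        "lambda_aB": repr(lam.aB),
        "lambda_AB": repr(lam.AB),
    }
    sim = {
        "strategy": config.deployment.strategy,
        "start_freq_1": repr(cal.start_freq1),
        "start_freq_2": repr(cal.start_freq2),
        "recombination": repr(cal.recombination),
        "threshold": repr(config.threshold),
        "max_generations": str(config.max_generations),
        "insecticide_order": ",".join(str(i) for i in config.deployment.insecticide_order),
    }
    if config.deployment.insecticide is not None:
        sim["insecticide"] = str(config.deployment.insecticide)
    if config.relax_span is not None:
        sim["relax_generations"] = f"{config.relax_span[0]}-{config.relax_span[1]}"
    parser["simulation"] = sim
    with open(path, "w") as fh:
        parser.write(fh)


# ---------------------------------------------------------------------------
# shipped fixtures


def fixture_path(name: str) -> Path:
    """Path of a packaged fixture configuration file."""
    ref = resources.files("resistsim").joinpath("fixtures", f"{name}.cfg")
    return Path(str(ref))


#: Exposure of the idealised scenario: 90% of both sexes encounter the
#: deployed insecticide(s), 10% escape (the classic "escape = 0.1"
#: convention); this calibration reproduces the printed one-generation
#: update 0.1% -> 0.98% and the solo crossing times 3/4/5 generations for
#: starts of 1e-2/1e-3/1e-4.
CURTIS_EXPOSURE = 0.9


def curtis_idealised(start_freq1: float = 0.01, start_freq2: float = 0.001) -> Calibration:
    """The idealised calibration: each insecticide kills every SS mosquito
    it contacts (effectiveness 1), resistance is fully dominant and fully
    restores fitness, and carries no cost."""
    ideal = InsecticideParams.from_restoration(1.0, 1.0, 1.0)
    return Calibration(
        insecticide1=ideal,
        insecticide2=ideal,
        start_freq1=start_freq1,
        start_freq2=start_freq2,
    )


def curtis_mixture_spec() -> DeploymentSpec:
    return DeploymentSpec(strategy="mixture", exposure=CURTIS_EXPOSURE)


def curtis_single_spec(insecticide: int) -> DeploymentSpec:
    return DeploymentSpec(
        strategy="single", exposure=CURTIS_EXPOSURE, insecticide=insecticide
    )


def curtis_sequential_spec(order: tuple[int, int] = (1, 2)) -> DeploymentSpec:
    return DeploymentSpec(
        strategy="sequential", exposure=CURTIS_EXPOSURE, insecticide_order=order
    )


def curtis_fig1_relaxed_schedule(max_generations: int = 20) -> tuple[Calibration, Schedule]:
    """Idealised single-insecticide deployment interrupted by a relaxed
    span (no insecticide) over generations 4-12, then resumed."""
    cal = curtis_idealised(start_freq1=0.001, start_freq2=0.0)
    deployed = curtis_single_spec(1)
    relax = DeploymentSpec(strategy="none", exposure=0.0)
    schedule = Schedule(
        (
            Span(1, 3, deployed),
            Span(4, 12, relax),
            Span(13, max_generations, deployed),
        )
    )
    return cal, schedule


#: Starting-frequency grid of the classic sequential-vs-mixture comparison:
#: (locus 1 "old" insecticide start, locus 2 "new" insecticide start).
TABLE3_GRID = tuple(
    (p1, p2) for p2 in (1e-2, 1e-3, 1e-4) for p1 in (0.01, 0.1, 0.3)
)


def curtis_table3_grid() -> list[Calibration]:
    """Idealised calibrations over the starting-frequency grid; the "new"
    (lower starting resistance) insecticide is at locus 2 and is deployed
    second in sequential runs."""
    return [curtis_idealised(p1, p2) for p1, p2 in TABLE3_GRID]


def hch_ddt_synthetic() -> Calibration:
    """Approximate HCH/DDT-style calibration (synthetic stand-in).

    Only the DDT-like locus is calibrated from the published survival
    figures (SS survives exposure with fitness 0.27, RR with 0.50, i.e.
    effectiveness 0.73 and selection 0.23); the HCH-like locus parameters
    are placeholders the user is expected to replace.  Shipped clearly
    marked as incomplete.
    """
    ddt_like = InsecticideParams(effectiveness=0.73, dominance=0.5, selection=0.23)
    hch_like = InsecticideParams(effectiveness=0.73, dominance=0.5, selection=0.23)
    return Calibration(
        insecticide1=ddt_like, insecticide2=hch_like, start_freq1=0.1, start_freq2=0.01
    )
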