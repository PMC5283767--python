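"""Global sensitivity analysis of deployment-strategy choice.

Samples operational and genetic parameters independently from their
ranges, runs solo, sequential, mixture and adaptive-mixture deployments
for every set under a two-niche structure (insecticide-free plus the
deployed insecticide(s)) with no fitness costs, and analyses the results
with partial rank correlation coefficients (PRCC), classification trees
and a fitted linear decision boundary in the (exposure, summed
effectiveness) plane.

The batch engine is a vectorised re-implementation of the per-generation
recursion in :mod:`resistsim.genetics` across all parameter sets at once
(unlinked loci, r = 0.5); a test pins it against the single-run engine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genetics import step_kernel
from .genotypes import COUPLING, G1_INDEX, G2_INDEX, REPULSION, segregation_matrix

__all__ = [
    "VariableRange",
    "ParameterRanges",
    "DEFAULT_RANGES",
    "sample_parameter_sets",
    "run_sensitivity",
    "prcc",
    "compare_strategies",
    "DecisionLine",
    "fit_decision_line",
    "classification_rates",
    "build_classification_tree",
    "TreeResult",
]

log = logging.getLogger(__name__)

_M_FREE = segregation_matrix(0.5)


@dataclass(frozen=True)
class VariableRange:
    """Sampling range of one input variable (uniform or log-uniform)."""

    name: str
    lo: float
    hi: float
    log: bool = False

    def __post_init__(self):
        if not self.lo <= self.hi:
            raise ValueError(f"invalid bounds for {self.name}: [{self.lo}, {self.hi}]")
        if self.log and self.lo <= 0:
            raise ValueError(f"log-uniform bounds for {self.name} must be positive")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.log:
            u = rng.uniform(np.log10(self.lo), np.log10(self.hi), n)
            return 10.0**u
        return rng.uniform(self.lo, self.hi, n)


@dataclass(frozen=True)
class ParameterRanges:
    """The sampled variables: log-uniform starting frequencies, uniform
    exposure/dominance/effectiveness/restoration/deployment quality.
    Fitness costs are fixed at zero throughout the sensitivity analysis."""

    variables: tuple[VariableRange, ...]

    def names(self) -> list[str]:
        return [v.name for v in self.variables]


DEFAULT_RANGES = ParameterRanges(
    (
        VariableRange("start_freq_allele1", 0.0001, 0.1, log=True),
        VariableRange("start_freq_allele2", 0.0001, 0.1, log=True),
        VariableRange("exposure", 0.1, 0.9),
        VariableRange("male_exposure_prop", 0.0, 1.0),
        VariableRange("effectiveness_ins1", 0.3, 1.0),
        VariableRange("effectiveness_ins2", 0.3, 1.0),
        VariableRange("dominance_allele1", 0.0, 1.0),
        VariableRange("dominance_allele2", 0.0, 1.0),
        VariableRange("rr_restoration_ins1", 0.2, 1.0),
        VariableRange("rr_restoration_ins2", 0.2, 1.0),
        VariableRange("correct_mix_deploy", 0.5, 1.0),
    )
)

PARAMETER_NAMES = DEFAULT_RANGES.names()


def sample_parameter_sets(
    n: int, seed: int, ranges: ParameterRanges = DEFAULT_RANGES
) -> pd.DataFrame:
    """Draw ``n`` parameter sets, each variable independently."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    data = {v.name: v.sample(rng, n) for v in ranges.variables}
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# vectorised batch engine


def _hwe_le_state(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """HWE/LE genotype frequencies, shape (n, 2, 10)."""
    v1 = np.stack([(1 - q1) ** 2, 2 * q1 * (1 - q1), q1**2], axis=1)
    v2 = np.stack([(1 - q2) ** 2, 2 * q2 * (1 - q2), q2**2], axis=1)
    f = v1[:, G1_INDEX] * v2[:, G2_INDEX]
    f[:, COUPLING] *= 0.5
    f[:, REPULSION] *= 0.5
    return np.repeat(f[:, None, :], 2, axis=1)


def _locus_fitness(phi: np.ndarray, h: np.ndarray, restoration: np.ndarray) -> np.ndarray:
    """Per-run (w_SS, w_RS, w_RR) in the presence of the insecticide, (n, 3)."""
    s = restoration * phi
    return np.stack([1.0 - phi, 1.0 - phi + h * s, 1.0 - phi + s], axis=1)


def _marginal_solo(params: pd.DataFrame, which: int) -> np.ndarray:
    """Marginal fitness (n, 2, 10) under solo deployment of insecticide 1 or 2."""
    k = str(which)
    w = _locus_fitness(
        params[f"effectiveness_ins{k}"].to_numpy(),
        params[f"dominance_allele{k}"].to_numpy(),
        params[f"rr_restoration_ins{k}"].to_numpy(),
    )
    g_idx = G1_INDEX if which == 1 else G2_INDEX
    wg = w[:, g_idx]  # (n, 10)
    e_f = params["exposure"].to_numpy()
    e_m = e_f * params["male_exposure_prop"].to_numpy()
    out = np.empty((len(params), 2, 10))
    for sex, e in enumerate((e_f, e_m)):
        out[:, sex, :] = (1.0 - e)[:, None] + e[:, None] * wg
    return out


def _marginal_mixture(params: pd.DataFrame) -> np.ndarray:
    """Marginal fitness (n, 2, 10) under mixture deployment with imperfect
    deployment splitting the incorrectly-treated fraction equally between
    the two single-insecticide niches."""
    w1 = _locus_fitness(
        params["effectiveness_ins1"].to_numpy(),
        params["dominance_allele1"].to_numpy(),
        params["rr_restoration_ins1"].to_numpy(),
    )[:, G1_INDEX]
    w2 = _locus_fitness(
        params["effectiveness_ins2"].to_numpy(),
        params["dominance_allele2"].to_numpy(),
        params["rr_restoration_ins2"].to_numpy(),
    )[:, G2_INDEX]
    e_f = params["exposure"].to_numpy()
    e_m = e_f * params["male_exposure_prop"].to_numpy()
    c = params["correct_mix_deploy"].to_numpy()
    out = np.empty((len(params), 2, 10))
    for sex, e in enumerate((e_f, e_m)):
        a_mix = e * c
        a_single = e * (1.0 - c) / 2.0
        out[:, sex, :] = (
            (1.0 - e)[:, None]
            + a_mix[:, None] * w1 * w2
            + a_single[:, None] * w1
            + a_single[:, None] * w2
        )
    return out


def _batch_times(
    F0: np.ndarray,
    W: np.ndarray,
    threshold: float,
    max_generations: int,
    need: str,
):
    """Iterate the recursion for a batch of runs until the required loci
    have crossed the threshold (or the cap).

    ``need`` is ``"locus1"``, ``"locus2"`` or ``"both"``.  Returns
    ``(cross, q_other, first_locus)`` where ``cross`` is (n, 2) raw
    crossing generations (-1 if not reached), ``q_other`` is the surviving
    allele's frequency one generation after the first crossing (the
    replacement generation under the one-generation detection lag) and
    ``first_locus`` the locus (0/1) that crossed first (-1 if none); the
    last two are only tracked when ``need == "both"``.
    """
    n = F0.shape[0]
    cross = -np.ones((n, 2), dtype=np.int64)
    q_other = np.full(n, np.nan)
    first_locus = -np.ones(n, dtype=np.int64)
    active = np.arange(n)
    F = F0.copy()
    Wa = W
    for generation in range(1, max_generations + 1):
        F = step_kernel(F, Wa, _M_FREE)
        q1 = F[:, 0, :] @ G1_INDEX / 2.0  # sexes identical after random union
        q2 = F[:, 0, :] @ G2_INDEX / 2.0
        for locus, q in enumerate((q1, q2)):
            newly = (q > threshold) & (cross[active, locus] < 0)
            if newly.any():
                cross[active[newly], locus] = generation
        if need == "locus1":
            done = cross[active, 0] >= 0
        elif need == "locus2":
            done = cross[active, 1] >= 0
        else:
            # surviving allele's frequency at the replacement generation
            # (one generation after the first crossing)
            fl = first_locus[active]
            pending = (fl >= 0) & np.isnan(q_other[active])
            if pending.any():
                pidx = active[pending]
                q_other[pidx] = np.where(fl[pending] == 0, q2[pending], q1[pending])
            # register first crossings (ties resolve to locus 1; the value
            # of q_other is then immaterial because the adaptive time
            # equals the mixture time)
            just = (first_locus[active] < 0) & (
                (cross[active, 0] >= 0) | (cross[active, 1] >= 0)
            )
            if just.any():
                jidx = active[just]
                crossed1 = cross[jidx, 0] >= 0
                first_locus[jidx] = np.where(crossed1, 0, 1)
            done = (cross[active, 0] >= 0) & (cross[active, 1] >= 0)
        if done.any():
            keep = ~done
            active = active[keep]
            if active.size == 0:
                break
            F = F[keep]
            Wa = Wa[keep]
    return cross, q_other, first_locus


def run_sensitivity(
    sets: pd.DataFrame,
    threshold: float = 0.5,
    max_generations: int = 500,
) -> pd.DataFrame:
    """Run every strategy for every sampled parameter set.

    Returns one record per run with the sampled parameters, the solo
    times-to-threshold of each insecticide, the sequential total (solo
    first insecticide + one switch-lag generation + solo second), the
    mixture first/both crossing times, the derived adaptive-mixture time,
    censoring flags (time not reached within the cap) and the two
    starting-frequency ratios used in the tree analyses.  Times are NaN
    where censored.
    """
    n = len(sets)
    q1 = sets["start_freq_allele1"].to_numpy()
    q2 = sets["start_freq_allele2"].to_numpy()

    # solo deployments (also the sequential phases, costs being zero)
    cross1, _, _ = _batch_times(
        _hwe_le_state(q1, np.zeros(n)), _marginal_solo(sets, 1), threshold, max_generations, "locus1"
    )
    cross2, _, _ = _batch_times(
        _hwe_le_state(np.zeros(n), q2), _marginal_solo(sets, 2), threshold, max_generations, "locus2"
    )
    t_solo1 = np.where(cross1[:, 0] >= 0, cross1[:, 0], np.nan).astype(float)
    t_solo2 = np.where(cross2[:, 1] >= 0, cross2[:, 1], np.nan).astype(float)

    # mixture deployment; reported time includes the one-generation
    # detection lag before the exhausted mixture would be replaced
    crossM, q_other, first_locus = _batch_times(
        _hwe_le_state(q1, q2), _marginal_mixture(sets), threshold, max_generations, "both"
    )
    t_mix1 = np.where(crossM[:, 0] >= 0, crossM[:, 0], np.nan).astype(float)
    t_mix2 = np.where(crossM[:, 1] >= 0, crossM[:, 1], np.nan).astype(float)
    t_mix_first = np.fmin(t_mix1, t_mix2)
    with np.errstate(invalid="ignore"):
        t_mix_both = np.where(
            np.isnan(t_mix1) | np.isnan(t_mix2), np.nan, np.maximum(t_mix1, t_mix2) + 1.0
        )
    t_mix_both = np.where(t_mix_both <= max_generations, t_mix_both, np.nan)

    # sequential: insecticide 1 first, one-generation switch lag, then 2
    t_seq = t_solo1 + 1.0 + t_solo2
    t_seq = np.where(t_seq <= max_generations, t_seq, np.nan)

    # adaptive mixture: mixture until the first crossing is detected (one
    # further generation), then the survivor alone from an HWE/LE restart
    # at its frequency at the replacement generation
    t_adapt = np.where(
        (~np.isnan(t_mix1)) & (~np.isnan(t_mix2)) & (t_mix1 == t_mix2), t_mix_both, np.nan
    )
    started = ~np.isnan(t_mix_first) & ~np.isnan(q_other)
    pending = started & np.isnan(t_adapt)
    for locus_first, survivor in ((0, 2), (1, 1)):
        grp = np.where(pending & (first_locus == locus_first))[0]
        if grp.size == 0:
            continue
        sub = sets.iloc[grp]
        qs = q_other[grp]
        F0 = _hwe_le_state(qs, np.zeros(grp.size)) if survivor == 1 else _hwe_le_state(
            np.zeros(grp.size), qs
        )
        crossS, _, _ = _batch_times(
            F0, _marginal_solo(sub, survivor), threshold, max_generations, f"locus{survivor}"
        )
        t_solo_rest = crossS[:, survivor - 1].astype(float)
        t_solo_rest[t_solo_rest < 0] = np.nan
        total = t_mix_first[grp] + 1.0 + t_solo_rest
        total = np.where(total <= max_generations, total, np.nan)
        t_adapt[grp] = total

    records = sets.copy()
    records["t_solo1"] = t_solo1
    records["t_solo2"] = t_solo2
    records["t_seq"] = t_seq
    records["t_mix1"] = t_mix1
    records["t_mix2"] = t_mix2
    records["t_mix_first"] = t_mix_first
    records["t_mix_both"] = t_mix_both
    records["t_adapt"] = t_adapt
    records["censored_seq"] = np.isnan(t_seq)
    records["censored_mix"] = np.isnan(t_mix_both)
    records["censored_adapt"] = np.isnan(t_adapt)
    records["censored"] = records["censored_seq"] & records["censored_mix"]
    records["effectiveness_sum"] = (
        records["effectiveness_ins1"] + records["effectiveness_ins2"]
    )
    records["resist_start_1_div_2"] = (
        records["start_freq_allele1"] / records["start_freq_allele2"]
    )
    hi = np.maximum(records["start_freq_allele1"], records["start_freq_allele2"])
    lo = np.minimum(records["start_freq_allele1"], records["start_freq_allele2"])
    records["resist_start_hi_div_lo"] = hi / lo
    return records


# ---------------------------------------------------------------------------
# PRCC


def prcc(X: pd.DataFrame, y: pd.Series | np.ndarray) -> pd.Series:
    """Partial rank correlation coefficient of each input with the outcome.

    All columns are rank-transformed; each input's coefficient is the
    Pearson correlation between the residuals of its ranks regressed on
    the other inputs' ranks and the residuals of the outcome ranks
    regressed on the same.  Constant columns yield NaN.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if len(X) < 3:
        raise ValueError("PRCC requires at least 3 records")
    if len(X) != len(y):
        raise ValueError("X and y must have equal length")
    ranks = np.column_stack([stats.rankdata(X[c]) for c in X.columns])
    ry = stats.rankdata(y)
    out = {}
    n = len(X)
    for j, col in enumerate(X.columns):
        if np.ptp(ranks[:, j]) == 0:
            out[col] = np.nan
            continue
        others = np.delete(ranks, j, axis=1)
        design = np.column_stack([np.ones(n), others])
        beta_x, *_ = np.linalg.lstsq(design, ranks[:, j], rcond=None)
        beta_y, *_ = np.linalg.lstsq(design, ry, rcond=None)
        res_x = ranks[:, j] - design @ beta_x
        res_y = ry - design @ beta_y
        denom = np.sqrt((res_x**2).sum() * (res_y**2).sum())
        out[col] = float((res_x * res_y).sum() / denom) if denom > 0 else np.nan
    return pd.Series(out)


# ---------------------------------------------------------------------------
# strategy comparison and the decision line

_PAIR_COLUMNS = {"mixture": "t_mix_both", "adaptive": "t_adapt"}


def _complete(records: pd.DataFrame, pair: str) -> pd.DataFrame:
    col = _PAIR_COLUMNS[pair]
    return records.loc[records[col].notna() & records["t_seq"].notna()]


def compare_strategies(
    records: pd.DataFrame, margin: float = 0.0, pair: str = "mixture"
) -> pd.DataFrame:
    """Label each completed run by the superior strategy.

    The mixture-type strategy (``pair`` = ``"mixture"`` or ``"adaptive"``)
    is superior when its time to resistance is strictly more than
    ``(1 + margin)`` times the sequential time; ties favour sequential.
    Censored runs (either time missing) are dropped.  Adds ``label`` and
    ``time_diff`` (mixture-type minus sequential) columns.
    """
    out = _complete(records, pair).copy()
    t_mix = out[_PAIR_COLUMNS[pair]]
    superior = t_mix > (1.0 + margin) * out["t_seq"]
    out["label"] = np.where(superior, "mixture", "sequential")
    out["time_diff"] = t_mix - out["t_seq"]
    return out


@dataclass(frozen=True)
class DecisionLine:
    """Linear decision boundary: mixture-type deployment is predicted
    superior when summed effectiveness > intercept + slope * exposure."""

    intercept: float
    slope: float
    margin: float = 0.0

    def predict_mixture(self, exposure, effectiveness_sum) -> np.ndarray:
        return np.asarray(effectiveness_sum) > self.intercept + self.slope * np.asarray(
            exposure
        )


def fit_decision_line(
    records: pd.DataFrame, margin: float = 0.0, pair: str = "adaptive"
) -> DecisionLine:
    """Fit the decision boundary through the equal-time runs.

    With ``margin`` 0 the boundary set is the runs whose two times are
    exactly equal (times are integer generation counts); with a positive
    margin it is the runs whose mixture-type time is between 19% and 21%
    longer than sequential.  Ordinary least squares of summed
    effectiveness on exposure over that set.
    """
    complete = _complete(records, pair)
    t_mix = complete[_PAIR_COLUMNS[pair]]
    if margin == 0.0:
        boundary = complete.loc[t_mix == complete["t_seq"]]
    else:
        rel = t_mix / complete["t_seq"] - 1.0
        boundary = complete.loc[(rel >= margin - 0.01) & (rel <= margin + 0.01)]
    if len(boundary) < 2:
        raise ValueError("fewer than 2 boundary runs: cannot fit a decision line")
    slope, intercept = np.polyfit(
        boundary["exposure"].to_numpy(), boundary["effectiveness_sum"].to_numpy(), 1
    )
    return DecisionLine(intercept=float(intercept), slope=float(slope), margin=margin)


def classification_rates(
    records: pd.DataFrame, line: DecisionLine, pair: str = "adaptive"
) -> tuple[float, float]:
    """True positive and true negative rates of the line's prediction
    against the simulated labels (positives = mixture-type superior)."""
    labelled = compare_strategies(records, line.margin, pair=pair)
    actual = labelled["label"].to_numpy() == "mixture"
    predicted = line.predict_mixture(
        labelled["exposure"].to_numpy(), labelled["effectiveness_sum"].to_numpy()
    )
    pos = actual.sum()
    neg = (~actual).sum()
    tpr = float((predicted & actual).sum() / pos) if pos else np.nan
    tnr = float((~predicted & ~actual).sum() / neg) if neg else np.nan
    return tpr, tnr


# ---------------------------------------------------------------------------
# classification trees

TREE_FEATURES = PARAMETER_NAMES + ["resist_start_1_div_2", "resist_start_hi_div_lo"]


@dataclass
class TreeResult:
    """Pruned and unpruned classification trees with the depth-selection table."""

    tree: object
    unpruned: object
    depth: int
    selection: pd.DataFrame
    feature_names: list[str] = field(default_factory=lambda: list(TREE_FEATURES))

    def export_text(self, pruned: bool = True) -> str:
        from sklearn.tree import export_text

        return export_text(
            self.tree if pruned else self.unpruned, feature_names=self.feature_names
        )

    def to_dict(self, pruned: bool = True) -> dict:
        """Machine-readable nested structure of the tree."""
        t = (self.tree if pruned else self.unpruned).tree_

        def node(i: int) -> dict:
            counts = t.value[i][0] * t.weighted_n_node_samples[i]
            leaf = {"n": int(t.n_node_samples[i]), "counts": [float(c) for c in counts]}
            if t.children_left[i] == -1:
                return leaf
            leaf.update(
                {
                    "feature": self.feature_names[t.feature[i]],
                    "threshold": float(t.threshold[i]),
                    "left": node(t.children_left[i]),
                    "right": node(t.children_right[i]),
                }
            )
            return leaf

        return node(0)


def build_classification_tree(
    records: pd.DataFrame,
    margin: float = 0.0,
    pair: str = "mixture",
    max_depth: int = 8,
    cv: int = 10,
    random_state: int = 0,
) -> TreeResult:
    """Binary recursive partitioning of the sampled inputs (plus the two
    starting-frequency ratios) against the strategy label.

    Depth is restricted to the minimum number of levels at which the
    resubstitution relative error plus its cross-validated standard error
    falls below the cross-validation error (guarding against overfitting);
    errors are expressed relative to the root (majority-class) error, as
    is conventional for recursive-partitioning software.  The unpruned
    tree is also retained for inspection.
    """
    from sklearn.model_selection import cross_val_score
    from sklearn.tree import DecisionTreeClassifier

    labelled = compare_strategies(records, margin, pair=pair)
    X = labelled[TREE_FEATURES].to_numpy()
    y = (labelled["label"] == "mixture").to_numpy()
    if y.all() or (~y).all():
        tree = DecisionTreeClassifier(max_depth=1, random_state=random_state).fit(X, y)
        return TreeResult(tree, tree, 0, pd.DataFrame())

    root_error = min(y.mean(), 1 - y.mean())
    rows = []
    fitted = {}
    for depth in range(1, max_depth + 1):
        clf = DecisionTreeClassifier(
            max_depth=depth, min_samples_leaf=20, random_state=random_state
        ).fit(X, y)
        fitted[depth] = clf
        rel_error = (1.0 - clf.score(X, y)) / root_error
        scores = cross_val_score(
            DecisionTreeClassifier(
                max_depth=depth, min_samples_leaf=20, random_state=random_state
            ),
            X,
            y,
            cv=cv,
        )
        cv_errors = (1.0 - scores) / root_error
        rows.append(
            {
                "depth": depth,
                "rel_error": rel_error,
                "cv_error": float(cv_errors.mean()),
                "cv_se": float(cv_errors.std(ddof=1) / np.sqrt(len(cv_errors))),
            }
        )
    table = pd.DataFrame(rows)
    ok = table.loc[table["rel_error"] + table["cv_se"] < table["cv_error"]]
    if len(ok):
        chosen = int(ok["depth"].iloc[0])
    else:
        chosen = int(table.loc[table["cv_error"].idxmin(), "depth"])
    return TreeResult(fitted[chosen], fitted[max_depth], chosen, table)
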