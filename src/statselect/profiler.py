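"""Answer the tree's questions directly from a tabular dataset.

Given a CSV-style table and a :class:`HypothesisConfig` describing which
columns are analyzed and under what study design, :func:`profile_dataset`
derives machine-checkable facts — variable scale types, group counts,
sample dependency, and a Shapiro–Wilk normality verdict — and maps them to
yes/no answers for the knowledge base's questions.  Every derived answer
carries a justification naming the evidence (column, statistic, threshold)
so a traversal driven by data remains auditable.

The profiler adds no routing logic of its own: :func:`answers_from_profile`
simply walks the tree and looks each question's answer up in the profile,
so its outcome always equals ``run_answers`` on the extracted vector.
Questions whose answer is not derivable from the data (study goals,
person-time designs with count data) must be supplied through the config;
they are never guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InsufficientDataError,
    MissingColumnError,
    ProfileError,
    UnanswerableQuestionError,
)
from .model import KnowledgeBase
from .session import Answer, DecisionTrace, answer as apply_answer, start_session, trace_of

__all__ = ["HypothesisConfig", "VariableProfile", "DatasetProfile",
           "profile_dataset", "answers_from_profile"]

#: observations required per analyzed variable (Shapiro–Wilk needs >= 3)
MIN_OBSERVATIONS = 3

#: distinct-value ceiling under which an integer variable is not called
#: continuous without a declared ordering
FEW_LEVELS = 6


@dataclass(frozen=True)
class HypothesisConfig:
    """What is being analyzed, and under which study design.

    Parameters
    ----------
    analysis_columns:
        The measurement column(s).  A paired design names the two paired
        columns (e.g. before/after); other designs name one column.
    group_column:
        Optional grouping column for independent-group designs.
    design:
        ``independent_groups`` | ``paired`` | ``one_sample``.
    normality_alpha:
        Significance level of the Shapiro–Wilk normality decision.
    goal:
        ``compare`` (group differences), ``associate`` or ``agree``.
    ordered_levels:
        Per-column category orderings; a variable is only ever called
        ordinal when its ordering is declared here (ordinality is
        semantics, not syntax).
    person_time:
        Whether the measurements are person-time exposure data.  ``None``
        means "decide from scale type if possible": a continuous or binary
        analysis variable is evidence against person-time data, while for
        count-like variables the question is unanswerable without this
        field.
    extra_answers:
        Explicit yes/no answers (by question id) for questions outside the
        profile's evidence, e.g. study-goal special cases.
    """

    analysis_columns: tuple[str, ...]
    group_column: str | None = None
    design: str = "independent_groups"
    normality_alpha: float = 0.05
    goal: str = "compare"
    ordered_levels: dict = field(default_factory=dict)
    person_time: bool | None = None
    extra_answers: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.analysis_columns:
            raise ProfileError("analysis_columns must name at least one column")
        if self.design not in ("independent_groups", "paired", "one_sample"):
            raise ProfileError(f"unknown design {self.design!r}")
        if self.design == "paired" and len(self.analysis_columns) != 2:
            raise ProfileError(
                "a paired design requires exactly two analysis columns "
                "(the paired measurements)")
        if self.goal not in ("compare", "associate", "agree"):
            raise ProfileError(f"unknown goal {self.goal!r}")


@dataclass(frozen=True)
class NormalityDecision:
    statistic: float
    p_value: float
    verdict: str        # "normal" | "not_normal"
    n: int
    on: str             # what was tested, e.g. "differences(after-before)"

    @property
    def is_normal(self) -> bool:
        return self.verdict == "normal"


@dataclass(frozen=True)
class VariableProfile:
    column: str
    scale: str          # continuous | ordinal | nominal | binary
    n_nonmissing: int
    n_missing: int
    n_distinct: int


@dataclass
class DatasetProfile:
    """Machine-derived facts sufficient to answer tree questions."""

    config: HypothesisConfig
    variables: dict[str, VariableProfile]
    n_variables: int
    n_samples: int
    group_sizes: dict
    dependent: bool
    normality: NormalityDecision
    derived_answers: dict[str, tuple[Answer, str]]  # question id -> (answer, justification)

    def answer_for(self, question_id: str) -> tuple[Answer, str] | None:
        return self.derived_answers.get(question_id)

    def to_dict(self) -> dict:
        return {
            "n_variables": self.n_variables,
            "n_samples": self.n_samples,
            "group_sizes": dict(self.group_sizes),
            "dependent": self.dependent,
            "variables": {
                c: {"scale": v.scale, "n": v.n_nonmissing,
                    "missing": v.n_missing, "distinct": v.n_distinct}
                for c, v in self.variables.items()
            },
            "normality": {
                "statistic": self.normality.statistic,
                "p_value": self.normality.p_value,
                "verdict": self.normality.verdict,
                "n": self.normality.n,
                "on": self.normality.on,
            },
            "derived_answers": {
                qid: {"answer": str(a), "justification": j}
                for qid, (a, j) in self.derived_answers.items()
            },
        }


# --------------------------------------------------------------------------

def profile_dataset(table: pd.DataFrame | str | Path,
                    config: HypothesisConfig) -> DatasetProfile:
    """Profile a data table against a hypothesis configuration.

    ``table`` may be a DataFrame or a path to a delimited text file (CSV
    by default; the delimiter is sniffed by pandas when reading a path).
    Missing values are dropped pairwise within the analyzed variables and
    the deletion count is reported in the justifications.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table)

    for col in list(config.analysis_columns) + (
            [config.group_column] if config.group_column else []):
        if col not in table.columns:
            raise MissingColumnError(col)

    variables = {
        col: _profile_variable(table[col], config)
        for col in config.analysis_columns
    }
    for col, vp in variables.items():
        if vp.n_nonmissing == 0:
            raise InsufficientDataError(col, 0, MIN_OBSERVATIONS)
        if vp.n_nonmissing < MIN_OBSERVATIONS:
            raise InsufficientDataError(col, vp.n_nonmissing, MIN_OBSERVATIONS)

    # group structure
    if config.design == "paired":
        n_samples = 2
        pair = table[list(config.analysis_columns)].dropna()
        group_sizes = {config.analysis_columns[0]: len(pair),
                       config.analysis_columns[1]: len(pair)}
        dependent = True
    elif config.design == "one_sample":
        n_samples = 1
        col = config.analysis_columns[0]
        group_sizes = {col: variables[col].n_nonmissing}
        dependent = False
    else:
        dependent = False
        if config.group_column is not None:
            sizes = table.groupby(config.group_column, observed=True)[
                config.analysis_columns[0]].count()
            group_sizes = {str(k): int(v) for k, v in sizes.items()}
            n_samples = len(group_sizes)
        else:
            col = config.analysis_columns[0]
            group_sizes = {col: variables[col].n_nonmissing}
            n_samples = 1

    normality = _normality_decision(table, config)
    profile = DatasetProfile(
        config=config, variables=variables,
        n_variables=_conceptual_n_variables(config),
        n_samples=n_samples, group_sizes=group_sizes, dependent=dependent,
        normality=normality, derived_answers={},
    )
    profile.derived_answers = _derive_answers(profile, table)
    return profile


def _conceptual_n_variables(config: HypothesisConfig) -> int:
    # paired before/after columns are two measurements of ONE variable
    if config.design == "paired":
        return 1
    return len(config.analysis_columns)


def _profile_variable(series: pd.Series, config: HypothesisConfig
                      ) -> VariableProfile:
    nonmissing = series.dropna()
    n = len(nonmissing)
    distinct = nonmissing.nunique()
    if distinct == 2:
        scale = "binary"
    elif series.name in config.ordered_levels:
        scale = "ordinal"
    elif pd.api.types.is_numeric_dtype(nonmissing):
        values = nonmissing.to_numpy()
        integral = np.all(np.equal(np.mod(values, 1), 0)) if n else False
        scale = "nominal" if (integral and distinct <= FEW_LEVELS) else "continuous"
    else:
        scale = "nominal"
    return VariableProfile(
        column=str(series.name), scale=scale, n_nonmissing=n,
        n_missing=int(series.isna().sum()), n_distinct=int(distinct),
    )


def _normality_decision(table: pd.DataFrame,
                        config: HypothesisConfig) -> NormalityDecision:
    """Shapiro–Wilk at ``normality_alpha``; paired designs test differences."""
    if config.design == "paired":
        a, b = config.analysis_columns
        pair = table[[a, b]].dropna()
        values = (pair[b] - pair[a]).to_numpy(dtype=float)
        target = f"differences({b}-{a})"
    else:
        col = config.analysis_columns[0]
        values = table[col].dropna().to_numpy()
        target = col
        if not np.issubdtype(np.asarray(values).dtype, np.number):
            return NormalityDecision(float("nan"), float("nan"),
                                     "not_normal", len(values),
                                     f"{target} (non-numeric)")
        values = values.astype(float)
    if len(values) < MIN_OBSERVATIONS:
        raise InsufficientDataError(target, len(values), MIN_OBSERVATIONS)
    stat, p = stats.shapiro(values)
    verdict = "normal" if p > config.normality_alpha else "not_normal"
    return NormalityDecision(float(stat), float(p), verdict, len(values), target)


# --------------------------------------------------------------------------
# mapping facts -> answers for the packaged tree's questions

def _yes(cond: bool) -> Answer:
    return Answer.YES if cond else Answer.NO


def _derive_answers(profile: DatasetProfile,
                    table: pd.DataFrame | None = None
                    ) -> dict[str, tuple[Answer, str]]:
    cfg = profile.config
    first = profile.variables[cfg.analysis_columns[0]]
    scales = {v.scale for v in profile.variables.values()}
    nd = profile.normality
    small_n_note = (" (note: n < 30)" if nd.n < 30 else "")

    answers: dict[str, tuple[Answer, str]] = {}

    answers["q_one_variable"] = (
        _yes(profile.n_variables == 1),
        f"{profile.n_variables} analysis variable(s): "
        + ", ".join(cfg.analysis_columns)
        + ("; paired columns measure one variable twice"
           if cfg.design == "paired" else ""))
    answers["q_one_sample"] = (
        _yes(profile.n_samples == 1),
        f"design={cfg.design}, {profile.n_samples} sample(s)")
    answers["q_two_samples"] = (
        _yes(profile.n_samples == 2),
        f"{profile.n_samples} sample(s) with sizes {profile.group_sizes}")
    answers["q_normal"] = (
        _yes(nd.is_normal),
        f"Shapiro-Wilk on {nd.on}: W={nd.statistic:.4f}, p={nd.p_value:.4g} "
        f"{'>' if nd.is_normal else '<='} alpha={cfg.normality_alpha}, "
        f"n={nd.n}{small_n_note}")
    answers["q_binomial"] = (
        _yes(first.scale == "binary"),
        f"column {first.column!r} has {first.n_distinct} distinct values "
        f"(scale={first.scale})")
    answers["q_independent"] = (
        _yes(not profile.dependent),
        f"design={cfg.design}: samples are "
        f"{'dependent' if profile.dependent else 'independent'}")
    answers["q_ordinal_or_continuous"] = (
        _yes(first.scale in ("ordinal", "continuous")),
        f"column {first.column!r} scale={first.scale}")
    answers["q_more_than_two_categories"] = (
        _yes(max(v.n_distinct for v in profile.variables.values()) > 2),
        "distinct value counts: "
        + ", ".join(f"{v.column}={v.n_distinct}"
                    for v in profile.variables.values()))
    answers["q_two_groups"] = (
        _yes(profile.n_samples == 2),
        f"{profile.n_samples} group(s)")
    if first.scale in ("continuous", "binary"):
        answers["q_count_rare"] = (
            Answer.NO,
            f"column {first.column!r} scale={first.scale} is not a count "
            "of rare events")
    answers["q_two_variables"] = (
        _yes(profile.n_variables == 2),
        f"{profile.n_variables} analysis variable(s)")

    # hypothesis-driven questions: answered from the declared design/goal,
    # overridable through extra_answers, never from silent guesses
    answers["q_compare_variances"] = (
        Answer.NO,
        f"goal={cfg.goal}: hypothesis concerns means/association, "
        "not variability")
    answers["q_posthoc"] = (
        Answer.NO, "no post hoc (multiple comparison) stage declared")
    answers["q_variance_known"] = (
        Answer.NO, "population variance not declared in configuration")
    answers["q_compare_distribution"] = (
        Answer.NO,
        f"goal={cfg.goal}, not a distribution goodness-of-fit question")
    answers["q_hypothesized_median"] = (
        _yes(cfg.design == "one_sample" and cfg.goal == "compare"),
        f"design={cfg.design}, goal={cfg.goal}")

    if "q_trend" not in cfg.extra_answers:
        answers["q_trend"] = (
            Answer.NO, "no trend hypothesis declared in configuration")

    # binary variable: adequacy of the normal approximation from n*p*(1-p)
    if first.scale == "binary" and table is not None:
        col = table[first.column].dropna()
        p_hat = float((col == col.unique()[0]).mean())
        npq = first.n_nonmissing * p_hat * (1.0 - p_hat)
        answers["q_large_sample"] = (
            _yes(npq >= 5.0),
            f"n*p*(1-p) = {npq:.2f} with n={first.n_nonmissing}, "
            f"p={p_hat:.3f} (threshold 5)")

    # two independent groups: Levene's check for variance homogeneity
    if (table is not None and cfg.design == "independent_groups"
            and cfg.group_column is not None and profile.n_samples == 2):
        col, grp = cfg.analysis_columns[0], cfg.group_column
        sub = table[[col, grp]].dropna()
        groups = [g[col].to_numpy(dtype=float)
                  for _, g in sub.groupby(grp, observed=True)]
        if all(len(g) >= 2 for g in groups):
            w, p = stats.levene(*groups)
            answers["q_equal_variances"] = (
                _yes(p > cfg.normality_alpha),
                f"Levene's test on {col!r} by {grp!r}: W={w:.4f}, "
                f"p={p:.4g} vs alpha={cfg.normality_alpha}")

    # person-time: config wins; otherwise a continuous/binary measurement is
    # evidence against person-time data, and count-like data is unanswerable.
    if cfg.person_time is not None:
        answers["q_person_time"] = (
            _yes(cfg.person_time), "declared in configuration")
    elif first.scale in ("continuous", "binary"):
        answers["q_person_time"] = (
            Answer.NO,
            f"column {first.column!r} is a {first.scale} measurement, "
            "not event counts over exposure time")

    # scale-type questions about variable pairs
    answers["q_both_continuous"] = (
        _yes(scales == {"continuous"}),
        "scales: " + ", ".join(f"{v.column}={v.scale}"
                               for v in profile.variables.values()))
    answers["q_both_categorical"] = (
        _yes(scales <= {"nominal", "binary", "ordinal"}),
        "scales: " + ", ".join(f"{v.column}={v.scale}"
                               for v in profile.variables.values()))

    # goal-driven questions
    answers["q_agreement"] = (
        _yes(cfg.goal == "agree"), f"goal={cfg.goal}")
    answers["q_predict"] = (Answer.NO, f"goal={cfg.goal} (not prediction)")

    # explicit config-supplied answers override / extend the derived ones
    for qid, val in cfg.extra_answers.items():
        a = val if isinstance(val, Answer) else _yes(bool(val))
        answers[qid] = (a, "declared in configuration")
    return answers


def answers_from_profile(profile: DatasetProfile, kb: KnowledgeBase
                         ) -> tuple[str, DecisionTrace]:
    """Walk the tree answering every question from the profile.

    Returns the compact answer vector and the full trace with per-step
    justifications.  Raises :class:`UnanswerableQuestionError` naming the
    question and the missing evidence if the realized path reaches a
    question the profile cannot answer.
    """
    session = start_session(kb)
    justifications: dict[str, str] = {}
    while not session.completed:
        node = kb.nodes[session.position]
        qid = node.question_id
        derived = profile.answer_for(qid)
        if derived is None:
            q = kb.questions[qid]
            raise UnanswerableQuestionError(
                qid, q.text,
                "no evidence in the dataset profile and no configured answer")
        a, justification = derived
        justifications[qid] = justification
        session = apply_answer(session, a)
    trace = trace_of(session, justifications)
    return trace.answer_vector, trace
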