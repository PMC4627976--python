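"""Stateful traversal of a knowledge base.

A :class:`Session` walks the tree one yes/no answer at a time, supports
single-step undo, and keeps its answer history as the single source of
truth: the current position is always reproducible by replaying the
history from the root.  :func:`run_answers` is the batch twin of the
interactive flow — it applies a whole answer vector and succeeds only if
the vector lands *exactly* on a recommendation.

Sessions are immutable: :func:`answer` and :func:`go_back` return new
Session objects, which makes the undo-inverse property
(``go_back(answer(s, a)) == s``) literal structural equality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import ClassVar

from .errors import (
    AnswerParseError,
    EmptyHistoryError,
    SessionCompletedError,
    TooFewAnswersError,
    TooManyAnswersError,
)
from .model import KnowledgeBase, Question, Recommendation

__all__ = [
    "Answer", "Session", "TraceStep", "DecisionTrace",
    "parse_answer", "parse_answer_vector",
    "start_session", "answer", "go_back", "current_question",
    "run_answers", "render_trace",
]

_YES_TOKENS = {"y", "yes"}
_NO_TOKENS = {"n", "no"}


@dataclass(frozen=True)
class Answer:
    """A yes/no answer. ``Answer.YES`` and ``Answer.NO`` are the two values."""

    value: str  # "yes" | "no"

    YES: ClassVar["Answer"]
    NO: ClassVar["Answer"]

    def __post_init__(self):
        if self.value not in ("yes", "no"):
            raise AnswerParseError(self.value)

    @property
    def is_yes(self) -> bool:
        return self.value == "yes"

    def __str__(self) -> str:
        return self.value


Answer.YES = Answer("yes")
Answer.NO = Answer("no")


def parse_answer(token: str) -> Answer:
    """Leniently parse ``y/yes/n/no`` (any case) into an :class:`Answer`."""
    t = token.strip().lower()
    if t in _YES_TOKENS:
        return Answer.YES
    if t in _NO_TOKENS:
        return Answer.NO
    raise AnswerParseError(token)


def parse_answer_vector(text: str) -> list[Answer]:
    """Parse a compact answer string such as ``"ynynnnn"``.

    Separators (spaces, commas) and full ``yes``/``no`` words are accepted:
    ``"y,n,y"``, ``"yes no yes"`` and ``"yny"`` are equivalent.
    """
    cleaned = text.strip().lower().replace(",", " ")
    if " " in cleaned:
        tokens = cleaned.split()
    else:
        tokens = list(cleaned)
    return [parse_answer(tok) for tok in tokens]


@dataclass(frozen=True)
class Session:
    """A live traversal: history of ``(node_id, Answer)`` plus current position."""

    kb: KnowledgeBase
    history: tuple[tuple[str, Answer], ...] = ()
    position: str = ""  # node id while in progress, recommendation id when done

    @property
    def status(self) -> str:
        return "completed" if self.kb.is_recommendation(self.position) else "in_progress"

    @property
    def completed(self) -> bool:
        return self.status == "completed"

    @property
    def depth(self) -> int:
        return len(self.history)


@dataclass(frozen=True)
class TraceStep:
    step: int
    question_id: str
    question_text: str
    explanation: str
    answer: Answer
    justification: str = ""


@dataclass(frozen=True)
class DecisionTrace:
    """Step-numbered record of a traversal plus its outcome (if completed)."""

    steps: tuple[TraceStep, ...]
    outcome: Recommendation | None = None
    pending_question: Question | None = None

    @property
    def answer_vector(self) -> str:
        return "".join("y" if s.answer.is_yes else "n" for s in self.steps)


def start_session(kb: KnowledgeBase) -> Session:
    """Open a fresh session positioned at the root question."""
    return Session(kb=kb, history=(), position=kb.root)


def current_question(session: Session) -> Question:
    """The question pending at the session's position (in-progress only)."""
    if session.completed:
        raise SessionCompletedError(session.position)
    return session.kb.question_of(session.position)


def answer(session: Session, a: Answer) -> Session:
    """Advance one step; answering a completed session is an error."""
    if session.completed:
        raise SessionCompletedError(session.position)
    node = session.kb.nodes[session.position]
    return Session(
        kb=session.kb,
        history=session.history + ((node.id, a),),
        position=node.target(a.is_yes),
    )


def go_back(session: Session) -> Session:
    """Undo the last answer; the abandoned sub-path is discarded."""
    if not session.history:
        raise EmptyHistoryError()
    last_node, _ = session.history[-1]
    return Session(kb=session.kb, history=session.history[:-1],
                   position=last_node)


def trace_of(session: Session, justifications: dict[str, str] | None = None
             ) -> DecisionTrace:
    """Build the human-readable trace of a session's history."""
    steps = []
    for i, (node_id, a) in enumerate(session.history, start=1):
        q = session.kb.question_of(node_id)
        steps.append(TraceStep(
            step=i, question_id=q.id, question_text=q.text,
            explanation=q.explanation, answer=a,
            justification=(justifications or {}).get(q.id, ""),
        ))
    outcome = (session.kb.recommendations[session.position]
               if session.completed else None)
    pending = None if session.completed else session.kb.question_of(session.position)
    return DecisionTrace(steps=tuple(steps), outcome=outcome,
                         pending_question=pending)


def run_answers(kb: KnowledgeBase, answers: list[Answer] | str) -> DecisionTrace:
    """Apply an answer vector from the root; must land exactly on a leaf.

    Raises :class:`TooFewAnswersError` (reporting the pending question) if
    the vector is exhausted early, and :class:`TooManyAnswersError`
    (reporting the recommendation reached and the surplus count) if answers
    remain after a recommendation.
    """
    if isinstance(answers, str):
        answers = parse_answer_vector(answers)
    session = start_session(kb)
    for i, a in enumerate(answers):
        if session.completed:
            return _too_many(session, surplus=len(answers) - i)
        session = answer(session, a)
    if not session.completed:
        q = current_question(session)
        raise TooFewAnswersError(q.id, q.text, n_consumed=len(answers))
    return trace_of(session)


def _too_many(session: Session, surplus: int):
    raise TooManyAnswersError(session.position, surplus=surplus,
                              n_consumed=len(session.history))


def render_trace(trace: DecisionTrace, kb: KnowledgeBase | None = None) -> str:
    """Deterministic plain-text rendering in step/question/answer layout."""
    lines = ["Step  Answer  Question", "----  ------  --------"]
    for s in trace.steps:
        lines.append(f"{s.step:>4}  {str(s.answer):<6}  {s.question_text}")
        if s.justification:
            lines.append(f"{'':12}  [{s.justification}]")
    if trace.outcome is not None:
        label = (trace.outcome.label(kb) if kb is not None
                 else " or ".join(trace.outcome.test_ids))
        lines.append(f"Recommendation — use {label}")
        if trace.outcome.guidance:
            lines.append(f"Guidance: {trace.outcome.guidance}")
    elif trace.pending_question is not None:
        lines.append(f"Pending question: {trace.pending_question.text}")
    return "\n".join(lines)
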