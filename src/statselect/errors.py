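"""Exception hierarchy.

Structural problems detected while *auditing* a knowledge base are not
exceptions (see :mod:`statselect.analysis`); exceptions are reserved for
contract violations: malformed documents, dangling references, misuse of a
session, and batch answer vectors that do not land exactly on a
recommendation.
"""

from __future__ import annotations


class StatSelectError(Exception):
    """Base class for all package errors."""


class KBError(StatSelectError):
    """Base class for knowledge-base loading/saving errors."""


class KBSchemaError(KBError):
    """The document violates the KB schema.

    Carries the offending top-level section, record id (when known) and
    field so error messages pinpoint the record to fix.
    """

    def __init__(self, message: str, *, section: str | None = None,
                 record_id: str | None = None, field: str | None = None):
        self.section = section
        self.record_id = record_id
        self.field = field
        where = "/".join(x for x in (section, record_id, field) if x)
        super().__init__(f"{message} (at {where})" if where else message)


class DanglingReferenceError(KBError):
    """An id mentioned in one record does not resolve to any record."""

    def __init__(self, source_id: str, target_id: str, field: str):
        self.source_id = source_id
        self.target_id = target_id
        self.field = field
        super().__init__(
            f"record {source_id!r} field {field!r} references "
            f"unknown id {target_id!r}"
        )


class InvalidKBError(KBError):
    """An operation refused to run on a knowledge base that fails validation.

    The attached :class:`~statselect.analysis.ValidationReport` lists why.
    """

    def __init__(self, report):
        self.report = report
        errs = ", ".join(f.code for f in report.findings if f.severity == "error")
        super().__init__(f"knowledge base failed validation: {errs or 'see report'}")


class SessionError(StatSelectError):
    """Base class for traversal misuse."""


class SessionCompletedError(SessionError):
    """Attempt to answer a session that already reached a recommendation."""

    def __init__(self, recommendation_id: str):
        self.recommendation_id = recommendation_id
        super().__init__(
            f"session already completed at recommendation {recommendation_id!r}"
        )


class EmptyHistoryError(SessionError):
    """Attempt to go back from the root (no answers to undo)."""

    def __init__(self):
        super().__init__("nothing to undo: the session is at the first question")


class AnswerParseError(StatSelectError):
    """Token not interpretable as yes/no."""

    def __init__(self, token: str):
        self.token = token
        super().__init__(f"cannot interpret {token!r} as yes/no "
                         "(accepted: y, yes, n, no, any case)")


class TooFewAnswersError(StatSelectError):
    """The answer vector ran out before reaching a recommendation."""

    def __init__(self, pending_question_id: str, pending_question_text: str,
                 n_consumed: int):
        self.pending_question_id = pending_question_id
        self.pending_question_text = pending_question_text
        self.n_consumed = n_consumed
        super().__init__(
            f"answer vector exhausted after {n_consumed} answer(s); "
            f"pending question {pending_question_id!r}: {pending_question_text}"
        )


class TooManyAnswersError(StatSelectError):
    """The answer vector continued past a recommendation."""

    def __init__(self, recommendation_id: str, surplus: int, n_consumed: int):
        self.recommendation_id = recommendation_id
        self.surplus = surplus
        self.n_consumed = n_consumed
        super().__init__(
            f"recommendation {recommendation_id!r} reached after "
            f"{n_consumed} answer(s) but {surplus} surplus answer(s) remain"
        )


class ProfileError(StatSelectError):
    """Base class for dataset-profiling errors."""


class MissingColumnError(ProfileError):
    def __init__(self, column: str):
        self.column = column
        super().__init__(f"column {column!r} not present in the data table")


class InsufficientDataError(ProfileError):
    def __init__(self, column: str, n: int, minimum: int):
        self.column = column
        self.n = n
        self.minimum = minimum
        super().__init__(
            f"column {column!r} has {n} non-missing observation(s); "
            f"at least {minimum} required"
        )


class UnanswerableQuestionError(ProfileError):
    """A tree question cannot be answered from the dataset profile."""

    def __init__(self, question_id: str, question_text: str, reason: str):
        self.question_id = question_id
        self.question_text = question_text
        self.reason = reason
        super().__init__(
            f"question {question_id!r} ({question_text}) cannot be answered "
            f"from the data: {reason}"
        )


class UnreachableTestError(StatSelectError):
    """No root-to-leaf path recommends the requested test (KB coverage bug)."""

    def __init__(self, test_id: str):
        self.test_id = test_id
        super().__init__(f"no path in the tree reaches a recommendation "
                         f"containing test {test_id!r}")
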