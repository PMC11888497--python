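"""Exception hierarchy shared across the pipeline.

Every stage raises a subclass of :class:`BabeldxError`, so callers can
distinguish pipeline faults from programming errors with one except clause.
"""


class BabeldxError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(BabeldxError):
    """A vignette JSON document is missing required structure."""


class CurieError(SchemaError):
    """An identifier does not parse as a PREFIX:LOCALID CURIE."""


class EmptyCohortError(BabeldxError):
    """A cohort directory yielded zero parseable vignettes."""


class FormatError(BabeldxError):
    """A tabular fixture (lexicon TSV, graph JSON) is malformed."""


class EncodingError(FormatError):
    """Input bytes are not valid UTF-8."""


class MissingTranslationError(BabeldxError):
    """No translated label exists for (term, language).

    Non-fatal by design: the cohort filter is built on catching this.
    """

    def __init__(self, term_id: str, language: str):
        self.term_id = term_id
        self.language = language
        super().__init__(f"no {language!r} translation for {term_id}")


class UnknownDiseaseError(BabeldxError):
    """A disease id is absent from the disease graph."""


class NoTemplateError(BabeldxError):
    """No prompt template registered for the requested language."""


class BackendUnavailableError(BabeldxError):
    """An LLM backend cannot serve the request (retryable)."""


class SpecError(BabeldxError):
    """A generator or mock specification is internally inconsistent."""


class EmptyInputError(BabeldxError):
    """An aggregation was asked to summarize zero results."""


class DegenerateError(BabeldxError):
    """A frequency is undefined because every case lacked a diagnosis."""


class InsufficientGroupsError(BabeldxError):
    """A cross-group comparison needs at least two non-empty groups."""
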