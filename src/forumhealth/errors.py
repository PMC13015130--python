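"""Structured exceptions shared across the pipeline."""


class ForumHealthError(Exception):
    """Base class for all package errors."""


class CorpusFormatError(ForumHealthError):
    """A post record is malformed (missing fields, bad JSON/CSV row)."""

    def __init__(self, message: str, record_index: int | None = None):
        self.record_index = record_index
        if record_index is not None:
            message = f"record {record_index}: {message}"
        super().__init__(message)


class DuplicatePostIdError(ForumHealthError):
    def __init__(self, post_id: str, record_index: int | None = None):
        self.post_id = post_id
        self.record_index = record_index
        where = f" at record {record_index}" if record_index is not None else ""
        super().__init__(f"duplicate post_id {post_id!r}{where}")


class LexiconError(ForumHealthError):
    """Bad lexicon content: unknown category or conflicting synonym targets."""


class RatingFormatError(ForumHealthError):
    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class VocabularyError(ForumHealthError):
    """Term missing from an embedding vocabulary, or an empty vocabulary."""


class GraphError(ForumHealthError):
    """Degenerate keyword graph (too few nodes, missing assignment)."""


class IncompleteDesignError(ForumHealthError):
    """A rating aggregation was requested on an incomplete expert x post x question design."""

    def __init__(self, message: str, missing: list | None = None):
        self.missing = missing or []
        super().__init__(message)


class ConfigError(ForumHealthError):
    """Invalid generator or pipeline configuration."""


class StageDependencyError(ForumHealthError):
    def __init__(self, stage: str, prerequisite: str, artifact: str):
        self.stage = stage
        self.prerequisite = prerequisite
        self.artifact = artifact
        super().__init__(
            f"stage {stage!r} needs artifact {artifact!r}; run stage {prerequisite!r} first"
        )
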