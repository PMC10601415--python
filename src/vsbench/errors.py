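"""Exception hierarchy for vsbench.

Every error raised deliberately by the toolkit derives from :class:`VsbenchError`,
so callers (and the CLI) can distinguish pipeline errors from programming bugs.
"""


class VsbenchError(Exception):
    """Base class for all vsbench errors."""


class ConfigError(VsbenchError):
    """Invalid or missing configuration value; the message names the key."""


class LibraryError(VsbenchError):
    """Empty library, duplicate ids, or an unusable molecule collection."""


class DescriptorError(VsbenchError):
    """A molecular descriptor could not be computed (unparsable structure)."""


class IntegrityError(VsbenchError):
    """Internal consistency violated: duplicate ids in a score table,
    mismatched id sets across engines, overlapping chunk partitions."""


class IncompleteRunError(VsbenchError):
    """A per-chunk result is missing when merging a staged run."""


class StageFailure(VsbenchError):
    """A pipeline stage failed on a chunk; carries the chunk index and log."""

    def __init__(self, chunk_index: int, log: str = ""):
        self.chunk_index = chunk_index
        self.log = log
        super().__init__(f"stage failed on chunk {chunk_index}: {log}")


class EngineUnavailableError(VsbenchError):
    """The named screening engine's executable or callable is not available."""


class SelectionError(VsbenchError):
    """Structure selection produced no candidates (filter or ligand code)."""


class UndefinedMetricError(VsbenchError):
    """Metric undefined for the haystack (zero actives or zero decoys)."""


class DegenerateTestError(VsbenchError):
    """Paired test undefined: the per-target differences have zero variance."""


class FetchError(VsbenchError):
    """Remote data fetch failed: unknown target, transport error, or a
    malformed recorded response."""
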