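"""Exception hierarchy shared by all gelquant modules."""


class GelQuantError(Exception):
    """Base class for all errors raised by gelquant."""


class InputError(GelQuantError):
    """Unreadable or malformed input file or argument."""


class ValidationError(GelQuantError):
    """A domain object violates its invariants (geometry, bounds, parameters)."""


class StoreError(GelQuantError):
    """Datastore-level failure (missing store, schema mismatch, unknown entity)."""


class ReadOnlyStoreError(StoreError):
    """Mutation attempted on a store opened in viewing (read-only) mode."""


class NoReferenceError(GelQuantError):
    """Normalization requested but no successful reference lane is available."""


class ReplayMismatchError(GelQuantError):
    """Replaying a logged analysis did not reproduce the stored values."""

    def __init__(self, message, mismatches=None):
        super().__init__(message)
        self.mismatches = mismatches or []
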