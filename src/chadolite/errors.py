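"""Exception hierarchy for the store and its loaders."""


class ChadoliteError(Exception):
    """Base class for all package errors."""


class StoreExistsError(ChadoliteError):
    """Raised when initialising over an already-populated store."""


class ConflictError(ChadoliteError):
    """A record with the same natural key already exists."""


class DanglingOwnerError(ChadoliteError):
    """A property or link refers to an owner record that does not exist."""


class TermLookupError(ChadoliteError):
    """A controlled-vocabulary term could not be resolved."""


class ValidationError(ChadoliteError):
    """Input violates a stated storage convention."""


class OboParseError(ChadoliteError):
    """An OBO file could not be parsed; message names the offending line."""


class NotEncodableError(ChadoliteError):
    """Alleles cannot be collapsed to a single IUPAC ambiguity base."""


class ImportError_(ChadoliteError):
    """A flat-file export could not be re-imported."""
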