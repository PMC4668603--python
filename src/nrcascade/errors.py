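"""Exception hierarchy shared across the package."""


class NRCascadeError(Exception):
    """Base class for all package-specific errors."""


class FastaFormatError(NRCascadeError, ValueError):
    """Malformed FASTA input (e.g. sequence data before any header)."""


class EmptyInputError(NRCascadeError, ValueError):
    """An input file or collection contained no usable records."""


class DuplicateIdError(NRCascadeError, ValueError):
    """Two records in one collection share an identifier."""


class LabelError(NRCascadeError, ValueError):
    """A class label falls outside the declared label set."""


class SequenceDomainError(NRCascadeError, ValueError):
    """A residue or sequence violates an encoder's domain contract."""


class ConsistencyError(NRCascadeError, ValueError):
    """Parallel inputs disagree (mixed feature sets, dimension mismatch)."""


class ConfigurationError(NRCascadeError, ValueError):
    """Invalid configuration value (bad feature-set name, k out of range)."""
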