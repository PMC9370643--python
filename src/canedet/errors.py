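"""Exception hierarchy shared across the pipeline."""


class CanedetError(Exception):
    """Base class for all pipeline errors."""


class FormatError(CanedetError, ValueError):
    """A file or table violates its declared format."""


class DuplicateKeyError(FormatError):
    """An identifier that must be unique occurs more than once."""


class MissingLengthError(FormatError):
    """A transcript in the count matrix has no length."""


class VocabularyError(FormatError):
    """A categorical field holds a value outside its vocabulary."""


class DuplicateDesignError(FormatError):
    """Two libraries share the same (genotype, tissue, condition, replicate)."""


class EmptyInputError(CanedetError, ValueError):
    """An input that must be nonempty is empty."""


class SpecificationError(CanedetError, ValueError):
    """A comparison or rule specification is inconsistent with the data."""


class DomainError(CanedetError, ValueError):
    """A numeric argument lies outside the operation's domain."""
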