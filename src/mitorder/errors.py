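"""Exception hierarchy for mitorder."""


class MitorderError(Exception):
    """Base class for all mitorder errors."""


class UnknownGeneName(MitorderError):
    """A raw gene/product name could not be mapped to the canonical vocabulary."""

    def __init__(self, token: str, suggestions: list[str] | None = None):
        self.token = token
        self.suggestions = suggestions or []
        msg = f"unknown gene name: {token!r}"
        if self.suggestions:
            msg += f" (nearest synonyms: {', '.join(self.suggestions)})"
        super().__init__(msg)


class MissingAnchor(MitorderError):
    """No linearization anchor gene present in the arrangement."""


class EmptyFeatureTable(MitorderError):
    """GenBank record carries no usable gene features."""


class ArrangementTooShort(MitorderError):
    """Fewer than two elements remain after control-region handling."""


class GeneContentMismatch(MitorderError):
    """Two arrangements differ in gene content where equality is required."""

    def __init__(self, only_a: set, only_b: set):
        self.only_a = only_a
        self.only_b = only_b
        super().__init__(
            f"gene content differs: only in first={sorted(only_a)}, "
            f"only in second={sorted(only_b)}"
        )


class DuplicateTaxonId(MitorderError):
    """Same taxon id supplied twice where a unique id is required."""


class UnknownTaxon(MitorderError):
    """Taxon id absent from a catalogue or tree."""


class InvalidSegment(MitorderError):
    """Rearrangement event segment indices invalid for the arrangement."""


class OrderTableParseError(MitorderError):
    """Malformed line in a gene-order table."""

    def __init__(self, path, lineno: int, message: str):
        self.path = path
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")
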