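"""Exception hierarchy shared across the package."""


class MarkerScoreError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MarkerScoreError):
    """An endpoint definition, source config or run config is invalid."""


class ValidationError(MarkerScoreError):
    """Input data violates a structural contract (missing column, empty file...)."""


class AmbiguousSymbolError(MarkerScoreError):
    """A gene symbol matches more than one unified gene id."""

    def __init__(self, symbol: str, species: str, candidates: list[str]):
        self.symbol = symbol
        self.species = species
        self.candidates = sorted(candidates)
        super().__init__(
            f"symbol {symbol!r} ({species}) is ambiguous: matches gene_ids "
            f"{', '.join(self.candidates)}"
        )


class OntologyError(MarkerScoreError):
    """The cell ontology is malformed or a cell type id is unknown."""
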