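"""Exception hierarchy.

Exit codes used by the command-line layer map onto these classes so that
scripted pipelines can distinguish usage mistakes from data problems.
"""


class OmigraphError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(OmigraphError):
    """A schema, query, or design-table constraint was violated."""

    exit_code = 3


class ConversionError(OmigraphError):
    """Source data could not be lifted to RDF (bad row, bad GFF line...)."""

    exit_code = 3


class StoreError(OmigraphError):
    """Triplestore I/O or query-engine failure."""

    exit_code = 4


class ReproductionError(OmigraphError):
    """A reproduction suite observed a count different from its expectation."""

    exit_code = 5
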