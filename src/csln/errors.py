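"""Exception hierarchy.

``CSLNError`` is the root; the CLI maps :class:`DataError` subclasses to
exit code 2 and usage problems to exit code 1.
"""


class CSLNError(Exception):
    """Base class for all errors raised by this package."""


class DataError(CSLNError):
    """Malformed or inconsistent input data (files, vectors, networks)."""


class ParseError(DataError):
    """A file or string could not be parsed; carries location context."""


class UnscoreableTargetError(CSLNError):
    """Target has fewer than two member drugs after exclusion.

    The local-network mean similarity S1 averages over x(x-1)/2 member
    pairs, which is empty for x < 2, so such targets cannot be scored.
    """


class DegenerateLocalNetworkError(CSLNError):
    """All member pairs of a target have Tanimoto 0, so S1 = 0.

    The ratio S2/S1 is undefined; screening skips and reports such
    targets instead of producing an infinite score.
    """
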