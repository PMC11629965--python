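"""Exception hierarchy.

Three classes of failure are distinguished so that the command-line
interface can map them onto distinct exit codes: misuse of the API or
CLI (:class:`UsageError`), malformed input files (:class:`FormatError`),
and inputs that parse but are inconsistent with each other or with the
requested operation (:class:`DataError`).
"""


class TxsumError(Exception):
    """Base class for all txsum errors."""

    exit_code = 1


class UsageError(TxsumError):
    """Invalid combination of options or illegal call."""

    exit_code = 2


class FormatError(TxsumError):
    """An input file does not conform to its declared format."""

    exit_code = 3


class DataError(TxsumError):
    """Inputs are well-formed but mutually inconsistent or out of domain."""

    exit_code = 4
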