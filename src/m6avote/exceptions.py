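"""Exception hierarchy shared across the package."""


class M6aVoteError(Exception):
    """Base class for all package-specific errors."""


class FastaFormatError(M6aVoteError):
    """Malformed FASTA input (missing header or empty record)."""


class AlphabetError(M6aVoteError):
    """A residue outside the accepted RNA/DNA alphabet."""

    def __init__(self, seq_id: str, offset: int, char: str):
        self.seq_id = seq_id
        self.offset = offset  # 1-based
        self.char = char
        super().__init__(
            f"invalid residue {char!r} in sequence {seq_id!r} at offset {offset}"
        )


class SequenceTooShortError(M6aVoteError):
    """Sequence shorter than an operation requires."""


class InsufficientLengthError(SequenceTooShortError):
    """Sequence too short for the requested number of correlation tiers."""

    def __init__(self, length: int, lam: int):
        self.length = length
        self.lam = lam
        super().__init__(
            f"sequence of length {length} supports at most lambda={length - 2} "
            f"correlation tiers, got lambda={lam}"
        )


class DegeneratePropertyError(M6aVoteError):
    """A physicochemical property column with zero variance cannot be standardized."""


class ConfigError(M6aVoteError):
    """Inconsistent or out-of-range configuration."""


class TrainingError(M6aVoteError):
    """Training preconditions violated (e.g. a single-class fold)."""


class FoldError(M6aVoteError):
    """A cross-validation round lost one class entirely."""

    def __init__(self, round_index: int, message: str):
        self.round_index = round_index
        super().__init__(f"round {round_index}: {message}")
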