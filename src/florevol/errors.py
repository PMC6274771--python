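"""Exception hierarchy shared across the package."""


class FlorevolError(Exception):
    """Base class for package-specific failures."""


class FrameError(FlorevolError, ValueError):
    """CDS not translatable: length not a multiple of 3, or internal stop codon."""


class SaturationError(FlorevolError, ArithmeticError):
    """Substitution proportions too high for the Kimura two-parameter correction."""


class EmptyAlignmentError(FlorevolError, ValueError):
    """No comparable (ungapped) codon columns in a pairwise alignment."""


class UndefinedDistanceError(FlorevolError, ValueError):
    """No comparable columns for a sequence pair under the gap-deletion mode."""


class DegenerateInputError(FlorevolError, ValueError):
    """A statistic is undefined for the given input (e.g. zero variance)."""


class StateError(FlorevolError, RuntimeError):
    """Operation applied to data in the wrong state (e.g. double normalization)."""


class DependencyError(FlorevolError, RuntimeError):
    """A pipeline stage was run before the stage(s) it depends on."""

    def __init__(self, stage: str, missing: str):
        self.stage = stage
        self.missing = missing
        super().__init__(
            f"stage {stage!r} requires outputs of stage {missing!r}; run it first"
        )
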