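"""Exception hierarchy for the synapcover pipeline."""


class SynapcoverError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(SynapcoverError, ValueError):
    """A parameter violates its documented domain (e.g. non-positive area)."""


class PlacementError(SynapcoverError):
    """Puncta could not be placed on the membrane band without exceeding
    the maximum allowed crowding.

    Attributes
    ----------
    attempted : int
        Number of puncta the caller asked for.
    placed : int
        Number successfully placed before giving up.
    """

    def __init__(self, attempted: int, placed: int):
        self.attempted = attempted
        self.placed = placed
        super().__init__(
            f"could not place {attempted} puncta on the membrane band "
            f"(placed {placed}); reduce coverage or minimum separation"
        )


class DegenerateChannelError(SynapcoverError):
    """A channel is constant (or near-constant) and cannot be normalized;
    flagged downstream as a poor-contrast QC failure."""


class NoNeuronFoundError(SynapcoverError):
    """No connected component survived the minimum soma-area filter;
    maps to the 'incorrect neuron' QC deletion reason."""


class InvalidInputError(SynapcoverError, ValueError):
    """Input object missing a required channel or field."""


class InvalidPairingError(SynapcoverError, ValueError):
    """Neuron mask and puncta set do not come from images of the same shape."""


class UndefinedCorrelationError(SynapcoverError):
    """Correlation undefined (constant vector or too few complete pairs)."""


class CollinearityError(SynapcoverError):
    """Design matrix is rank deficient.

    Attributes
    ----------
    aliased : list[str]
        Names of the aliased (linearly dependent) columns.
    """

    def __init__(self, aliased):
        self.aliased = list(aliased)
        super().__init__(f"rank-deficient design; aliased terms: {self.aliased}")


class ConfigurationError(SynapcoverError, ValueError):
    """Invalid configuration (schema violation, infeasible correlation
    matrix, missing required keys).

    Attributes
    ----------
    keys : list[str]
        Offending configuration keys, when identifiable.
    """

    def __init__(self, message: str, keys=()):
        self.keys = list(keys)
        super().__init__(message if not self.keys else f"{message}: {self.keys}")


class MissingOutcomeError(SynapcoverError):
    """Outcome variable entirely absent for one of the contrasted groups."""


class CaseExcludedError(SynapcoverError):
    """A case has zero QC-passing neurons and is dropped from cohort tables."""


class EmptyInputError(SynapcoverError, ValueError):
    """An operation requiring a non-empty collection received an empty one."""
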