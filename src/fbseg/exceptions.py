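"""Exception types shared across fbseg modules."""


class FbsegError(Exception):
    """Base class for all fbseg-specific errors."""


class ConfigurationError(FbsegError, ValueError):
    """A layer stack, config file, or parameter set is internally inconsistent."""


class ShapeError(FbsegError, ValueError):
    """An input tensor does not match the shape a model or operation expects."""


class TrainingError(FbsegError, RuntimeError):
    """Training could not proceed (empty data, non-finite loss, ...)."""


class DegenerateRangeError(FbsegError, ValueError):
    """A min-max rescale or normalization was asked of a constant map."""


class GenerationError(FbsegError, RuntimeError):
    """Synthetic scene generation failed (e.g. infeasible lesion packing)."""


class SamplingError(FbsegError, ValueError):
    """A patch-sampling request exceeds the available pixels of a class."""


class GateBudgetError(FbsegError, ValueError):
    """Brute-force gate enumeration refused: too many optimizable gates."""
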