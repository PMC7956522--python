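"""Exception types shared across the pipeline stages."""


class ConfigurationError(ValueError):
    """A config object or argument combination is invalid."""


class DecompositionError(ValueError):
    """A signal is too short for the requested wavelet decomposition."""


class TrainingDivergedError(RuntimeError):
    """Training produced a non-finite loss.

    Carries the parameters from the end of the last completed epoch in
    ``last_good_params`` (``None`` if the first epoch diverged).
    """

    def __init__(self, message: str, last_good_params=None):
        super().__init__(message)
        self.last_good_params = last_good_params


class EmptyDatasetError(RuntimeError):
    """A pipeline stage was left with no usable data (names the stage)."""
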