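"""Exception hierarchy shared across the package."""


class FohrlearnError(Exception):
    """Base class for all package-specific errors."""


class DivergenceError(FohrlearnError):
    """A simulated state became non-finite.

    Attributes
    ----------
    step : int
        Index of the first step at which a non-finite value appeared.
    time : float
        Corresponding time on the integration grid.
    """

    def __init__(self, step: int, time: float):
        self.step = step
        self.time = time
        super().__init__(
            f"non-finite state encountered at step {step} (t = {time:g})"
        )


class InsufficientDataError(FohrlearnError):
    """Not enough events (spikes, bursts, samples) to support the analysis."""


class WeightDivergenceError(FohrlearnError):
    """Adaptive weights grew beyond the configured safety bound."""

    def __init__(self, norm: float, bound: float, time: float):
        self.norm = norm
        self.bound = bound
        self.time = time
        super().__init__(
            f"weight norm {norm:.3g} exceeded bound {bound:.3g} at t = {time:g}"
        )
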