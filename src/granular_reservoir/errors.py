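"""Package exceptions."""


class ConfigurationError(ValueError):
    """Invalid protocol, network, or experiment parameters."""


class NetworkInstabilityError(RuntimeError):
    """Raised when firing rates diverge during integration.

    Carries the time step at which the rate bound was exceeded so unstable
    runs can be reported (or excluded from replicate averages) instead of
    silently saturating.
    """

    def __init__(self, step: int, max_rate: float):
        self.step = int(step)
        self.max_rate = float(max_rate)
        super().__init__(
            f"firing rates exceeded bound at step {step} (max rate {max_rate:.3g})"
        )
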