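"""Exception types shared across the pipeline."""


class Ki67Error(Exception):
    """Base class for all package errors."""


class ConfigurationError(Ki67Error):
    """A slide or study specification violates its invariants."""


class GenerationError(Ki67Error):
    """Synthetic-data generation could not satisfy its constraints."""


class RegistrationFailedError(Ki67Error):
    """Serial-section alignment failed; the case is excluded from the VDS arm."""


class NoHotspotError(Ki67Error):
    """No candidate window satisfies the minimum-cell constraint."""
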