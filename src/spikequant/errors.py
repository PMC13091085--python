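"""Exception hierarchy shared across the package."""


class SpikeQuantError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SpikeQuantError):
    """A spike-in protocol or species specification is invalid."""


class ProfileError(SpikeQuantError):
    """A relative-abundance profile violates its invariants."""


class SpikeNotDetectedError(SpikeQuantError):
    """A spike-in taxon is absent (or at zero abundance) in a profile."""


class SpikeDominatesSampleError(SpikeQuantError):
    """Spike-in cells exceed the estimated total; the sample is degenerate."""


class QCFailureError(SpikeQuantError):
    """Quantification refused because the sample failed QC."""
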