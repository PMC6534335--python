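"""Exception hierarchy for wavemix.

All domain errors derive from :class:`WavemixError` so callers can catch
one base class at pipeline level while tests assert on the specific type.
"""


class WavemixError(Exception):
    """Base class for all wavemix domain errors."""


class InvalidBandError(WavemixError):
    """Requested frequency band is empty or violates the Nyquist limit."""


class TooShortError(WavemixError):
    """Signal too short for the requested operation (filter warm-up, window)."""


class NoCyclesError(WavemixError):
    """Fewer than two zero-crossings: no complete oscillation half-cycle."""


class EmptyAfterFilterError(WavemixError):
    """Amplitude-percentile filter removed every cycle.

    Carries the threshold that was applied, for diagnostics.
    """

    def __init__(self, threshold: float):
        self.threshold = threshold
        super().__init__(
            f"no cycles survive the amplitude filter (threshold={threshold:g})"
        )


class UndefinedStatisticError(WavemixError):
    """A statistic is undefined, e.g. no crests or no troughs retained."""


class UndefinedCorrelationError(WavemixError):
    """Correlation undefined because at least one input is constant."""


class NoPeakError(WavemixError):
    """No oscillatory spectral peak above the aperiodic background."""


class UnderdeterminedFitError(WavemixError):
    """Fewer usable fit points than model coefficients."""


class FormatError(WavemixError):
    """Corrupted or inconsistent serialized dataset."""


class ChannelMismatchError(WavemixError):
    """Recording channels do not match the channels a model was fit on."""
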