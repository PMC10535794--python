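"""Exception hierarchy shared across the pipeline stages."""


class TroutRiskError(Exception):
    """Base class for all package errors."""


class ValidationError(TroutRiskError):
    """A dataset row or value violates an invariant (named in the message)."""


class ConfigurationError(TroutRiskError):
    """A parameter registry or configuration is incomplete or inconsistent."""


class PairingError(TroutRiskError):
    """Replicates cannot be matched one-to-one across matrices."""


class EmptyGroupError(TroutRiskError):
    """A summary or test was requested on an empty group."""


class DegenerateDataError(TroutRiskError):
    """The data admit no test statistic (e.g. all differences exactly zero)."""
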