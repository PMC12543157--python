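"""Exception hierarchy shared across the pipeline stages."""


class MorbrulesError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MorbrulesError):
    """A configuration object or file is invalid."""


class InputError(MorbrulesError):
    """Input data violate a structural precondition (bad dates, codes, ids)."""
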