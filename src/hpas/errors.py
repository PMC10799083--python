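"""Exception hierarchy shared by all modules."""


class HpasError(Exception):
    """Base class for every error raised by this package."""


class ConfigurationError(HpasError):
    """A library/config entry is malformed (e.g. a SMARTS that does not parse)."""


class InvalidStructureError(HpasError):
    """A molecule violates a structural precondition (unsanitizable, non-cata, ...)."""


class ContractError(HpasError):
    """An operation was called with arguments outside its contract."""


class DeadEndError(HpasError):
    """A growth step produced no chemically valid product."""


class SchemaError(HpasError):
    """A data file does not match the expected column schema."""

    def __init__(self, missing: list[str]):
        self.missing = list(missing)
        super().__init__(f"missing required columns: {', '.join(self.missing)}")
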