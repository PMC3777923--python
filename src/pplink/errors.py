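class PPLinkError(Exception):
    """Base class for errors raised by pplink."""


class ParseError(PPLinkError):
    """A file could not be parsed; carries the offending line number when known."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
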