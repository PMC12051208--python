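"""Exception hierarchy for pslflex."""


class PslflexError(Exception):
    """Base class for all pslflex errors."""


class StructureError(PslflexError):
    """A structure file is unusable (e.g. contains no C-alpha atoms)."""


class FormatError(PslflexError):
    """A text input (STRIDE output, feature table) violates its format."""


class JoinError(PslflexError):
    """Structure and secondary-structure records cannot be aligned."""
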