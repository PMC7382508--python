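"""Exception hierarchy."""


class CGBindError(Exception):
    """Base class for all package-specific errors."""


class StructureParseError(CGBindError):
    """A structure or trajectory file could not be parsed."""


class TriclinicBoxError(CGBindError):
    """Only orthorhombic simulation boxes are supported."""


class SelectionError(CGBindError):
    """Invalid bead selection."""


class IntegrationError(CGBindError):
    """Brownian-dynamics integration is unstable or ill-posed."""
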