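"""Exception hierarchy shared by all craniomorph stages."""


class CraniomorphError(Exception):
    """Base class for all craniomorph errors."""


class MeshFormatError(CraniomorphError):
    """A mesh or landmark file could not be read or failed validation."""


class ParameterError(CraniomorphError):
    """A parameter is outside its documented range."""


class DegenerateInputError(CraniomorphError):
    """Input geometry or data is degenerate for the requested operation."""


class EmptyExteriorError(CraniomorphError):
    """No face is visible from the required number of viewpoints.

    Usually indicates inverted face winding or corrupt input geometry.
    """


class RegistrationError(CraniomorphError):
    """Non-rigid registration or correspondence matching failed."""


class ConfigError(CraniomorphError):
    """A pipeline configuration file failed schema validation."""
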