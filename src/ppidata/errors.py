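"""Exception hierarchy for the ppidata package."""


class PPIDataError(Exception):
    """Base class for all ppidata errors."""


class RegistrySchemaError(PPIDataError):
    """A registry source is missing a required column or key."""


class DuplicateIRIError(PPIDataError):
    """Two terms in a registry share the same IRI (or term name)."""


class UnknownCategoryError(PPIDataError):
    """A term declares a category outside the six defined categories."""


class TermNotFoundError(KeyError, PPIDataError):
    """A registry lookup key matched neither a term name nor an IRI."""


class UnsupportedFormatError(PPIDataError):
    """An unsupported serialization format token was requested."""


class DatasetContractError(PPIDataError):
    """An operation requiring a valid dataset received an invalid one."""


class ArchiveManifestError(PPIDataError):
    """A Darwin Core Archive lacks meta.xml or has an unusable manifest."""


class ArchiveSchemaError(PPIDataError):
    """An archive's core row type is not the Event class."""


class XMLSecurityError(PPIDataError):
    """An XML document declares a DTD or entities and was rejected."""


class RDFStructureError(PPIDataError):
    """A graph does not follow the occurrence/event/measurement mapping."""


class RDFSerializationError(PPIDataError):
    """A dataset cannot be mapped to triples (e.g. free-text-only relationship type)."""


class RoleResolutionError(PPIDataError):
    """A relationship's members could not be resolved to one plant and one animal."""
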