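"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`RhizonetError` so callers can catch
pipeline failures without swallowing programming errors.
"""


class RhizonetError(Exception):
    """Base class for all pipeline errors."""


class InvalidDesignError(RhizonetError, ValueError):
    """A simulation design or generator argument is out of range."""


class ConfigurationError(RhizonetError, ValueError):
    """An unknown preset, flag or configuration value was requested."""


class DimensionError(RhizonetError, ValueError):
    """Shapes or sample sets of two inputs do not match."""


class ValidationError(RhizonetError, ValueError):
    """An input object violates its contract (IDs, symmetry, labels)."""


class MissingTaxonError(ValidationError):
    """A taxon required by an operation is absent from the phylogeny."""


class InsufficientDataError(RhizonetError, ValueError):
    """Too few samples/taxa/edges for the requested statistic."""


class EmptyNetworkError(RhizonetError):
    """Thresholding produced a graph with no edges."""


class CannotRewireError(RhizonetError):
    """The graph admits no degree-preserving double-edge swap."""


class UndefinedTopologyError(RhizonetError):
    """Topology metrics requested on an empty network."""


class UndefinedVulnerabilityError(RhizonetError):
    """Vulnerability requested on a graph with zero global efficiency."""


class DegenerateFitError(RhizonetError, ValueError):
    """Regression requested on data with zero predictor variance."""


class NoUsableTaxaError(RhizonetError, ValueError):
    """All taxa were excluded (e.g. zero variance) from an index."""
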