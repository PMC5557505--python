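"""Exception hierarchy shared across the package."""


class PersimorphError(Exception):
    """Base class for all package errors."""


class ParseError(PersimorphError):
    """Malformed SWC line or non-finite coordinate."""


class MultipleRootsError(ParseError):
    """More than one record with parent -1 (and forest mode not requested)."""


class MissingParentError(ParseError):
    """A record references a parent id absent from the file."""


class CycleError(ParseError):
    """Parent pointers do not form an acyclic structure."""


class DegenerateTreeError(PersimorphError):
    """Synthetic growth collapsed to a single node."""


class MissingValueError(PersimorphError):
    """Descriptor value map does not cover every node."""


class NonFiniteValueError(PersimorphError):
    """Descriptor value map contains NaN or infinity."""


class DisconnectedTreeError(PersimorphError):
    """Operation requires a connected tree."""


class ConfigError(PersimorphError):
    """Invalid configuration (range, dimension, k, grid...)."""


class EmptyCollectionError(PersimorphError):
    """Operation requires at least one non-empty input."""


class DimensionMismatchError(PersimorphError):
    """Vectors of unequal length were combined or compared."""


class ConfigMismatchError(PersimorphError):
    """Persistence vectors built under different configs were compared."""


class GridMismatchError(PersimorphError):
    """Sholl profiles on different radius grids were compared."""


class MissingFeatureError(PersimorphError):
    """An L-Measure vector lacks a feature present in the collection."""


class OrderMismatchError(PersimorphError):
    """Distance matrices with different neuron orderings were combined."""


class NonPositiveRadiusError(PersimorphError):
    """Sholl radius must be strictly positive."""


class DisconnectedGraphError(PersimorphError):
    """k-NN graph for the eigenmap is not connected."""
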