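"""Exception hierarchy for ginpipe."""


class GinpipeError(Exception):
    """Base class for all ginpipe errors."""


class CapacityError(GinpipeError):
    """Requested more genes than the plate format can hold."""


class DegeneratePlateError(GinpipeError):
    """Plate unusable for normalization (all-zero or mostly empty)."""


class LayoutError(GinpipeError):
    """Paired plates do not share a position -> gene map."""


class DegenerateDistributionError(GinpipeError):
    """Zero spread: Z-scores undefined."""


class EmptyNetworkError(GinpipeError):
    """Network construction produced no usable nodes/edges."""


class UndefinedModularityError(GinpipeError):
    """Modularity undefined (graph has no edge weight)."""
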