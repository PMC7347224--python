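"""Exception hierarchy shared by all layervis modules."""


class LayervisError(Exception):
    """Base class for all package errors."""


class ValidationError(LayervisError):
    """Input data violates a documented invariant (shape, sign, range, duplicates)."""


class MalformedLabelError(ValidationError):
    """A sample label does not parse to a (treatment, replicate) pair."""


class DesignError(ValidationError):
    """The sample design is unusable (e.g. fewer than two treatments)."""


class UnknownIdError(LayervisError, KeyError):
    """A gene id, hexagon id, panel, metric or treatment was not found."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return Exception.__str__(self)


class ConfigError(LayervisError):
    """A run configuration is internally inconsistent or out of range."""


class IteratorExhausted(LayervisError):
    """Signal that a gene iterator has stepped past its last gene.

    Deliberately not a crash: callers stepping through a metric-ordered gene
    list catch this to know the tour is over; the figure is left unchanged.
    """
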