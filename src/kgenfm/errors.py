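"""Exception hierarchy shared across the package."""


class KgenfmError(Exception):
    """Base class for package errors."""


class ParseError(KgenfmError):
    """Malformed input file (carries the offending line number where known)."""


class LookupEntityError(KgenfmError, KeyError):
    """An entity or relation id is unknown to the object being queried."""

    def __str__(self) -> str:  # KeyError quotes its payload; keep the message readable
        return Exception.__str__(self)


class DimensionError(KgenfmError, ValueError):
    """Vector/matrix shapes do not chain."""


class ConfigError(KgenfmError, ValueError):
    """Invalid configuration value."""


class FeaturizationError(KgenfmError):
    """A drug or protein could not be featurized (names the entity/position)."""


class SamplingError(KgenfmError):
    """Negative/corruption sampling is impossible for the given universe."""


class TrainingDivergedError(KgenfmError):
    """Non-finite loss during optimization (names the epoch)."""


class TrainingSetupError(KgenfmError, ValueError):
    """Training inputs violate a precondition (e.g. single-class labels)."""


class MetricError(KgenfmError, ValueError):
    """A metric is undefined for the given labels."""


class ColdEntityError(KgenfmError, KeyError):
    """A pair references an entity absent from the knowledge graph embeddings.

    Scope rule: cold-start drugs/proteins must still exist in the KG (they lack
    DTI edges, not heterogeneous information); an entity missing from the KG
    altogether is outside the method's scope.
    """

    def __str__(self) -> str:
        return Exception.__str__(self)
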