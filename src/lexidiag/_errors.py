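"""Exception hierarchy shared across the package."""


class LexidiagError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(LexidiagError):
    """An object was configured with mutually incompatible or invalid fields."""


class GenerationExhaustedError(LexidiagError):
    """The pseudoword sampler could not produce the requested items within
    its rejection budget (the bigram graph admits too few chains)."""


class UnsegmentableTextError(LexidiagError):
    """A grapheme cluster is longer than the available segment capacity, so
    the text cannot be split without breaking the cluster."""

    def __init__(self, cluster: str, capacity: int):
        self.cluster = cluster
        self.capacity = capacity
        super().__init__(
            f"cluster {cluster!r} (length {len(cluster)}) cannot fit into "
            f"segments of capacity {capacity}"
        )


class SessionAbortedError(LexidiagError):
    """A diagnostic session ended prematurely; the partial trial log is
    preserved on the ``trial_log`` attribute."""

    def __init__(self, message: str, trial_log=None):
        super().__init__(message)
        self.trial_log = list(trial_log or [])


class NonMonotoneOracleError(LexidiagError):
    """An outcome oracle violated monotonicity (meeting an extra condition
    turned a pass into a fail); carries the violating subset pair."""

    def __init__(self, smaller, larger):
        self.smaller = frozenset(smaller)
        self.larger = frozenset(larger)
        super().__init__(
            f"oracle passes on {sorted(self.smaller)} but fails on the "
            f"superset {sorted(self.larger)}"
        )


class NonCanonicalClassificationError(LexidiagError):
    """Cause attribution was requested from a classification that is not in
    canonical conjunctive form."""
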