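"""Exception types shared across the pipeline."""


class InvalidConfigError(ValueError):
    """A configuration value is outside its documented range."""


class SchemaError(ValueError):
    """An input table or matrix violates its schema."""


class DisconnectedTemplateError(RuntimeError):
    """The thresholded connectome is not a single connected component."""

    def __init__(self, components):
        self.components = components
        super().__init__(
            f"disconnected-template: {len(components)} components "
            f"(sizes {[len(c) for c in components]})"
        )


class ExcludedParcelError(RuntimeError):
    """A probability was requested from a parcel excluded by the mixture fit."""


class RankDeficientError(ValueError):
    """A regression design matrix is rank deficient."""

    def __init__(self, aliased):
        self.aliased = list(aliased)
        super().__init__(f"rank-deficient design; aliased terms: {self.aliased}")
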