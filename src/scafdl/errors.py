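"""Exception types shared across the package."""


class DegenerateInputError(ValueError):
    """An input is structurally valid but too degenerate to process
    (e.g. an empty foreground mask, a foreground too small to host a
    fracture line)."""


class UndefinedMetricError(ValueError):
    """A metric is requested on data for which it is undefined
    (e.g. AUROC with a single class present)."""
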