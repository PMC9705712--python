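"""Exception types shared across the pipeline."""


class SeedtaxError(Exception):
    """Base class for pipeline errors."""


class NoForegroundError(SeedtaxError, ValueError):
    """An image or mask contains no usable foreground object."""


class RenderBoundsError(SeedtaxError, ValueError):
    """A requested seed geometry cannot fit inside the image frame."""


class AmbiguousShapeError(SeedtaxError, ValueError):
    """A mask's skeleton does not reduce to a single two-ended path."""


class InvalidPlanError(SeedtaxError, ValueError):
    """An augmentation plan violates the fixed family cardinalities."""


class LeakageError(SeedtaxError, ValueError):
    """A test-partition image was offered to a training-only stage."""
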