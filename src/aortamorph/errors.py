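"""Exceptions raised by the morphometry pipeline."""


class AortaMorphError(Exception):
    """Base class for all package-specific errors."""


class LabelValidationError(AortaMorphError):
    """A label volume contains voxel codes outside the declared label map."""

    def __init__(self, bad_codes):
        self.bad_codes = sorted(int(c) for c in bad_codes)
        super().__init__(
            f"voxel values outside the declared label map: {set(self.bad_codes)}"
        )


class DisconnectedMaskError(AortaMorphError):
    """The aortic mask splits into several large connected components."""

    def __init__(self, sizes):
        self.sizes = sorted(int(s) for s in sizes)
        super().__init__(
            f"union mask has {len(self.sizes)} large 6-connected components "
            f"(voxel counts: {self.sizes}); expected a single aorta"
        )


class MaskTooThinError(AortaMorphError):
    """The mask is too thin to skeletonise into a usable path."""


class PlaneExtentError(AortaMorphError):
    """An orthogonal cross-section exceeds the sampling plane extent."""


class PerfectSeparationError(AortaMorphError):
    """A marker perfectly separates the outcome groups; the logistic
    likelihood-ratio statistic is unbounded."""
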