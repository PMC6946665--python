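"""Exception hierarchy for ringmelt."""


class RingmeltError(Exception):
    """Base class for all ringmelt errors."""


class GeometryError(RingmeltError):
    """Invalid or ill-conditioned geometry (non-positive distance,
    touching contours, non-closed ring, ...)."""


class OverstretchedBondError(RingmeltError):
    """A FENE bond reached r_max during integration.

    The simulation aborts because a bond at r_max signals imminent chain
    crossing, which would silently corrupt the topological invariants.
    """

    def __init__(self, message, last_state=None, step=None):
        super().__init__(message)
        self.last_state = last_state
        self.step = step


class BuilderError(RingmeltError):
    """Melt construction failed (overlap resolution or topology gate)."""


class ConcatenationAnomalyError(RingmeltError):
    """A piercing pattern inconsistent with nonconcatenated rings
    (odd piercing count or nonzero signed crossing sum)."""


class ConfigMismatchError(RingmeltError):
    """Files produced under different configurations were mixed."""
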