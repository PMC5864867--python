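"""Physical scale of the emulated recordings.

The imaging geometry is fixed by the acquisition setup: a 768×576 px 8-bit
sensor at 0.833 µm per pixel, 50 frames per second, 25-frame sequences.
"""

from __future__ import annotations

__all__ = ["PIXEL_SIZE_UM", "FRAME_RATE_FPS", "um_to_px", "px_to_um"]

#: Pixel pitch of the recordings, micrometres per pixel.
PIXEL_SIZE_UM = 0.833
#: Acquisition rate, frames per second.
FRAME_RATE_FPS = 50.0


def um_to_px(um: float) -> float:
    """Convert a length in micrometres to pixels."""
    return um / PIXEL_SIZE_UM


def px_to_um(px: float) -> float:
    """Convert a length in pixels to micrometres."""
    return px * PIXEL_SIZE_UM
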