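"""Chromatin-state labels for putative enhancer regions."""

from __future__ import annotations

from enum import Enum

__all__ = ["State", "NAMED_STATES", "MARKS_BY_STATE"]


class State(str, Enum):
    """Chromatin state of a putative enhancer region.

    The five named states follow the presence/absence patterns of
    H3K4me1, H3K27ac and H3K27me3 across replicates; UNCLASSIFIED
    collects every other pattern, and LATENT marks a region carrying no
    mark at all in a given cellular context (used when tracking state
    dynamics across tissues).
    """

    ACTIVE = "active"
    BIVALENT = "bivalent"
    K4ME1_ONLY = "h3k4me1_only"
    K27AC_ONLY = "h3k27ac_only"
    K27ME3_ONLY = "h3k27me3_only"
    UNCLASSIFIED = "unclassified"
    LATENT = "latent"

    @classmethod
    def parse(cls, text: str) -> "State":
        return cls(text.strip().lower())


#: The five classified enhancer states (excludes unclassified/latent).
NAMED_STATES = (
    State.ACTIVE,
    State.BIVALENT,
    State.K4ME1_ONLY,
    State.K27AC_ONLY,
    State.K27ME3_ONLY,
)

#: True mark content implied by each state (used by the simulator).
MARKS_BY_STATE: dict[State, tuple[str, ...]] = {
    State.ACTIVE: ("H3K4me1", "H3K27ac"),
    State.BIVALENT: ("H3K4me1", "H3K27me3"),
    State.K4ME1_ONLY: ("H3K4me1",),
    State.K27AC_ONLY: ("H3K27ac",),
    State.K27ME3_ONLY: ("H3K27me3",),
    State.LATENT: (),
}
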