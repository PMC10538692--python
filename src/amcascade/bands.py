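"""Band definitions for the phonological amplitude-modulation hierarchy.

Speech rhythm is organised as nested amplitude modulation (AM): a prosodic
rhythm at 1-4 Hz, a syllabic rhythm at 4-12 Hz and a phonetic rhythm at
12-40 Hz, all riding on a carrier above 40 Hz.  Content below 1 Hz
(sentence-level rhythm) is kept as a separate band but excluded from the
rhythm summaries.
"""

from __future__ import annotations

from typing import NamedTuple


class Band(NamedTuple):
    name: str
    lo_hz: float
    hi_hz: float


#: The four hierarchy levels, slow to fast.  Edges are fixed at 1/4/12/40 Hz.
HIERARCHY_BANDS: tuple[Band, ...] = (
    Band("low_delta", 0.0, 1.0),
    Band("delta", 1.0, 4.0),
    Band("theta_alpha", 4.0, 12.0),
    Band("beta_gamma", 12.0, 40.0),
)

#: Rhythm names used in feature tables, mapped to the band carrying them.
RHYTHM_TO_BAND: dict[str, str] = {
    "prosody": "delta",
    "syllable": "theta_alpha",
    "phoneme": "beta_gamma",
}

BAND_TO_RHYTHM: dict[str, str] = {v: k for k, v in RHYTHM_TO_BAND.items()}

#: Ordered band pairs analysed for directed coupling, slow member first.
TE_PAIRS: tuple[tuple[str, str], ...] = (
    ("prosody", "syllable"),
    ("prosody", "phoneme"),
    ("syllable", "phoneme"),
)

#: Carrier cutoff: everything above this is "carrier", not rhythm.
CARRIER_CUTOFF_HZ = 40.0

BAND_BY_NAME: dict[str, Band] = {b.name: b for b in HIERARCHY_BANDS}

#: Order index for deciding top-down (slower -> faster) vs bottom-up.
BAND_ORDER: dict[str, int] = {b.name: i for i, b in enumerate(HIERARCHY_BANDS)}


def band_of_rhythm(rhythm: str) -> Band:
    """Return the (name, lo, hi) band carrying a named rhythm."""
    try:
        return BAND_BY_NAME[RHYTHM_TO_BAND[rhythm]]
    except KeyError:
        raise ValueError(f"unknown rhythm {rhythm!r}") from None
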