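"""ARPAbet phoneme inventory and phonetic attribute lookup.

Five attributes describe each phone: manner of articulation, place of
articulation, voicing, vowel height (high/low) and vowel backness
(front/back).  Attributes that do not apply to a segment class (e.g. place
for vowels, height for consonants) carry the sentinel value ``"na"`` and
are excluded from attribute-restricted analyses.
"""

from __future__ import annotations

NA = "na"

ATTRIBUTE_COLUMNS = ("manner", "place", "voicing", "height", "backness")

# label -> (manner, place, voicing, height, backness)
_VOWELS = {
    # monophthongs
    "AA": ("low", "back"),
    "AE": ("low", "front"),
    "AH": ("mid", "central"),
    "AO": ("mid", "back"),
    "EH": ("mid", "front"),
    "ER": ("mid", "central"),
    "IH": ("high", "front"),
    "IY": ("high", "front"),
    "UH": ("high", "back"),
    "UW": ("high", "back"),
    # diphthongs, classified by their nucleus
    "AW": ("low", "back"),
    "AY": ("low", "central"),
    "EY": ("mid", "front"),
    "OW": ("mid", "back"),
    "OY": ("mid", "back"),
}

_CONSONANTS = {
    # label: (manner, place, voiced)
    "P": ("plosive", "bilabial", False),
    "B": ("plosive", "bilabial", True),
    "T": ("plosive", "alveolar", False),
    "D": ("plosive", "alveolar", True),
    "K": ("plosive", "velar", False),
    "G": ("plosive", "velar", True),
    "CH": ("affricate", "postalveolar", False),
    "JH": ("affricate", "postalveolar", True),
    "F": ("fricative", "labiodental", False),
    "V": ("fricative", "labiodental", True),
    "TH": ("fricative", "dental", False),
    "DH": ("fricative", "dental", True),
    "S": ("fricative", "alveolar", False),
    "Z": ("fricative", "alveolar", True),
    "SH": ("fricative", "postalveolar", False),
    "ZH": ("fricative", "postalveolar", True),
    "HH": ("fricative", "glottal", False),
    "M": ("nasal", "bilabial", True),
    "N": ("nasal", "alveolar", True),
    "NG": ("nasal", "velar", True),
    "L": ("approximant", "alveolar", True),
    "R": ("approximant", "alveolar", True),
    "W": ("approximant", "velar", True),
    "Y": ("approximant", "palatal", True),
}


def _build() -> dict[str, dict[str, str]]:
    table: dict[str, dict[str, str]] = {}
    for label, (height, backness) in _VOWELS.items():
        table[label] = {
            "manner": "vowel",
            "place": NA,
            "voicing": "voiced",
            "height": height,
            "backness": backness,
        }
    for label, (manner, place, voiced) in _CONSONANTS.items():
        table[label] = {
            "manner": manner,
            "place": place,
            "voicing": "voiced" if voiced else "unvoiced",
            "height": NA,
            "backness": NA,
        }
    return table


PHONEME_ATTRIBUTES: dict[str, dict[str, str]] = _build()
PHONEMES: tuple[str, ...] = tuple(sorted(PHONEME_ATTRIBUTES))


def attributes_of(label: str) -> dict[str, str]:
    """Return the five phonetic attributes of an ARPAbet label."""
    try:
        return dict(PHONEME_ATTRIBUTES[label])
    except KeyError:
        raise KeyError(f"unknown ARPAbet label: {label!r}") from None
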