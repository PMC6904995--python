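"""Discrete property alphabets used to encode residue windows.

Every residue of a window is described on five parallel tracks: the amino
acid itself, its polarization-charge class, its hydropathy class, the
predicted secondary-structure state, and the dichotomized relative solvent
accessibility (RSA).  Each track has a small symbol alphabet whose last
symbol is always the dummy ``'X'`` so that chain-terminal padding is
representable on every track.

The charge and hydropathy groupings are fixed class maps over the 20
standard amino acids.  Note two deliberate oddities kept exactly as the
method defines them: proline (P) counts as positively charged and
histidine (H) as uncharged, and the hydropathy class labels are treated
as opaque group names (the grouping, not the naming, is what the encoder
uses).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import yaml

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
DUMMY = "X"

#: Residue -> polarization-charge class.  'p' = positively charged (K, R, P),
#: 'n' = negatively charged (D, E), 'u' = uncharged (the remaining 15).
CHARGE_CLASSES: Mapping[str, str] = {
    "p": "KRP",
    "n": "DE",
    "u": "NQHLIVAMFSTYWCG",
}

#: Hydropathy grouping into six classes; labels '1'..'6' are opaque group
#: names for {R,D,E,N,Q,K,H}, {L,I,V,A,M,F}, {S,T,Y,W}, {P}, {G}, {C}.
HYDRO_CLASSES: Mapping[str, str] = {
    "1": "RDENQKH",
    "2": "LIVAMF",
    "3": "STYW",
    "4": "P",
    "5": "G",
    "6": "C",
}

SS_STATES = "HEC"  # alpha-helix, beta-strand, coil

#: RSA threshold: exposed iff RSA > 25%.  Exactly 0.25 is classed buried.
RSA_THRESHOLD = 0.25


@dataclass(frozen=True)
class TrackAlphabet:
    """An ordered symbol alphabet for one track; the dummy 'X' is last."""

    name: str
    symbols: tuple

    def __post_init__(self):
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError(f"duplicate symbols in alphabet {self.name!r}")
        if self.symbols.count(DUMMY) != 1 or self.symbols[-1] != DUMMY:
            raise ValueError(f"alphabet {self.name!r} must end with a single 'X'")
        object.__setattr__(self, "_index", {s: i for i, s in enumerate(self.symbols)})

    @property
    def size(self) -> int:
        """Symbol count A, including the dummy."""
        return len(self.symbols)

    def index(self, symbol: str) -> int:
        try:
            return self._index[symbol]
        except KeyError:
            raise ValueError(
                f"symbol {symbol!r} not in {self.name} alphabet {self.symbols}"
            ) from None

    def encode(self, window: str) -> list:
        return [self.index(s) for s in window]


ALPHABETS: Mapping[str, TrackAlphabet] = {
    "amino": TrackAlphabet("amino", tuple(AMINO_ACIDS) + (DUMMY,)),
    "charge": TrackAlphabet("charge", ("p", "n", "u", DUMMY)),
    "hydro": TrackAlphabet("hydro", tuple("123456") + (DUMMY,)),
    "ss": TrackAlphabet("ss", tuple(SS_STATES) + (DUMMY,)),
    "rsa": TrackAlphabet("rsa", ("e", "b", DUMMY)),
}

#: Fixed track order used everywhere features are concatenated.
TRACKS = ("amino", "charge", "hydro", "ss", "rsa")

_CHARGE_OF = {aa: cls for cls, aas in CHARGE_CLASSES.items() for aa in aas}
_HYDRO_OF = {aa: cls for cls, aas in HYDRO_CLASSES.items() for aa in aas}


def _check_partition(mapping: Mapping[str, str], name: str) -> None:
    covered = "".join(mapping.values())
    if sorted(covered) != sorted(AMINO_ACIDS):
        raise AssertionError(f"{name} classes do not partition the 20 amino acids")


_check_partition(CHARGE_CLASSES, "charge")
_check_partition(HYDRO_CLASSES, "hydropathy")


def charge_class(residue: str) -> str:
    """Polarization-charge class of a residue ('p'/'n'/'u', 'X' for dummy)."""
    if residue == DUMMY:
        return DUMMY
    try:
        return _CHARGE_OF[residue]
    except KeyError:
        raise ValueError(f"unknown residue {residue!r}") from None


def hydro_class(residue: str) -> str:
    """Hydropathy class ('1'..'6', 'X' for dummy)."""
    if residue == DUMMY:
        return DUMMY
    try:
        return _HYDRO_OF[residue]
    except KeyError:
        raise ValueError(f"unknown residue {residue!r}") from None


def rsa_class(rsa_value: float) -> str:
    """Dichotomize relative solvent accessibility: 'e'(xposed) iff RSA > 0.25."""
    if not 0.0 <= rsa_value <= 1.0:
        raise ValueError(f"RSA value {rsa_value} outside [0, 1]")
    return "e" if rsa_value > RSA_THRESHOLD else "b"


def encode_tracks(
    window: str,
    ss_window: str,
    rsa_window: Sequence[Optional[float]],
) -> dict:
    """Encode one residue window into the five track strings.

    ``rsa_window`` holds one RSA fraction per position, with ``None`` at
    padded positions.  A dummy 'X' in the residue window stays 'X' on every
    derived track.
    """
    if not (len(window) == len(ss_window) == len(rsa_window)):
        raise ValueError("window, ss_window and rsa_window lengths differ")
    charge = []
    hydro = []
    rsa = []
    for aa, ss, rv in zip(window, ss_window, rsa_window):
        if ss not in "HEC" + DUMMY:
            raise ValueError(f"secondary-structure symbol {ss!r} not in {{H,E,C,X}}")
        charge.append(charge_class(aa))
        hydro.append(hydro_class(aa))
        rsa.append(DUMMY if rv is None else rsa_class(rv))
    return {
        "amino": window,
        "charge": "".join(charge),
        "hydro": "".join(hydro),
        "ss": ss_window,
        "rsa": "".join(rsa),
    }


def dump_class_maps(path) -> None:
    """Write the residue class maps and alphabets to YAML for auditing."""
    payload = {
        "charge_classes": {k: list(v) for k, v in CHARGE_CLASSES.items()},
        "hydropathy_classes": {k: list(v) for k, v in HYDRO_CLASSES.items()},
        "rsa_threshold": RSA_THRESHOLD,
        "alphabets": {n: list(a.symbols) for n, a in ALPHABETS.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
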