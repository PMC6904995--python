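"""Sliding-window segmentation of padded chains.

Every residue becomes the center of exactly one window of odd length L;
(L-1)/2 dummy 'X' residues are appended to both chain ends so terminal
residues get full windows.  A segment is positive iff its center residue
is annotated as binding the ligand under study.  All five property tracks
are padded with their own 'X' and cut on the same grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence

import pandas as pd

from .alphabets import DUMMY, charge_class, hydro_class, rsa_class
from .io import ProteinRecord

#: Default window-length grid swept during window selection.
WINDOW_GRID = (5, 7, 9, 11, 13, 15, 17)


def _check_window_length(length: int) -> int:
    if length % 2 == 0 or length < 3:
        raise ValueError(f"window length must be odd and >= 3, got {length}")
    return (length - 1) // 2


def pad_sequence(sequence: str, length: int) -> str:
    """Append (L-1)/2 dummy 'X' residues to both ends."""
    half = _check_window_length(length)
    return DUMMY * half + sequence + DUMMY * half


@dataclass(frozen=True)
class Segment:
    """One fixed-length window centered on a residue."""

    chain_id: str
    center_index: int  # 0-based residue index in the unpadded chain
    window: str        # amino-acid window, may contain 'X' padding
    positive: bool
    track_windows: Dict[str, str]

    @property
    def label(self) -> str:
        return "positive" if self.positive else "negative"


def extract_segments(record: ProteinRecord, ligand_code: str,
                     length: int) -> List[Segment]:
    """One segment per residue of the chain, labelled from the binding mask.

    A ligand with no annotation on this chain yields all-negative segments.
    """
    half = _check_window_length(length)
    n = len(record)
    pad = DUMMY * half

    amino = pad + record.sequence + pad
    charge = pad + "".join(charge_class(a) for a in record.sequence) + pad
    hydro = pad + "".join(hydro_class(a) for a in record.sequence) + pad
    ss = pad + record.ss_track + pad
    rsa = pad + "".join(rsa_class(v) for v in record.rsa_track) + pad

    mask = record.binding.get(ligand_code)
    segments = []
    for i in range(n):
        segments.append(
            Segment(
                chain_id=record.chain_id,
                center_index=i,
                window=amino[i:i + length],
                positive=bool(mask[i]) if mask is not None else False,
                track_windows={
                    "amino": amino[i:i + length],
                    "charge": charge[i:i + length],
                    "hydro": hydro[i:i + length],
                    "ss": ss[i:i + length],
                    "rsa": rsa[i:i + length],
                },
            )
        )
    return segments


def segments_from_records(records: Iterable[ProteinRecord], ligand_code: str,
                          length: int) -> List[Segment]:
    """Concatenate segments over all chains (chain order preserved)."""
    out: List[Segment] = []
    for rec in records:
        out.extend(extract_segments(rec, ligand_code, length))
    return out


def dataset_summary(records: Sequence[ProteinRecord], ligand_code: str,
                    length: int) -> dict:
    """Chains / positive segments / negative segments, benchmark-table style."""
    segs = segments_from_records(records, ligand_code, length)
    pos = sum(s.positive for s in segs)
    return {
        "ligand": ligand_code,
        "chains": len(records),
        "positive_segments": pos,
        "negative_segments": len(segs) - pos,
    }


def write_segment_table(segments: Iterable[Segment], path) -> None:
    """TSV: chain, 1-based center position, label, and the five windows."""
    rows = [
        {
            "chain_id": s.chain_id,
            "position": s.center_index + 1,
            "label": s.label,
            **{f"window_{t}": w for t, w in s.track_windows.items()},
        }
        for s in segments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
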