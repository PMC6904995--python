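"""Reading and writing the plain-text formats the pipeline touches.

Formats:
  * FASTA chain sequences (via Bio.SeqIO);
  * binding annotations, BioLip-style TSV:
    ``pdb_id<TAB>chain<TAB>ligand_code<TAB>pos1,pos2,...`` with 1-based
    residue positions;
  * per-chain secondary-structure tracks: ``chain_id<TAB>HECC...``;
  * per-chain RSA tracks: ``chain_id<TAB>0.12,0.80,...``;
  * chain metadata: ``chain_id<TAB>resolution``.

Annotation positions are 1-based on disk (BioLip convention) and converted
to 0-based masks at assembly; nothing downstream sees 1-based indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from Bio import SeqIO

from .alphabets import AMINO_ACIDS, DUMMY

logger = logging.getLogger(__name__)

_VALID = set(AMINO_ACIDS) | {DUMMY}


def sanitize_sequence(seq: str) -> str:
    """Uppercase and map anything outside the 20 standard residues to 'X'."""
    up = seq.upper()
    return "".join(c if c in _VALID else DUMMY for c in up)


@dataclass
class ProteinRecord:
    """One protein chain with aligned per-residue tracks and annotations."""

    chain_id: str
    sequence: str
    binding: Dict[str, np.ndarray]  # ligand code -> boolean mask, 0-based
    ss_track: str
    rsa_track: np.ndarray
    resolution: Optional[float] = None

    def __post_init__(self):
        self.sequence = sanitize_sequence(self.sequence)
        n = len(self.sequence)
        if len(self.ss_track) != n:
            raise ValueError(f"{self.chain_id}: SS track length != sequence length")
        if set(self.ss_track) - set("HECX"):
            raise ValueError(f"{self.chain_id}: SS track has symbols outside HECX")
        self.rsa_track = np.asarray(self.rsa_track, dtype=float)
        if self.rsa_track.shape != (n,):
            raise ValueError(f"{self.chain_id}: RSA track length != sequence length")
        if np.any((self.rsa_track < 0) | (self.rsa_track > 1)):
            raise ValueError(f"{self.chain_id}: RSA values outside [0, 1]")
        for lig, mask in self.binding.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != (n,):
                raise ValueError(
                    f"{self.chain_id}: binding mask for {lig} length != sequence"
                )
            self.binding[lig] = mask

    @property
    def ligand_codes(self) -> Set[str]:
        return set(self.binding)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DatasetFilters:
    """Chain-level inclusion predicates applied before windowing."""

    max_resolution: float = 3.0   # keep iff resolution < this, strictly
    min_length: int = 50          # keep iff length > this, strictly
    identity_representatives: Optional[Sequence[str]] = None

    def __post_init__(self):
        if self.max_resolution <= 0:
            raise ValueError("max_resolution must be positive")
        if self.min_length <= 0:
            raise ValueError("min_length must be positive")


def read_fasta(path) -> List[Tuple[str, str]]:
    """Parse FASTA into (chain_id, sanitized sequence) pairs."""
    entries: List[Tuple[str, str]] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        entries.append((rec.id, sanitize_sequence(str(rec.seq))))
    if not entries:
        raise ValueError(f"no FASTA records found in {path}")
    return entries


def read_binding_annotations(path, ligand_code: str) -> Dict[str, Set[int]]:
    """Binding positions (1-based) per chain for one ligand code.

    Rows for other ligands are skipped; repeated rows for the same chain
    union their position sets.
    """
    result: Dict[str, Set[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields")
            pdb_id, chain, lig, pos_field = parts
            if lig != ligand_code:
                continue
            positions = set()
            for tok in pos_field.split(","):
                tok = tok.strip()
                if not tok.isdigit():
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric position {tok!r}"
                    )
                positions.add(int(tok))
            result.setdefault(f"{pdb_id}_{chain}", set()).update(positions)
    return result


def write_binding_annotations(path, annotations: Dict[str, Set[int]],
                              ligand_code: str) -> None:
    """Inverse of read_binding_annotations (chain ids as ``pdb_chain``)."""
    with open(path, "w") as fh:
        for chain_id in sorted(annotations):
            pdb_id, _, chain = chain_id.rpartition("_")
            positions = ",".join(str(p) for p in sorted(annotations[chain_id]))
            fh.write(f"{pdb_id}\t{chain}\t{ligand_code}\t{positions}\n")


def read_ss_tracks(path) -> Dict[str, str]:
    """Per-chain secondary-structure strings over {H, E, C}."""
    tracks: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            chain_id, _, track = line.partition("\t")
            if not track:
                raise ValueError(f"{path}:{lineno}: missing track column")
            tracks[chain_id] = track
    return tracks


def read_rsa_tracks(path) -> Dict[str, np.ndarray]:
    """Per-chain RSA fractions in [0, 1], comma separated."""
    tracks: Dict[str, np.ndarray] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            chain_id, _, values = line.partition("\t")
            try:
                tracks[chain_id] = np.asarray(
                    [float(v) for v in values.split(",")], dtype=float
                )
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed RSA values") from None
    return tracks


def read_metadata(path) -> Dict[str, float]:
    """Per-chain resolution in angstroms."""
    meta: Dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            chain_id, _, res = line.partition("\t")
            meta[chain_id] = float(res)
    return meta


def write_tracks(path_ss, path_rsa, records: Iterable[ProteinRecord]) -> None:
    with open(path_ss, "w") as fs, open(path_rsa, "w") as fr:
        for rec in records:
            fs.write(f"{rec.chain_id}\t{rec.ss_track}\n")
            fr.write(
                f"{rec.chain_id}\t" + ",".join(f"{v:.4f}" for v in rec.rsa_track) + "\n"
            )


def assemble_records(
    fasta_entries: Sequence[Tuple[str, str]],
    annotations: Dict[str, Set[int]],
    ligand_code: str,
    ss_tracks: Dict[str, str],
    rsa_tracks: Dict[str, np.ndarray],
    metadata: Optional[Dict[str, float]] = None,
) -> List[ProteinRecord]:
    """Join sequences, tracks and 1-based annotations into records.

    Chains missing an SS or RSA track raise an error listing the ids.
    """
    missing = [cid for cid, _ in fasta_entries
               if cid not in ss_tracks or cid not in rsa_tracks]
    if missing:
        raise ValueError(f"chains missing SS/RSA tracks: {', '.join(missing)}")
    records = []
    for chain_id, seq in fasta_entries:
        mask = np.zeros(len(seq), dtype=bool)
        for pos in annotations.get(chain_id, ()):  # 1-based on disk
            if not 1 <= pos <= len(seq):
                raise ValueError(
                    f"{chain_id}: binding position {pos} beyond chain length {len(seq)}"
                )
            mask[pos - 1] = True
        records.append(
            ProteinRecord(
                chain_id=chain_id,
                sequence=seq,
                binding={ligand_code: mask},
                ss_track=ss_tracks[chain_id],
                rsa_track=rsa_tracks[chain_id],
                resolution=(metadata or {}).get(chain_id),
            )
        )
    return records


def apply_filters(records: Iterable[ProteinRecord],
                  filters: DatasetFilters) -> List[ProteinRecord]:
    """Keep chains passing the resolution/length/identity predicates.

    Both numeric predicates are strict, matching the dataset definition:
    resolution < max_resolution and length > min_length.  Records without
    resolution metadata are kept with a warning.
    """
    reps = (set(filters.identity_representatives)
            if filters.identity_representatives is not None else None)
    kept = []
    for rec in records:
        if reps is not None and rec.chain_id not in reps:
            continue
        if rec.resolution is None:
            logger.warning("%s: no resolution metadata; kept", rec.chain_id)
        elif not rec.resolution < filters.max_resolution:
            continue
        if not len(rec) > filters.min_length:
            continue
        kept.append(rec)
    return kept
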