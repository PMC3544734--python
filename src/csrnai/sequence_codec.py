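"""Deterministic machine encodings of nucleotide sequences.

Three representations feed the downstream siRNA feature extractors:

* a binary indicator matrix (BIM): L positions x 4 channels, one-hot per position;
* a 4-bit digital signal: the codebook A=1000, G=0100, T=0010, C=0001
  concatenated in sequence order (length 4L);
* a 9x9 "disk image": the sequence wrapped around a disk of radius 4 pixels,
  one equal angular sector per nucleotide, its 4-bit code laid radially.

The disk encoding turns a 19-mer into a small rounded shape so that texture
and moment descriptors developed for cell imagery apply to it. All encoders
are pure and total on the {A,C,G,T} alphabet; RNA input (U) is normalized to
T on ingest.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("csrnai")

#: Channel order of the binary indicator matrix columns.
BIM_CHANNELS = "AGTC"

#: 4-bit codebook used by the digital-signal encoding.
CODEBOOK = {
    "A": (1, 0, 0, 0),
    "G": (0, 1, 0, 0),
    "T": (0, 0, 1, 0),
    "C": (0, 0, 0, 1),
}

ALPHABET = frozenset("ACGT")

#: Disk geometry: radius in pixels and grid side (center at (5,5), 1-based).
DISK_RADIUS = 4
DISK_SIDE = 9

# Sequence lengths outside this range rasterize poorly on the 9x9 grid.
_DISK_COMFORT_RANGE = (15, 25)


class InvalidSequenceError(ValueError):
    """Raised when a sequence contains a character outside {A,C,G,T,U}."""


def normalize_sequence(residues: str) -> str:
    """Uppercase, convert U->T and validate against the {A,C,G,T} alphabet.

    Raises
    ------
    InvalidSequenceError
        Naming the 1-based position of the first offending character.
    """
    seq = residues.upper().replace("U", "T")
    if not seq:
        raise InvalidSequenceError("empty sequence")
    for i, ch in enumerate(seq):
        if ch not in ALPHABET:
            raise InvalidSequenceError(
                f"invalid character {ch!r} at position {i + 1} (alphabet is A/C/G/T/U)"
            )
    return seq


@dataclass(frozen=True)
class DiskImage:
    """A nucleotide sequence rasterized onto a 9x9 binary disk.

    ``pixels[r, c]`` is the bit of the (sector, radial band) cell the pixel
    center falls in; pixels outside the inscribed disk of radius 4 around the
    central pixel are 0. ``n_slides`` equals the sequence length (one angular
    sector per nucleotide).
    """

    pixels: np.ndarray
    n_slides: int
    center: tuple[int, int] = (5, 5)  # 1-based grid coordinate

    def __post_init__(self) -> None:
        assert self.pixels.shape == (DISK_SIDE, DISK_SIDE)

    def to_text(self) -> str:
        """Plain-text 9x9 grid of 0/1 characters."""
        return "\n".join("".join(str(int(v)) for v in row) for row in self.pixels)


def to_bim(residues: str) -> np.ndarray:
    """Encode a sequence as an L x 4 binary indicator matrix.

    Rows index sequence positions; columns index the channels A, G, T, C
    (in that fixed order). Exactly one cell per row is 1.
    """
    seq = normalize_sequence(residues)
    bim = np.zeros((len(seq), 4), dtype=np.int8)
    for i, ch in enumerate(seq):
        bim[i, BIM_CHANNELS.index(ch)] = 1
    return bim


def digitize(residues: str) -> np.ndarray:
    """Encode a sequence as a 4-bit-per-residue digital signal of length 4L."""
    seq = normalize_sequence(residues)
    return np.array([b for ch in seq for b in CODEBOOK[ch]], dtype=np.int8)


def disk_cell(row: int, col: int, n_slides: int) -> tuple[int, int] | None:
    """Map a 0-based pixel coordinate to its (sector, radial band) cell.

    Returns None for pixels outside the disk. Geometry: polar coordinates
    about the center pixel, angle measured counter-clockwise from the
    positive x-axis; sector s covers [2*pi*s/N, 2*pi*(s+1)/N); radial bands
    are (0,1], (1,2], (2,3], (3,4] (band index 0..3 = bit 1..4 of the code);
    the exact center belongs to band 0 of sector 0. Band membership uses
    integer squared radii, so rasterization is platform-exact.
    """
    c0 = DISK_SIDE // 2
    dx = col - c0
    dy = c0 - row  # y increases upward
    r2 = dx * dx + dy * dy
    if r2 > DISK_RADIUS * DISK_RADIUS:
        return None
    if r2 == 0:
        return 0, 0
    band = next(b for b in range(DISK_RADIUS) if r2 <= (b + 1) ** 2)
    theta = math.atan2(dy, dx) % (2.0 * math.pi)
    sector = min(int(n_slides * theta / (2.0 * math.pi)), n_slides - 1)
    return sector, band


def to_disk_image(residues: str) -> DiskImage:
    """Rasterize a sequence onto the 9x9 disk.

    Each of the N equal angular sectors carries the 4-bit code of one
    nucleotide laid radially, bit k at radial band k (center outward).
    """
    seq = normalize_sequence(residues)
    n = len(seq)
    lo, hi = _DISK_COMFORT_RANGE
    if not lo <= n <= hi:
        logger.warning(
            "disk encoding of a %d-mer: the transform is tuned for %d-%d bp", n, lo, hi
        )
    codes = [CODEBOOK[ch] for ch in seq]
    pixels = np.zeros((DISK_SIDE, DISK_SIDE), dtype=np.int8)
    for r in range(DISK_SIDE):
        for c in range(DISK_SIDE):
            cell = disk_cell(r, c, n)
            if cell is not None:
                sector, band = cell
                pixels[r, c] = codes[sector][band]
    return DiskImage(pixels=pixels, n_slides=n)


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

@dataclass
class SequenceSet:
    """An ordered, id-addressable collection of validated sequences."""

    ids: list[str] = field(default_factory=list)
    sequences: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences must have equal length")

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(zip(self.ids, self.sequences))

    def get(self, seq_id: str) -> str:
        return self.sequences[self.ids.index(seq_id)]


def read_fasta(path) -> SequenceSet:
    """Read a FASTA file, normalizing U->T and validating the alphabet.

    A record with a non-ACGTU character raises InvalidSequenceError naming
    the record and position.
    """
    ids, seqs = [], []
    for record in SeqIO.parse(str(path), "fasta"):
        raw = str(record.seq)
        if raw.upper() != raw.upper().replace("U", "T"):
            logger.info("record %s: U residues normalized to T", record.id)
        try:
            seqs.append(normalize_sequence(raw))
        except InvalidSequenceError as exc:
            raise InvalidSequenceError(f"record {record.id}: {exc}") from exc
        ids.append(record.id)
    return SequenceSet(ids=ids, sequences=seqs)


def write_fasta(seqset: SequenceSet, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in seqset
    ]
    SeqIO.write(records, str(path), "fasta")
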