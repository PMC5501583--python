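"""Sequence input/output and fragment preparation.

Training material for the classifier is built by cutting labeled genomes
into fixed-length, non-overlapping fragments: every virus genome is tiled
exhaustively, and an equal number of fragments is drawn at random from the
pooled host genomes so the two classes are balanced.  A point-substitution
mutator supports robustness experiments against sequence divergence and
sequencing error.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Label",
    "GenomeRecord",
    "Fragment",
    "read_fasta",
    "write_fasta",
    "split_genome",
    "subsample_fragments",
    "mutate_sequence",
    "fragments_to_records",
]

_VALID = set("ACGTN")
# lowercase is folded to uppercase; any IUPAC ambiguity code other than
# A/C/G/T becomes N
_NORMALIZE = str.maketrans(
    "acgtnRYSWKMBDHVryswkmbdhvUu-.",
    "ACGTN" + "N" * 24,
)


class Label(str, enum.Enum):
    VIRUS = "virus"
    HOST = "host"
    UNLABELED = "unlabeled"


@dataclasses.dataclass(frozen=True)
class GenomeRecord:
    """A named DNA sequence with a class label.

    The sequence is normalized on construction: uppercase, alphabet
    restricted to {A, C, G, T, N}.
    """

    id: str
    sequence: str
    label: Label = Label.UNLABELED

    def __post_init__(self) -> None:
        seq = normalize_sequence(self.sequence)
        if len(seq) == 0:
            raise ValueError(f"record {self.id!r}: empty sequence")
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "label", Label(self.label))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass(frozen=True)
class Fragment:
    """A fixed-length window cut from a parent genome."""

    parent_id: str
    start: int
    length: int
    sequence: str
    label: Label

    def __post_init__(self) -> None:
        if len(self.sequence) != self.length:
            raise ValueError(
                f"fragment {self.parent_id}:{self.start}: sequence length "
                f"{len(self.sequence)} != declared length {self.length}"
            )
        object.__setattr__(self, "label", Label(self.label))

    @property
    def id(self) -> str:
        return f"{self.parent_id}|{self.start}|{self.length}|{self.label.value}"


def normalize_sequence(seq: str) -> str:
    """Uppercase *seq* and map every non-ACGT symbol to N."""
    out = seq.translate(_NORMALIZE)
    bad = set(out) - _VALID
    if bad:
        raise ValueError(f"unrecognized sequence characters: {sorted(bad)}")
    return out


def read_fasta(path: str | Path, label: Label | str = Label.UNLABELED) -> list[GenomeRecord]:
    """Read a FASTA file into labeled, normalized records.

    Raises ``ValueError`` on an empty file or a file whose first
    non-blank line is not a FASTA header.
    """
    path = Path(path)
    label = Label(label)
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: line {lineno}: expected FASTA header, got {line.strip()[:40]!r}"
                    )
                break
        else:
            raise ValueError(f"{path}: empty FASTA file")
    records = [
        GenomeRecord(id=rec.id, sequence=str(rec.seq), label=label)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"{path}: empty FASTA file")
    return records


def write_fasta(records: Iterable[GenomeRecord | Fragment], path: str | Path) -> None:
    """Write genome records or fragments as multi-FASTA.

    Fragments use the header convention ``parentID|start|L|label``.
    """
    seq_records = []
    for rec in records:
        name = rec.id if isinstance(rec, GenomeRecord) else rec.id
        seq_records.append(SeqRecord(Seq(rec.sequence), id=name, description=""))
    SeqIO.write(seq_records, str(path), "fasta")


def split_genome(record: GenomeRecord, L: int) -> list[Fragment]:
    """Tile *record* into non-overlapping length-*L* fragments from position 0.

    The trailing remainder shorter than *L* is discarded; a genome shorter
    than *L* yields an empty list.
    """
    if L < 1:
        raise ValueError(f"fragment length must be positive, got {L}")
    n = len(record.sequence) // L
    return [
        Fragment(
            parent_id=record.id,
            start=i * L,
            length=L,
            sequence=record.sequence[i * L : (i + 1) * L],
            label=record.label,
        )
        for i in range(n)
    ]


def subsample_fragments(
    records: Sequence[GenomeRecord],
    L: int,
    n: int,
    seed: int,
) -> list[Fragment]:
    """Draw *n* non-overlapping fragments uniformly from pooled genome slots.

    The sampling universe is the union over all genomes of the L-aligned
    grid slots (starts 0, L, 2L, ...), so longer genomes contribute
    proportionally more slots.  Sampling is without replacement and
    deterministic for a fixed *seed*.
    """
    if L < 1:
        raise ValueError(f"fragment length must be positive, got {L}")
    if n < 0:
        raise ValueError(f"sample size must be non-negative, got {n}")
    slots: list[tuple[int, int]] = []  # (record index, start)
    for ri, rec in enumerate(records):
        for j in range(len(rec.sequence) // L):
            slots.append((ri, j * L))
    if n > len(slots):
        raise ValueError(
            f"requested {n} fragments but only {len(slots)} non-overlapping "
            f"slots of length {L} are available"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(slots), size=n, replace=False)
    out = []
    for idx in sorted(chosen.tolist()):
        ri, start = slots[idx]
        rec = records[ri]
        out.append(
            Fragment(
                parent_id=rec.id,
                start=start,
                length=L,
                sequence=rec.sequence[start : start + L],
                label=rec.label,
            )
        )
    return out


def mutate_sequence(seq: str, rate: float, seed: int) -> str:
    """Introduce independent point substitutions at the given per-site rate.

    Each A/C/G/T position is substituted with probability *rate*; the
    replacement base is drawn uniformly from the three other bases.  N
    positions are left untouched.  Length is preserved (no indels).
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"mutation rate must be in [0, 1], got {rate}")
    if rate == 0.0 or not seq:
        return seq
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    # base -> 0..3 code; N and anything else -> 4
    code = np.full(256, 4, dtype=np.uint8)
    code[bases] = np.arange(4, dtype=np.uint8)
    codes = code[arr]
    hit = (rng.random(arr.size) < rate) & (codes < 4)
    n_hit = int(hit.sum())
    if n_hit:
        # uniform over the three alternatives: add 1..3 mod 4
        shift = rng.integers(1, 4, size=n_hit).astype(np.uint8)
        codes_hit = (codes[hit] + shift) % 4
        arr[hit] = bases[codes_hit]
    return arr.tobytes().decode("ascii")


def fragments_to_records(fragments: Iterable[Fragment]) -> list[GenomeRecord]:
    """View fragments as standalone records (header keeps provenance)."""
    return [
        GenomeRecord(id=f.id, sequence=f.sequence, label=f.label) for f in fragments
    ]
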