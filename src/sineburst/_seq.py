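"""Small shared sequence utilities (complementation, FASTA I/O, encoding)."""

from __future__ import annotations

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """ACGT string -> uint8 codes 0..3."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(len(arr), 255, dtype=np.uint8)
    for b, i in _CODE.items():
        out[arr == ord(b)] = i
    if (out == 255).any():
        bad = int(np.argmax(out == 255))
        raise ValueError(f"non-ACGT character {seq[bad]!r} at position {bad}")
    return out


def decode(codes: np.ndarray) -> str:
    lut = np.frombuffer("ACGT".encode("ascii"), dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def random_seq(rng: np.random.Generator, length: int, freqs=(0.25, 0.25, 0.25, 0.25)) -> str:
    codes = rng.choice(4, size=length, p=np.asarray(freqs, dtype=float))
    return decode(codes.astype(np.uint8))


def read_fasta(path) -> dict[str, str]:
    """Multi-contig FASTA -> ordered {name: sequence} (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
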