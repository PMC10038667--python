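"""Alignment file I/O: FASTA (read/write) and Stockholm (read-only)."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO

from .msa import Alphabet, Msa


def read_fasta_msa(path: str | Path, alphabet: Alphabet | None = None,
                   strict: bool = False) -> Msa:
    """Read an aligned FASTA file into an :class:`Msa`.

    Records must all have the same length; row order is preserved.
    Non-canonical residues follow the alphabet's gap-mapping policy.
    """
    return _read(path, "fasta", alphabet, strict)


def read_stockholm_msa(path: str | Path, alphabet: Alphabet | None = None,
                       strict: bool = False) -> Msa:
    """Read a Stockholm alignment (convenience; FASTA is the primary format)."""
    return _read(path, "stockholm", alphabet, strict)


def _read(path, fmt, alphabet, strict):
    records = list(SeqIO.parse(str(path), fmt))
    if not records:
        raise ValueError(f"no records in {path}")
    ids = [r.id for r in records]
    seqs = [str(r.seq) for r in records]
    return Msa.from_sequences(seqs, ids=ids, alphabet=alphabet, strict=strict)


def write_fasta_msa(msa: Msa, path: str | Path) -> None:
    """Write an MSA as FASTA, one record per row; empty ids become ``seq<k>``."""
    with open(path, "w") as fh:
        for k, (sid, seq) in enumerate(zip(msa.ids, msa.sequences())):
            fh.write(f">{sid or f'seq{k}'}\n{seq}\n")
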