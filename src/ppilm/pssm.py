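"""Position-specific scoring matrix (PSSM) input/output.

A PSSM is the R x 20 profile PSI-BLAST emits for a query protein of
length R: entry d(i, j) scores the j-th amino acid at sequence position
i, with high values at well-conserved positions.  This module reads and
writes the PSI-BLAST ``-out_ascii_pssm`` dialect (only the first 20
numeric columns — the log-odds block — are used), constructs profiles
from position frequencies and a mutation matrix, and handles the
tab-separated pair lists that carry the +/-1 interaction labels.
"""

from __future__ import annotations

import shutil
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO

from .residues import AA_INDEX, AA_ORDER, NONCANONICAL

__all__ = [
    "PSSM",
    "ProteinRecord",
    "PSSMParseError",
    "read_pssm_file",
    "write_pssm_file",
    "build_pssm_from_frequencies",
    "read_pair_list",
    "write_pair_list",
    "read_fasta",
    "psiblast_command",
]


class PSSMParseError(ValueError):
    """Raised when a profile or pair-list file is malformed."""


@dataclass
class ProteinRecord:
    """A named amino-acid sequence.

    Residues outside the 20-letter alphabet (B, Z, X, U, ...) are
    tolerated with a warning; anything else raises ``ValueError``.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        seq = self.sequence.upper()
        bad = set(seq) - set(AA_ORDER)
        if bad - NONCANONICAL:
            raise ValueError(
                f"protein {self.id!r}: invalid residue codes {sorted(bad - NONCANONICAL)}"
            )
        if bad:
            warnings.warn(
                f"protein {self.id!r}: non-canonical residues {sorted(bad)} "
                "map to zero-score profile rows",
                stacklevel=2,
            )
        self.sequence = seq

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PSSM:
    """An R x 20 profile for one protein, columns in :data:`AA_ORDER`."""

    protein_id: str
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(AA_ORDER):
            raise ValueError(
                f"PSSM {self.protein_id!r}: expected R x 20 matrix, "
                f"got shape {self.matrix.shape}"
            )
        if self.matrix.shape[0] < 1:
            raise ValueError(f"PSSM {self.protein_id!r}: empty matrix")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError(f"PSSM {self.protein_id!r}: non-finite entries")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]


_HEADER_COMMENT = (
    "Last position-specific scoring matrix computed, weighted observed "
    "percentages rounded down, information per position, and relative "
    "weight of gapless real matches to pseudocounts"
)


def _is_aa_header(tokens: list[str]) -> bool:
    # PSI-BLAST prints the 20 letters once (old) or twice (log-odds +
    # percentage blocks); either counts as the column header.
    return (
        len(tokens) in (20, 40)
        and all(t in AA_INDEX for t in tokens)
        and sorted(set(tokens)) == sorted(AA_ORDER)
    )


def read_pssm_file(path: str | Path, protein_id: str | None = None) -> PSSM:
    """Read a PSI-BLAST ASCII profile file.

    Only the first 20 numeric columns after the position index and the
    query residue (the log-odds block) are kept.  The protein id
    defaults to the filename stem.  Malformed rows raise
    :class:`PSSMParseError` naming the offending line number.
    """
    path = Path(path)
    if protein_id is None:
        protein_id = path.stem
    rows: list[list[float]] = []
    seen_header = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                if seen_header and rows:
                    break  # blank line ends the matrix block
                continue
            if not seen_header:
                if _is_aa_header(tokens):
                    seen_header = True
                continue
            if not tokens[0].lstrip("-").isdigit():
                if rows:
                    break  # trailing K/Lambda statistics block
                raise PSSMParseError(
                    f"{path}:{lineno}: expected a position row, got {line!r}"
                )
            body = tokens[2:] if not _is_number(tokens[1]) else tokens[1:]
            if len(body) < 20:
                raise PSSMParseError(
                    f"{path}:{lineno}: row has {len(body)} numeric columns, "
                    "expected at least 20"
                )
            try:
                rows.append([float(v) for v in body[:20]])
            except ValueError as exc:
                raise PSSMParseError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    if not seen_header:
        raise PSSMParseError(f"{path}: no amino-acid column header found")
    if not rows:
        raise PSSMParseError(f"{path}: matrix block is empty")
    return PSSM(protein_id=protein_id, matrix=np.array(rows))


def _is_number(tok: str) -> bool:
    try:
        float(tok)
    except ValueError:
        return False
    return True


def write_pssm_file(pssm: PSSM, path: str | Path, sequence: str | None = None) -> None:
    """Write a profile in the PSI-BLAST ASCII dialect.

    Scores are printed with six decimals; reading the file back returns
    the matrix exactly at that printed precision.  ``sequence``
    optionally supplies the query-residue column (defaults to 'X').
    """
    pssm_path = Path(path)
    R = pssm.length
    if sequence is not None and len(sequence) != R:
        raise ValueError("sequence length does not match matrix rows")
    with open(pssm_path, "w") as fh:
        fh.write("\n" + _HEADER_COMMENT + "\n")
        fh.write(" " * 10 + "".join(f"{a:>11s}" for a in AA_ORDER) + "\n")
        for i in range(R):
            res = sequence[i] if sequence is not None else "X"
            cells = "".join(f"{v:>11.6f}" for v in pssm.matrix[i])
            fh.write(f"{i + 1:>5d} {res:1s}   {cells}\n")
        fh.write("\n")
        fh.write("                      K         Lambda\n")
        fh.write("Standard Ungapped    0.1347     0.3179\n")


def build_pssm_from_frequencies(
    freq: np.ndarray,
    mut: np.ndarray,
    protein_id: str = "query",
    atol: float = 1e-9,
) -> PSSM:
    """Construct a profile from position frequencies and a mutation matrix.

    Entry (u, v) of the result is sum_k p(u, k) * w(v, k): the frequency
    profile at position u scored against amino acid v under mutation
    matrix w — the matrix product ``freq @ mut.T`` with both operands in
    the shared column order.  ``freq`` must be row-stochastic (rows sum
    to 1 within ``atol``).
    """
    freq = np.asarray(freq, dtype=float)
    mut = np.asarray(mut, dtype=float)
    if freq.ndim != 2 or freq.shape[1] != 20:
        raise ValueError(f"frequency matrix must be R x 20, got {freq.shape}")
    if mut.shape != (20, 20):
        raise ValueError(f"mutation matrix must be 20 x 20, got {mut.shape}")
    sums = freq.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=atol, rtol=0.0):
        off = int(np.argmax(np.abs(sums - 1.0)))
        raise ValueError(
            f"frequency row {off} sums to {sums[off]:.12g}, expected 1"
        )
    return PSSM(protein_id=protein_id, matrix=freq @ mut.T)


def read_pair_list(path: str | Path) -> list[tuple[str, str, int]]:
    """Read a TSV pair list: ``id_a<TAB>id_b<TAB>label`` with label +/-1."""
    pairs: list[tuple[str, str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise PSSMParseError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}"
                )
            a, b, lab = parts
            if lab not in {"1", "+1", "-1"}:
                raise PSSMParseError(
                    f"{path}:{lineno}: label must be +1 or -1, got {lab!r}"
                )
            pairs.append((a, b, 1 if lab in {"1", "+1"} else -1))
    return pairs


def write_pair_list(pairs: Iterable[tuple[str, str, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b, lab in pairs:
            if lab not in (1, -1):
                raise ValueError(f"label must be +/-1, got {lab!r}")
            fh.write(f"{a}\t{b}\t{lab:+d}\n".replace("+1", "1"))


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file (ids and sequences only)."""
    return [
        ProteinRecord(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def psiblast_command(
    query_fasta: str | Path,
    database: str,
    out_ascii_pssm: str | Path,
    evalue: float = 0.001,
    num_iterations: int = 3,
) -> list[str]:
    """Assemble (but do not run) the PSI-BLAST profile-generation command.

    Profiles are conventionally produced with an e-value threshold of
    0.001 and three search iterations against a large sequence database;
    those are the defaults here.  The caller is responsible for running
    the command — this package never executes PSI-BLAST itself, it only
    documents the interface and parses the resulting ASCII profile.
    """
    exe = shutil.which("psiblast") or "psiblast"
    return [
        exe,
        "-query", str(query_fasta),
        "-db", database,
        "-evalue", str(evalue),
        "-num_iterations", str(num_iterations),
        "-out_ascii_pssm", str(out_ascii_pssm),
    ]
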