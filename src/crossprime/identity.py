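"""Multiple-sequence-alignment ingestion, percent-identity scoring, and
conserved-region discovery.

The conservation statistic used throughout is, per aligned sequence,

    percent identity = matches * 100 / alignment length (including gaps)

where "matches" counts columns at which the sequence agrees with the
column's majority residue (gaps never win a majority; majority ties break
alphabetically).  Dividing by the full column count, gap columns included,
means a short fragment aligned into a long family alignment scores roughly
fragment_length / alignment_length — the deliberate behavior that exposes
fragmentary annotations.  A ``pairwise_mean`` mode (mean of all pairwise
identities over the same denominator) is provided as an alternative
reading of "matches" for families of more than two sequences.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO

from .thermo import CODE_FOR_BASES, degeneracy as _degeneracy

__all__ = [
    "Alignment",
    "Consensus",
    "IdentityScore",
    "ConservedWindow",
    "AlignerUnavailableError",
    "MafftConfig",
    "read_alignment",
    "write_alignment",
    "align_external",
    "consensus",
    "percent_identity",
    "conserved_regions",
]

_ALPHABET = frozenset("ACGT-")


@dataclass(frozen=True)
class Alignment:
    """A gapped nucleotide alignment: >= 2 equal-length rows over {A,C,G,T,-}."""

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("alignment requires at least 2 rows")
        lengths = {len(seq) for _, seq in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment rows: lengths {sorted(lengths)}")
        for rid, seq in self.rows:
            bad = set(seq) - _ALPHABET
            if bad:
                raise ValueError(f"row {rid!r}: invalid alignment characters {sorted(bad)}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "Alignment":
        norm = tuple((rid, seq.upper().replace(".", "-")) for rid, seq in pairs)
        return cls(rows=norm)

    @property
    def length(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rid for rid, _ in self.rows)

    def ungapped(self, row_id: str) -> str:
        for rid, seq in self.rows:
            if rid == row_id:
                return seq.replace("-", "")
        raise KeyError(row_id)

    def column(self, i: int) -> tuple[str, ...]:
        return tuple(seq[i] for _, seq in self.rows)


def read_alignment(path: str | Path, format: str = "aligned_fasta") -> Alignment:
    """Read an aligned FASTA or Clustal file; '.' gaps are normalized to '-'."""
    fmt = {"aligned_fasta": "fasta", "clustal": "clustal"}.get(format)
    if fmt is None:
        raise ValueError(f"unknown alignment format {format!r}")
    msa = AlignIO.read(str(path), fmt)
    return Alignment.from_pairs((rec.id, str(rec.seq)) for rec in msa)


def write_alignment(alignment: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in alignment.rows:
            fh.write(f">{rid}\n{seq}\n")


class AlignerUnavailableError(RuntimeError):
    """The external aligner is not on PATH; supply a precomputed alignment."""


@dataclass(frozen=True)
class MafftConfig:
    """Contract for the external aligner invocation.

    Defaults mirror the workflow's stated alignment conditions: maximum
    iterations 0, tree rebuilding number 2, gap open penalty 1.53, gap
    extension penalty 0.0, no direction adjustment.
    """

    executable: str = "mafft"
    args: tuple[str, ...] = ("--retree", "2", "--maxiterate", "0", "--op", "1.53", "--ep", "0.0")


def align_external(
    sequences: Sequence[tuple[str, str]], config: MafftConfig | None = None
) -> Alignment:
    """Align unaligned sequences with the external aligner (never reimplemented).

    Raises :class:`AlignerUnavailableError` if the executable is missing —
    there is no silent fallback.
    """
    config = config or MafftConfig()
    if shutil.which(config.executable) is None:
        raise AlignerUnavailableError(
            f"{config.executable!r} not found on PATH; provide a precomputed alignment"
        )
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences to align")
    with tempfile.TemporaryDirectory() as tmp:
        infile = Path(tmp) / "input.fasta"
        infile.write_text("".join(f">{rid}\n{seq}\n" for rid, seq in sequences))
        proc = subprocess.run(
            [config.executable, *config.args, str(infile)],
            capture_output=True,
            text=True,
            check=True,
        )
        outfile = Path(tmp) / "aligned.fasta"
        outfile.write_text(proc.stdout)
        aln = read_alignment(outfile, "aligned_fasta")
    by_id = dict(sequences)
    for rid in aln.ids:
        if aln.ungapped(rid) != by_id[rid].upper():
            raise RuntimeError(f"aligner altered sequence {rid!r}")
    return aln


@dataclass(frozen=True)
class Consensus:
    """Consensus string plus per-column gap flags.

    In ``iupac`` mode each column carries the minimal ambiguity code
    covering all non-gap residues (the primer-design consensus); in
    ``majority`` mode it carries the majority residue (the scoring
    consensus).  Columns containing any gap are flagged and rendered '-'
    in ``sequence`` only when all residues are gaps.
    """

    sequence: str
    gap_flags: tuple[bool, ...]


_MAJORITY_ORDER = "ACGT"


def _majority_residue(column: Sequence[str]) -> str:
    counts = {b: 0 for b in _MAJORITY_ORDER}
    for ch in column:
        if ch in counts:
            counts[ch] += 1
    best = max(counts.values())
    if best == 0:
        return "-"  # all-gap column: nothing can match here
    # ties break alphabetically; a gap never wins
    return min(b for b in _MAJORITY_ORDER if counts[b] == best)


def consensus(alignment: Alignment, mode: str = "iupac") -> Consensus:
    """Per-column consensus of an alignment (see :class:`Consensus`)."""
    if mode not in ("iupac", "majority"):
        raise ValueError(f"unknown consensus mode {mode!r}")
    chars = []
    flags = []
    for i in range(alignment.length):
        col = alignment.column(i)
        residues = frozenset(c for c in col if c != "-")
        flags.append("-" in col)
        if not residues:
            chars.append("-")
        elif mode == "iupac":
            chars.append(CODE_FOR_BASES[residues])
        else:
            chars.append(_majority_residue(col))
    return Consensus(sequence="".join(chars), gap_flags=tuple(flags))


@dataclass(frozen=True)
class IdentityScore:
    """Per-sequence percent-identity scores with the family mean and SD."""

    per_sequence: dict[str, float]
    mean: float
    sd: float
    alignment_length: int
    gene_count: int


def percent_identity(alignment: Alignment, mode: str = "consensus") -> IdentityScore:
    """Score each sequence against the family alignment.

    ``consensus`` (default): matches are columns where the row equals the
    column majority residue.  ``pairwise_mean``: each row's score is the
    mean of its pairwise identities against every other row.  Either way
    the denominator is the full alignment length, gap columns included.
    """
    n = len(alignment.rows)
    if n < 2:
        raise ValueError("percent identity requires >= 2 sequences")
    length = alignment.length
    scores: dict[str, float] = {}
    if mode == "consensus":
        maj = consensus(alignment, mode="majority").sequence
        for rid, seq in alignment.rows:
            matches = sum(
                1 for a, b in zip(seq, maj) if a == b and b != "-"
            )
            scores[rid] = matches * 100.0 / length
    elif mode == "pairwise_mean":
        for i, (rid, seq) in enumerate(alignment.rows):
            vals = []
            for j, (_, other) in enumerate(alignment.rows):
                if i == j:
                    continue
                matches = sum(1 for a, b in zip(seq, other) if a == b and a != "-")
                vals.append(matches * 100.0 / length)
            scores[rid] = float(np.mean(vals))
    else:
        raise ValueError(f"unknown scoring mode {mode!r}")
    values = np.array(list(scores.values()))
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return IdentityScore(
        per_sequence=scores,
        mean=float(values.mean()),
        sd=sd,
        alignment_length=length,
        gene_count=n,
    )


@dataclass(frozen=True)
class ConservedWindow:
    """A gap-free alignment window ranked by consensus degeneracy."""

    start: int
    length: int
    degeneracy: int
    gap_free: bool = True


def conserved_regions(
    alignment: Alignment,
    window_lengths: Sequence[int] = tuple(range(18, 24)),
    max_degeneracy: int | None = None,
) -> list[ConservedWindow]:
    """Gap-free windows ranked ascending by IUPAC-consensus degeneracy.

    Windows overlapping any gap-containing column are excluded.  Ties rank
    by leftmost start, then shorter window.  An empty result is not an
    error — it means no feasible window exists.
    """
    cons = consensus(alignment, mode="iupac")
    has_gap = np.array(cons.gap_flags)
    # per-column expansion count of the covering code (0-degeneracy never occurs)
    col_deg = np.array(
        [1 if g else _degeneracy(c) for c, g in zip(cons.sequence, cons.gap_flags)],
        dtype=np.int64,
    )
    out: list[ConservedWindow] = []
    for L in window_lengths:
        if L > alignment.length:
            continue
        gap_in_window = np.convolve(has_gap.astype(int), np.ones(L, dtype=int), "valid") > 0
        for s in range(alignment.length - L + 1):
            if gap_in_window[s]:
                continue
            deg = int(np.prod(col_deg[s : s + L]))
            if max_degeneracy is not None and deg > max_degeneracy:
                continue
            out.append(ConservedWindow(start=s, length=L, degeneracy=deg))
    out.sort(key=lambda w: (w.degeneracy, w.start, w.length))
    return out
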