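"""IUPAC degenerate-base algebra and nearest-neighbor duplex thermodynamics.

A degenerate primer is a defined mixture of concrete oligonucleotides: each
IUPAC ambiguity code (R, Y, S, W, K, M, B, D, H, V, N) stands for the set of
bases synthesized at that position, so a primer with codes of sizes
``k1, k2, ...`` is a mixture of ``k1 * k2 * ...`` distinct sequences.  This
module provides the expansion algebra (:func:`expand_degenerate`,
:func:`degeneracy`), GC-content bounds over the mixture
(:func:`gc_content`), and duplex melting temperatures for concrete
sequences (:func:`melting_temperature`) or mixtures (:func:`tm_range`)
using the unified SantaLucia nearest-neighbor parameter set.

Inosine is deliberately unsupported: it is not a defined base mixture and
its pairing thermodynamics are not part of this model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product as _iterproduct

from Bio.SeqUtils import MeltingTemp as _mt

__all__ = [
    "IUPAC_CODES",
    "CODE_FOR_BASES",
    "DegeneratePrimer",
    "ThermoParams",
    "DEFAULT_PARAMS",
    "reverse_complement",
    "expand_degenerate",
    "degeneracy",
    "gc_content",
    "melting_temperature",
    "tm_range",
]

#: Base sets denoted by each IUPAC nucleotide code (concrete bases included).
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Minimal IUPAC code covering a given base set (inverse of IUPAC_CODES).
CODE_FOR_BASES: dict[frozenset[str], str] = {v: k for k, v in IUPAC_CODES.items()}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")

#: Nearest-neighbor tables selectable through ThermoParams.nn_table_id.
NN_TABLES = {
    "santalucia98": _mt.DNA_NN3,  # unified parameter set
    "santalucia04": _mt.DNA_NN4,
}


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a (possibly degenerate) IUPAC sequence."""
    seq = _validated(sequence)
    return seq.translate(_COMPLEMENT)[::-1]


def _validated(sequence: str) -> str:
    seq = str(sequence).upper()
    for i, ch in enumerate(seq):
        if ch not in IUPAC_CODES:
            raise ValueError(
                f"invalid IUPAC symbol {ch!r} at position {i + 1} in {sequence!r}"
            )
    return seq


@dataclass(frozen=True)
class DegeneratePrimer:
    """A named IUPAC primer with orientation and intended targets.

    ``orientation`` follows PCR convention: ``upstream`` (forward) primers
    match the sense strand, ``downstream`` (reverse) primers are written
    5'->3' on the antisense strand.
    """

    name: str
    sequence: str
    orientation: str = "upstream"
    intended_targets: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        seq = _validated(self.sequence)
        if not seq:
            raise ValueError("primer sequence must be non-empty")
        if self.orientation not in ("upstream", "downstream"):
            raise ValueError(f"orientation must be upstream/downstream, got {self.orientation!r}")
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "intended_targets", tuple(self.intended_targets))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ThermoParams:
    """Duplex-model parameters.

    monovalent_salt
        Total monovalent cation concentration in mol/L (default 50 mM).
    primer_conc
        Primer strand concentration in mol/L (default 250 nM); the template
        is assumed to be in vast defect, i.e. not self-complementary excess.
    nn_table_id
        Nearest-neighbor parameter set; ``santalucia98`` is the unified set.
    mismatch_penalty
        Flat Tm penalty in deg C applied per internal mismatch when scoring
        imperfect duplexes (see :func:`crossprime.scan.site_tm`).
    """

    monovalent_salt: float = 0.05
    primer_conc: float = 250e-9
    nn_table_id: str = "santalucia98"
    mismatch_penalty: float = 5.0

    def __post_init__(self) -> None:
        if self.monovalent_salt <= 0:
            raise ValueError("monovalent_salt must be > 0")
        if self.primer_conc <= 0:
            raise ValueError("primer_conc must be > 0")
        if self.nn_table_id not in NN_TABLES:
            raise ValueError(f"unknown nn_table_id {self.nn_table_id!r}; known: {sorted(NN_TABLES)}")
        if self.mismatch_penalty < 0:
            raise ValueError("mismatch_penalty must be >= 0")


DEFAULT_PARAMS = ThermoParams()


def _sequence_of(primer: "DegeneratePrimer | str") -> str:
    if isinstance(primer, DegeneratePrimer):
        return primer.sequence
    return _validated(primer)


def degeneracy(primer: "DegeneratePrimer | str") -> int:
    """Number of concrete sequences in the mixture, without materializing it."""
    seq = _sequence_of(primer)
    if not seq:
        raise ValueError("empty sequence")
    return math.prod(len(IUPAC_CODES[c]) for c in seq)


def expand_degenerate(
    primer: "DegeneratePrimer | str", max_degeneracy: int | None = None
) -> list[str]:
    """All concrete expansions of a degenerate primer, in lexicographic order."""
    seq = _sequence_of(primer)
    if not seq:
        raise ValueError("empty sequence")
    n = degeneracy(seq)
    if max_degeneracy is not None and n > max_degeneracy:
        raise ValueError(f"degeneracy {n} exceeds cap {max_degeneracy}; expand explicitly")
    choices = [sorted(IUPAC_CODES[c]) for c in seq]
    return ["".join(p) for p in _iterproduct(*choices)]


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def gc_content(primer: "DegeneratePrimer | str") -> tuple[int, int]:
    """(min, max) GC percentage over all expansions, rounded half-up.

    Computed positionwise: a code contributes to the minimum only if every
    base it denotes is G/C (e.g. S), and to the maximum if any is (e.g. R).
    """
    seq = _sequence_of(primer)
    if not seq:
        raise ValueError("empty sequence")
    gc = frozenset("GC")
    lo = sum(1 for c in seq if IUPAC_CODES[c] <= gc)
    hi = sum(1 for c in seq if IUPAC_CODES[c] & gc)
    n = len(seq)
    return _round_half_up(lo * 100 / n), _round_half_up(hi * 100 / n)


def melting_temperature(sequence: str, params: ThermoParams | None = None) -> float:
    """Nearest-neighbor melting temperature (deg C) of a concrete sequence.

    Uses the unified SantaLucia nearest-neighbor deltaH/deltaS parameters
    with initiation terms, the SantaLucia (1998) monovalent-salt entropy
    correction, and the configured primer concentration (primer in excess
    over template).  Degenerate input is an error; use :func:`tm_range`.
    """
    params = params or DEFAULT_PARAMS
    seq = _validated(sequence)
    if len(seq) < 2:
        raise ValueError("sequence must have length >= 2")
    if degeneracy(seq) > 1:
        raise ValueError("degenerate sequence; use tm_range for mixtures")
    return float(
        _mt.Tm_NN(
            seq,
            nn_table=NN_TABLES[params.nn_table_id],
            Na=params.monovalent_salt * 1e3,  # mM
            K=0,
            Tris=0,
            Mg=0,
            dNTPs=0,
            dnac1=params.primer_conc * 1e9,  # nM
            dnac2=0,
            saltcorr=5,
            selfcomp=False,
        )
    )


def tm_range(
    primer: "DegeneratePrimer | str",
    params: ThermoParams | None = None,
    max_degeneracy: int = 4096,
) -> tuple[float, float]:
    """(min, max) melting temperature over all expansions of a primer."""
    tms = [melting_temperature(s, params) for s in expand_degenerate(primer, max_degeneracy)]
    return min(tms), max(tms)
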