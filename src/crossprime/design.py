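"""Primer panel construction by two complementary strategies.

Approach A (consensus / degenerate): pick a pair of gap-free conserved
windows from a family alignment, take the minimal covering IUPAC consensus
of each window as the primer, and minimize the total number of concrete
sequences in the resulting mixture (forward degeneracy x reverse
degeneracy) subject to the amplicon-size, GC and Tm-pairing constraints.
Suited to families whose identity score clears the 75% cutoff.

Approach B (unique per-gene): design one non-degenerate pair per gene,
letting binding positions drift between genes but forcing every pair to
produce exactly the same amplicon size; a single common size S in the
allowed range is chosen to maximize the number of designable genes.
Suited to plastic families below the cutoff.

Both operations are pure functions of their inputs and rerun
bit-identically; infeasibility is reported, never silently relaxed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .identity import Alignment, ConservedWindow, conserved_regions, consensus
from .thermo import (
    DEFAULT_PARAMS,
    DegeneratePrimer,
    ThermoParams,
    degeneracy,
    gc_content,
    melting_temperature,
    reverse_complement,
    tm_range,
)

__all__ = [
    "DesignConstraints",
    "PrimerPair",
    "PrimerPanel",
    "InfeasibleDesignError",
    "design_approach_A",
    "design_approach_B",
    "validate_pair",
    "recommend_approach",
    "APPROACH_CUTOFF",
]

#: Family percent-identity cutoff separating the two design approaches.
APPROACH_CUTOFF = 75.0


@dataclass(frozen=True)
class DesignConstraints:
    """Primer-design constraints (defaults are the workflow's stated ones).

    primer_len
        Allowed primer length range in nt.
    amplicon_len
        Allowed PCR product size range in bp (qPCR-friendly).
    gc_target
        Soft GC target in %; deviation from it is a penalty, not a bound.
    gc_max
        Hard GC ceiling in %.
    tm_pair_delta_max
        Maximum melting-temperature difference within a pair, deg C.
    max_degeneracy_per_primer
        Cap on expansions a single consensus primer may represent.
    """

    primer_len: tuple[int, int] = (18, 23)
    amplicon_len: tuple[int, int] = (180, 240)
    gc_target: float = 50.0
    gc_max: float = 80.0
    tm_pair_delta_max: float = 5.0
    max_degeneracy_per_primer: int = 32

    def __post_init__(self) -> None:
        for lo, hi in (self.primer_len, self.amplicon_len):
            if lo > hi:
                raise ValueError("range min must be <= max")


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse pair; the reverse primer is stored 5'->3' on the
    antisense strand, and product size counts both primers inclusively."""

    forward: DegeneratePrimer
    reverse: DegeneratePrimer
    template_id: str
    product_size: int
    tm_delta: float


@dataclass(frozen=True)
class PrimerPanel:
    pairs: tuple[PrimerPair, ...]
    approach: str
    common_product_size: int | None = None
    infeasible: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.approach == "B":
            sizes = {p.product_size for p in self.pairs}
            if len(sizes) > 1 or (self.pairs and self.common_product_size is None):
                raise ValueError("approach B requires a single common product size")


class InfeasibleDesignError(RuntimeError):
    """No primer pair satisfies the constraints; message names the most
    frequently violated one."""


def _mid(rng: tuple[float, float]) -> float:
    return 0.5 * (rng[0] + rng[1])


def design_approach_A(
    alignment: Alignment,
    constraints: DesignConstraints | None = None,
    params: ThermoParams | None = None,
) -> PrimerPair:
    """Degenerate consensus pair on conserved windows of a family alignment.

    Deterministic: among feasible window pairs, minimizes total degeneracy
    (forward x reverse), breaking ties by Tm-midpoint closeness, then
    leftmost forward window, then leftmost reverse window, then lengths.
    The per-row ungapped product size must lie inside the amplicon range
    for every row of the alignment.
    """
    constraints = constraints or DesignConstraints()
    params = params or DEFAULT_PARAMS
    lmin, lmax = constraints.primer_len
    amin, amax = constraints.amplicon_len

    windows = conserved_regions(
        alignment, tuple(range(lmin, lmax + 1)), constraints.max_degeneracy_per_primer
    )
    failures: Counter[str] = Counter()
    if not windows:
        raise InfeasibleDesignError(
            "no gap-free window within the degeneracy cap exists in this alignment"
        )

    cons = consensus(alignment, mode="iupac").sequence
    # cache per-window primer string, GC ceiling, Tm-range midpoint
    gc_ok: dict[tuple[int, int], bool] = {}
    tm_mid: dict[tuple[int, int], float] = {}

    def window_seq(w: ConservedWindow) -> str:
        return cons[w.start : w.start + w.length]

    def window_gc_ok(w: ConservedWindow) -> bool:
        key = (w.start, w.length)
        if key not in gc_ok:
            gc_ok[key] = gc_content(window_seq(w))[1] <= constraints.gc_max
        return gc_ok[key]

    def window_tm_mid(w: ConservedWindow) -> float:
        key = (w.start, w.length)
        if key not in tm_mid:
            tm_mid[key] = _mid(tm_range(window_seq(w), params))
        return tm_mid[key]

    # per-row cumulative non-gap counts for O(1) ungapped product sizes
    cum = {
        rid: np.concatenate(
            [[0], np.cumsum(np.frombuffer(seq.encode(), np.uint8) != ord("-"))]
        )
        for rid, seq in alignment.rows
    }
    total_gap_cols = alignment.length - min(int(c[-1]) for c in cum.values())
    span_max = amax + total_gap_cols

    by_start: dict[int, list[ConservedWindow]] = {}
    for w in windows:
        by_start.setdefault(w.start, []).append(w)

    best_key: tuple | None = None
    best: tuple[ConservedWindow, ConservedWindow] | None = None
    for fw in windows:
        if not window_gc_ok(fw):
            failures["gc_max"] += 1
            continue
        lo_start = fw.start + fw.length
        hi_start = fw.start + span_max
        for rs in range(lo_start, min(hi_start, alignment.length) + 1):
            for rv in by_start.get(rs, ()):
                sizes = [
                    int(c[rv.start + rv.length] - c[fw.start]) for c in cum.values()
                ]
                if not all(amin <= s <= amax for s in sizes):
                    failures["amplicon_size"] += 1
                    continue
                if not window_gc_ok(rv):
                    failures["gc_max"] += 1
                    continue
                delta = abs(window_tm_mid(fw) - window_tm_mid(rv))
                if delta > constraints.tm_pair_delta_max:
                    failures["tm_pair_delta"] += 1
                    continue
                key = (
                    fw.degeneracy * rv.degeneracy,
                    delta,
                    fw.start,
                    rv.start,
                    fw.length,
                    rv.length,
                )
                if best_key is None or key < best_key:
                    best_key, best = key, (fw, rv)
    if best is None:
        worst = failures.most_common(1)
        detail = f"; most frequent violation: {worst[0][0]} ({worst[0][1]}x)" if worst else ""
        raise InfeasibleDesignError(f"no feasible window pair{detail}")

    fw, rv = best
    fseq = window_seq(fw)
    rseq = reverse_complement(window_seq(rv))
    template_id = "|".join(alignment.ids)
    forward = DegeneratePrimer(
        name="consensus_U", sequence=fseq, orientation="upstream",
        intended_targets=alignment.ids,
    )
    reverse = DegeneratePrimer(
        name="consensus_D", sequence=rseq, orientation="downstream",
        intended_targets=alignment.ids,
    )
    sizes = [int(c[rv.start + rv.length] - c[fw.start]) for c in cum.values()]
    return PrimerPair(
        forward=forward,
        reverse=reverse,
        template_id=template_id,
        product_size=max(sizes),
        tm_delta=float(best_key[1]),
    )


def _window_stats(seq: str, lengths: Sequence[int], params: ThermoParams):
    """Per-start GC% (exact, unrounded) and Tm arrays for each window length."""
    arr = np.frombuffer(seq.encode(), np.uint8)
    is_gc = np.isin(arr, np.frombuffer(b"GC", np.uint8)).astype(np.int64)
    cum = np.concatenate([[0], np.cumsum(is_gc)])
    stats = {}
    for L in lengths:
        n = len(seq) - L + 1
        if n <= 0:
            stats[L] = (np.empty(0), np.empty(0))
            continue
        gc = (cum[L:] - cum[:-L]) * 100.0 / L
        tm = np.array([melting_temperature(seq[i : i + L], params) for i in range(n)])
        stats[L] = (gc, tm)
    return stats


def design_approach_B(
    genes: Sequence[tuple[str, str]],
    constraints: DesignConstraints | None = None,
    params: ThermoParams | None = None,
) -> PrimerPanel:
    """One non-degenerate pair per gene, all sharing one product size.

    The common size S is searched exhaustively over the amplicon range;
    chosen to maximize the number of designable genes, ties broken by
    smaller total |GC - target| penalty, then total Tm spread, then
    smaller S.  Genes with no feasible pair at the chosen S are listed in
    ``infeasible`` rather than silently dropped.
    """
    constraints = constraints or DesignConstraints()
    params = params or DEFAULT_PARAMS
    if not genes:
        raise ValueError("need at least one gene")
    lmin, lmax = constraints.primer_len
    amin, amax = constraints.amplicon_len
    lengths = tuple(range(lmin, lmax + 1))
    target = constraints.gc_target

    stats = {}
    for gid, seq in genes:
        seq = seq.upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"gene {gid!r}: non-ACGTN characters {sorted(bad)}")
        stats[gid] = (seq, _window_stats(seq, lengths, params))

    def best_pair_for(gid: str, S: int):
        """Minimal-penalty (i, lf, lr) pair with product size exactly S."""
        seq, per_len = stats[gid]
        best = None
        for lf in lengths:
            gcf_all, tmf_all = per_len[lf]
            for lr in lengths:
                if S - lr < lf:  # primers must not overlap
                    continue
                gcr_all, tmr_all = per_len[lr]
                n = len(seq) - S + 1
                if n <= 0:
                    continue
                i = np.arange(n)
                j = i + S - lr
                gcf, tmf = gcf_all[i], tmf_all[i]
                gcr, tmr = gcr_all[j], tmr_all[j]
                delta = np.abs(tmf - tmr)
                ok = (
                    (gcf <= constraints.gc_max)
                    & (gcr <= constraints.gc_max)
                    & (delta <= constraints.tm_pair_delta_max)
                )
                if not ok.any():
                    continue
                pen = np.abs(gcf - target) + np.abs(gcr - target)
                idx = np.nonzero(ok)[0]
                order = np.lexsort((idx, delta[idx], pen[idx]))
                k = idx[order[0]]
                cand = (float(pen[k]), float(delta[k]), int(k), lf, lr)
                if best is None or cand < best:
                    best = cand
        return best

    per_size: dict[int, dict[str, tuple]] = {}
    for S in range(amin, amax + 1):
        found = {}
        for gid, _ in genes:
            bp = best_pair_for(gid, S)
            if bp is not None:
                found[gid] = bp
        per_size[S] = found

    def size_key(S: int):
        found = per_size[S]
        return (
            -len(found),
            sum(v[0] for v in found.values()),  # total |GC - target|
            sum(v[1] for v in found.values()),  # total Tm delta
            S,
        )

    S_best = min(range(amin, amax + 1), key=size_key)
    chosen = per_size[S_best]
    if not chosen:
        raise InfeasibleDesignError(
            f"no common product size in [{amin}, {amax}] is feasible for any gene"
        )

    pairs = []
    infeasible = []
    for gid, _ in genes:
        if gid not in chosen:
            infeasible.append(gid)
            continue
        _, delta, i, lf, lr = chosen[gid]
        seq, _ = stats[gid]
        j = i + S_best - lr
        forward = DegeneratePrimer(
            name=f"{gid}_U", sequence=seq[i : i + lf], orientation="upstream",
            intended_targets=(gid,),
        )
        reverse = DegeneratePrimer(
            name=f"{gid}_D", sequence=reverse_complement(seq[j : j + lr]),
            orientation="downstream", intended_targets=(gid,),
        )
        pairs.append(
            PrimerPair(
                forward=forward, reverse=reverse, template_id=gid,
                product_size=S_best, tm_delta=float(delta),
            )
        )
    return PrimerPanel(
        pairs=tuple(pairs),
        approach="B",
        common_product_size=S_best,
        infeasible=tuple(infeasible),
    )


def validate_pair(
    pair: PrimerPair, constraints: DesignConstraints | None = None
) -> list[str]:
    """Constraint-violation report for a pair; empty means compliant.

    Violations are data, not exceptions: a published pair that breaks a
    rule is still representable.
    """
    constraints = constraints or DesignConstraints()
    lmin, lmax = constraints.primer_len
    amin, amax = constraints.amplicon_len
    violations = []
    for primer in (pair.forward, pair.reverse):
        L = len(primer.sequence)
        if not (lmin <= L <= lmax):
            violations.append(f"primer_length: {primer.name} is {L} nt, allowed [{lmin}, {lmax}]")
        if gc_content(primer.sequence)[1] > constraints.gc_max:
            violations.append(
                f"gc_max: {primer.name} exceeds {constraints.gc_max:g}% GC"
            )
    if not (amin <= pair.product_size <= amax):
        violations.append(
            f"amplicon_size: {pair.product_size} bp, allowed [{amin}, {amax}]"
        )
    if pair.tm_delta > constraints.tm_pair_delta_max:
        violations.append(
            f"tm_pair_delta: {pair.tm_delta:.1f} C exceeds {constraints.tm_pair_delta_max:g} C"
        )
    return violations


def recommend_approach(identity_score: float) -> str:
    """Route a family to a design approach by its percent-identity score.

    Scores of 75% and above use approach A (consensus/degenerate); below
    75%, approach B (unique per-gene pairs).  The boundary score routes to
    A by decision.
    """
    if not (0.0 <= identity_score <= 100.0):
        raise ValueError(f"identity score must be in [0, 100], got {identity_score}")
    return "A" if identity_score >= APPROACH_CUTOFF else "B"
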