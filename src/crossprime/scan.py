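"""Genome-wide in-silico primer binding search and amplicon prediction.

A binding site is an ungapped, full-length alignment of one concrete
primer expansion against the template (no insertion/deletion states).  A
window is reported only if it satisfies every rule:

* at least ``min_matched`` matched bases (18 by default; 17 in control
  mode for validating short primers),
* at most ``max_mismatches`` mismatches (3),
* no two consecutive mismatches,
* the 3' terminal base matches, and the 5' terminal base matches,
* the mismatch-penalized duplex temperature falls inside ``tm_window``
  (30-100 deg C).

The joint match/mismatch constraints imply every reported site has a
primer-template identity strictly above 80%.  Degenerate primers are
evaluated through their expansions; each (position, strand) is reported
once with its best expansion.  Template N never matches any primer base.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio import Feature, GenomeRecord, collapse_product_label
from .thermo import (
    DEFAULT_PARAMS,
    DegeneratePrimer,
    ThermoParams,
    expand_degenerate,
    melting_temperature,
    reverse_complement,
)

__all__ = [
    "ScanRules",
    "CONTROL_RULES",
    "BindingSite",
    "AmpliconPrediction",
    "IDENTITY_BINS",
    "TM_BINS",
    "scan_primer",
    "classify_identity",
    "classify_tm",
    "site_tm",
    "predict_amplicons",
    "annotate_sites",
    "summarize_hits",
]


@dataclass(frozen=True)
class ScanRules:
    """Binding-site acceptance rules (defaults are the audit's stated ones)."""

    min_matched: int = 18
    max_mismatches: int = 3
    forbid_consecutive_mismatches: bool = True
    require_3prime_match: bool = True
    exclude_5prime_mismatch: bool = True
    tm_window: tuple[float, float] = (30.0, 100.0)
    max_product_size: int = 5000
    max_degeneracy: int = 4096

    def __post_init__(self) -> None:
        if self.min_matched < 1:
            raise ValueError("min_matched must be >= 1")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if self.tm_window[0] >= self.tm_window[1]:
            raise ValueError("tm_window min must be < max")


#: Control-target mode: binding may be as short as 17 matched bases.
CONTROL_RULES = ScanRules(min_matched=17)


@dataclass
class BindingSite:
    """One primer-template hit.

    ``start``/``end`` are 0-based half-open template coordinates of the
    bound region regardless of strand; ``mismatch_positions`` are 1-based
    primer coordinates counted from the primer's 5' end.
    """

    primer_name: str
    expansion_used: str
    genome_id: str
    start: int
    end: int
    strand: str
    matches: int
    mismatches: int
    identity: float
    duplex_tm: float
    mismatch_positions: tuple[int, ...]
    target_locus: str | None = None
    target_product: str | None = None


@dataclass(frozen=True)
class AmpliconPrediction:
    """A convergent forward/reverse site pair and its product size."""

    forward_site: BindingSite
    reverse_site: BindingSite
    product_size: int
    intended: bool
    target_locus: str = "noncoding region"


def _as_primer(primer: "DegeneratePrimer | str") -> DegeneratePrimer:
    if isinstance(primer, DegeneratePrimer):
        return primer
    return DegeneratePrimer(name="primer", sequence=primer)


def _as_genome(genome: "GenomeRecord | str") -> GenomeRecord:
    if isinstance(genome, GenomeRecord):
        return genome
    return GenomeRecord(id="template", description="", sequence=genome.upper())


def scan_primer(
    primer: "DegeneratePrimer | str",
    genome: "GenomeRecord | str",
    rules: ScanRules | None = None,
    params: ThermoParams | None = None,
) -> list[BindingSite]:
    """All rule-compliant binding sites of a primer on both template strands.

    Degenerate primers are scanned through every expansion; a given
    (position, strand) is reported once, keeping the expansion with the
    most matches (ties: lexicographically smallest expansion).  Sites are
    sorted by template position, then strand.
    """
    rules = rules or ScanRules()
    params = params or DEFAULT_PARAMS
    primer = _as_primer(primer)
    genome = _as_genome(genome)
    L = len(primer.sequence)
    G = len(genome.sequence)
    if G < L:
        return []
    expansions = expand_degenerate(primer.sequence, rules.max_degeneracy)

    plus = np.frombuffer(genome.sequence.encode(), np.uint8)
    minus = np.frombuffer(reverse_complement(genome.sequence).encode(), np.uint8)
    win_plus = np.lib.stride_tricks.sliding_window_view(plus, L)
    win_minus = np.lib.stride_tricks.sliding_window_view(minus, L)

    best: dict[tuple[int, str], tuple[int, str, np.ndarray, float]] = {}
    for expansion in expansions:
        exp_tm = melting_temperature(expansion, params)
        exp_bytes = np.frombuffer(expansion.encode(), np.uint8)
        for strand, wins in (("+", win_plus), ("-", win_minus)):
            eq = wins == exp_bytes
            matches = eq.sum(axis=1)
            mism = L - matches
            ok = (matches >= rules.min_matched) & (mism <= rules.max_mismatches)
            if rules.exclude_5prime_mismatch:
                ok &= eq[:, 0]
            if rules.require_3prime_match:
                ok &= eq[:, -1]
            if rules.forbid_consecutive_mismatches and L > 1:
                ok &= ~((~eq[:, :-1]) & (~eq[:, 1:])).any(axis=1)
            tm = exp_tm - params.mismatch_penalty * mism
            ok &= (tm >= rules.tm_window[0]) & (tm <= rules.tm_window[1])
            for p in np.nonzero(ok)[0]:
                p = int(p)
                start = p if strand == "+" else G - p - L
                key = (start, strand)
                cand = (int(matches[p]), expansion, eq[p], float(tm[p]))
                prev = best.get(key)
                if (
                    prev is None
                    or cand[0] > prev[0]
                    or (cand[0] == prev[0] and cand[1] < prev[1])
                ):
                    best[key] = cand
    sites = []
    for (start, strand), (nmatch, expansion, eqrow, tm) in sorted(best.items()):
        mism_pos = tuple(int(i) + 1 for i in np.nonzero(~eqrow)[0])
        sites.append(
            BindingSite(
                primer_name=primer.name,
                expansion_used=expansion,
                genome_id=genome.id,
                start=start,
                end=start + L,
                strand=strand,
                matches=nmatch,
                mismatches=L - nmatch,
                identity=nmatch * 100.0 / L,
                duplex_tm=tm,
                mismatch_positions=mism_pos,
            )
        )
    return sites


IDENTITY_BINS = ("100%", "90.0-99.9%", "80.0-89.9%")


def classify_identity(site: "BindingSite | float") -> str:
    """Identity bin of a site: {100%} / [90, 100) / (80, 90), on identity
    rounded to 0.1."""
    value = site.identity if isinstance(site, BindingSite) else float(site)
    v = round(value, 1)
    if v >= 100.0:
        return IDENTITY_BINS[0]
    if v >= 90.0:
        return IDENTITY_BINS[1]
    if v > 80.0:
        return IDENTITY_BINS[2]
    raise ValueError(f"identity {value} <= 80% cannot arise from a compliant scan")


TM_BINS = ("<=49.9", "50.0-54.9", "55.0-59.9", "60.0-64.9", "65.0-69.9", ">=70.0")


def classify_tm(site: "BindingSite | float") -> str:
    """5-degree melting-temperature bin of a site."""
    value = site.duplex_tm if isinstance(site, BindingSite) else float(site)
    if value < 50.0:
        return TM_BINS[0]
    if value >= 70.0:
        return TM_BINS[5]
    return TM_BINS[1 + int((value - 50.0) // 5.0)]


def site_tm(site: BindingSite, params: ThermoParams | None = None) -> float:
    """Mismatch-penalized duplex temperature of a site.

    Defined as the perfect-duplex Tm of the expansion minus a flat penalty
    per mismatch (default 5 deg C, configurable to 0 to disable); never
    exceeds the perfect-duplex Tm.
    """
    params = params or DEFAULT_PARAMS
    return melting_temperature(site.expansion_used, params) - params.mismatch_penalty * site.mismatches


def predict_amplicons(
    sites_forward: Sequence[BindingSite],
    sites_reverse: Sequence[BindingSite],
    rules: ScanRules | None = None,
    intended_window: tuple[int, int] = (180, 240),
    intended_features: Sequence[Feature] | None = None,
    features: Sequence[Feature] | None = None,
) -> list[AmpliconPrediction]:
    """Convergent forward/reverse site pairs that would yield a PCR product.

    A product forms only from sites on opposite strands of the same genome
    with 3' ends facing (the plus-strand site upstream of the minus-strand
    site) and a product no longer than ``max_product_size``.  Same-strand
    or divergent site pairs never amplify — two primers bound at the same
    location and orientation cannot produce a product.  Product size spans
    the plus-strand 5' end to the minus-strand 5' end inclusively.

    ``intended`` is set when the size falls in ``intended_window`` and, if
    ``intended_features`` is given, the product span overlaps one of them.
    """
    rules = rules or ScanRules()
    ann = features if features is not None else intended_features
    out = []
    for f in sites_forward:
        for r in sites_reverse:
            if f.genome_id != r.genome_id or f.strand == r.strand:
                continue
            p, m = (f, r) if f.strand == "+" else (r, f)
            if not (p.start <= m.start and p.end <= m.end):
                continue  # divergent or crossed: 3' ends not facing
            size = m.end - p.start
            if size > rules.max_product_size:
                continue
            in_window = intended_window[0] <= size <= intended_window[1]
            if intended_features is not None:
                overlaps = any(
                    feat.start < m.end and feat.end > p.start
                    and feat.seq_id in ("", f.genome_id)
                    for feat in intended_features
                )
                intended = in_window and overlaps
            else:
                intended = in_window
            locus = "noncoding region"
            if ann:
                mid = (p.start + m.end - 1) // 2
                for feat in sorted(ann, key=lambda x: (x.start, x.end)):
                    if feat.seq_id in ("", f.genome_id) and feat.start <= mid < feat.end:
                        locus = feat.locus_tag
                        break
            out.append(
                AmpliconPrediction(
                    forward_site=f,
                    reverse_site=r,
                    product_size=size,
                    intended=intended,
                    target_locus=locus,
                )
            )
    out.sort(key=lambda a: (a.forward_site.genome_id, a.forward_site.start, a.product_size))
    return out


def annotate_sites(
    sites: Iterable[BindingSite], features: Sequence[Feature]
) -> list[BindingSite]:
    """Assign each site the feature whose interval contains its midpoint.

    Sites in intergenic spans are labeled "noncoding region"; umbrella
    'unknown function' product labels are collapsed to one category.
    """
    feats = sorted(features, key=lambda f: (f.start, f.end))
    out = []
    for site in sites:
        mid = (site.start + site.end - 1) // 2
        locus, product = "noncoding region", "noncoding region"
        for feat in feats:
            if feat.seq_id not in ("", site.genome_id):
                continue
            if feat.start <= mid < feat.end:
                locus = feat.locus_tag
                product = collapse_product_label(feat.product)
                break
        out.append(replace_site(site, target_locus=locus, target_product=product))
    return out


def replace_site(site: BindingSite, **kw) -> BindingSite:
    return replace(site, **kw)


def summarize_hits(
    panel: Sequence[DegeneratePrimer],
    genomes: Sequence[GenomeRecord],
    rules: ScanRules | None = None,
    params: ThermoParams | None = None,
    features: Mapping[str, Sequence[Feature]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-primer hit counts by identity bin, plus the full hit edge list.

    Returns ``(counts, edges)``: ``counts`` is indexed by primer name with
    one column per identity bin; ``edges`` has one row per binding site
    (primer, genome, locus, product, identity bin, Tm bin, strand, 1-based
    position).  Ordering is deterministic: panel order, then genome order,
    then template position.
    """
    rules = rules or ScanRules()
    params = params or DEFAULT_PARAMS
    counts = pd.DataFrame(
        0, index=[p.name for p in panel], columns=list(IDENTITY_BINS), dtype=int
    )
    counts.index.name = "primer"
    edge_rows = []
    for primer in panel:
        for genome in genomes:
            sites = scan_primer(primer, genome, rules, params)
            if features and genome.id in features:
                sites = annotate_sites(sites, features[genome.id])
            for s in sites:
                ibin = classify_identity(s)
                counts.loc[primer.name, ibin] += 1
                edge_rows.append(
                    {
                        "primer": s.primer_name,
                        "genome": s.genome_id,
                        "locus": s.target_locus or "noncoding region",
                        "product": s.target_product or "noncoding region",
                        "identity_bin": ibin,
                        "tm_bin": classify_tm(s),
                        "strand": s.strand,
                        "position": s.start + 1,  # reported 1-based inclusive
                        "identity": round(s.identity, 1),
                        "tm": round(s.duplex_tm, 1),
                    }
                )
    edges = pd.DataFrame(
        edge_rows,
        columns=[
            "primer", "genome", "locus", "product", "identity_bin",
            "tm_bin", "strand", "position", "identity", "tm",
        ],
    )
    return counts, edges
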