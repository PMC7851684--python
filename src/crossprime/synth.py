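"""Synthetic communities with known ground truth.

Every stage of the workflow is testable without downloads: this module
fabricates gene families with controlled pairwise divergence, random
genome backgrounds at a chosen GC content, planted primer-binding sites
with specified mismatch structure, and truth tables recording what a
compliant scanner must and must not report.

The mutation model is substitution-only (each site of each copy mutates
independently with probability ``divergence``, uniformly over the three
alternative bases), so planted identities are exact arithmetic and the
expected pairwise identity has the closed form

    E[identity] = 1 - 2 d (1 - d) - d^2 * 2/3

for two copies independently derived from one ancestor.  All randomness
flows from explicit seeds; no global random state is touched.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .design import DesignConstraints, design_approach_B
from .scan import ScanRules
from .seqio import Feature, GenomeRecord, PrimerRow, write_fasta, write_primer_table
from .thermo import DegeneratePrimer, expand_degenerate, reverse_complement

__all__ = [
    "SimConfig",
    "PlantedSiteSpec",
    "TruthSite",
    "DECOY_RULES",
    "expected_pairwise_identity",
    "random_background",
    "simulate_gene_family",
    "plant_sites",
    "make_test_community",
]

_BASES = np.frombuffer(b"ACGT", np.uint8)

#: Named rules a decoy site may violate (exactly one each).
DECOY_RULES = (
    "adjacent_mismatches",
    "three_prime_mismatch",
    "five_prime_mismatch",
    "too_many_mismatches",
)


@dataclass(frozen=True)
class PlantedSiteSpec:
    """One site to write into a background: compliant (decoy=None) or a
    decoy violating exactly the named rule."""

    mismatches: int = 0
    position: int | None = None
    strand: str = "+"
    decoy: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be + or -")
        if self.decoy is not None and self.decoy not in DECOY_RULES:
            raise ValueError(f"unknown decoy rule {self.decoy!r}; known: {DECOY_RULES}")


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    Defaults emulate the shape of the motivating problem: a six-member
    community carrying one shared gene family whose pairwise divergence
    (0.2 substitutions/site, ~65% pairwise identity) sits in the range
    observed for efflux-pump families, embedded in 50 kb backgrounds at
    50% GC (desk-scaled stand-ins for full genomes).
    """

    seed: int
    n_genes: int = 6
    gene_len: int = 1500
    divergence: float = 0.2
    background_len: int = 50_000
    background_gc: float = 50.0
    planted_sites: tuple[PlantedSiteSpec, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.divergence < 1.0):
            raise ValueError("divergence must be in [0, 1)")
        if not (0.0 <= self.background_gc <= 100.0):
            raise ValueError("background_gc must be a percentage")
        if self.n_genes < 1 or self.gene_len < 1 or self.background_len < 1:
            raise ValueError("counts and lengths must be positive")


@dataclass(frozen=True)
class TruthSite:
    """Ground truth for one planted site (0-based half-open coordinates)."""

    primer_name: str
    start: int
    end: int
    strand: str
    mismatches: int
    mismatch_positions: tuple[int, ...]
    compliant: bool
    violated_rule: str | None = None


def expected_pairwise_identity(divergence: float) -> float:
    """Closed-form expected pairwise % identity of two independent copies."""
    d = divergence
    return 100.0 * (1.0 - 2.0 * d * (1.0 - d) - d * d * 2.0 / 3.0)


def random_background(length: int, gc: float, rng: np.random.Generator) -> str:
    p_gc = gc / 100.0
    probs = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]
    return rng.choice(_BASES, size=length, p=probs).tobytes().decode("ascii")


def simulate_gene_family(config: SimConfig) -> tuple[list[tuple[str, str]], float]:
    """Draw an ancestor and ``n_genes`` independently mutated copies.

    Returns the copies and the closed-form expected pairwise identity.
    Deterministic per seed; same seed, byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    p_gc = config.background_gc / 100.0
    probs = np.array([(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2])
    ancestor = rng.choice(_BASES, size=config.gene_len, p=probs)
    copies = []
    for i in range(config.n_genes):
        copy = ancestor.copy()
        mutate = rng.random(config.gene_len) < config.divergence
        for pos in np.nonzero(mutate)[0]:
            alternatives = _BASES[_BASES != copy[pos]]
            copy[pos] = rng.choice(alternatives)
        copies.append((f"gene_{i + 1:02d}", copy.tobytes().decode("ascii")))
    return copies, expected_pairwise_identity(config.divergence)


def _mismatch_positions(
    L: int, n: int, rng: np.random.Generator, rules: ScanRules
) -> tuple[int, ...]:
    """n scattered internal non-adjacent 1-based positions in [2, L-1]."""
    max_allowed = min(rules.max_mismatches, L - rules.min_matched)
    if n > max_allowed:
        raise ValueError(
            f"{n} mismatches on a {L}-mer violates the scan rules "
            f"(max {max_allowed} allowed)"
        )
    if n == 0:
        return ()
    for _ in range(1000):
        pos = sorted(rng.choice(np.arange(2, L), size=n, replace=False).tolist())
        if all(b - a >= 2 for a, b in zip(pos, pos[1:])):
            return tuple(int(p) for p in pos)
    raise RuntimeError("could not place non-adjacent mismatches")


def _decoy_positions(L: int, rule: str, rng: np.random.Generator) -> tuple[int, ...]:
    if rule == "adjacent_mismatches":
        k = int(rng.integers(3, L - 1))  # internal, keeps both termini matched
        return (k, k + 1)
    if rule == "three_prime_mismatch":
        return (L,)
    if rule == "five_prime_mismatch":
        return (1,)
    if rule == "too_many_mismatches":
        # scattered non-adjacent internal mismatches, one more than allowed
        pos = list(range(3, L - 1, 2))[:4]
        return tuple(pos)
    raise ValueError(rule)


def _apply_mismatches(
    word: str, positions: Sequence[int], rng: np.random.Generator
) -> str:
    arr = np.frombuffer(word.encode(), np.uint8).copy()
    for p in positions:
        current = arr[p - 1]
        alternatives = _BASES[_BASES != current]
        arr[p - 1] = rng.choice(alternatives)
    return arr.tobytes().decode("ascii")


def plant_sites(
    genome: str,
    primer: "DegeneratePrimer | str",
    specs: Sequence[PlantedSiteSpec],
    seed: int,
    rules: ScanRules | None = None,
) -> tuple[str, list[TruthSite]]:
    """Write binding words for ``primer`` into a background sequence.

    Compliant sites (decoy=None) carry scattered internal non-adjacent
    mismatches and are scanner-recoverable by construction; decoys violate
    exactly the named rule and must never be reported at their planted
    coordinates.  Overlapping placements are an error.
    """
    rules = rules or ScanRules()
    rng = np.random.default_rng(seed)
    if isinstance(primer, str):
        primer = DegeneratePrimer(name="planted", sequence=primer)
    expansions = expand_degenerate(primer.sequence, rules.max_degeneracy)
    arr = np.frombuffer(genome.upper().encode(), np.uint8).copy()
    G, L = len(genome), len(primer.sequence)
    occupied: list[tuple[int, int]] = []
    truth: list[TruthSite] = []
    for spec in specs:
        expansion = expansions[int(rng.integers(len(expansions)))]
        if spec.decoy is None:
            positions = _mismatch_positions(L, spec.mismatches, rng, rules)
        else:
            positions = _decoy_positions(L, spec.decoy, rng)
        word = _apply_mismatches(expansion, positions, rng)
        if spec.strand == "-":
            word = reverse_complement(word)
        if spec.position is not None:
            start = spec.position
            if any(start < e and start + L > s for s, e in occupied):
                raise ValueError(f"planted site at {start} overlaps an earlier site")
        else:
            start = None
            for _ in range(1000):
                cand = int(rng.integers(0, G - L + 1))
                if not any(cand < e and cand + L > s for s, e in occupied):
                    start = cand
                    break
            if start is None:
                raise RuntimeError("could not place site without overlap")
        if start < 0 or start + L > G:
            raise ValueError(f"planted site [{start}, {start + L}) outside background")
        arr[start : start + L] = np.frombuffer(word.encode(), np.uint8)
        occupied.append((start, start + L))
        truth.append(
            TruthSite(
                primer_name=primer.name,
                start=start,
                end=start + L,
                strand=spec.strand,
                mismatches=len(positions),
                mismatch_positions=tuple(positions),
                compliant=spec.decoy is None,
                violated_rule=spec.decoy,
            )
        )
    return arr.tobytes().decode("ascii"), truth


_EFFLUX_PRODUCTS = (
    "RND efflux transporter",
    "multidrug efflux pump",
    "MFS multidrug transporter",
    "MATE family efflux transporter",
    "SMR multidrug resistance protein",
    "ABC multidrug efflux permease",
)

_DECOY_PRODUCTS = (
    "DNA polymerase III subunit alpha",
    "50S ribosomal protein L2",
    "cell division protein FtsZ",
)


def make_test_community(config: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Emit a multi-genome fixture exercising the full pipeline.

    One shared divergent gene family (one copy per genome, annotated with
    efflux keywords among decoy products), a per-gene primer panel
    designed by the unique-pair approach, and a truth table of the
    intended binding coordinates.  A manifest records the seed and
    configuration so the fixture regenerates bit-identically.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    family, expected_id = simulate_gene_family(
        dataclasses.replace(config, seed=int(rng.integers(2**31 - 1)))
    )
    panel = design_approach_B(family)
    pair_by_gene = {p.template_id: p for p in panel.pairs}

    genomes: list[GenomeRecord] = []
    features: list[Feature] = []
    truth_rows: list[dict] = []
    for i, (gid, gene_seq) in enumerate(family):
        genome_id = f"syn_genome_{i + 1:02d}"
        bg = random_background(config.background_len, config.background_gc, rng)
        glen = len(gene_seq)
        insert_at = int(rng.integers(0, config.background_len - glen + 1))
        gene_strand = "+" if rng.random() < 0.5 else "-"
        inserted = gene_seq if gene_strand == "+" else reverse_complement(gene_seq)
        seq = bg[:insert_at] + inserted + bg[insert_at + glen :]
        locus = f"SYN{i + 1:02d}_0001"
        features.append(
            Feature(
                locus_tag=locus,
                product=_EFFLUX_PRODUCTS[i % len(_EFFLUX_PRODUCTS)],
                feature_type="CDS",
                start=insert_at,
                end=insert_at + glen,
                strand=gene_strand,
                seq_id=genome_id,
            )
        )
        # decoy annotations on plain background, clear of the gene
        for d, product in enumerate(_DECOY_PRODUCTS):
            for _ in range(200):
                s = int(rng.integers(0, config.background_len - 900))
                if s + 900 <= insert_at or s >= insert_at + glen:
                    features.append(
                        Feature(
                            locus_tag=f"SYN{i + 1:02d}_{100 + d}",
                            product=product,
                            feature_type="CDS",
                            start=s,
                            end=s + 900,
                            strand="+",
                            seq_id=genome_id,
                        )
                    )
                    break
        genomes.append(GenomeRecord(id=genome_id, description="synthetic community member", sequence=seq))

        pair = pair_by_gene.get(gid)
        if pair is None:
            continue
        lf, lr = len(pair.forward.sequence), len(pair.reverse.sequence)
        i_f = gene_seq.find(pair.forward.sequence)
        j_r = gene_seq.find(reverse_complement(pair.reverse.sequence))
        for name, off, L, strand_on_gene in (
            (pair.forward.name, i_f, lf, "+"),
            (pair.reverse.name, j_r, lr, "-"),
        ):
            if gene_strand == "+":
                start, strand = insert_at + off, strand_on_gene
            else:
                start = insert_at + glen - (off + L)
                strand = "-" if strand_on_gene == "+" else "+"
            truth_rows.append(
                {
                    "primer": name,
                    "genome": genome_id,
                    "start": start,
                    "end": start + L,
                    "strand": strand,
                    "mismatches": 0,
                    "identity": 100.0,
                }
            )

    paths = {
        "fasta": out / "community.fasta",
        "gff3": out / "community.gff3",
        "primers": out / "primers.tsv",
        "truth": out / "truth.tsv",
        "manifest": out / "manifest.json",
    }
    write_fasta(genomes, paths["fasta"])
    _write_gff3(features, paths["gff3"])
    rows = []
    for pair in panel.pairs:
        for primer in (pair.forward, pair.reverse):
            rows.append(
                PrimerRow(
                    species=pair.template_id,
                    gene=pair.template_id,
                    orientation=primer.orientation,
                    sequence=primer.sequence,
                )
            )
    write_primer_table(rows, paths["primers"])
    pd.DataFrame(truth_rows).to_csv(paths["truth"], sep="\t", index=False)
    manifest = {
        "config": {
            **{k: v for k, v in dataclasses.asdict(config).items() if k != "planted_sites"},
            "planted_sites": [dataclasses.asdict(s) for s in config.planted_sites],
        },
        "expected_pairwise_identity": expected_id,
        "common_product_size": panel.common_product_size,
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths


def _write_gff3(features: Sequence[Feature], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in sorted(features, key=lambda x: (x.seq_id, x.start)):
            attrs = f"ID={f.locus_tag};locus_tag={f.locus_tag};product={f.product}"
            fh.write(
                "\t".join(
                    [
                        f.seq_id,
                        "crossprime_synth",
                        f.feature_type,
                        str(f.start + 1),  # GFF3 is 1-based inclusive
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
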