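"""Reading and writing the workflow's standard formats.

Genomes arrive as FASTA, annotations as GenBank flat files or GFF3, and
primer panels as TSV tables (columns: species, gene, orientation, sequence,
tm, gc).  Internal coordinates are 0-based half-open throughout; anything
printed for a reader is 1-based inclusive.

Genome sequences are restricted to {A, C, G, T, N}: ambiguity codes other
than N are rejected at parse time, and N never matches any primer base
during scanning.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib.resources import files as _pkg_files
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .thermo import DegeneratePrimer, IUPAC_CODES, reverse_complement

__all__ = [
    "Feature",
    "GenomeRecord",
    "PrimerRow",
    "DEFAULT_KEYWORDS",
    "HYPOTHETICAL_LABELS",
    "collapse_product_label",
    "read_fasta",
    "write_fasta",
    "read_annotations",
    "search_features",
    "extract_gene_sequence",
    "read_primer_table",
    "write_primer_table",
    "load_panel",
    "panel_primers",
]

_GENOME_ALPHABET = frozenset("ACGTN")

#: Annotation keywords used to retrieve efflux-pump candidates.
DEFAULT_KEYWORDS = (
    "multidrug",
    "efflux",
    "transporter",
    "outer membrane",
    "inner membrane",
    "resistance",
)

#: Umbrella annotation labels collapsed to a single category in reports.
HYPOTHETICAL_LABELS = frozenset(
    {
        "hypothetical protein",
        "conserved hypothetical protein",
        "conserved protein of unknown function",
        "conserved exported protein of unknown function",
    }
)


def collapse_product_label(product: str) -> str:
    """Collapse the various 'unknown function' labels to one category."""
    if product.strip().lower() in HYPOTHETICAL_LABELS:
        return "hypothetical protein"
    return product


@dataclass(frozen=True)
class Feature:
    """An annotated genome feature in 0-based half-open coordinates."""

    locus_tag: str
    product: str
    feature_type: str
    start: int
    end: int
    strand: str
    seq_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid feature interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand symbol {self.strand!r} for {self.locus_tag!r}")


@dataclass
class GenomeRecord:
    """A named nucleotide sequence plus its annotated features."""

    id: str
    description: str
    sequence: str
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"genome {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a (multi-)FASTA of genome sequences.

    Sequences are uppercased, U is normalized to T, and any residue outside
    {A, C, G, T, N} is an error naming the offending record and position.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        for i, ch in enumerate(seq):
            if ch not in _GENOME_ALPHABET:
                raise ValueError(
                    f"record {rec.id!r}: non-IUPAC genome character {ch!r} at position {i + 1}"
                )
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(GenomeRecord(id=rec.id, description=rec.description, sequence=seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 70) -> None:
    recs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def _genbank_features(path: str | Path) -> list[Feature]:
    out: list[Feature] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        length = len(rec.seq)
        for feat in rec.features:
            if feat.type == "source":
                continue
            start, end = int(feat.location.start), int(feat.location.end)
            if end > length:
                raise ValueError(
                    f"feature end {end} beyond sequence length {length} in {rec.id!r}"
                )
            if feat.location.strand == 1:
                strand = "+"
            elif feat.location.strand == -1:
                strand = "-"
            else:
                raise ValueError(f"unknown strand for feature at [{start}, {end}) in {rec.id!r}")
            quals = feat.qualifiers
            out.append(
                Feature(
                    locus_tag=quals.get("locus_tag", [""])[0],
                    product=quals.get("product", [""])[0],
                    feature_type=feat.type,
                    start=start,
                    end=end,
                    strand=strand,
                    seq_id=rec.id,
                )
            )
    return out


def _gff3_features(path: str | Path, genome_lengths: dict[str, int] | None) -> list[Feature]:
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
        id_spec=["ID", "locus_tag", "Name"],
    )
    out: list[Feature] = []
    for feat in db.all_features():
        if feat.strand not in ("+", "-"):
            raise ValueError(
                f"unknown strand symbol {feat.strand!r} for feature {feat.id!r}"
            )
        start, end = feat.start - 1, feat.end  # GFF3 is 1-based inclusive
        if genome_lengths is not None and feat.seqid in genome_lengths:
            if end > genome_lengths[feat.seqid]:
                raise ValueError(
                    f"feature end {end} beyond sequence length "
                    f"{genome_lengths[feat.seqid]} in {feat.seqid!r}"
                )
        attrs = feat.attributes
        locus = (attrs.get("locus_tag") or attrs.get("ID") or [""])[0]
        product = (attrs.get("product") or [""])[0]
        out.append(
            Feature(
                locus_tag=locus,
                product=product,
                feature_type=feat.featuretype,
                start=start,
                end=end,
                strand=feat.strand,
                seq_id=feat.seqid,
            )
        )
    return out


def read_annotations(
    path: str | Path,
    format: str = "gff3",
    genome_lengths: dict[str, int] | None = None,
) -> list[Feature]:
    """Read features from a GenBank flat file or GFF3.

    Coordinates are converted to 0-based half-open; product strings are
    retained verbatim.  For GFF3, bounds are checked against
    ``genome_lengths`` when provided (GenBank files carry their own length).
    """
    if format == "genbank":
        return _genbank_features(path)
    if format == "gff3":
        return _gff3_features(path, genome_lengths)
    raise ValueError(f"unknown annotation format {format!r}")


def search_features(
    features: Sequence[Feature], keywords: Sequence[str] = DEFAULT_KEYWORDS
) -> list[Feature]:
    """Case-insensitive substring search over product names and locus tags.

    Returns deduplicated features ordered by genome position; adding
    keywords can only grow the result.
    """
    if not keywords:
        raise ValueError("keywords must be non-empty")
    kws = [k.lower() for k in keywords]
    hits: dict[tuple, Feature] = {}
    for feat in features:
        haystacks = (feat.product.lower(), feat.locus_tag.lower())
        if any(kw in hs for kw in kws for hs in haystacks):
            hits.setdefault((feat.seq_id, feat.start, feat.end, feat.locus_tag, feat.feature_type), feat)
    return sorted(hits.values(), key=lambda f: (f.seq_id, f.start, f.end, f.locus_tag))


def extract_gene_sequence(genome: GenomeRecord, feature: Feature) -> str:
    """Gene sequence in coding orientation (minus-strand features reverse-complemented)."""
    if feature.end > len(genome.sequence):
        raise ValueError(
            f"feature [{feature.start}, {feature.end}) outside genome {genome.id!r} "
            f"of length {len(genome.sequence)}"
        )
    sub = genome.sequence[feature.start : feature.end]
    return reverse_complement(sub) if feature.strand == "-" else sub


# ---------------------------------------------------------------------------
# Primer tables


@dataclass(frozen=True)
class PrimerRow:
    """One row of a primer panel table.

    Stated Tm/GC are as printed by the source protocol, either a single
    value or a (min, max) range; None when the table leaves the cell empty.
    """

    species: str
    gene: str
    orientation: str
    sequence: str
    tm_min: float | None = None
    tm_max: float | None = None
    gc_min: float | None = None
    gc_max: float | None = None

    def __post_init__(self) -> None:
        if self.orientation not in ("upstream", "downstream"):
            raise ValueError(f"orientation must be upstream/downstream, got {self.orientation!r}")


_RANGE_RE = re.compile(r"^\s*([0-9.]+)\s*[-–]\s*([0-9.]+)\s*$")


def _parse_range(cell: str) -> tuple[float | None, float | None]:
    cell = (cell or "").strip()
    if not cell:
        return None, None
    m = _RANGE_RE.match(cell)
    if m:
        return float(m.group(1)), float(m.group(2))
    return float(cell), float(cell)


def _format_range(lo: float | None, hi: float | None) -> str:
    if lo is None:
        return ""
    if lo == hi:
        return f"{lo:g}"
    return f"{lo:g}-{hi:g}"


_REQUIRED_COLUMNS = ("species", "gene", "orientation", "sequence", "tm", "gc")


def read_primer_table(path: str | Path) -> list[PrimerRow]:
    """Read a primer panel TSV; whitespace in sequences is stripped."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"primer table missing columns: {missing}")
    rows: list[PrimerRow] = []
    for idx, rec in df.iterrows():
        line_no = idx + 2  # header is line 1
        seq = re.sub(r"\s+", "", rec["sequence"]).upper()
        bad = [c for c in seq if c not in IUPAC_CODES]
        if not seq or bad:
            raise ValueError(f"row {line_no}: invalid IUPAC sequence {rec['sequence']!r}")
        tm_lo, tm_hi = _parse_range(rec["tm"])
        gc_lo, gc_hi = _parse_range(rec["gc"])
        rows.append(
            PrimerRow(
                species=rec["species"],
                gene=rec["gene"],
                orientation=rec["orientation"],
                sequence=seq,
                tm_min=tm_lo,
                tm_max=tm_hi,
                gc_min=gc_lo,
                gc_max=gc_hi,
            )
        )
    return rows


def write_primer_table(rows: Iterable[PrimerRow], path: str | Path) -> None:
    rows = list(rows)
    df = pd.DataFrame(
        {
            "species": [r.species for r in rows],
            "gene": [r.gene for r in rows],
            "orientation": [r.orientation for r in rows],
            "sequence": [r.sequence for r in rows],
            "tm": [_format_range(r.tm_min, r.tm_max) for r in rows],
            "gc": [_format_range(r.gc_min, r.gc_max) for r in rows],
        }
    )
    df.to_csv(path, sep="\t", index=False)


_PANEL_FILES = {
    "mdrep": "mdrep_primers.tsv",
    "leuc": "leuc_primers.tsv",
    "16s": "universal_16s.tsv",
}


def load_panel(name: str) -> list[PrimerRow]:
    """Load a packaged primer panel: 'mdrep', 'leuc', or '16s'."""
    try:
        fname = _PANEL_FILES[name]
    except KeyError:
        raise ValueError(f"unknown panel {name!r}; known: {sorted(_PANEL_FILES)}") from None
    resource = _pkg_files("crossprime").joinpath("data", fname)
    with resource.open("r") as fh:  # type: ignore[call-arg]
        return read_primer_table(fh)


def _species_abbrev(species: str) -> str:
    parts = species.split()
    if len(parts) >= 2:
        return parts[0][0] + parts[-1]
    return species.replace(" ", "_")


def panel_primers(rows: Sequence[PrimerRow]) -> list[DegeneratePrimer]:
    """Convert table rows to named primers (name = species/gene/orientation)."""
    primers = []
    for r in rows:
        suffix = "U" if r.orientation == "upstream" else "D"
        if r.species == r.gene:
            name = f"{r.gene}_{suffix}"
        else:
            name = f"{_species_abbrev(r.species)}_{r.gene}_{suffix}"
        primers.append(
            DegeneratePrimer(
                name=name,
                sequence=r.sequence,
                orientation=r.orientation,
                intended_targets=(r.gene,),
            )
        )
    return primers
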