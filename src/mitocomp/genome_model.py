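"""Annotated circular mitogenome: data model, coordinate arithmetic, I/O.

Coordinates are 1-based and inclusive on both ends, the convention of
published mitogenome annotation tables.  Features may span the origin
(``end < start``).  The model does not force features to tile the
circle: published tables sometimes leave terminal nucleotides
unannotated, and those are preserved verbatim.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

from Bio import SeqIO
from Bio.Seq import Seq

from .gene_order import GeneOrder
from .vocab import (
    ALL_TOKENS,
    CATEGORY_OF,
    LABEL_OF,
    NCR_TOKEN,
    PCGS,
    RRNAS,
    TRNAS,
    _TRNA_BY_AA,
)


class FormatError(ValueError):
    """Malformed annotation table / sequence input."""


@dataclass(frozen=True)
class GeneFeature:
    """One gene (or non-coding region) on the circular genome."""

    name: str
    category: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str  # 'H' or 'L'
    start_codon: str | None = None
    stop_codon: str | None = None
    anticodon: str | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("H", "L"):
            raise FormatError(f"strand must be H or L, got {self.strand!r}")
        if self.category not in CATEGORY_OF.values() and self.category not in (
            "PCG", "tRNA", "rRNA", "CR", "NCR"
        ):
            raise FormatError(f"unknown category {self.category!r}")
        if self.start < 1 or self.end < 1:
            raise FormatError("coordinates are 1-based positive integers")


@dataclass
class MitoAnnotation:
    """Ordered gene features of one circular mitogenome."""

    species_id: str
    accession: str
    genome_length: int
    features: list[GeneFeature] = field(default_factory=list)
    circular: bool = True

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise FormatError("genome_length must be positive")
        names = [f.name for f in self.features]
        dup = {n for n in names if names.count(n) > 1}
        if dup:
            raise FormatError(f"duplicate gene name(s): {sorted(dup)}")
        for f in self.features:
            if not (1 <= f.start <= self.genome_length and 1 <= f.end <= self.genome_length):
                raise FormatError(
                    f"{f.name}: coordinates ({f.start},{f.end}) outside "
                    f"[1,{self.genome_length}]"
                )
        for cat, cap in (("CR", 1), ("NCR", 1)):
            if sum(f.category == cat for f in self.features) > cap:
                raise FormatError(f"more than one {cat} feature")
        self.features = sorted(self.features, key=lambda f: f.start)

    def __len__(self) -> int:
        return len(self.features)

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def is_complete(self) -> bool:
        """True if the full 37-gene complement (13 PCG + 22 tRNA + 2 rRNA)
        plus a control region is annotated.  The ambiguous tRNA(Lys|Asn)
        token K stands in for tRNA-Lys."""
        names = {f.name for f in self.features}
        return (
            set(PCGS) <= names
            and set(TRNAS) <= names
            and set(RRNAS) <= names
            and any(f.category == "CR" for f in self.features)
        )


@dataclass(frozen=True)
class SeqRecord:
    """Minimal uppercase-normalized nucleotide record."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError("empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# coordinate arithmetic


def gene_length(f: GeneFeature, genome_length: int) -> int:
    """Feature length in bp; origin-spanning features wrap the circle."""
    if f.end >= f.start:
        return f.end - f.start + 1
    return genome_length - f.start + 1 + f.end


def intergenic_spacer(prev: GeneFeature, nxt: GeneFeature, genome_length: int) -> int:
    """Nucleotides between two adjacent features (negative = overlap).

    ``nxt`` must be the circular successor of ``prev``; the last-to-first
    junction is measured across the origin.
    """
    if prev is nxt or (prev.name == nxt.name):
        raise FormatError("spacer of a feature with itself is undefined")
    d = nxt.start - prev.end - 1
    if nxt.start <= prev.start:  # wrapped around the origin
        d = nxt.start + genome_length - prev.end - 1
    return d


class SpacerTable(NamedTuple):
    entries: list[tuple[str, int]]  # (feature name, spacer to successor)
    n_overlaps: int
    n_positive: int
    largest: tuple[str, int] | None


def spacer_table(annotation: MitoAnnotation) -> SpacerTable:
    """Spacer of every feature to its circular successor, with the
    overlap / positive-interval counts reported alongside."""
    feats = annotation.features
    entries = []
    for i, f in enumerate(feats):
        nxt = feats[(i + 1) % len(feats)]
        if len(feats) == 1:
            break
        entries.append((f.name, intergenic_spacer(f, nxt, annotation.genome_length)))
    n_over = sum(1 for _, s in entries if s < 0)
    n_pos = sum(1 for _, s in entries if s > 0)
    largest = max(entries, key=lambda e: e[1]) if entries else None
    return SpacerTable(entries, n_over, n_pos, largest)


def extract_gene_order(annotation: MitoAnnotation) -> GeneOrder:
    """Signed gene order in genomic start order; the NCR becomes token O,
    L-strand features get a negative sign."""
    toks = []
    for f in annotation.features:
        tok = NCR_TOKEN if f.category == "NCR" else f.name
        toks.append(("-" if f.strand == "L" else "") + tok)
    return GeneOrder(tuple(toks), circular=annotation.circular)


def extract_gene_sequences(
    annotation: MitoAnnotation, record: SeqRecord
) -> dict[str, str]:
    """Per-gene sequences in reading orientation: L-strand genes are
    reverse-complemented, origin-spanning genes concatenated across the
    origin."""
    if len(record) != annotation.genome_length:
        raise FormatError(
            f"sequence length {len(record)} != genome_length {annotation.genome_length}"
        )
    seq = record.sequence
    out: dict[str, str] = {}
    for f in annotation.features:
        if f.end >= f.start:
            sub = seq[f.start - 1 : f.end]
        else:
            sub = seq[f.start - 1 :] + seq[: f.end]
        if f.strand == "L":
            sub = str(Seq(sub).reverse_complement())
        out[f.name] = sub
    return out


# ---------------------------------------------------------------------------
# feature-table dialect: UTF-8 TSV, '#'-comments, mandatory header

_COLUMNS = ["gene", "category", "start", "end", "strand",
            "start_codon", "stop_codon", "anticodon"]
_PRAGMA = re.compile(r"^#\s*(species|accession|genome_length|circular)\s*[:=]\s*(\S+)")


def read_feature_table(path) -> MitoAnnotation:
    """Read one genome's annotation from the tab-separated dialect."""
    meta: dict[str, str] = {}
    rows: list[dict[str, str]] = []
    header: list[str] | None = None
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                m = _PRAGMA.match(line)
                if m:
                    meta[m.group(1)] = m.group(2)
                continue
            cells = line.split("\t")
            if header is None:
                header = [c.strip() for c in cells]
                missing = [c for c in _COLUMNS[:5] if c not in header]
                if missing:
                    raise FormatError(f"header missing required column(s) {missing}")
                continue
            rows.append(dict(zip(header, cells)))
    if header is None or not rows:
        raise FormatError(f"no feature rows in {path}")
    if "genome_length" not in meta:
        raise FormatError("missing '# genome_length:' pragma")

    feats = []
    for r in rows:
        name = r["gene"].strip()
        if name not in ALL_TOKENS:
            raise FormatError(f"unknown gene token {name!r}")
        def opt(key: str) -> str | None:
            v = r.get(key, "").strip()
            return v or None if v not in ("-", "–", "") else None
        feats.append(
            GeneFeature(
                name=name,
                category=r["category"].strip(),
                start=int(r["start"]),
                end=int(r["end"]),
                strand=r["strand"].strip(),
                start_codon=opt("start_codon"),
                stop_codon=opt("stop_codon"),
                anticodon=opt("anticodon"),
                label=LABEL_OF.get(name),
            )
        )
    return MitoAnnotation(
        species_id=meta.get("species", "unknown"),
        accession=meta.get("accession", ""),
        genome_length=int(meta["genome_length"]),
        circular=meta.get("circular", "true").lower() != "false",
        features=feats,
    )


def write_feature_table(annotation: MitoAnnotation, path) -> None:
    """Writer inverse to :func:`read_feature_table` (bit-exact round trip
    up to comment lines)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# species: {annotation.species_id}\n")
        fh.write(f"# accession: {annotation.accession}\n")
        fh.write(f"# genome_length: {annotation.genome_length}\n")
        fh.write(f"# circular: {str(annotation.circular).lower()}\n")
        fh.write("\t".join(_COLUMNS) + "\n")
        for f in annotation.features:
            fh.write(
                "\t".join(
                    [
                        f.name, f.category, str(f.start), str(f.end), f.strand,
                        f.start_codon or "-", f.stop_codon or "-", f.anticodon or "-",
                    ]
                )
                + "\n"
            )


def write_bed(annotation: MitoAnnotation, path) -> None:
    """BED6 export (0-based half-open; strand column +/-).  Origin-spanning
    features are written as a single record running to the origin."""
    with open(path, "w", encoding="utf-8") as fh:
        for f in annotation.features:
            strand = "+" if f.strand == "H" else "-"
            end = f.end if f.end >= f.start else annotation.genome_length
            fh.write(
                f"{annotation.accession or annotation.species_id}\t{f.start - 1}\t"
                f"{end}\t{f.name}\t0\t{strand}\n"
            )


def to_zero_based(f: GeneFeature) -> tuple[int, int]:
    """(start, end) as 0-based half-open."""
    return f.start - 1, f.end


def from_zero_based(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


# ---------------------------------------------------------------------------
# FASTA / GenBank

def read_fasta(path) -> list[SeqRecord]:
    recs = [SeqRecord(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not recs:
        raise FormatError(f"no FASTA records in {path}")
    return recs


def write_fasta(records: Iterable[SeqRecord], path, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.sequence), width):
                fh.write(r.sequence[i : i + width] + "\n")


def write_gene_fastas(annotation: MitoAnnotation, record: SeqRecord, path) -> None:
    """One FASTA with one record per annotated gene."""
    seqs = extract_gene_sequences(annotation, record)
    write_fasta([SeqRecord(name, s) for name, s in seqs.items()], path)


_PCG_BY_PRODUCT = {
    "nadh dehydrogenase subunit 1": "ND1", "nadh dehydrogenase subunit 2": "ND2",
    "nadh dehydrogenase subunit 3": "ND3", "nadh dehydrogenase subunit 4": "ND4",
    "nadh dehydrogenase subunit 4l": "ND4L", "nadh dehydrogenase subunit 5": "ND5",
    "nadh dehydrogenase subunit 6": "ND6",
    "cytochrome c oxidase subunit i": "COX1", "cytochrome c oxidase subunit ii": "COX2",
    "cytochrome c oxidase subunit iii": "COX3",
    "atp synthase f0 subunit 6": "ATP6", "atp synthase f0 subunit 8": "ATP8",
    "cytochrome b": "CYTB",
}


def read_genbank(path) -> tuple[MitoAnnotation, SeqRecord]:
    """Best-effort import of a GenBank flat file (CDS / tRNA / rRNA /
    D-loop features) into the fixed vocabulary."""
    gb = next(SeqIO.parse(str(path), "genbank"))
    feats: list[GeneFeature] = []
    seen: set[str] = set()
    for ft in gb.features:
        name = _genbank_token(ft)
        if name is None or name in seen:
            continue
        seen.add(name)
        start = int(ft.location.start) + 1
        end = int(ft.location.end)
        strand = "L" if ft.location.strand == -1 else "H"
        feats.append(
            GeneFeature(
                name=name,
                category=CATEGORY_OF[name],
                start=start,
                end=end,
                strand=strand,
                label=LABEL_OF.get(name),
            )
        )
    ann = MitoAnnotation(
        species_id=gb.annotations.get("organism", gb.id),
        accession=gb.id,
        genome_length=len(gb.seq),
        features=feats,
    )
    return ann, SeqRecord(gb.id, str(gb.seq))


def _genbank_token(ft) -> str | None:
    q = ft.qualifiers
    gene = (q.get("gene", [""])[0] or q.get("product", [""])[0]).strip()
    low = gene.lower()
    if ft.type == "CDS":
        norm = low.replace("coi", "cox1").replace("nad", "nd").upper()
        norm = {"COB": "CYTB", "CYTB": "CYTB"}.get(norm, norm)
        if norm in PCGS:
            return norm
        return _PCG_BY_PRODUCT.get(q.get("product", [""])[0].strip().lower())
    if ft.type == "tRNA":
        m = re.search(r"trna[-_ ]?(\w{3})", low)
        if not m:
            return None
        aa = m.group(1).capitalize()
        if aa == "Leu":
            return "L1" if "cun" in low or "tag" in low else "L2"
        if aa == "Ser":
            return "S2" if "agy" in low or "gct" in low else "S1"
        return _TRNA_BY_AA.get(aa)
    if ft.type == "rRNA":
        if "12" in low or "small" in low:
            return "12S"
        if "16" in low or "large" in low:
            return "16S"
    if ft.type in ("D-loop", "misc_feature") and ("d-loop" in low or "control" in low or ft.type == "D-loop"):
        return "CR"
    return None
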