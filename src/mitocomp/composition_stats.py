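"""Nucleotide composition, strand skews, codon usage and RSCU.

All codon work uses the vertebrate mitochondrial genetic code
(translation table 2): AGA/AGG are stop codons, ATA is Met, TGA is Trp.
Skews follow the usual conventions AT skew = (A-T)/(A+T) and
GC skew = (G-C)/(G+C); ambiguity letters are excluded from every
denominator.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from Bio.Data import CodonTable

VERT_MITO = CodonTable.unambiguous_dna_by_id[2]
STOP_CODONS = frozenset(VERT_MITO.stop_codons)
#: sense codon -> one-letter amino acid
AA_OF = dict(VERT_MITO.forward_table)
#: amino acid -> synonymous family (sorted codons)
FAMILIES: dict[str, tuple[str, ...]] = {}
for _c, _a in sorted(AA_OF.items()):
    FAMILIES.setdefault(_a, ())
    FAMILIES[_a] = FAMILIES[_a] + (_c,)

_BASES = "ACGT"


class CompositionError(ValueError):
    pass


@dataclass
class CompositionSummary:
    pct_A: float
    pct_T: float
    pct_G: float
    pct_C: float
    pct_AT: float
    at_skew: float
    gc_skew: float
    total_length: int


@dataclass
class CodonUsage:
    counts: dict[str, int]
    rscu: dict[str, float] = field(default_factory=dict)
    amino_acid_totals: dict[str, int] = field(default_factory=dict)
    #: amino acids whose whole family is unobserved (RSCU reported as 0)
    absent_families: set[str] = field(default_factory=set)
    #: trailing 1-2 nt that do not form a codon (incomplete stop)
    remainder: str = ""


def at_skew(pct_a: float, pct_t: float) -> float:
    """(A-T)/(A+T); accepts counts or percentages."""
    if pct_a + pct_t <= 0:
        raise CompositionError("A+T is zero; AT skew undefined")
    return (pct_a - pct_t) / (pct_a + pct_t)


def gc_skew(pct_g: float, pct_c: float) -> float:
    """(G-C)/(G+C); accepts counts or percentages."""
    if pct_g + pct_c <= 0:
        raise CompositionError("G+C is zero; GC skew undefined")
    return (pct_g - pct_c) / (pct_g + pct_c)


def base_composition(sequence: str) -> CompositionSummary:
    """Base percentages and skews on the unambiguous-base denominator."""
    seq = sequence.upper()
    counts = Counter(b for b in seq if b in _BASES)
    n = sum(counts.values())
    if n == 0:
        raise CompositionError("no unambiguous bases in sequence")
    pct = {b: 100.0 * counts[b] / n for b in _BASES}
    ats = counts["A"] + counts["T"]
    gcs = counts["G"] + counts["C"]
    return CompositionSummary(
        pct_A=pct["A"], pct_T=pct["T"], pct_G=pct["G"], pct_C=pct["C"],
        pct_AT=pct["A"] + pct["T"],
        at_skew=at_skew(counts["A"], counts["T"]) if ats else float("nan"),
        gc_skew=gc_skew(counts["G"], counts["C"]) if gcs else float("nan"),
        total_length=n,
    )


def codon_counts(cds: str, frame: int = 0, strip_stops: bool = False) -> CodonUsage:
    """Codon counts of a CDS under the vertebrate mitochondrial code.

    A trailing 1-2 nt remainder (incomplete stop codon, completed by
    polyadenylation in vivo) is retained in ``remainder`` but never
    counted.  With ``strip_stops`` full stop codons are excluded too.
    Codons containing ambiguity letters are skipped.
    """
    if frame not in (0, 1, 2):
        raise CompositionError(f"frame must be 0, 1 or 2, got {frame}")
    seq = cds.upper()[frame:]
    if len(seq) < 3:
        raise CompositionError("CDS shorter than one codon")
    n_codons = len(seq) // 3
    counts: Counter[str] = Counter()
    for i in range(n_codons):
        codon = seq[3 * i : 3 * i + 3]
        if any(b not in _BASES for b in codon):
            continue
        if strip_stops and codon in STOP_CODONS:
            continue
        counts[codon] += 1
    usage = CodonUsage(counts=dict(counts), remainder=seq[3 * n_codons :])
    totals: Counter[str] = Counter()
    for codon, k in counts.items():
        if codon in AA_OF:
            totals[AA_OF[codon]] += k
    usage.amino_acid_totals = dict(totals)
    return usage


def rscu(usage: CodonUsage) -> CodonUsage:
    """Relative synonymous codon usage.

    RSCU(c) = count(c) / (mean count over c's synonymous family), so a
    family used uniformly has RSCU 1 for every member and the family sum
    equals the family size.  Fully unobserved families get RSCU 0 and
    are flagged in ``absent_families``.
    """
    values: dict[str, float] = {}
    absent: set[str] = set()
    totals: dict[str, int] = {}
    for aa, family in FAMILIES.items():
        total = sum(usage.counts.get(c, 0) for c in family)
        totals[aa] = total
        if total == 0:
            absent.add(aa)
            for c in family:
                values[c] = 0.0
            continue
        mean = total / len(family)
        for c in family:
            values[c] = usage.counts.get(c, 0) / mean
    return CodonUsage(
        counts=dict(usage.counts),
        rscu=values,
        amino_acid_totals=totals,
        absent_families=absent,
        remainder=usage.remainder,
    )


def classify_terminal_codon(cds: str) -> dict:
    """Start codon, (possibly incomplete) stop codon and completeness.

    A CDS whose length is 1 (mod 3) ends in a bare ``T``, 2 (mod 3) in
    ``TA``-style dinucleotides; both are reported incomplete.  Unknown
    full terminal 3-mers are reported verbatim as complete.
    """
    seq = cds.upper()
    if len(seq) < 3:
        raise CompositionError("CDS shorter than one codon")
    start = seq[:3]
    rem = len(seq) % 3
    if rem == 0:
        return {"start_codon": start, "stop_codon": seq[-3:], "complete": True}
    return {"start_codon": start, "stop_codon": seq[-rem:], "complete": False}


#: starts observed in these mitogenomes (ATT: ND1; GTG: COX1)
RECOGNIZED_STARTS = ("ATG", "ATT", "GTG")


def per_gene_composition(genomes: list[tuple]) -> pd.DataFrame:
    """Mean per-PCG composition across genomes.

    ``genomes`` is a list of ``(MitoAnnotation, SeqRecord)`` pairs.
    Percentages are averaged per gene across genomes; skews are computed
    from the mean percentages (the convention of published per-PCG
    summary tables).  A genome missing a PCG is excluded from that
    gene's average with a warning.
    """
    from .genome_model import extract_gene_sequences
    from .vocab import PCGS

    if not genomes:
        raise CompositionError("no genomes supplied")
    acc: dict[str, list[CompositionSummary]] = {g: [] for g in PCGS}
    for ann, rec in genomes:
        seqs = extract_gene_sequences(ann, rec)
        for gene in PCGS:
            if gene not in seqs:
                warnings.warn(f"{ann.species_id}: PCG {gene} missing; excluded")
                continue
            acc[gene].append(base_composition(seqs[gene]))
    rows = []
    for gene in PCGS:
        stats = acc[gene]
        if not stats:
            continue
        mT = sum(s.pct_T for s in stats) / len(stats)
        mC = sum(s.pct_C for s in stats) / len(stats)
        mA = sum(s.pct_A for s in stats) / len(stats)
        mG = sum(s.pct_G for s in stats) / len(stats)
        rows.append(
            {
                "gene": gene,
                "pct_T": mT, "pct_C": mC, "pct_A": mA, "pct_G": mG,
                "pct_AT": mA + mT,
                "mean_length": sum(s.total_length for s in stats) / len(stats),
                "gc_skew": gc_skew(mG, mC) if mG + mC else float("nan"),
                "at_skew": at_skew(mA, mT) if mA + mT else float("nan"),
                "n_genomes": len(stats),
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def composition_table(genomes: list[tuple]) -> pd.DataFrame:
    """Whole-genome composition summary, one row per genome."""
    rows = []
    for ann, rec in genomes:
        s = base_composition(rec.sequence)
        rows.append(
            {
                "species": ann.species_id, "accession": ann.accession,
                "pct_T": s.pct_T, "pct_C": s.pct_C, "pct_A": s.pct_A,
                "pct_G": s.pct_G, "total_length": s.total_length,
                "pct_AT": s.pct_AT, "gc_skew": s.gc_skew, "at_skew": s.at_skew,
            }
        )
    return pd.DataFrame(rows)
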