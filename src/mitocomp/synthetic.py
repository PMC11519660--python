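"""Seeded generators emulating annotated circular mitogenomes.

The defaults mirror the study system: gene lengths and layout follow
the R. jiemuxiensis annotation, base frequencies its printed whole-
genome composition, and gene orders one of the three rearrangement
patterns seen in Rana.  Sequence divergence is simulated site-i.i.d.
under the two-parameter (transition/transversion) process, coding
divergence by a proposal-acceptance scheme whose nonsynonymous
acceptance probability is omega.  Every generator is a pure function of
its spec (seed-deterministic, byte-identical reruns).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .composition_stats import AA_OF, STOP_CODONS
from .gene_order import (
    GeneOrder,
    TranspositionEvent,
    apply_tdrl,
    apply_transposition,
)
from .genome_model import GeneFeature, MitoAnnotation, SeqRecord
from .molevol import DEFAULT_SEED
from .vocab import CATEGORY_OF, token_abs, token_sign

_BASES = "ACGT"

#: R. jiemuxiensis gene lengths (bp), the template for synthetic genomes
RJ_GENE_LENGTHS: dict[str, int] = {
    "L1": 74, "T": 70, "P": 69, "F": 72, "12S": 930, "V": 69, "16S": 1575,
    "L2": 74, "ND1": 954, "I": 71, "Q": 71, "M": 71, "ND2": 1035, "W": 70,
    "A": 71, "N": 73, "O": 25, "C": 66, "Y": 67, "COX1": 1554, "S1": 72,
    "D": 69, "COX2": 553, "K": 69, "ATP8": 163, "ATP6": 714, "COX3": 785,
    "G": 70, "ND3": 350, "R": 70, "ND4L": 285, "ND4": 1372, "H": 68,
    "S2": 67, "ND5": 1788, "ND6": 495, "E": 69, "CYTB": 1143, "CR": 1525,
}

#: The three Rana gene-order patterns.  Pattern 1 is the ancestral
#: vertebrate arrangement; pattern 2 relocates the L1/T/P tRNA cluster
#: next to tRNA-Phe downstream of the control region; pattern 3 further
#: transposes ND5 behind the control region.
PATTERN_1 = GeneOrder((
    "F", "12S", "V", "16S", "L2", "ND1", "I", "-Q", "M", "ND2", "W", "-A",
    "-N", "O", "-C", "-Y", "COX1", "-S1", "D", "COX2", "K", "ATP8", "ATP6",
    "COX3", "G", "ND3", "R", "ND4L", "ND4", "H", "S2", "L1", "ND5", "-ND6",
    "-E", "CYTB", "T", "-P", "CR",
))
PATTERN_2 = GeneOrder((
    "L1", "T", "-P", "F", "12S", "V", "16S", "L2", "ND1", "I", "-Q", "M",
    "ND2", "W", "-A", "-N", "O", "-C", "-Y", "COX1", "-S1", "D", "COX2",
    "K", "ATP8", "ATP6", "COX3", "G", "ND3", "R", "ND4L", "ND4", "H", "S2",
    "ND5", "-ND6", "-E", "CYTB", "CR",
))
PATTERN_3 = GeneOrder((
    "L1", "T", "-P", "F", "12S", "V", "16S", "L2", "ND1", "I", "-Q", "M",
    "ND2", "W", "-A", "-N", "O", "-C", "-Y", "COX1", "-S1", "D", "COX2",
    "K", "ATP8", "ATP6", "COX3", "G", "ND3", "R", "ND4L", "ND4", "H", "S2",
    "-ND6", "-E", "CYTB", "CR", "ND5",
))
PATTERNS: dict[str, GeneOrder] = {
    "pattern1": PATTERN_1, "pattern2": PATTERN_2, "pattern3": PATTERN_3,
}

#: whole-genome base frequencies (A, C, G, T) from the study genome
RJ_BASE_FREQS = (0.2433, 0.3074, 0.1581, 0.2912)


class SimulationError(ValueError):
    pass


@dataclass
class SimSpec:
    seed: int = DEFAULT_SEED
    genome_length: int | None = None  # default: sum of template gene lengths
    base_freqs: tuple[float, float, float, float] = RJ_BASE_FREQS
    pattern: str = "pattern2"
    d: float = 0.08        # substitutions/site between a simulated pair
    kappa: float = 4.0     # transition/transversion rate ratio
    omega: float = 0.2     # nonsynonymous/synonymous rate ratio
    n_taxa: int = 4

    def __post_init__(self) -> None:
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise SimulationError("base_freqs must sum to 1")
        if self.d < 0:
            raise SimulationError("divergence d must be >= 0")
        if self.pattern not in PATTERNS:
            raise SimulationError(f"unknown pattern {self.pattern!r}")


_SENSE_CODONS = sorted(c for c in AA_OF if c not in STOP_CODONS)


def _random_cds(rng: np.random.Generator, length: int) -> str:
    """Random CDS of exactly ``length`` nt: ATG start, sense codons, and
    either a full TAA stop or an incomplete TA-/T- terminal codon when the
    length is not a codon multiple."""
    n_full = length // 3
    rem = length % 3
    n_sense = n_full - 1 - (1 if rem == 0 else 0)
    picks = rng.choice(len(_SENSE_CODONS), size=max(n_sense, 0))
    seq = "ATG" + "".join(_SENSE_CODONS[i] for i in picks)
    seq += "TA"[:rem] if rem else "TAA"
    return seq[:length]


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def make_genome(spec: SimSpec) -> tuple[MitoAnnotation, SeqRecord]:
    """Synthetic annotated circular mitogenome.

    Features abut (all spacers zero) and tile the circle in the chosen
    pattern's order, with template gene lengths; any extra genome length
    is absorbed by the control region.  PCGs carry a valid start codon
    and stop codon and no internal stops; the rest of the sequence is
    i.i.d. from ``base_freqs``.
    """
    rng = np.random.default_rng(spec.seed)
    order = PATTERNS[spec.pattern]
    lengths = dict(RJ_GENE_LENGTHS)
    total = sum(lengths[token_abs(t)] for t in order.tokens)
    if spec.genome_length is not None:
        if spec.genome_length < total:
            raise SimulationError(
                f"genome_length {spec.genome_length} < sum of gene lengths {total}"
            )
        lengths["CR"] += spec.genome_length - total
        total = spec.genome_length

    seq_parts: list[str] = []
    feats: list[GeneFeature] = []
    pos = 1
    for tok in order.tokens:
        name = token_abs(tok)
        strand = "H" if token_sign(tok) > 0 else "L"
        ln = lengths[name]
        if CATEGORY_OF[name] == "PCG":
            cds = _random_cds(rng, ln)
            part = cds if strand == "H" else _revcomp(cds)
            stop_codon = cds[-(ln % 3) :] if ln % 3 else cds[-3:]
            start_codon = cds[:3]
        else:
            part = "".join(
                _BASES[i] for i in rng.choice(4, size=ln, p=spec.base_freqs)
            )
            start_codon = stop_codon = None
        seq_parts.append(part)
        feats.append(
            GeneFeature(
                name="O" if name == "O" else name,
                category=CATEGORY_OF[name],
                start=pos,
                end=pos + ln - 1,
                strand=strand,
                start_codon=start_codon,
                stop_codon=stop_codon,
            )
        )
        pos += ln
    ann = MitoAnnotation(
        species_id=f"sim_{spec.pattern}_{spec.seed}",
        accession=f"SIM{spec.seed}",
        genome_length=total,
        features=feats,
    )
    return ann, SeqRecord(ann.species_id, "".join(seq_parts))


# ---------------------------------------------------------------------------
# sequence-pair divergence (K80 process)


def _k80_probs(d: float, kappa: float) -> tuple[float, float]:
    """(transition, total transversion) substitution probabilities after
    expected divergence ``d`` under the two-parameter process."""
    if d == 0:
        return 0.0, 0.0
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    p_ts = 0.25 + 0.25 * math.exp(-4.0 * beta * d) - 0.5 * math.exp(-2.0 * (alpha + beta) * d)
    p_tv = 0.5 - 0.5 * math.exp(-4.0 * beta * d)
    return p_ts, p_tv


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def evolve_pair(sequence: str, d: float, kappa: float = 4.0, seed: int = DEFAULT_SEED) -> str:
    """Copy of ``sequence`` after expected ``d`` substitutions/site under
    the two-parameter process (exact finite-time site probabilities, sites
    i.i.d.).  Non-ACGT characters are copied unchanged."""
    if d < 0:
        raise SimulationError("d must be >= 0")
    seq = sequence.upper()
    if d == 0:
        return seq
    p_ts, p_tv = _k80_probs(d, kappa)
    rng = np.random.default_rng(seed)
    u = rng.random(len(seq))
    pick = rng.integers(2, size=len(seq))  # which transversion target
    arr = np.frombuffer(seq.encode(), "S1").astype("U1")
    code = np.full(len(seq), -1)
    for i, b in enumerate(_BASES):
        code[arr == b] = i
    # per-base lookup: transition target, and the two transversion targets
    ts_target = np.array([_BASES.index(_TRANSITION[b]) for b in _BASES])
    tv_targets = np.array([[_BASES.index(x) for x in _TRANSVERSIONS[b]] for b in _BASES])
    out = code.copy()
    valid = code >= 0
    is_ts = valid & (u < p_ts)
    is_tv = valid & (u >= p_ts) & (u < p_ts + p_tv)
    out[is_ts] = ts_target[code[is_ts]]
    out[is_tv] = tv_targets[code[is_tv], pick[is_tv]]
    res = arr.copy()
    base_arr = np.array(list(_BASES))
    res[valid] = base_arr[out[valid]]
    return "".join(res)


def evolve_cds(cds: str, omega: float, t: float, seed: int = DEFAULT_SEED) -> str:
    """CDS after a proposal-acceptance substitution process.

    Proposals arrive at rate ``t`` per site (Poisson-many, uniform sites,
    uniform target base); a proposal is rejected if it creates a stop
    codon, accepted with probability ``omega`` if it changes the amino
    acid, and always accepted if synonymous.
    """
    up = cds.upper()
    if len(up) % 3 != 0 or not up:
        raise SimulationError("CDS length must be a positive multiple of 3")
    terminal_stop = ""
    if up[-3:] in STOP_CODONS:  # terminal stop is kept fixed, not evolved
        up, terminal_stop = up[:-3], up[-3:]
    seq = list(up)
    for i in range(0, len(seq), 3):
        if "".join(seq[i : i + 3]) in STOP_CODONS:
            raise SimulationError(f"internal stop codon at nt {i + 1}")
    if omega < 0:
        raise SimulationError("omega must be >= 0")
    rng = np.random.default_rng(seed)
    n_prop = rng.poisson(t * len(seq))
    for _ in range(n_prop):
        site = int(rng.integers(len(seq)))
        old = seq[site]
        if old not in _BASES:
            continue
        new = _BASES[int(rng.integers(4))]
        if new == old:
            continue
        cstart = site - site % 3
        old_codon = "".join(seq[cstart : cstart + 3])
        new_codon = old_codon[: site % 3] + new + old_codon[site % 3 + 1 :]
        if new_codon in STOP_CODONS:
            continue
        if AA_OF[new_codon] != AA_OF[old_codon] and rng.random() >= omega:
            continue
        seq[site] = new
    return "".join(seq) + terminal_stop


# ---------------------------------------------------------------------------
# gene-order perturbations


def random_tdrl(
    order: GeneOrder, block: tuple[int, int], seed: int = DEFAULT_SEED
) -> tuple[GeneOrder, dict[str, int]]:
    """Apply a TDRL of ``block`` = (start, length) with a uniformly random
    retention assignment; returns the derived order and the ground-truth
    retention."""
    start, length = block
    if not (0 < length <= len(order)):
        raise SimulationError("block outside order")
    rng = np.random.default_rng(seed)
    toks = [order.tokens[(start + k) % len(order)] for k in range(length)]
    retention = {t: int(rng.integers(1, 3)) for t in toks}
    derived = apply_tdrl(tuple(order.tokens), start, length, retention)
    return GeneOrder(derived, order.circular), retention


def random_transposition(
    order: GeneOrder, seed: int = DEFAULT_SEED, max_block: int = 3
) -> tuple[GeneOrder, TranspositionEvent]:
    """Move one random contiguous block (1..max_block genes) to a random
    other position; returns the derived order and the ground-truth event."""
    rng = np.random.default_rng(seed)
    n = len(order)
    length = int(rng.integers(1, min(max_block, n - 2) + 1))
    start = int(rng.integers(n))
    rest = [order.tokens[(start + length + k) % n] for k in range(n - length)]
    # exclude the slot that puts the block straight back where it came from
    after = rest[int(rng.integers(len(rest) - 1))]
    derived = apply_transposition(tuple(order.tokens), start, length, after)
    event = TranspositionEvent(
        tuple(order.tokens[(start + k) % n] for k in range(length)), after
    )
    return GeneOrder(derived, order.circular), event
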