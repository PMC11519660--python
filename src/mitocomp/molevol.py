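"""Pairwise and per-gene molecular-evolution statistics.

Implements the classical comparative toolkit for mitogenome studies:

* Kimura two-parameter (K2P) distances from transition / transversion
  proportions, with pairwise deletion of gapped or ambiguous sites;
* sliding-window nucleotide diversity (Nei's pi, unweighted average of
  pairwise differences per compared site);
* Nei-Gojobori (1986) Ka/Ks with pathway averaging over multi-hit
  codons and the Jukes-Cantor correction, under the vertebrate
  mitochondrial code;
* an entropy-based substitution-saturation index with a Monte-Carlo
  full-saturation critical value (a seeded simulation proxy; it is not
  the regression-calibrated index of DAMBE);
* a neighbor-joining tree as plumbing for quick distance-based checks.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .composition_stats import AA_OF, STOP_CODONS

_BASES = "ACGT"
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")

#: default seed: the R. jiemuxiensis voucher number, for reproducibility
DEFAULT_SEED = 20211037


class SaturationError(ValueError):
    """K2P log argument non-positive: distance beyond the model's reach."""


class AlignmentError(ValueError):
    pass


@dataclass
class PairwiseEvo:
    P: float = 0.0
    Q: float = 0.0
    n_sites: int = 0
    d_k2p: float | None = None
    Ka: float | None = None
    Ks: float | None = None
    omega: float | None = None
    omega_defined: bool = False


@dataclass
class WindowDiversity:
    window_start: int  # 1-based alignment column
    window_size: int
    step: int
    pi: float | None  # None when no compared sites in the window


@dataclass
class SaturationResult:
    Iss: float
    Iss_c_sim: float
    sv_curve: list[tuple[float, int, int]] = field(default_factory=list)
    reps: int = 0
    seed: int = DEFAULT_SEED


# ---------------------------------------------------------------------------
# K2P


def _valid_mask(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ok = np.isin(a, list(_BASES)) & np.isin(b, list(_BASES))
    return ok


def count_pq(a: str, b: str) -> tuple[float, float, int]:
    """Transition (P) and transversion (Q) proportions with pairwise
    deletion of sites carrying a gap or ambiguity in either sequence."""
    if len(a) != len(b):
        raise AlignmentError("aligned sequences differ in length")
    x = np.frombuffer(a.upper().encode(), dtype="S1").astype("U1")
    y = np.frombuffer(b.upper().encode(), dtype="S1").astype("U1")
    ok = _valid_mask(x, y)
    n = int(ok.sum())
    if n == 0:
        raise AlignmentError("no comparable sites (all gapped/ambiguous)")
    x, y = x[ok], y[ok]
    diff = x != y
    pur_x = np.isin(x, ["A", "G"])
    pur_y = np.isin(y, ["A", "G"])
    transitions = diff & (pur_x == pur_y)
    transversions = diff & (pur_x != pur_y)
    return float(transitions.sum()) / n, float(transversions.sum()) / n, n


def k2p_distance(P: float, Q: float) -> float:
    """d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q)."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"K2P undefined for P={P:.4f}, Q={Q:.4f} (saturated divergence)"
        )
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k2p_pair(a: str, b: str) -> PairwiseEvo:
    P, Q, n = count_pq(a, b)
    ev = PairwiseEvo(P=P, Q=Q, n_sites=n)
    try:
        ev.d_k2p = k2p_distance(P, Q)
    except SaturationError:
        ev.d_k2p = None
    return ev


def distance_matrix(alignment: dict[str, str]) -> pd.DataFrame:
    """Symmetric K2P distance matrix (pairwise deletion per pair).

    Saturated pairs are reported as NaN rather than aborting the matrix.
    """
    labels = list(alignment)
    if len(labels) < 2:
        raise AlignmentError("need at least two sequences")
    m = np.zeros((len(labels), len(labels)))
    for i, j in itertools.combinations(range(len(labels)), 2):
        try:
            d = k2p_distance(*count_pq(alignment[labels[i]], alignment[labels[j]])[:2])
        except SaturationError:
            d = np.nan
            warnings.warn(f"saturated pair {labels[i]}/{labels[j]}; NaN recorded")
        m[i, j] = m[j, i] = d
    return pd.DataFrame(m, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# nucleotide diversity


def _pairwise_pi(cols_a: np.ndarray, cols_b: np.ndarray) -> float | None:
    ok = _valid_mask(cols_a, cols_b)
    n = int(ok.sum())
    if n == 0:
        return None
    return float((cols_a[ok] != cols_b[ok]).sum()) / n


def sliding_pi(
    alignment: dict[str, str], window: int, step: int
) -> list[WindowDiversity]:
    """Nei's nucleotide diversity in sliding windows of alignment columns.

    pi(window) = mean over sequence pairs of (differences / compared
    sites) inside the window; pairs with no compared sites are dropped,
    and a window where every pair is dropped gets ``pi=None``.
    """
    seqs = [np.frombuffer(s.upper().encode(), "S1").astype("U1") for s in alignment.values()]
    if len(seqs) < 2:
        raise AlignmentError("need at least two sequences")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise AlignmentError("alignment rows differ in length")
    if not (1 <= window <= length):
        raise AlignmentError("window must be within the alignment length")
    if step < 1:
        raise AlignmentError("step must be >= 1")
    out = []
    for start in range(0, length - window + 1, step):
        vals = []
        for a, b in itertools.combinations(seqs, 2):
            v = _pairwise_pi(a[start : start + window], b[start : start + window])
            if v is not None:
                vals.append(v)
        pi = sum(vals) / len(vals) if vals else None
        out.append(WindowDiversity(start + 1, window, step, pi))
    return out


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986)


@lru_cache(maxsize=None)
def _syn_fraction(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon.

    Per position, the fraction of the three single-nucleotide changes
    that preserve the amino acid; changes creating a stop codon count as
    nonsynonymous, so the two counts always sum to 3.
    """
    if codon in STOP_CODONS or codon not in AA_OF:
        raise AlignmentError(f"cannot count sites of stop/invalid codon {codon}")
    syn = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in STOP_CODONS and AA_OF[alt] == AA_OF[codon]:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def _path_counts(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) difference counts
    between two codons, enumerating all substitution orderings and
    skipping pathways through stop codons (all-blocked pairs fall back
    to counting through stops)."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0

    def walk(allow_stops: bool):
        paths = []
        for order in itertools.permutations(diffs):
            cur = c1
            sd = nd = 0.0
            blocked = False
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if nxt in STOP_CODONS and not allow_stops:
                    blocked = True
                    break
                if nxt in STOP_CODONS or AA_OF.get(nxt) != AA_OF.get(cur):
                    nd += 1
                else:
                    sd += 1
                cur = nxt
            if not blocked:
                paths.append((sd, nd))
        return paths

    paths = walk(allow_stops=False)
    if not paths:
        paths = walk(allow_stops=True)
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """d = -(3/4) ln(1 - 4p/3)."""
    if p >= 0.75:
        raise SaturationError(f"Jukes-Cantor undefined for p={p:.4f}")
    return 0.0 if p == 0 else -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def _strip_terminal_stop(cds: str) -> str:
    if len(cds) >= 3 and cds[-3:] in STOP_CODONS and len(cds) % 3 == 0:
        return cds[:-3]
    return cds


def ng86_kaks(cds_a: str, cds_b: str, on_stop: str = "error") -> PairwiseEvo:
    """Nei-Gojobori (1986) Ka/Ks for a pair of in-frame CDSs.

    Fractional synonymous/nonsynonymous site counts are averaged over
    both sequences, multi-hit codons are pathway-averaged, and pS/pN are
    Jukes-Cantor corrected.  ``omega`` is flagged undefined when Ks = 0.
    Codons with an ambiguity/gap in either sequence are excluded.
    ``on_stop='skip'`` drops codon columns holding an internal stop
    instead of raising (the usual treatment of annotation artifacts).
    """
    a, b = cds_a.upper(), cds_b.upper()
    if len(a) != len(b):
        raise AlignmentError("CDS lengths differ")
    if len(a) % 3 != 0 or len(a) == 0:
        raise AlignmentError("CDS length must be a positive multiple of 3")
    # drop the terminal codon column when either sequence ends in a stop
    if len(a) >= 3 and (a[-3:] in STOP_CODONS or b[-3:] in STOP_CODONS):
        a, b = a[:-3], b[:-3]
    if not a:
        raise AlignmentError("no codons left after stop stripping")
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if any(x not in _BASES for x in ca + cb):
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            if on_stop == "skip":
                continue
            raise AlignmentError(f"internal stop codon at nt {i + 1}")
        sa, na = _syn_fraction(ca)
        sb, nb = _syn_fraction(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = _path_counts(ca, cb)
        Sd += sd
        Nd += nd
        n_codons += 1
    if n_codons == 0:
        raise AlignmentError("no comparable codons")
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    ev = PairwiseEvo(n_sites=3 * n_codons)
    ev.Ks = jukes_cantor(pS)
    ev.Ka = jukes_cantor(pN)
    if ev.Ks > 0:
        ev.omega = ev.Ka / ev.Ks
        ev.omega_defined = True
    P, Q, _ = count_pq(a, b)
    ev.P, ev.Q = P, Q
    try:
        ev.d_k2p = k2p_distance(P, Q)
    except SaturationError:
        ev.d_k2p = None
    return ev


def ng86_site_counts(cds: str) -> tuple[float, float]:
    """Total (synonymous, nonsynonymous) site counts of one CDS; the two
    always sum to 3 x codon count."""
    cds = _strip_terminal_stop(cds.upper())
    S = N = 0.0
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        if any(x not in _BASES for x in codon):
            continue
        s, n = _syn_fraction(codon)
        S += s
        N += n
    return S, N


def kaks_summary(
    genomes: dict[str, dict[str, str]], on_stop: str = "error"
) -> pd.DataFrame:
    """Per-gene mean/SD of Ka, Ks and Ka/Ks over all unordered species
    pairs.  Pairs with undefined omega (Ks = 0) are excluded from the
    omega aggregation and counted in ``n_omega_excluded``."""
    species = sorted(genomes)
    if len(species) < 2:
        raise AlignmentError("need at least two genomes")
    genes = sorted(set.intersection(*(set(genomes[s]) for s in species)))
    rows = []
    for gene in genes:
        ka, ks, om, excl = [], [], [], 0
        for s1, s2 in itertools.combinations(species, 2):
            ev = ng86_kaks(genomes[s1][gene], genomes[s2][gene], on_stop=on_stop)
            ka.append(ev.Ka)
            ks.append(ev.Ks)
            if ev.omega_defined:
                om.append(ev.omega)
            else:
                excl += 1
        rows.append(
            {
                "gene": gene,
                "mean_Ka": float(np.mean(ka)), "sd_Ka": float(np.std(ka, ddof=0)),
                "mean_Ks": float(np.mean(ks)), "sd_Ks": float(np.std(ks, ddof=0)),
                "mean_omega": float(np.mean(om)) if om else np.nan,
                "sd_omega": float(np.std(om, ddof=0)) if om else np.nan,
                "n_pairs": len(ka), "n_omega_excluded": excl,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


# ---------------------------------------------------------------------------
# substitution saturation


def _alignment_entropy(mat: np.ndarray) -> float:
    """Mean per-column Shannon entropy (nats) over unambiguous bases."""
    hs = []
    for col in mat.T:
        col = col[np.isin(col, list(_BASES))]
        if col.size == 0:
            continue
        _, counts = np.unique(col, return_counts=True)
        p = counts / counts.sum()
        hs.append(float(-(p * np.log(p)).sum()))
    return float(np.mean(hs)) if hs else 0.0


def saturation_test(
    alignment: dict[str, str], reps: int = 100, seed: int = DEFAULT_SEED
) -> SaturationResult:
    """Entropy-based substitution-saturation assessment.

    ``Iss`` is the mean per-site entropy of the observed alignment
    divided by the entropy expected at full saturation given the
    observed base frequencies.  ``Iss_c_sim`` is the 5th percentile of
    Iss over ``reps`` alignments simulated at full saturation
    (i.i.d. column draws from the observed frequencies) -- a seeded
    Monte-Carlo proxy for a critical value, deliberately simpler than
    DAMBE's fitted coefficients.  ``Iss < Iss_c_sim`` indicates usable
    signal.  ``sv_curve`` pairs each pairwise K2P distance with its raw
    transition/transversion counts for saturation scatter plots.
    """
    if reps < 10:
        raise AlignmentError("reps must be >= 10")
    labels = list(alignment)
    if len(labels) < 4:
        raise AlignmentError("need at least 4 sequences")
    mat = np.array(
        [np.frombuffer(alignment[l].upper().encode(), "S1").astype("U1") for l in labels]
    )
    flat = mat[np.isin(mat, list(_BASES))]
    if flat.size == 0:
        raise AlignmentError("alignment holds no unambiguous bases")
    bases, counts = np.unique(flat, return_counts=True)
    freqs = np.zeros(4)
    for b, c in zip(bases, counts):
        freqs[_BASES.index(b)] = c
    freqs = freqs / freqs.sum()
    h_full = float(-(freqs[freqs > 0] * np.log(freqs[freqs > 0])).sum())
    if h_full == 0:
        raise AlignmentError("degenerate base frequencies")
    iss = _alignment_entropy(mat) / h_full

    rng = np.random.default_rng(seed)
    n_seq, n_sites = mat.shape
    sims = []
    base_arr = np.array(list(_BASES))
    for _ in range(reps):
        sim = base_arr[rng.choice(4, size=(n_seq, n_sites), p=freqs)]
        sims.append(_alignment_entropy(sim) / h_full)
    iss_c = float(np.percentile(sims, 5))

    curve = []
    for i, j in itertools.combinations(range(n_seq), 2):
        a, b = mat[i], mat[j]
        ok = _valid_mask(a, b)
        x, y = a[ok], b[ok]
        diff = x != y
        pur_x, pur_y = np.isin(x, ["A", "G"]), np.isin(y, ["A", "G"])
        s = int((diff & (pur_x == pur_y)).sum())
        v = int((diff & (pur_x != pur_y)).sum())
        n = int(ok.sum())
        try:
            d = k2p_distance(s / n, v / n)
        except SaturationError:
            d = float("nan")
        curve.append((d, s, v))
    curve.sort(key=lambda t: (math.isnan(t[0]), t[0]))
    return SaturationResult(Iss=iss, Iss_c_sim=iss_c, sv_curve=curve, reps=reps, seed=seed)


# ---------------------------------------------------------------------------
# neighbor joining (plumbing)


def nj_tree(matrix, labels: list[str] | None = None) -> str:
    """Neighbor-joining tree in Newick text from a symmetric zero-diagonal
    distance matrix.  Negative branch lengths are clamped to zero with a
    warning.  Backed by scikit-bio's NJ implementation."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if isinstance(matrix, pd.DataFrame):
        labels = list(matrix.index)
        arr = matrix.to_numpy(dtype=float)
    else:
        arr = np.asarray(matrix, dtype=float)
        if labels is None:
            labels = [f"t{i}" for i in range(arr.shape[0])]
    if arr.shape[0] < 3:
        raise AlignmentError("need at least 3 taxa")
    if not np.allclose(arr, arr.T, atol=1e-9):
        raise AlignmentError("distance matrix is not symmetric")
    tree = nj(DistanceMatrix(arr, ids=labels))
    clamped = False
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped = True
    if clamped:
        warnings.warn("negative NJ branch length(s) clamped to 0")
    return str(tree).strip()
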