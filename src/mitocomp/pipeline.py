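"""End-to-end orchestration over a directory of annotated genomes.

``run_all`` consumes genomes given as (annotation, sequence) pairs —
read from feature-table TSV + FASTA files — and emits the full set of
comparative tables as TSV/JSON, together with a reproducibility
manifest recording inputs, parameters and seeds.  Stages whose inputs
are unavailable (e.g. unequal-length genes where an alignment would be
required) are skipped with a warning rather than failing the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .composition_stats import codon_counts, composition_table, per_gene_composition, rscu
from .gene_order import (
    DEFAULT_ANCHOR,
    classify_patterns,
    pattern_frequencies,
    scenario_report,
)
from .genome_model import (
    MitoAnnotation,
    SeqRecord,
    extract_gene_order,
    extract_gene_sequences,
    read_fasta,
    read_feature_table,
    spacer_table,
)
from .molevol import (
    DEFAULT_SEED,
    distance_matrix,
    kaks_summary,
    nj_tree,
    saturation_test,
    sliding_pi,
)
from .vocab import PCGS

log = logging.getLogger("mitocomp")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    genomes: list[tuple[str, str]]  # (feature table path, fasta path) pairs
    out_dir: str = "mitocomp_out"
    window: int = 200
    step: int = 20
    saturation_reps: int = 100
    seed: int = DEFAULT_SEED
    kaks_method: str = "NG86+JC"
    anchor: str = DEFAULT_ANCHOR
    ncr_masked: bool = False

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Flat ``key = value`` config; `genome = table.tsv,genome.fa` may
        repeat."""
        genomes = []
        kwargs: dict = {}
        for raw in Path(path).read_text(encoding="utf-8").splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "genome":
                table, _, fasta = value.partition(",")
                genomes.append((table.strip(), fasta.strip()))
            elif key in ("window", "step", "saturation_reps", "seed"):
                kwargs[key] = int(value)
            elif key == "ncr_masked":
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif key in ("out_dir", "anchor", "kaks_method"):
                kwargs[key] = value
        if not genomes:
            raise PipelineError(f"no 'genome =' entries in {path}")
        return cls(genomes=genomes, **kwargs)


def _digest(path: str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _load_genomes(config: RunConfig) -> list[tuple[MitoAnnotation, SeqRecord | None]]:
    out = []
    for table, fasta in config.genomes:
        ann = read_feature_table(table)
        rec = None
        if fasta:
            rec = read_fasta(fasta)[0]
        out.append((ann, rec))
    return out


def run_all(config: RunConfig) -> dict:
    """Run the complete comparative analysis; returns a result summary
    and writes the report bundle under ``config.out_dir``."""
    if not config.genomes:
        raise PipelineError("empty input: at least one genome required")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genomes = _load_genomes(config)
    n_warn = 0
    summary: dict = {"n_genomes": len(genomes)}

    # -- annotation arithmetic ------------------------------------------
    rows = []
    for ann, _ in genomes:
        st = spacer_table(ann)
        for name, spacer in st.entries:
            rows.append({"species": ann.species_id, "gene": name, "spacer": spacer})
        log.info(
            "spacers species=%s features=%d overlaps=%d intervals=%d",
            ann.species_id, len(ann), st.n_overlaps, st.n_positive,
        )
    pd.DataFrame(rows).to_csv(out / "spacers.tsv", sep="\t", index=False)

    with_seq = [(a, r) for a, r in genomes if r is not None]

    # -- composition ----------------------------------------------------
    if with_seq:
        composition_table(with_seq).to_csv(out / "composition.tsv", sep="\t", index=False)
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            per_gene_composition(with_seq).to_csv(out / "per_pcg_composition.tsv", sep="\t")
            n_warn += len(wlist)
        usage_rows = []
        for ann, rec in with_seq:
            seqs = extract_gene_sequences(ann, rec)
            concat = "".join(
                seqs[g][: len(seqs[g]) - len(seqs[g]) % 3] for g in PCGS if g in seqs
            )
            cu = rscu(codon_counts(concat, strip_stops=True))
            for codon, val in sorted(cu.rscu.items()):
                usage_rows.append(
                    {
                        "species": ann.species_id, "codon": codon,
                        "count": cu.counts.get(codon, 0), "rscu": round(val, 5),
                    }
                )
        pd.DataFrame(usage_rows).to_csv(out / "rscu.tsv", sep="\t", index=False)

    # -- per-gene concatenated "alignment" stages -----------------------
    aln = _concatenated_pcgs(with_seq)
    if aln is not None:
        dm = distance_matrix(aln)
        dm.to_csv(out / "k2p_distances.tsv", sep="\t")
        pis = sliding_pi(aln, min(config.window, len(next(iter(aln.values())))), config.step)
        pd.DataFrame(
            [
                {"window_start": w.window_start, "window_size": w.window_size,
                 "step": w.step, "pi": w.pi}
                for w in pis
            ]
        ).to_csv(out / "window_pi.tsv", sep="\t", index=False)
        if len(aln) >= 4:
            sat = saturation_test(aln, reps=config.saturation_reps, seed=config.seed)
            (out / "saturation.json").write_text(
                json.dumps(
                    {"Iss": sat.Iss, "Iss_c_sim": sat.Iss_c_sim, "reps": sat.reps,
                     "saturated": sat.Iss >= sat.Iss_c_sim},
                    indent=2,
                )
            )
        if len(aln) >= 3 and not dm.isna().any().any():
            (out / "nj_tree.nwk").write_text(nj_tree(dm) + "\n")
        cds_by_species = _pcg_cds(with_seq)
        if cds_by_species is not None:
            kaks_summary(cds_by_species, on_stop="skip").to_csv(
                out / "kaks_summary.tsv", sep="\t"
            )
    elif with_seq:
        warnings.warn("unequal gene lengths across genomes; distance/pi/KaKs skipped")
        n_warn += 1

    # -- gene orders ----------------------------------------------------
    orders = {ann.species_id: extract_gene_order(ann) for ann, _ in genomes}
    from .synthetic import PATTERNS

    patterns = classify_patterns(
        orders, anchor=config.anchor, ncr_masked=config.ncr_masked, references=PATTERNS
    )
    freqs = pattern_frequencies(patterns)
    pd.DataFrame(
        [{"label": f["label"], "n": f["n"], "pct": f["pct"],
          "members": ";".join(f["members"])} for f in freqs]
    ).to_csv(out / "patterns.tsv", sep="\t", index=False)
    labels = [p.label for p in patterns if p.label != "other"]
    pairs = []
    if "pattern1" in labels and "pattern2" in labels:
        pairs.append(("pattern1", "pattern2"))
    if "pattern2" in labels and "pattern3" in labels:
        pairs.append(("pattern2", "pattern3"))
    if pairs:
        report = scenario_report(
            PATTERNS, pairs,
            narrative_blocks={("pattern1", "pattern2"): ("ND4", "CR")},
            anchor=config.anchor,
        )
        (out / "scenarios.json").write_text(json.dumps(report, indent=2))
    summary["patterns"] = freqs

    # -- manifest -------------------------------------------------------
    manifest = {
        "mitocomp_version": __version__,
        "seed": config.seed,
        "parameters": {
            "window": config.window, "step": config.step,
            "saturation_reps": config.saturation_reps,
            "kaks_method": config.kaks_method, "anchor": config.anchor,
            "ncr_masked": config.ncr_masked,
        },
        "inputs": [
            {"table": t, "fasta": f,
             "table_sha256": _digest(t), "fasta_sha256": _digest(f) if f else None}
            for t, f in config.genomes
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    summary["n_warnings"] = n_warn
    summary["out_dir"] = str(out)
    return summary


def _concatenated_pcgs(with_seq) -> dict[str, str] | None:
    """Concatenated in-frame PCG pseudo-alignment; None unless every
    genome yields equal per-gene lengths (pre-aligned input regime)."""
    if len(with_seq) < 2:
        return None
    per = {}
    for ann, rec in with_seq:
        seqs = extract_gene_sequences(ann, rec)
        per[ann.species_id] = {g: seqs[g] for g in PCGS if g in seqs}
    genes = set.intersection(*(set(v) for v in per.values()))
    if not genes:
        return None
    for g in genes:
        if len({len(per[s][g]) for s in per}) != 1:
            return None
    return {
        s: "".join(per[s][g][: len(per[s][g]) - len(per[s][g]) % 3] for g in sorted(genes))
        for s in per
    }


def _pcg_cds(with_seq) -> dict[str, dict[str, str]] | None:
    if len(with_seq) < 2:
        return None
    out = {}
    for ann, rec in with_seq:
        seqs = extract_gene_sequences(ann, rec)
        out[ann.species_id] = {
            g: seqs[g][: len(seqs[g]) - len(seqs[g]) % 3] for g in PCGS if g in seqs
        }
    return out
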