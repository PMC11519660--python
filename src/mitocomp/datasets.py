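"""Packaged reference data: the two study annotations, the published
22-genome composition table, and the Rana gene-order pattern
memberships."""

from __future__ import annotations

from importlib.resources import as_file, files

import pandas as pd

from .gene_order import GeneOrder
from .genome_model import MitoAnnotation, read_feature_table

_DATA = files("mitocomp.data")


def _annotation(name: str) -> MitoAnnotation:
    with as_file(_DATA / name) as path:
        return read_feature_table(path)


def rj_annotation() -> MitoAnnotation:
    """R. jiemuxiensis annotation (record PP228843, 17,506 bp)."""
    return _annotation("rj_annotation.tsv")


def rh_annotation() -> MitoAnnotation:
    """R. hanluica annotation (record PP228844, 17,505 bp)."""
    return _annotation("rh_annotation.tsv")


def rana_composition() -> pd.DataFrame:
    """Published whole-genome composition of the 22 Rana records."""
    with as_file(_DATA / "rana_composition.tsv") as path:
        return pd.read_csv(path, sep="\t", comment="#")


def rana_pattern_members() -> pd.DataFrame:
    """Species/accession -> gene-order pattern membership (22 records)."""
    with as_file(_DATA / "rana_patterns.tsv") as path:
        return pd.read_csv(path, sep="\t", comment="#")


def rana_gene_orders() -> dict[str, GeneOrder]:
    """Per-record gene orders of the 22 Rana mitogenomes, expanded from
    the pattern memberships (keyed ``species|accession``)."""
    from .synthetic import PATTERNS

    members = rana_pattern_members()
    return {
        f"{row.species}|{row.accession}": PATTERNS[row.pattern]
        for row in members.itertuples()
    }
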