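"""Module annotation: ortholog mapping, biomarker overlap and gene-set
over-representation.

Cross-species application of the modules (mouse discovery data, human
validation data) goes through a static two-column ortholog map.  Modules are
characterised against a biomarker gene list (e.g. known lung-fibrosis
markers) by simple intersection, and against gene-set collections (GMT) by
one-sided Fisher exact tests with Benjamini-Hochberg correction across sets
within each module.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from .deg import bh_adjust


# ---------------------------------------------------------------------------
# file readers


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines and '#' comments skipped."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene-set file: name <tab> description <tab> gene ids..."""
    sets: dict[str, list[str]] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{i}: GMT line needs >= 3 tab-separated fields")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def read_ortholog_map(path: str | Path) -> pd.DataFrame:
    """Two-column TSV (source_id, target_id); a header row is optional."""
    table = pd.read_csv(path, sep="\t", dtype=str, header=None)
    if table.shape[1] != 2:
        raise ValueError(f"ortholog map must have exactly 2 columns, got {table.shape[1]}")
    table.columns = ["source_id", "target_id"]
    if table.iloc[0, 0].lower() in ("source_id", "source", "from"):
        table = table.iloc[1:].reset_index(drop=True)
    bad = table.index[table.isna().any(axis=1) |
                      (table == "").any(axis=1)].tolist()
    if bad:
        lines = [i + 1 for i in bad[:5]]
        raise ValueError(f"ortholog map has empty identifiers at line(s) {lines}")
    return table


# ---------------------------------------------------------------------------
# operations


@dataclass
class MappingReport:
    """Per-module (input count, mapped count) bookkeeping."""

    input_count: dict[str, int]
    mapped_count: dict[str, int]
    unmapped: dict[str, list[str]]


def map_orthologs(
    module_genes: Mapping[str, Sequence[str]],
    ortholog_map: pd.DataFrame,
) -> tuple[dict[str, list[str]], MappingReport]:
    """Translate each module's gene list through the ortholog map.

    Genes without a target are dropped and counted; one-to-many mappings
    expand to all targets, de-duplicated per module.  Returns the translated
    lists plus a report of input/mapped counts and dropped ids.
    """
    lookup: dict[str, list[str]] = {}
    for row in ortholog_map.itertuples():
        lookup.setdefault(row.source_id, []).append(row.target_id)
    mapped: dict[str, list[str]] = {}
    inp, got, lost = {}, {}, {}
    for module, genes in module_genes.items():
        targets: list[str] = []
        missing: list[str] = []
        for g in genes:
            hits = lookup.get(g)
            if hits:
                targets += hits
            else:
                missing.append(g)
        seen: dict[str, None] = dict.fromkeys(targets)
        mapped[module] = list(seen)
        inp[module] = len(genes)
        got[module] = len(seen)
        lost[module] = missing
    return mapped, MappingReport(input_count=inp, mapped_count=got, unmapped=lost)


def biomarker_overlap(module_genes: Sequence[str],
                      biomarkers: Sequence[str]) -> tuple[int, list[str]]:
    """Exact-identifier intersection with a biomarker list (sorted)."""
    if not biomarkers:
        raise ValueError("biomarker list is empty")
    hits = sorted(set(module_genes) & set(biomarkers))
    return len(hits), hits


def fisher_enrichment(
    module_genes: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
    universe: Sequence[str],
    module_id: str | int = "",
) -> pd.DataFrame:
    """One-sided (over-representation) Fisher exact test per gene set.

    The 2x2 table counts membership of the module and the gene set over the
    universe; the p-value is the upper hypergeometric tail P(X >= overlap).
    Gene sets are intersected with the universe first; BH correction is
    applied across sets.  Rows are sorted by adjusted p, then set name.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("universe is empty")
    mod = set(module_genes) & uni
    rows = []
    for name in sorted(gene_sets):
        gs = set(gene_sets[name]) & uni
        overlap = len(mod & gs)
        # P(X >= overlap) drawing |mod| genes from a universe with |gs| successes
        p = float(stats.hypergeom.sf(overlap - 1, len(uni), len(gs), len(mod)))
        rows.append({
            "module_id": module_id, "gene_set": name, "overlap": overlap,
            "module_size": len(mod), "set_size": len(gs),
            "universe_size": len(uni), "pvalue": min(p, 1.0),
        })
    table = pd.DataFrame(rows)
    if len(table):
        table["padj"] = bh_adjust(table["pvalue"].to_numpy())
        table = table.sort_values(["padj", "gene_set"]).reset_index(drop=True)
    return table


def enrich_modules(
    module_genes: Mapping[str, Sequence[str]],
    gene_sets: Mapping[str, Sequence[str]],
    universe: Sequence[str],
) -> pd.DataFrame:
    """Fisher enrichment for every module, concatenated."""
    parts = [
        fisher_enrichment(genes, gene_sets, universe, module_id=module)
        for module, genes in sorted(module_genes.items())
    ]
    return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()
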