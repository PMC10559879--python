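"""Over-representation analysis of significant entities against gene sets.

Significant proteins/sites are collapsed to gene symbols and tested against
each gene set with the one-sided hypergeometric upper tail, using the
reliably quantified entities of the analysed scope as the background
universe.  P-values are Benjamini-Hochberg adjusted within the collection;
sets are called enriched at FDR <= 0.05.  The direction of regulation of a
set is the sign of the median log2 fold change of the significant
proteins/sites assigned to it, so PTM effects can dominate direction in
integrative analyses.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .differential import DEFAULT_ALPHA, benjamini_hochberg
from .model import GeneSetCollection, ValidationError, split_site_entity

log = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = [
    "set_name",
    "layer_scope",
    "k",
    "K",
    "n",
    "N",
    "p",
    "fdr",
    "significant",
    "direction",
    "members",
]


def map_to_genes(entities: Iterable[str], mapping: Mapping[str, str]) -> set[str]:
    """Collapse protein/site entity keys to their gene symbols.

    Site keys (``accession_SiteId``) map through their parent accession.
    Unmapped accessions are dropped (logged).
    """
    if not mapping:
        raise ValidationError("empty accession-to-gene mapping")
    genes: set[str] = set()
    unmapped = 0
    for entity in entities:
        acc = entity
        if entity not in mapping and "_" in entity:
            acc = split_site_entity(entity)[0]
        symbol = mapping.get(acc)
        if symbol is None:
            unmapped += 1
        else:
            genes.add(symbol)
    if unmapped:
        log.info("dropped %d entities with no gene mapping", unmapped)
    return genes


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N population, K marked, n drawn)."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def direction_call(values: Sequence[float]) -> str:
    """Direction of regulation from the median member log2FC."""
    values = list(values)
    if not values:
        raise ValidationError("direction_call needs at least one member value")
    med = float(np.median(values))
    if med > 0:
        return "up"
    if med < 0:
        return "down"
    return "mixed-zero"


def enrich(
    significant: set[str],
    universe: set[str],
    collection: GeneSetCollection,
    gene_log2fc: Mapping[str, Sequence[float]] | None = None,
    alpha: float = DEFAULT_ALPHA,
    layer_scope: str = "layer",
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``significant`` within
    ``universe`` for every set of the collection that intersects the
    universe.

    ``gene_log2fc`` maps a gene symbol to the log2FC values of the
    significant entities behind it; the direction call pools the values of
    a set's significant members.
    """
    if not universe:
        raise ValidationError("empty universe")
    extra = significant - universe
    if extra:
        raise ValidationError(
            f"significant genes outside the universe: {sorted(extra)[:5]}"
        )
    N, n = len(universe), len(significant)
    rows = []
    for set_name, members in collection.sets.items():
        in_universe = universe.intersection(members)
        K = len(in_universe)
        if K == 0:
            continue
        hits = sorted(significant.intersection(in_universe))
        k = len(hits)
        p = hypergeom_upper_tail(k, K, n, N)
        direction = ""
        if hits and gene_log2fc is not None:
            pooled = [v for g in hits for v in gene_log2fc.get(g, [])]
            if pooled:
                direction = direction_call(pooled)
        rows.append(
            {
                "set_name": set_name,
                "layer_scope": layer_scope,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": p,
                "direction": direction,
                "members": ";".join(hits),
            }
        )
    res = pd.DataFrame(rows, columns=[c for c in ENRICHMENT_COLUMNS if c not in ("fdr", "significant")])
    if len(res) == 0:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    res["fdr"] = benjamini_hochberg(res["p"].to_numpy())
    res["significant"] = res["fdr"] <= alpha
    return res[ENRICHMENT_COLUMNS].sort_values("p", kind="mergesort").reset_index(drop=True)


def integrative_enrich(
    per_layer_significant: Mapping[str, Iterable[str]],
    per_layer_universe: Mapping[str, Iterable[str]],
    collection: GeneSetCollection,
    mapping: Mapping[str, str],
    per_layer_log2fc: Mapping[str, Mapping[str, float]] | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Over-representation on the union of all omics layers.

    Significant and universe gene sets are the unions of the per-layer
    gene mappings; member log2FCs for direction pool all significant
    proteins and sites across layers (site values after protein
    normalization).
    """
    if len(per_layer_significant) < 2:
        raise ValidationError("integrative enrichment needs at least 2 layers")
    significant: set[str] = set()
    universe: set[str] = set()
    for layer, entities in per_layer_significant.items():
        significant |= map_to_genes(entities, mapping)
    for layer, entities in per_layer_universe.items():
        universe |= map_to_genes(entities, mapping)
    gene_fc: dict[str, list[float]] = {}
    if per_layer_log2fc is not None:
        for layer, entity_fc in per_layer_log2fc.items():
            sig = set(per_layer_significant.get(layer, ()))
            for entity, value in entity_fc.items():
                if entity not in sig:
                    continue
                genes = map_to_genes([entity], mapping)
                for g in genes:
                    gene_fc.setdefault(g, []).append(float(value))
    return enrich(
        significant,
        universe,
        collection,
        gene_log2fc=gene_fc or None,
        alpha=alpha,
        layer_scope="integrative",
    )


def map_compartments(
    entities: Iterable[str],
    go_cc: GeneSetCollection,
    mapping: Mapping[str, str],
) -> pd.DataFrame:
    """Annotate entities with every GO cellular-component set containing
    their gene; entities without any hit are labelled ``unmapped``."""
    gene_to_sets: dict[str, list[str]] = {}
    for set_name, members in go_cc.sets.items():
        for g in members:
            gene_to_sets.setdefault(g, []).append(set_name)
    rows = []
    for entity in entities:
        genes = map_to_genes([entity], mapping) if mapping else set()
        hits: list[str] = []
        for g in sorted(genes):
            hits.extend(gene_to_sets.get(g, []))
        rows.append(
            {"entity": entity, "compartments": ";".join(sorted(set(hits))) or "unmapped"}
        )
    return pd.DataFrame(rows, columns=["entity", "compartments"])
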