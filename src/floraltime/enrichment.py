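"""Hypergeometric enrichment of GO terms and TF families.

Both tests ask the same question: drawing the study set from the universe
without replacement, is the observed overlap with a category surprisingly
large?  p = P(X >= k_obs) for X ~ Hypergeometric(N, K, n).  GO terms are
tested within the up- and down-regulated sets of each contrast, with a
minimum number of annotated genes in the input list ("mapping entries")
before a term is tested; TF families are tested as DEGs vs expressed genes.
Benjamini-Hochberg FDR is applied across the categories of each run.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .diffexp import bh_adjust

logger = logging.getLogger("floraltime")


def hypergeom_upper(k_obs: int, universe: int, universe_hits: int, draws: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k_obs)."""
    if k_obs <= 0:
        return 1.0
    return float(hypergeom.sf(k_obs - 1, universe, universe_hits, draws))


def _finish(rows: list[dict], fdr_threshold: float) -> pd.DataFrame:
    cols = ["category_id", "universe_size", "universe_hits", "set_size", "set_hits",
            "p", "fdr", "enriched"]
    if not rows:
        return pd.DataFrame(columns=cols)
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    out["enriched"] = out["fdr"] < fdr_threshold
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)[cols]


def go_enrichment(gene_set: set[str], universe: set[str], go_map: dict[str, set[str]],
                  min_entries: int = 10, fdr_threshold: float = 0.05) -> pd.DataFrame:
    """GO term over-representation in one gene set.

    ``go_map`` maps gene id -> GO terms.  A term is tested only when at
    least ``min_entries`` genes of ``gene_set`` carry it; N = annotated
    universe genes, K = universe genes with the term, n = annotated genes
    in the set, k = set genes with the term.
    """
    if not gene_set:
        logger.warning("go_enrichment: empty gene set")
        return _finish([], fdr_threshold)
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    annotated_universe = {g for g in universe if go_map.get(g)}
    annotated_set = {g for g in gene_set if go_map.get(g)}
    n_universe = len(annotated_universe)
    n_set = len(annotated_set)
    term_universe: dict[str, int] = {}
    term_set: dict[str, int] = {}
    for g in annotated_universe:
        for t in go_map[g]:
            term_universe[t] = term_universe.get(t, 0) + 1
    for g in annotated_set:
        for t in go_map[g]:
            term_set[t] = term_set.get(t, 0) + 1
    rows = []
    for term, k_obs in sorted(term_set.items()):
        if k_obs < min_entries:
            continue
        rows.append({
            "category_id": term,
            "universe_size": n_universe,
            "universe_hits": term_universe[term],
            "set_size": n_set,
            "set_hits": k_obs,
            "p": hypergeom_upper(k_obs, n_universe, term_universe[term], n_set),
        })
    return _finish(rows, fdr_threshold)


def tf_family_enrichment(deg_set: set[str], expressed_set: set[str],
                         tf_map: dict[str, str],
                         flowering_genes: set[str] | None = None,
                         fdr_threshold: float = 0.05) -> pd.DataFrame:
    """DEG over-representation per TF family against the expressed genes.

    Per family: N = expressed genes, K = all DEGs, n = expressed family
    members, k = family DEGs.  Families with no expressed member are
    skipped.  When ``flowering_genes`` is given, the count of flowering
    DEGs per family is reported alongside.
    """
    if not deg_set <= expressed_set:
        raise ValueError("deg_set must be a subset of expressed_set")
    n_universe = len(expressed_set)
    n_degs = len(deg_set)
    families = sorted({f for g, f in tf_map.items() if g in expressed_set})
    rows = []
    for fam in families:
        members = {g for g, f in tf_map.items() if f == fam and g in expressed_set}
        if not members:
            logger.info("tf_family_enrichment: family %s has no expressed member; skipped", fam)
            continue
        fam_degs = members & deg_set
        row = {
            "category_id": fam,
            "universe_size": n_universe,
            "universe_hits": n_degs,
            "set_size": len(members),
            "set_hits": len(fam_degs),
            "p": hypergeom_upper(len(fam_degs), n_universe, n_degs, len(members)),
        }
        if flowering_genes is not None:
            row["flowering_degs"] = len(fam_degs & flowering_genes)
        rows.append(row)
    out = _finish(rows, fdr_threshold)
    if rows and flowering_genes is not None:
        extra = pd.DataFrame(rows).set_index("category_id")["flowering_degs"]
        out["flowering_degs"] = out["category_id"].map(extra)
    return out
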