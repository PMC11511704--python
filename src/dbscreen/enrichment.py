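"""Gene-set over-representation analysis and dual-control secondary-marker
discovery.

The marker-discovery procedure asks which biological pathways are altered
in a patient group beyond age-dependent variation: it runs the DEP stage
against the healthy-newborn cohort and again against the healthy-adult
cohort, takes the top enriched terms of each comparison, intersects them
("commonly altered" pathways), and reports the proteins that are DEPs in
the same direction in both comparisons and belong to a common pathway.
Those proteins are candidate secondary screening markers (e.g. platelet
proteins in thrombocytopenic patients) for diseases whose causative
protein cannot be measured directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection
from .matrix import ValidationError


@dataclass
class MarkerConfig:
    """Knobs for enrichment and marker discovery."""

    top_n_terms: int = 10
    enrichment_adjust: str = "benjamini_hochberg"
    universe_policy: str = "quantified_proteins"  # or "explicit_list"
    zero_overlap: str = "p_one"  # report k=0 sets with p=1, or "skip"

    def __post_init__(self) -> None:
        if self.top_n_terms < 1:
            raise ValidationError("top_n_terms must be >= 1")
        if self.enrichment_adjust != "benjamini_hochberg":
            raise ValidationError("only benjamini_hochberg adjustment is supported")
        if self.zero_overlap not in ("p_one", "skip"):
            raise ValidationError("zero_overlap must be 'p_one' or 'skip'")


def ora_hypergeometric(
    query: list[str],
    genesets: GeneSetCollection,
    universe: list[str],
    config: MarkerConfig | None = None,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of a query gene list.

    For each set, with universe size N, set size K (after intersection with
    the universe), query size n and overlap k, p = P(X >= k) for
    X ~ Hypergeometric(N, K, n).  BH adjustment runs across all tested
    sets.  The query must be a subset of the universe.
    """
    config = config or MarkerConfig()
    uni = list(dict.fromkeys(universe))
    if not uni:
        raise ValidationError("universe must not be empty")
    uni_set = set(uni)
    query_set = set(query)
    stray = query_set - uni_set
    if stray:
        raise ValidationError(f"query gene(s) not in universe: {sorted(stray)[:5]}")
    n = len(query_set)
    rows = []
    for term, members in genesets.sets.items():
        in_uni = [m for m in members if m in uni_set]
        K = len(in_uni)
        if K == 0:
            continue
        k = len(query_set.intersection(in_uni))
        if k == 0 and config.zero_overlap == "skip":
            continue
        # survival function at k-1 gives P(X >= k)
        p = float(stats.hypergeom.sf(k - 1, len(uni), K, n)) if k > 0 else 1.0
        rows.append(
            {
                "term": term,
                "overlap_k": k,
                "set_size_K": K,
                "query_size_n": n,
                "universe_size_N": len(uni),
                "p_value": min(p, 1.0),
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "term", "overlap_k", "set_size_K", "query_size_n",
            "universe_size_N", "p_value",
        ],
    )
    if len(result):
        result["adjusted_p"] = multipletests(result["p_value"], method="fdr_bh")[1]
    else:
        result["adjusted_p"] = pd.Series(dtype=float)
    return result.sort_values(
        ["adjusted_p", "p_value", "term"], kind="stable"
    ).reset_index(drop=True)


def _top_terms(enrichment: pd.DataFrame, top_n: int) -> list[str]:
    """Top terms ranked by adjusted p ascending, ties by larger overlap then
    term name.  Terms with no overlapping gene are never "enriched" and are
    excluded before ranking."""
    enrichment = enrichment[enrichment["overlap_k"] > 0]
    if enrichment.empty:
        return []
    ranked = enrichment.sort_values(
        ["adjusted_p", "overlap_k", "term"],
        ascending=[True, False, True],
        kind="stable",
    )
    return list(ranked["term"].head(top_n))


def common_pathways(
    enrichment_vs_newborn: pd.DataFrame,
    enrichment_vs_adult: pd.DataFrame,
    config: MarkerConfig | None = None,
) -> list[str]:
    """Terms in the top-N of both control comparisons (order: newborn rank)."""
    config = config or MarkerConfig()
    top_nb = _top_terms(enrichment_vs_newborn, config.top_n_terms)
    top_ad = set(_top_terms(enrichment_vs_adult, config.top_n_terms))
    return [t for t in top_nb if t in top_ad]


def dual_control_markers(
    deps_vs_newborn: pd.DataFrame,
    deps_vs_adult: pd.DataFrame,
    genesets: GeneSetCollection,
    universe: list[str],
    config: MarkerConfig | None = None,
) -> pd.DataFrame:
    """Secondary markers supported by both control comparisons.

    A marker must be a DEP with the same direction in the patient-vs-newborn
    and patient-vs-adult comparisons, and belong to at least one pathway
    enriched (top-N) in both comparisons.  Returns one row per marker with
    direction, supporting terms and both q-values.
    """
    config = config or MarkerConfig()
    dep_nb = deps_vs_newborn[deps_vs_newborn["is_dep"]]
    dep_ad = deps_vs_adult[deps_vs_adult["is_dep"]]
    shared = dep_nb.index.intersection(dep_ad.index)
    same_dir = [
        g for g in shared
        if dep_nb.loc[g, "direction"] == dep_ad.loc[g, "direction"]
    ]
    enr_nb = ora_hypergeometric(list(dep_nb.index), genesets, universe, config)
    enr_ad = ora_hypergeometric(list(dep_ad.index), genesets, universe, config)
    terms = common_pathways(enr_nb, enr_ad, config)
    rows = []
    for gene in same_dir:
        support = [t for t in terms if gene in genesets.sets.get(t, ())]
        if not support:
            continue
        rows.append(
            {
                "marker": gene,
                "direction": dep_nb.loc[gene, "direction"],
                "supporting_terms": ";".join(support),
                "q_vs_newborn": dep_nb.loc[gene, "q_value"],
                "q_vs_adult": dep_ad.loc[gene, "q_value"],
            }
        )
    report = pd.DataFrame(
        rows,
        columns=["marker", "direction", "supporting_terms", "q_vs_newborn", "q_vs_adult"],
    )
    report.attrs["common_pathways"] = terms
    return report
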