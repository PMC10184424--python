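"""Hypergeometric over-representation analysis (ORA) and method comparison.

Gene sets come from a GMT file (one term per line: id, description, member
genes).  For a query of ``n`` genes drawn from a background universe of
``N`` genes, a term with ``K`` annotated background genes and ``k`` of them
in the query gets the upper-tail hypergeometric probability
``p = P(X >= k)``, with Benjamini-Hochberg adjustment across the tested
terms.  Significance defaults to raw ``p < 0.05``; an adjusted-p mode is
available because popular ORA tools differ on this point.

*Effective terms* are the significant terms shared between the drug-target
gene set and the disease-gene set; they serve as the reference against which
the key networks of competing importance methods are compared
(:func:`method_coverage`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .importance import ImportanceResult

logger = logging.getLogger(__name__)


def read_gmt(path: Union[str, Path]) -> dict[str, set[str]]:
    """Read a GMT file into ``{term_id: gene set}`` (descriptions discarded)."""
    sets: dict[str, set[str]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: GMT needs term, description, >=1 gene")
            term = parts[0].strip()
            if term in sets:
                raise ValueError(f"line {lineno}: duplicate term id {term!r}")
            sets[term] = {g.strip().upper() for g in parts[2:] if g.strip()}
    return sets


def write_gmt(gene_sets: Mapping[str, set[str]], path: Union[str, Path]) -> None:
    with Path(path).open("w") as fh:
        for term in gene_sets:
            fh.write("\t".join([term, "na"] + sorted(gene_sets[term])) + "\n")


@dataclass
class EnrichmentResult:
    """Per-term ORA statistics plus the significant-term set."""

    table: pd.DataFrame  # columns: term_id, k, n, K, N, p_value, p_adjusted
    significant_terms: set[str]
    alpha: float
    adjusted: bool


def ora(
    query: Iterable[str],
    gene_sets: Mapping[str, set[str]],
    background: Optional[Iterable[str]] = None,
    alpha: float = 0.05,
    adjusted: bool = False,
) -> EnrichmentResult:
    """Upper-tail hypergeometric ORA of ``query`` against every GMT term.

    The background universe defaults to the union of all GMT genes.  Query
    genes outside the background are dropped with a logged count; terms with
    no background gene are skipped.  Raises ``ValueError`` if nothing of the
    query survives the intersection.
    """
    norm_sets = {term: {g.upper() for g in genes} for term, genes in gene_sets.items()}
    if background is None:
        bg = set().union(*norm_sets.values()) if norm_sets else set()
    else:
        bg = {g.upper() for g in background}
    query = {g.upper() for g in query}
    dropped = len(query - bg)
    query &= bg
    if dropped:
        logger.info("ora: %d query gene(s) outside the background dropped", dropped)
    if not query:
        raise ValueError("query is empty after intersecting with the background universe")
    N, n = len(bg), len(query)
    rows = []
    for term in norm_sets:
        members = norm_sets[term] & bg
        K = len(members)
        if K == 0:
            continue
        k = len(members & query)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, n, K, N, min(p, 1.0)))
    table = pd.DataFrame(rows, columns=["term_id", "k", "n", "K", "N", "p_value"])
    if len(table):
        table["p_adjusted"] = multipletests(table["p_value"].to_numpy(), method="fdr_bh")[1]
    else:
        table["p_adjusted"] = pd.Series(dtype=float)
    crit = table["p_adjusted"] if adjusted else table["p_value"]
    significant = set(table.loc[crit < alpha, "term_id"])
    return EnrichmentResult(table=table, significant_terms=significant, alpha=alpha, adjusted=adjusted)


def effective_terms(
    target_genes: Iterable[str],
    pathogenic_genes: Iterable[str],
    gene_sets: Mapping[str, set[str]],
    background: Optional[Iterable[str]] = None,
    alpha: float = 0.05,
    adjusted: bool = False,
) -> set[str]:
    """Significant terms shared by the target gene set and the disease gene set."""
    sig_t = ora(target_genes, gene_sets, background, alpha, adjusted).significant_terms
    sig_p = ora(pathogenic_genes, gene_sets, background, alpha, adjusted).significant_terms
    return sig_t & sig_p


def method_coverage(
    method_results: Mapping[str, ImportanceResult],
    effective: set[str],
    gene_sets: Mapping[str, set[str]],
    background: Optional[Iterable[str]] = None,
    alpha: float = 0.05,
    adjusted: bool = False,
) -> dict[str, float]:
    """Effective-term coverage of each importance method's key network.

    ``coverage = |significant(ORA(key-network genes)) ∩ effective| /
    |effective|``.  A method whose key network contributes no usable query
    genes covers 0.
    """
    if not effective:
        raise ValueError("effective term set is empty; coverage comparison undefined")
    out: dict[str, float] = {}
    for method, res in method_results.items():
        genes = res.key_genes()
        try:
            sig = ora(genes, gene_sets, background, alpha, adjusted).significant_terms
        except ValueError:
            sig = set()
        out[method] = len(sig & effective) / len(effective)
    return out
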