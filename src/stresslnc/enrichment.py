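"""Hypergeometric over-representation analysis of target gene sets.

For a term annotated to K of N background genes, with k of the n foreground
genes carrying it, the enrichment p-value is the exact upper tail

    p = sum_{i=k}^{min(n,K)} C(K,i) C(N-K, n-i) / C(N, n).

BH q-values are computed within each namespace separately, so adding
pathway terms can never change GO q-values.  Significance follows the
asymmetric reporting convention of the analysis this package reproduces:
GO terms at raw p < 0.05, pathways at BH q < 0.05 (both configurable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .expression import bh_adjust

__all__ = [
    "EnrichmentResult",
    "hypergeom_pvalue",
    "hypergeom_enrich",
    "enrichment_to_frame",
    "read_term_map",
    "GO_NAMESPACES",
]


def hypergeom_pvalue(k: int, N: int, K: int, n: int) -> float:
    """Exact upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not 0 <= k <= min(n, K):
        raise ValueError(f"k={k} outside [0, min(n, K)]")
    return float(min(1.0, stats.hypergeom.sf(k - 1, N, K, n)))

GO_NAMESPACES = ("BP", "CC", "MF", "GO")


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    namespace: str
    k: int
    n: int
    K: int
    N: int
    pvalue: float
    qvalue: float
    significant: bool


def read_term_map(path) -> pd.DataFrame:
    """Read a gene->term TSV with columns gene_id, term_id[, namespace, name]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "namespace" not in df.columns:
        df["namespace"] = "GO"
    if "name" not in df.columns:
        df["name"] = df["term_id"]
    return df[["gene_id", "term_id", "namespace", "name"]]


def hypergeom_enrich(
    foreground: Iterable[str],
    background: Iterable[str],
    term_map: pd.DataFrame | Mapping[str, Iterable[str]],
    go_p: float = 0.05,
    pathway_q: float = 0.05,
) -> list[EnrichmentResult]:
    """Exact hypergeometric enrichment of foreground genes per term.

    ``term_map`` is either a DataFrame (gene_id, term_id, namespace, name)
    or a mapping gene -> terms (namespace then defaults to "GO").  Genes in
    the background without annotation count toward N only.  Terms with no
    foreground gene are excluded from the output, which is sorted by
    (namespace, pvalue, term_id).
    """
    fg = set(foreground)
    bg = set(background)
    if not fg:
        raise ValueError("empty foreground")
    if not fg <= bg:
        raise ValueError(f"foreground not contained in background: {sorted(fg - bg)[:5]}")

    if isinstance(term_map, pd.DataFrame):
        df = term_map
    else:
        df = pd.DataFrame(
            [(g, t) for g, terms in term_map.items() for t in terms],
            columns=["gene_id", "term_id"],
        )
        df["namespace"] = "GO"
        df["name"] = df["term_id"]
    df = df[df["gene_id"].isin(bg)]

    N, n = len(bg), len(fg)
    rows = []
    for (term, namespace, name), sub in df.groupby(
        ["term_id", "namespace", "name"], sort=True
    ):
        genes = set(sub["gene_id"])
        K = len(genes)
        k = len(genes & fg)
        if k == 0:
            continue
        rows.append([term, name, namespace, k, n, K, N, hypergeom_pvalue(k, N, K, n)])

    results: list[EnrichmentResult] = []
    frame = pd.DataFrame(
        rows, columns=["term_id", "name", "namespace", "k", "n", "K", "N", "pvalue"]
    )
    for namespace, sub in frame.groupby("namespace"):
        q = bh_adjust(sub["pvalue"].values)
        for (_, row), qv in zip(sub.iterrows(), q):
            sig = (
                qv < pathway_q
                if namespace == "pathway"
                else row["pvalue"] < go_p
            )
            results.append(
                EnrichmentResult(
                    term_id=row["term_id"],
                    term_name=row["name"],
                    namespace=namespace,
                    k=int(row["k"]),
                    n=int(row["n"]),
                    K=int(row["K"]),
                    N=int(row["N"]),
                    pvalue=float(row["pvalue"]),
                    qvalue=float(qv),
                    significant=bool(sig),
                )
            )
    results.sort(key=lambda r: (r.namespace, r.pvalue, r.term_id))
    return results


def enrichment_to_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "term_name": r.term_name,
                "namespace": r.namespace,
                "k": r.k,
                "n": r.n,
                "K": r.K,
                "N": r.N,
                "pvalue": r.pvalue,
                "qvalue": r.qvalue,
                "significant": r.significant,
            }
            for r in results
        ],
        columns=[
            "term_id", "term_name", "namespace", "k", "n", "K", "N",
            "pvalue", "qvalue", "significant",
        ],
    )
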