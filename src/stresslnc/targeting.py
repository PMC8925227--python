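"""cis/trans target prediction for differentially expressed lncRNAs.

A protein-coding gene is a *cis* target of a lncRNA when it lies within a
100-kb window either side of the lncRNA span on the same chromosome (strand
ignored; the boundary gap of exactly 100,000 bp is included).  A gene is a
*trans* target when the Pearson correlation of the two expression profiles
across all samples satisfies |r| >= 0.95.  "Common targets" are genes that
are a cis target of some DE lncRNA, a trans target of some DE lncRNA, and
themselves differentially expressed.

Note: with six samples an |r| >= 0.95 cutoff carries no multiplicity
control; no p-value filter is applied to r, by design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import AnnotationSet, GenomicInterval, TranscriptModel

__all__ = [
    "TargetLink",
    "CommonTargetSet",
    "cis_targets",
    "trans_targets",
    "common_targets",
    "links_to_frame",
]

DEFAULT_CIS_WINDOW = 100_000
DEFAULT_R_MIN = 0.95


@dataclass(frozen=True)
class TargetLink:
    """A predicted (lncRNA, gene) regulatory relation."""

    lnc_id: str
    gene_id: str
    mode: str  # "cis" or "trans"
    distance: int | None = None  # bp gap, cis only; 0 on overlap
    r: float | None = None  # Pearson correlation, trans only

    def __post_init__(self) -> None:
        if self.mode not in ("cis", "trans"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "cis" and self.distance is None:
            raise ValueError("cis link requires a distance")
        if self.mode == "trans" and self.r is None:
            raise ValueError("trans link requires a correlation")


def links_to_frame(links: Iterable[TargetLink]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lnc_id": l.lnc_id,
                "gene_id": l.gene_id,
                "mode": l.mode,
                "distance": "" if l.distance is None else l.distance,
                "r": "" if l.r is None else l.r,
            }
            for l in links
        ],
        columns=["lnc_id", "gene_id", "mode", "distance", "r"],
    )


def cis_targets(
    de_lncs: Iterable[TranscriptModel],
    genes: AnnotationSet | Mapping[str, GenomicInterval],
    window: int = DEFAULT_CIS_WINDOW,
) -> list[TargetLink]:
    """Genes within ``window`` bp of each lncRNA span (gap <= window).

    The gap is ``later.start - earlier.end - 1`` and 0 on overlap; strand is
    ignored.  Output is sorted by (lnc_id, gene_id).
    """
    gene_spans = genes.genes if isinstance(genes, AnnotationSet) else dict(genes)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    for chrom in {iv.chrom for iv in gene_spans.values()}:
        items = sorted(
            ((gid, iv) for gid, iv in gene_spans.items() if iv.chrom == chrom),
            key=lambda kv: (kv[1].start, kv[0]),
        )
        by_chrom[chrom] = (
            np.array([iv.start for _, iv in items]),
            np.array([iv.end for _, iv in items]),
            [gid for gid, _ in items],
        )

    links: list[TargetLink] = []
    for lnc in de_lncs:
        span = lnc.interval
        entry = by_chrom.get(span.chrom)
        if entry is None:
            continue
        starts, ends, gids = entry
        near = (starts <= span.end + window + 1) & (ends >= span.start - window - 1)
        for i in np.flatnonzero(near):
            giv = GenomicInterval(span.chrom, int(starts[i]), int(ends[i]))
            gap = span.gap(giv)
            if gap is not None and gap <= window:
                links.append(
                    TargetLink(lnc.transcript_id, gids[i], "cis", distance=gap)
                )
    links.sort(key=lambda l: (l.lnc_id, l.gene_id))
    return links


def trans_targets(
    de_lnc_ids: Sequence[str],
    gene_ids: Sequence[str],
    fpkm: pd.DataFrame,
    r_min: float = DEFAULT_R_MIN,
    log2: bool = False,
) -> list[TargetLink]:
    """lncRNA-gene pairs whose FPKM profiles correlate with |r| >= r_min.

    Correlation is computed on raw FPKM across all samples (``log2=True``
    switches to log2(FPKM+1)).  Zero-variance profiles are skipped with a
    warning.  Self-pairs (same feature id) are never emitted.
    """
    if fpkm.shape[1] < 3:
        raise ValueError("trans prediction needs >= 3 samples")
    missing = [f for f in list(de_lnc_ids) + list(gene_ids) if f not in fpkm.index]
    if missing:
        raise ValueError(f"features missing from FPKM table: {missing[:10]}")

    X = fpkm.loc[list(de_lnc_ids)].values.astype(float)
    Y = fpkm.loc[list(gene_ids)].values.astype(float)
    if log2:
        X, Y = np.log2(X + 1), np.log2(Y + 1)
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    xn = np.sqrt((Xc**2).sum(axis=1))
    yn = np.sqrt((Yc**2).sum(axis=1))
    n_skip = int((xn == 0).sum() + (yn == 0).sum())
    if n_skip:
        warnings.warn(f"skipping {n_skip} zero-variance profiles (undefined r)")
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (Xc @ Yc.T) / np.outer(xn, yn)

    links: list[TargetLink] = []
    for i, lnc in enumerate(de_lnc_ids):
        for j in np.flatnonzero(np.abs(R[i]) >= r_min):
            gene = gene_ids[j]
            if gene == lnc or not np.isfinite(R[i, j]):
                continue
            links.append(TargetLink(lnc, gene, "trans", r=float(R[i, j])))
    links.sort(key=lambda l: (l.lnc_id, l.gene_id))
    return links


@dataclass
class CommonTargetSet:
    """Genes that are cis targets, trans targets and differentially expressed."""

    members: dict[str, dict] = field(default_factory=dict)

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.members

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": g,
                "n_cis_links": len(m["cis"]),
                "n_trans_links": len(m["trans"]),
                "de_flag": m["de_flag"],
            }
            for g, m in sorted(self.members.items())
        ]
        return pd.DataFrame(
            rows, columns=["gene_id", "n_cis_links", "n_trans_links", "de_flag"]
        )


def common_targets(
    cis_links: Iterable[TargetLink],
    trans_links: Iterable[TargetLink],
    de_flags: Mapping[str, str] | pd.Series,
    mode: str = "any_lnc",
) -> CommonTargetSet:
    """Intersect cis and trans predictions over differentially expressed genes.

    mode "any_lnc" (default): the cis and trans links may come from different
    lncRNAs; mode "same_lnc": at least one lncRNA must support both.
    """
    if mode not in ("any_lnc", "same_lnc"):
        raise ValueError(f"unknown mode {mode!r}")
    flags = dict(de_flags) if not isinstance(de_flags, pd.Series) else de_flags.to_dict()

    cis_by_gene: dict[str, list[TargetLink]] = {}
    for l in cis_links:
        cis_by_gene.setdefault(l.gene_id, []).append(l)
    trans_by_gene: dict[str, list[TargetLink]] = {}
    for l in trans_links:
        trans_by_gene.setdefault(l.gene_id, []).append(l)

    out = CommonTargetSet()
    for gene in sorted(set(cis_by_gene) & set(trans_by_gene)):
        if flags.get(gene, "ns") == "ns":
            continue
        cis_l, trans_l = cis_by_gene[gene], trans_by_gene[gene]
        if mode == "same_lnc":
            shared = {l.lnc_id for l in cis_l} & {l.lnc_id for l in trans_l}
            if not shared:
                continue
            cis_l = [l for l in cis_l if l.lnc_id in shared]
            trans_l = [l for l in trans_l if l.lnc_id in shared]
        out.members[gene] = {
            "cis": cis_l,
            "trans": trans_l,
            "de_flag": flags[gene],
        }
    return out
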