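"""miRNA -> lncRNA target prediction by complementarity expectation scoring.

An ungapped antiparallel window of miRNA length slides along the lncRNA;
each miRNA position (counted from its 5' end) is paired with the opposite
target base and penalized 0 for a Watson-Crick pair, 0.5 for a G:U wobble
and 1.0 for a mismatch.  Penalties inside the seed region (miRNA positions
2-13 by default) are doubled.  The expectation of a site is the penalty
sum; sites at or below the cutoff (default 5.0) are reported, best first.
A perfect complementary site therefore scores exactly 0.

T and U are equivalent throughout.  Gaps/bulges and target-accessibility
scoring are deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["MirnaSiteHit", "ScoringParams", "score_sites", "dem_delnc_links"]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
# (miRNA base, target base) pairs counted as G:U wobble
_WOBBLE = {("G", "T"), ("T", "G")}

MIN_MIRNA_LEN = 15


@dataclass(frozen=True)
class ScoringParams:
    gu_penalty: float = 0.5
    mismatch_penalty: float = 1.0
    seed_start: int = 2  # miRNA positions, 1-based inclusive
    seed_end: int = 13
    seed_multiplier: float = 2.0
    cutoff: float = 5.0


@dataclass(frozen=True)
class MirnaSiteHit:
    mirna_id: str
    lnc_id: str
    site_start: int  # 1-based position of the aligned window on the lncRNA
    expectation: float
    alignment: tuple[str, ...]  # per miRNA position: match | gu | mismatch

    @property
    def alignment_string(self) -> str:
        return "".join({"match": "|", "gu": "o", "mismatch": "."}[s] for s in self.alignment)


def _clean(seq: str, what: str) -> str:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"{what} contains non-nucleotide symbols: {sorted(bad)}")
    return seq


def score_sites(
    mirna: str,
    lnc_seq: str,
    params: ScoringParams | None = None,
    mirna_id: str = "",
    lnc_id: str = "",
) -> list[MirnaSiteHit]:
    """All target windows on ``lnc_seq`` with expectation <= cutoff.

    The miRNA is aligned antiparallel: its 5' end pairs with the 3' side of
    the window, so miRNA position i faces window position L - i + 1.
    Hits are sorted by expectation, ties by leftmost site.
    """
    params = params or ScoringParams()
    m = _clean(mirna, "miRNA")
    t = _clean(lnc_seq, "lncRNA sequence")
    L = len(m)
    if L < MIN_MIRNA_LEN:
        raise ValueError(f"miRNA shorter than {MIN_MIRNA_LEN} nt ({L})")
    if L > len(t):
        raise ValueError("miRNA longer than the target sequence")

    weights = np.ones(L)
    weights[params.seed_start - 1 : params.seed_end] = params.seed_multiplier

    hits: list[MirnaSiteHit] = []
    for off in range(len(t) - L + 1):
        window = t[off : off + L]
        states = []
        total = 0.0
        for i in range(L):
            mb = m[i]
            tb = window[L - 1 - i]
            if _COMPLEMENT[mb] == tb:
                states.append("match")
            elif (mb, tb) in _WOBBLE:
                states.append("gu")
                total += params.gu_penalty * weights[i]
            else:
                states.append("mismatch")
                total += params.mismatch_penalty * weights[i]
            if total > params.cutoff:
                break
        if total <= params.cutoff and len(states) == L:
            hits.append(
                MirnaSiteHit(
                    mirna_id=mirna_id,
                    lnc_id=lnc_id,
                    site_start=off + 1,
                    expectation=total,
                    alignment=tuple(states),
                )
            )
    hits.sort(key=lambda h: (h.expectation, h.site_start))
    return hits


def dem_delnc_links(
    dems: Mapping[str, str],
    delncs: Mapping[str, str],
    params: ScoringParams | None = None,
) -> pd.DataFrame:
    """Best-site links between DE miRNAs and DE lncRNA sequences.

    ``dems`` maps miRNA id -> sequence, ``delncs`` maps lncRNA id ->
    sequence.  One row per (miRNA, lncRNA) pair with at least one site at or
    below the cutoff, carrying the pair's best (lowest-expectation) site.
    """
    params = params or ScoringParams()
    missing = [k for k, v in list(dems.items()) + list(delncs.items()) if not v]
    if missing:
        raise ValueError(f"missing sequences for: {missing}")
    rows = []
    for mid in sorted(dems):
        for lid in sorted(delncs):
            if len(dems[mid]) > len(delncs[lid]):
                continue
            hits = score_sites(dems[mid], delncs[lid], params, mirna_id=mid, lnc_id=lid)
            if hits:
                best = hits[0]
                rows.append(
                    {
                        "mirna_id": mid,
                        "lnc_id": lid,
                        "site_start": best.site_start,
                        "expectation": best.expectation,
                        "alignment": best.alignment_string,
                    }
                )
    return pd.DataFrame(
        rows, columns=["mirna_id", "lnc_id", "site_start", "expectation", "alignment"]
    )
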