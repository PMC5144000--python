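"""Post-quantification metrics: relative contribution and miRNA cleavage sites.

Relative contribution (RC) is a circle's abundance divided by its host gene's
abundance; because library and sequencing biases act similarly on a circRNA
and its host, the quotient enables cross-sample comparison.  miRNA-guided
cleavage sites are full-length miRNA matches with at most 4 mismatches, none
of which may fall in the seed (miRNA positions 2-8); the circle sequence is
doubled so sites spanning the back-splice junction are found exactly once.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable

from .formats import revcomp

MISSING = float("nan")


def relative_contribution(circ_abundance: float, host_abundance: float) -> float:
    """circ/host quotient; NaN (missing) when the host has zero abundance."""
    if circ_abundance < 0 or host_abundance < 0:
        raise ValueError("abundances must be non-negative")
    if host_abundance == 0:
        return MISSING
    return circ_abundance / host_abundance


def _clean_mirna(seq: str) -> str | None:
    seq = seq.upper().replace("U", "T")
    if set(seq) - set("ACGT"):
        return None
    return seq


def mirna_cleavage_sites(
    circ_monomer_seq: str,
    mirnas: Iterable[tuple[str, str]],
    max_mismatch: int = 4,
    seed_region: tuple[int, int] = (2, 8),
) -> int:
    """Count full-length miRNA binding sites on a circle.

    The reverse complement of each miRNA is slid over the doubled circle
    sequence at offsets 0..L-1 (L = monomer length), so a site spanning the
    BSJ is counted once.  A position is a site iff total mismatches <=
    ``max_mismatch`` AND no mismatch falls within the seed (miRNA positions
    ``seed_region``, 1-based).  miRNAs with non-ACGTU characters are skipped
    with a warning; U is read as T.
    """
    monomer = circ_monomer_seq.upper()
    L = len(monomer)
    doubled = monomer * 2
    lo_seed, hi_seed = seed_region
    total = 0
    for name, mseq in mirnas:
        mseq_clean = _clean_mirna(mseq)
        if mseq_clean is None:
            warnings.warn(f"miRNA {name}: non-ACGTU characters; skipped")
            continue
        k = len(mseq_clean)
        if k > L:
            continue
        target = revcomp(mseq_clean)
        for p in range(L):
            window = doubled[p : p + k]
            mm = 0
            seed_hit = False
            for t in range(k):
                if window[t] != target[t]:
                    mm += 1
                    mir_pos = k - t  # target index t pairs miRNA position k - t
                    if lo_seed <= mir_pos <= hi_seed:
                        seed_hit = True
                        break
                    if mm > max_mismatch:
                        break
            else:
                total += 1
                continue
            if not seed_hit and mm <= max_mismatch:
                total += 1
    return total


def annotate_expression(
    abundance_df,
    gene_abundance: dict[str, float],
    circ_host: dict[str, str],
    circ_monomers: dict[str, str] | None = None,
    mirnas: list[tuple[str, str]] | None = None,
    max_mismatch: int = 4,
):
    """Extend an abundance table with rc and mirna_site_count columns.

    ``gene_abundance`` maps host gene ids to linear abundance; circles whose
    host gene is unknown or has zero abundance get a missing rc.  The table
    keeps a ``folding_energy`` column for optional ingestion of external
    secondary-structure results.
    """
    df = abundance_df.copy()
    rcs, sites = [], []
    for cid, ab in zip(df["circ_id"], df["abundance"]):
        host = circ_host.get(cid)
        host_ab = gene_abundance.get(host, 0.0) if host else 0.0
        rcs.append(relative_contribution(float(ab), float(host_ab)) if host else MISSING)
        if mirnas and circ_monomers and cid in circ_monomers:
            sites.append(mirna_cleavage_sites(circ_monomers[cid], mirnas, max_mismatch))
        else:
            sites.append(0 if mirnas else math.nan)
    df["rc"] = rcs
    df["mirna_site_count"] = sites
    if "folding_energy" not in df.columns:
        df["folding_energy"] = math.nan
    return df
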