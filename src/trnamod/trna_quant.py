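"""Isodecoder-level tRNA quantification with modification-tolerant mapping.

Mature tRNAs within an anticodon family differ by only a handful of bases,
and modified positions read out as apparent mismatches, so quantification
assigns each read to its best ungapped match over all references while
mismatches at known modified positions cost nothing.  Reads tied between
references are split fractionally; reads beyond the mismatch budget are
discarded.  Differential abundance between two samples is computed on
per-sample isodecoder proportions with a two-proportion test on raw counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log2
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from .core_io import ReferenceSet, normalize_sequence


@dataclass
class IsodecoderCounts:
    """Fractional read counts per isodecoder for one sample."""

    sample_id: str
    counts: dict[str, float]
    assigned_total: int
    discarded_total: int


@dataclass
class AbundanceResult:
    isodecoder_id: str
    proportion_A: float
    proportion_B: float
    log2fc: float
    p_value: float
    q_value: float


def assign_reads(
    reads: Iterable[str],
    refs: ReferenceSet,
    max_mismatch: int = 2,
    mod_mask: set[tuple[str, int]] | None = None,
    sample_id: str = "sample",
) -> IsodecoderCounts:
    """Assign reads to isodecoders by masked ungapped Hamming distance.

    Each read is scored against every reference at its best ungapped
    offset; mismatches at ``mod_mask`` positions (1-based, per reference)
    cost 0.  A read is assigned to the minimum-distance reference if that
    distance is <= ``max_mismatch``, split equally among co-minimal
    references on ties, and discarded otherwise (including reads longer
    than every reference).
    """
    if len(refs) == 0:
        raise ValueError("empty reference set")
    mod_mask = mod_mask or set()
    enc = {}
    masks = {}
    for rec in refs:
        enc[rec.id] = np.frombuffer(rec.sequence.encode(), dtype=np.uint8)
        m = np.zeros(len(rec), dtype=bool)
        for rid, pos in mod_mask:
            if rid == rec.id and 1 <= pos <= len(rec):
                m[pos - 1] = True
        masks[rec.id] = m

    counts: dict[str, float] = {rec.id: 0.0 for rec in refs}
    assigned = 0
    discarded = 0
    # identical reads share one scoring pass
    unique: dict[str, int] = {}
    for read in reads:
        read = normalize_sequence(read)
        unique[read] = unique.get(read, 0) + 1

    for read, n in unique.items():
        arr = np.frombuffer(read.encode(), dtype=np.uint8)
        best = None
        winners: list[str] = []
        for rec in refs:
            ref_arr = enc[rec.id]
            if len(arr) > len(ref_arr) or len(arr) == 0:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(ref_arr, len(arr))
            mask_win = np.lib.stride_tricks.sliding_window_view(
                masks[rec.id], len(arr)
            )
            dists = ((windows != arr) & ~mask_win).sum(axis=1)
            d = int(dists.min())
            if best is None or d < best:
                best = d
                winners = [rec.id]
            elif d == best:
                winners.append(rec.id)
        if best is None or best > max_mismatch:
            discarded += n
            continue
        assigned += n
        for rid in winners:
            counts[rid] += n / len(winners)
    return IsodecoderCounts(
        sample_id=sample_id,
        counts=counts,
        assigned_total=assigned,
        discarded_total=discarded,
    )


def proportions(counts: Mapping[str, float], pseudocount: float = 0.5) -> dict[str, float]:
    """Pseudocounted isodecoder proportions for one sample (sum to 1)."""
    ids = sorted(counts)
    vals = np.array([counts[i] for i in ids], dtype=float) + pseudocount
    return dict(zip(ids, (vals / vals.sum()).tolist()))


def differential_abundance(
    a: IsodecoderCounts, b: IsodecoderCounts, pseudocount: float = 0.5
) -> list[AbundanceResult]:
    """Per-isodecoder abundance change from sample A to sample B.

    log2 fold change is computed on pseudocounted proportions; the p-value
    is a two-proportion z-test on the raw (un-pseudocounted) counts, with
    Benjamini-Hochberg correction across isodecoders.
    """
    universe = sorted(set(a.counts) | set(b.counts))
    tot_a = sum(a.counts.values())
    tot_b = sum(b.counts.values())
    if tot_a <= 0 or tot_b <= 0:
        raise ValueError("zero total counts in at least one sample")
    counts_a = {i: a.counts.get(i, 0.0) for i in universe}
    counts_b = {i: b.counts.get(i, 0.0) for i in universe}
    prop_a = proportions(counts_a, pseudocount)
    prop_b = proportions(counts_b, pseudocount)
    pvals = []
    for i in universe:
        ca, cb = counts_a[i], counts_b[i]
        if ca == 0 and cb == 0:
            pvals.append(1.0)
            continue
        _, p = proportions_ztest(
            np.array([round(ca), round(cb)]),
            np.array([round(tot_a), round(tot_b)]),
        )
        pvals.append(1.0 if np.isnan(p) else float(p))
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    return [
        AbundanceResult(
            isodecoder_id=i,
            proportion_A=prop_a[i],
            proportion_B=prop_b[i],
            log2fc=log2(prop_b[i] / prop_a[i]),
            p_value=pvals[k],
            q_value=float(qvals[k]),
        )
        for k, i in enumerate(universe)
    ]


def rollup_by_family(
    counts: Mapping[str, float], family_of: Mapping[str, str]
) -> dict[str, float]:
    """Aggregate isodecoder counts to anticodon families for reporting."""
    out: dict[str, float] = {}
    for iso, n in counts.items():
        fam = family_of.get(iso, iso)
        out[fam] = out.get(fam, 0.0) + n
    return out
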