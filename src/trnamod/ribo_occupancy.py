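"""Ribosome and disome footprint analysis: per-codon occupancy statistics.

A footprint's decoding-site codons are located from its 5' end via a
length-specific A-site offset table; the P and E sites are the two codons
immediately 5' of the A site.  Per-codon occupancy is the mean, over all
occurrences of a codon across included transcripts, of the transcript-
normalised read density at that codon (so 1.0 means "average dwell").
For disome footprints the offset targets the A site of the leading (stalled)
ribosome of the collided pair.

The module also provides KO/WT occupancy ratios, meta-codon profiles
averaged around every occurrence of a chosen codon, and a simple
translation-efficiency (footprint density relative to mRNA abundance)
classifier.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core_io import AlignmentRecord, ReferenceSet

logger = logging.getLogger("trnamod")


@dataclass
class OffsetTable:
    """Footprint-length -> A-site-offset (nt from the 5' end) lookup.

    Footprints whose length is not listed are rejected by site assignment.
    """

    kind: str  # "monosome" or "disome"
    offsets: dict[int, int]

    def offset(self, length: int) -> int | None:
        return self.offsets.get(length)

    def lengths(self) -> list[int]:
        return sorted(self.offsets)


#: Default monosome offsets (common practice for 28-30 nt footprints).
MONOSOME_OFFSETS = OffsetTable("monosome", {28: 12, 29: 12, 30: 13})
#: Default disome offsets targeting the leading ribosome's A site.
DISOME_OFFSETS = OffsetTable("disome", {n: 45 for n in range(59, 64)})


def default_offsets(kind: str) -> OffsetTable:
    if kind == "monosome":
        return MONOSOME_OFFSETS
    if kind == "disome":
        return DISOME_OFFSETS
    raise ValueError(f"unknown footprint kind {kind!r}")


@dataclass
class SiteAssignment:
    """1-based E/P/A codon indices of one footprint."""

    E: int
    P: int
    A: int

    def __getitem__(self, site: str) -> int:
        return getattr(self, site)


def assign_sites(
    fp: AlignmentRecord, offsets: OffsetTable, cds_length: int
) -> SiteAssignment | None:
    """Locate the E/P/A codons of a footprint; ``None`` if rejected.

    A-site codon index = floor((start - 1 + offset(length)) / 3) + 1, with
    P = A - 1 and E = A - 2.  Footprints of unlisted length, footprints
    extending outside the CDS, and footprints whose E index < 1 or A index
    beyond the last codon are rejected.
    """
    length = len(fp.bases)
    off = offsets.offset(length)
    if off is None:
        return None
    if fp.start < 1 or fp.end > cds_length:
        return None
    a = (fp.start - 1 + off) // 3 + 1
    if a - 2 < 1 or a > cds_length // 3:
        return None
    return SiteAssignment(E=a - 2, P=a - 1, A=a)


@dataclass
class OccupancyTable:
    site: str
    values: dict[str, float]
    n_occurrences: dict[str, int]
    kind: str = "monosome"
    n_transcripts: int = 0


def _site_codon_indices(
    footprints: Sequence[AlignmentRecord],
    offsets: OffsetTable,
    cds_lengths: Mapping[str, int],
    site: str,
) -> tuple[dict[str, np.ndarray], int]:
    """Per-transcript arrays of 1-based chosen-site codon indices.

    Returns the arrays and the number of rejected footprints.
    """
    if site not in ("E", "P", "A"):
        raise ValueError(f"site must be E, P or A, not {site!r}")
    by_ref: dict[str, list[int]] = {}
    rejected = 0
    for fp in footprints:
        n = cds_lengths.get(fp.ref_id)
        if n is None:
            rejected += 1
            continue
        assignment = assign_sites(fp, offsets, n)
        if assignment is None:
            rejected += 1
            continue
        by_ref.setdefault(fp.ref_id, []).append(assignment[site])
    if rejected:
        logger.info("rejected %d footprints (length/boundary)", rejected)
    return {k: np.asarray(v, dtype=int) for k, v in by_ref.items()}, rejected


def _codons_of(seq: str) -> list[str]:
    return [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]


def codon_occupancy(
    footprints: Sequence[AlignmentRecord],
    cds: ReferenceSet,
    offsets: OffsetTable,
    site: str = "A",
    exclude_start: int = 15,
    exclude_end: int = 5,
    min_reads_per_transcript: int = 64,
) -> OccupancyTable:
    """Mean normalised per-codon density at the chosen decoding site.

    Per included transcript, density(codon i) = reads with the chosen site
    at codon i divided by the mean reads per included codon (so the mean
    density over included codons is exactly 1).  The first ``exclude_start``
    and last ``exclude_end`` codons are excluded to avoid initiation and
    termination artifacts, and transcripts with fewer than
    ``min_reads_per_transcript`` reads in the included region are dropped.
    Occupancy per codon identity is the unweighted mean of density over all
    included occurrences of that codon across transcripts.
    """
    for rec in cds:
        if len(rec) % 3:
            raise ValueError(f"CDS {rec.id!r} length not divisible by 3")
    cds_lengths = {rec.id: len(rec) for rec in cds}
    by_ref, _ = _site_codon_indices(footprints, offsets, cds_lengths, site)

    sums: dict[str, float] = {}
    ns: dict[str, int] = {}
    n_transcripts = 0
    for rec in cds:
        idx = by_ref.get(rec.id)
        if idx is None:
            continue
        n_codons = len(rec) // 3
        lo, hi = exclude_start + 1, n_codons - exclude_end  # 1-based inclusive
        if hi < lo:
            continue
        counts = np.bincount(idx, minlength=n_codons + 1)[1:]  # per codon 1..n
        included = counts[lo - 1 : hi]
        total = int(included.sum())
        if total < min_reads_per_transcript:
            continue
        n_transcripts += 1
        density = included / included.mean()
        codons = _codons_of(rec.sequence)[lo - 1 : hi]
        for codon, d in zip(codons, density):
            sums[codon] = sums.get(codon, 0.0) + float(d)
            ns[codon] = ns.get(codon, 0) + 1
    if n_transcripts == 0:
        raise ValueError("no transcript passes the minimum read threshold")
    values = {c: sums[c] / ns[c] for c in sums}
    return OccupancyTable(
        site=site,
        values=values,
        n_occurrences=ns,
        kind=offsets.kind,
        n_transcripts=n_transcripts,
    )


def occupancy_ratio(
    ko: OccupancyTable, wt: OccupancyTable, min_occurrences: int = 100
) -> dict[str, float]:
    """Per-codon KO/WT occupancy ratio over well-observed codons.

    Codons with fewer than ``min_occurrences`` included occurrences in
    either condition are omitted, as are codons with zero WT occupancy
    (logged as a warning).
    """
    ratios: dict[str, float] = {}
    for codon, ko_val in ko.values.items():
        if codon not in wt.values:
            continue
        if ko.n_occurrences[codon] < min_occurrences:
            continue
        if wt.n_occurrences[codon] < min_occurrences:
            continue
        wt_val = wt.values[codon]
        if wt_val == 0:
            logger.warning("codon %s has zero occupancy in WT; omitted", codon)
            continue
        ratios[codon] = ko_val / wt_val
    return ratios


def metacodon_profile(
    footprints: Sequence[AlignmentRecord],
    cds: ReferenceSet,
    offsets: OffsetTable,
    center_codon: str,
    window: int = 30,
    min_local_coverage: int = 1,
    site: str = "A",
    exclude_start: int = 15,
    exclude_end: int = 5,
    min_reads_per_transcript: int = 64,
) -> np.ndarray:
    """Average normalised density around every occurrence of a codon.

    Returns a vector of length ``2 * window + 1``; index ``window`` is the
    centre codon, positions are in codons relative to it.  Occurrences whose
    full window does not fit inside the included region, or whose window
    holds fewer than ``min_local_coverage`` reads, are skipped.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    center_codon = center_codon.upper().replace("U", "T")
    cds_lengths = {rec.id: len(rec) for rec in cds}
    by_ref, _ = _site_codon_indices(footprints, offsets, cds_lengths, site)

    acc = np.zeros(2 * window + 1)
    n_occ = 0
    for rec in cds:
        idx = by_ref.get(rec.id)
        if idx is None:
            continue
        n_codons = len(rec) // 3
        lo, hi = exclude_start + 1, n_codons - exclude_end
        if hi < lo:
            continue
        counts = np.bincount(idx, minlength=n_codons + 1)[1:]
        included = counts[lo - 1 : hi]
        if int(included.sum()) < min_reads_per_transcript:
            continue
        density = included / included.mean()
        codons = _codons_of(rec.sequence)
        for pos in range(lo + window, hi - window + 1):  # 1-based centre
            if codons[pos - 1] != center_codon:
                continue
            w0 = (pos - window) - lo  # offset into the included slice
            raw = counts[pos - window - 1 : pos + window]
            if int(raw.sum()) < min_local_coverage:
                continue
            acc += density[w0 : w0 + 2 * window + 1]
            n_occ += 1
    if n_occ == 0:
        raise ValueError(f"no qualifying occurrence of codon {center_codon}")
    return acc / n_occ


# ---------------------------------------------------------------------------
# Translation efficiency
# ---------------------------------------------------------------------------

@dataclass
class TEClassification:
    transcript_id: str
    te_A: float
    te_B: float
    delta_log2_te: float
    te_class: str  # up | down | unchanged


def translation_efficiency(
    rpf_counts: Mapping[str, float],
    rna_counts: Mapping[str, float],
    pseudocount: float = 0.5,
) -> dict[str, float]:
    """TE per transcript: footprint proportion over mRNA proportion.

    Proportions use ``(count + pseudocount)`` normalisation over the shared
    transcript universe.
    """
    transcripts = sorted(set(rpf_counts) | set(rna_counts))
    if not transcripts:
        raise ValueError("empty transcript universe")
    rpf = np.array([rpf_counts.get(t, 0) for t in transcripts], dtype=float)
    rna = np.array([rna_counts.get(t, 0) for t in transcripts], dtype=float)
    if rpf.sum() <= 0 or rna.sum() <= 0:
        raise ValueError("zero total counts")
    rpf_prop = (rpf + pseudocount) / (rpf + pseudocount).sum()
    rna_prop = (rna + pseudocount) / (rna + pseudocount).sum()
    te = rpf_prop / rna_prop
    return dict(zip(transcripts, te.tolist()))


def classify_te(
    te_a: Mapping[str, float],
    te_b: Mapping[str, float],
    threshold_log2: float = 1.0,
) -> list[TEClassification]:
    """Classify transcripts as TE up/down/unchanged from condition A to B."""
    out = []
    for t in sorted(set(te_a) & set(te_b)):
        delta = math.log2(te_b[t] / te_a[t])
        if delta <= -threshold_log2:
            cls = "down"
        elif delta >= threshold_log2:
            cls = "up"
        else:
            cls = "unchanged"
        out.append(
            TEClassification(
                transcript_id=t,
                te_A=te_a[t],
                te_B=te_b[t],
                delta_log2_te=delta,
                te_class=cls,
            )
        )
    return out
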