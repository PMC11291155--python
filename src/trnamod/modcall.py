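"""Acetylation-site calling from treated/control chemical-probing pileups.

Borohydride reduction of an acetylated cytidine leaves a scar that reverse
transcription reads as either a C->T misincorporation or a premature stop.
This module turns treated (reduced) and mock-treated control alignments
into per-position pileups and calls modified sites from three signals:

* the C->T misincorporation rate (``C2T.MRD``: T count over base-presenting
  coverage at a reference C),
* its treated-vs-control significance (``pval.CT2``: two-sided Fisher exact
  on the 2x2 T/non-T table, Benjamini-Hochberg corrected per run),
* the fold RT stop: depth-normalised read starts at the position one base
  5' of the site, treated over control, with the conventional sentinel of
  exactly 100 when the control shows no stops at all.

Sites are additionally annotated for the 5'-CCG-3' consensus context (the
queried C as the middle base) and filtered on coverage (>100 reads in both
libraries by default), a minimum 2% misincorporation rate, q <= 0.05, and
treated rate exceeding control.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import AlignmentRecord, DELETION, ReferenceSet

logger = logging.getLogger("trnamod")

#: Smallest representable positive float; p-values are floored here rather
#: than reported as 0.
MIN_PVALUE = sys.float_info.min * sys.float_info.epsilon  # 5e-324

#: Sentinel fold-RT-stop value when the control shows zero read starts.
RT_STOP_SENTINEL = 100.0

_CHANNELS = ("A", "C", "G", "T", DELETION)
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_CHANNELS):
    _CODE[ord(_b)] = _i


@dataclass
class SitePileup:
    """Per-position base counts and read-start counts."""

    ref_id: str
    position: int
    coverage: int  # reads presenting a base (deletions excluded)
    base_counts: dict[str, int]
    start_count: int  # reads whose leftmost position equals this position
    library_depth: int  # total aligned reads in the library


@dataclass
class SiteCall:
    ref_id: str
    position: int
    mrd_treated: float
    mrd_control: float
    p_value: float
    q_value: float
    fold_rt_stop: float
    ccg_context: bool
    passes_filters: bool


def pileup(
    alignments: Sequence[AlignmentRecord], refs: ReferenceSet
) -> dict[tuple[str, int], SitePileup]:
    """Per-position pileup over all aligned reads.

    ``coverage`` counts reads presenting a base at the position; deletions
    are tallied separately; ``start_count`` counts reads whose leftmost
    aligned position is the position.  ``library_depth`` is the total
    number of aligned reads.
    """
    depth = len(alignments)
    counts: dict[str, np.ndarray] = {}
    starts: dict[str, np.ndarray] = {}
    for rec in refs:
        counts[rec.id] = np.zeros((len(rec), len(_CHANNELS)), dtype=np.int64)
        starts[rec.id] = np.zeros(len(rec), dtype=np.int64)
    for aln in alignments:
        if aln.ref_id not in counts:
            raise ValueError(f"alignment to unknown reference {aln.ref_id!r}")
        codes = _CODE[np.frombuffer(aln.bases.encode(), dtype=np.uint8)]
        if (codes < 0).any():
            raise ValueError(
                f"read {aln.read_id!r} contains a non-ACGT, non-deletion base"
            )
        idx = np.arange(aln.start - 1, aln.start - 1 + len(codes))
        if idx[-1] >= counts[aln.ref_id].shape[0] or aln.start < 1:
            raise ValueError(
                f"read {aln.read_id!r} extends outside reference {aln.ref_id!r}"
            )
        np.add.at(counts[aln.ref_id], (idx, codes), 1)
        starts[aln.ref_id][aln.start - 1] += 1

    out: dict[tuple[str, int], SitePileup] = {}
    for rec in refs:
        mat = counts[rec.id]
        cov = mat[:, :4].sum(axis=1)
        for pos in range(1, len(rec) + 1):
            out[(rec.id, pos)] = SitePileup(
                ref_id=rec.id,
                position=pos,
                coverage=int(cov[pos - 1]),
                base_counts={b: int(mat[pos - 1, i]) for i, b in enumerate(_CHANNELS)},
                start_count=int(starts[rec.id][pos - 1]),
                library_depth=depth,
            )
    return out


def misincorporation_rate(p: SitePileup, ref_base: str) -> float:
    """C->T misincorporation rate: T count over base-presenting coverage."""
    if ref_base != "C":
        raise ValueError(
            f"misincorporation rate is defined at reference C, not {ref_base!r}"
        )
    if p.coverage == 0:
        raise ValueError(
            f"undefined site: zero coverage at {p.ref_id}:{p.position}"
        )
    return p.base_counts["T"] / p.coverage


def site_test(treated: SitePileup, control: SitePileup) -> float:
    """Two-sided Fisher exact p-value for the treated-vs-control T excess.

    The 2x2 table is [[T, non-T] treated, [T, non-T] control] over
    base-presenting coverage.
    """
    if treated.coverage == 0 or control.coverage == 0:
        raise ValueError("zero coverage in treated or control library")
    t_t = treated.base_counts["T"]
    t_c = control.base_counts["T"]
    table = [
        [t_t, treated.coverage - t_t],
        [t_c, control.coverage - t_c],
    ]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p)


def fold_rt_stop(treated: SitePileup, control: SitePileup) -> float:
    """Depth-normalised ratio of read starts, treated over control.

    Computed at the position one base 5' of the queried site.  If the
    control has zero starts and the treated library at least one, the ratio
    is set to exactly 100 by convention; if both are zero it is 1 (no
    evidence either way).
    """
    if treated.library_depth <= 0 or control.library_depth <= 0:
        raise ValueError("library depth must be positive in both libraries")
    if control.start_count == 0:
        return RT_STOP_SENTINEL if treated.start_count > 0 else 1.0
    return (treated.start_count / treated.library_depth) / (
        control.start_count / control.library_depth
    )


def annotate_context(refs: ReferenceSet, ref_id: str, position: int) -> bool:
    """True iff the queried C is the middle base of a 5'-CCG-3' triplet.

    Positions at the sequence edge return False (no context available).
    """
    rec = refs[ref_id]
    if not 1 <= position <= len(rec):
        raise ValueError(f"position {position} outside reference {ref_id!r}")
    if position == 1 or position == len(rec):
        return False
    return rec.sequence[position - 2 : position + 1] == "CCG"


@dataclass
class CallThresholds:
    min_coverage: int = 100  # strict: > min_coverage reads in both libraries
    min_mrd: float = 0.02
    q_max: float = 0.05

    def __post_init__(self) -> None:
        if self.min_coverage <= 0 or self.min_mrd <= 0 or self.q_max <= 0:
            raise ValueError("thresholds must be positive")


def call_sites(
    treated: Mapping[tuple[str, int], SitePileup],
    control: Mapping[tuple[str, int], SitePileup],
    refs: ReferenceSet,
    thresholds: CallThresholds | None = None,
) -> list[SiteCall]:
    """Call candidate acetylation sites at every testable reference C.

    A position is testable when both libraries exceed ``min_coverage``
    base-presenting reads there.  q-values are Benjamini-Hochberg over all
    tested positions in the run.  ``passes_filters`` additionally requires
    the misincorporation rate >= ``min_mrd``, q <= ``q_max``, and a treated
    rate strictly above control.
    """
    th = thresholds or CallThresholds()
    rows: list[SiteCall] = []
    pvals: list[float] = []
    for rec in refs:
        for pos in range(1, len(rec) + 1):
            if rec.base(pos) != "C":
                continue
            tp = treated.get((rec.id, pos))
            cp = control.get((rec.id, pos))
            if tp is None or cp is None:
                continue
            if tp.coverage <= th.min_coverage or cp.coverage <= th.min_coverage:
                continue
            mrd_t = misincorporation_rate(tp, "C")
            mrd_c = misincorporation_rate(cp, "C")
            p = max(site_test(tp, cp), MIN_PVALUE)
            if pos > 1:
                t_up = treated.get((rec.id, pos - 1))
                c_up = control.get((rec.id, pos - 1))
                fold = (
                    fold_rt_stop(t_up, c_up)
                    if t_up is not None and c_up is not None
                    else 1.0
                )
            else:
                fold = 1.0
            rows.append(
                SiteCall(
                    ref_id=rec.id,
                    position=pos,
                    mrd_treated=mrd_t,
                    mrd_control=mrd_c,
                    p_value=p,
                    q_value=1.0,
                    fold_rt_stop=fold,
                    ccg_context=annotate_context(refs, rec.id, pos),
                    passes_filters=False,
                )
            )
            pvals.append(p)
    if not rows:
        logger.warning("no testable C positions at the requested coverage")
        return []
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    for call, q in zip(rows, qvals):
        call.q_value = float(q)
        call.passes_filters = (
            call.mrd_treated >= th.min_mrd
            and call.q_value <= th.q_max
            and call.mrd_treated > call.mrd_control
        )
    return rows


#: Output column order mirroring the supplementary-table schema.
CALL_SCHEMA = (
    "ref_id",
    "position",
    "C2T.MRD",
    "mrd.control",
    "pval.CT2",
    "qval.CT2",
    "fold.RT.stop",
    "ccg.context",
    "pass",
)


def calls_to_rows(calls: Sequence[SiteCall]) -> list[dict]:
    return [
        {
            "ref_id": c.ref_id,
            "position": c.position,
            "C2T.MRD": c.mrd_treated,
            "mrd.control": c.mrd_control,
            "pval.CT2": c.p_value,
            "qval.CT2": c.q_value,
            "fold.RT.stop": c.fold_rt_stop,
            "ccg.context": c.ccg_context,
            "pass": c.passes_filters,
        }
        for c in calls
    ]
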