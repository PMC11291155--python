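"""Synonymous codon-usage statistics over transcript sets.

Implements the codon-composition comparisons used to characterise
translationally affected transcript sets: per-transcript codon fractions
and amino-acid-family-relative fractions, U/A-rich vs C/G-rich Leu/Ser
group content, two-sample comparisons by Student's t, per-codon bias of a
transcript set against a background, overlapping dipeptide enrichment, and
a wobble-rule decoding table mapping each sense codon to the anticodons
that can read it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from .core_io import normalize_sequence

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
#: codon -> one-letter amino acid, standard genetic code (61 sense codons).
AA_OF: dict[str, str] = dict(_STANDARD.forward_table)
STOP_CODONS = tuple(_STANDARD.stop_codons)
SENSE_CODONS = sorted(AA_OF)
#: amino acid -> synonymous codon family.
FAMILY_OF: dict[str, list[str]] = {}
for _c, _a in AA_OF.items():
    FAMILY_OF.setdefault(_a, []).append(_c)

#: Leu/Ser codon groups split by U/A- vs C/G-richness of the codon.
UA_RICH_LEU = frozenset({"TTA", "TTG", "CTA", "CTT"})
CG_RICH_LEU = frozenset({"CTG", "CTC"})
UA_RICH_SER = frozenset({"TCA", "TCT", "AGT"})
CG_RICH_SER = frozenset({"AGC", "TCC", "TCG"})


@dataclass
class CodonProfile:
    """Codon composition of one coding sequence.

    ``fractions`` are per sense codon over all sense codons; a codon's
    ``family_fraction`` is its share within its synonymous amino-acid
    family (0 for every member of an absent family).  The terminal stop is
    tracked separately and excluded from sense totals.
    """

    transcript_id: str
    counts: dict[str, int]
    sense_total: int
    stop_codon: str | None
    fractions: dict[str, float]
    family_fractions: dict[str, float]
    protein: str


def codon_counts(sequence: str, transcript_id: str = "") -> CodonProfile:
    """Frame-0 codon composition of a CDS.

    The sequence length must be divisible by 3 and contain no internal stop
    codon; a terminal stop, if present, is recorded but excluded from sense
    totals.  RNA and lowercase input are accepted.
    """
    seq = normalize_sequence(sequence)
    if len(seq) % 3:
        raise ValueError(
            f"CDS {transcript_id!r} length {len(seq)} not divisible by 3"
        )
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    stop = None
    if codons and codons[-1] in STOP_CODONS:
        stop = codons.pop()
    counts = {c: 0 for c in SENSE_CODONS}
    protein = []
    for i, codon in enumerate(codons, start=1):
        if codon in STOP_CODONS:
            raise ValueError(
                f"internal stop codon {codon} at codon index {i} "
                f"in {transcript_id!r}"
            )
        if codon not in counts:
            raise ValueError(f"non-ACGT codon {codon!r} at codon index {i}")
        counts[codon] += 1
        protein.append(AA_OF[codon])
    total = len(codons)
    fractions = {c: (counts[c] / total if total else 0.0) for c in SENSE_CODONS}
    family_fractions = {}
    for aa, fam in FAMILY_OF.items():
        fam_total = sum(counts[c] for c in fam)
        for c in fam:
            family_fractions[c] = counts[c] / fam_total if fam_total else 0.0
    return CodonProfile(
        transcript_id=transcript_id,
        counts=counts,
        sense_total=total,
        stop_codon=stop,
        fractions=fractions,
        family_fractions=family_fractions,
        protein="".join(protein),
    )


def group_content(
    profile: CodonProfile, group: Sequence[str], denominator: str = "all_sense"
) -> float | None:
    """Combined content of a codon group within one transcript.

    ``denominator="all_sense"`` divides by all sense codons;
    ``denominator="family"`` divides by the group's amino-acid families.
    Returns ``None`` (undefined) for a family denominator of 0.
    """
    group = [normalize_sequence(c) for c in group]
    if not group:
        raise ValueError("empty codon group")
    num = sum(profile.counts[c] for c in group)
    if denominator == "all_sense":
        if profile.sense_total == 0:
            return None
        return num / profile.sense_total
    if denominator == "family":
        families = {AA_OF[c] for c in group}
        denom = sum(
            profile.counts[c] for aa in families for c in FAMILY_OF[aa]
        )
        if denom == 0:
            return None
        return num / denom
    raise ValueError(f"unknown denominator {denominator!r}")


def stars(p_value: float) -> str:
    """Significance stars: * p<0.05, ** p<0.01, *** p<0.001, else ns."""
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return "ns"


def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float]
) -> dict[str, float | str]:
    """Two-sample two-tailed Student's t test (pooled variance) with stars."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in input")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=True)
        t, p = float(t), float(p)
    return {"t_statistic": t, "p_value": p, "stars": stars(p)}


def bias_vs_background(
    set_profiles: Sequence[CodonProfile],
    background_profiles: Sequence[CodonProfile],
    mode: str = "absolute",
) -> dict[str, float]:
    """Per-codon usage difference of a transcript set versus a background.

    ``absolute``: difference of per-transcript-averaged codon fractions.
    ``family_relative``: the same difference on family-relative fractions,
    excluding transcripts that lack the codon's amino-acid family from that
    codon's mean (NaN when no transcript in a group has the family).
    A positive value means the codon is more used in the set.
    """
    if not set_profiles or not background_profiles:
        raise ValueError("both transcript sets must be non-empty")

    def mean_fraction(profiles: Sequence[CodonProfile], codon: str) -> float:
        if mode == "absolute":
            return float(np.mean([p.fractions[codon] for p in profiles]))
        if mode == "family_relative":
            fam = FAMILY_OF[AA_OF[codon]]
            vals = [
                p.family_fractions[codon]
                for p in profiles
                if sum(p.counts[c] for c in fam) > 0
            ]
            return float(np.mean(vals)) if vals else float("nan")
        raise ValueError(f"unknown mode {mode!r}")

    return {
        c: mean_fraction(set_profiles, c) - mean_fraction(background_profiles, c)
        for c in SENSE_CODONS
    }


def pooled_codon_fractions(profiles: Sequence[CodonProfile]) -> dict[str, float]:
    """Codon fractions pooled over the concatenated coding sequence."""
    totals = {c: 0 for c in SENSE_CODONS}
    for p in profiles:
        for c, n in p.counts.items():
            totals[c] += n
    grand = sum(totals.values())
    if grand == 0:
        raise ValueError("no sense codons in the profile set")
    return {c: totals[c] / grand for c in SENSE_CODONS}


def dipeptide_counts(profiles: Sequence[CodonProfile]) -> tuple[dict[str, int], int]:
    """Overlapping amino-acid pair counts over a transcript set."""
    counts: dict[str, int] = {}
    total = 0
    for p in profiles:
        prot = p.protein
        if not prot:
            continue
        for i in range(len(prot) - 1):
            pair = prot[i : i + 2]
            counts[pair] = counts.get(pair, 0) + 1
            total += 1
    return counts, total


def dipeptide_enrichment(
    set_profiles: Sequence[CodonProfile],
    background_profiles: Sequence[CodonProfile],
) -> dict[str, dict[str, float]]:
    """Enrichment of overlapping amino-acid pairs in a set vs a background.

    Fold = pseudocounted pair frequency ratio (pc = 0.5 / total pairs per
    group); p-values from a two-proportion z-test on the raw pair counts,
    Benjamini-Hochberg corrected over the 400 possible pairs.
    """
    set_counts, set_total = dipeptide_counts(set_profiles)
    bg_counts, bg_total = dipeptide_counts(background_profiles)
    if set_total == 0 or bg_total == 0:
        raise ValueError("no amino-acid pairs in at least one group")
    aas = sorted(set(AA_OF.values()))
    pairs = [a + b for a in aas for b in aas]
    pc_set = 0.5 / set_total
    pc_bg = 0.5 / bg_total
    folds = {}
    pvals = []
    for pair in pairs:
        ns = set_counts.get(pair, 0)
        nb = bg_counts.get(pair, 0)
        folds[pair] = (ns / set_total + pc_set) / (nb / bg_total + pc_bg)
        if ns == 0 and nb == 0:
            pvals.append(1.0)
            continue
        _, p = proportions_ztest(
            np.array([ns, nb]), np.array([set_total, bg_total])
        )
        pvals.append(1.0 if np.isnan(p) else float(p))
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    return {
        pair: {"fold": folds[pair], "p_value": pvals[i], "q_value": float(qvals[i])}
        for i, pair in enumerate(pairs)
    }


# ---------------------------------------------------------------------------
# Wobble decoding
# ---------------------------------------------------------------------------

_WC = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: anticodon position-34 base -> codon third bases it can pair with:
#: Watson-Crick, G:U and U:G wobble, and inosine pairing with U, C, A.
WOBBLE_34: dict[str, frozenset[str]] = {
    "A": frozenset({"T"}),
    "C": frozenset({"G"}),
    "G": frozenset({"C", "T"}),  # G:U wobble
    "T": frozenset({"A", "G"}),  # U:G wobble
    "I": frozenset({"T", "C", "A"}),
}


def wobble_decoders(codon: str) -> set[str]:
    """Anticodons (5'->3', alphabet A,C,G,T,I) that can decode a sense codon.

    Anticodon positions 35 and 36 must be Watson-Crick to codon positions 2
    and 1; position 34 pairs the codon's third base under Watson-Crick,
    G:U / U:G wobble, or inosine (pairs U, C, A) rules.
    """
    codon = normalize_sequence(codon)
    if codon in STOP_CODONS:
        raise ValueError(f"{codon} is a stop codon")
    if codon not in AA_OF:
        raise ValueError(f"{codon!r} is not a sense codon")
    pos35 = _WC[codon[1]]
    pos36 = _WC[codon[0]]
    return {
        b34 + pos35 + pos36
        for b34, thirds in WOBBLE_34.items()
        if codon[2] in thirds
    }
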