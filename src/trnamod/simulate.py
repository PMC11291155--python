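"""Synthetic data with known ground truth for every pipeline stage.

Generators cover: tRNA-like references carrying an acetylation-site
(5'-CCG-3' with the modified C in the middle, at position 12), chemical
probing reads in which a reduced acetyl-cytidine causes either an RT stop
or a C->T misincorporation, ribosome/disome footprints under a per-codon
dwell-time model, codon-usage-shifted CDS sets, tRNA-quantification reads,
and cross offspring under per-genotype viability.

Every generator is deterministic under a fixed seed and returns a
ground-truth log sufficient to recompute its own expectations exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core_io import AlignmentRecord, Annotation, ReferenceRecord, ReferenceSet
from .cross_stats import GenotypeCounts, normalize_genotype_tuple
from .ribo_occupancy import OffsetTable, default_offsets

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: All 64 codons / the 61 sense codons of the standard genetic code.
ALL_CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = [c for c in ALL_CODONS if c not in STOP_CODONS]

#: Modified-site annotation label used by :func:`make_trna_references`.
AC4C_LABEL = "ac4C"


# ---------------------------------------------------------------------------
# Ground-truth models
# ---------------------------------------------------------------------------

@dataclass
class SiteTruth:
    """Known chemistry of one modified site.

    ``stoichiometry`` is the fraction of molecules carrying the
    modification; a modified, chemically reduced site either terminates
    reverse transcription (probability ``p_stop_given_mod``, emitting a
    read starting one base 5' of the site), misincorporates T
    (``p_mis_given_mod``), or reads through.
    """

    ref_id: str
    position: int
    stoichiometry: float
    p_mis_given_mod: float = 0.5
    p_stop_given_mod: float = 0.2

    def __post_init__(self) -> None:
        for name in ("stoichiometry", "p_mis_given_mod", "p_stop_given_mod"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.p_mis_given_mod + self.p_stop_given_mod > 1.0 + 1e-12:
            raise ValueError("p_mis_given_mod + p_stop_given_mod must be <= 1")


@dataclass
class DwellModel:
    """Per-codon ribosome dwell-time multipliers (default 1.0 everywhere)."""

    multipliers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.multipliers = {
            k.upper().replace("U", "T"): float(v)
            for k, v in self.multipliers.items()
        }
        for codon, m in self.multipliers.items():
            if m <= 0:
                raise ValueError(f"dwell multiplier for {codon} must be > 0")

    def weight(self, codon: str) -> float:
        return self.multipliers.get(codon, 1.0)


def validate_viability(viability: Mapping | None) -> dict:
    """Normalise a genotype-tuple -> survival-fraction map."""
    out = {}
    for genotype, v in (viability or {}).items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"viability {v} for {genotype} outside [0, 1]")
        out[normalize_genotype_tuple(genotype)] = float(v)
    return out


# ---------------------------------------------------------------------------
# References
# ---------------------------------------------------------------------------

def make_trna_references(
    n_families: int,
    acetylated_family_ids: Sequence[str],
    length: int = 76,
    seed: int = 0,
) -> ReferenceSet:
    """Random tRNA-like references, some carrying an acetylation site.

    Ids are ``tRNA-1`` .. ``tRNA-n``.  Acetylated families carry C,C,G at
    positions 11-13 (the modified C is position 12, the middle of the CCG
    triplet) with an annotation at position 12; non-acetylated families are
    guaranteed not to present a C at position 12 in CCG context.
    """
    if length < 20:
        raise ValueError("reference length must be >= 20")
    ids = [f"tRNA-{i + 1}" for i in range(n_families)]
    unknown = set(acetylated_family_ids) - set(ids)
    if unknown:
        raise ValueError(f"acetylated ids not among generated ids: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    refs = ReferenceSet()
    for rid in ids:
        seq = rng.choice(list("ACGT"), size=length)
        if rid in acetylated_family_ids:
            seq[10:13] = ["C", "C", "G"]
            annotations = [Annotation(position=12, label=AC4C_LABEL)]
        else:
            # no C at 12 => no CCG context centred there
            seq[11] = rng.choice(list("AGT"))
            annotations = []
        refs.add(ReferenceRecord(id=rid, sequence="".join(seq), annotations=annotations))
    return refs


# ---------------------------------------------------------------------------
# Chemical probing reads
# ---------------------------------------------------------------------------

def _apply_errors(mat: np.ndarray, error_rate: float, rng) -> None:
    """Substitute bases in-place with uniform per-base error."""
    if error_rate <= 0:
        return
    err = rng.random(mat.shape) < error_rate
    if not err.any():
        return
    shift = rng.integers(1, 4, size=int(err.sum()))
    codes = np.searchsorted(_BASES, mat[err])
    mat[err] = _BASES[(codes + shift) % 4]


def simulate_ac4cseq_reads(
    refs: ReferenceSet,
    truths: Sequence[SiteTruth],
    coverage: int,
    error_rate: float = 0.0,
    treated: bool = True,
    seed: int = 0,
) -> tuple[list[AlignmentRecord], dict]:
    """Full-length probing reads with stop/misincorporation chemistry.

    Each reference receives ``coverage`` molecules.  In the treated library
    a molecule is modified at a truth site with probability equal to the
    site's stoichiometry; a modified encounter yields an RT stop (read whose
    leftmost reference position is site - 1) with ``p_stop_given_mod``, else
    a T misincorporation at the site with ``p_mis_given_mod``, else correct
    readthrough.  The untreated control carries only the uniform per-base
    ``error_rate``.  Returns the reads and a per-site ground-truth event log
    ``{(ref_id, position): {n_molecules, n_modified, n_mis, n_stop}}``.
    """
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    truths_by_ref: dict[str, list[SiteTruth]] = {}
    for t in truths:
        if t.ref_id not in refs:
            raise ValueError(f"truth references unknown id {t.ref_id!r}")
        if not 1 <= t.position <= len(refs[t.ref_id]):
            raise ValueError(
                f"truth position {t.position} outside reference {t.ref_id!r}"
            )
        truths_by_ref.setdefault(t.ref_id, []).append(t)

    rng = np.random.default_rng(seed)
    reads: list[AlignmentRecord] = []
    log: dict[tuple[str, int], dict[str, int]] = {
        (t.ref_id, t.position): dict(n_molecules=0, n_modified=0, n_mis=0, n_stop=0)
        for t in truths
    }
    for rec in refs:
        L = len(rec)
        mat = np.tile(np.frombuffer(rec.sequence.encode(), dtype=np.uint8), (coverage, 1))
        _apply_errors(mat, error_rate, rng)
        starts = np.ones(coverage, dtype=int)
        if treated:
            # RT proceeds 3'->5'; the most 3' stop truncates the molecule
            for t in sorted(truths_by_ref.get(rec.id, []), key=lambda t: -t.position):
                entry = log[(t.ref_id, t.position)]
                covered = starts <= t.position
                modified = covered & (rng.random(coverage) < t.stoichiometry)
                u = rng.random(coverage)
                stop = modified & (u < t.p_stop_given_mod)
                mis = modified & ~stop & (
                    u < t.p_stop_given_mod + t.p_mis_given_mod
                )
                starts[stop] = max(t.position - 1, 1)
                mat[mis, t.position - 1] = ord("T")
                entry["n_molecules"] += int(covered.sum())
                entry["n_modified"] += int(modified.sum())
                entry["n_mis"] += int(mis.sum())
                entry["n_stop"] += int(stop.sum())
        else:
            for t in truths_by_ref.get(rec.id, []):
                log[(t.ref_id, t.position)]["n_molecules"] += coverage
        for i in range(coverage):
            s = int(starts[i])
            reads.append(
                AlignmentRecord(
                    read_id=f"{rec.id}/{i}",
                    ref_id=rec.id,
                    start=s,
                    bases=mat[i, s - 1 :].tobytes().decode(),
                )
            )
    return reads, log


# ---------------------------------------------------------------------------
# Ribosome / disome footprints
# ---------------------------------------------------------------------------

def simulate_footprints(
    cds: ReferenceSet,
    dwell: DwellModel,
    n_reads: int,
    kind: str = "monosome",
    length_weights: Mapping[int, float] | None = None,
    seed: int = 0,
    offsets: OffsetTable | None = None,
) -> tuple[list[AlignmentRecord], dict[str, int]]:
    """Footprints whose A-site codon follows a dwell-time model.

    A transcript is chosen with probability proportional to its length, a
    footprint length is drawn from ``length_weights`` (defaults: monosome
    {28, 29, 30}, disome {59..63}, uniform), and the A-site codon within the
    transcript is drawn with probability proportional to the dwell
    multiplier of the codon at each eligible position.  The 5' end is placed
    so the matching offset table recovers that A-site codon exactly.
    Returns the footprints and the ground-truth count of chosen A-site
    codons per codon identity.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    for rec in cds:
        if len(rec) % 3:
            raise ValueError(f"CDS {rec.id!r} length not divisible by 3")
    offsets = offsets or default_offsets(kind)
    if length_weights is None:
        length_weights = {n: 1.0 for n in offsets.lengths()}
    for n in length_weights:
        if offsets.offset(n) is None:
            raise ValueError(f"length {n} missing from the offset table")

    rng = np.random.default_rng(seed)
    recs = list(cds)
    lens = np.array([len(r) for r in recs], dtype=float)
    t_idx = rng.choice(len(recs), size=n_reads, p=lens / lens.sum())
    lengths_arr = np.array(sorted(length_weights), dtype=int)
    lw = np.array([length_weights[int(n)] for n in lengths_arr], dtype=float)
    l_idx = rng.choice(len(lengths_arr), size=n_reads, p=lw / lw.sum())

    # per (transcript, length): eligible A-site codons and dwell weights
    cache: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}

    def eligible(ti: int, length: int) -> tuple[np.ndarray, np.ndarray]:
        key = (ti, length)
        if key not in cache:
            rec = recs[ti]
            n_codons = len(rec) // 3
            off = offsets.offset(length)
            a_min = max(3, -(-(off + 3) // 3))  # start >= 1 and E >= 1
            a_max = min(n_codons, (len(rec) + off + 3 - length) // 3)
            if a_max < a_min:
                raise ValueError(
                    f"CDS {rec.id!r} too short for {length} nt footprints"
                )
            a_vals = np.arange(a_min, a_max + 1)
            codons = [rec.sequence[3 * (a - 1) : 3 * a] for a in a_vals]
            w = np.array([dwell.weight(c) for c in codons], dtype=float)
            cache[key] = (a_vals, w / w.sum())
        return cache[key]

    reads: list[AlignmentRecord] = []
    truth: dict[str, int] = {}
    order = np.lexsort((l_idx, t_idx))
    pos = 0
    a_chosen = np.empty(n_reads, dtype=int)
    while pos < len(order):
        ti = int(t_idx[order[pos]])
        li = int(l_idx[order[pos]])
        end = pos
        while end < len(order) and t_idx[order[end]] == ti and l_idx[order[end]] == li:
            end += 1
        a_vals, p = eligible(ti, int(lengths_arr[li]))
        a_chosen[order[pos:end]] = rng.choice(a_vals, size=end - pos, p=p)
        pos = end
    for i in range(n_reads):
        rec = recs[int(t_idx[i])]
        length = int(lengths_arr[int(l_idx[i])])
        off = offsets.offset(length)
        a = int(a_chosen[i])
        start = 3 * (a - 1) + 1 - off
        codon = rec.sequence[3 * (a - 1) : 3 * a]
        truth[codon] = truth.get(codon, 0) + 1
        reads.append(
            AlignmentRecord(
                read_id=f"fp{i}",
                ref_id=rec.id,
                start=start,
                bases=rec.sequence[start - 1 : start - 1 + length],
            )
        )
    return reads, truth


# ---------------------------------------------------------------------------
# Codon-usage-shifted CDS sets
# ---------------------------------------------------------------------------

def simulate_codon_shifted_cds(
    n: int,
    length_codons: int,
    base_usage: Mapping[str, float] | None = None,
    shifted: Mapping[str, float] | None = None,
    seed: int = 0,
    id_prefix: str = "cds",
) -> ReferenceSet:
    """Random CDS set with interior codon usage ``base_usage x shifted``.

    Every CDS begins with ATG, ends with a stop codon, and draws its
    ``length_codons - 2`` interior codons from the renormalised product of
    ``base_usage`` (default: uniform over the 61 sense codons) and the
    ``shifted`` multipliers.  Total length is ``3 * length_codons`` nt.
    """
    if length_codons < 3:
        raise ValueError("length_codons must be >= 3")
    usage = dict(base_usage) if base_usage else {c: 1.0 for c in SENSE_CODONS}
    usage = {k.upper().replace("U", "T"): float(v) for k, v in usage.items()}
    for codon, w in usage.items():
        if codon in STOP_CODONS:
            raise ValueError(f"stop codon {codon} in interior draw set")
        if w <= 0:
            raise ValueError(f"non-positive weight for {codon}")
    for codon, m in (shifted or {}).items():
        codon = codon.upper().replace("U", "T")
        if codon in usage:
            usage[codon] *= float(m)
    codons = sorted(usage)
    w = np.array([usage[c] for c in codons], dtype=float)
    w /= w.sum()
    rng = np.random.default_rng(seed)
    refs = ReferenceSet()
    for i in range(n):
        interior = rng.choice(codons, size=length_codons - 2, p=w)
        stop = rng.choice(list(STOP_CODONS))
        refs.add(
            ReferenceRecord(
                id=f"{id_prefix}-{i + 1}",
                sequence="ATG" + "".join(interior) + stop,
            )
        )
    return refs


# ---------------------------------------------------------------------------
# tRNA quantification reads
# ---------------------------------------------------------------------------

def simulate_trna_reads(
    refs: ReferenceSet,
    proportions: Mapping[str, float],
    n_reads: int,
    seed: int = 0,
    p_mis_at_mod: float = 0.0,
    error_rate: float = 0.0,
) -> tuple[list[str], dict[str, int]]:
    """Full-length tRNA reads drawn from known isodecoder proportions.

    Annotated (modified) positions misincorporate T with probability
    ``p_mis_at_mod``, mimicking modification-induced misincorporation;
    ``error_rate`` adds uniform substitution noise.  Returns the read
    sequences and the true per-isodecoder source counts.
    """
    ids = sorted(proportions)
    p = np.array([proportions[i] for i in ids], dtype=float)
    if (p < 0).any() or p.sum() <= 0:
        raise ValueError("proportions must be non-negative with positive sum")
    p /= p.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_reads, p)
    reads: list[str] = []
    truth: dict[str, int] = {}
    for rid, k in zip(ids, counts):
        if k == 0:
            continue
        truth[rid] = int(k)
        rec = refs[rid]
        mat = np.tile(np.frombuffer(rec.sequence.encode(), dtype=np.uint8), (k, 1))
        _apply_errors(mat, error_rate, rng)
        if p_mis_at_mod > 0:
            for ann in rec.annotations:
                hit = rng.random(k) < p_mis_at_mod
                mat[hit, ann.position - 1] = ord("T")
        reads.extend(mat[i].tobytes().decode() for i in range(k))
    order = rng.permutation(len(reads))
    return [reads[i] for i in order], truth


# ---------------------------------------------------------------------------
# Genetic crosses
# ---------------------------------------------------------------------------

def simulate_cross(
    parent1: Sequence[str] | str,
    parent2: Sequence[str] | str,
    n_offspring: int,
    viability: Mapping | None = None,
    seed: int = 0,
    loci: Sequence[str] | None = None,
) -> tuple[GenotypeCounts, GenotypeCounts]:
    """Offspring of a cross under per-genotype viability.

    ``n_offspring`` conceptions are drawn with independent per-locus gamete
    transmission; each conceptus survives with probability
    ``viability[genotype]`` (default 1).  Returns
    ``(surviving_counts, conception_counts)``.
    """
    p1 = normalize_genotype_tuple(parent1)
    p2 = normalize_genotype_tuple(parent2)
    if len(p1) != len(p2):
        raise ValueError("parents must have the same number of loci")
    viab = validate_viability(viability)
    loci = list(loci) if loci is not None else [f"locus{i + 1}" for i in range(len(p1))]
    rng = np.random.default_rng(seed)
    per_locus_genotypes = []
    for g1, g2 in zip(p1, p2):
        a1 = np.array(g1.split("/"))
        a2 = np.array(g2.split("/"))
        gam1 = a1[rng.integers(0, 2, size=n_offspring)]
        gam2 = a2[rng.integers(0, 2, size=n_offspring)]
        per_locus_genotypes.append(
            ["/".join(sorted((x, y), key={"+": 0, "-": 1}.__getitem__))
             for x, y in zip(gam1, gam2)]
        )
    conceived = GenotypeCounts(loci=loci)
    surviving = GenotypeCounts(loci=loci)
    u = rng.random(n_offspring)
    for i in range(n_offspring):
        genotype = tuple(col[i] for col in per_locus_genotypes)
        conceived.add(genotype)
        if u[i] < viab.get(genotype, 1.0):
            surviving.add(genotype)
    return surviving, conceived
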