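"""Ground-truth behaviour of the synthetic-data generators."""

import itertools

import numpy as np
import pytest

import trnamod as tm
from trnamod.simulate import SENSE_CODONS


class TestMakeTrnaReferences:
    def test_acetylated_family_has_ccg_and_annotation(self):
        refs = tm.make_trna_references(2, ["tRNA-1"], length=76, seed=11)
        rec = refs["tRNA-1"]
        assert rec.sequence[10:13] == "CCG"
        assert [(a.position, a.label) for a in rec.annotations] == [(12, "ac4C")]

    def test_deterministic_under_seed(self):
        a = tm.make_trna_references(4, ["tRNA-2"], seed=5)
        b = tm.make_trna_references(4, ["tRNA-2"], seed=5)
        assert [r.sequence for r in a] == [r.sequence for r in b]

    def test_non_acetylated_family_lacks_site(self):
        refs = tm.make_trna_references(3, ["tRNA-1"], seed=7)
        for rid in ("tRNA-2", "tRNA-3"):
            rec = refs[rid]
            assert rec.annotations == []
            assert not (
                rec.base(12) == "C" and rec.sequence[10:13] == "CCG"
            )

    def test_short_length_rejected(self):
        with pytest.raises(ValueError):
            tm.make_trna_references(1, [], length=19, seed=0)


class TestAc4cseqReads:
    def test_zero_stoichiometry_is_clean(self):
        refs = tm.make_trna_references(1, ["tRNA-1"], seed=1)
        truth = tm.SiteTruth("tRNA-1", 12, stoichiometry=0.0)
        reads, log = tm.simulate_ac4cseq_reads(refs, [truth], 500, 0.0, seed=2)
        assert all(r.start == 1 for r in reads)
        assert all(r.bases[11] == "C" for r in reads)
        assert log[("tRNA-1", 12)]["n_modified"] == 0

    def test_full_stop_truncates_all_reads(self):
        refs = tm.make_trna_references(1, ["tRNA-1"], seed=1)
        truth = tm.SiteTruth(
            "tRNA-1", 12, stoichiometry=1.0, p_mis_given_mod=0.0, p_stop_given_mod=1.0
        )
        reads, log = tm.simulate_ac4cseq_reads(refs, [truth], 100, 0.0, seed=3)
        assert all(r.start == 11 for r in reads)
        assert log[("tRNA-1", 12)]["n_stop"] == 100

    def test_misincorporation_fraction_matches_event_log(self):
        # stoichiometry 0.5 with p_mis 0.8 -> expected T fraction 0.40
        refs = tm.make_trna_references(1, ["tRNA-1"], seed=1)
        truth = tm.SiteTruth(
            "tRNA-1", 12, stoichiometry=0.5, p_mis_given_mod=0.8, p_stop_given_mod=0.0
        )
        n = 10_000
        reads, log = tm.simulate_ac4cseq_reads(refs, [truth], n, 0.0, seed=4)
        t_count = sum(r.bases[11 - r.start + 1] == "T" for r in reads)
        assert t_count == log[("tRNA-1", 12)]["n_mis"]
        se = np.sqrt(0.4 * 0.6 / n)
        assert abs(t_count / n - 0.4) < 3 * se

    def test_untreated_control_has_no_modification_signal(self):
        refs = tm.make_trna_references(1, ["tRNA-1"], seed=1)
        truth = tm.SiteTruth("tRNA-1", 12, stoichiometry=1.0)
        reads, log = tm.simulate_ac4cseq_reads(
            refs, [truth], 200, 0.0, treated=False, seed=5
        )
        assert all(r.start == 1 and r.bases[11] == "C" for r in reads)
        assert log[("tRNA-1", 12)]["n_modified"] == 0

    def test_position_outside_reference_rejected(self):
        refs = tm.make_trna_references(1, ["tRNA-1"], length=30, seed=1)
        with pytest.raises(ValueError):
            tm.simulate_ac4cseq_reads(
                refs, [tm.SiteTruth("tRNA-1", 31, 0.5)], 10, seed=0
            )


@pytest.fixture(scope="module")
def cds():
    return tm.simulate_codon_shifted_cds(6, 80, seed=21)


class TestFootprints:
    def test_deterministic_under_seed(self, cds):
        a, _ = tm.simulate_footprints(cds, tm.DwellModel(), 500, seed=9)
        b, _ = tm.simulate_footprints(cds, tm.DwellModel(), 500, seed=9)
        assert a == b

    def test_uniform_dwell_is_uniform_over_positions(self, cds):
        from scipy import stats

        reads, truth = tm.simulate_footprints(cds, tm.DwellModel(), 60_000, seed=10)
        # chi-square goodness of fit of A-site codon counts against the
        # eligible-position codon composition
        expected = _eligible_codon_probs(cds, tm.DwellModel())
        codons = sorted(expected)
        obs = np.array([truth.get(c, 0) for c in codons])
        exp = np.array([expected[c] for c in codons]) * obs.sum()
        keep = exp > 0
        p = stats.chisquare(obs[keep], exp[keep]).pvalue
        assert p > 0.001

    def test_dwell_share_matches_closed_form(self, cds):
        dwell = tm.DwellModel({"TTA": 3.0})
        _, truth = tm.simulate_footprints(cds, dwell, 120_000, seed=12)
        expected = _eligible_codon_probs(cds, dwell)
        share = truth.get("TTA", 0) / sum(truth.values())
        se = np.sqrt(expected["TTA"] * (1 - expected["TTA"]) / 120_000)
        assert abs(share - expected["TTA"]) < 4 * se

    def test_footprint_start_recovers_a_site(self, cds):
        reads, truth = tm.simulate_footprints(cds, tm.DwellModel(), 300, seed=13)
        recovered = {}
        for fp in reads:
            rec = cds[fp.ref_id]
            sites = tm.assign_sites(fp, tm.MONOSOME_OFFSETS, len(rec))
            codon = rec.sequence[3 * (sites.A - 1) : 3 * sites.A]
            recovered[codon] = recovered.get(codon, 0) + 1
        assert recovered == truth

    def test_non_triplet_cds_rejected(self):
        refs = tm.ReferenceSet([tm.ReferenceRecord(id="x", sequence="ATGAA")])
        with pytest.raises(ValueError):
            tm.simulate_footprints(refs, tm.DwellModel(), 10, seed=0)


def _eligible_codon_probs(cds, dwell):
    """Closed-form A-site codon distribution of the footprint generator.

    Transcript chosen proportional to length; within a transcript, each
    eligible position proportional to its dwell multiplier; lengths uniform
    over the monosome table.
    """
    lengths = tm.MONOSOME_OFFSETS.lengths()
    total_len = sum(len(r) for r in cds)
    probs = {}
    for rec in cds:
        p_t = len(rec) / total_len
        for length in lengths:
            off = tm.MONOSOME_OFFSETS.offset(length)
            a_min = max(3, -(-(off + 3) // 3))
            a_max = min(len(rec) // 3, (len(rec) + off + 3 - length) // 3)
            codons = [rec.sequence[3 * (a - 1) : 3 * a] for a in range(a_min, a_max + 1)]
            w = np.array([dwell.weight(c) for c in codons])
            w = w / w.sum()
            for codon, wi in zip(codons, w):
                probs[codon] = probs.get(codon, 0.0) + p_t * wi / len(lengths)
    return probs


class TestCodonShiftedCds:
    def test_structure(self):
        refs = tm.simulate_codon_shifted_cds(5, 40, seed=31)
        for rec in refs:
            assert len(rec) == 120
            assert rec.sequence.startswith("ATG")
            assert rec.sequence[-3:] in ("TAA", "TAG", "TGA")

    def test_unshifted_matches_base_usage(self):
        refs = tm.simulate_codon_shifted_cds(40, 200, seed=32)
        counts = _interior_counts(refs)
        total = sum(counts.values())
        freqs = np.array([counts.get(c, 0) / total for c in SENSE_CODONS])
        se = np.sqrt((1 / 61) * (1 - 1 / 61) / total)
        assert np.all(np.abs(freqs - 1 / 61) < 5 * se)

    def test_shift_renormalises(self):
        refs = tm.simulate_codon_shifted_cds(
            60, 200, shifted={"TTA": 2.0}, seed=33
        )
        counts = _interior_counts(refs)
        total = sum(counts.values())
        expected = 2.0 / (60 + 2.0)  # renormalised weight of TTA
        se = np.sqrt(expected * (1 - expected) / total)
        assert abs(counts["TTA"] / total - expected) < 4 * se

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            tm.simulate_codon_shifted_cds(1, 2, seed=0)


def _interior_counts(refs):
    counts = {}
    for rec in refs:
        for i in range(3, len(rec) - 3, 3):
            c = rec.sequence[i : i + 3]
            counts[c] = counts.get(c, 0) + 1
    return counts


class TestSimulateCross:
    def test_mendelian_null_fraction(self):
        surv, conc = tm.simulate_cross("+/-", "+/-", 20_000, seed=41)
        assert surv.counts == conc.counts
        frac = surv.counts[("-/-",)] / surv.total
        se = np.sqrt(0.25 * 0.75 / 20_000)
        assert abs(frac - 0.25) < 3 * se

    def test_lethal_genotype_absent(self):
        surv, conc = tm.simulate_cross(
            "+/-", "+/-", 5000, viability={("-/-",): 0.0}, seed=42
        )
        assert ("-/-",) not in surv.counts
        assert conc.counts[("-/-",)] > 0

    def test_dihybrid_double_ko_fraction(self):
        # exact product of per-locus probabilities: 1/4 * 1/4
        probs = _exhaustive_cross_probs(("+/-", "+/-"), ("+/-", "+/-"))
        assert probs[("-/-", "-/-")] == pytest.approx(1 / 16)
        surv, _ = tm.simulate_cross("+/-;+/-", "+/-;+/-", 40_000, seed=43)
        frac = surv.counts[("-/-", "-/-")] / surv.total
        se = np.sqrt((1 / 16) * (15 / 16) / 40_000)
        assert abs(frac - 1 / 16) < 3 * se

    def test_viability_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            tm.simulate_cross("+/-", "+/-", 10, viability={("-/-",): 1.5}, seed=0)


def _exhaustive_cross_probs(parent1, parent2):
    """Enumerate all gamete combinations over all loci."""
    per_locus = []
    for g1, g2 in zip(parent1, parent2):
        a1, a2 = g1.split("/"), g2.split("/")
        combos = {}
        for x in a1:
            for y in a2:
                child = "/".join(sorted((x, y), key={"+": 0, "-": 1}.__getitem__))
                combos[child] = combos.get(child, 0) + 0.25
        per_locus.append(combos)
    out = {}
    for combo in itertools.product(*(c.items() for c in per_locus)):
        key = tuple(g for g, _ in combo)
        out[key] = out.get(key, 0.0) + float(np.prod([p for _, p in combo]))
    return out
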