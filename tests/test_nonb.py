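"""Non-B motif scanners vs brute-force oracles, densities, permutation
tests and windowed stability scores."""

import numpy as np
import pytest

import motif_oracles as oracles
from cendyn.intervals import ChromSizes, GenomicInterval as GI
from cendyn.io import SequenceRecord
from cendyn.nonb import (
    NN_DG37,
    NN_INITIATION,
    compare_region_energy,
    motif_density,
    permutation_enrichment,
    scan_motifs,
    window_free_energy,
)
from cendyn.windows import make_windows


def _rand_seq(rng, n, gc=0.4):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _spans(hits):
    return sorted((h.interval.start, h.interval.end) for h in hits)


class TestScannerExamples:
    def test_apr_three_phased_tracts(self):
        s = "AAA" + "CGCG" + "TTT" + "CGCG" + "AAA"
        hits = scan_motifs(SequenceRecord("s", s), "APR")
        assert _spans(hits) == [(0, 17)]
        assert hits[0].matched == s
        assert hits[0].attrs["n_tracts"] == 3

    def test_apr_long_run_is_not_a_tract(self):
        # a 12-bp A-run exceeds the 9-bp tract limit and breaks the chain
        s = "AAA" + "CGCG" + "A" * 12 + "CGCG" + "AAA"
        assert scan_motifs(SequenceRecord("s", s), "APR") == []

    def test_gq_canonical(self):
        s = "GGGTTAGGGTTAGGGTTAGGG"
        hits = scan_motifs(SequenceRecord("s", s), "GQ")
        assert _spans(hits) == [(0, 21)]
        assert hits[0].strand == "+"

    def test_gq_minus_strand(self):
        s = "CCCTTACCCTTACCCTTACCC"
        (hit,) = scan_motifs(SequenceRecord("s", s), "GQ")
        assert hit.strand == "-"

    def test_poly_c_matches_nothing_but_str(self):
        rec = SequenceRecord("s", "C" * 100)
        for cls in ("APR", "DR", "GQ", "IR", "MR", "Z"):
            assert scan_motifs(rec, cls) == []
        # a homopolymer is itself a mononucleotide tandem repeat
        assert _spans(scan_motifs(rec, "STR")) == [(0, 100)]

    def test_z_alternating(self):
        assert _spans(scan_motifs(SequenceRecord("s", "GCGCGCGCGCGC"), "Z")) == [(0, 12)]
        assert scan_motifs(SequenceRecord("s", "GCGCGCGCGC"), "Z") == []  # 10 < 12
        assert scan_motifs(SequenceRecord("s", "ATATATATATATAT"), "Z") == []  # AT excluded

    def test_ir_hairpin(self):
        arm = "ACGTACGTACGT"
        s = "TT" + arm + "AAAA" + arm.translate(str.maketrans("ACGT", "TGCA"))[::-1] + "TT"
        (hit,) = scan_motifs(SequenceRecord("s", s), "IR")
        assert hit.attrs["arm"] >= 12 and hit.attrs["loop"] <= 4

    def test_mr_mirror(self):
        arm = "ACCGTTAGCAGT"
        s = "GG" + arm + "CCCC" + arm[::-1] + "GG"
        (hit,) = scan_motifs(SequenceRecord("s", s), "MR")
        assert hit.attrs["arm"] >= 12

    def test_dr_tandem_unit(self):
        unit = "ACGTTGCACCGT"  # 12 bp
        (hit,) = scan_motifs(SequenceRecord("s", "TT" + unit * 3 + "TT"), "DR")
        assert hit.attrs["unit"] == 12 and hit.attrs["n_units"] == 3

    def test_matched_equals_genome_slice(self):
        rng = np.random.default_rng(0)
        rec = SequenceRecord("s", _rand_seq(rng, 3_000))
        for cls in ("APR", "STR", "Z", "GQ"):
            for h in scan_motifs(rec, cls):
                assert h.matched == rec.sequence[h.interval.start : h.interval.end]

    def test_unknown_class(self):
        with pytest.raises(ValueError):
            scan_motifs(SequenceRecord("s", "ACGT"), "H-DNA")


ORACLES = {
    "APR": oracles.apr_oracle,
    "GQ": oracles.gq_oracle,
    "Z": oracles.z_oracle,
    "STR": lambda s: oracles.tandem_oracle(s, 1, 9, lambda u: 9 if u == 1 else 20),
    "DR": lambda s: oracles.tandem_oracle(s, 10, 50, lambda u: 2 * u, mixed_unit=True),
    "IR": lambda s: oracles.palindrome_oracle(s, mirror=False),
    "MR": lambda s: oracles.palindrome_oracle(s, mirror=True),
}


@pytest.mark.parametrize("cls", list(ORACLES))
def test_scanner_equals_bruteforce_oracle(cls):
    """Every scanner reproduces the exhaustive rule-checker exactly on
    random sequences (AT-rich, like the genomes it targets)."""
    rng = np.random.default_rng(hash(cls) % 2**31)
    n_seqs = 8
    for _ in range(n_seqs):
        seq = _rand_seq(rng, 2_000, gc=0.35)
        got = _spans(scan_motifs(SequenceRecord("s", seq), cls))
        assert got == sorted(ORACLES[cls](seq)), f"{cls} mismatch"


def test_scanner_oracle_agreement_with_planted_motifs():
    from cendyn.simulate import simulate_genome

    for cls in ("APR", "GQ", "Z", "STR"):
        rec, truth = simulate_genome(
            4_000, gc=0.35, plantings=[(cls, 1_000, 10)], seed=17
        )
        got = _spans(scan_motifs(rec, cls))
        assert got == sorted(ORACLES[cls](rec.sequence))
        assert len(got) >= 5  # planted instances are found


class TestDensity:
    def test_no_hits_all_zero(self):
        grid = make_windows(ChromSizes({"s": 1_000_000}), 200_000)
        df = motif_density([], grid)
        assert (df["count"] == 0).all() and (df["coverage"] == 0).all()

    def test_counts_and_coverage(self):
        from cendyn.nonb import MotifHit

        grid = make_windows(ChromSizes({"s": 400_000}), 200_000)
        hits = [
            MotifHit("Z", GI("s", 1_000 + i * 60, 1_050 + i * 60), "N" * 50)
            for i in range(10)
        ]
        df = motif_density(hits, grid)
        assert df.loc[0, "count"] == 10
        assert df.loc[0, "coverage"] == pytest.approx(500 / 200_000)
        assert df.loc[1, "count"] == 0

    def test_overlapping_hits_merge_in_coverage(self):
        from cendyn.nonb import MotifHit

        grid = make_windows(ChromSizes({"s": 200_000}), 200_000)
        hits = [
            MotifHit("Z", GI("s", 0, 100), "N" * 100),
            MotifHit("Z", GI("s", 50, 150), "N" * 100),
        ]
        df = motif_density(hits, grid)
        assert df.loc[0, "coverage"] == pytest.approx(150 / 200_000)
        assert df.loc[0, "count"] == 2


class TestPermutationEnrichment:
    def test_equal_densities_p_one(self):
        obs, p = permutation_enrichment([1.0] * 50, [0, 1, 2], seed=0)
        assert p == 1.0

    def test_dominant_centromere_minimal_p(self):
        dens = [1.0] * 10 + [0.0] * 90
        obs, p = permutation_enrichment(dens, list(range(10)), n_perm=1000, seed=0)
        assert p == pytest.approx(1 / 1001)
        assert obs == 1.0

    def test_rescaling_invariance(self):
        rng = np.random.default_rng(5)
        dens = rng.random(80)
        cen = [3, 4, 5, 6]
        _, p1 = permutation_enrichment(dens, cen, seed=9)
        _, p2 = permutation_enrichment(dens * 1000, cen, seed=9)
        assert p1 == p2

    def test_null_calibration(self):
        """i.i.d. densities: rejection rate at alpha=0.05 within the
        binomial 95% band over 100 repetitions."""
        rng = np.random.default_rng(1)
        rejections = 0
        for rep in range(100):
            dens = rng.random(60)
            _, p = permutation_enrichment(dens, list(range(8)), n_perm=400, seed=rep)
            rejections += p < 0.05
        assert 1 <= rejections <= 11

    def test_pool_too_small(self):
        with pytest.raises(ValueError):
            permutation_enrichment([1.0] * 10, list(range(6)), seed=0)

    def test_planted_centromere_enrichment_pipeline(self):
        """Motifs planted only inside a designated centromere give p <= 0.01
        through the density + permutation pipeline."""
        from cendyn.simulate import simulate_genome

        rec, truth = simulate_genome(
            300_000, gc=0.35, plantings=[("APR", 150_000, 60)], seed=23
        )
        grid = make_windows(ChromSizes({rec.id: len(rec)}), 10_000)
        hits = scan_motifs(rec, "APR")
        df = motif_density(hits, grid)
        cen = [i for i, w in enumerate(grid.windows) if 140_000 <= w.start < 160_000]
        _, p = permutation_enrichment(df["count"].to_numpy(), cen, n_perm=1000, seed=1)
        assert p <= 0.01


class TestFreeEnergy:
    def test_gc_more_stable_than_at(self):
        a = window_free_energy(SequenceRecord("a", "A" * 300))[0]
        g = window_free_energy(SequenceRecord("g", "G" * 300))[0]
        assert g.score < a.score

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(4)
        seq = _rand_seq(rng, 300)
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        s1 = window_free_energy(SequenceRecord("x", seq))[0].score
        s2 = window_free_energy(SequenceRecord("y", rc))[0].score
        assert s1 == pytest.approx(s2)

    def test_translation_by_one_step_shifts_scores(self):
        rng = np.random.default_rng(6)
        seq = _rand_seq(rng, 1_500)
        w1 = window_free_energy(SequenceRecord("x", seq))
        w2 = window_free_energy(SequenceRecord("y", seq[150:]))
        assert [w.score for w in w1[1:4]] == pytest.approx([w.score for w in w2[0:3]])

    def test_score_matches_tabulated_sum(self):
        seq = "ACGT"
        (w,) = window_free_energy(SequenceRecord("s", seq), width=300)
        expected = NN_INITIATION + NN_DG37["AC"] + NN_DG37["CG"] + NN_DG37["GT"]
        assert w.score == pytest.approx(expected)

    def test_external_engine(self):
        import pandas as pd

        scores = pd.DataFrame(
            {"chrom": ["s"], "start": [0], "end": [300], "score": [-42.0]}
        )
        (w,) = window_free_energy(
            SequenceRecord("s", "A" * 300), engine="external", external_scores=scores
        )
        assert w.score == -42.0
        with pytest.raises(ValueError):
            window_free_energy(SequenceRecord("s", "A" * 300), engine="mfe")


class TestCompareRegionEnergy:
    def _windows(self, rng, start, n, mu):
        from cendyn.nonb import EnergyWindow

        return [
            EnergyWindow(GI("s", start + i * 150, start + i * 150 + 300),
                         float(rng.normal(mu, 0.5)))
            for i in range(n)
        ]

    def test_identical_sets_p_one(self):
        rng = np.random.default_rng(2)
        ws = self._windows(rng, 0, 20, -25.0)
        regions = {"R1": [GI("s", 0, 10**6)], "R2": [GI("s", 0, 10**6)]}
        df = compare_region_energy(ws, regions)
        assert df.loc[0, "p_value"] == 1.0

    def test_shifted_region_detected(self):
        """R2 shifted -0.3 kcal/mol is detected in >= 90% of seeds at 200
        windows per region."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            w1 = self._windows(rng, 0, 200, -24.8)
            w2 = self._windows(rng, 100_000, 200, -25.1)
            df = compare_region_energy(
                w1 + w2,
                {"R1": [GI("s", 0, 60_000)], "R2": [GI("s", 100_000, 160_000)]},
            )
            row = df.iloc[0]
            hits += (row["p_value"] < 0.05) and (row["mean_b"] < row["mean_a"])
        assert hits >= 18

    def test_region_too_small(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            compare_region_energy(
                self._windows(rng, 0, 2, -25.0), {"R1": [GI("s", 0, 10**6)]}
            )
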