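import numpy as np
import pytest

from satkit.repeat_align import (
    MaskParams,
    SaturatedDivergenceError,
    count_substitutions,
    k2p_distance,
    local_align,
    mask_assembly,
    mask_sample,
    read_mask_tsv,
    read_repeatmasker_align,
    write_mask_tsv,
)
from satkit.satsim import FamilySimSpec, SimSpec, build_genome, generate_background, shear_reads
from satkit.seqcore import SatFamily, SatLibrary

from _oracles import brute_force_local_score, random_dna


class TestK2P:
    def test_zero(self):
        assert k2p_distance(0.0, 0.0) == 0.0

    def test_closed_form(self):
        # -1/2 ln(0.75 * sqrt(0.9))
        assert k2p_distance(0.1, 0.05) == pytest.approx(0.17018, abs=1e-5)

    @pytest.mark.parametrize("P,Q", [(0.5, 0.0), (0.3, 0.4), (0.0, 0.5)])
    def test_domain_edges_raise(self, P, Q):
        with pytest.raises(SaturatedDivergenceError):
            k2p_distance(P, Q)

    def test_dominates_p_distance(self):
        rng = np.random.default_rng(2024)
        n = 0
        while n < 1000:
            P, Q = rng.uniform(0, 0.5, size=2)
            if 1 - 2 * P - Q <= 0.01 or 1 - 2 * Q <= 0.01:
                continue
            n += 1
            k = k2p_distance(P, Q)
            assert k >= P + Q - 1e-12
            if P + Q > 0:
                assert k > P + Q - 1e-9 or k == pytest.approx(P + Q)


class TestCountSubstitutions:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGT", "ACGT", (0, 0, 4, 0)),
            ("AG", "GA", (2, 0, 2, 0)),  # A<->G both ways: transitions
            ("A-CT", "AGCA", (0, 1, 3, 1)),  # T vs A: transversion; one gap col
            ("ANGT", "AAGT", (0, 0, 3, 0)),  # ambiguity column excluded
            ("ACGT", "TGCA", (0, 4, 4, 0)),
        ],
    )
    def test_classification(self, a, b, expected):
        assert count_substitutions(a, b) == expected

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            count_substitutions("AC", "ACG")


class TestLocalAlign:
    def test_exact_substring(self):
        aln = local_align("ACGTAC", "TTTACGTACTTT")
        assert aln.score == 6
        assert aln.aligned_read == "ACGTAC"
        assert aln.aligned_ref == "ACGTAC"
        assert aln.ref_span == (3, 9)

    def test_mismatch_trimmed_ends(self):
        # local alignment clips the mismatching prefix
        aln = local_align("TTACGT", "CCACGT")
        assert aln.score == 4
        assert aln.read_span == (2, 6)

    def test_gap_cost_convention(self):
        # deleting 2 bases between 8-bp anchors: 16 matches + open(-4) +
        # extend(-1) = 11, which beats any ungapped local alignment (8)
        aln = local_align("ACGTACTGGGACCTGAAC", "ACGTACTGACCTGAAC")
        assert aln.score == 11
        assert "--" in aln.aligned_ref

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            a = random_dna(rng, 12)
            b = random_dna(rng, 12)
            fast = local_align(a, b).score
            slow = brute_force_local_score(a, b)
            assert fast == slow, (a, b)

    def test_deterministic(self):
        a, b = "ACGTACGTT", "ACGTTACGT"
        r1 = local_align(a, b)
        r2 = local_align(a, b)
        assert (r1.aligned_read, r1.aligned_ref, r1.score) == (
            r2.aligned_read,
            r2.aligned_ref,
            r2.score,
        )


@pytest.fixture(scope="module")
def pure_family_reads():
    """Reads drawn entirely from a zero-divergence satellite array."""
    rng = np.random.default_rng(55)
    monomer = random_dna(rng, 183)
    array = monomer * 40
    reads = shear_reads(array, 150, 3.0, 56)
    library = SatLibrary([SatFamily(name="fam", rank=1, monomer=monomer)])
    return reads, library


class TestMaskSample:
    def test_pure_family_all_assigned(self, pure_family_reads):
        reads, library = pure_family_reads
        result = mask_sample(reads, library, sample="pure")
        assigned = {r.read_id for r in result.records}
        assert assigned == {rid for rid, _ in reads}
        assert all(r.k2p_divergence == 0.0 for r in result.records)

    def test_background_false_positive_rate(self):
        rng = np.random.default_rng(60)
        background = generate_background(600_000, 0.59, rng)
        reads = shear_reads(background, 150, 1.0, 61)
        monomer = random_dna(rng, 183)
        library = SatLibrary([SatFamily(name="fam", rank=1, monomer=monomer)])
        result = mask_sample(reads, library, sample="bg")
        assert len(result.records) < 0.001 * len(reads)

    def test_mean_divergence_recovered(self, small_sim):
        # the mean K2P over records must track the divergence the copies
        # actually realized (truth table), within one divergence point
        from satkit.repeat_align import k2p_distance
        from satkit.satsim import k2p_site_probabilities

        mask = small_sim["mask"]
        spec = small_sim["spec"]
        truth = small_sim["truth"]
        for fam in spec.families:
            recs = [r for r in mask.records if r.family == fam.name]
            mean_k2p = np.mean([r.k2p_divergence for r in recs])
            P, Q = k2p_site_probabilities(fam.divergence, fam.kappa)
            scale = truth[fam.name].realized_divergence / (P + Q)
            realized_k2p = 100 * k2p_distance(P * scale, Q * scale)
            assert mean_k2p == pytest.approx(realized_k2p, abs=1.0)
            # and the nominal parameter is recovered within the combined
            # simulation + estimation tolerance
            assert mean_k2p == pytest.approx(100 * fam.divergence, abs=2.0)

    def test_read_order_invariance(self, pure_family_reads):
        reads, library = pure_family_reads
        r1 = mask_sample(reads, library)
        shuffled = list(reads)[::-1]
        r2 = mask_sample(shuffled, library)
        key = lambda r: (r.read_id, r.family, r.read_start, r.score)
        assert sorted(map(key, r1.records)) == sorted(map(key, r2.records))

    def test_invariants(self, small_sim):
        mask = small_sim["mask"]
        assert sum(r.bp_weight for r in mask.records) <= mask.total_sampled_bp
        for r in mask.records:
            assert r.transitions + r.transversions <= r.aligned_columns
            assert r.read_end - r.read_start <= r.read_length
            p_dist = 100 * (r.transitions + r.transversions) / r.aligned_columns
            assert r.k2p_divergence >= p_dist - 1e-9


class TestMaskAssembly:
    def test_recovers_truth_proportions(self, small_sim):
        result = mask_assembly(small_sim["genome"], small_sim["library"])
        truth = small_sim["truth"]
        for fam in small_sim["library"]:
            bp = sum(r.bp_weight for r in result.records if r.family == fam.name)
            prop = bp / result.total_sampled_bp
            assert prop == pytest.approx(truth[fam.name].true_proportion, rel=0.1)

    def test_empty_assembly(self, small_sim):
        result = mask_assembly([], small_sim["library"])
        assert result.records == []

    def test_collapsed_arrays_underestimate(self, small_sim):
        # replace every array by just two monomers: the classic assembly
        # collapse; the masked proportion must fall far below the truth
        spec = small_sim["spec"]
        genome = dict(small_sim["genome"])["chr1"]
        truth = small_sim["truth"]
        keep = []
        pos = 0
        cuts = sorted(
            (s, e, fam.name)
            for fam in spec.families
            for _, s, e in truth[fam.name].intervals
        )
        for s, e, name in cuts:
            keep.append(genome[pos:s])
            fam = next(f for f in spec.families if f.name == name)
            keep.append(genome[s : s + 2 * len(fam.monomer)])
            pos = e
        keep.append(genome[pos:])
        collapsed = "".join(keep)
        result = mask_assembly([("chr1", collapsed)], small_sim["library"])
        for fam in spec.families:
            bp = sum(r.bp_weight for r in result.records if r.family == fam.name)
            prop = bp / result.total_sampled_bp
            assert prop < 0.5 * truth[fam.name].true_proportion


class TestSerialization:
    def test_tsv_round_trip(self, small_sim, tmp_path):
        mask = small_sim["mask"]
        p = tmp_path / "mask.tsv"
        write_mask_tsv(mask, p)
        back = read_mask_tsv(p)
        assert back.sample == mask.sample
        assert back.total_sampled_bp == mask.total_sampled_bp
        assert back.n_reads == mask.n_reads
        assert len(back.records) == len(mask.records)
        for a, b in zip(back.records, mask.records):
            assert (a.read_id, a.family, a.strand, a.read_start, a.read_end) == (
                b.read_id,
                b.family,
                b.strand,
                b.read_start,
                b.read_end,
            )
            assert a.k2p_divergence == pytest.approx(b.k2p_divergence, abs=1e-3)

    def test_repeatmasker_align_reader(self, tmp_path):
        # synthetic .align-style block (post-divergence-script layout)
        text = (
            "239 17.31 0.00 0.00 read0001 1 144 (6) TaquSat1-183#Satellite 10 153 (213) m_b1 1\n"
            "\n"
            "  read0001      1 ACGTACGT 8\n"
            "                  ii v\n"
            "  TaquSat1-183  10 ATGTACGT 17\n"
            "\n"
            "Matrix = 20p43g.matrix\n"
            "Kimura (with divCpGMod) = 19.85\n"
            "\n"
            "120 5.00 0.00 0.00 read0002 3 100 (50) C TaquSat2-107#Satellite (0) 214 100 m_b2 2\n"
            "Kimura (with divCpGMod) = 5.12\n"
        )
        p = tmp_path / "sample.align"
        p.write_text(text)
        result = read_repeatmasker_align(p, total_sampled_bp=1_000_000)
        assert len(result.records) == 2
        r1, r2 = result.records
        assert r1.read_id == "read0001"
        assert r1.family == "TaquSat1-183"
        assert r1.strand == "+"
        assert (r1.read_start, r1.read_end) == (0, 144)
        assert r1.read_length == 150
        assert r1.k2p_divergence == pytest.approx(19.85)
        assert r2.strand == "-"
        assert r2.k2p_divergence == pytest.approx(5.12)
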