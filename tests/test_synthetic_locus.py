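"""Synthetic locus construction, NAHR events, and the data simulators."""

import math

import numpy as np
import pytest

import locuskit as lk
from locuskit.errors import InputError, LayoutError, UnsupportedEventError
from locuskit.synthetic import _surviving_parent_positions


def small_config(seed=1, divergence=0.01, genes=(("g1", "+", "fam"), ("g2", "+", "fam"))):
    return lk.LocusConfig(
        genome_length=12_000,
        clusters=(lk.ClusterSpec("c", 1_000, genes, (500,) * (len(genes) - 1)),),
        unique_genes=(("u", 400, 9_000),),
        seed=seed,
        per_site_divergence=divergence,
    )


class TestBuildLocus:
    def test_zero_divergence_gives_identical_copies(self):
        locus = lk.build_locus(small_config(divergence=0.0))
        assert locus.pair_truth("g1", "g2") == ()
        assert locus.gene_sequence("g1") == locus.gene_sequence("g2")

    def test_truth_sites_match_brute_force_recount(self):
        """Planted site lists equal a position-by-position recount of the
        emitted paralog sequences (independent oracle)."""
        locus = lk.build_locus(small_config(seed=5, divergence=0.01))
        a = locus.gene_sequence("g1")
        b = locus.gene_sequence("g2")
        recount = tuple(i + 1 for i, (x, y) in enumerate(zip(a, b)) if x != y)
        assert locus.pair_truth("g1", "g2") == recount
        assert len(recount) > 0

    def test_seed_determinism_byte_identical(self, tmp_path):
        import locuskit.io as lio

        cfg = lk.i_i_allele_config(seed=42)
        for name in ("one", "two"):
            locus = lk.build_locus(cfg)
            lio.write_fasta(tmp_path / f"{name}.fasta", [(locus.contig, locus.sequence)])
            lio.write_gff3(tmp_path / f"{name}.gff3", locus)
        assert (tmp_path / "one.fasta").read_bytes() == (tmp_path / "two.fasta").read_bytes()
        assert (tmp_path / "one.gff3").read_bytes() == (tmp_path / "two.gff3").read_bytes()

    def test_different_seeds_differ(self):
        l1 = lk.build_locus(small_config(seed=1))
        l2 = lk.build_locus(small_config(seed=2))
        assert l1.sequence != l2.sequence

    def test_preset_structure(self, preset_locus):
        """The preset carries 12 family members of which 6 form three
        exactly reverse-complementary inverted-repeat pairs flanking one
        unique central gene."""
        members = preset_locus.family_members()
        assert len(members) == 12
        ir_pairs = [("CHS1a", "CHS1c"), ("CHS3a", "CHS3c"), ("CHS4a", "CHS4c")]
        for left, right in ir_pairs:
            assert preset_locus.pair_truth(left, right) == ()
            fl = preset_locus.feature(left)
            fr = preset_locus.feature(right)
            assert {fl.strand, fr.strand} == {"+", "-"}
            # the ATG-oriented sequences agree, i.e. the arms are exact
            # reverse complements at these genes
            assert preset_locus.gene_sequence(left) == preset_locus.gene_sequence(right)
        hypo = preset_locus.feature("hypothetical")
        assert hypo.family == "unique"
        arm_genes = [preset_locus.feature(g) for pair in ir_pairs for g in pair]
        assert min(f.start for f in arm_genes) < hypo.start < max(f.end for f in arm_genes)

    def test_preset_donor_acceptor_distance(self, preset_locus):
        d = preset_locus.feature("CHS5")
        a = preset_locus.feature("CHS1")
        assert a.start - d.start == 138_092

    def test_overlapping_features_rejected(self):
        cfg = lk.LocusConfig(
            genome_length=10_000,
            clusters=(lk.ClusterSpec("c", 1_000, (("g1", "+", "fam"),)),),
            unique_genes=(("u", 500, 1_200),),  # collides with g1
            seed=0,
        )
        with pytest.raises(LayoutError, match="g1.*u|u.*g1"):
            lk.build_locus(cfg)

    def test_feature_outside_genome_rejected(self):
        cfg = lk.LocusConfig(
            genome_length=2_000,
            clusters=(lk.ClusterSpec("c", 1_500, (("g1", "+", "fam"),)),),
            unique_genes=(),
            seed=0,
        )
        with pytest.raises(LayoutError):
            lk.build_locus(cfg)


class TestApplyNahr:
    def test_deletion_length_equals_atg_distance(self, preset_locus):
        """Oracle: deletion length is coordinate subtraction on the
        annotation, for any junction."""
        for junction in (1, 600, 1295):
            _, ev = lk.apply_nahr(preset_locus, "CHS5", "CHS1", junction)
            assert ev.deletion_length == 138_092

    def test_length_conservation(self, preset_locus, nahr_mutant):
        mutant, ev = nahr_mutant
        assert mutant.genome_length + ev.deletion_length == preset_locus.genome_length

    def test_chimera_is_donor_prefix_plus_acceptor_suffix(self, preset_locus):
        j = 400
        mutant, ev = lk.apply_nahr(preset_locus, "CHS5", "CHS1", j)
        expected = (
            preset_locus.gene_sequence("CHS5")[:j]
            + preset_locus.gene_sequence("CHS1")[j:]
        )
        assert mutant.gene_sequence(ev.chimera_id) == expected

    def test_boundary_junction_chimera_identical_to_donor(self, preset_locus):
        tlen = preset_locus.feature("CHS5").length
        mutant, ev = lk.apply_nahr(preset_locus, "CHS5", "CHS1", tlen)
        assert mutant.gene_sequence(ev.chimera_id) == preset_locus.gene_sequence("CHS5")
        assert ev.deletion_length == 138_092

    def test_feature_recount_after_deletion(self, preset_locus, nahr_mutant):
        """Brute-force recount: surviving family members = original − copies
        inside the deletion − donor − acceptor + 1 chimera; unique genes
        inside the deletion vanish from the annotation."""
        mutant, ev = nahr_mutant
        s, e = ev.deleted_interval
        inside = [
            f
            for f in preset_locus.family_members()
            if f.start >= s and f.end <= e
        ]
        recount = len(preset_locus.family_members()) - len(inside) - 2 + 1
        assert len(mutant.family_members()) == recount == 1
        deleted_unique = {
            f.gene_id
            for f in preset_locus.features
            if f.family == "unique" and f.start >= s and f.end <= e
        }
        assert deleted_unique == {"u1", "u2", "u3", "u4", "u5",
                                  "hypothetical", "u7", "u8"}
        survivors = {f.gene_id for f in mutant.features}
        assert deleted_unique.isdisjoint(survivors)
        assert {"subtilisin", "epimerase", "galactosidase"} <= survivors

    def test_opposite_strand_pair_rejected(self, preset_locus):
        with pytest.raises(UnsupportedEventError):
            lk.apply_nahr(preset_locus, "CHS5", "CHS1c", 100)

    def test_downstream_donor_rejected(self, preset_locus):
        with pytest.raises(InputError, match="upstream"):
            lk.apply_nahr(preset_locus, "CHS1", "CHS5", 100)

    def test_minus_strand_pair_supported(self, preset_locus):
        """A same-orientation minus-strand pair recombines with the
        ATG-upstream (rightmost) copy as donor."""
        mutant, ev = lk.apply_nahr(preset_locus, "CHS1c", "CHS4c", 200)
        assert ev.deletion_length == (
            preset_locus.feature("CHS1c").end - preset_locus.feature("CHS4c").end
        )
        assert mutant.genome_length + ev.deletion_length == preset_locus.genome_length
        expected = (
            preset_locus.gene_sequence("CHS1c")[:200]
            + preset_locus.gene_sequence("CHS4c")[200:]
        )
        assert mutant.gene_sequence(ev.chimera_id) == expected


class TestSimulateCoverage:
    def test_no_event_uniform_track(self, preset_locus):
        track = lk.simulate_coverage(
            preset_locus, preset_locus,
            lk.CoverageSimConfig(mean_depth=25.0, seed=1, noise_dispersion=0.0),
        )
        assert np.allclose(track.values, 25.0)

    def test_allocation_model_closed_form(self, preset_locus, nahr_mutant):
        """With 12→1 surviving copies, every reference family copy carries
        mean_depth × 1/12 before noise; deleted unique genes carry 0;
        surviving unique sequence keeps mean_depth."""
        mutant, ev = nahr_mutant
        track = lk.simulate_coverage(
            preset_locus, mutant,
            lk.CoverageSimConfig(mean_depth=24.0, seed=1, noise_dispersion=0.0),
        )
        for gid in ("CHS5", "CHS3b", "CHS1c", "CHS1"):
            f = preset_locus.feature(gid)
            assert track.slice_mean(f.start, f.end) == pytest.approx(24.0 / 12)
        for gid in ("u3", "hypothetical"):
            f = preset_locus.feature(gid)
            assert track.slice_mean(f.start, f.end) == 0.0
        for gid in ("subtilisin", "galactosidase"):
            f = preset_locus.feature(gid)
            assert track.slice_mean(f.start, f.end) == pytest.approx(24.0)

    def test_noise_preserves_mean(self, preset_locus):
        track = lk.simulate_coverage(
            preset_locus, preset_locus,
            lk.CoverageSimConfig(mean_depth=30.0, seed=2, noise_dispersion=0.05),
        )
        assert track.values.mean() == pytest.approx(30.0, rel=0.01)
        assert track.values.std() > 0

    def test_surviving_position_bookkeeping(self):
        ev = lk.NahrEvent("d", "a", 1, (3, 5), "d:a")
        mask = _surviving_parent_positions(8, [ev])
        assert list(mask) == [True, True, False, False, False, True, True, True]


class TestSimulateDpcr:
    def test_zero_ratio_no_target_positives(self):
        assays = lk.simulate_dpcr(lk.DpcrSimConfig(1000, 0.5, 0.0, 5, seed=3))
        assert all(a.positives_target == 0 for a in assays)
        assert all(a.positives_ref > 0 for a in assays)

    def test_unit_ratio_symmetric_in_expectation(self):
        assays = lk.simulate_dpcr(lk.DpcrSimConfig(10_000, 0.5, 1.0, 200, seed=4))
        t = np.mean([a.positives_target for a in assays])
        r = np.mean([a.positives_ref for a in assays])
        assert t == pytest.approx(r, rel=0.02)

    def test_deterministic_given_seed(self):
        cfg = lk.DpcrSimConfig(770, 0.5, 11.0, 4, seed=9)
        assert lk.simulate_dpcr(cfg) == lk.simulate_dpcr(cfg)


class TestSimulateVariants:
    def test_zero_rates_empty_table(self):
        cfg = lk.IntrogressionConfig(0.0, (100, 200), 0.0, seed=1)
        assert len(lk.simulate_variants(cfg, 10_000)) == 0

    def test_positions_unique_and_sorted(self):
        cfg = lk.IntrogressionConfig(0.5, (2_000, 8_000), 5.0, seed=2)
        table = lk.simulate_variants(cfg, 20_000)
        pos = table.records.pos.to_numpy()
        assert (np.diff(pos) > 0).all()

    def test_block_density_elevated(self):
        cfg = lk.IntrogressionConfig(0.1, (50_000, 150_000), 3.0, seed=3)
        table = lk.simulate_variants(cfg, 300_000)
        inside = table.in_region("locus", 50_000, 150_000)
        outside_n = len(table) - len(inside)
        # ~300 expected inside vs ~20 outside
        assert len(inside) > 5 * outside_n

    def test_block_outside_genome_rejected(self):
        cfg = lk.IntrogressionConfig(0.1, (50, 500), 1.0, seed=1)
        with pytest.raises(InputError):
            lk.simulate_variants(cfg, 300)

    def test_variant_pair_plants_exact_sharing(self):
        cfg = lk.IntrogressionConfig(0.2, (1_000, 5_000), 2.0, seed=6)
        a, b, planted = lk.simulate_variant_pair(cfg, 50_000, 0.83)
        assert lk.variant_sharing(a, b) == pytest.approx(planted)
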