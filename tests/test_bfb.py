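"""Breakage-fusion-bridge mechanics, profiles and consistency checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import karyorecon as kr
from karyorecon.bfb import (
    Block,
    LinearChromosome,
    arm_start_counts,
    bfb_consistent,
    bridge_break,
    bundled_scenario,
    cn_profile,
    dicentric,
    isodicentric,
    normal_chromosome,
    run_bfb,
    run_scenario,
    sister_fusion,
)

FOUNDING = [("9", "p"), ("22", "p")]


def make_dic():
    return dicentric(("9", "p24.3"), ("22", "p12"))


def brute_force_profile(structures, cmap, chrom):
    """Independent oracle: piecewise integration of block coverage over the
    exact partition induced by all block boundaries within each band."""
    n = len(cmap.bands(chrom))
    out = np.zeros(n)
    blocks = [b for s in structures for b in s.blocks if b.chrom == chrom]
    for i in range(n):
        cuts = sorted({float(i), float(i + 1)} |
                      {x for b in blocks for x in (b.lo, b.hi)
                       if i < x < i + 1})
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            mid = (lo + hi) / 2
            cover = sum(1 for b in blocks if b.lo <= mid < b.hi)
            out[i] += cover * (hi - lo)
    return out


class TestBridgeBreak:
    def test_products_partition_parent(self):
        dic = make_dic()
        rng = np.random.default_rng(0)
        left, right = bridge_break(dic, rng)
        assert left.length + right.length == pytest.approx(dic.length)
        # conservation of per-chromosome material
        for chrom in ("9", "22"):
            parent = sum(b.length for b in dic.blocks if b.chrom == chrom)
            got = sum(b.length for s in (left, right)
                      for b in s.blocks if b.chrom == chrom)
            assert got == pytest.approx(parent)

    def test_one_centromere_per_product_broken_ends_face_break(self):
        dic = make_dic()
        for seed in range(20):
            left, right = bridge_break(dic, np.random.default_rng(seed))
            assert len(left.active_centromeres()) == 1
            assert len(right.active_centromeres()) == 1
            assert not left.right_capped and left.left_capped
            assert not right.left_capped and right.right_capped

    def test_fixed_seed_replays_identically(self):
        a = bridge_break(make_dic(), np.random.default_rng(5))
        b = bridge_break(make_dic(), np.random.default_rng(5))
        assert a[0].describe() == b[0].describe()

    def test_not_dicentric_rejected(self):
        with pytest.raises(ValueError, match="dicentric"):
            bridge_break(normal_chromosome("9"), np.random.default_rng(0))

    def test_break_position_uniform_between_centromeres(self):
        """Chi-square uniformity over the inter-centromeric span."""
        dic = make_dic()
        cens = dic.active_centromeres()
        d1, d2 = cens[0][3], cens[1][3]
        rng = np.random.default_rng(123)
        draws = []
        for _ in range(10_000):
            left, _ = bridge_break(dic, rng)
            draws.append(left.length)
        hist, _ = np.histogram(draws, bins=20, range=(d1, d2))
        assert stats.chisquare(hist).pvalue > 0.01


class TestSisterFusion:
    def test_mirror_construction(self):
        broken = LinearChromosome(
            [Block("1", 0, 2, True, ((1.0, True),)), Block("2", 0, 1, True)],
            left_capped=True, right_capped=False)
        fused = sister_fusion(broken)
        assert len(fused.blocks) == 4
        a, b, c, d = fused.blocks
        assert (c.chrom, c.lo, c.hi, c.forward) == ("2", 0, 1, False)
        assert (d.chrom, d.lo, d.hi, d.forward) == ("1", 0, 2, False)

    def test_palindrome_about_fusion_junction(self):
        rng = np.random.default_rng(1)
        current = make_dic()
        for _ in range(4):
            left, right = bridge_break(current, rng)
            chosen = left if rng.random() < 0.5 else right
            fused = sister_fusion(chosen)
            sig = [(b.chrom, b.lo, b.hi, b.forward) for b in fused.blocks]
            mirror = [(b.chrom, b.lo, b.hi, not b.forward)
                      for b in reversed(fused.blocks)]
            assert sig == mirror
            assert len(fused.blocks) == 2 * len(chosen.blocks)
            current = fused

    def test_monocentric_input_becomes_dicentric(self):
        left, _ = bridge_break(make_dic(), np.random.default_rng(2))
        fused = sister_fusion(left)
        assert fused.is_dicentric

    def test_isodicentric_matches_fusion_of_pericentric_segment(self, cmap):
        """A pericentromeric 20q11.2 segment fused with its mirror is the
        proposed centromere-flanked isodicentric."""
        iso = isodicentric("20", "q11.23", cmap)
        cens = iso.active_centromeres()
        assert len(cens) == 2
        assert {c[1] for c in cens} == {"20"}
        # mirror symmetric with the centromere copies at the outer flanks
        sig = [(b.lo, b.hi, b.forward) for b in iso.blocks]
        assert sig[0][:2] == sig[1][:2] and sig[0][2] != sig[1][2]
        assert cens[0][3] < iso.length / 4 and cens[1][3] > 3 * iso.length / 4

    def test_no_broken_end_rejected(self):
        with pytest.raises(ValueError, match="broken"):
            sister_fusion(normal_chromosome("9"))


class TestRunBfb:
    def test_zero_cycles_no_stabilisation_is_identity(self):
        dic = make_dic()
        hist = run_bfb(dic, 0, "none", seed=3)
        assert hist.final[0].describe() == dic.describe()

    def test_history_replays_to_final(self):
        for mode, params in [("none", None),
                             ("centromere_inactivation", {}),
                             ("ring_excision", {})]:
            hist = run_bfb(make_dic(), 3, mode, seed=11, params=params)
            assert hist.replay()[0].describe() == hist.final[0].describe()

    def test_telomere_capture_caps_broken_end(self):
        donor = {"chrom": "11", "from": "q24.1", "to": "qter"}
        hist = run_bfb(make_dic(), 2, "telomere_capture", seed=4,
                       params={"donor": donor})
        final = hist.final[0]
        assert final.broken_ends == 0
        assert any(b.chrom == "11" for b in final.blocks)

    def test_centromere_capture_replaces_native_centromere(self):
        donor = {"chrom": "19", "from": "p11", "to": "q12"}
        hist = run_bfb(make_dic(), 2, "centromere_capture", seed=4,
                       params={"donor": donor})
        final = hist.final[0]
        actives = [(c, a) for c, _, a in final.all_centromeres() if a]
        assert actives == [("19", True)]
        assert final.broken_ends == 0

    def test_ring_excision_emits_centric_ring_and_remnants(self):
        hist = run_bfb(make_dic(), 2, "ring_excision", seed=8, params={})
        ring = hist.final[0]
        assert ring.ring
        actives = [c for c, _, a in ring.all_centromeres() if a]
        assert len(actives) == 1 and actives[0] in ("9", "22")

    def test_invalid_mode_named_in_error(self):
        with pytest.raises(ValueError, match="unknown stabilisation"):
            run_bfb(make_dic(), 1, "teleport", seed=0)


class TestCnProfile:
    def test_two_normal_homologues_flat_two(self, cmap):
        prof = cn_profile([normal_chromosome("9", cmap)] * 2, cmap)
        assert (prof["count"] == 2).all()

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, cmap, seed):
        hist = run_bfb(make_dic(), int(np.random.default_rng(seed).integers(1, 5)),
                       "none", seed=seed)
        prof = cn_profile(hist.final, cmap)
        for chrom in ("9", "22"):
            got = prof[prof.chrom == chrom]["count"].to_numpy()
            want = brute_force_profile(hist.final, cmap, chrom)
            if got.size == 0:   # chromosome entirely lost from the lineage
                assert np.allclose(want, 0.0)
            else:
                assert np.allclose(got, want)

    def test_confinement_between_founding_centromeres(self, cmap):
        """Elevation above the lineage's telomeric-arm level stays strictly
        between the founding centromeres, for every seed and cycle count."""
        for seed in range(100):
            cycles = int(np.random.default_rng(1000 + seed).integers(1, 7))
            hist = run_bfb(make_dic(), cycles, "none", seed=seed)
            prof = cn_profile(hist.final, cmap)
            starts = arm_start_counts(prof, FOUNDING)
            rep = bfb_consistent(prof, FOUNDING, start_counts=starts,
                                 cmap=cmap)
            assert rep.confined, rep.violations


class TestBfbConsistent:
    def test_simulated_output_consistent_by_construction(self, cmap):
        hist = run_bfb(make_dic(), 4, "none", seed=21)
        prof = cn_profile(hist.final, cmap)
        rep = bfb_consistent(prof, FOUNDING,
                             start_counts=arm_start_counts(prof, FOUNDING),
                             cmap=cmap)
        assert rep.consistent

    def test_distal_amplification_rejected(self, cmap):
        """Amplification on the telomeric side of a founding centromere
        violates the between-centromeres rule."""
        rows = []
        for i, b in enumerate(cmap.bands("9")):
            count = 3.0 if b.name.startswith("q") else 1.0
            rows.append(("9", b.name, i, count))
        prof = pd.DataFrame(rows, columns=["chrom", "band", "index", "count"])
        rep = bfb_consistent(prof, [("9", "p")], start_counts={"9": 1.0},
                             cmap=cmap)
        assert not rep.consistent
        assert "inter-centromeric" in rep.violations[0]

    def test_der9_like_fixture_profile_consistent(self, cmap):
        """9p24.3-p21.2 elevated, 9q at baseline: the observed der(9)
        pattern under founding centromeres 9cen and 22cen."""
        elevated = {"p24.3", "p24.2", "p24.1", "p23", "p22.3", "p22.2",
                    "p22.1", "p21.3", "p21.2"}
        rows = []
        for i, b in enumerate(cmap.bands("9")):
            rows.append(("9", b.name, i, 3.0 if b.name in elevated else 1.0))
        for i, b in enumerate(cmap.bands("22")):
            rows.append(("22", b.name, i, 2.0 if b.name.startswith("p") else 1.0))
        prof = pd.DataFrame(rows, columns=["chrom", "band", "index", "count"])
        rep = bfb_consistent(prof, FOUNDING,
                             start_counts={"9": 1.0, "22": 1.0}, cmap=cmap)
        assert rep.consistent


class TestScenarios:
    def test_psu_dic_replay(self, cmap):
        """The bundled dic(9;22) replay yields a pseudodicentric with
        9p-only and 22p-only elevation and one inactivated centromere."""
        hist = run_scenario(bundled_scenario("psu_dic_22_9.json"), seed=7)
        final = hist.final[0]
        states = [a for _, _, a in final.all_centromeres()]
        assert states.count(False) == 1 and states.count(True) == 1
        assert sum(1 for b in final.blocks if b.chrom == "9") >= 2
        assert sum(1 for b in final.blocks if b.chrom == "22") >= 2
        prof = cn_profile(hist.final, cmap)
        starts = arm_start_counts(prof, FOUNDING)
        for chrom in ("9", "22"):
            sub = prof[prof.chrom == chrom]
            elev = sub[sub["count"] > starts[chrom] + 1e-9]
            assert set(elev.band.str[0]) <= {"p"}   # never on the q arms
            assert not elev.empty                   # both 9p and 22p elevated

    def test_psu_dic_9p_exceeds_9q_everywhere_elevated(self, cmap):
        hist = run_scenario(bundled_scenario("psu_dic_22_9.json"), seed=7)
        prof = cn_profile(hist.final, cmap)
        nine = prof[prof.chrom == "9"]
        q_max = nine[nine.band.str.startswith("q")]["count"].max()
        p_elev = nine[nine.band.str.startswith("p")]["count"]
        assert p_elev.max() > q_max

    def test_ring_scenario_matches_r20_architecture(self, cmap):
        """Excision yields a 20-centromere-bearing ring with no telomeric
        termini, plus two acentric remnants in the history."""
        hist = run_scenario(bundled_scenario("ring_20_excision.json"), seed=3)
        ring = hist.final[0]
        assert ring.ring and ring.broken_ends == 0
        actives = [c for c, _, a in ring.all_centromeres() if a]
        assert actives == ["20"]
        assert all(b.chrom == "20" for b in ring.blocks)
        assert len(hist.discarded) >= 2
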