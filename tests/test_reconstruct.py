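"""Inversion: segmentation, allele-specific calling, assembly, recovery."""

import numpy as np
import pandas as pd
import pytest

import karyorecon as kr
from karyorecon.genome import BandInterval
from karyorecon.observe import (
    PaintObservation,
    ProbeGrid,
    assign_homologues,
    simulate_array,
    simulate_fish,
)
from karyorecon.reconstruct import (
    AssemblyProblem,
    CalledSegment,
    assign_segments,
    call_allelic_cn,
    call_segments,
    recover,
    segment_baf_lrr,
)
from conftest import TOY_CHROMS


class TestSegmentation:
    def test_homogeneous_region_no_changepoints(self):
        hk = assign_homologues(kr.parse_karyotype("46,XX"))
        grid = ProbeGrid(density=20, chromosomes=("5",), seed=4)
        obs = simulate_array(hk, grid, 0.0, 0.0, seed=0)
        assert segment_baf_lrr(obs)["5"] == []

    def test_noise_free_breakpoints_exact(self, toy_hk, toy_grid):
        obs = simulate_array(toy_hk, toy_grid, 0.0, 0.0, seed=0)
        cps = segment_baf_lrr(obs)
        # truth: one copy-state transition per rearranged chromosome
        for chrom in ("1", "2", "5"):
            sub = obs.probes[obs.probes.chrom == chrom].sort_values("pos")
            t = (sub.nA + sub.nB).to_numpy()
            b = sub.nB.to_numpy()
            true_cps = [i for i in range(1, len(sub))
                        if t[i] != t[i - 1] or b[i] != b[i - 1]]
            assert cps[chrom] == true_cps

    def test_too_few_probes_flagged_empty(self):
        hk = assign_homologues(kr.parse_karyotype("46,XX"))
        grid = ProbeGrid(density=1, chromosomes=("21",), seed=0)
        obs = simulate_array(hk, grid, 0.1, 0.03, seed=0)
        assert segment_baf_lrr(obs, min_probes=10)["21"] == []

    def test_changepoint_localisation_under_noise(self):
        """A (1,1)|(2,1) junction is localised within +-10 probes in >=90%
        of seeds at sigma_baf = 0.03."""
        n_side = 200
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            t = np.r_[np.full(n_side, 2.0), np.full(n_side, 3.0)]
            nb = np.r_[np.full(n_side, 1.0), np.full(n_side, 1.0)]
            lrr = np.log2(t / 2) + rng.normal(0, 0.15, 2 * n_side)
            baf = np.clip(nb / t + rng.normal(0, 0.03, 2 * n_side), 0, 1)
            df = pd.DataFrame({
                "probe_id": [f"p{i}" for i in range(2 * n_side)],
                "chrom": "2", "band": "q22.1",
                "ordinal": 1, "pos": np.arange(2 * n_side, dtype=float),
                "lrr": lrr, "baf": baf,
                "het": True, "no_signal": False,
            })
            from karyorecon.observe import ArrayObservation
            obs = ArrayObservation(df, 0.15, 0.03, seed, 2)
            cps = segment_baf_lrr(obs)["2"]
            if len(cps) >= 1 and min(abs(c - n_side) for c in cps) <= 10:
                hits += 1
        assert hits / n_seeds >= 0.9


class TestAllelicCalling:
    @pytest.mark.parametrize("lrr,fold,expected", [
        (0.0, 0.0, (1, 1)),              # diploid heterozygous
        (np.log2(3 / 2), 1 / 6, (2, 1)),   # folded BAF of the 1/3-2/3 state
        (0.0, 0.5, (2, 0)),              # LOH at two copies
        (np.log2(5 / 2), 0.1, (3, 2)),
        (-10.0, 0.0, (0, 0)),            # homozygous deletion
    ])
    def test_examples(self, lrr, fold, expected):
        assert call_allelic_cn(lrr, fold) == expected

    def test_tie_breaks_toward_balance(self):
        # t=2 and folded BAF exactly between (1,1) and (2,0): prefer (1,1)
        assert call_allelic_cn(0.0, 0.25) == (1, 1)

    def test_total_capped(self):
        nA, nB = call_allelic_cn(5.0, 0.5, max_total=8)
        assert nA + nB == 8

    def test_no_het_probes_called_loh(self):
        assert call_allelic_cn(0.0, float("nan")) == (2, 0)


class TestAssignment:
    def _mk_seg(self, chrom, start, end, terminal=False):
        return CalledSegment(BandInterval(chrom, start, end), 10, 0.0, 0.0,
                             2, 1, 1, terminal=terminal)

    def _paint(self, name, sources, cen=None, ring=False, blocks=()):
        return PaintObservation(name, frozenset(sources), list(blocks),
                                cen or {}, 0, ring=ring)

    def test_unique_solution_matches_exhaustive_oracle(self):
        segs = [
            self._mk_seg("1", "pter", "p34.1", terminal=True),
            self._mk_seg("5", "q31.1", "qter", terminal=True),
            self._mk_seg("2", "pter", "q24.1", terminal=True),
            self._mk_seg("6", "p21.1", "pter", terminal=True),
        ]
        paints = [self._paint("derA", {"1", "5"}),
                  self._paint("derB", {"2", "6"})]
        problem = AssemblyProblem(segs, paints, frozenset("123456"))
        result = assign_segments(problem)
        assert result.feasible and len(result.solutions) == 1
        sol = result.solutions[0]
        assert sol == {0: "derA", 1: "derA", 2: "derB", 3: "derB"}

        # independent oracle: enumerate all 2^4 assignments
        def valid(assign):
            for name, srcs in (("derA", {"1", "5"}), ("derB", {"2", "6"})):
                got = {segs[i].interval.chrom
                       for i in range(4) if assign[i] == name}
                if got != srcs:
                    return False
            return True

        from itertools import product
        oracle = [dict(enumerate(a))
                  for a in product(["derA", "derB"], repeat=4) if valid(dict(enumerate(a)))]
        assert oracle == [sol]

    def test_terminal_segment_rejected_from_interior(self):
        """Three terminal segments cannot all fit on one derivative's two
        ends."""
        segs = [self._mk_seg("1", "pter", "p34.1", terminal=True),
                self._mk_seg("5", "q31.1", "qter", terminal=True),
                self._mk_seg("2", "q22.1", "qter", terminal=True)]
        paints = [self._paint("derA", {"1", "5", "2"})]
        res = assign_segments(AssemblyProblem(segs, paints, frozenset("125")))
        assert not res.feasible
        assert "terminal" in res.infeasible_reason

    def test_ring_receives_no_terminal_segment(self):
        segs = [self._mk_seg("20", "p11.1", "q11.21"),
                self._mk_seg("19", "p13.2", "qter", terminal=True)]
        paints = [self._paint("ring", {"20", "19"}, ring=True)]
        res = assign_segments(AssemblyProblem(segs, paints, frozenset({"19", "20"})))
        assert not res.feasible

    def test_missing_source_chromosome_is_infeasible(self):
        segs = [self._mk_seg("11", "q23.2", "qter", terminal=True)]
        paints = [self._paint("der19", {"11", "15", "19", "20"})]
        res = assign_segments(AssemblyProblem(segs, paints,
                                              frozenset({"11", "15", "19", "20"})))
        assert not res.feasible
        assert "source set" in res.infeasible_reason

    def test_brute_force_agreement_on_random_instances(self):
        """Backtracking equals exhaustive enumeration on small instances."""
        from itertools import product
        rng = np.random.default_rng(7)
        chroms = ["1", "2", "3", "5", "7", "9"]
        for trial in range(20):
            n_seg = int(rng.integers(3, 7))
            segs = [self._mk_seg(str(rng.choice(chroms)), "q21.1", "q21.3")
                    for _ in range(n_seg)]
            names = ["d0", "d1"]
            paints = [self._paint(n, {segs[i].interval.chrom
                                      for i in rng.choice(n_seg, size=2)})
                      for n in names]
            problem = AssemblyProblem(segs, paints, frozenset(chroms))
            res = assign_segments(problem)
            placeable = [i for i in range(n_seg)
                         if any(segs[i].interval.chrom in p.source_set
                                for p in paints)]

            def valid(assign):
                for p in paints:
                    got = {segs[i].interval.chrom for i in assign
                           if assign[i] == p.name}
                    if got != set(p.source_set):
                        return False
                return True

            oracle = []
            for combo in product(names, repeat=len(placeable)):
                a = dict(zip(placeable, combo))
                if valid(a):
                    oracle.append(a)
            got = [dict(sorted(s.items())) for s in res.solutions]
            assert sorted(got, key=str) == sorted(
                [dict(sorted(a.items())) for a in oracle], key=str)


class TestRecover:
    def test_noise_free_inversion_is_exact(self, toy_hk, toy_grid, toy_paints):
        obs = simulate_array(toy_hk, toy_grid, 0.0, 0.0, seed=0)
        rep = recover(obs, toy_paints, toy_hk)
        assert rep.band_accuracy == 1.0
        assert rep.composition_accuracy == 1.0

    def test_conservation_in_noise_free_limit(self, toy_hk, toy_grid, cmap):
        """Total called copy mass per chromosome equals the truth's."""
        from karyorecon.observe import band_copy_table
        obs = simulate_array(toy_hk, toy_grid, 0.0, 0.0, seed=0)
        called = call_segments(obs, cmap=cmap)
        truth = band_copy_table(toy_hk, list(TOY_CHROMS))
        for chrom in TOY_CHROMS:
            leaf_ords = {cmap._ordmap(chrom)[b.name] for b in cmap.bands(chrom)}
            mass = 0
            for seg in called:
                if seg.interval.chrom != chrom:
                    continue
                span = seg.interval.covered_span(cmap)
                covered = sum(1 for o in leaf_ords if span.lo <= o <= span.hi)
                mass += seg.total * covered
            tsub = truth[truth.chrom == chrom]
            assert mass == int((tsub.nA + tsub.nB).sum())

    def test_same_seed_same_report(self, toy_hk, toy_grid, toy_paints):
        obs1 = simulate_array(toy_hk, toy_grid, 0.15, 0.03, seed=2)
        obs2 = simulate_array(toy_hk, toy_grid, 0.15, 0.03, seed=2)
        r1 = recover(obs1, toy_paints, toy_hk)
        r2 = recover(obs2, toy_paints, toy_hk)
        assert r1.band_accuracy == r2.band_accuracy
        assert r1.n_solutions == r2.n_solutions

    def test_mean_accuracy_under_noise(self, toy_hk, toy_grid, toy_paints):
        accs = []
        for seed in range(10):
            obs = simulate_array(toy_hk, toy_grid, 0.15, 0.03, seed=seed)
            accs.append(recover(obs, toy_paints, toy_hk).band_accuracy)
        assert float(np.mean(accs)) >= 0.95
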