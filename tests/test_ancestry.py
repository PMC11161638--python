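"""Window tiling, likelihood classification, and ancestry aggregation."""

import numpy as np
import pandas as pd
import pytest

from guidebias.ancestry import (WindowSet, assign_predominant,
                                ancestry_at_locus, build_windows,
                                global_ancestry_fractions,
                                infer_local_ancestry)
from guidebias.config import InputError
from guidebias.types import (AncestryPanel, GeneticMap, GlobalAncestry,
                             LocalAncestryTrack, VariantGenotypes)


def uniform_map(length=10_000_000, cm=10.0, chroms=("chr1",)):
    return GeneticMap.uniform(list(chroms), length, cm)


class TestBuildWindows:
    def test_uniform_map_window_count(self):
        ws = build_windows(uniform_map(), min_cm=0.2)
        assert ws.n_windows == 50
        spans = ws.table["cm_end"] - ws.table["cm_start"]
        assert np.allclose(spans, 0.2)

    def test_short_chromosome_single_window(self):
        ws = build_windows(uniform_map(length=100_000, cm=0.1))
        assert ws.n_windows == 1

    def test_terminal_remainder_window(self):
        ws = build_windows(uniform_map(cm=10.05), min_cm=0.2)
        assert ws.n_windows == 51
        assert ws.table["cm_end"].iloc[-1] - \
            ws.table["cm_start"].iloc[-1] == pytest.approx(0.05)

    def test_membership_matches_bruteforce_interpolation(self):
        gmap = uniform_map(cm=7.3)
        ws = build_windows(gmap, 0.2)
        rng = np.random.default_rng(0)
        pos = np.sort(rng.integers(0, 10_000_000, size=500))
        variants = pd.DataFrame({"chrom": "chr1", "pos0": pos,
                                 "ref": "A", "alt": "C"})
        got = ws.assign_variants(gmap, variants)
        cm = gmap.cm_at("chr1", pos)
        for i, c in enumerate(cm):
            lo = ws.table["cm_start"].to_numpy()
            hi = ws.table["cm_end"].to_numpy()
            brute = np.flatnonzero((c >= lo - 1e-9) & (c < hi - 1e-9))
            expect = brute[0] if brute.size else ws.n_windows - 1
            assert got[i] == expect

    def test_variant_outside_map_rejected(self):
        gmap = uniform_map()
        with pytest.raises(InputError):
            gmap.cm_at("chr1", 10_000_001)


def _toy_panel_and_genos(freq_a, freq_b, dosage, n_var=40):
    variants = pd.DataFrame({
        "chrom": "chr1",
        "pos0": np.arange(n_var) * 1000 + 500,
        "ref": "A", "alt": "C"})
    variants.index = pd.Index([f"v{i}" for i in range(n_var)],
                              name="variant_id")
    freqs = pd.DataFrame({"A": freq_a, "B": freq_b}, index=variants.index)
    panel = AncestryPanel(variants=variants, freqs=freqs)
    dosages = pd.DataFrame([np.full(n_var, dosage, dtype=float)],
                           index=pd.Index(["s0"], name="sample_id"),
                           columns=variants.index)
    genos = VariantGenotypes(variants=variants, dosages=dosages)
    gmap = GeneticMap.uniform(["chr1"], n_var * 1000, 0.1)
    ws = build_windows(gmap, 0.2)  # single window
    return panel, genos, gmap, ws


class TestInferLocalAncestry:
    def test_dominant_likelihood_homozygous_pair(self):
        panel, genos, gmap, ws = _toy_panel_and_genos(0.9, 0.1, 2.0)
        track = infer_local_ancestry(genos, panel, ws, gmap)
        assert track.pair[0, 0].tolist() == [0, 0]  # (A, A)
        assert track.margin[0, 0] > 0

    def test_identical_frequencies_tie_to_first_homozygous(self):
        panel, genos, gmap, ws = _toy_panel_and_genos(0.5, 0.5, 1.0)
        track = infer_local_ancestry(genos, panel, ws, gmap)
        assert track.pair[0, 0].tolist() == [0, 0]
        assert track.margin[0, 0] == pytest.approx(0.0)

    def test_heterozygous_ancestry_recovered(self):
        panel, genos, gmap, ws = _toy_panel_and_genos(0.95, 0.05, 1.0,
                                                      n_var=200)
        track = infer_local_ancestry(genos, panel, ws, gmap)
        assert sorted(track.pair[0, 0].tolist()) == [0, 1]  # (A, B)

    def test_all_missing_window_inherits_left_neighbour(self):
        n_var = 40
        panel, genos, gmap, _ = _toy_panel_and_genos(0.9, 0.1, 2.0, n_var)
        ws = build_windows(gmap, 0.02)  # several windows
        dos = genos.dosages.copy()
        last = ws.assign_variants(gmap, panel.variants) == ws.n_windows - 1
        dos.loc[:, panel.variants.index[last]] = np.nan
        genos2 = VariantGenotypes(variants=panel.variants, dosages=dos)
        track = infer_local_ancestry(genos2, panel, ws, gmap)
        assert track.imputed[0, -1]
        assert track.pair[0, -1].tolist() == track.pair[0, -2].tolist()

    def test_recovery_improves_with_divergence(self):
        from guidebias.config import SimConfig
        from guidebias.simulate import simulate_cohort
        accs = []
        for fst in (0.02, 0.1, 0.3):
            cfg = SimConfig(n_populations=3, fst=fst, n_samples=12,
                            n_chromosomes=1, n_variants_per_chrom=3000,
                            cm_per_chrom=4.0, seed=7)
            c = simulate_cohort(cfg)
            track = infer_local_ancestry(c.genotypes, c.panel, c.windows,
                                         c.gmap)
            tp = np.sort(c.truth.ancestry_painting.transpose(0, 2, 1),
                         axis=-1)
            accs.append((track.pair == tp).all(axis=-1).mean())
        assert accs[0] <= accs[1] + 0.05 <= accs[2] + 0.10
        assert accs[2] > 0.9


class TestGlobalAncestry:
    def _track(self, pairs, chroms):
        """pairs: (n_windows, 2) ints; chroms: list of chrom per window."""
        pairs = np.asarray(pairs)[None, :, :]
        table = pd.DataFrame({
            "chrom": chroms,
            "start": np.arange(len(chroms)) * 10,
            "end": np.arange(len(chroms)) * 10 + 10,
            "cm_start": 0.0, "cm_end": 0.2})
        ws = WindowSet(table=table, min_cm=0.2)
        track = LocalAncestryTrack(
            samples=pd.Index(["s0"]), populations=["A", "B", "C"],
            pair=pairs, margin=np.zeros(pairs.shape[:2]),
            imputed=np.zeros(pairs.shape[:2], dtype=bool))
        return track, ws

    def test_single_population_identity(self):
        track, ws = self._track([[0, 0]] * 4, ["chr1"] * 4)
        glob = global_ancestry_fractions(track, ws)
        assert glob.fractions.loc["s0", "A"] == 1.0

    def test_chromosomes_equally_weighted(self):
        # chr1: 3 windows all A; chr2: 1 window B -> 0.5 / 0.5
        track, ws = self._track([[0, 0]] * 3 + [[1, 1]],
                                ["chr1"] * 3 + ["chr2"])
        glob = global_ancestry_fractions(track, ws)
        assert glob.fractions.loc["s0", "A"] == pytest.approx(0.5)
        assert glob.fractions.loc["s0", "B"] == pytest.approx(0.5)

    def test_heterozygous_windows_split_half(self):
        track, ws = self._track([[0, 1]] * 4, ["chr1"] * 4)
        glob = global_ancestry_fractions(track, ws)
        assert glob.fractions.loc["s0", "A"] == pytest.approx(0.5)
        assert glob.fractions.loc["s0", "B"] == pytest.approx(0.5)
        assert glob.predominant.loc["s0"] == "Admixed"

    def test_fractions_sum_to_one(self, small_cohort):
        track = infer_local_ancestry(small_cohort.genotypes,
                                     small_cohort.panel,
                                     small_cohort.windows,
                                     small_cohort.gmap)
        glob = global_ancestry_fractions(track, small_cohort.windows)
        assert np.allclose(glob.fractions.sum(axis=1), 1.0, atol=1e-9)


class TestAssignPredominant:
    @pytest.mark.parametrize("fracs,expect", [
        ({"AFR": 0.89, "EUR": 0.11}, "AFR"),
        ({"AFR": 0.80, "EUR": 0.20}, "Admixed"),  # strict inequality
        ({"AFR": 0.5, "EUR": 0.5}, "Admixed"),
    ])
    def test_threshold_rule(self, fracs, expect):
        assert assign_predominant(pd.Series(fracs)) == expect

    def test_invariant_under_label_permutation(self):
        fracs = pd.Series({"AFR": 0.85, "EAS": 0.1, "EUR": 0.05})
        perm = pd.Series({"EUR": 0.85, "AFR": 0.1, "EAS": 0.05})
        assert assign_predominant(fracs) == "AFR"
        assert assign_predominant(perm) == "EUR"


class TestAncestryAtLocus:
    def _setup(self):
        panel, genos, gmap, ws = _toy_panel_and_genos(0.9, 0.1, 2.0)
        pair = np.array([[[0, 0], [0, 1]]])  # window 1 hom-A, window 2 het
        ws = build_windows(gmap, gmap.chrom_span_cm("chr1") / 2)
        track = LocalAncestryTrack(
            samples=pd.Index(["s0"]), populations=["A", "B"],
            pair=pair, margin=np.zeros((1, 2)),
            imputed=np.zeros((1, 2), dtype=bool))
        return track, ws, gmap

    def test_homozygous_window_label(self):
        track, ws, gmap = self._setup()
        glob = GlobalAncestry(
            fractions=pd.DataFrame({"A": [0.75], "B": [0.25]},
                                   index=["s0"]),
            predominant=pd.Series(["A"], index=["s0"]))
        lab = ancestry_at_locus(track, ws, gmap, glob, "chr1", 100)
        assert lab.loc["s0"] == "A"

    def test_heterozygous_resolved_by_global_fraction(self):
        track, ws, gmap = self._setup()
        glob = GlobalAncestry(
            fractions=pd.DataFrame({"A": [0.3], "B": [0.7]}, index=["s0"]),
            predominant=pd.Series(["B"], index=["s0"]))
        # second window is (A,B); B has the larger global fraction
        lab = ancestry_at_locus(track, ws, gmap, glob, "chr1", 35_000)
        assert lab.loc["s0"] == "B"

    def test_position_past_chromosome_end_rejected(self):
        track, ws, gmap = self._setup()
        glob = GlobalAncestry(
            fractions=pd.DataFrame({"A": [1.0], "B": [0.0]}, index=["s0"]),
            predominant=pd.Series(["A"], index=["s0"]))
        with pytest.raises(InputError):
            ancestry_at_locus(track, ws, gmap, glob, "chr1", 10**9)
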