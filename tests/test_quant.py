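import numpy as np
import pandas as pd
import pytest

import panelcall as pc
from panelcall.quant import (
    IpcBin,
    QuantError,
    YieldEstimate,
    _invert_collisions,
    _invert_dropout,
    collapse_identifiers,
)

from oracles import truth_ipc_bins


def _ipc_df(rows):
    return pd.DataFrame(rows, columns=["sample", "mutation_id", "identifier"])


class TestBinIpcs:
    def test_basic_grouping(self):
        df = _ipc_df([("S1", "M", "AAAAAAAA"), ("S1", "M", "AAAAAAAA"), ("S1", "M", "GGGGCCCC")])
        bins = pc.bin_ipcs(df)
        assert sorted(b.cluster_count for b in bins) == [1, 2]
        assert {b.identifier for b in bins} == {"AAAAAAAA", "GGGGCCCC"}

    def test_empty(self):
        assert pc.bin_ipcs(_ipc_df([])) == []

    def test_bin_sizes_sum_to_cluster_count(self):
        rng = np.random.default_rng(0)
        idents = ["".join("ACGT"[i] for i in rng.integers(0, 4, 8)) for _ in range(40)]
        rows = [("S1", "M", idents[int(rng.integers(0, 40))]) for _ in range(500)]
        bins = pc.bin_ipcs(_ipc_df(rows), collapse_distance=0)
        assert sum(b.cluster_count for b in bins) == 500

    def test_matches_brute_force_truth_grouping(self, small_panel, clean_sim, clean_clusters):
        clusters, _ = clean_clusters
        ipc = clusters[clusters.label == "IPC"]
        rows = [(r.sample, r.mutations, r.identifier) for r in ipc.itertuples(index=False)]
        bins = pc.bin_ipcs(_ipc_df(rows), collapse_distance=0)
        expected = truth_ipc_bins(clean_sim.truth, small_panel)
        observed = {(b.mutation_id, b.identifier): b.cluster_count for b in bins}
        assert observed == expected


class TestCollapse:
    def test_hamming1_absorbed_into_more_abundant(self):
        counts = {"AAAAAAAA": 10, "AAAAAAAT": 1, "GGGGGGGG": 5}
        out = collapse_identifiers(counts)
        assert out == {"AAAAAAAA": 11, "GGGGGGGG": 5}

    def test_hamming2_kept(self):
        counts = {"AAAAAAAA": 10, "AAAAAATT": 2}
        assert collapse_identifiers(counts) == counts

    def test_chain_absorbs_in_abundance_order(self):
        counts = {"AAAAAAAA": 10, "AAAAAAAT": 3, "AAAAAATT": 1}
        out = collapse_identifiers(counts)
        # AT absorbs into the 10-parent; ATT is H1 of AT (already absorbed),
        # H2 of the kept parent -> kept
        assert out == {"AAAAAAAA": 13, "AAAAAATT": 1}


class TestYield:
    def _bins(self, sizes, mutation="M", sample="S1"):
        return [
            IpcBin(f"ID{i:06d}", sample, mutation, s) for i, s in enumerate(sizes)
        ]

    def test_naive_arithmetic(self):
        ye = pc.estimate_yield(self._bins([2] * 50), "M", "S1", 50, correct=False)
        assert ye.cluster_yield == pytest.approx(2.0)
        assert ye.observed_bins == 50 and ye.total_clusters == 100

    def test_missing_yield_flag(self):
        ye = pc.estimate_yield([], "M", "S1", 50)
        assert not ye.available and ye.cluster_yield is None

    def test_requires_positive_spike(self):
        with pytest.raises(QuantError):
            pc.estimate_yield([], "M", "S1", 0)

    def test_correction_negligible_at_high_depth(self):
        # 50 bins of 80 clusters: dropout and collision corrections ~ 0
        ye = pc.estimate_yield(self._bins([80] * 50), "M", "S1", 50)
        assert ye.cluster_yield == pytest.approx(80.0, rel=0.01)

    def test_dropout_inversion_recovers_founders(self):
        # s_obs = s * (1 - exp(-T/s)) inverts exactly on the expectation
        s, T = 40.0, 60
        s_obs = s * (1 - np.exp(-T / s))
        assert _invert_dropout(s_obs, T, spiked=50) == pytest.approx(s, rel=1e-6)

    def test_collision_inversion(self):
        # expected distinct of s=100 draws from 4**8 is slightly below 100
        M = 4 ** 8
        expected_distinct = M * (1 - (1 - 1 / M) ** 100)
        assert _invert_collisions(int(round(expected_distinct)), 8) == pytest.approx(100, abs=1)

    def test_corrected_yield_tracks_simulator_truth(self, small_panel, clean_sim, clean_clusters):
        clusters, _ = clean_clusters
        truth = clean_sim.truth
        q = pc.quantify_sample(clusters, small_panel, "S1", 30, clean_sim.input_genomes)
        for mid in small_panel.mutation_ids:
            ipc = truth[(truth.founder_class == "IPC") & (truth.mutation_id == mid)]
            truth_yield = ipc.read_count.sum() / len(ipc)
            est = float(q.loc[q.mutation_id == mid, "cluster_yield"].iloc[0])
            assert est == pytest.approx(truth_yield, rel=0.10)


class TestCopyArithmetic:
    def test_copies(self):
        assert pc.estimate_copies(50, 10.0) == pytest.approx(5.0)
        assert pc.estimate_copies(0, 10.0) == 0.0
        assert pc.estimate_copies(0, None) == 0.0
        assert pc.estimate_copies(5, None) is None

    def test_monotone_in_clusters(self):
        ns = [pc.estimate_copies(c, 7.0) for c in range(0, 100, 7)]
        assert all(b > a for a, b in zip(ns, ns[1:]))

    def test_abundance_standard_input_arithmetic(self, panel):
        g_300ng = panel.genomes_from_mass(300.0)
        assert round(pc.abundance(10, g_300ng), 2) == 0.01
        assert pc.abundance(1, 100_000) == pytest.approx(0.001)
        assert pc.abundance(0, 100_000) == 0.0

    def test_abundance_rejects_nonpositive_genomes(self):
        with pytest.raises(QuantError):
            pc.abundance(1, 0)

    def test_plasma_normalization(self):
        assert pc.normalize_per_5ml(20, 5.0) == 20
        assert pc.normalize_per_5ml(20, 10.0) == 10
        assert pc.normalize_per_5ml(7, 2.5) == pytest.approx(14)
        with pytest.raises(QuantError):
            pc.normalize_per_5ml(1, 0)


class TestQuantifySample:
    def test_zero_copies_iff_zero_clusters(self, small_panel, clean_sim, clean_clusters):
        clusters, _ = clean_clusters
        q = pc.quantify_sample(clusters, small_panel, "S1", 30, clean_sim.input_genomes)
        for row in q.itertuples(index=False):
            assert (row.est_copies == 0) == (row.mutant_clusters == 0)

    def test_no_spike_flags_missing(self, small_panel, clean_sim, clean_clusters):
        clusters, _ = clean_clusters
        q = pc.quantify_sample(clusters, small_panel, "S1", {"KRAS G12D": 30}, 500)
        v600 = q[q.mutation_id == "BRAF V600E"].iloc[0]
        assert "no_ipc_spiked" in v600["flags"] and np.isnan(v600.cluster_yield)

    def test_recovers_spiked_copies(self, small_panel, clean_sim, clean_clusters):
        clusters, _ = clean_clusters
        q = pc.quantify_sample(clusters, small_panel, "S1", 30, clean_sim.input_genomes)
        g12d = q[q.mutation_id == "KRAS G12D"].iloc[0]
        assert g12d.est_copies == pytest.approx(20, rel=0.35)  # 20 spiked copies

    def test_depth_invariance_of_copy_estimate(self, small_panel):
        # doubling reads doubles C and Y but leaves N = C/Y unchanged
        est = {}
        for depth in (4000, 8000):
            cfg = pc.SimConfig(
                input_genomes=500, mutant_copies={"KRAS G12D": 40}, ipc_copies=30,
                per_base_error_per_cycle=0.0, retain_mut=0.9, retain_wt=0.9,
                enrich_cycles=4, reads_per_sample=depth, seed=31,
            )
            sim = pc.simulate_sample(small_panel, cfg)
            clusters, _ = pc.process_pool(sim.r1, sim.r2, small_panel, {"S1": cfg.barcode})
            q = pc.quantify_sample(clusters, small_panel, "S1", 30, 500)
            row = q[q.mutation_id == "KRAS G12D"].iloc[0]
            est[depth] = (row.mutant_clusters, row.cluster_yield, row.est_copies)
        c_ratio = est[8000][0] / est[4000][0]
        y_ratio = est[8000][1] / est[4000][1]
        assert c_ratio == pytest.approx(2.0, rel=0.2)
        assert y_ratio == pytest.approx(2.0, rel=0.2)
        assert est[8000][2] == pytest.approx(est[4000][2], rel=0.15)
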