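"""Synapse filtering, fine-process geometry, distance profiles, and the
bootstrap-of-means comparison."""

import numpy as np
import pandas as pd
import pytest

from thirststate.errors import DataError
from thirststate.synthetic_data import AnatomySpec, SimConfig, Skeleton, gen_anatomy
from thirststate.vicinity import (
    bootstrap_mean_test,
    classify_tps,
    filter_synapses,
    fine_process_nodes,
    read_swc,
    transmitter_ratios,
    vicinity_profile,
    write_swc,
)


def _synapses(rows):
    return pd.DataFrame(
        rows, columns=["x", "y", "z", "cleft_score", "connection_score", "transmitter"]
    )


class TestFilterSynapses:
    def test_inclusive_thresholds(self):
        recs = _synapses(
            [
                [0, 0, 0, 50.0, 33.0, "glutamate"],  # exactly at thresholds: kept
                [0, 0, 0, 49.9, 100.0, "glutamate"],
                [0, 0, 0, 0.0, 100.0, "GABA"],
                [0, 0, 0, 100.0, 32.9, "GABA"],
                [0, 0, 0, 80.0, 60.0, "acetylcholine"],
            ]
        )
        kept = filter_synapses(recs)
        assert len(kept) == 2
        assert kept.iloc[0]["cleft_score"] == 50.0

    def test_missing_scores_rejected_with_warning(self):
        recs = _synapses([[0, 0, 0, np.nan, 60.0, "glutamate"],
                          [0, 0, 0, 80.0, 60.0, "glutamate"]])
        with pytest.warns(UserWarning, match="missing scores"):
            kept = filter_synapses(recs)
        assert len(kept) == 1

    def test_planted_pass_fraction_recovered(self):
        spec = AnatomySpec(score_fail_fraction=0.4)
        _, synapses, truth = gen_anatomy(SimConfig(seed=3, anatomy_spec=spec))
        kept = filter_synapses(synapses)
        assert len(kept) == truth.synapse_passes_scores.sum()


class TestFineProcessNodes:
    def _skeleton(self, radii):
        n = len(radii)
        return Skeleton(
            nodes=pd.DataFrame(
                {
                    "node_id": np.arange(1, n + 1),
                    "parent_id": [-1] + list(range(1, n)),
                    "x": np.zeros(n), "y": np.zeros(n), "z": np.zeros(n),
                    "radius": radii,
                }
            )
        )

    def test_strict_300nm_boundary(self):
        fine = fine_process_nodes(self._skeleton([299.0, 300.0, 301.0, 50.0]))
        assert fine["radius"].tolist() == [299.0, 50.0]

    def test_generator_radius_mix_exact_count(self):
        skel, _, _ = gen_anatomy(SimConfig(seed=5))
        fine = fine_process_nodes(skel)
        assert len(fine) == (skel.nodes["radius"] < 300.0).sum()

    def test_empty_result_warns(self):
        with pytest.warns(UserWarning):
            fine_process_nodes(self._skeleton([400.0, 500.0]))

    def test_bad_geometry_rejected(self):
        with pytest.raises(DataError):
            fine_process_nodes(self._skeleton([0.0, 100.0]))


class TestVicinityProfile:
    def _nodes(self, pos):
        pos = np.asarray(pos, float)
        return pd.DataFrame(
            {"node_id": np.arange(len(pos)), "parent_id": -1,
             "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2], "radius": 100.0}
        )

    def test_synapse_at_node_distance_zero(self):
        nodes = self._nodes([[0, 0, 0]])
        syn = _synapses([[0, 0, 0, 80, 60, "glutamate"]])
        prof = vicinity_profile(nodes, syn)
        assert prof.distances["glutamate"][0] == 0.0

    def test_matches_exhaustive_bruteforce(self):
        rng = np.random.default_rng(0)
        nodes = self._nodes(rng.uniform(-3000, 3000, (50, 3)))
        spos = rng.uniform(-4000, 4000, (200, 3))
        syn = pd.DataFrame(
            {"x": spos[:, 0], "y": spos[:, 1], "z": spos[:, 2],
             "cleft_score": 80.0, "connection_score": 60.0,
             "transmitter": "glutamate"}
        )
        prof = vicinity_profile(nodes, syn, half_width=1e9)
        npos = nodes[["x", "y", "z"]].to_numpy()
        brute = np.sqrt(
            ((spos[:, None, :] - npos[None, :, :]) ** 2).sum(-1)
        ).min(axis=1)
        assert np.allclose(np.sort(prof.distances["glutamate"]), np.sort(brute),
                           atol=1e-9)

    def test_box_mode_uses_chebyshev_gate(self):
        nodes = self._nodes([[0, 0, 0]])
        # corner point: inside the 2 um box but farther than 2 um euclidean
        syn = _synapses(
            [
                [1900, 1900, 1900, 80, 60, "glutamate"],
                [2100, 0, 0, 80, 60, "GABA"],  # outside the box
            ]
        )
        box = vicinity_profile(nodes, syn, mode="box")
        assert len(box.distances["glutamate"]) == 1
        assert "GABA" not in box.counts or box.counts["GABA"] == 0
        sphere = vicinity_profile(nodes, syn, mode="sphere")
        assert sphere.counts.get("glutamate", 0) == 0  # 3290 nm away

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        npos = rng.uniform(-2000, 2000, (30, 3))
        spos = rng.uniform(-2500, 2500, (80, 3))
        # a rotation about z plus a translation
        th = 0.7
        R = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        shift = np.array([500.0, -300.0, 800.0])

        def prof_for(n_, s_):
            syn = pd.DataFrame(
                {"x": s_[:, 0], "y": s_[:, 1], "z": s_[:, 2],
                 "cleft_score": 80.0, "connection_score": 60.0,
                 "transmitter": "glutamate"}
            )
            return vicinity_profile(self._nodes(n_), syn, mode="sphere")

        p1 = prof_for(npos, spos)
        p2 = prof_for(npos @ R.T + shift, spos @ R.T + shift)
        assert np.allclose(
            np.sort(p1.distances["glutamate"]), np.sort(p2.distances["glutamate"]),
            atol=1e-6,
        )

    def test_empty_inputs_rejected(self):
        with pytest.raises(DataError):
            vicinity_profile(self._nodes([[0, 0, 0]]).iloc[:0], _synapses([]))


class TestBootstrapMeanTest:
    def test_identical_vectors_not_significant(self):
        a = np.random.default_rng(0).normal(1000, 300, 200)
        res = bootstrap_mean_test(a, a.copy(), seed=1)
        assert res.p > 0.9

    def test_bootstrap_mean_consistency(self):
        rng = np.random.default_rng(2)
        a = rng.normal(1000, 300, 400)
        b = rng.normal(1000, 300, 400)
        res = bootstrap_mean_test(a, b, seed=3)
        sem = a.std(ddof=1) / np.sqrt(a.size)
        assert abs(res.boot_means_a.mean() - a.mean()) < 2 * sem

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 50), rng.normal(0, 1, 50)
        r1 = bootstrap_mean_test(a, b, seed=7)
        r2 = bootstrap_mean_test(a, b, seed=7)
        assert r1.p == r2.p
        assert np.array_equal(r1.boot_means_a, r2.boot_means_a)

    def test_degenerate_group_variance_floor(self):
        a = np.full(50, 100.0)
        b = np.full(50, 200.0)
        res = bootstrap_mean_test(a, b, seed=1)
        assert res.variance_floored
        assert res.p < 1e-6

    def test_group_size_minimum(self):
        with pytest.raises(DataError):
            bootstrap_mean_test(np.ones(5), np.ones(50))


class TestTps:
    def test_astrocyte_partner_flags_tps(self):
        recs = pd.DataFrame({"post_ids": ["n1;astro-1", "n2", "astro-2;n3"]})
        flags = classify_tps(recs, ["astro-1", "astro-2"])
        assert flags.tolist() == [True, False, True]

    def test_rerun_identical(self):
        recs = pd.DataFrame({"post_ids": ["n1;astro-1"] * 20 + ["n9"] * 30})
        f1 = classify_tps(recs, ["astro-1"])
        f2 = classify_tps(recs, ["astro-1"])
        assert np.array_equal(f1, f2)

    def test_planted_tps_fraction_exact(self):
        spec = AnatomySpec(tps_fraction=0.1)
        _, synapses, truth = gen_anatomy(SimConfig(seed=6, anatomy_spec=spec))
        flags = classify_tps(synapses, ["astro-1"])
        assert np.array_equal(flags, truth.tps_mask)


class TestTransmitterRatios:
    def test_single_transmitter(self):
        n = 40
        ratios = transmitter_ratios(
            np.ones(n, bool), np.ones(n, bool), np.array(["glutamate"] * n)
        )
        row = ratios.iloc[0]
        assert (row["fraction_tps"], row["fraction_vicinity"], row["enrichment"]) == (1, 1, 1)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(5)
        trans = rng.choice(["glutamate", "GABA", "acetylcholine"], 300)
        tps = rng.random(300) < 0.2
        ratios = transmitter_ratios(tps, np.ones(300, bool), trans)
        assert ratios["fraction_tps"].sum() == pytest.approx(1.0)
        assert ratios["fraction_vicinity"].sum() == pytest.approx(1.0)

    def test_planted_enrichment_recovered(self):
        rng = np.random.default_rng(6)
        n = 2000
        trans = np.where(rng.random(n) < 0.5, "glutamate", "acetylcholine")
        p_tps = np.where(trans == "glutamate", 0.2, 0.1)  # 2x enrichment in odds
        tps = rng.random(n) < p_tps
        ratios = transmitter_ratios(tps, np.ones(n, bool), trans).set_index("transmitter")
        rel = ratios.loc["glutamate", "enrichment"] / ratios.loc["acetylcholine", "enrichment"]
        assert rel == pytest.approx(2.0, rel=0.25)

    def test_empty_tps_rejected(self):
        with pytest.raises(DataError):
            transmitter_ratios(np.zeros(5, bool), np.ones(5, bool), np.array(["g"] * 5))


def test_swc_round_trip(tmp_path):
    skel, _, _ = gen_anatomy(SimConfig(seed=7))
    path = tmp_path / "astro.swc"
    write_swc(skel, path)
    back = read_swc(path, astrocyte_id=skel.astrocyte_id)
    pd.testing.assert_frame_equal(
        back.nodes.reset_index(drop=True),
        skel.nodes[["node_id", "parent_id", "x", "y", "z", "radius"]].reset_index(drop=True),
        check_dtype=False,
    )
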