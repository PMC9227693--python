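"""Generators: determinism, ground-truth bookkeeping, and planted structure."""

import numpy as np
import pandas as pd
import pytest

from metabarcode.library import filter_by_frequency, tally_votes, write_library
from metabarcode.network import assemble_network, load_edges
from metabarcode.synthetic import (
    LibraryPlan,
    NetworkPlan,
    SynergyPlan,
    default_library_plan,
    gen_combinations,
    gen_library,
    gen_network,
    gen_plate,
    make_pipeline_fixtures,
)
from metabarcode.synergy import rates_from_od
from metabarcode.votecount import build_barcode, compare_methods


def theta_plan(theta, k, n_metabolites=50, seed=0):
    rows = [
        {
            "metabolite_id": f"m{i}",
            "sample_type": "blood",
            "true_direction": 1,
            "theta": theta,
            "k": k,
        }
        for i in range(n_metabolites)
    ]
    studies = pd.DataFrame(
        {
            "study_id": [f"B{i}" for i in range(k)],
            "sample_type": "blood",
            "platform": "GC-MS",
            "n_case": 10,
            "n_control": 10,
        }
    )
    return LibraryPlan(metabolites=pd.DataFrame(rows), studies=studies, seed=seed)


class TestLibraryGenerator:
    def test_pure_function_of_seed(self, tmp_path):
        a, _ = gen_library(default_library_plan(seed=5))
        b, _ = gen_library(default_library_plan(seed=5))
        pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_library(a, pa)
        write_library(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_degenerate_theta_all_concordant(self):
        records, truth = gen_library(theta_plan(theta=0.999999, k=8))
        votes = tally_votes(records, "blood")
        assert all(v.n_up == 8 and v.n_down == 0 for v in votes)

    def test_fair_coin_theta_binomial_rate(self):
        records, truth = gen_library(theta_plan(theta=0.5, k=10, n_metabolites=1000))
        assert truth["n_up"].mean() / 10 == pytest.approx(0.5, abs=0.02)

    def test_frequency_equals_planned_study_count(self):
        plan = default_library_plan(seed=2)
        records, _ = gen_library(plan)
        for st in ("blood", "tissue"):
            votes = {v.metabolite_id: v for v in tally_votes(records, st)}
            planned = plan.metabolites[plan.metabolites["sample_type"] == st]
            for row in planned.itertuples(index=False):
                assert votes[row.metabolite_id].frequency == row.k

    def test_corpus_scale_counts(self):
        """The default plan reproduces the corpus structure end to end:
        330 metabolites, 254 frequent overall, 50/43 frequent per sample
        type, tissue barcode 28 up + 6 down, blood 15 up + 12 down."""
        records, _ = gen_library(default_library_plan(seed=1))
        pooled = tally_votes(records, None)
        assert len(pooled) == 330
        assert len(filter_by_frequency(pooled, 3)) == 254
        expected = {"blood": (50, 15, 12), "tissue": (43, 28, 6)}
        for st, (n_freq, n_up, n_down) in expected.items():
            kept = filter_by_frequency(tally_votes(records, st), 3)
            assert len(kept) == n_freq
            barcode = build_barcode(kept)
            assert sum(1 for e in barcode if e.direction > 0) == n_up
            assert sum(1 for e in barcode if e.direction < 0) == n_down
            comparison = compare_methods(kept)
            assert comparison.attrs["n_detected_bayes"] == n_up + n_down


class TestNetworkGenerator:
    def test_files_round_trip_to_planted_counts(self, tmp_path, small_network):
        gen = gen_network(NetworkPlan(seed=7), out_dir=tmp_path)
        met_prot = load_edges(tmp_path / "stitch_edges.tsv")
        prot_prot = load_edges(tmp_path / "string_edges.tsv")
        net = assemble_network(gen.metabolite_ids, met_prot, prot_prot)
        assert net.N == gen.planted_nodes == small_network.planted_nodes
        assert net.n_edges == gen.planted_edges
        assert net.node_ids == gen.net.node_ids

    def test_fixed_seed_byte_identical_files(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        gen_network(NetworkPlan(seed=4), out_dir=d1)
        gen_network(NetworkPlan(seed=4), out_dir=d2)
        for name in ("stitch_edges.tsv", "string_edges.tsv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_cleanup_leaves_no_isolates(self, small_network):
        assert (small_network.net.A.sum(axis=1) > 0).all()


class TestCombinationGenerator:
    def test_noise_free_labels_linearly_separable(self, small_network):
        from sklearn.linear_model import LogisticRegression

        combo = gen_combinations(
            SynergyPlan(n_combinations=200, label_noise=0.0, seed=1),
            small_network.net,
        )
        X = combo.features.to_numpy()
        y = combo.truth["observed_label"].to_numpy()
        acc = LogisticRegression(max_iter=5000, C=100).fit(X, y).score(X, y)
        assert acc > 0.97

    def test_flip_bookkeeping_consistent(self, small_network):
        combo = gen_combinations(SynergyPlan(n_combinations=100, seed=2), small_network.net)
        t = combo.truth
        assert (
            (t["observed_label"] != t["true_label"]) == t["flipped"]
        ).all()
        assert t["flipped"].mean() == pytest.approx(0.1, abs=0.08)

    def test_matrix_shape_matches_plan(self, small_network):
        combo = gen_combinations(SynergyPlan(n_combinations=120, seed=3), small_network.net)
        assert combo.features.shape == (120, small_network.net.N)
        assert np.allclose(combo.features.sum(axis=1), 1.0, atol=1e-9)

    def test_extreme_noise_rejected(self):
        with pytest.raises(ValueError, match="noise"):
            SynergyPlan(label_noise=0.5)


class TestPlateGenerator:
    def test_noiseless_recovery_exact(self):
        plate = gen_plate(
            {"drug_a": 0.6, "drug_b": 0.7, "combination": 0.3}, noise_sd=0.0, seed=0
        )
        rates = rates_from_od(plate)
        assert rates.loc["drug_a", "survival_rate"] == pytest.approx(0.6, abs=1e-12)
        assert rates.loc["combination", "survival_rate"] == pytest.approx(0.3, abs=1e-12)

    def test_bliss_null_mode_sets_product_rate(self):
        plate = gen_plate({"drug_a": 0.6, "drug_b": 0.7}, bliss_null=True, noise_sd=0.0)
        rates = rates_from_od(plate)
        assert rates.loc["combination", "survival_rate"] == pytest.approx(0.42)

    def test_planted_multiplier_pushes_q_above_one(self):
        from metabarcode.synergy import evaluate_plate

        qs = [
            evaluate_plate(
                gen_plate(
                    {"drug_a": 0.6, "drug_b": 0.7, "combination": 0.42 * 0.7},
                    noise_sd=0.05,
                    seed=s,
                )
            ).q
            for s in range(30)
        ]
        assert np.mean(qs) > 1.0

    def test_deterministic(self):
        p1 = gen_plate({"drug_a": 0.5, "drug_b": 0.5}, bliss_null=True, seed=8)
        p2 = gen_plate({"drug_a": 0.5, "drug_b": 0.5}, bliss_null=True, seed=8)
        pd.testing.assert_frame_equal(p1, p2)


def test_fixture_set_is_mutually_consistent(pipeline_fixture_dir):
    paths = pipeline_fixture_dir
    met_prot = load_edges(paths["stitch_edges"])
    prot_prot = load_edges(paths["string_edges"])
    targets = pd.read_csv(paths["drug_targets"], sep="\t")
    combos = pd.read_csv(paths["combos"], sep="\t")
    nodes = {e.node_a for e in met_prot + prot_prot} | {
        e.node_b for e in met_prot + prot_prot
    }
    assert set(targets["target_id"]).issubset(nodes)
    assert set(combos["drug_a"]) | set(combos["drug_b"]) <= set(targets["drug_id"])
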