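"""Benchmark generator: trees, gene content, sequences, reproducibility."""

import collections

import numpy as np
import pytest

from bacascan.classify import FinalCall
from bacascan.io_formats import BACKGROUND
from bacascan.synthetic_data import (
    FamilySpec,
    SimConfig,
    TruthRecord,
    TruthTable,
    _node_depths,
    assign_taxonomy,
    emit_family_sequences,
    family_consensus_profiles,
    generate_benchmark,
    make_decoys,
    pick_family_anchors,
    score_recovery,
    simulate_gene_content,
    simulate_species_tree,
)


class TestSpeciesTree:
    def test_deterministic_newick(self):
        a = simulate_species_tree(10, 1.0, 0.0, 5).as_string(schema="newick")
        b = simulate_species_tree(10, 1.0, 0.0, 5).as_string(schema="newick")
        assert a == b

    def test_tip_count(self):
        t = simulate_species_tree(3, 1.0, 0.0, 1)
        assert sum(1 for _ in t.leaf_node_iter()) == 3

    def test_yule_depth_matches_closed_form(self):
        # birth-only expectation for root (2 lineages) to the n-th tip:
        # E[depth] = sum_{k=2}^{n-1} 1 / (k * birth)
        n, birth = 8, 1.0
        expected = sum(1.0 / (k * birth) for k in range(2, n))
        depths = []
        for s in range(200):
            t = simulate_species_tree(n, birth, 0.0, s)
            d = _node_depths(t)
            depths.append(max(d[lf] for lf in t.leaf_node_iter()))
        assert np.mean(depths) == pytest.approx(expected, rel=0.10)

    def test_taxonomy_is_nested(self):
        t = simulate_species_tree(30, 1.0, 0.0, 2)
        meta = assign_taxonomy(t)
        by_class = collections.defaultdict(set)
        by_order = collections.defaultdict(set)
        for m in meta:
            by_class[m.class_].add(m.phylum)
            by_order[m.order].add(m.class_)
        assert all(len(v) == 1 for v in by_class.values())
        assert all(len(v) == 1 for v in by_order.values())

    def test_anchors_disjoint(self):
        t = simulate_species_tree(60, 1.0, 0.0, 3)
        anchors = pick_family_anchors(t, 5)
        assert len(anchors) == 5
        seen = set()
        for a in anchors:
            assert not (a & seen)
            seen |= a


class TestGeneContent:
    def test_conserved_without_loss(self):
        t = simulate_species_tree(12, 1.0, 0.0, 7)
        fam = FamilySpec("BclA", gain_rate=0.0, loss_rate=0.0, hgt_rate=0.0, root_present=True)
        presence, events = simulate_gene_content(t, [fam], 1)
        assert all(presence[(f"S{i:04d}", "BclA")] for i in range(1, 13))

    def test_absent_without_gain(self):
        t = simulate_species_tree(12, 1.0, 0.0, 7)
        fam = FamilySpec("BclA", gain_rate=0.0, loss_rate=0.5, hgt_rate=0.0, root_present=False)
        presence, _ = simulate_gene_content(t, [fam], 1)
        assert not any(presence.values())

    def test_loss_matches_exponential_survival(self):
        # root present, no gain/HGT: P(tip present) = exp(-loss * depth)
        t = simulate_species_tree(10, 1.0, 0.0, 11)
        depths = _node_depths(t)
        tips = {lf.taxon.label: depths[lf] for lf in t.leaf_node_iter()}
        loss = 0.4
        fam = FamilySpec("BclA", 0.0, loss, 0.0, root_present=True)
        counts = collections.Counter()
        reps = 150
        for s in range(reps):
            presence, _ = simulate_gene_content(t, [fam], s)
            for tip in tips:
                counts[tip] += presence[(tip, "BclA")]
        for tip, depth in tips.items():
            p_expected = np.exp(-loss * depth)
            se = max(np.sqrt(p_expected * (1 - p_expected) / reps), 1e-3)
            assert abs(counts[tip] / reps - p_expected) < 4 * se + 0.02

    def test_planted_anchor_gain(self):
        t = simulate_species_tree(20, 1.0, 0.0, 13)
        anchors = pick_family_anchors(t, 2)
        fam = FamilySpec("BacA", 0.0, 0.0, 0.0, root_present=False, anchor_tips=anchors[0])
        presence, events = simulate_gene_content(t, [fam], 3)
        present_tips = {sp for (sp, _), v in presence.items() if v}
        assert present_tips == set(anchors[0])
        assert any(ev == "planted_gain" for _, ev, _ in events["BacA"])


class TestSequences:
    def test_zero_divergence_identical_members(self):
        profiles = family_consensus_profiles(100, 5)
        presence = {("s1", "BclA"): True, ("s2", "BclA"): True}
        recs, truth = emit_family_sequences(presence, profiles, 0.0, 9)
        assert recs[0].sequence == recs[1].sequence
        assert truth.family_of(recs[0].protein_id) == "BclA"

    def test_pairwise_identity_bound(self):
        # expected identity between two members >= (1 - divergence)^2
        profiles = family_consensus_profiles(400, 6)
        presence = {(f"s{i}", "BacA"): True for i in range(15)}
        recs, _ = emit_family_sequences(presence, profiles, 0.3, 10)
        idents = []
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                a, b = recs[i].sequence, recs[j].sequence
                idents.append(sum(x == y for x, y in zip(a, b)) / len(a))
        assert np.mean(idents) >= (1 - 0.3) ** 2

    def test_unrelated_profiles_never_share_ssn_edges(self):
        # two families built from unrelated random profiles: zero
        # inter-family edges at the study threshold
        from bacascan.pairwise_ssn import ScoringScheme, all_vs_all, build_network
        from bacascan.synthetic_data import FamilyProfile

        rng = np.random.default_rng(12)
        profiles = {
            name: FamilyProfile(name, rng.choice(20, size=400, p=BACKGROUND))
            for name in ("BacA", "BclA")
        }
        presence = {(f"s{i}", f): True for i in range(6) for f in ("BacA", "BclA")}
        recs, _ = emit_family_sequences(presence, profiles, 0.2, 13)
        pairs = all_vs_all(recs, ScoringScheme())
        ssn = build_network(pairs, 115.0, nodes=[r.protein_id for r in recs])
        for e in ssn.edges:
            assert e.id1.split("_")[0] == e.id2.split("_")[0]

    def test_decoys_deterministic_and_sized(self):
        a = make_decoys(5, 200, seed=3)
        b = make_decoys(5, 200, seed=3)
        assert [r.sequence for r in a] == [r.sequence for r in b]
        assert make_decoys(0, 200) == []

    def test_decoy_false_positive_rate(self):
        # fraction of decoys reaching E <= 1e-5 against a family model
        # stays at or below 1e-3
        from bacascan.io_formats import SeedAlignment
        from bacascan.profile_hmm import build_profile, calibrate, e_value, score_forward

        rng = np.random.default_rng(21)
        row = "".join("ACDEFGHIKLMNPQRSTVWY"[j] for j in rng.integers(0, 20, 180))
        hmm = build_profile(SeedAlignment([f"r{i}" for i in range(8)], [row] * 8))
        g = calibrate(hmm, n_random=200, mean_len=180, seed=22)
        decoys = make_decoys(1000, 180, seed=23)
        n_hits = sum(
            1
            for d in decoys
            if e_value(g, score_forward(hmm, d.sequence), 1000, len(d.sequence), 180) <= 1e-5
        )
        assert n_hits / 1000 <= 1e-3


class TestBenchmark:
    def test_reproducible_byte_identical(self, tmp_path):
        cfg = SimConfig(n_species=12, n_decoys_per_species=2, protein_length=120, seed=4)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_benchmark(cfg, out_dir=d1)
        generate_benchmark(cfg, out_dir=d2)
        files1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        files2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
        assert files1 == files2
        for rel in files1:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes()

    def test_truth_matches_fasta_universe(self):
        cfg = SimConfig(n_species=12, n_decoys_per_species=2, protein_length=120, seed=5)
        bench = generate_benchmark(cfg)
        assert set(bench.truth.records) == {p.protein_id for p in bench.proteins}
        assert len(bench.proteins) == len({p.protein_id for p in bench.proteins})

    def test_seed_alignments_shapes(self):
        cfg = SimConfig(n_species=12, n_decoys_per_species=1, protein_length=100, seed=6)
        bench = generate_benchmark(cfg)
        assert bench.mining_seed.n_rows == 10  # two rows per family
        for fam, seed in bench.family_seeds.items():
            assert seed.n_rows == cfg.n_seed_rows
            assert seed.width == 100


class TestRecovery:
    def _truth(self):
        return TruthTable(
            {
                "b1": TruthRecord("BacA", "s1"),
                "c1": TruthRecord("BclA", "s1"),
                "m1": TruthRecord("MBacA", "s2"),
                "e1": TruthRecord("ExsE", "s2"),
                "d1": TruthRecord("decoy", "s2"),
            }
        )

    def test_perfect_predictions(self):
        finals = [
            FinalCall("b1", "BacA", "none", "R3"),
            FinalCall("c1", "BclA", "none", "R4"),
            FinalCall("m1", "BclA", "none", "R4"),
            FinalCall("e1", "excluded", "clade_A_outgroup", "R1"),
        ]
        sc = score_recovery(finals, self._truth())
        assert sc.macro_f1 == 1.0

    def test_all_excluded_zero_recall(self):
        finals = [FinalCall(p, "excluded", "small_or_singleton", "R6") for p in ("b1", "c1", "m1")]
        sc = score_recovery(finals, self._truth())
        assert sc.per_class["BacA"][1] == 0.0
        assert sc.per_class["BclA"][1] == 0.0

    def test_unknown_protein_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            score_recovery([FinalCall("nope", "BacA", "none", "R3")], self._truth())

    def test_component_purity(self):
        finals = []
        comp_of = {"b1": 0, "c1": 0, "m1": 1, "e1": 1, "d1": 2}
        sc = score_recovery(finals, self._truth(), comp_of)
        # comp0 pure-est family 1/2, comp1 1/2, comp2 1/1 -> (1+1+1)/5
        assert sc.component_purity == pytest.approx(3 / 5)

    def test_presence_absence_identity_under_perfect_calls(self):
        # final calls derived directly from truth reproduce the generated
        # presence/absence matrix exactly
        from bacascan.distribution import presence_absence
        from bacascan.synthetic_data import TRUTH_TO_FINAL

        cfg = SimConfig(n_species=12, n_decoys_per_species=1, protein_length=100, seed=8)
        bench = generate_benchmark(cfg)
        finals = []
        for pid, tr in bench.truth.records.items():
            lab = TRUTH_TO_FINAL[tr.true_family]
            finals.append(
                FinalCall(pid, lab, "none" if lab != "excluded" else "small_or_singleton", "R3")
            )
        pa = presence_absence(finals, bench.proteins, bench.species_table)
        for sp in bench.species_table:
            sid = sp.species_id
            want_bacA = bench.truth.records.get(f"BacA_{sid}") is not None
            want_bclA = any(
                bench.truth.records.get(f"{f}_{sid}") is not None for f in ("BclA", "MBacA")
            )
            assert pa.has_bacA(sid) == want_bacA
            assert pa.has_bclA(sid) == want_bclA
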