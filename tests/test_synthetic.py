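import numpy as np
import pytest

from upna_ppi import (ComplementarityModel, GenerationError, count_four_cycles,
                      degree_preserved_swap, generate_embedding_table,
                      generate_network, generate_sequences, make_fixture,
                      trigrams, write_fixture)
from upna_ppi.synthetic import reserved_letters


class TestGenerateNetwork:
    def test_deterministic_given_seed(self):
        g1, t1 = generate_network(ComplementarityModel(seed=9))
        g2, t2 = generate_network(ComplementarityModel(seed=9))
        assert set(g1.edges) == set(g2.edges)
        assert np.array_equal(t1.keys, t2.keys)

    def test_full_density_connects_compatible_pairs(self):
        model = ComplementarityModel(n_proteins=40, density=1.0, noise=0.0, seed=1)
        g, truth = generate_network(model)
        assert set(g.edges) == set(truth.positives)

    def test_edges_respect_rule_at_zero_noise(self, fixture0):
        truth = fixture0.truth
        for a, b in list(fixture0.graph.edges)[:100]:
            assert truth.is_compatible(a, b)

    def test_positives_negatives_partition(self, fixture0):
        truth = fixture0.truth
        n = len(truth.node_ids)
        assert not set(truth.positives) & set(truth.hard_negatives)
        assert len(truth.positives) + len(truth.hard_negatives) == n * (n - 1) // 2

    def test_degenerate_parameters_raise(self):
        # with two proteins there is a single pair: one of the compatible /
        # incompatible sets is necessarily empty
        with pytest.raises(GenerationError):
            generate_network(ComplementarityModel(n_proteins=2, seed=0))

    def test_four_cycle_enrichment_vs_degree_matched_rewiring(self):
        """Complementarity-driven networks are 4-cycle rich; rewiring destroys it.

        The strict key/lock (exact complement) limit is strongly bipartite-like
        and loses most of its 4-cycles under degree-preserved randomization;
        the partial-matching default keeps a milder but still positive excess
        (its compatibility correlates with degree, which swaps preserve).
        """
        def median_ratio(rule, n_seeds):
            ratios = []
            for seed in range(n_seeds):
                model = ComplementarityModel(n_proteins=120, rule=rule, seed=seed)
                g, _ = generate_network(model)
                c_orig = count_four_cycles(g)
                swapped, _rej = degree_preserved_swap(g, 5 * g.n_edges,
                                                      seed=seed + 1)
                ratios.append(c_orig / max(count_four_cycles(swapped), 1))
            return float(np.median(ratios))

        assert median_ratio("exact_complement", 8) > 1.5
        assert median_ratio("dot_threshold", 9) > 1.0


class TestGenerateSequences:
    def test_motif_written_at_recorded_position(self, fixture0):
        truth = fixture0.truth
        for pid in list(truth.node_ids)[:20]:
            s = fixture0.sequences[pid].residues
            start = truth.motif_start[pid]
            assert s[start - 1:start - 1 + truth.motif_length] == truth.motif[pid]

    def test_reserved_letters_only_in_motifs(self, fixture0):
        reserved = set(reserved_letters(4))
        truth = fixture0.truth
        for pid in list(truth.node_ids)[:20]:
            s = fixture0.sequences[pid].residues
            start0 = truth.motif_start[pid] - 1
            outside = s[:start0] + s[start0 + truth.motif_length:]
            assert not set(outside) & reserved

    def test_identical_keys_give_identical_key_slots(self):
        g, truth = generate_network(ComplementarityModel(n_proteins=40, seed=3))
        generate_sequences(truth, length=60)
        ids = truth.node_ids
        j = next(k for k in range(1, 40)
                 if np.array_equal(truth.keys[k], truth.keys[0]))
        mi, mj = truth.motif[ids[0]], truth.motif[ids[j]]
        # the four key slots (every 3rd residue) agree; spacers may differ
        assert mi[::3][:4] == mj[::3][:4]

    def test_trigram_multiset_contains_motif_trigrams(self, fixture0):
        truth = fixture0.truth
        pid = truth.node_ids[0]
        seq = fixture0.sequences[pid]
        motif = truth.motif[pid]
        seq_trigrams = {t for _pos, t in trigrams(seq)}
        for k in range(len(motif) - 2):
            assert motif[k:k + 3] in seq_trigrams

    def test_length_too_small_rejected(self):
        _g, truth = generate_network(ComplementarityModel(n_proteins=20, seed=0))
        with pytest.raises(ValueError):
            generate_sequences(truth, length=20)


class TestGenerateEmbeddingTable:
    def test_complete_over_alphabet(self):
        t = generate_embedding_table("ACDE", dim=4, seed=0)
        assert len(t.vectors) == 4 ** 3

    def test_full_alphabet_has_8000_entries(self, fixture0):
        assert len(fixture0.table.vectors) == 8000

    def test_oov_is_recomputable_mean(self):
        t = generate_embedding_table("ACD", dim=3, seed=1)
        mean = np.mean(np.stack(list(t.vectors.values())), axis=0)
        np.testing.assert_allclose(t.oov, mean, atol=1e-12)

    def test_deterministic(self):
        t1 = generate_embedding_table("ACD", dim=3, seed=5)
        t2 = generate_embedding_table("ACD", dim=3, seed=5)
        for tok in t1.vectors:
            np.testing.assert_array_equal(t1.vectors[tok], t2.vectors[tok])

    def test_compositional_structure(self):
        # shared letters pull trigram vectors together
        t = generate_embedding_table("ACDE", dim=8, seed=2, residual_scale=0.05)
        d_shared = np.linalg.norm(t.vectors["AAC"] - t.vectors["AAD"])
        rng = np.random.default_rng(0)
        toks = sorted(t.vectors)
        d_rand = np.mean([np.linalg.norm(t.vectors[toks[i]] - t.vectors[toks[j]])
                          for i, j in rng.integers(0, len(toks), size=(50, 2))])
        assert d_shared < d_rand


def test_write_fixture_round_trips(tmp_path, fixture0):
    from upna_ppi import load_edge_list, read_embedding_table, read_fasta

    write_fixture(fixture0, tmp_path)
    g = load_edge_list(tmp_path / "edges.tsv")
    assert set(g.edges) == set(fixture0.graph.edges)
    seqs = read_fasta(tmp_path / "sequences.fasta")
    assert len(seqs) == len(fixture0.sequences)
    table = read_embedding_table(tmp_path / "embeddings.txt")
    assert table.dim == fixture0.table.dim
    import json

    truth = json.loads((tmp_path / "truth.json").read_text())
    assert truth["motif_start"] == fixture0.truth.motif_start
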