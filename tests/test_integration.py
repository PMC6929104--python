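"""Connection networks, gene gating, network summaries, tri-omics triplets."""

import itertools

import numpy as np
import pytest

from mirconcord import (
    GeneKey,
    MetaboliteRecord,
    TargetInteraction,
    find_consistent_connections,
    find_triomics_triplets,
    gate_consistent_genes,
    gate_consistent_mirnas,
    parse_mirna_name,
    summarize_network,
)
from conftest import gene_record, mir_record
from oracles import oracle_connections, oracle_triplets


def edge(mirna, gene, evidence="reporter"):
    return TargetInteraction(
        mirna=parse_mirna_name(mirna), gene=GeneKey(gene, "human"), evidence=evidence
    )


class TestFindConsistentConnections:
    def test_anti_correlated_pair_connects(self):
        """A down-regulated miRNA with an up-regulated validated target."""
        conns = find_consistent_connections(
            [mir_record("hsa-miR-218-5p", -1.4)],
            [gene_record("ODC1", 2.1)],
            [edge("hsa-miR-218-5p", "ODC1")],
        )
        (c,) = conns
        assert c.mirna_direction == "down" and c.gene_direction == "up"

    def test_same_direction_rejected(self):
        conns = find_consistent_connections(
            [mir_record("hsa-miR-218-5p", 1.4)],
            [gene_record("ODC1", 2.1)],
            [edge("hsa-miR-218-5p", "ODC1")],
        )
        assert conns == []

    def test_absent_endpoint_rejected(self):
        conns = find_consistent_connections(
            [mir_record("hsa-miR-218-5p", -1.4)],
            [gene_record("GLI2", 2.1)],
            [edge("hsa-miR-218-5p", "ODC1")],
        )
        assert conns == []

    def test_matches_brute_force_on_random_instances(self):
        """Exact set equality with a double-loop oracle (larger sweep in the
        acceptance suite)."""
        rng = np.random.default_rng(23)
        for _ in range(10):
            n_mir, n_gene = 20, 40
            mirs = [f"hsa-miR-{100 + i}-3p" for i in range(n_mir)]
            genes = [f"G{i:03d}" for i in range(n_gene)]
            mir_de = [
                mir_record(m, float(rng.normal(0, 2)))
                for m in mirs
                if rng.random() < 0.7
            ]
            gene_de = [
                gene_record(g, float(rng.normal(0, 2)))
                for g in genes
                if rng.random() < 0.7
            ]
            edges = [
                edge(m, g) for m in mirs for g in genes if rng.random() < 0.08
            ]
            got = {
                (c.mirna.mature_key, c.gene.match_key)
                for c in find_consistent_connections(mir_de, gene_de, edges)
            }
            want = oracle_connections(
                {r.feature.mature_key: r.log2fc for r in mir_de},
                {r.feature.match_key: r.log2fc for r in gene_de},
                [(e.mirna.mature_key, e.gene.match_key) for e in edges],
            )
            assert got == want

    def test_monotone_in_significance(self):
        """Shrinking either significant set never adds connections."""
        rng = np.random.default_rng(29)
        mir_de = [mir_record(f"hsa-miR-{i}-5p", float(rng.normal(0, 2))) for i in range(15)]
        gene_de = [gene_record(f"G{i}", float(rng.normal(0, 2))) for i in range(30)]
        edges = [
            edge(f"hsa-miR-{i}-5p", f"G{j}")
            for i in range(15)
            for j in range(30)
            if rng.random() < 0.1
        ]
        full = find_consistent_connections(mir_de, gene_de, edges)
        sub = find_consistent_connections(mir_de[:8], gene_de[:15], edges)
        as_keys = lambda conns: {(c.mirna.mature_key, c.gene.match_key) for c in conns}
        assert as_keys(sub) <= as_keys(full)

    def test_deterministic_sorted_output(self):
        mir_de = [mir_record("hsa-miR-2-3p", -1), mir_record("hsa-miR-1-3p", -1)]
        gene_de = [gene_record("B", 1), gene_record("A", 1)]
        edges = [
            edge("hsa-miR-2-3p", "B"), edge("hsa-miR-1-3p", "B"),
            edge("hsa-miR-2-3p", "A"), edge("hsa-miR-1-3p", "A"),
        ]
        conns = find_consistent_connections(mir_de, gene_de, edges)
        labels = [(str(c.mirna), str(c.gene)) for c in conns]
        assert labels == sorted(labels)

    def test_permutation_null_connection_rate(self):
        """Shuffling target labels in a sign-balanced instance keeps the
        expected connection count at about half the eligible edges."""
        rng = np.random.default_rng(31)
        n = 30
        mir_de = [
            mir_record(f"hsa-miR-{i}-3p", 2.0 if i % 2 else -2.0) for i in range(n)
        ]
        gene_de = [gene_record(f"G{j}", 2.0 if j % 2 else -2.0) for j in range(n)]
        genes = [f"G{j}" for j in range(n)]
        counts = []
        for _ in range(200):
            perm = rng.permutation(n)
            edges = [edge(f"hsa-miR-{i}-3p", genes[perm[i]]) for i in range(n)]
            counts.append(len(find_consistent_connections(mir_de, gene_de, edges)))
        mean = np.mean(counts)
        # each edge is anti-correlated w.p. 1/2; MC error ~ sqrt(n/4)/sqrt(200)
        assert abs(mean - n / 2) < 4 * np.sqrt(n / 4) / np.sqrt(200) + 0.5


class TestGateConsistentGenes:
    def test_concordant_significant_gene_kept(self):
        kept = gate_consistent_genes(
            {
                "A": [gene_record("ODC1", 2.0, 0.01, "A")],
                "B": [gene_record("ODC1", 1.8, 0.02, "B")],
            }
        )
        (rec,) = kept
        assert rec.feature.symbol == "ODC1"
        assert rec.log2fc == pytest.approx(1.9)
        assert rec.padj == 0.02

    def test_discordant_gene_dropped(self):
        kept = gate_consistent_genes(
            {
                "A": [gene_record("GLI2", 2.0, 0.01, "A")],
                "B": [gene_record("GLI2", -2.0, 0.01, "B")],
            }
        )
        assert kept == []

    def test_not_significant_everywhere_dropped(self):
        kept = gate_consistent_genes(
            {
                "A": [gene_record("GLI2", 2.0, 0.01, "A")],
                "B": [gene_record("GLI2", 2.0, 0.50, "B")],
            }
        )
        assert kept == []

    def test_single_study_passthrough_warns(self):
        with pytest.warns(UserWarning, match="single study"):
            kept = gate_consistent_genes({"A": [gene_record("ODC1", 2.0, 0.01, "A")]})
        assert len(kept) == 1

    def test_planted_concordant_count_recovered(self):
        rng = np.random.default_rng(37)
        concordant = [f"C{i}" for i in range(12)]
        noise = [f"N{i}" for i in range(20)]
        tables = {"A": [], "B": []}
        for g in concordant:
            s = 1 if rng.random() < 0.5 else -1
            for st in tables:
                tables[st].append(gene_record(g, s * 2.0, 0.001, st))
        for g in noise:  # significant in only one study
            tables["A"].append(gene_record(g, 2.0, 0.001, "A"))
            tables["B"].append(gene_record(g, 2.0, 0.9, "B"))
        kept = gate_consistent_genes(tables)
        assert {r.feature.symbol for r in kept} == set(concordant)


class TestGateConsistentMirnas:
    def test_mature_key_join_across_comparisons(self):
        tables = {
            "H1": [mir_record("hsa-miR-143-3p", 4.1, 2.9e-3, "H1")],
            "H2": [mir_record("hsa-miR-143-3p", 7.5, 1.2e-7, "H2")],
        }
        (rec,) = gate_consistent_mirnas(tables)
        assert rec.feature.mature_key == "mir-143-3p"
        assert rec.log2fc == pytest.approx(5.8)

    def test_sign_disagreement_dropped(self):
        tables = {
            "H1": [mir_record("hsa-miR-143-3p", 4.1, 1e-3, "H1")],
            "H2": [mir_record("hsa-miR-143-3p", -7.5, 1e-7, "H2")],
        }
        assert gate_consistent_mirnas(tables) == []


class TestSummarizeNetwork:
    def test_empty_network(self):
        s = summarize_network([])
        assert (s.n_connections, s.n_mirnas, s.n_targets) == (0, 0, 0)
        assert s.n_targets_up == s.n_targets_down == 0

    def test_multi_targeting_counts_edges_not_genes(self):
        mir_de = [mir_record(f"hsa-miR-{i}-3p", -1.0) for i in range(3)]
        gene_de = [gene_record("CPT1A", 2.0)]
        edges = [edge(f"hsa-miR-{i}-3p", "CPT1A") for i in range(3)]
        s = summarize_network(find_consistent_connections(mir_de, gene_de, edges))
        assert (s.n_connections, s.n_mirnas, s.n_targets) == (3, 3, 1)
        assert (s.n_targets_up, s.n_targets_down) == (1, 0)

    def test_split_adds_up(self):
        rng = np.random.default_rng(41)
        mir_de = [mir_record(f"hsa-miR-{i}-3p", float(rng.normal(0, 2))) for i in range(10)]
        gene_de = [gene_record(f"G{j}", float(rng.normal(0, 2))) for j in range(20)]
        edges = [
            edge(f"hsa-miR-{i}-3p", f"G{j}")
            for i in range(10) for j in range(20) if rng.random() < 0.2
        ]
        s = summarize_network(find_consistent_connections(mir_de, gene_de, edges))
        assert s.n_targets_up + s.n_targets_down == s.n_targets


def met(name, lfc, padj=0.01):
    return MetaboliteRecord(metabolite=name, log2fc=lfc, padj=padj)


class TestTriOmicsTriplets:
    def _setup(self):
        gene_de = [gene_record("SLC1A2", 3.55)]  # higher in the second state
        conns = find_consistent_connections(
            [mir_record("hsa-miR-199b-3p", -2.5)],
            gene_de,
            [edge("hsa-miR-199b-3p", "SLC1A2")],
        )
        return gene_de, conns

    def test_full_triplet_emitted(self):
        gene_de, conns = self._setup()
        trips = find_triomics_triplets(
            gene_de, conns, [met("glutamate", 0.95)], [("SLC1A2", "glutamate", "transported")]
        )
        (t,) = trips
        assert t.gene.symbol == "SLC1A2"
        assert t.opposing_mirnas == frozenset({"mir-199b-3p"})
        assert t.linked_metabolites == (("glutamate", "up", True),)

    def test_metabolite_direction_annotated_not_filtered(self):
        gene_de, conns = self._setup()
        trips = find_triomics_triplets(
            gene_de, conns, [met("glutamate", -0.95)], [("SLC1A2", "glutamate", "transported")]
        )
        assert trips[0].linked_metabolites == (("glutamate", "down", False),)

    def test_insignificant_metabolite_blocks_triplet(self):
        gene_de, conns = self._setup()
        trips = find_triomics_triplets(
            gene_de, conns, [met("glutamate", 0.95, padj=0.5)],
            [("SLC1A2", "glutamate", "transported")],
        )
        assert trips == []

    def test_missing_map_warns_and_returns_empty(self):
        gene_de, conns = self._setup()
        with pytest.warns(UserWarning, match="no metabolite layer"):
            assert find_triomics_triplets(gene_de, conns, [met("glutamate", 1.0)], None) == []

    def test_matches_enumeration_oracle_on_small_instances(self):
        """All 2^9 significance patterns of a 4-gene/3-miRNA/3-metabolite
        instance agree with the literal three-criteria oracle."""
        genes = ["G0", "G1", "G2", "G3"]
        mirs = ["hsa-miR-1-3p", "hsa-miR-2-3p", "hsa-miR-3-3p"]
        mets = ["m0", "m1", "m2"]
        edges = [
            edge("hsa-miR-1-3p", "G0"), edge("hsa-miR-2-3p", "G1"),
            edge("hsa-miR-3-3p", "G2"), edge("hsa-miR-1-3p", "G3"),
        ]
        adjacency = [("G0", "m0", "substrate"), ("G1", "m1", "product"), ("G3", "m2", "substrate")]
        signs = {"G0": 1, "G1": -1, "G2": 1, "G3": -1}
        mir_signs = {"mir-1-3p": -1, "mir-2-3p": 1, "mir-3-3p": 1}
        for pattern in itertools.product([0, 1], repeat=9):
            gene_sig = {g for g, b in zip(genes, pattern[:4]) if b}
            mir_sig = dict(zip(mirs, pattern[4:7]))
            met_sig = {m for m, b in zip(mets, pattern[7:] + (1,)) if b}
            gene_de = [gene_record(g, signs[g] * 2.0) for g in gene_sig]
            mir_de = [mir_record(m, mir_signs[parse_mirna_name(m).mature_key] * 2.0)
                      for m, b in mir_sig.items() if b]
            met_de = [met(m, 1.0, 0.01 if m in met_sig else 0.9) for m in mets]
            conns = find_consistent_connections(mir_de, gene_de, edges)
            got = {str(t.gene) for t in find_triomics_triplets(gene_de, conns, met_de, adjacency)}
            sig_mir_signs = {
                parse_mirna_name(m).mature_key: mir_signs[parse_mirna_name(m).mature_key]
                for m, b in mir_sig.items()
                if b
            }
            want = oracle_triplets(
                gene_sig,
                signs,
                sig_mir_signs,
                [(e.mirna.mature_key, e.gene.match_key) for e in edges],
                [(g, m) for g, m, _ in adjacency],
                met_sig,
            )
            assert got == want, pattern
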