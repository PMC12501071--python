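import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snatlas.modules import (GeneModule, cluster_modules,
                             derive_consensus_genes,
                             discover_consensus_modules,
                             extract_candidate_modules, filter_nonrecurrent,
                             score_cells, similarity_matrix, sorensen_index)
from snatlas.qc import normalize
from snatlas.simulate import (PlantedModule, SimulationConfig,
                              default_multi_tumor_config,
                              generate_multi_tumor_dataset)

from conftest import make_count_matrix


def brute_force_sorensen(a, b):
    """Independent set-arithmetic oracle: 2|A∩B| / (|A|+|B|)."""
    a, b = set(a), set(b)
    inter = sum(1 for x in a if x in b)
    return 2.0 * inter / (len(a) + len(b))


class TestSorensen:
    def test_identity_disjoint_and_partial(self):
        assert sorensen_index({"a", "b"}, {"a", "b"}) == 1.0
        assert sorensen_index({"a"}, {"b"}) == 0.0
        assert sorensen_index({"g1", "g2", "g3"},
                              {"g2", "g3", "g4"}) == pytest.approx(2 / 3)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            sorensen_index(set(), {"a"})

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.sets(st.integers(0, 30), min_size=1),
           st.sets(st.integers(0, 30), min_size=1))
    def test_matches_brute_force_oracle(self, a, b):
        assert sorensen_index(a, b) == brute_force_sorensen(a, b)


@pytest.fixture(scope="module")
def planted_dataset():
    cfg = default_multi_tumor_config(seed=11)
    cm, gt = generate_multi_tumor_dataset(cfg)
    return cm, gt, normalize(cm)


class TestExtractCandidates:
    def test_default_module_count_and_size(self, planted_dataset):
        _, _, nm = planted_dataset
        mods = extract_candidate_modules(nm, "T0")
        assert len(mods) == 20
        assert all(len(m.genes) == 50 for m in mods)
        assert {m.component_index for m in mods} == set(range(1, 11))
        assert {m.sign for m in mods} == {"+", "-"}

    def test_small_tumor_skipped(self, planted_dataset):
        _, _, nm = planted_dataset
        sub = nm.subset_cells(np.arange(200))
        assert extract_candidate_modules(sub, "T0") == []

    def test_planted_program_in_leading_component(self):
        cfg = SimulationConfig(
            n_tumors=1, cells_per_tumor=400, n_genes=800,
            planted_modules=[PlantedModule(50, carriers=(0,), effect=2.0)],
            seed=3)
        cm, gt = generate_multi_tumor_dataset(cfg)
        mods = extract_candidate_modules(normalize(cm), "T0")
        pc1 = {g for m in mods if m.component_index == 1 for g in m.genes}
        overlap = len(pc1 & set(gt.module_genes["M0"]))
        assert overlap >= 45


def _sim_from_neighbors(rows):
    """Square similarity DataFrame from a dict of dicts (symmetrized)."""
    ids = sorted(rows)
    S = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for i, nbrs in rows.items():
        for j, s in nbrs.items():
            S.loc[i, j] = S.loc[j, i] = s
    return S


class TestFilterNonrecurrent:
    def test_two_strong_neighbors_kept(self):
        S = _sim_from_neighbors({
            "m0": {"m1": 0.5, "m2": 0.45, "m3": 0.1},
            "m1": {"m2": 0.5}, "m2": {}, "m3": {}})
        kept = filter_nonrecurrent(S)
        assert "m0" in kept.index

    def test_single_neighbor_discarded(self):
        S = _sim_from_neighbors({
            "m0": {"m1": 0.9, "m2": 0.39},
            "m1": {"m2": 0.9, "m3": 0.9}, "m2": {"m3": 0.9}, "m3": {}})
        kept = filter_nonrecurrent(S)
        assert "m0" not in kept.index

    def test_all_below_threshold_gives_empty_result(self):
        S = _sim_from_neighbors({"m0": {"m1": 0.39}, "m1": {}})
        kept = filter_nonrecurrent(S)
        assert len(kept) == 0

    def test_lowering_threshold_is_monotone(self, rng):
        n = 30
        X = rng.uniform(0, 0.8, size=(n, n))
        S = pd.DataFrame((X + X.T) / 2, index=[f"m{i}" for i in range(n)],
                         columns=[f"m{i}" for i in range(n)])
        np.fill_diagonal(S.values, 1.0)
        sizes = [len(filter_nonrecurrent(S, sim_threshold=t))
                 for t in (0.6, 0.5, 0.4, 0.3)]
        assert sizes == sorted(sizes)


def _block_similarity(n_per_block, tumors_per_block, within=0.8, between=0.05):
    """Two planted blocks of modules; ids carry their source tumor."""
    ids = []
    for b, n_tumors in enumerate(tumors_per_block):
        for i in range(n_per_block):
            ids.append(f"T{b * 10 + i % n_tumors}|B{b}m{i}")
    n = len(ids)
    S = np.full((n, n), between)
    half = n_per_block
    for b in range(len(tumors_per_block)):
        sl = slice(b * half, (b + 1) * half)
        S[sl, sl] = within
    np.fill_diagonal(S, 1.0)
    return pd.DataFrame(S, index=ids, columns=ids)


class TestClusterModules:
    def test_two_planted_blocks_recovered(self):
        S = _block_similarity(4, [4, 4])
        clusters = cluster_modules(S)
        assert len(clusters) == 2
        members = sorted(tuple(sorted(c.member_ids)) for c in clusters)
        assert members[0] == tuple(sorted(S.index[:4]))
        assert members[1] == tuple(sorted(S.index[4:]))

    def test_two_tumor_block_dropped(self):
        S = _block_similarity(4, [4, 2])
        clusters = cluster_modules(S)
        assert len(clusters) == 1
        assert all("B0" in m for m in clusters[0].member_ids)

    def test_singleton_never_emitted(self):
        S = _block_similarity(4, [4])
        lone = pd.DataFrame(np.eye(1), index=["T9|x"], columns=["T9|x"])
        full = pd.DataFrame(np.full((5, 5), 0.02),
                            index=list(S.index) + ["T9|x"],
                            columns=list(S.index) + ["T9|x"])
        full.iloc[:4, :4] = S.to_numpy()
        np.fill_diagonal(full.values, 1.0)
        clusters = cluster_modules(full)
        assert all("T9|x" not in c.member_ids for c in clusters)


class TestConsensusGenes:
    def _cluster_and_modules(self):
        mods = [
            GeneModule("T1|PC1+", "T1", 1, "+", ["a", "b", "dup"]),
            GeneModule("T1|PC1-", "T1", 1, "-", ["dup", "z"]),
            GeneModule("T2|PC1+", "T2", 1, "+", ["a", "c"]),
            GeneModule("T3|PC1+", "T3", 1, "+", ["c", "d"]),
            GeneModule("T4|PC1+", "T4", 1, "+", ["d", "e"]),
        ]
        from snatlas.modules import ConsensusModule
        cluster = ConsensusModule(id="CM1",
                                  member_ids=[m.id for m in mods],
                                  tumors=["T1", "T2", "T3", "T4"])
        return cluster, mods

    def test_half_of_tumors_inclusive(self):
        cluster, mods = self._cluster_and_modules()
        cm = derive_consensus_genes(cluster, mods)
        # "a": T1,T2 = 2/4 = 50% -> kept; "c","d" likewise
        assert {"a", "c", "d"} <= set(cm.genes)

    def test_quarter_of_tumors_excluded(self):
        cluster, mods = self._cluster_and_modules()
        cm = derive_consensus_genes(cluster, mods)
        assert "b" not in cm.genes and "e" not in cm.genes

    def test_gene_in_both_signed_modules_counted_once(self):
        cluster, mods = self._cluster_and_modules()
        cm = derive_consensus_genes(cluster, mods)
        # "dup" appears in both T1 modules: 1 tumor of 4 -> excluded
        assert "dup" not in cm.genes
        # brute-force tumor-set oracle
        tumor_sets = {}
        for m in mods:
            for g in m.genes:
                tumor_sets.setdefault(g, set()).add(m.source_tumor)
        expected = sorted(g for g, tu in tumor_sets.items()
                          if len(tu) / 4 >= 0.5)
        assert cm.genes == expected


class TestEndToEnd:
    def test_recovery_of_shared_programs_only(self, planted_dataset):
        cm, gt, nm = planted_dataset
        consensus, _, _ = discover_consensus_modules(nm)
        assert len(consensus) == 3
        shared_sets = [set(gt.module_genes[m]) for m in gt.shared_module_ids]
        for c in consensus:
            jac = max(len(set(c.genes) & s) / len(set(c.genes) | s)
                      for s in shared_sets)
            assert jac >= 0.7
        private_sets = [set(gt.module_genes[m])
                        for m in gt.private_module_ids]
        for c in consensus:
            for s in private_sets:
                assert len(set(c.genes) & s) / len(set(c.genes) | s) < 0.2

    def test_invariant_to_cell_and_gene_permutation(self, planted_dataset):
        cm, _, nm = planted_dataset
        consensus, _, _ = discover_consensus_modules(nm)
        local = np.random.default_rng(0)
        cm2 = cm.subset_cells(local.permutation(cm.n_cells))
        cm2 = cm2.subset_genes(local.permutation(cm2.n_genes))
        consensus2, _, _ = discover_consensus_modules(normalize(cm2))
        sets1 = sorted(tuple(sorted(c.genes)) for c in consensus)
        sets2 = sorted(tuple(sorted(c.genes)) for c in consensus2)
        assert sets1 == sets2


class TestScoreCells:
    def test_argmax_label_and_tie_break(self):
        from snatlas.modules import ConsensusModule
        counts = np.zeros((60, 3), dtype=int)
        counts[:20, 0] = 10   # cell 0 high in CM_a genes
        counts[20:40, 1] = 10
        counts[:, 2] = 1
        nm = normalize(make_count_matrix(counts))
        mods = [ConsensusModule("CM_a", [], [], [f"G{i}" for i in range(20)]),
                ConsensusModule("CM_b", [], [],
                                [f"G{i}" for i in range(20, 40)])]
        table = score_cells(nm, mods, seed=0)
        assert table.loc["C0", "label"] == "CM_a"
        assert table.loc["C1", "label"] == "CM_b"
        # cell 2 is flat: scores tie at 0 -> lowest module id wins
        assert table.loc["C2", "label"] == "CM_a"

    def test_shift_linearity_within_control_bound(self):
        from snatlas.modules import ConsensusModule
        # 25 expression levels x 20 genes: each level fills one bin exactly,
        # so a +1 shift in one cell cannot move genes across bins
        n_genes, n_cells = 500, 50
        counts = np.repeat(np.arange(25), 20)[:, None] * np.ones(
            (1, n_cells), dtype=int)
        module = [f"G{i}" for i in range(10, 500, 20)]  # one gene per bin
        cm = make_count_matrix(counts)
        nm = normalize(cm)
        nm_shift = normalize(cm)
        idx = [list(nm.gene_ids).index(g) for g in module]
        nm_shift.values[idx, 0] += 1.0
        mods = [ConsensusModule("CM1", [], [], module)]
        base = score_cells(nm, mods, seed=1)
        shifted = score_cells(nm_shift, mods, seed=1)
        delta_a = shifted.loc["C0", "CM1"] - base.loc["C0", "CM1"]
        delta_b = shifted.loc["C1", "CM1"] - base.loc["C1", "CM1"]
        # +1 on the module mean, minus whatever control contamination leaks
        assert 0.85 <= delta_a <= 1.0
        assert abs(delta_b) < 0.05

    def test_high_activity_cells_labeled_with_their_program(
            self, planted_dataset):
        cm, gt, nm = planted_dataset
        consensus, _, _ = discover_consensus_modules(nm)
        table = score_cells(nm, consensus, seed=0)
        act = gt.module_activity
        single = ((act[gt.shared_module_ids].sum(axis=1) == 1)
                  & (act[gt.private_module_ids].sum(axis=1) == 0))
        for c in consensus:
            planted = max(gt.shared_module_ids,
                          key=lambda m: len(set(c.genes)
                                            & set(gt.module_genes[m])))
            cells = (act[planted] == 1) & single
            frac = (table["label"][cells.to_numpy()] == c.id).mean()
            assert frac >= 0.9

    def test_missing_module_genes_error(self, planted_dataset):
        from snatlas.modules import ConsensusModule
        _, _, nm = planted_dataset
        with pytest.raises(ValueError, match="no genes present"):
            score_cells(nm, [ConsensusModule("CMx", [], [], ["ABSENT"])],
                        seed=0)
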