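"""Species-matrix aggregation, partial-network extraction, betweenness."""

import collections
import itertools

import numpy as np
import pytest

from mycorrnet import (
    SampleTable,
    SpeciesMatrix,
    aggregate_to_species,
    betweenness_scores,
    extract_partial,
)


def _table(counts, labels, forest="f1"):
    counts = np.asarray(counts)
    n, m = counts.shape
    return SampleTable(
        forest_id=forest,
        sample_ids=[f"s{i}" for i in range(n)],
        plant_labels=labels,
        otu_ids=[f"otu{j}" for j in range(m)],
        counts=counts,
    )


class TestAggregation:
    def test_counts_samples_not_reads(self):
        t = _table([[4, 1], [9, 0], [0, 999]], ["pA", "pA", "pA"])
        m = aggregate_to_species(t)
        assert m.plant_labels == ["pA"]
        assert m.assoc.tolist() == [[2, 2]]

    def test_matches_naive_double_loop(self, random_table):
        m = aggregate_to_species(random_table)
        for pi, plant in enumerate(m.plant_labels):
            for oj, otu in enumerate(m.otu_ids):
                expected = sum(
                    1
                    for i in range(random_table.n_samples)
                    if random_table.plant_labels[i] == plant
                    and random_table.counts[i, random_table.otu_ids.index(otu)] > 0
                )
                assert m.assoc[pi, oj] == expected

    def test_conserves_presence_pairs(self, random_table):
        m = aggregate_to_species(random_table)
        assert m.assoc.sum() == (random_table.counts > 0).sum()

    def test_cell_bounded_by_samples_per_plant(self, random_table):
        m = aggregate_to_species(random_table)
        per_plant = collections.Counter(random_table.plant_labels)
        for pi, plant in enumerate(m.plant_labels):
            assert np.all(m.assoc[pi] <= per_plant[plant])

    def test_row_order_invariance(self, random_table):
        m1 = aggregate_to_species(random_table)
        rng = np.random.default_rng(1)
        m2 = aggregate_to_species(
            random_table.subset_samples(rng.permutation(random_table.n_samples))
        )
        assert m1.plant_labels == m2.plant_labels
        assert np.array_equal(m1.assoc, m2.assoc)


class TestExtractPartial:
    def _matrix(self):
        # plants: p0 AM_PLANT, p1 ECM_PLANT, p2 NM_PLANT, p3 DUAL
        # otus: o0,o1 AM; o2,o3 ECM; o4 SAPENDO
        return SpeciesMatrix(
            plant_labels=["p0", "p1", "p2", "p3"],
            otu_ids=["o0", "o1", "o2", "o3", "o4"],
            assoc=np.array(
                [
                    [2, 1, 0, 0, 1],
                    [0, 1, 3, 0, 1],
                    [1, 0, 0, 0, 2],
                    [0, 2, 0, 1, 0],
                ]
            ),
            forest_id="f1",
        )

    def _annotations(self):
        from mycorrnet import OTUAnnotationTable, PlantAnnotationTable

        otus = OTUAnnotationTable(
            otu_ids=["o0", "o1", "o2", "o3", "o4"],
            guilds=["AM", "AM", "ECM", "ECM", "SAPENDO"],
        )
        plants = PlantAnnotationTable(
            plant_labels=["p0", "p1", "p2", "p3"],
            mycorrhizal_types=["AM_PLANT", "ECM_PLANT", "NM_PLANT", "DUAL"],
        )
        return otus, plants

    def test_guild_category_keeps_guild_columns(self):
        otus, plants = self._annotations()
        m = extract_partial(self._matrix(), otus, plants, "AM")
        assert m.otu_ids == ["o0", "o1"]
        assert m.category == "AM"

    def test_ecm_ex_keeps_compatible_plants_and_prunes(self):
        otus, plants = self._annotations()
        # ECM columns are o2, o3; compatible plants are p1 (ECM) and p3 (DUAL).
        # o2 associates only with p1, o3 only with p3; nothing pruned here.
        m = extract_partial(self._matrix(), otus, plants, "ECM_EX")
        assert set(m.plant_labels) == {"p1", "p3"}
        assert set(m.otu_ids) == {"o2", "o3"}

    def test_ecm_ex_prunes_otu_hosted_only_by_incompatible_plant(self):
        otus, plants = self._annotations()
        base = self._matrix()
        # make o3 associate only with the AM plant p0 -> empty column in ECM_EX
        assoc = base.assoc.copy()
        assoc[:, 3] = [2, 0, 0, 0]
        m = extract_partial(
            SpeciesMatrix(base.plant_labels, base.otu_ids, assoc, forest_id="f1"),
            otus,
            plants,
            "ECM_EX",
        )
        assert "o3" not in m.otu_ids

    def test_am_ex_excludes_nm_and_ecm_plants(self):
        otus, plants = self._annotations()
        m = extract_partial(self._matrix(), otus, plants, "AM_EX")
        assert set(m.plant_labels) <= {"p0", "p3"}

    def test_guild_columns_partition_all(self):
        otus, plants = self._annotations()
        rng = np.random.default_rng(3)
        assoc = rng.integers(0, 3, size=(4, 5))
        assoc[assoc.sum(axis=1) == 0, 0] = 1
        base = SpeciesMatrix(
            ["p0", "p1", "p2", "p3"], ["o0", "o1", "o2", "o3", "o4"], assoc,
            forest_id="f1",
        ).pruned()
        union = set()
        for cat in ("AM", "ECM", "SAPENDO", "PATHO"):
            sub = extract_partial(base, otus, plants, cat)
            union |= set(sub.otu_ids)
        unknown = {
            o for o in base.otu_ids
            if otus.guild_of(o) == "UNKNOWN"
            and base.assoc[:, base.otu_ids.index(o)].sum() > 0
        }
        assert union | unknown == set(base.otu_ids)

    def test_output_is_submatrix_of_input(self):
        otus, plants = self._annotations()
        base = self._matrix()
        m = extract_partial(base, otus, plants, "ECM")
        for pi, p in enumerate(m.plant_labels):
            for oj, o in enumerate(m.otu_ids):
                assert (
                    m.assoc[pi, oj]
                    == base.assoc[base.plant_labels.index(p), base.otu_ids.index(o)]
                )

    def test_prune_is_fixpoint(self):
        base = self._matrix()
        once = base.pruned()
        twice = once.pruned()
        assert np.array_equal(once.assoc, twice.assoc)
        assert once.plant_labels == twice.plant_labels

    def test_small_result_flagged_degenerate(self):
        otus, plants = self._annotations()
        base = self._matrix()
        assoc = base.assoc.copy()
        assoc[:, 2] = 0  # ECM reduces to one OTU
        m = extract_partial(
            SpeciesMatrix(base.plant_labels, base.otu_ids, assoc, forest_id="f1"),
            otus,
            plants,
            "ECM",
        )
        assert m.degenerate


def _betweenness_oracle(adj: dict) -> dict:
    """Brute-force betweenness: enumerate all shortest paths per node pair."""
    nodes = sorted(adj)
    score = {v: 0.0 for v in nodes}

    def shortest_paths(s, t):
        # BFS distances from s, then DFS back-tracking enumerates paths
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        if t not in dist:
            return []
        paths = []

        def walk(path):
            u = path[-1]
            if u == t:
                paths.append(list(path))
                return
            for v in adj[u]:
                if dist.get(v) == dist[u] + 1 and dist[v] <= dist[t]:
                    walk(path + [v])

        walk([s])
        return [p for p in paths if len(p) - 1 == dist[t]]

    for s, t in itertools.combinations(nodes, 2):
        paths = shortest_paths(s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            score[v] += through / len(paths)
    return score


class TestBetweenness:
    def test_star_center_dominates(self):
        m = SpeciesMatrix(["hub"], [f"o{j}" for j in range(5)],
                          np.ones((1, 5), dtype=int), forest_id="f1")
        scores = {c.node_id: c.betweenness for c in betweenness_scores(m)}
        assert scores["hub"] > 0
        assert all(scores[f"o{j}"] == 0 for j in range(5))

    def test_path_graph(self):
        # p1 - o1 - p2: only o1 lies between the endpoints
        m = SpeciesMatrix(["p1", "p2"], ["o1"], np.array([[1], [1]]), forest_id="f")
        scores = {(c.side, c.node_id): c.betweenness for c in betweenness_scores(m)}
        assert scores[("fungus", "o1")] > 0
        assert scores[("plant", "p1")] == 0
        assert scores[("plant", "p2")] == 0

    def test_matches_path_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        assoc = (rng.random((8, 8)) < 0.3).astype(int)
        assoc[0, 0] = 1  # guarantee non-degenerate
        assoc[1, 1] = 1
        m = SpeciesMatrix(
            [f"p{i}" for i in range(8)], [f"o{j}" for j in range(8)], assoc,
            forest_id="f1",
        ).pruned()
        adj = {}
        for i, p in enumerate(m.plant_labels):
            adj.setdefault(("P", p), set())
            for j, o in enumerate(m.otu_ids):
                adj.setdefault(("F", o), set())
                if m.assoc[i, j]:
                    adj[("P", p)].add(("F", o))
                    adj[("F", o)].add(("P", p))
        expected = _betweenness_oracle(adj)
        got = {
            ("P" if c.side == "plant" else "F", c.node_id): c.betweenness
            for c in betweenness_scores(m)
        }
        for node, val in expected.items():
            assert got[(node[0], node[1])] == pytest.approx(val, abs=1e-9)
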