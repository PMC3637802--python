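"""Predominance classification, mobile-element filter, proximity clusters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gpmatch.relate import (classify_predominance,
                            export_relation_figures, extract_clusters,
                            filter_mobile_elements, gene_strain_view,
                            relations_frame)


class TestPredominance:
    def test_boundaries_inclusive(self):
        r = classify_predominance([1, 1, 1, 0], importance=1.0,
                                  importance_split=0.5)
        assert r.presence_state == "predominantly_present"   # exactly 75%
        r = classify_predominance([0, 0, 0, 1], importance=0.1,
                                  importance_split=0.5)
        assert r.presence_state == "predominantly_absent"    # 75% absent
        r = classify_predominance([1, 1, 0, 0], importance=1.0,
                                  importance_split=0.5)
        assert r.presence_state == "subset" and r.partial

    def test_exhaustive_fraction_oracle(self):
        """Brute-force rule check for every presence count at n = 1..40."""
        for n in range(1, 41):
            for k in range(n + 1):
                occ = [1] * k + [0] * (n - k)
                r = classify_predominance(occ, 1.0, 0.5)
                f = k / n
                if f >= 0.75:
                    expected = "predominantly_present"
                elif f <= 0.25:
                    expected = "predominantly_absent"
                else:
                    expected = "subset"
                assert r.presence_state == expected, (n, k)
                assert r.partial == (expected == "subset")

    def test_six_categories_plus_partial_partition(self):
        seen = set()
        for k in range(0, 21):
            for imp in (0.0, 1.0):
                r = classify_predominance([1] * k + [0] * (20 - k), imp, 0.5)
                assert r.presence_state in ("predominantly_present",
                                            "predominantly_absent", "subset")
                assert r.importance_level in ("high", "low")
                seen.add((r.presence_state, r.importance_level))
        assert len(seen) == 6

    def test_empty_class_errors(self):
        with pytest.raises(ValueError):
            classify_predominance([], 1.0, 0.5)


class TestMobileFilter:
    def _genes(self, annotations):
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(len(annotations))],
            "og_id": [f"og{i}" for i in range(len(annotations))],
            "replicon": "chr", "start": range(1, len(annotations) + 1),
            "annotation": annotations})

    def test_keyword_removal(self):
        genes = self._genes(["IS981 transposase", "hypothetical protein",
                             "Phage tail protein", "prophage Integrase"])
        kept, removed = filter_mobile_elements(genes)
        assert list(kept["gene_id"]) == ["g1"]
        assert len(removed) == 3

    def test_empty_keyword_list_is_identity(self):
        genes = self._genes(["IS981 transposase", "x"])
        kept, removed = filter_mobile_elements(genes, keywords=())
        assert len(kept) == 2 and removed.empty


class TestExtractClusters:
    def _genes(self, starts, replicon="chr"):
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(len(starts))],
            "og_id": [f"og{i}" for i in range(len(starts))],
            "replicon": replicon, "start": starts})

    def test_gap_2500_inclusive(self):
        clusters, singles = extract_clusters(self._genes([1000, 3500]), "ref")
        assert len(clusters) == 1 and clusters[0].size == 2
        assert singles.empty

    def test_gap_over_2500_splits(self):
        clusters, singles = extract_clusters(self._genes([1000, 3600]), "ref")
        assert clusters == [] and len(singles) == 2

    def test_order_invariance_and_no_gene_lost(self):
        rng = np.random.default_rng(0)
        starts = rng.integers(1, 200_000, 60).tolist()
        genes = self._genes(starts)
        shuffled = genes.sample(frac=1, random_state=1)
        c1, s1 = extract_clusters(genes, "ref")
        c2, s2 = extract_clusters(shuffled, "ref")
        assert [c.gene_ids for c in c1] == [c.gene_ids for c in c2]
        all_ids = set(genes["gene_id"])
        covered = set(s1["gene_id"]) | {g for c in c1 for g in c.gene_ids}
        assert covered == all_ids
        assert len(s1) + sum(c.size for c in c1) == len(all_ids)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 120))
    def test_matches_union_find_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        starts = np.sort(rng.integers(1, 300_000, n))
        genes = self._genes(starts.tolist())
        clusters, singles = extract_clusters(genes, "ref", proximity_bp=2500)

        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(n):
            for j in range(i + 1, n):
                if abs(int(starts[j]) - int(starts[i])) <= 2500:
                    parent[find(i)] = find(j)
        comps = {}
        for i in range(n):
            comps.setdefault(find(i), []).append(i)
        expected = sorted(tuple(sorted(v)) for v in comps.values()
                          if len(v) >= 2)
        got = sorted(tuple(sorted(int(g[1:]) for g in c.gene_ids))
                     for c in clusters)
        assert got == expected

    def test_multiple_replicons_never_chain(self):
        genes = pd.concat([self._genes([100, 200], "chr"),
                           self._genes([150, 250], "plasmid_1")])
        clusters, _ = extract_clusters(genes, "ref")
        assert len(clusters) == 2
        assert {c.replicon for c in clusters} == {"chr", "plasmid_1"}


class TestGeneStrainView:
    def test_views_merge_occurrence_and_contribution(self):
        from gpmatch.pheno_prep import PhenotypeUnit
        from gpmatch.selector import PhenotypeResult
        unit = PhenotypeUnit("e", "1", ("a", "b"), ("c",))
        genes = pd.DataFrame({"importance": [1.0], "provenance": ["selected"],
                              "sponsor": ["og1"]}, index=pd.Index(["og1"],
                                                                  name="og_id"))
        pr = PhenotypeResult(unit, 0.9, genes)
        matrix = pd.DataFrame([[1, 0, 0]], index=["og1"],
                              columns=["a", "b", "c"])
        scores = pd.DataFrame([[0.2, 0.0, -0.1]], index=["og1"],
                              columns=["a", "b", "c"])
        view = gene_strain_view(pr, matrix, scores)
        cat = view.set_index("strain")["category"]
        assert cat["a"] == "present_contributing"
        assert cat["b"] == "absent_unrelated"
        assert cat["c"] == "absent_unrelated"

    def test_unretained_strains_excluded(self):
        from gpmatch.pheno_prep import PhenotypeUnit
        from gpmatch.selector import PhenotypeResult
        unit = PhenotypeUnit("e", "1", ("a",), ("b",))
        genes = pd.DataFrame({"importance": [1.0], "provenance": ["selected"],
                              "sponsor": ["og1"]},
                             index=pd.Index(["og1"], name="og_id"))
        pr = PhenotypeResult(unit, 0.9, genes)
        matrix = pd.DataFrame([[1, 0, 1]], index=["og1"],
                              columns=["a", "b", "z"])
        scores = pd.DataFrame([[0.2, 0.0, 0.5]], index=["og1"],
                              columns=["a", "b", "z"])
        view = gene_strain_view(pr, matrix, scores)
        assert set(view["strain"]) == {"a", "b"}


def test_export_handles_empty_category(tmp_path):
    relations = relations_frame([])
    gene_table = pd.DataFrame({"gene_id": ["g1"], "og_id": ["og1"],
                               "replicon": ["chr"], "start": [1],
                               "annotation": ["x"]})
    categories = pd.Series({"e1": "sugar", "e2": "metal"})
    written = export_relation_figures(relations, gene_table, categories,
                                      "ref", tmp_path)
    assert any(p.endswith("relations_sugar_ref.tsv") for p in written)
    assert not any(p.endswith(".png") for p in written)
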