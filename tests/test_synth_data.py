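import filecmp

import numpy as np
import pytest
from scipy.stats import ks_2samp

from netpharm.datasets import load_cbeo_contents
from netpharm.synth_data import (
    GeneratorError,
    ScoreModel,
    SyntheticTruth,
    expected_ppi_edges,
    gen_compound_target_map,
    gen_disease_sources,
    gen_library,
    gen_ppi,
    generate_study,
)
from netpharm.target_sets import SourceFilter, merge_disease_targets


class TestCompoundTargetMap:
    def test_planted_actives_have_largest_degrees_at_defaults(self):
        cmap, truth = gen_compound_target_map(
            active_set=["compound01", "compound02"], seed=1
        )
        degrees = sorted(cmap.entries, key=lambda c: -len(cmap.entries[c]))
        assert set(degrees[:2]) == truth.planted_active_compounds

    def test_boost_one_gives_matched_degree_distributions(self):
        active_degs, inactive_degs = [], []
        for seed in range(100):
            cmap, truth = gen_compound_target_map(
                active_set=["compound01", "compound02"],
                active_degree_boost=1.0,
                private_fringe_per_active=0,
                seed=seed,
            )
            for c, genes in cmap.entries.items():
                (active_degs if c in truth.planted_active_compounds else inactive_degs).append(
                    len(genes)
                )
        assert ks_2samp(active_degs, inactive_degs).pvalue > 0.01

    def test_single_compound_degenerates_gracefully(self):
        cmap, _ = gen_compound_target_map(n_compounds=1, n_targets=5, core_size=2,
                                          fringe_size=1, base_degree_mean=2, seed=0)
        assert len(cmap.entries) == 1

    def test_parameter_validation(self):
        with pytest.raises(GeneratorError):
            gen_compound_target_map(active_degree_boost=0.5)
        with pytest.raises(GeneratorError):
            gen_compound_target_map(active_set=["nope"])
        with pytest.raises(GeneratorError):
            gen_compound_target_map(n_targets=5, core_size=4, fringe_size=3)


class TestDiseaseSources:
    def _gen(self, seed=0, planted_n=29):
        pool = [f"TG{i + 1:03d}" for i in range(121)]
        planted = pool[:planted_n]
        return planted, gen_disease_sources(
            sizes=(82, 260, 29, 376),
            target_pool=pool,
            planted_overlap=planted,
            score_models=(
                ScoreModel(0.0, 30.0, 12.0),
                ScoreModel(0.0, 1.0, 0.35),
                None,
                None,
            ),
            seed=seed,
            source_names=("genecards", "disgenet", "ttd", "omim"),
        )

    def test_merged_union_retains_all_planted_genes_after_filters(self):
        planted, sources = self._gen()
        merged = merge_disease_targets(
            sources,
            {"genecards": SourceFilter("score", 10.0, "ge"),
             "disgenet": SourceFilter("score", 0.3, "ge")},
        ).merged
        assert set(planted) <= merged

    def test_single_source_union_is_that_source(self):
        pool = [f"TG{i + 1:03d}" for i in range(30)]
        sources = gen_disease_sources(
            sizes=(20,), target_pool=pool, planted_overlap=pool[:5],
            score_models=(None,), seed=0,
        )
        out = merge_disease_targets(sources)
        assert out.merged == out.per_source[sources[0][0]]

    def test_overtight_threshold_filters_planted_out(self):
        # monotonicity: raising the threshold past the score model's
        # maximum removes planted genes from the filtered union
        planted, sources = self._gen()
        loose = merge_disease_targets(
            sources, {"genecards": SourceFilter("score", 10.0, "ge")}
        ).merged
        tight = merge_disease_targets(
            sources, {"genecards": SourceFilter("score", 100.0, "ge")}
        ).merged
        assert tight <= loose

    def test_size_below_planted_share_rejected(self):
        pool = [f"TG{i + 1:03d}" for i in range(30)]
        with pytest.raises(GeneratorError):
            gen_disease_sources(
                sizes=(2,), target_pool=pool, planted_overlap=pool[:20],
                score_models=(None,), seed=0,
            )


class TestPPI:
    def test_realized_edges_near_expectation(self):
        members = [f"G{i}" for i in range(28)]
        hubs = members[:6]
        counts = [len(gen_ppi(members, hub_set=hubs, seed=s)) for s in range(200)]
        expect = expected_ppi_edges(28, 6)
        # mean over 200 draws within 3 sigma of the analytic expectation
        sigma = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expect) <= 3 * max(sigma, 1e-9)
        assert expect == pytest.approx(82, abs=5)

    def test_zero_boost_hubs_indistinguishable(self):
        hub_degs, bg_degs = [], []
        members = [f"G{i}" for i in range(28)]
        hubs = members[:6]
        for seed in range(100):
            el = gen_ppi(members, hub_set=hubs, hub_boost=0.0, seed=seed)
            degs = {m: 0 for m in members}
            for a, _, b in el.edges:
                degs[a] += 1
                degs[b] += 1
            hub_degs += [degs[h] for h in hubs]
            bg_degs += [degs[m] for m in members[6:]]
        assert ks_2samp(hub_degs, bg_degs).pvalue > 0.01

    def test_two_members_at_most_one_edge(self):
        assert len(gen_ppi(["A", "B"], edge_prob=0.99, seed=0)) <= 1

    def test_edge_prob_validation(self):
        with pytest.raises(GeneratorError):
            gen_ppi(["A", "B"], edge_prob=1.5)


class TestLibrary:
    def test_single_term_library_valid(self):
        lib, planted = gen_library(
            n_terms=1, term_size_range=(3, 5),
            universe=[f"G{i}" for i in range(20)],
            enriched_term_overlap=2, query=["G0", "G1", "G2"], seed=0,
        )
        assert len(lib) == 1 and planted == lib.terms[0].term_id

    def test_planted_term_absorbs_requested_overlap(self):
        query = [f"G{i}" for i in range(10)]
        lib, planted = gen_library(
            universe=[f"G{i}" for i in range(100)],
            enriched_term_overlap=6, query=query, seed=3,
        )
        assert len(lib[planted].genes & set(query)) >= 6

    def test_overlap_larger_than_query_rejected(self):
        with pytest.raises(GeneratorError):
            gen_library(universe=["A", "B"], enriched_term_overlap=3, query=["A"],
                        term_size_range=(1, 2))


class TestStudyPreset:
    def test_scales_mirror_the_reference_study(self, study):
        assert len(study.compound_map.entries) == 18
        assert len(study.truth.planted_overlap) == 29
        assert len(study.truth.planted_hubs) == 6
        assert len(study.libraries) == 3
        assert {name for name, _ in study.disease_sources} == {
            "genecards", "disgenet", "ttd", "omim",
        }

    def test_determinism_byte_identical_files(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        generate_study(seed=42).write(a)
        generate_study(seed=42).write(b)
        names = sorted(p.name for p in a.iterdir())
        assert names == sorted(p.name for p in b.iterdir())
        for name in names:
            assert filecmp.cmp(a / name, b / name, shallow=False), name

    def test_different_seeds_differ(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        generate_study(seed=1).write(a)
        generate_study(seed=2).write(b)
        assert not filecmp.cmp(a / "compound_targets.tsv", b / "compound_targets.tsv",
                               shallow=False)

    def test_truth_round_trips_through_json(self, study, tmp_path):
        p = tmp_path / "truth.json"
        study.truth.to_json(p)
        back = SyntheticTruth.from_json(p)
        assert back.planted_active_compounds == study.truth.planted_active_compounds
        assert back.planted_overlap == study.truth.planted_overlap
        assert back.planted_hubs == study.truth.planted_hubs
        assert back.planted_enriched_terms == study.truth.planted_enriched_terms

    def test_compound_names_match_packaged_table(self, study):
        assert set(study.compound_map.entries) == set(load_cbeo_contents().names)
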