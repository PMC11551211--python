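import numpy as np
import pandas as pd
import pytest

from micage import (
    MetaboliteReference,
    MetaboliteSet,
    PeakSimSpec,
    PeakTable,
    build_sets,
    enrichment_score,
    gsea,
    make_reference,
    rank_features,
    sim_peak_table,
)
from micage.differential import DifferentialRecord
from micage.integration import RankedList, leading_edge


def _ranked(ids, metrics):
    metric = pd.Series(metrics, index=ids)
    order = np.argsort(-metric.values, kind="stable")
    return RankedList([ids[i] for i in order], metric)


def brute_force_es(ranked, members, p=1.0):
    """Independent running-sum walk over the ranked list."""
    r = [ranked.metric[f] for f in ranked.feature_ids]
    is_member = [f in members for f in ranked.feature_ids]
    n_r = sum(abs(ri) ** p for ri, m in zip(r, is_member) if m)
    n_miss = len(r) - sum(is_member)
    run, hi, lo = 0.0, 0.0, 0.0
    for ri, m in zip(r, is_member):
        if m:
            run += abs(ri) ** p / n_r
        else:
            run -= 1.0 / n_miss
        hi, lo = max(hi, run), min(lo, run)
    # ties between the positive and negative extremum resolve positive
    return hi if hi >= -lo - 1e-9 else lo


class TestBuildSets:
    def _fixture(self):
        ref, scmap = make_reference(n_metabolites=80, n_pathways=6,
                                    n_superclasses=2, seed=9)
        annotation = {f"f{i}": f"met_{i:04d}" for i in range(80)}
        return ref, scmap, annotation

    def test_no_significant_pathway_gives_zero_sets(self):
        ref, scmap, ann = self._fixture()
        recs = [DifferentialRecord(pw, "t", 0.0, 0.9) for pw in scmap]
        assert build_sets(recs, ref, ann, scmap) == []

    def test_union_semantics_deduplicate_shared_features(self):
        rows = []
        for i in range(30):
            pws = ["P1"] if i < 7 else (["P2"] if i < 13 else ["P3"])
            if i in (0, 5):  # shared between P1 and P2
                pws = ["P1", "P2"]
            rows.append({"name": f"m{i}", "hmdb_id": "", "kegg_id": "",
                         "mass": 100.0 + i, "pathways": pws,
                         "superclass": "S1"})
        ref = MetaboliteReference(pd.DataFrame(rows).set_index("name"))
        scmap = {"P1": "S1", "P2": "S1", "P3": "S2"}
        ann = {f"f{i}": f"m{i}" for i in range(30)}
        recs = [DifferentialRecord("P1", "t", 0, 0.01),
                DifferentialRecord("P2", "t", 0, 0.02),
                DifferentialRecord("P3", "t", 0, 0.9)]
        sets = build_sets(recs, ref, ann, scmap, min_set_size=5)
        assert len(sets) == 1
        assert sets[0].superclass_id == "S1"
        assert len(sets[0]) == 13  # 7 + 6 distinct metabolites' features
        assert sets[0].source_pathways == ["P1", "P2"]

    def test_below_minimum_size_excluded(self):
        ref, scmap, ann = self._fixture()
        small_ann = {k: v for k, v in list(ann.items())[:9]}
        recs = [DifferentialRecord(pw, "t", 0.0, 0.001) for pw in scmap]
        sets = build_sets(recs, ref, small_ann, scmap, min_set_size=10)
        assert all(len(s) >= 10 for s in sets)
        nine = build_sets(recs, ref, small_ann, scmap, min_set_size=9)
        assert len(nine) >= len(sets)


class TestRankFeatures:
    def _peaks(self, cols):
        samples = [f"s{i}" for i in range(6)]
        inten = pd.DataFrame(cols, index=samples)
        features = pd.DataFrame({"mz": 100.0, "rt": 1.0, "mode": "positive"},
                                index=inten.columns)
        groups = pd.Series(["old"] * 3 + ["young"] * 3, index=samples)
        return PeakTable(features, inten, groups)

    def test_equal_means_zero_metric(self):
        peaks = self._peaks({"fA": [10, 100, 1000, 10, 100, 1000]})
        ranked = rank_features(peaks, positive_group="old")
        assert ranked.metric["fA"] == pytest.approx(0.0)

    def test_hand_computed_t_metric(self):
        # log10 intensities 1,2,3 vs 4,5,6 -> (2-5)/sqrt(1/3+1/3)
        peaks = self._peaks({"fA": [10.0, 100, 1000, 1e4, 1e5, 1e6]})
        ranked = rank_features(peaks, positive_group="old", sd_floor=0.0)
        assert ranked.metric["fA"] == pytest.approx(-3.674, abs=1e-3)

    def test_invariant_to_multiplicative_rescale(self):
        cols = {"fA": [12.0, 15, 11, 30, 33, 29],
                "fB": [5.0, 6, 7, 5, 6, 7]}
        p1 = self._peaks(cols)
        p2 = self._peaks({k: list(np.asarray(v) * 100.0)
                          for k, v in cols.items()})
        r1 = rank_features(p1, positive_group="old", sd_floor=0.0)
        r2 = rank_features(p2, positive_group="old", sd_floor=0.0)
        assert np.allclose(r1.metric, r2.metric)
        assert r1.feature_ids == r2.feature_ids


class TestEnrichmentScore:
    def test_toy_hand_walk(self):
        # |r| = 4,3,2,1,0.5; members at positions 1 and 3 -> ES = 2/3
        ranked = _ranked(["f1", "f2", "f3", "f4", "f5"],
                         [4.0, 3.0, 2.0, 1.0, 0.5])
        es, profile = enrichment_score(
            ranked, MetaboliteSet("S", ["f1", "f3"], []), p=1.0)
        assert es == pytest.approx(2 / 3)

    def test_bottom_set_negative(self):
        ranked = _ranked([f"f{i}" for i in range(10)],
                         list(np.linspace(5, -5, 10)))
        es, _ = enrichment_score(ranked,
                                 MetaboliteSet("S", ["f8", "f9"], []))
        assert es < 0

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            n = int(rng.integers(10, 60))
            ids = [f"f{i}" for i in range(n)]
            metrics = rng.normal(size=n)
            ranked = _ranked(ids, metrics)
            k = int(rng.integers(2, n - 1))
            members = list(rng.choice(ids, size=k, replace=False))
            es, _ = enrichment_score(ranked, MetaboliteSet("S", members, []))
            assert es == pytest.approx(
                brute_force_es(ranked, set(members)), abs=1e-12)

    def test_scale_invariance_of_weighted_es(self):
        ranked = _ranked([f"f{i}" for i in range(8)],
                         [3.0, 2.5, 1.0, 0.5, -0.2, -1.0, -2.0, -3.5])
        scaled = _ranked([f"f{i}" for i in range(8)],
                         [30.0, 25, 10, 5, -2, -10, -20, -35])
        s = MetaboliteSet("S", ["f0", "f4", "f6"], [])
        assert enrichment_score(ranked, s)[0] == pytest.approx(
            enrichment_score(scaled, s)[0], abs=1e-12)

    def test_whole_list_set_rejected(self):
        ranked = _ranked(["f0", "f1"], [1.0, -1.0])
        with pytest.raises(ValueError):
            enrichment_score(ranked, MetaboliteSet("S", ["f0", "f1"], []))

    def test_leading_edge_members_at_or_before_extremum(self):
        rng = np.random.default_rng(21)
        ids = [f"f{i}" for i in range(30)]
        ranked = _ranked(ids, rng.normal(size=30))
        members = list(rng.choice(ids, size=8, replace=False))
        s = MetaboliteSet("S", members, [])
        es, profile = enrichment_score(ranked, s)
        edge = leading_edge(ranked, s)
        idx = int(np.argmax(np.abs(profile)))
        positions = [ranked.feature_ids.index(f) for f in edge]
        assert set(edge) <= set(members)
        if es >= 0:
            assert all(p <= idx for p in positions)
        else:
            assert all(p >= idx for p in positions)


class TestGsea:
    def _planted(self, seed):
        ref, _ = make_reference(seed=0)
        rng = np.random.default_rng(seed)
        peaks, _ = sim_peak_table(PeakSimSpec(
            reference=ref, n_features=100, frac_differential=0.0,
            seed=20_000 + seed))
        members = sorted(rng.choice(peaks.feature_ids, 15, replace=False))
        inten = peaks.intensities.copy()
        inten.loc[peaks.groups == "old", members] *= 10 ** 0.301
        peaks = PeakTable(peaks.features, inten, peaks.groups)
        sets = [MetaboliteSet("planted", members, [])]
        pool = [f for f in peaks.feature_ids if f not in members]
        for k in range(5):
            sets.append(MetaboliteSet(
                f"null{k}", sorted(rng.choice(pool, 15, replace=False)), []))
        return peaks, sets

    def test_planted_set_tops_and_clears_fdr(self):
        peaks, sets = self._planted(seed=1)
        res = gsea(peaks, sets, positive_group="old", n_perm=1000, seed=2)
        best = max(res, key=lambda r: abs(r.nes))
        assert best.superclass_id == "planted"
        assert best.fdr < 0.05
        assert best.es > 0 and np.sign(best.nes) == np.sign(best.es)

    def test_es_within_unit_interval_and_edge_subset(self):
        peaks, sets = self._planted(seed=3)
        for r in gsea(peaks, sets, positive_group="old", n_perm=200, seed=4):
            assert -1.0 <= r.es <= 1.0
            members = next(s.members for s in sets
                           if s.superclass_id == r.superclass_id)
            assert set(r.leading_edge) <= set(members)

    def test_fdr_monotone_in_abs_nes_within_sign(self):
        peaks, sets = self._planted(seed=5)
        res = gsea(peaks, sets, positive_group="old", n_perm=500, seed=6)
        for sign in (1, -1):
            rs = sorted((r for r in res if np.sign(r.nes) == sign or
                         (sign == 1 and r.nes == 0)),
                        key=lambda r: -abs(r.nes))
            fdrs = [r.fdr for r in rs]
            assert fdrs == sorted(fdrs)

    def test_deterministic_under_seed(self):
        peaks, sets = self._planted(seed=7)
        r1 = gsea(peaks, sets, n_perm=300, seed=8)
        r2 = gsea(peaks, sets, n_perm=300, seed=8)
        assert [(a.es, a.nes, a.p, a.fdr) for a in r1] == \
            [(a.es, a.nes, a.p, a.fdr) for a in r2]

    def test_exhaustive_phenotype_enumeration_for_larger_groups(self):
        ref, _ = make_reference(seed=0)
        peaks, _ = sim_peak_table(PeakSimSpec(
            reference=ref, n_features=40, n_per_group=7,
            frac_differential=0.0, seed=33))
        sets = [MetaboliteSet("S", sorted(peaks.feature_ids[:12]), [])]
        # C(14,7)=3432 distinct splits fit in n_perm -> enumeration is
        # exhaustive, so results cannot depend on the seed
        r1 = gsea(peaks, sets, n_perm=5000, perm_type="phenotype", seed=0)
        r2 = gsea(peaks, sets, n_perm=5000, perm_type="phenotype", seed=99)
        assert (r1[0].es, r1[0].nes, r1[0].p, r1[0].fdr) == \
            (r2[0].es, r2[0].nes, r2[0].p, r2[0].fdr)
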