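"""Scoring, confidence labels, the two-run identification, ISF detection,
adduct clustering and the xenobiotic-metabolite search."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metaline import annotate, chem, features, simdata
from metaline.annotate import PartialScores, ScoreWeights
from metaline.msio import SpectrumRecord


class TestPartialScores:
    @pytest.mark.parametrize("dppm,tol,expected", [
        (0.0, 5.0, 100.0),
        (5.0, 5.0, 0.0),
        (2.5, 5.0, 50.0),
        (-2.5, 5.0, 50.0),
        (10.0, 5.0, 0.0),
    ])
    def test_mass_score_linear_decay(self, dppm, tol, expected):
        assert annotate.mass_score(dppm, tol) == pytest.approx(expected)

    def test_isotope_score_identity_and_absence(self):
        p = chem.theoretical_isotope_pattern("C30H50O5", 3)
        assert annotate.isotope_score((p.offsets, p.abundances), p) == \
            pytest.approx(100.0)
        assert annotate.isotope_score(None, p) == 0.0

    def test_isotope_score_against_cosine_oracle(self):
        a = chem.theoretical_isotope_pattern("C30H50O5", 4)
        b = chem.theoretical_isotope_pattern("C10H20O2", 4)
        va, vb = np.array(a.abundances), np.array(b.abundances)
        oracle = 100.0 * va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb))
        assert annotate.isotope_score((a.offsets, a.abundances), b) == \
            pytest.approx(oracle, abs=1e-9)

    def test_fragment_score_identity_disjoint_absent(self):
        s = SpectrumRecord([(100.0, 50.0), (150.0, 100.0)])
        t = SpectrumRecord([(300.0, 50.0), (350.0, 100.0)])
        assert annotate.fragment_score(s, s) == pytest.approx(100.0)
        assert annotate.fragment_score(s, t) == 0.0
        assert annotate.fragment_score(None, s) == 0.0
        assert annotate.fragment_score(s, SpectrumRecord([])) == 0.0

    def test_fragment_score_matches_matchms_oracle(self):
        """Half-overlapping spectra: the greedy sqrt-cosine agrees with the
        independent matchms CosineGreedy implementation."""
        matchms = pytest.importorskip("matchms")
        from matchms.similarity import CosineGreedy

        rng = np.random.default_rng(5)
        shared = np.sort(rng.uniform(100, 400, 6))
        only_q = np.sort(rng.uniform(420, 500, 3))
        only_r = np.sort(rng.uniform(520, 600, 3))
        qi = rng.uniform(10, 100, 9)
        ri = rng.uniform(10, 100, 9)
        q = SpectrumRecord(list(zip(np.concatenate([shared, only_q]), qi)))
        r = SpectrumRecord(list(zip(np.concatenate([shared, only_r]), ri)))
        ours = annotate.fragment_score(q, r, mz_tol=0.01)
        sq = matchms.Spectrum(mz=q.mz_array(),
                              intensities=np.sqrt(q.intensity_array()))
        sr = matchms.Spectrum(mz=r.mz_array(),
                              intensities=np.sqrt(r.intensity_array()))
        oracle = float(CosineGreedy(tolerance=0.01).pair(sq, sr)["score"]) * 100
        assert ours == pytest.approx(oracle, abs=1.0)

    def test_ccs_score(self):
        assert annotate.ccs_score(180.0, 180.0, 2.0) == pytest.approx(100.0)
        assert annotate.ccs_score(180.0 * 1.02, 180.0, 2.0) == pytest.approx(0.0, abs=1e-9)
        assert annotate.ccs_score(None, 180.0) is None


class TestOverallScore:
    def test_mass_only_with_default_weights(self):
        """A candidate matched by exact mass alone (S_M=100, no isotope or
        fragment evidence, CCS inactive) scores OS=30 with the default
        weights and is labeled orange / level 3 / 1 star."""
        p = PartialScores(s_m=100.0, s_ip=0.0, s_f=0.0, s_ccs=None)
        os_score = annotate.overall_score(p, ScoreWeights())
        assert os_score == pytest.approx(30.0)
        color, stars, level = annotate.assign_confidence(os_score, True, 1,
                                                         {"mass": True})
        assert (color, stars, level) == ("orange", 1, "3")

    def test_all_perfect_any_weights(self):
        p = PartialScores(100.0, 100.0, 100.0, 100.0)
        for wts in (ScoreWeights(), ScoreWeights(1, 1, 1, 1),
                    ScoreWeights(50, 10, 40, 0)):
            assert annotate.overall_score(p, wts) == pytest.approx(100.0)

    def test_custom_weights_hand_arithmetic(self):
        p = PartialScores(s_m=100.0, s_ip=0.0, s_f=0.0, s_ccs=None)
        assert annotate.overall_score(p, ScoreWeights(50, 10, 40, 0)) == \
            pytest.approx(50.0)

    def test_zero_weight_sum_rejected(self):
        with pytest.raises(ValueError):
            ScoreWeights(0, 0, 0, 0)

    @given(st.floats(0, 100), st.floats(0, 100), st.floats(0, 100),
           st.floats(0, 1))
    @settings(derandomize=True, max_examples=100)
    def test_os_bounded_and_monotone(self, sm, sip, sf, bump):
        wts = ScoreWeights()
        base = annotate.overall_score(PartialScores(sm, sip, sf, None), wts)
        assert 0.0 <= base <= 100.0
        for kwargs in ({"s_m": min(100, sm + bump)},
                       {"s_ip": min(100, sip + bump)},
                       {"s_f": min(100, sf + bump)}):
            p = PartialScores(**{"s_m": sm, "s_ip": sip, "s_f": sf,
                                 "s_ccs": None, **kwargs})
            assert annotate.overall_score(p, wts) >= base - 1e-9


class TestConfidence:
    def test_threshold_grid(self):
        """Color assignment over a grid of OS values and candidate
        availability: green strictly above 60, orange at or below, red only
        without candidates, light-green for run-2 promotions."""
        for os_score in np.linspace(0, 100, 41):
            color, stars, _ = annotate.assign_confidence(os_score, True, 1)
            if os_score > 60.0:
                assert color == "green"
            else:
                assert color == "orange"
            expected_stars = 1 + sum(os_score >= b for b in (40, 60, 80))
            assert stars == expected_stars
            color2, _, level2 = annotate.assign_confidence(os_score, True, 2)
            assert color2 == "light-green" and level2 == "2b"
            color3, _, level3 = annotate.assign_confidence(os_score, False, 1)
            assert color3 == "red" and level3 == "5"

    def test_boundary_61_green_60_orange(self):
        assert annotate.assign_confidence(61.0, True, 1)[0] == "green"
        assert annotate.assign_confidence(60.0, True, 1)[0] == "orange"


@pytest.fixture(scope="module")
def identified(small_study, small_matrix):
    compounds, runs, gt = small_study
    db = simdata.reference_db_for(compounds)
    anns = annotate.identify_run1(small_matrix, db, rt_tol=0.2)
    return compounds, db, anns


class TestRun1:
    def test_every_compound_protonated_green_rank1(self, identified,
                                                   small_matrix):
        compounds, db, anns = identified
        for c in compounds:
            mz = chem.adduct_mz(chem.monoisotopic_mass(c.formula), "[M+H]+")
            hits = [a for a in anns if a.compound_id == c.name
                    and a.adduct == "[M+H]+" and a.rank == 1]
            assert hits, f"{c.name} not annotated"
            a = hits[0]
            assert a.color == "green"
            assert abs(small_matrix.features[a.feature].mz - mz) < mz * 5e-6

    def test_isobars_without_ms2_tie(self, small_matrix, small_study):
        """Two isobaric DB entries with identical evidence share the OS."""
        compounds, _, _ = small_study
        db = simdata.reference_db_for(compounds[:1])
        twin = simdata.reference_db_for(compounds[:1]).records[0]
        twin.id, twin.name = "twin", "twin"
        twin.spectra = {}
        db.records[0].spectra = {}
        db.records.append(twin)
        db.records[0].rt = None
        twin.rt = None
        anns = annotate.identify_run1(small_matrix, db, rt_tol=0.2)
        target = [a for a in anns if a.compound_id in ("cmpd00", "twin")]
        by_feature = {}
        for a in target:
            by_feature.setdefault(a.feature, []).append(a)
        tied = [v for v in by_feature.values() if len(v) == 2]
        assert tied
        for pair in tied:
            assert pair[0].os == pytest.approx(pair[1].os, abs=1e-9)

    def test_db_order_does_not_change_scores(self, small_matrix, small_study):
        compounds, _, _ = small_study
        db1 = simdata.reference_db_for(compounds)
        db2 = simdata.reference_db_for(compounds)
        db2.records = list(reversed(db2.records))
        a1 = annotate.identify_run1(small_matrix, db1, rt_tol=0.2)
        a2 = annotate.identify_run1(small_matrix, db2, rt_tol=0.2)
        key = lambda a: (a.feature, a.compound_id, a.adduct)  # noqa: E731
        m1 = {key(a): a.os for a in a1 if a.compound_id}
        m2 = {key(a): a.os for a in a2 if a.compound_id}
        assert m1 == m2

    def test_rt_mismatch_removes_candidate(self, small_matrix, small_study):
        compounds, _, _ = small_study
        db = simdata.reference_db_for(compounds)
        db.get("cmpd00").rt = compounds[0].rt + 1.0  # 5 x tolerance away
        anns = annotate.identify_run1(small_matrix, db, rt_tol=0.2)
        assert not [a for a in anns if a.compound_id == "cmpd00"]

    def test_empty_db_rejected(self, small_matrix):
        with pytest.raises(ValueError):
            annotate.identify_run1(small_matrix, simdata.reference_db_for([]))

    def test_cost_scales_with_features_not_samples(self, small_study):
        """The same study processed with 2x the samples yields the same
        number of scored (feature, candidate) operations."""
        compounds, _, _ = small_study
        counts = {}
        for reps in (2, 4):
            runs, _ = simdata.simulate_study(compounds, {"A": reps},
                                             noise_sigma=0.0, seed=11,
                                             k_isotopologues=2)
            m = features.process_study(runs, {"snr_min": 3.0})
            db = simdata.reference_db_for(compounds)
            anns = annotate.identify_run1(m, db, rt_tol=0.2)
            counts[reps] = len(anns)
        assert counts[2] == counts[4]


class TestRun2AndClustering:
    @pytest.fixture()
    def full_chain(self, identified, small_matrix):
        compounds, db, anns = identified
        anns2 = annotate.extend_run2(list(anns), small_matrix, db,
                                     rt_tol=0.1)
        links = annotate.detect_isf(small_matrix, rt_tol=0.1)
        clusters = annotate.cluster_adducts(anns2, small_matrix, links,
                                            rt_tol=0.1)
        return compounds, db, anns2, links, clusters

    def test_all_adducts_and_isf_promoted(self, full_chain):
        compounds, _, anns2, _, _ = full_chain
        promoted = [a for a in anns2 if a.run == 2]
        assert len(promoted) == len(compounds) * 3  # Na, K, water-loss ISF
        assert all(a.color == "light-green" for a in promoted)

    def test_run2_never_demotes(self, identified, small_matrix):
        compounds, db, anns = identified
        before = {id(a): (a.color, a.os) for a in anns}
        anns2 = annotate.extend_run2(list(anns), small_matrix, db, rt_tol=0.1)
        for a in anns2:
            if id(a) in before:
                assert (a.color, a.os) == before[id(a)]

    def test_one_cluster_per_compound(self, full_chain):
        compounds, _, _, _, clusters = full_chain
        assert len(clusters) == len(compounds)
        for cl in clusters:
            assert len(cl.members) == 4  # [M+H]+, [M+Na]+, [M+K]+, ISF
            assert len({a.compound_id for a in cl.members}) == 1
            assert cl.representative.adduct == "[M+H]+"

    def test_isf_links_found(self, full_chain, small_matrix):
        compounds, _, _, links, _ = full_chain
        assert len(links) == len(compounds)
        for lo, hi in links:
            assert small_matrix.features[lo].mz < small_matrix.features[hi].mz
            assert abs(small_matrix.features[lo].rt
                       - small_matrix.features[hi].rt) <= 0.1

    def test_rt_apart_not_promoted(self, small_study):
        """A feature with the right m/z but the wrong RT is not promoted."""
        compounds = [simdata.SimCompound("a", "C8H13NO2", rt=1.0,
                                         adducts=("[M+H]+",)),
                     ]
        # a sodiated-mass impostor eluting 1 min away
        na_mass = chem.monoisotopic_mass("C8H13NO2") + \
            chem.MONOISOTOPIC_MASS["Na"] - chem.MONOISOTOPIC_MASS["H"]
        impostor = simdata.SimCompound("imp", "C8H13NO2", rt=2.0,
                                       adducts=("[M+Na]+",))
        runs, _ = simdata.simulate_study([compounds[0], impostor], {"A": 3},
                                         noise_sigma=0.0, seed=7,
                                         k_isotopologues=2)
        m = features.process_study(runs, {"snr_min": 3.0})
        db = simdata.reference_db_for(compounds)
        anns = annotate.identify_run1(m, db, rt_tol=0.2)
        anns2 = annotate.extend_run2(anns, m, db, rt_tol=0.1)
        promoted = [a for a in anns2 if a.run == 2]
        assert promoted == []

    def test_anticorrelated_trend_not_promoted(self):
        """Correct m/z and RT but an anticorrelated trend across samples
        blocks promotion."""
        anchor = simdata.SimCompound("a", "C8H13NO2", rt=1.0,
                                     adducts=("[M+H]+",),
                                     group_means={"A": 1.0, "B": 4.0})
        fake = simdata.SimCompound("fake", "C8H13NO2", rt=1.0,
                                   adducts=("[M+Na]+",),
                                   group_means={"A": 4.0, "B": 1.0})
        runs, _ = simdata.simulate_study([anchor, fake], {"A": 3, "B": 3},
                                         noise_sigma=0.05, seed=8,
                                         k_isotopologues=2)
        m = features.process_study(runs, {"snr_min": 3.0})
        db = simdata.reference_db_for([anchor])
        anns = annotate.identify_run1(m, db, rt_tol=0.2)
        anns2 = annotate.extend_run2(anns, m, db, rt_tol=0.1)
        assert [a for a in anns2 if a.run == 2] == []

    def test_zero_noise_precision_recall_perfect(self, full_chain):
        """Compound-level precision and recall are both 1.0 on the
        zero-noise study with a complete database."""
        compounds, _, _, _, clusters = full_chain
        predicted = {cl.compound_id for cl in clusters}
        truth = {c.name for c in compounds}
        assert predicted == truth

    def test_require_trend_excludes_decorrelated_member(self, full_chain,
                                                        small_matrix):
        compounds, db, anns2, links, _ = full_chain
        clusters = annotate.cluster_adducts(anns2, small_matrix, links,
                                            rt_tol=0.1, require_trend=True,
                                            trend_r_min=0.8)
        # zero-noise: all true members share the trend, clusters unchanged
        sizes = sorted(len(c.members) for c in clusters
                       if len(c.members) > 1)
        assert sizes and all(s == 4 for s in sizes)


class TestXenobiotic:
    def test_oxidation_metabolite_labeled(self):
        parent = simdata.SimCompound("drug", "C8H13NO2", rt=1.0)
        metab = simdata.SimCompound("drug+O", "C8H13NO3", rt=1.6)
        runs, _ = simdata.simulate_study([parent, metab], {"A": 2},
                                         noise_sigma=0.0, seed=9,
                                         k_isotopologues=1)
        m = features.process_study(runs, {"snr_min": 3.0})
        labels = annotate.search_xenobiotic_metabolites(
            m, [("drug", "C8H13NO2")], rules=["oxidation"], depth=1)
        assert len(labels) == 1
        (fname, tags), = labels.items()
        assert "via oxidation" in tags[0]
        expect = chem.adduct_mz(chem.monoisotopic_mass("C8H13NO3"), "[M+H]+")
        assert m.features[fname].mz == pytest.approx(expect, abs=1e-3)

    def test_no_products_no_labels(self, small_matrix):
        labels = annotate.search_xenobiotic_metabolites(
            small_matrix, [("drug", "C40H80N10")], rules=["glucuronidation"])
        assert labels == {}

    def test_labels_coexist_with_db_annotations(self, identified,
                                                small_matrix):
        """Advisory labels never override database annotations."""
        compounds, db, anns = identified
        # cmpd01 is cmpd00 + CH2; demethylation of cmpd01 "predicts" cmpd00
        labels = annotate.search_xenobiotic_metabolites(
            small_matrix, [("parent", compounds[1].formula)],
            rules=["demethylation"], depth=1)
        labeled_features = set(labels)
        annotated = {a.feature for a in anns if a.compound_id == "cmpd00"}
        assert labeled_features & annotated
        for a in anns:
            if a.feature in labeled_features and a.compound_id == "cmpd00":
                assert a.color == "green"  # annotation untouched
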