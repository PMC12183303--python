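"""Decay weights, publication weights and per-pair metric aggregation."""
import math
import random
from datetime import date, timedelta

import pytest
from hypothesis import given, settings, strategies as st

from trialtarget import (
    DecayConfig,
    ReferenceType,
    ReferenceWeights,
    build_evidence,
    compute_pair_metrics,
    decay_weight,
    n_publication_weighted,
    n_study_newness,
    reference_weight,
    resolve_as_of,
    study_age,
)
from trialtarget.scoring import NoUsableDateError

from conftest import make_disease_link, make_drug_link, make_ref, make_study


class TestStudyAge:
    def test_zero_when_as_of_equals_completion(self):
        s = make_study(completion=date(2020, 1, 1))
        assert study_age(s, date(2020, 1, 1)) == 0.0

    def test_day_count_over_mean_year_length(self):
        s = make_study(completion=date(2010, 1, 1))
        got = study_age(s, date(2010, 1, 1) + timedelta(days=3652))
        assert got == pytest.approx(3652 / 365.25)  # ~9.9986 years

    def test_future_dated_study_floored_at_zero(self):
        s = make_study(completion=date(2030, 1, 1))
        assert study_age(s, date(2020, 1, 1)) == 0.0

    def test_falls_back_to_start_date(self):
        s = make_study(start=date(2015, 1, 1), completion=None)
        assert study_age(s, date(2016, 1, 1)) == pytest.approx(365 / 365.25)

    def test_undated_study_signals_no_usable_date(self):
        s = make_study(start=None, completion=None)
        with pytest.raises(NoUsableDateError):
            study_age(s, date(2020, 1, 1))

    def test_auto_as_of_is_latest_reference_date(self):
        studies = [make_study(completion=date(2019, 5, 1)),
                   make_study(nct="NCT2", completion=None, start=date(2021, 2, 3)),
                   make_study(nct="NCT3", completion=None, start=None)]
        assert resolve_as_of(studies, DecayConfig()) == date(2021, 2, 3)


class TestDecayWeight:
    def test_new_study_counts_double(self):
        assert decay_weight(0.0) == 2.0

    def test_recent_branch_value(self):
        assert decay_weight(5.0) == pytest.approx(2 * math.exp(-1), abs=1e-6)

    def test_old_branch_value(self):
        assert decay_weight(20.0) == pytest.approx(2 * math.exp(-2), abs=1e-6)

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            decay_weight(-0.1)

    def test_threshold_discontinuity_is_literal(self):
        # weight jumps upward just past the 10-year boundary by design
        assert decay_weight(10.0) == pytest.approx(2 * math.exp(-2))
        assert decay_weight(10.0 + 1e-9) == pytest.approx(2 * math.exp(-1), rel=1e-6)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.floats(min_value=0, max_value=200, allow_nan=False),
           st.floats(min_value=0, max_value=200, allow_nan=False))
    def test_bounded_and_monotone_within_branch(self, a, b):
        cfg = DecayConfig()
        wa, wb = decay_weight(a, cfg), decay_weight(b, cfg)
        assert 0 < wa <= 2 and 0 < wb <= 2
        same_branch = (a <= cfg.age_threshold) == (b <= cfg.age_threshold)
        if same_branch and a < b:
            assert wa >= wb
            if b - a > 1e-9:  # strict decrease once the gap is resolvable in floats
                assert wa > wb


class TestNewnessAndPublicationWeights:
    def test_empty_ages_sum_to_zero(self):
        assert n_study_newness([]) == 0.0

    def test_two_study_sum(self):
        assert n_study_newness([0, 5]) == pytest.approx(2 + 2 * math.exp(-1))

    def test_reference_type_weight_map(self):
        w = ReferenceWeights()
        assert reference_weight(ReferenceType.RESULT, w) == 1.0
        assert reference_weight(ReferenceType.BACKGROUND, w) == 0.5
        assert reference_weight(ReferenceType.DERIVED, w) == 0.25

    def test_unknown_reference_type_gets_lowest_weight(self):
        assert reference_weight("EDITORIAL") == 0.25

    def test_mixed_types_sum(self):
        refs = [("p1", ReferenceType.RESULT), ("p2", ReferenceType.BACKGROUND),
                ("p3", ReferenceType.DERIVED)]
        assert n_publication_weighted(refs) == pytest.approx(1.75)

    def test_pmid_dedupe_keeps_max_weight(self):
        refs = [("p1", ReferenceType.BACKGROUND), ("p1", ReferenceType.RESULT)]
        assert n_publication_weighted(refs) == 1.0

    def test_empty_is_zero(self):
        assert n_publication_weighted([]) == 0.0

    def test_invalid_weight_ordering_rejected(self):
        with pytest.raises(ValueError):
            ReferenceWeights(result=0.5, background=1.0, derived=0.25)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.tuples(st.sampled_from(["p1", "p2", "p3", "p4"]),
                              st.sampled_from(list(ReferenceType)))))
    def test_bounded_by_result_weight_times_npub(self, refs):
        w = ReferenceWeights()
        total = n_publication_weighted(refs, w)
        npub = len({p for p, _ in refs})
        assert total <= npub * w.result + 1e-12
        if refs and all(t is ReferenceType.RESULT for _, t in refs):
            assert total == pytest.approx(npub * w.result)


class TestComputePairMetrics:
    def _fixture(self):
        as_of = date(2024, 9, 30)
        studies = [
            make_study(nct="NCT1", completion=as_of),                        # age 0
            make_study(nct="NCT2", completion=date(2019, 9, 30)),            # ~5y
            make_study(nct="NCT3", completion=None, start=None),             # undated
        ]
        refs = [make_ref(nct="NCT1", pmid="p1"),
                make_ref(nct="NCT1", pmid="p2", rtype=ReferenceType.BACKGROUND),
                make_ref(nct="NCT2", pmid="p3", rtype=ReferenceType.DERIVED),
                make_ref(nct="NCT2", pmid=None, rtype=ReferenceType.RESULT)]
        drug_links = [make_drug_link(nct="NCT1", drug="a", gene="G1"),
                      make_drug_link(nct="NCT2", drug="b", gene="G1"),
                      make_drug_link(nct="NCT3", drug="a", gene="G1")]
        disease_links = [make_disease_link(nct="NCT1", doid="DOID:1"),
                         make_disease_link(nct="NCT2", doid="DOID:1"),
                         make_disease_link(nct="NCT3", doid="DOID:2")]
        return studies, refs, drug_links, disease_links

    def test_hand_counted_fixture(self):
        studies, refs, drug_links, disease_links = self._fixture()
        rows, _ = build_evidence(studies, refs, drug_links, disease_links)
        pairs = {(p.doid, p.gene_symbol): p
                 for p in compute_pair_metrics(rows, studies=studies)}
        p = pairs[("DOID:1", "G1")]
        assert (p.nStud, p.nPub, p.nDrug) == (2, 3, 2)
        assert p.nDiseases == 2  # G1 appears under DOID:1 and DOID:2 set-wide
        age2 = (date(2024, 9, 30) - date(2019, 9, 30)).days / 365.25
        assert p.nStudyNewness == pytest.approx(2.0 + 2 * math.exp(-age2 / 5))
        # p1 RESULT + p2 BACKGROUND + p3 DERIVED; the pmid-less RESULT ref is excluded
        assert p.nPublicationWeighted == pytest.approx(1.75)

    def test_undated_study_still_counts_toward_nstud(self):
        studies, refs, drug_links, disease_links = self._fixture()
        rows, _ = build_evidence(studies, refs, drug_links, disease_links)
        pairs = {(p.doid, p.gene_symbol): p
                 for p in compute_pair_metrics(rows, studies=studies)}
        p = pairs[("DOID:2", "G1")]
        assert p.nStud == 1
        assert p.nStudyNewness == 0.0  # no usable date, excluded from newness
        assert p.nPub == 0 and p.nPublicationWeighted == 0.0  # still emitted

    def test_duplicate_provenance_rows_do_not_inflate(self):
        """Replicated references leave study counts and newness unchanged."""
        studies = [make_study(nct="NCT1", completion=date(2024, 1, 1))]
        refs = [make_ref(nct="NCT1", pmid="p1", rtype=t) for t in ReferenceType]
        rows, _ = build_evidence(studies, refs, [make_drug_link(nct="NCT1")],
                                 [make_disease_link(nct="NCT1")])
        assert len(rows) == 3
        (p,) = compute_pair_metrics(rows, studies=studies)
        assert p.nStud == 1 and p.nPub == 1
        assert p.nStudyNewness == pytest.approx(2.0)
        assert p.nPublicationWeighted == 1.0  # max weight across the pmid's types

    def test_matches_brute_force_recount(self):
        """Metrics equal an independent per-pair recount on a random fixture."""
        rng = random.Random(3)
        as_of = date(2024, 9, 30)
        studies = [make_study(nct=f"NCT{i}",
                              completion=date(rng.randrange(1998, 2025), 6, 15))
                   for i in range(30)]
        ncts = [s.nct_id for s in studies]
        drug_links = [make_drug_link(nct=rng.choice(ncts), drug=f"d{rng.randrange(8)}",
                                     gene=f"G{rng.randrange(6)}") for _ in range(40)]
        disease_links = [make_disease_link(nct=rng.choice(ncts), doid=f"DOID:{rng.randrange(5)}")
                         for _ in range(30)]
        refs = [make_ref(nct=rng.choice(ncts), pmid=str(rng.randrange(50, 80)),
                         rtype=rng.choice(list(ReferenceType))) for _ in range(40)]
        rows, _ = build_evidence(studies, refs, drug_links, disease_links)
        cfg = DecayConfig(as_of_date=as_of)
        pairs = compute_pair_metrics(rows, decay=cfg, studies=studies)
        assert pairs  # fixture produces a non-trivial table

        by_nct = {s.nct_id: s for s in studies}
        wmap = {ReferenceType.RESULT: 1.0, ReferenceType.BACKGROUND: 0.5,
                ReferenceType.DERIVED: 0.25}
        keys = {(r.doid, r.gene_symbol) for r in rows}
        for doid, gene in keys:
            sub = [r for r in rows if r.doid == doid and r.gene_symbol == gene]
            p = next(x for x in pairs if (x.doid, x.gene_symbol) == (doid, gene))
            assert p.nStud == len({r.nct_id for r in sub})
            assert p.nPub == len({r.pmid for r in sub if r.pmid})
            assert p.nDrug == len({r.drug_name for r in sub})
            assert p.nDiseases == len({r.doid for r in rows if r.gene_symbol == gene})
            ages = {r.nct_id: (as_of - by_nct[r.nct_id].completion_date).days / 365.25
                    for r in sub}
            expect_newness = sum(2 * math.exp(-max(t, 0) / (5 if t <= 10 else 10))
                                 for t in ages.values())
            assert p.nStudyNewness == pytest.approx(expect_newness)
            best = {}
            for r in sub:
                if r.pmid:
                    best[r.pmid] = max(best.get(r.pmid, 0.0), wmap[r.reference_type])
            assert p.nPublicationWeighted == pytest.approx(sum(best.values()))
            # spec'd bounds
            assert p.nStudyNewness <= 2 * p.nStud + 1e-9
            assert p.nPublicationWeighted <= p.nPub + 1e-9
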