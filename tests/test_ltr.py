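"""Flank anchoring, five-way classification and twin-LTR dating."""

import numpy as np
import pytest

from bloodpeach.io import GenomeIndex
from bloodpeach.ltr import (
    LtrComparison,
    LtrElement,
    TargetIndex,
    anchor_flank,
    element_age,
    estimate_age,
    extract_flanks,
    filter_intact,
    pair_anchors,
    revcomp,
)
from bloodpeach.sim import random_genome


def _element(start, end, ltr=516, id="e1", contig="tig1"):
    return LtrElement(id=id, contig=contig, start=start, end=end,
                      ltr5=(start, start + ltr - 1), ltr3=(end - ltr + 1, end))


class TestFilterIntact:
    @pytest.mark.parametrize("length, kept",
                             [(6688, True), (1999, False), (2000, True),
                              (7000, True), (7001, False)])
    def test_inclusive_bounds(self, length, kept):
        el = _element(10_001, 10_000 + length, ltr=300)
        assert (el in filter_intact([el])) is kept


class TestExtractFlanks:
    @pytest.fixture
    def genome(self, rng):
        return GenomeIndex({"tig1": random_genome(40_000, rng)})

    def test_coordinate_arithmetic(self, genome):
        fl = extract_flanks(_element(10_001, 16_688), genome)
        assert fl.up_span == (9_501, 10_000)
        assert fl.down_span == (16_689, 17_188)

    def test_round_trip_against_genome(self, genome):
        fl = extract_flanks(_element(10_001, 16_688), genome)
        assert fl.up == genome.fetch("tig1", 9_501, 10_000)
        assert fl.down == genome.fetch("tig1", 16_689, 17_188)

    def test_element_at_contig_start_has_no_up_flank(self, genome):
        fl = extract_flanks(_element(1, 6_688), genome)
        assert fl.up is None and fl.down is not None

    def test_short_clipped_flank_dropped(self, genome):
        fl = extract_flanks(_element(51, 6_738), genome, min_flank=100)
        assert fl.up is None  # only 50 bp available upstream

    def test_element_outside_contig_errors(self, genome):
        with pytest.raises(ValueError):
            extract_flanks(_element(39_000, 45_999), genome)


class TestAnchorFlank:
    def _target(self, seq):
        return TargetIndex(GenomeIndex({"t1": seq}))

    def test_verbatim_copy_unique_full_score(self, rng):
        flank = random_genome(500, rng)
        target = self._target(random_genome(3_000, rng) + flank + random_genome(3_000, rng))
        hit = anchor_flank(flank, target)
        assert hit.unique
        assert hit.score == 500
        assert hit.start == 3_001 and hit.end == 3_500
        assert hit.orientation == "+"

    def test_duplicated_flank_not_unique(self, rng):
        flank = random_genome(500, rng)
        pad = random_genome(2_000, rng)
        target = self._target(pad + flank + pad + flank + pad)
        hit = anchor_flank(flank, target)
        assert not hit.unique
        assert hit.score == hit.second_best_score == 500

    def test_two_mismatches_score_len_minus_4(self, rng):
        flank = random_genome(500, rng)
        mutated = list(flank)
        for i in (100, 400):
            mutated[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[i]]
        target = self._target(random_genome(1_000, rng) + "".join(mutated)
                              + random_genome(1_000, rng))
        hit = anchor_flank(flank, target)
        assert hit.score == 500 - 4

    def test_reverse_complement_hit_found(self, rng):
        flank = random_genome(500, rng)
        target = self._target(random_genome(1_000, rng) + revcomp(flank)
                              + random_genome(1_000, rng))
        hit = anchor_flank(flank, target)
        assert hit.unique and hit.orientation == "-"

    def test_no_seed_match_returns_none(self, rng):
        assert anchor_flank("A" * 200, self._target("C" * 5_000)) is None

    def test_empty_flank_errors(self, rng):
        with pytest.raises(ValueError):
            anchor_flank("", self._target("ACGT" * 100))


class TestPairAnchors:
    def _hit(self, start, end, contig="t1", orientation="+", unique=True):
        from bloodpeach.ltr import AnchorHit

        return AnchorHit(side="up", contig=contig, start=start, end=end,
                         orientation=orientation, score=500.0,
                         second_best_score=0.0, unique=unique)

    def test_intact_target_copy_is_present(self):
        el = _element(10_001, 13_000, ltr=300)
        g = pair_anchors(self._hit(1, 500), self._hit(3_501, 4_000), el)
        assert g.kind == "present"
        assert g.gap == 3_000
        assert g.inner_span == (501, 3_500)

    def test_adjacent_anchors_absent(self):
        el = _element(10_001, 13_000, ltr=300)
        g = pair_anchors(self._hit(1, 500), self._hit(496, 995), el)
        assert g.kind == "absent"

    def test_different_contigs_unanchored(self):
        el = _element(10_001, 13_000, ltr=300)
        g = pair_anchors(self._hit(1, 500), self._hit(1_000, 1_499, contig="t2"), el)
        assert g.kind == "unanchored"

    def test_over_20kb_span_unanchored(self):
        el = _element(10_001, 13_000, ltr=300)
        g = pair_anchors(self._hit(1, 500), self._hit(30_000, 30_499), el)
        assert g.kind == "unanchored"

    def test_non_unique_hit_unanchored(self):
        el = _element(10_001, 13_000, ltr=300)
        g = pair_anchors(self._hit(1, 500, unique=False),
                         self._hit(3_501, 4_000), el)
        assert g.kind == "unanchored"


class TestClassification:
    def test_truth_table_agreement(self, pav_fixture):
        query, truth, target, expected = pav_fixture
        elements = [LtrElement.from_gff(t.to_gff_element()) for t in truth]
        res = LtrComparison(query, elements, target).fit()
        assert res.labels() == expected

    def test_self_comparison_all_high_shared(self, pav_fixture):
        query, truth, _, _ = pav_fixture
        elements = [LtrElement.from_gff(t.to_gff_element()) for t in truth]
        res = LtrComparison(query, elements, query).fit()
        assert set(res.labels().values()) == {"HIGH_SHARED"}

    def test_classification_total_one_label_each(self, pav_fixture):
        query, truth, target, _ = pav_fixture
        elements = [LtrElement.from_gff(t.to_gff_element()) for t in truth]
        res = LtrComparison(query, elements, target).fit()
        assert len(res.table) == len(elements)
        assert res.table["label"].isin(
            ["HIGH_SHARED", "LOW_SHARED", "INSERTION", "ELIMINATION", "UNKNOWN"]
        ).all()
        assert sum(res.class_counts.values()) == len(elements)

    def test_summary_reports_mu_and_counts(self, pav_fixture):
        query, truth, target, _ = pav_fixture
        elements = [LtrElement.from_gff(t.to_gff_element()) for t in truth]
        res = LtrComparison(query, elements, target).fit()
        assert "mu = 1.5e-08" in res.summary()
        assert "HIGH_SHARED" in res.summary()


class TestAge:
    def test_identical_ltrs_age_zero(self):
        a = estimate_age("ACGTACGTAA" * 30, "ACGTACGTAA" * 30)
        assert a.d == 0.0 and a.K == 0.0 and a.T == 0.0

    def test_closed_form_example(self):
        # d = 0.02 -> K = -(3/4) ln(1 - 4*0.02/3) ~ 0.020273; T = K / (2 mu)
        rng = np.random.default_rng(5)
        ltr = random_genome(500, rng)
        mutated = list(ltr)
        pos = rng.choice(500, 10, replace=False)
        for i in pos:
            mutated[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[i]]
        a = estimate_age(ltr, "".join(mutated), mu=1e-8)
        assert a.d == pytest.approx(0.02, abs=1e-9)
        assert a.K == pytest.approx(0.020273, abs=1e-5)
        assert a.T / 1e6 == pytest.approx(1.0136, abs=0.001)

    def test_saturation_errors(self):
        # d = 0.8 between unalignable-level divergent copies
        a = "A" * 400
        b = ("A" * 1 + "C" * 4) * 80  # 80% mismatching columns
        with pytest.raises(ValueError, match="saturation"):
            estimate_age(a, b)

    def test_monotone_in_divergence(self):
        rng = np.random.default_rng(9)
        ltr = random_genome(600, rng)
        ages = []
        for n_mut in (0, 6, 18, 36):
            m = list(ltr)
            for i in rng.choice(600, n_mut, replace=False):
                m[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[m[i]]
            ages.append(estimate_age(ltr, "".join(m)).T)
        assert ages == sorted(ages)
        assert ages[0] == 0.0

    def test_element_age_uses_annotated_spans(self, pav_fixture):
        query, truth, _, _ = pav_fixture
        gi = GenomeIndex(query)
        el = LtrElement.from_gff(truth[0].to_gff_element())
        age = element_age(el, gi)
        # fixture plants 1% per-LTR divergence: ~2% between the copies
        assert 0.0 < age.d < 0.06

    def test_invalid_mu_errors(self):
        with pytest.raises(ValueError):
            estimate_age("ACGT" * 100, "ACGT" * 100, mu=0)
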