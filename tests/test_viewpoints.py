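"""Viewpoint scores and the three construction strategies."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

from chcdesign.alignability import load_alignability
from chcdesign.digestion import digest_genome, get_enzyme
from chcdesign.fixtures import FixtureSpec, make_alignability, make_genome
from chcdesign.genome import GenomeHandle
from chcdesign.params import DesignParameters
from chcdesign.probes import REJECTED
from chcdesign.targets import Target
from chcdesign.viewpoints import (
    ScoreModel,
    build_extended_viewpoint,
    build_simple_viewpoint,
    extended_score,
    patch_viewpoint,
    reset_viewpoint,
    set_digest_selected,
    simple_score,
)

MODEL = ScoreModel(mu_D_bar=600.0, up_max=5000, down_max=1500)  # sigma_simple = 100


class TestSimpleScore:
    def test_three_sigma_span(self):
        assert simple_score(1000 - 300, 1000 + 300, 1000, MODEL) == pytest.approx(
            2 * norm.cdf(3) - 1, abs=1e-9
        )

    def test_tss_at_digest_end_scores_half(self):
        assert simple_score(1000, 1000 + 10 * 100, 1000, MODEL) == pytest.approx(
            0.5, abs=1e-3
        )

    def test_long_centred_digest_scores_one(self):
        assert simple_score(1000 - 600, 1000 + 600, 1000, MODEL) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_empty_span_scores_zero(self):
        assert simple_score(1000, 1000, 1000, MODEL) == 0.0

    @given(st.integers(0, 2000), st.integers(0, 2000))
    def test_symmetry_about_the_tss(self, a, b):
        tss = 5000
        assert simple_score(tss - a, tss + b, tss, MODEL) == pytest.approx(
            simple_score(tss - b, tss + a, tss, MODEL), abs=1e-12
        )

    @given(st.integers(0, 1000), st.integers(0, 1000), st.integers(0, 300),
           st.integers(0, 300))
    def test_monotone_in_span_extension(self, a, b, da, db):
        tss = 5000
        base = simple_score(tss - a, tss + b, tss, MODEL)
        wider = simple_score(tss - a - da, tss + b + db, tss, MODEL)
        assert wider >= base - 1e-12
        assert 0.0 <= wider <= 1.0

    @given(st.integers(1, 12))
    def test_limit_matches_closed_form(self, n):
        tss = 50_000
        span = simple_score(tss - n * 100, tss + n * 100, tss, MODEL)
        assert span == pytest.approx(2 * norm.cdf(n) - 1, abs=1e-12)


def riemann_extended(intervals, tss, strand, model):
    """Midpoint Riemann sum of the piecewise half-normal density, 1 bp steps."""
    total = 0.0
    for s, e in intervals:
        for b in range(s, e):
            d = (b - tss) if strand == "+" else (tss - b)
            mid = d + 0.5
            sigma = model.sigma_down if mid >= 0 else model.sigma_up
            total += norm.pdf(mid / sigma) / sigma
    return total


class TestExtendedScore:
    def test_full_window_coverage_is_100(self):
        tss = 40_000
        iv = [(tss - 6 * int(MODEL.sigma_up), tss + 6 * int(MODEL.sigma_down))]
        assert extended_score(iv, tss, "+", MODEL) == pytest.approx(100.0, abs=0.01)

    def test_no_digests_scores_zero(self):
        assert extended_score([], 1000, "+", MODEL) == 0.0

    def test_upstream_half_only_scores_50(self):
        tss = 40_000
        assert extended_score([(tss - 5000, tss)], tss, "+", MODEL) == pytest.approx(
            50.0, abs=0.05
        )

    def test_digests_near_tss_contribute_more(self):
        tss = 40_000
        near = extended_score([(tss, tss + 100)], tss, "+", MODEL)
        far = extended_score([(tss + 1000, tss + 1100)], tss, "+", MODEL)
        assert near > far > 0

    def test_agrees_with_riemann_integration(self):
        tss = 40_000
        intervals = [
            (tss - 2000, tss - 500),
            (tss - 100, tss + 300),
            (tss + 700, tss + 1200),
        ]
        for strand in "+-":
            cdf_based = extended_score(intervals, tss, strand, MODEL) / 100.0
            riemann = riemann_extended(intervals, tss, strand, MODEL)
            assert cdf_based == pytest.approx(riemann, abs=1e-6)

    def test_strand_mirror_equivalence(self):
        tss = 40_000
        intervals = [(tss - 900, tss - 200), (tss + 50, tss + 600)]
        mirrored = [(2 * tss - e + 1, 2 * tss - s + 1) for s, e in intervals]
        minus = extended_score(intervals, tss, "-", MODEL)
        plus = extended_score(mirrored, tss, "+", MODEL)
        assert minus == pytest.approx(plus, abs=1e-12)


@pytest.fixture(scope="module")
def vp_env(tmp_path_factory):
    """12.9 kb chromosome, DpnII digests of 430 bp plus one 82 bp digest and
    one digest with unmappable margins."""
    d = tmp_path_factory.mktemp("vp")
    length = 12_900
    cuts = [c for c in range(430, length, 430)] + [6532]
    spec = FixtureSpec(
        chrom_lengths={"chr1": length},
        cut_sites={"chr1": {"DpnII": sorted(cuts)}},
        alignability={"chr1": [(0, 10_300, 1.0), (10_760, length, 1.0)]},
        seed=11,
    )
    genome = GenomeHandle(make_genome(spec, d / "g.fa"))
    amap = load_alignability(make_alignability(spec, d / "a.bedgraph"))
    params = DesignParameters()
    digest_map = digest_genome(genome, [get_enzyme("DpnII")])
    model = ScoreModel.from_design(digest_map, params)
    return genome, amap, params, digest_map, model


def build(env, tss, strand="+", approach="simple", **overrides):
    genome, amap, params, digest_map, model = env
    params = params.with_(**overrides) if overrides else params
    target = Target("G", "chr1", tss, strand)
    fn = build_extended_viewpoint if approach == "extended" else build_simple_viewpoint
    return fn(target, digest_map, genome, amap, params, model), params, model


class TestSimpleViewpoint:
    def test_tss_mid_digest_selects_it(self, vp_env):
        vp, _, model = build(vp_env, 5375)
        assert vp.is_valid and len(vp.selected) == 1
        assert vp.span == (5160, 5590)
        assert vp.score == pytest.approx(simple_score(5160, 5590, 5375, model))
        assert vp.tss_digest_selected

    def test_short_tss_digest_gives_invalid_viewpoint(self, vp_env):
        vp, _, _ = build(vp_env, 6500)  # inside the 82 bp digest [6450, 6532)
        assert not vp.is_valid and vp.score == 0.0
        assert vp.tss_digest_key == ("chr1", 6450, 6532)

    def test_adjacent_unusable_digest_is_not_available(self, vp_env):
        vp, _, _ = build(vp_env, 6100)  # digest [6020,6450); 3' neighbour is short
        na = vp.candidate_by_key(("chr1", 6450, 6532))
        assert na.digest_class == REJECTED and not na.available

    def test_three_candidates_with_tss_digest_in_middle(self, vp_env):
        vp, _, _ = build(vp_env, 5375)
        keys = [c.key for c in vp.candidates]
        assert keys == [("chr1", 4730, 5160), ("chr1", 5160, 5590), ("chr1", 5590, 6020)]


class TestPatching:
    def test_low_score_adds_nearer_neighbour(self, vp_env):
        vp, params, model = build(vp_env, 5165, allow_patching=True)
        before = vp.score
        assert before < params.patch_threshold
        patch_viewpoint(vp, params, model)
        assert vp.patched
        assert vp.span == (4730, 5590)  # 5' neighbour joined
        assert vp.score > before

    def test_good_score_left_unchanged(self, vp_env):
        vp, params, model = build(vp_env, 5375, allow_patching=True)
        before = vp.score
        patch_viewpoint(vp, params, model)
        assert not vp.patched and vp.score == before and len(vp.selected) == 1

    def test_failing_neighbour_blocks_patch(self, vp_env):
        # TSS near the 5' end of [6532, 6880); the nearer neighbour is 82 bp
        vp, params, model = build(vp_env, 6540, allow_patching=True)
        assert vp.score < params.patch_threshold
        patch_viewpoint(vp, params, model)
        assert not vp.patched and len(vp.selected) == 1


class TestExtendedViewpoint:
    def test_window_filters_and_selects(self, vp_env):
        vp, params, _ = build(vp_env, 9460, approach="extended")
        sel_keys = {c.key for c in vp.selected}
        # the short digest and the unmappable-margin digest stay unselected
        assert ("chr1", 6450, 6532) not in sel_keys
        assert ("chr1", 10320, 10750) not in sel_keys
        cand_keys = {c.key for c in vp.candidates}
        assert ("chr1", 6450, 6532) in cand_keys
        assert ("chr1", 10320, 10750) in cand_keys
        assert len(vp.candidates) - len(vp.selected) == 2
        for c in vp.selected:
            assert c.digest_class != REJECTED

    def test_minus_strand_window_is_reflected(self, vp_env):
        plus, _, _ = build(vp_env, 6880, approach="extended")
        minus, _, _ = build(vp_env, 6880, strand="-", approach="extended")
        lo_p = min(c.digest.start for c in plus.candidates)
        hi_p = max(c.digest.end for c in plus.candidates)
        lo_m = min(c.digest.start for c in minus.candidates)
        hi_m = max(c.digest.end for c in minus.candidates)
        # upstream extension flips to the higher-coordinate side
        assert 6880 - lo_p > hi_p - 6880
        assert hi_m - 6880 > 6880 - lo_m

    def test_score_within_percent_bounds(self, vp_env):
        vp, _, _ = build(vp_env, 9460, approach="extended")
        assert 0.0 < vp.score <= 100.0


class TestManualEditing:
    def test_deselect_only_digest_invalidates(self, vp_env):
        vp, _, model = build(vp_env, 5375)
        set_digest_selected(vp, ("chr1", 5160, 5590), False, model)
        assert not vp.is_valid and vp.score == 0.0 and vp.manually_edited

    def test_select_neighbour_increases_score_for_offcentre_tss(self, vp_env):
        vp, _, model = build(vp_env, 5165)
        before = vp.score
        set_digest_selected(vp, ("chr1", 4730, 5160), True, model)
        assert vp.score > before

    def test_non_candidate_digest_is_an_error(self, vp_env):
        vp, _, model = build(vp_env, 5375)
        with pytest.raises(KeyError):
            set_digest_selected(vp, ("chr1", 0, 430), True, model)

    def test_rejected_candidate_cannot_be_selected(self, vp_env):
        vp, _, model = build(vp_env, 6100)
        with pytest.raises(ValueError, match="n/a"):
            set_digest_selected(vp, ("chr1", 6450, 6532), True, model)

    def test_reset_restores_original_state(self, vp_env):
        vp, _, model = build(vp_env, 5375)
        original = ([c.selected for c in vp.candidates], vp.score)
        set_digest_selected(vp, ("chr1", 5160, 5590), False, model)
        set_digest_selected(vp, ("chr1", 4730, 5160), True, model)
        reset_viewpoint(vp, model)
        assert ([c.selected for c in vp.candidates], vp.score) == original
        assert not vp.manually_edited
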