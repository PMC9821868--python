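import numpy as np
import pandas as pd
import pytest

from sleepv2g.restriction import FragmentMap
from sleepv2g.v2g import (
    FOUR_FRAGMENT,
    ONE_FRAGMENT,
    BaitedPromoter,
    ExpressionRecord,
    Interaction,
    Peak,
    ProxyVariant,
    SentinelSignal,
    annotate_loops,
    attach_percentiles,
    expand_proxies,
    filter_expression,
    flag_open_baits,
    overlap_peaks,
    summarize_v2g,
)


def sentinel(signal="rsS", locus="L1", chrom="chr1", pos=100):
    return SentinelSignal(signal, chrom, pos, locus, signal)


class TestExpandProxies:
    def test_strict_cutoff(self):
        ld = pd.DataFrame(
            [("rsS", f"rs{i}", "chr1", 10 + i, r2) for i, r2 in enumerate([0.84, 0.71, 0.70])],
            columns=["sentinel_id", "rsid", "chrom", "pos", "r2"],
        )
        out = expand_proxies([sentinel()], ld, 0.7)
        rsids = {p.rsid for p in out}
        assert rsids == {"rsS", "rs0", "rs1"}  # 0.70 dropped, sentinel added

    def test_sentinel_without_records_is_its_own_proxy(self):
        out = expand_proxies([sentinel()], pd.DataFrame(columns=["sentinel_id", "rsid", "chrom", "pos", "r2"]))
        assert len(out) == 1 and out[0].r2 == 1.0 and out[0].rsid == "rsS"

    def test_duplicates_keep_max_r2(self):
        ld = pd.DataFrame(
            [("rsS", "rsA", "chr1", 5, 0.75), ("rsS", "rsA", "chr1", 5, 0.92)],
            columns=["sentinel_id", "rsid", "chrom", "pos", "r2"],
        )
        out = expand_proxies([sentinel()], ld)
        assert [p.r2 for p in out if p.rsid == "rsA"] == [0.92]

    def test_unknown_sentinel_error(self):
        ld = pd.DataFrame([("rsX", "rsA", "chr1", 5, 0.8)],
                          columns=["sentinel_id", "rsid", "chrom", "pos", "r2"])
        with pytest.raises(ValueError, match="unknown sentinel"):
            expand_proxies([sentinel()], ld)

    def test_matches_naive_row_filter(self, rng):
        sentinels = [sentinel(f"rsS{i}", f"L{i}") for i in range(5)]
        rows = [
            (f"rsS{rng.integers(5)}", f"rs{j}", "chr1", int(rng.integers(1, 10_000)),
             float(rng.uniform(0, 1)))
            for j in range(500)
        ]
        ld = pd.DataFrame(rows, columns=["sentinel_id", "rsid", "chrom", "pos", "r2"])
        out = expand_proxies(sentinels, ld, 0.7)
        naive = {}
        for sid, rsid, chrom, pos, r2 in rows:
            if r2 > 0.7 and naive.get((sid, rsid), -1) < r2:
                naive[(sid, rsid)] = r2
        for s in sentinels:
            naive[(s.signal_id, s.rsid)] = 1.0
        assert {(p.sentinel_id, p.rsid): p.r2 for p in out} == pytest.approx(naive)


class TestOverlapPeaks:
    def proxy(self, pos):
        return ProxyVariant("rsP", "chr1", pos, 0.8, "rsS", "L1")

    def test_halfopen_containment(self):
        peaks = [Peak("pk1", "chr1", 100, 200)]
        inside, = overlap_peaks([self.proxy(101)], peaks)  # 1-based 101 -> 0-based 100
        assert inside.open_flag and inside.peak_id == "pk1"
        outside, = overlap_peaks([self.proxy(201)], peaks)  # 0-based 200 = peak end
        assert not outside.open_flag and outside.peak_id is None

    def test_empty_peaks_all_closed(self):
        assert not overlap_peaks([self.proxy(5)], [])[0].open_flag

    def test_matches_allpairs_oracle(self, rng):
        peaks = [
            Peak(f"pk{i}", "chr1", int(s), int(s) + int(rng.integers(10, 500)))
            for i, s in enumerate(rng.integers(0, 50_000, size=300))
        ]
        proxies = [
            ProxyVariant(f"rs{i}", "chr1", int(p), 0.9, "rsS", "L1")
            for i, p in enumerate(rng.integers(1, 50_001, size=1000))
        ]
        got = overlap_peaks(proxies, peaks)
        for p, g in zip(proxies, got):
            hits = [pk for pk in peaks if pk.start <= p.pos - 1 < pk.end]
            assert g.open_flag == bool(hits)
            if hits:
                best = min(hits, key=lambda k: (k.start, k.end, k.peak_id))
                assert g.peak_id == best.peak_id


class LoopFixture:
    """Hand-built geometry: 10-unit fragments on a 200 bp chromosome.

    map1 fragments are [0,20), [20,40), ...; the proxy sits in fragment 7
    ([140,160)), the bait occupies fragment 2 ([40,60)).
    """

    def __init__(self):
        self.map1 = FragmentMap({"chr1": np.arange(0, 201, 20)})
        self.map4 = self.map1.concat(4)
        self.bait = BaitedPromoter("B", "chr1", 40, 60, ["G"], [True])
        self.bait2 = BaitedPromoter("B2", "chr1", 120, 140, ["H"], [False])
        self.peaks = [Peak("pkP", "chr1", 145, 155), Peak("pkB", "chr1", 45, 55)]

    def proxy(self, pos1=150):
        p = ProxyVariant("rsP", "chr1", pos1, 0.84, "rsS", "L1")
        return overlap_peaks([p], self.peaks)[0]

    def baits(self):
        return flag_open_baits([self.bait, self.bait2], self.peaks)

    def interaction(self, score=5.3, resolution=ONE_FRAGMENT, bait_id="B"):
        if resolution == ONE_FRAGMENT:
            oe = (140, 160)
        else:
            oe = (80, 160)  # four-fragment bin containing fragment 7
        return Interaction(bait_id, "chr1", oe[0], oe[1], score, resolution)


class TestAnnotateLoops:
    def test_link_emitted_above_score_cutoff(self):
        fx = LoopFixture()
        for res in (ONE_FRAGMENT, FOUR_FRAGMENT):
            links = annotate_loops([fx.proxy()], [fx.interaction(5.3, res)], fx.baits(),
                                   fx.map1, fx.map4, 5.0)
            assert [(l.rsid, l.gene, l.resolution) for l in links] == [("rsP", "G", res)]

    def test_subthreshold_score_yields_no_link(self):
        fx = LoopFixture()
        assert annotate_loops([fx.proxy()], [fx.interaction(4.9)], fx.baits(),
                              fx.map1, fx.map4, 5.0) == []

    def test_proxy_inside_any_bait_excluded(self):
        fx = LoopFixture()
        # 1-based 131 falls inside bait2 [120,140) but also inside a peak
        fx.peaks.append(Peak("pkX", "chr1", 125, 135))
        proxy = fx.proxy(131)
        assert proxy.open_flag
        ia = Interaction("B", "chr1", 120, 140, 8.0, ONE_FRAGMENT)
        assert annotate_loops([proxy], [ia], fx.baits(), fx.map1, fx.map4, 5.0) == []

    def test_closed_bait_yields_no_link(self):
        fx = LoopFixture()
        fx.peaks = [Peak("pkP", "chr1", 145, 155)]  # bait peak removed
        links = annotate_loops([fx.proxy()], [fx.interaction()], fx.baits(),
                               fx.map1, fx.map4, 5.0)
        assert links == []

    def test_closed_proxy_never_links(self):
        fx = LoopFixture()
        p = ProxyVariant("rsP", "chr1", 150, 0.84, "rsS", "L1")  # open_flag False
        assert annotate_loops([p], [fx.interaction()], fx.baits(), fx.map1, fx.map4, 5.0) == []

    def test_unknown_bait_error(self):
        fx = LoopFixture()
        with pytest.raises(ValueError, match="unknown bait"):
            annotate_loops([fx.proxy()], [fx.interaction(bait_id="nope")], fx.baits(),
                           fx.map1, fx.map4, 5.0)

    def test_multiple_genes_per_bait_and_dedup(self):
        fx = LoopFixture()
        fx.bait = BaitedPromoter("B", "chr1", 40, 60, ["G1", "G2"], [True, False])
        ias = [fx.interaction(6.0), fx.interaction(9.0)]  # duplicate geometry
        links = annotate_loops([fx.proxy()], ias, fx.baits(), fx.map1, fx.map4, 5.0)
        assert [(l.gene, l.score) for l in links] == [("G1", 9.0), ("G2", 9.0)]

    def test_monotone_in_cutoff_and_interactions(self):
        fx = LoopFixture()
        ias = [fx.interaction(5.3), fx.interaction(7.0, FOUR_FRAGMENT)]
        n_all = len(annotate_loops([fx.proxy()], ias, fx.baits(), fx.map1, fx.map4, 5.0))
        n_some = len(annotate_loops([fx.proxy()], ias[:1], fx.baits(), fx.map1, fx.map4, 5.0))
        n_high = len(annotate_loops([fx.proxy()], ias, fx.baits(), fx.map1, fx.map4, 6.5))
        assert n_all >= n_some and n_all >= n_high
        assert annotate_loops([fx.proxy()], [], fx.baits(), fx.map1, fx.map4, 5.0) == []


class TestExpression:
    def links(self):
        fx = LoopFixture()
        return annotate_loops([fx.proxy()], [fx.interaction(6.0)], fx.baits(),
                              fx.map1, fx.map4, 5.0)

    @pytest.mark.parametrize(
        "tpm,pct,expressed",
        [(1.6, 51.0, True), (1.5, 99.0, False), (100.0, 50.0, False), (1.6, 50.1, True)],
    )
    def test_strict_conjunction(self, tpm, pct, expressed):
        out = filter_expression(self.links(), [ExpressionRecord("G", tpm, pct)])
        assert out[0].expressed_flag is expressed

    def test_missing_gene_not_expressed(self):
        out = filter_expression(self.links(), [])
        assert out[0].expressed_flag is False

    def test_percentiles_are_percent_ranks_with_tied_average(self):
        recs = {e.gene: e for e in attach_percentiles({"a": 1.0, "b": 2.0, "c": 2.0, "d": 5.0})}
        assert recs["a"].percentile == pytest.approx(25.0)
        assert recs["b"].percentile == recs["c"].percentile == pytest.approx(62.5)
        assert recs["d"].percentile == pytest.approx(100.0)


class TestSummarize:
    def test_empty_links_all_zero(self):
        assert set(summarize_v2g([]).to_dict().values()) == {0}

    def test_hand_enumerated_fixture(self):
        fx = LoopFixture()
        fx.bait = BaitedPromoter("B", "chr1", 40, 60, ["G1", "G2"], [True, False])
        proxies = [fx.proxy(150), fx.proxy(151)]
        proxies[1].rsid = "rsQ"
        links = annotate_loops(proxies, [fx.interaction(6.0)], fx.baits(),
                               fx.map1, fx.map4, 5.0)
        links = filter_expression(links, [ExpressionRecord("G1", 10.0, 90.0)])
        c = summarize_v2g(links).to_dict()
        assert c == {
            "loci_with_link": 1, "informative_proxies": 2, "open_chromatin_regions": 1,
            "open_baited_regions": 1, "genes": 2, "coding_genes": 1,
            "distinct_interactions": 1, "expressed_genes": 1,
        }
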