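"""Variant-to-gene mapping through open chromatin and promoter contacts.

The chain of evidence runs: GWAS sentinel SNP -> LD proxies (r2 above a
cutoff) -> proxies inside ATAC-seq open-chromatin peaks -> restriction
fragments carrying those proxies -> promoter Capture C interactions whose
"other end" overlaps that fragment at the interaction's resolution -> genes
of the (open) baited promoter.  A link is emitted only for non-bait-to-bait
geometry: the proxy itself must not sit in any baited promoter region.
Expression status (TPM and percentile thresholds) annotates links, it does
not remove them.

All thresholds are strict inequalities (r2 > 0.7, score > 5, TPM > 1.5,
percentile > 50) and are exposed as parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import rankdata

from sleepv2g.restriction import FragmentMap

ONE_FRAGMENT = "one_fragment"
FOUR_FRAGMENT = "four_fragment"


@dataclass(frozen=True)
class SentinelSignal:
    rsid: str
    chrom: str
    pos: int  # 1-based
    locus_id: str
    signal_id: str


@dataclass
class ProxyVariant:
    rsid: str
    chrom: str
    pos: int  # 1-based
    r2: float
    sentinel_id: str
    locus_id: str
    open_flag: bool = False
    peak_id: str | None = None
    fragment_index: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0:
            raise ValueError(f"r2 must be in [0,1], got {self.r2}")
        if self.pos < 1:
            raise ValueError("positions are 1-based; pos must be >= 1")

    @property
    def pos0(self) -> int:
        return self.pos - 1


@dataclass(frozen=True)
class Peak:
    peak_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty peak interval {self.peak_id}")


@dataclass
class BaitedPromoter:
    bait_id: str
    chrom: str
    start: int
    end: int
    gene_names: list[str]
    coding_flags: list[bool]
    open_flag: bool = False

    def __post_init__(self) -> None:
        if not self.gene_names:
            raise ValueError(f"bait {self.bait_id} has no gene names")
        if len(self.gene_names) != len(self.coding_flags):
            raise ValueError(f"bait {self.bait_id}: genes/coding flags mismatch")


@dataclass(frozen=True)
class Interaction:
    bait_id: str
    other_chrom: str
    other_start: int
    other_end: int
    score: float
    resolution: str  # ONE_FRAGMENT | FOUR_FRAGMENT

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("interaction score must be >= 0")
        if self.resolution not in (ONE_FRAGMENT, FOUR_FRAGMENT):
            raise ValueError(f"unknown resolution {self.resolution!r}")


@dataclass(frozen=True)
class ExpressionRecord:
    gene: str
    tpm: float
    percentile: float

    def __post_init__(self) -> None:
        if self.tpm < 0 or not 0 <= self.percentile <= 100:
            raise ValueError(f"invalid expression record for {self.gene}")


@dataclass
class V2GLink:
    locus_id: str
    sentinel_id: str
    rsid: str
    peak_id: str
    bait_id: str
    gene: str
    coding: bool
    score: float
    resolution: str
    other_chrom: str
    other_start: int
    other_end: int
    expressed_flag: bool | None = None


def expand_proxies(
    sentinels: Sequence[SentinelSignal],
    ld_records: pd.DataFrame | Iterable[tuple],
    cutoff: float = 0.7,
) -> list[ProxyVariant]:
    """LD-expand sentinels into proxies with r2 strictly above ``cutoff``.

    ``ld_records`` has columns/fields (sentinel_id, rsid, chrom, pos, r2)
    with 1-based positions.  Each sentinel contributes itself as a proxy with
    r2 = 1; duplicates of the same rsid under one sentinel keep the max r2.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError("cutoff must be in (0, 1]")
    if not isinstance(ld_records, pd.DataFrame):
        ld_records = pd.DataFrame(
            list(ld_records), columns=["sentinel_id", "rsid", "chrom", "pos", "r2"]
        )
    by_signal = {s.signal_id: s for s in sentinels}
    best: dict[tuple[str, str], ProxyVariant] = {}
    for s in sentinels:
        best[(s.signal_id, s.rsid)] = ProxyVariant(
            s.rsid, s.chrom, s.pos, 1.0, s.signal_id, s.locus_id
        )
    for row in ld_records.itertuples(index=False):
        sent = by_signal.get(row.sentinel_id)
        if sent is None:
            raise ValueError(f"LD record references unknown sentinel {row.sentinel_id!r}")
        r2 = float(row.r2)
        if r2 <= cutoff:
            continue
        key = (row.sentinel_id, row.rsid)
        if key not in best or best[key].r2 < r2:
            best[key] = ProxyVariant(
                row.rsid, row.chrom, int(row.pos), r2, sent.signal_id, sent.locus_id
            )
    return sorted(best.values(), key=lambda p: (p.locus_id, p.sentinel_id, p.rsid))


def _peak_trees(peaks: Sequence[Peak]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for pk in peaks:
        trees.setdefault(pk.chrom, IntervalTree()).addi(pk.start, pk.end, pk)
    return trees


def overlap_peaks(proxies: Sequence[ProxyVariant], peaks: Sequence[Peak]) -> list[ProxyVariant]:
    """Flag proxies whose SNP position falls inside an open-chromatin peak.

    Containment is half-open at the 0-based position (pos - 1).  When several
    peaks contain a proxy, the lexicographically smallest (start, end,
    peak_id) wins, keeping output deterministic.
    """
    trees = _peak_trees(peaks)
    out = []
    for p in proxies:
        hits = trees.get(p.chrom, IntervalTree())[p.pos0]
        if hits:
            pk = min((iv.data for iv in hits), key=lambda k: (k.start, k.end, k.peak_id))
            out.append(replace(p, open_flag=True, peak_id=pk.peak_id))
        else:
            out.append(replace(p, open_flag=False, peak_id=None))
    return out


def flag_open_baits(baits: Sequence[BaitedPromoter], peaks: Sequence[Peak]) -> list[BaitedPromoter]:
    """Set each bait's open flag: true iff it overlaps >= 1 peak."""
    trees = _peak_trees(peaks)
    out = []
    for b in baits:
        tree = trees.get(b.chrom)
        is_open = bool(tree.overlap(b.start, b.end)) if tree is not None else False
        out.append(replace_bait(b, open_flag=is_open))
    return out


def replace_bait(b: BaitedPromoter, **kw) -> BaitedPromoter:
    return BaitedPromoter(
        bait_id=b.bait_id,
        chrom=b.chrom,
        start=b.start,
        end=b.end,
        gene_names=list(b.gene_names),
        coding_flags=list(b.coding_flags),
        open_flag=kw.get("open_flag", b.open_flag),
    )


def annotate_loops(
    open_proxies: Sequence[ProxyVariant],
    interactions: Sequence[Interaction],
    baits: Sequence[BaitedPromoter],
    map1: FragmentMap,
    map4: FragmentMap,
    score_cutoff: float = 5.0,
) -> list[V2GLink]:
    """Emit a link for every gene of every open bait looped to an open proxy.

    A (proxy, bait, gene) link requires all four conditions:
      (i) the proxy's fragment, at the interaction's stated resolution,
          overlaps the interaction's other end by >= 1 bp;
      (ii) interaction score strictly above ``score_cutoff``;
      (iii) the proxy position lies in no baited region (non-bait-to-bait);
      (iv) the linked bait is open.
    Links are deduplicated on (proxy, bait, gene), keeping the best score.
    """
    if score_cutoff <= 0:
        raise ValueError("score_cutoff must be > 0")
    bait_by_id = {b.bait_id: b for b in baits}
    for ia in interactions:
        if ia.bait_id not in bait_by_id:
            raise ValueError(f"interaction references unknown bait {ia.bait_id!r}")
    bait_trees: dict[str, IntervalTree] = {}
    for b in baits:
        bait_trees.setdefault(b.chrom, IntervalTree()).addi(b.start, b.end, b.bait_id)
    passing = [ia for ia in interactions if ia.score > score_cutoff]
    best: dict[tuple[str, str, str], V2GLink] = {}
    for p in open_proxies:
        if not p.open_flag:
            continue
        tree = bait_trees.get(p.chrom)
        if tree is not None and tree[p.pos0]:
            continue  # proxy sits inside a baited promoter region
        f1 = map1.locate(p.chrom, p.pos0)
        f4 = map4.locate(p.chrom, p.pos0)
        for ia in passing:
            if ia.other_chrom != p.chrom:
                continue
            frag = f1 if ia.resolution == ONE_FRAGMENT else f4
            if not (frag.start < ia.other_end and ia.other_start < frag.end):
                continue
            bait = bait_by_id[ia.bait_id]
            if not bait.open_flag:
                continue
            for gene, coding in zip(bait.gene_names, bait.coding_flags):
                key = (p.rsid, bait.bait_id, gene)
                link = V2GLink(
                    locus_id=p.locus_id,
                    sentinel_id=p.sentinel_id,
                    rsid=p.rsid,
                    peak_id=p.peak_id,
                    bait_id=bait.bait_id,
                    gene=gene,
                    coding=coding,
                    score=ia.score,
                    resolution=ia.resolution,
                    other_chrom=ia.other_chrom,
                    other_start=ia.other_start,
                    other_end=ia.other_end,
                )
                if key not in best or best[key].score < ia.score:
                    best[key] = link
    return sorted(best.values(), key=lambda l: (l.locus_id, l.rsid, l.gene, l.bait_id))


def attach_percentiles(tpms: Mapping[str, float]) -> list[ExpressionRecord]:
    """Build expression records, deriving percentiles as TPM percent ranks.

    Percent rank of gene i = average-rank(tpm_i) / n x 100, ties averaged.
    """
    genes = sorted(tpms)
    values = np.array([tpms[g] for g in genes], dtype=float)
    pct = rankdata(values, method="average") / len(values) * 100.0
    return [ExpressionRecord(g, float(v), float(p)) for g, v, p in zip(genes, values, pct)]


def filter_expression(
    links: Sequence[V2GLink],
    expression: Sequence[ExpressionRecord],
    tpm_min: float = 1.5,
    pct_min: float = 50.0,
) -> list[V2GLink]:
    """Annotate links with expressed_flag = (TPM > tpm_min and pct > pct_min).

    Strict inequalities on both thresholds; genes missing from the table are
    not expressed.  Links are annotated, never removed.
    """
    if tpm_min < 0 or pct_min < 0:
        raise ValueError("thresholds must be >= 0")
    table = {e.gene: e for e in expression}
    out = []
    for l in links:
        e = table.get(l.gene)
        flag = bool(e is not None and e.tpm > tpm_min and e.percentile > pct_min)
        out.append(replace(l, expressed_flag=flag))
    return out


@dataclass(frozen=True)
class SummaryCounts:
    n_loci: int
    n_proxies: int
    n_peaks: int
    n_baits: int
    n_genes: int
    n_coding_genes: int
    n_interactions: int
    n_expressed_genes: int

    def to_dict(self) -> dict[str, int]:
        return {
            "loci_with_link": self.n_loci,
            "informative_proxies": self.n_proxies,
            "open_chromatin_regions": self.n_peaks,
            "open_baited_regions": self.n_baits,
            "genes": self.n_genes,
            "coding_genes": self.n_coding_genes,
            "distinct_interactions": self.n_interactions,
            "expressed_genes": self.n_expressed_genes,
        }


def summarize_v2g(links: Sequence[V2GLink]) -> SummaryCounts:
    """Distinct-entity counts over the link list.

    Distinct interactions are counted as (bait_id, other-end interval,
    resolution) triples.
    """
    coding = {l.gene for l in links if l.coding}
    expressed = {l.gene for l in links if l.expressed_flag}
    interactions = {
        (l.bait_id, l.other_chrom, l.other_start, l.other_end, l.resolution) for l in links
    }
    return SummaryCounts(
        n_loci=len({l.locus_id for l in links}),
        n_proxies=len({l.rsid for l in links}),
        n_peaks=len({l.peak_id for l in links}),
        n_baits=len({l.bait_id for l in links}),
        n_genes=len({l.gene for l in links}),
        n_coding_genes=len(coding),
        n_interactions=len(interactions),
        n_expressed_genes=len(expressed),
    )


def links_to_frame(links: Sequence[V2GLink]) -> pd.DataFrame:
    cols = [
        "locus_id", "sentinel_id", "rsid", "peak_id", "bait_id", "gene", "coding",
        "score", "resolution", "other_chrom", "other_start", "other_end", "expressed_flag",
    ]
    return pd.DataFrame([{c: getattr(l, c) for c in cols} for l in links], columns=cols)
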