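"""Seeded synthetic inputs with planted ground truth for every stage.

Three generators:

* :func:`gen_landscape` - a synthetic genome plus regulatory landscape
  (sentinels/proxies with LD, ATAC peaks, baited promoters, Capture C
  interactions, expression table) in the exact dialects the mapping pipeline
  consumes.  A ledger records which (proxy, gene) links must survive all four
  link conditions and which decoys violate exactly one named condition.
* :func:`gen_fly_traces` / :func:`gen_zf_traces` - per-minute behavior traces
  from a two-state (sleep/wake) discrete-time Markov chain with separate
  day/night transition matrices; fly wake minutes carry Poisson beam counts
  (clipped to >= 1 so wake is never miscalled immobile), zebrafish wake
  minutes Gamma movement-seconds clipped to [0.5, 60] and sleep minutes
  Uniform[0, 0.5), respecting the strict 0.5-s scoring boundary on both
  sides.
* :func:`gen_stimulus_responses` - Bernoulli responses to mechanical stimuli
  drawn from a supplied response curve, rendered as per-second movement
  traces consumable by the arousal/reactivity analyses.

All randomness flows from an explicit integer seed; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from sleepv2g.fly import ActivityTrace, StimulusEvent, immobility_duration_min, score_fly_sleep
from sleepv2g.restriction import DPNII, Enzyme, FragmentMap
from sleepv2g.v2g import (
    FOUR_FRAGMENT,
    ONE_FRAGMENT,
    BaitedPromoter,
    ExpressionRecord,
    Interaction,
    Peak,
    SentinelSignal,
    attach_percentiles,
)
from sleepv2g.zebrafish import ZfTrace

# ------------------------------------------------------------------ landscape


@dataclass
class LandscapeLedger:
    """Ground truth bookkeeping for a generated regulatory landscape."""

    planted: list[dict] = field(default_factory=list)  # links that must survive
    decoys: list[dict] = field(default_factory=list)  # each violates one condition
    unexpressed_genes: list[str] = field(default_factory=list)

    def planted_pairs(self) -> set[tuple[str, str]]:
        return {(d["rsid"], d["gene"]) for d in self.planted}

    def to_dict(self) -> dict:
        return {
            "planted": self.planted,
            "decoys": self.decoys,
            "unexpressed_genes": self.unexpressed_genes,
        }


@dataclass
class Landscape:
    sequences: dict[str, str]
    map1: FragmentMap
    map4: FragmentMap
    sentinels: list[SentinelSignal]
    ld_records: pd.DataFrame
    peaks: list[Peak]
    baits: list[BaitedPromoter]
    interactions: list[Interaction]
    expression: list[ExpressionRecord]
    ledger: LandscapeLedger


def _random_genome(rng: np.random.Generator, n_chroms: int, length: int) -> dict[str, str]:
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return {
        f"chr{i + 1}": rng.choice(bases, size=length).tobytes().decode("ascii")
        for i in range(n_chroms)
    }


class _FragmentPool:
    """Hands out usable fragments whose four-fragment bins are all distinct.

    Distinct bins guarantee that a four-fragment other end planted for one
    proxy can never accidentally cover another selected fragment, keeping the
    ledger exactly equal to the pipeline output.
    """

    def __init__(self, map1: FragmentMap, rng: np.random.Generator, min_len: int = 80):
        candidates = []
        for chrom in map1.chroms:
            n = map1.n_fragments(chrom)
            for frag in map1.fragments(chrom):
                if 2 <= frag.index < n - 2 and frag.length >= min_len:
                    candidates.append((chrom, frag.index))
        order = rng.permutation(len(candidates))
        self._queue = [candidates[i] for i in order]
        self._used_bins: set[tuple[str, int]] = set()
        self._map1 = map1

    def take(self):
        while self._queue:
            chrom, idx = self._queue.pop()
            bin_key = (chrom, idx // 4)
            if bin_key in self._used_bins:
                continue
            self._used_bins.add(bin_key)
            return self._map1.fragment(chrom, idx)
        raise ValueError(
            "infeasible geometry: not enough distinct usable fragments; "
            "increase genome_length or reduce loci/decoys"
        )


def gen_landscape(
    n_loci: int = 8,
    n_proxies_per_locus: int = 3,
    genome_length: int = 100_000,
    n_chroms: int = 2,
    enzyme: Enzyme = DPNII,
    fraction_open: float = 1.0,
    fraction_looped: float = 1.0,
    n_decoy_suites: int = 1,
    n_unexpressed_loci: int = 1,
    n_background_genes: int = 150,
    seed: int = 0,
    out_dir=None,
) -> Landscape:
    """Generate a regulatory landscape with planted effector genes.

    Planted loci place proxies inside open-chromatin peaks on dedicated
    restriction fragments and loop those fragments to open baited promoters
    with scores above 5.  Each decoy suite adds four loci that violate
    exactly one link condition each (closed proxy, proxy inside a baited
    region, sub-threshold score, closed bait).  ``fraction_open`` /
    ``fraction_looped`` withhold peaks / interactions from a fraction of
    planted loci, which removes them from the ledger.
    """
    if n_loci < 0 or n_proxies_per_locus < 1 or genome_length < 10_000:
        raise ValueError("invalid landscape geometry")
    rng = np.random.default_rng(seed)
    sequences = _random_genome(rng, n_chroms, genome_length)
    map1 = FragmentMap.from_sequences(sequences, enzyme)
    map4 = map1.concat(4)
    pool = _FragmentPool(map1, rng)
    ledger = LandscapeLedger()

    sentinels: list[SentinelSignal] = []
    ld_rows: list[dict] = []
    peaks: list[Peak] = []
    baits: list[BaitedPromoter] = []
    interactions: list[Interaction] = []
    tpms: dict[str, float] = {}
    gene_counter = 0
    peak_counter = 0

    def new_gene(expressed: bool) -> str:
        nonlocal gene_counter
        gene_counter += 1
        g = f"GENE{gene_counter:04d}"
        tpms[g] = float(rng.uniform(5, 80)) if expressed else float(rng.uniform(0.2, 1.0))
        return g

    def new_peak(chrom: str, start: int, end: int) -> Peak:
        nonlocal peak_counter
        peak_counter += 1
        pk = Peak(f"peak{peak_counter:04d}", chrom, start, end)
        peaks.append(pk)
        return pk

    def new_bait(frag, open_: bool, expressed: bool = True, n_genes: int | None = None):
        if n_genes is None:
            n_genes = int(rng.integers(1, 3))
        genes = [new_gene(expressed) for _ in range(n_genes)]
        coding = [bool(rng.random() < 0.75) for _ in genes]
        bait = BaitedPromoter(
            f"bait{len(baits):03d}", frag.chrom, frag.start, frag.end, genes, coding,
            open_flag=open_,
        )
        baits.append(bait)
        if open_:
            new_peak(frag.chrom, frag.start + 5, frag.start + 35)
        return bait

    def new_interaction(bait, proxy_frag, score: float, resolution: str):
        if resolution == FOUR_FRAGMENT:
            oe = map4.locate(proxy_frag.chrom, proxy_frag.start)
        else:
            oe = proxy_frag
        ia = Interaction(bait.bait_id, oe.chrom, oe.start, oe.end, round(score, 3), resolution)
        interactions.append(ia)
        return ia

    def new_locus(tag: str):
        locus_id = f"locus_{tag}"
        frag = pool.take()
        srs = f"rs{tag}s"
        sentinel = SentinelSignal(srs, frag.chrom, frag.end - 5 + 1, locus_id, srs)
        sentinels.append(sentinel)
        return locus_id, frag, sentinel

    n_looped = round(fraction_looped * n_loci)
    for i in range(n_loci):
        tag = f"P{i:03d}"
        locus_id, frag, sentinel = new_locus(tag)
        looped = i < n_looped
        expressed = i >= n_unexpressed_loci  # the first loci carry unexpressed genes
        n_open = round(fraction_open * n_proxies_per_locus)
        open_peak = (
            new_peak(frag.chrom, frag.start + 10, frag.start + 10 + 3 * n_proxies_per_locus + 10)
            if n_open > 0
            else None
        )
        bait = new_bait(pool.take(), open_=True, expressed=expressed) if looped else None
        if bait is not None and not expressed:
            ledger.unexpressed_genes.extend(bait.gene_names)
        if looped:
            resolution = ONE_FRAGMENT if rng.random() < 0.5 else FOUR_FRAGMENT
            new_interaction(bait, frag, float(rng.uniform(5.5, 15.0)), resolution)
        for j in range(n_proxies_per_locus):
            rsid = f"rs{tag}p{j}"
            is_open = j < n_open
            pos0 = frag.start + 12 + 3 * j if is_open else frag.end - 10 - j
            ld_rows.append(
                {
                    "sentinel_id": sentinel.signal_id,
                    "rsid": rsid,
                    "chrom": frag.chrom,
                    "pos": pos0 + 1,
                    "r2": round(float(rng.uniform(0.72, 0.99)), 3),
                }
            )
            if looped and is_open and bait is not None:
                for gene in bait.gene_names:
                    ledger.planted.append(
                        {
                            "locus_id": locus_id,
                            "sentinel_id": sentinel.signal_id,
                            "rsid": rsid,
                            "peak_id": open_peak.peak_id,
                            "bait_id": bait.bait_id,
                            "gene": gene,
                        }
                    )
            elif not is_open:
                ledger.decoys.append(
                    {"condition": "closed_proxy_fraction", "rsid": rsid, "locus_id": locus_id}
                )
            elif not looped:
                ledger.decoys.append(
                    {"condition": "not_looped_fraction", "rsid": rsid, "locus_id": locus_id}
                )
        # one sub-cutoff LD record per locus, dropped at proxy expansion
        ld_rows.append(
            {
                "sentinel_id": sentinel.signal_id,
                "rsid": f"rs{tag}low",
                "chrom": frag.chrom,
                "pos": frag.end - 3 + 1,
                "r2": round(float(rng.uniform(0.2, 0.65)), 3),
            }
        )

    for d in range(n_decoy_suites):
        # closed proxy: qualifying loop and open bait, but the SNP is not in a peak
        tag = f"Da{d}"
        locus_id, frag, sentinel = new_locus(tag)
        bait = new_bait(pool.take(), open_=True)
        new_interaction(bait, frag, float(rng.uniform(6, 12)), ONE_FRAGMENT)
        rsid = f"rs{tag}p0"
        ld_rows.append(
            {"sentinel_id": sentinel.signal_id, "rsid": rsid, "chrom": frag.chrom,
             "pos": frag.start + 15 + 1, "r2": 0.85}
        )
        ledger.decoys.append(
            {"condition": "closed_proxy", "rsid": rsid, "bait_id": bait.bait_id,
             "locus_id": locus_id}
        )

        # baited proxy: open SNP with a qualifying loop, but inside a bait region
        tag = f"Db{d}"
        locus_id, host_frag, sentinel = new_locus(tag)
        host = new_bait(host_frag, open_=False)  # peak added below covers the SNP
        target = new_bait(pool.take(), open_=True)
        pos0 = host_frag.start + 20
        pk = new_peak(host_frag.chrom, pos0 - 10, pos0 + 10)
        host.open_flag = True  # the proxy peak overlaps the host bait
        new_interaction(target, host_frag, float(rng.uniform(6, 12)), ONE_FRAGMENT)
        rsid = f"rs{tag}p0"
        ld_rows.append(
            {"sentinel_id": sentinel.signal_id, "rsid": rsid, "chrom": host_frag.chrom,
             "pos": pos0 + 1, "r2": 0.85}
        )
        ledger.decoys.append(
            {"condition": "baited_proxy", "rsid": rsid, "bait_id": target.bait_id,
             "host_bait_id": host.bait_id, "peak_id": pk.peak_id, "locus_id": locus_id}
        )

        # sub-threshold score: everything else qualifies
        tag = f"Dc{d}"
        locus_id, frag, sentinel = new_locus(tag)
        bait = new_bait(pool.take(), open_=True)
        new_interaction(bait, frag, float(rng.uniform(3.5, 4.9)), ONE_FRAGMENT)
        pos0 = frag.start + 15
        pk = new_peak(frag.chrom, pos0 - 10, pos0 + 10)
        rsid = f"rs{tag}p0"
        ld_rows.append(
            {"sentinel_id": sentinel.signal_id, "rsid": rsid, "chrom": frag.chrom,
             "pos": pos0 + 1, "r2": 0.85}
        )
        ledger.decoys.append(
            {"condition": "low_score", "rsid": rsid, "bait_id": bait.bait_id,
             "peak_id": pk.peak_id, "locus_id": locus_id}
        )

        # closed bait: open SNP, qualifying loop, but the bait has no peak
        tag = f"Dd{d}"
        locus_id, frag, sentinel = new_locus(tag)
        bait = new_bait(pool.take(), open_=False)
        new_interaction(bait, frag, float(rng.uniform(6, 12)), ONE_FRAGMENT)
        pos0 = frag.start + 15
        pk = new_peak(frag.chrom, pos0 - 10, pos0 + 10)
        rsid = f"rs{tag}p0"
        ld_rows.append(
            {"sentinel_id": sentinel.signal_id, "rsid": rsid, "chrom": frag.chrom,
             "pos": pos0 + 1, "r2": 0.85}
        )
        ledger.decoys.append(
            {"condition": "closed_bait", "rsid": rsid, "bait_id": bait.bait_id,
             "peak_id": pk.peak_id, "locus_id": locus_id}
        )

    for _ in range(n_background_genes):
        g = f"BG{len(tpms):04d}"
        tpms[g] = float(rng.lognormal(0.5, 1.5))

    ld_records = pd.DataFrame(
        ld_rows, columns=["sentinel_id", "rsid", "chrom", "pos", "r2"]
    )
    expression = attach_percentiles(tpms)
    landscape = Landscape(
        sequences, map1, map4, sentinels, ld_records, peaks, baits, interactions,
        expression, ledger,
    )
    if out_dir is not None:
        write_landscape(landscape, out_dir)
    return landscape


def write_landscape(landscape: Landscape, out_dir) -> dict[str, Path]:
    """Materialize a landscape in the dialects the mapping pipeline reads."""
    import json

    from sleepv2g import io as svio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "genome.fa",
        "proxies": out / "proxies.tsv",
        "peaks": out / "peaks.bed",
        "baits": out / "baits.bed",
        "interactions": out / "interactions.tsv",
        "expression": out / "expression.tsv",
        "ledger": out / "ledger.json",
    }
    svio.write_fasta(landscape.sequences, paths["fasta"])
    svio.write_proxy_table(landscape.sentinels, landscape.ld_records, paths["proxies"])
    svio.write_peaks_bed(landscape.peaks, paths["peaks"])
    svio.write_baits_bed(landscape.baits, paths["baits"])
    svio.write_interactions(landscape.interactions, landscape.baits, paths["interactions"])
    svio.write_expression(landscape.expression, paths["expression"])
    with open(paths["ledger"], "w") as fh:
        json.dump(landscape.ledger.to_dict(), fh, indent=1, sort_keys=True)
    return paths


# ------------------------------------------------------------------ behavior


@dataclass(frozen=True)
class FlyBehaviorSpec:
    """Two-state Markov sleep model for fly traces (per-minute probabilities).

    Defaults give a stationary sleep fraction of 0.25 by day and 0.8 by
    night, i.e. roughly 180 day + 576 night sleep minutes - an unremarkable
    wild-type-like fly on a 12:12 cycle.  ``wake_lambda`` is the mean beam
    count per waking minute.
    """

    p_wake_to_sleep_day: float = 0.02
    p_sleep_to_wake_day: float = 0.06
    p_wake_to_sleep_night: float = 0.06
    p_sleep_to_wake_night: float = 0.015
    wake_lambda: float = 2.0

    def __post_init__(self) -> None:
        probs = [
            self.p_wake_to_sleep_day, self.p_sleep_to_wake_day,
            self.p_wake_to_sleep_night, self.p_sleep_to_wake_night,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if self.wake_lambda <= 0:
            raise ValueError("wake_lambda must be > 0")


def _simulate_states(
    rng: np.random.Generator,
    a_day: np.ndarray, b_day: np.ndarray,
    a_night: np.ndarray, b_night: np.ndarray,
    n_minutes: int, clock_start_min: int, lights_on: int, lights_off: int,
) -> np.ndarray:
    """Vectorized per-minute sleep/wake chain for n animals (rows).

    ``a`` = P(wake->sleep), ``b`` = P(sleep->wake).  The first minute is
    drawn from the stationary distribution of the starting phase.
    """
    n = a_day.size
    states = np.empty((n, n_minutes), dtype=bool)
    mod0 = clock_start_min % 1440
    day0 = lights_on <= mod0 < lights_off
    a0, b0 = (a_day, b_day) if day0 else (a_night, b_night)
    states[:, 0] = rng.random(n) < a0 / (a0 + b0)
    for t in range(1, n_minutes):
        mod = (clock_start_min + t) % 1440
        if lights_on <= mod < lights_off:
            a, b = a_day, b_day
        else:
            a, b = a_night, b_night
        u = rng.random(n)
        prev = states[:, t - 1]
        states[:, t] = np.where(prev, u >= b, u < a)
    return states


def _scored_run_fraction(b: float) -> float:
    """Fraction of sleep-state minutes inside runs >= 5 min (geometric runs)."""
    q = 1.0 - b
    return q**4 * (5.0 - 4.0 * q)


def expected_scored_sleep_per_day(spec: FlyBehaviorSpec, b_scale: float = 1.0) -> float:
    """Closed-form expected scored sleep minutes per 24 h.

    Sleep-state occupancy is the stationary fraction a/(a+b); the 5-min rule
    keeps a fraction q^4(5-4q) of sleep minutes (geometric sojourns).  Phase
    boundary truncation is ignored, which is a small bias shared by every
    line and irrelevant to SD-unit effect calibration.
    """
    total = 0.0
    for a, b, minutes in (
        (spec.p_wake_to_sleep_day, spec.p_sleep_to_wake_day * b_scale, 720),
        (spec.p_wake_to_sleep_night, spec.p_sleep_to_wake_night * b_scale, 720),
    ):
        b = min(max(b, 1e-9), 1.0)
        total += minutes * (a / (a + b)) * _scored_run_fraction(b)
    return total


def _null_sleep_distribution(
    spec: FlyBehaviorSpec, n_days: int, rng: np.random.Generator, n_animals: int = 200
) -> tuple[float, float]:
    """Monte-Carlo mean and SD of per-animal scored sleep (min/day)."""
    a = np.full(n_animals, spec.p_wake_to_sleep_day)
    b = np.full(n_animals, spec.p_sleep_to_wake_day)
    an = np.full(n_animals, spec.p_wake_to_sleep_night)
    bn = np.full(n_animals, spec.p_sleep_to_wake_night)
    states = _simulate_states(rng, a, b, an, bn, n_days * 1440, 0, 0, 720)
    totals = np.array(
        [score_fly_sleep(1 - states[i].astype(np.int8))[0].sum() / n_days
         for i in range(n_animals)]
    )
    return float(totals.mean()), float(totals.std(ddof=1))


def _effect_scale(spec: FlyBehaviorSpec, effect_sd: float, null_sd: float) -> float:
    """Scale factor on both sleep->wake probabilities planting an SD-unit shift."""
    if effect_sd == 0.0:
        return 1.0
    base = expected_scored_sleep_per_day(spec)
    target = base + effect_sd * null_sd
    target = min(max(target, 1.0), 1439.0)

    def g(f: float) -> float:
        return expected_scored_sleep_per_day(spec, b_scale=f) - target

    return float(brentq(g, 1e-4, 100.0, xtol=1e-8))


def gen_fly_traces(
    spec: FlyBehaviorSpec,
    n_lines: int,
    n_flies_per_line: int,
    n_days: int = 2,
    effects_sd: Mapping[str, float] | None = None,
    seed: int = 0,
    line_ids: Sequence[str] | None = None,
    calibration_n: int = 200,
) -> tuple[list[ActivityTrace], pd.DataFrame]:
    """Generate DAM-style activity traces for an RNAi-screen-like design.

    ``effects_sd`` maps line ids to planted total-sleep shifts in units of
    the null animal-level SD (positive = long sleeper).  Returns the traces
    (starting at ZT0) and a per-line truth table with the planted effect,
    the calibrated transition-probability scale, and the null mean/SD used.
    """
    if line_ids is None:
        line_ids = [f"line{i:03d}" for i in range(n_lines)]
    if len(line_ids) != n_lines:
        raise ValueError("line_ids length must equal n_lines")
    effects = dict(effects_sd or {})
    unknown = set(effects) - set(line_ids)
    if unknown:
        raise ValueError(f"effects reference unknown lines: {sorted(unknown)}")
    ss = np.random.SeedSequence(seed)
    cal_rng, sim_rng, count_rng = (np.random.default_rng(c) for c in ss.spawn(3))
    if any(v != 0.0 for v in effects.values()):
        null_mu, null_sd = _null_sleep_distribution(spec, n_days, cal_rng, calibration_n)
    else:
        null_mu, null_sd = float("nan"), float("nan")

    n_total = n_lines * n_flies_per_line
    a_day = np.full(n_total, spec.p_wake_to_sleep_day)
    b_day = np.full(n_total, spec.p_sleep_to_wake_day)
    a_night = np.full(n_total, spec.p_wake_to_sleep_night)
    b_night = np.full(n_total, spec.p_sleep_to_wake_night)
    truth_rows = []
    for li, line in enumerate(line_ids):
        k = effects.get(line, 0.0)
        f = _effect_scale(spec, k, null_sd) if k else 1.0
        sl = slice(li * n_flies_per_line, (li + 1) * n_flies_per_line)
        b_day[sl] *= f
        b_night[sl] *= f
        truth_rows.append(
            {
                "line_id": line,
                "effect_sd": k,
                "b_scale": f,
                "expected_sleep_min_per_day": expected_scored_sleep_per_day(spec, f),
                "null_mean": null_mu,
                "null_sd": null_sd,
            }
        )
    states = _simulate_states(
        sim_rng, a_day, b_day, a_night, b_night, n_days * 1440, 0, 0, 720
    )
    counts = np.zeros(states.shape, dtype=np.int16)
    wake = ~states
    counts[wake] = np.maximum(count_rng.poisson(spec.wake_lambda, int(wake.sum())), 1)
    traces = []
    for li, line in enumerate(line_ids):
        for j in range(n_flies_per_line):
            idx = li * n_flies_per_line + j
            traces.append(ActivityTrace(f"{line}_f{j:02d}", line, counts[idx]))
    return traces, pd.DataFrame(truth_rows)


@dataclass(frozen=True)
class ZfBehaviorSpec:
    """Two-state Markov sleep model for larval zebrafish on a 14:10 cycle.

    Defaults put the scramble-injected control near 11% sleep by day and 57%
    by night (roughly 90 day + 340 night sleep minutes per cycle).  Wake
    movement is Gamma(shape, scale) seconds clipped to [0.5, 60]; sleep
    movement Uniform[0, 0.5).
    """

    p_wake_to_sleep_day: float = 0.015
    p_sleep_to_wake_day: float = 0.12
    p_wake_to_sleep_night: float = 0.06
    p_sleep_to_wake_night: float = 0.045
    wake_gamma_shape: float = 3.0
    wake_gamma_scale: float = 2.0

    def __post_init__(self) -> None:
        probs = [
            self.p_wake_to_sleep_day, self.p_sleep_to_wake_day,
            self.p_wake_to_sleep_night, self.p_sleep_to_wake_night,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("transition probabilities must lie in [0, 1]")


def expected_night_sleep(
    a_day: float, b_day: float, a_night: float, b_night: float,
    clock_start_min: int, n_minutes: int, analysis_start: int, analysis_len: int,
    lights_on: int = 540, lights_off: int = 1380,
) -> float:
    """Exact expected night sleep minutes inside the analysis window.

    Propagates the marginal sleep probability through the alternating
    day/night transition matrices in closed form segment by segment
    (p_t = s + (p_0 - s) r^t with r = 1 - a - b), so calibration against it
    is exact rather than a stationarity approximation.
    """
    mod = (clock_start_min + np.arange(n_minutes)) % 1440
    is_day = (mod >= lights_on) & (mod < lights_off)
    in_win = (np.arange(n_minutes) >= analysis_start) & (
        np.arange(n_minutes) < analysis_start + analysis_len
    )
    a0, b0 = (a_day, b_day) if is_day[0] else (a_night, b_night)
    p = a0 / (a0 + b0)
    total = float(p) if (in_win[0] and not is_day[0]) else 0.0
    # change points of (phase, in-window) after minute 0
    keys = is_day.astype(np.int8) * 2 + in_win.astype(np.int8)
    cps = [1] + [int(t) for t in np.flatnonzero(np.diff(keys)) + 1 if t >= 1] + [n_minutes]
    cps = sorted(set(cps))
    for t0, t1 in zip(cps, cps[1:]):
        n = t1 - t0
        a, b = (a_day, b_day) if is_day[t0] else (a_night, b_night)
        s = a / (a + b)
        r = 1.0 - a - b
        seg_sum = n * s + (p - s) * r * (1 - r**n) / (1 - r)
        p = s + (p - s) * r**n
        if in_win[t0] and not is_day[t0]:
            total += seg_sum
    return total


def gen_zf_traces(
    spec: ZfBehaviorSpec,
    n_scramble: int = 42,
    n_ko: int = 48,
    planted_night_sleep_delta_min: float = 60.0,
    total_hours: int = 72,
    clock_start_min: int = 840,  # plates loaded at 14:00 on day 0
    analysis_days: int = 2,
    seed: int = 0,
) -> tuple[list[ZfTrace], dict]:
    """Generate tracking traces for a scramble-vs-knockout sleep assay.

    The knockout group's night sleep->wake probability is calibrated against
    the exact closed-form expectation so the expected cumulative night-sleep
    difference over the ``analysis_days``-cycle window equals the planted
    delta.  Returns traces (acclimation included; callers trim) and a truth
    dict with the calibrated parameters and expected group means.
    """
    rng = np.random.default_rng(seed)
    n_minutes = total_hours * 60
    offset = (540 - clock_start_min) % 1440
    analysis_len = analysis_days * 1440
    if offset + analysis_len > n_minutes:
        raise ValueError("trace too short for the requested analysis window")

    def e_night(b_night: float) -> float:
        return expected_night_sleep(
            spec.p_wake_to_sleep_day, spec.p_sleep_to_wake_day,
            spec.p_wake_to_sleep_night, b_night,
            clock_start_min, n_minutes, offset, analysis_len,
        )

    e_scr = e_night(spec.p_sleep_to_wake_night)
    delta = float(planted_night_sleep_delta_min)
    if delta == 0.0:
        b_ko = spec.p_sleep_to_wake_night
    else:
        target = e_scr + delta
        night_total = analysis_days * (1440 - 840)  # 600 night minutes per cycle
        if not 0 < target < night_total:
            raise ValueError("planted delta infeasible for the analysis window")
        b_ko = float(brentq(lambda b: e_night(b) - target, 1e-6, 0.999999, xtol=1e-12))

    n_total = n_scramble + n_ko
    a_day = np.full(n_total, spec.p_wake_to_sleep_day)
    b_day = np.full(n_total, spec.p_sleep_to_wake_day)
    a_night = np.full(n_total, spec.p_wake_to_sleep_night)
    b_night = np.full(n_total, spec.p_sleep_to_wake_night)
    b_night[n_scramble:] = b_ko
    states = _simulate_states(
        rng, a_day, b_day, a_night, b_night, n_minutes, clock_start_min, 540, 1380
    )
    movement = np.empty(states.shape, dtype=float)
    n_sleep = int(states.sum())
    movement[states] = rng.uniform(0.0, 0.5, n_sleep)
    movement[~states] = np.clip(
        rng.gamma(spec.wake_gamma_shape, spec.wake_gamma_scale, states.size - n_sleep),
        0.5, 60.0,
    )
    traces = []
    for i in range(n_total):
        group = "scramble" if i < n_scramble else "ko"
        j = i if i < n_scramble else i - n_scramble
        traces.append(
            ZfTrace(f"{group}_{j:03d}", group, movement[i], clock_start_min=clock_start_min)
        )
    truth = {
        "planted_night_sleep_delta_min": delta,
        "expected_scramble_night_sleep_min": e_scr,
        "expected_ko_night_sleep_min": e_scr + delta,
        "b_night_ko": b_ko,
        "analysis_offset_min": offset,
        "analysis_len_min": analysis_len,
    }
    return traces, truth


# ------------------------------------------------------------------ stimuli


def gen_stimulus_responses(
    sleep_states: np.ndarray,
    schedule: Sequence,
    response_curve: Callable[[float, float], float],
    seed: int = 0,
    response_mm: float = 5.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Draw Bernoulli stimulus responses and render them as movement traces.

    ``sleep_states`` is (n_flies, n_minutes) boolean; ``schedule`` is either
    a flat list of :class:`StimulusEvent` (fixed-intensity reactivity) or a
    list of escalating-intensity trials (lists of events).
    ``response_curve(intensity_g, immobility_min)`` must return a probability
    in [0, 1].  Responses appear as ``response_mm`` displacement pulses a few
    seconds after the stimulus; within an escalating trial no further stimuli
    are drawn once the fly has responded (it is awake).
    """
    sleep_states = np.asarray(sleep_states, dtype=bool)
    rng = np.random.default_rng(seed)
    n_flies, n_minutes = sleep_states.shape
    movement = np.zeros((n_flies, n_minutes * 60), dtype=np.float32)
    trials = list(schedule)
    if trials and isinstance(trials[0], StimulusEvent):
        trials = [[ev] for ev in trials]
    rows = []
    for fly in range(n_flies):
        for trial_idx, trial in enumerate(trials):
            responded_in_trial = False
            for ev in trial:
                minute = ev.time_s // 60
                asleep = bool(sleep_states[fly, minute])
                dur = immobility_duration_min(sleep_states[fly], minute)
                responded = False
                if asleep and not responded_in_trial:
                    p = float(response_curve(ev.intensity_g, float(dur)))
                    if not 0.0 <= p <= 1.0:
                        raise ValueError(f"response curve returned {p}, outside [0, 1]")
                    responded = bool(rng.random() < p)
                    if responded:
                        movement[fly, ev.time_s + 2 : ev.time_s + 5] = response_mm
                        responded_in_trial = True
                rows.append(
                    {
                        "fly": fly, "trial": trial_idx, "time_s": ev.time_s,
                        "intensity_g": ev.intensity_g, "asleep": asleep,
                        "immobility_min": dur, "responded": responded,
                    }
                )
    events = pd.DataFrame(
        rows,
        columns=["fly", "trial", "time_s", "intensity_g", "asleep",
                 "immobility_min", "responded"],
    )
    return movement, events
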