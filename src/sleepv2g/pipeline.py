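"""End-to-end orchestration of the synthetic demo pipeline.

Stages: ``landscape`` (synthesize regulatory inputs), ``v2g`` (variant to
gene mapping), ``fly`` (trace generation, sleep scoring, screen calls),
``zf`` (zebrafish scoring and group comparison).  Outputs land in a run
directory with a JSON report and a sha256 manifest; everything is
deterministic given the config seed - log lines carry no timestamps so a
rerun is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from sleepv2g import io as svio
from sleepv2g import zebrafish as zf
from sleepv2g.config import PipelineConfig
from sleepv2g.fly import call_screen_hits, is_dead, score_fly_sleep, summarize_fly_sleep
from sleepv2g.restriction import ENZYMES, FragmentMap, fragment_stats
from sleepv2g.synth import (
    FlyBehaviorSpec,
    ZfBehaviorSpec,
    gen_fly_traces,
    gen_landscape,
    gen_zf_traces,
)
from sleepv2g.v2g import (
    annotate_loops,
    expand_proxies,
    filter_expression,
    flag_open_baits,
    links_to_frame,
    overlap_peaks,
    summarize_v2g,
)

ALL_STAGES = ("landscape", "v2g", "fly", "zf")

log = logging.getLogger("sleepv2g.pipeline")


def _derive_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, stages=ALL_STAGES, out_dir=None) -> dict:
    """Run the requested stages; returns the report dict.

    Stage dependencies: ``v2g`` needs the landscape files (from the
    ``landscape`` stage or from ``config.inputs``); behavior stages are
    independent.  Every stage logs its effective thresholds.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = tuple(stages)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    seeds = dict(zip(ALL_STAGES, _derive_seeds(config.seed, len(ALL_STAGES))))
    thr = config.thresholds
    report: dict = {"seed": config.seed, "stages": list(stages)}

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        if "landscape" in stages:
            lc = config.landscape
            log.info("landscape: seed=%d n_loci=%d", seeds["landscape"], lc.n_loci)
            gen_landscape(
                n_loci=lc.n_loci,
                n_proxies_per_locus=lc.n_proxies_per_locus,
                genome_length=lc.genome_length,
                n_chroms=lc.n_chroms,
                enzyme=ENZYMES[lc.enzyme],
                fraction_open=lc.fraction_open,
                fraction_looped=lc.fraction_looped,
                n_decoy_suites=lc.n_decoy_suites,
                seed=seeds["landscape"],
                out_dir=out / "landscape",
            )
            report["landscape"] = {"dir": "landscape"}

        if "v2g" in stages:
            src = Path(config.inputs["landscape_dir"]) if "landscape_dir" in config.inputs else out / "landscape"
            needed = ["genome.fa", "proxies.tsv", "peaks.bed", "baits.bed",
                      "interactions.tsv", "expression.tsv"]
            missing = [f for f in needed if not (src / f).exists()]
            if missing:
                raise FileNotFoundError(
                    f"v2g stage: missing inputs {missing} in {src}; run the "
                    "landscape stage first or point config.inputs.landscape_dir at them"
                )
            log.info(
                "v2g: r2>%.3g score>%.3g tpm>%.3g pct>%.3g",
                thr.r2_cutoff, thr.chicago_cutoff, thr.tpm_min, thr.pct_min,
            )
            sequences = svio.read_fasta(src / "genome.fa")
            enzyme = ENZYMES[config.landscape.enzyme]
            map1 = FragmentMap.from_sequences(sequences, enzyme)
            map4 = map1.concat(4)
            sentinels, ld = svio.read_proxy_table(src / "proxies.tsv")
            peaks = svio.read_peaks_bed(src / "peaks.bed")
            baits = flag_open_baits(svio.read_baits_bed(src / "baits.bed"), peaks)
            interactions = svio.read_interactions(src / "interactions.tsv")
            expression = svio.read_expression(src / "expression.tsv")
            proxies = overlap_peaks(expand_proxies(sentinels, ld, thr.r2_cutoff), peaks)
            links = annotate_loops(proxies, interactions, baits, map1, map4, thr.chicago_cutoff)
            links = filter_expression(links, expression, thr.tpm_min, thr.pct_min)
            links_to_frame(links).to_csv(out / "v2g_links.tsv", sep="\t", index=False,
                                         float_format="%.6g")
            counts = summarize_v2g(links).to_dict()
            mean_len, median_len = fragment_stats(map1)
            counts["fragment_mean_bp"] = round(mean_len, 3)
            counts["fragment_median_bp"] = median_len
            pd.DataFrame([counts]).to_csv(out / "v2g_summary.tsv", sep="\t", index=False)
            report["v2g"] = counts

        if "fly" in stages:
            fc = config.fly
            log.info(
                "fly: immobility>=%d min, screen band +/- %.3g SD, reference=%s",
                thr.immobility_min, thr.screen_k_sd, fc.screen_reference,
            )
            traces, truth = gen_fly_traces(
                FlyBehaviorSpec(), fc.n_lines, fc.n_flies_per_line, fc.n_days,
                effects_sd=fc.effects_sd, seed=seeds["fly"],
            )
            truth.to_csv(out / "fly_truth.tsv", sep="\t", index=False, float_format="%.6g")
            rows, line_totals = [], {}
            for t in traces:
                if fc.drop_dead and is_dead(t.counts):
                    continue
                state, bouts = score_fly_sleep(t.counts, thr.immobility_min)
                s = summarize_fly_sleep(state, t, bouts)
                rows.append({"animal_id": t.animal_id, "line": t.line,
                             "total_sleep_min": s.total_sleep_min,
                             "day_sleep_min": s.day_sleep_min,
                             "night_sleep_min": s.night_sleep_min,
                             "bout_number": s.bout_number,
                             "mean_bout_length_min": s.mean_bout_length_min,
                             "waking_activity": s.waking_activity})
                line_totals.setdefault(t.line, []).append(s.total_sleep_min)
            pd.DataFrame(rows).to_csv(out / "fly_sleep.tsv", sep="\t", index=False,
                                      float_format="%.6g")
            if fc.screen_reference == "controls":
                reference = [l for l in line_totals if fc.effects_sd.get(l, 0.0) == 0.0]
            else:
                reference = "all_animals"
            calls = call_screen_hits(line_totals, reference, thr.screen_k_sd)
            pd.DataFrame([c.__dict__ for c in calls]).to_csv(
                out / "fly_screen.tsv", sep="\t", index=False, float_format="%.6g")
            report["fly"] = {
                "n_animals": len(rows),
                "hits": {c.line_id: c.call for c in calls if c.call != "none"},
            }

        if "zf" in stages:
            zc = config.zf
            log.info(
                "zf: sleep < %.3g s/min, delta=%.3g min, efficiency > %.3g",
                thr.zf_threshold_sec, zc.planted_night_sleep_delta_min, thr.efficiency_cutoff,
            )
            traces, truth = gen_zf_traces(
                ZfBehaviorSpec(), zc.n_scramble, zc.n_ko,
                zc.planted_night_sleep_delta_min, zc.total_hours,
                zc.clock_start_min, zc.analysis_days, seed=seeds["zf"],
            )
            rows, groups = [], {"scramble": [], "ko": []}
            for t in traces:
                trimmed = zf.trim_acclimation(t, zc.analysis_days)
                state = zf.score_zf_sleep(trimmed, thr.zf_threshold_sec)
                s = zf.summarize_zf(trimmed, state)
                rows.append({"larva_id": t.larva_id, "group": t.group,
                             "day_sleep_min": s.day_sleep_min,
                             "night_sleep_min": s.night_sleep_min,
                             "day_bout_number": s.day_bout_number,
                             "night_bout_number": s.night_bout_number,
                             "night_mean_bout_min": s.night_mean_bout_min,
                             "waking_activity": s.waking_activity})
                groups[t.group].append(s.night_sleep_min)
            pd.DataFrame(rows).to_csv(out / "zf_sleep.tsv", sep="\t", index=False,
                                      float_format="%.6g")
            res = zf.zf_group_compare(groups["ko"], groups["scramble"])
            comp = {
                "mean_difference_min": res.mean_difference, "se": res.se,
                "t": res.t_statistic, "df": res.df, "p": res.p_value,
                "planted_delta_min": truth["planted_night_sleep_delta_min"],
            }
            pd.DataFrame([comp]).to_csv(out / "zf_compare.tsv", sep="\t", index=False,
                                        float_format="%.6g")
            report["zf"] = comp

        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
        manifest = {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name not in ("manifest.json", "run.log")
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    finally:
        log.removeHandler(handler)
        handler.close()
    return report
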