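"""End-to-end workflows: simulate -> analyze -> metrics, with a checksum manifest.

Two workflows are wired:

* ``amplicon`` — the targeted specificity experiment: bisulfite read pairs
  for a target and an off-target amplicon per sample, the bis-seq pipeline,
  and a specificity report against the reference (wild-type) sample.
* ``mbd`` — the genome-wide experiment: MBD fragments per sample over a
  synthetic CGI genome, binned RPKM coverage, internal re-calibration, CGI
  classification, differential peaks and fold-reduction of off-target gain.

``full`` runs both.  Identical config + seed reproduce byte-identical
artifacts; the manifest records a sha256 per file.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import bisseq, io, mbd, metrics, synth
from ._utils import derive_seed, round_half_away
from .config import make_config
from .errors import MethylEditError

log = logging.getLogger("methyledit")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict | None = None, workflow: str = "full") -> dict:
    """Execute a workflow; returns the manifest (also written to the outdir)."""
    cfg = make_config(config if isinstance(config, dict) else None) if not _is_complete(config) else config
    if workflow not in ("amplicon", "mbd", "full"):
        raise MethylEditError(f"unknown workflow {workflow!r}")
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    try:
        if workflow in ("amplicon", "full"):
            artifacts += _run_amplicon(cfg, outdir)
        if workflow in ("mbd", "full"):
            artifacts += _run_mbd(cfg, outdir)
    except MethylEditError as exc:
        raise MethylEditError(f"[{workflow}] {exc}") from exc

    manifest = {
        "workflow": workflow,
        "seed": cfg["seed"],
        "config": cfg,
        "artifacts": {str(p.relative_to(outdir)): _sha256(p) for p in sorted(artifacts)},
    }
    io.write_json(outdir / "manifest.json", manifest)
    return manifest


def _is_complete(config) -> bool:
    return isinstance(config, dict) and {"seed", "amplicon", "mbd", "offtarget"} <= set(config)


# ---------------------------------------------------------------------------
# amplicon workflow
# ---------------------------------------------------------------------------

def _run_amplicon(cfg: dict, outdir: Path) -> list[Path]:
    a = cfg["amplicon"]
    seed = cfg["seed"]
    target = synth.make_amplicon(
        name="target_syn",
        length=a["target_length"],
        n_cpgs=a["target_n_cpgs"],
        blocked_indices=tuple(a["target_blocked"]),
        analysis_indices=tuple(a["target_analysis"]),
        seed=derive_seed(seed, "target-amplicon"),
    )
    offt = synth.make_amplicon(
        name="offtarget_syn",
        length=a["offtarget_length"],
        n_cpgs=a["offtarget_n_cpgs"],
        blocked_indices=(),
        analysis_indices=tuple(range(1, a["offtarget_n_cpgs"] + 1)),
        seed=derive_seed(seed, "offtarget-amplicon"),
    )
    artifacts: list[Path] = []
    for amp in (target, offt):
        p = outdir / f"{amp.name}.json"
        io.write_json(p, amp.to_dict())
        artifacts.append(p)

    base_t = synth.amplicon_baseline_probs(target, seed=derive_seed(seed, "truth-target"))
    base_o = synth.amplicon_baseline_probs(offt, seed=derive_seed(seed, "truth-offtarget"))

    summaries = []
    truth_rows = []
    for sample in a["samples"]:
        name = sample["name"]
        pt = synth.treated_target_probs(base_t, target, sample["p_on"])
        po = synth.treated_offtarget_probs(
            base_o, sample["theta"], a["accessibility"], a["p_max"]
        )
        row = {"sample": name}
        for amp, probs, channel in ((target, pt, "on"), (offt, po, "off")):
            params = synth.SimulationParams(
                conversion_rate=a["conversion_rate"],
                inappropriate_conversion=a["inappropriate_conversion"],
                sequencing_error_rate=a["sequencing_error_rate"],
                # reads never extend past the amplicon (no adapter read-through
                # is simulated), so cap the read length per amplicon
                read_length=min(a["read_length"], len(amp.sequence)),
                n_read_pairs=a["n_read_pairs"],
                seed=derive_seed(seed, f"reads:{name}:{amp.name}"),
            )
            r1, r2 = synth.simulate_bisulfite_reads(amp, probs, params)
            f1 = outdir / f"{name}_{amp.name}_R1.fastq"
            f2 = outdir / f"{name}_{amp.name}_R2.fastq"
            io.write_fastq(f1, r1)
            io.write_fastq(f2, r2)
            artifacts += [f1, f2]
            profile, qc = bisseq.run_bisseq(
                r1,
                r2,
                amp,
                q_trim=a["q_trim"],
                min_overlap=a["min_overlap"],
                max_mismatch_frac=a["max_mismatch_frac"],
                min_identity=a["min_identity"],
                min_base_quality=a["min_base_quality"],
            )
            log.info("%s/%s: %s", name, amp.name, qc)
            site_tsv = outdir / f"{name}_{amp.name}_sites.tsv"
            io.write_tsv(
                site_tsv,
                pd.DataFrame(
                    {
                        "cpg_index": np.arange(1, amp.n_cpgs + 1),
                        "offset": list(amp.cpg_offsets),
                        "meth": profile.meth,
                        "unmeth": profile.unmeth,
                        "level": profile.levels,
                    }
                ),
            )
            artifacts.append(site_tsv)
            row[f"{channel}_target_pct"] = round_half_away(
                bisseq.region_mean(profile, amp, min_reads=a["min_reads"]), 2
            )
            row[f"{channel}_conversion_pct"] = qc["conversion_rate_pct"]
            for j, p in enumerate(probs, 1):
                truth_rows.append(
                    {"sample": name, "amplicon": amp.name, "cpg_index": j, "probability": p}
                )
        summaries.append(row)

    summary_df = pd.DataFrame(summaries)
    sum_tsv = outdir / "amplicon_summaries.tsv"
    io.write_tsv(sum_tsv, summary_df)
    truth_tsv = outdir / "amplicon_truth.tsv"
    io.write_tsv(truth_tsv, pd.DataFrame(truth_rows))
    report = metrics.build_report(summary_df, reference=a["reference_sample"])
    rep_tsv = outdir / "specificity_report.tsv"
    io.write_tsv(rep_tsv, report)
    return artifacts + [sum_tsv, truth_tsv, rep_tsv]


# ---------------------------------------------------------------------------
# mbd workflow
# ---------------------------------------------------------------------------

def _run_mbd(cfg: dict, outdir: Path) -> list[Path]:
    m = cfg["mbd"]
    seed = cfg["seed"]
    genome = synth.make_genome(
        n_cgis=m["n_cgis"],
        cgi_length=m["cgi_length"],
        spacer_length=m["spacer_length"],
        frac_methylated=m["frac_methylated"],
        seed=derive_seed(seed, "mbd-genome"),
    )
    artifacts: list[Path] = []
    fasta = outdir / "genome.fa"
    io.write_fasta(fasta, genome.sequences)
    cgis_bed = outdir / "cgis.bed"
    io.write_bed(cgis_bed, genome.cgis)
    artifacts += [fasta, cgis_bed]

    sizes = genome.chrom_sizes
    tracks: dict[str, mbd.CoverageTrack] = {}
    truths: dict[str, synth.MethylomeTruth] = {}
    sample_names = ["untreated"] + [s["name"] for s in m["samples"]]
    for sample in [{"name": "untreated", "theta": None}] + list(m["samples"]):
        name = sample["name"]
        theta = sample["theta"] if sample["theta"] is not None else 1.0
        truth = synth.simulate_methylome(
            genome,
            theta=theta,
            p_on=m["p_on"],
            p_max=m["p_max"],
            seed=derive_seed(seed, "mbd-truth"),
        )
        truths[name] = truth
        condition = "untreated" if name == "untreated" else "treated"
        params = synth.SimulationParams(
            n_fragments=m["n_fragments"],
            fragment_length_mean=m["fragment_length_mean"],
            fragment_length_sd=m["fragment_length_sd"],
            mbd_capture_q=m["mbd_capture_q"],
            seed=derive_seed(seed, f"mbd-frags:{name}"),
        )
        frags = synth.simulate_mbd_fragments(genome, truth, params, condition=condition)
        bed = outdir / f"{name}_fragments.bed"
        io.write_bed(bed, frags)
        artifacts.append(bed)
        tracks[name] = mbd.rpkm_normalize(mbd.bin_coverage(frags, sizes, m["bin_size"]))

    recal, factors = mbd.recalibrate(
        tracks, genome.cgis, mbd.RecalibrationConfig(k=m["k"], reference_sample="untreated")
    )
    sf = outdir / "scale_factors.json"
    io.write_json(sf, factors)
    artifacts.append(sf)
    for name, track in recal.items():
        bg = outdir / f"{name}_recal.bedgraph"
        io.write_bedgraph(bg, track.to_bedgraph())
        artifacts.append(bg)

    labels = mbd.classify_cgis(recal["untreated"], genome.cgis)
    per_cgi = {"cgi": genome.cgis.names, "class": labels}
    for name in sample_names:
        per_cgi[f"mean_{name}"] = mbd.quantify_intervals(recal[name], genome.cgis)
    cgi_tsv = outdir / "cgi_quantification.tsv"
    io.write_tsv(cgi_tsv, pd.DataFrame(per_cgi))
    artifacts.append(cgi_tsv)

    peak_cfg = mbd.PeakCallConfig(
        background_quantile=m["background_quantile"],
        min_differential=m["min_differential"],
        min_width=m["min_width"],
        merge_gap=m["merge_gap"],
    )
    unmeth = genome.cgis.subset(labels == "unmethylated")
    results = {"scale_factors": factors, "peaks": {}, "fold_reduction": {}}
    first = m["samples"][0]["name"] if m["samples"] else None
    for sample in m["samples"]:
        name = sample["name"]
        peaks = mbd.call_new_peaks(recal[name], recal["untreated"], genome.cgis, peak_cfg)
        pbed = outdir / f"{name}_new_peaks.bed"
        io.write_bed(pbed, peaks)
        artifacts.append(pbed)
        counts = mbd.intersect_counts(peaks, genome.cgis, unmeth)
        results["peaks"][name] = {
            "n_peaks": counts["n_peaks"],
            "n_in_cgis": counts["n_in_cgis"],
            "n_in_unmethylated_cgis": counts["n_in_subset"],
        }
        if first is not None and name != first:
            fr = mbd.fold_reduction(
                mbd.quantify_intervals(recal[first], unmeth),
                mbd.quantify_intervals(recal[name], unmeth),
                mbd.quantify_intervals(recal["untreated"], unmeth),
            )
            results["fold_reduction"][f"{first}_vs_{name}"] = {
                "fold": round_half_away(fr.fold, 2),
                "censored": fr.censored,
            }
    res_json = outdir / "mbd_results.json"
    io.write_json(res_json, results)
    artifacts.append(res_json)
    return artifacts
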