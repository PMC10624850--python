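"""End-to-end pipeline driver.

Stages, in order: (1) obtain per-sample aligned end coordinates — from
the synthetic generator or from BED files listed in the manifest; (2)
count uniquely mapped spike-in reads outside the cross-map mask; (3)
build strand-specific 5'/3'-end tracks and merge replicates per
(condition, antibody); (4) derive normalization factors and scale every
merged track to nf-cRPM; (5) call TSNs from the control sample's
5'-ends and pause sites per sample; (6) compute ratio tracks, composite
profiles, gbRPK activity and heat-shock response classes. All outputs
are plain text (bedGraph/TSV/JSON) with a provenance report; re-running
with identical inputs and seed is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genes import GeneModel, write_bed_genes
from .manifest import SampleManifest
from .normalize import NormFactors, apply_nf_cRPM, compute_nf_longGE, compute_nf_spikein
from .profiles import (
    composite_profile, classify_hs_response, gbRPK, group_by_activity,
    log2_ratio_track, sum_antibody_activity,
)
from .simulate import SimConfig, TruthTable, simulate_gene_set, simulate_sample_reads
from .spikein import MaskSet, count_spikein
from .tracks import (
    EndTrack, FIVE_PRIME, THREE_PRIME, merge_replicates, read_bed,
    reads_to_end_track, write_bedgraph,
)
from .tsn_pause import call_sites_for_genes, call_tsn, tss_offset_stats, TSNCall


@dataclass
class PipelineResult:
    outdir: Path
    genes: list[GeneModel]
    factors: NormFactors
    tsn_table: pd.DataFrame
    pause_tables: dict[str, pd.DataFrame]
    activity: pd.DataFrame
    truth: TruthTable | None = None
    merged_raw: dict[str, dict[str, EndTrack]] = field(default_factory=dict)
    normalized: dict[str, dict[str, EndTrack]] = field(default_factory=dict)


def run_pipeline(
    manifest: SampleManifest,
    config: SimConfig,
    outdir: str | Path,
    mask: MaskSet | None = None,
    genes: list[GeneModel] | None = None,
    gbrpk_start_offset: int = 500,
) -> PipelineResult:
    """Execute all stages on a simulated or file-backed experiment.

    When the manifest table has ``primary_bed``/``spike_bed`` columns,
    alignments are read from those files and ``genes`` must be given;
    otherwise the experiment is simulated from ``config`` (gene set and
    per-sample reads, deterministically from ``config.seed``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mask = mask or MaskSet({})
    file_mode = "primary_bed" in manifest.table.columns

    truth = None
    if file_mode:
        if genes is None:
            raise ValueError("file-backed manifests require a gene annotation")
    else:
        genes, truth = simulate_gene_set(config)
        write_bed_genes(genes, outdir / "genes.bed")
        truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)

    chrom_sizes = None if file_mode else {
        "chrSim1": config.genome_length, "chrSpk1": config.spike_genome_length,
    }

    # stage 1-2: per-replicate tracks and spike-in counts
    stage_log: list[dict] = []
    rep_tracks: dict[tuple[str, str], list[dict]] = {}
    for cond, ab, sub in manifest.merged_groups():
        entries = []
        for row in sub.itertuples(index=False):
            if file_mode:
                primary = read_bed(row.primary_bed)
                spike = read_bed(row.spike_bed) if getattr(row, "spike_bed", None) else primary.iloc[0:0]
            else:
                sim = simulate_sample_reads(
                    genes, truth, config, antibody=ab, condition=cond,
                    replicate=int(row.replicate),
                )
                primary, spike = sim.alignments, sim.spike_alignments
            spike_n = count_spikein(spike, mask)
            meta = dict(sample=row.sample, condition=cond, antibody=ab,
                        replicate=int(row.replicate))
            entries.append(
                dict(
                    five=reads_to_end_track(primary, FIVE_PRIME, metadata=meta,
                                            chrom_sizes=chrom_sizes),
                    three=reads_to_end_track(primary, THREE_PRIME, metadata=meta,
                                             chrom_sizes=chrom_sizes),
                    spike=spike_n,
                )
            )
            stage_log.append(
                dict(stage="tracks", sample=row.sample, primary_reads=len(primary),
                     spike_reads=int(spike_n))
            )
        rep_tracks[(cond, ab)] = entries

    # stage 3: merge replicates per (condition, antibody)
    merged: dict[str, dict] = {}
    for (cond, ab), entries in rep_tracks.items():
        mid = f"{cond}_{ab}"
        five, _ = merge_replicates([e["five"] for e in entries])
        three, spike_n = merge_replicates(
            [e["three"] for e in entries], [e["spike"] for e in entries]
        )
        for t in (five, three):
            t.metadata.update(sample=mid, condition=cond, antibody=ab)
        merged[mid] = dict(five=five, three=three, spike=spike_n,
                           condition=cond, antibody=ab)

    # stage 4: normalization factors and nf-cRPM tracks
    control_id = manifest.control_merged_id
    if control_id not in merged:
        raise ValueError(f"designated control {control_id} absent from manifest")
    ctrl_ab = manifest.control_antibody
    ctrl_cond = manifest.control_condition
    nf_spike = {}
    for mid, entry in merged.items():
        anchor = merged.get(f"{entry['condition']}_{ctrl_ab}")
        if anchor is None:
            raise ValueError(
                f"condition {entry['condition']} lacks a {ctrl_ab} sample for nf_spike-in"
            )
        nf_spike[mid] = compute_nf_spikein(entry["spike"], anchor["spike"])
    nf_longge = {}
    ref_three = merged[control_id]["three"]
    for cond in manifest.conditions:
        if cond == ctrl_cond:
            nf_longge[cond] = 1.0
        else:
            nf_longge[cond] = compute_nf_longGE(
                merged[f"{cond}_{ctrl_ab}"]["three"], ref_three, genes
            )
    factors = NormFactors(
        nf_spikein=nf_spike, nf_longGE=nf_longge,
        control_depth=merged[control_id]["three"].total_count,
        control_sample=control_id,
        sample_condition={mid: e["condition"] for mid, e in merged.items()},
    )
    factors.to_frame().assign(
        spike_count=[merged[s]["spike"] for s in factors.to_frame()["sample"]]
    ).to_csv(outdir / "norm_factors.tsv", sep="\t", index=False)

    normalized = {
        mid: dict(
            five=apply_nf_cRPM(e["five"], factors, mid),
            three=apply_nf_cRPM(e["three"], factors, mid),
        )
        for mid, e in merged.items()
    }
    trackdir = outdir / "tracks"
    trackdir.mkdir(exist_ok=True)
    for mid, pair in normalized.items():
        write_bedgraph(pair["three"], trackdir / f"{mid}_3p_nfcRPM")
        write_bedgraph(pair["five"], trackdir / f"{mid}_5p_nfcRPM")

    # stage 5: TSN from the control sample's 5'-ends; pause per sample
    rep_calls: dict[str, TSNCall] = {
        g.gene_id: call_tsn(merged[control_id]["five"], g) for g in genes
    }
    tsn_table, _ = call_sites_for_genes(
        merged[control_id]["five"], merged[control_id]["three"], genes,
        representative_tsn=rep_calls,
    )
    tsn_table.to_csv(outdir / "tsn_calls.tsv", sep="\t", index=False)
    called = [c for c in rep_calls.values() if c.called]
    if called:
        mean_off, median_off, hist = tss_offset_stats(list(rep_calls.values()))
        hist.to_frame().to_csv(outdir / "tsn_offset_histogram.tsv", sep="\t")
    else:
        mean_off = median_off = float("nan")

    genes_with_tsn = [
        g.with_tsn(rep_calls[g.gene_id].tsn) for g in genes if rep_calls[g.gene_id].called
    ]
    pause_tables = {}
    for mid, e in merged.items():
        _, pause = call_sites_for_genes(
            e["five"], e["three"], genes, representative_tsn=rep_calls
        )
        pause.to_csv(outdir / f"pause_calls_{mid}.tsv", sep="\t", index=False)
        pause_tables[mid] = pause

    # stage 6: ratio tracks, composite profiles, activity
    for cond in manifest.conditions:
        base = normalized.get(f"{cond}_{ctrl_ab}")
        for ab in manifest.antibodies:
            if ab == ctrl_ab or base is None:
                continue
            mid = f"{cond}_{ab}"
            if mid not in normalized:
                continue
            ratio = log2_ratio_track(normalized[mid]["three"], base["three"])
            write_bedgraph(ratio, trackdir / f"{mid}_vs_{ctrl_ab}_log2")  # type: ignore[arg-type]

    profdir = outdir / "profiles"
    profdir.mkdir(exist_ok=True)
    profile_genes = [g for g in genes_with_tsn if g.pos_to_offset(g.tsn, g.cps) + 1 >= 50]
    if profile_genes:
        for mid, pair in normalized.items():
            prom = composite_profile(pair["three"], profile_genes, anchor="tsn",
                                     window=(-1000, 1000), bin_width=5)
            prom.summary_frame().to_csv(profdir / f"{mid}_promoter.tsv", sep="\t", index=False)
            body = composite_profile(pair["three"], profile_genes, anchor="body")
            body.summary_frame().to_csv(profdir / f"{mid}_genebody.tsv", sep="\t", index=False)

    activity_rows = []
    body_genes = [
        g for g in genes_with_tsn if g.pos_to_offset(g.tsn, g.cps) > gbrpk_start_offset
    ]
    for g in body_genes:
        row: dict = dict(gene=g.gene_id)
        for cond in manifest.conditions:
            per_ab = {}
            for ab in manifest.antibodies:
                mid = f"{cond}_{ab}"
                if mid in normalized:
                    per_ab[ab] = gbRPK(normalized[mid]["three"], g,
                                       body_start_offset=gbrpk_start_offset)
                    row[f"gbRPK_{mid}"] = per_ab[ab]
            try:
                row[f"sum_gbRPK_{cond}"] = sum_antibody_activity(per_ab)
            except ValueError:
                row[f"sum_gbRPK_{cond}"] = float(sum(per_ab.values()))
        activity_rows.append(row)
    activity = pd.DataFrame(activity_rows)
    if len(activity) >= 4 and f"sum_gbRPK_{ctrl_cond}" in activity:
        activity = activity.rename(columns={f"sum_gbRPK_{ctrl_cond}": "sum_gbRPK"})
        activity = group_by_activity(activity, n_groups=4)
        activity = activity.rename(columns={"sum_gbRPK": f"sum_gbRPK_{ctrl_cond}"})
    other = [c for c in manifest.conditions if c != ctrl_cond]
    if other and not activity.empty:
        treated = other[0]
        activity["hs_response"] = [
            classify_hs_response(r, t)
            for r, t in zip(activity[f"sum_gbRPK_{ctrl_cond}"], activity[f"sum_gbRPK_{treated}"])
        ]
    activity.to_csv(outdir / "activity.tsv", sep="\t", index=False)

    provenance = dict(
        package="proipseq", version=__version__, seed=config.seed,
        config=_jsonable(asdict(config)),
        control_sample=control_id,
        nf_spikein={k: float(v) for k, v in sorted(nf_spike.items())},
        nf_longGE={k: float(v) for k, v in sorted(nf_longge.items())},
        control_depth=float(factors.control_depth),
        tsn_offset_mean=float(mean_off), tsn_offset_median=float(median_off),
        n_genes=len(genes), n_tsn_called=len(called),
        stages=stage_log,
    )
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=1, sort_keys=True)
        fh.write("\n")

    return PipelineResult(
        outdir=outdir, genes=genes, factors=factors, tsn_table=tsn_table,
        pause_tables=pause_tables, activity=activity, truth=truth,
        merged_raw={m: {"five": e["five"], "three": e["three"]} for m, e in merged.items()},
        normalized=normalized,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
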