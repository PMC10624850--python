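"""RPM and nf-cRPM normalization.

Plain reads-per-million (RPM) assumes all samples share the same total
transcriptional output, which breaks down when transcription changes
genome-wide (e.g. during heat shock). The nf-cRPM scheme instead scales
every sample by two correction factors before a common RPM step:

* ``nf_spikein`` — the sample's uniquely mapped spike-in read count
  divided by that of the unphosphorylated-CTD sample of the *same*
  run-on reaction (condition); corrects within-condition pulldown and
  library-depth differences against an extrinsic reference.
* ``nf_longGE`` — the ratio of 3'-end counts at the far ends of long
  (>150 kb) genes between the test condition's and the reference
  condition's unphosphorylated-CTD samples; in a 30-min perturbation the
  transcription wave (~2 kb/min) cannot have reached those regions, so
  they are assumed unchanged between conditions.

Each count is multiplied by ``(1/nf_spikein) * (1/nf_longGE) *
1e6/control_depth``, where ``control_depth`` is the designated control
sample's primary-genome read depth. The control sample (by default the
unphosphorylated-CTD antibody in the unstressed condition) has both
factors exactly 1, so all samples land on a y-scale comparable to the
control's sequencing-depth RPM. The scheme assumes equal pulldown
efficiency of spike-in material across samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genes import GeneModel
from .tracks import EndTrack


@dataclass
class NormFactors:
    """Per-sample spike-in factors and per-condition long-gene-end factors."""

    nf_spikein: dict[str, float]  # sample id -> factor
    nf_longGE: dict[str, float]  # condition -> factor
    control_depth: float
    control_sample: str
    sample_condition: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, mapping in (("nf_spikein", self.nf_spikein), ("nf_longGE", self.nf_longGE)):
            for key, value in mapping.items():
                if not value > 0:
                    raise ValueError(f"{name}[{key}] must be positive, got {value}")
        if not self.control_depth > 0:
            raise ValueError("control_depth must be positive")

    def combined_prefactor(self, sample: str) -> float:
        """nf_spikein × nf_longGE for one sample (exactly 1 for the control)."""
        condition = self.sample_condition.get(sample)
        if sample not in self.nf_spikein or condition not in self.nf_longGE:
            raise ValueError(f"no normalization factors registered for sample {sample!r}")
        if sample == self.control_sample:
            return 1.0
        return self.nf_spikein[sample] * self.nf_longGE[condition]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample": s,
                "condition": self.sample_condition.get(s, ""),
                "nf_spikein": f,
                "nf_longGE": self.nf_longGE.get(self.sample_condition.get(s), np.nan),
                "control": s == self.control_sample,
            }
            for s, f in sorted(self.nf_spikein.items())
        ]
        return pd.DataFrame(rows)


def compute_nf_spikein(sample_spike_count: float, control_spike_count: float) -> float:
    """Spike-in factor: sample's spike-in reads over the control antibody's.

    The control antibody of the same run-on reaction receives factor 1
    by construction (counted against itself).
    """
    if not control_spike_count > 0:
        raise ValueError("control spike-in count must be positive for normalization")
    return sample_spike_count / control_spike_count


def long_gene_end_window(gene: GeneModel, end_fraction: float = 0.25, cap: int = 50_000) -> tuple[int, int]:
    """Genomic window [start, end) covering the final stretch of a gene body.

    The window spans the last ``end_fraction`` of the gene, capped at
    ``cap`` bp before the CPS — far enough that a 30-min transcription
    wave cannot have altered the signal on >150 kb genes.
    """
    span = min(int(round(gene.length * end_fraction)), cap)
    span = max(span, 1)
    if gene.strand == "+":
        return gene.end - span, gene.end
    return gene.start, gene.start + span


def compute_nf_longGE(
    track_test: EndTrack,
    track_ref: EndTrack,
    genes: list[GeneModel],
    min_length: int = 150_000,
    end_fraction: float = 0.25,
    end_cap: int = 50_000,
) -> float:
    """Between-condition factor from 3'-end counts at long-gene ends.

    ``track_test``/``track_ref`` are the *control-antibody* 3'-end
    tracks of the test and reference conditions. Counts are summed on
    the gene strand within each qualifying (>``min_length``) gene's end
    window; the factor is their ratio. Raw (not spike-in-corrected)
    counts enter the ratio.
    """
    qualifying = [g for g in genes if g.length > min_length]
    if not qualifying:
        raise ValueError(f"no genes longer than {min_length} bp; nf_longGE undefined")
    test_sum = ref_sum = 0.0
    for gene in qualifying:
        start, end = long_gene_end_window(gene, end_fraction, end_cap)
        test_sum += track_test.window_counts(gene.chrom, gene.strand, start, end).sum()
        ref_sum += track_ref.window_counts(gene.chrom, gene.strand, start, end).sum()
    if not ref_sum > 0:
        raise ValueError("reference condition has zero counts in long-gene end windows")
    return float(test_sum / ref_sum)


def apply_nf_cRPM(track: EndTrack, factors: NormFactors, sample: str | None = None) -> EndTrack:
    """Scale a raw track to nf-corrected control RPM.

    Every count is multiplied by ``(1/nf_spikein) × (1/nf_longGE) ×
    1e6/control_depth``; the control sample's combined pre-RPM factor is
    exactly 1, so its output equals its control-depth RPM.
    """
    sample = sample or track.metadata.get("sample")
    if sample is None:
        raise ValueError("sample id required (pass explicitly or set track.metadata['sample'])")
    prefactor = factors.combined_prefactor(sample)
    scale = (1.0 / prefactor) * 1e6 / factors.control_depth
    return track.scaled(
        scale,
        provenance={
            "scheme": "nf-cRPM",
            "sample": sample,
            "nf_spikein": factors.nf_spikein[sample],
            "nf_longGE": factors.nf_longGE[factors.sample_condition[sample]],
            "control_depth": factors.control_depth,
            "control_sample": factors.control_sample,
        },
    )


def rpm(track: EndTrack) -> EndTrack:
    """Reads-per-million scaling by the track's own total count."""
    total = track.total_count
    if not total > 0:
        raise ValueError("cannot RPM-normalize an empty track")
    return track.scaled(1e6 / total, provenance={"scheme": "RPM", "depth": total})


def estimate_spikein_fraction(
    spike_cells: float,
    spike_genome_bp: float,
    spike_ploidy: float,
    main_cells: float,
    main_genome_bp: float,
    main_ploidy: float,
) -> float:
    """Spike-in chromatin as a percentage of the primary chromatin.

    Chromatin mass scales with cells × ploidy × genome size; the
    returned value is 100 × spike chromatin / primary chromatin. With
    2.5e5 diploid mouse cells (2.5e9 bp genome) spiked into 3e7
    hypotriploid human cells (2.9e9 bp), this evaluates to ~0.5%.
    """
    for name, value in (
        ("spike_cells", spike_cells), ("spike_genome_bp", spike_genome_bp),
        ("spike_ploidy", spike_ploidy), ("main_cells", main_cells),
        ("main_genome_bp", main_genome_bp), ("main_ploidy", main_ploidy),
    ):
        if not value > 0:
            raise ValueError(f"{name} must be positive, got {value}")
    spike_chromatin = spike_cells * spike_ploidy * spike_genome_bp
    main_chromatin = main_cells * main_ploidy * main_genome_bp
    return 100.0 * spike_chromatin / main_chromatin
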