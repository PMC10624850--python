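"""Cross-mapping mask and spike-in read counting.

Reads from the primary organism that also align to the spike-in genome
would inflate the spike-in count, so regions of the spike-in genome
receiving such foreign alignments are masked (set to N in the reference
and excluded from counting). Spike-in counts feed the per-sample
normalization factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class MaskSet:
    """Per-chromosome sorted, merged, disjoint intervals (0-based half-open)."""

    intervals: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, arr in self.intervals.items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            if len(arr) and (
                np.any(arr[:, 1] <= arr[:, 0])
                or np.any(np.diff(arr[:, 0]) <= 0)
                or np.any(arr[1:, 0] < arr[:-1, 1])
            ):
                raise ValueError(f"{chrom}: mask intervals must be sorted and disjoint")
            self.intervals[chrom] = arr

    @property
    def total_masked(self) -> int:
        return int(sum((arr[:, 1] - arr[:, 0]).sum() for arr in self.intervals.values()))

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        arr = self.intervals.get(chrom)
        if arr is None or not len(arr):
            return False
        i = np.searchsorted(arr[:, 0], end) - 1
        return i >= 0 and arr[i, 1] > start

    def to_bed3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.intervals):
                for start, end in self.intervals[chrom]:
                    fh.write(f"{chrom}\t{start}\t{end}\n")

    @classmethod
    def from_bed3(cls, path: str | Path) -> "MaskSet":
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end"],
            usecols=range(3), dtype={"chrom": str},
        )
        return build_crossmap_mask(df.assign(strand="+"))


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    merged = []
    cur_s, cur_e = int(starts[0]), int(ends[0])
    for s, e in zip(starts[1:].tolist(), ends[1:].tolist()):
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            merged.append((cur_s, cur_e))
            cur_s, cur_e = s, e
    merged.append((cur_s, cur_e))
    return np.array(merged, dtype=np.int64)


def build_crossmap_mask(
    foreign_alignments: pd.DataFrame,
    chrom_sizes: dict[str, int] | None = None,
    padding: int = 0,
) -> MaskSet:
    """Union of foreign-read intervals on the spike-in genome, merged.

    ``foreign_alignments`` is BED-like with chrom/start/end columns
    (strand ignored: a cross-mapping region is masked on both strands).
    Intervals beyond known chromosome bounds are clipped with a warning.
    ``padding`` widens each read interval symmetrically before merging.
    """
    if foreign_alignments.empty:
        return MaskSet({})
    intervals: dict[str, np.ndarray] = {}
    for chrom, sub in foreign_alignments.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy(dtype=np.int64) - padding
        ends = sub["end"].to_numpy(dtype=np.int64) + padding
        if chrom_sizes is not None:
            if chrom not in chrom_sizes:
                raise ValueError(f"foreign alignment on unknown spike-in chromosome {chrom!r}")
            bound = chrom_sizes[chrom]
            if np.any(ends > bound) or np.any(starts < 0):
                warnings.warn(f"{chrom}: clipping mask intervals to [0, {bound})")
            ends = np.clip(ends, None, bound)
        starts = np.clip(starts, 0, None)
        keep = ends > starts
        if keep.any():
            intervals[str(chrom)] = _merge_intervals(starts[keep], ends[keep])
    return MaskSet(intervals)


def apply_mask(sequences: dict[str, str], mask: MaskSet) -> dict[str, str]:
    """Replace masked positions by N; lengths and other bases unchanged."""
    unknown = set(mask.intervals) - set(sequences)
    if unknown:
        raise ValueError(f"mask references chromosomes absent from genome: {sorted(unknown)}")
    out = dict(sequences)
    for chrom, arr in mask.intervals.items():
        seq = list(out[chrom])
        for start, end in arr:
            end = min(int(end), len(seq))
            seq[int(start):end] = "N" * (end - int(start))
        out[chrom] = "".join(seq)
    return out


def apply_mask_fasta(fasta_in: str | Path, mask: MaskSet, fasta_out: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq

    records = list(SeqIO.parse(str(fasta_in), "fasta"))
    masked = apply_mask({r.id: str(r.seq) for r in records}, mask)
    for r in records:
        r.seq = Seq(masked[r.id])
    SeqIO.write(records, str(fasta_out), "fasta")


def count_spikein(sample_alignments: pd.DataFrame, mask: MaskSet) -> int:
    """Count uniquely mapped spike-in reads clear of the cross-map mask.

    Uniqueness is taken from the record's ``score`` field (>= 1 means
    uniquely mapped) or a boolean ``unique`` column if present; any
    overlap of >= 1 bp with the mask excludes a read.
    """
    if sample_alignments.empty:
        return 0
    if "unique" in sample_alignments.columns:
        unique = sample_alignments["unique"].to_numpy(dtype=bool)
    else:
        unique = sample_alignments["score"].to_numpy(dtype=float) >= 1
    df = sample_alignments[unique]
    total = 0
    for chrom, sub in df.groupby("chrom", sort=False):
        arr = mask.intervals.get(str(chrom))
        starts = sub["start"].to_numpy(dtype=np.int64)
        ends = sub["end"].to_numpy(dtype=np.int64)
        if arr is None or not len(arr):
            total += len(sub)
            continue
        # read [s, e) overlaps some mask interval iff the last interval
        # starting before e extends past s
        idx = np.searchsorted(arr[:, 0], ends, side="left") - 1
        overlapping = (idx >= 0) & (arr[np.clip(idx, 0, None), 1] > starts)
        total += int((~overlapping).sum())
    return total
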