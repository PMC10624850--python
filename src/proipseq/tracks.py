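"""Strand-specific single-nucleotide end-count tracks.

A run-on read reports two informative coordinates: its 5'-end marks the
nascent RNA's first nucleotide (the transcription start nucleotide for
promoter-anchored molecules) and its 3'-end marks the position of the
transcription bubble — the active site of the engaged polymerase. The
:class:`EndTrack` container keeps, per (chromosome, strand), a sparse
sorted map position -> count for one of the two end kinds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


@dataclass
class EndTrack:
    """Sparse per-nucleotide counts of read 5'- or 3'-ends on one genome.

    ``data`` maps (chromosome, strand) to a pair of equally long arrays:
    sorted unique 0-based positions and their (non-negative) counts.
    Counts are float so the same container carries raw and normalized
    tracks; ``metadata`` records sample/condition/antibody/replicate and
    any normalization provenance.
    """

    genome: str
    end_kind: str
    data: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)
    chrom_sizes: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.end_kind not in (FIVE_PRIME, THREE_PRIME):
            raise ValueError(f"end_kind must be five_prime or three_prime, got {self.end_kind!r}")
        for key, (pos, cnt) in self.data.items():
            if len(pos) != len(cnt):
                raise ValueError(f"{key}: positions and counts differ in length")
            if len(pos) > 1 and not np.all(np.diff(pos) > 0):
                raise ValueError(f"{key}: positions must be strictly increasing")

    @property
    def total_count(self) -> float:
        return float(sum(cnt.sum() for _, cnt in self.data.values()))

    def keys(self):
        return self.data.keys()

    def arrays(self, chrom: str, strand: str) -> tuple[np.ndarray, np.ndarray]:
        pos, cnt = self.data.get((chrom, strand), (np.empty(0, dtype=np.int64), np.empty(0)))
        return pos, cnt

    def window_counts(self, chrom: str, strand: str, start: int, end: int) -> np.ndarray:
        """Dense counts over [start, end) on one strand (genomic orientation)."""
        if end <= start:
            return np.zeros(0)
        pos, cnt = self.arrays(chrom, strand)
        out = np.zeros(end - start)
        lo, hi = np.searchsorted(pos, [start, end])
        out[pos[lo:hi] - start] = cnt[lo:hi]
        return out

    def scaled(self, factor: float, provenance: dict | None = None) -> "EndTrack":
        data = {k: (pos.copy(), cnt * factor) for k, (pos, cnt) in self.data.items()}
        meta = dict(self.metadata)
        if provenance:
            meta["normalization"] = provenance
        return EndTrack(self.genome, self.end_kind, data, meta, self.chrom_sizes)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (chrom, strand), (pos, cnt) in sorted(self.data.items()):
            rows.append(
                pd.DataFrame(
                    {"chrom": chrom, "pos": pos, "count": cnt, "strand": strand}
                )
            )
        if not rows:
            return pd.DataFrame(columns=["chrom", "pos", "count", "strand"])
        return pd.concat(rows, ignore_index=True)


def _counts_from_positions(chroms, strands, positions) -> dict:
    df = pd.DataFrame({"chrom": chroms, "strand": strands, "pos": positions})
    data = {}
    for (chrom, strand), sub in df.groupby(["chrom", "strand"], sort=True):
        pos, cnt = np.unique(sub["pos"].to_numpy(dtype=np.int64), return_counts=True)
        data[(str(chrom), str(strand))] = (pos, cnt.astype(float))
    return data


def reads_to_end_track(
    alignments: pd.DataFrame,
    end_kind: str,
    genome: str = "primary",
    metadata: dict | None = None,
    chrom_sizes: dict[str, int] | None = None,
) -> EndTrack:
    """Project aligned reads onto their 5'- or 3'-end positions.

    ``alignments`` is BED6-like (0-based half-open, ``strand`` in +/-).
    For a plus-strand read [start, end) the 5'-end is ``start`` and the
    3'-end ``end - 1``; on the minus strand the roles swap. One count is
    added per record at the chosen end, on the record's strand.
    """
    if end_kind not in (FIVE_PRIME, THREE_PRIME):
        raise ValueError(f"unknown end_kind {end_kind!r}")
    if alignments.empty:
        return EndTrack(genome, end_kind, {}, metadata or {}, chrom_sizes)
    strand = alignments["strand"].to_numpy()
    if not np.isin(strand, ["+", "-"]).all():
        raise ValueError("strandless alignment record")
    start = alignments["start"].to_numpy(dtype=np.int64)
    end = alignments["end"].to_numpy(dtype=np.int64)
    plus = strand == "+"
    if end_kind == FIVE_PRIME:
        pos = np.where(plus, start, end - 1)
    else:
        pos = np.where(plus, end - 1, start)
    data = _counts_from_positions(alignments["chrom"].to_numpy(), strand, pos)
    return EndTrack(genome, end_kind, data, metadata or {}, chrom_sizes)


def merge_replicates(
    tracks: list[EndTrack], spike_counts: list[float] | None = None
) -> tuple[EndTrack, float]:
    """Pool replicate tracks by positionwise summation of raw counts.

    Spike-in read counts are summed alongside so the pooled sample's
    normalization factor is count-weighted. All inputs must share genome
    and end kind.
    """
    if not tracks:
        raise ValueError("no tracks to merge")
    first = tracks[0]
    for t in tracks[1:]:
        if t.genome != first.genome or t.end_kind != first.end_kind:
            raise ValueError("cannot merge tracks with different genome or end_kind")
    data: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    keys = sorted({k for t in tracks for k in t.data})
    for key in keys:
        parts = [t.data[key] for t in tracks if key in t.data]
        pos = np.concatenate([p for p, _ in parts])
        cnt = np.concatenate([c for _, c in parts])
        upos, inv = np.unique(pos, return_inverse=True)
        summed = np.zeros(len(upos))
        np.add.at(summed, inv, cnt)
        data[key] = (upos, summed)
    meta = dict(first.metadata)
    meta.pop("replicate", None)
    meta["n_replicates"] = len(tracks)
    spike_total = float(sum(spike_counts)) if spike_counts is not None else 0.0
    return EndTrack(first.genome, first.end_kind, data, meta, first.chrom_sizes), spike_total


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=BED6_COLUMNS, usecols=range(6),
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "name": str, "strand": str},
    )
    return df


def write_bed(alignments: pd.DataFrame, path: str | Path) -> None:
    alignments.loc[:, BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(track: EndTrack, prefix: str | Path) -> tuple[Path, Path]:
    """Write one bedGraph per strand (suffixes ``_pl``/``_mn``).

    Minus-strand values are written as positive numbers; single-nt
    intervals, no track lines, 0-based half-open — the common
    nascent-RNA-seq dialect.
    """
    prefix = Path(prefix)
    paths = []
    for strand, suffix in (("+", "_pl"), ("-", "_mn")):
        path = prefix.parent / f"{prefix.name}{suffix}.bedgraph"
        with open(path, "w") as fh:
            for (chrom, s), (pos, cnt) in sorted(track.data.items()):
                if s != strand:
                    continue
                for p, c in zip(pos.tolist(), cnt.tolist()):
                    fh.write(f"{chrom}\t{p}\t{p + 1}\t{_fmt(c)}\n")
        paths.append(path)
    return tuple(paths)


def _fmt(value: float) -> str:
    return str(int(value)) if float(value).is_integer() else repr(float(value))


def read_bedgraph(
    plus_path: str | Path, minus_path: str | Path, end_kind: str,
    genome: str = "primary", metadata: dict | None = None,
) -> EndTrack:
    """Read a strand pair of bedGraph files back into an EndTrack."""
    data: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for path, strand in ((plus_path, "+"), (minus_path, "-")):
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
        )
        if df.empty:
            continue
        rows = []
        for chrom, sub in df.groupby("chrom", sort=True):
            starts = sub["start"].to_numpy(dtype=np.int64)
            ends = sub["end"].to_numpy(dtype=np.int64)
            vals = sub["value"].to_numpy(dtype=float)
            # expand multi-nt intervals to single-nt entries
            reps = ends - starts
            pos = np.repeat(starts, reps) + _interval_offsets(reps)
            val = np.repeat(vals, reps)
            order = np.argsort(pos, kind="stable")
            data[(str(chrom), strand)] = (pos[order], val[order])
    return EndTrack(genome, end_kind, data, metadata or {})


def _interval_offsets(reps: np.ndarray) -> np.ndarray:
    if len(reps) == 0:
        return np.empty(0, dtype=np.int64)
    total = int(reps.sum())
    idx = np.arange(total, dtype=np.int64)
    starts = np.repeat(np.cumsum(reps) - reps, reps)
    return idx - starts
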