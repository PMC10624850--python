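"""Raw-read preprocessing: demultiplexing, UMI collapse, trimming.

Library layout (Read 1, sequenced antisense to the nascent RNA)::

    [6-nt barcode][C][revcomp(RNA insert)][G][6-nt UMI field][3'-adapter ...]

The 6-nt inline barcode sits at the start of Read 1 followed by the
constant ligation-site C; the 6-nt UMI field sits just before the
3'-adapter, preceded by the constant G. Barcode tables are stored in
read orientation (the reverse complement of the hexamer printed in the
adapter's sense). Processing removes the adapter, strips the two 7-nt
tags, and reverse-complements Read 1 so the stored sequence runs 5'→3'
along the nascent RNA.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

#: adapter encountered at the end of Read 1 / Read 2 (platform small-RNA design)
ADAPTER_READ1 = "TGGAATTCTCGGGTGCCAAGGAACTCCAGTCAC"
ADAPTER_READ2 = "GATCGTCGGACTGTAGAACTCTGAACGTGTAGATCTCGGTGGTCGCCGTATCATT"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReadRecord:
    name: str
    seq: str
    qual: str
    seq2: str | None = None
    qual2: str | None = None
    barcode: str | None = None
    umi: str | None = None


def read_fastq(path: str | Path) -> list[ReadRecord]:
    opener = gzip.open if str(path).endswith(".gz") else open
    reads = []
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            qual = fh.readline().strip()
            reads.append(ReadRecord(name=header.strip().lstrip("@"), seq=seq, qual=qual))
    return reads


def write_fastq(reads: list[ReadRecord], path: str | Path) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.seq}\n+\n{r.qual}\n")


def read_barcode_table(path: str | Path) -> dict[str, str]:
    """Read a ``sample<TAB>barcode`` table."""
    table = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, barcode = line.split("\t")[:2]
            table[sample] = barcode.upper()
    return table


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def validate_barcode_table(table: dict[str, str], max_mismatch: int = 0) -> None:
    codes = list(table.values())
    if len(set(codes)) != len(codes):
        raise ValueError("barcode table contains duplicate barcodes")
    for code in codes:
        if len(code) != 6 or set(code) - set("ACGTN"):
            raise ValueError(f"barcode {code!r} is not a 6-nt ACGTN string")
    required = 2 * max_mismatch
    for i, a in enumerate(codes):
        for b in codes[i + 1 :]:
            if _hamming(a, b) <= required:
                raise ValueError(
                    f"barcodes {a} and {b} are within Hamming distance "
                    f"{required} — ambiguous at max_mismatch={max_mismatch}"
                )


def split_barcodes(
    reads: list[ReadRecord],
    barcode_table: dict[str, str],
    max_mismatch: int = 0,
) -> dict[str, list[ReadRecord]]:
    """Assign each read to the sample whose barcode matches its first 6 nt.

    A read is assigned when exactly one barcode lies within
    ``max_mismatch`` of its leading hexamer; reads with no match, an
    ambiguous (equidistant) match, or an N in the barcode land in the
    ``"unassigned"`` bin. The output bins partition the input.
    """
    validate_barcode_table(barcode_table, max_mismatch)
    bins: dict[str, list[ReadRecord]] = {sample: [] for sample in barcode_table}
    bins["unassigned"] = []
    for read in reads:
        observed = read.seq[:6].upper()
        target = "unassigned"
        if len(observed) == 6 and "N" not in observed:
            best: list[str] = []
            best_d = max_mismatch + 1
            for sample, code in barcode_table.items():
                d = _hamming(observed, code)
                if d < best_d:
                    best, best_d = [sample], d
                elif d == best_d:
                    best.append(sample)
            if len(best) == 1 and best_d <= max_mismatch:
                target = best[0]
        read.barcode = observed if len(observed) == 6 else None
        bins[target].append(read)
    return bins


def collapse_umi(reads: list[ReadRecord]) -> list[ReadRecord]:
    """Collapse PCR duplicates: one representative per (UMI, sequence).

    Keeps the first occurrence of each group, preserving input order —
    idempotent, and invariant to duplicating the whole input. Reads
    whose UMI contains N form their own ordinary groups.
    """
    seen: set[tuple[str | None, str]] = set()
    out = []
    for read in reads:
        if read.umi is None:
            raise ValueError(f"read {read.name}: UMI not extracted before collapse")
        key = (read.umi, read.seq)
        if key not in seen:
            seen.add(key)
            out.append(read)
    return out


@dataclass
class TrimLog:
    n_input: int = 0
    n_kept: int = 0
    n_no_adapter: int = 0
    n_too_short: int = 0
    counts: dict = field(default_factory=dict)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tcount\n")
            for k in ("n_input", "n_kept", "n_no_adapter", "n_too_short"):
                fh.write(f"{k}\t{getattr(self, k)}\n")


def _strip_adapter(seq: str, adapter: str, min_overlap: int = 5) -> str | None:
    """Remove an adapter occurrence; suffix-prefix overlaps count too."""
    idx = seq.find(adapter)
    if idx >= 0:
        return seq[:idx]
    max_ov = min(len(adapter) - 1, len(seq))
    for ov in range(max_ov, min_overlap - 1, -1):
        if seq.endswith(adapter[:ov]):
            return seq[: len(seq) - ov]
    return None


def trim_and_orient(
    reads: list[ReadRecord],
    adapter1: str = ADAPTER_READ1,
    adapter2: str = ADAPTER_READ2,
) -> tuple[list[ReadRecord], TrimLog]:
    """Trim adapters and the two 7-nt tags; orient reads 5'→3'.

    For each Read 1: the 3'-adapter (and anything after it) is removed;
    the trailing 7 nt (constant G + UMI field) and leading 7 nt
    (barcode + constant C) are stripped, recording the barcode and UMI
    on the read; the remaining insert is reverse-complemented so the
    stored sequence runs 5'→3' of the nascent RNA. Reads without a
    recognizable adapter, or empty after tag removal, are dropped and
    counted in the log. Never increases read length.
    """
    out = []
    log = TrimLog(n_input=len(reads))
    for read in reads:
        trimmed = _strip_adapter(read.seq, adapter1)
        if trimmed is None:
            log.n_no_adapter += 1
            continue
        qual = read.qual[: len(trimmed)]
        if len(trimmed) <= 14:  # barcode+C and G+UMI leave no insert
            log.n_too_short += 1
            continue
        barcode = trimmed[:6]
        umi = trimmed[-6:]
        insert = trimmed[7:-7]
        insert_qual = qual[7:-7][::-1]
        seq2, qual2 = read.seq2, read.qual2
        if seq2 is not None:
            t2 = _strip_adapter(seq2, adapter2)
            if t2 is not None:
                seq2, qual2 = t2, (read.qual2 or "")[: len(t2)]
        out.append(
            ReadRecord(
                name=read.name, seq=revcomp(insert), qual=insert_qual,
                seq2=seq2, qual2=qual2, barcode=barcode, umi=umi,
            )
        )
        log.n_kept += 1
    return out, log


def preprocess_pool(
    reads: list[ReadRecord],
    barcode_table: dict[str, str],
    max_mismatch: int = 0,
) -> tuple[dict[str, list[ReadRecord]], dict[str, TrimLog]]:
    """Full preprocessing: demultiplex, trim/orient, collapse duplicates."""
    bins = split_barcodes(reads, barcode_table, max_mismatch)
    out: dict[str, list[ReadRecord]] = {}
    logs: dict[str, TrimLog] = {}
    for sample, sample_reads in bins.items():
        if sample == "unassigned":
            out[sample] = sample_reads
            continue
        trimmed, log = trim_and_orient(sample_reads)
        collapsed = collapse_umi(trimmed)
        log.counts["n_molecules"] = len(collapsed)
        out[sample] = collapsed
        logs[sample] = log
    return out, logs
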