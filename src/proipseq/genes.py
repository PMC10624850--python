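"""Gene models and annotation input.

Internally all coordinates are 0-based half-open genomic intervals. The
transcription start site (TSS) is the annotated first transcribed
nucleotide; the cleavage-and-polyadenylation site (CPS) is the last.
The transcription start nucleotide (TSN) — the empirically called +1 nt —
is attached to a gene only after calling and usually lies downstream of
the annotated TSS.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd


@dataclass(frozen=True)
class GeneModel:
    """A gene (or representative transcript) on one strand.

    ``start``/``end`` delimit the annotated transcription unit as a
    0-based half-open interval; ``tsn`` is the called +1 nt (absolute
    coordinate) once known.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    tsn: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})")

    @property
    def tss(self) -> int:
        """Annotated first transcribed nucleotide (0-based)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def cps(self) -> int:
        """Annotated last transcribed nucleotide (0-based)."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def with_tsn(self, tsn: int) -> "GeneModel":
        return replace(self, tsn=tsn)

    def offset_to_pos(self, anchor: int, offset: int) -> int:
        """Genomic position ``offset`` nt downstream (strand-aware) of ``anchor``."""
        return anchor + offset if self.strand == "+" else anchor - offset

    def pos_to_offset(self, anchor: int, pos: int) -> int:
        """Strand-aware downstream distance of ``pos`` from ``anchor``."""
        return pos - anchor if self.strand == "+" else anchor - pos


def read_annotations(path: str | Path, dialect: str | None = None) -> list[GeneModel]:
    """Read gene annotations from BED6/BED12 or GTF into GeneModel records.

    ``dialect`` is ``"bed"`` or ``"gtf"``; inferred from the file suffix
    when omitted. GTF coordinates (1-based inclusive) are converted to
    the internal 0-based half-open convention; BED is taken as is.
    Records with strand ``"."`` are rejected.
    """
    path = Path(path)
    if dialect is None:
        suffix = path.suffix.lower()
        if suffix in (".bed", ".bed6", ".bed12"):
            dialect = "bed"
        elif suffix in (".gtf", ".gff"):
            dialect = "gtf"
        else:
            raise ValueError(f"cannot infer annotation dialect from {path.name}")
    if dialect == "bed":
        return _read_bed_genes(path)
    if dialect == "gtf":
        return _read_gtf_genes(path)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def _read_bed_genes(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path.name}:{lineno}: BED record needs >=6 fields")
            chrom, start, end, name, _score, strand = fields[:6]
            if strand == ".":
                raise ValueError(f"{path.name}:{lineno}: strandless record rejected")
            try:
                gene = GeneModel(name, chrom, strand, int(start), int(end))
            except ValueError as exc:
                raise ValueError(f"{path.name}:{lineno}: {exc}") from exc
            genes.append(gene)
    return genes


def _read_gtf_genes(path: Path) -> list[GeneModel]:
    import pyranges as pr

    gr = pr.read_gtf(str(path))  # pyranges converts to 0-based half-open
    df = gr.df if hasattr(gr, "df") else pd.DataFrame(gr)
    features = df["Feature"].unique()
    feature = "transcript" if "transcript" in features else "gene"
    df = df[df["Feature"] == feature]
    name_col = next(
        (c for c in ("transcript_id", "gene_id", "gene_name") if c in df.columns), None
    )
    if name_col is None:
        raise ValueError(f"{path.name}: no transcript_id/gene_id attribute found")
    genes = []
    for row in df.itertuples(index=False):
        strand = getattr(row, "Strand")
        if strand == ".":
            raise ValueError(f"{path.name}: strandless {feature} {getattr(row, name_col)}")
        genes.append(
            GeneModel(
                gene_id=str(getattr(row, name_col)),
                chrom=str(getattr(row, "Chromosome")),
                strand=str(strand),
                start=int(getattr(row, "Start")),
                end=int(getattr(row, "End")),
            )
        )
    return genes


def write_bed_genes(genes: list[GeneModel], path: str | Path) -> None:
    """Write genes as BED6 (score column carries 0)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
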