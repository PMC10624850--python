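"""Sample manifest: the experimental design table driving the pipeline."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

MANIFEST_COLUMNS = ["sample", "condition", "antibody", "replicate", "barcode"]


@dataclass
class SampleManifest:
    """Rows of (sample, condition, antibody, replicate, barcode, paths...).

    Exactly one (condition, antibody) pair is the designated control —
    by default the unphosphorylated-CTD antibody in the unstressed
    condition — whose merged sample anchors all normalization factors.
    """

    table: pd.DataFrame
    control_condition: str
    control_antibody: str = "unPh"

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        key = self.table[["condition", "antibody", "replicate"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate (condition, antibody, replicate): {dup}")
        barcodes = self.table["barcode"].dropna()
        if barcodes.duplicated().any():
            raise ValueError("barcodes must be unique within a pool")
        if "control" in self.table.columns:
            flagged = self.table.loc[self.table["control"], ["condition", "antibody"]]
            pairs = set(map(tuple, flagged.values))
            if len(pairs) != 1:
                raise ValueError(f"manifest must designate exactly one control pair, got {len(pairs)}")
            ((cond, ab),) = pairs
            if (cond, ab) != (self.control_condition, self.control_antibody):
                raise ValueError(
                    f"control column designates {(cond, ab)} but manifest header "
                    f"says {(self.control_condition, self.control_antibody)}"
                )
        pair = (
            (self.table["condition"] == self.control_condition)
            & (self.table["antibody"] == self.control_antibody)
        )
        if not pair.any():
            raise ValueError(
                f"control pair ({self.control_condition}, {self.control_antibody}) "
                "has no rows in the manifest"
            )

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.table["condition"]))

    @property
    def antibodies(self) -> list[str]:
        return list(dict.fromkeys(self.table["antibody"]))

    @property
    def control_merged_id(self) -> str:
        return f"{self.control_condition}_{self.control_antibody}"

    def merged_groups(self) -> list[tuple[str, str, pd.DataFrame]]:
        """(condition, antibody, replicate rows) in manifest order."""
        groups = []
        for (cond, ab), sub in self.table.groupby(["condition", "antibody"], sort=False):
            groups.append((str(cond), str(ab), sub))
        return groups

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path: str | Path, control_condition: str | None = None,
        control_antibody: str = "unPh",
    ) -> "SampleManifest":
        table = pd.read_csv(path, sep="\t", dtype={"barcode": str})
        if control_condition is None:
            control_condition = str(table["condition"].iloc[0])
        return cls(table, control_condition, control_antibody)


def default_manifest(
    conditions: tuple[str, ...] = ("NHS", "HS30"),
    antibodies: tuple[str, ...] = ("unPh", "Ser2Ph", "Ser5Ph", "Ser7Ph"),
    n_replicates: int = 2,
) -> SampleManifest:
    """A full-factorial manifest with deterministic barcodes."""
    from .simulate import default_barcode_table

    rows = []
    for cond in conditions:
        for ab in antibodies:
            for rep in range(1, n_replicates + 1):
                rows.append(
                    dict(sample=f"{cond}_{ab}_r{rep}", condition=cond,
                         antibody=ab, replicate=rep, barcode=None)
                )
    table = pd.DataFrame(rows)
    codes = default_barcode_table(table["sample"].tolist())
    table["barcode"] = table["sample"].map(codes)
    return SampleManifest(table, control_condition=conditions[0])
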