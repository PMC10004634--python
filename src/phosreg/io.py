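"""Readers and writers for the tabular dialects the pipeline consumes.

Phosphosite tables are tab-separated exports in the style of a search engine's
site table (one row per site, per-experiment ratio columns). Expression data
use GCT 1.2 with CLS group labels; gene sets use GMT. Everything round-trips
through pandas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .silac import SITE_COLUMNS

log = logging.getLogger("phosreg")

__all__ = [
    "PhosphositeDialect",
    "read_phosphosite_table",
    "write_phosphosite_table",
    "read_gct",
    "write_gct",
    "read_gmt",
    "write_gmt",
    "read_cls",
]


@dataclass(frozen=True)
class PhosphositeDialect:
    """Column mapping of a phosphosite TSV plus the per-experiment swap map."""

    protein: str = "Protein names"
    gene: str = "Gene names"
    position: str = "Position"
    residue: str = "Amino acid"
    sequence_window: str = "Sequence window"
    localization_prob: str = "Localization prob"
    ratio_rep1: str = "Ratio H/L normalized Exp1"
    ratio_rep2_raw: str = "Ratio H/L Exp2"
    swap_map: dict = field(default_factory=lambda: {"Exp2": True})

    def columns(self) -> dict[str, str]:
        return {
            "protein": self.protein,
            "gene": self.gene,
            "position": self.position,
            "residue": self.residue,
            "sequence_window": self.sequence_window,
            "localization_prob": self.localization_prob,
            "ratio_rep1": self.ratio_rep1,
            "ratio_rep2_raw": self.ratio_rep2_raw,
        }


def read_phosphosite_table(
    path: str | Path, dialect: PhosphositeDialect | None = None
) -> pd.DataFrame:
    """Parse a phosphosite TSV into the canonical column layout.

    Rows with malformed numeric cells are dropped with a logged warning count;
    a missing mapped column is a hard error naming the column.
    """
    dialect = dialect or PhosphositeDialect()
    raw = pd.read_csv(path, sep="\t", dtype=str)
    mapping = dialect.columns()
    missing = [src for src in mapping.values() if src not in raw.columns]
    if missing:
        raise ValueError(f"missing mapped column(s): {', '.join(missing)}")
    df = raw[[mapping[c] for c in SITE_COLUMNS]].copy()
    df.columns = SITE_COLUMNS

    numeric = ["position", "localization_prob", "ratio_rep1", "ratio_rep2_raw"]
    parsed = df.copy()
    for col in numeric:
        parsed[col] = pd.to_numeric(df[col], errors="coerce")
    # ratios may legitimately be missing (empty cell); malformed = non-empty but unparseable
    bad = pd.Series(False, index=df.index)
    for col in numeric:
        nonempty = df[col].notna() & (df[col].str.strip() != "")
        bad |= nonempty & parsed[col].isna()
    # position and localization are mandatory per record
    bad |= parsed["position"].isna() | parsed["localization_prob"].isna()
    if bad.any():
        log.warning("dropped %d malformed row(s) while reading %s", int(bad.sum()), path)
    out = parsed.loc[~bad].reset_index(drop=True)
    out["position"] = out["position"].astype(int)
    out.attrs["n_malformed"] = int(bad.sum())
    return out


def write_phosphosite_table(
    records: pd.DataFrame, path: str | Path, dialect: PhosphositeDialect | None = None
) -> None:
    dialect = dialect or PhosphositeDialect()
    mapping = dialect.columns()
    out = records[SITE_COLUMNS].copy()
    out.columns = [mapping[c] for c in SITE_COLUMNS]
    out.to_csv(path, sep="\t", index=False)


def read_gct(path: str | Path) -> pd.DataFrame:
    """GCT 1.2 matrix (probes x samples); dimension header validated."""
    with open(path) as fh:
        version = fh.readline().strip()
        if not version.startswith("#1.2"):
            raise ValueError(f"unsupported GCT version line: {version!r}")
        dims = fh.readline().split()
        n_rows, n_cols = int(dims[0]), int(dims[1])
        body = pd.read_csv(fh, sep="\t")
    if body.shape[0] != n_rows or body.shape[1] - 2 != n_cols:
        raise ValueError(
            f"GCT dimension mismatch: header says {n_rows}x{n_cols}, "
            f"body is {body.shape[0]}x{body.shape[1] - 2}"
        )
    matrix = body.set_index(body.columns[0]).drop(columns=[body.columns[1]])
    matrix.index.name = "probe"
    return matrix


def write_gct(matrix: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{matrix.shape[0]}\t{matrix.shape[1]}\n")
        out = matrix.copy()
        out.insert(0, "Description", "na")
        out.insert(0, "Name", matrix.index)
        out.to_csv(fh, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene sets: name <tab> description <tab> member..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line {line_no}: need name, description, >=1 member")
            members = {g for g in parts[2:] if g}
            if not members:
                raise ValueError(f"GMT line {line_no}: empty gene set {parts[0]!r}")
            sets[parts[0]] = members
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


def read_cls(path: str | Path) -> list[str]:
    """CLS categorical phenotype labels, one per sample."""
    with open(path) as fh:
        header = fh.readline().split()
        n_samples = int(header[0])
        fh.readline()  # class-name line
        labels = fh.readline().split()
    if len(labels) != n_samples:
        raise ValueError(
            f"CLS mismatch: header says {n_samples} samples, found {len(labels)} labels"
        )
    return labels
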