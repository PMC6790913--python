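"""Readers and writers for every external table the pipeline touches.

The quantitation input follows the MaxQuant ``proteinGroups.txt`` dialect:
tab-separated, one row per protein group, per-sample ``Intensity <label>``
and optional ``iBAQ <label>`` columns, and ``Reverse`` / ``Potential
contaminant`` flag columns that contain ``+`` for true and are empty
otherwise.  An intensity of 0 (or an empty cell) means *not detected*;
downstream code never treats 0 as a measured abundance.

Gene sets for over-representation analysis are read from standard GMT
files (one set per line: name, description, members).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KD",
    "NT",
    "MOCK",
    "BLANK",
    "CONDITIONS",
    "SampleDesign",
    "ProteinQuantTable",
    "GeneSet",
    "GeneSetCollection",
    "DesignError",
    "TableFormatError",
    "read_design",
    "write_design",
    "read_protein_groups",
    "write_protein_groups",
    "read_gmt",
    "write_gmt",
    "read_table",
    "write_table",
    "DEFAULT_KERATIN_PATTERN",
]

KD = "KD"
NT = "NT"
MOCK = "MOCK"
BLANK = "BLANK"
CONDITIONS = frozenset({KD, NT, MOCK, BLANK})

#: Gene symbols beginning "KRT" followed by a digit (KRT1, KRT10, krt14 ...).
DEFAULT_KERATIN_PATTERN = re.compile(r"^KRT\d", re.IGNORECASE)


class DesignError(ValueError):
    """Raised when a sample-design table violates its invariants."""


class TableFormatError(ValueError):
    """Raised when an input table cannot be parsed as specified."""


# ---------------------------------------------------------------------------
# Sample design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleDesign:
    """Maps each mass-spectrometry sample label to donor, condition and
    technical-run index.  This is the pairing backbone of every computation:
    differential analysis compares, within each donor, the knockdown (KD)
    samples against the matched non-targeting (NT) control samples.
    """

    table: pd.DataFrame  # columns: sample_label, donor, condition, tech_rep

    def __post_init__(self) -> None:
        _validate_design_frame(self.table)

    @property
    def sample_labels(self) -> list[str]:
        return list(self.table["sample_label"])

    @property
    def donors(self) -> list[str]:
        """Donor identifiers in first-appearance order (BLANK rows excluded)."""
        sub = self.table[self.table["condition"] != BLANK]
        return list(dict.fromkeys(sub["donor"]))

    def samples(self, donor: str | None = None, condition: str | None = None) -> list[str]:
        """Sample labels matching the given donor and/or condition."""
        t = self.table
        if donor is not None:
            t = t[t["donor"] == donor]
        if condition is not None:
            t = t[t["condition"] == condition]
        return list(t["sample_label"])

    def require_paired(self) -> None:
        """Check every donor has both KD and NT samples (needed for
        differential analysis); raise :class:`DesignError` otherwise."""
        missing = []
        for donor in self.donors:
            for cond in (KD, NT):
                if not self.samples(donor=donor, condition=cond):
                    missing.append(f"{donor}/{cond}")
        if missing:
            raise DesignError(
                "differential analysis needs KD and NT samples for every "
                f"donor; missing: {', '.join(missing)}"
            )


def _validate_design_frame(table: pd.DataFrame) -> None:
    required = ["sample_label", "donor", "condition", "tech_rep"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise DesignError(f"design table missing columns: {missing}")
    dup = table["sample_label"][table["sample_label"].duplicated()]
    if len(dup):
        raise DesignError(f"duplicate sample_label(s): {sorted(set(dup))}")
    bad = set(table["condition"]) - CONDITIONS
    if bad:
        raise DesignError(f"unknown condition token(s): {sorted(bad)}")
    if (table["tech_rep"] < 1).any():
        raise DesignError("tech_rep indices must be >= 1")
    # tech_rep contiguous from 1 within each (donor, condition)
    for (donor, cond), grp in table.groupby(["donor", "condition"], sort=False):
        reps = sorted(grp["tech_rep"])
        if reps != list(range(1, len(reps) + 1)):
            raise DesignError(
                f"tech_rep indices for ({donor}, {cond}) are {reps}; "
                "expected contiguous 1..n"
            )


def read_design(path: str | Path) -> SampleDesign:
    """Read a tab-separated sample-design table.

    Expected header columns: ``sample_label``, ``donor``, ``condition``
    (case-insensitive KD / NT / MOCK / BLANK) and ``tech_rep``.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["sample_label", "donor", "condition", "tech_rep"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise DesignError(f"{path}: design table missing columns: {missing}")
    for i, tok in enumerate(raw["condition"]):
        if tok.strip().upper() not in CONDITIONS:
            raise DesignError(
                f"{path}, line {i + 2}: unknown condition token {tok!r}"
            )
    table = pd.DataFrame(
        {
            "sample_label": raw["sample_label"].str.strip(),
            "donor": raw["donor"].str.strip(),
            "condition": raw["condition"].str.strip().str.upper(),
            "tech_rep": pd.to_numeric(raw["tech_rep"]).astype(int),
        }
    )
    return SampleDesign(table)


def write_design(design: SampleDesign, path: str | Path) -> None:
    write_table(design.table, path)


# ---------------------------------------------------------------------------
# Protein quantitation table
# ---------------------------------------------------------------------------

_ID_COLUMNS = ("Protein IDs", "protein_group_id")
_GENE_COLUMNS = ("Gene names", "gene_name")
_NTHEO_COLUMNS = ("Number of theoretically observable peptides", "n_theoretical_peptides")
_REVERSE_COLUMNS = ("Reverse", "is_reverse")
_CONTAMINANT_COLUMNS = ("Potential contaminant", "is_contaminant")


@dataclass
class ProteinQuantTable:
    """Per-protein-group quantitation with identifier flags.

    ``annotations`` is indexed by protein_group_id with columns
    ``gene_name``, ``is_reverse``, ``is_contaminant``, ``is_keratin`` and
    ``n_theoretical_peptides``.  ``intensity`` (and the optional ``ibaq``)
    hold one column per sample label; 0 encodes *not detected*.
    """

    annotations: pd.DataFrame
    intensity: pd.DataFrame
    ibaq: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.annotations.index.duplicated().any():
            dups = self.annotations.index[self.annotations.index.duplicated()]
            raise TableFormatError(
                f"duplicate protein_group_id(s): {sorted(set(dups))[:5]}"
            )
        if not self.annotations.index.equals(self.intensity.index):
            raise TableFormatError("annotations and intensity indexes differ")
        if (self.intensity.to_numpy() < 0).any():
            raise TableFormatError("negative intensities are not allowed")
        if self.ibaq is not None and not self.ibaq.index.equals(self.intensity.index):
            raise TableFormatError("ibaq index differs from intensity index")

    @property
    def protein_ids(self) -> pd.Index:
        return self.annotations.index

    @property
    def sample_labels(self) -> list[str]:
        return list(self.intensity.columns)

    def __len__(self) -> int:
        return len(self.annotations)

    def copy(self) -> "ProteinQuantTable":
        return ProteinQuantTable(
            self.annotations.copy(),
            self.intensity.copy(),
            None if self.ibaq is None else self.ibaq.copy(),
        )

    def subset(self, ids: Iterable[str]) -> "ProteinQuantTable":
        idx = pd.Index(ids)
        return ProteinQuantTable(
            self.annotations.loc[idx],
            self.intensity.loc[idx],
            None if self.ibaq is None else self.ibaq.loc[idx],
        )


def _pick_column(columns: Sequence[str], candidates: Sequence[str]) -> str | None:
    for c in candidates:
        if c in columns:
            return c
    return None


def is_keratin_gene(gene_name: str, pattern: re.Pattern = DEFAULT_KERATIN_PATTERN,
                    explicit: Iterable[str] | None = None) -> bool:
    """True when any of the (semicolon-separated) gene symbols looks like a
    keratin, either by the pattern or by membership of an explicit list."""
    explicit_upper = {g.upper() for g in explicit} if explicit else set()
    for sym in str(gene_name).split(";"):
        sym = sym.strip()
        if not sym:
            continue
        if sym.upper() in explicit_upper or pattern.match(sym):
            return True
    return False


def read_protein_groups(
    path: str | Path,
    design: SampleDesign,
    keratin_pattern: re.Pattern = DEFAULT_KERATIN_PATTERN,
    keratin_genes: Iterable[str] | None = None,
) -> ProteinQuantTable:
    """Read a proteinGroups-dialect TSV against a sample design.

    Every design sample label must have a matching ``Intensity <label>``
    column; ``iBAQ <label>`` columns are optional (all-or-none).  Missing or
    empty numeric cells parse as 0 (undetected); a non-numeric cell is a
    hard error naming the row and column.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = list(raw.columns)

    id_col = _pick_column(cols, _ID_COLUMNS)
    if id_col is None:
        raise TableFormatError(f"{path}: no protein id column ({_ID_COLUMNS})")
    gene_col = _pick_column(cols, _GENE_COLUMNS)
    ntheo_col = _pick_column(cols, _NTHEO_COLUMNS)
    rev_col = _pick_column(cols, _REVERSE_COLUMNS)
    con_col = _pick_column(cols, _CONTAMINANT_COLUMNS)

    labels = design.sample_labels
    missing = [lab for lab in labels if f"Intensity {lab}" not in cols]
    if missing:
        raise TableFormatError(
            f"{path}: no 'Intensity <label>' column for design sample(s): {missing}"
        )
    have_ibaq = all(f"iBAQ {lab}" in cols for lab in labels)

    def numeric(colname: str) -> np.ndarray:
        s = raw[colname].str.strip()
        vals = pd.to_numeric(s.replace("", "0"), errors="coerce")
        if vals.isna().any():
            row = int(np.argmax(vals.isna().to_numpy()))
            raise TableFormatError(
                f"{path}: non-numeric cell {s.iloc[row]!r} in column "
                f"{colname!r}, data row {row + 1}"
            )
        return vals.to_numpy(dtype=float)

    def flag(colname: str | None) -> np.ndarray:
        if colname is None:
            return np.zeros(len(raw), dtype=bool)
        return (raw[colname].str.strip() == "+").to_numpy()

    ids = raw[id_col].str.strip()
    genes = raw[gene_col].str.strip() if gene_col else pd.Series([""] * len(raw))
    annotations = pd.DataFrame(
        {
            "gene_name": genes.to_numpy(),
            "is_reverse": flag(rev_col),
            "is_contaminant": flag(con_col),
            "n_theoretical_peptides": (
                numeric(ntheo_col).astype(int) if ntheo_col else np.zeros(len(raw), dtype=int)
            ),
        },
        index=pd.Index(ids, name="protein_group_id"),
    )
    annotations["is_keratin"] = [
        is_keratin_gene(g, keratin_pattern, keratin_genes) for g in annotations["gene_name"]
    ]

    intensity = pd.DataFrame(
        {lab: numeric(f"Intensity {lab}") for lab in labels}, index=annotations.index
    )
    ibaq = None
    if have_ibaq:
        ibaq = pd.DataFrame(
            {lab: numeric(f"iBAQ {lab}") for lab in labels}, index=annotations.index
        )
    return ProteinQuantTable(annotations, intensity, ibaq)


def write_protein_groups(table: ProteinQuantTable, path: str | Path) -> None:
    """Write a ProteinQuantTable in the proteinGroups dialect so that
    :func:`read_protein_groups` round-trips it."""
    ann = table.annotations
    out = pd.DataFrame(
        {
            "Protein IDs": ann.index,
            "Gene names": ann["gene_name"].to_numpy(),
            "Reverse": np.where(ann["is_reverse"], "+", ""),
            "Potential contaminant": np.where(ann["is_contaminant"], "+", ""),
            "Number of theoretically observable peptides": ann[
                "n_theoretical_peptides"
            ].to_numpy(),
        }
    )
    for lab in table.sample_labels:
        out[f"Intensity {lab}"] = table.intensity[lab].to_numpy()
    if table.ibaq is not None:
        for lab in table.sample_labels:
            out[f"iBAQ {lab}"] = table.ibaq[lab].to_numpy()
    write_table(out, path)


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]


@dataclass
class GeneSetCollection:
    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise TableFormatError(f"duplicate gene-set name(s): {dup}")
        for s in self.sets:
            if not s.members:
                raise TableFormatError(f"gene set {s.name!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one gene set per line, tab-separated
    ``name<TAB>description<TAB>member...``; duplicate members de-duplicated."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise TableFormatError(
                    f"{path}, line {lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            members = frozenset(g.strip() for g in fields[2:] if g.strip())
            sets.append(GeneSet(fields[0], fields[1], members))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


# ---------------------------------------------------------------------------
# Generic result tables
# ---------------------------------------------------------------------------

def write_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write any tabular result as UTF-8 TSV: header row, '.' decimal
    separator, no index column, NaN serialised as 'NA'."""
    rows.to_csv(path, sep="\t", index=False, na_rep="NA", encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    """Inverse of :func:`write_table` for generic result tables."""
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
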