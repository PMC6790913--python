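"""Cleaning, normalization and quality control of the quantitation table.

Pipeline order is fixed: remove decoys and contaminants, subtract the
blank-run keratin background, then normalize every sample to the lowest
total protein yield.  Subtraction precedes normalization so that blank
keratin mass cannot distort the per-sample scale factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ProteinQuantTable, SampleDesign

__all__ = [
    "NormalizedTable",
    "filter_contaminants_decoys",
    "subtract_keratin_blank",
    "normalize_total",
    "compute_ibaq",
    "replicate_correlation",
    "intensity_histogram",
    "preprocess",
]


@dataclass
class NormalizedTable(ProteinQuantTable):
    """A ProteinQuantTable after total-abundance normalization.

    Every sample's intensities have been multiplied by
    ``scale_factor = normalization_target / raw_total`` where the target
    is the smallest per-sample raw total, so all post-normalization
    totals are equal and every factor is <= 1.
    """

    scale_factors: pd.Series | None = None
    normalization_target: float = float("nan")


def filter_contaminants_decoys(
    table: ProteinQuantTable,
) -> tuple[ProteinQuantTable, dict[str, int]]:
    """Drop reversed-sequence decoys and flagged contaminants.

    A row flagged both reverse and contaminant is counted once, under
    reverse.  Keratin rows *not* flagged contaminant are retained: they
    are handled by blank subtraction, not removal.
    """
    ann = table.annotations
    n_reverse = int(ann["is_reverse"].sum())
    n_contaminant = int((ann["is_contaminant"] & ~ann["is_reverse"]).sum())
    keep = ~(ann["is_reverse"] | ann["is_contaminant"])
    report = {"reverse": n_reverse, "contaminant": n_contaminant}
    return table.subset(ann.index[keep]), report


def subtract_keratin_blank(
    table: ProteinQuantTable, blank: pd.Series | pd.DataFrame
) -> ProteinQuantTable:
    """Subtract blank-run keratin background from keratin rows.

    ``blank`` maps protein_group_id to a background intensity; a scalar
    per protein (applied to every sample) or a per-sample DataFrame.
    Non-keratin rows are untouched even if listed in ``blank``; results
    are floored at 0; blank entries for ids absent from the table are
    ignored with a warning.  Apply before normalization.
    """
    out = table.copy()
    unknown = blank.index.difference(table.protein_ids)
    if len(unknown):
        warnings.warn(
            f"blank entries for {len(unknown)} id(s) absent from the table "
            f"were ignored (e.g. {list(unknown[:3])})"
        )
    keratin_ids = table.protein_ids[table.annotations["is_keratin"]]
    target = keratin_ids.intersection(blank.index)
    if len(target) == 0:
        return out
    if isinstance(blank, pd.DataFrame):
        sub = blank.loc[target, out.intensity.columns]
    else:
        sub = pd.DataFrame(
            np.repeat(blank.loc[target].to_numpy()[:, None], out.intensity.shape[1], axis=1),
            index=target,
            columns=out.intensity.columns,
        )
    new_vals = (out.intensity.loc[target] - sub).clip(lower=0.0)
    out.intensity.loc[target] = new_vals
    return out


def normalize_total(table: ProteinQuantTable) -> NormalizedTable:
    """Normalize each sample to total protein abundance, adjusting to the
    lowest total protein yield: intensities are scaled so every sample's
    total equals the smallest pre-normalization total.  iBAQ values are
    scaled by the same per-sample factor to stay consistent."""
    totals = table.intensity.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total intensity: {list(zero)}")
    target = float(totals.min())
    factors = target / totals
    intensity = table.intensity.mul(factors, axis=1)
    ibaq = None if table.ibaq is None else table.ibaq.mul(factors, axis=1)
    return NormalizedTable(
        annotations=table.annotations.copy(),
        intensity=intensity,
        ibaq=ibaq,
        scale_factors=factors.rename("scale_factor"),
        normalization_target=target,
    )


def compute_ibaq(peptide_intensity_sum, n_theoretical_peptides):
    """iBAQ: summed tryptic-peptide intensity divided by the number of
    theoretically observable peptides.  Scalar or array-valued; a zero
    peptide count yields NaN with a warning."""
    s = np.asarray(peptide_intensity_sum, dtype=float)
    n = np.asarray(n_theoretical_peptides, dtype=float)
    if np.any(n == 0):
        warnings.warn("n_theoretical_peptides = 0: iBAQ undefined, returning NaN")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(n > 0, s / np.where(n > 0, n, 1.0), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def replicate_correlation(
    table: ProteinQuantTable,
    design: SampleDesign,
    use: str = "ibaq",
    min_common: int = 3,
) -> pd.DataFrame:
    """Pairwise Pearson correlation of log2 quantities between samples.

    For each sample pair, r is computed over proteins detected (> 0) in
    both samples, on log2(iBAQ) by default (log2 intensity when iBAQ is
    unavailable or ``use='intensity'``).  Pairs with fewer than
    ``min_common`` shared detected proteins get NaN.  The matrix is
    symmetric with unit diagonal.
    """
    if use == "ibaq" and table.ibaq is not None:
        values = table.ibaq
    else:
        values = table.intensity
    labels = [lab for lab in design.sample_labels if lab in values.columns]
    mat = values[labels].to_numpy(dtype=float)
    out = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            both = (mat[:, i] > 0) & (mat[:, j] > 0)
            if both.sum() < min_common:
                r = np.nan
            else:
                x = np.log2(mat[both, i])
                y = np.log2(mat[both, j])
                r = float(np.corrcoef(x, y)[0, 1])
            out.iat[i, j] = out.iat[j, i] = r
    return out


def intensity_histogram(
    table: ProteinQuantTable,
    bin_width: float = 1.0,
    use: str = "ibaq",
    normalised: bool = False,
) -> pd.DataFrame:
    """Per-sample histogram of log2 quantities of detected proteins.

    Returns a DataFrame indexed by the left bin edge (bins
    ``[edge, edge + bin_width)`` on the log2 scale) with one column per
    sample.  Zero values (undetected) fall in no bin, so each column
    sums to that sample's number of detected proteins (or to 1 with
    ``normalised=True``, as in a normalised-count QC plot).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    values = table.ibaq if (use == "ibaq" and table.ibaq is not None) else table.intensity
    arr = values.to_numpy(dtype=float)
    detected = arr > 0
    if not detected.any():
        return pd.DataFrame(columns=values.columns)
    logv = np.where(detected, np.log2(np.where(detected, arr, 1.0)), np.nan)
    lo = np.floor(np.nanmin(logv) / bin_width) * bin_width
    hi = np.floor(np.nanmax(logv) / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    cols = {}
    for j, lab in enumerate(values.columns):
        col = logv[:, j]
        col = col[~np.isnan(col)]
        counts, _ = np.histogram(col, bins=edges)
        if normalised and counts.sum() > 0:
            cols[lab] = counts / counts.sum()
        else:
            cols[lab] = counts
    out = pd.DataFrame(cols, index=pd.Index(edges[:-1], name="log2_bin_left"))
    return out


def preprocess(
    table: ProteinQuantTable, blank: pd.Series | pd.DataFrame | None = None
) -> tuple[NormalizedTable, dict[str, int]]:
    """Full cleaning pass: filter decoys/contaminants, subtract the blank
    keratin background (if given), normalize to the lowest total yield."""
    filtered, report = filter_contaminants_decoys(table)
    if blank is not None:
        filtered = subtract_keratin_blank(filtered, blank)
    return normalize_total(filtered), report
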