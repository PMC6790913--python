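"""Per-donor knockdown/control ratios, volcano statistics, and the
consistency-based UP/DOWN classification.

Rather than a significance cut-off, proteins are called differentially
abundant when the direction of change agrees across *all* biological
replicates (donors) and the magnitude passes a fold-ratio threshold in
at least three of four donors:

* DOWN: every donor with a defined ratio shows KD/NT < 1, at least
  ``min_qualifying`` donors have ratio <= ``down_ratio`` (0.5) *or* the
  protein dropped to undetectable in KD while detected in NT, and at
  most ``max_undetectable`` (2) donors are KD-undetectable.
* UP: every donor with a defined ratio shows KD/NT > 1, at least
  ``min_qualifying`` donors have ratio >= ``up_ratio`` (1.2), and no
  donor shows the protein lost in KD (an observed reduction contradicts
  an increase in all replicates).  A donor where the protein is absent
  from NT yields an undefined ratio and neither qualifies nor
  disqualifies either call.

The volcano statistic is the donor-mean log2(KD/NT) paired with an
unadjusted two-sided paired t-test on log10-transformed donor-level
abundances; the classification itself never uses the p-value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import KD, NT, ProteinQuantTable, SampleDesign

__all__ = [
    "DOWN",
    "UP",
    "NS",
    "INELIGIBLE",
    "ClassifierThresholds",
    "PairedTResult",
    "aggregate_technical",
    "donor_ratios",
    "eligibility_filter",
    "classify_consistency",
    "classify_all",
    "paired_t_log10",
    "volcano_table",
    "differential_calls",
    "volcano_plot",
]

DOWN = "DOWN"
UP = "UP"
NS = "NS"
INELIGIBLE = "INELIGIBLE"


@dataclass(frozen=True)
class ClassifierThresholds:
    """Thresholds of the consistency rule (defaults as used in the study)."""

    down_ratio: float = 0.5
    up_ratio: float = 1.2
    max_undetectable: int = 2
    min_detected_donors: int = 3
    min_qualifying: int = 3

    def __post_init__(self) -> None:
        if not self.down_ratio < 1 < self.up_ratio:
            raise ValueError("need down_ratio < 1 < up_ratio")


DEFAULT_THRESHOLDS = ClassifierThresholds()


def aggregate_technical(
    table: ProteinQuantTable, design: SampleDesign
) -> pd.DataFrame:
    """Collapse technical runs to one value per (protein, donor, condition).

    The aggregate is the arithmetic mean of normalized intensity over the
    technical runs in which the protein was detected (> 0); 0 when
    detected in none.  Returns a long DataFrame with columns
    protein_group_id, donor, condition, value, n_detected.
    """
    frames = []
    for (donor, cond), grp in design.table.groupby(["donor", "condition"], sort=False):
        if cond not in (KD, NT):
            continue
        labs = list(grp["sample_label"])
        block = table.intensity[labs].to_numpy(dtype=float)
        detected = block > 0
        n_det = detected.sum(axis=1)
        with np.errstate(invalid="ignore"):
            value = np.where(
                n_det > 0, block.sum(axis=1) / np.maximum(n_det, 1), 0.0
            )
        frames.append(
            pd.DataFrame(
                {
                    "protein_group_id": table.protein_ids,
                    "donor": donor,
                    "condition": cond,
                    "value": value,
                    "n_detected": n_det,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def donor_ratios(agg: pd.DataFrame) -> pd.DataFrame:
    """Per-protein, per-donor KD/NT ratios from the technical aggregate.

    Ratio is defined only when both conditions are detected; otherwise
    NaN (undefined).  Donors missing one condition entirely are excluded
    with a warning.  Columns: protein_group_id, donor, kd_value,
    nt_value, detected_kd, detected_nt, ratio.
    """
    wide = agg.pivot_table(
        index=["protein_group_id", "donor"],
        columns="condition",
        values="value",
        aggfunc="first",
    )
    dropped = [c for c in (KD, NT) if c not in wide.columns]
    if dropped:
        raise ValueError(f"no samples at all for condition(s): {dropped}")
    incomplete = wide.index[wide[KD].isna() | wide[NT].isna()]
    if len(incomplete):
        donors = sorted({d for _, d in incomplete})
        warnings.warn(
            f"donor(s) missing one condition excluded from differential: {donors}"
        )
        wide = wide.dropna(subset=[KD, NT])
    out = wide.reset_index().rename(columns={KD: "kd_value", NT: "nt_value"})
    out["detected_kd"] = out["kd_value"] > 0
    out["detected_nt"] = out["nt_value"] > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = out["kd_value"] / out["nt_value"]
    out["ratio"] = np.where(out["detected_kd"] & out["detected_nt"], ratio, np.nan)
    return out


def eligibility_filter(
    ratio_table: pd.DataFrame, min_detected_donors: int = 3
) -> pd.Index:
    """Proteins detected (in either condition) in at least
    ``min_detected_donors`` donors — the volcano/classification universe."""
    det = ratio_table["detected_kd"] | ratio_table["detected_nt"]
    n = det.groupby(ratio_table["protein_group_id"]).sum()
    return pd.Index(n.index[n >= min_detected_donors])


def classify_consistency(
    ratios: Sequence[float | None],
    thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS,
    kd_detected: Sequence[bool] | None = None,
    nt_detected: Sequence[bool] | None = None,
) -> str:
    """Classify one (eligible) protein from its per-donor ratios.

    ``ratios`` holds one entry per donor: a positive float when both
    conditions were detected, else None/NaN (undefined).  When detection
    flags are omitted, an undefined ratio is taken as the
    KD-undetectable / NT-detected case.  Returns DOWN, UP or NS.
    """
    vals = [None if (r is None or (isinstance(r, float) and math.isnan(r))) else float(r)
            for r in ratios]
    n = len(vals)
    if kd_detected is None:
        kd_detected = [r is not None for r in vals]
    if nt_detected is None:
        nt_detected = [True] * n
    defined = [r for r, k, t in zip(vals, kd_detected, nt_detected) if k and t]
    kd_lost = sum(1 for r, k, t in zip(vals, kd_detected, nt_detected) if t and not k)

    down = (
        all(r < 1 for r in defined)
        and sum(1 for r in defined if r <= thresholds.down_ratio) + kd_lost
        >= thresholds.min_qualifying
        and kd_lost <= thresholds.max_undetectable
    )
    up = (
        all(r > 1 for r in defined)
        and sum(1 for r in defined if r >= thresholds.up_ratio) >= thresholds.min_qualifying
        and kd_lost == 0
    )
    if down:
        return DOWN
    if up:
        return UP
    return NS


def classify_all(
    ratio_table: pd.DataFrame,
    thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Vectorised classification of every protein in a donor-ratio table.

    Returns a DataFrame indexed by protein_group_id with columns
    ``call`` (DOWN / UP / NS / INELIGIBLE) and ``n_donors_detected``.
    Proteins detected in fewer than ``min_detected_donors`` donors are
    INELIGIBLE and never receive a DOWN/UP/NS call.
    """
    g = ratio_table.groupby("protein_group_id", sort=True)
    ratio = ratio_table["ratio"]
    defined = ratio.notna()
    det_any = ratio_table["detected_kd"] | ratio_table["detected_nt"]
    kd_lost = ratio_table["detected_nt"] & ~ratio_table["detected_kd"]

    n_detected = det_any.groupby(ratio_table["protein_group_id"]).sum()
    n_defined = defined.groupby(ratio_table["protein_group_id"]).sum()
    n_lt1 = (defined & (ratio < 1)).groupby(ratio_table["protein_group_id"]).sum()
    n_gt1 = (defined & (ratio > 1)).groupby(ratio_table["protein_group_id"]).sum()
    n_le_down = (
        (defined & (ratio <= thresholds.down_ratio))
        .groupby(ratio_table["protein_group_id"])
        .sum()
    )
    n_ge_up = (
        (defined & (ratio >= thresholds.up_ratio))
        .groupby(ratio_table["protein_group_id"])
        .sum()
    )
    n_kd_lost = kd_lost.groupby(ratio_table["protein_group_id"]).sum()

    down = (
        (n_lt1 == n_defined)
        & (n_le_down + n_kd_lost >= thresholds.min_qualifying)
        & (n_kd_lost <= thresholds.max_undetectable)
    )
    up = (n_gt1 == n_defined) & (n_ge_up >= thresholds.min_qualifying) & (n_kd_lost == 0)
    eligible = n_detected >= thresholds.min_detected_donors

    call = pd.Series(NS, index=n_detected.index, name="call")
    call[down] = DOWN
    call[up] = UP
    call[~eligible] = INELIGIBLE
    return pd.DataFrame({"call": call, "n_donors_detected": n_detected.astype(int)})


class PairedTResult(NamedTuple):
    t: float
    df: float
    p: float
    n_pairs: int
    zero_variance: bool


def paired_t_log10(
    kd_values: Sequence[float], nt_values: Sequence[float]
) -> PairedTResult:
    """Two-sided paired t-test on log10-transformed abundances.

    Only pairs with both values > 0 contribute; df = usable pairs − 1.
    Fewer than 2 usable pairs, or zero variance of the paired
    differences, yields NaN statistics (the latter with
    ``zero_variance=True``).  P-values are reported unadjusted.
    """
    kd = np.asarray(kd_values, dtype=float)
    nt = np.asarray(nt_values, dtype=float)
    if kd.shape != nt.shape:
        raise ValueError("kd_values and nt_values must have equal length")
    usable = (kd > 0) & (nt > 0)
    n = int(usable.sum())
    if n < 2:
        return PairedTResult(math.nan, math.nan, math.nan, n, False)
    diffs = np.log10(kd[usable]) - np.log10(nt[usable])
    if np.allclose(diffs, diffs[0], rtol=0.0, atol=0.0):
        return PairedTResult(math.nan, float(n - 1), math.nan, n, True)
    res = stats.ttest_rel(np.log10(kd[usable]), np.log10(nt[usable]))
    return PairedTResult(float(res.statistic), float(n - 1), float(res.pvalue), n, False)


def volcano_table(
    ratio_table: pd.DataFrame,
    min_detected_donors: int = 3,
) -> pd.DataFrame:
    """Volcano coordinates for eligible proteins: mean per-donor
    log2(KD/NT) over donors with defined ratios, with the paired-t
    p-value on log10 donor-level abundances."""
    eligible = eligibility_filter(ratio_table, min_detected_donors)
    sub = ratio_table[ratio_table["protein_group_id"].isin(eligible)]
    rows = []
    for pid, grp in sub.groupby("protein_group_id", sort=True):
        r = grp["ratio"].to_numpy(dtype=float)
        defined = ~np.isnan(r)
        mean_l2 = float(np.mean(np.log2(r[defined]))) if defined.any() else math.nan
        tt = paired_t_log10(grp["kd_value"].to_numpy(), grp["nt_value"].to_numpy())
        rows.append(
            {
                "protein_group_id": pid,
                "mean_log2_ratio": mean_l2,
                "t": tt.t,
                "df": tt.df,
                "p": tt.p,
                "n_pairs": tt.n_pairs,
                "zero_variance": tt.zero_variance,
            }
        )
    return pd.DataFrame(rows)


def differential_calls(
    ratio_table: pd.DataFrame,
    thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """One row per protein: consistency call, per-donor ratios, donor-mean
    log2 ratio and unadjusted paired-t p-value."""
    calls = classify_all(ratio_table, thresholds)
    volcano = volcano_table(ratio_table, thresholds.min_detected_donors).set_index(
        "protein_group_id"
    )
    ratios_wide = ratio_table.pivot(
        index="protein_group_id", columns="donor", values="ratio"
    )
    ratios_wide.columns = [f"ratio_{d}" for d in ratios_wide.columns]
    out = calls.join(ratios_wide).join(
        volcano[["mean_log2_ratio", "t", "df", "p", "zero_variance"]]
    )
    out.index.name = "protein_group_id"
    return out.reset_index()


def volcano_plot(volcano: pd.DataFrame, path: str, calls: pd.DataFrame | None = None):
    """Write a volcano plot (mean log2 ratio vs −log10 p), optionally
    coloured by consistency call."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = volcano.dropna(subset=["mean_log2_ratio", "p"])
    colors = "0.6"
    if calls is not None:
        cmap = {DOWN: "tab:blue", UP: "tab:red", NS: "0.6", INELIGIBLE: "0.85"}
        call_of = calls.set_index("protein_group_id")["call"]
        colors = [cmap.get(call_of.get(p, NS), "0.6") for p in df["protein_group_id"]]
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(df["mean_log2_ratio"], -np.log10(df["p"]), s=4, c=colors, linewidths=0)
    ax.set_xlabel("mean log2 (KD / NT)")
    ax.set_ylabel("-log10 unadjusted p (paired t, log10 data)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
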