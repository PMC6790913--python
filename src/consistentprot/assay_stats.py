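"""Statistics for the companion bench assays.

Covers the small, explicitly defined computations around the proteomics
core: 2^-ΔΔCt qPCR fold changes against a reference gene, histology
layer-thickness summaries (mean of three slide positions, paired KD/NT
thickness ratios with mean ± SEM), mean-of-k functional measurements
(e.g. capacitance), per-replicate condition ratios for lipid species
with a t-based 95% CI, and a shared paired t-test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import KD, NT

__all__ = [
    "CtRecord",
    "ThicknessRecord",
    "ddct_fold_change",
    "qpcr_summary",
    "thickness_summary",
    "mean_of_k",
    "condition_ratio",
    "paired_t",
]


@dataclass(frozen=True)
class CtRecord:
    """qPCR cycle thresholds for one replicate under one condition."""

    replicate_id: str
    condition: str  # KD or NT
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for v in (self.ct_target, self.ct_reference):
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"Ct values must be finite and positive, got {v}")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


@dataclass(frozen=True)
class ThicknessRecord:
    """Layer thickness of one slide: three positions (right, middle, left)."""

    replicate_id: str
    condition: str
    layer: str  # VCL or SC
    positions: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.positions) != 3:
            raise ValueError("exactly three position measurements required")
        if any(p <= 0 for p in self.positions):
            raise ValueError("thickness measurements must be > 0")

    @property
    def mean(self) -> float:
        return float(np.mean(self.positions))


def ddct_fold_change(kd: CtRecord, nt: CtRecord) -> float:
    """Fold change by the 2^-ΔΔCt method for a matched replicate pair:
    ΔCt = Ct_target − Ct_reference per condition,
    ΔΔCt = ΔCt_KD − ΔCt_NT, fold = 2^(−ΔΔCt)."""
    ddct = kd.delta_ct - nt.delta_ct
    return float(2.0 ** (-ddct))


def qpcr_summary(ct_table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-replicate 2^-ΔΔCt fold changes and their summary.

    ``ct_table`` is long-format with columns replicate_id, condition
    (KD/NT), ct_target, ct_reference.  Replicates missing either
    condition are excluded with a warning.  Returns the per-replicate
    table (replicate_id, ddct, fold_change) and a summary dict with the
    mean fold change, SEM, and a paired t-test on the per-condition
    ΔCt values.
    """
    per_rep = []
    for rep, grp in ct_table.groupby("replicate_id", sort=True):
        by_cond = {c: g for c, g in grp.groupby("condition")}
        if KD not in by_cond or NT not in by_cond:
            warnings.warn(f"replicate {rep!r} missing a condition; excluded")
            continue
        kd_row = by_cond[KD].iloc[0]
        nt_row = by_cond[NT].iloc[0]
        kd = CtRecord(str(rep), KD, kd_row["ct_target"], kd_row["ct_reference"])
        nt = CtRecord(str(rep), NT, nt_row["ct_target"], nt_row["ct_reference"])
        per_rep.append(
            {
                "replicate_id": str(rep),
                "ddct": kd.delta_ct - nt.delta_ct,
                "fold_change": ddct_fold_change(kd, nt),
            }
        )
    per_rep = pd.DataFrame(per_rep)
    if per_rep.empty:
        raise ValueError("no complete KD/NT replicate pairs in Ct table")
    folds = per_rep["fold_change"].to_numpy()
    dcts = per_rep["ddct"].to_numpy()
    t, p = paired_t(dcts, np.zeros_like(dcts))
    summary = {
        "n": int(len(per_rep)),
        "mean_fold_change": float(folds.mean()),
        "sem_fold_change": float(folds.std(ddof=1) / math.sqrt(len(folds)))
        if len(folds) > 1
        else math.nan,
        "mean_ddct": float(dcts.mean()),
        "t": t,
        "p": p,
    }
    return per_rep, summary


def _records_from_frame(thickness: pd.DataFrame) -> list[ThicknessRecord]:
    pos_cols = [c for c in thickness.columns if c.startswith("pos_")]
    if len(pos_cols) != 3:
        raise ValueError(f"expected exactly three pos_* columns, got {pos_cols}")
    return [
        ThicknessRecord(
            str(row["replicate_id"]),
            str(row["condition"]),
            str(row["layer"]),
            tuple(float(row[c]) for c in pos_cols),
        )
        for _, row in thickness.iterrows()
    ]


def thickness_summary(
    records: Iterable[ThicknessRecord] | pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Histology layer-thickness analysis.

    Accepts ThicknessRecords or a long DataFrame (columns replicate_id,
    condition, layer, pos_left, pos_mid, pos_right).  Each slide is
    summarised as the mean of its three positions; per replicate and
    layer the KD/NT thickness ratio is formed; per layer the ratios are
    summarised as mean ± SEM (sd/√n) with a paired t-test on the
    per-replicate mean thicknesses.  Replicates missing either condition
    are excluded with a warning.

    Returns ``(per_replicate, per_layer)`` DataFrames.
    """
    if isinstance(records, pd.DataFrame):
        records = _records_from_frame(records)
    rows = pd.DataFrame(
        {
            "replicate_id": [r.replicate_id for r in records],
            "condition": [r.condition for r in records],
            "layer": [r.layer for r in records],
            "mean_um": [r.mean for r in records],
        }
    )
    per_rep = []
    for (layer, rep), grp in rows.groupby(["layer", "replicate_id"], sort=True):
        by_cond = dict(zip(grp["condition"], grp["mean_um"]))
        if KD not in by_cond or NT not in by_cond:
            warnings.warn(f"replicate {rep!r}, layer {layer!r} missing a condition; excluded")
            continue
        per_rep.append(
            {
                "layer": layer,
                "replicate_id": rep,
                "kd_mean_um": by_cond[KD],
                "nt_mean_um": by_cond[NT],
                "ratio": by_cond[KD] / by_cond[NT],
            }
        )
    per_rep = pd.DataFrame(per_rep)
    if per_rep.empty:
        raise ValueError("no complete KD/NT replicate pairs in thickness records")
    layer_rows = []
    for layer, grp in per_rep.groupby("layer", sort=True):
        ratios = grp["ratio"].to_numpy()
        t, p = paired_t(grp["kd_mean_um"].to_numpy(), grp["nt_mean_um"].to_numpy())
        layer_rows.append(
            {
                "layer": layer,
                "n": int(len(grp)),
                "mean_ratio": float(ratios.mean()),
                "sem_ratio": float(ratios.std(ddof=1) / math.sqrt(len(ratios)))
                if len(ratios) > 1
                else math.nan,
                "t": t,
                "p": p,
            }
        )
    return per_rep, pd.DataFrame(layer_rows)


def mean_of_k(values: Sequence[float], k: int) -> float:
    """Arithmetic mean of exactly k measurements (hard error otherwise)."""
    if len(values) != k:
        raise ValueError(f"expected exactly {k} values, got {len(values)}")
    return float(np.mean(values))


def condition_ratio(
    values_kd: Sequence[float],
    values_nt: Sequence[float],
    log_scale: bool = False,
) -> tuple[np.ndarray, dict]:
    """Element-wise per-replicate KD/NT ratios with mean and t-based 95% CI.

    Replicates with a non-positive NT denominator are excluded with a
    warning.  With ``log_scale=True`` the mean and CI are computed on
    log2 ratios and back-transformed (geometric summary).
    """
    kd = np.asarray(values_kd, dtype=float)
    nt = np.asarray(values_nt, dtype=float)
    if kd.shape != nt.shape:
        raise ValueError("paired value vectors must have equal length")
    ok = nt > 0
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} replicate(s) with non-positive NT value dropped")
    ratios = kd[ok] / nt[ok]
    n = len(ratios)
    if n == 0:
        raise ValueError("no usable replicate pairs")
    if log_scale:
        if np.any(ratios <= 0):
            raise ValueError("log-scale summary requires positive ratios")
        x = np.log2(ratios)
        back = lambda v: float(2.0 ** v)
    else:
        x = ratios
        back = float
    mean = x.mean()
    if n > 1 and x.std(ddof=1) > 0:
        sem = x.std(ddof=1) / math.sqrt(n)
        tcrit = stats.t.ppf(0.975, df=n - 1)
        lo, hi = mean - tcrit * sem, mean + tcrit * sem
    else:
        lo = hi = mean
    summary = {
        "n": n,
        "mean_ratio": back(mean),
        "ci95_low": back(lo),
        "ci95_high": back(hi),
    }
    return ratios, summary


def paired_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired t-test on untransformed values; (t, p), NaN when
    fewer than 2 pairs or the differences have zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    if len(x) < 2 or np.ptp(x - y) == 0:
        return math.nan, math.nan
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)
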