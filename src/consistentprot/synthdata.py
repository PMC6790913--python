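"""Synthetic data with known ground truth for the whole pipeline.

The generator emulates the paired skin-organoid knockdown study design:
``n_donors`` biological replicates (donor-matched KD and NT organoids),
each protein extract run in ``n_tech_reps`` technical replicates, with
thousands of protein groups quantified per sample.

Generative model, on the log2-intensity scale, for protein *p* in the
sample of donor *d*, condition *c*, technical run *t*:

    log2 I = mu_p + delta_d + beta_p * 1[c = KD] + eps

with ``mu_p ~ Uniform(base_mean_range)``, donor random effect
``delta_d ~ Normal(0, donor_sd)``, technical noise
``eps ~ Normal(0, tech_sd)``, and the planted knockdown effect ``beta_p``
equal to ``effect_log2_down`` for the DOWN_TRUE class,
``effect_log2_up`` for UP_TRUE and 0 otherwise.  Values whose log2
intensity falls below the detection limit are left-censored to 0
(the pipeline's "not detected" convention).

The table also carries contaminant keratins (condition-independent
means, flagged contaminant + keratin), a few endogenous keratins among
the null proteins (keratin-flagged but *not* contaminant, so that
blank-run subtraction acts on retained rows, as for genuinely expressed
epidermal keratins), and reversed-sequence decoys drawn from the same
null model so decoy removal is exercised non-trivially.

All outputs are pure functions of the configuration, seed included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .io_formats import (
    KD,
    NT,
    GeneSet,
    GeneSetCollection,
    ProteinQuantTable,
    SampleDesign,
)

__all__ = [
    "SynthConfig",
    "DOWN_TRUE",
    "UP_TRUE",
    "NULL_TRUE",
    "CONTAMINANT",
    "DECOY",
    "generate_dataset",
    "generate_blank_run",
    "generate_gene_sets",
    "generate_assay_tables",
]

DOWN_TRUE = "DOWN_TRUE"
UP_TRUE = "UP_TRUE"
NULL_TRUE = "NULL_TRUE"
CONTAMINANT = "CONTAMINANT"
DECOY = "DECOY"


@dataclass(frozen=True)
class SynthConfig:
    """Study-design and noise parameters of the generator.

    Defaults reproduce the proteomics study conditions: 4 donors x 2
    conditions in quadruplicate technical runs, 9000 protein groups, 5%
    planted down-regulated at log2 fold change -2.0, 5% up-regulated at
    +0.5 (deliberately near the 1.2-fold calling threshold), donor and
    technical standard deviations of 0.5 and 0.25 log2 units, and a
    detection limit at the 2nd percentile of the baseline means.
    """

    seed: int = 0
    n_donors: int = 4
    n_tech_reps: int = 4
    n_proteins: int = 9000
    frac_down: float = 0.05
    frac_up: float = 0.05
    effect_log2_down: float = -2.0
    effect_log2_up: float = 0.5
    donor_sd: float = 0.5
    tech_sd: float = 0.25
    detect_limit: float | None = None  # None -> quantile of baseline means
    detect_limit_quantile: float = 0.02
    n_keratin_contaminants: int = 10
    n_endogenous_keratins: int = 6
    n_decoys: int = 100
    base_mean_range: tuple[float, float] = (20.0, 30.0)
    blank_fraction: float = 0.3

    def __post_init__(self) -> None:
        if not (0 <= self.frac_down <= 1 and 0 <= self.frac_up <= 1):
            raise ValueError("frac_down and frac_up must lie in [0, 1]")
        if self.frac_down + self.frac_up >= 1:
            raise ValueError("frac_down + frac_up must be < 1")
        if self.donor_sd < 0 or self.tech_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_donors < 1 or self.n_tech_reps < 1 or self.n_proteins < 1:
            raise ValueError("n_donors, n_tech_reps, n_proteins must be >= 1")
        if not self.base_mean_range[0] < self.base_mean_range[1]:
            raise ValueError("base_mean_range must be an increasing pair")

    @property
    def donors(self) -> list[str]:
        return [f"MS{i + 1}" for i in range(self.n_donors)]


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    # independent deterministic streams per generator, all keyed on the seed
    return np.random.default_rng([int(config.seed) % (2**31), stream])


def _make_design(config: SynthConfig) -> SampleDesign:
    rows = []
    for donor in config.donors:
        for cond in (KD, NT):
            for t in range(1, config.n_tech_reps + 1):
                rows.append((f"{donor}_{cond}_{t}", donor, cond, t))
    return SampleDesign(
        pd.DataFrame(rows, columns=["sample_label", "donor", "condition", "tech_rep"])
    )


def generate_dataset(
    config: SynthConfig,
) -> tuple[ProteinQuantTable, SampleDesign, pd.Series]:
    """Generate a quantitation table, its design and per-protein truth labels.

    Returns
    -------
    table : ProteinQuantTable
        ``n_proteins + n_keratin_contaminants + n_decoys`` rows over the
        full design; decoys flagged ``is_reverse``; contaminant keratins
        flagged ``is_contaminant`` and ``is_keratin``.
    design : SampleDesign
    truth : pandas.Series
        protein_group_id -> one of DOWN_TRUE / UP_TRUE / NULL_TRUE /
        CONTAMINANT / DECOY, covering every generated row exactly once.
    """
    rng = _rng(config, 0)
    design = _make_design(config)
    labels = design.sample_labels
    n_samples = len(labels)
    lo, hi = config.base_mean_range

    n_down = int(round(config.frac_down * config.n_proteins))
    n_up = int(round(config.frac_up * config.n_proteins))
    n_null = config.n_proteins - n_down - n_up

    ids = [f"P{i + 1:05d}" for i in range(config.n_proteins)]
    genes = [f"GENE{i + 1:05d}" for i in range(config.n_proteins)]
    classes = np.array([DOWN_TRUE] * n_down + [UP_TRUE] * n_up + [NULL_TRUE] * n_null)
    beta = np.where(
        classes == DOWN_TRUE,
        config.effect_log2_down,
        np.where(classes == UP_TRUE, config.effect_log2_up, 0.0),
    )

    # endogenous keratins: rename the first few NULL proteins to KRT symbols
    n_endo = min(config.n_endogenous_keratins, n_null)
    endo_krt_numbers = [1, 2, 5, 6, 10, 14, 16, 17][: n_endo] if n_endo <= 8 else list(
        range(1, n_endo + 1)
    )
    for j in range(n_endo):
        genes[n_down + n_up + j] = f"KRT{endo_krt_numbers[j]}"

    mu = rng.uniform(lo, hi, size=config.n_proteins)
    delta = rng.normal(0.0, config.donor_sd, size=config.n_donors)
    donor_of = np.array([config.donors.index(d) for d in design.table["donor"]])
    is_kd = (design.table["condition"] == KD).to_numpy()

    log2i = (
        mu[:, None]
        + delta[donor_of][None, :]
        + beta[:, None] * is_kd[None, :]
        + rng.normal(0.0, config.tech_sd, size=(config.n_proteins, n_samples))
    )

    detect_limit = (
        float(np.quantile(mu, config.detect_limit_quantile))
        if config.detect_limit is None
        else float(config.detect_limit)
    )

    # contaminant keratins: condition- and donor-independent lab background
    n_con = config.n_keratin_contaminants
    con_ids = [f"CON__KER{i + 1:02d}" for i in range(n_con)]
    con_genes = [f"KRT{70 + i}" for i in range(n_con)]  # disjoint from endogenous
    con_mu = rng.uniform(lo, hi, size=n_con)
    con_log2i = con_mu[:, None] + rng.normal(0.0, config.tech_sd, size=(n_con, n_samples))

    # decoys: same null model as real proteins
    n_dec = config.n_decoys
    dec_ids = [f"REV__P{i + 1:04d}" for i in range(n_dec)]
    dec_mu = rng.uniform(lo, hi, size=n_dec)
    dec_log2i = (
        dec_mu[:, None]
        + delta[donor_of][None, :]
        + rng.normal(0.0, config.tech_sd, size=(n_dec, n_samples))
    )

    all_log2 = np.vstack([log2i, con_log2i, dec_log2i])
    intensity = np.where(all_log2 < detect_limit, 0.0, np.exp2(all_log2))

    all_ids = ids + con_ids + dec_ids
    all_genes = genes + con_genes + [""] * n_dec
    all_classes = np.concatenate([classes, [CONTAMINANT] * n_con, [DECOY] * n_dec])
    n_rows = len(all_ids)
    n_theo = rng.integers(5, 60, size=n_rows)

    index = pd.Index(all_ids, name="protein_group_id")
    is_keratin = np.array([g.startswith("KRT") for g in all_genes])
    annotations = pd.DataFrame(
        {
            "gene_name": all_genes,
            "is_reverse": np.array([False] * (config.n_proteins + n_con) + [True] * n_dec),
            "is_contaminant": np.array(
                [False] * config.n_proteins + [True] * n_con + [False] * n_dec
            ),
            "is_keratin": is_keratin,
            "n_theoretical_peptides": n_theo,
        },
        index=index,
    )
    intensity_df = pd.DataFrame(intensity, index=index, columns=labels)
    ibaq_df = intensity_df.div(pd.Series(n_theo, index=index), axis=0)

    table = ProteinQuantTable(annotations, intensity_df, ibaq_df)
    truth = pd.Series(all_classes, index=index, name="truth_class")
    return table, design, truth


def generate_blank_run(config: SynthConfig, table: ProteinQuantTable) -> pd.Series:
    """Blank-run keratin background: a fixed fraction
    (``config.blank_fraction``) of each keratin row's sample-mean
    intensity; zero for every non-keratin row."""
    mean_int = table.intensity.mean(axis=1)
    blank = np.where(
        table.annotations["is_keratin"].to_numpy(),
        config.blank_fraction * mean_int.to_numpy(),
        0.0,
    )
    return pd.Series(blank, index=table.protein_ids, name="blank_intensity")


def generate_gene_sets(
    truth: pd.Series,
    config: SynthConfig,
    table: ProteinQuantTable,
    set_size: int = 50,
    purity: float = 0.8,
    n_null_sets: int = 20,
) -> GeneSetCollection:
    """Gene sets for testing over-representation analysis.

    One set enriched for DOWN_TRUE genes and one for UP_TRUE genes, each
    with the given purity (fraction of members drawn from the truth
    class, remainder uniform from the other real genes), plus
    ``n_null_sets`` sets drawn uniformly from all real genes.
    """
    rng = _rng(config, 1)
    genes = table.annotations["gene_name"]
    real = truth.isin([DOWN_TRUE, UP_TRUE, NULL_TRUE])
    universe = genes[real].to_numpy()

    def enriched(cls: str, name: str) -> GeneSet:
        pool = genes[truth == cls].to_numpy()
        n_in = min(int(round(purity * set_size)), len(pool))
        members = list(rng.choice(pool, size=n_in, replace=False))
        others = np.setdiff1d(universe, pool)
        members += list(rng.choice(others, size=set_size - n_in, replace=False))
        return GeneSet(name, f"planted {cls} enriched, purity {purity}", frozenset(members))

    sets = [enriched(DOWN_TRUE, "DOWN_ENRICHED"), enriched(UP_TRUE, "UP_ENRICHED")]
    for i in range(n_null_sets):
        members = rng.choice(universe, size=set_size, replace=False)
        sets.append(GeneSet(f"NULL_SET_{i + 1:02d}", "random null set", frozenset(members)))
    return GeneSetCollection(sets)


@dataclass(frozen=True)
class AssayConfig:
    """Noise and effect parameters for the companion assay fixtures."""

    n_qpcr_replicates: int = 8
    planted_ddct: float = 3.0  # strong mRNA knockdown: fold change 2^-3
    base_dct: float = 8.0
    ct_reference_mean: float = 15.0
    ct_sd: float = 0.15
    replicate_dct_sd: float = 0.3

    n_histology_replicates: int = 10
    sc_ratio: float = 0.83  # planted stratum-corneum KD/NT thickness ratio
    vcl_ratio: float = 1.0  # viable cell layers unchanged
    nt_sc_um: float = 20.0
    nt_vcl_um: float = 60.0
    ratio_sd_log2: float = 0.25  # biological spread of per-replicate ratios
    position_cv: float = 0.10  # measurement noise per slide position


def generate_assay_tables(
    config: SynthConfig, assay: AssayConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired qPCR Ct and histology thickness fixtures with planted effects.

    Returns
    -------
    qpcr : DataFrame with columns replicate_id, condition, ct_target,
        ct_reference — target vs. EF1A-style reference cycle thresholds,
        with a planted knockdown of ``assay.planted_ddct`` cycles.
    thickness : DataFrame with columns replicate_id, condition, layer
        (VCL / SC), pos_left, pos_mid, pos_right — three measurement
        positions per slide, with planted KD/NT ratios per layer.
    """
    assay = assay or AssayConfig()
    rng = _rng(config, 2)

    qpcr_rows = []
    for i in range(1, assay.n_qpcr_replicates + 1):
        rep_effect = rng.normal(0.0, assay.replicate_dct_sd)
        for cond in (NT, KD):
            dct = assay.base_dct + rep_effect + (assay.planted_ddct if cond == KD else 0.0)
            ct_ref = assay.ct_reference_mean + rng.normal(0.0, assay.ct_sd)
            ct_tgt = ct_ref + dct + rng.normal(0.0, assay.ct_sd)
            qpcr_rows.append((f"R{i}", cond, ct_tgt, ct_ref))
    qpcr = pd.DataFrame(
        qpcr_rows, columns=["replicate_id", "condition", "ct_target", "ct_reference"]
    )

    thick_rows = []
    layer_base = {"VCL": (assay.nt_vcl_um, assay.vcl_ratio), "SC": (assay.nt_sc_um, assay.sc_ratio)}
    for i in range(1, assay.n_histology_replicates + 1):
        rep_scale = np.exp2(rng.normal(0.0, 0.2))  # overall thickness varies by donor
        for layer, (base_um, ratio) in layer_base.items():
            rep_ratio = ratio * np.exp2(rng.normal(0.0, assay.ratio_sd_log2))
            for cond in (NT, KD):
                mean_um = base_um * rep_scale * (rep_ratio if cond == KD else 1.0)
                pos = mean_um * (1.0 + rng.normal(0.0, assay.position_cv, size=3))
                thick_rows.append((f"R{i}", cond, layer, *pos))
    thickness = pd.DataFrame(
        thick_rows,
        columns=["replicate_id", "condition", "layer", "pos_left", "pos_mid", "pos_right"],
    )
    return qpcr, thickness
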