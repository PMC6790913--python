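"""Consistency-based differential abundance analysis for paired
knockdown vs. control label-free proteomics.

The package re-usably implements a donor-paired analysis of MaxQuant
proteinGroups-style quantitation: decoy/contaminant filtering, blank-run
keratin subtraction, total-abundance normalization to the lowest yield,
per-donor KD/NT ratios, a consistency-based UP/DOWN classification
(direction agreement in all donors plus fold thresholds in >= 3 of 4),
volcano statistics, hypergeometric over-representation analysis, and
the companion assay statistics (2^-ΔΔCt, thickness ratios, paired
t-tests).  A synthetic-data generator with known ground truth makes
every stage testable without the deposited raw data.
"""

from . import assay_stats, differential, enrichment, io_formats, preprocess_qc, synthdata
from .differential import (
    ClassifierThresholds,
    aggregate_technical,
    classify_consistency,
    differential_calls,
    donor_ratios,
    paired_t_log10,
)
from .io_formats import (
    GeneSetCollection,
    ProteinQuantTable,
    SampleDesign,
    read_design,
    read_gmt,
    read_protein_groups,
    write_table,
)
from .preprocess_qc import normalize_total, preprocess, replicate_correlation
from .enrichment import bh_fdr, hypergeometric_tail_p, ora
from .synthdata import SynthConfig, generate_dataset

__version__ = "0.1.0"

__all__ = [
    "assay_stats",
    "differential",
    "enrichment",
    "io_formats",
    "preprocess_qc",
    "synthdata",
    "ClassifierThresholds",
    "GeneSetCollection",
    "ProteinQuantTable",
    "SampleDesign",
    "SynthConfig",
    "aggregate_technical",
    "bh_fdr",
    "classify_consistency",
    "differential_calls",
    "donor_ratios",
    "generate_dataset",
    "hypergeometric_tail_p",
    "normalize_total",
    "ora",
    "paired_t_log10",
    "preprocess",
    "read_design",
    "read_gmt",
    "read_protein_groups",
    "replicate_correlation",
    "write_table",
]


def run_differential(table, design, blank=None, thresholds=None):
    """End-to-end convenience: preprocess a quantitation table and return
    (calls, ratio_table, normalized_table, removal_report)."""
    from .differential import DEFAULT_THRESHOLDS

    thresholds = thresholds or DEFAULT_THRESHOLDS
    design.require_paired()
    norm, report = preprocess(table, blank)
    agg = aggregate_technical(norm, design)
    ratios = donor_ratios(agg)
    calls = differential_calls(ratios, thresholds)
    return calls, ratios, norm, report
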