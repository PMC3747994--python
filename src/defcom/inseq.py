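"""Transposon-insertion (Tn-seq / INSeq) fitness scoring.

A saturating transposon mutant library is introduced into animals; each
mutant's fitness is the ratio of its representation (normalized
sequencing counts) in the fecal *output* population to its representation
in the gavaged *input* population. Mutants that vanish from the output
have an undefined ratio and are reported at a floor of 0.01 ("<0.01"),
as are computed ratios below the floor; the raw ratio is kept alongside.
Gene-level fitness aggregates mutants whose insertion falls within the
first 80% of the gene (3'-end insertions often leave function intact).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "normalize_library",
    "mutant_fitness",
    "fitness_table",
    "gene_fitness",
    "library_stats",
    "FITNESS_FLOOR",
    "COVERAGE_CUTOFF",
]

FITNESS_FLOOR = 0.01
COVERAGE_CUTOFF = 0.8


def normalize_library(counts: pd.Series) -> pd.Series:
    """Per-mutant proportions: count / population total."""
    if len(counts) == 0:
        raise ValueError("empty count table")
    total = counts.sum()
    if total <= 0:
        raise ValueError("population total must be positive")
    return counts / total


def mutant_fitness(
    input_prop: float, output_prop: float, floor: float = FITNESS_FLOOR
) -> tuple[float, bool]:
    """Fitness = output proportion / input proportion, floored at 0.01.

    Zero output (ratio denominator of zero instances) and computed ratios
    below the floor are both reported at the floor with ``floored=True``.
    Mutants with zero input representation cannot be normalized and must
    be excluded before calling.
    """
    if input_prop <= 0:
        raise ValueError("input proportion must be positive (exclude absent mutants)")
    raw = output_prop / input_prop
    if raw < floor:
        return floor, True
    return raw, False


def fitness_table(records: pd.DataFrame, floor: float = FITNESS_FLOOR) -> pd.DataFrame:
    """Per-mutant fitness from an insertion count table.

    ``records`` has columns mutant_id, gene_id, position_fraction,
    input_count, output_count. Mutants with zero input counts are
    excluded (noted in the ``n_excluded_zero_input`` attribute of the
    result). Adds input_prop, output_prop, fitness, raw_fitness, floored.
    """
    required = {"mutant_id", "input_count", "output_count"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records lack columns: {sorted(missing)}")
    keep = records["input_count"] > 0
    n_excluded = int((~keep).sum())
    out = records.loc[keep].copy()
    out["input_prop"] = normalize_library(out["input_count"])
    out["output_prop"] = normalize_library(out["output_count"])
    raw = out["output_prop"] / out["input_prop"]
    out["raw_fitness"] = raw
    out["floored"] = raw < floor
    out["fitness"] = raw.clip(lower=floor)
    out.attrs["n_excluded_zero_input"] = n_excluded
    return out


def gene_fitness(
    table: pd.DataFrame, coverage_cutoff: float = COVERAGE_CUTOFF
) -> pd.DataFrame:
    """Mean mutant fitness per gene over qualifying insertions.

    Qualifying insertions are genic with position_fraction ≤
    coverage_cutoff (default: the first 80% of the gene). Genes with no
    qualifying insertion are absent from the output.
    """
    qual = table[
        table["gene_id"].notna() & (table["position_fraction"] <= coverage_cutoff)
    ]
    if qual.empty:
        return pd.DataFrame(columns=["gene_fitness", "n_insertions"])
    agg = qual.groupby("gene_id").agg(
        gene_fitness=("fitness", "mean"), n_insertions=("fitness", "size")
    )
    return agg


def library_stats(
    records: pd.DataFrame,
    gene_catalog: pd.Series | list[str],
    coverage_cutoff: float = COVERAGE_CUTOFF,
) -> dict[str, float]:
    """Library summary: distinct mutants, ORF coverage, insertions per ORF.

    An ORF counts as covered when it has at least one insertion within its
    first ``coverage_cutoff`` fraction; the mean number of distinct
    insertion mutants per ORF is computed over covered ORFs only.
    """
    catalog = pd.Index(gene_catalog)
    qual = records[
        records["gene_id"].notna()
        & (records["position_fraction"] <= coverage_cutoff)
    ]
    per_gene = qual.groupby("gene_id").size().reindex(catalog, fill_value=0)
    covered = per_gene[per_gene > 0]
    return {
        "n_distinct_mutants": int(records["mutant_id"].nunique()),
        "pct_orfs_covered": 100.0 * len(covered) / len(catalog) if len(catalog) else np.nan,
        "mean_insertions_per_orf": float(covered.mean()) if len(covered) else np.nan,
    }
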