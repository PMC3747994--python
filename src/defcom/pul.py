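"""Polysaccharide utilization locus (PUL) activation calling.

PULs in Bacteroidetes are marked by adjacent susC/susD homolog pairs
(outer-membrane transporter + glycan-binding lipoprotein). Growing a
strain in minimal medium plus one carbohydrate at a time and comparing
each gene's normalized expression to the minimal-medium-plus-glucose
(MM-Glc) reference reveals which PULs a substrate switches on. A pair is
*reported* when either gene exceeds 100-fold induction in at least one
replicate, and called *activated* when, for both genes of the pair, at
least two replicates exceed 100-fold and the mean fold-change across all
replicates exceeds 100 (both comparisons strict). The in-vivo cross-
reference asks whether both genes of a pair were consistently detected at
the RNA level (≥5 of 7 animals) or protein level (2 of 2 animals) on a
diet.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SusCDPair",
    "pair_suscd",
    "fold_change_vs_reference",
    "reporting_filter",
    "activation_call",
    "ActivationCall",
    "call_pairs",
    "crossref_in_vivo",
]

FOLD_THRESHOLD = 100.0


@dataclass(frozen=True)
class SusCDPair:
    susC_gene_id: str
    susD_gene_id: str
    pul_id: Optional[str]
    species_id: str
    adjacency: int  # genomic order index of the susC gene


def pair_suscd(
    annotation: pd.DataFrame, max_intervening: int = 1
) -> tuple[list[SusCDPair], list[str]]:
    """Form susC/susD pairs from an annotation table.

    ``annotation`` needs columns gene_id, species, start (genome order)
    and sus_role; a ``pul`` column is carried through when present. Pairs
    are formed left-to-right within each species from a susC followed by a
    susD with at most ``max_intervening`` genes between them (and the same
    PUL id when both are annotated with one). Unpaired susC/susD homologs
    are returned separately, never as an error.
    """
    required = {"gene_id", "species", "start", "sus_role"}
    missing = required - set(annotation.columns)
    if missing:
        raise ValueError(f"annotation lacks columns: {sorted(missing)}")
    pairs: list[SusCDPair] = []
    unpaired: list[str] = []
    for species, sub in annotation.groupby("species"):
        sub = sub.sort_values("start").reset_index(drop=True)
        used: set[int] = set()
        roles = sub["sus_role"].fillna("none").to_numpy()
        for i in range(len(sub)):
            if roles[i] != "susC" or i in used:
                continue
            found = False
            for j in range(i + 1, min(i + 2 + max_intervening, len(sub))):
                if j in used:
                    continue
                if roles[j] == "susC":
                    break  # a new susC starts a new candidate cassette
                if roles[j] == "susD":
                    pul_i = sub.at[i, "pul"] if "pul" in sub else None
                    pul_j = sub.at[j, "pul"] if "pul" in sub else None
                    if (
                        pul_i is not None
                        and pul_j is not None
                        and not (isinstance(pul_i, float) and math.isnan(pul_i))
                        and pul_i != pul_j
                    ):
                        continue
                    pairs.append(
                        SusCDPair(
                            susC_gene_id=sub.at[i, "gene_id"],
                            susD_gene_id=sub.at[j, "gene_id"],
                            pul_id=pul_i if not (isinstance(pul_i, float) and math.isnan(pul_i)) else None,
                            species_id=species,
                            adjacency=i,
                        )
                    )
                    used.update((i, j))
                    found = True
                    break
            if not found:
                unpaired.append(sub.at[i, "gene_id"])
        for i in range(len(sub)):
            if roles[i] == "susD" and i not in used:
                unpaired.append(sub.at[i, "gene_id"])
    return pairs, unpaired


def fold_change_vs_reference(
    normalized_counts: pd.DataFrame,
    sample_conditions: pd.Series,
    reference: str = "MM-Glc",
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene, per-replicate fold-change versus the reference condition.

    FC = (value + pseudocount) / (mean reference value + pseudocount),
    computed on normalized counts. Columns of the result are the
    non-reference samples.
    """
    ref_samples = sample_conditions.index[sample_conditions == reference]
    if len(ref_samples) == 0:
        raise ValueError(f"no replicates of reference condition {reference!r}")
    ref_mean = normalized_counts[list(ref_samples)].mean(axis=1)
    others = [s for s in normalized_counts.columns if s not in set(ref_samples)]
    fc = normalized_counts[others].add(pseudocount, axis=0).div(
        ref_mean + pseudocount, axis=0
    )
    return fc


def reporting_filter(
    pair_fcs: pd.DataFrame, threshold: float = FOLD_THRESHOLD
) -> bool:
    """Reported ⇔ either gene exceeds the threshold in ≥1 replicate (strict >)."""
    if pair_fcs.shape[1] < 1:
        raise ValueError("need at least one replicate")
    return bool((pair_fcs.to_numpy(dtype=float) > threshold).any())


def activation_call(
    pair_fcs: pd.DataFrame,
    threshold: float = FOLD_THRESHOLD,
    min_reps_over: int = 2,
    mean: str = "arithmetic",
) -> bool:
    """Activated ⇔ both genes: ≥2 replicates > threshold and mean > threshold.

    ``pair_fcs`` has one row per gene of the pair (susC, susD) and one
    column per replicate. The mean across all replicates is arithmetic by
    default (``mean='geometric'`` is available). With a single replicate
    activation cannot be called and the pair is not activated (warning).
    """
    mat = pair_fcs.to_numpy(dtype=float)
    if mat.shape[1] < min_reps_over:
        warnings.warn(
            f"fewer than {min_reps_over} replicates: cannot call activation",
            RuntimeWarning,
            stacklevel=2,
        )
        return False
    for row in mat:
        if (row > threshold).sum() < min_reps_over:
            return False
        avg = float(np.mean(row)) if mean == "arithmetic" else float(
            np.exp(np.mean(np.log(np.maximum(row, 1e-300))))
        )
        if not avg > threshold:
            return False
    return True


@dataclass
class ActivationCall:
    pair: SusCDPair
    substrate: str
    mean_fc_susC: float
    mean_fc_susD: float
    reported: bool
    activated: bool


def call_pairs(
    pairs: Sequence[SusCDPair],
    fold_changes: pd.DataFrame,
    sample_conditions: pd.Series,
    threshold: float = FOLD_THRESHOLD,
) -> pd.DataFrame:
    """Apply reporting and activation rules for every (pair, substrate).

    ``fold_changes`` is gene × sample (from
    :func:`fold_change_vs_reference`); ``sample_conditions`` maps those
    samples to substrate labels. Returns one row per pair × substrate.
    """
    rows = []
    for substrate, cols in sample_conditions.groupby(sample_conditions).groups.items():
        cols = [c for c in cols if c in fold_changes.columns]
        if not cols:
            continue
        for pair in pairs:
            if (
                pair.susC_gene_id not in fold_changes.index
                or pair.susD_gene_id not in fold_changes.index
            ):
                continue
            sub = fold_changes.loc[[pair.susC_gene_id, pair.susD_gene_id], cols]
            rows.append(
                {
                    "susC": pair.susC_gene_id,
                    "susD": pair.susD_gene_id,
                    "pul": pair.pul_id,
                    "species": pair.species_id,
                    "substrate": substrate,
                    "mean_fc_susC": float(sub.iloc[0].mean()),
                    "mean_fc_susD": float(sub.iloc[1].mean()),
                    "reported": reporting_filter(sub, threshold),
                    "activated": activation_call(sub, threshold),
                }
            )
    return pd.DataFrame(rows)


def crossref_in_vivo(
    pair: SusCDPair,
    rna_detect: pd.DataFrame,
    protein_detect: pd.DataFrame,
    de_flags: Optional[dict[str, bool]] = None,
    rna_rule: tuple[int, int] = (5, 7),
) -> dict[str, str]:
    """Cross-reference a pair against in-vivo detection per diet.

    ``rna_detect`` / ``protein_detect`` are gene × animal boolean frames
    for one diet group each call; here they are dicts-of-frames flattened:
    pass frames with a MultiIndex column (diet, animal) or call per diet.
    For each diet and assay: expressed ⇔ both genes detected in ≥5/7
    animals (RNA, scaled ceil(5/7 × n)) or 2/2 animals (protein);
    ``expressed_significant`` when the DE flag for the pair's diet is set.
    Missing flags give category ``unknown``.
    """
    out = {}
    genes = [pair.susC_gene_id, pair.susD_gene_id]
    for assay, frame in (("rna", rna_detect), ("protein", protein_detect)):
        diets = frame.columns.get_level_values(0).unique()
        for diet in diets:
            sub = frame[diet]
            if not all(g in frame.index for g in genes):
                out[f"{assay}:{diet}"] = "unknown"
                continue
            n = sub.shape[1]
            if assay == "rna":
                need = math.ceil(rna_rule[0] / rna_rule[1] * n)
            else:
                need = n  # protein rule: all assayed animals
            ok = all(int(sub.loc[g].sum()) >= need for g in genes)
            if not ok:
                out[f"{assay}:{diet}"] = "absent"
            elif de_flags is not None and de_flags.get(diet, False):
                out[f"{assay}:{diet}"] = "expressed_significant"
            else:
                out[f"{assay}:{diet}"] = "expressed"
    return out
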