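"""Label-free spectral-count proteomics for defined communities.

Spectral counts per protein, collected in technical duplicate runs per
sample, are normalized either by the total microbial spectra in a run
(normalization by community, NBC — a protein's share of the whole
metaproteome) or by the total spectra of the protein's own species in
that run (normalization by species, NBS — regulation within a member).

Call rules mirror standard defined-community practice: a protein is
*present* in a sample when its two runs together carry at least four raw
spectral counts; differential testing requires at least three *valid*
runs (a run with more than five counts, strict); a protein is called UP
(DOWN) when its Mann–Whitney p and Storey q values are both below 0.05
and the group-median spectral-count difference exceeds 5 in magnitude,
and NULL otherwise. Under NBC, q-values are computed over all tested
proteins; under NBS, separately within each species' protein set.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.interpolate import UnivariateSpline

__all__ = [
    "normalize_spectra",
    "presence_call",
    "presence_table",
    "eligibility",
    "qvalues",
    "diff_call",
    "rna_protein_correlation",
]

_REQUIRED_COLS = {"protein", "species", "sample", "run", "count"}


def _check_long(table: pd.DataFrame) -> None:
    missing = _REQUIRED_COLS - set(table.columns)
    if missing:
        raise ValueError(f"spectral table lacks columns: {sorted(missing)}")


def normalize_spectra(table: pd.DataFrame, mode: str = "NBC") -> pd.DataFrame:
    """Add a ``norm`` column: count over the chosen per-run denominator.

    NBC divides by the total spectra in that (sample, run); NBS divides by
    the total spectra of the protein's species in that (sample, run). A
    species absent from a run (zero denominator under NBS) yields a
    missing value, not zero.
    """
    _check_long(table)
    if mode not in ("NBC", "NBS"):
        raise ValueError(f"mode must be 'NBC' or 'NBS', got {mode!r}")
    out = table.copy()
    keys = ["sample", "run"] if mode == "NBC" else ["species", "sample", "run"]
    denom = out.groupby(keys)["count"].transform("sum").astype(float)
    if mode == "NBC" and (denom <= 0).any():
        raise ValueError("a run has zero total spectra")
    out["norm"] = out["count"] / denom.replace(0, np.nan)
    return out


def presence_call(run_counts: Sequence[int], min_total: int = 4) -> bool:
    """Present ⇔ raw counts summed over a sample's runs ≥ min_total."""
    return int(np.sum(run_counts)) >= min_total


def presence_table(table: pd.DataFrame, min_total: int = 4) -> pd.DataFrame:
    """Protein × sample presence flags from run-aggregated raw counts."""
    _check_long(table)
    agg = table.groupby(["protein", "sample"])["count"].sum().unstack(fill_value=0)
    return agg >= min_total


def eligibility(
    run_counts: Sequence[int], min_valid_runs: int = 3, valid_above: int = 5
) -> bool:
    """Eligible for testing ⇔ ≥3 valid runs; valid ⇔ count > 5 (strict)."""
    counts = np.asarray(run_counts)
    return int((counts > valid_above).sum()) >= min_valid_runs


def qvalues(p_list: Sequence[float], pi0: Optional[float] = None) -> np.ndarray:
    """Storey q-values with smoother-based π₀ estimation.

    π₀ is estimated on the λ grid 0.05, 0.10, …, 0.95 as
    #{p > λ} / (m (1 − λ)) and extrapolated to λ → 1 with a cubic
    smoothing spline, clipped to (0, 1]. With fewer than 20 p-values the
    estimate is unstable and π₀ = 1 is used (Benjamini–Hochberg
    behavior). q(i) = min over j ≥ i of π₀ m p(j) / j on sorted p-values;
    q is monotone nondecreasing in p.
    """
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        return np.array([])
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        if m < 20:
            pi0 = 1.0
        else:
            lam = np.arange(0.05, 0.96, 0.05)
            pi0_lam = np.array([(p > L).sum() / (m * (1 - L)) for L in lam])
            spline = UnivariateSpline(lam, pi0_lam, k=3)
            pi0 = float(np.clip(spline(lam.max()), 1.0 / m, 1.0))
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def diff_call(
    table: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    mode: str = "NBC",
    alpha: float = 0.05,
    min_median_diff: float = 5.0,
) -> pd.DataFrame:
    """UP / DOWN / NULL calls per protein between two treatment groups.

    ``table`` is the long-format spectral-count table (protein, species,
    sample, run, count); groups are lists of sample ids. Only proteins
    with at least three valid runs (> 5 counts) across all runs are
    tested. The Mann–Whitney test uses per-sample normalized values (mean
    of the sample's run-level NBC/NBS values); the median-difference rule
    uses group medians of per-sample summed raw counts. q-values are
    computed over all tested proteins under NBC and within each species'
    tested set under NBS.

    Returns a table (protein, species, eligible, p, q, median_diff_counts,
    median_diff_norm, call); ineligible proteins carry no call.
    """
    from .transcriptomics import mann_whitney_exact

    norm = normalize_spectra(table, mode)
    groups = {"a": list(group_a), "b": list(group_b)}
    rows = []
    for (prot, species), sub in norm.groupby(["protein", "species"], sort=True):
        elig = eligibility(sub["count"].to_numpy())
        row: dict = {"protein": prot, "species": species, "eligible": elig}
        if elig:
            per_sample_norm = sub.groupby("sample")["norm"].mean()
            per_sample_raw = sub.groupby("sample")["count"].sum()
            va = per_sample_norm.reindex(groups["a"]).to_numpy(dtype=float)
            vb = per_sample_norm.reindex(groups["b"]).to_numpy(dtype=float)
            if np.isnan(va).any() or np.isnan(vb).any():
                row["eligible"] = False
            else:
                row["p"] = mann_whitney_exact(va, vb)
                ra = per_sample_raw.reindex(groups["a"]).to_numpy(dtype=float)
                rb = per_sample_raw.reindex(groups["b"]).to_numpy(dtype=float)
                row["median_diff_counts"] = float(
                    np.median(rb) - np.median(ra)
                )
                row["median_diff_norm"] = float(np.median(vb) - np.median(va))
        rows.append(row)
    out = pd.DataFrame(rows).set_index("protein")
    tested = out.index[out["eligible"] & out["p"].notna()] if "p" in out else []
    out["q"] = np.nan
    if len(tested):
        if mode == "NBC":
            out.loc[tested, "q"] = qvalues(out.loc[tested, "p"].to_numpy())
        else:
            for _, idx in out.loc[tested].groupby("species").groups.items():
                out.loc[idx, "q"] = qvalues(out.loc[idx, "p"].to_numpy())
    call = pd.Series(pd.NA, index=out.index, dtype="object")
    if "p" in out:
        testable = out["eligible"] & out["p"].notna()
        sig = testable & (out["p"] < alpha) & (out["q"] < alpha)
        call[testable] = "NULL"
        call[sig & (out["median_diff_counts"] > min_median_diff)] = "UP"
        call[sig & (out["median_diff_counts"] < -min_median_diff)] = "DOWN"
    out["call"] = call
    return out


def rna_protein_correlation(
    rna_lfc: pd.Series,
    protein_lfc: pd.Series,
    category_map: Optional[dict[str, str]] = None,
    min_genes: int = 3,
) -> pd.DataFrame:
    """Pearson r between RNA and protein log fold-changes.

    Inputs are per-gene log-transformed diet fold-changes; only genes
    present in both series are used (genes undetectable in either assay
    must already be excluded upstream). Returns the overall correlation
    and, when ``category_map`` is given, one row per functional category
    with at least ``min_genes`` genes.
    """
    common = rna_lfc.index.intersection(protein_lfc.index)
    if len(common) < min_genes:
        raise ValueError(f"need >= {min_genes} genes detected in both assays")
    rows = []

    def _corr(genes: pd.Index) -> float:
        r, _ = sps.pearsonr(
            rna_lfc[genes].to_numpy(dtype=float),
            protein_lfc[genes].to_numpy(dtype=float),
        )
        return float(r)

    rows.append({"category": "all", "n_genes": len(common), "r": _corr(common)})
    if category_map is not None:
        cats = pd.Series({g: category_map.get(g) for g in common}).dropna()
        for cat, genes in cats.groupby(cats).groups.items():
            genes = pd.Index(genes)
            if len(genes) < min_genes:
                warnings.warn(
                    f"category {cat!r} has < {min_genes} genes; r undefined",
                    RuntimeWarning,
                    stacklevel=2,
                )
                continue
            rows.append({"category": cat, "n_genes": len(genes), "r": _corr(genes)})
    return pd.DataFrame(rows).set_index("category")
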