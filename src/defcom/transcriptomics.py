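"""Metatranscriptome analysis for defined communities.

Counts from a defined community can be normalized in two ways that answer
different questions: at the *community* level (all genes in one table) a
function's share of the whole metatranscriptome is measured; at the
*species* level (each species' genes normalized independently) regulation
within each member is measured. When a dominant contributor's total
transcriptome share shifts between conditions, the two levels can disagree
in sign — the community trend "masks" the within-species regulation.
:func:`detect_masking` flags exactly this situation.

The module re-implements median-of-ratios size factors, EC-number binning,
a negative-binomial exact test, an exact Mann–Whitney U test, response-
kinetics classification, bootstrap-supported hierarchical clustering, and
the present / differentially-expressed call rules used for array data.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "CountMatrix",
    "DiffResult",
    "KineticsLabel",
    "size_factors",
    "normalize",
    "bin_by_ec",
    "nb_exact_test",
    "mann_whitney_exact",
    "classify_kinetics",
    "detect_masking",
    "cluster_with_bootstrap",
    "present_and_de_calls",
    "detection_percentages",
]


@dataclass
class CountMatrix:
    """Feature × sample counts with annotation and normalization state.

    ``counts`` is features × samples; ``annotation`` maps feature →
    species / EC / CAZy / KEGG category; ``sample_meta`` maps sample →
    diet / animal / run. ``state`` is one of ``raw``,
    ``community_normalized``, ``species_normalized``.
    """

    counts: pd.DataFrame
    annotation: pd.DataFrame
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    assay: str = "rnaseq"
    state: str = "raw"
    size_factors: Optional[pd.DataFrame] = None  # rows: scope, cols: samples

    def require_raw(self) -> None:
        if self.state != "raw":
            raise ValueError(f"operation requires raw counts, matrix is {self.state!r}")

    def species_of(self, feature_ids: Iterable[str]) -> pd.Series:
        return self.annotation.loc[list(feature_ids), "species"]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each feature with nonzero counts in *all* samples, compute
    count / geometric mean of that feature across samples; the factor for
    a sample is the median of those ratios. If no feature is nonzero in
    all samples, falls back to library-size ratios (scaled to geometric
    mean 1) with a warning.
    """
    mat = counts.to_numpy(dtype=float)
    usable = (mat > 0).all(axis=1)
    if not usable.any():
        warnings.warn(
            "no feature nonzero in all samples; falling back to library-size factors",
            RuntimeWarning,
            stacklevel=2,
        )
        lib = mat.sum(axis=0)
        if (lib <= 0).any():
            raise ValueError("empty sample: cannot compute size factors")
        return pd.Series(lib / np.exp(np.mean(np.log(lib))), index=counts.columns)
    sub = mat[usable]
    log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = sub / np.exp(log_geo)
    return pd.Series(np.median(ratios, axis=0), index=counts.columns)


def normalize(matrix: CountMatrix, level: str = "community") -> CountMatrix:
    """Normalize a raw matrix at community or species level.

    Community level computes one size-factor set from all features;
    species level computes size factors independently within each species'
    feature subset and applies them only there. Species with fewer than
    two features fall back to library-size factors for that subset.
    """
    matrix.require_raw()
    if level not in ("community", "species"):
        raise ValueError(f"level must be 'community' or 'species', got {level!r}")
    counts = matrix.counts
    if level == "community":
        sf = size_factors(counts)
        norm = counts / sf
        sf_tab = pd.DataFrame([sf.to_numpy()], index=["community"], columns=counts.columns)
        state = "community_normalized"
    else:
        species = matrix.annotation.loc[counts.index, "species"]
        norm = counts.astype(float).copy()
        sf_rows = {}
        for sid, idx in counts.groupby(species).groups.items():
            sub = counts.loc[idx]
            if len(idx) < 2:
                lib = sub.sum(axis=0).to_numpy(dtype=float)
                sf = pd.Series(
                    lib / np.exp(np.mean(np.log(np.maximum(lib, 1e-12)))),
                    index=counts.columns,
                )
            else:
                sf = size_factors(sub)
            norm.loc[idx] = sub / sf
            sf_rows[sid] = sf.to_numpy()
        sf_tab = pd.DataFrame(sf_rows, index=counts.columns).T
        state = "species_normalized"
    return CountMatrix(
        counts=norm,
        annotation=matrix.annotation,
        sample_meta=matrix.sample_meta,
        assay=matrix.assay,
        state=state,
        size_factors=sf_tab,
    )


def _split_ecs(ec: object) -> list[str]:
    if ec is None or (isinstance(ec, float) and math.isnan(ec)):
        return []
    return [e.strip() for e in str(ec).replace(",", ";").split(";") if e.strip()]


def bin_by_ec(
    matrix: CountMatrix, species: Optional[str] = None
) -> pd.DataFrame:
    """Collapse raw gene counts to EC-number bins (EC × sample totals).

    Genes without an EC contribute to no bin; a gene annotated with
    multiple ECs contributes its full count to each of them. Restricting
    to ``species`` bins only that species' genes (the within-species view
    used for masking analysis).
    """
    matrix.require_raw()
    annot = matrix.annotation.loc[matrix.counts.index]
    keep = annot.index
    if species is not None:
        keep = annot.index[annot["species"] == species]
    rows: dict[str, np.ndarray] = {}
    for gene in keep:
        for ec in _split_ecs(annot.at[gene, "ec"]):
            vec = matrix.counts.loc[gene].to_numpy(dtype=float)
            rows[ec] = rows.get(ec, 0) + vec
    if not rows:
        return pd.DataFrame(columns=matrix.counts.columns)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=matrix.counts.columns)
    return out.sort_index()


# ---------------------------------------------------------------------------
# tests


@dataclass
class DiffResult:
    """Per-feature differential test results (B over A)."""

    table: pd.DataFrame  # columns: statistic, p, q, fold_change, direction

    def significant(self, alpha: float = 0.05) -> pd.Index:
        return self.table.index[self.table["p"] < alpha]


def _nb_pmf(k: np.ndarray, mu: float, dispersion: float) -> np.ndarray:
    if mu <= 0:
        return np.where(k == 0, 1.0, 0.0)
    if dispersion <= 1e-12:
        return sps.poisson.pmf(k, mu)
    r = 1.0 / dispersion
    return sps.nbinom.pmf(k, r, r / (r + mu))


def _mom_dispersion(norm_a: np.ndarray, norm_b: np.ndarray, floor: float = 1e-8) -> float:
    """Method-of-moments NB dispersion pooled over both groups."""
    alphas = []
    for g in (norm_a, norm_b):
        if len(g) >= 2:
            m = g.mean()
            if m > 0:
                alphas.append((g.var(ddof=1) - m) / m**2)
    if not alphas:
        return floor
    return max(float(np.mean(alphas)), floor)


def nb_exact_test(
    ec_matrix: pd.DataFrame,
    size_factors: pd.Series,
    group_a: Sequence[str],
    group_b: Sequence[str],
    dispersion: Optional[float] = None,
    dispersion_mode: str = "pooled",
    pseudocount: float = 1.0,
) -> DiffResult:
    """Two-sided exact test of equal means under a negative binomial model.

    Group totals per feature are modeled as NB with a dispersion
    estimated by method-of-moments on normalized counts (floored at
    1e-8). With few replicates per-feature estimates are unstable, so the
    default ``dispersion_mode='pooled'`` shares one dispersion — the
    median of the per-feature estimates — across all features (the
    generator and most small-n count data fit a shared dispersion well);
    ``'per-feature'`` uses each feature's own estimate and a float
    ``dispersion`` overrides both. The p-value sums the probabilities of
    all splits of the observed grand total that are no more likely than
    the observed one; at dispersion 0 the model degenerates to Poisson
    totals, i.e. the conditional binomial exact test. Fold changes are
    (mean normalized B + pc) / (mean normalized A + pc).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 samples per group")
    if dispersion_mode not in ("pooled", "per-feature"):
        raise ValueError(f"unknown dispersion_mode {dispersion_mode!r}")
    sf_a = size_factors[list(group_a)].to_numpy(dtype=float)
    sf_b = size_factors[list(group_b)].to_numpy(dtype=float)
    mat_a = ec_matrix[list(group_a)].to_numpy(dtype=float)
    mat_b = ec_matrix[list(group_b)].to_numpy(dtype=float)
    if dispersion is not None:
        alphas = np.full(len(ec_matrix), float(dispersion))
    else:
        alphas = np.array(
            [
                _mom_dispersion(mat_a[i] / sf_a, mat_b[i] / sf_b)
                for i in range(len(ec_matrix))
            ]
        )
        if dispersion_mode == "pooled" and len(alphas):
            alphas = np.full_like(alphas, np.median(alphas))
    rows = []
    for i, feat in enumerate(ec_matrix.index):
        ca, cb = mat_a[i], mat_b[i]
        ka, kb = int(ca.sum()), int(cb.sum())
        ks = ka + kb
        mean_a = (ca / sf_a).mean()
        mean_b = (cb / sf_b).mean()
        fc = (mean_b + pseudocount) / (mean_a + pseudocount)
        if ks == 0:
            p = 1.0
        else:
            alpha = alphas[i]
            mu = ks / (sf_a.sum() + sf_b.sum())
            k = np.arange(ks + 1)
            pa = _nb_pmf(k, mu * sf_a.sum(), alpha)
            pb = _nb_pmf(ks - k, mu * sf_b.sum(), alpha)
            joint = pa * pb
            total = joint.sum()
            p = 1.0 if total <= 0 else min(
                1.0, float(joint[joint <= joint[ka] * (1 + 1e-12)].sum() / total)
            )
        direction = "up" if fc > 1 else ("down" if fc < 1 else "none")
        rows.append(
            {"feature": feat, "statistic": float(ka), "p": p, "fold_change": fc, "direction": direction}
        )
    tab = pd.DataFrame(rows).set_index("feature")
    from .proteomics import qvalues  # deferred: proteomics imports this module

    tab["q"] = qvalues(tab["p"].to_numpy())
    return DiffResult(tab[["statistic", "p", "q", "fold_change", "direction"]])


def mwu_test(
    values: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    pseudocount: float = 1.0,
) -> DiffResult:
    """Per-feature exact Mann–Whitney U test on (normalized) values.

    Nonparametric companion to :func:`nb_exact_test`; used for the
    community- vs species-level comparisons behind masking detection.
    """
    rows = []
    for feat in values.index:
        va = values.loc[feat, list(group_a)].to_numpy(dtype=float)
        vb = values.loc[feat, list(group_b)].to_numpy(dtype=float)
        p = mann_whitney_exact(va, vb)
        fc = (vb.mean() + pseudocount) / (va.mean() + pseudocount)
        direction = "up" if fc > 1 else ("down" if fc < 1 else "none")
        rows.append(
            {
                "feature": feat,
                "statistic": float(sps.rankdata(np.concatenate([va, vb]))[: len(va)].sum()),
                "p": p,
                "fold_change": fc,
                "direction": direction,
            }
        )
    tab = pd.DataFrame(rows).set_index("feature")
    from .proteomics import qvalues

    tab["q"] = qvalues(tab["p"].to_numpy())
    return DiffResult(tab[["statistic", "p", "q", "fold_change", "direction"]])


def mann_whitney_exact(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Two-sided exact Mann–Whitney U p-value.

    The null distribution of U is built by full enumeration of all
    C(n_a + n_b, n_a) group labelings of the pooled midranks when that is
    tractable (≤ 184,756 labelings, i.e. n ≤ 20); the p-value is the
    fraction of labelings with |U − n_a n_b / 2| at least as large as
    observed. Larger inputs fall back to scipy's implementation.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("missing values are not allowed")
    na, nb = len(a), len(b)
    if na < 1 or nb < 1:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks
    mid = na * nb / 2.0
    r_a = ranks[:na].sum()
    u_obs = r_a - na * (na + 1) / 2.0
    dev_obs = abs(u_obs - mid)
    n = na + nb
    if math.comb(n, na) <= 184_756:
        count = 0
        total = 0
        base = na * (na + 1) / 2.0
        for combo in itertools.combinations(range(n), na):
            u = ranks[list(combo)].sum() - base
            if abs(u - mid) >= dev_obs - 1e-9:
                count += 1
            total += 1
        return count / total
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# kinetics


@dataclass
class KineticsLabel:
    label: str  # rapid | gradual | delayed | none
    fraction_of_change_by_day2: float


def classify_kinetics(
    trajectory: pd.Series,
    switch_day: int,
    phase_end_day: int,
    response_floor: Optional[float] = None,
) -> KineticsLabel:
    """Classify a response trajectory as rapid, gradual, delayed or none.

    ``trajectory`` is indexed by day. The net change is value(phase end) −
    value(switch). Below the response floor (default: 25% of the
    trajectory's dynamic range) the label is ``none``. Otherwise: *rapid*
    if at least ⅔ of the net change is reached within 2 days of the
    switch; *delayed* if at most ⅓ is reached early and at least ⅔ of the
    net change accrues in the final inter-sample interval; *gradual*
    otherwise.
    """
    days = trajectory.index.to_numpy()
    if switch_day not in days or phase_end_day not in days:
        raise ValueError("trajectory must include switch_day and phase_end_day")
    early_days = [d for d in days if switch_day < d <= switch_day + 2]
    if not early_days:
        raise ValueError("trajectory must include a day within 2 d after the switch")
    if response_floor is None:
        response_floor = 0.25 * (trajectory.max() - trajectory.min())
    v0 = trajectory[switch_day]
    v_end = trajectory[phase_end_day]
    net = v_end - v0
    early = trajectory[max(early_days)] - v0
    frac_early = float(early / net) if net != 0 else 0.0
    if abs(net) < response_floor or net == 0:
        return KineticsLabel("none", frac_early)
    phase_days = sorted(d for d in days if switch_day <= d <= phase_end_day)
    last_interval = v_end - trajectory[phase_days[-2]]
    if frac_early >= 2 / 3:
        label = "rapid"
    elif frac_early <= 1 / 3 and last_interval / net >= 2 / 3:
        label = "delayed"
    else:
        label = "gradual"
    return KineticsLabel(label, frac_early)


# ---------------------------------------------------------------------------
# masking


def detect_masking(
    community_results: DiffResult,
    species_results: DiffResult,
    alpha: float = 0.05,
) -> list[str]:
    """Flag features whose community- and species-level trends conflict.

    A feature is flagged when both levels are significant at ``alpha`` and
    the fold-change directions are opposite — the signature of a
    community-level trend that masks regulation within the dominant
    contributing species. Features absent at either level are skipped.
    """
    flagged = []
    ct, st = community_results.table, species_results.table
    for feat in ct.index.intersection(st.index):
        pc, ps = ct.at[feat, "p"], st.at[feat, "p"]
        dc, ds = ct.at[feat, "direction"], st.at[feat, "direction"]
        if pc < alpha and ps < alpha and {dc, ds} == {"up", "down"}:
            flagged.append(feat)
    return flagged


def dominant_contributor(matrix: CountMatrix) -> pd.Series:
    """Species contributing the largest share of each EC bin's counts."""
    matrix.require_raw()
    annot = matrix.annotation.loc[matrix.counts.index]
    totals = matrix.counts.sum(axis=1)
    shares: dict[str, dict[str, float]] = {}
    for gene, tot in totals.items():
        sp = annot.at[gene, "species"]
        for ec in _split_ecs(annot.at[gene, "ec"]):
            shares.setdefault(ec, {})[sp] = shares.get(ec, {}).get(sp, 0.0) + tot
    return pd.Series(
        {ec: max(by_sp, key=by_sp.get) for ec, by_sp in shares.items()},
        name="dominant_species",
    ).sort_index()


def masking_pipeline(
    matrix: CountMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    species_id: Optional[str] = None,
    alpha: float = 0.05,
) -> tuple[DiffResult, DiffResult, list[str]]:
    """Dual-level EC analysis (community vs within-species) + masking flags.

    EC bins are built twice from the raw gene matrix: over all genes
    (community level) and within a species (species level), each
    normalized with size factors computed at the matching level (all
    genes vs that species' gene subset). By default each EC's species-
    level test runs within its *dominant contributor* — the species
    providing the largest share of the bin's counts — which is the
    species whose regulation a community trend can mask; passing
    ``species_id`` forces one species for every EC instead. Each EC is
    tested with the exact Mann–Whitney U test between the two sample
    groups, and :func:`detect_masking` flags ECs whose two levels are
    significant in opposite directions.
    """
    matrix.require_raw()
    ec_comm = bin_by_ec(matrix)
    sf_comm = size_factors(matrix.counts)
    comm_norm = ec_comm / sf_comm

    annot = matrix.annotation.loc[matrix.counts.index]
    if species_id is not None:
        dominant = pd.Series(species_id, index=ec_comm.index)
    else:
        dominant = dominant_contributor(matrix)
    sp_rows = []
    for sp in dominant.unique():
        species_genes = annot.index[annot["species"] == sp]
        ec_sp = bin_by_ec(matrix, species=sp)
        sf_sp = size_factors(matrix.counts.loc[species_genes])
        ecs = dominant.index[dominant == sp].intersection(ec_sp.index)
        sp_rows.append(ec_sp.loc[ecs] / sf_sp)
    sp_norm = pd.concat(sp_rows).sort_index()

    common = comm_norm.index.intersection(sp_norm.index)
    comm_res = mwu_test(comm_norm.loc[common], group_a, group_b)
    sp_res = mwu_test(sp_norm.loc[common], group_a, group_b)
    flagged = detect_masking(comm_res, sp_res, alpha)
    return comm_res, sp_res, flagged


# ---------------------------------------------------------------------------
# clustering


def _cluster_leaf_sets(z: np.ndarray, labels: Sequence[str]) -> set[frozenset]:
    n = len(labels)
    members: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    out = set()
    for i, (a, b, _, _) in enumerate(z):
        s = members[int(a)] | members[int(b)]
        members[n + i] = s
        out.add(s)
    return out


def _corr_linkage(values: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(values.T)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum((dist + dist.T) / 2, 0.0)
    return hierarchy.linkage(squareform(dist, checks=False), method="average")


def cluster_with_bootstrap(
    values: pd.DataFrame, n_boot: int = 100, seed: int = 0
) -> tuple[np.ndarray, pd.DataFrame]:
    """Average-linkage clustering of samples with bootstrap support.

    Columns (samples) are clustered on correlation distance (1 − Pearson r
    over features). Support for each internal cluster is the fraction of
    feature-resampled bootstrap trees containing the same leaf set
    (ordinary bootstrap proportion).

    Returns the scipy linkage matrix and a table (cluster members,
    support).
    """
    if values.shape[1] < 3:
        raise ValueError("need at least 3 columns to cluster")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    labels = list(values.columns)
    mat = values.to_numpy(dtype=float)
    z = _corr_linkage(mat)
    ref_sets = _cluster_leaf_sets(z, labels)
    hits = {s: 0 for s in ref_sets}
    n_feat = mat.shape[0]
    for _ in range(n_boot):
        idx = rng.integers(0, n_feat, size=n_feat)
        bz = _corr_linkage(mat[idx])
        bsets = _cluster_leaf_sets(bz, labels)
        for s in ref_sets:
            if s in bsets:
                hits[s] += 1
    rows = [
        {"members": tuple(sorted(s)), "size": len(s), "support": hits[s] / n_boot}
        for s in sorted(ref_sets, key=len)
    ]
    return z, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# array-style present / DE calls


def _regularized_t(
    expr: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    n_prior: int = 10,
    window: int = 101,
) -> pd.DataFrame:
    """Moderated t-test with variance shrunk toward similarly expressed genes.

    The prior variance for each gene is the mean sample variance within a
    rank window of genes with similar overall mean expression; the
    posterior variance blends it with the gene's own pooled variance using
    ``n_prior`` pseudo-observations (extra degrees of freedom).
    """
    a = expr[list(group_a)].to_numpy(dtype=float)
    b = expr[list(group_b)].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    df = na + nb - 2
    v_pool = ((na - 1) * va + (nb - 1) * vb) / df
    order = np.argsort(expr.mean(axis=1).to_numpy())
    w = min(window, len(order))
    v_sorted = v_pool[order]
    kernel = np.ones(w) / w
    smoothed = np.convolve(np.pad(v_sorted, w // 2, mode="edge"), kernel, mode="valid")[
        : len(order)
    ]
    v_prior = np.empty_like(v_pool)
    v_prior[order] = smoothed
    v_post = (n_prior * v_prior + df * v_pool) / (n_prior + df)
    se = np.sqrt(v_post * (1 / na + 1 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (mb - ma) / se, 0.0)
    p = 2 * sps.t.sf(np.abs(t), df + n_prior)
    return pd.DataFrame(
        {"statistic": t, "p": p, "mean_a": ma, "mean_b": mb}, index=expr.index
    )


def present_and_de_calls(
    expr: pd.DataFrame,
    detect_flags: pd.DataFrame,
    groups: dict[str, Sequence[str]],
    p_cutoff: float = 0.01,
    fc_cutoff: float = 2.0,
    presence_rule: tuple[int, int] = (5, 7),
) -> tuple[pd.Series, DiffResult]:
    """Array-style presence filtering and differential-expression calls.

    A gene is *present* if detected in at least 5 of 7 animals (scaled as
    ceil(5/7 × n) for other group sizes) in at least one group. Among
    present genes, DE requires p < 0.01 from a regularized t-statistic and
    |fold-change| ≥ 2 (ratio of group means with a pseudocount of 1).
    """
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    (ga_name, ga), (gb_name, gb) = groups.items()
    num, den = presence_rule
    present = pd.Series(False, index=expr.index)
    for cols in (ga, gb):
        need = math.ceil(num / den * len(cols))
        present |= detect_flags[list(cols)].sum(axis=1) >= need
    if min(len(ga), len(gb)) < 2:
        empty = DiffResult(
            pd.DataFrame(
                columns=["statistic", "p", "q", "fold_change", "direction"]
            )
        )
        return present, empty
    sub = expr.loc[present]
    if sub.empty:
        return present, DiffResult(
            pd.DataFrame(columns=["statistic", "p", "q", "fold_change", "direction"])
        )
    res = _regularized_t(sub, ga, gb)
    fc = (res["mean_b"] + 1.0) / (res["mean_a"] + 1.0)
    from .proteomics import qvalues

    res["q"] = qvalues(res["p"].to_numpy())
    res["fold_change"] = fc
    abs_fc = np.maximum(fc, 1 / fc)
    de = (res["p"] < p_cutoff) & (abs_fc >= fc_cutoff)
    res["direction"] = np.where(
        ~de, "none", np.where(fc >= 1, "up", "down")
    )
    return present, DiffResult(
        res[["statistic", "p", "q", "fold_change", "direction"]]
    )


def detection_percentages(
    present_a: np.ndarray,
    present_b: np.ndarray,
    de: np.ndarray,
    cazy: Optional[np.ndarray] = None,
) -> dict[str, float]:
    """Summary percentages over per-gene boolean call vectors.

    Returns the percent of all genes expressed on both conditions, the
    percent differentially expressed, and (when a CAZy mask is given) the
    percent of CAZy-annotated genes that are differentially expressed.
    Percentages are rounded to one decimal, the reporting convention for
    these summaries.
    """
    present_a = np.asarray(present_a, dtype=bool)
    present_b = np.asarray(present_b, dtype=bool)
    de = np.asarray(de, dtype=bool)
    n = len(present_a)
    out = {
        "pct_expressed_both": round(100.0 * (present_a & present_b).sum() / n, 1),
        "pct_de": round(100.0 * de.sum() / n, 1),
    }
    if cazy is not None:
        cazy = np.asarray(cazy, dtype=bool)
        out["pct_cazy_de"] = round(100.0 * (de & cazy).sum() / cazy.sum(), 1)
    return out
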