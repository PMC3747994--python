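"""Community profiling by sequencing (COPRO-Seq).

Species proportions in a defined community are estimated from fixed-length
shotgun reads that can be *unambiguously* assigned to exactly one member
genome. Because community members share sequence (rRNA operons, mobile
elements, conserved genes), the raw unique-read count understates the
abundance of species with less distinctive genomes; dividing by the
*informative genome size* — the number of genome positions whose k-mer is
unique within the union of all community genomes — removes that bias.

The module also provides the presence threshold (default 0.003% of the
community), the percentage-of-maximum-achieved (PoMA) transform for
comparing diet responses across species with very different abundances,
Hellinger-distance principal-coordinates ordination, and a cross-timepoint
predictiveness R².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synthetic import CommunityGenomeSet, ReadSet, revcomp

__all__ = [
    "compute_informative_sizes",
    "assign_reads",
    "AssignmentResult",
    "quantify",
    "presence_filter",
    "poma",
    "hellinger_distances",
    "hellinger_pcoa",
    "predictiveness_r2",
    "DEFAULT_PRESENCE_THRESHOLD",
]

#: Presence/absence cutoff as a percent of the community, chosen from the
#: rate at which reads spuriously assign to distractor genomes.
DEFAULT_PRESENCE_THRESHOLD = 0.003


def _canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def _kmer_species_index(genomes: CommunityGenomeSet, k: int) -> dict[str, object]:
    """Map canonical k-mer -> species_id if single-species, else the tuple
    (count of occurrences does not matter beyond 'more than one species'),
    stored as None for multi-species k-mers."""
    index: dict[str, object] = {}
    for sid, sp in genomes.species.items():
        seq = sp.sequence
        for i in range(len(seq) - k + 1):
            km = _canonical(seq[i : i + k])
            prev = index.get(km)
            if prev is None and km in index:
                continue  # already ambiguous
            if prev is None:
                index[km] = sid
            elif prev != sid:
                index[km] = None
    return index


def compute_informative_sizes(genomes: CommunityGenomeSet, k: int) -> pd.Series:
    """Count genome positions whose canonical k-mer is unique in the union.

    A position is informative when its length-k substring (canonical over
    both strands) occurs exactly once across all community genomes; the
    per-species totals are the normalization denominators for unique-read
    counts.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    min_len = min(len(sp.sequence) for sp in genomes.species.values())
    if k > min_len:
        raise ValueError(f"k={k} exceeds shortest genome length {min_len}")
    counts: dict[str, int] = {}
    for sp in genomes.species.values():
        seq = sp.sequence
        for i in range(len(seq) - k + 1):
            km = _canonical(seq[i : i + k])
            counts[km] = counts.get(km, 0) + 1
    sizes = {}
    for sid, sp in genomes.species.items():
        seq = sp.sequence
        n = 0
        for i in range(len(seq) - k + 1):
            if counts[_canonical(seq[i : i + k])] == 1:
                n += 1
        sizes[sid] = n
    return pd.Series(sizes, name="informative_size")


@dataclass
class AssignmentResult:
    unique_counts: pd.Series  # species -> reads uniquely assigned
    ambiguous: int
    unassigned: int

    @property
    def total(self) -> int:
        return int(self.unique_counts.sum()) + self.ambiguous + self.unassigned


def assign_reads(reads: ReadSet, genomes: CommunityGenomeSet) -> AssignmentResult:
    """Tally reads by unambiguous exact match to community genomes.

    A read counts for a species iff its sequence matches (exact, either
    strand) a location in exactly one species' genome; matches in two or
    more species are ambiguous; no match is unassigned. The three tallies
    always sum to the input read count.
    """
    unique = {sid: 0 for sid in genomes.species_ids}
    ambiguous = 0
    unassigned = 0
    if len(reads) == 0:
        return AssignmentResult(pd.Series(unique, dtype=int), 0, 0)
    L = reads.read_length
    index = _kmer_species_index(genomes, L)
    for seq in reads.reads:
        hit = index.get(_canonical(seq), "missing")
        if hit == "missing":
            unassigned += 1
        elif hit is None:
            ambiguous += 1
        else:
            unique[hit] += 1
    return AssignmentResult(pd.Series(unique, dtype=int), ambiguous, unassigned)


def quantify(
    unique_counts: pd.DataFrame | pd.Series,
    informative_sizes: pd.Series,
) -> pd.DataFrame:
    """Convert unique-read counts into normalized proportional abundances.

    ``unique_counts`` is sample × species (a Series is treated as one
    sample). normalized = count / informative size; proportion = percent
    of the sample's normalized total. A species with reads but informative
    size 0 cannot be quantified and raises a ValueError naming it.
    """
    if isinstance(unique_counts, pd.Series):
        unique_counts = unique_counts.to_frame().T
    counts = unique_counts.astype(float)
    inf = informative_sizes.reindex(counts.columns)
    bad = [
        s
        for s in counts.columns
        if inf[s] == 0 and (counts[s] > 0).any()
    ]
    if bad:
        raise ValueError(
            f"species with nonzero reads but zero informative size: {bad}"
        )
    safe = inf.replace(0, np.nan)
    normalized = counts / safe
    normalized = normalized.fillna(0.0)
    totals = normalized.sum(axis=1)
    proportion = normalized.div(totals.replace(0, np.nan), axis=0) * 100.0
    proportion = proportion.fillna(0.0)
    long = pd.concat(
        {
            "unique_reads": counts.stack(),
            "normalized": normalized.stack(),
            "proportion": proportion.stack(),
        },
        axis=1,
    )
    long.index.names = ["sample", "species"]
    return long.reset_index()


def presence_filter(
    table: pd.DataFrame, threshold: float = DEFAULT_PRESENCE_THRESHOLD
) -> pd.DataFrame:
    """Flag species presence: present ⇔ proportion ≥ threshold (percent).

    The comparison is inclusive; below-threshold rows are retained and
    flagged absent, not removed or zeroed.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    out = table.copy()
    out["present"] = out["proportion"] >= threshold
    return out


def poma(table: pd.DataFrame) -> pd.DataFrame:
    """Percentage of maximum achieved per (animal, species) trajectory.

    Each proportion is expressed as a percent of that species' maximum
    proportion across all of the same animal's time-points, putting
    strongly and weakly represented species on a common 0–100 response
    scale. All-zero trajectories have no defined maximum and yield missing
    values with a warning.
    """
    required = {"animal", "day", "species", "proportion"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table lacks required columns: {sorted(missing)}")
    out = table.copy()
    gmax = out.groupby(["animal", "species"])["proportion"].transform("max")
    zero = gmax == 0
    if zero.any():
        pairs = out.loc[zero, ["animal", "species"]].drop_duplicates()
        warnings.warn(
            f"all-zero trajectories, PoMA undefined for: "
            f"{list(pairs.itertuples(index=False, name=None))}",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        out["poma"] = np.where(zero, np.nan, 100.0 * out["proportion"] / gmax)
    return out


def hellinger_distances(props: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Hellinger distances between samples.

    ``props`` is sample × species; rows are rescaled to sum to 1, and
    d(p, q) = sqrt(Σ (sqrt(p_i) − sqrt(q_i))²).
    """
    mat = props.to_numpy(dtype=float)
    rows = mat.sum(axis=1, keepdims=True)
    if (rows <= 0).any():
        raise ValueError("every sample must have positive total abundance")
    root = np.sqrt(mat / rows)
    diff = root[:, None, :] - root[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    return pd.DataFrame(d, index=props.index, columns=props.index)


def hellinger_pcoa(
    props: pd.DataFrame, n_axes: Optional[int] = None
) -> tuple[pd.DataFrame, pd.Series, np.ndarray]:
    """Principal-coordinates analysis of Hellinger distances.

    Classical metric scaling: the squared-distance matrix is double
    centered, eigendecomposed, and sample coordinates are eigenvectors
    scaled by sqrt(eigenvalue) for positive eigenvalues. Negative
    eigenvalues are returned but excluded from the percent-variance
    denominators.

    Returns (coordinates, percent variance per axis, all eigenvalues).
    """
    if props.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    d = hellinger_distances(props).to_numpy()
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > 1e-10
    n_pos = int(pos.sum())
    if n_axes is None:
        n_axes = n_pos
    elif n_axes > n_pos:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; reducing axes from {n_axes}",
            RuntimeWarning,
            stacklevel=2,
        )
        n_axes = n_pos
    coords = eigvec[:, :n_axes] * np.sqrt(eigval[:n_axes])
    pct = 100.0 * eigval[:n_axes] / eigval[pos].sum()
    axes = [f"PC{i + 1}" for i in range(n_axes)]
    return (
        pd.DataFrame(coords, index=props.index, columns=axes),
        pd.Series(pct, index=axes, name="pct_variance"),
        eigval,
    )


def predictiveness_r2(
    props_day_a: Sequence[float], props_day_b: Sequence[float]
) -> float:
    """Squared Pearson correlation of two per-species proportion vectors.

    Measures how well community composition at one time-point predicts
    composition at another (e.g. the ends of two same-diet phases).
    """
    a = np.asarray(props_day_a, dtype=float)
    b = np.asarray(props_day_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("vectors must have equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 species")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance: R^2 undefined")
    r, _ = sps.pearsonr(a, b)
    return float(r**2)
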