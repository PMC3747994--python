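"""Theoretical peptidomes and peptide uniqueness accounting.

In a defined community the complete protein complement is known, so the
set of peptides an in-silico tryptic digest can produce — the *theoretical
peptidome* — can be enumerated exactly. A peptide found in exactly one
protein of the composite search database (community members plus host,
distractor species and contaminants) is *unique* and attributes a
peptide-spectrum match unambiguously; peptides shared between homologous
proteins are nonunique. Per-species uniqueness fractions quantify how
well each member's proteome can be profiled by shotgun proteomics.

Digestion follows the classical trypsin rule (cleave C-terminal to K or R
except before P), masses are monoisotopic (residues + water, unmodified,
via pyteomics), and the default index filters match common instrument
practice: 600–4890 Da, at most one missed cleavage.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd
from pyteomics import mass as _ptmass

__all__ = [
    "Peptide",
    "PeptidomeIndex",
    "digest",
    "peptide_mass",
    "build_theoretical_peptidome",
    "classify_uniqueness",
    "uniqueness_summaries",
]

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
_NONSTANDARD = re.compile(r"[^ACDEFGHIKLMNPQRSTVWY]")


@dataclass
class Peptide:
    sequence: str
    mass: float  # monoisotopic Da
    missed_cleavages: int
    # (protein_id, source, start) with 1-based start position
    occurrences: list[tuple[str, str, int]] = field(default_factory=list)

    @property
    def n_occurrences(self) -> int:
        return len(self.occurrences)

    @property
    def proteins(self) -> set[str]:
        return {p for p, _, _ in self.occurrences}


@dataclass
class PeptidomeIndex:
    peptides: dict[str, Peptide]
    sources: list[str]  # database manifest
    mass_min: float
    mass_max: float
    max_missed: int

    def __len__(self) -> int:
        return len(self.peptides)


def _check_sequence(protein: str) -> None:
    if not protein:
        raise ValueError("empty protein sequence")
    m = _NONSTANDARD.search(protein)
    if m:
        raise ValueError(
            f"non-standard residue {m.group()!r} at position {m.start() + 1}"
        )


def peptide_mass(sequence: str) -> float:
    """Monoisotopic peptide mass in Da (residue masses + water, unmodified)."""
    _check_sequence(sequence)
    return float(_ptmass.fast_mass(sequence))


def cleavage_sites(protein: str, suppress_proline: bool = True) -> list[int]:
    """Positions after which trypsin cleaves (0-based index of K/R residue).

    Classical rule: C-terminal to K or R, suppressed when the next residue
    is P. The protein C-terminus is not a cleavage site.
    """
    sites = []
    for i, aa in enumerate(protein[:-1]):
        if aa in "KR" and not (suppress_proline and protein[i + 1] == "P"):
            sites.append(i)
    return sites


def digest(
    protein: str,
    max_missed: int = 0,
    suppress_proline: bool = True,
) -> list[tuple[str, int, int]]:
    """In-silico tryptic digest with up to ``max_missed`` missed cleavages.

    Returns (sequence, start position 1-based, missed cleavage count) for
    every fragment spanning 0..max_missed internal cleavage sites. The
    zero-missed fragments partition the protein.
    """
    _check_sequence(protein)
    sites = cleavage_sites(protein, suppress_proline)
    # fragment boundaries: starts of fully tryptic fragments
    bounds = [0] + [s + 1 for s in sites] + [len(protein)]
    out = []
    n_frag = len(bounds) - 1
    for i in range(n_frag):
        for m in range(max_missed + 1):
            j = i + m + 1
            if j > n_frag:
                break
            seq = protein[bounds[i] : bounds[j]]
            out.append((seq, bounds[i] + 1, m))
    return out


def build_theoretical_peptidome(
    proteomes: dict[str, dict[str, str]],
    mass_min: float = 600.0,
    mass_max: float = 4890.0,
    max_missed: int = 1,
    suppress_proline: bool = True,
) -> PeptidomeIndex:
    """Digest every protein and index peptides passing the filters.

    ``proteomes`` maps source (species or auxiliary source name) →
    {protein_id: sequence}. Fragments outside [mass_min, mass_max]
    (inclusive) or with more than ``max_missed`` missed cleavages are
    dropped; identical sequences across proteins are merged into one
    :class:`Peptide` with pooled occurrences. Duplicate protein ids
    across sources are rejected.
    """
    if not proteomes:
        raise ValueError("at least one proteome is required")
    if not (0 < mass_min < mass_max):
        raise ValueError("need 0 < mass_min < mass_max")
    seen_ids: set[str] = set()
    peptides: dict[str, Peptide] = {}
    for source, prots in proteomes.items():
        for pid, seq in prots.items():
            if pid in seen_ids:
                raise ValueError(f"duplicate protein_id {pid!r}")
            seen_ids.add(pid)
            for frag, start, missed in digest(seq, max_missed, suppress_proline):
                pep = peptides.get(frag)
                if pep is None:
                    m = peptide_mass(frag)
                    if not (mass_min <= m <= mass_max):
                        continue
                    pep = Peptide(frag, m, missed)
                    peptides[frag] = pep
                else:
                    pep.missed_cleavages = min(pep.missed_cleavages, missed)
                pep.occurrences.append((pid, source, start))
    return PeptidomeIndex(
        peptides=peptides,
        sources=list(proteomes),
        mass_min=mass_min,
        mass_max=mass_max,
        max_missed=max_missed,
    )


def classify_uniqueness(
    index: PeptidomeIndex, collapse_within_protein: bool = False
) -> pd.Series:
    """Unique flag per peptide sequence.

    Default (per-occurrence) reading: a peptide is unique iff it occurs at
    exactly one locus of one protein in the composite database; a peptide
    found at two loci of the *same* protein is nonunique. With
    ``collapse_within_protein=True``, multiple loci within one protein
    collapse and uniqueness means "found in exactly one protein".
    """
    flags = {}
    for seq, pep in index.peptides.items():
        if collapse_within_protein:
            flags[seq] = len(pep.proteins) == 1
        else:
            flags[seq] = pep.n_occurrences == 1
    return pd.Series(flags, name="unique")


def uniqueness_summaries(
    index: PeptidomeIndex,
    species_map: dict[str, str],
    category_map: Optional[dict[str, str]] = None,
    collapse_within_protein: bool = False,
) -> tuple[pd.DataFrame, Optional[pd.DataFrame]]:
    """Per-source and per-category uniqueness summaries.

    ``species_map`` maps protein_id → species/source; every protein with
    an occurrence must be mapped. Per source: number of peptides, percent
    unique, and the source's percent contribution to the unique
    metaproteome (contributions sum to 100). Per category (optional
    ``category_map``: protein_id → functional category): percent unique.

    A peptide occurring in several proteins of one species counts once for
    that species; a nonunique peptide shared across sources counts for
    each source it occurs in.
    """
    unique = classify_uniqueness(index, collapse_within_protein)
    per_source: dict[str, list[int]] = {}
    per_cat: dict[str, list[int]] = {}
    total_unique = 0
    unique_by_source: dict[str, int] = {}
    for seq, pep in index.peptides.items():
        srcs = set()
        cats = set()
        for pid, _, _ in pep.occurrences:
            if pid not in species_map:
                raise ValueError(f"protein {pid!r} not in species_map")
            srcs.add(species_map[pid])
            if category_map is not None and pid in category_map:
                cats.add(category_map[pid])
        is_u = bool(unique[seq])
        for s in srcs:
            tot_u = per_source.setdefault(s, [0, 0])
            tot_u[0] += 1
            tot_u[1] += is_u
        for c in cats:
            tot_u = per_cat.setdefault(c, [0, 0])
            tot_u[0] += 1
            tot_u[1] += is_u
        if is_u:
            total_unique += 1
            (src,) = srcs
            unique_by_source[src] = unique_by_source.get(src, 0) + 1
    rows = []
    for s, (n, nu) in sorted(per_source.items()):
        rows.append(
            {
                "source": s,
                "n_peptides": n,
                "fraction_unique": 100.0 * nu / n if n else math.nan,
                "contribution_to_unique_metaproteome": (
                    100.0 * unique_by_source.get(s, 0) / total_unique
                    if total_unique
                    else math.nan
                ),
            }
        )
    source_tab = pd.DataFrame(rows).set_index("source")
    cat_tab = None
    if category_map is not None:
        cat_tab = pd.DataFrame(
            [
                {
                    "category": c,
                    "n_peptides": n,
                    "fraction_unique": 100.0 * nu / n if n else math.nan,
                }
                for c, (n, nu) in sorted(per_cat.items())
            ]
        ).set_index("category")
    return source_tab, cat_tab


def index_to_table(index: PeptidomeIndex) -> pd.DataFrame:
    """Flatten a peptidome index to a table (one row per peptide)."""
    unique = classify_uniqueness(index)
    rows = []
    for seq, pep in index.peptides.items():
        rows.append(
            {
                "sequence": seq,
                "mass": pep.mass,
                "missed_cleavages": pep.missed_cleavages,
                "n_occurrences": pep.n_occurrences,
                "unique": bool(unique[seq]),
                "sources": ";".join(sorted({s for _, s, _ in pep.occurrences})),
            }
        )
    return pd.DataFrame(rows).sort_values("sequence").reset_index(drop=True)
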