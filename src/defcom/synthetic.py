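"""Synthetic defined-community data generators.

Every downstream analysis in this package (read-based community profiling,
EC-binned metatranscriptomics, theoretical peptidomes, spectral-count
proteomics, Tn-seq fitness, growth phenotyping) can be exercised end to end
on data produced here, with known ground truth.

The generators emulate a 12-member gnotobiotic community fed alternating
diets: multi-species genomes with controllable inter-species homology
(the source of ambiguous reads and shared peptides), multinomial shotgun
read sampling, negative-binomial count matrices with per-gene diet effects
and per-species load shifts (the mechanism behind community-level
"masking"), spectral-count tables split into technical duplicate runs,
transposon-insertion libraries with per-gene fitness, and logistic OD600
growth curves.

All randomness flows from a single integer seed through
``numpy.random.default_rng``; identical designs with identical seeds
reproduce every output exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .transcriptomics import CountMatrix

DNA = np.array(list("ACGT"))
AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: KEGG-style functional categories used for gene annotation.
KEGG_CATEGORIES = (
    "Carbohydrate metabolism",
    "Amino acid metabolism",
    "Translation",
    "Energy metabolism",
    "Nucleotide metabolism",
    "Glycan biosynthesis and metabolism",
)


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class HomologyBlock:
    """A sequence block copied from one species to another.

    ``shared_fraction`` of the donor genome is copied into the acceptor
    genome with point substitutions applied at ``100 - percent_identity``
    percent of positions. Blocks are packed left-to-right on both genomes.
    """

    species_pair: tuple[str, str]
    shared_fraction: float
    percent_identity: float

    def validate(self) -> None:
        if not (0.0 <= self.shared_fraction <= 1.0):
            raise ValueError(f"shared_fraction must be in [0,1], got {self.shared_fraction}")
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError(f"percent_identity must be in [0,100], got {self.percent_identity}")


@dataclass
class SyntheticDesign:
    """Full description of a synthetic defined-community experiment.

    Defaults mirror the study design the package targets: a 12-member
    community, two diets fed in three oscillating phases (days 0–13,
    14–27, 28–41), seven animals per treatment group, and a halving of a
    responsive species' transcriptome share on the second diet (the load
    shift that produces community-level masking).
    """

    n_species: int = 12
    genome_length_per_species: int = 50_000
    genes_per_species: int = 100
    homology_blocks: list[HomologyBlock] = field(default_factory=list)
    diet_labels: tuple[str, str] = ("LF/HPP", "HF/HS")
    phase_schedule: list[tuple[int, str, tuple[int, int]]] = field(
        default_factory=lambda: [
            (1, "LF/HPP", (0, 13)),
            (2, "HF/HS", (14, 27)),
            (3, "LF/HPP", (28, 41)),
        ]
    )
    animals_per_group: int = 7
    per_gene_log2_diet_effect: float = 2.0
    species_load_multiplier_per_diet: float = 0.5
    nb_dispersion: float = 0.05
    sequencing_depth: int = 100_000
    seed: int = 0
    # annotation structure
    ec_fraction: float = 0.4
    cazy_fraction: float = 0.1
    puls_per_species: int = 3
    responsive_fraction: float = 0.1
    responsive_genes: Optional[list[str]] = None
    load_shift_species: Optional[list[str]] = None

    def validate(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.genome_length_per_species < 100:
            raise ValueError("genome_length_per_species must be >= 100")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        for blk in self.homology_blocks:
            blk.validate()
        days_seen: list[tuple[int, int]] = []
        last_end = -1
        for _, diet, (d0, d1) in self.phase_schedule:
            if diet not in self.diet_labels:
                raise ValueError(f"phase diet {diet!r} not in diet_labels")
            if d0 > d1:
                raise ValueError(f"phase day range ({d0}, {d1}) reversed")
            if d0 <= last_end:
                raise ValueError("phase day ranges must be disjoint and ordered")
            last_end = d1
            days_seen.append((d0, d1))


@dataclass
class GeneRecord:
    gene_id: str
    species_id: str
    start: int  # 0-based, inclusive
    end: int  # 0-based, exclusive
    strand: str
    ec: Optional[str] = None
    cazy: Optional[str] = None
    sus_role: str = "none"  # susC | susD | none
    pul: Optional[str] = None
    kegg_category: Optional[str] = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SpeciesGenome:
    species_id: str
    sequence: str
    genes: list[GeneRecord]


@dataclass
class CommunityGenomeSet:
    """Genomes + annotated gene records for every community member.

    ``aux_proteomes`` carries the extra protein sources of a composite
    search database: host proteins, distractor species not expected in any
    sample, and common contaminants.
    """

    species: dict[str, SpeciesGenome]
    aux_proteomes: dict[str, dict[str, str]] = field(default_factory=dict)

    @property
    def species_ids(self) -> list[str]:
        return list(self.species)

    def genome_lengths(self) -> dict[str, int]:
        return {sid: len(sp.sequence) for sid, sp in self.species.items()}

    def gene_table(self) -> pd.DataFrame:
        rows = []
        for sp in self.species.values():
            for g in sp.genes:
                rows.append(
                    {
                        "gene_id": g.gene_id,
                        "species": g.species_id,
                        "start": g.start,
                        "end": g.end,
                        "strand": g.strand,
                        "ec": g.ec,
                        "cazy": g.cazy,
                        "sus_role": g.sus_role,
                        "pul": g.pul,
                        "kegg_category": g.kegg_category,
                    }
                )
        return pd.DataFrame(rows)


def _random_dna(rng: np.random.Generator, length: int) -> np.ndarray:
    return DNA[rng.integers(0, 4, size=length)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, sub_rate: float) -> np.ndarray:
    """Point-substitute sub_rate of positions, always to a different base."""
    seq = seq.copy()
    if sub_rate <= 0:
        return seq
    hit = rng.random(len(seq)) < sub_rate
    idx = np.flatnonzero(hit)
    if idx.size:
        # shift 1..3 letters around the 4-letter alphabet: never the same base
        cur = np.searchsorted(DNA, seq[idx])
        shift = rng.integers(1, 4, size=idx.size)
        seq[idx] = DNA[(cur + shift) % 4]
    return seq


_STOP_TO_RESIDUE = str.maketrans("*", "S")


def _translate(dna: str) -> str:
    """Translate a CDS; internal stops are recoded to serine.

    The generator's proteins are stand-ins, not biological ORFs, so stops
    inside a frame are mapped to a residue rather than truncating — this
    keeps protein homology congruent with the underlying DNA homology.
    """
    from Bio.Seq import Seq

    usable = len(dna) - len(dna) % 3
    return str(Seq(dna[:usable]).translate()).translate(_STOP_TO_RESIDUE)


def generate_genomes(design: SyntheticDesign) -> CommunityGenomeSet:
    """Generate community genomes with annotations per the design.

    Homology blocks are copied between designated species pairs at the
    stated identity; blocks are packed from the genome start, and a species
    whose blocks would overlap (total block length exceeding its genome)
    is rejected. Gene annotations (EC, CAZy, susC/susD pairs with PUL ids,
    KEGG category) are assigned at the design's proportions.

    Deterministic for a fixed seed.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    L = design.genome_length_per_species
    ids = [f"sp{i + 1:02d}" for i in range(design.n_species)]
    arrays = {sid: _random_dna(rng, L) for sid in ids}

    # homology blocks, packed left-to-right per species
    cursor = {sid: 0 for sid in ids}
    for blk in design.homology_blocks:
        a, b = blk.species_pair
        if a not in arrays or b not in arrays:
            raise ValueError(f"homology block references unknown species {blk.species_pair}")
        blen = int(round(blk.shared_fraction * L))
        if blen == 0:
            continue
        if cursor[a] + blen > L or cursor[b] + blen > L:
            raise ValueError(
                f"overlapping homology blocks: species pair {blk.species_pair} "
                f"exceeds genome length"
            )
        donor = arrays[a][cursor[a] : cursor[a] + blen]
        sub_rate = (100.0 - blk.percent_identity) / 100.0
        arrays[b][cursor[b] : cursor[b] + blen] = _mutate(rng, donor, sub_rate)
        cursor[a] += blen
        cursor[b] += blen

    species: dict[str, SpeciesGenome] = {}
    for sid in ids:
        seq = "".join(arrays[sid])
        genes = _lay_out_genes(rng, design, sid, L)
        species[sid] = SpeciesGenome(sid, seq, genes)

    aux = _generate_aux_proteomes(rng)
    return CommunityGenomeSet(species=species, aux_proteomes=aux)


def _lay_out_genes(
    rng: np.random.Generator, design: SyntheticDesign, sid: str, L: int
) -> list[GeneRecord]:
    n = design.genes_per_species
    spacing = L // n
    gene_len = max(30, int(spacing * 0.8) // 3 * 3)  # multiple of 3 for translation
    genes: list[GeneRecord] = []
    ec_pool = [f"{a}.{b}.{c}.{d}" for a in (1, 2, 3) for b in (1, 2) for c in (1, 4) for d in (1, 8)]
    cazy_pool = ["GH10", "GH5", "GH8", "CE1", "CE6", "PL1", "GT2"]
    for i in range(n):
        start = i * spacing
        end = min(start + gene_len, L)
        g = GeneRecord(
            gene_id=f"{sid}_g{i + 1:04d}",
            species_id=sid,
            start=start,
            end=end,
            strand="+" if rng.random() < 0.5 else "-",
        )
        if rng.random() < design.ec_fraction:
            g.ec = ec_pool[rng.integers(0, len(ec_pool))]
        if rng.random() < design.cazy_fraction:
            g.cazy = cazy_pool[rng.integers(0, len(cazy_pool))]
        g.kegg_category = KEGG_CATEGORIES[rng.integers(0, len(KEGG_CATEGORIES))]
        genes.append(g)
    # susC/susD pairs marking PULs: consecutive gene pairs, susC first
    if design.puls_per_species > 0 and n >= 2 * design.puls_per_species:
        starts = rng.choice(n // 2 - 1, size=design.puls_per_species, replace=False)
        for k, half in enumerate(sorted(starts)):
            i = int(half) * 2
            pul_id = f"{sid}_PUL{k + 1}"
            genes[i].sus_role = "susC"
            genes[i].pul = pul_id
            genes[i + 1].sus_role = "susD"
            genes[i + 1].pul = pul_id
    return genes


def _generate_aux_proteomes(rng: np.random.Generator) -> dict[str, dict[str, str]]:
    """Host, three distractor species and contaminant proteins."""

    def prots(prefix: str, n: int, mean_len: int) -> dict[str, str]:
        out = {}
        for i in range(n):
            ln = max(30, int(rng.normal(mean_len, mean_len / 5)))
            out[f"{prefix}_{i + 1:03d}"] = "".join(AA20[rng.integers(0, 20, size=ln)])
        return out

    aux = {"host": prots("host", 40, 350)}
    for d in ("distractor1", "distractor2", "distractor3"):
        aux[d] = prots(d, 30, 300)
    aux["contaminants"] = prots("contam", 10, 400)
    return aux


def community_proteomes(genomes: CommunityGenomeSet) -> dict[str, dict[str, str]]:
    """Translate each species' gene set into its theoretical proteome.

    Strand-aware translation of each annotated CDS; homologous DNA yields
    homologous proteins, so shared genome blocks propagate into shared
    peptides.
    """
    out: dict[str, dict[str, str]] = {}
    for sid, sp in genomes.species.items():
        prots = {}
        for g in sp.genes:
            cds = sp.sequence[g.start : g.end]
            if g.strand == "-":
                cds = revcomp(cds)
            prots[g.gene_id] = _translate(cds)
        out[sid] = prots
    return out


# ---------------------------------------------------------------------------
# shotgun reads


@dataclass
class ReadSet:
    """Fixed-length shotgun reads with true species-of-origin labels."""

    reads: list[str]
    read_ids: list[str]
    true_species: list[str]
    read_length: int

    def __len__(self) -> int:
        return len(self.reads)


def simulate_shotgun_reads(
    genomes: CommunityGenomeSet,
    proportions: dict[str, float],
    n_reads: int,
    read_length: int = 25,
    error_rate: float = 0.0,
    seed: int = 0,
) -> ReadSet:
    """Sample fixed-length reads with multinomial species origins.

    Read origins are multinomial in expectation proportional to
    ``proportion × genome length`` (uniform start positions, random strand).
    Each read carries its true species label for downstream validation.
    """
    rng = np.random.default_rng(seed)
    sids = genomes.species_ids
    props = np.array([proportions.get(s, 0.0) for s in sids], dtype=float)
    if (props < 0).any():
        raise ValueError("proportions must be nonnegative")
    if not math.isclose(props.sum(), 1.0, rel_tol=0, abs_tol=1e-6):
        raise ValueError(f"proportions must sum to 1, got {props.sum()}")
    lengths = np.array([len(genomes.species[s].sequence) for s in sids])
    if read_length > lengths.min():
        raise ValueError("read_length exceeds shortest genome")
    weights = props * lengths
    weights = weights / weights.sum()
    origins = rng.choice(len(sids), size=n_reads, p=weights)
    reads, ids, labels = [], [], []
    for i, oi in enumerate(origins):
        sid = sids[oi]
        seq = genomes.species[sid].sequence
        start = rng.integers(0, len(seq) - read_length + 1)
        frag = seq[start : start + read_length]
        if rng.random() < 0.5:
            frag = revcomp(frag)
        if error_rate > 0:
            frag = "".join(_mutate(rng, np.array(list(frag)), error_rate))
        reads.append(frag)
        ids.append(f"read{i + 1:07d}")
        labels.append(sid)
    return ReadSet(reads=reads, read_ids=ids, true_species=labels, read_length=read_length)


# ---------------------------------------------------------------------------
# count matrices


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB with var = mu + dispersion * mu^2; Poisson when dispersion = 0."""
    mu = np.asarray(mu, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate_count_matrix(
    design: SyntheticDesign,
    genomes: CommunityGenomeSet,
    assay: str = "rnaseq",
) -> CountMatrix:
    """Simulate a gene × sample count matrix with diet effects and load shifts.

    Per-gene counts are negative binomial with

        mean = depth_scale × species_load(diet) × gene_baseline × 2^(diet effect)

    and a shared dispersion. Responsive genes carry the design's log2 diet
    effect on the second diet; species in ``load_shift_species`` have all
    gene means multiplied by ``species_load_multiplier_per_diet`` on the
    second diet — the two ingredients of the masking scenario. The
    ``spectral`` assay additionally splits each sample's counts into two
    technical runs by binomial thinning (p = 0.5), mirroring duplicate MS
    runs.
    """
    if assay not in ("rnaseq", "spectral"):
        raise ValueError(f"unknown assay {assay!r}")
    design.validate()
    rng = np.random.default_rng(design.seed + 1)
    gene_tab = genomes.gene_table()
    gene_ids = gene_tab["gene_id"].to_numpy()
    gene_species = gene_tab["species"].to_numpy()
    n_genes = len(gene_ids)

    baseline = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    baseline /= baseline.sum()

    if design.responsive_genes is not None:
        responsive = np.isin(gene_ids, design.responsive_genes)
    elif design.per_gene_log2_diet_effect != 0 and design.responsive_fraction > 0:
        responsive = rng.random(n_genes) < design.responsive_fraction
    else:
        responsive = np.zeros(n_genes, dtype=bool)

    shift_species = set(design.load_shift_species or [])
    diet_a, diet_b = design.diet_labels[0], design.diet_labels[1]

    samples, meta_rows, cols = [], [], []
    for diet in (diet_a, diet_b):
        load = np.ones(n_genes)
        if diet == diet_b and shift_species:
            load = np.where(
                np.isin(gene_species, list(shift_species)),
                design.species_load_multiplier_per_diet,
                1.0,
            )
        effect = np.where(
            responsive & (diet == diet_b), design.per_gene_log2_diet_effect, 0.0
        )
        mu = design.sequencing_depth * load * baseline * np.exp2(effect)
        for a in range(design.animals_per_group):
            counts = _nb_draw(rng, mu, design.nb_dispersion)
            sample_id = f"{'A' if diet == diet_a else 'B'}{a + 1}"
            samples.append(counts)
            cols.append(sample_id)
            meta_rows.append({"sample": sample_id, "diet": diet, "animal": sample_id})

    counts = pd.DataFrame(np.column_stack(samples), index=gene_ids, columns=cols)
    meta = pd.DataFrame(meta_rows).set_index("sample")

    if assay == "spectral":
        run_cols, run_meta = {}, []
        for c in counts.columns:
            r1 = rng.binomial(counts[c].to_numpy(), 0.5)
            r2 = counts[c].to_numpy() - r1
            run_cols[f"{c}.run1"] = r1
            run_cols[f"{c}.run2"] = r2
            for r in (1, 2):
                run_meta.append(
                    {
                        "sample": f"{c}.run{r}",
                        "diet": meta.loc[c, "diet"],
                        "animal": c,
                        "run": r,
                    }
                )
        counts = pd.DataFrame(run_cols, index=gene_ids)
        meta = pd.DataFrame(run_meta).set_index("sample")

    annot = gene_tab.set_index("gene_id")[["species", "ec", "cazy", "kegg_category"]]
    return CountMatrix(counts=counts, annotation=annot, sample_meta=meta, assay=assay)


def masking_scenario(
    seed: int = 0,
    animals_per_group: int = 4,
    target_ec: str = "3.2.1.8",
    load_multiplier: float = 0.2,
    log2_effect: float = 1.0,
) -> tuple[SyntheticDesign, CommunityGenomeSet, CountMatrix, str, str]:
    """Canonical community-level masking scenario.

    Three species; one (sp02) halves-and-more its transcriptome share on
    the second diet (load × ``load_multiplier``) while one of its genes —
    the only gene carrying ``target_ec`` — is up-regulated by
    ``log2_effect`` log2 units within the species. Community-normalized,
    the EC's trend is load × 2^effect (down for the defaults, 0.2 × 2 =
    0.4); species-normalized the load cancels and the trend is 2^effect
    (up). Four animals per diet give the canonical 4-vs-4 design.

    Returns (design, genomes, count matrix, shifted species id, target EC).
    """
    design = SyntheticDesign(
        n_species=3,
        genome_length_per_species=20_000,
        genes_per_species=100,
        animals_per_group=animals_per_group,
        per_gene_log2_diet_effect=log2_effect,
        species_load_multiplier_per_diet=load_multiplier,
        nb_dispersion=0.01,
        sequencing_depth=300_000,
        seed=seed,
    )
    genomes = generate_genomes(design)
    species_id = "sp02"
    target_gene = genomes.species[species_id].genes[10].gene_id
    # EC structure of the scenario: the target EC is the shifted species'
    # distinctive enzyme and the only EC its genes carry (>99% of the bin
    # from one species, as for a xylanase specialist); other ECs are
    # shared among the stable species.
    rng = np.random.default_rng(design.seed + 2)
    ec_pool = [f"1.1.1.{i + 1}" for i in range(12)]
    for sp in genomes.species.values():
        for g in sp.genes:
            g.ec = None
    stable = [s for s in genomes.species_ids if s != species_id]
    for ec in ec_pool:
        for sid in stable:
            genes = genomes.species[sid].genes
            for j in rng.choice(len(genes), size=2, replace=False):
                genes[j].ec = ec if genes[j].ec is None else genes[j].ec
    for g in genomes.species[species_id].genes:
        if g.gene_id == target_gene:
            g.ec = target_ec
    design.responsive_genes = [target_gene]
    design.load_shift_species = [species_id]
    counts = simulate_count_matrix(design, genomes, assay="rnaseq")
    return design, genomes, counts, species_id, target_ec


# ---------------------------------------------------------------------------
# transposon-insertion libraries


def simulate_inseq(
    genomes: CommunityGenomeSet,
    n_mutants: int,
    per_gene_fitness: dict[str, float],
    bottleneck: int,
    seed: int = 0,
    species_id: Optional[str] = None,
    input_depth: int = 1_000_000,
) -> pd.DataFrame:
    """Simulate input/output counts for a transposon-insertion library.

    Insertion positions are uniform over the target species' genome; output
    counts are multinomial over mutants with weights proportional to
    input representation × fitness of the disrupted gene (intergenic
    insertions have fitness 1).

    Returns a table with columns mutant_id, gene_id, position, gene_length,
    position_fraction, input_count, output_count.
    """
    if n_mutants <= 0:
        raise ValueError("n_mutants must be positive")
    bad = {g: f for g, f in per_gene_fitness.items() if f < 0}
    if bad:
        raise ValueError(f"fitness values must be >= 0: {bad}")
    rng = np.random.default_rng(seed)
    sid = species_id or genomes.species_ids[0]
    sp = genomes.species[sid]
    L = len(sp.sequence)
    positions = rng.integers(0, L, size=n_mutants)

    starts = np.array([g.start for g in sp.genes])
    ends = np.array([g.end for g in sp.genes])
    gids = [g.gene_id for g in sp.genes]

    gene_id, gene_len, pos_frac, fitness = [], [], [], []
    for pos in positions:
        j = np.searchsorted(starts, pos, side="right") - 1
        if j >= 0 and pos < ends[j]:
            gid = gids[j]
            gl = int(ends[j] - starts[j])
            gene_id.append(gid)
            gene_len.append(gl)
            pos_frac.append((pos - starts[j]) / gl)
            fitness.append(per_gene_fitness.get(gid, 1.0))
        else:
            gene_id.append(None)
            gene_len.append(np.nan)
            pos_frac.append(np.nan)
            fitness.append(1.0)

    input_w = rng.lognormal(0.0, 0.25, size=n_mutants)
    input_counts = rng.multinomial(input_depth, input_w / input_w.sum())
    out_w = input_counts.astype(float) * np.asarray(fitness)
    if out_w.sum() <= 0:
        raise ValueError("all output weights are zero")
    output_counts = rng.multinomial(bottleneck, out_w / out_w.sum())

    return pd.DataFrame(
        {
            "mutant_id": [f"m{i + 1:06d}" for i in range(n_mutants)],
            "gene_id": gene_id,
            "position": positions,
            "gene_length": gene_len,
            "position_fraction": pos_frac,
            "input_count": input_counts,
            "output_count": output_counts,
        }
    )


# ---------------------------------------------------------------------------
# growth curves


@dataclass
class GrowthParams:
    """Logistic growth parameters for one substrate."""

    substrate: str
    lag_h: float = 5.0
    max_rate: float = 0.1  # OD / h
    carrying_capacity: float = 1.0  # OD
    initial_od: float = 0.05
    noise_sd: float = 0.01
    n_replicates: int = 6
    duration_h: float = 72.0  # study: readings over 3 d
    dt_h: float = 0.5


def simulate_growth_curves(
    params: Sequence[GrowthParams], seed: int = 0, species: str = "spX"
) -> pd.DataFrame:
    """Logistic OD600 trajectories with additive Gaussian noise.

    Uses the Zwietering reparameterized logistic so lag, maximum rate and
    carrying capacity are direct inputs:

        od(t) = A0 + A / (1 + exp(4 μ (λ − t) / A + 2)),  A = K − A0

    Returns a long-format table (species, substrate, replicate, time_h,
    od600).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for p in params:
        if p.duration_h <= 0:
            raise ValueError("duration must be positive")
        if not (p.carrying_capacity > p.initial_od >= 0):
            raise ValueError("need carrying_capacity > initial_od >= 0")
        t = np.arange(0.0, p.duration_h + p.dt_h / 2, p.dt_h)
        A = p.carrying_capacity - p.initial_od
        if p.max_rate > 0:
            z = 4.0 * p.max_rate * (p.lag_h - t) / A + 2.0
            od = p.initial_od + A / (1.0 + np.exp(np.clip(z, -700, 700)))
        else:
            od = np.full_like(t, p.initial_od)
        for r in range(p.n_replicates):
            noisy = od + rng.normal(0.0, p.noise_sd, size=od.size) if p.noise_sd > 0 else od
            noisy = np.maximum(noisy, 0.0)
            for ti, oi in zip(t, noisy):
                rows.append(
                    {
                        "species": species,
                        "substrate": p.substrate,
                        "replicate": r + 1,
                        "time_h": ti,
                        "od600": oi,
                    }
                )
    return pd.DataFrame(rows)
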