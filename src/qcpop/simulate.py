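"""Synthetic multi-region cohort generator with planted QC artifacts.

Emulates the statistical structure a genotype-array QC pipeline must handle:

* 10 discrete subpopulations on a north-south cline (hierarchical
  Balding-Nichols allele frequencies);
* within-region families (trios, sibling pairs, half-sibling pairs,
  parent-offspring pairs, consanguineous pairs) by gamete-dropping with
  recombination along a genetic map;
* planted long-range-LD haplotype blocks (few founder haplotypes copied);
* plate-level genotype-calling artifacts (directional het->hom miscalls with
  correspondingly degraded probeset clustering metrics);
* sex chromosomes with XO / XO-mosaic / XXX / XXY karyotypes expressed in
  chrX genotypes, mean LRR, and B-allele-frequency bands;
* intentional duplicates at fixed plate positions (well H12 replaced by a
  duplicate of well D1 of the previous plate);
* box-level genotyping selection with case over-ascertainment.

Every planted artifact is recorded in :class:`TruthLabels` so downstream
detectors can be scored against ground truth.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data import MISSING, GeneticMap, GenotypeDataset
from . import io_plink

# approximate latitude/longitude of ten recruitment regions spanning a
# north-south cline (degrees)
DEFAULT_REGION_COORDS = {
    "harbin": (45.8, 126.5),
    "qingdao": (36.1, 120.4),
    "henan": (34.8, 113.6),
    "gansu": (36.0, 104.0),
    "suzhou": (31.3, 120.6),
    "zhejiang": (30.3, 120.2),
    "sichuan": (30.7, 104.1),
    "hunan": (27.7, 111.7),
    "liuzhou": (24.3, 109.4),
    "haikou": (20.0, 110.3),
}

PLATE_ROWS = "ABCDEFGH"
PLATE_COLS = 12
PLATE_SIZE = len(PLATE_ROWS) * PLATE_COLS

# karyotype expression parameters: mean chrX LRR shift and BAF band centres
KARYOTYPE_LRR = {"XX": 0.0, "XO": -0.6, "XO_mosaic": -0.3, "XXX": 0.4, "XXY": 0.0}
KARYOTYPE_BAF_BANDS = {
    "XX": (0.5,),
    "XO": (),
    "XO_mosaic": (0.35, 0.65),
    "XXX": (1 / 3, 2 / 3),
    "XXY": (0.5,),
}
# chrY/chrX probe intensity ratio cluster means (arbitrary units)
RATIO_MEANS = {"male": 2.0, "female": 0.4, "XXY": 1.2, "XO": 0.55}


@dataclass
class PedigreeSpec:
    """Counts of planted relationship structures per region."""

    trios: int = 0
    sib_pairs: int = 0
    half_sib_pairs: int = 0
    parent_offspring_pairs: int = 0
    duplicate_pairs: int = 0
    consanguineous_pairs: int = 0  # triple second cousins


@dataclass
class SimConfig:
    """Generative parameters of the synthetic cohort (the stated world).

    Defaults are desk-scale: 2 autosomes + chrX, 10 regions on a north-south
    cline, region differentiation fst=0.01 around a cline with fst_ns=0.02.
    """

    n_regions: int = 10
    samples_per_region: int = 60
    n_variants: int = 400          # per autosome
    n_autosomes: int = 2
    n_x_variants: int = 150
    chrom_size_bp: int = 100_000_000
    cm_per_mb: float = 1.0
    fst: float = 0.01              # region-level differentiation
    fst_ns: float = 0.02           # north-south cline differentiation
    region_coords: dict = field(default_factory=lambda: dict(DEFAULT_REGION_COORDS))
    pedigree_spec: PedigreeSpec = field(default_factory=PedigreeSpec)
    lrld_blocks: list = field(default_factory=list)  # (chrom, start, end, n_haps)
    plate_effects: list = field(default_factory=list)  # (plate, [variant idx], delta)
    plate_effect_model: str = "af_shift"  # or "miscall" (het->hom, prob delta)
    aneuploidy_counts: dict = field(default_factory=dict)  # karyotype -> count
    box_size: int = 24
    box_full_selection_fraction: float = 0.6  # fraction of boxes fully genotyped
    case_prevalence: dict = field(default_factory=lambda: {"D1": 0.04})
    case_ascertainment: dict = field(default_factory=lambda: {"D1": 1.0})
    genotype_error: float = 0.0
    missing_rate: float = 0.002
    plates_per_batch: int = 5
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.fst < 1):
            raise ValueError("fst must be in [0, 1)")
        if not (0 <= self.fst_ns < 1):
            raise ValueError("fst_ns must be in [0, 1)")
        if not (0 <= self.box_full_selection_fraction <= 1):
            raise ValueError("box_full_selection_fraction must be in [0, 1]")
        if self.plate_effect_model not in ("af_shift", "miscall"):
            raise ValueError("plate_effect_model must be 'af_shift' or 'miscall'")
        for name in ("n_regions", "samples_per_region", "n_variants",
                     "n_autosomes", "n_x_variants", "box_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        ped = self.pedigree_spec
        ped_members = (3 * ped.trios + 2 * ped.sib_pairs + 2 * ped.half_sib_pairs
                       + 2 * ped.parent_offspring_pairs + 2 * ped.consanguineous_pairs)
        if ped_members > self.samples_per_region:
            raise ValueError(
                "pedigree_spec requires more samples than samples_per_region "
                f"({ped_members} > {self.samples_per_region})"
            )
        if self.n_regions > len(self.region_coords):
            raise ValueError(
                f"n_regions={self.n_regions} exceeds region_coords entries "
                f"({len(self.region_coords)})"
            )


@dataclass
class TruthLabels:
    """Simulator ground truth for parameter-recovery tests."""

    relationships: list = field(default_factory=list)   # (id_i, id_j, relation)
    karyotypes: dict = field(default_factory=dict)      # sample id -> karyotype
    lrld_intervals: list = field(default_factory=list)  # (chrom, start, end)
    affected_probesets: list = field(default_factory=list)  # (plate, variant id)
    regions: dict = field(default_factory=dict)         # sample id -> region
    migrants: list = field(default_factory=list)        # sample ids
    boxes: dict = field(default_factory=dict)           # sample id -> box id
    box_fractions: dict = field(default_factory=dict)   # box id -> selection fraction
    cases: dict = field(default_factory=dict)           # disease -> [sample ids]
    population_prevalence: dict = field(default_factory=dict)  # disease -> float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthLabels":
        d = json.loads(text)
        d["relationships"] = [tuple(r) for r in d["relationships"]]
        d["lrld_intervals"] = [tuple(r) for r in d["lrld_intervals"]]
        d["affected_probesets"] = [tuple(r) for r in d["affected_probesets"]]
        return cls(**d)


@dataclass
class SampleMetrics:
    """Per-sample intensity and QC summaries (DQC, chrX F, chrY/chrX ratio,
    mean chrX LRR) plus chrX BAF values at heterozygous-called probes."""

    table: pd.DataFrame
    baf: dict = field(default_factory=dict)  # sample id -> np.ndarray of BAF values


@dataclass
class ClusterMetrics:
    """Per (probeset, batch) clustering scores (FLD, HetSO, HomRO, call rate)."""

    table: pd.DataFrame


# ---------------------------------------------------------------------------
# allele-frequency and haplotype machinery


def balding_nichols_freqs(p_anc: np.ndarray, fst: float, rng: np.random.Generator) -> np.ndarray:
    """Draw subpopulation frequencies Beta(p(1-F)/F, (1-p)(1-F)/F) around p_anc."""
    p = np.asarray(p_anc, dtype=float)
    if fst <= 0:
        return p.copy()
    a = p * (1 - fst) / fst
    b = (1 - p) * (1 - fst) / fst
    out = rng.beta(a, b)
    return np.clip(out, 1e-6, 1 - 1e-6)


def sample_haplotypes(freqs: np.ndarray, n_haplotypes: int, rng: np.random.Generator) -> np.ndarray:
    """(n_haplotypes, m) binary haplotypes with independent sites at ``freqs``."""
    return (rng.random((n_haplotypes, freqs.size)) < freqs).astype(np.uint8)


def _crossover_gamete(hap_pair: np.ndarray, cm_positions: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Recombined gamete from one phased diploid over a single chromosome.

    Crossover count ~ Poisson(length_cM / 100); breakpoints uniform on the
    genetic-distance scale; starting haplotype chosen at random.
    """
    length = cm_positions[-1] - cm_positions[0]
    n_x = rng.poisson(max(length, 0.0) / 100.0)
    current = rng.integers(2)
    if n_x == 0:
        return hap_pair[current].copy()
    breaks = np.sort(rng.uniform(cm_positions[0], cm_positions[-1], size=n_x))
    # haplotype index flips at each breakpoint
    n_breaks_before = np.searchsorted(breaks, cm_positions, side="right")
    which = (current + n_breaks_before) % 2
    return hap_pair[which, np.arange(hap_pair.shape[1])]


def drop_gametes(
    father: np.ndarray,
    mother: np.ndarray,
    chrom_index: np.ndarray,
    cm_positions: np.ndarray | None,
    rng: np.random.Generator,
    unlinked: bool = False,
) -> np.ndarray:
    """One offspring (2, m) phased genotype from two phased parents.

    Parameters
    ----------
    father, mother
        (2, m) phased haplotypes.
    chrom_index
        integer chromosome label per variant (sorted runs).
    cm_positions
        genetic position per variant; required unless ``unlinked``.
    unlinked
        treat every site as independently segregating (free recombination).
    """
    m = father.shape[1]
    child = np.empty((2, m), dtype=np.uint8)
    if unlinked:
        child[0] = father[rng.integers(2, size=m), np.arange(m)]
        child[1] = mother[rng.integers(2, size=m), np.arange(m)]
        return child
    if cm_positions is None:
        raise ValueError("cm_positions required for linked gamete dropping")
    for chrom in np.unique(chrom_index):
        sel = chrom_index == chrom
        child[0, sel] = _crossover_gamete(father[:, sel], cm_positions[sel], rng)
        child[1, sel] = _crossover_gamete(mother[:, sel], cm_positions[sel], rng)
    return child


def apply_genotype_errors(calls: np.ndarray, rate: float, freqs: np.ndarray,
                          rng: np.random.Generator) -> np.ndarray:
    """Resample a fraction ``rate`` of calls from Hardy-Weinberg at ``freqs``."""
    out = calls.copy()
    if rate <= 0:
        return out
    err = (rng.random(out.shape) < rate) & (out != MISSING)
    n_err = int(err.sum())
    if n_err:
        p = np.broadcast_to(freqs, out.shape)[err]
        u = rng.random((n_err, 2))
        out[err] = ((u[:, 0] < p).astype(np.int8) + (u[:, 1] < p).astype(np.int8))
    return out


# ---------------------------------------------------------------------------
# relationship pair simulation (acceptance workhorse)


def simulate_relationship_pairs(
    relationship: str,
    n_pairs: int,
    n_snps: int = 10_000,
    maf_range: tuple[float, float] = (0.05, 0.5),
    genotype_error: float = 0.0,
    seed: int = 0,
):
    """Simulate genotype pairs of a given relationship at independent SNPs.

    Returns ``(calls_a, calls_b, freqs)`` where calls are (n_pairs, n_snps)
    int8 dosage matrices.  Supported relationships: ``full_sib``,
    ``half_sib``, ``parent_offspring``, ``duplicate``, ``unrelated``,
    ``second_cousin``, ``triple_second_cousin``.
    """
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(*maf_range, size=n_snps)
    chrom = np.zeros(n_snps, dtype=int)
    a_list, b_list = [], []

    def founder():
        return sample_haplotypes(freqs, 2, rng)

    def child(fa, mo):
        return drop_gametes(fa, mo, chrom, None, rng, unlinked=True)

    for _ in range(n_pairs):
        if relationship == "full_sib":
            fa, mo = founder(), founder()
            a, b = child(fa, mo), child(fa, mo)
        elif relationship == "half_sib":
            shared, fa1, fa2 = founder(), founder(), founder()
            a, b = child(fa1, shared), child(fa2, shared)
        elif relationship == "parent_offspring":
            fa, mo = founder(), founder()
            a, b = fa, child(fa, mo)
        elif relationship == "duplicate":
            fa, mo = founder(), founder()
            a = child(fa, mo)
            b = a.copy()
        elif relationship == "unrelated":
            a, b = child(founder(), founder()), child(founder(), founder())
        elif relationship == "second_cousin":
            a, b = _cousin_pair(founder, child, degree=2, n_links=1)
        elif relationship == "triple_second_cousin":
            a, b = _cousin_pair(founder, child, degree=2, n_links=3)
        else:
            raise ValueError(f"unknown relationship {relationship!r}")
        a_list.append(a.sum(axis=0).astype(np.int8))
        b_list.append(b.sum(axis=0).astype(np.int8))

    calls_a = np.vstack([g[None, :] for g in a_list])
    calls_b = np.vstack([g[None, :] for g in b_list])
    if genotype_error > 0:
        calls_a = apply_genotype_errors(calls_a, genotype_error, freqs, rng)
        calls_b = apply_genotype_errors(calls_b, genotype_error, freqs, rng)
    return calls_a, calls_b, freqs


def _cousin_pair(founder, child, degree: int, n_links: int):
    """Pair of (multi-link) cousins of the given degree.

    degree 2 = second cousins: shared great-grandparental couples.  With
    ``n_links`` > 1, several of the two individuals' ancestral couples are
    shared (triple second cousins: 3 of 4 great-grandparent couples).
    """
    # generation depth: degree d cousins share ancestors d+1 generations up
    depth = degree + 1

    def lineage(shared_couples):
        """Descend ``depth`` generations; ``shared_couples`` is a list of
        (father_haps, mother_haps) couples available at the top generation."""
        # build this individual's 2**(depth-1) grandparent-level couples:
        # each top-generation slot draws a child from a shared couple when
        # available, else from a fresh founder couple.
        top_people = []
        for k in range(2 ** depth):
            couple_idx = k // 2
            if couple_idx < len(shared_couples):
                fa, mo = shared_couples[couple_idx]
                top_people.append(child(fa, mo))
            else:
                top_people.append(child(founder(), founder()))
        people = top_people
        while len(people) > 1:
            people = [child(people[2 * t], people[2 * t + 1])
                      for t in range(len(people) // 2)]
        return people[0]

    shared = [(founder(), founder()) for _ in range(n_links)]
    return lineage(shared), lineage(shared)


# ---------------------------------------------------------------------------
# full cohort simulation


def _default_genetic_map(config: SimConfig) -> GeneticMap:
    sizes = {str(c + 1): config.chrom_size_bp for c in range(config.n_autosomes)}
    sizes["X"] = config.chrom_size_bp
    return GeneticMap.uniform(sizes, cm_per_mb=config.cm_per_mb)


def _variant_table(config: SimConfig) -> pd.DataFrame:
    rows = []
    rng = np.random.default_rng(config.seed + 101)
    for c in range(config.n_autosomes):
        pos = np.sort(rng.choice(
            np.arange(1, config.chrom_size_bp, 50), config.n_variants, replace=False))
        for k, p in enumerate(pos):
            rows.append((f"as{c + 1}_{k}", str(c + 1), int(p)))
    posx = np.sort(rng.choice(
        np.arange(1, config.chrom_size_bp, 50), config.n_x_variants, replace=False))
    for k, p in enumerate(posx):
        rows.append((f"asX_{k}", "X", int(p)))
    tab = pd.DataFrame(rows, columns=["id", "chrom", "pos"])
    alleles = rng.choice(["A", "C", "G", "T"], size=(len(tab), 2))
    same = alleles[:, 0] == alleles[:, 1]
    alleles[same, 1] = np.where(alleles[same, 0] == "A", "G", "A")
    tab["allele1"] = alleles[:, 0]
    tab["allele2"] = alleles[:, 1]
    tab["probeset"] = "ps_" + tab["id"]
    return tab


def _well_name(index: int) -> str:
    return f"{PLATE_ROWS[index // PLATE_COLS]}{index % PLATE_COLS + 1:02d}"


def simulate_cohort(config: SimConfig, genetic_map: GeneticMap | None = None):
    """Generate a full synthetic cohort with planted artifacts.

    Returns ``(dataset, sample_metrics, cluster_metrics, truth)``.
    Deterministic: the same (config, seed) yields identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    gmap = genetic_map or _default_genetic_map(config)
    variants = _variant_table(config)
    m = len(variants)
    is_x = (variants["chrom"] == "X").to_numpy()
    chrom_codes = pd.factorize(variants["chrom"])[0]
    cm_pos = np.concatenate([
        gmap.interpolate(chrom, variants.loc[variants["chrom"] == chrom, "pos"])
        for chrom in variants["chrom"].unique()
    ])

    regions = list(config.region_coords)[: config.n_regions]
    lat = np.array([config.region_coords[r][0] for r in regions])
    lat_w = (lat - lat.min()) / max(lat.max() - lat.min(), 1e-9)

    # hierarchical Balding-Nichols: ancestral -> north/south poles -> regions
    p_anc = rng.uniform(0.05, 0.95, size=m)
    p_north = balding_nichols_freqs(p_anc, config.fst_ns, rng)
    p_south = balding_nichols_freqs(p_anc, config.fst_ns, rng)
    region_freqs = {}
    for r, w in zip(regions, lat_w):
        cline = w * p_north + (1 - w) * p_south
        region_freqs[r] = balding_nichols_freqs(cline, config.fst, rng)

    # planted LRLD blocks: restricted founder-haplotype diversity inside block
    truth = TruthLabels()
    block_haps = []
    for chrom, start, end, n_haps in config.lrld_blocks:
        sel = ((variants["chrom"] == str(chrom)) & (variants["pos"] >= start)
               & (variants["pos"] <= end)).to_numpy()
        if sel.sum() == 0:
            continue
        pool = sample_haplotypes(p_anc[sel], int(n_haps), rng)
        block_haps.append((sel, pool))
        truth.lrld_intervals.append((str(chrom), int(start), int(end)))

    def founder_haps(region: str, n_hap: int) -> np.ndarray:
        haps = sample_haplotypes(region_freqs[region], n_hap, rng)
        for sel, pool in block_haps:
            pick = rng.integers(pool.shape[0], size=n_hap)
            haps[:, sel] = pool[pick][:, :]
        return haps

    # --- build individuals region by region -------------------------------
    sample_rows = []        # manifest rows
    genotypes = []          # phased (2, m) haplotypes per sample
    sexes = []
    ped = config.pedigree_spec
    counter = 0

    age_of: dict[str, int] = {}

    def new_person(region, haps, sex, father="0", mother="0", age=None):
        nonlocal counter
        sid = f"S{counter:05d}"
        counter += 1
        latitude, longitude = config.region_coords[region]
        if age is None:
            age = int(rng.integers(30, 80))
        sample_rows.append(
            {"id": sid, "region": region, "lat": latitude, "lon": longitude,
             "sex": sex, "age": age, "father": father, "mother": mother}
        )
        age_of[sid] = age
        genotypes.append(haps)
        sexes.append(sex)
        truth.regions[sid] = region
        return sid

    def spawn_founder(region):
        sex = "M" if rng.random() < 0.5 else "F"
        return new_person(region, founder_haps(region, 2), sex)

    def spawn_child(region, fid, mid, fhaps, mhaps):
        sex = "M" if rng.random() < 0.5 else "F"
        haps = drop_gametes(fhaps, mhaps, chrom_codes, cm_pos, rng)
        # offspring are strictly younger than any genotyped parent
        parent_ages = [age_of[p] for p in (fid, mid) if p in age_of]
        age = max(18, (min(parent_ages) if parent_ages else 50)
                  - int(rng.integers(20, 31)))
        return new_person(region, haps, sex, father=fid, mother=mid, age=age)

    for region in regions:
        used = 0
        # trios
        for _ in range(ped.trios):
            f_h, m_h = founder_haps(region, 2), founder_haps(region, 2)
            fid = new_person(region, f_h, "M")
            mid = new_person(region, m_h, "F")
            cid = spawn_child(region, fid, mid, f_h, m_h)
            truth.relationships += [
                (fid, cid, "parent_offspring"), (mid, cid, "parent_offspring"),
                (fid, mid, "unrelated_couple"),
            ]
            used += 3
        # sibling pairs (parents not genotyped)
        for _ in range(ped.sib_pairs):
            f_h, m_h = founder_haps(region, 2), founder_haps(region, 2)
            a = new_person(region, drop_gametes(f_h, m_h, chrom_codes, cm_pos, rng),
                           "M" if rng.random() < 0.5 else "F")
            b = new_person(region, drop_gametes(f_h, m_h, chrom_codes, cm_pos, rng),
                           "M" if rng.random() < 0.5 else "F")
            truth.relationships.append((a, b, "full_sibling"))
            used += 2
        # half-sibling pairs
        for _ in range(ped.half_sib_pairs):
            shared = founder_haps(region, 2)
            a = new_person(region,
                           drop_gametes(founder_haps(region, 2), shared,
                                        chrom_codes, cm_pos, rng),
                           "M" if rng.random() < 0.5 else "F")
            b = new_person(region,
                           drop_gametes(founder_haps(region, 2), shared,
                                        chrom_codes, cm_pos, rng),
                           "M" if rng.random() < 0.5 else "F")
            truth.relationships.append((a, b, "half_sibling"))
            used += 2
        # parent-offspring pairs (other parent not genotyped)
        for _ in range(ped.parent_offspring_pairs):
            f_h, m_h = founder_haps(region, 2), founder_haps(region, 2)
            fid = new_person(region, f_h, "M")
            cid = spawn_child(region, fid, "0", f_h, m_h)
            truth.relationships.append((fid, cid, "parent_offspring"))
            used += 2
        # consanguineous pairs: gamete-dropped triple second cousins
        for _ in range(ped.consanguineous_pairs):
            a_h, b_h = _linked_triple_second_cousins(
                lambda: founder_haps(region, 2), chrom_codes, cm_pos, rng)
            a = new_person(region, a_h, "M" if rng.random() < 0.5 else "F")
            b = new_person(region, b_h, "M" if rng.random() < 0.5 else "F")
            truth.relationships.append((a, b, "triple_second_cousin"))
            used += 2
        for _ in range(config.samples_per_region - used):
            spawn_founder(region)

    samples = pd.DataFrame(sample_rows)
    n = len(samples)
    phased = np.stack(genotypes)           # (n, 2, m)
    calls = phased.sum(axis=1).astype(np.int8)

    # --- sex chromosomes & karyotypes -------------------------------------
    sex_arr = samples["sex"].to_numpy()
    karyotype = np.where(sex_arr == "M", "XY", "XX").astype(object)
    x_copies = np.where(sex_arr == "M", 1, 2)
    # males: haploid chrX coded 0/2 from haplotype 0
    male = sex_arr == "M"
    calls[np.ix_(male, is_x)] = (phased[male][:, 0, :][:, is_x] * 2).astype(np.int8)

    # plant aneuploidies
    an_counts = dict(config.aneuploidy_counts)
    fem_idx = list(np.flatnonzero(~male))
    male_idx = list(np.flatnonzero(male))
    rng.shuffle(fem_idx)
    rng.shuffle(male_idx)
    for karyo, count in an_counts.items():
        for _ in range(count):
            if karyo in ("XO", "XO_mosaic", "XXX"):
                if not fem_idx:
                    raise ValueError(f"not enough female samples to plant {karyo}")
                i = fem_idx.pop()
            elif karyo == "XXY":
                if not male_idx:
                    raise ValueError("not enough male samples to plant XXY")
                i = male_idx.pop()
            else:
                raise ValueError(f"unknown karyotype {karyo!r}")
            karyotype[i] = karyo
            sid = samples.at[i, "id"]
            truth.karyotypes[sid] = karyo
            if karyo == "XO":
                calls[i, is_x] = (phased[i, 0, is_x] * 2).astype(np.int8)
                x_copies[i] = 1
            elif karyo == "XXY":
                # two X haplotypes -> diploid-like chrX het pattern
                calls[i, is_x] = phased[i, :, is_x].sum(axis=1).astype(np.int8)
    for i in range(n):
        sid = samples.at[i, "id"]
        if sid not in truth.karyotypes:
            truth.karyotypes[sid] = "XY" if male[i] else "XX"

    # --- plate / box / batch layout ---------------------------------------
    order = rng.permutation(n)
    plate = np.empty(n, dtype=int)
    well = np.empty(n, dtype=object)
    dup_rows = []
    slot = 0
    d1_by_plate: dict[int, int] = {}
    for idx in order:
        p, w = divmod(slot, PLATE_SIZE)
        # intentional duplicate: H12 of plate p duplicates D1 of plate p-1
        if _well_name(w) == "H12" and (p - 1) in d1_by_plate:
            dup_rows.append((d1_by_plate[p - 1], p, w))
            slot += 1
            p, w = divmod(slot, PLATE_SIZE)
        plate[idx] = p
        well[idx] = _well_name(w)
        if _well_name(w) == "D01":
            d1_by_plate[p] = idx
        slot += 1
    samples["plate"] = plate
    samples["well"] = well
    samples["batch"] = samples["plate"] // config.plates_per_batch
    samples["array_version"] = 2

    # append intentional duplicate entries as extra samples
    extra_rows, extra_calls = [], []
    for src_idx, p, w in dup_rows:
        src = samples.iloc[src_idx]
        sid = f"{src['id']}_dup"
        row = dict(src)
        row.update({"id": sid, "plate": p, "well": _well_name(w),
                    "batch": p // config.plates_per_batch})
        extra_rows.append(row)
        g = calls[src_idx].copy()
        extra_calls.append(g)
        truth.relationships.append((src["id"], sid, "intentional_duplicate"))
        truth.regions[sid] = src["region"]
        truth.karyotypes[sid] = truth.karyotypes[src["id"]]
    if extra_rows:
        samples = pd.concat([samples, pd.DataFrame(extra_rows)], ignore_index=True)
        calls = np.vstack([calls, np.array(extra_calls, dtype=np.int8)])
        sex_arr = samples["sex"].to_numpy()
        male = sex_arr == "M"
        x_copies = np.concatenate([x_copies,
                                   [x_copies[s] for s, _, _ in dup_rows]])
        n = len(samples)

    # repeat-participant style duplicates at arbitrary positions
    if ped.duplicate_pairs > 0:
        pick = rng.choice(n, size=min(ped.duplicate_pairs, n), replace=False)
        rep_rows, rep_calls = [], []
        for src_idx in pick:
            src = samples.iloc[src_idx]
            sid = f"{src['id']}_rep"
            row = dict(src)
            row["id"] = sid
            rep_rows.append(row)
            rep_calls.append(calls[src_idx].copy())
            truth.relationships.append((src["id"], sid, "repeat_participant"))
            truth.regions[sid] = src["region"]
            truth.karyotypes[sid] = truth.karyotypes[src["id"]]
        samples = pd.concat([samples, pd.DataFrame(rep_rows)], ignore_index=True)
        calls = np.vstack([calls, np.array(rep_calls, dtype=np.int8)])
        sex_arr = samples["sex"].to_numpy()
        male = sex_arr == "M"
        x_copies = np.concatenate([x_copies, [x_copies[s] for s in pick]])
        n = len(samples)

    # --- boxes and genotyping selection -----------------------------------
    n_boxes = int(np.ceil(n / config.box_size))
    box_assign = rng.permutation(np.repeat(np.arange(n_boxes), config.box_size)[:n])
    samples["box"] = box_assign
    # disease status in the underlying population
    for disease, prev in config.case_prevalence.items():
        case = rng.random(n) < prev
        truth.cases[disease] = samples.loc[case, "id"].tolist()
        truth.population_prevalence[disease] = float(case.mean())
        samples[f"case_{disease}"] = case
    # exactly the configured fraction of boxes is fully genotyped
    n_full = int(round(config.box_full_selection_fraction * n_boxes))
    full_boxes = np.zeros(n_boxes, dtype=bool)
    full_boxes[rng.permutation(n_boxes)[:n_full]] = True
    selected = full_boxes[box_assign].copy()
    # over-ascertainment: cases from unselected boxes are individually added
    for disease in config.case_prevalence:
        selected |= samples[f"case_{disease}"].to_numpy()
    for b in range(n_boxes):
        members = box_assign == b
        truth.box_fractions[str(b)] = float(selected[members].mean())
    for sid, b in zip(samples["id"], box_assign):
        truth.boxes[sid] = int(b)
    samples["genotyped"] = selected
    samples["ascertainment"] = "random"
    for disease in config.case_prevalence:
        is_case = samples[f"case_{disease}"].to_numpy()
        picked = is_case & ~full_boxes[box_assign]
        samples.loc[picked, "ascertainment"] = f"case_{disease}"

    # --- planted plate effects --------------------------------------------
    # "af_shift": genotypes on the plate resampled from HWE at p + delta
    # (clipped) — a frequency-scale calling artifact.  "miscall": directional
    # het->minor-hom miscalls with probability delta — a cluster-boundary
    # failure that leaves the dosage mean nearly unchanged.
    for plate_id, variant_idx, delta in config.plate_effects:
        on_plate = (samples["plate"] == plate_id).to_numpy()
        for v in variant_idx:
            p_v = float(np.mean([region_freqs[r][v] for r in regions]))
            if config.plate_effect_model == "af_shift":
                p_new = float(np.clip(p_v + delta if p_v < 0.5 else p_v - delta,
                                      0.01, 0.99))
                calls[on_plate, v] = rng.binomial(2, p_new, on_plate.sum()
                                                  ).astype(np.int8)
            else:
                hets = on_plate & (calls[:, v] == 1)
                flip = hets & (rng.random(n) < delta)
                hom = 0 if p_v >= 0.5 else 2  # collapse into the minor homozygote
                calls[flip, v] = hom
            truth.affected_probesets.append((int(plate_id), variants.at[v, "id"]))

    # --- genotype errors and missingness ----------------------------------
    pool_freq = np.mean([region_freqs[r] for r in regions], axis=0)
    if config.genotype_error > 0:
        calls = apply_genotype_errors(calls, config.genotype_error, pool_freq, rng)
    if config.missing_rate > 0:
        miss = rng.random(calls.shape) < config.missing_rate
        calls[miss] = MISSING

    # --- per-sample intensity metrics --------------------------------------
    karyo_arr = np.asarray([truth.karyotypes[s] for s in samples["id"]], dtype=object)
    metrics = _sample_metrics(samples, calls, is_x, x_copies, pool_freq,
                              karyo_arr, rng)
    cluster = _cluster_metrics(variants, samples, calls, truth, rng)

    variants = variants.copy()
    variants["cm"] = cm_pos
    dataset = GenotypeDataset(calls=calls, variants=variants, samples=samples)
    return dataset, metrics, cluster, truth


def _linked_triple_second_cousins(founder, chrom_codes, cm_pos, rng):
    """Gamete-dropped triple-second-cousin pair (3 shared ancestor couples)."""
    def child(fa, mo):
        return drop_gametes(fa, mo, chrom_codes, cm_pos, rng)

    shared = [(founder(), founder()) for _ in range(3)]

    def lineage():
        tops = []
        for k in range(8):
            cpl = k // 2
            if cpl < 3:
                tops.append(child(*shared[cpl]))
            else:
                tops.append(child(founder(), founder()))
        gps = [child(tops[2 * t], tops[2 * t + 1]) for t in range(4)]
        parents = [child(gps[0], gps[1]), child(gps[2], gps[3])]
        return child(parents[0], parents[1])

    return lineage(), lineage()


def _sample_metrics(samples, calls, is_x, x_copies, pool_freq, karyotype, rng):
    n = len(samples)
    x_calls = calls[:, is_x]
    px = pool_freq[is_x]
    exp_het = float(np.mean(2 * px * (1 - px)))
    obs_het = np.array([
        np.mean(row[row != MISSING] == 1) if (row != MISSING).any() else np.nan
        for row in x_calls
    ])
    chrx_f = 1.0 - obs_het / exp_het

    lrr = np.array([KARYOTYPE_LRR.get(k, 0.0) for k in karyotype])
    lrr = lrr + rng.normal(0, 0.05, n)

    ratio = np.empty(n)
    for i, k in enumerate(karyotype):
        if k == "XY":
            ratio[i] = rng.normal(RATIO_MEANS["male"], 0.12)
        elif k == "XXY":
            ratio[i] = rng.normal(RATIO_MEANS["XXY"], 0.12)
        elif k == "XO":
            ratio[i] = rng.normal(RATIO_MEANS["XO"], 0.06)
        else:
            ratio[i] = rng.normal(RATIO_MEANS["female"], 0.06)

    dqc = np.clip(rng.normal(0.99, 0.004, n), 0, 1)
    qc_cr = np.clip(rng.normal(0.995, 0.002, n), 0, 1)
    full_cr = 1.0 - (calls == MISSING).mean(axis=1)

    auto = ~is_x
    het_auto = np.array([
        np.mean(row[row != MISSING] == 1) if (row != MISSING).any() else np.nan
        for row in calls[:, auto]
    ])

    baf = {}
    n_baf = 80
    for i, k in enumerate(karyotype):
        bands = () if k == "XY" else KARYOTYPE_BAF_BANDS.get(k, (0.5,))
        if not bands:
            baf[samples.at[i, "id"]] = np.array([])
            continue
        pick = rng.integers(len(bands), size=n_baf)
        vals = np.array(bands)[pick] + rng.normal(0, 0.03, n_baf)
        baf[samples.at[i, "id"]] = np.clip(vals, 0, 1)

    table = pd.DataFrame({
        "id": samples["id"],
        "dqc": dqc,
        "qc_callrate": qc_cr,
        "call_rate": full_cr,
        "het_autosomal": het_auto,
        "roh_kb": 0.0,
        "chrx_f": chrx_f,
        "y_x_ratio": ratio,
        "chrx_lrr_mean": lrr,
    })
    return SampleMetrics(table=table, baf=baf)


def _cluster_metrics(variants, samples, calls, truth, rng):
    batches = sorted(samples["batch"].unique())
    affected = {}
    plate_batch = samples.drop_duplicates("plate").set_index("plate")["batch"].to_dict()
    for plate_id, vid in truth.affected_probesets:
        b = plate_batch.get(plate_id)
        affected.setdefault((vid, b), True)
    rows = []
    for b in batches:
        in_batch = (samples["batch"] == b).to_numpy()
        sub = calls[in_batch]
        cr = 1.0 - (sub == MISSING).mean(axis=0)
        fld = rng.normal(14.0, 2.5, len(variants))
        hetso = rng.normal(0.9, 0.08, len(variants))
        homro = rng.normal(4.5, 0.4, len(variants))
        for v in range(len(variants)):
            vid = variants.at[v, "id"]
            if (vid, b) in affected:
                fld[v] = rng.uniform(3.0, 7.5)
                hetso[v] = rng.uniform(0.3, 0.6)
                homro[v] = rng.uniform(1.0, 3.0)
            rows.append((variants.at[v, "probeset"], vid, b, fld[v], hetso[v],
                         homro[v], cr[v]))
    table = pd.DataFrame(
        rows, columns=["probeset", "variant", "batch", "fld", "hetso", "homro",
                       "call_rate"])
    return ClusterMetrics(table=table)


# ---------------------------------------------------------------------------
# fixtures


def write_fixture(dataset: GenotypeDataset, truth: TruthLabels, directory: str,
                  metrics: SampleMetrics | None = None,
                  cluster: ClusterMetrics | None = None,
                  genetic_map: GeneticMap | None = None) -> None:
    """Write PLINK1 binary + TSV manifests + truth JSON to ``directory``."""
    os.makedirs(directory, exist_ok=True)
    io_plink.write_fileset(dataset, directory, prefix="cohort")
    with open(os.path.join(directory, "truth.json"), "w") as fh:
        fh.write(truth.to_json())
    if metrics is not None:
        metrics.table.to_csv(os.path.join(directory, "intensity.tsv"),
                             sep="\t", index=False)
        baf_rows = [(sid, v) for sid, vals in metrics.baf.items() for v in vals]
        pd.DataFrame(baf_rows, columns=["id", "baf"]).to_csv(
            os.path.join(directory, "baf.tsv"), sep="\t", index=False)
    if cluster is not None:
        cluster.table.to_csv(os.path.join(directory, "cluster_metrics.tsv"),
                             sep="\t", index=False)
    if genetic_map is not None:
        genetic_map.to_frame().to_csv(os.path.join(directory, "map.tsv"),
                                      sep="\t", index=False)


def read_fixture(directory: str):
    """Round-trip reader for :func:`write_fixture` output."""
    dataset = io_plink.read_bed(os.path.join(directory, "cohort"))
    manifest = pd.read_csv(os.path.join(directory, "samples.tsv"), sep="\t",
                           dtype={"id": str})
    dataset = GenotypeDataset(calls=dataset.calls, variants=dataset.variants,
                              samples=manifest)
    with open(os.path.join(directory, "truth.json")) as fh:
        truth = TruthLabels.from_json(fh.read())
    return dataset, truth
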