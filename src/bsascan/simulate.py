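"""Synthetic BC2F2 study generator.

Everything downstream of wet-lab work is testable against this module: it
simulates a backcross-derived cotton-like mapping population (donor parent
crossed to a recurrent parent, two backcrosses, one selfing), correlated
seedling traits with an optional planted salt-tolerance QTL, pooled-bulk
sequencing depths at parent-polymorphic markers, and raw reads with planted
quality defects plus a truth table saying what read cleaning should do.

Genetic model
-------------
Each individual is a pair of haplotypes per chromosome, coded 1 for the donor
allele and 0 for the recurrent allele at every marker.  Meiosis uses Haldane's
no-interference model: the crossover count per chromosome is Poisson with mean
equal to the map length in Morgans (``length_bp / 1e6 * cM_per_Mb / 100``) and
breakpoints fall uniformly along the chromosome.  Under the fixed crossing
scheme P1xP2 -> F1, F1xP1 -> BC1F1, BC1F1xP1 -> BC2F1, BC2F1 selfed -> BC2F2,
the expected donor-allele frequency at any marker is (1/2)^3 = 0.125.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import open_text_write
from .readqc import find_adapter_start
from .variants import ad_col, gt_col, rd_col

TRAITS = ("SL", "RL", "SFW", "RFW", "SDW", "RDW", "CHL")
#: weights and lengths cannot be negative; chlorophyll (SPAD) is left untruncated
NONNEGATIVE_TRAITS = frozenset(TRAITS) - {"CHL"}

# Defaults emulate the stressed (150 mmol NaCl) BC2F2 seedling phenotypes:
# per-trait means/SDs and the full pairwise Pearson correlation structure of
# the seven traits (shoot/root lengths in cm, fresh/dry weights in g, SPAD).
DEFAULT_BASE_MEANS = {
    "SL": 21.31, "RL": 26.94, "SFW": 7.35, "RFW": 3.42,
    "SDW": 0.88, "RDW": 0.25, "CHL": 36.75,
}
DEFAULT_TRAIT_SD = {
    "SL": 3.46, "RL": 4.03, "SFW": 3.67, "RFW": 1.71,
    "SDW": 0.46, "RDW": 0.12, "CHL": 6.28,
}
DEFAULT_TRAIT_CORR = np.array([
    [1.000, 0.090, 0.641, 0.598, 0.681, 0.544, 0.052],
    [0.090, 1.000, 0.272, 0.259, 0.244, 0.370, 0.183],
    [0.641, 0.272, 1.000, 0.723, 0.929, 0.793, 0.165],
    [0.598, 0.259, 0.723, 1.000, 0.765, 0.867, 0.161],
    [0.681, 0.244, 0.929, 0.765, 1.000, 0.812, 0.122],
    [0.544, 0.370, 0.793, 0.867, 0.812, 1.000, 0.230],
    [0.052, 0.183, 0.165, 0.161, 0.122, 0.230, 1.000],
])

#: fixed crossing scheme producing a BC2F2 population
CROSS_SCHEME = ("P1xP2->F1", "F1xP1->BC1F1", "BC1F1xP1->BC2F1", "BC2F1self->BC2F2")

SAMPLE_RECURRENT = "recurrent"
SAMPLE_DONOR = "donor"
SAMPLE_RES_BULK = "bulk_res"
SAMPLE_SUS_BULK = "bulk_sus"

_CONSEQUENCE_BY_IMPACT = {
    "HIGH": "stop_gained",
    "MODERATE": "missense_variant",
    "LOW": "synonymous_variant",
    "MODIFIER": "intergenic_region",
}


def default_trait_cov() -> np.ndarray:
    """Default 7x7 trait covariance: D R D from the default SDs/correlations."""
    d = np.diag([DEFAULT_TRAIT_SD[t] for t in TRAITS])
    return d @ DEFAULT_TRAIT_CORR @ d


# ---------------------------------------------------------------------------
# Genome / QTL / population containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeModel:
    """A toy reference: chromosome sizes plus biallelic marker positions/alleles."""

    chromosomes: tuple[tuple[str, int], ...]
    markers: Mapping[str, np.ndarray]  # 1-based positions, strictly increasing
    ref: Mapping[str, np.ndarray]
    alt: Mapping[str, np.ndarray]

    def __post_init__(self):
        lengths = dict(self.chromosomes)
        for chrom, pos in self.markers.items():
            if chrom not in lengths:
                raise ValueError(f"markers declared on unknown chromosome {chrom!r}")
            pos = np.asarray(pos)
            if len(pos) and (np.any(np.diff(pos) <= 0) or pos[0] < 1 or pos[-1] > lengths[chrom]):
                raise ValueError(f"marker positions on {chrom} must be strictly increasing within [1, length]")
            if np.any(self.ref[chrom] == self.alt[chrom]):
                raise ValueError(f"ref == alt at some marker on {chrom}")

    @property
    def chrom_names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def n_markers(self, chrom: str) -> int:
        return len(self.markers[chrom])

    def marker_index(self, chrom: str, pos: int) -> int:
        """Index of the marker at (or nearest to) ``pos`` on ``chrom``."""
        positions = self.markers[chrom]
        i = int(np.argmin(np.abs(positions - pos)))
        return i

    @classmethod
    def default(cls, n_chromosomes: int = 3, chrom_length: int = 2_000_000,
                markers_per_chrom: int = 400, seed: int = 0) -> "GenomeModel":
        """3 chromosomes x 2 Mb with 400 SNP markers each, by default."""
        rng = np.random.default_rng(seed)
        bases = np.array(list("ACGT"))
        chroms, markers, ref, alt = [], {}, {}, {}
        for i in range(n_chromosomes):
            name = f"chr{i + 1}"
            chroms.append((name, chrom_length))
            pos = np.sort(rng.choice(chrom_length, size=markers_per_chrom, replace=False)) + 1
            r = rng.integers(0, 4, markers_per_chrom)
            a = (r + rng.integers(1, 4, markers_per_chrom)) % 4
            markers[name] = pos.astype(np.int64)
            ref[name] = bases[r]
            alt[name] = bases[a]
        return cls(tuple(chroms), markers, ref, alt)


@dataclass(frozen=True)
class QTLSpec:
    """A planted locus: additive shift per donor-allele copy on each affected trait."""

    chrom: str
    pos: int
    effects: Mapping[str, float]

    def __post_init__(self):
        if not any(v != 0 for v in self.effects.values()):
            raise ValueError("QTL must have at least one nonzero effect")
        unknown = set(self.effects) - set(TRAITS)
        if unknown:
            raise ValueError(f"unknown traits in QTL effects: {sorted(unknown)}")

    @classmethod
    def default(cls, genome: GenomeModel) -> "QTLSpec":
        """Large-effect QTL mid-chromosome-2: +1 phenotypic SD per donor copy
        on the three bulk-selection traits (SFW, SDW, RFW)."""
        chrom = genome.chrom_names[min(1, len(genome.chrom_names) - 1)]
        pos = int(genome.markers[chrom][genome.marker_index(chrom, genome.lengths[chrom] // 2)])
        return cls(chrom, pos, {
            "SFW": DEFAULT_TRAIT_SD["SFW"],
            "SDW": DEFAULT_TRAIT_SD["SDW"],
            "RFW": DEFAULT_TRAIT_SD["RFW"],
        })


@dataclass
class Population:
    """Simulated individuals as per-marker donor-allele dosages (0/1/2)."""

    genome: GenomeModel
    generation: str
    ids: list[str]
    dosages: dict[str, np.ndarray]  # chrom -> (n_individuals, n_markers) int8

    def __post_init__(self):
        for chrom, d in self.dosages.items():
            if d.min(initial=0) < 0 or d.max(initial=0) > 2:
                raise ValueError(f"dosages on {chrom} outside {{0,1,2}}")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.ids)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"individual {e.args[0]!r} not in population") from None

    def donor_frequency(self, chrom: str, ids: Iterable[str] | None = None) -> np.ndarray:
        """Mean donor-allele frequency (dosage/2) per marker, optionally over a subset."""
        d = self.dosages[chrom]
        if ids is not None:
            d = d[self.index_of(ids)]
        return d.mean(axis=0) / 2.0

    def dosage_at(self, chrom: str, pos: int) -> np.ndarray:
        return self.dosages[chrom][:, self.genome.marker_index(chrom, pos)]


@dataclass(frozen=True)
class DepthModel:
    """Sequencing-depth model for pooled bulks and parents.

    ``mean_depth`` is the Poisson mean reads/site; ``error_rate`` is the
    symmetric per-read allele-flip probability; ``overdispersion`` > 0 mixes
    the Poisson mean with a Gamma of that squared coefficient of variation.
    """

    mean_depth: float = 40.0
    error_rate: float = 0.001
    overdispersion: float = 0.0

    def __post_init__(self):
        if self.mean_depth <= 0:
            raise ValueError("mean depth must be > 0")
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error rate must be in [0, 0.5)")

    def draw_depths(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.overdispersion > 0:
            shape = 1.0 / self.overdispersion
            lam = rng.gamma(shape, self.mean_depth / shape, size=n)
        else:
            lam = self.mean_depth
        return rng.poisson(lam, size=n)


# ---------------------------------------------------------------------------
# Crossing
# ---------------------------------------------------------------------------

def _gamete(h1: np.ndarray, h2: np.ndarray, positions: np.ndarray,
            length_bp: int, rate_cm_per_mb: float, rng: np.random.Generator) -> np.ndarray:
    """One meiotic product under Haldane's model (Poisson crossovers, no interference)."""
    morgans = length_bp / 1e6 * rate_cm_per_mb / 100.0
    k = rng.poisson(morgans)
    start = int(rng.integers(2))
    if k == 0:
        return (h1 if start == 0 else h2).copy()
    breaks = np.sort(rng.uniform(0, length_bp, size=k))
    phase = (start + np.searchsorted(breaks, positions)) % 2
    return np.where(phase == 0, h1, h2).astype(np.int8)


def simulate_cross(genome: GenomeModel, n_offspring: int, seed: int,
                   rate_cm_per_mb: float = 1.0,
                   scheme: Sequence[str] = CROSS_SCHEME,
                   return_pedigree: bool = False):
    """Simulate ``n_offspring`` BC2F2 individuals through the fixed scheme.

    Each offspring descends from its own independently simulated BC1F1 and
    BC2F1 ancestors.  With ``return_pedigree=True`` the per-offspring BC2F1
    parental dosages are returned alongside, which makes Mendelian
    expectations (e.g. the 1:2:1 selfing ratio at a heterozygous marker)
    directly checkable.

    Returns a :class:`Population` (generation ``BC2F2``), or a tuple
    ``(population, bc2f1_dosages)`` with the same chrom -> (n, m) layout.
    """
    if tuple(scheme) != CROSS_SCHEME:
        raise ValueError(f"only the fixed BC2F2 scheme {CROSS_SCHEME} is supported")
    if n_offspring < 1:
        raise ValueError("n_offspring must be >= 1")
    rng = np.random.default_rng(seed)
    dosages: dict[str, np.ndarray] = {}
    pedigree: dict[str, np.ndarray] = {}
    for chrom, length in genome.chromosomes:
        pos = genome.markers[chrom]
        m = len(pos)
        ones = np.ones(m, dtype=np.int8)
        zeros = np.zeros(m, dtype=np.int8)
        out = np.empty((n_offspring, m), dtype=np.int8)
        ped = np.empty((n_offspring, m), dtype=np.int8)
        for i in range(n_offspring):
            # F1 = donor haplotype + recurrent haplotype; backcross twice to P1
            bc1 = _gamete(ones, zeros, pos, length, rate_cm_per_mb, rng)      # other haplotype is all-0
            bc2 = _gamete(bc1, zeros, pos, length, rate_cm_per_mb, rng)
            g1 = _gamete(bc2, zeros, pos, length, rate_cm_per_mb, rng)
            g2 = _gamete(bc2, zeros, pos, length, rate_cm_per_mb, rng)
            out[i] = g1 + g2
            ped[i] = bc2  # BC2F1 dosage == its donor haplotype (other is all-0)
        dosages[chrom] = out
        pedigree[chrom] = ped
    ids = [f"L{i + 1:04d}" for i in range(n_offspring)]
    pop = Population(genome, "BC2F2", ids, dosages)
    if return_pedigree:
        return pop, pedigree
    return pop


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

def simulate_traits(pop: Population, qtl: QTLSpec | None = None,
                    base_means: Mapping[str, float] | None = None,
                    cov: np.ndarray | None = None, seed: int = 0) -> pd.DataFrame:
    """Per-individual trait values: base mean + QTL dosage x effect + MVN noise.

    Negative draws for weight/length traits are truncated at zero.  Returns a
    DataFrame indexed by individual ID with the seven trait columns.
    """
    means = np.array([(base_means or DEFAULT_BASE_MEANS)[t] for t in TRAITS])
    cov = default_trait_cov() if cov is None else np.asarray(cov, dtype=float)
    if cov.shape != (7, 7) or not np.allclose(cov, cov.T):
        raise ValueError("covariance must be a symmetric 7x7 matrix")
    if np.min(np.linalg.eigvalsh(cov)) < -1e-8 * max(1.0, np.max(np.abs(cov))):
        raise ValueError("covariance must be positive semi-definite")
    rng = np.random.default_rng(seed)
    values = np.tile(means, (pop.n, 1)) + rng.multivariate_normal(
        np.zeros(7), cov, size=pop.n, method="svd")
    if qtl is not None:
        if qtl.chrom not in pop.genome.lengths:
            raise ValueError(f"QTL chromosome {qtl.chrom!r} not in genome")
        positions = pop.genome.markers[qtl.chrom]
        if int(qtl.pos) not in positions:
            raise ValueError(f"QTL position {qtl.pos} is not a marker on {qtl.chrom}")
        dosage = pop.dosage_at(qtl.chrom, qtl.pos).astype(float)
        for j, t in enumerate(TRAITS):
            values[:, j] += dosage * qtl.effects.get(t, 0.0)
    df = pd.DataFrame(values, index=pd.Index(pop.ids, name="line"), columns=list(TRAITS))
    for t in NONNEGATIVE_TRAITS:
        df[t] = df[t].clip(lower=0.0)
    return df


def replicate_table(traits: pd.DataFrame, n_replicates: int = 3,
                    rep_sd_frac: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """Expand per-line trait values into a replicated long table.

    Replicate measurements are the line value plus independent noise with SD
    equal to ``rep_sd_frac`` of each trait's across-line SD, then truncated at
    zero for the non-negative traits.  Layout: line, replicate, 7 trait columns.
    """
    rng = np.random.default_rng(seed)
    sds = traits.std(ddof=1).to_numpy() * rep_sd_frac
    rows = []
    for rep in range(1, n_replicates + 1):
        noise = rng.normal(0.0, 1.0, size=traits.shape) * sds
        vals = traits.to_numpy() + noise
        block = pd.DataFrame(vals, index=traits.index, columns=traits.columns)
        for t in NONNEGATIVE_TRAITS:
            block[t] = block[t].clip(lower=0.0)
        block.insert(0, "replicate", f"R{rep}")
        rows.append(block.reset_index())
    return pd.concat(rows, ignore_index=True).sort_values(["line", "replicate"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Bulk sequencing depths -> site table
# ---------------------------------------------------------------------------

def simulate_bulk_depths(pop: Population, res_ids: Iterable[str], sus_ids: Iterable[str],
                         dm: DepthModel, seed: int = 0, qtl: QTLSpec | None = None,
                         impacts: Mapping[str, int] | None = None,
                         indel_lengths: Mapping[int, int] | None = None
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pooled-sequencing read depths for two bulks plus the fixed parents.

    At each marker the bulk's true donor-allele frequency is mean(dosage)/2;
    total depth is Poisson (optionally overdispersed) and the donor-allele
    depth is Binomial(depth, f(1-e) + (1-f)e) under the symmetric error model.
    Parents are emitted as fixed homozygotes (recurrent 0/0, donor 1/1) with
    the same depth/error model.

    ``impacts`` plants exact counts of HIGH/MODERATE/LOW annotations at random
    markers (all remaining markers are MODIFIER); ``indel_lengths`` converts
    planted counts of markers into indels of the given signed lengths.

    Returns ``(site_table, truth_table)`` where the truth table records the
    per-marker true bulk frequencies and the QTL flag.
    """
    res_ids, sus_ids = list(res_ids), list(sus_ids)
    if not res_ids or not sus_ids:
        raise ValueError("both bulks must be nonempty")
    if set(res_ids) & set(sus_ids):
        raise ValueError("bulks must be disjoint")
    rng = np.random.default_rng(seed)
    genome = pop.genome
    e = dm.error_rate

    chroms = np.concatenate([[c] * genome.n_markers(c) for c in genome.chrom_names])
    pos = np.concatenate([genome.markers[c] for c in genome.chrom_names])
    ref = np.concatenate([np.asarray(genome.ref[c], dtype=object) for c in genome.chrom_names])
    alt = np.concatenate([np.asarray(genome.alt[c], dtype=object) for c in genome.chrom_names])
    f_res = np.concatenate([pop.donor_frequency(c, res_ids) for c in genome.chrom_names])
    f_sus = np.concatenate([pop.donor_frequency(c, sus_ids) for c in genome.chrom_names])
    n_sites = len(pos)

    # optional planted indels: lengthen alt (insertion) or ref (deletion)
    vclass = np.array(["SNP"] * n_sites, dtype=object)
    if indel_lengths:
        total = sum(indel_lengths.values())
        chosen = rng.choice(n_sites, size=total, replace=False)
        bases = np.array(list("ACGT"))
        k = 0
        for length, count in indel_lengths.items():
            if length == 0:
                raise ValueError("indel length 0 is not an indel")
            for _ in range(count):
                i = chosen[k]; k += 1
                tail = "".join(rng.choice(bases, size=abs(length)))
                if length > 0:
                    alt[i] = str(ref[i]) + tail
                    vclass[i] = "INS"
                else:
                    ref[i] = str(ref[i]) + tail
                    alt[i] = str(ref[i])[0]
                    vclass[i] = "DEL"

    impact = np.array(["MODIFIER"] * n_sites, dtype=object)
    if impacts:
        unknown = set(impacts) - {"HIGH", "MODERATE", "LOW"}
        if unknown:
            raise ValueError(f"plantable impact classes are HIGH/MODERATE/LOW, got {sorted(unknown)}")
        total = sum(impacts.values())
        chosen = rng.choice(n_sites, size=total, replace=False)
        k = 0
        for label, count in impacts.items():
            impact[chosen[k:k + count]] = label
            k += count
    consequence = np.array([_CONSEQUENCE_BY_IMPACT[i] for i in impact], dtype=object)

    def bulk_columns(f_true):
        depth = dm.draw_depths(n_sites, rng)
        f_obs = f_true * (1 - e) + (1 - f_true) * e
        ad = rng.binomial(depth, f_obs)
        rd = depth - ad
        gt = np.where(ad == 0, "0/0", np.where(rd == 0, "1/1", "0/1"))
        gt = np.where(depth == 0, "./.", gt)
        return gt, rd, ad

    data = {
        "chrom": chroms, "pos": pos, "ref": ref, "alt": alt,
        "vclass": vclass, "impact": impact, "consequence": consequence,
    }
    for sample, f_true in ((SAMPLE_RECURRENT, np.zeros(n_sites)),
                           (SAMPLE_DONOR, np.ones(n_sites)),
                           (SAMPLE_RES_BULK, f_res), (SAMPLE_SUS_BULK, f_sus)):
        gt, rd, ad = bulk_columns(f_true)
        if sample == SAMPLE_RECURRENT:
            gt = np.where(gt == "./.", "./.", "0/0")
        elif sample == SAMPLE_DONOR:
            gt = np.where(gt == "./.", "./.", "1/1")
        data[gt_col(sample)] = gt
        data[rd_col(sample)] = rd
        data[ad_col(sample)] = ad
    sites = pd.DataFrame(data)

    is_qtl = np.zeros(n_sites, dtype=bool)
    if qtl is not None:
        qi = genome.marker_index(qtl.chrom, qtl.pos)
        offset = 0
        for c in genome.chrom_names:
            if c == qtl.chrom:
                is_qtl[offset + qi] = True
                break
            offset += genome.n_markers(c)
    truth = pd.DataFrame({
        "chrom": chroms, "pos": pos, "f_res": f_res, "f_sus": f_sus,
        "is_qtl": is_qtl, "vclass": vclass, "impact": impact,
    })
    return sites, truth


# ---------------------------------------------------------------------------
# FASTQ with planted defects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FastqDefects:
    """Proportions of reads given exactly one planted defect (rest are clean Q40).

    ``p_adapter``: adapter appended at the 3' end (removal shortens the read by
    ``len(adapter)``).  ``p_low5``/``p_low3``: 5' Q10 or 3' Q2 tails of the
    stated lengths (trimmed).  ``p_n``: a contiguous interior N run covering
    ``n_frac`` of the read (dropped by the N-rate filter).  ``p_lowq``: an
    alternating Q40/Q12 quality pattern putting ~half the bases below Q15
    (dropped by the low-quality-fraction filter).
    """

    adapter: str = "AGATCGGAAGAGC"
    p_adapter: float = 0.0
    p_low5: float = 0.0
    low5_len: int = 8
    p_low3: float = 0.0
    low3_len: int = 10
    p_n: float = 0.0
    n_frac: float = 0.12
    p_lowq: float = 0.0

    def probabilities(self) -> np.ndarray:
        p = np.array([self.p_adapter, self.p_low5, self.p_low3, self.p_n, self.p_lowq])
        if p.min() < 0 or p.sum() > 1:
            raise ValueError("defect proportions must be >= 0 and sum to <= 1")
        return np.append(p, 1 - p.sum())  # last slot: clean


_CATEGORIES = ("adapter", "low5", "low3", "n_run", "lowq", "clean")


def synth_fastq(n_reads: int, read_len: int = 150, defects: FastqDefects | None = None,
                seed: int = 0) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Generate reads with planted, mutually exclusive quality defects.

    Returns ``(reads, truth)``: reads as (id, sequence, Phred+33 quality
    string) tuples and a truth table with each read's defect category, whether
    the cleaning procedure should keep it, and the expected post-trim length.
    """
    if read_len < 1:
        raise ValueError("read_len must be >= 1")
    defects = defects or FastqDefects()
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    cats = rng.choice(len(_CATEGORIES), size=n_reads, p=defects.probabilities())
    q40, q35, q12, q10, q2 = (chr(q + 33) for q in (40, 35, 12, 10, 2))
    reads, truth_rows = [], []
    for i in range(n_reads):
        cat = _CATEGORIES[cats[i]]
        seq = "".join(rng.choice(bases, size=read_len))
        if cat != "adapter":
            # a chance adapter-prefix match at the read end would make the
            # cleaner trim a "clean" read; regenerate until none exists
            while find_adapter_start(seq, defects.adapter) is not None:
                seq = "".join(rng.choice(bases, size=read_len))
        qual = q40 * read_len
        keep, exp_len = True, read_len
        if cat == "adapter":
            alen = len(defects.adapter)
            seq = seq[: read_len - alen] + defects.adapter
            exp_len = read_len - alen
            keep = exp_len >= 30
        elif cat == "low5":
            k = defects.low5_len
            qual = q10 * k + q40 * (read_len - k)
            exp_len = read_len - k
            keep = exp_len >= 30
        elif cat == "low3":
            k = defects.low3_len
            qual = q40 * (read_len - k) + q2 * k
            exp_len = read_len - k
            keep = exp_len >= 30
        elif cat == "n_run":
            n_n = math.ceil(defects.n_frac * read_len)
            start = min(20, read_len - n_n)
            seq = seq[:start] + "N" * n_n + seq[start + n_n:]
            qual = qual[:start] + q35 * n_n + qual[start + n_n:]
            keep, exp_len = False, 0
        elif cat == "lowq":
            pattern = [(q40 if j % 2 == 0 else q12) for j in range(read_len)]
            pattern[-1] = q40
            qual = "".join(pattern)
            keep, exp_len = False, 0
        reads.append((f"read{i + 1:06d}", seq, qual))
        truth_rows.append({"read_id": f"read{i + 1:06d}", "category": cat,
                           "expect_kept": keep, "expect_len": exp_len if keep else 0})
    return reads, pd.DataFrame(truth_rows)


def write_fastq(reads: Iterable[tuple[str, str, str]], path) -> None:
    """Write (id, seq, qual) tuples as FASTQ; gzip-compressed if path ends in .gz."""
    with open_text_write(path) as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
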