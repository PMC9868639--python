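"""Forward simulation of crossbred dairy cattle genomes and test-day phenotypes.

Emulates the data structure of an Indian smallholder crossbred population:
three diverged ancestral populations (indigenous *B. indicus*, Holstein-
Friesian, Jersey) genotyped on an array ascertained in *B. taurus* (so
indigenous-origin alleles are skewed toward low MAF), crossbred cows built
from recombined ancestral segments at roughly .36/.49/.15 indigenous/HF/
Jersey ancestry, planted QTL that are either fixed between ancestors
("breed-origin" QTL) or segregating within one ancestor, and repeated
monthly test-day milk yields recorded in very small herds.

Allele frequencies evolve by Balding-Nichols drift from a shared ancestral
frequency; no coalescent machinery is used.  Within-population LD can be
added by sampling each panel haplotype as a mosaic of a finite founder pool.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

INDICUS = "INDICUS"
HF = "HF"
JERSEY = "JERSEY"
EXOTIC = "EXOTIC"
ORIGINS3 = (INDICUS, HF, JERSEY)
ORIGINS2 = (INDICUS, EXOTIC)

REF_PREFIX = "REF_"
CROSSBRED = "CROSSBRED"

DIM_MIN, DIM_MAX = 8, 340


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SnpMap:
    """Marker map: physical (bp) and genetic (cM) positions per chromosome.

    Positions must be strictly increasing within a chromosome; column index
    is implicit 0..n_snp-1 in storage order (chromosomes concatenated).
    """

    chrom: np.ndarray          # int chromosome id per SNP
    pos_bp: np.ndarray         # int64 bp
    cm: np.ndarray             # float centimorgan

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.cm = np.asarray(self.cm, dtype=float)
        if not (len(self.chrom) == len(self.pos_bp) == len(self.cm)):
            raise ValueError("chrom, pos_bp and cm must have equal length")
        for c, sl in self.chromosome_slices().items():
            if np.any(np.diff(self.pos_bp[sl]) <= 0):
                raise ValueError(f"pos_bp not strictly increasing on chromosome {c}")

    @property
    def n_snp(self) -> int:
        return len(self.pos_bp)

    def chromosome_slices(self) -> dict:
        """Ordered mapping chromosome -> slice of SNP indices."""
        out = {}
        chroms, starts = np.unique(self.chrom, return_index=True)
        order = np.argsort(starts)
        bounds = list(np.sort(starts)) + [len(self.chrom)]
        for k, i in enumerate(order):
            out[chroms[i]] = slice(bounds[k], bounds[k + 1])
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "pos_bp": self.pos_bp, "cm": self.cm,
             "idx": np.arange(self.n_snp)}
        )


def uniform_map(n_snp: int, n_chrom: int, chrom_length_bp: int = 100_000_000,
                cm_per_mb: float = 1.0) -> SnpMap:
    """Evenly spaced markers on `n_chrom` chromosomes, 1 cM/Mb by default."""
    per = np.full(n_chrom, n_snp // n_chrom)
    per[: n_snp % n_chrom] += 1
    chroms, pos, cm = [], [], []
    for c in range(n_chrom):
        m = per[c]
        p = np.linspace(1, chrom_length_bp, m, dtype=np.int64)
        chroms.append(np.full(m, c + 1))
        pos.append(p)
        cm.append(p / 1e6 * cm_per_mb)
    return SnpMap(np.concatenate(chroms), np.concatenate(pos), np.concatenate(cm))


@dataclass
class HaplotypePanel:
    """Phased 0/1 allele matrix (haplotypes x SNPs, 1 = allele A).

    Rows 2i and 2i+1 are the phase pair of sample i.  `pop_labels` is one
    label per sample (REF_INDICUS / REF_HF / REF_JERSEY / CROSSBRED).
    """

    hap_matrix: np.ndarray
    sample_ids: list
    pop_labels: np.ndarray
    snp_map: SnpMap
    pop_freqs: dict | None = None   # origin -> per-SNP allele-A frequency

    def __post_init__(self) -> None:
        self.hap_matrix = np.asarray(self.hap_matrix, dtype=np.int8)
        self.pop_labels = np.asarray(self.pop_labels)
        if self.hap_matrix.ndim != 2:
            raise ValueError("hap_matrix must be 2-D")
        if self.hap_matrix.shape[0] != 2 * len(self.sample_ids):
            raise ValueError("expected exactly 2 haplotype rows per sample")
        if len(self.pop_labels) != len(self.sample_ids):
            raise ValueError("one pop label per sample required")
        if self.hap_matrix.shape[1] != self.snp_map.n_snp:
            raise ValueError("hap_matrix columns must match snp_map")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snp(self) -> int:
        return self.hap_matrix.shape[1]

    def dosage(self) -> np.ndarray:
        """Genotype dosage of allele A per sample (n_samples x n_snp)."""
        return (self.hap_matrix[0::2].astype(np.int16)
                + self.hap_matrix[1::2]).astype(np.int8)

    def samples_of(self, pop: str) -> np.ndarray:
        return np.flatnonzero(self.pop_labels == pop)

    def hap_rows_of(self, pop: str) -> np.ndarray:
        s = self.samples_of(pop)
        return np.sort(np.concatenate([2 * s, 2 * s + 1])) if len(s) else np.array([], int)

    def subset_samples(self, sample_idx: np.ndarray) -> "HaplotypePanel":
        sample_idx = np.asarray(sample_idx)
        rows = np.empty(2 * len(sample_idx), dtype=int)
        rows[0::2], rows[1::2] = 2 * sample_idx, 2 * sample_idx + 1
        return HaplotypePanel(
            self.hap_matrix[rows], [self.sample_ids[i] for i in sample_idx],
            self.pop_labels[sample_idx], self.snp_map, self.pop_freqs)


@dataclass
class QtlSpec:
    """One planted causative locus.

    kind BREED_ORIGIN: fixed for alternative alleles between the favored
    ancestor and the rest; its dosage is the count of haplotypes of the
    favored origin.  kind WITHIN_<pop>: segregating in exactly that ancestor
    and monomorphic elsewhere.  `alpha` is the allele-substitution effect in
    kg/day per copy.
    """

    kind: str                   # BREED_ORIGIN | WITHIN_INDICUS | WITHIN_HF | WITHIN_JERSEY
    chrom: int
    pos_bp: int
    alpha: float
    favored_origin: str | None = None   # BREED_ORIGIN only
    freq: float = 0.3                   # WITHIN_* segregating frequency
    snp_idx: int | None = None          # resolved marker-map index

    def within_origin(self) -> str:
        if not self.kind.startswith("WITHIN_"):
            raise ValueError(f"not a within-ancestor QTL: {self.kind}")
        return self.kind.removeprefix("WITHIN_")


@dataclass
class SimTruth:
    """Ground truth carried alongside a simulated crossbred population."""

    origins: tuple                     # origin label order used in hap_origin codes
    hap_origin: np.ndarray             # uint8 (2*n_cows, n_snp) index into origins
    hap_source: list                   # per hap: list of (start, end, origin_idx, source_row)
    composition: np.ndarray            # (n_cows, n_origins) genome-wide ancestry
    qtls: list = field(default_factory=list)
    qtl_dosage: np.ndarray | None = None      # (n_cows, n_qtl)
    genetic_values: np.ndarray | None = None  # (n_cows,) QTL part only
    breeding_values: np.ndarray | None = None # (n_cows,) QTL + polygenic
    herd_effects: dict | None = None
    variance_components: dict | None = None   # test-day and cow-mean scale shares

    @property
    def n_cows(self) -> int:
        return self.hap_origin.shape[0] // 2

    def composition_check(self) -> np.ndarray:
        """Recompute composition from hap_origin (mean indicator)."""
        k = len(self.origins)
        n = self.n_cows
        out = np.empty((n, k))
        for j in range(k):
            ind = (self.hap_origin == j).mean(axis=1)
            out[:, j] = 0.5 * (ind[0::2] + ind[1::2])
        return out

    def origin_at(self, hap_row: int, snp_idx: int) -> int:
        return int(self.hap_origin[hap_row, snp_idx])

    def source_at(self, hap_row: int, snp_idx: int) -> int:
        segs = self.hap_source[hap_row]
        i = bisect.bisect_right([s[0] for s in segs], snp_idx) - 1
        start, end, _o, src = segs[i]
        if not (start <= snp_idx < end):
            raise KeyError(f"snp {snp_idx} not covered by hap {hap_row}")
        return src


# ---------------------------------------------------------------------------
# ancestral panels
# ---------------------------------------------------------------------------

DEFAULT_DIVERGENCE = {
    # Balding-Nichols drift from the shared ancestor: the indicus/taurus
    # split is much deeper than the HF/Jersey split within taurus.
    "indicus": 0.22,
    "taurus": 0.12,
    "hf": 0.05,
    "jersey": 0.05,
}


def _bn_drift(p: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    """One Balding-Nichols drift step: Beta with mean p, 'variance' f*p*(1-p)."""
    if f <= 0:
        return p.copy()
    a = p * (1 - f) / f
    b = (1 - p) * (1 - f) / f
    return np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4)


def simulate_ancestral_frequencies(
    n_snp: int,
    n_chrom: int = 2,
    divergence: dict | None = None,
    maf_skew: str = "array",
    desi_subpops: int = 1,
    desi_f: float = 0.01,
    seed: int | np.random.Generator = 0,
    snp_map: SnpMap | None = None,
) -> tuple[SnpMap, dict]:
    """Draw per-population allele-A frequencies for the three ancestors.

    maf_skew="array" applies taurus-biased array ascertainment (SNPs kept
    with probability proportional to their exotic heterozygosity), which
    leaves indigenous-origin alleles skewed toward low MAF and exotic-origin
    alleles toward high MAF.  "none" keeps every drawn SNP.
    """
    if n_snp < 1:
        raise ValueError("n_snp must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    div = dict(DEFAULT_DIVERGENCE, **(divergence or {}))
    for k, v in div.items():
        if not 0 <= v < 1:
            raise ValueError(f"divergence[{k}] outside [0, 1)")
    if maf_skew not in ("array", "none"):
        raise ValueError("maf_skew must be 'array' or 'none'")

    kept: list[np.ndarray] = []
    n_kept = 0
    while n_kept < n_snp:
        batch = max(2048, 2 * (n_snp - n_kept))
        p0 = rng.uniform(0.05, 0.95, batch)
        p_ind = _bn_drift(p0, div["indicus"], rng)
        p_tau = _bn_drift(p0, div["taurus"], rng)
        p_hf = _bn_drift(p_tau, div["hf"], rng)
        p_jr = _bn_drift(p_tau, div["jersey"], rng)
        if maf_skew == "array":
            q = 0.5 * (p_hf + p_jr)
            accept = rng.random(batch) < (2 * q * (1 - q)) / 0.5
        else:
            accept = np.ones(batch, dtype=bool)
        block = np.stack([p_ind[accept], p_hf[accept], p_jr[accept]], axis=1)
        kept.append(block)
        n_kept += block.shape[0]
    freq = np.concatenate(kept, axis=0)[:n_snp]
    freqs = {INDICUS: freq[:, 0], HF: freq[:, 1], JERSEY: freq[:, 2]}
    if desi_subpops > 1:
        # heterogeneous "Desi" indigenous base: ~desi_f of indicus variation
        # lies between subpopulations
        freqs["_DESI"] = np.stack(
            [_bn_drift(freq[:, 0], desi_f, rng) for _ in range(desi_subpops)], axis=0)
    if snp_map is None:
        snp_map = uniform_map(n_snp, n_chrom)
    elif snp_map.n_snp != n_snp:
        raise ValueError("snp_map size does not match n_snp")
    return snp_map, freqs


def sample_panel(
    snp_map: SnpMap,
    freqs: dict,
    n_per_pop: dict,
    seed: int | np.random.Generator = 0,
    ld_founders: int | None = None,
    ld_switch_cm: float = 1.0,
    label_prefix: str = REF_PREFIX,
) -> HaplotypePanel:
    """Sample labelled reference haplotypes at the given population frequencies.

    With `ld_founders`, each haplotype is a mosaic of a finite founder pool
    (switches Poisson at 1/ld_switch_cm per cM), creating within-population
    LD so that within-ancestor QTL have tagging SNPs.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = snp_map.n_snp
    haps, ids, pops = [], [], []
    for pop, n in n_per_pop.items():
        if n < 2:
            raise ValueError(f"need >= 2 samples per population (got {n} for {pop})")
        p = freqs[pop]
        if ld_founders:
            founders = (rng.random((ld_founders, m)) < p).astype(np.int8)
            block = np.empty((2 * n, m), dtype=np.int8)
            for h in range(2 * n):
                block[h] = _mosaic_of(founders, snp_map, 1.0 / ld_switch_cm, rng)
            haps.append(block)
        else:
            haps.append((rng.random((2 * n, m)) < p).astype(np.int8))
        ids.extend(f"{pop}_{i:04d}" for i in range(n))
        pops.extend([label_prefix + pop] * n)
    return HaplotypePanel(np.vstack(haps), ids, np.array(pops), snp_map,
                          pop_freqs=dict(freqs))


def _mosaic_of(pool: np.ndarray, snp_map: SnpMap, rate_per_cm: float,
               rng: np.random.Generator) -> np.ndarray:
    """Copy a haplotype as a founder mosaic with Poisson switches on the cM map."""
    m = snp_map.n_snp
    out = np.empty(m, dtype=np.int8)
    for sl in snp_map.chromosome_slices().values():
        cm = snp_map.cm[sl]
        cuts = _poisson_breakpoints(cm, rate_per_cm, rng)
        bounds = [0] + cuts + [sl.stop - sl.start]
        for a, b in zip(bounds[:-1], bounds[1:]):
            src = rng.integers(pool.shape[0])
            out[sl.start + a: sl.start + b] = pool[src, sl.start + a: sl.start + b]
    return out


def _poisson_breakpoints(cm: np.ndarray, rate_per_cm: float,
                         rng: np.random.Generator) -> list[int]:
    """Indices (within-chromosome) where a new segment starts."""
    if rate_per_cm <= 0 or len(cm) == 0:
        return []
    length = cm[-1] - cm[0]
    k = rng.poisson(rate_per_cm * length)
    if k == 0:
        return []
    pos = np.sort(rng.uniform(cm[0], cm[-1], k))
    idx = np.searchsorted(cm, pos, side="right")
    idx = np.unique(idx[(idx > 0) & (idx < len(cm))])
    return list(idx)


def simulate_ancestral_panels(
    n_per_pop: dict,
    n_snp: int,
    n_chrom: int = 2,
    divergence: dict | None = None,
    maf_skew: str = "array",
    seed: int | np.random.Generator = 0,
    ld_founders: int | None = None,
    **freq_kwargs,
) -> HaplotypePanel:
    """Three labelled reference panels with taurus-ascertained MAF spectra."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    snp_map, freqs = simulate_ancestral_frequencies(
        n_snp, n_chrom, divergence, maf_skew, seed=rng, **freq_kwargs)
    return sample_panel(snp_map, freqs, n_per_pop, seed=rng,
                        ld_founders=ld_founders)


# ---------------------------------------------------------------------------
# crossbreds
# ---------------------------------------------------------------------------

def simulate_crossbreds(
    panels: HaplotypePanel,
    n_cows: int,
    target_props: dict,
    n_generations: int = 4,
    mating_scheme: str = "copying",
    recomb_scale: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> tuple[HaplotypePanel, SimTruth]:
    """Build crossbred cows from ancestral panels with SNP-resolution truth.

    "copying" (default): each transmitted haplotype is a mosaic whose
    breakpoints follow a Poisson process at `n_generations * recomb_scale`
    per Morgan on the genetic map and whose segment origins are i.i.d.
    `target_props`; alleles are copied from a random panel haplotype of the
    segment's origin.  Expected ancestry composition equals `target_props`
    exactly.  "f1": one whole-genome haplotype from each of the two origins
    (a pure x pure first cross).

    `n_generations` may be an int or a sequence of (generations, weight)
    pairs, in which case each haplotype draws its own generation depth —
    real crossbred populations mix deep and very recent crossbreeding.
    recomb_scale=0 gives single-ancestry chromosome copies.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    origins = tuple(target_props)
    props = np.array([target_props[o] for o in origins], dtype=float)
    if abs(props.sum() - 1) > 1e-8:
        raise ValueError("target proportions must sum to 1")
    pool_rows = {o: panels.hap_rows_of(REF_PREFIX + o) for o in origins}
    for o, rows in pool_rows.items():
        if len(rows) == 0:
            raise ValueError(f"no ancestor panel haplotypes for origin {o}")
    snp_map = panels.snp_map
    m = snp_map.n_snp
    H = 2 * n_cows
    hap = np.empty((H, m), dtype=np.int8)
    orig = np.empty((H, m), dtype=np.uint8)
    sources: list[list[tuple]] = []
    if np.isscalar(n_generations):
        gens = np.full(H, float(n_generations))
    else:
        vals, weights = zip(*n_generations)
        weights = np.asarray(weights, dtype=float)
        gens = rng.choice(vals, size=H, p=weights / weights.sum())

    if mating_scheme == "f1":
        if len(origins) != 2:
            raise ValueError("f1 scheme requires exactly two origins")
        for h in range(H):
            o_idx = h % 2
            segs = _copy_haplotype_fixed_origin(
                hap[h], orig[h], o_idx, pool_rows[origins[o_idx]],
                panels.hap_matrix, snp_map,
                gens[h] * recomb_scale / 100.0, rng)
            sources.append(segs)
    elif mating_scheme == "copying":
        for h in range(H):
            segs = _copy_haplotype(
                hap[h], orig[h], props, [pool_rows[o] for o in origins],
                panels.hap_matrix, snp_map,
                gens[h] * recomb_scale / 100.0, rng)
            sources.append(segs)
    else:
        raise ValueError(f"unknown mating_scheme {mating_scheme!r}")

    ids = [f"XB_{i:05d}" for i in range(n_cows)]
    cross = HaplotypePanel(hap, ids, np.array([CROSSBRED] * n_cows), snp_map,
                           pop_freqs=panels.pop_freqs)
    truth = SimTruth(origins=origins, hap_origin=orig, hap_source=sources,
                     composition=np.empty((n_cows, len(origins))))
    truth.composition = truth.composition_check()
    return cross, truth


def _copy_haplotype(out_alleles, out_orig, props, pools, panel_haps,
                    snp_map: SnpMap, rate_per_cm: float,
                    rng: np.random.Generator) -> list[tuple]:
    segs = []
    for sl in snp_map.chromosome_slices().values():
        cm = snp_map.cm[sl]
        cuts = _poisson_breakpoints(cm, rate_per_cm, rng)
        bounds = [0] + cuts + [sl.stop - sl.start]
        for a, b in zip(bounds[:-1], bounds[1:]):
            o = rng.choice(len(props), p=props)
            src = pools[o][rng.integers(len(pools[o]))]
            lo, hi = sl.start + a, sl.start + b
            out_alleles[lo:hi] = panel_haps[src, lo:hi]
            out_orig[lo:hi] = o
            segs.append((lo, hi, int(o), int(src)))
    return segs


def _copy_haplotype_fixed_origin(out_alleles, out_orig, o_idx, pool, panel_haps,
                                 snp_map: SnpMap, rate_per_cm: float,
                                 rng: np.random.Generator) -> list[tuple]:
    segs = []
    for sl in snp_map.chromosome_slices().values():
        cm = snp_map.cm[sl]
        cuts = _poisson_breakpoints(cm, rate_per_cm, rng)
        bounds = [0] + cuts + [sl.stop - sl.start]
        for a, b in zip(bounds[:-1], bounds[1:]):
            src = pool[rng.integers(len(pool))]
            lo, hi = sl.start + a, sl.start + b
            out_alleles[lo:hi] = panel_haps[src, lo:hi]
            out_orig[lo:hi] = o_idx
            segs.append((lo, hi, int(o_idx), int(src)))
    return segs


# ---------------------------------------------------------------------------
# QTL
# ---------------------------------------------------------------------------

def plant_qtl(
    panels: HaplotypePanel,
    truth: SimTruth,
    qtl_specs: list[QtlSpec],
    seed: int | np.random.Generator = 0,
) -> SimTruth:
    """Plant QTL and record per-cow dosages and genotypic values in truth.

    BREED_ORIGIN QTL are fixed for alternative alleles between the favored
    ancestor and the rest, so a cow's dosage is her count of favored-origin
    haplotypes at the locus.  WITHIN_* QTL alleles are drawn segregating on
    the named ancestor's panel haplotypes (monomorphic elsewhere) and ride
    into crossbreds through the recorded segment sources.

    Mutates `panels.hap_matrix` at WITHIN_* loci only if the QTL position is
    a typed marker; by default pipelines exclude QTL columns from markers.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    snp_map = panels.snp_map
    n = truth.n_cows
    dos = np.zeros((n, len(qtl_specs)))
    specs = []
    for q_i, q in enumerate(qtl_specs):
        q = replace(q)
        if q.snp_idx is None:
            on_chrom = np.flatnonzero(snp_map.chrom == q.chrom)
            if len(on_chrom) == 0:
                raise ValueError(f"QTL chromosome {q.chrom} not simulated")
            q.snp_idx = int(on_chrom[np.argmin(np.abs(snp_map.pos_bp[on_chrom] - q.pos_bp))])
        j = q.snp_idx
        if q.kind == "BREED_ORIGIN":
            if q.favored_origin not in truth.origins:
                raise ValueError(f"favored_origin {q.favored_origin} not simulated")
            o = truth.origins.index(q.favored_origin)
            ind = (truth.hap_origin[:, j] == o)
            dos[:, q_i] = ind[0::2].astype(float) + ind[1::2]
        elif q.kind.startswith("WITHIN_"):
            pop = q.within_origin()
            if pop not in truth.origins:
                raise ValueError(f"{q.kind}: origin {pop} not simulated")
            if not 0 < q.freq < 1:
                raise ValueError(f"{q.kind}: segregating frequency must be in (0,1)")
            rows = panels.hap_rows_of(REF_PREFIX + pop)
            alleles = np.zeros(panels.hap_matrix.shape[0], dtype=np.int8)
            draw = (rng.random(len(rows)) < q.freq).astype(np.int8)
            if draw.min() == draw.max():   # degenerate draw: force segregation
                draw[rng.integers(len(draw))] = 1 - draw[0]
            alleles[rows] = draw
            panels.hap_matrix[:, j] = alleles
            o = truth.origins.index(pop)
            for h in range(2 * n):
                if truth.hap_origin[h, j] == o:
                    dos[h // 2, q_i] += alleles[truth.source_at(h, j)]
        else:
            raise ValueError(f"unknown QTL kind {q.kind!r}")
        specs.append(q)
    truth.qtls = specs
    truth.qtl_dosage = dos
    truth.genetic_values = dos @ np.array([q.alpha for q in specs]) \
        if specs else np.zeros(n)
    return truth


# ---------------------------------------------------------------------------
# test-day phenotypes
# ---------------------------------------------------------------------------

@dataclass
class FixedEffectConfig:
    """Magnitudes (kg/day) of the simulated fixed-effect structure."""

    n_parity: int = 3
    n_cdc: int = 4
    n_year_month: int = 8
    parity_sd: float = 0.4
    cdc_sd: float = 0.3
    year_month_sd: float = 0.3
    curve_sd: float = 0.25      # SD of per-parity / per-cdc Legendre P1-P3 coefficients
    mean_yield: float = 7.22    # kg/day grand mean


def _scaled_normal(rng: np.random.Generator, var: float, n: int) -> np.ndarray:
    """Centered normal draws moment-matched to the exact target variance."""
    if var <= 0 or n < 2:
        return np.zeros(n)
    x = rng.normal(0, 1, n)
    x -= x.mean()
    return x / x.std() * np.sqrt(var)


def _legendre_values(dim: np.ndarray) -> np.ndarray:
    x = 2.0 * (np.asarray(dim, dtype=float) - DIM_MIN) / (DIM_MAX - DIM_MIN) - 1.0
    return np.stack([np.ones_like(x), x, 0.5 * (3 * x ** 2 - 1),
                     0.5 * (5 * x ** 3 - 3 * x)], axis=-1)


def simulate_testday(
    truth: SimTruth,
    h2: float = 0.18,
    repeatability: float = 0.35,
    herd_var_frac: float = 0.10,
    herd_size_dist: str = "poisson2",
    n_td_per_cow: int = 6,
    fixed_effect_config: FixedEffectConfig | None = None,
    phen_sd: float = 2.0,
    h2_scale: str = "cow_mean",
    panel: HaplotypePanel | None = None,
    n_polygenic_loci: int = 2000,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate repeated monthly test-day yields with herd structure.

    `h2` is, by default, the heritability of the analyzed trait — the
    per-cow mean adjusted test-day yield — so that a genomic analysis of
    cow means recovers it directly; the corresponding (smaller) test-day
    scale additive share is derived from `repeatability`, `herd_var_frac`
    and the record count and stored in ``truth.variance_components``.
    Set h2_scale="testday" to interpret `h2` on the single-record scale.

    yield = mu + parity + cdc + year_month + per-parity and per-cdc
    third-order Legendre lactation curves + herd + animal (additive QTL +
    polygene, plus permanent environment) + residual.

    When the crossbred `panel` is supplied, the residual polygene is built
    from `n_polygenic_loci` randomly chosen segregating SNPs with iid normal
    effects, so breeding values carry the genomic covariance a GRM model
    assumes; without a panel the polygene is iid noise per cow (then a
    marker-based analysis cannot recover the heritability).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cfg = fixed_effect_config or FixedEffectConfig()
    n = truth.n_cows
    t, c = repeatability, herd_var_frac
    if not 0 <= h2 <= 1 or not 0 <= t < 1 or not 0 <= c < 1:
        raise ValueError("variance shares must lie in [0, 1)")
    if t + c >= 1:
        raise ValueError("repeatability + herd share must be < 1")
    e_share = 1.0 - t - c
    if h2_scale == "cow_mean":
        d = t + c + e_share / n_td_per_cow
        h2_td = h2 * d
    elif h2_scale == "testday":
        h2_td = h2
    else:
        raise ValueError("h2_scale must be 'cow_mean' or 'testday'")
    if h2_td > t:
        raise ValueError("implied additive share exceeds repeatability")

    var_p = phen_sd ** 2
    var_a = h2_td * var_p
    var_pe = (t - h2_td) * var_p
    var_h = c * var_p
    var_e = e_share * var_p

    g = truth.genetic_values if truth.genetic_values is not None else np.zeros(n)
    var_qtl = float(np.var(g))
    var_poly = max(var_a - var_qtl, 0.0)
    if panel is not None and var_poly > 0:
        if panel.n_samples != n:
            raise ValueError("panel/truth cow count mismatch")
        dos = panel.dosage().astype(float)
        freq = dos.mean(axis=0) / 2
        seg = np.flatnonzero((freq > 0.01) & (freq < 0.99))
        loci = rng.choice(seg, size=min(n_polygenic_loci, len(seg)), replace=False)
        poly = (dos[:, loci] - 2 * freq[loci]) @ rng.normal(0, 1, len(loci))
        poly -= poly.mean()
        poly *= np.sqrt(var_poly) / max(poly.std(), 1e-12)
    else:
        poly = _scaled_normal(rng, var_poly, n)
    a = g - g.mean() + poly
    pe = _scaled_normal(rng, var_pe, n)

    # herds: sizes 1 + Poisson so the mean is ~2.17 cows per herd
    herd_of = np.empty(n, dtype=int)
    herd_eff = []
    i = 0
    while i < n:
        size = 1 + rng.poisson(1.17) if herd_size_dist == "poisson2" else 1
        size = min(size, n - i)
        herd_of[i: i + size] = len(herd_eff)
        herd_eff.append(rng.normal())
        i += size
    herd_eff = np.array(herd_eff)
    if len(herd_eff) > 1 and herd_eff.std() > 0:
        herd_eff = herd_eff / herd_eff.std() * np.sqrt(var_h)
    else:
        herd_eff = herd_eff * np.sqrt(var_h)
    herd_of = herd_of[rng.permutation(n)]

    parity = rng.integers(1, cfg.n_parity + 1, n)
    cdc = rng.integers(0, cfg.n_cdc, n)
    par_eff = rng.normal(0, cfg.parity_sd, cfg.n_parity)
    cdc_eff = rng.normal(0, cfg.cdc_sd, cfg.n_cdc)
    ym_eff = rng.normal(0, cfg.year_month_sd, cfg.n_year_month)
    par_curve = rng.normal(0, cfg.curve_sd, (cfg.n_parity, 3))
    cdc_curve = rng.normal(0, cfg.curve_sd, (cfg.n_cdc, 3))

    rows = []
    for i in range(n):
        start = rng.integers(DIM_MIN, DIM_MIN + 35)
        dims = start + 30 * np.arange(n_td_per_cow) + rng.integers(-5, 6, n_td_per_cow)
        dims = np.clip(dims, DIM_MIN, DIM_MAX)
        ym0 = int(rng.integers(0, cfg.n_year_month))
        lp = _legendre_values(dims)[:, 1:]
        mu_i = (cfg.mean_yield + par_eff[parity[i] - 1] + cdc_eff[cdc[i]]
                + a[i] + pe[i] + herd_eff[herd_of[i]])
        curve = lp @ par_curve[parity[i] - 1] + lp @ cdc_curve[cdc[i]]
        for k in range(n_td_per_cow):
            ym = (ym0 + k) % cfg.n_year_month
            y = mu_i + ym_eff[ym] + curve[k] + rng.normal(0, np.sqrt(var_e))
            rows.append((f"XB_{i:05d}", f"H{herd_of[i]:05d}", parity[i],
                         f"C{cdc[i]}", f"YM{ym:02d}", int(dims[k]), y))

    truth.breeding_values = a
    truth.herd_effects = {f"H{j:05d}": herd_eff[j] for j in range(len(herd_eff))}
    truth.variance_components = {
        "var_a_td": var_a, "var_pe_td": var_pe, "var_h_td": var_h,
        "var_e_td": var_e, "h2_td": var_a / var_p, "repeatability": t,
        "h2_cow_mean": var_a / (var_a + var_pe + var_h + var_e / n_td_per_cow),
    }
    return pd.DataFrame(rows, columns=["cow_id", "herd_id", "parity", "cdc",
                                       "year_month", "dim", "yield"])
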