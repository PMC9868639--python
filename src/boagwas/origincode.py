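"""Breed-origin coding of SNP alleles and the GWAS design vectors.

Once each crossbred haplotype window carries an ancestral origin label, every
allele inherits the label of its haplotype.  From the labelled alleles this
module builds, per cow and SNP, the origin-count and origin-specific dosage
vectors used by the partitioned association models:

    w1  count of indigenous-origin haplotypes (0-2)
    w2  A-allele dosage on indigenous-origin haplotypes
    w3  A-allele dosage on exotic-origin haplotypes (two-way)
    w4  A-allele dosage on HF-origin haplotypes (three-way)
    w5  A-allele dosage on Jersey-origin haplotypes (three-way)
    w6  count of Jersey-origin haplotypes
    w7  count of HF-origin haplotypes

By construction w2+w3 (two-way) and w2+w4+w5 (three-way) equal the raw
genotype dosage, and w1+w6+w7 = 2 at every locus.  Per-origin allele
frequencies among the origin-assigned haplotypes give the MAF > 1% inclusion
masks that select the per-SNP model variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simcross import HaplotypePanel, INDICUS, HF, JERSEY, EXOTIC
from .ancestry import AncestryTrack

GENOTYPES = ("aa", "aA", "Aa", "AA")


# ---------------------------------------------------------------------------
# state enumeration
# ---------------------------------------------------------------------------

@dataclass
class AncestryStateTable:
    """Ordered ancestry-genotype combinations and their distinguishable classes.

    An ordered state is a pair of (allele, origin) slots, one per haplotype;
    two states are indistinguishable when they differ only by swapping the
    two slots.  Classes are found by brute-force orbit collapse.
    """

    n_origins: int
    ordered_states: list          # [((allele, origin), (allele, origin)), ...]
    classes: list                 # list of frozensets of ordered states
    n_ordered: int
    n_distinguishable: int


def enumerate_states(n_origins: int) -> AncestryStateTable:
    if n_origins < 1:
        raise ValueError("n_origins must be >= 1")
    named = {1: ("I",), 2: ("I", "E"), 3: ("I", "H", "J")}
    origins = list(named.get(n_origins,
                             tuple(f"O{i + 1}" for i in range(n_origins))))
    slots = [(a, o) for a in "aA" for o in origins]
    ordered = [(s1, s2) for s1 in slots for s2 in slots]
    seen, classes = set(), []
    for st in ordered:
        if st in seen:
            continue
        orbit = frozenset({st, (st[1], st[0])})
        seen.update(orbit)
        classes.append(orbit)
    return AncestryStateTable(n_origins, ordered, classes,
                              len(ordered), len(classes))


# ---------------------------------------------------------------------------
# allele-origin assignment
# ---------------------------------------------------------------------------

@dataclass
class OriginAssignment:
    """Per-haplotype, per-SNP origin labels for SNPs in retained windows."""

    origins: tuple
    labels: np.ndarray            # uint8 (2*n_samples, n_included_snp)
    snp_idx: np.ndarray           # global SNP indices included
    n_excluded: int               # SNPs outside any retained window


def assign_allele_origins(panel: HaplotypePanel, track: AncestryTrack) -> OriginAssignment:
    """Propagate each haplotype's window origin label to its SNP alleles.

    SNPs falling in no retained window (dropped trailing windows) are
    excluded and counted.
    """
    w_of = track.partition.snp_to_window(panel.n_snp)
    included = np.flatnonzero(w_of >= 0)
    labels = track.labels[:, w_of[included]]
    return OriginAssignment(track.origins, labels.astype(np.uint8),
                            included, int((w_of < 0).sum()))


# ---------------------------------------------------------------------------
# design vectors
# ---------------------------------------------------------------------------

@dataclass
class OriginDesign:
    """Per-cow x SNP origin counts and origin-specific allele dosages."""

    mode: str                     # "two_way" | "three_way"
    w: dict                       # name -> int8 (n_cows, n_snp) matrix
    snp_idx: np.ndarray
    origin_freq: pd.DataFrame | None = None
    masks: dict = field(default_factory=dict)   # origin -> bool include array

    @property
    def n_cows(self) -> int:
        return next(iter(self.w.values())).shape[0]

    @property
    def n_snp(self) -> int:
        return len(self.snp_idx)

    def subset(self, cols: np.ndarray) -> "OriginDesign":
        """Column (SNP) subset, e.g. one chromosome for a LOCO scan."""
        cols = np.asarray(cols)
        return OriginDesign(
            self.mode, {k: v[:, cols] for k, v in self.w.items()},
            self.snp_idx[cols], None,
            {o: m[cols] for o, m in self.masks.items()})

    def reorder_cows(self, order: np.ndarray) -> "OriginDesign":
        """Row subset/permutation aligning the design to a phenotype order."""
        return OriginDesign(
            self.mode, {k: v[order] for k, v in self.w.items()},
            self.snp_idx, self.origin_freq, self.masks)


def build_design(panel: HaplotypePanel, origins: OriginAssignment,
                 mode: str = "two_way") -> OriginDesign:
    """Compile the w-vectors from origin-labelled alleles.

    two_way collapses HF and Jersey labels to EXOTIC.  Cows with no
    haplotype of an origin contribute 0 to that origin's dosage vector, the
    only coding under which the dosage-conservation identities hold.
    """
    alleles = panel.hap_matrix[:, origins.snp_idx]
    lab = origins.labels
    names = origins.origins

    def hapsum(mask: np.ndarray) -> np.ndarray:
        v = mask.astype(np.int8)
        return v[0::2] + v[1::2]

    def dosage_on(mask: np.ndarray) -> np.ndarray:
        v = (alleles * mask).astype(np.int8)
        return v[0::2] + v[1::2]

    if INDICUS not in names:
        raise ValueError("origin labels must include INDICUS")
    is_ind = lab == names.index(INDICUS)
    if mode == "two_way":
        w = {"w1": hapsum(is_ind), "w2": dosage_on(is_ind),
             "w3": dosage_on(~is_ind)}
    elif mode == "three_way":
        if HF not in names or JERSEY not in names:
            raise ValueError("three_way mode needs HF and JERSEY labels")
        is_hf = lab == names.index(HF)
        is_jr = lab == names.index(JERSEY)
        w = {"w1": hapsum(is_ind), "w2": dosage_on(is_ind),
             "w4": dosage_on(is_hf), "w5": dosage_on(is_jr),
             "w6": hapsum(is_jr), "w7": hapsum(is_hf)}
    else:
        raise ValueError("mode must be 'two_way' or 'three_way'")
    design = OriginDesign(mode, w, origins.snp_idx)
    design.origin_freq, design.masks = origin_maf(panel, origins, mode)
    return design


def origin_maf(panel: HaplotypePanel, origins: OriginAssignment,
               mode: str = "two_way", threshold: float = 0.01
               ) -> tuple[pd.DataFrame, dict]:
    """Per-SNP allele-A frequency and MAF>threshold mask per origin.

    Frequencies are computed on the crossbred cows' origin-assigned
    haplotypes; a SNP with no haplotype of an origin has an undefined
    frequency and is masked for that origin.
    """
    alleles = panel.hap_matrix[:, origins.snp_idx]
    lab = origins.labels
    names = origins.origins
    if mode == "two_way":
        groups = {INDICUS: lab == names.index(INDICUS)}
        groups[EXOTIC] = ~groups[INDICUS]
    else:
        groups = {o: lab == names.index(o) for o in (INDICUS, HF, JERSEY)}
    rows, masks = [], {}
    for o, mask in groups.items():
        n_hap = mask.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(n_hap > 0, (alleles * mask).sum(axis=0) / np.maximum(n_hap, 1),
                            np.nan)
        maf = np.fmin(freq, 1 - freq)
        include = (n_hap > 0) & (maf > threshold)
        masks[o] = include
        rows.append(pd.DataFrame({
            "snp": origins.snp_idx, "origin": o, "n_haplotypes": n_hap,
            "freq_A": freq, "maf": maf, "included": include}))
    return pd.concat(rows, ignore_index=True), masks


def save_design(design: OriginDesign, path) -> None:
    """Columnar container (.npz) plus a sidecar TSV schema (<path>.schema.tsv)."""
    import numpy as _np
    arrays = {f"w_{k}": v for k, v in design.w.items()}
    arrays["snp_idx"] = design.snp_idx
    for o, m in design.masks.items():
        arrays[f"mask_{o}"] = m
    _np.savez_compressed(path, mode=design.mode, **arrays)
    schema = pd.DataFrame(
        [{"array": k, "dtype": str(v.dtype), "shape": "x".join(map(str, v.shape))}
         for k, v in arrays.items()])
    schema.to_csv(f"{path}.schema.tsv", sep="\t", index=False)


def load_design(path) -> OriginDesign:
    with np.load(path, allow_pickle=False) as z:
        mode = str(z["mode"])
        w = {k[2:]: z[k] for k in z.files if k.startswith("w_")}
        masks = {k[5:]: z[k] for k in z.files if k.startswith("mask_")}
        snp_idx = z["snp_idx"]
    return OriginDesign(mode, w, snp_idx, None, masks)


def collapse_three_to_two(origins3: OriginAssignment) -> OriginAssignment:
    """Relabel HF/Jersey as EXOTIC, yielding a two-way assignment."""
    names = origins3.origins
    lab = origins3.labels
    out = np.where(lab == names.index(INDICUS), 0, 1).astype(np.uint8)
    return OriginAssignment((INDICUS, EXOTIC), out, origins3.snp_idx,
                            origins3.n_excluded)
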