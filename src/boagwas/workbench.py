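"""Configuration, file formats, and end-to-end pipeline orchestration.

Ties the five analysis stages — simulation, test-day adjustment, local
ancestry, origin coding, partitioned GWAS — into one reproducible run.  A
single master seed deterministically spawns per-stage random streams;
every written artifact is hashed into a JSON manifest.

Coordinates are 0-based half-open internally; VCF output is 1-based (the
only place 1-based coordinates appear).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import simcross, tdadjust, ancestry, origincode, bogwas
from .simcross import (HaplotypePanel, SnpMap, QtlSpec,
                       INDICUS, HF, JERSEY, CROSSBRED, DIM_MIN, DIM_MAX)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """One structured configuration for an end-to-end run.

    Window, MAF and FDR defaults follow the analysis conventions: 500-SNP
    windows retained at >= 80% size, 1% MAF thresholds, FDR tiers at
    5/10/20/30%, days in milk restricted to [8, 340].
    """

    seed: int = 0
    # simulation
    n_ref: dict = field(default_factory=lambda: {INDICUS: 95, HF: 220, JERSEY: 176})
    n_cows: int = 500
    n_snp: int = 5000
    n_chrom: int = 2
    target_props: dict = field(default_factory=lambda: {INDICUS: .36, HF: .49, JERSEY: .15})
    n_generations: int = 4
    divergence: dict | None = None
    maf_skew: str = "array"
    ld_founders: int | None = 30
    qtls: list = field(default_factory=list)        # QtlSpec or dicts
    exclude_qtl_markers: bool = True
    h2: float = 0.18
    repeatability: float = 0.35
    herd_var_frac: float = 0.10
    n_td_per_cow: int = 6
    phen_sd: float = 2.0
    # adjustment
    adjust_vc: tuple | None = None
    # windows / ancestry
    W: int = 500
    min_fraction: float = 0.8
    K: int = 10
    tau: float = 0.01
    ridge: float = 1e-4
    # gwas
    models: tuple = ("1", "2", "3", "4")
    maf_threshold: float = 0.01
    fdr_levels: tuple = bogwas.FDR_LEVELS
    max_gap_bp: int = 2_000_000
    bc_bins: int = 3
    mean_yield: float = 7.22

    def qtl_specs(self) -> list[QtlSpec]:
        return [q if isinstance(q, QtlSpec) else QtlSpec(**q) for q in self.qtls]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["models"] = list(d["models"])
        d["fdr_levels"] = list(d["fdr_levels"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def fixture_config(seed: int = 0) -> PipelineConfig:
    """Small bundled fixture: 200 cows, 2,000 SNPs on 2 chromosomes."""
    return PipelineConfig(
        seed=seed, n_ref={INDICUS: 30, HF: 40, JERSEY: 30}, n_cows=200,
        n_snp=2000, n_chrom=2, W=200, K=6, n_td_per_cow=5,
        qtls=[{"kind": "BREED_ORIGIN", "chrom": 1, "pos_bp": 50_000_000,
               "alpha": 0.4, "favored_origin": INDICUS}])


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Deterministic per-stage random streams from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def subset_snps(panel: HaplotypePanel, idx: np.ndarray) -> HaplotypePanel:
    """Column subset of a panel with its map (marker filtering)."""
    idx = np.asarray(idx)
    sm = panel.snp_map
    new_map = SnpMap(sm.chrom[idx], sm.pos_bp[idx], sm.cm[idx])
    freqs = None
    if panel.pop_freqs is not None:
        freqs = {k: np.asarray(v)[..., idx] for k, v in panel.pop_freqs.items()}
    return HaplotypePanel(panel.hap_matrix[:, idx], list(panel.sample_ids),
                          panel.pop_labels, new_map, freqs)


def write_phased_vcf(panel: HaplotypePanel, path) -> None:
    """Phased VCF (GT with '|'), positions 1-based, genetic map in INFO/CM."""
    sm = panel.snp_map
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=boagwas\n")
        fh.write('##INFO=<ID=CM,Number=1,Type=Float,Description="Genetic position (cM)">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c, sl in sm.chromosome_slices().items():
            fh.write(f"##contig=<ID={c},length={int(sm.pos_bp[sl][-1]) + 1}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, panel.sample_ids)) + "\n")
        H = panel.hap_matrix
        for j in range(sm.n_snp):
            gts = "\t".join(f"{H[2 * i, j]}|{H[2 * i + 1, j]}"
                            for i in range(panel.n_samples))
            fh.write(f"{sm.chrom[j]}\t{sm.pos_bp[j]}\tsnp{j}\tA\tB\t.\tPASS\t"
                     f"CM={sm.cm[j]:.6f}\tGT\t{gts}\n")


def read_phased_vcf(path, pop_labels=None) -> HaplotypePanel:
    """Read a phased VCF written by this package (or any phased biallelic VCF)."""
    from cyvcf2 import VCF
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms, pos, cm, rows = [], [], [], []
    for var in vcf:
        chroms.append(var.CHROM)
        pos.append(var.POS)
        info_cm = var.INFO.get("CM")
        cm.append(float(info_cm) if info_cm is not None else var.POS / 1e6)
        g = np.array(var.genotypes)   # (n, 3): a, b, phased
        if not np.all(g[:, 2]):
            raise ValueError(f"unphased genotype at {var.CHROM}:{var.POS}")
        rows.append(g[:, :2].reshape(-1))
    hap = np.array(rows, dtype=np.int8).T
    try:
        chrom_arr = np.array([int(c) for c in chroms])
    except ValueError:
        chrom_arr = np.array(chroms)
    sm = SnpMap(chrom_arr, np.array(pos, dtype=np.int64), np.array(cm))
    if pop_labels is None:
        labels = np.array([CROSSBRED] * len(samples))
    elif isinstance(pop_labels, (str, Path)):
        tsv = pd.read_csv(pop_labels, sep="\t")
        labels = tsv.set_index("sample_id")["pop_label"].reindex(samples).to_numpy()
    else:
        labels = np.asarray(pop_labels)
    return HaplotypePanel(hap, samples, labels, sm)


def write_pop_tsv(panel: HaplotypePanel, path) -> None:
    pd.DataFrame({"sample_id": panel.sample_ids,
                  "pop_label": panel.pop_labels}).to_csv(path, sep="\t", index=False)


def write_phenotypes_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def read_phenotypes_csv(path) -> pd.DataFrame:
    rec = pd.read_csv(path)
    bad = rec[(rec["dim"] < DIM_MIN) | (rec["dim"] > DIM_MAX)]
    if len(bad):
        raise ValueError(
            f"{len(bad)} records outside the allowed days-in-milk range "
            f"[{DIM_MIN}, {DIM_MAX}] (first: dim={bad['dim'].iloc[0]} "
            f"for cow {bad['cow_id'].iloc[0]})")
    return rec


def write_windows_bed(partition: ancestry.WindowPartition, snp_map: SnpMap,
                      path) -> None:
    """Window spans as 0-based half-open BED-like records."""
    with open(path, "w") as fh:
        for w, (c, s, e) in enumerate(partition.windows):
            fh.write(f"{c}\t{int(snp_map.pos_bp[s]) - 1}\t{int(snp_map.pos_bp[e - 1])}"
                     f"\twin{w}\t{e - s}\n")


def write_tracks_tsv(track: ancestry.AncestryTrack, snp_map: SnpMap, path) -> None:
    rows = []
    for i, sid in enumerate(track.sample_ids):
        for hap in (0, 1):
            h = 2 * i + hap
            for w, (c, s, e) in enumerate(track.partition.windows):
                rows.append([sid, hap + 1, c, int(snp_map.pos_bp[s]) - 1,
                             int(snp_map.pos_bp[e - 1]), s, e,
                             track.origins[track.labels[h, w]],
                             *np.round(track.posteriors[h, w], 6)])
    cols = (["sample", "haplotype", "chrom", "start_bp", "end_bp",
             "snp_start", "snp_end", "label"]
            + [f"p_{o}" for o in track.origins])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_tracks_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_results_tsv(rows: pd.DataFrame, path) -> None:
    rows.to_csv(path, sep="\t", index=False)


def read_results_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def bc_env_covariates(bc: np.ndarray, env: np.ndarray, bc_bins: int = 3) -> np.ndarray:
    """Breed-composition x environment fixed covariates for the GWAS models.

    Breed composition (genome-wide indigenous proportion) is binned into
    `bc_bins` quantile classes crossed with the environment factor; the
    continuous composition is kept as an additional covariate so that
    residual genome-wide ancestry cannot masquerade as local breed-origin
    signal in a short simulated genome.
    """
    bc_class = pd.qcut(bc, bc_bins, labels=False, duplicates="drop")
    cells = pd.Series([f"{b}|{e}" for b, e in zip(bc_class, env)])
    dummies = pd.get_dummies(cells, drop_first=True).to_numpy(float)
    return np.column_stack([bc - bc.mean(), dummies])


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """simulate -> adjust -> ancestry -> origin coding -> GWAS -> reports.

    Writes phased VCFs, population and phenotype tables, ancestry tracks,
    per-model association results, lambda and region reports, and a manifest
    with the seed, per-stage wall times, counts and output hashes.  Returns
    the in-memory artifacts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng_freq, rng_ref, rng_founder, rng_cross, rng_qtl, rng_td = spawn_rngs(config.seed, 6)
    manifest = {"seed": config.seed, "stages": {}, "counts": {}, "files": {}}
    t0 = time.time()

    def stage_done(name):
        manifest["stages"][name] = round(time.time() - t0, 3)

    # --- simulate ---------------------------------------------------------
    snp_map, freqs = simcross.simulate_ancestral_frequencies(
        config.n_snp, config.n_chrom, config.divergence, config.maf_skew,
        seed=rng_freq)
    ref_panel = simcross.sample_panel(snp_map, freqs, config.n_ref, seed=rng_ref,
                                      ld_founders=config.ld_founders)
    founder_n = {o: max(40, n // 2) for o, n in config.n_ref.items()}
    founder_panel = simcross.sample_panel(snp_map, freqs, founder_n,
                                          seed=rng_founder,
                                          ld_founders=config.ld_founders)
    cross_panel, truth = simcross.simulate_crossbreds(
        founder_panel, config.n_cows, config.target_props,
        config.n_generations, seed=rng_cross)
    truth = simcross.plant_qtl(founder_panel, truth, config.qtl_specs(),
                               seed=rng_qtl)
    records = simcross.simulate_testday(
        truth, config.h2, config.repeatability, config.herd_var_frac,
        n_td_per_cow=config.n_td_per_cow, phen_sd=config.phen_sd,
        panel=cross_panel, seed=rng_td)

    # marker set: overall MAF filter, QTL columns hidden
    dos = cross_panel.dosage()
    maf = np.minimum(dos.mean(axis=0) / 2, 1 - dos.mean(axis=0) / 2)
    marker_mask = maf > config.maf_threshold
    if config.exclude_qtl_markers:
        for q in truth.qtls:
            marker_mask[q.snp_idx] = False
    marker_idx = np.flatnonzero(marker_mask)
    markers_cross = subset_snps(cross_panel, marker_idx)
    markers_ref = subset_snps(ref_panel, marker_idx)
    manifest["counts"]["n_snp_simulated"] = int(config.n_snp)
    manifest["counts"]["n_snp_markers"] = int(len(marker_idx))
    write_phased_vcf(markers_cross, outdir / "crossbred.vcf")
    write_phased_vcf(markers_ref, outdir / "reference.vcf")
    write_pop_tsv(markers_ref, outdir / "reference_pops.tsv")
    write_phenotypes_csv(records, outdir / "phenotypes.csv")
    stage_done("simulate")

    # --- adjust -----------------------------------------------------------
    fit = tdadjust.fit_adjustment(
        records, tdadjust.AdjustConfig(vc=config.adjust_vc, seed=config.seed))
    ystar = tdadjust.adjusted_phenotypes(fit, records)
    ystar.to_csv(outdir / "adjusted_phenotypes.tsv", sep="\t", index=False)
    stage_done("adjust")

    # --- ancestry ---------------------------------------------------------
    partition = ancestry.partition_windows(markers_cross.snp_map, config.W,
                                           config.min_fraction)
    model = ancestry.train_window_models(markers_ref, partition,
                                         origins=tuple(config.target_props),
                                         K=config.K, ridge=config.ridge)
    track = ancestry.infer_ancestry(model, markers_cross, tau=config.tau)
    write_windows_bed(partition, markers_cross.snp_map, outdir / "windows.bed")
    write_tracks_tsv(track, markers_cross.snp_map, outdir / "ancestry_tracks.tsv")
    manifest["counts"]["n_windows"] = partition.n_windows
    manifest["counts"]["n_snp_window_dropped"] = partition.n_dropped_snps
    stage_done("ancestry")

    # --- origin coding ----------------------------------------------------
    origins3 = origincode.assign_allele_origins(markers_cross, track)
    design2 = origincode.build_design(markers_cross,
                                      origincode.collapse_three_to_two(origins3),
                                      mode="two_way")
    design3 = origincode.build_design(markers_cross, origins3, mode="three_way")
    design2.origin_freq.to_csv(outdir / "origin_freq_two_way.tsv", sep="\t", index=False)
    design3.origin_freq.to_csv(outdir / "origin_freq_three_way.tsv", sep="\t", index=False)
    origincode.save_design(design2, outdir / "design_two_way.npz")
    origincode.save_design(design3, outdir / "design_three_way.npz")
    for name, d in (("two_way", design2), ("three_way", design3)):
        manifest["counts"][f"masked_{name}"] = {
            o: int((~m).sum()) for o, m in d.masks.items()}
    stage_done("origincode")

    # --- gwas -------------------------------------------------------------
    cow_order = ystar["cow_id"].to_numpy()
    idx_of = {sid: i for i, sid in enumerate(markers_cross.sample_ids)}
    order = np.array([idx_of[c] for c in cow_order])
    y = ystar["y_star"].to_numpy()
    herd_of = records.drop_duplicates("cow_id").set_index("cow_id")["herd_id"]
    herd_ids = herd_of.reindex(cow_order).to_numpy()

    content = ancestry.breed_content(track)[order]
    bc = content[:, list(track.origins).index(INDICUS)]
    env = records.drop_duplicates("cow_id").set_index("cow_id")["cdc"].reindex(cow_order)
    Xcov = bc_env_covariates(bc, env.to_numpy(), config.bc_bins)

    dosage = markers_cross.dosage()[order].astype(float)
    grm = bogwas.vanraden_grm(dosage)
    vc = bogwas.reml_null(y, Xcov, grm, herd_ids)
    manifest["counts"]["vc"] = {"var_a": vc.var_a, "var_h": vc.var_h,
                                "var_e": vc.var_e, "h2": vc.h2,
                                "converged": vc.converged}

    snp_meta = markers_cross.snp_map.to_frame()
    results, lambdas_all = {}, {}
    for model_id in config.models:
        design = design2 if model_id in ("1", "2") else design3
        d_ord = origincode.OriginDesign(
            design.mode, {k: v[order] for k, v in design.w.items()},
            design.snp_idx, design.origin_freq, design.masks)
        scan = bogwas.snp_scan(model_id, d_ord, y, Xcov, vc, grm,
                               herd_ids, snp_meta=snp_meta)
        rows, lambdas = bogwas.genomic_control(scan.rows)
        rows = bogwas.fdr_tiers(rows, config.fdr_levels)
        results[model_id] = rows
        lambdas_all[model_id] = lambdas
        write_results_tsv(rows, outdir / f"gwas_model{model_id}.tsv")
    pd.DataFrame([{"model": m, "effect_type": e, "lambda": v}
                  for m, d in lambdas_all.items() for e, v in d.items()]
                 ).to_csv(outdir / "lambda_report.tsv", sep="\t", index=False)
    regions = pd.concat(
        [bogwas.summarize_regions(r, max_gap_bp=config.max_gap_bp,
                                  mean_yield=config.mean_yield).assign(model=m)
         for m, r in results.items()], ignore_index=True)
    regions.to_csv(outdir / "regions_fdr5.tsv", sep="\t", index=False)
    stage_done("gwas")

    for f in sorted(outdir.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][f.name] = _sha256(f)
    manifest["lambda"] = lambdas_all
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    return {"config": config, "truth": truth, "records": records, "fit": fit,
            "ystar": ystar, "partition": partition, "track": track,
            "design2": design2, "design3": design3, "grm": grm, "vc": vc,
            "results": results, "lambdas": lambdas_all, "regions": regions,
            "manifest": manifest, "markers_cross": markers_cross,
            "markers_ref": markers_ref}
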