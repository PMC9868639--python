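"""Partitioned mixed-model association on breed-origin-coded alleles.

The phenotype is the per-cow mean adjusted test-day yield y*.  The null
model fits y* = Xb + a + h + e with a ~ N(0, G sigma_a^2) under a VanRaden
method-1 genomic relationship matrix and iid herd effects; association
scans hold the estimated covariance fixed across SNPs (one Cholesky reused,
EMMAX style) and fit, per SNP, generalized-least-squares effects of

  model 1: the raw genotype dosage (g)
  model 2: indigenous-origin count w1 (g1) plus within-indigenous w2 (g2)
           and within-exotic w3 (g3) allele dosages; variants 2a/2b drop the
           within-origin term whose origin-specific MAF is below 1%
  models 3/4: three-ancestor partition with HF/Jersey origin counts (g6/g7)
           and within-origin dosages g2/g4/g5, variants a/b analogous

Per-effect genomic control (observed over expected median chi-square) and
Benjamini-Hochberg FDR tiers at 5/10/20/30% follow, with region summaries
reporting the homozygote difference 2x|estimate|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as la
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .origincode import OriginDesign
from .simcross import INDICUS, HF, JERSEY, EXOTIC

CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))   # 0.4549364...
FDR_LEVELS = (0.05, 0.10, 0.20, 0.30)

# w-term fitting order per model; within-origin terms listed after the
# origin-count terms so collinearity drops them first (reverse scan)
_MODEL_TERMS = {
    "1": [("g", "raw")],
    "2": [("g1", "w1"), ("g3", "w3"), ("g2", "w2")],
    "3": [("g1", "w1"), ("g6", "w6"), ("g4", "w4"), ("g5", "w5"), ("g2", "w2")],
    "4": [("g1", "w1"), ("g7", "w7"), ("g4", "w4"), ("g5", "w5"), ("g2", "w2")],
}
_ORIGIN_TERMS = {"g", "g1", "g6", "g7"}
_MASK_OF = {"g2": INDICUS, "g3": EXOTIC, "g4": HF, "g5": JERSEY}


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------

@dataclass
class Grm:
    matrix: np.ndarray
    freqs: np.ndarray
    n_snp_used: int


def vanraden_grm(dosage: np.ndarray, freqs: np.ndarray | None = None) -> Grm:
    """VanRaden method-1 GRM: G = MM' / (2 sum p(1-p)), M = dosage - 2p.

    The cross-product is accumulated in the dosage's floating dtype (pass
    float32 for large panels to halve memory traffic); the returned matrix
    is float64.
    """
    dosage = np.asarray(dosage)
    if not np.issubdtype(dosage.dtype, np.floating):
        dosage = dosage.astype(np.float64)
    if dosage.min() < 0 or dosage.max() > 2:
        raise ValueError("dosages must lie in [0, 2]")
    if freqs is None:
        freqs = dosage.mean(axis=0, dtype=np.float64) / 2.0
    freqs = np.asarray(freqs, dtype=np.float64)
    poly = (freqs > 0) & (freqs < 1)
    if not poly.any():
        raise ValueError("all SNPs monomorphic; GRM undefined")
    M = dosage[:, poly] - 2 * freqs[poly].astype(dosage.dtype)
    denom = 2.0 * np.sum(freqs[poly] * (1 - freqs[poly]))
    G = (M @ M.T).astype(np.float64) / denom
    return Grm(G, freqs, int(poly.sum()))


def loco_grms(dosage: np.ndarray, chrom: np.ndarray,
              freqs: np.ndarray | None = None) -> dict:
    """Leave-one-chromosome-out GRMs, avoiding proximal contamination.

    Returns {chromosome: Grm built from all other chromosomes}.  Each GRM
    uses the VanRaden method-1 scaling restricted to the retained SNPs.
    """
    dosage = np.asarray(dosage, dtype=float)
    chrom = np.asarray(chrom)
    if freqs is None:
        freqs = dosage.mean(axis=0) / 2.0
    poly = (freqs > 0) & (freqs < 1)
    M = (dosage - 2 * freqs) * poly
    w = 2.0 * freqs * (1 - freqs) * poly
    full = M @ M.T
    s_full = w.sum()
    out = {}
    for c in pd.unique(chrom):
        on = chrom == c
        Mc = M[:, on]
        s_c = w[on].sum()
        out[c] = Grm((full - Mc @ Mc.T) / (s_full - s_c), freqs,
                     int(poly.sum() - (poly & on).sum()))
    return out


# ---------------------------------------------------------------------------
# null REML
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    var_a: float
    var_h: float
    var_e: float
    loglik: float
    converged: bool
    n_iter: int

    @property
    def h2(self) -> float:
        return self.var_a / (self.var_a + self.var_h + self.var_e)


def _herd_groups(herd_ids) -> list:
    herd_ids = np.asarray(herd_ids)
    return [np.flatnonzero(herd_ids == h) for h in pd.unique(herd_ids)]


def reml_null(y: np.ndarray, X: np.ndarray | None, grm: Grm | np.ndarray,
              herd_ids=None, max_iter: int = 60, tol: float = 1e-6,
              verbose: bool = False) -> VarianceComponents:
    """Average-information REML of the GRM + herd null model.

    X is the covariate matrix without intercept (one is added); herd_ids may
    be None for a model without herd effects.  Falls back to an EM step
    whenever the AI update leaves the parameter space or lowers the REML
    log-likelihood; converges on log-likelihood change < tol.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    G = grm.matrix if isinstance(grm, Grm) else np.asarray(grm, float)
    Xf = np.ones((n, 1)) if X is None else np.column_stack([np.ones(n), X])
    p = Xf.shape[1]
    if n < p + 2:
        raise ValueError("not enough records for the fixed effects")
    groups = _herd_groups(herd_ids) if herd_ids is not None else None

    vy = float(np.var(y))
    theta = np.array([0.3 * vy, 0.1 * vy if groups is not None else 0.0, 0.6 * vy])
    active = [0, 2] if groups is None else [0, 1, 2]
    floor = 1e-8 * vy

    def build_V(th):
        V = th[0] * G + th[2] * np.eye(n)
        if groups is not None and th[1] > 0:
            for g in groups:
                V[np.ix_(g, g)] += th[1]
        return V

    def quad_tr(th):
        V = build_V(th)
        cf = la.cho_factor(V, lower=True)
        Vinv = la.cho_solve(cf, np.eye(n))
        A = Vinv @ Xf                                   # V^-1 X
        XtVinvX = Xf.T @ A
        cfx = la.cho_factor(XtVinvX)
        logdet_V = 2 * np.log(np.diag(cf[0])).sum()
        logdet_X = np.linalg.slogdet(XtVinvX)[1]

        def Pv(v):
            u = Vinv @ v
            return u - A @ la.cho_solve(cfx, Xf.T @ u)

        Py = Pv(y)
        yPy = float(y @ Py)
        ll = -0.5 * (logdet_V + logdet_X + yPy)

        # tr(P Vi) for Vi in (G, ZZ', I)
        tr = np.empty(3)
        corr = la.cho_solve(cfx, (A.T @ G) @ A)
        tr[0] = np.sum(Vinv * G) - np.trace(corr)
        if groups is not None:
            s_vinv = sum(Vinv[np.ix_(g, g)].sum() for g in groups)
            ZtA = np.vstack([A[g].sum(axis=0) for g in groups])
            tr[1] = s_vinv - np.trace(la.cho_solve(cfx, ZtA.T @ ZtA))
        tr[2] = np.trace(Vinv) - np.trace(la.cho_solve(cfx, A.T @ A))

        def Vi_dot(i, v):
            if i == 0:
                return G @ v
            if i == 2:
                return v
            out = np.zeros_like(v)
            for g in groups:
                out[g] = v[g].sum()
            return out

        ViPy = [Vi_dot(i, Py) if i in active else None for i in range(3)]
        PViPy = [Pv(ViPy[i]) if i in active else None for i in range(3)]
        return ll, Py, tr, ViPy, PViPy

    # Levenberg-Marquardt-damped AI iteration with an active set at the
    # parameter floor.  Damping handles the near-singular AI matrix that
    # arises when components are weakly identified (e.g. G ~ I); convergence
    # requires a small log-likelihood change at an undamped step together
    # with a small scale-free gradient.
    def propose(th, score, AI, Py, ViPy, tr, lm):
        free = [i for i in active
                if not (th[i] <= 1.05 * floor and score[i] < 0)]
        idx = np.array(free if free else active)
        A = AI[np.ix_(idx, idx)].copy()
        A[np.diag_indices_from(A)] += lm * np.abs(np.diag(A)).mean()
        try:
            step = np.linalg.solve(A, score[idx])
            cand = th.copy()
            cand[idx] = np.maximum(th[idx] + step, floor)
            return cand
        except np.linalg.LinAlgError:
            cand = th.copy()
            for i in idx:
                qf = float(Py @ ViPy[i])
                cand[i] = max(th[i] + th[i] ** 2 * (qf - tr[i]) / n, floor)
            return cand

    state = None        # (theta, ll, score, AI, Py, ViPy, tr) last accepted
    lm = 0.0
    converged = False
    for it in range(1, max_iter + 1):
        ll, Py, tr, ViPy, PViPy = quad_tr(theta)
        if state is not None and ll < state[1] - 1e-10:
            # reject: re-propose from the last accepted point, more damping
            lm = max(10 * lm, 1e-3)
            theta = propose(state[0], state[2], state[3], state[4], state[5],
                            state[6], lm)
            continue
        score = np.array([
            -0.5 * (tr[i] - float(Py @ ViPy[i])) if i in active else 0.0
            for i in range(3)])
        AI = np.zeros((3, 3))
        for i in active:
            for j in active:
                if j >= i:
                    AI[i, j] = AI[j, i] = 0.5 * float(PViPy[i] @ ViPy[j])
        grad_small = all(abs(score[i]) * max(theta[i], floor) < 1e-4 * n
                         for i in active)
        if state is not None and abs(ll - state[1]) < tol \
                and (lm == 0.0 or grad_small):
            state = (theta.copy(), ll, score, AI, Py, ViPy, tr)
            converged = True
            break
        lm = lm / 5 if lm > 1e-8 else 0.0
        state = (theta.copy(), ll, score, AI, Py, ViPy, tr)
        if it == 1:
            # first step by EM for stability
            cand = theta.copy()
            for i in active:
                qf = float(Py @ ViPy[i])
                cand[i] = max(theta[i] + theta[i] ** 2 * (qf - tr[i]) / n, floor)
            theta = cand
        else:
            theta = propose(theta, score, AI, Py, ViPy, tr, lm)
    theta, ll = state[0], state[1]
    return VarianceComponents(float(theta[0]), float(theta[1]), float(theta[2]),
                              float(ll), converged, it)


# ---------------------------------------------------------------------------
# SNP scan
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    rows: pd.DataFrame
    model_id: str
    skipped: list = field(default_factory=list)   # (snp, effect, reason)
    lambdas: dict = field(default_factory=dict)


def _build_V(vc: VarianceComponents, G: np.ndarray, herd_ids) -> np.ndarray:
    n = G.shape[0]
    V = vc.var_a * G + vc.var_e * np.eye(n)
    if herd_ids is not None and vc.var_h > 0:
        for g in _herd_groups(herd_ids):
            V[np.ix_(g, g)] += vc.var_h
    return V


def snp_scan(model_id: str, design: OriginDesign, y: np.ndarray,
             X: np.ndarray | None, vc: VarianceComponents,
             grm: Grm | np.ndarray, herd_ids=None,
             snp_meta: pd.DataFrame | None = None,
             block: int = 2048) -> ScanResult:
    """GLS scan of one association model across all SNPs in the design.

    The covariance V implied by `vc` is fixed across SNPs (single Cholesky).
    Per SNP the model's w-terms are selected by the origin-MAF masks (model
    variants a/b), zero-variance terms are skipped, and linearly dependent
    terms are dropped within-origin-first.  Returns Wald statistics per
    fitted effect.
    """
    if model_id not in _MODEL_TERMS:
        raise ValueError(f"unknown model {model_id!r}")
    terms = _MODEL_TERMS[model_id]
    y = np.asarray(y, dtype=float)
    n = len(y)
    G = grm.matrix if isinstance(grm, Grm) else np.asarray(grm, float)
    V = _build_V(vc, G, herd_ids)
    L = la.cholesky(V, lower=True)
    Xf = np.ones((n, 1)) if X is None else np.column_stack([np.ones(n), X])
    Q = la.solve_triangular(L, Xf, lower=True)
    yt = la.solve_triangular(L, y, lower=True)
    QtQ, Qty, p = Q.T @ Q, Q.T @ yt, Q.shape[1]

    w_names = [w for _e, w in terms]
    if "raw" in w_names:
        raw = sum(design.w[k] for k in design.w if k in ("w2", "w3", "w4", "w5"))
        mats = {"raw": raw}
    else:
        mats = {}
    for wn in w_names:
        if wn != "raw":
            mats[wn] = design.w[wn]

    m = design.n_snp
    wty = {wn: np.empty(m) for wn in w_names}
    QtW = {wn: np.empty((p, m)) for wn in w_names}
    cross = {}
    for i, wi in enumerate(w_names):
        for wj in w_names[i:]:
            cross[_ck(wi, wj)] = np.empty(m)
    for s in range(0, m, block):
        e = min(s + block, m)
        wt = {}
        for wn in w_names:
            Wt = la.solve_triangular(L, mats[wn][:, s:e].astype(float), lower=True)
            wt[wn] = Wt
            wty[wn][s:e] = Wt.T @ yt
            QtW[wn][:, s:e] = Q.T @ Wt
        for i, wi in enumerate(w_names):
            for wj in w_names[i:]:
                cross[_ck(wi, wj)][s:e] = np.einsum("ij,ij->j", wt[wi], wt[wj])

    meta = snp_meta
    out = {k: [] for k in ("snp", "chrom", "pos_bp", "effect_type",
                           "estimate", "se", "chi2", "p", "variant")}
    skipped = []
    masks = design.masks

    QtQ_inv = np.linalg.inv(QtQ)
    for j in range(m):
        fit_terms, variant_flags = [], []
        for eff, wn in terms:
            if eff in _MASK_OF:   # within-origin effect: needs MAF>1% in its origin
                o = _MASK_OF[eff]
                if o in masks and not masks[o][j]:
                    variant_flags.append(eff)
                    continue
            u = QtW[wn][:, j]
            ww = cross[_ck(wn, wn)][j]
            var_w = ww - u @ QtQ_inv @ u   # residual variance after covariates
            if ww <= 0 or var_w <= 1e-10 * max(ww, 1.0):
                skipped.append((j, eff, "zero-variance"))
                continue
            fit_terms.append((eff, wn))
        if not fit_terms:
            continue
        while fit_terms:
            d = p + len(fit_terms)
            C = np.empty((d, d))
            rhs = np.empty(d)
            C[:p, :p] = QtQ
            rhs[:p] = Qty
            for a_i, (_e, wa) in enumerate(fit_terms):
                C[:p, p + a_i] = QtW[wa][:, j]
                C[p + a_i, :p] = QtW[wa][:, j]
                rhs[p + a_i] = wty[wa][j]
                for b_i, (_e2, wb) in enumerate(fit_terms):
                    C[p + a_i, p + b_i] = cross[_ck(wa, wb)][j]
            try:
                cf = la.cho_factor(C)
                Cinv = la.cho_solve(cf, np.eye(d))
                break
            except np.linalg.LinAlgError:
                # drop the last-listed (within-origin before origin) term
                dropped = fit_terms.pop()
                skipped.append((j, dropped[0], "collinear"))
        else:
            continue
        coef = Cinv @ rhs
        se = np.sqrt(np.maximum(np.diag(Cinv), 0.0))
        for a_i, (eff, _w) in enumerate(fit_terms):
            est, s_e = coef[p + a_i], se[p + a_i]
            if s_e <= 0:
                skipped.append((j, eff, "degenerate-se"))
                continue
            chi2 = (est / s_e) ** 2
            out["snp"].append(design.snp_idx[j])
            out["chrom"].append(meta["chrom"].iloc[j] if meta is not None else 0)
            out["pos_bp"].append(meta["pos_bp"].iloc[j] if meta is not None else 0)
            out["effect_type"].append(eff)
            out["estimate"].append(est)
            out["se"].append(s_e)
            out["chi2"].append(chi2)
            out["p"].append(stats.chi2.sf(chi2, 1))
            out["variant"].append(model_id + ("" if not variant_flags else
                                              "-" + ",".join(variant_flags)))
    rows = pd.DataFrame(out)
    return ScanResult(rows, model_id, skipped)


def _ck(a: str, b: str) -> tuple:
    """Canonical (sorted) key into the whitened cross-product cache."""
    return (a, b) if a <= b else (b, a)


def snp_scan_exact(model_id: str, design: OriginDesign, y: np.ndarray,
                   X: np.ndarray | None, grm: Grm | np.ndarray, herd_ids=None,
                   snps: np.ndarray | None = None,
                   snp_meta: pd.DataFrame | None = None,
                   reml_kwargs: dict | None = None) -> ScanResult:
    """Per-SNP exact REML scan: the variance components are re-estimated
    for every tested SNP with its w-terms in the fixed part, instead of
    reusing one null fit.  Orders of magnitude slower than `snp_scan`;
    meant for spot checks on a handful of SNPs (`snps` selects design
    columns, default all).
    """
    terms = _MODEL_TERMS[model_id]
    y = np.asarray(y, dtype=float)
    n = len(y)
    G = grm.matrix if isinstance(grm, Grm) else np.asarray(grm, float)
    Xf = np.empty((n, 0)) if X is None else np.asarray(X, float)
    cols = np.arange(design.n_snp) if snps is None else np.asarray(snps)
    out = {k: [] for k in ("snp", "chrom", "pos_bp", "effect_type",
                           "estimate", "se", "chi2", "p", "variant")}
    skipped = []
    for j in cols:
        fit_terms = []
        for eff, wn in terms:
            if eff in _MASK_OF and _MASK_OF[eff] in design.masks \
                    and not design.masks[_MASK_OF[eff]][j]:
                continue
            w = design.w[wn][:, j].astype(float) if wn != "raw" else \
                sum(design.w[k][:, j] for k in design.w
                    if k in ("w2", "w3", "w4", "w5")).astype(float)
            if w.std() <= 1e-12:
                skipped.append((j, eff, "zero-variance"))
                continue
            fit_terms.append((eff, w))
        if not fit_terms:
            continue
        Xj = np.column_stack([Xf] + [w for _e, w in fit_terms])
        vc = reml_null(y, Xj, G, herd_ids, **(reml_kwargs or {}))
        V = _build_V(vc, G, herd_ids)
        L = la.cholesky(V, lower=True)
        D = la.solve_triangular(
            L, np.column_stack([np.ones(n), Xj]), lower=True)
        yt = la.solve_triangular(L, y, lower=True)
        C = D.T @ D
        Cinv = np.linalg.inv(C)
        coef = Cinv @ (D.T @ yt)
        se = np.sqrt(np.maximum(np.diag(Cinv), 0.0))
        base = 1 + Xf.shape[1]
        for a_i, (eff, _w) in enumerate(fit_terms):
            est, s_e = coef[base + a_i], se[base + a_i]
            chi2 = (est / s_e) ** 2
            out["snp"].append(design.snp_idx[j])
            out["chrom"].append(snp_meta["chrom"].iloc[j] if snp_meta is not None else 0)
            out["pos_bp"].append(snp_meta["pos_bp"].iloc[j] if snp_meta is not None else 0)
            out["effect_type"].append(eff)
            out["estimate"].append(est)
            out["se"].append(s_e)
            out["chi2"].append(chi2)
            out["p"].append(stats.chi2.sf(chi2, 1))
            out["variant"].append(model_id + "-exact")
    return ScanResult(pd.DataFrame(out), model_id, skipped)


def snp_scan_by_chromosome(model_id: str, design: OriginDesign, y, X,
                           vc: VarianceComponents, dosage: np.ndarray,
                           marker_chrom: np.ndarray, design_chrom: np.ndarray,
                           herd_ids=None,
                           snp_meta: pd.DataFrame | None = None) -> ScanResult:
    """LOCO scan: per chromosome, exclude its markers from the GRM."""
    grms = loco_grms(dosage, marker_chrom)
    all_rows, skipped = [], []
    for c, grm in grms.items():
        cols = np.flatnonzero(design_chrom == c)
        if not len(cols):
            continue
        sub = design.subset(cols)
        meta = snp_meta.iloc[cols].reset_index(drop=True) if snp_meta is not None else None
        res = snp_scan(model_id, sub, y, X, vc, grm, herd_ids, snp_meta=meta)
        all_rows.append(res.rows)
        skipped.extend(res.skipped)
    rows = pd.concat(all_rows, ignore_index=True) if all_rows else pd.DataFrame()
    return ScanResult(rows, model_id, skipped)


# ---------------------------------------------------------------------------
# inference adjustments
# ---------------------------------------------------------------------------

def genomic_control(rows: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-effect genomic control: lambda = median(chi2) / 0.4549.

    Chi-square statistics are divided by lambda (also when lambda < 1) and
    p_gc recomputed on 1 df.
    """
    rows = rows.copy()
    lambdas = {}
    rows["p_gc"] = np.nan
    for eff, grp in rows.groupby("effect_type"):
        chi2 = grp["chi2"].to_numpy()
        lam = float(np.median(chi2) / CHI2_MEDIAN_1DF)
        lambdas[eff] = lam
        rows.loc[grp.index, "p_gc"] = stats.chi2.sf(chi2 / lam, 1)
    return rows, lambdas


def fdr_tiers(rows: pd.DataFrame, levels=FDR_LEVELS,
              p_col: str = "p_gc") -> pd.DataFrame:
    """Benjamini-Hochberg q-values and FDR tier, separately per effect type."""
    rows = rows.copy()
    rows["q"] = np.nan
    levels = sorted(levels)
    for _eff, grp in rows.groupby("effect_type"):
        q = multipletests(grp[p_col].to_numpy(), method="fdr_bh")[1]
        rows.loc[grp.index, "q"] = q
    tier = np.full(len(rows), "NS", dtype=object)
    for lev in reversed(levels):
        tier[rows["q"].to_numpy() <= lev] = f"FDR{int(round(lev * 100))}"
    rows["tier"] = tier
    return rows


_FAVOR = {"g1": (INDICUS, EXOTIC), "g6": (JERSEY, HF), "g7": (HF, JERSEY)}


def summarize_regions(rows: pd.DataFrame, level: float = 0.05,
                      max_gap_bp: int = 2_000_000,
                      mean_yield: float = 7.22) -> pd.DataFrame:
    """Merge significant SNPs into regions and report homozygote differences.

    SNPs with q <= level are merged when within `max_gap_bp` of the previous
    significant SNP (per chromosome and effect).  The homozygote difference
    is 2x|estimate| per SNP; the favored origin is the one whose extra copy
    increases yield.
    """
    sig = rows[rows["q"] <= level]
    recs = []
    for (eff, chrom), grp in sig.groupby(["effect_type", "chrom"]):
        grp = grp.sort_values("pos_bp")
        pos = grp["pos_bp"].to_numpy()
        splits = np.flatnonzero(np.diff(pos) > max_gap_bp)
        bounds = np.concatenate([[0], splits + 1, [len(grp)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            sub = grp.iloc[a:b]
            hom = 2 * np.abs(sub["estimate"].to_numpy())
            mean_est = sub["estimate"].mean()
            fav = ""
            if eff in _FAVOR:
                fav = _FAVOR[eff][0] if mean_est > 0 else _FAVOR[eff][1]
            recs.append({
                "chrom": chrom, "start_mbp": pos[a] / 1e6,
                "end_mbp": pos[b - 1] / 1e6,
                "n_snp": b - a, "effect_type": eff,
                "hom_diff_mean": float(hom.mean()),
                "hom_diff_sd": float(hom.std()),
                "favored_origin": fav,
                "pct_mean_yield": float(hom.mean() / mean_yield * 100.0),
            })
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# power arithmetic
# ---------------------------------------------------------------------------

def rel_power(m: float) -> float:
    """Power of a QTL test relative to its maximum, m(1-m)/0.25."""
    if not 0 < m < 1:
        raise ValueError("allele frequency must lie strictly in (0, 1)")
    return m * (1.0 - m) / 0.25


def equivalent_n(ancestry_proportion: float, n_crossbred: int,
                 round_to: int = 50) -> int:
    """Purebred sample size with power equal to the crossbred within-origin scan."""
    if not 0 < ancestry_proportion <= 1:
        raise ValueError("ancestry proportion must lie in (0, 1]")
    if n_crossbred <= 0:
        raise ValueError("n_crossbred must be positive")
    x = ancestry_proportion * n_crossbred
    return int(round(x / round_to) * round_to) if round_to else int(round(x))
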