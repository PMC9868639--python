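"""Adjustment of test-day milk records under a repeatability model.

Monthly test-day (TD) yields are corrected for fixed effects — parity,
management centre (CDC), year-month, CDC x year-month, and third-order
Legendre lactation curves nested within parity and within CDC — with random
animal and herd effects under a repeatability model.  The per-cow average of
the adjusted records (animal + herd + residual solutions, equivalently the
cow mean of yield minus the fitted fixed part) is the phenotype y* used by
every downstream association model.

Variance components are estimated by EM-REML on the mixed-model equations;
for populations too large for dense MME inversion the components are
estimated on a herd-stratified subsample and the full solutions obtained by
one sparse solve at those components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .simcross import DIM_MIN, DIM_MAX, _legendre_values


def legendre_basis(dim):
    """Legendre values (P0..P3) at days-in-milk mapped to [-1, 1].

    x = 2*(dim-8)/(340-8) - 1; P2 = (3x^2-1)/2, P3 = (5x^3-3x)/2.
    Accepts scalars or arrays; raises for dim outside [8, 340].
    """
    arr = np.asarray(dim, dtype=float)
    if np.any((arr < DIM_MIN) | (arr > DIM_MAX)):
        raise ValueError(f"days in milk must lie in [{DIM_MIN}, {DIM_MAX}]")
    vals = _legendre_values(arr)
    return vals if arr.ndim else vals.reshape(4)


def validate_records(records: pd.DataFrame, min_records: int = 4) -> pd.DataFrame:
    """Check dim bounds and drop cows with fewer than `min_records` records."""
    required = {"cow_id", "herd_id", "parity", "cdc", "year_month", "dim", "yield"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    bad = records[(records["dim"] < DIM_MIN) | (records["dim"] > DIM_MAX)]
    if len(bad):
        raise ValueError(
            f"{len(bad)} records with days in milk outside [{DIM_MIN}, {DIM_MAX}] "
            f"(first offending dim={bad['dim'].iloc[0]})")
    counts = records.groupby("cow_id")["yield"].size()
    keep = counts.index[counts >= min_records]
    return records[records["cow_id"].isin(keep)].reset_index(drop=True)


@dataclass
class AdjustConfig:
    min_cell: int = 3              # CDC x year-month cells below this merge to margin
    min_records: int = 4
    max_iter: int = 200
    tol: float = 1e-5              # relative VC change
    vc: tuple | None = None        # (var_animal, var_herd, var_e) -> skip REML
    max_dense_dim: int = 3500      # above this, estimate VC on a subsample
    subsample_cows: int = 1200
    seed: int = 0
    rank_tol: float = 1e-8


@dataclass
class _DesignInfo:
    """Factor levels and kept columns, so X can be rebuilt for new records."""

    parity_levels: list
    cdc_levels: list
    ym_levels: list
    interaction_cells: list
    kept_columns: list | None = None
    dropped_columns: list = field(default_factory=list)


def _raw_design(records: pd.DataFrame, info: _DesignInfo) -> tuple[np.ndarray, list]:
    n = len(records)
    cols, names = [np.ones(n)], ["mu"]
    lp = legendre_basis(records["dim"].to_numpy())[:, 1:]

    def dummies(values, levels, label, drop_first=True):
        for lev in (levels[1:] if drop_first else levels):
            cols.append((values == lev).astype(float))
            names.append(f"{label}[{lev}]")

    parity = records["parity"].to_numpy()
    cdc = records["cdc"].to_numpy()
    ym = records["year_month"].to_numpy()
    dummies(parity, info.parity_levels, "parity")
    dummies(cdc, info.cdc_levels, "cdc")
    dummies(ym, info.ym_levels, "year_month")
    for c, y in info.interaction_cells:
        cols.append(((cdc == c) & (ym == y)).astype(float))
        names.append(f"cdc:ym[{c},{y}]")
    for lev in info.parity_levels:
        mask = (parity == lev).astype(float)
        for k in range(3):
            cols.append(mask * lp[:, k])
            names.append(f"parity[{lev}]:P{k + 1}")
    for lev in info.cdc_levels:
        mask = (cdc == lev).astype(float)
        for k in range(3):
            cols.append(mask * lp[:, k])
            names.append(f"cdc[{lev}]:P{k + 1}")
    return np.column_stack(cols), names


def build_fixed_design(records: pd.DataFrame, min_cell: int = 3,
                       info: _DesignInfo | None = None,
                       rank_tol: float = 1e-8) -> tuple[np.ndarray, _DesignInfo]:
    """Full-rank fixed-effect design (first level of each factor as reference).

    CDC x year-month interaction cells with fewer than `min_cell` records are
    merged into the margins (their column is not fitted).  Aliased columns
    are detected by pivoted QR and dropped, recorded in the design info.
    """
    if info is None:
        cells = (records.groupby(["cdc", "year_month"]).size()
                 .loc[lambda s: s >= min_cell].index.tolist())
        info = _DesignInfo(
            parity_levels=sorted(records["parity"].unique()),
            cdc_levels=sorted(records["cdc"].unique()),
            ym_levels=sorted(records["year_month"].unique()),
            interaction_cells=cells,
        )
        X, names = _raw_design(records, info)
        from scipy.linalg import qr
        _, r, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        rank = int((diag > rank_tol * diag[0]).sum())
        keep = np.sort(piv[:rank])
        info.dropped_columns = [names[j] for j in piv[rank:]]
        info.kept_columns = [names[j] for j in keep]
        return X[:, keep], info
    X, names = _raw_design(records, info)
    idx = [names.index(c) for c in info.kept_columns]
    return X[:, idx], info


@dataclass
class AdjustmentFit:
    beta: pd.Series
    animal: pd.Series
    herd: pd.Series
    vc: dict                        # var_animal, var_herd, var_e
    loglik: float
    converged: bool
    n_iter: int
    design_info: _DesignInfo
    min_cell: int

    @property
    def phenotypic_variance(self) -> float:
        return self.vc["var_animal"] + self.vc["var_herd"] + self.vc["var_e"]

    def fixed_part(self, records: pd.DataFrame) -> np.ndarray:
        X, _ = build_fixed_design(records, self.min_cell, self.design_info)
        return X @ self.beta.to_numpy()


def _indicator(codes: np.ndarray, n_levels: int) -> sp.csr_matrix:
    n = len(codes)
    return sp.csr_matrix((np.ones(n), (np.arange(n), codes)), shape=(n, n_levels))


def _em_reml(y, X, Za, Zh, max_iter, tol, start=None):
    """EM-REML for y = Xb + Za a + Zh h + e with iid a, h.

    Returns (var_a, var_h, var_e), solutions (beta, a, h), REML log-likelihood,
    convergence flag, iterations.
    """
    n, p = X.shape
    qa, qh = Za.shape[1], Zh.shape[1]
    Z = sp.hstack([Za, Zh]).tocsr()
    XtX = X.T @ X
    XtZ = X.T @ Z
    ZtZ = (Z.T @ Z).toarray()
    Xty = X.T @ y
    Zty = Z.T @ y
    yty = float(y @ y)
    var_y = float(np.var(y))
    va, vh, ve = start if start is not None else (0.2 * var_y, 0.1 * var_y, 0.7 * var_y)
    ll = -np.inf
    converged = False
    for it in range(1, max_iter + 1):
        kd = np.concatenate([np.full(qa, ve / va), np.full(qh, ve / vh)])
        C = np.block([[XtX, XtZ], [XtZ.T, ZtZ + np.diag(kd)]])
        rhs = np.concatenate([Xty, Zty])
        cf = np.linalg.cholesky(C)
        sol = np.linalg.solve(C, rhs)
        Cinv = np.linalg.inv(C)
        a_hat = sol[p: p + qa]
        h_hat = sol[p + qa:]
        tr_aa = np.trace(Cinv[p: p + qa, p: p + qa])
        tr_hh = np.trace(Cinv[p + qa:, p + qa:])
        ve_new = (yty - sol @ rhs) / (n - p)
        va_new = (a_hat @ a_hat + ve * tr_aa) / qa
        vh_new = (h_hat @ h_hat + ve * tr_hh) / qh
        logdet_c = 2.0 * np.log(np.diag(cf)).sum()
        ll = -0.5 * ((n - qa - qh - p) * np.log(ve) + qa * np.log(va)
                     + qh * np.log(vh) + logdet_c + (yty - sol @ rhs) / ve)
        rel = max(abs(va_new - va) / max(va, 1e-12),
                  abs(vh_new - vh) / max(vh, 1e-12),
                  abs(ve_new - ve) / max(ve, 1e-12))
        va, vh, ve = max(va_new, 1e-10 * var_y), max(vh_new, 1e-10 * var_y), ve_new
        if rel < tol:
            converged = True
            break
    beta, a_hat, h_hat = _solve_mme(y, X, Za, Zh, va, vh, ve)
    return (va, vh, ve), (beta, a_hat, h_hat), ll, converged, it


def _solve_mme(y, X, Za, Zh, va, vh, ve):
    """One (sparse) solve of the mixed-model equations at fixed components."""
    p = X.shape[1]
    qa, qh = Za.shape[1], Zh.shape[1]
    Z = sp.hstack([Za, Zh]).tocsc()
    Xs = sp.csc_matrix(X)
    W = sp.hstack([Xs, Z]).tocsc()
    kd = np.concatenate([np.zeros(p), np.full(qa, ve / va), np.full(qh, ve / vh)])
    C = (W.T @ W + sp.diags(kd)).tocsc()
    rhs = W.T @ y
    sol = spla.spsolve(C, rhs)
    return sol[:p], sol[p: p + qa], sol[p + qa:]


def fit_adjustment(records: pd.DataFrame, config: AdjustConfig | None = None) -> AdjustmentFit:
    """Fit the repeatability adjustment model and return solutions.

    Raises on singular fixed-effect structure only implicitly: aliased
    columns are dropped by pivoted QR and reported in
    ``fit.design_info.dropped_columns``.
    """
    config = config or AdjustConfig()
    records = validate_records(records, config.min_records)
    X, info = build_fixed_design(records, config.min_cell, rank_tol=config.rank_tol)
    y = records["yield"].to_numpy(dtype=float)

    cows = pd.Categorical(records["cow_id"])
    herds = pd.Categorical(records["herd_id"])
    Za = _indicator(cows.codes, len(cows.categories))
    Zh = _indicator(herds.codes, len(herds.categories))
    dim_total = X.shape[1] + Za.shape[1] + Zh.shape[1]

    if config.vc is not None:
        va, vh, ve = config.vc
        beta, a_hat, h_hat = _solve_mme(y, X, Za, Zh, va, vh, ve)
        ll, converged, n_iter = np.nan, True, 0
    elif dim_total <= config.max_dense_dim:
        (va, vh, ve), (beta, a_hat, h_hat), ll, converged, n_iter = _em_reml(
            y, X, Za, Zh, config.max_iter, config.tol)
    else:
        # herd-stratified subsample for the variance components, then one
        # sparse solve on the full data
        rng = np.random.default_rng(config.seed)
        herd_ids = herds.categories.to_numpy()
        rng.shuffle(herd_ids := herd_ids.copy())
        cows_per_herd = records.groupby("herd_id")["cow_id"].nunique()
        take, total = [], 0
        for hid in herd_ids:
            take.append(hid)
            total += int(cows_per_herd[hid])
            if total >= config.subsample_cows:
                break
        sub = records[records["herd_id"].isin(take)].reset_index(drop=True)
        Xs, _ = build_fixed_design(sub, config.min_cell, info)
        cs = pd.Categorical(sub["cow_id"])
        hs = pd.Categorical(sub["herd_id"])
        (va, vh, ve), _, ll, converged, n_iter = _em_reml(
            sub["yield"].to_numpy(float), Xs,
            _indicator(cs.codes, len(cs.categories)),
            _indicator(hs.codes, len(hs.categories)),
            config.max_iter, config.tol)
        beta, a_hat, h_hat = _solve_mme(y, X, Za, Zh, va, vh, ve)

    return AdjustmentFit(
        beta=pd.Series(beta, index=info.kept_columns),
        animal=pd.Series(a_hat, index=cows.categories),
        herd=pd.Series(h_hat, index=herds.categories),
        vc={"var_animal": float(va), "var_herd": float(vh), "var_e": float(ve)},
        loglik=float(ll), converged=bool(converged), n_iter=int(n_iter),
        design_info=info, min_cell=config.min_cell)


def adjusted_phenotypes(fit: AdjustmentFit, records: pd.DataFrame) -> pd.DataFrame:
    """Per-cow mean adjusted TD yield y* (animal + herd + residual solutions).

    Because residuals satisfy e = y - Xb - a - h record-wise, y* equals the
    cow mean of (y - fitted fixed part); record order is irrelevant.
    """
    unknown = set(records["cow_id"]) - set(fit.animal.index)
    if unknown:
        raise KeyError(f"cows present in records but absent from fit: "
                       f"{sorted(unknown)[:5]}{'...' if len(unknown) > 5 else ''}")
    adj = records["yield"].to_numpy(float) - fit.fixed_part(records)
    out = (pd.DataFrame({"cow_id": records["cow_id"], "adj": adj})
           .groupby("cow_id", sort=True)["adj"].agg(["mean", "size"])
           .reset_index())
    out.columns = ["cow_id", "y_star", "n_records"]
    return out
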