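"""Window-based local ancestry inference for admixed haplotypes.

SNPs are partitioned into fixed-size windows per chromosome; within each
window a PCA is trained on pooled reference haplotypes and each origin is
summarised by a Gaussian (diagonal covariance) in PC space.  Crossbred
haplotypes are decoded with a hidden Markov model over windows (constant
switch probability per boundary) by the forward-backward algorithm, giving
per-window posterior origin probabilities and hard labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .simcross import HaplotypePanel, SnpMap, REF_PREFIX

LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

@dataclass
class WindowPartition:
    """Ordered, non-overlapping half-open SNP-index windows per chromosome.

    The trailing window of a chromosome is kept only if it holds at least
    ceil(min_fraction * W) SNPs.
    """

    windows: list                  # (chrom, start, end) half-open global SNP idx
    W: int
    min_fraction: float
    n_dropped_snps: int = 0

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def snp_to_window(self, n_snp: int) -> np.ndarray:
        """Per-SNP window index, -1 for SNPs in no retained window."""
        out = np.full(n_snp, -1, dtype=np.int32)
        for w, (_c, s, e) in enumerate(self.windows):
            out[s:e] = w
        return out

    def chrom_window_ranges(self) -> list:
        """Contiguous [first, last) window-index runs per chromosome."""
        runs, start = [], 0
        for i in range(1, len(self.windows) + 1):
            if i == len(self.windows) or self.windows[i][0] != self.windows[start][0]:
                runs.append((self.windows[start][0], start, i))
                start = i
        return runs


def partition_windows(snp_map: SnpMap, W: int = 500,
                      min_fraction: float = 0.8) -> WindowPartition:
    if W < 1:
        raise ValueError("window size W must be >= 1")
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must lie in [0, 1]")
    min_keep = max(1, math.ceil(min_fraction * W))
    windows, dropped = [], 0
    for chrom, sl in snp_map.chromosome_slices().items():
        lo, hi = sl.start, sl.stop
        for s in range(lo, hi, W):
            e = min(s + W, hi)
            if e - s >= min_keep:
                windows.append((chrom, s, e))
            else:
                dropped += e - s
    return WindowPartition(windows, W, min_fraction, dropped)


# ---------------------------------------------------------------------------
# per-window PCA classifier
# ---------------------------------------------------------------------------

@dataclass
class _WindowModel:
    mean: np.ndarray          # (m_w,)
    components: np.ndarray    # (K, m_w) orthonormal rows
    class_means: np.ndarray   # (n_origins, K)
    class_vars: np.ndarray    # (n_origins, K), floored at ridge

    def project(self, haps: np.ndarray) -> np.ndarray:
        return (haps - self.mean) @ self.components.T


@dataclass
class AncestryModel:
    origins: tuple
    partition: WindowPartition
    K: int
    ridge: float
    window_models: list = field(default_factory=list)


def train_window_models(ref_panel: HaplotypePanel, partition: WindowPartition,
                        origins: tuple = None, K: int = 10,
                        ridge: float = 1e-4) -> AncestryModel:
    """Fit the per-window PCA + per-origin Gaussian summaries.

    PCA is fitted on reference haplotypes pooled over origins; class means
    and diagonal variances come from the projected haplotypes of each origin,
    variances floored at `ridge`.
    """
    if origins is None:
        origins = tuple(sorted({p.removeprefix(REF_PREFIX)
                                for p in np.unique(ref_panel.pop_labels)
                                if p.startswith(REF_PREFIX)}))
    rows = {}
    for o in origins:
        r = ref_panel.hap_rows_of(REF_PREFIX + o)
        if len(r) < 2:
            raise ValueError(f"origin {o} needs >= 2 reference haplotypes")
        rows[o] = r
    pooled = np.concatenate([rows[o] for o in origins])
    model = AncestryModel(origins, partition, K, ridge)
    H = ref_panel.hap_matrix
    for (_c, s, e) in partition.windows:
        block = H[pooled, s:e].astype(float)
        mean = block.mean(axis=0)
        centered = block - mean
        _u, sv, vt = np.linalg.svd(centered, full_matrices=False)
        k_eff = min(K, (sv > 1e-9 * max(sv[0], 1e-30)).sum())
        k_eff = max(k_eff, 1)
        comps = vt[:k_eff]
        cms, cvs = [], []
        for o in origins:
            z = (H[rows[o], s:e] - mean) @ comps.T
            cms.append(z.mean(axis=0))
            cvs.append(np.maximum(z.var(axis=0), ridge))
        model.window_models.append(
            _WindowModel(mean, comps, np.array(cms), np.array(cvs)))
    return model


def window_loglik(model: AncestryModel, haplotypes: np.ndarray,
                  window_idx: int) -> np.ndarray:
    """Per-origin Gaussian log-density of haplotype PC projections.

    haplotypes: (H, m_w) alleles over exactly the window's SNPs (or the full
    SNP axis, from which the window is sliced).  Returns (H, n_origins).
    """
    wm = model.window_models[window_idx]
    _c, s, e = model.partition.windows[window_idx]
    if haplotypes.shape[-1] != e - s:
        haplotypes = haplotypes[..., s:e]
    z = wm.project(np.atleast_2d(haplotypes).astype(float))   # (H, K)
    d = z[:, None, :] - wm.class_means[None, :, :]            # (H, O, K)
    ll = -0.5 * ((d * d / wm.class_vars[None]).sum(-1)
                 + np.log(wm.class_vars).sum(-1)[None]
                 + wm.class_vars.shape[1] * LOG2PI)
    return ll


# ---------------------------------------------------------------------------
# HMM decoding
# ---------------------------------------------------------------------------

@dataclass
class AncestryTrack:
    """Posterior origin probabilities and hard labels per haplotype x window."""

    sample_ids: list
    origins: tuple
    partition: WindowPartition
    posteriors: np.ndarray      # (2*n_samples, n_windows, n_origins)
    labels: np.ndarray          # (2*n_samples, n_windows) origin index
    tau: float

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def _logsumexp(a: np.ndarray, axis: int = -1) -> np.ndarray:
    mx = a.max(axis=axis, keepdims=True)
    return (mx + np.log(np.exp(a - mx).sum(axis=axis, keepdims=True))).squeeze(axis)


def forward_backward(emissions: np.ndarray, log_trans: np.ndarray,
                     log_prior: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior marginals and data log-likelihood of a chain of windows.

    emissions: (..., T, K) log-densities; log_trans: (K, K) or (T-1, K, K)
    for boundary-specific transitions; log_prior: (K,).  Vectorised over
    leading axes.
    """
    T = emissions.shape[-2]
    per_boundary = log_trans.ndim == 3
    alpha = np.empty_like(emissions)
    beta = np.empty_like(emissions)
    alpha[..., 0, :] = log_prior + emissions[..., 0, :]
    for t in range(1, T):
        lt = log_trans[t - 1] if per_boundary else log_trans
        prev = alpha[..., t - 1, :, None] + lt[None, :, :]
        alpha[..., t, :] = _logsumexp(prev, axis=-2) + emissions[..., t, :]
    beta[..., T - 1, :] = 0.0
    for t in range(T - 2, -1, -1):
        lt = log_trans[t] if per_boundary else log_trans
        nxt = beta[..., t + 1, None, :] + emissions[..., t + 1, None, :] + lt[None, :, :]
        beta[..., t, :] = _logsumexp(nxt, axis=-1)
    loglik = _logsumexp(alpha[..., T - 1, :], axis=-1)
    gamma = alpha + beta - loglik[..., None, None]
    return np.exp(gamma), loglik


def _switch_matrix(p_switch: float, K: int) -> np.ndarray:
    with np.errstate(divide="ignore"):
        lt = np.full((K, K),
                     np.log(p_switch / (K - 1)) if p_switch > 0 else -np.inf)
        np.fill_diagonal(lt, np.log1p(-p_switch))
    return lt


def infer_ancestry(model: AncestryModel, crossbred_panel: HaplotypePanel,
                   tau: float = 0.01, prior: np.ndarray | None = None,
                   transition: str = "constant",
                   snp_map=None) -> AncestryTrack:
    """Decode breed origin of every crossbred haplotype window-by-window.

    With transition="constant", tau is the per-boundary switch probability
    (split evenly over the other origins).  With transition="map", tau is a
    switch rate per cM and each boundary's switch probability is
    1 - exp(-tau * d) for the genetic gap d between window midpoints
    (requires `snp_map`).  Decoding is forward-backward in log space,
    independent per chromosome; hard labels are posterior argmax, ties
    broken toward the higher-prior origin.
    """
    if tau < 0 or (transition == "constant" and tau >= 1):
        raise ValueError("tau out of range for the chosen transition model")
    K = len(model.origins)
    prior = np.full(K, 1.0 / K) if prior is None else np.asarray(prior, float)
    if len(prior) != K or abs(prior.sum() - 1) > 1e-8:
        raise ValueError("prior must be a distribution over origins")
    if crossbred_panel.n_snp < model.partition.windows[-1][2]:
        raise ValueError("panel does not cover the model's window partition")
    if transition == "map" and snp_map is None:
        snp_map = crossbred_panel.snp_map
    with np.errstate(divide="ignore"):
        log_prior = np.log(prior)
    log_trans = _switch_matrix(tau, K) if K > 1 else np.zeros((1, 1))

    H = crossbred_panel.hap_matrix
    n_win = model.partition.n_windows
    emissions = np.empty((H.shape[0], n_win, K))
    for w in range(n_win):
        emissions[:, w, :] = window_loglik(model, H, w)

    post = np.empty_like(emissions)
    for _chrom, w0, w1 in model.partition.chrom_window_ranges():
        if transition == "map" and w1 - w0 > 1:
            mids = np.array([0.5 * (snp_map.cm[s] + snp_map.cm[e - 1])
                             for _c, s, e in model.partition.windows[w0:w1]])
            p_sw = 1.0 - np.exp(-tau * np.diff(mids))
            lt = np.stack([_switch_matrix(min(p, 1 - 1e-12), K) for p in p_sw])
        elif transition == "constant":
            lt = log_trans
        elif transition == "map":
            lt = log_trans
        else:
            raise ValueError("transition must be 'constant' or 'map'")
        post[:, w0:w1, :], _ll = forward_backward(
            emissions[:, w0:w1, :], lt, log_prior)

    # argmax with ties toward the higher-prior origin
    order = np.argsort(-(prior + np.arange(K) * 1e-15))  # stable prior ranking
    ranked = post[..., order]
    labels = order[np.argmax(ranked, axis=-1)]
    return AncestryTrack(list(crossbred_panel.sample_ids), model.origins,
                         model.partition, post, labels.astype(np.int8), tau)


# ---------------------------------------------------------------------------
# summaries and validation
# ---------------------------------------------------------------------------

def breed_content(track: AncestryTrack, method: str = "posterior") -> np.ndarray:
    """Per-sample origin proportions (n_samples x n_origins, rows sum to 1)."""
    if method == "posterior":
        per_hap = track.posteriors.mean(axis=1)
    elif method == "hard":
        K = len(track.origins)
        per_hap = np.stack([(track.labels == j).mean(axis=1) for j in range(K)], axis=1)
    else:
        raise ValueError("method must be 'posterior' or 'hard'")
    return 0.5 * (per_hap[0::2] + per_hap[1::2])


def validate_assignment(track: AncestryTrack, truth_labels: np.ndarray) -> dict:
    """Accuracy of window labels against truth, overall and per true origin.

    truth_labels: (2*n_samples, n_windows) origin indices.  Returns the
    overall window accuracy plus, per origin, the distribution (mean, SD,
    min, max) of each haplotype's correct-assignment fraction on windows
    truly of that origin.
    """
    if truth_labels.shape != track.labels.shape:
        raise ValueError("truth label matrix shape mismatch")
    if truth_labels.max(initial=0) >= len(track.origins):
        raise ValueError("truth labels outside the track's origin set")
    correct = (track.labels == truth_labels)
    report = {"overall_accuracy": float(correct.mean()), "per_origin": {}}
    for j, o in enumerate(track.origins):
        mask = truth_labels == j
        has = mask.any(axis=1)
        if not has.any():
            continue
        acc = np.array([correct[h][mask[h]].mean() for h in np.flatnonzero(has)])
        report["per_origin"][o] = {
            "mean": float(acc.mean()), "sd": float(acc.std()),
            "min": float(acc.min()), "max": float(acc.max()),
            "n_haplotypes": int(len(acc)),
        }
    return report


def truth_window_labels(hap_origin: np.ndarray,
                        partition: WindowPartition) -> np.ndarray:
    """Collapse SNP-resolution truth to per-window majority labels."""
    H = hap_origin.shape[0]
    out = np.empty((H, partition.n_windows), dtype=np.int8)
    for w, (_c, s, e) in enumerate(partition.windows):
        block = hap_origin[:, s:e]
        K = int(block.max()) + 1
        counts = np.stack([(block == j).sum(axis=1) for j in range(K)], axis=1)
        out[:, w] = np.argmax(counts, axis=1)
    return out
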