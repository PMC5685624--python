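"""Population differentiation and model-based structure inference.

AMOVA follows the one-level Excoffier decomposition of squared Euclidean
band distances into among- and within-group components, yielding Phi_ST with
a label-permutation p-value.  Structure inference replaces the STRUCTURE
Gibbs sampler with a maximum-likelihood admixture model for binary band
data, P(x_il = 1) = sum_k q_ik f_kl, fitted by EM with random restarts; the
best log-likelihood L(K) plays the role of LnP(D) in Evanno's delta-K rule
for choosing the number of subpopulations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .errors import DataError, ParameterError
from .io import GroupLabels, SSRPanel

__all__ = [
    "AMOVAResult",
    "PCAResult",
    "AdmixtureModel",
    "AdmixtureResult",
    "amova",
    "pairwise_fst",
    "wright_fst",
    "pca",
    "fit_admixture",
    "run_structure_grid",
    "evanno_delta_k",
    "assign_membership",
    "align_q",
]


# ---------------------------------------------------------------------------
# AMOVA / F_ST
# ---------------------------------------------------------------------------


@dataclass
class AMOVAResult:
    df_among: int
    df_within: int
    ssd_among: float
    ssd_within: float
    ssd_total: float
    sigma2_among: float
    sigma2_within: float
    pct_among: float
    pct_within: float
    phi_st: float
    p_value: float | None = None
    n_permutations: int = 0

    def __post_init__(self):
        if abs(self.ssd_among + self.ssd_within - self.ssd_total) > 1e-6 * max(1.0, self.ssd_total):
            raise DataError("AMOVA sums of squares do not add up")

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "df": [self.df_among, self.df_within, self.df_among + self.df_within],
                "sum_of_squares": [self.ssd_among, self.ssd_within, self.ssd_total],
                "variance_component": [self.sigma2_among, self.sigma2_within, np.nan],
                "pct_variation": [self.pct_among, self.pct_within, np.nan],
            },
            index=["among_populations", "within_populations", "total"],
        )


def _squared_distances(panel: SSRPanel) -> np.ndarray:
    """Squared Euclidean band distances with pairwise-complete scaling.

    For 0/1 calls the squared difference equals the mismatch count over
    jointly scored loci, rescaled to the full locus count L.
    """
    X = panel.calls
    L = panel.n_loci
    M = (~np.isnan(X)).astype(float)
    B = np.where(np.isnan(X), 0.0, X)
    shared = M @ M.T
    mism = B @ (M - B).T + (M - B) @ B.T
    off = shared + np.eye(len(shared))
    if (off == 0).any():
        raise DataError("accession pair shares no scored loci")
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = L * mism / np.where(shared > 0, shared, 1.0)
    np.fill_diagonal(d2, 0.0)
    return (d2 + d2.T) / 2.0


def _amova_components(d2: np.ndarray, codes: np.ndarray, n_groups: int):
    N = len(codes)
    iu = np.triu_indices(N, 1)
    ssd_total = float(d2[iu].sum()) / N
    ssd_within = 0.0
    sizes = np.empty(n_groups)
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        sizes[g] = len(idx)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            su = np.triu_indices(len(idx), 1)
            ssd_within += float(sub[su].sum()) / len(idx)
    ssd_among = ssd_total - ssd_within
    G = n_groups
    msd_among = ssd_among / (G - 1)
    msd_within = ssd_within / (N - G)
    n_bar = (N - float(np.sum(sizes**2)) / N) / (G - 1)
    sigma_w = msd_within
    sigma_a = (msd_among - msd_within) / n_bar
    total = sigma_a + sigma_w
    phi = sigma_a / total if total > 0 else 0.0
    return ssd_total, ssd_within, ssd_among, sigma_a, sigma_w, phi


def _group_codes(panel: SSRPanel, groups: GroupLabels):
    labeled = [a for a in panel.accession_ids if a in groups.labels]
    if len(labeled) < panel.n_accessions:
        panel = panel.select_accessions(labeled)
    names = sorted({groups.labels[a] for a in labeled})
    code_of = {g: i for i, g in enumerate(names)}
    codes = np.array([code_of[groups.labels[a]] for a in labeled])
    return panel, codes, names


def amova(panel: SSRPanel, groups: GroupLabels, n_perm: int = 1000, seed: int | None = None) -> AMOVAResult:
    """One-level AMOVA on squared Euclidean band distances.

    Requires at least two groups, each with at least two accessions.  The
    permutation p-value shuffles group labels over accessions and compares
    Phi_ST (plus-one corrected).
    """
    panel, codes, names = _group_codes(panel, groups)
    G = len(names)
    if G < 2:
        raise DataError("AMOVA needs at least two groups")
    sizes = np.bincount(codes, minlength=G)
    if (sizes < 2).any():
        small = [names[g] for g in np.flatnonzero(sizes < 2)]
        raise DataError(f"groups with fewer than two accessions: {small}")
    N = panel.n_accessions
    d2 = _squared_distances(panel)
    ssd_total, ssd_within, ssd_among, sigma_a, sigma_w, phi = _amova_components(d2, codes, G)
    total = sigma_a + sigma_w
    pct_among = 100.0 * sigma_a / total if total > 0 else 0.0
    p = None
    if n_perm and n_perm > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(N)
            stats = _amova_components(d2, codes[perm], G)
            if stats[5] >= phi - 1e-12:
                hits += 1
        p = (1 + hits) / (n_perm + 1)
    return AMOVAResult(
        df_among=G - 1,
        df_within=N - G,
        ssd_among=ssd_among,
        ssd_within=ssd_within,
        ssd_total=ssd_total,
        sigma2_among=sigma_a,
        sigma2_within=sigma_w,
        pct_among=pct_among,
        pct_within=100.0 - pct_among,
        phi_st=phi,
        p_value=p,
        n_permutations=int(n_perm or 0),
    )


def pairwise_fst(panel: SSRPanel, groups: GroupLabels, n_perm: int = 1000, seed: int | None = None):
    """Phi_ST for every group pair (AMOVA restricted to the pair).

    Returns (fst DataFrame, p-value DataFrame); diagonals 0 / NaN.
    """
    by_group = groups.groups()
    names = sorted(g for g, members in by_group.items() if len(members) >= 2)
    if len(names) < 2:
        raise DataError("need at least two groups of size >= 2")
    fst = pd.DataFrame(0.0, index=names, columns=names)
    pvals = pd.DataFrame(np.nan, index=names, columns=names)
    rng = np.random.default_rng(seed)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            members = [x for x in panel.accession_ids if x in set(by_group[a]) | set(by_group[b])]
            sub = panel.select_accessions(members)
            sublabels = GroupLabels({x: groups.labels[x] for x in members})
            res = amova(sub, sublabels, n_perm=n_perm, seed=int(rng.integers(2**31)))
            fst.loc[a, b] = fst.loc[b, a] = res.phi_st
            pvals.loc[a, b] = pvals.loc[b, a] = res.p_value
    return fst, pvals


def wright_fst(panel: SSRPanel, groups: GroupLabels) -> float:
    """Frequency-based multi-locus F_ST: per-locus ANOVA of band frequencies
    (Weir-Cockerham-style theta for haploid data, ratio of sums over loci).

    Works from group allele frequencies rather than pairwise distances, so
    it serves as the allele-frequency route to the differentiation that
    AMOVA measures from squared distances.
    """
    panel, codes, names = _group_codes(panel, groups)
    G = len(names)
    X = panel.calls
    num = 0.0  # sum over loci of sigma^2_among
    den = 0.0  # sum over loci of sigma^2_among + sigma^2_within
    for l in range(X.shape[1]):
        x = X[:, l]
        obs = ~np.isnan(x)
        if obs.sum() < 2:
            continue
        n_g = np.array([np.sum(obs & (codes == g)) for g in range(G)], dtype=float)
        if (n_g < 1).sum() > 0 or (n_g > 0).sum() < 2:
            continue
        p_g = np.array([np.nanmean(x[codes == g]) for g in range(G)])
        N = n_g.sum()
        p_bar = float(np.sum(n_g * p_g) / N)
        ssb = float(np.sum(n_g * (p_g - p_bar) ** 2))
        ssw = float(np.sum(n_g * p_g * (1 - p_g)))
        groups_present = int((n_g > 0).sum())
        msb = ssb / (groups_present - 1)
        msw = ssw / (N - groups_present)
        n_c = (N - float(np.sum(n_g**2)) / N) / (groups_present - 1)
        sigma_a = (msb - msw) / n_c
        num += sigma_a
        den += sigma_a + msw
    return num / den if den > 0 else 0.0


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    scores: pd.DataFrame  # accession x component
    variance_fraction: np.ndarray

    def __post_init__(self):
        v = self.variance_fraction
        if (v < -1e-12).any() or (np.diff(v) > 1e-9).any() or v.sum() > 1 + 1e-9:
            raise DataError("variance fractions must be non-negative, non-increasing, sum <= 1")


def pca(panel: SSRPanel, n_components: int | None = None) -> PCAResult:
    """Principal components of the mean-centered band matrix.

    Missing calls are replaced by the locus mean before centering; loci with
    no scored calls are excluded with a warning.
    """
    if panel.n_accessions < 2:
        raise DataError("PCA needs at least two accessions")
    X = panel.calls.copy()
    n_calls = np.sum(~np.isnan(X), axis=0)
    if (n_calls == 0).any():
        dead = [panel.locus_ids[j] for j in np.flatnonzero(n_calls == 0)]
        warnings.warn(f"excluding {len(dead)} all-missing loci from PCA", stacklevel=2)
        keep = n_calls > 0
        X = X[:, keep]
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(s**2))
    frac = s**2 / total if total > 0 else np.zeros_like(s)
    c = len(s) if n_components is None else min(n_components, len(s))
    scores = pd.DataFrame(
        (U * s)[:, :c], index=panel.accession_ids, columns=[f"PC{i + 1}" for i in range(c)]
    )
    return PCAResult(scores=scores, variance_fraction=frac[:c])


# ---------------------------------------------------------------------------
# admixture model (EM)
# ---------------------------------------------------------------------------


@dataclass
class AdmixtureResult:
    """Fitted admixture model for one K (the Q-matrix and band frequencies)."""

    K: int
    Q: np.ndarray  # n_accessions x K, rows sum to 1
    freqs: np.ndarray  # K x n_loci subpopulation band frequencies
    loglik: float
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    restart_logliks: list[float]
    seed: int | None
    accession_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-6):
            raise DataError("Q rows must sum to 1")
        if not np.isfinite(self.loglik):
            raise DataError("non-finite log-likelihood")

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.Q, index=self.accession_ids or None,
            columns=[f"pop{k + 1}" for k in range(self.K)],
        )
        df.attrs["loglik"] = self.loglik
        df.attrs["converged"] = self.converged
        return df

    def assign(self, threshold: float = 0.70) -> list[str]:
        return assign_membership(self, threshold)


class AdmixtureModel:
    """Maximum-likelihood admixture model for binary band data.

    P(x_il = 1 | Q, F) = sum_k q_ik f_kl, fitted by EM.  Missing calls drop
    out of the likelihood.  ``fit`` keeps the best of ``n_restarts`` random
    initializations; the likelihood is non-decreasing across iterations.
    """

    def __init__(self, panel: SSRPanel, K: int):
        if K < 1 or K > panel.n_accessions:
            raise ParameterError("K must lie in 1..n_accessions")
        self.panel = panel
        self.K = K
        X = panel.calls
        self._obs = ~np.isnan(X)
        self._x1 = (X == 1.0) & self._obs
        self._x0 = (X == 0.0) & self._obs

    def _loglik(self, Q, F):
        P1 = np.clip(Q @ F, 1e-12, 1 - 1e-12)
        return float(np.sum(np.log(P1[self._x1])) + np.sum(np.log((1 - P1)[self._x0])))

    def _em(self, Q, F, max_iter, tol):
        x1 = self._x1
        x0 = self._x0
        n_obs_per_acc = self._obs.sum(axis=1).astype(float)
        trace = []
        prev = -np.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            # responsibilities gamma[i,k,l] for observed cells
            like1 = F[None, :, :]  # K x L broadcast over i
            like0 = 1.0 - F[None, :, :]
            w = Q[:, :, None] * (x1[:, None, :] * like1 + x0[:, None, :] * like0)
            norm = w.sum(axis=1, keepdims=True)
            norm = np.where(norm > 0, norm, 1.0)
            g = w / norm
            Q = g.sum(axis=2) / n_obs_per_acc[:, None]
            Q = Q / Q.sum(axis=1, keepdims=True)
            g1 = (g * x1[:, None, :]).sum(axis=0)
            gtot = g.sum(axis=0)
            F = np.where(gtot > 0, g1 / np.where(gtot > 0, gtot, 1.0), F)
            F = np.clip(F, 1e-6, 1 - 1e-6)
            ll = self._loglik(Q, F)
            trace.append(ll)
            if ll - prev < tol and it > 1:
                converged = True
                break
            prev = ll
        return Q, F, np.array(trace), converged, it

    def fit(self, n_restarts: int = 10, max_iter: int = 500, tol: float = 1e-6,
            seed: int | None = None) -> AdmixtureResult:
        panel = self.panel
        n, L, K = panel.n_accessions, panel.n_loci, self.K
        if K == 1:
            # closed form: f_l is the observed band frequency
            with np.errstate(invalid="ignore"):
                f = self._x1.sum(axis=0) / np.maximum(self._obs.sum(axis=0), 1)
            F = np.clip(f[None, :], 1e-6, 1 - 1e-6)
            Q = np.ones((n, 1))
            ll = self._loglik(Q, F)
            return AdmixtureResult(1, Q, F, ll, np.array([ll]), True, 0, [ll], seed,
                                   list(panel.accession_ids))
        rng = np.random.default_rng(seed)
        best = None
        restart_lls = []
        for _ in range(n_restarts):
            Q0 = rng.dirichlet(np.ones(K), size=n)
            F0 = rng.uniform(0.1, 0.9, size=(K, L))
            Q1, F1, trace, conv, it = self._em(Q0, F0, max_iter, tol)
            restart_lls.append(trace[-1])
            if best is None or trace[-1] > best[2][-1][-1]:
                best = (Q1, F1, [trace], conv, it)
        Q1, F1, traces, conv, it = best
        return AdmixtureResult(K, Q1, F1, float(traces[-1][-1]), traces[-1], conv, it,
                               restart_lls, seed, list(panel.accession_ids))


def fit_admixture(panel: SSRPanel, K: int, n_restarts: int = 10, max_iter: int = 500,
                  tol: float = 1e-6, seed: int | None = None) -> AdmixtureResult:
    return AdmixtureModel(panel, K).fit(n_restarts=n_restarts, max_iter=max_iter, tol=tol, seed=seed)


def run_structure_grid(panel: SSRPanel, K_values=range(1, 13), n_runs: int = 10,
                       n_restarts: int = 1, max_iter: int = 300, tol: float = 1e-5,
                       seed: int | None = None) -> dict[int, list[AdmixtureResult]]:
    """Fit the admixture model for each K, ``n_runs`` independent runs each.

    Each run uses its own random initialization so the spread of L(K) across
    runs feeds Evanno's delta-K.
    """
    rng = np.random.default_rng(seed)
    out: dict[int, list[AdmixtureResult]] = {}
    for K in K_values:
        out[int(K)] = [
            fit_admixture(panel, int(K), n_restarts=n_restarts, max_iter=max_iter, tol=tol,
                          seed=int(rng.integers(2**31)))
            for _ in range(n_runs)
        ]
    return out


def evanno_delta_k(fits: dict[int, list]) -> pd.DataFrame:
    """Evanno second-difference table from per-K replicate log-likelihoods.

    Accepts {K: [AdmixtureResult | float, ...]}.  delta_K(K) =
    |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K)); undefined (NaN)
    at the grid edges and where sd = 0.
    """
    Ks = sorted(fits)
    if len(Ks) < 3 or Ks != list(range(Ks[0], Ks[-1] + 1)):
        raise ParameterError("need >= 3 consecutive K values")
    rows = {}
    for K in Ks:
        lls = [f.loglik if hasattr(f, "loglik") else float(f) for f in fits[K]]
        if len(lls) < 2:
            raise ParameterError(f"K={K}: need >= 2 runs for Evanno")
        rows[K] = (float(np.mean(lls)), float(np.std(lls, ddof=1)))
    recs = []
    for K in Ks:
        mean_l, sd_l = rows[K]
        lp = mean_l - rows[K - 1][0] if K - 1 in rows else np.nan
        lpp = (
            abs((rows[K + 1][0] - mean_l) - lp)
            if (K + 1 in rows and K - 1 in rows)
            else np.nan
        )
        if np.isnan(lpp):
            dk = np.nan
        elif sd_l == 0:
            dk = np.nan  # undefined, reported as such
        else:
            dk = lpp / sd_l
        recs.append({"K": K, "mean_L": mean_l, "sd_L": sd_l, "Lp": lp, "Lpp_abs": lpp, "delta_K": dk})
    return pd.DataFrame(recs).set_index("K")


def best_k(evanno: pd.DataFrame) -> int:
    """argmax of delta_K over interior K values."""
    valid = evanno["delta_K"].dropna()
    if valid.empty:
        raise DataError("no interior K with defined delta_K")
    return int(valid.idxmax())


def assign_membership(fit: AdmixtureResult, threshold: float = 0.70) -> list[str]:
    """Hard subpopulation labels: argmax membership if above threshold else 'mixed'."""
    if not (0.5 < threshold <= 1.0):
        raise ParameterError("membership threshold must lie in (0.5, 1]")
    out = []
    for row in fit.Q:
        k = int(np.argmax(row))
        out.append(f"pop{k + 1}" if row[k] > threshold else "mixed")
    return out


def align_q(Q_est: np.ndarray, Q_ref: np.ndarray) -> np.ndarray:
    """Permute estimated ancestry columns to best match a reference Q.

    Resolves label switching by Hungarian assignment on column overlaps.
    """
    if Q_est.shape != Q_ref.shape:
        raise ParameterError("Q matrices must share a shape")
    cost = -(Q_est.T @ Q_ref)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(Q_est.shape[1], dtype=int)
    perm[cols] = rows
    return Q_est[:, perm]
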