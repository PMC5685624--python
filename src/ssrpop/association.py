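"""Per-marker association scans with structure and kinship control.

Two scan models are provided per trait and environment:

* GLM: ordinary least squares of the trait on [intercept, Q columns,
  marker], with a 1-df F test for the marker;
* MLM (Q+K): the mixed model y = X beta + Q v + u + e with Var(u) =
  sigma_g^2 K and Var(e) = sigma_e^2 I, fitted by restricted maximum
  likelihood through the spectral decomposition of K, reducing the variance
  problem to a one-dimensional search over delta = sigma_e^2 / sigma_g^2
  (the EMMA device).  ``per_marker`` mode re-estimates delta for every
  marker; ``P3D`` estimates it once on the null model and reuses it.

Multiple-testing adjustments: Sidak single-step and Storey's q-value with a
smoother-estimated pi0.  The minimum Bayes factor BFmin = -e p ln p bounds
the evidence against the null from a p-value alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline
from scipy.optimize import minimize_scalar

from .errors import DataError, ParameterError
from .io import TRAITS, PhenotypeTable, SSRPanel
from .kinship_ld import KinshipMatrix


# ---------------------------------------------------------------------------
# phenotype preparation
# ---------------------------------------------------------------------------


def normalize_impute(pheno: PhenotypeTable) -> PhenotypeTable:
    """Mean-impute missing trait values and z-score within environment-trait."""
    table = pheno.table.copy()
    for env in pheno.environments:
        sel = table["environment"] == env
        for trait in TRAITS:
            vals = table.loc[sel, trait].to_numpy(dtype=float)
            present = np.isfinite(vals)
            if not present.any():
                raise DataError(f"trait {trait} entirely missing in environment {env}")
            mu = vals[present].mean()
            vals[~present] = mu
            sd = vals.std(ddof=1)
            table.loc[sel, trait] = (vals - mu) / sd if sd > 0 else 0.0
    return PhenotypeTable(table, units={t: "z" for t in TRAITS}, normalized=True)


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------


@dataclass
class AssociationResult:
    """Per-locus scan results for one trait in one environment."""

    table: pd.DataFrame  # index locus: beta, F, p, p_sidak, q, bfmin [, p_perm]
    model: str  # "GLM" | "MLM"
    trait: str
    environment: str
    n_obs: int
    covariates: dict = field(default_factory=dict)
    variance: dict = field(default_factory=dict)  # MLM: delta, sigma_g2, sigma_e2
    skipped: list[str] = field(default_factory=list)

    def __post_init__(self):
        p = self.table["p"].dropna()
        if ((p <= 0) | (p > 1)).any():
            raise DataError("p-values outside (0, 1]")

    def significant(self, alpha: float = 0.05, column: str = "p") -> pd.DataFrame:
        return self.table[self.table[column] <= alpha]

    def summary(self, top: int = 10) -> pd.DataFrame:
        return self.table.sort_values("p").head(top)


def _finalize(table: pd.DataFrame) -> pd.DataFrame:
    valid = table["p"].notna()
    p = table.loc[valid, "p"].to_numpy()
    table.loc[valid, "p_sidak"] = adjust_pvalues(p, method="sidak")
    table.loc[valid, "q"] = adjust_pvalues(p, method="storey_q")
    table.loc[valid, "bfmin"] = min_bayes_factor(p)
    return table


def _align(panel: SSRPanel, y: pd.Series, Q: pd.DataFrame | np.ndarray | None):
    """Intersect accessions, mean-impute marker missing calls, drop last Q column."""
    y = y.dropna()
    common = [a for a in panel.accession_ids if a in y.index]
    if len(common) < 3:
        raise DataError("fewer than 3 accessions with phenotype and genotype")
    sub = panel.select_accessions(common)
    X = sub.calls.copy()
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    yv = y.loc[common].to_numpy(dtype=float)
    n = len(common)
    W = np.ones((n, 1))
    q_cols = 0
    if Q is not None:
        Qm = Q.loc[common].to_numpy(dtype=float) if isinstance(Q, pd.DataFrame) else np.asarray(Q, dtype=float)
        if Qm.shape[0] != n:
            raise DataError("Q rows do not match accessions")
        if Qm.shape[1] > 1:
            Qm = Qm[:, :-1]  # drop one column: rows sum to one
        q_cols = Qm.shape[1]
        W = np.hstack([W, Qm])
    return sub, X, yv, W, q_cols


# ---------------------------------------------------------------------------
# GLM scan
# ---------------------------------------------------------------------------


def glm_scan(panel: SSRPanel, y: pd.Series, Q=None, trait: str = "", environment: str = "") -> AssociationResult:
    """OLS scan: trait ~ intercept + Q + marker, 1-df marker F test.

    Markers collinear with the covariates are skipped (NaN row, listed in
    ``skipped``).
    """
    sub, X, yv, W, q_cols = _align(panel, y, Q)
    n, L = X.shape
    p_cov = W.shape[1]
    if n <= p_cov + 1:
        raise DataError("not enough observations for the GLM")
    # residualize on covariates
    WtW_inv = np.linalg.pinv(W.T @ W)
    H = W @ WtW_inv @ W.T
    My = yv - H @ yv
    MX = X - H @ X
    ssx = np.einsum("ij,ij->j", MX, MX)
    rss0 = float(My @ My)
    dfd = n - p_cov - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = (MX.T @ My) / ssx
        explained = beta**2 * ssx
        rss1 = rss0 - explained
        F = explained / (rss1 / dfd)
    skipped = [sub.locus_ids[j] for j in np.flatnonzero(ssx <= 1e-10 * n)]
    bad = ssx <= 1e-10 * n
    beta[bad] = np.nan
    F[bad] = np.nan
    pvals = stats.f.sf(F, 1, dfd)
    pvals = np.where(np.isnan(F), np.nan, np.clip(pvals, np.finfo(float).tiny, 1.0))
    table = pd.DataFrame(
        {"beta": beta, "F": F, "p": pvals, "p_sidak": np.nan, "q": np.nan, "bfmin": np.nan},
        index=pd.Index(sub.locus_ids, name="locus"),
    )
    return AssociationResult(
        table=_finalize(table), model="GLM", trait=trait, environment=environment,
        n_obs=n, covariates={"q_columns": q_cols}, skipped=skipped,
    )


# ---------------------------------------------------------------------------
# MLM scan (EMMA-style REML)
# ---------------------------------------------------------------------------


def _reml_neg_loglik(log_delta: float, yt: np.ndarray, Wt: np.ndarray, w: np.ndarray):
    delta = math.exp(log_delta)
    v = w + delta
    vi = 1.0 / v
    WtVW = Wt.T @ (Wt * vi[:, None])
    try:
        beta = np.linalg.solve(WtVW, Wt.T @ (yt * vi))
    except np.linalg.LinAlgError:
        return 1e30, None, None
    res = yt - Wt @ beta
    n, p = Wt.shape
    rss = float(res @ (res * vi))
    if rss <= 0:
        return 1e30, None, None
    sigma_g2 = rss / (n - p)
    sign, logdet_WtVW = np.linalg.slogdet(WtVW)
    if sign <= 0:
        return 1e30, None, None
    nll = 0.5 * ((n - p) * math.log(2 * math.pi * sigma_g2) + np.sum(np.log(v))
                 + logdet_WtVW + (n - p))
    return nll, beta, sigma_g2


def _optimize_delta(yt, Wt, w, grid=None):
    grid = np.linspace(-10.0, 10.0, 41) if grid is None else grid
    vals = [_reml_neg_loglik(g, yt, Wt, w)[0] for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(lambda g: _reml_neg_loglik(g, yt, Wt, w)[0],
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-8})
    return float(math.exp(res.x)), float(res.fun)


class MixedLMScan:
    """Q+K mixed-model association scan (statsmodels-style model object).

    Parameters
    ----------
    panel : SSRPanel
        MAF-filtered genotypes.
    y : pd.Series
        Trait values indexed by accession (one environment).
    Q : DataFrame | ndarray | None
        Admixture proportions used as fixed covariates (last column dropped).
    K : KinshipMatrix | ndarray
        Polygenic covariance scale; jittered by 1e-8 if not quite PSD.
    """

    def __init__(self, panel: SSRPanel, y: pd.Series, Q=None, K=None,
                 trait: str = "", environment: str = ""):
        if K is None:
            raise ParameterError("MLM requires a kinship matrix")
        sub, X, yv, W, q_cols = _align(panel, y, Q)
        if isinstance(K, KinshipMatrix):
            Kdf = K.to_dataframe()
            missing = [a for a in sub.accession_ids if a not in Kdf.index]
            if missing:
                raise DataError(f"kinship lacks accessions {missing[:5]}")
            Km = Kdf.loc[sub.accession_ids, sub.accession_ids].to_numpy()
        else:
            Km = np.asarray(K, dtype=float)
            if Km.shape != (len(yv), len(yv)):
                raise DataError("kinship shape does not match accession set")
        Km = (Km + Km.T) / 2.0
        w, U = np.linalg.eigh(Km)
        # estimator noise can push small eigenvalues below zero; bend those
        # to the PSD cone, but refuse clearly indefinite matrices
        if w.min() < -0.01 * max(1.0, abs(w.max())):
            raise DataError(f"kinship not PSD beyond jitter tolerance (min eigenvalue {w.min():.3g})")
        w = np.clip(w, 0.0, None) + 1e-8
        self.panel = sub
        self._w = w
        self._yt = U.T @ yv
        self._Wt = U.T @ W
        self._Xt = U.T @ X
        self._q_cols = q_cols
        self.trait = trait
        self.environment = environment

    def fit(self, variance_mode: str = "per_marker", n_perm: int = 0,
            seed: int | None = None) -> AssociationResult:
        if variance_mode not in ("per_marker", "P3D"):
            raise ParameterError("variance_mode must be 'per_marker' or 'P3D'")
        yt, Wt, w, Xt = self._yt, self._Wt, self._w, self._Xt
        n, L = Xt.shape
        p_full = Wt.shape[1] + 1
        dfd = n - p_full
        if dfd < 1:
            raise DataError("not enough observations for the MLM")

        delta_null, _ = _optimize_delta(yt, Wt, w)
        beta = np.full(L, np.nan)
        F = np.full(L, np.nan)
        deltas = np.full(L, np.nan)
        skipped = []
        for j in range(L):
            Wj = np.hstack([Wt, Xt[:, j:j + 1]])
            if np.linalg.matrix_rank(Wj) < Wj.shape[1]:
                skipped.append(self.panel.locus_ids[j])
                continue
            if variance_mode == "per_marker":
                dj, _ = _optimize_delta(yt, Wj, w)
            else:
                dj = delta_null
            stat = self._wald(yt, Wj, w, dj)
            if stat is None:
                skipped.append(self.panel.locus_ids[j])
                continue
            beta[j], F[j] = stat
            deltas[j] = dj
        pvals = stats.f.sf(F, 1, dfd)
        pvals = np.where(np.isnan(F), np.nan, np.clip(pvals, np.finfo(float).tiny, 1.0))
        table = pd.DataFrame(
            {"beta": beta, "F": F, "p": pvals, "p_sidak": np.nan, "q": np.nan,
             "bfmin": np.nan, "delta": deltas},
            index=pd.Index(self.panel.locus_ids, name="locus"),
        )
        if n_perm and n_perm > 0:
            table["p_perm"] = self._permutation_p(F, delta_null, n_perm, seed)
        nll = _reml_neg_loglik(math.log(delta_null), yt, Wt, w)
        sigma_g2 = nll[2] if nll[2] is not None else np.nan
        return AssociationResult(
            table=_finalize(table), model="MLM", trait=self.trait,
            environment=self.environment, n_obs=n,
            covariates={"q_columns": self._q_cols},
            variance={"delta_null": delta_null, "sigma_g2": sigma_g2,
                      "sigma_e2": sigma_g2 * delta_null if sigma_g2 is not None else np.nan,
                      "mode": variance_mode},
            skipped=skipped,
        )

    @staticmethod
    def _wald(yt, Wj, w, delta):
        v = w + delta
        vi = 1.0 / v
        A = Wj.T @ (Wj * vi[:, None])
        try:
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            return None
        beta = Ainv @ (Wj.T @ (yt * vi))
        res = yt - Wj @ beta
        n, p = Wj.shape
        rss = float(res @ (res * vi))
        if rss <= 0 or n - p < 1:
            return None
        sigma_g2 = rss / (n - p)
        se2 = sigma_g2 * Ainv[-1, -1]
        if se2 <= 0:
            return None
        return float(beta[-1]), float(beta[-1] ** 2 / se2)

    def _permutation_p(self, F_obs, delta_null, n_perm, seed):
        """Trait-permutation p per marker at the null delta (P3D for speed)."""
        rng = np.random.default_rng(seed)
        yt, Wt, w, Xt = self._yt, self._Wt, self._w, self._Xt
        n, L = Xt.shape
        hits = np.zeros(L)
        valid = np.isfinite(F_obs)
        # permute the trait in the original basis: y_perm = U' P U yt requires U;
        # equivalent and simpler: permute the rotated residual trait entries
        for _ in range(n_perm):
            yp = yt[rng.permutation(n)]
            for j in np.flatnonzero(valid):
                Wj = np.hstack([Wt, Xt[:, j:j + 1]])
                stat = self._wald(yp, Wj, w, delta_null)
                if stat is not None and stat[1] >= F_obs[j]:
                    hits[j] += 1
        p = np.full(L, np.nan)
        p[valid] = (1 + hits[valid]) / (n_perm + 1)
        return p


def mlm_scan(panel: SSRPanel, y: pd.Series, Q=None, K=None, variance_mode: str = "per_marker",
             n_perm: int = 0, seed: int | None = None, trait: str = "",
             environment: str = "") -> AssociationResult:
    """Convenience wrapper around :class:`MixedLMScan`."""
    return MixedLMScan(panel, y, Q=Q, K=K, trait=trait, environment=environment).fit(
        variance_mode=variance_mode, n_perm=n_perm, seed=seed
    )


# ---------------------------------------------------------------------------
# multiple testing and Bayes factors
# ---------------------------------------------------------------------------


def adjust_pvalues(p, method: str = "sidak") -> np.ndarray:
    """Sidak single-step adjustment or Storey q-values (smoother pi0)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ParameterError("empty p-value vector")
    if ((p < 0) | (p > 1)).any():
        raise ParameterError("p-values outside [0, 1]")
    m = p.size
    if method == "sidak":
        return 1.0 - (1.0 - p) ** m
    if method == "storey_q":
        lambdas = np.arange(0.05, 0.96, 0.05)
        pi0_hat = np.array([np.mean(p > lam) / (1 - lam) for lam in lambdas])
        if m >= 100:
            spline = UnivariateSpline(lambdas, pi0_hat, k=3)
            pi0 = float(spline(lambdas[-1]))
        else:  # smoother unstable for tiny m; fall back to the median estimate
            pi0 = float(np.median(pi0_hat))
        pi0 = min(max(pi0, 1.0 / m), 1.0)
        order = np.argsort(p)
        ranked = p[order]
        q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
        q = np.empty(m)
        q[order] = np.clip(q_sorted, 0.0, 1.0)
        return q
    raise ParameterError(f"unknown adjustment method {method!r}")


_E = math.e


def min_bayes_factor(p):
    """BFmin = -e p ln p, the minimum Bayes factor bound for a p-value.

    Defined on (0, 1/e); beyond 1/e the formula exceeds its own bound of 1,
    so values are clamped to 1.  Smaller BFmin = stronger evidence.
    """
    scalar = np.isscalar(p)
    arr = np.atleast_1d(np.asarray(p, dtype=float))
    if (arr <= 0).any() or (arr > 1).any():
        raise ParameterError("p must lie in (0, 1]")
    with np.errstate(invalid="ignore"):
        bf = -_E * arr * np.log(arr)
    bf = np.where(arr >= 1.0 / _E, 1.0, bf)
    return float(bf[0]) if scalar else bf


# ---------------------------------------------------------------------------
# consensus and catalog join
# ---------------------------------------------------------------------------


def cross_environment_consensus(res_a: AssociationResult, res_b: AssociationResult,
                                alpha: float = 0.05, bf_max: float | None = None) -> pd.DataFrame:
    """Loci significant in BOTH environments (p <= alpha, optionally BFmin <= bf_max).

    Commutative in its two inputs.
    """
    set_a, set_b = set(res_a.table.index), set(res_b.table.index)
    common = sorted(set_a & set_b, key=list(res_a.table.index).index)
    if not common:
        raise DataError("association results share no loci")
    a = res_a.table.loc[common]
    b = res_b.table.loc[common]
    sel = (a["p"] <= alpha) & (b["p"] <= alpha)
    if bf_max is not None:
        sel &= (a["bfmin"] <= bf_max) & (b["bfmin"] <= bf_max)
    sel = sel.fillna(False)
    out = pd.DataFrame(
        {
            "trait": res_a.trait,
            f"F_{res_a.environment or 'A'}": a.loc[sel, "F"],
            f"p_{res_a.environment or 'A'}": a.loc[sel, "p"],
            f"F_{res_b.environment or 'B'}": b.loc[sel, "F"],
            f"p_{res_b.environment or 'B'}": b.loc[sel, "p"],
            f"bfmin_{res_a.environment or 'A'}": a.loc[sel, "bfmin"],
            f"bfmin_{res_b.environment or 'B'}": b.loc[sel, "bfmin"],
        }
    )
    out.index.name = "locus"
    return out


def known_qtl_join(consensus: pd.DataFrame, catalog: pd.DataFrame | None = None) -> pd.DataFrame:
    """Annotate consensus loci with a user-supplied known-QTL catalog.

    ``catalog`` needs columns locus, trait, reference.  Missing catalog: all
    loci are novel.  Adds 'match' and 'reference' columns and records
    matched/novel counts in ``df.attrs``.
    """
    out = consensus.copy()
    if catalog is None or catalog.empty:
        out["match"] = False
        out["reference"] = ""
    else:
        cat = catalog.set_index("locus")
        matches, refs = [], []
        for locus, row in out.iterrows():
            if locus in cat.index:
                entry = cat.loc[[locus]]
                trait_ok = entry[entry["trait"] == row.get("trait", "")]
                hit = trait_ok if len(trait_ok) else entry
                matches.append(len(trait_ok) > 0)
                refs.append(";".join(map(str, hit["reference"].tolist())))
            else:
                matches.append(False)
                refs.append("")
        out["match"] = matches
        out["reference"] = refs
    out.attrs["n_matched"] = int(out["match"].sum())
    out.attrs["n_novel"] = int((~out["match"]).sum())
    return out
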