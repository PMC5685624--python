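"""Marker-based kinship and genome-wide pairwise linkage disequilibrium.

Kinship uses a standardized-covariance (allele-sharing) estimator on band
indicators, centered at panel band frequencies, so unrelated accessions in a
panmictic panel score ~0; negatives may be truncated to 0 for reporting.

Because loci are binary band indicators, the multiallelic weighted-average
LD statistic reduces to the plain squared Pearson correlation r^2 per locus
pair; significance comes from a rapid label-permutation test with the
plus-one correction.  Decay of r^2 with genetic map distance is fitted by a
Hill-Weir drift-expectation curve, a constrained exponential, or a lowess
smoother, and summarized by threshold-crossing distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DataError, ParameterError
from .io import GeneticMap, SSRPanel


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------


@dataclass
class KinshipMatrix:
    accession_ids: list[str]
    matrix: np.ndarray
    estimator: str = "standardized_covariance"
    truncated: bool = False

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if not np.allclose(m, m.T, atol=1e-9):
            raise DataError("kinship matrix not symmetric")
        if not np.isfinite(np.diag(m)).all():
            raise DataError("non-finite kinship diagonal")
        if self.truncated and (m < -1e-12).any():
            raise DataError("truncated kinship contains negatives")
        self.matrix = (m + m.T) / 2.0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.accession_ids, columns=self.accession_ids)


def kinship_matrix(panel: SSRPanel, estimator: str = "standardized_covariance",
                   truncate_negative: bool = True) -> KinshipMatrix:
    """k_ij = sum_l (x_il - p_l)(x_jl - p_l) / sum_l p_l (1 - p_l), over loci
    scored in both accessions.  MAF-filtered input is recommended.
    """
    if estimator != "standardized_covariance":
        raise ParameterError(f"unknown kinship estimator {estimator!r}")
    X = panel.calls
    n_calls = np.sum(~np.isnan(X), axis=0).astype(float)
    if (n_calls == 0).any():
        raise DataError("locus with no scored calls; filter the panel first")
    p = np.nansum(X, axis=0) / n_calls
    C = X - p
    M = (~np.isnan(X)).astype(float)
    Cz = np.where(np.isnan(C), 0.0, C)
    num = Cz @ Cz.T
    w = p * (1.0 - p)
    denom = (M * w) @ M.T
    off = denom + np.eye(len(denom))
    if (off == 0).any():
        i, j = np.argwhere(off == 0)[0]
        raise DataError(
            f"accessions {panel.accession_ids[i]!r}/{panel.accession_ids[j]!r} share no "
            "informative loci; kinship undefined"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        k = num / np.where(denom > 0, denom, np.nan)
    k = np.where(np.isfinite(k), k, 0.0)
    if truncate_negative:
        diag = np.diag(k).copy()
        k = np.clip(k, 0.0, None)
        np.fill_diagonal(k, np.clip(diag, 0.0, None))
    return KinshipMatrix(list(panel.accession_ids), k, estimator, truncated=truncate_negative)


def kinship_distribution(K: KinshipMatrix, edges=(0.0, 0.05, 0.25)) -> pd.DataFrame:
    """Banded histogram of off-diagonal kinship: {0}, (0, e1], ..., > e_last.

    Fractions partition all unordered pairs (they sum to 1).
    """
    m = K.matrix
    n = len(K.accession_ids)
    iu = np.triu_indices(n, 1)
    vals = m[iu]
    total = len(vals)
    rows = [{"bin": "0", "count": int(np.sum(vals <= edges[0]))}]
    lo = edges[0]
    for hi in edges[1:]:
        rows.append({"bin": f"({lo}, {hi}]", "count": int(np.sum((vals > lo) & (vals <= hi)))})
        lo = hi
    rows.append({"bin": f"> {lo}", "count": int(np.sum(vals > lo))})
    df = pd.DataFrame(rows)
    df["fraction"] = df["count"] / total if total else 0.0
    return df


# ---------------------------------------------------------------------------
# pairwise LD
# ---------------------------------------------------------------------------


@dataclass
class LDResult:
    pairs: pd.DataFrame  # locus1, locus2, r2, p, same_chromosome, distance_cM
    n_pairs: int
    n_perm: int
    seed: int | None
    n_accessions: int
    n_skipped: int = 0

    def __post_init__(self):
        r2 = self.pairs["r2"].dropna()
        if ((r2 < -1e-9) | (r2 > 1 + 1e-9)).any():
            raise DataError("r^2 outside [0, 1]")
        if self.n_pairs != len(self.pairs):
            raise DataError("n_pairs inconsistent with pair table")


def _pairwise_r2_missing(X: np.ndarray) -> np.ndarray:
    """r^2 for all locus pairs with pairwise deletion of missing calls."""
    Xl = X.T  # loci x accessions
    Msk = (~np.isnan(Xl)).astype(float)
    B = np.where(np.isnan(Xl), 0.0, Xl)
    n = Msk @ Msk.T
    Sx = B @ Msk.T  # sum of x_i over shared (binary: also sum of squares)
    Sxy = B @ B.T
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = Sx / n
        my = Sx.T / n
        cov = Sxy / n - mx * my
        vx = mx * (1 - mx)
        vy = my * (1 - my)
        r2 = cov**2 / (vx * vy)
    r2[~np.isfinite(r2)] = np.nan
    return np.clip(r2, 0.0, 1.0)


def ld_pairwise(panel: SSRPanel, gmap: GeneticMap | None = None, n_perm: int = 10000,
                seed: int | None = None) -> LDResult:
    """r^2 and permutation p for every unordered locus pair.

    The panel should already be MAF-filtered.  Observed r^2 uses pairwise
    deletion; the permutation null shuffles accession labels of one member
    of each pair (one shared set of shuffles, vectorized over all pairs, on
    the standardized mean-imputed matrix).  p is plus-one corrected.  Pairs
    constant after deletion get NaN r^2/p and count as skipped.
    """
    L = panel.n_loci
    if L < 2:
        raise DataError("need at least two loci")
    X = panel.calls
    r2 = _pairwise_r2_missing(X)

    # standardized mean-imputed matrix for the permutation null
    col_mean = np.nanmean(X, axis=0)
    Z = np.where(np.isnan(X), col_mean[None, :], X) - col_mean[None, :]
    sd = Z.std(axis=0)
    sd[sd == 0] = 1.0
    Z = Z / sd
    n = panel.n_accessions

    iu = np.triu_indices(L, 1)
    r2_obs = r2[iu]
    p = np.full(len(r2_obs), np.nan)
    if n_perm and n_perm > 0:
        rng = np.random.default_rng(seed)
        hits = np.zeros(len(r2_obs))
        valid = np.isfinite(r2_obs)
        for _ in range(n_perm):
            perm = rng.permutation(n)
            Rp = (Z.T @ Z[perm]) / n
            r2p = (Rp**2)[iu]
            hits[valid] += r2p[valid] >= r2_obs[valid] - 1e-15
        p[valid] = (1 + hits[valid]) / (n_perm + 1)

    loci = panel.locus_ids
    l1 = [loci[i] for i in iu[0]]
    l2 = [loci[j] for j in iu[1]]
    same_chrom = np.full(len(l1), np.nan, dtype=object)
    dist = np.full(len(l1), np.nan)
    if gmap is not None:
        chrom = {l: (gmap.chromosome(l) if gmap.is_placed(l) else None) for l in loci}
        posn = {l: (gmap.position(l) if gmap.is_placed(l) else None) for l in loci}
        for idx, (a, b) in enumerate(zip(l1, l2)):
            ca, cb = chrom[a], chrom[b]
            if ca is None or cb is None:
                continue
            same_chrom[idx] = ca == cb
            if ca == cb:
                dist[idx] = abs(posn[a] - posn[b])
    pairs = pd.DataFrame(
        {
            "locus1": l1,
            "locus2": l2,
            "r2": r2_obs,
            "p": p,
            "same_chromosome": same_chrom,
            "distance_cM": dist,
        }
    )
    return LDResult(
        pairs=pairs,
        n_pairs=len(pairs),
        n_perm=int(n_perm or 0),
        seed=seed,
        n_accessions=n,
        n_skipped=int(np.sum(~np.isfinite(r2_obs))),
    )


DEFAULT_LD_THRESHOLDS = {0.05: 0.005, 0.1: 0.001, 0.2: 0.0001}


def ld_summary(ld: LDResult, thresholds: dict[float, float] | None = None) -> pd.DataFrame:
    """Counts/fractions of pairs with r^2 >= r2_min and p <= p_max."""
    thresholds = DEFAULT_LD_THRESHOLDS if thresholds is None else thresholds
    rows = []
    r2 = ld.pairs["r2"].to_numpy()
    p = ld.pairs["p"].to_numpy()
    for r2_min, p_max in sorted(thresholds.items()):
        sel = (r2 >= r2_min) & (p <= p_max)
        count = int(np.nansum(sel))
        rows.append(
            {
                "r2_min": r2_min,
                "p_max": p_max,
                "count": count,
                "fraction": count / ld.n_pairs if ld.n_pairs else 0.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------


@dataclass
class LDDecayFit:
    family: str  # default family used for the headline crossings
    fits: dict[str, dict] = field(default_factory=dict)  # family -> params
    crossings: dict[str, dict[float, float | None]] = field(default_factory=dict)
    binned: pd.DataFrame | None = None
    n_syntenic_pairs: int = 0

    def crossing(self, r2_threshold: float, family: str | None = None):
        """Smallest distance (cM) at which the fitted curve drops below the
        threshold, or None when the curve never crosses ('beyond range')."""
        return self.crossings[family or self.family].get(r2_threshold)


def _hill_weir(d, rho, n):
    C = rho * np.asarray(d, dtype=float)
    term = ((10 + C) / ((2 + C) * (11 + C))) * (
        1 + ((3 + C) * (12 + 12 * C + C**2)) / (n * (2 + C) * (11 + C))
    )
    return term


def _exponential(d, a, b, c):
    return a * np.exp(-b * np.asarray(d, dtype=float)) + c


def ld_decay(ld: LDResult, gmap: GeneticMap | None = None,
             families=("hill_weir", "exponential", "loess"),
             r2_thresholds=(0.05, 0.1, 0.2), min_pairs: int = 30,
             n_bins: int = 10, default_family: str = "hill_weir") -> LDDecayFit:
    """Fit expected r^2 against genetic distance on same-chromosome pairs.

    Inter-chromosomal and unplaced pairs are excluded from fitting.  Each
    requested family yields fitted parameters and the distances at which the
    fitted (non-increasing) curve crosses the r^2 thresholds.
    """
    sub = ld.pairs
    syn = sub[(sub["same_chromosome"] == True) & np.isfinite(sub["distance_cM"]) & np.isfinite(sub["r2"])]  # noqa: E712
    n_syn = len(syn)
    if n_syn < min_pairs:
        raise DataError(f"only {n_syn} syntenic pairs with map distances (< {min_pairs})")
    d = syn["distance_cM"].to_numpy(dtype=float)
    r2 = syn["r2"].to_numpy(dtype=float)
    n = ld.n_accessions
    grid = np.linspace(0.0, max(d.max(), 1.0), 2001)

    fit = LDDecayFit(family=default_family, n_syntenic_pairs=n_syn)

    curves: dict[str, np.ndarray] = {}
    for fam in families:
        if fam == "hill_weir":
            try:
                popt, _ = curve_fit(lambda x, rho: _hill_weir(x, rho, n), d, r2,
                                    p0=[0.5], bounds=(1e-9, np.inf), maxfev=10000)
            except RuntimeError as exc:  # pragma: no cover
                raise DataError(f"Hill-Weir fit failed: {exc}") from None
            rho = float(popt[0])
            fit.fits[fam] = {"rho_per_cM": rho, "n": n}
            curves[fam] = _hill_weir(grid, rho, n)
        elif fam == "exponential":
            a0 = float(np.clip(r2.max() - r2.min(), 0.01, 1.0))
            c0 = float(np.clip(r2.min(), 0.0, 1.0))
            try:
                popt, _ = curve_fit(_exponential, d, r2, p0=[a0, 0.1, c0],
                                    bounds=([0, 0, 0], [1.0, np.inf, 1.0]), maxfev=10000)
            except RuntimeError as exc:  # pragma: no cover
                raise DataError(f"exponential fit failed: {exc}") from None
            a, b, c = (float(v) for v in popt)
            fit.fits[fam] = {"a": a, "b_per_cM": b, "c": c}
            curves[fam] = _exponential(grid, a, b, c)
        elif fam == "loess":
            from statsmodels.nonparametric.smoothers_lowess import lowess

            sm = lowess(r2, d, frac=0.5, return_sorted=True)
            yhat = np.interp(grid, sm[:, 0], sm[:, 1])
            # enforce a non-increasing envelope
            yhat = np.minimum.accumulate(yhat)
            fit.fits[fam] = {"frac": 0.5}
            curves[fam] = yhat
        else:
            raise ParameterError(f"unknown decay family {fam!r}")

    for fam, y in curves.items():
        fit.crossings[fam] = {}
        for thr in r2_thresholds:
            below = np.flatnonzero(y < thr)
            if len(below) == 0 or below[0] == 0:
                # curve never decays below the threshold in range, or never
                # attains it at all: no crossing, reported as beyond range
                fit.crossings[fam][thr] = None
            else:
                fit.crossings[fam][thr] = float(grid[below[0]])

    # binned means by distance quantile
    qs = np.quantile(d, np.linspace(0, 1, n_bins + 1))
    qs[-1] += 1e-9
    which = np.clip(np.searchsorted(qs, d, side="right") - 1, 0, n_bins - 1)
    fit.binned = pd.DataFrame(
        {
            "bin_mid_cM": [d[which == b].mean() if (which == b).any() else np.nan for b in range(n_bins)],
            "mean_r2": [r2[which == b].mean() if (which == b).any() else np.nan for b in range(n_bins)],
            "n": [int((which == b).sum()) for b in range(n_bins)],
        }
    )
    return fit
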