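"""Synthetic SSR panels with planted population structure, LD and QTL.

The generator emulates a self-pollinated (effectively haploid/inbred)
germplasm collection genotyped with multiallelic SSR markers scored as
dominant band presence/absence:

* ``K_true`` latent subpopulations whose allele frequencies drift from a
  common ancestral frequency vector under a Balding-Nichols-style Dirichlet
  model with drift parameter ``F_st_target``;
* admixed accession ancestries drawn from a Dirichlet with concentration
  ``alpha``;
* map-distance-dependent LD created mechanistically: each subpopulation is a
  finite founder pool recombined for ``recomb_generations`` generations
  (crossovers placed by the Haldane model, no interference), so nearby loci
  stay associated through shared haplotype blocks while distant and
  inter-chromosomal loci approach linkage equilibrium;
* two-environment quantitative traits built from planted marker (QTL)
  effects with per-environment multipliers (GxE), a polygenic term with
  covariance proportional to the realized marker kinship, an environment
  mean shift, and i.i.d. noise.

Defaults mirror a 288-accession panel genotyped with 108 SSRs carrying 2-5
alleles each (mean ~2.8), mapped to 26 chromosomes, and measured for the
four HVI fiber traits in two environments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, ParameterError
from .io import TRAITS, GeneticMap, GroupLabels, PhenotypeTable, SSRPanel

import pandas as pd

#: trait means per environment and per-trait scale used to place simulated
#: z-scores on the instrument scales (inches, g/tex, micronaire, %)
DEFAULT_TRAIT_MEANS = {
    "UZB": {"FL": 1.30, "FS": 38.8, "FM": 4.25, "FU": 84.7},
    "USA": {"FL": 1.36, "FS": 36.5, "FM": 4.06, "FU": 87.3},
}
DEFAULT_TRAIT_SCALES = {"FL": 0.08, "FS": 2.8, "FM": 0.5, "FU": 1.5}

#: allele-count distribution over 2..5 alleles per SSR (mean 2.78)
DEFAULT_ALLELE_DIST = {2: 0.45, 3: 0.37, 4: 0.13, 5: 0.05}


@dataclass
class QTL:
    """A planted marker effect: additive ``effect`` on the z-score scale of
    ``trait``, scaled per environment by ``env_multiplier``."""

    locus: str
    trait: str
    effect: float
    env_multiplier: dict[str, float] = field(default_factory=dict)

    def multiplier(self, environment: str) -> float:
        return self.env_multiplier.get(environment, 1.0)


@dataclass
class SimConfig:
    n_accessions: int = 288
    K_true: int = 3
    alpha: float = 0.2
    F_st_target: float = 0.2
    n_markers: int = 108
    alleles_per_marker: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_ALLELE_DIST))
    n_chromosomes: int = 26
    chrom_length_cM: float = 150.0
    n_founders: int = 30
    recomb_generations: int = 20
    qtl_spec: list[QTL] = field(default_factory=list)
    h2_polygenic: float = 0.4
    environments: tuple[str, ...] = ("UZB", "USA")
    env_effects: dict[str, dict[str, float]] | None = None  # env -> trait -> mean
    noise_sd: float = 1.0
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        for name in ("n_accessions", "K_true", "n_markers", "n_chromosomes", "n_founders"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if not (0.0 < self.F_st_target < 1.0):
            raise ParameterError("F_st_target must lie in (0, 1)")
        if not (0.0 <= self.h2_polygenic <= 1.0):
            raise ParameterError("h2_polygenic must lie in [0, 1]")
        if self.recomb_generations < 0 or self.noise_sd < 0 or self.missing_rate < 0:
            raise ParameterError("negative rate parameter")
        bad = [k for k in self.alleles_per_marker if not 2 <= k <= 5]
        if bad:
            raise ParameterError(f"allele counts outside 2..5: {bad}")


@dataclass
class SimTruth:
    """Generating truth, for parameter-recovery tests."""

    Q: np.ndarray  # n_accessions x K_true admixture proportions
    subpop_freqs: list[np.ndarray]  # per marker: K_true x n_alleles
    ancestral_freqs: list[np.ndarray]  # per marker: n_alleles
    founder_pools: np.ndarray  # K_true x n_founders x n_markers allele indices
    kinship: np.ndarray  # realized marker kinship, mean diagonal 1
    bands_complete: np.ndarray  # accession x locus 0/1 before missing injection
    qtl: list[QTL]
    variance_decomposition: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-9):
            raise DataError("truth Q rows must sum to 1")


def simulate_subpop_frequencies(cfg: SimConfig, rng: np.random.Generator | None = None,
                                allele_counts: np.ndarray | None = None):
    """Draw ancestral and per-subpopulation allele frequencies.

    Ancestral frequencies are symmetric-Dirichlet; each subpopulation then
    drifts as Dirichlet(p * (1-F)/F), the Balding-Nichols construction whose
    expected Wright F_ST across markers is ``F_st_target``.

    Returns (allele_counts, ancestral list, subpop list of K x k arrays).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if allele_counts is None:
        ks = np.array(sorted(cfg.alleles_per_marker))
        ws = np.array([cfg.alleles_per_marker[k] for k in ks], dtype=float)
        ws = ws / ws.sum()
        allele_counts = rng.choice(ks, size=cfg.n_markers, p=ws)
    F = cfg.F_st_target
    scale = (1.0 - F) / F
    ancestral, subpop = [], []
    for k_m in allele_counts:
        p = rng.dirichlet(np.ones(k_m))
        # guard against degenerate Dirichlet draws on the simplex boundary
        p = np.clip(p, 1e-6, None)
        p = p / p.sum()
        fk = rng.dirichlet(p * scale, size=cfg.K_true)
        subpop.append(np.clip(fk, 1e-9, 1.0))
        ancestral.append(p)
    return np.asarray(allele_counts), ancestral, subpop


def _haldane_switch_probs(gaps_cM: np.ndarray) -> np.ndarray:
    """Recombination fraction for inter-locus gaps under Haldane's map."""
    return 0.5 * (1.0 - np.exp(-2.0 * gaps_cM / 100.0))


def _recombine(parent_a: np.ndarray, parent_b: np.ndarray, switch_p: np.ndarray,
               chrom_start: np.ndarray, rng) -> np.ndarray:
    """One meiosis: copy along the marker order, switching parents at
    recombination events; an independent coin starts each chromosome."""
    n = parent_a.shape[0]
    use_b = np.empty(n, dtype=bool)
    cur = bool(rng.integers(2))
    for m in range(n):
        if chrom_start[m]:
            cur = bool(rng.integers(2))
        elif rng.random() < switch_p[m]:
            cur = not cur
        use_b[m] = cur
    return np.where(use_b, parent_b, parent_a)


def simulate_panel(cfg: SimConfig) -> tuple[SSRPanel, GeneticMap, GroupLabels, SimTruth]:
    """Generate a panel, its genetic map, origin labels and the truth record.

    Deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    allele_counts, ancestral, subpop_freqs = simulate_subpop_frequencies(cfg, rng)
    M, K, n = cfg.n_markers, cfg.K_true, cfg.n_accessions

    # marker placement: markers spread over chromosomes, positions uniform
    chrom = rng.integers(1, cfg.n_chromosomes + 1, size=M)
    pos = rng.uniform(0.0, cfg.chrom_length_cM, size=M)
    order = np.lexsort((pos, chrom))
    chrom, pos, allele_counts = chrom[order], pos[order], allele_counts[order]
    ancestral = [ancestral[i] for i in order]
    subpop_freqs = [subpop_freqs[i] for i in order]

    chrom_start = np.zeros(M, dtype=bool)
    chrom_start[0] = True
    chrom_start[1:] = chrom[1:] != chrom[:-1]
    gaps = np.zeros(M)
    gaps[1:] = pos[1:] - pos[:-1]
    switch_p = _haldane_switch_probs(gaps)

    # founder pools per subpopulation, recombined for recomb_generations
    pools = np.empty((K, cfg.n_founders, M), dtype=np.int64)
    for k in range(K):
        for f in range(cfg.n_founders):
            for m in range(M):
                pools[k, f, m] = rng.choice(allele_counts[m], p=subpop_freqs[m][k])
    for _ in range(cfg.recomb_generations):
        new_pools = np.empty_like(pools)
        for k in range(K):
            for f in range(cfg.n_founders):
                i, j = rng.integers(cfg.n_founders, size=2)
                new_pools[k, f] = _recombine(pools[k, i], pools[k, j], switch_p, chrom_start, rng)
        pools = new_pools

    # admixed accessions: mosaic copying from the pools
    Q = rng.dirichlet(np.full(K, cfg.alpha), size=n)
    haplotypes = np.empty((n, M), dtype=np.int64)
    for i in range(n):
        k = rng.choice(K, p=Q[i])
        h = rng.integers(cfg.n_founders)
        for m in range(M):
            if chrom_start[m] or rng.random() < switch_p[m]:
                k = rng.choice(K, p=Q[i])
                h = rng.integers(cfg.n_founders)
            haplotypes[i, m] = pools[k, h, m]

    # expand allele indices to band presence per allele-locus
    locus_ids: list[str] = []
    locus_marker_idx: list[int] = []
    locus_allele_idx: list[int] = []
    map_rows = []
    for m in range(M):
        name = f"M{m + 1:03d}"
        for a in range(allele_counts[m]):
            locus_ids.append(f"{name}_{150 + 20 * a}")
            locus_marker_idx.append(m)
            locus_allele_idx.append(a)
            map_rows.append((locus_ids[-1], int(chrom[m]), float(pos[m])))
    L = len(locus_ids)
    bands = (haplotypes[:, locus_marker_idx] == np.asarray(locus_allele_idx)).astype(float)

    # realized kinship on the band scale, centered at ancestral band freqs
    p_anc = np.array([ancestral[locus_marker_idx[j]][locus_allele_idx[j]] for j in range(L)])
    C = bands - p_anc
    denom = float(np.sum(p_anc * (1.0 - p_anc)))
    kinship = C @ C.T / denom
    d = np.mean(np.diag(kinship))
    if d > 0:
        kinship = kinship / d  # mean diagonal 1

    calls = bands.copy()
    if cfg.missing_rate > 0:
        miss = rng.random(calls.shape) < cfg.missing_rate
        calls[miss] = np.nan

    accession_ids = [f"acc{i + 1:03d}" for i in range(n)]
    panel = SSRPanel(accession_ids, locus_ids, calls)
    gmap = GeneticMap(
        pd.DataFrame(
            {"chromosome": [r[1] for r in map_rows], "position_cM": [r[2] for r in map_rows]},
            index=pd.Index([r[0] for r in map_rows], name="locus"),
        )
    )
    labels = GroupLabels({accession_ids[i]: f"pop{int(np.argmax(Q[i])) + 1}" for i in range(n)})

    for q in cfg.qtl_spec:
        if q.locus not in set(locus_ids):
            raise DataError(f"QTL locus {q.locus!r} not in simulated panel")
        if q.trait not in TRAITS:
            raise DataError(f"QTL trait {q.trait!r} unknown")

    truth = SimTruth(
        Q=Q,
        subpop_freqs=subpop_freqs,
        ancestral_freqs=ancestral,
        founder_pools=pools,
        kinship=kinship,
        bands_complete=bands,
        qtl=list(cfg.qtl_spec),
    )
    return panel, gmap, labels, truth


def simulate_phenotypes(panel: SSRPanel, truth: SimTruth, cfg: SimConfig,
                        rng: np.random.Generator | None = None) -> PhenotypeTable:
    """Two-environment phenotypes: y = mu_env + sum_q beta_q m_env,q x_q + g + e.

    The polygenic term g ~ N(0, sigma_g^2 K) is drawn once per trait (it is
    genetic, hence shared across environments); environment multipliers on
    the QTL effects implement GxE; e is i.i.d. noise per environment.
    z-scores are mapped onto instrument scales via per-trait means/scales.
    """
    if panel.n_accessions != truth.bands_complete.shape[0]:
        raise DataError("panel and truth accession sets differ")
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    n = panel.n_accessions
    h2 = cfg.h2_polygenic
    sigma_e = cfg.noise_sd
    sigma_g2 = h2 / (1.0 - h2) * sigma_e**2 if h2 < 1.0 else 1.0
    # MVN draw via eigendecomposition (kinship may be singular)
    w, V = np.linalg.eigh(truth.kinship)
    w = np.clip(w, 0.0, None)
    root = V * np.sqrt(w)

    means = cfg.env_effects or DEFAULT_TRAIT_MEANS
    locus_pos = {l: j for j, l in enumerate(panel.locus_ids)}

    g_by_trait = {t: np.sqrt(sigma_g2) * (root @ rng.standard_normal(n)) for t in TRAITS}
    rows = []
    decomposition: dict[str, dict[str, float]] = {}
    for env in cfg.environments:
        env_means = means.get(env) or DEFAULT_TRAIT_MEANS.get(env) or {t: 0.0 for t in TRAITS}
        for t in TRAITS:
            z = g_by_trait[t].copy()
            for q in truth.qtl:
                if q.trait != t:
                    continue
                x = truth.bands_complete[:, locus_pos[q.locus]]
                z = z + q.effect * q.multiplier(env) * x
            e = sigma_e * rng.standard_normal(n)
            z = z + e
            scale = DEFAULT_TRAIT_SCALES[t]
            y = env_means.get(t, 0.0) + scale * z
            decomposition[f"{env}:{t}"] = {
                "var_polygenic": float(np.var(g_by_trait[t])),
                "var_noise": float(np.var(e)),
                "h2_realized": float(np.var(g_by_trait[t]) / max(np.var(z), 1e-12)),
            }
            if t == TRAITS[0]:
                env_rows = {a: {} for a in panel.accession_ids}
            for a, val in zip(panel.accession_ids, y):
                env_rows[a][t] = val
        for a in panel.accession_ids:
            rows.append({"accession": a, "environment": env, **env_rows[a]})
    truth.variance_decomposition = decomposition
    table = pd.DataFrame(rows, columns=["accession", "environment", *TRAITS])
    return PhenotypeTable(table)


def simulate_dataset(cfg: SimConfig):
    """Convenience wrapper: panel + map + labels + phenotypes + truth."""
    panel, gmap, labels, truth = simulate_panel(cfg)
    pheno = simulate_phenotypes(panel, truth, cfg)
    return panel, gmap, labels, pheno, truth
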