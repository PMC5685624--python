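"""End-to-end orchestration: simulate-or-load -> phenotypes -> diversity ->
structure/AMOVA -> kinship/LD -> association -> consensus report.

Every stage derives its own seed from the master seed by stable hashing, so
adding or re-running a stage never perturbs another stage's random stream,
and a fixed config + seed reproduces every artifact bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, diversity, kinship_ld, phenotypes, simulate, structure
from . import io as sio
from .errors import SSRPopError

log = logging.getLogger("ssrpop")


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed: sha256 of 'master:stage' reduced mod 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % (2**31)


@dataclass
class RunConfig:
    """All knobs of a full run; defaults mirror the usual study settings."""

    # either a simulation block or input paths
    simulation: simulate.SimConfig | None = None
    genotypes: str | None = None
    phenotypes: str | None = None
    genetic_map: str | None = None
    groups: str | None = None
    qtl_catalog: str | None = None

    maf_threshold: float = 0.05
    ld_thresholds: dict[float, float] = field(
        default_factory=lambda: dict(kinship_ld.DEFAULT_LD_THRESHOLDS)
    )
    alpha: float = 0.05
    bf_max: float | None = 0.13
    membership_threshold: float = 0.70
    gd_thresholds: tuple[float, ...] = (0.5, 0.4, 0.2)

    k_min: int = 1
    k_max: int = 12
    k_runs: int = 10
    em_max_iter: int = 300

    n_perm_amova: int = 1000
    n_perm_ld: int = 10000
    n_perm_mlm: int = 0
    mlm_variance_mode: str = "P3D"

    seed: int = 0
    outdir: str = "ssrpop_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            qtl = [simulate.QTL(**q) for q in sim.pop("qtl_spec", [])]
            cfg.simulation = simulate.SimConfig(**sim, qtl_spec=qtl)
        return cfg

    def config_hash(self) -> str:
        payload = {k: repr(v) for k, v in vars(self).items() if k != "outdir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _load_inputs(cfg: RunConfig):
    if cfg.simulation is not None:
        sim = cfg.simulation
        panel, gmap, groups, pheno, truth = simulate.simulate_dataset(sim)
        return panel, gmap, groups, pheno, truth
    if cfg.genotypes is None:
        raise SSRPopError("config must provide a simulation block or a genotypes path")
    panel = sio.read_genotypes(cfg.genotypes)
    gmap = sio.read_map(cfg.genetic_map) if cfg.genetic_map else None
    groups = sio.read_groups(cfg.groups) if cfg.groups else None
    pheno = sio.read_phenotypes(cfg.phenotypes) if cfg.phenotypes else None
    return panel, gmap, groups, pheno, None


def run_all(cfg: RunConfig) -> dict:
    """Execute all stages in dependency order; returns the run manifest.

    Artifacts are written under ``cfg.outdir``; a stage failure aborts with
    the stage name while earlier artifacts remain on disk.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": {},
    }
    stage = "inputs"
    try:
        t0 = time.time()
        panel, gmap, groups, pheno, truth = _load_inputs(cfg)
        sio.write_genotypes(panel, out / "genotypes.tsv")
        if gmap is not None:
            sio.write_map(gmap, out / "map.tsv")
        if groups is not None:
            sio.write_groups(groups, out / "groups.tsv")
        if pheno is not None:
            sio.write_phenotypes(pheno, out / "phenotypes.tsv")
        manifest["stages"][stage] = {
            "n_accessions": panel.n_accessions,
            "n_loci": panel.n_loci,
            "n_markers": len(panel.marker_ids),
            "seconds": round(time.time() - t0, 3),
        }

        # ---- phenotypes ---------------------------------------------------
        if pheno is not None:
            stage = "phenotypes"
            t0 = time.time()
            desc = phenotypes.describe(pheno)
            desc.to_csv(out / "trait_summary.tsv", sep="\t")
            envs = pheno.environments
            r_within, _ = phenotypes.trait_correlations(pheno, "within_env", envs[0])
            r_within.to_csv(out / f"correlations_{envs[0]}.tsv", sep="\t")
            extra = {}
            if len(envs) >= 2:
                r_cross, _ = phenotypes.trait_correlations(pheno, "cross_env")
                r_cross.to_csv(out / "correlations_cross_env.tsv", sep="\t")
                anova = phenotypes.environment_anova(pheno)
                anova.to_csv(out / "environment_anova.tsv", sep="\t")
                extra["anova_min_p"] = float(anova["p"].min())
            manifest["stages"][stage] = {"n_rows": len(pheno.table), **extra,
                                         "seconds": round(time.time() - t0, 3)}

        # ---- diversity ----------------------------------------------------
        stage = "diversity"
        t0 = time.time()
        freqs = diversity.allele_frequencies(panel)
        pic_series, pic_sum = diversity.pic(freqs)
        h_series, h_sum = diversity.gene_diversity(freqs)
        stats_df = pd.DataFrame({"PIC": pic_series, "H": h_series})
        stats_df.to_csv(out / "marker_stats.tsv", sep="\t")
        summary = diversity.allele_summary(panel)
        summary.to_csv(out / "allele_summary.tsv", sep="\t", index=False)
        filtered = diversity.maf_filter(panel, cfg.maf_threshold)
        dist = diversity.distance_matrix(panel)
        dist.to_dataframe().to_csv(out / "distance_matrix.tsv", sep="\t")
        tree_u = diversity.upgma(dist)
        (out / "upgma.nwk").write_text(sio.write_newick(tree_u), encoding="utf-8")
        tree_nj = diversity.neighbor_joining(dist)
        (out / "nj.nwk").write_text(sio.write_newick(tree_nj), encoding="utf-8")
        clusters = diversity.cluster_report(tree_u, dist, cfg.gd_thresholds)
        (out / "clusters.json").write_text(json.dumps(clusters, indent=2, default=str))
        manifest["stages"][stage] = {
            "mean_band_freq": float(np.nanmean(freqs.band_freq.to_numpy())),
            "mean_PIC": pic_sum["mean"],
            "mean_H": h_sum["mean"],
            "n_loci_retained": filtered.n_loci,
            "n_loci_rare": panel.n_loci - filtered.n_loci,
            "mean_GD": dist.mean_offdiagonal(),
            "seconds": round(time.time() - t0, 3),
        }

        # ---- structure ----------------------------------------------------
        stage = "structure"
        t0 = time.time()
        pca_res = structure.pca(panel)
        pca_res.scores.iloc[:, :12].to_csv(out / "pca_scores.tsv", sep="\t")
        info = {"pc1_var": float(pca_res.variance_fraction[0])}
        if groups is not None and len({v for v in groups.labels.values()}) >= 2:
            amova_res = structure.amova(panel, groups, n_perm=cfg.n_perm_amova,
                                        seed=derive_seed(cfg.seed, "amova"))
            amova_res.summary().to_csv(out / "amova.tsv", sep="\t")
            fst, fst_p = structure.pairwise_fst(panel, groups, n_perm=min(cfg.n_perm_amova, 200),
                                               seed=derive_seed(cfg.seed, "pairwise_fst"))
            fst.to_csv(out / "pairwise_fst.tsv", sep="\t")
            info["phi_st"] = amova_res.phi_st
            info["amova_p"] = amova_res.p_value
        grid = structure.run_structure_grid(
            filtered, range(cfg.k_min, cfg.k_max + 1), n_runs=cfg.k_runs,
            max_iter=cfg.em_max_iter, seed=derive_seed(cfg.seed, "structure"),
        )
        for K, fits in grid.items():
            best = max(fits, key=lambda f: f.loglik)
            best.summary().to_csv(out / f"qmatrix_K{K}.tsv", sep="\t")
        if cfg.k_max - cfg.k_min >= 2:
            ev = structure.evanno_delta_k(grid)
            ev.to_csv(out / "evanno.tsv", sep="\t")
            k_hat = structure.best_k(ev)
            info["best_K"] = k_hat
            best_fit = max(grid[k_hat], key=lambda f: f.loglik)
            membership = structure.assign_membership(best_fit, cfg.membership_threshold)
            pd.DataFrame({"accession": best_fit.accession_ids, "membership": membership}).to_csv(
                out / "membership.tsv", sep="\t", index=False
            )
        manifest["stages"][stage] = {**info, "seconds": round(time.time() - t0, 3)}

        # ---- kinship / LD -------------------------------------------------
        stage = "kinship_ld"
        t0 = time.time()
        K_mat = kinship_ld.kinship_matrix(filtered)  # truncated, for reporting
        K_mlm = kinship_ld.kinship_matrix(filtered, truncate_negative=False)
        K_mat.to_dataframe().to_csv(out / "kinship.tsv", sep="\t")
        kin_hist = kinship_ld.kinship_distribution(K_mat)
        kin_hist.to_csv(out / "kinship_distribution.tsv", sep="\t", index=False)
        ld = kinship_ld.ld_pairwise(filtered, gmap, n_perm=cfg.n_perm_ld,
                                    seed=derive_seed(cfg.seed, "ld"))
        ld.pairs.to_csv(out / "ld_pairs.tsv", sep="\t", index=False)
        ld_sum = kinship_ld.ld_summary(ld, cfg.ld_thresholds)
        ld_sum.to_csv(out / "ld_summary.tsv", sep="\t", index=False)
        info = {"n_pairs": ld.n_pairs, "zero_kinship_fraction": float(kin_hist["fraction"][0])}
        if gmap is not None:
            try:
                decay = kinship_ld.ld_decay(ld, gmap)
                (out / "ld_decay.json").write_text(
                    json.dumps({"family": decay.family, "fits": decay.fits,
                                "crossings": {f: {str(k): v for k, v in c.items()}
                                              for f, c in decay.crossings.items()}},
                               indent=2, default=str)
                )
                info["decay_crossing_r2_0.1"] = decay.crossing(0.1)
            except SSRPopError as exc:
                log.warning("LD decay skipped: %s", exc)
                info["decay"] = f"skipped: {exc}"
        else:
            info["decay"] = "skipped: no genetic map"
        manifest["stages"][stage] = {**info, "seconds": round(time.time() - t0, 3)}

        # ---- association --------------------------------------------------
        if pheno is not None and len(pheno.environments) >= 1:
            stage = "association"
            t0 = time.time()
            norm = association.normalize_impute(pheno)
            q_for_assoc = None
            if "best_K" in manifest["stages"].get("structure", {}):
                k_hat = manifest["stages"]["structure"]["best_K"]
                best_fit = max(grid[k_hat], key=lambda f: f.loglik)
                q_for_assoc = pd.DataFrame(best_fit.Q, index=best_fit.accession_ids)
            consensus_counts = {}
            for trait in sio.TRAITS:
                per_env = []
                for env in norm.environments:
                    y = norm.env(env)[trait]
                    res = association.mlm_scan(
                        filtered, y, Q=q_for_assoc, K=K_mlm,
                        variance_mode=cfg.mlm_variance_mode, n_perm=cfg.n_perm_mlm,
                        seed=derive_seed(cfg.seed, f"mlm:{trait}:{env}"),
                        trait=trait, environment=env,
                    )
                    res.table.to_csv(out / f"assoc_mlm_{trait}_{env}.tsv", sep="\t")
                    per_env.append(res)
                if len(per_env) >= 2:
                    cons = association.cross_environment_consensus(
                        per_env[0], per_env[1], alpha=cfg.alpha, bf_max=None
                    )
                    catalog = None
                    if cfg.qtl_catalog:
                        catalog = sio._read_table(cfg.qtl_catalog)
                    cons = association.known_qtl_join(cons, catalog)
                    cons.to_csv(out / f"consensus_{trait}.tsv", sep="\t")
                    consensus_counts[trait] = len(cons)
            manifest["stages"][stage] = {"consensus_counts": consensus_counts,
                                         "seconds": round(time.time() - t0, 3)}
    except Exception as exc:
        raise SSRPopError(f"stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (out / "report.md").write_text(report(manifest), encoding="utf-8")
    return manifest


def report(manifest: dict) -> str:
    """Render the run manifest into a human-readable summary."""
    lines = ["# ssrpop run report", "",
             f"config hash: {manifest.get('config_hash', 'absent')}  seed: {manifest.get('seed', 'absent')}", ""]
    for name in ("inputs", "phenotypes", "diversity", "structure", "kinship_ld", "association"):
        lines.append(f"## {name}")
        info = manifest.get("stages", {}).get(name)
        if info is None:
            lines.append("(absent)")
        else:
            for k, v in info.items():
                lines.append(f"- {k}: {v}")
        lines.append("")
    return "\n".join(lines)
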