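"""Synthetic multi-cohort generator with planted, recorded signals.

Generates paired tumor/normal expression cohorts together with a gene
catalog, a PPI network, per-cohort CNV/methylation matrices and a
:class:`TruthLedger` recording every planted signal, so the whole analysis
pipeline can be exercised and validated without any external download.

Expression model (per gene g, pair i)::

    normal  N_gi = exp(mu_g + eps)
    tumor   T_gi = exp(mu_g + delta_g * ln2 + eps')

with ``mu_g ~ Normal(baseline_log_mean, baseline_log_sd)`` and
``eps, eps' ~ Normal(0, noise_sd)`` independent across genes, pairs and the
two tissues.  ``delta_g`` is the planted per-gene effect on the log2 scale:
zero unless the gene is planted differentially expressed (DE) in that
cohort, in which case ``delta_g = s * e`` with random sign ``s`` and
``e ~ Exponential(mean = effect_scale[category(g)])``.

Planted structures:

* disjoint gene categories (TF, RBP, lncRNA, allOnco, a COSMIC-like
  mutation class) with category-specific DE probability and effect scale;
* hub RBPs: designated DE RBPs with a boosted effect, each wired to a fixed
  number of partners of which a set fraction are allOnco genes and a set
  fraction are force-planted DE in every cohort, on top of an
  Erdos-Renyi background network;
* CNV coupling: for a fraction of each cohort's planted-DE RBPs, the CNV
  value of a tumor sample is the realized per-pair log2 expression change
  plus Gaussian noise calibrated so the population Spearman correlation is
  approximately ``cnv_rho_target``; methylation is independent noise,
  mirroring a genetic-not-epigenetic attribution;
* per-cohort tissue-specific sets planted DE in the matched cohort only,
  with a fixed fraction of them under-expressed;
* pathways: for each declared similar cohort pair, one pathway whose member
  genes receive positively correlated effects in the two cohorts (shared
  effect plus small jitter) and independent effects elsewhere.

All randomness flows from a single seed through named, ordered substreams
(layout, network, then per-cohort planting / expression / CNV /
methylation), so identical config + seed gives bit-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .io import GeneCatalog, MolecularMatrix, PairedCohort, PPINetwork

LN2 = float(np.log(2.0))


class ConfigurationError(ValueError):
    """Raised when a SimConfig is infeasible."""


def _default_category_sizes() -> dict[str, int]:
    return {
        "TF": 400,
        "RBP": 500,
        "lncRNA": 120,
        "allOnco": 500,
        "COSMIC_frameshift": 100,
    }


def _default_de_prob() -> dict[str, float]:
    return {
        "other": 0.10,
        "TF": 0.10,
        "RBP": 0.30,
        "lncRNA": 0.03,
        "allOnco": 0.35,
        "COSMIC_frameshift": 0.20,
    }


def _default_effect_scale() -> dict[str, float]:
    # Mean |log2 effect| per category; ordering allOnco > TF > lncRNA > RBP
    # reproduces the amplitude pattern the analysis is meant to detect.
    return {
        "other": 1.2,
        "TF": 2.0,
        "RBP": 1.0,
        "lncRNA": 1.5,
        "allOnco": 2.6,
        "COSMIC_frameshift": 1.2,
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic multi-cohort study."""

    n_cohorts: int = 4
    cohort_ids: list[str] | None = None
    n_genes: int = 5000
    n_pairs: int = 30
    category_sizes: dict[str, int] = field(default_factory=_default_category_sizes)
    de_prob: dict[str, float] = field(default_factory=_default_de_prob)
    effect_scale: dict[str, float] = field(default_factory=_default_effect_scale)
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.0
    noise_sd: float = 0.2
    # hub RBPs (cascade signal)
    n_hub_rbps: int = 5
    hub_neighbor_count: int = 30
    hub_onco_frac: float = 0.5
    hub_de_frac: float = 0.7
    hub_min_effect: float = 3.5
    mean_degree: float = 6.0
    # CNV / methylation (attribution signal)
    cnv_coupled_frac: float = 0.5
    cnv_rho_target: float = 0.6
    cnv_null_sd: float = 0.5
    # tissue-specific sets
    tissue_set_size: int = 100
    tissue_under_frac: float = 0.8
    tissue_effect_scale: float = 1.5
    # pathway coupling (clustering signal)
    similar_cohort_pairs: list[tuple[str, str]] | None = None
    pathway_sizes: dict[str, int] = field(
        default_factory=lambda: {"pathway_shared": 60, "pathway_background": 60}
    )
    pathway_effect_scale: float = 1.5
    pathway_jitter_sd: float = 0.3
    seed: int = 0

    def resolved_cohort_ids(self) -> list[str]:
        if self.cohort_ids is not None:
            return list(self.cohort_ids)
        return [f"C{i + 1}" for i in range(self.n_cohorts)]

    def resolved_similar_pairs(self) -> list[tuple[str, str]]:
        ids = self.resolved_cohort_ids()
        if self.similar_cohort_pairs is not None:
            return [tuple(p) for p in self.similar_cohort_pairs]
        return [(ids[0], ids[1])] if len(ids) >= 2 else []

    def validate(self) -> None:
        errs: list[str] = []
        ids = self.resolved_cohort_ids()
        if self.n_cohorts < 2:
            errs.append("n_cohorts must be >= 2")
        if len(ids) != self.n_cohorts or len(set(ids)) != len(ids):
            errs.append("cohort_ids must be n_cohorts unique ids")
        if self.n_genes < 100:
            errs.append("n_genes must be >= 100")
        if self.n_pairs < 2:
            errs.append("n_pairs must be >= 2")
        if sum(self.category_sizes.values()) > self.n_genes:
            errs.append("category sizes sum exceeds n_genes")
        for name, p in self.de_prob.items():
            if not 0.0 <= p <= 1.0:
                errs.append(f"de_prob[{name}] outside [0, 1]")
        for name, s in self.effect_scale.items():
            if s <= 0:
                errs.append(f"effect_scale[{name}] must be positive")
        for prob_name in ("hub_onco_frac", "hub_de_frac", "cnv_coupled_frac",
                          "tissue_under_frac"):
            if not 0.0 <= getattr(self, prob_name) <= 1.0:
                errs.append(f"{prob_name} outside [0, 1]")
        if not 0.0 < self.cnv_rho_target < 1.0:
            errs.append("cnv_rho_target must be in (0, 1)")
        if self.noise_sd <= 0:
            errs.append("noise_sd must be positive")
        if self.hub_neighbor_count > self.n_genes - 1:
            errs.append("hub_neighbor_count exceeds n_genes - 1")
        if self.n_hub_rbps > self.category_sizes.get("RBP", 0):
            errs.append("n_hub_rbps exceeds the RBP category size")
        n_other = self.n_genes - sum(self.category_sizes.values())
        n_reserved = (
            self.n_cohorts * self.tissue_set_size + sum(self.pathway_sizes.values())
        )
        if n_reserved > n_other:
            errs.append(
                "tissue sets and pathways need more plain genes than available "
                f"({n_reserved} > {n_other})"
            )
        pairs = self.resolved_similar_pairs()
        for a, b in pairs:
            if a not in ids or b not in ids or a == b:
                errs.append(f"similar cohort pair ({a}, {b}) is invalid")
        if len(pairs) > len(self.pathway_sizes):
            errs.append("fewer pathways than similar cohort pairs")
        if errs:
            raise ConfigurationError("; ".join(errs))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort_ids"] = self.resolved_cohort_ids()
        d["similar_cohort_pairs"] = [list(p) for p in self.resolved_similar_pairs()]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown SimConfig keys: {sorted(unknown)}")
        cfg = cls(**d)
        if cfg.similar_cohort_pairs is not None:
            cfg.similar_cohort_pairs = [tuple(p) for p in cfg.similar_cohort_pairs]
        return cfg


@dataclass
class TruthLedger:
    """Planted parameters of a synthetic dataset, consumed only by tests.

    ``de`` maps cohort -> gene -> planted log2 effect; ``categories`` maps
    category -> member genes.  The ledger is sufficient to recompute every
    planted rate exactly.
    """

    seed: int
    categories: dict[str, list[str]]
    de: dict[str, dict[str, float]]
    hub_rbps: list[str]
    hub_partners: dict[str, list[str]]
    forced_de_partners: list[str]
    cnv_coupled: dict[str, list[str]]
    tissue: dict[str, dict]
    similar_cohort_pairs: list[list[str]]
    coupled_pathways: dict[str, list[str]]
    pathways: dict[str, list[str]]

    def category_of(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for cat, genes in self.categories.items():
            for g in genes:
                out[g] = cat
        return out

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "TruthLedger":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


@dataclass
class SimResult:
    cohorts: list[PairedCohort]
    catalog: GeneCatalog
    network: PPINetwork
    mats: dict[str, dict[str, MolecularMatrix]]
    truth: TruthLedger


def _signed_exponential(rng: np.random.Generator, scale: float, size: int) -> np.ndarray:
    mag = rng.exponential(scale, size=size)
    sign = rng.choice([-1.0, 1.0], size=size)
    return sign * mag


def cnv_noise_sd(noise_sd: float, rho_target: float) -> float:
    """Std-dev of the additive CNV noise giving Spearman ~ rho_target.

    The per-pair log2 expression change of a gene has (pseudocount aside)
    standard deviation ``sigma_x = sqrt(2) * noise_sd / ln 2``.  For a
    bivariate normal, Spearman rho_s relates to Pearson rho_p by
    ``rho_s = (6 / pi) * arcsin(rho_p / 2)``; the noise sd solves the
    attenuation equation for the corresponding Pearson target.
    """
    sigma_x = np.sqrt(2.0) * noise_sd / LN2
    rho_p = 2.0 * np.sin(np.pi * rho_target / 6.0)
    return float(sigma_x * np.sqrt(1.0 / rho_p**2 - 1.0))


def _sample_expression(
    rng: np.random.Generator,
    delta: np.ndarray,
    n_pairs: int,
    baseline_log_mean: float,
    baseline_log_sd: float,
    noise_sd: float,
) -> tuple[np.ndarray, np.ndarray]:
    n_genes = delta.shape[0]
    mu = rng.normal(baseline_log_mean, baseline_log_sd, size=n_genes)
    eps_n = rng.normal(0.0, noise_sd, size=(n_genes, n_pairs))
    eps_t = rng.normal(0.0, noise_sd, size=(n_genes, n_pairs))
    normal = np.exp(mu[:, None] + eps_n)
    tumor = np.exp(mu[:, None] + delta[:, None] * LN2 + eps_t)
    return tumor, normal


def _build_cohort(
    cohort_id: str, genes: list[str], tumor: np.ndarray, normal: np.ndarray
) -> PairedCohort:
    n_pairs = tumor.shape[1]
    samples: list[str] = []
    pairs: list[tuple[str, str, str]] = []
    expr = np.empty((len(genes), 2 * n_pairs))
    for i in range(n_pairs):
        patient = f"{cohort_id}-P{i:03d}"
        tcol, ncol = f"{patient}-T", f"{patient}-N"
        samples.extend([tcol, ncol])
        pairs.append((patient, tcol, ncol))
        expr[:, 2 * i] = tumor[:, i]
        expr[:, 2 * i + 1] = normal[:, i]
    return PairedCohort(
        cohort_id=cohort_id, genes=genes, samples=samples, expr=expr, pairs=pairs
    )


def generate(config: SimConfig) -> SimResult:
    """Generate the full synthetic dataset described by ``config``."""
    config.validate()
    ids = config.resolved_cohort_ids()
    n = config.n_cohorts
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(2 + 4 * n)
    layout_rng = np.random.default_rng(children[0])
    net_child = children[1]
    plant_rngs = [np.random.default_rng(children[2 + i]) for i in range(n)]
    expr_rngs = [np.random.default_rng(children[2 + n + i]) for i in range(n)]
    cnv_rngs = [np.random.default_rng(children[2 + 2 * n + i]) for i in range(n)]
    meth_rngs = [np.random.default_rng(children[2 + 3 * n + i]) for i in range(n)]

    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    gene_idx = {g: i for i, g in enumerate(genes)}

    # --- layout: categories, tissue sets, pathways, hubs ------------------
    perm = list(layout_rng.permutation(config.n_genes))
    cursor = 0
    categories: dict[str, list[str]] = {}
    cat_of = np.full(config.n_genes, "other", dtype=object)
    for cat, size in config.category_sizes.items():
        members = [genes[perm[cursor + j]] for j in range(size)]
        cursor += size
        categories[cat] = sorted(members)
        for g in members:
            cat_of[gene_idx[g]] = cat
    plain_pool = [genes[perm[j]] for j in range(cursor, config.n_genes)]
    categories["other"] = sorted(plain_pool)

    pool_cursor = 0
    tissue: dict[str, dict] = {}
    for cid in ids:
        tgenes = plain_pool[pool_cursor : pool_cursor + config.tissue_set_size]
        pool_cursor += config.tissue_set_size
        n_under = int(round(config.tissue_under_frac * len(tgenes)))
        tissue[cid] = {
            "set_name": f"tissue_{cid}",
            "genes": list(tgenes),
            "under": list(tgenes[:n_under]),
        }

    pathways: dict[str, list[str]] = {}
    for pname, psize in config.pathway_sizes.items():
        pathways[pname] = plain_pool[pool_cursor : pool_cursor + psize]
        pool_cursor += psize

    similar_pairs = config.resolved_similar_pairs()
    pathway_names = list(config.pathway_sizes)
    coupled_pathways = {
        pathway_names[i]: list(pair) for i, pair in enumerate(similar_pairs)
    }

    # Pathway effects, drawn in a fixed (pathway, cohort) order.  Coupled
    # pathways share one effect vector (plus jitter) between their two
    # cohorts; everything else is independent.
    pathway_delta: dict[str, dict[str, np.ndarray]] = {}
    for pname in pathway_names:
        members = pathways[pname]
        per_cohort: dict[str, np.ndarray] = {}
        pair = coupled_pathways.get(pname)
        if pair is not None:
            shared = _signed_exponential(
                layout_rng, config.pathway_effect_scale, len(members)
            )
        for cid in ids:
            if pair is not None and cid in pair:
                per_cohort[cid] = shared + layout_rng.normal(
                    0.0, config.pathway_jitter_sd, size=len(members)
                )
            else:
                per_cohort[cid] = _signed_exponential(
                    layout_rng, config.pathway_effect_scale, len(members)
                )
        pathway_delta[pname] = per_cohort

    # Hubs and their wired partners.
    rbp_members = categories.get("RBP", [])
    hubs = (
        sorted(
            str(g)
            for g in layout_rng.choice(
                rbp_members, size=config.n_hub_rbps, replace=False
            )
        )
        if config.n_hub_rbps > 0
        else []
    )
    onco_pool = [g for g in categories.get("allOnco", []) if g not in hubs]
    free_plain = plain_pool[pool_cursor:]
    hub_partners: dict[str, list[str]] = {}
    forced_de: list[str] = []
    used: set[str] = set(hubs)
    n_onco_per_hub = int(round(config.hub_onco_frac * config.hub_neighbor_count))
    for hub in hubs:
        avail_onco = [g for g in onco_pool if g not in used]
        avail_plain = [g for g in free_plain if g not in used]
        if len(avail_onco) < n_onco_per_hub or len(avail_plain) < (
            config.hub_neighbor_count - n_onco_per_hub
        ):
            raise ConfigurationError("not enough genes to wire hub neighborhoods")
        part_onco = [
            str(g)
            for g in layout_rng.choice(avail_onco, size=n_onco_per_hub, replace=False)
        ]
        part_plain = [
            str(g)
            for g in layout_rng.choice(
                avail_plain,
                size=config.hub_neighbor_count - n_onco_per_hub,
                replace=False,
            )
        ]
        partners = part_onco + part_plain
        used.update(partners)
        hub_partners[hub] = partners
        n_forced = int(round(config.hub_de_frac * len(partners)))
        forced = [str(g) for g in layout_rng.choice(partners, size=n_forced, replace=False)]
        forced_de.extend(forced)
    forced_de_set = set(forced_de)

    # --- per-cohort planting ----------------------------------------------
    de: dict[str, dict[str, float]] = {}
    deltas: dict[str, np.ndarray] = {}
    for ci, cid in enumerate(ids):
        rng = plant_rngs[ci]
        delta = np.zeros(config.n_genes)
        planted: set[str] = set()

        tinfo = tissue[cid]
        under = set(tinfo["under"])
        for g in tinfo["genes"]:
            mag = rng.exponential(config.tissue_effect_scale)
            delta[gene_idx[g]] = -mag if g in under else mag
            planted.add(g)

        for pname in pathway_names:
            vec = pathway_delta[pname][cid]
            for g, d in zip(pathways[pname], vec):
                delta[gene_idx[g]] = d
                planted.add(g)

        for hub in hubs:
            mag = config.hub_min_effect + rng.exponential(
                config.effect_scale.get("RBP", 1.0)
            )
            sign = rng.choice([-1.0, 1.0])
            delta[gene_idx[hub]] = sign * mag
            planted.add(hub)

        for g in forced_de:
            if g in planted:
                continue
            scale = config.effect_scale.get(str(cat_of[gene_idx[g]]), 1.0)
            delta[gene_idx[g]] = float(_signed_exponential(rng, scale, 1)[0])
            planted.add(g)

        # Category-probability DE for everything not already planted.
        u = rng.random(config.n_genes)
        mags = rng.exponential(1.0, size=config.n_genes)
        signs = rng.choice([-1.0, 1.0], size=config.n_genes)
        for gi, g in enumerate(genes):
            if g in planted or g in forced_de_set:
                continue
            cat = str(cat_of[gi])
            if u[gi] < config.de_prob.get(cat, config.de_prob.get("other", 0.0)):
                scale = config.effect_scale.get(cat, 1.0)
                delta[gi] = signs[gi] * mags[gi] * scale
        de[cid] = {
            genes[gi]: float(delta[gi])
            for gi in range(config.n_genes)
            if delta[gi] != 0.0
        }
        deltas[cid] = delta

    # --- expression --------------------------------------------------------
    cohorts: list[PairedCohort] = []
    tumor_by_cohort: dict[str, np.ndarray] = {}
    normal_by_cohort: dict[str, np.ndarray] = {}
    for ci, cid in enumerate(ids):
        tumor, normal = _sample_expression(
            expr_rngs[ci],
            deltas[cid],
            config.n_pairs,
            config.baseline_log_mean,
            config.baseline_log_sd,
            config.noise_sd,
        )
        tumor_by_cohort[cid] = tumor
        normal_by_cohort[cid] = normal
        cohorts.append(_build_cohort(cid, genes, tumor, normal))

    # --- network ------------------------------------------------------------
    import networkx as nx

    net_seed = int(net_child.generate_state(1)[0] & 0x7FFFFFFF)
    p_edge = min(1.0, config.mean_degree / max(1, config.n_genes - 1))
    g_bg = nx.fast_gnp_random_graph(config.n_genes, p_edge, seed=net_seed)
    edges = {
        (genes[a], genes[b]) if genes[a] <= genes[b] else (genes[b], genes[a])
        for a, b in g_bg.edges()
    }
    for hub, partners in hub_partners.items():
        for p in partners:
            edges.add((hub, p) if hub <= p else (p, hub))
    network = PPINetwork(nodes=set(genes), edges=edges)

    # --- CNV / methylation --------------------------------------------------
    mats: dict[str, dict[str, MolecularMatrix]] = {}
    cnv_coupled: dict[str, list[str]] = {}
    sigma_eta = cnv_noise_sd(config.noise_sd, config.cnv_rho_target)
    rbp_set = set(rbp_members)
    for ci, cid in enumerate(ids):
        rng = cnv_rngs[ci]
        de_rbps = sorted(g for g in de[cid] if g in rbp_set)
        n_coupled = int(round(config.cnv_coupled_frac * len(de_rbps)))
        coupled = (
            sorted(str(g) for g in rng.choice(de_rbps, size=n_coupled, replace=False))
            if n_coupled > 0
            else []
        )
        cnv_coupled[cid] = coupled
        x = np.log2(
            (tumor_by_cohort[cid] + 1.0) / (normal_by_cohort[cid] + 1.0)
        )
        cnv = rng.normal(0.0, config.cnv_null_sd, size=x.shape)
        coupled_idx = [gene_idx[g] for g in coupled]
        if coupled_idx:
            cnv[coupled_idx, :] = x[coupled_idx, :] + rng.normal(
                0.0, sigma_eta, size=(len(coupled_idx), config.n_pairs)
            )
        tumor_samples = cohorts[ci].tumor_columns
        meth = meth_rngs[ci].beta(2.0, 2.0, size=x.shape)
        mats[cid] = {
            "cnv": MolecularMatrix("cnv", genes, tumor_samples, cnv),
            "methylation": MolecularMatrix(
                "methylation", genes, tumor_samples, meth
            ),
        }

    # --- catalog ------------------------------------------------------------
    sets: dict[str, set[str]] = {c: set(m) for c, m in categories.items()}
    set_kind = {c: "category" for c in categories}
    tissue_to_cohort: dict[str, str] = {}
    for cid, tinfo in tissue.items():
        sets[tinfo["set_name"]] = set(tinfo["genes"])
        set_kind[tinfo["set_name"]] = "tissue"
        tissue_to_cohort[tinfo["set_name"]] = cid
    for pname, members in pathways.items():
        sets[pname] = set(members)
        set_kind[pname] = "pathway"
    catalog = GeneCatalog(
        universe=set(genes),
        sets=sets,
        set_kind=set_kind,
        tissue_to_cohort=tissue_to_cohort,
    )

    truth = TruthLedger(
        seed=config.seed,
        categories={c: sorted(m) for c, m in categories.items()},
        de=de,
        hub_rbps=list(hubs),
        hub_partners=hub_partners,
        forced_de_partners=sorted(forced_de_set),
        cnv_coupled=cnv_coupled,
        tissue=tissue,
        similar_cohort_pairs=[list(p) for p in similar_pairs],
        coupled_pathways=coupled_pathways,
        pathways={p: list(m) for p, m in pathways.items()},
    )
    return SimResult(
        cohorts=cohorts, catalog=catalog, network=network, mats=mats, truth=truth
    )


def null_cohort(
    n_genes: int, n_pairs: int, seed: int, cohort_id: str = "NULL",
    baseline_log_mean: float = 5.0, baseline_log_sd: float = 1.0,
    noise_sd: float = 0.2,
) -> PairedCohort:
    """A single cohort with no planted signal (all effects zero).

    Used by type-I-error suites: tumor and normal columns are exchangeable
    in distribution for every gene.
    """
    if n_pairs < 2:
        raise ConfigurationError("n_pairs must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    genes = [f"G{i:05d}" for i in range(n_genes)]
    tumor, normal = _sample_expression(
        rng, np.zeros(n_genes), n_pairs, baseline_log_mean, baseline_log_sd,
        noise_sd,
    )
    return _build_cohort(cohort_id, genes, tumor, normal)


def write_dataset(result: SimResult, outdir: str) -> dict[str, str]:
    """Write the full file set (core formats + truth.json); returns paths."""
    import os

    from . import io as dio

    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}
    for cohort in result.cohorts:
        cid = cohort.cohort_id
        expr = os.path.join(outdir, f"{cid}_expression.tsv")
        pairs = os.path.join(outdir, f"{cid}_pairs.tsv")
        dio.write_expression(cohort, expr, pairs)
        paths[f"{cid}_expression"] = expr
        paths[f"{cid}_pairs"] = pairs
        for assay, mat in result.mats[cid].items():
            mpath = os.path.join(outdir, f"{cid}_{assay}.tsv")
            dio.write_molecular(mat, mpath)
            paths[f"{cid}_{assay}"] = mpath
    for kind, fname in (
        ("category", "categories.gmt"),
        ("tissue", "tissue.gmt"),
        ("pathway", "pathways.gmt"),
    ):
        path = os.path.join(outdir, fname)
        dio.write_gmt(result.catalog, path, kind=kind)
        paths[fname] = path
    net_path = os.path.join(outdir, "network.tsv")
    dio.write_network(result.network, net_path)
    paths["network"] = net_path
    truth_path = os.path.join(outdir, "truth.json")
    result.truth.to_json(truth_path)
    paths["truth"] = truth_path
    return paths
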