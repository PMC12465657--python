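"""Synthetic genotypes, phenotypes and annotation layers for the pipeline.

The generator emulates the statistical structure the downstream analysis
assumes, at desk scale: a dense "WGS-like" marker panel containing a
designated medium-density array subset; linkage disequilibrium from a
first-order Markov haplotype chain along each chromosome; QTL effects drawn
from a four-component normal mixture (null plus variances 1e-4/1e-3/1e-2 of
the genetic variance); trait phenotypes with contemporary-group fixed
effects, a dam-age polynomial, an optional maternal random effect keyed by
dam, and birth years for forward splitting; plus annotation layers (gene
models with exon/UTR structure, named gene sets, QTL intervals) with
controllable enrichment of true QTL.

Phenotypes are generated on a unit core-variance scale: the variance of
genetic + maternal + residual parts is 1, so ``h2`` and ``h2_maternal`` are
direct variance shares; contemporary-group effects (SD ``cg_sd``) sit on top
as fixed-effect structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from gpsel.geno_grm import GenotypeMatrix
from gpsel.ld_select import MarkerSet

MIXTURE_SCALES = (0.0, 1e-4, 1e-3, 1e-2)


class SimConfigError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass
class SimConfig:
    n_individuals: int = 1000
    n_markers_dense: int = 5000
    n_markers_panel: int = 1000
    n_chromosomes: int = 5
    ld_rho: float = 0.7
    maf_range: tuple = (0.05, 0.5)
    n_qtl: int = 100
    mixture_props: tuple = (0.0, 0.5, 0.3, 0.2)
    h2: float = 0.3
    h2_maternal: float = 0.0
    n_cg: int = 20
    cg_sd: float = 1.0
    birth_years: tuple = tuple(range(2010, 2020))
    seed: int = 0
    # nuisance structure not pinned down by the study design; defaults chosen
    # as field-realistic values and configurable
    progeny_per_dam: int = 4
    dam_age_range: tuple = (2.0, 12.0)
    dam_age_beta: tuple = (0.2, -0.015)
    age_range_days: tuple = (300, 700)
    marker_spacing_bp: int = 1000
    # size of the founder haplotype pool individuals draw from; None means a
    # fully outbred sample (2 * n_individuals independent haplotypes). A small
    # pool emulates the strong relatedness of a livestock population with a
    # small effective size (e.g. ~200 haplotypes for Ne ~ 100).
    n_founder_haplotypes: int | None = None
    gene_fraction: float = 0.3
    n_genes_per_chrom: int = 20
    n_gene_sets: int = 3
    qtl_enrichment: float = 0.5
    qtl_interval_halfwidth_bp: int = 5000

    def validate(self) -> None:
        if not (0 < self.n_markers_panel <= self.n_markers_dense):
            raise SimConfigError("need 0 < n_markers_panel <= n_markers_dense")
        if not 0 <= self.ld_rho < 1:
            raise SimConfigError("ld_rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise SimConfigError("maf_range must be within (0, 0.5]")
        if abs(sum(self.mixture_props) - 1.0) > 1e-12:
            raise SimConfigError("mixture_props must sum to 1")
        if any(p < 0 for p in self.mixture_props):
            raise SimConfigError("mixture_props must be non-negative")
        if not (0 <= self.h2 < 1 and 0 <= self.h2_maternal < 1):
            raise SimConfigError("h2 and h2_maternal must be in [0, 1)")
        if self.h2 + self.h2_maternal >= 1:
            raise SimConfigError("h2 + h2_maternal must be < 1")
        if self.n_qtl > self.n_markers_dense:
            raise SimConfigError("n_qtl exceeds n_markers_dense")
        for name in ("n_individuals", "n_markers_dense", "n_chromosomes"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise SimConfigError(f"{name} must be a positive integer")


@dataclass
class AnnotationBundle:
    """Gene models, named gene sets, and labelled QTL intervals.

    ``gene_models``: feature table (gene_id, chrom, start, end, strand,
    feature, biotype) with 1-based inclusive coordinates as in GFF3.
    ``gene_sets``: mapping set name -> list of gene ids.
    ``qtl_intervals``: chrom, start, end (0-based half-open) and trait_class.
    """

    gene_models: pd.DataFrame
    gene_sets: dict
    qtl_intervals: pd.DataFrame

    def write_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for _, r in self.gene_models.iterrows():
                attrs = (f"ID={r.gene_id}" if r.feature in ("gene", "ncRNA_gene")
                         else f"Parent={r.gene_id}")
                fh.write(f"{r.chrom}\tgpsel\t{r.feature}\t{r.start}\t{r.end}\t.\t"
                         f"{r.strand}\t.\t{attrs}\n")

    def write_qtl_bed(self, path) -> None:
        self.qtl_intervals.to_csv(path, sep="\t", header=False, index=False,
                                  columns=["chrom", "start", "end", "trait_class"])

    def write_gene_sets(self, path) -> None:
        rows = [(name, g) for name, genes in self.gene_sets.items() for g in genes]
        pd.DataFrame(rows, columns=["set_name", "gene_id"]).to_csv(
            path, sep="\t", index=False)


@dataclass
class SimOutput:
    genotypes: GenotypeMatrix
    panel_ids: MarkerSet
    qtl_effects: np.ndarray
    true_breeding_values: np.ndarray
    phenotypes: pd.DataFrame
    annotations: AnnotationBundle
    config: SimConfig


def _chrom_sizes(cfg: SimConfig) -> np.ndarray:
    base = cfg.n_markers_dense // cfg.n_chromosomes
    sizes = np.full(cfg.n_chromosomes, base, dtype=int)
    sizes[: cfg.n_markers_dense - base * cfg.n_chromosomes] += 1
    return sizes


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Markov-chain haplotypes with adjacent-allele correlation ``ld_rho``.

    Each chromosome is a first-order chain over allele indicators: with
    allele2 frequencies p drawn uniformly from ``maf_range``, the transition
    P(X_j=1 | X_{j-1}=x) = p_j + rho*sqrt(p_j q_j / p_{j-1} q_{j-1})*(x - p_{j-1})
    (clipped into [0,1]) gives exact correlation rho at equal frequencies, so
    pairwise r2 decays geometrically with marker distance. Genotypes are the
    sum of two independent haplotypes.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    pool = cfg.n_founder_haplotypes
    n2 = 2 * cfg.n_individuals if pool is None else pool
    if pool is not None and pool < 2:
        raise SimConfigError("n_founder_haplotypes must be >= 2")
    if pool is None:
        ia = np.arange(cfg.n_individuals)
        ib = np.arange(cfg.n_individuals, 2 * cfg.n_individuals)
    else:
        # each individual draws two distinct haplotypes from the shared pool;
        # haplotype sharing between individuals creates relatedness
        ia = rng.integers(0, pool, size=cfg.n_individuals)
        ib = (ia + 1 + rng.integers(0, pool - 1, size=cfg.n_individuals)) % pool
    cols, meta = [], []
    for chrom_i, m_c in enumerate(_chrom_sizes(cfg), start=1):
        p = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m_c)
        hap = np.empty((n2, m_c), dtype=np.int8)
        hap[:, 0] = rng.random(n2) < p[0]
        for j in range(1, m_c):
            slope = cfg.ld_rho * np.sqrt(p[j] * (1 - p[j]) / (p[j - 1] * (1 - p[j - 1])))
            prob = np.clip(p[j] + slope * (hap[:, j - 1] - p[j - 1]), 0.0, 1.0)
            hap[:, j] = rng.random(n2) < prob
        calls = hap[ia] + hap[ib]
        cols.append(calls.astype(np.int8))
        gaps = rng.integers(1, 2 * cfg.marker_spacing_bp, size=m_c)
        pos = np.cumsum(gaps)
        meta.append(pd.DataFrame({
            "id": [f"snp{chrom_i}_{j}" for j in range(m_c)],
            "chrom": chrom_i,
            "pos": pos,
            "a1": "A",
            "a2": "B",
        }))
    markers = pd.concat(meta, ignore_index=True)
    ids = np.array([f"ind{i}" for i in range(cfg.n_individuals)], dtype=object)
    return GenotypeMatrix(np.hstack(cols), ids, markers)


def panel_subset(geno: GenotypeMatrix, cfg: SimConfig) -> MarkerSet:
    """The designated medium-density array subset: evenly spaced markers."""
    idx = np.linspace(0, geno.n_markers - 1, cfg.n_markers_panel).round().astype(int)
    idx = np.unique(idx)
    return MarkerSet(geno.markers["id"].to_numpy(object)[idx], "panel")


def assign_qtl_effects(geno: GenotypeMatrix, cfg: SimConfig) -> np.ndarray:
    """Per-marker true effects from the null + three-variance normal mixture.

    ``n_qtl`` markers are sampled without replacement; each draws a scale
    c in {0, 1e-4, 1e-3, 1e-2} by ``mixture_props`` and an effect
    N(0, c * sigma_g^2) on the standardized-genotype scale, converted to a
    per-dosage effect. Effects are rescaled post hoc so the in-sample variance
    of the breeding values equals ``h2`` exactly (core variance scale).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1)
    m = geno.n_markers
    effects = np.zeros(m)
    qtl_idx = rng.choice(m, size=cfg.n_qtl, replace=False)
    comp = rng.choice(4, size=cfg.n_qtl, p=np.asarray(cfg.mixture_props))
    scales = np.asarray(MIXTURE_SCALES)[comp]
    raw = rng.standard_normal(cfg.n_qtl) * np.sqrt(scales)
    calls = geno.calls[:, qtl_idx].astype(np.float64)
    p = calls.mean(axis=0) / 2.0
    sd = np.sqrt(np.maximum(2 * p * (1 - p), 1e-12))
    effects[qtl_idx] = raw / sd  # per-dosage scale
    g = geno.calls.astype(np.float64)[:, qtl_idx] @ effects[qtl_idx]
    var_g = g.var()
    if var_g > 0 and cfg.h2 > 0:
        effects *= np.sqrt(cfg.h2 / var_g)
    elif cfg.h2 == 0:
        effects[:] = 0.0
    return effects


def true_breeding_values(geno: GenotypeMatrix, effects: np.ndarray) -> np.ndarray:
    g = geno.calls.astype(np.float64) @ effects
    return g - g.mean()


def simulate_phenotypes(geno: GenotypeMatrix, effects: np.ndarray,
                        cfg: SimConfig) -> pd.DataFrame:
    """Trait records: CG effect + dam-age polynomial + genetics + maternal + e.

    y = CG + b1*dam_age + b2*dam_age^2 + sum(x * effect) + maternal(dam) + e
    with maternal ~ N(0, h2_maternal) shared within dam and
    e ~ N(0, 1 - h2 - h2_maternal). Dam identifiers, birth years, sexes, ages
    and contemporary groups are assigned at random from the config.
    """
    cfg.validate()
    if len(effects) != geno.n_markers:
        raise ValueError("effects not aligned to genotype markers")
    rng = np.random.default_rng(cfg.seed + 2)
    n = geno.n_individuals
    tbv = true_breeding_values(geno, effects)

    n_dams = max(1, n // cfg.progeny_per_dam)
    dam_idx = rng.integers(0, n_dams, size=n)
    maternal_fx = rng.standard_normal(n_dams) * np.sqrt(cfg.h2_maternal)
    cg_idx = rng.integers(0, cfg.n_cg, size=n)
    cg_fx = rng.standard_normal(cfg.n_cg) * cfg.cg_sd
    dam_age = rng.uniform(*cfg.dam_age_range, size=n)
    age_days = rng.integers(cfg.age_range_days[0], cfg.age_range_days[1] + 1, size=n)
    birth_year = rng.choice(np.asarray(cfg.birth_years), size=n)
    sex = rng.choice(np.array(["M", "F"], dtype=object), size=n)
    herd = np.array([f"H{h}" for h in rng.integers(0, max(1, cfg.n_cg // 4), size=n)],
                    dtype=object)
    sigma_e = np.sqrt(1.0 - cfg.h2 - cfg.h2_maternal)
    e = rng.standard_normal(n) * sigma_e
    b1, b2 = cfg.dam_age_beta
    y = cg_fx[cg_idx] + b1 * dam_age + b2 * dam_age ** 2 + tbv \
        + maternal_fx[dam_idx] + e
    meas_date = birth_year.astype(int) * 10000 + 601 + (age_days // 180)
    return pd.DataFrame({
        "individual_id": geno.individual_ids,
        "trait": y,
        "dam_id": [f"dam{d}" for d in dam_idx],
        "sex": sex,
        "herd": herd,
        "birth_year": birth_year.astype(int),
        "management_group": "mg1",
        "measurement_date": meas_date,
        "age_days": age_days,
        "dam_age": dam_age,
        "cg_id": [f"cg{c}" for c in cg_idx],
    })


def emit_annotations(geno: GenotypeMatrix, cfg: SimConfig,
                     qtl_effects: np.ndarray | None = None) -> AnnotationBundle:
    """Gene models, gene sets, and QTL intervals with controlled enrichment.

    Genes tile a ``gene_fraction`` share of each chromosome with exon/UTR
    structure on random strands; gene sets partition the genes; a
    ``qtl_enrichment`` fraction of true QTL markers (nonzero effects) gets a
    covering QTL interval, the remaining intervals are placed at random.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    features = []
    for chrom in sorted(geno.markers["chrom"].unique()):
        sub = geno.markers[geno.markers["chrom"] == chrom]
        chrom_len = int(sub["pos"].max()) + cfg.marker_spacing_bp
        n_genes = cfg.n_genes_per_chrom
        gene_len = max(200, int(chrom_len * cfg.gene_fraction / n_genes))
        slot = chrom_len // n_genes
        for k in range(n_genes):
            start = k * slot + int(rng.integers(0, max(1, slot - gene_len)))
            end = start + gene_len
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"gene{chrom}_{k}"
            is_nc = rng.random() < 0.15
            gtype = "ncRNA_gene" if is_nc else "gene"
            features.append((gid, chrom, start + 1, end, strand, gtype,
                             "ncRNA" if is_nc else "protein_coding"))
            n_exons = int(rng.integers(2, 5))
            bounds = np.sort(rng.choice(
                np.arange(1, gene_len - 1), size=2 * n_exons - 2, replace=False))
            edges = np.concatenate([[0], bounds, [gene_len - 1]])
            exons = [(start + 1 + int(edges[2 * i]), start + 1 + int(edges[2 * i + 1]))
                     for i in range(n_exons)]
            for es, ee in exons:
                features.append((gid, chrom, es, ee, strand, "exon",
                                 "ncRNA" if is_nc else "protein_coding"))
            if not is_nc:
                first, last = exons[0], exons[-1]
                utr_left = (first[0], first[0] + max(0, (first[1] - first[0]) // 4))
                utr_right = (last[1] - max(0, (last[1] - last[0]) // 4), last[1])
                five, three = (utr_left, utr_right) if strand == "+" else (utr_right, utr_left)
                features.append((gid, chrom, five[0], five[1], strand,
                                 "five_prime_UTR", "protein_coding"))
                features.append((gid, chrom, three[0], three[1], strand,
                                 "three_prime_UTR", "protein_coding"))
    gene_models = pd.DataFrame(
        features, columns=["gene_id", "chrom", "start", "end", "strand",
                           "feature", "biotype"])

    gene_ids = gene_models.loc[gene_models["feature"].isin(["gene", "ncRNA_gene"]),
                               "gene_id"].to_numpy(object)
    perm = rng.permutation(len(gene_ids))
    names = ["growth", "carcass", "reproduction"][: cfg.n_gene_sets] or ["growth"]
    gene_sets = {name: sorted(gene_ids[perm[i::len(names)]])
                 for i, name in enumerate(names)}

    classes = ["Production QTL", "Meat and Carcass QTL", "Reproduction QTL"]
    rows = []
    if qtl_effects is not None:
        qtl_pos = geno.markers.loc[np.flatnonzero(qtl_effects != 0), ["chrom", "pos"]]
        n_cover = int(round(cfg.qtl_enrichment * len(qtl_pos)))
        cover = qtl_pos.iloc[rng.permutation(len(qtl_pos))[:n_cover]]
        for _, r in cover.iterrows():
            start = max(0, int(r.pos) - 1 - cfg.qtl_interval_halfwidth_bp)
            rows.append((r.chrom, start, int(r.pos) + cfg.qtl_interval_halfwidth_bp,
                         classes[int(rng.integers(0, len(classes)))]))
    for chrom in sorted(geno.markers["chrom"].unique()):
        chrom_len = int(geno.markers.loc[geno.markers["chrom"] == chrom, "pos"].max())
        for _ in range(3):
            s = int(rng.integers(0, max(1, chrom_len)))
            rows.append((chrom, s, s + 2 * cfg.qtl_interval_halfwidth_bp,
                         classes[int(rng.integers(0, len(classes)))]))
    qtl_intervals = pd.DataFrame(rows, columns=["chrom", "start", "end", "trait_class"])
    return AnnotationBundle(gene_models, gene_sets, qtl_intervals)


def simulate(cfg: SimConfig) -> SimOutput:
    """Run the full generator: genotypes, QTL, phenotypes, annotations."""
    cfg.validate()
    geno = simulate_genotypes(cfg)
    effects = assign_qtl_effects(geno, cfg)
    tbv = true_breeding_values(geno, effects)
    pheno = simulate_phenotypes(geno, effects, cfg)
    bundle = emit_annotations(geno, cfg, effects)
    return SimOutput(geno, panel_subset(geno, cfg), effects, tbv, pheno, bundle, cfg)
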