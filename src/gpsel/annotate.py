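"""Interval- and gene-based marker selection and sequence classification.

Markers are classified into nine gene-based categories with the precedence
exonic > splicing > ncRNA > utr5 > utr3 > intronic > upstream > downstream >
intergenic. "Coding region" = {exonic, splicing}; "genic region" = all eight
non-intergenic classes. Interval arithmetic is 0-based half-open internally;
marker positions and GFF3 coordinates are 1-based.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from gpsel.geno_grm import GenotypeMatrix
from gpsel.ld_select import MarkerSet
from gpsel.sim_data import AnnotationBundle

VARIANT_CLASSES = ["exonic", "splicing", "ncRNA", "utr5", "utr3", "intronic",
                   "upstream", "downstream", "intergenic"]
_PRIORITY = {c: i for i, c in enumerate(VARIANT_CLASSES)}
CODING_CLASSES = {"exonic", "splicing"}
GENIC_CLASSES = set(VARIANT_CLASSES) - {"intergenic"}


def read_gff3(path) -> pd.DataFrame:
    """Read a GFF3 gene-model file into the feature-table layout."""
    raw = pd.read_csv(path, sep="\t", comment="#", header=None,
                      names=["chrom", "source", "feature", "start", "end",
                             "score", "strand", "frame", "attrs"])
    gene_ids = raw["attrs"].str.extract(r"(?:ID|Parent)=([^;]+)")[0]
    biotype = np.where(raw["feature"].eq("ncRNA_gene"), "ncRNA", "protein_coding")
    out = pd.DataFrame({"gene_id": gene_ids, "chrom": raw["chrom"],
                        "start": raw["start"], "end": raw["end"],
                        "strand": raw["strand"], "feature": raw["feature"],
                        "biotype": biotype})
    nc = set(out.loc[out["feature"] == "ncRNA_gene", "gene_id"])
    out.loc[out["gene_id"].isin(nc), "biotype"] = "ncRNA"
    return out


def read_bed_intervals(path) -> pd.DataFrame:
    """Read BED (0-based half-open) with an optional 4th label column."""
    bed = pd.read_csv(path, sep="\t", header=None)
    bed.columns = ["chrom", "start", "end", "trait_class"][: bed.shape[1]]
    if "trait_class" not in bed.columns:
        bed["trait_class"] = ""
    return bed


def select_by_intervals(geno: GenotypeMatrix, intervals: pd.DataFrame,
                        class_filter: list[str] | None = None) -> MarkerSet:
    """Markers whose position falls in any interval passing the class filter.

    ``intervals`` uses 0-based half-open coordinates (BED convention);
    1-based marker position P is covered by [start, end) iff
    start < P <= end.
    """
    if class_filter is not None:
        valid = set(intervals["trait_class"].unique())
        unknown = set(class_filter) - valid
        if unknown:
            raise ValueError(f"unknown trait class tags {sorted(unknown)}; "
                             f"valid: {sorted(valid)}")
        intervals = intervals[intervals["trait_class"].isin(class_filter)]
    hits = np.zeros(geno.n_markers, dtype=bool)
    pos0 = geno.markers["pos"].to_numpy() - 1  # 0-based marker coordinate
    for chrom, sub in intervals.groupby("chrom"):
        on_chrom = geno.markers["chrom"].to_numpy() == chrom
        if not on_chrom.any():
            continue
        p = pos0[on_chrom]
        cover = np.zeros(len(p), dtype=bool)
        for s, e in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
            cover |= (p >= s) & (p < e)
        hits[np.flatnonzero(on_chrom)[cover]] = True
    return MarkerSet(geno.markers["id"].to_numpy(object)[hits], "intervals")


def expand_gene_sets(bundle: AnnotationBundle, set_names: list[str]) -> pd.DataFrame:
    """Union of gene spans (transcript start-end) for the named gene sets.

    Returns merged intervals (chrom, start, end) in 0-based half-open
    coordinates; unresolved gene ids are reported via warning.
    """
    wanted: list[str] = []
    for name in set_names:
        if name not in bundle.gene_sets:
            raise KeyError(f"unknown gene set '{name}'")
        wanted.extend(bundle.gene_sets[name])
    genes = bundle.gene_models[
        bundle.gene_models["feature"].isin(["gene", "ncRNA_gene"])]
    found = genes[genes["gene_id"].isin(wanted)]
    unresolved = sorted(set(wanted) - set(found["gene_id"]))
    if unresolved:
        warnings.warn(f"{len(unresolved)} gene ids unresolved: {unresolved[:5]}")
    if found.empty:
        raise ValueError("no resolvable genes in the requested sets")
    rows = []
    for chrom, sub in found.groupby("chrom"):
        ivs = sorted(zip(sub["start"] - 1, sub["end"]))  # to 0-based half-open
        cs, ce = ivs[0]
        for s, e in ivs[1:]:
            if s <= ce:
                ce = max(ce, e)
            else:
                rows.append((chrom, cs, ce))
                cs, ce = s, e
        rows.append((chrom, cs, ce))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    out["trait_class"] = "+".join(set_names)
    return out


def classify_variants(geno: GenotypeMatrix, gene_models: pd.DataFrame,
                      upstream_bp: int = 1000, splice_bp: int = 2) -> pd.Series:
    """One of the nine sequence classes per marker, by precedence.

    Splicing = within ``splice_bp`` of an exon-intron boundary on the intron
    side; upstream/downstream = within ``upstream_bp`` of the transcript
    start/end, respecting strand; ncRNA covers markers inside non-coding gene
    spans. Malformed gene records (features outside the gene span) are
    skipped with a warning.
    """
    cls = np.full(geno.n_markers, _PRIORITY["intergenic"], dtype=int)
    pos = geno.markers["pos"].to_numpy()
    chrom = geno.markers["chrom"].to_numpy()

    genes = gene_models[gene_models["feature"].isin(["gene", "ncRNA_gene"])]
    feats = gene_models[~gene_models["feature"].isin(["gene", "ncRNA_gene"])]

    def mark(mask: np.ndarray, name: str) -> None:
        prio = _PRIORITY[name]
        sel = mask & (cls > prio)
        cls[sel] = prio

    for _, g in genes.iterrows():
        on = chrom == g.chrom
        if not on.any():
            continue
        sub = feats[feats["gene_id"] == g.gene_id]
        bad = sub[(sub["start"] < g.start) | (sub["end"] > g.end)]
        if len(bad):
            warnings.warn(f"skipping malformed gene record {g.gene_id}")
            continue
        p = pos
        in_span = on & (p >= g.start) & (p <= g.end)
        if g.biotype == "ncRNA":
            mark(in_span, "ncRNA")
        else:
            exons = sub[sub["feature"] == "exon"]
            in_exon = np.zeros_like(in_span)
            near_splice = np.zeros_like(in_span)
            for _, ex in exons.iterrows():
                in_exon |= on & (p >= ex.start) & (p <= ex.end)
                if ex.start > g.start:  # intron to the left of this exon
                    near_splice |= on & (p >= ex.start - splice_bp) & (p < ex.start)
                if ex.end < g.end:  # intron to the right
                    near_splice |= on & (p > ex.end) & (p <= ex.end + splice_bp)
            in_utr5 = np.zeros_like(in_span)
            in_utr3 = np.zeros_like(in_span)
            for _, u in sub[sub["feature"] == "five_prime_UTR"].iterrows():
                in_utr5 |= on & (p >= u.start) & (p <= u.end)
            for _, u in sub[sub["feature"] == "three_prime_UTR"].iterrows():
                in_utr3 |= on & (p >= u.start) & (p <= u.end)
            mark(in_exon & ~in_utr5 & ~in_utr3, "exonic")
            mark(near_splice & in_span & ~in_exon, "splicing")
            mark(in_utr5, "utr5")
            mark(in_utr3, "utr3")
            mark(in_span, "intronic")
        if g.strand == "+":
            up = on & (p >= g.start - upstream_bp) & (p < g.start)
            down = on & (p > g.end) & (p <= g.end + upstream_bp)
        else:
            up = on & (p > g.end) & (p <= g.end + upstream_bp)
            down = on & (p >= g.start - upstream_bp) & (p < g.start)
        mark(up, "upstream")
        mark(down, "downstream")
    names = np.asarray(VARIANT_CLASSES, dtype=object)[cls]
    return pd.Series(names, index=geno.markers["id"].to_numpy(object), name="class")


def class_marker_sets(classes: pd.Series) -> dict:
    """Coding and genic marker sets from one classification pass."""
    ids = classes.index.to_numpy(object)
    coding = ids[classes.isin(CODING_CLASSES).to_numpy()]
    genic = ids[classes.isin(GENIC_CLASSES).to_numpy()]
    return {"coding": MarkerSet(coding, "coding"),
            "genic": MarkerSet(genic, "genic")}
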