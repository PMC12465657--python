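"""LD-based marker selection: r2, indep-pairwise pruning, clumping, subsets.

Pruning follows the indep-pairwise convention: a sliding window of
``window_markers`` position-sorted markers advancing by ``step_markers``;
within a window every pair with r2 above the threshold loses its lower-MAF
member (MAF ties drop the marker at the larger position). Clumping removes
preselected candidates that are redundant (high r2 within a distance window)
with a base panel, so that composed prediction panels are disjoint unions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from gpsel.geno_grm import GenotypeMatrix, allele_freq_and_maf


@dataclass
class MarkerSet:
    """Ordered marker identifiers with a provenance label."""

    ids: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate marker ids in set")

    def __len__(self) -> int:
        return len(self.ids)

    def union(self, other: "MarkerSet", label: str = "") -> "MarkerSet":
        seen = set(self.ids)
        extra = [i for i in other.ids if i not in seen]
        return MarkerSet(np.concatenate([self.ids, np.asarray(extra, object)]),
                         label or f"{self.label}+{other.label}")

    def difference(self, other: "MarkerSet", label: str = "") -> "MarkerSet":
        drop = set(other.ids)
        return MarkerSet(np.asarray([i for i in self.ids if i not in drop], object),
                         label or self.label)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(map(str, self.ids)) + ("\n" if len(self.ids) else ""))

    @classmethod
    def from_file(cls, path, label: str = "") -> "MarkerSet":
        with open(path) as fh:
            ids = [line.strip() for line in fh if line.strip()]
        return cls(np.asarray(ids, object), label)


@dataclass
class PruneParams:
    window_markers: int = 5000
    step_markers: int = 100
    r2_threshold: float = 0.95

    def __post_init__(self) -> None:
        if self.window_markers < 2:
            raise ValueError("window_markers must be >= 2")
        if not 0 < self.r2_threshold <= 1:
            raise ValueError("r2_threshold must be in (0, 1]")


def _sorted_ids(geno: GenotypeMatrix, idx) -> np.ndarray:
    sub = geno.markers.iloc[np.sort(np.asarray(idx, dtype=int))]
    return sub["id"].to_numpy(object)


def ld_r2(geno: GenotypeMatrix, marker_a: str, marker_b: str) -> float:
    """Squared Pearson correlation of genotype dosages at two markers.

    Computed over individuals non-missing at both markers; either marker
    having zero variance there is an error.
    """
    ia, ib = geno.marker_index([marker_a, marker_b])
    a = geno.calls[:, ia].astype(np.float64)
    b = geno.calls[:, ib].astype(np.float64)
    keep = (geno.calls[:, ia] >= 0) & (geno.calls[:, ib] >= 0)
    a, b = a[keep], b[keep]
    if a.std() == 0 or b.std() == 0:
        raise ValueError(f"zero genotype variance at {marker_a} or {marker_b}")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _r2_matrix(calls: np.ndarray) -> np.ndarray:
    """Pairwise genotype r2 for a block of columns (missing -> column mean)."""
    x = calls.astype(np.float64)
    miss = calls < 0
    if miss.any():
        obs = ~miss
        means = np.where(obs, x, 0.0).sum(0) / np.maximum(obs.sum(0), 1)
        x = np.where(miss, means, x)
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = np.nan
    c = (x.T @ x) / len(x)
    with np.errstate(invalid="ignore"):
        r = c / np.outer(sd, sd)
    return r * r


def prune_indep_pairwise(geno: GenotypeMatrix, params: PruneParams) -> MarkerSet:
    """Greedy LD pruning: drop the lower-MAF member of each high-r2 pair.

    Within each window, pairs are scanned by ascending position of the left
    member, re-evaluating survivors after each removal; surviving markers
    contain no within-window pair with r2 above the threshold.
    """
    m = geno.n_markers
    freqs = allele_freq_and_maf(geno)
    maf = freqs["maf"].to_numpy()
    alive = np.ones(m, dtype=bool)
    alive[freqs["all_missing"].to_numpy()] = False
    start = 0
    while True:
        stop = min(start + params.window_markers, m)
        window = np.flatnonzero(alive[start:stop]) + start
        if len(window) >= 2:
            r2 = _r2_matrix(geno.calls[:, window])
            local_alive = np.ones(len(window), dtype=bool)
            changed = True
            while changed:
                changed = False
                for i in range(len(window)):
                    if not local_alive[i]:
                        continue
                    for j in range(i + 1, len(window)):
                        if not local_alive[j]:
                            continue
                        if np.isnan(r2[i, j]) or r2[i, j] <= params.r2_threshold:
                            continue
                        gi, gj = window[i], window[j]
                        # drop lower MAF; tie -> larger position (j is later)
                        drop_local = i if maf[gi] < maf[gj] else j
                        local_alive[drop_local] = False
                        changed = True
                        if drop_local == i:
                            break
            alive[window[~local_alive]] = False
        if stop >= m:
            break
        start += params.step_markers
    return MarkerSet(_sorted_ids(geno, np.flatnonzero(alive)), "pruned")


def clump_against_panel(
    geno: GenotypeMatrix,
    candidates: MarkerSet,
    base: MarkerSet,
    r2_threshold: float = 0.95,
    window_kb: float = 1000.0,
) -> MarkerSet:
    """Remove candidates redundant with the base panel.

    A candidate is dropped if it appears in the base set, or if any base
    marker within ``window_kb`` on the same chromosome has r2 above the
    threshold with it.
    """
    base_ids = set(base.ids)
    cand_ids = [i for i in candidates.ids if i not in base_ids]
    if not cand_ids:
        return MarkerSet(np.asarray([], object), candidates.label)
    meta = geno.markers.set_index("id")
    window_bp = window_kb * 1000.0
    base_by_chrom: dict = {}
    for bid in base.ids:
        row = meta.loc[bid]
        base_by_chrom.setdefault(row["chrom"], []).append((row["pos"], bid))
    for chrom in base_by_chrom:
        base_by_chrom[chrom].sort()
    survivors = []
    for cid in cand_ids:
        row = meta.loc[cid]
        chrom, pos = row["chrom"], row["pos"]
        keep = True
        if chrom in base_by_chrom:
            positions = [p for p, _ in base_by_chrom[chrom]]
            lo = np.searchsorted(positions, pos - window_bp, side="left")
            hi = np.searchsorted(positions, pos + window_bp, side="right")
            for _, bid in base_by_chrom[chrom][lo:hi]:
                try:
                    if ld_r2(geno, cid, bid) > r2_threshold:
                        keep = False
                        break
                except ValueError:
                    continue
        if keep:
            survivors.append(cid)
    idx = geno.marker_index(survivors) if survivors else []
    return MarkerSet(_sorted_ids(geno, idx), candidates.label or "clumped")


def select_by_pvalue(gwas: pd.DataFrame, alpha: float = 0.01) -> MarkerSet:
    """Markers with association p strictly below ``alpha``, position-sorted.

    ``gwas`` is an association table with columns id, chrom, pos, p (as
    produced by :func:`gpsel.gwas_mlm.mlma_scan`); missing p (untested
    markers) never qualify.
    """
    ok = gwas["p"].notna() & (gwas["p"] < alpha)
    hits = gwas.loc[ok].sort_values(["chrom", "pos"], kind="stable")
    return MarkerSet(hits["id"].to_numpy(object), f"p<{alpha}")


def random_subset(marker_set: MarkerSet, n: int, seed: int,
                  geno: GenotypeMatrix | None = None) -> MarkerSet:
    """Uniform without-replacement subset of size n, deterministic per seed.

    Output preserves the set's ordering (position order when the set came
    from a position-sorted genotype matrix).
    """
    if n > len(marker_set):
        raise ValueError(f"cannot sample {n} from {len(marker_set)} markers")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(marker_set), size=n, replace=False))
    ids = marker_set.ids[idx]
    if geno is not None:
        ids = _sorted_ids(geno, geno.marker_index(ids))
    return MarkerSet(ids, f"{marker_set.label}-sub{n}")


def compose_panel(base: MarkerSet, preselected: MarkerSet,
                  geno: GenotypeMatrix | None = None, label: str = "") -> MarkerSet:
    """Disjoint union of the base panel and an already-clumped preselection.

    Overlap violates the clumping contract and raises.
    """
    overlap = set(base.ids) & set(preselected.ids)
    if overlap:
        raise ValueError(f"preselected markers overlap the base panel: {sorted(overlap)[:5]}")
    ids = np.concatenate([base.ids, preselected.ids])
    if geno is not None:
        ids = _sorted_ids(geno, geno.marker_index(ids))
    return MarkerSet(ids, label or f"{base.label}+{preselected.label}")
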