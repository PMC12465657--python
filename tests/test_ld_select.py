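"""LD selection tests, including brute-force oracles for pruning/clumping."""

import numpy as np
import pandas as pd
import pytest

from gpsel.geno_grm import GenotypeMatrix, allele_freq_and_maf
from gpsel.ld_select import (
    MarkerSet,
    PruneParams,
    clump_against_panel,
    compose_panel,
    ld_r2,
    prune_indep_pairwise,
    random_subset,
    select_by_pvalue,
)


def _geno(calls, pos=None, chrom=None):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    markers = pd.DataFrame({
        "id": [f"m{j}" for j in range(m)],
        "chrom": chrom if chrom is not None else np.ones(m, int),
        "pos": pos if pos is not None else np.arange(1, m + 1) * 100,
        "a1": "A", "a2": "B",
    })
    return GenotypeMatrix(calls, np.array([f"i{k}" for k in range(n)], object), markers)


def _random_geno(rng, n, m, n_chrom=2):
    """Random genotypes with some duplicated/near-duplicate columns."""
    calls = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    for _ in range(m // 5):
        j, k = rng.integers(0, m, size=2)
        calls[:, k] = calls[:, j]  # exact LD pair
    chrom = np.sort(rng.integers(1, n_chrom + 1, size=m))
    pos = np.concatenate([np.sort(rng.choice(np.arange(1, 10 * m), size=(chrom == c).sum(),
                                             replace=False)) for c in range(1, n_chrom + 1)])
    return _geno(calls, pos=pos, chrom=chrom)


def brute_force_prune(geno, params):
    """All-pairs greedy oracle for indep-pairwise pruning (single pass logic
    identical to the production rules but with naive O(m^2) scans)."""
    maf = allele_freq_and_maf(geno)["maf"].to_numpy()
    m = geno.n_markers
    x = geno.calls.astype(float)
    alive = maf == maf  # all True
    alive &= ~allele_freq_and_maf(geno)["all_missing"].to_numpy()
    start = 0
    while True:
        stop = min(start + params.window_markers, m)
        changed = True
        while changed:
            changed = False
            idx = [j for j in range(start, stop) if alive[j]]
            for a_i, i in enumerate(idx):
                for j in idx[a_i + 1:]:
                    if not (alive[i] and alive[j]):
                        continue
                    xi, xj = x[:, i], x[:, j]
                    if xi.std() == 0 or xj.std() == 0:
                        continue
                    r2 = np.corrcoef(xi, xj)[0, 1] ** 2
                    if r2 <= params.r2_threshold:
                        continue
                    drop = i if maf[i] < maf[j] else j
                    alive[drop] = False
                    changed = True
                if not alive[i]:
                    continue
        if stop >= m:
            break
        start += params.step_markers
    return list(geno.markers["id"].to_numpy(object)[alive])


class TestLdR2:
    def test_identical_columns(self):
        g = _geno(np.array([[0, 0], [1, 1], [2, 2], [1, 1]]))
        assert ld_r2(g, "m0", "m1") == pytest.approx(1.0)

    def test_allele_flip_invariant(self):
        a = np.array([0, 1, 2, 1, 0], dtype=np.int8)
        g = _geno(np.column_stack([a, 2 - a]))
        assert ld_r2(g, "m0", "m1") == pytest.approx(1.0)

    def test_hand_vectors_brute_force_value(self):
        """r2 of (0,0,1,2) vs (0,1,1,2) equals cov^2/(va*vb) = 8/11."""
        g = _geno(np.array([[0, 0], [0, 1], [1, 1], [2, 2]]))
        a = np.array([0, 0, 1, 2.0])
        b = np.array([0, 1, 1, 2.0])
        oracle = np.cov(a, b, ddof=0)[0, 1] ** 2 / (a.var() * b.var())
        assert ld_r2(g, "m0", "m1") == pytest.approx(oracle)
        assert ld_r2(g, "m0", "m1") == pytest.approx(8 / 11)

    def test_zero_variance_errors(self):
        g = _geno(np.array([[1, 0], [1, 1], [1, 2]]))
        with pytest.raises(ValueError, match="zero"):
            ld_r2(g, "m0", "m1")

    def test_missing_pairs_excluded(self):
        g = _geno(np.array([[0, 0], [1, -1], [2, 2], [0, 0], [2, 2]]))
        # non-missing rows have identical dosage patterns
        assert ld_r2(g, "m0", "m1") == pytest.approx(1.0)


class TestPrune:
    def test_lower_maf_member_removed(self):
        rng = np.random.default_rng(0)
        a = (rng.random(200) < 0.3).astype(np.int8) + (rng.random(200) < 0.3).astype(np.int8)
        b = a.copy()
        b[:6] = np.where(b[:6] > 0, b[:6] - 1, 0)  # maf ~0.27, r2 still > 0.95
        g = _geno(np.column_stack([a, b]))
        maf = allele_freq_and_maf(g)["maf"]
        assert maf[1] < maf[0]
        kept = prune_indep_pairwise(g, PruneParams(window_markers=10, step_markers=5))
        assert list(kept.ids) == ["m0"]

    def test_independent_markers_all_survive(self, rng):
        calls = rng.integers(0, 3, size=(300, 40)).astype(np.int8)
        g = _geno(calls)
        kept = prune_indep_pairwise(g, PruneParams(window_markers=40, step_markers=10))
        assert len(kept) == 40

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        for rep in range(20):
            n = int(rng.integers(50, 150))
            m = int(rng.integers(10, 60))
            g = _random_geno(rng, n, m)
            params = PruneParams(window_markers=5000, step_markers=100,
                                 r2_threshold=0.95)
            mine = list(prune_indep_pairwise(g, params).ids)
            oracle = brute_force_prune(g, params)
            assert mine == oracle, f"rep {rep}"

    def test_fixpoint_whole_window(self):
        rng = np.random.default_rng(7)
        g = _random_geno(rng, 120, 50)
        params = PruneParams(window_markers=5000, step_markers=100)
        once = prune_indep_pairwise(g, params)
        again = prune_indep_pairwise(g.subset_markers(once.ids), params)
        assert list(once.ids) == list(again.ids)

    def test_surviving_pairs_below_threshold(self):
        rng = np.random.default_rng(8)
        g = _random_geno(rng, 150, 40)
        params = PruneParams(window_markers=5000, step_markers=100)
        kept = prune_indep_pairwise(g, params)
        for i, a in enumerate(kept.ids):
            for b in kept.ids[i + 1:]:
                assert ld_r2(g, a, b) <= 0.95 + 1e-12

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(9)
        g = _random_geno(rng, 100, 50)
        counts = []
        for thr in (0.2, 0.5, 0.8, 0.95):
            p = PruneParams(window_markers=5000, step_markers=100, r2_threshold=thr)
            counts.append(len(prune_indep_pairwise(g, p)))
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_window_validation(self):
        with pytest.raises(ValueError, match="window"):
            PruneParams(window_markers=1)


class TestClump:
    def test_duplicate_of_base_removed(self, rng):
        calls = rng.integers(0, 3, size=(100, 4)).astype(np.int8)
        g = _geno(calls)
        out = clump_against_panel(g, MarkerSet(np.array(["m0", "m1"], object)),
                                  MarkerSet(np.array(["m1", "m3"], object)))
        assert "m1" not in out.ids

    def test_perfect_ld_neighbor_removed(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 3, size=100).astype(np.int8)
        calls = np.column_stack([a, a, rng.integers(0, 3, size=100).astype(np.int8)])
        g = _geno(calls, pos=[1000, 2000, 3000])
        out = clump_against_panel(g, MarkerSet(np.array(["m1", "m2"], object)),
                                  MarkerSet(np.array(["m0"], object)), window_kb=1.5)
        assert list(out.ids) == ["m2"]

    def test_other_chromosome_kept(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 3, size=100).astype(np.int8)
        g = _geno(np.column_stack([a, a]), pos=[1000, 1000], chrom=[1, 2])
        out = clump_against_panel(g, MarkerSet(np.array(["m1"], object)),
                                  MarkerSet(np.array(["m0"], object)))
        assert list(out.ids) == ["m1"]

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(10)
        for rep in range(10):
            g = _random_geno(rng, 80, 40)
            ids = g.markers["id"].to_numpy(object)
            pick = rng.permutation(40)
            base = MarkerSet(ids[np.sort(pick[:15])])
            cands = MarkerSet(ids[np.sort(pick[15:30])])
            out = clump_against_panel(g, cands, base, window_kb=0.2)
            meta = g.markers.set_index("id")
            survivors = []
            for c in cands.ids:
                drop = False
                for b in base.ids:
                    if meta.loc[c, "chrom"] != meta.loc[b, "chrom"]:
                        continue
                    if abs(meta.loc[c, "pos"] - meta.loc[b, "pos"]) > 200:
                        continue
                    xc = g.calls[:, g.marker_index([c])[0]].astype(float)
                    xb = g.calls[:, g.marker_index([b])[0]].astype(float)
                    if xc.std() == 0 or xb.std() == 0:
                        continue
                    if np.corrcoef(xc, xb)[0, 1] ** 2 > 0.95:
                        drop = True
                        break
                if not drop:
                    survivors.append(c)
            assert sorted(out.ids) == sorted(survivors), f"rep {rep}"


class TestSelectByPvalue:
    def _gwas(self, pvals):
        m = len(pvals)
        return pd.DataFrame({"id": [f"m{j}" for j in range(m)], "chrom": 1,
                             "pos": np.arange(1, m + 1), "p": pvals})

    def test_all_nonsignificant_empty(self):
        assert len(select_by_pvalue(self._gwas([0.5] * 10), 0.01)) == 0

    def test_exact_threshold_excluded(self):
        out = select_by_pvalue(self._gwas([0.01, 0.0099]), 0.01)
        assert list(out.ids) == ["m1"]

    def test_uniform_null_count_near_alpha(self):
        # aggregate over seeds so a single unlucky binomial draw cannot flip it
        m, total = 20000, 0
        for seed in range(8):
            r = np.random.default_rng(seed)
            total += len(select_by_pvalue(self._gwas(r.uniform(size=m)), 0.01))
        exp, sd = 8 * 0.01 * m, np.sqrt(8 * m * 0.01 * 0.99)
        assert abs(total - exp) < 3 * sd

    def test_missing_p_never_selected(self):
        out = select_by_pvalue(self._gwas([np.nan, 0.001]), 0.01)
        assert list(out.ids) == ["m1"]


class TestRandomSubsetAndCompose:
    def test_full_subset_is_identity(self):
        s = MarkerSet(np.array([f"m{j}" for j in range(5)], object))
        assert sorted(random_subset(s, 5, seed=1).ids) == sorted(s.ids)

    def test_deterministic_per_seed(self):
        s = MarkerSet(np.array([f"m{j}" for j in range(100)], object))
        a, b = random_subset(s, 10, seed=3), random_subset(s, 10, seed=3)
        assert list(a.ids) == list(b.ids)
        assert list(a.ids) != list(random_subset(s, 10, seed=4).ids)

    def test_uniform_inclusion_frequency(self):
        s = MarkerSet(np.array([f"m{j}" for j in range(20)], object))
        hits = {i: 0 for i in s.ids}
        n_rep = 500
        for seed in range(n_rep):
            for i in random_subset(s, 5, seed=seed).ids:
                hits[i] += 1
        freqs = np.array(list(hits.values())) / n_rep
        se = np.sqrt(0.25 * 0.75 / n_rep)
        assert np.all(np.abs(freqs - 0.25) < 5 * se)

    def test_oversample_rejected(self):
        s = MarkerSet(np.array(["a"], object))
        with pytest.raises(ValueError):
            random_subset(s, 2, seed=0)

    def test_compose_sizes_match_panel_arithmetic(self):
        """Base 44,827 plus 6,783 preselected gives the 51,610-marker panel."""
        base = MarkerSet(np.array([f"b{j}" for j in range(44827)], object))
        pre = MarkerSet(np.array([f"p{j}" for j in range(6783)], object))
        assert len(compose_panel(base, pre)) == 51610

    def test_compose_empty_preselection(self):
        base = MarkerSet(np.array(["a", "b"], object))
        out = compose_panel(base, MarkerSet(np.array([], object)))
        assert list(out.ids) == ["a", "b"]

    def test_compose_overlap_rejected(self):
        base = MarkerSet(np.array(["a", "b"], object))
        with pytest.raises(ValueError, match="overlap"):
            compose_panel(base, MarkerSet(np.array(["b"], object)))

    def test_union_difference(self):
        a = MarkerSet(np.array(["x", "y"], object))
        b = MarkerSet(np.array(["y", "z"], object))
        assert list(a.union(b).ids) == ["x", "y", "z"]
        assert list(a.difference(b).ids) == ["x"]

    def test_file_roundtrip(self, tmp_path):
        s = MarkerSet(np.array(["m1", "m2", "m3"], object), "lbl")
        s.to_file(tmp_path / "s.txt")
        back = MarkerSet.from_file(tmp_path / "s.txt")
        assert list(back.ids) == list(s.ids)
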