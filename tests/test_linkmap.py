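"""Two-point ML with phase, grouping, ordering and Kosambi maps."""

import itertools

import numpy as np
import pandas as pd
import pytest

from radmap import SimConfig, kosambi_cm, two_point
from radmap.genotype import MISSING
from radmap.linkmap import (
    TwoPointEngine,
    bin_cosegregating,
    build_sex_maps,
    detect_bridge_markers,
    form_groups,
    order_group,
)
from radmap.markerqc import classify_all, run_qc
from radmap.simdata import simulate_family, truth_genotype_matrix

LN10 = np.log(10.0)


# ---------------------------------------------------------------------------
# Independent oracle: brute-force joint-genotype likelihood on a 0.001 grid.


def _allele_probs(geno):
    return {0: [(0, 1.0)], 1: [(0, 0.5), (1, 0.5)], 2: [(1, 1.0)]}[geno]


def _oracle_gametes(g1, g2, phase, r):
    """Gamete (allele1, allele2) -> probability, with ``r`` scalar or array.

    Phase 0 puts allele A at both loci on the same homolog.  A parent not
    heterozygous at both loci transmits independently at each locus.
    """
    if g1 == 1 and g2 == 1:
        h1 = (0, phase)
        h2 = (1, 1 - phase)
        return {
            h1: (1 - r) / 2, h2: (1 - r) / 2,
            (h1[0], h2[1]): r / 2, (h2[0], h1[1]): r / 2,
        }
    out = {}
    for a1, p1 in _allele_probs(g1):
        for a2, p2 in _allele_probs(g2):
            out[(a1, a2)] = out.get((a1, a2), 0.0) + p1 * p2
    return {k: v * np.ones_like(r, dtype=float) for k, v in out.items()}


def oracle_joint_probs(parents_a, parents_b, phase_f, phase_m, rf, rm):
    """P(offspring genotype pair) by explicit enumeration; rf/rm may be
    arrays, giving a (len(rf), len(rm), 3, 3) grid."""
    rf = np.atleast_1d(np.asarray(rf, dtype=float))
    rm = np.atleast_1d(np.asarray(rm, dtype=float))
    mg = _oracle_gametes(parents_a[0], parents_b[0], phase_f, rf)
    pg = _oracle_gametes(parents_a[1], parents_b[1], phase_m, rm)
    probs = np.zeros((rf.size, rm.size, 3, 3))
    for (m1, m2), pmat in mg.items():
        for (p1, p2), ppat in pg.items():
            probs[:, :, m1 + p1, m2 + p2] += pmat[:, None] * ppat[None, :]
    return probs


def _oracle_counts(calls_a, calls_b, parents_a, parents_b):
    ok = (calls_a != MISSING) & (calls_b != MISSING)
    counts = np.zeros((3, 3))
    for ga, gb in zip(calls_a[ok], calls_b[ok]):
        counts[ga, gb] += 1
    # drop Mendelian-impossible cells (cleaned upstream in the pipeline)
    base = oracle_joint_probs(parents_a, parents_b, 0, 0, 0.25, 0.25)[0, 0]
    counts[base == 0] = 0
    return counts


def oracle_loglik(counts, parents_a, parents_b, rf, rm, pf, pm):
    probs = oracle_joint_probs(parents_a, parents_b, pf, pm,
                               0.25 if np.isnan(rf) else rf,
                               0.25 if np.isnan(rm) else rm)[0, 0]
    return float(np.where(counts > 0,
                          counts * np.log(np.maximum(probs, 1e-300)), 0.0).sum())


def oracle_two_point(calls_a, calls_b, parents_a, parents_b, step=0.001):
    """Exhaustive grid/phase maximisation of the exact joint likelihood."""
    mother_doubly = parents_a[0] == 1 and parents_b[0] == 1
    father_doubly = parents_a[1] == 1 and parents_b[1] == 1
    if not mother_doubly and not father_doubly:
        return None
    counts = _oracle_counts(calls_a, calls_b, parents_a, parents_b)

    grid = np.arange(0.0, 0.5 + step / 2, step)
    phases_f = (0, 1) if mother_doubly else (0,)
    phases_m = (0, 1) if father_doubly else (0,)
    rf_grid = grid if mother_doubly else np.array([0.25])
    rm_grid = grid if father_doubly else np.array([0.25])

    best = (-np.inf, None)
    for pf, pm in itertools.product(phases_f, phases_m):
        probs = oracle_joint_probs(parents_a, parents_b, pf, pm, rf_grid, rm_grid)
        logp = np.log(np.maximum(probs, 1e-300))
        ll = np.tensordot(logp, counts, axes=([2, 3], [0, 1]))
        ll[np.tensordot((probs == 0).astype(float), counts,
                        axes=([2, 3], [0, 1])) > 0] = -np.inf
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        if ll[i, j] > best[0]:
            best = (float(ll[i, j]), (rf_grid[i], rm_grid[j], pf, pm))
    ll_null = oracle_loglik(counts, parents_a, parents_b, 0.5, 0.5, 0, 0)
    ll, (rf, rm, pf, pm) = best
    return {
        "r_f": rf if mother_doubly else np.nan,
        "r_m": rm if father_doubly else np.nan,
        "lod": max(0.0, (ll - ll_null) / LN10),
        "ll_max": ll,
        "counts": counts,
    }


def assert_matches_oracle(res, ora, parents_a, parents_b, tol=0.001):
    """Estimates must agree with the oracle to grid resolution; where the
    likelihood has exact ties (the AB x AB surface has symmetry ridges),
    the implementation's maximiser must score the oracle's maximum."""
    deviates = False
    for key in ("r_f", "r_m"):
        got, want = getattr(res, key), ora[key]
        if np.isnan(want):
            assert np.isnan(got)
        elif abs(got - want) > tol + 1e-9:
            deviates = True
    assert res.lod == pytest.approx(ora["lod"], abs=1e-3)
    if deviates:
        phase = {"coupling": 0, "repulsion": 1, None: 0}
        ll_at_impl = oracle_loglik(
            ora["counts"], parents_a, parents_b, res.r_f, res.r_m,
            phase[res.phase_f], phase[res.phase_m],
        )
        assert ll_at_impl >= ora["ll_max"] - 1e-6, (
            f"implementation optimum ({res.r_f}, {res.r_m}) scores "
            f"{ll_at_impl} vs oracle max {ora['ll_max']}"
        )


def simulate_pair(rng, kind_a, kind_b, rf, rm, n, phase_f=0, phase_m=0,
                  missing_rate=0.0):
    """Simulate offspring calls for one marker pair of given cross types.

    Hom parents transmit allele 0; a doubly heterozygous parent transmits a
    phased haplotype pair with recombination probability r, a singly
    heterozygous parent transmits independently at its het locus.
    """
    parents = {"B3": (1, 1), "D1": (1, 0), "D2": (0, 1)}
    pa, pb = parents[kind_a], parents[kind_b]

    def transmit(het_a, het_b, r, phase):
        if het_a and het_b:
            a = rng.integers(0, 2, n)
            b = np.where(rng.random(n) < r, 1 - a, a)
            if phase:
                b = 1 - b
            return a, b
        a = rng.integers(0, 2, n) if het_a else np.zeros(n, dtype=int)
        b = rng.integers(0, 2, n) if het_b else np.zeros(n, dtype=int)
        return a, b

    m1, m2 = transmit(pa[0] == 1, pb[0] == 1, rf, phase_f)
    p1, p2 = transmit(pa[1] == 1, pb[1] == 1, rm, phase_m)
    calls_a = (m1 + p1).astype(np.int8)
    calls_b = (m2 + p2).astype(np.int8)
    if missing_rate:
        calls_a[rng.random(n) < missing_rate] = MISSING
        calls_b[rng.random(n) < missing_rate] = MISSING
    return calls_a, calls_b, pa, pb


class TestKosambi:
    def test_closed_form(self):
        assert kosambi_cm(0.0) == 0.0
        assert kosambi_cm(0.1) == pytest.approx(25 * np.log(1.2 / 0.8))
        assert kosambi_cm(0.1) == pytest.approx(10.137, abs=5e-4)
        assert kosambi_cm(0.25) == pytest.approx(25 * np.log(3.0))

    def test_domain(self):
        with pytest.raises(ValueError):
            kosambi_cm(0.5)
        with pytest.raises(ValueError):
            kosambi_cm(-0.01)

    def test_monotone_convex_and_small_r_limit(self):
        r = np.linspace(0, 0.49, 500)
        d = kosambi_cm(r)
        assert (np.diff(d) > 0).all()
        assert (np.diff(d, 2) > -1e-9).all()
        assert kosambi_cm(0.001) == pytest.approx(0.1, rel=1e-4)  # d ~ 100 r cM


class TestTwoPointWorkedExamples:
    def test_d1_d1_ten_recombinants(self):
        # mother doubly heterozygous, coupling, 10 of 96 recombinant
        ind = np.array([0] * 43 + [1] * 43 + [0] * 5 + [1] * 5)
        calls_a = ind.astype(np.int8)
        calls_b = np.concatenate([ind[:86], 1 - ind[86:]]).astype(np.int8)
        res = two_point(calls_a, calls_b, (1, 0), (1, 0))
        assert res.r_f == pytest.approx(10 / 96)
        expected_lod = (86 * np.log(86 / 96) + 10 * np.log(10 / 96)
                        + 96 * np.log(2)) / LN10
        assert res.lod == pytest.approx(expected_lod, abs=1e-9)
        assert res.lod == pytest.approx(14.97, abs=0.01)

    def test_marker_with_itself(self):
        calls = np.array([0, 1] * 48, dtype=np.int8)
        res = two_point(calls, calls, (1, 0), (1, 0))
        assert res.r_f == 0.0
        assert res.lod == pytest.approx(96 * np.log10(2), abs=1e-9)

    def test_independent_markers_near_half(self, rng):
        for _ in range(20):
            a, b, pa, pb = simulate_pair(rng, "D1", "D1", 0.5, 0.5, 96)
            res = two_point(a, b, pa, pb)
            assert res.r_f >= 0.3
            assert res.lod < 6

    def test_symmetry_under_pair_swap(self, rng):
        a, b, pa, pb = simulate_pair(rng, "B3", "B3", 0.1, 0.2, 96)
        r1 = two_point(a, b, pa, pb)
        r2 = two_point(b, a, pb, pa)
        assert r1.r_f == pytest.approx(r2.r_f, abs=1e-9)
        assert r1.r_m == pytest.approx(r2.r_m, abs=1e-9)
        assert r1.lod == pytest.approx(r2.lod, abs=1e-6)


class TestOracleEquivalence:
    @pytest.mark.parametrize("kind_a,kind_b", [
        ("D1", "D1"), ("D1", "B3"), ("D2", "B3"), ("B3", "B3"), ("D2", "D2"),
    ])
    def test_matches_exhaustive_grid(self, rng, kind_a, kind_b):
        for _ in range(4):
            rf = float(rng.uniform(0, 0.5))
            rm = float(rng.uniform(0, 0.5))
            a, b, pa, pb = simulate_pair(
                rng, kind_a, kind_b, rf, rm, 48,
                phase_f=int(rng.integers(2)), phase_m=int(rng.integers(2)),
                missing_rate=0.05,
            )
            res = two_point(a, b, pa, pb)
            ora = oracle_two_point(a, b, pa, pb)
            if res is None:
                assert ora is None
                continue
            assert_matches_oracle(res, ora, pa, pb)

    def test_d1_d2_pair_uninformative(self, rng):
        a, b, pa, pb = simulate_pair(rng, "D1", "D2", 0.1, 0.1, 48)
        assert two_point(a, b, pa, pb) is None
        assert oracle_two_point(a, b, pa, pb) is None


class TestGroupingPrimitives:
    def _pairs(self, rows):
        return pd.DataFrame(
            rows, columns=["locus_a", "locus_b", "r_f", "r_m", "lod"]
        )

    def test_bin_transitivity(self):
        pairs = self._pairs([
            ("a", "b", 0.0, 0.0, 28.0),
            ("b", "c", 0.005, 0.005, 25.0),
            ("a", "c", 0.02, 0.02, 30.0),   # fails rf gate, chain still joins
        ])
        missing = pd.Series({"a": 1, "b": 0, "c": 2})
        bins = bin_cosegregating(pairs, ["a", "b", "c"], missing, "female")
        assert bins == {"b": ["a", "b", "c"]}

    def test_bin_rf_gate(self):
        pairs = self._pairs([("a", "b", 0.02, 0.02, 30.0)])
        bins = bin_cosegregating(pairs, ["a", "b"], pd.Series({"a": 0, "b": 0}),
                                 "female")
        assert set(bins) == {"a", "b"}

    def test_form_groups_components(self):
        pairs = self._pairs([
            ("a", "b", 0.1, np.nan, 7.0),
            ("b", "c", 0.1, np.nan, 8.0),
            ("a", "c", 0.3, np.nan, 2.0),
        ])
        groups = form_groups(pairs, ["a", "b", "c", "d"])
        assert groups[0] == ["a", "b", "c"]
        assert ["d"] in groups

    def test_bridge_marker_detected(self):
        rows = []
        left = [f"l{i}" for i in range(5)]
        right = [f"r{i}" for i in range(5)]
        for grp in (left, right):
            rows += [(a, b, 0.05, 0.05, 20.0) for a, b in
                     itertools.combinations(grp, 2)]
        rows += [("l0", "x", 0.05, 0.05, 20.0), ("l1", "x", 0.05, 0.05, 20.0),
                 ("x", "r0", 0.05, 0.05, 20.0), ("x", "r1", 0.05, 0.05, 20.0)]
        pairs = self._pairs(rows)
        assert detect_bridge_markers(left + right + ["x"], pairs) == ["x"]
        assert detect_bridge_markers(left, self._pairs(
            [(a, b, 0.05, 0.05, 20.0) for a, b in itertools.combinations(left, 2)]
        )) == []


class TestRfLodMatrix:
    def test_layout(self):
        from radmap.linkmap import rf_lod_matrix

        pairs = pd.DataFrame(
            [("a", "b", 0.1, np.nan, 8.0)],
            columns=["locus_a", "locus_b", "r_f", "r_m", "lod"],
        )
        mat = rf_lod_matrix(pairs, ["a", "b"], sex="female")
        assert mat.loc["b", "a"] == pytest.approx(0.1)   # rf below diagonal
        assert mat.loc["a", "b"] == pytest.approx(8.0)   # LOD above
        assert np.isnan(mat.loc["a", "a"])


class TestOrdering:
    def test_additive_triangle(self):
        rf = {("a", "b"): 0.05, ("b", "c"): 0.05, ("a", "c"): 0.10}

        def lookup(x, y):
            return rf.get((x, y)) or rf.get((y, x)) or 0.5

        assert order_group(["b", "a", "c"], lookup) == ["a", "b", "c"]

    def test_two_markers_canonical(self):
        assert order_group(["b", "a"], lambda x, y: 0.1) == ["a", "b"]

    def test_recovers_simulated_order_with_ripple(self, rng):
        # 12 well-spaced markers, 200 meioses: order recovered up to reversal
        hits = 0
        for rep in range(20):
            n, m = 200, 12
            states = np.zeros((m, n), dtype=int)
            states[0] = rng.integers(0, 2, n)
            for k in range(1, m):
                flip = rng.random(n) < 0.05
                states[k] = np.where(flip, 1 - states[k - 1], states[k - 1])
            names = [f"m{chr(97 + i)}" for i in range(m)]
            rfhat = {}
            for i in range(m):
                for j in range(i + 1, m):
                    d = (states[i] != states[j]).mean()
                    rfhat[(names[i], names[j])] = min(d, 1 - d)

            def lookup(x, y):
                return rfhat.get((x, y)) or rfhat.get((y, x)) or 0.5

            got = order_group(sorted(names), lookup)
            if got == names or got == names[::-1]:
                hits += 1
        assert hits >= 18  # >= 90% of replicates


def _qc_maps(cfg):
    truth = simulate_family(cfg)
    gm = truth_genotype_matrix(truth)
    qc = run_qc(gm)
    maps = build_sex_maps(qc.filtered, qc.cross_types)
    return truth, qc, maps


class TestSexMaps:
    def test_d1_only_marker_set_gives_empty_male_map(self):
        cfg = SimConfig(
            n_chromosomes=2, markers_per_chromosome=10, n_offspring=96,
            psv_fraction=0.0, informativeness_mix=(0.0, 1.0, 0.0, 0.0), seed=21,
        ).validate()
        _, _, maps = _qc_maps(cfg)
        assert maps["male"].n_markers == 0
        assert maps["female"].n_markers > 0

    def test_b3_markers_in_both_maps(self):
        cfg = SimConfig(
            n_chromosomes=2, markers_per_chromosome=10, n_offspring=96,
            psv_fraction=0.0, informativeness_mix=(1.0, 0.0, 0.0, 0.0), seed=22,
        ).validate()
        _, qc, maps = _qc_maps(cfg)
        female = {m for g in maps["female"].groups for m in g.marker_positions()["marker"]}
        male = {m for g in maps["male"].groups for m in g.marker_positions()["marker"]}
        assert female and female == male

    def test_female_span_close_to_true_kosambi_sum(self):
        cfg = SimConfig(
            n_chromosomes=2, markers_per_chromosome=25, n_offspring=96,
            psv_fraction=0.0, inter_marker_rf_female=0.05,
            informativeness_mix=(0.0, 1.0, 0.0, 0.0), seed=23,
        ).validate()
        truth, qc, maps = _qc_maps(cfg)
        total = sum(g.span for g in maps["female"].groups)
        kept_per_chrom = []
        loci = truth.loci.set_index("locus_id")
        for g in maps["female"].groups:
            members = [m for rep in g.markers for m in g.members[rep]]
            orders = loci.loc[members, "order"].sort_values()
            kept_per_chrom.append(orders)
        expected = sum(
            kosambi_cm(0.5 * (1 - (1 - 2 * 0.05) ** (o2 - o1)))
            for orders in kept_per_chrom
            for o1, o2 in zip(orders, orders[1:])
        )
        assert abs(total - expected) / expected <= 0.15

    def test_positions_invariant_to_input_order(self):
        cfg = SimConfig(
            n_chromosomes=2, markers_per_chromosome=12, n_offspring=96,
            psv_fraction=0.0, seed=24,
        ).validate()
        truth = simulate_family(cfg)
        gm = truth_genotype_matrix(truth)
        qc = run_qc(gm)
        maps1 = build_sex_maps(qc.filtered, qc.cross_types)
        perm = np.random.default_rng(0).permutation(qc.filtered.n_loci)
        shuffled = qc.filtered.subset(perm)
        qc2_cross = classify_all(shuffled)
        maps2 = build_sex_maps(shuffled, qc2_cross)
        f1 = maps1["female"].to_frame().sort_values("marker").reset_index(drop=True)
        f2 = maps2["female"].to_frame().sort_values("marker").reset_index(drop=True)
        assert np.allclose(f1["position_cM"], f2["position_cM"], atol=1e-9)
        assert (f1["marker"] == f2["marker"]).all()

    def test_adjacent_rf_recovery(self):
        # |r_hat - r_true| <= 0.05 for >= 95% of informative adjacent pairs
        rf_true = 0.04
        cfg = SimConfig(
            n_chromosomes=3, markers_per_chromosome=20, n_offspring=96,
            psv_fraction=0.0, inter_marker_rf_female=rf_true,
            informativeness_mix=(0.0, 1.0, 0.0, 0.0), seed=25,
        ).validate()
        truth = simulate_family(cfg)
        gm = truth_genotype_matrix(truth)
        qc = run_qc(gm)
        engine = TwoPointEngine(qc.filtered, qc.cross_types)
        pairs = engine.pairwise()
        loci = truth.loci.set_index("locus_id")
        ok = total = 0
        for rec in pairs.itertuples():
            ca, cb = loci.loc[rec.locus_a], loci.loc[rec.locus_b]
            if ca["chrom"] != cb["chrom"] or abs(ca["order"] - cb["order"]) != 1:
                continue
            total += 1
            ok += abs(rec.r_f - rf_true) <= 0.05
        assert total > 20
        assert ok / total >= 0.95
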