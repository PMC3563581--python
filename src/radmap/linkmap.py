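"""Two-point linkage analysis and sex-specific Kosambi map construction.

Recombination fractions are estimated per pair of informative markers by
maximum likelihood with phase.  A parent heterozygous at both loci of a
pair transmits its two parental haplotypes with probability (1 - r)/2 each
and the two recombinants with probability r/2 each, where r is that
parent's recombination fraction; a parent not doubly heterozygous carries
no linkage information for the pair.  Likelihoods of the observed joint
genotype-class counts are maximised over (r_f, r_m) in [0, 0.5]^2 and over
phase; the LOD is the log10 likelihood ratio against r = 0.5.

For a pair where only one parent is doubly heterozygous the ML estimate has
a closed form: offspring whose transmitted haplotype at both loci can be
read off the genotypes give a binomial recombinant count (offspring that
are ambiguous — the AB class under an AB x AB marker — contribute only a
constant factor and drop out).  AB x AB pairs in both parents need the full
3 x 3 mixture likelihood, maximised numerically.

Map construction follows the two-stage outcross recipe: co-segregating
markers are binned (LOD >= 12 and rf <= 0.01, single linkage) and a
representative with the fewest missing calls is carried forward; linkage
groups are connected components at LOD >= 6; groups are ordered by
minimising the sum of adjacent recombination fractions (exhaustive for up
to seven markers, nearest-neighbour seriation plus a four-marker ripple
beyond); adjacent fractions map to centimorgans through the Kosambi
function.  Female maps use markers heterozygous in the dam (D1 + B3) with
r_f; male maps use D2 + B3 with r_m.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .genotype import MISSING, GenotypeMatrix
from .markerqc import CROSS_B3, CROSS_D1, CROSS_D2

LN10 = np.log(10.0)
PHASE_COUPLING = "coupling"
PHASE_REPULSION = "repulsion"

# ---------------------------------------------------------------------------
# Kosambi map function


def kosambi_cm(r):
    """Kosambi map distance d = 25 ln((1+2r)/(1-2r)) in centimorgans."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if d.ndim == 0 else d


# ---------------------------------------------------------------------------
# Transmission indicators and the joint-genotype likelihood

# _MATERNAL_INDICATOR[father_geno, offspring_geno] -> transmitted maternal
# allele (0/1) for a mother-heterozygous marker, or -9 if ambiguous /
# impossible / missing.
_NA = -9


def _build_indicator():
    table = np.full((3, 4), _NA, dtype=np.int8)  # col 3 = missing
    for hom, homallele in ((0, 0), (2, 1)):
        for m_allele in (0, 1):
            table[hom, m_allele + homallele] = m_allele
    table[1, 0] = 0  # other parent AB: hom offspring identify the allele
    table[1, 2] = 1
    return table


_IND_TABLE = _build_indicator()


def maternal_indicator(calls: np.ndarray, father_geno: int) -> np.ndarray:
    """Transmitted maternal allele per offspring (mother must be AB)."""
    g = np.where(np.asarray(calls) == MISSING, 3, np.asarray(calls))
    return _IND_TABLE[father_geno, g]


def paternal_indicator(calls: np.ndarray, mother_geno: int) -> np.ndarray:
    return _IND_TABLE[mother_geno, np.where(np.asarray(calls) == MISSING, 3, calls)]


def _binomial_lod(k: int, n: int) -> float:
    """log10 LR of r_hat = k/n against r = 0.5 (k = recombinants, k <= n/2)."""
    ll = n * np.log(2.0)
    if 0 < k:
        ll += k * np.log(k / n)
    if k < n:
        ll += (n - k) * np.log((n - k) / n)
    return float(ll / LN10)


# gamete-pair to genotype-cell tensor: maternal gamete a = 2*m1 + m2,
# paternal gamete b = 2*p1 + p2, cell c = 3*(m1+p1) + (m2+p2)
_GAMETE_MAP = np.zeros((4, 4, 9))
for _a, _b in itertools.product(range(4), range(4)):
    _m1, _m2 = _a >> 1, _a & 1
    _p1, _p2 = _b >> 1, _b & 1
    _GAMETE_MAP[_a, _b, 3 * (_m1 + _p1) + (_m2 + _p2)] = 1.0


def _gamete_probs(r):
    """Coupling-phase gamete probabilities for r in [0, 1].

    r > 0.5 parameterises the repulsion phase (r_eff = 1 - r), so a single
    sweep of [0, 1]^2 covers all four phase combinations of an AB x AB pair.
    """
    r = np.asarray(r, dtype=float)
    return np.stack(
        [(1 - r) / 2, r / 2, r / 2, (1 - r) / 2], axis=-1
    )


def b3_cell_probs(rf, rm) -> np.ndarray:
    """3x3 offspring genotype-class probabilities (flattened to 9) for an
    AB x AB / AB x AB pair, both parents in coupling at extended r in [0,1]."""
    qf = _gamete_probs(rf)
    qm = _gamete_probs(rm)
    return np.einsum("...a,...b,abc->...c", qf, qm, _GAMETE_MAP)


def joint_counts(calls_a: np.ndarray, calls_b: np.ndarray) -> np.ndarray:
    """Flattened 3x3 joint genotype counts over co-genotyped offspring."""
    ok = (calls_a != MISSING) & (calls_b != MISSING)
    cell = 3 * calls_a[ok].astype(np.int64) + calls_b[ok]
    return np.bincount(cell, minlength=9).astype(float)


_B3_GRID_CACHE: dict[float, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _b3_grid(step: float):
    """Precomputed (rf, rm, logP) over the extended [0, 1]^2 grid."""
    if step not in _B3_GRID_CACHE:
        r = np.round(np.arange(0.0, 1.0 + step / 2, step), 9)
        rf, rm = np.meshgrid(r, r, indexing="ij")
        p = b3_cell_probs(rf.ravel()[:, None], rm.ravel()[:, None]).reshape(-1, 9)
        logp = np.where(p > 0, np.log(np.maximum(p, 1e-300)), -1e30)
        _B3_GRID_CACHE[step] = (rf.ravel(), rm.ravel(), logp)
    return _B3_GRID_CACHE[step]


def _b3_ml_exhaustive(T: np.ndarray, step: float = 0.001):
    """Exhaustive scan of the extended grid (used by the per-pair API)."""
    rf, rm, logp = _b3_grid(step)
    ll = logp @ T
    best = int(np.argmax(ll))
    ll_null = float(np.log(np.maximum(b3_cell_probs(0.5, 0.5), 1e-300)) @ T)
    return rf[best], rm[best], float(ll[best]), ll_null


_B3_EQUAL_CACHE: dict[float, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _b3_equal_grids(step: float = 0.0005):
    """Extended equal-rate grids for AB x AB pairs.

    The unconstrained (r_f, r_m) likelihood of an AB x AB / AB x AB pair is
    only weakly identified: when the (AA, BB) anti-corner cells of the 3x3
    table are empty — expected already at moderate linkage — the joint MLE
    collapses onto the r_f = 0 (or r_m = 0) boundary ridge.  Map
    construction therefore estimates these pairs under the standard
    outcross constraint r_f = r_m = r, scanning r in [0, 1] for the two
    aligned phase pairs (coupling/coupling folds to repulsion/repulsion
    past 0.5) and again for the crossed pairs (coupling/repulsion).
    Returns (r_grid, logP_aligned, logP_crossed).
    """
    if step not in _B3_EQUAL_CACHE:
        r = np.round(np.arange(0.0, 1.0 + step / 2, step), 9)
        p_aligned = b3_cell_probs(r, r)
        p_crossed = b3_cell_probs(r, 1.0 - r)
        logs = []
        for p in (p_aligned, p_crossed):
            logs.append(
                np.where(p > 0, np.log(np.maximum(p, 1e-300)), -1e30).astype(np.float32)
            )
        _B3_EQUAL_CACHE[step] = (r, logs[0], logs[1])
    return _B3_EQUAL_CACHE[step]


def _b3_equal_ml_batch(T: np.ndarray, step: float = 0.0005):
    """Equal-rate ML per pair, vectorised.

    ``T`` is (m, 9).  Returns (r, phase_f, phase_m, ll_max, ll_null) with r
    already folded into [0, 0.5].
    """
    r_grid, log_aligned, log_crossed = _b3_equal_grids(step)
    m = T.shape[0]
    r = np.empty(m)
    phase_f = np.empty(m, dtype=object)
    phase_m = np.empty(m, dtype=object)
    ll_max = np.empty(m)
    chunk = 1024
    for s in range(0, m, chunk):
        block = T[s : s + chunk].astype(np.float32)
        ll_a = block @ log_aligned.T
        ll_c = block @ log_crossed.T
        best_a = np.argmax(ll_a, axis=1)
        best_c = np.argmax(ll_c, axis=1)
        rows = np.arange(block.shape[0])
        use_crossed = ll_c[rows, best_c] > ll_a[rows, best_a]
        best = np.where(use_crossed, best_c, best_a)
        ll_max[s : s + chunk] = np.where(
            use_crossed, ll_c[rows, best_c], ll_a[rows, best_a]
        )
        r_ext = r_grid[best]
        coupling_f = r_ext <= 0.5
        r[s : s + chunk] = np.minimum(r_ext, 1.0 - r_ext)
        phase_f[s : s + chunk] = np.where(
            coupling_f, PHASE_COUPLING, PHASE_REPULSION
        )
        # aligned: father phase equals mother's; crossed: opposite
        same = coupling_f ^ use_crossed
        phase_m[s : s + chunk] = np.where(same, PHASE_COUPLING, PHASE_REPULSION)
    ll_null = T @ np.log(np.maximum(b3_cell_probs(0.5, 0.5), 1e-300))
    return r, phase_f, phase_m, ll_max, ll_null


def _fold_phase(r_ext: float) -> tuple[float, str]:
    if r_ext <= 0.5:
        return float(r_ext), PHASE_COUPLING
    return float(1.0 - r_ext), PHASE_REPULSION


@dataclass
class TwoPointResult:
    """Pairwise recombination estimate with phase and LOD."""

    locus_a: str
    locus_b: str
    r_f: float          # nan where the dam is not doubly heterozygous
    r_m: float
    phase_f: str | None
    phase_m: str | None
    lod: float
    n: int              # co-genotyped offspring


def two_point(calls_a, calls_b, parents_a, parents_b,
              locus_a: str = "A", locus_b: str = "B",
              grid_step: float = 0.001) -> TwoPointResult | None:
    """Two-point ML for one marker pair.

    ``parents_*`` are (mother_call, father_call) genotype codes for each
    marker.  Returns None for pairs with no linkage information (no parent
    doubly heterozygous, or no co-genotyped offspring).  AB x AB pairs are
    maximised by exhaustive scan of a ``grid_step`` grid over the extended
    phase-folded parameter square.
    """
    calls_a = np.asarray(calls_a, dtype=np.int8)
    calls_b = np.asarray(calls_b, dtype=np.int8)
    ma, fa = int(parents_a[0]), int(parents_a[1])
    mb, fb = int(parents_b[0]), int(parents_b[1])
    mother_doubly = ma == 1 and mb == 1
    father_doubly = fa == 1 and fb == 1
    if not mother_doubly and not father_doubly:
        return None
    both = (calls_a != MISSING) & (calls_b != MISSING)
    n = int(both.sum())
    if n == 0:
        return None

    if mother_doubly and father_doubly:
        T = joint_counts(calls_a, calls_b)
        rf_ext, rm_ext, ll, ll_null = _b3_ml_exhaustive(T, grid_step)
        r_f, phase_f = _fold_phase(rf_ext)
        r_m, phase_m = _fold_phase(rm_ext)
        return TwoPointResult(
            locus_a, locus_b, r_f, r_m, phase_f, phase_m,
            lod=max(0.0, (ll - ll_null) / LN10), n=n,
        )

    if mother_doubly:
        ind_a = maternal_indicator(calls_a, fa)
        ind_b = maternal_indicator(calls_b, fb)
    else:
        ind_a = paternal_indicator(calls_a, ma)
        ind_b = paternal_indicator(calls_b, mb)
    ok = (ind_a != _NA) & (ind_b != _NA)
    n_u = int(ok.sum())
    if n_u == 0:
        return None
    mismatches = int((ind_a[ok] != ind_b[ok]).sum())
    k = min(mismatches, n_u - mismatches)
    r_hat = k / n_u
    phase = PHASE_COUPLING if mismatches <= n_u - mismatches else PHASE_REPULSION
    lod = _binomial_lod(k, n_u)
    if mother_doubly:
        return TwoPointResult(locus_a, locus_b, r_hat, np.nan, phase, None, lod, n)
    return TwoPointResult(locus_a, locus_b, np.nan, r_hat, None, phase, lod, n)


# ---------------------------------------------------------------------------
# Bulk pairwise engine


class TwoPointEngine:
    """All-pairs two-point estimation over a QC-passed genotype matrix.

    A cheap vectorised screen (closed-form binomial LOD on the
    unambiguous-transmission subset, plus a 2-df score statistic for
    AB x AB pairs) prunes unlinked pairs; surviving AB x AB / AB x AB
    pairs are estimated under the equal-rate constraint r_f = r_m with all
    four phase combinations (see :func:`_b3_equal_grids` for why the
    unconstrained joint MLE is not usable for map construction).
    """

    def __init__(self, gm: GenotypeMatrix, cross_types: pd.Series,
                 screen_lod: float = 1.5):
        self.gm = gm
        self.cross = cross_types.reindex(gm.loci)
        self.screen_lod = screen_lod
        ct = self.cross.to_numpy()
        self.informative = np.isin(ct, [CROSS_B3, CROSS_D1, CROSS_D2])
        self.mother_het = np.isin(ct, [CROSS_B3, CROSS_D1])
        self.father_het = np.isin(ct, [CROSS_B3, CROSS_D2])
        self._pairs: pd.DataFrame | None = None

    def _indicator_matrix(self, maternal: bool) -> np.ndarray:
        gm = self.gm
        out = np.full(gm.calls.shape, _NA, dtype=np.int8)
        het = self.mother_het if maternal else self.father_het
        other = gm.father if maternal else gm.mother
        for i in np.flatnonzero(het):
            table = _IND_TABLE[other[i]]
            g = np.where(gm.calls[i] == MISSING, 3, gm.calls[i])
            out[i] = table[g]
        return out

    @staticmethod
    def _closed_form_lod(ind: np.ndarray):
        """Pairwise (n_u, k, lod) matrices from an indicator matrix."""
        defined = (ind != _NA).astype(np.float32)
        ones = (ind == 1).astype(np.float32)
        zeros = (ind == 0).astype(np.float32)
        n_u = defined @ defined.T
        equal = ones @ ones.T + zeros @ zeros.T
        mism = n_u - equal
        k = np.minimum(mism, equal)
        with np.errstate(divide="ignore", invalid="ignore"):
            term_k = np.where(k > 0, k * np.log(k / np.maximum(n_u, 1)), 0.0)
            nk = n_u - k
            term_nk = np.where(nk > 0, nk * np.log(nk / np.maximum(n_u, 1)), 0.0)
        lod = (n_u * np.log(2.0) + term_k + term_nk) / LN10
        lod[n_u == 0] = 0.0
        return n_u, k, mism, lod

    def pairwise(self, keep_lod: float = 1.0) -> pd.DataFrame:
        """Two-point table for all informative pairs with LOD >= ``keep_lod``."""
        gm = self.gm
        n_loci = gm.n_loci
        loci = np.asarray(gm.loci)
        mi = self._indicator_matrix(maternal=True)
        pi = self._indicator_matrix(maternal=False)
        n_mat, k_mat, mism_mat, lod_mat = self._closed_form_lod(mi)
        n_pat, k_pat, mism_pat, lod_pat = self._closed_form_lod(pi)

        mat_pair = np.outer(self.mother_het, self.mother_het)
        pat_pair = np.outer(self.father_het, self.father_het)
        b3 = self.mother_het & self.father_het
        b3_pair = np.outer(b3, b3)

        upper = np.triu(np.ones((n_loci, n_loci), dtype=bool), k=1)
        screen = np.where(mat_pair, lod_mat, -np.inf)
        screen = np.maximum(screen, np.where(pat_pair, lod_pat, -np.inf))
        # For AB x AB pairs the unambiguous subset sees only ~a quarter of
        # the offspring (and none at all when the parents are in opposite
        # phases), so additionally screen on a 2-df score statistic over all
        # co-genotyped offspring: the centred-code cross-product z1 detects
        # same-phase linkage, and the homozygosity association z2 detects
        # the hom<->het coupling signature of mixed-phase linkage.
        x = np.where(gm.calls == MISSING, 0.0, gm.calls - 1.0).astype(np.float32)
        present = (gm.calls != MISSING).astype(np.float32)
        z1 = x @ x.T
        xsq = x * x
        var1 = np.maximum(xsq @ xsq.T, 1e-9)
        u = (xsq - 0.5) * present  # hom/het indicator centred at the B3 null
        z2 = u @ u.T
        usq = u * u
        var2 = np.maximum(usq @ usq.T, 1e-9)
        corr_proxy = (z1 * z1 / var1 + z2 * z2 / var2) / (2.0 * LN10)
        screen = np.where(
            b3_pair, np.maximum(lod_mat + lod_pat, corr_proxy), screen
        )
        candidates = upper & (screen >= min(self.screen_lod, keep_lod))

        present = (gm.calls != MISSING).astype(np.float32)
        n_cogeno = present @ present.T

        frames: list[pd.DataFrame] = []

        def fold_1d(mask: np.ndarray, n_u, k, mism, lod_all, maternal: bool):
            i_idx, j_idx = np.nonzero(mask)
            if i_idx.size == 0:
                return
            n_here = n_u[i_idx, j_idx]
            ok = n_here > 0
            i_idx, j_idx, n_here = i_idx[ok], j_idx[ok], n_here[ok]
            lod = lod_all[i_idx, j_idx]
            keep = lod >= keep_lod
            i_idx, j_idx, n_here, lod = i_idx[keep], j_idx[keep], n_here[keep], lod[keep]
            if i_idx.size == 0:
                return
            kk = k[i_idx, j_idx]
            r_hat = kk / n_here
            mm = mism[i_idx, j_idx]
            phase = np.where(mm <= n_here - mm, PHASE_COUPLING, PHASE_REPULSION)
            df = pd.DataFrame(
                {
                    "locus_a": loci[i_idx], "locus_b": loci[j_idx],
                    "i": i_idx, "j": j_idx,
                    "r_f": r_hat if maternal else np.nan,
                    "r_m": np.nan if maternal else r_hat,
                    "phase_f": phase if maternal else None,
                    "phase_m": None if maternal else phase,
                    "lod": lod,
                    "n": n_cogeno[i_idx, j_idx].astype(int),
                }
            )
            frames.append(df)

        fold_1d(candidates & mat_pair & ~b3_pair, n_mat, k_mat, mism_mat,
                lod_mat, maternal=True)
        fold_1d(candidates & pat_pair & ~b3_pair, n_pat, k_pat, mism_pat,
                lod_pat, maternal=False)

        # AB x AB pairs: full 3x3 mixture ML
        bi, bj = np.nonzero(candidates & b3_pair)
        if bi.size:
            present = gm.calls != MISSING
            G = [
                ((gm.calls == g) & present).astype(np.float32) for g in (0, 1, 2)
            ]
            T = np.empty((bi.size, 9))
            cell = 0
            for ga in range(3):
                for gb in range(3):
                    prod = G[ga] @ G[gb].T
                    T[:, cell] = prod[bi, bj]
                    cell += 1
            r_eq, phase_f, phase_m, ll_max, ll_null = _b3_equal_ml_batch(T)
            lods = np.maximum(0.0, (ll_max - ll_null) / LN10)
            n_pair = T.sum(axis=1).astype(int)
            keep = lods >= keep_lod
            if keep.any():
                frames.append(
                    pd.DataFrame(
                        {
                            "locus_a": loci[bi[keep]], "locus_b": loci[bj[keep]],
                            "i": bi[keep], "j": bj[keep],
                            "r_f": r_eq[keep],
                            "r_m": r_eq[keep],
                            "phase_f": phase_f[keep],
                            "phase_m": phase_m[keep],
                            "lod": lods[keep],
                            "n": n_pair[keep],
                        }
                    )
                )

        columns = ["locus_a", "locus_b", "i", "j", "r_f", "r_m",
                   "phase_f", "phase_m", "lod", "n"]
        if frames:
            pairs = pd.concat(frames, ignore_index=True)[columns]
        else:
            pairs = pd.DataFrame(columns=columns)
        self._pairs = pairs.sort_values(["locus_a", "locus_b"]).reset_index(drop=True)
        return self._pairs

    def pair(self, locus_a: str, locus_b: str) -> TwoPointResult | None:
        """Exact single-pair two-point (used to fill in unscreened pairs).

        AB x AB pairs use the same equal-rate estimator as the bulk table
        so map distances stay consistent.
        """
        gm = self.gm
        ia = gm.loci.get_loc(locus_a)
        ib = gm.loci.get_loc(locus_b)
        parents_a = (gm.mother[ia], gm.father[ia])
        parents_b = (gm.mother[ib], gm.father[ib])
        if all(p == 1 for p in (*parents_a, *parents_b)):
            T = joint_counts(gm.calls[ia], gm.calls[ib])
            if T.sum() == 0:
                return None
            r, pf, pm, ll, lln = _b3_equal_ml_batch(T[None, :])
            return TwoPointResult(
                locus_a, locus_b, float(r[0]), float(r[0]), pf[0], pm[0],
                lod=max(0.0, float(ll[0] - lln[0]) / LN10), n=int(T.sum()),
            )
        return two_point(
            gm.calls[ia], gm.calls[ib], parents_a, parents_b,
            locus_a=locus_a, locus_b=locus_b,
        )


# ---------------------------------------------------------------------------
# Grouping, ordering, maps


def rf_lod_matrix(pairs: pd.DataFrame, markers: list[str],
                  sex: str = "female") -> pd.DataFrame:
    """Square marker matrix with rf below the diagonal and LOD above.

    The classic recombination-matrix heat-map layout for reviewing a
    linkage group by eye; unestimated pairs are left NaN.
    """
    rcol = "r_f" if sex == "female" else "r_m"
    idx = {m: i for i, m in enumerate(markers)}
    mat = np.full((len(markers), len(markers)), np.nan)
    sub = pairs[pairs["locus_a"].isin(idx) & pairs["locus_b"].isin(idx)]
    for rec in sub.itertuples(index=False):
        i, j = idx[rec.locus_a], idx[rec.locus_b]
        lo, hi = min(i, j), max(i, j)
        mat[hi, lo] = getattr(rec, rcol)
        mat[lo, hi] = rec.lod
    return pd.DataFrame(mat, index=markers, columns=markers)


def bin_cosegregating(pairs: pd.DataFrame, markers: list[str],
                      missing_counts: pd.Series, sex: str,
                      lod_bin: float = 12.0, rf_bin: float = 0.01) -> dict[str, list[str]]:
    """Single-linkage bins of co-segregating markers.

    Edges require LOD >= ``lod_bin`` and the sex-specific rf <= ``rf_bin``.
    The representative of each bin is the member with the fewest missing
    genotypes (ties broken by locus id).  Returns representative -> members.
    """
    rcol = "r_f" if sex == "female" else "r_m"
    marker_set = set(markers)
    g = nx.Graph()
    g.add_nodes_from(markers)
    sub = pairs[
        pairs["locus_a"].isin(marker_set)
        & pairs["locus_b"].isin(marker_set)
        & (pairs["lod"] >= lod_bin)
        & (pairs[rcol] <= rf_bin)
    ]
    g.add_edges_from(zip(sub["locus_a"], sub["locus_b"]))
    bins = {}
    for comp in nx.connected_components(g):
        members = sorted(comp)
        rep = min(members, key=lambda m: (missing_counts.get(m, 0), m))
        bins[rep] = members
    return bins


def form_groups(pairs: pd.DataFrame, markers: list[str],
                lod_group: float = 6.0) -> list[list[str]]:
    """Connected components of the LOD >= ``lod_group`` graph."""
    marker_set = set(markers)
    g = nx.Graph()
    g.add_nodes_from(markers)
    sub = pairs[
        pairs["locus_a"].isin(marker_set)
        & pairs["locus_b"].isin(marker_set)
        & (pairs["lod"] >= lod_group)
    ]
    g.add_edges_from(zip(sub["locus_a"], sub["locus_b"]))
    comps = [sorted(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: (-len(c), c[0]))


def detect_bridge_markers(markers: list[str], pairs: pd.DataFrame,
                          lod_threshold: float = 6.0) -> list[str]:
    """Markers whose removal splits a group into components of >= 2 markers.

    These single-marker bridges are the signature of spurious joins between
    otherwise unlinked groups; they are flagged for review.
    """
    marker_set = set(markers)
    g = nx.Graph()
    g.add_nodes_from(markers)
    sub = pairs[
        pairs["locus_a"].isin(marker_set)
        & pairs["locus_b"].isin(marker_set)
        & (pairs["lod"] >= lod_threshold)
    ]
    g.add_edges_from(zip(sub["locus_a"], sub["locus_b"]))
    bridges = []
    for ap in nx.articulation_points(g):
        h = g.copy()
        h.remove_node(ap)
        comps = list(nx.connected_components(h))
        if len(comps) >= 2 and all(len(c) >= 2 for c in comps):
            bridges.append(ap)
    return sorted(bridges)


def _sarf(order: list[str], rf) -> float:
    return sum(rf(a, b) for a, b in zip(order, order[1:]))


def _canonical(order: list[str]) -> list[str]:
    if order and order[-1] < order[0]:
        return order[::-1]
    return order


def order_group(markers: list[str], rf, ripple_window: int = 4,
                exhaustive_limit: int = 7) -> list[str]:
    """Order markers by minimising the sum of adjacent recombination fractions.

    ``rf(a, b)`` returns the pairwise fraction (0.5 for unestimated pairs).
    Up to ``exhaustive_limit`` markers: exhaustive search.  Beyond: greedy
    nearest-neighbour chain seeded from the tightest pair, then a sliding
    ``ripple_window`` permutation pass repeated until no strict improvement.
    Orientation is canonicalised so the end marker with the lower id leads.
    """
    markers = sorted(markers)
    if len(markers) <= 2:
        return _canonical(markers)

    if len(markers) <= exhaustive_limit:
        first = markers[0]
        best, best_s = None, np.inf
        for perm in itertools.permutations(markers):
            if perm[0] > perm[-1]:
                continue  # each order once, up to reversal
            s = _sarf(list(perm), rf)
            if s < best_s - 1e-12:
                best, best_s = list(perm), s
        return _canonical(best)

    # greedy chain from the tightest pair
    pairs_sorted = sorted(
        ((rf(a, b), a, b) for i, a in enumerate(markers) for b in markers[i + 1:]),
        key=lambda t: (t[0], t[1], t[2]),
    )
    _, a, b = pairs_sorted[0]
    chain = [a, b]
    remaining = [m for m in markers if m not in chain]
    while remaining:
        head, tail = chain[0], chain[-1]
        best = min(
            ((rf(end, m), e_idx, m)
             for e_idx, end in ((0, head), (1, tail)) for m in remaining),
            key=lambda t: (t[0], t[2], t[1]),
        )
        _, e_idx, m = best
        if e_idx == 0:
            chain.insert(0, m)
        else:
            chain.append(m)
        remaining.remove(m)

    # ripple: permute every sliding window, accept strict SARF improvements
    w = ripple_window
    improved = True
    while improved:
        improved = False
        current = _sarf(chain, rf)
        for start in range(0, len(chain) - w + 1):
            window = chain[start : start + w]
            for perm in itertools.permutations(window):
                if list(perm) == window:
                    continue
                trial = chain[:start] + list(perm) + chain[start + w:]
                s = _sarf(trial, rf)
                if s < current - 1e-12:
                    chain, current = trial, s
                    improved = True
    return _canonical(chain)


@dataclass
class LinkageGroup:
    """Ordered markers with cumulative Kosambi positions for one sex."""

    group_id: str
    sex: str
    markers: list[str]            # ordered representatives
    adjacent_rf: list[float]
    positions: np.ndarray         # cM, positions[0] == 0
    members: dict[str, list[str]] = field(default_factory=dict)  # rep -> binned

    @property
    def span(self) -> float:
        return float(self.positions[-1]) if len(self.positions) else 0.0

    @property
    def n_markers(self) -> int:
        return sum(len(self.members.get(m, [m])) for m in self.markers)

    @property
    def is_fragment(self) -> bool:
        return self.n_markers < 4

    def marker_positions(self) -> pd.DataFrame:
        rows = []
        for rep, pos in zip(self.markers, self.positions):
            for m in self.members.get(rep, [rep]):
                rows.append({"marker": m, "position_cM": float(pos),
                             "representative": rep})
        return pd.DataFrame(rows)


@dataclass
class GeneticMap:
    """Per-sex map: linkage groups, small fragments, unplaced markers."""

    sex: str
    groups: list[LinkageGroup]
    fragments: list[LinkageGroup]
    unplaced: list[str]

    @property
    def total_length(self) -> float:
        return float(sum(g.span for g in self.groups))

    @property
    def n_markers(self) -> int:
        return sum(g.n_markers for g in self.groups)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for g in self.groups + self.fragments:
            df = g.marker_positions()
            df.insert(0, "group", g.group_id)
            df.insert(0, "sex", self.sex)
            df["is_fragment"] = g.is_fragment
            frames.append(df)
        if not frames:
            return pd.DataFrame(
                columns=["sex", "group", "marker", "position_cM",
                         "representative", "is_fragment"]
            )
        return pd.concat(frames, ignore_index=True)


MAX_ADJACENT_RF = 0.495  # Kosambi guard for boundary estimates


def _build_group(group_id: str, sex: str, ordered: list[str], rf,
                 members: dict[str, list[str]]) -> LinkageGroup:
    adj = [min(rf(a, b), MAX_ADJACENT_RF) for a, b in zip(ordered, ordered[1:])]
    positions = np.concatenate([[0.0], np.cumsum([kosambi_cm(r) for r in adj])])
    return LinkageGroup(
        group_id=group_id, sex=sex, markers=ordered,
        adjacent_rf=adj, positions=positions,
        members={m: members.get(m, [m]) for m in ordered},
    )


def build_sex_maps(gm: GenotypeMatrix, cross_types: pd.Series,
                   engine: TwoPointEngine | None = None,
                   pairs: pd.DataFrame | None = None,
                   lod_bin: float = 12.0, rf_bin: float = 0.01,
                   lod_group: float = 6.0, ripple_window: int = 4,
                   min_group_size: int = 4) -> dict[str, GeneticMap]:
    """Build the female and male maps from a QC-passed genotype matrix."""
    if engine is None:
        engine = TwoPointEngine(gm, cross_types)
    if pairs is None:
        pairs = engine.pairwise()
    missing_counts = pd.Series(
        (gm.calls == MISSING).sum(axis=1), index=gm.loci
    )

    maps = {}
    for sex, crosses, rcol in (
        ("female", (CROSS_D1, CROSS_B3), "r_f"),
        ("male", (CROSS_D2, CROSS_B3), "r_m"),
    ):
        markers = [
            locus for locus in gm.loci if cross_types.get(locus) in crosses
        ]
        sex_pairs = pairs[pairs[rcol].notna()]
        rf_lookup = {}
        for rec in sex_pairs.itertuples(index=False):
            key = (rec.locus_a, rec.locus_b)
            rf_lookup[key] = getattr(rec, rcol)
            rf_lookup[key[::-1]] = getattr(rec, rcol)

        def rf(a, b):
            # pairs below the keep threshold are effectively unlinked
            return rf_lookup.get((a, b), 0.5)

        def rf_adjacent(a, b):
            val = rf_lookup.get((a, b))
            if val is None:
                res = engine.pair(a, b)
                val = getattr(res, rcol) if res is not None else np.nan
                if val is None or np.isnan(val):
                    val = 0.5
                rf_lookup[(a, b)] = rf_lookup[(b, a)] = val
            return val

        bins = bin_cosegregating(
            sex_pairs, markers, missing_counts, sex,
            lod_bin=lod_bin, rf_bin=rf_bin,
        )
        reps = sorted(bins)
        components = form_groups(sex_pairs, reps, lod_group=lod_group)

        groups, fragments, unplaced = [], [], []
        lg_no = 0
        for comp in components:
            total_markers = sum(len(bins[r]) for r in comp)
            if total_markers == 1:
                unplaced.extend(bins[comp[0]])
                continue
            ordered = order_group(comp, rf, ripple_window=ripple_window)
            lg_no += 1
            group = _build_group(f"{sex[0].upper()}LG{lg_no:02d}", sex,
                                 ordered, rf_adjacent, bins)
            if group.n_markers < min_group_size:
                fragments.append(group)
            else:
                groups.append(group)
        maps[sex] = GeneticMap(
            sex=sex, groups=groups, fragments=fragments, unplaced=sorted(unplaced)
        )
    return maps
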