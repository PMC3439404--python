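"""Two-point linkage analysis and map construction for an outbred CP family.

A cross-pollinated (CP) full-sib family mixes marker segregation types:
dominant pseudo-testcross markers informative through one parent (1:1),
dominant intercross markers heterozygous in both parents (3:1), fully
informative codominant markers (1:1:1:1) and phase-unknown codominant
intercross markers (1:2:1).  For any pair of markers the joint progeny
class probabilities are assembled from the per-parent transmission model:
each parent that is heterozygous for both markers transmits the two marked
alleles together with probability (1-r) under coupling (r under
repulsion), and every other transmission is an independent fair coin.
Observation models map transmitted alleles to scored classes (dominant
presence is an OR over parents) and an optional known per-score error
rate is folded in as a symmetric misclassification channel.

The recombination fraction is estimated by maximizing this likelihood
over r in [0, 0.5) for every admissible phase combination; the supported
LOD is log10 L(r_hat)/L(0.5).  Pairs with no commonly informative parent
(e.g. two dominant testcross markers from different parents) are
structurally uninformative and reported with LOD 0.

Grouping is a single-linkage transitive closure over pairs exceeding a
LOD threshold with r_hat below a ceiling.  Ordering within a group is a
greedy insertion seriation minimizing the sum of adjacent recombination
fractions, refined by a window-1 ripple; framework mode defers markers
whose placement is poorly supported (goodness-of-fit jump above a
threshold, or a statistically ambiguous best position).  Distances are
cumulative Kosambi centiMorgans.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_data import (
    F2_INTERCROSS,
    FULLY_INFORMATIVE,
    INTERCROSS,
    MISSING,
    TESTCROSS_P1,
    TESTCROSS_P2,
)

_LN10 = math.log(10.0)
_R_CAP = 0.4999


# ---------------------------------------------------------------------------
# mapping function


def kosambi_cm(r: float | np.ndarray) -> float | np.ndarray:
    """Kosambi map distance d = 25 ln((1+2r)/(1-2r)) in centiMorgans."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must be in [0, 0.5)")
    d = 25.0 * np.log((1 + 2 * r) / (1 - 2 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_r(d: float | np.ndarray) -> float | np.ndarray:
    """Inverse Kosambi: r = tanh(d/50)/2; round-trips with kosambi_cm."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be >= 0")
    r = 0.5 * np.tanh(d / 50.0)
    return float(r) if r.ndim == 0 else r


# ---------------------------------------------------------------------------
# observation models

#: parents informative (heterozygous) for each segregation type
_INFORMATIVE = {
    TESTCROSS_P1: (True, False),
    TESTCROSS_P2: (False, True),
    INTERCROSS: (True, True),
    FULLY_INFORMATIVE: (True, True),
    F2_INTERCROSS: (True, True),
}

_N_OBS = {
    TESTCROSS_P1: 2,
    TESTCROSS_P2: 2,
    INTERCROSS: 2,
    FULLY_INFORMATIVE: 4,
    F2_INTERCROSS: 3,
}

_CODE_MAPS = {
    TESTCROSS_P1: {"0": 0, "1": 1},
    TESTCROSS_P2: {"0": 0, "1": 1},
    INTERCROSS: {"0": 0, "1": 1},
    FULLY_INFORMATIVE: {"bd": 0, "bc": 1, "ad": 2, "ac": 3},
    F2_INTERCROSS: {"bb": 0, "ab": 1, "aa": 2},
}


def _observe(seg_type: str, x1: int, x2: int) -> int:
    """Observed class index given marked-allele transmissions (x1, x2)."""
    if seg_type == TESTCROSS_P1:
        return x1
    if seg_type == TESTCROSS_P2:
        return x2
    if seg_type == INTERCROSS:
        return x1 | x2
    if seg_type == FULLY_INFORMATIVE:
        return 2 * x1 + x2
    if seg_type == F2_INTERCROSS:
        return x1 + x2
    raise ValueError(f"unknown segregation type {seg_type!r}")


def _error_channel(seg_type: str, eps: float) -> np.ndarray:
    """Observation transition matrix (true class -> scored class)."""
    f = np.array([[1 - eps, eps], [eps, 1 - eps]])
    if seg_type in (TESTCROSS_P1, TESTCROSS_P2, INTERCROSS):
        return f
    k4 = np.kron(f, f)  # state order 2*x1+x2
    if seg_type == FULLY_INFORMATIVE:
        return k4
    # 1:2:1 observes the allele count; the heterozygote class mixes the
    # (0,1) and (1,0) transmission states evenly
    collapse = np.zeros((3, 4))
    collapse[0, 0] = collapse[1, 1] = collapse[1, 2] = collapse[2, 3] = 1.0
    expand = np.zeros((4, 3))
    expand[0, 0] = expand[3, 2] = 1.0
    expand[1, 1] = expand[2, 1] = 0.5
    return collapse @ k4 @ expand


def shared_informative_parents(type_a: str, type_b: str) -> list[int]:
    """Parents (0-indexed) heterozygous for both markers of a pair."""
    ia, ib = _INFORMATIVE[type_a], _INFORMATIVE[type_b]
    return [p for p in range(2) if ia[p] and ib[p]]


def pair_class_probs(
    type_a: str,
    type_b: str,
    phase: tuple[int, ...],
    r: np.ndarray,
    error_rate: float = 0.0,
) -> np.ndarray:
    """Joint scored-class probabilities, shape (n_obs_a, n_obs_b, len(r)).

    ``phase`` gives one 0/1 flag (0 coupling, 1 repulsion) per shared
    informative parent, in parent order.
    """
    r = np.atleast_1d(np.asarray(r, dtype=float))
    shared = shared_informative_parents(type_a, type_b)
    if len(phase) != len(shared):
        raise ValueError("phase length must match shared informative parents")
    phase_by_parent = dict(zip(shared, phase))
    na, nb = _N_OBS[type_a], _N_OBS[type_b]
    probs = np.zeros((na, nb, r.size))
    for xa1 in (0, 1):
        for xb1 in (0, 1):
            for xa2 in (0, 1):
                for xb2 in (0, 1):
                    w = np.ones(r.size)
                    for parent, (xa, xb) in enumerate(
                        ((xa1, xb1), (xa2, xb2))
                    ):
                        if parent in phase_by_parent:
                            same = (xa == xb) ^ phase_by_parent[parent]
                            w = w * np.where(same, (1 - r) / 2, r / 2)
                        else:
                            w = w * 0.25
                    probs[_observe(type_a, xa1, xa2), _observe(type_b, xb1, xb2)] += w
    if error_rate > 0:
        ea = _error_channel(type_a, error_rate)
        eb = _error_channel(type_b, error_rate)
        probs = np.einsum("ij,jkl,mk->iml", ea, probs, eb)
    return probs


def encode_scores(scores: list[str] | np.ndarray, seg_type: str) -> np.ndarray:
    """Scored classes to integer codes (-1 for missing)."""
    table = _CODE_MAPS[seg_type]
    out = np.empty(len(scores), dtype=np.int8)
    for i, s in enumerate(scores):
        out[i] = table.get(str(s), -1) if str(s) != MISSING else -1
    return out


# ---------------------------------------------------------------------------
# two-point estimation


@dataclass
class TwoPointEstimate:
    marker_pair: tuple[str, str]
    r_hat: float
    phase: str
    lod: float
    n_shared: int
    informative: bool = True


_PHASE_NAMES = {0: "coupling", 1: "repulsion"}


def _phase_label(phase: tuple[int, ...], shared: list[int]) -> str:
    if not shared:
        return "uninformative"
    return "/".join(
        f"P{p + 1}:{_PHASE_NAMES[s]}" for p, s in zip(shared, phase)
    )


def _count_cells(codes_a: np.ndarray, codes_b: np.ndarray, na: int, nb: int) -> np.ndarray:
    valid = (codes_a >= 0) & (codes_b >= 0)
    return np.bincount(
        codes_a[valid] * nb + codes_b[valid], minlength=na * nb
    ).reshape(na, nb).astype(float)


def _loglik(counts: np.ndarray, probs: np.ndarray) -> np.ndarray:
    logp = np.log(np.maximum(probs, 1e-300))
    return np.tensordot(counts, logp, axes=([0, 1], [0, 1]))


_GOLDEN = (math.sqrt(5) - 1) / 2


def _golden_max(f, lo: float, hi: float, tol: float = 1e-6) -> float:
    a, b = lo, hi
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = f(d)
    return (a + b) / 2


def estimate_two_point(
    scores_a: list[str] | np.ndarray,
    scores_b: list[str] | np.ndarray,
    type_a: str,
    type_b: str,
    marker_pair: tuple[str, str] = ("A", "B"),
    error_rate: float = 0.0,
    min_shared: int = 20,
    tol: float = 1e-6,
) -> TwoPointEstimate:
    """Maximum-likelihood r and phase for one marker pair.

    The likelihood is maximized per candidate phase by golden-section
    search on [0, 0.5); the best-supported phase is retained, ties broken
    toward coupling.  Structurally uninformative pairs return LOD 0.
    """
    codes_a = encode_scores(scores_a, type_a)
    codes_b = encode_scores(scores_b, type_b)
    na, nb = _N_OBS[type_a], _N_OBS[type_b]
    counts = _count_cells(codes_a, codes_b, na, nb)
    n_shared = int(counts.sum())
    shared = shared_informative_parents(type_a, type_b)
    if not shared:
        return TwoPointEstimate(
            marker_pair, 0.5, "uninformative", 0.0, n_shared, informative=False
        )
    if n_shared < min_shared:
        raise ValueError(
            f"only {n_shared} individuals scored for both markers (< {min_shared})"
        )
    ll_half = float(
        _loglik(counts, pair_class_probs(type_a, type_b, (0,) * len(shared), np.array([0.5]), error_rate))[0]
    )
    best = None
    for code in range(2 ** len(shared)):
        phase = tuple((code >> k) & 1 for k in range(len(shared)))

        def ll(r: float, _phase=phase) -> float:
            return float(
                _loglik(
                    counts,
                    pair_class_probs(type_a, type_b, _phase, np.array([r]), error_rate),
                )[0]
            )

        r_hat = _golden_max(ll, 0.0, _R_CAP, tol=tol)
        for cand in (0.0, r_hat):  # boundary at r=0 beats an interior plateau edge
            val = ll(cand)
            if best is None or val > best[0] + 1e-12:
                best = (val, cand, phase)
    ll_best, r_best, phase_best = best
    lod = max(0.0, (ll_best - ll_half) / _LN10)
    return TwoPointEstimate(
        marker_pair,
        float(min(r_best, 0.5)),
        _phase_label(phase_best, shared),
        float(lod),
        n_shared,
    )


# ---------------------------------------------------------------------------
# vectorized all-pairs table


@dataclass
class TwoPointTable:
    """Symmetric pairwise r/LOD/phase matrices over a marker set."""

    markers: list[str]
    seg_types: list[str]
    r_hat: np.ndarray
    lod: np.ndarray
    n_shared: np.ndarray
    phase_code: np.ndarray  # -1 uninformative; else bitmask over shared parents
    codes: np.ndarray | None = None  # encoded scores (m x progeny), -1 missing
    error_rate: float = 0.0

    def index_of(self, marker: str) -> int:
        return self.markers.index(marker)

    def to_frame(self) -> pd.DataFrame:
        m = len(self.markers)
        iu, ju = np.triu_indices(m, k=1)
        return pd.DataFrame(
            {
                "marker_a": [self.markers[i] for i in iu],
                "marker_b": [self.markers[j] for j in ju],
                "r_hat": self.r_hat[iu, ju],
                "lod": self.lod[iu, ju],
                "n_shared": self.n_shared[iu, ju],
                "phase_code": self.phase_code[iu, ju],
            }
        )


def two_point_table(
    genotypes: pd.DataFrame,
    seg_types: pd.Series | dict[str, str],
    error_rate: float = 0.0,
    grid_size: int = 512,
    chunk_pairs: int = 40_000,
) -> TwoPointTable:
    """All-pairs two-point estimates by vectorized grid maximization.

    ``genotypes`` rows are markers (synthetic-data dialect with P1/P2
    columns allowed, ignored here); ``seg_types`` maps marker to
    segregation type.  The r grid spans [0, 0.5) at ~1e-3 resolution,
    adequate for grouping and seriation.
    """
    if isinstance(seg_types, dict):
        seg_types = pd.Series(seg_types)
    markers = [m for m in genotypes.index if m in seg_types.index]
    types = [seg_types[m] for m in markers]
    progeny_cols = [c for c in genotypes.columns if c not in ("P1", "P2")]
    m = len(markers)
    codes = np.full((m, len(progeny_cols)), -1, dtype=np.int8)
    for i, (mid, t) in enumerate(zip(markers, types)):
        codes[i] = encode_scores(genotypes.loc[mid, progeny_cols].tolist(), t)

    max_obs = max(_N_OBS[t] for t in types)
    indicators = [(codes == v).astype(np.float64) for v in range(max_obs)]
    valid = (codes >= 0).astype(np.float64)

    r_hat = np.full((m, m), 0.5)
    lod = np.zeros((m, m))
    n_shared = (valid @ valid.T).astype(np.int64)
    np.fill_diagonal(n_shared, valid.sum(axis=1).astype(np.int64))
    phase_code = np.full((m, m), -1, dtype=np.int8)

    r_grid = np.linspace(0.0, _R_CAP, grid_size)
    type_arr = np.array(types)
    type_rows: dict[str, np.ndarray] = {
        t: np.nonzero(type_arr == t)[0] for t in set(types)
    }

    for ta, rows_a in type_rows.items():
        for tb, rows_b in type_rows.items():
            if ta > tb:
                continue  # unordered type pairs; (ta, tb) with ta<=tb
            shared = shared_informative_parents(ta, tb)
            if not shared:
                continue
            na, nb = _N_OBS[ta], _N_OBS[tb]
            # log-prob tables: (n_phases, na*nb, grid+1), last column r=0.5
            n_ph = 2 ** len(shared)
            r_ext = np.concatenate([r_grid, [0.5]])
            logp = np.empty((n_ph, na * nb, r_ext.size))
            for code in range(n_ph):
                phase = tuple((code >> k) & 1 for k in range(len(shared)))
                p = pair_class_probs(ta, tb, phase, r_ext, error_rate)
                logp[code] = np.log(np.maximum(p, 1e-300)).reshape(na * nb, -1)

            if ta == tb:
                ii, jj = np.triu_indices(rows_a.size, k=1)
                pa, pb = rows_a[ii], rows_a[jj]
            else:
                pa = np.repeat(rows_a, rows_b.size)
                pb = np.tile(rows_b, rows_a.size)
            if pa.size == 0:
                continue

            for lo in range(0, pa.size, chunk_pairs):
                sa = pa[lo : lo + chunk_pairs]
                sb = pb[lo : lo + chunk_pairs]
                counts = np.empty((sa.size, na * nb))
                for a in range(na):
                    ia = indicators[a][sa]
                    for b in range(nb):
                        counts[:, a * nb + b] = np.einsum(
                            "ij,ij->i", ia, indicators[b][sb]
                        )
                best_ll = np.full(sa.size, -np.inf)
                best_r = np.full(sa.size, 0.5)
                best_ph = np.zeros(sa.size, dtype=np.int8)
                ll_half = counts @ logp[0, :, -1]
                for code in range(n_ph):
                    ll = counts @ logp[code, :, :-1]
                    k = np.argmax(ll, axis=1)
                    v = ll[np.arange(sa.size), k]
                    take = v > best_ll + 1e-9
                    best_ll[take] = v[take]
                    best_r[take] = r_grid[k[take]]
                    best_ph[take] = code
                pair_lod = np.maximum(0.0, (best_ll - ll_half) / _LN10)
                r_hat[sa, sb] = r_hat[sb, sa] = best_r
                lod[sa, sb] = lod[sb, sa] = pair_lod
                phase_code[sa, sb] = phase_code[sb, sa] = best_ph

    np.fill_diagonal(r_hat, 0.0)
    np.fill_diagonal(lod, 0.0)
    return TwoPointTable(
        markers=markers,
        seg_types=types,
        r_hat=r_hat,
        lod=lod,
        n_shared=n_shared,
        phase_code=phase_code,
        codes=codes,
        error_rate=error_rate,
    )


# ---------------------------------------------------------------------------
# grouping


@dataclass
class MappingParams:
    lod_threshold: float = 15.0
    r_max: float = 0.4
    ripple_window: int = 1
    jump_threshold: float = 5.0
    #: known per-score misclassification rate folded into the likelihood;
    #: 0 estimates r from raw concordance
    assay_error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.lod_threshold <= 0:
            raise ValueError("lod_threshold must be > 0")
        if not 0 < self.r_max < 0.5:
            raise ValueError("r_max must be in (0, 0.5)")


def group_markers(
    table: TwoPointTable, params: MappingParams | None = None
) -> tuple[list[list[str]], list[str]]:
    """Single-linkage grouping: components of {lod > threshold, r <= r_max}.

    Returns (groups with >= 2 markers, ungrouped singleton markers).
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    params = params or MappingParams()
    edges = (table.lod > params.lod_threshold) & (table.r_hat <= params.r_max)
    np.fill_diagonal(edges, False)
    n_comp, labels = connected_components(csr_matrix(edges), directed=False)
    groups, singletons = [], []
    for comp in range(n_comp):
        members = [table.markers[i] for i in np.nonzero(labels == comp)[0]]
        if len(members) > 1:
            groups.append(members)
        else:
            singletons.extend(members)
    groups.sort(key=len, reverse=True)
    return groups, singletons


# ---------------------------------------------------------------------------
# ordering


@dataclass
class LinkageGroup:
    group_id: str
    markers: list[str]
    positions_cm: np.ndarray
    mode: str  # framework | full
    deferred: list[str] = field(default_factory=list)

    @property
    def length_cm(self) -> float:
        return float(self.positions_cm[-1]) if len(self.positions_cm) else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.markers,
                "group": self.group_id,
                "cm": self.positions_cm,
                "mode": self.mode,
            }
        )


class _GroupLikelihood:
    """Two-point composite log-likelihood of a marker configuration.

    For one linkage group, pre-tabulates each informative pair's
    log-likelihood over an r grid (at the pair's supported phase); the
    composite likelihood of a vector of map positions is the sum over
    pairs of ll(r implied by the Kosambi distance between the two
    markers).  Used both to seriate (coordinate ascent on positions) and
    to calibrate inter-marker distances.
    """

    def __init__(self, table: TwoPointTable, idx: list[int], grid_size: int = 256):
        if table.codes is None:
            raise ValueError("two-point table lacks encoded scores")
        self.m = len(idx)
        self.r_grid = np.linspace(0.0, _R_CAP, grid_size)
        codes = table.codes[idx]
        types = [table.seg_types[i] for i in idx]
        phase = table.phase_code[np.ix_(idx, idx)]
        max_obs = max(_N_OBS[t] for t in types)
        indicators = [(codes == v).astype(np.float64) for v in range(max_obs)]

        pairs_i, pairs_j, lls = [], [], []
        by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for a in range(self.m):
            for b in range(a + 1, self.m):
                if int(phase[a, b]) < 0:
                    continue
                by_key.setdefault((types[a], types[b]), []).append((a, b))
        for (ta, tb), members in by_key.items():
            shared = shared_informative_parents(ta, tb)
            na, nb = _N_OBS[ta], _N_OBS[tb]
            rows_a = np.array([a for a, _ in members])
            rows_b = np.array([b for _, b in members])
            counts = np.empty((len(members), na * nb))
            for va in range(na):
                ia = indicators[va][rows_a]
                for vb in range(nb):
                    counts[:, va * nb + vb] = np.einsum(
                        "ij,ij->i", ia, indicators[vb][rows_b]
                    )
            # profile over linkage phase at every r: a weak pair's phase is
            # uncertain and locking a wrong phase in biases distances
            ll_best = None
            for code in range(2 ** len(shared)):
                phases = tuple((code >> k) & 1 for k in range(len(shared)))
                p = pair_class_probs(ta, tb, phases, self.r_grid, table.error_rate)
                logp = np.log(np.maximum(p, 1e-300)).reshape(na * nb, -1)
                ll = counts @ logp
                ll_best = ll if ll_best is None else np.maximum(ll_best, ll)
            lls.append(ll_best)
            pairs_i.extend(rows_a.tolist())
            pairs_j.extend(rows_b.tolist())
        self.pairs_i = np.array(pairs_i, dtype=np.int64)
        self.pairs_j = np.array(pairs_j, dtype=np.int64)
        self.ll_grid = (
            np.concatenate(lls, axis=0) if lls else np.empty((0, grid_size))
        )
        if self.ll_grid.size:
            # censor beyond r = 0.4 (the CP linkage ceiling): a pair's data
            # distinguish "far" from "close" but carry no usable distance
            # signal near r = 0.5, where noisy estimates explode on the map
            # scale and their accumulated pull stretches the configuration
            censor = int(np.searchsorted(self.r_grid, 0.4))
            self.ll_grid[:, censor:] = self.ll_grid[:, censor][:, None]
            # center each pair's ll at its maximum so totals are comparable
            self.ll_grid = self.ll_grid - self.ll_grid.max(axis=1, keepdims=True)
        # per-marker views for fast conditional evaluation
        self.by_marker: list[tuple[np.ndarray, np.ndarray]] = []
        for i in range(self.m):
            rows = np.nonzero((self.pairs_i == i) | (self.pairs_j == i))[0]
            partners = np.where(self.pairs_i[rows] == i, self.pairs_j[rows], self.pairs_i[rows])
            self.by_marker.append((rows, partners))
        self._grid_step = self.r_grid[1] - self.r_grid[0]

    def _r_index(self, gaps_cm: np.ndarray) -> np.ndarray:
        # internal additive scale is Haldane (matches a no-interference
        # crossover process, under which map distances are additive)
        r = 0.5 * (1.0 - np.exp(-2.0 * np.abs(gaps_cm) / 100.0))
        return np.minimum(
            (r / self._grid_step + 0.5).astype(np.int64), self.r_grid.size - 1
        )

    def total(self, pos: np.ndarray) -> float:
        gaps = pos[self.pairs_i] - pos[self.pairs_j]
        idx = self._r_index(gaps)
        return float(self.ll_grid[np.arange(self.pairs_i.size), idx].sum())

    def conditional(self, i: int, candidates: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Log-likelihood of marker i at each candidate position."""
        rows, partners = self.by_marker[i]
        if rows.size == 0:
            return np.zeros(candidates.size)
        gaps = candidates[:, None] - pos[partners][None, :]
        idx = self._r_index(gaps)
        return self.ll_grid[rows[None, :], idx].sum(axis=1)

    def _reversal_sweep(self, pos: np.ndarray) -> tuple[np.ndarray, bool]:
        """Try mirroring contiguous blocks of the current order in place.

        Within-block pair distances are invariant under mirroring, so the
        likelihood change involves only block-crossing pairs; accepted
        reversals repair large-scale folds that single-marker moves
        cannot.
        """
        improved = False
        order = np.argsort(pos, kind="stable")
        m = self.m
        sizes = []
        s = m // 2
        while s >= 2:
            sizes.append(s)
            s = int(s * 0.7)
        for size in sizes:
            step = max(1, size // 2)
            for start in range(0, m - size + 1, step):
                seg = order[start : start + size]
                lo, hi = pos[seg].min(), pos[seg].max()
                mirrored = lo + hi - pos[seg]
                delta = 0.0
                for member, new_p in zip(seg, mirrored):
                    rows, partners = self.by_marker[member]
                    if rows.size == 0:
                        continue
                    outside = ~np.isin(partners, seg)
                    if not outside.any():
                        continue
                    rr, pp = rows[outside], partners[outside]
                    sel = np.arange(rr.size)
                    old_idx = self._r_index(pos[member] - pos[pp])
                    new_idx = self._r_index(new_p - pos[pp])
                    delta += float(
                        (self.ll_grid[rr, new_idx] - self.ll_grid[rr, old_idx]).sum()
                    )
                if delta > 1e-6:
                    pos = pos.copy()
                    pos[seg] = mirrored
                    order = np.argsort(pos, kind="stable")
                    improved = True
        return pos, improved

    def _rescale(self, pos: np.ndarray) -> np.ndarray:
        """Globally rescale the configuration to its likelihood optimum.

        Coordinate ascent moves one marker at a time and recovers a
        wrong overall expansion/compression only very slowly; a direct
        line search over the scale factor fixes that collective mode.
        """
        center = pos.mean()
        scales = np.arange(0.6, 1.61, 0.02)
        lls = [self.total(center + s * (pos - center)) for s in scales]
        best = float(scales[int(np.argmax(lls))])
        return center + best * (pos - center)

    def refine(
        self,
        pos: np.ndarray,
        coarse_step: float = 1.0,
        fine_step: float = 0.1,
        max_passes: int = 15,
        tol_cm: float = 0.05,
    ) -> np.ndarray:
        """Alternate relocation, block-reversal and rescaling moves."""
        pos = pos.astype(float).copy()
        pos = self._rescale(pos)
        for sweep in range(3):
            for _ in range(max_passes):
                moved = 0.0
                lo, hi = pos.min() - 5.0, pos.max() + 5.0
                coarse = np.arange(lo, hi + coarse_step, coarse_step)
                for i in range(self.m):
                    cands = np.concatenate([coarse, [pos[i]]])
                    ll = self.conditional(i, cands, pos)
                    best = cands[int(np.argmax(ll))]
                    fine = best + np.arange(-1.0, 1.0 + fine_step, fine_step)
                    llf = self.conditional(i, fine, pos)
                    new = float(fine[int(np.argmax(llf))])
                    moved = max(moved, abs(new - pos[i]))
                    pos[i] = new
                if moved < tol_cm:
                    break
            pos = self._rescale(pos)
            pos, improved = self._reversal_sweep(pos)
            if not improved:
                break
        return pos - pos.min()


def _haldane_cm(r: np.ndarray) -> np.ndarray:
    return -50.0 * np.log(1.0 - 2.0 * np.minimum(r, _R_CAP))


def _seriation_orders(d: np.ndarray) -> list[np.ndarray]:
    """Candidate 1-D seriations of a (noisy, saturating) distance matrix.

    Three complementary heuristics: the principal classical-MDS axis; a
    horseshoe unroll (angular order in the first two MDS coordinates,
    cut at the largest angular gap); and the Fiedler vector of a local
    affinity graph.  Each alone is fold-prone under distance saturation;
    the caller selects among refinements by composite likelihood.
    """
    m = d.shape[0]
    j = np.eye(m) - 1.0 / m
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    coords = vecs[:, -2:][:, ::-1] * np.sqrt(np.maximum(vals[-2:][::-1], 0.0))
    orders = [np.argsort(coords[:, 0], kind="stable")]
    centered = coords - coords.mean(axis=0)
    ang = np.arctan2(centered[:, 1], centered[:, 0])
    ang_order = np.argsort(ang, kind="stable")
    sorted_ang = np.sort(ang)
    gaps = np.diff(np.concatenate([sorted_ang, [sorted_ang[0] + 2 * np.pi]]))
    cut = (int(np.argmax(gaps)) + 1) % m
    orders.append(np.roll(ang_order, -cut))
    w = np.exp(-d / 20.0)
    np.fill_diagonal(w, 0.0)
    lap = np.diag(w.sum(axis=1)) - w
    _, lvecs = np.linalg.eigh(lap)
    orders.append(np.argsort(lvecs[:, 1], kind="stable"))
    return orders


def _ls_positions(
    order: np.ndarray, d: np.ndarray, r: np.ndarray, lod: np.ndarray
) -> np.ndarray:
    """Windowed weighted-LS positions along a given seriation order."""
    m = d.shape[0]
    rank = np.empty(m, dtype=int)
    rank[order] = np.arange(m)
    w = lod.copy()
    w[(r > 0.45) | (np.abs(rank[:, None] - rank[None, :]) > 10)] = 0.0
    np.fill_diagonal(w, 0.0)
    sign = np.sign(rank[None, :] - rank[:, None])
    lap = np.diag(w.sum(axis=1)) - w + 1e-8 * np.eye(m)
    pos = np.linalg.solve(lap, -(w * sign * d).sum(axis=1))
    if not np.all(np.isfinite(pos)) or float(np.ptp(pos)) < 1e-6:
        pos = rank.astype(float)  # degenerate weight graph: rank spacing
    return pos - pos.min()


def _fit_jump(a: int, x: int, b: int, r: np.ndarray, n: np.ndarray) -> float:
    """Goodness-of-fit chi-square of a flanked marker's neighborhood.

    The observed recombinant count of the flanking pair (A, B) is
    compared with the count expected from the Kosambi-additive distance
    through the middle marker X (a 2-cell Pearson chi-square).
    """
    d = kosambi_cm(min(r[a, x], _R_CAP)) + kosambi_cm(min(r[x, b], _R_CAP))
    r_pred = min(float(kosambi_r(d)), _R_CAP)
    n_ab = float(n[a, b])
    if n_ab <= 0 or r_pred <= 0:
        return 0.0
    obs = min(r[a, b], _R_CAP) * n_ab
    exp = r_pred * n_ab
    if exp <= 0 or exp >= n_ab:
        return 0.0
    return float((obs - exp) ** 2 * n_ab / (exp * (n_ab - exp)))


def order_group(
    group: list[str],
    table: TwoPointTable,
    mode: str = "full",
    params: MappingParams | None = None,
    group_id: str = "LG",
) -> LinkageGroup:
    """Seriate one linkage group and assign Kosambi map positions.

    The order and spacing jointly maximize the two-point composite
    likelihood of the configuration: starting from a classical-MDS
    seriation of the pairwise Kosambi distances, every marker is
    repeatedly relocated to the position that maximizes its conditional
    two-point likelihood (a generalized ripple; window-1 adjacent swaps
    are a subset of these moves).  Positions are the maximizing
    configuration re-based to start at 0, i.e. cumulative Kosambi
    distances between adjacent placed markers.

    In framework mode, markers with poorly supported placements are
    deferred after the full fit: a marker is dropped when its
    neighborhood goodness-of-fit chi-square exceeds ``jump_threshold``,
    or when its local order is unresolvable (fewer than ~2 expected
    recombinants to its nearest retained neighbor).  Full mode keeps
    every marker.
    """
    params = params or MappingParams()
    if mode not in ("framework", "full"):
        raise ValueError("mode must be 'framework' or 'full'")
    idx = [table.index_of(mk) for mk in group]
    if len(idx) == 1:
        return LinkageGroup(group_id, list(group), np.zeros(1), mode)
    sub = np.ix_(idx, idx)
    r = np.minimum(table.r_hat[sub], 0.5)
    lod = table.lod[sub]
    n = table.n_shared[sub]
    m = len(idx)

    if m == 2:
        pos = np.array([0.0, kosambi_cm(min(r[0, 1], _R_CAP))])
        return LinkageGroup(group_id, list(group), pos, mode)

    def report_positions(internal: np.ndarray) -> np.ndarray:
        """Cumulative Kosambi distances over adjacent fitted r.

        ``internal`` is sorted positions on the additive (Haldane)
        scale; adjacent gaps are converted to recombination fractions
        and re-accumulated on the Kosambi scale (identical at dense
        spacing, conventional at sparse spacing).
        """
        gaps = np.diff(internal)
        r_adj = 0.5 * (1.0 - np.exp(-2.0 * gaps / 100.0))
        return np.concatenate([[0.0], np.cumsum(kosambi_cm(r_adj))])

    gl = _GroupLikelihood(table, idx)
    d = _haldane_cm(r)
    best_pos, best_ll = None, -np.inf
    for seed_order in _seriation_orders(d):
        cand = gl.refine(_ls_positions(seed_order, d, r, lod))
        ll = gl.total(cand)
        if ll > best_ll:
            best_pos, best_ll = cand, ll
    pos = best_pos
    order = list(np.argsort(pos, kind="stable"))

    deferred: list[int] = []
    if mode == "framework":
        support_ll = _LN10 * 1.0  # LOD-1 local order support

        def swap_cost(a: int, b: int, positions: np.ndarray) -> float:
            """Composite-likelihood cost of exchanging two neighbors.

            The (a, b) pair's own separation is unchanged by the swap,
            so only pairs to other markers contribute; a near-zero cost
            means the local order is unresolved by the data.
            """
            pa, pb = positions[a], positions[b]
            swapped = positions.copy()
            swapped[a], swapped[b] = pb, pa
            cost = 0.0
            for x, new_p in ((a, pb), (b, pa)):
                old = gl.conditional(x, np.array([positions[x]]), positions)[0]
                new = gl.conditional(x, np.array([new_p]), swapped)[0]
                cost += old - new
            return cost

        # one-shot misfit screen on the fitted adjacencies: flanked-pair
        # chi-square above the jump threshold (the statistic is only
        # meaningful for immediate neighbors, so it is not re-applied to
        # the widening triples that removals create)
        keep = list(order)
        misfit = {
            keep[k]
            for k in range(1, len(keep) - 1)
            if _fit_jump(keep[k - 1], keep[k], keep[k + 1], r, n)
            > params.jump_threshold
        }
        deferred.extend(i for i in keep if i in misfit)
        keep = [i for i in keep if i not in misfit]
        # unresolved local order: repeatedly drop the less-connected
        # member of the first adjacency whose swap is not rejected at
        # LOD 1; self-limiting, since spacing grows as markers drop
        changed = True
        while changed and len(keep) > 2:
            changed = False
            for k in range(len(keep) - 1):
                a, b = keep[k], keep[k + 1]
                if swap_cost(a, b, pos) < support_ll:
                    drop = k if lod[a].sum() < lod[b].sum() else k + 1
                    deferred.append(keep.pop(drop))
                    changed = True
                    break
        kept_set = set(keep)
        # retained markers keep their fitted positions: deferral judges
        # marker placements, it does not re-estimate the configuration
        order = [i for i in order if i in kept_set]

    return LinkageGroup(
        group_id,
        [group[i] for i in order],
        report_positions(np.sort(pos[order])),
        mode,
        deferred=[group[i] for i in deferred],
    )


def build_linkage_map(
    genotypes: pd.DataFrame,
    seg_types: pd.Series | dict[str, str],
    params: MappingParams | None = None,
    mode: str = "full",
    table: TwoPointTable | None = None,
) -> tuple[list[LinkageGroup], TwoPointTable, list[str]]:
    """Full pipeline: two-point table, grouping and per-group ordering."""
    params = params or MappingParams()
    if table is None:
        table = two_point_table(
            genotypes, seg_types, error_rate=params.assay_error_rate
        )
    groups, singletons = group_markers(table, params)
    linkage_groups = [
        order_group(g, table, mode=mode, params=params, group_id=f"LG{i + 1}")
        for i, g in enumerate(groups)
    ]
    return linkage_groups, table, singletons
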