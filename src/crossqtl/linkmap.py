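"""Linkage-map construction for an F2 intercross.

Two-point analysis estimates the recombination fraction r between every
marker pair by maximum likelihood over the nine F2 genotype-pair classes
(phase known from the F1, no interference); the double-heterozygote class
is the usual two-phase mixture ((1-r)^2 + r^2)/2.  Markers are grouped by
single-linkage transitive closure over pairs with two-point LOD >= lod_min
and r <= r_max, each group is ordered by a deterministic seriation that
minimises the sum of adjacent recombination fractions (SARF), and
cumulative Kosambi positions are assigned.

The user-facing entry point is :class:`LinkageMapper`, a model object whose
``fit()`` returns a :class:`LinkageMapResults` carrying the map and its
diagnostics; the individual steps are available as module functions.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .gmap import GeneticMap
from .io import GenotypeMatrix
from .mapfun import MAP_FUNCTIONS

_LN10 = np.log(10.0)
_R_FLOOR = 1e-9


class EstimationError(ValueError):
    pass


@dataclass
class PairEstimate:
    marker_a: str
    marker_b: str
    r_hat: float
    lod: float
    n_informative: int


def f2_joint_probs(r: float) -> np.ndarray:
    """3x3 table P(g_a, g_b | r), genotype coded 0=B-homo, 1=het, 2=A-homo."""
    c, rr = 1.0 - r, r
    p = np.empty((3, 3))
    p[0, 0] = p[2, 2] = c * c / 4.0
    p[0, 2] = p[2, 0] = rr * rr / 4.0
    p[0, 1] = p[1, 0] = p[1, 2] = p[2, 1] = rr * c / 2.0
    p[1, 1] = (c * c + rr * rr) / 2.0
    return p


def count_table(calls_a: np.ndarray, calls_b: np.ndarray) -> np.ndarray:
    """9-cell joint counts over pairwise-complete individuals."""
    ok = (calls_a >= 0) & (calls_b >= 0)
    a, b = calls_a[ok], calls_b[ok]
    counts = np.zeros((3, 3), dtype=int)
    np.add.at(counts, (a.astype(int), b.astype(int)), 1)
    return counts


def _loglik(counts: np.ndarray, r: float) -> float:
    p = np.clip(f2_joint_probs(r), 1e-300, None)
    return float((counts * np.log(p)).sum())


def estimate_rf(calls_a, calls_b, marker_a: str = "a", marker_b: str = "b") -> PairEstimate:
    """MLE of the two-point recombination fraction for one marker pair.

    Maximised by bounded 1-D optimisation of the joint F2 log-likelihood
    over r in [0, 0.5]; the two-point LOD is log10 L(r_hat) - log10 L(0.5).
    """
    calls_a = np.asarray(calls_a)
    calls_b = np.asarray(calls_b)
    counts = count_table(calls_a, calls_b)
    n = int(counts.sum())
    if n == 0:
        raise EstimationError(f"no jointly called individuals for {marker_a}/{marker_b}")
    res = minimize_scalar(
        lambda r: -_loglik(counts, r), bounds=(0.0, 0.5), method="bounded",
        options={"xatol": 1e-12},
    )
    r_hat = float(np.clip(res.x, 0.0, 0.5))
    # the bounded optimiser cannot land exactly on the boundary; snap if better
    for edge in (0.0, 0.5):
        if _loglik(counts, edge) >= _loglik(counts, r_hat):
            r_hat = edge
    lod = max((_loglik(counts, r_hat) - _loglik(counts, 0.5)) / _LN10, 0.0)
    return PairEstimate(marker_a, marker_b, r_hat, lod, n)


def pairwise_rf(g: GenotypeMatrix, max_iter: int = 200, tol: float = 1e-10):
    """All-pairs r and two-point LOD matrices via vectorised EM.

    The EM treats the number of recombinant gametes per individual as
    latent; every cell except the double heterozygote has a fixed
    recombinant-gamete count, and the double heterozygote contributes
    2 r^2 / ((1-r)^2 + r^2) expected recombinant gametes.  The fixed point
    is the same maximum as :func:`estimate_rf`.

    Returns ``(r_hat, lod, n)`` as (m x m) arrays with nan/0 diagonals.
    """
    calls = g.calls
    m = g.n_markers
    ind = [(calls == c).astype(np.float64) for c in (0, 1, 2)]
    N = {}
    for a in range(3):
        for b in range(3):
            N[(a, b)] = ind[a].T @ ind[b]
    n_tot = sum(N.values())
    # recombinant-gamete coefficient sums
    single = N[(2, 1)] + N[(1, 2)] + N[(1, 0)] + N[(0, 1)]
    double = N[(2, 0)] + N[(0, 2)]
    dhet = N[(1, 1)]

    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.full((m, m), 0.25)
        for _ in range(max_iter):
            w = 2.0 * r**2 / ((1.0 - r) ** 2 + r**2)
            r_new = (single + 2.0 * double + dhet * w) / (2.0 * n_tot)
            r_new = np.clip(r_new, _R_FLOOR, 0.5)
            delta = np.nanmax(np.abs(r_new - r))
            r = r_new
            if delta < tol:
                break

        def _ll(rv):
            c = 1.0 - rv
            return (
                (N[(2, 2)] + N[(0, 0)]) * np.log(np.clip(c * c / 4.0, 1e-300, None))
                + double * np.log(np.clip(rv * rv / 4.0, 1e-300, None))
                + single * np.log(np.clip(rv * c / 2.0, 1e-300, None))
                + dhet * np.log(np.clip((c * c + rv * rv) / 2.0, 1e-300, None))
            )

        lod = (_ll(r) - _ll(np.full_like(r, 0.5))) / _LN10
    lod = np.where(n_tot > 0, np.maximum(lod, 0.0), 0.0)
    r = np.where(n_tot > 0, r, np.nan)
    np.fill_diagonal(lod, 0.0)
    np.fill_diagonal(r, 0.0)
    return r, lod, n_tot.astype(int)


def group_markers(marker_names, r_hat, lod, lod_min: float = 5.0, r_max: float = 0.45):
    """Single-linkage transitive closure over edges with lod >= lod_min
    (inclusive) and r <= r_max.  Groups are sorted by descending size, ties
    by first marker name; members are sorted by name."""
    names = list(marker_names)
    m = len(names)
    parent = list(range(m))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    with np.errstate(invalid="ignore"):
        edge = (np.asarray(lod) >= lod_min) & (np.asarray(r_hat) <= r_max)
    ii, jj = np.nonzero(np.triu(edge, k=1))
    for i, j in zip(ii, jj):
        ri, rj = find(int(i)), find(int(j))
        if ri != rj:
            parent[rj] = ri
    comp: dict = {}
    for i in range(m):
        comp.setdefault(find(i), []).append(names[i])
    groups = sorted(
        (sorted(g) for g in comp.values()), key=lambda g: (-len(g), g[0])
    )
    return groups


def sarf(order, r_of) -> float:
    """Sum of adjacent recombination fractions of an ordering."""
    return float(sum(r_of(a, b) for a, b in zip(order, order[1:])))


def order_group(members, r_hat, lod, name_index, window: int = 4):
    """Deterministic SARF seriation of one linkage group.

    Greedy chain construction seeded by the highest-LOD pair, extension by
    the best end-attachment, then exhaustive local improvement over every
    sliding window of ``window`` adjacent positions repeated to a fixed
    point.  Ties break by lexicographic marker name; the returned order is
    canonicalised so the first marker name sorts before the last.
    """
    members = sorted(members)
    if len(members) <= 2:
        return members
    idx = {m: name_index[m] for m in members}

    def r_of(a, b):
        v = r_hat[idx[a], idx[b]]
        if not np.isfinite(v):
            warnings.warn(f"no pairwise estimate for {a}/{b}; assuming r=0.5")
            return 0.5
        return float(v)

    # seed with the highest-LOD pair
    best = None
    for a, b in itertools.combinations(members, 2):
        key = (-lod[idx[a], idx[b]], a, b)
        if best is None or key < best[0]:
            best = (key, (a, b))
    chain = list(best[1])
    remaining = set(members) - set(chain)
    while remaining:
        cands = []
        for end, attach_left in ((chain[0], True), (chain[-1], False)):
            k = min(remaining, key=lambda mname: (r_of(end, mname), mname))
            cands.append((r_of(end, k), k, attach_left))
        rbest, k, left = min(cands, key=lambda t: (t[0], t[1]))
        if left:
            chain.insert(0, k)
        else:
            chain.append(k)
        remaining.discard(k)

    # window-exhaustive local improvement to a fixed point
    improved = True
    while improved:
        improved = False
        for p in range(0, len(chain) - window + 1):
            seg = chain[p : p + window]
            left = chain[p - 1] if p > 0 else None
            right = chain[p + window] if p + window < len(chain) else None

            def seg_cost(s):
                c = sum(r_of(a, b) for a, b in zip(s, s[1:]))
                if left is not None:
                    c += r_of(left, s[0])
                if right is not None:
                    c += r_of(s[-1], right)
                return c

            base = seg_cost(seg)
            for perm in itertools.permutations(seg):
                perm = list(perm)
                if perm == seg:
                    continue
                if seg_cost(perm) < base - 1e-12:
                    chain[p : p + window] = perm
                    improved = True
                    break
    if chain[0] > chain[-1]:
        chain.reverse()
    return chain


@dataclass
class MapBuildLog:
    splits: list = field(default_factory=list)  # (group, marker_a, marker_b)
    unplaced: list = field(default_factory=list)  # singleton markers


def build_map(orders, r_hat, name_index, marker_meta: pd.DataFrame | None = None,
              map_function: str = "kosambi"):
    """Assign cumulative cM positions to ordered groups (Kosambi default).

    ``orders`` is a list of ordered marker lists (singletons allowed; a
    single-marker group sits at position 0 with length 0).  Where an
    adjacent pair has r >= 0.5 the group is broken at that junction and the
    split logged.  Groups of the final map are numbered by descending
    marker count (ties by first marker name).
    """
    to_cm = MAP_FUNCTIONS[map_function][0]
    log = MapBuildLog()
    pieces = []
    for order in orders:
        piece = [order[0]]
        for a, b in zip(order, order[1:]):
            r = r_hat[name_index[a], name_index[b]]
            if not np.isfinite(r) or r >= 0.5:
                log.splits.append((piece[-1], b))
                pieces.append(piece)
                piece = [b]
            else:
                piece.append(b)
        pieces.append(piece)
    pieces.sort(key=lambda p: (-len(p), p[0]))
    rows = []
    for gi, piece in enumerate(pieces, start=1):
        lg = f"LG{gi:02d}"
        pos = 0.0
        for j, mname in enumerate(piece):
            if j > 0:
                r = float(r_hat[name_index[piece[j - 1]], name_index[mname]])
                pos += to_cm(min(r, 0.5 - 1e-12))
            rows.append((mname, lg, pos))
    table = pd.DataFrame(rows, columns=["marker", "lg", "cm"]).set_index("marker")
    if marker_meta is not None:
        for col in ("scaffold", "bp"):
            if col in marker_meta.columns:
                table[col] = marker_meta[col].reindex(table.index)
    return GeneticMap(table), log


class LinkageMapper:
    """Estimate an F2 linkage map from a genotype matrix.

    Parameters
    ----------
    genotypes : GenotypeMatrix
        Filtered F2 calls (A/H/B/missing).
    lod_min : float
        Two-point LOD grouping threshold (inclusive), default 5.0.
    r_max : float
        Maximum recombination fraction for a grouping edge, default 0.45.
    min_group_size : int
        Groups smaller than this are reported as unplaced, default 2.
    map_function : str
        "kosambi" (default) or "haldane" for position assignment.
    """

    def __init__(self, genotypes: GenotypeMatrix, lod_min: float = 5.0,
                 r_max: float = 0.45, min_group_size: int = 2,
                 map_function: str = "kosambi"):
        self.genotypes = genotypes
        self.lod_min = lod_min
        self.r_max = r_max
        self.min_group_size = min_group_size
        self.map_function = map_function

    def fit(self) -> "LinkageMapResults":
        g = self.genotypes
        r_hat, lod, n_inf = pairwise_rf(g)
        names = g.marker_names
        name_index = {m: i for i, m in enumerate(names)}
        partition = group_markers(names, r_hat, lod, self.lod_min, self.r_max)
        placed = [grp for grp in partition if len(grp) >= self.min_group_size]
        unplaced = [m for grp in partition if len(grp) < self.min_group_size for m in grp]
        orders = [order_group(grp, r_hat, lod, name_index) for grp in placed]
        gmap, log = build_map(orders, r_hat, name_index, marker_meta=g.markers,
                              map_function=self.map_function)
        log.unplaced = unplaced
        return LinkageMapResults(
            model=self, map=gmap, r_hat=r_hat, lod=lod, n_informative=n_inf,
            name_index=name_index, build_log=log,
        )


@dataclass
class LinkageMapResults:
    model: LinkageMapper
    map: GeneticMap
    r_hat: np.ndarray
    lod: np.ndarray
    n_informative: np.ndarray
    name_index: dict
    build_log: MapBuildLog

    @property
    def n_groups(self) -> int:
        return self.map.n_groups

    @property
    def total_length_cm(self) -> float:
        return self.map.total_length_cm

    @property
    def n_placed(self) -> int:
        return self.map.n_markers

    def summary(self) -> str:
        gm = self.map
        lines = [
            "Linkage map summary",
            "===================",
            f"markers placed        {self.n_placed} of "
            f"{self.model.genotypes.n_markers}",
            f"linkage groups        {self.n_groups}",
            f"total length          {self.total_length_cm:.1f} cM",
            f"marker density        {gm.marker_density_cm():.2f} cM/marker",
            f"unplaced markers      {len(self.build_log.unplaced)}",
            "",
            f"{'group':<8}{'markers':>8}{'length cM':>12}",
        ]
        for lg in gm.groups:
            lines.append(
                f"{lg:<8}{len(gm.group_table(lg)):>8}{gm.group_length(lg):>12.1f}"
            )
        return "\n".join(lines)
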