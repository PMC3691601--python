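"""QTL mapping by Haley-Knott regression on an F2 panel.

The chain is: (1) multipoint genotype probabilities at markers and
pseudomarkers from a three-state hidden Markov model (states A-homozygote /
heterozygote / B-homozygote, transitions from the Kosambi inverse of the
map distance, emission error rate epsilon); (2) a genome scan regressing
the phenotype on the additive and dominance expectations

    p_add = P(A-homo) - P(B-homo),   p_dom = P(het)

with LOD = (n/2) * log10(RSS0 / RSS1); (3) genome-wide significance from
permutations of the phenotype; (4) a penalised forward/backward stepwise
search for multiple QTL with optional pairwise interactions; (5) Bayesian
credible intervals from the normalised 10^LOD profile; (6) per-genotype
effect summaries at the peak marker.

:class:`QTLModel` bundles the chain in a fit-style interface; every step is
also callable on its own.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gmap import GeneticMap
from .io import CODE_A, CODE_B, CODE_H, GenotypeMatrix
from .mapfun import kosambi_inv

_PRIOR = np.array([0.25, 0.5, 0.25])  # B-homo, het, A-homo at any locus
_STATE_OF_CODE = {CODE_B: 0, CODE_H: 1, CODE_A: 2}


def f2_transition(r: float) -> np.ndarray:
    """3x3 genotype transition matrix between linked loci (no interference)."""
    c = 1.0 - r
    return np.array(
        [
            [c * c, 2 * r * c, r * r],
            [r * c, c * c + r * r, r * c],
            [r * r, 2 * r * c, c * c],
        ]
    )


@dataclass
class GenoProbGrid:
    """Genotype probabilities on a (marker + pseudomarker) grid.

    ``positions`` has columns ``lg``, ``cm``, ``marker`` (name or None for a
    pseudomarker); ``probs`` is (individuals x positions x 3) ordered
    (B-homo, het, A-homo).
    """

    individuals: list
    positions: pd.DataFrame
    probs: np.ndarray
    error_rate: float
    step_cm: float

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    @property
    def p_add(self) -> np.ndarray:
        return self.probs[:, :, 2] - self.probs[:, :, 0]

    @property
    def p_dom(self) -> np.ndarray:
        return self.probs[:, :, 1]

    def lg_slice(self, lg) -> np.ndarray:
        return (self.positions["lg"] == lg).to_numpy()


def _grid_for_group(cm: np.ndarray, names: list, step_cm: float):
    """Merge marker positions with pseudomarkers every step_cm."""
    lo, hi = float(cm.min()), float(cm.max())
    pseudo = np.arange(lo, hi + 1e-9, step_cm) if step_cm > 0 else np.array([])
    allpos = np.concatenate([cm, pseudo])
    allpos = np.unique(np.round(allpos, 6))
    marker_at = {round(float(p), 6): None for p in allpos}
    for p, nm in zip(cm, names):
        marker_at[round(float(p), 6)] = nm
    return allpos, [marker_at[round(float(p), 6)] for p in allpos]


def calc_genoprob(
    g: GenotypeMatrix, gmap: GeneticMap, step_cm: float = 1.0, error_rate: float = 1e-4
) -> GenoProbGrid:
    """Forward-backward genotype probabilities for every individual.

    Transition probabilities between grid points at distance d use
    r = kosambi_inv(d) in the standard F2 transition matrix; emissions give
    the called state probability 1-eps and eps/2 to each other state, with
    a uniform emission at missing calls and pseudomarkers.
    """
    missing_from_map = set(g.marker_names) - set(gmap.table.index)
    if missing_from_map:
        raise KeyError(
            f"marker {sorted(missing_from_map)[0]!r} is not on the genetic map"
        )
    eps = error_rate
    n = g.n_individuals
    col_of = {m: j for j, m in enumerate(g.marker_names)}
    frames, prob_blocks = [], []
    for lg in gmap.groups:
        sub = gmap.group_table(lg)
        cm = sub["cm"].to_numpy(dtype=float)
        grid, marker_names = _grid_for_group(cm, list(sub.index), step_cm)
        npos = len(grid)
        # emissions
        emit = np.ones((n, npos, 3))
        for j, nm in enumerate(marker_names):
            if nm is None:
                continue
            calls = g.calls[:, col_of[nm]]
            called = calls >= 0
            if called.any():
                e = np.full((int(called.sum()), 3), eps / 2.0)
                states = np.array([_STATE_OF_CODE[int(c)] for c in calls[called]])
                e[np.arange(len(states)), states] = 1.0 - eps
                emit[called, j, :] = e
        trans = [f2_transition(kosambi_inv(d)) for d in np.diff(grid)]
        # scaled forward-backward, vectorised over individuals
        alpha = np.empty((n, npos, 3))
        scale = np.empty((n, npos))
        a = _PRIOR[None, :] * emit[:, 0, :]
        scale[:, 0] = a.sum(axis=1)
        alpha[:, 0, :] = a / scale[:, [0]]
        for j in range(1, npos):
            a = (alpha[:, j - 1, :] @ trans[j - 1]) * emit[:, j, :]
            scale[:, j] = a.sum(axis=1)
            alpha[:, j, :] = a / scale[:, [j]]
        beta = np.empty((n, npos, 3))
        beta[:, -1, :] = 1.0
        for j in range(npos - 2, -1, -1):
            b = (beta[:, j + 1, :] * emit[:, j + 1, :]) @ trans[j].T
            beta[:, j, :] = b / scale[:, [j + 1]]
        post = alpha * beta
        post /= post.sum(axis=2, keepdims=True)
        prob_blocks.append(post)
        frames.append(
            pd.DataFrame({"lg": lg, "cm": grid, "marker": marker_names})
        )
    positions = pd.concat(frames, ignore_index=True)
    probs = np.concatenate(prob_blocks, axis=1)
    return GenoProbGrid(list(g.individuals), positions, probs, error_rate, step_cm)


# ---------------------------------------------------------------------------
# Haley-Knott scan
# ---------------------------------------------------------------------------


@dataclass
class LodCurve:
    trait: str
    positions: pd.DataFrame  # lg, cm, marker
    lod: np.ndarray
    n_used: int

    def peak(self):
        j = int(np.argmax(self.lod))
        row = self.positions.iloc[j]
        return row["lg"], float(row["cm"]), float(self.lod[j])

    def to_frame(self) -> pd.DataFrame:
        out = self.positions.copy()
        out["lod"] = self.lod
        out.insert(0, "trait", self.trait)
        return out


def _project_out(C: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Residuals of the columns of M after OLS on C (via QR)."""
    q, _ = np.linalg.qr(C)
    return M - q @ (q.T @ M)


def _hk_lod_matrix(pa, pdom, Y, C) -> np.ndarray:
    """LOD (positions x traits) of y ~ C + p_add + p_dom at every position.

    Closed-form per-position 2x2 normal equations after projecting the
    covariates out of phenotypes and regressors (Frisch-Waugh).  Falls back
    to the additive-only regressor where the dominance column is collinear.
    """
    n = Y.shape[0]
    A = _project_out(C, pa)
    D = _project_out(C, pdom)
    Yr = _project_out(C, Y)
    rss0 = (Yr**2).sum(axis=0)  # (m,)
    saa = (A * A).sum(axis=0)
    sdd = (D * D).sum(axis=0)
    sad = (A * D).sum(axis=0)
    ca = A.T @ Yr  # (P, m)
    cd = D.T @ Yr
    det = saa * sdd - sad**2
    scale = np.maximum(saa * sdd, 1e-300)
    ok2 = det > 1e-10 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        b1 = (sdd[:, None] * ca - sad[:, None] * cd) / det[:, None]
        b2 = (saa[:, None] * cd - sad[:, None] * ca) / det[:, None]
        gain2 = b1 * ca + b2 * cd
        gain1 = np.where(saa[:, None] > 1e-12, ca**2 / np.maximum(saa, 1e-300)[:, None], 0.0)
    gain = np.where(ok2[:, None], gain2, gain1)
    rss1 = np.clip(rss0[None, :] - gain, 1e-300, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        lod = 0.5 * n * np.log10(np.maximum(rss0[None, :], 1e-300) / rss1)
    lod = np.where(rss0[None, :] > 1e-12, lod, 0.0)
    return np.maximum(lod, 0.0)


def _complete_cases(probs: GenoProbGrid, y: pd.Series):
    y = pd.Series(y).reindex(probs.individuals)
    ok = np.isfinite(y.to_numpy(dtype=float))
    return ok, y.to_numpy(dtype=float)[ok]


def scan_hk(probs: GenoProbGrid, y, trait: str | None = None) -> LodCurve:
    """Single-trait Haley-Knott genome scan (complete cases on y)."""
    trait = trait or (y.name if isinstance(y, pd.Series) and y.name else "trait")
    ok, yv = _complete_cases(probs, y)
    n = int(ok.sum())
    if n < 3:
        raise ValueError("need at least 3 phenotyped individuals")
    lod = _hk_lod_matrix(probs.p_add[ok], probs.p_dom[ok], yv[:, None], np.ones((n, 1)))[:, 0]
    return LodCurve(trait, probs.positions.copy(), lod, n)


def perm_threshold(
    probs: GenoProbGrid, y, n_perm: int = 1000, alpha: float = 0.05, seed: int = 0
):
    """Genome-wide LOD threshold from phenotype permutations.

    Phenotypes are shuffled among phenotyped individuals with genotypes
    fixed; the threshold is the ceil((1-alpha)(N+1))-th smallest of the N
    permutation maxima (order-statistic rule, exact small-sample validity).
    Returns ``(threshold, maxima)``; deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ok, yv = _complete_cases(probs, y)
    rng = np.random.default_rng(seed)
    n = len(yv)
    Y = np.empty((n, n_perm))
    for k in range(n_perm):
        Y[:, k] = yv[rng.permutation(n)]
    lod = _hk_lod_matrix(probs.p_add[ok], probs.p_dom[ok], Y, np.ones((n, 1)))
    maxima = lod.max(axis=0)
    k = int(np.ceil((1.0 - alpha) * (n_perm + 1)))
    k = min(max(k, 1), n_perm)
    threshold = float(np.sort(maxima)[k - 1])
    return threshold, maxima


# ---------------------------------------------------------------------------
# stepwise multiple-QTL search
# ---------------------------------------------------------------------------


@dataclass
class QtlModel:
    """A fitted multiple-QTL model: positions, effects, penalised LOD."""

    qtls: list = field(default_factory=list)  # dicts: lg, cm, add, dom, grid_index
    interactions: list = field(default_factory=list)  # (i, j) indices into qtls
    model_lod: float = 0.0
    plod: float = 0.0
    pve: float = 0.0
    n_used: int = 0
    main_penalty: float = 0.0
    int_penalty: float = 0.0

    @property
    def n_qtl(self) -> int:
        return len(self.qtls)


def _design(pa, pdom, qtl_idx, inter_pairs):
    n = pa.shape[0]
    cols = [np.ones(n)]
    for j in qtl_idx:
        cols.append(pa[:, j])
        cols.append(pdom[:, j])
    for (i, j) in inter_pairs:
        ai, di = pa[:, qtl_idx[i]], pdom[:, qtl_idx[i]]
        aj, dj = pa[:, qtl_idx[j]], pdom[:, qtl_idx[j]]
        cols.extend([ai * aj, ai * dj, di * aj, di * dj])
    return np.column_stack(cols)


def _fit_lod(X, yv, rss0):
    coef, _, _, _ = np.linalg.lstsq(X, yv, rcond=None)
    rss = float(((yv - X @ coef) ** 2).sum())
    rss = max(rss, 1e-300)
    n = len(yv)
    return 0.5 * n * np.log10(rss0 / rss), coef, rss


def stepwise_qtl(
    probs: GenoProbGrid,
    y,
    max_qtl: int = 10,
    main_penalty: float = 4.1,
    int_penalty: float | None = None,
    min_sep_cm: float = 10.0,
) -> QtlModel:
    """Forward/backward stepwise search maximising the penalised LOD

        pLOD = LOD(model) - main_penalty * #QTL - int_penalty * #interactions

    Forward steps consider adding a QTL anywhere on the grid (excluding a
    ``min_sep_cm`` window around QTL already in the model) or an interaction
    between included QTL; backward pruning then drops terms while the pLOD
    improves.  The model with the highest pLOD ever visited is returned,
    capped at ``max_qtl`` QTL.
    """
    if main_penalty <= 0:
        raise ValueError("main_penalty must be positive")
    if int_penalty is None:
        int_penalty = 2.0 * main_penalty
    ok, yv = _complete_cases(probs, y)
    n = int(ok.sum())
    pa = probs.p_add[ok]
    pdom = probs.p_dom[ok]
    pos = probs.positions
    rss0 = float(((yv - yv.mean()) ** 2).sum())
    if rss0 <= 1e-12:
        return QtlModel(n_used=n, main_penalty=main_penalty, int_penalty=int_penalty)

    def plod_of(lod, nq, ni):
        return lod - main_penalty * nq - int_penalty * ni

    qtl_idx: list = []
    inter: list = []
    cur_lod = 0.0
    best = QtlModel(n_used=n, main_penalty=main_penalty, int_penalty=int_penalty)
    cur_plod = 0.0
    while True:
        moves = []
        if len(qtl_idx) < max_qtl:
            C = _design(pa, pdom, qtl_idx, inter)
            lods = _hk_lod_matrix(pa, pdom, yv[:, None], C)[:, 0]
            # LOD of extended model = LOD(current) + conditional gain
            allowed = np.ones(len(lods), dtype=bool)
            for j in qtl_idx:
                same = (pos["lg"] == pos["lg"].iloc[j]).to_numpy()
                near = np.abs(pos["cm"].to_numpy() - pos["cm"].iloc[j]) < min_sep_cm
                allowed &= ~(same & near)
            if allowed.any():
                jbest = int(np.flatnonzero(allowed)[np.argmax(lods[allowed])])
                new_lod = cur_lod + float(lods[jbest])
                moves.append(
                    (plod_of(new_lod, len(qtl_idx) + 1, len(inter)), "add", jbest, new_lod)
                )
        for i in range(len(qtl_idx)):
            for j in range(i + 1, len(qtl_idx)):
                if (i, j) in inter:
                    continue
                X = _design(pa, pdom, qtl_idx, inter + [(i, j)])
                lod, _, _ = _fit_lod(X, yv, rss0)
                moves.append(
                    (plod_of(lod, len(qtl_idx), len(inter) + 1), "int", (i, j), lod)
                )
        if not moves:
            break
        moves.sort(key=lambda t: -t[0])
        top = moves[0]
        if top[0] <= cur_plod + 1e-9:
            break
        if top[1] == "add":
            qtl_idx.append(top[2])
        else:
            inter.append(top[2])
        # refit exactly (the scan gain is exact for 'add', but recompute for safety)
        X = _design(pa, pdom, qtl_idx, inter)
        cur_lod, _, _ = _fit_lod(X, yv, rss0)
        cur_plod = plod_of(cur_lod, len(qtl_idx), len(inter))
        if cur_plod > best.plod:
            best = _snapshot(pa, pdom, pos, qtl_idx, inter, yv, rss0, n,
                             main_penalty, int_penalty)

    # backward pruning
    improved = True
    while improved and (qtl_idx or inter):
        improved = False
        options = []
        for k in range(len(qtl_idx)):
            keep = qtl_idx[:k] + qtl_idx[k + 1 :]
            keep_int = [
                (i - (i > k), j - (j > k)) for (i, j) in inter if i != k and j != k
            ]
            X = _design(pa, pdom, keep, keep_int)
            lod, _, _ = _fit_lod(X, yv, rss0)
            options.append(
                (plod_of(lod, len(keep), len(keep_int)), keep, keep_int, lod)
            )
        for k in range(len(inter)):
            keep_int = inter[:k] + inter[k + 1 :]
            X = _design(pa, pdom, qtl_idx, keep_int)
            lod, _, _ = _fit_lod(X, yv, rss0)
            options.append(
                (plod_of(lod, len(qtl_idx), len(keep_int)), list(qtl_idx), keep_int, lod)
            )
        if not options:
            break
        options.sort(key=lambda t: -t[0])
        top = options[0]
        if top[0] > cur_plod + 1e-9:
            qtl_idx, inter, cur_lod, cur_plod = top[1], top[2], top[3], top[0]
            improved = True
            if cur_plod > best.plod:
                best = _snapshot(pa, pdom, pos, qtl_idx, inter, yv, rss0, n,
                                 main_penalty, int_penalty)
    return best


def _snapshot(pa, pdom, pos, qtl_idx, inter, yv, rss0, n, main_penalty, int_penalty):
    X = _design(pa, pdom, qtl_idx, inter)
    lod, coef, _ = _fit_lod(X, yv, rss0)
    qtls = []
    for k, j in enumerate(qtl_idx):
        row = pos.iloc[j]
        qtls.append(
            {
                "lg": row["lg"],
                "cm": float(row["cm"]),
                "add": float(coef[1 + 2 * k]),
                "dom": float(coef[2 + 2 * k]),
                "grid_index": int(j),
            }
        )
    return QtlModel(
        qtls=qtls,
        interactions=list(inter),
        model_lod=float(lod),
        plod=float(lod - main_penalty * len(qtl_idx) - int_penalty * len(inter)),
        pve=pve(lod, n),
        n_used=n,
        main_penalty=main_penalty,
        int_penalty=int_penalty,
    )


# ---------------------------------------------------------------------------
# intervals, PVE, effects
# ---------------------------------------------------------------------------


@dataclass
class CredibleInterval:
    lg: object
    lo_cm: float
    hi_cm: float
    prob: float
    degenerate: bool = False


def bayes_interval(curve: LodCurve, lg, prob: float = 0.95) -> CredibleInterval:
    """Bayesian credible interval on one linkage group.

    Grid points are weighted by the normalised posterior 10^LOD and included
    in decreasing-LOD order until the cumulative weight reaches ``prob``;
    grid points tied (to 1e-9 LOD) with the last included one enter as a
    block, so a symmetric profile yields a symmetric interval.  The interval
    is the cM span of the included points.  A flat zero curve yields the
    whole group, flagged degenerate.
    """
    mask = (curve.positions["lg"] == lg).to_numpy()
    if not mask.any():
        raise KeyError(f"linkage group {lg!r} not in curve")
    cm = curve.positions["cm"].to_numpy(dtype=float)[mask]
    lod = curve.lod[mask]
    if np.all(lod <= 1e-12):
        return CredibleInterval(lg, float(cm.min()), float(cm.max()), prob, degenerate=True)
    w = np.power(10.0, lod - lod.max())
    w = w / w.sum()
    order = np.argsort(-lod, kind="stable")
    cum = np.cumsum(w[order])
    k = int(np.searchsorted(cum, prob) + 1)
    k = min(k, len(order))
    cut = lod[order[k - 1]]
    chosen = lod >= cut - 1e-9
    return CredibleInterval(lg, float(cm[chosen].min()), float(cm[chosen].max()), prob)


def pve(lod_value: float, n: int) -> float:
    """Proportion of variance explained implied by a LOD score at sample
    size n: 1 - 10^(-2 LOD / n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(1.0 - 10.0 ** (-2.0 * lod_value / n))


def qtl_effects(g: GenotypeMatrix, gmap: GeneticMap, lg, pos_cm: float, y) -> dict:
    """Per-genotype-class phenotype means at the marker nearest a position.

    Returns class means/SEs/counts, the additive effect (mean_A - mean_B)/2,
    the dominance deviation mean_H - (mean_A + mean_B)/2, and a dominance
    classification (additive / incomplete dominance / overdominance) using a
    2-SE equivalence band on the dominance deviation.
    """
    sub = gmap.group_table(lg)
    if sub.empty:
        raise KeyError(f"linkage group {lg!r} not on map")
    marker = (sub["cm"] - pos_cm).abs().idxmin()
    col = g.marker_names.index(marker)
    calls = g.calls[:, col]
    yv = pd.Series(y).reindex(g.individuals).to_numpy(dtype=float)
    out = {"marker": marker, "lg": lg, "cm": float(sub.loc[marker, "cm"]), "classes": {}}
    stats = {}
    for label, code in (("A", CODE_A), ("H", CODE_H), ("B", CODE_B)):
        sel = (calls == code) & np.isfinite(yv)
        vals = yv[sel]
        if len(vals) == 0:
            stats[label] = None
            out["classes"][label] = {"n": 0, "mean": None, "se": None}
            continue
        mean = float(vals.mean())
        se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan")
        stats[label] = (mean, se)
        out["classes"][label] = {"n": int(len(vals)), "mean": mean, "se": se}
    if any(stats[k] is None for k in ("A", "H", "B")):
        out.update(add_effect=None, dom_effect=None, dominance="undetermined")
        return out
    (ma, sa), (mh, sh), (mb, sb) = stats["A"], stats["H"], stats["B"]
    add = (ma - mb) / 2.0
    dom = mh - (ma + mb) / 2.0
    se_dom = float(np.sqrt(np.nansum([sh**2, sa**2 / 4.0, sb**2 / 4.0])))
    if abs(dom) <= 2.0 * se_dom:
        label = "additive"
    elif abs(dom) > abs(add) + 2.0 * se_dom:
        label = "overdominance"
    else:
        label = "incomplete dominance"
    out.update(add_effect=float(add), dom_effect=float(dom), dominance=label)
    return out


# ---------------------------------------------------------------------------
# model / results front-end
# ---------------------------------------------------------------------------


class QTLModel:
    """Haley-Knott QTL analysis of one quantitative trait.

    Parameters
    ----------
    y : Series
        Phenotype keyed by individual ID (missing allowed; complete-case).
    genoprobs : GenoProbGrid
        Output of :func:`calc_genoprob`.
    genotypes, gmap : optional
        Raw calls and map; needed only for peak-marker effect summaries.
    """

    def __init__(self, y, genoprobs: GenoProbGrid, genotypes: GenotypeMatrix = None,
                 gmap: GeneticMap = None, trait: str | None = None):
        self.y = pd.Series(y)
        self.genoprobs = genoprobs
        self.genotypes = genotypes
        self.gmap = gmap
        self.trait = trait or (self.y.name if self.y.name else "trait")

    def fit(
        self,
        n_perm: int = 1000,
        alpha: float = 0.05,
        seed: int = 0,
        max_qtl: int = 10,
        main_penalty: float | None = None,
        int_penalty: float | None = None,
    ) -> "QTLResults":
        curve = scan_hk(self.genoprobs, self.y, trait=self.trait)
        threshold, maxima = None, None
        if n_perm > 0:
            threshold, maxima = perm_threshold(
                self.genoprobs, self.y, n_perm=n_perm, alpha=alpha, seed=seed
            )
        penalty = main_penalty if main_penalty is not None else threshold
        model = None
        if penalty is not None:
            model = stepwise_qtl(
                self.genoprobs, self.y, max_qtl=max_qtl,
                main_penalty=penalty, int_penalty=int_penalty,
            )
        else:
            warnings.warn("no permutations and no penalty given; stepwise search skipped")
        intervals, effects = [], []
        if model is not None:
            for q in model.qtls:
                intervals.append(bayes_interval(curve, q["lg"]))
                if self.genotypes is not None and self.gmap is not None:
                    effects.append(
                        qtl_effects(self.genotypes, self.gmap, q["lg"], q["cm"], self.y)
                    )
        return QTLResults(
            model=self, trait=self.trait, curve=curve, threshold=threshold,
            perm_maxima=maxima, qtl_model=model, intervals=intervals,
            effects=effects, alpha=alpha, n_perm=n_perm, seed=seed,
        )


@dataclass
class QTLResults:
    model: QTLModel
    trait: str
    curve: LodCurve
    threshold: float | None
    perm_maxima: np.ndarray | None
    qtl_model: QtlModel | None
    intervals: list
    effects: list
    alpha: float
    n_perm: int
    seed: int

    def peak(self):
        return self.curve.peak()

    def summary(self) -> str:
        lg, cm, lod = self.peak()
        lines = [
            f"QTL scan: {self.trait}",
            "=" * (10 + len(self.trait)),
            f"individuals used      {self.curve.n_used}",
            f"peak                  LOD {lod:.2f} at {lg} {cm:.1f} cM",
        ]
        if self.threshold is not None:
            lines.append(
                f"threshold             {self.threshold:.2f} "
                f"(alpha={self.alpha}, {self.n_perm} permutations)"
            )
        if self.qtl_model is not None and self.qtl_model.n_qtl:
            m = self.qtl_model
            lines.append(
                f"model                 {m.n_qtl} QTL, LOD {m.model_lod:.2f}, "
                f"PVE {100 * m.pve:.1f}%"
            )
            lines.append(f"{'LG':<6}{'cM':>8}{'add':>10}{'dom':>10}{'interval':>16}")
            for q, ci in zip(m.qtls, self.intervals):
                lines.append(
                    f"{q['lg']:<6}{q['cm']:>8.1f}{q['add']:>10.3f}{q['dom']:>10.3f}"
                    f"{ci.lo_cm:>8.1f}-{ci.hi_cm:.1f} cM"
                )
        else:
            lines.append("model                 no QTL retained")
        return "\n".join(lines)

    def plot(self, path=None, ax=None):
        from .plotting import plot_lod

        return plot_lod(self.curve, threshold=self.threshold, path=path, ax=ax)
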