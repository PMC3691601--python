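"""Synthetic F2 intercross generator with known truth.

Emulates the statistical structure of a RAD-seq F2 mapping panel: two
grandparent lines fixed for alternative alleles at every marker, uniformly
heterozygous F1, and F2 individuals produced by simulated meiosis.  Traits
follow the additive-dominance model

    y_i = mu + sum_q ( a_q * x_add_iq + d_q * x_dom_iq ) + e_i

with dosage x_add in {-1, 0, +1} (+1 for the grandsire homozygote), x_dom
in {0, 1}, and Gaussian residuals.  Genotypes are then masked
missing-completely-at-random at per-individual rates drawn from a Beta
distribution, reproducing the heavy per-individual missingness
heterogeneity of real reduced-representation panels.

A companion generator fragments a genome of known size into scaffolds that
tile the chromosomes in a random order and orientation and emits BLAST-like
marker hits, providing ground truth for the scaffold-anchoring stage.

Crossovers are a Poisson process along each chromosome (no interference,
i.e. Haldane's model) by default; sampling under Kosambi distances is
available as a marker-interval Markov approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gmap import GeneticMap
from .io import MISSING, GenotypeMatrix
from .mapfun import haldane_inv, kosambi_inv


class ConfigError(ValueError):
    """Invalid simulation configuration."""


# defaults mirror the study conditions the generator emulates: 160 F2
# males, 22 linkage groups totalling ~1,933 cM, one marker per 2.5 cM,
# mean 182 missing genotypes of 834 with strong per-individual skew.
N_INDIVIDUALS_DEFAULT = 160
MISSING_RATE_DEFAULT = 182.0 / 834.0
MISSING_DISPERSION_DEFAULT = 0.15


def default_chromosomes(n: int = 22, total_cm: float = 1933.0) -> list:
    """22 chromosomes with mildly varying lengths summing to ``total_cm``."""
    # deterministic length profile: linear taper from ~1.35x to ~0.65x mean
    w = np.linspace(1.35, 0.65, n)
    lengths = total_cm * w / w.sum()
    return [(f"LG{i + 1:02d}", float(round(l, 1))) for i, l in enumerate(lengths)]


@dataclass
class CrossConfig:
    n_individuals: int = N_INDIVIDUALS_DEFAULT
    chromosomes: list = field(default_factory=default_chromosomes)  # (name, length cM)
    # 2.35 cM spacing puts ~834 markers on the 1,933 cM default genome,
    # matching the emulated panel's marker count and map density
    marker_spacing_cm: float = 2.35
    missing_rate: float = MISSING_RATE_DEFAULT
    missing_dispersion: float = MISSING_DISPERSION_DEFAULT
    map_function: str = "haldane"
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ConfigError("n_individuals must be >= 1")
        if any(l <= 0 for _, l in self.chromosomes):
            raise ConfigError("chromosome lengths must be positive")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must lie in [0, 1)")
        if self.missing_dispersion < 0:
            raise ConfigError("missing_dispersion must be nonnegative")
        if self.map_function not in ("haldane", "kosambi"):
            raise ConfigError(f"unknown map function {self.map_function!r}")


@dataclass
class TraitArchitecture:
    trait_name: str
    mu: float = 0.0
    qtls: list = field(default_factory=list)  # (chromosome, position cM, a, d)
    sigma_e: float = 1.0

    def __post_init__(self):
        if self.sigma_e < 0:
            raise ConfigError("sigma_e must be nonnegative")


@dataclass
class GenomeLayoutConfig:
    genome_size_bp: int = 50_000_000
    n_scaffolds: int = 144
    scaffold_length_cv: float = 0.5
    spurious_hit_rate: float = 0.0
    marker_len_bp: int = 90
    seed: int = 0

    def __post_init__(self):
        if self.n_scaffolds < 1:
            raise ConfigError("n_scaffolds must be >= 1")
        if self.genome_size_bp < self.n_scaffolds:
            raise ConfigError("genome_size_bp must be >= n_scaffolds")
        if not (0.0 <= self.spurious_hit_rate < 1.0):
            raise ConfigError("spurious_hit_rate must lie in [0, 1)")


@dataclass
class SimTruth:
    """Ground truth of a simulated cross, for parameter-recovery scoring."""

    true_map: GeneticMap
    true_qtls: dict = field(default_factory=dict)  # trait -> list of qtl dicts
    true_layout: dict | None = None  # lg -> [(scaffold, orient, start, end)]

    def to_json_dict(self) -> dict:
        t = self.true_map.table
        return {
            "map": {
                "marker": list(t.index),
                "lg": list(t["lg"]),
                "cm": [float(x) for x in t["cm"]],
            },
            "qtls": self.true_qtls,
            "layout": self.true_layout,
        }


def target_pve_to_effect(target_pve: float, dom_ratio: float, sigma_e: float):
    """Solve for (a, d = dom_ratio*a) hitting a target proportion of variance
    explained under F2 genotype frequencies.

    With Var(x_add) = 1/2, Var(x_dom) = 1/4 and zero covariance, the QTL
    variance is a^2/2 + d^2/4, and PVE = v / (v + sigma_e^2).
    """
    if not (0.0 <= target_pve < 1.0):
        raise ValueError("target_pve must lie in [0, 1)")
    if target_pve == 0.0:
        return 0.0, 0.0
    v_needed = target_pve / (1.0 - target_pve) * sigma_e**2
    a = float(np.sqrt(v_needed / (0.5 + dom_ratio**2 / 4.0)))
    return a, dom_ratio * a


def _marker_positions(length_cm: float, spacing_cm: float) -> np.ndarray:
    n = int(np.floor(length_cm / spacing_cm + 1e-9)) + 1
    return np.arange(n) * spacing_cm


def _simulate_gametes(rng, n_gametes: int, positions: np.ndarray, map_function: str):
    """Alleles (0/1) for n gametes at the given cM positions of one
    chromosome.  A Markov chain over intervals with switch probability
    r(d) is exact for the no-interference Poisson model (Haldane) and a
    marker-interval approximation for Kosambi distances."""
    inv = haldane_inv if map_function == "haldane" else kosambi_inv
    d = np.diff(positions)
    r = inv(d)
    alleles = np.empty((n_gametes, len(positions)), dtype=np.int8)
    alleles[:, 0] = rng.random(n_gametes) < 0.5
    if len(d):
        switches = rng.random((n_gametes, len(d))) < r[None, :]
        alleles[:, 1:] = (alleles[:, [0]] + np.cumsum(switches, axis=1)) % 2
    return alleles


def simulate_cross(config: CrossConfig, traits: list | None = None):
    """Simulate an F2 intercross.

    Returns ``(GenotypeMatrix, phenotype DataFrame, SimTruth)``.  Identical
    seeds reproduce identical output.
    """
    traits = traits or []
    rng = np.random.default_rng(config.seed)
    chrom_names = [c for c, _ in config.chromosomes]
    chrom_len = dict(config.chromosomes)
    for tr in traits:
        for chrom, pos, _a, _d in tr.qtls:
            if chrom not in chrom_len:
                raise ConfigError(f"QTL chromosome {chrom!r} not configured")
            if not (0.0 <= pos <= chrom_len[chrom]):
                raise ConfigError(
                    f"QTL position {pos} cM outside chromosome {chrom} "
                    f"(0..{chrom_len[chrom]} cM)"
                )

    n = config.n_individuals
    marker_names, marker_lg, marker_cm = [], [], []
    geno_cols = []
    qtl_geno: dict = {}  # (chrom, pos) -> genotype vector
    for chrom in chrom_names:
        mpos = _marker_positions(chrom_len[chrom], config.marker_spacing_cm)
        qpos = sorted(
            {pos for tr in traits for (c, pos, _a, _d) in tr.qtls if c == chrom}
        )
        allpos = np.unique(np.concatenate([mpos, np.asarray(qpos, dtype=float)]))
        g1 = _simulate_gametes(rng, n, allpos, config.map_function)
        g2 = _simulate_gametes(rng, n, allpos, config.map_function)
        geno = (g1 + g2).astype(np.int8)  # 0=B-homo, 1=het, 2=A-homo
        is_marker = np.isin(allpos, mpos)
        for j, pos in enumerate(allpos):
            if is_marker[j]:
                marker_names.append(f"{chrom}_{len(marker_names):04d}")
                marker_lg.append(chrom)
                marker_cm.append(float(pos))
                geno_cols.append(geno[:, j])
            if pos in qpos:
                qtl_geno[(chrom, float(pos))] = geno[:, j]

    calls = np.column_stack(geno_cols).astype(np.int8)
    markers = pd.DataFrame(
        {"lg": marker_lg, "cm": marker_cm},
        index=pd.Index(marker_names, name="marker"),
    )
    individuals = [f"F2_{i + 1:03d}" for i in range(n)]

    # phenotypes
    pheno = {}
    true_qtls: dict = {}
    for tr in traits:
        y = np.full(n, tr.mu, dtype=float)
        var_g = 0.0
        qlist = []
        for chrom, pos, a, d in tr.qtls:
            gq = qtl_geno[(chrom, float(pos))]
            x_add = gq.astype(float) - 1.0
            x_dom = (gq == 1).astype(float)
            y += a * x_add + d * x_dom
            v_q = a**2 / 2.0 + d**2 / 4.0
            var_g += v_q
            qlist.append(
                {"chrom": chrom, "pos_cm": float(pos), "a": float(a), "d": float(d), "v": v_q}
            )
        if tr.sigma_e > 0:
            y += rng.normal(0.0, tr.sigma_e, size=n)
        denom = var_g + tr.sigma_e**2
        for q in qlist:
            q["true_pve"] = q.pop("v") / denom if denom > 0 else 0.0
        pheno[tr.trait_name] = y
        true_qtls[tr.trait_name] = qlist
    phenotypes = pd.DataFrame(pheno, index=individuals)
    phenotypes.index.name = "id"

    # per-individual MCAR masking with Beta-distributed rates
    if config.missing_rate > 0:
        m = config.missing_rate
        rho = config.missing_dispersion
        if rho > 0:
            kappa = (1.0 - rho) / rho  # Beta concentration; var = m(1-m)/(1+kappa)
            rates = rng.beta(m * kappa, (1.0 - m) * kappa, size=n)
        else:
            rates = np.full(n, m)
        mask = rng.random(calls.shape) < rates[:, None]
        calls = calls.copy()
        calls[mask] = MISSING

    g = GenotypeMatrix(individuals, markers, calls)
    truth = SimTruth(true_map=GeneticMap(markers.copy()), true_qtls=true_qtls)
    return g, phenotypes, truth


# ---------------------------------------------------------------------------
# genome layout / marker hits
# ---------------------------------------------------------------------------

HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def _largest_remainder(total: int, weights: np.ndarray, minimum: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to weights, each >= minimum."""
    k = len(weights)
    raw = weights / weights.sum() * (total - minimum * k)
    base = np.floor(raw).astype(int) + minimum
    rem = total - base.sum()
    order = np.argsort(-(raw - np.floor(raw)))
    base[order[:rem]] += 1
    return base


def simulate_genome_layout(config: GenomeLayoutConfig, gmap: GeneticMap):
    """Fragment a genome into scaffolds tiling the map's chromosomes.

    Returns ``(true_layout, hits DataFrame, scaffold lengths Series)``.
    Scaffolds tile each chromosome contiguously in a random order with
    random orientations; every marker receives one BLAST-like hit in
    scaffold-local coordinates (strand-consistent with the scaffold's
    orientation), plus an optional lower-scoring decoy hit on a random
    scaffold for a ``spurious_hit_rate`` fraction of markers.
    """
    rng = np.random.default_rng(config.seed)
    groups = gmap.groups
    lengths_cm = np.array([max(gmap.group_length(lg), 1e-9) for lg in groups])

    chrom_bp = _largest_remainder(config.genome_size_bp, lengths_cm, 1)
    n_scaf_per = _largest_remainder(config.n_scaffolds, lengths_cm, 1)

    order = rng.permutation(config.n_scaffolds)
    scaffold_names = [f"scaffold_{i + 1}" for i in order]

    cv = max(config.scaffold_length_cv, 1e-6)
    sigma = np.sqrt(np.log(1.0 + cv**2))
    true_layout: dict = {}
    scaffold_len: dict = {}
    scaffold_of: dict = {}  # lg -> (starts array, rows)
    idx = 0
    for lg, cbp, k in zip(groups, chrom_bp, n_scaf_per):
        w = rng.lognormal(mean=0.0, sigma=sigma, size=k)
        lens = _largest_remainder(int(cbp), w, 1)
        start = 1
        rows = []
        for j in range(k):
            name = scaffold_names[idx]
            idx += 1
            orient = "+" if rng.random() < 0.5 else "-"
            end = start + int(lens[j]) - 1
            rows.append((name, orient, start, end))
            scaffold_len[name] = int(lens[j])
            start = end + 1
        true_layout[lg] = rows
        starts = np.array([r[2] for r in rows])
        scaffold_of[lg] = (starts, rows)

    mlen = config.marker_len_bp
    all_names = sorted(scaffold_len)
    hit_rows = []
    marker_bp = {}
    t = gmap.table
    for lg in groups:
        sub = t[t["lg"] == lg]
        cm = sub["cm"].to_numpy(dtype=float)
        span = cm.max() - cm.min()
        cbp = int(chrom_bp[groups.index(lg)])
        rel = (cm - cm.min()) / span if span > 0 else np.zeros_like(cm)
        bp = 1 + np.round(rel * (cbp - 1)).astype(int)
        starts, rows = scaffold_of[lg]
        for name_m, b in zip(sub.index, bp):
            j = int(np.searchsorted(starts, b, side="right") - 1)
            scaf, orient, s0, s1 = rows[j]
            if orient == "+":
                lo = b - s0 + 1
            else:
                lo = s1 - b + 1
            slen = scaffold_len[scaf]
            lo = min(max(lo, 1), max(slen - mlen + 1, 1))
            hi = min(lo + mlen - 1, slen)
            if orient == "+":
                sstart, send = lo, hi
            else:
                sstart, send = hi, lo  # minus-strand hit: sstart > send
            score = 2.0 * mlen
            hit_rows.append(
                (name_m, scaf, round(rng.uniform(98.0, 100.0), 2), mlen, 0, 0,
                 1, mlen, sstart, send, 1e-40, score)
            )
            marker_bp[name_m] = (scaf, (lo + hi) // 2)

    n_decoy = int(round(config.spurious_hit_rate * len(marker_bp)))
    if n_decoy:
        decoy_markers = rng.choice(sorted(marker_bp), size=n_decoy, replace=False)
        for name_m in decoy_markers:
            scaf = all_names[rng.integers(len(all_names))]
            slen = scaffold_len[scaf]
            lo = int(rng.integers(1, max(slen - mlen, 1) + 1))
            hit_rows.append(
                (name_m, scaf, round(rng.uniform(85.0, 92.0), 2), mlen,
                 int(rng.integers(5, 12)), 1, 1, mlen, lo, min(lo + mlen - 1, slen),
                 1e-10, 0.4 * 2.0 * mlen)
            )

    hits = pd.DataFrame(hit_rows, columns=HIT_COLUMNS)
    lengths = pd.Series(scaffold_len, name="length").sort_index()
    return true_layout, hits, lengths


def write_hits(hits: pd.DataFrame, path) -> None:
    """Write hits as BLAST outfmt-6 TSV (no header)."""
    hits[HIT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def write_scaffold_lengths(lengths: pd.Series, path) -> None:
    lengths.rename_axis("scaffold").to_csv(path, sep="\t", header=True)
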