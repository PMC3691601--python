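"""Anchoring genome-assembly scaffolds to a linkage map.

Markers with known map positions are located on scaffolds via BLAST
tabular hits.  A scaffold is anchored to a linkage group when at least
``min_markers`` mapped markers from the same group hit it; anchored
scaffolds are ordered within each group by the mean cM of their supporting
markers and oriented by the sign of the Kendall rank correlation between
marker cM and scaffold bp.  The result is written as AGP v2.1 plus an
anchoring summary (anchored bp, fraction of the assembly, single-hit
scaffolds kept aside).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gmap import GeneticMap
from .io import FormatError
from .sim import HIT_COLUMNS

GAP_LEN = 100  # AGP U-gap length between consecutive scaffolds


def read_hits(path, min_identity: float = 0.0, uniqueness_ratio: float = 0.9):
    """Best-hit filtering of a 12-column BLAST outfmt-6 file.

    Per marker the highest-bitscore hit passing ``min_identity`` is kept;
    when the second-best bitscore reaches ``uniqueness_ratio`` times the
    best the marker is ambiguous and dropped.  Strand is read from the
    subject coordinate order and coordinates are normalised to
    sstart <= send (1-based inclusive).

    Returns ``(hits DataFrame, log DataFrame)``.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated fields, got {len(cells)}"
                )
            try:
                rows.append(
                    (cells[0], cells[1], float(cells[2]), int(cells[3]),
                     int(cells[8]), int(cells[9]), float(cells[11]))
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    raw = pd.DataFrame(
        rows, columns=["marker", "scaffold", "identity", "length", "sstart", "send", "score"]
    )
    return filter_hits(raw, min_identity=min_identity, uniqueness_ratio=uniqueness_ratio)


def filter_hits(raw: pd.DataFrame, min_identity: float = 0.0, uniqueness_ratio: float = 0.9):
    """Best-hit / uniqueness filtering on an in-memory hit table.

    Accepts either the 7-column table of :func:`read_hits` or a full
    outfmt-6 frame with the standard column names.
    """
    if set(HIT_COLUMNS).issubset(raw.columns):
        raw = raw.rename(
            columns={"qseqid": "marker", "sseqid": "scaffold", "pident": "identity",
                     "bitscore": "score"}
        )[["marker", "scaffold", "identity", "length", "sstart", "send", "score"]]
    raw = raw[raw["identity"] >= min_identity].copy()
    kept, log = [], []
    for marker, sub in raw.groupby("marker", sort=True):
        sub = sub.sort_values(["score", "scaffold"], ascending=[False, True])
        best = sub.iloc[0]
        if len(sub) > 1 and sub.iloc[1]["score"] >= uniqueness_ratio * best["score"]:
            log.append((marker, "ambiguous placement"))
            continue
        s, e = int(best["sstart"]), int(best["send"])
        strand = "+" if s <= e else "-"
        kept.append(
            (marker, best["scaffold"], min(s, e), max(s, e), strand,
             float(best["score"]), float(best["identity"]))
        )
    hits = pd.DataFrame(
        kept, columns=["marker", "scaffold", "sstart", "send", "strand", "score", "identity"]
    ).set_index("marker")
    log = pd.DataFrame(log, columns=["marker", "reason"]).set_index("marker")
    return hits, log


def read_scaffold_lengths(path) -> pd.Series:
    """Scaffold lengths from a 2-column TSV or a FASTA file."""
    path = str(path)
    if path.endswith((".fa", ".fasta", ".fna")):
        from Bio import SeqIO

        return pd.Series(
            {rec.id: len(rec.seq) for rec in SeqIO.parse(path, "fasta")}, name="length"
        )
    t = pd.read_csv(path, sep="\t")
    return pd.Series(t.iloc[:, 1].to_numpy(dtype=int), index=t.iloc[:, 0], name="length")


def assign_scaffolds(hits: pd.DataFrame, gmap: GeneticMap, min_markers: int = 2):
    """Assign scaffolds to linkage groups by the >= min_markers rule.

    Each scaffold goes to the linkage group contributing the most mapped
    markers, provided that count reaches ``min_markers``; a tie between
    groups leaves the scaffold unanchored (reason "LG conflict"), and
    scaffolds with exactly one mapped marker are reported separately.
    Markers absent from the map are logged and skipped.

    Returns ``(assignments, single_hit, conflict log)``.
    """
    t = gmap.table
    joined = hits.join(t[["lg", "cm"]], how="left")
    skipped = joined[joined["lg"].isna()]
    joined = joined.dropna(subset=["lg"])
    log_rows = [(m, "marker not on map") for m in skipped.index]

    assign_rows, single = [], []
    for scaf, sub in joined.groupby("scaffold", sort=True):
        counts = sub.groupby("lg").size().sort_values(ascending=False)
        if len(sub) == 1:
            single.append(scaf)
            continue
        top = counts.iloc[0]
        if top < min_markers:
            log_rows.append((scaf, "insufficient marker support"))
            continue
        tied = counts[counts == top]
        if len(tied) > 1:
            log_rows.append((scaf, "LG conflict"))
            continue
        lg = counts.index[0]
        n_conflict = int(len(sub) - top)
        if n_conflict:
            for m in sub.index[sub["lg"] != lg]:
                log_rows.append((m, f"conflicting marker on {scaf} (assigned {lg})"))
        assign_rows.append((scaf, lg, int(top), n_conflict))
    assignments = pd.DataFrame(
        assign_rows, columns=["scaffold", "lg", "n_markers", "n_conflicts"]
    ).set_index("scaffold")
    log = pd.DataFrame(log_rows, columns=["item", "reason"]).set_index("item")
    return assignments, single, log


@dataclass
class AnchoredMap:
    """Ordered, oriented scaffolds per linkage group."""

    per_lg: dict  # lg -> DataFrame(scaffold, orientation, marker_support, mean_cm)
    single_hit: list = field(default_factory=list)
    log: pd.DataFrame | None = None

    @property
    def n_scaffolds(self) -> int:
        return sum(len(v) for v in self.per_lg.values())

    def scaffold_order(self, lg) -> list:
        return list(self.per_lg[lg]["scaffold"])


def order_orient(assignments: pd.DataFrame, hits: pd.DataFrame, gmap: GeneticMap,
                 single_hit=None, log=None) -> AnchoredMap:
    """Order scaffolds by mean supporting-marker cM; orient by the sign of
    the Kendall correlation between marker cM and scaffold bp midpoint
    (zero correlation or a single distinct cM gives '?')."""
    t = gmap.table
    joined = hits.join(t[["lg", "cm"]], how="inner")
    joined["bp_mid"] = (joined["sstart"] + joined["send"]) / 2.0
    per_lg = {}
    for lg in gmap.groups:
        rows = []
        for scaf in assignments.index[assignments["lg"] == lg]:
            sup = joined[(joined.index.isin(hits.index))
                         & (joined["scaffold"] == scaf) & (joined["lg"] == lg)]
            mean_cm = float(sup["cm"].mean())
            orient = "?"
            if len(sup) >= 2 and sup["cm"].nunique() > 1 and sup["bp_mid"].nunique() > 1:
                tau = stats.kendalltau(sup["cm"], sup["bp_mid"]).statistic
                if np.isfinite(tau) and tau > 0:
                    orient = "+"
                elif np.isfinite(tau) and tau < 0:
                    orient = "-"
            rows.append((scaf, orient, int(len(sup)), mean_cm))
        if rows:
            frame = pd.DataFrame(
                rows, columns=["scaffold", "orientation", "marker_support", "mean_cm"]
            ).sort_values(["mean_cm", "scaffold"], kind="stable").reset_index(drop=True)
            per_lg[lg] = frame
    return AnchoredMap(per_lg=per_lg, single_hit=list(single_hit or []), log=log)


@dataclass
class AnchorStats:
    n_anchored_scaffolds: int
    anchored_bp: int
    assembly_bp: int
    anchored_fraction: float
    per_lg_counts: dict
    n_single_hit: int
    fraction_with_singles: float

    def as_dict(self) -> dict:
        return {
            "n_anchored_scaffolds": self.n_anchored_scaffolds,
            "anchored_bp": self.anchored_bp,
            "assembly_bp": self.assembly_bp,
            "anchored_fraction": self.anchored_fraction,
            "n_single_hit": self.n_single_hit,
            "fraction_with_singles": self.fraction_with_singles,
            "per_lg_counts": self.per_lg_counts,
        }


def anchor_summary(anchored: AnchoredMap, scaffold_lengths: pd.Series,
                   assembly_bp: int | None = None,
                   single_hit_scaffolds=None) -> AnchorStats:
    """Anchored-bp accounting: anchored fraction of the assembly, plus the
    fraction that would be anchored if single-hit scaffolds were included."""
    singles = list(single_hit_scaffolds if single_hit_scaffolds is not None
                   else anchored.single_hit)
    anchored_names = [s for lg in anchored.per_lg.values() for s in lg["scaffold"]]
    missing = [s for s in anchored_names if s not in scaffold_lengths.index]
    if missing:
        raise KeyError(f"no length for anchored scaffold {missing[0]!r}")
    anchored_bp = int(scaffold_lengths.loc[anchored_names].sum())
    if assembly_bp is None:
        assembly_bp = int(scaffold_lengths.sum())
    singles_bp = int(scaffold_lengths.reindex(singles).dropna().sum())
    return AnchorStats(
        n_anchored_scaffolds=len(anchored_names),
        anchored_bp=anchored_bp,
        assembly_bp=int(assembly_bp),
        anchored_fraction=anchored_bp / assembly_bp if assembly_bp else 0.0,
        per_lg_counts={lg: len(v) for lg, v in anchored.per_lg.items()},
        n_single_hit=len(singles),
        fraction_with_singles=(anchored_bp + singles_bp) / assembly_bp if assembly_bp else 0.0,
    )


def write_agp(anchored: AnchoredMap, scaffold_lengths: pd.Series, path) -> None:
    """Emit AGP v2.1: one object per linkage group, W component lines for
    scaffolds and 100-bp U gap lines (gap_type scaffold, linkage yes,
    evidence map) between them."""
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for lg, frame in anchored.per_lg.items():
            pos = 0
            part = 0
            for i, row in frame.iterrows():
                scaf = row["scaffold"]
                if scaf not in scaffold_lengths.index:
                    raise KeyError(f"no length for anchored scaffold {scaf!r}")
                if part > 0:
                    part += 1
                    fh.write(
                        f"{lg}\t{pos + 1}\t{pos + GAP_LEN}\t{part}\tU\t{GAP_LEN}"
                        f"\tscaffold\tyes\tmap\n"
                    )
                    pos += GAP_LEN
                length = int(scaffold_lengths.loc[scaf])
                part += 1
                fh.write(
                    f"{lg}\t{pos + 1}\t{pos + length}\t{part}\tW\t{scaf}\t1\t{length}"
                    f"\t{row['orientation']}\n"
                )
                pos += length


def validate_agp(path, scaffold_lengths: pd.Series | None = None) -> dict:
    """Check internal coordinate consistency of an AGP file.

    Every line's object span must equal the component/gap length, lines
    must tile each object contiguously from 1, and (when lengths are given)
    W components must span their full scaffold.  Returns per-object lengths.
    """
    objects: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            obj, beg, end, part, kind = cells[0], int(cells[1]), int(cells[2]), int(cells[3]), cells[4]
            span = end - beg + 1
            prev_end, prev_part = objects.get(obj, (0, 0))
            if beg != prev_end + 1:
                raise FormatError(f"{path}:{lineno}: object {obj} not contiguous")
            if part != prev_part + 1:
                raise FormatError(f"{path}:{lineno}: part numbers not sequential")
            if kind == "U":
                if int(cells[5]) != span:
                    raise FormatError(f"{path}:{lineno}: gap length != object span")
            elif kind == "W":
                comp_beg, comp_end = int(cells[6]), int(cells[7])
                if comp_end - comp_beg + 1 != span:
                    raise FormatError(f"{path}:{lineno}: component span != object span")
                if scaffold_lengths is not None:
                    if comp_end != int(scaffold_lengths.loc[cells[5]]) or comp_beg != 1:
                        raise FormatError(
                            f"{path}:{lineno}: component does not span scaffold {cells[5]}"
                        )
            else:
                raise FormatError(f"{path}:{lineno}: unsupported component type {kind!r}")
            objects[obj] = (end, part)
    return {obj: end for obj, (end, _) in objects.items()}


def write_scaffold_table(anchored: AnchoredMap, path) -> None:
    """Per-LG ordered scaffold table (TSV)."""
    rows = []
    for lg, frame in anchored.per_lg.items():
        for _, r in frame.iterrows():
            rows.append((lg, r["scaffold"], r["orientation"], r["marker_support"],
                         round(r["mean_cm"], 3)))
    pd.DataFrame(
        rows, columns=["lg", "scaffold", "orientation", "marker_support", "mean_cm"]
    ).to_csv(path, sep="\t", index=False)
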