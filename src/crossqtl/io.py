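"""Genotype and phenotype I/O, QC summaries, and marker filtering.

The central container is :class:`GenotypeMatrix`: F2 individuals x markers
with codes A (grandsire homozygote), H (heterozygote), B (granddam
homozygote) and ``-`` (missing).  Internally calls are int8 with B=0, H=1,
A=2, missing=-1, so the integer code doubles as the count of grandsire
alleles.

Two on-disk dialects are supported:

* a plain CSV dialect — row 1 holds ``id`` plus marker names, optional
  metadata rows labelled ``LG`` / ``cM`` / ``scaffold`` / ``bp`` in column 1,
  then one row per individual; phenotypes live in a separate CSV keyed by
  individual ID;
* a single-workbook layout (``.xlsx``) in which column A is the individual
  ID, columns B-L hold the phenotype columns, and marker columns follow with
  linkage group, cM position, scaffold and scaffold bp stacked under each
  marker name.  The genotype token vocabulary of a workbook is auto-detected
  and logged rather than assumed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

CODE_B = 0
CODE_H = 1
CODE_A = 2
MISSING = -1

CODE_TO_STR = {CODE_B: "B", CODE_H: "H", CODE_A: "A", MISSING: "-"}
STR_TO_CODE = {"B": CODE_B, "H": CODE_H, "A": CODE_A, "-": MISSING}

#: marker metadata columns carried alongside the calls
MARKER_META = ("lg", "cm", "scaffold", "bp")

_META_ROW_LABELS = {
    "lg": "lg",
    "linkage group": "lg",
    "cm": "cm",
    "position": "cm",
    "position (cm)": "cm",
    "scaffold": "scaffold",
    "bp": "bp",
    "scaffold position": "bp",
    "position (bp)": "bp",
}


class FormatError(ValueError):
    """Raised for malformed genotype/phenotype files."""


@dataclass
class GenotypeMatrix:
    """Individuals x markers genotype call matrix for an F2 intercross."""

    individuals: list
    markers: pd.DataFrame  # index = marker names; columns lg, cm, scaffold, bp
    calls: np.ndarray  # int8, shape (n individuals, n markers)
    unknown_tokens: dict = field(default_factory=dict)

    def __post_init__(self):
        self.individuals = list(self.individuals)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individuals), len(self.markers)):
            raise FormatError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.markers)} markers"
            )
        if self.markers.index.duplicated().any():
            dup = self.markers.index[self.markers.index.duplicated()][0]
            raise FormatError(f"duplicate marker name: {dup!r}")
        bad = ~np.isin(self.calls, (CODE_B, CODE_H, CODE_A, MISSING))
        if bad.any():
            raise FormatError(f"invalid genotype codes present: {np.unique(self.calls[bad])}")
        for col in MARKER_META:
            if col not in self.markers.columns:
                self.markers[col] = pd.NA

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_names(self) -> list:
        return list(self.markers.index)

    def subset_markers(self, names) -> "GenotypeMatrix":
        idx = self.markers.index.get_indexer(list(names))
        if (idx < 0).any():
            missing = [n for n, i in zip(names, idx) if i < 0]
            raise KeyError(f"unknown markers: {missing[:5]}")
        return GenotypeMatrix(
            self.individuals, self.markers.iloc[idx].copy(), self.calls[:, idx].copy()
        )

    def to_frame(self) -> pd.DataFrame:
        """Calls as a DataFrame of A/H/B/- strings (individuals x markers)."""
        sym = np.array(["B", "H", "A"], dtype=object)
        out = np.full(self.calls.shape, "-", dtype=object)
        called = self.calls >= 0
        out[called] = sym[self.calls[called]]
        return pd.DataFrame(out, index=self.individuals, columns=self.markers.index)


@dataclass
class QcReport:
    n_individuals: int
    n_markers: int
    class_fractions: tuple  # (A, H, B) among non-missing calls
    per_individual_missing: pd.Series
    per_marker_called: pd.Series
    mean_missing_per_individual: float

    def as_dict(self) -> dict:
        fa, fh, fb = self.class_fractions
        return {
            "n_individuals": self.n_individuals,
            "n_markers": self.n_markers,
            "frac_A": fa,
            "frac_H": fh,
            "frac_B": fb,
            "mean_missing_per_individual": self.mean_missing_per_individual,
        }


def qc_summary(g: GenotypeMatrix) -> QcReport:
    """Exact call counting: per-class fractions over non-missing calls,
    per-individual missing counts, per-marker called counts."""
    if g.n_individuals == 0 or g.n_markers == 0:
        raise ValueError("empty genotype matrix")
    calls = g.calls
    n_a = int((calls == CODE_A).sum())
    n_h = int((calls == CODE_H).sum())
    n_b = int((calls == CODE_B).sum())
    total = n_a + n_h + n_b
    fractions = (n_a / total, n_h / total, n_b / total) if total else (0.0, 0.0, 0.0)
    per_ind = pd.Series((calls == MISSING).sum(axis=1), index=g.individuals, name="missing")
    per_marker = pd.Series(
        (calls != MISSING).sum(axis=0), index=g.markers.index, name="called"
    )
    return QcReport(
        n_individuals=g.n_individuals,
        n_markers=g.n_markers,
        class_fractions=fractions,
        per_individual_missing=per_ind,
        per_marker_called=per_marker,
        mean_missing_per_individual=float(per_ind.mean()),
    )


def filter_markers(
    g: GenotypeMatrix,
    min_called: int = 100,
    hwe_alpha: float = 0.01,
    grandparents: tuple | None = None,
):
    """Apply the marker-selection rules for an F2 panel.

    Markers are kept when they are (i) called in at least ``min_called``
    individuals, (ii) compatible with 1:2:1 segregation by a chi-square
    goodness-of-fit test at ``hwe_alpha`` (df=2), and (iii), when grandparent
    calls are supplied as ``(grandsire, granddam)`` Series of codes, fixed
    for alternative alleles in the two grandparents (grandsire A-homozygous,
    granddam B-homozygous).

    Returns ``(filtered matrix, filter log)`` where the log is a DataFrame
    with one row per removed marker and its reason.
    """
    if min_called < 0:
        raise ValueError("min_called must be nonnegative")
    if min_called > g.n_individuals:
        raise ValueError("min_called exceeds the number of individuals")
    calls = g.calls
    n_a = (calls == CODE_A).sum(axis=0)
    n_h = (calls == CODE_H).sum(axis=0)
    n_b = (calls == CODE_B).sum(axis=0)
    n_called = n_a + n_h + n_b

    reasons = {}
    if grandparents is not None:
        gsire, gdam = grandparents
        gsire = pd.Series(gsire).reindex(g.markers.index)
        gdam = pd.Series(gdam).reindex(g.markers.index)
        fixed = (gsire == CODE_A) & (gdam == CODE_B)
        for name in g.markers.index[~fixed.to_numpy(dtype=bool)]:
            reasons.setdefault(name, "not differentially fixed in grandparents")

    low = n_called < min_called
    for name in g.markers.index[low]:
        reasons.setdefault(name, "insufficient calls")

    # 1:2:1 segregation GOF; expected counts from the per-marker called total
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = np.stack([n_called / 4.0, n_called / 2.0, n_called / 4.0])
        observed = np.stack([n_a, n_h, n_b]).astype(float)
        chi2 = np.where(
            n_called > 0, np.nansum((observed - expected) ** 2 / expected, axis=0), np.inf
        )
    pvals = stats.chi2.sf(chi2, df=2)
    distorted = pvals < hwe_alpha
    for name in g.markers.index[distorted]:
        reasons.setdefault(name, "segregation distortion")

    keep = [m for m in g.markers.index if m not in reasons]
    log = pd.DataFrame(
        {"marker": list(reasons), "reason": list(reasons.values())}
    ).set_index("marker")
    return g.subset_markers(keep), log


# ---------------------------------------------------------------------------
# plain CSV dialect
# ---------------------------------------------------------------------------


def write_genotypes(g: GenotypeMatrix, path) -> None:
    """Write the CSV dialect: marker-name header, metadata rows, call rows."""
    with open(path, "w") as fh:
        names = list(g.markers.index)
        fh.write(",".join(["id"] + names) + "\n")
        for col, label in (("lg", "LG"), ("cm", "cM"), ("scaffold", "scaffold"), ("bp", "bp")):
            vals = g.markers[col]
            if vals.isna().all():
                continue
            cells = []
            for v in vals:
                if pd.isna(v):
                    cells.append("")
                elif col == "cm":
                    cells.append(format(float(v), ".6g"))
                elif col == "bp":
                    cells.append(str(int(v)))
                else:
                    cells.append(str(v))
            fh.write(",".join([label] + cells) + "\n")
        frame = g.to_frame()
        for ind, row in zip(g.individuals, frame.to_numpy()):
            fh.write(",".join([str(ind)] + list(row)) + "\n")


def read_genotypes(path) -> GenotypeMatrix:
    """Read the CSV dialect written by :func:`write_genotypes`.

    Unrecognized genotype tokens are stored as missing; their counts are
    recorded in ``GenotypeMatrix.unknown_tokens`` and reported via a warning.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"empty genotype file: {path}")
    header = lines[0].split(",")
    names = header[1:]
    if len(set(names)) != len(names):
        seen, dup = set(), None
        for n in names:
            if n in seen:
                dup = n
                break
            seen.add(n)
        raise FormatError(f"duplicate marker name: {dup!r}")
    markers = pd.DataFrame(index=pd.Index(names, name="marker"))
    meta_labels = {"lg": "lg", "cm": "cm", "scaffold": "scaffold", "bp": "bp"}
    individuals, rows = [], []
    unknown: dict = {}
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split(",")
        if len(cells) != len(header):
            raise FormatError(f"{path}:{lineno}: expected {len(header)} fields, got {len(cells)}")
        label = cells[0].strip()
        key = meta_labels.get(label.lower())
        if key is not None and label.lower() in meta_labels:
            vals = [c if c != "" else None for c in cells[1:]]
            if key == "cm":
                markers[key] = [float(v) if v is not None else np.nan for v in vals]
            elif key == "bp":
                markers[key] = [int(v) if v is not None else pd.NA for v in vals]
            else:
                markers[key] = vals
            continue
        individuals.append(label)
        row = np.full(len(names), MISSING, dtype=np.int8)
        for j, tok in enumerate(cells[1:]):
            tok = tok.strip()
            code = STR_TO_CODE.get(tok)
            if code is None:
                if tok not in ("", "-"):
                    unknown[tok] = unknown.get(tok, 0) + 1
                code = MISSING
            row[j] = code
        rows.append(row)
    calls = np.vstack(rows) if rows else np.empty((0, len(names)), dtype=np.int8)
    if unknown:
        warnings.warn(f"{sum(unknown.values())} unrecognized genotype tokens: {unknown}")
    return GenotypeMatrix(individuals, markers, calls, unknown_tokens=unknown)


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, index_label="id")


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="id")


# ---------------------------------------------------------------------------
# workbook layout (single sheet: ID, phenotypes B-L, marker columns)
# ---------------------------------------------------------------------------

_WB_TOKEN_MAP = {
    "A": CODE_A, "AA": CODE_A,
    "H": CODE_H, "AB": CODE_H, "BA": CODE_H,
    "B": CODE_B, "BB": CODE_B,
    "-": MISSING, "--": MISSING, "": MISSING, "NA": MISSING, "U": MISSING,
}


def read_workbook(path, n_phenotypes: int = 11):
    """Convert a workbook in the combined layout into package containers.

    Returns ``(GenotypeMatrix, phenotype DataFrame, token table)``.  The
    genotype token vocabulary is auto-detected against a table of common
    encodings and logged in the returned token table; tokens outside it are
    stored as missing and counted in ``unknown_tokens``.
    """
    from openpyxl import load_workbook

    wb = load_workbook(path, read_only=True, data_only=True)
    ws = wb.active
    rows = [[c for c in row] for row in ws.iter_rows(values_only=True)]
    wb.close()
    if not rows:
        raise FormatError(f"empty workbook: {path}")
    header = rows[0]
    pheno_names = [str(v) for v in header[1 : 1 + n_phenotypes]]
    marker_names = [str(v) for v in header[1 + n_phenotypes :] if v is not None]
    n_mark = len(marker_names)
    markers = pd.DataFrame(index=pd.Index(marker_names, name="marker"))

    body_start = 1
    for row in rows[1:]:
        label = str(row[0]).strip().lower() if row[0] is not None else ""
        key = _META_ROW_LABELS.get(label)
        if key is None:
            break
        vals = list(row[1 + n_phenotypes : 1 + n_phenotypes + n_mark])
        if key == "cm":
            markers[key] = [float(v) if v is not None else np.nan for v in vals]
        elif key == "bp":
            markers[key] = [int(v) if v is not None else pd.NA for v in vals]
        else:
            markers[key] = [str(v) if v is not None else None for v in vals]
        body_start += 1

    individuals, pheno_rows, call_rows = [], [], []
    token_table: dict = {}
    unknown: dict = {}
    for row in rows[body_start:]:
        if row[0] is None:
            continue
        individuals.append(str(row[0]))
        pheno_rows.append(
            [float(v) if v is not None and v != "" else np.nan for v in row[1 : 1 + n_phenotypes]]
        )
        calls = np.full(n_mark, MISSING, dtype=np.int8)
        for j, v in enumerate(row[1 + n_phenotypes : 1 + n_phenotypes + n_mark]):
            tok = "" if v is None else str(v).strip().upper()
            if tok in _WB_TOKEN_MAP:
                code = _WB_TOKEN_MAP[tok]
                token_table[tok] = CODE_TO_STR[code]
            else:
                code = MISSING
                unknown[tok] = unknown.get(tok, 0) + 1
            calls[j] = code
        call_rows.append(calls)
    phenotypes = pd.DataFrame(pheno_rows, index=individuals, columns=pheno_names)
    phenotypes.index.name = "id"
    g = GenotypeMatrix(
        individuals, markers, np.vstack(call_rows), unknown_tokens=unknown
    )
    if unknown:
        warnings.warn(f"{sum(unknown.values())} unrecognized workbook tokens: {unknown}")
    return g, phenotypes, token_table


def write_workbook(g: GenotypeMatrix, phenotypes: pd.DataFrame, path) -> None:
    """Write the combined workbook layout (synthetic data helper)."""
    from openpyxl import Workbook

    wb = Workbook()
    ws = wb.active
    pheno_names = list(phenotypes.columns)
    ws.append(["ID"] + pheno_names + list(g.markers.index))
    pad = [None] * len(pheno_names)
    for col, label in (("lg", "LG"), ("cm", "cM"), ("scaffold", "scaffold"), ("bp", "bp")):
        vals = g.markers[col]
        if vals.isna().all():
            continue
        ws.append([label] + pad + [None if pd.isna(v) else v for v in vals])
    frame = g.to_frame()
    ph = phenotypes.reindex(g.individuals)
    for ind in g.individuals:
        ws.append(
            [ind]
            + [None if pd.isna(v) else float(v) for v in ph.loc[ind]]
            + list(frame.loc[ind])
        )
    wb.save(path)
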