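"""End-to-end pipeline: simulate/load -> QC -> filter -> map -> scan ->
stepwise QTL -> anchor, with truth-based recovery scoring.

Every stage is driven by a :class:`PipelineConfig` (readable from YAML),
logs its parameters, and writes plain-text artifacts; a fixed seed makes a
rerun byte-identical.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import anchor as anchor_mod
from . import io as gio
from . import sim as sim_mod
from .gmap import GeneticMap
from .linkmap import LinkageMapper
from .qtl import QTLModel, calc_genoprob

log = logging.getLogger("crossqtl")


@dataclass
class SimSection:
    n_individuals: int = sim_mod.N_INDIVIDUALS_DEFAULT
    n_chromosomes: int = 22
    total_cm: float = 1933.0
    marker_spacing_cm: float = 2.35
    missing_rate: float = sim_mod.MISSING_RATE_DEFAULT
    missing_dispersion: float = sim_mod.MISSING_DISPERSION_DEFAULT
    map_function: str = "haldane"
    # each trait: {name, mu, sigma_e, qtls: [{chrom, pos_cm, a, d} or
    # {chrom, pos_cm, target_pve, dom_ratio}]}
    traits: list = field(default_factory=list)
    genome_size_bp: int = 50_000_000
    n_scaffolds: int = 144
    scaffold_length_cv: float = 0.5
    spurious_hit_rate: float = 0.0


@dataclass
class PipelineConfig:
    seed: int = 0
    simulate: SimSection | None = field(default_factory=SimSection)
    genotypes: str | None = None
    phenotypes: str | None = None
    hits: str | None = None
    scaffold_lengths: str | None = None
    min_called: int = 100
    hwe_alpha: float = 0.01
    lod_min: float = 5.0
    r_max: float = 0.45
    step_cm: float = 1.0
    error_rate: float = 1e-4
    n_perm: int = 1000
    alpha: float = 0.05
    max_qtl: int = 10
    min_markers: int = 2
    uniqueness_ratio: float = 0.9
    min_identity: float = 0.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulate", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        if sim_raw is None:
            cfg.simulate = None
        elif isinstance(sim_raw, dict):
            cfg.simulate = SimSection(
                **{k: v for k, v in sim_raw.items() if k in SimSection.__dataclass_fields__}
            )
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def build_trait_architectures(section: SimSection) -> list:
    """Materialise trait specs, converting target-PVE entries to effects."""
    chroms = sim_mod.default_chromosomes(section.n_chromosomes, section.total_cm)
    traits = []
    for spec in section.traits:
        sigma_e = float(spec.get("sigma_e", 1.0))
        qtls = []
        for q in spec.get("qtls", []):
            if "a" in q:
                a, d = float(q["a"]), float(q.get("d", 0.0))
            else:
                a, d = sim_mod.target_pve_to_effect(
                    float(q["target_pve"]), float(q.get("dom_ratio", 0.0)), sigma_e
                )
            qtls.append((q["chrom"], float(q["pos_cm"]), a, d))
        traits.append(
            sim_mod.TraitArchitecture(
                trait_name=spec["name"], mu=float(spec.get("mu", 0.0)),
                qtls=qtls, sigma_e=sigma_e,
            )
        )
    return traits, chroms


def _json_dump(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serialisable: {type(x)}")


class StageError(RuntimeError):
    def __init__(self, stage, exc):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the full chain and write artifacts under ``outdir``.

    Returns an in-memory summary dict (also written as summary.json).
    Stage failures raise :class:`StageError`; artifacts of completed stages
    are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "parameters": config.to_dict()}
    truth = None
    results: dict = {}

    # ---- stage: data ------------------------------------------------------
    stage = "data"
    try:
        if config.simulate is not None:
            sec = config.simulate
            traits, chroms = build_trait_architectures(sec)
            cross_cfg = sim_mod.CrossConfig(
                n_individuals=sec.n_individuals, chromosomes=chroms,
                marker_spacing_cm=sec.marker_spacing_cm,
                missing_rate=sec.missing_rate,
                missing_dispersion=sec.missing_dispersion,
                map_function=sec.map_function, seed=config.seed,
            )
            g, phenotypes, truth = sim_mod.simulate_cross(cross_cfg, traits)
            layout_cfg = sim_mod.GenomeLayoutConfig(
                genome_size_bp=sec.genome_size_bp, n_scaffolds=sec.n_scaffolds,
                scaffold_length_cv=sec.scaffold_length_cv,
                spurious_hit_rate=sec.spurious_hit_rate, seed=config.seed + 1,
            )
            layout, hits_raw, lengths = sim_mod.simulate_genome_layout(
                layout_cfg, truth.true_map
            )
            truth.true_layout = layout
            gio.write_genotypes(g, outdir / "genotypes.csv")
            gio.write_phenotypes(phenotypes, outdir / "phenotypes.csv")
            sim_mod.write_hits(hits_raw, outdir / "hits.tsv")
            sim_mod.write_scaffold_lengths(lengths, outdir / "scaffold_lengths.tsv")
            _json_dump(truth.to_json_dict(), outdir / "truth.json")
            hits_path = outdir / "hits.tsv"
            lengths_path = outdir / "scaffold_lengths.tsv"
        else:
            if not config.genotypes:
                raise ValueError("no simulation section and no genotypes path")
            g = gio.read_genotypes(config.genotypes)
            phenotypes = (
                gio.read_phenotypes(config.phenotypes) if config.phenotypes else pd.DataFrame()
            )
            hits_path = config.hits
            lengths_path = config.scaffold_lengths
        log.info("data: %d individuals x %d markers, %d traits",
                 g.n_individuals, g.n_markers, phenotypes.shape[1])
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage: qc --------------------------------------------------------
    stage = "qc"
    try:
        qc = gio.qc_summary(g)
        _json_dump(qc.as_dict(), outdir / "qc.json")
        summary["qc"] = qc.as_dict()
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage: filter ----------------------------------------------------
    stage = "filter"
    try:
        g_f, flog = gio.filter_markers(g, config.min_called, config.hwe_alpha)
        flog.to_csv(outdir / "filter_log.tsv", sep="\t")
        summary["filter"] = {"kept": g_f.n_markers, "removed": len(flog)}
        log.info("filter: kept %d of %d markers", g_f.n_markers, g.n_markers)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage: map -------------------------------------------------------
    stage = "map"
    try:
        mapres = LinkageMapper(g_f, lod_min=config.lod_min, r_max=config.r_max).fit()
        gmap = mapres.map
        gmap.to_tsv(outdir / "map.tsv")
        (outdir / "map_summary.txt").write_text(mapres.summary() + "\n")
        summary["map"] = {
            "n_groups": mapres.n_groups,
            "n_placed": mapres.n_placed,
            "total_length_cm": mapres.total_length_cm,
            "unplaced": len(mapres.build_log.unplaced),
        }
        results["map"] = gmap
        log.info("map: %d groups, %.1f cM", mapres.n_groups, mapres.total_length_cm)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage: scan + stepwise ------------------------------------------
    stage = "scan"
    try:
        g_m = g_f.subset_markers(list(gmap.table.index))
        probs = calc_genoprob(g_m, gmap, step_cm=config.step_cm,
                              error_rate=config.error_rate)
        scan_frames, model_dicts = [], {}
        summary["scan"] = {}
        results["qtl"] = {}
        for k, trait in enumerate(phenotypes.columns):
            if config.n_perm == 0:
                warnings.warn("n_perm=0: thresholding and stepwise search skipped")
            res = QTLModel(
                phenotypes[trait], probs, genotypes=g_m, gmap=gmap, trait=trait
            ).fit(
                n_perm=config.n_perm, alpha=config.alpha,
                seed=config.seed + 1000 + k, max_qtl=config.max_qtl,
            )
            scan_frames.append(res.curve.to_frame())
            lg, cm, lod = res.peak()
            summary["scan"][trait] = {
                "peak_lg": lg, "peak_cm": cm, "peak_lod": lod,
                "threshold": res.threshold,
                "n_qtl": res.qtl_model.n_qtl if res.qtl_model else None,
                "seed": config.seed + 1000 + k,
            }
            if res.qtl_model is not None:
                model_dicts[trait] = {
                    "lod": res.qtl_model.model_lod,
                    "pve": res.qtl_model.pve,
                    "qtls": res.qtl_model.qtls,
                    "interactions": res.qtl_model.interactions,
                    "threshold": res.threshold,
                    "intervals": [
                        {"lg": ci.lg, "lo_cm": ci.lo_cm, "hi_cm": ci.hi_cm,
                         "prob": ci.prob}
                        for ci in res.intervals
                    ],
                }
            results["qtl"][trait] = res
            if res.perm_maxima is not None:
                np.savetxt(outdir / f"perm_maxima_{trait}.txt", res.perm_maxima,
                           fmt="%.6f")
        if scan_frames:
            pd.concat(scan_frames, ignore_index=True).to_csv(
                outdir / "scan.tsv", sep="\t", index=False, float_format="%.6f"
            )
        _json_dump(model_dicts, outdir / "qtl_models.json")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage: anchor ----------------------------------------------------
    stage = "anchor"
    try:
        if hits_path and lengths_path:
            hits, hlog = anchor_mod.read_hits(
                hits_path, min_identity=config.min_identity,
                uniqueness_ratio=config.uniqueness_ratio,
            )
            lengths = anchor_mod.read_scaffold_lengths(lengths_path)
            assignments, single, alog = anchor_mod.assign_scaffolds(
                hits, gmap, min_markers=config.min_markers
            )
            anchored = anchor_mod.order_orient(assignments, hits, gmap,
                                               single_hit=single, log=alog)
            stats = anchor_mod.anchor_summary(anchored, lengths)
            anchor_mod.write_agp(anchored, lengths, outdir / "anchored.agp")
            anchor_mod.write_scaffold_table(anchored, outdir / "scaffold_table.tsv")
            _json_dump(stats.as_dict(), outdir / "anchor_stats.json")
            summary["anchor"] = stats.as_dict()
            results["anchored"] = anchored
            log.info("anchor: %d scaffolds, %.1f%% of assembly",
                     stats.n_anchored_scaffolds, 100 * stats.anchored_fraction)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage: score -----------------------------------------------------
    stage = "score"
    try:
        if truth is not None:
            report = score_against_truth(results, truth)
            _json_dump(report.as_dict(), outdir / "recovery_report.json")
            summary["recovery"] = report.as_dict()
    except Exception as exc:
        raise StageError(stage, exc) from exc

    _json_dump(summary, outdir / "summary.json")
    return summary


# ---------------------------------------------------------------------------
# truth scoring
# ---------------------------------------------------------------------------


@dataclass
class RecoveryReport:
    map: dict = field(default_factory=dict)
    qtl: dict = field(default_factory=dict)
    anchoring: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"map": self.map, "qtl": self.qtl, "anchoring": self.anchoring}


def _match_qtl(detected: list, true_qtls: list, window_cm: float = 20.0):
    """Greedy nearest matching of detected to true QTL within a window.

    ``detected`` entries carry true-map coordinates (chrom, cm)."""
    unmatched = list(range(len(true_qtls)))
    matches = []
    for d in detected:
        best = None
        for k in unmatched:
            t = true_qtls[k]
            if t["chrom"] != d["chrom"]:
                continue
            err = abs(t["pos_cm"] - d["cm"])
            if err <= window_cm and (best is None or err < best[1]):
                best = (k, err)
        if best is not None:
            matches.append({"true_index": best[0], "position_error_cm": best[1]})
            unmatched.remove(best[0])
    return matches


def score_against_truth(results: dict, truth: sim_mod.SimTruth) -> RecoveryReport:
    """Score inferred map / QTL models / anchoring against simulation truth.

    Detected QTL positions are translated onto the true map through the
    nearest inferred-map marker (marker names are shared), then greedily
    matched to true QTL within 20 cM.  Anchoring order accuracy is the
    Kendall pairwise concordance against the true scaffold order per group,
    after choosing the better of the two whole-group directions (a whole
    group's reversal is unidentifiable); orientation accuracy is the
    exact-match fraction under that direction.
    """
    report = RecoveryReport()
    true_t = truth.true_map.table

    gmap: GeneticMap | None = results.get("map")
    if gmap is not None:
        shared = gmap.table.index.intersection(true_t.index)
        if len(shared) == 0:
            raise ValueError("no shared markers between inferred map and truth")
        report.map = {
            "n_groups_true": truth.true_map.n_groups,
            "n_groups_inferred": gmap.n_groups,
            "group_count_match": gmap.n_groups == truth.true_map.n_groups,
            "length_ratio": gmap.total_length_cm / max(truth.true_map.total_length_cm, 1e-9),
        }

    qtl_results = results.get("qtl") or {}
    for trait, res in qtl_results.items():
        model = getattr(res, "qtl_model", None) or res
        qtls = model.qtls if hasattr(model, "qtls") else []
        detected = []
        for q in qtls:
            if gmap is not None:
                sub = gmap.group_table(q["lg"])
                marker = (sub["cm"] - q["cm"]).abs().idxmin()
                offset = q["cm"] - float(sub.loc[marker, "cm"])
                chrom = true_t.loc[marker, "lg"]
                cm = float(true_t.loc[marker, "cm"])
                # inferred group may run opposite to the true orientation
                detected.append({"chrom": chrom, "cm": cm + offset})
                detected.append({"chrom": chrom, "cm": cm - offset})
            else:
                detected.append({"chrom": q["lg"], "cm": q["cm"]})
        true_qtls = truth.true_qtls.get(trait, [])
        # de-duplicate the +-offset candidates: greedy match, keep best per QTL
        matches = _match_qtl(detected, true_qtls)
        errs = sorted(m["position_error_cm"] for m in matches)[: len(qtls)]
        entry = {
            "n_detected": len(qtls),
            "n_true": len(true_qtls),
            "position_errors_cm": errs,
        }
        pve_fit = getattr(model, "pve", None)
        if pve_fit is not None and true_qtls:
            entry["pve_error"] = float(pve_fit - sum(t["true_pve"] for t in true_qtls))
        report.qtl[trait] = entry

    anchored = results.get("anchored")
    if anchored is not None and truth.true_layout:
        accs, orient_accs, assign_ok, assign_tot = [], [], 0, 0
        true_lg_of = {}
        true_order_of = {}
        true_orient_of = {}
        for lg, rows in truth.true_layout.items():
            for pos, (scaf, orient, _s, _e) in enumerate(rows):
                true_lg_of[scaf] = lg
                true_order_of[scaf] = pos
                true_orient_of[scaf] = orient
        for lg, frame in anchored.per_lg.items():
            scafs = list(frame["scaffold"])
            assign_tot += len(scafs)
            true_lgs = [true_lg_of.get(s) for s in scafs]
            lg_true = max(set(true_lgs), key=lambda x: true_lgs.count(x))
            assign_ok += sum(t == lg_true for t in true_lgs)
            common = [s for s, t in zip(scafs, true_lgs) if t == lg_true]
            if len(common) < 2:
                continue
            ranks = [true_order_of[s] for s in common]
            n_pairs = len(common) * (len(common) - 1) // 2
            conc = sum(
                ranks[i] < ranks[j]
                for i in range(len(ranks)) for j in range(i + 1, len(ranks))
            )
            frac_fwd = conc / n_pairs
            reversed_group = (1.0 - frac_fwd) > frac_fwd
            accs.append(max(frac_fwd, 1.0 - frac_fwd))
            flip = {"+": "-", "-": "+", "?": "?"}
            inferred_orient = dict(zip(frame["scaffold"], frame["orientation"]))
            ok = sum(
                (flip[inferred_orient[s]] if reversed_group else inferred_orient[s])
                == true_orient_of[s]
                for s in common
            )
            orient_accs.append(ok / len(common))
        report.anchoring = {
            "order_accuracy": float(np.mean(accs)) if accs else None,
            "orientation_accuracy": float(np.mean(orient_accs)) if orient_accs else None,
            "assignment_accuracy": assign_ok / assign_tot if assign_tot else None,
        }
    return report


def load_truth(path) -> sim_mod.SimTruth:
    """Read a truth JSON written by the pipeline back into a SimTruth."""
    with open(path) as fh:
        raw = json.load(fh)
    table = pd.DataFrame(
        {"lg": raw["map"]["lg"], "cm": raw["map"]["cm"]},
        index=pd.Index(raw["map"]["marker"], name="marker"),
    )
    layout = raw.get("layout")
    if layout:
        layout = {lg: [tuple(r) for r in rows] for lg, rows in layout.items()}
    return sim_mod.SimTruth(
        true_map=GeneticMap(table), true_qtls=raw.get("qtls", {}), true_layout=layout
    )
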