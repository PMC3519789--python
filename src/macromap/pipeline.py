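"""Stage orchestration and the consolidated run report.

Stages run in dependency order over file inputs (map TSV, Newick tree
directories, hit tables) or over an in-memory synthetic scenario, and
every stage contributes a table to a single JSON report plus TSV
artifacts.  Reruns with the same configuration and seed are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .dating import calls_to_classified_pairs, classify_families, tally_calls
from .density import grr_density_contrast, grr_scan
from .map import GeneticMap, colocalized_groups, load_lengths, load_map, write_map
from .synteny import (collinearity_by_pair, conserved_segments, load_hits,
                      reciprocal_best_hits, synteny_links)
from .tags import detect_tags, duplicate_distance_stats, permute_family_dispersion
from .trees import SupportTree, read_tree_set
from .uniformity import uniformity_table

logger = logging.getLogger(__name__)

ALL_STAGES = ["uniformity", "grr", "tags", "dispersion", "coloc", "dating",
              "transloc", "synteny"]


@dataclass
class RunConfig:
    """Inputs, thresholds and stage selection for a pipeline run.

    Default thresholds reproduce the analysis' standard settings:
    bootstrap support floor 50, RBH identity floor 80%, TAG windows
    1 / 5 cM, 1,000 permutation replicates.
    """

    out_dir: str = "macromap_out"
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    map_path: str | None = None
    lengths_path: str | None = None
    nj_dir: str | None = None
    mp_dir: str | None = None
    map_a_path: str | None = None        # synteny map A; defaults to map_path
    lengths_a_path: str | None = None
    map_b_path: str | None = None
    lengths_b_path: str | None = None
    hits_ab_path: str | None = None
    hits_ba_path: str | None = None
    alpha_grr: float = 0.05
    grid_step: float = 0.1
    min_support: float = 50.0
    min_identity: float = 80.0
    tag_w_inner: float = 1.0
    tag_w_outer: float = 5.0
    permutation_R: int = 1000
    coloc_epsilon: float = 0.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def read_tree_dir(path: str | Path) -> dict[str, SupportTree]:
    """Read ``<family>.nwk`` files from a directory into a family->tree map."""
    out = {}
    for f in sorted(Path(path).glob("*.nwk")):
        trees = read_tree_set(f)
        if len(trees) != 1:
            raise ValueError(f"{f}: expected one tree per family file, got {len(trees)}")
        out[f.stem] = trees[0]
    return out


def write_tree_dir(trees: dict[str, SupportTree], path: str | Path) -> None:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    for fam, t in trees.items():
        (p / f"{fam}.nwk").write_text(t.newick() + "\n")


class StageError(RuntimeError):
    """A stage is missing a required input artifact."""


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the selected stages and write all artifacts plus a JSON report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "stages": {},
    }
    need_map = {"uniformity", "grr", "tags", "dispersion", "coloc", "dating",
                "transloc"} & set(cfg.stages)
    gmap: GeneticMap | None = None
    if need_map:
        if cfg.map_path is None:
            raise StageError(f"stages {sorted(need_map)} require a map input")
        lengths = load_lengths(cfg.lengths_path) if cfg.lengths_path else None
        gmap = load_map(cfg.map_path, lengths)
        write_map(gmap, out / "map.tsv")

    if "uniformity" in cfg.stages:
        rows = uniformity_table(gmap)
        df = pd.DataFrame([r.__dict__ for r in rows])
        df.to_csv(out / "uniformity.tsv", sep="\t", index=False)
        report["stages"]["uniformity"] = df.to_dict("records")

    if "grr" in cfg.stages:
        profiles, calls = grr_scan(gmap, alpha=cfg.alpha_grr, grid_step=cfg.grid_step)
        for prof in profiles:
            pd.DataFrame({
                "position_cM": prof.grid, "density": prof.f_hat,
                "lower": prof.lower, "upper": prof.upper,
            }).to_csv(out / f"density_chr{prof.chromosome}.tsv", sep="\t", index=False)
        df = pd.DataFrame([c.__dict__ for c in calls])
        df.to_csv(out / "grr.tsv", sep="\t", index=False)
        inside, outside = grr_density_contrast(gmap, calls)
        report["stages"]["grr"] = {
            "calls": df.to_dict("records"),
            "n_calls": len(calls),
            "density_inside": inside,
            "density_outside": outside,
            "note": "no GRR detected" if not calls else "",
        }

    if "tags" in cfg.stages:
        arrays = detect_tags(gmap, cfg.tag_w_inner, cfg.tag_w_outer)
        df = pd.DataFrame([
            {"family_id": a.family_id, "chromosome": a.chromosome,
             "size": a.size, "span_cM": a.span, "window_class": a.window_class,
             "loci": ",".join(l.locus_id for l in a.loci)}
            for a in arrays
        ])
        df.to_csv(out / "tags.tsv", sep="\t", index=False)
        report["stages"]["tags"] = {
            "n_arrays": len(arrays),
            "n_1cM": sum(a.window_class == "1cM" for a in arrays),
            "n_5cM": sum(a.window_class == "5cM" for a in arrays),
            "n_member_loci": sum(a.size for a in arrays),
        }

    if "dispersion" in cfg.stages:
        disp = permute_family_dispersion(gmap, R=cfg.permutation_R, seed=cfg.seed)
        report["stages"]["dispersion"] = {
            "chi_square": disp.chi_square, "df": disp.df, "p_value": disp.p_value,
            "replicates": disp.replicates,
            "observed": disp.observed.tolist(),
            "simulated_mean": disp.simulated_mean.tolist(),
            "n_flagged_families": len(disp.flagged),
            "flagged_families": disp.flagged,
        }

    if "coloc" in cfg.stages:
        groups = colocalized_groups(gmap, epsilon=cfg.coloc_epsilon)
        df = pd.DataFrame([
            {"chromosome": g.chromosome, "size": len(g.loci),
             "position_cM": g.loci[0].position, "relation": g.relation,
             "loci": ",".join(l.locus_id for l in g.loci)}
            for g in groups
        ])
        df.to_csv(out / "coloc.tsv", sep="\t", index=False)
        report["stages"]["coloc"] = {
            "n_groups": len(groups),
            "n_genes": sum(len(g.loci) for g in groups),
        }

    calls = None
    if "dating" in cfg.stages:
        if not (cfg.nj_dir and cfg.mp_dir):
            raise StageError("stage 'dating' requires nj_dir and mp_dir tree inputs")
        nj = read_tree_dir(cfg.nj_dir)
        mp = read_tree_dir(cfg.mp_dir)
        calls, tally = classify_families(nj, mp, gmap, min_support=cfg.min_support)
        df = pd.DataFrame([c.__dict__ for c in calls])
        df.to_csv(out / "pair_ages.tsv", sep="\t", index=False)
        report["stages"]["dating"] = {
            "total_pairs": tally.total,
            "incongruent": tally.incongruent,
            "congruent": tally.congruent,
            "ancient": tally.ancient,
            "recent": tally.recent,
            "undetermined": tally.undetermined,
            "percentages_of_congruent": tally.percentages(),
            "ancient_recent_ratio": tally.ancient_recent_ratio,
        }

    if "transloc" in cfg.stages:
        if calls is None:
            raise StageError("stage 'transloc' requires the 'dating' stage output")
        pairs = calls_to_classified_pairs(calls)
        stats_ = duplicate_distance_stats(pairs)
        report["stages"]["transloc"] = {
            "counts": {k: list(v) for k, v in stats_.counts.items()},
            "chi_square": stats_.chi_square,
            "chi_p": stats_.chi_p,
            "mean_distance_cM": stats_.mean_distance,
            "welch_t": stats_.welch_t,
            "welch_df": stats_.welch_df,
            "welch_p": stats_.welch_p,
        }

    if "synteny" in cfg.stages:
        a_path = cfg.map_a_path or cfg.map_path
        missing = [n for n, v in [("map_a", a_path), ("map_b", cfg.map_b_path),
                                  ("hits_ab", cfg.hits_ab_path),
                                  ("hits_ba", cfg.hits_ba_path)] if v is None]
        if missing:
            raise StageError(f"stage 'synteny' missing inputs: {missing}")
        la_path = cfg.lengths_a_path or (cfg.lengths_path if not cfg.map_a_path else None)
        map_a = load_map(a_path, load_lengths(la_path) if la_path else None)
        lengths_b = load_lengths(cfg.lengths_b_path) if cfg.lengths_b_path else None
        map_b = load_map(cfg.map_b_path, lengths_b)
        rbh = reciprocal_best_hits(load_hits(cfg.hits_ab_path),
                                   load_hits(cfg.hits_ba_path), cfg.min_identity)
        syn = synteny_links(map_a, map_b, rbh)
        collinear, pct_col = collinearity_by_pair(syn)
        segments, cov_a, cov_b = conserved_segments(collinear, map_a, map_b)
        pd.DataFrame([l.__dict__ for l in syn.links]).to_csv(
            out / "synteny_links.tsv", sep="\t", index=False)
        pd.DataFrame([
            {"chrom_a": s.chrom_a, "chrom_b": s.chrom_b,
             "start_a": s.start_a, "end_a": s.end_a,
             "start_b": s.start_b, "end_b": s.end_b, "n_links": len(s.links)}
            for s in segments
        ]).to_csv(out / "segments.tsv", sep="\t", index=False)
        report["stages"]["synteny"] = {
            "n_rbh_pairs": len(rbh),
            "n_links": len(syn.links),
            "homoeology": syn.homoeology,
            "pct_syntenic": syn.pct_syntenic,
            "pct_collinear": pct_col,
            "n_segments": len(segments),
            "coverage_a_pct": cov_a,
            "coverage_b_pct": cov_b,
        }

    write_report(report, out)
    return report


def write_report(report: dict, out_dir: str | Path) -> None:
    """Write the JSON report and a small human-readable summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    lines = [f"macromap {report.get('version', '?')} run report",
             f"seed={report.get('seed')} config={report.get('config_hash')}", ""]
    stages = report.get("stages", {})
    if "dating" in stages:
        d = stages["dating"]
        pct = d["percentages_of_congruent"]
        lines += [
            "duplication ages (congruent pairs): "
            f"ancient {d['ancient']} ({pct['ancient']}%), "
            f"recent {d['recent']} ({pct['recent']}%), "
            f"undetermined {d['undetermined']} ({pct['undetermined']}%)",
            f"ancient:recent ratio = {d['ancient_recent_ratio']:.1f}:1",
        ]
    if "grr" in stages:
        g = stages["grr"]
        lines.append(g["note"] or f"gene-rich regions: {g['n_calls']} "
                     f"(density {g['density_inside']:.2f} vs {g['density_outside']:.2f} genes/cM)")
    if "synteny" in stages:
        s = stages["synteny"]
        lines.append(f"synteny: {s['pct_syntenic']:.1f}% syntenic, "
                     f"{s['pct_collinear']:.1f}% collinear, "
                     f"coverage {s['coverage_a_pct']:.1f}%/{s['coverage_b_pct']:.1f}%")
    (out / "report.txt").write_text("\n".join(lines) + "\n")
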