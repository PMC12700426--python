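"""End-to-end orchestration: simulate -> DE -> regulon -> motif -> ChIP ->
kinetics -> strength -> report, from one structured config.

Every stage draws from its own seed stream derived from a single master
seed, reads only declared inputs, and writes its table into the output
directory; a manifest records the config snapshot, seeds, file checksums and
per-stage status so a rerun with the same config and seed is reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import write_fasta, write_gff3
from .chipcov import (
    assign_summits,
    call_summits,
    meta_profile,
    normalize_rpm,
    promoter_peak_height,
    smooth_gaussian,
    write_bedgraph,
)
from .diffexpr import Contrast, run_contrast, write_de
from .kinetics import analyze_population, traces_to_tsv
from .lexabox import (
    boxes_to_frame,
    box_features,
    compare_groups,
    discover_boxes,
    extract_promoters,
    onehot_pca,
)
from .regulon import call_sos_regulon, classify_temporal, collapse_to_tus
from .strength import pearson_r2, strength_table
from .synthetic_data import SimConfig, generate_dataset

log = logging.getLogger("sostempo")

CONTRASTS = {
    "wt20": "WT:MMC:20 vs WT:none:0",
    "wt40": "WT:MMC:40 vs WT:none:0",
    "dlexa": "dlexAdsidA:none:0 vs WT:none:0",
    "dreca40": "drecA:MMC:40 vs drecA:none:0",
}


@dataclass
class AnalysisConfig:
    """Analysis-stage knobs with the study's published thresholds as defaults."""

    smoothing_sigma: float = 30.0
    summit_min_rpm: float | None = None  # None -> 3x genome median, auto
    bind_min_rpm: float | None = None  # promoter-height binding call; auto as above
    summit_min_separation: int = 200
    assign_margin: int = 100
    assign_anchor: str = "start"
    score_floor: float = 6.0
    r2_gate: float = 0.95
    n_cells: int = 100
    run_kinetics: bool = True


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {"sim", "analysis"}
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        sim = SimConfig.from_dict(raw.get("sim", {}))
        ana = AnalysisConfig(**raw.get("analysis", {}))
        return cls(sim, ana)

    def to_dict(self) -> dict:
        return {
            "sim": dataclasses.asdict(self.sim),
            "analysis": dataclasses.asdict(self.analysis),
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: PipelineConfig | str | Path,
    outdir: str | Path,
    seed: int = 0,
) -> dict:
    """Run every stage on one synthetic dataset; returns the results bundle.

    The bundle holds the in-memory tables; the output directory receives the
    simulated inputs, per-stage TSVs, a summary JSON and the run manifest.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    cfg, ana = config.sim, config.analysis
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    status: dict[str, str] = {}
    t_start = time.time()

    # --- simulate -----------------------------------------------------
    log.info("stage simulate: generating synthetic dataset (seed=%d)", seed)
    ds = generate_dataset(cfg, seed=seed, n_cells=ana.n_cells)
    write_fasta(ds.genome, outdir / "genome.fasta")
    write_gff3(ds.annotation, outdir / "annotation.gff3")
    ds.counts.to_tsv(outdir / "counts.tsv", outdir / "samples.tsv")
    write_bedgraph(ds.coverage, outdir / "coverage.bedgraph")
    traces_to_tsv(ds.traces_strong, outdir / "traces_strong.tsv")
    traces_to_tsv(ds.traces_weak, outdir / "traces_weak.tsv")
    ds.truth.to_json(outdir / "truth.json")
    status["simulate"] = "ok"

    # --- differential expression --------------------------------------
    log.info("stage diffexpr: running %d contrasts", len(CONTRASTS))
    de = {}
    for key, expr in CONTRASTS.items():
        de[key] = run_contrast(ds.counts, Contrast.parse(expr))
        write_de(de[key], outdir / f"de_{key}.tsv")
    status["diffexpr"] = "ok"

    # --- ChIP coverage ------------------------------------------------
    total_reads = float(ds.coverage.sum())
    track = smooth_gaussian(normalize_rpm(ds.coverage, total_reads), ana.smoothing_sigma)
    min_rpm = (
        ana.summit_min_rpm
        if ana.summit_min_rpm is not None
        else 3.0 * float(np.median(track.values))
    )
    summits = call_summits(track, min_rpm, ana.summit_min_separation)
    assignments = assign_summits(summits, ds.annotation, ana.assign_margin,
                                 ana.assign_anchor)
    # The binding criterion follows the promoter peak-height rule: a gene is
    # bound when the smoothed rpm maximum inside its promoter window clears
    # the threshold (summit-to-gene assignment stays available for
    # sigma-factor-style analyses).
    bind_min = ana.bind_min_rpm if ana.bind_min_rpm is not None else min_rpm
    heights = {
        g.gene_id: promoter_peak_height(track, g, ds.annotation.genome_length)
        for g in ds.annotation
    }
    bound_genes = sorted(g for g, h in heights.items() if h >= bind_min)
    pd.Series(heights, name="promoter_peak_rpm").rename_axis("gene_id").to_csv(
        outdir / "promoter_peak_heights.tsv", sep="\t"
    )
    pd.DataFrame(
        [(a.summit, a.height, a.gene_id) for a in assignments],
        columns=["summit", "height_rpm", "gene_id"],
    ).to_csv(outdir / "summit_assignments.tsv", sep="\t", index=False)
    status["chipcov"] = "ok"

    # --- regulon ------------------------------------------------------
    calls = call_sos_regulon(de["wt40"], de["dlexa"], de["dreca40"], bound_genes)
    tus = collapse_to_tus(calls, ds.annotation)
    temporal = classify_temporal(tus, de["wt20"], de["wt40"])
    calls.rename_axis("gene_id").to_csv(outdir / "regulon.tsv", sep="\t")
    temporal.to_csv(outdir / "temporal_classes.tsv", sep="\t")
    status["regulon"] = "ok"

    # --- LexA box discovery -------------------------------------------
    summary: dict = {}
    promoter_genes = temporal.reset_index().rename(columns={"promoter_gene": "gene_id"})
    boxes_df = pd.DataFrame()
    pca = None
    if len(promoter_genes) >= 5:
        proms = extract_promoters(
            ds.annotation, ds.genome, genes=list(promoter_genes["gene_id"])
        )
        disc = discover_boxes(proms, score_floor=ana.score_floor)
        boxes = {g: (box_features(b) if b else None) for g, b in disc.boxes.items()}
        disc.pwm.to_files(outdir / "pwm")
        boxes_df = boxes_to_frame(boxes)
        boxes_df.to_csv(outdir / "boxes.tsv", sep="\t", index=False)
        with_box = boxes_df[boxes_df["has_box"]]
        same_len = with_box.groupby(with_box["seq"].str.len())
        if len(with_box) >= 3:
            biggest = max(same_len.groups.values(), key=len)
            seqs = with_box.loc[biggest, "seq"].tolist()
            if len(seqs) >= 3:
                pca = onehot_pca(seqs)
                pd.DataFrame(
                    pca.scores[:, :2],
                    columns=["pc1", "pc2"],
                    index=with_box.loc[biggest, "gene_id"],
                ).to_csv(outdir / "pca_scores.tsv", sep="\t")
        summary["consensus"] = disc.pwm.consensus
        status["lexabox"] = "ok"
    else:
        status["lexabox"] = "skipped (fewer than 5 member promoters)"

    # --- kinetics -----------------------------------------------------
    kin = {}
    if ana.run_kinetics:
        for name, traces in (("strong", ds.traces_strong), ("weak", ds.traces_weak)):
            kin[name] = analyze_population(traces, r2_gate=ana.r2_gate)
        pd.DataFrame(
            [
                {
                    "population": name,
                    "t_ind_min": k["induction"].t_ind,
                    "censored": k["induction"].censored,
                    "censor_reason": k["induction"].censor_reason,
                    "r2": k["fit"].r2,
                    "cv": k["cv"],
                    "n_cells": k["induction"].n_cells,
                }
                for name, k in kin.items()
            ]
        ).to_csv(outdir / "kinetics.tsv", sep="\t", index=False)
        status["kinetics"] = "ok"
    else:
        status["kinetics"] = "skipped (disabled)"

    # --- promoter strength --------------------------------------------
    strength = pd.DataFrame()
    if len(temporal):
        pg = temporal.reset_index().rename(columns={"promoter_gene": "gene_id"})
        strength = strength_table(pg, de["dlexa"], de["wt40"], ds.counts, ds.annotation)
        strength.to_csv(outdir / "strength.tsv", sep="\t")
        status["strength"] = "ok"
    else:
        status["strength"] = "skipped (empty regulon)"

    # --- summary ------------------------------------------------------
    summary.update(
        {
            "n_genes": len(ds.truth.genes),
            "n_induced_wt20": int(de["wt20"]["induced"].sum()),
            "n_induced_wt40": int(de["wt40"]["induced"].sum()),
            "n_derepressed_dlexa": int(de["dlexa"]["induced"].sum()),
            "n_regulon_members": int(calls["member"].sum()),
            "n_member_tus": int(len(tus)),
            "n_early_tus": int((temporal["temporal_class"] == "early").sum()),
            "n_late_tus": int((temporal["temporal_class"] == "late").sum()),
            "n_summits": len(summits),
        }
    )
    member_sos = strength.dropna(subset=["beta_proxy", "damage_lfc"])
    if len(member_sos) >= 3:
        corr = pearson_r2(member_sos["beta_proxy"], member_sos["damage_lfc"])
        summary["r2_beta_vs_damage"] = corr["r2"]
        summary["pearson_r"] = corr["r"]
        early = member_sos[member_sos["temporal_class"] == "early"]["beta_proxy"]
        late = member_sos[member_sos["temporal_class"] == "late"]["beta_proxy"]
        if len(early) >= 2 and len(late) >= 2:
            _, p_mw = compare_groups(early, late, "mann_whitney")
            summary["p_beta_early_vs_late"] = p_mw
        early_g = member_sos[member_sos["temporal_class"] == "early"]["gene_id"]
        late_g = member_sos[member_sos["temporal_class"] == "late"]["gene_id"]
        if len(early_g) and len(late_g):
            summary["pct_early_bound"] = sum(g in set(bound_genes) for g in early_g) / len(early_g) * 100
            summary["pct_late_bound"] = sum(g in set(bound_genes) for g in late_g) / len(late_g) * 100
    if kin:
        for name, k in kin.items():
            summary[f"t_ind_{name}_min"] = k["induction"].t_ind
            summary[f"cv_{name}"] = k["cv"]

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))

    files = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "software_version": __version__,
        "seed": seed,
        "config": config.to_dict(),
        "stages": status,
        "files": files,
        "runtime_s": round(time.time() - t_start, 2),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return {
        "dataset": ds,
        "de": de,
        "calls": calls,
        "tus": tus,
        "temporal": temporal,
        "boxes": boxes_df,
        "pca": pca,
        "summits": summits,
        "assignments": assignments,
        "bound_genes": bound_genes,
        "track": track,
        "kinetics": kin,
        "strength": strength,
        "summary": summary,
        "manifest": manifest,
    }


def make_report(bundle: dict, outdir: str | Path) -> Path:
    """Deterministic text summary plus figures; plotting is best-effort.

    A failure in any figure is recorded in the report and never corrupts the
    data bundle.
    """
    outdir = Path(outdir)
    figdir = outdir / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    summary = bundle.get("summary", {})
    lines = ["sostempo run report", "===================", ""]
    if summary.get("n_regulon_members", 0) == 0:
        lines.append("Regulon: zero member genes called.")
    for key in sorted(summary):
        lines.append(f"{key}: {summary[key]}")
    missing = [k for k in ("de", "temporal", "strength") if k not in bundle or bundle[k] is None]
    for m in missing:
        lines.append(f"table absent: {m}")

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        figures = {
            "volcano.png": _plot_volcano,
            "strength_scatter.png": _plot_strength,
            "pca.png": _plot_pca,
            "meta_profile.png": _plot_meta,
            "traces.png": _plot_traces,
        }
        for fname, fn in figures.items():
            try:
                fig = fn(bundle)
                if fig is not None:
                    fig.savefig(figdir / fname, dpi=110)
                    plt.close(fig)
                    lines.append(f"figure written: figures/{fname}")
            except Exception as exc:  # noqa: BLE001 - report, never fail
                lines.append(f"figure failed: figures/{fname} ({exc})")
    except Exception as exc:  # matplotlib unavailable or broken backend
        lines.append(f"plotting unavailable: {exc}")

    report = outdir / "report.txt"
    report.write_text("\n".join(lines) + "\n")
    return report


def _plot_volcano(bundle):
    import matplotlib.pyplot as plt

    de = bundle["de"]["wt40"]
    members = set(bundle["calls"].index[bundle["calls"]["member"]])
    fig, ax = plt.subplots(figsize=(5, 4))
    logp = -np.log10(np.maximum(de["p"], 1e-300))
    is_m = de.index.isin(members)
    ax.scatter(de["log2fc"][~is_m], logp[~is_m], s=8, c="0.7", label="other")
    ax.scatter(de["log2fc"][is_m], logp[is_m], s=12, c="tab:red", label="regulon")
    ax.axvline(1, ls="--", c="k", lw=0.8)
    ax.axhline(2, ls="--", c="k", lw=0.8)
    ax.set_xlabel("log2 fold change (damage 40 min)")
    ax.set_ylabel("-log10 p")
    ax.legend(frameon=False)
    fig.tight_layout()
    return fig


def _plot_strength(bundle):
    import matplotlib.pyplot as plt

    st = bundle["strength"]
    if st is None or not len(st):
        return None
    fig, ax = plt.subplots(figsize=(4.5, 4))
    colors = st["temporal_class"].map({"early": "tab:blue", "late": "tab:red"})
    ax.scatter(st["beta_proxy"], st["damage_lfc"], c=colors, s=18)
    if "r2_beta_vs_damage" in bundle["summary"]:
        ax.set_title(f"r2 = {bundle['summary']['r2_beta_vs_damage']:.3f}")
    ax.set_xlabel("beta_max proxy (derepression log2FC)")
    ax.set_ylabel("damage log2FC (40 min)")
    fig.tight_layout()
    return fig


def _plot_pca(bundle):
    import matplotlib.pyplot as plt

    pca = bundle.get("pca")
    if pca is None:
        return None
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.scatter(pca.scores[:, 0], pca.scores[:, 1], s=18)
    ve = pca.variance_explained
    ax.set_xlabel(f"PC1 ({100 * ve[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * ve[1]:.1f}%)")
    fig.tight_layout()
    return fig


def _plot_meta(bundle):
    import matplotlib.pyplot as plt

    ds = bundle["dataset"]
    temporal = bundle["temporal"]
    if not len(temporal):
        return None
    profs = meta_profile(bundle["track"], ds.annotation,
                         list(temporal["promoter_gene"]))
    fig, ax = plt.subplots(figsize=(5, 4))
    block = profs["start"]
    ax.plot(block.columns.to_numpy(), block.mean(axis=0).to_numpy())
    ax.set_xlabel("position relative to CDS start (bp)")
    ax.set_ylabel("mean coverage (rpm)")
    fig.tight_layout()
    return fig


def _plot_traces(bundle):
    import matplotlib.pyplot as plt

    kin = bundle.get("kinetics") or {}
    if not kin:
        return None
    fig, ax = plt.subplots(figsize=(5, 4))
    for name, k in kin.items():
        ax.plot(k["time"], k["mean"], label=name)
        ax.fill_between(k["time"], k["mean"] - k["sd"], k["mean"] + k["sd"], alpha=0.2)
        if k["induction"].t_ind is not None:
            ax.axvline(k["induction"].t_ind, ls="--", lw=0.8)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("area-normalised intensity (a.u.)")
    ax.legend(frameon=False)
    fig.tight_layout()
    return fig
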