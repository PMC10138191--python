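"""End-to-end pipeline orchestration and report generation.

Runs, in order: probe-site assignment, per-sample event counts, global
burden test, per-probe differential table, nearest-TSS annotation and
promoter gene list, gene-set enrichment, figures, and a deterministic
JSON summary. Every number in the summary is computed by the module
operations themselves; the report layer only assembles them. Stage
failures abort with the stage name; outputs written before the failure
are kept and a MANIFEST notes the incompleteness.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import __version__, io as gio
from .differential import AnalysisParams, differential_probes, global_burden_test
from .enrichment import enrich, top_categories
from .errors import ConfigurationError, StageError
from .promoters import annotate_results, promoter_gene_list, table1_style, DEFAULT_WINDOW
from .sites import assign_probes_to_sites, per_sample_event_counts, DEFAULT_CUTOFF

logger = logging.getLogger(__name__)

plt.rcParams["svg.hashsalt"] = "tfbsmeth"


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run."""

    beta: str
    manifest: str
    sites: str
    sample_sheet: str
    tss: str
    gene_sets: str
    outdir: str
    cutoff: float = DEFAULT_CUTOFF
    window: int = DEFAULT_WINDOW
    params: AnalysisParams = field(default_factory=AnalysisParams)
    enrichment_universe: str = "assigned"  # or "annotation"
    top_k: int = 10
    flip_sign: bool = False
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        for name in ("beta", "manifest", "sites", "sample_sheet", "tss", "gene_sets"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise ConfigurationError(f"input '{name}' not found: {p}")
        if not 0.0 < self.cutoff <= 1.0:
            raise ConfigurationError(f"cutoff {self.cutoff} outside (0, 1]")
        if self.window <= 0:
            raise ConfigurationError(f"window must be > 0, got {self.window}")
        if self.enrichment_universe not in ("assigned", "annotation"):
            raise ConfigurationError("enrichment_universe must be 'assigned' or 'annotation'")
        if self.top_k < 1:
            raise ConfigurationError("top_k must be >= 1")
        self.params.validate()
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        params = AnalysisParams(**raw.pop("params", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigurationError(f"unknown pipeline config keys: {sorted(bad)}")
        required = ("beta", "manifest", "sites", "sample_sheet", "tss", "gene_sets", "outdir")
        missing = [k for k in required if k not in raw]
        if missing:
            raise ConfigurationError(f"pipeline config missing keys: {missing}")
        base = Path(path).parent
        for key in required:
            if not Path(raw[key]).is_absolute():
                raw[key] = str(base / raw[key])
        return cls(params=params, **raw).validate()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the report bundle.

    The bundle maps stage names to their in-memory results; files are
    written under ``config.outdir`` as each stage completes.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []
    bundle: dict = {}

    def stage(name):
        def deco(fn):
            try:
                bundle[name] = fn()
                completed.append(name)
                logger.info("stage %s done", name)
            except Exception as exc:
                (out / "MANIFEST.txt").write_text(
                    "INCOMPLETE RUN\ncompleted stages: " + ", ".join(completed)
                    + f"\nfailed stage: {name}\n"
                )
                raise StageError(name, exc) from exc
            return bundle[name]
        return deco

    @stage("load")
    def _load():
        manifest = gio.read_manifest(config.manifest)
        return {
            "manifest": manifest,
            "beta": gio.read_beta_matrix(config.beta, manifest),
            "sites": gio.read_bed(config.sites),
            "sheet": gio.read_sample_sheet(config.sample_sheet),
            "tss": gio.read_tss(config.tss),
            "gene_sets": gio.read_gmt(config.gene_sets),
        }

    data = bundle["load"]

    @stage("assignment")
    def _assign():
        a = assign_probes_to_sites(data["manifest"], data["sites"])
        logger.info(
            "assignment: %d/%d probes inside >= 1 of %d sites",
            len(a.assigned_probes), len(data["manifest"]), len(data["sites"]),
        )
        return a

    @stage("event_counts")
    def _counts():
        counts = per_sample_event_counts(data["beta"], bundle["assignment"], config.cutoff)
        counts.rename_axis("sample_id").reset_index().to_csv(
            out / "per_sample_event_counts.tsv", sep="\t", index=False
        )
        return counts

    @stage("burden_test")
    def _burden():
        return global_burden_test(bundle["event_counts"], data["sheet"], config.params)

    @stage("differential")
    def _diff():
        results, skipped = differential_probes(
            data["beta"], data["sheet"], bundle["assignment"], config.params
        )
        tsv = results.rename(
            columns={
                "mean_a": f"mean_{results.attrs['group_a']}",
                "mean_b": f"mean_{results.attrs['group_b']}",
            }
        )
        tsv.to_csv(out / "differential.tsv", sep="\t", index=False)
        if skipped:
            (out / "skipped_units.txt").write_text("\n".join(skipped) + "\n")
        return {"results": results, "skipped": skipped}

    @stage("annotation")
    def _annot():
        ann = annotate_results(
            bundle["differential"]["results"], data["manifest"], data["tss"],
            config.window, config.flip_sign,
        )
        table1_style(ann, config.params.alpha).to_csv(
            out / "gene_mapped_units.tsv", sep="\t", index=False
        )
        return ann

    @stage("promoter_genes")
    def _genes():
        genes = promoter_gene_list(bundle["annotation"], config.params.alpha)
        (out / "promoter_genes.txt").write_text("\n".join(genes) + ("\n" if genes else ""))
        return genes

    @stage("enrichment")
    def _enrich():
        ann = bundle["annotation"]
        if config.enrichment_universe == "assigned":
            universe = sorted(ann.loc[ann["gene_id"].notna(), "gene_id"].unique().tolist())
        else:
            universe = sorted(data["tss"]["gene_id"].unique().tolist())
        res = enrich(bundle["promoter_genes"], universe, data["gene_sets"])
        flat = res.copy()
        if not flat.empty:
            flat["genes"] = flat["genes"].map(";".join)
        flat.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        top = top_categories(res, config.top_k) if not res.empty else res
        return {"results": res, "top": top}

    @stage("figures")
    def _figures():
        return plot_outputs(bundle, data, config, out)

    @stage("summary")
    def _summary():
        ann = bundle["annotation"]
        results = bundle["differential"]["results"]
        alpha = config.params.alpha
        n_sig = int((results["p_value"] < alpha).sum())
        summary = {
            "package_version": __version__,
            "parameters": {
                "cutoff": config.cutoff,
                "window": config.window,
                "alpha": alpha,
                "test_variant": config.params.test_variant,
                "adjust": config.params.adjust,
                "enrichment_universe": config.enrichment_universe,
                "seed": config.seed,
            },
            "n_sites": int(len(data["sites"])),
            "n_probes": int(len(data["manifest"])),
            "n_probes_in_sites": len(bundle["assignment"].assigned_probes),
            "n_samples": {
                bundle["burden_test"]["group_a"]: bundle["burden_test"]["n_a"],
                bundle["burden_test"]["group_b"]: bundle["burden_test"]["n_b"],
            },
            "burden_test": bundle["burden_test"],
            "n_units_tested": int(len(results)),
            "n_units_skipped": len(bundle["differential"]["skipped"]),
            "n_significant": n_sig,
            "n_significant_hypo_in_b": int((results["direction"] == "hypo_in_b").sum()),
            "n_significant_hypo_in_a": int((results["direction"] == "hypo_in_a").sum()),
            "n_promoter_significant_units": int(
                ((ann["p_value"] < alpha) & ann["is_promoter"]).sum()
            ),
            "n_promoter_genes": len(bundle["promoter_genes"]),
            "n_gene_sets_tested": int(len(bundle["enrichment"]["results"])),
            "top_categories": [
                {"set_name": r.set_name, "fdr": float(r.fdr), "neg_log_fdr": float(r.neg_log_fdr)}
                for r in bundle["enrichment"]["top"].itertuples(index=False)
            ],
        }
        gio.write_json(summary, out / "summary.json")
        return summary

    (out / "MANIFEST.txt").write_text("COMPLETE RUN\nstages: " + ", ".join(completed) + "\n")
    return bundle


def plot_outputs(bundle: dict, data: dict, config: PipelineConfig, out: Path) -> list[str]:
    """Write the report figures; returns the file names written.

    Figures: per-group event-count comparison, heatmap of significant
    units with group annotation, top-k enrichment bars, and a linear
    genome-location plot of the promoter genes. An empty significant set
    yields placeholder text figures rather than a crash.
    """
    written: list[str] = []
    sheet = data["sheet"]
    alpha = config.params.alpha

    def save(fig, name):
        fig.savefig(out / name, metadata={"Date": None})
        plt.close(fig)
        written.append(name)

    # per-group counts
    counts = bundle["event_counts"]
    fig, ax = plt.subplots(figsize=(4, 4))
    groups = list(dict.fromkeys(sheet["group"]))
    by_group = [counts[sheet.loc[sheet["group"] == g, "sample_id"]].to_numpy() for g in groups]
    ax.boxplot(by_group, tick_labels=groups)
    for i, vals in enumerate(by_group):
        ax.plot(np.full(len(vals), i + 1) + np.linspace(-0.1, 0.1, len(vals)), vals, "k.", ms=3)
    ax.set_ylabel(f"hypomethylated sites per sample (beta < {config.cutoff})")
    ax.set_title(f"burden test p = {bundle['burden_test']['p_value']:.3g}")
    save(fig, "event_counts_by_group.svg")

    # heatmap of significant units
    results = bundle["differential"]["results"]
    sig_units = results.loc[results["p_value"] < alpha, "unit_id"].tolist()
    fig, ax = plt.subplots(figsize=(6, 4))
    if sig_units:
        ordered_samples = sheet.sort_values("group", kind="mergesort")["sample_id"].tolist()
        mat = data["beta"].loc[sig_units, ordered_samples].to_numpy()
        im = ax.imshow(mat, aspect="auto", cmap="RdYlBu", vmin=0, vmax=1, interpolation="nearest")
        fig.colorbar(im, ax=ax, label="beta")
        boundary = int((sheet.sort_values("group", kind="mergesort")["group"] == groups[0]).sum())
        ax.axvline(boundary - 0.5, color="k", lw=1)
        ax.set_xlabel("samples (grouped)")
        ax.set_ylabel(f"significant units (n={len(sig_units)})")
    else:
        logger.info("no significant units; heatmap replaced by placeholder")
        ax.text(0.5, 0.5, "no significant units", ha="center", va="center")
        ax.set_axis_off()
    save(fig, "significant_units_heatmap.svg")

    # enrichment bars
    top = bundle["enrichment"]["top"]
    fig, ax = plt.subplots(figsize=(6, 4))
    if len(top):
        ax.barh(top["set_name"][::-1], top["neg_log_fdr"][::-1])
        ax.set_xlabel("-log10(FDR)")
    else:
        ax.text(0.5, 0.5, "no gene sets tested", ha="center", va="center")
        ax.set_axis_off()
    fig.tight_layout()
    save(fig, "enrichment_top.svg")

    # linear genome-location plot of promoter genes
    genes = bundle["promoter_genes"]
    tss = data["tss"].set_index("gene_id")
    fig, ax = plt.subplots(figsize=(7, 3))
    chroms = list(dict.fromkeys(data["sites"]["chrom"]))
    if genes:
        for gi, g in enumerate(genes):
            row = tss.loc[g]
            lane = chroms.index(row["chrom"]) if row["chrom"] in chroms else len(chroms)
            ax.plot(row["tss"], lane, "o", ms=4, color="C3")
        ax.set_yticks(range(len(chroms)), chroms)
        ax.set_xlabel("position (bp)")
        ax.set_title(f"promoter genes with hypomethylated binding sites (n={len(genes)})")
    else:
        ax.text(0.5, 0.5, "no promoter genes", ha="center", va="center")
        ax.set_axis_off()
    save(fig, "promoter_gene_locations.svg")
    return written
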