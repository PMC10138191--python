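"""Synthetic study bundles with known ground truth.

Emulates a two-cohort methylation-array study anchored on transcription
factor binding sites: a beta-value matrix over probes placed inside (and
outside) ChIP-seq-style binding intervals, a probe manifest, a sample sheet,
a TSS annotation with gene sets, and a tissue-microarray IHC score sheet.
A configurable fraction of sites carries a planted hypomethylation effect
in one cohort, recorded in a :class:`GroundTruth` object so downstream
stages can be scored against truth.

Beta values are drawn from a Beta distribution parameterized by mean mu and
concentration ``precision`` (shape1 = mu*precision, shape2 =
(1-mu)*precision), matching the absolute-threshold event calling performed
downstream on the beta scale.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

GenomeSpec = list[tuple[str, int]]

#: default genome used by the CLI: three chromosomes, 120 Mb total
DEFAULT_GENOME: GenomeSpec = [("chr1", 50_000_000), ("chr2", 40_000_000), ("chr3", 30_000_000)]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic methylation cohort.

    Defaults mirror the emulated study design: 37 samples in cohort A
    (nonfunctional tumors) vs 15 in cohort B (hormone-secreting tumors),
    baseline methylation high (mean beta 0.80), and a planted
    hypomethylation effect of 0.25 in cohort B at a fraction of sites.
    The site universe is scaled down (2,000 sites, one probe per site,
    500 background probes) to keep a full pipeline run fast.
    """

    n_group_a: int = 37
    n_group_b: int = 15
    n_sites: int = 2000
    probes_per_site: int = 1
    n_background_probes: int = 500
    baseline_mean: float = 0.80
    effect_delta: float = 0.25
    planted_fraction: float = 0.10
    precision: float = 30.0
    missing_rate: float = 0.01
    direction: str = "hypo_in_b"  # or "hypo_in_a" (symmetric mode)
    group_a_label: str = "NFPA"
    group_b_label: str = "GHPA"
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.n_group_a < 2 or self.n_group_b < 2:
            raise ConfigurationError("each group needs >= 2 samples (t-tests require >= 2)")
        if self.n_sites < 1:
            raise ConfigurationError("n_sites must be >= 1")
        if self.probes_per_site < 1:
            raise ConfigurationError("probes_per_site must be >= 1")
        if self.n_background_probes < 0:
            raise ConfigurationError("n_background_probes must be >= 0")
        for name in ("baseline_mean", "planted_fraction", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.baseline_mean < 1.0:
            raise ConfigurationError("baseline_mean must lie strictly in (0, 1)")
        if self.baseline_mean - self.effect_delta <= 0.0:
            raise ConfigurationError("baseline_mean - effect_delta must be > 0")
        if self.precision <= 0:
            raise ConfigurationError("precision must be > 0")
        if self.direction not in ("hypo_in_b", "hypo_in_a"):
            raise ConfigurationError(f"unknown direction {self.direction!r}")
        return self

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ConfigurationError(f"unknown simulation config keys: {sorted(bad)}")
        return cls(**d).validate()


@dataclass
class GroundTruth:
    """Planted-effect bookkeeping for a simulated cohort.

    ``site_means`` maps each planted site id to the true per-group mean
    beta (group label -> mu).
    """

    planted_site_ids: tuple[str, ...]
    planted_probe_ids: tuple[str, ...]
    site_means: dict[str, dict[str, float]] = field(default_factory=dict)
    probe_site: dict[str, str] = field(default_factory=dict)  # planted probe -> its site

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_site_ids": list(self.planted_site_ids),
            "planted_probe_ids": list(self.planted_probe_ids),
            "site_means": self.site_means,
            "probe_site": self.probe_site,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            planted_site_ids=tuple(d["planted_site_ids"]),
            planted_probe_ids=tuple(d["planted_probe_ids"]),
            site_means=d["site_means"],
            probe_site=d["probe_site"],
        )


def _check_genome(genome_spec: GenomeSpec) -> None:
    if not genome_spec:
        raise ConfigurationError("genome_spec is empty")
    for chrom, length in genome_spec:
        if length <= 0:
            raise ConfigurationError(f"chromosome {chrom} has non-positive length {length}")


def simulate_binding_sites(
    genome_spec: GenomeSpec,
    n_sites: int,
    site_width: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw ``n_sites`` fixed-width intervals uniformly over a genome.

    Chromosomes are sampled proportionally to their placeable length;
    intervals use BED half-open coordinates, are sorted by (chrom, start,
    end) and assigned sequential site ids. Intervals may overlap.
    """
    _check_genome(genome_spec)
    if n_sites < 1:
        raise ConfigurationError("n_sites must be >= 1")
    if site_width < 1:
        raise ConfigurationError("site_width must be >= 1")
    for chrom, length in genome_spec:
        if length <= site_width:
            raise ConfigurationError(f"chromosome {chrom} shorter than site_width {site_width}")
    rng = np.random.default_rng(seed)
    chroms = [c for c, _ in genome_spec]
    placeable = np.array([length - site_width for _, length in genome_spec], dtype=float)
    chrom_idx = rng.choice(len(chroms), size=n_sites, p=placeable / placeable.sum())
    starts = np.empty(n_sites, dtype=np.int64)
    for i, (chrom, length) in enumerate(genome_spec):
        mask = chrom_idx == i
        starts[mask] = rng.integers(0, length - site_width, size=int(mask.sum()))
    df = pd.DataFrame(
        {
            "chrom": [chroms[i] for i in chrom_idx],
            "start": starts,
            "end": starts + site_width,
        }
    )
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    df["site_id"] = [f"site_{i:06d}" for i in range(len(df))]
    return df


def _site_trees(sites: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in sites.groupby("chrom", sort=False):
        tree = IntervalTree()
        for start, end in zip(sub["start"], sub["end"]):
            tree.addi(int(start), int(end))
        trees[chrom] = tree
    return trees


def simulate_cohort(
    config: SimulationConfig,
    sites: pd.DataFrame,
    genome_spec: GenomeSpec | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a two-cohort beta-value matrix over a site universe.

    Returns ``(beta, manifest, sample_sheet, truth)``. One probe set is
    placed inside sites (``probes_per_site`` per site), another outside all
    sites (``n_background_probes``, rejection-sampled). Planted sites get
    mean ``baseline_mean - effect_delta`` in the affected group; all other
    probe/group combinations keep ``baseline_mean``. Missing values are
    inserted missing-completely-at-random at ``missing_rate``.
    """
    config.validate()
    if sites is None or len(sites) == 0:
        raise ConfigurationError("sites must be non-empty")
    rng = np.random.default_rng(config.seed)

    n_planted = int(round(config.planted_fraction * len(sites)))
    planted_pos = np.sort(rng.choice(len(sites), size=n_planted, replace=False))
    planted_mask = np.zeros(len(sites), dtype=bool)
    planted_mask[planted_pos] = True

    # probes inside sites, 1-based positions
    records: list[tuple[str, str, int, bool, str]] = []  # probe, chrom, pos, planted, site
    k = 0
    for row, is_planted in zip(sites.itertuples(index=False), planted_mask):
        for _ in range(config.probes_per_site):
            pos0 = int(rng.integers(row.start, row.end))
            records.append((f"cg{k:08d}", row.chrom, pos0 + 1, bool(is_planted), row.site_id))
            k += 1

    # background probes strictly outside every site
    if genome_spec is None:
        genome_spec = [
            (str(chrom), int(sub["end"].max()) + 100_000)
            for chrom, sub in sites.groupby("chrom", sort=False)
        ]
    _check_genome(genome_spec)
    trees = _site_trees(sites)
    lengths = np.array([length for _, length in genome_spec], dtype=float)
    n_bg = 0
    while n_bg < config.n_background_probes:
        ci = int(rng.choice(len(genome_spec), p=lengths / lengths.sum()))
        chrom, length = genome_spec[ci]
        pos0 = int(rng.integers(0, length))
        if chrom in trees and trees[chrom].overlaps_point(pos0):
            continue
        records.append((f"cg{k:08d}", chrom, pos0 + 1, False, ""))
        k += 1
        n_bg += 1

    manifest = pd.DataFrame(
        [(r[0], r[1], r[2], "+") for r in records],
        columns=["probe_id", "chrom", "pos", "strand"],
    )

    samples_a = [f"{config.group_a_label}_{i + 1:02d}" for i in range(config.n_group_a)]
    samples_b = [f"{config.group_b_label}_{i + 1:02d}" for i in range(config.n_group_b)]
    sample_sheet = pd.DataFrame(
        {
            "sample_id": samples_a + samples_b,
            "group": [config.group_a_label] * config.n_group_a
            + [config.group_b_label] * config.n_group_b,
        }
    )

    n_probes = len(records)
    n_samples = len(sample_sheet)
    mu = np.full((n_probes, n_samples), config.baseline_mean)
    probe_planted = np.array([r[3] for r in records])
    if config.direction == "hypo_in_b":
        affected = slice(config.n_group_a, n_samples)
        mu_a, mu_b = config.baseline_mean, config.baseline_mean - config.effect_delta
    else:
        affected = slice(0, config.n_group_a)
        mu_a, mu_b = config.baseline_mean - config.effect_delta, config.baseline_mean
    mu[np.ix_(probe_planted, range(n_samples)[affected])] = config.baseline_mean - config.effect_delta

    beta_vals = rng.beta(mu * config.precision, (1.0 - mu) * config.precision)
    if config.missing_rate > 0:
        beta_vals[rng.random((n_probes, n_samples)) < config.missing_rate] = np.nan

    beta = pd.DataFrame(beta_vals, index=[r[0] for r in records], columns=sample_sheet["sample_id"].tolist())
    beta.index.name = "probe_id"

    planted_sites = tuple(sites["site_id"].to_numpy()[planted_mask])
    planted_probes = tuple(r[0] for r in records if r[3])
    truth = GroundTruth(
        planted_site_ids=planted_sites,
        planted_probe_ids=planted_probes,
        site_means={
            s: {config.group_a_label: mu_a, config.group_b_label: mu_b} for s in planted_sites
        },
        probe_site={r[0]: r[4] for r in records if r[3]},
    )
    logger.info(
        "simulated cohort: %d probes (%d in sites, %d background), %d samples, %d planted sites",
        n_probes, n_probes - n_bg, n_bg, n_samples, n_planted,
    )
    return beta, manifest, sample_sheet, truth


def simulate_tss_and_gene_sets(
    genome_spec: GenomeSpec,
    n_genes: int,
    n_sets: int,
    set_size_range: tuple[int, int] = (5, 50),
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, tuple[str, list[str]]]]:
    """Random TSS annotation plus GMT-style gene-set collection.

    Genes get unique ids, uniform TSS positions within chromosome bounds
    and random strands; each set samples members without replacement from
    the gene universe.
    """
    _check_genome(genome_spec)
    if n_genes < 1:
        raise ConfigurationError("n_genes must be >= 1")
    if n_sets < 0:
        raise ConfigurationError("n_sets must be >= 0")
    lo, hi = set_size_range
    if lo < 1 or hi < lo:
        raise ConfigurationError(f"invalid set_size_range {set_size_range}")
    if n_sets > 0 and hi > n_genes:
        raise ConfigurationError("set_size_range max exceeds n_genes")
    rng = np.random.default_rng(seed)
    lengths = np.array([length for _, length in genome_spec], dtype=float)
    chrom_idx = rng.choice(len(genome_spec), size=n_genes, p=lengths / lengths.sum())
    tss = pd.DataFrame(
        {
            "gene_id": [f"G{i:05d}" for i in range(n_genes)],
            "gene_name": [f"GN{i:05d}" for i in range(n_genes)],
            "chrom": [genome_spec[i][0] for i in chrom_idx],
            "strand": rng.choice(["+", "-"], size=n_genes),
            "tss": [int(rng.integers(1, genome_spec[i][1] + 1)) for i in chrom_idx],
        }
    )
    universe = tss["gene_id"].to_numpy()
    collection: dict[str, tuple[str, list[str]]] = {}
    for j in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = sorted(rng.choice(universe, size=size, replace=False).tolist())
        collection[f"SET{j:04d}"] = ("synthetic gene set", members)
    return tss, collection


def simulate_ihc(
    n_group_a: int = 39,
    n_group_b: int = 23,
    mean_a: float = 7.0,
    sd_a: float = 2.8,
    mean_b: float = 9.2,
    sd_b: float = 4.0,
    score_max: int = 14,
    seed: int = 0,
    group_a_label: str = "NFPA",
    group_b_label: str = "GHPA",
) -> pd.DataFrame:
    """Per-sample additive IHC scores from truncated normals.

    Scores are drawn from a normal truncated to [0, score_max] and rounded
    to the integer score lattice. Defaults follow the emulated TMA cohort:
    39 nonfunctional tumors at 7.0 +/- 2.8 vs 23 hormone-secreting tumors
    at 9.2 +/- 4.0, on a 0-14 scale (two replicate cores, 0-7 each).
    """
    if n_group_a < 0 or n_group_b < 0:
        raise ConfigurationError("group sizes must be non-negative")
    if sd_a <= 0 or sd_b <= 0:
        raise ConfigurationError("standard deviations must be > 0")
    if score_max < 1:
        raise ConfigurationError("score_max must be >= 1")
    rng = np.random.default_rng(seed)

    def draw(n: int, mean: float, sd: float) -> np.ndarray:
        if n == 0:
            return np.array([], dtype=int)
        a, b = (0.0 - mean) / sd, (score_max - mean) / sd
        x = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
        return np.clip(np.rint(x), 0, score_max).astype(int)

    rows = []
    for i, s in enumerate(draw(n_group_a, mean_a, sd_a)):
        rows.append((f"{group_a_label}_T{i + 1:02d}", group_a_label, int(s)))
    for i, s in enumerate(draw(n_group_b, mean_b, sd_b)):
        rows.append((f"{group_b_label}_T{i + 1:02d}", group_b_label, int(s)))
    return pd.DataFrame(rows, columns=["sample_id", "group", "score"])


#: representative percent-positive value for each category, used when
#: decomposing simulated totals into core records
_CATEGORY_PCT = {0: 0.5, 1: 5.0, 2: 20.0, 3: 50.0, 4: 90.0}


def simulate_ihc_cores(scores: pd.DataFrame, cores_per_sample: int = 2) -> pd.DataFrame:
    """Decompose per-sample total scores into replicate core records.

    Each total is split as evenly as possible across ``cores_per_sample``
    cores (each core capped at 7), then each core score c is written as
    intensity = c - min(4, c) and percent-positive category min(4, c), so
    intensity + category recovers c exactly.
    """
    if cores_per_sample < 1:
        raise ConfigurationError("cores_per_sample must be >= 1")
    if scores["score"].max() > 7 * cores_per_sample:
        raise ConfigurationError("total score exceeds cores_per_sample * 7")
    rows = []
    for sample_id, group, total in scores[["sample_id", "group", "score"]].itertuples(index=False):
        base, rem = divmod(int(total), cores_per_sample)
        for r in range(cores_per_sample):
            c = base + (1 if r < rem else 0)
            category = min(4, c)
            intensity = c - category
            rows.append((sample_id, group, r + 1, intensity, _CATEGORY_PCT[category]))
    return pd.DataFrame(
        rows, columns=["sample_id", "group", "core_replicate", "intensity", "percent_positive"]
    )


def tss_at_planted_probes(
    manifest: pd.DataFrame,
    truth: GroundTruth,
    genome_spec: GenomeSpec,
    n_background_genes: int = 100,
    clearance: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """TSS annotation placing one gene exactly at each planted probe.

    Planted probes land at distance 0 from their own gene's TSS (strand
    +), so they are promoter hits by construction; background genes are
    rejection-sampled at least ``clearance`` bp away from every probe so
    they can never collect promoter-proximal units. Useful for scoring
    promoter-gene recovery against truth.
    """
    _check_genome(genome_spec)
    rng = np.random.default_rng(seed)
    coords = manifest.set_index("probe_id")
    rows = []
    for i, probe in enumerate(truth.planted_probe_ids):
        rows.append(
            (f"PG{i:05d}", f"PGN{i:05d}", coords.loc[probe, "chrom"], "+",
             int(coords.loc[probe, "pos"]))
        )
    pos_by_chrom = {
        chrom: np.sort(sub["pos"].to_numpy(np.int64))
        for chrom, sub in manifest.groupby("chrom", sort=False)
    }
    lengths = np.array([length for _, length in genome_spec], dtype=float)
    placed = 0
    while placed < n_background_genes:
        ci = int(rng.choice(len(genome_spec), p=lengths / lengths.sum()))
        chrom, length = genome_spec[ci]
        tss = int(rng.integers(1, length + 1))
        probes = pos_by_chrom.get(chrom)
        if probes is not None and probes.size:
            j = np.searchsorted(probes, tss)
            near = [probes[k] for k in (j - 1, j) if 0 <= k < probes.size]
            if near and min(abs(tss - p) for p in near) < clearance:
                continue
        rows.append((f"BG{placed:05d}", f"BGN{placed:05d}", chrom, "+", tss))
        placed += 1
    return pd.DataFrame(rows, columns=["gene_id", "gene_name", "chrom", "strand", "tss"])


@dataclass
class SimulatedBundle:
    sites: pd.DataFrame
    beta: pd.DataFrame
    manifest: pd.DataFrame
    sample_sheet: pd.DataFrame
    tss: pd.DataFrame
    gene_sets: dict[str, tuple[str, list[str]]]
    ihc_scores: pd.DataFrame
    ihc_cores: pd.DataFrame
    truth: GroundTruth


def simulate_bundle(
    config: SimulationConfig | None = None,
    genome_spec: GenomeSpec | None = None,
    n_genes: int = 800,
    n_sets: int = 50,
    set_size_range: tuple[int, int] = (5, 50),
    site_width: int = 200,
) -> SimulatedBundle:
    """Generate a complete study bundle from one seed.

    All randomness flows from ``config.seed``; sub-stages use fixed
    offsets of it so the bundle is reproducible end to end.
    """
    config = (config or SimulationConfig()).validate()
    genome_spec = genome_spec or DEFAULT_GENOME
    seeds = np.random.SeedSequence(config.seed).generate_state(4) % (2**31)
    sites = simulate_binding_sites(genome_spec, config.n_sites, site_width, seed=int(seeds[0]))
    cohort_cfg = dataclasses.replace(config, seed=int(seeds[1]))
    beta, manifest, sheet, truth = simulate_cohort(cohort_cfg, sites, genome_spec)
    tss, gene_sets = simulate_tss_and_gene_sets(
        genome_spec, n_genes, n_sets, set_size_range, seed=int(seeds[2])
    )
    ihc_scores = simulate_ihc(
        seed=int(seeds[3]),
        group_a_label=config.group_a_label,
        group_b_label=config.group_b_label,
    )
    ihc_cores = simulate_ihc_cores(ihc_scores)
    return SimulatedBundle(sites, beta, manifest, sheet, tss, gene_sets, ihc_scores, ihc_cores, truth)


def write_bundle(bundle: SimulatedBundle, outdir: str | Path) -> dict[str, Path]:
    """Write every bundle component to ``outdir``; returns the path map."""
    from . import io as gio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "sites": out / "binding_sites.bed",
        "beta": out / "beta_matrix.tsv",
        "manifest": out / "probe_manifest.csv",
        "sample_sheet": out / "sample_sheet.csv",
        "tss": out / "tss_annotation.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "ihc_scores": out / "ihc_scores.csv",
        "ihc_cores": out / "ihc_cores.csv",
        "truth": out / "truth.json",
    }
    gio.write_bed(bundle.sites, paths["sites"])
    gio.write_beta_matrix(bundle.beta, paths["beta"])
    gio.write_manifest(bundle.manifest, paths["manifest"])
    gio.write_sample_sheet(bundle.sample_sheet, paths["sample_sheet"])
    gio.write_tss(bundle.tss, paths["tss"])
    gio.write_gmt(bundle.gene_sets, paths["gene_sets"])
    bundle.ihc_scores.to_csv(paths["ihc_scores"], index=False)
    bundle.ihc_cores.to_csv(paths["ihc_cores"], index=False)
    bundle.truth.to_json(paths["truth"])
    return paths
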