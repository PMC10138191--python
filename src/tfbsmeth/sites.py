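"""Probe-to-binding-site intersection and hypomethylation event calling.

A probe at 1-based position p overlaps a half-open site [s, e) iff
s <= p-1 < e; this is the only place the two coordinate conventions meet.
A beta value strictly below the cutoff (default 0.7) is a hypomethylation
event; a missing beta yields a missing event, never a False.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 0.7

SITE_AGGREGATIONS = ("mean", "median", "min")


@dataclass(frozen=True)
class ProbeSiteAssignment:
    """Bidirectional probe <-> site overlap mapping.

    Both mappings are complete (every probe and every site appears, with
    an empty tuple when there is no overlap) and sorted, so the object is
    deterministic and independent of input ordering. A probe overlapping
    several sites maps to each of them.
    """

    probe_to_sites: dict[str, tuple[str, ...]]
    site_to_probes: dict[str, tuple[str, ...]]

    @property
    def assigned_probes(self) -> list[str]:
        return [p for p, s in self.probe_to_sites.items() if s]

    def n_overlaps(self) -> int:
        return sum(len(s) for s in self.probe_to_sites.values())


def assign_probes_to_sites(manifest: pd.DataFrame, sites: pd.DataFrame) -> ProbeSiteAssignment:
    """Intersect manifest probes (1-based points) with BED intervals."""
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in sites.groupby("chrom", sort=False):
        tree = IntervalTree()
        for start, end, site_id in zip(sub["start"], sub["end"], sub["site_id"]):
            tree.addi(int(start), int(end), site_id)
        trees[chrom] = tree

    probe_to_sites: dict[str, tuple[str, ...]] = {}
    multi = 0
    for probe_id, chrom, pos in zip(manifest["probe_id"], manifest["chrom"], manifest["pos"]):
        tree = trees.get(chrom)
        hits = tuple(sorted(iv.data for iv in tree.at(int(pos) - 1))) if tree is not None else ()
        if len(hits) > 1:
            multi += 1
        probe_to_sites[probe_id] = hits
    if multi:
        logger.info("%d probe(s) overlap more than one site; counted in each", multi)

    site_to_probes: dict[str, list[str]] = {s: [] for s in sites["site_id"]}
    for probe_id in sorted(probe_to_sites):
        for site_id in probe_to_sites[probe_id]:
            site_to_probes[site_id].append(probe_id)
    return ProbeSiteAssignment(
        probe_to_sites={p: probe_to_sites[p] for p in sorted(probe_to_sites)},
        site_to_probes={s: tuple(sorted(v)) for s, v in sorted(site_to_probes.items())},
    )


def _check_cutoff(cutoff: float) -> None:
    if not 0.0 < cutoff <= 1.0:
        raise ConfigurationError(f"cutoff {cutoff} outside (0, 1]")


def call_hypomethylation(beta, cutoff: float = DEFAULT_CUTOFF):
    """Event indicator: beta strictly under the cutoff.

    Accepts a scalar (returns bool, or None for a missing value) or a
    pandas Series/DataFrame (returns nullable booleans, missing where beta
    is missing).
    """
    _check_cutoff(cutoff)
    if isinstance(beta, (pd.DataFrame, pd.Series)):
        return (beta < cutoff).astype("boolean").mask(beta.isna())
    if beta is None or (isinstance(beta, float) and np.isnan(beta)):
        return None
    if not 0.0 <= beta <= 1.0:
        raise DataError(f"beta value {beta} outside [0, 1]")
    return bool(beta < cutoff)


def site_beta_matrix(
    beta: pd.DataFrame,
    assignment: ProbeSiteAssignment,
    aggregation: str = "mean",
) -> pd.DataFrame:
    """Site x sample beta values, aggregating each site's probes.

    Default is the unweighted mean of non-missing probe betas (most sites
    carry a single probe, so the choice rarely binds); 'median' and 'min'
    are available. A site whose probes are all missing for a sample is
    missing there; sites with no probes are omitted.
    """
    if aggregation not in SITE_AGGREGATIONS:
        raise ConfigurationError(f"aggregation must be one of {SITE_AGGREGATIONS}")
    pairs = [
        (site_id, probe_id)
        for site_id, probes in assignment.site_to_probes.items()
        for probe_id in probes
        if probe_id in beta.index
    ]
    if not pairs:
        raise DataError("assignment has no probe-site overlaps present in the beta matrix")
    site_ids = [s for s, _ in pairs]
    probe_ids = [p for _, p in pairs]
    long = beta.loc[probe_ids]
    grouped = long.groupby(pd.Index(site_ids, name="site_id"), sort=True)
    out = getattr(grouped, aggregation)()
    return out


def per_sample_event_counts(
    beta: pd.DataFrame,
    assignment: ProbeSiteAssignment,
    cutoff: float = DEFAULT_CUTOFF,
    aggregation: str = "mean",
) -> pd.Series:
    """Number of hypomethylated sites per sample.

    A site counts for a sample iff its aggregated beta is non-missing and
    strictly under the cutoff.
    """
    _check_cutoff(cutoff)
    site_beta = site_beta_matrix(beta, assignment, aggregation)
    events = site_beta < cutoff  # NaN compares False, so missing never counts
    counts = events.sum(axis=0).astype(int)
    counts.name = "n_hypomethylated_sites"
    return counts
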