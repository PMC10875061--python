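"""Seeded generator of abundance tables with planted structure.

Emulates the compositional skeleton the visualization is designed to
expose: a *core microbiome* present in every sample, *group-shared* taxa
present only in one cohort's samples, and *sample-specific* taxa present
in exactly one sample. Within each sample, expected relative abundances
follow a log-normal profile — the canonical heavy-tailed shape of
rank-abundance curves in 16S surveys — and counts are drawn multinomially
at a fixed sequencing depth.

So that the planted presence/absence topology is exact (tests and figure
semantics depend on it), every taxon planted as present receives a floor
count of one read before the remaining depth is distributed
multinomially. Row sums therefore equal the depth exactly and planted
prevalences are recovered exactly, at the cost of a slight distortion of
the log-normal profile at low depth.

What this generator does **not** emulate: sequencing error and chimeras,
overdispersion between biological replicates, phylogenetic correlation
between taxa, and rare cross-group leakage of cohort taxa. Real tables
are noisier in all four respects.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .types import RANKS, UNASSIGNED, AbundanceTable, SampleMetadata, TaxonomyTable

__all__ = ["SyntheticSpec", "generate", "write_tables"]


@dataclass
class SyntheticSpec:
    """Parameters of the planted-structure generator.

    Defaults mirror a small 16S cohort study: 10 samples in two groups at
    a depth of 10,000 reads, a core microbiome, per-group marker taxa,
    and a few sample-specific taxa each, with log-normal abundance
    profiles (sigma = 1).
    """

    seed: int = 0
    n_samples: int = 10
    n_groups: int = 2
    n_core: int = 15
    n_group_shared: int = 10
    n_unique_per_sample: int = 5
    depth: int = 10_000
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_groups < 1:
            raise ValidationError("need at least one sample and one group")
        if self.n_samples < self.n_groups:
            raise ValidationError("n_samples must be >= n_groups")
        if min(self.n_core, self.n_group_shared, self.n_unique_per_sample) < 0:
            raise ValidationError("taxon block sizes must be non-negative")
        if self.n_core + self.n_group_shared + self.n_unique_per_sample == 0:
            raise ValidationError("at least one taxon block must be non-empty")
        if self.depth < 1:
            raise ValidationError("depth must be at least 1")
        max_eligible = self.n_core + self.n_group_shared + self.n_unique_per_sample
        if self.depth < max_eligible:
            raise ValidationError(
                f"depth {self.depth} cannot cover the floor count of "
                f"{max_eligible} taxa eligible per sample"
            )
        if self.lognormal_sigma < 0:
            raise ValidationError("lognormal_sigma must be non-negative")

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        with open(path, encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))


def _taxon_blocks(spec: SyntheticSpec):
    """(taxon id, genus, eligible-sample indices) for every taxon."""
    groups = [f"group{g + 1:02d}" for g in range(spec.n_groups)]
    members = {
        g: [i for i in range(spec.n_samples) if i % spec.n_groups == gi]
        for gi, g in enumerate(groups)
    }
    blocks = []
    for c in range(spec.n_core):
        blocks.append((f"core_{c + 1:03d}", "g__core", list(range(spec.n_samples))))
    for gi, g in enumerate(groups):
        for c in range(spec.n_group_shared):
            blocks.append(
                (f"{g}_shared_{c + 1:03d}", f"g__{g}", members[g])
            )
    for s in range(spec.n_samples):
        for c in range(spec.n_unique_per_sample):
            blocks.append(
                (f"s{s + 1:02d}_unique_{c + 1:02d}", f"g__unique_s{s + 1:02d}", [s])
            )
    return groups, members, blocks


def generate(spec: SyntheticSpec) -> tuple[AbundanceTable, TaxonomyTable, SampleMetadata]:
    """Generate (table, taxonomy, metadata); deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    groups, members, blocks = _taxon_blocks(spec)
    sample_ids = [f"sample{i + 1:02d}" for i in range(spec.n_samples)]
    taxon_ids = [tid for tid, _, _ in blocks]
    n_taxa = len(blocks)

    counts = np.zeros((spec.n_samples, n_taxa), dtype=int)
    eligible = np.zeros((spec.n_samples, n_taxa), dtype=bool)
    for j, (_, _, present_in) in enumerate(blocks):
        eligible[present_in, j] = True

    for i in range(spec.n_samples):
        idx = np.flatnonzero(eligible[i])
        weights = rng.lognormal(
            mean=spec.lognormal_mu, sigma=spec.lognormal_sigma, size=len(idx)
        )
        probs = weights / weights.sum()
        counts[i, idx] = 1  # floor: planted presence is exact
        residual = spec.depth - len(idx)
        if residual > 0:
            counts[i, idx] += rng.multinomial(residual, probs)

    table = AbundanceTable(
        pd.DataFrame(counts, index=sample_ids, columns=taxon_ids)
    )

    assignments = {}
    for j, (tid, genus, _) in enumerate(blocks):
        assignments[tid] = (
            "d__Bacteria",
            "k__Bacteria",
            "p__Synthetica",
            "c__Synthetica",
            "o__Planted",
            f"f__{genus[3:]}",
            genus,
            UNASSIGNED,  # species deliberately unassigned
        )
    taxonomy = TaxonomyTable(assignments)

    records = {}
    for i, sid in enumerate(sample_ids):
        group = groups[i % spec.n_groups]
        records[sid] = {"group": group, "replicate": i // spec.n_groups + 1}
    metadata = SampleMetadata(records=records, group_key="group")
    return table, taxonomy, metadata


def write_tables(spec: SyntheticSpec, outdir) -> dict[str, str]:
    """Generate and write the three TSVs; returns the file paths."""
    import os

    from . import io as io_mod

    table, taxonomy, metadata = generate(spec)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "abundance": os.path.join(outdir, "abundance.tsv"),
        "taxonomy": os.path.join(outdir, "taxonomy.tsv"),
        "metadata": os.path.join(outdir, "metadata.tsv"),
    }
    io_mod.write_abundance_table(table, paths["abundance"])
    io_mod.write_taxonomy_table(taxonomy, paths["taxonomy"])
    io_mod.write_sample_metadata(metadata, paths["metadata"])
    return paths
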