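"""Study-shaped synthetic fixtures: an 11-group ancient+modern sampling
design with geogroup-labelled modern samples and clustering-derived
haplogroup labels, plus small hand-checkable toy fixtures.

These stand in for real mitogenome datasets so that every downstream stage
(masking, summary statistics, ABC, dating, structure analyses) is testable
without any download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from . import coalsim
from .coalsim import (
    GEOGROUPS,
    GROUPS_11,
    ModelTemplate,
    MutationModel,
    model_library,
    simulate_dataset,
)
from .mito_data import (
    Alignment,
    SampleMetadata,
    write_fasta,
    write_metadata,
)
from .sumstats import pairwise_differences

#: Reduced default locus length for fixtures; statistics scale linearly in
#: L, so tests run on a 2 kb window of the 16.6 kb mitogenome.
DEFAULT_FIXTURE_L = 2_000


@dataclass
class StudyDesign:
    """Sampling design: group sizes/ages and the modern geogroup partition."""

    groups: list[tuple[str, str, int, float, float]] = field(
        default_factory=lambda: list(GROUPS_11)
    )
    geogroups: dict[str, int] = field(default_factory=lambda: dict(GEOGROUPS))

    def __post_init__(self) -> None:
        if any(g[2] < 1 for g in self.groups):
            raise ValueError("group sizes must be >= 1")
        ages = [g[3] for g in self.groups]
        if ages != sorted(ages, reverse=True):
            raise ValueError("group ages must decrease from oldest to modern")

    @property
    def n_total(self) -> int:
        return sum(g[2] for g in self.groups)


def assign_haplogroup_labels(
    aln: Alignment,
    threshold: float = 3.0,
    prefix: str = "SYN",
) -> list[str]:
    """Synthetic haplogroup labels via single-linkage sequence clustering.

    Sequences within ``threshold`` pairwise differences of a cluster member
    share a label.  This yields realistically sparse group-by-haplogroup
    contingency tables without requiring a real phylogeny.
    """
    if aln.n == 1:
        return [f"{prefix}1"]
    d = pairwise_differences(aln.matrix)
    clusters = fcluster(linkage(d, method="single"), t=threshold, criterion="distance")
    return [f"{prefix}{c}" for c in clusters]


def generate_study(
    design: StudyDesign | None = None,
    generating_model: str | ModelTemplate = "G",
    seed: int = 0,
    L: int = DEFAULT_FIXTURE_L,
    mu_site_gen: float = 4.16e-7,
    haplogroup_threshold: float = 3.0,
) -> tuple[Alignment, list[SampleMetadata]]:
    """Simulate one study-shaped dataset under a generating demography.

    Metadata carry the analysis-group label, per-simulation radiocarbon-
    drawn ages, geogroup labels for modern samples (partitioned per the
    design) and clustering-derived haplogroup labels.
    """
    design = design or StudyDesign()
    rng = np.random.default_rng(seed)
    if isinstance(generating_model, str):
        template = model_library(generating_model)
    else:
        template = generating_model
    template = ModelTemplate(
        name=template.name,
        priors=template.priors,
        scheme=coalsim.SamplingScheme(
            [
                coalsim.SampleGroup(name, deme_for(template, name), n, age, sd)
                for name, _, n, age, sd in design.groups
            ]
        )
        if not _uses_geo_demes(template)
        else template.scheme,
        builder=template.builder,
    )
    mut = MutationModel(L=L, mu_site_gen=mu_site_gen)
    ds = simulate_dataset(template, mut, rng)

    labels = assign_haplogroup_labels(ds.alignment, threshold=haplogroup_threshold)
    geo_cycle = _geogroup_assignment(design, ds.metadata)
    meta = []
    for m, hap in zip(ds.metadata, labels):
        geo = m.geogroup if m.geogroup is not None else geo_cycle.get(m.sample_id)
        meta.append(
            SampleMetadata(
                sample_id=m.sample_id,
                group=m.group,
                geogroup=geo,
                age_bp=m.age_bp,
                age_ci95=m.age_ci95,
                haplogroup=hap,
            )
        )
    return ds.alignment, meta


def _uses_geo_demes(template: ModelTemplate) -> bool:
    return any(g.name.startswith("modern_") for g in template.scheme.groups)


def deme_for(template: ModelTemplate, group_name: str) -> str:
    for g in template.scheme.groups:
        if g.name == group_name:
            return g.deme
    raise ValueError(f"group {group_name!r} not in template scheme")


def _geogroup_assignment(design: StudyDesign, metadata) -> dict[str, str]:
    """Partition the modern samples into the design's geogroups, in order."""
    modern_ids = [m.sample_id for m in metadata if m.age_bp == 0 and m.group.startswith("modern")]
    out: dict[str, str] = {}
    i = 0
    for geo, size in design.geogroups.items():
        for _ in range(size):
            if i < len(modern_ids):
                out[modern_ids[i]] = geo
                i += 1
    # Any remainder (scaled designs) cycles through the geogroups.
    geos = list(design.geogroups)
    while i < len(modern_ids):
        out[modern_ids[i]] = geos[i % len(geos)]
        i += 1
    return out


def write_study(
    out_dir: str | Path,
    design: StudyDesign | None = None,
    generating_model: str = "G",
    seed: int = 0,
    L: int = DEFAULT_FIXTURE_L,
) -> dict[str, Path]:
    """Generate a study and write modern.fasta / ancient.fasta / metadata.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aln, meta = generate_study(design, generating_model, seed=seed, L=L)
    modern_idx = [i for i, m in enumerate(meta) if m.age_bp == 0]
    ancient_idx = [i for i, m in enumerate(meta) if m.age_bp > 0]
    paths = {
        "modern": out_dir / "modern.fasta",
        "ancient": out_dir / "ancient.fasta",
        "metadata": out_dir / "metadata.tsv",
    }
    write_fasta(aln.take(modern_idx), paths["modern"])
    write_fasta(aln.take(ancient_idx), paths["ancient"])
    write_metadata(meta, paths["metadata"])
    return paths


# ---------------------------------------------------------------------------
# Toy fixtures


def generate_toy(name: str):
    """Hand-checkable fixtures used throughout the test-suite examples.

    - ``paleolithic_hd``: 12 sequences forming exactly 11 haplotypes (ten
      singletons, one pair) — unbiased Hd rounds to 0.98.
    - ``bronze_hd``: 17 sequences forming 16 haplotypes (one pair) — Hd
      rounds to 0.99.
    - ``star_rho``: star mutation tree with tip counts {2, 3, 4}.
    - ``fixed_diff_pops``: two internally monomorphic populations with one
      fixed difference (FST = 1).
    """
    if name == "paleolithic_hd":
        return _distinct_plus_pair(n=12, L=40)
    if name == "bronze_hd":
        return _distinct_plus_pair(n=17, L=40)
    if name == "star_rho":
        from .rho_dating import star_tree

        return star_tree([2, 3, 4])
    if name == "fixed_diff_pops":
        base_a = "A" * 20
        base_b = "A" * 19 + "T"
        pop1 = Alignment.from_sequences(["a1", "a2", "a3"], [base_a] * 3)
        pop2 = Alignment.from_sequences(["b1", "b2", "b3"], [base_b] * 3)
        return pop1, pop2
    raise ValueError(f"unknown toy fixture {name!r}")


def _distinct_plus_pair(n: int, L: int) -> Alignment:
    """n sequences: n-1 distinct haplotypes, the last two identical."""
    if n < 3 or L < n:
        raise ValueError("need n >= 3 and L >= n")
    bases = ["A"] * L
    seqs = []
    for i in range(n - 1):
        s = bases.copy()
        if i > 0:  # sequence 0 is the reference haplotype
            s[i] = "T"
        seqs.append("".join(s))
    seqs.append(seqs[-1])  # duplicate the final haplotype
    ids = [f"s{i + 1}" for i in range(n)]
    return Alignment.from_sequences(ids, seqs)
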