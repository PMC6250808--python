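"""Synthetic two-group expression data with known planted structure.

Generates matrices carrying three kinds of ground truth that the pipeline
should recover: planted mean-shift genes (DEGs), planted correlated modules
driven by a shared latent factor, and group-specific module activity (hub
rewiring between groups).  Expression is simulated on a log-like scale;
an optional count mode exponentiates and Poisson-samples to exercise
robustness only.

Within a module with loading rho and residual noise noise_sd, a gene value
in the active group is ``baseline + rho * z_sample + noise`` with z the
sample's shared standard-normal factor draw, so the expected within-module
correlation is rho^2 / (rho^2 + noise_sd^2) and ~0 in the inactive group.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from coexscreen.io import CASE, CONTROL, ExpressionMatrix, GeneSetCollection, SampleDesign

ACTIVE_CHOICES = ("control", "case", "both")


@dataclass(frozen=True)
class ModuleSpec:
    """A planted correlated gene module.

    ``members`` are gene indices into the matrix, ``rho`` the latent-factor
    loading in (0, 1), ``active_in`` the group(s) where the factor drives
    expression.  ``member_loadings`` optionally overrides the loading per
    member (e.g. to plant a weaker, intermediate hub inside a module).
    """

    members: tuple[int, ...]
    rho: float
    active_in: str = "both"
    member_loadings: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.rho < 1.0):
            raise ValueError(f"module loading rho must be in (0, 1), got {self.rho}")
        if self.active_in not in ACTIVE_CHOICES:
            raise ValueError(f"active_in must be one of {ACTIVE_CHOICES}")
        if len(self.members) == 0:
            raise ValueError("module has no members")
        if self.member_loadings is not None:
            if len(self.member_loadings) != len(self.members):
                raise ValueError("member_loadings must match members in length")
            if any(not (0.0 < l < 1.0) for l in self.member_loadings):
                raise ValueError("member loadings must be in (0, 1)")

    def loadings(self) -> tuple[float, ...]:
        if self.member_loadings is not None:
            return self.member_loadings
        return tuple(self.rho for _ in self.members)


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic two-group dataset."""

    n_genes: int
    n_control: int = 9
    n_case: int = 18
    modules: list[ModuleSpec] = field(default_factory=list)
    deg_fraction: float = 0.0
    deg_log2fc: float = 2.0
    planted_deg_indices: tuple[int, ...] | None = None
    noise_sd: float = 0.25
    baseline_mean: float = 5.0
    baseline_sd: float = 1.0
    lnc_fraction: float = 0.0
    counts_mode: bool = False
    allow_overlap: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_control < 3 or self.n_case < 3:
            raise ValueError("need at least 3 samples per group")
        if not (0.0 <= self.deg_fraction <= 1.0):
            raise ValueError("deg_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not (0.0 <= self.lnc_fraction <= 1.0):
            raise ValueError("lnc_fraction must be in [0, 1]")
        if self.planted_deg_indices is not None:
            bad = [i for i in self.planted_deg_indices if not (0 <= i < self.n_genes)]
            if bad:
                raise ValueError(f"planted DEG indices out of range: {bad}")
        seen: set[int] = set()
        for m in self.modules:
            bad = [i for i in m.members if not (0 <= i < self.n_genes)]
            if bad:
                raise ValueError(f"module member indices out of range: {bad}")
            if not self.allow_overlap and seen & set(m.members):
                raise ValueError(
                    "modules overlap; pass allow_overlap=True if intentional"
                )
            seen.update(m.members)


@dataclass
class GroundTruth:
    """What was planted, for downstream recovery checks."""

    planted_deg_ids: list[str]
    module_members: list[list[str]]  # gene ids per module, same order as spec
    module_active_in: list[str]
    expected_hubs_control: list[str]
    expected_hubs_case: list[str]
    expected_negative_dif_degree: list[str]  # control-only module genes
    expected_positive_dif_degree: list[str]  # case-only module genes

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _module_active_in_group(active_in: str, group: str) -> bool:
    return active_in == "both" or active_in == group


def generate_two_group_dataset(
    spec: SyntheticSpec, seed: int | None = None
) -> tuple[ExpressionMatrix, SampleDesign, GroundTruth]:
    """Sample one dataset; identical (spec, seed) gives bit-identical output.

    Per sample, each gene value is baseline + (rho x shared latent draw, if
    the gene's module is active in the sample's group) + planted case-group
    mean shift for DEG genes + Gaussian noise.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    n = spec.n_genes
    n_samples = spec.n_control + spec.n_case
    gene_ids = [f"G{i:05d}" for i in range(n)]
    sample_ids = [f"C{i:03d}" for i in range(spec.n_control)] + [
        f"P{i:03d}" for i in range(spec.n_case)
    ]
    groups = np.array([CONTROL] * spec.n_control + [CASE] * spec.n_case)

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=n)
    values = np.tile(baseline[:, None], (1, n_samples))

    for module in spec.modules:
        z = rng.standard_normal(n_samples)
        active = np.array([_module_active_in_group(module.active_in, g) for g in groups])
        members = np.asarray(module.members)
        loadings = np.asarray(module.loadings())
        # standardize the factor over the active samples: with few samples the
        # raw draw's variance wobbles wildly (chi-square with n-1 df), which
        # would make the realized module correlation uncontrollable
        za = z[active]
        za = (za - za.mean()) / za.std(ddof=0)
        values[np.ix_(members, np.nonzero(active)[0])] += loadings[:, None] * za[None, :]

    # planted DEGs: constant case-group shift, half up / half down
    if spec.planted_deg_indices is not None:
        deg_idx = np.asarray(spec.planted_deg_indices, dtype=int)
        n_deg = deg_idx.size
    else:
        n_deg = int(round(spec.deg_fraction * n))
        deg_idx = rng.choice(n, size=n_deg, replace=False) if n_deg else np.array([], dtype=int)
    signs = np.where(np.arange(n_deg) % 2 == 0, 1.0, -1.0)
    case_cols = np.nonzero(groups == CASE)[0]
    for i, s in zip(deg_idx, signs):
        values[i, case_cols] += s * spec.deg_log2fc

    if spec.noise_sd > 0:
        values += rng.normal(0.0, spec.noise_sd, size=values.shape)

    if spec.counts_mode:
        values = rng.poisson(np.exp2(np.clip(values, None, 30.0))).astype(float)

    biotype = None
    if spec.lnc_fraction > 0:
        n_lnc = int(round(spec.lnc_fraction * n))
        lnc_idx = set(rng.choice(n, size=n_lnc, replace=False).tolist())
        biotype = {
            g: ("lncRNA" if i in lnc_idx else "protein_coding")
            for i, g in enumerate(gene_ids)
        }

    matrix = ExpressionMatrix(gene_ids, sample_ids, values, gene_biotype=biotype)
    design = SampleDesign(dict(zip(sample_ids, groups)))

    module_members = [[gene_ids[i] for i in m.members] for m in spec.modules]
    hubs_control = [
        g
        for m, ids in zip(spec.modules, module_members)
        if _module_active_in_group(m.active_in, CONTROL)
        for g in ids
    ]
    hubs_case = [
        g
        for m, ids in zip(spec.modules, module_members)
        if _module_active_in_group(m.active_in, CASE)
        for g in ids
    ]
    truth = GroundTruth(
        planted_deg_ids=[gene_ids[i] for i in sorted(deg_idx.tolist())],
        module_members=module_members,
        module_active_in=[m.active_in for m in spec.modules],
        expected_hubs_control=hubs_control,
        expected_hubs_case=hubs_case,
        expected_negative_dif_degree=[
            g for m, ids in zip(spec.modules, module_members) if m.active_in == "control" for g in ids
        ],
        expected_positive_dif_degree=[
            g for m, ids in zip(spec.modules, module_members) if m.active_in == "case" for g in ids
        ],
    )
    return matrix, design, truth


def generate_fixture_genesets(
    ground_truth: GroundTruth,
    n_terms: int,
    universe: list[str] | None = None,
    seed: int = 0,
    enriched_size: int = 20,
    background_size: int = 20,
    deg_weight: float = 0.9,
    namespace: str = "fixture",
) -> GeneSetCollection:
    """Gene sets for exercising the enrichment stage.

    The first term draws ``deg_weight`` of its members from the planted
    DEGs (an enriched term); the remaining ``n_terms - 1`` terms are drawn
    uniformly from the universe (background).  Deterministic given the
    seed.
    """
    if n_terms < 1:
        raise ValueError(f"n_terms must be >= 1, got {n_terms}")
    rng = np.random.default_rng(seed)
    degs = list(ground_truth.planted_deg_ids)
    if universe is None:
        universe = sorted(set(degs) | {g for m in ground_truth.module_members for g in m})
    universe = list(universe)
    non_degs = [g for g in universe if g not in set(degs)]

    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    n_from_deg = min(len(degs), int(round(deg_weight * enriched_size)))
    n_rest = min(len(non_degs), enriched_size - n_from_deg)
    members = []
    if n_from_deg:
        members += rng.choice(degs, size=n_from_deg, replace=False).tolist()
    if n_rest:
        members += rng.choice(non_degs, size=n_rest, replace=False).tolist()
    sets["ENRICHED_1"] = ("planted-DEG-enriched term", tuple(sorted(members)))

    for k in range(2, n_terms + 1):
        size = min(len(universe), background_size)
        bg = rng.choice(universe, size=size, replace=False).tolist()
        sets[f"BACKGROUND_{k}"] = ("background term", tuple(sorted(bg)))
    return GeneSetCollection(sets, namespace=namespace)
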