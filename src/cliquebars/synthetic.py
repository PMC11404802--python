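"""Synthetic two-group cohorts of correlation matrices.

The generator emulates the structure the pipeline assumes in real
resting-state cohorts: each subject's matrix is the *sample* correlation of
T multivariate-normal draws (T = 500, matching a 6-minute multiband scan)
from a latent block (modular) covariance — communities of regions with
higher within- than between-module correlation.

The case group differs from controls only in the *ranking structure* of its
weights, because the density filtration is invariant under monotone weight
transforms: very strong edges are concentrated on a few disjoint node sets
(strong pairs and small hub cliques, their number growing with `effect`).
Pair and hub members merge almost immediately (a sharp peak of very short
0-dimensional bars) and hub cliques fill their own cycles with triangles as
they form (fewer, shorter 1-dimensional bars), so the case group has lower
persistent entropy in dimensions 0 and 1, while `effect = 0` makes the two
groups exchangeable by construction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .network import CohortManifest, WeightedNetwork

__all__ = ["CohortSpec", "SyntheticSubject", "generate_subject",
           "generate_cohort", "generate_cohort_to_dir"]

#: Effect size at which the pipeline's dim-0 entropy t-test reaches >= 80%
#: power at the study's group sizes (19 control / 24 case); see docs.
DEFAULT_EFFECT = 1.0


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults reproduce the study conditions: 259 nodes, 19 controls and
    24 cases, sample correlations over T = 500 time points, ages 13-17,
    sex assigned independently of group.
    """

    n_nodes: int = 259
    n_control: int = 19
    n_case: int = 24
    n_timepoints: int = 500
    n_modules: int = 8
    r_within: float = 0.35
    r_between: float = 0.05
    effect: float = DEFAULT_EFFECT
    pairs_per_effect: float = 16.0  # case-group strong pairs = round(16*effect)
    hubs_per_effect: float = 1.0  # case-group hub cliques = round(1*effect)
    hub_size: int = 6
    strong_corr: float = 0.55
    p_female: float = 15 / 43
    age_range: tuple[int, int] = (13, 17)
    sex_group_confound: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_between < self.r_within < 1.0):
            raise ValueError("need 0 <= r_between < r_within < 1")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")
        if self.n_modules < 1 or self.n_modules > self.n_nodes:
            raise ValueError("invalid number of modules")
        if self.n_control < 1 or self.n_case < 1:
            raise ValueError("need at least one subject per group")

    def module_sizes(self) -> np.ndarray:
        """Near-equal partition of the nodes into modules (sums to n_nodes)."""
        base = self.n_nodes // self.n_modules
        sizes = np.full(self.n_modules, base, dtype=int)
        sizes[: self.n_nodes - base * self.n_modules] += 1
        return sizes

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["age_range"] = list(d["age_range"])
        Path(path).write_text(json.dumps(d, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortSpec":
        d = json.loads(Path(path).read_text())
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        return cls(**d)


@dataclass
class SyntheticSubject:
    subject_id: str
    group: str  # "control" | "case"
    sex: int  # 0 = male, 1 = female
    age: float
    matrix: np.ndarray = field(repr=False)
    params: dict = field(default_factory=dict, repr=False)

    def network(self) -> WeightedNetwork:
        return WeightedNetwork(self.matrix.copy(), subject_id=self.subject_id)


def _latent_structure(
    spec: CohortSpec, group: str, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Per-node module labels, within-module correlations and hub cliques."""
    sizes = spec.module_sizes()
    labels = np.repeat(np.arange(spec.n_modules), sizes)
    within = np.full(spec.n_modules, spec.r_within)
    hubs: list[np.ndarray] = []
    if group == "case" and spec.effect > 0:
        # heavy-edge concentration: disjoint node sets whose internal edges
        # dominate the weight ranking.  Hub cliques merge almost immediately
        # and their cycles are filled by triangles as soon as they form
        # (fewer, shorter 1-dimensional bars); strong pairs add very early
        # component merges (a sharper peak of short 0-dimensional bars).
        n_hubs = int(round(spec.hubs_per_effect * spec.effect))
        n_pairs = int(round(spec.pairs_per_effect * spec.effect))
        perm = rng.permutation(spec.n_nodes)
        pos = 0
        for size in [spec.hub_size] * n_hubs + [2] * n_pairs:
            if pos + size > spec.n_nodes:
                break  # node budget exhausted at this effect level
            hubs.append(perm[pos:pos + size].copy())
            pos += size
    return labels, within, hubs


def generate_subject(
    spec: CohortSpec,
    group: str,
    rng: np.random.Generator,
    subject_id: str = "",
) -> SyntheticSubject:
    """Draw one subject: latent factor series -> sample correlation matrix.

    The latent covariance is a factor model (global factor for the
    between-module level, one factor per module, one per strong pair), so
    it is positive semidefinite by construction; a residual-variance check
    rejects configurations where the loadings would exceed unit variance.
    """
    if group not in ("control", "case"):
        raise ValueError(f"unknown group {group!r}")
    labels, within, hubs = _latent_structure(spec, group, rng)
    n, T = spec.n_nodes, spec.n_timepoints

    w_node = within[labels].copy()
    s_node = np.zeros(n)
    for h_nodes in hubs:
        # cap the module loading so the hub loading fits in unit variance
        w_node[h_nodes] = np.minimum(w_node[h_nodes], 0.3)
        s_node[h_nodes] = spec.strong_corr

    resid = 1.0 - w_node - s_node
    if np.any(resid <= 0) or np.any(w_node - spec.r_between < 0):
        raise ValueError("latent covariance not positive semidefinite "
                         "(factor loadings exceed unit variance)")

    g = rng.standard_normal((T, 1))
    f = rng.standard_normal((T, spec.n_modules))
    h = (rng.standard_normal((T, len(hubs)))
         if hubs else np.zeros((T, 0)))
    eps = rng.standard_normal((T, n))

    x = (
        math.sqrt(spec.r_between) * g
        + np.sqrt(w_node - spec.r_between) * f[:, labels]
        + eps * np.sqrt(resid)
    )
    for p, h_nodes in enumerate(hubs):
        x[:, h_nodes] += math.sqrt(spec.strong_corr) * h[:, p:p + 1]

    corr = np.corrcoef(x.T)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)

    if spec.sex_group_confound:
        p_f = 0.8 if group == "control" else 0.2
    else:
        p_f = spec.p_female
    sex = int(rng.random() < p_f)
    lo, hi = spec.age_range
    age = int(rng.integers(lo, hi + 1))

    return SyntheticSubject(
        subject_id=subject_id or f"{group}_anon",
        group=group,
        sex=sex,
        age=age,
        matrix=corr,
        params={
            "module_within": within.tolist(),
            "hubs": [h.tolist() for h in hubs],
            "effect": spec.effect if group == "case" else 0.0,
        },
    )


def generate_cohort(spec: CohortSpec) -> list[SyntheticSubject]:
    """All subjects of a cohort, in manifest order (controls then cases).

    Fully reproducible from ``spec.seed``; a given subject's draw depends
    only on the spec and its position.
    """
    rng = np.random.default_rng(spec.seed)
    subjects = []
    for i in range(spec.n_control):
        subjects.append(
            generate_subject(spec, "control", rng, f"control_{i + 1:03d}")
        )
    for i in range(spec.n_case):
        subjects.append(generate_subject(spec, "case", rng, f"case_{i + 1:03d}"))
    return subjects


def generate_cohort_to_dir(
    spec: CohortSpec, outdir: str | Path
) -> tuple[CohortManifest, list[SyntheticSubject]]:
    """Write the cohort's matrices and manifest under `outdir`."""
    from .io import write_correlation_matrix, write_manifest  # cycle guard

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    subjects = generate_cohort(spec)
    rows = []
    for s in subjects:
        fname = f"{s.subject_id}.csv"
        write_correlation_matrix(s.network(), outdir / fname)
        rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "sex": s.sex,
                "age": s.age,
                "matrix_path": fname,
            }
        )
    manifest = CohortManifest(pd.DataFrame(rows))
    write_manifest(manifest, outdir / "manifest.csv")
    spec.to_json(outdir / "cohort_spec.json")
    return manifest, subjects
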