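"""Cohort-level model: from correlation matrices to the topological report.

`CohortPersistence` holds the cohort (one weighted network per subject plus
demographics); `fit()` runs the full pipeline — density clique filtration,
persistent homology, persistent entropy — and returns a
`CohortPersistenceResults` carrying per-subject barcodes, the entropy
table, pooled bar-length KS tests, per-group normality checks, the entropy
t-test with Cohen's d, covariate regressions, and a `summary()` table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nio
from .entropy import bar_lengths, persistent_entropy
from .filtration import build_density_filtration
from .network import CohortManifest, WeightedNetwork
from .persistence import Barcode, compute_persistence
from .stats import (
    GroupComparison,
    PooledLengths,
    RegressionResult,
    compare_groups,
    entropy_regression,
    pool_lengths,
)
from .synthetic import CohortSpec, SyntheticSubject, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["CohortPersistence", "CohortPersistenceResults"]


def _sig12(x):
    """Round floats to 12 significant digits for serialized reports."""
    if isinstance(x, float):
        return float(f"{x:.12g}")
    if isinstance(x, dict):
        return {k: _sig12(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_sig12(v) for v in x]
    return x


class CohortPersistence:
    """Topological comparison model for a two-group cohort of networks.

    Parameters
    ----------
    networks
        One :class:`WeightedNetwork` per subject.
    meta
        DataFrame with columns subject_id, group ("control"/"case"),
        sex (0/1), age; aligned with `networks`.
    """

    def __init__(self, networks: list[WeightedNetwork], meta: pd.DataFrame):
        if len(networks) != len(meta):
            raise ValueError("networks and meta must have equal length")
        required = {"subject_id", "group", "sex", "age"}
        if not required.issubset(meta.columns):
            raise ValueError(f"meta must have columns {sorted(required)}")
        self.networks = list(networks)
        self.meta = meta.reset_index(drop=True).copy()

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_manifest(cls, path: str | Path) -> "CohortPersistence":
        """Load every subject's matrix listed in a cohort manifest."""
        manifest = nio.load_manifest(path)
        networks = [
            nio.load_correlation_matrix(row.matrix_path, subject_id=row.subject_id)
            for row in manifest.table.itertuples()
        ]
        return cls(networks, manifest.table.drop(columns=["matrix_path"]))

    @classmethod
    def from_synthetic(cls, spec: CohortSpec) -> "CohortPersistence":
        """Generate a synthetic cohort in memory from `spec`."""
        subjects = generate_cohort(spec)
        return cls.from_subjects(subjects)

    @classmethod
    def from_subjects(cls, subjects: list[SyntheticSubject]) -> "CohortPersistence":
        meta = pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in subjects],
                "group": [s.group for s in subjects],
                "sex": [int(s.sex) for s in subjects],
                "age": [float(s.age) for s in subjects],
            }
        )
        return cls([s.network() for s in subjects], meta)

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        max_dim: int = 2,
        density_cap: float | None = None,
        use_absolute_weights: bool = False,
        lilliefors_mc: int = 2000,
        stats_seed: int = 12345,
    ) -> "CohortPersistenceResults":
        """Run the pipeline for every subject and assemble the group report.

        With ``max_dim=1`` only dimension-0 results (components) are
        produced; ``max_dim=2`` adds dimension-1 (cycles).
        """
        CohortManifest(
            self.meta.assign(matrix_path="-")
        ).check_group_sizes()  # reuse validation: >= 2 subjects per group
        dims = (0,) if max_dim == 1 else (0, 1)
        barcodes: dict[str, Barcode] = {}
        lengths: dict[str, dict[int, np.ndarray]] = {}
        rows = []
        for net, row in zip(self.networks, self.meta.itertuples()):
            sid = row.subject_id
            logger.info("subject %s: filtration and persistence", sid)
            filt = build_density_filtration(
                net,
                max_dim=max_dim,
                density_cap=density_cap,
                use_absolute_weights=use_absolute_weights,
            )
            bc = compute_persistence(filt)
            barcodes[sid] = bc
            per_dim = {}
            ent = {}
            for d in dims:
                ls = bar_lengths(bc, d)
                per_dim[d] = ls.lengths
                ent[d] = persistent_entropy(ls).value
            lengths[sid] = per_dim
            rows.append(
                {
                    "subject_id": sid,
                    "group": row.group,
                    "sex": row.sex,
                    "age": row.age,
                    "e0": ent[0],
                    "e1": ent.get(1, np.nan),
                    "n_bars_dim0": bc.n_bars(0),
                    "n_bars_dim1": bc.n_bars(1) if max_dim == 2 else 0,
                }
            )
        table = pd.DataFrame(rows)
        groups = dict(zip(table["subject_id"], table["group"]))
        pooled = pool_lengths(lengths, groups, dims=dims)

        comparisons = {
            d: compare_groups(table, pooled, d, lilliefors_mc, stats_seed)
            for d in dims
        }
        regressions = {}
        for d in dims:
            for scaling in ("none", "minmax"):
                try:
                    regressions[(d, scaling)] = entropy_regression(
                        table, d, scaling
                    )
                except ValueError as exc:
                    logger.warning("regression e%d (%s) skipped: %s",
                                   d, scaling, exc)
        config = {
            "max_dim": max_dim,
            "density_cap": density_cap,
            "use_absolute_weights": use_absolute_weights,
            "lilliefors_mc": lilliefors_mc,
            "stats_seed": stats_seed,
        }
        return CohortPersistenceResults(
            model=self,
            barcodes=barcodes,
            entropy_table=table,
            pooled=pooled,
            comparisons=comparisons,
            regressions=regressions,
            config=config,
        )


@dataclass
class CohortPersistenceResults:
    """Fitted results: barcodes, entropies and the statistical report."""

    model: CohortPersistence
    barcodes: dict[str, Barcode]
    entropy_table: pd.DataFrame
    pooled: PooledLengths
    comparisons: dict[int, GroupComparison]
    regressions: dict[tuple[int, str], RegressionResult]
    config: dict = field(default_factory=dict)

    @property
    def bar_counts(self) -> pd.DataFrame:
        """Per-subject bar counts (the dimension-1 count is the number of
        1-dimensional holes per subject)."""
        return self.entropy_table[
            ["subject_id", "group", "n_bars_dim0", "n_bars_dim1"]
        ].copy()

    def group_means(self, dim: int) -> dict[str, tuple[float, float]]:
        """Group mean +/- SEM of e_dim."""
        t = self.comparisons[dim].ttest
        return {
            "control": (t["mean_control"], t["sem_control"]),
            "case": (t["mean_case"], t["sem_case"]),
        }

    # -- reporting ---------------------------------------------------------

    def to_dict(self) -> dict:
        out = {
            "config": self.config,
            "n_subjects": len(self.entropy_table),
            "n_control": int((self.entropy_table["group"] == "control").sum()),
            "n_case": int((self.entropy_table["group"] == "case").sum()),
            "comparisons": {
                str(d): c.to_dict() for d, c in self.comparisons.items()
            },
            "regressions": {
                f"e{d}_{s}": r.to_dict() for (d, s), r in self.regressions.items()
            },
        }
        return _sig12(out)

    def summary(self) -> str:
        lines = ["Cohort persistent-entropy comparison", "=" * 40]
        t = self.entropy_table
        lines.append(
            f"subjects: {len(t)} "
            f"({(t['group'] == 'control').sum()} control, "
            f"{(t['group'] == 'case').sum()} case)"
        )
        lines.append(f"config: {self.config}")
        for d, c in self.comparisons.items():
            tt = c.ttest
            lines += [
                "",
                f"dimension {d}",
                "-" * 40,
                (f"  entropy  control {tt['mean_control']:.3f} +/- "
                 f"{tt['sem_control']:.3f}   case {tt['mean_case']:.3f} +/- "
                 f"{tt['sem_case']:.3f}"),
                (f"  t = {tt['t']:.4f}  p = {tt['p']:.4g}  "
                 f"df = {tt['df']:.0f}  Cohen's d = {tt['cohen_d']:.4f}"),
                (f"  pooled bar-length KS: D = {c.ks_D:.4f}  "
                 f"p = {c.ks_p:.4g}  sizes = {c.pooled_sizes}"),
                (f"  Lilliefors (MC): control D = {c.lilliefors_control[0]:.4f} "
                 f"p = {c.lilliefors_control[1]:.4f}; case D = "
                 f"{c.lilliefors_case[0]:.4f} p = {c.lilliefors_case[1]:.4f}"),
            ]
            reg = self.regressions.get((d, "none"))
            if reg is not None:
                lines.append(f"  OLS e{d} ~ sex + age + diagnostic "
                             f"(raw scale, n = {reg.n}, "
                             f"R^2 = {reg.rsquared:.3f}):")
                for name, row in reg.to_frame().iterrows():
                    lines.append(
                        f"    {name:<10} beta = {row['coef']:+.4f}  "
                        f"SE = {row['std_err']:.4f}  t = {row['t']:+.3f}  "
                        f"p = {row['p']:.4f}"
                    )
        lines.append("")
        lines.append("p-values are unadjusted for multiple testing.")
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> None:
        """Write all artifacts: barcodes, tables, JSON + text report."""
        outdir = Path(outdir)
        bdir = outdir / "barcodes"
        bdir.mkdir(parents=True, exist_ok=True)
        for sid, bc in self.barcodes.items():
            nio.write_barcode(bc, bdir / f"{sid}.csv")
        nio.write_entropy_table(self.entropy_table, outdir / "entropy.csv")
        self.bar_counts.to_csv(outdir / "bar_counts.csv", index=False)
        (outdir / "report.json").write_text(
            json.dumps(self.to_dict(), indent=2) + "\n"
        )
        (outdir / "report.txt").write_text(self.summary() + "\n")
        (outdir / "config.json").write_text(
            json.dumps(_sig12(self.config), indent=2) + "\n"
        )
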