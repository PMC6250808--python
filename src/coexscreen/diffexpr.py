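"""Differential expression stage: log2 fold changes, Welch tests, BH-FDR.

The count-model DE step of the original study design is not re-implemented;
the stand-in is a Welch two-sample t-test on the normalized (log-scale)
matrix.  Users with a proper count-based DE result can bypass this stage by
supplying a precomputed DEG table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from coexscreen.io import ExpressionMatrix, SampleDesign

#: default DEG call thresholds (strict inequalities)
DEFAULT_FDR_MAX = 0.05
DEFAULT_MIN_ABS_LOG2FC = 1.0


@dataclass(frozen=True)
class DEGRecord:
    """Per-gene differential-expression result.

    ``direction`` is ``up``/``down`` only when the gene passes the call
    thresholds; everything else is ``ns``.
    """

    gene_id: str
    log2fc: float
    p_value: float
    fdr: float
    direction: str = "ns"


@dataclass
class DEGTable:
    records: list[DEGRecord]
    fdr_max: float = DEFAULT_FDR_MAX
    min_abs_log2fc: float = DEFAULT_MIN_ABS_LOG2FC

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def called_ids(self) -> list[str]:
        return [r.gene_id for r in self.records if r.direction != "ns"]

    def log2fc_of(self) -> dict[str, float]:
        return {r.gene_id: r.log2fc for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [r.gene_id for r in self.records],
                "log2fc": [r.log2fc for r in self.records],
                "p_value": [r.p_value for r in self.records],
                "fdr": [r.fdr for r in self.records],
                "direction": [r.direction for r in self.records],
            }
        )


def compute_log2fc(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    mode: str = "diff_of_logmeans",
    pseudocount: float = 0.0,
) -> np.ndarray:
    """Per-gene log2 fold change, oriented case vs control (positive = higher in case).

    ``diff_of_logmeans`` treats values as already log2-scale and returns the
    difference of group means.  ``ratio_of_means`` computes
    ``log2((case mean + pseudocount) / (control mean + pseudocount))`` and
    requires strictly positive shifted means.
    """
    if mode not in ("diff_of_logmeans", "ratio_of_means"):
        raise ValueError(f"unknown log2fc mode {mode!r}")
    sidx = matrix.sample_index()
    ctrl = [sidx[s] for s in design.samples_in(design.control_label)]
    case = [sidx[s] for s in design.samples_in(design.case_label)]
    if not ctrl or not case:
        raise ValueError("both groups must be nonempty")
    mean_ctrl = matrix.values[:, ctrl].mean(axis=1)
    mean_case = matrix.values[:, case].mean(axis=1)
    if mode == "diff_of_logmeans":
        return mean_case - mean_ctrl
    mean_ctrl = mean_ctrl + pseudocount
    mean_case = mean_case + pseudocount
    bad = (mean_ctrl <= 0) | (mean_case <= 0)
    if np.any(bad):
        genes = [matrix.gene_ids[i] for i in np.nonzero(bad)[0][:5]]
        raise ValueError(
            f"non-positive group mean in ratio mode for genes {genes}; "
            "supply a pseudocount or use diff_of_logmeans"
        )
    return np.log2(mean_case / mean_ctrl)


def two_group_test(matrix: ExpressionMatrix, design: SampleDesign) -> np.ndarray:
    """Welch two-sample t-test per gene; two-sided p in (0, 1].

    Degenerate genes (zero variance in both groups) get p = 1 when group
    means are equal and p -> 0 when they differ with zero spread; both
    groups need at least 2 samples.
    """
    sidx = matrix.sample_index()
    ctrl = [sidx[s] for s in design.samples_in(design.control_label)]
    case = [sidx[s] for s in design.samples_in(design.case_label)]
    if len(ctrl) < 2 or len(case) < 2:
        raise ValueError(
            "Welch test needs >= 2 samples per group; supply a precomputed DEG table instead"
        )
    x = matrix.values[:, case]
    y = matrix.values[:, ctrl]
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(x, y, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    # degenerate genes: zero variance in both groups -> nan from the t-test
    degenerate = np.isnan(p)
    if np.any(degenerate):
        equal_means = np.isclose(x.mean(axis=1), y.mean(axis=1))
        p[degenerate & equal_means] = 1.0
        p[degenerate & ~equal_means] = np.finfo(float).tiny
    return np.clip(p, np.finfo(float).tiny, 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    Adjusted value for the i-th smallest p (1-based rank ``k`` of ``m``) is
    ``min_{j >= k} p_(j) * m / j`` capped at 1; ties share their adjusted
    value and the output is matched to the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adjusted
    return out


def filter_degs(
    table: DEGTable,
    fdr_max: float = DEFAULT_FDR_MAX,
    min_abs_log2fc: float = DEFAULT_MIN_ABS_LOG2FC,
) -> tuple[list[str], list[str]]:
    """Partition called DEGs into (up, down) ids using strict thresholds.

    A gene is called iff ``fdr < fdr_max`` and ``|log2fc| > min_abs_log2fc``
    (both strict).
    """
    up, down = [], []
    for r in table.records:
        if r.fdr < fdr_max and abs(r.log2fc) > min_abs_log2fc:
            (up if r.log2fc > 0 else down).append(r.gene_id)
    return up, down


def make_deg_table(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    mode: str = "diff_of_logmeans",
    fdr_max: float = DEFAULT_FDR_MAX,
    min_abs_log2fc: float = DEFAULT_MIN_ABS_LOG2FC,
    pseudocount: float = 0.0,
) -> DEGTable:
    """Full DE stage: log2fc + Welch p + BH fdr + call, one record per gene."""
    log2fc = compute_log2fc(matrix, design, mode=mode, pseudocount=pseudocount)
    p = two_group_test(matrix, design)
    fdr = bh_adjust(p)
    records = []
    for gene, lfc, pv, q in zip(matrix.gene_ids, log2fc, p, fdr):
        called = q < fdr_max and abs(lfc) > min_abs_log2fc
        direction = ("up" if lfc > 0 else "down") if called else "ns"
        records.append(DEGRecord(gene, float(lfc), float(pv), float(q), direction))
    return DEGTable(records, fdr_max=fdr_max, min_abs_log2fc=min_abs_log2fc)


def read_deg_table(path: str | Path) -> DEGTable:
    """Read a precomputed DEG table TSV (gene_id, log2fc, p_value, fdr[, direction])."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    required = {"gene_id", "log2fc", "p_value", "fdr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing DEG columns {sorted(missing)}")
    records = []
    for row in df.itertuples():
        direction = getattr(row, "direction", "ns")
        records.append(
            DEGRecord(row.gene_id, float(row.log2fc), float(row.p_value), float(row.fdr), direction)
        )
    return DEGTable(records)


def write_deg_table(table: DEGTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")
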